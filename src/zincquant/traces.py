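"""ROI time-series quantification: from raw intensities to per-cell Zn2+.

The pipeline per cell: background-subtract each channel, form the working
signal (FRET/donor ratio for two-channel sensors, the background-subtracted
intensity for a single-channel dye), pull the calibration endpoints from the
chelator and ionophore phases, read off resting and peak values, and convert
both to fractional saturation and concentration through the sensor model.
QC flags (clipped saturation, negative background-subtracted frames, masked
ratio frames, undersized calibration phases) are carried on each cell
record; exclusion is by explicit flag only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core_model import (
    CalibrationEndpoints,
    FractionalSaturation,
    SaturatedSignalError,
    SensorParams,
    conc_from_saturation,
    fractional_saturation,
)
from .protocol import ProtocolPhase, find_phase, validate_phases

__all__ = [
    "RoiTrace",
    "CellQuantification",
    "ExperimentSummary",
    "CalibrationFailedError",
    "background_subtract",
    "fret_ratio",
    "boxcar_smooth",
    "extract_endpoints",
    "resting_value",
    "peak_value",
    "quantify_cell",
    "summarize_experiment",
]

DEFAULT_SMOOTH_WINDOW = 5
MAX_MASKED_FRACTION = 0.2


class CalibrationFailedError(ValueError):
    """The chelator/ionophore phases do not yield usable endpoints."""


@dataclass
class RoiTrace:
    """Per-cell ROI time series: one or two intensity channels plus a
    matched background series per channel.

    ``channels`` is keyed ``{"donor", "fret"}`` for a FRET sensor or
    ``{"dye"}`` for an intensity dye; ``background`` uses the same keys.
    """

    cell_id: str
    time_s: np.ndarray
    channels: dict[str, np.ndarray]
    background: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self.background = {k: np.asarray(v, dtype=float) for k, v in self.background.items()}
        n = self.time_s.size
        if n < 2:
            raise ValueError(f"cell {self.cell_id}: need at least 2 frames")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError(f"cell {self.cell_id}: times must be strictly increasing")
        if set(self.channels) != set(self.background):
            raise ValueError(f"cell {self.cell_id}: channel/background keys differ")
        for k, v in {**self.channels, **self.background}.items():
            if v.size != n:
                raise ValueError(f"cell {self.cell_id}: series {k!r} length {v.size} != {n}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"cell {self.cell_id}: series {k!r} has non-finite values")

    @property
    def n_frames(self) -> int:
        return self.time_s.size

    @property
    def is_ratiometric(self) -> bool:
        return "donor" in self.channels and "fret" in self.channels


def background_subtract(trace: RoiTrace) -> RoiTrace:
    """Subtract the per-frame background from every channel.

    Negative results are kept (they are informative about background-ROI
    placement) and surface later as a QC flag, not an error.
    """
    return RoiTrace(
        cell_id=trace.cell_id,
        time_s=trace.time_s,
        channels={k: v - trace.background[k] for k, v in trace.channels.items()},
        background={k: np.zeros_like(v) for k, v in trace.background.items()},
    )


def fret_ratio(trace: RoiTrace) -> np.ndarray:
    """Background-subtracted FRET/donor ratio series.

    Frames whose donor signal is <= 0 after subtraction cannot produce a
    meaningful ratio; they are returned as NaN (masked) rather than
    interpolated.
    """
    if not trace.is_ratiometric:
        raise ValueError(f"cell {trace.cell_id}: FRET ratio needs donor and fret channels")
    sub = background_subtract(trace)
    donor = sub.channels["donor"]
    fret = sub.channels["fret"]
    ratio = np.full(donor.shape, np.nan)
    ok = donor > 0
    ratio[ok] = fret[ok] / donor[ok]
    return ratio


def boxcar_smooth(y: np.ndarray, window: int) -> np.ndarray:
    """NaN-aware boxcar (moving-average) smoothing with edge shrinkage."""
    if window < 1:
        raise ValueError("window must be >= 1")
    y = np.asarray(y, dtype=float)
    if window == 1:
        return y.copy()
    good = np.isfinite(y)
    filled = np.where(good, y, 0.0)
    num = uniform_filter1d(filled, size=window, mode="constant", cval=0.0)
    den = uniform_filter1d(good.astype(float), size=window, mode="constant", cval=0.0)
    out = np.full(y.shape, np.nan)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def _phase_slice(time_s: np.ndarray, phase: ProtocolPhase) -> np.ndarray:
    return (time_s >= phase.t_start_s) & (time_s < phase.t_end_s)


def extract_endpoints(
    time_s: np.ndarray,
    series: np.ndarray,
    phases: Sequence[ProtocolPhase],
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> CalibrationEndpoints:
    """Calibration endpoints from the chelator minimum and ionophore maximum.

    The series is boxcar-smoothed first so the extrema are not single noisy
    frames — a reproducible surrogate for manual inspection of the
    calibration record.  Raises :class:`CalibrationFailedError` when a phase
    is missing/too short or the extracted maximum does not exceed the
    minimum (e.g. swapped phase annotations).
    """
    phases = validate_phases(phases)
    try:
        chel = find_phase(phases, "chelator")
        iono = find_phase(phases, "ionophore")
    except KeyError as e:
        raise CalibrationFailedError(str(e)) from e
    smoothed = boxcar_smooth(series, smooth_window)
    sel_min = _phase_slice(time_s, chel)
    sel_max = _phase_slice(time_s, iono)
    if sel_min.sum() < smooth_window or sel_max.sum() < smooth_window:
        raise CalibrationFailedError(
            f"calibration phase shorter than the {smooth_window}-frame smoothing window"
        )
    f_min = float(np.nanmin(smoothed[sel_min]))
    f_max = float(np.nanmax(smoothed[sel_max]))
    if not f_max > f_min:
        raise CalibrationFailedError(
            f"ionophore maximum ({f_max:.4g}) does not exceed chelator minimum ({f_min:.4g})"
        )
    return CalibrationEndpoints(f_min=f_min, f_max=f_max)


def resting_value(
    time_s: np.ndarray, series: np.ndarray, phases: Sequence[ProtocolPhase]
) -> float:
    """Mean of the series over the baseline phase."""
    base = find_phase(phases, "baseline")
    sel = _phase_slice(time_s, base)
    if not np.any(sel & np.isfinite(series)):
        raise ValueError("baseline phase contains no usable frames")
    return float(np.nanmean(series[sel]))


def peak_value(
    time_s: np.ndarray,
    series: np.ndarray,
    phases: Sequence[ProtocolPhase],
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> float:
    """Maximum of the smoothed series between stimulation onset and the
    start of the calibration (chelator) phase.

    The search window covers the stimulation and the entire post-stimulation
    recording segment, since individual cells peak at different delays and
    recover at different rates.
    """
    stim = find_phase(phases, "stimulation")
    try:
        window_end = find_phase(phases, "chelator").t_start_s
    except KeyError:
        window_end = float(time_s[-1]) + 1.0
    sel = (time_s >= stim.t_start_s) & (time_s < window_end)
    if sel.sum() < smooth_window:
        raise ValueError(
            f"peak search window has {int(sel.sum())} frames, fewer than the "
            f"{smooth_window}-frame smoothing window"
        )
    smoothed = boxcar_smooth(series, smooth_window)
    return float(np.nanmax(smoothed[sel]))


@dataclass
class CellQuantification:
    """Per-cell quantification with QC provenance.

    Concentrations are in pM and may be NaN when the corresponding
    fractional saturation clipped at 1 (saturated signal).  ``excluded``
    cells carry the failure reason instead of estimates.
    """

    cell_id: str
    resting_fs: Optional[FractionalSaturation] = None
    peak_fs: Optional[FractionalSaturation] = None
    resting_conc_pM: float = float("nan")
    peak_conc_pM: float = float("nan")
    endpoints: Optional[CalibrationEndpoints] = None
    qc_flags: list[str] = field(default_factory=list)
    excluded: bool = False
    exclude_reason: str = ""


def _conc_or_nan(fs: FractionalSaturation, sensor: SensorParams, flags: list[str], tag: str) -> float:
    try:
        return float(conc_from_saturation(fs, sensor))
    except SaturatedSignalError:
        flags.append(f"{tag}_saturated")
        return float("nan")


def quantify_cell(
    trace: RoiTrace,
    phases: Sequence[ProtocolPhase],
    sensor: SensorParams,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    max_masked_fraction: float = MAX_MASKED_FRACTION,
    has_stimulation: Optional[bool] = None,
) -> CellQuantification:
    """Full per-cell quantification: signal, endpoints, resting/peak FS and
    concentration.

    A cell whose calibration fails, or with more than ``max_masked_fraction``
    of frames masked (donor <= 0), is returned as an excluded record with
    the reason; all other anomalies become QC flags on a quantified record.
    """
    phases = validate_phases(phases)
    if has_stimulation is None:
        has_stimulation = any(p.name == "stimulation" for p in phases)
    flags: list[str] = []

    sub = background_subtract(trace)
    if any(np.any(v < 0) for v in sub.channels.values()):
        flags.append("negative_background_subtracted")

    if trace.is_ratiometric:
        series = fret_ratio(trace)
        masked = float(np.mean(~np.isfinite(series)))
        if masked > 0:
            flags.append("masked_frames")
        if masked > max_masked_fraction:
            return CellQuantification(
                trace.cell_id,
                qc_flags=flags,
                excluded=True,
                exclude_reason=f"{masked:.0%} of frames masked (donor <= 0)",
            )
    else:
        (series,) = (sub.channels[k] for k in sub.channels)

    try:
        endpoints = extract_endpoints(trace.time_s, series, phases, smooth_window)
    except CalibrationFailedError as e:
        return CellQuantification(
            trace.cell_id, qc_flags=flags, excluded=True, exclude_reason=str(e)
        )

    rest = resting_value(trace.time_s, series, phases)
    rest_fs = fractional_saturation(rest, endpoints)
    if rest_fs.clipped:
        flags.append("resting_fs_clipped")

    q = CellQuantification(
        cell_id=trace.cell_id,
        resting_fs=rest_fs,
        resting_conc_pM=_conc_or_nan(rest_fs, sensor, flags, "resting"),
        endpoints=endpoints,
        qc_flags=flags,
    )

    if has_stimulation:
        peak = peak_value(trace.time_s, series, phases, smooth_window)
        peak_fs = fractional_saturation(peak, endpoints)
        if peak_fs.clipped:
            flags.append("peak_fs_clipped")
        # noise floor from baseline residuals: a "peak" within noise of the
        # resting level is not evidence of a response
        base_sel = _phase_slice(trace.time_s, find_phase(phases, "baseline"))
        noise_sd = float(np.nanstd(series[base_sel]))
        if peak < rest + 2.0 * noise_sd:
            flags.append("peak_within_noise")
        q.peak_fs = peak_fs
        q.peak_conc_pM = _conc_or_nan(peak_fs, sensor, flags, "peak")
    return q


@dataclass
class ExperimentSummary:
    """Across-cell means and standard errors for one condition."""

    n_cells: int
    n_excluded: int
    mean: dict[str, float]
    sem: dict[str, float]
    exclusion_reasons: list[str] = field(default_factory=list)


def summarize_experiment(cells: Sequence[CellQuantification]) -> ExperimentSummary:
    """Mean and SEM (SD/sqrt(n), sample SD) of FS and concentration across
    included cells; excluded cells are counted with their reasons."""
    included = [c for c in cells if not c.excluded]
    excluded = [c for c in cells if c.excluded]
    if len(included) < 2:
        raise ValueError(f"need >= 2 included cells, have {len(included)}")

    quantities = {
        "resting_fs": [float(c.resting_fs) for c in included],
        "resting_conc_pM": [c.resting_conc_pM for c in included],
    }
    if any(c.peak_fs is not None for c in included):
        quantities["peak_fs"] = [float(c.peak_fs) for c in included if c.peak_fs is not None]
        quantities["peak_conc_pM"] = [c.peak_conc_pM for c in included if c.peak_fs is not None]

    mean: dict[str, float] = {}
    sem: dict[str, float] = {}
    for key, vals in quantities.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        mean[key] = float(np.mean(arr))
        sem[key] = float(np.std(arr, ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")

    return ExperimentSummary(
        n_cells=len(included),
        n_excluded=len(excluded),
        mean=mean,
        sem=sem,
        exclusion_reasons=[c.exclude_reason for c in excluded],
    )
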