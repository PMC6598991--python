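"""Ground-truthed synthetic data for every pipeline stage.

Generators for (i) in-vitro Hill titrations with replicate noise, (ii)
multi-phase calibration time courses (baseline -> chelator minimum ->
washout -> ionophore maximum), (iii) 10-second stimulation experiments with
transient-vs-sustained recovery heterogeneity, and (iv) two-channel puncta
images with a controllable colocalized fraction and inter-channel shift.
Every generator is deterministic under a fixed seed and returns the ground
truth alongside the data, so recovery tests can score the analysis against
what was actually simulated.

Signal model for traces: the true fractional saturation FS(t) relaxes
first-order (time constant ``transition_tau_s``, a faster constant during
the brief stimulation) toward the target saturation of the current protocol
phase.  Raw channels are built from FS(t) — a single dye intensity, or a
donor/FRET pair whose ratio follows the model — with multiplicative
cell-to-cell endpoint variability (lognormal), optional monoexponential
bleaching, a constant background offset, and additive Gaussian noise whose
SD is proportional to the local noiseless signal (EMCCD shot + read noise
at typical exposures is approximately signal-proportional).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .coloc import translate_int
from .core_model import (
    CalibrationEndpoints,
    SensorParams,
    load_sensor,
    saturation_from_conc,
)
from .protocol import (
    ProtocolPhase,
    calibration_protocol,
    find_phase,
    stimulation_protocol,
    validate_phases,
)
from .titration import TitrationDataset, hill_response
from .traces import RoiTrace

__all__ = [
    "SimulationConfig",
    "TraceGroundTruth",
    "simulate_titration",
    "simulate_calibration_trace",
    "simulate_stimulation_experiment",
    "simulate_image_pair",
]

# default FluoZin-3 dye signal scale (arbitrary camera units): the dye
# brightens ~50-fold on Zn2+ binding, so the zero-saturation floor is a
# small fraction of the saturated signal
DYE_F_MIN = 40.0
DYE_F_MAX = 2000.0
RATIO_R_MIN = 1.0
RATIO_R_MAX = 3.0
DONOR_LEVEL = 1000.0
BACKGROUND_LEVEL = 50.0
STIM_TAU_S = 2.0  # saturation kinetics during depolarization are much faster
SUSTAINED_PLATEAU = 0.8  # sustained cells hold this fraction of their peak rise
CONC_CV = 0.15  # cell-to-cell spread of true resting/peak concentrations


@dataclass
class SimulationConfig:
    """Knobs of the trace simulators.

    Parameters
    ----------
    n_cells : int
        Cells per simulated experiment.
    sampling_interval_s : float
        Frame interval, seconds.
    noise_sd : float
        Gaussian noise SD as a fraction of the local noiseless signal.
    endpoint_cv : float
        Lognormal cell-to-cell coefficient of variation of the calibration
        endpoints (applied to f_min and to the dynamic range separately, so
        f_max > f_min is preserved).
    transition_tau_s : float
        First-order time constant of chelation/saturation kinetics.
    bleach_rate_per_s : float
        Optional monoexponential photobleaching of the raw channels.
    seed : int
        Random seed; echoed in every generator's output metadata.
    """

    n_cells: int = 1
    sampling_interval_s: float = 2.0
    noise_sd: float = 0.02
    endpoint_cv: float = 0.2
    transition_tau_s: float = 20.0
    bleach_rate_per_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("sampling_interval_s", "noise_sd", "endpoint_cv",
                     "transition_tau_s", "bleach_rate_per_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sampling_interval_s == 0:
            raise ValueError("sampling_interval_s must be > 0")


@dataclass
class TraceGroundTruth:
    """What the simulator actually put into one cell's trace."""

    cell_id: str
    resting_conc_pM: float
    peak_conc_pM: float
    response_kind: str  # "transient" | "sustained" | "none"
    endpoints: CalibrationEndpoints
    seed: int

    def __post_init__(self) -> None:
        if self.peak_conc_pM < self.resting_conc_pM:
            raise ValueError("peak concentration must be >= resting concentration")
        if self.resting_conc_pM < 0:
            raise ValueError("concentrations must be >= 0")


def _lognormal_gain(rng: np.random.Generator, cv: float, size=None):
    """Unit-median lognormal multipliers with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def simulate_titration(
    params: SensorParams,
    endpoints: CalibrationEndpoints,
    conc_grid_nM: Sequence[float],
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> TitrationDataset:
    """Replicate titration curves on a shared concentration grid.

    ``response = f_min + (f_max - f_min) * FS(c) + N(0, noise_sd)``, with
    ``noise_sd`` in response units (e.g. 2% of the dynamic range).
    """
    grid = np.asarray(conc_grid_nM, dtype=float)
    if grid.size == 0:
        raise ValueError("concentration grid is empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    conc = np.tile(grid, n_replicates)
    resp = hill_response(conc, endpoints.f_min, endpoints.f_max, params.kd_nM, params.hill_n)
    resp = resp + rng.normal(0.0, noise_sd, size=conc.size) if noise_sd > 0 else resp
    reps = np.repeat(np.arange(n_replicates), grid.size)
    return TitrationDataset(free_zn_nM=conc, response=resp, replicate_id=reps)


def _phase_fs_targets(
    phases: Sequence[ProtocolPhase],
    fs_rest: float,
    fs_peak: float,
    response_kind: str,
) -> dict[int, tuple[float, float]]:
    """(target FS, tau multiplier) per phase index."""
    targets = {}
    for i, p in enumerate(phases):
        if p.name == "baseline":
            targets[i] = (fs_rest, 1.0)
        elif p.name == "stimulation":
            targets[i] = (fs_peak, STIM_TAU_S)  # absolute fast tau, see below
        elif p.name == "washout":
            if response_kind == "sustained":
                targets[i] = (fs_rest + SUSTAINED_PLATEAU * (fs_peak - fs_rest), 1.0)
            else:
                targets[i] = (fs_rest, 1.0)
        elif p.name == "chelator":
            targets[i] = (0.0, 1.0)
        elif p.name == "ionophore":
            targets[i] = (1.0, 1.0)
    return targets


def _fs_time_course(
    time_s: np.ndarray,
    phases: Sequence[ProtocolPhase],
    fs_rest: float,
    fs_peak: float,
    response_kind: str,
    tau_s: float,
) -> np.ndarray:
    targets = _phase_fs_targets(phases, fs_rest, fs_peak, response_kind)
    fs = np.empty_like(time_s)
    cur = fs_rest
    # step through frames, relaxing toward the target of the active phase
    bounds = [(p.t_start_s, p.t_end_s, i) for i, p in enumerate(phases)]
    prev_t = time_s[0]
    for j, t in enumerate(time_s):
        dt = t - prev_t
        active = None
        for t0, t1, i in bounds:
            if t0 <= t < t1:
                active = i
                break
        if active is not None and dt > 0:
            target, tau_mul = targets[active]
            tau = STIM_TAU_S if phases[active].name == "stimulation" else tau_s * tau_mul
            if tau <= 0:
                cur = target
            else:
                cur = target + (cur - target) * math.exp(-dt / tau)
        elif active is not None and dt == 0:
            # first frame inside the experiment: start at the phase target
            # only for baseline (resting steady state)
            target, _ = targets[active]
            if phases[active].name == "baseline":
                cur = target
        fs[j] = cur
        prev_t = t
    return fs


def _emit_trace(
    cell_id: str,
    time_s: np.ndarray,
    fs: np.ndarray,
    endpoints: CalibrationEndpoints,
    mode: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> RoiTrace:
    bleach = np.exp(-cfg.bleach_rate_per_s * time_s)
    bg = np.full_like(time_s, BACKGROUND_LEVEL)

    def noisy(x: np.ndarray) -> np.ndarray:
        if cfg.noise_sd == 0:
            return x.copy()
        return x + rng.normal(0.0, cfg.noise_sd * np.abs(x), size=x.shape)

    if mode == "dye":
        signal = (endpoints.f_min + endpoints.dynamic_range * fs) * bleach
        roi = signal + bg
        return RoiTrace(
            cell_id=cell_id,
            time_s=time_s,
            channels={"dye": noisy(roi)},
            background={"dye": noisy(bg)},
        )
    if mode == "fret":
        ratio = endpoints.f_min + endpoints.dynamic_range * fs
        donor = DONOR_LEVEL * bleach
        fret = donor * ratio
        return RoiTrace(
            cell_id=cell_id,
            time_s=time_s,
            channels={"donor": noisy(donor + bg), "fret": noisy(fret + bg)},
            background={"donor": noisy(bg), "fret": noisy(bg)},
        )
    raise ValueError(f"unknown trace mode {mode!r}")


def _cell_endpoints(
    base: CalibrationEndpoints, cv: float, rng: np.random.Generator
) -> CalibrationEndpoints:
    f_min = base.f_min * _lognormal_gain(rng, cv)
    rng_span = base.dynamic_range * _lognormal_gain(rng, cv)
    return CalibrationEndpoints(f_min=f_min, f_max=f_min + rng_span)


def simulate_calibration_trace(
    cfg: SimulationConfig,
    sensor: SensorParams | str = "nes-zapcv2",
    resting_conc_pM: float = 60.0,
    phases: Optional[Sequence[ProtocolPhase]] = None,
    mode: str = "fret",
    base_endpoints: Optional[CalibrationEndpoints] = None,
    hill_n: Optional[float] = 1.0,
) -> tuple[list[RoiTrace], list[TraceGroundTruth]]:
    """Resting-calibration experiment: baseline, chelator minimum,
    ionophore maximum.

    Defaults emulate a cytosolic FRET-sensor calibration at a 60 pM resting
    concentration.  The required phases are baseline, chelator and
    ionophore; a missing phase raises.
    """
    if phases is None:
        phases = calibration_protocol()
    phases = validate_phases(phases)
    for req in ("baseline", "chelator", "ionophore"):
        find_phase(phases, req)
    if isinstance(sensor, str):
        sensor = load_sensor(sensor, hill_n=hill_n)
    if base_endpoints is None:
        base_endpoints = (
            CalibrationEndpoints(DYE_F_MIN, DYE_F_MAX)
            if mode == "dye"
            else CalibrationEndpoints(RATIO_R_MIN, RATIO_R_MAX)
        )
    rng = np.random.default_rng(cfg.seed)
    t_end = phases[-1].t_end_s
    time_s = np.arange(0.0, t_end, cfg.sampling_interval_s)

    traces, truths = [], []
    for i in range(cfg.n_cells):
        cell_id = f"cell{i:03d}"
        ep = _cell_endpoints(base_endpoints, cfg.endpoint_cv, rng)
        fs_rest = float(saturation_from_conc(resting_conc_pM, sensor))
        fs = _fs_time_course(time_s, phases, fs_rest, fs_rest, "none", cfg.transition_tau_s)
        traces.append(_emit_trace(cell_id, time_s, fs, ep, mode, cfg, rng))
        truths.append(
            TraceGroundTruth(cell_id, resting_conc_pM, resting_conc_pM, "none", ep, cfg.seed)
        )
    return traces, truths


def simulate_stimulation_experiment(
    cfg: SimulationConfig,
    resting_mean_pM: float = 110.0,
    peak_mean_pM: float = 220.0,
    sustained_fraction: float = 0.3,
    phases: Optional[Sequence[ProtocolPhase]] = None,
    sensor: SensorParams | str = "fluozin3",
    mode: str = "dye",
    conc_cv: float = CONC_CV,
) -> tuple[list[RoiTrace], list[TraceGroundTruth]]:
    """Depolarization experiment: 1 min baseline, 10 s stimulation, washout
    imaging, then the chelator/ionophore calibration.

    Each cell rises to its own peak during the 10 s stimulation; a
    ``sustained_fraction`` share of cells then holds an elevated plateau
    through the washout while the rest decay back toward baseline.  Per-cell
    true concentrations are lognormal around the group means, with each
    cell's peak scaled from its own resting level so peak >= resting always
    holds in truth.  Defaults emulate a high-K+ depolarization with
    exogenous Zn2+ (resting 110 pM -> peak 220 pM) read out by an intensity
    dye.
    """
    if not 0.0 <= sustained_fraction <= 1.0:
        raise ValueError("sustained_fraction must lie in [0, 1]")
    if peak_mean_pM < resting_mean_pM:
        raise ValueError("peak_mean_pM must be >= resting_mean_pM")
    if phases is None:
        phases = stimulation_protocol()
    phases = validate_phases(phases)
    for req in ("baseline", "stimulation", "washout", "chelator", "ionophore"):
        find_phase(phases, req)
    if isinstance(sensor, str):
        sensor = load_sensor(sensor)
    base_endpoints = (
        CalibrationEndpoints(DYE_F_MIN, DYE_F_MAX)
        if mode == "dye"
        else CalibrationEndpoints(RATIO_R_MIN, RATIO_R_MAX)
    )
    rng = np.random.default_rng(cfg.seed)
    t_end = phases[-1].t_end_s
    time_s = np.arange(0.0, t_end, cfg.sampling_interval_s)
    n_sustained = int(round(sustained_fraction * cfg.n_cells))
    kinds = ["sustained"] * n_sustained + ["transient"] * (cfg.n_cells - n_sustained)
    rng.shuffle(kinds)

    traces, truths = [], []
    for i in range(cfg.n_cells):
        cell_id = f"cell{i:03d}"
        ep = _cell_endpoints(base_endpoints, cfg.endpoint_cv, rng)
        rest = resting_mean_pM * _lognormal_gain(rng, conc_cv)
        peak = rest * (peak_mean_pM / resting_mean_pM) * _lognormal_gain(rng, conc_cv / 2)
        peak = max(peak, rest)
        fs_rest = float(saturation_from_conc(rest, sensor))
        fs_peak = float(saturation_from_conc(peak, sensor))
        fs = _fs_time_course(time_s, phases, fs_rest, fs_peak, kinds[i], cfg.transition_tau_s)
        traces.append(_emit_trace(cell_id, time_s, fs, ep, mode, cfg, rng))
        truths.append(TraceGroundTruth(cell_id, rest, peak, kinds[i], ep, cfg.seed))
    return traces, truths


def _render_puncta(
    size: int, centers: np.ndarray, amplitudes: np.ndarray, psf_sigma: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size))
    for (cy, cx), amp in zip(centers, amplitudes):
        img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * psf_sigma**2))
    return img


def simulate_image_pair(
    n_puncta: int = 50,
    coloc_fraction: float = 0.5,
    shift: tuple[int, int] = (0, 0),
    psf_sigma: float = 1.5,
    noise_sd: float = 0.02,
    size: int = 128,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two-channel puncta field with a known colocalized fraction and shift.

    Channel A holds ``n_puncta`` Gaussian spots at random positions; a
    ``coloc_fraction`` share of channel-B spots share A's centers and the
    rest are placed independently.  Channel B is then translated by
    ``shift = (dx, dy)`` pixels (zero-filled border) and both channels get
    additive Gaussian noise of SD ``noise_sd`` (spot amplitudes are ~1).
    Returns ``(img_a, img_b, truth)`` with centers, fraction, shift and seed
    recorded in ``truth``.
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must lie in [0, 1]")
    dx, dy = shift
    if abs(dx) >= size or abs(dy) >= size:
        raise ValueError("shift must be smaller than the image size")
    rng = np.random.default_rng(seed)
    margin = 3.0 * psf_sigma
    centers_a = rng.uniform(margin, size - margin, size=(n_puncta, 2))
    amps_a = _lognormal_gain(rng, 0.2, size=n_puncta)
    n_shared = int(round(coloc_fraction * n_puncta))
    centers_b = np.concatenate(
        [centers_a[:n_shared], rng.uniform(margin, size - margin, size=(n_puncta - n_shared, 2))]
    )
    amps_b = _lognormal_gain(rng, 0.2, size=n_puncta)

    img_a = _render_puncta(size, centers_a, amps_a, psf_sigma)
    img_b = _render_puncta(size, centers_b, amps_b, psf_sigma)
    img_b, _ = translate_int(img_b, dx, dy)
    if noise_sd > 0:
        img_a = img_a + rng.normal(0.0, noise_sd, img_a.shape)
        img_b = img_b + rng.normal(0.0, noise_sd, img_b.shape)
    truth = {
        "centers_a": centers_a,
        "centers_b": centers_b,
        "n_shared": n_shared,
        "coloc_fraction": coloc_fraction,
        "shift": (dx, dy),
        "seed": seed,
    }
    return img_a, img_b, truth
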