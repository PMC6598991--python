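"""Sensor binding model: fractional saturation and Hill-equation inversion.

Ratiometric FRET sensors and intensity dyes report the fraction of sensor
molecules bound to Zn2+.  After an in-situ calibration that drives the sensor
to its zero-saturation signal (chelator) and full-saturation signal
(ionophore + excess Zn2+), any intermediate signal ``x`` maps to a fractional
saturation

    FS = (x - F_min) / (F_max - F_min)

and, through the Hill binding isotherm with dissociation constant ``Kd`` and
Hill coefficient ``n``, to a free-Zn2+ concentration

    [Zn2+] = Kd / (1/FS - 1)^(1/n)

Concentrations are carried internally in picomolar; ``Kd`` is accepted in
nanomolar at construction and converted once.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

__all__ = [
    "SensorParams",
    "CalibrationEndpoints",
    "FractionalSaturation",
    "ZincConcentration",
    "fractional_saturation",
    "conc_from_saturation",
    "saturation_from_conc",
    "load_sensor",
    "BUILTIN_SENSORS",
]

NM_TO_PM = 1000.0


class InvalidEndpointsError(ValueError):
    """F_max does not exceed F_min, so no calibration is possible."""


class SaturatedSignalError(ValueError):
    """FS = 1: the inferred concentration is unbounded."""


@dataclass(frozen=True)
class SensorParams:
    """Binding parameters of one Zn2+ sensor or dye.

    Parameters
    ----------
    label : str
        Short sensor name, e.g. ``"FluoZin-3"``.
    kd_nM : float
        Dissociation constant in nanomolar; must be positive and finite.
    hill_n : float
        Hill coefficient (dimensionless, > 0).  Cooperativity of binding;
        1 for a single-site dye such as FluoZin-3 AM.
    """

    label: str
    kd_nM: float
    hill_n: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.kd_nM) and self.kd_nM > 0):
            raise ValueError(f"kd_nM must be finite and > 0, got {self.kd_nM}")
        if not (math.isfinite(self.hill_n) and self.hill_n > 0):
            raise ValueError(f"hill_n must be finite and > 0, got {self.hill_n}")

    @property
    def kd_pM(self) -> float:
        return self.kd_nM * NM_TO_PM


@dataclass(frozen=True)
class CalibrationEndpoints:
    """Signal at zero (``f_min``) and full (``f_max``) sensor saturation.

    Units are arbitrary — a FRET ratio or a background-subtracted intensity —
    but must be shared by both endpoints and by the signals scored against
    them.
    """

    f_min: float
    f_max: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.f_min) and math.isfinite(self.f_max)):
            raise InvalidEndpointsError("endpoints must be finite")
        if not self.f_max > self.f_min:
            raise InvalidEndpointsError(
                f"f_max ({self.f_max}) must exceed f_min ({self.f_min})"
            )

    @property
    def dynamic_range(self) -> float:
        return self.f_max - self.f_min


@dataclass(frozen=True)
class FractionalSaturation:
    """Fraction of sensor bound, in [0, 1]; ``clipped`` marks out-of-range raw values."""

    value: float
    clipped: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"fractional saturation must lie in [0, 1], got {self.value}")

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class ZincConcentration:
    """Free Zn2+ concentration in picomolar (non-negative, finite)."""

    value_pM: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value_pM) and self.value_pM >= 0):
            raise ValueError(f"concentration must be finite and >= 0 pM, got {self.value_pM}")

    def __float__(self) -> float:
        return self.value_pM


def fractional_saturation(
    x: float, endpoints: CalibrationEndpoints
) -> FractionalSaturation:
    """Convert a calibrated signal to fractional saturation.

    FS = (x - f_min) / (f_max - f_min).  Noise can push a resting signal
    below the chelator minimum or above the ionophore maximum; such values
    are clipped to the nearest boundary and flagged rather than rejected, so
    batch analysis of a whole experiment never aborts on one noisy cell.
    """
    raw = (x - endpoints.f_min) / endpoints.dynamic_range
    if raw < 0.0:
        return FractionalSaturation(0.0, clipped=True)
    if raw > 1.0:
        return FractionalSaturation(1.0, clipped=True)
    return FractionalSaturation(raw, clipped=False)


def conc_from_saturation(
    fs: Union[FractionalSaturation, float], params: SensorParams
) -> ZincConcentration:
    """Invert fractional saturation to concentration: Kd / (1/FS - 1)^(1/n).

    Returns picomolar.  FS = 0 maps to 0 pM; FS = 1 raises
    :class:`SaturatedSignalError` because the Hill inversion diverges there.
    """
    v = float(fs)
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"fractional saturation outside [0, 1]: {v}")
    if v == 1.0:
        raise SaturatedSignalError("FS = 1: concentration is unbounded")
    if v == 0.0:
        return ZincConcentration(0.0)
    c_pM = params.kd_pM / (1.0 / v - 1.0) ** (1.0 / params.hill_n)
    return ZincConcentration(c_pM)


def saturation_from_conc(
    c: Union[ZincConcentration, float], params: SensorParams
) -> FractionalSaturation:
    """Forward Hill isotherm: FS = c^n / (Kd^n + c^n), with ``c`` in pM.

    Algebraic inverse of :func:`conc_from_saturation`; used by the
    simulators and the titration fitter.
    """
    v = float(c)
    if v < 0:
        raise ValueError(f"concentration must be >= 0, got {v}")
    if v == 0.0:
        return FractionalSaturation(0.0)
    # compute in ratio form for numerical stability at extreme c/Kd
    r = (v / params.kd_pM) ** params.hill_n
    return FractionalSaturation(r / (1.0 + r))


# Built-in sensor definitions.  The Hill coefficient of the NES-ZapCV2 FRET
# sensor is not a published constant and must be supplied by the user; only
# the intensity dye ships with a default n of 1.
BUILTIN_SENSORS = {
    "fluozin3": {"label": "FluoZin-3", "kd_nM": 9.1, "hill_n": 1.0},
    "nes-zapcv2": {"label": "NES-ZapCV2", "kd_nM": 5.3, "hill_n": None},
}


def load_sensor(
    source: Union[str, Path, dict], hill_n: float | None = None
) -> SensorParams:
    """Resolve a sensor definition from a built-in name, JSON file, or dict.

    JSON/dict schema: ``{"label": str, "kd_nM": float, "hill_n": float}``.
    ``hill_n`` passed here overrides (or supplies, for sensors without a
    default) the Hill coefficient.
    """
    if isinstance(source, dict):
        cfg = dict(source)
    elif isinstance(source, (str, Path)) and str(source).lower() in BUILTIN_SENSORS:
        cfg = dict(BUILTIN_SENSORS[str(source).lower()])
    else:
        with open(source) as fh:
            cfg = json.load(fh)
    if hill_n is not None:
        cfg["hill_n"] = hill_n
    if cfg.get("hill_n") is None:
        raise ValueError(
            f"sensor {cfg.get('label', source)!r} has no default Hill coefficient; "
            "pass hill_n explicitly"
        )
    return SensorParams(label=cfg["label"], kd_nM=cfg["kd_nM"], hill_n=cfg["hill_n"])
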