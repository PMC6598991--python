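"""Hill-curve fitting of in-vitro sensor titrations.

A titration measures the sensor response (a fluorescence ratio or intensity)
across a grid of buffered free-Zn2+ concentrations.  The response follows

    R(c) = f_min + (f_max - f_min) * c^n / (Kd^n + c^n)

and a pooled nonlinear least-squares fit across all replicates yields one
set of binding parameters (Kd, n) and endpoints (f_min, f_max), the way a
single apparent Kd is conventionally reported from a batch of titration
experiments.  Kd and n are optimized on a log scale to enforce positivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .core_model import CalibrationEndpoints, SensorParams

__all__ = ["TitrationDataset", "TitrationFit", "fit_titration", "hill_response"]


@dataclass
class TitrationDataset:
    """Pooled titration measurements.

    Parameters
    ----------
    free_zn_nM : array
        Buffered free Zn2+ concentration per point, nM, >= 0.
    response : array
        Observed signal (ratio or intensity), same length.
    replicate_id : array
        Label of the titration experiment each point belongs to.
    response_kind : {"ratio", "intensity"}
    """

    free_zn_nM: np.ndarray
    response: np.ndarray
    replicate_id: np.ndarray
    response_kind: str = "ratio"

    def __post_init__(self) -> None:
        self.free_zn_nM = np.asarray(self.free_zn_nM, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.replicate_id = np.asarray(self.replicate_id)
        n = self.free_zn_nM.size
        if self.response.size != n or self.replicate_id.size != n:
            raise ValueError("free_zn_nM, response and replicate_id must have equal length")
        if np.any(self.free_zn_nM < 0):
            raise ValueError("free Zn2+ concentrations must be >= 0")
        if not (np.all(np.isfinite(self.free_zn_nM)) and np.all(np.isfinite(self.response))):
            raise ValueError("titration data must be finite")

    @property
    def n_points(self) -> int:
        return self.free_zn_nM.size

    def n_distinct_concentrations(self) -> int:
        return np.unique(self.free_zn_nM).size


@dataclass
class TitrationFit:
    """Result of a pooled Hill-curve fit."""

    params: Optional[SensorParams]
    endpoints: Optional[CalibrationEndpoints]
    residual_sse: float
    standard_errors: dict = field(default_factory=dict)
    converged: bool = False
    n_points: int = 0
    message: str = ""


def hill_response(
    c_nM: np.ndarray, f_min: float, f_max: float, kd_nM: float, hill_n: float
) -> np.ndarray:
    """Noiseless titration response at concentrations ``c_nM``."""
    c = np.asarray(c_nM, dtype=float)
    out = np.full(c.shape, f_min, dtype=float)
    pos = c > 0
    r = (c[pos] / kd_nM) ** hill_n
    out[pos] = f_min + (f_max - f_min) * r / (1.0 + r)
    return out


def _initial_guess(data: TitrationDataset) -> tuple[float, float, float, float]:
    f_min = float(np.min(data.response))
    f_max = float(np.max(data.response))
    half = 0.5 * (f_min + f_max)
    pos = data.free_zn_nM > 0
    if np.any(pos):
        idx = np.argmin(np.abs(data.response[pos] - half))
        kd0 = float(data.free_zn_nM[pos][idx])
    else:
        kd0 = 1.0
    return f_min, f_max, max(kd0, 1e-6), 1.0


def fit_titration(
    data: TitrationDataset,
    fix_hill_n: float | None = None,
    init: tuple[float, float, float, float] | None = None,
) -> TitrationFit:
    """Pooled least-squares Hill fit of a titration dataset.

    Parameters
    ----------
    data : TitrationDataset
        Points from all replicates together; one parameter set is fitted.
    fix_hill_n : float, optional
        Hold the Hill coefficient at this value (> 0) instead of fitting it.
    init : (f_min, f_max, kd_nM, hill_n), optional
        Starting values; by default self-started from the data (endpoints
        from the response range, Kd from the concentration nearest the
        half-range response, n = 1).

    Returns
    -------
    TitrationFit
        Fitted parameters with curvature-based standard errors.  A fit that
        fails to converge is returned with ``converged=False`` and
        diagnostics in ``message`` rather than raising.
    """
    if fix_hill_n is not None and not fix_hill_n > 0:
        raise ValueError("fix_hill_n must be > 0")
    n_free = 3 if fix_hill_n is not None else 4
    if data.n_distinct_concentrations() < n_free:
        raise ValueError(
            f"need at least {n_free} distinct concentrations to fit {n_free} parameters"
        )

    f_min0, f_max0, kd0, n0 = init if init is not None else _initial_guess(data)
    if fix_hill_n is not None:
        n0 = fix_hill_n
    if f_max0 <= f_min0:
        f_max0 = f_min0 + 1.0

    c = data.free_zn_nM
    # fit on a normalized response scale: better conditioned, and makes the
    # fit exactly equivariant under rescaling of the responses
    scale = float(np.max(np.abs(data.response))) or 1.0
    y = data.response / scale
    f_min0, f_max0 = f_min0 / scale, f_max0 / scale

    def unpack(theta: np.ndarray) -> tuple[float, float, float, float]:
        if fix_hill_n is not None:
            fm, fM, lkd = theta
            return fm, fM, np.exp(lkd), fix_hill_n
        fm, fM, lkd, ln = theta
        return fm, fM, np.exp(lkd), np.exp(ln)

    def residuals(theta: np.ndarray) -> np.ndarray:
        fm, fM, kd, nn = unpack(theta)
        return hill_response(c, fm, fM, kd, nn) - y

    theta0 = [f_min0, f_max0, np.log(kd0)]
    if fix_hill_n is None:
        theta0.append(np.log(n0))
    sol = least_squares(
        residuals, np.asarray(theta0), method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15
    )

    sse = float(np.sum(sol.fun**2)) * scale**2
    if not sol.success:
        return TitrationFit(None, None, sse, {}, False, data.n_points, sol.message)

    fm, fM, kd, nn = unpack(sol.x)
    fm, fM = fm * scale, fM * scale
    if fM <= fm:
        return TitrationFit(
            None, None, sse, {}, False, data.n_points, "inverted endpoints (f_max <= f_min)"
        )

    # standard errors from local curvature: cov = s^2 (J^T J)^{-1},
    # delta-method back-transform for the log-scale parameters
    ses: dict[str, float] = {}
    dof = data.n_points - sol.x.size
    if dof > 0:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * (sse / scale**2 / dof)
            se = np.sqrt(np.diag(cov))
            ses = {"f_min": se[0] * scale, "f_max": se[1] * scale, "kd_nM": kd * se[2]}
            ses["hill_n"] = nn * se[3] if fix_hill_n is None else 0.0
        except np.linalg.LinAlgError:
            pass

    return TitrationFit(
        params=SensorParams(label="fitted", kd_nM=kd, hill_n=nn),
        endpoints=CalibrationEndpoints(f_min=fm, f_max=fM),
        residual_sse=sse,
        standard_errors=ses,
        converged=True,
        n_points=data.n_points,
        message=sol.message,
    )
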