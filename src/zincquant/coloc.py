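"""Two-channel colocalization: registration, thresholding, 2D correlation.

Channels acquired through different filter sets are displaced by a small
chromatic shift; to first order the displacement is a pure translation, so
registration here estimates an integer pixel shift from a reference pair
(e.g. multi-spectral beads) by cross-correlation and applies it to every
field before scoring.  Colocalization is scored as the Pearson correlation
of pixel intensities over the valid (overlap) region, either on raw
intensities or restricted to adaptively-thresholded foreground.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

__all__ = [
    "RegistrationParams",
    "ColocResult",
    "NoSignalError",
    "UndefinedCorrelationError",
    "estimate_registration",
    "apply_registration",
    "adaptive_threshold",
    "correlation2d",
    "coloc_pipeline",
]


class NoSignalError(ValueError):
    """An image has no spatial structure (zero variance); registration is undefined."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (zero variance or too few pixels)."""


@dataclass(frozen=True)
class RegistrationParams:
    """Integer translation (dx = columns, dy = rows) of channel B relative
    to channel A, and which reference produced it."""

    dx: int
    dy: int
    source: str = ""

    def invert(self) -> "RegistrationParams":
        return RegistrationParams(-self.dx, -self.dy, self.source)


@dataclass(frozen=True)
class ColocResult:
    """Pearson colocalization score for one field / channel pair."""

    correlation: float
    mode: str
    n_pixels: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.correlation <= 1.0 + 1e-12:
            raise ValueError(f"correlation outside [-1, 1]: {self.correlation}")


def translate_int(img: np.ndarray, dx: int, dy: int) -> tuple[np.ndarray, np.ndarray]:
    """Translate an image by integer pixels (+dx right, +dy down).

    Returns the shifted image with the vacated border zero-filled, plus a
    boolean validity mask that is False on that border.
    """
    h, w = img.shape
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError(f"shift ({dx}, {dy}) >= image size ({w}, {h})")
    out = np.zeros_like(img)
    mask = np.zeros(img.shape, dtype=bool)
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys, xs] = img[ys_src, xs_src]
    mask[ys, xs] = True
    return out, mask


def estimate_registration(
    reference_a: np.ndarray,
    reference_b: np.ndarray,
    max_shift: Optional[int] = None,
    source: str = "",
) -> RegistrationParams:
    """Integer shift of channel B relative to A maximizing cross-correlation.

    Computed by FFT cross-correlation of the mean-subtracted references over
    all cyclic shifts up to ``max_shift`` (default: just under half the
    smaller image dimension).  Ties are broken toward the smallest
    |dx| + |dy|, then lexicographically on (dx, dy), so the result is
    deterministic.
    """
    a = np.asarray(reference_a, dtype=float)
    b = np.asarray(reference_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("reference images must be 2-D and share a shape")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise NoSignalError("flat reference image: registration is undefined")
    h, w = a.shape
    if max_shift is None:
        max_shift = min(h, w) // 2 - 1
    a0 = a - a.mean()
    b0 = b - b.mean()
    # xc[dy % h, dx % w] = sum_x a0(x) * b0(x + (dy, dx))
    xc = np.real(np.fft.ifft2(np.conj(np.fft.fft2(a0)) * np.fft.fft2(b0)))

    dys = np.arange(-max_shift, max_shift + 1)
    dxs = np.arange(-max_shift, max_shift + 1)
    sub = xc[np.ix_(dys % h, dxs % w)]
    best = sub.max()
    tol = 1e-9 * max(abs(best), 1.0)
    cand = np.argwhere(sub >= best - tol)
    # (dx, dy) candidates; deterministic tie-breaking
    shifts = [(int(dxs[j]), int(dys[i])) for i, j in cand]
    dx, dy = min(shifts, key=lambda s: (abs(s[0]) + abs(s[1]), s))
    return RegistrationParams(dx=dx, dy=dy, source=source)


def apply_registration(
    img: np.ndarray, params: RegistrationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Translate an image by the registration shift.

    Returns ``(shifted, valid_mask)``; the zero-filled vacated border is
    False in the mask so it can be excluded from correlation.
    """
    return translate_int(np.asarray(img), params.dx, params.dy)


def adaptive_threshold(
    img: np.ndarray, sensitivity: float = 0.25, window: Optional[int] = None
) -> np.ndarray:
    """Local-mean foreground mask.

    A pixel is foreground when its intensity exceeds the mean of its
    window x window neighborhood scaled by f = 2 * (1 - sensitivity), so
    higher sensitivity admits more foreground.  Default window is
    2 * floor(min(dims) / 16) + 1.
    """
    if not 0.0 <= sensitivity <= 1.0:
        raise ValueError("sensitivity must lie in [0, 1]")
    img = np.asarray(img, dtype=float)
    if window is None:
        window = 2 * (min(img.shape) // 16) + 1
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if np.ptp(img) == 0:
        warnings.warn("constant image: adaptive threshold produces an empty mask")
        return np.zeros(img.shape, dtype=bool)
    local_mean = uniform_filter(img, size=window, mode="nearest")
    factor = 2.0 * (1.0 - sensitivity)
    return img > factor * local_mean


def correlation2d(
    img_a: np.ndarray, img_b: np.ndarray, mask: Optional[np.ndarray] = None, mode: str = "raw"
) -> ColocResult:
    """Pearson correlation of two images over the (optionally masked) pixels."""
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask must share the image shape")
        a = a[mask]
        b = b[mask]
    else:
        a = a.ravel()
        b = b.ravel()
    if a.size < 2:
        raise UndefinedCorrelationError(f"need >= 2 pixels, have {a.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return ColocResult(correlation=min(1.0, max(-1.0, r)), mode=mode, n_pixels=a.size)


def coloc_pipeline(
    fields: Iterable[tuple[str, np.ndarray, np.ndarray]],
    registration: Optional[RegistrationParams] = None,
    reference_pair: Optional[tuple[np.ndarray, np.ndarray]] = None,
    sensitivity: float = 0.25,
    window: Optional[int] = None,
) -> pd.DataFrame:
    """Score colocalization for a batch of two-channel fields of view.

    For each ``(field_id, img_a, img_b)``: align channel B using the
    supplied registration (or one estimated from ``reference_pair``), then
    report the Pearson correlation over the overlap region both on raw
    intensities and restricted to the union of the per-channel adaptive
    foreground masks.  Per-field failures are recorded (NaN correlation
    with the error message) and the batch continues.
    """
    if registration is None and reference_pair is not None:
        registration = estimate_registration(*reference_pair, source="reference pair")
    rows = []
    for field_id, img_a, img_b in fields:
        try:
            a = np.asarray(img_a, dtype=float)
            if registration is not None:
                b, valid = apply_registration(img_b, registration.invert())
            else:
                b = np.asarray(img_b, dtype=float)
                valid = np.ones(b.shape, dtype=bool)
            raw = correlation2d(a, b, mask=valid, mode="raw")
            rows.append((field_id, "raw", raw.correlation, raw.n_pixels, ""))
            fg = (adaptive_threshold(a, sensitivity, window)
                  | adaptive_threshold(b, sensitivity, window)) & valid
            thr = correlation2d(a, b, mask=fg, mode="thresholded")
            rows.append((field_id, "thresholded", thr.correlation, thr.n_pixels, ""))
        except (ValueError, NoSignalError) as e:
            rows.append((field_id, "error", float("nan"), 0, str(e)))
    return pd.DataFrame(rows, columns=["field_id", "mode", "correlation", "n_pixels", "error"])
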