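"""Translation invariance: position correlations, RF profiles, the TI
statistic, the SVD separability index, and classical-receptive-field (CRF)
estimation from a translation sweep.

The central object is a :class:`ResponseMatrix` of shape (stimuli x
positions).  Translation invariance is summarized by

    TI = sum_{i != j} Cov(p_i, p_j) / sum_{i != j} SD(p_i) SD(p_j)

over unique position pairs, where p_i is the column of responses at the
i-th position.  TI is 1 for exactly separable matrices (shape tuning x RF
profile), ~0 for uncorrelated columns, and bounded in [-1, 1] by
Cauchy-Schwarz applied pairwise.  Unlike a plain average of pairwise
correlations, weak positions do not get equal weight; unlike the SVD
separability index, TI is not biased upward by narrow RF profiles or high
shape selectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .shapes import FIELD_PX, StimulusImage

__all__ = [
    "ResponseMatrix",
    "PositionProfile",
    "CRFResult",
    "position_correlation",
    "rf_profile",
    "ti_metric",
    "separability_index",
    "estimate_crf",
    "ti_window",
    "SWEEP_CENTERS",
]

#: Default translation-sweep centers: a 100 px span in 2 px steps.
SWEEP_CENTERS = tuple(range(64, 165, 2))


@dataclass
class ResponseMatrix:
    """Real responses of one unit: stimuli (rows) x positions (columns)."""

    values: np.ndarray
    positions: np.ndarray
    stimulus_ids: Sequence | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.positions = np.asarray(self.positions)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (stimuli x positions)")
        if self.values.shape[1] != len(self.positions):
            raise ValueError("columns must align with positions")

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def n_positions(self) -> int:
        return self.values.shape[1]

    def restrict(self, mask: np.ndarray) -> "ResponseMatrix":
        return ResponseMatrix(self.values[:, mask], self.positions[mask],
                              self.stimulus_ids)


@dataclass
class PositionProfile:
    """Per-position aggregates: RF profile and/or correlation vs. reference."""

    positions: np.ndarray
    rf_value: np.ndarray | None = None
    corr_value: np.ndarray | None = None
    reference: int | None = None


def position_correlation(matrix: ResponseMatrix,
                         reference: int | None = None) -> PositionProfile:
    """Pearson r of each position's responses against the reference position.

    ``reference`` defaults to the center column.  A constant non-reference
    column yields NaN (undefined), never 0.
    """
    v = matrix.values
    if reference is None:
        reference = matrix.n_positions // 2
    ref = v[:, reference]
    if np.std(ref) == 0:
        raise ValueError("reference column is constant; correlation undefined")
    refc = ref - ref.mean()
    vc = v - v.mean(axis=0, keepdims=True)
    sd = np.sqrt((vc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (vc.T @ refc) / (sd * np.sqrt((refc ** 2).sum()))
    corr[sd == 0] = np.nan
    corr[reference] = 1.0
    return PositionProfile(matrix.positions, corr_value=corr, reference=reference)


def rf_profile(matrix: ResponseMatrix) -> PositionProfile:
    """L2 aggregate response per position: sqrt(sum of squared responses).

    Used instead of the mean because unit responses may be negative.
    """
    rf = np.sqrt((matrix.values ** 2).sum(axis=0))
    return PositionProfile(matrix.positions, rf_value=rf)


def ti_metric(matrix: ResponseMatrix) -> float:
    """Translation-invariance statistic in [-1, 1].

    Ratio of summed off-diagonal covariances to summed SD products over
    unique position pairs (sample, n-1 denominators; the ratio is
    invariant to that choice).  Zero-variance columns are dropped with a
    warning; returns NaN when fewer than two usable positions remain.
    """
    v = matrix.values
    if matrix.n_positions < 2 or matrix.n_stimuli < 3:
        raise ValueError("TI needs >= 2 positions and >= 3 stimuli")
    sd0 = v.std(axis=0)
    usable = sd0 > 0
    if not usable.all():
        warnings.warn(
            f"dropping {int((~usable).sum())} zero-variance position(s) from TI",
            RuntimeWarning, stacklevel=2)
        v = v[:, usable]
    if v.shape[1] < 2:
        return float("nan")
    cov = np.cov(v, rowvar=False)          # positions x positions
    sd = np.sqrt(np.diag(cov))
    off = ~np.eye(len(sd), dtype=bool)
    num = cov[off].sum()
    den = np.outer(sd, sd)[off].sum()
    return float(num / den)


def separability_index(matrix: ResponseMatrix) -> float:
    """First squared singular value over the sum of squared singular values.

    1 for exactly separable (rank-1) matrices; biased upward for narrow
    RF profiles or highly selective shape tuning, which is why TI is the
    primary statistic.
    """
    v = matrix.values
    if not np.any(v):
        raise ValueError("separability index undefined for an all-zero matrix")
    s = np.linalg.svd(v, compute_uv=False)
    return float(s[0] ** 2 / (s ** 2).sum())


# ---------------------------------------------------------------------------
# CRF estimation from a translation sweep
# ---------------------------------------------------------------------------

@dataclass
class CRFResult:
    """Outcome of a CRF sweep along one axis."""

    centers: np.ndarray
    responsive: np.ndarray
    run_first: int | None      # first/last sweep centers of the longest run
    run_last: int | None
    extent: float              # estimated CRF extent in pixels
    crf_lo: float | None       # estimated CRF pixel interval
    crf_hi: float | None
    eligible: bool             # wide enough for >= 3 two-pixel translations
    saturated: bool            # run touches both ends of the sweep
    max_width: int


def _shift_image(img: np.ndarray, dx: int, axis: int = 1) -> np.ndarray:
    """Integer-pixel shift with zero fill (no wraparound)."""
    out = np.zeros_like(img)
    if dx == 0:
        return img.copy()
    if axis == 1:
        if dx > 0:
            out[:, dx:] = img[:, :-dx]
        else:
            out[:, :dx] = img[:, -dx:]
    else:
        if dx > 0:
            out[dx:, :] = img[:-dx, :]
        else:
            out[:dx, :] = img[-dx:, :]
    return out


def estimate_crf(unit: Callable[[np.ndarray], float],
                 rendered: Sequence[StimulusImage],
                 axis: str = "horizontal",
                 centers: Sequence[int] = SWEEP_CENTERS,
                 tol: float = 0.0,
                 min_window: int = 3) -> CRFResult:
    """Estimate a unit's CRF extent by sweeping the stimulus set.

    ``rendered`` are stimuli rasterized at the field center; they are
    shifted in integer pixels along ``axis`` so that the set is centered
    on each sweep position in turn (rasterization is exactly translation
    equivariant for integer shifts).  Baseline is the response to the
    all-zero image; a position is responsive if any stimulus deviates
    from baseline by more than ``tol``.  The CRF extent is the pixel
    length of the longest contiguous responsive run minus the maximum
    stimulus width plus one; the unit is TI-eligible if the CRF admits at
    least ``min_window`` two-pixel translations of the whole set.
    """
    centers = np.asarray(list(centers), dtype=int)
    if len(rendered) == 0:
        raise ValueError("empty stimulus set")
    field = rendered[0].pixels.shape[0]
    ax = 1 if axis == "horizontal" else 0
    ref_center = rendered[0].center_xy[ax]

    # maximum stimulus extent along the sweep axis
    widths = []
    for im in rendered:
        mask = im.foreground_mask
        proj = mask.any(axis=1 - ax)
        nz = np.where(proj)[0]
        widths.append(0 if len(nz) == 0 else int(nz[-1] - nz[0] + 1))
    max_width = max(widths)

    baseline = float(unit(np.zeros((field, field))))
    responsive = np.zeros(len(centers), dtype=bool)
    for i, c in enumerate(centers):
        dx = int(c - ref_center)
        for im in rendered:
            if abs(float(unit(_shift_image(im.pixels, dx, axis=ax))) - baseline) > tol:
                responsive[i] = True
                break

    # longest contiguous responsive run (first such run on ties)
    best_len, best_start, cur_start = 0, None, None
    for i, flag in enumerate(np.append(responsive, False)):
        if flag and cur_start is None:
            cur_start = i
        elif not flag and cur_start is not None:
            if i - cur_start > best_len:
                best_len, best_start = i - cur_start, cur_start
            cur_start = None

    if best_start is None:
        return CRFResult(centers, responsive, None, None, 0.0, None, None,
                         False, False, max_width)

    first = int(centers[best_start])
    last = int(centers[best_start + best_len - 1])
    run_px = last - first
    extent = max(0.0, run_px - max_width + 1)
    crf_lo = first + max_width / 2.0
    crf_hi = last - max_width / 2.0
    saturated = first == centers[0] and last == centers[-1]
    # eligibility: valid window positions are centers whose whole set fits
    half = max_width / 2.0
    valid = (centers >= crf_lo + half) & (centers <= crf_hi - half)
    eligible = int(valid.sum()) >= min_window
    return CRFResult(centers, responsive, first, last, float(extent),
                     crf_lo, crf_hi, eligible, saturated, max_width)


def ti_window(matrix: ResponseMatrix, crf: CRFResult | tuple,
              stimulus_width: float | None = None) -> ResponseMatrix:
    """Restrict a response matrix to positions where the whole stimulus set
    lies inside the CRF.

    ``crf`` is either a :class:`CRFResult` or a raw ``(lo, hi)`` pixel
    interval; ``stimulus_width`` defaults to the CRF result's maximum
    stimulus width.  The returned matrix may have fewer than 2 positions,
    in which case the unit is excluded from TI by the caller.
    """
    if isinstance(crf, CRFResult):
        lo, hi = crf.crf_lo, crf.crf_hi
        if stimulus_width is None:
            stimulus_width = crf.max_width
    else:
        lo, hi = crf
        if stimulus_width is None:
            raise ValueError("stimulus_width required with a raw interval")
    if lo is None or hi is None:
        return matrix.restrict(np.zeros(matrix.n_positions, dtype=bool))
    half = stimulus_width / 2.0
    pos = np.asarray(matrix.positions, dtype=float)
    mask = (pos >= lo + half) & (pos <= hi - half)
    return matrix.restrict(mask)
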