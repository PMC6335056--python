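"""The angular-position-and-curvature (APC) tuning model and its grid fitter.

A unit's response to a closed shape is modeled as the maximum, over the
shape's boundary elements, of the product of two Gaussian tuning curves —
one over normalized curvature (mean ``mu_c``, SD ``sigma_c``) and one over
angular position (mean ``mu_a``, SD ``sigma_a``, with circular wrapping) —
scaled by a non-negative factor ``k``:

    R_i = k * max_j exp(-(c_ij - mu_c)^2 / 2 sigma_c^2)
                * exp(-(d(a_ij, mu_a))^2 / 2 sigma_a^2)

where d(a, mu) = min(|a - mu|, 360 - |a - mu|).  Fitting enumerates a
discrete grid of candidate parameters (by default 16 linearly spaced means
and 16 log-spaced SDs per dimension, 16^4 = 65,536 candidates), picks the
candidate maximizing the Pearson correlation between observed and
predicted responses (r is invariant to k), then sets k by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .shapes import BoundaryShape

__all__ = [
    "APCParams",
    "APCFit",
    "APCGrid",
    "DEFAULT_RANGES",
    "build_grid",
    "apc_predict",
    "prediction_matrix",
    "fit_apc",
    "shuffle_control",
    "pearson_p_value",
]

# Parameter ranges matching those observed for V4 cells under the original
# gradient-descent fits; grid endpoints coincide with these bounds.
DEFAULT_RANGES = {
    "mu_c": (-0.5, 1.0),
    "sigma_c": (0.01, 0.98),
    "mu_a": (0.0, 338.0),
    "sigma_a": (23.0, 171.0),
}


@dataclass(frozen=True)
class APCParams:
    """The five APC model parameters."""

    mu_c: float
    sigma_c: float
    mu_a: float
    sigma_a: float
    k: float = 1.0

    def __post_init__(self):
        if self.sigma_c <= 0 or self.sigma_a <= 0:
            raise ValueError("sigma_c and sigma_a must be positive")


@dataclass
class APCFit:
    """Result of a grid fit: best parameters plus fit quality."""

    params: APCParams | None
    r: float
    p_value: float
    n: int
    candidate_index: int = -1
    degenerate: bool = False
    reason: str = ""


class APCGrid:
    """Cartesian product of per-parameter candidate values.

    Candidates are enumerated in lexicographic order (mu_c, sigma_c,
    mu_a, sigma_a), the last axis varying fastest.
    """

    def __init__(self, mu_c: np.ndarray, sigma_c: np.ndarray,
                 mu_a: np.ndarray, sigma_a: np.ndarray):
        self.mu_c = np.asarray(mu_c, dtype=float)
        self.sigma_c = np.asarray(sigma_c, dtype=float)
        self.mu_a = np.asarray(mu_a, dtype=float)
        self.sigma_a = np.asarray(sigma_a, dtype=float)
        if (self.sigma_c <= 0).any() or (self.sigma_a <= 0).any():
            raise ValueError("SD grid values must be positive")

    def __len__(self) -> int:
        return len(self.mu_c) * len(self.sigma_c) * len(self.mu_a) * len(self.sigma_a)

    @property
    def shape(self) -> tuple:
        return (len(self.mu_c), len(self.sigma_c), len(self.mu_a), len(self.sigma_a))

    def params_at(self, index: int) -> APCParams:
        """Parameters of the candidate at a flat lexicographic index (k=1)."""
        n_mc, n_sc, n_ma, n_sa = self.shape
        i_sa = index % n_sa
        index //= n_sa
        i_ma = index % n_ma
        index //= n_ma
        i_sc = index % n_sc
        i_mc = index // n_sc
        return APCParams(self.mu_c[i_mc], self.sigma_c[i_sc],
                         self.mu_a[i_ma], self.sigma_a[i_sa])

    def iter_params(self):
        for i in range(len(self)):
            yield self.params_at(i)


def build_grid(ranges: dict | None = None, n_per_axis: int = 16) -> APCGrid:
    """Build the candidate grid: linear means, log-spaced SDs, inclusive ends."""
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    if r["sigma_c"][0] <= 0 or r["sigma_a"][0] <= 0:
        raise ValueError("SD range endpoints must be positive")
    return APCGrid(
        np.linspace(*r["mu_c"], n_per_axis),
        np.geomspace(*r["sigma_c"], n_per_axis),
        np.linspace(*r["mu_a"], n_per_axis),
        np.geomspace(*r["sigma_a"], n_per_axis),
    )


def wrapped_angle_diff(a, mu):
    """Circular distance in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - mu) % 360.0
    return np.minimum(d, 360.0 - d)


def apc_predict(params: APCParams, shape: BoundaryShape) -> float:
    """Model response of a unit with ``params`` to one shape."""
    c = shape.curvatures
    a = shape.angular_positions
    gc = np.exp(-((c - params.mu_c) ** 2) / (2 * params.sigma_c ** 2))
    da = wrapped_angle_diff(a, params.mu_a)
    ga = np.exp(-(da ** 2) / (2 * params.sigma_a ** 2))
    return float(params.k * np.max(gc * ga))


def prediction_matrix(grid: APCGrid, bank: Sequence[BoundaryShape]) -> np.ndarray:
    """Unit-scale (k = 1) predictions for every candidate x stimulus.

    Returns an array of shape (len(grid), len(bank)) in the grid's
    lexicographic candidate order.  Building this once per (grid, bank)
    makes per-unit fitting a single mat-vec.
    """
    n_mc, n_sc, n_ma, n_sa = grid.shape
    n_curv = n_mc * n_sc
    n_ang = n_ma * n_sa
    out = np.empty((len(grid), len(bank)), dtype=float)

    mu_c = np.repeat(grid.mu_c, n_sc)          # (n_curv,)
    sg_c = np.tile(grid.sigma_c, n_mc)
    mu_a = np.repeat(grid.mu_a, n_sa)          # (n_ang,)
    sg_a = np.tile(grid.sigma_a, n_ma)

    for s_idx, shape in enumerate(bank):
        c = shape.curvatures
        a = shape.angular_positions
        gc = np.exp(-((c[None, :] - mu_c[:, None]) ** 2) / (2 * sg_c[:, None] ** 2))
        da = wrapped_angle_diff(a[None, :], mu_a[:, None])
        ga = np.exp(-(da ** 2) / (2 * sg_a[:, None] ** 2))
        # (n_curv, n_ang, n_elem) product, max over elements
        prod = gc[:, None, :] * ga[None, :, :]
        out[:, s_idx] = prod.max(axis=2).ravel()
    return out


def pearson_p_value(r: float, n: int) -> float:
    """Two-tailed p-value for a Pearson r via the t distribution, n-2 df."""
    if n < 3 or not np.isfinite(r):
        return np.nan
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def fit_apc(responses: np.ndarray, bank: Sequence[BoundaryShape],
            grid: APCGrid, pred: np.ndarray | None = None) -> APCFit:
    """Grid-fit the APC model to one unit's responses.

    The winning candidate maximizes the Pearson correlation between
    observed and (unit-scale) predicted responses; ties break to the
    first candidate in grid order.  ``k`` is then the no-intercept
    least-squares scale of the winner's predictions onto the data; a
    negative k is flagged as degenerate.  ``pred`` may pass a cached
    :func:`prediction_matrix`.
    """
    x = np.asarray(responses, dtype=float)
    if len(x) != len(bank):
        raise ValueError("responses and bank are misaligned")
    if not np.all(np.isfinite(x)):
        raise ValueError("responses must be finite")
    n = len(x)
    if np.std(x) == 0:
        return APCFit(None, np.nan, np.nan, n, degenerate=True,
                      reason="constant responses")

    if pred is None:
        pred = prediction_matrix(grid, bank)
    # Pearson r per candidate without materializing a centered copy:
    # with xc centered, pred @ xc == pc @ xc, and ||pc||^2 = ss - n*mean^2.
    xc = x - x.mean()
    row_mean = pred.mean(axis=1)
    row_ss = np.einsum("ij,ij->i", pred, pred)
    pnorm = np.sqrt(np.maximum(row_ss - n * row_mean ** 2, 0.0))
    xnorm = np.sqrt((xc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r_all = (pred @ xc) / (pnorm * xnorm)
    r_all[~np.isfinite(r_all)] = -np.inf  # constant-prediction candidates
    best = int(np.argmax(r_all))
    r = float(r_all[best])
    if not np.isfinite(r):
        return APCFit(None, np.nan, np.nan, n, degenerate=True,
                      reason="no usable candidate")

    p_unit = pred[best]
    denom = float(p_unit @ p_unit)
    k = float(p_unit @ x) / denom if denom > 0 else 0.0
    params = grid.params_at(best)
    params = APCParams(params.mu_c, params.sigma_c, params.mu_a, params.sigma_a, k)
    return APCFit(params, r, pearson_p_value(r, n), n, candidate_index=best,
                  degenerate=k < 0, reason="negative k" if k < 0 else "")


def shuffle_control(responses: np.ndarray, seed: int) -> np.ndarray:
    """Permute a response vector across stimuli (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    x = np.asarray(responses, dtype=float)
    return x[rng.permutation(len(x))]
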