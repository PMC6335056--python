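"""Cross-validated comparison of tuning models as predictors of a target
unit's responses, plus residual fitting after removing the APC component.

Two families of predictors are put on equal footing by cross-validation:
the APC grid (select the candidate maximizing train-set correlation) and
a pool of candidate units (select the pool unit maximizing train-set
correlation, least-squares scaled).  For each of ``n_splits`` random
splits, the model is selected on a 4/5 training subset of stimuli and
scored by Pearson r on the held-out 1/5; the summary is the mean test r
and the [2.5, 97.5] percentile band.  Two models are declared
significantly different for a target when their percentile bands do not
overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .apc import APCGrid, APCFit, prediction_matrix, pearson_p_value
from .shapes import BoundaryShape

__all__ = [
    "APCGridModel",
    "UnitPoolModel",
    "CVResult",
    "cv_score",
    "compare_models",
    "orthogonalized_fit",
]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt((a ** 2).sum())
    nb = np.sqrt((b ** 2).sum())
    if na == 0 or nb == 0:
        return np.nan
    return float((a @ b) / (na * nb))


class APCGridModel:
    """Candidate family = unit-scale APC predictions over a grid."""

    def __init__(self, bank: Sequence[BoundaryShape], grid: APCGrid,
                 pred: np.ndarray | None = None):
        self.pred = prediction_matrix(grid, bank) if pred is None else pred

    @property
    def candidates(self) -> np.ndarray:
        return self.pred

    def fit(self, target: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
        """Select the best candidate on the training stimuli; return its
        full-length prediction vector (selection by r, which is scale-free)."""
        return _best_candidate(self.pred, target, train_idx)


class UnitPoolModel:
    """Candidate family = responses of a pool of units (rows x stimuli)."""

    def __init__(self, pool: np.ndarray):
        self.pool = np.asarray(pool, dtype=float)
        if self.pool.ndim != 2:
            raise ValueError("pool must be 2-D (units x stimuli)")

    @property
    def candidates(self) -> np.ndarray:
        return self.pool

    def fit(self, target: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
        return _best_candidate(self.pool, target, train_idx)


def _best_candidate(cands: np.ndarray, target: np.ndarray,
                    train_idx: np.ndarray) -> np.ndarray:
    sub = cands[:, train_idx]
    t = target[train_idx]
    tc = t - t.mean()
    tn = np.sqrt((tc ** 2).sum())
    sc = sub - sub.mean(axis=1, keepdims=True)
    sn = np.sqrt((sc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (sc @ tc) / (sn * tn)
    r[~np.isfinite(r)] = -np.inf
    return cands[int(np.argmax(r))]


@dataclass
class CVResult:
    mean_r: float
    band: tuple
    per_split_r: np.ndarray
    n_skipped: int = 0


def cv_score(target: np.ndarray, model, n_splits: int = 50,
             train_frac: float = 0.8, seed: int = 0) -> CVResult:
    """Cross-validated fit quality of a model family for one target.

    Each split draws a random ``train_frac`` subset of stimuli (no
    stratification; rotations of one base shape may fall on both sides),
    selects the best candidate on it, and scores Pearson r on the
    held-out remainder.  Degenerate splits (constant train or test
    target) are skipped and counted.
    """
    t = np.asarray(target, dtype=float)
    n = len(t)
    if n < 10:
        raise ValueError("target must have >= 10 stimuli")
    n_train = int(round(train_frac * n))
    rng = np.random.default_rng(seed)
    rs = []
    skipped = 0
    for _ in range(n_splits):
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        if np.std(t[train_idx]) == 0 or np.std(t[test_idx]) == 0:
            skipped += 1
            continue
        predictor = model.fit(t, train_idx)
        r = _pearson(predictor[test_idx], t[test_idx])
        if np.isfinite(r):
            rs.append(r)
        else:
            skipped += 1
    rs = np.asarray(rs)
    if len(rs) == 0:
        return CVResult(np.nan, (np.nan, np.nan), rs, skipped)
    band = (float(np.percentile(rs, 2.5)), float(np.percentile(rs, 97.5)))
    return CVResult(float(rs.mean()), band, rs, skipped)


def compare_models(targets: Sequence[np.ndarray], pool: np.ndarray,
                   bank: Sequence[BoundaryShape], grid: APCGrid,
                   n_splits: int = 50, seed: int = 0,
                   apc_pred: np.ndarray | None = None) -> pd.DataFrame:
    """Per-target APC-vs-pool comparison table.

    Returns a DataFrame with mean test r for each model, percentile
    bands, the winner by mean test r, and a significance flag set when
    the two bands do not overlap.
    """
    apc_model = APCGridModel(bank, grid, pred=apc_pred)
    pool_model = UnitPoolModel(pool)
    rows = []
    ss = np.random.SeedSequence(seed)
    for i, (t, child) in enumerate(zip(targets, ss.spawn(len(targets)))):
        s1, s2 = child.spawn(2)
        res_a = cv_score(t, apc_model, n_splits=n_splits,
                         seed=int(s1.generate_state(1)[0] % 2**31))
        res_p = cv_score(t, pool_model, n_splits=n_splits,
                         seed=int(s2.generate_state(1)[0] % 2**31))
        overlap = not (res_a.band[0] > res_p.band[1] or res_p.band[0] > res_a.band[1])
        winner = "apc" if res_a.mean_r >= res_p.mean_r else "pool"
        rows.append(dict(target_id=i,
                         r_apc_mean=res_a.mean_r, r_pool_mean=res_p.mean_r,
                         apc_lo=res_a.band[0], apc_hi=res_a.band[1],
                         pool_lo=res_p.band[0], pool_hi=res_p.band[1],
                         winner=winner, significant=not overlap))
    return pd.DataFrame(rows)


def orthogonalized_fit(target: np.ndarray, apc_fit: APCFit,
                       bank: Sequence[BoundaryShape], pool: np.ndarray,
                       intercept: bool = True) -> dict:
    """Correlation of the best pool unit with the APC-orthogonalized target.

    The component of the target explained by its best-fit APC model is
    removed by least squares (by default with an intercept, so the full
    explained variance is removed), then the pool unit best correlated
    with the residual is reported.  Returns a dict with ``residual_r``,
    ``pool_index``, ``p_value`` and a ``degenerate`` flag for a
    near-zero-variance residual.
    """
    if apc_fit.degenerate or apc_fit.params is None:
        raise ValueError("APC fit is degenerate; residual undefined")
    from .apc import apc_predict  # local import to avoid cycle at module load

    t = np.asarray(target, dtype=float)
    p = np.array([apc_predict(apc_fit.params, s) for s in bank])
    if intercept:
        X = np.column_stack([np.ones_like(p), p])
    else:
        X = p[:, None]
    coef, *_ = np.linalg.lstsq(X, t, rcond=None)
    resid = t - X @ coef

    if np.std(resid) < 1e-12 * max(1.0, np.std(t)):
        return dict(residual_r=np.nan, pool_index=-1, p_value=np.nan,
                    degenerate=True)
    pool = np.asarray(pool, dtype=float)
    rc = resid - resid.mean()
    pc = pool - pool.mean(axis=1, keepdims=True)
    pn = np.sqrt((pc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = (pc @ rc) / (pn * np.sqrt((rc ** 2).sum()))
    rs[~np.isfinite(rs)] = -np.inf
    best = int(np.argmax(rs))
    r = float(rs[best])
    return dict(residual_r=r, pool_index=best,
                p_value=pearson_p_value(r, len(t)), degenerate=False)
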