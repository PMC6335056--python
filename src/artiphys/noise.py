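"""Corrections for trial-to-trial variability in stochastic responses.

Two corrections are provided.  The explained-variance correction removes
the downward bias that response noise imparts on the correlation between
a model and trial-averaged data.  After a variance-stabilizing square
root transform (appropriate for near-Poisson spike counts), with m
stimuli, n trials, per-stimulus means centered on the grand mean, model
fitted by least squares:

    Rc^2 = (beta^2 - s2/n) / (alpha^2 + beta^2 - (s2/n) (m - 1))

where beta^2 is the sum of squared fitted model predictions, alpha^2 the
sum of squared residuals, and s2 the across-trial sample variance
averaged over stimuli.  Both corrections are identities in the no-noise
limit.

The TI statistic is not a correlation coefficient, so its noise ceiling
is estimated by simulation instead: an ideal perfectly-invariant neuron
is built by replicating the best position's mean responses at every other
position (rescaled to match each position's observed mean), Poisson
trials are simulated at the original repeat counts, and the average drop
of TI below 1 bounds how much noise could have depressed the measured TI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .invariance import ResponseMatrix, ti_metric

__all__ = [
    "TrialData",
    "CorrectedR2",
    "TINoiseCeiling",
    "corrected_r2",
    "corrected_r2_from_stats",
    "ti_noise_ceiling",
]


@dataclass
class TrialData:
    """Spike counts for one unit at one position: stimuli (m) x trials (n)."""

    counts: np.ndarray
    sqrt_applied: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (stimuli x trials)")
        m, n = self.counts.shape
        if m < 2 or n < 2:
            raise ValueError("need >= 2 stimuli and >= 2 trials")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_stimuli(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]


@dataclass
class CorrectedR2:
    r2_raw: float
    r2_corrected: float
    r_corrected: float
    clipped: bool
    beta2: float
    alpha2: float
    s2_bar: float


def corrected_r2_from_stats(beta2: float, alpha2: float, s2_bar: float,
                            n: int, m: int) -> tuple:
    """The correction formula itself; returns (Rc2, clipped_flag)."""
    num = beta2 - s2_bar / n
    den = alpha2 + beta2 - (s2_bar / n) * (m - 1)
    rc2 = num / den
    clipped = rc2 < 0.0 or rc2 > 1.0
    return float(np.clip(rc2, 0.0, 1.0)), clipped


def corrected_r2(trials: TrialData, predictions: np.ndarray,
                 sqrt_transform: bool = True) -> CorrectedR2:
    """Noise-corrected explained variance of a model on trial data.

    The square-root transform (skipped only if already applied) is
    mandatory before the formula, which assumes equal variance across
    stimuli.  Predictions are centered and least-squares scaled onto the
    grand-mean-centered per-stimulus means.  Out-of-range values are
    clipped to [0, 1] and flagged; the corrected r carries the sign of
    the raw fit.
    """
    y = trials.counts
    if sqrt_transform and not trials.sqrt_applied:
        y = np.sqrt(y)
    m, n = y.shape
    pred = np.asarray(predictions, dtype=float)
    if len(pred) != m:
        raise ValueError("predictions misaligned with stimuli")

    means = y.mean(axis=1)
    centered = means - means.mean()
    s2_bar = float(y.var(axis=1, ddof=1).mean())

    pc = pred - pred.mean()
    denom = float(pc @ pc)
    if denom == 0:
        raise ValueError("constant predictions; fit undefined")
    b = float(pc @ centered) / denom
    fitted = b * pc
    resid = centered - fitted
    beta2 = float((fitted ** 2).sum())
    alpha2 = float((resid ** 2).sum())
    tot = beta2 + alpha2
    r2_raw = beta2 / tot if tot > 0 else np.nan

    rc2, clipped = corrected_r2_from_stats(beta2, alpha2, s2_bar, n, m)
    r_corr = float(np.sign(b) * np.sqrt(rc2))
    return CorrectedR2(r2_raw, rc2, r_corr, clipped, beta2, alpha2, s2_bar)


@dataclass
class TINoiseCeiling:
    ti_drop: float
    corrected_upper_bound: float
    ti_sims: np.ndarray


def ti_noise_ceiling(trials_by_position: Sequence[TrialData],
                     raw_ti: float, n_sims: int = 100,
                     seed: int = 0,
                     best_position: str = "mean") -> TINoiseCeiling:
    """Upper bound on how much Poisson variability could depress TI.

    ``best_position`` selects the reference column: "mean" (greatest
    mean response across stimuli, the default) or "max" (greatest single
    response).
    """
    if len(trials_by_position) < 2:
        raise ValueError("need trial data at >= 2 positions")
    means = np.column_stack([t.counts.mean(axis=1) for t in trials_by_position])
    pos_mean = means.mean(axis=0)
    if np.any(pos_mean <= 0):
        raise ValueError("every position must have a positive mean response")
    if best_position == "mean":
        best = int(np.argmax(pos_mean))
    elif best_position == "max":
        best = int(np.argmax(means.max(axis=0)))
    else:
        raise ValueError("best_position must be 'mean' or 'max'")

    # ideal TI = 1 rate matrix: best column replicated, rescaled per position
    ideal = means[:, [best]] * (pos_mean / pos_mean[best])[None, :]
    repeats = [t.n_trials for t in trials_by_position]
    positions = np.arange(means.shape[1])

    rng = np.random.default_rng(seed)
    ti_sims = np.empty(n_sims)
    for s in range(n_sims):
        sim_means = np.column_stack([
            rng.poisson(ideal[:, [p]].repeat(repeats[p], axis=1)).mean(axis=1)
            for p in range(means.shape[1])
        ])
        ti_sims[s] = ti_metric(ResponseMatrix(sim_means, positions))
    ti_drop = float(np.mean(1.0 - ti_sims))
    return TINoiseCeiling(ti_drop, min(1.0, raw_ti + ti_drop), ti_sims)
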