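"""Synthetic units with known ground truth for every pipeline stage.

Generates descriptor-level units: APC-tuned responders (the forward
model, optionally with Gaussian or Poisson trial noise), stimuli x
positions response matrices with a controllable translation-invariance
level, and heterogeneous V4-like populations with Poisson spike counts
at realistic repeat counts (3-5 per stimulus for tuning data, more for
invariance data).  Every generated dataset carries its generating
parameters so recovery can be scored exactly.

The positioned-response construction is

    values[s, x] = G(x) * ((1 - eps) * T(s) + eps * T_x(s))

with T the base shape tuning, G a positive RF profile and T_x
position-specific tunings drawn as independent seeded permutations of T
(preserving the response distribution at every position while destroying
the across-position correlation that TI measures).  eps = 0 gives TI = 1
exactly; eps = 1 gives TI ~ 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .apc import APCGrid, APCParams, apc_predict, build_grid
from .invariance import ResponseMatrix
from .noise import TrialData
from .shapes import BoundaryShape

__all__ = [
    "SyntheticUnitSpec",
    "make_apc_unit",
    "make_positioned_unit",
    "make_v4like_dataset",
    "on_grid_params",
]


@dataclass
class SyntheticUnitSpec:
    """Declarative description of one synthetic unit.

    ``noise`` is None, ("gaussian", sd), or ("poisson", rate_scale,
    n_trials); ``rate_scale`` is the mean spike count of the best
    stimulus per trial (kept in the 0-50 regime of cortical data).
    """

    kind: str = "apc"
    apc_params: APCParams | None = None
    rf_width: float = 30.0
    ti_mix: float = 0.0
    noise: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.ti_mix <= 1.0:
            raise ValueError("ti_mix must lie in [0, 1]")


def on_grid_params(grid: APCGrid, rng: np.random.Generator,
                   k: float = 1.0) -> APCParams:
    """Draw APC parameters uniformly from the grid's candidate values."""
    return APCParams(
        float(rng.choice(grid.mu_c)), float(rng.choice(grid.sigma_c)),
        float(rng.choice(grid.mu_a)), float(rng.choice(grid.sigma_a)), k)


def _base_tuning(spec: SyntheticUnitSpec, bank: Sequence[BoundaryShape],
                 rng: np.random.Generator) -> np.ndarray:
    if spec.kind == "random":
        return rng.standard_normal(len(bank))
    if spec.apc_params is None:
        raise ValueError(f"kind {spec.kind!r} requires apc_params")
    return np.array([apc_predict(spec.apc_params, s) for s in bank])


def make_apc_unit(spec: SyntheticUnitSpec,
                  bank: Sequence[BoundaryShape]) -> tuple:
    """Responses of one APC-tuned unit; returns (responses, TrialData|None).

    With Poisson noise the returned responses are the across-trial mean
    counts and the raw counts ship alongside; rates are scaled so the
    best stimulus averages ``rate_scale`` counts per trial.
    """
    rng = np.random.default_rng(spec.seed)
    base = _base_tuning(spec, bank, rng)
    if spec.noise is None:
        return base, None
    kind = spec.noise[0]
    if kind == "gaussian":
        sd = float(spec.noise[1])
        return base + rng.normal(0.0, sd, size=len(base)), None
    if kind == "poisson":
        rate_scale, n_trials = float(spec.noise[1]), int(spec.noise[2])
        peak = base.max()
        rates = rate_scale * base / peak if peak > 0 else np.zeros_like(base)
        counts = rng.poisson(rates[:, None], size=(len(base), n_trials))
        trials = TrialData(counts.astype(float))
        return counts.mean(axis=1), trials
    raise ValueError(f"unknown noise kind {kind!r}")


def _rf_profile_values(positions: np.ndarray, width: float) -> np.ndarray:
    center = positions.mean()
    return np.exp(-((positions - center) ** 2) / (2 * (width / 2.355) ** 2))


def make_positioned_unit(spec: SyntheticUnitSpec,
                         bank: Sequence[BoundaryShape],
                         positions: Sequence[float]) -> ResponseMatrix:
    """Stimuli x positions responses with TI controlled by ``spec.ti_mix``."""
    rng = np.random.default_rng(spec.seed)
    positions = np.asarray(positions, dtype=float)
    T = _base_tuning(spec, bank, rng)
    G = _rf_profile_values(positions, spec.rf_width)
    eps = spec.ti_mix
    cols = []
    for x in range(len(positions)):
        T_x = rng.permutation(T)
        cols.append(G[x] * ((1.0 - eps) * T + eps * T_x))
    return ResponseMatrix(np.column_stack(cols), positions)


@dataclass
class V4LikeNeuron:
    """One simulated neuron: trial counts per position plus ground truth."""

    unit_id: str
    trials_by_position: list
    positions: np.ndarray
    mean_matrix: ResponseMatrix
    true_params: APCParams
    true_ti_mix: float
    rate_scale: float
    repeats: int


def make_v4like_dataset(n_neurons: int, bank: Sequence[BoundaryShape],
                        positions: Sequence[float],
                        repeats: tuple = (3, 5),
                        rate_range: tuple = (10.0, 50.0),
                        grid: APCGrid | None = None,
                        seed: int = 0) -> list:
    """Heterogeneous Poisson population with a ground-truth manifest.

    Per neuron: on-grid APC parameters, a TI mixing level eps ~ U[0, 1],
    a firing-rate scale in ``rate_range`` (mean counts per trial for the
    best stimulus), a repeat count drawn from ``repeats`` inclusive, and
    independent Poisson trials at every stimulus x position.
    """
    if grid is None:
        grid = build_grid()
    positions = np.asarray(positions, dtype=float)
    ss = np.random.SeedSequence(seed)
    neurons = []
    for i, child in enumerate(ss.spawn(n_neurons)):
        rng = np.random.default_rng(child)
        params = on_grid_params(grid, rng)
        eps = float(rng.uniform(0.0, 1.0))
        rate = float(rng.uniform(*rate_range))
        n_rep = int(rng.integers(repeats[0], repeats[1] + 1))
        unit_seed = int(child.generate_state(1)[0] % 2**31)
        spec = SyntheticUnitSpec(kind="apc", apc_params=params, ti_mix=eps,
                                 seed=unit_seed)
        mean_mat = make_positioned_unit(spec, bank, positions)
        peak = mean_mat.values.max()
        rates = rate * np.clip(mean_mat.values, 0.0, None) / peak if peak > 0 \
            else np.zeros_like(mean_mat.values)
        trials = []
        sim_means = np.empty_like(rates)
        for p in range(len(positions)):
            counts = rng.poisson(rates[:, [p]].repeat(n_rep, axis=1))
            trials.append(TrialData(counts.astype(float)))
            sim_means[:, p] = counts.mean(axis=1)
        neurons.append(V4LikeNeuron(
            unit_id=f"v4like-{i:03d}", trials_by_position=trials,
            positions=positions,
            mean_matrix=ResponseMatrix(sim_means, positions),
            true_params=params, true_ti_mix=eps, rate_scale=rate,
            repeats=n_rep))
    return neurons
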