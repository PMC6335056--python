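"""Response-sparsity screening by kurtosis.

Units whose response sparsity (fourth-moment kurtosis, population
estimators) falls outside the range observed in V4 spiking data
(2.9 to 42) are excluded before characterization: very sparse or
near-uniform responders give degenerate tuning-model fits.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["kurtosis", "sparsity_filter", "KURTOSIS_LO", "KURTOSIS_HI"]

KURTOSIS_LO = 2.9
KURTOSIS_HI = 42.0


def kurtosis(responses: np.ndarray) -> float:
    """K = (1/n) sum (x_i - mean)^4 / sd^4, population (1/n) moments.

    K >= 1 for any non-constant vector; a Gaussian gives 3.  Raises on a
    constant vector, where K is undefined.
    """
    x = np.asarray(responses, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("responses must be a 1-D vector of length >= 2")
    if np.std(x) == 0:
        raise ValueError("kurtosis undefined for a constant response vector")
    return float(stats.kurtosis(x, fisher=False, bias=True))


def sparsity_filter(units: Mapping[str, np.ndarray],
                    lo: float = KURTOSIS_LO,
                    hi: float = KURTOSIS_HI) -> tuple:
    """Retain units with lo <= K <= hi; report exclusions by reason.

    Returns ``(retained_ids, report)`` where ``report`` is a DataFrame
    with columns unit_id, K, reason, retained.  All-zero and constant
    units (undefined K) are always excluded.
    """
    rows = []
    retained = []
    for uid, x in units.items():
        x = np.asarray(x, dtype=float)
        if np.all(x == 0):
            rows.append((uid, np.nan, "no response", False))
            continue
        if np.std(x) == 0:
            rows.append((uid, np.nan, "constant response", False))
            continue
        k = kurtosis(x)
        if k < lo:
            rows.append((uid, k, "kurtosis below range", False))
        elif k > hi:
            rows.append((uid, k, "kurtosis above range", False))
        else:
            rows.append((uid, k, "", True))
            retained.append(uid)
    report = pd.DataFrame(rows, columns=["unit_id", "K", "reason", "retained"])
    return retained, report
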