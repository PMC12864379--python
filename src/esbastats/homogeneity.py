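"""Stuart-Maxwell test of marginal homogeneity for paired ordinal ratings.

For a K x K paired contingency table N (cell (i, j) = subjects rated i at
the first assessment and j at the second), the test compares the row and
column marginals.  With d the first K-1 components of the row-minus-column
marginal differences and V the estimated covariance of d under the null
(diagonal ``n_{i+} + n_{+i} - 2 n_{ii}``, off-diagonal ``-(n_{ij} +
n_{ji})``), the statistic is the quadratic form ``d' V^- d`` computed with
a Moore-Penrose generalized inverse.  The degrees of freedom default to
``rank(V)``, which handles tables whose baseline is concentrated in a
single category (singular V); ``df_method="categories"`` uses the fixed
K-1 convention of much mainstream software.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import PhaseCountTable, COOPERATIVE

__all__ = ["stuart_maxwell", "phase_transition_table"]


def stuart_maxwell(table, df_method: str = "rank"):
    """Stuart-Maxwell marginal-homogeneity test on a square count table.

    Returns ``(statistic, df, p)``.  A perfectly symmetric (or
    all-diagonal) table yields statistic 0 with df possibly 0, reported
    with p = 1.
    """
    N = np.asarray(table, dtype=float)
    if N.ndim != 2 or N.shape[0] != N.shape[1]:
        raise ValueError("table must be square")
    if np.any(N < 0):
        raise ValueError("counts must be non-negative")
    if N.sum() <= 0:
        raise ValueError("table total must be positive")
    K = N.shape[0]
    d = (N.sum(axis=1) - N.sum(axis=0))[:K - 1]
    V = np.empty((K - 1, K - 1))
    for i in range(K - 1):
        for j in range(K - 1):
            if i == j:
                V[i, j] = N[i].sum() + N[:, i].sum() - 2 * N[i, i]
            else:
                V[i, j] = -(N[i, j] + N[j, i])
    rank = int(np.linalg.matrix_rank(V))
    stat = float(d @ np.linalg.pinv(V) @ d)
    if df_method == "rank":
        df = rank
    elif df_method == "categories":
        df = K - 1
    else:
        raise ValueError("df_method must be 'rank' or 'categories'")
    if df == 0:
        return 0.0, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def phase_transition_table(data, phase: int, cohort: str | None = None
                           ) -> np.ndarray:
    """4 x 4 paired table of first-visit vs end-of-phase ratings.

    ``data`` may be a child-level DataFrame (columns ``frankl_t0`` and
    ``frankl_p{phase}``; optionally filtered to one cohort via
    ``cohort``), or a :class:`PhaseCountTable` of marginal counts.  In the
    latter case the joint table is only determined when the baseline is
    concentrated in a single category (the cooperative cohort); otherwise
    a ``ValueError`` explains that the joint table is undetermined.
    """
    if phase not in (1, 2, 3):
        raise ValueError("phase must be 1, 2 or 3")
    if isinstance(data, PhaseCountTable):
        baseline = np.asarray(data.counts[0])
        nonzero = np.nonzero(baseline)[0]
        if len(nonzero) != 1:
            raise ValueError(
                "joint table undetermined: marginal counts with more than "
                "one baseline category cannot be cross-tabulated; supply "
                "child-level data")
        out = np.zeros((4, 4), dtype=int)
        out[nonzero[0], :] = np.asarray(data.counts[phase], dtype=int)
        return out
    df = data
    if cohort is not None:
        init = 0 if cohort != COOPERATIVE else 1
        mask = df["frankl_t0"].map(lambda v: 0 if int(v) <= 2 else 1) == init
        df = df[mask]
    out = np.zeros((4, 4), dtype=int)
    for t0, tk in zip(df["frankl_t0"].astype(int),
                      df[f"frankl_p{phase}"].astype(int)):
        out[t0 - 1, tk - 1] += 1
    return out
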