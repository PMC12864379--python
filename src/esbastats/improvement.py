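"""Cohort-specific improvement probabilities and bootstrap intervals.

*Improvement* is defined relative to the baseline cohort: an initially
uncooperative child (``Init.Rating = 0``) has improved by the end of a
phase if rated positive or definitely positive there (``Y >= 3``); an
initially cooperative child (``Init.Rating = 1``) has improved if rated
definitely positive (``Y = 4``).

Model-based improvement probabilities come from a fitted cumulative
logit model containing ``Phase`` and ``Init.Rating``; 95% intervals use
the percentile bootstrap: resample children, refit the *selected* spec
(selection is not re-run), recompute the six predicted probabilities,
and take the 2.5 and 97.5 empirical percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import PhaseCountTable, frankl_to_level
from .ordinal import CumulativeLogitModel, CumulativeLogitResults, ModelSpec, \
    fit_proportional
from .selection import bootstrap_indices

__all__ = [
    "improved",
    "observed_improvement_pct",
    "improvement_probability",
    "ImprovementEstimate",
    "bootstrap_improvement_ci",
    "estimates_frame",
    "figure2_table",
]


def improved(init_rating: int, rating) -> bool:
    """Whether a rating counts as improvement for the given baseline cohort."""
    level = frankl_to_level(rating)
    if init_rating not in (0, 1):
        raise ValueError("init_rating must be 0 or 1")
    return level >= 3 if init_rating == 0 else level == 4


def observed_improvement_pct(table: PhaseCountTable) -> dict[int, float]:
    """Observed percentage of improved children per phase (1-3)."""
    out = {}
    for phase in table.phases():
        if phase == 0:
            continue
        counts = table.counts[phase]
        n_improved = sum(c for lev, c in zip((1, 2, 3, 4), counts)
                         if improved(table.init_rating, lev))
        out[phase] = round(100.0 * n_improved / table.n, 1)
    return out


def improvement_probability(fit: CumulativeLogitResults, init_rating: int,
                            phase: int) -> float:
    """Model-predicted improvement probability for one cohort and phase."""
    names = fit.model.exog_names
    if "Phase" not in names or "Init.Rating" not in names:
        raise ValueError("fit must include Phase and Init.Rating")
    probs = fit.predict({"Phase": float(phase),
                         "Init.Rating": float(init_rating)})
    return float(probs[2] + probs[3]) if init_rating == 0 else float(probs[3])


@dataclass(frozen=True)
class ImprovementEstimate:
    """Point estimate and percentile-bootstrap CI for one cohort-phase."""

    init_rating: int
    phase: int
    point: float
    ci_low: float
    ci_high: float
    level: float
    B: int
    seed: int
    n_invalid: int = 0

    @property
    def point_outside_ci(self) -> bool:
        return not (self.ci_low <= self.point <= self.ci_high)


def bootstrap_improvement_ci(spec: ModelSpec, long_df: pd.DataFrame,
                             B: int = 2000, seed: int = 0,
                             level: float = 0.95,
                             resample_unit: str = "child",
                             stratify: bool = True
                             ) -> list[ImprovementEstimate]:
    """Percentile-bootstrap CIs for the six improvement probabilities.

    One shared set of B bootstrap refits of ``spec`` produces all six
    intervals (2 cohorts x 3 phases).  Replicates with non-converged or
    degenerate fits are excluded and counted; more than B/2 exclusions is
    an error.  Fully reproducible given ``seed``.
    """
    from .ordinal import design_matrix

    base = fit_proportional(spec, long_df)
    points = {(init, phase): improvement_probability(base, init, phase)
              for init in (0, 1) for phase in (1, 2, 3)}
    rng = np.random.default_rng(seed)
    # complete cases for the spec's own predictors, resampled as children
    cc = long_df.loc[base.model.used_index].reset_index(drop=True)
    y_all, X_all, names, _ = design_matrix(cc, spec)
    draws = {key: [] for key in points}
    n_invalid = 0
    for _ in range(B):
        pos = bootstrap_indices(cc, rng, unit=resample_unit,
                                stratify=stratify)
        if np.any(np.bincount(y_all[pos], minlength=5)[1:] == 0):
            n_invalid += 1  # replicate lost a response category
            continue
        try:
            r = CumulativeLogitModel(y_all[pos], X_all[pos],
                                     exog_names=names, spec=spec).fit(
                start_params=base.params, compute_vcov=False)
        except Exception:
            n_invalid += 1
            continue
        if not r.converged or r.degenerate:
            n_invalid += 1
            continue
        for key in draws:
            draws[key].append(improvement_probability(r, *key))
    if n_invalid > B / 2:
        raise RuntimeError(f"{n_invalid} of {B} bootstrap replicates were "
                           "degenerate; intervals are unreliable")
    alpha = 1.0 - level
    out = []
    for (init, phase), vals in draws.items():
        vals = np.asarray(vals)
        lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2],
                             method="linear")
        out.append(ImprovementEstimate(
            init_rating=init, phase=phase, point=points[(init, phase)],
            ci_low=float(lo), ci_high=float(hi), level=level, B=B,
            seed=seed, n_invalid=n_invalid))
    return out


def estimates_frame(estimates: Sequence[ImprovementEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "init_rating": e.init_rating,
        "phase": e.phase,
        "point": e.point,
        "ci_low": e.ci_low,
        "ci_high": e.ci_high,
    } for e in estimates]).sort_values(["init_rating", "phase"]) \
        .reset_index(drop=True)


def figure2_table(fit: CumulativeLogitResults,
                  tables: Sequence[PhaseCountTable],
                  cis: Optional[Sequence[ImprovementEstimate]] = None
                  ) -> pd.DataFrame:
    """Observed vs model-predicted improvement percentages per cohort-phase.

    When bootstrap estimates are supplied, each row also carries the CI
    (as percentages) and a flag for observed values falling outside it.
    """
    ci_map = {}
    if cis is not None:
        ci_map = {(e.init_rating, e.phase): e for e in cis}
    rows = []
    for table in tables:
        observed = observed_improvement_pct(table)
        for phase in sorted(observed):
            pred = 100.0 * improvement_probability(fit, table.init_rating,
                                                   phase)
            row = {
                "cohort": table.cohort,
                "init_rating": table.init_rating,
                "phase": phase,
                "observed_pct": observed[phase],
                "predicted_pct": pred,
            }
            est = ci_map.get((table.init_rating, phase))
            if est is not None:
                row["ci_low_pct"] = 100.0 * est.ci_low
                row["ci_high_pct"] = 100.0 * est.ci_high
                row["observed_in_ci"] = bool(
                    row["ci_low_pct"] <= observed[phase] <= row["ci_high_pct"])
            rows.append(row)
    return pd.DataFrame(rows)
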