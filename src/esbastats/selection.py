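"""Model-space enumeration and bootstrap-BIC one-standard-error selection.

The candidate space over a predictor vocabulary containing ``Phase``
consists of every main-effect subset, plus — for each subset containing
``Phase`` and at least one other predictor X — one additional candidate
per choice of a *single* ``Phase x X`` interaction.  For p predictors this
gives ``2^p + (p-1) 2^(p-2)`` specifications: 3,328 for the ten study
predictors.

Selection proceeds in three steps: (1) draw B bootstrap copies of the
dataset, resampling whole children so that the three phase rows of a
child move together; (2) refit every candidate on every copy and record
its BIC; (3) take the model with the smallest mean bootstrap BIC, and
return the most parsimonious candidate whose mean BIC lies within one
standard deviation (of the winner's bootstrap BIC distribution) of the
winning mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence
import warnings

import numpy as np
import pandas as pd

from .ordinal import (
    CumulativeLogitModel,
    CumulativeLogitResults,
    ModelSpec,
    STUDY_PREDICTORS,
    design_matrix,
    fit_proportional,
)

__all__ = [
    "enumerate_models",
    "partition_figure1",
    "spec_n_params",
    "selection_sample",
    "bootstrap_indices",
    "BootstrapBICSummary",
    "bootstrap_bic",
    "select_min_bic",
    "select_1se",
    "refit_largest_sample",
]

#: design columns contributed by each predictor (reference-coded dummies)
_N_COLS = {
    "Phase": 1,
    "Init.Rating": 1,
    "Age": 1,
    "Gender": 1,
    "Natural birth": 1,
    "Medications": 1,
    "Previous anesthesia": 1,
    "Dental health status": 1,
    "Gingival status": 2,
    "Plaque index": 3,
}


def enumerate_models(vocabulary: Sequence[str] = STUDY_PREDICTORS
                     ) -> list[ModelSpec]:
    """All candidate specs over ``vocabulary`` in canonical order.

    Canonical order: by subset size, then by predictor positions in the
    vocabulary, main-effects-only before interaction variants.  If the
    vocabulary lacks ``Phase`` the plain power set is returned with a
    warning (no interactions are possible).
    """
    vocabulary = tuple(vocabulary)
    if len(set(vocabulary)) != len(vocabulary):
        raise ValueError("duplicate predictors in vocabulary")
    has_phase = "Phase" in vocabulary
    if not has_phase:
        warnings.warn("vocabulary has no 'Phase'; enumerating main-effect "
                      "subsets only")
    specs: list[ModelSpec] = []
    for size in range(len(vocabulary) + 1):
        for subset in combinations(vocabulary, size):
            specs.append(ModelSpec(subset))
            if has_phase and "Phase" in subset:
                for x in subset:
                    if x != "Phase":
                        specs.append(ModelSpec(subset, interaction=x))
    return specs


def spec_n_params(spec: ModelSpec) -> int:
    """Free parameters of the proportional-odds fit: 3 thresholds plus one
    slope per design column."""
    k = 3 + sum(_N_COLS[p] for p in spec.main_effects)
    if spec.interaction is not None:
        k += _N_COLS[spec.interaction]
    return k


FIGURE1_LABELS = {
    "i": "neither Phase nor Init.Rating",
    "ii": "Phase without Init.Rating",
    "iii": "Init.Rating without Phase",
    "iv": "both, no interaction",
    "v": "both, with a Phase interaction",
}


def partition_figure1(specs: Iterable[ModelSpec]) -> dict[str, list[ModelSpec]]:
    """Disjoint exhaustive partition of the model space into the five
    subgroups defined by membership of Phase / Init.Rating and presence of
    an interaction.  Subgroup (v) comprises every spec with both main
    effects and *any* ``Phase x X`` interaction (including X =
    Init.Rating)."""
    out: dict[str, list[ModelSpec]] = {k: [] for k in FIGURE1_LABELS}
    for spec in specs:
        has_phase = "Phase" in spec.main_effects
        has_init = "Init.Rating" in spec.main_effects
        if not has_phase and not has_init:
            out["i"].append(spec)
        elif has_phase and not has_init:
            out["ii"].append(spec)
        elif has_init and not has_phase:
            out["iii"].append(spec)
        elif spec.interaction is None:
            out["iv"].append(spec)
        else:
            out["v"].append(spec)
    return out


def selection_sample(long_df: pd.DataFrame,
                     vocabulary: Sequence[str] = STUDY_PREDICTORS
                     ) -> pd.DataFrame:
    """Rows of children with complete information on *all* vocabulary
    predictors — the common sample on which every candidate is compared."""
    full = ModelSpec(tuple(vocabulary))
    _, _, _, index = design_matrix(long_df, full)
    kept_children = set(long_df.loc[index, "child_id"])
    return long_df[long_df["child_id"].isin(kept_children)].copy()


def bootstrap_indices(long_df: pd.DataFrame, rng: np.random.Generator,
                      unit: str = "child", stratify: bool = True
                      ) -> np.ndarray:
    """Positional row indices of one bootstrap copy of the dataset.

    ``unit="child"`` resamples whole children (all their phase rows move
    together); ``unit="row"`` resamples long-format rows.  With
    ``stratify`` the draw is done within each baseline cohort
    (``init_rating`` stratum) to its original size, so neither cohort can
    vanish from a replicate.
    """
    if unit not in ("child", "row"):
        raise ValueError("resample unit must be 'child' or 'row'")
    init = long_df["init_rating"].to_numpy()
    if unit == "row":
        pos = np.arange(len(long_df))
        if stratify:
            picks = [rng.choice(pos[init == v], size=(init == v).sum(),
                                replace=True) for v in np.unique(init)]
            return np.concatenate(picks)
        return rng.choice(pos, size=len(pos), replace=True)
    # child level: build row-position lists per child
    child = long_df["child_id"].to_numpy()
    order = {}
    for i, c in enumerate(child):
        order.setdefault(c, []).append(i)
    ids = np.array(list(order))
    child_init = np.array([init[order[c][0]] for c in ids])
    if stratify:
        chosen = []
        for v in np.unique(child_init):
            pool = ids[child_init == v]
            chosen.append(rng.choice(pool, size=len(pool), replace=True))
        chosen = np.concatenate(chosen)
    else:
        chosen = rng.choice(ids, size=len(ids), replace=True)
    return np.concatenate([order[c] for c in chosen])


@dataclass
class BootstrapBICSummary:
    """Per-model bootstrap BIC distribution summary.

    ``table`` is indexed by spec label with columns ``mean_bic``,
    ``sd_bic``, ``n_invalid`` and ``n_params``; models invalid in more
    than B/2 replicates have NaN summaries and are excluded from
    selection.
    """

    specs: list[ModelSpec]
    table: pd.DataFrame
    B: int
    seed: int
    resample_unit: str = "child"
    stratified: bool = True

    def valid_specs(self) -> list[ModelSpec]:
        ok = self.table["mean_bic"].notna().to_numpy()
        return [s for s, v in zip(self.specs, ok) if v]


def bootstrap_bic(specs: Sequence[ModelSpec], long_df: pd.DataFrame,
                  B: int = 2000, seed: int = 0,
                  resample_unit: str = "child", stratify: bool = True,
                  tol: float = 1e-8) -> BootstrapBICSummary:
    """Bootstrap BIC distributions for every candidate spec.

    All candidates are refit on each of B bootstrap copies of
    ``long_df`` (which should be the common complete-case selection
    sample, see :func:`selection_sample`).  A replicate fit is *invalid*
    for a model when it fails to converge or leaves a response category
    empty (threshold drift); invalid replicates are excluded from that
    model's mean/SD and counted.
    """
    specs = list(specs)
    rng = np.random.default_rng(seed)
    long_df = long_df.reset_index(drop=True)
    # precompute each spec's design on the (complete-case) selection
    # sample once; bootstrap replicates then just index numpy rows
    designs = []
    starts = []
    for spec in specs:
        y, X, names, index = design_matrix(long_df, spec)
        if len(index) != len(long_df):
            raise ValueError(
                "bootstrap_bic expects a common complete-case sample for "
                "every candidate; pass selection_sample(long_df, vocabulary)")
        designs.append((y, X, names))
        try:
            r = CumulativeLogitModel(y, X, exog_names=names, spec=spec).fit(
                tol=tol, compute_vcov=False)
            starts.append(r.params if r.converged else None)
        except Exception:
            starts.append(None)
    scores = np.full((len(specs), B), np.nan)
    y_common = designs[0][0]
    for b in range(B):
        pos = bootstrap_indices(long_df, rng, unit=resample_unit,
                                stratify=stratify)
        # a replicate that loses a response category entirely yields
        # degenerate (hence invalid) fits for every model: skip it
        if np.any(np.bincount(y_common[pos], minlength=5)[1:] == 0):
            continue
        for i, spec in enumerate(specs):
            y, X, names = designs[i]
            try:
                model = CumulativeLogitModel(y[pos], X[pos],
                                             exog_names=names, spec=spec)
                r = model.fit(tol=tol, start_params=starts[i],
                              compute_vcov=False)
            except Exception:
                continue
            if r.converged and not r.degenerate:
                scores[i, b] = r.bic
    n_valid = np.sum(~np.isnan(scores), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(scores, axis=1)
        sds = np.nanstd(scores, axis=1, ddof=1)
    bad = n_valid < B / 2
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} models were invalid in more than "
                      "B/2 replicates and are excluded from selection")
    means[bad] = np.nan
    sds[bad] = np.nan
    table = pd.DataFrame({
        "mean_bic": means,
        "sd_bic": sds,
        "n_invalid": B - n_valid,
        "n_params": [spec_n_params(s) for s in specs],
    }, index=[s.label() for s in specs])
    return BootstrapBICSummary(specs=specs, table=table, B=B, seed=seed,
                               resample_unit=resample_unit,
                               stratified=stratify)


def _canonical_rank(specs: Sequence[ModelSpec]) -> dict[ModelSpec, int]:
    return {s: i for i, s in enumerate(specs)}


def select_min_bic(arg) -> ModelSpec:
    """Model with the minimum (mean) BIC.

    Accepts a :class:`BootstrapBICSummary` or a mapping
    ``ModelSpec -> BIC``.  Ties are broken toward fewer parameters, then
    canonical order.
    """
    if isinstance(arg, BootstrapBICSummary):
        items = [(s, m) for s, m in zip(arg.specs,
                                        arg.table["mean_bic"].to_numpy())
                 if np.isfinite(m)]
    else:
        items = [(s, v) for s, v in arg.items() if np.isfinite(v)]
    if not items:
        raise ValueError("no valid models to select from")
    rank = {s: i for i, (s, _) in enumerate(items)}
    return min(items, key=lambda sv: (sv[1], spec_n_params(sv[0]),
                                      rank[sv[0]]))[0]


def select_1se(summary: BootstrapBICSummary) -> ModelSpec:
    """Bootstrap-BIC one-standard-error rule.

    Let m* be the model with minimum mean bootstrap BIC and ``se`` the
    standard deviation of m*'s bootstrap BIC scores.  Among models whose
    mean BIC lies within ``(mean* - se, mean* + se)``, return the one with
    the fewest free parameters (ties: lower mean BIC, then canonical
    order).
    """
    means = summary.table["mean_bic"].to_numpy()
    sds = summary.table["sd_bic"].to_numpy()
    valid = np.isfinite(means)
    if not valid.any():
        raise ValueError("no valid models to select from")
    best = int(np.nanargmin(np.where(valid, means, np.inf)))
    se = sds[best]
    if not np.isfinite(se) or se == 0:
        return summary.specs[best]
    lo, hi = means[best] - se, means[best] + se
    candidates = [(s, means[i], i) for i, s in enumerate(summary.specs)
                  if valid[i] and lo < means[i] < hi]
    return min(candidates,
               key=lambda c: (spec_n_params(c[0]), c[1], c[2]))[0]


def refit_largest_sample(spec: ModelSpec, long_df: pd.DataFrame,
                         **fit_kw) -> CumulativeLogitResults:
    """Refit ``spec`` on the largest sample with complete information on
    its *own* predictors (e.g. a Phase + Init.Rating model uses every
    child, regardless of missingness in unused covariates)."""
    return fit_proportional(spec, long_df, **fit_kw)
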