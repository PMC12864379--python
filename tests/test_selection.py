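import itertools

import numpy as np
import pandas as pd
import pytest

from esbastats import to_long
from esbastats.ordinal import ModelSpec, STUDY_PREDICTORS
from esbastats.selection import (
    BootstrapBICSummary,
    bootstrap_bic,
    bootstrap_indices,
    enumerate_models,
    partition_figure1,
    refit_largest_sample,
    select_1se,
    select_min_bic,
    selection_sample,
    spec_n_params,
)
from esbastats.simulate import GeneratorConfig, generate_cohort, \
    scenario_library


def brute_force_count(p):
    """Independent enumeration: iterate subsets and interaction choices."""
    names = ["Phase"] + [f"X{i}" for i in range(p - 1)]
    count = 0
    for size in range(p + 1):
        for subset in itertools.combinations(names, size):
            count += 1
            if "Phase" in subset:
                count += len(subset) - 1
    return count


class TestEnumeration:
    def test_full_vocabulary_size(self):
        assert len(enumerate_models(STUDY_PREDICTORS)) == 3328

    @pytest.mark.parametrize("p", [1, 2, 3, 4, 5])
    def test_counting_formula_small_vocabularies(self, p):
        vocab = ("Phase",) + STUDY_PREDICTORS[2:p + 1]
        specs = enumerate_models(vocab)
        assert len(specs) == brute_force_count(p)
        if p >= 2:
            assert len(specs) == 2 ** p + (p - 1) * 2 ** (p - 2)

    def test_phase_alone(self):
        specs = enumerate_models(("Phase",))
        assert len(specs) == 2
        assert {s.label() for s in specs} == {"1", "Phase"}

    def test_no_duplicates_and_valid_interactions(self):
        specs = enumerate_models(STUDY_PREDICTORS[:5])
        assert len(set(specs)) == len(specs)
        for s in specs:
            if s.interaction is not None:
                assert "Phase" in s.main_effects
                assert s.interaction in s.main_effects

    def test_vocabulary_without_phase_warns(self):
        with pytest.warns(UserWarning):
            specs = enumerate_models(("Age", "Gender"))
        assert len(specs) == 4


class TestFigure1Partition:
    def test_subgroup_sizes(self):
        parts = partition_figure1(enumerate_models(STUDY_PREDICTORS))
        sizes = {k: len(v) for k, v in parts.items()}
        assert sizes["i"] == 256
        assert sizes["iii"] == 256
        assert sizes["iv"] == 256
        assert sum(sizes.values()) == 3328

    def test_partition_is_disjoint_and_exhaustive(self):
        specs = enumerate_models(STUDY_PREDICTORS[:4])
        parts = partition_figure1(specs)
        seen = [s for group in parts.values() for s in group]
        assert len(seen) == len(specs)
        assert set(seen) == set(specs)

    def test_group_v_always_has_interaction(self):
        parts = partition_figure1(enumerate_models(STUDY_PREDICTORS[:5]))
        assert all(s.interaction is not None for s in parts["v"])
        assert all(s.interaction is None for s in parts["iv"])


def make_summary(entries, B=100, seed=0):
    """entries: list of (spec, mean, sd)."""
    specs = [e[0] for e in entries]
    table = pd.DataFrame({
        "mean_bic": [e[1] for e in entries],
        "sd_bic": [e[2] for e in entries],
        "n_invalid": 0,
        "n_params": [spec_n_params(s) for s in specs],
    }, index=[s.label() for s in specs])
    return BootstrapBICSummary(specs=specs, table=table, B=B, seed=seed)


class TestSelectionRules:
    def test_min_bic_from_mapping(self):
        m1 = ModelSpec(("Phase",))
        m2 = ModelSpec(("Phase", "Init.Rating"))
        assert select_min_bic({m1: 310.0, m2: 305.0}) == m2

    def test_min_bic_tie_prefers_smaller_model(self):
        m1 = ModelSpec(("Phase",))
        m2 = ModelSpec(("Phase", "Init.Rating"))
        assert select_min_bic({m2: 300.0, m1: 300.0}) == m1

    def test_1se_zero_se_returns_minimum(self):
        null = ModelSpec(())
        a = ModelSpec(("Init.Rating",))
        summary = make_summary([(null, 370.0, 4.0), (a, 352.0, 0.0)])
        assert select_1se(summary) == a

    def test_1se_rule_by_hand(self):
        null = ModelSpec(())
        a = ModelSpec(("Init.Rating",))
        ab = ModelSpec(("Phase", "Init.Rating"))
        summary = make_summary([(null, 370.0, 3.0), (a, 352.0, 4.0),
                                (ab, 350.0, 5.0)])
        # interval (345, 355) contains A and A+B; A has fewer parameters
        assert select_1se(summary) == a

    def test_1se_never_larger_than_min_bic(self):
        rng = np.random.default_rng(0)
        specs = enumerate_models(("Phase", "Init.Rating", "Age"))
        for _ in range(20):
            entries = [(s, float(300 + 50 * rng.random()),
                        float(5 * rng.random())) for s in specs]
            summary = make_summary(entries)
            chosen = select_1se(summary)
            best = select_min_bic(summary)
            assert spec_n_params(chosen) <= spec_n_params(best)

    def test_empty_valid_set_rejected(self):
        with pytest.raises(ValueError):
            select_min_bic({})


@pytest.fixture(scope="module")
def synthetic_long():
    cfg = scenario_library()["paper-like"]
    return to_long(generate_cohort(cfg, seed=21))


class TestBootstrap:
    def test_child_resampling_keeps_triples(self, synthetic_long):
        rng = np.random.default_rng(0)
        pos = bootstrap_indices(synthetic_long, rng, unit="child")
        boot = synthetic_long.iloc[pos]
        assert len(boot) == len(synthetic_long)
        assert boot.groupby("child_id")["phase"].apply(
            lambda s: sorted(set(s)) == [1, 2, 3]).all()

    def test_stratification_preserves_cohort_sizes(self, synthetic_long):
        rng = np.random.default_rng(1)
        pos = bootstrap_indices(synthetic_long, rng, unit="child",
                                stratify=True)
        boot = synthetic_long.iloc[pos]
        orig = synthetic_long.groupby("init_rating").size()
        assert boot.groupby("init_rating").size().equals(orig)

    def test_bootstrap_bic_deterministic_given_seed(self, synthetic_long):
        vocab = ("Phase", "Init.Rating")
        specs = enumerate_models(vocab)
        sample = selection_sample(synthetic_long, vocab)
        a = bootstrap_bic(specs, sample, B=2, seed=123)
        b = bootstrap_bic(specs, sample, B=2, seed=123)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_monte_carlo_stability_single_model(self, synthetic_long):
        """Two independent bootstrap runs of one model agree in mean BIC
        within Monte-Carlo error."""
        vocab = ("Phase", "Init.Rating")
        spec = [ModelSpec(("Phase", "Init.Rating"))]
        sample = selection_sample(synthetic_long, vocab)
        a = bootstrap_bic(spec, sample, B=150, seed=1)
        b = bootstrap_bic(spec, sample, B=150, seed=2)
        sd = a.table["sd_bic"].iloc[0]
        tol = 4 * sd / np.sqrt(150)
        assert abs(a.table["mean_bic"].iloc[0] -
                   b.table["mean_bic"].iloc[0]) < tol


class TestLargestSampleRefit:
    def test_sparse_spec_uses_every_child(self):
        cfg = scenario_library()["paper-like"]
        long_df = to_long(generate_cohort(cfg, seed=3))
        res = refit_largest_sample(ModelSpec(("Phase", "Init.Rating")),
                                   long_df)
        assert res.nobs == 255  # all 85 children, no missing predictors
        full = refit_largest_sample(ModelSpec(STUDY_PREDICTORS), long_df)
        assert full.nobs < 255  # missingness in medical-history covariates
        assert full.nobs % 3 == 0  # whole children drop out

    def test_selection_sample_is_complete_case_on_vocabulary(self):
        cfg = scenario_library()["paper-like"]
        long_df = to_long(generate_cohort(cfg, seed=3))
        sample = selection_sample(long_df, STUDY_PREDICTORS)
        assert sample[["medication", "natural_birth",
                       "previous_anesthesia"]].notna().all().all()
        assert len(sample) % 3 == 0
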