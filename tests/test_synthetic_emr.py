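import numpy as np
import pandas as pd
import pytest

from pheindex.analytics import jaccard_matrix
from pheindex.criteria import CRITERIA, evaluate_cohort
from pheindex.emr import TermStatus, write_cohort
from pheindex.scoring import classify_matrix
from pheindex.synthetic import (
    DEFAULT_MULTIPLIERS,
    GeneratorConfig,
    expected_classification_rates,
    generate_cohort,
    inject_documentation_noise,
)

UNIT_MULT = {c: 1.0 for c in CRITERIA}


def met_frame(cohort):
    return evaluate_cohort(cohort).set_index("child_id")[list(CRITERIA)].astype(bool)


def truth_frame(truth):
    return truth.set_index("child_id")[list(CRITERIA)].astype(bool)


class TestGenerate:
    def test_all_rates_zero_yields_all_false(self):
        cohort, truth = generate_cohort(
            GeneratorConfig(n_children=150, seed=1, base_rates={}, co_occurrence_pairs=())
        )
        assert not truth_frame(truth).any().any()
        assert not met_frame(cohort).any().any()

    def test_forced_rate_one_meets_everyone(self):
        cfg = GeneratorConfig(
            n_children=60,
            seed=2,
            preterm_fraction=0.0,
            base_rates={"er_visits": 1.0},
            disorder_rate_multipliers=UNIT_MULT,
            co_occurrence_pairs=(),
        )
        cohort, truth = generate_cohort(cfg)
        assert truth["er_visits"].all()
        assert met_frame(cohort)["er_visits"].all()

    def test_seed_determinism_byte_identical_files(self, tmp_path):
        cfg = GeneratorConfig(n_children=80, seed=11)
        a, ta = generate_cohort(cfg)
        b, tb = generate_cohort(cfg)
        write_cohort(a, tmp_path / "a")
        write_cohort(b, tmp_path / "b")
        for name in ("children", "encounters", "diagnoses", "procedures", "lab_orders"):
            assert (tmp_path / "a" / f"{name}.csv").read_bytes() == (
                tmp_path / "b" / f"{name}.csv"
            ).read_bytes()
        pd.testing.assert_frame_equal(ta, tb)

    def test_latent_truth_never_in_emr_tables(self):
        cohort, truth = generate_cohort(GeneratorConfig(n_children=50, seed=3))
        for name in ("children", "encounters", "diagnoses", "procedures", "lab_orders"):
            assert "has_disorder" not in getattr(cohort, name).columns

    def test_preterm_children_never_intend_nicu(self):
        cohort, truth = generate_cohort(
            GeneratorConfig(n_children=400, seed=4, preterm_fraction=0.5)
        )
        pre = truth[truth["term_status"] == "pre_term"]
        assert not pre["nicu_stay"].any()

    def test_positive_rate_monotone_in_multipliers(self):
        def rate(mult_scale):
            mults = {c: max(1.0, m * mult_scale) for c, m in DEFAULT_MULTIPLIERS.items()}
            cfg = GeneratorConfig(
                n_children=4000,
                seed=5,
                disorder_rate_multipliers=mults,
                co_occurrence_pairs=(),
            )
            _, truth = generate_cohort(cfg)
            M = truth_frame(truth).to_numpy()
            return (classify_matrix(M)["classification"] == "positive").mean()

        assert rate(0.25) <= rate(1.0) <= rate(4.0)

    def test_cooccurrence_coupling_hits_target(self):
        cfg = GeneratorConfig(n_children=20000, seed=6)
        cohort, truth = generate_cohort(cfg)
        prof = truth.rename(columns={})  # truth already has met flags + term_status
        prof = truth.copy()
        for c in CRITERIA:
            prof[f"first_met_{c}"] = np.nan
        jm = jaccard_matrix(prof, TermStatus.FULL_TERM)
        assert jm[("heart_surgery", "nicu_stay")] == pytest.approx(0.44, abs=0.05)


class TestNoise:
    def test_zero_flip_rates_leave_cohort_unchanged(self):
        cohort, truth = generate_cohort(GeneratorConfig(n_children=100, seed=7))
        noisy = inject_documentation_noise(cohort, truth, {}, seed=1)
        for name in ("children", "encounters", "diagnoses", "procedures", "lab_orders"):
            pd.testing.assert_frame_equal(
                getattr(cohort, name).reset_index(drop=True),
                getattr(noisy, name).reset_index(drop=True),
            )

    def test_full_flip_rate_breaks_every_agreement(self):
        cfg = GeneratorConfig(n_children=120, seed=8, preterm_fraction=0.0)
        cohort, truth = generate_cohort(cfg)
        noisy = inject_documentation_noise(cohort, truth, {"er_visits": 1.0}, seed=2)
        agree = met_frame(noisy)["er_visits"] == truth_frame(truth)["er_visits"]
        assert not agree.any()

    def test_partial_flip_rate_lands_near_target(self):
        cfg = GeneratorConfig(n_children=2000, seed=9, preterm_fraction=0.0)
        cohort, truth = generate_cohort(cfg)
        noisy = inject_documentation_noise(cohort, truth, {"imaging": 0.1}, seed=3)
        agree = (met_frame(noisy)["imaging"] == truth_frame(truth)["imaging"]).mean()
        se = np.sqrt(0.1 * 0.9 / 2000)
        assert agree == pytest.approx(0.9, abs=3 * se)


class TestAnalyticOracle:
    def test_rates_sum_and_bounds(self):
        out = expected_classification_rates(GeneratorConfig(co_occurrence_pairs=()))
        assert 0 < out["sensitivity"] < 1
        assert 0.95 < out["specificity"] < 1
        assert 0 < out["positive_rate"] < 0.05

    def test_zero_rates_give_zero_positive_rate(self):
        cfg = GeneratorConfig(base_rates={}, co_occurrence_pairs=())
        out = expected_classification_rates(cfg)
        assert out["positive_rate"] == pytest.approx(0.0, abs=1e-9)


class TestConfigValidation:
    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(preterm_fraction=1.5)

    def test_multiplier_below_one_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(disorder_rate_multipliers={"er_visits": 0.5})

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(base_rates={"telepathy": 0.1})
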