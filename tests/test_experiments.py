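"""Experiment orchestration: comparison, ablation, importance, intervention."""

import numpy as np
import pytest

from hibpn.cohort import (
    CellParams,
    CohortConfig,
    generate_cohort,
    generate_intervention_cohort,
)
from hibpn.experiments import (
    ABLATION_VARIANTS,
    CORE_DIMENSIONS,
    dimension_importance,
    run_ablation,
    run_experiment1,
    run_experiment2,
)
from hibpn.training import TrainConfig, split_1_9, train_hibpn


def _noise_cells(hostile_mean=35.0):
    return {
        (g, c): CellParams(hostile_mean, 6.0, 38.0, 6.0)
        for g in ("dominant", "implicit", "neutral")
        for c in ("exclusion", "acceptance")
    }


@pytest.fixture(scope="module")
def narcissism_dominant_cohort():
    """Signal concentrated in the trait-group features: groups differ in
    exclusion exposure while hostile totals and covariates are nearly
    uninformative."""
    cfg = CohortConfig(
        n_participants=2000, seed=7,
        condition_ratio_by_group={"dominant": 0.85, "implicit": 0.85, "neutral": 0.25},
        table1_params=_noise_cells(), catch_noise_sd=40.0, basic_needs_effect=3.0,
    )
    return generate_cohort(cfg)


class TestExperiment1:
    def test_row_cardinality_and_consistency(self, small_cohort, fast_train_config):
        report, manifest = run_experiment1(small_cohort, fast_train_config)
        assert len(report.rows) == (1 + 10) * 2
        assert manifest["n_train"] + manifest["n_test"] == len(small_cohort)
        hibpn_fwd = report.row("hibpn", "forward")
        assert 0.0 <= hibpn_fwd.auc <= 1.0
        # ablation's all-features variant reproduces the same row
        abl = run_ablation(small_cohort, fast_train_config)
        full = abl.report.row("all_features", "forward")
        assert (full.acc, full.auc, full.f1) == (hibpn_fwd.acc, hibpn_fwd.auc, hibpn_fwd.f1)

    def test_reproducible_given_seed(self, small_cohort, fast_train_config):
        r1, _ = run_experiment1(small_cohort, fast_train_config)
        r2, _ = run_experiment1(small_cohort, fast_train_config)
        for a, b in zip(r1.rows, r2.rows):
            assert (a.model, a.chain, a.acc, a.auc, a.f1) == (b.model, b.chain, b.acc, b.auc, b.f1)


class TestAblation:
    def test_gap_table_has_both_denominator_modes(self, small_cohort, fast_train_config):
        result = run_ablation(small_cohort, fast_train_config)
        assert set(result.report.rows[0].__dict__) >= {"acc", "auc", "f1"}
        assert set(result.gaps) == set(ABLATION_VARIANTS) - {"all_features"}
        for variant in result.gaps.values():
            for metric in ("acc", "auc", "f1"):
                assert "reference" in variant[metric]

    def test_dropping_noise_group_changes_little_signal_group_much(self):
        """Concentrate the condition signal in the hostile totals; the
        narcissism features are noise for the forward task."""
        cells = _noise_cells()
        for g in ("dominant", "implicit", "neutral"):
            cells[(g, "exclusion")] = CellParams(42.0, 5.0, 34.0, 6.0)
            cells[(g, "acceptance")] = CellParams(30.0, 5.0, 42.0, 6.0)
        cfg = CohortConfig(
            n_participants=2000, seed=3, table1_params=cells,
            catch_noise_sd=60.0, basic_needs_effect=0.0,
        )
        result = run_ablation(generate_cohort(cfg), TrainConfig(epochs=300, seed=3))
        full = result.report.row("all_features", "forward").auc
        no_narc = result.report.row("without_narcissism", "forward").auc
        no_host = result.report.row("without_hostile_interpretation", "forward").auc
        assert abs(no_narc - full) < 0.1  # noise group: change within noise
        assert no_host < full - 0.2  # signal group: falls toward chance
        assert abs(no_host - 0.5) < 0.15

    def test_narcissism_dominance_ordering(self, narcissism_dominant_cohort):
        result = run_ablation(narcissism_dominant_cohort, TrainConfig(epochs=300, seed=7))
        no_narc = result.report.row("without_narcissism", "forward").auc
        no_host = result.report.row("without_hostile_interpretation", "forward").auc
        assert no_narc < no_host - 0.05


class TestImportance:
    def test_weights_sum_to_100(self, small_cohort):
        for chain in ("forward", "reverse"):
            rep = dimension_importance(small_cohort, chain, seed=0)
            assert sum(rep.weight_pct.values()) == pytest.approx(100.0, abs=0.01)
            assert all(v >= 0 for v in rep.weight_pct.values())
            assert set(rep.weight_pct) == set(CORE_DIMENSIONS)

    def test_narcissism_dominates_when_planted(self, narcissism_dominant_cohort):
        rep = dimension_importance(narcissism_dominant_cohort, "forward", seed=7)
        assert rep.weight_pct["narcissism"] == max(rep.weight_pct.values())

    def test_reverse_chain_narcissism_dominates_by_default(self, small_cohort):
        # trait groups drive hostile totals under the default conditions
        rep = dimension_importance(small_cohort, "reverse", seed=0)
        assert rep.weight_pct["narcissism"] == max(rep.weight_pct.values())

    def test_seed_determinism(self, small_cohort):
        a = dimension_importance(small_cohort, "forward", seed=5)
        b = dimension_importance(small_cohort, "forward", seed=5)
        assert a.weight_pct == b.weight_pct


@pytest.fixture(scope="module")
def forward_model():
    base = generate_cohort(CohortConfig(n_participants=1000, seed=21))
    cfg = TrainConfig(epochs=300, seed=21)
    train, _ = split_1_9(base, cfg)
    return train_hibpn(train, cfg)


class TestExperiment2:
    def test_identical_arms_give_zero_difference(self, forward_model):
        recs = generate_intervention_cohort(CohortConfig(arm_size=10, affirmation_effect=0.0, seed=1))
        # duplicate every record into both arms: rates must coincide
        doubled = []
        for r in recs:
            for arm in ("self_affirmation", "control"):
                d = r.as_dict()
                d["intervention"] = arm
                from hibpn.cohort import ParticipantRecord

                doubled.append(ParticipantRecord(**d))
        rep = run_experiment2(doubled, forward_model)
        assert rep.difference_pct_points == 0.0

    def test_empty_arm_rejected(self, forward_model):
        recs = generate_intervention_cohort(CohortConfig(arm_size=4, seed=2))
        only_control = [r for r in recs if r.intervention == "control"]
        with pytest.raises(ValueError):
            run_experiment2(only_control, forward_model)

    def test_large_planted_effect_raises_acceptance_rate(self, forward_model):
        diffs = []
        for s in range(10):
            recs = generate_intervention_cohort(
                CohortConfig(arm_size=1000, affirmation_effect=10.0, seed=100 + s)
            )
            diffs.append(run_experiment2(recs, forward_model).difference_pct_points)
        assert np.mean(diffs) > 0

    def test_effect_monotonicity(self, forward_model):
        """Mean predicted-acceptance advantage of the affirmation arm
        grows with the planted hostile-score reduction."""
        means = []
        for effect in (0.0, 2.5, 5.0, 10.0):
            diffs = [
                run_experiment2(
                    generate_intervention_cohort(
                        CohortConfig(arm_size=1000, affirmation_effect=effect, seed=200 + s)
                    ),
                    forward_model,
                ).difference_pct_points
                for s in range(20)
            ]
            means.append(np.mean(diffs))
        assert means[-1] > means[0]
        assert all(b > a for a, b in zip(means[:-1], means[1:]))
        assert means[2] > 0  # the study-sized 5-point effect is recovered
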