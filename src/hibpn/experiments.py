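"""Orchestration of the study's analyses.

Four entry points mirror the published analyses:

* :func:`run_experiment1` — the head-to-head model comparison: the
  network and the ten classical baselines, trained and evaluated on
  the identical 1:9 split, both chains.
* :func:`run_ablation` — retrain the forward chain with one feature
  dimension group removed (narcissism or hostile interpretation) and
  tabulate the relative performance drops in both denominator modes.
* :func:`dimension_importance` — a seeded random-forest surrogate fit
  on the same inputs a chain sees; per-feature importances are summed
  within each of the three core dimension groups (social exclusion,
  hostile interpretation bias, narcissism) and normalised to
  percentages summing to 100.
* :func:`run_experiment2` — the self-affirmation contrast: the trained
  forward chain classifies each intervention arm, and the arms'
  positive (predicted-acceptance) response rates are compared in
  percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .baselines import BaselineSpec, default_specs, evaluate_all_baselines
from .cohort import ParticipantRecord
from .evaluation import (
    MetricsReport,
    MetricsRow,
    accuracy,
    f1_score,
    relative_gap,
    roc_and_auc,
)
from .model import Standardizer, build_features
from .training import TrainConfig, TrainedHibpn, split_1_9, train_hibpn

__all__ = [
    "ABLATION_VARIANTS",
    "CORE_DIMENSIONS",
    "AblationResult",
    "ImportanceReport",
    "InterventionReport",
    "run_experiment1",
    "run_ablation",
    "dimension_importance",
    "run_experiment2",
]

#: variant name -> dimension groups removed before retraining
ABLATION_VARIANTS: Mapping[str, tuple[str, ...]] = {
    "all_features": (),
    "without_narcissism": ("narcissism",),
    "without_hostile_interpretation": ("hostile_interpretation",),
}

#: the three reported dimension groups (demographic covariates are fit
#: in the surrogate but excluded from the 100% normalisation)
CORE_DIMENSIONS = ("social_exclusion", "hostile_interpretation_bias", "narcissism")

_GROUP_ALIASES = {
    "social_exclusion": "social_exclusion",
    "hostile_interpretation": "hostile_interpretation_bias",
    "narcissism": "narcissism",
}

_POSITIVE = {"forward": "social_exclusion", "reverse": "high_hostile_interpretation"}


def _chain_arrays(records, chain, std: Standardizer | None = None):
    fm = build_features(records, chain)
    x, cols = fm.flat()
    y = fm.y_forward if chain == "forward" else fm.y_reverse
    return fm, x, cols, y.astype(int)


def _hibpn_row(model: TrainedHibpn, chain: str, test_records) -> MetricsRow:
    scores = (
        model.predict_forward(test_records)
        if chain == "forward"
        else model.predict_reverse(test_records)
    )
    fm = build_features(test_records, chain)
    y = (fm.y_forward if chain == "forward" else fm.y_reverse).astype(int)
    yhat = (scores >= 0.5).astype(int)
    roc, auc_val = roc_and_auc(y, scores)
    return MetricsRow(
        model="hibpn", chain=chain,
        acc=accuracy(y, yhat), f1=f1_score(y, yhat), auc=auc_val,
        roc_points=roc, n_test=len(test_records), positive_class=_POSITIVE[chain],
    )


def run_experiment1(
    cohort: Sequence[ParticipantRecord],
    train_config: TrainConfig | None = None,
    baseline_specs: Sequence[BaselineSpec] | None = None,
) -> tuple[MetricsReport, dict]:
    """Model comparison on the shared 1:9 split, both chains.

    Returns the metrics table (one row per model per chain, the
    network first) and a run manifest recording seeds and configs.
    """
    config = TrainConfig() if train_config is None else config_copy(train_config)
    specs = default_specs(seed=config.seed) if baseline_specs is None else list(baseline_specs)

    train, test = split_1_9(cohort, config)
    _require_both_classes(train, test)
    model = train_hibpn(train, config)

    report = MetricsReport()
    errors: dict[str, dict[str, str]] = {}
    for chain in ("forward", "reverse"):
        report.rows.append(_hibpn_row(model, chain, test))
        _, x_tr, cols, y_tr = _chain_arrays(train, chain)
        std = Standardizer.fit(x_tr, cols)
        _, x_te, _, y_te = _chain_arrays(test, chain)
        rows, errs = evaluate_all_baselines(
            specs, std.transform(x_tr), y_tr, std.transform(x_te), y_te,
            chain, positive_class=_POSITIVE[chain],
        )
        report.rows.extend(rows)
        if errs:
            errors[chain] = errs

    manifest = {
        "experiment": "model_comparison",
        "n_cohort": len(cohort), "n_train": len(train), "n_test": len(test),
        "seed": config.seed, "split_ratio": config.split_ratio,
        "epochs": config.epochs, "learning_rate": config.learning_rate,
        "baselines": [s.name for s in specs],
        "baseline_errors": errors,
    }
    return report, manifest


def config_copy(config: TrainConfig) -> TrainConfig:
    return TrainConfig(**vars(config))


def _require_both_classes(train, test) -> None:
    for name, recs in (("train", train), ("test", test)):
        for label, fn in (
            ("condition", lambda r: r.condition),
            ("hostile_bin", lambda r: r.hostile_bin),
        ):
            if len({fn(r) for r in recs}) < 2:
                raise ValueError(f"{name} set has a single {label} class; cannot evaluate")


@dataclass
class AblationResult:
    """Per-variant forward-chain metrics plus relative drops."""

    report: MetricsReport
    gaps: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def run_ablation(
    cohort: Sequence[ParticipantRecord],
    train_config: TrainConfig | None = None,
) -> AblationResult:
    """Retrain the forward chain with whole dimension groups removed.

    All variants share the identical split and seed; the companion gap
    table reports each degraded variant against the full model in both
    denominator modes (``reference`` = full model, ``value`` = the
    ablated figure).
    """
    config = TrainConfig() if train_config is None else config_copy(train_config)
    train, test = split_1_9(cohort, config)
    _require_both_classes(train, test)

    report = MetricsReport()
    for variant, dropped in ABLATION_VARIANTS.items():
        model = train_hibpn(train, config, drop_groups=dropped)
        row = _hibpn_row(model, "forward", test)
        row.model = variant
        report.rows.append(row)

    full = report.row("all_features", "forward")
    gaps: dict[str, dict[str, dict[str, float]]] = {}
    for variant in ABLATION_VARIANTS:
        if variant == "all_features":
            continue
        row = report.row(variant, "forward")
        gaps[variant] = {}
        for metric in ("acc", "auc", "f1"):
            full_v, abl_v = getattr(full, metric), getattr(row, metric)
            entry = {"reference": relative_gap(full_v, abl_v, "reference")}
            if abl_v != 0:  # value-mode denominator is the ablated figure
                entry["value"] = relative_gap(full_v, abl_v, "value")
            gaps[variant][metric] = entry
    manifest = {
        "experiment": "ablation", "seed": config.seed,
        "n_train": len(train), "n_test": len(test),
        "variants": {k: list(v) for k, v in ABLATION_VARIANTS.items()},
    }
    return AblationResult(report=report, gaps=gaps, manifest=manifest)


@dataclass
class ImportanceReport:
    """Grouped feature-importance percentages for one chain."""

    chain: str
    weight_pct: dict[str, float]
    demographics_pct: float = 0.0
    n_trees: int = 500

    def as_dict(self) -> dict:
        return {
            "chain": self.chain,
            "weight_pct": dict(self.weight_pct),
            "demographics_pct": self.demographics_pct,
        }


def dimension_importance(
    cohort: Sequence[ParticipantRecord],
    chain: str,
    seed: int = 0,
    n_trees: int = 500,
) -> ImportanceReport:
    """Random-forest surrogate importance grouped by dimension.

    The surrogate sees exactly the features the chain sees (so the
    forward chain's social-exclusion dimension contains the basic
    needs and estimated-catch covariates, never the condition label
    itself).  Importances are summed within each core dimension group
    and normalised to percentages summing to 100; an absent group is
    reported as 0 with a warning.
    """
    fm, x, cols, y = _chain_arrays(cohort, chain)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(x, y)
    importances = rf.feature_importances_

    sums = {dim: 0.0 for dim in CORE_DIMENSIONS}
    demo = 0.0
    for col, imp in zip(cols, importances):
        group = fm.dimension_group_map[col]
        if group == "demographics":
            demo += float(imp)
        else:
            sums[_GROUP_ALIASES[group]] += float(imp)

    total = sum(sums.values())
    if total == 0:
        raise ValueError("no core-dimension features present")
    weights = {}
    for dim in CORE_DIMENSIONS:
        if sums[dim] == 0.0:
            warnings.warn(f"dimension group {dim!r} has no features; weight 0", stacklevel=2)
        weights[dim] = 100.0 * sums[dim] / total
    demo_pct = 100.0 * demo / (total + demo) if (total + demo) > 0 else 0.0
    return ImportanceReport(chain=chain, weight_pct=weights, demographics_pct=demo_pct,
                            n_trees=n_trees)


@dataclass
class InterventionReport:
    """Positive (predicted-acceptance) response rates per intervention arm."""

    rate_affirmation: float
    rate_control: float
    n_affirmation: int
    n_control: int

    @property
    def difference_pct_points(self) -> float:
        return 100.0 * (self.rate_affirmation - self.rate_control)

    def as_dict(self) -> dict:
        return {
            "positive_response_rate": {
                "self_affirmation": self.rate_affirmation,
                "control": self.rate_control,
            },
            "difference_pct_points": self.difference_pct_points,
            "arm_sizes": {
                "self_affirmation": self.n_affirmation,
                "control": self.n_control,
            },
        }


def run_experiment2(
    cohort_exp2: Sequence[ParticipantRecord],
    trained_forward: TrainedHibpn,
) -> InterventionReport:
    """Score the two intervention arms with the trained forward chain.

    The positive response rate of an arm is the fraction of its
    participants the forward chain classifies as socially *accepted*
    (predicted exclusion probability below 0.5).
    """
    arms = {
        "self_affirmation": [r for r in cohort_exp2 if r.intervention == "self_affirmation"],
        "control": [r for r in cohort_exp2 if r.intervention == "control"],
    }
    for name, recs in arms.items():
        if not recs:
            raise ValueError(f"empty intervention arm {name!r}")
    rates = {}
    for name, recs in arms.items():
        p_excl = trained_forward.predict_forward(recs)
        rates[name] = float(np.mean(p_excl < 0.5))
    return InterventionReport(
        rate_affirmation=rates["self_affirmation"],
        rate_control=rates["control"],
        n_affirmation=len(arms["self_affirmation"]),
        n_control=len(arms["control"]),
    )
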