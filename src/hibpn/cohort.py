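"""Synthetic cohort generation for the Cyberball exclusion design.

No participant-level data are distributed with the original study, so
this module generates cohorts carrying the reported statistical
structure: trait groups in 27/27/46 proportions, hostile and
non-hostile interpretation totals drawn per (trait group x condition)
cell from the published cell means and SDs, Cyberball catch schedules
(2/30 catches under exclusion, per-pass probability 1/3 under
acceptance), basic-needs totals lowered under exclusion, and the
two-arm self-affirmation design of the intervention experiment.

Everything is seed-deterministic: the same config and seed reproduce
the same cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy import stats

from .scales import HOSTILE_SCORE_RANGE, assign_trait_groups, bin_hostile

__all__ = [
    "TABLE1_PARAMS",
    "CellParams",
    "CohortConfig",
    "CyberballOutcome",
    "ParticipantRecord",
    "simulate_cyberball",
    "sample_interpretation_scores",
    "generate_cohort",
    "generate_intervention_cohort",
    "shuffle_conditions",
]

N_PASSES = 30
EXCLUSION_CATCHES = 2
ACCEPTANCE_CATCH_P = 1.0 / 3.0


@dataclass(frozen=True)
class CellParams:
    """Interpretation-score distribution for one trait-group x condition cell."""

    hostile_mean: float
    hostile_sd: float
    non_hostile_mean: float
    non_hostile_sd: float


#: Published cell means/SDs of hostile and non-hostile interpretation
#: totals per trait group and condition.
TABLE1_PARAMS: Mapping[tuple[str, str], CellParams] = {
    ("neutral", "exclusion"): CellParams(30.09, 6.65, 42.50, 7.40),
    ("dominant", "exclusion"): CellParams(45.65, 4.06, 32.73, 7.00),
    ("implicit", "exclusion"): CellParams(43.91, 4.95, 34.82, 4.68),
    ("neutral", "acceptance"): CellParams(30.56, 6.53, 42.53, 7.16),
    ("dominant", "acceptance"): CellParams(36.68, 7.70, 36.39, 8.07),
    ("implicit", "acceptance"): CellParams(43.64, 4.55, 34.69, 6.19),
}


@dataclass
class CohortConfig:
    """All generator knobs; defaults reproduce the study conditions."""

    n_participants: int = 258
    condition_ratio: float = 0.5  # fraction assigned to exclusion
    # optional per-trait-group exclusion fractions (observational designs
    # where trait and situation are correlated); None = condition_ratio
    condition_ratio_by_group: Mapping[str, float] | None = None
    table1_params: Mapping[tuple[str, str], CellParams] = field(
        default_factory=lambda: dict(TABLE1_PARAMS)
    )
    group_proportions: tuple[float, float, float] = (0.27, 0.27, 0.46)
    basic_needs_effect: float = 10.0  # mean drop under exclusion, scale points
    basic_needs_mean: float = 75.0
    basic_needs_sd: float = 10.0
    catch_noise_sd: float = 10.0  # noise on the subjective catch estimate, pct points
    male_fraction: float = 2.0 / 3.0
    age_range: tuple[int, int] = (19, 22)
    # intervention experiment
    arm_size: int = 18
    affirmation_effect: float = 5.0  # hostile-score mean reduction, scale points
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 4:
            raise ValueError("n_participants must be at least 4")
        if not 0.0 < self.condition_ratio < 1.0:
            raise ValueError("condition_ratio must lie strictly in (0, 1)")
        if self.condition_ratio_by_group is not None:
            for g, ratio in self.condition_ratio_by_group.items():
                if g not in ("dominant", "implicit", "neutral"):
                    raise ValueError(f"unknown trait group {g!r} in condition_ratio_by_group")
                if not 0.0 < ratio < 1.0:
                    raise ValueError("per-group condition ratios must lie strictly in (0, 1)")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")
        if self.arm_size <= 0:
            raise ValueError("arm_size must be positive")
        for key, cell in self.table1_params.items():
            if cell.hostile_sd < 0 or cell.non_hostile_sd < 0:
                raise ValueError(f"negative SD in table1_params cell {key}")


@dataclass(frozen=True)
class CyberballOutcome:
    """Result of one simulated 30-pass ball-tossing game."""

    n_passes: int
    catches: int
    catch_rate_pct: float
    schedule: tuple[int, ...]  # per-pass participant-receipt indicator


@dataclass
class ParticipantRecord:
    """One synthetic participant."""

    id: int
    gender: str  # 'male' | 'female'
    age: int
    trait_group: str  # 'dominant' | 'implicit' | 'neutral'
    condition: str  # 'exclusion' | 'acceptance'
    npi16_score: int
    hsns_score: int
    basic_needs_score: int
    estimated_catch_pct: float
    hostile_score: int
    non_hostile_score: int
    hostile_bin: str  # 'low' | 'high'
    intervention: str = "none"  # 'self_affirmation' | 'control' | 'none'

    def validate(self) -> None:
        lo, hi = HOSTILE_SCORE_RANGE
        checks = [
            (0 <= self.npi16_score <= 16, "npi16_score outside [0, 16]"),
            (10 <= self.hsns_score <= 50, "hsns_score outside [10, 50]"),
            (20 <= self.basic_needs_score <= 100, "basic_needs_score outside [20, 100]"),
            (0.0 <= self.estimated_catch_pct <= 100.0, "estimated_catch_pct outside [0, 100]"),
            (lo <= self.hostile_score <= hi, f"hostile_score outside [{lo}, {hi}]"),
            (lo <= self.non_hostile_score <= hi, f"non_hostile_score outside [{lo}, {hi}]"),
            (self.condition in ("exclusion", "acceptance"), "unknown condition"),
            (self.trait_group in ("dominant", "implicit", "neutral"), "unknown trait_group"),
            (self.gender in ("male", "female"), "unknown gender"),
            (self.intervention in ("self_affirmation", "control", "none"), "unknown intervention"),
            (self.hostile_bin == bin_hostile(self.hostile_score), "hostile_bin inconsistent"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"participant {self.id}: {msg}")

    def as_dict(self) -> dict:
        return asdict(self)


def simulate_cyberball(condition: str, seed: int) -> CyberballOutcome:
    """Simulate one 30-pass Cyberball game.

    Under exclusion the participant catches the ball exactly twice,
    both times within the first 15 passes (the avatars keep the ball to
    themselves in the second half), a 6.67% catch rate.  Under
    acceptance every pass reaches the participant independently with
    probability 1/3.
    """
    if condition not in ("exclusion", "acceptance"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    schedule = np.zeros(N_PASSES, dtype=int)
    if condition == "exclusion":
        catch_passes = rng.choice(N_PASSES // 2, size=EXCLUSION_CATCHES, replace=False)
        schedule[catch_passes] = 1
    else:
        schedule = (rng.random(N_PASSES) < ACCEPTANCE_CATCH_P).astype(int)
    catches = int(schedule.sum())
    return CyberballOutcome(
        n_passes=N_PASSES,
        catches=catches,
        catch_rate_pct=100.0 * catches / N_PASSES,
        schedule=tuple(schedule.tolist()),
    )


def _truncnorm_int(
    mean: float, sd: float, lo: float, hi: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Integer draws from a [lo, hi]-truncated normal (summed-Likert semantics)."""
    if sd == 0:
        return np.full(n, int(round(np.clip(mean, lo, hi))))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    draws = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.round(draws), lo, hi).astype(int)


def sample_interpretation_scores(
    trait_group: str,
    condition: str,
    n: int,
    params: Mapping[tuple[str, str], CellParams] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (hostile, non-hostile) total pairs for one design cell.

    Scores come from a normal with the cell's mean/SD, truncated to the
    attainable instrument range [12, 60] and rounded to integers.
    """
    params = dict(TABLE1_PARAMS) if params is None else params
    key = (trait_group, condition)
    if key not in params:
        raise KeyError(f"no distribution parameters for cell {key}")
    if n < 1:
        raise ValueError("n must be at least 1")
    cell = params[key]
    lo, hi = HOSTILE_SCORE_RANGE
    rng = np.random.default_rng(seed)
    hostile = _truncnorm_int(cell.hostile_mean, cell.hostile_sd, lo, hi, n, rng)
    non_hostile = _truncnorm_int(cell.non_hostile_mean, cell.non_hostile_sd, lo, hi, n, rng)
    return hostile, non_hostile


def _group_sizes(n: int, proportions: tuple[float, float, float]) -> tuple[int, int, int]:
    n_dom = int(round(proportions[0] * n))
    n_imp = int(round(proportions[1] * n))
    return n_dom, n_imp, n - n_dom - n_imp


def _sample_demographics(n: int, config: CohortConfig, rng: np.random.Generator):
    gender = np.where(rng.random(n) < config.male_fraction, "male", "female")
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    return gender, age


def _assemble_records(
    ids: np.ndarray,
    groups: list[str],
    conditions: np.ndarray,
    npi: np.ndarray,
    hsns: np.ndarray,
    interventions: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
    hostile_shift: np.ndarray | None = None,
) -> list[ParticipantRecord]:
    n = ids.size
    gender, age = _sample_demographics(n, config, rng)
    lo, hi = HOSTILE_SCORE_RANGE

    # Basic needs: baseline minus the exclusion effect, clipped to [20, 100].
    bn = rng.normal(config.basic_needs_mean, config.basic_needs_sd, size=n)
    bn = bn - np.where(conditions == "exclusion", config.basic_needs_effect, 0.0)
    bn = np.clip(np.round(bn), 20, 100).astype(int)

    # Subjective catch estimate: true game rate plus zero-mean noise.
    est_catch = np.empty(n)
    for i in range(n):
        game = simulate_cyberball(str(conditions[i]), int(rng.integers(0, 2**31 - 1)))
        est_catch[i] = game.catch_rate_pct + rng.normal(0.0, config.catch_noise_sd)
    est_catch = np.clip(est_catch, 0.0, 100.0)

    # Interpretation totals, cell by cell.
    hostile = np.empty(n, dtype=int)
    non_hostile = np.empty(n, dtype=int)
    groups_arr = np.asarray(groups)
    for g in ("dominant", "implicit", "neutral"):
        for c in ("exclusion", "acceptance"):
            mask = (groups_arr == g) & (conditions == c)
            m = int(mask.sum())
            if m == 0:
                continue
            cell = config.table1_params[(g, c)]
            shift = 0.0
            if hostile_shift is not None:
                shifts = np.unique(hostile_shift[mask])
                for s in shifts:
                    sub = mask & (hostile_shift == s)
                    msub = int(sub.sum())
                    h = _truncnorm_int(cell.hostile_mean - s, cell.hostile_sd, lo, hi, msub, rng)
                    nh = _truncnorm_int(
                        cell.non_hostile_mean, cell.non_hostile_sd, lo, hi, msub, rng
                    )
                    hostile[sub], non_hostile[sub] = h, nh
                continue
            h = _truncnorm_int(cell.hostile_mean - shift, cell.hostile_sd, lo, hi, m, rng)
            nh = _truncnorm_int(cell.non_hostile_mean, cell.non_hostile_sd, lo, hi, m, rng)
            hostile[mask], non_hostile[mask] = h, nh

    records = []
    for i in range(n):
        rec = ParticipantRecord(
            id=int(ids[i]),
            gender=str(gender[i]),
            age=int(age[i]),
            trait_group=str(groups_arr[i]),
            condition=str(conditions[i]),
            npi16_score=int(npi[i]),
            hsns_score=int(hsns[i]),
            basic_needs_score=int(bn[i]),
            estimated_catch_pct=float(est_catch[i]),
            hostile_score=int(hostile[i]),
            non_hostile_score=int(non_hostile[i]),
            hostile_bin=bin_hostile(int(hostile[i])),
            intervention=str(interventions[i]),
        )
        rec.validate()
        records.append(rec)
    return records


def generate_cohort(config: CohortConfig | None = None) -> list[ParticipantRecord]:
    """Generate a full between-subjects cohort.

    NPI-16 and HSNS totals are drawn first and trait groups derived by
    actually running the top-27% assignment on them, so scores and
    group labels are consistent by construction.  Conditions are
    assigned within each trait group at the configured ratio;
    interpretation totals then come from the group x condition cells.
    """
    config = CohortConfig() if config is None else config
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    npi = _truncnorm_int(8.0, 3.0, 0, 16, n, rng)
    hsns = _truncnorm_int(30.0, 6.0, 10, 50, n, rng)
    assignments = assign_trait_groups(hsns.astype(float), npi.astype(float))
    groups = [a.group for a in assignments]

    # Random condition assignment at the configured ratio within each group.
    conditions = np.empty(n, dtype=object)
    groups_arr = np.asarray(groups)
    by_group = config.condition_ratio_by_group or {}
    for g in ("dominant", "implicit", "neutral"):
        idx = np.flatnonzero(groups_arr == g)
        perm = rng.permutation(idx)
        ratio = by_group.get(g, config.condition_ratio)
        n_excl = int(round(ratio * idx.size))
        conditions[perm[:n_excl]] = "exclusion"
        conditions[perm[n_excl:]] = "acceptance"

    ids = np.arange(1, n + 1)
    interventions = np.full(n, "none", dtype=object)
    return _assemble_records(ids, groups, conditions, npi, hsns, interventions, config, rng)


def generate_intervention_cohort(config: CohortConfig | None = None) -> list[ParticipantRecord]:
    """Generate the two-arm self-affirmation cohort (implicit narcissists only).

    Participants are drawn from the upper HSNS range (all qualify for
    the implicit group), randomised to the self-affirmation or control
    arm, then assigned to exclusion/acceptance as in the main design.
    The affirmation arm's hostile-score cell mean is reduced by
    ``config.affirmation_effect`` scale points before sampling.
    """
    config = CohortConfig() if config is None else config
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = 2 * config.arm_size

    npi = _truncnorm_int(8.0, 3.0, 0, 16, n, rng)
    hsns = _truncnorm_int(42.0, 3.0, 36, 50, n, rng)  # upper HSNS range
    groups = ["implicit"] * n

    interventions = np.full(n, "control", dtype=object)
    perm = rng.permutation(n)
    interventions[perm[: config.arm_size]] = "self_affirmation"

    conditions = np.empty(n, dtype=object)
    perm2 = rng.permutation(n)
    n_excl = int(round(config.condition_ratio * n))
    conditions[perm2[:n_excl]] = "exclusion"
    conditions[perm2[n_excl:]] = "acceptance"

    shift = np.where(interventions == "self_affirmation", config.affirmation_effect, 0.0)
    ids = np.arange(1, n + 1)
    return _assemble_records(
        ids, groups, conditions, npi, hsns, interventions, config, rng, hostile_shift=shift
    )


def shuffle_conditions(records: list[ParticipantRecord], seed: int) -> list[ParticipantRecord]:
    """Permute condition labels across a cohort, severing feature-label links.

    Produces a null cohort in which no feature carries information
    about exclusion vs. acceptance; used for calibration checks.
    """
    rng = np.random.default_rng(seed)
    conds = [r.condition for r in records]
    perm = rng.permutation(len(records))
    out = []
    for i, rec in enumerate(records):
        d = rec.as_dict()
        d["condition"] = conds[perm[i]]
        out.append(ParticipantRecord(**d))
    return out
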