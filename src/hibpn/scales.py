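"""Psychometric scale scoring and trait-group assignment.

Scores the four instruments used around the Cyberball paradigm:

* NPI-16 — 16 forced-choice items, one point per narcissistic option,
  total 0–16 (grandiose/dominant narcissism).
* HSNS — Hypersensitive Narcissism Scale, 10 Likert items (1–5),
  total 10–50 (implicit/vulnerable narcissism).
* Basic Needs Scale — 20 Likert items (1–5) measuring threatened
  belonging, self-esteem, meaning and control after the ball-tossing
  game; nine items are reverse-keyed; higher totals mean *less* threat.
* Hostile-interpretation material — 12 ambiguous sentences, each with a
  hostile and a non-hostile reading rated 1–5; the hostile and
  non-hostile totals are summed separately (each 12–60).

Also provides the low/high binning of hostile totals (cut between 35
and 36) and the top-27% / top-27% / middle-46% trait-group assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "BASIC_NEEDS_REVERSE_ITEMS",
    "HOSTILE_SCORE_RANGE",
    "ScaleResponses",
    "TraitGroupAssignment",
    "score_npi16",
    "score_hsns",
    "score_basic_needs",
    "score_interpretations",
    "reverse_key",
    "bin_hostile",
    "assign_trait_groups",
    "response_rate",
]

#: 1-based positions of the reverse-keyed Basic Needs items.
BASIC_NEEDS_REVERSE_ITEMS = frozenset({1, 3, 5, 7, 9, 11, 14, 16, 20})

#: Attainable range of a hostile/non-hostile total: 12 ambiguous
#: sentences, each interpretation rated 1–5.
HOSTILE_SCORE_RANGE = (12, 60)

#: Single cut separating low (<=35) from high (>=36) hostile totals.
HOSTILE_BIN_THRESHOLD = 36

TraitGroup = Literal["dominant", "implicit", "neutral"]


def _check_items(items: Sequence[int], n: int, lo: int, hi: int, name: str) -> np.ndarray:
    arr = np.asarray(items)
    if arr.shape != (n,):
        raise ValueError(f"{name}: expected exactly {n} items, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.number) or np.any(arr != np.floor(arr)):
        raise ValueError(f"{name}: items must be integers")
    if np.any((arr < lo) | (arr > hi)):
        raise ValueError(f"{name}: items must lie in [{lo}, {hi}]")
    return arr.astype(int)


@dataclass(frozen=True)
class ScaleResponses:
    """Raw item-level responses for one participant."""

    npi16_items: Sequence[int]
    hsns_items: Sequence[int]
    basic_needs_items: Sequence[int]
    hostile_ratings: Sequence[int]
    non_hostile_ratings: Sequence[int]
    post_game_exclusion_items: Sequence[int] = (1, 1)
    estimated_catch_pct: float = 0.0

    def __post_init__(self) -> None:
        _check_items(self.npi16_items, 16, 0, 1, "npi16_items")
        _check_items(self.hsns_items, 10, 1, 5, "hsns_items")
        _check_items(self.basic_needs_items, 20, 1, 5, "basic_needs_items")
        if len(self.hostile_ratings) != len(self.non_hostile_ratings):
            raise ValueError("hostile/non-hostile rating lists must have equal length")
        if not 0.0 <= float(self.estimated_catch_pct) <= 100.0:
            raise ValueError("estimated_catch_pct must lie in [0, 100]")


@dataclass(frozen=True)
class TraitGroupAssignment:
    """One participant's narcissistic trait group with its rank evidence."""

    participant_id: int
    group: TraitGroup
    hsns_percentile: float
    npi_percentile: float


def score_npi16(items: Sequence[int]) -> int:
    """Total NPI-16 score: the count of narcissistic-option endorsements (0–16)."""
    return int(_check_items(items, 16, 0, 1, "npi16_items").sum())


def score_hsns(items: Sequence[int]) -> int:
    """Total HSNS score: sum of the 10 Likert items (10–50)."""
    return int(_check_items(items, 10, 1, 5, "hsns_items").sum())


def reverse_key(items: Sequence[int]) -> np.ndarray:
    """Map 5-point Likert responses v -> 6 - v (an involution)."""
    arr = np.asarray(items, dtype=int)
    if np.any((arr < 1) | (arr > 5)):
        raise ValueError("Likert items must lie in [1, 5]")
    return 6 - arr


def score_basic_needs(items: Sequence[int]) -> int:
    """Basic Needs total (20–100) with nine reverse-keyed items.

    Items at 1-based positions 1, 3, 5, 7, 9, 11, 14, 16 and 20 are
    mapped v -> 6 - v before summation.  Higher totals indicate lower
    perceived threat to basic needs.
    """
    arr = _check_items(items, 20, 1, 5, "basic_needs_items")
    rev = np.array([i + 1 in BASIC_NEEDS_REVERSE_ITEMS for i in range(20)])
    scored = np.where(rev, 6 - arr, arr)
    return int(scored.sum())


def score_interpretations(
    hostile_ratings: Sequence[int], non_hostile_ratings: Sequence[int]
) -> tuple[int, int]:
    """Sum the hostile and non-hostile likelihood ratings separately.

    Returns ``(hostile_score, non_hostile_score)``; each rating must be
    a 1–5 Likert value and both lists must cover the same sentences.
    """
    h = np.asarray(hostile_ratings, dtype=int)
    nh = np.asarray(non_hostile_ratings, dtype=int)
    if h.shape != nh.shape:
        raise ValueError("hostile/non-hostile rating lists must have equal length")
    for name, arr in (("hostile_ratings", h), ("non_hostile_ratings", nh)):
        if np.any((arr < 1) | (arr > 5)):
            raise ValueError(f"{name}: ratings must lie in [1, 5]")
    return int(h.sum()), int(nh.sum())


def bin_hostile(score: int) -> str:
    """Bin a hostile-interpretation total into ``'low'`` (<=35) or ``'high'`` (>=36).

    The score must lie in the instrument's attainable range [12, 60].
    """
    lo, hi = HOSTILE_SCORE_RANGE
    if not lo <= score <= hi:
        raise ValueError(f"hostile score {score} outside attainable range [{lo}, {hi}]")
    return "high" if score >= HOSTILE_BIN_THRESHOLD else "low"


def _top_k_indices(scores: np.ndarray, k: int) -> set[int]:
    # Highest scores win; ties broken by ascending participant index
    # (stable sort on (-score, index)).
    order = np.lexsort((np.arange(scores.size), -scores))
    return set(order[:k].tolist())


def assign_trait_groups(
    hsns_scores: Sequence[float],
    npi_scores: Sequence[float],
    participant_ids: Sequence[int] | None = None,
) -> list[TraitGroupAssignment]:
    """Partition a cohort into implicit / dominant / neutral trait groups.

    The top 27% of HSNS totals form the implicit-narcissism group and
    the top 27% of NPI-16 totals the dominant-narcissism group; the
    remaining middle 46% are the neutral controls.  Group counts are
    ``round(0.27 * n)`` each, remainder to neutral; ties are broken by
    ascending participant index.  A participant in both top sets goes
    to the scale on which their percentile rank is higher, HSNS winning
    exact ties.
    """
    hsns = np.asarray(hsns_scores, dtype=float)
    npi = np.asarray(npi_scores, dtype=float)
    if hsns.size == 0:
        raise ValueError("empty cohort")
    if hsns.shape != npi.shape:
        raise ValueError("HSNS and NPI score lists must cover the same participants")
    n = hsns.size
    if n < 4:
        raise ValueError("need at least 4 participants to form three groups")
    ids = np.arange(n) if participant_ids is None else np.asarray(participant_ids)

    k = int(round(0.27 * n))
    top_hsns = _top_k_indices(hsns, k)
    top_npi = _top_k_indices(npi, k)

    # Percentile rank (fraction of cohort scoring strictly below).
    hsns_pct = 100.0 * (hsns[:, None] > hsns[None, :]).mean(axis=1)
    npi_pct = 100.0 * (npi[:, None] > npi[None, :]).mean(axis=1)

    groups: list[str] = []
    for i in range(n):
        if i in top_hsns and i in top_npi:
            groups.append("implicit" if hsns_pct[i] >= npi_pct[i] else "dominant")
        elif i in top_hsns:
            groups.append("implicit")
        elif i in top_npi:
            groups.append("dominant")
        else:
            groups.append("neutral")

    # Overlap between the two top sets leaves one group short; refill from
    # the highest-ranked unassigned participants so counts stay round(0.27n).
    for group, scores_arr in (("implicit", hsns), ("dominant", npi)):
        deficit = k - groups.count(group)
        if deficit > 0:
            order = np.lexsort((np.arange(n), -scores_arr))
            for i in order:
                if deficit == 0:
                    break
                if groups[i] == "neutral":
                    groups[i] = group
                    deficit -= 1

    return [
        TraitGroupAssignment(
            participant_id=int(ids[i]),
            group=groups[i],  # type: ignore[arg-type]
            hsns_percentile=float(hsns_pct[i]),
            npi_percentile=float(npi_pct[i]),
        )
        for i in range(n)
    ]


def response_rate(returned: int, distributed: int) -> float:
    """Questionnaire response rate as a percentage, to one decimal."""
    if distributed <= 0:
        raise ValueError("distributed must be positive")
    if not 0 <= returned <= distributed:
        raise ValueError("returned must lie in [0, distributed]")
    return round(100.0 * returned / distributed, 1)
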