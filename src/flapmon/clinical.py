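"""Bedside flap scoring and the re-exploration decision rule.

Each observation grades four signs — flap colour, temperature,
re-capillarization time and tissue turgor — with fixed point values:

========== === ============= === =========== === ======== ===
colour     pts temperature   pts recap       pts turgor   pts
========== === ============= === =========== === ======== ===
pale white 3   cold          2   approx. 1 s 2   soft     2
pink       1   body          1   > 2 s       1   elastic  1
red        2   superheated   2   < 1 s       3   plump    2
blue       3                     no refill   3
========== === ============= === =========== === ======== ===

Re-exploration is indicated when the total is >= 9, OR two signs jointly
score 6 points (only colour and recapillarization can reach 3 points, so
this means both at their 3-point levels), OR the colour has stayed pale
white/blue for more than 60 minutes while recapillarization is absent or
under one second.  The colour-duration memory travels on the observation
(``abnormal_color_duration``), keeping the rule itself stateless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

COLOR_POINTS = {"pale_white": 3, "pink": 1, "red": 2, "blue": 3}
TEMPERATURE_POINTS = {"cold": 2, "body": 1, "superheated": 2}
RECAP_POINTS = {"approx_1s": 2, "gt_2s": 1, "lt_1s": 3, "none": 3}
TURGOR_POINTS = {"soft": 2, "elastic": 1, "plump": 2}

CLAUSES = ("total_ge_9", "two_vars_6", "color_60min_and_recap")


@dataclass
class ClinicalScore:
    color_points: int
    temperature_points: int
    recap_points: int
    turgor_points: int
    total: int
    reexplore: bool = False
    triggered_clauses: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.total != (
            self.color_points + self.temperature_points + self.recap_points + self.turgor_points
        ):
            raise ValueError("total must equal the sum of the four category points")


def _lookup(table: dict, level: str, field: str) -> int:
    try:
        return table[level]
    except KeyError:
        raise ValueError(f"unknown level {level!r} for field {field!r}") from None


def _get(obs, key: str):
    if hasattr(obs, key):
        return getattr(obs, key)
    return obs[key]


def score_observation(obs) -> ClinicalScore:
    """Assign the point values of one observation (no decision yet).

    ``obs`` is a :class:`~flapmon.records.ClinicalObservation` or any
    mapping/row with the same fields; an unknown category level is rejected
    with a diagnostic naming the field.
    """
    cp = _lookup(COLOR_POINTS, _get(obs, "color"), "color")
    tp = _lookup(TEMPERATURE_POINTS, _get(obs, "temperature"), "temperature")
    rp = _lookup(RECAP_POINTS, _get(obs, "recap"), "recap")
    gp = _lookup(TURGOR_POINTS, _get(obs, "turgor"), "turgor")
    return ClinicalScore(cp, tp, rp, gp, total=cp + tp + rp + gp)


def reexploration_decision(score: ClinicalScore, obs) -> tuple[bool, frozenset]:
    """Evaluate the three re-exploration clauses; returns (decision, fired clauses)."""
    clauses = set()
    if score.total >= 9:
        clauses.add("total_ge_9")
    if score.color_points + score.recap_points == 6:
        clauses.add("two_vars_6")
    if float(_get(obs, "abnormal_color_duration")) > 60 and _get(obs, "recap") in ("none", "lt_1s"):
        clauses.add("color_60min_and_recap")
    return bool(clauses), frozenset(clauses)


def score_and_decide(obs) -> ClinicalScore:
    """Score one observation and fill in the re-exploration decision."""
    score = score_observation(obs)
    decision, clauses = reexploration_decision(score, obs)
    score.reexplore = decision
    score.triggered_clauses = clauses
    return score


def clinical_detection_time(observations: pd.DataFrame) -> Optional[float]:
    """Timestamp of the earliest observation indicating re-exploration, or None.

    ``observations`` holds one flap's bedside checks; they are sorted by
    timestamp before the first-true scan.
    """
    obs = observations.sort_values("timestamp", kind="stable")
    for _, row in obs.iterrows():
        if score_and_decide(row).reexplore:
            return float(row.timestamp)
    return None


def score_cohort(clinical: pd.DataFrame) -> pd.DataFrame:
    """Score every observation of a cohort table; one output row per observation."""
    rows = []
    for _, row in clinical.iterrows():
        s = score_and_decide(row)
        rows.append(
            {
                "flap_id": row["flap_id"],
                "timestamp": row["timestamp"],
                "color_points": s.color_points,
                "temperature_points": s.temperature_points,
                "recap_points": s.recap_points,
                "turgor_points": s.turgor_points,
                "total": s.total,
                "reexplore": s.reexplore,
                "triggered_clauses": "+".join(sorted(s.triggered_clauses)),
            }
        )
    return pd.DataFrame(rows)
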