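"""Monitoring time grid for free-flap follow-up.

Intraoperative measurements happen at four discrete events — flap origin
(t0), flap raise (t1), completed anastomosis (t2) and flap inset (t3) —
while postoperative monitoring is organised in 12-hour windows starting at
inset.  Flap inset defines the clock origin: every timestamp in this
package is decimal hours post-inset, with intraoperative events carrying
non-positive timestamps (t3 = 0) and postoperative measurements strictly
positive ones.

Postoperative intervals are half-open on the left::

    t4 = (0, 12],  t5 = (12, 24],  ...  t9 = (60, 72],  t10 = (72, inf)

so every positive timestamp belongs to exactly one interval.
"""

from __future__ import annotations

import math

INTRAOP_POINTS: tuple[str, ...] = ("t0", "t1", "t2", "t3")
POSTOP_INTERVALS: tuple[str, ...] = ("t4", "t5", "t6", "t7", "t8", "t9", "t10")
ALL_TIMEPOINTS: tuple[str, ...] = INTRAOP_POINTS + POSTOP_INTERVALS

#: (lower, upper] bounds of each postoperative interval in hours post-inset.
INTERVAL_BOUNDS: dict[str, tuple[float, float]] = {
    "t4": (0.0, 12.0),
    "t5": (12.0, 24.0),
    "t6": (24.0, 36.0),
    "t7": (36.0, 48.0),
    "t8": (48.0, 60.0),
    "t9": (60.0, 72.0),
    "t10": (72.0, math.inf),
}

INTERVAL_WIDTH_H = 12.0


def is_postoperative(label: str) -> bool:
    return label in INTERVAL_BOUNDS


def interval_label(timestamp: float) -> str:
    """Map a strictly positive timestamp (hours post-inset) to its interval label.

    Raises ``ValueError`` for non-positive timestamps, which belong to the
    intraoperative point grid and carry explicit labels instead.
    """
    if not timestamp > 0:
        raise ValueError(
            f"timestamp {timestamp!r} is not postoperative; intraoperative "
            "events are labelled explicitly (t0-t3)"
        )
    index = min(int(math.ceil(timestamp / INTERVAL_WIDTH_H)) - 1, len(POSTOP_INTERVALS) - 1)
    return POSTOP_INTERVALS[index]


def interval_index(label: str) -> int:
    """Position of a postoperative interval label in monitoring order (t4 -> 0)."""
    try:
        return POSTOP_INTERVALS.index(label)
    except ValueError:
        raise ValueError(f"{label!r} is not a postoperative interval label") from None
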