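"""Packaged baseline cohort: 65 head-and-neck free flaps.

The cohort composition mirrors the published baseline table of the study
population this package models: 65 flaps of six types, 46 without and 19
with re-exploration for perfusion compromise, the four causes of
compromise, reconstruction regime, irradiation status and recipient
arteries.  The table is built programmatically from its margins, which are
also exported for the margin-conservation checks of the synthetic
generator.

The fixture is metadata only: monitoring time courses are not part of it,
so the two detection-time columns are left empty.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import FLAP_COLUMNS

#: marginal counts of the baseline cohort (split R_minus / R_plus)
MARGINS = {
    "n": {"R_minus": 46, "R_plus": 19, "total": 65},
    "flap_type": {
        "RFF": (16, 8),
        "UFF": (13, 3),
        "OMFF": (13, 3),
        "LDF": (1, 3),
        "OMSF": (2, 1),
        "UAF": (1, 1),
    },
    # venous 8 + arterial 7 + haematoma 3 + kinking 1 = 19 revised flaps; the
    # published table prints "8" for arterial but its own percentage (36.8% of
    # 19 = 7) and the revision total identify that as a typo
    "cause": {"venous_thrombosis": 8, "arterial_thrombosis": 7, "haematoma": 3, "kinking": 1},
    "regime": {"primary": (39, 15), "secondary": (7, 4)},
    "irradiated": (6, 3),
    "recipient_artery": {
        "superior_thyroid": (30, 13),
        "lingual": (8, 3),
        "external_carotid": (5, 2),
        "facial": (3, 1),
    },
    "failed": 7,
    "surgery_duration_mean": {"R_minus": 543.7, "R_plus": 527.3},
    "surgery_duration_sd": {"R_minus": 126.5, "R_plus": 128.1},
}

#: failures by cause (7 complete losses among the 19 revised flaps; arterial
#: compromise carries the worst salvage prognosis, so it takes the majority)
FAILURES_BY_CAUSE = {"venous_thrombosis": 2, "arterial_thrombosis": 4, "haematoma": 1, "kinking": 0}


def _expand(pairs: dict[str, tuple[int, int]], group_idx: int) -> list[str]:
    out: list[str] = []
    for level, counts in pairs.items():
        out.extend([level] * counts[group_idx])
    return out


def fixture_table2() -> pd.DataFrame:
    """Build the 65-row baseline flap-metadata table.

    Every univariate margin (per group) equals the published count exactly;
    the joint assignment of attributes is a deterministic sequential fill,
    since only the margins are specified.
    """
    rows: list[dict] = []
    for gi, group in enumerate(("R_minus", "R_plus")):
        n = MARGINS["n"][group]
        types = _expand(MARGINS["flap_type"], gi)
        regimes = _expand(MARGINS["regime"], gi)
        arteries = _expand(MARGINS["recipient_artery"], gi)
        irradiated = [True] * MARGINS["irradiated"][gi] + [False] * (n - MARGINS["irradiated"][gi])
        if group == "R_plus":
            causes: list[str] = []
            failed: list[bool] = []
            for cause, count in MARGINS["cause"].items():
                n_fail = FAILURES_BY_CAUSE[cause]
                causes.extend([cause] * count)
                failed.extend([True] * n_fail + [False] * (count - n_fail))
        else:
            causes = ["none"] * n
            failed = [False] * n
        duration = MARGINS["surgery_duration_mean"][group]
        for i in range(n):
            rows.append(
                {
                    "flap_id": f"F{len(rows) + 1:03d}",
                    "flap_type": types[i],
                    "regime": regimes[i],
                    "irradiated": irradiated[i],
                    "recipient_artery": arteries[i],
                    "surgery_duration": duration,
                    "group": group,
                    "cause": causes[i],
                    "failed": failed[i],
                    "clinical_detection_time": np.nan,
                    "hsi_crossing_time": np.nan,
                }
            )
    return pd.DataFrame(rows, columns=FLAP_COLUMNS)
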