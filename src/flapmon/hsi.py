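"""Hyperspectral malperfusion metrics and the four-criterion detection rule.

For every monitoring event three relative-change metrics are derived per
parameter (StO2, NPI, THI, TWI), all as percent change
``(flap - anchor) / anchor * 100``:

* ``*_dref`` — drop against the simultaneously measured adjacent reference
  site (the "drop rate");
* ``*_dt3``  — change against the same flap's inset (t3) measurement;
* ``*_dpre`` — change against the immediately preceding measurement (the
  first postoperative event therefore anchors on t3).

Malperfusion is flagged when, at a postoperative event, any of four
criteria crosses its threshold: StO2 or its drop rate, NPI or its drop
rate.  The default thresholds are the published dichotomization values
(the revised-group means); they can also be re-derived from a cohort.

Sign convention: the published group means put the revised group at a MORE
negative drop rate (e.g. StO2 drop −38.1% vs −18.3%), and the rule flags a
"negative deviation", so a drop-rate criterion fires when the drop is at
least as severe as (<=) its threshold.  The inequality directions as
literally printed in the source abstract (``> −38`` / ``>= −13.4``) would
flag every healthy flap; they remain available through
``strict_printed_signs=True`` so both readings can be run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import isfinite, isnan
from typing import Optional, Union

import numpy as np
import pandas as pd

from .records import Cohort, HSI_PARAMETERS
from .timegrid import POSTOP_INTERVALS

logger = logging.getLogger(__name__)

DELTA_KINDS = ("dref", "dt3", "dpre")
DELTA_COLUMNS = [f"{p}_{k}" for p in HSI_PARAMETERS for k in DELTA_KINDS]

#: criteria names in reporting order
CRITERIA = ("sto2", "sto2_dref", "npi", "npi_dref")


@dataclass(frozen=True)
class Thresholds:
    """Dichotomization thresholds of the four detection criteria."""

    sto2_max: float
    sto2_dref_max: float
    npi_max: float
    npi_dref_max: float

    def __post_init__(self) -> None:
        for name in ("sto2_max", "sto2_dref_max", "npi_max", "npi_dref_max"):
            if not isfinite(getattr(self, name)):
                raise ValueError(f"threshold {name} must be finite")
        for name in ("sto2_max", "npi_max"):
            if not 0 <= getattr(self, name) <= 100:
                raise ValueError(f"threshold {name} must lie in [0, 100]")

    def as_dict(self) -> dict[str, float]:
        return {
            "sto2_max": self.sto2_max,
            "sto2_dref_max": self.sto2_dref_max,
            "npi_max": self.npi_max,
            "npi_dref_max": self.npi_dref_max,
        }


#: published rule thresholds (flap-side StO2 %, drop rates in %)
DEFAULT_THRESHOLDS = Thresholds(
    sto2_max=32.0, sto2_dref_max=-38.0, npi_max=32.9, npi_dref_max=-13.4
)


def _relative_change(value: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    anchor = np.asarray(anchor, dtype=float)
    value = np.asarray(value, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (value - anchor) / anchor * 100.0
    out[~np.isfinite(out)] = np.nan
    return out


def compute_deltas(hsi: pd.DataFrame) -> pd.DataFrame:
    """Append the twelve delta columns to a measurement table.

    Rows are returned sorted by (flap_id, timestamp).  A delta whose anchor
    is missing or zero is left absent (NaN) and logged, never raised.
    """
    df = hsi.sort_values(["flap_id", "timestamp"], kind="stable").reset_index(drop=True).copy()
    for param in HSI_PARAMETERS:
        df[f"{param}_dref"] = _relative_change(df[param], df[f"ref_{param}"])

    for param in HSI_PARAMETERS:
        df[f"{param}_dt3"] = np.nan
        df[f"{param}_dpre"] = np.nan
    for flap_id, idx in df.groupby("flap_id", sort=False).groups.items():
        sub = df.loc[idx]
        t3_rows = sub[sub.timepoint == "t3"]
        for param in HSI_PARAMETERS:
            values = sub[param].to_numpy(dtype=float)
            if len(t3_rows):
                anchor_t3 = float(t3_rows.iloc[0][param])
                df.loc[idx, f"{param}_dt3"] = _relative_change(
                    values, np.full(len(values), anchor_t3)
                )
            else:
                logger.warning("flap %s has no t3 measurement; dt3 left absent", flap_id)
            prev = np.concatenate([[np.nan], values[:-1]])
            df.loc[idx, f"{param}_dpre"] = _relative_change(values, prev)
    n_missing = int(df[DELTA_COLUMNS].isna().sum().sum())
    if n_missing:
        logger.debug("%d delta values are absent (zero or missing anchors)", n_missing)
    return df


def evaluate_criteria(
    sto2: float,
    sto2_dref: float,
    npi: float,
    npi_dref: float,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    strict_printed_signs: bool = False,
) -> tuple[bool, frozenset]:
    """Evaluate the four-criterion rule on one event; absent deltas never fire.

    All boundaries are inclusive.  With ``strict_printed_signs`` the
    drop-rate inequalities follow the literally printed directions instead
    of the negative-deviation reading (see module docstring).
    """
    fired = set()
    if not isnan(sto2) and sto2 <= thresholds.sto2_max:
        fired.add("sto2")
    if not isnan(npi) and npi <= thresholds.npi_max:
        fired.add("npi")
    if strict_printed_signs:
        if not isnan(sto2_dref) and sto2_dref > thresholds.sto2_dref_max:
            fired.add("sto2_dref")
        if not isnan(npi_dref) and npi_dref >= thresholds.npi_dref_max:
            fired.add("npi_dref")
    else:
        if not isnan(sto2_dref) and sto2_dref <= thresholds.sto2_dref_max:
            fired.add("sto2_dref")
        if not isnan(npi_dref) and npi_dref <= thresholds.npi_dref_max:
            fired.add("npi_dref")
    return bool(fired), frozenset(fired)


def malperfusion_criteria(
    row,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    strict_printed_signs: bool = False,
) -> tuple[bool, frozenset]:
    """Rule evaluation for a delta-annotated measurement row (mapping-like)."""
    get = row.get if hasattr(row, "get") else lambda k: getattr(row, k)
    return evaluate_criteria(
        float(get("sto2")),
        float(get("sto2_dref")),
        float(get("npi")),
        float(get("npi_dref")),
        thresholds=thresholds,
        strict_printed_signs=strict_printed_signs,
    )


def hsi_detection_time(
    flap_deltas: pd.DataFrame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    strict_printed_signs: bool = False,
) -> tuple[Optional[float], frozenset]:
    """Earliest postoperative event at which the rule fires, for one flap.

    Intraoperative events (timestamp <= 0) never trigger detection: the
    clock runs from flap inset and no pre-inset group differences exist.
    Returns ``(None, frozenset())`` when the series never crosses.
    """
    postop = flap_deltas[flap_deltas.timestamp > 0].sort_values("timestamp", kind="stable")
    for _, row in postop.iterrows():
        hit, fired = malperfusion_criteria(
            row, thresholds=thresholds, strict_printed_signs=strict_printed_signs
        )
        if hit:
            return float(row.timestamp), fired
    return None, frozenset()


def derive_thresholds(
    cohort: Cohort,
    timepoints: tuple[str, ...] = POSTOP_INTERVALS,
    deltas: Optional[pd.DataFrame] = None,
) -> Thresholds:
    """Dichotomization thresholds as revised-group means over postoperative events.

    Each threshold is the arithmetic mean of its quantity over all
    measurements of revised (R_plus) flaps in the requested timepoints,
    computed per measurement (not per flap).
    """
    if deltas is None:
        deltas = compute_deltas(cohort.hsi)
    groups = cohort.flaps.set_index("flap_id")["group"]
    sel = deltas[
        deltas.flap_id.map(groups).eq("R_plus") & deltas.timepoint.isin(timepoints)
    ]
    if sel.empty:
        raise ValueError("cannot derive thresholds: no revised-group measurements in range")
    return Thresholds(
        sto2_max=float(sel.sto2.mean()),
        sto2_dref_max=float(sel.sto2_dref.mean()),
        npi_max=float(sel.npi.mean()),
        npi_dref_max=float(sel.npi_dref.mean()),
    )


def detect_cohort(
    cohort: Cohort,
    thresholds: Union[Thresholds, str, None] = None,
    strict_printed_signs: bool = False,
) -> pd.DataFrame:
    """Per-flap clinical and HSI detection times.

    ``thresholds`` may be a :class:`Thresholds`, ``"derive"`` (re-derive
    from this cohort) or ``None``/``"printed"`` (published defaults).
    Returns one row per flap: ``flap_id, group, hsi_time, clinical_time,
    lead_time, fired`` with absent times as NaN and ``fired`` as a
    ``+``-joined criterion list at the first crossing.
    """
    from .clinical import clinical_detection_time  # local to avoid cycle at import time

    deltas = compute_deltas(cohort.hsi)
    if thresholds is None or thresholds == "printed":
        th = DEFAULT_THRESHOLDS
    elif thresholds == "derive":
        th = derive_thresholds(cohort, deltas=deltas)
    elif isinstance(thresholds, Thresholds):
        th = thresholds
    else:
        raise ValueError(f"unknown thresholds specification {thresholds!r}")

    rows = []
    clin_by_flap = dict(tuple(cohort.clinical.groupby("flap_id", sort=False)))
    for flap_id, flap_deltas in deltas.groupby("flap_id", sort=False):
        h_time, fired = hsi_detection_time(
            flap_deltas, thresholds=th, strict_printed_signs=strict_printed_signs
        )
        obs = clin_by_flap.get(flap_id)
        c_time = clinical_detection_time(obs) if obs is not None else None
        lead = (
            c_time - h_time if (c_time is not None and h_time is not None) else np.nan
        )
        rows.append(
            {
                "flap_id": flap_id,
                "hsi_time": np.nan if h_time is None else h_time,
                "clinical_time": np.nan if c_time is None else c_time,
                "lead_time": lead,
                "fired": "+".join(sorted(fired)),
            }
        )
    out = pd.DataFrame(rows, columns=["flap_id", "hsi_time", "clinical_time", "lead_time", "fired"])
    order = {fid: i for i, fid in enumerate(cohort.flaps.flap_id)}
    return out.sort_values("flap_id", key=lambda s: s.map(order), kind="stable").reset_index(
        drop=True
    )


@dataclass
class DetectionComparison:
    """Paired clinical-vs-HSI detection summary over flaps with both times."""

    n_paired: int
    clinical_mean: float
    clinical_sd: float
    hsi_mean: float
    hsi_sd: float
    lead_mean: float
    lead_sd: float
    wilcoxon_statistic: Optional[float]
    wilcoxon_p: Optional[float]


def compare_detection(detections: pd.DataFrame) -> DetectionComparison:
    """Summarise paired detection times and test them with Wilcoxon signed-rank.

    The mean lead time equals mean(clinical) - mean(HSI) over the paired
    set by arithmetic identity; this is asserted.  With all-zero paired
    differences the signed-rank p is undefined and reported absent.
    """
    from .stats import paired_compare

    paired = detections.dropna(subset=["hsi_time", "clinical_time"])
    if paired.empty:
        raise ValueError("no flaps with both detection times present")
    lead = (paired.clinical_time - paired.hsi_time).to_numpy(dtype=float)
    c = paired.clinical_time.to_numpy(dtype=float)
    h = paired.hsi_time.to_numpy(dtype=float)
    assert abs(lead.mean() - (c.mean() - h.mean())) < 1e-9
    if np.any(lead != 0):
        test = paired_compare(lead)
        stat, p = test.statistic, test.p_value
    else:
        stat, p = None, None
    ddof = 1 if len(paired) > 1 else 0
    return DetectionComparison(
        n_paired=len(paired),
        clinical_mean=float(c.mean()),
        clinical_sd=float(c.std(ddof=ddof)),
        hsi_mean=float(h.mean()),
        hsi_sd=float(h.std(ddof=ddof)),
        lead_mean=float(lead.mean()),
        lead_sd=float(lead.std(ddof=ddof)),
        wilcoxon_statistic=stat,
        wilcoxon_p=p,
    )
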