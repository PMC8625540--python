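"""Cohort-level statistics.

Implements the statistical layer used around flap monitoring: descriptive
group summaries (mean, SD, min, max, SEM), normality-gated two-group
comparison (Shapiro-Wilk at alpha = 0.05 deciding between Student's t and
Mann-Whitney U), Wilcoxon signed-rank for paired detection times,
contingency tests with the small-expected-count rule (Pearson chi-square,
Fisher's exact when any expected cell frequency is below 5), one-way
eta-squared, and the salvage rate.

Conventions: sample SD (n-1 denominator) throughout; all tests two-sided;
rank ties handled by scipy's mid-rank corrections; zero paired differences
dropped before the signed-rank test.  No multiple-testing correction is
applied anywhere — reports state this prominently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .records import Cohort
from .timegrid import POSTOP_INTERVALS

logger = logging.getLogger(__name__)

METRIC_SUFFIX = {
    "raw": "",
    "delta_reference": "_dref",
    "delta_t3": "_dt3",
    "delta_prevalue": "_dpre",
}


@dataclass
class TestResult:
    test_name: str
    statistic: Optional[float]
    p_value: Optional[float]
    n: tuple
    eta_squared: Optional[float] = None
    details: dict = field(default_factory=dict)


def summarize(
    cohort: Cohort,
    parameter: str,
    metric: str = "raw",
    timepoint: str = "overall",
    deltas: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-group summary (n, mean, sd, min, max, sem) of one measurement cell.

    ``timepoint`` is a postoperative interval label or ``"overall"`` (all
    of t4-t10).  ``metric`` selects the raw parameter or one of its delta
    metrics, in which case a delta table is used (computed on the fly if
    not supplied).  Groups without measurements in the cell are omitted
    (logged), not errors.  The sd of a single value is left absent
    (sample-sd convention).
    """
    if metric not in METRIC_SUFFIX:
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "raw":
        table = cohort.hsi
        column = parameter
    else:
        if deltas is None:
            from .hsi import compute_deltas

            deltas = compute_deltas(cohort.hsi)
        table = deltas
        column = parameter + METRIC_SUFFIX[metric]
    if column not in table.columns:
        raise ValueError(f"no column {column!r} for parameter/metric requested")

    wanted = POSTOP_INTERVALS if timepoint == "overall" else (timepoint,)
    sel = table[table.timepoint.isin(wanted)]
    groups = cohort.flaps.set_index("flap_id")["group"]
    sel = sel.assign(group=sel.flap_id.map(groups)).dropna(subset=[column])

    rows = []
    for group in ("R_minus", "R_plus"):
        values = sel.loc[sel.group == group, column].to_numpy(dtype=float)
        if len(values) == 0:
            logger.warning("empty summary cell: %s/%s/%s/%s", parameter, metric, timepoint, group)
            continue
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else np.nan
        rows.append(
            {
                "group": group,
                "n": len(values),
                "mean": float(values.mean()),
                "sd": sd,
                "min": float(values.min()),
                "max": float(values.max()),
                "sem": sd / np.sqrt(len(values)) if len(values) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def _normality_p(sample: np.ndarray) -> float:
    """Shapiro-Wilk p, with degenerate samples treated as non-normal."""
    if np.ptp(sample) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(sample).pvalue)


def compare_groups(values_a: Sequence, values_b: Sequence, alpha: float = 0.05) -> TestResult:
    """Two-group comparison with Shapiro-Wilk-gated test selection.

    Both samples normal at ``alpha`` -> two-sided unpaired Student's t;
    otherwise two-sided Mann-Whitney U.  Kolmogorov-Smirnov normality
    statistics are computed and reported alongside but never decide the
    path (one arbiter avoids contradictory selections).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 values")
    sw_a, sw_b = _normality_p(a), _normality_p(b)
    details = {"shapiro_p": (sw_a, sw_b)}
    for name, s in (("ks_p_a", a), ("ks_p_b", b)):
        sd = s.std(ddof=1)
        details[name] = (
            float(sps.kstest((s - s.mean()) / sd, "norm").pvalue) if sd > 0 else 0.0
        )
    if sw_a > alpha and sw_b > alpha:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        name = "t_test"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney_u"
    details["path"] = name
    return TestResult(name, float(stat), float(p), (len(a), len(b)), details=details)


def paired_compare(differences: Sequence) -> TestResult:
    """Two-sided Wilcoxon signed-rank on paired differences (zeros dropped)."""
    d = np.asarray(differences, dtype=float)
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        raise ValueError("all paired differences are zero; signed-rank p undefined")
    stat, p = sps.wilcoxon(nonzero, alternative="two-sided")
    return TestResult(
        "wilcoxon_signed_rank",
        float(stat),
        float(p),
        (len(d),),
        details={"n_nonzero": len(nonzero)},
    )


def _fisher_exact_rx2(table: np.ndarray) -> float:
    """Two-sided Freeman-Halton exact p for an r x 2 table by full enumeration.

    Sums the probabilities of all tables with the observed margins whose
    multivariate-hypergeometric probability does not exceed the observed
    table's (with a small relative tolerance against float noise).
    """
    rows = table.sum(axis=1)
    col1 = int(table[:, 0].sum())
    n = int(table.sum())
    size = int(np.prod(rows + 1))
    if size > 5_000_000:
        raise ValueError("table too large for exact enumeration; use chi-square instead")
    const = gammaln(col1 + 1) + gammaln(n - col1 + 1) - gammaln(n + 1)

    def logp(first_col: Sequence[int]) -> float:
        lp = const
        for r, a in zip(rows, first_col):
            lp += gammaln(r + 1) - gammaln(a + 1) - gammaln(r - a + 1)
        return lp

    lp_obs = logp(table[:, 0])
    total = 0.0
    for combo in product(*(range(r + 1) for r in rows)):
        if sum(combo) != col1:
            continue
        lp = logp(combo)
        if lp <= lp_obs + 1e-9:
            total += float(np.exp(lp))
    return min(total, 1.0)


def contingency(table) -> TestResult:
    """Association test for a 2x2 or r x 2 count table.

    Pearson chi-square when every expected cell frequency is at least 5
    (the boundary value 5 stays chi-square); otherwise Fisher's exact test
    (scipy for 2x2, full enumeration for r x 2).
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a 2D contingency table with at least 2 rows and columns")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(np.asarray(table, dtype=float) % 1 != 0) or np.any(t < 0):
            raise ValueError("counts must be nonnegative integers")
        t = t.astype(int)
    expected = sps.contingency.expected_freq(t)
    if np.all(expected >= 5):
        res = sps.chi2_contingency(t, correction=False)
        return TestResult(
            "chi_square",
            float(res.statistic),
            float(res.pvalue),
            tuple(t.sum(axis=1)),
            details={"expected_min": float(expected.min()), "path": "chi_square"},
        )
    if t.shape == (2, 2):
        stat, p = sps.fisher_exact(t, alternative="two-sided")
        stat = float(stat)
    else:
        if t.shape[1] != 2:
            if t.shape[0] == 2:
                t = t.T
            else:
                raise ValueError("Fisher's exact test supported for 2x2 and r x 2 tables only")
        p, stat = _fisher_exact_rx2(t), None
    return TestResult(
        "fisher_exact",
        stat,
        float(p),
        tuple(np.asarray(table).sum(axis=1)),
        details={"expected_min": float(expected.min()), "path": "fisher_exact"},
    )


def eta_squared(values: Sequence, labels: Sequence) -> float:
    """One-way eta-squared: fraction of total variance explained by group."""
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if len(v) != len(lab) or len(v) < 2:
        raise ValueError("need matching values/labels with at least 2 observations")
    if len(np.unique(lab)) < 2:
        raise ValueError("need at least 2 groups")
    grand = v.mean()
    ss_total = float(((v - grand) ** 2).sum())
    if ss_total == 0:
        raise ValueError("zero total variance; eta-squared undefined")
    ss_between = float(
        sum(len(v[lab == g]) * (v[lab == g].mean() - grand) ** 2 for g in np.unique(lab))
    )
    return ss_between / ss_total


@dataclass
class SalvageRate:
    rate: float  # percent, one decimal
    rate_rounded: int
    n_revised: int
    n_failed: int


def salvage_rate(flaps: pd.DataFrame) -> SalvageRate:
    """Fraction of re-explored flaps that survived, as a percentage."""
    revised = flaps[flaps.group == "R_plus"]
    n_rev = len(revised)
    if n_rev == 0:
        raise ValueError("no revised flaps; salvage rate undefined")
    n_fail = int(revised.failed.sum())
    rate = 100.0 * (n_rev - n_fail) / n_rev
    return SalvageRate(round(rate, 1), round(rate), n_rev, n_fail)


def summarize_by_timepoint(cohort: Cohort, deltas: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Long-format per-group summaries for every parameter, metric and timepoint."""
    from .hsi import compute_deltas
    from .records import HSI_PARAMETERS

    if deltas is None:
        deltas = compute_deltas(cohort.hsi)
    rows = []
    for parameter in HSI_PARAMETERS:
        for metric in METRIC_SUFFIX:
            for timepoint in ("overall",) + POSTOP_INTERVALS:
                cell = summarize(cohort, parameter, metric, timepoint, deltas=deltas)
                for group, r in cell.iterrows():
                    rows.append(
                        {"parameter": parameter, "metric": metric, "timepoint": timepoint,
                         "group": group, **r.to_dict()}
                    )
    return pd.DataFrame(rows)


def cohort_tests(cohort: Cohort, deltas: Optional[pd.DataFrame] = None,
                 detections: Optional[pd.DataFrame] = None) -> dict:
    """The cohort's main hypothesis tests as a JSON-serialisable mapping."""
    from .hsi import compute_deltas

    if deltas is None:
        deltas = compute_deltas(cohort.hsi)
    groups = cohort.flaps.set_index("flap_id")["group"]
    postop = deltas[deltas.timestamp > 0].assign(group=deltas.flap_id.map(groups))
    out: dict[str, dict] = {}
    for name, column in (("sto2", "sto2"), ("sto2_dref", "sto2_dref"),
                         ("npi", "npi"), ("npi_dref", "npi_dref")):
        a = postop.loc[postop.group == "R_minus", column].dropna()
        b = postop.loc[postop.group == "R_plus", column].dropna()
        if len(a) >= 3 and len(b) >= 3:
            r = compare_groups(a, b)
            out[f"group_difference_{name}"] = {
                "test": r.test_name, "statistic": r.statistic, "p_value": r.p_value,
                "n": list(r.n),
            }
    if detections is not None:
        paired = detections.dropna(subset=["clinical_time", "hsi_time"])
        lead = (paired.clinical_time - paired.hsi_time).to_numpy()
        if len(lead) and np.any(lead != 0):
            r = paired_compare(lead)
            out["paired_detection_times"] = {
                "test": r.test_name, "statistic": r.statistic, "p_value": r.p_value,
                "n": list(r.n),
            }
    eta = eta_squared(cohort.flaps.surgery_duration, cohort.flaps.group)
    out["surgery_duration_vs_revision"] = {"test": "eta_squared", "eta_squared": eta}
    out["note"] = "no multiple-testing correction applied"
    return out


# ---------------------------------------------------------------------------
# plain-text cohort report


def build_report(cohort: Cohort, detections: Optional[pd.DataFrame] = None) -> str:
    """Render a plain-text cohort report mirroring the baseline-table layout."""
    from .hsi import compare_detection, compute_deltas

    flaps = cohort.flaps
    lines = ["# Cohort report", ""]
    lines.append("NOTE: no multiple-testing correction is applied to any p-value below.")
    lines.append("")
    lines.append("## Baseline")
    lines.append(f"{'':24s}{'no revision':>12s}{'revision':>12s}{'total':>8s}")
    g1 = flaps[flaps.group == "R_minus"]
    g2 = flaps[flaps.group == "R_plus"]
    lines.append(f"{'N':24s}{len(g1):>12d}{len(g2):>12d}{len(flaps):>8d}")
    for col, title in (("flap_type", "Flap types"), ("regime", "Reconstruction regime")):
        lines.append(title)
        for level in flaps[col].unique():
            a = int((g1[col] == level).sum())
            b = int((g2[col] == level).sum())
            lines.append(f"  {level:22s}{a:>12d}{b:>12d}{a + b:>8d}")
    lines.append("Cause for malperfusion")
    for level, count in g2.cause.value_counts().items():
        lines.append(f"  {level:22s}{'':>12s}{int(count):>12d}{int(count):>8d}")
    try:
        sr = salvage_rate(flaps)
        lines.append(
            f"Complete failures: {sr.n_failed}/{sr.n_revised} revised "
            f"-> salvage rate {sr.rate:.1f}% (~{sr.rate_rounded}%)"
        )
    except ValueError:
        lines.append("No revised flaps; salvage rate undefined.")
    lines.append("")
    lines.append("## Postoperative HSI summaries (t4-t10, per measurement)")
    deltas = compute_deltas(cohort.hsi)
    for parameter, metric in (
        ("sto2", "raw"),
        ("sto2", "delta_reference"),
        ("npi", "raw"),
        ("npi", "delta_reference"),
    ):
        s = summarize(cohort, parameter, metric, "overall", deltas=deltas)
        label = parameter.upper() + ("" if metric == "raw" else " drop to reference (%)")
        lines.append(label)
        for group, row in s.iterrows():
            lines.append(
                f"  {group:8s} n={int(row['n']):4d}  mean={row['mean']:7.2f}  "
                f"sd={row['sd']:6.2f}  sem={row['sem']:5.2f}"
            )
    if detections is not None:
        lines.append("")
        lines.append("## Detection comparison (clinical vs HSI)")
        try:
            cmp = compare_detection(detections)
            p = "n/a (all differences zero)" if cmp.wilcoxon_p is None else f"{cmp.wilcoxon_p:.2e}"
            lines.append(
                f"  paired flaps: {cmp.n_paired}\n"
                f"  clinical: {cmp.clinical_mean:.1f} +/- {cmp.clinical_sd:.1f} h\n"
                f"  HSI:      {cmp.hsi_mean:.1f} +/- {cmp.hsi_sd:.1f} h\n"
                f"  lead:     {cmp.lead_mean:.1f} +/- {cmp.lead_sd:.1f} h "
                f"(Wilcoxon signed-rank p = {p})"
            )
        except ValueError as exc:
            lines.append(f"  not available: {exc}")
    return "\n".join(lines) + "\n"
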