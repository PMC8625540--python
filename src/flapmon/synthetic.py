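"""Seeded synthetic cohorts of monitored free flaps.

The generator emulates the study population this package models: 65 (or
any requested number of) head-and-neck free flaps with intraoperative HSI
measurements (t0-t3), one paired HSI + bedside monitoring event per
12-hour postoperative interval (t4-t10), reference-site values, and — for
flaps that develop a perfusion compromise — ground-truth clinical and HSI
detection times with a configurable lead-time law.

Construction principles
-----------------------

* **Detection times.**  The lead time (clinical minus HSI detection) is
  drawn from its configured law; the HSI crossing time is drawn from a
  gamma law derived by moment subtraction from the clinical-detection law
  (mean difference, variance difference), and the clinical time is their
  sum.  This keeps the means and sds of all three quantities at their
  configured values exactly while guaranteeing a strictly postoperative
  crossing; rejection of invalid pairs would bias all three means.

* **Shared latent severity.**  Per measurement, the four
  detection-relevant quantities (StO2, its drop rate, NPI, its drop rate)
  are affine in one latent standard-normal severity z, so "no criterion
  fires" and "at least one criterion fires" are single truncations of z.
  Never-crossing flaps draw z from a truncated normal recentred by its
  conditional mean, making group means exact while the support stays clear
  of every threshold.  Compromised flaps use one-sided truncations before
  and at the crossing; the conditional-mean offsets these introduce are
  cancelled by giving the unconstrained post-crossing draws a computed
  compensating mean, per (group, timepoint) context.

* **Reference sites.**  The published flap-side means and drop-rate means
  jointly determine the reference level (value / (1 + drop/100)); the
  generator therefore derives the reference from the sampled pair, which
  lands StO2 references around the low end of the physiological 50-70%
  band rather than drawing them independently.

* **Truncation.**  After the re-exploration decision no further monitoring
  rows are emitted.  The decision event itself is recorded (bedside check
  plus a final HSI measurement), so an interval can hold two events when
  crossing and decision fall into the same 12-hour window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .config import DistributionSpec, GeneratorConfig
from .hsi import DEFAULT_THRESHOLDS, Thresholds
from .records import (
    CLINICAL_COLUMNS,
    Cohort,
    FLAP_COLUMNS,
    HSI_COLUMNS,
)
from .table2 import FAILURES_BY_CAUSE, MARGINS, fixture_table2
from .timegrid import (
    INTERVAL_BOUNDS,
    INTRAOP_POINTS,
    POSTOP_INTERVALS,
    interval_label,
)

_CONGESTIVE_CAUSES = ("venous_thrombosis", "haematoma", "kinking")

# ---------------------------------------------------------------------------
# latent-severity machinery


def _mills(t: float) -> float:
    """E[z | z > t] for standard normal z (asymptotic form far in the tail)."""
    if t > 8.0:
        return t + 1.0 / t
    return float(norm.pdf(t) / norm.sf(t))


@dataclass(frozen=True)
class _Context:
    """Calibration of the four criterion quantities at one (group, timepoint)."""

    means: tuple[float, float, float, float]  # sto2, sto2_dref, npi, npi_dref
    sds: tuple[float, float, float, float]
    zstar: float  # max standardized threshold: z <= zstar  <=>  some criterion fires
    safe_lower: Optional[float]  # truncation point of the mean-exact no-fire draw
    safe_shift: Optional[float]  # conditional mean removed from that draw
    mu_up: float  # E[z | z > zstar]
    mu_lo: float  # E[z | z <= zstar]


class _LatentSampler:
    def __init__(self, config: GeneratorConfig, thresholds: Thresholds):
        self._config = config
        self._thresholds = (
            thresholds.sto2_max,
            thresholds.sto2_dref_max,
            thresholds.npi_max,
            thresholds.npi_dref_max,
        )
        self._cache: dict[tuple[str, str], _Context] = {}

    def context(self, group: str, timepoint: str) -> _Context:
        key = (group, timepoint)
        if key in self._cache:
            return self._cache[key]
        cal = self._config.calibration
        quantities = ("sto2", "sto2_dref", "npi", "npi_dref")
        means, sds = [], []
        for q in quantities:
            m, s = cal.lookup(group, q, timepoint)
            if s <= 0:
                raise ValueError(
                    f"calibration sd for ({group}, {q}) must be positive for simulation"
                )
            means.append(m)
            sds.append(s)
        zstar = max((t - m) / s for t, m, s in zip(self._thresholds, means, sds))
        safe_lower = safe_shift = None
        if group == "R_minus":
            if zstar >= -0.01:
                raise ValueError(
                    "non-revised calibration sits on or below the detection "
                    f"thresholds (standardized margin {zstar:.3f}); no "
                    "never-crossing trajectory exists at these settings"
                )
            hi = max(8.0, -2.0 / zstar)
            safe_lower = brentq(lambda t: t - _mills(t) - zstar, 2 * zstar - 10.0, hi)
            safe_shift = _mills(safe_lower)
        mu_up = _mills(zstar)
        mu_lo = -float(norm.pdf(zstar) / norm.cdf(zstar))
        ctx = _Context(tuple(means), tuple(sds), zstar, safe_lower, safe_shift, mu_up, mu_lo)
        self._cache[key] = ctx
        return ctx

    @staticmethod
    def draw_z(ctx: _Context, mode: str, rng: np.random.Generator, offset: float = 0.0) -> float:
        u = rng.uniform()
        if mode == "safe":
            p = ndtr(ctx.safe_lower)
            return float(ndtri(p + u * (1.0 - p)) - ctx.safe_shift)
        if mode == "nofire":
            p = ndtr(ctx.zstar)
            return float(ndtri(p + u * (1.0 - p)))
        if mode == "fire":
            p = ndtr(ctx.zstar)
            return float(ndtri(u * p))
        if mode == "free":
            return float(rng.normal() + offset)
        raise ValueError(f"unknown draw mode {mode!r}")


def _draw_criteria_values(
    sampler: _LatentSampler,
    ctx: _Context,
    mode: str,
    rng: np.random.Generator,
    offset: float = 0.0,
) -> dict[str, float]:
    """Sample (sto2, sto2_dref, npi, npi_dref) plus derived reference values.

    Redraws (not clips) until flap values land in [0, 100], drops stay
    above -95% and the derived references are usable; the truncation mode
    is preserved on every attempt.
    """
    for _ in range(1000):
        z = sampler.draw_z(ctx, mode, rng, offset)
        sto2, sto2_dref, npi, npi_dref = (
            m + s * z for m, s in zip(ctx.means, ctx.sds)
        )
        if not (0.0 <= sto2 <= 100.0 and 0.0 <= npi <= 100.0):
            continue
        if sto2_dref <= -95.0 or npi_dref <= -95.0:
            continue
        ref_sto2 = sto2 / (1.0 + sto2_dref / 100.0)
        ref_npi = npi / (1.0 + npi_dref / 100.0)
        if not (0.5 <= ref_sto2 <= 100.0 and 0.5 <= ref_npi <= 100.0):
            continue
        return {
            "sto2": sto2,
            "npi": npi,
            "ref_sto2": ref_sto2,
            "ref_npi": ref_npi,
        }
    raise RuntimeError("could not draw in-range parameter values (calibration implausible)")


def _draw_bounded(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Truncated-normal redraw within the 0-100 parameter scale."""
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if 0.0 <= v <= 100.0:
            return float(v)
    raise RuntimeError(f"could not draw a bounded value around {mean}")


def _gamma(rng: np.random.Generator, law: DistributionSpec) -> float:
    return float(max(rng.gamma(law.shape, law.scale), 1e-6))


# ---------------------------------------------------------------------------
# trajectory plans


@dataclass
class TrajectoryPlan:
    """Per-flap simulation plan: event schedule and per-phase parameter anchors."""

    flap_id: str
    group: str
    cause: str
    intraop_events: list  # (timestamp, label)
    postop_events: list  # (timestamp, label, mode)
    crossing_time: Optional[float] = None
    clinical_time: Optional[float] = None
    #: phase ("intraop"/"postop") -> quantity -> mean anchor
    anchors: dict = field(default_factory=dict)


def assign_scenario(flap, config: GeneratorConfig, rng: np.random.Generator) -> TrajectoryPlan:
    """Build the measurement schedule and parameter anchors for one flap.

    ``flap`` is a row (mapping) with at least ``flap_id``, ``group``,
    ``cause``, ``surgery_duration`` and, for compromised flaps, the two
    detection times.  Intraoperative anchors use the non-revised
    calibration for both groups (no pre-inset group differences);
    postoperative anchors of compromised flaps use the revised-group
    calibration, with a THI elevation for congestive causes (venous
    thrombosis, haematoma, kinking) and a THI depression for arterial
    inflow failure.
    """
    duration_h = float(flap["surgery_duration"]) / 60.0
    intraop = [
        (-duration_h, "t0"),
        (-0.55 * duration_h, "t1"),
        (-0.15 * duration_h, "t2"),
        (0.0, "t3"),
    ]
    cal = config.calibration
    group = flap["group"]
    postop: list[tuple[float, str, str]] = []

    def uniform_in(label: str) -> float:
        lo, hi = INTERVAL_BOUNDS[label]
        hi = min(hi, lo + 12.0)
        return float(lo + rng.uniform() * (hi - lo))

    if group == "R_minus":
        for label in POSTOP_INTERVALS:
            postop.append((uniform_in(label), label, "safe"))
        crossing = clinical = None
    else:
        crossing = float(flap["hsi_crossing_time"])
        clinical = float(flap["clinical_detection_time"])
        label_h = interval_label(crossing)
        label_c = interval_label(clinical)
        i_h = POSTOP_INTERVALS.index(label_h)
        i_c = POSTOP_INTERVALS.index(label_c)
        for i, label in enumerate(POSTOP_INTERVALS):
            if i < i_h:
                postop.append((uniform_in(label), label, "nofire"))
            elif i == i_h:
                postop.append((crossing, label, "fire"))
            elif i < i_c:
                postop.append((uniform_in(label), label, "free"))
            elif i == i_c:
                postop.append((clinical, label, "free"))
            else:
                break
        if i_c == i_h:
            postop.append((clinical, label_c, "free"))

    thi_shift = 0.0
    if group == "R_plus":
        thi_shift = (
            config.thi_congestion_shift
            if flap["cause"] in _CONGESTIVE_CAUSES
            else config.thi_arterial_shift
        )
    anchors = {
        "intraop": {
            q: cal.lookup("R_minus", q, "overall")[0] for q in ("sto2", "npi", "thi", "twi")
        },
        "postop": {
            "sto2": cal.lookup(group, "sto2", "overall")[0],
            "npi": cal.lookup(group, "npi", "overall")[0],
            "thi": cal.lookup(group, "thi", "overall")[0] + thi_shift,
            "twi": cal.lookup(group, "twi", "overall")[0],
        },
    }
    return TrajectoryPlan(
        flap_id=flap["flap_id"],
        group=group,
        cause=flap["cause"],
        intraop_events=intraop,
        postop_events=postop,
        crossing_time=crossing,
        clinical_time=clinical,
        anchors=anchors,
    )


# ---------------------------------------------------------------------------
# metadata sampling


def _truncated_duration(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if 120.0 <= v <= 1200.0:
            return float(round(v))
    raise RuntimeError("implausible surgery-duration law")


def _sample_metadata(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    if config.replicate_table2:
        flaps = fixture_table2().copy()
        flaps["surgery_duration"] = [
            _truncated_duration(
                rng,
                MARGINS["surgery_duration_mean"][g],
                MARGINS["surgery_duration_sd"][g],
            )
            for g in flaps.group
        ]
        return flaps

    n_total = {"R_minus": 46, "R_plus": 19}
    p_plus = n_total["R_plus"] / 65.0
    type_levels = list(MARGINS["flap_type"])
    cause_levels = list(MARGINS["cause"])
    cause_p = np.array([MARGINS["cause"][c] for c in cause_levels], dtype=float)
    cause_p /= cause_p.sum()
    fail_p = {c: FAILURES_BY_CAUSE[c] / MARGINS["cause"][c] for c in cause_levels}
    rows = []
    for i in range(config.n_flaps):
        group = "R_plus" if rng.uniform() < p_plus else "R_minus"
        gi = 0 if group == "R_minus" else 1
        n_g = n_total[group]
        type_p = np.array([MARGINS["flap_type"][t][gi] for t in type_levels], dtype=float) / n_g
        regime_p = np.array([MARGINS["regime"][r][gi] for r in ("primary", "secondary")]) / n_g
        artery_levels = list(MARGINS["recipient_artery"])
        artery_p = (
            np.array([MARGINS["recipient_artery"][a][gi] for a in artery_levels], dtype=float)
            / n_g
        )
        if group == "R_plus":
            cause = str(rng.choice(cause_levels, p=cause_p))
            failed = bool(rng.uniform() < fail_p[cause])
        else:
            cause, failed = "none", False
        rows.append(
            {
                "flap_id": f"F{i + 1:03d}",
                "flap_type": str(rng.choice(type_levels, p=type_p)),
                "regime": str(rng.choice(["primary", "secondary"], p=regime_p)),
                "irradiated": bool(rng.uniform() < MARGINS["irradiated"][gi] / n_g),
                "recipient_artery": str(rng.choice(artery_levels, p=artery_p)),
                "surgery_duration": _truncated_duration(
                    rng,
                    MARGINS["surgery_duration_mean"][group],
                    MARGINS["surgery_duration_sd"][group],
                ),
                "group": group,
                "cause": cause,
                "failed": failed,
                "clinical_detection_time": np.nan,
                "hsi_crossing_time": np.nan,
            }
        )
    return pd.DataFrame(rows, columns=FLAP_COLUMNS)


# ---------------------------------------------------------------------------
# clinical sign sampling

_BENIGN = {
    "color": (("pink", "red"), (0.8, 0.2)),
    "temperature": (("body",), (1.0,)),
    "recap": (("gt_2s", "approx_1s"), (0.7, 0.3)),
    "turgor": (("elastic", "plump"), (0.8, 0.2)),
}

#: pathological sign profiles by cause; every profile satisfies the
#: re-exploration rule (total >= 9 and/or two 3-point signs)
_PATHOLOGICAL = {
    "venous_thrombosis": {"color": "blue", "recap": "lt_1s", "turgor": "plump"},
    "haematoma": {"color": "blue", "recap": "lt_1s", "turgor": "plump"},
    "kinking": {"color": "blue", "recap": "none", "turgor": "elastic"},
    "arterial_thrombosis": {"color": "pale_white", "recap": "none", "turgor": "soft"},
}


def _benign_observation(rng: np.random.Generator) -> dict:
    obs = {
        key: str(rng.choice(levels, p=probs)) for key, (levels, probs) in _BENIGN.items()
    }
    obs["abnormal_color_duration"] = 0.0
    return obs


def _pathological_observation(cause: str, rng: np.random.Generator) -> dict:
    profile = dict(_PATHOLOGICAL[cause])
    profile["temperature"] = str(rng.choice(("cold", "body"), p=(0.7, 0.3)))
    profile["abnormal_color_duration"] = float(round(65.0 + 115.0 * rng.uniform(), 1))
    return profile


# ---------------------------------------------------------------------------
# main entry points


def simulate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a cohort of flap records, HSI series and bedside observations.

    Deterministic for a fixed config (the seed lives on the config).  With
    ``replicate_table2`` the flap-type x revision margins of the packaged
    baseline table are reproduced exactly; otherwise attributes are sampled
    from the corresponding conditional proportions.
    """
    rng = np.random.default_rng(config.seed)
    flaps = _sample_metadata(config, rng)

    lead_law = config.lead_time_law
    clin_law = config.clinical_detection_law
    crossing_law = DistributionSpec(
        mean=clin_law.mean - lead_law.mean,
        sd=float(np.sqrt(clin_law.sd**2 - lead_law.sd**2)),
    )
    for idx in flaps.index[flaps.group == "R_plus"]:
        crossing = _gamma(rng, crossing_law)
        lead = _gamma(rng, lead_law)
        flaps.loc[idx, "hsi_crossing_time"] = crossing
        flaps.loc[idx, "clinical_detection_time"] = crossing + lead

    plans = [assign_scenario(row, config, rng) for _, row in flaps.iterrows()]

    # compensation offsets: cancel the conditional-mean bias of constrained
    # revised-group draws with the unconstrained post-crossing draws
    sampler = _LatentSampler(config, DEFAULT_THRESHOLDS)
    bucket_sum: dict[str, float] = {}
    bucket_free: dict[str, int] = {}
    for plan in plans:
        if plan.group != "R_plus":
            continue
        for _, label, mode in plan.postop_events:
            ctx = sampler.context("R_plus", label)
            if mode == "nofire":
                bucket_sum[label] = bucket_sum.get(label, 0.0) + ctx.mu_up
            elif mode == "fire":
                bucket_sum[label] = bucket_sum.get(label, 0.0) + ctx.mu_lo
            elif mode == "free":
                bucket_free[label] = bucket_free.get(label, 0) + 1
    offsets: dict[str, float] = {}
    residual = 0.0
    for label, s in bucket_sum.items():
        if bucket_free.get(label, 0) > 0:
            offsets[label] = -s / bucket_free[label]
        else:
            residual += s
    total_free = sum(bucket_free.values())
    extra = -residual / total_free if total_free else 0.0

    cal = config.calibration
    hsi_rows: list[dict] = []
    clinical_rows: list[dict] = []
    for plan in plans:
        cause_shift = 0.0
        if plan.group == "R_plus":
            cause_shift = (
                config.thi_congestion_shift
                if plan.cause in _CONGESTIVE_CAUSES
                else config.thi_arterial_shift
            )
        for ts, label in plan.intraop_events:
            ctx = sampler.context("R_minus", label)
            vals = _draw_criteria_values(sampler, ctx, "free", rng)
            hsi_rows.append(_hsi_row(plan.flap_id, ts, label, vals, cal, "R_minus", 0.0, rng))
        for ts, label, mode in plan.postop_events:
            group_cal = "R_minus" if plan.group == "R_minus" else "R_plus"
            ctx = sampler.context(group_cal, label)
            offset = offsets.get(label, 0.0) + extra if mode == "free" else 0.0
            vals = _draw_criteria_values(sampler, ctx, mode, rng, offset)
            hsi_rows.append(
                _hsi_row(plan.flap_id, ts, label, vals, cal, group_cal, cause_shift, rng)
            )
            if plan.group == "R_plus" and plan.clinical_time is not None and ts == plan.clinical_time:
                obs = _pathological_observation(plan.cause, rng)
            else:
                obs = _benign_observation(rng)
            obs.update({"flap_id": plan.flap_id, "timestamp": ts})
            clinical_rows.append(obs)

    hsi = pd.DataFrame(hsi_rows, columns=HSI_COLUMNS)
    clinical = pd.DataFrame(clinical_rows, columns=CLINICAL_COLUMNS)
    # the bedside decision event can duplicate the crossing event's interval;
    # keep one clinical row per timestamp
    clinical = clinical.drop_duplicates(subset=["flap_id", "timestamp"], keep="last").reset_index(
        drop=True
    )
    return Cohort(flaps=flaps, hsi=hsi, clinical=clinical)


def _hsi_row(
    flap_id: str,
    ts: float,
    label: str,
    vals: dict,
    cal,
    group_cal: str,
    thi_shift: float,
    rng: np.random.Generator,
) -> dict:
    thi_mean, thi_sd = cal.lookup(group_cal, "thi", label)
    twi_mean, twi_sd = cal.lookup(group_cal, "twi", label)
    rthi_mean, rthi_sd = cal.lookup(group_cal, "ref_thi", label)
    rtwi_mean, rtwi_sd = cal.lookup(group_cal, "ref_twi", label)
    shift = thi_shift if ts > 0 else 0.0
    return {
        "flap_id": flap_id,
        "timestamp": ts,
        "timepoint": label,
        "sto2": vals["sto2"],
        "npi": vals["npi"],
        "thi": _draw_bounded(rng, min(max(thi_mean + shift, 0.0), 100.0), thi_sd),
        "twi": _draw_bounded(rng, twi_mean, twi_sd),
        "ref_sto2": vals["ref_sto2"],
        "ref_npi": vals["ref_npi"],
        "ref_thi": _draw_bounded(rng, rthi_mean, rthi_sd),
        "ref_twi": _draw_bounded(rng, rtwi_mean, rtwi_sd),
    }


def filter_monitoring_complete(cohort: Cohort) -> Cohort:
    """Keep only flaps with complete regular monitoring.

    Complete means HSI coverage of t0-t10 and bedside coverage of t4-t10,
    where intervals lying entirely beyond a flap's re-exploration decision
    count as covered by truncation.  Flap order is preserved.
    """
    keep = []
    hsi_tp = cohort.hsi.groupby("flap_id")["timepoint"].agg(set)
    clin_iv = cohort.clinical[cohort.clinical.timestamp > 0].groupby("flap_id")["timestamp"].agg(
        lambda ts: {interval_label(t) for t in ts}
    )
    for _, flap in cohort.flaps.iterrows():
        trunc = flap["clinical_detection_time"]
        trunc = np.inf if pd.isna(trunc) else float(trunc)
        required_post = [
            label for label in POSTOP_INTERVALS if INTERVAL_BOUNDS[label][0] < trunc
        ]
        have_hsi = hsi_tp.get(flap["flap_id"], set())
        have_clin = clin_iv.get(flap["flap_id"], set())
        if not set(INTRAOP_POINTS).issubset(have_hsi):
            continue
        if not set(required_post).issubset(have_hsi):
            continue
        if not set(required_post).issubset(have_clin):
            continue
        keep.append(flap["flap_id"])
    return cohort.subset(keep)
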