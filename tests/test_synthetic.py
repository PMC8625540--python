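"""Synthetic cohort generator: determinism, margins, anchoring, bounds."""

import numpy as np
import pandas as pd
import pydantic
import pytest

import flapmon as fm
from flapmon.records import Cohort
from flapmon.synthetic import assign_scenario, filter_monitoring_complete, simulate_cohort
from flapmon.table2 import MARGINS
from flapmon.timegrid import INTERVAL_BOUNDS, INTRAOP_POINTS, POSTOP_INTERVALS

VALUE_COLUMNS = ["sto2", "npi", "thi", "twi", "ref_sto2", "ref_npi", "ref_thi", "ref_twi"]


def test_identical_config_identical_cohort(cohort65):
    again = simulate_cohort(fm.default_generator_config(seed=7))
    assert cohort65.equals(again)


def test_different_seed_different_cohort(cohort65):
    other = simulate_cohort(fm.default_generator_config(seed=8))
    assert not cohort65.hsi.equals(other.hsi)


class TestMargins:
    def test_group_and_type_margins(self, cohort65):
        f = cohort65.flaps
        assert len(f) == 65
        assert (f.group == "R_plus").sum() == 19
        rff = f[f.flap_type == "RFF"]
        assert len(rff) == 24 and (rff.group == "R_plus").sum() == 8
        for flap_type, (n_minus, n_plus) in MARGINS["flap_type"].items():
            sub = f[f.flap_type == flap_type]
            assert (len(sub), (sub.group == "R_plus").sum()) == (n_minus + n_plus, n_plus)

    def test_cause_regime_artery_margins(self, cohort65):
        f = cohort65.flaps
        revised = f[f.group == "R_plus"]
        assert revised.cause.value_counts().to_dict() == MARGINS["cause"]
        assert int(revised.failed.sum()) == MARGINS["failed"]
        for regime, (a, b) in MARGINS["regime"].items():
            assert (f.regime == regime).sum() == a + b
        for artery, (a, b) in MARGINS["recipient_artery"].items():
            assert (f.recipient_artery == artery).sum() == a + b

    def test_multinomial_mode_varies_margins(self):
        c = simulate_cohort(
            fm.GeneratorConfig(
                n_flaps=10, seed=1, replicate_table2=False,
                calibration=fm.default_calibration(),
            )
        )
        assert c.n_flaps == 10


class TestConfigValidation:
    def test_nonpositive_n_rejected(self):
        with pytest.raises(pydantic.ValidationError):
            fm.GeneratorConfig(n_flaps=0, calibration=fm.default_calibration())

    def test_bounded_mean_outside_scale_rejected(self):
        with pytest.raises(pydantic.ValidationError):
            fm.CalibrationEntry(group="R_minus", quantity="sto2", mean=120.0, sd=5.0)

    def test_replicate_requires_65(self):
        with pytest.raises(pydantic.ValidationError):
            fm.GeneratorConfig(
                n_flaps=50, replicate_table2=True, calibration=fm.default_calibration()
            )

    def test_incompatible_time_laws_rejected(self):
        with pytest.raises(pydantic.ValidationError):
            fm.GeneratorConfig(
                n_flaps=65, calibration=fm.default_calibration(),
                lead_time_law=fm.DistributionSpec(mean=30.0, sd=5.0),
            )


class TestTrajectories:
    def test_values_within_scale_without_clipping_artifacts(self, cohort500):
        values = cohort500.hsi[VALUE_COLUMNS]
        assert (values.to_numpy() >= 0).all() and (values.to_numpy() <= 100).all()
        # redraw-based truncation leaves no mass piled at the bounds
        assert not np.isin(values.to_numpy(), (0.0, 100.0)).any()

    def test_reference_values_strictly_positive(self, cohort500):
        refs = cohort500.hsi[["ref_sto2", "ref_npi", "ref_thi", "ref_twi"]]
        assert (refs.to_numpy() > 0).all()

    def test_reference_sto2_near_physiological_band(self, cohort500):
        ref = cohort500.hsi.ref_sto2
        assert 45.0 < ref.mean() < 70.0

    def test_timepoint_coverage(self, cohort65):
        flaps = cohort65.flaps.set_index("flap_id")
        for flap_id, rows in cohort65.hsi.groupby("flap_id"):
            tps = set(rows.timepoint)
            assert set(INTRAOP_POINTS) <= tps
            trunc = flaps.loc[flap_id, "clinical_detection_time"]
            trunc = np.inf if pd.isna(trunc) else float(trunc)
            expected = {tp for tp in POSTOP_INTERVALS if INTERVAL_BOUNDS[tp][0] < trunc}
            assert expected <= tps
            # no monitoring rows after the re-exploration decision
            assert (rows.timestamp <= trunc).all()

    def test_timestamps_match_interval_labels(self, cohort65):
        postop = cohort65.hsi[cohort65.hsi.timestamp > 0]
        for tp, (lo, hi) in INTERVAL_BOUNDS.items():
            ts = postop.loc[postop.timepoint == tp, "timestamp"]
            assert ((ts > lo) & (ts <= min(hi, lo + 12.0 if tp != "t10" else np.inf))).all()

    def test_lead_times_recover_configured_law(self, cohort500):
        revised = cohort500.flaps[cohort500.flaps.group == "R_plus"]
        lead = revised.clinical_detection_time - revised.hsi_crossing_time
        assert (lead > 0).all()
        sem = lead.std(ddof=1) / np.sqrt(len(lead))
        assert abs(lead.mean() - 4.8) < 2 * sem


class TestAssignScenario:
    def _flap(self, group="R_minus", cause="none", tc=None, th=None):
        return {
            "flap_id": "F1", "group": group, "cause": cause, "surgery_duration": 480.0,
            "clinical_detection_time": tc, "hsi_crossing_time": th,
        }

    def test_control_flap_never_crosses(self):
        plan = assign_scenario(self._flap(), fm.default_generator_config(seed=1),
                               np.random.default_rng(0))
        assert plan.crossing_time is None
        assert {mode for _, _, mode in plan.postop_events} == {"safe"}
        assert len(plan.postop_events) == len(POSTOP_INTERVALS)

    def test_venous_cause_elevates_postop_thi_anchor(self):
        plan = assign_scenario(
            self._flap("R_plus", "venous_thrombosis", tc=20.0, th=15.0),
            fm.default_generator_config(seed=1), np.random.default_rng(0),
        )
        assert plan.anchors["postop"]["thi"] > plan.anchors["intraop"]["thi"]

    def test_arterial_cause_keeps_thi_low(self):
        plan = assign_scenario(
            self._flap("R_plus", "arterial_thrombosis", tc=20.0, th=15.0),
            fm.default_generator_config(seed=1), np.random.default_rng(0),
        )
        assert plan.anchors["postop"]["thi"] <= plan.anchors["intraop"]["thi"]

    def test_crossing_scheduled_exactly_at_configured_time(self):
        plan = assign_scenario(
            self._flap("R_plus", "arterial_thrombosis", tc=10.0, th=6.0),
            fm.default_generator_config(seed=1), np.random.default_rng(0),
        )
        fire = [(t, tp) for t, tp, mode in plan.postop_events if mode == "fire"]
        assert fire == [(6.0, "t4")]
        assert plan.postop_events[-1][0] == 10.0  # decision event closes the series


class TestMonitoringFilter:
    def test_flap_missing_intraop_point_removed(self, cohort65):
        hsi = cohort65.hsi
        pruned = Cohort(
            cohort65.flaps,
            hsi[~((hsi.flap_id == "F001") & (hsi.timepoint == "t2"))].reset_index(drop=True),
            cohort65.clinical,
        )
        kept = filter_monitoring_complete(pruned)
        assert kept.n_flaps == cohort65.n_flaps - 1
        assert "F001" not in set(kept.flaps.flap_id)

    def test_complete_cohort_unchanged(self, cohort65):
        kept = filter_monitoring_complete(cohort65)
        assert kept.n_flaps == cohort65.n_flaps
        assert list(kept.flaps.flap_id) == list(cohort65.flaps.flap_id)

    def test_empty_cohort(self, cohort65):
        empty = cohort65.subset([])
        assert filter_monitoring_complete(empty).n_flaps == 0

    def test_truncated_revised_flap_counts_as_complete(self, cohort65):
        revised = cohort65.flaps[cohort65.flaps.group == "R_plus"].iloc[0]
        kept = filter_monitoring_complete(cohort65)
        assert revised.flap_id in set(kept.flaps.flap_id)
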