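"""Delta metrics, threshold derivation and the four-criterion detection rule."""

import numpy as np
import pandas as pd
import pytest

import flapmon as fm
from flapmon.hsi import (
    DEFAULT_THRESHOLDS,
    Thresholds,
    compare_detection,
    compute_deltas,
    derive_thresholds,
    evaluate_criteria,
    hsi_detection_time,
)
from flapmon.records import Cohort, FLAP_COLUMNS


def hsi_frame(rows):
    cols = ["flap_id", "timestamp", "timepoint", "sto2", "npi", "thi", "twi",
            "ref_sto2", "ref_npi", "ref_thi", "ref_twi"]
    return pd.DataFrame(rows, columns=cols)


def measurement(flap_id="F", timestamp=3.0, timepoint="t4", sto2=43.2, npi=42.8,
                thi=50.0, twi=50.0, ref_sto2=52.88, ref_npi=40.0, ref_thi=50.0, ref_twi=50.0):
    return (flap_id, timestamp, timepoint, sto2, npi, thi, twi, ref_sto2, ref_npi,
            ref_thi, ref_twi)


class TestComputeDeltas:
    def test_drop_to_reference(self):
        out = compute_deltas(hsi_frame([measurement()]))
        # (43.2 - 52.88) / 52.88 * 100: a typical non-revised flap sits ~18% below
        # its reference site
        assert out.sto2_dref.iloc[0] == pytest.approx(-18.3055, abs=1e-3)

    def test_identity_and_boundary(self):
        out = compute_deltas(
            hsi_frame([measurement(sto2=50.0, ref_sto2=50.0, npi=0.0, ref_npi=50.0)])
        )
        assert out.sto2_dref.iloc[0] == 0.0
        assert out.npi_dref.iloc[0] == -100.0

    def test_zero_anchor_gives_absent_delta(self):
        out = compute_deltas(hsi_frame([measurement(ref_sto2=0.0)]))
        assert np.isnan(out.sto2_dref.iloc[0])

    def test_t3_and_previous_anchors(self):
        rows = [
            measurement(timestamp=-8.0, timepoint="t0", sto2=60.0),
            measurement(timestamp=0.0, timepoint="t3", sto2=50.0),
            measurement(timestamp=5.0, timepoint="t4", sto2=40.0),
            measurement(timestamp=15.0, timepoint="t5", sto2=30.0),
        ]
        out = compute_deltas(hsi_frame(rows)).set_index("timepoint")
        assert out.loc["t3", "sto2_dt3"] == 0.0
        assert out.loc["t4", "sto2_dt3"] == pytest.approx(-20.0)
        # first postoperative measurement anchors its pre-value delta on t3
        assert out.loc["t4", "sto2_dpre"] == pytest.approx(-20.0)
        assert out.loc["t5", "sto2_dpre"] == pytest.approx(-25.0)
        assert np.isnan(out.loc["t0", "sto2_dpre"])


class TestCriteria:
    def test_low_sto2_fires_alone(self):
        hit, fired = evaluate_criteria(31.9, -10.0, 40.0, 0.0)
        assert hit and fired == {"sto2"}

    def test_nominal_values_clear(self):
        hit, fired = evaluate_criteria(45.0, -10.0, 40.0, 0.0)
        assert not hit and fired == frozenset()

    def test_boundaries_inclusive(self):
        assert evaluate_criteria(45.0, -10.0, 40.0, -13.4)[1] == {"npi_dref"}
        assert evaluate_criteria(32.0, -10.0, 40.0, 0.0)[1] == {"sto2"}
        assert evaluate_criteria(45.0, -38.0, 40.0, 0.0)[1] == {"sto2_dref"}

    def test_absent_deltas_never_fire(self):
        hit, fired = evaluate_criteria(45.0, np.nan, 40.0, np.nan)
        assert not hit

    def test_strict_printed_signs_flag_typical_healthy_drop(self):
        # under the literally printed inequality a typical healthy drop rate
        # (~ -18%) counts as malperfusion; the default reading does not
        healthy = dict(sto2=45.0, sto2_dref=-18.3, npi=42.8, npi_dref=8.8)
        assert not evaluate_criteria(**healthy)[0]
        hit, fired = evaluate_criteria(**healthy, strict_printed_signs=True)
        assert hit and fired == {"sto2_dref", "npi_dref"}


def _tiny_cohort(group_values):
    """Cohort with one revised flap carrying the given postoperative StO2 values."""
    flap = {c: None for c in FLAP_COLUMNS}
    flap.update(
        flap_id="F1", flap_type="RFF", regime="primary", irradiated=False,
        recipient_artery="facial", surgery_duration=500.0, group="R_plus",
        cause="venous_thrombosis", failed=False,
        clinical_detection_time=40.0, hsi_crossing_time=30.0,
    )
    rows = [
        measurement("F1", float(5 + 12 * i), f"t{4 + i}", sto2=v, npi=v, ref_sto2=50.0,
                    ref_npi=50.0)
        for i, v in enumerate(group_values)
    ]
    return Cohort(pd.DataFrame([flap]), hsi_frame(rows), pd.DataFrame(
        columns=["flap_id", "timestamp", "color", "temperature", "recap", "turgor",
                 "abnormal_color_duration"]))


class TestDeriveThresholds:
    def test_toy_mean(self):
        th = derive_thresholds(_tiny_cohort([30.0, 34.0, 33.8]))
        assert th.sto2_max == pytest.approx(32.6)

    def test_single_measurement(self):
        th = derive_thresholds(_tiny_cohort([31.0]))
        assert th.sto2_max == pytest.approx(31.0)
        assert th.npi_max == pytest.approx(31.0)

    def test_rejects_cohort_without_revised_measurements(self):
        cohort = _tiny_cohort([30.0])
        cohort.flaps.loc[0, ["group", "cause", "clinical_detection_time",
                             "hsi_crossing_time"]] = ["R_minus", "none", None, None]
        with pytest.raises(ValueError):
            derive_thresholds(cohort)

    def test_recovers_calibration_on_synthetic_cohort(self, cohort500):
        # 500-flap cohort at default calibration: derived thresholds sit at the
        # revised-group means they were calibrated to
        th = derive_thresholds(cohort500)
        assert th.sto2_max == pytest.approx(32.6, abs=1.5)
        assert th.npi_max == pytest.approx(32.9, abs=2.0)


class TestDetectionTime:
    def _series(self, statuses):
        # map (time, fires?) to rows: firing rows get sto2 below threshold
        return compute_deltas(hsi_frame([
            measurement("F", t, "t4" if t <= 12 else "t5", sto2=20.0 if fire else 45.0,
                        ref_sto2=50.0, npi=50.0, ref_npi=50.0)
            for t, fire in statuses
        ]))

    def test_first_true_scan(self):
        assert hsi_detection_time(self._series([(5, False), (16, True), (28, True)]))[0] == 16.0

    def test_absent_when_never_firing(self):
        t, fired = hsi_detection_time(self._series([(5, False), (16, False)]))
        assert t is None and fired == frozenset()

    def test_intraoperative_rows_never_trigger(self):
        rows = [measurement("F", -5.0, "t1", sto2=10.0, ref_sto2=50.0),
                measurement("F", 5.0, "t4", sto2=45.0, ref_sto2=50.0, npi=50.0, ref_npi=50.0)]
        assert hsi_detection_time(compute_deltas(hsi_frame(rows)))[0] is None

    def test_matches_linear_scan_oracle(self):
        from conftest import first_true_time

        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = rng.integers(1, 9)
            times = np.sort(rng.uniform(0.5, 80, n))
            rows = [
                measurement("F", float(t), "t4", sto2=float(rng.uniform(20, 55)),
                            npi=float(rng.uniform(20, 55)),
                            ref_sto2=float(rng.uniform(40, 70)),
                            ref_npi=float(rng.uniform(30, 60)))
                for t in times
            ]
            deltas = compute_deltas(hsi_frame(rows))
            got, _ = hsi_detection_time(deltas)
            expected = first_true_time(
                (row.timestamp, evaluate_criteria(row.sto2, row.sto2_dref, row.npi,
                                                  row.npi_dref)[0])
                for row in deltas.itertuples()
            )
            assert got == expected

    def test_detection_antitone_in_thresholds(self):
        """Relaxing any threshold (easier firing) never delays detection."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            rows = [
                measurement("F", float(t), "t4", sto2=float(rng.uniform(25, 50)),
                            npi=float(rng.uniform(25, 50)),
                            ref_sto2=float(rng.uniform(40, 70)),
                            ref_npi=float(rng.uniform(30, 60)))
                for t in np.sort(rng.uniform(0.5, 60, 6))
            ]
            deltas = compute_deltas(hsi_frame(rows))
            tight = Thresholds(30.0, -40.0, 30.0, -20.0)
            loose = Thresholds(34.0, -35.0, 34.0, -10.0)
            t_tight, _ = hsi_detection_time(deltas, tight)
            t_loose, _ = hsi_detection_time(deltas, loose)
            assert (t_loose or np.inf) <= (t_tight or np.inf)


class TestCompareDetection:
    def _detections(self, pairs):
        return pd.DataFrame(
            [{"flap_id": f"F{i}", "clinical_time": c, "hsi_time": h,
              "lead_time": c - h, "fired": "sto2"} for i, (c, h) in enumerate(pairs)]
        )

    def test_paired_means(self):
        cmp = compare_detection(self._detections([(10.0, 6.0), (20.0, 18.0)]))
        assert cmp.clinical_mean == 15.0
        assert cmp.hsi_mean == 12.0
        assert cmp.lead_mean == 3.0

    def test_identical_times_degenerate(self):
        cmp = compare_detection(self._detections([(10.0, 10.0), (20.0, 20.0)]))
        assert cmp.lead_mean == 0.0
        assert cmp.wilcoxon_p is None

    def test_rejects_empty_paired_set(self):
        det = self._detections([(10.0, 6.0)])
        det.loc[0, "hsi_time"] = np.nan
        with pytest.raises(ValueError):
            compare_detection(det)


def test_generator_anchoring(cohort65, detections65):
    """Detection applied to generated series recovers the planned times exactly."""
    merged = cohort65.flaps.merge(detections65, on="flap_id")
    revised = merged[merged.group == "R_plus"]
    assert (revised.hsi_time == revised.hsi_crossing_time).all()
    assert (revised.clinical_time == revised.clinical_detection_time).all()
    spared = merged[merged.group == "R_minus"]
    assert spared.hsi_time.isna().all()
    assert spared.clinical_time.isna().all()
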