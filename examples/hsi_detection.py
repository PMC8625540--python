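"""Run the hyperspectral malperfusion rule and compare detection channels.

On a calibrated 500-flap synthetic cohort: derive the dichotomization
thresholds (revised-group means), apply the published four-criterion rule,
and compare HSI detection times with the bedside decision times.
"""

import flapmon as fm

cohort = fm.simulate_cohort(
    fm.default_generator_config(n_flaps=500, seed=1, replicate_table2=False)
)
cohort = fm.filter_monitoring_complete(cohort)

deltas = fm.compute_deltas(cohort.hsi)
derived = fm.derive_thresholds(cohort, deltas=deltas)
print("Derived dichotomization thresholds (revised-group postoperative means):")
print(f"  StO2 <= {derived.sto2_max:.1f} %   StO2 drop <= {derived.sto2_dref_max:.1f} %")
print(f"  NPI  <= {derived.npi_max:.1f}     NPI drop  <= {derived.npi_dref_max:.1f} %")
print("Published rule thresholds:", fm.DEFAULT_THRESHOLDS.as_dict())

detections = fm.detect_cohort(cohort, thresholds="printed")
cmp = fm.compare_detection(detections)
print(f"\nPaired comparison over {cmp.n_paired} compromised flaps:")
print(f"  clinical decision: {cmp.clinical_mean:.1f} +/- {cmp.clinical_sd:.1f} h post-inset")
print(f"  HSI criteria:      {cmp.hsi_mean:.1f} +/- {cmp.hsi_sd:.1f} h post-inset")
print(f"  lead time:         {cmp.lead_mean:.1f} +/- {cmp.lead_sd:.1f} h "
      f"(Wilcoxon signed-rank p = {cmp.wilcoxon_p:.1e})")
print("\nA positive lead time means the imaging criteria flagged the perfusion "
      "problem hours before the bedside decision to re-explore.")
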