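# flapmon

Free-flap perfusion monitoring, simulated and analysed.

After microvascular free-tissue transfer in the head and neck, flap
survival hinges on catching perfusion failure (venous or arterial
thrombosis, haematoma, pedicle kinking) early enough for salvage surgery.
The bedside gold standard — grading flap colour, temperature,
recapillarization time and turgor — is subjective and slow to react.
Hyperspectral imaging (HSI) offers an objective alternative: non-contact
parameter maps of tissue oxygen saturation (StO₂, %), a near-infrared
perfusion index for deep tissue (NPI, 0–100 a.u.), and haemoglobin and
water distribution indices (THI, TWI, 0–100 a.u.), each compared against
an adjacent unoperated reference site.

`flapmon` is a library for clinical-imaging researchers who want to study
this monitoring problem quantitatively without patient data. It provides:

* **`flapmon.synthetic`** — a seeded generator of monitored cohorts:
  flap metadata matching the modelled study's baseline table (65 flaps,
  46/19 by revision status), intraoperative measurements (t0–t3), one
  paired HSI + bedside event per 12-h postoperative interval (t4–t10),
  and ground-truth clinical/HSI detection times for compromised flaps.
* **`flapmon.clinical`** — the bedside scoring system and re-exploration
  rule: re-explore iff `total ≥ 9` **or** two signs at their 3-point
  levels **or** colour pale-white/blue for > 60 min with recapillarization
  absent or < 1 s.
* **`flapmon.hsi`** — relative-change metrics per parameter
  (Δreference, Δt3, Δpre-value, all `(flap − anchor)/anchor × 100`) and
  the four-criterion malperfusion rule

  StO₂ ≤ 32 % ∨ StO₂Δref ≤ −38 % ∨ NPI ≤ 32.9 ∨ NPIΔref ≤ −13.4 %,

  with thresholds either fixed at these published dichotomization values
  or re-derived as revised-group means from a cohort.
* **`flapmon.roi`** — polygon-ROI quantification on parameter maps
  (rasterization, mean/SD/histogram, false-colour rendering), as in the
  device's report view.
* **`flapmon.stats`** — group summaries, Shapiro-gated t/Mann-Whitney
  selection, Wilcoxon signed-rank for paired detection times, χ²/Fisher
  contingency tests with the expected-count-< 5 rule, η², salvage rate.

## Worked example

```python
import flapmon as fm

cohort = fm.simulate_cohort(
    fm.default_generator_config(n_flaps=500, seed=1, replicate_table2=False)
)
cohort = fm.filter_monitoring_complete(cohort)
detections = fm.detect_cohort(cohort, thresholds="printed")
cmp = fm.compare_detection(detections)
print(f"clinical {cmp.clinical_mean:.1f} h, HSI {cmp.hsi_mean:.1f} h, "
      f"lead {cmp.lead_mean:.1f} h, p = {cmp.wilcoxon_p:.1e}")
```

prints

```
clinical 22.5 h, HSI 18.1 h, lead 4.4 h, p = 7.2e-26
```

i.e. over the 147 compromised flaps of this simulated cohort, the HSI
criteria fired on average 4.4 hours before the bedside decision to
re-explore, and the paired difference is far from chance under a Wilcoxon
signed-rank test. `examples/` contains one narrative script per
capability (simulation, scoring, detection, ROI quantification, cohort
statistics); `flapmon --help` exposes the same pipeline as a thin CLI
(`simulate`, `score`, `deltas`, `detect`, `compare`, `report`,
`quantify-roi`).

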