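# Methods

## Setting and time grid

The package models postoperative monitoring of microvascular free flaps
in the head and neck. Time is measured in decimal hours from flap inset
(t3 = 0). Intraoperative measurement points carry non-positive
timestamps: flap origin (t0), flap raise (t1), completed anastomosis
(t2), inset (t3); their spacing is derived from the surgery duration
(t0 = −D, t1 = −0.55 D, t2 = −0.15 D hours for a D-hour procedure).
Postoperative monitoring is organised in half-open 12-hour intervals
t4 = (0, 12] … t9 = (60, 72], t10 = (72, ∞), so every positive timestamp
belongs to exactly one interval. HSI is acquired at t0–t10, bedside
checks at t4–t10; flaps lacking that coverage are excluded by
`filter_monitoring_complete`, with intervals beyond a flap's
re-exploration decision counting as covered by truncation.

## Clinical scoring rule

Each bedside observation grades colour (pale white 3 / pink 1 / red 2 /
blue 3), temperature (cold 2 / body 1 / superheated 2),
recapillarization (≈1 s 2 / >2 s 1 / <1 s 3 / none 3) and turgor (soft 2
/ elastic 1 / plump 2); totals span 4–10. Re-exploration is indicated
when total ≥ 9, or when two signs jointly reach 6 points, or when the
colour has been pale white/blue for more than 60 minutes while
recapillarization is absent or under one second. Two readings needed
fixing against the source wording: no single sign can score 6, so "two
variables scored 6 points" is implemented as two signs at their 3-point
levels (only colour and recapillarization qualify); and the third
clause's conjunction binds the colour-duration and recapillarization
conditions to each other, not to the other clauses. The colour-duration
memory travels on the observation (`abnormal_color_duration`), keeping
the rule itself stateless; every clause is monotone in points/duration,
which the property tests exploit.

## HSI metrics and the detection rule

For each parameter p ∈ {StO₂, NPI, THI, TWI} three relative changes are
computed per measurement, all as (flap − anchor)/anchor × 100: against
the simultaneous reference-site value (Δreference), against the same
flap's t3 value (Δt3), and against the immediately preceding measurement
(Δpre-value; the first postoperative event anchors on t3). Deltas with
missing or zero anchors are absent, never errors, and absent deltas
never fire a criterion.

Malperfusion is flagged at the earliest postoperative measurement where
any of four criteria holds, all boundaries inclusive:
StO₂ ≤ 32 %, StO₂Δreference ≤ −38 %, NPI ≤ 32.9, NPIΔreference ≤ −13.4 %.
Two deliberate choices:

* **Sign convention.** The source abstract prints the drop-rate
  inequalities as `> −38` / `≥ −13.4`, but the revised group's drop
  rates are *more* negative than the spared group's (−38.1 vs −18.3;
  −13.4 vs +8.8) and the rule is described as flagging a negative
  deviation. Taken literally, the printed direction would classify a
  typical healthy flap (Δ ≈ −18 %) as malperfused. The rule is therefore
  implemented as "drop at least as severe as the threshold" (≤); the
  literal reading stays available via `strict_printed_signs=True` so
  both are runnable, and a unit test documents that the literal reading
  flags typical healthy values.
* **Relative, not absolute, drops.** The drop rate is percent change,
  not a percentage-point difference: back-computing the reference from
  the spared-group values (StO₂ 43.2 % at −18.3 %) puts the reference at
  ≈ 52.9 %, inside the physiological 50–70 % reference band, whereas the
  absolute reading lands outside it.

`derive_thresholds` reproduces the dichotomization procedure: each
threshold is the per-measurement mean of its quantity over all revised
(R+) postoperative measurements (t4–t10). Intraoperative measurements
never trigger detection: the clock runs from inset and no pre-inset
group differences exist.

## Synthetic cohort generator

No raw data are published for this setting, so all cohort-level numbers
are reproduced through a calibrated generator whose defaults encode the
published distributions. It emulates:

* **Baseline composition.** With `replicate_table2` (default at
  n = 65), flap type × revision margins, causes, regimes, recipient
  arteries and irradiation counts equal the packaged baseline table
  exactly; otherwise attributes are drawn from the corresponding
  conditional proportions. One published inconsistency had to be
  resolved: the cause counts print as 8/8/3/1 (sum 20) against 19
  revisions, while the printed arterial percentage (36.8 % = 7/19)
  identifies the arterial count as the typo; the generator uses
  8 venous / 7 arterial / 3 haematoma / 1 kinking. Seven of the 19
  revised flaps fail completely (salvage 63 %), allocated 2/4/1/0 across
  those causes (arterial compromise carries the worst prognosis).
* **Detection times.** The lead time (clinical minus HSI) follows
  gamma(mean 4.8 h, sd 5 h) — a gamma keeps both moments on nonnegative
  support, where a truncated normal would shift the mean. The HSI
  crossing time is gamma with mean 23.1 − 4.8 and sd √(21.9² − 5²),
  and the clinical decision time is their sum. This additive
  construction keeps the means and sds of clinical time (23.1 ± 21.9 h)
  and lead (4.8 ± 5 h) exact while guaranteeing a strictly postoperative
  crossing; the alternative — independent draws with rejection of
  invalid pairs — was measured to bias all three means beyond their
  estimation error. The implied mean crossing time, 18.3 h, matches the
  published 18.2 h to that source's own rounding.
* **Parameter values.** Per measurement, the four detection-relevant
  quantities (StO₂, StO₂Δref, NPI, NPIΔref) are affine in one shared
  latent standard-normal severity z — physiologically, one perfusion
  state drives all indices — so "no criterion fires" and "some criterion
  fires" are single truncations of z. Spared flaps (and the revised
  group's intraoperative points) use the spared-group calibration
  (StO₂ 43.2 ± 10.3 %, Δref −18.3 ± 15.9 %, NPI 42.8 ± 9.8,
  Δref +8.8 ± 25.7); revised flaps use the revised-group calibration
  (32.6 ± 9.8, −38.1 ± 18.2, 32.9 ± 12.8, −13.4 ± 36.9) for **all**
  postoperative measurements — consistent with the finding that the
  revised group is depressed at every postoperative interval — with the
  trajectory constrained to cross the rule thresholds first at exactly
  the planned crossing time.
* **Mean-exact truncation.** For never-crossing flaps, z is drawn from
  a normal truncated at T\* and recentred by its conditional mean, with
  T\* solving T − E[z | z > T] = max_k (θ_k − μ_k)/σ_k; the support then
  stays clear of every threshold while group means equal the calibration
  exactly (at the cost of a somewhat reduced within-group sd). For
  revised flaps, pre-crossing draws are conditioned above the firing
  cut and the crossing draw below it; the conditional-mean offsets these
  introduce are cancelled by giving the unconstrained post-crossing
  draws a computed compensating mean per (group, timepoint) context, so
  expected group means remain at calibration.
* **Reference sites.** Because the published flap-side means and drop
  rates jointly determine the reference level, reference values are
  derived as ref = value/(1 + Δref/100) from the sampled pair rather
  than drawn independently; StO₂ references land around 50–55 %, i.e.
  at the lower end of the physiological 50–70 % band, consistent with
  back-computation, but they are not uniform across that band. Values
  are kept on their 0–100 scales by redrawing (never clipping); drops
  below −95 % are redrawn to keep references physical, which nudges the
  heavy-tailed NPIΔref mean slightly upward (≈ 1–2 points, within the
  2·SEM recovery tolerance at n = 500).
* **THI/TWI.** Group-level THI/TWI means are not published as numbers,
  only as directions; defaults put both mid-scale, add +12 THI after
  onset for congestive causes (venous thrombosis, haematoma, kinking)
  and −5 for arterial inflow failure, and place revised-group TWI
  slightly lower. These are invented, clearly-labelled defaults; the
  detection rule never uses THI/TWI.
* **Timepoint-specific calibration.** Calibration entries can target a
  single interval; the packaged first-interval profile (t4: revised
  StO₂ 34.9 ± 10, NPI 37.3 ± 7.5; spared 49.1 ± 13.5, 43.75 ± 10.52) is
  off by default because mixing it with the overall means would move the
  overall group means away from their own calibration. t9 is generated
  and carried even though no separate statistics exist for it — the
  monitoring protocol includes it.
* **Clinical observations.** Spared flaps and pre-decision events draw
  benign sign combinations whose maximal total (7) cannot trigger the
  rule; at the decision time a cause-specific pathological pattern
  (venous congestion: blue/< 1 s/plump; arterial: pale-white/no
  refill/soft; …) satisfies the rule by construction. Monitoring stops
  at the decision event; the decision observation itself (and a final
  HSI measurement) is recorded, so one interval can hold two events when
  crossing and decision fall in the same window.

**What passing tests do and do not show.** The generator reproduces the
published summary structure by construction — group means, detection-time
moments, margins, 100 % clinical sensitivity among compromised flaps and
0 % among spared ones. Tests passing on it validate the pipeline's
correctness (rules, metrics, scans, statistics), not the clinical claims:
real data would add measurement noise, inter-rater variability,
autocorrelated within-flap trajectories, HSI false positives in healthy
flaps, and missed visits, none of which are modelled.

## Statistics

Sample SD (n − 1) throughout; SEM = sd/√n; all tests two-sided; ties get
scipy's mid-rank corrections. Shapiro–Wilk at α = 0.05 is the sole
arbiter between Student's t and Mann–Whitney U (Kolmogorov–Smirnov is
computed and reported alongside, but one arbiter avoids contradictory
paths). Paired detection times use Wilcoxon signed-rank with zeros
dropped; an all-zero difference set has no defined p and is reported
absent. Contingency tables use Pearson χ² unless some expected cell
frequency is < 5 (exactly 5 stays χ², per the quoted rule), in which
case Fisher's exact test runs — scipy for 2×2, full enumeration of the
multivariate-hypergeometric distribution (Freeman–Halton two-sided
definition) for r×2. η² = SS_between/SS_total for the one-way layout.
No multiple-testing correction is applied anywhere, matching the
modelled analysis; reports state this prominently.

## ROI quantification

Pixels are unit squares centred on integer coordinates (0-based,
row-major, origin top-left, default pitch 0.1 mm/pixel); a pixel belongs
to an ROI iff its centre lies strictly inside the polygon (even-odd
rule, boundary centres excluded; self-intersecting polygons rejected).
ROI statistics use the population SD (denominator n) over masked pixels
and a histogram with 1-unit bins over [0, 100] (the final bin closed),
so pixel counts reconcile exactly. False-colour rendering interpolates
linearly between blue (0), green (100/3), yellow (200/3) and red (100);
only the endpoint semantics are given by the device convention, the
equally spaced interior anchors are this package's choice. Maps
round-trip as 16-bit grayscale PNG (code = round(value × 655.35), i.e.
exact to ±0.00076 units) or plain-matrix text; polygons as GeoJSON in
pixel coordinates.

## Problem sizes and determinism

All randomness flows through one `numpy.random.Generator` seeded from
the configuration; identical config ⇒ byte-identical cohort tables.
Parameter-recovery and detection-comparison checks run on 500-flap
cohorts (≈ 147 compromised flaps, ≈ 5,000 measurements), which puts
2·SEM at roughly ±0.9 % StO₂ on revised-group means and ±3.5 h / ±0.8 h
on clinical/lead detection-time means; recovered values are expected
within those bands, and an individual seed can land near a band's edge.
The acceptance script regenerates both cohorts and recomputes every
reported quantity at run time from the requested seed.

## Known limitations

* Within-flap trajectories are anchored but not autocorrelated between
  events; the generator targets cross-sectional moments, not temporal
  spectra.
* The spared group never satisfies either detection rule by
  construction, so specificity cannot be studied without widening the
  generator.
* The reference-site derivation ties reference values to the sampled
  drop rate; reference dynamics (e.g. systemic changes) are not
  modelled.
* The raw spectral cubes and the manufacturer's index algorithms are out
  of scope; the package operates on already-computed parameter values
  and maps.
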