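# Methods

## Scope and data model

The package operates on per-vessel time–attenuation curves (TACs): mean
attenuation in Hounsfield units at each volume of a dynamic CTA
acquisition. Image-space processing (segmentation, MIP reconstruction,
visual grading) is out of scope; where the original workflow is a visual
read — the antegrade filling ratio and the three-level collateral grade —
those gradings enter as inputs and only the decision rules are implemented.

The acquisition grid defaults to 19 volumes at 2.0 s spacing starting
8.0 s after contrast injection. The inter-volume interval of the emulated
protocol is not published; 2.0 s is consistent with the sub-volume
differences visible in the published case readings (e.g. onsets 19.0 s vs
20.9 s across hemispheres read from different volumes of the same series),
and all scoring works on arbitrary strictly increasing grids. Times are
reported on the grid; there is no sub-sample interpolation, so every
timing score is quantized to the acquisition spacing. Baselines default to
the first-volume attenuation (the pre-contrast volume is acquired first).

## Phase selection

V-TAC is the grid time of the maximum SSS enhancement. A-TAC is chosen
among grid times strictly before V-TAC as the time maximizing the *minimum*
of the two baseline-corrected MCA enhancements, ties broken toward the
earlier time. The published criterion ("best contrast opacification of the
bilateral MCA, less affected by cortical veins") is visual; the bilateral
minimum restricted to pre-venous times is the closest deterministic
surrogate: it rewards simultaneous bilateral filling and the pre-venous
constraint excludes venous contamination.

## Timing and extent rules

A single visibility threshold — 50 HU enhancement above baseline — is
shared by onset (CVF₁), clearance (CVF₃) and presence (CVF+/CVF−) scoring.
The original adjudication is visual and thresholdless; a single documented
knob keeps the three readings mutually consistent, and 50 HU is ten
standard deviations above the default 5 HU acquisition noise, so threshold
crossings are effectively deterministic for real contrast levels.

* CVF₁: earliest grid time at which any *present* vein reaches threshold.
* CVF₂: "most veins at maximum opacification" is operationalized as the
  earliest time at which at least 50 % (rounded up) of the present veins
  are within 5 % of their own maximum enhancement. For a single vein this
  degrades to its (tolerance-padded) argmax. When distinct peaks make a
  configured strict majority unattainable at any single time, the earliest
  time with the best attainable count is used.
* CVF₃: earliest grid time after CVF₂ at which every present vein is below
  threshold. A vein still opacified at the last volume yields an explicit
  censored-clearance flag and a missing CVF₃, never an imputed value.

Absent (CVF−) veins are excluded from all three timing detections: a
never-filling vein would otherwise force censoring of a hemisphere that is
in fact scoreable.

Presence is judged over a venous window. The window is anchored at CVF₁
(one grid interval before it, through the last volume), but CVF₁ itself is
computed from present veins, so scoring is two-pass: a provisional
presence read over the fallback window [V-TAC − 2 intervals, last volume]
feeds a provisional CVF₁; the definitive presence read uses
[CVF₁ − 1 interval, last volume]; CVF₁/₂/₃ are then detected on the
definitively present set. The fallback window is also used when a
hemisphere's onset is censored. Presence uses a ≥-threshold convention, so
a curve touching the threshold at exactly one volume counts as present.

Ipsilateral CVF− is a vein absent on the affected side *and* present
contralaterally; bilateral absence is treated as anatomical variation and
excluded. The count category CVF−=3 is representable even though it may
never occur in a given sample.

Velocity labels are a median split: fast ⇔ value ≤ cohort median (mean of
central order statistics for even n), so at least half the cohort is
always fast. Thresholds are computed within the analysis cohort — the
symptomatic group — not the pooled study, matching how the early-to-peak
cut of 1.9 s arises from symptomatic medians.

## Decision rules

Antegrade flow is preserved iff the affected-side filling ratio is
strictly greater than 2/3 ("more than two-thirds"); exactly 2/3 is
compromised. Collateral status is good iff the grade is `complete` at
either A-TAC or V-TAC, with grades ordered none < peripheral < complete.

## Statistics

* **Odds ratios**: cross-product estimate with the Woolf log-normal 95 %
  interval, `exp(ln OR ± 1.959964·√(Σ 1/cell))`. Any zero cell triggers
  the Haldane–Anscombe +0.5 correction of *all* cells before both the
  estimate and the interval (method reported as `woolf_haldane`). This
  convention reproduces both published intervals from their printed
  counts.
* **2×2 association**: Pearson chi-square in closed form, Yates continuity
  correction, or the exact two-sided Fisher test — implemented by
  enumerating the conditional hypergeometric distribution in exact
  rational arithmetic and summing probabilities ≤ the observed table's, so
  probability ties are resolved exactly. Default mode `auto` uses Fisher
  when any expected cell is below 5. A zero margin is degenerate:
  statistic 0, p = 1, flagged.
* **Continuous comparisons**: pooled-variance Student t, or Mann–Whitney U
  with midranks; the two-sided Mann–Whitney p is computed by complete
  enumeration of group labelings when the pooled sample size is ≤ 10
  (2·min(P(U ≤ u), P(U ≥ u)), capped at 1) and by the tie-corrected normal
  approximation otherwise.
* **Logistic regression**: Newton–Raphson maximum likelihood (tolerance
  1e-8, 100 iterations; the numerical core is statsmodels' Logit behind
  this package's interface) with Wald 95 % intervals. Perfect or
  quasi-complete separation — a singular information matrix or any
  |coefficient| above 15 — raises an explicit error rather than returning
  a divergent fit. The outcome-model adjustment set defaults to admission
  NIHSS. For the two-vein extent category the odds ratio is oriented with
  the favorable outcome as the case, the orientation whose interval the
  emulated study prints.
* Percentages in tables round half-away-from-zero to integers; continuous
  summaries print as mean ± sd or median (q1–q3). No multiple-testing
  correction is applied.

## Synthetic cohort generator

Every vessel's TAC is a gamma-variate curve plus i.i.d. Gaussian noise
(default 5 HU). Defaults: arterial arrival ~ N(9.0, 0.6²) s, arterial
shape α = 3, β = 1.5 s with 350 HU peak enhancement; cortical veins arrive
4.0 s later (α = 3, β = 1.8 s, 250 ± 30 HU); the SSS trails the veins by
0.5 s with a broader, stronger curve (β = 2.0 s, 420 HU), so its sampled
peak defines V-TAC. These values place onsets, peaks and clearances inside
the 19-volume window at positions comparable to the published case
readings; they are plumbing, not fitted quantities.

The affected hemisphere's veins are delayed two ways: the arrival shifts
by δ₁ (the onset delay) and the timescale widens, β′ = β + δ₂₁/α at fixed
peak enhancement, which moves the peak by exactly δ₁ + δ₂₁. Onset and
clearance scale with β′, so the scored rCVF₂₁ slightly undershoots the
injected δ₂₁ (the onset also moves a fraction of δ₂₁); together with grid
quantization this is the dominant recovery error and stays well within one
grid interval at the group-median level.

δ₁ and δ₂₁ are drawn from shifted log-normals matched to the published
group medians — δ₁: 2.0 s (symptomatic) / 1.8 s (asymptomatic); δ₂₁:
1.9 s / 0.1 s, with shifts −2.0 s and −0.2 s so negative early-to-peak
differences occur as observed in one published case. The log-sigmas
(0.76/0.80 and 0.72/0.60) approximate the printed interquartile ranges;
exact IQR matching is impossible for the asymptomatic onset delay without
unrealistically heavy tails, so median fidelity took priority. Each vein
is independently absent (pure-noise curve) with the published per-group,
per-side proportions; collateral status is drawn conditional on whether
the injected δ₂₁ is at or below its group median (P(poor|fast) = 11/19,
P(poor|slow) = 3/17); the 3-month outcome is drawn conditional on the true
ipsilateral CVF− count (P(poor|0,1,≥2) = 2/17, 3/12, 6/7), and mRS/NIHSS
are drawn consistently with the outcome class. Demographics and risk
factors follow the published group frequencies.

What the generator does *not* emulate: spatially correlated noise, partial
volume and beam hardening, inter-reader variability in the visual scores,
intra-hemisphere heterogeneity of vein timing, and any dependence between
risk factors and hemodynamics. Passing recovery tests therefore show that
the scoring rules invert the generative model on its own terms — not that
they match radiologist readings of real dynamic CTA.

## Numerical and reproducibility choices

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configs give byte-identical cohorts,
scores and result files. The shipped analysis seed is 20210408. Recovery
and acceptance runs use 200 + 200 patients noiseless and ~170–400 patients
noisy, sizes at which group medians are stable while a full
simulate–score–analyze pass completes in seconds. Argmax-style selections
break ties toward the earlier grid time throughout. Degenerate inputs
(empty cohorts, zero margins, all-zero tables, both-constant t samples)
raise or flag explicitly.

## Known limitations

* Timing scores are grid-quantized; sub-interval delays (< 2 s by default)
  are only detectable in aggregate, not per patient.
* The cohort medians and p-values of the emulated study are not
  reproducible targets: its per-patient data are unpublished. Synthetic
  cohorts reproduce effect *directions* and the printed-count statistics
  only.
* With realistic small samples the outcome logistic model can be separated
  (every two-vein-absent patient has a poor outcome); the package reports
  this as an explicit separation error, while the Haldane-corrected Woolf
  interval remains available.
* The published point estimate 0.04 for the two-vein outcome odds ratio is
  not the cross-product of its printed counts (0.035); this package
  reports the as-computed value, whose Woolf interval endpoints match the
  printed ones.
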