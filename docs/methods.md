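# Methods

## Scope and data model

The package analyses per-structure cumulative DVHs (dose in Gy on a
uniform grid starting at 0, absolute volume in cc) with a binary injury
label per structure. Three structures per patient are modelled: the whole
brain and the left/right half-brains, whose absolute volumes sum to the
whole brain at every dose edge exactly. All dose–volume arithmetic is
linear-interpolation based, the universal DVH convention; the differential
form used by the power mean assigns each bin the volume difference of its
bracketing edges, with any residual volume at or above the final edge kept
in the last bin so total volume is conserved exactly.

## The gEUD family

`EUD(a) = (Σ v_i D_i^a)^(1/a)` is evaluated on relative weights within the
chosen reference volume. For the restricted family `EUD_V_D` the reference
volume is the subvolume covered by doses ≥ D: the partial bin containing D
is split by linear interpolation and the retained weights are renormalized
to sum to 1. Renormalization is the only reading under which the reduction
remains a dose (an un-renormalized power mean of a sub-unity weight vector
is not); the retained volume equals `V_D` exactly, an invariant under
test. Numerically the power mean is computed as
`D_max · (Σ v_i (D_i/D_max)^a)^(1/a)`, which is exact in exact arithmetic
and keeps `x^a` in [0, 1] for the large exponents on the grid (checked up
to a = 200 against the max-dose limit).

Two conventions close the family under edge cases:

* an empty restricted subvolume (`V_D = 0`) has EUD 0 Gy, so every
  observation stays scoreable at every threshold and a patient with no
  volume above D ranks lowest for injury risk — the ordering a ROC
  analysis needs. Exclusion of such observations is representable (the
  empty differential DVH is a value, not an error) but not the default.
* `D_V` at V = 0 is the maximum dose, the V → 0⁺ limit of the inverse
  curve; on a flat cumulative segment `D_V` returns the highest dose
  attaining ≥ V (the conservative choice for injury prediction).

## ROC machinery

AUC is the tie-corrected pair probability computed from midranks
(equivalently the Mann–Whitney statistic); the test suite pins it to both
exhaustive pair counting and the trapezoidal ROC integral at 1e-12. The
95% CI uses DeLong's structural-components variance (cross-checked
against an independent reference implementation at 1e-9). Operating
points maximize Youden's J = sensitivity + specificity − 1 over candidate
cutoffs at midpoints between adjacent distinct scores, rule
"score ≥ cutoff ⇒ predicted injury"; ties in J resolve to the lower
cutoff (higher sensitivity). Scores are oriented so that higher predicts
injury; constant scores yield AUC 0.5 with an explicit degenerate flag
rather than a silent number.

The optimal volume-effect parameter per threshold is the argmax of AUC
over the a-grid; AUC values within 1e-12 of the maximum are treated as
exact ties (on ~100 observations AUC is a rational with a small
denominator, so exact ties are real) and resolved to the median of the
tied set, the midpoint of the two central values when the set has even
size. Correlation and t statistics are thin, degenerate-input-aware
wrappers over scipy (Pearson with the t-transform p; paired t as a
one-sample t on differences; pooled-variance two-sample t by default with
Welch as an option); zero-variance inputs signal infinite-t or undefined
values explicitly. No multiple-testing correction is applied anywhere —
the screening is deliberately in-sample and descriptive.

Half-brain analyses treat each half as an observation with its own label
(two per patient); within-patient correlation is ignored. This matches
the bookkeeping in which left, right, or both sides can be injured, and
doubles the nominal sample without claiming independence — a limitation
to keep in mind when reading half-brain CIs.

## Synthetic cohorts

The generator emulates whole-brain DVHs from nasopharyngeal-carcinoma
IMRT at the cohort scale the analysis expects (103 patients, ~32% injury
prevalence). Each relative cumulative curve is a two-component mixture:

* a stretched-exponential plateau `exp(−(d/λ)^k)`, rescaled to reach zero
  at a per-patient cutoff dose drawn below the prescription region
  (λ ≈ 22 ± 4 Gy, k ≈ 1.6 ± 0.25, cutoff ≈ 65 ± 1.5 Gy within
  [60, 67.5]) — the dominant low/intermediate-dose volume;
* a descending logistic tail step across a per-patient tail-center dose
  (uniform 68–74 Gy, width 1.5–3.5 Gy) carrying a log-normal tail volume
  (median 3 cc, σ = 0.7, capped at 20 cc), so V_70Gy is of order 0–8 cc.

Total volume is normal (1300 ± 120 cc, truncated ≥ 1000 cc). Both
components are monotone by construction; an isotonic-projection guard
remains as a counted safety net. Halves are split bin-by-bin: plateau
bins by a tight symmetric Beta share (Beta(200, 200), so the halves'
relative distributions nearly coincide with the brain's), tail bins by a
broad symmetric Beta (Beta(1.2, 1.2)) that lets the high-dose tail
lateralize. The right bin volume is computed as brain-minus-left and the
whole-brain curve is defined as the elementwise sum of the halves, so
half + half = whole holds exactly in floating point, per bin and per
edge.

Injury is Bernoulli per half-brain with logistic probability in one
driver metric, then OR-ed to the patient level. The default driver is the
mean dose of the ≥ 55 Gy subvolume — the generative embodiment of the
view that dose to the critical-dose volume, not the whole-organ average,
drives injury; whole-volume gEUD at a chosen exponent and `D_V` drivers
are available for parameter-recovery and planted-signal experiments. The
slope is specified per driver standard deviation (default 1.5, at which
the driver itself scores AUC ≈ 0.85, the discrimination typically
reported for the best dosimetric predictors of this endpoint); the
intercept then solves for expected patient-level prevalence 0.32 on the
realized cohort by bracketed root finding, erroring out (rather than
drifting) if the target is unreachable or the driver is constant. One
`numpy` Generator seeded per cohort is the only randomness; identical
seed and configuration reproduce the cohort bit-for-bit.

What the generator does *not* emulate: real DVH irregularity (multiple
hot spots, plan-specific gradients, inter-planner variability),
anatomical correlation between tail location and injury site, and any
clinical covariates. Passing pipeline tests on these cohorts therefore
demonstrates that the machinery recovers planted structure at realistic
signal-to-noise, not that the clinical effect sizes themselves are
reproduced. One consequence is worth spelling out: with labels drawn from
a logistic model at AUC ≈ 0.85, the in-sample argmax of AUC over the
a-grid at thresholds ≥ 55 Gy sits within ~0.005 AUC of a = 1 but lands
*exactly* on a = 1 only part of the time — adjacent exponents reorder so
few patient pairs that a single borderline label draw moves the argmax.
The smooth seven-parameter curve family makes neighbouring-exponent
rankings more similar than irregular clinical DVHs would, so the
identity of the argmax is the least stable output of the sweep; its
near-optimality margin is the robust quantity.

## Pipeline and reproducibility

Stages are pure functions of (cohort, configuration): the (D, a) AUC
sweep per structure class (degenerate cells flagged NaN, never
fabricated); Pearson correlations between D, mAUC and optimal a,
restricted by default to D ≤ 55 Gy where the relationship is monotone;
the predictor comparison table (critical-dose-volume EUD at its optimal
a, whole-volume EUD at its optimal a, best `D_V`, best `V_D` — each with
DeLong CI and Youden operating point) plus the per-exponent dominance
series for a ≤ 22 with a paired t-test; and the mean-dose feasibility
window, whose scores are identically the a = 1 column of the sweep (an
identity under test). The critical threshold defaults to 55 Gy and is
configurable. CSVs are written with a fixed float format after all
computation finishes, so identical inputs give byte-identical artifacts
and failures leave no partial output. The EQD2 conversion
`D·(d + α/β)/(2 + α/β)` uses α/β = 3 Gy (the conventional late-CNS
value) and 31 fractions by default; both are configuration fields, and
2 Gy-per-fraction schedules are a fixed point.

Default problem sizes throughout (103 patients per cohort, 59 × 15 sweep
grid, 10-seed majority checks for stochastic properties) keep a full
analysis under a second and the entire verification suite under a
minute on one core, while matching the cohort scale the method is meant
for.
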