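# geudpred

Dose–volume-histogram (DVH) reduction to the generalized equivalent uniform
dose (gEUD) and ROC-based evaluation of how well it predicts
radiation-induced brain injury after intensity-modulated radiotherapy for
nasopharyngeal carcinoma — for medical physicists and outcome modellers who
want the whole chain (DVH → candidate metric → AUC → operating point) as
tested, scriptable code.

## The model

A cumulative DVH gives the structure volume receiving at least each dose.
The gEUD compresses it into one number via the weighted power mean

```
EUD(a) = ( Σ_i v_i · D_i^a )^(1/a)
```

with `D_i` the dose of bin *i* (1 Gy/bin), `v_i` its relative volume and
`a` the volume-effect parameter: `a = 1` is the mean dose (parallel-organ
behaviour), large `a` approaches the maximum dose (serial-organ
behaviour). The *critical-dose-volume* variant `EUD_V_D` applies the same
reduction to only the subvolume covered by doses ≥ D, with weights
renormalized inside that subvolume, removing the influence of the large
low-dose volume.

The package grid-searches `a` (1–30, step 0.5) and the threshold `D`
(0–70 Gy, step 5) by maximal ROC AUC against binary injury labels,
selects Youden-optimal cutoffs with DeLong 95% CIs, compares the EUD
family against the simple point metrics `D_V` (dose to the hottest V,
0–5 cc) and `V_D` (volume covered by ≥ D, 40–75 Gy), and maps the
threshold window in which the plain mean dose of `V_D` is non-inferior to
the tuned whole-volume EUD. Because no patient-level DVH set is publicly
deposited for this endpoint, a first-class synthetic-cohort generator
(`geudpred.synth`) emulates NPC-IMRT whole-brain DVHs — ~1.3 L brains, a
dominant low/intermediate-dose plateau, a few-cc high-dose tail near the
68–74 Gy prescription, exactly additive left/right half-brains, and
logistic injury labels calibrated to ~32% prevalence.

## Worked example

```python
import numpy as np
from geudpred import (CumulativeDVH, cumulative_to_differential, compute_eud,
                      eud_of_restricted, volume_at_dose, dose_at_volume)

edges = np.arange(0.0, 81.0)                      # 1 Gy/bin grid
vol = 1300.0 * np.exp(-(edges / 22.0) ** 1.6)     # smooth whole-brain-like curve
vol[-1] = 0.0
brain = CumulativeDVH(edges, vol)

print(f"V_55Gy  = {volume_at_dose(brain, 55.0):6.1f} cc")
print(f"D_2cc   = {dose_at_volume(brain, 2.0):6.1f} Gy")
print(f"EUD(a=1)    = {compute_eud(cumulative_to_differential(brain), 1.0):5.1f} Gy")
print(f"EUD(a=21.5) = {compute_eud(cumulative_to_differential(brain), 21.5):5.1f} Gy")
print(f"EUD_V55(a=1)= {eud_of_restricted(brain, 55.0, 1.0):5.1f} Gy")
```

prints

```
V_55Gy  =   17.1 cc
D_2cc   =   70.7 Gy
EUD(a=1)    =  19.7 Gy
EUD(a=21.5) =  57.2 Gy
EUD_V55(a=1)=  62.2 Gy
```

17.1 cc of this brain receives ≥ 55 Gy and its hottest 2 cc receives
≥ 70.7 Gy. The whole-volume mean dose (19.7 Gy) is dominated by the
low-dose plateau; at `a = 21.5` the power mean has climbed to 57.2 Gy,
close to the hot region. The critical-dose-volume reduction reads off the
mean dose of the ≥ 55 Gy subvolume directly — 62.2 Gy — with no exponent
to fit.

The full pipeline runs from the shell:

```sh
geudpred synth --seed 1 --out cohort          # DVH + labels CSVs
geudpred run --dvh cohort/dvh.csv --labels cohort/labels.csv --out results
```

writing `sweep.csv` (AUC over the (D, a) grid), `sweep_summary.csv`
(per-threshold mAUC and optimal a), `correlations.csv`, `comparison.csv`
(AUC/CI/cutoff/sensitivity/specificity/Youden per predictor),
`dominance.csv`, `window.csv` and `provenance.json`; `--plots` adds figure
versions. Omitting `--dvh/--labels` synthesizes a default cohort in
memory.

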