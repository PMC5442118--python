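# aarcmr

Multi-parametric cardiac MR quantification of myocardial infarct size (IS)
and area-at-risk (AAR), exercised end-to-end on synthetic short-axis phantom
cohorts with known ground truth.

## The problem

After an acute myocardial infarction, *myocardial salvage* — the fraction of
jeopardized tissue (the AAR) that survives — is the sensitive endpoint for
cardioprotection studies, but it requires measuring the AAR.  T2-weighted
CMR infers the AAR from ischemia-induced edema; the catch is that some
cardioprotective interventions (notably ischemic preconditioning, IPC)
reduce edema itself, so T2 mapping then *underestimates* the AAR.
Arterial-spin-labeling (ASL) perfusion CMR offers an edema-independent
alternative: at 72 h of reperfusion the AAR still shows a microvascular
perfusion deficit, and because the deficit threshold is calibrated against
each animal's own remote myocardium, the measurement is also robust to
global perfusion changes (e.g. under cyclosporin-A, CsA).

`aarcmr` implements that full analysis chain for preclinical
(9.4 T mouse-style) data, plus a seeded digital phantom cohort standing in
for the in-vivo scans, so every stage is testable against ground truth:

* **phantom** — annular LV phantoms (128×128, 6–7 slices) with a transmural
  AAR sector, nested infarct, reduced-edema and perfusion-deficit structure,
  simulated multi-echo spin-echo, paired Look-Locker inversion-recovery,
  LGE, and histology label images; four study arms (control / IPC /
  vehicle / CsA).
* **relaxometry** — pixel-wise T2 maps from S(TE) = S0·e^(−TE/T2) and T1
  maps from the 3-parameter Look-Locker model s(t) = A − B·e^(−t/T1\*) with
  polarity restoration and the correction T1 = T1\*(B/A − 1).
* **asl** — blood-pool-input FAIR quantification,
  MBF = 60·(λ/T1_blood)·(T1_global/T1_selective − 1) in ml/g/min.
* **regional** — normal-ROI statistics on the second-from-most-basal slice
  and strict mean ± k·SD thresholds: T2/T1 > +1 SD → AAR, perfusion
  < −1 SD → AAR, < −2 SD → IS, LGE > +5 SD → IS; label-image planimetry
  for histology; per-animal IS/LV%, AAR/LV%, IS/AAR% by modality.
* **agreement** — Bland-Altman (bias, 1.96·SD limits), paired/unpaired t
  tests, one-way ANOVA with Bonferroni-adjusted pairwise comparisons.
* **pipeline / CLI** — `aarcmr simulate | fit | quantify | compare |
  run-study` over a NIfTI+JSON cohort directory with YAML configuration.

See `docs/methods.md` for models, defaults, and limitations.

## Worked example

```python
from aarcmr import GroupSpec, generate_cohort, analyze_cohort, bland_altman, paired_t

groups = [GroupSpec("control", 64.3, 6.1, 50.6, 6.9, n_animals=6),
          GroupSpec("IPC", 59.8, 7.9, 27.9, 3.7, n_animals=6,
                    edema_extent_multiplier=0.85)]
df = analyze_cohort(generate_cohort(groups, seed=7))
print(df[["animal_id", "hist_aar_lv_pct", "t2_aar_lv_pct",
          "asl_1sd_aar_lv_pct"]].round(1).to_string(index=False))
for g in ("control", "IPC"):
    sub = df[df.group == g]
    ba = bland_altman(sub["hist_aar_lv_pct"], sub["t2_aar_lv_pct"])
    ba2 = bland_altman(sub["hist_aar_lv_pct"], sub["asl_1sd_aar_lv_pct"])
    print(f"{g}: T2 bias {ba.bias:+.1f}%; ASL-1SD bias {ba2.bias:+.1f}%")
```

prints

```
 animal_id  hist_aar_lv_pct  t2_aar_lv_pct  asl_1sd_aar_lv_pct
control_01             65.2           65.6                65.2
control_02             72.8           73.0                72.5
...
    IPC_01             72.2           61.7                72.3
    IPC_02             50.1           42.9                50.4
...
control: T2 bias +0.3%; ASL-1SD bias -0.3%
IPC: T2 bias -9.0%; ASL-1SD bias +0.0%
```

Read: in controls both T2 and ASL recover the histology AAR/LV% to a
fraction of a percentage point.  Under IPC the edema covers only 85% of the
AAR, so the T2-derived AAR is biased low by ~9 points — while the
perfusion-based estimate is unaffected.  That asymmetry is the scientific
point of the multi-parametric protocol.

The same study runs from the shell:

```bash
aarcmr run-study --seed 7 out/           # simulate + fit + quantify + compare
ls out/compare                           # agreement.csv, anova_hist_aar.csv,
                                         # group_summary.csv, bland_altman.png
```

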