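# heartcac

Fully automated total and **vessel-specific** coronary artery calcium
(CAC) scoring on ECG-gated non-contrast cardiac CT.

## The problem

The Agatston score — the standard CT measure of coronary calcium burden —
requires an expert to click through every scan, labelling each calcific
lesion with its vessel (left main, left anterior descending, left
circumflex, right coronary artery). Fully automated scorers exist, but
vessel-specific attribution and the rejection of *non-coronary* calcium
(aortic wall, mitral annulus, pericardium, lymph nodes, pulmonary trunk)
remain the hard parts. `heartcac` is for image-analysis researchers and
methodologists who want an explainable two-stage pipeline for this
problem, plus the simulation and statistics machinery to evaluate it
end to end without patient data.

## The method

**Stage 1 — heart labelling.** A 3D U-Net (two input channels: the
HU-windowed CT and a binary heart mask) segments the heart into six
classes: outside-heart, the four coronary perfusion territories, and a
non-coronary "other" region. Training labels are *sparse*: experts only
label calcified voxels, so the multi-class Dice loss

```
D_c = 2 Σ p_c y_c / (Σ_sup p_c + Σ y_c + ε),    loss = 1 − mean_c D_c
```

is evaluated over labelled voxels only — the gradient is exactly zero at
unlabelled voxels, and the network extrapolates territories from where
calcium happened to occur. Automatically generated labels (structures
> 10 HU inside the heart, morphologically opened so that thin coronary
tubes vanish) supervise the non-coronary region.

**Stage 2 — deterministic Agatston scoring.** Calcium is every voxel
≥ 130 HU; lesions are 26-connected components; each axial slice
component with area ≥ 1 mm² contributes

```
area (mm²) × cofactor × dz/3.0,   cofactor = 1/2/3/4 for peak HU in
                                  [130,200)/[200,300)/[300,400)/≥400
```

Each lesion is attributed by majority vote over the predicted territory
map; lesions voted non-coronary are **excluded** from the score (that is
the false-positive rejection), and totals are binned into the risk
categories <1 / 1–10 / 10–100 / 100–400 / >400.

A seeded phantom generator produces synthetic gated-CCT volumes with
known territories, lesions, distractor calcifications and an exactly
computed ground-truth report, so the whole pipeline is testable offline.
See `docs/methods.md` for the model details and design rationale.

## Worked example

Simulate two phantoms and score one against its ground-truth territory
map:

```bash
heartcac simulate --n 2 --seed 42 --out phantoms
heartcac score --ct phantoms/scan001_ct.nii.gz \
               --labels phantoms/scan001_labels.nii.gz --out report.json
```

prints `{"total": 231.27999212265019, "category": 3}`, and
`report.json` contains the audit trail:

```json
{
  "per_vessel": {"LM": 41.16, "LAD": 190.12, "LCX": 0.0, "RCA": 0.0},
  "total": 231.28,
  "excluded_noncoronary": 0.0,
  "risk_category": 3,
  "n_lesions": 3,
  "lesions": [
    {"lesion_id": 1, "vessel": "LM",  "score": 41.16,  "n_voxels": 21},
    {"lesion_id": 2, "vessel": "LAD", "score": 49.00,  "n_voxels": 100},
    {"lesion_id": 3, "vessel": "LAD", "score": 141.12, "n_voxels": 144}
  ]
}
```

Three lesions — one on the left main, two on the LAD — summing to an
Agatston total of 231.3, risk category 3 (100–400). The stored
ground-truth report for this phantom gives the same totals to rounding
(231.28, category 3): scoring on the noisy rendering with the *true*
territory map recovers the oracle. The full learned pipeline
(simulate → train → predict → score → evaluate) is one command:

```bash
heartcac run --seed 0 --out run/       # ~6 minutes on one CPU
```

which writes `run/reports/evaluation.json` with the held-out
risk-category confusion matrix, Cohen's kappa, per-class Dice, and
Bland–Altman / Pearson / Kolmogorov–Smirnov score agreement.

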