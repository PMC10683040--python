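# Methods

`heartcac` quantifies coronary artery calcium (CAC) on ECG-gated
non-contrast cardiac CT in two stages that deliberately separate the
learned from the rule-based part of the problem:

1. **Heart labelling.** A 3D U-Net segments the heart into six classes —
   outside-heart, the four coronary perfusion territories (LM, LAD, LCX,
   RCA), and a non-coronary "other" region (aorta, valves, chambers,
   mediastinal structures). The network is trained from *sparse* labels:
   expert annotations exist only at calcified voxels, so the Dice loss is
   evaluated only where labels exist and the network is free to
   extrapolate territories elsewhere.
2. **Deterministic Agatston scoring.** Calcium is thresholded at 130 HU,
   grouped into lesions, scored per slice as
   `area (mm²) × density cofactor × (dz / 3.0)`, attributed to a vessel by
   majority vote over the predicted territory map, and summed. Lesions
   whose majority territory is non-coronary are excluded from the score —
   this exclusion is the pipeline's false-positive rejection mechanism
   for aortic-wall, mitral-annulus, pericardial, lymph-node, and
   pulmonary calcifications.

The explainability argument is that stage 2 is fully auditable: every
scored lesion carries its voxels, per-slice areas, peak HU, cofactor, and
territory vote.

## Scoring rules

- Threshold: HU ≥ 130 (inclusive), the conventional reading of the
  130-HU calcium definition.
- Lesion identity: 26-connectivity in 3D. Per-slice components:
  8-connectivity in-plane. The ≥ 1 mm² area filter applies per slice
  component, since the Agatston score is a per-slice sum; both choices
  follow common scoring implementations and are tested at their
  boundaries (129/130 HU, 0.75/1.25 mm²).
- Density cofactor from the slice component's peak HU: 1 for
  [130, 200), 2 for [200, 300), 3 for [300, 400), 4 for ≥ 400.
- Slice-thickness factor `dz / 3.0`, unity at the 3.0 mm gated-CCT
  protocol the score is defined for; other thicknesses are scored with a
  logged warning rather than rejected.
- Risk categories on the continuous total: 0: < 1; 1: [1, 10];
  2: (10, 100]; 3: (100, 400]; 4: > 400. The half-open bands resolve the
  ambiguity between the "11–100" and "10–100" renderings of the same
  scheme in the clinical literature.
- Vessel attribution: majority vote of lesion voxels over the territory
  map, ties broken LM > LAD > LCX > RCA. There is no established rule for
  lesions spanning vascular beds; majority vote is this package's choice
  and is flagged as such.

## Supervision construction

Three label sources merge into one supervision volume (sentinel −1 =
unlabelled, excluded from the loss):

- **Sparse vessel labels**: calcified voxels annotated with their vessel
  (codes 1–4). Conflicting annotations are an error, not an overwrite.
- **Automatic "other" labels**: voxels strictly above 10 HU inside the
  heart, opened with `n_iter` erosions then dilations (radius-1 3D ball,
  6-connected). Opening removes tube-like structures thinner than about
  `2·n_iter` voxels — the coronary arteries — while keeping thick bright
  structures (blood pool, annulus or aortic-wall calcification). The
  default `n_iter = 2` removes structures ≲ 3 mm across at 0.7 mm
  in-plane voxels, i.e. coronary calibre.
- **Dense outside-heart labels**: every voxel outside the heart mask is
  class 0.

Optionally a fourth source, dense whole-course coronary labels (as would
be transferred from a contrast-enhanced acquisition of the same
anatomy), merges at the same priority as sparse labels; sparse expert
codes win any residual conflict. Priority: vessels > other > outside.

## Network and training

A compact 3D U-Net implemented directly in numpy (im2col convolutions
with explicit backward passes, verified against finite differences):
two input channels (HU-windowed CT, binary heart mask), six softmax
output channels, encoder depth 2, 8 base channels, two 3³ convolutions
per level with instance normalization and leaky rectifiers (slope 0.1),
2× max-pooling, nearest-neighbour upsampling with skip concatenation,
and a 1³ output convolution initialized small so the network starts near
uniform class probabilities. Instance normalization, the gentle output
initialization, a warm-up/step-decay learning-rate schedule, and global
gradient-norm clipping (at 5) are all there for the same reason: the
masked Dice loss on severely imbalanced classes otherwise collapses onto
the dominant background class.

The loss is soft multi-class Dice over supervised voxels only,
`D_c = 2Σ(p_c·y_c) / (Σ_sup p_c + Σ y_c + ε)` with ε = 10⁻⁶, averaged
over the classes present among supervised voxels in the batch (classes
with no ground-truth voxels are skipped to avoid 0/0); the loss is
`1 − mean_c D_c`. Gradients are exactly zero with respect to
probabilities at unsupervised voxels — this masking property is tested
as an invariant. Within a batch the Dice overlap is pooled across
samples, which damps the gradient variance of classes with few voxels.

Training samples patches centred class-balanced over the in-heart
supervised classes (otherwise LM, with the fewest labelled voxels, never
anchors a patch and collapses out of the softmax), augmented with random
isotropic rescale (0.9–1.1), integer shifts (≤ 2 voxels), and additive
Gaussian HU noise (σ up to 15 HU); labels transform with
nearest-neighbour interpolation and −1 fill so augmentation never
invents supervision. Optimization is adaptive-moment gradient descent
(Adam, lr 10⁻³ by default; the reference study uses 3·10⁻³, chosen by
pilot for the phantom conditions, where instance normalization keeps it
stable).

The network runs on a *working grid*: the input is mean-pooled by
configurable integer factors (default (1, 2, 2); the reference study
uses (1, 4, 4), i.e. ~2.8 mm in-plane) and the predicted probabilities
are upsampled back to native resolution before the argmax. The
territories being segmented are ≥ 10 mm structures, so the coarse grid
costs little accuracy and makes CPU training a minutes-scale job; the
≥ 130 HU scoring always runs at native resolution. Inference tiles the
volume with 50%-overlap windows and uniform probability averaging, and
voxels outside the heart mask are forced to class 0.

The HU window default is (−200, 1500), spanning soft tissue through
dense calcium; the reference study narrows it to (−100, 300) because on
3 mm gated CCT the anatomy that distinguishes territories (vessels,
blood pool, myocardium) lives entirely in the soft-tissue band, and
calcium saturating at 1.0 loses nothing the scorer needs — scoring never
sees the windowed data.

## The phantom generator

Tests and the acceptance script run on synthetic gated-CCT phantoms with
exactly known ground truth: an ellipsoidal heart (default semi-axes
(42, 25, 25) mm) in a soft-tissue mediastinum with lung background,
(3.0, 0.7, 0.7) mm voxels matching the 3 mm gated protocol, four
parametric coronary courses rendered as thin ~1 mm bright tubes,
calcific lesions as HU plateaus (≥ 130 HU) centred on the courses,
additive Gaussian noise (default σ = 10 HU), and non-coronary
calcified distractors drawn from the clinical false-positive taxonomy
(aortic wall, mitral annulus, pericardium, mediastinal lymph node,
pulmonary trunk).

Ground-truth territories partition the heart by nearest coronary course
(Euclidean, in mm) within a 13 mm capture radius; the remainder, and
always the central blood pool (chambers/aorta — the courses must run
outside it), is the non-coronary "other" region. The ground-truth
Agatston report is *computed*, not asserted: the scoring engine runs on
the noiseless rendering with the true territory map, so the oracle and
the implementation can only agree if the whole chain is consistent; an
independent brute-force enumerator guards against a common-mode bug.

Design choices made for testability rather than realism:

- Lesions are HU plateaus, not gradients, so per-slice peak-HU cofactors
  are analytically predictable (noise can still push a peak across a
  cofactor edge — the residual over-scoring this causes on noisy data is
  a real property of Agatston scoring, and the phantom keeps it).
- Tissue HU levels are idealized (myocardial compartment at 0 HU, blood
  pool 45, vessels 50, soft tissue 40, lung −800): bright-structure
  extraction inside the heart then behaves qualitatively as on real
  scans (thin coronary tubes vanish under opening, thick structures
  survive).
- Randomized datasets draw roughly one third of scans lesion-free
  (screening-style case mix), 1–6 lesions otherwise with plateaus
  160–900 HU and radii 1.4–4 mm, distractors independently per kind, and
  mild jitter of heart pose and size. Per-scan seeds derive from one
  master seed; everything is bit-reproducible.

What the phantom does **not** emulate: real myocardial texture, motion
or beam-hardening artefacts, partial-volume gradients at lesion edges,
anatomical variation of vessel courses beyond affine jitter, or
contrast-enhanced acquisitions. Passing the end-to-end criteria
therefore demonstrates that the method's machinery (sparse-label masked
training, territory extrapolation, deterministic scoring, non-coronary
exclusion) works as specified — not that the shipped tiny network would
reach clinical accuracy on patient data, which in the source setting
required hundreds of real scans and GPU-scale training.

## The reference study

`pipeline.reference_study(seed)` is the scaled-down end-to-end
experiment: 24 training phantoms (one third carrying dense coronary
course labels, mirroring a small fully-annotated subset of the training
data), 25 held-out phantoms, 55 epochs × 10 steps × batch 4 on the
(1, 4, 4) working grid — a few minutes on one CPU. It reports:

- held-out risk-category agreement with a Wilson 95% CI, and Cohen's
  kappa of the 5×5 category table;
- per-class Dice **over the labelled voxels** of the held-out scans'
  supervision volumes (what masked training can honestly claim, and the
  only Dice measurable in the real setting, where no dense territory
  ground truth exists either), and, as a diagnostic, per-class Dice
  against the full phantom territory maps — the latter is systematically
  lower because the capture-radius boundary between a territory and the
  unsupervised interior is not identifiable from sparse labels;
- the full score-agreement suite (Bland–Altman with 1.96·SD limits using
  the n−1 standard deviation, Pearson r, two-sample Kolmogorov–Smirnov
  with the asymptotic p-value).

Problem sizes in the tests and acceptance script (phantom counts,
epochs, working grid) are the package's reference configuration, chosen
by pilot so that a laptop-class CPU reproduces the study in minutes.

## Known limitations

- Majority-vote vessel attribution can flip a lesion that genuinely
  straddles two territories; only per-vessel subtotals are affected, the
  total is not.
- Noise-inflated peak HU at cofactor edges biases scores slightly
  upward on noisy data (visible in the phantom Bland–Altman mean
  difference).
- The numpy network is single-threaded and CPU-bound by design; it is a
  faithful but small instance of the architecture, not a performance
  implementation.
- DICOM support is read-only and assumes axial series with uniform slice
  spacing and rescale tags present.
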