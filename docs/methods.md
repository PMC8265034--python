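# Methods

This note documents the models, numerical choices and limitations of
`mrflesion` — what each stage assumes, which knobs matter, and what the
synthetic phantoms can and cannot tell you about real patient data.

## Signal model

Fingerprints follow a perfectly spoiled gradient-echo recursion with
slice-shuffled inversion-recovery preparation. Every frame's repetition
opens with a 180° inversion; the longitudinal state recovers for the frame's
inversion delay TI, the slice is excited with effective flip angle
`b1 · α_i`, and the remainder of the TR relaxes toward equilibrium. With
`z_i` the longitudinal state (in units of M0) just before frame *i*'s
inversion:

    Mz⁻(i)  = 1 − (1 + z_i) · exp(−TI_i / T1)
    S_i     = |Mz⁻(i)| · |sin(b1 α_i)| · exp(−TE_i / T2*) · M0
    z_{i+1} = 1 − (1 − Mz⁻(i) cos(b1 α_i)) · exp(−(TR_i − TI_i) / T1)

With inversion disabled the two recovery segments concatenate into ordinary
saturation recovery over the full TR.

The per-frame inversion delay is essential, not decorative: at repetition
times of 3.5–6.4 s, a model that only relaxes between frames lets every
T1 ≲ 1 s recover completely each TR — adjacent short-T1 dictionary atoms
then differ at the 10⁻⁵ level and T1 below ~700 ms is unidentifiable in
principle. Sampling the inversion-recovery curve at delays spanning tens of
milliseconds to seconds (as slice-shuffled IR-EPI does physically) restores
T1 sensitivity across the whole 300–3500 ms dictionary range.

Out of scope: EPI k-space sampling and distortion, slice profiles, B0
off-resonance, flow, and magnetization transfer.

### Default schedule

35 frames. Flip angles follow a smooth two-cycle raised-cosine envelope
rescaled to attain 34° and 86° exactly. TE takes the 35 linearly spaced
values in 16–76.5 ms and TR the 35 linearly spaced values in 3530–6370 ms
(ascending); each frame's TI is `(rank + 0.5)/35` of its TR.

The *assignment* of TE values and TI ranks to frames uses a frozen pair of
permutations chosen by a one-time discrete search (2-opt descent on a
differential proxy) minimizing the worst-case alignment between the T2*
signal-derivative direction and the span of the T1 and B1 derivative
directions over the dictionary domain. The rationale: with smooth monotone
orderings, a long-T2* signature (a small tilt across the TE ramp) is nearly
collinear with off-grid T1 residuals, and matching trades T2* errors of
20–30% against them; with the de-correlated orderings the measured
worst-case matching error over 10 × 1000 random draws is 4.5%, close to the
half-grid-step bound of ~2.5%. Custom protocols can be loaded from a
plain-text table (`frame, flip_deg, te_ms, tr_ms[, ti_ms]`).

## Dictionary reconstruction

Grids are geometric with exactly 5% relative steps: T1 300–3500 ms
(52 values), T2* 10–2500 ms (115 values); the last entry may exceed the
upper bound by less than one step so the range is covered. B1 scale is
0.6–1.4 in steps of 0.1 (9 values): 53 820 atoms. Atoms are simulated at
M0 = 1, L2-normalized, and stored in float64 — adjacent long-TR/short-T1
atoms differ below float32 inner-product resolution. Matching maximizes the
normalized inner product, is invariant to positive scaling of the input,
breaks ties toward the lowest atom index, and is chunked over voxels purely
for memory (results are independent of chunk size; an exhaustive-search
oracle test enforces this). `m0` is reported as the projection coefficient
onto the unit-norm best atom; all-zero fingerprints return a flagged
all-zero result. B1 is matched independently per voxel, with no spatial
regularization.

## MPPCA denoising

2-D sliding windows (default 5 × 5 in-plane; slices are 2 mm thick and the
network is 2-D, so no through-slice windowing) form `(25 × 35)` Casorati
matrices. For each window the Gram matrix of the smaller dimension
R = min(N, M), scaled by L = max(N, M), is eigen-decomposed. With
eigenvalues λ₁ ≥ … ≥ λ_R, candidate signal rank p is accepted at the first

    (λ_{p+1} − λ_R) / (4 √((R − p)/L))  ≤  mean(λ_{p+1} … λ_R) + 10⁻⁸ λ₁

i.e. the remaining bulk's width fits inside the Marchenko–Pastur support for
the variance estimated from its mean; the round-off floor keeps exactly
noiseless (zero-bulk) windows from being over-ranked. Noise variance is the
bulk mean. Suppressed components are projected out; overlapping windows are
averaged with uniform weights (`mode="center"` writes back only the center
voxel). Negative reconstructed values are clipped to zero (magnitude data)
and counted. On unit-variance Gaussian noise the median σ estimate is
0.96–0.99; Rician noise-floor (bias) correction is deliberately not
performed.

## Digital brain phantom

The phantom supplies every ground-truth map: T1, T2*, M0, B1+, soft
NAWM/GM/CSF probabilities, a binary lesion mask, and the brain mask.

* **Geometry** — concentric ellipsoids: brain envelope, an in-plane
  morphological shell of ~3 voxels as the GM ribbon, interior WM, central
  ellipsoidal CSF ventricles. Default matrix 240 × 240 at 1 × 1 mm in-plane,
  2 mm slices; tests use a reduced 64 × 64 matrix.
* **Tissue values** (typical 3 T literature values, all inside the
  dictionary ranges, configurable): NAWM T1/T2* 850/50 ms, GM 1400/55 ms,
  CSF 3300/1500 ms; M0 0.75/0.85/1.0 a.u.
* **Probability maps** — Gaussian blur (σ = 1 voxel in-plane) of the hard
  labels, renormalized to sum to 1 inside the brain; emulates the soft 0–100%
  output of a tissue segmenter and creates partial-volume boundaries.
* **Quantitative maps** — partial-volume mixing is done in relaxation-*rate*
  space (1/T weighted by the probabilities, then inverted). Rates add across
  compartments; mixing the times linearly would let a thin CSF rim dominate
  the white-matter T2* distribution and break the lesion-hyperintensity
  contract at the class boundaries.
* **Lesions** — Poisson count (default mean 8) of ellipsoidal blobs with a
  plateau-cosine radial profile (half-height at the drawn radius, default
  2–10 in-plane voxels), placed in deep WM with a minimum separation so
  components remain countable, never overlapping CSF. Each lesion multiplies
  T1 and T2* by 1 + e with e ~ U(0.10, 0.60), rolled off smoothly at the rim.
  The paper-scale lesion size/count distribution is unreported anywhere, so
  these are exposed defaults, not measurements.
* **B1+ field** — a smooth low-order polynomial (linear + bilinear +
  quadratic terms with seeded coefficients), clipped to the dictionary's
  0.6–1.4 range.
* **Noise** — Rician: each magnitude value v becomes √((v+g₁)² + g₂²) with
  g₁, g₂ ~ N(0, σ²) and σ = (mean within-brain first-frame signal)/SNR,
  default SNR 40. Background acquires the expected Rayleigh floor.
* **Annotation emulation** — `perturb_lesion_mask` jitters the mask boundary
  by adding a smooth random field to its signed Euclidean distance and
  re-thresholding; the internal scale (1.26 voxels at severity 1) is
  calibrated so a severity-1 perturbation of default phantom lesions lands
  near the ~0.68 dice typical of repeated human annotations of MS lesions.
  Dice decreases monotonically in expectation with severity; severity 0 is
  the identity.

All randomness flows through seeded, per-component `SeedSequence` streams:
the same seed gives a bit-identical phantom, and changing e.g. the lesion
count leaves the B1+ field untouched.

**What passing tests do and do not show.** The phantom has realistic
adjacency (lesions near GM, partial-volume rims, B1 gradients) and a
voxel-wise exact forward model, but real MRF-EPI data additionally contain
EPI distortion, motion, coil shading, non-Rician parallel-imaging noise,
pathology heterogeneity and imperfect manual annotations. Results on the
phantom demonstrate *self-consistency* of the pipeline — that the network
can invert the forward model and localize lesions whose only signature is
elevated relaxation — not clinical performance.

## Lesion-probability U-net

2-D encoder–decoder with encoder depth 3, two 3 × 3 conv + ReLU layers per
resolution level, 2 × 2 max-pooling, nearest-neighbour upsampling, channel
concatenation skips, and a linear 1 × 1 output head. Channel width starts at
`base_channels` (default 32; scaled-down runs use 8) and doubles per level.
The implementation is plain NumPy with explicit im2col convolutions and
hand-written backpropagation (verified against directional numerical
derivatives), plus Adam. Everything is float32 except loss computation.

Inputs are the 35 magnitude frames scaled by the per-case mean within-brain
signal; targets are T1/3500 ms, T2*/2500 ms, the two tissue probabilities,
and the binary lesion mask — all O(1), which an unweighted multi-channel
loss requires. The final activation is linear: probability channels are
clipped to [0, 1] only at evaluation, so the lesion-probability background
stays non-zero and threshold sweeps remain meaningful.

Losses: MSE, MAE, log-cosh (LCL, computed stably as
|x| + log1p(e^(−2|x|)) − log 2), and soft dice
(1 − (2Σpt + ε)/(Σp + Σt + ε), ε = 10⁻⁶, per channel). Multi-channel losses
average channels with equal weight.

Training is patch-wise: slices whose in-slice lesion volume reaches 100 µl
(50 voxels at 1 × 1 × 2 mm — the configured threshold is interpreted as
microliters, since 100 ml would exceed any plausible total lesion load) are
listed `augment_factor` = 5 times per epoch; each listed slice contributes
`patches_per_slice` random patches (defaults 64 patches of 64 × 64; the
patch stream is fully seeded and reproducible). Optimizer is Adam — the
community default for U-nets — at learning rate 1e-4 (default). Per epoch
the mean loss and, when validation cases are supplied, the lesion-channel
dice at the 33% threshold are recorded; the best-validation weights are
restored at the end. Non-finite losses abort with a diagnostic. After
training, a lesion channel that is empty at the 33% threshold on the
validation cases while their reference masks are not is flagged as
*converged to empty prediction* — the all-zero local minimum that several
loss variants fall into. In this synthetic setting LCL-1 and MAE-1 collapse
this way; DICE-1 with a linear head instead inflates its predictions
without useful localization, so the collapse demonstration uses LCL-1.

Inference is whole-slice: slices are reflect-padded to a multiple of 2³,
pushed through the network in one pass and cropped.

### Scaled-down study conditions

Tests and the training acceptance check run a reduced protocol chosen to fit
a single CPU: five 64 × 64 × 6 phantoms (four training, one held out),
lesion radii 2.5–5 voxels, Poisson mean 6, SNR 40; ground-truth targets from
the phantom; 24 × 24 patches, 48 per slice, batch 4, learning rate 3e-3,
base width 8, 20 epochs. Lesion onset (the paper-like phase where tissue
channels converge first and the lesion channel only later starts producing
probability mass) is governed by the number of optimizer steps and its
timing varies two- to three-fold across initialization seeds, so the small
patches and batch exist purely to buy steps per second and the per-slice
patch count is sized so even late-onset seeds converge within the 20
epochs; onset typically lands between epochs 4 and 17, held-out lesion dice
then exceeds 0.9, and a lesion-free phantom yields an empty binarized mask.
Per-epoch validation with best-checkpoint restoration matters here: the
small-batch trajectory occasionally destabilizes in a late epoch and the
checkpoint shields the evaluation from it. At full scale the paper-style
64 × 64 patches and batch 64 are the defaults.

## Evaluation metrics

* Dice 2|A∩B|/(|A|+|B|); both-empty = 1 by convention, so healthy subjects
  with empty predictions score perfect agreement.
* Binarization is closed (≥), making the printed 33% lesion and 80% tissue
  thresholds inclusive.
* Ground-truth lesions are 26-connected components; a lesion is *detected*
  if the predicted mask overlaps it in ≥ 1 voxel — the most permissive
  criterion, consistent with detection rates exceeding dice.
* Threshold sweeps report dice and detection rate over a strictly
  increasing threshold list plus the argmax-dice threshold; mask volume and
  detection rate are monotone non-increasing in the threshold.
* Per-lesion statistics: volume in µl (voxel count × voxel volume),
  per-lesion dice computed inside the component's bounding box dilated by
  2 voxels (a documented convention; the local box prevents neighbouring
  lesions from diluting each other), predicted volume as the sum of
  overlapping predicted components, and the detection flag.
* `mean_relative_deviation` is mean |test − ref|/ref over a mask, used for
  the quantitative maps.
* `lesion_profile` reports voxel-wise percent elevation of T1/T2* over the
  mean NAWM value and extracts horizontal/vertical cuts through a single
  lesion's centroid alongside the predicted probability.

## Orchestration

`run_experiment` chains simulate → denoise → dictionary → reconstruct →
train → evaluate. Every stage writes under the run directory, records a
content hash of its configuration, and is skipped when the hash matches —
so the phantoms and the 53 820-atom dictionary are generated once and
reused when several network variants are trained on the same dataset. Stage
seeds derive deterministically from the single global seed via hashed
`SeedSequence` spawn keys; identical config + seed reproduces evaluation
CSVs bit-for-bit. Volumes are NIfTI (float32 maps, uint8 masks, voxel size
in the affine), tables CSV, summaries JSON, configuration YAML.

## Known limitations

* The signal model is a voxel-level recursion; nothing in the image domain
  (distortion, blurring, ghosting) is simulated, so the network never has to
  learn the distortion correction that real processing includes.
* The dictionary's printed 5% step is taken as the grid step, implying a
  ≤ ~2.5% nearest-neighbour quantization error plus cross-parameter leakage;
  measured worst-case off-grid error is ~4.5%.
* Matching carries no spatial prior on B1+, and MPPCA rank selection is
  per-window; both can flicker at tissue boundaries.
* The NumPy U-net is CPU-bound; full-scale (240 × 240, base width 32, 100
  epochs) training is possible but slow — the package's scaled-down
  protocol is the supported regime for experimentation.
* Collapse behaviour of loss variants is reproduced qualitatively (which
  losses fail), not quantitatively (at which epoch), and DICE-1's failure
  mode differs in kind from the all-zero collapse seen with LCL-1/MAE-1.
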