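# Methods

## Problem and model

The package implements a reconstruction-based anomaly detector for stacks
of 2-D grayscale slices (axial chest CT is the motivating modality). The
premise is the usual one-class setting of CT screening: normal anatomy is
abundant, lesions are rare and heterogeneous, so the network is trained on
normal slices only and an abnormality is anything it cannot reproduce.

The network is a vector-quantized autoencoder with an inner one-class
bottleneck:

    x --Encoder1--> z_e(x) --Encoder2--> z(x) --Decoder2--> z_d(x)
      --quantize--> z_q(x) --Decoder1--> x̂

* **Encoder 1 / Decoder 1** form the outer autoencoder. The latent map
  `z_e(x)` has side `input_size/4` and `D` channels (full-scale defaults:
  64×64×128 for 256×256 inputs, codebook K=128, D=128).
* **Quantization** replaces each channel vector of the decoded map with its
  nearest codebook entry (Euclidean argmin, ties to the smallest index).
  The argmin is not differentiable; gradients use the straight-through
  estimator, and the codebook itself learns from a stop-gradient split:
  the codebook term `‖sg[z_d]−e‖²` updates only the embeddings, the
  commitment term `λ‖z_d−sg[e]‖²` (λ=0.25) updates only the encoder side.
* **Encoder 2 / Decoder 2** compress the latent map to a single vector
  `z(x)` (dimension ≪ map size) and expand it back. The one-class (SVDD)
  objective pulls `z(x)` toward a hypersphere center `c`; because the
  redundant spatial map is squeezed through this bottleneck, abnormal
  structure has nowhere to hide and fails to reconstruct.

Training is staged:

1. **Stage 1** — outer autoencoder + codebook only, with the inner pair
   bypassed (`z_d ≡ z_e`). Loss: `‖x−x̂‖² + (1−MS-SSIM) + codebook +
   commitment`.
2. **Stage 2** — full network, plus a latent-consistency term
   `‖z_e−z_d‖²`; no one-class term yet. Afterwards the center `c` is set
   to the mean `z(x)` over the training slices.
3. **Stage 3** — full loss with `‖z(x)−c‖²` added; `c` is replaced at the
   end of every epoch by the mean of that epoch's latents (it is data, not
   a trained weight, and receives no gradient).

The slice anomaly score is `S(x) = ‖x−x̂‖² + ‖z(x)−c‖²`; an examinee's
representative score is the maximum over their slices. The classification
threshold maximizes the Youden index over representative scores (reported
as an in-sample threshold), and ranking quality is summarized by the
trapezoidal AUC. A plain convolutional VAE trained with the same
reconstruction terms plus a KL prior serves as the comparison baseline,
scored by its reconstruction error.

## MS-SSIM

All losses and the SSIM fidelity metric share one windowed-statistics
implementation (Gaussian 11×11, σ=1.5, valid-mode windows; a uniform
window is available for oracle tests). Stabilizers δ1=1e-4, δ2=9e-4,
δ3=4.5e-4 — the standard SSIM constants for a [0,1] dynamic range. The
multi-scale index is the product over scales `j=0..M` of the
window-averaged contrast and structure terms (2×2 average-pool halvings
between scales) times the luminance term at the coarsest scale.

Two structure forms are provided. `standard` (default) is the
covariance-normalized term `(σ_xy+δ3)/(σ_x σ_y+δ3)`; with δ3=δ2/2 the
single-scale product L·C·S then reduces exactly to the textbook SSIM
formula (verified against scikit-image to machine precision). `literal`
reproduces a printed variant that divides by `(σ_x+σ_y+δ3)`; it is kept
for comparison but is dimensionally inconsistent and not used in losses.

`M` auto-reduces so the coarsest scale still fits one window
(`side >> M ≥ window`): 256-pixel inputs use M=4, the 64-pixel benchmark
M=2, each with a logged warning. Variances are clamped at zero before the
square root and the square root's derivative is bounded at the origin, so
zero-variance (constant) windows are exact and finite in the backward
pass.

## Synthetic phantom generator

The private screening database the method was designed around is not
available, so all experiments run on seeded synthetic chest phantoms: an
elliptical body wall (intensity 0.6), two darker lung fields (0.2) whose
cross-section waxes and wanes along the stack, vessel-like bright
random-walk curves and dots (0.75, 12 per slice, resampled every slice),
Gaussian smoothing and additive noise (σ=0.02), clipped to [0,1]. Per-case
anatomy (ellipse geometry, slice count 8–12) derives from `(seed,
case_index)`, so datasets are bit-reproducible and order-independent.

Abnormal cases take a normal volume and inject one lesion on three
contiguous slices, placed uniformly where a disk of the requested radius
fits inside the lung on every affected slice: bright smooth **nodules**
(Δ=+0.4, r=6), textured **consolidations** (Δ=+0.25), and structure-free
dark **voids** (Δ=−0.15, r=7) that also erase vessel texture, emulating
the black, structureless appearance of emphysematous lung. Slice flags
and masks accompany every volume; fidelity statistics for abnormal cases
are pooled over flagged slices only.

What the phantoms do *not* model: Hounsfield calibration, 3-D lesion
morphology, slice-thickness effects, scanner noise spectra, and the
anatomical diversity of real examinees. Passing the benchmark therefore
demonstrates that the implementation learns and separates as designed,
not that the trained weights transfer to real CT.

## Scaled-down benchmark

Full-scale training (256×256, 1200 cases, 200 epochs per stage, batch 64,
Adam 1e-4) is a GPU workload. The repository's experiments and acceptance
script instead pin one reduced configuration (`vqsvdd.benchmark`): 64×64
phantoms, 20 normal training cases (~200 slices), held-out 12 normal + 12
abnormal cases (nodules and voids alternating), reduced widths (D=16,
K=32, inner latent 1024 — a fourfold compression of the 16×16×16 latent
map), 10 epochs per stage. The optimizer settings for this regime are the
package's own choice: at ~200 slices a batch-64 epoch is only 4 updates
and the full-scale 1e-4 step would leave the network at initialization,
so the benchmark trains with batch 4 and Adam 3e-3 (~50 updates per
epoch). The VAE baseline gets the same total epoch budget (30 epochs) in
a single stage at batch 16.

Two caveats a reader should know. First, examinee-level AUC on 12 vs 12
held-out cases is a coarse statistic (one rank swap moves it by 1/144)
and varies noticeably between seeds. Second, the anomaly-suppression
mechanism — a network so specialized to normal anatomy that it refuses to
reproduce lesions — only partially emerges at this training budget; a
briefly-trained autoencoder is still a fairly generic compressor, and the
smooth synthetic lesions are easy for it to reproduce, which caps the
separation the benchmark can show.

## Numerical and design choices

* **Reconstruction L2** is the summed squared error per image (the norm as
  printed), not the pixel mean; this sets its scale relative to the
  MS-SSIM term and the one-class distance.
* **Leaky rectifiers** (slope 0.1) are used throughout instead of plain
  ReLU: with a bias-free one-class objective and large early gradients,
  plain ReLU stacks in the inner encoder reliably died to a constant
  latent (the classic SVDD collapse), which leaky units prevent. No
  normalization layers are used in Encoder 2 for the same reason.
* **Encoder 2's output is linear** (no activation): a bounded activation
  would let the hypersphere shrink by saturation rather than by learning.
* **Codebook initialization** is uniform in [−1/K, 1/K]; quantization ties
  break toward the smallest index, making runs bit-reproducible.
* **Center updates** reuse the latents collected during the epoch rather
  than a fresh full-dataset pass (`initialize_center` provides the
  two-pass variant).
* **Min–max scaling is per case volume**, not per slice, so one
  examinee's tissue keeps consistent gray levels across slices.
* **Bicubic resize** uses the Keys a=−0.5 kernel (Pillow's BICUBIC).
* **Youden threshold** scans midpoints between consecutive distinct
  scores plus sentinels beyond both extremes; ties in J break toward
  higher specificity (screening favors fewer false alarms), and a case is
  abnormal only when its score is strictly above the threshold.
* **AUC ties** use the Mann–Whitney half-credit convention, so the
  trapezoidal curve and the pairwise-concordance count agree exactly.
* **Paired t-tests** across folds use df = folds−1; identical per-fold
  metrics are reported as t=0, p=1 rather than an undefined statistic.

## Known limitations

* The figure-only layer annotations of the original architecture are not
  recoverable; the reference stack honors all stated constraints (¼-size
  latent map, 128×128 codebook, compressed inner latent, residual blocks)
  but is not claimed to be layer-identical.
* At the benchmark's budget the inner one-class distance is a weak,
  high-variance signal; the anomaly score is dominated by the
  reconstruction term.
* The in-sample Youden threshold is optimistic by construction; it is
  labelled as such in every report.
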