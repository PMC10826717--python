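# Methods

`tieqpi` implements a complete, self-contained simulation and analysis
chain for single-shot quantitative phase imaging (QPI): a scalar
optical forward model produces through-focus intensity stacks of
transparent phantoms, a transport-of-intensity (TIE) solver recovers
quantitative phase from three of those frames, and a conditional GAN
trained on (defocused intensity, TIE phase) pairs learns to produce a
phase map from a *single* intensity frame taken anywhere in the
recorded defocus range.  A metric suite (MSE, PSNR, UIQI, SSIM) scores
both reconstruction routes against ground truth across the defocus
sweep.

## Optical forward model

Objects are thin complex transmittances u(x, y) = A e^{iφ} sampled on
a uniform grid whose pitch is the camera pixel divided by the
magnification (3.45 µm / 40 = 0.08625 µm at the default 40×/0.65 NA
configuration; λ = 627 nm; immersion water, n = 1.33).

* **Beads.** A sphere of diameter d at transverse radius ρ has
  projected thickness h(ρ) = 2√((d/2)² − ρ²); the phase is
  φ = 2π Δn h / λ with Δn = n_bead − n_medium (0.35 for polystyrene in
  water, peak 14.03 rad for d = 4 µm), the amplitude e^{−µh/2} for an
  optional intensity attenuation coefficient µ.  The default µ repeats
  the 0.843 µm⁻¹ figure quoted for the immersion water in the source
  protocol; quantitative round-trip validations use µ = 0 because
  polystyrene is transparent at 627 nm and a uniform medium loss
  cancels in the transport equation anyway.
* **Cells.** A white-noise texture is hard band-limited at 1/ℓ (ℓ =
  `smoothness_um`), scaled into user-set cytoplasm and nucleus phase
  ranges, and confined to a soft super-Gaussian cytoplasm mask with a
  blended denser nucleus.  The final band-limiting filter is followed
  only by a DC lift, so the generated phase is simultaneously
  non-negative and strictly band-limited.  Fields are deterministic
  functions of their seed.

Propagation between defocus planes uses the exact angular-spectrum
transfer function H = exp(i2π dz √((n/λ)² − u² − v²)) with evanescent
components set to zero; a paraxial (Fresnel) variant is selectable.
Stack recording pads the field to twice its size (edge padding) before
the FFT to suppress periodic wrap-around, and optionally applies
seeded Poisson shot noise.  Propagation without padding is unitary:
power conservation and composition hold to 1e−9 whenever the sampled
spectrum lies inside the propagating band.

## TIE phase retrieval

The transport of intensity equation for a paraxial beam,
∂I/∂z = −(λ/2π) ∇·(I ∇φ), is solved with Teague's auxiliary-function
method: with f = −(2π/λ) ∂I/∂z, two spectral Poisson solves give
φ = ∇⁻²[∇·((1/I) ∇ ∇⁻² f)].  Implementation choices:

* **Wavelength in the medium.** The forward model defocuses inside the
  immersion medium, so the solver uses λ/n.  Omitting the factor biases
  every recovered phase low by exactly 1/n (≈ 25 % in water).
* **Axial derivative.** Central difference (I(z+Δz) − I(z−Δz))/2Δz by
  default; a forward scheme is available.  Against a Richardson-
  extrapolated fine-step (0.01 µm) oracle the central estimate at
  Δz = 1 µm is accurate to < 2 % RMS for smooth phases.
* **Inverse Laplacian.** Division by −4π²(u²+v²) with the DC mode
  nulled (output is zero-mean; TIE determines phase up to a constant)
  and an optional additive regularizer ε for noisy data.  On resolved
  (band-limited) fields it agrees with a dense pseudo-inverse of the
  5-point Laplacian to < 1 %; on white noise the two discretizations
  legitimately differ by ~4 % because their symbols diverge near the
  Nyquist frequency.
* **Boundaries.** Default even-mirror extension (reflect to 2N, FFT,
  crop) — Neumann-like, avoids wrap-around phase artifacts at object
  edges; the vector field inside the divergence gets the matching odd
  extension.  Periodic mode is retained for oracle tests.
* **1/I guard.** The in-focus intensity is clamped below
  `intensity_floor_fraction` × max(I) (default 1e−3) before division.
* **Autofocus.** The Tamura coefficient √(σ/µ) of each frame; a
  pure-phase object is *least* sharp in focus (default `mode="min"`),
  an absorbing object sharpest (`mode="max"`).  Ties break toward
  z = 0.
* **Thickness.** h = λφ/(2πΔn) with the vacuum wavelength.

**Validated accuracy.** A 3 rad Gaussian phase (σ = 5 µm) simulated at
512², defocused ±1 µm, is recovered with < 0.1 % peak error and
windowed SSIM > 0.99.  A 4 µm bead (Δn = 0.35, peak 14 rad) is
recovered with its thickness peak within 10 % of 4 µm for Δz ∈ {0.5,
1, 2} µm **under the paraxial propagator at 0.0431 µm sampling**.  The
bead's edge carries spatial frequencies beyond n/λ; the angular-
spectrum model removes them as evanescent, which is physically correct
but inconsistent with the paraxial transport equation, and the
recovered peak then saturates near 2.8 µm at any sampling.  This is a
real limitation of TIE on steep, high-phase objects, not of the
solver; the paraxial forward model is the self-consistent validation
setting.

## Dataset construction

Every defocused frame of a stack is paired with that stack's single
in-focus TIE phase map — the pairing that teaches defocus robustness.
Intensity tiles are min–max normalized to [−1, 1] per tile; phase
tiles are normalized with one *dataset-global* (min, max) stored in
the dataset and the model checkpoint.  A per-tile phase normalization
would destroy quantitativeness at inference time, where no per-tile
record exists for an unseen frame; the global record is what converts
the tanh output back to radians.  Splits are disjoint by source
object (never by frame), sized exactly as requested by truncating the
last dealt source, and reproducible from the seed.

## Conditional GAN

The generator is a U-Net: 4×4 stride-2 convolutions halving the
spatial size at each encoder stage (64 base channels doubling to a
512 cap at full scale), a mirrored decoder of 4×4 stride-2 transposed
convolutions with skip concatenations, Leaky ReLU (0.2) after every
encoder stage, batch normalization after each layer except the first
and the 1×1 bottleneck, dropout (0.5) in the first three decoder
stages, and a tanh output.  The discriminator is a five-conv PatchGAN
(three stride-2, two stride-1 stages) on the concatenated
(intensity, phase) pair, emitting a sigmoid patch map (30×30 for
256 px tiles, 2×2 for 32 px).

Training follows the paired image-to-image translation recipe: the
discriminator maximizes log D(x, y) + log(1 − D(x, G(x))) on a
combined real/fake batch; the generator minimizes the non-saturating
adversarial loss −log D(x, G(x)) plus λ_L1 ‖G(x) − y‖₁ with λ_L1 = 100
(settable to 0 to recover the bare adversarial objective).  Adam uses
the published learning rate 1e−4 and batch size 4 with momentum
(0.5, 0.999).  The noise input of the conditional objective is
realized as decoder dropout rather than an explicit noise vector.

Because no GPU tensor library is assumed, the layers (im2col
convolution, transposed convolution as its exact adjoint, batch norm,
dropout, Adam) are implemented directly in numpy with hand-written
backward passes; all gradients are verified against numerical
differentiation in the test suite.  Training is single-threaded
deterministic for a fixed seed.

**Inference mode.** Batch normalization uses the statistics of the
presented input (the pix2pix convention, equivalent to instance
normalization at batch size 1) with running averages untouched, and
dropout is off unless noise mode is requested.  Early in training the
running averages lag the activation distribution and eval-mode outputs
collapse toward a constant; input statistics avoid that failure mode
and keep inference deterministic.  The checkpoint retained is the
epoch with the best validation SSIM.

## Metrics

MSE, PSNR = 10·log₁₀(L²/MSE), UIQI (correlation × luminance ×
contrast, stabilized variants available for degenerate windows), and
SSIM with c₁ = (0.01 L)², c₂ = (0.03 L)².  Both a global whole-image
value and an 8×8 sliding-window mean are provided; the windowed value
is the default report.  Variance is population (divide by N) by
default with a sample-variance flag (which makes windowed SSIM agree
with scikit-image's uniform-window implementation to 1e−7).  Phase
maps are rendered to the 0–255 scale with the *ground truth's* (min,
max) before scoring, so MSE/PSNR magnitudes are on the familiar 8-bit
scale and any radian-scale disagreement counts as error.

The defocus sweep treats each interior plane z of a stack as a trial
focus: conventional TIE uses the three frames centred there, the
network maps the single frame at z, and both are scored against the
in-focus TIE ground truth.

## Problem sizes

Full-scale training (256 px tiles, 700 pairs, 200–300 epochs) is
supported by the code but the shipped validation profiles are scaled
down so the whole chain runs on one CPU in minutes, as pure-numpy
training throughput dictates:

* quick profile: 64 px tiles, 50 training pairs, 5 epochs, 16 base
  channels;
* analog profiles (bead and cell evaluations): 64 px tiles at 20×
  sampling (0.1725 µm pitch, 11 µm field), 24 objects × 9 planes →
  150/24/36 pairs, 25 epochs;
* defocus sweep: 20 held-out cell stacks, 9 planes each.

At these sizes the cell run reaches held-out windowed SSIM ≈ 0.87 and
8-bit MSE ≈ 110 against TIE ground truth, and the sweep reproduces the
qualitative full-scale picture: TIE similarity is 1.0 at focus and
collapses off focus (range ≈ 0.98), while the single-shot network
stays within a ≈ 0.1 band across ±60 µm.

## What the synthetic conditions do and do not show

The phantoms share the experiment's optical constants, defocus
protocol (±60 µm, 15 µm steps), and training recipe, but they are
noise-free by default (Poisson shot noise is available), fully
coherent (no partial-coherence blur from the LED source), aberration-
free, and NA-unlimited.  Real buccal cells are larger, richer in
texture, and imaged through camera MTF and fixed-pattern noise none of
which is modelled.  Passing the suite therefore demonstrates the
internal consistency of the method chain — forward model ↔ TIE ↔
learned inverse — and the qualitative defocus-robustness claim, not
instrument-level performance on clinical samples.

## Known limitations

* TIE thickness on steep high-phase objects is only quantitative in
  the paraxial validation setting (see above); under the full angular-
  spectrum model the evanescent cutoff biases sharp-edge objects low.
* The discriminator, trained real-vs-generated, assigns arbitrary
  (often high) scores to off-manifold inputs such as uniform noise;
  only the real-versus-generated ordering is meaningful.
* Smoke- and analog-scale GANs underfit by construction; their SSIM
  numbers are analogs, not reproductions, of full-scale results.
* Absolute amplitude calibration of inferred phase is limited at
  analog scale: held-out bead peak phase overshoots by ~20 %
  (systematic, defocus-independent), a consequence of input-statistics
  normalization at inference combined with underfitting.  Structural
  fidelity (SSIM) improves with training; the peak-amplitude bias does
  not, and is reported, not asserted, by the acceptance script.
* The inverse Laplacian's spectral symbol differs from the 5-point
  stencil near Nyquist; oracle agreement holds on resolved fields.
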