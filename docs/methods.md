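# Methods

This note records the models, numerical conventions and design
decisions behind `spectralstain`, at the level of detail a maintainer
or reviewer needs to judge what the code computes and what the tests
do and do not demonstrate.

## Data model and calibration

A hyperspectral cube is an `H×W×B` transmittance array bound to a
uniform wavelength grid (nm, both endpoints included). The working grid
is 420–720 nm at 5 nm (61 bands), cropped from a 350–1100 nm 151-band
sensor range. Band indices shown to users are 1-based, so channels
10/11/12 name the 465/470/475 nm bands; pixel coordinates are 0-based,
row-major, origin top-left.

Raw counts are calibrated per pixel and band as

    T = (I_raw/E_raw − I_dark/E_dark) / (I_white/E_white − I_dark/E_dark)

with dark (illumination off) and white (blank slide) references and
per-frame exposures E. A zero denominator is an error naming the first
offending pixel and band. Negative T (raw below dark, possible with
noise) is clipped to 0 so that downstream logarithms stay defined;
values above 1 are kept, because clipping them would destroy the noise
structure around the bright reference. Saturated-pixel handling beyond
this is out of scope. Cubes are stored as multi-page float TIFF (one
page per band) with a JSON sidecar holding `{start_nm, stop_nm,
step_nm}`; reading validates that the page count matches the grid.

## Spectral bases

The identity loss needs the cube collapsed to 3 channels. Three
candidate 3×61 bases are built:

1. **Band selection** — one-hot rows for channels 10/11/12; projection
   equals band slicing.
2. **PCA + LDF** — the first two eigenvectors of the covariance of
   pooled, mean-centred pixel spectra (covariance, not correlation:
   all bands share a physical scale), signs fixed so the
   largest-magnitude coefficient is positive, plus the LDF.
3. **LDF + dye transmittances** — the LDF plus the eosin and
   hematoxylin transmittance spectra obtained from absorbance via
   Beer–Lambert, `T(λ) = 10^(−A(λ))`.

Basis rows are used unnormalised (projection is plain matrix
multiplication); a per-row max-normalisation helper exists for
conditioning experiments. For feeding the 3-channel projection to a
network, each row's output is divided by a fixed bound
`Σ_b |basis[k,b]| · 1.2`, which maps it into the network's [−1, 1]
working range without data-dependent rescaling.

The published LDF coefficients and measured H&E absorbance curves are
not shipped. Stand-ins are provided and labelled as such: smooth
Gaussian absorbance bumps (eosin centred at 525 nm so it renders pink,
hematoxylin at 605 nm so it renders bluish), and a fallback LDF derived
by two-class linear discriminant analysis (scikit-learn, lsqr +
shrinkage) on labelled elastic/collagen spectra sampled from the
phantom generator, unit-normalised and oriented so elastic scores
higher. Real acquisitions should substitute measured spectra through
the documented CSV format.

## Colorimetry

Cubes are rendered to sRGB by
`XYZ = Σ_b S(λ_b) T(λ_b) cmf(λ_b) Δλ`, normalised per channel so a
perfect transmitter (T ≡ 1) lands exactly on the display white point,
then through the standard XYZ→linear-sRGB matrix, gamma encoding, and
clipping to 8 bits. The CIE 1931 2° observer is evaluated from the
Wyman–Sloan–Shirley multi-lobe Gaussian fit (accurate to a few parts
per thousand — well inside the 1-gray-level tolerance the tests use);
the default illuminant is equal-energy, since the microscope LED's
spectrum is acquisition-specific and accepted as a config input.

## Registration

Ground-truth pairs are built by registering the EVG tile (moving) onto
the H&E tile (fixed, via its sRGB rendering): scale/rotation-invariant
keypoints (ORB by default, SIFT optional; the detector is a pluggable
contract), nearest-descriptor matching with Lowe ratio 0.75 and
cross-check, then a 2×3 affine estimated by MSAC — 2000 iterations of
3-point exact fits scored by squared residuals truncated at the inlier
tolerance (3 px default), best model refit by least squares on its
inliers. MSAC is seeded and bit-reproducible. Warping is bilinear with
zero fill. The green/magenta overlay (EVG luminance in green, H&E in
red+blue) gives the standard visual alignment check.

## Networks

Both generators are U-Nets with identical spatial input/output size:
a stride-1 conv stem, `depth` stride-2 conv encoder levels (instance
norm + LeakyReLU 0.2), a bottleneck, and a decoder of nearest-neighbour
2× upsampling, conv, skip concatenation and fusion conv (instance norm
+ ReLU), ending in a 1×1 conv with tanh. They differ only in channel
counts: 61→3 and 3→61. Discriminators are PatchGANs — stride-2 conv
stacks ending in a 1-channel patch-score map. Full-scale defaults are
depth 4 / 64 filters (generators) and 3 levels / 64 filters
(discriminators); the toy preset used throughout the tests is depth 2 /
8 filters and 2 levels / 8 filters. Exact widths, normalisation and
activation choices are standard-practice defaults and fully
configurable.

The layers are implemented directly in NumPy with hand-written
backpropagation (im2col convolutions, instance-norm backward, Adam
with β₁ = 0.5). Layers are functional — `forward` returns `(y, cache)`
and `backward(cache, dy)` returns the input gradient — so one module
can appear at several places in a computation graph, as the generators
do inside the cycle and identity terms. Working precision is float32
(switchable to float64, which the finite-difference gradient-check
tests do); given a fixed seed, data order and thread count, training
histories are bit-reproducible. Convolutions are He-initialised; at toy
widths this keeps the skip connections carrying input structure from
the first forward pass, which empirically helps the adversarial signal
select the correct output polarity (see "Known behaviour" below).

Images enter the networks scaled to [−1, 1]: transmittance by fixed
bounds [0, 1.2], RGB from [0, 255]. The 58 zero channels of the padded
EVG input are appended to the 8-bit image *before* rescaling, so the
padding sits at −1, the dark end of the range. This matters: padding
with mid-range values makes the padded-EVG identity task
distributionally overlap real cubes and teaches the 61→3 generator a
"copy the first three channels" shortcut, which renders fibers as
background (H&E fibers are transparent at 420–430 nm).

## Training

Phase 1 minimises `L_adv + λ·L_cycle + γ·L_identity` with λ = 5.0 and
γ = 0.5, Adam at 2e-4 (full scale), batch size 1 (1–6 supported), one
discriminator and one generator update per batch, no image-history
buffer. Adversarial terms are least-squares: the discriminator
minimises `E[(D(real)−1)²] + E[D(fake)²]`, the generator
`E[(D(fake)−1)²]`. Cycle and identity terms are elementwise L1 with
expectations estimated by batch means. The identity loss is
`MAE(G_EVG→HE(HE_red), HE_org) + MAE(G_HE→EVG(EVG_inc), EVG_org)`,
computed in the [−1, 1] working space. Model selection: when held-out
registered pairs are supplied, the per-epoch checkpoint with the best
validation SSIM is returned; otherwise the final epoch.

Phase 2 re-trains G_HE→EVG alone with MSE on registered pairs at
3e-5 (0.15× the phase-1 rate), initialised from the phase-1 weights;
starting from random weights is an explicit ablation flag, and the
epoch log carries an `init` provenance tag. The phase-1 discriminators
play no role in the phase-2 objective and are discarded.

**Toy preset.** The tests and the `end-to-end-toy` command train at
32×32 with the toy networks, 30 epochs, an unpaired pool of 32 tiles
per domain, phase-1 rate 5e-4 and phase-2 rate 1.5e-4 (the same 0.15
ratio). The higher rate is a toy-scale choice: at ~1000 updates the
full-scale rate leaves the model essentially untrained. A complete toy
run takes roughly a minute on one CPU.

## Synthetic phantoms

The generator fabricates what the pipeline assumes about real data:
random curvilinear elastic and collagen fiber strokes (mutually
disjoint after bounded placement retries; overlapping nuclei occlude
fibers in both the masks and the rendering), elliptical nuclei, and a
61-band cube built by Beer–Lambert mixing
`T(λ) = 10^(−(c_h A_h(λ) + c_e A_e(λ)))` — eosin-dominant
concentrations drawn from *identical* distributions for both fiber
classes (under H&E the classes must be near-indistinguishable),
hematoxylin-dominant nuclei, T ≈ 1 background, multiplicative Gaussian
noise (sd 0.01 by default). Elastic fibers additionally carry a small
smooth multiplicative transmittance bump (4% peak at 560 nm, σ = 25 nm,
capped at 5%) — an invented, documented stand-in for the real elastic
spectral signature that a linear discriminant can exploit; its
amplitude is a config knob. The paired EVG rendering paints the same
geometry with deep blue (40, 40, 120) elastic, orchid (218, 112, 214)
collagen, near-black nuclei and pale background, plus slight sensor
noise; the fiber colors sit inside the HSV mask ranges used by the
metrics (mask recall 1.0 across test seeds). Datasets are written as
`unpaired/{he,evg}`, `paired/{he,evg,masks,transforms}` and a manifest
listing every file with its seed and role; unpaired H&E and EVG pools
use disjoint seed sets, and paired EVG tiles can be perturbed by a
saved random affine for registration testing.

What the phantoms do **not** emulate: optical blur and chromatic
aberration, stain variability between labs, tissue morphology beyond
strokes and ellipses, spatially correlated noise, and any real
elastic-fiber spectroscopy. Tests passing on phantoms therefore
demonstrate the correctness and internal consistency of the pipeline,
not clinical performance.

## Evaluation

MSE is averaged over all `H·W·C` elements, RMSE is its square root,
PSNR is `10·log10(255²/MSE)` with an infinity sentinel (printed as
`inf`) for identical images. SSIM is computed per channel from *global*
image statistics — mean, variance and cross-covariance of all pixels —
as `(2μ_aμ_b+C1)(2cov+C2) / ((μ_a²+μ_b²+C1)(σ_a²+σ_b²+C2))` with
`C1 = (0.01·255)²`, `C2 = (0.03·255)²`, `C3 = C2/2`, unit exponents,
then averaged over R, G, B. The conventional 11×11 windowed SSIM is
available separately but is not the headline metric. Fibrous pixels are
those inside either HSV box [110, 50, 50]–[170, 255, 255]
(blue-to-pink) or [120, 0, 55]–[150, 30, 90] (near-black variants),
hue on the 0–179 integer scale — the only scale on which these bounds
are meaningful (blue ≈ 120, pink ≈ 150–170). The fibrous mask is taken
from the ground-truth EVG image by default (it defines where fibers
truly are); a union-with-prediction option exists. Dataset reports
average per-image metrics (not pooled pixels), skipping infinite PSNRs.

## Known behaviour and limitations

* At toy scale the unsupervised phase is strongly seed-dependent: the
  cycle loss is polarity-blind (a color-inverted generator pair is
  cycle-consistent), and with λ = 5 the cycle term can lock in an
  inverted mapping that only the weak toy discriminators oppose. Some
  seeds therefore converge to visibly wrong color polarity within 30
  epochs. Validation-SSIM model selection mitigates but does not
  eliminate this. The directional comparisons in the test suite
  (identity loss on/off; phase 2 versus phase 1; pretrained versus
  random refinement init) are accordingly checked as inequalities of
  means across three seeds at the toy conditions above. The two
  refinement orderings are robust seed by seed; the identity-loss
  ordering holds in the mean but with a small margin at this scale.
* Problem sizes used by the test suite and acceptance script: 32×32
  tiles for training runs, 64×64 for the PCA variance measurement,
  128×128 for feature-based registration (ORB needs texture), pools of
  32 unpaired tiles, 3 paired tiles, 4 test tiles.
* The NumPy networks are CPU-only and intended for correctness and
  small-scale experiments, not full-scale training.
* Registration assumes an affine relationship between the two
  acquisitions; nonrigid tissue deformation is out of scope.
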