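# Methods

This note documents the models, algorithms and numerical choices behind
`artmech`: a dispersed-fibre hyperelastic description of arterial tissue
whose material parameters can either be identified classically from
mechanical tests or predicted by a residual-network encoder from
collagen-orientation imaging and histology.

## Constitutive model

Arterial media is modelled as an incompressible hyperelastic solid with
an isotropic neo-Hookean ground matrix and two symmetric collagen fibre
families with mean in-plane directions

    M4 = (cos a, sin a, 0),   M6 = (cos a, -sin a, 0),

where `a` is the mean fibre angle from the circumferential axis.
Orientation statistics enter through the generalized structure tensor

    H_i = A I + B M_i (x) M_i + (1 - 3A - B) M_n (x) M_n,
    A = 2 k_op k_ip,   B = 2 k_op (1 - 2 k_ip),

with in-plane dispersion `k_ip` in [0, 1/2] (1/2 = planar isotropy) and
out-of-plane dispersion `k_op` in (0, 1/2] (1/2 = all fibres in the wall
plane, 1/3 = 3D isotropy).  The coefficients satisfy three pinning
identities used as tests: trace(H) = 1, H positive semidefinite over the
admissible box, and H_nn = 1 - 2 k_op.  The strain energy is

    Psi = c/2 (I1 - 3)
        + sum_{i=4,6} k1/(2 k2) { exp[ k2 (I_i* - 1)^2 ] - 1 },

with the generalized invariant I_i* = tr(C H_i) and stress-like
parameters c (matrix) and k1 (fibres) in kPa, dimensionless stiffening
exponent k2.  Table units are not stated in the source data; kPa is
assumed throughout.  Two conventions:

- **Fibre tension switch** (default on, configurable): the fibre term
  contributes only when I* > 1, so compressed fibre families carry no
  load and the reference state is stress-free from both sides.
- **k2 -> 0 limit**: fitted cohorts frequently return k2 = 0; below
  k2 = 1e-8 the analytic limit (k1/2)(I* - 1)^2 replaces the 0/0-prone
  exponential form.

### Uniaxial boundary-value problem

For uniaxial extension along the circumferential (axial) axis with
traction-free transverse faces, the deformation gradient is diagonal and
incompressibility gives l1 l2 l3 = 1.  The Lagrange pressure is
eliminated from the thickness-direction zero-stress equation, leaving
one scalar equation for the in-plane transverse stretch, solved by a
bracket scan on [0.2, 2.0] followed by Brent iteration (tolerance 1e-15
on the stretch; the transverse stress vanishes to 1e-10 x max(1 kPa,
sigma_load)).  A vectorized bisection variant solves whole stretch grids
at once.  Inside the bracket scan the fibre exponent is clamped (the
scan visits unphysical states whose stress magnitude is irrelevant, only
its sign matters); user-facing energy/stress evaluations raise an
explicit numeric-range error on overflow instead.

Goodness of fit uses R^2 = 1 - S_res/S_tot with residuals pooled over
all points of all of a sample's curves; R^2 is undefined (error) for a
constant observed signal and may be negative.

## Classical identification and the standard baseline

Per sample, (c, k1, k2) minimize the pooled squared stress residuals via
bounded trust-region least squares (bounds c in [1e-3, 1e3] kPa, k1 in
[0, 1e4] kPa, k2 in [0, 1e3]; five log-spaced starts; tolerances 1e-12).
Residuals are unweighted.  With a single loading direction and small
stretches, c and k1 trade off; the fit reports the condition number of
the final Jacobian and warns above 1e8.

The **standard prediction baseline** fits every sample individually and
predicts a sample of interest from its own structural parameters plus
the componentwise median of all other samples' fitted parameters
(leave-one-out over the cohort; even-count medians average the middle
two).  `group_fit` (one parameter set fitted to all training curves) is
retained as the rejected alternative baseline.

The **latent space** is (log10 c, log10 k1, log10 k2); k1 and k2 are
floored at 1e-3 before the logarithm (flagged) so fitted zeros stay
finite.  The **region of interest (ROI)** is the closed Euclidean ball
of radius 0.74 orders of magnitude around the componentwise median
point.  A fold's test sample is the non-validation sample closest to the
median of the remaining points, ties to the lowest id.

## Orientation imaging

Intensity plots are 68 x 54 maps of collagen-orientation signal over
tissue depth (rows) x in-plane angle (columns; column j maps to
-90 + j(180/54) degrees, periodic in 180 degrees), normalized to max 1
(not sum 1) so augmentation and masking preserve brightness semantics.
Preprocessing: (1) rescale to a cohort-uniform physical pixel size with
the thickest sample spanning 68 rows; (2) linear interpolation of every
plot to exactly 68 x 54.  Augmentation applies periodic integer column
shifts.

In-plane structural parameters come from the depth-averaged angular
distribution by maximum likelihood under the symmetric two-family
pi-periodic von Mises mixture 1/2 rho(phi - a) + 1/2 rho(phi + a) with
concentration `a` (Nelder-Mead over a grid of starts; a single-mode fit
replaces the mixture when the modes merge below one bin width).  The
in-plane dispersion is the Bessel ratio k_ip = 1/2 (1 - I1(a)/I0(a)),
which equals the sin^2 moment of the density; uniform input returns
k_ip = 1/2 with the angle flagged undefined.  The out-of-plane
dispersion is the second moment k_op = 1/2 (1 - <sin^2 Theta>) of an
out-of-plane angle histogram, consistent with H_nn = 1 - 2 k_op.
Real out-of-plane image stacks are not part of the pipeline; k_op enters
as a per-sample scalar (the synthetic generator produces it).

## Hybrid model

The deep-learning block maps an intensity plot plus the histological
volume fractions (phi_CO, phi_EF, phi_SMC) to (c, k1, k2):

- 7x7 stride-2 convolution stem, 3x3 stride-2 max pooling;
- four residual blocks of four 3x3 convolutions each (two skip
  connections per block), ReLU + batch normalization, filters
  (2, 4, 8, 16); blocks 2-4 downsample by stride 2 with a 1x1
  projection on the skip path (17 convolution layers in the main path);
- global average pooling (16 features), concatenation with the raw
  histology triplet, dense head of [12, 8, 4] softplus units and a
  final 3-unit softplus output layer, so predicted parameters are
  strictly positive.  (The published head lists [12, 8, 4] units but
  three outputs are needed; appending a 3-unit output layer was chosen
  over reinterpreting the last listed layer.)

Glorot-uniform initialization, deterministic per seed.  Convolutions
feeding batch norm carry no bias.  Batch-norm inference statistics use
an exponential moving average with momentum 0.99.  Checkpoints embed an
architecture hash.  An optional output-bias initialization
(``DLBlockSpec.output_scale_init``) can start predictions at a chosen
(c, k1, k2) scale; it defaults to off because, at short training
budgets, starting near the cohort-typical scale lets the single-sample
early-stopping metric peak during the initial transient and freeze a
barely-trained network.

The network stack is implemented in numpy with explicit backpropagation
(verified against central finite differences in the test suite), with
numba-compiled kernels for the shallow convolutions, batch normalization
and pooling; the multi-restart protocol trains all restarts as
independent "lanes" of one ensemble pass that share the batch sequence,
differing only in initialization.

### Training

Adam (learning rate 0.001, Keras-style eps), mean-squared-error loss on
stress residuals, batches of 32 stress-stretch pairs drawn as a random
permutation of the pooled (augmented) pair set each epoch (final partial
batch kept).  The published loss is written as a bare sum; the mean
convention is used (constant factor absorbed into the step size) and
recorded in the configuration as `loss: mean_squared_error`.  Training
augments each training sample into 8 periodically shifted plot copies
(shifts drawn without replacement from {1..53}); test and validation
samples are never augmented.

The stress of a training pair is evaluated at its measured stretch
through the uniaxial equilibrium: each pair's transverse stretch is
recomputed every batch by warm-started Newton iteration (bisection
fallback) at the current predicted parameters and treated as locally
constant within the step, so the loss gradient in (c, k1, k2) -- and
through every network weight -- is exact.  This is the recorded
alternative to implicit differentiation.

Early stopping selects, per restart, the checkpoint of the epoch with
the best test-sample R^2 (ties to the earliest); across restarts the
best validation R^2 wins.  Seeds derive from a master seed via
`numpy.random.SeedSequence` spawning (fold seeds -> batch stream and
per-restart init seeds), making full runs bit-reproducible.

### Cross-validation protocols

- **ROI strategy**: validation folds iterate over latent-ROI members;
  the per-fold test sample is chosen by the median-proximity rule above.
  With `max_folds` set, only the ROI members closest to the cohort
  median -- the samples with the most common mechanical properties --
  are validated; the protocol-scale runs in this package use
  `max_folds=6`, the size of the published ROI.  (The synthetic cohorts
  place roughly half the fitted cohort inside the 0.74-decade ball, and
  training every member at the full budget is out of proportion for a
  desk-scale run; restricting to the six most central members keeps the
  published fold count and the "most common properties" semantics.)
- **Full strategy**: folds iterate over all samples and the held-out
  sample serves as both test and validation sample.  The early-stopping
  signal therefore sees the held-out sample -- deliberate leakage that
  mimics a data-rich setting -- and the result carries a flag saying so.

A no-leakage assertion (validation sample absent from every training
batch) runs on every fold of both strategies.

## Synthetic cohort generator

The study's raw data are not deposited, so a generator emulates all
three inputs with known ground truth.  Per sample: volume fractions
(phi_CO, phi_EF, phi_SMC) = 0.9 x Dirichlet(4, 3, 3); mean angle
alpha ~ U(20, 55) degrees; k_ip ~ U(0.12, 0.30); k_op ~ U(0.42, 0.50);
collagen waviness w ~ U(0, 0.3); then, with i.i.d. eps ~ N(0, 0.05^2),

    c  = 20 (phi_EF + 0.5 phi_SMC) exp(eps1)   kPa
    k1 = 60 phi_CO (1 - k_ip)      exp(eps2)   kPa
    k2 = 12 phi_CO + 30 w exp(eps3)

The waviness contribution to k2 is only observable through the rendered
image (the mean angle oscillates over depth as
alpha_r = alpha (1 + w sin 2 pi t)), so a predictor must use the
convolutional encoder to resolve it.  Plots carry multiplicative
lognormal speckle (sigma = 0.05); curves carry 2% multiplicative
Gaussian stress noise on an n-point grid from stretch 1 to where the
noise-free stress reaches 300 kPa (stretch capped at 1.35).

Problem sizes are the package's own defaults: 27 samples, 4 points per
curve, one loading direction per sample alternating circumferential /
axial (dog-bone specimens are cut in a single orientation).  Cohort
assembly feeds the *imaging round trip* (rendered plot -> marginal ->
maximum-likelihood fit), not the ground truth, into downstream
structural parameters, so extraction error is part of every pipeline
result.

What the generator does *not* emulate: acquisition optics and clearing
artifacts, rupture/softening, preconditioning history, depth-dependent
dispersion, histology segmentation error, and any systematic mismatch
between the constitutive model and tissue behaviour (the synthetic
curves are exactly realizable by the model).  Passing tests therefore
demonstrate correctness of the algorithms and the identifiability logic
under the stated noise model -- not performance on real tissue.

One consequence deserves emphasis: the generated cohorts are mechanically
much more homogeneous than real arterial cohorts (the generative mapping
is smooth and the volume-fraction spread is moderate), and the stretch
grids adapt to each curve's stress level.  The median-parameter-transfer
baseline therefore reaches R^2 ~ 0.95-0.99 on the most-central samples
of synthetic cohorts -- far above the ~0.68 published for real tissue --
so the hybrid model's margin over the baseline is small and varies from
cohort seed to cohort seed, even where its own fold accuracy clears 0.9.
Comparisons of the two methods on synthetic cohorts should be read with
that ceiling effect in mind.

## Numerical choices and limitations

- Stretch-grid root-finds: bracket [0.2, 2.0]; Brent xtol 1e-15
  (scalar) / bisection to 1e-13 (vectorized); solver errors carry the
  offending stretch and residual range.
- Bessel-ratio inversion for k_ip -> concentration: Brent on
  [0, 1e4], tolerance 1e-10.
- Latent floor 1e-3 on k1, k2 before log10; floored points are flagged
  and never drive ROI radius claims.
- Training mechanics clamp the fibre exponent at 80 to keep a diverging
  restart's loss finite; restarts with non-finite loss abort and are
  excluded from selection.
- The reduced training budget used at protocol scale (200 epochs, 3
  restarts, 6 folds) is a scaled-down stand-in for the published budget
  (1000 epochs, 10 restarts); the published defaults remain the
  `TrainConfig` defaults.
- Known limitations: no shear/3D boundary-value problems, no
  viscoelasticity or damage, no uncertainty quantification of fitted
  parameters, single-channel image input, and no hyperparameter search
  (the published architecture is hard-coded).
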