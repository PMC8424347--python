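# artmech

Constitutive modelling of arterial tissue with dispersed collagen
fibres, plus a hybrid deep-learning predictor that maps microstructural
imaging and histology to the model's material parameters.

`artmech` is aimed at soft-tissue biomechanics researchers who work with
uniaxial stress–stretch data from arterial samples alongside
second-harmonic-generation (SHG) orientation imaging and histological
composition. It answers two questions:

1. *Descriptive*: given a sample's curves, what are its material
   parameters under a fibre-dispersion hyperelastic model?
2. *Predictive*: can the mechanical response of a **new, untested**
   sample be predicted from its collagen-orientation image and volume
   fractions alone?

## The model

Tissue is incompressible and hyperelastic with a neo-Hookean matrix and
two symmetric collagen fibre families at mean angle ±α from the
circumferential axis. Fibre dispersion enters through the generalized
structure tensor

    H_i = A I + B M_i ⊗ M_i + (1 − 3A − B) M_n ⊗ M_n ,
    A = 2 κ_op κ_ip ,   B = 2 κ_op (1 − 2 κ_ip) ,

and the strain energy is

    Ψ = c/2 (I₁ − 3) + Σ_{i=4,6} k₁/(2k₂) { exp[ k₂ (I_i* − 1)² ] − 1 } ,
    I_i* = tr(C H_i) ,

with matrix stiffness `c` (kPa), fibre stiffness `k₁` (kPa) and
stiffening exponent `k₂`. The structural parameters (α, κ_ip, κ_op) are
extracted from orientation imaging; the material parameters (c, k₁, k₂)
are either fitted to curves by bounded least squares or predicted by the
hybrid model: a 17-layer residual encoder reads the 68×54 depth×angle
intensity plot, its 16 pooled features are concatenated with
(φ_CO, φ_EF, φ_SMC) and a [12, 8, 4]-unit softplus head outputs the
three parameters, which drive the constitutive law end-to-end during
training (Adam on the stress mean-squared error).

Because the study-scale cohorts this emulates are small (27 samples),
evaluation uses leave-one-out cross-validation, a single
median-representative test sample per fold, and optionally restricts
validation to the latent-space region of interest (ROI): the closed ball
of radius 0.74 decades around the cohort median in
(log₁₀c, log₁₀k₁, log₁₀k₂).

## Worked example

```sh
python examples/01_uniaxial_response.py
```

prints the uniaxial response of a typical medial sample
(α = 35°, κ_ip = 0.2, κ_op = 0.45, c = 8 kPa, k₁ = 15 kPa, k₂ = 8):

```
stretch   sigma_circ [kPa]   sigma_axial [kPa]
  1.000             0.000               0.000
  1.050             1.838               1.220
  1.100             4.086               2.494
  1.150             6.920               3.857
  1.200            10.651               5.348
  1.250            15.852               7.009

at stretch 1.25 (circ): transverse stretches lambda_2 = 0.8230, lambda_3 = 0.9721, Lagrange pressure p = 8.929 kPa
```

The circumferential direction is stiffer because the fibres lie closer
to it (α < 45°); the exponential fibre term produces the characteristic
progressive stiffening. Other examples cover orientation extraction
(`02`), classical fitting and the leave-one-out baseline (`03`), the
on-disk cohort format (`04`) and hybrid-model training (`05`). A thin
CLI (`artmech synth | extract-structural | fit | loo-standard | train |
loo-cv | report`) wraps the same calls for shell use.

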