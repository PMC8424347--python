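"""Synthetic cohort generator with known ground truth.

The study's three data types are emulated per sample:

* **Histology**: volume fractions (phi_CO, phi_EF, phi_SMC) drawn as
  0.9 x Dirichlet(4, 3, 3) (collagen-rich media with a solid-free rest
  fraction).
* **Fibre architecture**: mean angle alpha ~ U(20deg, 55deg), in-plane
  dispersion kappa_ip ~ U(0.12, 0.30), out-of-plane dispersion
  kappa_op ~ U(0.42, 0.50), collagen waviness w ~ U(0, 0.3).
* **Material parameters** follow a deterministic microstructure-to-
  mechanics mapping with small lognormal scatter (eps ~ N(0, 0.05^2)):

      c  = 20 (phi_EF + 0.5 phi_SMC) exp(eps1)   [kPa]
      k1 = 60 phi_CO (1 - kappa_ip)  exp(eps2)   [kPa]
      k2 = 12 phi_CO + 30 w exp(eps3)

  The waviness contribution to k2 is observable only through the rendered
  intensity plot (the mean angle oscillates over depth), so a predictor
  must exploit the image to resolve it.
* **Intensity plot**: depth row r (fraction t = r/68) has angular density
  equal to the symmetric two-family von Mises mixture at +-alpha_r with
  alpha_r = alpha (1 + w sin 2 pi t) and concentration a solving the
  Bessel-ratio relation for kappa_ip; multiplicative lognormal speckle;
  normalized to max 1.
* **Curves**: per configured direction, an n-point stretch grid from 1.0
  up to the stretch where the noise-free stress reaches the cap (300 kPa,
  stretch capped at 1.35), stresses from the uniaxial solver plus
  multiplicative Gaussian noise.

``make_cohort`` assembles complete sample records whose in-plane
structural parameters come from the imaging round trip (rendered plot ->
marginal -> maximum-likelihood fit), not from the ground truth, so the
extraction error of the real pipeline is present in all downstream tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .constitutive import (
    FibreArchitecture,
    MaterialParams,
    StressStretchCurve,
    predict_curve,
    uniaxial_stresses,
)
from .errors import DomainError
from .fitting import HistologyFractions, SampleRecord
from .imaging import (
    PLOT_COLS,
    PLOT_ROWS,
    AngularDistribution,
    IntensityPlot,
    angular_marginal,
    bin_angles_rad,
    concentration_from_kappa_ip,
    fit_fibre_distribution,
)

__all__ = ["CohortConfig", "GroundTruthRecord", "sample_ground_truth",
           "render_intensity_plot", "simulate_curves", "make_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    """Generation settings for one synthetic cohort.

    ``directions``: "alternate" gives sample i a single loading direction
    (circumferential for even i, axial for odd), mirroring dog-bone
    specimens cut in one orientation each; "both" gives every sample both
    directions (used for identifiability studies).
    """

    n_samples: int = 27
    seed: int = 0
    # noise levels
    curve_noise: float = 0.02        # s.d. as fraction of stress
    speckle: float = 0.05            # lognormal sigma of image speckle
    # stretch grid
    n_points: int = 4                # points per curve (incl. lambda = 1)
    max_stretch: float = 1.35
    stress_cap_kpa: float = 300.0
    directions: str = "alternate"    # "alternate" | "both" | "circ" | "axial"
    # ground-truth parameter ranges
    alpha_range_deg: tuple = (20.0, 55.0)
    kappa_ip_range: tuple = (0.12, 0.30)
    kappa_op_range: tuple = (0.42, 0.50)
    waviness_range: tuple = (0.0, 0.3)
    dirichlet: tuple = (4.0, 3.0, 3.0)
    solid_fraction: float = 0.9
    scatter_sd: float = 0.05
    # mapping coefficients (see module docstring)
    c_scale: float = 20.0
    c_smc_weight: float = 0.5
    k1_scale: float = 60.0
    k2_collagen: float = 12.0
    k2_waviness: float = 30.0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_points < 2:
            raise DomainError("need n_samples >= 1 and n_points >= 2")
        if self.directions not in ("alternate", "both", "circ", "axial"):
            raise DomainError(f"unknown directions mode {self.directions!r}")


@dataclass(frozen=True)
class GroundTruthRecord:
    """True per-sample parameters of the generative model."""

    sample_id: str
    alpha: float          # radians
    kappa_ip: float
    kappa_op: float
    c: float
    k1: float
    k2: float
    phi_co: float
    phi_ef: float
    phi_smc: float
    waviness: float

    @property
    def arch(self) -> FibreArchitecture:
        return FibreArchitecture(self.alpha, self.kappa_ip, self.kappa_op)

    @property
    def params(self) -> MaterialParams:
        return MaterialParams(self.c, self.k1, self.k2)

    @property
    def histology(self) -> HistologyFractions:
        return HistologyFractions(self.phi_co, self.phi_ef, self.phi_smc)


def sample_ground_truth(config: CohortConfig, rng: np.random.Generator,
                        sample_id: str = "s") -> GroundTruthRecord:
    """Draw one sample's ground truth from the generative model."""
    phi = config.solid_fraction * rng.dirichlet(config.dirichlet)
    alpha = np.deg2rad(rng.uniform(*config.alpha_range_deg))
    kip = rng.uniform(*config.kappa_ip_range)
    kop = rng.uniform(*config.kappa_op_range)
    w = rng.uniform(*config.waviness_range)
    eps = rng.normal(0.0, config.scatter_sd, size=3)
    c = config.c_scale * (phi[1] + config.c_smc_weight * phi[2]) * np.exp(eps[0])
    k1 = config.k1_scale * phi[0] * (1.0 - kip) * np.exp(eps[1])
    k2 = config.k2_collagen * phi[0] + config.k2_waviness * w * np.exp(eps[2])
    return GroundTruthRecord(sample_id=sample_id, alpha=float(alpha),
                             kappa_ip=float(kip), kappa_op=float(kop),
                             c=float(c), k1=float(k1), k2=float(k2),
                             phi_co=float(phi[0]), phi_ef=float(phi[1]),
                             phi_smc=float(phi[2]), waviness=float(w))


def render_intensity_plot(truth: GroundTruthRecord, config: CohortConfig,
                          rng: Optional[np.random.Generator] = None
                          ) -> IntensityPlot:
    """Render the depth x angle orientation map of one sample."""
    a = concentration_from_kappa_ip(truth.kappa_ip, tol=1e-10)
    phi = bin_angles_rad()
    t = np.arange(PLOT_ROWS) / PLOT_ROWS
    alpha_r = truth.alpha * (1.0 + truth.waviness * np.sin(2 * np.pi * t))
    # symmetric two-family mixture per depth row (rows x angle bins)
    d1 = np.exp(a * (np.cos(2 * (phi[None, :] - alpha_r[:, None])) - 1.0))
    d2 = np.exp(a * (np.cos(2 * (phi[None, :] + alpha_r[:, None])) - 1.0))
    grid = 0.5 * (d1 + d2)
    if rng is not None and config.speckle > 0:
        grid = grid * np.exp(config.speckle * rng.standard_normal(grid.shape))
    return IntensityPlot(grid / grid.max())


def _directions_for(index: int, config: CohortConfig):
    if config.directions == "both":
        return ("circ", "axial")
    if config.directions == "alternate":
        return ("circ",) if index % 2 == 0 else ("axial",)
    return (config.directions,)


def _grid_end(truth: GroundTruthRecord, direction: str,
              config: CohortConfig) -> float:
    """Stretch where the noise-free stress reaches the cap (bisection),
    bounded above by the configured maximum stretch."""
    arch, mat = truth.arch, truth.params
    cap = config.stress_cap_kpa
    hi = config.max_stretch
    if float(uniaxial_stresses([hi], direction, arch, mat)[0]) <= cap:
        return hi
    lo = 1.0 + 1e-6
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if float(uniaxial_stresses([mid], direction, arch, mat)[0]) > cap:
            hi = mid
        else:
            lo = mid
    return lo


def simulate_curves(truth: GroundTruthRecord, config: CohortConfig,
                    rng: Optional[np.random.Generator] = None,
                    directions: Optional[Sequence[str]] = None,
                    noise: Optional[float] = None) -> list:
    """Noisy uniaxial stress-stretch curves from the ground truth."""
    if directions is None:
        directions = _directions_for(0, config)
    noise = config.curve_noise if noise is None else noise
    curves = []
    for d in directions:
        lam_end = _grid_end(truth, d, config)
        lam = np.linspace(1.0, lam_end, config.n_points)
        sig = uniaxial_stresses(lam, d, truth.arch, truth.params)
        if rng is not None and noise > 0:
            sig = sig * (1.0 + noise * rng.standard_normal(sig.shape))
        curves.append(StressStretchCurve(d, lam, sig))
    return curves


def make_cohort(config: CohortConfig = CohortConfig(),
                out_dir=None) -> tuple:
    """Generate a complete cohort.

    Returns ``(samples, truths)``: sample records ready for fitting and
    training (structural in-plane parameters from the imaging round trip,
    true kappa_op) and the matching ground-truth records.  When
    ``out_dir`` is given the cohort is also written to disk in the
    package's on-disk format.
    """
    rng = np.random.default_rng(config.seed)
    samples, truths = [], []
    for i in range(config.n_samples):
        sid = f"s{i + 1:02d}"
        truth = sample_ground_truth(config, rng, sample_id=sid)
        plot = render_intensity_plot(truth, config, rng)
        fit = fit_fibre_distribution(angular_marginal(plot))
        if not fit.alpha_defined:
            raise DomainError(f"sample {sid}: isotropic plot, alpha undefined")
        arch = FibreArchitecture(alpha=fit.alpha,
                                 kappa_ip=min(fit.kappa_ip, 0.5),
                                 kappa_op=truth.kappa_op)
        curves = simulate_curves(truth, config, rng,
                                 directions=_directions_for(i, config))
        samples.append(SampleRecord(sample_id=sid, curves=curves, arch=arch,
                                    histology=truth.histology, plot=plot,
                                    ground_truth=truth.params))
        truths.append(truth)
    if out_dir is not None:
        from .io import save_cohort
        save_cohort(samples, out_dir, truths=truths, config=config)
    return samples, truths
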