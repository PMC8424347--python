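"""Collagen-orientation intensity plots and structural-parameter extraction.

An intensity plot is a 68 x 54 map of collagen-orientation signal over
tissue depth (rows, outermost layer first) x in-plane fibre angle
(columns).  Column j corresponds to the angle Phi_j = -90 + j * (180/54)
degrees relative to the circumferential direction; the angle axis is
periodic with period 180 degrees.  Intensities are normalized to a
maximum of 1 so that augmentation and masking do not change brightness
semantics.

Preprocessing mirrors the acquisition pipeline: (1) plots are rescaled to
a cohort-uniform physical pixel size, the thickest sample spanning 68
rows; (2) every plot is then linearly interpolated to exactly 68 rows and
54 angle columns; (3) training-time augmentation applies periodic integer
shifts along the angle axis.

The in-plane structural parameters are extracted from the depth-averaged
angular distribution by maximum likelihood under a pi-periodic von Mises
model, symmetric two-family version

    f(Phi; alpha, a) = [exp(a cos 2(Phi - alpha)) + exp(a cos 2(Phi + alpha))]
                       / (2 pi I0(a)),

from which the in-plane dispersion is the Bessel ratio

    kappa_ip = 1/2 (1 - I1(a) / I0(a)),

so kappa_ip = 1/2 for a -> 0 (in-plane isotropy) and -> 0 for a -> inf
(perfect alignment).  The out-of-plane dispersion comes from the second
moment of the out-of-plane angle distribution, kappa_op =
1/2 (1 - <sin^2 Theta>), consistent with the structure-tensor identity
H_nn = 1 - 2 kappa_op.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import i0e, i1e
from skimage.transform import resize

from .errors import DomainError

__all__ = [
    "PLOT_ROWS", "PLOT_COLS", "IntensityPlot", "AngularDistribution",
    "FibreOrientationFit", "bin_angles_deg", "bin_angles_rad",
    "rescale_plot", "augment_shift", "angular_marginal",
    "fit_fibre_distribution", "kappa_ip_from_concentration",
    "concentration_from_kappa_ip", "kappa_op_from_profile",
]

PLOT_ROWS = 68   # tissue depth (vertical)
PLOT_COLS = 54   # fibre angle (horizontal)


def bin_angles_deg(n: int = PLOT_COLS) -> np.ndarray:
    """Angle of each column in degrees, uniformly spanning [-90, 90)."""
    return -90.0 + np.arange(n) * (180.0 / n)


def bin_angles_rad(n: int = PLOT_COLS) -> np.ndarray:
    return np.deg2rad(bin_angles_deg(n))


@dataclass
class IntensityPlot:
    """68 x 54 normalized orientation-intensity map (max intensity 1)."""

    grid: np.ndarray
    row_mask: np.ndarray = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (PLOT_ROWS, PLOT_COLS):
            raise DomainError(
                f"intensity plot must be {PLOT_ROWS}x{PLOT_COLS}, "
                f"got {self.grid.shape}")
        if np.any(self.grid < 0):
            raise DomainError("intensities must be non-negative")
        if self.row_mask is None:
            self.row_mask = np.ones(PLOT_ROWS, dtype=bool)
        mx = self.grid.max()
        if mx <= 0:
            raise DomainError("empty (all-zero) intensity plot")
        if abs(mx - 1.0) > 1e-9:
            self.grid = self.grid / mx


@dataclass
class AngularDistribution:
    """54-bin probability vector over the angle axis."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (PLOT_COLS,):
            raise DomainError(f"expected {PLOT_COLS} bins")
        if np.any(self.probs < 0):
            raise DomainError("probabilities must be non-negative")
        s = self.probs.sum()
        if s <= 0:
            raise DomainError("empty angular distribution")
        self.probs = self.probs / s


@dataclass(frozen=True)
class FibreOrientationFit:
    """Result of the in-plane orientation fit."""

    alpha: float              # mean fibre angle, radians
    kappa_ip: float
    concentration: float      # von Mises concentration a
    alpha_defined: bool = True
    single_mode: bool = False

    @property
    def alpha_deg(self) -> float:
        return float(np.rad2deg(self.alpha))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def rescale_plot(raw: np.ndarray, pixel_scale: float,
                 cohort_max_thickness: float) -> IntensityPlot:
    """Two-step rescaling of a raw depth x angle intensity map.

    Parameters
    ----------
    raw : array (rows, cols)
        Raw intensity map, row 1 = outermost depth layer.
    pixel_scale : float
        Physical depth per raw pixel (same length unit as
        ``cohort_max_thickness``).
    cohort_max_thickness : float
        Thickness of the thickest sample of the cohort; after step 1 that
        sample spans exactly 68 rows and thinner samples proportionally
        fewer.

    Step 2 linearly interpolates every plot to exactly 68 rows; the angle
    axis is resampled to 54 columns; intensities are normalized to max 1.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.size == 0:
        raise DomainError("raw intensity grid must be a non-empty 2D array")
    if pixel_scale <= 0 or cohort_max_thickness <= 0:
        raise DomainError("pixel scale and cohort thickness must be positive")
    if raw.max() <= 0:
        raise DomainError("zero-intensity raw grid")
    thickness = raw.shape[0] * pixel_scale
    if thickness > cohort_max_thickness * (1 + 1e-9):
        raise DomainError("sample thicker than the stated cohort maximum")
    # step 1: cohort-uniform pixel scale
    rows1 = max(int(round(PLOT_ROWS * thickness / cohort_max_thickness)), 2)
    step1 = resize(raw, (rows1, PLOT_COLS), order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
    # step 2: stretch to the uniform 68-row format
    step2 = resize(step1, (PLOT_ROWS, PLOT_COLS), order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
    return IntensityPlot(np.clip(step2, 0.0, None))


def augment_shift(plot: IntensityPlot, shift: int) -> IntensityPlot:
    """Periodic shift along the angle axis (columns); mass preserving."""
    if not (0 <= shift < PLOT_COLS):
        raise DomainError(f"shift must lie in [0, {PLOT_COLS}), got {shift}")
    return IntensityPlot(np.roll(plot.grid, shift, axis=1),
                         row_mask=plot.row_mask.copy())


def angular_marginal(plot: IntensityPlot) -> AngularDistribution:
    """Column sums over valid rows, normalized to a probability vector."""
    sums = plot.grid[plot.row_mask].sum(axis=0)
    if sums.sum() <= 0:
        raise DomainError("all-zero intensity plot")
    return AngularDistribution(sums)


# ---------------------------------------------------------------------------
# orientation statistics
# ---------------------------------------------------------------------------

def kappa_ip_from_concentration(a: float) -> float:
    """kappa_ip = 1/2 (1 - I1(a)/I0(a)) via exponentially scaled Bessels."""
    if a < 0:
        raise DomainError("concentration must be non-negative")
    if a == 0:
        return 0.5
    return 0.5 * (1.0 - i1e(a) / i0e(a))


def concentration_from_kappa_ip(kappa_ip: float, tol: float = 1e-10,
                                a_max: float = 1e4) -> float:
    """Invert the Bessel-ratio relation by bracketed root-finding."""
    if not (0.0 < kappa_ip <= 0.5):
        raise DomainError("kappa_ip must lie in (0, 1/2] for inversion")
    if kappa_ip == 0.5:
        return 0.0
    f = lambda a: kappa_ip_from_concentration(a) - kappa_ip
    if f(a_max) > 0:
        raise DomainError(f"kappa_ip={kappa_ip} too small to invert "
                          f"(needs a > {a_max})")
    return float(brentq(f, 0.0, a_max, xtol=tol))


def _mixture_density(phi, alpha, a):
    """pi-periodic two-family von Mises mixture density on (-pi/2, pi/2]."""
    norm = 2.0 * np.pi * i0e(a)
    # exp(a cos x - a) = exp(a cos x) / e^a pairs with i0e = I0 e^-a
    return (np.exp(a * (np.cos(2 * (phi - alpha)) - 1.0))
            + np.exp(a * (np.cos(2 * (phi + alpha)) - 1.0))) / norm


def _neg_loglik(theta, phi, p, single_mode):
    alpha, log_a = theta
    a = np.exp(min(max(log_a, -12.0), 12.0))
    if single_mode:
        dens = np.exp(a * (np.cos(2 * (phi - alpha)) - 1.0)) / (np.pi * i0e(a))
    else:
        dens = _mixture_density(phi, alpha, a)
    return -float(np.sum(p * np.log(dens + 1e-300)))


def fit_fibre_distribution(dist: AngularDistribution) -> FibreOrientationFit:
    """Maximum-likelihood fit of the symmetric two-family pi-periodic von
    Mises model to a binned angular distribution.

    Uniform (isotropic) input returns kappa_ip = 1/2 with the mean angle
    flagged undefined.  When the fitted modes merge (alpha below one bin
    width) the degenerate mixture is replaced by a single-mode fit.
    """
    p = dist.probs
    phi = bin_angles_rad()
    bin_w = np.pi / PLOT_COLS

    # moment-based isotropy screen: resultant of the doubled angles
    r2 = abs(np.sum(p * np.exp(2j * phi)))
    # mixture fit from a grid of starts
    best = None
    for a0 in (0.5, 2.0, 8.0):
        for alpha0 in np.deg2rad([0.0, 20.0, 40.0, 60.0, 80.0]):
            res = minimize(_neg_loglik, x0=(alpha0, np.log(a0)),
                           args=(phi, p, False), method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-12,
                                    "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
    alpha = float(best.x[0])
    a = float(np.exp(min(max(best.x[1], -12.0), 12.0)))
    # wrap alpha into (-pi/2, pi/2]; the mixture is even in alpha
    alpha = (alpha + np.pi / 2) % np.pi - np.pi / 2
    alpha = abs(alpha)

    single = False
    if alpha < bin_w:
        # modes merged: refit a single pi-periodic von Mises
        best_s = None
        for a0 in (0.5, 2.0, 8.0):
            for alpha0 in np.deg2rad([0.0, 30.0, 60.0]):
                res = minimize(_neg_loglik, x0=(alpha0, np.log(a0)),
                               args=(phi, p, True), method="Nelder-Mead",
                               options={"xatol": 1e-8, "fatol": 1e-12,
                                        "maxiter": 2000})
                if best_s is None or res.fun < best_s.fun:
                    best_s = res
        if best_s.fun <= best.fun + 1e-9:
            alpha = float((best_s.x[0] + np.pi / 2) % np.pi - np.pi / 2)
            a = float(np.exp(min(max(best_s.x[1], -12.0), 12.0)))
            single = True

    if a < 1e-3 or r2 < 1e-6:
        return FibreOrientationFit(alpha=0.0, kappa_ip=0.5, concentration=0.0,
                                   alpha_defined=False, single_mode=True)
    return FibreOrientationFit(alpha=alpha,
                               kappa_ip=kappa_ip_from_concentration(a),
                               concentration=a, single_mode=single)


def kappa_op_from_profile(theta: np.ndarray, weights: np.ndarray) -> float:
    """Out-of-plane dispersion from an angle histogram.

    Parameters
    ----------
    theta : array, radians
        Bin centres of the out-of-plane angle (from the circumferential-
        axial plane), in [-pi/2, pi/2].
    weights : array
        Non-negative histogram weights (density already includes any
        solid-angle factor).

    Returns kappa_op = 1/2 (1 - <sin^2 theta>).
    """
    theta = np.asarray(theta, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if theta.size == 0 or theta.shape != weights.shape:
        raise DomainError("empty or mismatched out-of-plane histogram")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise DomainError("weights must be non-negative with positive sum")
    s2 = float(np.sum(weights * np.sin(theta) ** 2) / weights.sum())
    return 0.5 * (1.0 - s2)
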