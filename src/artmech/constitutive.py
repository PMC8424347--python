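"""Dispersed-fibre hyperelastic model of arterial tissue.

The tissue is modelled as an incompressible hyperelastic solid with a
neo-Hookean ground matrix and two symmetric families of collagen fibres
whose orientation statistics enter through a generalized structure tensor

    H_i = A I + B M_i (x) M_i + (1 - 3A - B) M_n (x) M_n ,   i = 4, 6,

with mean fibre directions M4 = (cos a, sin a, 0), M6 = (cos a, -sin a, 0)
in the circumferential-axial plane, out-of-plane normal M_n = e3, and
coefficients

    A = 2 k_op k_ip ,      B = 2 k_op (1 - 2 k_ip),

where k_ip in [0, 1/2] and k_op in (0, 1/2] are the in-plane and
out-of-plane dispersion parameters.  The strain energy is

    Psi = c/2 (I1 - 3) + sum_{i=4,6} k1/(2 k2) { exp[k2 (I_i* - 1)^2] - 1 },

with the generalized invariant I_i* = tr(C H_i).  Fibres only store energy
in extension (I* > 1); this tension switch is a configuration flag.  The
k2 -> 0 limit of the fibre energy, (k1/2)(I* - 1)^2, is applied below a
small threshold so k2 = 0 is admissible.

The uniaxial incompressible boundary-value problem (loading along the
circumferential or axial axis, traction-free transverse faces) is solved
by eliminating the Lagrange pressure from the thickness-direction
zero-stress equation and root-finding on the remaining in-plane transverse
stretch.  Stresses and the stiffness-like parameters c, k1 are in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, NumericRangeError, SolverError, UndefinedStatisticError

__all__ = [
    "FibreArchitecture",
    "MaterialParams",
    "DeformationState",
    "UniaxialSolution",
    "StressStretchCurve",
    "GoodnessOfFit",
    "structure_tensor",
    "generalized_invariant",
    "strain_energy",
    "cauchy_stress_components",
    "solve_uniaxial",
    "uniaxial_stresses",
    "predict_curve",
    "r_squared",
]

Direction = Literal["circ", "axial"]

#: Exponent threshold below which the analytic k2 -> 0 limit of the fibre
#: energy is used (avoids the 0/0 in k1/(2 k2)).
K2_EPS = 1e-8

#: Largest admissible argument of the exponential fibre term before an
#: explicit numeric-range error is raised.
_EXP_MAX = 700.0

#: Bracket for the transverse-stretch root-find.
_BRACKET = (0.2, 2.0)


def _norm_direction(direction: str) -> Direction:
    d = direction.lower()
    if d in ("circ", "circumferential", "1"):
        return "circ"
    if d in ("axial", "ax", "2"):
        return "axial"
    raise DomainError(f"unknown loading direction {direction!r}")


@dataclass(frozen=True)
class FibreArchitecture:
    """Structural description of the collagen network.

    Parameters
    ----------
    alpha : float
        Mean fibre angle in radians, measured from the circumferential
        axis in the circumferential-axial plane; -pi/2 < alpha < pi/2.
    kappa_ip : float
        In-plane dispersion, 0 <= kappa_ip <= 1/2 (1/2 = planar isotropy).
    kappa_op : float
        Out-of-plane dispersion, 0 < kappa_op <= 1/2 (1/2 = all fibres in
        the wall plane, 1/3 = 3D isotropy).
    """

    alpha: float
    kappa_ip: float
    kappa_op: float

    def __post_init__(self):
        if not (-np.pi / 2 < self.alpha < np.pi / 2):
            raise DomainError(f"alpha must lie in (-pi/2, pi/2), got {self.alpha}")
        if not (0.0 <= self.kappa_ip <= 0.5):
            raise DomainError(f"kappa_ip must lie in [0, 1/2], got {self.kappa_ip}")
        if not (0.0 < self.kappa_op <= 0.5):
            raise DomainError(f"kappa_op must lie in (0, 1/2], got {self.kappa_op}")

    @classmethod
    def from_degrees(cls, alpha_deg: float, kappa_ip: float, kappa_op: float):
        return cls(np.deg2rad(alpha_deg), kappa_ip, kappa_op)

    @property
    def alpha_deg(self) -> float:
        return float(np.rad2deg(self.alpha))

    # Structure-tensor coefficients
    @property
    def A(self) -> float:
        return 2.0 * self.kappa_op * self.kappa_ip

    @property
    def B(self) -> float:
        return 2.0 * self.kappa_op * (1.0 - 2.0 * self.kappa_ip)

    @property
    def M4(self) -> np.ndarray:
        return np.array([np.cos(self.alpha), np.sin(self.alpha), 0.0])

    @property
    def M6(self) -> np.ndarray:
        return np.array([np.cos(self.alpha), -np.sin(self.alpha), 0.0])

    @property
    def Mn(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class MaterialParams:
    """Material parameters of the strain-energy function.

    c and k1 are stress-like (kPa); k2 is a dimensionless stiffening
    exponent.  k2 = 0 is admitted through the analytic limit of the fibre
    energy.
    """

    c: float
    k1: float
    k2: float

    def __post_init__(self):
        if not self.c > 0:
            raise DomainError(f"c must be > 0, got {self.c}")
        if self.k1 < 0:
            raise DomainError(f"k1 must be >= 0, got {self.k1}")
        if self.k2 < 0:
            raise DomainError(f"k2 must be >= 0, got {self.k2}")

    def as_array(self) -> np.ndarray:
        return np.array([self.c, self.k1, self.k2], dtype=float)


@dataclass(frozen=True)
class DeformationState:
    """Principal stretches of a diagonal deformation gradient
    F = diag(l1, l2, l3) (circumferential, axial, thickness)."""

    l1: float
    l2: float
    l3: float

    def __post_init__(self):
        if min(self.l1, self.l2, self.l3) <= 0:
            raise DomainError("principal stretches must be positive")

    @classmethod
    def incompressible(cls, l1: float, l2: float) -> "DeformationState":
        return cls(l1, l2, 1.0 / (l1 * l2))

    @property
    def F(self) -> np.ndarray:
        return np.diag([self.l1, self.l2, self.l3])

    @property
    def C(self) -> np.ndarray:
        return np.diag([self.l1**2, self.l2**2, self.l3**2])

    @property
    def J(self) -> float:
        return self.l1 * self.l2 * self.l3

    def is_incompressible(self, tol: float = 1e-12) -> bool:
        return abs(self.J - 1.0) <= tol

    @property
    def I1(self) -> float:
        return self.l1**2 + self.l2**2 + self.l3**2

    def I4(self, arch: FibreArchitecture) -> float:
        # identical for both symmetric families under diagonal C
        ca, sa = np.cos(arch.alpha), np.sin(arch.alpha)
        return self.l1**2 * ca**2 + self.l2**2 * sa**2

    @property
    def In(self) -> float:
        return self.l3**2


@dataclass(frozen=True)
class UniaxialSolution:
    """Equilibrium state of an incompressible uniaxial extension test."""

    direction: Direction
    deformation: DeformationState
    p: float
    sigma_load: float


@dataclass
class StressStretchCurve:
    """Ordered (stretch, Cauchy stress) pairs for one loading direction."""

    direction: Direction
    stretch: np.ndarray
    stress: np.ndarray

    def __post_init__(self):
        self.direction = _norm_direction(self.direction)
        self.stretch = np.asarray(self.stretch, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.stretch.shape != self.stress.shape or self.stretch.ndim != 1:
            raise DomainError("stretch and stress must be matching 1D arrays")
        if self.stretch.size and self.stretch[0] < 1.0:
            raise DomainError("first stretch must be >= 1")
        if np.any(np.diff(self.stretch) <= 0):
            raise DomainError("stretches must be strictly increasing")

    def __len__(self):
        return self.stretch.size


@dataclass(frozen=True)
class GoodnessOfFit:
    """Coefficient of determination with its building blocks (kPa^2)."""

    r2: float
    s_res: float
    s_tot: float
    n_points: int


# ---------------------------------------------------------------------------
# structure tensor and invariants
# ---------------------------------------------------------------------------

def structure_tensor(arch: FibreArchitecture, family: int = 4) -> np.ndarray:
    """Generalized structure tensor H_i = A I + B M_i(x)M_i + (1-3A-B) Mn(x)Mn.

    trace(H) = 1 and H is positive semidefinite for all admissible
    dispersion parameters.
    """
    if family not in (4, 6):
        raise DomainError(f"fibre family must be 4 or 6, got {family}")
    M = arch.M4 if family == 4 else arch.M6
    A, B = arch.A, arch.B
    H = A * np.eye(3) + B * np.outer(M, M) + (1.0 - 3.0 * A - B) * np.outer(arch.Mn, arch.Mn)
    return H


def generalized_invariant(state: DeformationState, arch: FibreArchitecture,
                          family: int = 4) -> float:
    """I* = tr(C H) = A I1 + B I_i + (1 - 3A - B) I_n."""
    if family not in (4, 6):
        raise DomainError(f"fibre family must be 4 or 6, got {family}")
    A, B = arch.A, arch.B
    return A * state.I1 + B * state.I4(arch) + (1.0 - 3.0 * A - B) * state.In


def _istar(l1, l2, l3, arch: FibreArchitecture):
    """Vector-friendly generalized invariant (same for families 4 and 6)."""
    ca2 = np.cos(arch.alpha) ** 2
    sa2 = np.sin(arch.alpha) ** 2
    A, B = arch.A, arch.B
    I1 = l1**2 + l2**2 + l3**2
    I4 = l1**2 * ca2 + l2**2 * sa2
    return A * I1 + B * I4 + (1.0 - 3.0 * A - B) * l3**2


def _fibre_energy_term(istar, mat: MaterialParams, fibre_switch: bool):
    """Energy of one fibre family at generalized invariant `istar`."""
    e = np.asarray(istar, dtype=float) - 1.0
    if fibre_switch:
        e = np.where(e > 0.0, e, 0.0)
    q = mat.k2 * e**2
    if np.any(q > _EXP_MAX):
        raise NumericRangeError(
            f"fibre exponential overflow: k2*(I*-1)^2 = {float(np.max(q)):.3g}")
    if mat.k2 < K2_EPS:
        return 0.5 * mat.k1 * e**2
    return mat.k1 / (2.0 * mat.k2) * np.expm1(q)


def strain_energy(state: DeformationState, arch: FibreArchitecture,
                  mat: MaterialParams, fibre_switch: bool = True) -> float:
    """Strain energy Psi (kPa) of matrix plus both fibre families."""
    psi_m = 0.5 * mat.c * (state.I1 - 3.0)
    istar = generalized_invariant(state, arch, 4)
    # the two families share I* for diagonal C: energy contributes twice
    psi_f = 2.0 * _fibre_energy_term(istar, mat, fibre_switch)
    return float(psi_m + psi_f)


def _psi4_prime(istar, mat: MaterialParams, fibre_switch: bool,
                clamp: bool = False):
    """d Psi_f,i / d I* = k1 (I*-1) exp[k2 (I*-1)^2] (zero in compression
    when the tension switch is on).

    ``clamp`` caps the exponent instead of raising, for use inside the
    root-finder whose bracket scan visits unphysical states; the sign of
    the residual is unaffected.
    """
    e = np.asarray(istar, dtype=float) - 1.0
    if fibre_switch:
        e = np.where(e > 0.0, e, 0.0)
    q = mat.k2 * e**2
    if np.any(q > _EXP_MAX):
        if not clamp:
            raise NumericRangeError(
                f"fibre exponential overflow: k2*(I*-1)^2 = "
                f"{float(np.max(q)):.3g}")
        # cap low enough that downstream products stay finite (the
        # residual sign, all bisection needs, is preserved)
        q = np.minimum(q, 500.0)
    return mat.k1 * e * np.exp(q)


def cauchy_stress_components(state: DeformationState, p: float,
                             arch: FibreArchitecture, mat: MaterialParams,
                             fibre_switch: bool = True):
    """Diagonal Cauchy stresses (kPa) of the incompressible model,

        s11 = [c + 4 (A + B cos^2 a) psi4'] l1^2 - p,
        s22 = [c + 4 (A + B sin^2 a) psi4'] l2^2 - p,
        s33 = [c + 4 (1 - 2A - B)   psi4'] l3^2 - p,

    with psi4' = k1 (I4*-1) exp[k2 (I4*-1)^2] shared by both families
    (diagonal deformation implies I4* = I6*).
    """
    A, B = arch.A, arch.B
    ca2 = np.cos(arch.alpha) ** 2
    sa2 = np.sin(arch.alpha) ** 2
    psi4p = _psi4_prime(generalized_invariant(state, arch, 4), mat, fibre_switch)
    s11 = (mat.c + 4.0 * (A + B * ca2) * psi4p) * state.l1**2 - p
    s22 = (mat.c + 4.0 * (A + B * sa2) * psi4p) * state.l2**2 - p
    s33 = (mat.c + 4.0 * (1.0 - 2.0 * A - B) * psi4p) * state.l3**2 - p
    return float(s11), float(s22), float(s33)


# ---------------------------------------------------------------------------
# uniaxial boundary-value problem
# ---------------------------------------------------------------------------

def _uniaxial_arrays(lam_load, lam_t, direction: Direction,
                     arch: FibreArchitecture, mat: MaterialParams,
                     fibre_switch: bool):
    """Loading-direction and transverse in-plane stress with p eliminated
    from the thickness-direction zero-stress equation.  Fully vectorized in
    (lam_load, lam_t).

    Returns (sigma_load, sigma_transverse, lam3, p).
    """
    lam_load = np.asarray(lam_load, dtype=float)
    lam_t = np.asarray(lam_t, dtype=float)
    lam3 = 1.0 / (lam_load * lam_t)
    if direction == "circ":
        l1, l2 = lam_load, lam_t
        m2_load, m2_trans = np.cos(arch.alpha) ** 2, np.sin(arch.alpha) ** 2
    else:
        l1, l2 = lam_t, lam_load
        m2_load, m2_trans = np.sin(arch.alpha) ** 2, np.cos(arch.alpha) ** 2
    A, B = arch.A, arch.B
    psi4p = _psi4_prime(_istar(l1, l2, lam3, arch), mat, fibre_switch,
                        clamp=True)
    p = (mat.c + 4.0 * (1.0 - 2.0 * A - B) * psi4p) * lam3**2
    sig_load = (mat.c + 4.0 * (A + B * m2_load) * psi4p) * lam_load**2 - p
    sig_trans = (mat.c + 4.0 * (A + B * m2_trans) * psi4p) * lam_t**2 - p
    return sig_load, sig_trans, lam3, p


def _solve_transverse_vec(lam_load, direction: Direction, arch, mat,
                          fibre_switch: bool = True, tol: float = 1e-10,
                          n_scan: int = 41):
    """Vectorized transverse-stretch solve: bracket scan + bisection.

    Returns the in-plane transverse stretch array.  Raises SolverError when
    no sign change is found inside the admissible bracket.
    """
    lam_load = np.atleast_1d(np.asarray(lam_load, dtype=float))
    grid = np.linspace(_BRACKET[0], _BRACKET[1], n_scan)
    # residual on the scan grid: shape (n_scan, n)
    res = np.empty((n_scan, lam_load.size))
    for k, lt in enumerate(grid):
        res[k] = _uniaxial_arrays(lam_load, np.full_like(lam_load, lt),
                                  direction, arch, mat, fibre_switch)[1]
    sign = np.signbit(res)
    flip = sign[:-1] != sign[1:]
    has = flip.any(axis=0)
    if not has.all():
        bad = int(np.argmin(has))
        raise SolverError(
            "transverse equilibrium not bracketed in [0.2, 2.0]",
            diagnostics={"lambda_load": float(lam_load[bad]),
                         "direction": direction, "params": mat,
                         "residual_range": (float(res[:, bad].min()),
                                            float(res[:, bad].max()))})
    first = flip.argmax(axis=0)
    lo = grid[first]
    hi = grid[first + 1]
    flo = res[first, np.arange(lam_load.size)]
    n_iter = int(np.ceil(np.log2((grid[1] - grid[0]) / min(tol, 1e-13))))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        fm = _uniaxial_arrays(lam_load, mid, direction, arch, mat, fibre_switch)[1]
        left = (np.signbit(fm) == np.signbit(flo))
        lo = np.where(left, mid, lo)
        flo = np.where(left, fm, flo)
        hi = np.where(left, hi, mid)
    return 0.5 * (lo + hi)


def solve_uniaxial(lambda_load: float, direction: str, arch: FibreArchitecture,
                   mat: MaterialParams, tol: float = 1e-10,
                   fibre_switch: bool = True) -> UniaxialSolution:
    """Solve the incompressible uniaxial extension problem at one stretch.

    The Lagrange pressure is eliminated from the thickness-direction
    zero-stress equation; the remaining scalar equation for the in-plane
    transverse stretch is solved by bracketed root-finding (Brent) in
    [0.2, 2.0] with a bisection-backed scan fallback.
    """
    direction = _norm_direction(direction)
    if lambda_load < 1.0:
        raise DomainError(f"lambda_load must be >= 1, got {lambda_load}")
    if tol <= 0:
        raise DomainError("tol must be positive")

    def residual(lt):
        return float(_uniaxial_arrays(lambda_load, lt, direction, arch, mat,
                                      fibre_switch)[1])

    # scan for a sign change, then Brent (with bisection guarantee)
    grid = np.linspace(_BRACKET[0], _BRACKET[1], 41)
    vals = [residual(g) for g in grid]
    lt = None
    for k in range(len(grid) - 1):
        if np.sign(vals[k]) != np.sign(vals[k + 1]) or vals[k] == 0.0:
            if vals[k] == 0.0:
                lt = float(grid[k])
            else:
                lt = float(brentq(residual, grid[k], grid[k + 1], xtol=1e-15))
            break
    if lt is None:
        raise SolverError(
            "transverse equilibrium not bracketed in [0.2, 2.0]",
            diagnostics={"lambda_load": lambda_load, "direction": direction,
                         "params": mat,
                         "residual_range": (min(vals), max(vals))})
    sig_load, sig_trans, lam3, p = _uniaxial_arrays(
        lambda_load, lt, direction, arch, mat, fibre_switch)
    if direction == "circ":
        state = DeformationState(lambda_load, lt, float(lam3))
    else:
        state = DeformationState(lt, lambda_load, float(lam3))
    sig_load = float(sig_load)
    if abs(float(sig_trans)) > tol * max(1.0, abs(sig_load)):
        raise SolverError("transverse stress did not vanish",
                          diagnostics={"sigma_transverse": float(sig_trans)})
    return UniaxialSolution(direction, state, float(p), sig_load)


def uniaxial_stresses(lambda_grid, direction: str, arch: FibreArchitecture,
                      mat: MaterialParams, fibre_switch: bool = True,
                      tol: float = 1e-10) -> np.ndarray:
    """Vectorized loading-direction Cauchy stress over a stretch grid."""
    direction = _norm_direction(direction)
    lam = np.atleast_1d(np.asarray(lambda_grid, dtype=float))
    lt = _solve_transverse_vec(lam, direction, arch, mat, fibre_switch, tol)
    return _uniaxial_arrays(lam, lt, direction, arch, mat, fibre_switch)[0]


def predict_curve(lambda_grid, direction: str, arch: FibreArchitecture,
                  mat: MaterialParams, fibre_switch: bool = True,
                  tol: float = 1e-10) -> StressStretchCurve:
    """Model stress-stretch curve on a strictly increasing stretch grid."""
    direction = _norm_direction(direction)
    lam = np.atleast_1d(np.asarray(lambda_grid, dtype=float))
    if lam.size == 0:
        raise DomainError("empty stretch grid")
    if lam[0] < 1.0 or np.any(np.diff(lam) <= 0):
        raise DomainError("grid must be strictly increasing with min >= 1")
    try:
        sig = uniaxial_stresses(lam, direction, arch, mat, fibre_switch, tol)
    except SolverError as err:
        err.diagnostics.setdefault("grid", lam)
        raise
    if np.any(np.diff(sig) < -1e-8 * max(1.0, float(np.abs(sig).max()))):
        raise SolverError("predicted stress not monotone on the grid",
                          diagnostics={"stress": sig})
    return StressStretchCurve(direction, lam, sig)


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def _as_curve_list(x) -> list:
    if isinstance(x, StressStretchCurve):
        return [x]
    return list(x)


def r_squared(observed, modelled) -> GoodnessOfFit:
    """Coefficient of determination R^2 = 1 - S_res / S_tot, pooled over all
    points of all of a sample's curves (the observed mean is the pooled
    mean).  May be negative.  Raises if the observed signal is constant.
    """
    obs = _as_curve_list(observed)
    mod = _as_curve_list(modelled)
    if len(obs) != len(mod) or not obs:
        raise DomainError("observed and modelled curve lists must match")
    o_all, m_all = [], []
    for co, cm in zip(obs, mod):
        if co.direction != cm.direction or not np.allclose(co.stretch, cm.stretch):
            raise DomainError("curves must share direction and stretch grid")
        o_all.append(co.stress)
        m_all.append(cm.stress)
    o = np.concatenate(o_all)
    m = np.concatenate(m_all)
    s_res = float(np.sum((o - m) ** 2))
    s_tot = float(np.sum((o - o.mean()) ** 2))
    if s_tot == 0.0:
        raise UndefinedStatisticError("R^2 undefined: observed signal is constant")
    return GoodnessOfFit(1.0 - s_res / s_tot, s_res, s_tot, int(o.size))
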