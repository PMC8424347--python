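"""Classical material-parameter identification and the standard
leave-one-out prediction baseline.

Per sample, the material parameters (c, k1, k2) are estimated by bounded
trust-region nonlinear least squares on the pooled stress residuals of all
of the sample's uniaxial curves, with the structural parameters (alpha,
kappa_ip, kappa_op) held fixed at their image-derived values.  Because the
loss surface has a c/k1 trade-off valley for single-direction data at
small stretches, the fit is multi-started from a log-spaced grid and the
condition number of the final Jacobian is reported.

The "standard fitting" prediction protocol: every sample is fitted
individually; a sample of interest is then predicted using its own
structural parameters and the componentwise median of all OTHER samples'
fitted (c, k1, k2) -- leave-one-out cross-validation over the cohort.

The latent space is the (log10 c, log10 k1, log10 k2) cloud of the fitted
cohort.  The region of interest (ROI) is the closed Euclidean ball of
radius 0.74 orders of magnitude around the componentwise median point;
samples inside it have "common" mechanical properties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constitutive import (
    FibreArchitecture,
    GoodnessOfFit,
    MaterialParams,
    StressStretchCurve,
    predict_curve,
    r_squared,
    uniaxial_stresses,
)
from .errors import DomainError, FitError, SolverError

__all__ = [
    "HistologyFractions", "SampleRecord", "FitResult", "LatentPoint",
    "FitOptions", "fit_material_params", "median_params",
    "loo_standard_prediction", "LooStandardResult", "group_fit",
    "latent_point", "roi_members", "select_test_sample",
    "ROI_RADIUS", "LATENT_FLOOR",
]

log = logging.getLogger(__name__)

#: Radius (orders of magnitude) of the latent-space region of interest.
ROI_RADIUS = 0.74

#: Positive floor applied to k1, k2 before taking log10 for latent
#: coordinates (fitted k2 is frequently exactly 0).
LATENT_FLOOR = 1e-3


@dataclass(frozen=True)
class HistologyFractions:
    """Volume fractions of collagen, elastic fibres and smooth muscle."""

    phi_co: float
    phi_ef: float
    phi_smc: float

    def __post_init__(self):
        vals = (self.phi_co, self.phi_ef, self.phi_smc)
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise DomainError(f"volume fractions must lie in [0, 1]: {vals}")
        if sum(vals) > 1.0 + 1e-6:
            raise DomainError(f"volume fractions sum to {sum(vals)} > 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.phi_co, self.phi_ef, self.phi_smc])


@dataclass
class SampleRecord:
    """One tissue sample: mechanical curves, orientation intensity plot,
    histology fractions and structural parameters, plus optional known
    ground-truth material parameters (synthetic cohorts only)."""

    sample_id: str
    curves: list
    arch: FibreArchitecture
    histology: HistologyFractions
    plot: object = None          # imaging.IntensityPlot
    ground_truth: Optional[MaterialParams] = None

    def __post_init__(self):
        if not self.curves:
            raise DomainError(f"sample {self.sample_id} has no curves")
        dirs = [c.direction for c in self.curves]
        if len(set(dirs)) != len(dirs):
            raise DomainError(f"sample {self.sample_id}: duplicate directions")


@dataclass
class FitResult:
    params: MaterialParams
    fit: GoodnessOfFit
    converged: bool
    n_restarts_used: int
    cost: float
    jacobian_cond: float


@dataclass(frozen=True)
class LatentPoint:
    """(log10 c, log10 k1, log10 k2); flagged when flooring was applied."""

    log_c: float
    log_k1: float
    log_k2: float
    floored: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.log_c, self.log_k1, self.log_k2])


@dataclass(frozen=True)
class FitOptions:
    """Bounded multi-start least-squares settings.

    Bounds: c in [1e-3, 1e3] kPa, k1 in [0, 1e4] kPa, k2 in [0, 1e3];
    5 starts on a log grid.
    """

    bounds_lo: tuple = (1e-3, 0.0, 0.0)
    bounds_hi: tuple = (1e3, 1e4, 1e3)
    n_starts: int = 5
    fibre_switch: bool = True
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12

    @property
    def starts(self):
        return [
            (1.0, 1.0, 0.1),
            (10.0, 10.0, 1.0),
            (100.0, 100.0, 10.0),
            (3.0, 30.0, 3.0),
            (30.0, 3.0, 0.3),
        ][: self.n_starts]


def _residuals(theta, curves, arch, fibre_switch):
    mat = MaterialParams(max(theta[0], 1e-12), max(theta[1], 0.0),
                         max(theta[2], 0.0))
    out = []
    for c in curves:
        try:
            sig = uniaxial_stresses(c.stretch, c.direction, arch, mat,
                                    fibre_switch=fibre_switch)
        except (SolverError, FloatingPointError):
            return np.full(sum(len(c) for c in curves), 1e6)
        out.append(sig - c.stress)
    return np.concatenate(out)


def fit_material_params(sample: SampleRecord,
                        opts: FitOptions = FitOptions()) -> FitResult:
    """Estimate (c, k1, k2) for one sample by multi-start bounded least
    squares on the pooled stress residuals of all its curves."""
    curves = sample.curves
    if not curves:
        raise DomainError("sample has no curves to fit")
    arch = sample.arch
    best = None
    n_used = 0
    for x0 in opts.starts:
        n_used += 1
        try:
            res = least_squares(
                _residuals, x0, bounds=(opts.bounds_lo, opts.bounds_hi),
                args=(curves, arch, opts.fibre_switch), method="trf",
                xtol=opts.xtol, ftol=opts.ftol, gtol=opts.gtol)
        except Exception as err:  # noqa: BLE001 - collected into FitError
            log.debug("fit start %s failed: %s", x0, err)
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.isfinite(best.cost):
        raise FitError("all least-squares starts failed", best_result=best)
    params = MaterialParams(float(best.x[0]), float(best.x[1]), float(best.x[2]))
    modelled = [predict_curve(c.stretch, c.direction, arch, params,
                              fibre_switch=opts.fibre_switch) for c in curves]
    gof = r_squared(curves, modelled)
    sv = np.linalg.svd(best.jac, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if cond > 1e8:
        log.warning("sample %s: ill-conditioned fit (cond=%.2g); "
                    "c/k1 may trade off", sample.sample_id, cond)
    return FitResult(params=params, fit=gof, converged=bool(best.success),
                     n_restarts_used=n_used, cost=float(best.cost),
                     jacobian_cond=cond)


def median_params(results: Sequence[MaterialParams]) -> MaterialParams:
    """Componentwise median; even counts use the mean of the middle two."""
    if not results:
        raise DomainError("empty parameter list")
    arr = np.array([[p.c, p.k1, p.k2] for p in results])
    med = np.median(arr, axis=0)
    return MaterialParams(float(med[0]), float(med[1]), float(max(med[2], 0.0)))


@dataclass
class LooStandardResult:
    """Per-sample leave-one-out standard-fitting predictions."""

    sample_ids: list
    r2: dict                    # sample_id -> R^2
    params_used: dict           # sample_id -> MaterialParams (median of others)
    fits: dict                  # sample_id -> FitResult (individual fit)
    errors: dict = field(default_factory=dict)

    def median_r2(self, exclude_below: Optional[float] = None) -> float:
        vals = [v for v in self.r2.values()
                if exclude_below is None or v >= exclude_below]
        if not vals:
            raise DomainError("no folds left after exclusion")
        return float(np.median(vals))

    def sd_r2(self, exclude_below: Optional[float] = None) -> float:
        vals = [v for v in self.r2.values()
                if exclude_below is None or v >= exclude_below]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def loo_standard_prediction(samples: Sequence[SampleRecord],
                            opts: FitOptions = FitOptions(),
                            fits: Optional[dict] = None) -> LooStandardResult:
    """Leave-one-out standard-fitting prediction over a cohort.

    Each sample's curves are predicted from its own structural parameters
    and the componentwise median of the other samples' individually fitted
    material parameters.  Per-sample fit failures are recorded, logged and
    skipped without aborting the cohort.
    """
    if len(samples) < 2:
        raise DomainError("leave-one-out needs at least 2 samples")
    if fits is None:
        fits = {}
        for s in samples:
            try:
                fits[s.sample_id] = fit_material_params(s, opts)
            except FitError as err:
                log.warning("fit failed for sample %s: %s", s.sample_id, err)
    result = LooStandardResult(sample_ids=[s.sample_id for s in samples],
                               r2={}, params_used={}, fits=fits)
    for s in samples:
        others = [fits[t.sample_id].params for t in samples
                  if t.sample_id != s.sample_id and t.sample_id in fits]
        if not others:
            result.errors[s.sample_id] = "no other fitted samples"
            continue
        med = median_params(others)
        try:
            modelled = [predict_curve(c.stretch, c.direction, s.arch, med,
                                      fibre_switch=opts.fibre_switch)
                        for c in s.curves]
            result.r2[s.sample_id] = r_squared(s.curves, modelled).r2
            result.params_used[s.sample_id] = med
        except (SolverError, DomainError) as err:
            log.warning("prediction failed for sample %s: %s", s.sample_id, err)
            result.errors[s.sample_id] = str(err)
    return result


def group_fit(samples: Sequence[SampleRecord],
              opts: FitOptions = FitOptions()) -> FitResult:
    """Single (c, k1, k2) minimizing the pooled residuals of all training
    samples' curves, each sample keeping its own structural parameters.
    (The alternative transfer baseline; kept for comparison only.)"""
    if not samples:
        raise DomainError("group fit needs at least one sample")

    def resid(theta):
        return np.concatenate([
            _residuals(theta, s.curves, s.arch, opts.fibre_switch)
            for s in samples])

    best = None
    n_used = 0
    for x0 in opts.starts:
        n_used += 1
        try:
            res = least_squares(resid, x0,
                                bounds=(opts.bounds_lo, opts.bounds_hi),
                                method="trf", xtol=opts.xtol, ftol=opts.ftol,
                                gtol=opts.gtol)
        except Exception as err:  # noqa: BLE001
            log.debug("group fit start %s failed: %s", x0, err)
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.isfinite(best.cost):
        raise FitError("all group-fit starts failed", best_result=best)
    params = MaterialParams(*map(float, best.x))
    obs, mod = [], []
    for s in samples:
        for c in s.curves:
            obs.append(c)
            mod.append(predict_curve(c.stretch, c.direction, s.arch, params,
                                     fibre_switch=opts.fibre_switch))
    gof = r_squared(obs, mod)
    sv = np.linalg.svd(best.jac, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    return FitResult(params=params, fit=gof, converged=bool(best.success),
                     n_restarts_used=n_used, cost=float(best.cost),
                     jacobian_cond=cond)


def latent_point(params: MaterialParams,
                 floor: float = LATENT_FLOOR) -> LatentPoint:
    """(log10 c, log10 k1, log10 k2) with k1, k2 floored at ``floor``."""
    floored = params.k1 < floor or params.k2 < floor
    return LatentPoint(
        log_c=float(np.log10(max(params.c, floor))),
        log_k1=float(np.log10(max(params.k1, floor))),
        log_k2=float(np.log10(max(params.k2, floor))),
        floored=floored,
    )


def _median_point(points: Sequence[LatentPoint]) -> np.ndarray:
    return np.median(np.array([p.as_array() for p in points]), axis=0)


def roi_members(points: dict, center: Optional[LatentPoint] = None,
                radius: float = ROI_RADIUS) -> set:
    """IDs whose latent points lie in the closed ball of ``radius`` around
    ``center`` (componentwise median of all points when not given)."""
    if not points:
        return set()
    ctr = center.as_array() if center is not None else _median_point(
        list(points.values()))
    out = set()
    for sid, p in points.items():
        if np.linalg.norm(p.as_array() - ctr) <= radius:
            out.add(sid)
    return out


def select_test_sample(points: dict, excluded_id) -> str:
    """The non-excluded sample closest (log-space Euclidean) to the
    componentwise median of all non-excluded points; ties break to the
    lowest sample id."""
    cand = {sid: p for sid, p in points.items() if sid != excluded_id}
    if len(cand) < 2:
        raise DomainError("need at least 2 candidate samples")
    ctr = _median_point(list(cand.values()))
    best_id, best_d = None, np.inf
    for sid in sorted(cand):
        d = float(np.linalg.norm(cand[sid].as_array() - ctr))
        if d < best_d - 1e-15:
            best_id, best_d = sid, d
    return best_id
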