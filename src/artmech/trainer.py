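"""Training loop and leave-one-out cross-validation protocols for the
hybrid model.

Training minimizes the mean squared error between model stresses and the
measured stresses of randomly batched stress-stretch pairs (Adam, fixed
learning rate, Glorot initialization).  The stress of a pair is evaluated
at its measured stretch through the uniaxial equilibrium solution: the
in-plane transverse stretch of every pair is recomputed each batch by a
warm-started Newton update (bisection fallback) at the current predicted
parameters and treated as locally constant within the step, so the loss
gradient with respect to (c, k1, k2) -- and through the network weights --
is exact and cheap.  The choice is recorded in the run configuration.

The multi-restart protocol runs all restarts as independent "lanes" of a
single ensemble network (see :mod:`artmech.nn`): every restart sees the
same batch sequence (drawn from the fold seed) but its own Glorot
initialization (drawn from per-restart seeds spawned from the master
seed).  Early stopping selects, per restart, the checkpoint from the epoch
with the best test-sample R^2 (ties to the earliest epoch); the restart
with the best validation R^2 wins.

Two cross-validation strategies:

* ``loo_cv_roi`` -- validation folds iterate only over samples inside the
  latent region of interest; the test sample of each fold is the
  remaining sample closest to the latent median of the others.
* ``loo_cv_full`` -- folds iterate over all samples, and the held-out
  sample serves as both test and validation sample.  This mimics a
  data-rich setting and is leakage by construction (the early-stopping
  signal sees the held-out sample); it is reproduced deliberately and
  flagged in the result.

Training-sample augmentation statically expands each training sample into
``aug_copies`` periodically shifted intensity-plot copies (shifts drawn
without replacement from {1..53}); test and validation samples are never
augmented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .constitutive import predict_curve, r_squared
from .errors import DomainError
from .fitting import (
    FitOptions,
    SampleRecord,
    fit_material_params,
    latent_point,
    roi_members,
    select_test_sample,
)
from .hybridnet import DLBlockSpec, HybridNet
from .imaging import PLOT_COLS, augment_shift
from .nn import Adam

__all__ = [
    "TrainConfig", "Split", "CVResult", "FoldResult", "TrainedState",
    "mse_loss", "make_batches", "train_once", "train_with_restarts",
    "loo_cv_roi", "loo_cv_full",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol settings (defaults as published)."""

    learning_rate: float = 0.001
    epochs: int = 1000
    batch_size: int = 32
    restarts: int = 10
    aug_copies: int = 8
    master_seed: int = 0
    fibre_switch: bool = True
    loss: str = "mean_squared_error"

    def __post_init__(self):
        if min(self.learning_rate, self.epochs, self.batch_size,
               self.restarts, self.aug_copies) <= 0:
            raise DomainError("all training settings must be positive")


@dataclass(frozen=True)
class Split:
    """Train / test / validation partition of sample ids."""

    train_ids: tuple
    test_id: str
    validation_id: str

    def __post_init__(self):
        if self.validation_id in self.train_ids or self.test_id in self.train_ids:
            raise DomainError("test/validation samples must not be trained on")


@dataclass
class TrainedState:
    """Outcome of one restart (lane): selected checkpoint + log."""

    network: HybridNet             # single-lane network at the best epoch
    epoch_log: list                # (epoch, train_loss, test_r2)
    best_epoch: int
    best_test_r2: float
    validation_r2: float = np.nan
    aborted: bool = False


@dataclass
class FoldResult:
    validation_id: str
    test_id: str
    r2: float
    best_restart: int
    best_epoch: int
    restart_val_r2: list


@dataclass
class CVResult:
    """Cross-validation outcome over all folds."""

    strategy: str
    folds: List[FoldResult]
    leakage_checked: bool = False
    leakage_note: str = ""

    @property
    def per_fold_r2(self) -> Dict[str, float]:
        return {f.validation_id: f.r2 for f in self.folds}

    def r2_values(self, exclude_below: Optional[float] = None):
        vals = [f.r2 for f in self.folds
                if exclude_below is None or f.r2 >= exclude_below]
        return vals

    def median_r2(self, exclude_below: Optional[float] = None) -> float:
        vals = self.r2_values(exclude_below)
        if not vals:
            raise DomainError("no folds left after exclusion")
        return float(np.median(vals))

    def sd_r2(self, exclude_below: Optional[float] = None) -> float:
        vals = self.r2_values(exclude_below)
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    @property
    def n_excluded(self) -> int:
        return sum(1 for f in self.folds if f.r2 <= -1.0)


def mse_loss(predicted, observed):
    """Mean of squared stress residuals over a batch."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise DomainError(f"length mismatch: {p.shape} vs {o.shape}")
    return float(np.mean((p - o) ** 2))


def make_batches(n_pairs: int, rng: np.random.Generator,
                 batch_size: int = 32) -> list:
    """Random permutation of pair indices partitioned into batches; the
    final partial batch is kept.  Every pair appears exactly once."""
    if n_pairs < 1:
        raise DomainError("need at least one stress-stretch pair")
    perm = rng.permutation(n_pairs)
    return [perm[i:i + batch_size] for i in range(0, n_pairs, batch_size)]


# ---------------------------------------------------------------------------
# vectorized uniaxial mechanics for training
# ---------------------------------------------------------------------------

_EXP_CLAMP = 80.0   # exponent clamp keeping the training loss finite


def _sigma_and_grads(lam_load, lam_t, m2l, m2t, A, B, c, k1, k2, fibre_switch):
    """Loading/transverse stress and d(sigma_load)/d(c, k1, k2) with the
    transverse stretch held fixed.  All arrays broadcast together."""
    lam3 = 1.0 / (lam_load * lam_t)
    l3sq = lam3 * lam3
    llsq = lam_load * lam_load
    ltsq = lam_t * lam_t
    I1 = llsq + ltsq + l3sq
    I4 = llsq * m2l + ltsq * m2t
    istar = A * I1 + B * I4 + (1.0 - 3.0 * A - B) * l3sq
    E = istar - 1.0
    if fibre_switch:
        E = np.where(E > 0.0, E, 0.0)
    g = np.exp(np.minimum(k2 * E * E, _EXP_CLAMP))
    psi = k1 * E * g
    cn = 1.0 - 2.0 * A - B
    p = (c + 4.0 * cn * psi) * l3sq
    sig_l = (c + 4.0 * (A + B * m2l) * psi) * llsq - p
    sig_t = (c + 4.0 * (A + B * m2t) * psi) * ltsq - p
    G = 4.0 * ((A + B * m2l) * llsq - cn * l3sq)
    d_c = llsq - l3sq
    d_k1 = G * E * g
    d_k2 = G * k1 * (E ** 3) * g
    return sig_l, sig_t, d_c, d_k1, d_k2


def _sigma_t_only(lam_load, lam_t, m2l, m2t, A, B, c, k1, k2, fibre_switch):
    lam3 = 1.0 / (lam_load * lam_t)
    l3sq = lam3 * lam3
    llsq = lam_load * lam_load
    ltsq = lam_t * lam_t
    istar = (A * (llsq + ltsq + l3sq) + B * (llsq * m2l + ltsq * m2t)
             + (1.0 - 3.0 * A - B) * l3sq)
    E = istar - 1.0
    if fibre_switch:
        E = np.where(E > 0.0, E, 0.0)
    psi = k1 * E * np.exp(np.minimum(k2 * E * E, _EXP_CLAMP))
    p = (c + 4.0 * (1.0 - 2.0 * A - B) * psi) * l3sq
    return (c + 4.0 * (A + B * m2t) * psi) * ltsq - p


def _bisect_transverse(lam_load, m2l, m2t, A, B, c, k1, k2, fibre_switch,
                       lo=0.25, hi=1.9, iters=45):
    """Vectorized bisection for the transverse stretch (all-array args)."""
    lo = np.full_like(np.asarray(lam_load, dtype=float), lo)
    hi = np.full_like(lo, hi)
    flo = _sigma_t_only(lam_load, lo, m2l, m2t, A, B, c, k1, k2, fibre_switch)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = _sigma_t_only(lam_load, mid, m2l, m2t, A, B, c, k1, k2,
                           fibre_switch)
        left = np.signbit(fm) == np.signbit(flo)
        lo = np.where(left, mid, lo)
        flo = np.where(left, fm, flo)
        hi = np.where(left, hi, mid)
    return 0.5 * (lo + hi)


def _newton_transverse(lam_load, lam_t0, m2l, m2t, A, B, c, k1, k2,
                       fibre_switch, iters=3):
    """Warm-started damped Newton on the transverse equilibrium; falls
    back to bisection where the update left the bracket or stalled."""
    lt = np.clip(lam_t0, 0.25, 1.9)
    h = 1e-6
    for _ in range(iters):
        f = _sigma_t_only(lam_load, lt, m2l, m2t, A, B, c, k1, k2, fibre_switch)
        fp = _sigma_t_only(lam_load, lt + h, m2l, m2t, A, B, c, k1, k2,
                           fibre_switch)
        df = (fp - f) / h
        step = np.where(np.abs(df) > 1e-30, f / np.where(df == 0, 1, df), 0.0)
        lt = np.clip(lt - np.clip(step, -0.2, 0.2), 0.25, 1.9)
    f = _sigma_t_only(lam_load, lt, m2l, m2t, A, B, c, k1, k2, fibre_switch)
    bad = ~(np.abs(f) <= 1e-6 * np.maximum(1.0, np.abs(c) * 10 + k1))
    if np.any(bad):
        lt_b = _bisect_transverse(lam_load[..., :], m2l, m2t, A, B, c, k1, k2,
                                  fibre_switch)
        lt = np.where(bad, lt_b, lt)
    return lt


# ---------------------------------------------------------------------------
# fold workspace
# ---------------------------------------------------------------------------

class _FoldData:
    """Augmented training pool of one fold: image stack, histology,
    per-pair mechanics constants and the transverse-stretch cache."""

    def __init__(self, samples_by_id, split: Split, config: TrainConfig,
                 rng: np.random.Generator, dtype=np.float32):
        images, hists = [], []
        pair_cols = {k: [] for k in ("copy", "lam", "sig", "m2l", "m2t",
                                     "A", "B")}
        self.copy_sample_ids = []
        for sid in split.train_ids:
            s = samples_by_id[sid]
            shifts = rng.choice(np.arange(1, PLOT_COLS), size=config.aug_copies,
                                replace=False)
            arch = s.arch
            ca2 = np.cos(arch.alpha) ** 2
            sa2 = np.sin(arch.alpha) ** 2
            for sh in shifts:
                ci = len(images)
                images.append(augment_shift(s.plot, int(sh)).grid)
                hists.append(s.histology.as_array())
                self.copy_sample_ids.append(sid)
                for curve in s.curves:
                    m2l = ca2 if curve.direction == "circ" else sa2
                    m2t = sa2 if curve.direction == "circ" else ca2
                    for lam, sig in zip(curve.stretch, curve.stress):
                        pair_cols["copy"].append(ci)
                        pair_cols["lam"].append(lam)
                        pair_cols["sig"].append(sig)
                        pair_cols["m2l"].append(m2l)
                        pair_cols["m2t"].append(m2t)
                        pair_cols["A"].append(arch.A)
                        pair_cols["B"].append(arch.B)
        self.images = np.asarray(images, dtype=dtype)
        self.hist = np.asarray(hists, dtype=dtype)
        self.copy = np.asarray(pair_cols["copy"])
        self.pairs = {k: np.asarray(v, dtype=float)
                      for k, v in pair_cols.items() if k != "copy"}
        self.n_pairs = self.copy.size
        self.n_copies = len(images)

    def pair_arrays(self, idx):
        p = self.pairs
        return (self.copy[idx], p["lam"][idx], p["sig"][idx], p["m2l"][idx],
                p["m2t"][idx], p["A"][idx], p["B"][idx])


def _eval_sample_r2(net: HybridNet, sample: SampleRecord,
                    fibre_switch: bool) -> np.ndarray:
    """Per-lane pooled R^2 of the hybrid prediction for one sample."""
    out = net.forward(sample.plot.grid[None], sample.histology.as_array()[None],
                      training=False)   # (R, 1, 3)
    arch = sample.arch
    ca2 = np.cos(arch.alpha) ** 2
    sa2 = np.sin(arch.alpha) ** 2
    r2 = np.empty(net.n_lanes)
    obs = np.concatenate([c.stress for c in sample.curves])
    s_tot = float(np.sum((obs - obs.mean()) ** 2))
    for r in range(net.n_lanes):
        c, k1, k2 = [float(v) for v in out[r, 0]]
        preds = []
        for curve in sample.curves:
            m2l = ca2 if curve.direction == "circ" else sa2
            m2t = sa2 if curve.direction == "circ" else ca2
            lt = _bisect_transverse(curve.stretch, m2l, m2t, arch.A, arch.B,
                                    c, k1, k2, fibre_switch)
            sig = _sigma_and_grads(curve.stretch, lt, m2l, m2t, arch.A, arch.B,
                                   c, k1, k2, fibre_switch)[0]
            preds.append(sig)
        res = np.concatenate(preds) - obs
        r2[r] = 1.0 - float(np.sum(res ** 2)) / s_tot if s_tot > 0 else np.nan
    return r2


# ---------------------------------------------------------------------------
# training engine
# ---------------------------------------------------------------------------

def _train_lanes(samples_by_id, split: Split, config: TrainConfig,
                 init_seeds: Sequence[int], batch_seed: int,
                 spec: DLBlockSpec = DLBlockSpec()) -> List[TrainedState]:
    """Train ``len(init_seeds)`` restarts in lockstep lanes.

    All lanes share the batch sequence drawn from ``batch_seed``; lane r is
    Glorot-initialized from ``init_seeds[r]``.  Returns one TrainedState
    per lane with the checkpoint of its best test epoch.
    """
    R = len(init_seeds)
    rng = np.random.default_rng(batch_seed)
    data = _FoldData(samples_by_id, split, config, rng)
    test_sample = samples_by_id[split.test_id]

    # lanes with explicit per-restart init seeds
    net = HybridNet(spec, seed=0, dtype=np.float32, n_lanes=R)
    for r, s in enumerate(init_seeds):
        single = HybridNet(spec, seed=int(s), dtype=np.float32, n_lanes=1)
        net.set_lane_state(r, single.get_lane_state(0))
    opt = Adam(net.params, lr=config.learning_rate)

    stem_cache = net.stem_cols(data.images)
    cols_all, n_imgs, oh, ow = stem_cache
    cols_per_img = cols_all.reshape(n_imgs, oh * ow, -1)

    # transverse-stretch cache per (lane, pair), filled at initial params
    p = data.pairs
    params0 = net.forward(data.images, data.hist, training=False)  # (R,C,3)
    cpar = params0[:, data.copy, :]                                # (R,P,3)
    lt_cache = _bisect_transverse(
        p["lam"][None, :], p["m2l"][None, :], p["m2t"][None, :],
        p["A"][None, :], p["B"][None, :],
        cpar[..., 0], cpar[..., 1], cpar[..., 2], config.fibre_switch)

    logs = [[] for _ in range(R)]
    best = [{"r2": -np.inf, "epoch": -1, "state": None} for _ in range(R)]
    dead = np.zeros(R, dtype=bool)

    for epoch in range(1, config.epochs + 1):
        ep_loss = np.zeros(R)
        n_batches = 0
        for idx in make_batches(data.n_pairs, rng, config.batch_size):
            uniq, inv = np.unique(data.copy[idx], return_inverse=True)
            sel_cols = cols_per_img[uniq].reshape(1, -1, cols_per_img.shape[-1])
            out = net.forward(None, data.hist[uniq], training=True,
                              stem_cols=(sel_cols, uniq.size, oh, ow))
            pp = out[:, inv, :].astype(float)     # (R, B, 3)
            lam = p["lam"][idx][None, :]
            m2l = p["m2l"][idx][None, :]
            m2t = p["m2t"][idx][None, :]
            A = p["A"][idx][None, :]
            B = p["B"][idx][None, :]
            sig_exp = p["sig"][idx][None, :]
            c, k1, k2 = pp[..., 0], pp[..., 1], pp[..., 2]
            lt = _newton_transverse(np.broadcast_to(lam, c.shape), lt_cache[:, idx],
                                    m2l, m2t, A, B, c, k1, k2,
                                    config.fibre_switch)
            lt_cache[:, idx] = lt
            sig, _, d_c, d_k1, d_k2 = _sigma_and_grads(
                lam, lt, m2l, m2t, A, B, c, k1, k2, config.fibre_switch)
            res = sig - sig_exp
            loss = np.mean(res ** 2, axis=1)
            bad = ~np.isfinite(loss)
            if np.any(bad & ~dead):
                for r in np.where(bad & ~dead)[0]:
                    log.warning("restart %d: non-finite loss at epoch %d; "
                                "lane aborted", r, epoch)
                dead |= bad
            ep_loss += np.where(np.isfinite(loss), loss, 0.0)
            n_batches += 1
            dres = 2.0 * res / res.shape[1]
            dres[dead] = 0.0
            dpp = np.stack([dres * d_c, dres * d_k1, dres * d_k2], axis=2)
            # accumulate pair gradients onto their unique images
            dout = np.zeros(out.shape, dtype=np.float64)
            np.add.at(dout, (slice(None), inv), dpp)
            net.zero_grad()
            net.backward(dout.astype(net.dtype))
            opt.step()
        test_r2 = _eval_sample_r2(net, test_sample, config.fibre_switch)
        for r in range(R):
            logs[r].append((epoch, float(ep_loss[r] / max(n_batches, 1)),
                            float(test_r2[r])))
            if not dead[r] and test_r2[r] > best[r]["r2"] + 1e-15:
                best[r] = {"r2": float(test_r2[r]), "epoch": epoch,
                           "state": net.get_lane_state(r)}

    states = []
    for r in range(R):
        if best[r]["state"] is None:
            states.append(TrainedState(network=net.extract_lane(r),
                                       epoch_log=logs[r], best_epoch=-1,
                                       best_test_r2=-np.inf, aborted=True))
            continue
        single = HybridNet(spec, seed=0, dtype=np.float32, n_lanes=1)
        single.set_lane_state(0, best[r]["state"])
        states.append(TrainedState(network=single, epoch_log=logs[r],
                                   best_epoch=best[r]["epoch"],
                                   best_test_r2=best[r]["r2"],
                                   aborted=bool(dead[r])))
    return states


def train_once(samples, split: Split, config: TrainConfig,
               init_seed: int, batch_seed: Optional[int] = None,
               spec: DLBlockSpec = DLBlockSpec()) -> TrainedState:
    """Single-restart training run (one lane)."""
    samples_by_id = {s.sample_id: s for s in samples} \
        if not isinstance(samples, dict) else samples
    bs = init_seed if batch_seed is None else batch_seed
    return _train_lanes(samples_by_id, split, config, [init_seed], bs,
                        spec)[0]


def train_with_restarts(samples, split: Split, config: TrainConfig,
                        fold_seed: Optional[int] = None,
                        spec: DLBlockSpec = DLBlockSpec(),
                        validation_sample: Optional[SampleRecord] = None):
    """Multi-restart training; returns (best TrainedState, all states).

    Restart init seeds and the shared batch stream are derived from
    ``fold_seed`` (default: the config master seed).  The winning restart
    maximizes R^2 on the validation sample (the test sample when no
    validation sample is given).
    """
    samples_by_id = {s.sample_id: s for s in samples} \
        if not isinstance(samples, dict) else samples
    seed = config.master_seed if fold_seed is None else fold_seed
    ss = np.random.SeedSequence(seed)
    batch_seed = int(ss.generate_state(1)[0] % (2 ** 31))
    init_seeds = [int(c.generate_state(1)[0] % (2 ** 31))
                  for c in ss.spawn(config.restarts)]
    states = _train_lanes(samples_by_id, split, config, init_seeds,
                          batch_seed, spec)
    vs = validation_sample if validation_sample is not None \
        else samples_by_id[split.test_id]
    for st in states:
        if st.aborted and st.best_epoch < 0:
            st.validation_r2 = -np.inf
            continue
        st.validation_r2 = float(_eval_sample_r2(st.network, vs,
                                                 config.fibre_switch)[0])
    if all(st.aborted and st.best_epoch < 0 for st in states):
        raise DomainError("all restarts aborted with non-finite loss")
    best = int(np.argmax([st.validation_r2 for st in states]))
    return states[best], states


# ---------------------------------------------------------------------------
# cross-validation protocols
# ---------------------------------------------------------------------------

def _check_no_leakage(split: Split, cv: CVResult):
    if split.validation_id in split.train_ids:
        raise DomainError(f"leakage: validation sample {split.validation_id} "
                          "in training set")
    cv.leakage_checked = True


def _latent_points(samples, fits, fit_opts):
    if fits is None:
        fits = {s.sample_id: fit_material_params(s, fit_opts) for s in samples}
    return {sid: latent_point(f.params) for sid, f in fits.items()}, fits


def loo_cv_roi(samples: Sequence[SampleRecord], config: TrainConfig,
               fits: Optional[dict] = None,
               fit_opts: FitOptions = FitOptions(),
               spec: DLBlockSpec = DLBlockSpec(),
               max_folds: Optional[int] = None) -> CVResult:
    """Region-of-interest LOO-CV: folds iterate over ROI members only;
    each fold's test sample is the non-validation sample closest to the
    latent median of the remaining samples.

    ``max_folds`` keeps only the ROI members closest to the cohort latent
    median (the samples with the most common mechanical properties), the
    way the published protocol validated a six-sample ROI.
    """
    samples_by_id = {s.sample_id: s for s in samples}
    points, fits = _latent_points(samples, fits, fit_opts)
    roi = roi_members(points)
    if not roi:
        raise DomainError("latent region of interest is empty")
    fold_ids = sorted(roi)
    if max_folds is not None and len(fold_ids) > max_folds:
        ctr = np.median(np.array([p.as_array() for p in points.values()]),
                        axis=0)
        fold_ids = sorted(sorted(
            fold_ids,
            key=lambda sid: (float(np.linalg.norm(points[sid].as_array() - ctr)),
                             sid))[:max_folds])
    cv = CVResult(strategy="roi", folds=[])
    ss = np.random.SeedSequence(config.master_seed)
    fold_seeds = {sid: int(c.generate_state(1)[0] % (2 ** 31))
                  for sid, c in zip(fold_ids, ss.spawn(len(fold_ids)))}
    for vid in fold_ids:
        test_id = select_test_sample(points, excluded_id=vid)
        train_ids = tuple(sid for sid in sorted(samples_by_id)
                          if sid not in (vid, test_id))
        split = Split(train_ids=train_ids, test_id=test_id, validation_id=vid)
        _check_no_leakage(split, cv)
        best, states = train_with_restarts(
            samples_by_id, split, config, fold_seed=fold_seeds[vid], spec=spec,
            validation_sample=samples_by_id[vid])
        cv.folds.append(FoldResult(
            validation_id=vid, test_id=test_id, r2=best.validation_r2,
            best_restart=states.index(best), best_epoch=best.best_epoch,
            restart_val_r2=[st.validation_r2 for st in states]))
        log.info("ROI fold %s: R2=%.4f (test %s, restart %d, epoch %d)",
                 vid, best.validation_r2, test_id, states.index(best),
                 best.best_epoch)
    return cv


def loo_cv_full(samples: Sequence[SampleRecord], config: TrainConfig,
                spec: DLBlockSpec = DLBlockSpec()) -> CVResult:
    """Full-cohort LOO-CV with the held-out sample used as both test and
    validation sample (deliberate leakage mimicking a data-rich test set;
    flagged in the result)."""
    samples_by_id = {s.sample_id: s for s in samples}
    cv = CVResult(strategy="full", folds=[],
                  leakage_note=("held-out sample drives early stopping by "
                                "protocol (data-rich mimicry)"))
    ss = np.random.SeedSequence(config.master_seed)
    ids = sorted(samples_by_id)
    fold_seeds = {sid: int(c.generate_state(1)[0] % (2 ** 31))
                  for sid, c in zip(ids, ss.spawn(len(ids)))}
    for vid in ids:
        train_ids = tuple(sid for sid in ids if sid != vid)
        split = Split(train_ids=train_ids, test_id=vid, validation_id=vid)
        _check_no_leakage(split, cv)
        best, states = train_with_restarts(
            samples_by_id, split, config, fold_seed=fold_seeds[vid], spec=spec,
            validation_sample=samples_by_id[vid])
        cv.folds.append(FoldResult(
            validation_id=vid, test_id=vid, r2=best.validation_r2,
            best_restart=states.index(best), best_epoch=best.best_epoch,
            restart_val_r2=[st.validation_r2 for st in states]))
        log.info("full fold %s: R2=%.4f (restart %d, epoch %d)",
                 vid, best.validation_r2, states.index(best), best.best_epoch)
    return cv
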