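"""Hybrid model: residual-network encoder + dense softplus head composed
with the dispersed-fibre constitutive law.

The encoder maps a 68 x 54 collagen-orientation intensity plot to 16
features: a 7x7 stride-2 convolution stem with 3x3/stride-2 max pooling,
followed by four residual blocks of four 3x3 convolutions each (two skip
connections per block, one after each pair of convolutions) with ReLU
activations and batch normalization.  Filter counts start at 2 and double
after each block (2, 4, 8, 16); blocks 2-4 downsample with stride 2 using
a 1x1 projection on the skip path.  Convolution-layer count: 1 stem + 16
in blocks = 17.

The encoder output is globally average-pooled, concatenated with the three
histological volume fractions (phi_CO, phi_EF, phi_SMC) and passed through
a densely connected feedforward head of [12, 8, 4] units with softplus
activations plus a final 3-unit softplus layer, so the predicted material
parameters (c, k1, k2) are strictly positive by construction.

Weights use Glorot uniform initialization, deterministic for a given seed.
A network can hold several independent "lanes" (weight sets sharing one
forward pass; see :mod:`artmech.nn`), which the trainer uses to run the
multi-restart protocol in lockstep.  ``n_lanes=1`` is the ordinary case.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .constitutive import (
    FibreArchitecture,
    GoodnessOfFit,
    MaterialParams,
    predict_curve,
    r_squared,
)
from .errors import DomainError
from .nn import Adam, BatchNorm2D, Conv2D, Dense, GlobalAvgPool, MaxPool2D, ReLU, Softplus

__all__ = [
    "DLBlockSpec", "HybridNet", "HybridPrediction",
    "build_dl_block", "forward", "hybrid_predict", "INPUT_SHAPE",
]

INPUT_SHAPE = (68, 54)


@dataclass(frozen=True)
class DLBlockSpec:
    """Architecture description of the deep-learning block."""

    input_shape: tuple = INPUT_SHAPE
    stem_kernel: int = 7
    stem_stride: int = 2
    pool_kernel: int = 3
    pool_stride: int = 2
    n_blocks: int = 4
    convs_per_block: int = 4
    filters: tuple = (2, 4, 8, 16)
    head_units: tuple = (12, 8, 4)
    n_outputs: int = 3
    n_histology: int = 3
    bn_momentum: float = 0.99
    #: optional softplus-space bias initialization of the output layer
    #: (predictions start near the given (c, k1, k2) scale instead of
    #: O(1)).  None keeps the plain Glorot/zero-bias initialization the
    #: training protocol describes, which is the default.
    output_scale_init: tuple = None

    def __post_init__(self):
        if len(self.filters) != self.n_blocks:
            raise DomainError("one filter count per residual block required")
        if self.n_outputs != 3:
            raise DomainError("the head predicts exactly (c, k1, k2)")

    @property
    def n_conv_layers(self) -> int:
        """Main-path convolution layers (stem + residual blocks)."""
        return 1 + self.n_blocks * self.convs_per_block

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True, default=list)

    @property
    def sha256(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


class _ResidualUnit:
    """Two 3x3 convolutions with batch norm and a skip connection.

    The first unit of a downsampling block uses stride 2 on its first
    convolution and a 1x1 stride-2 projection (with batch norm) on the
    skip path; otherwise the skip is the identity.
    """

    def __init__(self, in_ch, out_ch, stride, rngs, dtype, momentum, name):
        R = len(rngs)
        self.conv1 = Conv2D(in_ch, out_ch, 3, stride, 1, rngs, dtype,
                            name + ".conv1", bias=False)
        self.bn1 = BatchNorm2D(out_ch, R, momentum, dtype=dtype,
                               name=name + ".bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2D(out_ch, out_ch, 3, 1, 1, rngs, dtype,
                            name + ".conv2", bias=False)
        self.bn2 = BatchNorm2D(out_ch, R, momentum, dtype=dtype,
                               name=name + ".bn2")
        self.relu2 = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2D(in_ch, out_ch, 1, stride, 0, rngs, dtype,
                               name + ".proj", bias=False)
            self.proj_bn = BatchNorm2D(out_ch, R, momentum, dtype=dtype,
                                       name=name + ".proj_bn")
        else:
            self.proj = None
            self.proj_bn = None

    @property
    def conv_layers(self):
        return [self.conv1, self.conv2]

    @property
    def params(self):
        out = [*self.conv1.params, *self.bn1.params,
               *self.conv2.params, *self.bn2.params]
        if self.proj is not None:
            out += [*self.proj.params, *self.proj_bn.params]
        return out

    @property
    def bn_layers(self):
        out = [self.bn1, self.bn2]
        if self.proj_bn is not None:
            out.append(self.proj_bn)
        return out

    def forward(self, x, training=False):
        y = self.conv1.forward(x, training)
        y = self.bn1.forward(y, training)
        y = self.relu1.forward(y, training)
        y = self.conv2.forward(y, training)
        y = self.bn2.forward(y, training)
        if self.proj is not None:
            skip = self.proj_bn.forward(self.proj.forward(x, training), training)
        else:
            skip = x
        y += skip
        return self.relu2.forward(y, training)

    def backward(self, dy):
        d = self.relu2.backward(dy)
        dmain = self.bn2.backward(d)
        dmain = self.conv2.backward(dmain)
        dmain = self.relu1.backward(dmain)
        dmain = self.bn1.backward(dmain)
        dmain = self.conv1.backward(dmain)
        if self.proj is not None:
            dskip = self.proj.backward(self.proj_bn.backward(d))
            dmain += dskip
        else:
            dmain += d
        return dmain


class HybridNet:
    """Deep-learning block: residual encoder + dense softplus head.

    ``forward`` maps (intensity plots, histology fractions) to strictly
    positive material parameters of shape (n_lanes, N, 3); ``backward``
    propagates parameter-space gradients to every weight.
    """

    def __init__(self, spec: DLBlockSpec = DLBlockSpec(), seed: int = 0,
                 dtype=np.float32, n_lanes: int = 1):
        self.spec = spec
        self.dtype = dtype
        self.n_lanes = n_lanes
        self.seed = seed
        rngs = [np.random.default_rng(s)
                for s in np.random.SeedSequence(seed).spawn(n_lanes)] \
            if n_lanes > 1 else [np.random.default_rng(seed)]
        mom = spec.bn_momentum

        self.stem = Conv2D(1, spec.filters[0], spec.stem_kernel, spec.stem_stride,
                           spec.stem_kernel // 2, rngs, dtype, "stem",
                           need_input_grad=False, bias=False)
        self.stem_bn = BatchNorm2D(spec.filters[0], n_lanes, mom, dtype=dtype,
                                   name="stem_bn")
        self.stem_relu = ReLU()
        self.pool = MaxPool2D(spec.pool_kernel, spec.pool_stride, 1)

        self.units = []
        in_ch = spec.filters[0]
        for b, f in enumerate(spec.filters):
            stride = 1 if b == 0 else 2
            self.units.append(_ResidualUnit(in_ch, f, stride, rngs, dtype, mom,
                                            f"block{b + 1}.unit1"))
            self.units.append(_ResidualUnit(f, f, 1, rngs, dtype, mom,
                                            f"block{b + 1}.unit2"))
            in_ch = f

        self.gap = GlobalAvgPool()
        n_feat = spec.filters[-1] + spec.n_histology
        self.head = []
        widths = [n_feat, *spec.head_units, spec.n_outputs]
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            self.head.append(Dense(a, b, rngs, dtype, f"head{i + 1}"))
            self.head.append(Softplus())
        if spec.output_scale_init is not None:
            # inverse softplus of the target scale
            scale = np.asarray(spec.output_scale_init, dtype=dtype)
            out_dense = self.head[-2]
            out_dense.b.value[...] = np.log(np.expm1(scale))
        self._n_hist = spec.n_histology

    # -- introspection ----------------------------------------------------
    @property
    def conv_layers(self):
        """Main-path convolutions: stem + 4 per residual block (17 total).
        Skip-path 1x1 projections are listed separately."""
        out = [self.stem]
        for u in self.units:
            out.extend(u.conv_layers)
        return out

    @property
    def projection_layers(self):
        return [u.proj for u in self.units if u.proj is not None]

    @property
    def filter_schedule(self):
        return tuple(self.spec.filters)

    @property
    def params(self):
        out = [*self.stem.params, *self.stem_bn.params]
        for u in self.units:
            out.extend(u.params)
        for layer in self.head:
            out.extend(layer.params)
        return out

    @property
    def bn_layers(self):
        out = [self.stem_bn]
        for u in self.units:
            out.extend(u.bn_layers)
        return out

    # -- forward / backward ------------------------------------------------
    def _check_images(self, images):
        x = np.asarray(images, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.spec.input_shape:
            raise DomainError(
                f"intensity plots must have shape {self.spec.input_shape}, "
                f"got {x.shape[1:]}")
        if not np.isfinite(x).all():
            raise DomainError("non-finite network inputs")
        return x

    def stem_cols(self, images):
        """Precompute the stem's im2col matrix for a fixed image set (the
        stem input windows never change during training, so the trainer
        builds them once per fold and indexes into them per batch).
        Returns (cols, n, oh, ow) with cols of shape (1, n*oh*ow, k*k)."""
        x = self._check_images(images)
        return self.stem.im2col(x[None, :, None])

    def encode(self, images, training=False, stem_cols=None):
        """Encoder features (n_lanes, N, 16) from plots (N, 68, 54)."""
        if stem_cols is not None:
            cols, n, oh, ow = stem_cols
            x = self.stem.forward_cols(cols, n, oh, ow)
        else:
            x = self._check_images(images)
            x = self.stem.forward(x[None, :, None], training)
        x = self.stem_bn.forward(x, training)
        x = self.stem_relu.forward(x, training)
        x = self.pool.forward(x, training)
        for u in self.units:
            x = u.forward(x, training)
        return self.gap.forward(x, training)

    def forward(self, images, histology, training=False, stem_cols=None):
        """Material parameters (n_lanes, N, 3) = (c, k1, k2), positive."""
        hist = np.atleast_2d(np.asarray(histology, dtype=self.dtype))
        if not np.isfinite(hist).all():
            raise DomainError("non-finite network inputs")
        if hist.shape[-1] != self._n_hist:
            raise DomainError(f"expected {self._n_hist} histology fractions")
        feats = self.encode(images, training, stem_cols=stem_cols)
        self._n_feat = feats.shape[-1]
        hist_b = np.broadcast_to(hist[None], (feats.shape[0],) + hist.shape)
        z = np.concatenate([feats, hist_b], axis=2)
        for layer in self.head:
            z = layer.forward(z, training)
        return z

    def backward(self, dparams):
        """Backpropagate d(loss)/d(c,k1,k2) of shape (n_lanes, N, 3);
        accumulates gradients on every parameter."""
        d = np.asarray(dparams, dtype=self.dtype)
        for layer in reversed(self.head):
            d = layer.backward(d)
        dfeat = np.ascontiguousarray(d[:, :, :self._n_feat])
        x = self.gap.backward(dfeat)
        for u in reversed(self.units):
            x = u.backward(x)
        x = self.pool.backward(x)
        x = self.stem_relu.backward(x)
        x = self.stem_bn.backward(x)
        self.stem.backward(x)
        return dfeat

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    # -- lane handling -----------------------------------------------------
    def get_lane_state(self, lane: int):
        """Snapshot (copy) of one lane's weights and batch-norm statistics."""
        state = {p.name: p.value[lane].copy() for p in self.params}
        for bn in self.bn_layers:
            state[bn.name + ".running_mean"] = bn.running_mean[lane].copy()
            state[bn.name + ".running_var"] = bn.running_var[lane].copy()
        return state

    def set_lane_state(self, lane: int, state):
        for p in self.params:
            p.value[lane] = state[p.name]
        for bn in self.bn_layers:
            bn.running_mean[lane] = state[bn.name + ".running_mean"]
            bn.running_var[lane] = state[bn.name + ".running_var"]

    def extract_lane(self, lane: int) -> "HybridNet":
        """Single-lane copy of one weight set (for prediction / saving)."""
        net = HybridNet(self.spec, seed=self.seed, dtype=self.dtype, n_lanes=1)
        net.set_lane_state(0, self.get_lane_state(lane))
        return net

    # -- serialization -----------------------------------------------------
    def state_dict(self):
        state = {p.name: p.value for p in self.params}
        for bn in self.bn_layers:
            state[bn.name + ".running_mean"] = bn.running_mean
            state[bn.name + ".running_var"] = bn.running_var
        return state

    def load_state_dict(self, state):
        for p in self.params:
            p.value = np.array(state[p.name], dtype=self.dtype)
        for bn in self.bn_layers:
            bn.running_mean = np.array(state[bn.name + ".running_mean"],
                                       dtype=self.dtype)
            bn.running_var = np.array(state[bn.name + ".running_var"],
                                      dtype=self.dtype)

    def save(self, path):
        """Checkpoint (npz) with an embedded architecture hash."""
        np.savez(path, __spec_json__=self.spec.to_json(),
                 __spec_sha256__=self.spec.sha256,
                 __n_lanes__=self.n_lanes, **self.state_dict())

    @classmethod
    def load(cls, path, dtype=np.float32):
        with np.load(path, allow_pickle=False) as data:
            spec_kw = json.loads(str(data["__spec_json__"]))
            for key in ("input_shape", "filters", "head_units",
                        "output_scale_init"):
                if spec_kw.get(key) is not None:
                    spec_kw[key] = tuple(spec_kw[key])
            spec = DLBlockSpec(**spec_kw)
            if str(data["__spec_sha256__"]) != spec.sha256:
                raise DomainError("checkpoint spec hash mismatch")
            net = cls(spec, seed=0, dtype=dtype, n_lanes=int(data["__n_lanes__"]))
            net.load_state_dict({k: data[k] for k in data.files
                                 if not k.startswith("__")})
        return net


@dataclass
class HybridPrediction:
    """Predicted parameters and curves for one sample."""

    params: MaterialParams
    curves: list
    fit: Optional[GoodnessOfFit] = None


def build_dl_block(spec: DLBlockSpec = DLBlockSpec(), init_seed: int = 0,
                   dtype=np.float32, n_lanes: int = 1) -> HybridNet:
    """Deterministically initialized hybrid network for a given seed."""
    return HybridNet(spec, seed=init_seed, dtype=dtype, n_lanes=n_lanes)


def forward(plot, histology, network: HybridNet, lane: int = 0) -> MaterialParams:
    """Single-sample forward pass returning a MaterialParams triple."""
    grid = getattr(plot, "grid", plot)
    hist = getattr(histology, "as_array", lambda: histology)()
    out = network.forward(np.asarray(grid)[None], np.asarray(hist)[None],
                          training=False)[lane, 0]
    return MaterialParams(float(out[0]), float(out[1]), float(out[2]))


def hybrid_predict(sample, network: HybridNet, lambda_grid=None,
                   fibre_switch: bool = True) -> HybridPrediction:
    """Compose the network with the constitutive law for one sample.

    Uses the sample's own structural parameters (alpha, kappa_ip, kappa_op)
    and predicts its observed directions on their stretch grids (or on
    ``lambda_grid`` for every observed direction when given).  When
    observed curves exist and are predicted on their own grids, the pooled
    R^2 against them is attached.
    """
    params = forward(sample.plot, sample.histology, network)
    arch: FibreArchitecture = sample.arch
    curves = []
    for obs in sample.curves:
        grid = np.asarray(lambda_grid, dtype=float) if lambda_grid is not None \
            else obs.stretch
        curves.append(predict_curve(grid, obs.direction, arch, params,
                                    fibre_switch=fibre_switch))
    fit = None
    if sample.curves and lambda_grid is None:
        fit = r_squared(sample.curves, curves)
    return HybridPrediction(params=params, curves=curves, fit=fit)
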