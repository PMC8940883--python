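"""The 14-layer attention-gated pre-activation ResNet.

Architecture: an initial 3x3 convolution, four stages of pre-activation
residual units (filters 8, 16, 32, 64; units 1, 2, 2, 1 — six in total) with
soft attention gates after the 32- and 64-filter stages, a final BN/ReLU,
global average pooling to a 64-d embedding, and a dense softmax head over the
three tissue classes. The "14-layer" name counts the initial convolution, the
twelve convolutions inside the six residual units, and the dense head;
projection shortcuts and attention-branch convolutions are not counted.

Each residual unit is ordered BN -> ReLU -> conv (twice), the pre-activation
arrangement that protects early-layer gradient flow. Each attention gate
computes a soft mask M in [0, 1] from a bottleneck convolution pair and
rescales the trunk as ``trunk * (1 + alpha * M)`` with a learnable per-gate
scalar alpha parameterized as ``alpha = raw**2`` so it is non-negative by
construction: at alpha = 0 the gate is an exact no-op, so the attention path
can only modulate (never suppress) the trunk signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConfigError, GeometryError
from .nn import (
    DTYPE,
    BatchNorm,
    Conv2d,
    Dense,
    GlobalAvgPool,
    Layer,
    Param,
    ReLU,
    Sigmoid,
    softmax,
)


@dataclass(frozen=True)
class ModelConfig:
    """Declarative architecture description."""

    input_shape: tuple[int, int, int] = (128, 256, 1)
    stage_filters: tuple[int, ...] = (8, 16, 32, 64)
    units_per_stage: tuple[int, ...] = (1, 2, 2, 1)
    attention_stages: tuple[int, ...] = (32, 64)  # by filter count
    alpha_init: float = 0.01
    n_classes: int = 3
    l2_coefficient: float = 1e-4

    def __post_init__(self) -> None:
        if len(self.stage_filters) != len(self.units_per_stage):
            raise ConfigError("stage_filters and units_per_stage: lengths differ")
        if any(b <= a for a, b in zip(self.stage_filters, self.stage_filters[1:])):
            raise ConfigError("stage_filters: must be strictly increasing")
        if not set(self.attention_stages) <= set(self.stage_filters):
            raise ConfigError("attention_stages: must be a subset of stage_filters")
        if sum(self.units_per_stage) != 6:
            raise ConfigError("units_per_stage: must sum to 6 residual units")
        if self.alpha_init < 0:
            raise ConfigError("alpha_init: must be >= 0")
        if self.n_classes != 3:
            raise ConfigError("n_classes: this classifier is three-way")
        if self.l2_coefficient < 0:
            raise ConfigError("l2_coefficient: must be >= 0")

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape),
            "stage_filters": list(self.stage_filters),
            "units_per_stage": list(self.units_per_stage),
            "attention_stages": list(self.attention_stages),
            "alpha_init": self.alpha_init,
            "n_classes": self.n_classes,
            "l2_coefficient": self.l2_coefficient,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            input_shape=tuple(d["input_shape"]),
            stage_filters=tuple(d["stage_filters"]),
            units_per_stage=tuple(d["units_per_stage"]),
            attention_stages=tuple(d["attention_stages"]),
            alpha_init=float(d["alpha_init"]),
            n_classes=int(d["n_classes"]),
            l2_coefficient=float(d["l2_coefficient"]),
        )


@dataclass
class ForwardOutput:
    probabilities: np.ndarray           # (n, n_classes)
    embedding: np.ndarray               # (n, last stage filters)
    stage_feature_maps: dict = field(default_factory=dict)


class PreActResidualUnit(Layer):
    """BN -> ReLU -> conv -> BN -> ReLU -> conv plus (projected) shortcut."""

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 rng: np.random.Generator | None = None, name: str = "unit"):
        if stride not in (1, 2):
            raise ConfigError(f"{name}: stride must be 1 or 2")
        rng = rng or np.random.default_rng(0)
        self.bn1 = BatchNorm(cin, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv1 = Conv2d(cin, cout, 3, stride, rng, name=f"{name}.conv1")
        self.bn2 = BatchNorm(cout, name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, 1, rng, name=f"{name}.conv2")
        # residual branch starts as an exact identity/projection: zero-init of
        # the unit's last conv speeds early optimization at the low prescribed
        # learning rate without changing the converged model class
        self.conv2.W.value[...] = 0.0
        self.project = cin != cout or stride != 1
        self.proj = (Conv2d(cin, cout, 1, stride, rng, name=f"{name}.proj")
                     if self.project else None)

    def params(self) -> list[Param]:
        ps = (self.bn1.params() + self.conv1.params() + self.bn2.params()
              + self.conv2.params())
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        a = self.relu1.forward(self.bn1.forward(x, training), training)
        h = self.conv1.forward(a, training)
        h = self.relu2.forward(self.bn2.forward(h, training), training)
        h = self.conv2.forward(h, training)
        sc = self.proj.forward(a, training) if self.proj is not None else x
        return sc + h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.conv2.backward(dy)
        dh = self.bn2.backward(self.relu2.backward(dh))
        da = self.conv1.backward(dh)
        if self.proj is not None:
            da = da + self.proj.backward(dy)
            dx = self.bn1.backward(self.relu1.backward(da))
        else:
            dx = self.bn1.backward(self.relu1.backward(da)) + dy
        return dx


class AttentionGate(Layer):
    """Soft mask gate: out = trunk * (1 + alpha * M(trunk)), alpha = raw**2 >= 0."""

    def __init__(self, c: int, alpha_init: float = 0.0,
                 rng: np.random.Generator | None = None, name: str = "gate"):
        if alpha_init < 0:
            raise ConfigError(f"{name}: alpha_init must be >= 0")
        rng = rng or np.random.default_rng(0)
        cmid = max(c // 8, 1)
        self.conv_a = Conv2d(c, cmid, 1, 1, rng, bias=True, name=f"{name}.conv_a")
        self.relu = ReLU()
        self.conv_b = Conv2d(cmid, c, 1, 1, rng, bias=True, name=f"{name}.conv_b")
        self.sigmoid = Sigmoid()
        self.raw = Param(np.array(np.sqrt(alpha_init)), name=f"{name}.alpha_raw")
        self._cache = None

    @property
    def alpha(self) -> float:
        return float(self.raw.value ** 2)

    def params(self) -> list[Param]:
        return self.conv_a.params() + self.conv_b.params() + [self.raw]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        m = self.sigmoid.forward(
            self.conv_b.forward(self.relu.forward(self.conv_a.forward(x, training),
                                                  training), training), training)
        alpha = DTYPE(self.raw.value ** 2)
        self._cache = (x, m, alpha)
        return x * (1.0 + alpha * m)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, m, alpha = self._cache
        self.raw.grad += 2.0 * self.raw.value * np.sum(dy * x * m)
        dm = (dy * x * alpha).astype(DTYPE)
        dx_branch = self.conv_a.backward(
            self.relu.backward(self.conv_b.backward(self.sigmoid.backward(dm))))
        return (dy * (1.0 + alpha * m) + dx_branch).astype(DTYPE)


class AttentionResNet:
    """The full classifier; built deterministically from (config, seed)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        f = config.stage_filters
        self.conv0 = Conv2d(config.input_shape[2], f[0], 3, 1, rng, name="conv0")
        self.stages: list[list[PreActResidualUnit]] = []
        self.gates: dict[int, AttentionGate] = {}
        cin = f[0]
        for si, (cout, n_units) in enumerate(zip(f, config.units_per_stage)):
            units = []
            for ui in range(n_units):
                stride = 2 if (si > 0 and ui == 0) else 1
                units.append(PreActResidualUnit(cin, cout, stride, rng,
                                                name=f"stage{si}.unit{ui}"))
                cin = cout
            self.stages.append(units)
            if cout in config.attention_stages:
                self.gates[si] = AttentionGate(cout, config.alpha_init, rng,
                                               name=f"gate{cout}")
        self.bn_final = BatchNorm(f[-1], name="bn_final")
        self.relu_final = ReLU()
        self.gap = GlobalAvgPool()
        self.dense = Dense(f[-1], config.n_classes, rng, name="head")
        self._stage_maps: dict[str, np.ndarray] = {}

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[Param]:
        ps = self.conv0.params()
        for si, units in enumerate(self.stages):
            for u in units:
                ps += u.params()
            if si in self.gates:
                ps += self.gates[si].params()
        ps += self.bn_final.params() + self.dense.params()
        return ps

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    @property
    def n_layers(self) -> int:
        """Counted convolutional layers + dense head (the "14-layer" convention)."""
        return 1 + 2 * sum(self.config.units_per_stage) + 1

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.value[...] = w

    def get_state(self) -> dict:
        """Weights plus batch-norm running statistics."""
        state = {p.name: p.value.copy() for p in self.params()}
        for name, bn in self._batchnorms():
            state[f"{name}.running_mean"] = bn.running_mean.copy()
            state[f"{name}.running_var"] = bn.running_var.copy()
        return state

    def set_state(self, state: dict) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for name, bn in self._batchnorms():
            bn.running_mean[...] = state[f"{name}.running_mean"]
            bn.running_var[...] = state[f"{name}.running_var"]

    def _batchnorms(self):
        for si, units in enumerate(self.stages):
            for ui, u in enumerate(units):
                yield f"stage{si}.unit{ui}.bn1", u.bn1
                yield f"stage{si}.unit{ui}.bn2", u.bn2
        yield "bn_final", self.bn_final

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        h, w, c = self.config.input_shape
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 3:
            x = x[..., None] if x.shape[1:] == (h, w) else x[None, ...]
        if x.ndim != 4 or x.shape[1:] != (h, w, c):
            raise GeometryError(
                f"expected input of shape (n, {h}, {w}, {c}), got {x.shape}"
            )
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Run the trunk; returns logits and records stage feature maps."""
        x = self._check_input(x)
        h = self.conv0.forward(x, training)
        self._stage_maps = {}
        for si, units in enumerate(self.stages):
            for u in units:
                h = u.forward(h, training)
            name = f"stage{si}_f{self.config.stage_filters[si]}"
            self._stage_maps[name] = h
            if si in self.gates:
                h = self.gates[si].forward(h, training)
                self._stage_maps[name + "_gated"] = h
        h = self.relu_final.forward(self.bn_final.forward(h, training), training)
        emb = self.gap.forward(h, training)
        self._embedding = emb
        return self.dense.forward(emb, training)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.gap.backward(self.dense.backward(dlogits))
        dh = self.bn_final.backward(self.relu_final.backward(dh))
        for si in range(len(self.stages) - 1, -1, -1):
            if si in self.gates:
                dh = self.gates[si].backward(dh)
            for u in reversed(self.stages[si]):
                dh = u.backward(dh)
        return self.conv0.backward(dh)

    def forward_output(self, x: np.ndarray, training: bool = False) -> ForwardOutput:
        logits = self.forward(x, training)
        return ForwardOutput(
            probabilities=softmax(logits.astype(np.float64)),
            embedding=self._embedding.copy(),
            stage_feature_maps=dict(self._stage_maps),
        )

    # -- interpretability hook ---------------------------------------------

    def stage_map_and_gradient(self, x: np.ndarray, class_index: int,
                               stage: int | None = None
                               ) -> tuple[np.ndarray, np.ndarray]:
        """Feature map of a stage (post-gate where gated) and
        d(logit_class)/d(map), in eval mode.

        ``stage`` is the 0-based stage index; ``None`` selects the deepest
        stage. The gradient is backpropagated from the class logit through
        everything above the requested map.
        """
        if stage is None:
            stage = len(self.stages) - 1
        if not 0 <= stage < len(self.stages):
            raise ConfigError(f"stage index {stage} outside 0..{len(self.stages) - 1}")
        logits = self.forward(x, training=False)
        dlogits = np.zeros_like(logits)
        dlogits[:, class_index] = 1.0
        dh = self.gap.backward(self.dense.backward(dlogits))
        dh = self.bn_final.backward(self.relu_final.backward(dh))
        for si in range(len(self.stages) - 1, stage - 1, -1):
            key = f"stage{si}_f{self.config.stage_filters[si]}"
            gated_key = key + "_gated" if si in self.gates else key
            if si == stage:
                return self._stage_maps[gated_key], dh
            if si in self.gates:
                dh = self.gates[si].backward(dh)
            for u in reversed(self.stages[si]):
                dh = u.backward(dh)
        raise AssertionError("unreachable")

    # -- reporting ----------------------------------------------------------

    def layer_table(self) -> list[tuple[str, str, int]]:
        rows = [("conv0", "conv 3x3", self.conv0.W.value.size)]
        for si, units in enumerate(self.stages):
            for ui, u in enumerate(units):
                n = sum(p.value.size for p in u.params())
                stride = 2 if (si > 0 and ui == 0) else 1
                rows.append((f"stage{si}.unit{ui}",
                             f"pre-act residual unit, stride {stride}", n))
            if si in self.gates:
                g = self.gates[si]
                rows.append((f"gate{self.config.stage_filters[si]}",
                             "attention gate", sum(p.value.size for p in g.params())))
        rows.append(("bn_final", "BN + ReLU + global avg pool",
                     sum(p.value.size for p in self.bn_final.params())))
        rows.append(("head", "dense softmax", sum(p.value.size for p in self.dense.params())))
        return rows

    def describe(self) -> str:
        lines = [f"AttentionResNet: {self.n_layers} counted layers, "
                 f"{self.n_parameters} trainable parameters"]
        for name, kind, n in self.layer_table():
            lines.append(f"  {name:<18} {kind:<36} {n:>8d} params")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def build_model(config: ModelConfig, seed: int = 0) -> AttentionResNet:
    return AttentionResNet(config, seed)


def predict_proba(model: AttentionResNet, frames: np.ndarray,
                  batch_size: int = 32) -> np.ndarray:
    """Class probabilities, one row per frame; rows sum to 1."""
    x = model._check_input(np.asarray(frames))
    out = []
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i:i + batch_size], training=False)
        out.append(softmax(logits.astype(np.float64)))
    return np.vstack(out)


def extract_features(model: AttentionResNet, frames: np.ndarray,
                     batch_size: int = 32) -> np.ndarray:
    """Last-average-pool embeddings (n x last-stage-filters), used by t-SNE."""
    x = model._check_input(np.asarray(frames))
    out = []
    for i in range(0, len(x), batch_size):
        model.forward(x[i:i + batch_size], training=False)
        out.append(model._embedding.copy())
    return np.vstack(out)


def save_checkpoint(model: AttentionResNet, path) -> None:
    """Weights as .npz plus the exact ModelConfig in a JSON sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.get_state())
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(model.config.to_dict(), fh, indent=1)


def load_checkpoint(path) -> AttentionResNet:
    import json
    from pathlib import Path

    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        config = ModelConfig.from_dict(json.load(fh))
    model = AttentionResNet(config, seed=0)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        model.set_state({k: z[k] for k in z.files})
    return model
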