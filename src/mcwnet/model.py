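"""The ACL classifier: attention gate, LSTM cell, softmax, and the 28-layer graph.

The full network is a sequence-input CNN: two conv/BN/ReLU/maxpool blocks, a
four-conv attention block whose sigmoid branch produces a gating map that is
element-wise multiplied with the trunk features, then flatten -> single-step
LSTM(100) -> FC(100) -> ReLU -> 40% dropout -> FC(n_classes) -> softmax.
Each image travels as a length-1 sequence (the fold/unfold idiom), so the
LSTM executes exactly one step per image.

Ablation variants:

``case1``
    no attention branch, no LSTM ("plain CNN");
``case2``
    no attention branch, LSTM kept ("only LSTM");
``case3``
    attention kept, no LSTM ("only attention");
``full``
    everything.

Two attention wirings are supported.  The default ``sequential`` mode keeps
the attention block as a sequential conv stack: the sigmoid branch
(conv5 -> ReLU -> conv6, padded "same" so shapes line up) produces the
coefficient map that multiplies the trunk's max-pooled features.  The
``additive`` mode implements the explicit additive gate
alpha = sigma(phi^T(wx^T x + wg^T g + b_g) + b_phi) with the gating signal
g taken from the preceding convolution (centre-cropped to align); it
replaces the four branch layers with one gate node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .nn import F32

VARIANTS = ("full", "case1", "case2", "case3")
VARIANT_TITLES = {
    "full": "Attention + LSTM",
    "case1": "No attention, no LSTM",
    "case2": "Only LSTM",
    "case3": "Only attention",
}


# ---------------------------------------------------------------------------
# functional ops with explicit weight containers (oracle-facing surface)
# ---------------------------------------------------------------------------

def softmax(scores: np.ndarray) -> np.ndarray:
    """Shift-stabilised softmax along the last axis."""
    x = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("softmax requires finite scores")
    shifted = x - x.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class AttentionGateWeights:
    """1x1 channel-mixing weights of the additive attention gate."""

    w_x: np.ndarray   # (c_x, c_inter)
    w_g: np.ndarray   # (c_g, c_inter)
    b_g: np.ndarray   # (c_inter,)
    phi: np.ndarray   # (c_inter, 1)
    b_phi: float

    def __post_init__(self) -> None:
        ci = self.w_x.shape[1]
        if self.w_g.shape[1] != ci or self.b_g.shape != (ci,):
            raise ValueError("inconsistent intermediate channel dimensions")
        if self.phi.shape != (ci, 1):
            raise ValueError("phi must map the intermediate channels to one channel")

    @classmethod
    def random(cls, c_x: int, c_g: int, c_inter: int,
               rng: np.random.Generator) -> "AttentionGateWeights":
        return cls(rng.standard_normal((c_x, c_inter)),
                   rng.standard_normal((c_g, c_inter)),
                   rng.standard_normal(c_inter),
                   rng.standard_normal((c_inter, 1)),
                   float(rng.standard_normal()))


def attention_gate(x: np.ndarray, g: np.ndarray, w: AttentionGateWeights,
                   return_alpha: bool = False):
    """``out = alpha * x`` with ``alpha = sigma(phi^T(wx^T x + wg^T g + bg) + bphi)``.

    ``x`` (H,W,c_x) and ``g`` (H,W,c_g) must be spatially aligned (resample
    before calling if they are not).  ``alpha`` is one coefficient per pixel,
    strictly inside (0, 1), broadcast over the channels of ``x``.
    """
    x = np.asarray(x, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if x.shape[:-1] != g.shape[:-1]:
        raise ValueError(f"x and g are not spatially aligned: "
                         f"{x.shape[:-1]} vs {g.shape[:-1]}")
    inter = x @ w.w_x + g @ w.w_g + w.b_g
    s = inter @ w.phi + w.b_phi
    alpha = 1.0 / (1.0 + np.exp(-s))
    out = alpha * x
    return (out, alpha) if return_alpha else out


@dataclass
class LSTMCellWeights:
    """Gate weights over the concatenation ``[x_t, h_prev, C_prev]``."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray
    hidden: int = 100

    def __post_init__(self) -> None:
        h = self.hidden
        for name in ("W_f", "W_i", "W_c", "W_o"):
            w = getattr(self, name)
            if w.ndim != 2 or w.shape[0] != h:
                raise ValueError(f"{name} must be (hidden x (input + 2*hidden))")
            if w.shape[1] <= 2 * h:
                raise ValueError(f"{name} columns must cover [x, h, C]")
        for name in ("b_f", "b_i", "b_c", "b_o"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} must have length hidden")

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1] - 2 * self.hidden

    @classmethod
    def random(cls, input_size: int, hidden: int,
               rng: np.random.Generator) -> "LSTMCellWeights":
        d = input_size + 2 * hidden
        mk = lambda: rng.standard_normal((hidden, d))
        bk = lambda: rng.standard_normal(hidden)
        return cls(mk(), mk(), mk(), mk(), bk(), bk(), bk(), bk(), hidden)


@dataclass
class LSTMState:
    h: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        if self.h.shape != self.C.shape:
            raise ValueError("h and C must have equal lengths")
        if not (np.all(np.isfinite(self.h)) and np.all(np.isfinite(self.C))):
            raise ValueError("state must be finite")

    @classmethod
    def zeros(cls, hidden: int) -> "LSTMState":
        return cls(np.zeros(hidden), np.zeros(hidden))


def lstm_cell_step(x_t: np.ndarray, state: LSTMState,
                   w: LSTMCellWeights) -> LSTMState:
    """One LSTM step with forget/input/output gates over ``[x, h_prev, C_prev]``.

    ``C_t = f*C_prev + i*tanh(W_c [x,h,C] + b_c)``, ``h_t = o*tanh(C_t)``.
    The memory vector participates in every gate's input (a peephole-style
    concatenation); the candidate is the standard weighted tanh.
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    if x_t.shape != (w.input_size,):
        raise ValueError(f"expected input of length {w.input_size}, "
                         f"got {x_t.shape}")
    z = np.concatenate([x_t, state.h, state.C])
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    f = sig(w.W_f @ z + w.b_f)
    i = sig(w.W_i @ z + w.b_i)
    cand = np.tanh(w.W_c @ z + w.b_c)
    o = sig(w.W_o @ z + w.b_o)
    c_new = f * state.C + i * cand
    return LSTMState(o * np.tanh(c_new), c_new)


# ---------------------------------------------------------------------------
# network spec and model
# ---------------------------------------------------------------------------

@dataclass
class LayerSpec:
    name: str
    kind: str
    info: dict = field(default_factory=dict)
    inputs: list[str] = field(default_factory=list)
    out_shape: tuple = ()


@dataclass
class NetworkSpec:
    layers: list[LayerSpec]
    variant: str
    input_dims: tuple[int, int, int] = (100, 100, 3)
    n_classes: int = 3
    attention_mode: str = "sequential"

    @property
    def layer_count(self) -> int:
        return len(self.layers)

    def kinds(self) -> list[str]:
        return [l.kind for l in self.layers]

    def describe(self) -> str:
        rows = [f"{i + 1:>2}  {l.name:<18} {l.kind:<12} "
                f"{l.info.get('text', ''):<55} {l.out_shape}"
                for i, l in enumerate(self.layers)]
        head = (f"ACL network, variant={self.variant} "
                f"({VARIANT_TITLES[self.variant]}), attention={self.attention_mode}")
        return "\n".join([head, "-" * len(head)] + rows)

    def to_dict(self) -> dict:
        return {"variant": self.variant,
                "input_dims": list(self.input_dims),
                "n_classes": self.n_classes,
                "attention_mode": self.attention_mode,
                "layers": [{"name": l.name, "kind": l.kind, "info": l.info,
                            "inputs": l.inputs,
                            "out_shape": list(l.out_shape)}
                           for l in self.layers]}


def make_network_spec(variant: str = "full",
                      input_dims: tuple[int, int, int] = (100, 100, 3),
                      n_classes: int = 3,
                      attention_mode: str = "sequential",
                      n_filters: int = 16,
                      lstm_hidden: int = 100,
                      fc_hidden: int = 100,
                      dropout: float = 0.40) -> NetworkSpec:
    """Declarative layer list for one variant, with propagated shapes."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    if attention_mode not in ("sequential", "additive"):
        raise ValueError(f"unknown attention mode {attention_mode!r}")
    h, w, c = input_dims
    nf = n_filters
    with_attention = variant in ("full", "case3")
    with_lstm = variant in ("full", "case2")

    rows: list[LayerSpec] = []
    shapes: dict[str, tuple] = {}
    prev = "input"

    def add(name: str, kind: str, shape: tuple, info_text: str = "",
            inputs: list[str] | None = None, **info) -> None:
        nonlocal prev
        info["text"] = info_text
        rows.append(LayerSpec(name, kind, info,
                              [prev] if inputs is None else inputs, shape))
        shapes[name] = shape
        prev = name

    add("input", "input", (h, w, c),
        f"sequence input, {h} x {w} x {c}", inputs=[])
    add("fold", "fold", (h, w, c), "sequence folding")

    def conv_block(idx: int, c_in: int, shape: tuple, batchnorm: bool) -> tuple:
        hh, ww = shape[0] - 2, shape[1] - 2
        add(f"conv{idx}", "conv", (hh, ww, nf),
            f"{nf} 3 x 3 x {c_in} convolutions, stride 1, padding 0",
            c_in=c_in, c_out=nf, padding=0)
        if batchnorm:
            add(f"batchnorm{idx}", "bn", (hh, ww, nf),
                f"batch normalisation, {nf} channels", channels=nf)
        add(f"relu{idx}", "relu", (hh, ww, nf), "ReLU")
        return hh, ww

    hh, ww = conv_block(1, c, (h, w), batchnorm=True)
    add("maxpool1", "maxpool", (hh - 2, ww - 2, nf),
        "3 x 3 max pooling, stride 1, padding 0")
    hh, ww = conv_block(2, nf, shapes["maxpool1"], batchnorm=True)
    add("maxpool2", "maxpool", (hh - 2, ww - 2, nf),
        "3 x 3 max pooling, stride 1, padding 0")
    hh, ww = conv_block(3, nf, shapes["maxpool2"], batchnorm=False)
    add("conv4", "conv", (hh - 2, ww - 2, nf),
        f"{nf} 3 x 3 x {nf} convolutions, stride 1, padding 0",
        c_in=nf, c_out=nf, padding=0)
    add("maxpool3", "maxpool",
        (shapes["conv4"][0] - 2, shapes["conv4"][1] - 2, nf),
        "3 x 3 max pooling, stride 1, padding 0")
    trunk = "maxpool3"
    th, tw, _ = shapes[trunk]

    if with_attention:
        if attention_mode == "sequential":
            add("conv5", "conv", (th, tw, nf),
                f"{nf} 3 x 3 x {nf} convolutions, stride 1, padding same",
                c_in=nf, c_out=nf, padding="same", inputs=[trunk])
            add("relu5", "relu", (th, tw, nf), "ReLU")
            add("conv6", "conv", (th, tw, nf),
                f"{nf} 3 x 3 x {nf} convolutions, stride 1, padding same",
                c_in=nf, c_out=nf, padding="same")
            add("sigmoid1", "sigmoid", (th, tw, nf), "sigmoid")
            add("mul1", "mul", (th, tw, nf),
                "element-wise multiplication of 2 inputs",
                inputs=["sigmoid1", trunk])
        else:  # additive: explicit additive gate, g from conv4 (centre-cropped)
            add("crop_g", "crop", (th, tw, nf),
                f"centre crop gating signal to {th} x {tw}",
                target=(th, tw), inputs=["conv4"])
            add("attn_gate", "attention_gate", (th, tw, 1),
                "additive attention gate (1 x 1 mixes, sigmoid)",
                c_x=nf, c_g=nf, c_inter=nf, inputs=[trunk, "crop_g"])
            add("mul1", "mul", (th, tw, nf),
                "element-wise multiplication of 2 inputs",
                inputs=["attn_gate", trunk])
    feat = prev

    add("unfold", "unfold", shapes[feat], "sequence unfolding", inputs=[feat])
    flat_dim = int(np.prod(shapes[feat]))
    add("flatten", "flatten", (flat_dim,), "flatten")
    if with_lstm:
        add("lstm", "lstm", (lstm_hidden,),
            f"LSTM with {lstm_hidden} hidden units",
            d_in=flat_dim, hidden=lstm_hidden)
        fc0_in = lstm_hidden
    else:
        fc0_in = flat_dim
    add("fc0", "fc", (fc_hidden,), f"{fc_hidden} fully connected",
        d_in=fc0_in, d_out=fc_hidden)
    add("relu_fc", "relu", (fc_hidden,), "ReLU")
    add("dropout", "dropout", (fc_hidden,), f"{dropout:.0%} dropout",
        rate=dropout)
    add("fc1", "fc", (n_classes,), f"{n_classes} fully connected",
        d_in=fc_hidden, d_out=n_classes)
    add("softmax", "softmax", (n_classes,), "softmax")
    add("class_output", "output", (n_classes,), "cross-entropy classification")

    # graph sanity: every input must be declared earlier (acyclicity), and
    # both multiplication operands must be shape-compatible
    seen: set[str] = set()
    for row in rows:
        for inp in row.inputs:
            if inp not in seen:
                raise ValueError(f"layer {row.name} consumes undeclared {inp!r}")
        if row.kind == "mul":
            a, b = (shapes[i] for i in row.inputs)
            if a[:-1] != b[:-1] or (a[-1] != b[-1] and a[-1] != 1):
                raise ValueError(f"multiplication inputs disagree: {a} vs {b}")
        seen.add(row.name)
    return NetworkSpec(rows, variant, input_dims, n_classes, attention_mode)


_LAYER_FACTORY = {
    "input": lambda i: nn.Identity(),
    "fold": lambda i: nn.Identity(),
    "unfold": lambda i: nn.Identity(),
    "output": lambda i: nn.Identity(),
    "conv": lambda i: nn.Conv2D(i["c_in"], i["c_out"], 3, i["padding"]),
    "bn": lambda i: nn.BatchNorm2D(i["channels"]),
    "relu": lambda i: nn.ReLU(),
    "maxpool": lambda i: nn.MaxPool2D(3),
    "sigmoid": lambda i: nn.Sigmoid(),
    "mul": lambda i: nn.Multiply(),
    "crop": lambda i: nn.CenterCrop(tuple(i["target"])),
    "attention_gate": lambda i: nn.AttentionGate(i["c_x"], i["c_g"], i["c_inter"]),
    "flatten": lambda i: nn.Flatten(),
    "lstm": lambda i: nn.LSTMStep(i["d_in"], i["hidden"]),
    "fc": lambda i: nn.Dense(i["d_in"], i["d_out"]),
    "dropout": lambda i: nn.Dropout(i["rate"]),
    "softmax": lambda i: nn.Softmax(),
}


class NetworkModel:
    """A :class:`NetworkSpec` plus its parameter store and execution engine."""

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        self.layers: dict[str, nn.Layer] = {
            row.name: _LAYER_FACTORY[row.kind](row.info) for row in spec.layers
        }
        rng = np.random.default_rng(seed)
        for row in spec.layers:  # deterministic init order = layer order
            self.layers[row.name].init(rng)

    # -- execution ----------------------------------------------------------

    def _forward(self, batch: np.ndarray, train: bool,
                 rng: np.random.Generator | None) -> dict[str, np.ndarray]:
        h, w, c = self.spec.input_dims
        batch = np.asarray(batch, dtype=F32)
        if batch.ndim != 4 or batch.shape[1:] != (h, w, c):
            raise ValueError(f"expected input batch of shape "
                             f"(N, {h}, {w}, {c}), got {batch.shape}")
        values: dict[str, np.ndarray] = {}
        for row in self.spec.layers:
            xs = [values[i] for i in row.inputs] if row.inputs else [batch]
            values[row.name] = self.layers[row.name].forward(
                *xs, train=train, rng=rng)
        return values

    def forward(self, batch: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class-probability rows for a batch (rows sum to 1)."""
        self._values = self._forward(batch, train, rng)
        return self._values["softmax"]

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient injected at the final FC output.

        The trainer folds softmax and cross-entropy together, so the starting
        gradient is ``(probabilities - onehot) / batch``.
        """
        grad_map: dict[str, np.ndarray] = {"fc1": dlogits.astype(F32)}
        for row in reversed(self.spec.layers):
            g = grad_map.pop(row.name, None)
            if g is None or not row.inputs:
                continue
            dins = self.layers[row.name].backward(g)
            for inp, di in zip(row.inputs, dins):
                if inp in grad_map:
                    grad_map[inp] = grad_map[inp] + di
                else:
                    grad_map[inp] = di

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{name}/{key}": arr
                for name, layer in self.layers.items()
                for key, arr in layer.params.items()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{name}/{key}": arr
                for name, layer in self.layers.items()
                for key, arr in layer.grads.items()}

    def set_parameters(self, flat: dict[str, np.ndarray]) -> None:
        for key, arr in flat.items():
            name, pkey = key.split("/", 1)
            self.layers[name].params[pkey] = arr.astype(F32)

    def param_count(self) -> int:
        return sum(layer.param_count() for layer in self.layers.values())

    def describe(self) -> str:
        lines = self.spec.describe().splitlines()
        lines.append(f"total learnable parameters: {self.param_count():,}")
        return "\n".join(lines)


def build_acl(variant: str = "full",
              input_dims: tuple[int, int, int] = (100, 100, 3),
              n_classes: int = 3, seed: int = 0,
              attention_mode: str = "sequential") -> NetworkModel:
    """Construct and initialise one ACL variant."""
    spec = make_network_spec(variant, input_dims, n_classes, attention_mode)
    return NetworkModel(spec, seed=seed)


def forward(model: NetworkModel, batch: np.ndarray) -> np.ndarray:
    """Inference-mode class probabilities for a batch of images."""
    return model.forward(batch, train=False)


# ---------------------------------------------------------------------------
# serialization: YAML spec + npz parameter blob (runtime artifacts)
# ---------------------------------------------------------------------------

def save_model(model: NetworkModel, path_prefix: str | Path) -> None:
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    meta = model.spec.to_dict()
    meta["seed"] = model.seed
    prefix.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    blob = dict(model.parameters())
    for name, layer in model.layers.items():
        if isinstance(layer, nn.BatchNorm2D):
            blob[f"{name}/__running_mean"] = layer.running_mean
            blob[f"{name}/__running_var"] = layer.running_var
    np.savez(prefix.with_suffix(".npz"), **blob)


def load_model(path_prefix: str | Path) -> NetworkModel:
    prefix = Path(path_prefix)
    meta = yaml.safe_load(prefix.with_suffix(".yaml").read_text())
    spec = make_network_spec(meta["variant"], tuple(meta["input_dims"]),
                             meta["n_classes"], meta["attention_mode"])
    model = NetworkModel(spec, seed=meta.get("seed", 0))
    with np.load(prefix.with_suffix(".npz")) as blob:
        flat = {}
        for key in blob.files:
            name, pkey = key.split("/", 1)
            if pkey == "__running_mean":
                model.layers[name].running_mean = blob[key]
            elif pkey == "__running_var":
                model.layers[name].running_var = blob[key]
            else:
                flat[key] = blob[key]
    model.set_parameters(flat)
    return model
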