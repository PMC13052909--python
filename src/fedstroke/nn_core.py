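"""From-scratch differentiable hybrid MLP-GRU network.

The network has three parts, all implemented directly on numpy arrays
with hand-derived gradients (no autodiff):

* an MLP branch over the static clinical feature vector, each layer
  computing ``a^(l) = f(W^(l)ᵀ a^(l-1) + b^(l))``;
* a GRU branch consuming the image as a row-by-row sequence, with
  update gate ``z_t = σ(W_z·[h_{t-1}, x_t] + b_z)``, reset gate
  ``r_t = σ(W_r·[h_{t-1}, x_t] + b_r)``, candidate
  ``h̃_t = tanh(W·[r_t ⊙ h_{t-1}, x_t] + b)`` and state update
  ``h_t = (1 - z_t) ⊙ h_{t-1} + z_t ⊙ h̃_t`` — note the update gate
  scales the *candidate* (some textbooks use the opposite
  orientation; this one is used consistently here, forward and
  backward);
* a fusion head: one dense layer mapping the concatenation
  ``[mlp_out ‖ h_T]`` to a single logit, squashed by a sigmoid into a
  stroke probability.

Training minimizes the binary cross-entropy; gradients flow through
backpropagation (through time for the GRU, summing the gate-path
contributions at every step) and are averaged over the batch.
Optimizers: plain SGD and Adam with bias correction. Every function
here is deterministic; randomness enters only through the seeded
initializer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MLPLayer",
    "GRUCellParams",
    "ModelParams",
    "init_model",
    "mlp_forward",
    "gru_step",
    "gru_forward",
    "image_to_sequence",
    "sequence_to_image",
    "fused_forward",
    "loss_bce",
    "backward",
    "AdamState",
    "optimizer_step",
    "save_params",
    "load_params",
]

EPS_LOG = 1e-12  # probability clamp in the log-loss


# --- activations ---------------------------------------------------------

def _sigmoid(x):
    # numerically stable two-branch form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


ACTIVATIONS = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda x, a: (x > 0).astype(float)),
    "sigmoid": (_sigmoid, lambda x, a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda x, a: 1.0 - a * a),
    "identity": (lambda x: x, lambda x, a: np.ones_like(x)),
}


# --- parameter containers -------------------------------------------------

@dataclass
class MLPLayer:
    """One dense layer: weights (in, out), bias (out,), activation name."""

    W: np.ndarray
    b: np.ndarray
    activation: str = "relu"

    def __post_init__(self):
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.W.shape[1] != self.b.shape[0]:
            raise ValueError("bias length must equal layer width")


@dataclass
class GRUCellParams:
    """Gate weights, each of shape (hidden + input, hidden)."""

    Wz: np.ndarray
    Wr: np.ndarray
    Wc: np.ndarray
    bz: np.ndarray
    br: np.ndarray
    bc: np.ndarray

    def __post_init__(self):
        if not (self.Wz.shape == self.Wr.shape == self.Wc.shape):
            raise ValueError("the three gate matrices must share one shape")

    @property
    def hidden(self) -> int:
        return self.Wz.shape[1]

    @property
    def input_size(self) -> int:
        return self.Wz.shape[0] - self.hidden


@dataclass
class ModelParams:
    """Complete parameter collection of one MLP-GRU-fusion network."""

    mlp_layers: list[MLPLayer]
    gru: GRUCellParams
    fusion: MLPLayer  # identity activation; sigmoid applied in fused_forward

    def __post_init__(self):
        if self.mlp_layers:  # with no layers the static input passes through
            expected = self.mlp_layers[-1].W.shape[1] + self.gru.hidden
            if self.fusion.W.shape[0] != expected:
                raise ValueError(
                    f"fusion input dim {self.fusion.W.shape[0]} != "
                    f"mlp_out + gru_hidden = {expected}"
                )

    # fixed traversal order used by flatten, optimizers and FedAvg
    def tree(self) -> list[tuple[str, np.ndarray]]:
        items = []
        for i, layer in enumerate(self.mlp_layers):
            items.append((f"mlp{i}.W", layer.W))
            items.append((f"mlp{i}.b", layer.b))
        g = self.gru
        items += [
            ("gru.Wz", g.Wz), ("gru.Wr", g.Wr), ("gru.Wc", g.Wc),
            ("gru.bz", g.bz), ("gru.br", g.br), ("gru.bc", g.bc),
        ]
        items += [("fusion.W", self.fusion.W), ("fusion.b", self.fusion.b)]
        return items

    def flatten(self) -> np.ndarray:
        return np.concatenate([a.ravel() for _, a in self.tree()])

    def shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        return [(name, a.shape) for name, a in self.tree()]

    def unflatten(self, vec: np.ndarray) -> "ModelParams":
        """New ModelParams with this model's shapes, values from ``vec``."""
        vec = np.asarray(vec, dtype=np.float64)
        out = self.copy()
        pos = 0
        for _, a in out.tree():
            n = a.size
            a[...] = vec[pos : pos + n].reshape(a.shape)
            pos += n
        if pos != vec.size:
            raise ValueError("vector length does not match parameter count")
        return out

    def copy(self) -> "ModelParams":
        return ModelParams(
            mlp_layers=[
                MLPLayer(l.W.copy(), l.b.copy(), l.activation) for l in self.mlp_layers
            ],
            gru=GRUCellParams(
                self.gru.Wz.copy(), self.gru.Wr.copy(), self.gru.Wc.copy(),
                self.gru.bz.copy(), self.gru.br.copy(), self.gru.bc.copy(),
            ),
            fusion=MLPLayer(
                self.fusion.W.copy(), self.fusion.b.copy(), self.fusion.activation
            ),
        )

    def zeros_like(self) -> "ModelParams":
        z = self.copy()
        for _, a in z.tree():
            a[...] = 0.0
        return z


def _glorot(rng, n_in, n_out):
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def init_model(
    static_dim: int,
    seq_input: int,
    mlp_hidden: tuple[int, ...] = (32, 16),
    gru_hidden: int = 32,
    seed: int = 0,
    mlp_activation: str = "relu",
) -> ModelParams:
    """Glorot-style seeded initialization of the full network."""
    rng = np.random.default_rng(seed)
    layers = []
    d = static_dim
    for h in mlp_hidden:
        layers.append(MLPLayer(_glorot(rng, d, h), np.zeros(h), mlp_activation))
        d = h
    cat = gru_hidden + seq_input
    gru = GRUCellParams(
        Wz=_glorot(rng, cat, gru_hidden),
        Wr=_glorot(rng, cat, gru_hidden),
        Wc=_glorot(rng, cat, gru_hidden),
        bz=np.zeros(gru_hidden),
        br=np.zeros(gru_hidden),
        bc=np.zeros(gru_hidden),
    )
    fusion = MLPLayer(_glorot(rng, d + gru_hidden, 1), np.zeros(1), "identity")
    return ModelParams(layers, gru, fusion)


# --- forward passes -------------------------------------------------------

def mlp_forward(layers: list[MLPLayer], x: np.ndarray) -> list[np.ndarray]:
    """Activations per layer, ``a[0]`` being the input itself.

    ``x`` may be a single vector (d,) or a batch (B, d).
    """
    a = np.asarray(x, dtype=np.float64)
    if a.ndim == 1:
        a = a[None, :]
    acts = [a]
    for layer in layers:
        if acts[-1].shape[1] != layer.W.shape[0]:
            raise ValueError(
                f"input width {acts[-1].shape[1]} != layer fan-in {layer.W.shape[0]}"
            )
        z = acts[-1] @ layer.W + layer.b
        f, _ = ACTIVATIONS[layer.activation]
        acts.append(f(z))
    return acts


def gru_step(params: GRUCellParams, h_prev: np.ndarray, x_t: np.ndarray):
    """One GRU update. Returns (h_t, cache of intermediates).

    Inputs may be single vectors or batches (B, ·).
    """
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=np.float64))
    x_t = np.atleast_2d(np.asarray(x_t, dtype=np.float64))
    if h_prev.shape[1] != params.hidden or x_t.shape[1] != params.input_size:
        raise ValueError("gru_step dimension mismatch")
    cat = np.concatenate([h_prev, x_t], axis=1)
    z = _sigmoid(cat @ params.Wz + params.bz)
    r = _sigmoid(cat @ params.Wr + params.br)
    cat_c = np.concatenate([r * h_prev, x_t], axis=1)
    h_cand = np.tanh(cat_c @ params.Wc + params.bc)
    h_t = (1.0 - z) * h_prev + z * h_cand
    cache = {"h_prev": h_prev, "x_t": x_t, "z": z, "r": r,
             "h_cand": h_cand, "cat": cat, "cat_c": cat_c}
    return h_t, cache


def gru_forward(params: GRUCellParams, xs: np.ndarray):
    """Iterate gru_step over a sequence from h₀ = 0.

    ``xs`` has shape (T, input) or batched (B, T, input). Returns the
    final hidden state and the per-step caches for BPTT.
    """
    xs = np.asarray(xs, dtype=np.float64)
    single = xs.ndim == 2
    if single:
        xs = xs[None, ...]
    if xs.shape[1] == 0:
        raise ValueError("empty sequence")
    B, T, _ = xs.shape
    h = np.zeros((B, params.hidden))
    caches = []
    for t in range(T):
        h, cache = gru_step(params, h, xs[:, t, :])
        caches.append(cache)
    return (h[0] if single else h), caches


def image_to_sequence(image: np.ndarray, transpose: bool = False) -> np.ndarray:
    """Row-major scan of an H×W image into a sequence of H rows.

    With ``transpose=True`` the columns become the timesteps instead.
    Lossless: :func:`sequence_to_image` reverses it.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image must be a non-empty 2-D array")
    return image.T.copy() if transpose else image.copy()


def sequence_to_image(seq: np.ndarray, transpose: bool = False) -> np.ndarray:
    seq = np.asarray(seq, dtype=np.float64)
    return seq.T.copy() if transpose else seq.copy()


def fused_forward(model: ModelParams, x_static: np.ndarray, x_seq: np.ndarray):
    """Full forward pass; returns (probabilities, cache).

    ``x_static``: (B, d) or (d,). ``x_seq``: (B, T, W) or (T, W).
    Output probabilities lie strictly in (0, 1) for finite parameters.
    """
    x_static = np.asarray(x_static, dtype=np.float64)
    x_seq = np.asarray(x_seq, dtype=np.float64)
    single = x_static.ndim == 1
    if single:
        x_static = x_static[None, :]
        x_seq = x_seq[None, ...]
    mlp_acts = mlp_forward(model.mlp_layers, x_static)
    h_T, gru_caches = gru_forward(model.gru, x_seq)
    u = np.concatenate([mlp_acts[-1], h_T], axis=1)
    logit = (u @ model.fusion.W + model.fusion.b)[:, 0]
    p = _sigmoid(logit)
    cache = {"mlp_acts": mlp_acts, "gru_caches": gru_caches, "h_T": h_T,
             "u": u, "logit": logit, "p": p}
    return (p[0] if single else p), cache


def loss_bce(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy with ε-clamped probabilities."""
    p = np.clip(np.asarray(p, dtype=np.float64), EPS_LOG, 1.0 - EPS_LOG)
    y = np.asarray(y, dtype=np.float64)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


# --- backward pass --------------------------------------------------------

def backward(model: ModelParams, cache: dict, y: np.ndarray) -> ModelParams:
    """Gradients of the mean BCE loss w.r.t. every parameter.

    Returns a ModelParams whose arrays hold the gradients. Uses the
    identity dL/dlogit = p − y for the sigmoid+BCE composition, then
    backpropagates through the fusion head, the MLP, and through time
    across every GRU step, accumulating the update-, reset- and
    candidate-gate path contributions.
    """
    y = np.atleast_1d(np.asarray(y, dtype=np.float64))
    p = np.atleast_1d(cache["p"])
    B = p.shape[0]
    grads = model.zeros_like()

    dlogit = (p - y) / B  # (B,)

    # fusion head
    u = cache["u"]
    grads.fusion.W[...] = u.T @ dlogit[:, None]
    grads.fusion.b[...] = dlogit.sum()
    du = dlogit[:, None] @ model.fusion.W.T  # (B, mlp_out + H)
    mlp_out_dim = cache["mlp_acts"][-1].shape[1]
    d_mlp_out = du[:, :mlp_out_dim]
    dh = du[:, mlp_out_dim:]

    # MLP branch
    acts = cache["mlp_acts"]
    delta = d_mlp_out
    for li in range(len(model.mlp_layers) - 1, -1, -1):
        layer = model.mlp_layers[li]
        a_out, a_in = acts[li + 1], acts[li]
        # activation derivative expressed through the activation value
        if layer.activation == "relu":
            dz = delta * (a_out > 0)
        elif layer.activation == "sigmoid":
            dz = delta * a_out * (1.0 - a_out)
        elif layer.activation == "tanh":
            dz = delta * (1.0 - a_out * a_out)
        else:  # identity
            dz = delta
        grads.mlp_layers[li].W[...] = a_in.T @ dz
        grads.mlp_layers[li].b[...] = dz.sum(axis=0)
        delta = dz @ layer.W.T

    # GRU branch: BPTT
    g = model.gru
    H = g.hidden
    for step in reversed(cache["gru_caches"]):
        h_prev, z, r = step["h_prev"], step["z"], step["r"]
        h_cand, cat, cat_c = step["h_cand"], step["cat"], step["cat_c"]

        dz = dh * (h_cand - h_prev)
        dh_cand = dh * z
        dh_prev = dh * (1.0 - z)

        da_c = dh_cand * (1.0 - h_cand * h_cand)
        grads.gru.Wc += cat_c.T @ da_c
        grads.gru.bc += da_c.sum(axis=0)
        dcat_c = da_c @ g.Wc.T
        drh = dcat_c[:, :H]
        dr = drh * h_prev
        dh_prev += drh * r

        da_z = dz * z * (1.0 - z)
        da_r = dr * r * (1.0 - r)
        grads.gru.Wz += cat.T @ da_z
        grads.gru.Wr += cat.T @ da_r
        grads.gru.bz += da_z.sum(axis=0)
        grads.gru.br += da_r.sum(axis=0)
        dcat = da_z @ g.Wz.T + da_r @ g.Wr.T
        dh_prev += dcat[:, :H]

        dh = dh_prev
    return grads


# --- optimizers ------------------------------------------------------------

@dataclass
class AdamState:
    m: np.ndarray
    v: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, n_params: int) -> "AdamState":
        return cls(m=np.zeros(n_params), v=np.zeros(n_params), t=0)


@dataclass(frozen=True)
class OptimizerConfig:
    kind: str = "adam"  # or "sgd"
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


def optimizer_step(
    params: ModelParams,
    grads: ModelParams,
    state: AdamState | None,
    config: OptimizerConfig,
) -> tuple[ModelParams, AdamState | None]:
    """One optimizer update on the flattened parameter vector.

    SGD: θ ← θ − lr·g. Adam: bias-corrected moment recursion. The
    returned params are a new object; inputs are untouched.
    """
    theta = params.flatten()
    gvec = grads.flatten()
    if config.kind == "sgd":
        return params.unflatten(theta - config.lr * gvec), state
    if config.kind != "adam":
        raise ValueError(f"unknown optimizer {config.kind!r}")
    if state is None:
        state = AdamState.zeros(theta.size)
    t = state.t + 1
    m = config.beta1 * state.m + (1.0 - config.beta1) * gvec
    v = config.beta2 * state.v + (1.0 - config.beta2) * gvec * gvec
    m_hat = m / (1.0 - config.beta1 ** t)
    v_hat = v / (1.0 - config.beta2 ** t)
    theta = theta - config.lr * m_hat / (np.sqrt(v_hat) + config.eps)
    return params.unflatten(theta), AdamState(m=m, v=v, t=t)


# --- checkpoint round trip --------------------------------------------------

def save_params(directory, model: ModelParams) -> None:
    """Write a checkpoint: flat float64 array + JSON shape manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "params.npy", model.flatten())
    manifest = {
        "shapes": [[name, list(shape)] for name, shape in model.shapes()],
        "mlp_activations": [l.activation for l in model.mlp_layers],
        "mlp_dims": [list(l.W.shape) for l in model.mlp_layers],
        "gru_hidden": model.gru.hidden,
        "gru_input": model.gru.input_size,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_params(directory) -> ModelParams:
    directory = Path(directory)
    if not (directory / "params.npy").exists():
        raise FileNotFoundError(f"no checkpoint found under {directory}")
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    mlp_hidden = tuple(d[1] for d in manifest["mlp_dims"])
    static_dim = manifest["mlp_dims"][0][0] if manifest["mlp_dims"] else 0
    skeleton = init_model(
        static_dim=static_dim,
        seq_input=manifest["gru_input"],
        mlp_hidden=mlp_hidden,
        gru_hidden=manifest["gru_hidden"],
        seed=0,
    )
    for layer, act in zip(skeleton.mlp_layers, manifest["mlp_activations"]):
        layer.activation = act
    return skeleton.unflatten(np.load(directory / "params.npy"))
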