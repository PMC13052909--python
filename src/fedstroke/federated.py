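"""Federated simulation: partitioning, local training, Federated
Averaging, and the round loop.

The simulation mirrors a three-client deployment on one machine: the
multimodal dataset is split into (near-)equal disjoint parts, each
client trains the shared MLP-GRU architecture on its own part for a
fixed number of local epochs, and the server aggregates the returned
parameter vectors with Federated Averaging,

    θ_global = (1/K) Σ_k θ_k,

the unweighted elementwise mean over the K clients (a sample-weighted
variant is available, and coincides with the uniform one when the
splits are equal). The aggregated model is broadcast back and the
cycle repeats until the global validation loss stops improving or the
round budget is exhausted. Raw data never crosses the client boundary:
the server-side aggregator consumes only :class:`ClientUpdate` values.

Optimizer state (Adam moments) is reset at every broadcast — the
server aggregates parameters only, so moments cannot meaningfully be
averaged.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import evaluate as ev
from .config import ExperimentConfig
from .nn_core import (
    AdamState,
    ModelParams,
    OptimizerConfig,
    backward,
    fused_forward,
    init_model,
    loss_bce,
    optimizer_step,
)
from .preprocess import FeaturePipeline, SmoteConfig, smote_oversample
from .synthdata import MultimodalDataset

__all__ = [
    "ArrayDataset",
    "ClientUpdate",
    "RoundLog",
    "FederationResult",
    "derive_seed",
    "dataset_to_arrays",
    "stratified_split",
    "partition_clients",
    "local_train",
    "fedavg",
    "run_federation",
    "train_centralized",
]


def derive_seed(base: int, *keys) -> int:
    """Stable child seed below 2**31 from a base seed and labels."""
    ints = [int(base)]
    for k in keys:
        ints.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k))
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2**31))


@dataclass
class ArrayDataset:
    """Model-ready arrays: static features, image sequences, labels."""

    x_static: np.ndarray  # (N, d)
    x_seq: np.ndarray  # (N, T, W)
    y: np.ndarray  # (N,)

    def __len__(self) -> int:
        return self.y.shape[0]

    def subset(self, idx) -> "ArrayDataset":
        idx = np.asarray(idx)
        return ArrayDataset(self.x_static[idx], self.x_seq[idx], self.y[idx])


@dataclass
class ClientUpdate:
    """What a client sends to the server: parameters + bookkeeping."""

    client_id: int
    params: ModelParams
    n_samples: int
    metrics: dict = field(default_factory=dict)


@dataclass
class RoundLog:
    round_index: int
    client_metrics: list  # one dict per client
    global_metrics: dict

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FederationResult:
    round_logs: list
    params: ModelParams
    pipeline: FeaturePipeline | None = None
    val_data: ArrayDataset | None = None

    @property
    def final_global_metrics(self) -> dict:
        return self.round_logs[-1].global_metrics if self.round_logs else {}

    def write_logs(self, out_dir) -> None:
        """Round log as JSON-lines plus a summary TSV table."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "rounds.jsonl", "w") as fh:
            for rl in self.round_logs:
                fh.write(json.dumps(rl.to_dict()) + "\n")
        with open(out_dir / "rounds_summary.tsv", "w") as fh:
            fh.write("round\tglobal_val_loss\tglobal_val_accuracy\n")
            for rl in self.round_logs:
                fh.write(
                    f"{rl.round_index}\t{rl.global_metrics['val_loss']:.6f}"
                    f"\t{rl.global_metrics['val_accuracy']:.6f}\n"
                )


# --- data plumbing ---------------------------------------------------------

def dataset_to_arrays(
    dataset: MultimodalDataset,
    pipeline: FeaturePipeline,
    transpose_scan: bool = False,
) -> ArrayDataset:
    records = [rec for rec, _ in dataset.pairs]
    x_static = pipeline.transform(records)
    imgs = np.stack([img.pixels for _, img in dataset.pairs])
    x_seq = np.transpose(imgs, (0, 2, 1)) if transpose_scan else imgs
    return ArrayDataset(x_static, x_seq, dataset.labels)


def stratified_split(y: np.ndarray, val_fraction: float, seed: int):
    """Seeded stratified (train_idx, val_idx) index split."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * idx.size))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return (
        np.sort(np.array(train_idx, dtype=int)),
        np.sort(np.array(val_idx, dtype=int)),
    )


def partition_clients(
    n_or_labels, n_clients: int, mode: str = "equal-random", seed: int = 0
) -> list[np.ndarray]:
    """Disjoint near-equal index partition; sizes differ by <= 1.

    ``n_or_labels`` is either the dataset size (equal-random mode) or
    the label vector (required for stratified mode, which preserves
    the class mix per client within rounding).
    """
    if isinstance(n_or_labels, (int, np.integer)):
        n, y = int(n_or_labels), None
    else:
        y = np.asarray(n_or_labels)
        n = y.size
    if n_clients < 1:
        raise ValueError("n_clients must be >= 1")
    if n < n_clients:
        raise ValueError("more clients than samples")
    rng = np.random.default_rng(seed)

    if mode == "equal-random":
        perm = rng.permutation(n)
        sizes = [n // n_clients + (1 if k < n % n_clients else 0)
                 for k in range(n_clients)]
        parts, pos = [], 0
        for s in sizes:
            parts.append(np.array(perm[pos : pos + s], dtype=int))
            pos += s
        return parts
    if mode == "stratified":
        if y is None:
            raise ValueError("stratified mode needs the label vector")
        parts = [[] for _ in range(n_clients)]
        offset = 0
        for cls in np.unique(y):
            idx = rng.permutation(np.flatnonzero(y == cls))
            for j, i in enumerate(idx):
                parts[(offset + j) % n_clients].append(int(i))
            offset += idx.size
        return [np.array(sorted(p), dtype=int) for p in parts]
    raise ValueError(f"unknown partition mode {mode!r}")


# --- local training --------------------------------------------------------

def _train_split_with_smote(data: ArrayDataset, cfg: ExperimentConfig, seed: int):
    """Client-local stratified train/val split + optional train SMOTE.

    Returns flattened-feature training arrays (x_static, x_seq, y) and
    the validation subset. SMOTE interpolates the concatenated
    [static ‖ flattened image] vector so a synthetic sample stays a
    consistent multimodal pair; it is skipped when the local minority
    is too small to define neighbors.
    """
    tr_idx, va_idx = stratified_split(
        data.y, cfg.federated.client_val_fraction, derive_seed(seed, "split")
    )
    if tr_idx.size == 0:
        raise ValueError("empty local training split")
    train, val = data.subset(tr_idx), data.subset(va_idx)

    xs, xq, yy = train.x_static, train.x_seq, train.y
    pp = cfg.preprocess
    classes, counts = np.unique(yy, return_counts=True)
    if pp.smote_enabled and classes.size == 2 and counts.min() >= 2:
        k = min(pp.smote_k, int(counts.min()) - 1)
        if k >= 1:
            T, W = xq.shape[1], xq.shape[2]
            flat = np.hstack([xs, xq.reshape(len(yy), -1)])
            flat_aug, y_aug = smote_oversample(
                flat, yy,
                SmoteConfig(k_neighbors=k, target_ratio=pp.smote_ratio,
                            seed=derive_seed(seed, "smote")),
            )
            xs = flat_aug[:, : xs.shape[1]]
            xq = flat_aug[:, xs.shape[1] :].reshape(-1, T, W)
            yy = y_aug
    return xs, xq, yy, val


def _epoch_pass(params, opt_state, xs, xq, yy, rng, cfg):
    """One seeded-shuffle epoch of minibatch training; returns updates."""
    opt = OptimizerConfig(kind=cfg.federated.optimizer, lr=cfg.federated.lr)
    perm = rng.permutation(len(yy))
    bs = cfg.federated.batch_size
    for start in range(0, len(yy), bs):
        b = perm[start : start + bs]
        p, cache = fused_forward(params, xs[b], xq[b])
        grads = backward(params, cache, yy[b])
        params, opt_state = optimizer_step(params, grads, opt_state, opt)
    return params, opt_state


def _split_metrics(params, xs, xq, yy, prefix) -> dict:
    p, _ = fused_forward(params, xs, xq)
    p = np.atleast_1d(p)
    rep = ev.scores(ev.confusion(yy, p))
    return {
        f"{prefix}_loss": loss_bce(p, yy),
        f"{prefix}_accuracy": rep["accuracy"],
    }


def local_train(
    data: ArrayDataset,
    global_params: ModelParams,
    cfg: ExperimentConfig,
    client_id: int = 0,
    seed: int = 0,
) -> ClientUpdate:
    """Local training pass of one client starting from the broadcast.

    Runs ``epochs_per_client`` seeded-shuffle epochs of minibatch
    updates on the client's own training split (after optional SMOTE)
    and returns the updated parameters with per-epoch metrics. The
    global parameter object is never mutated.
    """
    if len(data) == 0:
        raise ValueError("empty client dataset")
    xs, xq, yy, val = _train_split_with_smote(data, cfg, seed)
    params = global_params.copy()
    opt_state = AdamState.zeros(params.flatten().size)
    rng = np.random.default_rng(derive_seed(seed, "epochs"))
    epoch_log = []
    for _ in range(cfg.federated.epochs_per_client):
        params, opt_state = _epoch_pass(params, opt_state, xs, xq, yy, rng, cfg)
        m = _split_metrics(params, xs, xq, yy, "train")
        if len(val) > 0:
            m.update(_split_metrics(params, val.x_static, val.x_seq, val.y, "val"))
        epoch_log.append(m)
    metrics = dict(epoch_log[-1]) if epoch_log else _split_metrics(params, xs, xq, yy, "train")
    if epoch_log and "val_loss" not in metrics and len(val) > 0:
        metrics.update(_split_metrics(params, val.x_static, val.x_seq, val.y, "val"))
    metrics["epochs"] = epoch_log
    return ClientUpdate(
        client_id=client_id, params=params, n_samples=len(data), metrics=metrics
    )


# --- server side -----------------------------------------------------------

def fedavg(updates: list[ClientUpdate], weighting: str = "uniform") -> ModelParams:
    """Aggregate client parameters.

    ``uniform``: θ_global = (1/K) Σ_k θ_k, the plain elementwise mean.
    ``by-samples``: weights n_k / Σ n_k, the weighting used by the
    wider FedAvg literature; identical to uniform for equal splits.
    """
    if not updates:
        raise ValueError("no client updates to aggregate")
    vecs = [u.params.flatten() for u in updates]
    sizes = {v.size for v in vecs}
    if len(sizes) != 1:
        raise ValueError("client parameter shapes differ")
    if weighting == "uniform":
        w = np.full(len(updates), 1.0 / len(updates))
    elif weighting == "by-samples":
        n = np.array([u.n_samples for u in updates], dtype=float)
        if n.sum() <= 0:
            raise ValueError("sample counts must be positive for by-samples")
        w = n / n.sum()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    avg = np.zeros_like(vecs[0])
    for wi, v in zip(w, vecs):
        avg += wi * v
    return updates[0].params.unflatten(avg)


def _prepare(dataset: MultimodalDataset, cfg: ExperimentConfig):
    """Global split → fit transforms on train → arrays + partitions."""
    labels = dataset.labels
    tr_idx, va_idx = stratified_split(
        labels, cfg.federated.val_fraction, derive_seed(cfg.seed, "global_split")
    )
    train_records = [dataset.pairs[i][0] for i in tr_idx]
    pipeline = FeaturePipeline.fit(
        train_records, dataset.schema, impute_strategy=cfg.preprocess.impute_strategy
    )
    arrays = dataset_to_arrays(dataset, pipeline, cfg.model.transpose_scan)
    return arrays, pipeline, tr_idx, va_idx


def _init_from_cfg(arrays: ArrayDataset, cfg: ExperimentConfig) -> ModelParams:
    return init_model(
        static_dim=arrays.x_static.shape[1],
        seq_input=arrays.x_seq.shape[2],
        mlp_hidden=tuple(cfg.model.mlp_hidden),
        gru_hidden=cfg.model.gru_hidden,
        seed=derive_seed(cfg.seed, "init"),
    )


def run_federation(
    dataset: MultimodalDataset, cfg: ExperimentConfig
) -> FederationResult:
    """Full federated loop: broadcast → local train → FedAvg → evaluate.

    Stops at ``cfg.federated.rounds`` or earlier once the global
    validation loss has improved by less than ``tol`` for ``patience``
    consecutive rounds.
    """
    arrays, pipeline, tr_idx, va_idx = _prepare(dataset, cfg)
    val = arrays.subset(va_idx)
    train_arrays = arrays.subset(tr_idx)

    part_arg = train_arrays.y if cfg.federated.partition_mode == "stratified" \
        else len(train_arrays)
    parts = partition_clients(
        part_arg, cfg.federated.n_clients, cfg.federated.partition_mode,
        seed=derive_seed(cfg.seed, "partition"),
    )
    client_data = [train_arrays.subset(p) for p in parts]

    global_params = _init_from_cfg(arrays, cfg)
    logs: list[RoundLog] = []
    best_loss = np.inf
    stall = 0
    for r in range(cfg.federated.rounds):
        updates = [
            local_train(
                client_data[k], global_params, cfg, client_id=k,
                seed=derive_seed(cfg.seed, "local", r, k),
            )
            for k in range(cfg.federated.n_clients)
        ]
        global_params = fedavg(updates, cfg.federated.weighting)
        gm = _split_metrics(global_params, val.x_static, val.x_seq, val.y, "val")
        rep = ev.evaluate_predictions(
            val.y, np.atleast_1d(fused_forward(global_params, val.x_static, val.x_seq)[0])
        )
        gm.update({"val_f1": rep.f1, "val_auc": rep.auc})
        logs.append(
            RoundLog(
                round_index=r,
                client_metrics=[
                    {k2: v for k2, v in u.metrics.items() if k2 != "epochs"}
                    for u in updates
                ],
                global_metrics=gm,
            )
        )
        if best_loss - gm["val_loss"] < cfg.federated.tol:
            stall += 1
        else:
            stall = 0
        best_loss = min(best_loss, gm["val_loss"])
        if stall >= cfg.federated.patience:
            break
    return FederationResult(
        round_logs=logs, params=global_params, pipeline=pipeline, val_data=val
    )


def train_centralized(
    dataset: MultimodalDataset, cfg: ExperimentConfig
) -> FederationResult:
    """Centralized reference trajectory for the single-client check.

    Deliberately re-implements the training loop (its own shuffle,
    batch, SMOTE and Adam code path, not a call into
    :func:`local_train`/:func:`fedavg`) while drawing the same derived
    seeds a one-client federation would, so the two trajectories can
    be compared bit-for-bit.
    """
    arrays, pipeline, tr_idx, va_idx = _prepare(dataset, cfg)
    val = arrays.subset(va_idx)
    train_arrays = arrays.subset(tr_idx)
    part_arg = train_arrays.y if cfg.federated.partition_mode == "stratified" \
        else len(train_arrays)
    order = partition_clients(
        part_arg, 1, cfg.federated.partition_mode,
        seed=derive_seed(cfg.seed, "partition"),
    )[0]
    data = train_arrays.subset(order)

    params = _init_from_cfg(arrays, cfg)
    opt = OptimizerConfig(kind=cfg.federated.optimizer, lr=cfg.federated.lr)
    logs = []
    best_loss = np.inf
    stall = 0
    for r in range(cfg.federated.rounds):
        seed = derive_seed(cfg.seed, "local", r, 0)
        xs, xq, yy, lval = _train_split_with_smote(data, cfg, seed)
        state = AdamState.zeros(params.flatten().size)
        rng = np.random.default_rng(derive_seed(seed, "epochs"))
        for _ in range(cfg.federated.epochs_per_client):
            perm = rng.permutation(len(yy))
            for start in range(0, len(yy), cfg.federated.batch_size):
                b = perm[start : start + cfg.federated.batch_size]
                p, cache = fused_forward(params, xs[b], xq[b])
                grads = backward(params, cache, yy[b])
                params, state = optimizer_step(params, grads, state, opt)
        gm = _split_metrics(params, val.x_static, val.x_seq, val.y, "val")
        logs.append(RoundLog(round_index=r, client_metrics=[], global_metrics=gm))
        if best_loss - gm["val_loss"] < cfg.federated.tol:
            stall += 1
        else:
            stall = 0
        best_loss = min(best_loss, gm["val_loss"])
        if stall >= cfg.federated.patience:
            break
    return FederationResult(
        round_logs=logs, params=params, pipeline=pipeline, val_data=val
    )
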