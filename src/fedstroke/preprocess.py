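"""Preprocessing transforms: imputation, min-max scaling, categorical
encoding, image resize/normalize and SMOTE oversampling.

Every transform follows the fit-on-train / apply-anywhere contract:
``fit`` learns its statistics from the training split only, ``apply``
(``transform``) never mutates the fitted state, and the fitted
parameters serialize to a JSON dict for exact re-application.

Min-max scaling maps a raw feature value C to

    C_norm = (C - C_min) / (C_max - C_min)

with C_min, C_max the fitted training minimum and maximum; a constant
feature maps to 0 and out-of-range apply-time values are deliberately
NOT clipped, which keeps the map affine.

SMOTE synthesizes minority samples on the segment between a minority
point x_i and one of its k nearest minority neighbors x_nn:
x_new = x_i + u (x_nn - x_i) with u ~ Uniform(0, 1), until the
minority/majority ratio reaches the configured target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy.spatial.distance import cdist

from .schema import TabularRecord, TabularSchema
from .synthdata import ImageSample

__all__ = [
    "MinMaxScaler",
    "Imputer",
    "OneHotEncoder",
    "SmoteConfig",
    "smote_oversample",
    "resize_normalize_images",
]


class NotFittedError(RuntimeError):
    pass


@dataclass
class MinMaxScaler:
    """Per-feature affine rescale to the fitted [C_min, C_max] range."""

    c_min: np.ndarray | None = None
    c_max: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.c_min is not None

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] < 1 or not np.all(np.isfinite(np.nanmin(X, axis=0))):
            raise ValueError("fit requires at least one finite value per feature")
        self.c_min = np.nanmin(X, axis=0)
        self.c_max = np.nanmax(X, axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError("transform called before fit")
        X = np.asarray(X, dtype=np.float64)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        rng = self.c_max - self.c_min
        out = np.where(rng > 0, (X - self.c_min) / np.where(rng > 0, rng, 1.0), 0.0)
        return out[:, 0] if squeeze else out

    def to_json(self) -> dict:
        if not self.fitted:
            raise NotFittedError("cannot serialize an unfitted scaler")
        return {"c_min": self.c_min.tolist(), "c_max": self.c_max.tolist()}

    @classmethod
    def from_json(cls, d: dict) -> "MinMaxScaler":
        return cls(c_min=np.array(d["c_min"]), c_max=np.array(d["c_max"]))


@dataclass
class Imputer:
    """Replace missing entries by a fill value learned on the train split.

    ``strategy`` applies to continuous features (mean or median);
    categorical features always use the mode.
    """

    strategy: str = "mean"
    fill_values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in ("mean", "median"):
            raise ValueError("strategy must be 'mean' or 'median'")

    @property
    def fitted(self) -> bool:
        return bool(self.fill_values)

    def fit(
        self, records: list[TabularRecord], schema: TabularSchema
    ) -> "Imputer":
        self.fill_values = {}
        for attr in schema.attributes:
            if attr.kind not in ("continuous", "categorical"):
                continue
            vals = [r[attr.name] for r in records if r[attr.name] is not None]
            if not vals:
                raise ValueError(f"feature {attr.name!r} entirely missing in training split")
            if attr.kind == "continuous":
                arr = np.array(vals, dtype=np.float64)
                self.fill_values[attr.name] = float(
                    np.mean(arr) if self.strategy == "mean" else np.median(arr)
                )
            elif attr.kind == "categorical":
                uniq, counts = np.unique(vals, return_counts=True)
                self.fill_values[attr.name] = str(uniq[np.argmax(counts)])
        return self

    def transform(self, records: list[TabularRecord]) -> list[TabularRecord]:
        if not self.fitted:
            raise NotFittedError("transform called before fit")
        out = []
        for rec in records:
            values = dict(rec.values)
            for name, fill in self.fill_values.items():
                if values.get(name) is None:
                    values[name] = fill
            out.append(TabularRecord(values))
        return out

    def to_json(self) -> dict:
        return {"strategy": self.strategy, "fill_values": self.fill_values}

    @classmethod
    def from_json(cls, d: dict) -> "Imputer":
        return cls(strategy=d["strategy"], fill_values=dict(d["fill_values"]))


@dataclass
class OneHotEncoder:
    """Schema-ordered one-hot expansion of the tabular record.

    Categorical fields expand into one indicator column per allowed
    value (schema order); binary fields pass through as 0/1; continuous
    fields pass through unchanged (scale them separately). The ``id``
    and ``stroke`` columns are excluded from the feature matrix.
    ``unknown_policy`` decides what an out-of-vocabulary category does
    at apply time: ``"error"`` raises, ``"ignore"`` emits all zeros.
    """

    unknown_policy: str = "error"

    def __post_init__(self) -> None:
        if self.unknown_policy not in ("error", "ignore"):
            raise ValueError("unknown_policy must be 'error' or 'ignore'")

    def feature_names(self, schema: TabularSchema) -> list[str]:
        names = []
        for attr in schema.attributes:
            if attr.name in ("id", "stroke"):
                continue
            if attr.kind == "categorical":
                names.extend(f"{attr.name}={v}" for v in attr.values)
            else:
                names.append(attr.name)
        return names

    def transform(
        self, records: list[TabularRecord], schema: TabularSchema
    ) -> tuple[np.ndarray, list[str]]:
        names = self.feature_names(schema)
        X = np.zeros((len(records), len(names)), dtype=np.float64)
        for i, rec in enumerate(records):
            col = 0
            for attr in schema.attributes:
                if attr.name in ("id", "stroke"):
                    continue
                v = rec[attr.name]
                if attr.kind == "categorical":
                    if v in attr.values:
                        X[i, col + attr.values.index(v)] = 1.0
                    elif self.unknown_policy == "error":
                        raise ValueError(
                            f"unseen category {v!r} for attribute {attr.name!r}"
                        )
                    col += len(attr.values)
                else:
                    if v is None:
                        raise ValueError(
                            f"missing value in {attr.name!r}: impute before encoding"
                        )
                    X[i, col] = float(v)
                    col += 1
        return X, names


def resize_normalize_images(
    samples: list[ImageSample], height: int, width: int
) -> list[ImageSample]:
    """Bilinear-resize every image and rescale intensities to [0, 1].

    The intensity map is linear over the dataset-wide source range;
    a constant dataset maps to all zeros (degenerate-range rule).
    """
    if not samples:
        raise ValueError("no images to resize")
    if height < 1 or width < 1:
        raise ValueError("target dimensions must be >= 1")
    lo = min(float(s.pixels.min()) for s in samples)
    hi = max(float(s.pixels.max()) for s in samples)
    span = hi - lo
    out = []
    for s in samples:
        px = s.pixels
        if px.shape != (height, width):
            im = Image.fromarray(px.astype(np.float32), mode="F")
            px = np.asarray(
                im.resize((width, height), resample=Image.BILINEAR), dtype=np.float64
            )
        px = (px - lo) / span if span > 0 else np.zeros_like(px)
        px = np.clip(px, 0.0, 1.0)  # guard interpolation overshoot
        out.append(ImageSample(px, s.label, s.patient_id))
    return out


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    target_ratio: float = 1.0  # minority/majority after oversampling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0.0 < self.target_ratio <= 1.0:
            raise ValueError("target_ratio must be in (0, 1]")


def smote_oversample(
    X: np.ndarray, y: np.ndarray, config: SmoteConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class by neighbor interpolation.

    Synthetic samples are appended after the originals until the
    minority count reaches ``round(target_ratio * majority count)``.
    Already-balanced input is returned unchanged (copied).
    """
    config = config or SmoteConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y lengths differ")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE requires exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class must have at least 2 samples")
    if config.k_neighbors >= n_min:
        raise ValueError("k_neighbors must be smaller than the minority count")

    n_target = int(round(config.target_ratio * n_maj))
    n_new = max(0, n_target - n_min)
    if n_new == 0:
        return X.copy(), y.copy()

    Xm = X[y == minority]
    # k nearest minority neighbors of each minority point (self excluded)
    d = cdist(Xm, Xm)
    np.fill_diagonal(d, np.inf)
    nn_idx = np.argsort(d, axis=1, kind="stable")[:, : config.k_neighbors]

    rng = np.random.default_rng(config.seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, config.k_neighbors, size=n_new)
    u = rng.random(size=n_new)
    xi = Xm[base]
    xnn = Xm[nn_idx[base, pick]]
    X_new = xi + u[:, None] * (xnn - xi)

    return (
        np.vstack([X, X_new]),
        np.concatenate([y, np.full(n_new, minority, dtype=int)]),
    )


@dataclass
class FeaturePipeline:
    """Impute → one-hot encode → min-max scale, fitted on train only.

    Produces the static feature matrix the MLP branch consumes. The
    scaler is fitted on the encoded training matrix, so categorical
    indicators (already 0/1) pass through unchanged while continuous
    columns are rescaled to the training [min, max].
    """

    schema: TabularSchema
    imputer: Imputer
    encoder: OneHotEncoder
    scaler: MinMaxScaler
    feature_names: list[str] = field(default_factory=list)

    @classmethod
    def fit(
        cls,
        train_records: list[TabularRecord],
        schema: TabularSchema,
        impute_strategy: str = "mean",
        unknown_policy: str = "error",
    ) -> "FeaturePipeline":
        imputer = Imputer(strategy=impute_strategy).fit(train_records, schema)
        encoder = OneHotEncoder(unknown_policy=unknown_policy)
        X, names = encoder.transform(imputer.transform(train_records), schema)
        scaler = MinMaxScaler().fit(X)
        return cls(schema, imputer, encoder, scaler, names)

    def transform(self, records: list[TabularRecord]) -> np.ndarray:
        X, _ = self.encoder.transform(self.imputer.transform(records), self.schema)
        return self.scaler.transform(X)


def save_transforms(path, **transforms) -> None:
    """Serialize fitted transforms to one JSON parameter file."""
    payload = {name: t.to_json() for name, t in transforms.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_transforms(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for name, d in payload.items():
        if "c_min" in d:
            out[name] = MinMaxScaler.from_json(d)
        elif "fill_values" in d:
            out[name] = Imputer.from_json(d)
        else:
            raise ValueError(f"unrecognized transform payload under {name!r}")
    return out
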