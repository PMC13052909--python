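"""Seeded synthetic multimodal stroke datasets.

Generates (a) tabular patient records under the 12-attribute stroke
schema, with controllable class imbalance and MCAR missingness in the
two clinical measurements, and (b) paired two-class grayscale image
samples emulating a brain-CT collection (a shared noisy background;
the stroke class carries a localized bright anomaly). Both generators
are pure functions of their arguments including the seed, so every
dataset is exactly reproducible.

Readers/writers cover the standard on-disk layouts: delimited text for
the tabular side, one 8-bit grayscale PNG per image in directory-per-
class folders plus an ``index.csv``, or a single packed ``.npz`` array
file for speed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .schema import TabularRecord, TabularSchema, stroke_schema

__all__ = [
    "ImageSample",
    "MultimodalDataset",
    "generate_tabular",
    "generate_images",
    "generate_multimodal",
    "join_multimodal",
    "write_dataset",
    "read_dataset",
]

# Class-conditional parameters of the tabular generator. Stroke-positive
# patients are older with higher glucose, mirroring the direction of the
# associations in public stroke EHR data; shifts are large enough that
# the classes are learnably separated at desk scale.
TABULAR_PARAMS = {
    "age_mean": {0: 45.0, 1: 65.0},
    "age_sd": 12.0,
    "glucose_mean": {0: 95.0, 1: 135.0},
    "glucose_sd": 25.0,
    "bmi_mean": {0: 27.0, 1: 30.0},
    "bmi_sd": 5.0,
    "hypertension_p": {0: 0.08, 1: 0.30},
    "heart_disease_p": {0: 0.04, 1: 0.20},
    "gender_p": (0.41, 0.58, 0.01),  # Male, Female, Other
    "ever_married_p": (0.34, 0.66),  # No, Yes
    "work_type_p": (0.13, 0.13, 0.004, 0.57, 0.166),
    "residence_p": (0.49, 0.51),  # Rural, Urban
    "smoking_p": (0.17, 0.37, 0.15, 0.31),
}


@dataclass
class ImageSample:
    """One grayscale image with binary label and owning patient id."""

    pixels: np.ndarray  # H x W float array in [0, 1]
    label: int  # 0 normal, 1 stroke
    patient_id: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class MultimodalDataset:
    """Tabular records paired with images on patient_id, sorted by id."""

    pairs: list[tuple[TabularRecord, ImageSample]] = field(default_factory=list)
    schema: TabularSchema = field(default_factory=stroke_schema)
    n_rejected: int = 0  # pairs dropped for stroke-field / image-label mismatch

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([img.label for _, img in self.pairs], dtype=int)

    def subset(self, indices) -> "MultimodalDataset":
        return MultimodalDataset(
            pairs=[self.pairs[i] for i in indices], schema=self.schema
        )


def generate_tabular(
    n: int,
    stroke_fraction: float = 0.2,
    missing_rate: float = 0.05,
    seed: int = 0,
    schema: TabularSchema | None = None,
    id_start: int = 1,
) -> list[TabularRecord]:
    """Draw ``n`` synthetic patient records.

    Exactly ``round(n * stroke_fraction)`` records carry ``stroke=1``;
    their age and glucose distributions are shifted upwards so the
    classes are separable. ``missing_rate`` of the bmi and
    avg_glucose_level entries are independently blanked (MCAR).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= stroke_fraction <= 1.0:
        raise ValueError("stroke_fraction must be in [0, 1]")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    schema = schema or stroke_schema()
    rng = np.random.default_rng(seed)
    P = TABULAR_PARAMS

    n_pos = int(round(n * stroke_fraction))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(labels)

    records: list[TabularRecord] = []
    for i, y in enumerate(labels):
        y = int(y)
        age = float(np.clip(rng.normal(P["age_mean"][y], P["age_sd"]), 1.0, 100.0))
        glucose = float(
            np.clip(rng.normal(P["glucose_mean"][y], P["glucose_sd"]), 45.0, 300.0)
        )
        bmi = float(np.clip(rng.normal(P["bmi_mean"][y], P["bmi_sd"]), 12.0, 60.0))
        rec = TabularRecord(
            {
                "id": id_start + i,
                "gender": schema["gender"].values[
                    rng.choice(3, p=np.array(P["gender_p"]) / sum(P["gender_p"]))
                ],
                "age": age,
                "hypertension": int(rng.random() < P["hypertension_p"][y]),
                "heart_disease": int(rng.random() < P["heart_disease_p"][y]),
                "ever_married": schema["ever_married"].values[
                    rng.choice(2, p=np.array(P["ever_married_p"]) / sum(P["ever_married_p"]))
                ],
                "work_type": schema["work_type"].values[
                    rng.choice(5, p=np.array(P["work_type_p"]) / sum(P["work_type_p"]))
                ],
                "residence_type": schema["residence_type"].values[
                    rng.choice(2, p=np.array(P["residence_p"]) / sum(P["residence_p"]))
                ],
                "avg_glucose_level": glucose,
                "bmi": bmi,
                "smoking_status": schema["smoking_status"].values[
                    rng.choice(4, p=np.array(P["smoking_p"]) / sum(P["smoking_p"]))
                ],
                "stroke": y,
            }
        )
        # MCAR missingness, injected only where public stroke EHR data
        # is actually incomplete
        if rng.random() < missing_rate:
            rec["bmi"] = None
        if rng.random() < missing_rate:
            rec["avg_glucose_level"] = None
        records.append(rec)
    return records


def generate_images(
    n_class0: int = 1551,
    n_class1: int = 950,
    height: int = 32,
    width: int = 32,
    separation: float = 0.5,
    seed: int = 0,
    blob_frac: float = 0.25,
    id_start: int = 1,
) -> list[ImageSample]:
    """Draw two-class grayscale image samples.

    Default class counts follow the composition of the public brain-CT
    collection (1,551 normal + 950 stroke = 2,501 scans). Every image
    shares a noisy mid-gray background; class-1 images additionally
    carry one bright square anomaly of side ``blob_frac * min(H, W)``
    at a random interior position, with added intensity ``separation``.
    With ``separation=0`` the two classes are statistically identical.
    Patient ids are assigned sequentially from ``id_start``.
    """
    if n_class0 < 0 or n_class1 < 0:
        raise ValueError("class counts must be non-negative")
    if n_class0 + n_class1 == 0:
        raise ValueError("at least one sample required")
    if height < 4 or width < 4:
        raise ValueError("height and width must be >= 4")
    rng = np.random.default_rng(seed)

    labels = np.array([0] * n_class0 + [1] * n_class1)
    rng.shuffle(labels)
    blob = max(2, int(round(blob_frac * min(height, width))))

    samples: list[ImageSample] = []
    for i, y in enumerate(labels):
        img = rng.normal(0.30, 0.08, size=(height, width))
        if y == 1:
            r0 = rng.integers(0, height - blob + 1)
            c0 = rng.integers(0, width - blob + 1)
            img[r0 : r0 + blob, c0 : c0 + blob] += separation
        img = np.clip(img, 0.0, 1.0)
        samples.append(ImageSample(img, int(y), id_start + i))
    return samples


def generate_multimodal(
    n: int,
    stroke_fraction: float = 0.38,
    missing_rate: float = 0.05,
    height: int = 32,
    width: int = 32,
    separation: float = 0.5,
    seed: int = 0,
) -> MultimodalDataset:
    """One call producing an id-consistent paired tabular+image dataset.

    The default stroke fraction 0.38 matches the 950/2501 composition
    of the CT collection. Records and images are generated with
    matching patient ids and consistent labels, then inner-joined.
    """
    tab = generate_tabular(n, stroke_fraction, missing_rate, seed=seed)
    # image labels must agree with the tabular stroke field per patient:
    # generate images in id order with the record's own label
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    blob = max(2, int(round(0.25 * min(height, width))))
    images = []
    for rec in tab:
        img = rng.normal(0.30, 0.08, size=(height, width))
        if rec.stroke == 1:
            r0 = rng.integers(0, height - blob + 1)
            c0 = rng.integers(0, width - blob + 1)
            img[r0 : r0 + blob, c0 : c0 + blob] += separation
        img = np.clip(img, 0.0, 1.0)
        images.append(ImageSample(img, rec.stroke, rec.patient_id))
    return join_multimodal(tab, images)


def join_multimodal(
    tabular: list[TabularRecord],
    images: list[ImageSample],
    schema: TabularSchema | None = None,
) -> MultimodalDataset:
    """Inner-join records and images on patient_id.

    Pairs whose tabular stroke field disagrees with the image label are
    excluded and counted in ``n_rejected``. Output is sorted by
    patient_id. Duplicate ids within either input are an error.
    """
    schema = schema or stroke_schema()
    tab_ids = [r.patient_id for r in tabular]
    img_ids = [s.patient_id for s in images]
    if len(set(tab_ids)) != len(tab_ids):
        raise ValueError("duplicate patient ids in tabular input")
    if len(set(img_ids)) != len(img_ids):
        raise ValueError("duplicate patient ids in image input")

    by_id_tab = {r.patient_id: r for r in tabular}
    by_id_img = {s.patient_id: s for s in images}
    shared = sorted(set(by_id_tab) & set(by_id_img))
    if not shared:
        warnings.warn("join produced an empty dataset: no shared patient ids")

    pairs, rejected = [], 0
    for pid in shared:
        rec, img = by_id_tab[pid], by_id_img[pid]
        if rec.stroke != img.label:
            rejected += 1
            continue
        pairs.append((rec, img))
    return MultimodalDataset(pairs=pairs, schema=schema, n_rejected=rejected)


# ---------------------------------------------------------------------------
# on-disk round trip


def _format_value(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_dataset(path, dataset: MultimodalDataset, packed: bool = False) -> None:
    """Write a multimodal dataset under ``path``.

    Tabular side: ``tabular.csv`` (comma-delimited, header row, empty
    field = missing). Images: ``class0/``, ``class1/`` PNG folders plus
    ``index.csv`` mapping filename to patient_id — or, with
    ``packed=True``, a single ``images.npz`` array file.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    names = dataset.schema.names
    with open(path / "tabular.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(names)
        for rec, _ in dataset.pairs:
            w.writerow([_format_value(rec[nm]) for nm in names])

    if packed:
        np.savez(
            path / "images.npz",
            pixels=np.stack([img.pixels for _, img in dataset.pairs])
            if dataset.pairs
            else np.zeros((0, 1, 1)),
            labels=np.array([img.label for _, img in dataset.pairs], dtype=int),
            patient_ids=np.array([img.patient_id for _, img in dataset.pairs], dtype=int),
        )
        return

    for cls in (0, 1):
        (path / f"class{cls}").mkdir(exist_ok=True)
    with open(path / "index.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "patient_id"])
        for _, img in dataset.pairs:
            fname = f"class{img.label}/p{img.patient_id}.png"
            arr = np.round(img.pixels * 255.0).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(path / fname)
            w.writerow([fname, img.patient_id])


def _parse_value(raw: str, kind: str):
    if raw == "":
        return None
    if kind == "continuous":
        return float(raw)
    if kind in ("binary", "integer-id"):
        return int(raw)
    return raw


def read_dataset(path, schema: TabularSchema | None = None) -> MultimodalDataset:
    """Read a dataset written by :func:`write_dataset`.

    An empty or missing directory yields an empty dataset. A tabular
    header that does not match the schema raises ``ValueError``.
    """
    path = Path(path)
    schema = schema or stroke_schema()
    tab_file = path / "tabular.csv"
    records: list[TabularRecord] = []
    if tab_file.exists():
        with open(tab_file, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or header != schema.names:
                raise ValueError(
                    f"tabular header {header} does not match schema {schema.names}"
                )
            for row in reader:
                rec = TabularRecord(
                    {
                        nm: _parse_value(raw, schema[nm].kind)
                        for nm, raw in zip(schema.names, row)
                    }
                )
                rec.validate(schema)
                records.append(rec)

    images: list[ImageSample] = []
    npz_file = path / "images.npz"
    idx_file = path / "index.csv"
    if npz_file.exists():
        data = np.load(npz_file)
        for px, lab, pid in zip(data["pixels"], data["labels"], data["patient_ids"]):
            images.append(ImageSample(px, int(lab), int(pid)))
    elif idx_file.exists():
        with open(idx_file, newline="") as fh:
            reader = csv.reader(fh)
            next(reader)  # header
            for fname, pid in reader:
                label = 1 if fname.startswith("class1") else 0
                arr = np.asarray(Image.open(path / fname), dtype=np.float64) / 255.0
                images.append(ImageSample(arr, label, int(pid)))

    if not records and not images:
        return MultimodalDataset(schema=schema)
    return join_multimodal(records, images, schema)
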