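"""Image/label I/O, preprocessing, splits, and the synthetic generator.

Label manifests follow the NIH ChestX-ray14 dialect: a CSV with an image
filename column and a pipe-delimited findings column over a fixed
vocabulary of 14 findings plus the "No Finding" sentinel (which marks a
normal radiograph and never co-occurs with a finding).  A CheXpert-style
reader (one column per observation, uncertain −1 mapped to 0) is
available behind a flag.

The synthetic generator emulates the structure of multi-label chest
radiographs without any download: each of the L classes owns a fixed
visual template (blob / ring / bar / square / cross) at a distinct
location on the image grid, deposited additively whenever the label is
positive, over a smooth background with Gaussian pixel noise.  Labels are
drawn per class from Bernoulli prevalences, optionally correlated through
a one-factor Gaussian copula.  Everything is determined by the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.stats import norm

from .errors import ConfigurationError, ManifestError

__all__ = [
    "NIH_CLASSES",
    "NO_FINDING",
    "LabelManifest",
    "read_manifest",
    "write_manifest",
    "preprocess",
    "split_dataset",
    "binarize_labels",
    "SyntheticSpec",
    "SyntheticDataset",
    "class_templates",
    "generate_synthetic",
    "matched_filter_scores",
]

NO_FINDING = "No Finding"

NIH_CLASSES: tuple[str, ...] = (
    "Atelectasis", "Cardiomegaly", "Consolidation", "Edema", "Effusion",
    "Emphysema", "Fibrosis", "Hernia", "Infiltration", "Mass", "Nodule",
    "Pleural_Thickening", "Pneumonia", "Pneumothorax",
)


@dataclass(frozen=True)
class LabelManifest:
    """Image ids with their finding-label sets over a fixed vocabulary."""

    image_ids: tuple[str, ...]
    labels: tuple[frozenset[str], ...]          # positive findings per image
    classes: tuple[str, ...] = NIH_CLASSES      # vocabulary without sentinel
    image_dir: str | None = None

    def __post_init__(self):
        if len(self.image_ids) != len(self.labels):
            raise ManifestError("image_ids and labels length mismatch")
        known = set(self.classes)
        for i, labs in enumerate(self.labels):
            unknown = labs - known
            if unknown:
                raise ManifestError(
                    f"row {i}: unknown label(s) {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.image_ids)

    @property
    def vocabulary(self) -> tuple[str, ...]:
        """Ordered class names including the sentinel."""
        return self.classes + (NO_FINDING,)

    def label_matrix(self) -> np.ndarray:
        """(n, L) binary matrix in vocabulary order (sentinel excluded)."""
        mat = np.zeros((len(self), len(self.classes)), dtype=np.int8)
        index = {c: j for j, c in enumerate(self.classes)}
        for i, labs in enumerate(self.labels):
            for c in labs:
                mat[i, index[c]] = 1
        return mat

    def image_paths(self) -> list[Path]:
        base = Path(self.image_dir or ".")
        return [base / name for name in self.image_ids]

    def subset(self, idx: np.ndarray) -> "LabelManifest":
        return dataclasses.replace(
            self,
            image_ids=tuple(self.image_ids[i] for i in idx),
            labels=tuple(self.labels[i] for i in idx),
        )


def read_manifest(csv_path: str | Path, image_dir: str | Path | None = None,
                  classes: tuple[str, ...] = NIH_CLASSES,
                  dialect: str = "nih",
                  check_files: bool = True) -> LabelManifest:
    """Parse a label manifest CSV.

    ``nih``: first column is the image filename, the findings column is
    pipe-delimited class names (or the "No Finding" sentinel alone).
    ``chexpert``: one column per class; 1 positive, 0/blank negative,
    −1 (uncertain) mapped to negative.
    """
    df = pd.read_csv(csv_path)
    if df.empty:
        raise ManifestError(f"{csv_path}: manifest is empty")
    file_col = "Image Index" if "Image Index" in df.columns else df.columns[0]
    ids = tuple(str(v) for v in df[file_col])
    known = set(classes)
    labels: list[frozenset[str]] = []
    if dialect == "nih":
        find_col = ("Finding Labels" if "Finding Labels" in df.columns
                    else df.columns[1])
        for row_no, raw in enumerate(df[find_col]):
            if not isinstance(raw, str) or not raw.strip():
                raise ManifestError(f"row {row_no}: empty findings field")
            names = [t.strip() for t in raw.split("|")]
            if NO_FINDING in names and len(names) > 1:
                raise ManifestError(
                    f"row {row_no}: '{NO_FINDING}' co-occurs with other labels"
                )
            if names == [NO_FINDING]:
                labels.append(frozenset())
                continue
            unknown = [n for n in names if n not in known]
            if unknown:
                raise ManifestError(f"row {row_no}: unknown class name(s) {unknown}")
            labels.append(frozenset(names))
    elif dialect == "chexpert":
        missing = [c for c in classes if c not in df.columns]
        if missing:
            raise ManifestError(f"missing class column(s) {missing}")
        for row_no in range(len(df)):
            pos = {c for c in classes
                   if float(pd.to_numeric(df[c].iloc[row_no], errors="coerce") or 0) == 1.0}
            labels.append(frozenset(pos))
    else:
        raise ManifestError(f"unknown manifest dialect {dialect!r}")
    manifest = LabelManifest(ids, tuple(labels), tuple(classes),
                             None if image_dir is None else str(image_dir))
    if check_files and image_dir is not None:
        for row_no, path in enumerate(manifest.image_paths()):
            if not path.is_file():
                raise ManifestError(f"row {row_no}: image file {path} not found")
    return manifest


def write_manifest(manifest: LabelManifest, csv_path: str | Path) -> None:
    """Write the NIH-dialect CSV (sorted pipe-joined findings)."""
    rows = []
    for name, labs in zip(manifest.image_ids, manifest.labels):
        finding = "|".join(sorted(labs)) if labs else NO_FINDING
        rows.append({"Image Index": name, "Finding Labels": finding})
    pd.DataFrame(rows).to_csv(csv_path, index=False, lineterminator="\n")


def preprocess(image: str | Path | Image.Image,
               side: int = 224) -> np.ndarray:
    """Decode → grayscale (luminance) → bilinear resize → [0,1] float map.

    Returns a (1, side, side) float32 array.
    """
    if isinstance(image, (str, Path)):
        try:
            img = Image.open(image)
            img.load()
        except Exception as exc:
            raise IOError(f"cannot decode image file {image}: {exc}") from exc
    else:
        img = image
    if img.mode in ("I", "I;16", "I;16B"):
        arr = np.asarray(img.convert("I"), dtype=np.float32) / 65535.0
        img = Image.fromarray(arr)              # 32-bit float, resampled below
    elif img.mode != "L":
        img = img.convert("L")
    if img.size != (side, side):
        img = img.resize((side, side), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float32)
    if arr.max() > 1.5:                         # 8-bit path
        arr = arr / 255.0
    return arr[None, :, :]


def load_images(manifest: LabelManifest, side: int = 224) -> np.ndarray:
    """Preprocess every manifest image into an (n, 1, side, side) stack."""
    return np.stack([preprocess(p, side) for p in manifest.image_paths()])


def nih_patient_id(image_id: str) -> str:
    """Patient part of an NIH-style filename, e.g. 00000013_005.png."""
    return Path(image_id).stem.split("_")[0]


def split_dataset(manifest: LabelManifest, train_fraction: float = 0.8,
                  seed: int = 0,
                  unit: str = "image") -> tuple[LabelManifest, LabelManifest]:
    """Disjoint, exhaustive random split with ⌊n·f⌋ train rows.

    ``unit="image"`` shuffles records independently (the default, matching
    a plain random split); ``unit="patient"`` keeps all images of one
    patient (NIH filename prefix) on the same side of the split.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ConfigurationError(
            f"train_fraction must lie in (0, 1), got {train_fraction}"
        )
    n = len(manifest)
    n_train = int(n * train_fraction)
    if n_train < 1 or n - n_train < 1:
        raise ConfigurationError(
            f"cannot split {n} records into non-empty {train_fraction:.0%}/"
            f"{1 - train_fraction:.0%} parts"
        )
    rng = np.random.default_rng(seed)
    if unit == "image":
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    elif unit == "patient":
        patients = [nih_patient_id(i) for i in manifest.image_ids]
        unique = sorted(set(patients))
        order = rng.permutation(len(unique))
        taken: list[int] = []
        train_set: set[str] = set()
        for pos in order:  # fill the train side patient by patient
            if len(taken) >= n_train:
                break
            pid = unique[pos]
            train_set.add(pid)
            taken.extend(i for i, p in enumerate(patients) if p == pid)
        train_idx = np.array(taken[: max(1, len(taken))], dtype=int)
        test_idx = np.array([i for i in range(n) if i not in set(train_idx)],
                            dtype=int)
        if len(test_idx) == 0:
            raise ConfigurationError(
                "patient-level split left the test side empty; too few "
                "patients for the requested fraction"
            )
    else:
        raise ConfigurationError(f"unknown split unit {unit!r}")
    return (manifest.subset(np.sort(train_idx)),
            manifest.subset(np.sort(test_idx)))


def binarize_labels(manifest: LabelManifest) -> LabelManifest:
    """Collapse to the normal/abnormal task: 0 iff the record is normal."""
    labels = tuple(
        frozenset() if not labs else frozenset({"Abnormal"})
        for labs in manifest.labels
    )
    return dataclasses.replace(manifest, labels=labels, classes=("Abnormal",))


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the synthetic multi-label image generator."""

    n_images: int = 200
    image_side: int = 224
    n_classes: int = 14
    prevalence: float | tuple[float, ...] = 0.3
    co_occurrence: float = 0.0      # one-factor Gaussian-copula correlation
    amplitude: float = 0.5          # planted-pattern intensity
    noise_sigma: float = 0.1        # additive Gaussian pixel noise
    background: float = 0.2
    seed: int = 0

    def prevalence_vector(self) -> np.ndarray:
        p = np.asarray(self.prevalence, dtype=float)
        if p.ndim == 0:
            p = np.full(self.n_classes, float(p))
        if p.shape != (self.n_classes,):
            raise ConfigurationError(
                f"prevalence vector has shape {p.shape}, expected "
                f"({self.n_classes},)"
            )
        if ((p < 0) | (p > 1)).any():
            raise ConfigurationError("prevalences must lie in [0, 1]")
        return p

    def __post_init__(self):
        if self.n_images < 1 or self.n_classes < 1:
            raise ConfigurationError("n_images and n_classes must be positive")
        if not (0.0 <= self.co_occurrence < 1.0):
            raise ConfigurationError("co_occurrence must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise sigma must be non-negative")
        self.prevalence_vector()


@dataclass(frozen=True)
class SyntheticDataset:
    images: np.ndarray              # (n, 1, side, side) float32 in [0, 1]
    label_matrix: np.ndarray        # (n, L) int8
    manifest: LabelManifest
    templates: np.ndarray           # (L, side, side) float32
    spec: SyntheticSpec


def class_templates(side: int = 224, n_classes: int = 14) -> np.ndarray:
    """The fixed per-class pattern catalogue on a side×side grid.

    Patterns cycle through blob / ring / horizontal bar / vertical bar /
    square / cross / diagonal stripe, each anchored at a distinct cell of
    a 4×4 placement grid; peak amplitude is 1 for every class.
    """
    if n_classes > 16:
        raise ConfigurationError("at most 16 distinct pattern locations")
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float32)
    centers = [((i + 0.5) * side / 4, (j + 0.5) * side / 4)
               for i in range(4) for j in range(4)][:n_classes]
    if len(set(centers)) != len(centers):
        raise ConfigurationError("duplicate class locations in catalogue")
    sig = side / 20.0
    out = np.zeros((n_classes, side, side), dtype=np.float32)
    for cls, (cy, cx) in enumerate(centers):
        dy, dx = yy - cy, xx - cx
        r = np.sqrt(dy ** 2 + dx ** 2)
        kind = cls % 7
        if kind == 0:      # Gaussian blob
            t = np.exp(-(r ** 2) / (2 * sig ** 2))
        elif kind == 1:    # ring
            t = np.exp(-((r - 1.6 * sig) ** 2) / (2 * (sig / 3) ** 2))
        elif kind == 2:    # horizontal bar
            t = np.exp(-(dy ** 2) / (2 * (sig / 3) ** 2)) * (np.abs(dx) < 2 * sig)
        elif kind == 3:    # vertical bar
            t = np.exp(-(dx ** 2) / (2 * (sig / 3) ** 2)) * (np.abs(dy) < 2 * sig)
        elif kind == 4:    # filled square
            t = ((np.abs(dy) < sig) & (np.abs(dx) < sig)).astype(np.float32)
        elif kind == 5:    # cross
            t = np.maximum(
                np.exp(-(dy ** 2) / (2 * (sig / 4) ** 2)),
                np.exp(-(dx ** 2) / (2 * (sig / 4) ** 2)),
            ) * (r < 2 * sig)
        else:              # diagonal stripe
            t = np.exp(-((dy - dx) ** 2) / (2 * (sig / 3) ** 2)) * (r < 2 * sig)
        out[cls] = t.astype(np.float32)
    return out


def _draw_labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli labels with a one-factor Gaussian-copula co-occurrence."""
    p = spec.prevalence_vector()
    thresh = norm.ppf(p)                        # label = 1 iff z < Φ⁻¹(p)
    c = spec.co_occurrence
    shared = rng.standard_normal((spec.n_images, 1))
    indiv = rng.standard_normal((spec.n_images, spec.n_classes))
    z = np.sqrt(c) * shared + np.sqrt(1.0 - c) * indiv
    return (z < thresh).astype(np.int8)


def generate_synthetic(spec: SyntheticSpec,
                       out_dir: str | Path | None = None) -> SyntheticDataset:
    """Draw a fully seed-determined synthetic dataset.

    When ``out_dir`` is given, 8-bit grayscale PNGs and the NIH-dialect
    ``manifest.csv`` are written there; the in-memory images are the same
    uint8-quantised values rescaled to [0, 1], so disk and memory paths
    agree bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed)
    templates = class_templates(spec.image_side, spec.n_classes)
    labels = _draw_labels(spec, rng)
    side = spec.image_side
    grad = np.linspace(0.0, 0.08, side, dtype=np.float32)[:, None]  # mild shading
    images = np.empty((spec.n_images, 1, side, side), dtype=np.float32)
    for i in range(spec.n_images):
        canvas = spec.background + grad + spec.amplitude * np.tensordot(
            labels[i].astype(np.float32), templates, axes=(0, 0))
        canvas += rng.normal(0.0, spec.noise_sigma, size=(side, side))
        quant = np.clip(np.round(canvas * 255.0), 0, 255).astype(np.uint8)
        images[i, 0] = quant.astype(np.float32) / 255.0
    ids = tuple(f"synthetic_{i:05d}.png" for i in range(spec.n_images))
    classes = NIH_CLASSES[:spec.n_classes] if spec.n_classes <= len(NIH_CLASSES) \
        else tuple(f"Class_{k}" for k in range(spec.n_classes))
    label_sets = tuple(
        frozenset(classes[j] for j in np.flatnonzero(labels[i]))
        for i in range(spec.n_images)
    )
    manifest = LabelManifest(ids, label_sets, classes,
                             None if out_dir is None else str(out_dir))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, name in enumerate(ids):
            arr = (images[i, 0] * 255.0).round().astype(np.uint8)
            Image.fromarray(arr, mode="L").save(out / name)
        write_manifest(manifest, out / "manifest.csv")
    return SyntheticDataset(images, labels, manifest, templates, spec)


def matched_filter_scores(images: np.ndarray,
                          templates: np.ndarray) -> np.ndarray:
    """Correlate each zero-mean class template against each image.

    The resulting (n, L) score matrix is the ideal-observer baseline used
    to validate that a synthetic dataset is separable before any network
    is trained on it.
    """
    flat = images.reshape(len(images), -1)
    t = templates.reshape(len(templates), -1)
    t = t - t.mean(axis=1, keepdims=True)
    return flat @ t.T
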