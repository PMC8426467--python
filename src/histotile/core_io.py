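"""Raster tile I/O, dataset-tree indexing, naming conventions and manifests.

Histology tile datasets are laid out as ``root/<class>/<patient>[/<roi>]/<tile>``:
the first directory level below the root is the class label (e.g. ``mature`` /
``immature``), the second the patient, and optionally a third the annotated
region of interest (ROI) the tile was cut from.  Every mutating operation in
the package records what it did in a :class:`RunManifest` written beside its
output so results can be traced back to their source files.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import EmptyDatasetError, FormatError, NestingError

#: Raster extensions recognised when scanning a dataset tree.
IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}

#: Codes for the seven non-identity square symmetries used in augmented
#: file names (m = horizontal mirror, r = clockwise rotation).
AUGMENT_CODES = ("m", "r90", "r180", "r270", "mr90", "mr180", "mr270")

MANIFEST_FILENAME = "histotile_manifest.json"


@dataclass
class TileImage:
    """An 8-bit raster tile held in memory.

    ``pixels`` is ``(H, W)`` for grayscale or ``(H, W, 3)`` for RGB, dtype
    uint8.  ``source_path`` records provenance ("" for synthetic images).
    """

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")
        if px.ndim == 3 and px.shape[2] != 3:
            raise ValueError(f"3-D pixels must have 3 channels, got {px.shape[2]}")
        if px.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2-D or 3-D, got {px.ndim}-D")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        self.pixels = px

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else 3

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class TileRecord:
    """One catalogued tile: its path and its position in the class/patient[/roi] tree."""

    path: Path
    class_label: str
    patient_id: str
    roi_id: str = ""

    @property
    def stem(self) -> str:
        return self.path.stem


@dataclass
class DatasetIndex:
    """Catalogue of the image tiles found under a dataset root."""

    root: Path
    records: list[TileRecord]

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.class_label] = counts.get(r.class_label, 0) + 1
        return counts

    @property
    def patients(self) -> list[str]:
        return sorted({r.patient_id for r in self.records})

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class RunManifest:
    """Record of one mutating run: the operation, its parameters, the
    effective seed, and one (source, action, destination) entry per file
    touched.  Serialises losslessly to/from JSON."""

    operation_name: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    actions: list[tuple[str, str, str]] = field(default_factory=list)

    _VALID_ACTIONS = {"created", "moved", "deleted", "replaced"}

    def add_action(self, source: str | os.PathLike, action: str,
                   destination: str | os.PathLike = "") -> None:
        if action not in self._VALID_ACTIONS:
            raise ValueError(f"unknown action {action!r}")
        self.actions.append((str(source), action, str(destination)))

    def to_json(self) -> str:
        payload = {
            "operation": self.operation_name,
            "parameters": self.parameters,
            "seed": self.seed,
            "actions": [list(a) for a in self.actions],
        }
        return json.dumps(payload, indent=2, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        d = json.loads(text)
        return cls(
            operation_name=d["operation"],
            parameters=d["parameters"],
            seed=d["seed"],
            actions=[tuple(a) for a in d["actions"]],
        )

    def write(self, directory: str | os.PathLike) -> Path:
        """Write the manifest as ``histotile_manifest.json`` under *directory*."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = directory / MANIFEST_FILENAME
        out.write_text(self.to_json())
        return out


def read_image(path: str | os.PathLike) -> TileImage:
    """Read a raster file into an 8-bit :class:`TileImage`.

    Grayscale files yield one channel and colour files three; alpha channels
    are discarded.  16-bit inputs are rejected rather than silently rescaled.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            mode = im.mode
            if mode in ("I", "I;16", "I;16B", "I;16L", "F"):
                raise FormatError(f"{path}: >8-bit pixel depth not supported")
            if mode == "L":
                arr = np.asarray(im, dtype=np.uint8)
            elif mode in ("LA",):
                arr = np.asarray(im.convert("L"), dtype=np.uint8)
            else:
                arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except FormatError:
        raise
    except Exception as exc:  # Pillow raises many types for bad files
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    return TileImage(arr, source_path=str(path))


def write_image(img: TileImage, path: str | os.PathLike, *,
                allow_lossy: bool = False) -> Path:
    """Write a tile to disk.  PNG (the default) is lossless; JPEG is refused
    unless ``allow_lossy=True`` is passed explicitly."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".png" or ext in (".tif", ".tiff", ".bmp"):
        pass
    elif ext in (".jpg", ".jpeg"):
        if not allow_lossy:
            raise FormatError(
                f"{path}: JPEG output is lossy; pass allow_lossy=True to permit it")
    else:
        raise FormatError(f"{path}: unsupported output format {ext!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img.pixels).save(path)
    return path


def scan_dataset(root: str | os.PathLike,
                 levels: str = "class/patient") -> DatasetIndex:
    """Catalogue the image files under ``root/<class>/<patient>[/<roi>]``.

    ``levels`` is ``"class/patient"`` or ``"class/patient/roi"``.  Non-image
    files are ignored; an empty tree raises :class:`EmptyDatasetError`.
    """
    root = Path(root)
    if levels not in ("class/patient", "class/patient/roi"):
        raise ValueError(f"unknown layout {levels!r}")
    depth = 3 if levels == "class/patient" else 4
    records: list[TileRecord] = []
    if root.is_dir():
        for p in sorted(root.rglob("*")):
            if not p.is_file() or p.suffix.lower() not in IMAGE_EXTENSIONS:
                continue
            rel = p.relative_to(root)
            if len(rel.parts) != depth:
                continue
            if depth == 3:
                cls, patient = rel.parts[0], rel.parts[1]
                roi = ""
            else:
                cls, patient, roi = rel.parts[0], rel.parts[1], rel.parts[2]
            records.append(TileRecord(p, cls, patient, roi))
    if not records:
        raise EmptyDatasetError(f"no image tiles found under {root} "
                                f"with layout {levels!r}")
    return DatasetIndex(root=root, records=records)


def mirror_tree(src_root: str | os.PathLike, dst_root: str | os.PathLike,
                index: DatasetIndex) -> dict[Path, Path]:
    """Replicate the directory structure of *index* under *dst_root* and
    return the source-path → destination-path mapping (no files copied)."""
    src_root = Path(src_root).resolve()
    dst_root = Path(dst_root).resolve()
    if dst_root == src_root or src_root in dst_root.parents:
        raise NestingError(f"destination {dst_root} lies inside source {src_root}")
    mapping: dict[Path, Path] = {}
    for rec in index.records:
        rel = Path(rec.path).resolve().relative_to(src_root)
        dst = dst_root / rel
        dst.parent.mkdir(parents=True, exist_ok=True)
        mapping[rec.path] = dst
    return mapping


def make_patch_name(stem: str, row: int, col: int) -> str:
    """Coordinate-stamped name for a patch cut from a larger image:
    ``<stem>_r<row>_c<col>`` with 0-based grid indices (row from top,
    column from left).  Injective over (stem, row, col)."""
    if row < 0 or col < 0:
        raise ValueError(f"patch indices must be non-negative, got ({row}, {col})")
    return f"{stem}_r{row}_c{col}"


def make_augmented_name(stem: str, code: str) -> str:
    """Name for an augmented copy: ``<stem>_aug-<code>``.

    ``code`` is one of the seven non-identity symmetry codes; the identity
    produces no new file and is rejected.
    """
    if code == "identity":
        raise ValueError("identity transform produces no new file")
    if code not in AUGMENT_CODES:
        raise ValueError(f"unknown transform code {code!r}")
    return f"{stem}_aug-{code}"


def split_by_patient(index: DatasetIndex,
                     fractions: tuple[float, float, float],
                     seed: int) -> tuple[DatasetIndex, DatasetIndex, DatasetIndex]:
    """Partition a dataset into train/test/validation at the patient level.

    Every patient's tiles land in exactly one split.  Test and validation get
    ``floor(fraction * n_patients)`` patients each; the remainder goes to
    train so the training set is never starved.  Deterministic given *seed*.
    """
    f_train, f_test, f_val = fractions
    if min(fractions) <= 0:
        raise ValueError("all fractions must be positive")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    patients = index.patients
    if len(patients) < 3:
        raise ValueError(f"need at least 3 patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    n = len(patients)
    n_test = int(math.floor(f_test * n))
    n_val = int(math.floor(f_val * n))
    test_p = set(order[:n_test])
    val_p = set(order[n_test:n_test + n_val])
    train_p = set(order[n_test + n_val:])
    assert not (train_p & test_p) and not (train_p & val_p) and not (test_p & val_p)

    def subset(pats: set[str]) -> DatasetIndex:
        return DatasetIndex(root=index.root,
                            records=[r for r in index.records
                                     if r.patient_id in pats])

    return subset(train_p), subset(test_p), subset(val_p)
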