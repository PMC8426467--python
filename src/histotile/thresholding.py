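"""Tissue/whitespace masking and coverage-based tile filtering.

H&E-stained tiles have a bright, near-white background (whitespace) and
darker stained tissue, so tissue is taken to be the *dark* class: a pixel is
tissue when its gray value falls below the threshold.  Three thresholding
methods are provided — a fixed global gray level, Otsu's between-class
variance maximisation, and an adaptive local-mean threshold — and the
fraction of tissue pixels ("approximate tissue coverage") is used to remove
or relocate tiles that are mostly background.
"""

from __future__ import annotations

import csv
import os
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core_io import DatasetIndex, RunManifest, TileImage
from .errors import ConfigurationError, DegenerateHistogramError

#: Default fixed gray threshold: typical H&E background exceeds this level.
DEFAULT_FIXED_THRESHOLD = 220
#: Adaptive-threshold defaults: local-mean window size and subtracted offset.
DEFAULT_ADAPTIVE_BLOCK = 51
DEFAULT_ADAPTIVE_OFFSET = 10

#: Rec. 601 luma weights for RGB → grayscale conversion.
_LUMA = (0.299, 0.587, 0.114)


@dataclass
class BinaryMask:
    """Per-pixel tissue map (True = tissue, i.e. stained/dark) together with
    the method and effective threshold that produced it."""

    tissue: np.ndarray  # bool, same H×W as the source image
    method: str         # "fixed" | "otsu" | "adaptive"
    threshold_used: float  # gray level; for "adaptive" the offset


@dataclass
class CoverageResult:
    coverage: float
    n_tissue: int
    n_total: int


@dataclass
class FilterReport:
    """Outcome of a coverage filter run: per-class kept/removed counts plus
    the per-tile rows (path, coverage, action taken)."""

    min_coverage: float
    action: str
    kept_per_class: dict[str, int] = field(default_factory=dict)
    removed_per_class: dict[str, int] = field(default_factory=dict)
    rows: list[tuple[str, float, str]] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return sum(self.kept_per_class.values())

    @property
    def n_removed(self) -> int:
        return sum(self.removed_per_class.values())

    def write_csv(self, path: str | os.PathLike) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["path", "coverage", "action"])
            w.writerows(self.rows)
        return path


def to_grayscale(img: TileImage) -> TileImage:
    """Convert an RGB tile to single-channel gray by Rec. 601 luma weights
    (0.299 R + 0.587 G + 0.114 B, rounded half-up).  Grayscale input is
    returned unchanged."""
    if img.n_channels == 1:
        return img
    px = img.pixels.astype(np.float64)
    gray = _LUMA[0] * px[..., 0] + _LUMA[1] * px[..., 1] + _LUMA[2] * px[..., 2]
    gray = np.floor(gray + 0.5).astype(np.uint8)  # round half-up
    return TileImage(gray, source_path=img.source_path)


def _require_gray(img: TileImage, op: str) -> np.ndarray:
    if img.n_channels != 1:
        raise ValueError(f"{op} requires a 1-channel image; "
                         "convert with to_grayscale first")
    return img.pixels


def binary_mask_fixed(gray: TileImage, threshold: float) -> BinaryMask:
    """Global threshold: tissue where gray value < *threshold*."""
    px = _require_gray(gray, "binary_mask_fixed")
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    return BinaryMask(tissue=px < threshold, method="fixed",
                      threshold_used=float(threshold))


def otsu_threshold(gray_values: np.ndarray) -> int:
    """Integer threshold t maximising the between-class variance
    ω₀ω₁(μ₀−μ₁)² of the split {v < t} vs {v ≥ t}, ties broken low."""
    hist = np.bincount(gray_values.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "Otsu binarisation needs at least two distinct gray values")
    # cumulative counts/sums of the below-threshold class for t = 0..255
    levels = np.arange(256, dtype=np.float64)
    c0 = np.concatenate(([0.0], np.cumsum(hist)[:-1]))       # #{v < t}
    s0 = np.concatenate(([0.0], np.cumsum(hist * levels)[:-1]))
    c1 = n - c0
    s1 = hist @ levels - s0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(c0 > 0, s0 / c0, 0.0)
        mu1 = np.where(c1 > 0, s1 / c1, 0.0)
        var_between = (c0 / n) * (c1 / n) * (mu0 - mu1) ** 2
    var_between[(c0 == 0) | (c1 == 0)] = -np.inf
    return int(np.argmax(var_between))  # argmax takes the first (lowest) tie


def binary_mask_otsu(gray: TileImage) -> BinaryMask:
    """Otsu binarisation: tissue is the below-threshold (dark) class."""
    px = _require_gray(gray, "binary_mask_otsu")
    t = otsu_threshold(px)
    return BinaryMask(tissue=px < t, method="otsu", threshold_used=float(t))


def binary_mask_adaptive(gray: TileImage,
                         block: int = DEFAULT_ADAPTIVE_BLOCK,
                         offset: float = DEFAULT_ADAPTIVE_OFFSET) -> BinaryMask:
    """Adaptive local-mean threshold: tissue where
    ``value < mean(block×block neighbourhood) − offset``, with reflective
    borders.  *block* must be odd and ≥ 3."""
    px = _require_gray(gray, "binary_mask_adaptive")
    if block < 3 or block % 2 == 0:
        raise ValueError(f"block must be odd and >= 3, got {block}")
    if not -255 <= offset <= 255:
        raise ValueError(f"offset must be in [-255, 255], got {offset}")
    local_mean = ndimage.uniform_filter(px.astype(np.float64), size=block,
                                        mode="reflect")
    return BinaryMask(tissue=px < local_mean - offset, method="adaptive",
                      threshold_used=float(offset))


def tissue_coverage(mask: BinaryMask) -> CoverageResult:
    """Exact fraction of tissue pixels in a mask."""
    n_total = int(mask.tissue.size)
    if n_total == 0:
        raise ValueError("empty mask")
    n_tissue = int(np.count_nonzero(mask.tissue))
    return CoverageResult(coverage=n_tissue / n_total,
                          n_tissue=n_tissue, n_total=n_total)


def compute_mask(gray: TileImage, method: str, *, threshold: float | None = None,
                 block: int = DEFAULT_ADAPTIVE_BLOCK,
                 offset: float = DEFAULT_ADAPTIVE_OFFSET) -> BinaryMask:
    if method == "fixed":
        t = DEFAULT_FIXED_THRESHOLD if threshold is None else threshold
        return binary_mask_fixed(gray, t)
    if method == "otsu":
        return binary_mask_otsu(gray)
    if method == "adaptive":
        return binary_mask_adaptive(gray, block=block, offset=offset)
    raise ConfigurationError(f"unknown thresholding method {method!r}")


def filter_tiles(index: DatasetIndex, method: str = "fixed", *,
                 threshold: float | None = None,
                 block: int = DEFAULT_ADAPTIVE_BLOCK,
                 offset: float = DEFAULT_ADAPTIVE_OFFSET,
                 min_coverage: float = 0.8,
                 action: str = "delete",
                 relocate_dir: str | os.PathLike | None = None) -> FilterReport:
    """Remove or relocate tiles whose tissue coverage falls below
    *min_coverage*; tiles exactly at the cutoff survive.

    Relocated tiles keep their tree structure under *relocate_dir*; survivors
    are untouched.  Every action is recorded in a manifest beside the root.
    """
    from .core_io import read_image  # local import avoids cycle at module load

    if not 0 <= min_coverage <= 1:
        raise ValueError(f"min_coverage must be in [0, 1], got {min_coverage}")
    if action not in ("delete", "relocate"):
        raise ConfigurationError(f"unknown action {action!r}")
    if action == "relocate" and relocate_dir is None:
        raise ConfigurationError("action='relocate' requires relocate_dir")
    manifest = RunManifest(
        "threshold",
        parameters={"method": method, "threshold": threshold, "block": block,
                    "offset": offset, "min_coverage": min_coverage,
                    "action": action,
                    "relocate_dir": str(relocate_dir) if relocate_dir else ""},
    )
    report = FilterReport(min_coverage=min_coverage, action=action)
    for rec in index.records:
        gray = to_grayscale(read_image(rec.path))
        mask = compute_mask(gray, method, threshold=threshold,
                            block=block, offset=offset)
        cov = tissue_coverage(mask).coverage
        cls = rec.class_label
        if cov < min_coverage:
            if action == "delete":
                os.remove(rec.path)
                manifest.add_action(rec.path, "deleted")
            else:
                rel = Path(rec.path).relative_to(index.root)
                dst = Path(relocate_dir) / rel
                dst.parent.mkdir(parents=True, exist_ok=True)
                shutil.move(str(rec.path), str(dst))
                manifest.add_action(rec.path, "moved", dst)
            report.removed_per_class[cls] = report.removed_per_class.get(cls, 0) + 1
            report.rows.append((str(rec.path), cov, action + "d"))
        else:
            report.kept_per_class[cls] = report.kept_per_class.get(cls, 0) + 1
            report.rows.append((str(rec.path), cov, "kept"))
    manifest.write(index.root)
    return report
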