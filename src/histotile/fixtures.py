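"""Deterministic synthetic tiles and dataset trees for testing and demos.

Mature tumour stroma shows fine, elongated collagen fibres with roughly
parallel orientation; immature stroma shows disorganised fibres, often with
oedema (bright, fluid-filled patches).  The generators here emulate those
two texture regimes with band-limited oriented noise — enough signal for a
structure-tensor statistic to separate the classes — plus whitespace tiles
with controlled tissue coverage and channel-affine "stain shift" batches
mimicking H&E staining batch effects.  They exist to exercise the
pre-processing code paths deterministically, not to model collagen
biophysics, and make no attempt at realistic H&E appearance.

All generators are pure functions of their seeds: reruns are byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core_io import DatasetIndex, TileImage, scan_dataset, write_image

#: Default tile edge in pixels (the working tile size of the emulated study).
DEFAULT_TILE_SIZE = 250

# H&E-like tint: gray texture mapped into a pink/purple palette so both
# grayscale conversion and per-channel normalisation are exercised.  Gains
# near 1 keep channel histograms wide and smooth (no bin hoards probability
# mass), and bases are placed so a moderate stain shift cannot clip.
_TINT_GAIN = np.array([0.72, 0.82, 0.75])
_TINT_BASE = np.array([148.0, 116.0, 134.0])


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a synthetic dataset tree (class/patient/roi layout)."""

    n_patients: int = 4
    rois_per_patient: int = 2
    tiles_per_roi: int = 5
    tile_size: int = DEFAULT_TILE_SIZE
    class_ratio: float = 0.5  # fraction of patients labelled immature
    stain_shift_range: float = 0.08  # per-patient gain jitter; bias +-8
    seed: int = 0

    def __post_init__(self):
        if min(self.n_patients, self.rois_per_patient, self.tiles_per_roi) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.class_ratio <= 1:
            raise ValueError("class_ratio must be in [0, 1]")


def _tint(gray: np.ndarray) -> np.ndarray:
    """Map a float gray texture (0..255) into an H&E-like RGB palette."""
    rgb = _TINT_BASE[None, None, :] + (gray[..., None] - 128.0) * _TINT_GAIN
    return np.clip(np.floor(rgb + 0.5), 0, 255).astype(np.uint8)


def make_fiber_tile(size: int, orientation: float, coherence: float,
                    seed: int, *, rgb: bool = True) -> TileImage:
    """A fibre-textured tile with controllable orientation coherence.

    *orientation* (degrees, fibre direction measured from the x-axis) and
    *coherence* in [0, 1] set the texture regime: high coherence gives
    near-parallel oriented bands (mature-like), low coherence an isotropic
    fibre mix with bright blobs imitating oedema (immature-like).
    """
    if size < 16:
        raise ValueError(f"tile size must be >= 16, got {size}")
    if not 0 <= coherence <= 1:
        raise ValueError(f"coherence must be in [0, 1], got {coherence}")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)

    # oriented component: sinusoidal bands along the fibre direction.
    # the wave vector is perpendicular to the fibres.
    theta = np.deg2rad(orientation + 90.0)
    proj = xx * np.cos(theta) + yy * np.sin(theta)
    oriented = np.zeros((size, size))
    for wavelength in (6.0, 11.0, 17.0):
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.6, 1.0)
        oriented += amp * np.sin(2 * np.pi * proj / wavelength + phase)
    oriented /= oriented.std() + 1e-12

    # isotropic component: band-pass filtered white noise
    noise = rng.normal(size=(size, size))
    iso = ndimage.gaussian_filter(noise, 2.0) - ndimage.gaussian_filter(noise, 6.0)
    iso /= iso.std() + 1e-12

    tex = coherence * oriented + (1.0 - coherence) * iso
    tex = np.clip(tex / (tex.std() + 1e-12), -2.4, 2.4)

    # fine-grained intensity noise: stained tissue is never histogram-sparse,
    # and it keeps any single gray level from hoarding probability mass
    gray = 128.0 + 40.0 * tex + rng.normal(0, 6.0, size=(size, size))
    if coherence < 0.5:
        # oedema-like bright blobs for the disorganised regime (noisy, so no
        # single gray level dominates the histogram)
        blob = ndimage.gaussian_filter(rng.normal(size=(size, size)), size / 12)
        blob = (blob - blob.mean()) / (blob.std() + 1e-12)
        pale = blob > 1.2
        gray[pale] = np.maximum(gray[pale],
                                rng.normal(222.0, 8.0, size=int(pale.sum())))
    gray = np.clip(gray, 0, 255)
    if not rgb:
        return TileImage(np.floor(gray + 0.5).astype(np.uint8))
    rgb_px = _TINT_BASE[None, None, :] + (gray[..., None] - 128.0) * _TINT_GAIN
    rgb_px += rng.normal(0, 3.0, size=rgb_px.shape)  # chroma noise
    return TileImage(np.clip(np.floor(rgb_px + 0.5), 0, 255).astype(np.uint8))


def orientation_coherence(img: TileImage) -> tuple[float, float]:
    """Dominant texture orientation (degrees, fibre direction) and an
    anisotropy statistic in [0, 1] from the gradient structure tensor.

    The statistic is (l1 - l2) / (l1 + l2) for eigenvalues l1 >= l2 of the
    summed tensor: near 1 for parallel banding, near 0 for isotropic
    texture.  Used both in tests and as a trivial stand-in classifier.
    """
    px = img.pixels
    if px.ndim == 3:
        px = px.mean(axis=2)
    g = px.astype(np.float64)
    gy, gx = np.gradient(g)
    jxx, jyy, jxy = (gx * gx).sum(), (gy * gy).sum(), (gx * gy).sum()
    # eigen-decomposition of [[jxx, jxy], [jxy, jyy]]
    tr, diff = jxx + jyy, jxx - jyy
    root = np.hypot(diff, 2 * jxy)
    l1, l2 = (tr + root) / 2, (tr - root) / 2
    anisotropy = float((l1 - l2) / (l1 + l2)) if tr > 0 else 0.0
    # dominant gradient direction; fibres run perpendicular to it
    grad_angle = 0.5 * np.arctan2(2 * jxy, diff)
    fibre_angle = np.rad2deg(grad_angle) + 90.0
    return float((fibre_angle + 90.0) % 180.0 - 90.0), anisotropy


def make_whitespace_tile(size: int, coverage: float, seed: int) -> TileImage:
    """A bright background tile with a dark tissue-like region occupying the
    requested area fraction (within ±0.02 under the default gray threshold
    of 220): background ≥ 240, tissue ≤ 120."""
    if not 0 <= coverage <= 1:
        raise ValueError(f"coverage must be in [0, 1], got {coverage}")
    rng = np.random.default_rng(seed)
    gray = rng.integers(240, 256, size=(size, size)).astype(np.float64)
    k = int(round(coverage * size * size))
    if k > 0:
        field = ndimage.gaussian_filter(rng.normal(size=(size, size)), size / 10)
        # threshold the smooth field at its k-th order statistic so the dark
        # region is a connected-looking blob of exactly k pixels
        cut = np.sort(field.ravel())[k - 1]
        dark = field <= cut
        gray[dark] = rng.integers(40, 121, size=int(dark.sum()))
    return TileImage(_tint_neutral(gray))


def _tint_neutral(gray: np.ndarray) -> np.ndarray:
    """RGB promotion with a faint pink cast that keeps luma within ±3 of the
    gray source, so threshold semantics survive the colour round-trip."""
    rgb = np.stack([np.clip(gray + 3, 0, 255), gray,
                    np.clip(gray + 1, 0, 255)], axis=2)
    return np.floor(rgb + 0.5).astype(np.uint8)


def apply_stain_shift(img: TileImage, gain, bias) -> TileImage:
    """Channel-wise affine stain shift out = gain * in + bias (clipped),
    simulating an H&E staining batch effect."""
    gain = np.broadcast_to(np.asarray(gain, dtype=np.float64), (3,))
    bias = np.broadcast_to(np.asarray(bias, dtype=np.float64), (3,))
    if np.any(gain <= 0):
        raise ValueError(f"gains must be positive, got {gain}")
    if img.n_channels != 3:
        raise ValueError("stain shift requires a 3-channel image")
    px = img.pixels.astype(np.float64) * gain[None, None, :] + bias[None, None, :]
    return TileImage(np.clip(np.floor(px + 0.5), 0, 255).astype(np.uint8),
                     source_path=img.source_path)


def build_dataset(spec: FixtureSpec, root: str | os.PathLike) -> DatasetIndex:
    """Write a synthetic ``root/<class>/<patient>/<roi>/`` tree to disk.

    Patients are assigned immature with probability *class_ratio* by count
    (``round(ratio * n_patients)`` immature patients); mature patients get
    high-coherence tiles, immature patients low-coherence ones, each patient
    with its own stain shift.  Refuses a non-empty root.  Returns the
    scanned index.
    """
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        raise FileExistsError(f"refusing to write into non-empty {root}")
    rng = np.random.default_rng(spec.seed)
    n_imm = int(round(spec.class_ratio * spec.n_patients))
    order = rng.permutation(spec.n_patients)
    immature_patients = set(order[:n_imm].tolist())
    for p in range(spec.n_patients):
        cls = "immature" if p in immature_patients else "mature"
        coherence = rng.uniform(0.05, 0.2) if cls == "immature" \
            else rng.uniform(0.85, 1.0)
        g = 1.0 + rng.uniform(-spec.stain_shift_range, spec.stain_shift_range,
                              size=3)
        b = rng.uniform(-20, 20, size=3)
        for r in range(spec.rois_per_patient):
            base_orient = rng.uniform(-80, 80)
            for t in range(spec.tiles_per_roi):
                orient = base_orient + rng.uniform(-4, 4)
                tile = make_fiber_tile(
                    spec.tile_size, orient, coherence,
                    seed=int(rng.integers(0, 2**31)))
                tile = apply_stain_shift(tile, g, b)
                dst = (root / cls / f"p{p + 1:02d}" / f"roi{r + 1}" /
                       f"tile{t + 1:03d}.png")
                write_image(tile, dst)
    return scan_dataset(root, "class/patient/roi")
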