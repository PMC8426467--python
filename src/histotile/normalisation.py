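"""Stain normalisation by per-channel cumulative-histogram matching.

Batch effects in H&E staining leave tiles from different slides with
inconsistent colour ranges.  Matching remaps each channel of an input image
monotonically so its cumulative intensity distribution agrees with that of a
single user-chosen target image: source value v maps to the smallest target
gray level u whose cumulative frequency reaches that of v,

    m(v) = min { u : F_target(u) >= F_source(v) }.

Channels are matched independently in RGB space; single-channel inputs are
promoted to RGB by replication first.  Note that histogram matching can
introduce artefacts (e.g. artefactual whitespace) when source and target
content differ strongly; the method corrects colour distributions, not
content.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_io import (DatasetIndex, RunManifest, TileImage, read_image,
                      write_image)
from .errors import FormatError


@dataclass
class HistogramProfile:
    """Per-channel 256-bin histograms and cumulative distributions.

    ``counts[c, v]`` is the number of pixels of channel c at gray value v;
    ``cdf[c, v] = (# pixels <= v) / n`` is non-decreasing and ends at 1.
    """

    counts: np.ndarray  # (n_channels, 256) int64
    cdf: np.ndarray     # (n_channels, 256) float64

    @property
    def n_channels(self) -> int:
        return self.counts.shape[0]


def ensure_rgb(img: TileImage) -> TileImage:
    """Promote a 1-channel image to RGB by replicating the channel;
    3-channel input is returned unchanged."""
    if img.n_channels == 3:
        return img
    rgb = np.repeat(img.pixels[:, :, np.newaxis], 3, axis=2)
    return TileImage(np.ascontiguousarray(rgb), source_path=img.source_path)


def channel_profile(img: TileImage) -> HistogramProfile:
    """Exact per-channel histogram and cumulative distribution of a tile."""
    px = img.pixels
    channels = px[np.newaxis] if px.ndim == 2 else np.moveaxis(px, 2, 0)
    counts = np.stack([np.bincount(ch.ravel(), minlength=256)
                       for ch in channels])
    n = px.shape[0] * px.shape[1]
    cdf = np.cumsum(counts, axis=1) / n
    return HistogramProfile(counts=counts.astype(np.int64), cdf=cdf)


def histogram_match(src: TileImage, target_profile: HistogramProfile) -> TileImage:
    """Remap each channel of *src* so its cumulative histogram matches the
    target profile (min-inverse of the target CDF; monotone non-decreasing
    mapping, ties resolved toward the smallest eligible gray level)."""
    if target_profile.counts.sum() == 0:
        raise ValueError("empty target profile")
    if src.n_channels != target_profile.n_channels:
        raise ValueError(
            f"channel mismatch: source has {src.n_channels}, "
            f"target profile has {target_profile.n_channels}; apply ensure_rgb")
    src_profile = channel_profile(src)
    px = src.pixels
    channels = px[np.newaxis] if px.ndim == 2 else np.moveaxis(px, 2, 0)
    out = np.empty_like(channels)
    for c in range(target_profile.n_channels):
        # lookup table: v -> min{u : F_t(u) >= F_s(v)}
        lut = np.searchsorted(target_profile.cdf[c], src_profile.cdf[c],
                              side="left")
        lut = np.minimum(lut, 255).astype(np.uint8)
        out[c] = lut[channels[c]]
    result = out[0] if px.ndim == 2 else np.ascontiguousarray(np.moveaxis(out, 0, 2))
    return TileImage(result, source_path=src.source_path)


def normalise_directory(index: DatasetIndex, target_image: str | os.PathLike,
                        dst_root: str | os.PathLike | None = None, *,
                        in_place: bool = False) -> dict:
    """Match every tile in *index* to the profile of one fixed target image.

    Writes a mirrored tree under *dst_root* (or replaces files in place when
    *in_place* is set).  Unreadable tiles are recorded as skipped and the run
    continues.  Returns a report dict with counts and skipped paths.
    """
    if in_place == (dst_root is not None):
        raise ValueError("pass exactly one of dst_root or in_place=True")
    target = ensure_rgb(read_image(target_image))
    profile = channel_profile(target)
    manifest = RunManifest(
        "normalise",
        parameters={"target": str(target_image), "in_place": in_place,
                    "dst": str(dst_root) if dst_root else ""},
    )
    n_done = 0
    skipped: list[str] = []
    for rec in index.records:
        try:
            img = ensure_rgb(read_image(rec.path))
        except FormatError:
            skipped.append(str(rec.path))
            continue
        matched = histogram_match(img, profile)
        if in_place:
            dst = rec.path
            write_image(matched, dst)
            manifest.add_action(rec.path, "replaced", dst)
        else:
            rel = Path(rec.path).relative_to(index.root)
            dst = Path(dst_root) / rel.with_suffix(".png")
            write_image(matched, dst)
            manifest.add_action(rec.path, "created", dst)
        n_done += 1
    manifest.write(index.root if in_place else Path(dst_root))
    return {"n_normalised": n_done, "n_skipped": len(skipped),
            "skipped": skipped, "target": str(target_image)}
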