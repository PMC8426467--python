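"""Pixel-level augmentation operators and pipelines.

The central operator is embossing, which accentuates edge/fibre structure
and is applied here as the blend of an identity kernel with a directional
emboss kernel: each channel is convolved with

    K = (1 - alpha) * E + alpha * M(s),
    M(s) = [[-1-s, -s, 0],
            [ -s,   1, s],
            [  0,   s, 1+s]]

where E is the 3x3 identity kernel (centre 1), s >= 0 is the emboss
strength ("intensity") and alpha in [0, 1] the blend fraction.  M(s) sums to
1 for every s, so constant regions — and in particular whitespace — keep
their mean brightness, and constant images are exact fixed points.
Convolutions use reflective border padding to avoid dark halos at tile
edges.  All operators preserve shape, channel count and the 8-bit range
(outputs are clipped to [0, 255]); seeded operators are pure functions of
(input, parameters, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core_io import (IMAGE_EXTENSIONS, RunManifest, TileImage, read_image,
                      write_image)
from .errors import ConfigurationError

#: Emboss parameters used for stroma-texture accentuation experiments.
DEFAULT_EMBOSS_STRENGTH = 2.0
DEFAULT_EMBOSS_ALPHA = 1.0


def _as_float_channels(img: TileImage) -> np.ndarray:
    px = img.pixels.astype(np.float64)
    return px[np.newaxis] if px.ndim == 2 else np.moveaxis(px, 2, 0)


def _from_float_channels(channels: np.ndarray, img: TileImage) -> TileImage:
    out = np.clip(np.floor(channels + 0.5), 0, 255).astype(np.uint8)
    result = out[0] if img.pixels.ndim == 2 else np.ascontiguousarray(
        np.moveaxis(out, 0, 2))
    return TileImage(result, source_path=img.source_path)


def emboss_kernel(strength: float, alpha: float) -> np.ndarray:
    """The blended emboss kernel K = (1-alpha) E + alpha M(s).  Sums to 1
    for every (strength, alpha)."""
    if not 0 <= alpha <= 1:
        raise ValueError(f"emboss: alpha must be in [0, 1], got {alpha}")
    if strength < 0:
        raise ValueError(f"emboss: strength must be >= 0, got {strength}")
    s = float(strength)
    m = np.array([[-1 - s, -s, 0.0],
                  [-s, 1.0, s],
                  [0.0, s, 1 + s]])
    e = np.zeros((3, 3))
    e[1, 1] = 1.0
    return (1 - alpha) * e + alpha * m


def emboss(img: TileImage, strength: float = DEFAULT_EMBOSS_STRENGTH,
           alpha: float = DEFAULT_EMBOSS_ALPHA) -> TileImage:
    """Emboss each channel by convolution with the blended kernel
    (reflective borders, clipped to [0, 255])."""
    k = emboss_kernel(strength, alpha)
    channels = _as_float_channels(img)
    out = np.stack([ndimage.convolve(ch, k, mode="reflect") for ch in channels])
    return _from_float_channels(out, img)


def gaussian_blur(img: TileImage, sigma: float) -> TileImage:
    """Gaussian smoothing with standard deviation *sigma* (pixels)."""
    if sigma < 0:
        raise ValueError(f"gaussian_blur: sigma must be >= 0, got {sigma}")
    channels = _as_float_channels(img)
    out = np.stack([ndimage.gaussian_filter(ch, sigma, mode="reflect")
                    for ch in channels])
    return _from_float_channels(out, img)


def sharpen(img: TileImage, alpha: float) -> TileImage:
    """Unsharp masking: out = img + alpha * (img - blur(img, sigma=1))."""
    if alpha < 0:
        raise ValueError(f"sharpen: alpha must be >= 0, got {alpha}")
    channels = _as_float_channels(img)
    blurred = np.stack([ndimage.gaussian_filter(ch, 1.0, mode="reflect")
                        for ch in channels])
    return _from_float_channels(channels + alpha * (channels - blurred), img)


def additive_gaussian_noise(img: TileImage, sd: float, seed: int) -> TileImage:
    """Add zero-mean Gaussian noise of standard deviation *sd* gray levels."""
    if sd < 0:
        raise ValueError(f"additive_gaussian_noise: sd must be >= 0, got {sd}")
    rng = np.random.default_rng(seed)
    channels = _as_float_channels(img)
    return _from_float_channels(channels + rng.normal(0, sd, channels.shape), img)


def adjust_contrast(img: TileImage, gain: float, bias: float = 0.0) -> TileImage:
    """Affine intensity map out = gain * in + bias, clipped."""
    if gain < 0:
        raise ValueError(f"adjust_contrast: gain must be >= 0, got {gain}")
    return _from_float_channels(gain * _as_float_channels(img) + bias, img)


def pixel_dropout(img: TileImage, fraction: float, seed: int) -> TileImage:
    """Independently zero each pixel (all channels) with probability
    *fraction*."""
    if not 0 <= fraction <= 1:
        raise ValueError(f"pixel_dropout: fraction must be in [0, 1], "
                         f"got {fraction}")
    rng = np.random.default_rng(seed)
    h, w = img.pixels.shape[:2]
    drop = rng.random((h, w)) < fraction
    out = img.pixels.copy()
    out[drop] = 0
    return TileImage(out, source_path=img.source_path)


def channel_dropout(img: TileImage, channel: int | None, seed: int) -> TileImage:
    """Zero one colour channel (chosen at random when *channel* is None)."""
    if img.n_channels != 3:
        raise ValueError("channel_dropout: requires a 3-channel image")
    if channel is None:
        channel = int(np.random.default_rng(seed).integers(0, 3))
    if not 0 <= channel <= 2:
        raise ValueError(f"channel_dropout: channel must be 0..2, got {channel}")
    out = img.pixels.copy()
    out[:, :, channel] = 0
    return TileImage(out, source_path=img.source_path)


@dataclass(frozen=True)
class AugmentationSpec:
    """One pipeline step: operator name plus its parameter mapping."""

    op_name: str
    parameters: dict = field(default_factory=dict)


# operator registry: name -> (callable, needs_seed)
_OPS: dict[str, tuple] = {
    "emboss": (emboss, False),
    "gaussian_blur": (gaussian_blur, False),
    "sharpen": (sharpen, False),
    "additive_gaussian_noise": (additive_gaussian_noise, True),
    "adjust_contrast": (adjust_contrast, False),
    "pixel_dropout": (pixel_dropout, True),
    "channel_dropout": (channel_dropout, True),
}


def apply_pipeline(img: TileImage, specs: list[AugmentationSpec],
                   seed: int = 0) -> TileImage:
    """Apply operators in order.  One master seed deterministically derives
    an independent sub-seed for every seeded step."""
    child_seeds = iter(np.random.SeedSequence(seed).spawn(max(len(specs), 1)))
    out = img
    for spec in specs:
        if spec.op_name not in _OPS:
            raise ConfigurationError(f"unknown augmentation op {spec.op_name!r}")
        fn, needs_seed = _OPS[spec.op_name]
        kwargs = dict(spec.parameters)
        ss = next(child_seeds)
        if needs_seed and "seed" not in kwargs:
            kwargs["seed"] = int(ss.generate_state(1)[0] % (2**31))
        out = fn(out, **kwargs)
    return out


def augment_directory(src_root: str | os.PathLike,
                      specs: list[AugmentationSpec],
                      dst_root: str | os.PathLike | None = None, *,
                      in_place: bool = False, seed: int = 0,
                      suffix: str | None = None) -> dict:
    """Run an augmentation pipeline over every image under *src_root*.

    Outputs mirror the source tree under *dst_root* with an operator suffix
    in the filename (default: the op names joined by '-'), or overwrite in
    place when explicitly requested.  Deterministic given *seed*.
    """
    if in_place == (dst_root is not None):
        raise ValueError("pass exactly one of dst_root or in_place=True")
    src_root = Path(src_root)
    if suffix is None:
        suffix = "-".join(s.op_name for s in specs) or "noop"
    manifest = RunManifest(
        "augment",
        parameters={"pipeline": [{"op": s.op_name, **s.parameters}
                                 for s in specs],
                    "in_place": in_place,
                    "dst": str(dst_root) if dst_root else ""},
        seed=seed,
    )
    n = 0
    files = [p for p in sorted(src_root.rglob("*"))
             if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS]
    for i, p in enumerate(files):
        img = read_image(p)
        # per-file sub-seed so reordering files cannot alias random streams
        out = apply_pipeline(img, specs, seed=(seed * 1_000_003 + i) % (2**31))
        if in_place:
            dst = p
            write_image(out, dst)
            manifest.add_action(p, "replaced", dst)
        else:
            rel = p.relative_to(src_root)
            dst = (Path(dst_root) / rel.parent /
                   f"{p.stem}_{suffix}.png")
            write_image(out, dst)
            manifest.add_action(p, "created", dst)
        n += 1
    manifest.write(src_root if in_place else Path(dst_root))
    return {"n_augmented": n, "pipeline": [s.op_name for s in specs],
            "seed": seed}
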