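"""Cut larger images into fixed-size tiles on a deterministic grid.

Convolutional networks need inputs of consistent dimensions, so larger
source images are diced into patches placed at top-left offsets
``(row * stride_v, col * stride_h)`` and named with their grid coordinates
(``<stem>_r<row>_c<col>``).  Partial edge tiles are dropped by default;
with stride equal to the patch size the grid is non-overlapping and every
retained source pixel appears in exactly one patch.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path

from .core_io import (IMAGE_EXTENSIONS, RunManifest, TileImage, make_patch_name,
                      read_image, write_image)


@dataclass(frozen=True)
class PatchGrid:
    """Grid geometry: patch size in pixels, strides, and whether partial
    edge tiles are dropped (default) or kept."""

    patch_height: int
    patch_width: int
    stride_vertical: int = 0   # 0 → defaults to patch_height
    stride_horizontal: int = 0  # 0 → defaults to patch_width
    drop_partial: bool = True

    def __post_init__(self):
        if self.patch_height < 1 or self.patch_width < 1:
            raise ValueError("patch dimensions must be >= 1")
        if self.stride_vertical == 0:
            object.__setattr__(self, "stride_vertical", self.patch_height)
        if self.stride_horizontal == 0:
            object.__setattr__(self, "stride_horizontal", self.patch_width)
        if self.stride_vertical < 1 or self.stride_horizontal < 1:
            raise ValueError("strides must be >= 1")


@dataclass
class PatchReport:
    n_source_images: int
    n_patches_written: int
    grid: PatchGrid


def extract_patches(img: TileImage, grid: PatchGrid
                    ) -> list[tuple[TileImage, int, int]]:
    """Return ``(patch, row, col)`` triples cut from *img* on *grid*.

    Patches are exact crops (no interpolation, no padding).  When the patch
    is larger than the image and partial tiles are dropped, the result is
    empty and a warning is emitted rather than an exception.
    """
    h, w = img.pixels.shape[:2]
    ph, pw = grid.patch_height, grid.patch_width
    sv, sh = grid.stride_vertical, grid.stride_horizontal
    out: list[tuple[TileImage, int, int]] = []
    if grid.drop_partial and (ph > h or pw > w):
        warnings.warn(f"patch {ph}x{pw} larger than image {h}x{w}; "
                      "no patches produced", stacklevel=2)
        return out
    row = 0
    y = 0
    while y < h:
        x = 0
        col = 0
        while x < w:
            y1, x1 = y + ph, x + pw
            if y1 > h or x1 > w:
                if grid.drop_partial:
                    x += sh
                    col += 1
                    continue
                y1, x1 = min(y1, h), min(x1, w)
            crop = img.pixels[y:y1, x:x1].copy()
            out.append((TileImage(crop, source_path=img.source_path), row, col))
            x += sh
            col += 1
        y += sv
        row += 1
    return out


def patch_directory(src_root: str | os.PathLike, dst_root: str | os.PathLike,
                    grid: PatchGrid) -> PatchReport:
    """Patch every image under *src_root*, mirroring its directory structure
    under *dst_root* with coordinate-stamped patch names, and write a
    manifest beside the output."""
    src_root, dst_root = Path(src_root), Path(dst_root)
    manifest = RunManifest(
        "patch",
        parameters={"patch_height": grid.patch_height,
                    "patch_width": grid.patch_width,
                    "stride_vertical": grid.stride_vertical,
                    "stride_horizontal": grid.stride_horizontal,
                    "drop_partial": grid.drop_partial,
                    "src": str(src_root), "dst": str(dst_root)},
    )
    n_src = 0
    n_out = 0
    seen: set[Path] = set()
    for p in sorted(src_root.rglob("*")):
        if not p.is_file() or p.suffix.lower() not in IMAGE_EXTENSIONS:
            continue
        n_src += 1
        img = read_image(p)
        rel_dir = p.parent.relative_to(src_root)
        for patch, row, col in extract_patches(img, grid):
            name = make_patch_name(p.stem, row, col) + ".png"
            dst = dst_root / rel_dir / name
            if dst in seen:
                raise RuntimeError(f"patch name collision at {dst}")
            seen.add(dst)
            write_image(patch, dst)
            manifest.add_action(p, "created", dst)
            n_out += 1
    manifest.write(dst_root)
    return PatchReport(n_source_images=n_src, n_patches_written=n_out, grid=grid)
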