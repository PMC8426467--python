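"""Class balancing by reduction or seeded dihedral augmentation.

Datasets with unequal class sizes bias training towards the majority class.
Classes are equalised either by removing surplus tiles (down to the smallest
class) or by creating new tiles with the seven non-identity symmetries of
the square — horizontal mirroring, clockwise rotation by 90°/180°/270°, or
mirroring followed by one rotation.  These are exact pixel permutations, so
each source tile yields at most 7 genuinely new images; augmentation-based
modes therefore require that no class holds less than one eighth of the
largest class's samples, which guarantees the planner never needs the same
(source, transform) pair twice.
"""

from __future__ import annotations

import os
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (AUGMENT_CODES, DatasetIndex, RunManifest, TileImage,
                      TileRecord, make_augmented_name, read_image, scan_dataset,
                      write_image)
from .errors import EighthRuleError

#: The eight axis-aligned symmetries of the square (dihedral group D4),
#: parameterised as an optional horizontal mirror applied first, then a
#: clockwise rotation by k * 90 degrees.
DIHEDRAL_CODES = ("identity", "r90", "r180", "r270", "m", "mr90", "mr180", "mr270")


@dataclass(frozen=True)
class DihedralTransform:
    """One square symmetry, named by its mirror/rotation code."""

    code: str

    def __post_init__(self):
        if self.code not in DIHEDRAL_CODES:
            raise ValueError(f"unknown dihedral code {self.code!r}")

    @property
    def mirrored(self) -> bool:
        return self.code.startswith("m")

    @property
    def quarter_turns(self) -> int:
        """Clockwise quarter turns applied after the (optional) mirror."""
        if self.code in ("identity", "m"):
            return 0
        return int(self.code.lstrip("m").lstrip("r")) // 90


IDENTITY = DihedralTransform("identity")
#: The 7 augmentations (all non-identity elements).
AUGMENTATIONS = tuple(DihedralTransform(c) for c in DIHEDRAL_CODES if c != "identity")


def dihedral_apply(img: TileImage, t: DihedralTransform) -> TileImage:
    """Apply a square symmetry as an exact pixel permutation (mirror first,
    then clockwise rotation; no interpolation)."""
    px = img.pixels
    if t.mirrored:
        px = np.fliplr(px)
    k = t.quarter_turns
    if k:
        px = np.rot90(px, k=-k)  # np.rot90 is counter-clockwise; negate
    return TileImage(np.ascontiguousarray(px), source_path=img.source_path)


def enumerate_augmentations(img: TileImage
                            ) -> list[tuple[DihedralTransform, TileImage]]:
    """Apply all 7 non-identity symmetries.  For a generic asymmetric image
    the outputs are pairwise distinct ("up to 7 unique images"); symmetric
    inputs may produce coincident outputs, which the caller may deduplicate."""
    return [(t, dihedral_apply(img, t)) for t in AUGMENTATIONS]


def check_eighth_rule(class_counts: dict[str, int]
                      ) -> tuple[bool, list[str]]:
    """Check that no class holds less than one eighth of the largest class.

    Returns ``(passed, offending_classes)``.  The boundary is inclusive:
    exactly max/8 passes.
    """
    if len(class_counts) < 2:
        raise ValueError("need at least 2 classes")
    if any(c < 1 for c in class_counts.values()):
        empty = [k for k, c in class_counts.items() if c < 1]
        raise ValueError(f"classes with no samples: {empty}")
    biggest = max(class_counts.values())
    offending = sorted(k for k, c in class_counts.items() if c < biggest / 8)
    return (not offending, offending)


@dataclass
class BalancePlan:
    """What to create and what to remove so every class reaches the target."""

    mode: str  # "to_min" | "to_max" | "to_mean"
    seed: int
    targets: dict[str, int]                      # class → target count
    current: dict[str, int]                      # class → count before
    to_create: list[tuple[TileRecord, DihedralTransform]] = field(default_factory=list)
    to_remove: list[TileRecord] = field(default_factory=list)


def _plan_augment(records: list[TileRecord], deficit: int,
                  rng: np.random.Generator
                  ) -> list[tuple[TileRecord, DihedralTransform]]:
    """Draw (source, transform) pairs in rounds of without-replacement
    sampling; each source's transforms are drawn without repetition across
    rounds, so no pair can recur.  The one-eighth precondition guarantees
    deficit <= 7 * len(records), i.e. at most 7 rounds."""
    n = len(records)
    assert deficit <= 7 * n, "one-eighth precondition violated upstream"
    # per-source transform order, fixed once from the seeded generator
    transform_order = {i: rng.permutation(7) for i in range(n)}
    used = {i: 0 for i in range(n)}
    pairs: list[tuple[TileRecord, DihedralTransform]] = []
    remaining = deficit
    while remaining > 0:
        take = min(remaining, n)
        chosen = rng.choice(n, size=take, replace=False)
        for i in chosen:
            t = AUGMENTATIONS[transform_order[i][used[i]]]
            used[i] += 1
            pairs.append((records[i], t))
        remaining -= take
    return pairs


def plan_balance(index: DatasetIndex, mode: str, seed: int) -> BalancePlan:
    """Decide which tiles to remove or which augmented copies to create.

    Modes: ``to_min`` reduces every class to the smallest; ``to_max``
    augments every class up to the largest; ``to_mean`` targets the rounded
    mean, reducing classes above it and augmenting those below.  Deterministic
    given *seed*.
    """
    if mode not in ("to_min", "to_max", "to_mean"):
        raise ValueError(f"unknown balance mode {mode!r}")
    counts = index.class_counts
    if mode in ("to_max", "to_mean"):
        passed, offending = check_eighth_rule(counts)
        if not passed:
            raise EighthRuleError(
                "augmentation-based balancing requires that no class contains "
                "less than one eighth of the samples of the largest class; "
                f"offending: {offending} (counts {counts})")
    if mode == "to_min":
        target = min(counts.values())
    elif mode == "to_max":
        target = max(counts.values())
    else:
        target = int(np.floor(sum(counts.values()) / len(counts) + 0.5))
    plan = BalancePlan(mode=mode, seed=seed,
                       targets={c: target for c in counts}, current=dict(counts))
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[TileRecord]] = {c: [] for c in counts}
    for r in index.records:
        by_class[r.class_label].append(r)
    for cls in sorted(counts):
        recs = sorted(by_class[cls], key=lambda r: str(r.path))
        n = len(recs)
        if n > target:
            drop_idx = rng.choice(n, size=n - target, replace=False)
            plan.to_remove.extend(recs[i] for i in sorted(drop_idx))
        elif n < target:
            plan.to_create.extend(_plan_augment(recs, target - n, rng))
    return plan


@dataclass
class BalanceReport:
    mode: str
    seed: int
    before: dict[str, int]
    after: dict[str, int]
    n_created: int
    n_removed: int
    removed_dir: str


def execute_balance(index: DatasetIndex, plan: BalancePlan, *,
                    removed_dir_name: str = "Removed Images",
                    hard_delete: bool = False) -> BalanceReport:
    """Execute a balance plan on disk.

    Augmented tiles are written beside their source with symmetry-coded names
    (``<stem>_aug-<code>``).  Surplus tiles are relocated, structure
    preserved, into a directory named *removed_dir_name* beside the dataset
    root — or permanently deleted when *hard_delete* is set.  After execution
    a rescan shows every class at its target count.
    """
    root = Path(index.root)
    removed_root = root.parent / removed_dir_name
    manifest = RunManifest(
        "balance",
        parameters={"mode": plan.mode, "hard_delete": hard_delete,
                    "removed_dir": "" if hard_delete else str(removed_root)},
        seed=plan.seed,
    )
    written: set[Path] = set()
    for rec, t in plan.to_create:
        img = read_image(rec.path)
        out = dihedral_apply(img, t)
        name = make_augmented_name(rec.path.stem, t.code) + rec.path.suffix
        dst = rec.path.parent / name
        if dst in written or dst.exists():
            raise RuntimeError(f"augmented filename collision at {dst}; "
                               "duplicate (source, transform) pair?")
        written.add(dst)
        write_image(out, dst)
        manifest.add_action(rec.path, "created", dst)
    for rec in plan.to_remove:
        if hard_delete:
            os.remove(rec.path)
            manifest.add_action(rec.path, "deleted")
        else:
            rel = Path(rec.path).relative_to(root)
            dst = removed_root / rel
            dst.parent.mkdir(parents=True, exist_ok=True)
            shutil.move(str(rec.path), str(dst))
            manifest.add_action(rec.path, "moved", dst)
    manifest.write(root)
    after = scan_dataset(root, _layout_of(index)).class_counts
    for cls, tgt in plan.targets.items():
        if after.get(cls, 0) != tgt:
            raise RuntimeError(f"class {cls!r} ended at {after.get(cls, 0)}, "
                               f"target {tgt}")
    return BalanceReport(mode=plan.mode, seed=plan.seed, before=plan.current,
                         after=after, n_created=len(plan.to_create),
                         n_removed=len(plan.to_remove),
                         removed_dir="" if hard_delete else str(removed_root))


def _layout_of(index: DatasetIndex) -> str:
    has_roi = any(r.roi_id for r in index.records)
    return "class/patient/roi" if has_roi else "class/patient"
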