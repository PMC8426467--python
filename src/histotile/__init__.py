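"""histotile: headless pre-processing and evaluation for histology image tiles.

Subpackages cover the stages of a tile-based deep-learning workflow:
patching large images into fixed-size tiles, tissue/whitespace thresholding,
class balancing via dihedral augmentation, stain normalisation by histogram
matching, pixel-level augmentation (embossing et al.), synthetic fixture
generation, and tile → ROI → patient majority-vote evaluation metrics.
"""

from .core_io import (DatasetIndex, RunManifest, TileImage, TileRecord,
                      make_augmented_name, make_patch_name, mirror_tree,
                      read_image, scan_dataset, split_by_patient, write_image)
from .patching import PatchGrid, PatchReport, extract_patches, patch_directory
from .thresholding import (BinaryMask, CoverageResult, binary_mask_adaptive,
                           binary_mask_fixed, binary_mask_otsu, filter_tiles,
                           tissue_coverage, to_grayscale)
from .balancing import (AUGMENTATIONS, DihedralTransform, check_eighth_rule,
                        dihedral_apply, enumerate_augmentations,
                        execute_balance, plan_balance)
from .normalisation import (HistogramProfile, channel_profile, ensure_rgb,
                            histogram_match, normalise_directory)
from .augmentation import (AugmentationSpec, apply_pipeline, augment_directory,
                           emboss)
from .metrics import (ConfusionMatrix, accuracy, aggregate_predictions,
                      classify_tile, confusion, exact_binomial_ci, f1,
                      fleiss_kappa, load_predictions, patient_vote, precision,
                      recall, roc_auc, roi_vote, sensitivity, specificity)
from .fixtures import (FixtureSpec, apply_stain_shift, build_dataset,
                       make_fiber_tile, make_whitespace_tile)

__version__ = "0.1.0"

__all__ = [
    "TileImage", "TileRecord", "DatasetIndex", "RunManifest",
    "read_image", "write_image", "scan_dataset", "mirror_tree",
    "make_patch_name", "make_augmented_name", "split_by_patient",
    "PatchGrid", "PatchReport", "extract_patches", "patch_directory",
    "BinaryMask", "CoverageResult", "to_grayscale", "binary_mask_fixed",
    "binary_mask_otsu", "binary_mask_adaptive", "tissue_coverage",
    "filter_tiles",
    "DihedralTransform", "AUGMENTATIONS", "dihedral_apply",
    "enumerate_augmentations", "check_eighth_rule", "plan_balance",
    "execute_balance",
    "HistogramProfile", "ensure_rgb", "channel_profile", "histogram_match",
    "normalise_directory",
    "AugmentationSpec", "emboss", "apply_pipeline", "augment_directory",
    "ConfusionMatrix", "classify_tile", "roi_vote", "patient_vote",
    "confusion", "precision", "recall", "f1", "accuracy", "specificity",
    "sensitivity", "exact_binomial_ci", "roc_auc", "fleiss_kappa",
    "aggregate_predictions", "load_predictions",
    "FixtureSpec", "make_fiber_tile", "make_whitespace_tile",
    "apply_stain_shift", "build_dataset",
]
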