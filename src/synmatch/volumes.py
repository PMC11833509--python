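"""Volume- and intensity-based partner-matching indices on labeled 3D stacks.

In the fly antennal lobe, one olfactory receptor neuron (ORN) type's axons
and one projection neuron (PN) type's dendrites meet in a single
glomerulus, so voxel overlap between segmented axon and dendrite channels
operationalizes synaptic partner matching:

* match index    = |axon ∩ dendrite| / |dendrite|
* mismatch index = |axon ∩ dendrite| / |axon|
* mistarget index = sum of axon fluorescence in glomerulus A over the sum
  in glomeruli A and B (intensity-based; masks must be disjoint)

Ratios are computed on voxel counts: the voxel volume cancels for masks on
a common grid, including anisotropic ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

logger = logging.getLogger(__name__)


@dataclass
class LabeledVolume:
    """A single-channel 3D voxel grid with physical voxel size in micrometers."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.voxels.ndim}")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive: {self.voxel_size}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
        channel: str = "",
    ) -> "LabeledVolume":
        return cls(tifffile.imread(str(path)), voxel_size, channel)

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.voxels)


@dataclass
class BinaryMask:
    """Segmentation of a LabeledVolume (same grid shape as its source)."""

    voxels: np.ndarray
    source_channel: str = ""
    threshold_used: float = float("nan")
    min_object_size: int = 0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.voxels.astype(np.uint8) * 255)


_CONNECTIVITY = {6: 1, 26: 3}  # face-only vs face+edge+corner neighborhoods


def segment_volume(
    vol: LabeledVolume,
    threshold: float | Literal["auto"] = "auto",
    min_size: int = 0,
    connectivity: Literal[6, 26] = 26,
) -> BinaryMask:
    """Threshold a volume and drop connected components below min_size.

    ``threshold="auto"`` uses Otsu's method on the intensity histogram.
    Voxels with value >= threshold are foreground.  An all-background
    result is returned as a valid empty mask with a warning.
    """
    if vol.voxels.size == 0:
        raise ValueError("empty volume")
    data = vol.voxels
    if threshold == "auto":
        if np.all(data == data.flat[0]):
            warnings.warn("constant volume; returning empty mask", stacklevel=2)
            return BinaryMask(np.zeros(data.shape, bool), vol.channel, np.inf, min_size)
        thr = float(threshold_otsu(data))
    else:
        thr = float(threshold)
    mask = data >= thr
    if min_size > 0 and mask.any():
        labels = cc_label(mask, connectivity=_CONNECTIVITY[connectivity])
        counts = np.bincount(labels.ravel())
        too_small = counts < min_size
        too_small[0] = False
        mask[too_small[labels]] = False
    if not mask.any():
        warnings.warn("segmentation produced an empty mask", stacklevel=2)
    return BinaryMask(mask, vol.channel, thr, min_size)


def _check_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    if a.voxels.shape != b.voxels.shape:
        raise ValueError(
            f"masks on different grids: {a.voxels.shape} vs {b.voxels.shape}"
        )


def match_index(axon: BinaryMask, dendrite: BinaryMask) -> float:
    """Overlap volume over total dendrite volume, in [0, 1]."""
    _check_same_grid(axon, dendrite)
    denom = dendrite.n_voxels
    if denom == 0:
        raise ValueError("empty dendrite mask: match index undefined")
    return float(np.count_nonzero(axon.voxels & dendrite.voxels)) / denom


def mismatch_index(axon: BinaryMask, dendrite: BinaryMask) -> float:
    """Overlap volume over total axon volume, in [0, 1]."""
    _check_same_grid(axon, dendrite)
    denom = axon.n_voxels
    if denom == 0:
        raise ValueError("empty axon mask: mismatch index undefined")
    return float(np.count_nonzero(axon.voxels & dendrite.voxels)) / denom


def mistarget_index(
    intensity: LabeledVolume, glom_a: BinaryMask, glom_b: BinaryMask
) -> float:
    """Axon fluorescence in glomerulus A over fluorescence in A plus B."""
    _check_same_grid(glom_a, glom_b)
    if intensity.voxels.shape != glom_a.voxels.shape:
        raise ValueError("intensity grid does not match the glomerulus masks")
    if np.any(glom_a.voxels & glom_b.voxels):
        raise ValueError("glomerulus masks overlap; they must be disjoint")
    sum_a = float(intensity.voxels[glom_a.voxels].sum())
    sum_b = float(intensity.voxels[glom_b.voxels].sum())
    total = sum_a + sum_b
    if total <= 0:
        raise ValueError("zero combined signal in both glomeruli")
    return sum_a / total


def normalize_mean_intensity(
    region_mean: float, image_max: float, image_min: float
) -> float:
    """Min-max normalize a region's mean intensity against its image."""
    if image_max <= image_min:
        raise ValueError("degenerate image: max <= min")
    if not (image_min <= region_mean <= image_max):
        raise ValueError("region mean outside [image_min, image_max]")
    return (region_mean - image_min) / (image_max - image_min)
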