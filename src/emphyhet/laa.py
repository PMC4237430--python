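"""Voxel-level low-attenuation quantification.

Emphysema burden on CT is measured as the fraction of lung voxels at or
below a density threshold (−950 HU by default): the "percent low
attenuation area", %LAA.  The chain implemented here is

1. :func:`threshold_laa` — mark in-lobe voxels at or below the threshold;
2. :func:`filter_small_clusters` — drop in-plane connected components
   smaller than 3 mm² (noise suppression; strictly 2D, per axial slice);
3. :func:`quantify_lobes` — tally voxels/volumes per lobe and aggregate
   to left lung, right lung and whole lung.

No smoothing is applied anywhere; the cluster filter runs after
thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

#: Lobe label convention: left upper/lower, right upper/middle/lower.
LOBE_NAMES = {1: "LUL", 2: "LLL", 3: "RUL", 4: "RML", 5: "RLL"}
LEFT_LOBES = (1, 2)
RIGHT_LOBES = (3, 4, 5)
#: The right middle lobe counts with the upper zone.
UPPER_LOBES = (1, 3, 4)
LOWER_LOBES = (2, 5)

DEFAULT_THRESHOLD_HU = -950.0
DEFAULT_MIN_AREA_MM2 = 3.0


@dataclass
class LabeledVolume:
    """A CT-like volume in Hounsfield Units plus a co-registered lobe mask.

    Parameters
    ----------
    image
        3D array of HU values.
    lobes
        Integer array of the same shape; 0 = background, 1–5 = lobes
        (see :data:`LOBE_NAMES`).
    spacing
        Voxel spacing in mm per axis.
    slice_axis
        Axis index of the slice (through-plane) direction; the other two
        axes are in-plane.
    """

    image: np.ndarray
    lobes: np.ndarray
    spacing: tuple[float, float, float]
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.lobes = np.asarray(self.lobes)
        if self.image.ndim != 3:
            raise ValueError("image must be 3D")
        if self.image.shape != self.lobes.shape:
            raise ValueError(
                f"image shape {self.image.shape} != lobe mask shape {self.lobes.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        extra = set(np.unique(self.lobes)) - {0, 1, 2, 3, 4, 5}
        if extra:
            raise ValueError(f"unexpected lobe labels {sorted(extra)}")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must be 0, 1 or 2")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def pixel_area_mm2(self) -> float:
        """In-plane pixel area (product of the two non-slice spacings)."""
        inplane = [s for i, s in enumerate(self.spacing) if i != self.slice_axis]
        return float(inplane[0] * inplane[1])

    def save(self, image_path: str, lobes_path: str) -> None:
        """Write image and lobe mask as paired NIfTI files with a diagonal affine."""
        affine = np.diag(list(self.spacing) + [1.0])
        nib.save(nib.Nifti1Image(self.image.astype(np.float32), affine), image_path)
        nib.save(nib.Nifti1Image(self.lobes.astype(np.int16), affine), lobes_path)

    @classmethod
    def load(cls, image_path: str, lobes_path: str) -> "LabeledVolume":
        img = nib.load(image_path)
        lob = nib.load(lobes_path)
        if img.shape != lob.shape:
            raise ValueError("image and lobe mask grids differ")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(
            image=np.asarray(img.dataobj, dtype=np.float32),
            lobes=np.asarray(lob.dataobj, dtype=np.int16),
            spacing=spacing,
        )


@dataclass
class LAAMask:
    """Boolean mask of voxels counted as low-attenuation area."""

    mask: np.ndarray
    pre_filter_count: int
    post_filter_count: int
    threshold_hu: float
    min_area_mm2: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class RegionTally:
    """Voxel and volume tallies for one region (a lobe or a lung)."""

    voxels: int
    volume_ml: float
    laa_voxels: int
    laa_volume_ml: float
    laa_pct: float | None  # None when the region is empty (undefined, flagged)

    @property
    def empty(self) -> bool:
        return self.voxels == 0


@dataclass
class LobeQuant:
    """Per-region densitometry: the five lobes plus left/right/whole lung."""

    regions: dict[str, RegionTally] = field(default_factory=dict)
    threshold_hu: float = DEFAULT_THRESHOLD_HU
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2

    def __getitem__(self, region: str) -> RegionTally:
        return self.regions[region]

    @property
    def missing_lobes(self) -> list[str]:
        return [name for name in LOBE_NAMES.values() if self.regions[name].empty]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": name,
                "voxels": t.voxels,
                "volume_ml": t.volume_ml,
                "laa_voxels": t.laa_voxels,
                "laa_volume_ml": t.laa_volume_ml,
                "laa_pct": np.nan if t.laa_pct is None else t.laa_pct,
            }
            for name, t in self.regions.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LobeQuant":
        quant = cls()
        for row in df.itertuples(index=False):
            pct = None if pd.isna(row.laa_pct) else float(row.laa_pct)
            quant.regions[row.region] = RegionTally(
                voxels=int(row.voxels),
                volume_ml=float(row.volume_ml),
                laa_voxels=int(row.laa_voxels),
                laa_volume_ml=float(row.laa_volume_ml),
                laa_pct=pct,
            )
        return quant


def threshold_laa(
    volume: LabeledVolume,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    inclusive: bool = True,
) -> LAAMask:
    """Mark in-lobe voxels at (or below) the attenuation threshold.

    ``inclusive=True`` counts voxels with HU ≤ threshold; ``False`` uses a
    strict ``<``.  Background voxels (lobe label 0) are never marked.
    """
    if inclusive:
        low = volume.image <= threshold_hu
    else:
        low = volume.image < threshold_hu
    mask = low & (volume.lobes > 0)
    n = int(mask.sum())
    return LAAMask(mask=mask, pre_filter_count=n, post_filter_count=n,
                   threshold_hu=threshold_hu)


def filter_small_clusters(
    mask: LAAMask,
    volume: LabeledVolume,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
    connectivity: int = 2,
) -> LAAMask:
    """Remove in-plane connected components smaller than ``min_area_mm2``.

    Components are computed per axial slice in 2D — clusters are never
    merged across slices.  ``connectivity`` follows scikit-image: 2 means
    8-connectivity (the default here), 1 means 4-connectivity.
    """
    if min_area_mm2 < 0:
        raise ValueError(f"min_area_mm2 must be >= 0, got {min_area_mm2}")
    if mask.mask.shape != volume.image.shape:
        raise ValueError("mask and volume grids differ")
    pixel_area = volume.pixel_area_mm2
    out = np.zeros_like(mask.mask)
    axis = volume.slice_axis
    min_pixels = min_area_mm2 / pixel_area
    for k in range(mask.mask.shape[axis]):
        sl = [slice(None)] * 3
        sl[axis] = k
        plane = mask.mask[tuple(sl)]
        if not plane.any():
            continue
        labels = cc_label(plane, connectivity=connectivity)
        counts = np.bincount(labels.ravel())
        keep = counts >= min_pixels  # area = pixels * pixel_area; kept iff >= min_area
        keep[0] = False
        out[tuple(sl)] = keep[labels]
    return LAAMask(
        mask=out,
        pre_filter_count=mask.pre_filter_count,
        post_filter_count=int(out.sum()),
        threshold_hu=mask.threshold_hu,
        min_area_mm2=min_area_mm2,
    )


def quantify_lobes(mask: LAAMask, volume: LabeledVolume) -> LobeQuant:
    """Tally LAA per lobe and aggregate to left/right/whole lung.

    %LAA = 100 × LAA volume / region volume.  A lobe absent from the
    label mask is reported with zero volume and an *undefined* (None)
    %LAA rather than a silent 0.
    """
    if mask.mask.shape != volume.image.shape:
        raise ValueError("mask and volume grids differ")
    if mask.mask[volume.lobes == 0].any():
        raise ValueError("LAA mask marks voxels outside the lobe labels")
    vox_ml = volume.voxel_volume_ml
    flat_lobes = volume.lobes.ravel()
    flat_mask = mask.mask.ravel()
    total = np.bincount(flat_lobes, minlength=6)
    laa = np.bincount(flat_lobes[flat_mask], minlength=6)

    quant = LobeQuant(threshold_hu=mask.threshold_hu, min_area_mm2=mask.min_area_mm2)

    def tally(labels: tuple[int, ...]) -> RegionTally:
        n = int(total[list(labels)].sum())
        k = int(laa[list(labels)].sum())
        pct = None if n == 0 else 100.0 * k / n
        return RegionTally(
            voxels=n,
            volume_ml=n * vox_ml,
            laa_voxels=k,
            laa_volume_ml=k * vox_ml,
            laa_pct=pct,
        )

    for lbl, name in LOBE_NAMES.items():
        quant.regions[name] = tally((lbl,))
    quant.regions["left"] = tally(LEFT_LOBES)
    quant.regions["right"] = tally(RIGHT_LOBES)
    quant.regions["whole"] = tally(LEFT_LOBES + RIGHT_LOBES)
    return quant


def quantify_volume(
    volume: LabeledVolume,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
    connectivity: int = 2,
    inclusive: bool = True,
) -> LobeQuant:
    """Full densitometry chain: threshold → cluster filter → tallies."""
    mask = threshold_laa(volume, threshold_hu, inclusive=inclusive)
    mask = filter_small_clusters(mask, volume, min_area_mm2, connectivity=connectivity)
    return quantify_lobes(mask, volume)
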