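"""Volumetric data model, NIfTI I/O, and map-level geometry and statistics.

All analyses in this package operate on 3-D volumes sharing one reference
grid (MNI space in real use, a small synthetic grid in simulations).  Three
containers cover every need: :class:`VolumeGrid` (shape + affine),
:class:`ScalarMap` (one real value per voxel plus an analysis mask), and
:class:`BinaryMask` (lesions, ROIs, atlases).  Grids are never resampled
implicitly — silent resampling corrupts voxel-wise statistics — so congruence
is checked on every binary operation and :func:`resample` must be called
explicitly when grids differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DegenerateDataError, DimensionalityError, GridError

#: tolerance (mm) for element-wise affine equality between congruent grids
GRID_ATOL = 1e-4


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel grid: shape plus a voxel-index -> world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    space_label: str = "unknown"

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise GridError(f"grid shape must be 3 positive integers, got {self.shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise GridError("affine must be a 4x4 matrix")
        det = np.linalg.det(aff[:3, :3])
        if not np.isfinite(det) or abs(det) < 1e-12:
            raise GridError("affine is not invertible (zero voxel volume)")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", aff)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def congruent(self, other: "VolumeGrid", atol: float = GRID_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol, rtol=0.0
        )

    def voxel_to_world(self, ijk: Sequence[float]) -> np.ndarray:
        """World (mm) coordinate of a 0-based voxel index."""
        ijk = np.asarray(ijk, dtype=float)
        return self.affine[:3, :3] @ ijk + self.affine[:3, 3]


def _require_congruent(*grids: VolumeGrid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.congruent(g):
            raise GridError(
                "grids are not congruent; resample explicitly with lnmap.volumes.resample"
            )


@dataclass
class ScalarMap:
    """One real value per voxel plus a boolean analysis mask.

    Values outside ``analysis_mask`` are ignored by every statistic.
    Non-finite input values are removed from the mask on construction.
    """

    grid: VolumeGrid
    values: np.ndarray
    analysis_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.shape:
            raise GridError(
                f"values shape {vals.shape} does not match grid shape {self.grid.shape}"
            )
        if self.analysis_mask is None:
            mask = np.ones(self.grid.shape, dtype=bool)
        else:
            mask = np.asarray(self.analysis_mask, dtype=bool)
            if mask.shape != self.grid.shape:
                raise GridError("analysis_mask shape does not match grid shape")
            mask = mask.copy()
        # NaN/inf voxels are undefined, not zero: drop them from the mask
        mask &= np.isfinite(vals)
        vals = np.where(mask, vals, 0.0)
        self.values = vals
        self.analysis_mask = mask

    def masked_values(self) -> np.ndarray:
        return self.values[self.analysis_mask]

    def positive_part(self) -> "ScalarMap":
        return ScalarMap(self.grid, np.clip(self.values, 0.0, None), self.analysis_mask)

    def negative_part(self) -> "ScalarMap":
        """Magnitude of the negative values (a non-negative map)."""
        return ScalarMap(self.grid, np.clip(-self.values, 0.0, None), self.analysis_mask)

    def peak_voxel(self) -> tuple[int, int, int]:
        """Voxel index of the largest in-mask value; ties by scan order."""
        flat = np.where(self.analysis_mask.ravel(), self.values.ravel(), -np.inf)
        return tuple(int(i) for i in np.unravel_index(int(np.argmax(flat)), self.grid.shape))


@dataclass
class BinaryMask:
    """A boolean indicator volume (lesion tracing, ROI, atlas region)."""

    grid: VolumeGrid
    indicator: np.ndarray

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator) != 0
        if ind.shape != self.grid.shape:
            raise GridError("indicator shape does not match grid shape")
        self.indicator = ind

    @property
    def voxel_count(self) -> int:
        return int(self.indicator.sum())

    def to_scalar(self) -> ScalarMap:
        return ScalarMap(self.grid, self.indicator.astype(float))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _grid_from_img(img: nib.spatialimages.SpatialImage, space_label: str) -> VolumeGrid:
    return VolumeGrid(tuple(img.shape[:3]), np.asarray(img.affine), space_label)


def load_volume(path: str | Path, as_mask: bool = False,
                space_label: str = "unknown") -> ScalarMap | BinaryMask:
    """Read a 3-D NIfTI volume as a :class:`ScalarMap` or :class:`BinaryMask`.

    Masks binarize at strictly nonzero.  4-D files are rejected here: use
    :func:`lnmap.connectome.load_timeseries` for BOLD runs.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise IOError(f"could not read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path} is {data.ndim}-D; load 4-D timeseries with "
            "lnmap.connectome.load_timeseries"
        )
    grid = _grid_from_img(img, space_label)
    if as_mask:
        with np.errstate(invalid="ignore"):
            ind = np.nan_to_num(np.asarray(data, dtype=float)) != 0
        return BinaryMask(grid, ind)
    return ScalarMap(grid, np.asarray(data, dtype=float))


def save_volume(vol: ScalarMap | BinaryMask, path: str | Path) -> None:
    """Write a map or mask as NIfTI-1; masks are stored as 8-bit integers."""
    path = Path(path)
    if isinstance(vol, BinaryMask):
        data = vol.indicator.astype(np.uint8)
    else:
        data = vol.values.astype(np.float64)
    img = nib.Nifti1Image(data, vol.grid.affine)
    nib.save(img, str(path))


def resample(vol: ScalarMap | BinaryMask, target: VolumeGrid) -> ScalarMap | BinaryMask:
    """Explicit resampling onto ``target``: trilinear for maps, nearest for masks."""
    src_grid = vol.grid
    # voxel(target) -> world -> voxel(source)
    combined = np.linalg.inv(src_grid.affine) @ target.affine
    matrix, offset = combined[:3, :3], combined[:3, 3]
    if isinstance(vol, BinaryMask):
        out = ndimage.affine_transform(
            vol.indicator.astype(np.uint8), matrix, offset,
            output_shape=target.shape, order=0, mode="constant", cval=0)
        return BinaryMask(target, out != 0)
    vals = ndimage.affine_transform(
        vol.values, matrix, offset, output_shape=target.shape,
        order=1, mode="constant", cval=0.0)
    mask = ndimage.affine_transform(
        vol.analysis_mask.astype(np.uint8), matrix, offset,
        output_shape=target.shape, order=0, mode="constant", cval=0)
    return ScalarMap(target, vals, mask != 0)


# ---------------------------------------------------------------------------
# Map-level statistics
# ---------------------------------------------------------------------------

def spatial_correlation(map_a: ScalarMap, map_b: ScalarMap,
                        mask: BinaryMask | None = None) -> float:
    """Pearson correlation of two maps over their shared analysis mask.

    The effective mask is the intersection of both analysis masks and the
    optional restriction mask; it must contain at least 3 voxels and neither
    map may be constant on it.
    """
    _require_congruent(map_a.grid, map_b.grid,
                       *( [mask.grid] if mask is not None else [] ))
    eff = map_a.analysis_mask & map_b.analysis_mask
    if mask is not None:
        eff &= mask.indicator
    n = int(eff.sum())
    if n < 3:
        raise DegenerateDataError(f"effective mask has {n} voxels (< 3)")
    a = map_a.values[eff]
    b = map_b.values[eff]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        raise DegenerateDataError("spatial correlation undefined: constant map on mask")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def overlap_sum(circuit: ScalarMap, lesion: BinaryMask, positive_only: bool = True) -> float:
    """Sum of circuit values under a lesion, split by sign.

    ``positive_only=True`` sums the positive circuit component (negatives
    clamped to 0); ``positive_only=False`` sums the magnitude of the negative
    component.  A lesion disjoint from all nonzero voxels returns 0.
    """
    _require_congruent(circuit.grid, lesion.grid)
    sel = lesion.indicator & circuit.analysis_mask
    vals = circuit.values[sel]
    if positive_only:
        return float(np.clip(vals, 0.0, None).sum())
    return float(np.clip(-vals, 0.0, None).sum())


def lesion_frequency_map(lesions: Sequence[BinaryMask] | Iterable[BinaryMask]) -> ScalarMap:
    """Per-voxel count of lesions covering that voxel (lesion overlap map)."""
    lesions = list(lesions)
    if not lesions:
        raise ValueError("lesion_frequency_map requires at least one lesion")
    _require_congruent(*(l.grid for l in lesions))
    counts = np.zeros(lesions[0].grid.shape, dtype=float)
    for les in lesions:
        counts += les.indicator
    return ScalarMap(lesions[0].grid, counts)
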