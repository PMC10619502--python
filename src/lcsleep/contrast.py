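"""Locus coeruleus (LC) contrast from a magnetization-transfer-weighted volume.

The LC appears as a thin hyperintense tube in the dorsal pons on
MT-weighted images.  Its contrast is quantified per side by

1. *skeletonizing* the binary LC mask: in every axial slice that the mask
   touches, only the in-mask voxel with the highest intensity is kept;
2. normalizing each skeleton intensity to the mean of a square reference
   region (default 15 x 15 voxels) placed in the pontine tegmentum of the
   same slice: ``contrast_i = (LC_i - mean(pons_i)) / mean(pons_i)``;
3. averaging per-slice contrasts over slices (side contrast), and averaging
   the two side contrasts (bilateral contrast).

Inputs are assumed co-registered; no resampling or registration is done.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "Volume3D",
    "SkeletonEntry",
    "SkeletonizedLC",
    "ReferenceRegionSpec",
    "LCContrastResult",
    "load_volume",
    "load_mask",
    "skeletonize_lc",
    "reference_mean",
    "lc_contrast",
    "bilateral_contrast",
    "contrast_density",
]


@dataclass(frozen=True)
class Volume3D:
    """A 3D scalar intensity grid with voxel geometry.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units).
    voxel_size
        Voxel edge lengths in mm, one per grid axis.
    axial_axis
        Which grid axis indexes axial slices (0, 1 or 2).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (0.4, 0.4, 0.5)
    axial_axis: int = 0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume intensities must be finite")
        if self.axial_axis not in (0, 1, 2):
            raise ValueError(f"axial_axis must be 0, 1 or 2, got {self.axial_axis}")
        object.__setattr__(self, "data", data)

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.axial_axis]

    def axial_slice(self, index: int) -> np.ndarray:
        """Return the 2D in-plane array of axial slice ``index``."""
        return np.take(self.data, index, axis=self.axial_axis)


@dataclass(frozen=True)
class SkeletonEntry:
    slice_index: int
    coord: tuple[int, int]  # in-plane (row, col), 0-based
    intensity: float


@dataclass(frozen=True)
class SkeletonizedLC:
    """One brightest in-mask voxel per axial slice, for one LC side."""

    side: str
    entries: tuple[SkeletonEntry, ...]

    @property
    def slice_indices(self) -> list[int]:
        return [e.slice_index for e in self.entries]


@dataclass(frozen=True)
class ReferenceRegionSpec:
    """Square pontine reference region, one center per axial slice.

    ``size_voxels`` is the in-plane edge of the square (default 15, i.e.
    5.5 x 5.5 mm^2 at 0.37 mm in-plane resolution).  Centers are 0-based
    (row, col) in-plane coordinates; the square must fit entirely inside
    the grid on every mapped slice.
    """

    center_per_slice: Mapping[int, tuple[int, int]]
    size_voxels: int = 15
    physical_size_mm: float = 5.5

    def __post_init__(self) -> None:
        if self.size_voxels < 1 or self.size_voxels % 2 == 0:
            raise ValueError("size_voxels must be a positive odd integer")


@dataclass(frozen=True)
class LCContrastResult:
    """Per-slice and summary contrast for one LC side."""

    side: str
    slice_indices: tuple[int, ...]
    per_slice_contrast: tuple[float, ...]
    side_contrast: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.per_slice_contrast) == 0:
            raise ValueError("no per-slice contrasts")
        vals = np.asarray(self.per_slice_contrast, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("contrast values must be finite")
        object.__setattr__(self, "side_contrast", float(vals.mean()))


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_volume(path, axial_axis: int = 0) -> Volume3D:
    """Load a NIfTI-1 volume as a :class:`Volume3D`."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(data=data, voxel_size=zooms, axial_axis=axial_axis)


def load_mask(path) -> np.ndarray:
    """Load a NIfTI-1 binary mask as a boolean array."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0.5


# ---------------------------------------------------------------------------
# Skeletonization


def skeletonize_lc(volume: Volume3D, mask: np.ndarray, side: str) -> SkeletonizedLC:
    """Keep, per axial slice, the in-mask voxel with the highest intensity.

    Slices the mask does not touch are omitted.  Ties at the maximum are
    broken toward the smallest in-plane (row, col) coordinate in row-major
    order, which makes the result deterministic.

    Raises
    ------
    ValueError
        If the mask is empty or its grid does not match the volume's.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != volume.data.shape:
        raise ValueError(
            f"mask grid {mask.shape} does not match volume grid {volume.data.shape}"
        )
    if not mask.any():
        raise ValueError(f"empty LC mask for side {side!r}")

    entries = []
    for k in range(volume.n_slices):
        m2d = np.take(mask, k, axis=volume.axial_axis)
        if not m2d.any():
            continue
        plane = volume.axial_slice(k)
        vals = np.where(m2d, plane, -np.inf)
        # argmax on the flattened row-major array returns the first (i.e.
        # smallest (row, col)) occurrence of the maximum: the tie-break rule.
        flat = int(np.argmax(vals))
        coord = np.unravel_index(flat, vals.shape)
        entries.append(
            SkeletonEntry(
                slice_index=k,
                coord=(int(coord[0]), int(coord[1])),
                intensity=float(plane[coord]),
            )
        )
    return SkeletonizedLC(side=side, entries=tuple(entries))


# ---------------------------------------------------------------------------
# Reference region and contrast


def reference_mean(
    volume: Volume3D, slice_index: int, spec: ReferenceRegionSpec
) -> float:
    """Mean intensity of the reference square on one axial slice.

    Exactly ``size_voxels**2`` voxels contribute; a square clipped by the
    grid boundary is an error (partial squares would bias the mean).
    """
    if slice_index not in spec.center_per_slice:
        raise KeyError(f"no reference center mapped for slice {slice_index}")
    row, col = spec.center_per_slice[slice_index]
    half = spec.size_voxels // 2
    plane = volume.axial_slice(slice_index)
    r0, r1 = row - half, row + half + 1
    c0, c1 = col - half, col + half + 1
    if r0 < 0 or c0 < 0 or r1 > plane.shape[0] or c1 > plane.shape[1]:
        raise ValueError(
            f"reference square of edge {spec.size_voxels} centered at "
            f"({row}, {col}) exceeds the grid on slice {slice_index}"
        )
    patch = plane[r0:r1, c0:c1]
    return float(patch.mean())


def lc_contrast(
    volume: Volume3D, skeleton: SkeletonizedLC, spec: ReferenceRegionSpec
) -> LCContrastResult:
    """Per-slice normalized contrast and its mean for one LC side.

    For each skeleton slice i the contrast is
    ``(LC_i - mean(pons_i)) / mean(pons_i)`` with ``LC_i`` the skeleton
    intensity and ``mean(pons_i)`` the reference-square mean of that slice.
    The side contrast is the arithmetic mean over slices.  Negative
    contrasts are allowed; a non-positive reference mean is an error
    because the normalization is then undefined.
    """
    if not skeleton.entries:
        raise ValueError(f"skeleton for side {skeleton.side!r} has no entries")
    indices = []
    contrasts = []
    for entry in skeleton.entries:
        ref = reference_mean(volume, entry.slice_index, spec)
        if ref <= 0:
            raise ValueError(
                f"non-positive reference mean ({ref}) on slice "
                f"{entry.slice_index}: contrast undefined"
            )
        indices.append(entry.slice_index)
        contrasts.append((entry.intensity - ref) / ref)
    return LCContrastResult(
        side=skeleton.side,
        slice_indices=tuple(indices),
        per_slice_contrast=tuple(float(c) for c in contrasts),
    )


def bilateral_contrast(left: LCContrastResult, right: LCContrastResult) -> float:
    """Mean of the left and right side contrasts.

    Both sides are required; there is no silent one-sided fallback.
    """
    if left is None or right is None:
        raise ValueError("bilateral contrast requires both a left and a right result")
    return 0.5 * (left.side_contrast + right.side_contrast)


def contrast_density(
    contrasts: Sequence[float],
    bandwidth: float | None = None,
    grid_size: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of a sample of LC contrasts.

    Returns ``(grid, density)`` where the grid spans the sample range
    padded by three bandwidths so the density numerically integrates to
    one.  ``bandwidth`` overrides the automatic (Scott) factor and is the
    kernel standard deviation in contrast units.
    """
    x = np.asarray(contrasts, dtype=float)
    if x.size == 0:
        raise ValueError("empty contrast sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("contrast sample contains non-finite values")

    if bandwidth is not None:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
        if np.ptp(x) == 0.0 or x.size == 1:
            # degenerate sample: a single Gaussian bump at the common value
            grid = np.linspace(x[0] - 5 * h, x[0] + 5 * h, grid_size)
            dens = np.exp(-0.5 * ((grid - x[0]) / h) ** 2) / (h * np.sqrt(2 * np.pi))
            return grid, dens
        kde = gaussian_kde(x, bw_method=h / x.std(ddof=1))
    else:
        if np.unique(x).size < 2:
            raise ValueError(
                "automatic bandwidth needs at least two distinct values; "
                "pass an explicit bandwidth"
            )
        kde = gaussian_kde(x)
        h = float(np.sqrt(kde.covariance[0, 0]))

    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    return grid, kde(grid)
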