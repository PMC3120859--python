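"""Shared containers for image stacks, PSFs and segmented nuclei.

Coordinate conventions used throughout the package:

* Physical coordinates are Cartesian lab-frame ``(x, y, z)`` in micrometres:
  ``x`` along the illumination (light-sheet) axis, ``y`` along gravity and
  the nominal root axis, ``z`` along the collection (objective) axis.
* Voxel arrays are stored ``(z, y, x)`` (one TIFF page per z-slice);
  ``voxel_sizes`` and ``origin`` are always given in ``(x, y, z)`` order.
* Times are minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "PSF", "NucleusRecord", "RECORD_FIELDS"]


@dataclass
class ImageStack:
    """A single 3D fluorescence stack with physical metadata.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Non-negative intensities.
    voxel_sizes : tuple of float
        Voxel pitch ``(dx, dy, dz)`` in µm.
    time : float
        Acquisition time in minutes.
    origin : tuple of float
        Lab-frame position ``(x, y, z)`` in µm of voxel ``[0, 0, 0]``.
    """

    voxels: np.ndarray
    voxel_sizes: tuple[float, float, float]
    time: float = 0.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (z, y, x) array")
        if any(v <= 0 for v in self.voxel_sizes):
            raise ValueError("voxel sizes must be positive")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical (x, y, z) coordinate axes of voxel centres, in µm."""
        nz, ny, nx = self.voxels.shape
        dx, dy, dz = self.voxel_sizes
        ox, oy, oz = self.origin
        return (
            ox + dx * np.arange(nx),
            oy + dy * np.arange(ny),
            oz + dz * np.arange(nz),
        )

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Map fractional ``(z, y, x)`` indices to physical (x, y, z) µm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        dx, dy, dz = self.voxel_sizes
        ox, oy, oz = self.origin
        out = np.column_stack(
            [ox + idx[:, 2] * dx, oy + idx[:, 1] * dy, oz + idx[:, 0] * dz]
        )
        return out if np.asarray(indices).ndim > 1 else out[0]


@dataclass
class PSF:
    """Measured point-spread function.

    ``kernel`` is stored (z, y, x), normalized to unit sum, with a single
    global maximum; ``fwhm`` is reported per physical axis (x, y, z) in µm.
    """

    kernel: np.ndarray
    voxel_sizes: tuple[float, float, float]
    fwhm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        if np.any(self.kernel < 0):
            raise ValueError("PSF kernel must be non-negative")
        s = self.kernel.sum()
        if not np.isclose(s, 1.0, rtol=1e-6):
            raise ValueError("PSF kernel must sum to 1")


# Exact CSV column order for nucleus records (see io.write_records).
RECORD_FIELDS = (
    "id",
    "time",
    "x",
    "y",
    "z",
    "max_intensity",
    "mean_intensity",
    "voxel_count",
    "lateral_size",
    "lateral_eccentricity",
    "axial_size",
)


@dataclass
class NucleusRecord:
    """One segmented nucleus at one time point.

    Lateral quantities live in the (x, y) plane normal to the collection
    axis; axial quantities along z.  Sizes are twice the intensity-weighted
    RMS extent, in µm; eccentricity comes from the 2x2 lateral second-moment
    eigenvalues and lies in [0, 1).
    """

    id: int
    time: float
    centroid: np.ndarray  # (x, y, z) µm
    max_intensity: float
    mean_intensity: float
    voxel_count: int
    lateral_size: float
    lateral_eccentricity: float
    axial_size: float

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")
        if self.lateral_eccentricity < 0:
            raise ValueError("eccentricity must be >= 0")
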