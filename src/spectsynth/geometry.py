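"""Lattice and phantom geometry shared by all pipeline stages.

The reference geometry is a water-filled Jaszczak cylinder (diameter
21.6 cm, length 18.6 cm) voxelized on a cubic lattice.  Two presets are
provided:

``full``
    256 voxels @ 2.4 mm — the geometry of the original study.
``desk``
    32 voxels @ 4.8 mm — a half-scale phantom on a coarse lattice, sized
    so that the complete study (dataset build, simulation, u-net
    training, evaluation, reconstruction) runs in minutes on one CPU.

The cylinder occupies the same fraction of the lattice in both presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GridSpec", "PRESETS", "get_preset", "cylinder_support"]

# Fraction of the lattice extent covered by the cylinder, fixed by the
# full preset: 216 mm / (256 * 2.4 mm) and 186 mm / (256 * 2.4 mm).
_DIAMETER_FRACTION = 216.0 / 614.4
_LENGTH_FRACTION = 186.0 / 614.4


@dataclass(frozen=True)
class GridSpec:
    """Cubic voxel lattice holding the cylindrical phantom.

    Attributes
    ----------
    name : preset label.
    n : lattice size per axis (volumes are ``n**3``).
    voxel_size_mm : isotropic voxel edge in mm.
    het_period_voxels : period ``p`` of the heterogeneity field, in voxels.
    het_cutoff : spatial cutoff frequency ``M`` of the field.
    het_beta : spectral exponent ``beta`` of the field.
    """

    name: str
    n: int
    voxel_size_mm: float
    het_period_voxels: int = 50
    het_cutoff: int = 8
    het_beta: float = 0.9

    @property
    def extent_mm(self) -> float:
        return self.n * self.voxel_size_mm

    @property
    def cylinder_diameter_mm(self) -> float:
        return _DIAMETER_FRACTION * self.extent_mm

    @property
    def cylinder_length_mm(self) -> float:
        return _LENGTH_FRACTION * self.extent_mm

    @property
    def cylinder_radius_voxels(self) -> float:
        return 0.5 * self.cylinder_diameter_mm / self.voxel_size_mm

    @property
    def voxel_volume_ml(self) -> float:
        return (self.voxel_size_mm / 10.0) ** 3

    @property
    def center(self) -> float:
        """Geometric center of the lattice in voxel coordinates."""
        return (self.n - 1) / 2.0

    def scaled(self, **kwargs) -> "GridSpec":
        return replace(self, **kwargs)


PRESETS: dict[str, GridSpec] = {
    "full": GridSpec(name="full", n=256, voxel_size_mm=2.4,
                     het_period_voxels=50),
    # Heterogeneity period kept at the same physical length (120 mm).
    "desk": GridSpec(name="desk", n=32, voxel_size_mm=4.8,
                     het_period_voxels=25),
}


def get_preset(name: str) -> GridSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


def cylinder_support(grid: GridSpec) -> np.ndarray:
    """Boolean mask of the cylindrical phantom on the lattice.

    Axes are (x, y, z); the cylinder axis runs along z and is centered
    on the lattice.
    """
    c = grid.center
    r_vox = grid.cylinder_radius_voxels
    half_len_vox = 0.5 * grid.cylinder_length_mm / grid.voxel_size_mm
    x, y, z = np.ogrid[: grid.n, : grid.n, : grid.n]
    radial = (x - c) ** 2 + (y - c) ** 2 <= r_vox**2
    axial = np.abs(z - c) <= half_len_vox
    return radial & axial
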