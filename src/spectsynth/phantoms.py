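"""Assembly of heterogeneous activity masks from manifest entries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GridSpec, cylinder_support
from .heterogeneity import HeterogeneityField, apply_heterogeneity, evaluate_field
from .manifest import CATEGORIES
from .patterns import generate_pattern_mask, generate_random_shapes_mask

__all__ = ["ActivityMask", "build_activity_mask"]


@dataclass
class ActivityMask:
    """Voxelized relative activity distribution.

    ``grid`` holds integers in [0, 100] (100 = the highest activity
    concentration); the physical concentration of a voxel is
    ``grid/100 * max_activity_conc_mbq_ml``.
    """

    grid: np.ndarray
    voxel_size_mm: float
    category: str
    max_activity_conc_mbq_ml: float
    dataset_id: str = ""
    seed: int = 0
    #: voxel counts of the individually placed random shapes (empty for
    #: pattern categories)
    shape_voxel_counts: list[int] = field(default_factory=list)

    @property
    def concentration(self) -> np.ndarray:
        """Activity concentration per voxel in MBq/mL."""
        return self.grid.astype(np.float64) / 100.0 * self.max_activity_conc_mbq_ml


def build_activity_mask(entry, grid: GridSpec,
                        support: np.ndarray | None = None,
                        n_shapes_range: tuple[int, int] = (10, 25),
                        volume_range: tuple[int, int] = (8, 64),
                        floor: int = 1) -> ActivityMask:
    """Build the activity mask for one manifest row.

    ``entry`` needs attributes ``id``, ``category``, ``seed`` and
    ``max_conc_mbq_ml`` (a pandas row works).  The binary category mask
    is modulated by a freshly drawn heterogeneity field and rescaled to
    integers in [floor, 100].
    """
    category = entry.category
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if support is None:
        support = cylinder_support(grid)
    rng = np.random.default_rng(int(entry.seed))
    shape_counts: list[int] = []
    if category == "random":
        binary, shape_counts = generate_random_shapes_mask(
            rng, grid, support, n_shapes_range, volume_range)
    else:
        binary = generate_pattern_mask(category, rng, grid, support)
    fld = HeterogeneityField.draw(
        seed=int(rng.integers(2**31 - 1)),
        beta=grid.het_beta, M=grid.het_cutoff, p=grid.het_period_voxels)
    values = evaluate_field(fld, binary.shape)
    activity = apply_heterogeneity(binary.astype(np.int16), values, floor=floor)
    return ActivityMask(
        grid=activity,
        voxel_size_mm=grid.voxel_size_mm,
        category=category,
        max_activity_conc_mbq_ml=float(entry.max_conc_mbq_ml),
        dataset_id=str(entry.id),
        seed=int(entry.seed),
        shape_voxel_counts=shape_counts,
    )
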