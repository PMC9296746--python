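"""Special-category activity masks complementing the random-shape masks.

Six pattern families diversify the training distribution: an inverted
(hot cylinder, cold shapes) mask, chessboard, rod, cross and stripe
patterns, and a voxelized six-sphere arrangement mimicking the NEMA IEC
body-phantom insert.  All patterns except the sphere arrangement are
randomly rotated in 3D before being clipped to the cylinder support;
the spheres receive a random in-plane rotation only.

Physical dimensions (sphere diameters, stripe thicknesses) are defined
at the full-preset scale and shrink proportionally on smaller lattices,
where sub-voxel features round to single voxels.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .geometry import GridSpec, cylinder_support
from .shapes import (PlacementError, generate_random_shape, place_shapes,
                     random_rotation_matrix)

__all__ = ["PATTERN_CATEGORIES", "generate_pattern_mask", "generate_random_shapes_mask"]

PATTERN_CATEGORIES = ("inverted", "chessboard", "rod", "cross", "stripe", "nema")

#: NEMA IEC sphere inner diameters (mm) and the diameter of the circle on
#: which their centers sit, at the full-preset physical scale.
NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
NEMA_CIRCLE_RADIUS_MM = 57.2

_FULL_EXTENT_MM = 614.4  # 256 voxels * 2.4 mm


def _rotate_mask(mask: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Rotate a boolean mask about the grid center (nearest neighbour)."""
    c = (np.array(mask.shape) - 1) / 2.0
    inv = rot.T
    offset = c - inv @ c
    return ndimage.affine_transform(
        mask.astype(np.float32), inv, offset=offset, order=0,
        prefilter=False) > 0.5


def generate_random_shapes_mask(rng: np.random.Generator, grid: GridSpec,
                                support: np.ndarray | None = None,
                                n_shapes_range: tuple[int, int] = (10, 25),
                                volume_range: tuple[int, int] = (8, 64),
                                ) -> tuple[np.ndarray, list[int]]:
    """Union of 10-25 randomly rotated random shapes inside the cylinder."""
    if support is None:
        support = cylinder_support(grid)
    n_shapes = int(rng.integers(n_shapes_range[0], n_shapes_range[1] + 1))
    kinds = ("harmonic-sphere", "superformula", "perlin")
    mask = np.zeros(support.shape, dtype=bool)
    counts: list[int] = []
    for _ in range(n_shapes):
        # a shape too elongated for the support is redrawn, bounded
        for redraw in range(20):
            shape = generate_random_shape(
                kinds[rng.integers(3)], seed=int(rng.integers(2**31 - 1)),
                volume_range=volume_range)
            try:
                sub, c = place_shapes([shape], rng, support)
            except PlacementError:
                if redraw == 19:
                    raise
                continue
            mask |= sub
            counts.extend(c)
            break
    return mask, counts


def generate_pattern_mask(category: str, rng: np.random.Generator | int,
                          grid: GridSpec,
                          support: np.ndarray | None = None) -> np.ndarray:
    """Binary mask for one of the six special categories."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if support is None:
        support = cylinder_support(grid)
    if category == "inverted":
        shapes_mask, _ = generate_random_shapes_mask(rng, grid, support)
        return support & ~shapes_mask
    if category == "chessboard":
        return _chessboard(rng, grid) & support
    if category == "rod":
        return _rods(rng, grid) & support
    if category == "cross":
        return _cross(rng, grid) & support
    if category == "stripe":
        return _stripes(rng, grid) & support
    if category == "nema":
        return _nema_spheres(rng, grid) & support
    raise ValueError(
        f"unknown pattern category {category!r}; choose from {PATTERN_CATEGORIES}")


def _chessboard(rng: np.random.Generator, grid: GridSpec) -> np.ndarray:
    cell = int(rng.integers(max(2, grid.n // 32), max(3, grid.n // 6) + 1))
    offs = rng.integers(0, cell, size=3)
    idx = [(np.arange(grid.n) + offs[a]) // cell for a in range(3)]
    parity = (idx[0][:, None, None] + idx[1][None, :, None]
              + idx[2][None, None, :]) % 2
    return _rotate_mask(parity.astype(bool), random_rotation_matrix(rng))


def _rods(rng: np.random.Generator, grid: GridSpec) -> np.ndarray:
    pitch = int(rng.integers(max(3, grid.n // 24), max(4, grid.n // 6) + 1))
    radius = rng.uniform(0.25, 0.48) * pitch
    ax = np.arange(grid.n, dtype=float)
    off = rng.uniform(0, pitch, size=2)
    dx = (ax - off[0]) % pitch
    dy = (ax - off[1]) % pitch
    dx = np.minimum(dx, pitch - dx)
    dy = np.minimum(dy, pitch - dy)
    disc = dx[:, None] ** 2 + dy[None, :] ** 2 <= radius**2
    rods = np.broadcast_to(disc[:, :, None], (grid.n,) * 3).copy()
    return _rotate_mask(rods, random_rotation_matrix(rng))


def _cross(rng: np.random.Generator, grid: GridSpec) -> np.ndarray:
    c = grid.center
    half_w = rng.uniform(0.02, 0.06) * grid.n
    half_l = rng.uniform(0.1, 0.17) * grid.n
    ax = np.arange(grid.n, dtype=float) - c
    armx = (np.abs(ax)[:, None] <= half_l) & (np.abs(ax)[None, :] <= half_w)
    army = (np.abs(ax)[:, None] <= half_w) & (np.abs(ax)[None, :] <= half_l)
    cross2d = armx | army
    cross = np.broadcast_to(cross2d[:, :, None], (grid.n,) * 3).copy()
    return _rotate_mask(cross, random_rotation_matrix(rng))


def _stripes(rng: np.random.Generator, grid: GridSpec,
             n_stripes: int = 7) -> np.ndarray:
    vox = grid.voxel_size_mm
    thick_mm = rng.uniform(2.4, 16.8, size=n_stripes)
    thick = np.maximum(1, np.rint(thick_mm / vox).astype(int))
    # choose gaps so the stripe block stays well inside the cylinder
    budget_vox = 0.72 * grid.cylinder_diameter_mm / vox
    gap = max(1, int((budget_vox - thick.sum()) / (n_stripes - 1)))
    total = thick.sum() + gap * (n_stripes - 1)
    start = int(round(grid.center - total / 2.0))
    mask = np.zeros((grid.n,) * 3, dtype=bool)
    pos = start
    for t in thick:
        lo, hi = max(pos, 0), min(pos + t, grid.n)
        if lo < hi:
            mask[lo:hi, :, :] = True
        pos += t + gap
    return _rotate_mask(mask, random_rotation_matrix(rng))


def _nema_spheres(rng: np.random.Generator, grid: GridSpec) -> np.ndarray:
    scale = grid.extent_mm / _FULL_EXTENT_MM
    vox = grid.voxel_size_mm
    circle_r = NEMA_CIRCLE_RADIUS_MM * scale / vox
    phase = rng.uniform(0.0, 2 * np.pi)  # random in-plane rotation
    c = grid.center
    mask = np.zeros((grid.n,) * 3, dtype=bool)
    x, y, z = np.ogrid[: grid.n, : grid.n, : grid.n]
    for i, diam in enumerate(NEMA_SPHERE_DIAMETERS_MM):
        ang = phase + i * np.pi / 3.0
        cx = c + circle_r * np.cos(ang)
        cy = c + circle_r * np.sin(ang)
        r = 0.5 * diam * scale / vox
        sphere = (x - cx) ** 2 + (y - cy) ** 2 + (z - c) ** 2 <= max(r, 0.6) ** 2
        mask |= sphere
    return mask
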