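"""Stochastic voxelized shape generators and phantom placement.

Three generator families produce connected voxel blobs with a target
volume (in voxels):

``harmonic-sphere``
    A sphere whose radius function is perturbed by random real spherical
    harmonics up to degree 4, amplitudes ~ N(0, (sigma/l)^2).
``superformula``
    A star-convex body whose radius is the spherical product of two
    2D superformula profiles with randomized parameters.
``perlin``
    The largest connected component of thresholded multi-octave
    smoothed noise (fractal value noise).

Volumes are controlled through the order statistic of the voxel
radius-to-profile ratio (radial shapes) or of the noise values (noise
shapes), which selects the global scale enclosing the target count;
connectivity is enforced by keeping the largest 26-connected component
and re-checking the volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation
from scipy.special import sph_harm_y

__all__ = [
    "VoxelShape",
    "ShapeGenerationError",
    "PlacementError",
    "generate_random_shape",
    "place_shapes",
    "random_rotation_matrix",
]

KINDS = ("harmonic-sphere", "superformula", "perlin")

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class ShapeGenerationError(RuntimeError):
    """Raised when no shape in the volume range is found within the
    allotted rejection attempts; the message reports the seed."""


class PlacementError(RuntimeError):
    """Raised when a shape cannot be placed inside the phantom support."""


@dataclass
class VoxelShape:
    """A connected set of lattice voxels in local coordinates."""

    voxels: np.ndarray  # (n, 3) int
    generator_kind: str
    seed: int

    @property
    def volume(self) -> int:
        return len(self.voxels)


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation (via a normalized random quaternion)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def _largest_component(grid: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(grid, structure=_STRUCT26)
    if n <= 1:
        return grid.astype(bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def _dense_to_shape(grid: np.ndarray, kind: str, seed: int) -> VoxelShape:
    return VoxelShape(np.argwhere(grid), kind, seed)


def _radial_ratio(rho, half: int) -> np.ndarray:
    """Lattice of r / rho(direction); a voxel is inside the shape at
    global scale s iff its ratio is <= s."""
    ax = np.arange(-half, half + 1, dtype=float)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(x**2 + y**2 + z**2)
    theta = np.arccos(np.divide(z, r, out=np.zeros_like(r), where=r > 0))
    phi = np.arctan2(y, x)
    prof = rho(theta, phi)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(prof > 1e-6, r / np.where(prof > 1e-6, prof, 1.0),
                         np.inf)
    return ratio


def _radial_shape(rho, target: int, lo_hi: tuple[int, int]):
    """Voxelize the radial shape at the scale that encloses exactly the
    ``target`` smallest r/rho ratios, then enforce connectivity."""
    half = max(int(np.ceil(1.6 * target ** (1.0 / 3.0))) + 2, 4)
    for _ in range(4):
        ratio = _radial_ratio(rho, half)
        k = min(target, ratio.size)
        scale = np.partition(ratio.ravel(), k - 1)[k - 1]
        if not np.isfinite(scale):
            return None
        grid = ratio <= scale
        # expand the lattice if the shape touches its boundary
        edge = (grid[0].any() or grid[-1].any() or grid[:, 0].any()
                or grid[:, -1].any() or grid[:, :, 0].any()
                or grid[:, :, -1].any())
        if not edge:
            grid = _largest_component(grid)
            v = int(grid.sum())
            if lo_hi[0] <= v <= lo_hi[1]:
                return grid
            return None
        half = int(half * 1.5) + 1
    return None


def _harmonic_sphere_rho(rng: np.random.Generator, sigma: float = 0.3,
                         lmax: int = 4):
    coeffs = [(l, m, rng.normal(0.0, sigma / l))
              for l in range(1, lmax + 1) for m in range(-l, l + 1)]

    def rho(theta, phi):
        pert = np.zeros_like(theta)
        for l, m, a in coeffs:
            y = sph_harm_y(l, abs(m), theta, phi)
            if m > 0:
                basis = np.sqrt(2.0) * (-1) ** m * y.real
            elif m < 0:
                basis = np.sqrt(2.0) * (-1) ** m * y.imag
            else:
                basis = y.real
            pert = pert + a * basis
        r = 1.0 + pert
        return np.clip(r, 0.2, None) / max(np.max(r), 1.0)

    return rho


def _superformula_profile(rng: np.random.Generator):
    m = rng.integers(0, 9)
    n1 = rng.uniform(0.5, 4.0)
    n2 = rng.uniform(0.5, 4.0)
    n3 = rng.uniform(0.5, 4.0)

    def r(angle):
        t = np.abs(np.cos(m * angle / 4.0)) ** n2 + \
            np.abs(np.sin(m * angle / 4.0)) ** n3
        return t ** (-1.0 / n1)

    return r


def _superformula_rho(rng: np.random.Generator):
    r1 = _superformula_profile(rng)
    r2 = _superformula_profile(rng)

    def rho(theta, phi):
        # spherical product of the two profiles, as a radial function of
        # azimuth (phi) and latitude (theta measured from the pole)
        val = r1(phi) * r2(theta - np.pi / 2.0)
        val = np.nan_to_num(val, nan=0.0, posinf=0.0)
        top = np.max(val)
        return val / top if top > 0 else val

    return rho


def _perlin_shape(rng: np.random.Generator, target: int,
                  lo_hi: tuple[int, int]):
    side = max(int(np.ceil(3.0 * target ** (1.0 / 3.0))) + 4, 12)
    noise = np.zeros((side, side, side))
    for octave, amp in ((1, 1.0), (2, 0.5), (3, 0.25)):
        white = rng.standard_normal((side, side, side))
        noise += amp * ndimage.gaussian_filter(white, sigma=side / (3.0 * 2**octave))
    flat = np.sort(noise.ravel())[::-1]
    k = target
    for _ in range(30):
        k = min(max(k, lo_hi[0]), noise.size - 1)
        grid = _largest_component(noise >= flat[k - 1])
        v = int(grid.sum())
        if lo_hi[0] <= v <= lo_hi[1]:
            return grid
        k = int(k * 1.3) + 1 if v < lo_hi[0] else int(k * 0.8)
        if k >= noise.size:
            break
    return None


def generate_random_shape(kind: str, seed: int,
                          volume_range: tuple[int, int] = (8, 64),
                          max_attempts: int = 50) -> VoxelShape:
    """Generate one connected voxel shape with volume in ``volume_range``.

    Raises
    ------
    ShapeGenerationError
        If no acceptable shape is found in ``max_attempts`` draws; the
        seed is reported in the message.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown shape kind {kind!r}; choose from {KINDS}")
    lo, hi = volume_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid volume range {volume_range}")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        target = int(rng.integers(lo, hi + 1))
        if kind == "harmonic-sphere":
            grid = _radial_shape(_harmonic_sphere_rho(rng), target, (lo, hi))
        elif kind == "superformula":
            grid = _radial_shape(_superformula_rho(rng), target, (lo, hi))
        else:
            grid = _perlin_shape(rng, target, (lo, hi))
        if grid is not None:
            return _dense_to_shape(grid, kind, seed)
    raise ShapeGenerationError(
        f"no {kind} shape with volume in {volume_range} after "
        f"{max_attempts} attempts (seed={seed})")


def place_shapes(shapes: list[VoxelShape], rng: np.random.Generator,
                 support: np.ndarray, max_attempts: int = 100,
                 ) -> tuple[np.ndarray, list[int]]:
    """Randomly rotate and place shapes inside the phantom support.

    Each shape receives an independent uniform 3D rotation about its
    centroid (voxelized by rounding) and a uniformly random position
    among the support voxels such that every shape voxel stays inside
    the support.  Overlaps between shapes are allowed; the result is the
    union mask.

    Returns the binary mask and the per-shape placed voxel counts.
    """
    mask = np.zeros(support.shape, dtype=bool)
    support_idx = np.argwhere(support)
    if len(support_idx) == 0 and shapes:
        raise PlacementError("empty phantom support")
    placed_counts: list[int] = []
    for shape in shapes:
        coords = shape.voxels.astype(float)
        coords -= coords.mean(axis=0)
        placed = None
        for attempt in range(max_attempts):
            if attempt % 10 == 0:  # fresh rotation every few placements
                rot = coords @ random_rotation_matrix(rng).T
            center = support_idx[rng.integers(len(support_idx))]
            pts = np.unique(np.rint(rot + center).astype(int), axis=0)
            if (pts < 0).any() or (pts >= np.array(support.shape)).any():
                continue
            if support[pts[:, 0], pts[:, 1], pts[:, 2]].all():
                placed = pts
                break
        if placed is None:
            raise PlacementError(
                f"could not place {shape.generator_kind} shape "
                f"(volume {shape.volume}) after {max_attempts} attempts")
        mask[placed[:, 0], placed[:, 1], placed[:, 2]] = True
        placed_counts.append(len(placed))
    return mask, placed_counts
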