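"""Simplified SPECT acquisition model.

The projector is a rotation-based attenuated parallel-beam model with a
distance-dependent Gaussian collimator PSF, sigma(d) = sigma0 + slope*d.
It replaces a full Monte Carlo photon transport: no scatter, septal
penetration or energy-window modelling — but it preserves the
statistical contract of the study design: deterministic noise-free
projections that are scaled to expected counts and corrupted by seeded
Poisson noise.

Geometry: volume axes are (x, y, z) with the cylinder axis along z.
At gantry angle 0 the detector faces the volume from +y; angles increase
counter-clockwise, so projecting at angle a rotates the volume by -a
about z.  Attenuation is computed in the uniform water cylinder
co-located with the phantom support.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import GridSpec, cylinder_support
from .phantoms import ActivityMask

__all__ = [
    "DetectorOrbit",
    "AcquisitionConfig",
    "DESK_ACQUISITION",
    "ProjectionSet",
    "elliptical_orbit",
    "make_orbit",
    "forward_project",
    "back_project",
    "scale_to_counts",
    "add_poisson_noise",
    "NOISE_REALIZATION_SEEDS",
]

#: fixed base seeds distinguishing the named Poisson noise realizations
NOISE_REALIZATION_SEEDS: dict[str, int] = {"A": 11, "B": 23}

#: narrow-beam attenuation coefficient of water at 208 keV, 1/cm
MU_WATER_208KEV_PER_CM = 0.136


@dataclass(frozen=True)
class DetectorOrbit:
    """Per-angle radial distance of the detector face from the rotation
    center (cm), plus the applied radial expansion."""

    angles_deg: np.ndarray
    radius_cm: np.ndarray
    expansion_cm: float = 0.0

    def __post_init__(self):
        angles = np.asarray(self.angles_deg, dtype=float)
        radii = np.asarray(self.radius_cm, dtype=float)
        object.__setattr__(self, "angles_deg", angles)
        object.__setattr__(self, "radius_cm", radii)
        if angles.shape != radii.shape:
            raise ValueError("angles and radii must align")
        if (radii <= 0).any():
            raise ValueError("orbit radii must be strictly positive")
        if (np.diff(angles) <= 0).any() or angles[0] < 0 or angles[-1] >= 360:
            raise ValueError("angles must be strictly increasing in [0, 360)")

    def __len__(self) -> int:
        return len(self.angles_deg)


def elliptical_orbit(n_angles: int, a_cm: float, b_cm: float,
                     expansion_cm: float = 0.0) -> DetectorOrbit:
    """Synthetic non-circular base orbit: radius of an ellipse with
    semi-axes ``a_cm`` (at 0 deg) and ``b_cm`` (at 90 deg)."""
    angles = np.arange(n_angles) * (360.0 / n_angles)
    t = np.deg2rad(angles)
    r = a_cm * b_cm / np.sqrt((b_cm * np.cos(t)) ** 2 + (a_cm * np.sin(t)) ** 2)
    return make_orbit(DetectorOrbit(angles, r), expansion_cm)


def make_orbit(base: DetectorOrbit, expansion_cm: float,
               phantom_radius_cm: float = 0.0) -> DetectorOrbit:
    """Radially expand a base orbit by a constant offset (cm)."""
    radii = base.radius_cm + expansion_cm
    if (radii <= phantom_radius_cm).any():
        raise ValueError(
            f"expansion {expansion_cm} cm puts the detector at or inside "
            f"the phantom radius {phantom_radius_cm} cm")
    return DetectorOrbit(base.angles_deg.copy(), radii,
                         expansion_cm=base.expansion_cm + expansion_cm)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition parameters (defaults: the full-scale protocol)."""

    n_projections: int = 120
    time_per_view_s: float = 22.0
    matrix: int = 128
    mu_per_cm: float = MU_WATER_208KEV_PER_CM
    psf_sigma0_mm: float = 2.0
    psf_slope: float = 0.03  # mm of sigma per mm of source-detector distance
    sensitivity_cps_per_mbq: float = 10.0

    def __post_init__(self):
        if 360 % self.n_projections != 0:
            raise ValueError("projection count must divide 360 evenly")
        for name in ("time_per_view_s", "matrix"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DESK_ACQUISITION = AcquisitionConfig(n_projections=60, matrix=32)


@dataclass
class ProjectionSet:
    """Angle-indexed stack of 2D detector images.

    ``images`` has shape (n_angles, nu, nv) where u is the transaxial
    and v the axial detector coordinate.  ``units`` is ``relative`` for
    raw projector output and ``counts`` after scaling.
    """

    images: np.ndarray
    angles_deg: np.ndarray
    pixel_size_mm: float
    orbit: DetectorOrbit
    kind: str  # noise-free | noisy | synthetic
    units: str = "relative"
    realization: str | None = None
    seed: int | None = None
    time_per_view_s: float | None = None
    dataset_id: str = ""

    def subset(self, indices: np.ndarray) -> "ProjectionSet":
        """Angular subset (e.g. every other projection)."""
        indices = np.asarray(indices)
        sub_orbit = DetectorOrbit(self.orbit.angles_deg[indices],
                                  self.orbit.radius_cm[indices],
                                  self.orbit.expansion_cm)
        return ProjectionSet(self.images[indices], self.angles_deg[indices],
                             self.pixel_size_mm, sub_orbit, self.kind,
                             self.units, self.realization, self.seed,
                             self.time_per_view_s, self.dataset_id)


#: cached bilinear rotation tables keyed by (lattice size, angle)
_ROTATION_TABLES: dict[tuple[int, float], tuple] = {}


def _rotation_table(n: int, angle_deg: float):
    """Bilinear in-plane rotation as explicit scatter/gather tables.

    For every (x, y) lattice site the rotated position R(p - c) + c is
    split over its four neighbours.  Splatting with these weights is
    exactly count-conserving for voxels that stay in bounds (the water
    cylinder maps onto itself), and gathering with the same tables is
    the exact transpose — a matched projector/backprojector pair.
    """
    key = (n, round(float(angle_deg) % 360.0, 9))
    tab = _ROTATION_TABLES.get(key)
    if tab is not None:
        return tab
    c = (n - 1) / 2.0
    t = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(t), np.sin(t)
    xs, ys = np.meshgrid(np.arange(n, dtype=np.float64),
                         np.arange(n, dtype=np.float64), indexing="ij")
    xr = cos_t * (xs - c) - sin_t * (ys - c) + c
    yr = sin_t * (xs - c) + cos_t * (ys - c) + c
    x0 = np.floor(xr).astype(np.int64)
    y0 = np.floor(yr).astype(np.int64)
    fx = (xr - x0).astype(np.float32)
    fy = (yr - y0).astype(np.float32)
    idx = []
    wts = []
    for dx, wx in ((0, 1.0 - fx), (1, fx)):
        for dy, wy in ((0, 1.0 - fy), (1, fy)):
            xi = x0 + dx
            yi = y0 + dy
            inside = (xi >= 0) & (xi < n) & (yi >= 0) & (yi < n)
            w = (wx * wy) * inside
            xi = np.clip(xi, 0, n - 1)
            yi = np.clip(yi, 0, n - 1)
            idx.append((xi * n + yi).ravel())
            wts.append(w.ravel().astype(np.float32))
    tab = (tuple(idx), tuple(wts))
    _ROTATION_TABLES[key] = tab
    return tab


def _rotate_splat(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a volume about the z axis, distributing (splatting) each
    voxel bilinearly; exactly conserves in-bounds activity."""
    n = vol.shape[0]
    if angle_deg % 360.0 == 0.0:
        return vol.copy()
    idx, wts = _rotation_table(n, angle_deg)
    flat = vol.reshape(n * n, -1)
    out = np.zeros_like(flat)
    for i, w in zip(idx, wts):
        np.add.at(out, i, flat * w[:, None])
    return out.reshape(vol.shape)


def _rotate_gather(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    """Exact transpose of :func:`_rotate_splat` (bilinear sampling)."""
    n = vol.shape[0]
    if angle_deg % 360.0 == 0.0:
        return vol.copy()
    idx, wts = _rotation_table(n, angle_deg)
    flat = vol.reshape(n * n, -1)
    out = np.zeros_like(flat)
    for i, w in zip(idx, wts):
        out += flat[i] * w[:, None]
    return out.reshape(vol.shape)


def _attenuation_map(grid: GridSpec, mu_per_cm: float) -> np.ndarray:
    """exp(-mu * water path length) from each voxel to the +y detector."""
    support = cylinder_support(grid)
    voxel_cm = grid.voxel_size_mm / 10.0
    # cumulative water thickness towards +y, half-voxel self contribution
    water = support.astype(np.float32)
    thickness = (np.cumsum(water[:, ::-1, :], axis=1)[:, ::-1, :]
                 - 0.5 * water) * voxel_cm
    return np.exp(-mu_per_cm * thickness).astype(np.float32)


def _psf_sigma_px(config: AcquisitionConfig, radius_cm: float,
                  grid: GridSpec) -> np.ndarray:
    """Blur sigma (in voxels) for each y slab at one gantry angle."""
    c = grid.center
    y = np.arange(grid.n)
    dist_mm = radius_cm * 10.0 - (y - c) * grid.voxel_size_mm
    sigma_mm = config.psf_sigma0_mm + config.psf_slope * np.clip(dist_mm, 0, None)
    return sigma_mm / grid.voxel_size_mm


def forward_project(activity, orbit: DetectorOrbit, config: AcquisitionConfig,
                    grid: GridSpec, att: np.ndarray | None = None,
                    dtype=np.float32) -> ProjectionSet:
    """Noise-free projections of an activity volume along an orbit.

    ``activity`` is an :class:`ActivityMask` or a raw non-negative array
    on the same lattice; the output images are in the same (relative)
    units, ray-summed voxel values after attenuation and blur.
    """
    if isinstance(activity, ActivityMask):
        vol = activity.grid.astype(dtype)
        dataset_id = activity.dataset_id
    else:
        vol = np.asarray(activity, dtype=dtype)
        dataset_id = ""
    if vol.shape != (grid.n,) * 3:
        raise ValueError("activity volume does not match the grid")
    if att is None:
        att = _attenuation_map(grid, config.mu_per_cm)
    att = att.astype(dtype, copy=False)
    bin_f = grid.n // config.matrix
    if bin_f * config.matrix != grid.n:
        raise ValueError("matrix must divide the lattice size")
    images = np.empty((len(orbit), config.matrix, config.matrix),
                      dtype=dtype)
    for i, (ang, radius) in enumerate(zip(orbit.angles_deg, orbit.radius_cm)):
        weighted = _rotate_splat(vol, -ang) * att
        sigmas = _psf_sigma_px(config, radius, grid)
        proj = np.zeros((grid.n, grid.n), dtype=dtype)
        for iy in range(grid.n):
            slab = weighted[:, iy, :]
            if sigmas[iy] > 1e-6:
                proj += ndimage.gaussian_filter(slab, sigmas[iy])
            else:
                proj += slab
        if bin_f > 1:
            proj = proj.reshape(config.matrix, bin_f, config.matrix,
                                bin_f).sum(axis=(1, 3))
        images[i] = np.clip(proj, 0.0, None)
    return ProjectionSet(images, orbit.angles_deg.copy(),
                         pixel_size_mm=grid.voxel_size_mm * bin_f,
                         orbit=orbit, kind="noise-free", units="relative",
                         time_per_view_s=config.time_per_view_s,
                         dataset_id=dataset_id)


def back_project(images: np.ndarray, orbit: DetectorOrbit,
                 config: AcquisitionConfig, grid: GridSpec,
                 att: np.ndarray | None = None) -> np.ndarray:
    """Adjoint of :func:`forward_project` (matched pair for OS-EM)."""
    if att is None:
        att = _attenuation_map(grid, config.mu_per_cm)
    bin_f = grid.n // config.matrix
    vol = np.zeros((grid.n,) * 3, dtype=np.float32)
    for img, ang, radius in zip(images, orbit.angles_deg, orbit.radius_cm):
        img = np.asarray(img, dtype=np.float32)
        if bin_f > 1:
            img = np.repeat(np.repeat(img, bin_f, axis=0), bin_f, axis=1)
        sigmas = _psf_sigma_px(config, radius, grid)
        spread = np.empty((grid.n,) * 3, dtype=np.float32)
        for iy in range(grid.n):
            if sigmas[iy] > 1e-6:
                spread[:, iy, :] = ndimage.gaussian_filter(img, sigmas[iy])
            else:
                spread[:, iy, :] = img
        spread *= att
        vol += _rotate_gather(spread, -ang)
    return vol


def scale_to_counts(ps: ProjectionSet, max_conc_mbq_ml: float,
                    config: AcquisitionConfig, grid: GridSpec
                    ) -> ProjectionSet:
    """Scale relative noise-free projections to expected counts.

    The activity volume's value 100 corresponds to ``max_conc_mbq_ml``;
    expected counts per pixel are activity (MBq) x system sensitivity
    (cps/MBq) x time per view (s).
    """
    if max_conc_mbq_ml <= 0:
        raise ValueError("maximum activity concentration must be positive")
    if ps.units != "relative":
        raise ValueError("input must be unscaled relative projections")
    factor = (max_conc_mbq_ml / 100.0) * grid.voxel_volume_ml \
        * config.sensitivity_cps_per_mbq * config.time_per_view_s
    return replace(ps, images=ps.images * np.float32(factor), units="counts")


def add_poisson_noise(ps: ProjectionSet, realization: str,
                      seed: int) -> ProjectionSet:
    """Independent Poisson draw per pixel; bit-identical under the same
    (realization label, seed)."""
    if (ps.images < 0).any():
        raise ValueError("expected counts must be non-negative")
    try:
        base = NOISE_REALIZATION_SEEDS[realization]
    except KeyError:
        raise ValueError(f"unknown noise realization {realization!r}")
    rng = np.random.default_rng(np.random.SeedSequence([base, int(seed)]))
    noisy = rng.poisson(ps.images.astype(np.float64)).astype(np.float32)
    return replace(ps, images=noisy, kind="noisy", realization=realization,
                   seed=int(seed))
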