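"""Acquisition simulator: orbits, attenuated projection, counts, noise."""

import numpy as np
import pytest

from spectsynth.geometry import cylinder_support, get_preset
from spectsynth.projector import (AcquisitionConfig, DetectorOrbit,
                                  add_poisson_noise, elliptical_orbit,
                                  forward_project, make_orbit,
                                  scale_to_counts)

DELTA = dict(psf_sigma0_mm=0.0, psf_slope=0.0)


@pytest.fixture(scope="module")
def orbit():
    return elliptical_orbit(60, 8.0, 12.0)


@pytest.fixture(scope="module")
def grid():
    return get_preset("desk")


def test_orbit_validation():
    with pytest.raises(ValueError, match="positive"):
        DetectorOrbit(np.array([0.0, 180.0]), np.array([10.0, -1.0]))
    with pytest.raises(ValueError, match="increasing"):
        DetectorOrbit(np.array([10.0, 5.0]), np.array([10.0, 10.0]))


def test_make_orbit_expansion(orbit):
    same = make_orbit(orbit, 0.0)
    assert np.array_equal(same.radius_cm, orbit.radius_cm)
    plus4 = make_orbit(orbit, 4.0)
    assert np.allclose(plus4.radius_cm - orbit.radius_cm, 4.0)
    assert plus4.expansion_cm == 4.0
    with pytest.raises(ValueError, match="detector"):
        make_orbit(orbit, -float(orbit.radius_cm.min()))


def test_zero_activity_projects_to_zero(orbit, grid):
    cfg = AcquisitionConfig(n_projections=60, matrix=32)
    ps = forward_project(np.zeros((32,) * 3), orbit, cfg, grid)
    assert not ps.images.any()


def test_point_source_total_counts_angle_independent(orbit):
    """mu = 0 and a delta PSF conserve counts at every angle.

    An odd lattice puts the unit voxel exactly at the rotation center,
    where trilinear rotation is exact."""
    from spectsynth.geometry import GridSpec
    tiny = GridSpec(name="tiny", n=31, voxel_size_mm=4.8)
    cfg = AcquisitionConfig(n_projections=60, matrix=31, mu_per_cm=0.0,
                            **DELTA)
    vol = np.zeros((31,) * 3)
    vol[15, 15, 15] = 1.0
    sums = forward_project(vol, orbit, cfg, tiny).images.sum(axis=(1, 2))
    assert np.allclose(sums, sums[0], rtol=0.01)


def test_count_conservation_for_any_distribution(orbit, grid, rng):
    cfg = AcquisitionConfig(n_projections=60, matrix=32, mu_per_cm=0.0,
                            **DELTA)
    vol = rng.random((32,) * 3) * cylinder_support(grid)
    sums = forward_project(vol, orbit, cfg, grid).images.sum(axis=(1, 2))
    assert sums.max() / sums.min() < 1.01


def test_central_ray_matches_attenuated_integral(orbit, grid):
    """Uniform cylinder, delta PSF: the central ray value equals the 1D
    closed form a*(1 - exp(-mu L)) / mu for chord length L."""
    cfg = AcquisitionConfig(n_projections=60, matrix=32, **DELTA)
    support = cylinder_support(grid)
    ps = forward_project(support.astype(float), orbit, cfg, grid)
    vox_cm = grid.voxel_size_mm / 10.0
    xi, zi = 16, 16
    chord_cm = support[xi, :, zi].sum() * vox_cm
    closed_form = (1 - np.exp(-cfg.mu_per_cm * chord_cm)) \
        / (cfg.mu_per_cm * vox_cm)
    assert ps.images[0, xi, zi] == pytest.approx(closed_form, rel=0.02)


def test_projection_linearity(orbit, grid, rng):
    cfg = AcquisitionConfig(n_projections=60, matrix=32)
    sub = orbit.angles_deg[:5]
    small = DetectorOrbit(sub, orbit.radius_cm[:5])
    a = rng.random((32,) * 3)
    b = rng.random((32,) * 3)
    fa = forward_project(a, small, cfg, grid, dtype=np.float64).images
    fb = forward_project(b, small, cfg, grid, dtype=np.float64).images
    fab = forward_project(a + b, small, cfg, grid, dtype=np.float64).images
    assert np.allclose(fab, fa + fb, rtol=1e-8, atol=1e-8)


def test_blur_grows_with_distance_lowering_point_peak(orbit, grid):
    cfg = AcquisitionConfig(n_projections=60, matrix=32, mu_per_cm=0.0)
    vol = np.zeros((32,) * 3)
    vol[15, 15, 15] = 1.0
    near = forward_project(vol, orbit, cfg, grid).images
    far = forward_project(vol, make_orbit(orbit, 8.0), cfg, grid).images
    assert (far.max(axis=(1, 2)) < near.max(axis=(1, 2))).all()


def test_scale_to_counts_linearity_and_arithmetic(orbit, grid):
    cfg = AcquisitionConfig(n_projections=60, matrix=32, mu_per_cm=0.0,
                            **DELTA)
    vol = np.zeros((32,) * 3)
    vol[16, 16, 16] = 100.0  # one voxel at the maximum concentration
    ps = forward_project(vol, orbit, cfg, grid)
    counts = scale_to_counts(ps, 0.2, cfg, grid)
    # 0.2 MBq/mL * voxel volume * sensitivity * time, per projection
    expected = 0.2 * grid.voxel_volume_ml * 10.0 * 22.0
    assert counts.images[0].sum() == pytest.approx(expected, rel=1e-3)
    double_conc = scale_to_counts(ps, 0.4, cfg, grid)
    assert np.allclose(double_conc.images, 2 * counts.images, rtol=1e-6)
    cfg2 = AcquisitionConfig(n_projections=60, matrix=32, mu_per_cm=0.0,
                             time_per_view_s=44.0, **DELTA)
    double_time = scale_to_counts(ps, 0.2, cfg2, grid)
    assert np.allclose(double_time.images, 2 * counts.images, rtol=1e-6)
    with pytest.raises(ValueError):
        scale_to_counts(ps, -1.0, cfg, grid)


def test_poisson_noise_contract(orbit, grid):
    cfg = AcquisitionConfig(n_projections=60, matrix=32)
    zeros = forward_project(np.zeros((32,) * 3), orbit, cfg, grid)
    zeros = scale_to_counts(zeros, 1.0, cfg, grid)
    assert not add_poisson_noise(zeros, "A", 1).images.any()

    vol = cylinder_support(grid).astype(float) * 50
    ps = scale_to_counts(forward_project(vol, orbit, cfg, grid), 2.0, cfg,
                         grid)
    n1 = add_poisson_noise(ps, "A", 7)
    n2 = add_poisson_noise(ps, "A", 7)
    nb = add_poisson_noise(ps, "B", 7)
    assert np.array_equal(n1.images, n2.images)
    assert not np.array_equal(n1.images, nb.images)
    assert n1.kind == "noisy" and n1.realization == "A"
    assert np.array_equal(n1.images, np.rint(n1.images))  # integer counts

    with pytest.raises(ValueError, match="realization"):
        add_poisson_noise(ps, "C", 0)


def test_poisson_moments():
    """Mean of 10,000 draws at expectation 22 is within 4 SE."""
    from spectsynth.projector import ProjectionSet
    orbit1 = DetectorOrbit(np.array([0.0]), np.array([10.0]))
    ps = ProjectionSet(np.full((1, 100, 100), 22.0), np.array([0.0]), 4.8,
                       orbit1, "noise-free", "counts")
    noisy = add_poisson_noise(ps, "A", 3)
    se = np.sqrt(22.0 / 10000)
    assert abs(noisy.images.mean() - 22.0) < 4 * se
    assert noisy.images.var() == pytest.approx(22.0, rel=0.1)


def test_config_validation():
    with pytest.raises(ValueError, match="divide"):
        AcquisitionConfig(n_projections=50)
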