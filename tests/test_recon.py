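"""OS-EM reconstruction, calibration, SNR and recovery."""

import numpy as np
import pytest
from scipy import ndimage

from spectsynth.geometry import GridSpec, cylinder_support, get_preset
from spectsynth.projector import (AcquisitionConfig, add_poisson_noise,
                                  elliptical_orbit, forward_project,
                                  scale_to_counts)
from spectsynth.recon import (VOISpec, calibrate, osem_reconstruct,
                              poisson_loglik, recovery, snr,
                              to_concentration)


@pytest.fixture(scope="module")
def grid():
    return get_preset("desk")


@pytest.fixture(scope="module")
def orbit():
    return elliptical_orbit(60, 8.0, 12.0)


@pytest.fixture(scope="module")
def acq():
    return AcquisitionConfig(n_projections=60, matrix=32)


def test_point_source_localization(orbit):
    tiny = GridSpec(name="tiny", n=31, voxel_size_mm=4.8)
    cfg = AcquisitionConfig(n_projections=60, matrix=31, mu_per_cm=0.0)
    vol = np.zeros((31,) * 3, np.float32)
    vol[20, 13, 17] = 1.0
    ps = forward_project(vol, orbit, cfg, tiny)
    rec = osem_reconstruct(ps, cfg, tiny, iterations=4, subsets=6)
    assert np.unravel_index(rec.values.argmax(), rec.values.shape) == \
        (20, 13, 17)
    assert rec.values.min() >= 0.0


def test_em_fixed_point(grid, orbit, acq):
    """Consistent noise-free data with the true volume as the initial
    estimate leaves OS-EM unchanged."""
    support = cylinder_support(grid)
    true = (support * 3.0).astype(np.float32)
    ps = forward_project(true, orbit, acq, grid)
    rec = osem_reconstruct(ps, acq, grid, iterations=1, subsets=6,
                           initial=true)
    inside = support & (true > 0)
    assert np.allclose(rec.values[inside], true[inside], rtol=1e-6)


def test_subset_count_must_divide(grid, orbit, acq):
    ps = forward_project(np.zeros((32,) * 3), orbit, acq, grid)
    with pytest.raises(ValueError, match="subsets"):
        osem_reconstruct(ps, acq, grid, iterations=1, subsets=7)


def test_loglikelihood_nondecreasing_on_noisefree_data(grid, orbit, acq):
    support = cylinder_support(grid)
    vol = np.zeros((32,) * 3, np.float32)
    vol[10:14, 14:18, 14:18] = 1.0
    vol *= support
    ps = forward_project(vol, orbit, acq, grid)
    lls = []
    for its in (1, 2, 4):
        rec = osem_reconstruct(ps, acq, grid, iterations=its, subsets=6)
        reproj = forward_project(rec.values, orbit, acq, grid).images
        lls.append(poisson_loglik(ps.images, reproj))
    assert lls[0] <= lls[1] + 1e-6 <= lls[2] + 2e-6


@pytest.fixture(scope="module")
def uniform_recon(grid, orbit, acq):
    support = cylinder_support(grid)
    conc = 2.0  # MBq/mL
    vol = (support * 100).astype(np.int16)
    from spectsynth.phantoms import ActivityMask
    mask = ActivityMask(vol, grid.voxel_size_mm, "inverted", conc,
                        dataset_id="uniform")
    ps = scale_to_counts(forward_project(mask, orbit, acq, grid), conc, acq,
                         grid)
    noisy = add_poisson_noise(ps, "A", 17)
    # 12 iterations: enough for the slow central convergence of EM on an
    # attenuated uniform cylinder, before noise amplification dominates
    rec = osem_reconstruct(noisy, acq, grid, iterations=12, subsets=6)
    total_activity = conc * support.sum() * grid.voxel_volume_ml
    return rec, total_activity, conc, support


def test_calibration_round_trip(uniform_recon, grid, acq):
    rec, total_activity, conc, support = uniform_recon
    factor = calibrate(rec, total_activity, acq.time_per_view_s)
    conc_map = to_concentration(rec, factor, acq.time_per_view_s)
    c = grid.center
    voi = VOISpec("cube", (c, c, c), 0.5 * grid.cylinder_diameter_mm)
    mean_conc = conc_map[voi.mask(conc_map.shape, grid.voxel_size_mm)].mean()
    assert mean_conc == pytest.approx(conc, rel=0.05)
    # doubling the assumed true activity halves the concentration per count
    factor2 = calibrate(rec, 2 * total_activity, acq.time_per_view_s)
    assert factor2 == pytest.approx(factor / 2)


def test_calibration_voi_independence(uniform_recon, grid, acq):
    rec, total_activity, conc, _ = uniform_recon
    factor = calibrate(rec, total_activity, acq.time_per_view_s)
    conc_map = to_concentration(rec, factor, acq.time_per_view_s)
    c = grid.center
    small = VOISpec("cube", (c, c, c), 0.25 * grid.cylinder_diameter_mm)
    big = VOISpec("cube", (c, c, c), 0.5 * grid.cylinder_diameter_mm)
    ball = VOISpec("sphere", (c, c, c), 0.5 * grid.cylinder_diameter_mm)
    means = [conc_map[v.mask(conc_map.shape, grid.voxel_size_mm)].mean()
             for v in (small, big, ball)]
    assert max(means) / min(means) < 1.05


def test_snr_arithmetic_and_shift():
    vol = np.zeros((20, 20, 20))
    rng = np.random.default_rng(0)
    voi = VOISpec("cube", (10, 10, 10), 8 * 10.0)
    mask = voi.mask(vol.shape, 10.0)
    vals = rng.normal(100.0, 10.0, mask.sum())
    vol[mask] = vals
    expected = vals.mean() / vals.std()
    assert snr(vol, voi, 10.0) == pytest.approx(expected)
    assert snr(vol + 50.0 * mask, voi, 10.0) == pytest.approx(
        (vals.mean() + 50) / vals.std())
    flat = np.ones((20, 20, 20))
    assert snr(flat, voi, 10.0) == np.inf


def test_snr_poisson_moment_oracle():
    rng = np.random.default_rng(1)
    lam = 100.0
    vol = rng.poisson(lam, (22, 22, 22)).astype(float)
    voi = VOISpec("cube", (10.5, 10.5, 10.5), 21 * 10.0)
    assert voi.mask(vol.shape, 10.0).sum() >= 10**4
    assert snr(vol, voi, 10.0) == pytest.approx(np.sqrt(lam), rel=0.1)


def test_recovery_perfect_and_linear():
    conc = np.zeros((16, 16, 16))
    sphere = VOISpec("sphere", (8, 8, 8), 60.0).mask(conc.shape, 10.0)
    conc[sphere] = 5.0  # MBq/mL
    voxel_ml = 1.0
    true_act = 5.0 * sphere.sum() * voxel_ml
    rec = recovery(conc, [sphere], [true_act], voxel_ml)
    assert rec[0] == pytest.approx(1.0)
    rec_half = recovery(0.5 * conc, [sphere], [true_act], voxel_ml)
    assert rec_half[0] == pytest.approx(0.5)
    with pytest.raises(ValueError, match="empty"):
        recovery(conc, [np.zeros_like(sphere)], [1.0], voxel_ml)


def test_recovery_partial_volume_monotonic_in_diameter():
    """After blurring, smaller spheres lose a larger fraction of their
    activity to the surroundings (partial-volume effect)."""
    vol = np.zeros((40, 40, 40))
    centers = [(8, 8, 20), (8, 28, 20), (28, 8, 20), (28, 28, 20)]
    diams = [2.0, 4.0, 6.0, 8.0]  # voxels (voxel size 1 mm here)
    masks = []
    for ctr, d in zip(centers, diams):
        m = VOISpec("sphere", ctr, d).mask(vol.shape, 1.0)
        vol[m] = 1.0
        masks.append(m)
    blurred = ndimage.gaussian_filter(vol, sigma=1.2)
    true_acts = [m.sum() * 1e-3 for m in masks]
    recs = recovery(blurred, masks, true_acts, 1e-3)
    assert all(a <= b + 1e-9 for a, b in zip(recs, recs[1:]))
    assert recs[-1] < 1.0
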