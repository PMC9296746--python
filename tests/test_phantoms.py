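"""Shape generators, placement, pattern masks and manifests."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from spectsynth.geometry import get_preset
from spectsynth.manifest import (TABLE_COMPOSITION, build_manifest,
                                 scale_composition)
from spectsynth.patterns import generate_pattern_mask
from spectsynth.phantoms import build_activity_mask
from spectsynth.shapes import (KINDS, ShapeGenerationError,
                               generate_random_shape, place_shapes)

STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@pytest.mark.parametrize("kind", KINDS)
@pytest.mark.parametrize("seed", [0, 7, 99])
def test_random_shape_volume_connectivity_determinism(kind, seed):
    shape = generate_random_shape(kind, seed, volume_range=(8, 64))
    assert 8 <= shape.volume <= 64
    # single 26-connected component
    box = np.zeros(shape.voxels.max(axis=0) + 1, dtype=bool)
    box[tuple(shape.voxels.T)] = True
    assert ndimage.label(box, STRUCT26)[1] == 1
    again = generate_random_shape(kind, seed, volume_range=(8, 64))
    assert np.array_equal(shape.voxels, again.voxels)


def test_unperturbed_harmonic_sphere_is_a_ball(monkeypatch):
    """With all perturbation amplitudes zero the radius function is
    constant, so the voxelization is a digital ball of the target volume."""
    import spectsynth.shapes as sh

    original = sh._harmonic_sphere_rho

    def zero_rho(rng, sigma=0.0, lmax=4):
        return original(rng, sigma=0.0, lmax=lmax)

    monkeypatch.setattr(sh, "_harmonic_sphere_rho", zero_rho)
    shape = sh.generate_random_shape("harmonic-sphere", 3, (33, 33))
    assert shape.volume == 33
    center = shape.voxels.mean(axis=0)
    r = np.linalg.norm(shape.voxels - center, axis=1)
    # every included voxel is at most as far out as the nearest excluded one
    assert r.max() <= np.cbrt(3 * 40 / (4 * np.pi)) + 1.0


def test_shape_invalid_inputs():
    with pytest.raises(ValueError):
        generate_random_shape("banana", 0, (8, 64))
    with pytest.raises(ValueError):
        generate_random_shape("perlin", 0, (10, 5))
    with pytest.raises(ShapeGenerationError, match="seed"):
        # an impossible narrow huge target at tiny attempt budget
        generate_random_shape("perlin", 12345, (5000, 5001), max_attempts=1)


def test_place_shapes_empty_and_support(desk_grid, desk_support, rng):
    empty, counts = place_shapes([], rng, desk_support)
    assert not empty.any() and counts == []


@pytest.mark.parametrize("seed", range(6))
def test_masks_stay_inside_cylinder(desk_grid, desk_support, seed):
    mani = build_manifest({"random": 1}, seed=seed)
    mask = build_activity_mask(next(mani.itertuples()), desk_grid,
                               desk_support)
    assert not (mask.grid[~desk_support] != 0).any()
    assert mask.grid.min() >= 0 and mask.grid.max() <= 100
    assert 10 <= len(mask.shape_voxel_counts) <= 25
    assert max(mask.shape_voxel_counts) <= 64


def test_inverted_mask_is_complement(desk_grid, desk_support):
    rng = np.random.default_rng(5)
    from spectsynth.patterns import generate_random_shapes_mask
    rng2 = np.random.default_rng(5)
    inverted = generate_pattern_mask("inverted", rng, desk_grid, desk_support)
    shapes, _ = generate_random_shapes_mask(rng2, desk_grid, desk_support)
    assert np.array_equal(inverted, desk_support & ~shapes)


def test_nema_pattern_has_six_disjoint_spheres():
    grid = get_preset("full")
    mask = generate_pattern_mask("nema", 5, grid)
    assert ndimage.label(mask, STRUCT26)[1] == 6


def test_stripe_pattern_has_seven_slabs():
    grid = get_preset("full")
    mask = generate_pattern_mask("stripe", 11, grid)
    assert ndimage.label(mask, STRUCT26)[1] == 7


@pytest.mark.parametrize("category", ["chessboard", "rod", "cross"])
def test_other_patterns_nonempty_inside_support(category, desk_grid,
                                                desk_support):
    mask = generate_pattern_mask(category, 3, desk_grid, desk_support)
    assert mask.any()
    assert not mask[~desk_support].any()


def test_unknown_pattern_category(desk_grid):
    with pytest.raises(ValueError, match="category"):
        generate_pattern_mask("spiral", 0, desk_grid)


# ---------------------------------------------------------------- manifest

def test_composition_scaling_keeps_proportions():
    assert scale_composition(10000) == TABLE_COMPOSITION
    desk = scale_composition(100)
    assert desk["random"] == 75 and desk["inverted"] == 20
    assert all(desk[c] == 1 for c in
               ("chessboard", "rod", "cross", "stripe", "nema"))
    assert sum(desk.values()) == 100


def test_manifest_counts_splits_and_determinism():
    mani = build_manifest(scale_composition(100), seed=3,
                          split_fractions=(0.7, 0.1, 0.2))
    assert len(mani) == 100
    assert mani.category.value_counts()["random"] == 75
    assert set(mani.split) == {"train", "val", "test"}
    # per-category stratified rounding: 75 random -> 53/7/15
    random_splits = mani[mani.category == "random"].split.value_counts()
    assert random_splits["train"] == 53
    assert random_splits["val"] == 7 and random_splits["test"] == 15
    assert 68 <= mani.split.value_counts()["train"] <= 73
    again = build_manifest(scale_composition(100), seed=3,
                           split_fractions=(0.7, 0.1, 0.2))
    pd.testing.assert_frame_equal(mani, again)
    assert mani.id.is_unique


def test_manifest_concentrations_in_range():
    mani = build_manifest({"random": 500}, seed=11)
    assert (mani.max_conc_mbq_ml >= 0.2).all()
    assert (mani.max_conc_mbq_ml <= 14.0).all()
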