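"""Cyclic expansion, normalization, synthesis and assembly plumbing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectsynth.nn import UNetConfig, step_schedule, train
from spectsynth.projector import DetectorOrbit, ProjectionSet
from spectsynth.stacks import (assemble_interleaved, cyclic_crop,
                               cyclic_expand, generate_synthetic,
                               normalize_stack)


def _labels(n):
    """1-based labels as single-pixel images for order bookkeeping."""
    return np.arange(1, n + 1, dtype=float).reshape(n, 1, 1)


def test_cyclic_expand_60_to_64_wrap_order():
    out = cyclic_expand(_labels(60), 64).ravel().astype(int).tolist()
    assert out == [59, 60] + list(range(1, 61)) + [1, 2]


def test_cyclic_expand_30_to_32():
    out = cyclic_expand(_labels(30), 32).ravel().astype(int).tolist()
    assert out == [30] + list(range(1, 31)) + [1]


def test_cyclic_expand_identity_and_errors():
    x = _labels(10)
    assert np.array_equal(cyclic_expand(x, 10), x)
    with pytest.raises(ValueError):
        cyclic_expand(x, 8)


@pytest.mark.parametrize("n,target", [(60, 64), (30, 32), (120, 128),
                                      (10, 16), (7, 8)])
def test_cyclic_expand_then_crop_is_identity(n, target):
    x = _labels(n)
    assert np.array_equal(cyclic_crop(cyclic_expand(x, target), n), x)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.integers(2, 128), st.integers(0, 64))
def test_cyclic_expand_crop_identity_property(n, pad):
    """Expansion followed by the center crop recovers the original stack
    for every length/target pair, and padded entries are wrapped copies."""
    target = n + pad
    x = _labels(n)
    expanded = cyclic_expand(x, target)
    assert len(expanded) == target
    assert np.array_equal(cyclic_crop(expanded, n), x)
    front = pad // 2
    assert np.array_equal(expanded,
                          x[(np.arange(target) - front) % n])


def test_normalize_stack_round_trip(rng):
    x = rng.random((5, 4, 4)) * 40.0
    normed, factor = normalize_stack(x)
    assert normed.max() == pytest.approx(1.0)
    assert factor == pytest.approx(x.max())
    assert np.allclose(normed * factor, x, rtol=1e-12)
    with pytest.raises(ValueError, match="all-zero"):
        normalize_stack(np.zeros((3, 2, 2)), dataset_id="m007")


def _projection_set(images, angles, radii=None):
    angles = np.asarray(angles, dtype=float)
    radii = np.full(len(angles), 10.0) if radii is None else radii
    orbit = DetectorOrbit(angles, radii)
    return ProjectionSet(np.asarray(images, dtype=np.float32),
                         angles.copy(), 4.8, orbit, "noisy", "counts",
                         "A", 1, 22.0, "mtest")


@pytest.fixture(scope="module")
def tiny_model():
    """A quickly trained 16-angle shift-by-theta model for contracts."""
    rng = np.random.default_rng(2)
    x = rng.random((2, 16, 16, 16)).astype(np.float32)
    cfg = UNetConfig(label="T", n_input=16, n_output=16, cyclic_target=16,
                     rotation_shift_deg=11.25, n_train=2, n_val=1, epochs=2,
                     batch_size=2, base_channels=2, depth=2,
                     lr_schedule=step_schedule(1e-3, 10))
    return train(cfg, x, x, x[:1], x[:1], seed=0)


def test_generate_synthetic_angle_shift(tiny_model, rng):
    angles = np.arange(16) * 22.5
    ps = _projection_set(rng.random((16, 16, 16)), angles)
    synth = generate_synthetic(tiny_model, ps)
    assert synth.kind == "synthetic"
    assert np.allclose(synth.angles_deg, angles + 11.25)
    assert len(synth.images) == 16
    assert synth.images.min() >= 0


def test_generate_synthetic_zero_shift_keeps_angles(tiny_model, rng):
    import dataclasses
    model = tiny_model
    model0 = type(model)(model.weights,
                         dataclasses.replace(model.config,
                                             rotation_shift_deg=0.0),
                         model.best_val_loss, model.best_epoch, model.history)
    angles = np.arange(16) * 22.5
    ps = _projection_set(rng.random((16, 16, 16)), angles)
    synth = generate_synthetic(model0, ps)
    assert np.allclose(synth.angles_deg, angles)


def test_generate_synthetic_rejects_bad_input(tiny_model, rng):
    angles = np.arange(8) * 45.0
    ps = _projection_set(rng.random((8, 16, 16)), angles)
    with pytest.raises(ValueError, match="input projections"):
        generate_synthetic(tiny_model, ps)
    zeros = _projection_set(np.zeros((16, 16, 16)), np.arange(16) * 22.5)
    with pytest.raises(ValueError, match="all-zero"):
        generate_synthetic(tiny_model, zeros)


def test_assemble_interleaved_covers_grid(rng):
    even = _projection_set(rng.random((30, 8, 8)), np.arange(0, 360, 12))
    odd = _projection_set(rng.random((30, 8, 8)), np.arange(6, 360, 12))
    odd.kind = "synthetic"
    merged, prov = assemble_interleaved([even, odd],
                                        expected_angles=np.arange(0, 360, 6))
    assert len(merged.images) == 60
    assert np.array_equal(merged.angles_deg, np.arange(0, 360, 6))
    assert list(prov[:2]) == ["measured", "synthetic"]
    assert (prov == "synthetic").sum() == 30


def test_assemble_interleaved_rejects_duplicates_and_gaps(rng):
    a = _projection_set(rng.random((2, 4, 4)), [0.0, 10.0])
    b = _projection_set(rng.random((2, 4, 4)), [10.0, 20.0])
    with pytest.raises(ValueError, match="overlapping"):
        assemble_interleaved([a, b])
    c = _projection_set(rng.random((2, 4, 4)), [30.0, 40.0])
    with pytest.raises(ValueError, match="cover"):
        assemble_interleaved([a, c],
                             expected_angles=np.array([0.0, 10.0, 20.0, 30.0]))
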