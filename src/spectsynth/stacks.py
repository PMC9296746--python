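"""Projection-stack plumbing around the u-net.

Cyclic expansion pads the angular axis with wrapped copies so that every
intermediate angle is interpolated (never extrapolated) and the stack
length suits repeated halving: 60 projections expand to 64 as
[59, 60, 1, 2, ..., 59, 60, 1, 2] (1-based).  Stacks are normalized to
[0, 1] by the maximum of the *input* projections, and synthetic outputs
are rescaled with the same factor.
"""

from __future__ import annotations

import numpy as np

from .projector import DetectorOrbit, ProjectionSet
from .nn.train import TrainedModel, UNetConfig

__all__ = [
    "cyclic_expand", "cyclic_crop", "normalize_stack",
    "generate_synthetic", "assemble_interleaved",
]


def _pad_split(n: int, target: int) -> tuple[int, int]:
    if target < n:
        raise ValueError(f"cyclic target {target} < stack length {n}")
    deficit = target - n
    return deficit // 2, deficit - deficit // 2


def cyclic_expand(images: np.ndarray, target: int) -> np.ndarray:
    """Wrap-pad the angular (first) axis to ``target`` entries.

    The last ``deficit//2`` projections are prepended and the first
    ``deficit - deficit//2`` appended, e.g. 60 -> 64 gives the order
    [59, 60, 1..60, 1, 2].
    """
    n = len(images)
    front, back = _pad_split(n, target)
    idx = np.arange(-front, n + back) % n  # wraps again if padding > n
    return images[idx]


def cyclic_crop(images: np.ndarray, original_n: int) -> np.ndarray:
    """Inverse of :func:`cyclic_expand`: recover the original entries."""
    front, _ = _pad_split(original_n, len(images))
    return images[front:front + original_n]


def normalize_stack(images: np.ndarray, dataset_id: str = ""
                    ) -> tuple[np.ndarray, float]:
    """Scale a stack to [0, 1] by its maximum; returns (stack, factor)."""
    factor = float(np.max(images))
    if factor <= 0:
        raise ValueError(
            f"cannot normalize an all-zero projection stack"
            f"{f' (dataset {dataset_id})' if dataset_id else ''}")
    return images / factor, factor


def _interp_orbit(orbit: DetectorOrbit, angles: np.ndarray) -> DetectorOrbit:
    """Periodic interpolation of orbit radii at new angles."""
    base_a = np.concatenate([orbit.angles_deg, [orbit.angles_deg[0] + 360.0]])
    base_r = np.concatenate([orbit.radius_cm, [orbit.radius_cm[0]]])
    radii = np.interp(np.mod(angles, 360.0), base_a, base_r)
    order = np.argsort(angles)
    return DetectorOrbit(angles[order], radii[order], orbit.expansion_cm)


def generate_synthetic(model: TrainedModel, ps: ProjectionSet
                       ) -> ProjectionSet:
    """Apply a trained u-net to an input projection set.

    The input stack is cyclically expanded, normalized, pushed through
    the network, rescaled with the input's normalization factor and
    cropped to the configured output length.  Output angles are the
    input angles shifted by the configured rotation theta.
    """
    cfg: UNetConfig = model.config
    if len(ps.images) != cfg.n_input:
        raise ValueError(
            f"model {cfg.label} expects {cfg.n_input} input projections, "
            f"got {len(ps.images)}")
    expanded = cyclic_expand(ps.images, cfg.cyclic_target)
    normed, factor = normalize_stack(expanded, ps.dataset_id)
    net = model.build_network()
    out = net.predict(normed[None, ..., None])[0, ..., 0]
    out = cyclic_crop(out, cfg.n_output) * np.float32(factor)
    angles = np.mod(ps.angles_deg[:cfg.n_output] + cfg.rotation_shift_deg,
                    360.0)
    orbit = _interp_orbit(ps.orbit, angles)
    order = np.argsort(angles)
    return ProjectionSet(out[order], angles[order], ps.pixel_size_mm, orbit,
                         kind="synthetic", units=ps.units,
                         realization=ps.realization, seed=ps.seed,
                         time_per_view_s=ps.time_per_view_s,
                         dataset_id=ps.dataset_id)


def assemble_interleaved(stacks: list[ProjectionSet],
                         expected_angles: np.ndarray | None = None
                         ) -> tuple[ProjectionSet, np.ndarray]:
    """Merge measured and synthetic projection sets into one full set.

    Angle sets must be pairwise disjoint; if ``expected_angles`` is given
    their union must cover it exactly.  Returns the angle-sorted stack
    and a per-projection provenance array ('measured'/'synthetic').
    """
    if not stacks:
        raise ValueError("no stacks to assemble")
    angles = np.concatenate([s.angles_deg for s in stacks])
    if len(np.unique(angles)) != len(angles):
        raise ValueError("overlapping angles between stacks")
    if expected_angles is not None:
        if not np.array_equal(np.sort(angles), np.sort(expected_angles)):
            raise ValueError("assembled angles do not cover the target grid")
    images = np.concatenate([s.images for s in stacks])
    radii = np.concatenate([s.orbit.radius_cm for s in stacks])
    prov = np.concatenate([
        np.full(len(s.images),
                "synthetic" if s.kind == "synthetic" else "measured",
                dtype=object)
        for s in stacks])
    order = np.argsort(angles)
    ref = stacks[0]
    orbit = DetectorOrbit(angles[order], radii[order],
                          ref.orbit.expansion_cm)
    merged = ProjectionSet(images[order], angles[order], ref.pixel_size_mm,
                           orbit, kind=ref.kind, units=ref.units,
                           realization=ref.realization, seed=ref.seed,
                           time_per_view_s=ref.time_per_view_s,
                           dataset_id=ref.dataset_id)
    return merged, prov[order]
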