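"""On-disk formats: NIfTI volumes/stacks with JSON sidecars, orbit CSV."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantoms import ActivityMask
from .projector import DetectorOrbit, ProjectionSet
from .recon import ReconVolume

__all__ = [
    "save_activity_mask", "load_activity_mask",
    "save_projection_set", "load_projection_set",
    "save_recon_volume", "load_recon_volume",
    "save_orbit", "load_orbit",
]


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_activity_mask(mask: ActivityMask, path: str | Path) -> None:
    path = Path(path)
    affine = np.diag([mask.voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(mask.grid.astype(np.int16), affine), path)
    meta = {
        "category": mask.category,
        "max_activity_conc_mbq_ml": mask.max_activity_conc_mbq_ml,
        "dataset_id": mask.dataset_id,
        "seed": mask.seed,
        "shape_voxel_counts": list(map(int, mask.shape_voxel_counts)),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_activity_mask(path: str | Path) -> ActivityMask:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(_sidecar(path).read_text())
    return ActivityMask(
        grid=np.asarray(img.dataobj, dtype=np.int16),
        voxel_size_mm=round(float(img.header.get_zooms()[0]), 6),
        category=meta["category"],
        max_activity_conc_mbq_ml=meta["max_activity_conc_mbq_ml"],
        dataset_id=meta["dataset_id"],
        seed=meta["seed"],
        shape_voxel_counts=meta["shape_voxel_counts"],
    )


def save_projection_set(ps: ProjectionSet, path: str | Path) -> None:
    """NIfTI with the gantry angle as the third axis + JSON sidecar."""
    path = Path(path)
    data = np.moveaxis(ps.images, 0, 2).astype(np.float32)
    affine = np.diag([ps.pixel_size_mm, ps.pixel_size_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), path)
    meta = {
        "angles_deg": ps.angles_deg.tolist(),
        "radius_cm": ps.orbit.radius_cm.tolist(),
        "expansion_cm": ps.orbit.expansion_cm,
        "pixel_size_mm": ps.pixel_size_mm,
        "kind": ps.kind,
        "units": ps.units,
        "realization": ps.realization,
        "seed": ps.seed,
        "time_per_view_s": ps.time_per_view_s,
        "dataset_id": ps.dataset_id,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_projection_set(path: str | Path) -> ProjectionSet:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(_sidecar(path).read_text())
    images = np.moveaxis(np.asarray(img.dataobj, dtype=np.float32), 2, 0)
    orbit = DetectorOrbit(np.array(meta["angles_deg"]),
                          np.array(meta["radius_cm"]),
                          meta.get("expansion_cm", 0.0))
    return ProjectionSet(images, orbit.angles_deg.copy(),
                         meta["pixel_size_mm"], orbit, meta["kind"],
                         meta["units"], meta["realization"], meta["seed"],
                         meta["time_per_view_s"], meta["dataset_id"])


def save_recon_volume(vol: ReconVolume, path: str | Path) -> None:
    path = Path(path)
    affine = np.diag([vol.voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), path)
    meta = {
        "iterations": vol.iterations,
        "subsets": vol.subsets,
        "calibration_cps_per_mbq": vol.calibration_cps_per_mbq,
        "provenance": vol.provenance,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_recon_volume(path: str | Path) -> ReconVolume:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(_sidecar(path).read_text())
    return ReconVolume(np.asarray(img.dataobj, dtype=np.float32),
                       round(float(img.header.get_zooms()[0]), 6),
                       meta["iterations"], meta["subsets"],
                       meta["calibration_cps_per_mbq"], meta["provenance"])


def save_orbit(orbit: DetectorOrbit, path: str | Path) -> None:
    pd.DataFrame({"angle_deg": orbit.angles_deg,
                  "radius_cm": orbit.radius_cm}).to_csv(path, index=False)


def load_orbit(path: str | Path, expansion_cm: float = 0.0) -> DetectorOrbit:
    df = pd.read_csv(path)
    return DetectorOrbit(df.angle_deg.values, df.radius_cm.values,
                         expansion_cm)
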