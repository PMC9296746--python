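"""End-to-end study orchestration at configurable scale.

``run_study`` executes the whole pipeline deterministically under one
seed: manifest -> activity masks -> noise-free projections -> Poisson
realizations -> u-net training -> quantitative evaluation (metric table
and paired hypothesis tests) -> orbit-sensitivity table -> mixed
(measured + synthetic) reconstructions.

The default configuration is the desk-scale analog of the original
study: a 150-mask manifest with the reference category proportions
(105 train / 10 val / 35 test), a 60-angle / 6-degree acquisition of
32x32 projections on the 32-cube lattice, and three networks —

* ``U1``: 30 -> 30 projections, theta = +6 deg, noise realization A;
* ``U2``: identical but trained on realization B;
* ``U3``: identical to U1 but trained on a ~1/20 stratified subset with
  the longer low-learning-rate schedule.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import GridSpec, cylinder_support, get_preset
from .manifest import build_manifest, scale_composition
from .metrics import ComparisonResult, bland_altman, dataset_metrics, paired_compare
from .nn.train import (TrainedModel, UNetConfig, linear_schedule,
                       step_schedule, train)
from .phantoms import ActivityMask, build_activity_mask
from .projector import (AcquisitionConfig, DetectorOrbit, ProjectionSet,
                        add_poisson_noise, elliptical_orbit, forward_project,
                        make_orbit, scale_to_counts)
from .recon import VOISpec, calibrate, osem_reconstruct, snr, to_concentration
from .stacks import (assemble_interleaved, cyclic_expand, generate_synthetic,
                     normalize_stack)

__all__ = ["StudyConfig", "StudyReport", "default_unet_configs",
           "run_study", "orbit_study", "write_report"]


def default_unet_configs() -> list[UNetConfig]:
    """Desk-scale analogs of the study's U1/U2/U3 networks."""
    u1 = UNetConfig(label="U1", noise_realization="A", n_input=30,
                    n_output=30, cyclic_target=32, rotation_shift_deg=6.0,
                    n_train=105, n_val=10, epochs=15,
                    lr_schedule=step_schedule(2.8e-3, 5))
    u2 = UNetConfig(label="U2", noise_realization="B", n_input=30,
                    n_output=30, cyclic_target=32, rotation_shift_deg=6.0,
                    n_train=105, n_val=10, epochs=15,
                    lr_schedule=step_schedule(2.8e-3, 5))
    u3 = UNetConfig(label="U3", noise_realization="A", n_input=30,
                    n_output=30, cyclic_target=32, rotation_shift_deg=6.0,
                    n_train=5, n_val=1, epochs=50,
                    lr_schedule=linear_schedule(4.8e-4, 3.2e-4))
    return [u1, u2, u3]


@dataclass
class StudyConfig:
    preset: str = "desk"
    n_masks: int = 150
    split_fractions: tuple[float, float, float] = (0.70, 1 / 15, 7 / 30)
    acquisition: AcquisitionConfig = field(
        default_factory=lambda: AcquisitionConfig(n_projections=60, matrix=32))
    orbit_a_cm: float = 8.0
    orbit_b_cm: float = 12.0
    unet_configs: list[UNetConfig] = field(default_factory=default_unet_configs)
    test_realization: str = "A"
    orbit_expansions_cm: tuple[float, ...] = (2.0, 16.0)
    do_reconstruction: bool = True
    recon_iterations: int = 6
    recon_subsets: int = 6
    recon_conc_mbq_ml: float = 2.0


@dataclass
class StudyReport:
    per_dataset: pd.DataFrame
    summary: pd.DataFrame
    comparisons: dict[str, ComparisonResult]
    bland_altman_data: dict[str, pd.DataFrame]
    orbit_table: pd.DataFrame
    recon_metrics: dict[str, float]
    manifest: pd.DataFrame
    models: dict[str, TrainedModel]
    provenance: dict


def _dataset_seed(seed: int, index: int) -> int:
    return (seed * 1000003 + index) % (2**31 - 1)


def _stratified_take(df: pd.DataFrame, n: int) -> pd.DataFrame:
    """First-k stratified selection retaining category proportions."""
    counts = df.category.value_counts()
    raw = counts * n / len(df)
    take = raw.astype(int)
    short = n - int(take.sum())
    rema = (raw - take).sort_values(ascending=False)
    for cat in rema.index[:short]:
        take[cat] += 1
    parts = [df[df.category == cat].head(k) for cat, k in take.items() if k]
    return pd.concat(parts)


def _simulate_counts(mask: ActivityMask, orbit: DetectorOrbit,
                     acq: AcquisitionConfig, grid: GridSpec) -> ProjectionSet:
    ps = forward_project(mask, orbit, acq, grid)
    return scale_to_counts(ps, mask.max_activity_conc_mbq_ml, acq, grid)


def _training_pair(noisy: np.ndarray, noisefree: np.ndarray,
                   cfg: UNetConfig, n_acq: int, increment_deg: float,
                   dataset_id: str) -> tuple[np.ndarray, np.ndarray]:
    step = n_acq // cfg.n_input
    if step * cfg.n_input != n_acq:
        raise ValueError("input count must divide the acquisition grid")
    shift = int(round(cfg.rotation_shift_deg / increment_deg))
    in_idx = np.arange(0, n_acq, step)
    tgt_idx = (in_idx + shift) % n_acq
    source = noisy if cfg.target_kind == "noisy" else noisefree
    inp = cyclic_expand(noisy[in_idx], cfg.cyclic_target)
    tgt = cyclic_expand(source[tgt_idx], cfg.cyclic_target)
    inp_n, factor = normalize_stack(inp, dataset_id)
    return inp_n.astype(np.float32), (tgt / np.float32(factor)).astype(np.float32)


def _input_indices(cfg: UNetConfig, n_acq: int) -> tuple[np.ndarray, np.ndarray]:
    step = n_acq // cfg.n_input
    in_idx = np.arange(0, n_acq, step)
    shift = int(round(cfg.rotation_shift_deg * n_acq / 360.0))
    return in_idx, (in_idx + shift) % n_acq


class _StageCache:
    """Optional on-disk cache of expensive stages, keyed by the content
    hash of the upstream configuration and seed."""

    def __init__(self, root: Path | None):
        self.root = root
        if root is not None:
            root.mkdir(parents=True, exist_ok=True)

    def key(self, name: str, payload: dict) -> str:
        blob = json.dumps(payload, sort_keys=True, default=str)
        return f"{name}-{hashlib.sha256(blob.encode()).hexdigest()[:16]}"

    def load(self, key: str):
        if self.root is None:
            return None
        path = self.root / f"{key}.pkl"
        if path.exists():
            with open(path, "rb") as fh:
                return pickle.load(fh)
        return None

    def save(self, key: str, obj) -> None:
        if self.root is None:
            return
        with open(self.root / f"{key}.pkl", "wb") as fh:
            pickle.dump(obj, fh)


def run_study(config: StudyConfig, seed: int = 0,
              out_dir: str | Path | None = None,
              cache: bool = False, verbose: bool = False) -> StudyReport:
    """Run all study stages; identical (seed, config) give an identical
    report.  With ``cache=True`` and an output directory, the simulated
    projection stage is cached on disk and reused."""
    t_start = time.time()
    grid = get_preset(config.preset)
    acq = config.acquisition
    support = cylinder_support(grid)
    base_orbit = elliptical_orbit(acq.n_projections, config.orbit_a_cm,
                                  config.orbit_b_cm)
    n_acq = acq.n_projections
    increment = 360.0 / n_acq

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    stage_cache = _StageCache(out_path / "cache" if (cache and out_path)
                              else None)

    manifest = build_manifest(
        scale_composition(config.n_masks), seed=seed,
        split_fractions=config.split_fractions)

    needed_realizations = sorted(
        {c.noise_realization for c in config.unet_configs}
        | {config.test_realization})

    ck = stage_cache.key("sim", {"seed": seed, "cfg": asdict(config),
                                 "realizations": needed_realizations})
    cached = stage_cache.load(ck)
    if cached is not None:
        masks, noisefree, noisy = cached
    else:
        masks: dict[str, ActivityMask] = {}
        noisefree: dict[str, np.ndarray] = {}
        noisy: dict[tuple[str, str], np.ndarray] = {}
        for i, row in enumerate(manifest.itertuples()):
            mask = build_activity_mask(row, grid, support)
            masks[row.id] = mask
            nf = _simulate_counts(mask, base_orbit, acq, grid)
            noisefree[row.id] = nf.images
            for real in needed_realizations:
                noisy[(row.id, real)] = add_poisson_noise(
                    nf, real, _dataset_seed(seed, i)).images
        stage_cache.save(ck, (masks, noisefree, noisy))
    if verbose:
        print(f"simulated {len(masks)} datasets in "
              f"{time.time() - t_start:.0f}s")

    train_df = manifest[manifest.split == "train"]
    val_df = manifest[manifest.split == "val"]
    test_df = manifest[manifest.split == "test"]

    models: dict[str, TrainedModel] = {}
    for cfg in config.unet_configs:
        tr = _stratified_take(train_df, cfg.n_train)
        va = _stratified_take(val_df, cfg.n_val)
        real = cfg.noise_realization

        def pairs(df):
            ins, tgts = [], []
            for row in df.itertuples():
                i, t = _training_pair(noisy[(row.id, real)],
                                      noisefree[row.id], cfg, n_acq,
                                      increment, row.id)
                ins.append(i)
                tgts.append(t)
            return np.stack(ins), np.stack(tgts)

        x_tr, y_tr = pairs(tr)
        x_va, y_va = pairs(va)
        t0 = time.time()
        models[cfg.label] = train(cfg, x_tr, y_tr, x_va, y_va, seed=seed,
                                  verbose=verbose)
        if verbose:
            print(f"trained {cfg.label} in {time.time() - t0:.0f}s "
                  f"(best val {models[cfg.label].best_val_loss:.5f} "
                  f"@ epoch {models[cfg.label].best_epoch})")

    # ----- evaluation on the shared test set ------------------------------
    rows = []
    for cfg in config.unet_configs:
        model = models[cfg.label]
        in_idx, tgt_idx = _input_indices(cfg, n_acq)
        for row in test_df.itertuples():
            noisy_ps = ProjectionSet(
                noisy[(row.id, config.test_realization)],
                base_orbit.angles_deg.copy(), grid.voxel_size_mm
                * (grid.n // acq.matrix), base_orbit, "noisy", "counts",
                config.test_realization, None, acq.time_per_view_s, row.id)
            nf_ps = ProjectionSet(
                noisefree[row.id], base_orbit.angles_deg.copy(),
                noisy_ps.pixel_size_mm, base_orbit, "noise-free", "counts",
                None, None, acq.time_per_view_s, row.id)
            synth = generate_synthetic(model, noisy_ps.subset(in_idx))
            rec = dataset_metrics(synth, noisy_ps.subset(tgt_idx),
                                  nf_ps.subset(tgt_idx))
            rows.append((cfg.label, row.id, rec.mean_ssim_vs_noisy,
                         rec.mean_nrmse_vs_noisy, rec.mean_ssim_vs_noisefree,
                         rec.mean_nrmse_vs_noisefree))
    per_dataset = pd.DataFrame(rows, columns=[
        "unet", "dataset_id", "ssim_vs_noisy", "nrmse_vs_noisy",
        "ssim_vs_noisefree", "nrmse_vs_noisefree"])

    summary_rows = []
    for cfg in config.unet_configs:
        sub = per_dataset[per_dataset.unet == cfg.label]
        summary_rows.append([
            cfg.label,
            sub.ssim_vs_noisy.mean(), sub.ssim_vs_noisy.std(),
            sub.nrmse_vs_noisy.mean(), sub.nrmse_vs_noisy.std(),
            sub.ssim_vs_noisefree.mean(), sub.ssim_vs_noisefree.std(),
            sub.nrmse_vs_noisefree.mean(), sub.nrmse_vs_noisefree.std()])
    summary = pd.DataFrame(summary_rows, columns=[
        "unet", "ssim_vs_noisy_mean", "ssim_vs_noisy_sd",
        "nrmse_vs_noisy_mean", "nrmse_vs_noisy_sd",
        "ssim_vs_noisefree_mean", "ssim_vs_noisefree_sd",
        "nrmse_vs_noisefree_mean", "nrmse_vs_noisefree_sd"])

    # ----- paired hypothesis tests ---------------------------------------
    comparisons: dict[str, ComparisonResult] = {}
    ba_data: dict[str, pd.DataFrame] = {}
    for cfg in config.unet_configs:
        sub = per_dataset[per_dataset.unet == cfg.label]
        comparisons[f"{cfg.label}:ssim:noisefree_vs_noisy"] = paired_compare(
            sub.ssim_vs_noisefree.values, sub.ssim_vs_noisy.values, "ssim")
        comparisons[f"{cfg.label}:nrmse:noisefree_vs_noisy"] = paired_compare(
            sub.nrmse_vs_noisefree.values, sub.nrmse_vs_noisy.values, "nrmse")
    labels = [c.label for c in config.unet_configs]
    for other in labels[1:]:
        a = per_dataset[per_dataset.unet == labels[0]].set_index("dataset_id")
        b = per_dataset[per_dataset.unet == other].set_index("dataset_id")
        b = b.loc[a.index]
        for col, kind in (("ssim_vs_noisy", "ssim"),
                          ("nrmse_vs_noisy", "nrmse"),
                          ("ssim_vs_noisefree", "ssim"),
                          ("nrmse_vs_noisefree", "nrmse")):
            key = f"{labels[0]}_vs_{other}:{col}"
            comparisons[key] = paired_compare(a[col].values, b[col].values,
                                              kind)
            ba = bland_altman(a[col].values, b[col].values)
            ba_data[key] = pd.DataFrame(
                {"mean": ba.means, "difference": ba.differences})

    # ----- orbit sensitivity ----------------------------------------------
    orbit_table = orbit_study(
        models[labels[0]], config.orbit_expansions_cm, masks, test_df,
        base_orbit, acq, grid, seed,
        base_row=(per_dataset[per_dataset.unet == labels[0]]
                  [["ssim_vs_noisy", "nrmse_vs_noisy"]]),
        realization=config.test_realization)

    # ----- mixed reconstructions ------------------------------------------
    recon_metrics: dict[str, float] = {}
    if config.do_reconstruction:
        recon_metrics = _reconstruction_study(
            config, models[labels[0]], base_orbit, acq, grid, support, seed)

    provenance = {
        "seed": seed,
        "preset": config.preset,
        "n_masks": config.n_masks,
        "unets": labels,
        "test_realization": config.test_realization,
        "runtime_s": round(time.time() - t_start, 1),
    }
    report = StudyReport(per_dataset, summary, comparisons, ba_data,
                         orbit_table, recon_metrics, manifest, models,
                         provenance)
    if out_path is not None:
        write_report(report, out_path)
    return report


def orbit_study(model: TrainedModel, expansions_cm, masks: dict,
                test_df: pd.DataFrame, base_orbit: DetectorOrbit,
                acq: AcquisitionConfig, grid: GridSpec, seed: int,
                base_row: pd.DataFrame | None = None,
                realization: str = "A") -> pd.DataFrame:
    """Evaluate a base-orbit-trained model on radially expanded orbits.

    Returns one row per expansion (including 0 for the base orbit) with
    the mean/SD SSIM and NRMSE of synthetic vs noisy projections.
    """
    cfg = model.config
    n_acq = acq.n_projections
    in_idx, tgt_idx = _input_indices(cfg, n_acq)
    phantom_radius_cm = grid.cylinder_diameter_mm / 20.0
    rows = []
    if base_row is not None:
        rows.append((0.0, base_row.ssim_vs_noisy.mean(),
                     base_row.ssim_vs_noisy.std(),
                     base_row.nrmse_vs_noisy.mean(),
                     base_row.nrmse_vs_noisy.std()))
    id_to_index = {row.id: i for i, row in enumerate(test_df.itertuples())}
    for exp in expansions_cm:
        orbit = make_orbit(base_orbit, float(exp), phantom_radius_cm)
        ssims, nrmses = [], []
        for row in test_df.itertuples():
            mask = masks[row.id]
            nf = _simulate_counts(mask, orbit, acq, grid)
            noisy_ps = add_poisson_noise(
                nf, realization, _dataset_seed(seed, id_to_index[row.id]))
            synth = generate_synthetic(model, noisy_ps.subset(in_idx))
            rec = dataset_metrics(synth, noisy_ps.subset(tgt_idx),
                                  nf.subset(tgt_idx))
            ssims.append(rec.mean_ssim_vs_noisy)
            nrmses.append(rec.mean_nrmse_vs_noisy)
        rows.append((float(exp), float(np.mean(ssims)), float(np.std(ssims, ddof=1)),
                     float(np.mean(nrmses)), float(np.std(nrmses, ddof=1))))
    return pd.DataFrame(rows, columns=[
        "expansion_cm", "ssim_vs_noisy_mean", "ssim_vs_noisy_sd",
        "nrmse_vs_noisy_mean", "nrmse_vs_noisy_sd"])


def _reconstruction_study(config: StudyConfig, model: TrainedModel,
                          base_orbit: DetectorOrbit, acq: AcquisitionConfig,
                          grid: GridSpec, support: np.ndarray,
                          seed: int) -> dict[str, float]:
    """Uniform-cylinder SNR comparison: all-measured noisy reconstruction
    vs a half-measured, half-synthetic reconstruction; plus the image
    calibration round trip."""
    conc = config.recon_conc_mbq_ml
    uniform = ActivityMask(support.astype(np.int16) * 100, grid.voxel_size_mm,
                           "inverted", conc, dataset_id="uniform", seed=seed)
    nf = _simulate_counts(uniform, base_orbit, acq, grid)
    noisy_ps = add_poisson_noise(nf, "A", _dataset_seed(seed, 999983))

    rec_orig = osem_reconstruct(noisy_ps, acq, grid,
                                config.recon_iterations, config.recon_subsets)

    cfg = model.config
    in_idx, tgt_idx = _input_indices(cfg, acq.n_projections)
    synth = generate_synthetic(model, noisy_ps.subset(in_idx))
    mixed, _prov = assemble_interleaved(
        [noisy_ps.subset(in_idx), synth],
        expected_angles=base_orbit.angles_deg)
    rec_mixed = osem_reconstruct(mixed, acq, grid, config.recon_iterations,
                                 config.recon_subsets)

    c = grid.center
    voi = VOISpec("cube", (c, c, c), 0.5 * grid.cylinder_diameter_mm)
    total_activity = conc * support.sum() * grid.voxel_volume_ml
    factor = calibrate(rec_orig, total_activity, acq.time_per_view_s)
    conc_map = to_concentration(rec_orig, factor, acq.time_per_view_s)
    voi_mask = voi.mask(conc_map.shape, grid.voxel_size_mm)
    return {
        "snr_original_120pct_measured": snr(rec_orig, voi),
        "snr_mixed_half_synthetic": snr(rec_mixed, voi),
        "calibration_cps_per_mbq": factor,
        "voi_mean_concentration_mbq_ml": float(conc_map[voi_mask].mean()),
        "true_concentration_mbq_ml": conc,
    }


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Write the report tables as CSV and the summaries as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.manifest.to_csv(out / "manifest.csv", index=False)
    report.per_dataset.to_csv(out / "metrics_per_dataset.csv", index=False)
    report.summary.to_csv(out / "metrics_table.csv", index=False)
    report.orbit_table.to_csv(out / "orbit_table.csv", index=False)
    for key, df in report.bland_altman_data.items():
        safe = key.replace(":", "_")
        df.to_csv(out / f"bland_altman_{safe}.csv", index=False)
    comp = {k: asdict(v) for k, v in report.comparisons.items()}
    with open(out / "comparisons.json", "w") as fh:
        json.dump(comp, fh, indent=2)
    with open(out / "summary.json", "w") as fh:
        json.dump({"recon_metrics": report.recon_metrics,
                   "provenance": report.provenance}, fh, indent=2)
    for label, model in report.models.items():
        model.save(out / f"model_{label}.ckpt")
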