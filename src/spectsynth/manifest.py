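"""Dataset manifests: category composition, seeds, activity scaling, splits.

A manifest is a pandas DataFrame with one row per activity distribution:

    id, category, seed, max_conc_mbq_ml, split

The reference composition mirrors the 10,000-mask study dataset
(75% random shapes, 20% inverted, 1% each of five special patterns);
smaller manifests keep the proportions by largest-remainder rounding.
Maximum activity concentrations are sampled log-uniformly over
0.2–14 MBq/mL by default, covering the clinically reported range with
more mass at low concentrations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TABLE_COMPOSITION",
    "CATEGORIES",
    "scale_composition",
    "build_manifest",
]

TABLE_COMPOSITION: dict[str, int] = {
    "random": 7500,
    "inverted": 2000,
    "chessboard": 100,
    "rod": 100,
    "cross": 100,
    "stripe": 100,
    "nema": 100,
}

CATEGORIES = tuple(TABLE_COMPOSITION)

CONCENTRATION_RANGE_MBQ_ML = (0.2, 14.0)


def scale_composition(total: int,
                      base: dict[str, int] | None = None) -> dict[str, int]:
    """Proportionally scale a composition to ``total`` entries.

    Largest-remainder rounding; ties broken by the base-dict order.
    """
    base = dict(base or TABLE_COMPOSITION)
    base_total = sum(base.values())
    raw = {k: v * total / base_total for k, v in base.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    order = sorted(base, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


def _split_counts(n: int, fractions: tuple[float, float, float]) -> list[int]:
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    short = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in order[:short]:
        counts[i] += 1
    return counts


def build_manifest(composition: dict[str, int] | None = None,
                   conc_range: tuple[float, float] = CONCENTRATION_RANGE_MBQ_ML,
                   seed: int = 0,
                   split_fractions: tuple[float, float, float] = (0.9, 0.05, 0.05),
                   sampling: str = "log-uniform") -> pd.DataFrame:
    """Build a deterministic dataset manifest.

    Parameters
    ----------
    composition : category -> count; defaults to a 100-entry manifest
        with the reference proportions (75/20/1/1/1/1/1).
    conc_range : bounds of the sampled maximum activity concentration.
    seed : master seed; the same seed reproduces the manifest exactly.
    split_fractions : train/val/test fractions, applied per category
        (stratified) with largest-remainder rounding.
    sampling : ``log-uniform`` (default) or ``uniform`` concentration
        sampling.
    """
    if composition is None:
        composition = scale_composition(100)
    if any(v < 0 for v in composition.values()):
        raise ValueError("composition counts must be non-negative")
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    lo, hi = conc_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid concentration range {conc_range}")

    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for category, count in composition.items():
        seeds = rng.integers(0, 2**31 - 1, size=count)
        if sampling == "log-uniform":
            concs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=count))
        elif sampling == "uniform":
            concs = rng.uniform(lo, hi, size=count)
        else:
            raise ValueError(f"unknown sampling {sampling!r}")
        n_train, n_val, n_test = _split_counts(count, split_fractions)
        splits = np.array(["train"] * n_train + ["val"] * n_val
                          + ["test"] * n_test, dtype=object)
        rng.shuffle(splits)
        for s, conc, split in zip(seeds, concs, splits):
            rows.append((f"m{idx:05d}", category, int(s), float(conc), split))
            idx += 1
    return pd.DataFrame(
        rows, columns=["id", "category", "seed", "max_conc_mbq_ml", "split"])
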