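"""Synthetic single-cell data with ground-truth singlets and multiplets.

The generator emulates a FACS-sorted benchmark: each cell type has a
negative-binomial expression profile that is flat at ``base_mean`` except
on a disjoint block of marker genes elevated by ``marker_fold``; a
multiplet is the element-wise sum of independently drawn member cells,
optionally binomially downsampled to mimic reduced per-cell depth in a
shared droplet.  Every barcode carries a ground-truth category and
composition, so the full pipeline can be benchmarked offline.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._errors import ValidationError
from .io import ExpressionMatrix, write_annotations, write_counts

__all__ = [
    "SimulationConfig",
    "default_multiplet_spec",
    "simulate_reference",
    "simulate_cells",
    "write_simulation",
]


def type_names(n_types: int) -> list[str]:
    if n_types <= 26:
        return list(string.ascii_uppercase[:n_types])
    return [f"T{i:03d}" for i in range(n_types)]


def default_multiplet_spec(n_types: int, count: int = 100) -> list[tuple[str, int]]:
    """``count`` doublets for every adjacent pair of cell types."""
    names = type_names(n_types)
    return [("_".join(sorted((names[i], names[i + 1]))), count)
            for i in range(n_types - 1)]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults: 2000 genes, 4 cell types with 50 markers each at 8-fold
    elevation over a base mean of 4 counts/gene (~9400 UMI per singlet), negative-binomial
    dispersion 10, 500 singlets per type and 100 doublets per adjacent
    type pair at full depth (depth_scale 1).
    """

    n_genes: int = 2000
    n_types: int = 4
    markers_per_type: int = 50
    marker_fold: float = 8.0
    base_mean: float = 4.0
    dispersion: float = 10.0
    n_singlets_per_type: int = 500
    multiplet_spec: list[tuple[str, int]] | None = None
    depth_scale: float = 1.0
    seed: int = 1

    def __post_init__(self):
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValidationError("marker blocks exceed the gene universe")
        if self.marker_fold < 1:
            raise ValidationError("marker_fold must be >= 1")
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise ValidationError("base_mean and dispersion must be positive")
        if not 0 < self.depth_scale <= 1:
            raise ValidationError("depth_scale must lie in (0, 1]")
        if self.multiplet_spec is None:
            self.multiplet_spec = default_multiplet_spec(self.n_types)
        valid = set(type_names(self.n_types))
        for comp, count in self.multiplet_spec:
            members = comp.split("_")
            if len(members) < 2 or not set(members) <= valid:
                raise ValidationError(f"invalid multiplet composition: {comp!r}")
            if count < 0:
                raise ValidationError("multiplet counts must be >= 0")

    @property
    def types(self) -> list[str]:
        return type_names(self.n_types)


def simulate_reference(cfg: SimulationConfig) -> pd.DataFrame:
    """Genes x types mean-expression profiles (deterministic given cfg).

    Each type's profile equals ``base_mean`` everywhere and
    ``base_mean * marker_fold`` on its own disjoint marker block.
    """
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    prof = np.full((cfg.n_genes, cfg.n_types), cfg.base_mean)
    for j in range(cfg.n_types):
        block = slice(j * cfg.markers_per_type, (j + 1) * cfg.markers_per_type)
        prof[block, j] *= cfg.marker_fold
    return pd.DataFrame(prof, index=genes, columns=cfg.types)


def marker_blocks(cfg: SimulationConfig) -> dict[str, list[str]]:
    """The planted marker gene ids per type."""
    ref = simulate_reference(cfg)
    return {
        t: list(ref.index[j * cfg.markers_per_type:(j + 1) * cfg.markers_per_type])
        for j, t in enumerate(cfg.types)
    }


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float,
             size: tuple[int, int]) -> np.ndarray:
    """Negative binomial with variance mean + mean^2 / dispersion."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p[:, None], size=size)


def simulate_cells(cfg: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw singlets and additive multiplets with a ground-truth table.

    Returns the count matrix and a truth DataFrame with columns
    ``barcode, category, composition`` (singlet compositions are the type
    name).  A single seed drives one named stream per stage, so singlet and
    multiplet draws are independently reproducible.
    """
    ref = simulate_reference(cfg)
    root = np.random.SeedSequence(cfg.seed)
    rng_singlet, rng_multi = (np.random.default_rng(s) for s in root.spawn(2))

    blocks: list[np.ndarray] = []
    truth_rows: list[tuple[str, str, str]] = []
    bc = 0

    for t in cfg.types:
        counts = _nb_draw(rng_singlet, ref[t].to_numpy(), cfg.dispersion,
                          (cfg.n_genes, cfg.n_singlets_per_type))
        blocks.append(counts)
        for _ in range(cfg.n_singlets_per_type):
            truth_rows.append((f"bc{bc:06d}", "singlet", t))
            bc += 1

    for comp, count in cfg.multiplet_spec:
        if count == 0:
            continue
        members = comp.split("_")
        summed = np.zeros((cfg.n_genes, count), dtype=np.int64)
        for t in members:
            summed += _nb_draw(rng_multi, ref[t].to_numpy(), cfg.dispersion,
                               (cfg.n_genes, count))
        if cfg.depth_scale < 1.0:
            summed = rng_multi.binomial(summed, cfg.depth_scale)
        blocks.append(summed)
        category = "doublet" if len(members) == 2 else "multiplet"
        canonical = "_".join(sorted(members))
        for _ in range(count):
            truth_rows.append((f"bc{bc:06d}", category, canonical))
            bc += 1

    counts = sp.csr_matrix(np.concatenate(blocks, axis=1))
    truth = pd.DataFrame(truth_rows, columns=["barcode", "category", "composition"])
    m = ExpressionMatrix(counts, list(ref.index), list(truth["barcode"]))
    return m, truth


def singlet_annotations(truth: pd.DataFrame) -> pd.Series:
    """Barcode -> cell type for the ground-truth singlets (signature input)."""
    s = truth[truth["category"] == "singlet"]
    return pd.Series(s["composition"].to_numpy(), index=s["barcode"].to_numpy())


def write_simulation(cfg: SimulationConfig, outdir) -> dict[str, Path]:
    """Write matrix (10x MTX layout), truth TSV and singlet annotation TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m, truth = simulate_cells(cfg)
    paths = {
        "matrix": outdir / "matrix",
        "truth": outdir / "truth.tsv",
        "annotations": outdir / "annotations.tsv",
    }
    write_counts(m, paths["matrix"], fmt="mtx_dir")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    write_annotations(singlet_annotations(truth), paths["annotations"])
    return paths
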