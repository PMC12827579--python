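"""Ligand-receptor co-expression and spatial colocalization validation.

Two complementary checks on predicted physical interactions:

* within predicted doublets of two cell-type groups, a ligand or receptor
  counts as expressed in a doublet when its level strictly exceeds its mean
  across all selected doublets, and a pair is co-expressed when both genes
  are; the same strict-mean rule applies to spatial spots;
* across spatial spots, deconvolved cell-type proportions are tested for
  colocalization by thresholding (a spot holds both groups at >= 5% by
  default) and by pairwise Spearman rank correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from ._errors import FormatError, ValidationError
from .classify import BarcodeClassification
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SpotDeconvolution",
    "demo_lr_pairs",
    "read_lr_pairs",
    "select_pair_doublets",
    "lrp_coexpression",
    "colocalized_spots",
    "colocalization_correlation",
]


@dataclass
class SpotDeconvolution:
    """Spots x cell-types proportion table; rows renormalized to sum to 1."""

    spot_ids: list[str]
    cell_types: list[str]
    proportions: np.ndarray

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (len(self.spot_ids), len(self.cell_types)):
            raise ValidationError("proportions shape mismatch")
        if self.proportions.min() < 0 or self.proportions.max() > 1 + 1e-9:
            raise ValidationError("proportions must lie in [0, 1]")
        sums = self.proportions.sum(axis=1)
        off = np.abs(sums - 1.0) > 1e-6
        if off.any():
            warnings.warn(
                f"{int(off.sum())} spots had proportion sums off 1; renormalized",
                stacklevel=2)
            self.proportions = self.proportions / sums[:, None]

    @classmethod
    def read(cls, path) -> "SpotDeconvolution":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy())

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.spot_ids,
                            columns=self.cell_types)


def read_lr_pairs(path) -> pd.DataFrame:
    """Two-column TSV of (ligand, receptor); duplicates dropped, counts logged."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("ligand-receptor TSV needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["ligand", "receptor"]
    before = len(df)
    df = df.drop_duplicates(ignore_index=True)
    if len(df) < before:
        warnings.warn(f"dropped {before - len(df)} duplicate ligand-receptor pairs",
                      stacklevel=2)
    logger.info(
        "ligand-receptor list: %d pairs, %d unique ligands, %d unique receptors",
        len(df), df["ligand"].nunique(), df["receptor"].nunique(),
    )
    return df


def demo_lr_pairs() -> pd.DataFrame:
    """Small bundled demonstration ligand-receptor list (immune-centric).

    A hand-picked set of well-known human pairs for examples and tests;
    real analyses should supply a curated resource via :func:`read_lr_pairs`.
    """
    from importlib.resources import files

    return read_lr_pairs(files("ulmnet.data") / "demo_lr_pairs.tsv")


def select_pair_doublets(
    cls: list[BarcodeClassification],
    group_a: set[str],
    group_b: set[str],
) -> list[str]:
    """Doublets containing exactly one member of each group (e.g. T-B doublets)."""
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise ValidationError("cell-type groups must be disjoint")
    out = []
    for c in cls:
        if c.category != "doublet":
            continue
        members = set(c.active_signatures)
        if len(members & group_a) == 1 and len(members & group_b) == 1:
            out.append(c.barcode)
    return out


def lrp_coexpression(
    m: ExpressionMatrix,
    units: list[str],
    pairs: pd.DataFrame,
    min_units: int = 5,
    layer: str = "lognorm",
) -> pd.DataFrame:
    """Ligand-receptor pairs co-expressed in at least ``min_units`` units.

    A gene is expressed in a unit (doublet barcode or spatial spot) iff its
    value strictly exceeds its mean over all selected units; a pair is
    co-expressed in a unit iff both its genes are.  Pairs whose genes are
    absent from the matrix are dropped with a warning.

    Returns columns ``ligand, receptor, n_units, fraction``.
    """
    if len(units) < 2:
        raise ValidationError("need at least 2 units")
    bc_pos = {b: i for i, b in enumerate(m.barcodes)}
    missing = [u for u in units if u not in bc_pos]
    if missing:
        raise ValidationError(f"units absent from matrix: {missing[:5]}")
    if layer == "lognorm":
        if m.lognorm is None:
            raise ValidationError("lognorm layer absent")
        mat = m.lognorm
    elif layer == "counts":
        mat = m.counts
    else:
        raise ValidationError(f"unknown layer: {layer!r}")
    cols = [bc_pos[u] for u in units]

    genes_needed = sorted(set(pairs["ligand"]) | set(pairs["receptor"]))
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    present = [g for g in genes_needed if g in gene_pos]
    sub = np.asarray(mat[[gene_pos[g] for g in present], :][:, cols].todense(),
                     dtype=float)
    # strict-mean rule: expressed iff value > mean across the selected units
    expressed = sub > sub.mean(axis=1, keepdims=True)
    expr_by_gene = dict(zip(present, expressed))

    rows, dropped = [], 0
    for r in pairs.itertuples(index=False):
        lig, rec = str(r.ligand), str(r.receptor)
        if lig not in expr_by_gene or rec not in expr_by_gene:
            dropped += 1
            continue
        n = int((expr_by_gene[lig] & expr_by_gene[rec]).sum())
        if n >= min_units:
            rows.append((lig, rec, n, n / len(units)))
    if dropped:
        warnings.warn(f"{dropped} ligand-receptor pairs had genes absent from "
                      "the matrix and were dropped", stacklevel=2)
    out = pd.DataFrame(rows, columns=["ligand", "receptor", "n_units", "fraction"])
    return out.sort_values(["n_units", "ligand", "receptor"],
                           ascending=[False, True, True], ignore_index=True)


def colocalized_spots(
    d: SpotDeconvolution,
    group_a: set[str],
    group_b: set[str],
    min_prop: float = 0.05,
) -> list[str]:
    """Spots holding both groups at a proportion of at least ``min_prop``.

    Group proportions are sums over member cell types (inclusive >=).
    """
    df = d.frame()
    for grp in (group_a, group_b):
        unknown = set(grp) - set(d.cell_types)
        if unknown:
            raise ValidationError(f"unknown cell types in group: {sorted(unknown)}")
    a = df[list(group_a)].sum(axis=1)
    b = df[list(group_b)].sum(axis=1)
    keep = (a >= min_prop) & (b >= min_prop)
    return list(df.index[keep])


def colocalization_correlation(
    d: SpotDeconvolution,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation of cell-type proportions across spots.

    Returns (rho, p) DataFrames (cell_types x cell_types); constant columns
    yield missing values with a warning.  p-values are two-sided and
    tie-corrected.
    """
    if len(d.spot_ids) < 3:
        raise ValidationError("need at least 3 spots")
    X = d.proportions
    const = np.ptp(X, axis=0) == 0
    if const.any():
        names = [d.cell_types[i] for i in np.flatnonzero(const)]
        warnings.warn(f"constant proportion columns (rho undefined): {names}",
                      stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", scipy.stats.ConstantInputWarning)
        rho, p = scipy.stats.spearmanr(X, axis=0)
    k = len(d.cell_types)
    rho = np.atleast_2d(rho).reshape(k, k)
    p = np.atleast_2d(p).reshape(k, k)
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    p[const, :] = np.nan
    p[:, const] = np.nan
    np.fill_diagonal(rho, np.where(const, np.nan, 1.0))
    idx = pd.Index(d.cell_types)
    return (pd.DataFrame(rho, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx))
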