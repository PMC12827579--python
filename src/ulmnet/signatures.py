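"""Cell-type marker discovery and signature construction.

Markers come from one-vs-all differential expression on the log-normalized
layer: a two-sided Wilcoxon rank-sum test per gene, gated on a minimum
log2 fold change (0.25) and a minimum detection fraction (10%), with
Bonferroni adjustment per cell type.  Signatures are the top-N markers per
type ranked by fold change among those with adjusted p below threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.stats

from ._errors import ValidationError
from .io import ExpressionMatrix, GeneSignatureSet

__all__ = [
    "wilcoxon_rank_sum",
    "log2_fold_change",
    "find_markers_one_vs_all",
    "build_signatures",
]

MARKER_COLUMNS = ["cell_type", "gene", "log2fc", "p_value", "p_adj", "pct_in", "pct_out"]

# exact enumeration only pays off (and only matters) for small tie-free samples
EXACT_MAX_N = 25


def wilcoxon_rank_sum(x_in, x_out) -> tuple[float, float]:
    """Mann-Whitney U for the in-group with a two-sided p-value.

    Uses exact enumeration when the pooled sample is small (n <= 25) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x_in = np.asarray(x_in, dtype=float)
    x_out = np.asarray(x_out, dtype=float)
    if x_in.size == 0 or x_out.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x_in, x_out])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and tie_free) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x_in, x_out, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def log2_fold_change(x_in, x_out, pseudo: float = 1.0, base: float = 2.0) -> float:
    """Fold change on de-logged normalized values with a pseudocount.

    ``log2((mean(delog(x_in)) + pseudo) / (mean(delog(x_out)) + pseudo))``
    where ``delog`` inverts the log layer (``base**x - 1``).
    """
    m_in = float(np.mean(np.power(base, np.asarray(x_in, dtype=float)) - 1.0))
    m_out = float(np.mean(np.power(base, np.asarray(x_out, dtype=float)) - 1.0))
    return float(np.log2((m_in + pseudo) / (m_out + pseudo)))


def _delogged_group_stats(dense_ln: np.ndarray, mask: np.ndarray, base: float):
    """Mean de-logged expression and detection fraction for one cell group."""
    sub = dense_ln[:, mask]
    mean_delog = (np.power(base, sub) - 1.0).mean(axis=1)
    pct = (sub > 0).mean(axis=1)
    return mean_delog, pct


def find_markers_one_vs_all(
    m: ExpressionMatrix,
    annotations: pd.Series,
    min_log2fc: float = 0.25,
    min_pct: float = 0.10,
    pseudo: float = 1.0,
    base: float = 2.0,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """One-vs-all positive marker genes for every annotated cell type.

    For each cell type only genes passing both the detection filter
    (``max(pct_in, pct_out) >= min_pct``) and the positive fold-change gate
    (``log2fc >= min_log2fc``) are tested; the multiple-testing adjustment
    spans the genes actually tested for that type.  Cell types with fewer
    than 3 cells are skipped with a warning.

    Returns a DataFrame with columns ``cell_type, gene, log2fc, p_value,
    p_adj, pct_in, pct_out``.
    """
    if m.lognorm is None:
        raise ValidationError("lognorm layer required; run normalize_log_cp10k first")
    annotations = annotations.loc[annotations.index.intersection(m.barcode_index())]
    types = annotations.unique()
    if len(types) < 2:
        raise ValidationError("need at least two annotated cell types")
    pos = {b: i for i, b in enumerate(m.barcodes)}
    cols = np.array([pos[b] for b in annotations.index])
    dense = np.asarray(m.lognorm[:, cols].todense())
    labels = annotations.to_numpy()
    genes = np.asarray(m.gene_ids)

    frames = []
    for ct in types:
        in_mask = labels == ct
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        if n_in < 3:
            warnings.warn(f"cell type {ct!r} has {n_in} cells (<3); skipped",
                          stacklevel=2)
            continue
        mean_in, pct_in = _delogged_group_stats(dense, in_mask, base)
        mean_out, pct_out = _delogged_group_stats(dense, ~in_mask, base)
        log2fc = np.log2((mean_in + pseudo) / (mean_out + pseudo))
        testable = (np.maximum(pct_in, pct_out) >= min_pct) & (log2fc >= min_log2fc)
        idx = np.flatnonzero(testable)
        if idx.size == 0:
            continue
        x_in = dense[np.ix_(idx, in_mask)]
        x_out = dense[np.ix_(idx, ~in_mask)]
        res = scipy.stats.mannwhitneyu(
            x_in, x_out, alternative="two-sided", method="asymptotic", axis=1
        )
        pvals = np.asarray(res.pvalue, dtype=float)
        if n_in + n_out <= EXACT_MAX_N:
            # small pooled samples: switch tie-free genes to exact enumeration
            for j, gi in enumerate(idx):
                pooled = dense[gi, :]
                if np.unique(pooled).size == pooled.size:
                    _, pvals[j] = wilcoxon_rank_sum(x_in[j], x_out[j])
        p_adj = _adjust(pvals, idx.size, adjust)
        frames.append(pd.DataFrame({
            "cell_type": ct,
            "gene": genes[idx],
            "log2fc": log2fc[idx],
            "p_value": pvals,
            "p_adj": p_adj,
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
        }))
    if not frames:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    return pd.concat(frames, ignore_index=True)[MARKER_COLUMNS]


def _adjust(p: np.ndarray, n_tests: int, method: str) -> np.ndarray:
    if method == "bonferroni":
        return np.minimum(p * n_tests, 1.0)
    if method in ("bh", "fdr_bh"):
        order = np.argsort(p)
        ranked = p[order] * n_tests / (np.arange(n_tests) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValidationError(f"unknown adjustment method: {method!r}")


RECOMMENDED_TOP_N = (100, 300)
MAX_RECOMMENDED_TOP_N = 600


def build_signatures(
    markers: pd.DataFrame,
    top_n: int = 100,
    max_padj: float = 0.05,
    weight: str = "unit",
) -> GeneSignatureSet:
    """Top-N signature per cell type from a marker table.

    Keeps markers with ``p_adj < max_padj``, ranks by descending log2 fold
    change (ties broken by ascending adjusted p, then gene id) and takes the
    first ``top_n``.  ``weight='unit'`` gives binary membership weights;
    ``weight='log2fc'`` uses the fold change.  Set sizes of 100-300 genes are
    recommended; sizes above 600 are discouraged.
    """
    if markers is None or len(markers) == 0:
        raise ValidationError("marker table is empty")
    if not (RECOMMENDED_TOP_N[0] <= top_n <= RECOMMENDED_TOP_N[1]):
        if top_n > MAX_RECOMMENDED_TOP_N:
            warnings.warn(
                f"top_n={top_n} exceeds the recommended maximum of "
                f"{MAX_RECOMMENDED_TOP_N}; signature sets of 100-300 genes are "
                "recommended", stacklevel=2)
        else:
            warnings.warn(
                f"top_n={top_n} is outside the recommended 100-300 range",
                stacklevel=2)
    sets: dict[str, list[tuple[str, float]]] = {}
    for ct, grp in markers.groupby("cell_type", sort=False):
        keep = grp[grp["p_adj"] < max_padj]
        if keep.empty:
            raise ValidationError(
                f"cell type {ct!r} has no markers with p_adj < {max_padj}"
            )
        ranked = keep.sort_values(
            ["log2fc", "p_adj", "gene"], ascending=[False, True, True],
            kind="mergesort",
        ).head(top_n)
        if len(ranked) < top_n:
            warnings.warn(
                f"signature {ct!r} has only {len(ranked)} genes (< top_n={top_n})",
                stacklevel=2)
        if weight == "unit":
            sets[str(ct)] = [(g, 1.0) for g in ranked["gene"]]
        elif weight == "log2fc":
            sets[str(ct)] = list(zip(ranked["gene"], ranked["log2fc"].astype(float)))
        else:
            raise ValidationError(f"unknown weight scheme: {weight!r}")
    return GeneSignatureSet(
        sets, metadata={"top_n": top_n, "max_padj": max_padj, "weight": weight}
    )
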