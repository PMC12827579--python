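"""Univariate linear model signature activity scoring.

Each barcode's log-normalized expression vector ``y`` (over the full gene
universe) is regressed on a signature's membership-weight vector ``x``
(weight for member genes, 0 elsewhere).  The slope t-statistic is the
activity score of that signature in that cell; its two-sided p-value comes
from the t distribution at ``G - 2`` degrees of freedom.  The t-statistic
is invariant to positive scaling and shifts of ``y``, so the choice of log
base in normalization does not affect scores.

Everything is computed from sufficient statistics (sums, sums of squares
and the cross-product matrix), so the sparse expression layer is never
densified per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from ._errors import ValidationError
from .io import ExpressionMatrix, GeneSignatureSet

__all__ = ["ActivityScoreMatrix", "ulm_fit", "score_signatures"]

# caps for degenerate perfect fits (zero residual variance)
T_CAP = 1e6
P_FLOOR = 1e-300


@dataclass
class ActivityScoreMatrix:
    """Cells x signatures t-values and p-values from the univariate fits."""

    barcodes: list[str]
    signatures: list[str]
    t_value: np.ndarray  # (n_cells, n_signatures)
    p_value: np.ndarray  # same shape, in [0, 1]
    df: int              # G_used - 2
    genes_used: int

    def __post_init__(self):
        self.t_value = np.asarray(self.t_value, dtype=float)
        self.p_value = np.asarray(self.p_value, dtype=float)
        expected = (len(self.barcodes), len(self.signatures))
        if self.t_value.shape != expected or self.p_value.shape != expected:
            raise ValidationError("score matrix shape mismatch")
        if not np.all(np.isfinite(self.t_value)):
            raise ValidationError("non-finite t-values")
        if self.df < 1:
            raise ValidationError("degrees of freedom must be >= 1")

    def t_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.t_value, index=self.barcodes, columns=self.signatures)

    def p_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_value, index=self.barcodes, columns=self.signatures)

    def to_long(self) -> pd.DataFrame:
        """Tidy (barcode, signature, t, p) table."""
        t = self.t_frame().stack()
        p = self.p_frame().stack()
        out = pd.DataFrame({"t": t, "p": p}).reset_index()
        out.columns = ["barcode", "signature", "t", "p"]
        return out

    def write(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, df: int | None = None) -> "ActivityScoreMatrix":
        long = pd.read_csv(path, sep="\t")
        t = long.pivot(index="barcode", columns="signature", values="t")
        p = long.pivot(index="barcode", columns="signature", values="p")
        # df cannot be recovered from the table; callers may supply it
        return cls(
            barcodes=list(t.index),
            signatures=list(t.columns),
            t_value=t.to_numpy(),
            p_value=p.to_numpy(),
            df=df if df is not None else 1,
            genes_used=0,
        )


def ulm_fit(y, x) -> tuple[float, float, float, int]:
    """Ordinary least squares of ``y = b0 + b1 x``; returns (b1, t, p, df).

    ``t = b1 / SE(b1)`` with the standard error from the residual variance
    at ``df = G - 2``; p is two-sided.  Perfect fits are capped at
    ``|t| = 1e6``, ``p = 1e-300``; a constant ``y`` scores t = 0, p = 1.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    g = y.size
    if g < 3 or x.size != g:
        raise ValidationError("need G >= 3 observations with matching lengths")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValidationError("zero predictor variance")
    syy = float(np.sum((y - y.mean()) ** 2))
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    beta1 = sxy / sxx
    df = g - 2
    if syy == 0.0:
        return 0.0, 0.0, 1.0, df
    ss_res = syy - beta1 * sxy
    if ss_res <= 0.0 or ss_res < 1e-14 * syy:
        warnings.warn("perfect fit: t capped", stacklevel=2)
        t = T_CAP if beta1 >= 0 else -T_CAP
        return beta1, t, P_FLOOR, df
    se = np.sqrt(ss_res / df / sxx)
    t = beta1 / se
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return beta1, float(t), float(p), df


def _signature_design(m: ExpressionMatrix, sigs: GeneSignatureSet,
                      min_overlap: int) -> np.ndarray:
    """Dense (genes x signatures) weight matrix over the matrix's gene universe."""
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    X = np.zeros((m.n_genes, len(sigs)), dtype=float)
    for j, name in enumerate(sigs.names()):
        hits = 0
        for gene, w in sigs.sets[name]:
            i = gene_pos.get(gene)
            if i is not None:
                X[i, j] = w
                hits += 1
        if hits < min_overlap:
            raise ValidationError(
                f"signature {name!r} overlaps the matrix in {hits} genes "
                f"(min_overlap={min_overlap})"
            )
    return X


def score_signatures(
    m: ExpressionMatrix,
    sigs: GeneSignatureSet,
    min_overlap: int = 5,
) -> ActivityScoreMatrix:
    """Score every barcode against every signature with the univariate model.

    The predictor for a signature carries the member-gene weights and 0 for
    every other gene of the matrix; the same gene universe is used for all
    signatures and cells.  Barcodes with zero expression variance get
    t = 0, p = 1 with a warning.
    """
    if m.lognorm is None:
        raise ValidationError("lognorm layer required; run normalize_log_cp10k first")
    g = m.n_genes
    if g < 3:
        raise ValidationError("need at least 3 genes to fit the univariate model")
    X = _signature_design(m, sigs, min_overlap)
    Y = sp.csc_matrix(m.lognorm, dtype=float)

    sum_x = X.sum(axis=0)                       # (S,)
    sxx = (X ** 2).sum(axis=0) - sum_x ** 2 / g
    if np.any(sxx == 0):
        flat = [sigs.names()[j] for j in np.flatnonzero(sxx == 0)]
        raise ValidationError(f"zero predictor variance for signatures: {flat}")
    sum_y = np.asarray(Y.sum(axis=0)).ravel()   # (C,)
    sum_y2 = np.asarray(Y.multiply(Y).sum(axis=0)).ravel()
    syy = sum_y2 - sum_y ** 2 / g
    xty = np.asarray((Y.T @ X))                 # (C, S)
    sxy = xty - np.outer(sum_y, sum_x) / g

    df = g - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = sxy ** 2 / np.outer(syy, sxx)
    # relative tolerance: catches constant cells whose centered sum of squares
    # is only floating-point residue
    zero_var = syy <= 1e-12 * np.maximum(sum_y2, 1e-300)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} barcodes have zero expression variance; "
            "scored t=0, p=1", stacklevel=2)
        r2[zero_var, :] = 0.0
    # t of the slope equals r * sqrt(df / (1 - r^2)); sign follows the slope
    r2 = np.clip(r2, 0.0, 1.0)
    perfect = r2 >= 1.0 - 1e-14
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.sign(sxy) * np.sqrt(r2 * df / (1.0 - r2))
    t[perfect] = np.sign(sxy[perfect]) * T_CAP
    t[zero_var, :] = 0.0
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    p[perfect] = P_FLOOR
    p[zero_var, :] = 1.0
    if perfect.any():
        warnings.warn(f"{int(perfect.sum())} perfect fits: t capped", stacklevel=2)
    return ActivityScoreMatrix(
        barcodes=list(m.barcodes),
        signatures=sigs.names(),
        t_value=t,
        p_value=p,
        df=df,
        genes_used=g,
    )
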