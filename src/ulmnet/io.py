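"""Core data containers and readers/writers for single-cell expression data.

The central container is :class:`ExpressionMatrix`, a genes x cells count
matrix (sparse-capable) with an optional log-normalized layer.  Readers
accept the 10x Matrix Market triplet directory layout and dense CSV/TSV;
gene signatures travel as GMT or two-column TSV.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSignatureSet",
    "QCParams",
    "read_counts",
    "write_counts",
    "read_annotations",
    "write_annotations",
    "normalize_log_cp10k",
    "qc_filter",
    "read_signatures",
    "write_signatures",
]


def _check_unique(labels, what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise ValidationError(f"duplicate {what}: {dups[:10]}")


class ExpressionMatrix:
    """Genes x cells count matrix with an optional log-normalized layer.

    Parameters
    ----------
    counts
        Non-negative integral matrix, genes on rows, cells on columns.
        Dense arrays are converted to CSR.
    gene_ids, barcodes
        Unique row / column labels.
    lognorm
        Optional derived layer of identical shape; reproducibly derivable
        from ``counts`` via :func:`normalize_log_cp10k`.
    """

    def __init__(self, counts, gene_ids, barcodes, lognorm=None):
        counts = sp.csr_matrix(counts)
        gene_ids = [str(g) for g in gene_ids]
        barcodes = [str(b) for b in barcodes]
        if counts.shape != (len(gene_ids), len(barcodes)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(gene_ids)} genes x {len(barcodes)} barcodes"
            )
        _check_unique(gene_ids, "gene ids")
        _check_unique(barcodes, "barcodes")
        if counts.nnz and counts.data.min() < 0:
            raise ValidationError("negative values in count matrix")
        if counts.nnz and np.any(counts.data != np.round(counts.data)):
            raise ValidationError("non-integer values in count matrix")
        self.counts = counts
        self.gene_ids = gene_ids
        self.barcodes = barcodes
        if lognorm is not None:
            lognorm = sp.csr_matrix(lognorm)
            if lognorm.shape != counts.shape:
                raise ValidationError("lognorm layer shape mismatch")
        self.lognorm = lognorm

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def __repr__(self) -> str:
        layer = "+lognorm" if self.lognorm is not None else ""
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_cells} cells{layer})"

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def barcode_index(self) -> pd.Index:
        return pd.Index(self.barcodes)

    def total_counts(self) -> np.ndarray:
        """Per-cell library sizes."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Per-cell number of genes with nonzero counts."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def subset_barcodes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Column subset by boolean mask or integer positions."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        bc = [self.barcodes[i] for i in keep]
        ln = self.lognorm[:, keep] if self.lognorm is not None else None
        return ExpressionMatrix(self.counts[:, keep], self.gene_ids, bc, lognorm=ln)

    def to_dense_lognorm(self) -> np.ndarray:
        if self.lognorm is None:
            raise ValidationError("lognorm layer absent; call normalize_log_cp10k first")
        return np.asarray(self.lognorm.todense())


@dataclass(frozen=True)
class QCParams:
    """Barcode quality-control thresholds.

    Defaults retain cells with at least 500 detected genes, a mitochondrial
    fraction below 25% and fewer than 5000 total UMI.
    """

    min_genes: int = 500
    max_mito_frac: float = 0.25
    max_umi: int = 5000
    mito_prefix: tuple[str, ...] = ("MT-", "mt-")

    def __post_init__(self):
        if self.min_genes < 0:
            raise ValidationError("min_genes must be >= 0")
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ValidationError("max_mito_frac must lie in [0, 1]")


@dataclass
class GeneSignatureSet:
    """Per-cell-type ordered marker gene lists with positive weights.

    ``sets`` maps cell type -> list of ``(gene, weight)`` in descending
    ranking order.  ``metadata`` records how the sets were built.
    """

    sets: dict[str, list[tuple[str, float]]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"signature {name!r} is empty")
            genes = [g for g, _ in members]
            if len(set(genes)) != len(genes):
                raise ValidationError(f"duplicate genes within signature {name!r}")
            if any(w <= 0 for _, w in members):
                raise ValidationError(f"non-positive weight in signature {name!r}")

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return [g for g, _ in self.sets[name]]

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSignatureSet):
            return NotImplemented
        return self.sets == other.sets


# -- count matrix I/O ------------------------------------------------------

def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find_file(d: Path, stems: list[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = d / name
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {stems} found in {d}")


def read_counts(path, fmt: str | None = None) -> ExpressionMatrix:
    """Read a count matrix from a 10x MTX directory or a dense CSV/TSV.

    For ``mtx_dir`` the directory must hold ``matrix.mtx[.gz]``,
    ``features.tsv[.gz]`` (or ``genes.tsv``) and ``barcodes.tsv[.gz]``.
    For CSV/TSV the first column holds gene ids and the header row barcodes.
    Gene and barcode order is preserved from file.
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "mtx_dir"
        elif path.suffix.lower() == ".csv":
            fmt = "csv"
        else:
            fmt = "tsv"
    if fmt == "mtx_dir":
        if not path.is_dir():
            raise FileNotFoundError(f"not a directory: {path}")
        mtx = _find_file(path, ["matrix.mtx"])
        feat = _find_file(path, ["features.tsv", "genes.tsv"])
        bcs = _find_file(path, ["barcodes.tsv"])
        with _open_maybe_gz(mtx) as fh:
            m = sp.csr_matrix(scipy.io.mmread(fh))
        with _open_maybe_gz(feat) as fh:
            genes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
        with _open_maybe_gz(bcs) as fh:
            barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
        if m.shape[0] != len(genes):
            raise FormatError(
                f"features file lists {len(genes)} genes but matrix has {m.shape[0]} rows"
            )
        if m.shape[1] != len(barcodes):
            raise FormatError(
                f"barcodes file lists {len(barcodes)} barcodes but matrix has "
                f"{m.shape[1]} columns"
            )
        return ExpressionMatrix(m, genes, barcodes)
    if fmt in ("csv", "tsv"):
        if not path.exists():
            raise FileNotFoundError(f"no such file: {path}")
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return ExpressionMatrix(
            sp.csr_matrix(df.to_numpy()), list(df.index), list(df.columns)
        )
    raise ValidationError(f"unknown counts format: {fmt!r}")


def write_counts(m: ExpressionMatrix, path, fmt: str = "mtx_dir") -> None:
    """Write counts in a layout :func:`read_counts` can read back."""
    path = Path(path)
    if fmt == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(m.counts))
        (path / "features.tsv").write_text(
            "".join(f"{g}\t{g}\tGene Expression\n" for g in m.gene_ids)
        )
        (path / "barcodes.tsv").write_text("".join(b + "\n" for b in m.barcodes))
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.DataFrame(
            np.asarray(m.counts.todense(), dtype=int),
            index=m.gene_ids,
            columns=m.barcodes,
        )
        df.to_csv(path, sep=sep)
    else:
        raise ValidationError(f"unknown counts format: {fmt!r}")


def read_annotations(path) -> pd.Series:
    """Read a barcode -> cell_type TSV (columns ``barcode``, ``cell_type``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t")
    if not {"barcode", "cell_type"}.issubset(df.columns):
        raise FormatError("annotation TSV needs columns 'barcode' and 'cell_type'")
    if df["cell_type"].isna().any() or (df["cell_type"].astype(str) == "").any():
        raise ValidationError("empty cell_type labels in annotation file")
    ser = pd.Series(
        df["cell_type"].astype(str).to_numpy(), index=df["barcode"].astype(str)
    )
    _check_unique(ser.index, "annotated barcodes")
    return ser


def write_annotations(ann: pd.Series, path) -> None:
    pd.DataFrame({"barcode": ann.index, "cell_type": ann.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def check_annotations(ann: pd.Series, m: ExpressionMatrix) -> None:
    """Every annotated barcode must exist in the matrix it annotates."""
    missing = ann.index.difference(m.barcode_index())
    if len(missing):
        raise ValidationError(
            f"{len(missing)} annotated barcodes absent from matrix, e.g. "
            f"{list(missing[:5])}"
        )


# -- normalization and QC --------------------------------------------------

def normalize_log_cp10k(
    m: ExpressionMatrix, scale: float = 1e4, base: float = 2.0
) -> ExpressionMatrix:
    """Attach a log counts-per-10k layer: ``log_base(1 + c * scale / total)``.

    Recomputed from counts each call, so the layer is idempotent.  Zeros map
    to zeros exactly, so sparsity is preserved.  Cells with zero total counts
    are rejected (their normalization is undefined).
    """
    totals = m.total_counts()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [m.barcodes[i] for i in zero[:10]]
        raise ValidationError(f"cells with zero total counts: {bad}")
    ln = sp.csc_matrix(m.counts, dtype=float)
    # scale each column by scale/total, then log1p/log(base) on stored values only
    ln.data *= np.repeat(scale / totals, np.diff(ln.indptr))
    np.log1p(ln.data, out=ln.data)
    ln.data /= np.log(base)
    return ExpressionMatrix(m.counts, m.gene_ids, m.barcodes, lognorm=sp.csr_matrix(ln))


def qc_filter(m: ExpressionMatrix, p: QCParams | None = None) -> ExpressionMatrix:
    """Retain barcodes passing gene-count, mitochondrial and UMI thresholds.

    A barcode survives iff detected genes >= ``min_genes``, mitochondrial
    count fraction < ``max_mito_frac`` and total UMI < ``max_umi``.
    """
    p = p or QCParams()
    totals = m.total_counts()
    detected = m.genes_detected()
    prefixes = tuple(pref.lower() for pref in p.mito_prefix)
    mito_mask = np.array([g.lower().startswith(prefixes) for g in m.gene_ids])
    if mito_mask.any():
        mito = np.asarray(m.counts[mito_mask].sum(axis=0)).ravel()
    else:
        mito = np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    keep = (detected >= p.min_genes) & (mito_frac < p.max_mito_frac) & (totals < p.max_umi)
    removed = int((~keep).sum())
    logger.info("qc_filter removed %d of %d barcodes", removed, m.n_cells)
    if not keep.any():
        warnings.warn("qc_filter removed every barcode", stacklevel=2)
    return m.subset_barcodes(keep)


# -- gene signature I/O ----------------------------------------------------

def read_signatures(path, fmt: str | None = None) -> GeneSignatureSet:
    """Read signatures from GMT (one set per line) or TSV (cell_type, gene[, weight]).

    Duplicate genes within a set are deduplicated with a warning; empty sets
    are an error.  Missing TSV weights default to 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if fmt is None:
        fmt = "gmt" if path.suffix.lower() == ".gmt" else "tsv"
    sets: dict[str, list[tuple[str, float]]] = {}
    if fmt == "gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line needs name, description, >=1 gene: {line!r}")
            name, genes = parts[0], parts[2:]
            sets[name] = _dedup(name, [(g, 1.0) for g in genes if g])
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        if not {"cell_type", "gene"}.issubset(df.columns):
            raise FormatError("signature TSV needs columns 'cell_type' and 'gene'")
        if "weight" not in df.columns:
            df["weight"] = 1.0
        for name, grp in df.groupby("cell_type", sort=False):
            sets[str(name)] = _dedup(
                str(name),
                list(zip(grp["gene"].astype(str), grp["weight"].astype(float))),
            )
    else:
        raise ValidationError(f"unknown signature format: {fmt!r}")
    if not sets:
        raise ValidationError(f"no signatures found in {path}")
    return GeneSignatureSet(sets)


def _dedup(name: str, members: list[tuple[str, float]]) -> list[tuple[str, float]]:
    seen: dict[str, float] = {}
    for g, w in members:
        if g in seen:
            warnings.warn(f"duplicate gene {g!r} in signature {name!r}; keeping first",
                          stacklevel=3)
        else:
            seen[g] = w
    if not seen:
        raise ValidationError(f"signature {name!r} is empty")
    return list(seen.items())


def write_signatures(sigs: GeneSignatureSet, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "gmt" if path.suffix.lower() == ".gmt" else "tsv"
    if fmt == "gmt":
        lines = [
            "\t".join([name, "na"] + [g for g, _ in members])
            for name, members in sigs.sets.items()
        ]
        path.write_text("".join(line + "\n" for line in lines))
    elif fmt == "tsv":
        rows = [
            (name, g, w)
            for name, members in sigs.sets.items()
            for g, w in members
        ]
        pd.DataFrame(rows, columns=["cell_type", "gene", "weight"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValidationError(f"unknown signature format: {fmt!r}")
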