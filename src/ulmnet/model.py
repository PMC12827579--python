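"""Model/Results surface tying the pipeline together.

:class:`UlmNet` is constructed from an expression matrix plus either
precomputed gene signatures or per-cell annotations (from which signatures
are derived); :meth:`UlmNet.fit` runs signature scoring, barcode
classification and network construction, returning an
:class:`UlmNetResults` carrying the activity scores, per-barcode calls,
the multiplet frequency table and the interaction network, with
``summary()``, benchmarking and plotting attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from ._errors import ValidationError
from . import classify as _classify
from . import network as _network
from .benchmark import BenchmarkResult, evaluate_doublet_calls
from .classify import BarcodeClassification
from .io import ExpressionMatrix, GeneSignatureSet, normalize_log_cp10k
from .scoring import ActivityScoreMatrix, score_signatures
from .signatures import build_signatures, find_markers_one_vs_all

__all__ = ["UlmNet", "UlmNetResults"]


class UlmNet:
    """Univariate-linear-model multiplet deconvolution of a count matrix.

    Parameters
    ----------
    matrix
        Genes x cells counts; a log layer is derived automatically when
        absent.
    signatures
        Precomputed cell-type signatures.  If omitted, ``annotations``
        (barcode -> cell type, typically covering reference singlets) must
        be given and signatures are built by one-vs-all marker selection.
    annotations
        Per-barcode cell-type labels used for signature generation.
    top_n, min_log2fc, min_pct, max_padj
        Marker-selection and signature-size parameters.
    t_min, p_max
        Activity thresholds: a signature is active when t > t_min and
        p < p_max (strict).
    min_count
        Minimum multiplet-type frequency retained for the network.
    min_overlap
        Minimum signature genes that must exist in the matrix.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        signatures: GeneSignatureSet | None = None,
        annotations: pd.Series | None = None,
        *,
        top_n: int = 100,
        min_log2fc: float = 0.25,
        min_pct: float = 0.10,
        max_padj: float = 0.05,
        t_min: float = 1.0,
        p_max: float = 0.05,
        min_count: int = 10,
        min_overlap: int = 5,
    ):
        if signatures is None and annotations is None:
            raise ValidationError(
                "either precomputed signatures or annotations (to derive "
                "signatures from) are required"
            )
        if matrix.lognorm is None:
            matrix = normalize_log_cp10k(matrix)
        self.matrix = matrix
        self.signatures = signatures
        self.annotations = annotations
        self.params = dict(
            top_n=top_n, min_log2fc=min_log2fc, min_pct=min_pct,
            max_padj=max_padj, t_min=t_min, p_max=p_max,
            min_count=min_count, min_overlap=min_overlap,
        )

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, **kwargs) -> "UlmNet":
        """Build from a genes x cells DataFrame of counts."""
        m = ExpressionMatrix(counts.to_numpy(), list(counts.index),
                             list(counts.columns))
        return cls(m, **kwargs)

    def fit(self) -> "UlmNetResults":
        """Run signatures -> scoring -> classification -> network."""
        p = self.params
        sigs = self.signatures
        markers = None
        if sigs is None:
            markers = find_markers_one_vs_all(
                self.matrix, self.annotations,
                min_log2fc=p["min_log2fc"], min_pct=p["min_pct"],
            )
            sigs = build_signatures(markers, top_n=p["top_n"],
                                    max_padj=p["max_padj"])
        scores = score_signatures(self.matrix, sigs, min_overlap=p["min_overlap"])
        active = _classify.active_signatures(scores, t_min=p["t_min"],
                                             p_max=p["p_max"])
        calls = _classify.classify_barcodes(active)
        table = _network.tabulate_multiplets(calls)
        kept = _network.filter_multiplets(table, min_count=p["min_count"])
        graph = _network.build_network(kept)
        return UlmNetResults(
            model=self, signatures=sigs, markers=markers, scores=scores,
            classifications=calls, multiplet_table=table,
            filtered_table=kept, network=graph,
        )


@dataclass
class UlmNetResults:
    """Fitted pipeline state: scores, calls, multiplet table and network."""

    model: UlmNet
    signatures: GeneSignatureSet
    scores: ActivityScoreMatrix
    classifications: list[BarcodeClassification]
    multiplet_table: pd.DataFrame
    filtered_table: pd.DataFrame
    network: nx.Graph
    markers: pd.DataFrame | None = None
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    def classification_frame(self) -> pd.DataFrame:
        if self._frame is None:
            self._frame = _classify.classification_frame(self.classifications)
        return self._frame

    def category_counts(self) -> dict[str, int]:
        counts = self.classification_frame()["category"].value_counts()
        return {c: int(counts.get(c, 0)) for c in _classify.CATEGORIES}

    def benchmark(self, truth: pd.Series,
                  true_composition: pd.Series | None = None,
                  composition_exact: bool = False) -> BenchmarkResult:
        """Confusion-matrix evaluation against ground-truth labels."""
        return evaluate_doublet_calls(
            self.classifications, truth, true_composition=true_composition,
            composition_exact=composition_exact,
        )

    def plot_network(self, path, weight_scale: float = 10.0, seed: int = 0) -> None:
        _network.plot_network(self.network, path, weight_scale=weight_scale,
                              seed=seed)

    def summary(self) -> str:
        """Human-readable run summary."""
        counts = self.category_counts()
        lines = [
            "ULMnet multiplet deconvolution",
            "=" * 46,
            f"cells scored:        {len(self.scores.barcodes)}",
            f"genes in universe:   {self.scores.genes_used}",
            f"signatures:          {len(self.signatures)} "
            f"({', '.join(self.signatures.names())})",
            f"activity thresholds: t > {self.model.params['t_min']}, "
            f"p < {self.model.params['p_max']}",
            "-" * 46,
        ]
        total = sum(counts.values())
        for cat in _classify.CATEGORIES:
            lines.append(f"{cat:<12} {counts[cat]:>8}  "
                         f"({counts[cat] / max(total, 1):6.1%})")
        lines.append("-" * 46)
        lines.append(
            f"multiplet types: {len(self.multiplet_table)} "
            f"({len(self.filtered_table)} pass min_count="
            f"{self.model.params['min_count']})"
        )
        lines.append(
            f"network: {self.network.number_of_nodes()} nodes, "
            f"{self.network.number_of_edges()} edges, "
            f"total weight {_network.total_edge_weight(self.network)}"
        )
        top = self.multiplet_table.head(5)
        if len(top):
            lines.append("top multiplet types:")
            for r in top.itertuples(index=False):
                lines.append(f"  {r.composition:<20} n={r.frequency}")
        return "\n".join(lines)
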