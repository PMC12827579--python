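# ulmnet

Multiplet deconvolution and physical cell–cell interaction networks from
single-cell RNA-seq, via univariate linear model (ULM) signature scoring.

## The problem

Droplet scRNA-seq barcodes are usually treated as single cells, but a
fraction of barcodes capture two or more cells — often physically attached
neighbours that survived tissue dissociation.  Those multiplets are not just
artifacts: their composition records which cell types were touching in the
tissue.  This package identifies multiplet barcodes, deconvolutes their
cell-type composition, and aggregates the compositions into a weighted,
undirected *physical interaction network* between cell types.  Downstream
modules validate predicted interactions through ligand–receptor
co-expression inside predicted doublets and through cell-type colocalization
in deconvolved spatial transcriptomics spots.

## The method

For each cell type *k* a gene signature is derived by one-vs-all
differential expression on annotated reference cells (Wilcoxon rank-sum
test; minimum log2 fold change 0.25, minimum detection fraction 10%,
Bonferroni adjustment; top 100 genes by fold change with adjusted p < 0.05).

Every barcode *c* is then scored against every signature with a univariate
linear model over the full gene universe *G*:

    y_c(g) = β0 + β1 · x_k(g) + ε,    g = 1 … G

where *y_c* is the barcode's log-normalized expression and *x_k* carries the
signature's membership weights (weight for member genes, 0 elsewhere).  The
activity score is the slope t-statistic

    t = β1 / SE(β1),   df = G − 2,

with a two-sided p-value.  A signature is *active* when t > 1 and p < 0.05
(both strict).  Barcodes with one active signature are singlets; two,
doublets; three or more, multiplets; none, unassigned.  Doublet/multiplet
compositions are tallied, rare compositions (frequency < 10 by default) are
dropped, and each retained multiplet of size *k* contributes its frequency
to all C(k, 2) pairs of its member types, producing the interaction graph.

A negative-binomial simulator with planted marker blocks and additive
doublets provides ground truth for every stage, so the complete pipeline is
testable offline.

## Worked example

```python
import ulmnet as u

cfg = u.SimulationConfig(seed=1)          # 4 types, 500 singlets/type,
matrix, truth = u.simulate_cells(cfg)     # 100 doublets per adjacent pair
model = u.UlmNet(matrix, annotations=u.singlet_annotations(truth))
res = model.fit()
print(res.summary())
```

```
ULMnet multiplet deconvolution
==============================================
cells scored:        2300
genes in universe:   2000
signatures:          4 (A, B, C, D)
activity thresholds: t > 1.0, p < 0.05
----------------------------------------------
unassigned          0  (  0.0%)
singlet          1994  ( 86.7%)
doublet           306  ( 13.3%)
multiplet           0  (  0.0%)
----------------------------------------------
multiplet types: 5 (3 pass min_count=10)
network: 4 nodes, 3 edges, total weight 303
top multiplet types:
  B_C                  n=102
  C_D                  n=101
  A_B                  n=100
```

Of 2300 barcodes, 306 are called doublets; the three planted adjacent-pair
compositions (A_B, B_C, C_D) dominate with ~100 barcodes each, and after
frequency filtering the network contains exactly those three edges.  Against
the simulator's ground truth:

```python
labels = truth.set_index("barcode")["category"].map(
    lambda c: "singlet" if c == "singlet" else "doublet")
print(res.benchmark(labels).metrics())
# {'tp': 300, 'fp': 6, 'tn': 1994, 'fn': 0, 'sensitivity': 1.0,
#  'precision': 0.98, 'specificity': 0.997, 'accuracy': 0.997, 'f1': 0.99}
```

All 300 planted doublets are recovered (sensitivity 1.0) and only 6 of 2000
singlets are miscalled (precision 0.98).

## Command line

The same pipeline is available as subcommands that compose exactly like
`run`:

```bash
ulmnet simulate --seed 1 --out sim/
ulmnet run --counts sim/matrix --annotations sim/annotations.tsv \
           --truth sim/truth.tsv --out results/
ulmnet network --classification results/classification.tsv \
               --min-count 5 --out network.graphml
```

`run` writes every intermediate table plus `manifest.json` (parameters,
versions, stage counts) sufficient to reproduce the run.  Inputs can be 10x
Matrix Market directories or dense CSV/TSV; signatures travel as GMT or
TSV.

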