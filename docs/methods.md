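# Methods

## Model

The core statistic is the slope t-value of an ordinary least squares fit of
one barcode's log-normalized expression on one signature's membership
weights, taken over the full gene universe of the matrix.  Writing
`y ∈ R^G` for the barcode and `x ∈ R^G` for the signature vector (weight
for member genes, 0 elsewhere),

    β̂1 = Sxy / Sxx,   t = β̂1 / sqrt(σ̂² / Sxx),   σ̂² = RSS / (G − 2),

with a two-sided p-value from the t distribution at `G − 2` degrees of
freedom.  The statistic asks: *are this signature's genes systematically
above this cell's own average expression level?*  It is exactly invariant
to affine transforms of `y`, so the log base used in normalization (log2
here, natural log in many toolchains) cannot change a score — only the
nonlinear counts-per-10k rescaling matters, and that is fixed (`scale
= 1e4`).

Assumptions worth being explicit about:

- **Gene universe.**  All genes of the input matrix enter every fit with
  weight 0 outside the signature.  Scores from different universes (e.g.
  HVG-restricted matrices) are not comparable.
- **Independence across genes** is assumed by the OLS standard error.  Real
  expression data are co-regulated, so the p-values are approximate; the
  strict activity gate (t > 1 *and* two-sided p < 0.05, i.e. effectively
  t ≳ 1.96 at large G) is a decision rule, not a calibrated error
  guarantee.
- **Additivity of multiplets.**  A doublet's profile is modeled as the sum
  of its members' counts.  This is what makes a doublet score positively
  for both member signatures.

Degenerate cases are handled deterministically: constant predictor is an
error (a signature with one weight level across all genes is meaningless);
constant expression gives t = 0, p = 1 with a warning; zero residual
variance (perfect fit) caps t at ±1e6 and floors p at 1e-300 so downstream
arithmetic never sees infinities.  Zero-variance detection uses a relative
tolerance (`Syy ≤ 1e-12 · Σy²`) because a constant nonzero cell leaves
floating-point residue in the centered sum of squares.

## Signature generation

One-vs-all positive markers per annotated cell type: Wilcoxon rank-sum on
the log layer, exact enumeration when the pooled sample is ≤ 25 and
tie-free, otherwise the normal approximation with tie and continuity
corrections.  Genes are tested only if `max(pct_in, pct_out) ≥ 0.10` and
`log2fc ≥ 0.25`, where the fold change is computed on de-logged normalized
means with pseudocount 1 — the convention of the standard single-cell
toolchain.  Adjustment is Bonferroni over the genes tested per cell type
(Benjamini–Hochberg available).  Signatures keep the top 100 markers by
fold change among those with adjusted p < 0.05; ties are broken by
ascending adjusted p, then gene id, so signature construction is fully
deterministic.  Set sizes of 100–300 genes are recommended and sizes above
600 are warned against: larger sets buy a little sensitivity at a steady
cost in precision.  Weights default to binary membership; fold-change
weighting is available but changes nothing about the t-statistic's
invariances.

## Classification and network

A barcode's active set is `{k : t_k > 1 and p_k < 0.05}` with *strict*
inequalities at both thresholds.  The partition is total: 0 active →
unassigned, 1 → singlet, 2 → doublet, ≥ 3 → multiplet.  No multiple-testing
correction is applied across signatures per cell by default (the
`bonferroni_across_signatures` flag enables one).  Compositions are
canonical sorted labels joined by `_`, so column order can never affect a
call.

Multiplet types below a minimum frequency (default 10; 5 is a reasonable
choice for smaller tissues) are filtered *before* decomposition.  Each
retained type of size k adds its full frequency to all C(k, 2) member pairs
(clique expansion) — the only reading under which a triplet supports all
three of its pairwise contacts — giving the conservation identity
`Σ edge weights = Σ freq · C(size, 2)`, which is property-tested.

## Crosstalk validation

Within a selected doublet population (e.g. doublets pairing the B/plasma
group with the T group), a ligand or receptor is *expressed* in a doublet
iff its value strictly exceeds its mean across the selected doublets, and a
pair is co-expressed where both are; pairs co-expressed in ≥ 5 doublets are
retained.  The mean is taken over the selected units only — the rule is
self-referential to the population under test.  The identical rule serves
for spatial spots.  Spot colocalization uses inclusive thresholds: a spot
holds two groups when each group's *summed* proportion is ≥ 5%.  The
wording differs deliberately: "higher than its mean" is strict,
"at least 5%" is inclusive.  Pairwise cell-type colocalization across spots
is Spearman rank correlation (tie-corrected, two-sided p), checked in tests
against a rank-then-Pearson oracle.  Note that proportions are
compositional: renormalizing rows to sum to 1 induces negative dependence
between columns, so correlations should be read comparatively, not as
independent effect sizes.

## The synthetic benchmark

`simulate` draws cell-type-structured negative-binomial counts
(`variance = μ + μ²/dispersion`) from per-type mean profiles that are flat
at `base_mean` except on a disjoint block of `markers_per_type` genes
elevated `marker_fold`-fold.  Multiplets are element-wise sums of
independently drawn member cells, optionally binomially thinned by
`depth_scale` to emulate reduced per-cell depth in a shared droplet.  A
single seed feeds one named stream per stage, so the singlet and multiplet
draws are independently reproducible and runs are bit-identical.

Default conditions: 2000 genes, 4 types, 50 markers/type at 8-fold,
500 singlets per type, 100 doublets per adjacent type pair,
`depth_scale = 1`, `base_mean = 4`, `dispersion = 10`.  The depth was set
so that the generator honors its clean-benchmark contract — strong,
well-separated signatures with libraries (~9400 UMI per singlet over the
2000-gene universe) typical of a well-sequenced droplet run; at this depth
the full pipeline recovers planted doublets with sensitivity ~1.0 and
precision 0.95–0.98 across seeds, and the filtered network equals the
planted pair set.  Precision is the depth-sensitive metric: at shallow
depth (~1 count/gene) the per-gene log values are dominated by the
zero/nonzero dichotomy, the wrong-signature t distribution among singlets
(≈ N(−0.4, 1)) leaks past the t > 1.96 gate at ~0.6% per signature, and
precision drops to ~0.89.  `dispersion = 10` keeps biological noise low
(near-Poisson at moderate means), which is the point of a clean benchmark:
it isolates the method's behaviour from noise-model mismatch.

What the generator does *not* emulate — and therefore what passing tests do
not show about real data: ambient RNA, batch effects, gene–gene
correlation beyond the marker blocks, depleted (below-background) off-type
marker expression, cell-cycle structure, and random co-encapsulation
doublets with no biological meaning.  In real tissue the method cannot
distinguish biological doublets from random ones; frequency filtering and
spatial validation are the mitigations, not the solution.

## Numerical and design choices

- Log normalization is `log2(1 + count · 1e4 / total)` (base configurable);
  zeros map to zeros so sparsity is preserved, and the layer is recomputed
  from counts on each call (idempotent).
- QC keeps barcodes with detected genes ≥ 500, mitochondrial fraction
  < 0.25 (prefix-matched, `MT-`/`mt-` case-insensitive) and total UMI
  < 5000; bounds on the "at least" side are inclusive, on the "less than"
  side exclusive, following the usual phrasing of these filters.
- Scoring never densifies the cell dimension: per-signature sufficient
  statistics (Σx, Σx², X'Y, Σy, Σy²) are computed on the sparse layer, and
  the vectorized path is tested to 1e-8 against the per-vector fit.
- The exact/asymptotic Wilcoxon switch is at pooled n ≤ 25 with no ties;
  above it the approximation is within 0.02 of exact for group sizes ≥ 20
  (tested).
- Unassigned barcodes count as singlet predictions in benchmarking —
  conservative for a detector whose positive class is "doublet".
- The CLI resolves parameters as flag > YAML > default and every `run`
  writes a manifest with parameters, versions and stage counts.

## Known limitations

- P-values inherit the independence-across-genes assumption; treat activity
  calls as ranked decisions, not calibrated tests.
- Signature quality bounds everything: closely related types with shared
  markers will cross-activate, inflating doublet calls between them.
- The composition-exact benchmark mode is stricter than detection mode and
  is the right metric only when the reference annotation vocabulary matches
  the truth labels exactly.
- Spot-level deconvolution is consumed, not performed; errors in the
  upstream deconvolution propagate directly into colocalization estimates.
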