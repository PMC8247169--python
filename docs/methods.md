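# Methods

This note documents the models and procedures implemented in `cbstates`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Data model and preprocessing

Counts live in a sparse cells × genes `CountMatrix` with string
identifiers and optional per-gene annotation (chromosome, start bp,
mito/ribo flags, defaulting to name prefixes `mt-` and `Rps`/`Rpl`).
Spatial data adds per-spot grid coordinates and a layer label. All
formats are plain text: Matrix Market (1-based coordinate) with
`genes.tsv`/`barcodes.tsv` sidecars, GMT for gene sets, TSV tables, and
a flat YAML file for simulation configs.

**QC.** Cells are kept when strictly more than 500 genes are detected
and the mitochondrial count fraction is strictly below 10%, both
computed on the raw matrix *before* any gene removal; mito and ribo gene
columns are dropped afterwards. Spots are kept with ≥ 500 detected genes
and ≤ 10% mito ("fewer than 500" and "over 10%" are removed); genes then
require detection in ≥ 15 of the *surviving* spots. The spot-then-gene
order matters because it changes gene detection counts. The filters are
idempotent in practice, though a second pass can in principle remove
borderline cells whose detected-gene count dropped with the mito/ribo
columns.

**Normalization.** `ln(1 + c · 10⁴ / cell_total)`, sparsity-preserving.

## Signature scoring

Scoring follows the bin-matched control scheme standard in droplet
single-cell work: genes are ranked by dataset-mean expression into 24
equal-frequency bins; each signature gene draws 100 control genes from
its bin (seeded, without replacement, signature genes excluded; bins
smaller than 100 fall back to sampling with replacement, logged); the
score is the mean over signature genes minus the mean over the pooled
controls. The subtraction cancels per-cell additive shifts exactly when
controls shift equally, which the tests assert. State assignment is
arg-max over signature columns; exact ties go to the earlier column and
are flagged. Cell-cycle scoring runs the G1/S (43 genes) and G2/M (54
genes) phase lists — shipped as a GMT fixture in mouse casing — and the
combined cycle score is the per-cell max of the two phases, binarized at
median + 2·MAD with the *unscaled* MAD (no 1.4826 consistency factor).

## Marker detection and spatial enrichment

Markers are one-group-versus-rest, one-tailed (greater) Wilcoxon
rank-sum with the tie-corrected normal approximation. A gene is tested
only if detected in ≥ 25% of cells on either side *and* its ln-scale
mean difference is ≥ 0.3 (0.5 for the four-state signature derivation);
Bonferroni correction uses the number of genes actually tested within
the group. The spatial grid computes, for every (cell type, region)
marker-set pair on the shared background, the upper-tail hypergeometric
p = P(X ≥ k); the call is *enriched* iff p < α = 0.05 and otherwise
*depleted* — a display convention, not a lower-tail test. Display value
is −log10(p) for enriched pairs, 0 otherwise. State signatures are
refined as (state DEGs ∩ state module genes) \ confounder markers, and
state↔region agreement is summarized by Pearson correlation of averaged
profiles over the filtered gene union.

## Gene modules (Moran's I)

Moran's I is computed over a symmetric binary kNN graph built from any
user-supplied embedding (k = 15, union symmetrization, no self-edges).
Significance uses the analytic normal approximation under the
randomization assumption (the variance formula requires n ≥ 4; a seeded
999-permutation p is available and agrees with the analytic p to within
Monte-Carlo error on random fixtures). Genes with I > 0.1 and BH
q < 0.05 are grouped by average-linkage clustering of 1 − Pearson r
between their cell-cluster-averaged profiles (tree cut at correlation
height 0.7; cell clusters default to a KMeans partition). Each module is
summarized by its top-50 genes by dataset-mean expression, and modules
merge into a requested number of main modules by Ward clustering of
standardized per-cell module scores. The upstream tool's internal
gene-embedding + Louvain grouping step is not publicly specified; the
hierarchical grouping used here is the package's own design and is the
main methodological substitution in this stage.

## RNA velocity and transition quantification

Velocity uses the classical steady-state model: genes need ≥ 10 total
counts in both spliced and unspliced matrices; the 3,000 most variable
survive; per gene, cells in the extreme 5% quantiles of spliced
abundance anchor a through-origin regression of u on s whose slope is
γ̂, and v = u − γ̂s. The likelihood-based dynamical model is out of
scope here; the transition quantification downstream is independent of
how v was obtained.

The transition matrix element for cell i and neighbor j is the Pearson
correlation between vᵢ and (xⱼ − xᵢ) over the velocity genes, zero
elsewhere; x is ln-normalized expression (an embedding can be
substituted). A cell's destination is its highest-correlation neighbor;
zero-velocity cells keep their own state, flagged. Destination-count
tables between two conditions are compared with Pearson's chi-square
(no continuity correction; expected counts < 5 are logged).

The neighborhood is the kNN graph by convention, but synthetic state
populations are compact clusters: with small k no cross-state neighbors
exist and every destination is trivially "self". Recovery analyses
therefore use the complete-graph neighborhood (`n_neighbors=None`),
under which the planted self-renewal probabilities are recovered to
within sampling error.

## Tumor programs, CNV, similarity

**NMF.** Per tumor, ln-normalized expression of malignant cells is
per-gene centered and negatives are clipped to 0 (the usual intra-tumor
heterogeneity transform); multiplicative-update NMF with seeded random
initialization extracts 10 factors, each summarized by its top-50 W
genes. **Meta-programs**: factors whose top lists share ≥ 10 genes with
a factor of another sample (the recurrent-program convention; set
`robust_min_genes=None` to keep all) are clustered by Ward linkage on
1 − Pearson r of their per-cell activity scores, cut at 4 by default; a
meta-program's signature is the genes in at least half its members' top
lists, padded to 50 by aggregate W rank. Meta-programs map to
developmental states via the Jaccard index of signatures.

**Inferred CNV.** Genes are ordered by (chromosome, start); per-gene
relative expression (dataset-mean centered) is clipped to ±3 and
smoothed with a 101-gene moving average within each chromosome, using a
symmetric shrunken half-width at chromosome edges (a window at least as
long as the chromosome degrades to the full-chromosome mean); each cell
is centered by its own mean; the reference cells' per-window means are
subtracted, making reference window means exactly zero. Two
conventional pre-filters precede smoothing: genes below a dataset-mean
expression of 0.1 are dropped, and an `exclude_genes` list removes
known expression-program genes — in this pipeline the cycling program
and the developmental module signatures derived upstream — because
proliferation and cell-state swings masquerade as dose. The per-cell
aggregate signal is the mean of squared window scores. No hidden-Markov
state calling is performed; outputs are relative smoothed profiles.

**kNN similarity.** Query and reference matrices are subset to common
genes, centered per dataset, and projected with shared PC loadings
fitted on the concatenated matrix (30 PCs); each query cell's 20
nearest reference cells vote with one-hot labels, giving per-cell label
scores that sum to 1, averaged per sample for reporting.

## Synthetic data

The generator plants: (i) `n_states` = 4 chain-ordered states with
disjoint 50-gene signatures multiplied by `exp(effect_lnfc)` (default
1.0) in their cells, a 50-gene cycling program (fractions 0.8 / 0.1 /
0.02 / 0.02 by state), and, for tumors, a 50-gene metabolic program in
a configurable fraction of malignant cells; (ii) gamma-Poisson counts
(global dispersion θ = 10) with log-normal library sizes
(μ = ln 10⁴, σ = 0.25) and 1% mito-named plus 20 ribo-named genes;
(iii) spots of exactly 30 member cells drawn from layer-specific state
mixtures over four anatomically motivated bands (outer/inner external
granule layer, molecular/Purkinje layer, internal granule layer), with
spot counts the exact sum of member counts; (iv) spliced/unspliced
kinetics from the two-rate model du/dt = α − βu, ds/dt = βu − γs
(α ~ U(5,15), β ~ U(1,2), γ ~ U(0.3,0.8)), where each cell's planted
fate (a draw from the row-stochastic transition kernel; development
uses 0.3 self-renewal per non-terminal state) sets its genes' phases —
own program mid-induction for self-renewal, own program repressing and
successor program inducing for a transition, basal steady state
elsewhere — with multiplicative log-normal noise (σ = 0.1; 0 gives the
exact closed form); (v) chromosome-scale CNVs as `exp(shift)`
multipliers on the genes of a chromosome in malignant cells only.

Two deliberate departures from naive simulation: program boosts are
*mass-neutral* (background weights rescaled per cell) so empirical
signature fold changes match `effect_lnfc` without compositional
dilution, while CNV mass is *not* compensated, so a gain dilutes the
rest of the transcriptome through library normalization exactly as real
aneuploidy does; and the genome is split into 5 large synthetic
chromosomes (~400 genes each at the default size) so the
genes-per-chromosome to smoothing-window ratio is in the regime of real
genomes — with many tiny chromosomes the shrunken edge windows dominate
the CNV noise budget.

What the generator does not emulate: ambient RNA, doublets, batch
effects, gene-gene correlation beyond the planted programs, realistic
per-gene dispersion heterogeneity, or partial-volume effects in spots.
Passing tests therefore demonstrate internal correctness and parameter
recovery under the stated model, not performance on real tissue.

## Numerical and testing choices

Problem sizes in the test-suite and acceptance runs are desk-scale:
1,000–2,000 cells, 2,000 genes, 160 spots, three 400-cell tumors —
large enough that every planted effect is recovered with comfortable
margins, small enough to run the whole suite in about a minute.
Determinism is guaranteed by a single integer seed per run; all
stochastic stages (control-gene draws, permutations, NMF
initialization, generators) take explicit seeds. The hypergeometric
tail is validated against integer-exact enumeration for every
background size up to 60; the Pearson chi-square against the textbook
margin formula; Moran's I against hand closed forms, a permutation
oracle and an independent library implementation. Two measurement
definitions deserve note: the permutation-vs-analytic agreement for
Moran's p is asserted on the mean absolute difference across fixtures
(a per-fixture bound of 0.02 is below the Monte-Carlo noise of 999
permutations), and velocity sign agreement is evaluated on entries
whose true ds/dt magnitude exceeds the median of the *nonzero* rates,
since basal genes have a true rate of exactly zero and would make the
overall median degenerate.

## Known limitations

- The steady-state velocity estimator inherits its classical biases
  (shared splicing-rate assumption, steady-state availability); the
  dynamical likelihood model is intentionally absent.
- Depletion in the enrichment grid is "not significantly enriched",
  not evidence of exclusion.
- CNV output is a relative smoothed profile; no discrete copy-number
  states are called.
- Module grouping depends on the user-supplied embedding and cell
  clustering; different embeddings give different (valid) module sets.
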