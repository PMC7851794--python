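# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical conventions. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Differential-expression engines

**Per-gene test (bulk, microarray).** Counts are depth-normalized by
median-of-ratios size factors (total-count scaling when no gene is positive
in every sample; only size-factor ratios matter downstream) and moved to
log2 with a pseudocount (default 1). Each gene then gets a Welch *t* test
with Welch–Satterthwaite degrees of freedom, two-sided *p*, and
Benjamini–Hochberg *q* within the contrast. Degenerate genes with zero
variance in both groups get *p* = 1 when the means agree, and the machine
minimum when they do not. A gene is a DEG at fold change > 2
(|log2FC| > 1) and *p* < 0.01; the marker screen uses the up-regulated side
only, since it seeks genes induced in TI-Tregs, while signature construction
keeps both directions (repressed genes are part of a transcriptional
program).

**Characteristic Direction.** Differential expression as the unit normal of
a regularized linear-discriminant hyperplane: *b* ∝ (γI + (1−γ)Σ̂)⁻¹Δμ with
Σ̂ the pooled within-group covariance and γ ∈ [0, 1] the shrinkage toward
the identity (default 0.5). Because genes vastly outnumber samples, Σ̂ is
singular in gene space; the solve is performed in the orthonormal subspace
spanned by the grand-mean-centered samples, which contains Δμ and every
within-group deviation, and shrinking toward the identity commutes with the
rotation, so the subspace solution equals the (regularized) full-space one.
At γ = 1 the direction reduces exactly to the normalized mean difference.
The vector is oriented so that *b*·Δμ > 0, making "positive score" mean
"induced in the test group" — the orientation is otherwise arbitrary. A
gene's score is *b*ᵢ², so scores sum to 1 and the uniform model assigns
1/n; genes above 1/n (and positively signed, for induced-gene selection)
are kept.

**Two-part zero-inflated test (single cell).** Part 1: two-sided Fisher
exact test on the per-group zero/non-zero 2×2 table. Part 2: two-sided
Wilcoxon rank-sum on depth-normalized non-zero values (cells scaled to the
median library size; the zero pattern is unaffected by scaling). Parts are
combined by Fisher's method (χ², 4 df); when a group has no non-zero cells
the defined part stands alone. This targets the same two signals —
detection-rate shifts and magnitude shifts — that dedicated zero-inflated
single-cell DE models decompose; it is not a ZINB mixture and assigns no DE
subtype labels.

## Gene-set algebra and orthologs

Derived sets carry provenance tuples recording every input and operation, so
the final marker list's derivation is reconstructible. Ortholog maps are
strictly one-to-one; reciprocal-best-hit derivation keeps (m, h) only when
each is the other's unique best score — ties drop the pair rather than being
resolved arbitrarily, trading recall for determinism. Overlap significance
between two sets in an explicit finite universe is the one-sided
hypergeometric upper tail; the universe is a required argument, never
guessed from the inputs.

## Treg coregulatory network

Built from Treg samples only (three Treg populations × replicates, nine
samples by default). Genes whose maximum expression never exceeds the
expression floor are removed; the floor is the maximum over
lineage-negative control genes (B-cell/macrophage markers, which a pure
T-cell sort should not express) of each control's per-sample maximum. The
max-of-maxima is the strictest reading; mean-of-maxima is available as an
option. Rows are then scaled to unit root-mean-square — per gene, so that
the values entering correlation are scale-free; Pearson correlation is
invariant to this, and the axis choice is a convention, not an inference
step. Every unordered pair is tested with t = r√((m−2)/(1−r²)), df = m−2,
two-sided; |r| = 1 caps at p = 0. Edges require p below the threshold
(default 0.01). With nine samples this demands |r| ≳ 0.8, so the network is
sparse and dominated by genuinely coexpressed genes.

**Modularity validation.** The within-group connectivity of a gene group is
the number of edges with both endpoints in the group. Its significance is
assessed against random node groups of the same in-network size, drawn
uniformly without replacement; the sampled empirical *p* uses an add-one
correction (1 + exceedances)/(1 + draws) so it is never zero — at 100,000
draws the strongest possible outcome is *p* < 0.00001. When C(n, k) ≤ 10⁵
the null is enumerated exhaustively instead. The null randomizes node
groups, not edges: connectivity is a node-group statistic, and resampling
groups of the observed size directly answers "is this group more
interconnected than a random group of equal size"; degree-preserving edge
rewiring is deliberately out of scope.

## Context-associated centrality

For each network gene, the universe is the node set minus the focal gene;
the context signature is intersected with that universe. The CAC *p*-value
is the one-sided hypergeometric upper tail of the overlap between the
gene's neighbors and the in-universe signature, BH-adjusted across all
nodes; CAC = −log₁₀(q) (q floored at 1e−300 to keep the score finite).
Ranking is by ascending *p*, ties broken by descending overlap and then
gene id, so top-decile membership is reproducible. Degree-0 genes get
*p* = 1 and a flag. Restricting the universe to network nodes (rather than
all measured genes) makes CAC a property of the network context; with a
uniformly random signature, high- and low-degree genes score alike, which
distinguishes CAC from degree centrality.

## Clinical outcome

The marker score is log₂((marker + c)/(FOXP3 + c)) with pseudocount c = 1 —
a ratio rather than a difference because bulk expression is
composition-confounded and the ratio approximates per-Treg expression; the
pseudocount makes the score defined at zero expression. Stratification
takes scores strictly above the (1−upper) quantile as High and strictly
below the lower quantile as Low (defaults 0.3/0.3); subjects tied exactly
at a cut are excluded and logged, so group membership never depends on sort
order. Kaplan–Meier curves and the two-sided log-rank test come from
lifelines; Mann–Whitney U uses exact enumeration for combined n ≤ 12
without ties and the tie-corrected normal approximation otherwise.
Cox modeling and multivariate adjustment are out of scope.

## Synthetic data

The generators define the study conditions; every pipeline claim about
recovery is a claim about these conditions.

* **Bulk (six populations × 3 replicates, 2,000 genes).** Negative-binomial
  counts (Gamma–Poisson, var = μ + αμ²) with common dispersion α = 0.01 —
  sorted, pure cell populations from isogenic mice sit at the low end of
  observed RNA-seq dispersions for well-expressed genes. Gene abundances are
  log2-normal (mean 6, sd 1.5). Planted markers (30, +2 log2 units in
  TI-Treg only) draw abundances from log2-N(7, 0.5): the screen's premise is
  markers expressed at screenable levels, as the real Treg surface genes
  are. Library sizes are log-normal with CV 0.2 so the normalization path
  matters. Coregulated modules (five of 20 genes, abundance log2-N(7, 0.5))
  share a per-sample latent factor with amplitude 1.5 log2 units: the hub
  carries the factor with loading 1 (it drives the module), members load
  √ρ, giving member–member latent correlation exactly ρ (default 0.9) and
  hub–member correlation √ρ — hub edges are the strongest, which is what
  makes a hub a hub. The context signature is a fixed fraction (default
  0.5) of each module's non-hub members. Six negative-marker genes sit at
  the ~1-count technical floor.
* **Single cell (four populations × 200 cells).** Same NB family on a
  4-log2-lower abundance scale, thinned by dropout: detection probability
  expit(a + b·log2(μ+1)), defaults (−1.0, 0.8), so lowering the intercept
  raises the zero fraction and abundant genes are rarely dropped. Markers
  are induced in tumor Tregs only; the pipeline plants a configurable
  conserved fraction (default 0.5) of the bulk markers' orthologs.
* **Microarray (three conditions × 5 replicates).** Log-normal intensities
  with replicate sd 0.35 log2 (typical array repeatability); one set
  (+2 log2) in the chronic condition only, another in chronic and acute, to
  exercise the subtraction rule. Shares the bulk gene universe so the core
  signature intersection is meaningful.
* **Cohort (n = 300).** Latent score z ~ N(0,1); exponential event times
  with hazard λ₀·HRᶻ (λ₀ from a 24-unit baseline median survival, HR
  default 2.5); independent Uniform(0, τ) censoring with τ calibrated
  numerically to the target censoring fraction (default 0.3) — uniform,
  independent censoring satisfies the non-informative assumption of the KM
  estimator. Response is Bernoulli with log-odds −z. Marker and normalizer
  expression are constructed so the log2 ratio recovers z.

All randomness flows from one seed through named, CRC-keyed substreams, so
any generator is reproducible independently of call order.

**What the generators do not emulate:** batch effects, UMI/ambient-RNA
structure, gene-length and GC bias, mean–dispersion trends, doublets,
cell-cycle covariation, correlated censoring, or the sample sizes of any
public dataset. Passing the planted-truth tests therefore shows the
pipeline's logic is correct and well calibrated under clean, strongly
planted conditions; it does not bound performance on real data, where DE
engines with information sharing across genes (e.g., NB GLMs with dispersion
shrinkage) would be substituted for the built-in engines via the same
selection interface.

## Numerical conventions and degenerate inputs

BH is used wherever a *q*-value is required. Pseudocounts default to 1.
Empty DEG tables warn and yield empty sets; all-zero samples, absent
negative markers, degenerate (all-equal) score vectors, hazard ratios ≤ 0,
and cohorts under 20 subjects are errors. Constant gene rows are excluded
from correlation with a flag. Writers round to 6 significant digits and
round-trip losslessly at that precision. The pipeline's stages write outputs
and a completion summary before the next stage starts; a rerun recomputes
exactly the stages whose outputs are missing, plus their dependents, and
identical configuration + seed yields a byte-identical manifest.

## Scale choices

The default synthetic study (2,000 genes, 18 bulk samples, 800 cells,
n = 300 cohort) is sized so the full pipeline runs in seconds and the
repeated-seed acceptance checks (100 network/CAC studies, 1,000 null
cohorts, 200 power cohorts) complete in minutes on one CPU, while keeping
every statistic in the regime where its asymptotics are exercised
(thousands of genes, hundreds of cells/subjects).

## Known limitations

* The connectivity null's "random groups" reading is one of two defensible
  interpretations of a permutation null for group connectivity (the other
  being random edge sets); the node-group reading is implemented because
  the statistic is a node-group property.
* The CAC universe excludes genes outside the network; enrichment against
  all measured genes would shift absolute *p*-values but rarely the ranking.
* The built-in DE engines are deliberately generic surrogates; they share
  the published selection thresholds but not the internals of NB-GLM,
  ZINB-mixture, or moderated-*t* packages.
* FOXP3 normalization is a log-ratio with pseudocount 1; a linear-scale
  ratio is available by stratifying on raw expression columns instead.
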