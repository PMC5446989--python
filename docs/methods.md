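# Methods

## Scope and data model

The package analyses tissue-resolved expression atlases of developing
plant organs. An *atlas* is a genes × samples matrix of normalised log2
expression values plus a sample sheet assigning every sample to a
(*set*, *tissue*, *replicate*) triple. A **set** is one experiment's group
of co-sampled tissues (for example FACS-sorted root cell layers, or the
regions of a seed captured at one embryo stage); a **tissue** may recur in
several sets under the same name (the endosperm regions and seed coat
appear at every seed stage), and the number of *distinct* tissue types T
is what downstream diversity calculations use. The default topology has
four sets — one root set of five concentric layers and three seed stages —
covering T = 10 distinct tissue types with 3 replicates each
(54 samples).

All comparisons are confined to tissue pairs *within* a set. Comparing
across organs or developmental stages would confound tissue identity with
organ- and stage-level programmes, so it is deliberately unsupported.

## Synthetic data generator

The generator emulates the real study design so every downstream stage can
be scored against known planted truth:

- Expression: gene g's baseline is drawn once from
  Normal(μ₀, σ_gene) (defaults μ₀ = 8, σ_gene = 2 log2 units — the
  log-normal spread of expression levels across genes that makes
  biological replicates correlate strongly); each sample adds i.i.d.
  replicate noise Normal(0, σ) with σ = 0.25 log2 units, typical
  array-level reproducibility after normalisation. Values are generated
  directly on the log2 scale; simulating raw intensities would add
  nothing testable.
- Planted gradients: a fraction (default 10%) of genes get one uniformly
  chosen (set, tissue) whose mean is offset by Δ = 2.0 log2 units (a
  4-fold change, the size of effect the detection defaults are meant to
  catch). The per-gene baseline cancels in every between-tissue
  comparison, so planting is orthogonal to it.
- Families: domain annotations with log-normal family sizes
  (median ≈ 14, log-sd 0.6 — family-size distributions are close to
  straight lines on log-normal probability axes). Planted enriched
  families draw each member from the planted gradient genes with
  probability 0.9. Planted families are pairwise disjoint: a gene carries
  at most one planted domain, mirroring how domain families largely
  partition a genome and keeping planted truth stable under the
  non-overlap curation step.
- Species counts: family f's count in species s is Poisson with rate
  base·factor(f,s)·N_s/N_ref, so factor = 1 everywhere means family sizes
  merely track genome size; zero-inflation emulates families absent from
  the simplest species. Default genome totals are the published gene-locus
  counts of the four reference genomes (17,741 / 32,926 / 27,416 / 42,189
  for the alga, moss, eudicot and monocot respectively).
- Localization: one consensus compartment label per gene from a fixed
  8-term vocabulary.

What the generator does **not** emulate: probe-level array artefacts,
cross-hybridisation, correlated noise between tissues of one biological
specimen, families whose members split across platforms, or multi-locus
gene models. Passing recovery tests therefore demonstrates the pipeline's
statistical correctness under the declared noise model, not robustness to
every artefact of real atlases.

A deterministic 66-family reference fixture (`reference_counts_fixture`)
reproduces the curated catalogue's summary shape — per-species medians
41/46/21/2 and 25 families absent from the alga — from smooth log-spaced
quantiles; it is synthetic and not copied from any published table.

## Gradient detection

**Reproducibility filter.** For each (set, tissue), pairwise Pearson
correlations between replicate columns are computed; while any replicate's
median pairwise correlation is below the threshold (default 0.9), the
worst replicate is removed and correlations re-evaluated. Greedy removal
matters: with three replicates the median for a *good* replicate is the
midpoint of its two pairwise correlations, so a single corrupt mate would
otherwise drag its well-behaved partners below the threshold. A tissue
left with < 2 replicates invalidates its whole set (logged).

**Test statistic.** The default is an empirical-Bayes moderated t. Per
gene, the within-tissue variance is pooled across all tissues of the set
(one-way layout, d residual df). The per-gene variances s²_g are modelled
as s₀²·F(d, d₀); (d₀, s₀²) are estimated by matching the mean and variance
of log s²_g (digamma/trigamma moments, with a Newton trigamma inverse),
and the moderated variance is s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d) with
d₀ + d degrees of freedom (normal reference when d₀ = ∞, which is the
correct limit when variances are homoscedastic across genes). The
motivation is numeric: with 3 replicates a per-gene Welch t has ≈ 4 df, so
even an exactly reproduced 4-fold change has p ≈ 6·10⁻⁴ — too large to
survive FDR control across the ~2·10⁴ (gene, pair) tests of a set. Whether
a real effect is detectable would then depend almost entirely on how many
other effects exist, which is statistically indefensible for this design.
Variance moderation is the established remedy for small-n expression
designs; a plain Welch t remains available (`statistic="welch"`). The
moderated statistic is cross-checked in the test suite against an
independent Bioconductor implementation of empirical-Bayes moderation on a
heteroscedastic fixture (agreement to 10⁻¹⁰ in p).

**Calling.** Within each set, p-values from all tested (gene, pair)
combinations are BH-adjusted together; a GradientCall requires q < α
(default 0.05) and |log2 fold| ≥ 1.0 (2-fold). The peak tissue is the pair
member with the larger mean. Degenerate tests (zero variance and equal
means) are suppressed and logged; zero variance with unequal means is
treated as an exact difference (p = 0), which makes the noiseless limit
behave correctly. By default all within-set pairs are tested; an explicit
adjacency list can restrict testing to anatomically neighbouring layers.
The gradient-gene list is the deduplicated, lexicographically ordered
union of called genes across sets.

## Family catalogue and enrichment

One candidate family per domain accession with ≥ 10 member genes (one gene
per locus). Domains whose member sets have Jaccard similarity ≥ 0.75 are
unioned by transitive closure — the threshold is set so that domains
co-occurring in ~19 of 21 genes (Jaccard ≈ 0.9) merge while casual overlap
does not. Manual merges (forced unions) and manual splits (explicit gene
lists carved into a new family) stand in for by-hand curation such as
separating soluble kinases from receptor-like kinases. Genes belonging to
several merged families are assigned to the family containing their rarest
constituent domain (the most specific annotation), making the catalogue
non-overlapping; families dropping below the size floor afterwards are
removed. Because merging always restarts from the raw domain annotation
recorded in the catalogue, the operation is idempotent.

Enrichment of a family among the gradient genes is the upper-tail
hypergeometric probability against the platform universe (the genes
measured by the chip, not the whole genome — the gradient list can only
contain measured genes), BH-adjusted across families; enriched means
q < α. The same machinery applied to a gene → keyword table tests
annotation keywords (e.g. hormone names).

## Expansion analysis

The genome-size-corrected Poisson test asks whether a family in species 2
is larger than expected from its size in species 1 after accounting for
overall genome growth: λ = max(k₁, 1)·N₂/N₁ and p = P(Poisson(λ) ≥ k₂),
computed as the upper-tail survival function. The zero-count floor is a
deliberate conservative choice: with k₁ = 0 the raw expectation is 0 and
any non-zero k₂ would be infinitely significant; flooring the rate at one
expected gene (λ = N₂/N₁) instead requires the observed count to beat what
a single ancestral gene would predict. The test is one-sided at α = 0.05
by default with no correction across families (fractions of "significantly
expanded" families are reported as raw rates); a BH option exists and can
only reduce the count. Medians use the midpoint convention; probability-
plot coordinates pair Φ⁻¹((i − ½)/n) with log₁₀ size for non-zero counts.
The gradient-versus-background size comparison is a one-sided Mann–Whitney
U (midranks, normal approximation with continuity correction), per
species.

## Tissue diversity

Members of a family that received at least one gradient call are each
assigned to one tissue: the tissue with the highest mean expression among
the tissues of the sets where the gene was called (when a tissue type
appears in several called sets, the largest per-set mean represents it).
Ties are broken by the fixed tissue ordering and logged. Uncalled members
contribute nothing — the measure characterises where a family's *gradient*
members peak, not its overall expression breadth. An alternative mode
splits each member's unit weight evenly across all distinct tissues in
which it was the peak of a significant call, yielding fractional counts.

For a count vector n₁…n_T with n = Σnᵢ and pᵢ = nᵢ/n, the diversity is

    H = −Σ_{nᵢ>0} pᵢ ln pᵢ        D = H / ln T ∈ [0, 1]

with the 0·ln 0 = 0 convention. D = 0 iff exactly one tissue is populated;
D = 1 iff all T tissues are populated equally; D is invariant under tissue
permutation and count rescaling. The log base cancels in the ratio. T is
the number of distinct tissue types in the atlas (default 10), not the
number of tissue slots across sets — a family peaking in the seed coat at
three stages is specialized, not diverse. Families with D < 0.5 (strict)
are labelled "specialized", the rest "diverse".

## Localization comparison

Each gene carries one consensus compartment label from a configurable
vocabulary (extracellular/apoplast, plasma membrane, cytosol, nucleus,
plastid, ER, mitochondrion, other); unassigned genes count as "other".
For a subset versus its universe, each compartment gets both
hypergeometric tails: over-represented if P(X ≥ k) < α, under-represented
if P(X ≤ k) < α, on raw p-values by default (BH optional). The two flags
are mutually exclusive for any α ≤ 0.5.

## Numerical and design notes

- All randomness flows from a single integer seed per run; regeneration is
  bit-identical.
- Tail probabilities use scipy's hypergeometric/Poisson survival
  functions; the test suite pins them against exact rational enumeration
  (N ≤ 60) and term-by-term pmf summation (λ ≤ 100, k ≤ 500) at 10⁻¹².
- BH adjustment is statsmodels' `multipletests(method="fdr_bh")`.
- Problem sizes in the test suite (2000-gene atlases, 20-seed batteries,
  10⁴-family null simulations) were chosen as the smallest sizes at which
  the binomial/Monte-Carlo error of each check is well below its margin.
- TSV is the universal interchange format; writers and readers are exact
  round-trips, and each pipeline run writes a manifest with parameters,
  seed and output checksums.

## Known limitations

- The moderated model assumes within-set homoscedasticity across tissues
  for a given gene; strongly tissue-dependent variance would mildly
  miscalibrate it.
- The reproducibility filter uses a global correlation over all genes; it
  cannot detect tissue-swap errors that preserve overall correlation
  structure.
- The expansion test treats paralog counts as independent Poisson draws;
  real family evolution (bursts of tandem duplication, whole-genome
  duplication) is over-dispersed, so raw p-values are optimistic for such
  families.
- Member→tissue assignment picks a single peak tissue; genes with genuine
  multi-tissue plateaus are represented by one tissue in the default mode.
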