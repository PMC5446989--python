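# gradfam

Analysis toolkit for finding **gradient genes** — genes whose expression
differs significantly between neighbouring tissues of the same organ — and
for characterising the gene families they belong to: which families are
over-represented among gradient genes, whether those families expanded
across species of increasing body-plan complexity, how their products are
distributed across subcellular compartments, and how evenly their members
spread across tissues.

The intended setting is a collection of replicated, normalised log2
expression atlases of plant tissues (e.g. FACS-sorted root cell layers and
laser-microdissected seed regions), protein-domain annotations defining
gene families, and per-species family-count tables from annotated genomes.
A first-class synthetic-data module generates all of these inputs with
known planted truth, so the full pipeline is testable end to end without
any download.

## Methods at a glance

- **Gradient detection.** Replicates failing a replicate-to-replicate
  Pearson-correlation filter are dropped. For each tissue pair within a
  set, a moderated two-sample t statistic is computed on log2 values: the
  per-gene within-tissue variance pooled across the set is shrunk toward a
  scaled-F prior fitted to all genes (empirical Bayes), and p-values are
  Benjamini–Hochberg adjusted across all (gene, pair) tests in the set. A
  call requires q < α and |log2 fold| ≥ a minimum effect.
- **Family enrichment.** Families are protein-domain member sets with ≥ 10
  genes; domains with Jaccard-similar membership are merged (with optional
  manual curation). Over-representation among gradient genes uses the
  upper-tail hypergeometric probability
  p = Σ_{i≥k} C(K,i)·C(N−K, n−i)/C(N,n) against the platform universe,
  BH-adjusted across families.
- **Expansion analysis.** For a family with k₁ members among N₁ gene loci
  of species 1, the genome-size-corrected expectation in species 2 is
  λ = max(k₁,1)·N₂/N₁ and an observed count k₂ is a significant expansion
  when P(Poisson(λ) ≥ k₂) < α. Per-species medians, absence counts,
  log-normal probability-plot coordinates, and a one-sided Mann–Whitney
  comparison against the background of all families are also provided.
- **Tissue diversity.** Each called family member counts toward its
  peak-expression tissue; the family's diversity is the normalised Shannon
  entropy D = −Σ pᵢ ln pᵢ / ln T ∈ [0,1] of that count vector — 0 when all
  members sit in one tissue ("specialized"), 1 when they occur with equal
  frequency in all T tissues ("diverse").
- **Localization.** Per-compartment hypergeometric tails compare the
  compartment composition of a gene set against its universe.

## Worked example

Run the full pipeline on synthetic data (4 tissue sets over 10 tissue
types, 3 replicates, 2000 genes, 10% planted gradient genes at 2.0 log2
effect, 5 planted enriched families):

```bash
gradfam run --outdir demo --seed 1
```

prints

```json
{
 "n_gradient_genes": 200,
 "n_enriched_families": 5,
 "diversity_summary": {
  "median_D": 0.7364516253185087,
  "n_specialized": 0,
  "n_families": 5
 }
}
```

All 200 planted gradient genes are recovered and all 5 planted enriched
families are flagged. `demo/family_enrichment.tsv` holds the per-family
hypergeometric results, e.g.

```
family_id  universe_size  family_size  set_size  overlap  p_value    q_value    enriched
D0004      2000           41           200       35       1.54e-30   5.08e-29   True
D0000      2000           16           200       15       8.99e-15   1.48e-13   True
```

(35 of family D0004's 41 members are among the 200 gradient genes, far
more than the ~4 expected by chance). The diversity summary says the
flagged families spread their members over many tissues (median D ≈ 0.74)
rather than piling into one. Individual stages are available as
`gradfam {simulate,gradients,enrich,expand,diversity,localize}`; every
output is TSV/JSON with a manifest recording parameters, seed and
checksums.

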