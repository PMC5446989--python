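"""Domain-defined gene families and over-representation testing.

Families are assembled one-per-protein-domain accession, keeping only
domains with at least ``min_size`` member genes in the reference species
(one gene per locus).  Because a gene model often carries several
accessions describing the same underlying family (e.g. the three
multicopper-oxidase domains co-occurring in 19 of 21 multicopper-oxidase
genes), domains whose member sets have Jaccard similarity above a
threshold are merged by transitive closure, with config-driven manual
merges and splits standing in for by-hand curation.  Over-representation
of a family among the gradient genes is assessed with the upper-tail
hypergeometric test against the platform universe, BH-corrected across
families.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 10
DEFAULT_JACCARD = 0.75

ENRICHMENT_COLUMNS = (
    "family_id", "universe_size", "family_size", "set_size", "overlap",
    "p_value", "q_value", "enriched",
)


class CatalogError(ValueError):
    """Raised on malformed annotations or curation config."""


@dataclass
class FamilyCatalog:
    """Curated gene families.

    Attributes
    ----------
    families
        family_id -> member gene ids (reference species).
    provenance
        family_id -> constituent domain accessions.
    domain_members
        original per-domain member sets (kept so that curation always
        operates on the raw domain annotation, making merging idempotent).
    """

    families: dict[str, set[str]]
    provenance: dict[str, tuple[str, ...]]
    domain_members: dict[str, set[str]]
    min_size: int = DEFAULT_MIN_SIZE

    def member_counts(self) -> pd.Series:
        return pd.Series({f: len(m) for f, m in self.families.items()}, name="size")


def build_catalog(annotations: pd.DataFrame, min_size: int = DEFAULT_MIN_SIZE) -> FamilyCatalog:
    """One family per domain accession with >= ``min_size`` member genes.

    ``annotations`` has columns (gene_id, domain_id); duplicate rows are
    deduplicated with a log note.
    """
    if annotations.empty:
        raise CatalogError("annotation table is empty")
    for col in ("gene_id", "domain_id"):
        if col not in annotations.columns:
            raise CatalogError(f"annotation table missing column {col!r}")
    n_raw = len(annotations)
    annotations = annotations.drop_duplicates(["gene_id", "domain_id"])
    if len(annotations) < n_raw:
        logger.info("deduplicated %d duplicate (gene, domain) rows", n_raw - len(annotations))

    domain_members = {
        dom: set(group["gene_id"])
        for dom, group in annotations.groupby("domain_id", sort=True)
    }
    families = {d: set(m) for d, m in domain_members.items() if len(m) >= min_size}
    provenance = {d: (d,) for d in families}
    return FamilyCatalog(families, provenance, domain_members, min_size)


def _jaccard(a: set[str], b: set[str]) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / len(a | b)


def merge_redundant_domains(
    catalog: FamilyCatalog,
    jaccard_threshold: float = DEFAULT_JACCARD,
    manual_merges: list[list[str]] | None = None,
    manual_splits: dict[str, list[str]] | None = None,
) -> FamilyCatalog:
    """Merge domains with near-identical membership into single families.

    Domains whose member-set Jaccard similarity >= ``jaccard_threshold``
    are unioned by transitive closure.  ``manual_merges`` (lists of domain
    accessions to force together) and ``manual_splits`` (new_family_id ->
    explicit gene list carved out of whatever family currently holds those
    genes) emulate by-hand curation.  Genes belonging to several merged
    families are assigned to the family containing their most specific
    (rarest) domain, so the final catalogue is non-overlapping; families
    falling below ``min_size`` after this resolution are dropped.

    Merging always starts from the raw domain annotation recorded in the
    catalogue, so the operation is idempotent.
    """
    if not 0 < jaccard_threshold <= 1:
        raise CatalogError("jaccard_threshold must lie in (0, 1]")
    domains = sorted(
        d for d, m in catalog.domain_members.items() if len(m) >= catalog.min_size
    )
    member_of = {d: catalog.domain_members[d] for d in domains}

    # union-find over domains
    parent = {d: d for d in domains}

    def find(d: str) -> str:
        while parent[d] != d:
            parent[d] = parent[parent[d]]
            d = parent[d]
        return d

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for a, b in itertools.combinations(domains, 2):
        if _jaccard(member_of[a], member_of[b]) >= jaccard_threshold:
            union(a, b)
    for group in manual_merges or []:
        unknown = [d for d in group if d not in parent]
        if unknown:
            raise CatalogError(f"manual merge names unknown domain(s): {unknown}")
        for a, b in zip(group, group[1:]):
            union(a, b)

    components: dict[str, list[str]] = {}
    for d in domains:
        components.setdefault(find(d), []).append(d)

    families: dict[str, set[str]] = {}
    provenance: dict[str, tuple[str, ...]] = {}
    for doms in components.values():
        doms = tuple(sorted(doms))
        fam_id = "+".join(doms)
        families[fam_id] = set().union(*(member_of[d] for d in doms))
        provenance[fam_id] = doms

    # non-overlap: a gene in several families goes to the one holding its
    # rarest domain (ties broken by domain accession order)
    gene_families: dict[str, list[str]] = {}
    for fam, members in families.items():
        for g in members:
            gene_families.setdefault(g, []).append(fam)
    for g, fams in gene_families.items():
        if len(fams) < 2:
            continue
        def rarest_domain_size(fam: str) -> tuple[int, str]:
            doms_with_gene = [d for d in provenance[fam] if g in catalog.domain_members[d]]
            best = min(doms_with_gene, key=lambda d: (len(catalog.domain_members[d]), d))
            return len(catalog.domain_members[best]), best
        keep = min(fams, key=lambda f: (*rarest_domain_size(f), f))
        for fam in fams:
            if fam != keep:
                families[fam].discard(g)
        logger.debug("gene %s assigned to %s among %s", g, keep, fams)

    for new_id, genes in (manual_splits or {}).items():
        genes = set(genes)
        missing = genes - set(gene_families)
        if missing:
            raise CatalogError(f"manual split {new_id!r} names unknown gene(s): {sorted(missing)}")
        for fam in families:
            families[fam] -= genes
        families[new_id] = genes
        provenance[new_id] = (new_id,)

    kept = {f: m for f, m in families.items() if len(m) >= catalog.min_size}
    dropped = set(families) - set(kept)
    if dropped:
        logger.info("dropped %d families below min_size after curation", len(dropped))
    return FamilyCatalog(
        kept,
        {f: provenance[f] for f in kept},
        catalog.domain_members,
        catalog.min_size,
    )


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k < 0 or K < 0 or n < 0 or K > N or n > N or k > min(K, n):
        raise ValueError(f"invalid hypergeometric arguments k={k} N={N} K={K} n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _enrichment_table(
    sets_map: dict[str, set[str]],
    query_set: set[str],
    universe: set[str],
    alpha: float,
) -> pd.DataFrame:
    if not query_set <= universe:
        raise CatalogError("query gene set must be a subset of the universe")
    N, n = len(universe), len(query_set)
    rows = []
    for fam_id in sorted(sets_map):
        members = sets_map[fam_id]
        outside = members - universe
        if outside:
            logger.info(
                "%s: %d member(s) absent from universe dropped", fam_id, len(outside)
            )
        members = members & universe
        K = len(members)
        k = len(members & query_set)
        p = hypergeom_upper_tail(k, N, K, n) if K else 1.0
        rows.append((fam_id, N, K, n, k, p))
    table = pd.DataFrame(rows, columns=list(ENRICHMENT_COLUMNS[:6]))
    if table.empty:
        table["q_value"] = []
        table["enriched"] = []
        return table
    _, q, _, _ = multipletests(table["p_value"].to_numpy(), method="fdr_bh")
    table["q_value"] = q
    table["enriched"] = table["q_value"] < alpha
    return table.sort_values(["q_value", "p_value", "family_id"]).reset_index(drop=True)


def test_overrepresentation(
    catalog: FamilyCatalog,
    gradient_genes: set[str] | list[str],
    universe: set[str] | list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each family among the
    gradient genes, BH-corrected across families.

    The universe is the set of genes represented on the measurement
    platform, and the gradient set must be contained in it.
    """
    return _enrichment_table(catalog.families, set(gradient_genes), set(universe), alpha)


def keyword_enrichment(
    keyword_annotations: pd.DataFrame,
    gene_set: set[str] | list[str],
    universe: set[str] | list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Same hypergeometric machinery applied to annotation keywords
    (e.g. hormone names) instead of domain families.

    ``keyword_annotations`` has columns (gene_id, keyword).
    """
    for col in ("gene_id", "keyword"):
        if col not in keyword_annotations.columns:
            raise CatalogError(f"keyword table missing column {col!r}")
    sets_map = {
        kw: set(group["gene_id"])
        for kw, group in keyword_annotations.groupby("keyword", sort=True)
    }
    return _enrichment_table(sets_map, set(gene_set), set(universe), alpha)
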