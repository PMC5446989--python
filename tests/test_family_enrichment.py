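import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gradfam.family_enrichment import (
    CatalogError,
    build_catalog,
    hypergeom_upper_tail,
    keyword_enrichment,
    merge_redundant_domains,
)
from gradfam.family_enrichment import test_overrepresentation as overrepresentation_test


def hypergeom_enumeration(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact upper-tail probability by direct summation over draw counts."""
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(num, comb(N, n))


def annotations_from(families: dict[str, list[str]]) -> pd.DataFrame:
    rows = [(g, d) for d, genes in families.items() for g in genes]
    return pd.DataFrame(rows, columns=["gene_id", "domain_id"])


class TestHypergeometricTail:
    def test_matches_enumeration_on_small_instances(self):
        for N in (10, 25, 50, 60):
            for K in (3, 10, N // 2):
                for n in (2, 10, N // 3):
                    for k in range(0, min(K, n) + 1):
                        exact = float(hypergeom_enumeration(k, N, K, n))
                        assert abs(hypergeom_upper_tail(k, N, K, n) - exact) < 1e-12

    def test_worked_example_n50(self):
        exact = float(hypergeom_enumeration(5, 50, 10, 10))
        assert hypergeom_upper_tail(5, 50, 10, 10) == pytest.approx(exact, abs=1e-12)

    def test_zero_overlap_gives_one(self):
        assert hypergeom_upper_tail(0, 100, 20, 10) == 1.0

    def test_complete_overlap_closed_form(self):
        # k = K = n: only one of the C(N, n) draws contains the whole family
        assert hypergeom_upper_tail(5, 100, 5, 5) == pytest.approx(
            1 / comb(100, 5), abs=1e-15
        )

    @given(st.data())
    def test_non_increasing_in_overlap(self, data):
        N = data.draw(st.integers(10, 80))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        ps = [hypergeom_upper_tail(k, N, K, n) for k in range(min(K, n) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 10, 20, 5)


class TestBuildCatalog:
    def test_min_size_boundary(self):
        fams = {
            "D_small": [f"g{i}" for i in range(9)],
            "D_exact": [f"h{i}" for i in range(10)],
        }
        catalog = build_catalog(annotations_from(fams), min_size=10)
        assert "D_small" not in catalog.families
        assert len(catalog.families["D_exact"]) == 10

    def test_duplicate_rows_deduplicated(self):
        ann = annotations_from({"D1": [f"g{i}" for i in range(10)]})
        doubled = pd.concat([ann, ann], ignore_index=True)
        catalog = build_catalog(doubled, min_size=10)
        assert len(catalog.families["D1"]) == 10

    def test_empty_annotations_rejected(self):
        with pytest.raises(CatalogError):
            build_catalog(pd.DataFrame(columns=["gene_id", "domain_id"]))


class TestMergeRedundantDomains:
    def test_identical_member_sets_merged(self):
        genes = [f"g{i}" for i in range(12)]
        catalog = build_catalog(annotations_from({"Da": genes, "Db": genes}))
        merged = merge_redundant_domains(catalog)
        assert list(merged.families) == ["Da+Db"]
        assert merged.provenance["Da+Db"] == ("Da", "Db")

    def test_cooccurring_domains_union_to_one_family(self):
        # three domains over 21 genes, co-occurring in 19 (Jaccard ~0.90)
        shared = [f"m{i}" for i in range(19)]
        fams = {
            "Dx": shared + ["m19"],
            "Dy": shared + ["m20"],
            "Dz": shared + ["m19"],
        }
        catalog = build_catalog(annotations_from(fams))
        merged = merge_redundant_domains(catalog, jaccard_threshold=0.75)
        assert len(merged.families) == 1
        (members,) = merged.families.values()
        assert len(members) == 21
        (prov,) = merged.provenance.values()
        assert prov == ("Dx", "Dy", "Dz")

    def test_disjoint_domains_unchanged(self):
        fams = {
            "Da": [f"a{i}" for i in range(10)],
            "Db": [f"b{i}" for i in range(10)],
        }
        catalog = build_catalog(annotations_from(fams))
        merged = merge_redundant_domains(catalog)
        assert set(merged.families) == {"Da", "Db"}

    def test_merge_is_idempotent(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(200)]
        fams = {}
        for j in range(15):
            size = int(rng.integers(10, 30))
            fams[f"D{j:02d}"] = list(rng.choice(genes, size=size, replace=False))
        fams["D90"] = fams["D00"][:]  # guaranteed redundant pair
        catalog = build_catalog(annotations_from(fams))
        once = merge_redundant_domains(catalog)
        twice = merge_redundant_domains(once)
        assert once.families == twice.families
        assert once.provenance == twice.provenance

    def test_result_is_non_overlapping(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(120)]
        fams = {
            f"D{j}": list(rng.choice(genes, size=15, replace=False)) for j in range(8)
        }
        merged = merge_redundant_domains(build_catalog(annotations_from(fams)))
        for fa, fb in itertools.combinations(merged.families, 2):
            assert not (merged.families[fa] & merged.families[fb])

    def test_unknown_manual_merge_rejected(self):
        catalog = build_catalog(annotations_from({"Da": [f"g{i}" for i in range(10)]}))
        with pytest.raises(CatalogError):
            merge_redundant_domains(catalog, manual_merges=[["Da", "Dnope"]])

    def test_manual_split_carves_out_family(self):
        genes = [f"g{i}" for i in range(30)]
        catalog = build_catalog(annotations_from({"Da": genes}))
        merged = merge_redundant_domains(
            catalog, manual_splits={"Da_subset": genes[:12]}
        )
        assert set(merged.families["Da_subset"]) == set(genes[:12])
        assert set(merged.families["Da"]) == set(genes[12:])


class TestOverrepresentation:
    def test_end_to_end_planted_families_flagged(self, annotated_run):
        from gradfam.gradient_detection import detect_gradients_all_sets, union_gradient_genes

        atlas, truth, annotations = annotated_run
        calls = detect_gradients_all_sets(atlas)
        gradient_genes = set(union_gradient_genes(calls))
        catalog = merge_redundant_domains(build_catalog(annotations))
        result = overrepresentation_test(
            catalog, gradient_genes, set(atlas.values.index)
        )
        flagged = set(result.loc[result["enriched"], "family_id"])
        for fam in truth.planted_enriched_families:
            assert any(fam in f.split("+") for f in flagged)

    def test_q_at_least_p_and_counts_consistent(self, annotated_run):
        atlas, _, annotations = annotated_run
        catalog = build_catalog(annotations)
        universe = set(atlas.values.index)
        gradient = set(list(universe)[:150])
        result = overrepresentation_test(catalog, gradient, universe)
        assert (result["q_value"] >= result["p_value"] - 1e-15).all()
        assert (result["overlap"] <= result[["family_size", "set_size"]].min(axis=1)).all()

    def test_member_outside_universe_dropped(self):
        genes = [f"g{i}" for i in range(10)]
        catalog = build_catalog(annotations_from({"Da": genes}))
        universe = set(genes[:8]) | {f"u{i}" for i in range(40)}
        result = overrepresentation_test(catalog, set(genes[:4]), universe)
        assert result.loc[0, "family_size"] == 8

    def test_gradient_set_must_be_in_universe(self):
        catalog = build_catalog(annotations_from({"Da": [f"g{i}" for i in range(10)]}))
        with pytest.raises(CatalogError):
            overrepresentation_test(catalog, {"zz"}, {f"g{i}" for i in range(10)})


class TestKeywordEnrichment:
    def test_ubiquitous_keyword_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        ann = pd.DataFrame({"gene_id": universe, "keyword": "auxin"})
        result = keyword_enrichment(ann, set(universe[:10]), set(universe))
        assert result.loc[0, "p_value"] == 1.0

    def test_confined_keyword_closed_form(self):
        universe = [f"g{i}" for i in range(100)]
        ann = pd.DataFrame({"gene_id": universe[:5], "keyword": "ga"})
        result = keyword_enrichment(ann, set(universe[:5]), set(universe))
        assert result.loc[0, "p_value"] == pytest.approx(1 / comb(100, 5), rel=1e-12)

    def test_random_keywords_raw_positive_rate_near_alpha(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(2000)]
        rows = []
        for j in range(150):
            for g in rng.choice(universe, size=50, replace=False):
                rows.append((g, f"kw{j:03d}"))
        ann = pd.DataFrame(rows, columns=["gene_id", "keyword"])
        gene_set = set(rng.choice(universe, size=400, replace=False))
        result = keyword_enrichment(ann, gene_set, set(universe))
        # discreteness makes the raw test conservative: rate <= alpha + noise
        assert (result["p_value"] < 0.05).mean() <= 0.08
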