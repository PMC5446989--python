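import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from gradfam.gradient_detection import (
    AtlasError,
    ExpressionAtlas,
    detect_gradients,
    detect_gradients_all_sets,
    fit_scaled_f_prior,
    reproducibility_filter,
    union_gradient_genes,
)
from gradfam.synthetic_data import AtlasConfig, generate_atlas


def _tiny_atlas(values: np.ndarray, tissues: list[str], reps: int) -> ExpressionAtlas:
    rows = [
        {"sample_id": f"s.{t}.r{r}", "set": "s", "tissue": t, "replicate": r}
        for t in tissues
        for r in range(1, reps + 1)
    ]
    sheet = pd.DataFrame(rows)
    genes = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionAtlas(
        pd.DataFrame(values, index=genes, columns=list(sheet["sample_id"])), sheet
    )


class TestReproducibilityFilter:
    def test_identical_replicates_retained(self):
        atlas, _ = generate_atlas(AtlasConfig(n_genes=100, noise_sd=0.0, seed=2))
        out = reproducibility_filter(atlas, 0.95)
        pd.testing.assert_frame_equal(out.values, atlas.values)

    def test_permuted_outlier_dropped_mates_kept(self):
        atlas, _ = generate_atlas(AtlasConfig(n_genes=500, seed=11))
        rng = np.random.default_rng(0)
        atlas.values["root.cortex.r3"] = rng.permutation(
            atlas.values["root.cortex.r1"].to_numpy()
        )
        out = reproducibility_filter(atlas, 0.95)
        assert out.samples_of("root", "cortex") == ["root.cortex.r1", "root.cortex.r2"]
        assert "root" in out.set_names()

    def test_all_pass_is_identity(self, default_atlas_truth):
        atlas, _ = default_atlas_truth
        out = reproducibility_filter(atlas, 0.9)
        pd.testing.assert_frame_equal(out.values, atlas.values)
        pd.testing.assert_frame_equal(
            out.sample_sheet.reset_index(drop=True), atlas.sample_sheet
        )

    def test_set_invalidated_when_tissue_collapses(self):
        atlas, _ = generate_atlas(AtlasConfig(n_genes=300, seed=3))
        rng = np.random.default_rng(1)
        for col in atlas.samples_of("root", "stele"):
            atlas.values[col] = rng.normal(8, 2, 300)
        out = reproducibility_filter(atlas, 0.95)
        assert "root" not in out.set_names()
        assert len(out.set_names()) == 3

    def test_empty_atlas_rejected(self):
        with pytest.raises(AtlasError):
            ExpressionAtlas(pd.DataFrame(), pd.DataFrame())


class TestDetectGradients:
    def test_planted_genes_called_with_correct_peak(self, default_atlas_truth):
        atlas, truth = default_atlas_truth
        calls = detect_gradients_all_sets(atlas)
        called = set(union_gradient_genes(calls))
        planted = truth.planted_gradient_genes
        assert len(called & planted) / len(planted) >= 0.95
        # calls in the planted set that involve the planted tissue peak there
        for gene in sorted(planted)[:50]:
            set_name, tissue = truth.planted_gene_targets[gene]
            sub = calls[
                (calls["gene_id"] == gene)
                & (calls["set"] == set_name)
                & ((calls["tissue_a"] == tissue) | (calls["tissue_b"] == tissue))
            ]
            assert not sub.empty
            assert (sub["peak_tissue"] == tissue).all()

    def test_null_set_call_fraction_below_alpha(self):
        atlas, _ = generate_atlas(AtlasConfig(gradient_fraction=0.0, seed=21))
        calls = detect_gradients(atlas, "root", alpha=0.05, min_abs_log2_fold=0.0)
        n_tests = 2000 * 10  # genes x tissue pairs
        assert len(calls) / n_tests <= 0.05

    def test_infinite_fold_threshold_empty(self, small_atlas_truth):
        atlas, _ = small_atlas_truth
        calls = detect_gradients(atlas, "root", min_abs_log2_fold=np.inf)
        assert calls.empty

    def test_global_shift_invariance(self, small_atlas_truth):
        atlas, _ = small_atlas_truth
        shifted = ExpressionAtlas(atlas.values + 5.0, atlas.sample_sheet)
        c1 = detect_gradients(atlas, "root")
        c2 = detect_gradients(shifted, "root")
        pd.testing.assert_frame_equal(c1, c2)

    def test_swapping_pair_negates_fold_preserves_p(self, small_atlas_truth):
        atlas, _ = small_atlas_truth
        c1 = detect_gradients(atlas, "root", pairs=[("cortex", "stele")])
        c2 = detect_gradients(atlas, "root", pairs=[("stele", "cortex")])
        m = c1.merge(c2, on="gene_id", suffixes=("_ab", "_ba"))
        assert len(m) == len(c1) == len(c2)
        assert np.allclose(m["log2_fold_ab"], -m["log2_fold_ba"])
        assert np.allclose(m["p_value_ab"], m["p_value_ba"])
        assert (m["peak_tissue_ab"] == m["peak_tissue_ba"]).all()

    def test_q_value_at_least_p_value(self, small_atlas_truth):
        atlas, _ = small_atlas_truth
        calls = detect_gradients(atlas, "seed_globular")
        assert (calls["q_value"] >= calls["p_value"] - 1e-15).all()

    def test_constant_matrix_suppressed_not_crashing(self):
        values = np.full((20, 6), 8.0)
        atlas = _tiny_atlas(values, ["t1", "t2"], 3)
        calls = detect_gradients(atlas, "s")
        assert calls.empty

    def test_noiseless_planted_effect_called_by_both_statistics(self):
        values = np.full((10, 6), 8.0)
        values[0, :3] += 2.0  # gene g0 higher in t1
        atlas = _tiny_atlas(values, ["t1", "t2"], 3)
        for statistic in ("moderated", "welch"):
            calls = detect_gradients(atlas, "s", statistic=statistic)
            assert list(calls["gene_id"]) == ["g0"]
            assert calls.loc[0, "peak_tissue"] == "t1"
            assert calls.loc[0, "log2_fold"] == pytest.approx(2.0)

    def test_unknown_statistic_rejected(self, small_atlas_truth):
        atlas, _ = small_atlas_truth
        with pytest.raises(ValueError):
            detect_gradients(atlas, "root", statistic="anova")


class TestUnion:
    def test_union_across_sets(self):
        a = pd.DataFrame({"gene_id": ["g1", "g2"]})
        b = pd.DataFrame({"gene_id": ["g2", "g3"]})
        assert union_gradient_genes([a, b]) == ["g1", "g2", "g3"]

    def test_empty_calls(self):
        assert union_gradient_genes([]) == []
        assert union_gradient_genes(pd.DataFrame(columns=["gene_id"])) == []


class TestModeratedStatisticOracle:
    def test_matches_independent_ebayes_implementation(self, tmp_path):
        """Moderated t p-values agree with Bioconductor limma on a
        heteroscedastic one-way layout."""
        rng = np.random.default_rng(5)
        n, reps = 150, 3
        tissues = ["t1", "t2", "t3"]
        s2_true = 0.04 * 4 / rng.chisquare(4, n)
        base = rng.normal(8, 2, n)[:, None]
        blocks = {
            t: base + rng.normal(0, 1, (n, reps)) * np.sqrt(s2_true)[:, None]
            for t in tissues
        }
        ss = sum(((m - m.mean(1, keepdims=True)) ** 2).sum(1) for m in blocks.values())
        df = float(sum(reps - 1 for _ in tissues))
        s2 = ss / df
        d0, s0 = fit_scaled_f_prior(s2, df)
        assert np.isfinite(d0)
        s2_tilde = (d0 * s0 + df * s2) / (d0 + df)
        diff = blocks["t1"].mean(1) - blocks["t2"].mean(1)
        from scipy import stats

        t = diff / np.sqrt(s2_tilde * (2 / reps))
        p_mine = 2 * stats.t.sf(np.abs(t), d0 + df)

        cols = [f"{t}.r{i}" for t in tissues for i in range(reps)]
        mat = pd.DataFrame(np.hstack([blocks[t] for t in tissues]), columns=cols)
        mat.to_csv(tmp_path / "m.tsv", sep="\t")
        groups = [t for t in tissues for _ in range(reps)]
        pd.DataFrame({"g": groups}).to_csv(tmp_path / "g.tsv", sep="\t", index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("{tmp_path}/m.tsv", row.names=1))
            g <- factor(read.delim("{tmp_path}/g.tsv")$g)
            design <- model.matrix(~0+g); colnames(design) <- levels(g)
            fit <- lmFit(m, design)
            ct <- makeContrasts(contrasts="t1-t2", levels=design)
            fit2 <- eBayes(contrasts.fit(fit, ct))
            write.csv(data.frame(p=fit2$p.value[,1], d0=fit2$df.prior,
                                 s0=fit2$s2.prior), "{tmp_path}/out.csv")
        """)
        (tmp_path / "s.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "s.R")], check=True, capture_output=True)
        out = pd.read_csv(tmp_path / "out.csv", index_col=0)
        assert d0 == pytest.approx(out["d0"].iloc[0], rel=1e-9)
        assert s0 == pytest.approx(out["s0"].iloc[0], rel=1e-9)
        assert np.abs(p_mine - out["p"].to_numpy()).max() < 1e-10
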