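"""End-to-end orchestration: simulate -> gradients -> enrich -> expand ->
diversity -> localize, with a run manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import expansion_analysis, family_enrichment, gradient_detection
from . import localization_enrichment, synthetic_data, tissue_diversity
from . import io as gio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters for a full synthetic-data pipeline run.

    All randomness flows from the single ``seed``.
    """

    outdir: str = "gradfam_run"
    seed: int = 0
    # synthetic-data stage
    n_genes: int = 2000
    gradient_fraction: float = 0.10
    gradient_effect: float = 2.0
    noise_sd: float = 0.25
    replicates_per_tissue: int = 3
    n_families: int = 40
    n_enriched: int = 5
    # gradient detection
    alpha: float = 0.05
    min_abs_log2_fold: float = 1.0
    min_correlation: float = 0.9
    # family curation / enrichment
    min_size: int = 10
    jaccard_threshold: float = 0.75
    manual_merges: list = field(default_factory=list)
    # expansion
    alpha_expansion: float = 0.05
    # diversity
    diversity_cutoff: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic data and write all outputs plus a
    manifest under ``config.outdir``.  Deterministic given the seed."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        outputs[name] = str(path)

    # -- simulate -------------------------------------------------------------
    atlas_cfg = synthetic_data.AtlasConfig(
        n_genes=config.n_genes,
        gradient_fraction=config.gradient_fraction,
        gradient_effect=config.gradient_effect,
        noise_sd=config.noise_sd,
        replicates_per_tissue=config.replicates_per_tissue,
        seed=config.seed,
    )
    atlas, truth = synthetic_data.generate_atlas(atlas_cfg)
    annotations = synthetic_data.generate_family_annotations(
        list(atlas.values.index), truth,
        n_families=config.n_families, n_enriched=config.n_enriched,
        seed=config.seed + 1,
    )
    fam_ids = sorted(truth.family_members)
    counts_df = synthetic_data.generate_species_counts(
        fam_ids,
        expansion_map={
            (f, s): 4.0
            for f in truth.planted_enriched_families
            for s in ("Physcomitrella", "Arabidopsis", "Oryza")
        },
        zero_inflation={"Chlamydomonas": 0.3},
        seed=config.seed + 2,
    )
    table = expansion_analysis.SpeciesCountTable(
        counts_df, dict(synthetic_data.DEFAULT_SPECIES_TOTALS)
    )
    localization = synthetic_data.generate_localization(
        list(atlas.values.index), seed=config.seed + 3
    )

    matrix_path, samples_path = out / "expression.tsv", out / "samples.tsv"
    gio.write_expression(atlas, matrix_path, samples_path)
    emit("expression", matrix_path)
    emit("samples", samples_path)
    gio.write_table(annotations, out / "annotations.tsv")
    emit("annotations", out / "annotations.tsv")
    gio.write_species_counts(table, out / "species_counts.tsv", out / "species_totals.tsv")
    emit("species_counts", out / "species_counts.tsv")
    gio.write_table(localization, out / "localization.tsv")
    emit("localization", out / "localization.tsv")
    (out / "truth.json").write_text(truth.to_json() + "\n")
    emit("truth", out / "truth.json")

    # -- gradients ------------------------------------------------------------
    filtered = gradient_detection.reproducibility_filter(atlas, config.min_correlation)
    calls = gradient_detection.detect_gradients_all_sets(
        filtered, config.alpha, config.min_abs_log2_fold
    )
    gradient_genes = gradient_detection.union_gradient_genes(calls)
    gio.write_table(calls, out / "gradient_calls.tsv")
    emit("gradient_calls", out / "gradient_calls.tsv")
    gio.write_gene_list(gradient_genes, out / "gradient_genes.txt")
    emit("gradient_genes", out / "gradient_genes.txt")

    # -- enrichment -----------------------------------------------------------
    catalog = family_enrichment.build_catalog(annotations, config.min_size)
    catalog = family_enrichment.merge_redundant_domains(
        catalog, config.jaccard_threshold, config.manual_merges or None
    )
    universe = set(atlas.values.index)
    enrichment = family_enrichment.test_overrepresentation(
        catalog, set(gradient_genes), universe, config.alpha
    )
    gio.write_table(enrichment, out / "family_enrichment.tsv")
    emit("family_enrichment", out / "family_enrichment.tsv")
    enriched_fams = sorted(enrichment.loc[enrichment["enriched"], "family_id"])

    # -- expansion ------------------------------------------------------------
    species = table.species
    expansion_rows = []
    for s_from, s_to in zip(species, species[1:]):
        n_sig, frac = expansion_analysis.expansion_fraction(
            table, s_from, s_to, config.alpha_expansion
        )
        expansion_rows.append(
            {"species_from": s_from, "species_to": s_to,
             "n_significant": n_sig, "fraction": frac}
        )
    summary = expansion_analysis.family_size_summary(table)
    expansion_summary = {
        "fractions": expansion_rows,
        "medians": {s: summary[s]["median"] for s in species},
        "n_absent": {s: summary[s]["n_absent"] for s in species},
    }
    (out / "expansion_summary.json").write_text(
        json.dumps(expansion_summary, indent=1, sort_keys=True) + "\n"
    )
    emit("expansion_summary", out / "expansion_summary.json")

    # -- diversity (over enriched families; all families if none enriched) ----
    fams_for_diversity = {
        f: set().union(*(catalog.families[f],)) for f in (enriched_fams or catalog.families)
        if f in catalog.families
    }
    scores = tissue_diversity.score_families(fams_for_diversity, calls, filtered)
    tissue_order = filtered.distinct_tissues()
    if scores:
        labels, div_summary = tissue_diversity.classify(scores, config.diversity_cutoff)
        frame = tissue_diversity.scores_to_frame(scores, tissue_order)
        frame["label"] = frame["family_id"].map(labels)
    else:
        div_summary = {"median_D": float("nan"), "n_specialized": 0, "n_families": 0}
        frame = pd.DataFrame()
    gio.write_table(frame, out / "tissue_diversity.tsv")
    emit("tissue_diversity", out / "tissue_diversity.tsv")

    # -- localization ---------------------------------------------------------
    grad_set = set(gradient_genes) or universe
    comparison = localization_enrichment.compare_proportions(
        grad_set, universe, localization, config.alpha
    )
    gio.write_table(comparison, out / "localization_comparison.tsv")
    emit("localization_comparison", out / "localization_comparison.tsv")

    manifest = {
        "gradfam_version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "outputs": {k: gio.sha256_of(v) for k, v in outputs.items()},
        "n_gradient_genes": len(gradient_genes),
        "n_enriched_families": len(enriched_fams),
        "diversity_summary": div_summary,
        "expansion_summary": expansion_summary,
    }
    gio.write_manifest(manifest, out / "manifest.json")

    return {
        "atlas": filtered,
        "truth": truth,
        "calls": calls,
        "gradient_genes": gradient_genes,
        "catalog": catalog,
        "enrichment": enrichment,
        "expansion_summary": expansion_summary,
        "diversity_scores": scores,
        "diversity_summary": div_summary,
        "localization_comparison": comparison,
        "manifest": manifest,
        "outputs": outputs,
    }
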