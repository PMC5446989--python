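"""Readers and writers for the pipeline's TSV/JSON interchange formats.

All tables are plain TSV: an expression matrix with gene ids as the first
column and sample ids as the header; a sample sheet (sample_id, set,
tissue, replicate); two-column annotation tables; a species-count table
(family_id plus one column per species) with a separate totals table; and
one-id-per-line gene lists.  Writers and readers are lossless round-trips
of each other.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .gradient_detection import SAMPLE_SHEET_COLUMNS, AtlasError, ExpressionAtlas


def read_expression(matrix_path, samples_path) -> ExpressionAtlas:
    """Load and validate an atlas from a matrix TSV + sample-sheet TSV."""
    matrix_path, samples_path = Path(matrix_path), Path(samples_path)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    non_numeric = values.columns[
        [not pd.api.types.is_numeric_dtype(values[c]) for c in values.columns]
    ]
    if len(non_numeric):
        for c in non_numeric:
            bad = values[pd.to_numeric(values[c], errors="coerce").isna()].index[:3]
            raise AtlasError(
                f"non-numeric expression values in column {c!r}, e.g. rows {list(bad)}"
            )
    sheet = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise AtlasError(f"sample sheet {samples_path} missing columns {missing}")
    return ExpressionAtlas(values, sheet)


def write_expression(atlas: ExpressionAtlas, matrix_path, samples_path) -> None:
    atlas.values.to_csv(Path(matrix_path), sep="\t", index_label="gene_id")
    atlas.sample_sheet.to_csv(Path(samples_path), sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    text = Path(path).read_text().split()
    return list(dict.fromkeys(text))


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if len(genes) else ""))


def read_two_column(path, columns: tuple[str, str]) -> pd.DataFrame:
    table = pd.read_csv(Path(path), sep="\t")
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return table[list(columns)]


def read_annotations(path) -> pd.DataFrame:
    return read_two_column(path, ("gene_id", "domain_id"))


def read_localization(path) -> pd.DataFrame:
    return read_two_column(path, ("gene_id", "compartment"))


def write_table(table: pd.DataFrame, path, index: bool = False) -> None:
    table.to_csv(Path(path), sep="\t", index=index)


def read_species_counts(counts_path, totals_path):
    """Read a species-count TSV and a totals TSV (species, total_loci)."""
    from .expansion_analysis import SpeciesCountTable

    counts = pd.read_csv(Path(counts_path), sep="\t", index_col="family_id")
    totals_df = pd.read_csv(Path(totals_path), sep="\t")
    for col in ("species", "total_loci"):
        if col not in totals_df.columns:
            raise ValueError(f"{totals_path}: missing column {col!r}")
    totals = dict(zip(totals_df["species"], totals_df["total_loci"].astype(int)))
    return SpeciesCountTable(counts, totals)


def write_species_counts(table, counts_path, totals_path) -> None:
    table.counts.to_csv(Path(counts_path), sep="\t", index_label="family_id")
    pd.DataFrame(
        {"species": list(table.totals), "total_loci": list(table.totals.values())}
    ).to_csv(Path(totals_path), sep="\t", index=False)


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
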