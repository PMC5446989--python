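"""Subcellular-localization composition of gene sets.

Compares the proportion of each compartment (extracellular/apoplast,
plasma membrane, cytosol, nucleus, plastid, ER, mitochondrion, other)
between a gene subset and its universe, flagging compartments whose
representation shifts significantly.  Each gene carries exactly one
consensus compartment label (multi-localised proteins are resolved to a
consensus upstream); genes without an assignment count as "other".

Per compartment the shift is assessed with both hypergeometric tails:
over-represented if the upper tail < alpha, under-represented if the
lower tail < alpha (raw p-values by default; BH across compartments is
available as an option).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_VOCABULARY: tuple[str, ...] = (
    "extracellular",
    "plasma_membrane",
    "cytosol",
    "nucleus",
    "plastid",
    "er",
    "mitochondrion",
    "other",
)

UNASSIGNED = "other"


class LocalizationError(ValueError):
    """Raised on malformed localization tables or set mismatches."""


def _as_assignment_map(table: pd.DataFrame, vocabulary: tuple[str, ...]) -> dict[str, str]:
    for col in ("gene_id", "compartment"):
        if col not in table.columns:
            raise LocalizationError(f"localization table missing column {col!r}")
    if table["gene_id"].duplicated().any():
        dups = table.loc[table["gene_id"].duplicated(), "gene_id"].head().tolist()
        raise LocalizationError(f"multiple labels for gene(s): {dups}")
    bad = sorted(set(table["compartment"]) - set(vocabulary))
    if bad:
        raise LocalizationError(f"labels outside vocabulary: {bad}")
    return dict(zip(table["gene_id"], table["compartment"]))


def proportion_table(
    gene_set,
    table: pd.DataFrame,
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY,
) -> pd.Series:
    """Fraction of the gene set in each compartment (sums to 1).

    Genes absent from the localization table are counted under "other".
    """
    genes = sorted(set(gene_set))
    if not genes:
        raise LocalizationError("empty gene set")
    assign = _as_assignment_map(table, vocabulary)
    counts = {c: 0 for c in vocabulary}
    for g in genes:
        counts[assign.get(g, UNASSIGNED)] += 1
    fractions = pd.Series(counts, dtype=float) / len(genes)
    return fractions


def compare_proportions(
    subset,
    universe,
    table: pd.DataFrame,
    alpha: float = 0.05,
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-compartment two-tailed hypergeometric comparison of a subset
    against its universe.

    Returns a DataFrame with counts (k in subset, K in universe), the two
    tail probabilities, and a direction flag ("over", "under" or "").
    Over/under flags are mutually exclusive per compartment.
    """
    subset, universe = set(subset), set(universe)
    if not subset <= universe:
        raise LocalizationError("subset must be contained in the universe")
    if not subset:
        raise LocalizationError("empty subset")
    assign = _as_assignment_map(table, vocabulary)
    N, n = len(universe), len(subset)
    rows = []
    for comp in vocabulary:
        K = sum(1 for g in universe if assign.get(g, UNASSIGNED) == comp)
        k = sum(1 for g in subset if assign.get(g, UNASSIGNED) == comp)
        p_over = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_under = float(stats.hypergeom.cdf(k, N, K, n))
        rows.append((comp, k, K, n, N, p_over, p_under))
    out = pd.DataFrame(
        rows, columns=["compartment", "k", "K", "n", "N", "p_over", "p_under"]
    )
    if bh_correct:
        _, out["p_over"], _, _ = multipletests(out["p_over"].to_numpy(), method="fdr_bh")
        _, out["p_under"], _, _ = multipletests(out["p_under"].to_numpy(), method="fdr_bh")
    flags = np.where(
        out["p_over"] < alpha, "over", np.where(out["p_under"] < alpha, "under", "")
    )
    # a compartment cannot be both tails at any alpha <= 0.5; the order
    # above also guarantees exclusivity structurally
    out["flag"] = flags
    return out
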