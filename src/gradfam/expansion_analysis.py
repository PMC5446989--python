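"""Cross-species family-size comparison and expansion testing.

The central statistic is a genome-size-corrected Poisson test: if a family
has k1 members among the N1 gene loci of species 1, then under pure
genome-size scaling its expected size among the N2 loci of species 2 is
lambda = k1 * N2 / N1, and an observed count k2 is called a significant
expansion when the upper-tail probability P(Poisson(lambda) >= k2) falls
below alpha.  When k1 = 0 the rate is floored at one expected gene
(lambda = N2 / N1): without the floor any non-zero k2 would yield p = 0,
and a one-gene pseudo-count is the conservative choice for families absent
from the simpler species.

Also provided: per-species size summaries (medians, absence counts, and
log-normal probability-plot coordinates), and a one-sided Mann-Whitney
comparison of a family subset against the background of all families.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

EXPANSION_COLUMNS = (
    "family_id", "species_from", "species_to", "k1", "k2", "N1", "N2",
    "lam", "p_value", "significant",
)


@dataclass
class SpeciesCountTable:
    """Per-species family counts plus total gene-locus counts.

    ``counts``: DataFrame indexed by family_id, one integer column per
    species; ``totals``: species -> total gene loci (one gene per locus).
    """

    counts: pd.DataFrame
    totals: dict[str, int]

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.totals]
        if missing:
            raise ValueError(f"totals missing for species: {missing}")
        if (self.counts < 0).any().any():
            raise ValueError("family counts must be non-negative")
        for s in self.counts.columns:
            if self.totals[s] <= 0:
                raise ValueError(f"total for {s!r} must be positive")
            if self.counts[s].max() > self.totals[s]:
                raise ValueError(f"family count exceeds genome total for {s!r}")

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ExpansionResult:
    family_id: str
    species_from: str
    species_to: str
    k1: int
    k2: int
    N1: int
    N2: int
    lam: float
    p_value: float
    significant: bool


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam)."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    if k <= 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def poisson_expansion_test(
    k1: int,
    N1: int,
    k2: int,
    N2: int,
    alpha: float = DEFAULT_ALPHA,
    family_id: str = "",
    species_from: str = "",
    species_to: str = "",
) -> ExpansionResult:
    """Genome-size-corrected Poisson expansion test.

    lambda = max(k1, 1) * N2 / N1 (zero-count floor); p is the upper-tail
    Poisson probability of observing at least k2 genes.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("genome totals must be positive")
    lam = max(k1, 1) * N2 / N1
    p = poisson_upper_tail(k2, lam)
    return ExpansionResult(
        family_id, species_from, species_to, k1, k2, N1, N2, lam, p, p < alpha
    )


def expansion_table(
    table: SpeciesCountTable,
    species_from: str,
    species_to: str,
    alpha: float = DEFAULT_ALPHA,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Apply the expansion test to every family between two species.

    By default significance is assessed on raw p-values; ``bh_correct``
    switches to BH-adjusted q-values across families.
    """
    for s in (species_from, species_to):
        if s not in table.counts.columns:
            raise ValueError(f"species {s!r} not in count table")
    N1, N2 = table.totals[species_from], table.totals[species_to]
    rows = []
    for fam, rec in table.counts.iterrows():
        r = poisson_expansion_test(
            int(rec[species_from]), N1, int(rec[species_to]), N2, alpha,
            family_id=str(fam), species_from=species_from, species_to=species_to,
        )
        rows.append(
            (r.family_id, r.species_from, r.species_to, r.k1, r.k2, r.N1, r.N2,
             r.lam, r.p_value, r.significant)
        )
    out = pd.DataFrame(rows, columns=list(EXPANSION_COLUMNS))
    if bh_correct and not out.empty:
        _, q, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
        out["q_value"] = q
        out["significant"] = out["q_value"] < alpha
    return out


def expansion_fraction(
    table: SpeciesCountTable,
    species_from: str,
    species_to: str,
    alpha: float = DEFAULT_ALPHA,
    bh_correct: bool = False,
) -> tuple[int, float]:
    """(number, fraction) of families significantly expanded between two
    species."""
    out = expansion_table(table, species_from, species_to, alpha, bh_correct)
    n_sig = int(out["significant"].sum())
    return n_sig, n_sig / len(out) if len(out) else 0.0


def family_size_summary(table: SpeciesCountTable) -> dict[str, dict]:
    """Per-species summary: median size (midpoint convention), number of
    absent families (count 0), and probability-plot coordinates on which a
    log-normal size distribution appears as a straight line.

    The coordinates pair the standard-normal quantile of the plotting
    position (i - 0.5)/n with log10(size), for non-zero sizes ordered
    smallest to largest.
    """
    if table.counts.empty:
        raise ValueError("empty count table")
    summary: dict[str, dict] = {}
    for s in table.species:
        sizes = np.sort(table.counts[s].to_numpy())
        nonzero = sizes[sizes > 0]
        m = len(nonzero)
        coords = pd.DataFrame(
            {
                "normal_quantile": stats.norm.ppf((np.arange(1, m + 1) - 0.5) / m),
                "log10_size": np.log10(nonzero),
            }
        )
        summary[s] = {
            "median": float(np.median(sizes)),
            "n_absent": int((sizes == 0).sum()),
            "lognormal_coords": coords,
        }
    return summary


def compare_to_background(
    table: SpeciesCountTable,
    focal_families: set[str] | list[str],
) -> pd.Series:
    """One-sided test that focal (gradient) families are larger than the
    remaining families, per species.

    Mann-Whitney U with midranks for ties, normal approximation and
    continuity correction; alternative: focal sizes stochastically larger.
    """
    focal = set(focal_families)
    unknown = focal - set(table.counts.index)
    if unknown:
        raise ValueError(f"focal families not in table: {sorted(unknown)[:5]}")
    background = set(table.counts.index) - focal
    if len(focal) < 2 or len(background) < 2:
        raise ValueError("need >= 2 families in both focal and background groups")
    pvals = {}
    for s in table.species:
        x = table.counts.loc[sorted(focal), s].to_numpy()
        y = table.counts.loc[sorted(background), s].to_numpy()
        res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        pvals[s] = float(res.pvalue)
    return pd.Series(pvals, name="p_greater")
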