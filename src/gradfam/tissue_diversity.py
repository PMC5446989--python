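"""Normalised-entropy tissue-diversity score for gene families.

Each gradient member of a family is assigned to the tissue where its mean
expression peaks (among tissues of the sets where it was called), giving a
count vector n_1..n_T over the T distinct tissue types.  The diversity of
the family is the Shannon entropy of the member-to-tissue distribution
normalised by its maximum:

    H = -sum_i p_i ln p_i,   p_i = n_i / n,   D = H / ln(T)

so D = 0 when every member sits in a single tissue ("specialized") and
D = 1 when members occur with equal frequency in all T tissues
("diverse").  The logarithm base cancels in the ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gradient_detection import ExpressionAtlas

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.5


class DiversityError(ValueError):
    """Raised on degenerate count vectors or invalid tissue counts."""


@dataclass
class DiversityScore:
    family_id: str
    tissue_counts: np.ndarray  # length T, non-negative (fractional allowed)
    n: float
    H: float
    D: float


def diversity(tissue_counts, T: int | None = None, family_id: str = "") -> DiversityScore:
    """Normalised Shannon entropy of a tissue-count vector.

    ``T`` defaults to the vector length; it must be >= 2 and at least the
    number of populated entries.  Zero-count tissues contribute nothing
    (0 ln 0 = 0 convention).
    """
    counts = np.asarray(tissue_counts, dtype=float)
    if counts.ndim != 1:
        raise DiversityError("tissue_counts must be a 1-d vector")
    if (counts < 0).any():
        raise DiversityError("tissue counts must be non-negative")
    if T is None:
        T = len(counts)
    if T < 2:
        raise DiversityError("need at least 2 tissues")
    if len(counts) > T:
        raise DiversityError("count vector longer than tissue count T")
    n = counts.sum()
    if n <= 0:
        raise DiversityError("all-zero tissue counts: diversity undefined")
    p = counts[counts > 0] / n
    H = float(-np.sum(p * np.log(p)))
    return DiversityScore(family_id, counts, float(n), H, H / np.log(T))


def assign_member_tissues(
    members,
    calls: pd.DataFrame,
    atlas: ExpressionAtlas,
    tissue_order: list[str] | None = None,
    mode: str = "peak",
) -> np.ndarray:
    """Tally family members into tissues, yielding the count vector for
    :func:`diversity`.

    mode="peak" (default): each member with at least one gradient call
    contributes one count to the tissue with the highest mean expression
    among the tissues of the sets where it was called; ties are broken by
    the fixed tissue ordering and logged.  mode="significant": the
    member's unit weight is split evenly across the distinct tissues in
    which it was called as the peak tissue, giving fractional counts.
    Members with no call contribute nothing.
    """
    if mode not in ("peak", "significant"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    if tissue_order is None:
        tissue_order = atlas.distinct_tissues()
    index_of = {t: i for i, t in enumerate(tissue_order)}
    counts = np.zeros(len(tissue_order), dtype=float)

    member_set = set(members)
    sub = calls[calls["gene_id"].isin(member_set)]
    if sub.empty:
        return counts

    for gene, gene_calls in sub.groupby("gene_id", sort=True):
        if mode == "significant":
            peaks = sorted(set(gene_calls["peak_tissue"]))
            for t in peaks:
                counts[index_of[t]] += 1.0 / len(peaks)
            continue
        # peak mode: highest mean expression over tissues of called sets
        called_sets = sorted(set(gene_calls["set"]))
        means: dict[str, float] = {}
        for set_name in called_sets:
            for tissue in atlas.tissues_in_set(set_name):
                cols = atlas.samples_of(set_name, tissue)
                m = float(atlas.values.loc[gene, cols].mean())
                means[tissue] = max(means.get(tissue, -np.inf), m)
        best = max(means.values())
        top = [t for t, m in means.items() if m == best]
        if len(top) > 1:
            logger.info("gene %s: peak-tissue tie among %s, fixed order wins", gene, top)
        peak = min(top, key=lambda t: index_of[t])
        counts[index_of[peak]] += 1.0
    return counts


def score_families(
    family_members: dict[str, set[str]],
    calls: pd.DataFrame,
    atlas: ExpressionAtlas,
    tissue_order: list[str] | None = None,
    mode: str = "peak",
) -> list[DiversityScore]:
    """Diversity score per family; families with no called member are
    skipped with a log note."""
    if tissue_order is None:
        tissue_order = atlas.distinct_tissues()
    scores = []
    for fam in sorted(family_members):
        counts = assign_member_tissues(family_members[fam], calls, atlas, tissue_order, mode)
        if counts.sum() <= 0:
            logger.info("family %s has no gradient members; skipped", fam)
            continue
        scores.append(diversity(counts, len(tissue_order), family_id=fam))
    return scores


def classify(
    scores: list[DiversityScore], cutoff: float = DEFAULT_CUTOFF
) -> tuple[dict[str, str], dict[str, float]]:
    """Label families as specialized (D < cutoff, strict) or diverse.

    Returns (labels, summary) where summary reports the median D and the
    number of specialized families.
    """
    if not scores:
        raise DiversityError("no diversity scores to classify")
    labels = {
        s.family_id: ("specialized" if s.D < cutoff else "diverse") for s in scores
    }
    ds = np.array([s.D for s in scores])
    summary = {
        "median_D": float(np.median(ds)),
        "n_specialized": int(sum(1 for s in scores if s.D < cutoff)),
        "n_families": len(scores),
    }
    return labels, summary


def scores_to_frame(scores: list[DiversityScore], tissue_order: list[str]) -> pd.DataFrame:
    """Flatten scores to a table: family_id, n, one column per tissue, H, D."""
    rows = []
    for s in scores:
        row = {"family_id": s.family_id, "n": s.n}
        row.update({t: c for t, c in zip(tissue_order, s.tissue_counts)})
        row.update({"H": s.H, "D": s.D})
        rows.append(row)
    return pd.DataFrame(rows)
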