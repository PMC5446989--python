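"""Synthetic data with planted ground truth for the full analysis pipeline.

Emulates the structure of the real study system: four tissue "sets" (a
FACS-sorted root atlas and laser-capture seed atlases at three embryo
stages) covering 10 distinct tissue types with ~3 replicates each; gene
families of log-normally distributed sizes annotated by protein-domain
accessions; per-species family-count tables with planted expansions; and
subcellular-compartment assignments.  Every generator records what it
planted so downstream stages can be scored against known truth.

All expression values are generated directly on the log2 scale (arrays of
this kind are conventionally analysed after RMA-style log2 normalisation;
simulating raw intensities would add nothing testable).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gradient_detection import ExpressionAtlas

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised on invalid generator configuration."""


#: Default tissue topology: one root set of five concentric cell layers and
#: three seed sets (pre-globular, globular, heart embryo stages).  The
#: embryo, endosperm regions and seed coat recur across stages under the
#: same tissue name, so the distinct tissue types total 10.
DEFAULT_SETS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("root", ("columella", "lateral_root_cap_epidermis", "cortex", "endodermis", "stele")),
    ("seed_preglobular", ("embryo", "micropylar_endosperm", "peripheral_endosperm", "seed_coat")),
    ("seed_globular", ("embryo", "suspensor", "micropylar_endosperm", "peripheral_endosperm", "seed_coat")),
    ("seed_heart", ("embryo", "micropylar_endosperm", "peripheral_endosperm", "seed_coat")),
)

#: Published total gene-locus counts for the four reference genomes
#: (one gene per locus).
DEFAULT_SPECIES_TOTALS: dict[str, int] = {
    "Chlamydomonas": 17741,
    "Physcomitrella": 32926,
    "Arabidopsis": 27416,
    "Oryza": 42189,
}

DEFAULT_COMPARTMENTS: tuple[str, ...] = (
    "extracellular",
    "plasma_membrane",
    "cytosol",
    "nucleus",
    "plastid",
    "er",
    "mitochondrion",
    "other",
)


@dataclass
class AtlasConfig:
    """Configuration of the synthetic expression atlas.

    Attributes
    ----------
    sets
        Ordered (set_name, tissue names) topology.  The default mirrors the
        study design: 5 root layers plus three seed stages sharing tissue
        names, 10 distinct tissue types in total.
    replicates_per_tissue
        Biological replicates per (set, tissue); at least 2.
    noise_sd
        Between-replicate standard deviation in log2 units.
    baseline_mean
        Centre of the per-gene baseline log2 expression distribution.
    gene_baseline_sd
        Spread of per-gene baselines in log2 units (log-normal expression
        levels across genes).  This gene-level signal is shared by all of
        a gene's samples and is what makes biological replicates correlate
        strongly; it cancels in every between-tissue comparison.
    gradient_fraction
        Fraction of genes with a planted between-tissue gradient.
    gradient_effect
        Planted offset, in log2 units, of one tissue's mean for each
        planted gene.
    """

    sets: tuple[tuple[str, tuple[str, ...]], ...] = DEFAULT_SETS
    replicates_per_tissue: int = 3
    n_genes: int = 2000
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    gene_baseline_sd: float = 2.0
    gradient_fraction: float = 0.10
    gradient_effect: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.replicates_per_tissue < 2:
            raise ConfigError("replicates_per_tissue must be >= 2")
        if self.noise_sd < 0 or self.gene_baseline_sd < 0:
            raise ConfigError("noise_sd and gene_baseline_sd must be non-negative")
        if not 0 <= self.gradient_fraction < 1:
            raise ConfigError("gradient_fraction must lie in [0, 1)")
        if self.gradient_effect <= 0:
            raise ConfigError("gradient_effect must be positive")
        if not self.sets:
            raise ConfigError("at least one tissue set is required")
        for name, tissues in self.sets:
            if len(tissues) < 2:
                raise ConfigError(f"set {name!r} needs >= 2 tissues")

    @property
    def distinct_tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, tissues in self.sets:
            for t in tissues:
                seen.setdefault(t)
        return list(seen)

    @property
    def n_samples(self) -> int:
        return sum(len(t) for _, t in self.sets) * self.replicates_per_tissue


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators, for recovery tests."""

    planted_gradient_genes: set[str] = field(default_factory=set)
    #: planted gene -> (set, tissue) where its mean was offset
    planted_gene_targets: dict[str, tuple[str, str]] = field(default_factory=dict)
    planted_enriched_families: set[str] = field(default_factory=set)
    family_members: dict[str, set[str]] = field(default_factory=dict)
    #: (family, (species_from, species_to)) -> expansion factor
    planted_expansions: dict[tuple[str, tuple[str, str]], float] = field(default_factory=dict)
    #: family -> tissue-count vector over the distinct tissue types
    planted_tissue_profiles: dict[str, list[float]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "planted_gradient_genes": sorted(self.planted_gradient_genes),
            "planted_gene_targets": {g: list(v) for g, v in sorted(self.planted_gene_targets.items())},
            "planted_enriched_families": sorted(self.planted_enriched_families),
            "family_members": {f: sorted(m) for f, m in sorted(self.family_members.items())},
            "planted_expansions": [
                [fam, list(pair), factor] for (fam, pair), factor in sorted(self.planted_expansions.items())
            ],
            "planted_tissue_profiles": {f: list(v) for f, v in sorted(self.planted_tissue_profiles.items())},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate_atlas(config: AtlasConfig) -> tuple[ExpressionAtlas, SyntheticTruth]:
    """Generate a replicated log2 expression atlas with planted gradients.

    Each gene receives a baseline drawn from Normal(baseline_mean,
    gene_baseline_sd); every sample value is then the baseline plus i.i.d.
    replicate noise Normal(0, noise_sd).  Each planted gradient gene is
    assigned one (set, tissue) uniformly at random; its mean in that
    tissue's samples is offset by ``gradient_effect``.  Reproducible given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)

    sheet_rows = []
    for set_name, tissues in config.sets:
        for tissue in tissues:
            for r in range(1, config.replicates_per_tissue + 1):
                sheet_rows.append(
                    {
                        "sample_id": f"{set_name}.{tissue}.r{r}",
                        "set": set_name,
                        "tissue": tissue,
                        "replicate": r,
                    }
                )
    sheet = pd.DataFrame(sheet_rows)

    baselines = rng.normal(config.baseline_mean, config.gene_baseline_sd, config.n_genes)
    values = baselines[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, len(sheet))
    )

    truth = SyntheticTruth()
    n_planted = int(round(config.gradient_fraction * config.n_genes))
    if n_planted:
        planted_idx = rng.choice(config.n_genes, size=n_planted, replace=False)
        slots = [(s, t) for s, tissues in config.sets for t in tissues]
        col_of = {sid: j for j, sid in enumerate(sheet["sample_id"])}
        for i in planted_idx:
            set_name, tissue = slots[rng.integers(len(slots))]
            gene = genes[i]
            truth.planted_gradient_genes.add(gene)
            truth.planted_gene_targets[gene] = (set_name, tissue)
            target_cols = [
                col_of[sid]
                for sid, s, t in zip(sheet["sample_id"], sheet["set"], sheet["tissue"])
                if s == set_name and t == tissue
            ]
            values[i, target_cols] += config.gradient_effect

    matrix = pd.DataFrame(
        values, index=pd.Index(genes, name="gene_id"), columns=list(sheet["sample_id"])
    )
    return ExpressionAtlas(matrix, sheet), truth


def generate_family_annotations(
    gene_ids: list[str],
    truth: SyntheticTruth,
    n_families: int = 40,
    size_log_mean: float = math.log(14.0),
    size_log_sd: float = 0.6,
    n_enriched: int = 5,
    enrichment_bias: float = 0.9,
    min_enriched_size: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a gene -> protein-domain annotation table.

    Family sizes are log-normal (rounded, clipped to >= 1), matching the
    roughly straight-line appearance of family-size distributions on
    log-normal probability axes.  The first ``n_enriched`` families are
    planted as enriched: each of their members is, with probability
    ``enrichment_bias``, drawn from the planted gradient genes.  Planted
    families are pairwise disjoint (a gene carries at most one planted
    domain), mirroring how domain families largely partition a genome and
    keeping the planted truth stable under non-overlap curation.  The
    truth object is updated in place with family memberships and, for
    enriched families, the tissue profile implied by their planted
    members.

    Returns a two-column DataFrame (gene_id, domain_id); genes may carry
    zero or several domains.
    """
    if n_families < 1:
        raise ConfigError("n_families must be >= 1")
    if not 0 <= enrichment_bias <= 1:
        raise ConfigError("enrichment_bias must lie in [0, 1]")
    if n_enriched > n_families:
        raise ConfigError("n_enriched cannot exceed n_families")
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    n_genes = len(gene_ids)

    gradient_pool = sorted(truth.planted_gradient_genes)
    if n_enriched > 0 and not gradient_pool:
        raise ConfigError("cannot plant enriched families without planted gradient genes")

    sizes = np.clip(
        np.rint(rng.lognormal(size_log_mean, size_log_sd, size=n_families)).astype(int),
        1,
        None,
    )
    rows: list[tuple[str, str]] = []
    width = max(4, len(str(n_families)))
    available = set(gene_ids)
    for j in range(n_families):
        fam = f"D{j:0{width}d}"
        enriched = j < n_enriched
        size = max(int(sizes[j]), min_enriched_size) if enriched else int(sizes[j])
        if size > len(available):
            raise ConfigError(
                f"family {fam} requests {size} members but only "
                f"{len(available)} unassigned genes remain"
            )
        if enriched:
            grad_avail = sorted(available & set(gradient_pool))
            n_from_grad = int(np.sum(rng.random(size) < enrichment_bias))
            n_from_grad = min(n_from_grad, len(grad_avail), size)
            members = list(rng.choice(grad_avail, size=n_from_grad, replace=False))
            others = sorted(available - set(members))
            members += list(rng.choice(others, size=size - n_from_grad, replace=False))
            truth.planted_enriched_families.add(fam)
        else:
            members = list(rng.choice(sorted(available), size=size, replace=False))
        available -= set(members)
        truth.family_members[fam] = set(members)
        rows.extend((g, fam) for g in sorted(members))

    return pd.DataFrame(rows, columns=["gene_id", "domain_id"])


def tissue_profile_of_family(
    members: set[str], truth: SyntheticTruth, tissue_order: list[str]
) -> list[int]:
    """Planted tissue-count vector: one count per planted member, at the
    tissue where its gradient was planted."""
    counts = {t: 0 for t in tissue_order}
    for gene in members:
        target = truth.planted_gene_targets.get(gene)
        if target is not None:
            counts[target[1]] += 1
    return [counts[t] for t in tissue_order]


def generate_species_counts(
    family_ids: list[str],
    species_totals: dict[str, int] | None = None,
    base_counts: dict[str, float] | float = 10.0,
    expansion_map: dict[tuple[str, str], float] | None = None,
    zero_inflation: dict[str, float] | None = None,
    reference_species: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a per-species family-count table with planted expansions.

    The count of family *f* in species *s* is a Poisson draw with rate
    ``base_count(f) * expansion_factor(f, s) * N_s / N_ref`` where ``N_s``
    is the species' total gene-locus count, so a factor of 1 everywhere
    means family sizes merely track genome size.  ``zero_inflation[s]``
    optionally zeroes each family's count in species *s* with the given
    probability, emulating families with no representatives in the
    simplest species.

    Returns a DataFrame indexed by family_id with one column per species.
    """
    totals = dict(species_totals or DEFAULT_SPECIES_TOTALS)
    if any(v <= 0 for v in totals.values()):
        raise ConfigError("species totals must be positive")
    species = list(totals)
    ref = reference_species or species[0]
    if ref not in totals:
        raise ConfigError(f"reference species {ref!r} not in totals")
    expansion_map = expansion_map or {}
    zero_inflation = zero_inflation or {}
    for s, z in zero_inflation.items():
        if not 0 <= z <= 1:
            raise ConfigError(f"zero_inflation[{s!r}] must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    counts = np.zeros((len(family_ids), len(species)), dtype=int)
    for i, fam in enumerate(family_ids):
        base = base_counts[fam] if isinstance(base_counts, dict) else float(base_counts)
        for j, s in enumerate(species):
            factor = expansion_map.get((fam, s), 1.0)
            rate = base * factor * totals[s] / totals[ref]
            k = rng.poisson(rate)
            if rng.random() < zero_inflation.get(s, 0.0):
                k = 0
            counts[i, j] = k
    return pd.DataFrame(counts, index=pd.Index(family_ids, name="family_id"), columns=species)


def generate_localization(
    gene_ids: list[str],
    fractions: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each gene one subcellular-compartment label.

    ``fractions`` maps compartment -> probability (normalised internally);
    the default is a flat mix over the standard vocabulary.
    """
    if fractions is None:
        fractions = {c: 1.0 for c in DEFAULT_COMPARTMENTS}
    labels = list(fractions)
    probs = np.asarray([fractions[c] for c in labels], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ConfigError("compartment fractions must be non-negative and sum > 0")
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    assigned = rng.choice(labels, size=len(gene_ids), p=probs)
    return pd.DataFrame({"gene_id": list(gene_ids), "compartment": assigned})


def _sizes_with_median(median: float, n: int, spread: float, floor: int) -> list[int]:
    """Deterministic, roughly log-normal integer size vector of length n
    whose midpoint-convention median is exactly ``median``."""
    half = n // 2
    lower = [max(floor, int(round(median * spread ** ((i - half) / half)))) for i in range(half - 1)]
    upper = [int(round(median * spread ** ((i + 1) / half))) for i in range(half - 1)]
    mid = [int(math.floor(median)), int(math.ceil(median))]
    if (mid[0] + mid[1]) / 2 != median:
        # non-half-integer target: nudge the two central values
        mid = [int(round(median)), int(round(median))]
    sizes = sorted(lower + mid + upper)
    assert len(sizes) == n
    return sizes


def reference_counts_fixture() -> tuple[pd.DataFrame, dict[str, int]]:
    """Deterministic 66-family species-count table shaped like the curated
    gradient-family catalogue: per-species medians 41 (Arabidopsis),
    46 (Oryza), 21 (Physcomitrella) and 2 (Chlamydomonas), with 25 of the
    66 families absent from Chlamydomonas.

    Synthetic: sizes are built from smooth log-spaced quantiles, not taken
    from any published table.  Returns (counts, totals).
    """
    n = 66
    ath = _sizes_with_median(41.0, n, spread=6.0, floor=10)
    osa = _sizes_with_median(46.0, n, spread=6.0, floor=10)
    ppa = _sizes_with_median(21.0, n, spread=8.0, floor=1)
    # Chlamydomonas: 25 absences; remaining 41 counts arranged so the
    # 33rd/34th order statistics are both 2 (median 2 by the midpoint rule).
    cre = [0] * 25 + [1] * 7 + [2] * 4 + [3, 4, 5, 6, 8, 10, 12, 15, 18, 22] + [
        26, 30, 35, 40, 46, 52, 60, 68, 78, 88, 100, 115, 130, 150, 170, 190, 210, 230, 250, 275
    ]
    assert len(cre) == n
    counts = pd.DataFrame(
        {
            "Chlamydomonas": cre,
            "Physcomitrella": ppa,
            "Arabidopsis": ath,
            "Oryza": osa,
        },
        index=pd.Index([f"fam{i:02d}" for i in range(n)], name="family_id"),
    )
    return counts, dict(DEFAULT_SPECIES_TOTALS)
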