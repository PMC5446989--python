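"""Detection of expression-gradient genes within tissue sets.

A *gradient gene* is a gene with a statistically significant expression
difference between two tissues sampled in the same experiment ("set"),
e.g. adjacent cell layers of the root apex or neighbouring regions of a
developing seed.  Detection operates on an already-normalised log2
expression matrix with replicated samples per tissue:

1. replicate-reproducibility filtering drops outlier replicate columns
   (and whole sets when a tissue is left with fewer than two replicates);
2. per tissue pair, a two-sample t test on the log2 replicate values,
   with Benjamini-Hochberg FDR control across all (gene, pair) tests
   within a set;
3. a call is emitted when q < alpha and |log2 fold difference| exceeds a
   minimum-effect threshold; the peak tissue is the one with the larger
   mean.

With ~3 replicates per tissue a per-gene variance estimate has so few
degrees of freedom that even large, perfectly reproducible fold changes
cannot survive FDR control over tens of thousands of tests.  The default
statistic is therefore an empirical-Bayes moderated t in the style of
limma: per gene, the within-tissue variance pooled across the set is
shrunk toward a prior fitted to all genes (a scaled-F model estimated
from the log sample variances), and the test gains the prior degrees of
freedom.  A plain Welch t is available via ``statistic="welch"``.
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

#: default stage parameters, overridable in every entry point
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_ABS_LOG2_FOLD = 1.0
DEFAULT_MIN_CORRELATION = 0.9

SAMPLE_SHEET_COLUMNS = ("sample_id", "set", "tissue", "replicate")

#: columns of the gradient-call table
CALL_COLUMNS = (
    "gene_id",
    "set",
    "tissue_a",
    "tissue_b",
    "log2_fold",
    "p_value",
    "q_value",
    "peak_tissue",
)


class AtlasError(ValueError):
    """Raised when an expression atlas is malformed or inconsistent."""


@dataclass
class ExpressionAtlas:
    """A log2 expression matrix (genes x samples) plus its sample sheet.

    Parameters
    ----------
    values
        DataFrame of log2 expression values; index = gene ids, columns =
        sample ids.
    sample_sheet
        DataFrame with columns ``sample_id``, ``set``, ``tissue``,
        ``replicate``; every ``sample_id`` must be a column of ``values``.
    """

    values: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise AtlasError("empty expression matrix")
        missing_cols = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.sample_sheet.columns]
        if missing_cols:
            raise AtlasError(f"sample sheet missing columns: {missing_cols}")
        sheet_ids = list(self.sample_sheet["sample_id"])
        if len(set(sheet_ids)) != len(sheet_ids):
            raise AtlasError("duplicate sample ids in sample sheet")
        matrix_ids = set(self.values.columns)
        absent = [s for s in sheet_ids if s not in matrix_ids]
        if absent:
            raise AtlasError(f"samples in sheet missing from matrix: {absent}")
        if not np.issubdtype(np.asarray(self.values).dtype, np.number):
            raise AtlasError("expression matrix contains non-numeric values")

    # -- convenience accessors -------------------------------------------------

    def set_names(self) -> list[str]:
        """Set names in sheet order."""
        return list(dict.fromkeys(self.sample_sheet["set"]))

    def tissues_in_set(self, set_name: str) -> list[str]:
        sub = self.sample_sheet[self.sample_sheet["set"] == set_name]
        if sub.empty:
            raise AtlasError(f"unknown set: {set_name!r}")
        return list(dict.fromkeys(sub["tissue"]))

    def distinct_tissues(self) -> list[str]:
        """Distinct tissue types across all sets, in order of first appearance."""
        return list(dict.fromkeys(self.sample_sheet["tissue"]))

    def samples_of(self, set_name: str, tissue: str) -> list[str]:
        sub = self.sample_sheet
        mask = (sub["set"] == set_name) & (sub["tissue"] == tissue)
        return list(sub.loc[mask, "sample_id"])

    def n_replicates(self, set_name: str, tissue: str) -> int:
        return len(self.samples_of(set_name, tissue))


def reproducibility_filter(
    atlas: ExpressionAtlas, min_correlation: float = DEFAULT_MIN_CORRELATION
) -> ExpressionAtlas:
    """Drop replicates that do not reproduce their tissue-mates.

    For every (set, tissue) group all pairwise Pearson correlations between
    replicate columns are computed; while any replicate's *median* pairwise
    correlation falls below ``min_correlation``, the worst such replicate is
    dropped and the correlations re-evaluated (greedy removal, so one bad
    outlier cannot drag its well-behaved mates below the threshold).  A
    tissue left with fewer than two replicates invalidates its whole set,
    which is then excluded with a warning.
    """
    if not 0 < min_correlation < 1:
        raise ValueError("min_correlation must lie in (0, 1)")
    sheet = atlas.sample_sheet
    dropped_samples: set[str] = set()
    invalid_sets: set[str] = set()

    for (set_name, tissue), group in sheet.groupby(["set", "tissue"], sort=False):
        cols = list(group["sample_id"])
        if len(cols) < 2:
            raise AtlasError(
                f"tissue {tissue!r} in set {set_name!r} has fewer than 2 replicates"
            )
        kept = list(cols)
        while len(kept) >= 2:
            corr = np.corrcoef(atlas.values[kept].to_numpy().T)
            medians = np.array(
                [np.median(np.delete(corr[i], i)) for i in range(len(kept))]
            )
            if medians.min() >= min_correlation:
                break
            worst = int(np.argmin(medians))
            logger.warning(
                "dropping replicate %s (set=%s tissue=%s): median r=%.3f < %.3f",
                kept[worst], set_name, tissue, float(medians[worst]), min_correlation,
            )
            dropped_samples.add(kept.pop(worst))
        else:
            # a lone survivor cannot be assessed; treat it as unusable
            dropped_samples.update(kept)
            kept = []
        if len(kept) < 2:
            logger.warning(
                "set %s excluded: tissue %s left with %d replicate(s) after filtering",
                set_name, tissue, len(kept),
            )
            invalid_sets.add(set_name)

    keep_mask = ~sheet["sample_id"].isin(dropped_samples) & ~sheet["set"].isin(invalid_sets)
    new_sheet = sheet[keep_mask].reset_index(drop=True)
    if new_sheet.empty:
        raise AtlasError("no sets survived the reproducibility filter")
    return ExpressionAtlas(atlas.values[list(new_sheet["sample_id"])], new_sheet)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    from scipy.special import polygamma

    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    return x


def fit_scaled_f_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit a scaled-F prior to per-gene sample variances.

    Models s2 ~ s0^2 * F(df, d0) and estimates (d0, s0^2) by matching the
    mean and variance of log(s2), the standard empirical-Bayes recipe for
    variance moderation.  Returns d0 = inf when the observed spread of
    log-variances is no larger than expected under a single common
    variance.
    """
    from scipy.special import digamma, polygamma

    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if len(s2) < 2:
        return np.inf, float(s2.mean()) if len(s2) else 0.0
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0 = float(np.exp(e.mean()))
    return d0, s0


def _pooled_set_variance(
    atlas: ExpressionAtlas, set_name: str
) -> tuple[np.ndarray, float]:
    """Per-gene within-tissue variance pooled across all tissues of a set
    (one-way layout, homoscedastic across tissues), with its df."""
    ss = np.zeros(atlas.values.shape[0])
    df = 0.0
    for tissue in atlas.tissues_in_set(set_name):
        cols = atlas.samples_of(set_name, tissue)
        x = atlas.values[cols].to_numpy()
        ss += ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += len(cols) - 1
    return ss / df, df


def _moderated_test(
    diff: np.ndarray, s2_tilde: np.ndarray, df_total: float, na: int, nb: int
) -> np.ndarray:
    """Two-sided p for a mean difference given moderated variances."""
    se2 = s2_tilde * (1.0 / na + 1.0 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
    zero_se = se2 == 0
    p = np.where(zero_se & (diff != 0), 0.0, p)
    p = np.where(zero_se & (diff == 0), np.nan, p)
    return p


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t test over genes (rows).  Returns (t, p).

    Degenerate rows (zero variance in both groups) yield p = 0 when the
    means differ (the difference is exact) and p = NaN when they are equal
    (undefined statistic; the caller suppresses the test).
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_se = se2 == 0
    p = np.where(zero_se & (diff != 0), 0.0, p)
    p = np.where(zero_se & (diff == 0), np.nan, p)
    return t, p


def detect_gradients(
    atlas: ExpressionAtlas,
    set_name: str,
    alpha: float = DEFAULT_ALPHA,
    min_abs_log2_fold: float = DEFAULT_MIN_ABS_LOG2_FOLD,
    pairs: str | list[tuple[str, str]] = "all",
    statistic: str = "moderated",
) -> pd.DataFrame:
    """Differential expression between tissue pairs of one set.

    Parameters
    ----------
    pairs
        ``"all"`` tests every within-set tissue pair; alternatively an
        explicit list of (tissue_a, tissue_b) pairs restricts testing to an
        anatomical adjacency list.
    statistic
        ``"moderated"`` (default): empirical-Bayes moderated t with the
        within-tissue variance pooled across the set and shrunk toward a
        scaled-F prior fitted over genes.  ``"welch"``: per-pair Welch t.

    Returns
    -------
    DataFrame with one row per significant (gene, pair) call, columns
    :data:`CALL_COLUMNS`.  ``log2_fold`` is mean(tissue_a) - mean(tissue_b);
    ``peak_tissue`` is the tissue with the larger mean.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if min_abs_log2_fold < 0:
        raise ValueError("min_abs_log2_fold must be non-negative")
    if statistic not in ("moderated", "welch"):
        raise ValueError(f"unknown statistic {statistic!r}")
    tissues = atlas.tissues_in_set(set_name)
    if pairs == "all":
        pair_list = list(itertools.combinations(tissues, 2))
    else:
        pair_list = [tuple(p) for p in pairs]
        for ta, tb in pair_list:
            if ta not in tissues or tb not in tissues:
                raise AtlasError(f"pair ({ta!r}, {tb!r}) not in set {set_name!r}")

    genes = atlas.values.index.to_numpy()
    if statistic == "moderated":
        s2, df_resid = _pooled_set_variance(atlas, set_name)
        d0, s0 = fit_scaled_f_prior(s2, df_resid)
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0)
        else:
            s2_tilde = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    records: list[pd.DataFrame] = []
    for ta, tb in pair_list:
        cols_a = atlas.samples_of(set_name, ta)
        cols_b = atlas.samples_of(set_name, tb)
        a = atlas.values[cols_a].to_numpy()
        b = atlas.values[cols_b].to_numpy()
        lfc = a.mean(axis=1) - b.mean(axis=1)
        if statistic == "moderated":
            p = _moderated_test(lfc, s2_tilde, df_total, a.shape[1], b.shape[1])
        else:
            _, p = _welch(a, b)
        records.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "set": set_name,
                    "tissue_a": ta,
                    "tissue_b": tb,
                    "log2_fold": lfc,
                    "p_value": p,
                }
            )
        )
    table = pd.concat(records, ignore_index=True)

    suppressed = table["p_value"].isna()
    if suppressed.any():
        logger.info(
            "set %s: %d degenerate tests suppressed (zero variance, equal means)",
            set_name, int(suppressed.sum()),
        )
        table = table[~suppressed].reset_index(drop=True)
    if table.empty:
        return pd.DataFrame(columns=list(CALL_COLUMNS))

    # BH across all (gene, pair) tests within the set
    _, q, _, _ = multipletests(table["p_value"].to_numpy(), method="fdr_bh")
    table["q_value"] = q
    table["peak_tissue"] = np.where(
        table["log2_fold"] >= 0, table["tissue_a"], table["tissue_b"]
    )
    keep = (table["q_value"] < alpha) & (table["log2_fold"].abs() >= min_abs_log2_fold)
    calls = table[keep].reset_index(drop=True)
    return calls[list(CALL_COLUMNS)]


def detect_gradients_all_sets(
    atlas: ExpressionAtlas,
    alpha: float = DEFAULT_ALPHA,
    min_abs_log2_fold: float = DEFAULT_MIN_ABS_LOG2_FOLD,
    pairs: str | dict[str, list[tuple[str, str]]] = "all",
    statistic: str = "moderated",
) -> pd.DataFrame:
    """Run :func:`detect_gradients` on every set and concatenate the calls."""
    frames = []
    for set_name in atlas.set_names():
        set_pairs = pairs if pairs == "all" else pairs.get(set_name, "all")
        frames.append(
            detect_gradients(atlas, set_name, alpha, min_abs_log2_fold, set_pairs, statistic)
        )
    if not frames:
        return pd.DataFrame(columns=list(CALL_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def union_gradient_genes(calls: pd.DataFrame | list[pd.DataFrame]) -> list[str]:
    """Deduplicated, lexicographically ordered union of called gene ids."""
    if isinstance(calls, list):
        if not calls:
            return []
        calls = pd.concat(calls, ignore_index=True)
    if calls.empty:
        return []
    return sorted(set(calls["gene_id"]))
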