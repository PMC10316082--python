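"""Peptide and protein DE-scores.

The peptide DE-score is the clipped log2 of the median of all M×N pairwise
abundance ratios between the two sample groups. Each peptide also receives a
two-sided Mann–Whitney p-value, and within each protein a weight combining
its mean expression level with its positive Pearson correlations to sibling
peptides. The protein DE-score is the sum of significance-gated, weighted
peptide scores; single-peptide proteins use the unclipped log2 median ratio
gated by their own p-value.

Zero-abundance policy (zeros are missing values): a pair with both members
zero is uninformative and dropped; a zero denominator gives a ratio of +inf
and a zero numerator gives 0, so consistent presence in only one group drives
the score to the clip bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import (
    FilterParams,
    FilterReport,
    NormalizationParams,
    apply_filters,
    detect_outlier_samples,
    normalize_samples,
)
from .tables_io import (
    ContaminantAnnotation,
    PeptideTable,
    PepdescError,
    SampleDesign,
    ValidationError,
    align_table_to_design,
    logger,
)

__all__ = [
    "DEParams",
    "PepdescResult",
    "pairwise_ratio_median",
    "peptide_de_score",
    "wilcoxon_two_sided",
    "positive_pearson",
    "peptide_weights",
    "protein_de_score",
    "score_peptides",
    "run_pepdesc",
]

#: exact Mann–Whitney null is used up to this many pairs (tie-free only)
_EXACT_PAIR_LIMIT = 400


@dataclass
class DEParams:
    """Scoring parameters.

    clip:
        Bound on |peptide DE-score| (default 1.5).
    alpha:
        Significance gate: a peptide contributes to its protein's score only
        when its Mann–Whitney p-value is strictly below alpha (default 0.05).
    clip_single_peptide:
        Whether the single-peptide protein score is clipped like peptide
        scores; off by default (the single-peptide rule is written unclipped).
    weight_stats_on_observed:
        Compute the means and correlations behind the peptide weights over
        non-missing entries only, instead of over all retained samples with
        zeros included (the default, matching the fill-with-0 convention).
    """

    clip: float = 1.5
    alpha: float = 0.05
    clip_single_peptide: bool = False
    weight_stats_on_observed: bool = False

    def __post_init__(self) -> None:
        if self.clip <= 0:
            raise ValidationError("clip must be > 0")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# Peptide-level statistics
# ---------------------------------------------------------------------------


def pairwise_ratio_median(x1, x2) -> tuple[float, int]:
    """Median of all pairwise ratios x1[m] / x2[n] under the zero policy.

    Pairs with both members zero are dropped; a zero denominator yields +inf,
    a zero numerator yields 0. With an even number of retained pairs the
    median is the midpoint of the two central values (+inf wins a midpoint).

    Returns ``(median, n_pairs_retained)``; the median is NaN when every pair
    was dropped (an all-missing peptide), which excludes the peptide
    downstream.
    """
    a = np.asarray(x1, dtype=float)[:, None]
    b = np.asarray(x2, dtype=float)[None, :]
    both_zero = (a == 0) & (b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = (a / b)[~both_zero]
    n_pairs = int(ratios.size)
    if n_pairs == 0:
        return float("nan"), 0
    return float(np.median(ratios)), n_pairs


def peptide_de_score(median_ratio: float, clip: float = 1.5) -> float:
    """Clipped log2 of a median pairwise ratio; ±inf and 0 map to ±clip."""
    if np.isnan(median_ratio):
        return float("nan")
    if median_ratio == 0:
        return -clip
    if np.isinf(median_ratio):
        return clip
    return float(np.clip(np.log2(median_ratio), -clip, clip))


def wilcoxon_two_sided(x1, x2) -> float:
    """Two-sided Mann–Whitney p-value from U = min(U1, U2).

    Uses the exact null distribution when the input is tie-free and
    M·N ≤ 400, otherwise the tie-corrected normal approximation with
    continuity correction. Zeros (missing values) participate as tied
    observations. Completely tied data gives p = 1.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    pooled = np.concatenate([x1, x2])
    if np.all(pooled == pooled[0]):
        return 1.0
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if tie_free and x1.size * x2.size <= _EXACT_PAIR_LIMIT else "asymptotic"
    res = stats.mannwhitneyu(x1, x2, alternative="two-sided", method=method)
    return min(float(res.pvalue), 1.0)


def positive_pearson(xi, xj) -> float:
    """Pearson correlation truncated at zero; constant vectors give 0."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if np.ptp(xi) == 0 or np.ptp(xj) == 0:
        return 0.0
    r = float(np.corrcoef(xi, xj)[0, 1])
    if np.isnan(r) or r <= 0:
        return 0.0
    return r


def peptide_weights(
    peptide_matrix: np.ndarray, on_observed: bool = False
) -> np.ndarray:
    """Normalized fidelity weights for the peptides of one protein.

    The raw weight of peptide i is its mean abundance over all retained
    samples (zeros included) times the sum of its positive Pearson
    correlations with every peptide of the protein, the self term (r=1)
    included. Weights are normalized to sum to 1.

    Parameters
    ----------
    peptide_matrix:
        (I, S) array, one row per peptide, both groups pooled.
    on_observed:
        Restrict means and correlations to non-missing entries (pairwise
        complete for correlations); default uses all entries with zeros.

    Returns
    -------
    Weight vector of length I summing to 1, or raises if every raw weight is
    zero (protein excluded upstream).
    """
    X = np.asarray(peptide_matrix, dtype=float)
    n_pep = X.shape[0]
    if n_pep < 2:
        raise ValidationError("peptide_weights requires at least 2 peptides")
    if on_observed:
        masked = np.where(X == 0, np.nan, X)
        with np.errstate(invalid="ignore"):
            means = np.nanmean(masked, axis=1)
        means = np.nan_to_num(means)
    else:
        means = X.mean(axis=1)
    corr_sum = np.ones(n_pep)  # self term r_ii = 1
    for i in range(n_pep):
        for j in range(i + 1, n_pep):
            if on_observed:
                both = (X[i] != 0) & (X[j] != 0)
                r = positive_pearson(X[i][both], X[j][both]) if both.sum() >= 2 else 0.0
            else:
                r = positive_pearson(X[i], X[j])
            corr_sum[i] += r
            corr_sum[j] += r
    raw = means * corr_sum
    total = raw.sum()
    if total <= 0:
        raise PepdescError("all raw peptide weights are zero; protein excluded")
    return raw / total


# ---------------------------------------------------------------------------
# Protein-level aggregation
# ---------------------------------------------------------------------------


def protein_de_score(peptide_df: pd.DataFrame, params: DEParams) -> float:
    """Aggregate one protein's peptide scores into its DE-score.

    ``peptide_df`` must carry columns de_score, p_value, weight and
    median_ratio for the protein's retained peptides. Multi-peptide proteins
    sum weight-adjusted scores gated at p < alpha; single-peptide proteins
    use the unclipped log2 median ratio gated by their own p-value.
    """
    if len(peptide_df) == 1:
        row = peptide_df.iloc[0]
        if row["p_value"] >= params.alpha:
            return 0.0
        mr = row["median_ratio"]
        if mr == 0:
            score = -np.inf
        elif np.isinf(mr):
            score = np.inf
        else:
            score = float(np.log2(mr))
        if params.clip_single_peptide:
            score = float(np.clip(score, -params.clip, params.clip))
        return score
    gate = (peptide_df["p_value"] < params.alpha).to_numpy(dtype=float)
    adjusted = peptide_df["de_score"].to_numpy() * peptide_df["weight"].to_numpy()
    return float(np.sum(adjusted * gate))


def score_peptides(
    table: PeptideTable, design: SampleDesign, params: DEParams | None = None
) -> pd.DataFrame:
    """Per-peptide DE-scores, p-values and pair counts (no weights yet).

    Peptides whose every cross-group pair is dropped (all-missing) are
    excluded with a warning.
    """
    params = params or DEParams()
    g1 = table.abundances[design.group1_samples].to_numpy(dtype=float)
    g2 = table.abundances[design.group2_samples].to_numpy(dtype=float)
    rows = []
    dropped = []
    for k, pid in enumerate(table.peptide_ids):
        median, n_pairs = pairwise_ratio_median(g1[k], g2[k])
        if n_pairs == 0:
            dropped.append(pid)
            continue
        rows.append({
            "peptide_id": pid,
            "protein_accession": table.protein_accession.iloc[k],
            "median_ratio": median,
            "de_score": peptide_de_score(median, params.clip),
            "p_value": wilcoxon_two_sided(g1[k], g2[k]),
            "n_pairs_used": n_pairs,
        })
    if dropped:
        logger.warning("%d all-missing peptides excluded from scoring", len(dropped))
    return pd.DataFrame(rows, columns=[
        "peptide_id", "protein_accession", "median_ratio", "de_score",
        "p_value", "n_pairs_used"])


@dataclass
class PepdescResult:
    """Full pipeline output: score tables, audit report, effective design."""

    protein_scores: pd.DataFrame
    peptide_scores: pd.DataFrame
    report: FilterReport
    design: SampleDesign


def run_pepdesc(
    table: PeptideTable,
    design: SampleDesign,
    ann: ContaminantAnnotation | None = None,
    filter_params: FilterParams | None = None,
    norm_params: NormalizationParams | None = None,
    de_params: DEParams | None = None,
    outlier_k_mad: float = 3.0,
    outlier_max_missing: float = 0.95,
) -> PepdescResult:
    """Run the full pipeline: filtration, outlier removal, normalization,
    peptide scoring, protein aggregation.

    Deterministic given inputs and parameters. Proteins whose every peptide
    was filtered (or all-missing) are absent from the protein output; the
    report explains what was removed.
    """
    de_params = de_params or DEParams()
    table = align_table_to_design(table, design)
    table, report = apply_filters(table, ann, filter_params)
    if table.n_peptides == 0:
        logger.warning("no peptides survive filtration: %s", report.summary())
        return PepdescResult(
            protein_scores=pd.DataFrame(
                columns=["protein_accession", "de_score", "n_peptides_used"]),
            peptide_scores=pd.DataFrame(columns=[
                "peptide_id", "protein_accession", "de_score", "p_value",
                "weight", "adjusted_score"]),
            report=report, design=design)
    outliers = detect_outlier_samples(
        table, design, k_mad=outlier_k_mad, max_missing=outlier_max_missing)
    if outliers:
        design = design.drop_samples(outliers)
        table = table.subset_samples(design.sample_ids)
        report.outlier_samples.extend(outliers)
    if design.M < 2 or design.N < 2:
        raise PepdescError("fewer than 2 samples per group after outlier removal")
    table = normalize_samples(table, design, norm_params)

    pep = score_peptides(table, design, de_params)
    weights = pd.Series(np.nan, index=pep.index)
    protein_rows = []
    matrix = table.abundances
    for accession, grp in pep.groupby("protein_accession", sort=False):
        if len(grp) == 1:
            weights.loc[grp.index] = 1.0
        else:
            sub = matrix.loc[grp["peptide_id"]].to_numpy(dtype=float)
            try:
                w = peptide_weights(sub, on_observed=de_params.weight_stats_on_observed)
            except PepdescError:
                logger.warning("protein %s excluded: zero total weight", accession)
                continue
            weights.loc[grp.index] = w
        local = grp.assign(weight=weights.loc[grp.index].to_numpy())
        protein_rows.append({
            "protein_accession": accession,
            "de_score": protein_de_score(local, de_params),
            "n_peptides_used": len(grp),
        })
    pep = pep.assign(weight=weights)
    pep = pep[pep["weight"].notna()]
    gate = (pep["p_value"] < de_params.alpha).astype(float)
    pep = pep.assign(adjusted_score=pep["de_score"] * pep["weight"],
                     significant=gate.astype(bool))
    protein_scores = pd.DataFrame(
        protein_rows, columns=["protein_accession", "de_score", "n_peptides_used"])
    peptide_scores = pep[[
        "peptide_id", "protein_accession", "de_score", "p_value", "weight",
        "adjusted_score", "significant", "median_ratio", "n_pairs_used"]]
    return PepdescResult(protein_scores=protein_scores,
                         peptide_scores=peptide_scores.reset_index(drop=True),
                         report=report, design=design)
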