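"""Data filtration, outlier-sample removal, and normalization.

The filtration pipeline runs in a fixed order — contaminant accessions,
missingness, contaminant peak features — and each peptide is attributed to
the first rule that removes it. Filtration precedes outlier-sample removal,
which precedes normalization. No imputation is ever performed: missing
values stay 0 and are excluded from every location statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import (
    ContaminantAnnotation,
    PeptideTable,
    PepdescError,
    SampleDesign,
    ValidationError,
    logger,
)

__all__ = [
    "FilterParams",
    "FilterReport",
    "NormalizationParams",
    "filter_contaminant_accessions",
    "filter_by_missingness",
    "filter_contaminant_features",
    "apply_filters",
    "detect_outlier_samples",
    "normalize_samples",
]


@dataclass
class FilterParams:
    """Thresholds for the three filtration rules.

    missing_fraction_threshold:
        Peptides missing in strictly more than this fraction of samples are
        removed (default 0.6, i.e. "over 60%").
    rt_tolerance, mz_tolerance:
        A peptide is a feature-matched contaminant when |ΔRT| < rt_tolerance
        AND |Δm/z| < mz_tolerance against any annotated contaminant peak
        (strict inequalities; defaults 0.05 min and 2 Th).
    apply_feature_filter:
        Automatically skipped with a warning when the table lacks RT or m/z.
    """

    missing_fraction_threshold: float = 0.6
    rt_tolerance: float = 0.05
    mz_tolerance: float = 2.0
    apply_feature_filter: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.missing_fraction_threshold <= 1):
            raise ValidationError("missing_fraction_threshold must be in (0, 1]")
        if self.rt_tolerance <= 0 or self.mz_tolerance <= 0:
            raise ValidationError("RT and m/z tolerances must be strictly positive")


@dataclass
class FilterReport:
    """Audit trail of what filtration and outlier removal discarded."""

    removed_by_accession: list[str] = field(default_factory=list)
    removed_by_missingness: list[str] = field(default_factory=list)
    removed_by_feature_match: list[str] = field(default_factory=list)
    outlier_samples: list[str] = field(default_factory=list)

    @property
    def n_removed_by_accession(self) -> int:
        return len(self.removed_by_accession)

    @property
    def n_removed_by_missingness(self) -> int:
        return len(self.removed_by_missingness)

    @property
    def n_removed_by_feature_match(self) -> int:
        return len(self.removed_by_feature_match)

    @property
    def n_removed(self) -> int:
        return (self.n_removed_by_accession + self.n_removed_by_missingness
                + self.n_removed_by_feature_match)

    def merge(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            removed_by_accession=self.removed_by_accession + other.removed_by_accession,
            removed_by_missingness=(self.removed_by_missingness
                                    + other.removed_by_missingness),
            removed_by_feature_match=(self.removed_by_feature_match
                                      + other.removed_by_feature_match),
            outlier_samples=self.outlier_samples + other.outlier_samples,
        )

    def summary(self) -> str:
        return (
            f"removed {self.n_removed_by_accession} contaminant-accession, "
            f"{self.n_removed_by_missingness} high-missingness, "
            f"{self.n_removed_by_feature_match} feature-matched peptides; "
            f"{len(self.outlier_samples)} outlier samples"
        )


@dataclass
class NormalizationParams:
    """Normalization policy.

    method:
        ``auto`` (default) uses the per-sample median unless any retained
        sample exceeds ``mean_switch_threshold`` missingness, in which case
        the per-sample mean is used instead; ``median``/``mean`` force one;
        ``none`` disables normalization.
    per_group:
        When True (default), the rescaling target is the median of per-sample
        location statistics within each sample's own group rather than
        globally. Per-group targets cancel the composition bias that a global
        target introduces when many proteins genuinely change in one group
        (each sample is compared to its own group's typical scale), while
        still removing per-sample technical scale differences.
    """

    method: str = "auto"
    mean_switch_threshold: float = 0.5
    per_group: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("auto", "median", "mean", "none"):
            raise ValidationError(f"unknown normalization method {self.method!r}")
        if not (0 < self.mean_switch_threshold <= 1):
            raise ValidationError("mean_switch_threshold must be in (0, 1]")


# ---------------------------------------------------------------------------
# Filtration rules
# ---------------------------------------------------------------------------


def filter_contaminant_accessions(
    table: PeptideTable, ann: ContaminantAnnotation
) -> tuple[PeptideTable, FilterReport]:
    """Drop peptides whose protein accession starts with a contaminant prefix."""
    prefixes = tuple(ann.accession_prefixes)
    if not prefixes:
        return table, FilterReport()
    acc = table.protein_accession.astype(str)
    removed = acc.index[acc.str.startswith(prefixes)]
    kept = acc.index.difference(removed, sort=False)
    report = FilterReport(removed_by_accession=list(removed))
    if len(kept) == 0:
        logger.warning("contaminant-accession filter removed every peptide")
    return table.subset_peptides(kept), report


def filter_by_missingness(
    table: PeptideTable, threshold: float = 0.6
) -> tuple[PeptideTable, FilterReport]:
    """Drop peptides missing in strictly more than ``threshold`` of samples."""
    if not (0 < threshold <= 1):
        raise ValidationError("missingness threshold must be in (0, 1]")
    frac = table.missing_mask.mean(axis=1)
    removed = frac.index[frac > threshold]
    kept = frac.index.difference(removed, sort=False)
    return table.subset_peptides(kept), FilterReport(
        removed_by_missingness=list(removed))


def filter_contaminant_features(
    table: PeptideTable,
    ann: ContaminantAnnotation,
    params: FilterParams | None = None,
) -> tuple[PeptideTable, FilterReport]:
    """Drop peptides whose (RT, m/z) matches a known contaminant peak.

    A match requires |ΔRT| < rt_tolerance and |Δm/z| < mz_tolerance against
    at least one annotated feature; both comparisons are strict. A no-op when
    the table carries no RT/m-z metadata or the annotation has no features.
    """
    params = params or FilterParams()
    if ann.feature_table is None or len(ann.feature_table) == 0:
        return table, FilterReport()
    if not table.has_features():
        logger.warning(
            "peptide table has no retention-time/m-z columns; "
            "contaminant feature filter skipped")
        return table, FilterReport()
    rt = table.retention_time.to_numpy(dtype=float)[:, None]
    mz = table.mz.to_numpy(dtype=float)[:, None]
    feat = ann.feature_table
    hit = (
        (np.abs(rt - feat[None, :, 0]) < params.rt_tolerance)
        & (np.abs(mz - feat[None, :, 1]) < params.mz_tolerance)
    ).any(axis=1)
    # peptides without features never match
    hit &= ~(np.isnan(rt[:, 0]) | np.isnan(mz[:, 0]))
    removed = table.peptide_ids[hit]
    kept = table.peptide_ids.difference(removed, sort=False)
    return table.subset_peptides(kept), FilterReport(
        removed_by_feature_match=list(removed))


def apply_filters(
    table: PeptideTable,
    ann: ContaminantAnnotation | None = None,
    params: FilterParams | None = None,
) -> tuple[PeptideTable, FilterReport]:
    """Run the three filtration rules in their fixed order."""
    params = params or FilterParams()
    ann = ann or ContaminantAnnotation()
    table, rep1 = filter_contaminant_accessions(table, ann)
    table, rep2 = filter_by_missingness(table, params.missing_fraction_threshold)
    if params.apply_feature_filter:
        table, rep3 = filter_contaminant_features(table, ann, params)
    else:
        rep3 = FilterReport()
    return table, rep1.merge(rep2).merge(rep3)


# ---------------------------------------------------------------------------
# Outlier samples and normalization
# ---------------------------------------------------------------------------


def detect_outlier_samples(
    table: PeptideTable,
    design: SampleDesign,
    k_mad: float = 3.0,
    max_missing: float = 0.95,
    min_log_deviation: float = 0.3,
) -> list[str]:
    """Flag outlier samples before normalization.

    A sample is flagged when (a) its missing fraction exceeds ``max_missing``,
    or (b) the natural log of its total non-missing intensity deviates from
    the within-group median by more than ``k_mad`` normal-scaled MADs.
    Rule (b) additionally requires the deviation to exceed
    ``min_log_deviation`` (in ln units, default 0.3 ≈ a 35% intensity
    difference) so that a near-zero MAD on homogeneous samples cannot flag
    trivial fluctuations. Requires at least 3 samples per group for the MAD
    to be meaningful; otherwise returns an empty list with a warning.
    """
    if min(design.M, design.N) < 3:
        logger.warning("fewer than 3 samples per group; outlier detection skipped")
        return []
    flagged: list[str] = []
    missing_frac = table.missing_mask.mean(axis=0)
    totals = table.abundances.sum(axis=0)
    log_tot = np.log(totals.where(totals > 0, np.nan))
    for group_samples in (design.group1_samples, design.group2_samples):
        vals = log_tot[group_samples]
        med = vals.median()
        mad = 1.4826 * (vals - med).abs().median()
        for s in group_samples:
            if missing_frac[s] > max_missing:
                flagged.append(s)
            elif np.isnan(vals[s]) or (
                abs(vals[s] - med) > max(k_mad * mad, min_log_deviation)
            ):
                flagged.append(s)
    remaining = design.drop_samples(flagged) if flagged else design
    if flagged and (remaining.M < 2 or remaining.N < 2):
        raise PepdescError(
            f"outlier removal of {flagged} would leave a group with fewer than "
            "2 samples; review the data manually")
    if flagged:
        logger.warning("flagged outlier samples: %s", flagged)
    return flagged


def normalize_samples(
    table: PeptideTable,
    design: SampleDesign,
    params: NormalizationParams | None = None,
) -> PeptideTable:
    """Rescale each sample to a common location without touching missing cells.

    Each sample's non-missing abundances are divided by that sample's location
    statistic (median by default, mean when auto-switched) and multiplied by
    the median of the per-sample statistics, preserving the overall scale and
    all between-group ratios. With an even number of samples the median is the
    midpoint of the two central values.
    """
    params = params or NormalizationParams()
    if params.method == "none":
        return table
    ab = table.abundances
    observed = ab.where(~table.missing_mask)
    n_obs = observed.notna().sum(axis=0)
    if (n_obs == 0).any():
        empty = list(n_obs.index[n_obs == 0])
        raise PepdescError(
            f"samples with no observed abundances: {empty}; remove as outliers")
    method = params.method
    if method == "auto":
        worst = table.missing_mask.mean(axis=0).max()
        method = "mean" if worst > params.mean_switch_threshold else "median"
        logger.info("auto normalization selected %s (max sample missingness %.2f)",
                    method, worst)
    loc = observed.median(axis=0) if method == "median" else observed.mean(axis=0)
    if params.per_group:
        target = loc.copy()
        for group_samples in (design.group1_samples, design.group2_samples):
            target[group_samples] = loc[group_samples].median()
    else:
        target = pd.Series(loc.median(), index=loc.index)
    scaled = ab.mul(target / loc, axis=1)
    scaled = scaled.where(~table.missing_mask, other=0.0)
    return table.with_abundances(scaled)
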