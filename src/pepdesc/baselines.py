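"""Protein-level baseline methods: summation roll-up + t test / Wilcoxon.

These deliberately reproduce the conventional protein-level analysis arm,
including its weaknesses: peptide abundances are summed into a protein
abundance with missing values contributing 0, then tested per protein. No
peptide filtration is applied — that failure mode (zeros of a mostly-missing
peptide propagating into the sum) is exactly what the peptide-level method
avoids, and the baselines must exhibit it faithfully.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .descore import wilcoxon_two_sided
from .tables_io import PeptideTable, SampleDesign, ValidationError

__all__ = [
    "ProteinAbundanceTable",
    "rollup_proteins",
    "normalize_rollup",
    "student_t",
    "protein_wilcoxon",
    "run_baseline",
]


@dataclass
class ProteinAbundanceTable:
    """Protein × sample abundance matrix from peptide summation."""

    abundances: pd.DataFrame  # index = accession, columns = samples

    @property
    def accessions(self) -> pd.Index:
        return self.abundances.index


def rollup_proteins(table: PeptideTable) -> ProteinAbundanceTable:
    """Sum member-peptide abundances per protein (zero-filled missing)."""
    summed = table.abundances.groupby(table.protein_accession, sort=False).sum()
    summed.index.name = "protein_accession"
    return ProteinAbundanceTable(abundances=summed)


def normalize_rollup(
    pat: ProteinAbundanceTable,
    design: SampleDesign,
    per_group_target: bool = True,
) -> ProteinAbundanceTable:
    """Median-normalize each sample's protein abundances per sample group.

    Each sample is divided by its median over non-zero protein abundances and
    rescaled to the median of those per-sample medians within its own group
    (globally when ``per_group_target=False``). Zeros stay zero.
    """
    ab = pat.abundances
    observed = ab.where(ab > 0)
    loc = observed.median(axis=0)
    if (loc.isna() | (loc == 0)).any():
        bad = list(loc.index[loc.isna() | (loc == 0)])
        raise ValidationError(f"samples with no non-zero protein abundance: {bad}")
    if per_group_target:
        target = loc.copy()
        for group_samples in (design.group1_samples, design.group2_samples):
            target[group_samples] = loc[group_samples].median()
    else:
        target = pd.Series(loc.median(), index=loc.index)
    return ProteinAbundanceTable(abundances=ab.mul(target / loc, axis=1))


def student_t(x1, x2) -> tuple[float, float]:
    """Ordinary pooled-variance Student's t test (two-sided).

    With equal group sizes the pooled standard deviation is
    sp = sqrt((s1^2 + s2^2)/2); unequal sizes use the standard
    (n-weighted) pooled variance. Zero pooled variance gives t = 0, p = 1
    for equal means and p -> 0 otherwise.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValidationError("t test needs at least 2 samples per group")
    m1, m2 = x1.mean(), x2.mean()
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    if n1 == n2:
        sp = np.sqrt((v1 + v2) / 2.0)
    else:
        sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    df = n1 + n2 - 2
    if sp == 0:
        if m1 == m2:
            return 0.0, 1.0
        return float(np.sign(m1 - m2) * np.inf), 0.0
    t = (m1 - m2) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def protein_wilcoxon(x1, x2) -> float:
    """Two-sided Mann–Whitney p-value on protein abundances (shared engine)."""
    return wilcoxon_two_sided(x1, x2)


def run_baseline(
    table: PeptideTable,
    design: SampleDesign,
    method: str = "ttest",
    per_group_target: bool = True,
) -> pd.DataFrame:
    """Roll up, normalize, and test every protein.

    Returns a DataFrame with columns accession, statistic, p. The statistic
    is t for ``ttest`` and U = min(U1, U2) is not reported for ``wilcoxon``
    (NaN) since only the p-value ranks proteins.
    """
    if method not in ("ttest", "wilcoxon"):
        raise ValidationError(f"unknown baseline method {method!r}")
    pat = normalize_rollup(rollup_proteins(table.subset_samples(design.sample_ids)),
                           design, per_group_target=per_group_target)
    g1 = pat.abundances[design.group1_samples].to_numpy(dtype=float)
    g2 = pat.abundances[design.group2_samples].to_numpy(dtype=float)
    rows = []
    for k, accession in enumerate(pat.accessions):
        if method == "ttest":
            t, p = student_t(g1[k], g2[k])
        else:
            t, p = float("nan"), protein_wilcoxon(g1[k], g2[k])
        rows.append({"protein_accession": accession, "statistic": t, "p_value": p})
    return pd.DataFrame(rows, columns=["protein_accession", "statistic", "p_value"])
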