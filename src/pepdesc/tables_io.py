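"""Reading and writing peptide tables, sample designs, and score tables.

All formats are plain-text TSV/CSV with one header row. Missing abundances
are stored as 0 and tracked through a boolean mask; a measured intensity of
exactly 0 never occurs in label-free MS data, so input zeros are treated as
missing by convention.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("pepdesc")

__all__ = [
    "PepdescError",
    "TableFormatError",
    "ValidationError",
    "PeptideTable",
    "SampleDesign",
    "ContaminantAnnotation",
    "COLUMN_DIALECTS",
    "read_peptide_table",
    "read_design",
    "read_contaminant_features",
    "write_contaminant_features",
    "write_results",
    "read_score_table",
    "write_peptide_table",
    "write_design",
]


class PepdescError(Exception):
    """Base class for all package errors."""


class TableFormatError(PepdescError):
    """A file does not have the expected layout (missing column, bad header)."""


class ValidationError(PepdescError):
    """A file parses but violates a content contract (duplicates, bad values)."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class PeptideTable:
    """Wide peptide quantification matrix with per-peptide metadata.

    Attributes
    ----------
    abundances:
        DataFrame of non-negative intensities, index = unique peptide ids,
        columns = sample ids. Missing values are stored as 0.
    protein_accession:
        Series mapping peptide id -> master protein accession (one per row).
    sequence, retention_time, mz:
        Optional per-peptide metadata Series aligned with ``abundances``.
        Retention time is in the units of the input table (minutes by
        convention); m/z in Thomson.
    """

    abundances: pd.DataFrame
    protein_accession: pd.Series
    sequence: pd.Series | None = None
    retention_time: pd.Series | None = None
    mz: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean matrix, True where an abundance is missing (stored as 0)."""
        return self.abundances == 0

    @property
    def peptide_ids(self) -> pd.Index:
        return self.abundances.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.columns)

    @property
    def n_peptides(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[1]

    def has_features(self) -> bool:
        """Whether both retention time and m/z metadata are present."""
        return self.retention_time is not None and self.mz is not None

    def validate(self) -> None:
        idx = self.abundances.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate peptide_id values: {dupes[:5]}")
        if (self.abundances.to_numpy() < 0).any():
            raise ValidationError("negative abundance values are not allowed")
        if not self.protein_accession.index.equals(idx):
            raise ValidationError("protein_accession index does not match abundances")
        for name in ("sequence", "retention_time", "mz"):
            s = getattr(self, name)
            if s is not None and not s.index.equals(idx):
                raise ValidationError(f"{name} index does not match abundances")

    def subset_peptides(self, keep: pd.Index | list[str]) -> "PeptideTable":
        """Row subset preserving order of ``keep``."""
        keep = pd.Index(keep)
        return PeptideTable(
            abundances=self.abundances.loc[keep],
            protein_accession=self.protein_accession.loc[keep],
            sequence=None if self.sequence is None else self.sequence.loc[keep],
            retention_time=(
                None if self.retention_time is None else self.retention_time.loc[keep]
            ),
            mz=None if self.mz is None else self.mz.loc[keep],
        )

    def subset_samples(self, keep: list[str]) -> "PeptideTable":
        return dataclasses.replace(self, abundances=self.abundances[list(keep)])

    def with_abundances(self, abundances: pd.DataFrame) -> "PeptideTable":
        return dataclasses.replace(self, abundances=abundances)


@dataclass
class SampleDesign:
    """Two-group assignment of the sample columns.

    Group order follows first appearance in the design file: the first group
    (size M) is the numerator group of the pairwise abundance ratios.
    """

    sample_ids: list[str]
    group_labels: pd.Series  # index = sample_ids, values = group names
    group_names: tuple[str, str]

    def __post_init__(self) -> None:
        labels = set(self.group_labels.unique())
        if labels != set(self.group_names) or len(self.group_names) != 2:
            raise ValidationError(
                f"design must have exactly two groups, got {sorted(labels)}"
            )
        if list(self.group_labels.index) != list(self.sample_ids):
            raise ValidationError("group_labels index must equal sample_ids")

    @property
    def group1_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.group_labels[s] == self.group_names[0]]

    @property
    def group2_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.group_labels[s] == self.group_names[1]]

    @property
    def M(self) -> int:
        return len(self.group1_samples)

    @property
    def N(self) -> int:
        return len(self.group2_samples)

    def drop_samples(self, dropped: list[str]) -> "SampleDesign":
        keep = [s for s in self.sample_ids if s not in set(dropped)]
        return SampleDesign(
            sample_ids=keep,
            group_labels=self.group_labels.loc[keep],
            group_names=self.group_names,
        )


@dataclass
class ContaminantAnnotation:
    """Contamination annotation: accession prefixes plus known peak features.

    ``feature_table`` holds (retention_time, mz) pairs of contaminant peptide
    peaks; peptides whose own features fall within the matching tolerances of
    any entry are treated as misassigned contamination signals.
    """

    accession_prefixes: tuple[str, ...] = ("CON", "REV")
    feature_table: np.ndarray | None = None  # shape (k, 2): rt, mz

    def __post_init__(self) -> None:
        if any((not isinstance(p, str)) or p == "" for p in self.accession_prefixes):
            raise ValidationError("accession prefixes must be non-empty strings")
        if self.feature_table is not None:
            ft = np.asarray(self.feature_table, dtype=float)
            if ft.size == 0:
                ft = ft.reshape(0, 2)
            if ft.ndim != 2 or ft.shape[1] != 2:
                raise ValidationError("feature_table must be (k, 2): rt, mz")
            if (ft <= 0).any():
                raise ValidationError("feature RT and m/z must be positive")
            self.feature_table = ft


# ---------------------------------------------------------------------------
# Column dialects
# ---------------------------------------------------------------------------

#: Built-in header dialects. A column_map binds semantic roles to headers;
#: ``abundance_columns`` lists them explicitly, or ``abundance_prefix``
#: selects every column starting with the prefix (MaxQuant style), or neither
#: is given and every unmapped column is an abundance column.
COLUMN_DIALECTS: dict[str, dict] = {
    "generic": {
        "peptide_id": "peptide_id",
        "protein_accession": "protein",
        "sequence": "sequence",
        "retention_time": "retention_time",
        "mz": "mz",
    },
    "maxquant": {
        "peptide_id": "Sequence",
        "protein_accession": "Leading razor protein",
        "retention_time": "Retention time",
        "mz": "m/z",
        "abundance_prefix": "Intensity ",
    },
}

_ROLES = ("peptide_id", "protein_accession", "sequence", "retention_time", "mz")

DEFAULT_MISSING_CODES = frozenset({"", "NA", "NaN", "NAN", "nan", "N/A", "#N/A", "null"})


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_peptide_table(
    path: str | Path,
    column_map: Mapping[str, object] | str | None = None,
    missing_codes: frozenset[str] = DEFAULT_MISSING_CODES,
) -> PeptideTable:
    """Read a wide peptide quantification table.

    Parameters
    ----------
    path:
        TSV or CSV file (separator inferred from the extension), UTF-8,
        decimal point.
    column_map:
        Dialect name (``"generic"``, ``"maxquant"``) or an explicit mapping of
        semantic roles to column headers. Must name at least a ``peptide_id``
        and a ``protein_accession`` column; abundance columns are selected by
        ``abundance_columns`` (list), ``abundance_prefix`` (str) or default to
        every unmapped column.
    missing_codes:
        String tokens marking a missing cell, in addition to blank cells and
        the value 0.

    Returns
    -------
    PeptideTable with missing cells stored as 0 and flagged in
    ``missing_mask``. Column order is preserved from the file.
    """
    path = Path(path)
    if column_map is None:
        column_map = COLUMN_DIALECTS["generic"]
    elif isinstance(column_map, str):
        try:
            column_map = COLUMN_DIALECTS[column_map]
        except KeyError:
            raise TableFormatError(f"unknown column dialect {column_map!r}") from None
    df = pd.read_csv(
        path, sep=_sep_for(path), dtype=str, keep_default_na=False, encoding="utf-8"
    )

    def col(role: str, required: bool) -> str | None:
        name = column_map.get(role)
        if name is None:
            if required:
                raise TableFormatError(f"column_map does not define {role!r}")
            return None
        if name not in df.columns:
            if required:
                raise TableFormatError(f"required column {name!r} ({role}) not found")
            return None
        return str(name)

    id_col = col("peptide_id", required=True)
    acc_col = col("protein_accession", required=True)
    seq_col = col("sequence", required=False)
    rt_col = col("retention_time", required=False)
    mz_col = col("mz", required=False)
    meta_cols = {c for c in (id_col, acc_col, seq_col, rt_col, mz_col) if c}

    if "abundance_columns" in column_map:
        ab_cols = [str(c) for c in column_map["abundance_columns"]]  # type: ignore[index]
        for c in ab_cols:
            if c not in df.columns:
                raise TableFormatError(f"abundance column {c!r} not found")
    elif "abundance_prefix" in column_map:
        prefix = str(column_map["abundance_prefix"])
        ab_cols = [c for c in df.columns if c.startswith(prefix)]
    else:
        ab_cols = [c for c in df.columns if c not in meta_cols]
    if len(ab_cols) < 2:
        raise TableFormatError("need at least 2 abundance columns")

    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate peptide_id values: {dupes[:5]}")

    raw = df[ab_cols].copy()
    for c in ab_cols:
        stripped = raw[c].str.strip()
        raw[c] = stripped.where(~stripped.isin(missing_codes), other="0")
    try:
        values = raw.astype(float)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric abundance value: {exc}") from exc
    if (values.to_numpy() < 0).any():
        raise ValidationError("negative abundance values are not allowed")
    values = values.fillna(0.0)
    values.index = pd.Index(ids, name="peptide_id")
    # MaxQuant-style prefixed headers are stripped back to bare sample names
    if "abundance_prefix" in column_map:
        prefix = str(column_map["abundance_prefix"])
        values.columns = [c[len(prefix):] for c in ab_cols]

    def meta(colname: str | None, numeric: bool) -> pd.Series | None:
        if colname is None:
            return None
        s = df[colname].astype(str).str.strip()
        s = s.where(~s.isin(missing_codes), other="nan" if numeric else "")
        out = pd.to_numeric(s, errors="raise") if numeric else s
        out.index = values.index
        return out.rename(colname)

    return PeptideTable(
        abundances=values,
        protein_accession=meta(acc_col, numeric=False),  # type: ignore[arg-type]
        sequence=meta(seq_col, numeric=False),
        retention_time=meta(rt_col, numeric=True),
        mz=meta(mz_col, numeric=True),
    )


def read_design(path: str | Path) -> SampleDesign:
    """Read a two-column ``sample_id<TAB>group`` design table.

    A header row ``sample_id, group`` is accepted and skipped. Exactly two
    distinct groups are required; group order follows first appearance.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str,
                     keep_default_na=False, encoding="utf-8")
    if df.shape[1] != 2:
        raise TableFormatError(f"design must have 2 columns, got {df.shape[1]}")
    first = [c.strip().lower() for c in df.iloc[0]]
    if first == ["sample_id", "group"]:
        df = df.iloc[1:]
    samples = df.iloc[:, 0].str.strip().tolist()
    groups = df.iloc[:, 1].str.strip().tolist()
    if len(set(samples)) != len(samples):
        raise ValidationError("duplicate sample ids in design")
    distinct: list[str] = []
    for g in groups:
        if g not in distinct:
            distinct.append(g)
    if len(distinct) != 2:
        raise ValidationError(f"design must define exactly two groups, got {distinct}")
    labels = pd.Series(groups, index=pd.Index(samples, name="sample_id"), name="group")
    return SampleDesign(sample_ids=samples, group_labels=labels,
                        group_names=(distinct[0], distinct[1]))


def align_table_to_design(table: PeptideTable, design: SampleDesign) -> PeptideTable:
    """Reorder table columns to the design's sample order; error on absences."""
    missing = [s for s in design.sample_ids if s not in table.abundances.columns]
    if missing:
        raise ValidationError(f"samples in design absent from table: {missing[:5]}")
    return table.subset_samples(design.sample_ids)


def read_contaminant_features(path: str | Path) -> np.ndarray:
    """Read a 2-column ``retention_time<TAB>mz`` contaminant feature table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str,
                     keep_default_na=False, encoding="utf-8")
    if df.shape[1] != 2:
        raise TableFormatError("contaminant feature table must have 2 columns")
    first = [c.strip().lower() for c in df.iloc[0]]
    if first == ["retention_time", "mz"]:
        df = df.iloc[1:]
    if len(df) == 0:
        return np.empty((0, 2), dtype=float)
    try:
        return df.astype(float).to_numpy()
    except ValueError as exc:
        raise TableFormatError(f"non-numeric contaminant feature: {exc}") from exc


def write_contaminant_features(features: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame(np.asarray(features, float).reshape(-1, 2),
                      columns=["retention_time", "mz"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

PROTEIN_SCORE_COLUMNS = ["protein_accession", "de_score", "n_peptides_used"]
PEPTIDE_SCORE_COLUMNS = [
    "peptide_id", "protein_accession", "de_score", "p_value", "weight",
    "adjusted_score",
]


def write_results(
    protein_scores: pd.DataFrame,
    peptide_scores: pd.DataFrame,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write protein- and peptide-level score TSVs.

    Row order is preserved; floats are written with ``repr`` precision so a
    read/write round trip is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ppath = out_dir / "protein_scores.tsv"
    qpath = out_dir / "peptide_scores.tsv"
    protein_scores.reindex(columns=PROTEIN_SCORE_COLUMNS).to_csv(
        ppath, sep="\t", index=False)
    peptide_scores.reindex(columns=PEPTIDE_SCORE_COLUMNS).to_csv(
        qpath, sep="\t", index=False)
    return ppath, qpath


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read back a score TSV written by :func:`write_results` (or a baseline)."""
    return pd.read_csv(path, sep=_sep_for(Path(path)), encoding="utf-8",
                       float_precision="round_trip")


def write_peptide_table(table: PeptideTable, path: str | Path) -> None:
    """Write a PeptideTable in the generic wide dialect (missing as blank)."""
    df = pd.DataFrame({"peptide_id": table.peptide_ids,
                       "protein": table.protein_accession.to_numpy()})
    if table.sequence is not None:
        df["sequence"] = table.sequence.to_numpy()
    if table.retention_time is not None:
        df["retention_time"] = table.retention_time.to_numpy()
    if table.mz is not None:
        df["mz"] = table.mz.to_numpy()
    ab = table.abundances.copy()
    mask = table.missing_mask
    for c in ab.columns:
        col = ab[c].map(lambda v: repr(float(v)))
        df[c] = col.where(~mask[c].to_numpy(), other="").to_numpy()
    df.to_csv(path, sep="\t", index=False)


def write_design(design: SampleDesign, path: str | Path) -> None:
    pd.DataFrame({"sample_id": design.sample_ids,
                  "group": design.group_labels.to_numpy()}).to_csv(
        path, sep="\t", index=False)
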