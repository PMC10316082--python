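"""Synthetic peptide-level benchmarks with known ground truth.

Two generators are provided:

* a mixed single-cell benchmark — two groups of single cells, a core of
  stable proteins plus a set of differential proteins whose abundances are
  numerically scaled by a known fold change in group 1, hierarchical
  protein -> peptide structure, abundance-dependent (MNAR) dropout, and
  injected contamination;
* a two-proteome spike-in benchmark — technical replicates of two mixtures
  of a background proteome and a spiked proteome, where every true fold
  change follows from the mixing fractions in closed form.

The generative model per cell and peptide is multiplicative on the intensity
scale: protein base abundance (log-normal across proteins), cell-to-cell
biological variation (log-normal), a fixed per-peptide ionization efficiency
(log-normal, constant across cells — it cancels in cross-group ratios but
drives expression-level weights), and log-normal measurement noise. Dropout
is logistic in log intensity, so low-abundance peptides go missing first.

All draws flow from one seeded generator in a documented order (base
abundances, peptide counts, ionization factors, RT, m/z, cell effects,
measurement noise, dropout); contamination injection uses ``seed + 1``.
Identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import (
    LABEL_CHANGING,
    LABEL_STABLE,
    GroundTruth,
    write_ground_truth,
)
from .tables_io import (
    ContaminantAnnotation,
    PeptideTable,
    SampleDesign,
    ValidationError,
    write_contaminant_features,
    write_design,
    write_peptide_table,
)

__all__ = [
    "SimConfig",
    "SimOutput",
    "simulate_mixed_benchmark",
    "simulate_spike_in",
    "inject_contaminants",
    "write_sim_output",
    "PRESETS",
]


@dataclass
class SimConfig:
    """Benchmark generator configuration.

    The defaults reproduce the mixed single-cell design: 1000 stable + 200
    differential proteins whose abundances are halved in one group of 10
    cells, with heavy abundance-dependent missingness.

    Intensity units are arbitrary MS1-style ion counts (~1e6 scale);
    ``*_sdlog`` parameters are standard deviations on the natural-log scale.
    ``dropout_midpoint`` is the natural-log intensity at which the dropout
    probability is 0.5 and ``dropout_steepness`` its logistic slope.
    """

    n_stable_proteins: int = 1000
    n_de_proteins: int = 200
    fold_change: float = 0.5
    samples_per_group: int = 10
    peptides_per_protein_mean: float = 5.0  # geometric, minimum 1
    base_intensity_log_mean: float = 14.0
    base_intensity_sdlog: float = 1.5
    protein_abundance_sdlog: float = 0.5  # biological cell-to-cell spread
    peptide_ionization_sdlog: float = 1.0
    measurement_cv: float = 0.3  # sdlog of multiplicative noise
    dropout: bool = True
    dropout_midpoint: float = 13.5
    dropout_steepness: float = 2.0
    mcar_dropout: bool = False  # ablation: abundance-independent dropout
    mcar_rate: float = 0.4
    n_contaminant_peptides: int = 30
    n_masquerading_peptides: int = 20
    rt_range: tuple[float, float] = (0.0, 70.0)
    mz_range: tuple[float, float] = (350.0, 1600.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stable_proteins < 0 or self.n_de_proteins < 0:
            raise ValidationError("protein counts must be non-negative")
        if self.n_stable_proteins + self.n_de_proteins == 0:
            raise ValidationError("config yields an empty table")
        if self.fold_change <= 0:
            raise ValidationError("fold_change must be > 0")
        if self.samples_per_group < 2:
            raise ValidationError("need at least 2 samples per group")
        if self.peptides_per_protein_mean < 1:
            raise ValidationError("peptides_per_protein_mean must be >= 1")
        if not (0 <= self.mcar_rate <= 1):
            raise ValidationError("mcar_rate must be in [0, 1]")


@dataclass
class SimOutput:
    """Generated benchmark: table, design, truth, contamination bookkeeping."""

    table: PeptideTable
    design: SampleDesign
    truth: GroundTruth
    contaminant_annotation: ContaminantAnnotation
    contaminant_peptide_ids: list[str] = dataclasses.field(default_factory=list)
    masquerading_peptide_ids: list[str] = dataclasses.field(default_factory=list)


def _design(cfg: SimConfig) -> SampleDesign:
    s = cfg.samples_per_group
    ids = [f"g1_s{i + 1:02d}" for i in range(s)] + [f"g2_s{i + 1:02d}" for i in range(s)]
    labels = pd.Series(["group1"] * s + ["group2"] * s,
                       index=pd.Index(ids, name="sample_id"), name="group")
    return SampleDesign(sample_ids=ids, group_labels=labels,
                        group_names=("group1", "group2"))


def _dropout_mask(cfg: SimConfig, intensities: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """True where a measurement drops out. Draws one uniform per cell either way
    so toggling dropout does not shift downstream draws."""
    u = rng.random(intensities.shape)
    if not cfg.dropout:
        return np.zeros_like(u, dtype=bool)
    if cfg.mcar_dropout:
        return u < cfg.mcar_rate
    with np.errstate(over="ignore", divide="ignore"):
        logx = np.where(intensities > 0, np.log(intensities), -np.inf)
        p_miss = 1.0 / (1.0 + np.exp(cfg.dropout_steepness
                                     * (logx - cfg.dropout_midpoint)))
    return u < p_miss


def _assemble(cfg: SimConfig, accessions: np.ndarray, labels: np.ndarray,
              true_fc: np.ndarray, protein_cell: np.ndarray,
              rng: np.random.Generator, design: SampleDesign) -> SimOutput:
    """Shared peptide layer: counts, ionization, features, noise, dropout."""
    n_prot = len(accessions)
    p_geom = 1.0 / cfg.peptides_per_protein_mean
    counts = rng.geometric(p_geom, size=n_prot)
    n_pep = int(counts.sum())
    ionization = rng.lognormal(0.0, cfg.peptide_ionization_sdlog, size=n_pep)
    rt = rng.uniform(*cfg.rt_range, size=n_pep)
    mz = rng.uniform(*cfg.mz_range, size=n_pep)
    pep_protein = np.repeat(np.arange(n_prot), counts)
    noise = rng.lognormal(0.0, cfg.measurement_cv,
                          size=(n_pep, 2 * cfg.samples_per_group))
    X = protein_cell[pep_protein] * ionization[:, None] * noise
    miss = _dropout_mask(cfg, X, rng)
    X = np.where(miss, 0.0, X)

    pep_ids = [f"{accessions[p]}_pep{j + 1}" for p in range(n_prot)
               for j in range(counts[p])]
    idx = pd.Index(pep_ids, name="peptide_id")
    table = PeptideTable(
        abundances=pd.DataFrame(X, index=idx, columns=design.sample_ids),
        protein_accession=pd.Series(accessions[pep_protein], index=idx,
                                    name="protein"),
        retention_time=pd.Series(rt, index=idx, name="retention_time"),
        mz=pd.Series(mz, index=idx, name="mz"),
    )
    acc_idx = pd.Index(accessions, name="protein_accession")
    truth = GroundTruth(
        labels=pd.Series(labels, index=acc_idx, name="label"),
        true_log2_fold_change=pd.Series(true_fc, index=acc_idx,
                                        name="true_log2_fc"),
    )
    return SimOutput(table=table, design=design, truth=truth,
                     contaminant_annotation=ContaminantAnnotation())


def simulate_mixed_benchmark(cfg: SimConfig | None = None) -> SimOutput:
    """Mixed single-cell benchmark with known differential proteins.

    Differential proteins are scaled by ``fold_change`` in every group-1
    cell, so their true log2 fold change (group1/group2) is
    log2(fold_change) — exactly −1 for the default halving. Contamination is
    injected afterwards via :func:`inject_contaminants`.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    design = _design(cfg)
    n_prot = cfg.n_de_proteins + cfg.n_stable_proteins
    accessions = np.array(
        [f"DEP{i + 1:05d}" for i in range(cfg.n_de_proteins)]
        + [f"STA{i + 1:05d}" for i in range(cfg.n_stable_proteins)])
    labels = np.array([LABEL_CHANGING] * cfg.n_de_proteins
                      + [LABEL_STABLE] * cfg.n_stable_proteins)
    true_fc = np.where(labels == LABEL_CHANGING, np.log2(cfg.fold_change), 0.0)

    base = rng.lognormal(cfg.base_intensity_log_mean, cfg.base_intensity_sdlog,
                         size=n_prot)
    s = cfg.samples_per_group
    bio = rng.lognormal(0.0, cfg.protein_abundance_sdlog, size=(n_prot, 2 * s))
    protein_cell = base[:, None] * bio
    protein_cell[labels == LABEL_CHANGING, :s] *= cfg.fold_change

    out = _assemble(cfg, accessions, labels, true_fc, protein_cell, rng, design)
    if cfg.n_contaminant_peptides or cfg.n_masquerading_peptides:
        out = inject_contaminants(out, cfg)
    return out


def simulate_spike_in(
    cfg: SimConfig | None = None,
    background_fraction_1: float = 0.97,
    background_fraction_2: float = 0.94,
) -> SimOutput:
    """Two-proteome spike-in benchmark with closed-form fold changes.

    Group 1 mixes background (species A) at mass fraction f1 with spike
    (species B) at 1 − f1; group 2 at f2 / 1 − f2. Species-B proteins scale
    by (1−f1)/(1−f2) between groups — a true log2 fold change of −1 for the
    default 3% vs 6% spike — and species-A proteins by f1/f2 (≈ 0.045 log2,
    labelled stable, mirroring a spike-in's nominally constant background).
    Each species' mass fraction is divided by its protein count (the
    per-protein share of the load), so a small spike proteome is diluted but
    not vanishingly so, as in a real two-proteome mixture. Technical-replicate
    noise only: no biological cell-to-cell variation.
    """
    cfg = cfg or SimConfig()
    f1, f2 = background_fraction_1, background_fraction_2
    if not (0 < f1 < 1 and 0 < f2 < 1):
        raise ValidationError("background fractions must be in (0, 1)")
    rng = np.random.default_rng(cfg.seed)
    design = _design(cfg)
    n_b, n_a = cfg.n_de_proteins, cfg.n_stable_proteins
    accessions = np.array([f"ECO{i + 1:05d}" for i in range(n_b)]
                          + [f"HSA{i + 1:05d}" for i in range(n_a)])
    labels = np.array([LABEL_CHANGING] * n_b + [LABEL_STABLE] * n_a)
    true_fc = np.concatenate([
        np.full(n_b, np.log2((1 - f1) / (1 - f2))),
        np.full(n_a, np.log2(f1 / f2)),
    ])
    base = rng.lognormal(cfg.base_intensity_log_mean, cfg.base_intensity_sdlog,
                         size=n_b + n_a)
    s = cfg.samples_per_group
    # per-protein share of the load: mass fraction / species protein count,
    # rescaled so the pooled mixture stays on the base intensity scale
    norm = n_a + n_b
    scale = np.empty((n_b + n_a, 2 * s))
    scale[:n_b, :s] = (1 - f1) / n_b * norm
    scale[:n_b, s:] = (1 - f2) / n_b * norm
    scale[n_b:, :s] = f1 / n_a * norm
    scale[n_b:, s:] = f2 / n_a * norm
    protein_cell = base[:, None] * scale
    out = _assemble(cfg, accessions, labels, true_fc, protein_cell, rng, design)
    if cfg.n_contaminant_peptides or cfg.n_masquerading_peptides:
        out = inject_contaminants(out, cfg)
    return out


def inject_contaminants(out: SimOutput, cfg: SimConfig) -> SimOutput:
    """Add contamination: prefixed contaminant peptides plus masqueraders.

    (a) ``n_contaminant_peptides`` peptides with CON_-prefixed accessions and
    random peak features; their (RT, m/z) become the contaminant annotation.
    (b) ``n_masquerading_peptides`` peptides assigned to randomly chosen
    stable host proteins but whose peak features lie strictly within the
    default matching tolerances of an annotated contaminant — the
    misassigned-contamination trap. Masqueraders dominate their host
    protein's summed abundance and carry an acquisition-order intensity
    drift (carryover-style), so a summation roll-up sees a spurious group
    difference while the feature filter removes them outright.

    Uses generator seed ``cfg.seed + 1``; a no-op when both counts are 0.
    """
    if cfg.n_contaminant_peptides == 0 and cfg.n_masquerading_peptides == 0:
        return out
    rng = np.random.default_rng(cfg.seed + 1)
    table, design = out.table, out.design
    n_samples = len(design.sample_ids)
    new_ids: list[str] = []
    new_acc: list[str] = []
    new_rt: list[float] = []
    new_mz: list[float] = []
    new_rows: list[np.ndarray] = []

    n_con = cfg.n_contaminant_peptides
    con_rt = rng.uniform(*cfg.rt_range, size=max(n_con, 1))
    con_mz = rng.uniform(*cfg.mz_range, size=max(n_con, 1))
    con_base = rng.lognormal(cfg.base_intensity_log_mean + 1.5, 0.5, size=max(n_con, 1))
    for i in range(n_con):
        new_ids.append(f"CON{i + 1:03d}_pep1")
        new_acc.append(f"CON_{i + 1:03d}")
        new_rt.append(float(con_rt[i]))
        new_mz.append(float(con_mz[i]))
        new_rows.append(con_base[i] * rng.lognormal(0.0, 0.3, size=n_samples))
    features = np.column_stack([con_rt[:n_con], con_mz[:n_con]])

    masq_ids: list[str] = []
    if cfg.n_masquerading_peptides and n_con:
        stable_hosts = out.truth.labels.index[out.truth.labels == LABEL_STABLE]
        stable_hosts = [a for a in stable_hosts
                        if a in set(table.protein_accession.to_numpy())]
        n_masq = min(cfg.n_masquerading_peptides, len(stable_hosts))
        hosts = rng.choice(np.array(stable_hosts), size=n_masq, replace=False)
        host_totals = table.abundances.groupby(table.protein_accession,
                                               sort=False).sum().mean(axis=1)
        run_pos = np.linspace(-0.5, 0.5, n_samples)
        for k, host in enumerate(hosts):
            feat = features[rng.integers(0, n_con)]
            drift = rng.uniform(1.5, 3.0) * rng.choice([-1.0, 1.0])
            level = max(float(host_totals[host]), 1.0) * rng.uniform(10.0, 30.0)
            pid = f"{host}_masq{k + 1}"
            masq_ids.append(pid)
            new_ids.append(pid)
            new_acc.append(str(host))
            new_rt.append(float(feat[0] + rng.uniform(-0.04, 0.04)))
            new_mz.append(float(feat[1] + rng.uniform(-1.8, 1.8)))
            new_rows.append(level * np.exp(drift * run_pos)
                            * rng.lognormal(0.0, 0.3, size=n_samples))

    idx = pd.Index(new_ids, name="peptide_id")
    add = PeptideTable(
        abundances=pd.DataFrame(np.array(new_rows).reshape(len(new_ids), n_samples),
                                index=idx, columns=design.sample_ids),
        protein_accession=pd.Series(new_acc, index=idx, name="protein"),
        retention_time=pd.Series(new_rt, index=idx, name="retention_time"),
        mz=pd.Series(new_mz, index=idx, name="mz"),
    )
    merged = PeptideTable(
        abundances=pd.concat([table.abundances, add.abundances]),
        protein_accession=pd.concat([table.protein_accession,
                                     add.protein_accession]),
        retention_time=pd.concat([table.retention_time, add.retention_time]),
        mz=pd.concat([table.mz, add.mz]),
    )
    return dataclasses.replace(
        out,
        table=merged,
        contaminant_annotation=ContaminantAnnotation(
            accession_prefixes=("CON", "REV"),
            feature_table=features if n_con else None),
        contaminant_peptide_ids=[f"CON{i + 1:03d}_pep1" for i in range(n_con)],
        masquerading_peptide_ids=masq_ids,
    )


PRESETS: dict[str, dict] = {
    # mixed single-cell design: defaults as-is
    "d1": {},
    # low-input spike-in: 7 technical replicates per group, scaled-down
    # proteomes, spike-in generator
    "d2": {"n_stable_proteins": 300, "n_de_proteins": 100,
           "samples_per_group": 7, "protein_abundance_sdlog": 0.0,
           "n_masquerading_peptides": 10},
}


def simulate_preset(preset: str, seed: int = 0) -> SimOutput:
    """Generate a named preset: ``d1`` (mixed single-cell) or ``d2`` (spike-in)."""
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}")
    cfg = SimConfig(seed=seed, **PRESETS[preset])
    if preset == "d2":
        return simulate_spike_in(cfg)
    return simulate_mixed_benchmark(cfg)


def write_sim_output(out: SimOutput, out_dir: str | Path) -> dict[str, Path]:
    """Write peptides/design/truth/contaminant TSVs; deterministic bytes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptides": out_dir / "peptides.tsv",
        "design": out_dir / "design.tsv",
        "truth": out_dir / "truth.tsv",
        "contaminant_features": out_dir / "contaminant_features.tsv",
    }
    write_peptide_table(out.table, paths["peptides"])
    write_design(out.design, paths["design"])
    write_ground_truth(out.truth, paths["truth"])
    feats = out.contaminant_annotation.feature_table
    write_contaminant_features(
        feats if feats is not None else np.empty((0, 2)),
        paths["contaminant_features"])
    return paths
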