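# pepdesc

Peptide-level differential expression scoring for label-free single-cell
proteomics.

## The problem

In single-cell and low-input mass spectrometry, most proteins are quantified
by only a handful of peptides, 40–60% of peptide measurements are missing
(dropout concentrated at low abundance), and individual peptides are often
wrong — misassigned by match-between-runs, dominated by contamination
signals such as keratins, or mostly absent across cells. The conventional
workflow sums peptide intensities into a protein abundance (zero-filling
missing values) and runs a t test per protein; a single bad or mostly-missing
peptide then corrupts the protein-level result. `pepdesc` instead scores
differential expression *at the peptide level*, filters untrustworthy
peptides before they can do damage, and aggregates peptide evidence with
fidelity weights — with no imputation anywhere.

## The DE-score

For peptide *i* with abundances X over two groups of M and N samples
(missing values stored as 0), the peptide DE-score is the clipped log2
median of all between-group pairwise ratios:

    DE-score_i = log2( median{ X_im / X_in : m ∈ M, n ∈ N } ),  |DE-score_i| ≤ 1.5

Pairs where both members are 0 are dropped; a zero denominator contributes
+∞ and a zero numerator 0, so consistent presence in only one group drives
the score to the clip bound. Each peptide also gets a two-sided
Mann–Whitney p-value p_i (zeros participate as ties) and, within its
protein, a weight combining expression level with positive Pearson
correlation to sibling peptides:

    W'_i = mean(X_i) · Σ_j r⁺_ij ,   W_i = W'_i / Σ W'_i

The protein DE-score gates each peptide at p_i < α (default 0.05):

    DE-score = Σ_i DE-score_i · W_i · δ_i ,   δ_i = 1{p_i < α}

Proteins quantified by a single peptide use the unclipped log2 median ratio
if p < α, else 0. A protein is called changing when |DE-score| > 0.3.

Before scoring, the pipeline removes contaminant-accession peptides (CON/REV
prefixes), peptides missing in more than 60% of samples, and peptides whose
peak features match a known contaminant (|ΔRT| < 0.05 min and |Δm/z| < 2 Th),
then drops outlier samples and median-normalizes each sample within its
group (mean normalization auto-selected when any sample exceeds 50%
missingness).

The package also provides the conventional protein-level baselines
(summation roll-up + pooled t test or Wilcoxon), precision–recall
evaluation, and a synthetic benchmark generator with known ground truth.

## Worked example

```python
import pandas as pd
import pepdesc as pp

samples = [f"s{i}" for i in range(1, 9)]
idx = pd.Index(["ASF1B_p1", "ASF1B_p2", "MRI1_p1"], name="peptide_id")
table = pp.PeptideTable(
    abundances=pd.DataFrame(
        [[40, 44, 38, 42, 20, 22, 19, 21],      # halves in the treat group
         [10, 11,  9, 10,  5,  6,  5,  5],      # halves, lower abundance
         [30, 33, 27, 30, 31, 29, 30, 30.0]],   # stable
        index=idx, columns=samples),
    protein_accession=pd.Series(["ASF1B", "ASF1B", "MRI1"], index=idx),
)
design = pp.SampleDesign(
    sample_ids=samples,
    group_labels=pd.Series(["ctrl"] * 4 + ["treat"] * 4,
                           index=pd.Index(samples, name="sample_id")),
    group_names=("ctrl", "treat"))
res = pp.run_pepdesc(table, design)
print(res.peptide_scores[["peptide_id", "de_score", "p_value", "weight",
                          "adjusted_score"]].round(4).to_string(index=False))
print(res.protein_scores.round(4).to_string(index=False))
```

prints

```
peptide_id  de_score  p_value  weight  adjusted_score
  ASF1B_p1    1.0000   0.0202  0.8015          0.8015
  ASF1B_p2    0.9279   0.0211  0.1985          0.1842
   MRI1_p1   -0.0229   1.0000  1.0000         -0.0229

protein_accession  de_score  n_peptides_used
            ASF1B    0.9857                2
             MRI1    0.0000                1
```

Both ASF1B peptides double from treat to ctrl (log2 ratio ≈ 1) and are
significant, so the protein score is their weighted sum ≈ 0.99 — called
changing. The single MRI1 peptide is flat (p = 1), so its protein scores
exactly 0 — stable.

## Command line

```sh
pepdesc simulate --preset d1 --seed 1 --out bench/       # synthetic benchmark
pepdesc run --table bench/peptides.tsv --design bench/design.tsv \
    --features bench/contaminant_features.tsv --out results/
pepdesc baselines --table bench/peptides.tsv --design bench/design.tsv \
    --method ttest --out ttest.tsv
pepdesc evaluate --scores results/protein_scores.tsv \
    --truth bench/truth.tsv --out eval.tsv
```

`--preset d1` emulates a mixed single-cell design (1000 stable + 200 halved
proteins, 10 cells per group, heavy abundance-dependent dropout, injected
contamination); `--preset d2` a low-input two-proteome spike-in (3% vs 6%
spike, 7 technical replicates per group). Any pipeline parameter can be set
in a YAML config (`--config`) or by flags; the effective configuration is
echoed next to the outputs.

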