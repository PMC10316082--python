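# Methods

## Model and procedure

`pepdesc` scores differential protein expression between two groups of
label-free MS samples from peptide-level quantification alone. The pipeline
runs in a fixed order: filtration → outlier-sample removal → normalization →
peptide scoring → protein aggregation. Its core assumptions are:

* a detected label-free intensity is never exactly 0, so zeros in the input
  are missing values and are kept as 0 rather than imputed;
* between-group pairwise ratios of a peptide's abundances are a robust
  fold-change signal: their median is insensitive to a few aberrant cells,
  and presence/absence between groups is informative rather than noise
  (a zero denominator contributes +∞, a zero numerator 0, both-zero pairs
  are dropped);
* peptides of the same protein should co-vary; a high-abundance peptide that
  does not correlate with its siblings is suspect, so weights multiply mean
  abundance by the sum of positive Pearson correlations (self term r = 1
  included, which keeps the weight positive for any expressed peptide and
  reduces to pure abundance weighting when peptides are uncorrelated);
* the rank test controls which peptides may contribute: the protein score
  sums weight-adjusted peptide scores gated at p < α, so it is exactly 0
  when no peptide is individually significant.

Weights are normalized over *all* of a protein's retained peptides, so
non-significant peptides dilute the protein score — the gated sum is
conservative by construction. Single-peptide proteins use the unclipped
log2 median ratio gated by their own p-value; with presence/absence
patterns this can be ±∞, which ranks (correctly) at the extreme of the
score ordering and is excluded from averaged summaries.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `missing_fraction_threshold` | 0.6 | remove a peptide when its missing fraction is strictly over this |
| `rt_tolerance` | 0.05 min | contaminant feature match requires \|ΔRT\| strictly below |
| `mz_tolerance` | 2 Th | … and \|Δm/z\| strictly below |
| `clip` | 1.5 | bound on peptide \|DE-score\| |
| `alpha` | 0.05 | significance gate on the Mann–Whitney p-value |
| call threshold | 0.3 | a protein is "changing" when \|DE-score\| is strictly above |
| `normalization` | auto | per-sample median rescaling; mean when any sample is > 50% missing |
| `per_group` | true | rescaling target computed within each sample group |
| `outlier_kmad` / `outlier_max_missing` | 3 / 0.95 | outlier-sample rules (below) |

The Mann–Whitney p-value uses the exact null when the pooled data are
tie-free and M·N ≤ 400, otherwise the tie-corrected normal approximation
with continuity correction; zeros participate as tied observations, and
completely tied data yield p = 1.

## Normalization

Each sample's non-missing abundances are divided by that sample's location
statistic (median, or mean in high-missingness mode) and rescaled to the
median of those statistics across samples *of the same group*. Per-group
targets matter: when a sizeable fraction of the proteome genuinely changes
in one group, a global target mistakes the composition shift for a scale
difference and biases every ratio (on the default benchmark this inflates
stable-protein scores by ≈ 0.18 and attenuates the halved proteins' score
from −1.0 to −0.82); group-internal targets cancel the shift exactly while
still removing per-sample technical scale differences. A global-target
switch is retained. Normalization is idempotent and scale-equivariant, and
missing cells stay 0. The protein-level baseline arm normalizes its rolled-up
matrix the same way.

## Outlier samples

No standard definition exists at this pipeline stage, so the rule is
deliberately assumption-light: a sample is dropped when (a) its missing
fraction exceeds 0.95, or (b) the natural log of its total non-missing
intensity deviates from its group median by more than 3 normal-scaled MADs
*and* by more than 0.3 ln units. The absolute floor guards the degenerate
case of a near-zero MAD on homogeneous samples, where any fluctuation would
otherwise be flagged. Detection requires ≥ 3 samples per group and refuses
to leave a group with fewer than 2.

## Numerical choices

* Median of an even number of pairwise ratios is the midpoint of the two
  central values; a midpoint involving +∞ is +∞. Swapping group labels
  therefore negates peptide scores exactly for odd pair counts and up to the
  interpolation discrepancy for even ones.
* "Over 60% missing" and both feature tolerances are strict inequalities;
  boundary cases are retained.
* Filtration rules run accession → missingness → feature match, each peptide
  attributed to the first rule that removes it; the whole filter is
  idempotent.
* Proteins whose every peptide was filtered or is all-missing are absent
  from the output (not scored 0); the filter report records why.
* No multiple-testing correction is applied to the per-peptide gate — the
  gate is a raw p < α by design.

## The benchmark generator

`simulate_mixed_benchmark` emulates a mixed single-cell two-group design:
1000 stable + 200 differential proteins, the differential set multiplied by
`fold_change` (default 0.5) in every group-1 cell, 10 cells per group. The
generative model is multiplicative on intensity: protein base abundance
lognormal(ln-mean 14, sd 1.5) — arbitrary MS1-style units around 10⁶ —
cell-to-cell biological variation (sd 0.5 ln), a fixed per-peptide
ionization factor (sd 1.0 ln; it cancels in cross-group ratios but drives
the expression-level weights, which is what makes weight behaviour
testable), and measurement noise (sd 0.3 ln). Peptide counts per protein
are geometric (mean 5, minimum 1).

Dropout is missing-not-at-random: a logistic function of log intensity with
midpoint ln x = 13.5 and steepness 2.0 per ln unit, i.e. detection
transitions from 10% to 90% over roughly one decade of intensity, matching
the sharpness of empirical LC-MS detection-probability curves; overall
missingness at the defaults is ≈ 41%. An MCAR switch exists for ablation.

Contamination is injected in two forms: prefixed-accession contaminant
peptides whose (RT, m/z) populate the contaminant annotation, and
*masquerading* peptides — assigned to real stable proteins, dominating the
host's summed abundance (10–30×), with features strictly inside the default
matching tolerances of an annotated contaminant, and an acquisition-order
intensity drift (carryover-style, 1.5–3 ln units across the run). Because
groups are acquired in blocks, the drift produces a systematic group
difference in the host's roll-up sum — flipping the t-test baseline — while
the feature filter removes the peptide before it can touch the peptide-level
score. The host's truth label remains "stable".

`simulate_spike_in` emulates a two-proteome mixture (defaults 97:3 vs 94:6
by mass, 7 technical replicates per group, no biological variation). Each
species' mass fraction is divided by its protein count, so spike proteins
are diluted ~an order of magnitude rather than vanishing; true fold changes
follow in closed form — |log2 fc| = 1 exactly for the spike species, 0.045
for the background (labelled stable).

All draws flow from one seeded generator in a documented order; identical
configurations produce byte-identical output files.

### What the generator does not emulate

Real search-engine artifacts (shared peptides, FDR-dependent identification,
modified-peptide redundancy), chromatographic structure beyond a scalar RT,
batch effects, per-sample technical scale drift, and correlated biological
programs across proteins are absent. Passing tests therefore demonstrate
that the statistics behave as specified under a controlled
hierarchical-lognormal, MNAR-dropout regime — not that the method's
operating characteristics transfer quantitatively to any particular
instrument or search pipeline.

## Problem sizes

The default benchmark (1200 proteins, ≈ 6000 peptides, 20 samples) runs the
full pipeline in ≈ 6 s; the test suite uses this size where the claim needs
it (parameter recovery, seed-level comparisons over 10 replicates) and
much smaller tables elsewhere. The spike-in preset is scaled to 400
proteins with 7 + 7 replicates.

## Known limitations

* Single-peptide protein scores are unbounded (±∞ under presence/absence);
  a `clip_single_peptide` switch applies the peptide clip instead.
* The score gate inherits the rank test's low power at small n with heavy
  ties: proteins whose peptides all sit near the detection limit score 0
  regardless of their true fold change.
* The weight's self-correlation term and the treatment of zeros in means
  and correlations (included by default, observed-only as an option) are
  conventions; alternatives shift third decimals on the benchmarks.
* With unequal group sizes the t-test baseline generalizes the equal-n
  pooled form to the standard n-weighted pooled variance.
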