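# Methods

This note records the models implemented in `sweepscan`, the parameter
choices that matter, what the synthetic data does and does not emulate, and
the numerical decisions a maintainer would want to know. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Windowed F_ST and the d_i scan

Per-SNP differentiation between two subpopulations uses the Weir–Cockerham
(1984) variance components a (among populations), b (among individuals
within populations) and c (within individuals), computed from called
genotypes only; missing calls reduce that SNP's per-population sample size.
Observed heterozygote counts enter the components; when only allele counts
are available (`snp_fst_components` without `het_*`), the Hardy–Weinberg
expectation is substituted. Note the estimator is unbiased, not
non-negative: at identical sample frequencies the among-population
component is slightly negative at finite n and vanishes as n grows.

Window F_ST is the ratio of sums Σa / Σ(a+b+c) over the informative SNPs of
a window — more stable than averaging per-SNP ratios when low-MAF SNPs are
present. The window grid is anchored at position 1 with 1-based closed
intervals `[w·k+1, w·(k+1)]`, width 10 kb by default (a SNP at 30,595,130
falls in window index 3059, spanning 30,590,001–30,600,000). SNPs
monomorphic for the same allele in both populations are non-informative;
windows with no informative SNP for a pair are excluded from that pair's
analyzed set. Negative window values are retained — truncating at zero
would bias the standardization below.

d_i(w) for subpopulation i sums, over all other subpopulations j, the
z-score of F_ST^{ij}(w) against that pair's genome-wide mean and standard
deviation (population formula, divisor N, for reproducibility). d_i is
computed on the windows analyzed for *every* pair, with each pair's moments
taken over exactly that common window set; this makes the genome-wide mean
of d_i exactly zero per subpopulation by construction (the `FstPanel`
container additionally reports per-pair moments over each pair's own
analyzed set, which coincide with the common-set moments whenever no window
is missing for any pair). A pair with zero spread contributes a zero
summand with a warning.

Significance is empirical: the top `top_fraction` (default 0.001) of each
subpopulation's d_i distribution, k = ceil(top_fraction · N) windows, ties
at the k-th value broken by (chromosome, start) ascending so the selection
is deterministic. With fewer than ~1000 windows the empirical threshold is
coarse and a warning is raised.

## Kinship, FLK and hapFLK

The population tree comes from pairwise Reynolds θ distances. Two details
matter for calibration and are easy to get wrong:

1. **Sampling variance.** θ computed from sample frequencies is inflated by
   the binomial variance of the frequency estimates (~1/(2n) per
   population). `reynolds_distance` optionally subtracts an unbiased
   estimate of this term, and `reynolds_distance_matrix` does so by
   default, so distances reflect population drift only.
2. **Scale.** The pairwise θ between two populations estimates the *mean*
   of their two root-to-leaf drift coefficients, not the sum, while tree
   distances are branch-length sums. `drift_kinship` therefore doubles the
   distance matrix before neighbor joining. (The raw
   `kinship_from_tree(d)` applies no scaling — it maps whatever distances
   it is given onto a midpoint-rooted NJ tree, with negative NJ branch
   lengths clipped to zero with a warning; F[i][j] is the root-to-MRCA
   shared branch length, F[i][i] the root-to-leaf depth.) Without the
   doubling, the FLK statistic runs hot by roughly a factor (measured as
   null mean T ≈ 4 instead of 3 on a four-population drift-0.05 null).

Midpoint rooting stands in for an outgroup, which the intended use case
(subpopulations of one breed) does not have; it is deterministic.

FLK at a SNP: p̂0 = (1ᵀF⁻¹p)/(1ᵀF⁻¹1),
T = (p − p̂0·1)ᵀ[p̂0(1−p̂0)F]⁻¹(p − p̂0·1), referred to chi-square with
n_pops − 1 df. `flk_scan` adds the per-SNP binomial sampling term
(1 − F_ii)/(2 n_i) to the kinship diagonal, using each SNP's called sample
sizes, and skips SNPs monomorphic across the pooled sample. A singular
kinship falls back to the Moore–Penrose pseudo-inverse with a warning.

The chi-square reference is asymptotic in weak drift: under a
Balding–Nichols null the subpopulation frequencies are beta-distributed,
bounded and platykurtic, so at drift 0.05 the test sits slightly below
nominal (the acceptance suite measures mean T within 0.15 of 3 and a 5%
rejection rate within [0.035, 0.065] at 10,000 SNPs; the conservative
offset is on the order of 2–4 Monte-Carlo standard errors and shrinks with
drift). The calibration bands are wide enough for this approximation and
narrow enough to catch genuine scale errors.

### Haplotype-cluster model

LD is modeled fastPHASE-style: K ancestral haplotype clusters; at marker m
each haplotype either continues its current cluster or, with jump
probability ρ(m), re-draws a cluster from weights α(m); cluster k emits the
alternate allele with frequency θ_k(m). Unphased genotypes are handled
directly by a diploid HMM over ordered cluster pairs (K² states); the
rank-one structure of the per-haplotype transition operator keeps every
forward/backward step O(K²) per individual, and the jump-event sufficient
statistics needed for the exact EM updates of α and ρ are accumulated with
the same decomposition (verified against brute-force path enumeration in
development). The M-step for θ augments the hidden state with the allele
phase of heterozygotes, so the EM log-likelihood is monotone up to the
parameter clipping below. Defaults: 100 max iterations, relative tolerance
1e-6, θ clipped to [1e-4, 1−1e-4], α floored at 1e-6 and renormalized,
ρ in [1e-6, 0.999], ρ initialized from inter-marker distances via
1 − exp(−10⁻⁵ · gap). Restarts are seeded `seed + fit_index`; all fits are
retained because single EM runs do land in local optima (the test suite
contains a two-founder recovery case where two restarts both find the same
inferior optimum and the best of four recovers the founder frequencies to
RMSE ≈ 0.001). The published parameterization of this model class uses
K = 10 and 20 restarts; `fit_cluster_model` keeps K = 10 as the default
and defaults to 5 restarts, which desk-scale experiments showed sufficient
for the statistics built on top (both are configurable).

hapFLK evaluates the FLK quadratic form on each cluster's per-population
expected frequency vector (posterior cluster usage averaged within
subpopulation), sums over clusters and halves the sum — so K = 2 reduces
exactly to biallelic FLK on one cluster's frequency — then averages over
restarts. Because the null distribution of this summed form is not a clean
chi-square (clusters are neither independent nor do their frequencies have
binomial sampling properties), p-values come from a genome-wide robust
standardization: median/MAD → z → normal upper tail, flagged at
−log10 p > 4. This is an empirical outlier scale, adequate for ranking and
thresholding within a scan, not a frequentist error rate.

## Local haplotype sharing

s(m) = Σ_k f_k(m)² with f_k(m) the subpopulation's expected cluster
frequency: the probability that two random haplotypes share an ancestral
cluster at m, bounded by [1/K, 1], invariant to cluster relabeling, and
strictly increasing as mass concentrates. It is averaged over EM restarts.
This is deliberately *not* a reimplementation of any Bayesian
ancestral-haplotype association model: there are no Bayes factors here. The
significance rule standardizes the track by median/MAD, flags markers whose
−log10 normal tail probability exceeds the threshold (default 5, an
empirical analog of a log-Bayes-factor cutoff), removes runs shorter than
`min_run = 2` (an isolated SNP does not constitute a shared haplotype), and
exports surviving runs as intervals. On null panels the flagged fraction is
small (a few percent) but not the literal nominal tail level — an
empirical standardization cannot deliver 10⁻⁵ control, and outputs label
the score accordingly.

## Synthetic panels and ground truth

`simulate_panel` generates the structure the scans assume:

- **Drift.** Ancestral frequencies U(0.05, 0.95); each branch of a
  two-level tree (groups of subpopulations; default a single group, i.e.
  one level) draws from the Balding–Nichols beta with parameters
  p(1−F)/F and (1−p)(1−F)/F, giving Var(p_i) = F·p(1−p) exactly, hence
  expected pairwise Weir–Cockerham F_ST ≈ drift_f between independently
  drifted subpopulations.
- **LD.** Each subpopulation has `n_founder_haplotypes` (default 16)
  founders; individual haplotypes are founder mosaics with interval switch
  probability 1 − exp(−rate·gap) (default rate 10⁻⁵/bp). The founder pool
  is frequency-matched — round(n_f·p) founders carry the alternate allele,
  placed uniformly at random — because an i.i.d. Bernoulli pool would add
  ~p(1−p)/n_f of spurious drift (with 8–16 founders that dwarfs a nominal
  F of 0.05); matching leaves only an O(1/(12·n_f²)) quantization bias, and
  the realized genome-wide F_ST stays at the Balding–Nichols expectation.
- **Sweeps.** Inside the sweep interval, `favored_fraction` (in (0.5, 1]) of
  the target subpopulation's haplotypes copy founder 0, creating both an
  allele-frequency shift (seen by d_i/FLK) and a dominant local haplotype
  (seen by hapFLK/LHS). Truth records keep each sweep's interval, target,
  and the realized core-allele frequency per subpopulation at the marker
  nearest the interval midpoint.
- **Missingness** is uniform at random (QC exercise only). Positions are
  uniform without replacement, sorted, 1-based. Everything is reproducible
  bit-for-bit from the config seed.

`balding_nichols_panel` is the LD-free pure null (independent SNPs,
binomial genotype sampling) used for drift-model calibration.

What the generator does **not** emulate: recombination-map heterogeneity,
ascertainment bias of genotyping arrays, imputation artifacts, relatedness
within subpopulations, admixture, or background selection. Passing tests
therefore demonstrate correctness of the statistics under their own model
assumptions and detection power under idealized sweeps — not field
performance on array data.

`evaluate_recovery` scores detected ROI against truth with a ≥1 bp overlap
rule: recall requires an ROI of the correct subpopulation (population-
agnostic ROI labeled "all", as hapFLK produces, match any target);
precision counts detected ROI overlapping any truth interval and is
flagged undefined (NaN) when nothing was detected.

## ROI, consensus, annotation

Merging is single-linkage on each chromosome with the gap measured
edge-to-edge and the comparison inclusive (`gap ≤ max_gap`, default
500 kb); it is idempotent and order-invariant, and a lone significant
window is itself an ROI. The sharing matrix is boolean windows ×
subpopulations membership on the common grid, with per-window multiplicity,
a multiplicity histogram, and symmetric pairwise intersection counts.
Method overlap reports the fraction of one ROI list overlapped (≥1 bp) by
another. Gene annotation reads BED (0-based half-open, converted to the
package-wide 1-based closed convention at the boundary; an abutting BED
interval does not overlap) or GFF3 `gene` records, intersects with ≥1 bp,
and counts distinct gene identifiers per subpopulation (a gene hit by two
ROI of one subpopulation counts once).

The bundled reference tables (`sweepscan/data/`) transcribe the summary
tables of a published six-subpopulation Quarter Horse scan and serve as
worked-example inputs for this machinery. Two internal tensions in that
source are deliberately left untested: the shared-window table tallies
multiplicities 49/6/1 against the accompanying prose's 50/5/1 (the robust
count — 56 windows shared by ≥2 subpopulations — agrees either way), and
the ROI-count column sums to 332 against a printed total of 346. Pairwise
sharing counts are reported but not asserted against the prose.

## Genotype I/O and QC

PED/MAP and VCF v4.2 (GT-only, biallelic; phase accepted and discarded).
PED carries no reference/alternate orientation, so dosage is recoded
against the first allele seen per marker in file order — deterministic,
but a marker whose first called genotype is homozygous-alternate returns
with flipped coding after a write/read cycle (an equivalent panel for
every statistic here, all invariant to allele relabeling; the VCF path
round-trips exactly and is preferred for archival). Subpopulation labels
ride in the PED family-id column and in `##SAMPLE=<ID=...,Population=...>`
VCF header lines.

Marker QC applies three filters in a fixed order for reproducible
attrition reports — non-autosomal, call rate < 0.95, pooled MAF < 0.05 —
each marker attributed to its first failing filter. Removal is strict, so
boundary values (call rate exactly 0.95, MAF exactly 0.05) are retained;
MAF is pooled across all samples, not per subpopulation; QC is idempotent.
Per-sample QC and imputation are out of scope.

## Problem sizes

Unit and acceptance tests run at desk scale chosen to exercise every code
path with stable statistics: panels of 2–4 subpopulations, 20–50 diploids
each, 150–10,000 SNPs; cluster models with K = 2–5 and 1–4 restarts; 20
seeds for d_i sweep recovery and 10 sweep/null pairs for the
hapFLK/LHS contrast. `scripts/acceptance.py` uses the same sizes and
derives all of its randomness from `--seed`.
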