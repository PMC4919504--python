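# Methods

## Relative exon usage

Exon quantification follows the RPKM convention: for an exon of length
`L` bp with `c` overlapping reads in a library of `N` aligned reads,
`rpkm = c / ((N/1e6)(L/1e3))`. Coordinates are BED (0-based, half-open);
a read overlaps an exon if they share ≥ 1 base, and a junction-spanning
read increments every exon it touches (multicov semantics, not fractional
assignment).

Relative usage of exon *i* in one sample is
`u_i = 100 · r_i / (Σ_j r_j − r_i)` — the exon's RPKM against the summed
RPKM of all *other* exons of the gene. This is scale-invariant (per-sample
library depth and overall gene expression cancel), so usage profiles are
comparable across patients. Where the denominator is zero the value is
undefined (NaN); patients with zero total RPKM are dropped before
clustering. Usage/clinical tables are inner-joined on patient barcode;
records whose survival time cannot be derived (alive with no follow-up
date) are dropped with a logged count, and the cohort is then restricted
to survival time ≥ 90 days (inclusive), since very short follow-up is
uninformative and over-represented in registry data.

## Survival clustering

Patients are clustered by k-means (Lloyd, Euclidean) on raw usage
percentages — no per-exon standardization by default, since the usage
transform already removes the dominant scale effects; a z-score option
exists for callers who want variance equalization. `n_restarts`
initializations (default 10) are scored by within-cluster sum of squares
and the run is deterministic under the seed.

The initial k (default 4) is then reduced by survival similarity: the pair
of clusters with the **largest** pairwise log-rank p (most similar curves)
is merged first; merging is mandatory down to `k_target` (default 3) and
continues past it only while the largest pairwise p still exceeds
`p_merge` (default 0.2, i.e. curves statistically indistinguishable at a
lenient level). "Nearly identical survival curves" has no canonical
definition; this greedy rule is deterministic, records its merge map, and
reproduces a 4 → 3 reduction whenever one usage cluster was split across
two k-means labels with a shared hazard.

Kaplan–Meier estimation and the k-sample log-rank test (chi-squared on
k − 1 df) are delegated to lifelines; subjects censored at an event time
remain at risk for events at that time (standard convention). Per-cluster
usage summaries report median and quartiles with linear interpolation
(type-7), the default quantile rule of numpy/pandas — boxplot statistics
depend on this choice, so it is fixed here.

## Receptor-status comparisons

One two-sided Wilcoxon rank-sum test per exon between two status levels
(ER pos/neg or Her2 pos/neg); equivocal and unavailable records are
excluded. The null distribution is enumerated exactly when the combined
sample is ≤ 20 and tie-free — where enumeration is cheap — and otherwise
approximated normally with continuity correction and midranks for ties.
The family of per-exon p-values (all exons tested, by default the full
gene) is adjusted by the step-down Holm procedure, which controls the
family-wise error rate with no independence assumptions.

## Spectral-count statistics

A prey protein that binds every bait variant equally should split its
spectral counts across IP conditions in the same proportions as the bait
itself (the bait row measures per-condition pull-down recovery). Two tests
of that null are provided:

* **Yates chi-squared, 2×2**: rows (prey, bait), columns the two compared
  conditions; expectations from the row/column marginals; each cell
  contributes `max(0, |O−E| − 0.5)² / E`; p is the right tail on 1 df.
  The continuity-correction term is **floored at zero**: a prey tracking
  the bait within half a count in every cell must score exactly 0, not a
  spurious positive statistic.
* **G test**: `G = 2 Σ O ln(O/E)` with `0·ln 0 = 0`, against expectations
  split purely by bait proportions, `E_c = (Σ prey) · bait_c / (Σ bait)`;
  p on (#conditions − 1) df. This accepts any number of conditions.

The two tests use slightly different expectations (full marginals vs pure
bait proportions) but agree asymptotically and rank candidate preys
identically on the published counts. Both are reported; neither is
privileged. The volcano export uses
`lfc = log2((c_B + q)/(c_A + q))` with pseudocount `q = 0.5` and the Yates
p-value.

## Phosphosite occupancy

Measured intensity is modeled as concentration / ionization efficiency,
scaled by run-level spray conditions. For the phosphopeptide (I1, mod) and
its unmodified counterpart (I0, base), each ratioed against a co-eluting
unmodified peptide of the same protein (I3 and I2 respectively):

```
X = (I1t/I3t) / (I1c/I3c)      Y = (I0t/I2t) / (I0c/I2c)      a/b = X/Y
```

Efficiencies cancel because they are sequence properties constant across
runs; spray fluctuations cancel because co-eluting peptides share them;
the normalizing peptides' concentrations are assumed proportional to total
protein (they carry no regulated modification). `a` and `b` are occupancy
**odds** (mod/base), exactly the quantities for which the X/Y identity
holds; `odds_to_fraction` converts to fractional occupancy when wanted.
Replicate handling computes the ratio per replicate pair and then averages
(mean ± SD) — ratios, not intensities, are the run-invariant quantities.
A phase series reports each phase's odds ratio against a baseline phase
(baseline ≡ 1).

**Precision at realistic noise.** With independent multiplicative
log-normal noise of CV `c` on each of the eight intensities entering one
`a/b` estimate, `sd(log a/b) = sqrt(8 · ln(1+c²))` per replicate pair
(≈ 0.28 at c = 0.10), or ≈ 0.16 after averaging three replicates — a
median absolute relative error near 11%. This is the maximum-likelihood
variance floor, not an estimator defect: no procedure recovers the odds
ratio to better than ~10% median error from three replicate pairs at 10%
per-intensity noise. Halving the error requires roughly four times the
replicates (or per-intensity noise below ~5%). Shared run-level scale
fluctuations, by contrast, cancel exactly at any magnitude.

SRM support: monoisotopic peptide m/z from a 20-residue mass table with
water 18.01056 Da, proton 1.00728 Da, +79.96633 Da per phosphosite on
S/T/Y; values are rounded (2 dp) only at report time. Computed fragment
masses can deviate from older instrument-software printouts — the y7 ion
of AALMESQGQQQEER computes to 874.40, while 874.45 has circulated in print.
Trace quantification is a trapezoidal integral of fragment-ion intensity
over the retention window; a single point integrates to 0.

## Synthetic data: what it emulates and what it does not

`synthio` generates (i) cohorts of 37-exon usage profiles around three
cluster means — elevated exons 2–11 with depleted 30–37 (worst survival),
flat (intermediate, the pattern of untransformed MCF10A cells), and the
mirror image (best survival) — with truncated-Gaussian usage noise
(default sd 1.5 percentage points), exponential event times at hazards
5e-4 / 2e-4 / 1e-4 events/day (ratio 5:2:1), and uniform censoring on
[90 days, 3 × median survival] applied with probability 0.7 (most patients
in registry cohorts are alive at last contact); (ii) Poisson spectral
counts at given per-condition rates with bait counts passed through;
(iii) intensity quartets from latent efficiencies, per-run spray factors
(CV 25%, cancels by design) and independent per-intensity noise;
(iv) reads placed uniformly inside exons at rates proportional to
expression × length.

A usage vector has one fewer degree of freedom than its length, so cluster
profiles are mapped onto the realizable manifold via the composition
`w_i ∝ u_i/(100+u_i)`; profiles built with `usage_profile` are exactly
realizable and reproduce themselves at zero noise.

Not emulated: sequencing errors and mappability, isoform structure beyond
one gene's exon set, batch effects, informative censoring, covariate-
dependent receptor status, MS peak shapes and interference. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated generative model, not robustness to every artifact of real
cohorts.

All generators consume a single integer seed with a documented draw order,
so outputs are byte-reproducible.

## Problem sizes in tests

The test suite runs the survival pipeline at 600 patients, the occupancy
recovery at 200 seeds × 3 replicates, and the null Wilcoxon calibration at
1000 exons of 60 + 60 patients — sizes at which every stochastic assertion
has comfortable margin while the whole suite completes in seconds.
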