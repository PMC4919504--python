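# scribpipe

Tools for the quantitative analyses that link SCRIB exon usage in breast
tumors to patient survival, and Scribble's S1448 phosphorylation to its
protein interactions:

* **Relative exon usage from RNA-seq** — per-exon RPKM (computed from read
  counts over BED-defined exons, or read from quantification tables), each
  exon normalized by the summed RPKM of all *other* exons of the gene in
  the same sample, times 100.
* **Survival-linked clustering** — k-means on usage profiles (initially 4
  clusters), greedy merging of clusters with statistically indistinguishable
  survival (pairwise log-rank), Kaplan–Meier curves and a k-sample log-rank
  test on k−1 degrees of freedom.
* **Receptor-status comparisons** — per-exon two-sided Wilcoxon rank-sum
  between ER- or Her2-status groups with step-down Holm control of the
  family-wise error rate.
* **IP-LC/MS spectral-count statistics** — for each prey protein in an
  affinity-purification screen, a chi-squared test of independence (Yates
  correction floored at zero) on the 2×2 table of prey vs **bait** counts
  across two IP conditions, and a G test against bait-derived expected
  counts. The bait row normalizes for how much material each pull-down
  recovered.
* **Label-free phosphosite occupancy** — with co-eluting unmodified
  peptides of the same protein as internal standards, ionization
  efficiencies and spray fluctuations cancel in condition-to-condition
  ratios: writing `X = (I1t/I3t)/(I1c/I3c)` for the phosphopeptide and
  `Y = (I0t/I2t)/(I0c/I2c)` for its unmodified counterpart, the occupancy
  odds `a = mod_t/base_t` and `b = mod_c/base_c` obey `a/b = X/Y` exactly.
  Plus SRM targeting support: monoisotopic peptide/precursor m/z and
  trapezoidal integration of fragment-ion traces.
* **Synthetic cohorts** (`scribpipe.synthio`) — seeded generators for every
  input above with the latent truth returned alongside, so recovery is
  testable end to end.

## Worked example

Test which prey proteins prefer the phospho-mimetic bait (S1448D) over the
phospho-deficient one (S1448A), from the published pull-down spectral
counts:

```python
import pandas as pd
from scribpipe import ipstats

counts = pd.DataFrame.from_dict(
    {"SCRIB": (588, 920, 855), "VIM": (151, 277, 264), "NUMA1": (34, 8, 54),
     "GIT1": (20, 72, 66), "ARHGEF7": (11, 49, 60)},
    orient="index", columns=["WT", "S1448A", "S1448D"])
table = ipstats.SpectralCountTable(counts=counts, bait="SCRIB")
for r in ipstats.prey_tests(table, ("S1448A", "S1448D")):
    print(f"{r.protein:8s} chi2={r.chi2:6.3f}  p={r.p_chi2:.3g}")
```

```
VIM      chi2= 0.043  p=0.836
NUMA1    chi2=34.776  p=3.7e-09
GIT1     chi2= 0.000  p=1
ARHGEF7  chi2= 1.679  p=0.195
```

NUMA1's 8 vs 54 spectra deviate strongly from the bait's 920:855 recovery
ratio — it associates with the phospho-mimetic bait — while GIT1 and VIM
track the bait so closely that the floored Yates correction leaves nothing
(χ² = 0 means |observed − expected| < 0.5 in every cell).

The occupancy calculus on a synthetic cell-cycle series (true occupancies
0.2 / 0.35 / 0.7, latent efficiencies unknown to the estimator, 10%
intensity noise, 3 replicates):

```python
from scribpipe import phospho, synthio
spec = synthio.PhosphoSpec(
    occupancy_per_phase={"G1-S": 0.2, "G2": 0.35, "M": 0.7},
    efficiencies=(1.0, 0.6, 1.4, 0.9), noise_cv=0.1, seed=42)
series = phospho.phase_series(synthio.gen_phospho_intensities(spec), baseline="G1-S")
for ph, (m, s) in series.items():
    print(f"{ph:5s} occupancy odds ratio = {m:.2f} +/- {s:.2f}")
```

```
G1-S  occupancy odds ratio = 1.00 +/- 0.00
G2    occupancy odds ratio = 2.00 +/- 0.65
M     occupancy odds ratio = 6.88 +/- 1.72
```

The noiseless odds ratios are 2.15 (G2) and 9.33 (M); at 10% intensity
noise a three-replicate estimate scatters around them (see
`docs/methods.md` for the variance analysis).

The same analyses are available from the shell:

```sh
scribpipe run-all --seed 1 --out-dir out/          # simulate + full pipeline
scribpipe ip-test --counts counts.tsv --bait SCRIB --cols S1448A,S1448D --out ip.tsv
scribpipe occupancy --intensities phospho.csv --baseline G1-S --out occ.tsv
```

Every output table is TSV with a `#` provenance header (command line, seed,
input checksums).

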