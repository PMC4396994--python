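# gminscan

Scan genomes for recent introgression after secondary contact using the
haplotype statistic **G_min**.

When two diverged populations come back into contact, introgressed
haplotypes are shared across the population boundary while their
frequencies may still differ wildly — so the classical fixation index
F_ST, which needs allele frequencies to equalize, often misses them. For
a window with `n1` and `n2` phased haploid sequences from the two
populations,

    G_min = min(d_XY) / d̄_XY ,

the ratio of the minimum to the mean between-population pairwise distance
(uncorrected Hamming / p-distance). A single recently introgressed
haplotype collapses `min(d_XY)` without moving `d̄_XY`, so windows with
anomalously low G_min relative to the chromosome-wide distribution
(Z < −1.645 by default) are candidates for recent gene flow. The package
is aimed at population geneticists with phased population resequencing
data from two populations (inbred lines, phased VCFs, or haploid
assemblies).

The package provides:

- `gminscan.hapstats` — G_min, Hudson's distance-based
  `F_ST = 1 − (d̄_XX + d̄_YY) / (2 d̄_XY)`, and pairwise-distance
  summaries, with missing-data handling by pairwise deletion;
- `gminscan.coalsim` — a two-population structured-coalescent simulator
  with recombination (Hudson-style ancestral recombination graph),
  infinite-sites mutation, and an instantaneous *migration pulse*: at time
  `τ_M` each lineage of the recipient population switches to the source
  population with probability λ, and windows whose ancestry contains such
  a move are flagged as true migrant windows;
- `gminscan.sweep_eval` — Z-score outlier classification, sensitivity
  φ = |M∩Q|/|M| and specificity ψ = |M∩Q|/|Q| against the simulated
  truth set, parameter-grid sweeps, and percent-variance partitioning of
  the statistics across model parameters;
- `gminscan.genome_scan` — non-overlapping window scans (50 kb default)
  over multi-FASTA or phased VCF input with a 25% callable-fraction
  filter, chromosome-wide Z-scores, and per-window neighbor-joining trees;
- `gminscan.cli_io` — the `gminscan` command line (`simulate`, `sweep`,
  `scan`, `trees`, `fixtures`) with manifests and deterministic seeding.

## Worked example

Generate a synthetic 225 kb chromosome (45 × 5 kb windows, 10 + 10
haplotypes) in which five windows were simulated under secondary contact
(`τ_M = 0.05 τ_D`, `λ = 0.01`) and are known to contain a migrant
genealogy, then scan it:

```bash
gminscan fixtures --out-dir fix --seed 7 --window-size 5000 --n-windows 45
gminscan scan --fasta fix/fixture.fasta --popmap fix/fixture.popmap.tsv \
    --window-size 5000 --chrom chrS --out scan.tsv
# scanned 45 windows; 4 G_min outliers
```

The outlier rows of `scan.tsv` (0-based half-open coordinates):

```
chrom  start    end     gmin      fst    z_gmin     z_fst
 chrS  35000  40000 0.070307 0.194985 -2.065260 -0.960889
 chrS  40000  45000 0.064135 0.368480 -2.100196  0.515681
 chrS 165000 170000 0.029913 0.161764 -2.293920 -1.243621
 chrS 200000 205000 0.137127 0.125814 -1.687005 -1.549583
```

All four called windows are genuinely injected migrant windows (the truth
sidecar `fix/fixture.truth.json` lists windows 7, 8, 21, 33, 40; window 21
is missed at this threshold). Note the second row: a window that F_ST
ranks as *more* differentiated than average (z_fst = +0.52) still carries
a near-identical cross-population haplotype pair (gmin ≈ 0.06) — exactly
the signal G_min is built to catch. The same scan works from a phased
VCF (`--vcf fix/fixture.vcf`), and `gminscan trees` writes
neighbor-joining Newick trees for visual confirmation that a putative
migrant haplotype nests inside the source-population clade.

Simulation-side, a single sweep cell can be reproduced in a few lines:

```python
from gminscan import DemographicParams
from gminscan.sweep_eval import evaluate_batch

params = DemographicParams(theta=100, rho=10, tau_d=0.5, tau_m=0.025,
                           lam=0.01, n1=10, n2=10)
res = evaluate_batch(params, 2000, seed=20011)
res.phi_gmin[-1.645], res.phi_fst[-1.645]   # (0.376, 0.005)
res.psi_gmin[-1.645], res.psi_fst[-1.645]   # (0.987, 0.071)
```

G_min's Z-score screen is both far more sensitive and far more specific
than the F_ST screen for this recent, low-rate pulse.

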