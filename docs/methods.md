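# Methods

## The statistic

For a genomic window containing `n1` haploid sequences from population 1
and `n2` from population 2, let `d_XY` be the uncorrected Hamming distance
(or p-distance under missing data) between one sequence from each
population. With

    dbar_XY = (1 / (n1 n2)) * sum_XY d_XY

the window statistic is

    G_min = min(d_XY) / dbar_XY .

Under divergence in strict isolation, the minimum and the mean
between-population coalescence times track one another, so `G_min` sits
near its expectation and tends to 1 as divergence deepens (for
`tau_D >> 4N` each population is likely down to a single ancestral lineage
at the split, making all between-population distances nearly exchangeable).
A recently introgressed haplotype creates one (or a few) anomalously
recent between-population coalescence, dragging `min(d_XY)` — but barely
`dbar_XY` — toward zero. The comparison statistic is the distance form of
Hudson's fixation index,

    F_ST = 1 - (dbar_XX + dbar_YY) / (2 dbar_XY),

where `dbar_XX`, `dbar_YY` average the unordered within-population pairs
(self-comparisons excluded; a single-member population contributes a zero
within term, and such windows are flagged). Windows with `dbar_XY = 0`
leave both statistics undefined (`nan`); undefined windows are excluded
from Z-standardization and from outlier sets — an undefined value cannot
be an outlier.

Finite-sample caveat: both statistics are per-window ratios. Averaged over
windows, `F_ST` under panmixia has a small negative Jensen bias (about
-0.01 at `n1 = n2 = 5`) even though every distance component is unbiased;
the test suite bounds it rather than asserting an exact zero mean.

## The demographic model and simulator

The secondary-contact model: an ancestral population of size `N` splits
into two size-`N` descendants at `tau_D` (units of `N` generations).
At `tau_M <= tau_D`, looking backward in time, each lineage in recipient
population 1 independently switches to source population 2 with
probability `lambda` — a binomial number of movers with expectation
`k*lambda` over the `k` residents, the backward image of an instantaneous
unidirectional burst of gene flow. A window is a *migrant window* when at
least one lineage carrying material ancestral to the sample moved at the
pulse; that per-window flag defines the truth set for
sensitivity/specificity. Two conventions are deliberate: only
ancestral-material lineages count (non-ancestral ARG lineages are never
tracked), and a pulse at exactly `tau_M = tau_D` is a no-op (the
populations merge at that instant), so flags require `tau_M < tau_D`.

The simulator is a Hudson-style ancestral recombination graph over a
continuous unit interval. Lineages carry sorted disjoint segments of
ancestral material, each segment labelled with the set of sample leaves it
subtends (a bitmask). Coalescence merges segment lists, OR-ing leaf sets;
a segment reaching the full sample has found its MRCA and retires.
Recombination hits a lineage at rate `rho` times its span (leftmost to
rightmost endpoint, trapped gaps included, per standard `ms` semantics)
and splits it at a uniform breakpoint. The run ends at the grand MRCA of
every position.

Time units: the public API takes `tau` in units of `N` generations
(divided by 4 internally into 4N-generation units). The fixed contract is
E[within-population pairwise coalescence time] = 2N generations, with
`k` lineages coalescing at total rate `k(k-1)` per internal unit.
Mutation is infinite-sites at rate `theta` per unit branch length per unit
sequence, realized as an exponential-race clock over the accumulated
(branch length x sequence length) intensity; within an inter-event
interval the lineage configuration is constant, so only the per-interval
count matters. Under this scaling E[pi] = theta for a panmictic pair and
E[S] = theta * H_{n-1} for a panmictic sample of n — the two closed forms
used as anchors (theta = 10, n = 10 gives ~28.3 expected segregating
sites; theta = 150 gives ~424.3). Sites are emitted as biallelic 0/1
columns (ancestral state 0) in positional order; polarity is irrelevant to
Hamming distances.

Validation is three-pronged: the closed-form anchors above; an independent
lineage-counting oracle for the pulse (without recombination the number of
population-1 lineages at `tau_M` is a pure-death Kingman chain, giving
P(migrant window) = E[1 - (1-lambda)^K]); and distributional agreement
(two-sample KS on S and pi) with msprime configured as the identical
isolation model. msprime is used only as an oracle, never as the engine.

Reproducibility: one root seed; each window uses a counter-derived
substream (`default_rng([seed, window_index])`), so batches are
bit-deterministic and order-independent. A 10^7-event ceiling per window
guards runaway ARGs and raises rather than truncating.

## Outlier classification and sweeps

Within a batch (one parameter cell, or one chromosome in a scan), a
statistic is standardized by the batch's own mean and sample SD (ddof = 1;
the convention is declared since only "standardized deviation from the
genome-wide mean" is prescribed). Windows below a threshold Z form the
called set `Q`; thresholds are the normal lower-tail quantiles -1.645,
-2.326, -3.090. Sensitivity `phi = |M & Q| / |M|` and specificity
`psi = |M & Q| / |Q|`, undefined on empty denominators. This is an
operating-characteristic screen, not a formal test: no null distribution
is asserted and no multiple-testing correction applied. Standardization is
per cell (each simulated parameter combination is its own "genome");
pooling across cells would mix scales.

Variance partitioning regresses a cell-level response (per-cell mean or SD
of a statistic) on centered *numeric* covariates for `tau_D`, `theta`,
`rho`, `n2` plus the products `tau_D x n2` and `tau_D x rho` (all pairs
available behind a flag). On a balanced full factorial these columns are
mutually orthogonal — verified, not assumed — so percent-of-total sums of
squares are order-invariant and sum to 100 with the residual. The numeric
(rather than categorical) treatment is deliberate: a categorical model
with all interactions would be saturated on a one-observation-per-cell
table, leaving zero residual, whereas the observed residual of such
analyses is large precisely because the saturating response curve in
`tau_D` is nonlinear; that stochastic-plus-nonlinear remainder is what the
residual ("coalescent processes") represents.

## Genome scans

Chromosomes are tiled exactly into non-overlapping windows (default
50 kb, 0-based half-open; the short terminal window is kept and flagged
rather than silently dropped, since telomeric regions are where novel
signal tends to sit). Statistics use p-distances with pairwise deletion so
coverage differences cannot masquerade as low `min(d_XY)`; count mode is
reserved for complete-data simulation output (the two agree exactly on
complete data). A site is callable for a sequence when its state is an
unambiguous base; a window is dropped when its mean callable fraction
falls below 0.25 — a sequence-level proxy for read-level quality filters,
which are out of scope (the scanner consumes already-called phased
haplotypes). Z-scores are chromosome-wide over analyzable windows;
outliers default to Z < -1.645.

VCF input materializes absent sites as monomorphic callable reference
columns and missing genotypes as missing states at that site only;
diploid samples must be phased and contribute two haplotype rows,
haploid/inbred samples one.

Neighbor joining on the window p-distance matrix is implemented
in-package so its determinism is fully specified: Q-criterion ties join
the lexicographically smallest pair, and a negative branch length is
clamped to zero with the deficit moved to the sister branch (the pair
distance is preserved). It is consistent — additive matrices reproduce
their generating tree — and is cross-checked against scikit-bio's NJ in
the tests.

## Synthetic fixtures

The fixture generator writes a scan-ready chromosome (FASTA, VCF,
population map, truth sidecar) of 45 x 5 kb windows: isolation windows at
`theta = 50`, `rho = 5`, `tau_D = 1.0`, with five slots simulated under
secondary contact (`tau_M = 0.05 tau_D`, `lambda = 0.01`) and
rejection-sampled to contain a true migrant genealogy. Mutations are
placed at integer offsets within each window (colliding sites bumped to
the next free position; a saturated window drops the collision). These
fixtures emulate the ingredients the scan depends on — phased haplotypes,
known migrant windows, missingness plumbing — but not read-level error,
alignment artifacts, variable window callability, or linkage between
adjacent windows; passing tests therefore demonstrate the statistical
machinery, not robustness to upstream data-processing noise.

## Problem sizes used by the test suite

Simulation-heavy checks run at sizes chosen to keep the full suite
single-CPU-friendly while leaving Monte-Carlo noise far inside the
asserted tolerances: Watterson anchors at 10^4 windows; the isolation
variance sweep on a coarsened grid (20 `tau_D` values 0.4..8, `theta` in
{10, 50, 150}, `rho` in {0, 10, 150}, `n2` in {1, 10}) at 120 windows per
cell — a 60-windows-per-cell pilot already reproduces the `tau_D` percent
share within ~1 point of the full-scale values; expectation-curve
properties at 2 x 10^3 windows per point; the contact-model comparison at
2 x 10^3 windows per cell; engine cross-validation at 5 x 10^3 replicates
per side. All seeds are fixed in the tests.

## Known limitations

- No continuous migration, population growth, gene conversion, selection,
  or more than two populations; descendant and ancestral sizes are equal.
- The closed-form expectation of `G_min` is not provided; use the
  Monte-Carlo expectation (`expected_gmin_mc`).
- The Z-score screen loses power when gene flow is massive
  (`lambda >~ 0.05` leaves few "background" windows to standardize
  against) or older than about half the divergence time; in those regimes
  the outlier set can be empty.
- Per-window `F_ST` with `n2 = 1` is reported with a zero within-source
  term and flagged; it is not a meaningful allele-frequency measure there.
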