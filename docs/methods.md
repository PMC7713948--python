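# Methods

This note documents the models behind `condorabc`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic data can and
cannot establish.

## Data model

The observational unit is an aligned mtDNA sequence with a collection year,
decimal-degree coordinates, and a regional label.  Years are binned into
`historical` / `contemporary` around a breakpoint year, default 1950: the
sampling campaigns this design mirrors span 1884–1946 and 1961–2013, and
1950 is the midpoint of the gap; the breakpoint is an argument everywhere it
matters.  The default alignment is two concatenated partitions, a 145 bp
Control-region fragment and a 165 bp 12S fragment (310 bp haplotypes),
expressed as 0-based half-open column spans.  Sequences containing `N` or
gaps are excluded (with a log message) from haplotype collapsing and all
pairwise statistics rather than handled by pairwise deletion — partial
haplotypes carry little information at these lengths and excluding them
keeps every estimator's *n* consistent.  Regions are taken from metadata,
never inferred from coordinates.

## Diversity statistics

Haplotype diversity uses the unbiased estimator H = n(1 − Σp²)/(n − 1) with
Nei's (1987, eq. 8.12) sampling variance.  K is the mean Hamming distance
over all unordered pairs; its reported variance is Tajima's total
(stochastic + sampling, no recombination) variance
V(K) = (n+1)K/(3(n−1)) + 2(n²+n+3)K²/(9n(n−1)), which is defined for every
n ≥ 2.  Which of the several published K-variance formulas a given desktop
program reports is rarely stated; the identity π = K/L is exact here by
construction and is the quantity the tests pin down.  Tajima's D follows the
1989 constants a₁…e₂ and is undefined (NaN) for S = 0 or n < 4.  Reported
tables round π to 4 decimals and H, K to 3.

## Differentiation and spatial structure

φST comes from a one-level AMOVA variance partition treating the raw count
of pairwise nucleotide differences as the squared inter-individual distance
(the convention of the standard desktop implementation).  Negative estimates
are reported as computed.  Permutation p-values permute individuals between
groups and use the (b+1)/(B+1) estimator; for tiny designs an exact mode
enumerates all label assignments.  The hierarchical (two-level) AMOVA
partitions variance among groups / among populations within groups / within
populations with the unequal-size n-coefficients, and uses the three
standard permutation schemes: individuals globally for F_ST, individuals
among populations within groups for F_SC, and whole populations among
groups for F_CT.  Populations with a single sample are dropped with a
warning.  In the condor design the populations are the four period ×
(north vs central-south) cells — the df bookkeeping (1, 2, 69 for N = 73)
identifies P = 4, not 6, so the two southern regions are merged at this
level.

The exact test of differentiation is the Raymond & Rousset Markov chain
over haplotype-by-group contingency tables with fixed margins: a Metropolis
walk on ±1 "swap" proposals whose stationary law is the multivariate
hypergeometric, with the p-value the visited-state probability mass of
tables no more probable than the observed one and a batch-means standard
error.  Defaults are 10⁶ steps after 5 × 10⁵ dememorization steps.

The "maximum composite likelihood" genetic distance is implemented as the
TN93 distance with base frequencies pooled over all sequences (the
composite convention); when a TN93 logarithm is undefined (saturation) the
pair falls back to the p-distance and is flagged.  Mantel tests correlate
upper triangles of the genetic and log₁₀ great-circle (haversine) distance
matrices at the individual level, with a 1 km floor before the logarithm so
identical sampling locations stay finite.

## Haplotype networks

The network is a minimum spanning network on (optionally position-weighted)
Hamming distances: edges are processed in increasing weight classes and
every edge in a class that joins two components still separate at the start
of the class is kept, so co-minimal alternative connections survive and the
result is independent of input order.  Mutation-rate heterogeneity between
partitions is exposed as a single scalar weight on Control-region columns
(default 1.0, i.e. off; 0.5 reproduces the "downweight the fast partition"
consistency check).

Each link's statistical-parsimony probability is the posterior probability
that a j-step connection involved exactly j substitutions.  The model:
substitutions hit one of L equally mutable sites uniformly and change the
base to one of three alternatives, so the observed difference count performs
a random walk (up with probability (L−d)/L, down with d/(3L)); the number of
substitutions gets a Poisson prior whose mean is the Jukes–Cantor-corrected
expected substitution count for the observed divergence.  This reproduces
the familiar behaviour of the published estimator — ≈ 0.998 for one step on
310 bp, strictly decreasing in j, increasing in L — and is validated in the
tests against an independently coded matrix-power recursion.

The temporal layering reports per-period haplotype presence and a loss
statistic: the percentage of all distinct haplotypes present in the earliest
period but absent from the latest (1 of 6 → 17%).

## Coalescent simulator

The simulator is a single-population heterochronous (serial-sample)
coalescent.  mtDNA is matrilineally haploid, so Nef(t) is used directly —
pairwise coalescence rate k(k−1)/(2 Nef(t)) per generation, no diploid
factor.  Nef(t) is piecewise constant backward in time; waiting times are
exponential within an epoch and re-drawn at epoch boundaries (valid by
memorylessness), and sampled lineages enter at their pulse ages.  Times are
years at the interface, generations internally; the generation time default
is 7 years (condors first breed at 6–8 years).

The four scenarios, backward in time:

1. constant Nef1;
2. Nef1 on [0, t1), Nef2 > Nef1 beyond (recent bottleneck at t1);
3. Nef1 on [0, t2), Nef3 < Nef1 beyond (ancient bottleneck);
4. Nef1 / Nef2 / Nef4 / Nef2 on [0, t1) / [t1, te) / [te, t2) / [t2, ∞) —
   ancestral large size, ancient bottleneck at t2, expansion back at te,
   recent crash at t1, with 0 < t1 < te < t2 and Nef4 < Nef2.

Scenario 4's epoch order is the reading under which all three times and all
three sizes are identifiable from the reported posteriors; the alternative
reading (ancestral epoch at the small size) is available behind
`scenario4_oldest_nef2=False`.

Mutations follow HKY with closed-form transition probability matrices
(exact, verified against matrix exponentials to machine precision), applied
per branch with the root state drawn from the stationary frequencies.  The
mitochondrion is fully linked: one genealogy for both partitions, each with
a rate multiplier (mean 1 across columns; default Control region 1.5× the
alignment average, 12S correspondingly slower).  Defaults
µ = 10⁻⁶ /site/generation (≈ 1.4 × 10⁻⁷ /site/year at 7-year generations,
the order measured for avian Control region), κ = 10, base frequencies
(0.30, 0.30, 0.15, 0.25): these stand in for unavailable fitted values and
are configurable.  Finite-site multiple hits make observed differences fall
slightly below infinite-sites expectations (≈ 1% at the default rates); the
analytic tests use rates where this bias is far inside Monte-Carlo
tolerance.

## ABC engine

Priors are independent uniforms with the scenario conditioning (Nef2 > Nef1,
Nef3 < Nef1, Nef4 < Nef2, t1 < te < t2) enforced by rejection resampling;
bounds whose conditioning acceptance rate falls below 10⁻⁴ raise.  Regional
presets for Nef1: north (50–1000), central-south (500–5000), California
(10–500); t1 ∈ [7, 350] years, t2 ∈ [1000, 500000], te up to 50,000.  The
remaining size bounds (Nef2 ∈ [500, 5 × 10⁴], Nef3 ∈ [2, 1000],
Nef4 ∈ [2, 5 × 10⁴]) are package defaults chosen to bracket the magnitudes
a large soaring bird's mtDNA could plausibly support, and are configurable.

The summary-statistic vector (fixed order, 18 entries) holds, per temporal
sample: haplotype count, segregating sites, mean and variance of pairwise
differences, haplotype diversity, Tajima's D plus a defined-indicator
(undefined D is encoded 0 with indicator 0 so vectors stay complete); and
between samples: Hudson's F_ST (1 − Hw/Hb), mean between-sample pairwise
differences, and private segregating sites per sample.  This mirrors the
within/between mtDNA summaries of standard ABC software, which never prints
its exact list — the choice is a documented package decision.

Rejection standardizes statistics by the reference table's median absolute
deviation (standard-deviation fallback, constants dropped with a warning)
and keeps the ceil(tolerance · N) nearest rows in Euclidean distance;
tolerance defaults to 1%.  Scenario choice pools all tables, keeps the
nearest fraction, and fits a multinomial logistic regression of the scenario
label on standardized deviations, evaluated at deviation zero; the "direct"
method is acceptance fractions, and degenerate fits fall back to it.  CIs
for the posterior probabilities are a nonparametric bootstrap (default 500
resamples) over accepted simulations — the reference software's CI
construction is not public.  A selection whose best-scenario CI does not
overlap any other is flagged "decisive".

Parameter estimation is local-linear adjustment: parameters are logit-
transformed to their prior bounds, regressed on standardized deviations with
Epanechnikov weights on acceptance distance, shifted to deviation zero, and
back-transformed, yielding weighted posterior draws summarized by the 2.5 /
25 / 50 / 75 / 97.5% weighted quantiles (the interval type behind published
"ranges" is left open).  A small ridge (10⁻⁸) keeps collinear designs
solvable, and a warning fires when fewer than five accepted draws per
covariate support the regression — at 1% tolerance the default 2 × 10⁴-row
tables give 200 accepted draws for the 18 + 1 covariates, comfortably above
that line.

Validation utilities: prior-predictive PCA (observed projected into the
simulated statistic cloud; outlier score = fraction of simulations farther
from the centroid), type I/II error rates over pseudo-observed datasets,
coverage experiments, and per-statistic two-sided posterior-predictive
p-values.

## Problem sizes and reproducibility

The analysis-scale default is 2 × 10⁴ simulations per scenario with 1%
acceptance and 100 pods per validation experiment — the package's desk-scale
operating point (a production run of the original design used 5 × 10⁶; every
count is an argument).  At this scale the bundled experiments give ≈ 100%
selection of a strong recent bottleneck over a constant-size history and
≈ 95% empirical coverage of nominal 95% credible intervals for Nef1.  All
stochastic components are pure functions of (inputs, seed); reference
tables, pods, chains, and permutation tests all take explicit seeds.

## What the synthetic data does and does not show

The fixture generator reproduces the *structure* of the condor dataset —
sample sizes (35 + 38), regional sizes (24/28/21), six haplotypes with
strong north vs central-south sorting, one historical-only lineage two
Control-region transitions away from its neighbour — with sequences built by
explicit edits to a random reference, so the expected network topology,
haplotype-loss value, and AMOVA dimensions are known a priori.  Its
diversity lands at the right order (π ≈ 3 × 10⁻³) by design, not by fit: no
test asserts equality with any published diversity value, because the real
historical sequences are not redistributable.  Passing tests therefore
establish that the estimators, network logic, simulator, and ABC machinery
are correct and internally calibrated — not that any particular biological
conclusion about condors is reproduced from real data.

## Known limitations

- Single panmictic deme per analysis: no migration, selection,
  recombination, or nuclear loci.
- The exact-test chain reports batch-means standard errors, which are
  approximate for strongly autocorrelated chains; increase steps when the
  standard error matters.
- The K-variance and link-probability formulas are reasonable, documented
  interpretations of under-specified desktop conventions; both are oracle-
  tested against independent implementations rather than against those
  programs' binaries.
- Logistic model-choice probabilities use ridge-free sklearn defaults with
  moderate regularization (C = 10); with nearly separable scenario clouds
  the point probabilities saturate at 0/1 faster than an unregularized fit
  would.
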