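# Methods

## Model overview

`polysweep` treats autopolyploidy as a change in genome copy number under
polysomic inheritance: an individual carries k homologous copies that pair
at random, with no preferential pairing, no double reduction, no selfing,
and random mating. A population of N individuals therefore holds Nk
chromosomes, which sets both the drift/coalescent timescale (pairwise
coalescence at 1/(Nk) per generation) and the population-scaled mutation
and recombination rates θ = 2Nkμ and ρ = 2Nkr. Everything else — the
per-site, per-generation rates μ and r — is ploidy-independent.

### Selection and dominance

The selection coefficient s is the fitness difference between the two
homozygotes. A genotype with derived dosage d (0 ≤ d ≤ k) has fitness
1 + h(d)·s with

    h(d) = (d/k)^τ,   τ = 10^(−H),   −0.5 < H < 0.5.

H = 0 gives τ = 1 and the additive ladder h(d) = d/k; H < 0 gives τ > 1
(convex, recessive-like); H > 0 gives 0 < τ < 1 (concave, dominant-like).
This specific exponential is the simplest mapping satisfying those three
constraints while remaining continuous through H = 0; the mapping is
exposed as a hook (`tau_map`) for users who prefer another
parameterization. h(0) = 0 and h(k) = 1 are pinned exactly so the
homozygote contrast is exactly s.

### Trajectories

The deterministic update weights each binomial(k, p) genotype by its
fitness and by the fraction d/k of derived alleles it transmits,
normalised by mean fitness. The stochastic generation then draws the new
derived count as Binomial(Nk, p̂) — the exact distribution of the sum of N
independent binomial(k, p̂) genotype dosages — so every frequency is a
multiple of 1/(kN). Trajectories start at 1/(kN) and are conditioned on
fixation by rejection: lost runs are discarded and counted (the count
yields the fixation-probability estimate, which matches the
branching-process prediction 2·h(1)·s ≈ 2s/k for additive mutations).
The default rejection budget is 10⁶ attempts; strongly recessive,
high-ploidy, large-N combinations can exhaust it, which surfaces as an
explicit conditioning error rather than a silent hang. No generation cap
is imposed beyond absorption. Stochastic trajectories are stored forward
in time; the coalescent consumer reverses them itself.

## Trajectory-conditioned coalescent

The ancestry simulator is a Hudson-style ancestral-recombination-graph
walk over three phases, recorded directly into tskit node/edge tables:

1. **Post-fixation** (duration `tau_post`, default 0): both populations
   evolve neutrally; continuous-time exponential waiting times between
   events.
2. **Sweep phase** (duration = trajectory length): run discretely,
   generation by generation against the reversed trajectory, because the
   trajectory is a per-generation object. With parent-generation derived
   frequency x, pairs in the selected population coalesce at 1/(x·Nk)
   within the derived class and 1/((1−x)·Nk) within the ancestral class.
   Each lineage recombines at rate r per bp over its recombinable span —
   the hull of its ancestral material extended to the selected site —
   and a breakpoint separating material from the selected site redraws
   the allelic class of the separated piece (derived with probability x).
   Lineage counts in a class are capped at the ceiling of the number of
   parental chromosomes in that class; excess lineages are forcibly
   coalesced. At the trajectory origin the remaining derived lineages are
   forcibly merged (the mutation arose in a single copy) and the survivor
   joins the ancestral class; the two populations then merge, matching
   the design in which the mutation arises at the population split.
3. **Ancestral phase**: a single population run in continuous time to the
   grand MRCA of every chromosomal interval.

Within a sweep generation, recombination events are drawn first (Poisson
with start-of-generation rates), then coalescences, with small strictly
increasing time offsets so node times are valid. Multiple coalescences
per generation are allowed (the per-pair probability is re-evaluated
after each merger).

Mutations are dropped afterwards under the infinite-sites model: per
marginal tree of span ℓ and total branch length B, Poisson(μ·ℓ·B)
mutations land on branches proportionally to length and uniformly in
position. Positions are reported at the 10⁻⁶-of-locus resolution of the
ms dialect and kept strictly increasing. Every emitted column is
segregating by construction.

The neutral limit of this machinery (a pseudo-trajectory pinned near
x = 1 for longer than the expected TMRCA) reproduces neutral π, and the
neutral path is cross-validated against msprime in the test suite (mean
π, mean S, pairwise TMRCA). The sweep path is cross-validated for
diploids against msprime's `SweepGenicSelection` (mean central diversity
agrees within Monte-Carlo error).

### Decomposing trajectory vs diversity effects

The pipeline can cross the trajectory ploidy `k_traj` (which frequency
path the sweep follows) with the genomic ploidy `k_genomic` (copy number
used for coalescent and rate scaling). Note a consequence of the physical
scaling used here: because coalescence runs at 1/(Nk_genomic) per
generation while the sweep lasts a fixed number of generations, a sweep of
duration T floors relative diversity near the selected site at roughly
T/(N·k_genomic) (lineages that never escape still accumulate diversity
over the sweep itself). The hybrid cell (tetraploid trajectory, diploid
rates) therefore recovers *fastest* relative to its own baseline, rather
than sitting between the two matched cells; toolchains that hold the
coalescent timescale fixed and carry ploidy entirely in θ and ρ (the
classic ms-style construction) instead place the hybrid between the
matched cells, because there the "diversity" axis also scales sweep-phase
recombination per unit coalescent time. This difference is inherent to
the scaling convention, not a numerical artifact.

## Statistics

* **Windows**: width = L/(N/50), step = width/2, half-open, tiling
  [0, L); the last window may be truncated. Every interior site falls in
  exactly two windows.
* **π**: per-window sum of 2c(m−c)/(m(m−1)) over contained sites, divided
  by the window span (per-bp units).
* **Tajima's D**: the standard normalisation with the haplotype count
  m = n·k as sample size — ploidy enters only through the number of
  sampled sequences. Reported ×(−1) so sweeps score positive; windows
  with no segregating sites are missing (never zero-filled).
* **F_ST**: Hudson's 1 − π_within/π_between per window, with the plug-in
  heterozygosity 2p̂(1−p̂) within populations so that identical samples
  give exactly 0 and fixed differences exactly 1; windows with zero
  between-population diversity are missing. Scores are mean-standardized
  (mean 0, sd 1, ddof = 1) across windows within each replicate.
* **EHH/iHS/XP-EHH**: EHH is the probability that two random carriers of
  the focal allele are identical over the interval from the focal site
  outward; iHH is the trapezoidal integral of EHH versus bp distance,
  summed over both directions and truncated at the first point below
  0.05 (or at the locus edge — the locus is fully simulated, so there
  are no gaps to penalise). iHS = ln(iHH_ancestral/iHH_derived) at sites
  with minor-allele frequency ≥ 0.05, standardized within 50 equal-width
  derived-frequency bins pooled across a replicate set (per-replicate
  site counts are too small to standardize alone). XP-EHH uses the
  unconditioned site-EHH per population, integrated to a common
  truncation point (where the combined-sample EHH drops below 0.05, so
  the log-ratio is not biased by asymmetric truncation) and standardized
  within the replicate.

## Peak summaries

Profiles are smoothed by LOESS — locally weighted quadratic regression
with tricube weights over the max(5, ⌈span·n⌉) nearest points, span 0.1,
no robustness iterations — implemented in-package because the available
library smoother is degree-1 only. The baseline is the mean smoothed
per-window diversity of the non-selected population of the same replicate
(median available as an option). Magnitude = baseline − profile minimum;
Breadth = distance between the first positions left and right of the
selected site where the smoothed profile recovers to baseline/2
(half-depth recovery available as an option), divided by 100 kb;
Area = Magnitude·Breadth/2 exactly. A profile that never dips below
baseline/2 scores breadth 0 with `recovered=False`; a trough still below
the level at the locus edge is censored at the edge and flagged
`censored=True` — scoring such replicates 0 would invert the
diploid/tetraploid breadth comparison whenever wide diploid troughs
overflow the finite locus. The ±100 kb area under a metric profile is a
trapezoidal integral divided by 10⁵. Maxima of signed metrics (−D,
standardized F_ST, iHS, XP-EHH) are maxima of the signed value, matching
the sweep-positive orientation. The coefficient of variation of
per-replicate maxima uses sd/mean with a percentile interval from 1000
bootstrap draws of 200 replicates.

## Pipeline, seeding, defaults

Each grid cell × replicate chains trajectory → coalescent → statistics →
peaks and appends to three tidy TSVs (trajectory summaries, window/site
statistics, peak summaries), every row carrying its full parameter set
and seed. Replicate seeds are master_seed + crc32("cell:rep") (mod 2³¹),
so any replicate is independently re-runnable and a fixed master seed
reproduces byte-identical tables. Failed replicates (conditioning
failures are expected for strongly recessive high-ploidy cells) are
logged and skipped; a fully failed cell aborts. The headline grid spans
k ∈ {2,4,8}, s ∈ {0.001, 0.01, 0.1}, H ∈ {−0.4, 0, 0.4},
N ∈ {1000, 10000} with n = 10 individuals sampled per population;
μ = r = 10⁻⁸ per bp per generation on a 1 Mb locus with the selected
site at the midpoint. Sampling is by individuals (n·k haplotypes) by
default; by-allele sampling (fixed haplotype total across ploidies) is
available for equal-allele comparisons.

## Problem sizes and what the tests show

The test suite and the acceptance script run at desk scale chosen to keep
Monte-Carlo error well below the effects under test: 200 conditioned
trajectories per ploidy for the fixation-time ratio, 2×10⁵ origination
attempts per ploidy for fixation probabilities, 500 neutral replicates
per ploidy for the θ calibration, 2000 replicates for pairwise TMRCA,
and 50 sweep replicates per cell at N = 1000, s = 0.1 for the signal
orderings. Synthetic data emulates the idealised design only: constant
population size, a single hard sweep from a new mutation, no migration,
no gene conversion, no crossover interference, free recombination among
homologues (autopolyploids), perfect phasing, infinite sites. Passing
tests therefore demonstrate internal correctness of the model and
statistics, not robustness to demography, genotyping error or unphased
data. Two quantitative caveats from the study conditions themselves: at
N = 1000 and s = 0.1 the central-window (50 kb) relative dip is
borderline against a 0.25×baseline cutoff (the true fraction of
replicates passing it is ≈0.85–0.89 for both ploidies — an independent
reference simulator gives the same), and the decomposition cell ordering
depends on the scaling convention as described above.
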