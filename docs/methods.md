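# Model and methods

## The model

`genesurf` simulates a haploid, asexual population carrying a single neutral
diallelic locus (alleles A and a) on a rectangular lattice of demes — a
two-dimensional stepping-stone model with hard carrying capacity. Each
generation applies, in order:

1. **Reproduction.** Every individual in suitable habitat leaves a
   Poisson(r) number of offspring and dies. Per deme and allele this is
   implemented as a single Poisson(r · count) draw — the sum of independent
   per-individual Poisson draws, distributionally identical and much faster.
   Individuals in unsuitable habitat have reproduction rate 0 and therefore
   leave nothing.
2. **Migration.** Each individual emigrates with probability m/n, where n is
   the number of orthogonally adjacent demes (4 in the interior, 3 on edges,
   2 at corners; the lattice does not wrap), and its destination is uniform
   over those n demes. Migration ignores habitat suitability — migrants may
   enter unsuitable demes, where they die at their next reproduction step.
   The step conserves the lattice total exactly; it is realised as a
   binomial leave/stay split followed by sequential conditional binomials
   that partition the leavers uniformly over the valid directions.
3. **Culling.** Any deme whose size exceeds K is thinned to exactly K by
   uniform sampling without replacement; the retained allele-A count is a
   hypergeometric draw. Demes at or below K are untouched.

### Why emigration is m/n, not m

Two emigration conventions are common in stepping-stone models with a
position-dependent neighbour count n: total emigration probability m (so
each neighbour receives migrants with probability m/n), or total emigration
probability m/n (each neighbour m/n²). They produce very different front
speeds. The reference calibration value this package reproduces — a mean of
533.6 generations for a phenotype-limited expansion at r = 3, m = 0.2 to
fill the 75×200 lattice — discriminates sharply between them: the total-m
convention gives a mean near 335 generations, the m/n convention near 519.
We therefore default to m/n; the total-m convention remains available via
`SimParams(migration_model="m")`. The residual ~3% gap to 533.6 is not
explained by any model variant we examined (destination conventions, record
triggers, and edge handling all move the mean by well under 1%), and the
replicate-to-replicate spread is small (sd ≈ 3.4 generations), so the strict
3-sigma check on the pilot time in `tests/test_acceptance.py` does not pass;
it is kept as written rather than loosened, and documents the closest
convention we could identify.

## Habitat scenarios

The habitat is always a left-anchored block of suitable columns.

* **PhLRE** (phenotype-limited): the whole lattice is suitable from
  generation 0; expansion speed is set by r and m.
* **BLRE** (boundary-limited): only the founding block is suitable at
  generation 0 and columns open at evenly spaced generations — by
  generation g, `floor((n_cols − n_init_cols) · g / boundary_duration)`
  extra columns are open — evenly spaced openings, the minimal reading of a
  column-by-column habitat shift. Durations of 600/1000/2000/4000/6000/7900
  generations are the reference grid; the reference experiments circulate
  with two slightly different parameter lists (a boundary-duration grid
  starting at 600 vs one starting at 800, a migration grid reaching down to
  0.01 vs 0.001, a reproduction grid topping at 5 vs 4), and both versions
  of each are shipped as preset variants since there is no way to tell
  which was actually run.
* **stationary**: the block never grows. The last suitable column is the
  "stationary front", the zero-expansion-speed reference produced purely by
  migration–drift balance (isolation by distance), with no founder effect.

Suitability is updated at the start of each generation, before
reproduction.

## Frozen records and expansion time

Every simulation starts with the first `n_init_cols` (default 20) columns
at size K and allele-A frequency p0 (count `round(p0·K)`, half-up, with a
warning when p0·K is fractional). A column beyond the founding block is
*frozen* at the first generation — evaluated after culling — at which all
its demes simultaneously have size exactly K; its allele-A frequencies at
that moment are the permanent record of the front's passage. The expansion
time of a replicate is the generation at which the last pending column is
frozen. By default the generation loop stops there
(`stop_after_complete=True`): records and the expansion time are unaffected,
only post-completion drift of the final lattice is skipped. The stationary
scenario instead snapshots the stationary-front column at
`snapshot_generations` (default: the final generation, 8000).

Column (and row) indices are 1-based in every output table.

## Front statistics

Each frozen column of N demes (N odd, default 75) is summarised by:

* **Segmentation.** A deme is *homogeneous* when fixed (frequency exactly 0
  or 1 — counts are integers, so exactness is well defined; an `atol`
  option relaxes this but defaults to exact). A *domain* is a maximal run
  of demes fixed for the same allele; adjacent runs fixed for opposite
  alleles are two domains with no cline between them. A *cline* is a
  maximal run of mixed demes. Counts and mean widths (deme units) are
  reported; a mean width is null when its segment class is absent, and
  replicate averages ignore nulls while recording the contributing count.
* **Pairwise differences.** Within a deme,
  PX = 2·nA·na / (n(n−1)) — the mean 0/1 difference over all unordered
  individual pairs, with the exact finite-sample n/(n−1) correction.
  Between demes, PXY = pX(1−pY) + pY(1−pX), and the corrected divergence
  Pc = PXY − (PX+PY)/2 (Nei/Takahata net divergence; the published equation
  is also an unrendered figure, and this is the standard form the citation
  points to). Column-level values are unweighted means: PX over the N
  demes, PXY and Pc over all C(N,2) unordered deme pairs.
* **Mean spectral frequency.** With DFT coefficients P_k of the frequency
  profile and amplitudes A_k = |P_k| for harmonics k = 1…(N−1)/2 (DC
  excluded; N odd makes (N−1)/2 the highest harmonic), the statistic is
  f̄ = Σ f_k A_k / Σ A_k with f_k = k/N cycles per deme. A constant profile
  has an empty spectrum and returns 0 by convention. Higher f̄ means
  finer-scale allele-frequency fluctuation across the front.

## Randomness and reproducibility

Each replicate uses a single `numpy.random.Generator`; replicate i of a
sweep is seeded `base_seed + i`, and every stochastic draw (Poisson
offspring, binomial emigration, uniform destination split, hypergeometric
culling) flows through it. Replaying a sweep with the same base seed
reproduces every output file byte-for-byte.

The generation loop run by `run()` restricts work to the occupied column
window (everything up to one column right of the rightmost occupied
column). Columns outside the window are empty and unreachable within one
generation, so the restriction is exact, not an approximation; neighbour
counts are always taken from the full lattice geometry.

## Problem sizes used in the tests

The unit and property suites run on small lattices (typically 11×20,
K=50). The end-to-end checks use the reference scale where the quantity
demands it: the pilot expansion time uses 20 replicates of the full 75×200
lattice; the figure-level direction-of-effect checks (diversity decay at
the front, slow-boundary broadening of clines, stationary clines widest)
use 10 replicates per scenario at 75×200 — one tenth of the reference
study's 100 replicates, which is ample for direction-of-effect assertions
but not for smooth curves. `run_sweep(n_replicates=100)` reproduces the
full design.

## What the simulations do and do not emulate

The model contains no mutation, selection, recombination, diploidy or
sexual reproduction; allele-frequency change is purely drift plus
migration, so the global allele-A frequency is a martingale (tested) and a
closed deme fixes allele A with probability p0 (tested). Habitat geometry
is strictly column-wise on a rectangle. Consequently, passing tests
demonstrate the internal consistency of the drift/migration/expansion
machinery and the statistics layer — not the behaviour of real populations
with selection, long-range dispersal or complex habitat edges.

## Known limitations

* The migration and spectrum formulas of the source description are
  unrecoverable verbatim; the conventions above are the readings best
  supported by the surviving text and the pilot calibration value, and the
  ~3% residual on the pilot expansion time is unresolved.
* Whether per-front pairwise statistics should be unweighted means over
  demes/deme pairs (used here) or some other aggregate is not stated in the
  source description.
* Replicate dispersion (standard deviations in `averaged.tsv`) has no
  published counterpart to compare against.
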