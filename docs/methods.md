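# Methods

This note records the statistical model behind each procedure, the defaults
and why they were chosen, what the synthetic-study generator does and does
not emulate, and the numerical conventions a re-implementation would need to
match the package's output.

## Coordinate conventions

All coordinates are 0-based half-open (BED). Overlap requires at least one
shared base, so `[0,100)` and `[100,200)` do not overlap — but they do merge
at `gap=0`, because merging joins intervals whose gap is ≤ the parameter and
abutment has gap 0 (the behaviour of the standard merge tools this package
interoperates with). Distances between intervals on different chromosomes
are a typed `None`, never a large number, so cross-chromosome pairs can
never masquerade as proximal.

## Region–gene association

Two deliberately distinct conventions are exposed:

* **Proximity** (`annotation.proximal_gene_ids`, default 50,000 bp) is
  anchored on the gene *body*: a gene counts as proximal when the gap
  between its body and the nearest peak is ≤ the cutoff, overlap counting as
  0. This is equivalent to widening every gene by the cutoff
  (`extend_genes`) and intersecting with peaks; a property test asserts the
  two formulations give identical sets for every flank.
* **Nearest-gene assignment** (`annotation.nearest_gene`, cutoff
  1,000,000 bp) is anchored on the *TSS* (strand-aware: `start` for `+`,
  `end−1` for `−`) and on the peak midpoint (integer floor), with a signed
  distance that is negative upstream of the TSS in the gene's orientation.
  Ties on absolute distance resolve to the lower-coordinate TSS.

The body anchor is the default for enrichment because proximity cutoffs in
the tens of kilobases are meant to capture regulatory neighbourhoods of the
whole locus; the TSS anchor exists for distance-distribution summaries
where promoter-relative orientation matters.

## The 2×2 core

The sample odds ratio is ad/bc, reported as `+inf` when bc = 0 with ad > 0
and as `nan` when both products vanish; a Haldane–Anscombe-corrected variant
(+0.5 per cell) is available behind a flag, default off, because the plain
sample OR is what the field's standard tooling reports. The two-sided Fisher
exact p sums hypergeometric point probabilities over the support of the
table with margins fixed, including every table whose probability is ≤ the
observed table's times (1 + 1e−7); the tie tolerance is part of the contract
so that ports agree on tables with symmetric margins. The implementation
evaluates log-probabilities with `gammaln` and sums with `logsumexp`; the
test suite checks it against exact integer enumeration on all tables with
margins ≤ 30 (1e−9) and against an independent library implementation on
random larger tables.

BH q-values use the step-up rule (delegated to statsmodels); the family is
exactly the list of tests passed in one call and is never pooled across
calls — the caller decides what constitutes one family.

## Window-based repeat enrichment and its known bias

Windows (default 100 bp) are the exchangeable unit: a window is
family-positive or peak-positive at ≥1 bp overlap (a minimum covered
fraction is available behind `min_fraction`). Peaks spanning several windows
contribute several peak-positive windows by construction.

**Known limitation.** The Fisher test treats windows as independent, but a
feature longer than one window flips runs of adjacent windows together.
Simulation during development measured a variance inflation of ≈2× for a
neutral family of 80–160 bp instances (null P(p < 0.05) ≈ 0.15 instead of
0.05), while 1-bp instances were exactly calibrated. Interpret q-values for
long-instance families with care — enrichment calls with extreme q survive
this inflation, but borderline calls may not. This is a property of the
window-count method itself, not of the implementation.

## Resampling and permutation nulls

Empirical p-values use the add-one convention p = (1 + k)/(1 + R) with
k = #{null ≥ observed} (ties count against the observation; symmetric for
direction "less"). The floor is exactly 1/(R+1), which is why an analysis
with R = 1000 can honestly report "p < 0.001" but nothing smaller; the raw
k is also emitted so a k/R convention can be recovered. Resampled gene sets
are drawn uniformly without replacement, size-matched to the target set by
default (a fixed size, e.g. 512, is available). The permutation null
re-places every interval uniformly on its own chromosome with length
preserved, rejecting placements that touch the exclusion set (cap 1,000
attempts per interval, then a loud error). Keeping intervals on their
chromosome of origin preserves per-chromosome composition in the null.
Draw order is fixed (resamples/shuffles in replicate order, sets in input
order within a replicate) from a single seeded generator; determinism is
guaranteed within this implementation, not bit-for-bit across languages.

## Signal comparison

Bin means are exact integrals of the piecewise-constant tracks divided by
the bin width, on the same grid as the window tiling (trailing partial bin
dropped). The log-ratio uses a pseudocount ψ (default 1, the default of the
common two-track comparison tool); ψ = 0 is allowed only when no bin mean is
zero. Region aggregation includes a bin iff its midpoint lies in the region
— one unambiguous rule that never double-counts straddling bins. The t test
unit is the per-gene mean (one value per gene), which avoids
pseudoreplicating correlated bins within a gene; `unit="bin"` exists for
comparison with pipelines that test bins directly, and gives far smaller
p-values for exactly that reason. Student (pooled variance) is the default
variant, Welch available. Zero-variance degenerate inputs return (0, 1) for
equal means and (±inf, 0) with a warning otherwise.

## The synthetic-study generator

`simulate.generate_study` emulates the statistical structure the analyses
assume, not sequence-level biology: a genome of equal-length chromosomes
(default 4 × 10 Mb); non-overlapping genes with log-uniform lengths
(2–20 kb, 2,000 genes) including explicit gene clusters (20 clusters of 4
genes within 100 kb, because clustered targets are the hard case for
proximity planting); a 100-gene target set drawn half from clustered genes;
peak tracks (~200–260 peaks each) of background peaks, shared co-occupancy
loci copied into all tracks with ±20 bp jitter, and target-proximal planted
peaks; repeat families as uniform Poisson instances plus within-peak excess
instances (defaults: LINE-like 500–3,000 bp at 80/Mb with 8× within-peak
excess; a neutral simple-repeat family of 20–60 bp at 25/Mb — short so that
each instance spans ~1 window, keeping the neutral family's window test
calibrated, see above); a blacklist; and WT/KO coverage as per-bin Poisson
counts (rate 50 per 50-bp bin) with the KO rate multiplied by 0.5 over
target gene bodies.

**Planting an odds ratio.** With background proximity rate q0 (measured on
the realized background+shared peaks) and a requested odds ratio ω, the
target proximity rate q1 solves odds(q1) = ω·odds(q0). Because a peak
planted near one clustered gene also flips its neighbours, per-gene
Bernoulli planting overshoots ω; the calibrated mode therefore draws a goal
n₁ ~ Binomial(n_targets, q1) and plants peaks near randomly-ordered
non-proximal targets until the realized proximal-target count reaches n₁.
The literal Bernoulli mechanism remains available via `peaks.p_target`.
The defaults (planted ω = 5, ~200 primary peaks over 40 Mb, q0 ≈ 0.45) were
fixed by pre-build simulation so that the planted target separation exceeds
the maximum of 1,000 matched-size null draws with large margin across seeds.

**Determinism.** One master seed feeds named substreams (genes, target,
peaks, co-occupancy, repeats, signal, blacklist) spawned from a single
`SeedSequence`, so changing one component's parameters never perturbs
another's draws — this is what makes paired planted/null comparisons
(`null_variant`) meaningful. Identical config + seed reproduces
byte-identical output files.

**What passing tests do not show.** The generator has no sequence
composition, GC or mappability structure, no chromatin-domain organisation,
no overdispersion beyond Poisson in coverage, and uniform rather than
clustered repeat placement. Calibration results on it therefore demonstrate
correctness of the statistical machinery under its stated assumptions, not
robustness to the confounders of real genomes (for which GC/mappability-
matched nulls exist elsewhere and are out of scope here).

## Problem sizes used by the checked examples

The test suite runs the exhaustive Fisher check on all ~164,000 tables with
margins ≤ 30; interval arithmetic on 500 random fixtures over 2 × 10 kb
genomes; null calibration with 200 redrawn gene sets and 100 seeds of
resampling (R = 199) and permutation (R = 99) nulls; parameter recovery
over 50 seeds per planted value; and the repeat-family check on a 4 × 2 Mb
genome (80,000 windows) over 50 seeds. The acceptance script uses the full
default study (40 Mb, 2,000 genes) with R = 1000. These sizes were chosen
as the smallest at which the distributional claims stabilise.
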