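# Methods

## The question and the statistic

High taxonomic ranks (bacterial classes) are often used as ecological
units, implicitly assuming their member OTUs respond alike to the
environment. The pipeline's central object, the *coherence partition*,
makes that assumption testable. For a class *c* with member OTUs
*i = 1…k* observed over *n* samples, let **x**ᵢ be OTU *i*'s count vector
and **y** = Σᵢ **x**ᵢ the class abundance vector. Each OTU receives a
two-sided Pearson correlation *r*(**x**ᵢ, **y**), a p-value from the
*t* transform with *n* − 2 degrees of freedom, and a Bonferroni-adjusted
p-value *p·m* where *m* is the number of testable OTUs in the class.
Verdicts: `positive` (*r* > 0, adjusted *p* < α), `negative` (*r* < 0,
adjusted *p* < α), `nonsignificant`, or `untestable` (zero-variance
vector; Pearson *r* is undefined for constants). Default α = 0.05.

Design choices that were genuinely open:

- **Self-inclusion.** The class vector includes the focal OTU by
  default, matching the natural reading of "correlation with the parent
  class's abundance". In a class of one OTU this forces *r* = 1; the
  leave-one-out mode (`self_inclusion=False`) removes that inflation and
  is the right choice for very small classes. Under leave-one-out a
  constant leave-one-out target is treated as untestable rather than an
  error, which also makes exactly mirrored (class-total-constant)
  constructions testable.
- **Correction family.** Bonferroni over the class's testable OTUs
  (`within_class`), matching the per-class framing of the partition; a
  `global` family over all tested OTUs is available and can only demote
  significance (monotonicity is tested).
- **Reported shares.** `positive_fraction` returns the percent of
  *testable* OTUs that are positive, and the percent of the class's
  pooled sequences (untestable OTUs included in the denominator, since
  their sequences exist regardless of testability) carried by positive
  OTUs.
- **Subgroup summaries.** The "non-correlated" subgroup comprises
  `nonsignificant` verdicts only; negatives are reported separately
  (they are rare in practice). Percent-dominant is computed over the
  class's dominant OTUs (>0.1 % of pooled sequences, strict) that fall
  in either summarized subgroup, so the two percentages sum to 100.
  Subgroup Shannon is the pooled-count index by default; a
  per-sample-mean variant is also emitted
  (`shannon_per_sample_mean`) because "average diversity" admits both
  readings.

## Diversity and beta structure

Rarefaction draws without replacement (multivariate hypergeometric) to a
fixed depth; samples below depth are dropped and reported, the standard
handling when a few samples return too few sequences. Default depth 1000
= the smallest sample in the emulated design. Shannon is in nats by
default (the common ecology convention; base 2 available). MPD is the
mean patristic distance over all unordered pairs of present taxa —
presence-based by default, as in the common R implementation, with an
abundance-weighted variant behind a flag; it is undefined (missing) below
two taxa.

Bray–Curtis is computed on the rarefied table so sample depths are
comparable (on equal-sum columns, count and relative-abundance versions
coincide). Weighted-normalized UniFrac — Σ*l_b*·|*p_b*(x) − *p_b*(y)| /
Σ*l_b*·(*p_b*(x) + *p_b*(y)) over branches *b* — delegates to
scikit-bio's implementation behind the module surface and is verified
against an explicit branch-enumeration oracle in the tests. ANOSIM uses
Clarke's statistic R = (r̄_between − r̄_within)/(M/2) with M = n(n−1)/2
rank-transformed distances, seeded label permutations and the (+1)/(N+1)
p-value correction so p can never be zero. Per-class ANOSIM runs on the
class subset of the rarefied table without renormalization.

Upstream/downstream contrasts report a signed fold-change: up/down when
the upstream mean is at least the downstream mean, −(down/up) otherwise
(so the sign encodes direction and the magnitude is always ≥ 1), plus the
log2 ratio, with a one-way ANOVA p-value between the two reach groups
(reservoir excluded). Two identical groups yield ratio +1 and p = 1.

## Origin and dominance bookkeeping

Both schemes run on the non-rarefied table with campaigns pooled (a
per-campaign detection mode exists but pooling is the default). Origin =
farthest-upstream reach (or site, under site resolution) with a nonzero
count. Dominance = reach with the strictly greatest summed count; any
tie for the maximum → `no_change`. Reach sums are raw sums despite the
unequal site counts (6/1/5); a per-site-mean variant is provided.
Figure-style summaries compute, per campaign, each category's share of a
focal reach's class sequences (sites pooled by summation), then average
shares across campaigns; a class absent from a reach yields missing, not
zero. Pool-then-average versus average-then-pool differ, so the order is
fixed and stated.

## Environmental axes

Variables are standardized; components come from the correlation
matrix's eigendecomposition. The 2-component solution is rotated with
direct oblimin (γ = 0, oblique), which preserves per-variable
communalities while letting the axes align with interpretable gradients;
the inter-component correlation is reported, never assumed zero.
Component signs are fixed so each component's largest-|loading| variable
loads positively. Scores use the regression method (weights =
R⁺·structure on standardized data, pseudo-inverse for collinear inputs)
— oblique scores are not unique, so the choice is stated. Axis
correlations of OTUs and classes are unadjusted by default (screening
use), with a Bonferroni flag; constant entities are excluded as
untestable.

## The synthetic river metacommunity

The generator emulates a reservoir-interrupted river survey: 6 upstream,
1 reservoir and 5 downstream sites, 3 campaigns (Jul/Sep/Dec), per-sample
depths uniform in [1000, 6222]. Six focal classes mirror a
dominant-class community (richness / baseline sequence share / spatial
trend): Actinobacteria 387 / 68 % / up-responding (more abundant at and
below the reservoir), Betaproteobacteria 149 / 15 % / declining,
Alphaproteobacteria 79 / 6 % / up, Gammaproteobacteria 45 / 0.6 % /
declining, Flavobacteria 65 / 4 % / declining, Sphingobacteria 36 / 3 % /
declining, plus 196 rare filler OTUs (3.4 %) giving the 0.1 % dominance
threshold a realistic tail.

Per OTU *i* and sample *s* the log intensity is

    log w_i + σ_i·β·(space(s) − s̄) + γ_i·(season(s) − t̄) + ε_is

with `space` a step function at the reservoir, `season` a symmetric
campaign score, and ε a lognormal overdispersion jitter (CV 0.3 by
default) that keeps correlation recovery from being unrealistically
easy. Counts are multinomial per sample at the drawn depth, so columns
sum exactly and compositional coupling between taxa is present, as in
real tables. Effects enter as deviations from the design mean so each
OTU's base weight is its design-average abundance; otherwise a handful
of exponentially blooming opposite-responders can flip the sign of a
declining class's trend.

Planted structure, exported as ground truth:

- a fraction *f* of each class's OTUs are **coherent** (share the
  class's response signs on both axes; default *f* = 0.25, near the
  upper end of positively-correlated fractions seen in river surveys);
- 10 % are **anti-responders** (opposite signs on both axes) — enough to
  produce significant correlations of both signs within one class
  without cancelling the class trend;
- the rest are **null responders** with no systematic response on either
  axis, so the planted labels and the planted dynamics agree;
- each OTU gets an origin reach (default probabilities 0.8/0.1/0.1 for
  upstream/reservoir/downstream); an OTU is structurally absent above
  its origin, implementing unidirectional-flow arrival;
- base weights are lognormal (σ = 1.2 by default); a geometric decay
  over the coherent OTUs (default rate 0.3) plants a low-diversity
  coherent core, reproducing the empirical pattern that the positive
  subgroup is sequence-rich but uneven;
- the tree is random bifurcating with exponential branch lengths,
  class-monophyletic by default with the coherent core as a short-branch
  subclade;
- eight environmental variables (temperature, dissolved oxygen,
  daylength, conductivity, DIN, chlorophyll *a*, suspended solids, DOC)
  are linear in the same season/space factors plus noise, with
  conductivity, DIN, chlorophyll and solids declining downstream —
  giving separable seasonal and spatial axes.

Identical seeds give bit-identical bundles; the configuration is
serialized beside every written bundle.

**What the generator does not emulate:** sequencing error, chimeras and
clustering artifacts (the world starts at counts); tributary inputs or
soil recruitment (origin is a pure bookkeeping rule); temporal
autocorrelation within a campaign; taxon–taxon interactions beyond
compositional coupling; and environmental tables as collinear and noisy
as real ones (the synthetic axes separate more cleanly than the ~77 %
two-axis variance typical of field data). Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to every property of real surveys.

## Experiment sizes used in tests and the acceptance script

Parameter recovery uses a fixed two-class design (48 + 32 OTUs, baseline
shares 0.5/0.4, opposite trends, 10 % filler), strong reservoir effect
β = 2 (≈ 7-fold), base σ = 0.8 so planted responders are detectable at
the even depth of 2000, and 32 samples (the four December samples of the
first sites are dropped, mirroring winter sample loss in such surveys).
Planted coherent fractions 0.25/0.5/0.75 are recovered as the positive
share of testable OTUs; the median absolute error over 20 seeds is the
reported statistic. The low-diversity-core comparison plants decay 0.4
at *f* = 0.25 and compares pooled subgroup Shannon indices. Rotated-PCA
axis separation and the ANOSIM permutation oracle use the full default
design; the ANOSIM oracle compares the permutation p-value on 6-sample
instances against exhaustive enumeration of all 720 label permutations.

## Numerical notes and limitations

- Pearson p-values use the exact t transform; |r| = 1 maps to p = 0.
- Bonferroni adjustment is min(1, p·m).
- Rarefaction at a sample's own total returns the sample unchanged.
- All stochastic stages take explicit seeds; the pipeline splits one
  global seed per stage via `SeedSequence`, so stages are individually
  reproducible.
- Distance matrices are dense; the pipeline is designed for hundreds of
  OTUs and tens of samples, not thousands of samples.
- The coherence partition is correlational: a positive verdict means
  covariation with the class aggregate, not a causal or mechanistic
  link, and with self-inclusion an abundant OTU partly correlates with
  itself (use leave-one-out to quantify that).
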