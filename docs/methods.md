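# Methods

## The admixture model

An admixed population H is founded at generation 0 and evolves for 20
further non-overlapping generations. At g = 0 a fraction s_Afr,0 of the
2·N_0 parents comes from the African source and s_Eur,0 = 1 − s_Afr,0
from the European source. At each later generation g the 2·N_g parents
are drawn from the African source, the European source and H itself in
proportions (s_Afr,g, s_Eur,g, h_g) summing to one. Four scenarios
combine, per source, either **two pulses** (one-generation
contributions at distinct times t_p1 > t_p2, each with intensity in
[0, 1]) or a **recurring period** [t_t1, t_t2] (t_t2 ≥ t_t1 + 1) whose
intensity decreases monotonically from s_t1 to s_t2 ≤ s_t1.

Two quantities follow a rectangular-hyperbola interpolation with a
steepness parameter u ∈ [0, 0.5]:

* reproductive size: N(g) = N_0 + (N_20 − N_0) · gκ / (20κ + 20 − g)
  with κ = u_N/(0.5 − u_N), rounded half-up. u_N = 0.5 is exactly the
  linear interpolation; u_N → 0 keeps N(g) ≈ N_0 until a final jump to
  N_20; N_0 = N_20 gives a constant size regardless of u_N.
* recurring intensity: s(g) = s_t1 − (s_t1 − s_t2) ·
  (1 − (D − d)κ/(Dκ + d)) with D = t_t2 − t_t1, d = g − t_t1. u = 0.5
  decays linearly; u → 0 drops to s_t2 one generation after the period
  starts (a pulse followed by constant flow).

The literature source for this trajectory gives no closed form in the
text we model, so the form above was fixed as the package's own choice;
it satisfies every stated limiting behaviour and is isolated in two
functions so it can be swapped.

**Priors.** All times discrete uniform on [1, 20]; all intensities
uniform on [0, 1] (with s_t1 ≥ s_t2 imposed by sorting); s_Afr,0
uniform on [0, 1]; N_0 uniform on [10, 1000], N_20 uniform on
[100, 100000] with N_0 ≤ N_20 by rejection; u parameters uniform on
[0, 0.5]. Draws whose expanded schedule would need
s_Afr,g + s_Eur,g > 1 at any generation are rejected and redrawn whole,
preserving uniformity on the feasible region. One stated ordering
condition for recurring periods conflicts between two descriptions of
the model; we follow the explicit prose (period start before end,
t_t2 ≥ t_t1 + 1).

## The simulation engine

Source populations are represented by fixed **gamete reservoirs**: R
haploid genomes whose allele at each site is an independent
Bernoulli draw from that source's site frequency. Source parents are
assembled anew each generation by pairing two *different* reservoir
gametes; admixed parents are drawn with replacement from the previous
generation. Each of the N_g offspring draws an ordered pair of distinct
parents (parents return to the pool after every draw — no selfing, but
a parent may have many offspring) and receives one gamete from each,
every gamete being an independent per-site Mendelian choice between the
parent's two copies. Sites are unlinked and mutation-free, so a
diploid genotype in {0, 1, 2} per site is a sufficient parental state.

**Lazy evaluation.** Only sampled individuals' genotypes are ever
needed, so the default engine records the pedigree (parent assignments
and reservoir-gamete pairs) forward in time and resolves genotypes by
backward gene-dropping: for each (individual, gamete, site) lineage it
walks to the recorded parent, chooses which of the parent's two copies
it descends from, and terminates at a reservoir gamete. Every
segregation choice comes from a counter-based hash (splitmix64
finalizer) keyed by (generation, child, gamete, site), so two lineages
traversing the same gamete at the same site always make the same
choice — identity-by-descent is preserved exactly — and the fully
materialised forward engine using the same bits produces bit-identical
sampled genotypes (asserted in the tests). This is the same stochastic
process evaluated lazily, not an approximation; it makes reference-table
construction roughly two orders of magnitude cheaper at large N_g.

**Unrelated sampling.** Each final-generation individual carries the
identity codes of its four grandparents (source parents count as their
own unique synthetic ancestors, which also excludes half-sibs through a
shared source parent). Sampling searches randomized greedy orders for a
subset with pairwise-disjoint grandparent sets. Prior draws with small
N_20 sometimes cannot support a fully unrelated sample of the requested
size at all; reference-table builds therefore fall back to completing
the sample with the least-related individuals rather than rejecting the
draw (which would bias the prior against small sizes). The strict mode
raising an error remains the default everywhere else.

Reservoirs are built once per reference table and shared across its
simulations; per-simulation rebuilds are available through the API.

## Summary statistics

Allele-sharing dissimilarity between two diploids is the mean over
shared non-missing sites of |g_i − g_j|/2. Classical (Torgerson) MDS
double-centres the squared dissimilarities and scales eigenvectors by
the square roots of the leading eigenvalues; axes beyond the
configuration's rank get zero coordinates, and a substantially negative
leading eigenvalue is an error. The African admixture fraction α_i is
the orthogonal projection of an admixed individual onto the segment
joining the source-sample centroids in the first two MDS axes, scaled
to put the European centroid at 0 and the African at 1; α is *not*
clipped, so its min/max record overshoot. The angle θ_i is measured at
the individual between the directions to the two centroids (undefined,
with a warning, exactly at a centroid). The original angle construction
is described only in a figure we do not reproduce; this definition is
documented and kept behind one function so it can be swapped.

Per-SNP heterozygosity is the unbiased gene diversity
2p(1−p)·2n/(2n−1). Individual inbreeding F is the method-of-moments
(observed − expected homozygous count)/(polymorphic sites − expected),
with the small-sample-corrected expectation. Fst is the Weir–Cockerham
(1984) two-population estimator as a ratio of summed variance
components. f3(H; Eur, Afr) is mean (p_H − p_Eur)(p_H − p_Afr) minus
the heterozygosity correction h_H/(2n_H).

Distribution blocks use: Gaussian-kernel density mode (Silverman
bandwidth, 512-point grid), Fisher moment skewness, Pearson
(non-excess) kurtosis, and linearly interpolated (type-7) deciles —
the mode/skew/kurtosis/quantile conventions are not pinned down by the
modelled description, so these field-standard choices are fixed here
and only internal consistency matters for ABC.

## ABC machinery

**Prior check.** Statistics are z-scored over the reference table; the
goodness-of-fit statistic is the mean distance from the observation to
its 10 nearest simulations, with a null built from table rows treated
as pseudo-observed.

**Scenario choice** is a 500-tree random-forest classification on the
42 statistics augmented with the linear-discriminant axes (recorded in
the importances as LD1–LD3). Votes are per-tree predictions for the
observation; the prior error and confusion matrix are out-of-bag; the
posterior probability of the selected scenario is one minus the
prediction of a second regression forest fitted to the out-of-bag
misclassification indicators. Note the discriminant axes are fitted on
the full table, so label-permutation diagnostics must disable the
augmentation (it would leak the permuted labels into out-of-bag
features); the package's permutation-null check does so.

**Parameter estimation** retains the tolerance fraction of simulations
nearest to the observation (Euclidean distance on MAD-standardized
statistics), maps parameters to the real line by a bounded logit on
their prior ranges, z-scores them, and fits an ensemble of
single-hidden-layer networks (default 10 networks, 8 hidden units, L2
decay 0.5, lbfgs), each on a random half of the retained rows. The
regression adjustment uses *out-of-bag* residuals — each retained row's
residual comes from networks that did not train on it — because
in-sample residuals of a flexible regression collapse the adjusted
spread and produce overconfident intervals at the retained-set sizes
used here (a few hundred rows). Adjusted samples are back-transformed;
medians and 25–75% / 2.5–97.5% quantiles give the point estimate and
CIs. Cross-validation error is the mean squared error of the posterior
median over left-out rows divided by the parameter's table variance
(≈ 1 means prior-level, no information). The default tolerance (0.01)
mirrors usage with 10^5-row tables; desk-scale experiments use 0.25 so
that ~125 rows are retained.

## ROH × local ancestry

Ancestry segments per haplotype are extended to meet at the midpoint of
any inter-segment gap (and to the chromosome edges) before
intersection; the diploid dosage of each ancestry is piecewise constant
between the merged breakpoints, so any interval's per-ancestry content
is an exact piecewise-linear cumulative lookup. An ROH's content splits
a heterozygous-ancestry stretch half-and-half; ROH with any
heterozygous-ancestry stretch, or any ASN content, are excluded from
the excess statistic. Length-class boundaries put 0.25 cM in the medium
and 1 cM in the long class. The per-individual excess is the AFR share
of retained long-ROH content (over AFR + EUR) minus the genome-wide AFR
share (also over AFR + EUR, so negligible-ASN genomes behave as a
two-ancestry system and a whole-genome ROH gives exactly zero).

The permutation test re-places each individual's retained long ROH
uniformly on their own map — by default across chromosomes, each ROH
within one chromosome — with rejection of overlapping configurations,
preserving the per-individual length multiset by construction. The
statistic is the mean excess across individuals; the p-value is
two-sided with the +1 correction, p = (#{|null| ≥ |obs|} + 1)/(B + 1).

## Synthetic data

Source frequency pairs follow a Balding–Nichols model: ancestral
frequencies from Beta(0.8, 0.8) clipped to the minor-allele-frequency
floor (default 0.01, emulating singleton-free SNP panels), each
population's frequency from Beta with mean p and variance F·p(1−p).
The generator/estimator closure (Weir–Cockerham Fst on sampled
genotypes recovers the divergence parameter) is tested. User-supplied
frequency tables are accepted verbatim throughout.

ROH fixtures draw alternating exponential ancestry segments (mean
25 cM) over a 10 × 150 cM map with a target AFR fraction, identical on
both haplotypes by default so that the calibration experiments are
exclusion-free (an independent-haplotype mode exists; heterozygous
exclusion is unit-tested on hand-built tracks). Each individual gets
5 long, 3 medium and 4 short ROH; the association parameter is the
probability that a long ROH is forced inside homozygous-AFR ancestry
(0 = null, 1 = fully associated).

What the fixtures do **not** emulate: linkage disequilibrium, array
ascertainment, genotyping error, realistic chromosome-length and
recombination-map heterogeneity, or empirical site-frequency spectra.
Passing tests therefore demonstrate the correctness and calibration of
the machinery under the model's own assumptions, not performance on
real data.

## Desk-scale experiment design

Full-scale analyses in this design use 60,000 SNPs, 20,000-gamete
reservoirs and 10^4–10^5 simulations per scenario. The test suite runs
a documented scaled-down mirror: L = 5,000 SNPs, R = 2,000 gametes,
n = 30 admixed (60 per source), 500 simulations per scenario. At this
scale the four scenarios overlap heavily (out-of-bag prior error ≈ 0.67
against 0.75 chance), so the scenario-recovery experiment defines its
strong-signal inputs operationally: for each scenario, the three table
rows the forest classifies with the highest out-of-bag confidence are
re-simulated as fresh pseudo-observed datasets. This measures whether
the forest's confidently learned regions generalise to new data from
the same parameters, which is the recoverable notion of "strong signal"
at this scale. The founding-proportion coverage experiment fixes
s_Afr,0 = 0.7 and draws all other parameters from the prior; under the
full priors the founding proportion is close to unidentifiable (later
gene flow overwrites it — the honest posterior is near-prior, which is
what the estimator returns), while recent pulse times shrink well below
their priors and anchor the shrinkage check.

## Known limitations

* Two sources only; no sex-specific processes, bottlenecks, selection,
  linkage or mutation — all outside the modelled design.
* The exact hyperbola, angle, and mode conventions are
  contract-matched, documented stand-ins (see above), not guaranteed
  bit-identical to any external implementation.
* The NN-ABC hyperparameters are conventions chosen for small retained
  sets; they are all configurable and recorded in results metadata.
* VCF support is limited to a frequency-table converter; genotype
  matrices travel as TSV.
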