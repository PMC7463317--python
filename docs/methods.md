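# Methods

This note records the statistical models, the numerical choices, and the
limits of what the test suite demonstrates.

## Data model

Genotypes are biallelic calls coded 0/1/2 (copies of the second allele)
with −1 for missing, one collection (site/time sample) per individual.
Monomorphic loci are retained and flagged; each statistic decides its own
handling (they contribute 0 to heterozygosity means, are untestable for
HWE, and drop out of FST denominators naturally). Genepop files are read
with both 2- and 3-digit allele codes, mapping codes to alleles by
ascending numeric value, and always written with 3-digit codes; an
all-zero code is missing. The missingness purge removes individuals with
strictly more than the threshold fraction missing (default 30%), so a
tie at exactly the threshold is kept.

## Diversity and exact tests

Per locus and collection: Ho is the heterozygote fraction among
non-missing calls; uHe = [2n/(2n−1)](1 − p² − q²) with n the genotyped
count; FIS = (uHe − Ho)/uHe, undefined for monomorphic cells.
Collection summaries report mean ± SE over loci with SE = sd/√L.

The Hardy–Weinberg test is Levene's exact conditional test. For a
biallelic locus the distribution of the heterozygote count given the
allele counts is enumerated completely, so the probability test (sum of
outcomes no more probable than observed) is computed exactly rather
than by Markov chain; the conventional chain parameterization is kept
only for a Monte-Carlo cross-check mode. One-sided tail sums give the
deficit/excess direction. Exact tests on discrete support are
conservative: at n ≈ 60 individuals the realized size at nominal
α = 0.05 is about 0.03, which the calibration tests treat as the
expected operating point, not a defect.

The LD test is a log-likelihood-ratio (G) statistic on the 3×3 genotype
table of a locus pair within a collection, with p estimated by
permuting one locus across individuals using the unbiased
(1 + k)/(1 + N) estimator. Multiple testing uses Holm's step-down rule
throughout.

## Differentiation

Weir–Cockerham variance components a, b, c are computed per locus from
per-group sample sizes, allele frequencies and heterozygote
proportions; groups with no data at a locus drop out of that locus, and
loci with fewer than two populated groups are skipped. The multilocus
estimate is the ratio of sums. Negative per-locus estimates are kept as
computed; clamping at zero would bias the linearized values used in the
isolation-by-distance regression. Permutation tests shuffle individuals
between the two groups with sizes preserved, recomputing the full
estimator each time (vectorized across permutations). Note that the
attainable minimum p is 1/(1 + n_perm): when Holm is applied across
C(k,2) pairs, n_perm must exceed roughly C(k,2)/α before any pair can
be significant. Waterway distances are an input; a haversine
great-circle helper exists only as a clearly labeled fallback.

## Outlier scans

**Envelope scan.** The neutral target FST is the multilocus θ after two
refinement passes that exclude loci outside a provisional envelope
(mimicking a "forced" trimmed mean). Null loci are simulated under a
symmetric island model: ancestral frequency uniform, per-deme
frequencies Balding–Nichols with F equal to the target (for iid
Beta-distributed demes the deme count does not change the sampling
distribution of the per-locus estimator, so the nominal deme number is
recorded but does not enter the draw), then genotype counts binomial at
the observed group sizes under within-deme HWE. Empirical quantiles are
taken in 20 equal-count expected-heterozygosity bins, made monotone by
weighted isotonic regression, and interpolated at each observed locus.
The significance level is split across the two tails (0.05 → 0.025 and
0.975 quantiles), the usual confidence-envelope convention. The
envelope is only calibrated when the analyzed groups are approximately
exchangeable demes; hierarchical structure (collections nested in
clusters) inflates its false-positive rate, which is exactly why the
workflow pools collections into regions for scans and retains only the
two-method consensus.

**Bayesian F-model.** logit(FST_ij) = α_i + β_j with beta-binomial
allele counts given a per-locus ancestral frequency μ_i (the p_ij are
integrated analytically). Priors: α ~ N(0,1), β ~ N(−1,1), μ uniform on
(0,1) via logit random walk; prior odds for neutrality 10 (prior
inclusion 1/11). The reversible-jump move proposes toggling each
locus's α between zero and a draw from its prior (prior-as-proposal, so
densities cancel), alongside within-model random-walk updates; all
locus-indexed updates are vectorized per sweep. Posterior inclusion
probability above 0.99 flags a locus; the log10 Bayes factor and a
q-value (running mean of 1 − posterior probability down the ranked
list) are reported alongside. The `sample_size`/`thinning`/`burn_in`
parameterization of the tool of record is accepted and converted to
sweeps at L updates per sweep; explicit `n_sweeps` arguments override it.

**Consensus and the balanced design.** Consensus is the plain
intersection of the two flag sets. The pairwise-region design pools
collections per region and draws equal-size random subsets (default:
the smallest region's size) before scanning, avoiding uneven-sample
bias.

## Admixture clustering

The sampler is the classic admixture Gibbs scheme: latent origins z for
every gene copy, q_i | z ~ Dirichlet(α + counts), cluster frequencies
conjugate under the correlated-frequencies (F-model) prior, and
Metropolis updates for the ancestral frequencies (reflected random walk,
sd 0.05), the drift parameters F_k (logit random walk sd 0.3, prior
Beta(0.1, 9.9), mean 0.01), and α (uniform (0,10) prior). The z-update
dominates the cost and runs as a compiled kernel over a flattened list
of observed gene copies; a pure-numpy fallback implements the same
update.

Two choices depart from the long-chain defaults and exist for scaled
runs:

* **α proposal width.** The classic random-walk sd of 0.025 needs tens
  of thousands of sweeps to travel from the α = 1 start to the small
  values typical of well-separated clusters. Chains with burn-in below
  20,000 sweeps therefore use sd 0.15; production-length chains keep
  0.025.
* **Initialization.** Q and P are seeded from a k-means partition of
  the dosage matrix (restart seed tied to the chain seed). Random
  initialization plus short chains frequently stalls in label-merged
  modes (evidence gaps of thousands of nats between replicates);
  k-means starts remove that failure mode while replicate variability
  remains through the restart seed and the MCMC stream.

The evidence proxy is L(K) = mean(lnL) − var(lnL)/2 over retained
sweeps, with lnL the data log-likelihood at each sweep's (Q, P).
Credible intervals are equal-tailed quantiles of thinned retained
sweeps (90% by default). Replicate runs are aligned by maximizing mean
pairwise G′ = 1 − ‖Q_a − Q_bΠ‖_F/√(2n) over label permutations —
exhaustively when (K!)^(R−1) is small, otherwise greedily with
iterated refinement — and averaged into a consensus.

K selection reports Evanno's ΔK (second difference of mean L
normalized by the replicate sd, undefined at zero sd) and the four
cluster-count estimators: a cluster counts in a run if any collection's
mean (Mean family) or median (Med family) membership exceeds 0.5;
per-run counts are combined across runs by median (Med-) or maximum
(Max-). Each estimator's chosen K is its value at the *saturation
point* — the smallest analyzed K where the count falls below K —
because counts below the true K are structurally capped at K, and far
above the true K short chains spread ancestry too thinly for the
threshold. If the grid never saturates, the value at the largest K is
used.

An honest limit worth stating: with 91 SNPs at pairwise FST ≈ 0.10 the
posterior of q for a truly pure individual is genuinely diffuse (about
35 nats of Fisher information per individual), so posterior-mean
ancestries top out around 0.92–0.95, not 1.0. A numerical-integration
oracle of the exact posterior mean (cluster frequencies known) puts the
RMSE floor against one-hot truth near 0.08–0.11 at these settings; the
sampler's consensus estimates sit in the same range. Hard-assignment
accuracy (argmax q) is nonetheless ≈ 99%.

## DAPC

Dosages are mean-imputed per locus, centered, reduced by PCA (default:
smallest PC count explaining ≥ 90% of variance, capped at n/3), and
passed to eigen-solver LDA; singular within-group scatter triggers an
automatic reduction of the PC count. Discriminant vectors are mapped
back through the PCA rotation to per-locus squared, normalized
contributions.

## Hybrid-zone diagnostics

F1 simulation estimates allele frequencies in each parental pool
(subsampled to equal size) and gives every hybrid one Bernoulli gamete
per pool per locus, independent across loci — so hybrid heterozygosity
has the closed form p_A(1−p_B) + p_B(1−p_A), which the tests check. An
individual is called admixed when the 90% credible intervals of its
ancestry in the two focal clusters overlap, otherwise pure toward the
higher posterior mean; widening intervals can only move calls toward
admixed. Assignment uses the compound-Dirichlet (posterior-predictive)
genotype probability per baseline with a symmetric prior of 1/(number
of alleles) = 0.5 per allele, sequential updating between the two
drawn alleles, and leave-one-out removal of a query's own alleles from
its baseline.

## Synthetic generator

Hierarchy: ancestral frequency ~ Uniform(0.1, 0.9); cluster frequency ~
Balding–Nichols around it with per-cluster drift F (expected pairwise
FST between clusters ≈ mean of their drifts, verified by the estimator
at 10,000 loci); collection frequency drifted further with
within-cluster F (default 0.005); individuals binomial from their
collection, F1 hybrids one gamete from each parental cluster. Outlier
loci multiply cluster-level drift by the configured factor (default 5)
**and are redrawn until their realized among-cluster divergence reaches
the drift target**: with only three clusters a raw Beta draw leaves
roughly half of nominal "outlier" loci no more diverged than neutral
ones, which would make truth labels meaningless for power tests.
Missingness is uniform per call (default 5%) with a small fraction of
high-dropout individuals (1% at rate 40%), tuned so ~98% of individuals
show <10% missing data, matching a well-behaved assay panel.

The `sprat_like` preset encodes the study geometry the package targets:
three clusters (drifts 0.10/0.10/0.20 → pairwise FST ~0.10–0.20),
15/14/8 collections of ~60 fish plus three transition-zone collections
holding 73% F1-like admixed individuals between clusters 1 and 2, 9 of
91 loci outliers. `scale` shrinks collection counts and sizes for
desk-scale runs; the acceptance script uses scaled problem sizes
(e.g. 150–250 individuals, 1,000 permutation-test replicates, 20,000
envelope iterations, chains of a few thousand sweeps) chosen so the
full recomputation completes in about a minute.

What the generator does *not* emulate: linkage between loci, genotyping
error and allele dropout, temporal replicates, within-collection
relatedness, and realistic geography (distances for the IBD regression
must be supplied). Passing recovery tests therefore demonstrates
correctness of the estimators under the F-model assumptions, not
robustness to those real-data complications.

## Pipeline

Stages run in the study's order (filter → diversity/HWE → FST matrix →
outlier consensus → clustering/K selection → DAPC → IBD), each seeded
from the master seed, with a JSON manifest of parameters, seeds and
wall times sufficient to reproduce any run. Profiles: `paper` (the
production chain lengths) and `test` (~100× smaller); the test suite
and acceptance script use test-profile-scale settings throughout.
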