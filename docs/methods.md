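# Methods

This note documents the models and estimators implemented in `radpaint`,
the choices made where the design was genuinely open, and what the
bundled simulations do and do not demonstrate.

## Coancestry painting

For each RAD locus the alleles of each individual (the *recipient*) are
compared, SNP by SNP, against the alleles of every other individual.
The nearest neighbour of a recipient allele is the donor allele with the
fewest differences; `N` positions are excluded from every comparison.
One unit of coancestry per locus per recipient is distributed as:

* `1 / ploidy` per recipient allele — coancestry is averaged over the
  allele copies an individual carries, so haploids, diploids, and
  mixed-ploidy panels are all handled by the same rule;
* equal fractions of that mass to every tied nearest-neighbour allele,
  accumulated onto the carrying individual.  Tie splitting is exact and
  deterministic; there is no randomised tie-breaking anywhere.

A recipient's own alleles are never candidate donors and the diagonal of
the matrix is structurally zero: self-copying carries no information
about population structure.  A recipient allele that cannot be compared
with any candidate (an all-`N` allele, or nothing comparable at the
locus) passes its share to the recipient's remaining usable alleles; if
none remain the locus is treated as missing for that recipient.

Because loci contribute additively and independently, the matrix is
invariant under any permutation of loci — analyses with and without a
reference genome give identical coancestry matrices.

### Missing data

Missing cells are handled *pairwise*: the coancestry of a pair at loci
where either member is absent is credited in proportion to the
coancestry observed between them at their co-present loci.  Concretely,
each pair's accumulated weight is converted to a rate per co-present
locus, and every recipient's row of rates is then scaled to sum to the
total number of loci N, so row totals are conserved exactly.

Two refinements matter for structured missingness:

* per-locus contributions are normalised by the size of the recipient's
  candidate-donor pool at that locus (the weight is an *enrichment* over
  the uniform expectation given who was present).  With complete data
  the factor is constant and cancels; at loci with absent donors it
  stops the shrunken pool from inflating the apparent rates of the
  pairs that remain;
* rates, not raw sums, enter the matrix, so a pair co-observed at more
  loci (e.g. two samples from the same sequencing library) gains no
  spurious coancestry merely from being co-observed.

Without these corrections, library-batch missingness measurably leaks
into the inferred clusters (in our batch simulations the adjusted Rand
index against the true populations dropped to ~0.5); with them the
batch signal is confined to the presence/absence PCA where it belongs.
Allele dropout — missingness correlated with the divergence signal
itself — cannot be fully corrected this way and remains a caveat for
interpretation, which is why per-individual missingness and the
presence/absence PCA are first-class outputs.

## The variance-normalisation constant c

If each locus independently named a single closest relative, an entry of
the matrix would follow `x_ij ~ Binomial(N, p_ij)` with theoretical
variance `N p (1 - p)`.  Real data deviate in both directions: linkage
between loci inflates the sampling variance, while tie splitting and
ploidy averaging smooth the per-locus contribution and deflate it.  The
constant

    c = mean over off-diagonal entries of VE_ij / (N p_ij (1 - p_ij))

(the mean taken over entries with `0 < p < 1`) rescales counts so that
the clustering likelihood sees `N / c` effectively independent loci.

`VE` is a delete-block jackknife over consecutive loci, default block
size 100.  Each leave-block-out painting is rescaled back to full-N rows
before the variance is computed, so `VE` and the binomial reference are
on the same scale; a short final block is kept and weighted by its size
rather than discarded.  The pooling statistic across entries is the
arithmetic mean; a median option exists (`--c-summary median`) but is
more aggressive in our simulations — the median sits among the smooth,
heavily tied within-population entries and understates the noise of the
between-population entries, producing oversplit clusterings.

Note that `c < 1` is expected and *correct* for tie-heavy data (many
individuals, few SNPs per locus, diploid averaging): the painting is
smoother than a categorical draw, each locus genuinely carries more than
one locus's worth of binomial information, and the calibration says so.
The bundled calibration experiment therefore checks `c ~ 1` in the
regime where the binomial model's premise actually holds: haploid
samples painted at high-resolution loci (60 SNPs, per-site diversity
0.2) where the nearest neighbour is essentially always unique.

## LD-based locus reordering

The jackknife only sees correlation between loci that fall inside one
block.  For unmapped data, loci in strong LD should therefore be made
adjacent before painting; otherwise c is underestimated and the
clustering overconfident.

LD between loci is the squared Pearson correlation of per-individual
alternate-allele dosages, summed over all SNPs of each locus (missing
cells mean-imputed).  First-SNP-only scoring is available but not the
default: a single SNP's dosage across a small panel is so coarse that
unlinked loci collide on identical patterns and acquire r² = 1 by
chance.

Loci are grouped only when their LD clears a significance threshold
calibrated against the multiple-comparison noise floor: under
independence `r² (n-2) / (1 - r²)` is F(1, n-2)-distributed, and the
default threshold is the Bonferroni-corrected upper 5% quantile over all
locus pairs.  With, say, 20 individuals and 2 000 loci this lands near
r² = 0.83 — far above the naive "weak LD" thresholds, which at this
sample size would chain loci by realised noise and bias c upward.
Within each connected component of the thresholded LD graph a greedy
chain (strongest member first, then nearest unplaced member, ties by
original index) fixes the order; all other loci keep their original
positions, so on independent data the reordering is effectively the
identity and c is untouched.  The validation is the duplication
experiment: duplicating every locus, scattering the copies, and
reordering doubles c (observed ratios 1.98-2.10 over seeds) while `N/c`
is conserved.

## Clustering model

Counts are scaled as `y = round(x / c)` (half-to-even) and a partition
of the individuals into K populations is scored by a marginal likelihood
in which each recipient row is multinomial over donor *individuals*,
with cell probabilities tied at the population-pair level: a recipient
in population a donates to population b with total probability `P_ab`,
spread uniformly over the `n_b` available donors (self excluded).  The
`P_a` vectors carry a symmetric Dirichlet(β = 1) prior shared by the
recipients of each population and are integrated out analytically.  Up
to a partition-independent constant,

    log L = Σ_a [ ln Γ(Kβ) − ln Γ(Kβ + Y_a·) + Σ_b ( ln Γ(β + Y_ab) − ln Γ(β) ) ]
            − Σ_{i,b} n_ib ln m_ib

with `n_ib` the counts of recipient i into donor population b, `Y_ab`
their sums over recipients of population a, and `m_ib` the donor-pool
size of b as seen from i.  The single-population partition forces every
row towards uniformity over donors and is the likelihood reference
point; a split pays an Occam penalty through the Dirichlet
marginalisation and is rewarded exactly when rows differ by more than
the c-calibrated multinomial noise.  Block counts aggregated by
recipient and donor population are the model's sufficient statistics;
the pool-size term is what keeps the model comparable across K.  The
prior over partitions is uniform.

Increasing c flattens the likelihood surface (the spread of log L over
partitions shrinks), and the number of MAP populations never grows along
a c sweep — re-running the clustering at larger c is the supported way
to probe coarser structure.

### Sampler

Metropolis–Hastings over set partitions with four proposals, each drawn
with probability 1/4:

* **merge** a uniformly chosen pair of populations;
* **split** a uniformly chosen population by a uniform random
  bipartition into two non-empty parts (`2^(m-1) − 1` of them);
* **merge-resplit** a pair (symmetric, no Hastings correction);
* **move** one individual to another or a brand-new population (the
  forward and reverse option counts always coincide, so the correction
  is again 1).

Merge/split asymmetries carry exact Hastings factors; a proposal drawn
in an inapplicable state counts as a rejection.  The chain starts from
all singletons by default and is bitwise reproducible given its seed.
On four-individual problems the sampled partition frequencies match the
exactly enumerated posterior (all 15 partitions) to Monte-Carlo error,
which is the strongest correctness check a sampler of this kind admits.

Summaries: the MAP is the highest-posterior sampled partition; the
pairwise coincidence matrix gives the fraction of samples in which two
individuals co-cluster; the population-averaged matrix is the block mean
of x under the MAP; and the tree is built by greedily merging the pair
of populations whose merge loses the least log likelihood, each node
annotated with the fraction of samples in which exactly that set of
individuals formed one population.  The tree is illustrative of
between-group relationships, not an estimate of population history.

## The simulator

Each locus draws a root haplotype uniformly over {A,C,G,T} per SNP; each
population mutates it once at the per-site `divergence` rate; each
allele copy of each individual mutates its population haplotype at the
per-site `diversity` rate (substitutions to a uniformly chosen other
base; no indels, because RAD loci are fixed-length stacks).  Loci are
independent draws by construction; linkage is introduced only
explicitly, by duplicating loci.

Defaults — 2 populations × 10 diploids × 1 000 loci of 5 SNPs,
divergence 0.1, diversity 0.2 — are chosen as a realistic post-filter
RADseq regime: SNP sites are ascertained *because* they vary, so
per-site within-population diversity is high by construction and
typically exceeds per-site between-population divergence.  (Regimes
with divergence ≫ diversity make many independent loci carry literally
identical genotype patterns, which no real dataset shows and which
confounds any LD-based analysis.)  The "strong divergence" clustering
simulations raise divergence to 0.3 with diversity 0.1.

Missingness mechanisms, separately switchable: uniform random cell
dropout (`missing_rate`); a library batch effect (`n_batches` round-robin
batches, each losing its own disjoint `batch_missing_frac` of loci —
round-robin so batches cross-cut populations, the worst case for
confounding); and allele dropout (`dropout_rate`: whole populations
losing a locus together, the restriction-site-polymorphism proxy).  The
batch scenario used in the tests (5 batches × 10% of loci) keeps
per-sample missingness at 10%, inside what the standard >20% sample
filter would pass, mirroring a multi-library study that survived its own
QC.

What the star-phylogeny simulator does *not* emulate: coalescent
genealogy variance across loci, linked selection, allele-frequency
spectra of real ascertainment, paralog collapse, and sequencing error.
Passing tests therefore demonstrate the estimators' internal
consistency and their behaviour under controlled missingness and LD —
not performance guarantees on any particular empirical dataset.

## Numerical choices and degenerate inputs

* Tie splitting is exact rational arithmetic accumulated in floating
  point; row sums are conserved to 1e-9 by construction and tested.
* Distances use a sentinel larger than any locus length, so an all-`N`
  comparison can never win a nearest-neighbour contest.
* `estimate_c` excludes the structural diagonal and entries with
  `p ∈ {0, 1}` (zero theoretical variance).
* Loci that lose all variation (or every cell) during conversion are
  dropped with a warning; a locus missing in every individual is a
  format error; an individual unpaintable at every locus is a hard
  error naming the individual.
* Counts `y` are rounded half-to-even once, before the chain runs;
  `log Γ` terms come from `scipy.special.gammaln`.
* The >20% sample filter and >5 SNP locus filter are strict
  inequalities; samples are filtered before loci, and missingness is
  recounted in between.

## Known limitations

* c is a single global constant; entry-level variance heterogeneity is
  averaged over, and knife-edge oversplits (ΔlogL < 1) of genuinely
  homogeneous groups occur occasionally at high effective locus counts.
  The c-sweep is the designed mitigation.
* The uniform-bipartition split proposal mixes slowly for populations
  beyond a few dozen individuals; the panel sizes targeted here (tens
  of samples) are well inside its comfortable range.
* Allele dropout correlated with divergence biases co-presence and is
  only partially absorbed by the pairwise missing-data rule; the
  missingness diagnostics exist to surface it, not to fix it.
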