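# Methods

## The problem

Connectivity-based parcellation asks whether a cortical region — here a
frontal-pole-like seed — decomposes into subregions with distinct structural
connectivity. The raw evidence is one matrix per participant: streamline
visit counts from probabilistic tractography between every seed voxel and
every cell of a downsampled whole-brain target grid. Voxels are clustered
not on the counts themselves but on the similarity of their *connectivity
fingerprints*: the substrate for clustering is the seed × seed matrix of
Pearson correlations between count rows, Fisher-Z transformed (arctanh) and
averaged entrywise across participants. Each voxel's feature vector is its
full row of the averaged Z matrix, diagonal included — the constant diagonal
adds no between-row contrast, and keeping the full symmetric row avoids an
arbitrary vectorization choice.

Numerical details of this stage:

* Target downsampling sums counts over non-overlapping blocks anchored at
  the grid origin voxel; a trailing partial block is kept, so row totals are
  conserved exactly. The block size must be an integer multiple of the
  source spacing.
* A seed voxel whose count row has zero variance (no streamlines anywhere)
  has undefined correlations. The default is a hard error naming the voxels;
  an opt-in `drop` mode removes them from the parcellation domain. Silent
  imputation is deliberately not offered.
* Fisher-Z clips |r| at `1 − clip_epsilon` (default 1e-7) so the diagonal
  stays finite while no value with |r| ≤ 1 − 1e-6 changes at float
  precision.

## Parcellation

`kmeans_replicates` runs Lloyd k-means many times (default 1000) from
random data-row initializations (Forgy) and keeps the run with minimal
within-cluster squared point-to-centroid distance. The implementation is
scikit-learn's `KMeans` (`init='random'`, `n_init=n_replicates`,
`max_iter=300`); an exhaustive-bipartition oracle test confirms the
replicated search attains the global optimum on small instances. When data
contain exact duplicate rows (possible at zero synthetic noise) a winning
run can realize fewer than k clusters; the whole replicate batch is then
restarted with fresh centroids, a bounded number of times. No spatial
contiguity constraint is imposed.

Cluster labels carry no meaning across solutions, so comparisons that need
correspondence (symmetry, reporting) pair clusters by maximizing total
voxel overlap on the contingency table (Hungarian assignment). Cluster
centers of gravity are means of member voxel world coordinates under the
mask affine (RAS+, mm); label maps can be dilated by a world-space radius
(2 mm in the protocol), conflicts resolved by nearest labeled voxel and
ties by the lower label id.

## Choosing K: split-half variation of information

For two partitions C, C′ of the same n voxels,

    VI(C, C′) = H(C) + H(C′) − 2 I(C, C′),

with H and I computed from cluster occupancy proportions. VI is a metric on
partitions: zero iff the partitions coincide up to relabeling, symmetric,
triangle inequality, bounded by log(n). It is evaluated internally in the
equivalent conditional-entropy form H(C|C′) + H(C′|C), whose terms vanish
exactly for identical partitions instead of leaving rounding residue.
Logarithms are **base 10** by default — the protocol's printed bound for a
93-participant cohort, 1.96, is log10(93) — with the base exposed for
natural-log conventions. Note the printed bound counts participants, not
clustered voxels; `vi_upper_bound(n, base)` takes whatever element count the
caller means.

The split-half procedure: each of `n_repetitions` (default 100) repetitions
randomly divides the cohort into disjoint halves of ⌊N/2⌋ and ⌈N/2⌉,
averages each half's Fisher-Z profiles, clusters both averages at every K
with replicated k-means, and records the VI between the half-solutions
(relabeling-invariant, so no matching is needed). The same splits serve all
K, making the per-K comparisons paired. Per K the curve carries the mean,
a 95% t-interval, and a one-sided paired t-test of "VI(K) increased over
VI(K−1)" at alpha 0.05. Sidedness is a choice — the protocol's reported
p-values do not state it — and one-sided "increase" matches the wording of
the selection rule. A step with zero variance across repetitions is decided
by its constant sign. No correction is applied for the dependence between
overlapping repetitions, as none is described in the protocol.

The optimal K is the smallest K ≥ 3 whose step test shows no significant
increase. (The protocol states the rule once without and once with the
"greater than 2" qualifier; the qualified form is implemented.) If every
step significantly increases, the largest K is returned with an explicit
no-selection flag.

## Hierarchy and symmetry

The hierarchy index between a K-solution and a (K+1)-solution is the mean,
over clusters of the finer solution, of the largest fraction of each
cluster inherited from a single coarser cluster; 1 means perfectly nested,
and 1/(K−1) is the floor. It is invariant to relabeling of either solution.

The symmetry index mirrors the right-hemisphere mask across the midsagittal
plane (world x → −x; masks are assumed to live in a symmetric standard
space), restricts to voxels present in both hemispheres, pairs right
clusters to left clusters by optimal assignment on that overlap domain, and
reports the fraction of domain voxels whose labels agree under the pairing.

## Tract aggregation and contrasts

Per-cluster tract maps are normalized by the total possible streamline
count (seed voxels × samples per seed voxel — supplied in configuration,
since sampling counts are tool-specific), thresholded at a small proportion
(default 1%, boundary value survives), binarized, and averaged across
participants into overlap maps; voxels consistent in fewer than 50% of
participants are zeroed for display. The contrast of one cluster against
the rest uses the *thresholded but not binarized* maps: per participant the
difference map is (cluster − mean of other clusters); values below the 1%
threshold are zeroed, values above keep their magnitude.

Significance is assessed with a one-sample sign-flipping permutation test
on the mean difference, two-sided, with family-wise error across voxels
controlled by the permutation distribution of the maximum |t|. The identity
flip is included in the null so p-values are never zero, corrected p never
falls below uncorrected p, and larger statistics never receive larger
corrected p. Max-statistic correction replaces threshold-free cluster
enhancement deliberately: TFCE's enhancement integral has two free
parameters the protocol does not pin down, whereas the max statistic gives
exact FWE control under exchangeability with none. Voxels whose difference
is identically zero are assigned t = 0.

## The synthetic cohort

No scan data accompany the protocol, so a generator stands in for the
cohort. It is specified by the property the pipeline needs — voxels of the
same parcel share a fingerprint, so within-parcel count rows correlate more
strongly than between-parcel rows — with signal and noise exposed:

* Each parcel has a fingerprint over targets around a baseline count level
  of 20; `fingerprint_scale` (default 3) sets the between-parcel contrast
  and `noise_scale` (default 1) the s.d. of participant-by-parcel and
  voxel-level Gaussian noise. Draws are mapped to valid streamline counts
  by rounding the absolute value.
* Parcel labels are assigned balanced (sizes within one voxel), every
  parcel realized, shuffled deterministically by `rng_seed`.
* Seed voxels form a compact blob on a 2 mm grid with a left- or
  right-hemisphere affine (the right blob is the exact mirror of the left),
  so center-of-gravity, dilation and mirroring operate on realistic
  geometry.
* A mirrored hemisphere keeps each voxel's label with probability
  `symmetry_level`; exactly round((1−level)·n) voxels are relabeled to a
  *different* parcel. A `hierarchy_split` plants a nested parent → children
  refinement for hierarchy testing.

Two structural choices deserve emphasis, because the split-half selection
rule depends on them. First, fingerprints are *nested*: parcels are grouped
into families of two, one family geometry (heavy-mean center ± a fixed-norm
within-family offset) is drawn once, and every further family is a random
self-inverse permutation of the target axis applied to it. Permutation
preserves all within-family statistics, and self-inverseness makes the
cross-family correlation geometry exactly symmetric too — so every way of
merging families (K below the planted K) or of splitting a single family
(the step past a merge) is *exactly* tied, and only participant sampling
noise can break the tie. Had the fingerprints been drawn independently per
parcel, one merge would always be strictly best, both halves would pick it,
the VI curve would sit at zero for all K ≤ k_true, and the selection rule
would degenerate to always answering 3. The instability of
coarser-than-true solutions is precisely the signature the VI rule detects
in real data, and the generator must reproduce it to be a meaningful
testbed. Second, participant noise is drawn in *antithetic pairs*
(participant 2i's noise is the negation of participant 2i−1's), so the
cohort-mean noise cancels: in a fixed cohort the two halves of any split
have exactly opposite deviations from the cohort mean, and a cohort-level
noise bias would otherwise break the coarse-K ties identically in both
halves of every repetition, hiding the instability the procedure looks
for. Antithetic sampling leaves every marginal distribution unchanged and
is a standard variance-reduction device; here it makes the generated
cohort unbiased by construction.

What the generator does not emulate: spatially smooth fingerprint
gradients, distance-dependent connectivity, head-motion or registration
artifacts, inter-participant anatomical variability, or any diffusion
physics. Passing tests therefore certify the pipeline's statistical
machinery on data with planted truth, not its behavior on real scans.

## Problem sizes and defaults

Desk-scale defaults, chosen once: cohorts of N = 20 participants, 60 seed
voxels, 150 target cells, 4 planted parcels, signal/noise 5:1 where a
strong-signal regime is intended. The split-half procedure in tests uses
25 repetitions with 100 k-means replicates per half (the protocol-scale
100 × 1000 is available through configuration and used by the analysis
drivers where it matters). Null calibration of the permutation test uses
200 simulated datasets of 12 participants × 216 voxels at 500 sign-flips.

## Known limitations

* The optimal-K rule inherits the protocol's asymmetry: it can only ever
  return K ≥ 3, and with a monotonically non-increasing VI curve it returns
  3 regardless of structure.
* The paired t-test treats split-half repetitions as independent samples;
  they share participants, so the effective sample size is smaller than the
  repetition count.
* Mirroring assumes the hemispheres share a grid and a symmetric affine;
  no registration is attempted.
* The generator's exact ties are a stylized stand-in for the near-ties of
  real gradients; real VI curves are noisier and rarely touch zero.
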