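# Methods

This note documents the models and procedures implemented in `neurotf`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Screen scoring

**Enrichment metric.** Guide-level enrichment between two sequenced
populations is `log2((RPM_num + c) / (RPM_den + c))` with reads-per-million
normalization per population and pseudocount `c = 1`. The pseudocount keeps
scores finite in sparse sorted populations (where most guides have zero
counts) and maps 0-vs-0 to exactly 0. The metric is antisymmetric under
swapping numerator and denominator whenever the pseudocounted RPMs mirror
(equal depths).

**Empirical null.** The enrichment threshold is the nearest-rank q-quantile
(default q = 0.9) of the non-targeting control (NTC) guides: the k-th
smallest NTC value with `k = ceil(q·n)`. A guide is *enriched* iff strictly
greater than the threshold. With distinct values this places exactly a
fraction `1 − q` of NTCs above the cutoff — the "empirical FDR < 0.1"
construction. For an independent guide drawn from the same null the exact
false-call probability is `(n + 1 − k)/(n + 1)` (the order-statistic
identity), i.e. 101/1001 ≈ 0.1009 at n = 1000: the printed 10% plus a
finite-null correction of `1/(n + 1)`. The calibration test asserts this
exact expectation rather than the rounded 10%.

**Gene calls.** Per comparison, guides above that comparison's own
threshold are counted per gene; a gene is called at `min_guides = 2`, and
the essential set is the intersection of the two comparisons
(reporter-negative vs. unsorted input, and vs. reporter-positive). Calls
are monotone in `min_guides` and the intersection is a subset of each
per-comparison call set by construction.

**RIGER statistic.** Guides are ranked by enrichment (rank 1 = most
enriched; ties get average ranks) and normalized by library size to (0, 1].
A gene's score is `w1·r(1) + w2·r(2)` over its two best guides with equal
weights 0.5/0.5 (the weighting is exposed as a parameter; equal weights are
the neutral choice where no weighting is prescribed), making the score
invariant to everything below a gene's top two guides. Significance comes
from permuting gene labels over guides: under a uniform permutation a gene
receives a uniform random size-matched subset of the rank pool, so the null
is sampled directly as independent without-replacement draws per gene —
this keeps permutation p-values independent across genes under the global
null (a single shared permutation sequence would correlate them through the
common empirical null and distort uniformity diagnostics). The estimate
uses the +1/+1 correction, `p = (#null ≤ observed + 1)/(n_perm + 1)`, never
zero. For tiny libraries an exact mode enumerates all size-matched subsets
(equivalently, all label permutations up to multiplicity) and returns the
exact fraction. Genes with fewer than two guides are excluded with a
warning.

**Read counting.** Reads are 5'-trimmed at the hU6 promoter adapter
(`TCTTGTGGAAAGGACGAAACACCG`, error tolerance 20%, minimum overlap 5,
minimum remaining length 20), then the first 20 nt are matched to the
library on the sense strand only (the guide cassette orientation is fixed
by the vector) allowing one mismatch; reads matching two guides at one
mismatch are discarded as ambiguous and tallied. This is a pure-Python
implementation adequate for the package's scale; it is exercised against
constructed reads, not benchmarked against aligner output.

## Differential expression

The scientifically meaningful layer is the *call*: a gene changes iff
`|log2FC| ≥ 1` (inclusive), BH-adjusted `p < 0.05` (strict), and the larger
group mean is at least 10 (inclusive), on top of a low-count filter of 50
summed reads across the reference-group replicates. The boundaries are
configurable; inclusivity choices are fixed, documented and tested because
they change calls at exact threshold values.

The test engine behind the p-values is intentionally simple: a
negative-binomial Wald test comparing log group means, with per-gene
method-of-moments dispersion `α = (s² − m)/m²` pooled across the two groups
by degrees of freedom and clipped to [0.01, 10], delta-method variance
`(1/n)(1/(m + 0.5) + α)` per group, and a t reference with `n_a + n_b − 2`
degrees of freedom. The t reference (rather than a normal) compensates for
the noisy small-sample dispersion estimate; simulation shows type-I error
within 1.5× nominal at n = 4 for dispersions up to 0.2. `log2FC` is the
log2 ratio of pseudocounted (+1) group means. Any externally produced DE
table with columns `log2FC, p_adj, mean_a, mean_b` can be substituted — the
module's filters, the time-course assembly and the network criteria only
consume those columns. The delta-method standard deviation of `log2FC` at
4 replicates and dispersion 0.05 is ≈ 0.25 log2 units; recovery tests
therefore assert unbiasedness of the estimate and near-certainty of the
*call*, not unrealistically tight per-replicate fold-change precision.

The low-count filter is applied to the reference (baseline) group, and the
expected-count floor to the larger of the two group means, so that genes
silent at baseline but strongly induced are testable.

## Regulatory features

All intervals are 0-based half-open; adjacent intervals do not overlap, and
this boundary behavior is tested explicitly. Peaks overlapping a blacklist
interval by ≥ 1 bp are removed. Consensus peaks merge transitively
overlapping peaks across samples and are retained when supported by at
least `min_samples = 2` distinct samples, with per-sample counts recomputed
as sums over member peaks.

A TF gene's cis-regulatory region (CRE) is its gene body plus a 2 kb
strand-aware upstream window, clipped at the chromosome origin. Peaks are
assigned to CREs on any ≥ 1 bp overlap by default; a containment mode
restricts to peaks lying fully inside the CRE (strict containment drops
boundary-spanning peaks, which is why overlap is the default).

**PWM p-values.** Motif hits require a log-odds score (uniform background
by default, configurable) whose background tail probability is ≤ 5×10⁻⁵.
The threshold is computed exactly: per-position scores are discretized at
granularity 10⁻³ log-odds units and the full background score distribution
is built by dynamic programming (convolution of L four-point
distributions); the threshold is the smallest grid score with tail ≤ p.
Scanning uses the same integer grid, so threshold semantics and scan
semantics agree exactly; the DP tail is verified against brute-force
enumeration of all 4^L words. Degenerate matrices whose maximal score is
still too probable (e.g. a uniform PWM) return an infinite "no hit
possible" sentinel. `N` bases contribute a log-odds of 0 (background) and
cannot create hits on their own. Both strands are scanned; reverse-strand
hits are computed on the reverse complement and reported at their
forward-strand left edge, making the hit set invariant (up to strand
relabeling) under reverse-complementing the input.

**Pair features.** For each (regulator, target) pair — regulators
restricted to motif-bearing TFs — the supporting peaks are those assigned
to the target's CRE that carry ≥ 1 hit of the regulator's motif; reads are
summed over supporting peaks and all replicates per timepoint. Every pair
of the cross product is materialized, with `has_motif = False` and zero
reads when unsupported, so downstream criteria can treat "missing evidence"
uniformly. Replicate handling (summing across replicates at a timepoint) is
a documented choice; the downstream 50-read floor is calibrated to summed
reads.

**ChIP proximity.** Enrichment of ChIP binding near up- vs. down-regulated
genes uses the same CRE definition (window = 2 kb upstream, matching the
CRE convention since "proximal" is otherwise unquantified): the fold is the
ratio of the fractions of genes whose CRE overlaps ≥ 1 ChIP peak, with a
two-sided Fisher exact p on the 2×2 table, and a NaN sentinel when both
fractions are zero.

## Network inference

Edges are rule-based, not probabilistic. At each network timepoint
(default 12h, D1, D4 vs. an ESC baseline):

1. the target must be called up or down vs. baseline (the DE call above,
   recomputed from the raw DE columns at the configured thresholds so that
   threshold relaxation re-derives calls consistently);
2. the regulator must have been *up*-regulated at a previous network
   timepoint and carry a motif — with the seed regulators (NEUROG1/2,
   driven by induction rather than by the network) eligible throughout.
   "Previous" defaults to the cumulative union of earlier network
   timepoints; a `previous-only` window restricts to the immediately
   preceding one (both modes are tested — the cumulative default reflects
   that induction persists, so a TF up at 12h remains a plausible regulator
   at D4);
3. the pair's summed ATAC reads must strictly exceed 50 at the timepoint
   *and* strictly exceed the pair's summed reads at the ESC stage (this
   removes constitutively open chromatin that is not differentiation
   specific). Both inequalities are strict and boundary-tested.

Edge sign follows the target's direction (up = activating, down =
repressing). Unique-interaction totals deduplicate (regulator, target,
sign) across timepoints. The builder is verified edge-for-edge against a
brute-force evaluator that literally re-checks the three criteria per pair
per timepoint on random small instances, and monotonicity under uniform
threshold relaxation is enforced by contract: a "relaxed" configuration
must be no stricter in every component, otherwise the superset guarantee
does not hold and the call errors out.

Out-degree comparisons between early and late TF sets use unique-target
out-degrees over the deduplicated network and a Welch two-sample t-test;
the zero-variance degenerate case reports NaN for t.

## neTF characterization

**Clustering.** Per-TF log2FC profiles (baseline column included) are
centered and scaled by `max(sd, 0.25)` before k-means (k = 4, best of 50
seeded initializations). The scale floor — a quarter of one 2-fold change —
is what lets an essentially flat profile form its own coherent cluster:
plain z-scoring would inflate a flat TF's measurement noise to unit
variance and scatter the "no-change" archetype across clusters. Cluster
indices are renamed by centroid shape, computed on the mean *raw* profile
per cluster: D = flattest (smallest range); C = rise-then-fall (peak
strictly before the final timepoint and final value below half the peak,
falling back to the strongest peak-to-end decline if no cluster meets the
rule); A = earliest half-maximum rise time (linearly interpolated) of the
remaining pair; B = the other. Ties resolve deterministically by rise time
then amplitude. The mapping heuristic and its thresholds are this package's
own operationalization of qualitative archetype descriptions, and are
configurable.

**Resampling enrichment.** Overlap of a query set with a category is
compared to `n = 10⁴` size-matched sets drawn without replacement from the
declared universe; `p = (r + 1)/(n + 1)` with `r` the number of null draws
≥ the observed overlap, and fold = observed / null mean. On small universes
the empirical p agrees with the exact hypergeometric tail within
Monte-Carlo error.

**Accessibility by cluster.** Per regulator and timepoint, supporting-peak
read sums are normalized to reads-per-million using the timepoint's ATAC
library size and averaged over the regulator's supported targets; cluster
profiles average over member TFs, and the headline ratio compares cluster A
to the mean of B and C at the final timepoint. RPM normalization makes the
profile invariant to sequencing-depth rescaling, and the normalization is
recorded with the output.

**Hierarchy.** Cross-cluster edge counts use unique (regulator, target)
pairs; `A→(B∪C)` and `(B∪C)→A` are reported alongside per-cluster
network-presence fractions as regulator, as target, and as either (the
definition of "present" being ambiguous, all three are reported).
First-order subnetworks contain a focal set plus neTFs with a direct edge
to or from it, with edges restricted to those incident to a focal TF.

## Synthetic data: what it emulates and what it does not

The generator's defaults encode the study conditions: a library of 1891
TFs × 10 guides + 1000 NTCs; log-normal(0, 0.5) baseline guide abundances
(reproducing a narrow plasmid distribution); a sorted-negative population
in which essential-TF guides gain a 20-fold abundance factor while other
targeting guides survive the sort gate with probability 0.05 (so ~90% of
guides are lowly represented or absent, matching the phenomenology of a
stringent reporter-negative gate without modeling FACS optics); multinomial
sampling at 10⁶ reads per population; negative-binomial expression and
ATAC counts with dispersion 0.1, 4 expression replicates and 2 ATAC
replicates per timepoint. The toy genome allocates one gene per 10 kb slot
(4 kb body, alternating strands) on a uniform-composition chromosome, with
length-8 one-dominant-base PWMs (0.85/0.05) whose exact consensus is
planted once per planted edge in a 200 bp peak-sized window inside the
target's CRE, upstream positions first. At the 5×10⁻⁵ threshold only the
exact consensus of such a PWM scores above cutoff, which makes planted-hit
recovery deterministic and keeps the background false-hit rate below the
nominal p.

Planted expression profiles use a 4-fold effect: regulators rise one
timepoint before their edge's onset, activated targets rise (repressed
targets fall) from the onset, and planted peaks switch from a mean of 5 to
100 reads per replicate at the onset — sized so the 50-read criterion-3
floor is passed with large margin at the stated dispersion. Problem sizes
in tests (20–50 TFs for network runs, full 19,910-guide libraries for
screen scoring) are chosen so every recovery check runs in seconds while
exercising the full code path.

Not emulated: FACS optics and gating noise, doxycycline kinetics,
cell-cycle and fitness interactions beyond a simple dropout factor,
read-level sequencing error, fragment-length structure of ATAC libraries,
correlated guide efficacies, GC-dependent motif background, and overlapping
gene models. Passing recovery tests therefore demonstrates correctness of
the computational procedures under a faithful but idealized data-generating
process — not robustness to every artifact of real sequencing data.

## Known limitations

* The NB Wald engine is a deliberately simple stand-in for a shrinkage
  estimator; at very low counts or tiny replicate numbers its dispersion
  estimate is coarse (hence the floor and the t reference). Slotting in
  external DE tables is the supported path for production analyses.
* The read counter is exact but not optimized for billions of reads.
* Self-pairs (a TF regulating itself) are retained in the pair cross
  product; callers can drop them if their design excludes autoregulation.
* The A–D labeling heuristic assumes one cluster per archetype (k = 4);
  for other k the clusters are labeled generically and shape mapping is
  skipped.
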