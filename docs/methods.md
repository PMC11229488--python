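# Methods

## Scope and coordinate conventions

phbreak analyses genomic (DNA-level) breakpoints of reciprocal
translocations with two plus-strand partner genes, modeled on the
t(9;22) *BCR::ABL1* fusion. Internally all coordinates are 0-based (single
bases) with 0-based half-open regions; every file interface (cohort TSV,
region catalog) is 1-based inclusive to match GRCh38 notation as used in
the clinical genetics literature. BED output is 0-based half-open as the
format requires. A breakpoint pair stores, for a forward fusion, the last
chr22 base retained on the derivative 22 and the first chr9 base retained;
for a reciprocal fusion, the last chr9 base and the first chr22 base on the
derivative 9. Strand generality is deliberately out of scope: both *BCR*
and *ABL1* are plus-strand, and the arithmetic below assumes it.

## Junction decomposition and canonicalization

A junction-spanning sequence is decomposed by maximal contiguous prefix
(*p*, against partner A) and suffix (*s*, against partner B) extension from
seed anchors (default minimum anchor 12 bases; shorter anchors raise an
"unanchored junction" error, which is how complex events — inserted
third-chromosome sequence, chromosome-9 fragments inserted into the
BCR-analog — are flagged rather than mis-called). The three NHEJ signatures
are mutually exclusive by construction: `p + s` equal to, greater than, or
less than the fusion length gives blunt, microhomology (length
`h = p + s − |F|`), or untemplated insertion. For insertions the
decomposition `F[p : |F|−s]` is the *unique* minimal-length insert over all
explanations, because any explanation uses a prefix ≤ *p* and a suffix
≤ *s*; the test suite verifies agreement with an exhaustive enumeration
oracle on 10,000 uncontrolled random instances.

Within a microhomology window the crossover is ambiguous over `h + 1`
placements. The canonical breakpoint is the **leftmost** (5′-most)
placement on both partners, matching common SV normalization practice; no
convention is stated in the clinical literature for these fusions, so all
±1 bp / ±100 bp window comparisons are convention-stable only up to `h`.
IUPAC ambiguity codes in references are treated as mismatches (even against
an identical code), which makes homology calls conservative.

## Split-read caller

References are region-sized (≤ a few hundred kbp), so the caller uses an
exact 12-mer index with mismatch-counting extension along candidate
diagonals rather than an external aligner — fully deterministic and
dependency-free. Per read, the split `(j, m)` (head takes `read[:j]`, tail
takes `read[m:]`, insert `read[j:m]`) minimizes
`mismatches + 0.6 · insert_length`; the 0.6 insert-base cost sits below the
0.75 expected cost of forcing a random insert into alignment and above
realistic per-base error rates, so true inserts are preferred over noisy
splits and isolated sequencing errors stay mismatches. If the unconstrained
optimum violates the mismatch-rate filter (default 5% of aligned bases) a
constrained search over all feasible splits is used — without it, a long
untemplated insert that partially chance-aligns to a reference would get
its reads discarded entirely. Both orientations are scored (head on
partner A = forward-type junction; head on partner B = reciprocal-type);
ties between distinct junctions discard the read as multi-mapping.

Votes are leftmost-canonicalized, clustered within a ±3-base Chebyshev
window (absorbing canonicalization jitter from errors near the junction), a
consensus junction is built by per-column majority over the cluster's
reads, and the consensus is classified by the junction decomposition above,
which yields the final coordinates and mechanism. Clusters whose consensus
canonicalizes to the same junction are merged before the minimum-support
filter (default 2 reads) — vote scatter from chance-aligned insert bases
can otherwise split one junction's reads across nearby clusters.

## Synthetic cohorts

The generator emulates a two-gene fusion study at desk scale:

* **Toy reference.** A chr22-analog carrying minor (20 kbp), Major (3 kbp)
  and micro (1.3 kbp) breakpoint-cluster-region analogs and a chr9-analog
  with a single 40 kbp acceptor region, each flanked by 22 kbp pads so that
  large reciprocal deletions/duplications and read flanks never leave the
  sequence. Region lengths are configurable; real regions (71.5 / 3.2 /
  1.3 / 155 kbp) are scaled down only where it keeps simulation fast
  without changing any tested property.
* **Cohort composition.** 54% ALL-analog / 46% CML-analog; CML is 97%
  Major-BCR, ALL 75% minor-BCR — mirroring the p210/p190 split of the two
  diseases. ALL ages are 68% ≤ 16 years; CML ages are predominantly adult.
* **Breakpoint densities** are piecewise-constant over 10 equal sub-bins
  per region (user-editable). Defaults: minor-BCR skewed to the 3′ end in
  both groups; Major-BCR leaning 5′ in CML; the ABL1-analog 5′-skewed in
  CML and 3′-skewed in ALL (linear 1.5→0.5 vs 0.5→1.5 bin weights), which
  is what drives the between-group KS difference. In ALL minor-BCR
  patients older than 16 the profile is blended 30% toward its reflection,
  planting the moderate age effect the covariate screen looks for.
* **Mechanism mixture** defaults to the published cohort fractions
  48.6 / 36.6 / 12.4 (%) for microhomology / blunt / insertion,
  renormalized over the three simple-junction classes (the published
  percentages leave a 2.4% remainder of complex events that are out of
  scope). Homology lengths are geometric(p = 0.5) truncated at 71 bp
  (median 1); insert lengths geometric with continuous-sense median 2.5 bp
  capped at 42 bp, matching the published medians and ranges.
* **Microhomology realization.** The drawn homology k-mer is injected into
  the chr9-analog immediately 5′ of the acceptor breakpoint (copied from
  the chr22 flank) *before* sequences are emitted, and both boundary bases
  are fixed so the realized window is exactly the drawn length; blunt and
  insertion junctions get their boundary bases constrained so no accidental
  homology or absorbable insert edge arises. Every constrained chr9
  position is reserved so later patients cannot disturb it (sites are
  rejection-resampled on conflict, with retry counts reported). This makes
  ground truth exact: the classifier recovers 100% of mechanisms, lengths
  and canonical coordinates on error-free data, which is the identity the
  acceptance checks assert. Junction flanks are 100 bp so even a 71-bp
  homology leaves a 12-base anchored prefix.
* **Reciprocal fusions.** With probability `1 − p_imbalance` (default
  p_imbalance = 0.9) the pair is perfectly balanced (adjacency); otherwise
  each chromosome independently (0.75 each, at least one) draws a signed
  delta: 85% small (geometric, mean 30 bp) and 15% large (log-uniform
  100 bp – 20 kbp), deletions with probability 0.7. This reproduces the
  qualitative picture of mostly (near-)balanced translocations with a rare
  >10 kbp deletion/duplication tail; exact published counts depend on the
  real cohort's ascertainment and are not a simulation target.
* **Reads.** Junction-spanning, plus-strand, uniform split position with at
  least the caller's minimum anchor on each side, independent per-base
  substitution errors, constant quality; no indel errors, PCR duplicates,
  off-target reads or capture bias (so caller results on synthetic data
  bound real-data performance from above). All randomness flows from one
  seed through `numpy.random.SeedSequence` spawning.

Because the generator plants exactly the features the pipeline measures,
green tests demonstrate correctness of the *algorithms and arithmetic* —
recovery of known truth, agreement with brute-force oracles, calibrated
error rates — not performance on real capture data, whose artifacts
(coverage bias, duplicates, complex rearrangements) are declared out of
scope.

## Statistics

* **Uniformity**: Pearson chi-squared against the equal-bin uniform
  expectation, df = bins − 1. Auto-binning picks the largest equal-width
  bin count with expected count ≥ 5, capped at 100 bins; an explicit bin
  width is refused if any expected count falls below 1. Published
  chi-squared p-values for these regions depend on an unstated binning and
  are therefore only order-of-magnitude comparable.
* **Two-sample KS**: `scipy.stats.ks_2samp`; asymptotic p by default
  (standard practice at cohort scale), exact computation available and
  selected automatically for n_A·n_B ≤ 10,000 under `method="auto"`. The
  statistic is invariant under monotone coordinate transforms, so it is
  binning-free — which is why between-group comparisons are the
  numerically reproducible quantity.
* **Covariate screen**: logistic regression of the binary class on the
  min-max-normalized position, likelihood-ratio test against the
  intercept-only model (for a single-predictor logit the symmetric
  direction gives the same LRT p). Complete separation is flagged and the
  LRT statistic taken at the saturated bound.
* **Motif proximity**: observed = breakpoints within ±10 bp (default) of
  any hit after deduplicating and merging hit windows; null = breakpoints
  redrawn uniformly in the region (`n_perm` ≥ 1,000), upper-tail p with
  add-one correction, Benjamini–Hochberg across motifs per run. A
  density-matched null (resampling from the breakpoints' own 10-bin
  profile) is provided to separate motif attraction from regional
  non-uniformity. The permutation p is discrete, so realized type-I error
  sits at the largest achievable level ≤ α — slightly conservative
  (typically 3–5% at α = 5% in the calibration runs).

Calibration measurements use cohort-scale samples (n = 1,000 per
replicate for the uniformity null, where the 100-bin cap keeps every
expected count at 10; 100 breakpoints per replicate against a ~20%-coverage
hit set for the proximity null) so that the chi-squared approximation and
the permutation discreteness both operate in their intended regimes.

## Reciprocal balance arithmetic

With the retention conventions above, `delta22 = pos22_r − pos22_f − 1` and
`delta9 = pos9_f − pos9_r − 1`; adjacency (no base lost, none duplicated)
is the balanced case, positive deltas count bases on neither derivative
(deletion), negative deltas bases on both (duplication). "Perfectly
balanced" = both deltas 0; "±1 bp" = |delta| ≤ 1 on both; "±100 bp" is
per-gene. The −1 adjacency offset and the deletion-positive sign are
package conventions (the literature does not formalize them); the test
suite proves the closed form equal to explicit retained-base-set counting
on random pairs. The 10 kbp "large event" threshold is a named,
configurable constant.

## Motif scanning

IUPAC patterns are matched with a per-position allowed-character table and
a mismatch allowance, on both strands (minus strand via the
reverse-complement pattern, coordinates on the plus strand). RSS scanning
requires heptamer (consensus CACAGTG) and nonamer (consensus ACAAAAACC)
with a 12- or 23-base spacer (± configurable slack, default ±1 in the
shipped catalog) and per-element mismatch allowances, either orientation —
a consensus-match scanner, not a RIC-style information score. The shipped
motif config is a small illustrative subset (topoisomerase II consensus,
immunoglobulin switch pentamers, chi-like, RSS 12/23); published break-motif
catalogs can be supplied as YAML.

## Report

The report stage is plumbing: it copies stage outputs into one
deterministic JSON document (content hash + seed + version as provenance)
and renders a dependency-free HTML page with inline-SVG histograms and a
junction-structure pie. Missing stages are marked absent, never recomputed.

## Problem sizes and determinism

Default verification sizes: 2,000 patients for mixture recovery, 500 for
caller identity (20 error-free / 30 noisy reads per junction at 0.5%
error), 10,000 random pairs and instances for the delta and decomposition
oracles, 1,000 replicates for type-I calibration and 200 for KS power at
400 + 400. These sizes give 3-SE binomial resolution on the mixture and
sub-percent resolution on error rates while keeping a full verification
run in the minutes range on one CPU. Every stochastic component takes an
explicit seed and is reproducible bit-for-bit; derived seeds are spawned
via `SeedSequence` so stages are independently reproducible.

## Known limitations

* Both partners plus-strand; no inversions, no liftover, no SAM/BAM/VCF.
* The caller targets region-sized references and junction-spanning reads;
  it is not a general-purpose SV caller and does not model paired-end
  insert sizes, duplicates or capture artifacts.
* Homologies are reported verbatim up to 71 bp; distinguishing long
  "homologies" from templated insertions is left to interpretation.
* Complex events (third-chromosome inserts, nested fragments) are flagged
  unclassifiable, not resolved.
* Exact published cohort counts (reciprocal concordance percentages,
  chi-squared p-values) require the original patient table; with such a
  table ingested via `read_cohort_table`, the same operations reproduce
  binning-free quantities (KS, concordance counts) directly.
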