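# Methods

## The statistic

For two populations genotyped at the same markers, every sliding window of
`window_size` consecutive SNPs (default 50, step 1, never crossing a
chromosome boundary) yields one correlation matrix per population whose
entry (i, j) is the *signed r²* of markers i and j: sign(r)·r², with r the
Pearson correlation of the two dosage columns over pairwise-complete
samples (composite LD on unphased genotypes — no phasing is ever
required). The window score is the L1 distance between the two
descending-sorted eigenvalue spectra,

    S(w) = Σᵢ |λᵢ(A) − λᵢ(B)|.

Both matrices have unit diagonal, so each spectrum sums exactly to the
window size; the plain difference of traces is identically zero, which is
why the score takes absolute differences of the *ranked* eigenvalues. The
form makes S a proper metric (symmetric, non-negative, triangle inequality
from the ℓ¹ norm on sorted spectra), and those properties are tested.

Raw scores are standardized genome-wide within a comparison — std = (raw −
mean)/sd with the sample sd (n−1) — so thresholds are comparable across
population pairs with different background LD. Windows with standardized
score at or above the empirical 99.9th (and 99.99th) percentile are
flagged; flagged windows whose 50-SNP index ranges overlap or abut merge
into one signal region whose boundaries are the mid-bp (rounded mean of
first/last SNP position) of its first and last windows. Single-window
signals therefore have start = end; real scans produce such point signals
and that is intended.

Monte Carlo significance is available by pooling the individuals,
reassigning them at random to two groups of the original sizes, and
recomputing raw scores; the per-window p-value is
(1 + #{permuted ≥ observed})/(n_perm + 1). In a permuted split a rare
allele may land entirely in one group; those columns are treated as
zero-correlation inside the replicate rather than aborting it (the
observed scan is strict and rejects monomorphic columns).

## Assignment and annotation

A signal region is assigned to the population with the larger mean pairwise
r² over the SNPs inside [start, end] (both bounds inclusive; all
coordinates in the package are 1-based inclusive; BED files are converted
from 0-based half-open on read and back on write). The margin is the
difference of the two means. Regions holding fewer than two retained SNPs
are reported `unassigned` — this genuinely occurs when the sweep itself
fixed most local markers so that they fell to the MAF filter. Exact ties go
to the first population with a `tie` flag and a warning.

Gene and CNV annotations are plain interval tables; a (region, annotation)
pair is reported when the intervals share at least one base, with the
overlap length. Coverage sums the union of the called regions and divides
by the summed chromosome lengths (inferred as the maximum observed marker
position unless given).

## Quality control

Filters run per population in the order sample call rate → SNP call rate →
MAF → HWE → relatedness, and the whole pass repeats until a fixed point so
that the output jointly satisfies every threshold; `apply_qc` is therefore
idempotent by construction and the report attributes each removed record to
the first filter that caught it. Defaults: MAF ≥ 0.05, call rate ≥ 0.90 on
both axes, HWE p > 10⁻⁶, kinship ≤ 0.8.

The HWE test is the 1-df goodness-of-fit chi-square (equivalently the
squared z-test) at the sample allele frequency; monomorphic columns return
p = 1. The relatedness estimate is the frequency-weighted kinship
K[i,j] = meanₖ (gᵢₖ−2pₖ)(gⱼₖ−2pₖ)/(2pₖ(1−pₖ)), which has expectation ≈ 1
for duplicates and 0 for unrelated individuals under HWE; because pₖ is
estimated from the sample, entries carry the usual −1/(n−1) centering bias,
which is irrelevant at the 0.8 pruning threshold. Pruning is greedy on the
largest remaining pair, dropping the lower-call-rate member (ties:
lexicographically later id) — deterministic, and it keeps the
better-genotyped individual.

Population structure follows the classical route: kinship →
D²[i,j] = K[ii] + K[jj] − 2K[ij] → Torgerson MDS (double-centre,
eigendecompose, scale eigenvectors by √λ). Negative eigenvalues — non-
Euclidean noise of the kinship estimate — are dropped from both the
coordinates and the explained-variance denominator; each coordinate column
is signed so its largest-magnitude entry is positive, making plots and
tests reproducible.

## File formats and allele conventions

Dosages count copies of `allele_b`, defined as the lexicographically later
allele character — deterministic without an external frequency reference.
When two datasets are intersected (on chromosome + position), a marker whose
alleles are swapped between them has the second dataset recoded d → 2−d;
markers whose allele sets differ beyond a swap are dropped. A/T and C/G
swaps are treated as plain swaps, not strand flips — correct for
single-platform or simulated data, a documented limitation otherwise.
PED text cannot record an allele that never occurs, so a marker observed
with a single allele gets a synthesized partner (`z`, sorting after every
base code) and reads as dosage 0; round-trip identity of dosages holds for
every marker at which both alleles are observed.

## The simulator

The generator is a founder-copying (haplotype-mosaic) model, chosen over a
coalescent simulator because the pipeline needs controllable LD structure,
not demographic realism. Per marker, an allele frequency is drawn uniform
on [maf_floor, 1 − maf_floor] and shared by both populations (giving
cross-population frequency correlation); each population then draws its own
pool of founder haplotypes at those frequencies, and every sample haplotype
copies a founder, switching to a random founder after each marker interval
with probability `switch_prob`. Lower switch probability → longer founder
segments → slower LD decay; background r² is capped by founder sharing at
roughly 1/n_founders.

A sweep is a regional collapse of the copying pool: inside the interval,
founder indices map into a residual subset (default 2 of 30). Haplotype
diversity collapses, regional LD rises in that population only, and markers
on which the residual founders agree become monomorphic there — exactly the
sites a real chip loses to the MAF filter inside a sweep. The residual pool
is required to be ≥ 2 because an LD-based scan is blind to fully fixed
markers.

Defaults (the study conditions used by the tests and the acceptance
script): 2 populations × 150 samples; 2 chromosomes × 5,000 markers; mean
marker spacing 7,900 bp (typical of a high-density bovine chip after QC);
30 founders; switch probabilities 0.05 vs 0.15, reproducing the
slow/fast decay contrast between taurine- and indicine-like populations at
a qualitative level; founder frequencies uniform on [0.1, 0.9]; missing
rate 0.002; one 300-kb sweep (chr 1, 20.0–20.3 Mb) in POP1 with residual
pool 2. With ~7.9 kb spacing a 50-SNP window spans ~400 kb, so the 300-kb
sweep drives several overlapping windows.

What the simulator does *not* emulate: realistic site-frequency spectra,
mutation/recombination-rate variation, ascertainment bias of chip design,
admixture, or genuine pedigree structure. Passing the recovery tests shows
the scan detects regional LD-pattern collapse at realistic marker density
and sample size — not that it would attain any particular power on a given
real dataset.

## Numerical choices and edge cases

* Correlations are computed by masked cross-products (vectorized
  pairwise-complete), clipped into [−1, 1]; a pair with < 2 complete
  samples or zero variance on its joint support yields NaN, which counts as
  zero contribution in window means and is an error inside scan windows
  (monomorphic markers must be filtered first — `run_comparison` does this
  after intersection).
* Eigenvalues via `numpy.linalg.eigvalsh` (symmetric solver); conservation
  Σλ = window size holds to ~1e-12 and is asserted at 1e-8.
* Percentile thresholds use linear interpolation between order statistics.
* Window midpoints use the arithmetic mean of the first/last SNP bp —
  insensitive to uneven spacing; the median SNP position is a noted
  alternative.
* The permutation-null uniformity check runs on non-overlapping windows
  (step = window size): with step 1 adjacent windows share 49 SNPs and
  their p-values are strongly dependent, so a KS statistic against the
  uniform has no calibrated reference.
* Degenerate inputs raise typed errors: empty marker intersection, constant
  raw-score tracks (e.g. scanning a dataset against itself), all-removed QC
  output, regions exceeding chromosome bounds.

## Problem sizes

The shipped analyses and checks run at 150 + 150 samples and 5,000–10,000
markers — about one bovine chromosome's worth of high-density chip data —
which keeps a full scan at a few seconds per 10,000 windows and the
20-seed recovery study at a few minutes on one CPU. All stages are linear
in windows and quadratic only inside the 50-SNP window, so genome-scale
input (~500k SNPs) is a matter of wall-clock, not memory.

## Known limitations

* Kinship pruning approximates the GenABEL-style IBS relationship with the
  frequency-weighted estimator; the absolute scale of a 0.8 cutoff depends
  on the weighting, so thresholds ported from other software should be
  re-examined on the kinship histogram.
* No strand flipping: datasets typed on different platforms need external
  harmonization first.
* Two-population contrasts only; multi-population panels are handled as
  all pairwise comparisons, not as a joint score.
* The scan requires markers polymorphic in both populations, so sweeps
  that fixed nearly all local markers shrink their own signal support —
  visible in the occasional `unassigned` region.
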