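# Methods

`barcodesv` detects structural variants (SVs) by locally aligning two
densely-labelled optical-DNA-mapping intensity profiles ("barcodes") with a
length-constrained hidden Markov model, and reporting the significantly
matching sub-barcode pairs. Insertions, deletions, inversions, repeats,
translocations and their combinations all appear as characteristic patterns
of matched intervals, so no SV type needs to be assumed in advance. This
note records the model, the synthetic-data generator, the numerical choices,
and the places where the design was genuinely open.

## The alignment model

Let the query barcode be `Q = a_1..a_q` and the reference `D = b_1..b_d`,
both z-normalized. The state space has `2q + 2` states: a forward match
state `M_i^+` and a reverse match state `M_i^-` per query pixel, one flank
gap state (unaligned barcode ends, unconstrained length) and one joining gap
state (unmatched reference between aligned segments, minimum length `l_G`).
A path assigns one state per reference pixel. Valid paths partition the
reference into gap runs and *diagonal match runs*: within a run the query
index advances by +1 (forward) or −1 (reverse) per reference pixel, and a
run must span at least `l` pixels. Two runs may abut directly ("silent
re-entry"), which is how a deletion or a translocation with no unmatched
reference between the pieces is expressed.

Emissions: match state `M_i` emits `b_t ~ Normal(a_i, sigma_e^2)`; gap
states emit from the standard normal background (the marginal law of a
z-normalized barcode). Transitions: a match run continues with `p_MM`, a gap
run with `p_GG`; leaving a gap enters any of the `2q` match states
uniformly, which is what allows jumps to arbitrary diagonals and hence
repeats and translocations; the residual mass at a match exit is split
evenly between the joining gap, the flank gap and silent re-entry.

Decoding is exact Viterbi in log space. The minimum-run-length constraints
are enforced by *block entry*: entering a match run consumes its first `l`
pixels in one step (a joining gap likewise consumes `l_G`), with the
emission sums of all candidate blocks available from diagonal prefix sums
of the emission matrix. The decode is `O(q d)` time and memory; a 500 x 550
comparison takes a few tens of milliseconds.

An exhaustive oracle (`brute_force_align`) enumerates every valid run
structure for tiny instances (`q*d <= ~200`) and scores it with the same
model; the test suite checks exact score and path agreement with the DP on
200+ random instances. The two implementations sum identical terms in
different orders, so scores are compared at 1e-8 absolute tolerance.

## Parameters

| name | default | meaning |
|---|---|---|
| `p_MM` | 0.51 | match-run continuation probability |
| `p_GG` | 0.31 | gap-run continuation probability |
| `l` | 44 px | minimum match-run length (22 kb at 0.5 kb/px; shorter matches are not physically meaningful at this resolution) |
| `l_G` | 5 px | minimum joining-gap length (just above the PSF width) |
| `sigma_e` | sqrt(0.2) | match emission SD on z-scores; `sigma_e^2 = 2*nl` is the residual variance between two unit-variance profiles with correlation `1 − nl`, at an assumed working noise level `nl = 0.1` |
| `g` | 5 px | post-processing merge radius (~2.5 PSF widths; gaps below the PSF scale are not physical) |
| `p_thresh` | 0.01 | significance threshold on the per-segment p-value |
| `rescale_halfwidth` | 0.02 | half-range of the fine factor scan |
| `rescale_step` | 0.005 | grid step of the fine factor scan (9 factors) |

Pixel scale defaults: 0.5 kb/px with a Gaussian PSF of 2 px (~1 kb), the
standard operating point of dense-labelling nanochannel experiments.

## Pipeline

1. **Initial rescale factor.** Separate molecules stretch differently in
   nanochannels, so the query is globally length-rescaled. If the factor is
   unknown it is estimated by scanning a coarse grid (0.80–1.20, step 0.01):
   for each candidate the query is interpolated, and scored by a
   matrix-profile AB-join — the z-normalized Euclidean distance of every
   `l`-pixel window of the rescaled query to its nearest reference window,
   in both orientations — taking the mean of the 5 smallest profile values.
   The window length equals `l` so the profile is sensitive exactly at the
   scale of usable matches. If even the best score exceeds a simulated
   random-pair threshold the estimate is flagged low-confidence and 1.0 is
   used. For simulated data the scan is bypassed with the known factor.
2. **Viterbi decoding** per factor on the fine grid
   `factor0 * (1 ± 0.02)`, step 0.005.
3. **Factor selection** by `length * dist` of the longest decoded segment
   (`dist` = Pearson correlation of the paired sub-barcodes, computed in
   the rescaled frame). Alternatives were evaluated and rejected: a
   length-weighted sum over segments rewards spurious tiling at wrong
   factors; selection by path log-likelihood and by length-weighted mean
   dist both discriminated worse. A known limitation remains: linear
   interpolation smooths noise slightly, so `dist` at off-unity factors is
   inflated by a fraction of a percent, and adjacent factors differ by only
   ~2.5 px of cumulative drift over 500 px — below the PSF — so the
   selected factor is occasionally 1–2 grid steps off (measured ~87–92%
   within one step at noise 0.1).
4. **Merging.** Same-orientation segments whose facing edges are within `g`
   pixels on both axes *and* whose diagonals agree within `g` are merged to
   a fixed point. The diagonal condition is not part of the original rule
   set but prevents merging adjacent-but-offset segments, which would
   corrupt the merged pair's correlation; it can be disabled.
5. **Significance.** Each merged segment's `dist` is converted to an
   add-one-smoothed Monte-Carlo p-value, `p = (1 + #{null >= dist})/(n+1)`,
   and compared with `p_thresh`. Failing rows are kept in the output table,
   only flagged.

### The null model: why max-over-placements

Two nulls are implemented. The *pair* null draws the Pearson correlation of
one pair of independent PSF-convolved random barcodes per sample, for each
length on a 25–500 px grid. It is the textbook null for "are these two
fixed intervals correlated?", and it is the null against which the p-value
uniformity, mean and variance properties are tested.

It is, however, the wrong null for a *decoded* segment: the aligner
maximizes over roughly `2 q` candidate placements per reference window, so
the best spurious 44-px window between two unrelated 500-px smooth profiles
typically correlates at ~0.9, and the pair null (99th percentile ~0.6 at
that length) passes essentially every spurious segment — on unrelated
pairs the pipeline then reports ~8 "significant" segments per comparison.
The default *max* null therefore draws, per sample, the maximum window
correlation over all placements and both orientations between two fresh
random barcodes of a fixed 500-px comparison context — the same search the
decoder performs — for lengths on a coarser grid (44–500 px, 9 points;
decoded segments are never shorter than `l` = 44). With it, unrelated pairs
produce no significant segments, while genuine long matches
(`dist ~ 0.9` at 150+ px against a null maximum of ~0.5–0.6) pass
comfortably. The price is reduced power for short segments: a 50-px true
match at noise 0.1 sits near the null maximum for its length and is
sometimes flagged non-significant. That trade-off is intrinsic — at the
PSF resolution a 50-px window has only ~20 independent degrees of freedom —
and it is what drives the post-threshold TPR of inversion/translocation
blocks below that of insertions and deletions. p-values are calibrated for
comparisons at the ~500-px scale; the context length is configurable.

Production null models use `n = 500` samples per length (minimum attainable
p-value 1/501 < `p_thresh`), built once per process and cached.

## Synthetic data generator

The generator emulates the benchmark construction used throughout:

- **Random barcode**: i.i.d. standard Gaussians convolved with the Gaussian
  PSF, z-normalized. `3*psf` padding is generated on each side and trimmed,
  so there are no filter edge artifacts; the lag-k autocorrelation matches
  the closed form `exp(-k^2/(4 psf^2))`.
- **Noise**: an independent unit-variance array (PSF-convolved by default,
  so noisy barcodes keep the smoothness of real ones; white noise
  optional), added with weight `alpha = sqrt(1/(1-nl)^2 - 1)` and
  re-normalized, giving `E[Pearson(noisy, clean)] = 1 - nl` (verified to
  ±0.02 over 100 replicates at nl = 0.05/0.1/0.25).
- **SVs**: cut-and-paste edits of the pixel array of the already-convolved
  profile — deletion removes an interval, insertion splices in freshly
  generated PSF-convolved signal, inversion reverses an interval in place,
  repeat duplicates it c times, translocation moves it to a destination
  outside all edited intervals. Editing the convolved profile (rather than
  the raw array) keeps the ground truth exact at pixel resolution: every
  recorded (query, reference) pixel pair has identical values before noise.
  Junctions are therefore sharp at the single-pixel level, slightly sharper
  than a physical junction blurred by the PSF.
- **Ordering**: noise is applied after the SV edit by default, which keeps
  the clean original available as the query; the reverse ordering is
  available via a flag and leaves the TPR statistics unchanged.
- **Ground truth**: a table of (query_px, ref_px, orientation) triples,
  one-to-many for repeats, orientation −1 inside inverted intervals.

Benchmark instances place SVs in equal-width chunks of the barcode
interior (50-px edge margin, 10-px spacing) with rejection-sampled
translocation destinations, so flanking matches are always long enough to
be detectable.

What the generator does *not* emulate: microscope images, stage drift,
local (non-global) stretching, intensity non-uniformity along the molecule,
or sequence-derived (theoretical) barcode structure. Passing tests
therefore demonstrate correctness of the method under the stated noise
model, not performance on any particular experimental dataset.

## Evaluation

The decoded table and the ground truth are expanded into binary match
matrices (rows = query, columns = reference; only rows that passed the
threshold, unless requested otherwise). Truth entries are visited row-major
in ascending order; entry `(i, k)` is a true positive if a decoded entry
`(i, u)` with `u ∈ {k−1, k, k+1}` is available, and the consumed entry is
zeroed so no decoded pixel is counted twice; `TPR = TP/(TP+FN)`, with an
empty truth counting as 1 (vacuous). The tolerance is applied along the
reference axis only, and the fixed iteration order makes the rate
deterministic. The FPR on unrelated random pairs is the fraction of query
pixels covered by significant segments (a segment-count variant is
available). `run_noise_sweep` and `run_parameter_sweep` produce tidy
per-replicate tables for the TPR-vs-noise benchmark and (p_MM, p_GG)
heat-map grids; both bypass the factor scan, since simulated pairs have a
known stretch of exactly 1.

Typical results under the default conditions (500-px barcodes, one 50-px
SV, 30 pairs per type, computed by `scripts/acceptance.py` and the
acceptance tests): mean post-threshold TPR across the five SV types ~0.87
at noise 0.1, ~0.91–0.93 for noise in {0.05, 0.1}, exactly 1.0 for
noise-free deletions, and a monotone TPR-vs-noise curve from ~1.0 at noise
0.05 down to ~0.15 at noise 0.25; unrelated pairs yield no significant
segments.

## Numerical choices and degenerate inputs

- Log-space arithmetic throughout the DP; no rescaling needed.
- Viterbi tie-breaks: continuation is preferred over block entry at equal
  score, and the first-found optimum is kept in the oracle; exact ties have
  measure zero for continuous inputs.
- Coordinates are 0-based half-open internally; every serialized table is
  1-based inclusive. Back-mapped query coordinates round half-up; segments
  longer than the original query (possible after stretching) are trimmed.
- Constant barcodes, sub-barcodes, or empty files raise typed `ValueError`s;
  an alignment with no significant match is a normal empty-passed result,
  not an error.
- Merged segments rebuild their query interval from the longer input's
  diagonal (clipped to the barcode) so the pair keeps equal lengths; dist
  and p-value are always recomputed after merging.
- `estimate_initial_factor` scores candidates with BLAS-backed window
  dot-product matrices; the max-null sampler reuses the same kernel.

## Problem sizes

Defaults used by the test suite and the acceptance script: 500-px barcodes,
50-px SVs, 30 simulated pairs per SV type per condition, null models with
500 samples per length, oracle comparisons on instances up to 12x12 cells.
These sizes give Monte-Carlo standard errors of ~0.02 on mean TPR values
while keeping a full run in the minutes range on one core.

## Known limitations

- Per-segment stretch is global only; local stretch variation within a
  molecule is out of scope.
- p-values are per segment against the placement-maximum null; no
  multiple-testing correction is applied across segments or across
  many-pair database comparisons (deliberately, matching standard practice
  for this method; the threshold is tunable).
- Short (near-`l`) true segments at noise levels ≥0.1 are often
  non-significant under the max null — see the null-model section.
- The factor-selection resolution is PSF-limited (~87–92% within one
  0.005 step at noise 0.1).
- Circular plasmid topology is not modelled; barcodes are treated as
  linear.
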