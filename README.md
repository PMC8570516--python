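# barcodesv

Structural-variant detection in densely-labelled optical DNA mapping
barcodes, without sequence information.

Densely-labelled optical DNA mapping (e.g. competitive-binding YOYO-1 /
netropsin labelling of molecules stretched in nanochannels) produces a
continuous, sequence-specific intensity profile — a *barcode* — along each
long DNA molecule, at a resolution set by the optical point spread function
(~1 kb). Large genomic alterations (insertions, deletions, inversions,
repeats, translocations, and combinations) rearrange pieces of that
profile. `barcodesv` compares two such barcodes directly, with no reference
genome: it locally aligns a query barcode `Q = a_1..a_q` to a reference
barcode `D = b_1..b_d` and reports every significantly matching sub-barcode
pair, from which the SV structure can be read off. Typical users are groups
analysing plasmids or other long molecules with nanochannel optical
mapping, e.g. for tracking rearrangements of antibiotic-resistance
plasmids.

## Method in brief

The aligner is a length-constrained hidden Markov model with `2q + 2`
states: forward and reverse match states `M_i^±` for every query pixel
(match state `M_i` emits `b_t ~ N(a_i, σ_e²)` on z-scores), plus a flank
gap and a joining gap state emitting the standard-normal background. A
Viterbi path assigns a state to each reference pixel; match runs are
diagonal (query index ±1 per reference pixel) and must span at least
`l = 44` px (22 kb) — shorter matches are below the PSF-limited information
content. Run continuation probabilities are `p_MM = 0.51` (match) and
`p_GG = 0.31` (gap); gap-to-match entries are uniform over all `2q` match
states, which is what lets the path jump between diagonals and orientations
and hence express any combination of SV types. The pipeline is:

1. estimate the global length-rescale factor of the query (molecules
   stretch differently) with a matrix-profile scan, unless it is known;
2. run the Viterbi decoder for each factor on a ±2% grid;
3. keep the factor maximizing `length × dist` of the longest segment
   (*dist* = Pearson cross-correlation of the paired sub-barcodes);
4. merge segments whose edges lie within `g = 5` px on both axes;
5. convert each merged segment's *dist* to a Monte-Carlo p-value against
   the maximum window correlation between random barcodes of the same
   length (the decoder's own placement search, applied to noise) and flag
   segments with `p ≤ 0.01` as significant.

A synthetic-data module generates the benchmark inputs — PSF-convolved
Gaussian random barcodes, correlation-calibrated noise
(`E[corr(noisy, clean)] = 1 − noiseLevel`), and pixel-exact cut-and-paste
SVs with a ground-truth alignment table — so the whole method is testable
with no external data. The evaluation module scores a decoded alignment
against that truth with a ±1-pixel-tolerant true-positive rate.

## Worked example

```python
import barcodesv as bsv

# 500-px (250 kb) random query; reference = same molecule with a 50-px
# (25 kb) insertion, noisified so that corr(noisy, clean) = 0.9
query, reference, truth = bsv.make_benchmark_pair(
    500, ["insertion"], 50, noise_level=0.1, seed=3)

null = bsv.build_null_model(mode="max", n=500, seed=12345)
cfg = bsv.RunConfig(hmm=bsv.HMMParams(rescale_halfwidth=0.0),
                    factor0=1.0, null_model=null)   # known factor: no scan
table = bsv.align_pipeline(query, reference, cfg)
print(table.to_frame().to_string(index=False))

m = bsv.table_to_matrix(table, len(query), len(reference))
t = bsv.table_to_matrix(truth, len(query), len(reference))
print("TPR:", bsv.true_positive_rate(m, t))
```

prints (coordinates 1-based inclusive):

```
 segment_id  query_start  query_end  ref_start  ref_end orientation  length_px     dist   pvalue  passed
          1            1        295          1      295           +        295 0.908442 0.001996    True
          2          244        288        296      340           +         45 0.645742 1.000000   False
          3          296        456        346      506           +        161 0.936912 0.001996    True
          4          358        401        507      550           +         44 0.850918 1.000000   False
TPR: 0.912
```

Segments 1 and 3 are the two significant matches flanking the insertion:
together they cover the whole query, while their reference intervals leave
a ~50-px hole — the inserted material. Their `dist` scores (~0.91, 0.94)
sit near the simulated noise level and their p-values are the Monte-Carlo
minimum. Segments 2 and 4 are short spurious matches inside the inserted
(random) material; they fail the threshold and are kept only as flagged
rows. The TPR of 0.91 says 91% of the true pixel pairs are recovered
within ±1 px by the significant segments.

The same workflow from the shell:

```sh
barcodesv simulate --length-px 500 --sv insertion:200:50 \
    --noise-level 0.1 --seed 3 --out-prefix sim
barcodesv null --mode max --n 500 --seed 12345 --out null.tsv
barcodesv align --query sim_query.txt --reference sim_reference.txt \
    --factor0 1.0 --rescale-halfwidth 0 --null-file null.tsv --out table.tsv
barcodesv evaluate --mode tpr --table table.tsv --truth sim_truth.tsv \
    --query sim_query.txt --reference sim_reference.txt
```

Every command accepts `--config` (JSON) and writes a JSON provenance log
with the resolved configuration and seeds next to its output.

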