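"""Post-processing of decoded segments: merging, similarity scoring,
Monte-Carlo p-values and the final alignment table.

Gaps smaller than the optical resolution are not physical, so segments
whose facing edges lie within ``g`` pixels on both axes (and on compatible
diagonals) are merged.  Each merged segment's Pearson cross-correlation
(*dist*) is converted to a p-value against the empirical distribution of
correlations between independent random barcodes of the same length, and
segments with p > p_thresh are flagged as not significant (they are kept in
the table, only flagged).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .barcode import Barcode
from .hmm import HMMParams, Segment

__all__ = [
    "NullModel",
    "AlignmentTable",
    "merge_segments",
    "segment_dist",
    "build_null_model",
    "segment_pvalue",
    "filter_table",
]

DEFAULT_NULL_LENGTHS = tuple(range(25, 501, 25))
#: coarser grid for the (costlier) max-over-placements null; the decoder
#: never emits segments shorter than l = 44 px
MAX_NULL_LENGTHS = (44, 60, 80, 110, 150, 200, 270, 370, 500)


def segment_dist(query: Barcode, reference: Barcode, segment: Segment) -> float:
    """Pearson cross-correlation of the paired sub-barcodes (the query
    sub-barcode is reversed for orientation -1)."""
    qs, qe = segment.query_start, segment.query_end
    rs, re_ = segment.ref_start, segment.ref_end
    if qs < 0 or qe > len(query) or rs < 0 or re_ > len(reference):
        raise ValueError("segment interval out of barcode bounds")
    if qe - qs < 2:
        raise ValueError("segment too short for a correlation")
    x = query.values[qs:qe]
    if segment.orientation < 0:
        x = x[::-1]
    y = reference.values[rs:re_]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant sub-barcode: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def _mergeable(a: Segment, b: Segment, g: int, check_diagonal: bool) -> bool:
    if a.orientation != b.orientation:
        return False
    first, second = (a, b) if a.ref_start <= b.ref_start else (b, a)
    if abs(second.ref_start - first.ref_end) > g:
        return False
    if a.orientation > 0:
        qgap = second.query_start - first.query_end
        diag_a = a.query_start - a.ref_start
        diag_b = b.query_start - b.ref_start
    else:
        # along a reverse match the query runs backwards with the reference
        qgap = first.query_start - second.query_end
        diag_a = (a.query_end - 1) + a.ref_start
        diag_b = (b.query_end - 1) + b.ref_start
    if abs(qgap) > g:
        return False
    if check_diagonal and abs(diag_a - diag_b) > g:
        return False
    return True


def _merge_pair(a: Segment, b: Segment, bounds: tuple[int, int] | None) -> Segment:
    """Union on the reference axis; the query interval is rebuilt from the
    longer input's diagonal so the merged pair keeps equal lengths."""
    rs = min(a.ref_start, b.ref_start)
    re_ = max(a.ref_end, b.ref_end)
    longer = a if a.length_px >= b.length_px else b
    L = re_ - rs
    if longer.orientation > 0:
        diag = longer.query_start - longer.ref_start
        qs = rs + diag
    else:
        anti = (longer.query_end - 1) + longer.ref_start
        qs = anti - (re_ - 1)
    qe = qs + L
    if bounds is not None:
        q_len = bounds[0]
        if qs < 0:
            qs, qe = 0, L
        if qe > q_len:
            qs, qe = q_len - L, q_len
    return Segment(qs, qe, rs, re_, longer.orientation)


def merge_segments(
    segments: list[Segment],
    g: int,
    check_diagonal: bool = True,
    bounds: tuple[int, int] | None = None,
) -> list[Segment]:
    """Iteratively merge same-orientation segments whose facing edges are
    within ``g`` pixels on both axes (and whose diagonals agree within
    ``g``, unless ``check_diagonal`` is off) until a fixed point.

    ``bounds`` = (query_length, reference_length) clips rebuilt query
    intervals.  dist and p-values of merged segments must be recomputed by
    the caller.
    """
    segs = list(segments)
    changed = True
    while changed:
        changed = False
        for i in range(len(segs)):
            for j in range(i + 1, len(segs)):
                if _mergeable(segs[i], segs[j], g, check_diagonal):
                    merged = _merge_pair(segs[i], segs[j], bounds)
                    segs = [s for k, s in enumerate(segs) if k not in (i, j)]
                    segs.append(merged)
                    changed = True
                    break
            if changed:
                break
    return sorted(segs, key=lambda s: (s.ref_start, s.query_start))


@dataclass
class NullModel:
    """Empirical null distribution of Pearson correlations for independent
    random barcodes, per segment length; lengths between grid points use the
    nearest grid length.

    ``mode='pair'`` draws the correlation of one random sub-barcode pair per
    sample.  ``mode='max'`` draws, per sample, the maximum correlation over
    *all* length-L window placements (both orientations) between two random
    barcodes of ``context_px`` pixels — the same search the decoder
    performs, so p-values computed against it account for the decoder's
    selection of the best-matching placement."""

    lengths: np.ndarray
    samples: dict[int, np.ndarray]
    psf_px: float
    n: int
    seed: int
    mode: str = "pair"
    context_px: int = 500

    def nearest_length(self, length_px: int) -> int:
        idx = int(np.argmin(np.abs(self.lengths - length_px)))
        return int(self.lengths[idx])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for L in self.lengths:
            s = self.samples[int(L)]
            rows.append(
                pd.DataFrame(
                    {
                        "length_px": int(L),
                        "sample_index": np.arange(s.size),
                        "dist": s,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        meta = {"psf_px": self.psf_px, "n": self.n, "seed": self.seed,
                "mode": self.mode, "context_px": self.context_px,
                "lengths": [int(x) for x in self.lengths]}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "NullModel":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        samples = {
            int(L): np.asarray(sub["dist"], dtype=float)
            for L, sub in df.groupby("length_px")
        }
        return cls(
            np.asarray(meta["lengths"], dtype=int),
            samples,
            float(meta["psf_px"]),
            int(meta["n"]),
            int(meta["seed"]),
            mode=meta.get("mode", "pair"),
            context_px=int(meta.get("context_px", 500)),
        )


def _random_batch(
    n_rows: int, length: int, psf_px: float, rng: np.random.Generator
) -> np.ndarray:
    """(n_rows, length) matrix of independent z-normalized random barcodes."""
    pad = int(np.ceil(3 * psf_px))
    raw = rng.standard_normal((n_rows, length + 2 * pad))
    sm = gaussian_filter1d(raw, sigma=psf_px, axis=1, mode="constant")
    sm = sm[:, pad : pad + length]
    sm = sm - sm.mean(axis=1, keepdims=True)
    sm /= sm.std(axis=1, keepdims=True)
    return sm


def build_null_model(
    lengths=None,
    psf_px: float = 2.0,
    n: int = 500,
    seed: int = 0,
    mode: str = "pair",
    context_px: int = 500,
) -> NullModel:
    """Monte-Carlo null distribution of *dist* scores, per segment length.

    ``mode='pair'``: each sample is the Pearson correlation of one pair of
    independent PSF-convolved random barcodes of length L.  ``mode='max'``:
    each sample is the maximum window correlation over every length-L
    placement (both orientations) between an independent pair of
    ``context_px``-pixel random barcodes, matching the placement search the
    aligner performs.  Deterministic given ``seed``.
    """
    if lengths is None:
        lengths = DEFAULT_NULL_LENGTHS if mode == "pair" else MAX_NULL_LENGTHS
    lengths = np.asarray(sorted(set(int(x) for x in lengths)), dtype=int)
    if np.any(lengths < 4):
        raise ValueError("null-model lengths must be >= 4 px")
    if n < 100:
        raise ValueError("need n >= 100 null samples per length")
    if mode not in ("pair", "max"):
        raise ValueError(f"unknown null mode {mode!r}")
    rng = np.random.default_rng(seed)
    samples: dict[int, np.ndarray] = {}
    if mode == "pair":
        for L in lengths:
            sm = _random_batch(2 * n, int(L), psf_px, rng)
            x, y = sm[:n], sm[n:]
            samples[int(L)] = (x * y).mean(axis=1)
    else:
        from .rescale import _znorm_min_profile  # deferred: avoids a cycle

        if np.any(lengths > context_px):
            raise ValueError("null lengths must not exceed context_px")
        for L in lengths:
            a = _random_batch(n, context_px, psf_px, rng)
            b = _random_batch(n, context_px, psf_px, rng)
            out = np.empty(n)
            for k in range(n):
                dmin = _znorm_min_profile(a[k], b[k], int(L)).min()
                out[k] = 1.0 - dmin * dmin / (2.0 * L)
            samples[int(L)] = out
    return NullModel(lengths, samples, psf_px, n, seed, mode, context_px)


def segment_pvalue(dist: float, length_px: int, null_model: NullModel) -> float:
    """Add-one-smoothed Monte-Carlo p-value:
    p = (1 + #{null >= dist}) / (n + 1), in (0, 1]."""
    if not null_model.samples:
        raise ValueError("empty null model")
    s = null_model.samples[null_model.nearest_length(length_px)]
    return float((1 + int((s >= dist).sum())) / (s.size + 1))


@dataclass
class AlignmentTable:
    """Final pipeline output: one row per merged sub-barcode pair with its
    Pearson similarity C_i, p-value p_i and length l_i; rows that fail the
    p-value threshold are kept but flagged."""

    segments: list[Segment]
    factor: float = 1.0
    p_thresh: float = 0.01

    def __post_init__(self) -> None:
        self.segments = sorted(
            self.segments, key=lambda s: (s.ref_start, s.query_start)
        )

    def passing(self) -> list[Segment]:
        return [s for s in self.segments if s.passed]

    def to_frame(self) -> pd.DataFrame:
        """Serialized form: 1-based inclusive coordinates."""
        rows = []
        for k, s in enumerate(self.segments, start=1):
            rows.append(
                {
                    "segment_id": k,
                    "query_start": s.query_start + 1,
                    "query_end": s.query_end,
                    "ref_start": s.ref_start + 1,
                    "ref_end": s.ref_end,
                    "orientation": "+" if s.orientation > 0 else "-",
                    "length_px": s.length_px,
                    "dist": s.dist,
                    "pvalue": s.pvalue,
                    "passed": bool(s.passed),
                }
            )
        cols = [
            "segment_id", "query_start", "query_end", "ref_start", "ref_end",
            "orientation", "length_px", "dist", "pvalue", "passed",
        ]
        return pd.DataFrame(rows, columns=cols)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AlignmentTable":
        df = pd.read_csv(path, sep="\t")
        segs = []
        for _, r in df.iterrows():
            segs.append(
                Segment(
                    int(r["query_start"]) - 1,
                    int(r["query_end"]),
                    int(r["ref_start"]) - 1,
                    int(r["ref_end"]),
                    1 if r["orientation"] == "+" else -1,
                    dist=float(r["dist"]),
                    pvalue=float(r["pvalue"]),
                    passed=bool(r["passed"]),
                )
            )
        return cls(segs)


def filter_table(
    segments: list[Segment], params: HMMParams, factor: float = 1.0
) -> AlignmentTable:
    """Flag each segment as significant (p <= p_thresh) or not; all rows are
    retained."""
    for s in segments:
        if s.pvalue is None:
            raise ValueError("segments must carry p-values before filtering")
        s.passed = bool(s.pvalue <= params.p_thresh)
    return AlignmentTable(segments, factor=factor, p_thresh=params.p_thresh)
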