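"""Length-constrained HMM local alignment of two barcodes.

The reference barcode of length ``d`` is decoded against a state space built
from the query barcode of length ``q``: for every query pixel there is a
forward match state and a reverse match state (2q match states), plus a
flank gap state (unaligned barcode ends, any length) and a joining gap state
(unmatched reference between aligned segments, minimum length ``l_G``) —
2q + 2 states in total.  A valid Viterbi path partitions the reference into
gap runs and diagonal match runs; every match run advances the query index
by +1 (forward) or -1 (reverse) per reference pixel and must contain at
least ``l`` pixels, which keeps spurious short matches out of the decoded
alignment.  Two match runs may also abut directly (silent re-entry), which
is how deletions and translocations with no unmatched reference in between
appear in the path.

Match state i emits the reference intensity from Normal(a_i, sigma_e^2) on
z-scores; gap states emit from the standard normal background.  Decoding is
O(q d) via block entry: entering a match run (or a joining gap) consumes its
minimum length in one step, using diagonal prefix sums of the emission
matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .barcode import Barcode

__all__ = ["HMMParams", "Segment", "viterbi_align", "brute_force_align"]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
NEG_INF = -np.inf


@dataclass(frozen=True)
class HMMParams:
    """All tunables of the alignment pipeline.

    p_MM / p_GG are the probabilities of continuing a match run / gap run;
    ``l`` and ``l_G`` are the minimum match and joining-gap run lengths in
    pixels (l = 44 px is 22 kb at 0.5 kb/px, the shortest sub-barcode worth
    matching); ``sigma_e`` is the match-emission spread on z-scores, with
    sigma_e^2 = 2 * nl for an assumed noise level nl = 0.1 (the residual
    variance between two unit-variance profiles with correlation 1 - nl);
    ``g`` is the post-processing merge radius; ``p_thresh`` the significance
    cut; the rescale fields define the +-2% factor scan grid.
    """

    p_MM: float = 0.51
    p_GG: float = 0.31
    l: int = 44
    l_G: int = 5
    sigma_e: float = math.sqrt(0.2)
    g: int = 5
    p_thresh: float = 0.01
    rescale_halfwidth: float = 0.02
    rescale_step: float = 0.005

    def __post_init__(self) -> None:
        if not (0 < self.p_MM < 1 and 0 < self.p_GG < 1):
            raise ValueError("p_MM and p_GG must lie in (0, 1)")
        if self.l < 1 or self.l_G < 1:
            raise ValueError("l and l_G must be >= 1")
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be positive")
        if not (0 < self.p_thresh < 1):
            raise ValueError("p_thresh must lie in (0, 1)")
        if self.g < 0:
            raise ValueError("g must be >= 0")

    def replace(self, **kw) -> "HMMParams":
        return replace(self, **kw)


@dataclass
class Segment:
    """One aligned sub-barcode pair, 0-based half-open pixel intervals.

    For orientation -1, increasing reference position maps to decreasing
    query position; the interval bounds are still stored low-to-high.
    """

    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    orientation: int
    dist: float | None = None
    pvalue: float | None = None
    passed: bool | None = None

    def __post_init__(self) -> None:
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")
        if self.query_end - self.query_start != self.ref_end - self.ref_start:
            raise ValueError("query and reference intervals must have equal length")
        if self.query_end <= self.query_start:
            raise ValueError("empty segment interval")

    @property
    def length_px(self) -> int:
        return self.ref_end - self.ref_start

    def query_index_of(self, ref_px: int) -> int:
        """Query pixel matched to a given reference pixel of this segment."""
        off = ref_px - self.ref_start
        if self.orientation > 0:
            return self.query_start + off
        return self.query_end - 1 - off


class _Scoring:
    """Log-probability terms shared by every path through the model."""

    def __init__(self, query: np.ndarray, reference: np.ndarray, params: HMMParams):
        self.q = query.size
        self.d = reference.size
        p = params
        self.l = p.l
        self.l_G = p.l_G
        self.log_pmm = math.log(p.p_MM)
        self.log_pgg = math.log(p.p_GG)
        self.log_1mpmm = math.log1p(-p.p_MM)
        self.log_1mpgg = math.log1p(-p.p_GG)
        # gap->match entry is uniform over all 2q match states, which is what
        # permits translocations and repeats (jumps to any diagonal)
        self.log_entry = -math.log(2 * self.q)
        # match exit splits its residual mass over {joining gap, flank gap,
        # silent re-entry}
        self.log_w = -math.log(3.0)
        self.log_pi_g = math.log(0.5)
        self.log_pi_m = math.log(0.5) + self.log_entry
        sig = p.sigma_e
        b = reference
        a = query
        self.em = (
            -0.5 * ((b[:, None] - a[None, :]) / sig) ** 2
            - math.log(sig)
            - _LOG_SQRT_2PI
        )  # (d, q)
        self.gapem = -0.5 * b**2 - _LOG_SQRT_2PI


def _runs_to_segments(runs: list[tuple[int, int, int, int]]) -> list[Segment]:
    """Convert (ref_start, length, orientation, query_at_ref_start) runs."""
    segs = []
    for t0, L, o, i0 in runs:
        if o > 0:
            qs, qe = i0, i0 + L
        else:
            qs, qe = i0 - L + 1, i0 + 1
        segs.append(Segment(qs, qe, t0, t0 + L, o))
    return segs


def viterbi_align(
    query: Barcode, reference: Barcode, params: HMMParams
) -> list[Segment]:
    """Decode the maximum-probability valid path and return its match runs
    as segments (reference-disjoint, each >= ``l`` px).  An all-gap optimum
    returns an empty list.  Runtime O(q d)."""
    best_score, segs = viterbi_align_scored(query, reference, params)
    return segs


def viterbi_align_scored(
    query: Barcode, reference: Barcode, params: HMMParams
) -> tuple[float, list[Segment]]:
    """As :func:`viterbi_align`, also returning the optimal path log score."""
    a = np.asarray(query.values, dtype=float)
    b = np.asarray(reference.values, dtype=float)
    q, d, l, lG = a.size, b.size, params.l, params.l_G
    if q < l or d < l:
        raise ValueError(
            f"barcodes must be at least l={l} px long (got q={q}, d={d})"
        )
    sc = _Scoring(a, b, params)
    em, gapem = sc.em, sc.gapem

    # diagonal cumulative emission sums: cp for forward (+1 step in query per
    # reference pixel), cm for reverse
    cp = em.copy()
    cm = em.copy()
    for t in range(1, d):
        cp[t, 1:] += cp[t - 1, :-1]
        cm[t, :-1] += cm[t - 1, 1:]

    cumgap = np.concatenate(([0.0], np.cumsum(gapem)))

    def lead_end(t: int) -> float:
        # leading flank gap covering pixels 0..t
        return sc.log_pi_g + cumgap[t + 1] + t * sc.log_pgg

    Mp = np.full(q, NEG_INF)
    Mm = np.full(q, NEG_INF)
    choice_p = np.zeros((d, q), dtype=np.int8)  # 1 = continue, 2 = block entry
    choice_m = np.zeros((d, q), dtype=np.int8)
    mend = np.full(d, NEG_INF)  # best score of a match run ending at pixel t
    mend_o = np.zeros(d, dtype=np.int8)
    mend_i = np.zeros(d, dtype=np.int32)
    gj = np.full(d, NEG_INF)
    gj_choice = np.zeros(d, dtype=np.int8)  # 1 = entry, 2 = continue
    gt = np.full(d, NEG_INF)
    gt_choice = np.zeros(d, dtype=np.int8)  # 1 = from match, 2 = continue
    entry_score = np.full(d, NEG_INF)  # u pixels consumed before the block
    entry_choice = np.zeros(d, dtype=np.int8)  # 0 start, 1 lead, 2 GJ, 3 reentry

    block_bonus = (l - 1) * sc.log_pmm

    for t in range(d):
        # score of the best way to be "about to start a match block" with
        # u = t - l + 1 pixels already consumed
        u = t - l + 1
        if u >= 0:
            if u == 0:
                entry_score[0], entry_choice[0] = sc.log_pi_m, 0
            else:
                cands = (
                    lead_end(u - 1) + sc.log_1mpgg + sc.log_entry,
                    gj[u - 1] + sc.log_1mpgg + sc.log_entry,
                    mend[u - 1] + sc.log_1mpmm + sc.log_w + sc.log_entry,
                )
                k = int(np.argmax(cands))
                entry_score[u], entry_choice[u] = cands[k], k + 1

        new_p = np.full(q, NEG_INF)
        new_m = np.full(q, NEG_INF)
        ch_p = choice_p[t]
        ch_m = choice_m[t]
        if t >= 1:
            cont = Mp[:-1] + sc.log_pmm + em[t, 1:]
            new_p[1:] = cont
            ch_p[1:] = np.where(np.isfinite(cont), 1, 0)
            cont = Mm[1:] + sc.log_pmm + em[t, :-1]
            new_m[:-1] = cont
            ch_m[:-1] = np.where(np.isfinite(cont), 1, 0)
        if u >= 0 and np.isfinite(entry_score[u]):
            # block covering reference pixels [t-l+1, t]; forward blocks end
            # at query i >= l-1, reverse blocks at i <= q-l
            base = entry_score[u] + block_bonus
            if t - l >= 0:
                # forward block ending at (t, i): subtract the diagonal prefix
                # at (t-l, i-l); a block starting in query column 0 (i = l-1)
                # begins at its diagonal's origin, so nothing to subtract
                sub_p = np.empty(q - l + 1)
                sub_p[0] = 0.0
                sub_p[1:] = cp[t - l, : q - l]
                bp = base + cp[t, l - 1 :] - sub_p
                # reverse block ending at (t, i): subtract at (t-l, i+l);
                # i = q-l starts at its anti-diagonal's origin
                sub_m = np.empty(q - l + 1)
                sub_m[-1] = 0.0
                sub_m[:-1] = cm[t - l, l:]
                bm = base + cm[t, : q - l + 1] - sub_m
            else:  # block starts at reference pixel 0: sums are direct
                bp = base + cp[t, l - 1 :]
                bm = base + cm[t, : q - l + 1]
            better = bp > new_p[l - 1 :]
            new_p[l - 1 :] = np.where(better, bp, new_p[l - 1 :])
            ch_p[l - 1 :] = np.where(better, 2, ch_p[l - 1 :])
            better = bm > new_m[: q - l + 1]
            new_m[: q - l + 1] = np.where(better, bm, new_m[: q - l + 1])
            ch_m[: q - l + 1] = np.where(better, 2, ch_m[: q - l + 1])
        Mp, Mm = new_p, new_m

        ip, im = int(np.argmax(Mp)), int(np.argmax(Mm))
        if Mp[ip] >= Mm[im]:
            mend[t], mend_o[t], mend_i[t] = Mp[ip], 1, ip
        else:
            mend[t], mend_o[t], mend_i[t] = Mm[im], -1, im

        # joining gap: block entry consumes l_G pixels after a match end
        gj_entry = NEG_INF
        if t - lG >= 0 and np.isfinite(mend[t - lG]):
            gj_entry = (
                mend[t - lG]
                + sc.log_1mpmm
                + sc.log_w
                + (cumgap[t + 1] - cumgap[t + 1 - lG])
                + (lG - 1) * sc.log_pgg
            )
        gj_cont = (gj[t - 1] + sc.log_pgg + gapem[t]) if t >= 1 else NEG_INF
        if gj_entry >= gj_cont:
            gj[t], gj_choice[t] = gj_entry, 1
        else:
            gj[t], gj_choice[t] = gj_cont, 2

        # terminal flank gap (after the last match run, any length)
        gt_from_m = (
            mend[t - 1] + sc.log_1mpmm + sc.log_w + gapem[t] if t >= 1 else NEG_INF
        )
        gt_cont = (gt[t - 1] + sc.log_pgg + gapem[t]) if t >= 1 else NEG_INF
        if gt_from_m >= gt_cont:
            gt[t], gt_choice[t] = gt_from_m, 1
        else:
            gt[t], gt_choice[t] = gt_cont, 2

    finals = (mend[d - 1], gt[d - 1], lead_end(d - 1))
    kind = int(np.argmax(finals))
    best = finals[kind]
    if kind == 2:
        return best, []  # all-gap path

    # --- backtrace -------------------------------------------------------
    runs: list[tuple[int, int, int, int]] = []
    if kind == 1:
        t = d - 1
        while gt_choice[t] == 2:
            t -= 1
        t -= 1  # last match run ends here
    else:
        t = d - 1
    o, i = int(mend_o[t]), int(mend_i[t])
    while True:
        end_t, end_i = t, i
        choice = choice_p if o > 0 else choice_m
        while choice[t, i] == 1:
            t -= 1
            i -= o
        # block entry: run starts at t - l + 1
        t0 = t - l + 1
        i0 = i - o * (l - 1)  # query index at the run's first reference pixel
        L = end_t - t0 + 1
        runs.append((t0, L, o, i0))
        u = t0
        ec = entry_choice[u]
        if ec in (0, 1):  # path start or leading flank gap
            break
        if ec == 3:  # silent re-entry: previous run ends at u-1
            t = u - 1
            o, i = int(mend_o[t]), int(mend_i[t])
            continue
        # joining gap: walk back through its continuation to its entry
        tg = u - 1
        while gj_choice[tg] == 2:
            tg -= 1
        t = tg - lG  # match run ended here
        o, i = int(mend_o[t]), int(mend_i[t])

    runs.reverse()
    return best, _runs_to_segments(runs)


# ---------------------------------------------------------------------------
# Exhaustive oracle


def brute_force_align(
    query: Barcode, reference: Barcode, params: HMMParams, max_cells: int = 220
) -> list[Segment]:
    score, segs = brute_force_align_scored(query, reference, params, max_cells)
    return segs


def brute_force_align_scored(
    query: Barcode, reference: Barcode, params: HMMParams, max_cells: int = 220
) -> tuple[float, list[Segment]]:
    """Score every valid path by explicit enumeration of run structures and
    return the argmax.  Only feasible for tiny instances (q*d <= max_cells);
    intended as a test oracle for :func:`viterbi_align`."""
    a = np.asarray(query.values, dtype=float)
    b = np.asarray(reference.values, dtype=float)
    q, d, l, lG = a.size, b.size, params.l, params.l_G
    if q * d > max_cells:
        raise ValueError(f"instance too large for enumeration: {q}x{d}")
    if q < l or d < l:
        raise ValueError("barcodes must be at least l px long")

    sig = params.sigma_e
    log_pmm = math.log(params.p_MM)
    log_pgg = math.log(params.p_GG)
    log_1mpmm = math.log1p(-params.p_MM)
    log_1mpgg = math.log1p(-params.p_GG)
    log_entry = -math.log(2 * q)
    log_w = -math.log(3.0)
    log_pi_g = math.log(0.5)
    log_pi_m = math.log(0.5) + log_entry

    def match_em(t: int, i: int) -> float:
        z = (b[t] - a[i]) / sig
        return -0.5 * z * z - math.log(sig) - _LOG_SQRT_2PI

    gapem = [-0.5 * x * x - _LOG_SQRT_2PI for x in b]

    best: list = [NEG_INF, []]

    def consider(score: float, runs: list) -> None:
        if score > best[0]:
            best[0] = score
            best[1] = list(runs)

    def run_score(t: int, L: int, o: int, i0: int) -> float:
        s = (L - 1) * log_pmm
        for j in range(L):
            s += match_em(t + j, i0 + o * j)
        return s

    def place_run(t: int, score: float, runs: list) -> None:
        # a match run starts exactly at reference pixel t
        for o in (1, -1):
            for L in range(l, d - t + 1):
                offsets = range(0, q - L + 1) if o == 1 else range(L - 1, q)
                for i0 in offsets:
                    s = score + run_score(t, L, o, i0)
                    runs.append((t, L, o, i0))
                    end = t + L
                    if end == d:
                        consider(s, runs)
                    else:
                        # terminal flank gap to the end of the reference
                        tail = sum(gapem[end:]) + (d - end - 1) * log_pgg
                        consider(s + log_1mpmm + log_w + tail, runs)
                        # silent re-entry: next run abuts directly
                        place_run(end, s + log_1mpmm + log_w + log_entry, runs)
                        # joining gap of length G >= l_G, then another run
                        for G in range(lG, d - end - l + 1):
                            sg = (
                                s
                                + log_1mpmm
                                + log_w
                                + sum(gapem[end : end + G])
                                + (G - 1) * log_pgg
                                + log_1mpgg
                                + log_entry
                            )
                            place_run(end + G, sg, runs)
                    runs.pop()

    # all-gap path
    consider(log_pi_g + sum(gapem) + (d - 1) * log_pgg, [])
    # leading flank gap of every length (0 = start directly in a match)
    for t in range(0, d - l + 1):
        if t == 0:
            base = log_pi_m
        else:
            base = (
                log_pi_g
                + sum(gapem[:t])
                + (t - 1) * log_pgg
                + log_1mpgg
                + log_entry
            )
        place_run(t, base, [])

    return best[0], _runs_to_segments(best[1])
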