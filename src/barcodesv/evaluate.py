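"""Pixel-level evaluation of a decoded alignment against the ground truth.

The decoded alignment and the ground truth are both expanded into binary
match matrices (rows = query pixels, columns = reference pixels).  A truth
entry counts as a true positive if the decoded matrix has an entry in the
same query row within +-1 reference pixel; each decoded entry can be
consumed only once.  The false positive rate on unrelated random barcodes is
the fraction of query pixels covered by significant segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .barcode import Barcode
from .hmm import HMMParams, Segment
from .postprocess import AlignmentTable, NullModel
from .simulate import SV_TYPES, GroundTruthAlignment, make_benchmark_pair

__all__ = [
    "table_to_matrix",
    "true_positive_rate",
    "false_positive_rate",
    "run_noise_sweep",
    "run_parameter_sweep",
    "SweepResult",
]


def table_to_matrix(
    table: AlignmentTable | GroundTruthAlignment | list[Segment],
    q: int,
    d: int,
    passed_only: bool = True,
) -> np.ndarray:
    """Binary match matrix of shape (q, d).  Alignment tables expand only
    rows flagged as significant (unless ``passed_only`` is off); segments
    expand to their per-pixel diagonal pairs, reversed for orientation -1."""
    m = np.zeros((q, d), dtype=np.uint8)
    if isinstance(table, GroundTruthAlignment):
        if table.query_px.size:
            if table.query_px.min() < 0 or table.query_px.max() >= q:
                raise ValueError("ground-truth query index out of range")
            if table.ref_px.min() < 0 or table.ref_px.max() >= d:
                raise ValueError("ground-truth reference index out of range")
            m[table.query_px, table.ref_px] = 1
        return m
    segs = table.segments if isinstance(table, AlignmentTable) else table
    for s in segs:
        if isinstance(table, AlignmentTable) and passed_only and not s.passed:
            continue
        if s.query_start < 0 or s.query_end > q or s.ref_start < 0 or s.ref_end > d:
            raise ValueError("segment index out of range")
        ref = np.arange(s.ref_start, s.ref_end)
        if s.orientation > 0:
            qry = np.arange(s.query_start, s.query_end)
        else:
            qry = np.arange(s.query_end - 1, s.query_start - 1, -1)
        m[qry, ref] = 1
    return m


def true_positive_rate(hmm: np.ndarray, truth: np.ndarray) -> float:
    """TP / (TP + FN) with +-1 pixel tolerance along the reference axis.

    Truth entries are visited row-major in ascending index order; for truth
    entry (i, k) the first available decoded entry (i, u), u in
    {k-1, k, k+1}, is consumed (zeroed so no decoded pixel is matched
    twice).  Returns 1.0 for an empty truth (vacuous)."""
    hmm = np.asarray(hmm)
    truth = np.asarray(truth)
    if hmm.shape != truth.shape:
        raise ValueError(f"shape mismatch: {hmm.shape} vs {truth.shape}")
    avail = hmm.astype(bool).copy()
    d = truth.shape[1]
    tp = fn = 0
    rows, cols = np.nonzero(truth)
    for i, k in zip(rows, cols):
        hit = False
        for u in (k - 1, k, k + 1):
            if 0 <= u < d and avail[i, u]:
                avail[i, u] = False
                tp += 1
                hit = True
                break
        if not hit:
            fn += 1
    if tp + fn == 0:
        return 1.0
    return tp / (tp + fn)


def false_positive_rate(
    query: Barcode,
    reference: Barcode,
    pipeline_params: HMMParams,
    null_model: NullModel | None = None,
    mode: str = "pixel",
) -> float:
    """Run the full pipeline on a (presumed independent) pair and return the
    fraction of query pixels covered by significant segments
    (``mode='pixel'``) or the number of significant segments
    (``mode='count'``)."""
    from .pipeline import RunConfig, align_pipeline

    cfg = RunConfig(hmm=pipeline_params, factor0=1.0, null_model=null_model)
    table = align_pipeline(query, reference, cfg)
    passing = table.passing()
    if mode == "count":
        return float(len(passing))
    covered = np.zeros(len(query), dtype=bool)
    for s in passing:
        covered[max(0, s.query_start) : min(len(query), s.query_end)] = True
    return float(covered.sum() / len(query))


@dataclass
class SweepResult:
    """Tidy per-replicate table of a simulation sweep plus its grid axes."""

    table: pd.DataFrame
    axes: dict

    def summary(self) -> pd.DataFrame:
        keys = [c for c in ("sv_type", "noise_level", "p_MM", "p_GG")
                if c in self.table.columns]
        return (
            self.table.groupby(keys, as_index=False)[
                [c for c in ("tpr_pre", "tpr_post", "fpr") if c in self.table]
            ].mean()
        )

    def plot(self, path=None):
        """TPR-vs-noise curves, one line per SV type (noise sweeps only).
        Requires matplotlib; returns the figure, optionally saved to
        ``path``."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if "noise_level" not in self.table.columns:
            raise ValueError("plot() supports noise-sweep results only")
        fig, ax = plt.subplots(figsize=(5, 3.5))
        summary = self.summary()
        for sv_type, sub in summary.groupby("sv_type"):
            dist = 1.0 - sub["noise_level"]
            ax.plot(dist, sub["tpr_post"], "o-", label=sv_type)
        ax.set_xlabel("dist (1 - noise level)")
        ax.set_ylabel("post-threshold TPR")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
        return fig


def _pair_tpr(
    sv_type: str,
    barcode_len_px: int,
    sv_len_px: int,
    noise_level: float,
    seed: int,
    params: HMMParams,
    null_model: NullModel | None,
) -> tuple[float, float]:
    """Mean TPR for one simulated pair, before and after thresholding."""
    from .pipeline import RunConfig, align_pipeline

    query, reference, truth = make_benchmark_pair(
        barcode_len_px, [sv_type], sv_len_px, noise_level, seed
    )
    cfg = RunConfig(hmm=params, factor0=1.0, null_model=null_model)
    table = align_pipeline(query, reference, cfg)
    q, d = len(query), len(reference)
    t = table_to_matrix(truth, q, d)
    pre = true_positive_rate(table_to_matrix(table, q, d, passed_only=False), t)
    post = true_positive_rate(table_to_matrix(table, q, d, passed_only=True), t)
    return pre, post


def run_noise_sweep(
    sv_types=SV_TYPES,
    sv_len_px: int = 50,
    barcode_len_px: int = 500,
    noise_levels=(0.05, 0.10, 0.15, 0.20, 0.25),
    n_pairs: int = 100,
    seed: int = 0,
    params: HMMParams | None = None,
    null_model: NullModel | None = None,
) -> SweepResult:
    """TPR vs noise benchmark: for each (SV type, noise level), simulate
    ``n_pairs`` query/reference pairs with a single SV, run the pipeline at
    the known factor 1.0 and record the TPR before and after p-value
    thresholding."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    # simulated pairs have a known stretch factor of exactly 1, so the
    # factor scan is bypassed by default, as in the simulation benchmarks
    params = params or HMMParams(rescale_halfwidth=0.0)
    null_model = null_model or _default_null(seed)
    ss = np.random.SeedSequence(seed)
    rows = []
    for sv_type in sv_types:
        for nl in noise_levels:
            child = np.random.default_rng(
                np.random.SeedSequence(
                    (seed, SV_TYPES.index(sv_type), int(round(nl * 1000)))
                )
            )
            rep_seeds = child.integers(0, 2**31, size=n_pairs)
            for r, s in enumerate(rep_seeds):
                pre, post = _pair_tpr(
                    sv_type, barcode_len_px, sv_len_px, float(nl), int(s),
                    params, null_model,
                )
                rows.append(
                    {
                        "sv_type": sv_type,
                        "noise_level": float(nl),
                        "replicate": r,
                        "seed": int(s),
                        "tpr_pre": pre,
                        "tpr_post": post,
                    }
                )
    table = pd.DataFrame(rows)
    return SweepResult(
        table,
        axes={
            "sv_types": list(sv_types),
            "noise_levels": [float(x) for x in noise_levels],
            "sv_len_px": sv_len_px,
            "barcode_len_px": barcode_len_px,
            "n_pairs": n_pairs,
            "seed": seed,
        },
    )


def run_parameter_sweep(
    p_MM_grid,
    p_GG_grid,
    fixed_sim_config: dict | None = None,
    n_pairs: int = 20,
    seed: int = 0,
    null_model: NullModel | None = None,
) -> SweepResult:
    """Heat-map sweep over (p_MM, p_GG): mean TPR before/after thresholding
    and pixel FPR on independent pairs, per grid cell."""
    from .simulate import generate_random_barcode

    sim = {
        "sv_type": "deletion",
        "barcode_len_px": 500,
        "sv_len_px": 50,
        "noise_level": 0.1,
    }
    sim.update(fixed_sim_config or {})
    null_model = null_model or _default_null(seed)
    rows = []
    for p_mm in p_MM_grid:
        for p_gg in p_GG_grid:
            params = HMMParams(p_MM=float(p_mm), p_GG=float(p_gg),
                               rescale_halfwidth=0.0)
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, int(p_mm * 1e6), int(p_gg * 1e6)))
            )
            rep_seeds = rng.integers(0, 2**31, size=n_pairs)
            for r, s in enumerate(rep_seeds):
                pre, post = _pair_tpr(
                    sim["sv_type"], sim["barcode_len_px"], sim["sv_len_px"],
                    sim["noise_level"], int(s), params, null_model,
                )
                a = generate_random_barcode(
                    sim["barcode_len_px"], seed=int(s) ^ 0x5A5A5A
                )
                b = generate_random_barcode(
                    sim["barcode_len_px"], seed=int(s) ^ 0x3C3C3C
                )
                fpr = false_positive_rate(a, b, params, null_model)
                rows.append(
                    {
                        "p_MM": float(p_mm),
                        "p_GG": float(p_gg),
                        "replicate": r,
                        "tpr_pre": pre,
                        "tpr_post": post,
                        "fpr": fpr,
                    }
                )
    table = pd.DataFrame(rows)
    return SweepResult(
        table,
        axes={
            "p_MM_grid": [float(x) for x in p_MM_grid],
            "p_GG_grid": [float(x) for x in p_GG_grid],
            "sim": sim,
            "n_pairs": n_pairs,
            "seed": seed,
        },
    )


_null_cache: dict = {}


def _default_null(seed: int) -> NullModel:
    from .postprocess import build_null_model

    key = ("default-max", 2.0, 500, 12345)
    if key not in _null_cache:
        _null_cache[key] = build_null_model(
            psf_px=2.0, n=500, seed=12345, mode="max"
        )
    return _null_cache[key]
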