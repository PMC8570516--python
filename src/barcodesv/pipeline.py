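"""End-to-end pipeline driver.

Wires the five stages together: (1) initial rescale-factor estimate, (2)
per-factor Viterbi decoding, (3) factor selection by the length-weighted
similarity of the longest segment, (4) merging of segments within ``g``
pixels, (5) Pearson *dist*, Monte-Carlo p-value and significance flagging.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from .barcode import Barcode, znormalize
from .hmm import HMMParams
from .postprocess import (
    AlignmentTable,
    NullModel,
    build_null_model,
    filter_table,
    merge_segments,
    segment_dist,
    segment_pvalue,
)
from .rescale import estimate_initial_factor, scan_and_select

__all__ = ["RunConfig", "align_pipeline"]

log = logging.getLogger("barcodesv")

_null_cache: dict[tuple, NullModel] = {}


def _cached_null(
    lengths, psf_px: float, n: int, seed: int, mode: str, context_px: int
) -> NullModel:
    key = (
        None if lengths is None else tuple(lengths),
        float(psf_px), int(n), int(seed), mode, int(context_px),
    )
    if key not in _null_cache:
        log.info("building %s null model (n=%d, seed=%d)", mode, n, seed)
        _null_cache[key] = build_null_model(
            lengths, psf_px, n, seed, mode=mode, context_px=context_px
        )
    return _null_cache[key]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    ``factor0 = None`` triggers matrix-profile estimation of the initial
    rescale factor; a known factor (1.0 for simulated data) bypasses it.
    The null model is built lazily (and cached per process) from
    ``null_lengths`` / ``null_n`` / ``null_seed`` unless one is supplied.
    """

    hmm: HMMParams = field(default_factory=HMMParams)
    factor0: float | None = 1.0
    mp_window: int | None = None
    null_mode: str = "max"
    null_lengths: tuple | None = None
    null_n: int = 500
    null_seed: int = 12345
    null_context_px: int = 500
    null_model: NullModel | None = None
    check_diagonal: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        hmm_kw = d.pop("hmm", {})
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        hmm_known = {f.name for f in fields(HMMParams)}
        bad = set(hmm_kw) - hmm_known
        if bad:
            raise ValueError(f"unknown hmm config keys: {sorted(bad)}")
        return cls(hmm=HMMParams(**hmm_kw), **d)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            if f.name == "null_model":
                continue
            v = getattr(self, f.name)
            if f.name == "hmm":
                v = {g.name: getattr(v, g.name) for g in fields(HMMParams)}
            elif isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def resolve_null(self, psf_px: float) -> NullModel:
        if self.null_model is not None:
            return self.null_model
        return _cached_null(
            self.null_lengths, psf_px, self.null_n, self.null_seed,
            self.null_mode, self.null_context_px,
        )


def align_pipeline(
    query: Barcode, reference: Barcode, config: RunConfig | None = None
) -> AlignmentTable:
    """Align two barcodes and return the final table of sub-barcode pairs.

    Raises on degenerate inputs; a run with no significant match returns a
    table whose rows are all flagged as not passed (or an empty table), not
    an error.
    """
    config = config or RunConfig()
    params = config.hmm
    query = znormalize(query)
    reference = znormalize(reference)

    if config.factor0 is None:
        factor0 = estimate_initial_factor(
            query, reference, window_px=config.mp_window
        )
        log.info("estimated initial rescale factor: %.4f", factor0)
    else:
        factor0 = float(config.factor0)

    result = scan_and_select(query, reference, factor0, params)
    log.info(
        "selected factor %.4f with %d raw segment(s)",
        result.factor, len(result.segments),
    )

    merged = merge_segments(
        result.segments,
        params.g,
        check_diagonal=config.check_diagonal,
        bounds=(len(query), len(reference)),
    )

    null = config.resolve_null(reference.psf_px)
    for s in merged:
        s.dist = segment_dist(query, reference, s)
        s.pvalue = segment_pvalue(s.dist, s.length_px, null)
    table = filter_table(merged, params, factor=result.factor)
    log.info(
        "%d/%d segment(s) significant at p <= %g",
        len(table.passing()), len(table.segments), params.p_thresh,
    )
    return table
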