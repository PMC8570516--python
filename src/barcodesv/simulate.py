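"""Synthetic barcode generation: random barcodes, calibrated noise, and
pixel-level structural variants with an exact ground-truth alignment.

The generator emulates densely-labelled optical-map data: Gaussian white
noise convolved with the optical point spread function (PSF) gives a random
barcode whose autocorrelation matches a dense-labelling profile; additive
noise is calibrated so that 1 - Pearson(noisy, clean) equals a requested
``noise_level``; structural variants are cut-and-paste edits of the pixel
array, recorded pixel-by-pixel in a ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .barcode import (
    DEFAULT_KB_PER_PX,
    DEFAULT_PSF_PX,
    Barcode,
    znormalize,
    znormalize_values,
)

__all__ = [
    "SVSpec",
    "NoiseConfig",
    "GroundTruthAlignment",
    "generate_random_barcode",
    "add_noise",
    "apply_svs",
    "make_benchmark_pair",
]

SV_TYPES = ("insertion", "deletion", "inversion", "repeat", "translocation")


@dataclass(frozen=True)
class SVSpec:
    """One structural variant, in 0-based half-open pixel coordinates of the
    barcode it is applied to.

    ``extra`` is the destination pixel for a translocation and the copy count
    (>= 2) for a repeat; unused otherwise.
    """

    sv_type: str
    position_px: int
    length_px: int
    extra: int | None = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.length_px < 1:
            raise ValueError("length_px must be >= 1")
        if self.position_px < 0:
            raise ValueError("position_px must be >= 0")
        if self.sv_type == "repeat":
            if self.extra is None or self.extra < 2:
                raise ValueError("repeat requires extra = copy count >= 2")
        if self.sv_type == "translocation" and self.extra is None:
            raise ValueError("translocation requires extra = destination px")

    @property
    def interval(self) -> tuple[int, int]:
        """Affected source interval [start, end); zero-width for insertion."""
        if self.sv_type == "insertion":
            return (self.position_px, self.position_px)
        return (self.position_px, self.position_px + self.length_px)


@dataclass(frozen=True)
class NoiseConfig:
    """Additive-noise settings.  ``noise_level`` targets
    1 - E[Pearson(noisy, clean)]; noise is PSF-convolved by default so that
    it has the same smoothness as the signal."""

    noise_level: float
    convolve_noise_with_psf: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.noise_level < 1):
            raise ValueError("noise_level must lie in [0, 1)")


@dataclass
class GroundTruthAlignment:
    """Per-pixel ground truth: each row states that query pixel ``query_px``
    corresponds to reference pixel ``ref_px`` with the given orientation
    (+1 forward, -1 inside an inverted interval).  One-to-many query rows are
    allowed (repeats)."""

    query_px: np.ndarray
    ref_px: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        self.query_px = np.asarray(self.query_px, dtype=int)
        self.ref_px = np.asarray(self.ref_px, dtype=int)
        self.orientation = np.asarray(self.orientation, dtype=int)
        if not (self.query_px.shape == self.ref_px.shape == self.orientation.shape):
            raise ValueError("ground-truth columns must have equal length")
        if self.orientation.size and not np.all(np.isin(self.orientation, (-1, 1))):
            raise ValueError("orientation must be +1 or -1")

    def __len__(self) -> int:
        return self.query_px.size

    @classmethod
    def identity(cls, n: int) -> "GroundTruthAlignment":
        idx = np.arange(n)
        return cls(idx.copy(), idx.copy(), np.ones(n, dtype=int))

    def swapped(self) -> "GroundTruthAlignment":
        """Exchange the query and reference roles."""
        return GroundTruthAlignment(
            self.ref_px.copy(), self.query_px.copy(), self.orientation.copy()
        )

    def to_frame(self) -> pd.DataFrame:
        """1-based table for serialization."""
        return pd.DataFrame(
            {
                "query_px": self.query_px + 1,
                "ref_px": self.ref_px + 1,
                "orientation": np.where(self.orientation > 0, "+", "-"),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GroundTruthAlignment":
        orient = np.where(np.asarray(df["orientation"]) == "-", -1, 1)
        return cls(
            np.asarray(df["query_px"], dtype=int) - 1,
            np.asarray(df["ref_px"], dtype=int) - 1,
            orient,
        )


def _smooth_white_noise(n: int, psf_px: float, rng: np.random.Generator) -> np.ndarray:
    """White Gaussian array convolved with a Gaussian PSF, edge-trimmed.

    3*psf_px of padding is generated on each side and discarded so the
    returned array carries no filter edge artifacts.
    """
    pad = int(np.ceil(3 * psf_px))
    raw = rng.standard_normal(n + 2 * pad)
    smooth = gaussian_filter1d(raw, sigma=psf_px, mode="constant")
    return smooth[pad : pad + n]


def generate_random_barcode(
    length_px: int,
    psf_px: float = DEFAULT_PSF_PX,
    kb_per_px: float = DEFAULT_KB_PER_PX,
    seed: int | np.random.Generator = 0,
) -> Barcode:
    """Random barcode: i.i.d. standard-Gaussian pixels convolved with a
    Gaussian PSF of standard deviation ``psf_px``, then z-normalized.

    Deterministic given ``seed`` (an int or an existing Generator).
    """
    if length_px < 1 or psf_px <= 0 or kb_per_px <= 0:
        raise ValueError("length_px, psf_px and kb_per_px must be positive")
    if length_px < 10 * psf_px:
        raise ValueError(
            f"length_px={length_px} too short for psf_px={psf_px} "
            "(need length >= 10 * psf)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = _smooth_white_noise(length_px, psf_px, rng)
    return znormalize(Barcode(values, kb_per_px=kb_per_px, psf_px=psf_px))


def add_noise(barcode: Barcode, cfg: NoiseConfig) -> Barcode:
    """Add independent noise calibrated so the expected Pearson correlation
    between output and input equals ``1 - cfg.noise_level``.

    The clean signal is z-scored, an independent unit-variance noise array
    (PSF-convolved when ``convolve_noise_with_psf``) is added scaled by
    alpha = sqrt(1/(1-noise_level)^2 - 1), and the sum is re-z-normalized:
    corr = 1/sqrt(1+alpha^2) = 1 - noise_level.
    """
    nl = cfg.noise_level
    if not (0 <= nl < 1):
        raise ValueError("noise_level must lie in [0, 1)")
    if nl == 0:
        return barcode.with_values(barcode.values.copy())
    rng = np.random.default_rng(cfg.seed)
    x = znormalize_values(barcode.values)
    n = x.size
    if cfg.convolve_noise_with_psf:
        noise = znormalize_values(_smooth_white_noise(n, barcode.psf_px, rng))
    else:
        noise = znormalize_values(rng.standard_normal(n))
    alpha = np.sqrt(1.0 / (1.0 - nl) ** 2 - 1.0)
    return znormalize(barcode.with_values(x + alpha * noise))


def _validate_svs(svs: Sequence[SVSpec], n: int) -> None:
    intervals = []
    for sv in svs:
        s, e = sv.interval
        if sv.sv_type == "insertion":
            if not (0 <= s <= n):
                raise ValueError(f"insertion point {s} outside barcode of {n} px")
        else:
            if not (0 <= s and e <= n):
                raise ValueError(
                    f"{sv.sv_type} interval [{s},{e}) outside barcode of {n} px"
                )
        if sv.sv_type == "translocation":
            dest = int(sv.extra)
            if not (0 <= dest <= n):
                raise ValueError(f"translocation destination {dest} out of bounds")
            if s < dest < e:
                raise ValueError("translocation destination inside its source")
        if e > s:
            intervals.append((s, e, sv))
    intervals.sort(key=lambda t: t[0])
    for (s1, e1, a), (s2, e2, b) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError(
                f"overlapping SV intervals [{s1},{e1}) and [{s2},{e2})"
            )
    # translocation destinations must not fall strictly inside any interval
    for sv in svs:
        if sv.sv_type == "translocation":
            dest = int(sv.extra)
            for s, e, other in intervals:
                if s < dest < e:
                    raise ValueError(
                        "translocation destination lands inside an SV interval"
                    )


def apply_svs(
    barcode: Barcode, svs: Sequence[SVSpec], seed: int | np.random.Generator = 0
) -> tuple[Barcode, GroundTruthAlignment]:
    """Apply cut-and-paste structural variants to the pixel array.

    All SV coordinates refer to the *input* barcode; affected intervals must
    not overlap.  Inserted material is freshly generated PSF-convolved random
    signal and has no ground-truth rows.  Returns the edited barcode and the
    ground truth mapping each edited-barcode pixel (``query_px``) to its
    source pixel in the input (``ref_px``), with orientation -1 inside
    inverted intervals.
    """
    n = len(barcode)
    _validate_svs(svs, n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # paste events keyed by input-coordinate position, in input list order
    pastes: dict[int, list[list[tuple[int | None, int]]]] = {}
    starts: dict[int, SVSpec] = {}
    for sv in svs:
        if sv.sv_type == "insertion":
            pastes.setdefault(sv.position_px, []).append(
                [(None, 1)] * sv.length_px
            )
        elif sv.sv_type == "translocation":
            s, e = sv.interval
            starts[s] = sv
            pastes.setdefault(int(sv.extra), []).append(
                [(j, 1) for j in range(s, e)]
            )
        else:
            starts[sv.position_px] = sv

    tokens: list[tuple[int | None, int]] = []
    i = 0
    while True:
        for block in pastes.get(i, ()):  # zero-width events before pixel i
            tokens.extend(block)
        if i >= n:
            break
        sv = starts.get(i)
        if sv is None:
            tokens.append((i, 1))
            i += 1
            continue
        s, e = sv.interval
        if sv.sv_type == "deletion" or sv.sv_type == "translocation":
            pass  # emits nothing here
        elif sv.sv_type == "inversion":
            tokens.extend((j, -1) for j in range(e - 1, s - 1, -1))
        elif sv.sv_type == "repeat":
            for _ in range(int(sv.extra)):
                tokens.extend((j, 1) for j in range(s, e))
        i = e

    out = np.empty(len(tokens))
    q_idx, r_idx, orient = [], [], []
    fresh_needed = sum(1 for t in tokens if t[0] is None)
    fresh = (
        _smooth_white_noise(fresh_needed, barcode.psf_px, rng)
        if fresh_needed
        else np.empty(0)
    )
    if fresh_needed > 1:
        fresh = znormalize_values(fresh)
    k = 0
    for j, (src, o) in enumerate(tokens):
        if src is None:
            out[j] = fresh[k]
            k += 1
        else:
            out[j] = barcode.values[src]
            q_idx.append(j)
            r_idx.append(src)
            orient.append(o)
    truth = GroundTruthAlignment(
        np.asarray(q_idx, dtype=int),
        np.asarray(r_idx, dtype=int),
        np.asarray(orient, dtype=int),
    )
    return barcode.with_values(out), truth


def _place_svs(
    n: int,
    sv_types: Sequence[str],
    sv_len_px: int,
    rng: np.random.Generator,
    edge_margin: int = 50,
    min_gap: int = 10,
    repeat_copies: int = 2,
) -> list[SVSpec]:
    """Random non-overlapping placements, one SV per equal-width chunk of the
    interior; translocation destinations land in a different chunk."""
    k = len(sv_types)
    if k == 0:
        return []
    lo, hi = edge_margin, n - edge_margin
    span = hi - lo
    chunk = span // k
    if chunk < sv_len_px + 2 * min_gap:
        raise ValueError(
            f"cannot place {k} SVs of {sv_len_px} px in a {n}-px barcode"
        )
    positions = []
    for c, sv_type in enumerate(sv_types):
        c_lo = lo + c * chunk + min_gap
        c_hi = lo + (c + 1) * chunk - min_gap - sv_len_px
        positions.append(int(rng.integers(c_lo, c_hi + 1)))

    def clear_of_intervals(p: int) -> bool:
        return all(
            not (pos - min_gap < p < pos + sv_len_px + min_gap)
            for pos, t in zip(positions, sv_types)
            if t != "insertion"
        )

    specs: list[SVSpec] = []
    for pos, sv_type in zip(positions, sv_types):
        extra: int | None = None
        if sv_type == "repeat":
            extra = repeat_copies
        elif sv_type == "translocation":
            # rejection-sample a destination outside every SV interval
            for _ in range(1000):
                cand = int(rng.integers(lo, hi + 1))
                if clear_of_intervals(cand):
                    extra = cand
                    break
            if extra is None:
                raise ValueError("could not place a translocation destination")
        specs.append(SVSpec(sv_type, pos, sv_len_px, extra))
    return specs


def make_benchmark_pair(
    barcode_len_px: int,
    sv_types: Sequence[str],
    sv_len_px: int,
    noise_level: float,
    seed: int,
    psf_px: float = DEFAULT_PSF_PX,
    kb_per_px: float = DEFAULT_KB_PER_PX,
    sv_specs: Sequence[SVSpec] | None = None,
    swap_roles: bool = False,
    noise_before_svs: bool = False,
    convolve_noise_with_psf: bool = True,
) -> tuple[Barcode, Barcode, GroundTruthAlignment]:
    """Build one benchmark instance: a clean random query barcode, a
    noisified SV-carrying reference barcode derived from it, and the exact
    ground-truth pixel alignment between them.

    SV placements are drawn at random (non-overlapping, away from the
    edges) unless explicit ``sv_specs`` are given.  ``noise_before_svs``
    noisifies first and then edits, matching the alternative dataset
    ordering; the ground truth is exact either way.  ``swap_roles``
    exchanges which barcode is called query.
    """
    ss = np.random.SeedSequence(seed)
    rng_bar, rng_place, rng_sv, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    clean = generate_random_barcode(barcode_len_px, psf_px, kb_per_px, rng_bar)
    if sv_specs is None:
        sv_specs = _place_svs(barcode_len_px, list(sv_types), sv_len_px, rng_place)
    noise_cfg = NoiseConfig(
        noise_level,
        convolve_noise_with_psf=convolve_noise_with_psf,
        seed=int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31)),
    )
    if noise_before_svs:
        base = add_noise(clean, noise_cfg)
        edited, truth = apply_svs(base, sv_specs, rng_sv)
        reference = znormalize(edited)
    else:
        edited, truth = apply_svs(clean, sv_specs, rng_sv)
        reference = add_noise(znormalize(edited), noise_cfg)
    query = clean
    # apply_svs maps edited px -> clean px; the benchmark convention is
    # query = clean original, reference = edited copy
    truth = truth.swapped()
    if swap_roles:
        return reference, query, truth.swapped()
    return query, reference, truth
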