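"""Plain-text barcode and table I/O.

Barcode files hold one intensity value per line; optional leading comment
lines of the form ``# key=value`` carry the pixel scale and PSF width.  A
TSV container with one named barcode per column is also supported.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .barcode import DEFAULT_KB_PER_PX, DEFAULT_PSF_PX, Barcode
from .simulate import GroundTruthAlignment

__all__ = [
    "read_barcode",
    "write_barcode",
    "read_barcodes_tsv",
    "write_barcodes_tsv",
    "read_ground_truth",
    "write_ground_truth",
]


def write_barcode(barcode: Barcode, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kb_per_px={float(barcode.kb_per_px)!r}\n")
        fh.write(f"# psf_px={float(barcode.psf_px)!r}\n")
        for v in barcode.values:
            fh.write(f"{float(v)!r}\n")  # repr round-trips exactly


def read_barcode(path: str | Path) -> Barcode:
    path = Path(path)
    meta = {"kb_per_px": DEFAULT_KB_PER_PX, "psf_px": DEFAULT_PSF_PX}
    values = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    k = k.strip()
                    if k in meta:
                        meta[k] = float(v)
                continue
            try:
                values.append(float(line))
            except ValueError as err:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value {line!r}"
                ) from err
    if not values:
        raise ValueError(f"{path}: no intensity values found")
    return Barcode(np.asarray(values), **meta)


def write_barcodes_tsv(barcodes: dict[str, Barcode], path: str | Path) -> None:
    """One barcode per column (columns padded with NaN to equal length)."""
    df = pd.DataFrame({name: pd.Series(bc.values) for name, bc in barcodes.items()})
    df.to_csv(path, sep="\t", index=False)


def read_barcodes_tsv(
    path: str | Path,
    kb_per_px: float = DEFAULT_KB_PER_PX,
    psf_px: float = DEFAULT_PSF_PX,
) -> dict[str, Barcode]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for name in df.columns:
        v = df[name].dropna().to_numpy(dtype=float)
        out[str(name)] = Barcode(v, kb_per_px=kb_per_px, psf_px=psf_px)
    return out


def write_ground_truth(truth: GroundTruthAlignment, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> GroundTruthAlignment:
    return GroundTruthAlignment.from_frame(pd.read_csv(path, sep="\t"))
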