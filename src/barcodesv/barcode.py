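"""Barcode container and normalization.

A barcode is a 1-D continuous intensity profile along a stretched DNA
molecule, sampled at a fixed physical scale (``kb_per_px``).  The optical
point spread function blurs features below ``psf_px`` pixels, which sets the
resolution floor of everything downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Barcode", "znormalize"]

#: default physical scale: 0.5 kb per pixel
DEFAULT_KB_PER_PX = 0.5
#: default PSF standard deviation in pixels (~1 kb at the default scale)
DEFAULT_PSF_PX = 2.0


@dataclass(frozen=True)
class Barcode:
    """Intensity profile of one DNA molecule (or a consensus of molecules).

    Parameters
    ----------
    values
        Intensity per pixel, arbitrary units.
    kb_per_px
        Physical scale in kilobases per pixel.
    psf_px
        Standard deviation of the Gaussian point spread function, in pixels.
    """

    values: np.ndarray
    kb_per_px: float = DEFAULT_KB_PER_PX
    psf_px: float = DEFAULT_PSF_PX

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("barcode values must be a non-empty 1-D array")
        if not (self.psf_px > 0):
            raise ValueError(f"psf_px must be positive, got {self.psf_px}")
        if not (self.kb_per_px > 0):
            raise ValueError(f"kb_per_px must be positive, got {self.kb_per_px}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def length_kb(self) -> float:
        return len(self) * self.kb_per_px

    def with_values(self, values: np.ndarray) -> "Barcode":
        """Copy of this barcode with new intensity values, same metadata."""
        return replace(self, values=np.asarray(values, dtype=float))


def znormalize(barcode: Barcode) -> Barcode:
    """Z-score a barcode: subtract the mean, divide by the (population) SD.

    Emissions and Pearson *dist* scores are computed on z-scores so that the
    method is invariant to the overall brightness and contrast of a
    measurement (affine transforms of the intensities).

    Raises
    ------
    ValueError
        If the barcode is constant (SD = 0) or shorter than 2 pixels.
    """
    v = barcode.values
    if v.size < 2:
        raise ValueError("cannot z-normalize a barcode shorter than 2 px")
    sd = v.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-normalize a constant barcode")
    return barcode.with_values((v - v.mean()) / sd)


def znormalize_values(v: np.ndarray) -> np.ndarray:
    """Z-score a raw array (helper for sub-barcodes and noise arrays)."""
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot z-normalize a constant array")
    return (v - v.mean()) / sd
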