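"""Perceptual hashing of spectrogram images.

A 64x64 grayscale image is compressed by a 2-D type-II DCT; the 8x8
low-frequency block in the top-left corner is thresholded at its own mean to
give a 64-bit binary code.  Similar images yield codes at small Hamming
distance, which is the similarity measure driving instance transfer.

The DCT is the standard orthonormal 2-D DCT-II (scaling factors
alpha(0) = sqrt(1/N), alpha(u>0) = sqrt(2/N)).  The mean threshold includes
the DC coefficient by default; ``exclude_dc=True`` gives the common p-Hash
variant that drops it.  A coefficient exactly equal to the mean maps to
bit 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

HASH_BITS = 64
_BLOCK = 8


@dataclass(frozen=True)
class HashCode:
    """A 64-bit perceptual hash."""

    bits: np.ndarray  # uint8 vector of length 64, values in {0, 1}
    source_id: tuple = ()

    def __post_init__(self) -> None:
        if self.bits.shape != (HASH_BITS,):
            raise ValueError(f"hash must have {HASH_BITS} bits, got {self.bits.shape}")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("hash bits must be 0/1")

    def as_uint64(self) -> int:
        return int(np.packbits(self.bits).view(">u8")[0])


def dct2(image: np.ndarray) -> np.ndarray:
    """Orthonormal 2-D type-II DCT of a square matrix (N >= 8). Invertible."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"dct2 needs a square matrix, got shape {image.shape}")
    if image.shape[0] < _BLOCK:
        raise ValueError(f"dct2 needs N >= {_BLOCK}, got N={image.shape[0]}")
    return sp_fft.dctn(image, type=2, norm="ortho")


def idct2(coeffs: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dct2`."""
    return sp_fft.idctn(np.asarray(coeffs, dtype=float), type=2, norm="ortho")


def phash(image: np.ndarray, exclude_dc: bool = False, source_id: tuple = ()) -> HashCode:
    """64-bit perceptual hash of a 64x64 grayscale image.

    Steps: orthonormal 2-D DCT; keep the 8x8 top-left (low-frequency) block;
    threshold every block coefficient at the block mean (bit 1 iff strictly
    above); flatten row-major.  Invariant to positive intensity scaling
    because coefficients and their mean scale together.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != (64, 64):
        raise ValueError(f"phash expects a 64x64 image, got {image.shape}")
    block = dct2(image)[:_BLOCK, :_BLOCK]
    if exclude_dc:
        flat = block.flatten()
        m = flat[1:].mean()
    else:
        m = block.mean()
    bits = (block.flatten() > m).astype(np.uint8)
    return HashCode(bits=bits, source_id=source_id)


def hamming(h1: HashCode, h2: HashCode) -> int:
    """Number of differing bits between two hash codes (range 0..64).

    For binary codes this equals the sum of squared bit differences.
    """
    if h1.bits.shape != h2.bits.shape:
        raise ValueError("hash length mismatch")
    return int(np.count_nonzero(h1.bits != h2.bits))
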