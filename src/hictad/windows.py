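"""Per-bin sub-matrix extraction.

Boundary calling is cast as binary classification of the 10x10 sub-matrix
centred (asymmetrically: four bins upstream, five downstream) on each bin:
``SubM_i = M[i-4 : i+6, i-4 : i+6]``.  At a TAD boundary the upper-left and
lower-right quadrants of this window are contact-rich while the off-diagonal
quadrants are depleted — the corner pattern the classifier learns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hic_io import ContactMatrix

WINDOW_SIZE = 10
_UP = 4  # bins included upstream of the centre; WINDOW_SIZE-_UP-1 downstream

SCALINGS = ("none", "log1p", "log1p+minmax")


@dataclass
class BinWindow:
    """The 10x10 contact sub-matrix around one bin."""

    center_bin: int
    values: np.ndarray
    chrom: str = "chr?"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (WINDOW_SIZE, WINDOW_SIZE):
            raise ValueError(
                f"window must be {WINDOW_SIZE}x{WINDOW_SIZE}, got {self.values.shape}"
            )


def extract_window(m: ContactMatrix, i: int) -> BinWindow:
    """Extract the window for bin ``i``, zero-padding outside the chromosome.

    Every bin gets a window; near the chromosome ends the out-of-range rows
    and columns are zero so edge bins still receive a prediction.
    """
    n = m.n_bins
    if not 0 <= i < n:
        raise IndexError(f"bin {i} out of range for {n} bins")
    lo, hi = i - _UP, i - _UP + WINDOW_SIZE
    out = np.zeros((WINDOW_SIZE, WINDOW_SIZE), dtype=float)
    src_lo, src_hi = max(lo, 0), min(hi, n)
    dst_lo, dst_hi = src_lo - lo, src_hi - lo
    out[dst_lo:dst_hi, dst_lo:dst_hi] = m.values[src_lo:src_hi, src_lo:src_hi]
    return BinWindow(center_bin=i, values=out, chrom=m.chrom)


def preprocess_window(w: BinWindow, scaling: str = "log1p+minmax") -> BinWindow:
    """Scale window entries for the classifier.

    Default is elementwise ``log(1+x)`` followed by per-window min-max scaling
    to [0, 1]; a constant window maps to all zeros.  Raw contact counts span
    orders of magnitude, and per-window scaling makes the classifier sensitive
    to the contact *pattern* rather than the local sequencing depth.
    """
    if scaling not in SCALINGS:
        raise ValueError(f"scaling must be one of {SCALINGS}, got {scaling!r}")
    v = w.values
    if scaling == "none":
        return BinWindow(w.center_bin, v.copy(), w.chrom)
    v = np.log1p(v)
    if scaling == "log1p+minmax":
        lo, hi = v.min(), v.max()
        v = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    return BinWindow(w.center_bin, v, w.chrom)


def windows_for_chromosome(m: ContactMatrix) -> list[BinWindow]:
    """One window per bin, ordered by centre bin."""
    return [extract_window(m, i) for i in range(m.n_bins)]
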