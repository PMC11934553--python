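"""Reading, writing and balancing Hi-C contact matrices.

A chromosome-level Hi-C experiment is summarised by a symmetric matrix ``M``
whose entry ``m_ij`` counts ligation products between genomic bins ``i`` and
``j`` at a fixed resolution (default 25 kb).  This module reads the two text
encodings in common use (dense whitespace-delimited dumps and juicer-style
sparse triplets), applies vanilla-coverage (VC) and Knight-Ruiz-style (KR)
matrix balancing, and handles BED interval tracks.

Binary ``.hic``/``.cool`` containers are deliberately out of scope: the tool
consumes text dumps, which keeps the I/O layer dependency-free.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class MatrixFormatError(ValueError):
    """Raised when an input file is not a valid contact-matrix encoding."""


class ConvergenceError(RuntimeError):
    """Raised when iterative matrix balancing fails to reach tolerance."""


@dataclass
class ContactMatrix:
    """A symmetric, nonnegative per-chromosome contact matrix.

    Parameters
    ----------
    values : ndarray of shape (n_bins, n_bins)
        Contact counts (raw) or balanced counts.  Symmetric, ``>= 0``.
    resolution : int
        Bin width in base pairs.
    chrom : str
        Chromosome label.
    normalization : {"raw", "KR", "VC"}
        Provenance tag for the values.
    """

    values: np.ndarray
    resolution: int = 25_000
    chrom: str = "chr?"
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise MatrixFormatError(
                f"contact matrix must be square, got shape {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("contact matrix entries must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def copy(self) -> "ContactMatrix":
        return replace(self, values=self.values.copy())


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str = "."

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class PeakTrack:
    """Sorted genomic intervals (0-based, half-open) from a BED track."""

    intervals: list[Interval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def for_chrom(self, chrom: str) -> "PeakTrack":
        return PeakTrack([iv for iv in self.intervals if iv.chrom == chrom])

    def midpoints(self) -> np.ndarray:
        return np.array([iv.midpoint for iv in self.intervals], dtype=float)


def _symmetrize(values: np.ndarray) -> np.ndarray:
    return 0.5 * (values + values.T)


def read_dense_matrix(path: os.PathLike | str, resolution: int = 25_000,
                      chrom: str = "chr?") -> ContactMatrix:
    """Read a whitespace-delimited square matrix dump.

    NaN entries (unmappable bins in some dumps) become 0.  Slightly
    asymmetric input — some tools dump a single triangle or round
    asymmetrically — is symmetrized by averaging with its transpose.
    """
    try:
        values = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise MatrixFormatError(f"could not parse dense matrix {path}: {exc}") from exc
    if values.shape[0] != values.shape[1]:
        raise MatrixFormatError(
            f"dense matrix must be square, got {values.shape[0]}x{values.shape[1]}"
        )
    values = np.nan_to_num(values, nan=0.0)
    if np.any(values < 0):
        raise ValueError("contact counts must be nonnegative")
    return ContactMatrix(_symmetrize(values), resolution=resolution, chrom=chrom)


def write_dense_matrix(m: ContactMatrix, path: os.PathLike | str) -> None:
    # %.17g round-trips float64 exactly, so write-then-read is bit-identical
    np.savetxt(path, m.values, fmt="%.17g", delimiter="\t")


def read_sparse_triplets(path: os.PathLike | str, resolution: int, chrom: str,
                         n_bins: int) -> ContactMatrix:
    """Read juicer-dump style ``i j count`` triplets into a dense matrix.

    Coordinates may be 0-based bin indices or base-pair start positions that
    are multiples of the resolution; base pairs are auto-detected when any
    coordinate is ``>= n_bins``.  Duplicate entries are summed; the matrix is
    mirrored across the diagonal.
    """
    values = np.zeros((n_bins, n_bins), dtype=float)
    with open(path) as fh:
        if not fh.read().strip():
            return ContactMatrix(values, resolution=resolution, chrom=chrom)
    data = np.loadtxt(path, dtype=float, ndmin=2)
    if data.shape[1] < 3:
        raise MatrixFormatError("sparse triplet file needs 3 columns: i j count")
    ii, jj, counts = data[:, 0], data[:, 1], data[:, 2]
    if np.any(counts < 0):
        raise ValueError("contact counts must be nonnegative")
    coords = np.concatenate([ii, jj])
    if np.any(coords >= n_bins):  # base-pair positions
        if np.any(np.mod(coords, resolution) != 0):
            raise ValueError(
                "coordinates look like base pairs but are not multiples of the resolution"
            )
        ii = ii / resolution
        jj = jj / resolution
    bi = ii.astype(int)
    bj = jj.astype(int)
    if np.any(bi < 0) or np.any(bj < 0) or np.any(bi >= n_bins) or np.any(bj >= n_bins):
        raise ValueError("bin index out of range for n_bins=%d" % n_bins)
    np.add.at(values, (bi, bj), counts)
    upper = np.triu(values, 1)
    lower = np.tril(values, -1)
    sym = np.diag(np.diag(values)) + upper + lower + upper.T + lower.T
    return ContactMatrix(sym, resolution=resolution, chrom=chrom)


def vc_normalize(m: ContactMatrix) -> ContactMatrix:
    """Vanilla-coverage balancing: divide each contact by the product of its
    two loci's total coverage, then rescale to the input's total mass.

    Rows with zero coverage (gap bins) are left untouched.  The rescaling
    convention is ours: downstream steps are scale-covariant, so any fixed
    convention is safe, and mass preservation keeps the output on a familiar
    count-like scale.
    """
    total = m.values.sum()
    if total == 0:
        raise ValueError("cannot VC-normalize an all-zero matrix")
    r = m.row_sums()
    nz = r > 0
    scale = np.zeros_like(r)
    scale[nz] = 1.0 / r[nz]
    out = m.values * scale[:, None] * scale[None, :]
    out *= total / out.sum()
    return ContactMatrix(out, resolution=m.resolution, chrom=m.chrom,
                         normalization="VC")


def kr_normalize(m: ContactMatrix, tol: float = 1e-6,
                 max_iter: int = 3000) -> ContactMatrix:
    """Balance the matrix so every non-gap row sums to the input's mean row sum.

    Finds a diagonal scaling ``D`` with ``D @ M @ D`` having equal row sums —
    the Knight-Ruiz fixed point — via symmetric Sinkhorn iteration.  Zero rows
    are excluded before balancing and restored as zeros afterwards.

    Raises
    ------
    ConvergenceError
        If the relative row-sum spread still exceeds ``tol`` after
        ``max_iter`` sweeps.
    """
    r = m.row_sums()
    keep = r > 0
    if not np.any(keep):
        raise ValueError("cannot KR-normalize an all-zero matrix")
    sub = m.values[np.ix_(keep, keep)]
    target = sub.sum(axis=1).mean()
    d = np.ones(sub.shape[0])
    residual = np.inf
    for _ in range(max_iter):
        rowsums = d * (sub @ d)
        if np.any(rowsums <= 0):
            raise ConvergenceError(
                "matrix support is too sparse for balancing (decomposable block?)"
            )
        residual = np.max(np.abs(rowsums - target)) / target
        if residual < tol:
            break
        d *= np.sqrt(target / rowsums)
    else:
        raise ConvergenceError(
            f"KR balancing did not reach tol={tol:g} in {max_iter} iterations "
            f"(residual {residual:.3g})"
        )
    out = np.zeros_like(m.values)
    out[np.ix_(keep, keep)] = _symmetrize(d[:, None] * sub * d[None, :])
    return ContactMatrix(out, resolution=m.resolution, chrom=m.chrom,
                         normalization="KR")


NORMALIZERS = {"raw": lambda m: m, "KR": kr_normalize, "VC": vc_normalize}


def normalize(m: ContactMatrix, method: str = "KR") -> ContactMatrix:
    """Dispatch to a balancing method by name ({"raw", "KR", "VC"})."""
    try:
        return NORMALIZERS[method](m)
    except KeyError:
        raise ValueError(f"unknown normalization {method!r}") from None


def read_bed_intervals(path: os.PathLike | str) -> PeakTrack:
    """Read a BED3+ file into a sorted PeakTrack (overlaps are preserved)."""
    intervals: list[Interval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise MatrixFormatError(f"{path}:{line_no}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise MatrixFormatError(
                    f"{path}:{line_no}: start {start} >= end {end}"
                )
            name = parts[3] if len(parts) > 3 else "."
            intervals.append(Interval(chrom, start, end, name))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return PeakTrack(intervals)


def write_boundaries_bed(boundaries: Iterable[int], resolution: int, chrom: str,
                         path: os.PathLike | str) -> None:
    """Write boundary bins as 1-bin BED intervals."""
    with open(path, "w") as fh:
        for b in sorted(boundaries):
            fh.write(f"{chrom}\t{b * resolution}\t{(b + 1) * resolution}\n")


def read_boundaries(path: os.PathLike | str, resolution: int,
                    chrom: str | None = None) -> list[int]:
    """Read boundary bins from BED (interval start // resolution) or a
    1-column bin-index text file."""
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith(("#", "track")):
                first = line
                break
    if not first:
        return []
    n_cols = len(first.split())
    if n_cols == 1:
        bins = np.loadtxt(path, dtype=int, ndmin=1)
        return sorted(set(int(b) for b in bins))
    track = read_bed_intervals(path)
    if chrom is not None:
        track = track.for_chrom(chrom)
    return sorted({int(iv.start // resolution) for iv in track})


def _iter_nodes(nodes):
    for node in nodes:
        yield node
        yield from _iter_nodes(node.children)


def write_domains_bed(tads: Sequence, resolution: int, chrom: str,
                      path: os.PathLike | str) -> None:
    """Write a TAD hierarchy as BED4 with the nesting level in column 4.

    One line per node (parents and leaves); bin spans ``[start, end]`` become
    0-based half-open base-pair intervals ``[start*res, (end+1)*res)``.  Sorted
    by start, then by descending span so parents precede their children.
    """
    rows = [(node.start_bin * resolution, (node.end_bin + 1) * resolution, node.level)
            for node in _iter_nodes(tads)]
    rows.sort(key=lambda r: (r[0], -(r[1] - r[0])))
    with open(path, "w") as fh:
        for start, end, level in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{level}\n")


def filter_report_to_tsv(stats, path: os.PathLike | str) -> None:
    """Write per-candidate filter statistics as TSV."""
    frame = pd.DataFrame(
        [
            {
                "bin": s.bin, "p_value": s.p_value, "kept": s.kept,
                "n_upstream": len(s.U), "n_downstream": len(s.D),
                "n_cross": len(s.R),
            }
            for s in stats
        ]
    )
    frame.to_csv(path, sep="\t", index=False)
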