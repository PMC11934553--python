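"""Assembling boundaries into a nested TAD hierarchy.

Consecutive boundary bins delimit leaf TADs; adjacent TADs whose mean
contact profiles are sufficiently similar (cosine similarity strictly above
a threshold ``dt``, default 0.8) are merged into a parent domain, and
merging continues best-first until no adjacent pair qualifies — producing a
containment tree of nested domains.  Runs of zero-coverage bins of at least
``h`` bins (default 5) are annotated as gap regions, and no merge may span
a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hic_io import ContactMatrix


@dataclass
class TADNode:
    """A domain spanning bins ``[start_bin, end_bin]`` (both boundary bins).

    Children, when present, tile the parent contiguously: the first child
    starts at ``start_bin``, the last ends at ``end_bin``, and consecutive
    children share a boundary.
    """

    start_bin: int
    end_bin: int
    children: list["TADNode"] = field(default_factory=list)
    level: int = 0

    def __post_init__(self) -> None:
        if self.start_bin >= self.end_bin:
            raise ValueError("TAD needs start_bin < end_bin")

    @property
    def span(self) -> int:
        return self.end_bin - self.start_bin

    def leaves(self) -> list["TADNode"]:
        if not self.children:
            return [self]
        out: list[TADNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def validate(self) -> None:
        """Check containment/tiling invariants recursively."""
        if self.children:
            if self.children[0].start_bin != self.start_bin:
                raise AssertionError("first child must start at parent start")
            if self.children[-1].end_bin != self.end_bin:
                raise AssertionError("last child must end at parent end")
            for a, b in zip(self.children, self.children[1:]):
                if a.end_bin != b.start_bin:
                    raise AssertionError("consecutive children must share a boundary")
            for c in self.children:
                if not (self.start_bin <= c.start_bin and c.end_bin <= self.end_bin
                        and c.span < self.span):
                    raise AssertionError("child must be strictly contained in parent")
                if c.level != self.level + 1:
                    raise AssertionError("child level must be parent level + 1")
                c.validate()


@dataclass(frozen=True)
class GapRegion:
    start_bin: int
    end_bin: int  # inclusive

    @property
    def length(self) -> int:
        return self.end_bin - self.start_bin + 1


def boundaries_to_tads(boundaries) -> list[TADNode]:
    """n sorted boundary bins -> n-1 leaf TADs between consecutive pairs."""
    b = sorted(set(int(x) for x in boundaries))
    return [TADNode(start_bin=lo, end_bin=hi) for lo, hi in zip(b, b[1:])]


def detect_gaps(m: ContactMatrix, h: int = 5) -> list[GapRegion]:
    """Maximal runs of >= h consecutive zero-coverage bins."""
    if h < 1:
        raise ValueError("gap size h must be >= 1")
    zero = m.row_sums() == 0
    gaps: list[GapRegion] = []
    start = None
    for i, z in enumerate(zero):
        if z and start is None:
            start = i
        elif not z and start is not None:
            if i - start >= h:
                gaps.append(GapRegion(start, i - 1))
            start = None
    if start is not None and m.n_bins - start >= h:
        gaps.append(GapRegion(start, m.n_bins - 1))
    return gaps


def tad_profile(m: ContactMatrix, t: TADNode, flank: int = 40,
                columns: tuple[int, int] | None = None) -> np.ndarray:
    """Mean contact profile of a TAD: average of its rows over the columns
    ``[start-flank, end+flank]`` (or an explicit column range), zero-padded
    where the range leaves the chromosome so profiles computed over the same
    range align entry by entry."""
    lo, hi = (t.start_bin - flank, t.end_bin + flank) if columns is None else columns
    rows = m.values[t.start_bin:t.end_bin + 1]
    mean_row = rows.mean(axis=0)
    out = np.zeros(hi - lo + 1)
    src_lo, src_hi = max(lo, 0), min(hi, m.n_bins - 1)
    if src_lo <= src_hi:
        out[src_lo - lo:src_hi - lo + 1] = mean_row[src_lo:src_hi + 1]
    return out


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def _pair_similarity(m: ContactMatrix, left: TADNode, right: TADNode,
                     flank: int) -> float:
    cols = (left.start_bin - flank, right.end_bin + flank)
    return cosine_similarity(tad_profile(m, left, columns=cols),
                             tad_profile(m, right, columns=cols))


def _crosses_gap(left: TADNode, right: TADNode, gaps) -> bool:
    return any(g.start_bin <= right.end_bin and g.end_bin >= left.start_bin
               for g in gaps)


def _assign_levels(node: TADNode, level: int) -> None:
    node.level = level
    for c in node.children:
        _assign_levels(c, level + 1)


def merge_hierarchy(m: ContactMatrix, leaves: list[TADNode], dt: float = 0.8,
                    gaps=(), flank: int = 40) -> list[TADNode]:
    """Best-first agglomerative merging of adjacent TADs.

    Repeatedly merges the adjacent pair with the highest cosine similarity
    strictly above ``dt`` (leftmost pair on ties), recomputing profiles for
    merged nodes, and never merging a pair whose combined span touches a gap
    region.  Returns the root nodes with levels assigned top-down.
    """
    for a, b in zip(leaves, leaves[1:]):
        if a.end_bin > b.start_bin:
            raise ValueError("leaves must be ordered and non-overlapping")
    current = [TADNode(t.start_bin, t.end_bin, list(t.children)) for t in leaves]
    while len(current) > 1:
        best_sim, best_idx = dt, None
        for idx in range(len(current) - 1):
            left, right = current[idx], current[idx + 1]
            if left.end_bin != right.start_bin or _crosses_gap(left, right, gaps):
                continue
            sim = _pair_similarity(m, left, right, flank)
            if sim > best_sim:  # strict ">" both vs dt and vs earlier pairs
                best_sim, best_idx = sim, idx
        if best_idx is None:
            break
        left, right = current[best_idx], current[best_idx + 1]
        parent = TADNode(left.start_bin, right.end_bin, children=[left, right])
        current[best_idx:best_idx + 2] = [parent]
    for root in current:
        _assign_levels(root, 0)
    return current


def assemble(m: ContactMatrix, boundaries, dt: float = 0.8, h: int = 5,
             flank: int = 40) -> tuple[list[TADNode], list[GapRegion]]:
    """boundaries -> leaf TADs -> merged hierarchy, with gap detection."""
    gaps = detect_gaps(m, h=h)
    leaves = boundaries_to_tads(boundaries)
    roots = merge_hierarchy(m, leaves, dt=dt, gaps=gaps, flank=flank)
    return roots, gaps


def hierarchy_to_text(roots: list[TADNode]) -> str:
    """Indented text rendering of the hierarchy (one node per line)."""
    lines: list[str] = []

    def walk(node: TADNode) -> None:
        lines.append("  " * node.level
                     + f"[{node.start_bin}, {node.end_bin}] level={node.level}")
        for c in node.children:
            walk(c)

    for r in roots:
        walk(r)
    return "\n".join(lines) + ("\n" if lines else "")


def flat_partition(roots: list[TADNode]) -> list[tuple[int, int]]:
    """Leaf intervals (start_bin, end_bin) of the hierarchy, left to right."""
    out: list[tuple[int, int]] = []
    for r in roots:
        out.extend((leaf.start_bin, leaf.end_bin) for leaf in r.leaves())
    return out
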