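"""End-to-end TAD calling: predict -> filter -> assemble."""

from __future__ import annotations

from dataclasses import dataclass, field

from .assembly import GapRegion, TADNode, assemble
from .filtering import FilterStats, filter_boundaries
from .hic_io import ContactMatrix
from .model import BoundaryNet, BoundaryScore, predict_boundaries


@dataclass
class PipelineResult:
    """Everything one chromosome's TAD call produces."""

    scores: list[BoundaryScore]
    candidate_boundaries: list[int]
    boundaries: list[int]
    filter_stats: list[FilterStats]
    tads: list[TADNode] = field(default_factory=list)
    gaps: list[GapRegion] = field(default_factory=list)


def call_tads(net: BoundaryNet, m: ContactMatrix, threshold: float | None = None,
              w: int = 5, alpha: float = 0.05, dt: float = 0.8, h: int = 5,
              flank: int = 40, bh: bool = False) -> PipelineResult:
    """Run the full caller on one chromosome.

    Every bin is scored by the classifier; bins above the decision threshold
    become candidates; the Wilcoxon rank-sum filter drops candidates without
    significant within-vs-cross contact contrast; surviving boundaries are
    assembled into a nested hierarchy with gap annotation.
    """
    scores, candidates = predict_boundaries(net, m, threshold)
    kept, stats = filter_boundaries(m, candidates, w=w, alpha=alpha, bh=bh)
    tads, gaps = assemble(m, kept, dt=dt, h=h, flank=flank)
    return PipelineResult(scores=scores, candidate_boundaries=candidates,
                          boundaries=kept, filter_stats=stats, tads=tads,
                          gaps=gaps)
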