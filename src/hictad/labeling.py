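"""Training-sample construction from consensus boundary calls.

TAD boundary detection has no experimental ground truth, so positives are
bins that at least two independent callers agree on.  Positive windows are
augmented by a 90-degree clockwise rotation (doubling their count) and
negatives are drawn uniformly from the remaining bins at a 4:1
negative:positive ratio, computed against the post-augmentation positive
count.  Chromosomes are split whole into train/validation/test so no matrix
leaks across splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hic_io import ContactMatrix
from .windows import BinWindow, extract_window, preprocess_window

# chr1-12 train, chr13-19 validation, chr20-22 test; chrX excluded.
DEFAULT_SPLIT_SCHEME: dict[str, str] = {
    **{f"chr{i}": "train" for i in range(1, 13)},
    **{f"chr{i}": "validation" for i in range(13, 20)},
    **{f"chr{i}": "test" for i in range(20, 23)},
}


@dataclass
class LabeledSample:
    window: BinWindow
    label: int
    augmented: bool = False
    chrom: str = "chr?"
    center_bin: int = -1

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.augmented and self.label != 1:
            raise ValueError("only positive samples are augmented")


@dataclass
class DatasetSplit:
    train: list[LabeledSample] = field(default_factory=list)
    validation: list[LabeledSample] = field(default_factory=list)
    test: list[LabeledSample] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {"train": len(self.train), "validation": len(self.validation),
                "test": len(self.test)}


def consensus_boundaries(call_sets, min_support: int = 2,
                         tolerance_bins: int = 0) -> list[int]:
    """Bins called a boundary by at least ``min_support`` distinct callers.

    Matching is exact-bin by default; ``tolerance_bins=1`` lets calls within
    one bin of each other support the same boundary (the supporting caller's
    vote goes to the queried bin).
    """
    call_sets = [set(s) for s in call_sets]
    if len(call_sets) < min_support:
        raise ValueError(
            f"need at least {min_support} call sets, got {len(call_sets)}"
        )
    union = sorted(set().union(*call_sets))
    out = []
    for b in union:
        support = 0
        for s in call_sets:
            if any(abs(b - c) <= tolerance_bins for c in s) if tolerance_bins else b in s:
                support += 1
        if support >= min_support:
            out.append(b)
    return out


def augment_positive(w: BinWindow) -> BinWindow:
    """Rotate the window 90 degrees clockwise: ``out[r][c] = in[9-c][r]``."""
    rotated = np.rot90(w.values, k=-1)
    return BinWindow(center_bin=w.center_bin, values=rotated.copy(), chrom=w.chrom)


def build_dataset(m: ContactMatrix, positives, neg_ratio: int = 4,
                  seed: int = 123, scaling: str = "log1p+minmax",
                  exclude_flank: int = 0) -> list[LabeledSample]:
    """Build labeled windows for one chromosome.

    Each positive bin contributes its window as-is and once rotated, so the
    positive count doubles; negatives are sampled uniformly without
    replacement from non-positive bins, ``neg_ratio`` per augmented positive.
    ``exclude_flank=k`` additionally bars bins within ``k`` of any positive
    from the negative pool (near-boundary bins can carry partial
    boundary-like signal).
    """
    positives = sorted(set(int(b) for b in positives))
    if not positives:
        raise ValueError("need at least one positive bin")
    if any(b < 0 or b >= m.n_bins for b in positives):
        raise ValueError("positive bin out of range")

    samples: list[LabeledSample] = []
    for b in positives:
        w = preprocess_window(extract_window(m, b), scaling)
        samples.append(LabeledSample(w, 1, False, m.chrom, b))
        w_aug = preprocess_window(augment_positive(extract_window(m, b)), scaling)
        samples.append(LabeledSample(w_aug, 1, True, m.chrom, b))

    n_neg = neg_ratio * len(samples)
    excluded = set(positives)
    if exclude_flank:
        for b in positives:
            excluded.update(range(b - exclude_flank, b + exclude_flank + 1))
    pool = np.array([b for b in range(m.n_bins) if b not in excluded])
    if n_neg > len(pool):
        raise ValueError(
            f"need {n_neg} negative bins but only {len(pool)} candidates"
        )
    rng = np.random.default_rng(seed)
    for b in sorted(rng.choice(pool, size=n_neg, replace=False)):
        w = preprocess_window(extract_window(m, int(b)), scaling)
        samples.append(LabeledSample(w, 0, False, m.chrom, int(b)))
    return samples


def split_by_chromosome(samples_by_chrom: dict[str, list[LabeledSample]],
                        scheme: dict[str, str] | None = None) -> DatasetSplit:
    """Assign whole chromosomes to train/validation/test per ``scheme``."""
    scheme = DEFAULT_SPLIT_SCHEME if scheme is None else scheme
    split = DatasetSplit()
    for chrom, samples in samples_by_chrom.items():
        if chrom not in scheme:
            raise ValueError(f"chromosome {chrom!r} not assigned to any split")
        dest = scheme[chrom]
        if dest not in ("train", "validation", "test"):
            raise ValueError(f"unknown split {dest!r} for {chrom}")
        getattr(split, dest).extend(samples)
    return split
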