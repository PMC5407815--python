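"""Normalized junction expression and fold changes.

Relative expression of a junction is the number of unique supporting
fragments normalized to the total number of raw reads in the sample;
``fpm`` scales this ratio by 1e6 (fragments per million raw reads).
Cross-sample comparisons normalize each sample by its own raw total and
aggregate the per-sample fpm (arithmetic mean by default, median
configurable) before forming the ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, median
from typing import Sequence

__all__ = [
    "ExpressionRecord",
    "FoldChange",
    "normalized_expression",
    "fold_change",
    "group_fold_change",
    "round_half_up",
]


@dataclass(frozen=True)
class ExpressionRecord:
    sample_id: str
    junction_id: str
    supporting_count: int
    total_raw_reads: int

    def __post_init__(self):
        if self.supporting_count < 0:
            raise ValueError("supporting_count must be >= 0")
        if self.total_raw_reads <= 0:
            raise ValueError("total_raw_reads must be > 0")

    @property
    def normalized(self) -> float:
        return self.supporting_count / self.total_raw_reads

    @property
    def fpm(self) -> float:
        return self.normalized * 1e6

    @property
    def log2_fpm(self) -> float | None:
        """log2(fpm); missing (None) for zero support."""
        if self.supporting_count == 0:
            return None
        return math.log2(self.fpm)


@dataclass(frozen=True)
class FoldChange:
    ratio: float  # a / b
    fold: int  # round-half-up of max(ratio, 1/ratio)
    direction: str  # "up" if a >= b else "down"


def round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def normalized_expression(
    evidence, total_raw_reads: int, sample_id: str, junction_id: str
) -> ExpressionRecord:
    """Build an ExpressionRecord from SupportEvidence (or an int count)."""
    count = evidence if isinstance(evidence, int) else evidence.total_supporting
    return ExpressionRecord(
        sample_id=sample_id,
        junction_id=junction_id,
        supporting_count=count,
        total_raw_reads=total_raw_reads,
    )


def fold_change(a: ExpressionRecord, b: ExpressionRecord) -> FoldChange:
    """Expression ratio a/b with its nearest-integer fold.

    The samples may differ; each record is already normalized by its own
    raw-read total.  Undefined when b has zero support.
    """
    if b.normalized == 0:
        raise ValueError("fold change undefined against zero expression")
    ratio = a.normalized / b.normalized
    magnitude = max(ratio, 1.0 / ratio) if ratio > 0 else 0.0
    return FoldChange(
        ratio=ratio,
        fold=round_half_up(magnitude),
        direction="up" if ratio >= 1 else "down",
    )


def group_fold_change(
    group_a: Sequence[ExpressionRecord],
    group_b: Sequence[ExpressionRecord],
    aggregate: str = "mean",
) -> FoldChange:
    """Fold change between two sample groups.

    Each sample's fpm is computed against its own raw total; the group
    level is the mean (or median) of those per-sample values.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    agg = {"mean": mean, "median": median}[aggregate]
    a = agg([r.fpm for r in group_a])
    b = agg([r.fpm for r in group_b])
    if b == 0:
        raise ValueError("fold change undefined against zero expression")
    ratio = a / b
    magnitude = max(ratio, 1.0 / ratio) if ratio > 0 else 0.0
    return FoldChange(
        ratio=ratio,
        fold=round_half_up(magnitude),
        direction="up" if ratio >= 1 else "down",
    )
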