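"""Core domain containers shared by every analysis module.

All genomic coordinates are 0-based half-open (BED convention), both in
memory and on disk.  A transcription start site (TSS) is a single
0-based position.  Summits are stored as absolute positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally with a summit and score.

    ``summit`` is the absolute position of maximal enrichment (for ChIP
    peaks); when absent the interval midpoint stands in for it.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float | None = None
    strand: str = "."
    summit: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def effective_summit(self) -> int:
        """Summit if recorded, else the interval midpoint."""
        if self.summit is not None:
            return self.summit
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At least 1 bp of intersection."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between two intervals; 0 when overlapping; None across chroms."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


def _sort_key(iv: GenomicInterval):
    return (iv.chrom, iv.start, iv.end)


class PeakSet:
    """An ordered collection of :class:`GenomicInterval`.

    Intervals are kept sorted by (chrom, start, end).  After
    :func:`adipotf.intervals.merge_peak_calls` the set is additionally
    internally non-overlapping.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), name: str = ""):
        self.name = name
        self.intervals: list[GenomicInterval] = sorted(intervals, key=_sort_key)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet(name={self.name!r}, n={len(self)})"

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def summits(self) -> np.ndarray:
        return np.array([iv.effective_summit for iv in self.intervals], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
                "summit": [iv.effective_summit for iv in self.intervals],
                "source": [iv.source for iv in self.intervals],
            }
        )


@dataclass(frozen=True)
class GeneModel:
    """Gene with strand, TSS, body and exons.

    The TSS coincides with the strand-appropriate body edge: ``body.start``
    on '+' genes, ``body.end - 1`` on '-' genes.  Exons are disjoint,
    sorted, and contained in the body.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        expected = self.body.start if self.strand == "+" else self.body.end - 1
        if self.tss != expected:
            raise ValueError(
                f"gene {self.gene_id}: tss {self.tss} does not sit on the "
                f"strand-appropriate body edge ({expected})"
            )
        prev_end = self.body.start
        for ex in self.exons:
            if ex.start < prev_end or ex.end > self.body.end:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be disjoint, sorted and "
                    "contained in the body"
                )
            prev_end = ex.end

    def tss_window(self, flank: int) -> GenomicInterval:
        """Half-open window covering tss +/- flank (inclusive of both edges)."""
        return GenomicInterval(
            self.chrom, max(0, self.tss - flank), self.tss + flank + 1
        )

    def regulatory_window(self, upstream: int = 500) -> GenomicInterval:
        """Gene body extended by ``upstream`` bp upstream of the TSS (strand-aware)."""
        if self.strand == "+":
            return GenomicInterval(
                self.chrom, max(0, self.body.start - upstream), self.body.end
            )
        return GenomicInterval(self.chrom, self.body.start, self.body.end + upstream)


@dataclass
class GenomeLayout:
    """Chromosome name -> length (bp)."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, ln in self.lengths.items():
            if ln <= 0:
                raise ValueError(f"chromosome {chrom}: length must be > 0")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def validate(self, peaks: PeakSet) -> None:
        for iv in peaks:
            if iv.chrom not in self.lengths:
                raise KeyError(f"unknown chromosome {iv.chrom!r}")
            if iv.end > self.lengths[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {self.lengths[iv.chrom]}"
                )


class CountMatrix:
    """Features x samples integer counts plus per-sample metadata.

    ``counts`` is a DataFrame indexed by feature id with sample ids as
    columns; ``samples`` is a DataFrame indexed by sample id with at least
    a ``condition`` column (``replicate``/``timepoint`` optional).
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame):
        counts = counts.copy()
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(counts.columns) - set(samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for: {sorted(missing)}")
        self.counts = counts
        self.samples = samples.loc[list(counts.columns)].copy()

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_condition(self, condition: str) -> list[str]:
        mask = self.samples["condition"] == condition
        return list(self.samples.index[mask])

    def __repr__(self) -> str:
        return f"CountMatrix({self.counts.shape[0]} features x {self.counts.shape[1]} samples)"


def make_interval(chrom, start, end, **kw) -> GenomicInterval:
    """Convenience constructor used heavily in tests."""
    return GenomicInterval(chrom, int(start), int(end), **kw)


def replace_interval(iv: GenomicInterval, **kw) -> GenomicInterval:
    return replace(iv, **kw)
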