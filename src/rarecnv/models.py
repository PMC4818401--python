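"""Shared domain types for the rare-CNV screening pipeline.

Coordinate convention: all in-memory and report coordinates are 1-based
inclusive, so a segment of length L satisfies ``end - start + 1 == L``.
BED input (0-based half-open) is converted on read; see :mod:`rarecnv.io`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
from intervaltree import IntervalTree


class CnvType(str, enum.Enum):
    DEL = "DEL"
    DUP = "DUP"


class Phenotype(str, enum.Enum):
    CASE = "CASE"
    CONTROL = "CONTROL"


class Platform(str, enum.Enum):
    ARRAY = "ARRAY"
    QPCR = "QPCR"
    INSILICO = "INSILICO"


@dataclass(frozen=True)
class CnvCall:
    """One called deletion/duplication segment in one sample.

    ``copy_number`` may be None for assays that report carrier status only
    (e.g. qPCR panels); ``cnv_type`` is then authoritative.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    cnv_type: CnvType
    copy_number: Optional[int] = None
    n_probes: int = 0
    mean_probe_spacing: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"CNV call for {self.sample_id} at {self.chrom}:{self.start}-"
                f"{self.end}: end must exceed start"
            )
        if self.n_probes < 0:
            raise ValueError("n_probes must be non-negative")
        if self.copy_number is not None:
            if self.cnv_type is CnvType.DEL and self.copy_number >= 2:
                raise ValueError(
                    f"DEL call with copy_number {self.copy_number} (must be <2)"
                )
            if self.cnv_type is CnvType.DUP and self.copy_number <= 2:
                raise ValueError(
                    f"DUP call with copy_number {self.copy_number} (must be >2)"
                )

    @property
    def length(self) -> int:
        """Segment length in bp under the 1-based inclusive convention."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class SampleRecord:
    """Phenotype, panel membership, platform and QC metrics for one individual."""

    sample_id: str
    phenotype: Phenotype
    panel_id: str
    platform: Platform = Platform.ARRAY
    mapd: Optional[float] = None
    contrast_qc: Optional[float] = None
    batch_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.platform is Platform.INSILICO and self.phenotype is not Phenotype.CONTROL:
            raise ValueError(
                f"sample {self.sample_id}: in-silico samples must be controls"
            )
        if self.mapd is not None and self.mapd < 0:
            raise ValueError(f"sample {self.sample_id}: negative MAPD")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} has negative length"
            )
        if self.start < 1:
            raise ValueError(f"interval start {self.start} below 1 (1-based coords)")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GenomicTrack:
    """An ordered set of labelled genomic intervals (probes, gaps, common CNVs).

    Intervals are stored sorted by (chrom, start); overlapping intervals are
    preserved as given, never merged. Point tracks (start == end) model array
    probe positions.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self._starts: dict[str, np.ndarray] = {}
        chrom_starts: dict[str, list[int]] = {}
        for iv in self.intervals:
            chrom_starts.setdefault(iv.chrom, []).append(iv.start)
        for chrom, starts in chrom_starts.items():
            self._starts[chrom] = np.asarray(starts, dtype=np.int64)  # sorted by ctor
        self._trees: dict[str, IntervalTree] | None = None  # built on demand

    def _tree(self, chrom: str) -> Optional[IntervalTree]:
        if self._trees is None:
            self._trees = {}
            for iv in self.intervals:
                # interval tree uses half-open ends internally
                self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end + 1, iv
                )
        return self._trees.get(chrom)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    @property
    def chroms(self) -> set[str]:
        return set(self._starts)

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._starts

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """All intervals sharing >= 1 bp with [start, end] (1-based inclusive)."""
        tree = self._tree(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(start, end + 1)]
        hits.sort(key=lambda iv: (iv.start, iv.end))
        return hits

    def count_points_in(self, chrom: str, start: int, end: int) -> int:
        """Number of interval start positions inside [start, end].

        For point tracks (probe positions) this is the probe count.
        """
        pos = self._starts.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end, side="right") - np.searchsorted(pos, start, side="left"))

    def points_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        pos = self._starts.get(chrom)
        if pos is None:
            return np.array([], dtype=int)
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return pos[lo:hi]

    def coverage_bp(self, chrom: str, start: int, end: int) -> int:
        """Total bp of [start, end] covered by the track, overlaps merged."""
        clipped = []
        for iv in self.overlapping(chrom, start, end):
            clipped.append((max(iv.start, start), min(iv.end, end)))
        if not clipped:
            return 0
        clipped.sort()
        total = 0
        cur_s, cur_e = clipped[0]
        for s, e in clipped[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
        return total


@dataclass
class QpcrReplicateSet:
    """Technical qPCR replicate estimates for one sample x assay."""

    sample_id: str
    assay_id: str
    copy_numbers: tuple[Optional[float], ...] = ()
    confidence: Optional[float] = None
    z_score: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.copy_numbers) > 4:
            raise ValueError(
                f"{self.sample_id}/{self.assay_id}: more than 4 technical replicates"
            )
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(
                f"{self.sample_id}/{self.assay_id}: confidence must lie in [0, 1]"
            )

    @property
    def n_valid_replicates(self) -> int:
        return sum(1 for cn in self.copy_numbers if cn is not None)


def reciprocal_overlap(
    a_start: int, a_end: int, b_start: int, b_end: int
) -> float:
    """min(shared/len(A), shared/len(B)) for two 1-based inclusive intervals."""
    shared = min(a_end, b_end) - max(a_start, b_start) + 1
    if shared <= 0:
        return 0.0
    len_a = a_end - a_start + 1
    len_b = b_end - b_start + 1
    return min(shared / len_a, shared / len_b)
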