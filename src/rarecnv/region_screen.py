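"""Candidate-region construction and carrier-count screening.

Overlapping calls of the same CNV type on the same chromosome are merged by
single linkage (>= 1 bp shared, transitively) into candidate regions whose
span is the union of their members. Carrier counts are per distinct sample.
A region is selected when it has at least three case carriers and no control
carriers, or at least five case carriers and exactly one control carrier;
two or more control carriers always exclude it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .models import CnvCall, CnvType, Phenotype, SampleRecord


@dataclass
class CandidateRegion:
    """A merged interval of overlapping same-type rare calls."""

    chrom: str
    start: int
    end: int
    cnv_type: CnvType
    member_calls: list[CnvCall] = field(default_factory=list)
    case_carrier_ids: set[str] = field(default_factory=set)
    control_carrier_ids: set[str] = field(default_factory=set)
    selected: bool = False
    reason: str = ""

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.cnv_type.value}"

    @property
    def case_carriers(self) -> int:
        return len(self.case_carrier_ids)

    @property
    def control_carriers(self) -> int:
        return len(self.control_carrier_ids)

    @property
    def carrier_ids(self) -> set[str]:
        return self.case_carrier_ids | self.control_carrier_ids


def build_regions(calls: Sequence[CnvCall]) -> list[CandidateRegion]:
    """Single-linkage merge of same-type overlapping calls into regions.

    Deterministic and independent of input order: calls are grouped by
    (chromosome, type), sorted by start, and merged while the next call
    starts at or before the running union end (1-based inclusive overlap).
    """
    groups: dict[tuple[str, CnvType], list[CnvCall]] = {}
    for call in calls:
        groups.setdefault((call.chrom, call.cnv_type), []).append(call)

    regions: list[CandidateRegion] = []
    for (chrom, cnv_type), group in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        group = sorted(group, key=lambda c: (c.start, c.end, c.sample_id))
        current: Optional[CandidateRegion] = None
        for call in group:
            if current is not None and call.start <= current.end:
                current.end = max(current.end, call.end)
                current.member_calls.append(call)
            else:
                current = CandidateRegion(
                    chrom=chrom, start=call.start, end=call.end,
                    cnv_type=cnv_type, member_calls=[call],
                )
                regions.append(current)
    return regions


def count_carriers(
    regions: Sequence[CandidateRegion],
    samples: Mapping[str, SampleRecord] | Sequence[SampleRecord],
    min_carrier_overlap: float = 0.0,
) -> None:
    """Fill per-region distinct case/control carrier sets in place.

    A sample is a carrier of a region if any of its member calls overlaps the
    region span by more than ``min_carrier_overlap`` of the call's length
    (default 0: any overlap). A sample with several calls in one region
    counts once.
    """
    if not isinstance(samples, Mapping):
        samples = {s.sample_id: s for s in samples}
    for region in regions:
        region.case_carrier_ids = set()
        region.control_carrier_ids = set()
        span_len = region.end - region.start + 1
        for call in region.member_calls:
            shared = min(call.end, region.end) - max(call.start, region.start) + 1
            if shared <= 0:
                continue
            frac = shared / call.length
            if min_carrier_overlap > 0 and frac < min_carrier_overlap:
                continue
            rec = samples.get(call.sample_id)
            if rec is None:
                raise KeyError(f"call sample {call.sample_id!r} missing from phenotype table")
            if rec.phenotype is Phenotype.CASE:
                region.case_carrier_ids.add(call.sample_id)
            else:
                region.control_carrier_ids.add(call.sample_id)


def select_candidates(
    regions: Sequence[CandidateRegion],
    min_cases_no_control: int = 3,
    min_cases_one_control: int = 5,
) -> list[CandidateRegion]:
    """Apply the carrier-count inclusion rule; sets ``selected`` and ``reason``.

    Selected iff (case carriers >= 3 and control carriers == 0) or
    (case carriers >= 5 and control carriers == 1). Regions with exactly two
    control carriers fall outside both stated clauses and are conservatively
    not selected, with a distinct reason code; more than two control carriers
    are excluded outright.
    """
    for region in regions:
        cc, ctrl = region.case_carriers, region.control_carriers
        if ctrl == 0 and cc >= min_cases_no_control:
            region.selected = True
            region.reason = f"cases>={min_cases_no_control},controls=0"
        elif ctrl == 1 and cc >= min_cases_one_control:
            region.selected = True
            region.reason = f"cases>={min_cases_one_control},controls=1"
        elif ctrl > 2:
            region.selected = False
            region.reason = "excluded:controls>2"
        elif ctrl == 2:
            region.selected = False
            region.reason = "not_selected:controls=2_unaddressed"
        else:
            region.selected = False
            region.reason = "not_selected:insufficient_cases"
    return [r for r in regions if r.selected]
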