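"""Per-call and per-region technical filters applied before screening.

Call-level: probe support (>= 5 probes and mean inter-probe spacing <= 1 kb).
Region-level: assembly-gap span, known-common-CNV reciprocal overlap, and a
minimum probe count across the region. Each filter returns a
:class:`FilterVerdict` so every dropped call/region is traceable to a rule;
filters are independent and commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .models import CnvCall, CnvType, GenomicTrack, reciprocal_overlap


@dataclass
class FilterVerdict:
    """Outcome of one filter on one call or region."""

    identity: str
    rule: str
    keep: bool
    diagnostics: dict = field(default_factory=dict)


def _call_id(call: CnvCall) -> str:
    return f"{call.sample_id}:{call.chrom}:{call.start}-{call.end}:{call.cnv_type.value}"


def probe_support_filter(
    call: CnvCall,
    probe_track: Optional[GenomicTrack] = None,
    min_probes: int = 5,
    max_spacing: float = 1000.0,
    spacing_rule: bool = True,
) -> FilterVerdict:
    """Keep a call iff it has >= min_probes supporting probes and, when the
    spacing rule is enabled, mean inter-probe spacing <= max_spacing bp.

    When a probe track covering the call's chromosome is supplied, the probe
    count and spacing are recomputed from probe positions inside the call,
    overriding the record; a call on a chromosome the track does not cover is
    dropped with a "no probes" diagnostic. Mean spacing is
    (span between first and last probe) / (n_probes - 1).
    """
    n_probes = call.n_probes
    spacing = call.mean_probe_spacing
    source = "record"
    if probe_track is not None and len(probe_track) > 0:
        if not probe_track.has_chrom(call.chrom):
            return FilterVerdict(
                identity=_call_id(call),
                rule="probe_support",
                keep=False,
                diagnostics={"n_probes": 0, "mean_spacing": None, "note": "no probes"},
            )
        positions = probe_track.points_in(call.chrom, call.start, call.end)
        n_probes = int(len(positions))
        source = "track"
        spacing = (
            float(positions[-1] - positions[0]) / (n_probes - 1) if n_probes >= 2 else None
        )
    ok_count = n_probes >= min_probes
    if spacing_rule:
        ok_spacing = spacing is not None and spacing <= max_spacing
    else:
        ok_spacing = True
    return FilterVerdict(
        identity=_call_id(call),
        rule="probe_support",
        keep=ok_count and ok_spacing,
        diagnostics={
            "n_probes": n_probes,
            "mean_spacing": spacing,
            "probe_source": source,
            "ok_count": ok_count,
            "ok_spacing": ok_spacing,
        },
    )


def gap_span_filter(
    region_chrom: str,
    region_start: int,
    region_end: int,
    gap_track: GenomicTrack,
) -> FilterVerdict:
    """Drop a region iff assembly-gap bp inside it exceed non-gap bp.

    The rule is a strict comparison: a gap covering exactly half the region
    keeps the region.
    """
    total = region_end - region_start + 1
    gap_bp = gap_track.coverage_bp(region_chrom, region_start, region_end)
    covered_bp = total - gap_bp
    return FilterVerdict(
        identity=f"{region_chrom}:{region_start}-{region_end}",
        rule="gap_span",
        keep=not (gap_bp > covered_bp),
        diagnostics={"gap_bp": gap_bp, "covered_bp": covered_bp},
    )


def common_cnv_filter(
    region_chrom: str,
    region_start: int,
    region_end: int,
    common_track: GenomicTrack,
    min_reciprocal_overlap: float = 0.5,
    cnv_type: Optional[CnvType] = None,
) -> FilterVerdict:
    """Drop a region iff a known common CNV reciprocally overlaps it by >=
    ``min_reciprocal_overlap``.

    Common-track intervals labelled DEL or DUP only match regions of the same
    type; unlabelled intervals are type-agnostic.
    """
    best = 0.0
    best_label = None
    for iv in common_track.overlapping(region_chrom, region_start, region_end):
        if (
            cnv_type is not None
            and iv.label in (CnvType.DEL.value, CnvType.DUP.value)
            and iv.label != cnv_type.value
        ):
            continue
        ro = reciprocal_overlap(region_start, region_end, iv.start, iv.end)
        if ro > best:
            best, best_label = ro, iv.label
    return FilterVerdict(
        identity=f"{region_chrom}:{region_start}-{region_end}",
        rule="common_cnv",
        keep=best < min_reciprocal_overlap,
        diagnostics={
            "max_reciprocal_overlap": best,
            "matched_label": best_label,
            "threshold": min_reciprocal_overlap,
        },
    )


def region_probe_count_filter(
    region_chrom: str,
    region_start: int,
    region_end: int,
    probe_track: GenomicTrack,
    min_probes: int = 10,
) -> FilterVerdict:
    """Drop a region covered by fewer than ``min_probes`` probe positions.

    Probes are counted across the full region span.
    """
    n = probe_track.count_points_in(region_chrom, region_start, region_end)
    return FilterVerdict(
        identity=f"{region_chrom}:{region_start}-{region_end}",
        rule="region_probe_count",
        keep=n >= min_probes,
        diagnostics={"n_probes": n, "min_probes": min_probes},
    )


def apply_call_filters(
    calls: Sequence[CnvCall],
    probe_track: Optional[GenomicTrack] = None,
    min_probes: int = 5,
    max_spacing: float = 1000.0,
    spacing_rule: bool = True,
) -> tuple[list[CnvCall], list[FilterVerdict]]:
    """Run the call-level probe-support filter over a call set."""
    kept: list[CnvCall] = []
    verdicts: list[FilterVerdict] = []
    for call in calls:
        v = probe_support_filter(call, probe_track, min_probes, max_spacing, spacing_rule)
        verdicts.append(v)
        if v.keep:
            kept.append(call)
    return kept, verdicts
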