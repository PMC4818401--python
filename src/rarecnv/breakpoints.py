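"""Breakpoint-junction interpretation.

Given a resolved deletion (or the two junction-proximal sequences of any
rearrangement), this module computes the event size under the 1-based
inclusive convention, scans for sequence motifs shared by both breakpoints,
measures junction microhomology, searches the two flanks for homologous
repeats (exact k-mer seeding with ungapped mismatch-bounded extension), and
classifies the likely formation mechanism:

* NAHR  — homologous flanking repeats >= 100 bp at >= 85% identity on both
  sides (e.g. recombination between near-identical Alu elements);
* MMEJ  — junction microhomology of 2–10 bp;
* NHEJ  — microhomology <= 1 bp;
* UNCLASSIFIED — anything else (e.g. long microhomology without qualifying
  flanking repeats).

Thresholds follow common rearrangement-mechanism conventions and are
configuration, not claims; every report echoes the thresholds used.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

_VALID = set("ACGTN")


class Mechanism(str, enum.Enum):
    NAHR = "NAHR"
    MMEJ = "MMEJ"
    NHEJ = "NHEJ"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class RepeatHomology:
    """Best homologous segment shared by the two flanks."""

    length: int = 0
    identity: float = 0.0
    left_offset: int = -1
    right_offset: int = -1

    @property
    def found(self) -> bool:
        return self.length > 0


@dataclass
class SharedMotif:
    kmer: str
    left_offset: int  # bp from the breakpoint-proximal end of the left window
    right_offset: int


@dataclass
class JunctionReport:
    event_bp: Optional[int] = None
    event_kb: Optional[float] = None
    shared_motifs: list[SharedMotif] = field(default_factory=list)
    microhomology: int = 0
    repeat_homology: RepeatHomology = field(default_factory=RepeatHomology)
    mechanism: Mechanism = Mechanism.UNCLASSIFIED
    rule_fired: str = ""
    thresholds: dict = field(default_factory=dict)


def event_size(start: int, end: int) -> tuple[int, float]:
    """Event size in bp and rounded kb for a 1-based inclusive interval.

    kb is rounded to one decimal below 100 kb and to the nearest integer at
    or above 100 kb (so 15,761 bp prints as 15.8 kb and 133,901 bp as 134 kb).
    """
    if end <= start:
        raise ValueError(f"end ({end}) must exceed start ({start})")
    bp = end - start + 1
    kb = bp / 1000.0
    return bp, round(kb, 1) if bp < 100_000 else float(round(kb))


def _check_seq(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{name} contains non-nucleotide characters: {sorted(bad)}")
    return seq


def junction_motif_scan(
    left_flank_seq: str,
    right_flank_seq: str,
    k_min: int = 4,
    k_max: int = 20,
    window: int = 50,
) -> list[SharedMotif]:
    """All maximal k-mers shared by both breakpoint windows.

    ``left_flank_seq`` ends at the left breakpoint; ``right_flank_seq``
    ends at the right breakpoint — searching is restricted to the last
    ``window`` bp of each. A shared k-mer is reported only if it is maximal,
    i.e. not part of a longer shared k-mer occurrence at the same place.
    k-mers containing N never match. Ordered by (k descending, left offset).
    """
    left = _check_seq(left_flank_seq, "left flank")
    right = _check_seq(right_flank_seq, "right flank")
    if window > max(len(left), len(right)):
        window = max(len(left), len(right))
    lwin = left[-window:]
    rwin = right[-window:]

    def kmers(seq: str, k: int) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            out.setdefault(km, []).append(i)
        return out

    hits: list[SharedMotif] = []
    covered: set[tuple[int, int, int]] = set()  # (left_pos, right_pos, end overhangs) via containment check
    reported: list[tuple[int, int, int]] = []  # (left_pos, right_pos, k)
    for k in range(min(k_max, min(len(lwin), len(rwin))), k_min - 1, -1):
        lk = kmers(lwin, k)
        rk = kmers(rwin, k)
        for km in sorted(set(lk) & set(rk)):
            for li in lk[km]:
                for ri in rk[km]:
                    contained = any(
                        pl <= li and li + k <= pl + pk and pr <= ri and ri + k <= pr + pk
                        and (li - pl) == (ri - pr)
                        for pl, pr, pk in reported
                    )
                    if not contained:
                        reported.append((li, ri, k))
                        hits.append(
                            SharedMotif(
                                kmer=km,
                                left_offset=len(lwin) - (li + k),
                                right_offset=len(rwin) - (ri + k),
                            )
                        )
    hits.sort(key=lambda m: (-len(m.kmer), m.left_offset, m.right_offset, m.kmer))
    return hits


def microhomology_length(
    ref_seq: str, del_start: int, del_end: int, max_len: int = 100
) -> int:
    """Junction microhomology of a deletion within ``ref_seq``.

    Coordinates are 1-based inclusive. Returns the length of the longest
    string that is simultaneously a prefix of the sequence beginning at
    ``del_start`` and a prefix of the sequence beginning at ``del_end + 1``,
    capped at ``max_len``. This is the standard definition: bases that could
    belong to either side of the junction in the deleted allele.
    """
    ref = _check_seq(ref_seq, "reference")
    if not (1 <= del_start < del_end <= len(ref)):
        raise ValueError(
            f"deletion {del_start}-{del_end} out of bounds for length-{len(ref)} sequence"
        )
    s1 = ref[del_start - 1 :]
    s2 = ref[del_end:]
    n = 0
    for x, y in zip(s1, s2):
        if x != y or x == "N" or n >= max_len:
            break
        n += 1
    return n


def find_flanking_repeat(
    left_flank: str,
    right_flank: str,
    seed_k: int = 12,
    mismatch_penalty: float = 3.0,
) -> RepeatHomology:
    """Best homologous segment between the two flanks.

    Banded ungapped self-comparison: exact ``seed_k``-mer matches select
    candidate diagonals; on each such diagonal the maximal-scoring aligned
    segment (match +1, mismatch -``mismatch_penalty``) is found, which trims
    the hit to the homologous core instead of letting it drift into
    unrelated sequence. Returns the best segment over all diagonals (by
    score, then length); the mechanism classifier then tests it against its
    own length/identity thresholds.
    """
    left = _check_seq(left_flank, "left flank")
    right = _check_seq(right_flank, "right flank")
    if len(left) < seed_k or len(right) < seed_k:
        return RepeatHomology()

    seeds: dict[str, list[int]] = {}
    for i in range(len(left) - seed_k + 1):
        km = left[i : i + seed_k]
        if "N" not in km:
            seeds.setdefault(km, []).append(i)
    diagonals: set[int] = set()
    for j in range(len(right) - seed_k + 1):
        km = right[j : j + seed_k]
        for i in seeds.get(km, ()):
            diagonals.add(j - i)

    best = RepeatHomology()
    best_key = (0.0, 0)
    for d in sorted(diagonals):
        i_lo = max(0, -d)
        i_hi = min(len(left), len(right) - d)
        # maximal-scoring segment on this diagonal (Kadane)
        run_score, run_start = 0.0, i_lo
        seg_score, seg = 0.0, None
        for i in range(i_lo, i_hi):
            hit = left[i] == right[i + d] and left[i] != "N"
            run_score += 1.0 if hit else -mismatch_penalty
            if run_score <= 0:
                run_score, run_start = 0.0, i + 1
                continue
            if run_score > seg_score:
                seg_score, seg = run_score, (run_start, i + 1)
        if seg is None:
            continue
        lo, hi = seg
        while hi > lo and left[hi - 1] != right[hi - 1 + d]:
            hi -= 1
        while lo < hi and left[lo] != right[lo + d]:
            lo += 1
        length = hi - lo
        if length == 0:
            continue
        matches = sum(
            1 for x, y in zip(left[lo:hi], right[lo + d : hi + d]) if x == y and x != "N"
        )
        if (seg_score, length) > best_key:
            best_key = (seg_score, length)
            best = RepeatHomology(
                length=length, identity=matches / length, left_offset=lo, right_offset=lo + d
            )
    return best


def classify_mechanism(
    report: JunctionReport,
    min_repeat_len: int = 100,
    min_repeat_identity: float = 0.85,
    mmej_range: tuple[int, int] = (2, 10),
) -> JunctionReport:
    """Assign exactly one mechanism class to a populated junction report."""
    report.thresholds = {
        "min_repeat_len": min_repeat_len,
        "min_repeat_identity": min_repeat_identity,
        "mmej_range": list(mmej_range),
    }
    rh = report.repeat_homology
    if rh.found and rh.length >= min_repeat_len and rh.identity >= min_repeat_identity:
        report.mechanism = Mechanism.NAHR
        report.rule_fired = (
            f"flanking repeat {rh.length} bp at {rh.identity:.1%} >= "
            f"{min_repeat_len} bp/{min_repeat_identity:.0%}"
        )
    elif mmej_range[0] <= report.microhomology <= mmej_range[1]:
        report.mechanism = Mechanism.MMEJ
        report.rule_fired = f"microhomology {report.microhomology} bp in {mmej_range}"
    elif report.microhomology <= 1:
        report.mechanism = Mechanism.NHEJ
        report.rule_fired = f"microhomology {report.microhomology} bp <= 1"
    else:
        report.mechanism = Mechanism.UNCLASSIFIED
        report.rule_fired = (
            f"microhomology {report.microhomology} bp > {mmej_range[1]} without qualifying repeats"
        )
    return report


def analyze_junction(
    ref_seq: str,
    del_start: int,
    del_end: int,
    flank_len: int = 500,
    motif_window: int = 50,
    k_min: int = 4,
    k_max: int = 20,
    **classify_kwargs,
) -> JunctionReport:
    """Full junction workup for a deletion inside a reference sequence.

    The "left flank" for repeat search is the ``flank_len`` bp 5' of the
    deletion, the "right flank" the ``flank_len`` bp 3' of it. Motif
    scanning compares the windows ending at each breakpoint (the sequence
    immediately 5' of ``del_start`` and immediately 5' of ``del_end + 1``,
    i.e. the junction-proximal sequence on each side).
    """
    ref = _check_seq(ref_seq, "reference")
    if not (1 <= del_start < del_end <= len(ref)):
        raise ValueError("deletion interval out of bounds")
    bp, kb = event_size(del_start, del_end)
    left_flank = ref[max(0, del_start - 1 - flank_len) : del_start - 1]
    right_flank = ref[del_end : del_end + flank_len]
    # windows ending at each breakpoint (last bases before the junctions)
    left_bp_window = ref[max(0, del_start - 1 - motif_window) : del_start - 1]
    right_bp_window = ref[max(0, del_end - motif_window) : del_end]
    report = JunctionReport(
        event_bp=bp,
        event_kb=kb,
        shared_motifs=junction_motif_scan(
            left_bp_window, right_bp_window, k_min=k_min, k_max=k_max, window=motif_window
        ),
        microhomology=microhomology_length(ref, del_start, del_end),
        repeat_homology=find_flanking_repeat(left_flank, right_flank),
    )
    return classify_mechanism(report, **classify_kwargs)
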