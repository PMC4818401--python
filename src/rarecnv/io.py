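"""Readers and writers for the tab-separated dialects the pipeline consumes.

All files are UTF-8, tab-delimited, with ``#``-prefixed comment lines ignored.
Genomic coordinates are 1-based inclusive everywhere except BED input, which
follows the standard 0-based half-open convention and is converted on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

from .models import (
    CnvCall,
    CnvType,
    GenomicInterval,
    GenomicTrack,
    Phenotype,
    Platform,
    QpcrReplicateSet,
    SampleRecord,
)

PathLike = Union[str, Path]

CALL_COLUMNS = ["sample", "chrom", "start", "end", "type", "copy_number", "n_probes"]
PHENOTYPE_COLUMNS = ["sample", "phenotype", "panel", "platform"]


class ParseError(ValueError):
    """A malformed record, reported with its source line number."""

    def __init__(self, path: PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _data_lines(path: PathLike):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _header_index(path: PathLike, fields: list[str], required: list[str]) -> dict[str, int]:
    idx = {name.strip().lower(): i for i, name in enumerate(fields)}
    missing = [c for c in required if c not in idx]
    if missing:
        raise ParseError(path, 1, f"missing required column(s): {', '.join(missing)}")
    return idx


def read_cnv_calls(path: PathLike) -> list[CnvCall]:
    """Read SEG-like CNV segment calls.

    Required columns: sample, chrom, start, end, type, copy_number, n_probes;
    optional: mean_probe_spacing. ``copy_number`` may be "." or empty (carrier
    status only). Raises :class:`ParseError` naming the offending line.
    """
    calls: list[CnvCall] = []
    idx: Optional[dict[str, int]] = None
    for lineno, fields in _data_lines(path):
        if idx is None:
            idx = _header_index(path, fields, CALL_COLUMNS)
            continue
        try:
            start = int(fields[idx["start"]])
            end = int(fields[idx["end"]])
        except (ValueError, IndexError) as exc:
            raise ParseError(path, lineno, f"malformed coordinate: {exc}") from exc
        type_str = fields[idx["type"]].strip().upper()
        if type_str not in CnvType.__members__:
            raise ParseError(path, lineno, f"unknown CNV type {type_str!r}")
        cn_raw = fields[idx["copy_number"]].strip()
        copy_number = None if cn_raw in ("", ".", "NA") else int(cn_raw)
        spacing = None
        if "mean_probe_spacing" in idx and len(fields) > idx["mean_probe_spacing"]:
            sp_raw = fields[idx["mean_probe_spacing"]].strip()
            if sp_raw not in ("", ".", "NA"):
                spacing = float(sp_raw)
        try:
            calls.append(
                CnvCall(
                    sample_id=fields[idx["sample"]],
                    chrom=fields[idx["chrom"]],
                    start=start,
                    end=end,
                    cnv_type=CnvType[type_str],
                    copy_number=copy_number,
                    n_probes=int(fields[idx["n_probes"]]),
                    mean_probe_spacing=spacing,
                )
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from exc
    if idx is None:
        raise ParseError(path, 1, "empty file: header line required")
    return calls


def write_cnv_calls(calls: list[CnvCall], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CALL_COLUMNS + ["mean_probe_spacing"]) + "\n")
        for c in calls:
            cn = "." if c.copy_number is None else str(c.copy_number)
            sp = "." if c.mean_probe_spacing is None else f"{c.mean_probe_spacing:g}"
            fh.write(
                f"{c.sample_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.cnv_type.value}"
                f"\t{cn}\t{c.n_probes}\t{sp}\n"
            )


def read_phenotypes(path: PathLike) -> list[SampleRecord]:
    """Read the phenotype/panel table; duplicate sample ids are an error."""
    records: list[SampleRecord] = []
    seen: set[str] = set()
    idx: Optional[dict[str, int]] = None
    for lineno, fields in _data_lines(path):
        if idx is None:
            idx = _header_index(path, fields, PHENOTYPE_COLUMNS)
            continue
        sid = fields[idx["sample"]]
        if sid in seen:
            raise ParseError(path, lineno, f"duplicate sample id {sid!r}")
        seen.add(sid)
        pheno = fields[idx["phenotype"]].strip().upper()
        if pheno not in Phenotype.__members__:
            raise ParseError(
                path, lineno, f"phenotype must be case or control, got {pheno!r}"
            )
        plat = fields[idx["platform"]].strip().upper()
        if plat not in Platform.__members__:
            raise ParseError(path, lineno, f"unknown platform {plat!r}")

        def _opt_float(col: str) -> Optional[float]:
            if idx is None or col not in idx or len(fields) <= idx[col]:
                return None
            raw = fields[idx[col]].strip()
            return None if raw in ("", ".", "NA") else float(raw)

        batch = None
        if "batch" in idx and len(fields) > idx["batch"]:
            raw = fields[idx["batch"]].strip()
            batch = raw if raw not in ("", ".", "NA") else None
        try:
            records.append(
                SampleRecord(
                    sample_id=sid,
                    phenotype=Phenotype[pheno],
                    panel_id=fields[idx["panel"]],
                    platform=Platform[plat],
                    mapd=_opt_float("mapd"),
                    contrast_qc=_opt_float("contrast_qc"),
                    batch_id=batch,
                )
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from exc
    if idx is None:
        raise ParseError(path, 1, "empty file: header line required")
    return records


def write_phenotypes(records: list[SampleRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PHENOTYPE_COLUMNS + ["mapd", "contrast_qc", "batch"]) + "\n")
        for r in records:
            mapd = "." if r.mapd is None else f"{r.mapd:g}"
            cqc = "." if r.contrast_qc is None else f"{r.contrast_qc:g}"
            batch = r.batch_id if r.batch_id is not None else "."
            fh.write(
                f"{r.sample_id}\t{r.phenotype.value.lower()}\t{r.panel_id}"
                f"\t{r.platform.value.lower()}\t{mapd}\t{cqc}\t{batch}\n"
            )


def read_bed_track(path: PathLike) -> GenomicTrack:
    """Read a BED track (0-based half-open) into 1-based inclusive intervals.

    Unsorted input is accepted and sorted; negative coordinates are rejected.
    Overlapping intervals are preserved, not merged.
    """
    intervals: list[GenomicInterval] = []
    for lineno, fields in _data_lines(path):
        if fields[0] in ("track", "browser"):
            continue
        if len(fields) < 3:
            raise ParseError(path, lineno, "BED line needs >= 3 columns")
        try:
            bed_start = int(fields[1])
            bed_end = int(fields[2])
        except ValueError as exc:
            raise ParseError(path, lineno, f"malformed coordinate: {exc}") from exc
        if bed_start < 0 or bed_end < 0:
            raise ParseError(path, lineno, "negative BED coordinate")
        if bed_end <= bed_start:
            raise ParseError(path, lineno, "BED end must exceed start")
        label = fields[3] if len(fields) > 3 else ""
        intervals.append(
            GenomicInterval(chrom=fields[0], start=bed_start + 1, end=bed_end, label=label)
        )
    return GenomicTrack(intervals)


def write_bed_track(track: GenomicTrack, path: PathLike) -> None:
    """Write a track back to BED (inverse of the read-side conversion)."""
    with open(path, "w", encoding="utf-8") as fh:
        for iv in track:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.label}\n")


def read_qpcr_replicates(path: PathLike) -> list[QpcrReplicateSet]:
    """Read qPCR replicate sets: sample, assay, cn1..cn4, confidence, z_score."""
    sets: list[QpcrReplicateSet] = []
    idx: Optional[dict[str, int]] = None
    for lineno, fields in _data_lines(path):
        if idx is None:
            idx = _header_index(path, fields, ["sample", "assay", "confidence", "z_score"])
            continue

        def _opt(col: str) -> Optional[float]:
            if idx is None or col not in idx or len(fields) <= idx[col]:
                return None
            raw = fields[idx[col]].strip()
            return None if raw in ("", ".", "NA") else float(raw)

        cns = tuple(_opt(f"cn{i}") for i in range(1, 5))
        try:
            sets.append(
                QpcrReplicateSet(
                    sample_id=fields[idx["sample"]],
                    assay_id=fields[idx["assay"]],
                    copy_numbers=cns,
                    confidence=_opt("confidence"),
                    z_score=_opt("z_score"),
                )
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from exc
    if idx is None:
        raise ParseError(path, 1, "empty file: header line required")
    return sets
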