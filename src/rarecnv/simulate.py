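"""Synthetic multi-panel case-control cohorts with planted rare CNVs.

The generator emulates the study design this pipeline targets: several
case-control panels genotyped on different platforms (SNP array, qPCR, an
in-silico control set), rare risk CNVs carried independently per sample at
phenotype-specific frequencies, background passenger calls, common CNVs,
boundary jitter quantized to array probe positions, low-probe-support
false-positive calls, and a small fraction of noisy outlier samples whose
call counts far exceed the batch-wise Tukey fence. A truth table records
exactly which samples carry each planted variant, so downstream stages can
be tested end to end without any external data.

Simulated chromosomes are short synthetic coordinate spaces (a few Mb);
nothing downstream depends on real genome size. The generator emits segment
calls, never probe-level intensities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io import write_bed_track, write_cnv_calls, write_phenotypes
from .models import (
    CnvCall,
    CnvType,
    GenomicInterval,
    GenomicTrack,
    Phenotype,
    Platform,
    SampleRecord,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PanelConfig:
    panel_id: str
    n_cases: int
    n_controls: int
    platform: Platform = Platform.ARRAY


@dataclass(frozen=True)
class RiskCnv:
    chrom: str
    start: int
    end: int
    cnv_type: CnvType
    case_carrier_freq: float
    control_carrier_freq: float

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.cnv_type.value}"


@dataclass(frozen=True)
class CommonCnv:
    chrom: str
    start: int
    end: int
    cnv_type: CnvType
    population_freq: float


def study_panels() -> list[PanelConfig]:
    """The six panels of the emulated study design (post-QC sample sizes)."""
    return [
        PanelConfig("discovery", 902, 1564, Platform.ARRAY),
        PanelConfig("german_replication", 453, 1377, Platform.QPCR),
        PanelConfig("wtccc2", 2394, 4886, Platform.ARRAY),
        PanelConfig("norwegian", 252, 272, Platform.ARRAY),
        PanelConfig("lithuanian", 445, 1140, Platform.QPCR),
        PanelConfig("insilico_controls", 0, 4505, Platform.INSILICO),
    ]


def study_risk_cnvs() -> list[RiskCnv]:
    """Three planted risk CNVs at the study's combined carrier frequencies.

    Sizes mirror the three reported events (15.8, 119 and 134 kb) placed on
    synthetic chromosomes.
    """
    return [
        RiskCnv("sim1", 1_000_000, 1_015_760, CnvType.DEL, 0.0043, 0.0011),
        RiskCnv("sim2", 2_000_000, 2_118_887, CnvType.DUP, 0.0013, 0.0001),
        RiskCnv("sim3", 3_000_000, 3_133_900, CnvType.DUP, 0.0022, 0.0003),
    ]


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; the defaults are the study conditions.

    Background "passenger" calls model the polymorphic CNV landscape: they
    recur at a fixed set of background loci placed away from the planted
    risk CNVs, at ``passenger_rate`` expected calls per sample, so
    per-sample call counts resemble a real array cohort (and the batch-wise
    Tukey fence operates on a sensible distribution) without contaminating
    the planted regions. False positives are short, low-probe-support,
    uniformly scattered calls the probe-support filter should remove;
    outlier samples receive grossly inflated call counts the batch fence
    should flag.
    """

    seed: int = 0
    panels: list[PanelConfig] = field(default_factory=study_panels)
    risk_cnvs: list[RiskCnv] = field(default_factory=study_risk_cnvs)
    common_cnvs: list[CommonCnv] = field(
        default_factory=lambda: [CommonCnv("sim2", 4_000_000, 4_060_000, CnvType.DEL, 0.05)]
    )
    passenger_rate: float = 3.0
    boundary_jitter_sd: float = 2000.0
    false_positive_rate: float = 0.2
    outlier_fraction: float = 0.01
    probe_spacing_mean: float = 500.0
    passenger_mean_len: float = 30_000.0
    n_background_loci: int = 40
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rc in self.risk_cnvs:
            for f in (rc.case_carrier_freq, rc.control_carrier_freq):
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"carrier frequency {f} outside [0, 1]")
        for cc in self.common_cnvs:
            if not 0.0 <= cc.population_freq <= 1.0:
                raise ValueError(f"population frequency {cc.population_freq} outside [0, 1]")
        for name in ("passenger_rate", "false_positive_rate", "boundary_jitter_sd",
                     "probe_spacing_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must lie in [0, 1]")
        if (self.passenger_rate > 0 or self.outlier_fraction > 0) and self.n_background_loci < 1:
            raise ValueError("background calls requested but n_background_loci < 1")
        if not self.chrom_sizes:
            sizes: dict[str, int] = {}
            for iv in [*self.risk_cnvs, *self.common_cnvs]:
                sizes[iv.chrom] = max(sizes.get(iv.chrom, 0), iv.end + 500_000)
            if not sizes:
                sizes = {"sim1": 5_000_000}
            self.chrom_sizes = {c: min(s, 10_000_000) for c, s in sorted(sizes.items())}

    @property
    def noise_free(self) -> bool:
        return (
            self.passenger_rate == 0
            and self.false_positive_rate == 0
            and self.boundary_jitter_sd == 0
            and self.outlier_fraction == 0
            and not self.common_cnvs
        )


@dataclass
class TruthTable:
    """Ground truth of one simulated cohort."""

    carriers: dict[str, set[str]]  # risk region id -> carrier sample ids
    outliers: set[str]

    def to_json(self, path) -> None:
        payload = {
            "carriers": {k: sorted(v) for k, v in sorted(self.carriers.items())},
            "outliers": sorted(self.outliers),
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("region\tsample\n")
            for region, samples in sorted(self.carriers.items()):
                for s in sorted(samples):
                    fh.write(f"{region}\t{s}\n")


@dataclass
class Cohort:
    calls: list[CnvCall]
    phenotypes: list[SampleRecord]
    probe_track: GenomicTrack
    truth: TruthTable

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cnv_calls(self.calls, outdir / "calls.tsv")
        write_phenotypes(self.phenotypes, outdir / "phenotypes.tsv")
        write_bed_track(self.probe_track, outdir / "probes.bed")
        self.truth.to_json(outdir / "truth.json")
        self.truth.to_tsv(outdir / "truth.tsv")


def _probe_grid(config: SimulationConfig) -> dict[str, np.ndarray]:
    spacing = max(1, int(round(config.probe_spacing_mean)))
    return {
        chrom: np.arange(spacing, size + 1, spacing, dtype=np.int64)
        for chrom, size in config.chrom_sizes.items()
    }


_TRACK_CACHE: dict[tuple, GenomicTrack] = {}


def _probe_track(config: SimulationConfig, grids: dict[str, np.ndarray]) -> GenomicTrack:
    """Probe tracks depend only on the grid, not the seed; cache across draws."""
    key = (int(config.probe_spacing_mean), tuple(sorted(config.chrom_sizes.items())))
    track = _TRACK_CACHE.get(key)
    if track is None:
        track = GenomicTrack(
            GenomicInterval(chrom, int(p), int(p), "probe")
            for chrom in sorted(grids)
            for p in grids[chrom]
        )
        if len(_TRACK_CACHE) > 8:
            _TRACK_CACHE.clear()
        _TRACK_CACHE[key] = track
    return track


def _snap(pos: float, grid: np.ndarray) -> int:
    i = np.searchsorted(grid, pos)
    if i == 0:
        return int(grid[0])
    if i == len(grid):
        return int(grid[-1])
    return int(grid[i] if grid[i] - pos < pos - grid[i - 1] else grid[i - 1])


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Draw one cohort: identical config (including seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    grids = _probe_grid(config)
    probe_track = _probe_track(config, grids)
    chroms = sorted(config.chrom_sizes)

    # background polymorphic CNV loci, kept clear of planted intervals
    planted = [(iv.chrom, iv.start, iv.end) for iv in [*config.risk_cnvs, *config.common_cnvs]]
    background_loci: list[tuple[str, int, int, CnvType]] = []
    margin = 200_000
    attempts = 0
    while len(background_loci) < config.n_background_loci and attempts < 50 * config.n_background_loci:
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        size = config.chrom_sizes[chrom]
        length = max(
            int(2 * config.probe_spacing_mean) + 1,
            min(int(rng.lognormal(np.log(config.passenger_mean_len), 0.7)), size // 4),
        )
        start = int(rng.integers(1, max(2, size - length)))
        end = start + length
        if any(
            c == chrom and start - margin <= e and s <= end + margin
            for c, s, e in planted
        ):
            continue
        cnv_type = CnvType.DEL if rng.random() < 0.5 else CnvType.DUP
        background_loci.append((chrom, start, end, cnv_type))

    phenotypes: list[SampleRecord] = []
    calls: list[CnvCall] = []
    truth = TruthTable(carriers={rc.region_id: set() for rc in config.risk_cnvs}, outliers=set())

    def make_interval_call(sample_id: str, chrom: str, start: int, end: int,
                           cnv_type: CnvType, jitter: bool) -> CnvCall:
        grid = grids[chrom]
        if jitter and config.boundary_jitter_sd > 0:
            start = _snap(start + rng.normal(0, config.boundary_jitter_sd), grid)
            end = _snap(end + rng.normal(0, config.boundary_jitter_sd), grid)
            if end <= start:
                end = start + int(config.probe_spacing_mean)
        n_probes = int(np.searchsorted(grid, end, "right") - np.searchsorted(grid, start, "left"))
        positions = grid[np.searchsorted(grid, start, "left"): np.searchsorted(grid, end, "right")]
        spacing = float(positions[-1] - positions[0]) / (n_probes - 1) if n_probes >= 2 else None
        return CnvCall(
            sample_id=sample_id, chrom=chrom, start=int(start), end=int(end),
            cnv_type=cnv_type, copy_number=1 if cnv_type is CnvType.DEL else 3,
            n_probes=n_probes, mean_probe_spacing=spacing,
        )

    def random_background_call(sample_id: str) -> CnvCall:
        chrom, start, end, cnv_type = background_loci[rng.integers(len(background_loci))]
        return make_interval_call(sample_id, chrom, start, end, cnv_type, jitter=True)

    def false_positive_call(sample_id: str) -> CnvCall:
        chrom = chroms[rng.integers(len(chroms))]
        grid = grids[chrom]
        n_probes = int(rng.integers(2, 5))  # below the 5-probe support rule
        i = int(rng.integers(0, len(grid) - n_probes))
        start, end = int(grid[i]), int(grid[i + n_probes - 1]) + 1
        cnv_type = CnvType.DEL if rng.random() < 0.5 else CnvType.DUP
        spacing = (end - 1 - start) / (n_probes - 1)
        return CnvCall(
            sample_id=sample_id, chrom=chrom, start=start, end=end,
            cnv_type=cnv_type, copy_number=1 if cnv_type is CnvType.DEL else 3,
            n_probes=n_probes, mean_probe_spacing=spacing,
        )

    for panel in config.panels:
        groups = [
            (Phenotype.CASE, panel.n_cases, "case"),
            (Phenotype.CONTROL, panel.n_controls, "ctrl"),
        ]
        for phenotype, n, tag in groups:
            if n == 0:
                continue
            ids = [f"{panel.panel_id}_{tag}_{i:05d}" for i in range(n)]
            for sid in ids:
                phenotypes.append(
                    SampleRecord(
                        sample_id=sid, phenotype=phenotype, panel_id=panel.panel_id,
                        platform=panel.platform, batch_id=panel.panel_id,
                    )
                )
            # planted risk CNVs: independent Bernoulli per sample
            for rc in config.risk_cnvs:
                freq = (
                    rc.case_carrier_freq if phenotype is Phenotype.CASE
                    else rc.control_carrier_freq
                )
                carrier_mask = rng.random(n) < freq
                for idx in np.flatnonzero(carrier_mask):
                    sid = ids[idx]
                    truth.carriers[rc.region_id].add(sid)
                    calls.append(
                        make_interval_call(sid, rc.chrom, rc.start, rc.end, rc.cnv_type, jitter=True)
                    )
            # common CNVs: same frequency in both phenotypes
            for cc in config.common_cnvs:
                carrier_mask = rng.random(n) < cc.population_freq
                for idx in np.flatnonzero(carrier_mask):
                    calls.append(
                        make_interval_call(ids[idx], cc.chrom, cc.start, cc.end, cc.cnv_type, jitter=True)
                    )
            # passengers, false positives, outliers
            if config.passenger_rate > 0:
                counts = rng.poisson(config.passenger_rate, n)
                for idx in np.flatnonzero(counts):
                    for _ in range(counts[idx]):
                        calls.append(random_background_call(ids[idx]))
            if config.false_positive_rate > 0:
                counts = rng.poisson(config.false_positive_rate, n)
                for idx in np.flatnonzero(counts):
                    for _ in range(counts[idx]):
                        calls.append(false_positive_call(ids[idx]))
            if config.outlier_fraction > 0:
                outlier_mask = rng.random(n) < config.outlier_fraction
                for idx in np.flatnonzero(outlier_mask):
                    sid = ids[idx]
                    truth.outliers.add(sid)
                    for _ in range(30 + int(rng.poisson(10))):
                        calls.append(random_background_call(sid))

    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.sample_id, c.cnv_type.value))
    return Cohort(calls=calls, phenotypes=phenotypes, probe_track=probe_track, truth=truth)


def _mutate_to_identity(seq: np.ndarray, identity: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute exactly round((1-identity)*len) positions to different bases."""
    out = seq.copy()
    n_mut = int(round((1.0 - identity) * len(seq)))
    if n_mut == 0:
        return out
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def generate_junction(
    deleted_len: int = 15_761,
    flank_len: int = 610,
    planted_motif: str = "GATCAC",
    repeat_homology_len: int = 0,
    repeat_identity: float = 0.9,
    microhomology_len: int = 0,
    seed: int = 0,
) -> tuple[list[SeqRecord], dict]:
    """Build a synthetic deletion junction fixture as FASTA records.

    Returns ([reference_allele, deleted_allele], annotations). The reference
    is left flank + deleted segment + right flank; the deleted allele is the
    two flanks joined. The motif (if any) is planted immediately 5' of both
    breakpoints with a forced mismatch just before it, so a motif scan
    reports it exactly; the microhomology is planted as a shared prefix of
    the deleted segment and the right flank; the flanking repeat is an
    identical subsequence embedded in both flanks and mutated to the
    requested identity.
    """
    motif = planted_motif.upper() if planted_motif else ""
    if deleted_len < max(len(motif) + 1, microhomology_len + 1, 10):
        raise ValueError("deleted segment too short for the requested content")
    if flank_len <= len(motif) + 1:
        raise ValueError("planted motif longer than flank")
    if flank_len <= microhomology_len + 1:
        raise ValueError("microhomology longer than flank")
    if repeat_homology_len and flank_len < repeat_homology_len + len(motif) + 40:
        raise ValueError("flank too short for the requested repeat homology")
    rng = np.random.default_rng(seed)

    left = rng.choice(_BASES, flank_len)
    mid = rng.choice(_BASES, deleted_len)
    right = rng.choice(_BASES, flank_len)

    annotations: dict = {
        "del_start": flank_len + 1,
        "del_end": flank_len + deleted_len,
        "flank_len": flank_len,
        "deleted_len": deleted_len,
    }

    if repeat_homology_len:
        rep = rng.choice(_BASES, repeat_homology_len)
        left[20 : 20 + repeat_homology_len] = rep
        mutated = _mutate_to_identity(rep, repeat_identity, rng)
        right[20 : 20 + repeat_homology_len] = mutated
        annotations["repeat"] = {
            "length": repeat_homology_len,
            "target_identity": repeat_identity,
            "realized_identity": float(np.mean(rep == mutated)),
            "left_offset": 20,
            "right_offset": 20,
        }

    if motif:
        marr = np.array(list(motif))
        left[-len(motif):] = marr
        mid[-len(motif):] = marr
        # force a mismatch immediately 5' of each copy so the motif is the
        # maximal shared string at the breakpoints
        k = len(motif) + 1
        if left[-k] == mid[-k]:
            left[-k] = _BASES[_BASES != mid[-k]][0]
        annotations["motif"] = motif

    if microhomology_len:
        right[:microhomology_len] = mid[:microhomology_len]
    if right[microhomology_len] == mid[microhomology_len]:
        right[microhomology_len] = _BASES[_BASES != mid[microhomology_len]][0]
    annotations["microhomology_len"] = microhomology_len

    ref = "".join(left) + "".join(mid) + "".join(right)
    deleted = "".join(left) + "".join(right)
    records = [
        SeqRecord(Seq(ref), id="reference_allele", description="synthetic junction fixture"),
        SeqRecord(Seq(deleted), id="deleted_allele", description="synthetic junction fixture"),
    ]
    return records, annotations
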