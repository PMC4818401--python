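"""End-to-end workflow: QC -> call filters -> screening -> association
(-> breakpoints), mirroring a staged discovery/replication study design.

The discovery panel drives candidate-region detection; association tables
are then built per panel over the full cohort, pooled, and combined with a
stratified method. Every excluded sample, call and region is traceable to
the rule that removed it, and a fixed config + inputs + seed reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml
from Bio import SeqIO

from . import __version__
from .association import (
    AssociationResult,
    CarrierTable,
    associate,
    combine_stratified,
    pool_tables,
)
from .breakpoints import analyze_junction
from .call_filters import (
    apply_call_filters,
    common_cnv_filter,
    gap_span_filter,
    region_probe_count_filter,
)
from .io import read_bed_track, read_cnv_calls, read_phenotypes
from .models import CnvCall, GenomicTrack, Phenotype, SampleRecord
from .region_screen import (
    CandidateRegion,
    build_regions,
    count_carriers,
    select_candidates,
)
from .sample_qc import array_metric_filter, batch_outlier_filter

log = logging.getLogger("rarecnv")


@dataclass
class PipelineConfig:
    """Fully serializable configuration of one pipeline run."""

    calls_path: Optional[str] = None
    phenotypes_path: Optional[str] = None
    probe_bed: Optional[str] = None
    gap_bed: Optional[str] = None
    common_cnv_bed: Optional[str] = None
    junction_fasta: Optional[str] = None
    discovery_panel: str = "discovery"
    # sample QC (toggles allow stage-wise ablation; the batch fence is only
    # meaningful when per-sample call counts are well away from zero)
    array_metric_qc: bool = True
    batch_outlier_qc: bool = True
    mapd_max: float = 0.4
    contrastqc_min: float = 0.4
    iqr_mult: float = 1.5
    # call filters
    min_probes: int = 5
    max_spacing: float = 1000.0
    spacing_rule: bool = True
    min_region_probes: int = 10
    common_overlap: float = 0.5
    # screening
    min_cases_no_control: int = 3
    min_cases_one_control: int = 5
    min_carrier_overlap: float = 0.0
    # association
    combine_method: str = "stratified_permutation"
    n_permutations: int = 10_000
    bonferroni_m: Optional[int] = None  # default: number of selected regions
    seed: int = 0
    outdir: str = "run_output"

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class RegionAssociation:
    """Per-panel, pooled and combined association for one candidate region."""

    region: CandidateRegion
    panel_results: list[AssociationResult]
    pooled: AssociationResult
    combined: dict

    def to_dict(self) -> dict:
        def res_dict(r: AssociationResult) -> dict:
            return {
                "panel": r.table.panel_id,
                "case_carriers": r.table.a,
                "case_noncarriers": r.table.b,
                "control_carriers": r.table.c,
                "control_noncarriers": r.table.d,
                "case_carrier_pct": round(100 * r.table.case_carrier_freq, 2)
                if r.table.n_cases else None,
                "control_carrier_pct": round(100 * r.table.control_carrier_freq, 2)
                if r.table.n_controls else None,
                "p_two_sided": r.p_two_sided,
                "odds_ratio": None if math.isnan(r.odds_ratio) else r.odds_ratio,
                "ci_low": None if math.isnan(r.ci_low) else r.ci_low,
                "ci_high": None if math.isnan(r.ci_high) else r.ci_high,
                "p_bonferroni": r.p_bonferroni,
                "bonferroni_m": r.bonferroni_m,
            }

        return {
            "region": self.region.region_id,
            "cnv_type": self.region.cnv_type.value,
            "selected_reason": self.region.reason,
            "panels": [res_dict(r) for r in self.panel_results],
            "pooled": res_dict(self.pooled),
            "combined": self.combined,
        }


@dataclass
class PipelineResult:
    config: PipelineConfig
    qc_reports: list
    retained_samples: list[SampleRecord]
    filtered_calls: list[CnvCall]
    call_verdicts: list
    regions: list[CandidateRegion]
    region_verdicts: dict[str, list]
    selected: list[CandidateRegion]
    associations: list[RegionAssociation]
    junction_reports: list = field(default_factory=list)


def carrier_tables_by_panel(
    region: CandidateRegion,
    samples: Sequence[SampleRecord],
    calls: Sequence[CnvCall],
    min_carrier_overlap: float = 0.0,
) -> list[CarrierTable]:
    """2x2 carrier tables for one region, one per panel, over all samples.

    A sample carries the region if any of its same-type calls overlaps the
    region span (by more than ``min_carrier_overlap`` of the call length).
    """
    carriers: set[str] = set()
    for call in calls:
        if call.chrom != region.chrom or call.cnv_type != region.cnv_type:
            continue
        shared = min(call.end, region.end) - max(call.start, region.start) + 1
        if shared <= 0:
            continue
        if min_carrier_overlap > 0 and shared / call.length < min_carrier_overlap:
            continue
        carriers.add(call.sample_id)
    tables = []
    panels = sorted({s.panel_id for s in samples})
    for panel in panels:
        members = [s for s in samples if s.panel_id == panel]
        a = sum(1 for s in members if s.phenotype is Phenotype.CASE and s.sample_id in carriers)
        c = sum(1 for s in members if s.phenotype is Phenotype.CONTROL and s.sample_id in carriers)
        n_cases = sum(1 for s in members if s.phenotype is Phenotype.CASE)
        n_controls = len(members) - n_cases
        tables.append(CarrierTable(a=a, b=n_cases - a, c=c, d=n_controls - c, panel_id=panel))
    return tables


def run_pipeline(
    config: PipelineConfig,
    calls: Optional[Sequence[CnvCall]] = None,
    samples: Optional[Sequence[SampleRecord]] = None,
    probe_track: Optional[GenomicTrack] = None,
    gap_track: Optional[GenomicTrack] = None,
    common_track: Optional[GenomicTrack] = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Execute the staged workflow; inputs may be passed in memory or read
    from the paths in ``config``."""
    if calls is None:
        if config.calls_path is None:
            raise ValueError("no calls provided (in memory or via calls_path)")
        calls = read_cnv_calls(config.calls_path)
    if samples is None:
        if config.phenotypes_path is None:
            raise ValueError("no phenotypes provided (in memory or via phenotypes_path)")
        samples = read_phenotypes(config.phenotypes_path)
    if probe_track is None and config.probe_bed:
        probe_track = read_bed_track(config.probe_bed)
    if gap_track is None and config.gap_bed:
        gap_track = read_bed_track(config.gap_bed)
    if common_track is None and config.common_cnv_bed:
        common_track = read_bed_track(config.common_cnv_bed)

    panels = {s.panel_id for s in samples}
    if config.discovery_panel not in panels:
        raise ValueError(
            f"designated discovery panel {config.discovery_panel!r} not present "
            f"in phenotype table (panels: {sorted(panels)})"
        )

    # ---- stage 1: sample QC -------------------------------------------------
    log.info("[qc] %d samples, %d calls in", len(samples), len(calls))
    qc_reports = []
    failed: set[str] = set()
    if config.array_metric_qc:
        metric_report = array_metric_filter(samples, config.mapd_max, config.contrastqc_min)
        qc_reports.append(metric_report)
        failed |= metric_report.failed_samples
    if config.batch_outlier_qc:
        call_counts = {s.sample_id: 0 for s in samples}
        for c in calls:
            if c.sample_id in call_counts:
                call_counts[c.sample_id] += 1
        batches = {s.sample_id: (s.batch_id or s.panel_id) for s in samples}
        outlier_report = batch_outlier_filter(call_counts, batches, config.iqr_mult)
        qc_reports.append(outlier_report)
        failed |= outlier_report.failed_samples
    retained = [s for s in samples if s.sample_id not in failed]
    calls_qc = [c for c in calls if c.sample_id not in failed]
    log.info("[qc] excluded %d samples", len(failed))

    # ---- stage 2: call-level filters ---------------------------------------
    kept_calls, call_verdicts = apply_call_filters(
        calls_qc, probe_track, config.min_probes, config.max_spacing, config.spacing_rule
    )
    log.info("[filter] %d/%d calls pass probe support", len(kept_calls), len(calls_qc))

    # ---- stage 3: discovery screen ------------------------------------------
    discovery_ids = {s.sample_id for s in retained if s.panel_id == config.discovery_panel}
    discovery_calls = [c for c in kept_calls if c.sample_id in discovery_ids]
    regions = build_regions(discovery_calls)
    region_verdicts: dict[str, list] = {}
    surviving = []
    for region in regions:
        verdicts = []
        if gap_track is not None:
            verdicts.append(gap_span_filter(region.chrom, region.start, region.end, gap_track))
        if common_track is not None:
            verdicts.append(
                common_cnv_filter(region.chrom, region.start, region.end,
                                  common_track, config.common_overlap, region.cnv_type)
            )
        if probe_track is not None:
            verdicts.append(
                region_probe_count_filter(region.chrom, region.start, region.end,
                                          probe_track, config.min_region_probes)
            )
        region_verdicts[region.region_id] = verdicts
        if all(v.keep for v in verdicts):
            surviving.append(region)
    log.info("[screen] %d regions built, %d pass region filters", len(regions), len(surviving))

    retained_map = {s.sample_id: s for s in retained if s.sample_id in discovery_ids}
    count_carriers(surviving, retained_map, config.min_carrier_overlap)
    selected = select_candidates(
        surviving, config.min_cases_no_control, config.min_cases_one_control
    )
    log.info("[screen] %d candidate regions selected", len(selected))

    # ---- stage 4: association ------------------------------------------------
    m = config.bonferroni_m if config.bonferroni_m is not None else max(1, len(selected))
    associations = []
    for region in selected:
        tables = carrier_tables_by_panel(region, retained, kept_calls, config.min_carrier_overlap)
        panel_results = [associate(t) for t in tables]
        pooled = associate(pool_tables(tables), bonferroni_m=m)
        combined = combine_stratified(
            tables, config.combine_method, config.n_permutations, config.seed
        )
        combined["p_bonferroni"] = min(1.0, m * combined["p"])
        combined["bonferroni_m"] = m
        associations.append(
            RegionAssociation(region=region, panel_results=panel_results,
                              pooled=pooled, combined=combined)
        )

    # ---- stage 5: breakpoints (optional) ------------------------------------
    junction_reports = []
    if config.junction_fasta:
        records = {r.id: r for r in SeqIO.parse(config.junction_fasta, "fasta")}
        ref = records.get("reference_allele")
        meta_path = Path(config.junction_fasta).with_suffix(".json")
        if ref is not None and meta_path.exists():
            meta = json.loads(meta_path.read_text(encoding="utf-8"))
            junction_reports.append(
                analyze_junction(str(ref.seq), meta["del_start"], meta["del_end"])
            )

    result = PipelineResult(
        config=config,
        qc_reports=qc_reports,
        retained_samples=retained,
        filtered_calls=kept_calls,
        call_verdicts=call_verdicts,
        regions=regions,
        region_verdicts=region_verdicts,
        selected=selected,
        associations=associations,
        junction_reports=junction_reports,
    )
    if write_outputs:
        write_run_outputs(result)
    return result


def write_run_outputs(result: PipelineResult) -> Path:
    outdir = Path(result.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(outdir / "effective_config.yaml")
    for report in result.qc_reports:
        report.table.to_csv(outdir / f"qc_{report.rule}.tsv", sep="\t", index=False)
    with open(outdir / "filter_verdicts.tsv", "w", encoding="utf-8") as fh:
        fh.write("identity\trule\tkeep\tdiagnostics\n")
        for v in result.call_verdicts:
            fh.write(f"{v.identity}\t{v.rule}\t{v.keep}\t{json.dumps(v.diagnostics)}\n")
        for region_id, verdicts in sorted(result.region_verdicts.items()):
            for v in verdicts:
                fh.write(f"{v.identity}\t{v.rule}\t{v.keep}\t{json.dumps(v.diagnostics)}\n")
    with open(outdir / "candidate_regions.tsv", "w", encoding="utf-8") as fh:
        fh.write("region\tcnv_type\tcase_carriers\tcontrol_carriers\tselected\treason\n")
        for r in result.regions:
            fh.write(
                f"{r.region_id}\t{r.cnv_type.value}\t{r.case_carriers}\t"
                f"{r.control_carriers}\t{r.selected}\t{r.reason}\n"
            )
    with open(outdir / "candidate_regions.bed", "w", encoding="utf-8") as fh:
        for r in result.selected:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.cnv_type.value}\n")
    payload = [a.to_dict() for a in result.associations]
    (outdir / "associations.json").write_text(json.dumps(payload, indent=1), encoding="utf-8")
    if result.junction_reports:
        (outdir / "junctions.json").write_text(
            json.dumps(
                [
                    {
                        "event_bp": jr.event_bp,
                        "event_kb": jr.event_kb,
                        "microhomology": jr.microhomology,
                        "mechanism": jr.mechanism.value,
                        "rule_fired": jr.rule_fired,
                        "shared_motifs": [
                            {"kmer": m.kmer, "left_offset": m.left_offset,
                             "right_offset": m.right_offset}
                            for m in jr.shared_motifs[:20]
                        ],
                        "repeat_homology": {
                            "length": jr.repeat_homology.length,
                            "identity": jr.repeat_homology.identity,
                        },
                        "thresholds": jr.thresholds,
                    }
                    for jr in result.junction_reports
                ],
                indent=1,
            ),
            encoding="utf-8",
        )
    (outdir / "run_summary.json").write_text(
        json.dumps(
            {
                "version": __version__,
                "n_samples_in": len(result.retained_samples)
                + sum(r.summary["n_failed"] for r in result.qc_reports),
                "n_samples_retained": len(result.retained_samples),
                "n_calls_retained": len(result.filtered_calls),
                "n_regions": len(result.regions),
                "n_selected": len(result.selected),
            },
            indent=1,
        ),
        encoding="utf-8",
    )
    return outdir


def make_report(result: PipelineResult) -> str:
    """Human-readable association summary: one block per selected region,
    panel rows then pooled and combined rows; carrier percentages to 2 dp."""
    lines = []
    for assoc in result.associations:
        r = assoc.region
        bp = r.end - r.start + 1
        lines.append(f"== {r.cnv_type.value} {r.chrom}:{r.start:,}-{r.end:,} ({bp:,} bp) ==")
        lines.append(f"   selected: {r.reason}")
        header = (
            f"{'panel':<22} {'cases cc/N':>12} {'freq':>8} "
            f"{'ctrls cc/N':>12} {'freq':>8} {'P':>10} {'OR':>8}"
        )
        lines.append(header)

        def fmt_row(res: AssociationResult) -> str:
            t = res.table
            case_pct = f"{100 * t.case_carrier_freq:.2f}%" if t.n_cases else "-"
            ctrl_pct = f"{100 * t.control_carrier_freq:.2f}%" if t.n_controls else "-"
            if math.isnan(res.odds_ratio):
                orr = "NA"
            elif math.isinf(res.odds_ratio):
                orr = "Inf"
            else:
                orr = f"{res.odds_ratio:.2f}"
            return (
                f"{t.panel_id:<22} {f'{t.a}/{t.n_cases}':>12} {case_pct:>8} "
                f"{f'{t.c}/{t.n_controls}':>12} {ctrl_pct:>8} "
                f"{res.p_two_sided:>10.3g} {orr:>8}"
            )

        for res in assoc.panel_results:
            lines.append(fmt_row(res))
        lines.append(fmt_row(assoc.pooled))
        comb = assoc.combined
        lines.append(
            f"{'combined (' + comb['method'] + ')':<22} p = {comb['p']:.3g}"
            f"   Bonferroni (m={comb['bonferroni_m']}): {comb['p_bonferroni']:.3g}"
        )
        if assoc.pooled.p_bonferroni is not None:
            lines.append(
                f"{'pooled Bonferroni':<22} p = {assoc.pooled.p_bonferroni:.3g}"
                f" (m={assoc.pooled.bonferroni_m})"
            )
        lines.append("")
    if not result.associations:
        lines.append("no candidate regions selected")
    return "\n".join(lines)
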