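"""Cohort generator: determinism, truth tables, planted-signal fidelity."""

from __future__ import annotations

import numpy as np
import pytest

from rarecnv.io import read_cnv_calls, read_phenotypes
from rarecnv.models import CnvType, Phenotype, Platform
from rarecnv.simulate import (
    CommonCnv,
    PanelConfig,
    RiskCnv,
    SimulationConfig,
    generate_cohort,
    generate_junction,
)


def small_config(seed=0, **overrides):
    base = dict(
        seed=seed,
        panels=[PanelConfig("discovery", 200, 300, Platform.ARRAY)],
        risk_cnvs=[RiskCnv("sim1", 1_000_000, 1_015_760, CnvType.DEL, 0.05, 0.01)],
        common_cnvs=[],
        passenger_rate=0.0,
        false_positive_rate=0.0,
        boundary_jitter_sd=0.0,
        outlier_fraction=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_frequency_above_one_rejected(self):
        with pytest.raises(ValueError, match="frequency"):
            small_config(risk_cnvs=[RiskCnv("sim1", 10, 20, CnvType.DEL, 1.5, 0.0)])

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            small_config(passenger_rate=-1.0)

    def test_outlier_fraction_bounds(self):
        with pytest.raises(ValueError, match="outlier_fraction"):
            small_config(outlier_fraction=1.5)


class TestGenerateCohort:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        for d in ("a", "b"):
            generate_cohort(small_config(seed=11, passenger_rate=1.0,
                                         false_positive_rate=0.2,
                                         boundary_jitter_sd=1500.0,
                                         outlier_fraction=0.02)).write(tmp_path / d)
        for name in ("calls.tsv", "phenotypes.tsv", "probes.bed", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        a = generate_cohort(small_config(seed=1))
        b = generate_cohort(small_config(seed=2))
        assert {c.sample_id for c in a.calls} != {c.sample_id for c in b.calls}

    def test_zero_frequency_gives_empty_truth(self):
        cfg = small_config(risk_cnvs=[RiskCnv("sim1", 10_000, 20_000, CnvType.DEL, 0.0, 0.0)])
        cohort = generate_cohort(cfg)
        assert all(len(v) == 0 for v in cohort.truth.carriers.values())
        assert cohort.calls == []

    def test_noise_free_calls_exactly_equal_planted_intervals(self):
        cohort = generate_cohort(small_config(seed=3))
        rc = small_config().risk_cnvs[0]
        assert len(cohort.calls) > 0
        for call in cohort.calls:
            assert (call.chrom, call.start, call.end) == (rc.chrom, rc.start, rc.end)
            assert call.cnv_type is rc.cnv_type

    def test_truth_carriers_are_generated_samples_with_matching_calls(self):
        cohort = generate_cohort(small_config(seed=4))
        sample_ids = {s.sample_id for s in cohort.phenotypes}
        callers = {c.sample_id for c in cohort.calls}
        (carriers,) = cohort.truth.carriers.values()
        assert carriers <= sample_ids
        assert carriers == callers

    def test_outlier_samples_exceed_batch_fence_scale(self):
        cohort = generate_cohort(small_config(seed=5, passenger_rate=2.0, outlier_fraction=0.05))
        counts: dict[str, int] = {s.sample_id: 0 for s in cohort.phenotypes}
        for c in cohort.calls:
            counts[c.sample_id] += 1
        assert cohort.truth.outliers
        normal = [n for s, n in counts.items() if s not in cohort.truth.outliers]
        q75, q25 = np.percentile(normal, [75, 25])
        fence = q75 + 1.5 * (q75 - q25)
        assert all(counts[s] > fence for s in cohort.truth.outliers)

    def test_insilico_panels_are_control_only(self):
        cfg = small_config(panels=[
            PanelConfig("discovery", 50, 50, Platform.ARRAY),
            PanelConfig("public", 0, 100, Platform.INSILICO),
        ])
        cohort = generate_cohort(cfg)
        pub = [s for s in cohort.phenotypes if s.panel_id == "public"]
        assert len(pub) == 100
        assert all(s.phenotype is Phenotype.CONTROL for s in pub)

    def test_written_cohort_reads_back(self, tmp_path):
        cohort = generate_cohort(small_config(seed=6, passenger_rate=0.5))
        cohort.write(tmp_path)
        calls = read_cnv_calls(tmp_path / "calls.tsv")
        phenos = read_phenotypes(tmp_path / "phenotypes.tsv")
        assert calls == cohort.calls
        assert phenos == cohort.phenotypes

    def test_carrier_frequency_recovery_over_seeds(self):
        """Mean observed carrier frequency converges to the configured one
        (checked where n x freq >= 20 per draw)."""
        cfg0 = small_config(panels=[PanelConfig("d", 500, 500, Platform.ARRAY)],
                            risk_cnvs=[RiskCnv("sim1", 10_000, 40_000, CnvType.DEL, 0.2, 0.05)])
        case_freqs, ctrl_freqs = [], []
        for seed in range(30):
            cohort = generate_cohort(small_config(
                seed=seed,
                panels=cfg0.panels, risk_cnvs=cfg0.risk_cnvs,
            ))
            (carriers,) = cohort.truth.carriers.values()
            cases = {s.sample_id for s in cohort.phenotypes if s.phenotype is Phenotype.CASE}
            case_freqs.append(len(carriers & cases) / 500)
            ctrl_freqs.append(len(carriers - cases) / 500)
        se_case = np.sqrt(0.2 * 0.8 / (500 * 30))
        se_ctrl = np.sqrt(0.05 * 0.95 / (500 * 30))
        assert abs(np.mean(case_freqs) - 0.2) < 3 * se_case
        assert abs(np.mean(ctrl_freqs) - 0.05) < 3 * se_ctrl


class TestGenerateJunction:
    def test_deleted_allele_is_concatenation_of_flanks(self):
        records, ann = generate_junction(deleted_len=500, flank_len=80, seed=1)
        ref, deleted = str(records[0].seq), str(records[1].seq)
        s, e = ann["del_start"], ann["del_end"]
        assert deleted == ref[: s - 1] + ref[e:]
        assert len(ref) - len(deleted) == 500

    def test_motif_longer_than_flank_is_error(self):
        with pytest.raises(ValueError, match="motif"):
            generate_junction(deleted_len=500, flank_len=5, planted_motif="GATCACG")

    def test_no_planted_content_means_clean_junction(self):
        records, ann = generate_junction(
            deleted_len=400, flank_len=60, planted_motif="", microhomology_len=0, seed=7
        )
        from rarecnv.breakpoints import microhomology_length

        assert microhomology_length(str(records[0].seq), ann["del_start"], ann["del_end"]) == 0

    def test_repeat_realized_identity_close_to_target(self):
        _, ann = generate_junction(
            deleted_len=400, flank_len=400, planted_motif="",
            repeat_homology_len=300, repeat_identity=0.9, seed=8,
        )
        assert ann["repeat"]["realized_identity"] == pytest.approx(0.9, abs=0.01)
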