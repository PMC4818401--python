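"""Sample-level quality control.

Three independent rules, each producing a :class:`QcReport`:

* array metric thresholds — fail iff MAPD > 0.4 or contrastQC < 0.4
  (strict inequalities; both thresholds configurable);
* batch-wise call-count outliers — within each batch, a Tukey-style upper
  fence T = Q75 + 1.5 * (Q75 - Q25) over per-sample CNV call counts; samples
  with count strictly above T are flagged;
* qPCR replicate QC — discard iff confidence < 0.95, z-score >= 2.65, or
  fewer than 3 of the 4 technical replicates are valid.

A sample failing any rule is excluded from all downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import Platform, QpcrReplicateSet, SampleRecord


@dataclass
class QcReport:
    """Per-sample pass/fail flags for one QC rule plus cohort summary.

    ``table`` has one row per sample with at least columns ``sample`` and
    ``fail`` (bool); rule-specific diagnostic columns vary. ``thresholds``
    records the effective cutoffs so a run can be reproduced or re-applied
    with frozen thresholds.
    """

    rule: str
    table: pd.DataFrame
    thresholds: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def failed_samples(self) -> set[str]:
        return set(self.table.loc[self.table["fail"], "sample"])

    @property
    def retained_samples(self) -> set[str]:
        return set(self.table.loc[~self.table["fail"], "sample"])

    @property
    def summary(self) -> dict:
        return {
            "rule": self.rule,
            "n_samples": int(len(self.table)),
            "n_failed": int(self.table["fail"].sum()),
            "n_retained": int((~self.table["fail"]).sum()),
            "thresholds": self.thresholds,
        }


def array_metric_filter(
    samples: Sequence[SampleRecord],
    mapd_max: float = 0.4,
    contrastqc_min: float = 0.4,
) -> QcReport:
    """Flag array samples failing the intensity-noise QC thresholds.

    Samples without metrics (or on non-array platforms) pass this rule; a
    warning is recorded for array samples with missing metrics.
    """
    warnings: list[str] = []
    rows = []
    for s in samples:
        if s.mapd is not None and s.mapd < 0:
            raise ValueError(f"sample {s.sample_id}: negative MAPD")
        fail_mapd = s.mapd is not None and s.mapd > mapd_max
        fail_cqc = s.contrast_qc is not None and s.contrast_qc < contrastqc_min
        if s.platform is Platform.ARRAY and s.mapd is None and s.contrast_qc is None:
            warnings.append(
                f"array sample {s.sample_id} has no QC metrics; rule passed by default"
            )
        rows.append(
            {
                "sample": s.sample_id,
                "mapd": s.mapd,
                "contrast_qc": s.contrast_qc,
                "fail_mapd": fail_mapd,
                "fail_contrast_qc": fail_cqc,
                "fail": fail_mapd or fail_cqc,
            }
        )
    table = pd.DataFrame(
        rows, columns=["sample", "mapd", "contrast_qc", "fail_mapd", "fail_contrast_qc", "fail"]
    )
    return QcReport(
        rule="array_metrics",
        table=table,
        thresholds={"mapd_max": mapd_max, "contrastqc_min": contrastqc_min},
        warnings=warnings,
    )


def batch_call_count_thresholds(
    call_counts: Mapping[str, int],
    batches: Mapping[str, str],
    iqr_mult: float = 1.5,
    quantile_method: str = "linear",
) -> dict[str, float]:
    """Per-batch upper fences Q75 + iqr_mult * (Q75 - Q25) of call counts."""
    by_batch: dict[str, list[int]] = {}
    for sample, count in call_counts.items():
        if sample not in batches:
            raise ValueError(f"sample {sample} has no batch assignment")
        by_batch.setdefault(batches[sample], []).append(int(count))
    thresholds = {}
    for batch, counts in by_batch.items():
        arr = np.asarray(counts, dtype=float)
        q25, q75 = np.percentile(arr, [25, 75], method=quantile_method)
        thresholds[batch] = float(q75 + iqr_mult * (q75 - q25))
    return thresholds


def batch_outlier_filter(
    call_counts: Mapping[str, int],
    batches: Mapping[str, str],
    iqr_mult: float = 1.5,
    quantile_method: str = "linear",
    frozen_thresholds: Mapping[str, float] | None = None,
) -> QcReport:
    """Flag samples with more CNV calls than their batch's upper fence.

    Flagging is order-independent: the fence is computed from all samples in
    the batch, then applied with a strict ``count > T`` comparison. Passing
    ``frozen_thresholds`` re-applies fences from an earlier run instead of
    recomputing them (idempotent re-screening).
    """
    if frozen_thresholds is None:
        thresholds = batch_call_count_thresholds(
            call_counts, batches, iqr_mult, quantile_method
        )
    else:
        thresholds = dict(frozen_thresholds)
    warnings = []
    batch_sizes: dict[str, int] = {}
    for sample in call_counts:
        batch_sizes[batches[sample]] = batch_sizes.get(batches[sample], 0) + 1
    for batch, size in sorted(batch_sizes.items()):
        if size < 4:
            warnings.append(
                f"batch {batch} has only {size} sample(s); fence is unstable"
            )
    rows = []
    for sample in sorted(call_counts):
        batch = batches[sample]
        t = thresholds[batch]
        count = int(call_counts[sample])
        rows.append(
            {
                "sample": sample,
                "batch": batch,
                "call_count": count,
                "threshold": t,
                "fail": count > t,
            }
        )
    table = pd.DataFrame(rows, columns=["sample", "batch", "call_count", "threshold", "fail"])
    return QcReport(
        rule="batch_outlier",
        table=table,
        thresholds={
            "iqr_mult": iqr_mult,
            "quantile_method": quantile_method,
            "per_batch": thresholds,
        },
        warnings=warnings,
    )


def qpcr_replicate_filter(
    replicate_sets: Sequence[QpcrReplicateSet],
    confidence_min: float = 0.95,
    zscore_max: float = 2.65,
    min_replicates: int = 3,
) -> QcReport:
    """Discard qPCR measurements failing confidence/z-score/replicate rules.

    Discard iff confidence < ``confidence_min`` (strict), z-score >=
    ``zscore_max`` (inclusive), or valid replicates < ``min_replicates``.
    Confidence and z-score are consumed as computed upstream; their
    provenance (plate- vs assay-relative) is the caller's responsibility.
    """
    rows = []
    for rs in replicate_sets:
        fail_conf = rs.confidence is not None and rs.confidence < confidence_min
        fail_z = rs.z_score is not None and rs.z_score >= zscore_max
        fail_reps = rs.n_valid_replicates < min_replicates
        rows.append(
            {
                "sample": rs.sample_id,
                "assay": rs.assay_id,
                "confidence": rs.confidence,
                "z_score": rs.z_score,
                "n_replicates": rs.n_valid_replicates,
                "fail_confidence": fail_conf,
                "fail_zscore": fail_z,
                "fail_replicates": fail_reps,
                "fail": fail_conf or fail_z or fail_reps,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "sample", "assay", "confidence", "z_score", "n_replicates",
            "fail_confidence", "fail_zscore", "fail_replicates", "fail",
        ],
    )
    return QcReport(
        rule="qpcr_replicates",
        table=table,
        thresholds={
            "confidence_min": confidence_min,
            "zscore_max": zscore_max,
            "min_replicates": min_replicates,
        },
    )
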