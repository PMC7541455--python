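"""End-to-end QC of a normal/tumour BAM pair."""

from __future__ import annotations

from .alignment_io import (
    DEFAULT_POLICY,
    FilterPolicy,
    ReferenceIndex,
    depth_vector,
    filtered_reads,
)
from .callable_coverage import callable_bases
from .coverage_metrics import mean_coverage
from .gc_evenness import evenness_metrics
from .pair_integrity import pair_integrity_metrics
from .star_rating import (
    QCThresholds,
    SampleMetrics,
    StarReport,
    award_stars,
    evaluate_measures,
)

__all__ = ["compute_sample_metrics", "run_pair_qc"]


def compute_sample_metrics(bam_path, ref: ReferenceIndex,
                           policy: FilterPolicy = DEFAULT_POLICY):
    """All per-sample QC values for one BAM.

    Returns ``(SampleMetrics, depth)``; the depth vectors are reused for
    the joint callable-coverage measure so each sample's depth is
    computed once.
    """
    depth = depth_vector(bam_path, policy, ref.included_contigs)
    metrics = SampleMetrics(
        mean_coverage=mean_coverage(depth, ref),
        evenness=evenness_metrics(bam_path, policy, ref),
        pair_integrity=pair_integrity_metrics(
            filtered_reads(bam_path, policy, ref.included_contigs),
            ref.included_contigs,
        ),
    )
    return metrics, depth


def run_pair_qc(normal_bam, tumour_bam, ref: ReferenceIndex,
                thresholds: QCThresholds = QCThresholds(),
                policy: FilterPolicy = DEFAULT_POLICY,
                normal_id: str = "normal", tumour_id: str = "tumour") -> StarReport:
    """Compute all five measures for a pair and award the star rating."""
    normal_metrics, normal_depth = compute_sample_metrics(normal_bam, ref, policy)
    tumour_metrics, tumour_depth = compute_sample_metrics(tumour_bam, ref, policy)
    joint = callable_bases(normal_depth, tumour_depth, ref)
    outcomes = evaluate_measures(normal_metrics, tumour_metrics, joint, thresholds)
    return award_stars(outcomes, thresholds, normal_id=normal_id, tumour_id=tumour_id)
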