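"""VAF computation, replicate pooling, and thresholded positivity calls.

A marker is called ctDNA-positive when its VAF reaches the effective
cutoff — the larger of the global 0.01% assay cutoff and the marker's own
background LOD — at adequate coverage.  Replicate PCRs are integrated by
summing raw reads before the VAF is computed, which is how pooled
barcoded triplicates behave on the sequencer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from ctdnakit.core_model import ReadCounts
from ctdnakit.error_model import ErrorProfile

__all__ = [
    "CallResult",
    "SampleCall",
    "GLOBAL_CUTOFF_PCT",
    "MIN_COVERAGE",
    "compute_vaf",
    "pool_replicates",
    "call_marker",
    "call_sample",
    "write_calls_table",
    "read_calls_table",
]

#: assay-wide decision threshold in percent VAF
GLOBAL_CUTOFF_PCT = 0.01
#: below this depth a 0.01% call expects <1 supporting read
MIN_COVERAGE = 10_000
#: depth the assay aims for; calls between MIN_COVERAGE and this carry a warning
TARGET_COVERAGE = 100_000

STATUS_POSITIVE = "positive"
STATUS_WILD_TYPE = "wild_type"
STATUS_INSUFFICIENT = "insufficient_coverage"
SAMPLE_INCONCLUSIVE = "inconclusive"


def compute_vaf(counts: ReadCounts) -> float:
    """Variant allele frequency in percent: ``100 * alt / total``."""
    if counts.total_reads == 0:
        raise ValueError(f"{counts.marker_id}: VAF undefined at zero coverage")
    return 100.0 * counts.alt_reads / counts.total_reads


def pool_replicates(replicates: Sequence[ReadCounts]) -> ReadCounts:
    """Integrate replicate PCRs of one marker by summing raw read tallies.

    The pooled VAF is the mediant of the replicate VAFs and therefore
    always lies within their range.  A single replicate pools to itself.
    """
    if not replicates:
        raise ValueError("no replicates to pool")
    marker_ids = {r.marker_id for r in replicates}
    if len(marker_ids) != 1:
        raise ValueError(f"cannot pool across markers: {sorted(marker_ids)}")
    if len(replicates) == 1:
        return replicates[0]
    return ReadCounts(
        marker_id=marker_ids.pop(),
        replicate_index="pooled",
        alt_reads=sum(r.alt_reads for r in replicates),
        total_reads=sum(r.total_reads for r in replicates),
    )


@dataclass(frozen=True)
class CallResult:
    """Positivity decision for one marker in one sample."""

    marker_id: str
    vaf_pct: Optional[float]
    cutoff_pct: float
    status: str
    coverage: int = 0
    low_coverage_warning: bool = False


@dataclass(frozen=True)
class SampleCall:
    """Sample-level decision combining 1-3 tumor-informed markers.

    A sample is positive if any marker is positive (maximum sensitivity
    for multi-marker panels), wild type if at least one marker was
    adequately covered and none is positive, and inconclusive only when
    every marker lacked coverage.
    """

    sample_id: str
    marker_calls: tuple[CallResult, ...]
    sample_status: str


def call_marker(
    counts: ReadCounts,
    profile: Optional[ErrorProfile] = None,
    global_cutoff_pct: float = GLOBAL_CUTOFF_PCT,
    min_coverage: int = MIN_COVERAGE,
) -> CallResult:
    """Call one marker against its background-aware cutoff.

    The effective cutoff is ``max(global_cutoff_pct, profile.lod_pct)`` so
    markers with elevated background (e.g. noisy transitions) are never
    called below their own noise floor.  Coverage below ``min_coverage``
    yields ``insufficient_coverage`` regardless of VAF; coverage between
    ``min_coverage`` and the 100,000-read target is flagged but called.
    """
    if profile is not None and profile.marker_id != counts.marker_id:
        raise ValueError(
            f"profile for {profile.marker_id!r} does not match counts for {counts.marker_id!r}"
        )
    cutoff = global_cutoff_pct if profile is None else max(global_cutoff_pct, profile.lod_pct)
    if counts.total_reads < min_coverage:
        return CallResult(counts.marker_id, None, cutoff, STATUS_INSUFFICIENT, counts.total_reads)
    vaf = compute_vaf(counts)
    status = STATUS_POSITIVE if vaf >= cutoff else STATUS_WILD_TYPE
    return CallResult(
        counts.marker_id,
        vaf,
        cutoff,
        status,
        counts.total_reads,
        low_coverage_warning=counts.total_reads < TARGET_COVERAGE,
    )


def call_sample(sample_id: str, marker_calls: Sequence[CallResult]) -> SampleCall:
    """Combine per-marker calls into a sample-level ctDNA status (any-positive rule)."""
    if not marker_calls:
        raise ValueError(f"{sample_id}: no marker calls to combine")
    statuses = [c.status for c in marker_calls]
    if any(s == STATUS_POSITIVE for s in statuses):
        status = STATUS_POSITIVE
    elif all(s == STATUS_INSUFFICIENT for s in statuses):
        status = SAMPLE_INCONCLUSIVE
    else:
        status = STATUS_WILD_TYPE
    return SampleCall(sample_id, tuple(marker_calls), status)


CALLS_COLUMNS = ["sample_id", "marker_id", "vaf_pct", "cutoff_pct", "status"]


def write_calls_table(
    calls: Sequence[tuple[str, CallResult]], path: str | Path
) -> None:
    """Write ``(sample_id, call)`` records as a tab-delimited table.

    VAFs are serialized with 7 significant digits so 0.0001% steps stay
    distinguishable.
    """
    df = pd.DataFrame(
        {
            "sample_id": [s for s, _ in calls],
            "marker_id": [c.marker_id for _, c in calls],
            "vaf_pct": [c.vaf_pct for _, c in calls],
            "cutoff_pct": [c.cutoff_pct for _, c in calls],
            "status": [c.status for _, c in calls],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.7g")


def read_calls_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "marker_id": str})
    missing = [c for c in CALLS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"calls table {path}: missing columns {missing}")
    return df
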