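"""Background substitution error estimation and the empirical-rule LOD.

Wild-type control cfDNA carries no tumor variant, so any alt reads at a
marker position measure the assay's position-specific substitution error.
The limit of detection follows the empirical (three-sigma) rule: for a
roughly normal background, 99.73% of wild-type observations fall within
mean + 3*SD, so a VAF above that bound is unlikely to be error.  With the
control-cohort values measured for the KRAS c.35G>A marker (mean 0.0016%,
SD 0.0007%) this gives an LOD of 0.0037% — one mutant allele in 27,027.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from ctdnakit.core_model import MarkerSpec, ReadCounts

__all__ = [
    "ErrorProfile",
    "lod_pct",
    "estimate_error_profile",
    "lod_to_allele_ratio",
    "summarize_by_class",
    "resolve_profile",
    "write_profiles_table",
    "read_profiles_table",
]


def lod_pct(mean_fp_pct: float, sd_fp_pct: float, k: float = 3.0) -> float:
    """Empirical-rule limit of detection: background mean plus ``k`` SDs."""
    if mean_fp_pct < 0 or sd_fp_pct < 0:
        raise ValueError("mean and SD must be non-negative")
    if k < 0:
        raise ValueError("k must be non-negative")
    return mean_fp_pct + k * sd_fp_pct


@dataclass(frozen=True)
class ErrorProfile:
    """Per-marker background error summary from wild-type controls."""

    marker_id: str
    n_controls: int
    mean_fp_pct: float
    sd_fp_pct: float
    k: float = 3.0

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("ErrorProfile requires >= 2 controls")
        if self.mean_fp_pct < 0 or self.sd_fp_pct < 0:
            raise ValueError("error moments must be non-negative")

    @property
    def lod_pct(self) -> float:
        return lod_pct(self.mean_fp_pct, self.sd_fp_pct, self.k)


def estimate_error_profile(
    controls: Sequence[ReadCounts], k: float = 3.0
) -> ErrorProfile:
    """Estimate a marker's background error from wild-type control counts.

    Per-control false-positive VAF is ``100 * alt / total``; the profile
    holds their mean and sample standard deviation (n-1 denominator, the
    unbiased convention) and the derived ``mean + k*SD`` LOD.
    """
    if len(controls) < 2:
        raise ValueError("need >= 2 control measurements")
    marker_ids = {c.marker_id for c in controls}
    if len(marker_ids) != 1:
        raise ValueError(f"controls span multiple markers: {sorted(marker_ids)}")
    if any(c.total_reads == 0 for c in controls):
        raise ValueError("control with zero coverage")
    fps = [100.0 * c.alt_reads / c.total_reads for c in controls]
    return ErrorProfile(
        marker_id=marker_ids.pop(),
        n_controls=len(controls),
        mean_fp_pct=statistics.fmean(fps),
        sd_fp_pct=statistics.stdev(fps),
        k=k,
    )


def lod_to_allele_ratio(lod_pct_value: float) -> int:
    """Express an LOD as 'one mutant allele in N wild-type alleles'.

    0.0037% -> 27,027; 0.01% -> 10,000.
    """
    if lod_pct_value <= 0:
        raise ValueError("allele ratio undefined for a zero LOD")
    return round(100.0 / lod_pct_value)


def summarize_by_class(
    profiles: Sequence[ErrorProfile], markers: Sequence[MarkerSpec]
) -> pd.DataFrame:
    """Summarize background error by mutation class.

    Returns one row per class present with the median, min and max of the
    per-marker mean false-positive rates, plus the marker count.  Classes
    with no profiled marker are omitted.  Background error is strongly
    class-structured: transversions run roughly five-fold cleaner than
    transitions on this chemistry.
    """
    by_id = {m.marker_id: m for m in markers}
    rows = []
    for p in profiles:
        try:
            marker = by_id[p.marker_id]
        except KeyError:
            raise KeyError(f"profile for unknown marker_id {p.marker_id!r}") from None
        rows.append({"mutation_class": marker.mutation_class, "mean_fp_pct": p.mean_fp_pct})
    df = pd.DataFrame(rows)
    summary = (
        df.groupby("mutation_class")["mean_fp_pct"]
        .agg(n_markers="count", median_fp_pct="median", min_fp_pct="min", max_fp_pct="max")
        .reset_index()
    )
    return summary


def resolve_profile(
    marker: MarkerSpec,
    profiles: Sequence[ErrorProfile],
    markers: Sequence[MarkerSpec],
    k: float = 3.0,
) -> Optional[ErrorProfile]:
    """Profile for ``marker``, falling back to its class median background.

    Markers lacking dedicated controls borrow the median background of
    profiled markers in the same mutation class (class is the dominant
    error factor).  Returns ``None`` if neither is available.
    """
    for p in profiles:
        if p.marker_id == marker.marker_id:
            return p
    summary = summarize_by_class(profiles, markers) if profiles else pd.DataFrame()
    if len(summary) and (summary["mutation_class"] == marker.mutation_class).any():
        row = summary.loc[summary["mutation_class"] == marker.mutation_class].iloc[0]
        class_profiles = [
            p
            for p in profiles
            if {m.marker_id: m for m in markers}[p.marker_id].mutation_class
            == marker.mutation_class
        ]
        sd = statistics.median(p.sd_fp_pct for p in class_profiles)
        n = min(p.n_controls for p in class_profiles)
        return ErrorProfile(marker.marker_id, n, float(row["median_fp_pct"]), sd, k)
    return None


PROFILE_COLUMNS = ["marker_id", "n", "mean_fp_pct", "sd_fp_pct", "k", "lod_pct"]


def write_profiles_table(profiles: Sequence[ErrorProfile], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "marker_id": [p.marker_id for p in profiles],
            "n": [p.n_controls for p in profiles],
            "mean_fp_pct": [p.mean_fp_pct for p in profiles],
            "sd_fp_pct": [p.sd_fp_pct for p in profiles],
            "k": [p.k for p in profiles],
            "lod_pct": [p.lod_pct for p in profiles],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.7g")


def read_profiles_table(path: str | Path) -> list[ErrorProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile table {path}: missing columns {missing}")
    return [
        ErrorProfile(str(r.marker_id), int(r.n), float(r.mean_fp_pct), float(r.sd_fp_pct), float(r.k))
        for r in df.itertuples(index=False)
    ]
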