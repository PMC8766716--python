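"""Seeded simulation of template-limited deep amplicon sequencing.

The generative model mirrors the physical stages of a tumor-informed
liquid-biopsy assay:

1. *Template sampling* — the mutant molecules among the haploid genome
   copies pipetted into a PCR follow a binomial draw at the true VAF.
   With few nanograms of cfDNA this step, not sequencing depth, dominates
   detection: at 0.01% VAF and 5 ng input (1,666 copies) the chance that
   even one mutant molecule is present is only ~15%.
2. *Amplification* — proportional, with an optional per-template Bernoulli
   dropout capturing all-or-nothing amplification of low-copy templates.
3. *Sequencing* — reads are drawn binomially at ~150,000x coverage with a
   per-read substitution error that depends on mutation class (transitions
   ~1.6e-5, transversions ~3e-6 per read, matching the class medians
   observed in wild-type control cfDNA).

All randomness flows through a single ``numpy.random.Generator`` so runs
are reproducible from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ctdnakit.core_model import MarkerSpec, ReadCounts

__all__ = [
    "SimConfig",
    "ReadCounts",
    "LibraryFailure",
    "sample_templates",
    "sequence_reads",
    "simulate_control_cohort",
    "simulate_dilution_series",
    "simulate_patient_series",
    "write_counts_table",
    "read_counts_table",
]

#: per-read substitution error by mutation class (fractions, not percent);
#: class medians measured in wild-type control cfDNA: transitions 0.0016%,
#: transversions 0.0003%, indels ~0
DEFAULT_ERROR_RATES = {"transition": 1.6e-5, "transversion": 3e-6, "indel": 0.0}


class LibraryFailure(RuntimeError):
    """No amplifiable template survived — the library cannot be sequenced.

    Distinct from a clean zero-alt result: with zero templates there is
    nothing to sequence and a wild-type call would be unfounded.
    """


@dataclass
class SimConfig:
    """Parameters of one simulated sequencing experiment.

    Attributes
    ----------
    seed : int
        RNG seed; identical configs give bit-identical outputs.
    coverage_target : int
        Reads per target; actual coverage is drawn uniformly within
        +/-20% to mimic run-to-run depth variation.
    error_rate_by_class : dict
        Per-read substitution probability for each mutation class.
    input_mass_ng : float
        cfDNA mass per PCR reaction (sets the template copy number).
    replicates : int
        PCR replicates per sample.
    dropout : float
        Per-template amplification success probability; 1.0 disables
        dropout.
    """

    seed: int = 0
    coverage_target: int = 150_000
    error_rate_by_class: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ERROR_RATES)
    )
    input_mass_ng: float = 20.0
    replicates: int = 1
    dropout: float = 1.0

    def __post_init__(self) -> None:
        if self.coverage_target < 1:
            raise ValueError("coverage_target must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be a probability in [0, 1]")
        for cls_name, rate in self.error_rate_by_class.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"error rate for {cls_name!r} must be in [0, 1]")
        if self.input_mass_ng < 0:
            raise ValueError("input_mass_ng must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def error_rate_for(self, marker: MarkerSpec) -> float:
        cls_name = marker.mutation_class
        if cls_name in ("insertion", "deletion", "delins"):
            cls_name = "indel"
        try:
            return self.error_rate_by_class[cls_name]
        except KeyError:
            raise KeyError(f"no error rate configured for class {cls_name!r}") from None

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def sample_templates(
    copies: int, true_vaf_pct: float, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw the mutant/wild-type split of the templates entering one PCR.

    Binomial sampling with replacement approximates aliquoting from a
    plasma extract whose molecule count vastly exceeds the aliquot.
    Returns ``(mutant_copies, wt_copies)``; they always sum to ``copies``.
    """
    if copies < 0:
        raise ValueError("copies must be non-negative")
    if not 0.0 <= true_vaf_pct <= 100.0:
        raise ValueError("true_vaf_pct must be in [0, 100]")
    mutant = int(rng.binomial(copies, true_vaf_pct / 100.0)) if copies else 0
    return mutant, copies - mutant


def _thin(n: int, p: float, rng: np.random.Generator) -> int:
    return int(rng.binomial(n, p)) if (n and p < 1.0) else n


def sequence_reads(
    mutant_copies: int,
    wt_copies: int,
    marker: MarkerSpec,
    cfg: SimConfig,
    rng: np.random.Generator,
    replicate_index: int | str = 0,
) -> ReadCounts:
    """Sequence one amplicon library built from the given template molecules.

    Dropout (if configured) thins mutant and wild-type templates
    independently before amplification; the surviving alt fraction then
    sets the per-read alt probability, symmetrically contaminated by the
    class substitution error ``e``:

        p_alt = f*(1 - e) + (1 - f)*e

    Coverage is uniform in ``[0.8, 1.2] * coverage_target``.

    Raises
    ------
    LibraryFailure
        If no template (or no template surviving dropout) is available.
    """
    if mutant_copies < 0 or wt_copies < 0:
        raise ValueError("template counts must be non-negative")
    if mutant_copies + wt_copies < 1:
        raise LibraryFailure(f"{marker.marker_id}: zero input templates")
    mut_surv = _thin(mutant_copies, cfg.dropout, rng)
    wt_surv = _thin(wt_copies, cfg.dropout, rng)
    if mut_surv + wt_surv == 0:
        raise LibraryFailure(
            f"{marker.marker_id}: all {mutant_copies + wt_copies} templates "
            f"dropped out (dropout={cfg.dropout})"
        )
    frac_alt = mut_surv / (mut_surv + wt_surv)
    e = cfg.error_rate_for(marker)
    p_alt = frac_alt * (1.0 - e) + (1.0 - frac_alt) * e
    lo = max(1, int(round(cfg.coverage_target * 0.8)))
    hi = int(round(cfg.coverage_target * 1.2))
    coverage = int(rng.integers(lo, hi + 1))
    alt = int(rng.binomial(coverage, p_alt))
    return ReadCounts(marker.marker_id, replicate_index, alt, coverage)


def simulate_sample(
    true_vaf_pct: float,
    marker: MarkerSpec,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[ReadCounts]:
    """Simulate all PCR replicates of one plasma sample.

    Each replicate independently draws its own templates from
    ``cfg.input_mass_ng`` worth of cfDNA.  Replicates whose library fails
    are returned as zero-coverage placeholders only when *all* fail;
    otherwise failed replicates are dropped (a failed PCR yields no reads
    to pool).
    """
    from ctdnakit.core_model import mass_to_copies

    copies = mass_to_copies(cfg.input_mass_ng)
    out: list[ReadCounts] = []
    failures = 0
    for r in range(cfg.replicates):
        mut, wt = sample_templates(copies, true_vaf_pct, rng)
        try:
            out.append(sequence_reads(mut, wt, marker, cfg, rng, replicate_index=r))
        except LibraryFailure:
            failures += 1
    if not out:
        raise LibraryFailure(
            f"{marker.marker_id}: all {cfg.replicates} replicate libraries failed"
        )
    return out


def simulate_control_cohort(
    n_controls: int,
    marker: MarkerSpec,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[ReadCounts]:
    """Simulate wild-type control cfDNA samples for background-error estimation.

    Each control is a healthy-donor sample with true VAF 0; any alt reads
    are pure substitution error.  At least two controls are required so a
    sample standard deviation exists downstream.
    """
    if n_controls < 2:
        raise ValueError("need >= 2 controls for a standard deviation")
    rng = cfg.rng() if rng is None else rng
    from ctdnakit.core_model import mass_to_copies

    copies = max(1, mass_to_copies(cfg.input_mass_ng))
    return [
        sequence_reads(0, copies, marker, cfg, rng, replicate_index=i)
        for i in range(n_controls)
    ]


#: fine-grained molecule pool used when template sampling is switched off;
#: large enough to represent the default 45 -> 0.0045% series exactly
_UNLIMITED_POOL = 10_000_000


def simulate_dilution_series(
    marker: MarkerSpec,
    cfg: SimConfig,
    start_vaf_pct: float = 45.0,
    fold: float = 10.0,
    levels: int = 5,
    template_limited: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> list[tuple[float, ReadCounts]]:
    """Serially dilute mutant cfDNA in wild-type cfDNA and sequence each level.

    The default series (45% diluted 10-fold over 5 levels) spans
    45 -> 0.0045%, the range over which assay linearity is assessed.
    Returns ``[(expected_vaf_pct, counts), ...]`` in dilution order.

    With ``template_limited`` (the default) each level binomially samples
    its mutant templates from ``cfg.input_mass_ng`` worth of cfDNA; at
    30 ng the lowest level expects under one mutant molecule, so
    single-replicate quantification there is all-or-nothing.  Setting it
    False idealizes the template pool as effectively infinite, isolating
    read-level binomial noise — the regime in which log-log linearity of
    the response can be assessed independently of molecule sampling.
    """
    if not 0 < start_vaf_pct <= 100:
        raise ValueError("start_vaf_pct must be in (0, 100]")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    rng = cfg.rng() if rng is None else rng
    from ctdnakit.core_model import mass_to_copies

    copies = max(1, mass_to_copies(cfg.input_mass_ng))
    series = []
    for k in range(levels):
        expected = start_vaf_pct / fold**k
        if template_limited:
            mut, wt = sample_templates(copies, expected, rng)
        else:
            mut = round(expected / 100.0 * _UNLIMITED_POOL)
            wt = _UNLIMITED_POOL - mut
        series.append((expected, sequence_reads(mut, wt, marker, cfg, rng, replicate_index=k)))
    return series


def true_vaf_trajectory(
    days: Sequence[int],
    relapse_day: int,
    daily_rate_pct: float,
    clearance_until_day: int = 30,
) -> list[float]:
    """Ground-truth VAF at each sampling day.

    ctDNA is cleared (VAF 0) through ``clearance_until_day`` after tumor
    resection, then accumulates linearly at ``daily_rate_pct`` per day
    toward (and past) the imaging relapse day.
    """
    return [
        max(0.0, daily_rate_pct * (d - clearance_until_day)) if d >= clearance_until_day else 0.0
        for d in days
    ]


def simulate_patient_series(
    marker: MarkerSpec,
    relapse_day: int,
    daily_rate_pct: float,
    sampling_days: Sequence[int],
    cfg: SimConfig,
    clearance_until_day: int = 30,
    rng: Optional[np.random.Generator] = None,
    patient_id: str = "SIM",
):
    """Simulate a longitudinal monitoring series for one relapsing patient.

    Clinically, ctDNA falls below detection within the first month after
    resection and then re-accumulates at 0.003-0.012% VAF per day ahead of
    imaging-detectable relapse; ``daily_rate_pct`` picks the rate,
    ``relapse_day`` the imaging date.  Returns a
    :class:`~ctdnakit.clinical_monitoring.PatientSeries` whose samples
    hold per-replicate read counts for each sampling day.
    """
    from ctdnakit.clinical_monitoring import LongitudinalSample, PatientSeries

    if daily_rate_pct < 0:
        raise ValueError("daily_rate_pct must be non-negative")
    days = list(sampling_days)
    if days != sorted(days) or len(set(days)) != len(days):
        raise ValueError("sampling_days must be strictly increasing")
    rng = cfg.rng() if rng is None else rng
    truths = true_vaf_trajectory(days, relapse_day, daily_rate_pct, clearance_until_day)
    samples = []
    for day, vaf in zip(days, truths):
        counts = simulate_sample(min(vaf, 100.0), marker, cfg, rng)
        samples.append(LongitudinalSample(day=day, counts={marker.marker_id: counts}))
    return PatientSeries(
        patient_id=patient_id,
        markers=[marker],
        samples=samples,
        imaging_relapse_day=relapse_day,
    )


COUNTS_COLUMNS = ["sample_id", "marker_id", "replicate", "alt_reads", "total_reads"]


def write_counts_table(
    records: Sequence[tuple[str, ReadCounts]], path: str | Path
) -> None:
    """Write ``(sample_id, counts)`` records to a tab-delimited table."""
    df = pd.DataFrame(
        {
            "sample_id": [s for s, _ in records],
            "marker_id": [c.marker_id for _, c in records],
            "replicate": [c.replicate_index for _, c in records],
            "alt_reads": [c.alt_reads for _, c in records],
            "total_reads": [c.total_reads for _, c in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_counts_table(path: str | Path) -> list[tuple[str, ReadCounts]]:
    """Read a counts table written by :func:`write_counts_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "marker_id": str})
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts table {path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        rep = row.replicate
        rep = rep if isinstance(rep, str) else int(rep)
        out.append(
            (str(row.sample_id), ReadCounts(str(row.marker_id), rep, int(row.alt_reads), int(row.total_reads)))
        )
    return out
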