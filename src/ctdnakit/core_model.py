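"""Domain types, HGVS substitution parsing, and template-copy arithmetic.

The number of analyzable template molecules in a PCR is set by the mass of
cell-free DNA added: at ~3 pg per haploid human genome, 25 ng of cfDNA
corresponds to 8,333 haploid genome copies, so a single mutant molecule
represents a VAF of 100/8333 ~= 0.012%.  These arithmetic identities define
the theoretical floor of any template-limited assay and are used throughout
the simulation and power modules.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
NUCLEOTIDES = frozenset("ACGT")

#: mass of one haploid human genome copy, in picograms
PG_PER_HAPLOID_COPY = 3.0

MUTATION_CLASSES = ("transition", "transversion", "insertion", "deletion", "delins")


class HgvsFormatError(ValueError):
    """Raised when a coding-DNA HGVS string cannot be parsed."""


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """Classify a single-nucleotide substitution as transition or transversion.

    Transitions (purine<->purine, pyrimidine<->pyrimidine) show roughly
    5-fold higher sequencing background error than transversions, so the
    class matters when choosing ctDNA markers.
    """
    if ref_base not in NUCLEOTIDES or alt_base not in NUCLEOTIDES:
        raise ValueError(f"bases must be one of A,C,G,T: got {ref_base!r}>{alt_base!r}")
    if ref_base == alt_base:
        raise ValueError(f"ref and alt are identical: {ref_base!r}")
    same_chemistry = ({ref_base, alt_base} <= PURINES) or ({ref_base, alt_base} <= PYRIMIDINES)
    return "transition" if same_chemistry else "transversion"


# substitutions like "c.35G>A" or "c.35G > A" (whitespace around '>' tolerated)
_SUB_RE = re.compile(r"^c\.(\d+)\s*([ACGT])\s*>\s*([ACGT])$")
# non-substitution kinds we recognise but do not decompose
_NONSUB_RE = re.compile(r"^c\.[\d_+*-]+(?:\s*)(delins|del|dup|ins)", re.IGNORECASE)


def parse_hgvs_c(hgvs: str) -> tuple[int, Optional[str], Optional[str], str]:
    """Parse a coding-DNA HGVS change into ``(position, ref, alt, kind)``.

    Supports simple substitutions (``c.35G>A``, with or without spaces
    around ``>``) and flags insertion/deletion/delins/dup variants by kind
    with ``ref``/``alt`` set to ``None``.  Duplications are treated as
    insertions.

    Raises
    ------
    HgvsFormatError
        If the string is empty, lacks the ``c.`` prefix, or matches no
        recognised pattern.
    """
    if not hgvs or not hgvs.strip():
        raise HgvsFormatError("empty HGVS string")
    text = hgvs.strip()
    if not text.startswith("c."):
        raise HgvsFormatError(f"HGVS coding change must start with 'c.': {text!r}")
    m = _SUB_RE.match(text)
    if m:
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
        if ref == alt:
            raise HgvsFormatError(f"substitution with identical ref and alt: {text!r}")
        return pos, ref, alt, "substitution"
    m = _NONSUB_RE.match(text)
    if m:
        kind = {"del": "deletion", "ins": "insertion", "dup": "insertion", "delins": "delins"}[
            m.group(1).lower()
        ]
        first_pos = re.search(r"\d+", text)
        return int(first_pos.group()), None, None, kind
    raise HgvsFormatError(f"unparseable HGVS coding change: {text!r}")


@dataclass(frozen=True)
class MarkerSpec:
    """One tumor-informed mutation tracked in plasma.

    ``mutation_class`` is derived from ref/alt for substitutions when not
    given explicitly.
    """

    marker_id: str
    gene: str
    hgvs_c: str
    hgvs_p: Optional[str] = None
    ref_base: str = ""
    alt_base: str = ""
    mutation_class: str = field(default="")

    def __post_init__(self) -> None:
        if self.ref_base and self.alt_base:
            if self.ref_base not in NUCLEOTIDES or self.alt_base not in NUCLEOTIDES:
                raise ValueError(f"{self.marker_id}: SNV bases must be in ACGT")
            if self.ref_base == self.alt_base:
                raise ValueError(f"{self.marker_id}: ref and alt are identical")
            derived = classify_substitution(self.ref_base, self.alt_base)
            if not self.mutation_class:
                object.__setattr__(self, "mutation_class", derived)
            elif self.mutation_class != derived:
                raise ValueError(
                    f"{self.marker_id}: mutation_class {self.mutation_class!r} "
                    f"inconsistent with {self.ref_base}>{self.alt_base} ({derived})"
                )
        elif not self.mutation_class:
            raise ValueError(f"{self.marker_id}: mutation_class required for non-SNV markers")
        if self.mutation_class not in MUTATION_CLASSES:
            raise ValueError(f"{self.marker_id}: unknown mutation_class {self.mutation_class!r}")

    @classmethod
    def from_hgvs(
        cls,
        marker_id: str,
        gene: str,
        hgvs_c: str,
        hgvs_p: Optional[str] = None,
    ) -> "MarkerSpec":
        """Build a marker by parsing its coding-DNA HGVS string."""
        _, ref, alt, kind = parse_hgvs_c(hgvs_c)
        if kind == "substitution":
            return cls(marker_id, gene, hgvs_c, hgvs_p, ref_base=ref, alt_base=alt)
        return cls(marker_id, gene, hgvs_c, hgvs_p, mutation_class=kind)


@dataclass(frozen=True)
class ReadCounts:
    """Alt/total read tallies for one marker in one PCR replicate.

    ``replicate_index`` of ``"pooled"`` marks counts summed across
    replicate PCRs.
    """

    marker_id: str
    replicate_index: int | str
    alt_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.alt_reads < 0 or self.total_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_reads > self.total_reads:
            raise ValueError(
                f"{self.marker_id}: alt_reads {self.alt_reads} exceeds total {self.total_reads}"
            )


def mass_to_copies(mass_ng: float, pg_per_copy: float = PG_PER_HAPLOID_COPY) -> int:
    """Number of haploid genome copies in ``mass_ng`` nanograms of cfDNA.

    Floors to an integer: a fractional template molecule cannot be
    amplified.  25 ng at 3 pg/copy gives 8,333 copies.
    """
    if mass_ng < 0:
        raise ValueError(f"mass must be non-negative, got {mass_ng}")
    if pg_per_copy <= 0:
        raise ValueError(f"pg_per_copy must be positive, got {pg_per_copy}")
    return math.floor(mass_ng * 1000.0 / pg_per_copy)


def theoretical_quantification_limit(copies: int) -> float:
    """VAF (percent) at which exactly one template copy is mutant.

    8,333 copies -> 0.012%; 100,000 copies -> 0.001%.
    """
    if copies < 1:
        raise ValueError(f"need at least one template copy, got {copies}")
    return 100.0 / copies


def required_mass_for_limit(limit_pct: float, pg_per_copy: float = PG_PER_HAPLOID_COPY) -> float:
    """cfDNA mass (ng) needed so one mutant copy corresponds to ``limit_pct``.

    Inverse of ``theoretical_quantification_limit(mass_to_copies(m))``:
    a 0.001% limit requires ~300 ng at 3 pg/copy.
    """
    if not 0 < limit_pct <= 100:
        raise ValueError(f"limit must be in (0, 100] percent, got {limit_pct}")
    return (100.0 / limit_pct) * pg_per_copy / 1000.0


@dataclass(frozen=True)
class TemplateBudget:
    """Template molecules available to one PCR from a plasma draw."""

    input_mass_ng: float
    plasma_volume_ml: Optional[float] = None
    cfdna_conc_ng_per_ml: Optional[float] = None
    pg_per_haploid_copy: float = PG_PER_HAPLOID_COPY

    def __post_init__(self) -> None:
        if self.input_mass_ng < 0:
            raise ValueError("input_mass_ng must be non-negative")
        if self.pg_per_haploid_copy <= 0:
            raise ValueError("pg_per_haploid_copy must be positive")

    @property
    def copies(self) -> int:
        return mass_to_copies(self.input_mass_ng, self.pg_per_haploid_copy)

    @classmethod
    def from_plasma(
        cls,
        plasma_volume_ml: float,
        cfdna_conc_ng_per_ml: float,
        pg_per_haploid_copy: float = PG_PER_HAPLOID_COPY,
    ) -> "TemplateBudget":
        """Budget when the whole extract of a plasma draw goes into one PCR."""
        return cls(
            input_mass_ng=plasma_volume_ml * cfdna_conc_ng_per_ml,
            plasma_volume_ml=plasma_volume_ml,
            cfdna_conc_ng_per_ml=cfdna_conc_ng_per_ml,
            pg_per_haploid_copy=pg_per_haploid_copy,
        )


PANEL_COLUMNS = ["marker_id", "gene", "hgvs_c", "hgvs_p", "ref", "alt"]


def read_marker_panel(path: str | Path) -> list[MarkerSpec]:
    """Read a tumor-informed marker panel from a tab-delimited file.

    Expects the header ``marker_id  gene  hgvs_c  hgvs_p  ref  alt``;
    ``hgvs_p``, ``ref`` and ``alt`` may be empty.  Marker ids must be
    unique within the panel.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"marker panel {path}: missing columns {missing}")
    if df["marker_id"].duplicated().any():
        dups = sorted(df.loc[df["marker_id"].duplicated(), "marker_id"])
        raise ValueError(f"marker panel {path}: duplicate marker_id {dups}")
    markers = []
    for row in df.itertuples(index=False):
        if row.ref and row.alt:
            markers.append(
                MarkerSpec(
                    row.marker_id, row.gene, row.hgvs_c, row.hgvs_p or None,
                    ref_base=row.ref, alt_base=row.alt,
                )
            )
        else:
            markers.append(MarkerSpec.from_hgvs(row.marker_id, row.gene, row.hgvs_c, row.hgvs_p or None))
    return markers


def write_marker_panel(markers: list[MarkerSpec], path: str | Path) -> None:
    """Write a marker panel in the same tab-delimited schema read_marker_panel expects."""
    df = pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in markers],
            "gene": [m.gene for m in markers],
            "hgvs_c": [m.hgvs_c for m in markers],
            "hgvs_p": [m.hgvs_p or "" for m in markers],
            "ref": [m.ref_base for m in markers],
            "alt": [m.alt_base for m in markers],
        }
    )
    df.to_csv(path, sep="\t", index=False)
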