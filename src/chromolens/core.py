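"""Canonical in-memory data model for chromosome-centered lesion analysis.

Conventions
-----------
All interval coordinates held in memory are 0-based, half-open ``[start, end)``.
Per-base depth files and variant positions are 1-based on disk (the convention
of ``samtools depth`` output and of c./HGVS-style coordinates) and are converted
at the I/O boundary only.  Chromosome names are matched as literal strings; no
``chr`` prefix normalization is attempted.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np


class ChromolensError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ChromolensError):
    """An input value violates a documented contract."""


class StageFailure(ChromolensError):
    """A pipeline stage failed after config validation succeeded."""


class ParseError(ValidationError):
    """A file could not be parsed; carries the offending path and line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class LesionKind(str, enum.Enum):
    """Somatic lesion categories detectable by SNP-array segmentation."""

    DEL = "DEL"
    GAIN = "GAIN"
    UPD = "UPD"


class DiseasePhase(str, enum.Enum):
    """Coarse disease-phase grouping used by the association analyses.

    Patients showing myelofibrosis or an accelerated phase but not full
    leukemic transformation (<20% blasts) are grouped as chronic for the
    progression contrast; see :mod:`chromolens.presets`.
    """

    CHRONIC = "chronic"
    PROGRESSED_NON_AML = "progressed_non_AML"
    AML = "AML"


@dataclass(frozen=True)
class AberrationSegment:
    """One somatic lesion interval (deletion, gain or UPD) in one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    kind: LesionKind

    def __post_init__(self):
        object.__setattr__(self, "kind", LesionKind(self.kind))
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"segment requires 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass(frozen=True)
class CohortSample:
    """A sample record linking sample -> patient -> diagnosis/phase."""

    sample_id: str
    patient_id: str
    diagnosis: str
    phase: DiseasePhase | None = None


@dataclass
class CoverageTrack:
    """Per-base sequencing depth (raw counts or normalized fractions).

    Positions are 1-based as in depth files and strictly increasing; the
    representation is sparse — uncovered positions are absent, never
    zero-filled.
    """

    chrom: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise ValidationError("positions and values must be 1-D and equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValidationError("positions must be strictly increasing")
        if np.any(self.values < 0):
            raise ValidationError("depth values must be nonnegative")

    def __len__(self) -> int:
        return int(self.positions.size)

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class GeneModel:
    """A gene span with its coding sequence as ordered exonic sub-intervals."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_blocks: tuple = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        blocks = tuple((int(s), int(e)) for s, e in self.cds_blocks)
        for s, e in blocks:
            if not (self.start <= s < e <= self.end):
                raise ValidationError(
                    f"gene {self.gene_id}: CDS block [{s}, {e}) outside span "
                    f"[{self.start}, {self.end})"
                )
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"gene {self.gene_id}: overlapping CDS blocks "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        object.__setattr__(self, "cds_blocks", blocks)
        if blocks and self.cds_length % 3 != 0:
            warnings.warn(
                f"gene {self.gene_id}: CDS length {self.cds_length} is not a "
                "multiple of 3",
                stacklevel=2,
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_blocks)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass(frozen=True)
class VariantObservation:
    """A single-nucleotide variant with supporting read counts."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ref_reads: int
    alt_reads: int

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValidationError("ref and alt alleles must differ")
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValidationError("read counts must be nonnegative")

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def vaf(self) -> float:
        if self.depth == 0:
            raise ValidationError("VAF undefined at zero depth")
        return self.alt_reads / self.depth
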