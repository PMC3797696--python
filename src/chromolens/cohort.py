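"""Cohort-level summarization and lesion-phenotype association.

Counting can be done per sample (the default denominator) or per patient;
patients sampled at two disease stages contribute one unit in patient mode.
Recurrent lesions seen in two samples of the same patient are collapsed
before tallying so an event is never counted twice.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable

import pandas as pd

from .core import AberrationSegment, CohortSample, LesionKind, ValidationError
from .stats import ContingencyTable2x2, FisherResult, fisher_exact

Predicate = Callable[[AberrationSegment], bool]


def kind_is(kind) -> Predicate:
    """Predicate: segment is of the given lesion kind."""
    kind = LesionKind(kind)
    return lambda seg: seg.kind == kind


def overlaps_region(chrom: str, start: int, end: int) -> Predicate:
    """Predicate: segment overlaps [start, end) on chrom by >= 1 bp."""
    return lambda seg: seg.overlaps(chrom, start, end)


def _sample_index(samples: Iterable[CohortSample]) -> dict[str, CohortSample]:
    index: dict[str, CohortSample] = {}
    for s in samples:
        if s.sample_id in index:
            raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
        index[s.sample_id] = s
    return index


def _resolve(segments, index):
    for seg in segments:
        if seg.sample_id not in index:
            raise ValidationError(
                f"segment sample {seg.sample_id!r} not in the sample sheet"
            )


def _reciprocal_overlap(s1: AberrationSegment, s2: AberrationSegment) -> float:
    inter = min(s1.end, s2.end) - max(s1.start, s2.start)
    if inter <= 0:
        return 0.0
    return min(inter / s1.length, inter / s2.length)


def dedupe_recurrent(
    segments: list[AberrationSegment],
    samples: list[CohortSample],
    reciprocal_overlap: float = 0.9,
) -> list[AberrationSegment]:
    """Collapse recurrent same-patient lesions to a single representative.

    Segments of identical kind observed in different samples of the same
    patient are merged when their reciprocal overlap reaches the threshold;
    the coordinates of the earliest sample (sample-sheet order) are kept.
    Segments from distinct patients are never merged.
    """
    index = _sample_index(samples)
    _resolve(segments, index)
    order = {s.sample_id: i for i, s in enumerate(samples)}

    groups: dict[tuple, list[AberrationSegment]] = defaultdict(list)
    for seg in segments:
        key = (index[seg.sample_id].patient_id, seg.chrom, seg.kind)
        groups[key].append(seg)

    kept: list[AberrationSegment] = []
    for key, group in groups.items():
        group.sort(key=lambda s: (order[s.sample_id], s.start, s.end))
        representatives: list[AberrationSegment] = []
        for seg in group:
            dup = any(
                rep.sample_id != seg.sample_id
                and _reciprocal_overlap(rep, seg) >= reciprocal_overlap
                for rep in representatives
            )
            if not dup:
                representatives.append(seg)
        kept.extend(representatives)
    kept.sort(key=lambda s: (order[s.sample_id], s.chrom, s.start, s.end, s.kind.value))
    return kept


@dataclass
class CohortSummary:
    """Per-diagnosis lesion counts with totals and overall frequency."""

    rows: list[tuple]  # (diagnosis, n_units, n_units_with_lesion)
    unit: str

    @property
    def total(self) -> int:
        return sum(r[1] for r in self.rows)

    @property
    def total_with_lesion(self) -> int:
        return sum(r[2] for r in self.rows)

    @property
    def frequency_pct(self) -> float:
        """Overall lesion frequency, percent, one decimal."""
        if self.total == 0:
            return 0.0
        return round(100.0 * self.total_with_lesion / self.total, 1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=["diagnosis", "n", "n_with_lesion"])
        totals = pd.DataFrame(
            [{"diagnosis": "total", "n": self.total, "n_with_lesion": self.total_with_lesion}]
        )
        return pd.concat([df, totals], ignore_index=True)


def summarize_cohort(
    segments: list[AberrationSegment],
    samples: list[CohortSample],
    unit: str = "sample",
) -> CohortSummary:
    """Per-diagnosis lesion counts.

    ``unit='sample'`` counts samples; ``unit='patient'`` counts distinct
    patients, assigning each patient to the diagnosis of its first sample in
    sheet order and counting a patient as lesion-bearing if any of its
    samples carries a segment.
    """
    if unit not in ("sample", "patient"):
        raise ValidationError(f"unit must be 'sample' or 'patient', got {unit!r}")
    index = _sample_index(samples)
    _resolve(segments, index)
    with_lesion = {seg.sample_id for seg in segments}

    diagnoses: list[str] = []
    if unit == "sample":
        n: dict[str, int] = defaultdict(int)
        n_les: dict[str, int] = defaultdict(int)
        for s in samples:
            if s.diagnosis not in n:
                diagnoses.append(s.diagnosis)
            n[s.diagnosis] += 1
            if s.sample_id in with_lesion:
                n_les[s.diagnosis] += 1
    else:
        patient_dx: dict[str, str] = {}
        patient_les: dict[str, bool] = {}
        for s in samples:
            patient_dx.setdefault(s.patient_id, s.diagnosis)
            patient_les[s.patient_id] = patient_les.get(s.patient_id, False) or (
                s.sample_id in with_lesion
            )
        n = defaultdict(int)
        n_les = defaultdict(int)
        for pid, dx in patient_dx.items():
            if dx not in n:
                diagnoses.append(dx)
            n[dx] += 1
            if patient_les[pid]:
                n_les[dx] += 1
    rows = [(dx, n[dx], n_les[dx]) for dx in diagnoses]
    return CohortSummary(rows=rows, unit=unit)


def associate_lesions(
    segments: list[AberrationSegment],
    samples: list[CohortSample],
    group_a: Iterable[str],
    group_b: Iterable[str],
    predicate: Predicate | None = None,
    unit: str = "sample",
) -> FisherResult:
    """Exact test of lesion status (under ``predicate``) between two
    diagnosis groups.

    Builds the 2x2 table (rows = group a / group b, columns = with / without
    a qualifying lesion) and returns the Fisher result with the table
    attached for audit.
    """
    group_a, group_b = frozenset(group_a), frozenset(group_b)
    if group_a & group_b:
        raise ValidationError(f"groups overlap: {sorted(group_a & group_b)}")
    index = _sample_index(samples)
    _resolve(segments, index)
    predicate = predicate or (lambda seg: True)

    qualifying = {seg.sample_id for seg in segments if predicate(seg)}

    def units(group):
        members = [s for s in samples if s.diagnosis in group]
        if not members:
            raise ValidationError(f"group {sorted(group)} has no members")
        if unit == "sample":
            return [(s.sample_id, s.sample_id in qualifying) for s in members]
        by_patient: dict[str, bool] = {}
        for s in members:
            by_patient[s.patient_id] = by_patient.get(s.patient_id, False) or (
                s.sample_id in qualifying
            )
        return list(by_patient.items())

    ua, ub = units(group_a), units(group_b)
    a = sum(flag for _, flag in ua)
    c = sum(flag for _, flag in ub)
    table = ContingencyTable2x2(a, len(ua) - a, c, len(ub) - c)
    return fisher_exact(table)


@dataclass(frozen=True)
class AberrationTally:
    n_deletions: int
    n_gains: int
    n_upds: int
    n_excluded_complex: int

    @property
    def total(self) -> int:
        return self.n_deletions + self.n_gains + self.n_upds


def tally_aberrations(
    segments: list[AberrationSegment],
    samples: list[CohortSample] | None = None,
    exclude: Iterable[str] = (),
) -> AberrationTally:
    """Count deduplicated segments by kind, excluding listed samples.

    ``n_excluded_complex`` reports how many excluded samples actually
    carried segments (e.g. one sample with a complex rearrangement whose
    event count is not well defined).
    """
    if samples is not None:
        _resolve(segments, _sample_index(samples))
    exclude = frozenset(exclude)
    counts = {LesionKind.DEL: 0, LesionKind.GAIN: 0, LesionKind.UPD: 0}
    excluded_with_segments: set[str] = set()
    for seg in segments:
        if seg.sample_id in exclude:
            excluded_with_segments.add(seg.sample_id)
            continue
        counts[seg.kind] += 1
    return AberrationTally(
        n_deletions=counts[LesionKind.DEL],
        n_gains=counts[LesionKind.GAIN],
        n_upds=counts[LesionKind.UPD],
        n_excluded_complex=len(excluded_with_segments),
    )
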