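"""Common-aberrant-region detection by event-point sweep.

A support profile counts, between consecutive segment breakpoints, how many
distinct samples carry a lesion of the chosen kind covering that interval.
A common deleted (or gained/UPD) region is a maximal run of locally maximal
support: extending either boundary past the run strictly decreases support.
Samples are de-overlapped first, so a sample with two overlapping segments
contributes at most one per base — regions count patients' samples, not raw
segments.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .core import AberrationSegment, GeneModel, LesionKind, ValidationError


@dataclass
class SupportProfile:
    """Piecewise-constant per-sample coverage counts between breakpoints.

    ``support[i]`` holds the count on ``[breakpoints[i], breakpoints[i+1])``;
    ``interval_samples[i]`` the identities of the covering samples.
    """

    chrom: str
    breakpoints: np.ndarray
    support: np.ndarray
    interval_samples: list[frozenset] = field(default_factory=list)

    def support_at(self, pos: int) -> int:
        """Support at a single base (0 outside all segments)."""
        i = int(np.searchsorted(self.breakpoints, pos, side="right")) - 1
        if i < 0 or i >= len(self.support):
            return 0
        return int(self.support[i])


@dataclass
class CDRRegion:
    chrom: str
    start: int
    end: int
    support: int
    member_samples: frozenset
    genes: tuple = ()


def _merge_intervals(intervals):
    """Union of (start, end) intervals, returned sorted and disjoint."""
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_support_profile(
    segments: list[AberrationSegment],
    kind: LesionKind | str,
    samples=None,
) -> SupportProfile:
    """Sweep-line support profile for segments of one kind on one chromosome."""
    kind = LesionKind(kind)
    segs = [s for s in segments if s.kind == kind]
    chroms = {s.chrom for s in segs}
    if len(chroms) > 1:
        raise ValidationError(f"segments span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop() if chroms else ""
    if not segs:
        return SupportProfile(chrom, np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))

    per_sample: dict[str, list] = defaultdict(list)
    for s in segs:
        per_sample[s.sample_id].append((s.start, s.end))
    merged = {sid: _merge_intervals(iv) for sid, iv in per_sample.items()}

    breakpoints = np.array(
        sorted({b for iv in merged.values() for s, e in iv for b in (s, e)}),
        dtype=np.int64,
    )
    n = len(breakpoints) - 1
    support = np.zeros(n, dtype=np.int64)
    interval_samples = [set() for _ in range(n)]
    for sid, intervals in merged.items():
        for s, e in intervals:
            i0 = int(np.searchsorted(breakpoints, s))
            i1 = int(np.searchsorted(breakpoints, e))
            support[i0:i1] += 1
            for i in range(i0, i1):
                interval_samples[i].add(sid)
    return SupportProfile(
        chrom, breakpoints, support, [frozenset(s) for s in interval_samples]
    )


def find_cdrs(profile: SupportProfile, min_support: int = 2) -> list[CDRRegion]:
    """Maximal locally-maximal-support regions with support >= min_support.

    Adjacent elementary intervals with equal support are merged into runs; a
    run is reported when its support strictly exceeds both neighbouring runs
    (chromosome ends count as support 0) and reaches ``min_support``.
    """
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")
    if len(profile.support) == 0:
        return []

    runs = []  # (start_idx, end_idx_exclusive, support)
    start = 0
    for i in range(1, len(profile.support) + 1):
        if i == len(profile.support) or profile.support[i] != profile.support[start]:
            runs.append((start, i, int(profile.support[start])))
            start = i

    cdrs = []
    for r, (i0, i1, sup) in enumerate(runs):
        if sup < min_support:
            continue
        left = runs[r - 1][2] if r > 0 else 0
        right = runs[r + 1][2] if r + 1 < len(runs) else 0
        # non-adjacent runs (gap in breakpoints) still neighbour support 0
        if sup <= left or sup <= right:
            continue
        members = frozenset().union(
            *(profile.interval_samples[i] for i in range(i0, i1))
        ) if profile.interval_samples else frozenset()
        cdrs.append(
            CDRRegion(
                chrom=profile.chrom,
                start=int(profile.breakpoints[i0]),
                end=int(profile.breakpoints[i1]),
                support=sup,
                member_samples=members,
            )
        )
    return cdrs


def annotate_cdr_genes(
    cdrs: list[CDRRegion], gene_models: list[GeneModel]
) -> list[CDRRegion]:
    """Attach to each region all gene models overlapping it by >= 1 bp,
    in genomic order."""
    annotated = []
    ordered = sorted(gene_models, key=lambda g: (g.chrom, g.start, g.end))
    for cdr in cdrs:
        genes = tuple(
            g.gene_id for g in ordered if g.overlaps(cdr.chrom, cdr.start, cdr.end)
        )
        annotated.append(
            CDRRegion(cdr.chrom, cdr.start, cdr.end, cdr.support, cdr.member_samples, genes)
        )
    return annotated
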