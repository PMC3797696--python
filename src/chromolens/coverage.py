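"""Control-pool log2-ratio focal CNV detection from per-base exome depth.

The method: depth at each base of the analyzed chromosome is normalized by
the summed depth over all covered bases of that chromosome in that sample;
the case track is compared, position by position, to the median of a pool of
normalized control tracks, as log2(case/reference); maximal runs of targeted
positions whose median-smoothed ratio clears a threshold are reported as
focal gains or losses.  Normalization is per single chromosome by design —
the statistic is a within-chromosome relative coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CoverageTrack, ValidationError


@dataclass
class RatioTrack:
    """Per-position log2(case/reference) with a mask for unusable positions."""

    chrom: str
    positions: np.ndarray
    log2_ratio: np.ndarray
    masked: np.ndarray


@dataclass(frozen=True)
class FocalCall:
    chrom: str
    start: int  # 0-based half-open
    end: int
    direction: str  # 'gain' | 'loss'
    mean_log2: float
    n_positions: int
    targets_hit: tuple = ()


def normalize_track(track: CoverageTrack) -> CoverageTrack:
    """Divide each per-base depth by the chromosome-wide summed depth."""
    if len(track) == 0:
        raise ValidationError("cannot normalize an empty coverage track")
    total = track.total
    if total <= 0:
        raise ValidationError("cannot normalize an all-zero coverage track")
    return CoverageTrack(track.chrom, track.positions, track.values / total)


def build_reference(
    controls: list[CoverageTrack], min_controls: int = 3
) -> CoverageTrack:
    """Per-position median of normalized control tracks.

    Only positions present in every control enter the reference; positions
    whose median is 0 are retained and masked downstream.
    """
    if len(controls) < min_controls:
        raise ValidationError(
            f"need at least {min_controls} control tracks, got {len(controls)}"
        )
    chroms = {t.chrom for t in controls}
    if len(chroms) > 1:
        raise ValidationError(f"control tracks mix chromosomes: {sorted(chroms)}")
    shared = controls[0].positions
    for t in controls[1:]:
        shared = np.intersect1d(shared, t.positions, assume_unique=True)
    if shared.size == 0:
        raise ValidationError("control tracks share no positions")
    stack = np.empty((len(controls), shared.size))
    for i, t in enumerate(controls):
        idx = np.searchsorted(t.positions, shared)
        stack[i] = t.values[idx]
    return CoverageTrack(controls[0].chrom, shared, np.median(stack, axis=0))


def log2_ratio_track(
    case: CoverageTrack,
    reference: CoverageTrack,
    pseudocount: float | None = None,
) -> RatioTrack:
    """log2((case + pc) / (reference + pc)) at positions shared by both.

    The default pseudocount is 1/(100 x number of covered case positions).
    A normalized track sums to 1 over its n covered positions, so its mean
    value is 1/n; a pseudocount two orders of magnitude below that leaves
    ratios at typical coverage essentially untouched while keeping
    zero-coverage positions finite.  With pseudocount 0, reference-zero
    positions are masked instead.
    """
    if case.chrom != reference.chrom:
        raise ValidationError(
            f"case chromosome {case.chrom!r} != reference {reference.chrom!r}"
        )
    shared = np.intersect1d(case.positions, reference.positions, assume_unique=True)
    if shared.size == 0:
        raise ValidationError("case and reference share no positions")
    if pseudocount is None:
        pseudocount = 1.0 / (100.0 * len(case))
    cv = case.values[np.searchsorted(case.positions, shared)]
    rv = reference.values[np.searchsorted(reference.positions, shared)]
    masked = (rv + pseudocount) <= 0
    ratio = np.full(shared.size, np.nan)
    ok = ~masked
    ratio[ok] = np.log2((cv[ok] + pseudocount) / (rv[ok] + pseudocount))
    return RatioTrack(case.chrom, shared, ratio, masked)


def _running_median(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or values.size == 0:
        return values.copy()
    window = min(window, values.size)
    return (
        pd.Series(values)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def call_focal_events(
    ratio: RatioTrack,
    targets: list[tuple],
    threshold: float = 0.4,
    min_positions: int = 100,
    merge_gap: int = 50,
    smooth_window: int = 51,
) -> list[FocalCall]:
    """Call focal gains/losses over targeted positions of a ratio track.

    Positions inside the target intervals are median-smoothed
    (``smooth_window`` positions); maximal same-sign runs with
    |smoothed ratio| >= threshold become calls.  Same-sign runs separated by
    at most ``merge_gap`` targeted positions are merged; merged runs covering
    fewer than ``min_positions`` targeted positions are discarded.  Calls
    never extend outside targets and boundaries lie on observed positions.
    """
    chrom_targets = [t for t in targets if t[0] == ratio.chrom]
    if not chrom_targets or ratio.positions.size == 0:
        return []
    starts = np.array([t[1] for t in chrom_targets])
    ends = np.array([t[2] for t in chrom_targets])

    pos0 = ratio.positions - 1  # 0-based base coordinates
    in_target = np.zeros(pos0.size, dtype=bool)
    for s, e in zip(starts, ends):
        in_target |= (pos0 >= s) & (pos0 < e)
    usable = in_target & ~ratio.masked & np.isfinite(ratio.log2_ratio)
    idx = np.flatnonzero(usable)
    if idx.size == 0:
        return []

    pos = ratio.positions[idx]
    raw = ratio.log2_ratio[idx]
    smooth = _running_median(raw, smooth_window)
    sign = np.zeros(idx.size, dtype=np.int8)
    sign[smooth >= threshold] = 1
    sign[smooth <= -threshold] = -1

    # maximal runs of constant nonzero sign over the targeted subsequence
    runs = []  # (first_i, last_i, sign) as indices into pos/raw
    i = 0
    while i < sign.size:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < sign.size and sign[j + 1] == sign[i]:
            j += 1
        runs.append([i, j, int(sign[i])])
        i = j + 1

    # merge same-sign runs separated by <= merge_gap targeted positions
    merged = []
    for run in runs:
        if (
            merged
            and merged[-1][2] == run[2]
            and run[0] - merged[-1][1] - 1 <= merge_gap
        ):
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    calls = []
    for i0, i1, sgn in merged:
        n = i1 - i0 + 1
        if n < min_positions:
            continue
        start = int(pos[i0]) - 1
        end = int(pos[i1])
        hit = tuple(
            t[3]
            for t in chrom_targets
            if t[1] < end and start < t[2]
        )
        calls.append(
            FocalCall(
                chrom=ratio.chrom,
                start=start,
                end=end,
                direction="gain" if sgn > 0 else "loss",
                mean_log2=float(np.mean(raw[i0 : i1 + 1])),
                n_positions=n,
                targets_hit=hit,
            )
        )
    return calls
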