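"""Readers and writers for the external text formats.

Formats handled here:

* 5-column segment TSV (``sample  chrom  start  end  kind``), 0-based half-open;
* sample sheet TSV (``sample_id  patient_id  diagnosis``);
* three-column per-base depth text (``chrom  pos  depth``, 1-based, one
  chromosome per file — the de-facto ``samtools depth`` output layout);
* BED3/BED6 target intervals and BED12 gene models (blocks = CDS exons);
* minimal 7-column variant TSV.

Readers validate rather than coerce: every rejection names the offending
line.  Structured outputs are written as TSV with a header plus a JSON mirror.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AberrationSegment,
    CohortSample,
    CoverageTrack,
    GeneModel,
    LesionKind,
    ParseError,
    ValidationError,
    VariantObservation,
)

_SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "kind"]
_VARIANT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "ref_reads", "alt_reads"]


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def read_segments(path) -> list[AberrationSegment]:
    """Read aberration segments from a 5-column BED-like TSV.

    A header line is optional and detected by a non-integer third column.
    Coordinates on disk are 0-based half-open, matching the in-memory
    convention.
    """
    path = Path(path)
    segments: list[AberrationSegment] = []
    seen: set[tuple] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(
                    f"expected 5 tab-separated columns, got {len(fields)}",
                    path=path,
                    line=lineno,
                )
            if lineno == 1 and not _is_int(fields[2]):
                continue  # header
            sample_id, chrom, start_s, end_s, kind_s = fields
            if not (_is_int(start_s) and _is_int(end_s)):
                raise ParseError(
                    f"start/end must be integers, got {start_s!r}/{end_s!r}",
                    path=path,
                    line=lineno,
                )
            try:
                kind = LesionKind(kind_s)
            except ValueError:
                allowed = ", ".join(k.value for k in LesionKind)
                raise ParseError(
                    f"unknown lesion kind {kind_s!r}; allowed: {allowed}",
                    path=path,
                    line=lineno,
                ) from None
            try:
                seg = AberrationSegment(sample_id, chrom, int(start_s), int(end_s), kind)
            except ValidationError as exc:
                raise ParseError(str(exc), path=path, line=lineno) from None
            key = (seg.sample_id, seg.chrom, seg.start, seg.end, seg.kind)
            if key in seen:
                raise ParseError(f"duplicate segment {key}", path=path, line=lineno)
            seen.add(key)
            segments.append(seg)
    return segments


def write_segments(segments, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_SEGMENT_COLUMNS) + "\n")
        for s in segments:
            fh.write(f"{s.sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.kind.value}\n")


def read_sample_sheet(path) -> list[CohortSample]:
    """Read a sample sheet TSV with columns sample_id, patient_id, diagnosis."""
    path = Path(path)
    samples: list[CohortSample] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"expected 3 tab-separated columns, got {len(fields)}",
                    path=path,
                    line=lineno,
                )
            if lineno == 1 and fields[0] == "sample_id":
                continue
            sid, pid, diagnosis = fields
            if sid in seen:
                raise ParseError(f"duplicate sample_id {sid!r}", path=path, line=lineno)
            seen.add(sid)
            samples.append(CohortSample(sid, pid, diagnosis))
    return samples


def write_sample_sheet(samples, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpatient_id\tdiagnosis\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.patient_id}\t{s.diagnosis}\n")


def read_depth_track(path) -> CoverageTrack:
    """Read a three-column per-base depth file into a sparse coverage track.

    One chromosome per file; positions are 1-based and must be strictly
    increasing.  Missing positions stay absent — they are never zero-filled.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "depth"],
            dtype={"chrom": str, "pos": np.int64, "depth": np.float64},
        )
    except pd.errors.EmptyDataError:
        return CoverageTrack("", np.empty(0, dtype=np.int64), np.empty(0))
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"malformed depth file: {exc}", path=path) from None
    if df["chrom"].nunique() > 1:
        raise ParseError(
            f"multiple chromosomes in one depth file: {sorted(df['chrom'].unique())}",
            path=path,
        )
    if (df["depth"] < 0).any():
        bad = int(df.index[df["depth"] < 0][0]) + 1
        raise ParseError("negative depth", path=path, line=bad)
    pos = df["pos"].to_numpy()
    if pos.size and np.any(np.diff(pos) <= 0):
        bad = int(np.flatnonzero(np.diff(pos) <= 0)[0]) + 2
        raise ParseError("positions not strictly increasing", path=path, line=bad)
    chrom = str(df["chrom"].iloc[0]) if len(df) else ""
    return CoverageTrack(chrom, pos, df["depth"].to_numpy())


def write_depth_track(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for p, v in zip(track.positions, track.values):
            v = int(v) if float(v).is_integer() else float(v)
            fh.write(f"{track.chrom}\t{p}\t{v}\n")


def read_targets_bed(path) -> list[tuple]:
    """Read BED3/BED6 target intervals as (chrom, start, end, name) tuples."""
    path = Path(path)
    targets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("BED line with <3 columns", path=path, line=lineno)
            chrom, start_s, end_s = fields[:3]
            if not (_is_int(start_s) and _is_int(end_s)):
                raise ParseError("non-integer BED coordinates", path=path, line=lineno)
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ParseError(f"empty BED interval [{start},{end})", path=path, line=lineno)
            name = fields[3] if len(fields) > 3 else f"target_{len(targets) + 1}"
            targets.append((chrom, start, end, name))
    return targets


def write_targets_bed(targets, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in targets:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_gene_models(path, cds_path=None) -> list[GeneModel]:
    """Read gene models from BED12 (blocks = CDS exons) or BED6 + CDS BED.

    In the BED6 form the companion ``cds_path`` BED carries one line per CDS
    exon with the gene id in column 4.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 12):
                raise ParseError(
                    f"expected BED6 or BED12, got {len(fields)} columns",
                    path=path,
                    line=lineno,
                )
            rows.append((lineno, fields))

    genes: list[GeneModel] = []
    if rows and len(rows[0][1]) == 12:
        for lineno, f in rows:
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != len(starts):
                raise ParseError("blockSizes/blockStarts length mismatch", path=path, line=lineno)
            blocks = [(start + off, start + off + sz) for off, sz in zip(starts, sizes)]
            try:
                genes.append(GeneModel(name, chrom, start, end, strand, tuple(blocks)))
            except ValidationError as exc:
                raise ParseError(str(exc), path=path, line=lineno) from None
    else:
        cds_by_gene: dict[str, list] = {}
        if cds_path is not None:
            for chrom, s, e, name in read_targets_bed(cds_path):
                cds_by_gene.setdefault(name, []).append((s, e))
        for lineno, f in rows:
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            blocks = sorted(cds_by_gene.get(name, []))
            try:
                genes.append(GeneModel(name, chrom, start, end, strand, tuple(blocks)))
            except ValidationError as exc:
                raise ParseError(str(exc), path=path, line=lineno) from None
    return genes


def read_variants(path) -> list[VariantObservation]:
    """Read the minimal 7-column variant TSV (positions 1-based)."""
    path = Path(path)
    variants = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(
                    f"expected 7 tab-separated columns, got {len(fields)}",
                    path=path,
                    line=lineno,
                )
            if lineno == 1 and fields[0] == "sample_id":
                continue
            sid, chrom, pos, ref, alt, rr, ar = fields
            if not (_is_int(pos) and _is_int(rr) and _is_int(ar)):
                raise ParseError("non-integer pos/read counts", path=path, line=lineno)
            try:
                variants.append(
                    VariantObservation(sid, chrom, int(pos), ref, alt, int(rr), int(ar))
                )
            except ValidationError as exc:
                raise ParseError(str(exc), path=path, line=lineno) from None
    return variants


def write_variants(variants, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_VARIANT_COLUMNS) + "\n")
        for v in variants:
            fh.write(
                f"{v.sample_id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                f"{v.ref_reads}\t{v.alt_reads}\n"
            )


def write_table(df: pd.DataFrame, tsv_path, json_path=None) -> None:
    """Write a result table as TSV with header plus a JSON mirror."""
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2, default=str)
            fh.write("\n")
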