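"""End-to-end orchestration: config-driven runs producing one report bundle.

A run executes summarize -> dedupe -> tally -> CDR -> associations and,
when the inputs are configured, coverage CNV calling and dosage
classification.  Every output directory receives TSV tables, their JSON
mirrors and exactly one run manifest recording the tool version, the config
snapshot, input digests and per-stage record counts.  Outputs are
deterministic for fixed inputs (manifest timestamps excepted).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as clio
from .cdr import annotate_cdr_genes, build_support_profile, find_cdrs
from .cohort import (
    associate_lesions,
    dedupe_recurrent,
    kind_is,
    overlaps_region,
    summarize_cohort,
    tally_aberrations,
)
from .core import ChromolensError, StageFailure, ValidationError
from .coverage import build_reference, call_focal_events, log2_ratio_track, normalize_track
from .dosage import classify_mechanism

_KNOWN_TOP_KEYS = {
    "inputs",
    "summarize",
    "dedupe",
    "tally",
    "cdr",
    "associations",
    "coverage",
    "dosage",
}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(config: dict) -> dict:
    """Schema-check a run config before any stage executes."""
    if not isinstance(config, dict):
        raise ValidationError("config must be a mapping")
    unknown = set(config) - _KNOWN_TOP_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    inputs = config.get("inputs", {})
    for key in ("segments", "samples"):
        if key not in inputs:
            raise ValidationError(f"config inputs must declare {key!r}")
    declared = []
    for key, value in inputs.items():
        declared.extend(value if isinstance(value, list) else [value])
    for path in declared:
        if not Path(path).exists():
            raise ValidationError(f"declared input does not exist: {path}")
    return config


def _predicate_from_spec(spec):
    if not spec:
        return None
    preds = []
    if "kind" in spec:
        preds.append(kind_is(spec["kind"]))
    if "region" in spec:
        chrom, span = spec["region"].split(":")
        start, end = (int(x) for x in span.split("-"))
        preds.append(overlaps_region(chrom, start, end))
    if not preds:
        raise ValidationError(f"unusable predicate spec: {spec}")
    return lambda seg: all(p(seg) for p in preds)


def run_full_analysis(config: dict, out_dir) -> dict:
    """Execute the configured stages and write one report bundle.

    Returns the manifest dictionary.  Raises ValidationError before any
    stage runs when the config or its declared inputs are invalid; a stage
    failure propagates after a partial manifest is written.
    """
    config = validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = config["inputs"]
    manifest = {
        "tool": "chromolens",
        "version": __version__,
        "started_utc": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "input_digests": {},
        "stages": {},
    }
    for key, value in inputs.items():
        paths = value if isinstance(value, list) else [value]
        manifest["input_digests"][key] = {str(p): _sha256(p) for p in paths}

    def _finish(status: str):
        manifest["status"] = status
        manifest["finished_utc"] = datetime.now(timezone.utc).isoformat()
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
            fh.write("\n")

    try:
        segments = clio.read_segments(inputs["segments"])
        samples = clio.read_sample_sheet(inputs["samples"])

        summary = summarize_cohort(
            segments, samples, unit=config.get("summarize", {}).get("unit", "sample")
        )
        clio.write_table(
            summary.to_frame(), out_dir / "summary.tsv", out_dir / "summary.json"
        )
        manifest["stages"]["summarize"] = {
            "n_rows": len(summary.rows),
            "total": summary.total,
            "total_with_lesion": summary.total_with_lesion,
            "frequency_pct": summary.frequency_pct,
        }

        deduped = dedupe_recurrent(
            segments,
            samples,
            reciprocal_overlap=config.get("dedupe", {}).get("reciprocal_overlap", 0.9),
        )
        clio.write_segments(deduped, out_dir / "segments.deduped.tsv")
        manifest["stages"]["dedupe"] = {
            "n_input": len(segments),
            "n_output": len(deduped),
        }

        tally_cfg = config.get("tally", {})
        tally = tally_aberrations(deduped, samples, exclude=tally_cfg.get("exclude", []))
        clio.write_table(
            pd.DataFrame(
                [
                    {
                        "n_deletions": tally.n_deletions,
                        "n_gains": tally.n_gains,
                        "n_upds": tally.n_upds,
                        "n_excluded_complex": tally.n_excluded_complex,
                    }
                ]
            ),
            out_dir / "tally.tsv",
            out_dir / "tally.json",
        )
        manifest["stages"]["tally"] = {"n_events": tally.total}

        cdr_cfg = config.get("cdr", {})
        kind = cdr_cfg.get("kind", "DEL")
        chrom_segments = [s for s in deduped if s.kind.value == kind]
        cdrs = []
        if chrom_segments:
            profile = build_support_profile(deduped, kind)
            cdrs = find_cdrs(profile, min_support=cdr_cfg.get("min_support", 2))
            if "genes" in inputs:
                genes = clio.read_gene_models(inputs["genes"])
                cdrs = annotate_cdr_genes(cdrs, genes)
        clio.write_table(
            pd.DataFrame(
                [
                    {
                        "chrom": c.chrom,
                        "start": c.start,
                        "end": c.end,
                        "support": c.support,
                        "samples": ",".join(sorted(c.member_samples)),
                        "genes": ",".join(c.genes),
                    }
                    for c in cdrs
                ],
                columns=["chrom", "start", "end", "support", "samples", "genes"],
            ),
            out_dir / "cdrs.tsv",
            out_dir / "cdrs.json",
        )
        manifest["stages"]["cdr"] = {"n_cdrs": len(cdrs)}

        assoc_rows = []
        for spec in config.get("associations", []):
            result = associate_lesions(
                segments,
                samples,
                group_a=spec["group_a"],
                group_b=spec["group_b"],
                predicate=_predicate_from_spec(spec.get("predicate")),
                unit=spec.get("unit", "sample"),
            )
            t = result.table
            assoc_rows.append(
                {
                    "name": spec.get("name", "association"),
                    "a": t.a,
                    "b": t.b,
                    "c": t.c,
                    "d": t.d,
                    "odds_ratio": result.odds_ratio,
                    "p_two_sided": result.p_two_sided,
                    "p_one_sided_greater": result.p_one_sided_greater,
                }
            )
        if assoc_rows:
            clio.write_table(
                pd.DataFrame(assoc_rows),
                out_dir / "associations.tsv",
                out_dir / "associations.json",
            )
        manifest["stages"]["associations"] = {"n_tests": len(assoc_rows)}

        if "case_depth" in inputs and "control_depths" in inputs:
            cov_cfg = config.get("coverage", {})
            case = normalize_track(clio.read_depth_track(inputs["case_depth"]))
            controls = [
                normalize_track(clio.read_depth_track(p))
                for p in inputs["control_depths"]
            ]
            reference = build_reference(
                controls, min_controls=cov_cfg.get("min_controls", 3)
            )
            ratio = log2_ratio_track(case, reference)
            targets = clio.read_targets_bed(inputs["targets"])
            calls = call_focal_events(
                ratio,
                targets,
                threshold=cov_cfg.get("threshold", 0.4),
                min_positions=cov_cfg.get("min_positions", 100),
                merge_gap=cov_cfg.get("merge_gap", 50),
                smooth_window=cov_cfg.get("smooth_window", 51),
            )
            clio.write_table(
                pd.DataFrame(
                    [
                        {
                            "chrom": c.chrom,
                            "start": c.start,
                            "end": c.end,
                            "direction": c.direction,
                            "mean_log2": c.mean_log2,
                            "n_positions": c.n_positions,
                            "targets_hit": ",".join(c.targets_hit),
                        }
                        for c in calls
                    ],
                    columns=[
                        "chrom", "start", "end", "direction",
                        "mean_log2", "n_positions", "targets_hit",
                    ],
                ),
                out_dir / "focal_calls.tsv",
                out_dir / "focal_calls.json",
            )
            pd.DataFrame(
                {"chrom": ratio.chrom, "pos": ratio.positions, "log2_ratio": ratio.log2_ratio}
            ).to_csv(out_dir / "log2_ratio.tsv", sep="\t", index=False)
            manifest["stages"]["coverage_cnv"] = {"n_calls": len(calls)}

        if "variants" in inputs:
            dos_cfg = config.get("dosage", {})
            variants = clio.read_variants(inputs["variants"])
            rows = []
            for v in variants:
                overlapping = next(
                    (
                        s.kind.value
                        for s in deduped
                        if s.sample_id == v.sample_id
                        and s.overlaps(v.chrom, v.pos - 1, v.pos)
                    ),
                    "none",
                )
                call = classify_mechanism(
                    v,
                    overlapping_kind=overlapping,
                    clonality=dos_cfg.get("clonality"),
                    min_depth=dos_cfg.get("min_depth", 20),
                )
                rows.append(
                    {
                        "sample_id": v.sample_id,
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "observed_vaf": round(call.observed_vaf, 4),
                        "overlapping_kind": overlapping,
                        "mechanism": call.mechanism.value,
                        "expected_vaf": round(call.expected_vaf, 4),
                        "clonality": call.clonality,
                    }
                )
            clio.write_table(
                pd.DataFrame(
                    rows,
                    columns=[
                        "sample_id", "chrom", "pos", "observed_vaf",
                        "overlapping_kind", "mechanism", "expected_vaf", "clonality",
                    ],
                ),
                out_dir / "dosage_calls.tsv",
                out_dir / "dosage_calls.json",
            )
            manifest["stages"]["dosage"] = {"n_variants": len(rows)}
    except ChromolensError as exc:
        _finish("failed")  # partial manifest for the completed stages
        raise StageFailure(str(exc)) from exc
    _finish("ok")
    return manifest
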