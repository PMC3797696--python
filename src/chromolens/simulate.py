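"""Seeded generators for every input the pipeline consumes.

Each generator draws from its own independent random stream derived from one
global seed (``SeedSequence(seed, spawn_key=(stream,))``), so adding a
generator never perturbs the output of another.  Every generator returns its
ground truth alongside the data and can write both to disk; identical
(config, seed) pairs produce byte-identical files.

Defaults emulate the reference study conditions: a 13-diagnosis cohort of
813 samples with 52 lesion-bearing ones, a lesion-kind mix of 30:11:17
(DEL:GAIN:UPD), ~100x exome depth with an 8-sample control pool, and clone
read counts drawn binomially from the dosage model's expected VAF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as clio
from .core import (
    AberrationSegment,
    CohortSample,
    CoverageTrack,
    LesionKind,
    ValidationError,
    VariantObservation,
)
from .dosage import MECHANISM_STATES, ColonyTable, Mechanism, PhaseCall, expected_vaf
from .presets import DEFAULT_KIND_MIX, REFERENCE_COHORT_ROWS

_STREAMS = {"cohort": 1, "depth": 2, "clones": 3, "cdr": 4}

#: toy chromosome used by all generators: large enough for CDR geometry,
#: small enough for per-base oracles
TOY_CHROM = "chrT"
TOY_CHROM_LENGTH = 10_000_000


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# cohort generator

@dataclass
class CohortConfig:
    seed: int = 0
    rows: list = field(default_factory=lambda: list(REFERENCE_COHORT_ROWS))
    kind_mix: dict = field(default_factory=lambda: dict(DEFAULT_KIND_MIX))
    chrom: str = TOY_CHROM
    chrom_length: int = TOY_CHROM_LENGTH
    min_segment_length: int = 50_000
    max_segment_length: int = 3_000_000
    #: probability of a lesion-bearing sample carrying 1, 2 or 3 segments
    n_segment_probs: tuple = (0.75, 0.15, 0.10)


@dataclass
class CohortBundle:
    samples: list
    segments: list
    truth: dict

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        clio.write_sample_sheet(self.samples, out_dir / "samples.tsv")
        clio.write_segments(self.segments, out_dir / "segments.tsv")
        _write_json(self.truth, out_dir / "cohort_truth.json")


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a sample sheet and segment set matching a cohort layout.

    For each (diagnosis, n_samples, n_with_lesion) row, exactly
    ``n_with_lesion`` samples receive 1-3 segments with kinds drawn from the
    configured mix; coordinates are uniform over the toy chromosome.
    """
    mix_kinds = sorted(config.kind_mix)
    mix_p = np.array([config.kind_mix[k] for k in mix_kinds], dtype=float)
    if abs(mix_p.sum() - 1.0) > 1e-9:
        raise ValidationError("lesion kind mix proportions must sum to 1")
    rng = _rng(config.seed, "cohort")

    samples: list[CohortSample] = []
    segments: list[AberrationSegment] = []
    truth_lesions: dict[str, list] = {}
    counter = 0
    for diagnosis, n, n_with in config.rows:
        if n_with > n:
            raise ValidationError(
                f"{diagnosis}: n_with_lesion {n_with} > n_samples {n}"
            )
        for i in range(n):
            counter += 1
            sid = f"S{counter:04d}"
            samples.append(CohortSample(sid, f"P{counter:04d}", diagnosis))
            if i >= n_with:
                continue
            n_seg = int(rng.choice([1, 2, 3], p=config.n_segment_probs))
            truth_lesions[sid] = []
            for _ in range(n_seg):
                length = int(
                    rng.integers(config.min_segment_length, config.max_segment_length + 1)
                )
                length = min(length, config.chrom_length)
                start = int(rng.integers(0, config.chrom_length - length + 1))
                kind = str(rng.choice(mix_kinds, p=mix_p))
                seg = AberrationSegment(sid, config.chrom, start, start + length, kind)
                if any(
                    (s.start, s.end, s.kind) == (seg.start, seg.end, seg.kind)
                    for s in segments
                    if s.sample_id == sid
                ):
                    continue  # vanishingly rare exact duplicate draw
                segments.append(seg)
                truth_lesions[sid].append(
                    {"chrom": seg.chrom, "start": seg.start, "end": seg.end, "kind": kind}
                )
    truth = {
        "seed": config.seed,
        "n_samples": len(samples),
        "n_samples_with_lesion": len(truth_lesions),
        "lesions": truth_lesions,
    }
    return CohortBundle(samples, segments, truth)


# ---------------------------------------------------------------------------
# planted-CDR segment generator

@dataclass
class CDRConfig:
    seed: int = 7
    n_samples: int = 20
    core_start: int = 4_000_000
    core_end: int = 4_050_000  # 50 kb core
    kind: str = "DEL"
    max_extension: int = 500_000
    chrom: str = TOY_CHROM
    chrom_length: int = TOY_CHROM_LENGTH


def generate_cdr_segments(config: CDRConfig) -> CohortBundle:
    """Segments from ``n_samples`` samples all sharing a planted core region.

    One defining sample carries exactly the core; the others extend it by
    random amounts on each side, so the core is the unique maximal-support
    region.
    """
    if not (0 <= config.core_start < config.core_end <= config.chrom_length):
        raise ValidationError("planted core outside the toy chromosome")
    rng = _rng(config.seed, "cdr")
    samples, segments = [], []
    for i in range(config.n_samples):
        sid = f"C{i + 1:03d}"
        samples.append(CohortSample(sid, f"PC{i + 1:03d}", "synthetic"))
        if i == 0:
            start, end = config.core_start, config.core_end
        else:
            start = max(0, config.core_start - int(rng.integers(1, config.max_extension)))
            end = min(
                config.chrom_length,
                config.core_end + int(rng.integers(1, config.max_extension)),
            )
        segments.append(AberrationSegment(sid, config.chrom, start, end, config.kind))
    truth = {
        "seed": config.seed,
        "core": {
            "chrom": config.chrom,
            "start": config.core_start,
            "end": config.core_end,
            "support": config.n_samples,
        },
    }
    return CohortBundle(samples, segments, truth)


# ---------------------------------------------------------------------------
# depth-track generator

@dataclass
class DepthConfig:
    seed: int = 13
    depth: float = 100.0  # mean per-base depth at a unit-weight target
    n_controls: int = 8
    chrom: str = TOY_CHROM
    #: (start, end) target intervals, 0-based half-open; None -> auto layout
    targets: list | None = None
    n_targets: int = 24
    target_length: int = 400
    target_gap: int = 5_000
    first_target_start: int = 100_000
    #: per-target capture-efficiency lognormal sigma (shared across samples)
    weight_sigma: float = 0.3
    #: (start, end, copy_ratio) spikes, each inside the targets
    spikes: list = field(default_factory=list)


@dataclass
class DepthBundle:
    case: CoverageTrack
    controls: list
    targets: list  # (chrom, start, end, name)
    truth: dict

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        clio.write_depth_track(self.case, out_dir / "case.depth.txt")
        for i, t in enumerate(self.controls, start=1):
            clio.write_depth_track(t, out_dir / f"control{i}.depth.txt")
        clio.write_targets_bed(self.targets, out_dir / "targets.bed")
        _write_json(self.truth, out_dir / "depth_truth.json")


def _auto_targets(config: DepthConfig) -> list[tuple]:
    targets = []
    start = config.first_target_start
    for i in range(config.n_targets):
        targets.append((config.chrom, start, start + config.target_length, f"t{i + 1:03d}"))
        start += config.target_length + config.target_gap
    return targets


def generate_depth_tracks(config: DepthConfig) -> DepthBundle:
    """Poisson per-base depth over targeted intervals, case plus controls.

    Per-position depth is Poisson(depth x target weight x copy ratio); the
    copy ratio is 1 everywhere for controls and over the configured spikes
    for the case.  Target weights emulate uneven capture efficiency and are
    shared by all samples.
    """
    if config.depth <= 0:
        raise ValidationError("mean depth must be > 0")
    if config.targets is not None:
        targets = [
            (config.chrom, int(s), int(e), f"t{i + 1:03d}")
            for i, (s, e) in enumerate(config.targets)
        ]
    else:
        targets = _auto_targets(config)
    for s, e, r in config.spikes:
        covered = any(ts <= s and e <= te for _, ts, te, _ in targets)
        if not covered:
            raise ValidationError(
                f"spike [{s}, {e}) not contained in any target interval"
            )
        if r < 0:
            raise ValidationError("spike copy ratio must be nonnegative")

    rng = _rng(config.seed, "depth")
    weights = rng.lognormal(mean=0.0, sigma=config.weight_sigma, size=len(targets))

    positions = np.concatenate(
        [np.arange(s + 1, e + 1, dtype=np.int64) for _, s, e, _ in targets]
    )
    lam = np.concatenate(
        [np.full(e - s, config.depth * w) for (_, s, e, _), w in zip(targets, weights)]
    )
    ratio = np.ones(positions.size)
    for s, e, r in config.spikes:
        ratio[(positions > s) & (positions <= e)] = r

    case = CoverageTrack(config.chrom, positions, rng.poisson(lam * ratio).astype(float))
    controls = [
        CoverageTrack(config.chrom, positions, rng.poisson(lam).astype(float))
        for _ in range(config.n_controls)
    ]
    truth = {
        "seed": config.seed,
        "depth": config.depth,
        "target_weights": [float(w) for w in weights],
        "spikes": [
            {"start": int(s), "end": int(e), "copy_ratio": float(r)}
            for s, e, r in config.spikes
        ],
    }
    return DepthBundle(case, controls, targets, truth)


# ---------------------------------------------------------------------------
# toy CDS builder

#: sense codons used for random CDS filler (no stop codons)
_FILLER_CODONS = ("GCT", "GGA", "CTT", "AAA", "GAG", "TCC", "ACG", "GTT", "TGC", "CCA")


def make_toy_cds(n_codons: int, seed: int = 0, codon_overrides: dict | None = None) -> str:
    """A random complete CDS: ATG start, TAA stop, no internal stops.

    ``codon_overrides`` pins specific 1-based codon indices to given codons,
    e.g. to plant a known residue at a known position for annotation tests.
    """
    if n_codons < 3:
        raise ValidationError("CDS needs at least start, one codon and stop")
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + [
        str(rng.choice(_FILLER_CODONS)) for _ in range(n_codons - 2)
    ] + ["TAA"]
    for idx, codon in (codon_overrides or {}).items():
        if not 1 <= idx <= n_codons:
            raise ValidationError(f"codon override index {idx} outside CDS")
        codons[idx - 1] = codon
    return "".join(codons)


# ---------------------------------------------------------------------------
# clone observation generator

@dataclass
class CloneConfig:
    seed: int = 0
    #: (mechanism, clonality, depth, n_variants) tuples
    clone_spec: list = field(
        default_factory=lambda: [(m.value, 1.0, 80, 1) for m in MECHANISM_STATES]
    )
    #: (phase label, n_colonies) tuples
    colony_spec: list = field(default_factory=list)
    chrom: str = TOY_CHROM


_PHASE_PROBS = {
    PhaseCall.TRANS_COMPOUND_HETEROZYGOUS.value: (0.5, 0.5, 0.0, 0.0),
    PhaseCall.CIS_SAME_ALLELE.value: (0.0, 0.0, 0.5, 0.5),
    PhaseCall.SINGLE_VARIANT.value: (0.5, 0.0, 0.0, 0.5),
}


@dataclass
class CloneBundle:
    variants: list
    variant_truth: list  # dicts parallel to variants
    colonies: list  # (label, ColonyTable) with label = planted phase
    truth: dict

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        clio.write_variants(self.variants, out_dir / "variants.tsv")
        with open(out_dir / "colonies.tsv", "w") as fh:
            fh.write("planted_phase\ta_only\tb_only\tboth\tneither\n")
            for label, tab in self.colonies:
                fh.write(
                    f"{label}\t{tab.a_only}\t{tab.b_only}\t{tab.both}\t{tab.neither}\n"
                )
        _write_json(self.truth, out_dir / "clone_truth.json")


def generate_clone_observations(config: CloneConfig) -> CloneBundle:
    """Variant read counts and colony tables from planted mechanisms.

    Alt-read counts are Binomial(depth, expected VAF of the planted
    mechanism at the planted clonality); colony tables are multinomial draws
    from the planted phase configuration.
    """
    rng = _rng(config.seed, "clones")
    variants: list[VariantObservation] = []
    variant_truth: list[dict] = []
    counter = 0
    for mech_name, clonality, depth, n_variants in config.clone_spec:
        try:
            mech = Mechanism(mech_name)
        except ValueError:
            raise ValidationError(f"cannot simulate mechanism {mech_name!r}") from None
        if mech not in MECHANISM_STATES:
            raise ValidationError(f"cannot simulate mechanism {mech_name!r}")
        cn, m = MECHANISM_STATES[mech]
        vaf = expected_vaf(cn, m, clonality)
        for _ in range(int(n_variants)):
            counter += 1
            alt = int(rng.binomial(int(depth), vaf))
            variants.append(
                VariantObservation(
                    sample_id=f"V{counter:05d}",
                    chrom=config.chrom,
                    pos=1000 + counter,
                    ref="G",
                    alt="A",
                    ref_reads=int(depth) - alt,
                    alt_reads=alt,
                )
            )
            variant_truth.append(
                {
                    "mechanism": mech.value,
                    "clonality": float(clonality),
                    "expected_vaf": vaf,
                    "overlapping_kind": {
                        Mechanism.HETEROZYGOUS: "none",
                        Mechanism.UPD_HOMOZYGOUS: "UPD",
                        Mechanism.GAIN_AMPLIFIED_MUTANT: "GAIN",
                        Mechanism.GAIN_RETAINED_WILDTYPE: "GAIN",
                        Mechanism.HEMIZYGOUS_DELETED_LOCUS: "DEL",
                    }[mech],
                }
            )

    colonies = []
    for label, n_colonies in config.colony_spec:
        if label not in _PHASE_PROBS:
            raise ValidationError(f"unknown planted phase {label!r}")
        draw = rng.multinomial(int(n_colonies), _PHASE_PROBS[label])
        colonies.append((label, ColonyTable(*(int(x) for x in draw))))

    truth = {
        "seed": config.seed,
        "variants": variant_truth,
        "colonies": [
            {"planted_phase": label, "counts": [t.a_only, t.b_only, t.both, t.neither]}
            for label, t in colonies
        ],
    }
    return CloneBundle(variants, variant_truth, colonies, truth)
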