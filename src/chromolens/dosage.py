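"""Allele-dosage mechanism classification from VAF, lesions and clonality.

The malignant clone can raise mutant-allele dosage in several ways: copy-
neutral UPD homozygoses the mutation; a chromosomal gain can duplicate the
mutant (or retain only the wild-type) copy; a deletion leaves the locus
hemizygous; compound heterozygosity places two distinct mutations in trans.
Each mechanism predicts a variant allele fraction

    VAF = m*c / (k*c + 2*(1 - c))

where k is the total locus copy number in the aberrant clone, m the number
of mutant copies and c the clonality (fraction of cells in the clone;
non-clone cells are diploid wild type).  Mechanisms compatible with the
overlapping lesion kind are scored by binomial likelihood of the observed
alt-read count; a small sequencing error rate keeps homozygous hypotheses
(VAF = 1) from being annihilated by a single reference read.

Cis/trans configuration of two mutations is read from subclone colony
genotype tables: colonies carrying either mutation alone (and none with
both or neither) indicate trans compound heterozygosity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .core import ValidationError, VariantObservation


class Mechanism(str, enum.Enum):
    HETEROZYGOUS = "heterozygous"
    UPD_HOMOZYGOUS = "UPD_homozygous"
    GAIN_AMPLIFIED_MUTANT = "gain_amplified_mutant"
    GAIN_RETAINED_WILDTYPE = "gain_retained_wildtype"
    HEMIZYGOUS_DELETED_LOCUS = "hemizygous_deleted_locus"
    COMPOUND_HETEROZYGOUS = "compound_heterozygous"
    AMBIGUOUS = "ambiguous"


#: (total copy number in clone, mutant copies) per mechanism
MECHANISM_STATES = {
    Mechanism.HETEROZYGOUS: (2, 1),
    Mechanism.UPD_HOMOZYGOUS: (2, 2),
    Mechanism.GAIN_AMPLIFIED_MUTANT: (3, 2),
    Mechanism.GAIN_RETAINED_WILDTYPE: (3, 1),
    Mechanism.HEMIZYGOUS_DELETED_LOCUS: (1, 1),
}

#: mechanisms compatible with the lesion kind overlapping the variant
CANDIDATES_BY_KIND = {
    "none": (Mechanism.HETEROZYGOUS,),
    "DEL": (Mechanism.HEMIZYGOUS_DELETED_LOCUS, Mechanism.HETEROZYGOUS),
    "UPD": (Mechanism.UPD_HOMOZYGOUS, Mechanism.HETEROZYGOUS),
    "GAIN": (Mechanism.GAIN_AMPLIFIED_MUTANT, Mechanism.GAIN_RETAINED_WILDTYPE),
}

DEFAULT_CLONALITY_GRID = np.round(np.arange(0.05, 1.0001, 0.05), 2)


class PhaseCall(str, enum.Enum):
    TRANS_COMPOUND_HETEROZYGOUS = "trans_compound_heterozygous"
    CIS_SAME_ALLELE = "cis_same_allele"
    SINGLE_VARIANT = "single_variant"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class ColonyTable:
    """Colony counts by joint genotype over two variants A and B."""

    a_only: int
    b_only: int
    both: int
    neither: int

    def __post_init__(self):
        if min(self.a_only, self.b_only, self.both, self.neither) < 0:
            raise ValidationError("colony counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a_only + self.b_only + self.both + self.neither


@dataclass
class DosageCall:
    mechanism: Mechanism
    log_likelihoods: dict
    expected_vaf: float
    clonality: float | None
    observed_vaf: float
    ambiguous_between: tuple = ()


def expected_vaf(copy_number: int, mutant_copies: int, clonality: float) -> float:
    """VAF predicted by a clone of fraction ``clonality`` carrying
    ``mutant_copies`` of ``copy_number`` total copies (diploid wild type
    outside the clone)."""
    if copy_number < 1:
        raise ValidationError("copy_number must be >= 1")
    if not 0 <= mutant_copies <= copy_number:
        raise ValidationError(
            f"mutant_copies must be in [0, {copy_number}], got {mutant_copies}"
        )
    if not 0.0 <= clonality <= 1.0:
        raise ValidationError(f"clonality must be in [0, 1], got {clonality}")
    denom = copy_number * clonality + 2.0 * (1.0 - clonality)
    return mutant_copies * clonality / denom


def _vaf_with_error(vaf: float, error_rate: float) -> float:
    return vaf * (1.0 - error_rate) + (1.0 - vaf) * error_rate


def classify_mechanism(
    variant: VariantObservation,
    overlapping_kind: str = "none",
    clonality: float | None = None,
    min_depth: int = 20,
    decision_margin: float = 2.0,
    error_rate: float = 0.01,
    clonality_grid: np.ndarray | None = None,
) -> DosageCall:
    """Maximum-likelihood dosage mechanism for one variant.

    ``overlapping_kind`` is the lesion kind spanning the variant ('DEL',
    'GAIN', 'UPD' or 'none'); unknown clonality is profiled over a grid.
    Calls whose top two log-likelihoods differ by less than
    ``decision_margin`` natural-log units are returned as ambiguous, with
    the contenders listed.
    """
    kind = getattr(overlapping_kind, "value", overlapping_kind)
    if kind not in CANDIDATES_BY_KIND:
        raise ValidationError(
            f"overlapping_kind must be one of {sorted(CANDIDATES_BY_KIND)}, got {kind!r}"
        )
    depth = variant.depth
    if depth < min_depth:
        raise ValidationError(f"depth {depth} below min_depth {min_depth}")
    if clonality_grid is None:
        clonality_grid = DEFAULT_CLONALITY_GRID
    grid = np.array([clonality]) if clonality is not None else np.asarray(clonality_grid)

    lls: dict[Mechanism, float] = {}
    best_c: dict[Mechanism, float] = {}
    for mech in CANDIDATES_BY_KIND[kind]:
        k_cn, m = MECHANISM_STATES[mech]
        vafs = np.array([expected_vaf(k_cn, m, c) for c in grid])
        probs = _vaf_with_error(vafs, error_rate)
        ll = binom.logpmf(variant.alt_reads, depth, probs)
        i = int(np.argmax(ll))
        lls[mech] = float(ll[i])
        best_c[mech] = float(grid[i])

    ranked = sorted(lls, key=lls.get, reverse=True)
    winner = ranked[0]
    ambiguous_between: tuple = ()
    if len(ranked) > 1 and lls[ranked[0]] - lls[ranked[1]] < decision_margin:
        ambiguous_between = (ranked[0], ranked[1])
        mechanism = Mechanism.AMBIGUOUS
    else:
        mechanism = winner
    k_cn, m = MECHANISM_STATES[winner]
    return DosageCall(
        mechanism=mechanism,
        log_likelihoods={k.value: v for k, v in lls.items()},
        expected_vaf=expected_vaf(k_cn, m, best_c[winner]),
        clonality=best_c[winner],
        observed_vaf=variant.vaf,
        ambiguous_between=ambiguous_between,
    )


def classify_phase(colonies: ColonyTable, min_colonies: int = 10) -> PhaseCall:
    """Cis/trans configuration of two mutations from colony genotypes.

    trans: both single-mutant classes seen, no double-mutant and no
    wild-type colony.  cis: double mutants (with or without wild type) and
    no single-mutant colony.  A single mutation class alone is
    'single_variant'; anything mixed, or too few colonies, is inconclusive.
    """
    if colonies.total < min_colonies:
        return PhaseCall.INCONCLUSIVE
    a, b, both, neither = (
        colonies.a_only,
        colonies.b_only,
        colonies.both,
        colonies.neither,
    )
    if a > 0 and b > 0 and both == 0 and neither == 0:
        return PhaseCall.TRANS_COMPOUND_HETEROZYGOUS
    if both > 0 and a == 0 and b == 0:
        return PhaseCall.CIS_SAME_ALLELE
    if both == 0 and ((a > 0) != (b > 0)):
        return PhaseCall.SINGLE_VARIANT
    return PhaseCall.INCONCLUSIVE
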