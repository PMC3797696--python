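"""CDS-level annotation of tandem duplications and single-nucleotide variants.

All CDS positions are 1-based nucleotide coordinates on the coding sequence
(c.-style); protein positions are 1-based and include the initiator
methionine.  Translation uses the standard genetic code.

A tandem duplication inserts a copy of ``cds[start : start+length]``
immediately after the original.  When the length is a multiple of 3 the
event is in frame:

* codon-aligned duplications duplicate whole residues and are reported as a
  duplicated residue span (first, last);
* codon-internal in-frame duplications shift the junction and are reported
  as an insertion of novel residues after a reference position (e.g. a 6 nt
  duplication creating two new codons).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .core import ValidationError

_NUCLEOTIDES = set("ACGT")


@dataclass(frozen=True)
class DuplicationAnnotation:
    in_frame: bool
    dup_length_nt: int
    n_residues: int  # 0 for frameshifts
    residue_span: tuple | None = None  # (first, last), codon-aligned only
    inserted_after: int | None = None  # codon-internal in-frame only
    inserted_residues: str | None = None


def _check_cds(cds: str) -> str:
    cds = cds.upper()
    if not cds:
        raise ValidationError("empty CDS sequence")
    bad = set(cds) - _NUCLEOTIDES
    if bad:
        raise ValidationError(f"CDS contains non-ACGT characters: {sorted(bad)}")
    return cds


def translate_cds(cds: str) -> str:
    """Translate a CDS (length must be a multiple of 3), standard code."""
    cds = _check_cds(cds)
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} is not a multiple of 3")
    return str(Seq(cds).translate())


def cds_pos_to_codon(cds_pos: int, cds_length: int | None = None) -> int:
    """Map a 1-based CDS nucleotide position to its 1-based codon index."""
    if cds_pos < 1:
        raise ValidationError(f"CDS position must be >= 1, got {cds_pos}")
    if cds_length is not None and cds_pos > cds_length:
        raise ValidationError(
            f"CDS position {cds_pos} beyond CDS length {cds_length}"
        )
    return (cds_pos + 2) // 3


def apply_tandem_duplication(cds: str, dup_start: int, dup_length_nt: int) -> str:
    """Return the mutant CDS with cds[dup_start..] duplicated in tandem."""
    cds = _check_cds(cds)
    i = dup_start - 1
    if dup_start < 1 or dup_length_nt < 1 or i + dup_length_nt > len(cds):
        raise ValidationError(
            f"duplication [{dup_start}, +{dup_length_nt}] outside CDS of "
            f"length {len(cds)}"
        )
    return cds[: i + dup_length_nt] + cds[i:]


def annotate_tandem_duplication(
    cds_sequence: str, dup_start: int, dup_length_nt: int
) -> DuplicationAnnotation:
    """Annotate a tandem duplication of ``dup_length_nt`` bases starting at
    1-based CDS position ``dup_start``."""
    cds = _check_cds(cds_sequence)
    if len(cds) % 3 != 0:
        raise ValidationError(
            f"annotation requires a complete CDS (length {len(cds)} not a "
            "multiple of 3)"
        )
    mutant = apply_tandem_duplication(cds, dup_start, dup_length_nt)

    if dup_length_nt % 3 != 0:
        return DuplicationAnnotation(
            in_frame=False, dup_length_nt=dup_length_nt, n_residues=0
        )

    n_res = dup_length_nt // 3
    if (dup_start - 1) % 3 == 0:
        first = cds_pos_to_codon(dup_start, len(cds))
        dup_seq = cds[dup_start - 1 : dup_start - 1 + dup_length_nt]
        return DuplicationAnnotation(
            in_frame=True,
            dup_length_nt=dup_length_nt,
            n_residues=n_res,
            residue_span=(first, first + n_res - 1),
            inserted_residues=str(Seq(dup_seq).translate()),
        )

    # codon-internal: translate both proteins and take the leftmost-aligned
    # inserted block
    ref_prot = translate_cds(cds)
    mut_prot = translate_cds(mutant)
    p = 0
    while p < len(ref_prot) and ref_prot[p] == mut_prot[p]:
        p += 1
    return DuplicationAnnotation(
        in_frame=True,
        dup_length_nt=dup_length_nt,
        n_residues=n_res,
        inserted_after=p,
        inserted_residues=mut_prot[p : p + n_res],
    )


def annotate_snv(cds_sequence: str, cds_pos: int, alt: str) -> str:
    """Protein-change string ``<refAA><codon><altAA>`` for a CDS SNV.

    Synonymous changes are reported with identical amino-acid letters.
    """
    cds = _check_cds(cds_sequence)
    alt = alt.upper()
    if alt not in _NUCLEOTIDES:
        raise ValidationError(f"alt must be one of A/C/G/T, got {alt!r}")
    if not (1 <= cds_pos <= len(cds)):
        raise ValidationError(
            f"CDS position {cds_pos} outside CDS of length {len(cds)}"
        )
    if cds[cds_pos - 1] == alt:
        raise ValidationError(
            f"alt allele equals the reference base {alt!r} at position {cds_pos}"
        )
    codon_idx = cds_pos_to_codon(cds_pos, len(cds))
    c0 = (codon_idx - 1) * 3
    codon = cds[c0 : c0 + 3]
    if len(codon) < 3:
        raise ValidationError("variant falls in an incomplete terminal codon")
    offset = (cds_pos - 1) % 3
    mut_codon = codon[:offset] + alt + codon[offset + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mut_codon).translate())
    return f"{ref_aa}{codon_idx}{alt_aa}"
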