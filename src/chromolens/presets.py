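"""Cohort configuration presets: diagnosis labels, phase mapping, groupings.

The default phase mapping implements the progression convention used by the
association analysis: myelofibrotic and accelerated-phase MPN samples that
have not fully transformed (<20% blasts) count as chronic phase, while every
post-chronic-phase AML is grouped as AML.  The mapping lives in configuration,
not code paths, so alternative conventions can be supplied.
"""

from __future__ import annotations

from .core import DiseasePhase

#: (diagnosis, n_samples, n_samples_with_chr11_lesion) rows of the reference
#: myeloid-malignancy cohort (813 samples, 52 lesion-bearing).
REFERENCE_COHORT_ROWS = [
    ("Polycythemia vera", 177, 3),
    ("post-PV MF", 48, 3),
    ("post-PV AML", 19, 3),
    ("Essential thrombocythemia", 91, 2),
    ("post-ET MF", 18, 1),
    ("post-ET AML", 9, 1),
    ("Primary Myelofibrosis", 85, 5),
    ("post-PMF AP", 7, 0),
    ("post-PMF AML", 16, 6),
    ("MDS (chronic phase)", 61, 3),
    ("post-MDS AML", 40, 5),
    ("de novo AML", 180, 19),
    ("CML", 62, 1),
]

DEFAULT_PHASE_MAP = {
    "Polycythemia vera": DiseasePhase.CHRONIC,
    "Essential thrombocythemia": DiseasePhase.CHRONIC,
    "Primary Myelofibrosis": DiseasePhase.CHRONIC,
    "MDS (chronic phase)": DiseasePhase.CHRONIC,
    "CML": DiseasePhase.CHRONIC,
    "post-PV MF": DiseasePhase.PROGRESSED_NON_AML,
    "post-ET MF": DiseasePhase.PROGRESSED_NON_AML,
    "post-PMF AP": DiseasePhase.PROGRESSED_NON_AML,
    "post-PV AML": DiseasePhase.AML,
    "post-ET AML": DiseasePhase.AML,
    "post-PMF AML": DiseasePhase.AML,
    "post-MDS AML": DiseasePhase.AML,
    "de novo AML": DiseasePhase.AML,
}

#: post-MPN AML diagnoses (leukemic transformation of an MPN).
MPN_AML_GROUP = frozenset({"post-PV AML", "post-ET AML", "post-PMF AML"})

#: chronic-phase MPN diagnoses for the progression contrast; myelofibrotic and
#: accelerated-phase samples count as chronic here.
MPN_CHRONIC_GROUP = frozenset(
    {
        "Polycythemia vera",
        "post-PV MF",
        "Essential thrombocythemia",
        "post-ET MF",
        "Primary Myelofibrosis",
        "post-PMF AP",
    }
)

#: de novo vs secondary AML contrast used for CDR associations.
DE_NOVO_AML_GROUP = frozenset({"de novo AML"})
SECONDARY_AML_GROUP = frozenset(
    {"post-PV AML", "post-ET AML", "post-PMF AML", "post-MDS AML"}
)

#: lesion-kind proportions observed in the reference cohort after
#: deduplication and exclusion of the one complex sample (30 DEL, 11 GAIN,
#: 17 UPD out of 58 events).
DEFAULT_KIND_MIX = {"DEL": 30 / 58, "GAIN": 11 / 58, "UPD": 17 / 58}
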