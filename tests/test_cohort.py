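import numpy as np
import pytest

from chromolens.cohort import (
    associate_lesions,
    dedupe_recurrent,
    kind_is,
    overlaps_region,
    summarize_cohort,
    tally_aberrations,
)
from chromolens.core import AberrationSegment, CohortSample, ValidationError
from chromolens.presets import MPN_AML_GROUP, MPN_CHRONIC_GROUP
from chromolens.simulate import CohortConfig, generate_cohort


def seg(sample, start, end, kind, chrom="chr11"):
    return AberrationSegment(sample, chrom, start, end, kind)


TWO_SAMPLE_PATIENT = [
    CohortSample("S1", "P1", "PMF"),
    CohortSample("S2", "P1", "post-PMF AML"),
    CohortSample("S3", "P2", "PMF"),
]


class TestDedupeRecurrent:
    def test_identical_recurrent_lesion_collapsed_within_patient(self):
        segs = [
            seg("S1", 60_000_000, 134_000_000, "UPD"),
            seg("S2", 60_000_000, 134_000_000, "UPD"),
        ]
        kept = dedupe_recurrent(segs, TWO_SAMPLE_PATIENT)
        assert kept == [segs[0]]  # earliest sample's coordinates kept

    def test_distinct_patients_never_merged(self):
        segs = [seg("S1", 0, 100, "DEL"), seg("S3", 0, 100, "DEL")]
        assert len(dedupe_recurrent(segs, TWO_SAMPLE_PATIENT)) == 2

    def test_kind_mismatch_not_merged(self):
        segs = [seg("S1", 0, 100, "DEL"), seg("S2", 0, 100, "UPD")]
        assert len(dedupe_recurrent(segs, TWO_SAMPLE_PATIENT)) == 2

    def test_reciprocal_overlap_threshold(self):
        # 50% reciprocal overlap stays below the 0.9 default
        segs = [seg("S1", 0, 100, "DEL"), seg("S2", 50, 150, "DEL")]
        assert len(dedupe_recurrent(segs, TWO_SAMPLE_PATIENT)) == 2
        assert len(dedupe_recurrent(segs, TWO_SAMPLE_PATIENT, reciprocal_overlap=0.5)) == 1

    def test_unresolvable_sample_rejected(self):
        with pytest.raises(ValidationError, match="not in the sample sheet"):
            dedupe_recurrent([seg("SX", 0, 1, "DEL")], TWO_SAMPLE_PATIENT)


class TestSummarizeCohort:
    def test_reference_layout_totals(self, reference_cohort):
        summary = summarize_cohort(reference_cohort.segments, reference_cohort.samples)
        assert (summary.total, summary.total_with_lesion) == (813, 52)
        assert summary.frequency_pct == 6.4

    def test_empty_and_saturated_cohorts(self):
        samples = [CohortSample(f"S{i}", f"P{i}", "AML") for i in range(10)]
        empty = summarize_cohort([], samples)
        assert empty.total_with_lesion == 0 and empty.frequency_pct == 0.0
        full = summarize_cohort([seg(f"S{i}", 0, 10, "DEL") for i in range(10)], samples)
        assert full.frequency_pct == 100.0

    def test_totals_invariant_under_row_permutation(self, reference_cohort, rng):
        samples = list(reference_cohort.samples)
        segments = list(reference_cohort.segments)
        rng.shuffle(samples)
        rng.shuffle(segments)
        summary = summarize_cohort(segments, samples)
        assert (summary.total, summary.total_with_lesion) == (813, 52)

    def test_patient_unit_counts_patient_once(self):
        segs = [seg("S1", 0, 10, "UPD"), seg("S2", 0, 10, "UPD")]
        by_sample = summarize_cohort(segs, TWO_SAMPLE_PATIENT, unit="sample")
        by_patient = summarize_cohort(segs, TWO_SAMPLE_PATIENT, unit="patient")
        assert by_sample.total_with_lesion == 2
        assert by_patient.total_with_lesion == 1
        assert by_patient.total == 2  # two distinct patients

    def test_percentage_matches_reported_integers(self, reference_cohort):
        s = summarize_cohort(reference_cohort.segments, reference_cohort.samples)
        assert s.frequency_pct == round(100 * s.total_with_lesion / s.total, 1)


class TestAssociateLesions:
    def test_progression_contrast_table_and_p(self, reference_cohort):
        r = associate_lesions(
            reference_cohort.segments,
            reference_cohort.samples,
            group_a=MPN_AML_GROUP,
            group_b=MPN_CHRONIC_GROUP,
        )
        t = r.table
        assert (t.a, t.b, t.c, t.d) == (10, 34, 14, 412)
        assert r.p_two_sided < 1e-4

    def test_lesion_free_groups_give_p_one(self):
        samples = [CohortSample(f"A{i}", f"A{i}", "dxA") for i in range(5)] + [
            CohortSample(f"B{i}", f"B{i}", "dxB") for i in range(5)
        ]
        r = associate_lesions([], samples, group_a={"dxA"}, group_b={"dxB"})
        assert r.p_two_sided == pytest.approx(1.0)

    def test_overlapping_or_empty_groups_rejected(self, reference_cohort):
        with pytest.raises(ValidationError, match="overlap"):
            associate_lesions(
                reference_cohort.segments,
                reference_cohort.samples,
                group_a={"CML"},
                group_b={"CML", "de novo AML"},
            )
        with pytest.raises(ValidationError, match="no members"):
            associate_lesions(
                reference_cohort.segments,
                reference_cohort.samples,
                group_a={"no-such-diagnosis"},
                group_b={"CML"},
            )

    def test_predicate_filters_by_kind_and_region(self, reference_cohort):
        r = associate_lesions(
            reference_cohort.segments,
            reference_cohort.samples,
            group_a=MPN_AML_GROUP,
            group_b=MPN_CHRONIC_GROUP,
            predicate=kind_is("DEL"),
        )
        assert r.table.a <= 10  # DEL-only can never exceed any-lesion counts

    def test_planted_enrichment_detected_across_seeds(self):
        # a diagnosis with 60% lesion rate vs background 5%: the test should
        # reject at alpha = 0.05 in >= 95% of 200 seeded replicates
        rows = [("enriched", 50, 30), ("background", 200, 10)]
        hits = 0
        for seed in range(200):
            bundle = generate_cohort(CohortConfig(seed=seed, rows=rows))
            r = associate_lesions(
                bundle.segments, bundle.samples, group_a={"enriched"}, group_b={"background"}
            )
            hits += r.p_two_sided < 0.05
        assert hits >= 190


class TestTallyAberrations:
    def test_reference_event_mix(self):
        samples = [CohortSample(f"S{i}", f"P{i}", "AML") for i in range(58)]
        segs = (
            [seg(f"S{i}", 0, 10, "DEL") for i in range(30)]
            + [seg(f"S{i}", 0, 10, "GAIN") for i in range(30, 41)]
            + [seg(f"S{i}", 0, 10, "UPD") for i in range(41, 58)]
        )
        tally = tally_aberrations(segs, samples)
        assert (tally.n_deletions, tally.n_gains, tally.n_upds) == (30, 11, 17)

    def test_excluding_complex_sample(self):
        samples = [CohortSample("S1", "P1", "AML"), CohortSample("S42", "P42", "AML")]
        segs = [seg("S1", 0, 10, "DEL")] + [seg("S42", i * 20, i * 20 + 10, "DEL") for i in range(5)]
        tally = tally_aberrations(segs, samples, exclude={"S42"})
        assert tally.n_deletions == 1
        assert tally.n_excluded_complex == 1

    def test_excluding_everything_zeroes_the_tally(self):
        segs = [seg("S1", 0, 10, "GAIN")]
        tally = tally_aberrations(segs, exclude={"S1"})
        assert tally.total == 0

    def test_random_tally_sums_to_input_length(self, rng):
        kinds = ["DEL", "GAIN", "UPD"]
        segs = [
            seg(f"S{i}", 0, 10, kinds[int(rng.integers(0, 3))]) for i in range(200)
        ]
        assert tally_aberrations(segs).total == 200
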