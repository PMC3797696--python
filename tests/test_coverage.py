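import numpy as np
import pytest

from chromolens.core import CoverageTrack, ValidationError
from chromolens.coverage import (
    build_reference,
    call_focal_events,
    log2_ratio_track,
    normalize_track,
)
from chromolens.simulate import DepthConfig, generate_depth_tracks

TARGETS_WITH_513 = [(100_000, 100_513)] + [
    (200_000 + i * 6_000, 200_400 + i * 6_000) for i in range(23)
]


def track(values, positions=None, chrom="chrT"):
    values = np.asarray(values, dtype=float)
    if positions is None:
        positions = np.arange(1, len(values) + 1)
    return CoverageTrack(chrom, positions, values)


def pipeline(config):
    bundle = generate_depth_tracks(config)
    case = normalize_track(bundle.case)
    reference = build_reference([normalize_track(t) for t in bundle.controls])
    ratio = log2_ratio_track(case, reference)
    return bundle, ratio, call_focal_events(ratio, bundle.targets)


class TestNormalizeTrack:
    def test_divides_by_chromosome_total(self):
        norm = normalize_track(track([10, 30, 60]))
        assert norm.values == pytest.approx([0.1, 0.3, 0.6])
        assert norm.total == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        t = track([5, 7, 11, 2])
        assert normalize_track(t).values == pytest.approx(
            normalize_track(track(7 * t.values)).values
        )

    def test_all_zero_or_empty_rejected(self):
        with pytest.raises(ValidationError, match="all-zero"):
            normalize_track(track([0, 0, 0]))
        with pytest.raises(ValidationError, match="empty"):
            normalize_track(track([]))


class TestBuildReference:
    def test_per_position_median(self):
        controls = [track([0.1, 0.5]), track([0.2, 0.4]), track([0.9, 0.1])]
        ref = build_reference(controls)
        assert ref.values == pytest.approx([0.2, 0.4])

    def test_identical_controls_reproduce_any_control(self):
        controls = [track([1, 2, 3])] * 3
        assert build_reference(controls).values == pytest.approx([1, 2, 3])

    def test_restricted_to_shared_positions(self):
        controls = [
            track([1, 2, 3], positions=[1, 2, 3]),
            track([4, 5], positions=[2, 3]),
            track([6, 7], positions=[2, 4]),
        ]
        ref = build_reference(controls)
        assert list(ref.positions) == [2]

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValidationError, match="at least 3"):
            build_reference([track([1]), track([1])])

    def test_seeded_pool_tracks_generating_profile(self):
        # 8 controls at 100x: the median reference should track the true
        # capture-weight profile to within a few percent on average
        bundle = generate_depth_tracks(DepthConfig(seed=11, targets=TARGETS_WITH_513))
        ref = build_reference([normalize_track(t) for t in bundle.controls])
        weights = np.asarray(bundle.truth["target_weights"])
        lam = np.concatenate(
            [np.full(e - s, w) for (_, s, e, _), w in zip(bundle.targets, weights)]
        )
        expected = lam / lam.sum()
        rel_err = np.abs(ref.values - expected) / expected
        assert rel_err.mean() < 0.05


class TestLog2RatioTrack:
    def test_identity_gives_zero(self):
        t = normalize_track(track([3, 4, 5, 6]))
        ratio = log2_ratio_track(t, t)
        assert ratio.log2_ratio == pytest.approx(np.zeros(4), abs=1e-12)

    def test_doubling_gives_one_without_renormalization(self):
        ref = track([0.1, 0.2, 0.3])
        case = track([0.2, 0.4, 0.6])
        ratio = log2_ratio_track(case, ref, pseudocount=0.0)
        assert ratio.log2_ratio == pytest.approx(np.ones(3))

    def test_reference_zero_masked_at_zero_pseudocount(self):
        ratio = log2_ratio_track(track([1, 1]), track([0, 1]), pseudocount=0.0)
        assert bool(ratio.masked[0]) and not bool(ratio.masked[1])
        assert np.isnan(ratio.log2_ratio[0])

    def test_disjoint_positions_rejected(self):
        with pytest.raises(ValidationError, match="share no positions"):
            log2_ratio_track(track([1], positions=[1]), track([1], positions=[2]))

    def test_spiked_region_mean_matches_closed_form(self):
        config = DepthConfig(
            seed=11, targets=TARGETS_WITH_513, spikes=[(100_000, 100_513, 1.5)]
        )
        bundle = generate_depth_tracks(config)
        case = normalize_track(bundle.case)
        ref = build_reference([normalize_track(t) for t in bundle.controls])
        ratio = log2_ratio_track(case, ref)
        inside = (ratio.positions > 100_000) & (ratio.positions <= 100_513)
        # closed-form expectation: the spike itself inflates the case
        # chromosome total, shifting the whole normalized track down
        weights = np.asarray(bundle.truth["target_weights"])
        lam = np.concatenate(
            [np.full(e - s, w) for (_, s, e, _), w in zip(bundle.targets, weights)]
        )
        inflation = 1.0 + 0.5 * lam[inside].sum() / lam.sum()
        expected = np.log2(1.5) - np.log2(inflation)
        assert np.nanmean(ratio.log2_ratio[inside]) == pytest.approx(expected, abs=0.05)


class TestCallFocalEvents:
    def test_flat_zero_ratio_yields_no_calls(self):
        n = 1000
        from chromolens.coverage import RatioTrack

        ratio = RatioTrack(
            "chrT", np.arange(1, n + 1), np.zeros(n), np.zeros(n, dtype=bool)
        )
        assert call_focal_events(ratio, [("chrT", 0, n, "t1")]) == []

    def test_spiked_duplication_called_as_gain(self):
        _, _, calls = pipeline(
            DepthConfig(seed=13, targets=TARGETS_WITH_513, spikes=[(100_000, 100_513, 1.5)])
        )
        gains = [c for c in calls if c.direction == "gain"]
        assert len(gains) == 1
        overlap = min(gains[0].end, 100_513) - max(gains[0].start, 100_000)
        assert overlap >= 0.9 * 513
        assert gains[0].mean_log2 == pytest.approx(np.log2(1.5), abs=0.1)
        assert "t001" in gains[0].targets_hit

    def test_hemizygous_deletion_called_as_loss_near_minus_one(self):
        _, _, calls = pipeline(
            DepthConfig(seed=13, targets=TARGETS_WITH_513, spikes=[(100_000, 100_513, 0.5)])
        )
        losses = [c for c in calls if c.direction == "loss"]
        assert len(losses) == 1
        assert losses[0].mean_log2 == pytest.approx(-1.0, abs=0.15)

    def test_calls_confined_to_targets_on_observed_positions(self):
        bundle, ratio, calls = pipeline(
            DepthConfig(seed=5, targets=TARGETS_WITH_513, spikes=[(100_000, 100_513, 2.0)])
        )
        position_set = set(ratio.positions.tolist())
        for call in calls:
            assert call.start + 1 in position_set and call.end in position_set
            assert any(
                ts <= call.start and call.end <= te for _, ts, te, _ in bundle.targets
            )

    def test_detection_power_monotone_in_depth_and_ratio(self):
        # ratio 1.25 sits below the 0.4 log2 threshold (log2 1.25 = 0.32) and
        # should essentially never be called; 1.5 and 2.0 are well above it
        rates = {}
        for depth in (20, 50, 100):
            for copy_ratio in (1.25, 1.5, 2.0):
                hits = 0
                for seed in range(5):
                    _, _, calls = pipeline(
                        DepthConfig(
                            seed=1000 * depth + seed,
                            depth=float(depth),
                            targets=TARGETS_WITH_513,
                            spikes=[(100_000, 100_513, copy_ratio)],
                        )
                    )
                    hits += any(
                        c.direction == "gain"
                        and min(c.end, 100_513) - max(c.start, 100_000) >= 0.5 * 513
                        for c in calls
                    )
                rates[depth, copy_ratio] = hits
        for depth in (20, 50, 100):
            assert rates[depth, 1.25] <= rates[depth, 1.5] <= rates[depth, 2.0]
        for copy_ratio in (1.25, 1.5, 2.0):
            assert rates[20, copy_ratio] <= rates[100, copy_ratio] + 1

    def test_merge_gap_joins_interrupted_runs(self):
        from chromolens.coverage import RatioTrack

        n = 400
        values = np.full(n, 1.0)
        values[190:210] = 0.0  # a 20-position dip inside a long elevated run
        ratio = RatioTrack("chrT", np.arange(1, n + 1), values, np.zeros(n, dtype=bool))
        calls = call_focal_events(
            ratio, [("chrT", 0, n, "t1")], min_positions=100, merge_gap=50, smooth_window=1
        )
        assert len(calls) == 1
        assert calls[0].n_positions == n
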