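"""Generator behaviour: determinism, calibration, kernel shape, perturbations."""

import dataclasses

import numpy as np
import pytest

import cavnet as cn


class TestGenerateNetwork:
    def test_community_sizes_and_count(self):
        net = cn.generate_network(36, 3, seed=1)
        assert net.n_clusters == 36
        assert net.n_communities == 3
        sizes = np.bincount(net.community_of)
        assert sizes.max() <= 3 * sizes.min()

    def test_two_singleton_communities(self):
        net = cn.generate_network(2, 2, seed=0)
        assert sorted(net.community_of.tolist()) == [0, 1]

    def test_seed_determinism(self):
        a = cn.generate_network(30, 2, seed=7)
        b = cn.generate_network(30, 2, seed=7)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.community_of, b.community_of)

    def test_spatial_contiguity(self):
        # members of a community are closer to their own centroid than to
        # the farthest-away community centroid on average
        net = cn.generate_network(40, 4, seed=3)
        centroids = np.array(
            [net.positions[net.members(c)].mean(axis=0) for c in range(4)]
        )
        for c in range(4):
            pts = net.positions[net.members(c)]
            own = np.linalg.norm(pts - centroids[c], axis=1).mean()
            others = [
                np.linalg.norm(pts - centroids[o], axis=1).mean()
                for o in range(4)
                if o != c
            ]
            assert own < max(others)

    @pytest.mark.parametrize("args", [(1, 1), (5, 6), (3, 0)])
    def test_invalid_counts_raise(self, args):
        with pytest.raises(ValueError):
            cn.generate_network(args[0], args[1], seed=0)


class TestSimulateActivity:
    def test_determinism(self):
        net = cn.generate_network(20, 2, seed=4)
        a, ev_a = cn.simulate_activity(net, 600.0, seed=5)
        b, ev_b = cn.simulate_activity(net, 600.0, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert len(ev_a) == len(ev_b)

    def test_zero_participation_gives_silence(self):
        net = cn.generate_network(
            10, 2, seed=0, participation=0.0, cross_participation=0.0,
            bridge_fraction=0.0, independent_rate=0.0,
        )
        onsets, events = cn.simulate_activity(net, 600.0, seed=1)
        assert all(len(t) == 0 for t in onsets)
        assert events == []

    def test_event_rate_matches_ignition_rate(self):
        # law of large numbers on the renewal process: 10 000 simulated
        # minutes at 1 event/min
        net = cn.generate_network(
            6, 1, seed=2, ignition_rate=1.0, participation=1.0,
            independent_rate=0.0,
        )
        duration = 600_000.0
        _, events = cn.simulate_activity(net, duration, seed=3)
        n = len(events)
        expect = duration / 60.0
        assert abs(n - expect) <= 3.0 * np.sqrt(expect)

    def test_rate_calibration_in_printed_ranges(self):
        # per-cluster rates 1-2/min, sequences ~100 ms and 5-15 clusters,
        # separated by 1-10 s, for >= 90% of simulated cavities
        ok = 0
        n_cavities = 10
        for seed in range(n_cavities):
            net = cn.generate_network(36, 3, seed=seed)
            onsets, _ = cn.simulate_activity(net, 1800.0, seed=100 + seed)
            trains = [cn.OnsetTrain(i, t) for i, t in enumerate(onsets)]
            seqs = cn.detect_sequences(trains)
            rate = np.mean([60.0 * len(t) / 1800.0 for t in onsets])
            size = np.mean([s.size for s in seqs])
            dur = np.mean([s.duration for s in seqs])
            gap = np.mean(np.diff([s.start for s in seqs]))
            if 1.0 <= rate <= 2.0 and 5 <= size <= 15 and 0.05 <= dur <= 0.15 \
                    and 1.0 <= gap <= 10.0:
                ok += 1
        assert ok >= 0.9 * n_cavities

    def test_onsets_within_duration_and_sorted(self, small_cavity):
        for t in small_cavity["onsets"]:
            assert np.all(np.diff(t) > 0)
            if len(t):
                assert 0 <= t[0] and t[-1] < small_cavity["duration"]


class TestRenderTraces:
    def test_single_onset_peak_position(self):
        rec = cn.render_traces(
            [np.array([1.0])], noise_sd=0.0, seed=0, duration=4.0
        )
        peak = rec.traces[:, 0].argmax() * rec.frame_dt
        assert 1.0 <= peak <= 1.0 + 0.05 + 1e-9

    def test_empty_train_renders_zero(self):
        rec = cn.render_traces([np.array([])], noise_sd=0.0, seed=0, duration=2.0)
        assert np.all(rec.traces == 0)

    def test_superposition_residual(self):
        # 5 s apart with a 1 s decay: second peak within 1% of the first
        rec = cn.render_traces(
            [np.array([1.0, 6.0])],
            kernel=cn.CalciumKernel(rise_ms=50, decay_ms=1000),
            noise_sd=0.0, seed=0, duration=12.0,
        )
        t = rec.time
        p1 = rec.traces[(t >= 1.0) & (t < 3.0), 0].max()
        p2 = rec.traces[(t >= 6.0) & (t < 8.0), 0].max()
        assert abs(p2 - p1) / p1 < 0.01

    def test_determinism_and_noise(self):
        on = [np.array([0.5]), np.array([1.5])]
        a = cn.render_traces(on, noise_sd=0.05, seed=9, duration=3.0)
        b = cn.render_traces(on, noise_sd=0.05, seed=9, duration=3.0)
        assert np.array_equal(a.traces, b.traces)

    def test_invalid_kernel(self):
        with pytest.raises(ValueError):
            cn.CalciumKernel(rise_ms=100, decay_ms=50)


class TestApplyPerturbation:
    def test_identity_spec_changes_nothing(self):
        net = cn.generate_network(20, 2, seed=1)
        out = cn.apply_perturbation(net, cn.PerturbationSpec(), seed=2)
        assert np.array_equal(out.participation, net.participation)
        assert np.array_equal(out.independent_rate, net.independent_rate)

    def test_full_silencing_kills_all_activity(self):
        net = cn.generate_network(12, 2, seed=1)
        out = cn.apply_perturbation(
            net, cn.PerturbationSpec(silenced_fraction=1.0), seed=2
        )
        onsets, _ = cn.simulate_activity(out, 600.0, seed=3)
        assert all(len(t) == 0 for t in onsets)

    def test_conserves_structure_and_input(self):
        net = cn.generate_network(20, 3, seed=1)
        before = net.participation.copy()
        out = cn.apply_perturbation(
            net,
            cn.PerturbationSpec(silenced_fraction=0.3, weaken_factor=0.5,
                                boosted_fraction=0.1, boost_factor=3.0),
            seed=4,
        )
        assert out.n_clusters == net.n_clusters
        assert np.array_equal(out.community_of, net.community_of)
        assert np.array_equal(net.participation, before)  # input untouched

    def test_cross_weakening_lowers_sequence_rate(self):
        # same seed on both conditions: common-random-numbers comparison
        net = cn.generate_network(36, 3, seed=6)
        weak = cn.apply_perturbation(
            net, cn.PerturbationSpec(weaken_factor=0.3), seed=7
        )
        base_onsets, _ = cn.simulate_activity(net, 1800.0, seed=8)
        weak_onsets, _ = cn.simulate_activity(weak, 1800.0, seed=8)
        m_base = len(cn.detect_sequences([cn.OnsetTrain(i, t) for i, t in enumerate(base_onsets)]))
        m_weak = len(cn.detect_sequences([cn.OnsetTrain(i, t) for i, t in enumerate(weak_onsets)]))
        assert m_weak < m_base

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            cn.PerturbationSpec(silenced_fraction=1.5)
        with pytest.raises(ValueError):
            cn.PerturbationSpec(weaken_factor=-0.1)
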