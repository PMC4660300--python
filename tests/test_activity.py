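"""Firing-rate statistics, drift correction and difference summaries."""

import dataclasses

import numpy as np
import pytest

import cavnet as cn


def _summary(phi, Psi=1.0, duration=1800.0, ids=None):
    phi = np.asarray(phi, float)
    ids = tuple(range(len(phi))) if ids is None else tuple(ids)
    return cn.ActivitySummary(
        cluster_ids=ids, phi=phi, Phi=float(phi.mean()), Psi=Psi, duration=duration
    )


class TestSummarize:
    def test_rate_arithmetic(self):
        trains = [cn.OnsetTrain(0, np.linspace(1, 1780, 45))]
        s = cn.summarize_activity(trains, [], 1800.0)
        assert s.phi[0] == pytest.approx(1.5)

    def test_all_silent(self):
        trains = [cn.OnsetTrain(i, np.empty(0)) for i in range(4)]
        s = cn.summarize_activity(trains, [], 600.0)
        assert s.Phi == 0.0 and s.Psi == 0.0

    def test_default_cavity_in_printed_range(self, small_cavity):
        s = cn.summarize_activity(
            small_cavity["trains"], small_cavity["sequences"], 1800.0
        )
        assert 1.0 <= s.Phi <= 2.0


class TestDriftCorrection:
    def test_stable_control_is_identity(self):
        p0, p1 = _summary([1.0, 2.0]), _summary([1.5, 2.5], Psi=2.0)
        c = _summary([1.0, 1.0], Psi=1.0)
        corrected, model = cn.drift_correct(p0, p1, c, c)
        assert model.r_phi == 1.0
        np.testing.assert_allclose(corrected.phi, p1.phi)

    def test_doubling_control_cancels(self):
        p0 = _summary([1.0, 1.0], Psi=1.0)
        p1 = _summary([2.0, 2.0], Psi=2.0)
        c0 = _summary([1.0, 1.0], Psi=1.0)
        c1 = _summary([2.0, 2.0], Psi=2.0)
        corrected, model = cn.drift_correct(p0, p1, c0, c1)
        assert model.r_phi == 2.0
        assert corrected.Phi / p0.Phi == pytest.approx(1.0)
        assert corrected.Psi / p0.Psi == pytest.approx(1.0)

    def test_silent_control_raises(self):
        p = _summary([1.0, 1.0])
        silent = _summary([0.0, 0.0], Psi=0.0)
        with pytest.raises(ValueError, match="control"):
            cn.drift_correct(p, p, silent, p)

    def test_scale_equivariance(self):
        # multiplying every second-recording rate by c leaves corrected
        # ratios unchanged
        rng = np.random.default_rng(0)
        p0 = _summary(rng.uniform(0.5, 2.0, 10), Psi=3.0)
        p1 = _summary(rng.uniform(0.5, 2.0, 10), Psi=2.0)
        c0 = _summary(rng.uniform(0.5, 2.0, 10), Psi=4.0)
        c1 = _summary(rng.uniform(0.5, 2.0, 10), Psi=3.5)
        base, _ = cn.drift_correct(p0, p1, c0, c1)
        c = 1.2
        scale = lambda s: dataclasses.replace(s, phi=s.phi * c, Phi=s.Phi * c, Psi=s.Psi * c)
        scaled, _ = cn.drift_correct(p0, scale(p1), c0, scale(c1))
        np.testing.assert_allclose(scaled.phi, base.phi)
        assert scaled.Psi == pytest.approx(base.Psi)

    @pytest.mark.parametrize("rho", [0.5, 1.0])
    def test_programmed_ratio_recovery(self, rho):
        # programmed after/before activity ratio rho, plus a global x1.2
        # drift on all second recordings; the corrected ratio must recover
        # rho within 10% (8 wells averaged)
        drift = 1.2
        ratios = []
        for well in range(8):
            net = cn.generate_network(36, 3, seed=well)
            after_net = dataclasses.replace(
                net,
                ignition_rate=net.ignition_rate * rho * drift,
                independent_rate=net.independent_rate * rho * drift,
            )
            control_after = dataclasses.replace(
                net,
                ignition_rate=net.ignition_rate * drift,
                independent_rate=net.independent_rate * drift,
            )
            summaries = {}
            for key, n, s in [
                ("p0", net, 1000 + well), ("p1", after_net, 2000 + well),
                ("c0", net, 3000 + well), ("c1", control_after, 4000 + well),
            ]:
                onsets, _ = cn.simulate_activity(n, 1800.0, seed=s)
                trains = [cn.OnsetTrain(i, t) for i, t in enumerate(onsets)]
                summaries[key] = cn.summarize_activity(
                    trains, cn.detect_sequences(trains), 1800.0
                )
            corrected, _ = cn.drift_correct(
                summaries["p0"], summaries["p1"], summaries["c0"], summaries["c1"]
            )
            ratios.append(corrected.Phi / summaries["p0"].Phi)
        assert np.mean(ratios) == pytest.approx(rho, rel=0.10)


class TestDifferenceSummary:
    def test_no_change_gives_zero(self):
        s = _summary([1.0, 2.0, 3.0])
        d = cn.difference_summary(s, s)
        assert np.all(d.delta_phi_norm == 0)
        assert d.gamma == 0.0

    def test_silenced_cluster_boundary(self):
        before = _summary([1.0, 1.0, 1.0])
        after = _summary([0.0, 1.0, 1.0])
        d = cn.difference_summary(before, after)
        assert d.delta_phi_norm[0] == -1.0

    def test_silent_in_both_is_zero(self):
        before = _summary([0.0, 1.0])
        after = _summary([0.0, 2.0])
        d = cn.difference_summary(before, after)
        assert d.delta_phi_norm[0] == 0.0

    def test_bounded_and_antisymmetric(self):
        rng = np.random.default_rng(1)
        a = _summary(rng.uniform(0, 3, 30))
        b = _summary(rng.uniform(0, 3, 30))
        d_ab = cn.difference_summary(a, b)
        d_ba = cn.difference_summary(b, a)
        assert np.all(np.abs(d_ab.delta_phi_norm) <= 1.0)
        np.testing.assert_allclose(d_ab.delta_phi_norm, -d_ba.delta_phi_norm)

    def test_mismatched_clusters_raise(self):
        with pytest.raises(ValueError):
            cn.difference_summary(
                _summary([1.0], ids=["a"]), _summary([1.0], ids=["b"])
            )

    def test_left_skew_under_silencing_perturbation(self):
        # 30% silencing with weakened coupling: distribution piles up at -1
        before = _summary(np.full(30, 1.5))
        phi_after = np.full(30, 1.0)
        phi_after[:9] = 0.0
        d = cn.difference_summary(before, _summary(phi_after))
        assert d.gamma < 0
        assert np.mean(d.delta_phi_norm) < 0


class TestCompareConditions:
    def test_identical_samples_ks(self):
        x = np.arange(10.0)
        assert cn.compare_conditions(x, x, test="KS") == pytest.approx(1.0)

    def test_zero_shift_t(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cn.compare_conditions(x, x, test="t") == pytest.approx(1.0)

    def test_power_on_separated_gaussians(self):
        hits = 0
        n_runs = 50
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 15)
            b = rng.normal(3, 1, 15)
            if cn.compare_conditions(a, b, test="t") < 0.005:
                hits += 1
        assert hits >= 0.95 * n_runs

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            cn.compare_conditions([1.0], [1.0, 2.0])

    def test_stars(self):
        assert cn.significance_stars(0.04) == "*"
        assert cn.significance_stars(0.004) == "**"
        assert cn.significance_stars(0.5) == ""
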