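import numpy as np
import pytest

from popcode import peth as pe
from tests.conftest import poisson_train


class TestBuildPeth:
    def test_exactly_100_bins(self):
        p = pe.build_peth(np.array([5.0]), np.array([5.0]), 10.0)
        assert p.n_bins == 100
        np.testing.assert_allclose(p.bin_edges[0], -1.0)
        np.testing.assert_allclose(p.bin_edges[-1], 1.0)

    def test_spike_at_onset_in_first_post_bin(self):
        p = pe.build_peth(np.array([5.0]), np.array([5.0]), 10.0)
        post_idx = 50  # bin [0, 20 ms)
        assert p.rates[0, post_idx] == pytest.approx(1 / 0.02)
        assert p.rates[0, post_idx - 1] == 0.0

    def test_homogeneous_poisson_rate(self, rng):
        rate, duration = 10.0, 800.0
        spikes = poisson_train(rate, duration, rng)
        events = rng.uniform(1.5, duration - 1.5, 200)
        p = pe.build_peth(spikes, events, duration)
        mean_rate = p.trial_mean().mean()
        se = np.sqrt(rate / (0.02 * 200 * 100))
        assert abs(mean_rate - rate) < 3 * se

    def test_needs_an_event(self):
        with pytest.raises(ValueError, match="event"):
            pe.build_peth(np.array([1.0]), np.array([]), 10.0)

    def test_edge_events_masked_not_dropped(self):
        p = pe.build_peth(np.array([0.3]), np.array([0.5]), 10.0)
        assert not p.mask[0, :20].any()   # bins before t=0 masked
        assert p.mask[0, 30:].all()

    def test_cross_cycle_masking(self):
        # event at 10 s owns the epoch starting right after it; the epoch at
        # [8.5, 9.3] belongs to the previous cycle and must be masked
        orom = np.array([[8.5, 9.3], [10.05, 11.0]])
        p = pe.build_peth(np.array([5.0]), np.array([10.0]), 20.0, orom)
        centers = p.bin_centers + 10.0
        foreign = (centers > 8.5) & (centers < 9.3)
        assert not p.mask[0, foreign].any()
        own = (centers > 10.1) & (centers < 10.9)
        assert p.mask[0, own].all()

    def test_total_count_matches_interval_oracle(self, rng):
        spikes = poisson_train(20.0, 60.0, rng)
        events = np.array([10.0, 30.0, 50.0])
        p = pe.build_peth(spikes, events, 60.0)
        for i, t_e in enumerate(events):
            direct = np.sum((spikes >= t_e - 1.0) & (spikes < t_e + 1.0))
            got = np.nansum(p.rates[i]) * 0.02
            assert got == pytest.approx(direct)


class TestBootstrapSignificance:
    def test_zero_spike_unit_p1(self):
        p = pe.bootstrap_significance(np.array([]), np.array([5.0]), 100.0,
                                      n_boot=10, seed=0)
        assert p == 1.0

    def test_smallest_p_is_zero(self, rng):
        # a huge response: no sham maximum can beat it
        events = np.array([50.0, 150.0, 250.0])
        spikes = np.sort(np.concatenate([
            poisson_train(1.0, 300.0, rng),
            np.concatenate([e + rng.uniform(0, 0.1, 200) for e in events]),
        ]))
        p = pe.bootstrap_significance(spikes, events, 300.0, n_boot=1000, seed=1)
        assert p == 0.0

    def test_power_gain_detected(self, rng):
        # 5x rate gain in a 200 ms window at onset, 30 events, 10 Hz baseline
        duration = 600.0
        events = np.sort(rng.uniform(2.0, duration - 2.0, 30))
        base = poisson_train(10.0, duration, rng)
        extra = np.concatenate([
            e + rng.uniform(0.0, 0.2, rng.poisson(40.0 * 0.2)) for e in events
        ])
        spikes = np.sort(np.concatenate([base, extra]))
        p = pe.bootstrap_significance(spikes, events, duration, n_boot=1000,
                                      seed=2)
        assert p < 0.001

    def test_null_p_uniform(self, rng):
        # With randomized tie-breaking the null rank is exactly exchangeable,
        # so p is discrete-uniform on {0, 1/n, ..., 1}: KS bound at alpha=0.01
        # over 300 null Poisson units.  The default strict counting rule is
        # stochastically smaller (ties favor significance), checked alongside.
        duration = 400.0
        p_rand, p_strict = [], []
        for i in range(300):
            spikes = poisson_train(8.0, duration, rng)
            events = np.sort(rng.uniform(1.0, duration - 1.0, 20))
            kw = dict(n_boot=200, seed=i)
            p_rand.append(pe.bootstrap_significance(
                spikes, events, duration, tie_break="randomized", **kw))
            p_strict.append(pe.bootstrap_significance(
                spikes, events, duration, tie_break="strict", **kw))
        assert all(s <= r for s, r in zip(p_strict, p_rand))
        pvals = np.sort(p_rand)
        grid = np.arange(0, 1.001, 1 / 200)
        emp = np.searchsorted(pvals, grid, side="right") / len(pvals)
        # discrete uniform on {0, 1/200, ..., 1} has CDF (k+1)/201 at k/200
        disc = (np.round(grid * 200) + 1) / 201
        D = np.abs(emp - disc).max()
        assert D < 1.63 / np.sqrt(len(pvals))  # asymptotic 1% critical value

    def test_mask_applied_symmetrically(self, rng):
        spikes = poisson_train(15.0, 200.0, rng)
        events = np.array([50.0, 100.0])
        orom = np.array([[48.0, 49.0], [100.05, 101.0]])
        p1 = pe.bootstrap_significance(spikes, events, 200.0, n_boot=50,
                                       seed=3, orom_epochs=orom)
        assert 0.0 <= p1 <= 1.0


class TestBaselineSubtract:
    def test_constant_rate_cancels(self, rng):
        spikes = poisson_train(25.0, 500.0, rng)
        events = np.sort(rng.uniform(2.0, 498.0, 100))
        p = pe.build_peth(spikes, events, 500.0)
        bs = pe.baseline_subtract(p)
        assert abs(np.nanmean(bs.trial_mean())) < 1.0

    def test_occupied_baseline_drops_trial(self):
        # previous oromanual epoch covers the whole baseline window
        orom = np.array([[8.9, 9.85], [10.05, 11.0]])
        p = pe.build_peth(np.array([5.0]), np.array([10.0]), 20.0, orom)
        bs = pe.baseline_subtract(p, orom)
        assert bs.n_trials == 0

    def test_three_trial_hand_computation(self):
        # constructed spikes: trial baselines 2.5, 0, 5 Hz (hand-computed)
        events = np.array([10.0, 30.0, 50.0])
        spikes = np.sort(np.concatenate([
            10.0 + np.array([-0.9, -0.5]),          # 2 spikes in 0.8 s baseline
            [10.0 + 0.01],                            # 1 spike in first post bin
            [30.0 + 0.01],
            50.0 + np.array([-0.95, -0.75, -0.55, -0.35]),  # 4 spikes
        ]))
        p = pe.build_peth(spikes, events, 60.0)
        bs = pe.baseline_subtract(p)
        np.testing.assert_allclose(bs.baseline, [2.5, 0.0, 5.0])
        # first post-onset bin of trial 0: 50 Hz - 2.5 Hz
        assert bs.rates[0, 50] == pytest.approx(50.0 - 2.5)

    def test_commutes_with_averaging_on_complete_trials(self, rng):
        spikes = poisson_train(30.0, 300.0, rng)
        events = np.sort(rng.uniform(2.0, 298.0, 40))
        p = pe.build_peth(spikes, events, 300.0)
        bs = pe.baseline_subtract(p)
        route1 = bs.trial_mean()
        route2 = p.trial_mean() - np.mean(bs.baseline)
        np.testing.assert_allclose(route1, route2, atol=1e-12)


class TestZscore:
    def test_all_zero_guarded(self):
        p = pe.Peth(rates=np.zeros((3, 100)), mask=np.ones((3, 100), bool),
                    bin_edges=pe._bin_edges(), event_times=np.arange(3.0))
        z = pe.zscore_peth(p)
        np.testing.assert_array_equal(z.rates, 0.0)

    def test_scale_invariance(self, rng):
        rates = rng.normal(0, 5, (4, 100))
        base = pe.Peth(rates=rates, mask=np.ones((4, 100), bool),
                       bin_edges=pe._bin_edges(), event_times=np.arange(4.0))
        scaled = pe.Peth(rates=rates * 10, mask=base.mask,
                         bin_edges=base.bin_edges, event_times=base.event_times)
        np.testing.assert_allclose(pe.zscore_peth(base).rates,
                                   pe.zscore_peth(scaled).rates, atol=1e-12)

    def test_two_trial_hand_computation(self):
        rates = np.zeros((2, 100))
        rates[0, 50] = 10.0
        rates[1, 50] = 20.0   # trial mean has one bin at 15, rest 0
        p = pe.Peth(rates=rates, mask=np.ones((2, 100), bool),
                    bin_edges=pe._bin_edges(), event_times=np.arange(2.0))
        tm = p.trial_mean()
        sd = float(np.std(tm))  # hand: sqrt(mean(tm^2) - mean(tm)^2)
        z = pe.zscore_peth(p)
        assert z.trial_mean()[50] == pytest.approx(15.0 / sd)


class TestResponsivenessCategories:
    def test_all_three_significant(self):
        assert pe.venn_category(True, True, True) == "all"

    def test_none_category(self):
        assert pe.venn_category(False, False, False) == "none"

    @pytest.mark.parametrize("flags,expected", [
        ((True, False, False), "ipsi_only"),
        ((False, True, False), "contra_only"),
        ((False, False, True), "bi_only"),
        ((True, True, False), "ipsi+contra"),
        ((True, False, True), "ipsi+bi"),
        ((False, True, True), "contra+bi"),
    ])
    def test_venn_enumeration(self, flags, expected):
        assert pe.venn_category(*flags) == expected

    def test_missing_condition_excluded(self):
        pvals = {
            "u0": {"ipsilateral": 0.0, "contralateral": 0.5, "bimanual": 0.5},
            "u1": {"ipsilateral": 0.0},   # untested in two conditions
        }
        cats, props = pe.categorize_responsiveness(pvals)
        assert cats["u1"] == "untested"
        assert props["ipsi_only"] == pytest.approx(1.0)

    def test_planted_contra_only_proportion(self, rng):
        # 30% of units respond only to the contralateral condition; the
        # recovered proportion must land within 5 points over 200 units.
        duration = 300.0
        n_units, frac = 200, 0.3
        events = {c: np.sort(rng.uniform(2.0, duration - 2.0, 25))
                  for c in ("ipsilateral", "contralateral", "bimanual")}
        pvals = {}
        for i in range(n_units):
            responder = i < frac * n_units
            base = poisson_train(6.0, duration, rng)
            if responder:
                extra = np.concatenate([
                    e + rng.uniform(0, 0.15, rng.poisson(60.0 * 0.15))
                    for e in events["contralateral"]
                ])
                spikes = np.sort(np.concatenate([base, extra]))
            else:
                spikes = base
            pvals[f"u{i}"] = {
                c: pe.bootstrap_significance(spikes, events[c], duration,
                                             n_boot=500, seed=1000 + i)
                for c in events
            }
        _, props = pe.categorize_responsiveness(pvals, alpha=0.002)
        assert abs(props["contra_only"] - frac) < 0.05
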