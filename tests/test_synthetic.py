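import numpy as np
import pytest
from scipy import stats as sps

from esn.rate import episode_rates
from esn.session import AnalysisWindow, SpikeTrain, count_spikes
from esn.synthetic import (
    ConfigError,
    PlantedESN,
    SyntheticConfig,
    circular_surrogate,
    generate_pseudo_rates,
    generate_session,
    random_spike_times,
)


class TestGenerateSession:
    def test_same_seed_is_byte_identical(self):
        cfg = SyntheticConfig(n_units=3, n_episodes=16, episodes_per_block=8, seed=11)
        s1, t1 = generate_session(cfg)
        s2, t2 = generate_session(cfg)
        for a, b in zip(s1.units, s2.units):
            assert np.array_equal(a.spike_times, b.spike_times)
        assert t1.equals(t2)
        assert [e.__dict__ for e in s1.episodes] == [e.__dict__ for e in s2.episodes]

    def test_baseline_poisson_mean(self):
        cfg = SyntheticConfig(n_units=2, n_episodes=16, episodes_per_block=8, base_rate_hz=2.0, seed=3)
        session, _ = generate_session(cfg)
        dur = session.duration_s
        counts = []
        starts = np.linspace(0, dur - 4.0, 500)
        for u in session.units:
            for s in starts:
                counts.append(count_spikes(u, AnalysisWindow(s, s + 4.0)))
        mean = np.mean(counts)
        # 2 Hz x 4 s -> 8, with overlapping-window correlation inflating the s.e.
        assert abs(mean - 8.0) < 0.5

    def test_planted_esn_dominates_episode_rates(self):
        hits = 0
        n = 50
        for seed in range(n):
            cfg = SyntheticConfig(
                n_units=1, n_episodes=20, episodes_per_block=10, base_rate_hz=2.0,
                seed=seed, planted_esn=[PlantedESN(0, 3, rate_gain=5.0)],
            )
            s, _ = generate_session(cfg)
            enc = episode_rates(s.units[0], s.episodes, "encoding")
            ret = episode_rates(s.units[0], s.episodes, "retrieval")
            idx = [e.episode_id for e in s.episodes].index("ep003")
            hits += int(np.argmax(enc) == idx and np.argmax(ret) == idx)
        assert hits >= 0.9 * n

    def test_planted_episode_forced_remembered(self):
        cfg = SyntheticConfig(
            n_units=1, n_episodes=20, episodes_per_block=10, hit_rate=0.05,
            seed=5, planted_esn=[PlantedESN(0, 7, rate_gain=5.0)],
        )
        s, _ = generate_session(cfg)
        ep = {e.episode_id: e for e in s.episodes}["ep007"]
        assert ep.remembered

    def test_gain_at_most_one_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(planted_esn=[PlantedESN(0, 0, rate_gain=1.0)])

    def test_hit_rate_matches_label_frequency(self):
        cfg = SyntheticConfig(n_units=1, n_episodes=400, episodes_per_block=20, seed=2, hit_rate=0.68)
        s, _ = generate_session(cfg)
        assert abs(s.remembered_mask.mean() - 0.68) < 0.06


class TestPseudoRates:
    def test_open_interval_and_shape(self, rng):
        m = generate_pseudo_rates(585, 40, 2.0, rng)
        for x in (m.enc, m.ret):
            assert x.shape == (585, 40)
            assert np.all(x > 0) and np.all(x < 2.0)

    def test_uniform_moments(self, rng):
        m = generate_pseudo_rates(1000, 1000, 4.0, rng)
        assert abs(m.enc.mean() - 2.0) < 0.01
        assert abs(m.enc.var() - 16.0 / 12.0) < 0.01 * 16 / 12 + 0.01

    def test_invalid_inputs(self, rng):
        with pytest.raises(ConfigError):
            generate_pseudo_rates(5, 1, 2.0, rng)
        with pytest.raises(ConfigError):
            generate_pseudo_rates(5, 10, 0.0, rng)


class TestCircularSurrogate:
    def test_identity_rotation(self, planted_session):
        session, _ = planted_session
        out = circular_surrogate(session, np.random.default_rng(0), offset=0)
        for a, b in zip(session.units, out.units):
            assert np.allclose(a.spike_times, b.spike_times)

    def test_spike_counts_preserved(self, planted_session, rng):
        session, _ = planted_session
        out = circular_surrogate(session, rng)
        for a, b in zip(session.units, out.units):
            assert a.n_spikes == b.n_spikes

    def test_rotation_group_property(self, planted_session):
        """Rotating by k then by n_segments - k restores within-window spikes."""
        session, _ = planted_session
        n_seg = 2 * session.n_episodes
        once = circular_surrogate(session, np.random.default_rng(0), offset=5)
        back = circular_surrogate(once, np.random.default_rng(0), offset=n_seg - 5)
        windows = [w for ep in session.episodes for w in (ep.encoding_window, ep.retrieval_window)]
        for a, b in zip(session.units, back.units):
            for w in windows:
                lo, hi = np.searchsorted(a.spike_times, [w.start_s, w.end_s])
                lo2, hi2 = np.searchsorted(b.spike_times, [w.start_s, w.end_s])
                assert np.allclose(a.spike_times[lo:hi], b.spike_times[lo2:hi2], atol=1e-6)

    def test_session_granularity_conserves_counts(self, planted_session, rng):
        session, _ = planted_session
        out = circular_surrogate(session, rng, granularity="session")
        for a, b in zip(session.units, out.units):
            assert a.n_spikes == b.n_spikes


class TestRandomSpikeTimes:
    def test_range_and_count_contract(self, rng):
        t = np.sort(rng.uniform(3.4, 997.6, size=100))
        t[0], t[-1] = 3.4, 997.6
        train = SpikeTrain("u", "hippocampus", t)
        out = random_spike_times(train, rng)
        assert out.n_spikes == 100
        assert out.spike_times.min() >= 3 and out.spike_times.max() <= 998
        assert np.all(out.spike_times == np.round(out.spike_times))

    def test_degenerate_range_rejected(self, rng):
        train = SpikeTrain("u", "hippocampus", np.array([5.1, 5.2]))
        with pytest.raises(ValueError, match="degenerate"):
            random_spike_times(train, rng)

    def test_distribution_is_discrete_uniform(self, rng):
        t = np.sort(rng.uniform(0.0, 50.0, size=10_000))
        t[0], t[-1] = 0.0, 50.0
        out = random_spike_times(SpikeTrain("u", "hippocampus", t), rng)
        # KS distance between the empirical CDF and discrete uniform on 0..50
        values = np.arange(0, 51)
        cdf = np.searchsorted(out.spike_times, values, side="right") / out.n_spikes
        expect = (values + 1) / 51
        assert np.max(np.abs(cdf - expect)) < 0.02
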