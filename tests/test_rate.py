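import itertools

import numpy as np
import pytest

from esn.config import AnalysisConfig
from esn.rate import (
    ConstantRateError,
    ZRateVectors,
    compute_z_vectors,
    cue_response_exclusion,
    detect_esn_session,
    episode_rates,
    flag_esn,
    group_test,
    miss_esn_bootstrap,
    reinstatement_values,
    restrict_episodes,
    shuffle_threshold,
    zscore,
)
from esn.session import SpikeTrain
from esn.synthetic import PlantedESN, SyntheticConfig, generate_session

from conftest import make_episode


def zv(enc, ret, unit="u0"):
    enc = np.asarray(enc, dtype=float)
    return ZRateVectors(unit, [f"e{i}" for i in range(enc.size)], enc, np.asarray(ret, dtype=float))


class TestEpisodeRates:
    def test_rate_is_count_over_duration(self):
        ep = make_episode(0, 10.0, enc_dur=4.0)
        spikes = np.linspace(12.1, 15.9, 8)  # inside [assoc=12, response=16)
        train = SpikeTrain("u", "hippocampus", spikes)
        assert episode_rates(train, [ep], "encoding")[0] == pytest.approx(2.0)

    def test_encoding_window_starts_at_associate_onset(self):
        # a spike 1 s after the cue precedes the associates and must not count
        ep = make_episode(0, 10.0, enc_dur=4.0)
        train = SpikeTrain("u", "hippocampus", np.array([11.0]))
        assert episode_rates(train, [ep], "encoding")[0] == 0.0

    def test_against_linear_scan_oracle(self, planted_session):
        session, _ = planted_session
        train = session.units[0]
        for phase in ("encoding", "retrieval"):
            rates = episode_rates(train, session.episodes, phase)
            for i, ep in enumerate(session.episodes):
                if phase == "encoding":
                    lo, hi = ep.enc_assoc_onset_s, ep.enc_response_s
                else:
                    lo, hi = ep.ret_cue_onset_s, ep.ret_response_s
                n = np.sum((train.spike_times >= lo) & (train.spike_times < hi))
                assert rates[i] == pytest.approx(n / (hi - lo))


class TestZScore:
    def test_sample_sd_convention(self):
        assert np.allclose(zscore(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])

    def test_constant_rates_signal_exclusion(self):
        with pytest.raises(ConstantRateError):
            zscore(np.full(10, 3.0))

    def test_output_moments(self, rng):
        x = rng.uniform(0, 10, size=37)
        z = zscore(x)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1.0) < 1e-9


class TestRestrictEpisodes:
    def test_restriction_after_zscoring(self):
        episodes = [make_episode(i, 10.0 + 20.0 * i, remembered=(i < 14)) for i in range(20)]
        z = zv(np.arange(20.0), np.arange(20.0)[::-1])
        out = restrict_episodes(z, episodes, "remembered")
        assert out.n_episodes == 14
        assert np.array_equal(out.z_enc, z.z_enc[:14])

    def test_unit_dropped_below_eight_episodes(self):
        episodes = [make_episode(i, 10.0 + 20.0 * i, remembered=(i < 6)) for i in range(20)]
        z = zv(np.arange(20.0), np.arange(20.0))
        assert restrict_episodes(z, episodes, "remembered") is None

    def test_zscore_then_restrict_differs_from_restrict_then_zscore(self):
        """The pipeline standardizes over ALL episodes, then subsets."""
        episodes = [make_episode(i, 10.0 + 20.0 * i, remembered=(i != 0)) for i in range(9)]
        rates = np.array([50.0, 1, 2, 3, 4, 5, 6, 7, 8])  # forgotten outlier episode 0
        train_like = zscore(rates)
        z = zv(train_like, train_like)
        kept = restrict_episodes(z, episodes, "remembered")
        alternative = zscore(rates[1:])
        assert not np.allclose(kept.z_enc, alternative)
        assert np.array_equal(kept.z_enc, train_like[1:])


class TestReinstatementMeasures:
    @pytest.mark.parametrize(
        "measure,e,r,expected",
        [
            ("product", 2.0, 2.0, 4.0),
            ("sum", 2.0, 1.7, 3.7),
            ("normalized_product", 3.0, 1.0, 1.5),
        ],
    )
    def test_hand_computed_values(self, measure, e, r, expected):
        out = reinstatement_values(zv([e], [r]), measure)
        assert out[0] == pytest.approx(expected)

    def test_normalized_product_floored_at_epsilon(self):
        out = reinstatement_values(zv([2.0], [2.0]), "normalized_product", eps=1e-6)
        assert out[0] == pytest.approx(4.0 / 1e-6)

    def test_measures_agree_in_sign_when_equal(self):
        z = zv([2.0, -1.0], [2.0, -1.0])
        for m in ("product", "sum", "normalized_product"):
            vals = reinstatement_values(z, m)
            assert vals[0] > 0
        # equal negative z: product positive, sum negative - selection relies
        # on the z-gates to keep only jointly elevated episodes
        assert reinstatement_values(z, "product")[1] > 0


class TestShuffleThreshold:
    def test_constant_z_gives_constant_threshold(self, rng):
        z = zv([1.5, 1.5, 1.5], [1.5, 1.5, 1.5])
        thr, _ = shuffle_threshold(z, n_perm=200, rng=rng)
        assert thr == pytest.approx(1.5 * 1.5)

    def test_monte_carlo_matches_exhaustive_enumeration(self, rng):
        z = zv([-1.2, 0.3, 0.9], [-0.5, 1.4, -0.9])
        pooled = [
            z.z_enc[list(p)] * z.z_ret
            for p in itertools.permutations(range(3))
        ]
        exact = np.percentile(np.concatenate(pooled), 99)
        thr, _ = shuffle_threshold(z, n_perm=10_000, rng=rng)
        assert abs(thr - exact) < 0.05

    def test_threshold_monotone_in_percentile(self, rng):
        z = zv(rng.standard_normal(8), rng.standard_normal(8))
        thrs = [
            shuffle_threshold(z, n_perm=500, percentile=p, rng=np.random.default_rng(0))[0]
            for p in (90, 95, 99)
        ]
        assert thrs[0] <= thrs[1] <= thrs[2]


class TestFlagESN:
    def test_one_sided_firing_not_reinstated(self):
        z = zv([1.0], [5.0])
        res = flag_esn(z, reinstatement_values(z), threshold=2.0, z_gate=1.645)
        assert res.reinstated_episodes == set()
        assert not res.is_esn

    def test_joint_elevation_with_tie_included(self):
        z = zv([2.0], [2.0])
        res = flag_esn(z, reinstatement_values(z), threshold=3.9, z_gate=1.645)
        assert res.reinstated_episodes == {0}

    def test_strict_gate_variant_excludes(self):
        z = zv([2.0, 3.0], [2.5, 3.0])
        vals = reinstatement_values(z)
        loose = flag_esn(z, vals, threshold=4.0, z_gate=1.645)
        strict = flag_esn(z, vals, threshold=4.0, z_gate=2.6)
        assert 0 in loose.reinstated_episodes
        assert 0 not in strict.reinstated_episodes
        assert strict.reinstated_episodes == {1}

    def test_flags_invariant_to_rate_rescaling(self, planted_session, rng):
        session, _ = planted_session
        train = session.units[0]
        enc = episode_rates(train, session.episodes, "encoding")
        ret = episode_rates(train, session.episodes, "retrieval")
        for scale in (1.0, 7.3):
            z = zv(zscore(scale * enc), zscore(scale * ret))
            thr, _ = shuffle_threshold(z, n_perm=300, rng=np.random.default_rng(1))
            res = flag_esn(z, reinstatement_values(z), thr)
            if scale == 1.0:
                baseline = res.reinstated_episodes
            else:
                assert res.reinstated_episodes == baseline


class TestCueResponseExclusion:
    def test_silent_unit_not_excluded(self):
        episodes = [make_episode(i, 10.0 + 30.0 * i) for i in range(10)]
        train = SpikeTrain("u", "hippocampus", np.array([500.0]))
        assert not cue_response_exclusion(train, episodes, ["ep000", "ep001"])

    def test_cue_locked_unit_excluded(self, rng):
        episodes = [make_episode(i, 10.0 + 30.0 * i) for i in range(10)]
        spikes = []
        for ep in episodes:
            spikes.append(rng.uniform(ep.enc_cue_onset_s, ep.enc_cue_onset_s + 0.2, size=12))
        train = SpikeTrain("u", "hippocampus", np.sort(np.concatenate(spikes)))
        assert cue_response_exclusion(
            train, episodes, [ep.episode_id for ep in episodes], alpha=0.0005
        )

    def test_no_reinstated_episodes_returns_false(self):
        episodes = [make_episode(i, 10.0 + 30.0 * i) for i in range(10)]
        train = SpikeTrain("u", "hippocampus", np.arange(0.0, 300.0, 0.4))
        assert not cue_response_exclusion(train, episodes, [])

    def test_exclusion_clears_is_esn(self):
        from esn.rate import ReinstatementResult

        res = ReinstatementResult(
            "u", "product", ["e0"], np.array([9.0]), 1.0, 1.645, {0}, excluded_as_concept=True
        )
        assert res.n_reinstated == 1 and not res.is_esn


class TestGroupTest:
    def test_zero_empirical_count_gives_p_one(self, rng):
        flags = np.zeros((5, 100), dtype=bool)
        res = group_test([], flags, n_draws=200, rng=rng)
        assert res.p_value == 1.0

    def test_missing_stored_permutations_is_error(self, rng):
        with pytest.raises(ValueError, match="retention"):
            group_test([], None, rng=rng)

    def test_power_on_planted_session(self):
        """A session rich in strong planted ESNs yields a significant count."""
        cfg = AnalysisConfig()
        cfg.n_perm_rate, cfg.n_draws_rate = 500, 2000
        sig = 0
        n_seeds = 10
        for seed in range(n_seeds):
            scfg = SyntheticConfig(
                n_units=20, n_episodes=30, episodes_per_block=15, base_rate_hz=2.0,
                seed=seed,
                planted_esn=[PlantedESN(u, (3 * u) % 30, 5.0) for u in range(6)],
            )
            session, _ = generate_session(scfg)
            res = detect_esn_session(session, cfg, rng=np.random.default_rng(100 + seed))
            sig += res.group.p_value < 0.05
        assert sig >= 9


class TestMissBootstrap:
    def test_fully_reinstated_unit_always_null_miss(self, rng):
        res = miss_esn_bootstrap([np.ones(5, dtype=bool)], [3], 0, n_boot=500, rng=rng)
        assert np.all(res.null_counts == 1)

    def test_never_reinstated_unit_never_null_miss(self, rng):
        res = miss_esn_bootstrap([np.zeros(5, dtype=bool)], [3], 0, n_boot=500, rng=rng)
        assert np.all(res.null_counts == 0)

    def test_exact_probability_half(self, rng):
        # 2 remembered events (1 reinstated), 1 forgotten: P(null miss-ESN) = 1/2
        res = miss_esn_bootstrap(
            [np.array([True, False])], [1], 0, n_boot=10_000, rng=rng
        )
        assert abs(res.null_counts.mean() - 0.5) < 0.02

    def test_unit_without_forgotten_events_contributes_nothing(self, rng):
        res = miss_esn_bootstrap([np.ones(4, dtype=bool)], [0], 0, n_boot=200, rng=rng)
        assert np.all(res.null_counts == 0)
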