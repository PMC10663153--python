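import numpy as np
import pytest
from scipy import signal

from esn.config import AnalysisConfig
from esn.session import SpikeTrain
from esn.synthetic import PlantedTESN, SyntheticConfig, generate_session
from esn.temporal import (
    KernelConfig,
    TemporalTrial,
    detect_tesn,
    detect_tesn_session,
    instantaneous_rate,
    overlap_test,
    pairwise_xcorr_matrix,
    trial_gate,
    xcorr_reinstatement,
)


def train_at(times):
    return SpikeTrain("u", "hippocampus", np.sort(np.asarray(times, dtype=float)))


class TestInstantaneousRate:
    def test_peak_normalized_to_one(self):
        # single spike 2 s before the response lands on the 1-kHz grid
        trial = instantaneous_rate(train_at([8.0]), response_s=10.0)
        t = np.argmax(trial.rate_trace)
        assert trial.rate_trace[t] == pytest.approx(1.0)
        assert t == 3000  # [-5, 0) window: -2 s is sample 3000

    def test_one_sd_away(self):
        trial = instantaneous_rate(train_at([8.0]), response_s=10.0)
        assert trial.rate_trace[3000 + 100] == pytest.approx(np.exp(-0.5), rel=1e-6)
        assert trial.rate_trace[3000 - 100] == pytest.approx(np.exp(-0.5), rel=1e-6)

    def test_truncated_beyond_support(self):
        trial = instantaneous_rate(train_at([8.0]), response_s=10.0)
        assert trial.rate_trace[3000 + 301] == 0.0
        assert trial.rate_trace[3000 + 299] > 0.0

    def test_convolution_linearity(self):
        a = instantaneous_rate(train_at([7.0]), 10.0)
        b = instantaneous_rate(train_at([8.5]), 10.0)
        both = instantaneous_rate(train_at([7.0, 8.5]), 10.0)
        assert np.allclose(both.rate_trace, a.rate_trace + b.rate_trace)

    def test_edge_spike_contributes_after_trimming(self):
        # spike at -5.2 s: outside the trimmed [-5, 0) span but within kernel
        # reach of its edge, so convolve-then-trim must keep its mass
        trial = instantaneous_rate(train_at([4.8]), response_s=10.0)
        assert trial.rate_trace[0] == pytest.approx(np.exp(-(0.2**2) / (2 * 0.1**2)))
        assert trial.rate_trace[150] == 0.0

    def test_raw_spike_count_covers_untrimmed_window(self):
        trial = instantaneous_rate(train_at([4.5, 9.0, 10.5, 11.5]), response_s=10.0)
        assert trial.n_spikes_raw == 3  # [-6, +1) keeps 4.5, 9.0, 10.5


class TestTrialGate:
    @staticmethod
    def trial(n_spikes, eid="e0"):
        return TemporalTrial("u", eid, "enc", np.zeros(10), n_spikes)

    def test_both_phases_must_reach_ten_spikes(self):
        enc = [self.trial(10)]
        ret = [self.trial(3)]
        keep, ok = trial_gate(enc, ret)
        assert keep == [] and not ok

    def test_unit_needs_ten_qualifying_trials(self):
        enc = [self.trial(12, f"e{i}") for i in range(9)]
        ret = [self.trial(12, f"e{i}") for i in range(9)]
        keep, ok = trial_gate(enc, ret)
        assert len(keep) == 9 and not ok

    def test_tuned_episodes_dropped_before_gating(self):
        enc = [self.trial(12, f"e{i}") for i in range(10)]
        ret = [self.trial(12, f"e{i}") for i in range(10)]
        keep, ok = trial_gate(enc, ret, excluded_episodes={"e0"})
        assert len(keep) == 9 and not ok


class TestXcorr:
    def test_identical_traces_peak_at_zero_lag(self, rng):
        x = np.convolve(rng.random(800), np.ones(50), mode="same")
        c = signal.correlate(x, x, mode="full")
        lags = signal.correlation_lags(x.size, x.size, mode="full")
        assert lags[np.argmax(c)] == 0
        assert xcorr_reinstatement(x, x, 0.3, 1000) == pytest.approx(np.dot(x, x))

    def test_shifted_trace_peaks_at_shift(self, rng):
        base = np.zeros(3000)
        base[1000:1100] = 1.0
        shifted = np.roll(base, 1000)
        c = signal.correlate(base, shifted, mode="full")
        lags = signal.correlation_lags(base.size, shifted.size, mode="full")
        assert abs(lags[np.argmax(c)]) == 1000
        # the max within +/-2.5 s equals the aligned inner product
        assert xcorr_reinstatement(base, shifted, 2.5, 1000) == pytest.approx(np.dot(base, base))

    def test_zero_trace_gives_zero(self):
        assert xcorr_reinstatement(np.zeros(100), np.ones(100)) == 0.0

    def test_symmetric_under_swap(self, rng):
        x, y = rng.random(500), rng.random(500)
        assert xcorr_reinstatement(x, y, 0.2, 1000) == pytest.approx(
            xcorr_reinstatement(y, x, 0.2, 1000)
        )

    def test_pairwise_matrix_matches_single_calls(self, rng):
        enc = [rng.random(400) for _ in range(4)]
        ret = [rng.random(400) for _ in range(4)]
        M = pairwise_xcorr_matrix(enc, ret, 0.1, 1000)
        for i in range(4):
            for j in range(4):
                assert M[i, j] == pytest.approx(xcorr_reinstatement(enc[i], ret[j], 0.1, 1000))


class TestDetectTESN:
    def test_planted_motif_detected(self):
        cfg = SyntheticConfig(
            n_units=1, n_episodes=30, episodes_per_block=30, base_rate_hz=2.0,
            seed=0, hit_rate=0.999, planted_tesn=[PlantedTESN(0, 5)],
        )
        session, _ = generate_session(cfg)
        c = AnalysisConfig()
        c.n_perm_temporal, c.n_draws_temporal = 500, 500
        res = detect_tesn_session(session, c, rng=np.random.default_rng(0))
        r = res.results[0]
        assert "ep005" in [r.episode_ids[i] for i in r.reinstated_episodes]

    def test_under_gated_unit_absent(self):
        cfg = SyntheticConfig(
            n_units=1, n_episodes=12, episodes_per_block=12, base_rate_hz=0.3, seed=1
        )
        session, _ = generate_session(cfg)
        res = detect_tesn_session(session, AnalysisConfig(), rng=np.random.default_rng(0))
        assert res.results == [] and res.perm_flags is None

    def test_perm_flags_align_with_results(self, rng):
        trials_e = []
        trials_r = []
        for i in range(12):
            tr = rng.random(500)
            trials_e.append(TemporalTrial("u", f"e{i}", "enc", tr, 20))
            trials_r.append(TemporalTrial("u", f"e{i}", "ret", rng.random(500), 20))
        res, flags = detect_tesn(trials_e, trials_r, n_perm=100, rng=rng)
        assert flags.shape == (100,)
        assert res.values.shape == (12,)


class TestOverlap:
    @staticmethod
    def fake_result(unit, ids, reinstated):
        from esn.temporal import TemporalResult

        return TemporalResult(unit, list(ids), np.zeros(len(ids)), 0.0, set(reinstated))

    def test_identical_sets_full_overlap(self, rng):
        from esn.rate import ReinstatementResult

        rate = [
            ReinstatementResult("u0", "product", [f"e{i}" for i in range(10)],
                                np.zeros(10), 0.0, 1.645, {2, 5})
        ]
        tmp = [self.fake_result("u0", [f"e{i}" for i in range(10)], {2, 5})]
        res = overlap_test(rate, tmp, n_perm=400, rng=rng)
        assert res.pct_a_also_b == 100.0 and res.pct_b_also_a == 100.0
        assert res.p_a_also_b <= 0.05

    def test_empty_temporal_set_not_applicable(self, rng):
        from esn.rate import ReinstatementResult

        rate = [
            ReinstatementResult("u0", "product", ["e0", "e1"], np.zeros(2), 0.0, 1.645, {0})
        ]
        tmp = [self.fake_result("u0", ["e0", "e1"], set())]
        res = overlap_test(rate, tmp, n_perm=50, rng=rng)
        assert not res.applicable

    def test_disjoint_unit_sets_error(self, rng):
        from esn.rate import ReinstatementResult

        rate = [ReinstatementResult("u0", "product", ["e0"], np.zeros(1), 0.0, 1.645, {0})]
        tmp = [self.fake_result("u1", ["e0"], {0})]
        with pytest.raises(ValueError, match="share no units"):
            overlap_test(rate, tmp, n_perm=10, rng=rng)
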