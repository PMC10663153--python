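"""Temporal-code ESN (tESN) detection.

Spike trains around the response of each episode (6 s before to 1 s
after; 1 s trimmed at each edge after convolution) are turned into
instantaneous firing rates by summing peak-normalized Gaussian bumps
(sd 100 ms, support +/-300 ms) on a 1-kHz grid.  Because the moment an
episode is encoded/retrieved inside the window is unknown, the encoding
and retrieval traces of the same episode are cross-correlated (raw
sliding inner product, maximum lag +/-2.5 s) and the maximum is the
episode's temporal reinstatement value.  Inference mirrors the rate
pipeline: encoding-order shuffles give a pooled 99th-percentile
threshold (1,000 permutations), and a second level redraws stored
permutations to test the tESN count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .config import AnalysisConfig
from .session import Session, SpikeTrain
from .stats import (
    GroupTestResult,
    OverlapTestResult,
    group_count_test,
    permutation_p,
)


@dataclass(frozen=True)
class KernelConfig:
    """Peak-normalized Gaussian smoothing kernel."""

    sd_s: float = 0.100
    half_support_s: float = 0.300
    peak: float = 1.0
    sample_rate_hz: int = 1000


@dataclass
class TemporalTrial:
    """Instantaneous-rate trace of one (unit, episode, phase) trial."""

    unit_id: str
    episode_id: str
    phase: str
    rate_trace: np.ndarray
    n_spikes_raw: int


@dataclass
class TemporalResult:
    unit_id: str
    episode_ids: list
    values: np.ndarray
    threshold: float
    reinstated_episodes: set

    @property
    def is_tesn(self) -> bool:
        return bool(self.reinstated_episodes)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "unit_id": self.unit_id,
                "episode_id": self.episode_ids,
                "value": self.values,
                "threshold": self.threshold,
                "reinstated": [i in self.reinstated_episodes for i in range(len(self.episode_ids))],
            }
        )


def kernel_values(times_from_center: np.ndarray, kernel: KernelConfig = KernelConfig()) -> np.ndarray:
    """Kernel evaluated at signed offsets (seconds); zero beyond the support."""
    t = np.asarray(times_from_center, dtype=float)
    out = kernel.peak * np.exp(-(t**2) / (2.0 * kernel.sd_s**2))
    out[np.abs(t) > kernel.half_support_s] = 0.0
    return out


def instantaneous_rate(
    train: SpikeTrain,
    response_s: float,
    kernel: KernelConfig = KernelConfig(),
    pre_s: float = 6.0,
    post_s: float = 1.0,
    trim_s: float = 1.0,
    unit_id: Optional[str] = None,
    episode_id: str = "",
    phase: str = "",
) -> TemporalTrial:
    """Smoothed rate on [response - pre, response + post), trimmed by
    ``trim_s`` at each edge AFTER convolution, so spikes just outside the
    trimmed span still contribute their kernel mass."""
    fs = kernel.sample_rate_hz
    start = response_s - pre_s
    n_raw = int(round((pre_s + post_s) * fs))
    lo, hi = np.searchsorted(train.spike_times, [start, start + n_raw / fs], side="left")
    spikes = train.spike_times[lo:hi]

    trace = np.zeros(n_raw)
    half = int(round(kernel.half_support_s * fs))
    grid0 = start
    for s in spikes:
        center = (s - grid0) * fs
        i0 = max(0, int(np.ceil(center - half)))
        i1 = min(n_raw - 1, int(np.floor(center + half)))
        if i1 < i0:
            continue
        idx = np.arange(i0, i1 + 1)
        trace[idx] += kernel.peak * np.exp(
            -((idx - center) ** 2) / (2.0 * (kernel.sd_s * fs) ** 2)
        )
    k = int(round(trim_s * fs))
    trimmed = trace[k : n_raw - k]
    return TemporalTrial(
        unit_id=unit_id if unit_id is not None else train.unit_id,
        episode_id=episode_id,
        phase=phase,
        rate_trace=trimmed,
        n_spikes_raw=int(spikes.size),
    )


def trial_gate(
    enc_trials: Sequence[TemporalTrial],
    ret_trials: Sequence[TemporalTrial],
    min_spikes: int = 10,
    min_trials: int = 10,
    excluded_episodes: Optional[set] = None,
):
    """Indices of episodes passing the spike-count gate at BOTH phases.

    Returns (indices, unit_passes): the unit enters the analysis only
    when at least ``min_trials`` episodes qualify.  ``excluded_episodes``
    (Experiment-2 visual tuning) are dropped before gating.
    """
    excluded = excluded_episodes or set()
    keep = [
        i
        for i, (e, r) in enumerate(zip(enc_trials, ret_trials))
        if e.n_spikes_raw >= min_spikes
        and r.n_spikes_raw >= min_spikes
        and e.episode_id not in excluded
    ]
    return keep, len(keep) >= min_trials


def xcorr_reinstatement(
    enc: np.ndarray,
    ret: np.ndarray,
    max_lag_s: float = 2.5,
    sample_rate_hz: int = 1000,
    normalized: bool = False,
) -> float:
    """Maximum of the sliding inner product within +/- max_lag.

    Positive lag means the encoding trace leads (the retrieval pattern is
    delayed).  ``normalized=True`` divides by the L2 norms, giving a
    correlation coefficient-like bound of 1.
    """
    enc = np.asarray(enc, dtype=float)
    ret = np.asarray(ret, dtype=float)
    c = signal.correlate(enc, ret, mode="full", method="auto")
    lags = signal.correlation_lags(enc.size, ret.size, mode="full")
    max_lag = int(round(max_lag_s * sample_rate_hz))
    sel = np.abs(lags) <= max_lag
    val = float(np.max(c[sel]))
    if normalized:
        denom = float(np.linalg.norm(enc) * np.linalg.norm(ret))
        val = val / denom if denom > 0 else 0.0
    return val


def pairwise_xcorr_matrix(
    enc_traces: Sequence[np.ndarray],
    ret_traces: Sequence[np.ndarray],
    max_lag_s: float = 2.5,
    sample_rate_hz: int = 1000,
    normalized: bool = False,
) -> np.ndarray:
    """M[i, j] = max cross-correlation of encoding trace i with retrieval trace j.

    Computing all pairs once makes the 1,000 pairing shuffles a pure
    lookup instead of repeated convolutions.
    """
    enc = np.asarray(enc_traces, dtype=float)
    ret = np.asarray(ret_traces, dtype=float)
    n, T = enc.shape
    m = ret.shape[0]
    max_lag = int(round(max_lag_s * sample_rate_hz))
    lo, hi = T - 1 - max_lag, T - 1 + max_lag + 1  # central lag slice of the full xcorr
    out = np.empty((n, m))
    rev = ret[:, ::-1]
    # batched full correlation via FFT, chunked over encoding traces to bound memory
    chunk = max(1, int(2e8 // (m * 2 * T * 8)))
    for i0 in range(0, n, chunk):
        c = signal.fftconvolve(enc[i0 : i0 + chunk, None, :], rev[None, :, :], mode="full", axes=2)
        out[i0 : i0 + chunk] = c[:, :, lo:hi].max(axis=2)
    if normalized:
        denom = np.outer(np.linalg.norm(enc, axis=1), np.linalg.norm(ret, axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(denom > 0, out / denom, 0.0)
    return out


def detect_tesn(
    enc_trials: Sequence[TemporalTrial],
    ret_trials: Sequence[TemporalTrial],
    n_perm: int = 1000,
    percentile: float = 99.0,
    max_lag_s: float = 2.5,
    sample_rate_hz: int = 1000,
    rng: Optional[np.random.Generator] = None,
    normalized: bool = False,
):
    """First-level tESN test for one gated unit.

    Shuffles re-pair encoding trials with mismatched retrieval trials
    (uniform permutations of the encoding order); all permuted maxima are
    pooled and the 99th percentile thresholds the empirical per-episode
    values ("reached": >=).  Returns (TemporalResult, perm_flags) with
    one qualification flag per stored permutation for the group test.
    """
    rng = np.random.default_rng(rng)
    n = len(enc_trials)
    if n != len(ret_trials) or n == 0:
        raise ValueError("encoding and retrieval trial lists must align and be non-empty")
    M = pairwise_xcorr_matrix(
        [t.rate_trace for t in enc_trials],
        [t.rate_trace for t in ret_trials],
        max_lag_s,
        sample_rate_hz,
        normalized,
    )
    empirical = np.diag(M).copy()
    perms = np.empty((n_perm, n), dtype=np.int64)
    for p in range(n_perm):
        perms[p] = rng.permutation(n)
    vals = M[perms, np.arange(n)[None, :]]
    thr = float(np.percentile(vals, percentile))
    reinstated = set(np.flatnonzero(empirical >= thr).tolist())
    perm_flags = (vals >= thr).any(axis=1)
    result = TemporalResult(
        unit_id=enc_trials[0].unit_id,
        episode_ids=[t.episode_id for t in enc_trials],
        values=empirical,
        threshold=thr,
        reinstated_episodes=reinstated,
    )
    return result, perm_flags


@dataclass
class TemporalDetectionResult:
    results: list
    perm_flags: Optional[np.ndarray]
    group: Optional[GroupTestResult] = None
    analyzed_unit_ids: list = field(default_factory=list)

    @property
    def empirical_count(self) -> int:
        return sum(r.is_tesn for r in self.results)

    @property
    def tesn_unit_ids(self) -> list:
        return [r.unit_id for r in self.results if r.is_tesn]


def detect_tesn_session(
    session: Session,
    config: Optional[AnalysisConfig] = None,
    experiment: int = 1,
    keep: str = "remembered",
    rng: Optional[np.random.Generator] = None,
    run_group_test: bool = True,
) -> TemporalDetectionResult:
    """Full two-level temporal-code analysis of one session."""
    cfg = config or AnalysisConfig()
    rng = np.random.default_rng(rng)
    kernel = KernelConfig(cfg.kernel_sd_s, cfg.kernel_half_support_s, 1.0, cfg.sample_rate_hz)

    mask = session.remembered_mask
    if keep == "forgotten":
        mask = ~mask
    episodes = [ep for ep, m in zip(session.episodes, mask) if m]

    results: list = []
    flag_rows: list = []
    analyzed: list = []
    for train in session.units:
        enc_trials = [
            instantaneous_rate(
                train, ep.enc_response_s, kernel, cfg.trial_pre_s, cfg.trial_post_s,
                cfg.trial_trim_s, episode_id=ep.episode_id, phase="encoding",
            )
            for ep in episodes
        ]
        ret_trials = [
            instantaneous_rate(
                train, ep.ret_response_s, kernel, cfg.trial_pre_s, cfg.trial_post_s,
                cfg.trial_trim_s, episode_id=ep.episode_id, phase="retrieval",
            )
            for ep in episodes
        ]
        excluded = set()
        if experiment == 2 and session.tuning is not None:
            from .tuning import unit_is_concept

            tuned_images = unit_is_concept(train, session.tuning, cfg.tuning_alpha_strict)
            if tuned_images:
                # drop episodes whose cue or associate image the unit is
                # tuned to ("<episode_id>:<role>" image-id convention)
                from .synthetic import image_episode

                tuned_eps = {image_episode(im) for im in tuned_images}
                excluded = {ep.episode_id for ep in episodes if ep.episode_id in tuned_eps}
        keep_idx, passes = trial_gate(
            enc_trials, ret_trials, cfg.min_spikes_per_trial, cfg.min_trials, excluded
        )
        if not passes:
            continue
        analyzed.append(train.unit_id)
        res, flags = detect_tesn(
            [enc_trials[i] for i in keep_idx],
            [ret_trials[i] for i in keep_idx],
            cfg.n_perm_temporal,
            cfg.percentile,
            cfg.max_lag_s,
            cfg.sample_rate_hz,
            rng,
        )
        results.append(res)
        flag_rows.append(flags)

    perm_flags = np.array(flag_rows, dtype=bool) if flag_rows else None
    out = TemporalDetectionResult(results, perm_flags, analyzed_unit_ids=analyzed)
    if run_group_test and perm_flags is not None:
        out.group = group_test_tesn(results, perm_flags, cfg.n_draws_temporal, rng)
    return out


def group_test_tesn(
    results: Sequence,
    stored_perm_flags: Optional[np.ndarray],
    n_draws: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> GroupTestResult:
    if stored_perm_flags is None:
        raise ValueError(
            "stored first-level permutations are required; re-run "
            "detect_tesn_session with permutation retention enabled"
        )
    rng = np.random.default_rng(rng)
    empirical = sum(r.is_tesn for r in results)
    return group_count_test(stored_perm_flags, empirical, n_draws, rng, label="tesn")


def overlap_test(
    rate_results: Sequence,
    temporal_results: Sequence,
    n_perm: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> OverlapTestResult:
    """Do rate-code and temporal-code reinstated episodes coincide?

    For every unit analysed by both detectors, episode labels
    (reinstated / not) from the temporal analysis are shuffled within the
    unit to build the null overlap.  Percentages are pooled across units;
    p-values are one-sided (greater).
    """
    rng = np.random.default_rng(rng)
    rate_by_unit = {r.unit_id: r for r in rate_results}
    tmp_by_unit = {r.unit_id: r for r in temporal_results}
    common = [u for u in rate_by_unit if u in tmp_by_unit]
    if not common:
        raise ValueError("rate and temporal analyses share no units")

    pairs = []
    for u in common:
        ra, rb = rate_by_unit[u], tmp_by_unit[u]
        ids = [eid for eid in ra.episode_ids if eid in set(rb.episode_ids)]
        if not ids:
            continue
        a = np.array([ra.episode_ids.index(e) in ra.reinstated_episodes for e in ids])
        b = np.array([rb.episode_ids.index(e) in rb.reinstated_episodes for e in ids])
        pairs.append((a, b))

    tot_a = sum(int(a.sum()) for a, _ in pairs)
    tot_b = sum(int(b.sum()) for _, b in pairs)
    if tot_a == 0 or tot_b == 0:
        return OverlapTestResult(np.nan, np.nan, np.nan, np.nan, n_perm, applicable=False)

    def overlap(pair_list):
        inter = sum(int((a & b).sum()) for a, b in pair_list)
        na = sum(int(a.sum()) for a, _ in pair_list)
        nb = sum(int(b.sum()) for _, b in pair_list)
        return 100.0 * inter / na, 100.0 * inter / nb

    emp_ab, emp_ba = overlap(pairs)
    null_ab = np.empty(n_perm)
    null_ba = np.empty(n_perm)
    for p in range(n_perm):
        shuffled = [(a, b[rng.permutation(b.size)]) for a, b in pairs]
        null_ab[p], null_ba[p] = overlap(shuffled)
    return OverlapTestResult(
        pct_a_also_b=emp_ab,
        pct_b_also_a=emp_ba,
        p_a_also_b=permutation_p(null_ab, emp_ab, "greater"),
        p_b_also_a=permutation_p(null_ba, emp_ba, "greater"),
        n_perm=n_perm,
        applicable=True,
    )
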