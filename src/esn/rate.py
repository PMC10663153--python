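"""Rate-code episode-specific neuron (ESN) detection.

An ESN is a unit whose standardized firing rate is jointly elevated at
encoding and retrieval of the same episode:

* per-episode firing rate (Hz) at encoding (associate onset -> response)
  and retrieval (cue onset -> response),
* z-scored per unit across ALL episodes (encoding and retrieval
  separately), then restricted to later-remembered (hit) or
  later-forgotten (miss) episodes,
* per-episode reinstatement value: ``E*R`` (default), ``E+R``, or
  ``(E*R)/|E-R|``,
* first level: permute the encoding episode order (retrieval fixed),
  pool all permuted values, take the 99th percentile as the unit's
  threshold; an episode is reinstated when its value reaches the
  threshold and both z-scores reach the gate (1.645 by default),
* second level: redraw one stored permutation per unit and count units
  that would qualify, giving a group-level null for the ESN count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import AnalysisConfig
from .session import Session, SpikeTrain, count_spikes
from .stats import GroupTestResult, group_count_test, permutation_p

MEASURES = ("product", "sum", "normalized_product")


class ConstantRateError(ValueError):
    """Raised when a unit's episode rates have zero variance (e.g. silent unit)."""


@dataclass
class ZRateVectors:
    """Standardized encoding/retrieval rates of one unit, aligned by episode."""

    unit_id: str
    episode_ids: list
    z_enc: np.ndarray
    z_ret: np.ndarray

    def __post_init__(self) -> None:
        self.z_enc = np.asarray(self.z_enc, dtype=float)
        self.z_ret = np.asarray(self.z_ret, dtype=float)
        if self.z_enc.shape != self.z_ret.shape or len(self.episode_ids) != self.z_enc.size:
            raise ValueError(f"unit {self.unit_id}: misaligned z vectors")

    @property
    def n_episodes(self) -> int:
        return int(self.z_enc.size)


@dataclass
class ReinstatementResult:
    """Per-unit outcome of the rate-code ESN test."""

    unit_id: str
    measure: str
    episode_ids: list
    values: np.ndarray
    threshold: float
    z_gate: float
    reinstated_episodes: set
    excluded_as_concept: bool = False

    @property
    def is_esn(self) -> bool:
        return bool(self.reinstated_episodes) and not self.excluded_as_concept

    @property
    def n_reinstated(self) -> int:
        return len(self.reinstated_episodes)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "unit_id": self.unit_id,
                "measure": self.measure,
                "episode_id": self.episode_ids,
                "value": self.values,
                "threshold": self.threshold,
                "z_gate": self.z_gate,
                "reinstated": [i in self.reinstated_episodes for i in range(len(self.episode_ids))],
                "excluded_as_concept": self.excluded_as_concept,
            }
        )


def episode_rates(train: SpikeTrain, episodes: Sequence, phase: str) -> np.ndarray:
    """Firing rate (Hz) per episode in the phase-specific analysis window."""
    rates = np.empty(len(episodes))
    for i, ep in enumerate(episodes):
        win = Session.window(ep, phase)
        if win.duration_s <= 0:
            raise ValueError(f"episode {ep.episode_id}: zero-length {phase} window")
        rates[i] = count_spikes(train, win) / win.duration_s
    return rates


def zscore(rates: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standardize with the sample sd (n-1).  Constant input raises
    :class:`ConstantRateError`; callers exclude such units with a warning
    rather than propagate NaNs."""
    rates = np.asarray(rates, dtype=float)
    if rates.size < 2:
        raise ConstantRateError("need at least two episodes to z-score")
    sd = rates.std(ddof=ddof)
    if sd == 0:
        raise ConstantRateError("constant firing rates (sd = 0)")
    return (rates - rates.mean()) / sd


def compute_z_vectors(
    train: SpikeTrain, episodes: Sequence, ddof: int = 1
) -> Optional[ZRateVectors]:
    """Per-unit standardized rates over ALL episodes; None if degenerate."""
    try:
        z_enc = zscore(episode_rates(train, episodes, "encoding"), ddof)
        z_ret = zscore(episode_rates(train, episodes, "retrieval"), ddof)
    except ConstantRateError as err:
        warnings.warn(f"unit {train.unit_id} excluded: {err}", stacklevel=2)
        return None
    return ZRateVectors(train.unit_id, [ep.episode_id for ep in episodes], z_enc, z_ret)


def restrict_episodes(
    z: ZRateVectors,
    episodes: Sequence,
    keep: str = "remembered",
    min_episodes: int = 8,
) -> Optional[ZRateVectors]:
    """Keep later-remembered (hit analysis) or later-forgotten (miss
    analysis) episodes.  z-scores were computed over all episodes FIRST;
    this only subsets them.  Units with fewer than ``min_episodes``
    remaining are dropped (returns None)."""
    if keep not in ("remembered", "forgotten"):
        raise ValueError(f"keep must be 'remembered' or 'forgotten', got {keep!r}")
    mask = np.array([ep.remembered for ep in episodes], dtype=bool)
    if keep == "forgotten":
        mask = ~mask
    if mask.sum() < min_episodes:
        return None
    ids = [eid for eid, m in zip(z.episode_ids, mask) if m]
    return ZRateVectors(z.unit_id, ids, z.z_enc[mask], z.z_ret[mask])


def reinstatement_values(
    z: ZRateVectors, measure: str = "product", eps: float = 1e-6
) -> np.ndarray:
    """Per-episode encoding-retrieval reinstatement values."""
    return _measure_values(z.z_enc, z.z_ret, measure, eps)


def _measure_values(e: np.ndarray, r: np.ndarray, measure: str, eps: float) -> np.ndarray:
    if measure == "product":
        return e * r
    if measure == "sum":
        return e + r
    if measure == "normalized_product":
        return (e * r) / np.maximum(np.abs(e - r), eps)
    raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")


def shuffle_threshold(
    z: ZRateVectors,
    measure: str = "product",
    n_perm: int = 10_000,
    percentile: float = 99.0,
    rng: Optional[np.random.Generator] = None,
    eps: float = 1e-6,
    return_perms: bool = True,
):
    """Pooled-permutation threshold for one unit.

    The encoding episode order is permuted (uniformly over all n!
    orderings, identity included) while retrieval stays fixed; the
    elementwise measure is recomputed for every permutation and all
    ``n_perm * n_episodes`` values are pooled.  Returns the
    linear-interpolation percentile of the pool and, by default, the
    permutation index matrix so the group-level test can reuse the same
    draws.
    """
    rng = np.random.default_rng(rng)
    n = z.n_episodes
    perms = np.empty((n_perm, n), dtype=np.int64)
    base = np.arange(n)
    for p in range(n_perm):
        perms[p] = rng.permutation(base)
    vals = _measure_values(z.z_enc[perms], z.z_ret[None, :], measure, eps)
    thr = float(np.percentile(vals, percentile))
    if return_perms:
        return thr, perms
    return thr


def perm_esn_flags(
    z: ZRateVectors,
    perms: np.ndarray,
    threshold: float,
    z_gate: float = 1.645,
    measure: str = "product",
    eps: float = 1e-6,
    strict: bool = False,
) -> np.ndarray:
    """Whether each stored permutation would qualify the unit as an ESN.

    The permuted encoding z-scores stand in for the empirical ones; the
    identical criteria (same threshold, same gates) are applied.
    """
    vals = _measure_values(z.z_enc[perms], z.z_ret[None, :], measure, eps)
    cmp = np.greater if strict else np.greater_equal
    ok = cmp(vals, threshold) & cmp(z.z_enc[perms], z_gate) & cmp(z.z_ret[None, :], z_gate)
    return ok.any(axis=1)


def flag_esn(
    z: ZRateVectors,
    values: np.ndarray,
    threshold: float,
    z_gate: float = 1.645,
    measure: str = "product",
    strict: bool = False,
) -> ReinstatementResult:
    """Flag reinstated episodes: value and both z-scores reach their criteria."""
    cmp = np.greater if strict else np.greater_equal
    ok = cmp(values, threshold) & cmp(z.z_enc, z_gate) & cmp(z.z_ret, z_gate)
    return ReinstatementResult(
        unit_id=z.unit_id,
        measure=measure,
        episode_ids=list(z.episode_ids),
        values=np.asarray(values, dtype=float),
        threshold=float(threshold),
        z_gate=float(z_gate),
        reinstated_episodes=set(np.flatnonzero(ok).tolist()),
    )


def cue_response_exclusion(
    train: SpikeTrain,
    episodes: Sequence,
    reinstated_episode_ids: Sequence,
    alpha: float = 0.0005,
) -> bool:
    """Experiment-1 guard against cue-tuned concept cells.

    Treats the encoding cue onsets of the reinstated episodes as stimulus
    presentations and the 500 ms pre-cue windows of ALL episodes as the
    baseline pool, then applies the binned rank-sum + Simes tuning test.
    Returns True when the unit shows a significant post-cue firing
    increase (i.e. should be excluded).
    """
    from .tuning import baseline_counts, binned_counts, tuning_test

    ids = list(reinstated_episode_ids)
    if not ids:
        return False
    by_id = {ep.episode_id: ep for ep in episodes}
    onsets = np.array([by_id[i].enc_cue_onset_s for i in ids])
    all_onsets = np.array([ep.enc_cue_onset_s for ep in episodes])
    bins = binned_counts(train, onsets)
    baseline = baseline_counts(train, all_onsets)
    res = tuning_test(bins, baseline, alphas=(alpha,))
    return bool(res.significant_at[alpha])


@dataclass
class RateDetectionResult:
    """Session-level outcome: per-unit results, stored permutation flags,
    and the group-level count test."""

    results: list
    perm_flags: Optional[np.ndarray]
    group: Optional[GroupTestResult] = None
    analyzed_unit_ids: list = field(default_factory=list)

    @property
    def esn_unit_ids(self) -> list:
        return [r.unit_id for r in self.results if r.is_esn]

    @property
    def empirical_count(self) -> int:
        return sum(r.is_esn for r in self.results)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "unit_id": [r.unit_id for r in self.results],
                "is_esn": [r.is_esn for r in self.results],
                "n_reinstated": [r.n_reinstated for r in self.results],
                "threshold": [r.threshold for r in self.results],
                "excluded_as_concept": [r.excluded_as_concept for r in self.results],
            }
        )


def detect_esn_session(
    session: Session,
    config: Optional[AnalysisConfig] = None,
    experiment: int = 1,
    keep: str = "remembered",
    rng: Optional[np.random.Generator] = None,
    z_gate: Optional[float] = None,
    run_group_test: bool = True,
) -> RateDetectionResult:
    """Full two-level rate-code ESN analysis of one session."""
    cfg = config or AnalysisConfig()
    rng = np.random.default_rng(rng)
    gate = cfg.z_gate if z_gate is None else z_gate

    results: list = []
    flags_rows: list = []
    analyzed: list = []
    for train in session.units:
        z_all = compute_z_vectors(train, session.episodes, cfg.sd_ddof)
        if z_all is None:
            continue
        z = restrict_episodes(z_all, session.episodes, keep, cfg.min_episodes)
        if z is None:
            continue
        analyzed.append(train.unit_id)
        thr, perms = shuffle_threshold(
            z, cfg.measure, cfg.n_perm_rate, cfg.percentile, rng, cfg.normalized_eps
        )
        values = reinstatement_values(z, cfg.measure, cfg.normalized_eps)
        res = flag_esn(z, values, thr, gate, cfg.measure, cfg.strict_threshold)
        if res.reinstated_episodes:
            if experiment == 1:
                res.excluded_as_concept = cue_response_exclusion(
                    train,
                    session.episodes,
                    [res.episode_ids[i] for i in sorted(res.reinstated_episodes)],
                    cfg.cue_exclusion_alpha,
                )
            elif experiment == 2 and session.tuning is not None:
                from .tuning import unit_is_concept

                res.excluded_as_concept = bool(
                    unit_is_concept(train, session.tuning, cfg.tuning_alpha_strict)
                )
        results.append(res)
        flags_rows.append(
            perm_esn_flags(z, perms, thr, gate, cfg.measure, cfg.normalized_eps, cfg.strict_threshold)
        )

    perm_flags = np.array(flags_rows, dtype=bool) if flags_rows else None
    out = RateDetectionResult(results, perm_flags, analyzed_unit_ids=analyzed)
    if run_group_test and perm_flags is not None:
        out.group = group_test(results, perm_flags, cfg.n_draws_rate, rng)
    return out


def group_test(
    results: Sequence,
    stored_perm_flags: Optional[np.ndarray],
    n_draws: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> GroupTestResult:
    """Group-level (second-level) permutation test on the ESN count."""
    if stored_perm_flags is None:
        raise ValueError(
            "stored first-level permutations are required; re-run "
            "detect_esn_session with permutation retention enabled"
        )
    rng = np.random.default_rng(rng)
    empirical = sum(r.is_esn for r in results)
    return group_count_test(stored_perm_flags, empirical, n_draws, rng, label="esn")


def miss_esn_bootstrap(
    reinstated_masks: Sequence[np.ndarray],
    n_forgotten: Sequence[int],
    empirical_miss_count: int,
    n_boot: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> GroupTestResult:
    """Bootstrap control for the lower number of forgotten episodes.

    For each unit, ``reinstated_masks[u]`` marks which later-remembered
    episodes were reinstated and ``n_forgotten[u]`` counts that unit's
    forgotten events.  Each bootstrap samples, per unit, as many
    remembered events (with replacement) as were forgotten; the unit is a
    null miss-ESN when any sampled event is reinstated.  The one-sided p
    asks whether the empirical miss-ESN count is significantly LOWER than
    this matched-event-count null.
    """
    rng = np.random.default_rng(rng)
    null_counts = np.zeros(n_boot, dtype=int)
    for mask, n_f in zip(reinstated_masks, n_forgotten):
        mask = np.asarray(mask, dtype=bool)
        if n_f <= 0 or mask.size == 0:
            continue  # units without forgotten events contribute no samples
        draws = rng.integers(0, mask.size, size=(n_boot, int(n_f)))
        null_counts += mask[draws].any(axis=1)
    p = permutation_p(null_counts, empirical_miss_count, "less")
    return GroupTestResult(int(empirical_miss_count), null_counts, p, label="miss_esn")
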