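"""Synthetic sessions with known ground truth.

The generator emulates the statistical structure the detectors assume:
self-paced episodes of variable duration arranged in encoding blocks
followed by a distractor gap and a retrieval block; baseline spiking is
homogeneous Poisson per unit; planted effects add spikes where a real
effect would.  Planted effect types:

* rate ESN       — rate multiplied by ``rate_gain`` inside the episode's
                   encoding (associate -> response) and retrieval
                   (cue -> response) windows,
* temporal ESN   — a fixed multi-spike latency motif repeated before the
                   encoding and retrieval responses of one episode
                   (jittered; adds too few spikes to trip the rate code),
* concept cell   — rate elevated for 1 s after every presentation of one
                   image in the visual tuning task,
* time cell      — rate elevated in one of 40 within-block time bins of
                   every encoding block.

Also provides the two calibration input classes used to validate the
pipelines: uniform pseudo-rate matrices and circular / random-spike-time
surrogates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .session import EpisodeEvents, Session, SpikeTrain, TuningEvents


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedESN:
    unit: int
    episode: int
    rate_gain: float = 5.0


@dataclass(frozen=True)
class PlantedTESN:
    unit: int
    episode: int
    #: spike latencies relative to the response (seconds, negative = before)
    latencies_s: Tuple[float, ...] = (-2.8, -2.0, -1.2)
    jitter_sd_s: float = 0.020
    #: motif repetitions per phase: the repeated motif gives the smoothed
    #: traces reproducible cross-correlation structure while adding only
    #: ~len(latencies_s) * repeats spikes to each anchored trial window
    repeats: int = 3


@dataclass(frozen=True)
class PlantedConcept:
    unit: int
    image_id: str
    response_gain: float = 10.0


@dataclass(frozen=True)
class PlantedTC:
    unit: int
    preferred_bin: int
    gain: float = 8.0
    n_bins: int = 40


@dataclass
class SyntheticConfig:
    """All knobs of the generator.  The defaults are the study conditions:
    ~20 episodes per self-paced block, a hit rate near the observed
    ~65-68%, 2 s cue -> associate delay, and a distractor gap in the
    printed 22.43-224.52 s range."""

    n_units: int = 20
    n_episodes: int = 40
    base_rate_hz: float = 2.0
    enc_duration_s: Tuple[float, float] = (5.0, 20.0)   # log-uniform range
    ret_duration_s: Tuple[float, float] = (3.0, 12.0)   # log-uniform range
    iti_s: Tuple[float, float] = (1.0, 2.0)
    distractor_s: Tuple[float, float] = (22.43, 224.52)  # log-uniform range
    episodes_per_block: int = 20
    hit_rate: float = 0.68
    planted_esn: Sequence[PlantedESN] = field(default_factory=list)
    planted_tesn: Sequence[PlantedTESN] = field(default_factory=list)
    planted_concept: Sequence[PlantedConcept] = field(default_factory=list)
    planted_tc: Sequence[PlantedTC] = field(default_factory=list)
    include_tuning: bool = False
    tuning_repetitions: int = 6
    tuning_display_s: float = 1.0
    tuning_gap_s: Tuple[float, float] = (0.50, 0.55)
    region: str = "hippocampus"
    session_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.hit_rate < 1.0):
            raise ConfigError("hit_rate must be in (0, 1)")
        if self.base_rate_hz <= 0:
            raise ConfigError("base_rate_hz must be positive")
        for p in self.planted_esn:
            if p.rate_gain <= 1:
                raise ConfigError("planted ESN rate_gain must exceed 1")
            self._check(p.unit, p.episode)
        for p in self.planted_tesn:
            self._check(p.unit, p.episode)
        for p in self.planted_concept:
            if p.response_gain <= 1:
                raise ConfigError("planted concept response_gain must exceed 1")
            self._check(p.unit, None)
        for p in self.planted_tc:
            if p.gain <= 1:
                raise ConfigError("planted TC gain must exceed 1")
            self._check(p.unit, None)
            if not (0 <= p.preferred_bin < p.n_bins):
                raise ConfigError("planted TC preferred_bin out of range")

    def _check(self, unit: int, episode) -> None:
        if not (0 <= unit < self.n_units):
            raise ConfigError(f"planted unit index {unit} out of range")
        if episode is not None and not (0 <= episode < self.n_episodes):
            raise ConfigError(f"planted episode index {episode} out of range")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key, klass in (
            ("planted_esn", PlantedESN),
            ("planted_tesn", PlantedTESN),
            ("planted_concept", PlantedConcept),
            ("planted_tc", PlantedTC),
        ):
            if key in raw:
                items = []
                for item in raw[key]:
                    if "latencies_s" in item:
                        item["latencies_s"] = tuple(item["latencies_s"])
                    items.append(klass(**item))
                raw[key] = items
        for key in ("enc_duration_s", "ret_duration_s", "iti_s", "distractor_s", "tuning_gap_s"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _poisson_times(rng: np.random.Generator, rate_hz: float, start: float, end: float) -> np.ndarray:
    """Homogeneous Poisson arrivals on [start, end)."""
    if end <= start or rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * (end - start))
    return np.sort(rng.uniform(start, end, size=n))


def episode_image_ids(episode_id: str) -> Tuple[str, str]:
    """Tuning-task image ids derived from an episode: its cue and associate.

    The ``"<episode_id>:<role>"`` convention links visual-tuning images
    back to episodes for the Experiment-2 trial exclusion.
    """
    return (f"{episode_id}:cue", f"{episode_id}:assoc")


def image_episode(image_id: str) -> str:
    """Inverse of :func:`episode_image_ids` (episode stem of an image id)."""
    return str(image_id).split(":", 1)[0]


def generate_session(config: SyntheticConfig):
    """Generate a session plus its ground-truth table.

    Pure function of ``config`` (including ``config.seed``): the same
    config yields byte-identical spike tables.

    Returns
    -------
    (Session, pandas.DataFrame)
        The ground-truth table has columns
        ``unit_id, target, effect_type, magnitude``.
    """
    rng = np.random.default_rng(config.seed)
    n_ep = config.n_episodes

    # --- behavioural labels -------------------------------------------------
    remembered = rng.random(n_ep) < config.hit_rate
    for p in list(config.planted_esn) + list(config.planted_tesn):
        remembered[p.episode] = True

    # --- task timeline ------------------------------------------------------
    episodes = []
    blocks = []
    t = 5.0  # lead-in
    order = np.arange(n_ep)
    for b0 in range(0, n_ep, config.episodes_per_block):
        chunk = order[b0 : b0 + config.episodes_per_block]
        block_start = t
        enc_events = {}
        for i in chunk:
            cue = t
            assoc = cue + 2.0
            resp = assoc + float(_log_uniform(rng, *config.enc_duration_s))
            enc_events[i] = (cue, assoc, resp)
            t = resp + rng.uniform(*config.iti_s)
        block_end = t
        blocks.append((block_start, block_end))
        t += float(_log_uniform(rng, *config.distractor_s))
        ret_order = rng.permutation(chunk)
        ret_events = {}
        for i in ret_order:
            cue = t
            resp = cue + float(_log_uniform(rng, *config.ret_duration_s))
            ret_events[i] = (cue, resp)
            t = resp + rng.uniform(*config.iti_s)
        t += 5.0
        for i in chunk:
            cue, assoc, resp = enc_events[i]
            rcue, rresp = ret_events[i]
            episodes.append(
                EpisodeEvents(
                    episode_id=f"ep{i:03d}",
                    enc_cue_onset_s=cue,
                    enc_assoc_onset_s=assoc,
                    enc_response_s=resp,
                    ret_cue_onset_s=rcue,
                    ret_response_s=rresp,
                    remembered=bool(remembered[i]),
                )
            )
    episodes.sort(key=lambda ep: ep.enc_cue_onset_s)
    by_index = {int(ep.episode_id[2:]): ep for ep in episodes}

    # --- visual tuning task -------------------------------------------------
    tuning = None
    if config.include_tuning:
        images = [im for ep in episodes for im in episode_image_ids(ep.episode_id)]
        sequence = np.array(images * config.tuning_repetitions, dtype=object)
        sequence = sequence[rng.permutation(sequence.size)]
        onsets = []
        for _ in sequence:
            onsets.append(t)
            t += config.tuning_display_s + rng.uniform(*config.tuning_gap_s)
        tuning = TuningEvents(sequence, np.asarray(onsets))

    session_end = t + 1.0

    # --- spikes -------------------------------------------------------------
    extra_rate = config.base_rate_hz  # planted gains multiply the base rate
    units = []
    truth_rows = []
    for u in range(config.n_units):
        unit_id = f"u{u:03d}"
        spikes = [_poisson_times(rng, config.base_rate_hz, 0.0, session_end)]
        for p in config.planted_esn:
            if p.unit != u:
                continue
            ep = by_index[p.episode]
            add = (p.rate_gain - 1.0) * extra_rate
            spikes.append(_poisson_times(rng, add, ep.enc_assoc_onset_s, ep.enc_response_s))
            spikes.append(_poisson_times(rng, add, ep.ret_cue_onset_s, ep.ret_response_s))
            truth_rows.append((unit_id, ep.episode_id, "esn", p.rate_gain))
        for p in config.planted_tesn:
            if p.unit != u:
                continue
            ep = by_index[p.episode]
            for anchor in (ep.enc_response_s, ep.ret_response_s):
                for _ in range(p.repeats):
                    for lat in p.latencies_s:
                        spikes.append(
                            np.atleast_1d(anchor + lat + rng.normal(0.0, p.jitter_sd_s))
                        )
            truth_rows.append((unit_id, ep.episode_id, "tesn", float(len(p.latencies_s))))
        for p in config.planted_concept:
            if p.unit != u:
                continue
            if tuning is None:
                raise ConfigError("planted concept cells require include_tuning=True")
            add = (p.response_gain - 1.0) * extra_rate
            for onset in tuning.onsets_of(p.image_id):
                spikes.append(_poisson_times(rng, add, onset, onset + 1.0))
            truth_rows.append((unit_id, p.image_id, "concept", p.response_gain))
        for p in config.planted_tc:
            if p.unit != u:
                continue
            add = (p.gain - 1.0) * extra_rate
            for lo, hi in blocks:
                width = (hi - lo) / p.n_bins
                b_lo = lo + p.preferred_bin * width
                spikes.append(_poisson_times(rng, add, b_lo, b_lo + width))
            truth_rows.append((unit_id, f"bin{p.preferred_bin}", "tc", p.gain))
        merged = np.sort(np.concatenate(spikes))
        merged = merged[(merged >= 0) & (merged < session_end)]
        units.append(SpikeTrain(unit_id, config.region, merged))

    session = Session(config.session_id, units, episodes, tuning, blocks)
    truth = pd.DataFrame(truth_rows, columns=["unit_id", "target", "effect_type", "magnitude"])
    return session, truth


@dataclass
class PseudoRateMatrix:
    """Uniform pseudo-firing-rates for the false-positive calibration."""

    enc: np.ndarray
    ret: np.ndarray
    variance_factor: float


def generate_pseudo_rates(
    n_units: int,
    n_trials: int,
    variance_factor: float,
    rng: Optional[np.random.Generator] = None,
) -> PseudoRateMatrix:
    """i.i.d. uniform(0, variance_factor) pseudo-rates, open at both ends."""
    if n_trials < 2:
        raise ConfigError("need at least two trials")
    if variance_factor <= 0:
        raise ConfigError("variance_factor must be positive")
    rng = np.random.default_rng(rng)

    def draw():
        x = rng.random((n_units, n_trials))
        while np.any(x == 0.0):  # open interval at zero
            x[x == 0.0] = rng.random(int(np.sum(x == 0.0)))
        return x * variance_factor

    return PseudoRateMatrix(draw(), draw(), float(variance_factor))


def circular_surrogate(
    session: Session,
    rng: Optional[np.random.Generator] = None,
    granularity: str = "episode",
    offset: Optional[int] = None,
) -> Session:
    """Null session: episode-segmented spike times circularly shuffled.

    ``granularity="episode"`` (default) rotates the chronological
    sequence of per-segment spike blocks (segments = every episode's
    encoding span and retrieval span) by one random offset per unit,
    re-anchoring within-segment offsets proportionally to the new
    segment's length.  ``granularity="session"`` instead circularly
    shifts all spike times within the whole recording.  Spike counts per
    unit are preserved either way.  ``offset`` fixes the rotation (same
    for every unit) instead of drawing it per unit.
    """
    if session.n_episodes < 2:
        raise ValueError("need at least two episodes for a circular surrogate")
    rng = np.random.default_rng(rng)
    new_units = []
    if granularity == "session":
        dur = session.duration_s + 1e-9
        for u in session.units:
            off = rng.uniform(0.0, dur)
            t = np.sort((u.spike_times + off) % dur)
            new_units.append(SpikeTrain(u.unit_id, u.region, t))
    elif granularity == "episode":
        segments = []
        for ep in session.episodes:
            segments.append((ep.enc_cue_onset_s, ep.enc_response_s))
            segments.append((ep.ret_cue_onset_s, ep.ret_response_s))
        segments.sort()
        n_seg = len(segments)
        for u in session.units:
            k = int(rng.integers(0, n_seg)) if offset is None else int(offset) % n_seg
            t = u.spike_times.copy()
            moved = np.zeros(t.size, dtype=bool)
            out = t.copy()
            for i, (lo, hi) in enumerate(segments):
                nlo, nhi = segments[(i + k) % n_seg]
                sel = (t >= lo) & (t < hi) & ~moved
                out[sel] = nlo + (t[sel] - lo) * (nhi - nlo) / (hi - lo)
                moved |= sel
            new_units.append(SpikeTrain(u.unit_id, u.region, np.sort(out)))
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    return Session(
        session.session_id + "-surrogate",
        new_units,
        session.episodes,
        session.tuning,
        session.block_boundaries,
    )


def random_spike_times(
    train: SpikeTrain, rng: Optional[np.random.Generator] = None
) -> SpikeTrain:
    """Integer-valued random spike times spanning the empirical range.

    Empirical first/last spike times are rounded to the nearest integer
    second and the same number of spikes is redrawn from the discrete
    uniform distribution on that closed interval.
    """
    if train.n_spikes < 2:
        raise ValueError("need at least two spikes")
    rng = np.random.default_rng(rng)
    lo = int(np.rint(train.spike_times[0]))
    hi = int(np.rint(train.spike_times[-1]))
    if lo == hi:
        raise ValueError("degenerate spike-time range after rounding")
    t = np.sort(rng.integers(lo, hi + 1, size=train.n_spikes)).astype(float)
    return SpikeTrain(train.unit_id, train.region, t)
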