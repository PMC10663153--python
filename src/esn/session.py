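"""Domain types for single-unit episodic-memory sessions.

A *session* is one recording of a self-paced one-shot association task:
the participant encodes a cue-associate episode once (cue shown 2 s before
the associate images) and later retrieves it once from the cue.  All
analyses operate on sorted spike times (seconds from session start) and
half-open time windows ``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

REGIONS = ("hippocampus", "parahippocampus", "other")

#: Nominal cue -> associate-onset delay at encoding (seconds).
CUE_TO_ASSOC_S = 2.0
#: Tolerance on the cue -> associate delay (seconds); display jitter is
#: bounded well below one monitor frame.
CUE_TO_ASSOC_TOL_S = 1e-3


class SchemaError(ValueError):
    """A required column or field is missing from an input table."""


class ValidationError(ValueError):
    """An input value violates a session invariant."""


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time window ``[start_s, end_s)`` in seconds."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (self.end_s > self.start_s):
            raise ValidationError(
                f"window end ({self.end_s}) must be greater than start ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit.

    ``spike_times`` are seconds from session start, strictly
    non-decreasing, finite and non-negative.
    """

    unit_id: str
    region: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(
                f"unit {self.unit_id}: region {self.region!r} not in {REGIONS}"
            )
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: spike_times must be 1-D")
        if t.size and not np.all(np.isfinite(t)):
            raise ValidationError(f"unit {self.unit_id}: non-finite spike times")
        if t.size and t.min() < 0:
            raise ValidationError(f"unit {self.unit_id}: negative spike times")
        if np.any(np.diff(t) < 0):
            warnings.warn(
                f"unit {self.unit_id}: spike times were not sorted; sorting",
                stacklevel=2,
            )
            t = np.sort(t)
        self.spike_times = t

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class EpisodeEvents:
    """Event markers of one episode (all times in session seconds)."""

    episode_id: str
    enc_cue_onset_s: float
    enc_assoc_onset_s: float
    enc_response_s: float
    ret_cue_onset_s: float
    ret_response_s: float
    remembered: bool

    def __post_init__(self) -> None:
        e = self.episode_id
        if not (self.enc_cue_onset_s < self.enc_assoc_onset_s < self.enc_response_s):
            raise ValidationError(f"episode {e}: encoding events out of order")
        if not (self.ret_cue_onset_s < self.ret_response_s):
            raise ValidationError(f"episode {e}: retrieval events out of order")
        delay = self.enc_assoc_onset_s - self.enc_cue_onset_s
        if abs(delay - CUE_TO_ASSOC_S) > CUE_TO_ASSOC_TOL_S:
            raise ValidationError(
                f"episode {e}: cue->associate delay {delay:.4f} s deviates from "
                f"{CUE_TO_ASSOC_S} s by more than {CUE_TO_ASSOC_TOL_S} s"
            )

    @property
    def encoding_window(self) -> AnalysisWindow:
        """Associate onset to response: the span where the whole episode is present."""
        return AnalysisWindow(self.enc_assoc_onset_s, self.enc_response_s)

    @property
    def retrieval_window(self) -> AnalysisWindow:
        """Cue onset to the remembered-count response."""
        return AnalysisWindow(self.ret_cue_onset_s, self.ret_response_s)


@dataclass
class TuningEvents:
    """Image presentations of the visual tuning task (one row per onset)."""

    image_ids: np.ndarray
    onsets_s: np.ndarray

    def __post_init__(self) -> None:
        self.image_ids = np.asarray(self.image_ids, dtype=object)
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.image_ids.shape != self.onsets_s.shape:
            raise ValidationError("tuning: image_ids and onsets_s differ in length")
        if np.any(np.diff(self.onsets_s) <= 0):
            raise ValidationError("tuning: onsets must be strictly increasing")
        if self.onsets_s.size > 1 and np.min(np.diff(self.onsets_s)) <= 1.0:
            raise ValidationError(
                "tuning: inter-onset interval must exceed 1 s (1 s display + jitter)"
            )

    @property
    def images(self) -> list:
        seen: dict = {}
        for im in self.image_ids:
            seen.setdefault(im, None)
        return list(seen)

    def onsets_of(self, image_id) -> np.ndarray:
        return self.onsets_s[self.image_ids == image_id]

    @property
    def n_presentations(self) -> int:
        return int(self.onsets_s.size)


@dataclass
class Session:
    """One recording: units, episode events, optional tuning task, blocks."""

    session_id: str
    units: list = field(default_factory=list)
    episodes: list = field(default_factory=list)
    tuning: Optional[TuningEvents] = None
    block_boundaries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for phase in ("encoding", "retrieval"):
            wins = sorted(
                (self.window(ep, phase) for ep in self.episodes),
                key=lambda w: w.start_s,
            )
            for a, b in zip(wins, wins[1:]):
                if b.start_s < a.end_s:
                    raise ValidationError(
                        f"session {self.session_id}: overlapping {phase} windows"
                    )
        for lo, hi in self.block_boundaries:
            if not any(
                lo <= ep.enc_cue_onset_s and ep.enc_response_s <= hi
                for ep in self.episodes
            ):
                raise ValidationError(
                    f"session {self.session_id}: block [{lo}, {hi}] encloses no episode"
                )

    @staticmethod
    def window(episode: EpisodeEvents, phase: str) -> AnalysisWindow:
        if phase == "encoding":
            return episode.encoding_window
        if phase == "retrieval":
            return episode.retrieval_window
        raise ValueError(f"unknown phase {phase!r}")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_episodes(self) -> int:
        return len(self.episodes)

    @property
    def remembered_mask(self) -> np.ndarray:
        return np.array([ep.remembered for ep in self.episodes], dtype=bool)

    @property
    def duration_s(self) -> float:
        """End of the last event or spike, whichever is later."""
        t = 0.0
        for ep in self.episodes:
            t = max(t, ep.enc_response_s, ep.ret_response_s)
        if self.tuning is not None and self.tuning.onsets_s.size:
            t = max(t, float(self.tuning.onsets_s[-1]) + 1.0)
        for u in self.units:
            if u.n_spikes:
                t = max(t, float(u.spike_times[-1]))
        return t


def count_spikes(train: SpikeTrain, window: AnalysisWindow) -> int:
    """Number of spikes with ``start <= t < end`` (half-open window)."""
    lo, hi = np.searchsorted(train.spike_times, [window.start_s, window.end_s], side="left")
    return int(hi - lo)


def spikes_in(train: SpikeTrain, window: AnalysisWindow) -> np.ndarray:
    """Spike times falling in the half-open window."""
    lo, hi = np.searchsorted(train.spike_times, [window.start_s, window.end_s], side="left")
    return train.spike_times[lo:hi]
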