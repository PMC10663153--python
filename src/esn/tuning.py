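"""Putative concept-cell (visual tuning) detection.

Post-stimulus spiking in 19 overlapping 100-ms bins (50-ms step over the
first second — the unique tiling that yields 19 bins) is compared per bin
to the pooled 500-ms pre-stimulus baselines of every presentation in the
session with a two-tailed Mann-Whitney U test; the 19 bin p-values are
combined with the Simes procedure.  A unit counts as tuned to an image at
the conventional threshold P < 0.0005 or at the liberal P < 0.05; there
is deliberately no correction across images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .session import AnalysisWindow, SpikeTrain, TuningEvents, count_spikes

N_BINS = 19
BIN_WIDTH_S = 0.100
BIN_STEP_S = 0.050
BASELINE_S = 0.500


@dataclass
class TuningTestResult:
    bin_p_values: np.ndarray
    simes_p: float
    significant_at: dict
    increase: bool = True
    unit_id: str = ""
    image_id: str = ""


def binned_counts(train: SpikeTrain, onsets: np.ndarray) -> np.ndarray:
    """19 x n_presentations spike counts in bins [50k, 50k+100) ms post-onset."""
    onsets = np.asarray(onsets, dtype=float)
    out = np.empty((N_BINS, onsets.size), dtype=int)
    for k in range(N_BINS):
        lo = k * BIN_STEP_S
        for j, onset in enumerate(onsets):
            out[k, j] = count_spikes(train, AnalysisWindow(onset + lo, onset + lo + BIN_WIDTH_S))
    return out


def baseline_counts(train: SpikeTrain, all_onsets: np.ndarray) -> np.ndarray:
    """Spike count in [onset - 500 ms, onset) for every presentation of any image."""
    all_onsets = np.asarray(all_onsets, dtype=float)
    return np.array(
        [count_spikes(train, AnalysisWindow(t - BASELINE_S, t)) for t in all_onsets],
        dtype=int,
    )


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-tailed Mann-Whitney U p-value.

    Exact enumeration for tiny tie-free samples (both n <= 8); otherwise
    the normal approximation with continuity and tie correction — spike
    counts are heavily tied, and the exact method does not correct ties.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test needs at least one observation per group")
    both = np.concatenate([x, y])
    if np.all(both == both[0]):
        return 1.0
    tiny = x.size <= 8 and y.size <= 8
    no_ties = np.unique(both).size == both.size
    method = "exact" if (tiny and no_ties) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def simes(p_values: np.ndarray) -> float:
    """Simes global-null p: min over sorted p_(i) of m * p_(i) / i, capped at 1."""
    p = np.sort(np.asarray(p_values, dtype=float))
    m = p.size
    return float(min(1.0, np.min(m * p / np.arange(1, m + 1))))


def tuning_test(
    bin_matrix: np.ndarray,
    baseline_vector: np.ndarray,
    alphas=(0.0005, 0.05),
    unit_id: str = "",
    image_id: str = "",
) -> TuningTestResult:
    """Binned rank-sum + Simes test of one (unit, image) pair."""
    bin_matrix = np.asarray(bin_matrix)
    if bin_matrix.ndim != 2 or bin_matrix.shape[0] != N_BINS:
        raise ValueError(f"bin matrix must be {N_BINS} x n_presentations")
    if bin_matrix.shape[1] < 1:
        raise ValueError("need at least one presentation")
    p = np.array([rank_sum_p(bin_matrix[k], baseline_vector) for k in range(N_BINS)])
    sp = simes(p)
    # a tuned RESPONSE is a firing increase: the best bin's rate must exceed
    # the baseline rate.  Without this gate the two-tailed count comparison
    # flags high-rate units merely because 100-ms bin counts sit below
    # 500-ms baseline counts.
    best = int(np.argmin(p))
    bin_rate = bin_matrix[best].mean() / BIN_WIDTH_S
    base_rate = float(np.mean(baseline_vector)) / BASELINE_S
    increase = bool(bin_rate > base_rate)
    return TuningTestResult(
        bin_p_values=p,
        simes_p=sp,
        significant_at={a: sp < a and increase for a in alphas},
        increase=increase,
        unit_id=unit_id,
        image_id=image_id,
    )


def unit_is_concept(train: SpikeTrain, tuning: TuningEvents, alpha: float = 0.0005) -> set:
    """Image ids the unit is significantly tuned to at ``alpha``."""
    if tuning is None:
        raise ValueError("tuning-task event table is required for concept detection")
    baseline = baseline_counts(train, tuning.onsets_s)
    tuned = set()
    for image in tuning.images:
        bins = binned_counts(train, tuning.onsets_of(image))
        res = tuning_test(bins, baseline, alphas=(alpha,), unit_id=train.unit_id, image_id=image)
        if res.significant_at[alpha]:
            tuned.add(image)
    return tuned
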