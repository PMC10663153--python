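"""Baseline-standardized spike-density traces and the reinstated vs
non-reinstated comparison.

Per episode, spikes around the cue (1 s before to 5 s after) are smoothed
with the peak-normalized 100-ms Gaussian kernel, and the trace is
z-scored against the pre-cue baselines of ALL episodes:

    z(t) = (x(t) - mean of per-episode baseline means)
           / (sd of per-episode baseline means + 0.1)

The +0.1 regularizer keeps silent units finite.  Reinstated and
non-reinstated episode counts are equalized by bootstrap (N = 100
draws) before a paired, cluster-based permutation test across units
controls family-wise error over timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .session import Session, SpikeTrain
from .stats import permutation_p
from .temporal import KernelConfig, instantaneous_rate


def zscore_traces(traces: np.ndarray, n_pre_samples: int, regularizer: float = 0.1) -> np.ndarray:
    """Baseline z-scoring of an episodes x time trace matrix.

    z = (x - grand mean of per-episode baseline means)
        / (sd across per-episode baseline means + regularizer)
    """
    traces = np.asarray(traces, dtype=float)
    if traces.shape[0] < 2:
        raise ValueError("need at least two episodes (baseline sd undefined otherwise)")
    baselines = traces[:, :n_pre_samples].mean(axis=1)
    center = baselines.mean()
    spread = baselines.std(ddof=1) + regularizer
    return (traces - center) / spread


@dataclass
class DensityTrace:
    unit_id: str
    episode_id: str
    phase: str
    z_trace: np.ndarray
    label: str = ""  # "reinstated" | "non_reinstated"


def density_zscore(
    train: SpikeTrain,
    episodes: Sequence,
    phase: str = "encoding",
    kernel: KernelConfig = KernelConfig(),
    pre_s: float = 1.0,
    post_s: float = 5.0,
    regularizer: float = 0.1,
) -> list:
    """Eq.-style baseline z-scored density traces, one per episode."""
    if len(episodes) < 2:
        raise ValueError("need at least two episodes (baseline sd undefined otherwise)")
    fs = kernel.sample_rate_hz
    n_pre = int(round(pre_s * fs))
    raw = []
    for ep in episodes:
        cue = ep.enc_cue_onset_s if phase == "encoding" else ep.ret_cue_onset_s
        # direct kernel evaluation with no extra trimming: spikes just outside
        # the span still contribute their kernel mass at the edges
        trial = instantaneous_rate(
            train, cue + post_s, kernel,
            pre_s=pre_s + post_s + kernel.half_support_s,
            post_s=kernel.half_support_s,
            trim_s=kernel.half_support_s,
            episode_id=ep.episode_id, phase=phase,
        )
        raw.append(trial.rate_trace)
    z = zscore_traces(np.asarray(raw), n_pre, regularizer)
    return [
        DensityTrace(train.unit_id, ep.episode_id, phase, z[i])
        for i, ep in enumerate(episodes)
    ]


def bootstrap_equalize(
    traces_a: Sequence[DensityTrace],
    traces_b: Sequence[DensityTrace],
    n_boot: int = 100,
    rng: Optional[np.random.Generator] = None,
):
    """Equalize episode counts between two labels by bootstrap.

    Each draw resamples both classes with replacement down to the smaller
    class size and returns the per-draw mean trace of each class.  Units
    with an empty class cannot be equalized; callers drop them first.
    """
    if not traces_a or not traces_b:
        raise ValueError("both labels must be present to equalize")
    rng = np.random.default_rng(rng)
    a = np.asarray([t.z_trace for t in traces_a])
    b = np.asarray([t.z_trace for t in traces_b])
    n = min(a.shape[0], b.shape[0])
    means_a = np.empty((n_boot, a.shape[1]))
    means_b = np.empty((n_boot, b.shape[1]))
    for d in range(n_boot):
        means_a[d] = a[rng.integers(0, a.shape[0], size=n)].mean(axis=0)
        means_b[d] = b[rng.integers(0, b.shape[0], size=n)].mean(axis=0)
    return means_a, means_b


@dataclass
class Cluster:
    start: int
    stop: int  # half-open sample range
    mass: float
    p_value: float


@dataclass
class ClusterPermResult:
    t_values: np.ndarray
    critical_t: float
    clusters: list
    null_max_mass: np.ndarray

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        mask = np.zeros(self.t_values.size, dtype=bool)
        for c in self.clusters:
            if c.p_value < alpha:
                mask[c.start : c.stop] = True
        return mask


def _find_clusters(t: np.ndarray, crit: float):
    """Maximal runs of same-sign suprathreshold t; single points allowed."""
    out = []
    for sign in (1.0, -1.0):
        above = sign * t > crit
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        for lo, hi in zip(edges[::2], edges[1::2]):
            out.append((int(lo), int(hi), float(t[lo:hi].sum())))
    out.sort()
    return out


def cluster_permutation(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> ClusterPermResult:
    """Paired cluster-based permutation test between two unit x time matrices.

    Cluster-forming statistic: per-timepoint paired t across units,
    thresholded at the two-tailed ``cluster_alpha`` critical value;
    cluster mass is the summed t.  The null exchanges condition labels
    within units (sign flips of the paired differences) and records the
    maximum absolute cluster mass per iteration.
    """
    a = np.atleast_2d(np.asarray(cond_a, dtype=float))
    b = np.atleast_2d(np.asarray(cond_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("condition matrices must have identical shape")
    n_units, n_time = a.shape
    if n_units < 2:
        raise ValueError("need at least two units for a paired test")
    rng = np.random.default_rng(rng)

    d = a - b
    crit = float(sps.t.ppf(1.0 - cluster_alpha / 2.0, n_units - 1))

    def t_stats(mean, var):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n_units)
        return np.nan_to_num(t)

    mean_emp = d.mean(axis=0)
    var_emp = d.var(axis=0, ddof=1)
    t_emp = t_stats(mean_emp, var_emp)
    raw_clusters = _find_clusters(t_emp, crit)

    # sign-flip null, vectorized: flipping rows changes only the mean term
    sumsq = np.sum(d**2, axis=0)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_units))
    mean_null = signs @ d / n_units
    var_null = (sumsq[None, :] - n_units * mean_null**2) / (n_units - 1)
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        t_p = t_stats(mean_null[p], var_null[p])
        cl = _find_clusters(t_p, crit)
        if cl:
            null_max[p] = max(abs(m) for _, _, m in cl)

    clusters = [
        Cluster(lo, hi, mass, permutation_p(null_max, abs(mass), "greater"))
        for lo, hi, mass in raw_clusters
    ]
    return ClusterPermResult(t_emp, crit, clusters, null_max)


@dataclass
class DensityComparison:
    """Reinstated vs non-reinstated comparison aggregated over bootstrap draws."""

    mean_a: np.ndarray
    sem_a: np.ndarray
    mean_b: np.ndarray
    sem_b: np.ndarray
    significant_proportion: np.ndarray
    n_units: int
    n_boot: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample": np.arange(self.mean_a.size),
                "mean_reinstated": self.mean_a,
                "sem_reinstated": self.sem_a,
                "mean_non_reinstated": self.mean_b,
                "sem_non_reinstated": self.sem_b,
                "significant_proportion": self.significant_proportion,
            }
        )


def density_comparison(
    per_unit_reinstated: Sequence[Sequence[DensityTrace]],
    per_unit_non_reinstated: Sequence[Sequence[DensityTrace]],
    n_boot: int = 100,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> DensityComparison:
    """Bootstrap-equalized, cluster-corrected comparison across units.

    For each of the ``n_boot`` draws, every unit contributes one
    equalized mean trace per condition; a cluster permutation test is run
    per draw, and the per-timepoint proportion of draws whose significant
    cluster covers the timepoint is reported alongside grand means and
    s.e.m. across units.
    """
    rng = np.random.default_rng(rng)
    keep = [
        i
        for i, (ra, rb) in enumerate(zip(per_unit_reinstated, per_unit_non_reinstated))
        if len(ra) > 0 and len(rb) > 0
    ]
    if len(keep) < 2:
        raise ValueError("need at least two units with both episode labels")
    draws_a, draws_b = [], []
    for i in keep:
        ma, mb = bootstrap_equalize(
            per_unit_reinstated[i], per_unit_non_reinstated[i], n_boot, rng
        )
        draws_a.append(ma)
        draws_b.append(mb)
    # draws_x[unit] has shape (n_boot, T)
    stack_a = np.stack(draws_a, axis=1)  # (n_boot, n_units, T)
    stack_b = np.stack(draws_b, axis=1)

    n_time = stack_a.shape[2]
    cover = np.zeros(n_time)
    for d in range(n_boot):
        res = cluster_permutation(stack_a[d], stack_b[d], n_perm, cluster_alpha, rng)
        cover += res.significant_mask(cluster_alpha)
    unit_mean_a = stack_a.mean(axis=0)  # (n_units, T), average over draws
    unit_mean_b = stack_b.mean(axis=0)
    n_units = len(keep)
    return DensityComparison(
        mean_a=unit_mean_a.mean(axis=0),
        sem_a=unit_mean_a.std(axis=0, ddof=1) / np.sqrt(n_units),
        mean_b=unit_mean_b.mean(axis=0),
        sem_b=unit_mean_b.std(axis=0, ddof=1) / np.sqrt(n_units),
        significant_proportion=cover / n_boot,
        n_units=n_units,
        n_boot=n_boot,
    )
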