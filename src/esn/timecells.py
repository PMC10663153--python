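"""Time-cell (TC) detection within encoding blocks.

Spikes of each encoding block are smoothed with a 251-sample parametric
Gaussian window (width factor 2.5, i.e. sd = (N-1)/(2*2.5) samples at
1 kHz).  Because the task is self-paced, two block x time layouts are
analysed: *normalized* (each block cut into 40 equal bins) and *padded*
(bins on the longest block's clock; shorter blocks padded with NaN).  A
Kruskal-Wallis test asks whether the 40 bins differ across blocks; the
null distribution comes from independently circularly shifting each
block's trace and re-binning.  A group-level count test mirrors the ESN
second level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal
from scipy import stats as sps

from .config import AnalysisConfig
from .session import Session, SpikeTrain, spikes_in, AnalysisWindow
from .stats import GroupTestResult, group_count_test, permutation_p


def gaussian_window(length: int = 251, width_factor: float = 2.5) -> np.ndarray:
    """Classic parametric Gaussian window: exp(-0.5*(a*n/(N/2))^2).

    ``width_factor`` is the inverse-of-sd parameter a, so the sd is
    (N-1)/(2a) samples (50 samples = 50 ms at 1 kHz for the defaults).
    Center value 1, symmetric.
    """
    std = (length - 1) / (2.0 * width_factor)
    return signal.windows.gaussian(length, std)


@dataclass
class BlockTimeMatrix:
    """Block x time smoothed rate traces (padded) or 40-bin means (normalized)."""

    unit_id: str
    mode: str  # "padded" | "normalized"
    matrix: np.ndarray
    block_lengths: np.ndarray  # true (unpadded) lengths in samples


def block_traces(
    train: SpikeTrain,
    block_boundaries: Sequence,
    sample_rate_hz: int = 1000,
    kernel_len: int = 251,
    width_factor: float = 2.5,
) -> BlockTimeMatrix:
    """Smoothed per-block traces, NaN-padded to the longest block."""
    if len(block_boundaries) < 2:
        raise ValueError("need at least two encoding blocks")
    win = gaussian_window(kernel_len, width_factor)
    traces = []
    for lo, hi in block_boundaries:
        n = int(round((hi - lo) * sample_rate_hz))
        counts = np.zeros(n)
        idx = np.floor((spikes_in(train, AnalysisWindow(lo, hi)) - lo) * sample_rate_hz).astype(int)
        np.add.at(counts, np.clip(idx, 0, n - 1), 1.0)
        traces.append(np.convolve(counts, win, mode="same"))
    lengths = np.array([t.size for t in traces])
    width = int(lengths.max())
    mat = np.full((len(traces), width), np.nan)
    for i, t in enumerate(traces):
        mat[i, : t.size] = t
    return BlockTimeMatrix(train.unit_id, "padded", mat, lengths)


def _bin_edges(length: int, n_bins: int) -> np.ndarray:
    return np.round(np.linspace(0, length, n_bins + 1)).astype(int)


def _binned_means_row(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    out = np.full(edges.size - 1, np.nan)
    for k in range(edges.size - 1):
        lo, hi = edges[k], edges[k + 1]
        hi = min(hi, x.size)
        if hi > lo:
            out[k] = float(np.mean(x[lo:hi]))
    return out


def normalize_blocks(matrix: BlockTimeMatrix, n_bins: int = 40) -> BlockTimeMatrix:
    """Cut each block's true extent into ``n_bins`` equal spans (bin means)."""
    if matrix.mode != "padded":
        raise ValueError("normalize_blocks expects a padded matrix")
    rows = []
    for i, L in enumerate(matrix.block_lengths):
        if L < n_bins:
            raise ValueError(f"block {i} shorter than {n_bins} samples")
        rows.append(_binned_means_row(matrix.matrix[i, :L], _bin_edges(int(L), n_bins)))
    return BlockTimeMatrix(matrix.unit_id, "normalized", np.asarray(rows), matrix.block_lengths)


def padded_bins(matrix: BlockTimeMatrix, n_bins: int = 40) -> np.ndarray:
    """40-bin means on the longest block's clock; all-missing bins are NaN."""
    width = matrix.matrix.shape[1]
    edges = _bin_edges(width, n_bins)
    return np.asarray(
        [_binned_means_row(matrix.matrix[i, : int(L)], edges) for i, L in enumerate(matrix.block_lengths)]
    )


def kruskal_h(values: np.ndarray) -> float:
    """Kruskal-Wallis H over the columns of a blocks x bins matrix (NaN dropped),
    with tie correction; matches ``scipy.stats.kruskal`` on the same groups."""
    return float(_kruskal_h_many(values[None, ...])[0])


def _kruskal_h_many(stack: np.ndarray) -> np.ndarray:
    """Vectorized H for a (n_perm, n_blocks, n_bins) stack of binned matrices."""
    n_perm, n_blocks, n_bins = stack.shape
    flat = stack.reshape(n_perm, -1)
    valid = ~np.isnan(flat)
    ranks = sps.rankdata(flat, axis=1, nan_policy="omit")
    n_tot = valid.sum(axis=1).astype(float)

    group = np.tile(np.arange(n_bins), n_blocks)
    h = np.zeros(n_perm)
    for g in range(n_bins):
        sel = group == g
        r = np.where(valid[:, sel], ranks[:, sel], 0.0)
        n_g = valid[:, sel].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            h += np.where(n_g > 0, r.sum(axis=1) ** 2 / n_g, 0.0)
    h = 12.0 / (n_tot * (n_tot + 1.0)) * h - 3.0 * (n_tot + 1.0)

    # tie correction: 1 - sum(t^3 - t) / (N^3 - N)
    s = np.sort(np.where(valid, flat, np.inf), axis=1)
    with np.errstate(invalid="ignore"):  # inf - inf in padded tails -> NaN != 0
        same = np.diff(s, axis=1) == 0
    ties = np.zeros(n_perm)
    for p in range(n_perm):
        row = same[p]
        if not row.any():
            continue
        # run lengths of equal consecutive values
        edges = np.flatnonzero(np.diff(np.concatenate(([0], row.view(np.int8), [0]))))
        starts, ends = edges[::2], edges[1::2]
        t = (ends - starts + 1).astype(float)
        ties[p] = np.sum(t**3 - t)
    corr = 1.0 - ties / (n_tot**3 - n_tot)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(corr > 0, h / corr, np.nan)
    return h


@dataclass
class TCResult:
    unit_id: str
    mode: str
    h_statistic: float
    p_perm: float
    threshold: float
    is_tc: bool
    null_h: np.ndarray


def _shifted_binned(
    trace: np.ndarray, shifts: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Bin means of circularly shifted copies of ``trace`` (one row per shift).

    Uses a cumulative sum so each shift costs O(n_bins), not O(len(trace)).
    Bins reaching past the trace's true length (padded mode) are NaN.
    """
    L = trace.size
    c = np.concatenate(([0.0], np.cumsum(trace)))

    def seg_sum(a, m):  # sums over wrapped [a, a + m) for an array of starts a
        a = np.mod(a, L)
        end = a + m
        wrap = end > L
        return np.where(
            wrap, (c[L] - c[a]) + c[np.clip(end - L, 0, L)], c[np.clip(end, 0, L)] - c[a]
        )

    n_bins = edges.size - 1
    out = np.full((shifts.size, n_bins), np.nan)
    for k in range(n_bins):
        lo, hi = int(edges[k]), int(min(edges[k + 1], L))
        if hi <= lo:
            continue
        out[:, k] = seg_sum(shifts + lo, hi - lo) / (hi - lo)
    return out


def tc_test(
    matrix: BlockTimeMatrix,
    n_bins: int = 40,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    return_perm_flags: bool = False,
):
    """Kruskal-Wallis bin test with a circular-shift permutation null.

    Each permutation independently shifts every block's (unpadded) trace
    by a uniform random offset, re-bins, and recomputes H; the unit is a
    TC when the empirical H reaches the (1-alpha) percentile of the null.
    """
    rng = np.random.default_rng(rng)
    if matrix.mode != "padded":
        raise ValueError("tc_test expects the padded block x time matrix")
    n_blocks = matrix.matrix.shape[0]
    binned = padded_bins(matrix, n_bins)
    h_emp = kruskal_h(binned)

    stack = np.empty((n_perm, n_blocks, n_bins))
    for i, L in enumerate(matrix.block_lengths):
        L = int(L)
        trace = matrix.matrix[i, :L]
        edges = _bin_edges(matrix.matrix.shape[1], n_bins)
        shifts = rng.integers(0, L, size=n_perm)
        stack[:, i, :] = _shifted_binned(trace, shifts, edges)
    null_h = _kruskal_h_many(stack)
    thr = float(np.percentile(null_h, 100.0 * (1.0 - alpha)))
    p = permutation_p(null_h, h_emp, "greater")
    res = TCResult(matrix.unit_id, "padded", h_emp, p, thr, bool(h_emp >= thr), null_h)
    if return_perm_flags:
        return res, null_h >= thr
    return res


def tc_test_normalized(
    matrix: BlockTimeMatrix,
    n_bins: int = 40,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    rng: Optional[np.random.Generator] = None,
    return_perm_flags: bool = False,
):
    """Normalized-duration variant: bins tile each block's own extent."""
    rng = np.random.default_rng(rng)
    if matrix.mode != "padded":
        raise ValueError("tc_test_normalized expects the padded block x time matrix")
    n_blocks = matrix.matrix.shape[0]
    binned = normalize_blocks(matrix, n_bins).matrix
    h_emp = kruskal_h(binned)

    stack = np.empty((n_perm, n_blocks, n_bins))
    for i, L in enumerate(matrix.block_lengths):
        L = int(L)
        trace = matrix.matrix[i, :L]
        edges = _bin_edges(L, n_bins)
        shifts = rng.integers(0, L, size=n_perm)
        stack[:, i, :] = _shifted_binned(trace, shifts, edges)
    null_h = _kruskal_h_many(stack)
    thr = float(np.percentile(null_h, 100.0 * (1.0 - alpha)))
    p = permutation_p(null_h, h_emp, "greater")
    res = TCResult(matrix.unit_id, "normalized", h_emp, p, thr, bool(h_emp >= thr), null_h)
    if return_perm_flags:
        return res, null_h >= thr
    return res


@dataclass
class TCDetectionResult:
    results: list
    perm_flags: Optional[np.ndarray]
    group: Optional[GroupTestResult] = None

    @property
    def empirical_count(self) -> int:
        return sum(r.is_tc for r in self.results)

    @property
    def tc_unit_ids(self) -> list:
        return [r.unit_id for r in self.results if r.is_tc]


def detect_tc_session(
    session: Session,
    config: Optional[AnalysisConfig] = None,
    mode: str = "normalized",
    rng: Optional[np.random.Generator] = None,
    run_group_test: bool = True,
) -> TCDetectionResult:
    cfg = config or AnalysisConfig()
    rng = np.random.default_rng(rng)
    test = tc_test_normalized if mode == "normalized" else tc_test
    results, rows = [], []
    for train in session.units:
        if len(session.block_boundaries) < 2:
            continue  # unit skipped: a single block cannot show reproducibility
        mat = block_traces(
            train, session.block_boundaries, cfg.sample_rate_hz, cfg.tc_kernel_len, cfg.tc_width_factor
        )
        res, flags = test(mat, cfg.tc_n_bins, cfg.tc_n_perm, cfg.tc_alpha, rng, return_perm_flags=True)
        results.append(res)
        rows.append(flags)
    perm_flags = np.array(rows, dtype=bool) if rows else None
    out = TCDetectionResult(results, perm_flags)
    if run_group_test and perm_flags is not None:
        out.group = tc_group_test(results, perm_flags, cfg.tc_n_perm, rng)
    return out


def tc_group_test(
    results: Sequence,
    stored_perm_flags: Optional[np.ndarray],
    n_draws: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> GroupTestResult:
    if stored_perm_flags is None:
        raise ValueError(
            "stored first-level permutations are required; re-run "
            "detect_tc_session with permutation retention enabled"
        )
    rng = np.random.default_rng(rng)
    empirical = sum(r.is_tc for r in results)
    return group_count_test(stored_perm_flags, empirical, n_draws, rng, label="tc")


def unit_overlap_test(
    flags_a: np.ndarray,
    flags_b: np.ndarray,
    n_perm: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Permutation test of unit-set overlap (e.g. TC vs ESN) by shuffling
    which units carry one of the labels."""
    rng = np.random.default_rng(rng)
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag vectors must align unit-for-unit")
    emp = int(np.sum(a & b))
    null = np.array([int(np.sum(a & b[rng.permutation(b.size)])) for _ in range(n_perm)])
    return {
        "empirical_overlap": emp,
        "p_value": permutation_p(null, emp, "greater"),
        "null_mean": float(null.mean()),
        "n_perm": n_perm,
    }
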