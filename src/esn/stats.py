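"""Shared inference helpers: permutation p-values, group-level count tests,
behavioural chance levels and the z-gate constant."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import comb


def permutation_p(null: np.ndarray, empirical: float, alternative: str = "greater") -> float:
    """Permutation/bootstrap p-value with the (1 + b) / (1 + N) estimator.

    ``alternative="greater"`` counts null values >= the empirical one; it
    never returns exactly zero, so "P < 1/(N+1)" is the strongest claim a
    finite number of draws supports.
    """
    null = np.asarray(null)
    if alternative == "greater":
        b = int(np.sum(null >= empirical))
    elif alternative == "less":
        b = int(np.sum(null <= empirical))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + b) / (1 + null.size)


@dataclass
class GroupTestResult:
    """Second-level (group) permutation test of a unit count."""

    empirical_count: int
    null_counts: np.ndarray
    p_value: float
    label: str = "esn"

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "empirical_count": int(self.empirical_count),
            "p_value": float(self.p_value),
            "n_draws": int(np.asarray(self.null_counts).size),
            "null_counts": np.asarray(self.null_counts).astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupTestResult":
        return cls(
            empirical_count=int(d["empirical_count"]),
            null_counts=np.asarray(d["null_counts"], dtype=int),
            p_value=float(d["p_value"]),
            label=d.get("label", "esn"),
        )


def group_count_test(
    perm_flags: np.ndarray,
    empirical_count: int,
    n_draws: int,
    rng: np.random.Generator,
    label: str = "esn",
) -> GroupTestResult:
    """Group-level permutation test on the number of flagged units.

    ``perm_flags[u, p]`` says whether unit ``u`` would have been flagged
    under its ``p``-th stored first-level permutation.  Each draw picks one
    stored permutation per unit uniformly at random and counts flagged
    units; the one-sided p compares the empirical count with this null.
    """
    perm_flags = np.asarray(perm_flags, dtype=bool)
    if perm_flags.ndim != 2 or perm_flags.shape[1] == 0:
        raise ValueError(
            "stored first-level permutations are required; re-run the "
            "first-level test with permutation retention enabled"
        )
    n_units, n_perm = perm_flags.shape
    idx = rng.integers(0, n_perm, size=(n_draws, n_units))
    null_counts = perm_flags[np.arange(n_units)[None, :], idx].sum(axis=1)
    p = permutation_p(null_counts, empirical_count, "greater")
    return GroupTestResult(int(empirical_count), null_counts.astype(int), p, label)


def z_gate_for_alpha(alpha: float = 0.05) -> float:
    """Right-tailed standard-normal criterion; 1.645 at alpha = 0.05."""
    return float(sps.norm.ppf(1.0 - alpha))


def chance_level(experiment: int) -> float:
    """Probability of a correct recall response by guessing.

    Experiment 1: pick the 2 targets out of a 4-image array -> 1 / C(4,2).
    Experiment 2: pick the 1 target out of 4 -> 1/4.
    """
    if experiment == 1:
        return 1.0 / comb(4, 2, exact=True)
    if experiment == 2:
        return 1.0 / 4.0
    raise ValueError(f"unknown experiment {experiment!r}")


@dataclass
class OverlapTestResult:
    """Permutation test of episode-set overlap between two detectors."""

    pct_a_also_b: float
    pct_b_also_a: float
    p_a_also_b: float
    p_b_also_a: float
    n_perm: int
    applicable: bool = True

    def to_dict(self) -> dict:
        return {
            "pct_a_also_b": self.pct_a_also_b,
            "pct_b_also_a": self.pct_b_also_a,
            "p_a_also_b": self.p_a_also_b,
            "p_b_also_a": self.p_b_also_a,
            "n_perm": self.n_perm,
            "applicable": self.applicable,
        }
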