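"""Analysis configuration.

Every numeric constant of the pipeline lives here with its published
default, so a single flat key-value YAML file can re-parameterize a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # --- rate-code ESN detection ---
    measure: str = "product"           # product | sum | normalized_product
    z_gate: float = 1.645              # right-tailed P < 0.05 on the standard normal
    z_gate_strict: float = 2.6         # conservative variant
    n_perm_rate: int = 10_000          # first-level encoding-order permutations
    n_draws_rate: int = 10_000         # second-level (group) draws
    percentile: float = 99.0           # pooled-shuffle threshold percentile
    min_episodes: int = 8              # minimum episodes after hit/miss restriction
    normalized_eps: float = 1e-6       # floor on |E - R| for the normalized product
    strict_threshold: bool = False     # if True use > instead of >= at the threshold
    sd_ddof: int = 1                   # sample sd for z-scoring
    cue_exclusion_alpha: float = 0.0005
    miss_n_boot: int = 10_000

    # --- temporal-code (tESN) detection ---
    kernel_sd_s: float = 0.100         # Gaussian kernel sd
    kernel_half_support_s: float = 0.300
    sample_rate_hz: int = 1000
    trial_pre_s: float = 6.0           # raw window: response - 6 s ...
    trial_post_s: float = 1.0          # ... to response + 1 s
    trial_trim_s: float = 1.0          # edges trimmed after convolution
    max_lag_s: float = 2.5
    min_spikes_per_trial: int = 10
    min_trials: int = 10
    n_perm_temporal: int = 1000
    n_draws_temporal: int = 1000
    overlap_n_perm: int = 10_000

    # --- visual tuning (concept cells) ---
    tuning_n_bins: int = 19
    tuning_bin_width_s: float = 0.100
    tuning_bin_step_s: float = 0.050
    tuning_baseline_s: float = 0.500
    tuning_alpha_strict: float = 0.0005
    tuning_alpha_liberal: float = 0.05

    # --- time cells ---
    tc_kernel_len: int = 251           # samples at 1 kHz
    tc_width_factor: float = 2.5
    tc_n_bins: int = 40
    tc_n_perm: int = 10_000
    tc_alpha: float = 0.05

    # --- spike-density comparison ---
    density_pre_s: float = 1.0
    density_post_s: float = 5.0
    density_regularizer: float = 0.1
    density_n_boot: int = 100
    cluster_n_perm: int = 1000
    cluster_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path
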