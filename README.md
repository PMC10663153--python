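# esn-analysis

Detection of **episode-specific neurons (ESNs)** in human single-unit
recordings from one-shot episodic-memory tasks, with the associated
control analyses and calibration machinery.

## The scientific problem

In a self-paced association task, a participant encodes each episode
(an animal cue plus associate images) exactly once and later retrieves
it exactly once from the cue.  The indexing view of hippocampal coding
predicts single units that fire for the *conjunction* of an episode's
elements: such a unit should elevate its firing during the encoding of
one particular episode and again during that same episode's retrieval —
and for no other episode.  The competing explanation is that apparent
episode specificity is really concept tuning (a response to one image)
or time tuning (a response to a recurring within-block time point), so
both must be detected and excluded.

### The rate-code detector

For unit *i* and episode *j*, firing rates are computed in the encoding
window (associate onset → response; the cue alone, shown 2 s earlier,
does not define the episode) and the retrieval window (cue onset →
response).  Rates are z-scored per unit across all episodes, encoding
and retrieval separately, giving *E_ij* and *R_ij*; forgotten episodes
are then removed (sessions keeping < 8 episodes are dropped).  The
per-episode reinstatement value is the product *E_ij · R_ij* (the sum
*E + R* and the similarity-weighted (E·R)/|E−R| are available as
alternatives).  Inference is a two-level permutation scheme:

1. **Unit level.** The encoding episode order is permuted 10,000 times
   (retrieval fixed); all permuted products are pooled and their 99th
   percentile is the unit's threshold.  Episode *j* is *reinstated*
   when its value reaches the threshold **and** `E_ij ≥ 1.645` **and**
   `R_ij ≥ 1.645` (right-tailed P < 0.05 each), which blocks units that
   fire high in only one phase.  A unit with ≥ 1 reinstated episode —
   and no significant cue/image tuning — is an ESN.
2. **Group level.** Each of 10,000 draws picks one stored permutation
   per unit, applies the identical criteria, and counts units that
   qualify; the one-sided p-value is `(1 + #{null ≥ observed}) /
   (1 + draws)`.

### Controls and companions

* **Temporal code (tESN)** — instantaneous rates (Gaussian kernel,
  sd 100 ms, ±300 ms, peak 1) around each response are cross-correlated
  between encoding and retrieval (max lag ±2.5 s); the maximum is
  thresholded against 1,000 pairing shuffles with the same two-level
  logic, after a ≥ 10 spikes/trial and ≥ 10 trials gate.
* **Concept cells** — 19 overlapping 100-ms post-stimulus bins tested
  against pooled 500-ms pre-stimulus baselines (two-tailed rank-sum,
  Simes-combined, thresholds 0.0005 and 0.05, increase-gated).
* **Time cells** — 251-ms Gaussian-smoothed block × time matrices, 40
  bins per encoding block (duration-normalized or NaN-padded),
  Kruskal–Wallis across bins with a per-block circular-shift null.
* **Spike densities** — baseline-z-scored densities around the cue
  (`z = (x − mean_BL) / (sd_BL + 0.1)`), bootstrap count equalization
  (N = 100), and a paired cluster-based permutation test across units.
* **Synthetic sessions** — a generator that plants any of the above
  effects into Poisson baseline spiking with known ground truth, plus
  the two surrogate families used for null calibration (uniform
  pseudo-rates; circular / random-integer spike-time surrogates).

## Worked example

```python
import numpy as np
from esn import AnalysisConfig, SyntheticConfig, PlantedESN
from esn.synthetic import generate_session
from esn.rate import detect_esn_session

cfg = SyntheticConfig(
    n_units=20, n_episodes=30, episodes_per_block=15,
    base_rate_hz=2.0, seed=0,
    planted_esn=[PlantedESN(unit=u, episode=3 * u, rate_gain=5.0) for u in range(5)],
)
session, truth = generate_session(cfg)

ana = AnalysisConfig()
ana.n_perm_rate, ana.n_draws_rate = 1000, 2000
res = detect_esn_session(session, ana, rng=np.random.default_rng(1))
print("ESNs:", res.esn_unit_ids)
print("group p:", round(res.group.p_value, 4))
```

prints

```
ESNs: ['u000', 'u001', 'u002', 'u003', 'u004', 'u018']
group p: 0.0005
```

All five planted units (gain 5 on one episode each, 2 Hz baseline) are
flagged, plus one noise unit — single-unit thresholds are deliberately
not family-wise corrected, which is exactly why the group level exists:
the permutation test puts the count of 6/20 far outside its null
(p = 1/(draws+1) at 2,000 draws means no null draw reached it).  The same session can be written to TSV with
`esn.io.write_session` and analysed from the shell:

```bash
esn simulate --out demo/        # synthetic session + ground_truth.tsv
esn detect-rate demo/ --out out/ --n-perm 1000
esn validate demo/
```

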