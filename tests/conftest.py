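import numpy as np
import pytest

from esn.session import EpisodeEvents, Session, SpikeTrain
from esn.synthetic import PlantedESN, SyntheticConfig, generate_session


@pytest.fixture()
def rng():
    return np.random.default_rng(20230923)


def make_episode(i, enc_start, enc_dur=6.0, ret_start=None, ret_dur=4.0, remembered=True):
    ret_start = enc_start + 100.0 if ret_start is None else ret_start
    return EpisodeEvents(
        episode_id=f"ep{i:03d}",
        enc_cue_onset_s=enc_start,
        enc_assoc_onset_s=enc_start + 2.0,
        enc_response_s=enc_start + 2.0 + enc_dur,
        ret_cue_onset_s=ret_start,
        ret_response_s=ret_start + ret_dur,
        remembered=remembered,
    )


@pytest.fixture()
def tiny_session():
    """Two units, three episodes, hand-laid-out timeline."""
    episodes = [make_episode(i, 10.0 + 12.0 * i, ret_start=100.0 + 8.0 * i) for i in range(3)]
    units = [
        SpikeTrain("u000", "hippocampus", np.array([1.0, 12.5, 13.0, 101.0, 102.0])),
        SpikeTrain("u001", "parahippocampus", np.array([5.0, 50.0, 111.0])),
    ]
    return Session("tiny", units, episodes, None, [(10.0, 10.0 + 12.0 * 3)])


@pytest.fixture(scope="module")
def planted_session():
    """Synthetic session with one strong planted rate ESN (module-scoped)."""
    cfg = SyntheticConfig(
        n_units=6,
        n_episodes=20,
        episodes_per_block=10,
        base_rate_hz=2.0,
        seed=7,
        planted_esn=[PlantedESN(0, 3, rate_gain=8.0)],
    )
    session, truth = generate_session(cfg)
    return session, truth
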