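"""Shared fixtures: small synthetic sessions and fast decoding configs.

All fixtures are generated at run time from seeded configs; nothing is
read from disk.  The reduced sampling rates and repetition counts keep
the suite quick while exercising the same code paths as full-scale runs.
"""

import numpy as np
import pytest

import erpdecode as ed


@pytest.fixture(scope="session")
def fast_cfg():
    """Cheap decoding config: no C search, 2 repetitions."""
    return ed.DecodingConfig(group_size=2, n_folds=5, n_repetitions=2,
                             c_grid=(1.0,), seed=7)


@pytest.fixture(scope="session")
def null_epochs():
    """Balanced two-class epochs with zero class difference (gain 0)."""
    cfg = ed.SimulationConfig(
        n_blocks=1, trials_per_block=120, p_deviant=0.4, sfreq=64,
        gain=ed.GainProfile.constant(1, 0.0), seed=101)
    return ed.undersample_balance(ed.generate_epochs(cfg), 0)


@pytest.fixture(scope="session")
def signal_epochs():
    """Strong MMN+P3a epochs, easily decodable."""
    cfg = ed.SimulationConfig(
        n_blocks=1, trials_per_block=160, p_deviant=0.4, sfreq=64,
        components=(ed.mmn_component(-5.0), ed.p3a_component(6.0)),
        noise_white_sd=5.0, noise_pink_scale=3.0, seed=102)
    return ed.undersample_balance(ed.generate_epochs(cfg), 0)


@pytest.fixture(scope="session")
def noiseless_epochs():
    """Deterministic separable epochs (zero noise, zero jitter)."""
    cfg = ed.SimulationConfig(
        n_blocks=1, trials_per_block=80, p_deviant=0.4, sfreq=64,
        components=(ed.ComponentSpec("dev", 0.200, 0.080, 5.0),),
        noise_white_sd=0.0, noise_pink_scale=0.0,
        trial_amplitude_jitter_sd=0.0, seed=103)
    return ed.undersample_balance(ed.generate_epochs(cfg), 0)


def balanced_null(n_trials: int, seed: int, sfreq: float = 32.0) -> ed.EpochSet:
    """Exactly balanced null epochs (no component signal)."""
    cfg = ed.SimulationConfig(
        n_blocks=1, trials_per_block=int(n_trials * 1.6), p_deviant=0.4,
        sfreq=sfreq, gain=ed.GainProfile.constant(1, 0.0), seed=seed)
    e = ed.generate_epochs(cfg)
    y = e.y()
    half = n_trials // 2
    idx = np.sort(np.concatenate([np.flatnonzero(y == 0)[:half],
                                  np.flatnonzero(y == 1)[:half]]))
    return e.select_trials(idx)
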