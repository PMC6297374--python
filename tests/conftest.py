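"""Shared fixtures: small synthetic datasets built at test time."""

import numpy as np
import pytest

import synstab as ss


@pytest.fixture(scope="session")
def gait_matrix():
    """Preprocessed-style 12 x 3000 matrix from the 5-synergy generator.

    Built from the envelope-domain model (W_true @ C_true + 5% noise) on
    the 30 steady-state cycles, then peak- and variance-normalized as the
    preprocessing chain would.
    """
    cfg = ss.SynthConfig(seed=11)
    W = ss.make_weightings(seed=11)
    C, _ = ss.make_activations(cfg)
    M, truth = ss.synthesize_emg(W, C, cfg.additive_noise_sd, seed=11)
    em = ss.normalize_emg_matrix(M[:, 1000:4000])
    return em.values, truth


@pytest.fixture(scope="session")
def raw_recording():
    """Raw-mode synthetic recording (1 kHz, 50 cycles, 12 channels)."""
    return ss.synthesize_raw_recording(ss.SynthConfig(seed=21))


@pytest.fixture(scope="session")
def activation_series():
    """One noisy activation series on the 30-cycle analysis window."""
    C, _ = ss.observed_activations(ss.SynthConfig(seed=31))
    return C[1, 1000:4000]
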