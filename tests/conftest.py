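import numpy as np
import pytest

from smfretkit import CorrectionSet, TraceSimConfig, simulate_fret_trace


@pytest.fixture
def paper_corrections() -> CorrectionSet:
    """Leakage fractions of the emulated instrument, gamma left at 1."""
    return CorrectionSet(alpha=0.165, beta=0.017, gamma=1.0)


@pytest.fixture
def noiseless_config() -> TraceSimConfig:
    """Single-state, noise-free, non-bleaching trace config."""
    return TraceSimConfig(
        state_efficiencies=[0.83],
        transition_rates=[[0.0]],
        noise_sd=0.0,
        alpha=0.165,
        beta=0.017,
        gamma=1.66,
        donor_bleach_rate=0.0,
        acceptor_bleach_rate=0.0,
        n_frames=100,
    )


def make_gamma_cohort(n_traces: int, gamma: float = 1.66, seed: int = 1, **overrides):
    """Traces with mid-trace acceptor bleaching for gamma-estimation tests."""
    cfg = TraceSimConfig(
        state_efficiencies=[overrides.pop("efficiency", 0.83)],
        transition_rates=[[0.0]],
        gamma=gamma,
        acceptor_bleach_rate=0.02,
        donor_bleach_rate=0.002,
        **overrides,
    )
    ss = np.random.SeedSequence(seed)
    return [
        simulate_fret_trace(cfg, s, molecule_id=f"mol{i:04d}")
        for i, s in enumerate(ss.spawn(n_traces))
    ]
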