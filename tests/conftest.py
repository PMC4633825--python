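import numpy as np
import pytest

from thetaloco.io import LfpTrace

LFP_RATE = 1250.0


def sine_trace(freq_hz: float, duration_s: float = 20.0, amp: float = 1.0,
               rate_hz: float = LFP_RATE, phase0: float = 0.0) -> LfpTrace:
    t = np.arange(int(duration_s * rate_hz)) / rate_hz
    return LfpTrace(amp * np.cos(2 * np.pi * freq_hz * t + phase0), rate_hz)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def session_dir(tmp_path_factory):
    """A small simulated session on disk, shared by pipeline tests."""
    from thetaloco.pipeline import run_simulation
    from thetaloco.synth import GeneratorConfig

    out = tmp_path_factory.mktemp("session")
    cfg = GeneratorConfig(seed=42, duration_s=180.0, segment_s=30.0,
                          entrain_gain=0.9)
    run_simulation(cfg, out)
    return out
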