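import pytest

from mfudsa import AcquisitionSpec, PulseSpec, constant_waveform, simulate_gate


@pytest.fixture(scope="session")
def pulse5mhz():
    """Reference transmit pulse: 5 MHz, 4 half cycles, rectangular, 20 MHz fs."""
    return PulseSpec(fc=5e6, half_cycles=4, envelope="rectangular", fs_fast=20e6)


@pytest.fixture(scope="session")
def acq4k():
    """Reference acquisition: PRF 4 kHz, 2048 lines, 64-sample gate, 20 dB SNR."""
    return AcquisitionSpec(prf=4000.0, n_slow=2048, n_fast=64, snr_db=20.0, seed=1)


@pytest.fixture(scope="session")
def iq_constant(pulse5mhz, acq4k):
    """Speckle dataset with constant 0.2 m/s flow toward the transducer."""
    return simulate_gate(constant_waveform(0.2), pulse5mhz, acq4k)


@pytest.fixture(scope="session")
def iq_constant_clean(pulse5mhz):
    """Noise-free speckle dataset at 0.2 m/s (for deterministic spectral checks)."""
    acq = AcquisitionSpec(prf=4000.0, n_slow=2048, n_fast=64, snr_db=None, seed=0)
    return simulate_gate(constant_waveform(0.2), pulse5mhz, acq)
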