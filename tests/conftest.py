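import numpy as np
import pytest

from excessnet.preprocess import EpochRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_epoch(rng):
    """4-channel, 10-s, 512 Hz noise epoch."""
    fs = 512.0
    samples = rng.standard_normal((4, int(10 * fs)))
    return EpochRecording(["A", "B", "C", "D"], samples, fs)


def write_minimal_edf(path, labels, samples, fs):
    """Write a minimal EDF file (test helper; synthetic content).

    Samples are physically scaled 16-bit integers, one data record per
    second. Amplitudes must fit the +-2000 uV physical range.
    """
    n_ch = len(labels)
    n = samples.shape[1]
    n_records = int(n // fs)
    spr = int(fs)  # samples per record per signal

    def pad(s, width):
        s = str(s)[:width]
        return s + " " * (width - len(s))

    header = b""
    header += pad("0", 8).encode()
    header += pad("X X X X", 80).encode()          # patient id
    header += pad("Startdate X X X X", 80).encode()  # recording id
    header += pad("01.01.20", 8).encode()
    header += pad("00.00.00", 8).encode()
    header += pad(256 * (1 + n_ch), 8).encode()
    header += pad("", 44).encode()
    header += pad(n_records, 8).encode()
    header += pad("1", 8).encode()                  # record duration (s)
    header += pad(n_ch, 4).encode()

    def field(values, width):
        return b"".join(pad(v, width).encode() for v in values)

    phys_min, phys_max = -2000.0, 2000.0
    dig_min, dig_max = -32768, 32767
    header += field(labels, 16)
    header += field(["" for _ in labels], 80)       # transducer
    header += field(["uV" for _ in labels], 8)
    header += field([phys_min for _ in labels], 8)
    header += field([phys_max for _ in labels], 8)
    header += field([dig_min for _ in labels], 8)
    header += field([dig_max for _ in labels], 8)
    header += field(["" for _ in labels], 80)       # prefiltering
    header += field([spr for _ in labels], 8)
    header += field(["" for _ in labels], 32)       # reserved

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.clip(np.rint((samples - phys_min) / gain) + dig_min, dig_min, dig_max)
    digital = digital.astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for ch in range(n_ch):
                fh.write(digital[ch, rec * spr:(rec + 1) * spr].tobytes())
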