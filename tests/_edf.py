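"""Minimal EDF (16-bit) writer for generating test fixtures at run time.

Implements just enough of the European Data Format: one data record per
file, physical scaling chosen symmetric around zero.  Only used to produce
inputs for the EDF reading path.
"""

from __future__ import annotations

import numpy as np


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, sfreq: float, ch_names=None) -> None:
    """Write ``(n_channels, n_times)`` microvolt data as a single-record EDF."""
    data = np.asarray(data, dtype=float)
    n_ch, n_t = data.shape
    if ch_names is None:
        ch_names = [f"ch{i:03d}" for i in range(n_ch)]
    record_dur = n_t / sfreq
    phys_max = max(1.0, float(np.abs(data).max()) * 1.01)
    dig_max = 32767
    scaled = np.round(data / phys_max * dig_max).astype("<i2")

    header = b""
    header += _field("0", 8)
    header += _field("synthetic", 80)
    header += _field("test recording", 80)
    header += _field("01.01.20", 8)
    header += _field("00.00.00", 8)
    header += _field(str(256 * (1 + n_ch)), 8)
    header += _field("", 44)
    header += _field("1", 8)                        # one data record
    header += _field(f"{record_dur:g}", 8)
    header += _field(str(n_ch), 4)

    per_sig = [
        (ch_names, 16),
        (["" for _ in range(n_ch)], 80),            # transducer
        (["uV"] * n_ch, 8),
        ([f"{-phys_max:.4g}"] * n_ch, 8),
        ([f"{phys_max:.4g}"] * n_ch, 8),
        ([str(-dig_max - 1)] * n_ch, 8),
        ([str(dig_max)] * n_ch, 8),
        (["" for _ in range(n_ch)], 80),            # prefilter
        ([str(n_t)] * n_ch, 8),
        (["" for _ in range(n_ch)], 32),
    ]
    for values, width in per_sig:
        for v in values:
            header += _field(v, width)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(scaled.tobytes())
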