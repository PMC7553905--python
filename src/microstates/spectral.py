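"""Morlet-wavelet time-frequency analysis and per-microstate band power.

The transform is the complex Morlet convolution from :mod:`mne`
(``tfr_array_morlet``), evaluated on a 0.5-Hz grid from 1 to 40 Hz by
default.  The mother wavelet is parameterized by its time-domain FWHM at
1 Hz (default 3 s) and scaled as 1/f, which corresponds to a constant
number of cycles ``n_cycles = 2 * pi * fwhm / (2 * sqrt(2 ln 2))``
(about 8 cycles for the 3-s default).

Band power per microstate averages the squared magnitude over (i) the time
points carrying that label, (ii) the frequency bins of the band, and
(iii) all channels.  Samples within one wavelet half-width of an epoch edge
are flagged and excluded rather than mirrored, so edge transients cannot
bias the per-label averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backfit import LabelSequence
from .core import EEGRecording

__all__ = ["SpectralConfig", "TFPower", "morlet_tf", "band_power_by_microstate"]

DEFAULT_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.5, 8.0),
    "alpha": (8.5, 12.0),
    "beta": (12.5, 25.0),
    "gamma": (25.5, 40.0),
}


@dataclass
class SpectralConfig:
    """Frequency grid, wavelet width and band definitions."""

    f_min: float = 1.0
    f_max: float = 40.0
    f_step: float = 0.5
    fwhm_at_1hz: float = 3.0
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        if self.f_step <= 0:
            raise ValueError("f_step must be positive")
        spans = sorted(self.bands.values())
        for (lo1, hi1), (lo2, _) in zip(spans, spans[1:]):
            if lo2 < hi1:
                raise ValueError("bands must not overlap")
        for lo, hi in spans:
            if lo < self.f_min or hi > self.f_max:
                raise ValueError("band outside the frequency grid")

    @property
    def freqs(self) -> np.ndarray:
        n = int(round((self.f_max - self.f_min) / self.f_step)) + 1
        return self.f_min + self.f_step * np.arange(n)

    @property
    def n_cycles(self) -> float:
        # constant across frequencies because the FWHM scales as 1/f
        return float(2 * np.pi * self.fwhm_at_1hz / (2 * np.sqrt(2 * np.log(2))))

    def band_bins(self, band: str) -> np.ndarray:
        lo, hi = self.bands[band]
        f = self.freqs
        return np.flatnonzero((f >= lo) & (f <= hi))


@dataclass
class TFPower:
    """Nonnegative power (uV^2): ``(n_channels, n_freqs, n_times)``.

    ``edge`` is an ``(n_freqs, n_times)`` boolean mask of samples within one
    wavelet half-width of an epoch boundary.
    """

    power: np.ndarray
    freqs: np.ndarray
    edge: np.ndarray
    epochs: np.ndarray
    sfreq: float


def morlet_tf(recording: EEGRecording, config: SpectralConfig | None = None) -> TFPower:
    """Complex Morlet power per channel, frequency and time point."""
    from mne.time_frequency import tfr_array_morlet

    config = config or SpectralConfig()
    freqs = config.freqs
    if freqs[-1] >= recording.sfreq / 2:
        raise ValueError("max frequency must stay below Nyquist")
    sigma_t = config.n_cycles / (2 * np.pi * freqs)  # seconds, per frequency
    half_width = np.ceil(2.5 * sigma_t * recording.sfreq).astype(int)
    n_t = recording.n_times
    power = np.empty((recording.n_channels, len(freqs), n_t))
    edge = np.zeros((len(freqs), n_t), dtype=bool)
    for a, b in recording.epochs:
        seg = recording.data[np.newaxis, :, a:b]
        # full wavelet support is 10 sigma_t at the lowest frequency
        wav_len = int(np.ceil(10 * sigma_t[0] * recording.sfreq))
        if b - a < wav_len:
            raise ValueError(
                f"epoch of {b - a} samples shorter than the lowest-frequency "
                f"wavelet support ({wav_len} samples)"
            )
        out = tfr_array_morlet(
            seg, recording.sfreq, freqs, n_cycles=config.n_cycles,
            output="power", zero_mean=True, verbose="error",
        )
        power[:, :, a:b] = out[0]
        for i, hw in enumerate(half_width):
            hw = min(hw, (b - a) // 2)
            edge[i, a: a + hw] = True
            edge[i, b - hw: b] = True
    return TFPower(power, freqs, edge, recording.epochs.copy(), recording.sfreq)


def band_power_by_microstate(
    tf: TFPower, seq: LabelSequence, config: SpectralConfig | None = None
) -> pd.DataFrame:
    """Mean band power per (map, band), averaged over channels.

    For each map and band: the mean of ``power[channel, f, t]`` over the
    band's frequency bins, all channels, and the time points labelled with
    that map, excluding per-frequency edge-flagged samples.  Maps with zero
    presence get NaN.
    """
    config = config or SpectralConfig()
    if len(seq.labels) != tf.power.shape[2]:
        raise ValueError("labels and time-frequency power are not aligned")
    chan_mean = tf.power.mean(axis=0)  # (n_freqs, n_times)
    rows = []
    for k in range(1, seq.n_maps + 1):
        sel = seq.labels == k
        row: dict[str, float | int] = {"map": k}
        for band in config.bands:
            bins = config.band_bins(band)
            vals = []
            for i in bins:
                use = sel & ~tf.edge[i]
                if use.any():
                    vals.append(chan_mean[i, use].mean())
            row[band] = float(np.mean(vals)) if vals else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("map")
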