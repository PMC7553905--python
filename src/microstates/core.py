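"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`EEGRecording`: a channels x time matrix in
microvolts together with its sampling rate, channel identities and unit-sphere
sensor positions, and the boundaries of the (possibly concatenated) epochs it
is made of.  All sample coordinates are 0-based, half-open ``[start, stop)``
intervals; temporal operations never let a segment span an epoch boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["EEGRecording", "EventList"]


@dataclass
class EEGRecording:
    """Multichannel EEG data with sampling and montage metadata.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_times)``, in microvolts.
    sfreq:
        Sampling frequency in Hz.
    ch_names:
        One identifier per channel (order matches rows of ``data``).
    ch_pos:
        ``(n_channels, 3)`` sensor positions on the unit sphere, or ``None``
        when no montage is available (spherical-spline interpolation then
        refuses to run).
    epochs:
        ``(n_epochs, 2)`` integer array of half-open sample intervals that
        partition the time axis of ``data``.  A freshly simulated or loaded
        continuous recording is one epoch covering everything.
    condition:
        Free-form condition tag (e.g. ``"DE"``, ``"NE"``, ``"SL"``, ``"RW"``).
    provenance:
        Ordered log of the processing steps applied so far.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str] | None = None
    ch_pos: np.ndarray | None = None
    epochs: np.ndarray | None = None
    condition: str = ""
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a (n_channels, n_times) matrix")
        n_ch, n_t = self.data.shape
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.ch_names is None:
            self.ch_names = [f"ch{i:03d}" for i in range(n_ch)]
        if len(self.ch_names) != n_ch:
            raise ValueError(
                f"channel-count mismatch: {len(self.ch_names)} names for "
                f"{n_ch} data rows"
            )
        if self.ch_pos is not None:
            self.ch_pos = np.asarray(self.ch_pos, dtype=float)
            if self.ch_pos.shape != (n_ch, 3):
                raise ValueError(
                    f"channel-count mismatch: positions {self.ch_pos.shape} "
                    f"do not fit {n_ch} channels"
                )
        if self.epochs is None:
            self.epochs = np.array([[0, n_t]], dtype=int)
        self.epochs = np.asarray(self.epochs, dtype=int)
        self._check_epochs(n_t)

    def _check_epochs(self, n_t: int) -> None:
        ep = self.epochs
        if ep.ndim != 2 or ep.shape[1] != 2:
            raise ValueError("epochs must be an (n_epochs, 2) array")
        if np.any(ep[:, 0] >= ep[:, 1]):
            raise ValueError("empty or inverted epoch interval")
        if np.any(ep[:, 0] < 0) or np.any(ep[:, 1] > n_t):
            raise ValueError("epoch interval outside the recording")
        if np.any(ep[1:, 0] < ep[:-1, 1]):
            raise ValueError("epochs overlap or are out of order")

    # -- convenience -------------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Total duration of the data in seconds."""
        return self.n_times / self.sfreq

    def copy_with(self, **changes) -> "EEGRecording":
        """Return a copy with ``changes`` applied (data is not shared)."""
        new = replace(self, **changes)
        if "data" not in changes:
            new.data = self.data.copy()
        new.provenance = list(new.provenance)
        return new

    def log(self, step: str) -> None:
        self.provenance.append(step)


@dataclass
class EventList:
    """Event markers: ``(sample_index, condition_tag)`` pairs.

    Used to anchor epoch extraction (e.g. the 30-s window ending at each
    awakening).  ``tags`` not listed in ``condition_set`` (when given) are
    rejected.
    """

    samples: np.ndarray
    tags: list[str]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=int)
        if self.samples.ndim != 1 or len(self.samples) != len(self.tags):
            raise ValueError("samples and tags must have equal length")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[int, str]]) -> "EventList":
        if not pairs:
            return cls(np.empty(0, dtype=int), [])
        samples, tags = zip(*pairs)
        return cls(np.asarray(samples, dtype=int), list(tags))

    def validate(self, n_times: int, condition_set: Sequence[str] | None = None) -> None:
        if np.any(self.samples < 0) or np.any(self.samples > n_times):
            raise ValueError("event sample index outside recording")
        if condition_set is not None:
            bad = sorted(set(self.tags) - set(condition_set))
            if bad:
                raise ValueError(f"unknown condition tags: {bad}")
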