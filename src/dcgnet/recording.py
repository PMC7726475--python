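"""Multichannel recording container.

A recording is a channels-by-samples matrix of real-valued signal (EEG-like,
arbitrary microvolt-scale units) together with its sampling rate, channel
labels and an optional condition tag (e.g. ``"baseline"`` / ``"post_stim"``).
Every stage of the pipeline (band filtering, connectivity estimation) consumes
and produces this container, so validation lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class RecordingError(ValueError):
    """Raised when a recording violates its structural invariants."""


@dataclass
class MultichannelRecording:
    """Channels x samples signal matrix with metadata.

    Parameters
    ----------
    data:
        Array of shape ``(m, t)``: ``m`` channels, ``t`` samples.
    fs:
        Sampling rate in Hz, strictly positive.
    labels:
        ``m`` unique channel names.
    condition:
        Free-form tag identifying the recording period.
    """

    data: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise RecordingError("data must be a 2-D channels x samples array")
        m, t = self.data.shape
        if m < 2:
            raise RecordingError(f"need at least 2 channels, got {m}")
        if t < m + 2:
            raise RecordingError(f"need at least m+2={m + 2} samples, got {t}")
        if not self.fs > 0:
            raise RecordingError(f"sampling rate must be positive, got {self.fs}")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(m)]
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != m:
            raise RecordingError(
                f"{len(self.labels)} labels for {m} channels"
            )
        if len(set(self.labels)) != m:
            dup = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise RecordingError(f"duplicate channel labels: {dup}")
        bad = np.argwhere(~np.isfinite(self.data))
        if bad.size:
            i, j = bad[0]
            raise RecordingError(
                f"non-finite value at channel {self.labels[i]!r} (row {i}), sample {j}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def t(self) -> int:
        """Number of samples."""
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.t / self.fs

    def with_data(self, data: np.ndarray) -> "MultichannelRecording":
        """Copy of the recording with the signal matrix replaced (same shape)."""
        return replace(self, data=np.asarray(data, dtype=float))

    def select_channels(self, labels: list[str]) -> "MultichannelRecording":
        """Sub-recording restricted to ``labels`` in the given order."""
        idx = [self.labels.index(lbl) for lbl in labels]
        return MultichannelRecording(
            self.data[idx], self.fs, list(labels), self.condition
        )
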