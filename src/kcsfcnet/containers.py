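"""In-memory containers for epoched EEG trials.

The central object is :class:`EEGTrialSet`, a validated bundle of a trial
tensor ``(R, Nc, Nt)`` with binary class labels, the sampling rate, channel
names and (optionally) 2-D scalp positions.  All pipeline stages consume and
produce this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["EEGTrialSet"]


@dataclass
class EEGTrialSet:
    """Epoched multichannel EEG trials with binary class labels.

    Parameters
    ----------
    data : ndarray of shape (R, Nc, Nt)
        Trial tensor: R trials, Nc channels, Nt samples per channel, in
        microvolt-scale arbitrary units.
    labels : ndarray of shape (R,)
        Class labels, 0 (e.g. left hand) or 1 (right hand).  Both classes
        must be present.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One name per channel.
    channel_positions : ndarray of shape (Nc, 2), optional
        2-D scalp coordinates for topographic export.
    cue_onset : float
        Time of the task cue within each trial, in seconds from trial start.
        Epoch clipping windows are expressed relative to this instant.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    channel_positions: np.ndarray | None = None
    cue_onset: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be 3-D (trials, channels, samples), got {self.data.ndim}-D"
            )
        if not np.all(np.isfinite(self.data)):
            bad = np.unique(np.argwhere(~np.isfinite(self.data))[:, 0])
            raise ValueError(f"non-finite values in data (trial indices {bad.tolist()})")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"labels shape {self.labels.shape} does not match {self.data.shape[0]} trials"
            )
        uniq = set(np.unique(self.labels).tolist())
        if not uniq <= {0, 1}:
            raise ValueError(f"labels must be 0/1, got values {sorted(uniq)}")
        if uniq != {0, 1}:
            raise ValueError("both classes (0 and 1) must be present")
        self.labels = self.labels.astype(np.int64)
        if not self.channel_names:
            self.channel_names = [f"Ch{c + 1:02d}" for c in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[1]} channels"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    # -- convenience -------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_times / self.fs

    def with_data(self, data: np.ndarray, fs: float | None = None,
                  cue_onset: float | None = None) -> "EEGTrialSet":
        """Return a copy with ``data`` (and optionally fs / cue_onset) replaced."""
        return replace(
            self,
            data=data,
            fs=self.fs if fs is None else fs,
            cue_onset=self.cue_onset if cue_onset is None else cue_onset,
        )
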