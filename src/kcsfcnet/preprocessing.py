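"""Raw-EEG conditioning: Fourier resampling, Butterworth bandpass, epoch clip.

The pipeline order is fixed — resample to the target rate, bandpass with a
fifth-order Butterworth (default 4-40 Hz, spanning theta through high beta),
then clip to the motor-imagery segment relative to the cue onset.  Filtering
is zero-phase (forward-backward) by default so the MI segment suffers no
group delay; a causal mode is available through :class:`PreprocessConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import EEGTrialSet

__all__ = [
    "PreprocessConfig",
    "resample_fourier",
    "bandpass_butterworth",
    "clip_epoch",
    "flag_bad_trials",
    "preprocess",
    "EEGPreprocessor",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning parameters.

    fs_target : target sampling rate in Hz (downsampling only).
    band : bandpass edges (low, high) in Hz; must sit below fs_target/2.
    filter_order : Butterworth order of a single pass (the default
        zero-phase application doubles the effective order).
    window : epoch (t0, t1) in seconds relative to cue onset, half-open
        ``[t0, t1)`` in samples.
    zero_phase : forward-backward filtering if True, causal single pass if False.
    amplitude_threshold : optional bad-trial voltage bound; ``None`` disables
        the check (the default — synthetic data has no flagged trials).
    """

    fs_target: float = 128.0
    band: tuple[float, float] = (4.0, 40.0)
    filter_order: int = 5
    window: tuple[float, float] = (0.5, 2.5)
    zero_phase: bool = True
    amplitude_threshold: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.band
        nyq = self.fs_target / 2.0
        if not 0.0 < lo < hi:
            raise ValueError(f"band edges must satisfy 0 < low < high, got {self.band}")
        if hi >= nyq:
            raise ValueError(
                f"band high edge {hi} Hz is at or above Nyquist ({nyq} Hz) "
                f"for fs_target={self.fs_target}"
            )
        if self.window[0] >= self.window[1]:
            raise ValueError(f"window must satisfy t0 < t1, got {self.window}")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


def resample_fourier(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Downsample along the last axis by Fourier-domain truncation.

    Output length is ``round(n * fs_out / fs_in)``.  DC is preserved exactly;
    upsampling is rejected (out of scope).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("input must have at least 2 samples")
    if fs_out >= fs_in:
        raise ValueError(f"fs_out ({fs_out}) must be below fs_in ({fs_in}): downsampling only")
    n_out = int(round(x.shape[-1] * fs_out / fs_in))
    return signal.resample(x, n_out, axis=-1)


def _design_sos(cfg: PreprocessConfig, fs: float) -> np.ndarray:
    lo, hi = cfg.band
    nyq = fs / 2.0
    for edge, name in ((lo, "low"), (hi, "high")):
        if edge >= nyq:
            raise ValueError(
                f"{name} band edge {edge} Hz is at or above Nyquist ({nyq} Hz) at fs={fs}"
            )
    return signal.butter(cfg.filter_order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass_butterworth(trials: EEGTrialSet, cfg: PreprocessConfig) -> EEGTrialSet:
    """Bandpass every channel of every trial with the configured Butterworth.

    Applied independently per channel and trial, so there is no cross-channel
    leakage by construction.
    """
    sos = _design_sos(cfg, trials.fs)
    min_len = 3 * cfg.filter_order + 1
    if trials.n_times <= min_len:
        raise ValueError(
            f"trial length {trials.n_times} too short for order-{cfg.filter_order} "
            f"filter warm-up (need > {min_len})"
        )
    if cfg.zero_phase:
        out = signal.sosfiltfilt(sos, trials.data, axis=-1)
    else:
        out = signal.sosfilt(sos, trials.data, axis=-1)
    return trials.with_data(np.ascontiguousarray(out))


def clip_epoch(trials: EEGTrialSet, cfg: PreprocessConfig) -> EEGTrialSet:
    """Clip trials to the window ``[cue_onset + t0, cue_onset + t1)``.

    Sample indexing is half-open and 0-based, so the output has exactly
    ``round((t1 - t0) * fs)`` samples; the output's cue reference becomes
    its own sample 0 (cue_onset is re-referenced to ``-t0``).
    """
    t0, t1 = cfg.window
    i0 = int(round((trials.cue_onset + t0) * trials.fs))
    i1 = int(round((trials.cue_onset + t1) * trials.fs))
    if i0 < 0 or i1 > trials.n_times:
        raise ValueError(
            f"clip window [{trials.cue_onset + t0}, {trials.cue_onset + t1}) s lies "
            f"outside the recorded trial of {trials.duration} s"
        )
    return trials.with_data(trials.data[:, :, i0:i1].copy(), cue_onset=-t0)


def flag_bad_trials(trials: EEGTrialSet, threshold: float) -> np.ndarray:
    """Boolean mask of trials whose absolute amplitude exceeds ``threshold``."""
    return np.abs(trials.data).max(axis=(1, 2)) > threshold


def preprocess(trials: EEGTrialSet, cfg: PreprocessConfig | None = None) -> EEGTrialSet:
    """Full conditioning chain: resample -> bandpass -> clip (fixed order)."""
    cfg = cfg or PreprocessConfig()
    if trials.fs > cfg.fs_target:
        data = resample_fourier(trials.data, trials.fs, cfg.fs_target)
        trials = trials.with_data(data, fs=cfg.fs_target)
    trials = bandpass_butterworth(trials, cfg)
    trials = clip_epoch(trials, cfg)
    if cfg.amplitude_threshold is not None:
        keep = ~flag_bad_trials(trials, cfg.amplitude_threshold)
        if keep.sum() < trials.n_trials:
            trials = EEGTrialSet(
                data=trials.data[keep], labels=trials.labels[keep], fs=trials.fs,
                channel_names=trials.channel_names,
                channel_positions=trials.channel_positions, cue_onset=trials.cue_onset,
            )
    return trials


class EEGPreprocessor(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping the conditioning chain.

    Operates on raw trial tensors ``(R, Nc, Nt)``; ``fs_in`` and ``cue_onset``
    describe the incoming recording.  ``fit`` only validates parameters.
    """

    def __init__(self, fs_in: float = 512.0, fs_target: float = 128.0,
                 band: tuple[float, float] = (4.0, 40.0), filter_order: int = 5,
                 window: tuple[float, float] = (0.5, 2.5), cue_onset: float = 0.0,
                 zero_phase: bool = True):
        self.fs_in = fs_in
        self.fs_target = fs_target
        self.band = band
        self.filter_order = filter_order
        self.window = window
        self.cue_onset = cue_onset
        self.zero_phase = zero_phase

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            fs_target=self.fs_target, band=tuple(self.band),
            filter_order=self.filter_order, window=tuple(self.window),
            zero_phase=self.zero_phase,
        )

    def fit(self, X, y=None):
        self._config()  # parameter validation
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(f"expected (trials, channels, samples), got shape {X.shape}")
        cfg = self._config()
        fs = self.fs_in
        if fs > cfg.fs_target:
            X = resample_fourier(X, fs, cfg.fs_target)
            fs = cfg.fs_target
        sos = _design_sos(cfg, fs)
        X = signal.sosfiltfilt(sos, X, axis=-1) if cfg.zero_phase else signal.sosfilt(sos, X, axis=-1)
        i0 = int(round((self.cue_onset + cfg.window[0]) * fs))
        i1 = int(round((self.cue_onset + cfg.window[1]) * fs))
        if i0 < 0 or i1 > X.shape[-1]:
            raise ValueError("clip window lies outside the recorded trial")
        return np.ascontiguousarray(X[:, :, i0:i1])
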