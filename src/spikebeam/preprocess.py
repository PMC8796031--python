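"""Filtering, averaging, analysis-time-point selection and MEEG combination.

The pipeline convention follows clinical spike analysis: band-pass and
notch filtering of the raw trials (two-pass zero-phase Butterworth),
arithmetic averaging across trials, selection of the localization sample at
the middle of the spike's rising flank, and — for combined EEG+MEG — a
channelwise normalization by the per-sensor baseline noise standard
deviation applied identically to data and leadfields, after which the
stacked system is unit-free and can be treated like a single modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
from scipy import signal

from .forward import Leadfield
from .simulate import SpikeDataset

__all__ = [
    "EvokedData",
    "NormalizationVector",
    "bandpass_filter",
    "filter_dataset",
    "average_trials",
    "find_rising_flank_midpoint",
    "estimate_noise_std",
    "apply_normalization",
    "normalize_meeg",
]


@dataclass
class EvokedData:
    """Trial-averaged sensor data D_avg with localization metadata."""

    data: np.ndarray               # (S, T)
    srate: float
    peak_index: int
    modality: str
    channel_names: list[str] = field(default_factory=list)
    tmin: float = -0.5
    analysis_index: int | None = None
    baseline_window: tuple[int, int] | None = None   # sample range
    truth: dict | None = None

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise ValueError("data must be (S, T)")
        if not 0 <= self.peak_index < d.shape[1]:
            raise ValueError("peak_index outside the epoch")
        if self.analysis_index is not None and not (
                0 <= self.analysis_index < d.shape[1]):
            raise ValueError("analysis_index outside the epoch")
        self.data = d

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.n_times) - self.peak_index) / self.srate

    def sample_at(self, t_ms: float) -> int:
        """Sample index closest to ``t_ms`` milliseconds relative to the peak."""
        return int(round(self.peak_index + t_ms * 1e-3 * self.srate))


@dataclass(frozen=True)
class NormalizationVector:
    """Per-channel noise standard deviations (sensor units)."""

    stds: np.ndarray
    applied: bool = False

    def __post_init__(self):
        s = np.asarray(self.stds, dtype=float)
        if np.any(~np.isfinite(s)) or np.any(s <= 0):
            raise ValueError("noise standard deviations must be positive "
                             "and finite (zero-variance channel?)")
        object.__setattr__(self, "stds", s)


def bandpass_filter(data: np.ndarray, srate: float, low: float = 2.0,
                    high: float = 80.0, notch: float | None = 50.0,
                    order: int = 6) -> np.ndarray:
    """Two-pass zero-phase Butterworth band-pass with optional notch.

    Applied along the last axis. The forward-backward application doubles
    the effective order and cancels the phase response, so symmetric
    transients keep their peak latency.
    """
    if not 0 < low < high < srate / 2:
        raise ValueError("need 0 < low < high < Nyquist")
    data = np.asarray(data, float)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=srate,
                        output="sos")
    out = signal.sosfiltfilt(sos, data, axis=-1)
    if notch is not None:
        if not 0 < notch < srate / 2:
            raise ValueError("notch frequency must be below Nyquist")
        b, a = signal.iirnotch(notch, Q=30.0, fs=srate)
        out = signal.filtfilt(b, a, out, axis=-1)
    return out


def filter_dataset(dataset: SpikeDataset, low: float = 2.0,
                   high: float = 80.0, notch: float | None = 50.0,
                   order: int = 6) -> SpikeDataset:
    """Return a filtered copy of an epoched dataset."""
    filtered = bandpass_filter(dataset.trials, dataset.srate, low=low,
                               high=high, notch=notch, order=order)
    return SpikeDataset(trials=filtered, srate=dataset.srate,
                        peak_index=dataset.peak_index,
                        modality=dataset.modality,
                        channel_names=list(dataset.channel_names),
                        tmin=dataset.tmin, truth=dataset.truth)


def average_trials(dataset: SpikeDataset,
                   baseline_ms: tuple[float, float] = (-500.0, -300.0)
                   ) -> EvokedData:
    """Arithmetic mean across trials with metadata propagated.

    ``baseline_ms`` (relative to the event peak) is stored as the default
    window for noise estimation; it is clipped to the epoch.
    """
    if dataset.n_trials < 1:
        raise ValueError("dataset has no trials")
    d_avg = dataset.trials.mean(axis=0)
    lo = max(0, int(round(dataset.peak_index + baseline_ms[0] * 1e-3
                          * dataset.srate)))
    hi = max(lo + 1, int(round(dataset.peak_index + baseline_ms[1] * 1e-3
                               * dataset.srate)))
    return EvokedData(data=d_avg, srate=dataset.srate,
                      peak_index=dataset.peak_index,
                      modality=dataset.modality,
                      channel_names=list(dataset.channel_names),
                      tmin=dataset.tmin,
                      baseline_window=(lo, min(hi, d_avg.shape[1])),
                      truth=dataset.truth)


def global_field_power(data: np.ndarray) -> np.ndarray:
    """Root-mean-square across channels at each sample."""
    return np.sqrt(np.mean(np.asarray(data, float) ** 2, axis=0))


def find_rising_flank_midpoint(evoked: EvokedData,
                               channel_reduction: str | int = "gfp",
                               onset_frac: float = 0.2,
                               mid_frac: float = 0.5) -> int:
    """Sample index of the middle of the rising flank before the peak.

    The reduced amplitude (global field power by default, or a named/indexed
    channel's absolute value) is scanned backwards from the peak: the onset
    is the last sample at or below ``onset_frac`` of the peak amplitude, and
    the midpoint is the first sample at or after the onset reaching
    ``mid_frac`` of the peak amplitude. The result is stored on the evoked
    as ``analysis_index`` and returned.
    """
    if channel_reduction == "gfp":
        amp = global_field_power(evoked.data)
    else:
        if isinstance(channel_reduction, str):
            channel_reduction = evoked.channel_names.index(channel_reduction)
        amp = np.abs(evoked.data[channel_reduction])
    peak = evoked.peak_index
    peak_amp = amp[peak]
    if peak_amp <= 0 or np.allclose(amp[:peak + 1], amp[peak]):
        raise ValueError("no detectable rising flank (flat signal)")
    below = np.flatnonzero(amp[:peak] <= onset_frac * peak_amp)
    onset = int(below[-1]) if below.size else 0
    level = mid_frac * peak_amp
    above = np.flatnonzero(amp[onset:peak + 1] >= level)
    if above.size == 0:
        raise ValueError("no rising flank crosses the midpoint level")
    midpoint = onset + int(above[0])
    evoked.analysis_index = midpoint
    return midpoint


def estimate_noise_std(evoked: EvokedData,
                       window_ms: tuple[float, float] | None = None
                       ) -> NormalizationVector:
    """Per-channel standard deviation of the averaged data over a baseline.

    ``window_ms`` is relative to the event peak; if omitted the evoked's
    stored baseline window (default −500..−300 ms) is used.
    """
    if window_ms is None:
        if evoked.baseline_window is None:
            raise ValueError("no baseline window available")
        lo, hi = evoked.baseline_window
    else:
        lo = evoked.sample_at(window_ms[0])
        hi = evoked.sample_at(window_ms[1])
    if not 0 <= lo < hi <= evoked.n_times:
        raise ValueError("baseline window outside the epoch")
    stds = evoked.data[:, lo:hi].std(axis=1, ddof=1)
    if np.any(stds <= 0):
        bad = np.flatnonzero(stds <= 0)
        raise ValueError(f"zero-variance channel(s) in baseline: {bad.tolist()}")
    return NormalizationVector(stds=stds)


def apply_normalization(evoked: EvokedData, leadfield: Leadfield,
                        norms: NormalizationVector):
    """Divide data and leadfield rows by the per-channel noise std."""
    if evoked.n_channels != leadfield.n_sensors or \
            evoked.n_channels != norms.stds.size:
        raise ValueError("channel count mismatch between data, leadfield "
                         "and normalization vector")
    ev = _dc_replace(evoked, data=evoked.data / norms.stds[:, None])
    lf = Leadfield(gain=leadfield.gain / norms.stds[:, None],
                   modality=leadfield.modality,
                   n_sources=leadfield.n_sources, k=leadfield.k,
                   reference="none",  # row scaling breaks the average reference
                   per_source_basis=leadfield.per_source_basis,
                   channel_names=list(leadfield.channel_names))
    return ev, lf


def normalize_meeg(eeg: tuple[EvokedData, Leadfield],
                   meg: tuple[EvokedData, Leadfield],
                   norms: tuple[NormalizationVector, NormalizationVector]
                   ) -> tuple[EvokedData, Leadfield]:
    """Noise-normalize EEG and MEG and stack them into one unit-free system.

    Every channel of data *and* leadfield is divided by that channel's own
    baseline noise standard deviation, after which the combined
    S_eeg + S_meg system is used exactly like a single modality.
    """
    (eeg_ev, eeg_lf), (meg_ev, meg_lf) = eeg, meg
    if eeg_ev.n_times != meg_ev.n_times or \
            eeg_ev.peak_index != meg_ev.peak_index or \
            eeg_ev.srate != meg_ev.srate:
        raise ValueError("EEG and MEG epochs must share the time axis")
    if eeg_lf.n_sources != meg_lf.n_sources or eeg_lf.k != meg_lf.k:
        raise ValueError("EEG and MEG leadfields must share the source space")
    eeg_n, meg_n = norms
    eeg_ev2, eeg_lf2 = apply_normalization(eeg_ev, eeg_lf, eeg_n)
    meg_ev2, meg_lf2 = apply_normalization(meg_ev, meg_lf, meg_n)
    data = np.vstack([eeg_ev2.data, meg_ev2.data])
    names = list(eeg_ev.channel_names) + list(meg_ev.channel_names)
    combined_ev = EvokedData(
        data=data, srate=eeg_ev.srate, peak_index=eeg_ev.peak_index,
        modality="meeg", channel_names=names, tmin=eeg_ev.tmin,
        analysis_index=eeg_ev.analysis_index,
        baseline_window=eeg_ev.baseline_window, truth=eeg_ev.truth)
    combined_lf = Leadfield(
        gain=np.vstack([eeg_lf2.gain, meg_lf2.gain]), modality="meeg",
        n_sources=eeg_lf.n_sources, k=eeg_lf.k, reference="none",
        channel_names=names)
    return combined_ev, combined_lf
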