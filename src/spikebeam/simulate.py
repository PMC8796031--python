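"""Synthetic multi-trial spike and somatosensory-evoked datasets.

Emulates the statistical structure the localization pipeline assumes:
epoched multi-trial sensor recordings around an interictal spike peak
(epochs of ±0.5 s, default 2400 Hz), paired EEG/MEG somatosensory evoked
responses with a focal tangential source peaking 20 ms post-stimulus, and a
contiguous "resection volume" of source-grid points around the generator.

All randomness flows through a single seeded generator so any dataset is
reproducible from (configuration, seed); the ground truth used to generate
each dataset travels with it in the ``truth`` dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import Leadfield, SourceSpace

__all__ = [
    "SpikeDataset",
    "ResectionVolume",
    "make_spike_waveform",
    "simulate_spike_trials",
    "simulate_sep_sef",
    "make_resection",
    "PATIENT1_N_SPIKES",
    "PATIENT2_N_SPIKES",
    "RESECTION_RADIUS_MM",
]

# named presets for the number of averaged spikes
PATIENT1_N_SPIKES = 248
PATIENT2_N_SPIKES = 54
# radius (mm) of a ball with the ~1.4 cm^3 volume of a small resection
RESECTION_RADIUS_MM = (3 * 1400.0 / (4 * np.pi)) ** (1 / 3)


@dataclass
class SpikeDataset:
    """Epoched multi-trial sensor data with the event peak at ``peak_index``."""

    trials: np.ndarray          # (n_trials, S, T)
    srate: float                # Hz
    peak_index: int             # sample of the event peak (t = 0 for spikes)
    modality: str               # "eeg" | "meg" | "meeg"
    channel_names: list[str] = field(default_factory=list)
    tmin: float = -0.5          # epoch start relative to the peak, s
    truth: dict | None = None   # generator ground truth, if synthetic

    def __post_init__(self):
        tr = np.asarray(self.trials, dtype=float)
        if tr.ndim != 3 or tr.shape[0] < 1:
            raise ValueError("trials must be (n_trials, S, T) with n_trials >= 1")
        if not 0 <= self.peak_index < tr.shape[2]:
            raise ValueError("peak_index outside the epoch")
        self.trials = tr

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_times(self) -> int:
        return self.trials.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, 0 at the event peak."""
        return (np.arange(self.n_times) - self.peak_index) / self.srate


@dataclass(frozen=True)
class ResectionVolume:
    """Contiguous set of source-space points standing in for a resection."""

    member_indices: np.ndarray
    definition: dict

    def __post_init__(self):
        idx = np.asarray(self.member_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("resection volume must be nonempty")
        object.__setattr__(self, "member_indices", idx)

    def __contains__(self, index) -> bool:
        return bool(np.isin(int(index), self.member_indices))


def make_spike_waveform(srate: float, rise_ms: float = 20.0,
                        fall_ms: float = 30.0, sharp_amp: float = 1.0,
                        wave_amp: float = 0.4, wave_ms: float = 150.0,
                        shape: str = "linear", tmin: float = -0.5,
                        tmax: float = 0.5) -> np.ndarray:
    """Biphasic spike–wave time course with its peak (value 1) exactly at t=0.

    The sharp component rises monotonically over ``rise_ms`` (``shape`` is
    ``"linear"`` or ``"cosine"``), falls over ``fall_ms`` into a slow wave of
    opposite polarity and relative amplitude ``wave_amp`` lasting ``wave_ms``.
    Zero outside its support. Sampled on the epoch grid [tmin, tmax) with the
    peak on the exact t = 0 sample.
    """
    if rise_ms <= 0 or fall_ms <= 0 or wave_ms <= 0:
        raise ValueError("durations must be positive")
    n_pre = int(round(-tmin * srate))
    n_post = int(round(tmax * srate))
    t = (np.arange(n_pre + n_post) - n_pre) / srate * 1e3  # ms, 0 at peak
    w = np.zeros_like(t)
    rising = (t >= -rise_ms) & (t <= 0)
    if shape == "linear":
        w[rising] = (t[rising] + rise_ms) / rise_ms
    elif shape == "cosine":
        w[rising] = 0.5 * (1 - np.cos(np.pi * (t[rising] + rise_ms) / rise_ms))
    else:
        raise ValueError("shape must be 'linear' or 'cosine'")
    falling = (t > 0) & (t <= fall_ms)
    w[falling] = 1 - (1 + wave_amp) * 0.5 * (1 - np.cos(np.pi * t[falling] / fall_ms))
    slow = (t > fall_ms) & (t <= fall_ms + wave_ms)
    w[slow] = -wave_amp * 0.5 * (1 + np.cos(np.pi * (t[slow] - fall_ms) / wave_ms))
    return sharp_amp * w


def _noise_trials(rng: np.random.Generator, n_trials: int, S: int, T: int,
                  noise_model: str, leadfield: Leadfield | None,
                  ar_coeff: float = 0.95) -> np.ndarray:
    """Unit-variance noise, (n_trials, S, T)."""
    if noise_model == "iid":
        return rng.standard_normal((n_trials, S, T))
    if noise_model == "ar1":
        # AR(1) in time per channel plus an iid sensor-noise floor
        e = rng.standard_normal((n_trials, S, T))
        ar = np.empty_like(e)
        ar[..., 0] = e[..., 0] / np.sqrt(1.0 - ar_coeff**2)  # stationary start
        for tt in range(1, T):
            ar[..., tt] = ar_coeff * ar[..., tt - 1] + e[..., tt]
        ar *= np.sqrt(1.0 - ar_coeff**2)  # unit marginal variance
        noise = ar + 0.3 * rng.standard_normal((n_trials, S, T))
        return noise / np.sqrt(1 + 0.3**2)
    if noise_model == "spatially_correlated":
        if leadfield is None:
            raise ValueError("spatially correlated noise needs a leadfield")
        # random brain-noise dipoles projected through the leadfield
        n_noise = min(50, leadfield.n_sources)
        picks = rng.choice(leadfield.n_sources, size=n_noise, replace=False)
        topo = np.stack([leadfield.point(p) @ rng.standard_normal(3)
                         for p in picks], axis=1)          # (S, n_noise)
        topo /= np.linalg.norm(topo, axis=0, keepdims=True)
        brain = np.einsum("sk,nkt->nst", topo,
                          rng.standard_normal((n_trials, n_noise, T)))
        brain /= brain.std()
        noise = brain + 0.3 * rng.standard_normal((n_trials, S, T))
        return noise / np.sqrt(1 + 0.3**2)
    raise ValueError("noise_model must be 'iid', 'ar1' or 'spatially_correlated'")


def _shift_waveform(w: np.ndarray, shift: int) -> np.ndarray:
    """Shift with zero fill (positive = later)."""
    out = np.zeros_like(w)
    if shift >= 0:
        out[shift:] = w[:w.size - shift] if shift else w
    else:
        out[:shift] = w[-shift:]
    return out


def simulate_spike_trials(leadfield, source_index: int, orientation,
                          amplitude: float, waveform: np.ndarray,
                          n_trials: int, noise_model: str = "ar1",
                          snr: float = 5.0, seed: int = 0,
                          srate: float = 2400.0,
                          amp_jitter: float = 0.2,
                          latency_jitter_ms: float = 5.0,
                          tmin: float = -0.5):
    """Project a dipolar spike through the leadfield and add sensor noise.

    ``leadfield`` may be a single :class:`Leadfield` or a dict mapping
    modality names to leadfields; in the latter case one dataset per
    modality is returned (as a dict) with the *same* per-trial amplitude and
    latency jitters — the same physiological events seen by both sensor
    arrays — and independent sensor noise.

    The SNR convention: per-trial noise standard deviation is set so that
    (peak signal amplitude on the best channel) / (noise std on that
    channel) equals ``snr``. ``snr=np.inf`` produces noiseless trials.
    Amplitude jitter is lognormal (sigma ``amp_jitter``) and latency jitter
    uniform within ±``latency_jitter_ms``; set either to 0 to disable.
    """
    lfs = leadfield if isinstance(leadfield, dict) else {"_single": leadfield}
    orientation = np.asarray(orientation, float)
    if not np.isclose(np.linalg.norm(orientation), 1.0, atol=1e-9):
        raise ValueError("orientation must be unit-norm")
    if not snr > 0:
        raise ValueError("snr must be positive")
    first = next(iter(lfs.values()))
    if not 0 <= source_index < first.n_sources:
        raise ValueError("invalid source index")
    rng = np.random.default_rng(seed)
    T = waveform.size
    peak_index = int(round(-tmin * srate))

    amp_factors = (np.exp(rng.normal(0.0, amp_jitter, n_trials))
                   if amp_jitter > 0 else np.ones(n_trials))
    max_shift = int(round(latency_jitter_ms * 1e-3 * srate))
    shifts = (rng.integers(-max_shift, max_shift + 1, n_trials)
              if max_shift > 0 else np.zeros(n_trials, int))

    out = {}
    for name, lf in lfs.items():
        if lf.k != 3:
            raise ValueError("simulation requires a free-orientation leadfield")
        topo = lf.point(source_index) @ (orientation * amplitude)   # (S,)
        S = topo.size
        best = int(np.argmax(np.abs(topo)))
        signal_peak = np.abs(topo[best]) * np.max(np.abs(waveform))
        noise_std = 0.0 if np.isinf(snr) else signal_peak / snr
        trials = np.empty((n_trials, S, T))
        for i in range(n_trials):
            w_i = _shift_waveform(waveform, int(shifts[i])) * amp_factors[i]
            trials[i] = topo[:, None] * w_i[None, :]
        if noise_std > 0:
            child = np.random.default_rng(rng.integers(2**31))
            trials += noise_std * _noise_trials(child, n_trials, S, T,
                                                noise_model, lf)
        truth = {
            "source_index": int(source_index),
            "orientation": orientation.copy(),
            "amplitude": float(amplitude),
            "waveform": waveform.copy(),
            "topography": topo,
            "noise_std": noise_std,
            "snr": snr,
            "seed": int(seed),
            "amp_factors": amp_factors.copy(),
            "latency_shifts": shifts.copy(),
        }
        out[name] = SpikeDataset(trials=trials, srate=srate,
                                 peak_index=peak_index, modality=lf.modality,
                                 channel_names=list(lf.channel_names),
                                 tmin=tmin, truth=truth)
    return out["_single"] if "_single" in out else out


def simulate_sep_sef(eeg_leadfield: Leadfield, meg_leadfield: Leadfield,
                     p20_source: int, orientation, amplitude: float = 20.0,
                     n_trials: int = 600, snr: float = 10.0, seed: int = 0,
                     srate: float = 2400.0, noise_model: str = "ar1",
                     peak_ms: float = 20.0, width_ms: float = 4.0,
                     tmin: float = -0.1, tmax: float = 0.3):
    """Paired somatosensory evoked EEG (SEP) and MEG (SEF) datasets.

    A single focal source — by convention a mainly tangential generator —
    produces a Gaussian-envelope component peaking exactly ``peak_ms`` ms
    after the stimulus, simultaneously in both modalities. The EEG leadfield
    passed in must have been computed at the "true" skull conductivity whose
    recovery the calibration procedure is tested on. Stimulus-locked
    responses carry no latency or amplitude jitter.
    """
    n_pre = int(round(-tmin * srate))
    n_post = int(round(tmax * srate))
    t_ms = (np.arange(n_pre + n_post) - n_pre) / srate * 1e3
    waveform = np.exp(-0.5 * ((t_ms - peak_ms) / width_ms) ** 2)
    pair = simulate_spike_trials(
        {"eeg": eeg_leadfield, "meg": meg_leadfield}, p20_source, orientation,
        amplitude, waveform, n_trials, noise_model=noise_model, snr=snr,
        seed=seed, srate=srate, amp_jitter=0.0, latency_jitter_ms=0.0,
        tmin=tmin)
    peak_index = n_pre + int(round(peak_ms * 1e-3 * srate))
    for ds in pair.values():
        ds.peak_index = peak_index  # component peak, not the stimulus
        ds.truth["peak_ms"] = peak_ms
    return pair["eeg"], pair["meg"]


def make_resection(sources: SourceSpace, center_index: int,
                   radius: float = RESECTION_RADIUS_MM) -> ResectionVolume:
    """All source-grid points within ``radius`` mm of the center point."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = sources.points[center_index]
    d = np.linalg.norm(sources.points - center, axis=1)
    members = np.flatnonzero(d <= radius + 1e-12)
    if members.size == 0:
        raise ValueError("resection contains no grid points; increase radius")
    return ResectionVolume(
        member_indices=members,
        definition={"center_index": int(center_index),
                    "radius_mm": float(radius)})
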