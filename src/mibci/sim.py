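"""Synthetic motor-imagery EEG with a cue/rest trial protocol and ERD.

The generator emulates a 20-channel, Cz-referenced recording sampled at
1000 Hz, organised as sessions of randomly ordered cue trials (three tasks:
REST, MI-GRASP, MI-ELBOW; 3 s cue followed by a 5-7 s inter-trial rest).
Each channel is a sum of

* 1/f ("pink") background noise,
* band-limited mu (8-12 Hz) and beta (18-25 Hz) oscillators, and
* occasional low-frequency ocular transients on frontal channels.

Event-related desynchronization (ERD) is modelled as a multiplicative
attenuation of a band oscillator's amplitude on selected channels during
the cue window of a given class, with 200 ms cosine ramps at the window
edges to avoid spectral splatter. With attenuation fraction ``d`` the
oscillator amplitude during the cue is ``(1 - d)`` times its resting
amplitude, so band *power* scales by ``(1 - d)**2``.

All randomness flows from a single seed through per-stage child generators,
so identical configurations produce bit-identical output.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import CLASSES, EventList, Recording

logger = logging.getLogger(__name__)

#: Default 20-channel montage: a standard 10-20 subset covering frontal,
#: central/sensorimotor (C3, C4 and neighbours) and parietal sites,
#: referenced at the vertex (Cz).
DEFAULT_MONTAGE = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC6", "T7", "C3", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P3", "Pz", "P4",
]

DEFAULT_BANDS = {"mu": (8.0, 12.0), "beta": (18.0, 25.0)}

#: Frontal channels receiving ocular artifacts, with relative amplitudes.
_OCULAR_WEIGHTS = {"Fp1": 1.0, "Fp2": 1.0, "F7": 0.5, "F8": 0.5}

#: Duration of the cosine ERD on/off ramps (s).
_ERD_RAMP_S = 0.2

#: Silence before the first cue of a session (s).
_LEAD_IN_S = 2.0


def default_erd_depth(depth: float = 0.5) -> dict:
    """Class -> channel -> band ERD map used by the default configuration.

    MI-GRASP attenuates mu and beta over C3, MI-ELBOW over C4, and REST
    leaves the oscillators untouched. Real same-limb imagery is less
    lateralized; this spatial separation is a deliberate simplification
    that gives the three classes a controllable, localized contrast.
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    return {
        "MI-GRASP": {"C3": {"mu": depth, "beta": depth}},
        "MI-ELBOW": {"C4": {"mu": depth, "beta": depth}},
    }


@dataclass
class SimConfig:
    """Parameters of the simulated recording protocol and signal model.

    Amplitudes are root-mean-square microvolts. ``erd_depth`` maps
    class -> channel -> band -> attenuation fraction in [0, 1].
    """

    n_sessions: int = 4
    trials_per_task: int = 20
    cue_duration_s: float = 3.0
    rest_range_s: tuple[float, float] = (5.0, 7.0)
    fs: float = 1000.0
    channel_labels: list[str] = field(default_factory=lambda: list(DEFAULT_MONTAGE))
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    erd_depth: dict = field(default_factory=default_erd_depth)
    background_amp: float = 10.0
    oscillator_amp: dict[str, float] = field(
        default_factory=lambda: {"mu": 5.0, "beta": 3.0}
    )
    artifact_rate: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_sessions < 1 or self.trials_per_task < 1:
            raise ValueError("n_sessions and trials_per_task must be >= 1")
        if self.rest_range_s[0] > self.rest_range_s[1]:
            raise ValueError("rest_range_s min must be <= max")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        max_edge = max(hi for _, hi in self.bands.values())
        if self.fs <= 2 * max_edge:
            raise ValueError("fs must exceed twice the highest band edge")
        for cls, chans in self.erd_depth.items():
            if cls not in CLASSES:
                raise ValueError(f"erd_depth references unknown class {cls!r}")
            for ch, bands in chans.items():
                if ch not in self.channel_labels:
                    raise ValueError(f"erd_depth references unknown channel {ch!r}")
                for band, frac in bands.items():
                    if band not in self.bands:
                        raise ValueError(f"erd_depth references unknown band {band!r}")
                    if not 0.0 <= frac <= 1.0:
                        raise ValueError("attenuation fractions must lie in [0, 1]")


def pink_noise(n_samples: int, fs: float, seed) -> np.ndarray:
    """Zero-mean unit-variance noise with power spectral density ~ 1/f.

    The 1/f shaping applies from 1 Hz upward (the spectrum is flat below
    1 Hz, and the DC bin is zeroed), which covers the 1-100 Hz range EEG
    analysis cares about. ``seed`` may be an int or a Generator.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n_samples)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def _band_oscillator(n_samples: int, fs: float, band: tuple[float, float],
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian oscillator."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    return x / x.std()


def _erd_envelope(n_samples: int, fs: float, cue_onsets: np.ndarray,
                  cue_len: int, depth: float) -> np.ndarray:
    """Gain envelope: 1 at rest, (1 - depth) inside cues, cosine ramps."""
    env = np.ones(n_samples)
    ramp = int(round(_ERD_RAMP_S * fs))
    # half-cosine from 0 to 1 over the ramp
    up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    for onset in cue_onsets:
        stop = min(onset + cue_len, n_samples)
        gain = np.full(stop - onset, 1.0 - depth)
        k = min(ramp, len(gain))
        gain[:k] = 1.0 - depth * up[:k]
        gain[len(gain) - k:] = 1.0 - depth * up[:k][::-1]
        env[onset:stop] = gain
    return env


def _session_schedule(cfg: SimConfig, rng: np.random.Generator):
    """Randomized trial order and cue onset samples for one session."""
    labels = np.repeat(list(CLASSES), cfg.trials_per_task)
    labels = labels[rng.permutation(len(labels))]
    cue_len = int(round(cfg.cue_duration_s * cfg.fs))
    onsets = []
    t = int(round(_LEAD_IN_S * cfg.fs))
    for _ in labels:
        onsets.append(t)
        rest = rng.uniform(*cfg.rest_range_s)
        t += cue_len + int(round(rest * cfg.fs))
    n_samples = t + int(round(_LEAD_IN_S * cfg.fs))
    return np.array(onsets), labels, n_samples


def _session_signals(cfg: SimConfig, onsets: np.ndarray, labels: np.ndarray,
                     n_samples: int, rng: np.random.Generator) -> np.ndarray:
    cue_len = int(round(cfg.cue_duration_s * cfg.fs))
    n_ch = len(cfg.channel_labels)
    data = np.empty((n_ch, n_samples))
    class_onsets = {c: onsets[labels == c] for c in CLASSES}
    for ci, ch in enumerate(cfg.channel_labels):
        x = cfg.background_amp * pink_noise(n_samples, cfg.fs, rng)
        for band_name, band in cfg.bands.items():
            osc = cfg.oscillator_amp[band_name] * _band_oscillator(
                n_samples, cfg.fs, band, rng)
            env = np.ones(n_samples)
            for cls, chans in cfg.erd_depth.items():
                depth = chans.get(ch, {}).get(band_name, 0.0)
                if depth > 0:
                    env *= _erd_envelope(n_samples, cfg.fs,
                                         class_onsets[cls], cue_len, depth)
            x += env * osc
        data[ci] = x
    _add_ocular_artifacts(cfg, data, n_samples, rng)
    return data


def _add_ocular_artifacts(cfg: SimConfig, data: np.ndarray, n_samples: int,
                          rng: np.random.Generator) -> None:
    """Slow high-amplitude frontal transients (blink-like, < 4 Hz)."""
    minutes = n_samples / cfg.fs / 60.0
    n_events = rng.poisson(cfg.artifact_rate * minutes)
    width = int(round(0.4 * cfg.fs))  # ~0.4 s blink
    bump = 75.0 * np.hanning(width)
    targets = [(i, w) for i, ch in enumerate(cfg.channel_labels)
               for lbl, w in _OCULAR_WEIGHTS.items() if ch == lbl]
    if not targets:
        return
    for _ in range(n_events):
        start = rng.integers(0, max(1, n_samples - width))
        for ci, w in targets:
            data[ci, start:start + width] += w * bump


def generate_recording(config: SimConfig) -> tuple[Recording, EventList]:
    """Simulate the full multi-session experiment as one continuous recording.

    Sessions are generated independently (each from its own child seed) and
    concatenated; cue onsets are reported in the concatenated time base.
    Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    parts, onsets, labels = generate_sessions(config)
    data = np.concatenate([p.data for p in parts], axis=1)
    rec = Recording(data, config.fs, list(config.channel_labels), "Cz")
    return rec, EventList(onsets, labels)


def generate_sessions(config: SimConfig):
    """Per-session recordings plus global (concatenated) onsets and labels."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_sessions)
    parts: list[Recording] = []
    all_onsets: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    offset = 0
    for child in children:
        rng = np.random.default_rng(child)
        onsets, labels, n_samples = _session_schedule(config, rng)
        data = _session_signals(config, onsets, labels, n_samples, rng)
        parts.append(Recording(data, config.fs, list(config.channel_labels), "Cz"))
        all_onsets.append(onsets + offset)
        all_labels.append(labels)
        offset += n_samples
    return parts, np.concatenate(all_onsets), np.concatenate(all_labels)
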