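"""Synthetic multichannel surface-EMG generation.

Real forearm recordings of static hand gestures show, per bipolar channel, a
roughly stationary stochastic carrier whose envelope (and hence windowed RMS)
is gesture specific.  The generator reproduces exactly that structure: each
gesture is a K-vector of target per-channel RMS amplitudes; the carrier is
zero-mean Gaussian noise band-pass filtered to the 20-450 Hz band where
surface-EMG energy lives, amplitude-modulated by a trapezoidal envelope with
linear onset/offset ramps; additive white sensor noise is scaled to a
requested signal-to-noise ratio.

Amplitudes are in arbitrary units (real hardware reports mV; no calibration
is modelled).  The rest condition carries the sentinel label ``REST``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = [
    "REST",
    "GestureProfile",
    "EmgRecording",
    "synthesize_recording",
    "random_profiles",
    "series_schedule",
    "make_benchmark",
]

#: Label used for samples recorded between gesture trials.
REST = -1

#: Surface-EMG energy band (Hz) used for the carrier.
EMG_BAND = (20.0, 450.0)


@dataclass(frozen=True)
class GestureProfile:
    """Per-channel RMS signature of one static gesture.

    Parameters
    ----------
    gesture_id
        Integer class label; must be unique within a profile set and
        different from :data:`REST`.
    activation
        K-vector of target steady-state per-channel signal RMS amplitudes
        (arbitrary units).
    onset_ramp_ms
        Duration of the linear envelope rise and fall at trial boundaries.
    """

    gesture_id: int
    activation: np.ndarray
    onset_ramp_ms: float = 200.0

    def __post_init__(self) -> None:
        act = np.asarray(self.activation, dtype=float)
        if act.ndim != 1 or act.size == 0:
            raise ValueError("activation must be a non-empty 1-D vector")
        if np.any(act < 0):
            raise ValueError("activation values must be >= 0")
        if self.gesture_id != REST and not np.any(act > 0):
            raise ValueError(
                f"gesture {self.gesture_id}: at least one channel must be active"
            )
        if self.onset_ramp_ms < 0:
            raise ValueError("onset_ramp_ms must be >= 0")
        object.__setattr__(self, "activation", act)

    @property
    def n_channels(self) -> int:
        return int(self.activation.size)


@dataclass
class EmgRecording:
    """A K-channel sampled EMG signal with per-sample gesture labels."""

    samples: np.ndarray  # (T, K) float
    sampling_rate: float = 1000.0
    labels: np.ndarray = field(default=None)  # (T,) int, REST for rest
    channel_names: list[str] = field(default=None)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        t, k = self.samples.shape
        if t < 1 or k < 1:
            raise ValueError("recording must contain at least one sample and channel")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.labels is None:
            self.labels = np.full(t, REST, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (t,):
            raise ValueError(
                f"labels length {self.labels.size} does not match T={t}"
            )
        if self.channel_names is None:
            self.channel_names = [f"ch{i + 1}" for i in range(k)]
        if len(self.channel_names) != k:
            raise ValueError(
                f"{len(self.channel_names)} channel names for K={k} channels"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.samples.shape[1])

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sampling_rate * 1000.0


def _band_sos(sampling_rate: float) -> np.ndarray:
    lo, hi = EMG_BAND
    nyq = sampling_rate / 2.0
    hi = min(hi, 0.98 * nyq)  # keep the filter valid at low sampling rates
    return _sig.butter(4, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos")


def _carrier(rng: np.random.Generator, n: int, sos: np.ndarray) -> np.ndarray:
    """Unit-RMS band-limited Gaussian carrier of length n."""
    x = _sig.sosfiltfilt(sos, rng.standard_normal(n))
    r = float(np.sqrt(np.mean(x**2)))
    return x / r if r > 0 else x


def _envelope(n: int, ramp_samples: int) -> np.ndarray:
    ramp = int(min(ramp_samples, n // 2))
    env = np.ones(n)
    if ramp > 0:
        edge = np.linspace(0.0, 1.0, ramp, endpoint=False)
        env[:ramp] = edge
        env[n - ramp:] = edge[::-1]
    return env


def synthesize_recording(
    profiles,
    schedule,
    sampling_rate: float = 1000.0,
    snr_db: float = 20.0,
    seed: int = 0,
) -> EmgRecording:
    """Render a labelled recording from gesture profiles and a trial schedule.

    Parameters
    ----------
    profiles
        Iterable of :class:`GestureProfile` with unique ids and a common
        channel count.  A profile for :data:`REST` is optional; rest entries
        in the schedule default to zero activation.
    schedule
        Ordered ``(gesture_id, duration_ms)`` pairs.
    snr_db
        Whole-recording signal-to-noise ratio,
        ``20 * log10(signal RMS / additive-noise RMS)``.  ``inf`` disables
        sensor noise.  When the clean signal is identically zero the noise
        amplitude is referenced to 1.0 arbitrary unit instead.
    seed
        Single seed for all randomness; identical arguments give
        byte-identical output.
    """
    by_id: dict[int, GestureProfile] = {}
    for p in profiles:
        if p.gesture_id in by_id:
            raise ValueError(f"duplicate gesture_id {p.gesture_id} in profile set")
        by_id[p.gesture_id] = p
    if not by_id:
        raise ValueError("profile set is empty")
    n_channels = next(iter(by_id.values())).n_channels
    if any(p.n_channels != n_channels for p in by_id.values()):
        raise ValueError("all profiles must share the same channel count")
    if not np.isfinite(snr_db) and snr_db < 0:
        raise ValueError("snr_db must be finite or +inf")

    rng = np.random.default_rng(seed)
    sos = _band_sos(sampling_rate)

    chunks: list[np.ndarray] = []
    label_chunks: list[np.ndarray] = []
    for gesture_id, duration_ms in schedule:
        if duration_ms <= 0:
            raise ValueError(f"non-positive trial duration {duration_ms} ms")
        if gesture_id == REST and REST not in by_id:
            activation = np.zeros(n_channels)
            ramp_ms = 0.0
        elif gesture_id in by_id:
            prof = by_id[gesture_id]
            activation = prof.activation
            ramp_ms = prof.onset_ramp_ms
        else:
            raise ValueError(f"schedule references unknown gesture_id {gesture_id}")
        n = int(round(duration_ms * sampling_rate / 1000.0))
        env = _envelope(n, int(round(ramp_ms * sampling_rate / 1000.0)))
        block = np.zeros((n, n_channels))
        for k in range(n_channels):
            if activation[k] > 0:
                block[:, k] = activation[k] * env * _carrier(rng, n, sos)
        chunks.append(block)
        label_chunks.append(np.full(n, gesture_id, dtype=int))

    if not chunks:
        raise ValueError("schedule is empty")
    clean = np.vstack(chunks)
    labels = np.concatenate(label_chunks)

    signal_rms = float(np.sqrt(np.mean(clean**2)))
    if np.isfinite(snr_db):
        ref = signal_rms if signal_rms > 0 else 1.0
        noise_rms = ref / 10.0 ** (snr_db / 20.0)
        samples = clean + noise_rms * rng.standard_normal(clean.shape)
    else:
        samples = clean

    return EmgRecording(samples=samples, sampling_rate=sampling_rate, labels=labels)


def random_profiles(
    n_gestures: int,
    n_channels: int,
    seed: int | np.random.Generator = 0,
    min_separation: float = 0.4,
    onset_ramp_ms: float = 200.0,
    max_tries: int = 5000,
) -> list[GestureProfile]:
    """Draw well-separated random gesture profiles.

    Activations are uniform on [0.15, 1.0] per channel; candidates are
    rejection-sampled until every pairwise Euclidean distance between
    activation vectors is at least ``min_separation``.  The default 0.4 is
    roughly three times the standard error of a 200-sample RMS estimate
    summed over six channels, so profiles are separable by windowed RMS.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_gestures > 2**n_channels:
        warnings.warn(
            f"{n_gestures} gestures may exceed what {n_channels} channels can "
            "resolve; expect degraded classification",
            stacklevel=2,
        )
    chosen: list[np.ndarray] = []
    for _ in range(n_gestures):
        best, best_dist = None, -1.0
        for _ in range(max_tries):
            cand = rng.uniform(0.15, 1.0, size=n_channels)
            dist = min(
                (float(np.linalg.norm(cand - c)) for c in chosen), default=np.inf
            )
            if dist >= min_separation:
                best = cand
                break
            if dist > best_dist:
                best, best_dist = cand, dist
        else:
            warnings.warn(
                "could not reach the requested profile separation "
                f"({min_separation}); closest pair at {best_dist:.3f}",
                stacklevel=2,
            )
        chosen.append(best)
    return [
        GestureProfile(gesture_id=i, activation=a, onset_ramp_ms=onset_ramp_ms)
        for i, a in enumerate(chosen)
    ]


def series_schedule(
    gesture_order,
    trial_duration_ms: float,
    rest_ms: float = 500.0,
) -> list[tuple[int, float]]:
    """One trial per gesture in the given order, rest-separated."""
    schedule: list[tuple[int, float]] = []
    if rest_ms > 0:
        schedule.append((REST, rest_ms))
    for g in gesture_order:
        schedule.append((int(g), trial_duration_ms))
        if rest_ms > 0:
            schedule.append((REST, rest_ms))
    return schedule


def make_benchmark(
    n_gestures: int = 9,
    n_series: int = 2,
    trial_duration_ms: float = 2000.0,
    seed: int = 0,
    n_channels: int = 6,
    snr_db: float = 20.0,
    rest_ms: float = 500.0,
    sampling_rate: float = 1000.0,
    min_separation: float = 0.4,
):
    """Generate the gesture-series benchmark: one recording per series.

    Mirrors the acquisition protocol the decoder is designed for: each series
    performs every gesture exactly once in a seeded random order, with rest
    gaps between trials.  Series 1 is the learning set and series 2 the
    testing set.

    Returns
    -------
    tuple of EmgRecording, one per series.
    """
    if n_gestures < 2:
        raise ValueError("n_gestures must be >= 2")
    if n_series < 2:
        raise ValueError("n_series must be >= 2")
    rng = np.random.default_rng(seed)
    profiles = random_profiles(
        n_gestures, n_channels, seed=rng, min_separation=min_separation
    )
    recordings = []
    for _ in range(n_series):
        order = rng.permutation(n_gestures)
        schedule = series_schedule(order, trial_duration_ms, rest_ms)
        series_seed = int(rng.integers(2**31))
        recordings.append(
            synthesize_recording(
                profiles,
                schedule,
                sampling_rate=sampling_rate,
                snr_db=snr_db,
                seed=series_seed,
            )
        )
    return tuple(recordings)
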