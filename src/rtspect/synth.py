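"""Synthetic preprocessed-equivalent EEG epochs with planted structure.

The generator emulates the data a speeded speech-categorization experiment
would yield after preprocessing: 64-channel epochs spanning -200..800 ms,
per-trial response times drawn from a four-component mixture (fast, medium,
slow responses plus a sparse slow outlier tail), and band-limited
oscillatory power whose per-electrode amplitude depends on the trial's
response-speed category. Every downstream stage (clustering, augmentation,
topomaps, decoding, saliency, statistics) can therefore be exercised and
validated against a known planted ground truth.

Each trial is 1/f background noise plus sinusoidal bursts at the center
frequencies of the alpha/beta/gamma bands; the burst amplitude at an
electrode is the band's base amplitude times the EffectSpec factor for the
trial's category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .montage import Montage, default_montage

__all__ = [
    "CATEGORIES",
    "EffectSpec",
    "TrialSet",
    "default_effect_spec",
    "generate_trials",
    "sample_rts",
    "save_trialset",
    "load_trialset",
]

CATEGORIES = ("fast", "medium", "slow", "outlier")

#: band name -> (low Hz, high Hz, burst center Hz, base burst amplitude uV)
_DEFAULT_BANDS = {
    "alpha": (9.0, 13.0, 11.0, 4.0),
    "beta": (14.0, 30.0, 22.0, 2.5),
    "gamma": (31.0, 60.0, 45.0, 1.5),
}

#: Response-time mixture (ms): means, SDs, weights for
#: fast / medium / slow / outlier, truncated to [100, 2500] ms.
_DEFAULT_MIXTURE = {
    "means": (340.0, 640.0, 1030.0, 1800.0),
    "sds": (70.0, 65.0, 140.0, 250.0),
    "weights": (0.55, 0.27, 0.12, 0.06),
}

_RT_BOUNDS = (100.0, 2500.0)

#: Planted spatial-spectral effects: (electrode, band, category) -> factor.
#: The default planted ground truth is a single ordered left-frontal alpha
#: effect: FT7 alpha amplitude fast (3.0) > medium (1.8) > slow (1.0),
#: the monotone brain-behavior relation the decoding chain is meant to
#: recover. Category-independent anchors (posterior alpha, central
#: beta/gamma) reproduce the stable background topography of resting scalp
#: rhythms; without them each band plane of a no-effect category is nearly
#: uniform and per-image normalization amplifies noise into spurious
#: texture.
_CATEGORY_SPOTS = {
    ("FT7", "alpha", "fast"): 3.0,
    ("FT7", "alpha", "medium"): 1.8,
}
_ANCHORS = {}
for _cat in ("fast", "medium", "slow"):
    for _el in ("O1", "OZ", "O2"):
        _ANCHORS[(_el, "alpha", _cat)] = 2.2
    _ANCHORS[("POZ", "alpha", _cat)] = 1.8
    for _el in ("CZ", "FCZ"):
        _ANCHORS[(_el, "beta", _cat)] = 2.0
    _ANCHORS[("CZ", "gamma", _cat)] = 1.8
_DEFAULT_FACTORS = {**_CATEGORY_SPOTS, **_ANCHORS}


@dataclass(frozen=True)
class EffectSpec:
    """Planted ground truth: amplitude factors, band and RT-mixture defaults.

    ``factors`` maps (electrode, band, category) to a multiplicative burst
    amplitude factor; unlisted combinations default to 1. ``bands`` maps a
    band name to (lo, hi, center frequency, base amplitude in uV).
    """

    factors: dict = field(default_factory=lambda: dict(_DEFAULT_FACTORS))
    bands: dict = field(default_factory=lambda: dict(_DEFAULT_BANDS))
    rt_means: tuple = _DEFAULT_MIXTURE["means"]
    rt_sds: tuple = _DEFAULT_MIXTURE["sds"]
    rt_weights: tuple = _DEFAULT_MIXTURE["weights"]

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("EffectSpec amplitude factors must be > 0")
        if not np.isclose(sum(self.rt_weights), 1.0):
            raise ValueError("RT mixture weights must sum to 1")
        for name, (lo, hi, center, amp) in self.bands.items():
            if not (0 < lo < hi):
                raise ValueError(f"band {name}: edges must satisfy 0 < lo < hi")
            if not (lo <= center <= hi):
                raise ValueError(f"band {name}: center frequency outside band")

    def factor(self, electrode: str, band: str, category: str) -> float:
        return self.factors.get((electrode, band, category), 1.0)


def default_effect_spec() -> EffectSpec:
    return EffectSpec()


@dataclass
class TrialSet:
    """Epoched EEG trials with response-time metadata.

    data is (n_trials, n_channels, n_times) in microvolts; ``true_category``
    records the generating mixture component for synthetic data (None for
    real recordings).
    """

    data: np.ndarray
    rt_ms: np.ndarray
    subject_id: np.ndarray
    sfreq: float
    epoch_window: tuple[float, float] = (-200.0, 800.0)
    channel_names: tuple[str, ...] | None = None
    true_category: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rt_ms = np.asarray(self.rt_ms, dtype=float)
        self.subject_id = np.asarray(self.subject_id)
        n = self.data.shape[0]
        if len(self.rt_ms) != n or len(self.subject_id) != n:
            raise ValueError("rt_ms/subject_id length must match trial count")
        if np.any(self.rt_ms <= 0):
            raise ValueError("response times must be positive")
        if self.channel_names is not None and len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names must match the channel axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def times_ms(self) -> np.ndarray:
        start, _ = self.epoch_window
        return start + 1000.0 * np.arange(self.data.shape[2]) / self.sfreq


def sample_rts(n: int, effect: EffectSpec | None = None, seed: int = 0):
    """Draw n response times (ms) plus component names from the mixture."""
    effect = effect if effect is not None else default_effect_spec()
    return _sample_rts(effect, n, np.random.default_rng(seed))


def _sample_rts(effect: EffectSpec, n: int, rng: np.random.Generator):
    """Truncated mixture draw; returns (rt_ms, component_name)."""
    comp = rng.choice(len(CATEGORIES), size=n, p=np.asarray(effect.rt_weights))
    means = np.asarray(effect.rt_means)[comp]
    sds = np.asarray(effect.rt_sds)[comp]
    rt = rng.normal(means, sds)
    lo, hi = _RT_BOUNDS
    bad = (rt < lo) | (rt > hi)
    while np.any(bad):  # redraw out-of-range values from their own component
        rt[bad] = rng.normal(means[bad], sds[bad])
        bad = (rt < lo) | (rt > hi)
    return rt, np.asarray(CATEGORIES)[comp]


def _pink_noise(shape: tuple[int, ...], n_times: int, sfreq: float,
                rms: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-spectrum Gaussian noise, flat below 1 Hz, scaled to target RMS."""
    freqs = np.fft.rfftfreq(n_times, d=1.0 / sfreq)
    scale = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    scale[0] = 0.0  # zero-mean
    spec = (rng.standard_normal(shape + (len(freqs),))
            + 1j * rng.standard_normal(shape + (len(freqs),))) * scale
    x = np.fft.irfft(spec, n=n_times, axis=-1)
    cur = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x * (rms / np.maximum(cur, 1e-30))


def generate_trials(
    n_subjects: int,
    trials_per_subject: int,
    effect: EffectSpec | None = None,
    seed: int = 0,
    montage: Montage | None = None,
    sfreq: float = 500.0,
    epoch_window: tuple[float, float] = (-200.0, 800.0),
    noise_rms: float = 10.0,
    amplitude_jitter: float = 0.2,
) -> TrialSet:
    """Generate epoched trials with planted RT-dependent band structure.

    Per trial: a response time and its generating category are drawn from
    the mixture, then each channel receives 1/f background noise
    (``noise_rms`` uV RMS) plus one random-phase sinusoid per band at the
    band's center frequency, with amplitude
    ``base_amp * effect_factor * Uniform(1 - jitter, 1 + jitter)``.
    Deterministic for a given seed.
    """
    if n_subjects < 1 or trials_per_subject < 1:
        raise ValueError("n_subjects and trials_per_subject must be >= 1")
    effect = effect if effect is not None else default_effect_spec()
    montage = montage if montage is not None else default_montage()
    rng = np.random.default_rng(seed)

    n_ch = len(montage)
    n_times = int(round((epoch_window[1] - epoch_window[0]) / 1000.0 * sfreq))
    t = np.arange(n_times) / sfreq
    n_total = n_subjects * trials_per_subject

    rt, cat = _sample_rts(effect, n_total, rng)
    subj = np.repeat([f"S{i + 1:02d}" for i in range(n_subjects)], trials_per_subject)

    # Per-band factor matrix (n_trials, n_channels).
    band_names = list(effect.bands)
    factors = np.ones((len(band_names), n_total, n_ch))
    for (el, band, category), f in effect.factors.items():
        if el not in montage.channel_names:
            raise ValueError(f"EffectSpec electrode {el!r} not in montage")
        bi = band_names.index(band)
        ci = montage.index(el)
        factors[bi, cat == category, ci] = f

    data = np.empty((n_total, n_ch, n_times), dtype=np.float32)
    # Chunked by subject to bound the working set of the FFT noise draw.
    for s in range(n_subjects):
        sl = slice(s * trials_per_subject, (s + 1) * trials_per_subject)
        nt = trials_per_subject
        x = _pink_noise((nt, n_ch), n_times, sfreq, noise_rms, rng)
        for bi, name in enumerate(band_names):
            _, _, center, base_amp = effect.bands[name]
            phase = rng.uniform(0, 2 * np.pi, size=(nt, n_ch, 1))
            jit = rng.uniform(1 - amplitude_jitter, 1 + amplitude_jitter, size=(nt, n_ch, 1))
            amp = base_amp * factors[bi, sl][..., None] * jit
            x += amp * np.sin(2 * np.pi * center * t[None, None, :] + phase)
        data[sl] = x.astype(np.float32)

    return TrialSet(
        data=data,
        rt_ms=rt,
        subject_id=subj,
        sfreq=sfreq,
        epoch_window=epoch_window,
        channel_names=montage.channel_names,
        true_category=cat,
    )


def save_trialset(ts: TrialSet, path) -> None:
    """Write as a compressed array container plus a JSON sidecar."""
    path = str(path)
    np.savez_compressed(path if path.endswith(".npz") else path + ".npz", data=ts.data)
    side = {
        "rt_ms": ts.rt_ms.tolist(),
        "subject_id": [str(s) for s in ts.subject_id],
        "sfreq": ts.sfreq,
        "epoch_window": list(ts.epoch_window),
        "channel_names": list(ts.channel_names) if ts.channel_names else None,
        "true_category": ([str(c) for c in ts.true_category]
                          if ts.true_category is not None else None),
    }
    with open((path[:-4] if path.endswith(".npz") else path) + ".json", "w") as fh:
        json.dump(side, fh)


def load_trialset(path) -> TrialSet:
    path = str(path)
    stem = path[:-4] if path.endswith(".npz") else path
    data = np.load(stem + ".npz")["data"]
    with open(stem + ".json") as fh:
        side = json.load(fh)
    return TrialSet(
        data=data,
        rt_ms=np.array(side["rt_ms"]),
        subject_id=np.array(side["subject_id"]),
        sfreq=side["sfreq"],
        epoch_window=tuple(side["epoch_window"]),
        channel_names=tuple(side["channel_names"]) if side["channel_names"] else None,
        true_category=(np.array(side["true_category"])
                       if side["true_category"] is not None else None),
    )
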