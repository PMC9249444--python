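"""Synthetic annotated single-lead ECG records and labeled beat datasets.

Beats are sums of five Gaussian deflections (P, Q, R, S, T) on a linear
time grid — the standard Gaussian-wave ECG morphology model, without
limit-cycle dynamics.  Three default templates give class-distinct
shapes for the AAMI superclasses:

* N — full P-QRS-T complex;
* S — supraventricular ectopic: absent P wave, 10% narrower QRS;
* V — ventricular ectopic: absent P wave, QRS widened 2.5x, inverted T.

Records are beat trains at truncated-normal RR intervals plus additive
baseline-wander, powerline and white noise; annotations mark each R
center with the class symbol.  Every operation is deterministic under a
fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .records import Annotation, BeatSlice, RawRecord

__all__ = [
    "Wave",
    "BeatMorphology",
    "NoiseSpec",
    "InvalidMorphologyError",
    "default_morphology",
    "default_morphologies",
    "interpolate_morphology",
    "generate_beat",
    "generate_record",
    "make_dataset",
    "NOISE_PRESETS",
]

CLASS_SYMBOLS = ("N", "S", "V")

#: Default beat window geometry: 250 samples at 360 Hz, R point 100 samples in.
DEFAULT_R, DEFAULT_FS, DEFAULT_PRE = 250, 360.0, 100


class InvalidMorphologyError(ValueError):
    """Wave centers not strictly increasing (or otherwise unusable shape)."""


@dataclass(frozen=True)
class Wave:
    """One Gaussian deflection: amplitude (mV), center (s), width (s)."""

    amp: float
    center: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise InvalidMorphologyError(f"wave width must be > 0, got {self.width}")


@dataclass(frozen=True)
class BeatMorphology:
    """Five-wave Gaussian beat template for one AAMI class.

    Wave centers are absolute times on the beat's own grid [0, r/fs);
    the defaults place the R center at 100/360 s so that a 250-sample
    window at 360 Hz holds 100 samples before and 150 after the R point.
    `qrs_width_scale` multiplies the widths of the Q, R and S waves.
    """

    class_label: str
    waves: tuple[Wave, Wave, Wave, Wave, Wave]  # P, Q, R, S, T
    qrs_width_scale: float = 1.0

    def __post_init__(self):
        if self.qrs_width_scale < 0:
            raise InvalidMorphologyError("qrs_width_scale must be >= 0")
        active = [w.center for w in self.waves if w.amp != 0.0]
        if any(b <= a for a, b in zip(active, active[1:])):
            raise InvalidMorphologyError(
                f"wave centers of active deflections must be strictly "
                f"increasing (P,Q,R,S,T order), got {active}"
            )

    @property
    def r_center(self) -> float:
        return self.waves[2].center


_RC = DEFAULT_PRE / DEFAULT_FS  # R center, ~0.2778 s

_DEFAULTS = {
    "N": BeatMorphology(
        "N",
        (
            Wave(0.12, 0.100, 0.025),   # P
            Wave(-0.15, 0.245, 0.010),  # Q
            Wave(1.10, _RC, 0.012),     # R
            Wave(-0.20, 0.310, 0.010),  # S
            Wave(0.30, 0.500, 0.060),   # T
        ),
        qrs_width_scale=1.0,
    ),
    "S": BeatMorphology(
        "S",
        (
            Wave(0.0, 0.100, 0.025),
            Wave(-0.15, 0.245, 0.010),
            Wave(1.10, _RC, 0.012),
            Wave(-0.20, 0.310, 0.010),
            Wave(0.30, 0.500, 0.060),
        ),
        qrs_width_scale=0.9,
    ),
    "V": BeatMorphology(
        "V",
        (
            Wave(0.0, 0.100, 0.025),
            Wave(-0.15, 0.245, 0.010),
            Wave(1.10, _RC, 0.012),
            Wave(-0.20, 0.310, 0.010),
            Wave(-0.30, 0.500, 0.060),
        ),
        qrs_width_scale=2.5,
    ),
}


def default_morphology(class_label: str) -> BeatMorphology:
    """Default Gaussian-wave template for class N, S or V."""
    try:
        return _DEFAULTS[class_label]
    except KeyError:
        raise KeyError(f"no default morphology for class {class_label!r}") from None


def default_morphologies() -> dict[str, BeatMorphology]:
    return dict(_DEFAULTS)


def interpolate_morphology(
    a: BeatMorphology, b: BeatMorphology, t: float
) -> BeatMorphology:
    """Linear interpolation from `a` (t=0) to `b` (t=1), wave by wave."""
    waves = tuple(
        Wave(
            (1 - t) * wa.amp + t * wb.amp,
            (1 - t) * wa.center + t * wb.center,
            (1 - t) * wa.width + t * wb.width,
        )
        for wa, wb in zip(a.waves, b.waves)
    )
    return BeatMorphology(
        b.class_label,
        waves,
        qrs_width_scale=(1 - t) * a.qrs_width_scale + t * b.qrs_width_scale,
    )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: baseline wander + powerline hum + white noise.

    All amplitudes in mV.  `seed`, when set, draws the noise from its own
    generator instead of the record's.
    """

    baseline_amp: float = 0.0
    baseline_freq: float = 0.3
    powerline_amp: float = 0.0
    powerline_freq: float = 60.0
    white_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        for name in ("baseline_amp", "powerline_amp", "white_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def render(self, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
        if self.powerline_freq >= fs / 2:
            raise ValueError(
                f"powerline_freq {self.powerline_freq} Hz is at or above the "
                f"Nyquist frequency {fs / 2} Hz"
            )
        if self.seed is not None:
            rng = np.random.default_rng(self.seed)
        t = np.arange(n) / fs
        out = np.zeros(n)
        if self.baseline_amp > 0:
            out += self.baseline_amp * np.sin(
                2 * np.pi * self.baseline_freq * t + rng.uniform(0, 2 * np.pi)
            )
        if self.powerline_amp > 0:
            out += self.powerline_amp * np.sin(
                2 * np.pi * self.powerline_freq * t + rng.uniform(0, 2 * np.pi)
            )
        if self.white_sd > 0:
            out += rng.normal(0.0, self.white_sd, n)
        return out


NOISE_PRESETS: dict[str, NoiseSpec] = {
    "clean": NoiseSpec(),
    "ambulatory": NoiseSpec(
        baseline_amp=0.10, baseline_freq=0.3,
        powerline_amp=0.05, powerline_freq=60.0,
        white_sd=0.03,
    ),
}


def generate_beat(
    morph: BeatMorphology,
    fs: float = DEFAULT_FS,
    r: int = DEFAULT_R,
    jitter: float = 0.05,
    rng: np.random.Generator | None = None,
) -> BeatSlice:
    """Render one beat as the sum of five Gaussian deflections.

    `jitter` is the sd of a per-wave multiplicative log-normal
    perturbation of amplitudes and widths; with jitter = 0 the output is
    a deterministic function of (morph, fs, r).
    """
    if r < 8:
        raise ValueError(f"beat length r must be >= 8, got {r}")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    if jitter > 0 and rng is None:
        raise ValueError("jitter > 0 requires a seeded generator")

    t = np.arange(r) / fs
    out = np.zeros(r)
    for k, w in enumerate(morph.waves):
        amp, width = w.amp, w.width
        if k in (1, 2, 3):
            width *= morph.qrs_width_scale
        if jitter > 0:
            amp *= rng.lognormal(0.0, jitter)
            width *= rng.lognormal(0.0, jitter)
        if amp != 0.0:
            out += amp * np.exp(-((t - w.center) ** 2) / (2.0 * width**2))
    return BeatSlice(out, label=morph.class_label)


def _beat_support(morph: BeatMorphology) -> float:
    lo = min(w.center - 3 * w.width for w in morph.waves if w.amp != 0)
    hi = max(w.center + 3 * w.width for w in morph.waves if w.amp != 0)
    return hi - lo if hi > lo else 0.0


def generate_record(
    n_beats: int,
    class_mix: tuple[float, float, float] = (1.0, 0.0, 0.0),
    morphologies: dict[str, BeatMorphology] | None = None,
    fs: float = DEFAULT_FS,
    rr_mean: float = 0.8,
    rr_sd: float = 0.05,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    jitter: float = 0.05,
    record_id: str = "synthetic",
) -> RawRecord:
    """Generate a continuous annotated single-lead record.

    Beats are placed at truncated-normal RR intervals (lower bound 0.4 s,
    preventing overlap), each annotation marks the beat's R center, and
    class symbols are drawn i.i.d. from `class_mix` over (N, S, V).
    """
    if n_beats < 0:
        raise ValueError("n_beats must be >= 0")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (3,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix must be a probability triple summing to 1")
    morphologies = morphologies or default_morphologies()
    noise = noise or NoiseSpec()
    for m in morphologies.values():
        if rr_mean <= _beat_support(m):
            raise ValueError(
                f"rr_mean {rr_mean}s must exceed the beat support "
                f"({_beat_support(m):.3f}s for class {m.class_label})"
            )

    rng = np.random.default_rng(seed)
    beat_len = int(round(DEFAULT_R * fs / DEFAULT_FS))
    margin = int(round(0.5 * fs))

    # RR sequence, truncated at 0.4 s by rejection
    rr = np.empty(max(n_beats - 1, 0))
    for i in range(len(rr)):
        x = rng.normal(rr_mean, rr_sd)
        while x < 0.4:
            x = rng.normal(rr_mean, rr_sd)
        rr[i] = x
    r_positions = margin + np.round(np.cumsum(np.concatenate([[0.0], rr])) * fs).astype(int) \
        if n_beats > 0 else np.empty(0, dtype=int)

    labels = rng.choice(len(CLASS_SYMBOLS), size=n_beats, p=mix)
    n = (int(r_positions[-1]) + margin + beat_len) if n_beats > 0 else int(2 * margin)
    signal = np.zeros(n)
    annotations = []
    for pos, lab in zip(r_positions, labels):
        sym = CLASS_SYMBOLS[lab]
        morph = morphologies[sym]
        beat = generate_beat(morph, fs, beat_len, jitter, rng).values
        start = int(pos) - int(round(morph.r_center * fs))
        a, b = max(start, 0), min(start + beat_len, n)
        signal[a:b] += beat[a - start : b - start]
        annotations.append(Annotation(int(pos), sym))

    signal += noise.render(n, fs, rng)
    return RawRecord(signal, fs, annotations, record_id=record_id)


def make_dataset(
    n_per_class: tuple[int, int, int],
    separation: float = 1.0,
    fs: float = DEFAULT_FS,
    r: int = DEFAULT_R,
    seed: int = 0,
    jitter: float = 0.05,
    normalize: bool = True,
) -> list[BeatSlice]:
    """Labeled beat-slice dataset with controllable N/S confusability.

    `separation` = 1 uses the default well-separated templates;
    values < 1 pull the S template linearly toward N, making the two
    classes progressively harder to tell apart (identical at 0).
    """
    if any(k < 1 for k in n_per_class):
        raise ValueError("n_per_class entries must all be >= 1")
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must lie in [0, 1]")
    morphs = default_morphologies()
    morphs["S"] = interpolate_morphology(morphs["N"], morphs["S"], separation)

    rng = np.random.default_rng(seed)
    slices: list[BeatSlice] = []
    for sym, count in zip(CLASS_SYMBOLS, n_per_class):
        for i in range(count):
            beat = generate_beat(morphs[sym], fs, r, jitter, rng)
            vals = beat.values
            if normalize:
                vals = vals / np.linalg.norm(vals)
            slices.append(
                BeatSlice(vals, label=sym, source=("synthetic", i),
                          normalized=normalize)
            )
    return slices


def write_morphology(morph: BeatMorphology) -> dict:
    """JSON-serializable form of a morphology (used by the CLI run logs)."""
    return dataclasses.asdict(morph)
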