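"""Record preprocessing: wavelet denoising, beat segmentation, normalization.

The cleaning chain follows the usual ECG recipe: decompose the whole
record to nine wavelet scales, soft-threshold the detail coefficients
with the universal threshold sigma_hat * sqrt(2 ln N) (sigma_hat from
the finest detail level via the median absolute deviation), optionally
zero the coarsest approximation band to remove baseline wander, and
reconstruct by the inverse transform.  The record is then segmented
into fixed-length slices around each annotation and every slice is
scaled to unit L2 norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import resample_poly

from .records import Annotation, BeatSlice, RawRecord

__all__ = [
    "DecompositionDepthError",
    "DegenerateSliceError",
    "denoise_wavelet",
    "SegmentationResult",
    "segment_beats",
    "normalize_slice",
    "resample_record",
    "preprocess_record",
]

DEFAULT_R_SAMPLES = 250   # slice length at 360 Hz
DEFAULT_PRE_SAMPLES = 100  # samples kept before the annotated R point
TARGET_FS = 360.0


class DecompositionDepthError(ValueError):
    """Signal too short for the requested decomposition depth."""


class DegenerateSliceError(ValueError):
    """Zero-norm slice cannot be normalized."""


def denoise_wavelet(
    signal: np.ndarray,
    levels: int = 9,
    wavelet_name: str = "db6",
    threshold_scale: float = 1.0,
    remove_baseline: bool = False,
) -> np.ndarray:
    """Nine-scale DWT denoising with soft universal thresholding.

    With threshold_scale = 0 and remove_baseline off this is the identity
    up to transform round-off.  Raises DecompositionDepthError rather
    than silently reducing the depth when the signal is too short.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if threshold_scale < 0:
        raise ValueError("threshold_scale must be >= 0")
    if len(signal) < 2**levels:
        raise DecompositionDepthError(
            f"signal of length {len(signal)} cannot be decomposed to "
            f"{levels} scales (needs >= {2**levels} samples)"
        )
    coeffs = pywt.wavedec(signal, wavelet_name, level=levels, mode="periodization")
    if threshold_scale > 0:
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest)) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(len(signal))) * threshold_scale
        if thr > 0:
            coeffs = [coeffs[0]] + [
                pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]
            ]
    if remove_baseline:
        coeffs[0] = np.zeros_like(coeffs[0])
    out = pywt.waverec(coeffs, wavelet_name, mode="periodization")
    return out[: len(signal)]


@dataclass
class SegmentationResult:
    """Slices plus a report of annotations dropped at record boundaries."""

    slices: list[BeatSlice]
    n_dropped: int = 0
    dropped: list[Annotation] = field(default_factory=list)

    def __iter__(self):
        return iter(self.slices)

    def __len__(self):
        return len(self.slices)


def segment_beats(
    record: RawRecord,
    r: int = DEFAULT_R_SAMPLES,
    pre_samples: int = DEFAULT_PRE_SAMPLES,
) -> SegmentationResult:
    """Cut one r-sample slice per annotation, pre_samples before the R point.

    Annotations whose window would cross a record boundary are dropped
    and counted in the returned report; retained slices appear in
    annotation order and carry the annotation's symbol as label.
    """
    if not 0 < pre_samples < r:
        raise ValueError("pre_samples must satisfy 0 < pre_samples < r")
    n = len(record.samples)
    slices, dropped = [], []
    for k, ann in enumerate(record.annotations):
        start = ann.sample - pre_samples
        if start < 0 or start + r > n:
            dropped.append(ann)
            continue
        slices.append(
            BeatSlice(
                record.samples[start : start + r].copy(),
                label=ann.symbol,
                source=(record.record_id, k),
            )
        )
    return SegmentationResult(slices, n_dropped=len(dropped), dropped=dropped)


def normalize_slice(s: BeatSlice) -> BeatSlice:
    """Scale a slice to unit L2 norm (direction preserved)."""
    nrm = float(np.linalg.norm(s.values))
    if nrm <= 0.0:
        raise DegenerateSliceError("cannot normalize a zero slice")
    return BeatSlice(s.values / nrm, label=s.label, source=s.source, normalized=True)


def resample_record(record: RawRecord, target_fs: float = TARGET_FS) -> RawRecord:
    """Polyphase-resample a record to target_fs, rescaling annotation indices."""
    if abs(record.fs - target_fs) < 1e-9:
        return record
    from fractions import Fraction

    frac = Fraction(target_fs / record.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    samples = resample_poly(record.samples, up, down)
    scale = up / down
    anns = [
        Annotation(int(round(a.sample * scale)), a.symbol)
        for a in record.annotations
        if int(round(a.sample * scale)) < len(samples)
    ]
    return RawRecord(samples, record.fs * scale, anns, record_id=record.record_id)


def preprocess_record(
    record: RawRecord,
    r: int = DEFAULT_R_SAMPLES,
    pre_samples: int = DEFAULT_PRE_SAMPLES,
    levels: int = 9,
    wavelet_name: str = "db6",
    threshold_scale: float = 1.0,
    remove_baseline: bool = True,
) -> SegmentationResult:
    """Denoise the whole record, segment on annotations, unit-normalize.

    Records not sampled at 360 Hz are polyphase-resampled first so that
    one slice length covers the same beat duration everywhere.
    """
    record = resample_record(record, TARGET_FS)
    clean = denoise_wavelet(
        record.samples, levels, wavelet_name, threshold_scale, remove_baseline
    )
    seg = segment_beats(
        RawRecord(clean, record.fs, record.annotations, record.record_id),
        r=r,
        pre_samples=pre_samples,
    )
    seg.slices = [normalize_slice(s) for s in seg.slices]
    return seg
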