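"""Core data containers: annotated single-lead records and beat slices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Annotation", "RawRecord", "BeatSlice"]


@dataclass(frozen=True)
class Annotation:
    """One beat annotation: sample index of the R point and its symbol."""

    sample: int
    symbol: str


@dataclass
class RawRecord:
    """A continuous single-lead physiological signal with beat annotations.

    samples are in millivolts; annotation indices are 0-based sample
    positions of the annotated R points, strictly increasing and inside
    the record.
    """

    samples: np.ndarray
    fs: float
    annotations: list[Annotation] = field(default_factory=list)
    record_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("record signal must be one-dimensional")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n = len(self.samples)
        prev = -1
        for a in self.annotations:
            if not (0 <= a.sample < n) and n > 0:
                raise ValueError(
                    f"annotation sample {a.sample} outside record of length {n}"
                )
            if a.sample <= prev:
                raise ValueError("annotation indices must be strictly increasing")
            prev = a.sample

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class BeatSlice:
    """One fixed-length segmented beat, optionally unit-normalized."""

    values: np.ndarray
    label: str | None = None
    source: tuple[str, int] | None = None  # (record_id, annotation index)
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("beat slice must be one-dimensional")
        if self.normalized:
            nrm = float(np.linalg.norm(self.values))
            if abs(nrm - 1.0) >= 1e-9:
                raise ValueError(f"slice flagged normalized but ||v||2 = {nrm}")

    def __len__(self) -> int:
        return len(self.values)
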