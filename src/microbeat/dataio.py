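"""Text-dialect record IO, beat matrices, AAMI label mapping, run config.

The delimited record dialect is two tab-separated columns
(sample_index, value in mV) with `# key: value` header comments for the
record id and sampling rate, plus a sidecar annotation table
(sample_index, symbol) at `<stem>.ann.tsv`.  Beat matrices are stored
as a columnar `.npz` container (slice matrix + label column) or as
delimited text.  The run configuration is flat key-value text with
sections, chosen so experiment logs diff cleanly.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import Annotation, BeatSlice, RawRecord

__all__ = [
    "write_delimited",
    "read_delimited",
    "read_record",
    "save_beats",
    "load_beats",
    "write_beats_text",
    "LabelMap",
    "AAMI_MAP",
    "ExclusionReport",
    "map_labels",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# delimited record dialect


def write_delimited(record: RawRecord, path) -> Path:
    """Write `<path>` (signal) and `<stem>.ann.tsv` (annotations)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(f"# record_id: {record.record_id}\n")
        fh.write(f"# fs: {float(record.fs)!r}\n")
        for i, v in enumerate(record.samples):
            fh.write(f"{i}\t{float(v)!r}\n")
    ann_path = path.with_name(path.stem + ".ann.tsv")
    with ann_path.open("w") as fh:
        fh.write(f"# record_id: {record.record_id}\n")
        for a in record.annotations:
            fh.write(f"{a.sample}\t{a.symbol}\n")
    return path


def read_delimited(path) -> RawRecord:
    path = Path(path)
    record_id, fs = "", None
    values = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            key = key.strip()
            if key == "record_id":
                record_id = val.strip()
            elif key == "fs":
                fs = float(val)
            continue
        idx, _, val = line.partition("\t")
        values.append(float(val))
    if fs is None:
        raise ValueError(f"{path}: missing '# fs:' header")
    anns = []
    ann_path = path.with_name(path.stem + ".ann.tsv")
    if ann_path.exists():
        for lineno, line in enumerate(ann_path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                idx, _, sym = line.partition("\t")
                anns.append(Annotation(int(idx), sym.strip()))
            except ValueError as e:
                raise ValueError(f"{ann_path}:{lineno}: malformed annotation: {e}")
    return RawRecord(np.asarray(values), fs, anns, record_id=record_id)


def read_record(path, dialect: str = "auto", lead: str | None = None) -> RawRecord:
    """Read a record in either dialect; 'auto' keys on the .hea suffix."""
    path = Path(path)
    if dialect == "auto":
        dialect = "wfdb" if (path.suffix == ".hea" or
                             path.with_suffix(".hea").exists()) else "delimited"
    if dialect == "wfdb":
        from .wfdb_io import read_wfdb

        return read_wfdb(path, lead=lead)
    if dialect == "delimited":
        return read_delimited(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# beat matrices


def save_beats(slices: list[BeatSlice], path, fs: float | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    X = np.stack([s.values for s in slices]) if slices else np.empty((0, 0))
    labels = np.asarray([s.label or "?" for s in slices])
    normalized = np.asarray([s.normalized for s in slices], dtype=bool)
    np.savez(path, X=X, labels=labels, normalized=normalized,
             fs=np.asarray(fs if fs is not None else np.nan))
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_beats(path) -> list[BeatSlice]:
    with np.load(path, allow_pickle=False) as z:
        X, labels, normalized = z["X"], z["labels"], z["normalized"]
        return [
            BeatSlice(X[i], label=str(labels[i]), normalized=bool(normalized[i]))
            for i in range(len(X))
        ]


def write_beats_text(slices: list[BeatSlice], path) -> Path:
    """Delimited beat matrix: label column then r sample columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for s in slices:
            fh.write((s.label or "?") + "\t" +
                     "\t".join(repr(float(v)) for v in s.values) + "\n")
    return path


# ---------------------------------------------------------------------------
# AAMI label mapping


@dataclass(frozen=True)
class LabelMap:
    """Annotation-symbol to class-symbol mapping; unmapped -> excluded."""

    mapping: dict[str, str]

    def __post_init__(self):
        for sym, cls in self.mapping.items():
            if not isinstance(cls, str):
                raise ValueError(f"class for {sym!r} must be a symbol")

    def get(self, symbol: str) -> str | None:
        return self.mapping.get(symbol)


#: AAMI EC57 beat grouping restricted to the three reported superclasses;
#: fusion (F) and paced/unknown (Q, /, f) beats are excluded.
AAMI_MAP = LabelMap({
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
})


@dataclass
class ExclusionReport:
    total: int
    retained: int
    excluded_counts: dict[str, int] = field(default_factory=dict)

    @property
    def excluded(self) -> int:
        return sum(self.excluded_counts.values())


def map_labels(items, label_map: LabelMap = AAMI_MAP):
    """Relabel a RawRecord's annotations or a BeatSlice list to N/S/V.

    Returns (relabeled, report); retained + excluded = input count.
    """
    if isinstance(items, RawRecord):
        kept, excl = [], {}
        for a in items.annotations:
            cls = label_map.get(a.symbol)
            if cls is None:
                excl[a.symbol] = excl.get(a.symbol, 0) + 1
            else:
                kept.append(Annotation(a.sample, cls))
        rec = RawRecord(items.samples, items.fs, kept, record_id=items.record_id)
        return rec, ExclusionReport(len(items.annotations), len(kept), excl)

    kept, excl = [], {}
    for s in items:
        cls = label_map.get(s.label) if s.label else None
        if cls is None:
            key = s.label or "?"
            excl[key] = excl.get(key, 0) + 1
        else:
            kept.append(BeatSlice(s.values, label=cls, source=s.source,
                                  normalized=s.normalized))
    return kept, ExclusionReport(len(list(items)), len(kept), excl)


# ---------------------------------------------------------------------------
# run configuration


_SCHEMA: dict[str, dict[str, type]] = {
    "run": {"seed": int},
    "synthetic": {"n_n": int, "n_s": int, "n_v": int, "separation": float,
                  "fs": float, "r": int, "jitter": float},
    "preprocessing": {"levels": int, "wavelet": str, "threshold_scale": float,
                      "remove_baseline": bool, "r": int, "pre_samples": int},
    "extractor": {"omega": int, "cell_type": str, "hidden1": int,
                  "hidden2": int, "m": int, "activation": str,
                  "input_gain": float},
    "ensemble": {"eta": float, "c": float, "pi": float, "tau": float,
                 "h1": int, "h2": int, "activation": str},
    "training": {"lr": float, "epochs": int, "batch_size": int,
                 "train_extractor": bool},
    "split": {"train": float, "val": float, "test": float,
              "stratified": bool},
}

_DEFAULTS: dict[str, dict[str, object]] = {
    "run": {"seed": 0},
    "synthetic": {"n_n": 200, "n_s": 200, "n_v": 200, "separation": 1.0,
                  "fs": 360.0, "r": 250, "jitter": 0.05},
    "preprocessing": {"levels": 9, "wavelet": "db6", "threshold_scale": 1.0,
                      "remove_baseline": True, "r": 250, "pre_samples": 100},
    "extractor": {"omega": 25, "cell_type": "BiLSTM", "hidden1": 32,
                  "hidden2": 64, "m": 64, "activation": "tanh",
                  "input_gain": 15.8113883008419},
    "ensemble": {"eta": 1.0, "c": 2.0, "pi": 0.1, "tau": 0.1,
                 "h1": 32, "h2": 16, "activation": "tanh"},
    "training": {"lr": 1e-3, "epochs": 30, "batch_size": 32,
                 "train_extractor": False},
    "split": {"train": 0.6, "val": 0.2, "test": 0.2, "stratified": True},
}


@dataclass
class RunConfig:
    """Typed flat-text configuration covering every pipeline stage.

    Unknown sections or keys are rejected; serialization round-trips
    losslessly through `to_file`/`from_file`.
    """

    values: dict[str, dict[str, object]] = field(default_factory=dict)

    def __post_init__(self):
        merged = {s: dict(kv) for s, kv in _DEFAULTS.items()}
        for sec, kv in self.values.items():
            if sec not in _SCHEMA:
                raise ValueError(f"unknown config section [{sec}]")
            for key, val in kv.items():
                if key not in _SCHEMA[sec]:
                    raise ValueError(f"unknown config key [{sec}] {key}")
                merged[sec][key] = _SCHEMA[sec][key](val) \
                    if not isinstance(val, bool) and _SCHEMA[sec][key] is not bool \
                    else bool(val)
        self.values = merged

    def __getitem__(self, sec: str) -> dict[str, object]:
        return self.values[sec]

    def set(self, sec: str, key: str, val) -> None:
        if sec not in _SCHEMA or key not in _SCHEMA[sec]:
            raise ValueError(f"unknown config key [{sec}] {key}")
        caster = _SCHEMA[sec][key]
        if caster is bool and isinstance(val, str):
            val = val.lower() in ("1", "true", "yes", "on")
        self.values[sec][key] = caster(val)

    # -- factory views -----------------------------------------------------

    def extractor_config(self):
        from .features import ExtractorConfig

        e = self.values["extractor"]
        return ExtractorConfig(
            omega=e["omega"], cell_type=e["cell_type"], hidden1=e["hidden1"],
            hidden2=e["hidden2"], m=e["m"], activation=e["activation"],
            seed=self.values["run"]["seed"], input_gain=e["input_gain"],
        )

    def ensemble_hyper(self):
        from .ensemble import EnsembleHyper

        h = self.values["ensemble"]
        return EnsembleHyper(eta=h["eta"], c=h["c"], pi=h["pi"], tau=h["tau"],
                             h1=h["h1"], h2=h["h2"], activation=h["activation"])

    def train_config(self):
        from .pipeline import TrainConfig

        t = self.values["training"]
        return TrainConfig(lr=t["lr"], epochs=t["epochs"],
                           batch_size=t["batch_size"],
                           train_extractor=t["train_extractor"])

    def split_spec(self):
        from .pipeline import SplitSpec

        s = self.values["split"]
        return SplitSpec((s["train"], s["val"], s["test"]), s["stratified"],
                         seed=self.values["run"]["seed"])

    # -- (de)serialization ---------------------------------------------------

    def to_file(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cp = configparser.ConfigParser()
        for sec, kv in self.values.items():
            cp[sec] = {k: repr(v) if isinstance(v, float) else str(v)
                       for k, v in kv.items()}
        with path.open("w") as fh:
            cp.write(fh)
        return path

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cp = configparser.ConfigParser()
        read = cp.read(path)
        if not read:
            raise FileNotFoundError(path)
        values: dict[str, dict[str, object]] = {}
        for sec in cp.sections():
            if sec not in _SCHEMA:
                raise ValueError(f"unknown config section [{sec}]")
            values[sec] = {}
            for key, raw in cp[sec].items():
                if key not in _SCHEMA[sec]:
                    raise ValueError(f"unknown config key [{sec}] {key}")
                caster = _SCHEMA[sec][key]
                if caster is bool:
                    values[sec][key] = raw.lower() in ("1", "true", "yes", "on")
                else:
                    values[sec][key] = caster(raw)
        return cls(values)
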