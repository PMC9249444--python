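"""Micro two-level recurrent feature extractor.

Each unit-normalized beat slice is cut into windows of length omega.  A
single shared first-level recurrent cell encodes every window
independently into a summary vector (its final hidden state); a
second-level cell then encodes the window-summary sequence, and a
linear projection plus activation yields the fixed-length feature
vector.  Weight sharing across windows keeps the parameter count
independent of the slice length, which is what makes the model small.

Cells: plain RNN, GRU (default), LSTM, and BiLSTM (summary size doubles).
All forward passes are built on the in-package autodiff graph, so both
parameter gradients and input gradients are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .records import BeatSlice

__all__ = [
    "ExtractorConfig",
    "FeatureVector",
    "init_extractor",
    "n_params",
    "window_split",
    "level1_encode",
    "level2_encode",
    "extract_features",
    "extract_features_batch",
    "forward_batch",
    "forward_batch_with_input",
]

CELL_TYPES = ("plainRNN", "GRU", "LSTM", "BiLSTM")
_ACTIVATIONS = ("tanh", "identity")


@dataclass(frozen=True)
class ExtractorConfig:
    omega: int = 25          # window length in samples
    # BiLSTM reads each window and the window sequence in both directions,
    # so beat onset (P wave) information survives to the final state.
    cell_type: str = "BiLSTM"
    hidden1: int = 32        # level-1 state size
    hidden2: int = 64        # level-2 state size
    m: int = 64              # output feature length
    activation: str = "tanh"
    seed: int = 0
    # Unit-L2 slices of length r have per-sample RMS 1/sqrt(r); the gain
    # restores O(1) sample amplitude at the recurrent cell.  Default is
    # sqrt(250) for the default slice length.
    input_gain: float = 15.8113883008419

    def __post_init__(self):
        if self.omega < 1 or self.hidden1 < 1 or self.hidden2 < 1 or self.m < 1:
            raise ValueError("omega, hidden sizes and m must all be >= 1")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"cell_type must be one of {CELL_TYPES}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")

    @property
    def l1_out(self) -> int:
        return self.hidden1 * (2 if self.cell_type == "BiLSTM" else 1)

    @property
    def l2_out(self) -> int:
        return self.hidden2 * (2 if self.cell_type == "BiLSTM" else 1)


@dataclass
class FeatureVector:
    values: np.ndarray
    source: tuple[str, int] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")


# ---------------------------------------------------------------------------
# parameter initialization (uniform in +-1/sqrt(fan_in), seeded)

def _mat(rng, fan_in: int, rows: int, cols: int) -> Tensor:
    b = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-b, b, (rows, cols)), requires_grad=True)


def _vec(rng, fan_in: int, n: int) -> Tensor:
    b = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-b, b, n), requires_grad=True)


def _init_cell(rng, cell_type: str, in_dim: int, hid: int, prefix: str) -> dict:
    gates = {"plainRNN": [""], "GRU": ["z", "r", "n"],
             "LSTM": ["i", "f", "g", "o"]}
    p = {}
    if cell_type == "BiLSTM":
        p.update(_init_cell(rng, "LSTM", in_dim, hid, prefix + "fw."))
        p.update(_init_cell(rng, "LSTM", in_dim, hid, prefix + "bw."))
        return p
    for g in gates[cell_type]:
        p[f"{prefix}W{g}"] = _mat(rng, in_dim, in_dim, hid)
        p[f"{prefix}U{g}"] = _mat(rng, hid, hid, hid)
        b = _vec(rng, hid, hid)
        # "remember" bias: start the GRU update gate / LSTM forget gate
        # open so early-window information survives the scan
        if g in ("z", "f"):
            b.data += 1.0
        p[f"{prefix}b{g}"] = b
    return p


def init_extractor(config: ExtractorConfig) -> dict[str, Tensor]:
    """Seeded parameter dictionary for the full two-level extractor."""
    rng = np.random.default_rng(config.seed)
    p = {}
    p.update(_init_cell(rng, config.cell_type, 1, config.hidden1, "l1."))
    p.update(_init_cell(rng, config.cell_type, config.l1_out, config.hidden2, "l2."))
    p["proj.W"] = _mat(rng, config.l2_out, config.l2_out, config.m)
    p["proj.b"] = _vec(rng, config.l2_out, config.m)
    return p


def n_params(params: dict[str, Tensor]) -> int:
    return sum(t.data.size for t in params.values())


# ---------------------------------------------------------------------------
# recurrent cells (xs: list of (B, in) Tensors, one per timestep)

def _rnn_scan(p, prefix, xs, hid):
    h = Tensor(np.zeros((xs[0].shape[0], hid)))
    for x in xs:
        h = (x @ p[prefix + "W"] + h @ p[prefix + "U"] + p[prefix + "b"]).tanh()
    return h


def _gru_scan(p, prefix, xs, hid):
    h = Tensor(np.zeros((xs[0].shape[0], hid)))
    for x in xs:
        z = (x @ p[prefix + "Wz"] + h @ p[prefix + "Uz"] + p[prefix + "bz"]).sigmoid()
        r = (x @ p[prefix + "Wr"] + h @ p[prefix + "Ur"] + p[prefix + "br"]).sigmoid()
        n = (x @ p[prefix + "Wn"] + r * (h @ p[prefix + "Un"]) + p[prefix + "bn"]).tanh()
        h = (1.0 - z) * n + z * h
    return h


def _lstm_scan(p, prefix, xs, hid):
    B = xs[0].shape[0]
    h = Tensor(np.zeros((B, hid)))
    c = Tensor(np.zeros((B, hid)))
    for x in xs:
        i = (x @ p[prefix + "Wi"] + h @ p[prefix + "Ui"] + p[prefix + "bi"]).sigmoid()
        f = (x @ p[prefix + "Wf"] + h @ p[prefix + "Uf"] + p[prefix + "bf"]).sigmoid()
        g = (x @ p[prefix + "Wg"] + h @ p[prefix + "Ug"] + p[prefix + "bg"]).tanh()
        o = (x @ p[prefix + "Wo"] + h @ p[prefix + "Uo"] + p[prefix + "bo"]).sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
    return h


def _run_cell(p, cell_type, prefix, xs, hid) -> Tensor:
    if cell_type == "plainRNN":
        return _rnn_scan(p, prefix, xs, hid)
    if cell_type == "GRU":
        return _gru_scan(p, prefix, xs, hid)
    if cell_type == "LSTM":
        return _lstm_scan(p, prefix, xs, hid)
    if cell_type == "BiLSTM":
        fw = _lstm_scan(p, prefix + "fw.", xs, hid)
        bw = _lstm_scan(p, prefix + "bw.", list(reversed(xs)), hid)
        return concat([fw, bw], axis=1)
    raise ValueError(f"unknown cell type {cell_type!r}")


# ---------------------------------------------------------------------------
# windowing

def window_split(values: np.ndarray | BeatSlice, omega: int) -> list[np.ndarray]:
    """Split a slice into ceil(r/omega) windows of length omega.

    The final window is edge-padded (last sample replicated) when r is
    not a multiple of omega; concatenating the windows and truncating
    the padding reproduces the slice exactly.
    """
    if isinstance(values, BeatSlice):
        values = values.values
    values = np.asarray(values, dtype=np.float64)
    if omega < 1:
        raise ValueError("omega must be >= 1")
    r = len(values)
    k = -(-r // omega)
    out = []
    for j in range(k):
        w = values[j * omega : (j + 1) * omega]
        if len(w) < omega:
            w = np.concatenate([w, np.full(omega - len(w), w[-1])])
        out.append(w)
    return out


def _graph_windows(X: Tensor, omega: int) -> tuple[Tensor, int]:
    """In-graph windowing of X (B, r) -> (K*B, omega), window-major rows."""
    B, r = X.shape
    k = -(-r // omega)
    wins = []
    for j in range(k):
        a, b = j * omega, min((j + 1) * omega, r)
        w = X[:, a:b]
        pad = omega - (b - a)
        if pad:
            w = concat([w] + [X[:, b - 1 : b]] * pad, axis=1)
        wins.append(w)
    return concat(wins, axis=0), k


# ---------------------------------------------------------------------------
# forward passes

def _forward(X: Tensor, config: ExtractorConfig, params: dict) -> Tensor:
    B = X.shape[0]
    if config.input_gain != 1.0:
        X = X * config.input_gain
    Xw, k = _graph_windows(X, config.omega)
    xs1 = [Xw[:, t : t + 1] for t in range(config.omega)]
    h1 = _run_cell(params, config.cell_type, "l1.", xs1, config.hidden1)
    H = h1.reshape(k, B, config.l1_out)
    xs2 = [H[j] for j in range(k)]
    h2 = _run_cell(params, config.cell_type, "l2.", xs2, config.hidden2)
    y = h2 @ params["proj.W"] + params["proj.b"]
    return y.tanh() if config.activation == "tanh" else y


def forward_batch(X: np.ndarray, config: ExtractorConfig, params: dict) -> Tensor:
    """Features for a batch of slices (B, r) as a graph Tensor (B, m)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    return _forward(Tensor(X), config, params)


def forward_batch_with_input(
    X: np.ndarray, config: ExtractorConfig, params: dict
) -> tuple[Tensor, Tensor]:
    """Same as forward_batch but also returns the input leaf Tensor so
    gradients of features with respect to the raw slice samples can be
    read off after backward()."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Xt = Tensor(X, requires_grad=True)
    return _forward(Xt, config, params), Xt


# ---------------------------------------------------------------------------
# public single-slice ops

def level1_encode(
    windows: list[np.ndarray], config: ExtractorConfig, params: dict
) -> list[np.ndarray]:
    """Encode each window independently with the shared level-1 cell.

    The same parameters are applied to every window and no state is
    carried across windows: each summary depends only on its own window.
    """
    out = []
    for w in windows:
        w = np.asarray(w, dtype=np.float64) * config.input_gain
        if len(w) != config.omega:
            raise ValueError(
                f"window length {len(w)} does not match omega={config.omega}"
            )
        xs = [Tensor(w[t].reshape(1, 1)) for t in range(config.omega)]
        h = _run_cell(params, config.cell_type, "l1.", xs, config.hidden1)
        out.append(h.data[0].copy())
    return out


def level2_encode(
    summaries: list[np.ndarray], config: ExtractorConfig, params: dict
) -> FeatureVector:
    """Encode the window-summary sequence and project to m features."""
    if not summaries:
        raise ValueError("level2_encode requires a nonempty summary list")
    xs = [Tensor(np.asarray(s, dtype=np.float64).reshape(1, -1)) for s in summaries]
    h2 = _run_cell(params, config.cell_type, "l2.", xs, config.hidden2)
    y = h2 @ params["proj.W"] + params["proj.b"]
    y = y.tanh() if config.activation == "tanh" else y
    return FeatureVector(y.data[0].copy())


def extract_features(
    s: BeatSlice | np.ndarray, config: ExtractorConfig, params: dict
) -> FeatureVector:
    """window_split -> level1_encode -> level2_encode, as one batch pass."""
    values = s.values if isinstance(s, BeatSlice) else np.asarray(s, float)
    source = s.source if isinstance(s, BeatSlice) else None
    y = forward_batch(values.reshape(1, -1), config, params)
    return FeatureVector(y.data[0].copy(), source=source)


def extract_features_batch(
    X: np.ndarray, config: ExtractorConfig, params: dict
) -> np.ndarray:
    """Plain numpy feature matrix (B, m) for evaluation-time use."""
    return forward_batch(X, config, params).data.copy()
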