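"""Per-class one-class mini-classifier ensemble.

One three-layer perceptron scorer per class, trained only on its own
class with the one-class loss

    loss_i = E[-log sigmoid(f_i(X))]            (negative log likelihood)
           + eta * E[ ||d f_i(X) / dX||_2^c ]   (H-reg gradient penalty)
           + pi  * ||theta_i - mu_{1:i-1}||_2^2 (parameter anchor)

where X is the extracted feature of a class-i beat and theta_i is the
flattened parameter vector of scorer i.  The NLL pushes the own-class
score up; H-reg bounds the scorer's input sensitivity so scores cannot
grow without limit; the anchor keeps all scorers in a common region of
parameter space (mu is the mean of the previously initialized scorers).

After training, the "shared knowledge" of the bank — the mean of the
KL-divergence barycenter of per-scorer parameter posteriors, modeled as
isotropic Gaussians N(theta_i, sigma^2 I), which is the phi-weighted
mean sum_i phi_i theta_i — is subtracted once from every theta_i
(scaled by tau) to sharpen inter-class distinctions.  Prediction is the
argmax of the raw scores over the bank.

The H-reg input gradient of the perceptron is expressed in closed form
with ordinary graph operations, so one first-order backward pass yields
its parameter gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .features import ExtractorConfig, FeatureVector, init_extractor

__all__ = [
    "EnsembleHyper",
    "MiniClassifier",
    "EnsembleModel",
    "score",
    "nll_term",
    "hreg_term",
    "anchor_term",
    "one_class_loss",
    "init_from_previous",
    "shared_knowledge",
    "remove_shared",
    "predict",
]

ARCHIVE_VERSION = 1


@dataclass(frozen=True)
class EnsembleHyper:
    """Loss and fusion hyperparameters (eta, c, pi, tau) and scorer sizes."""

    eta: float = 1.0   # H-reg weight
    c: float = 2.0     # gradient-norm exponent
    pi: float = 0.1    # anchor weight
    tau: float = 0.1   # shared-knowledge removal step
    h1: int = 32       # scorer hidden sizes
    h2: int = 16
    activation: str = "tanh"  # hidden activation of the scorer

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("exponent c must be > 0")
        if min(self.eta, self.pi, self.tau) < 0:
            raise ValueError("eta, pi and tau must be >= 0")
        if self.activation not in ("tanh", "identity"):
            raise ValueError("scorer activation must be 'tanh' or 'identity'")


class MiniClassifier:
    """Three-layer perceptron scorer f(X) = W3·sigma(W2·sigma(W1·X)).

    The scorer is bias-free: a free bias would let the one-class loss
    push scores up while the gradient penalty shrinks every weight,
    collapsing the scorer to a constant function and making the
    cross-class argmax meaningless.  Weights are stored input-major
    (W1: m x h1, W2: h1 x h2, W3: h2 x 1); `theta` is the flattening,
    in the fixed order W1, W2, W3, each C-order raveled.
    """

    _PARAM_ORDER = ("W1", "W2", "W3")

    def __init__(self, class_index: int, m: int, h1: int = 32, h2: int = 16,
                 activation: str = "tanh",
                 rng: np.random.Generator | None = None):
        self.class_index = class_index
        self.m, self.h1, self.h2 = m, h1, h2
        self.activation = activation
        rng = rng or np.random.default_rng(0)

        def mat(fan_in, rows, cols):
            b = 1.0 / np.sqrt(fan_in)
            return Tensor(rng.uniform(-b, b, (rows, cols)), requires_grad=True)

        self.W1 = mat(m, m, h1)
        self.W2 = mat(h1, h1, h2)
        self.W3 = mat(h2, h2, 1)

    # -- parameters --------------------------------------------------------

    def param_list(self) -> list[Tensor]:
        return [getattr(self, n) for n in self._PARAM_ORDER]

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([p.data.ravel() for p in self.param_list()])

    def set_theta(self, theta: np.ndarray) -> None:
        theta = np.asarray(theta, dtype=np.float64)
        if theta.size != self.theta.size:
            raise ValueError(
                f"theta length {theta.size} does not match {self.theta.size}"
            )
        ofs = 0
        for p in self.param_list():
            k = p.data.size
            p.data = theta[ofs : ofs + k].reshape(p.data.shape).copy()
            ofs += k

    def theta_tensor(self) -> Tensor:
        return concat([p.reshape(-1) for p in self.param_list()], axis=0)

    # -- forward -----------------------------------------------------------

    def _act(self, z: Tensor) -> Tensor:
        return z.tanh() if self.activation == "tanh" else z

    def forward(self, X: Tensor) -> Tensor:
        """Raw (pre-sigmoid) scores for a feature batch (B, m) -> (B, 1)."""
        s1 = self._act(X @ self.W1)
        s2 = self._act(s1 @ self.W2)
        return s2 @ self.W3

    def input_gradient(self, X: Tensor) -> Tensor:
        """d f / d X for each row of X, in closed form: (B, m).

        With tanh hiddens: g = ((w3 ⊙ (1-s2²)) W2ᵀ ⊙ (1-s1²)) W1ᵀ.
        Built from graph ops, so its parameter gradients come from
        ordinary backprop (no second-order machinery needed).
        """
        z1 = X @ self.W1
        s1 = self._act(z1)
        z2 = s1 @ self.W2
        s2 = self._act(z2)
        w3 = self.W3.reshape(1, self.h2)
        if self.activation == "tanh":
            d2 = 1.0 - s2 * s2
            d1 = 1.0 - s1 * s1
            u2 = w3 * d2
            u1 = (u2 @ self.W2.t()) * d1
        else:
            u2 = w3 * Tensor(np.ones_like(z2.data))
            u1 = u2 @ self.W2.t()
        return u1 @ self.W1.t()


# ---------------------------------------------------------------------------
# loss terms


def _as_batch(X) -> Tensor:
    if isinstance(X, Tensor):
        return X
    if isinstance(X, FeatureVector):
        X = X.values
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    return Tensor(X)


def score(clf: MiniClassifier, F) -> float:
    """Raw scalar score of one feature vector."""
    t = _as_batch(F)
    if t.shape[1] != clf.m:
        raise ValueError(f"feature length {t.shape[1]} != scorer input {clf.m}")
    return float(clf.forward(t).data[0, 0])


def nll_term(clf: MiniClassifier, batch) -> Tensor:
    """Mean of -log sigmoid(f(X)) over a batch of own-class features."""
    X = _as_batch(batch)
    if X.shape[0] == 0:
        raise ValueError("nll_term requires a nonempty batch")
    f = clf.forward(X)
    return (-f).softplus().mean()


def hreg_term(clf: MiniClassifier, batch, c: float = 2.0) -> Tensor:
    """Mean of ||d f(X)/dX||_2^c over the batch (gradient penalty)."""
    if c <= 0:
        raise ValueError("exponent c must be > 0")
    X = _as_batch(batch)
    g = clf.input_gradient(X)
    sq = (g * g).sum(axis=1)
    if c != 2.0:
        sq = sq ** (c / 2.0)
    return sq.mean()


def anchor_term(clf: MiniClassifier, mu_prev: np.ndarray | None) -> Tensor:
    """Squared distance of theta to the previous-scorer mean (0 for i=1)."""
    if mu_prev is None:
        return Tensor(0.0)
    mu_prev = np.asarray(mu_prev, dtype=np.float64)
    th = clf.theta_tensor()
    if mu_prev.size != th.shape[0]:
        raise ValueError(
            f"anchor length {mu_prev.size} does not match theta {th.shape[0]}"
        )
    d = th - Tensor(mu_prev)
    return (d * d).sum()


def one_class_loss(clf: MiniClassifier, batch, hyper: EnsembleHyper,
                   mu_prev: np.ndarray | None = None) -> Tensor:
    """nll + eta * hreg + pi * anchor, exactly."""
    loss = nll_term(clf, batch)
    if hyper.eta != 0.0:
        loss = loss + hyper.eta * hreg_term(clf, batch, hyper.c)
    if hyper.pi != 0.0:
        loss = loss + hyper.pi * anchor_term(clf, mu_prev)
    return loss


# ---------------------------------------------------------------------------
# sequential initialization and shared-knowledge removal


def init_from_previous(
    thetas: list[np.ndarray], rng: np.random.Generator, perturb_sd: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Initialize scorer i from the mean of scorers 1..i-1.

    Returns (theta_init, mu_prev): the mean of the previous parameter
    vectors plus a small seeded perturbation to break symmetry, and the
    unperturbed mean itself (the anchor target).
    """
    if not thetas:
        raise ValueError("init_from_previous needs at least one previous scorer")
    mu = np.mean(np.stack(thetas), axis=0)
    return mu + rng.normal(0.0, perturb_sd, mu.shape), mu


@dataclass
class EnsembleModel:
    """Extractor + T mini-classifiers + hyperparameters."""

    config: ExtractorConfig
    extractor: dict[str, Tensor]
    classifiers: list[MiniClassifier]
    hyper: EnsembleHyper
    class_symbols: tuple[str, ...]
    phi: np.ndarray | None = None  # mixing ratios; default uniform
    # Training-set mean feature, subtracted before scoring.  Without it
    # the common feature component acts as an arbitrary per-scorer
    # offset (w_i . mean) that swamps the class-specific response.
    feature_center: np.ndarray | None = None
    # ZCA whitening matrix fit on training features; equalizes the scale
    # of the between-class axes (close class pairs would otherwise be
    # drowned by the dominant axis).
    feature_whiten: np.ndarray | None = None

    def __post_init__(self):
        T = len(self.classifiers)
        if len(self.class_symbols) != T:
            raise ValueError("one class symbol per classifier required")
        if self.phi is None:
            self.phi = np.full(T, 1.0 / T)
        self.phi = np.asarray(self.phi, dtype=np.float64)
        if self.phi.shape != (T,) or np.any(self.phi < 0) or \
                abs(self.phi.sum() - 1.0) > 1e-9:
            raise ValueError("phi must be nonnegative and sum to 1")
        sizes = {clf.theta.size for clf in self.classifiers}
        if len(sizes) > 1:
            raise ValueError("all mini-classifiers must share identical shapes")

    @property
    def T(self) -> int:
        return len(self.classifiers)

    # -- inference ---------------------------------------------------------

    def transform_features(self, F: np.ndarray) -> np.ndarray:
        """Center and whiten raw extractor features."""
        F = np.atleast_2d(np.asarray(F, dtype=np.float64))
        if self.feature_center is not None:
            F = F - self.feature_center
        if self.feature_whiten is not None:
            F = F @ self.feature_whiten
        return F

    def score_features(self, F: np.ndarray) -> np.ndarray:
        """Raw score matrix (B, T) for a feature batch (centered and
        whitened first)."""
        if isinstance(F, Tensor):
            F = F.data
        X = Tensor(self.transform_features(F))
        return np.column_stack([clf.forward(X).data[:, 0] for clf in self.classifiers])

    def features_of(self, X_slices: np.ndarray) -> np.ndarray:
        from .features import extract_features_batch

        return extract_features_batch(X_slices, self.config, self.extractor)

    def predict_features(self, F: np.ndarray) -> list[str]:
        s = self.score_features(F)
        return [self.class_symbols[i] for i in np.argmax(s, axis=1)]

    def predict_slices(self, X_slices: np.ndarray) -> list[str]:
        return self.predict_features(self.features_of(X_slices))

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"ext.{k}": t.data for k, t in self.extractor.items()}
        for i, clf in enumerate(self.classifiers):
            arrays[f"clf{i}.theta"] = clf.theta
        if self.feature_center is not None:
            arrays["feature_center"] = self.feature_center
        if self.feature_whiten is not None:
            arrays["feature_whiten"] = self.feature_whiten
        meta = {
            "version": ARCHIVE_VERSION,
            "config": self.config.__dict__,
            "hyper": self.hyper.__dict__,
            "class_symbols": list(self.class_symbols),
            "phi": self.phi.tolist(),
            "m": self.config.m,
        }
        arrays["meta"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode("utf-8"))
            if meta["version"] != ARCHIVE_VERSION:
                raise ValueError(f"unsupported archive version {meta['version']}")
            config = ExtractorConfig(**meta["config"])
            hyper = EnsembleHyper(**meta["hyper"])
            extractor = init_extractor(config)
            for k in extractor:
                extractor[k].data = z[f"ext.{k}"].copy()
            classifiers = []
            for i in range(len(meta["class_symbols"])):
                clf = MiniClassifier(i, config.m, hyper.h1, hyper.h2,
                                     hyper.activation)
                clf.set_theta(z[f"clf{i}.theta"])
                classifiers.append(clf)
            center = z["feature_center"].copy() if "feature_center" in z else None
            whiten = z["feature_whiten"].copy() if "feature_whiten" in z else None
        return cls(config, extractor, classifiers, hyper,
                   tuple(meta["class_symbols"]), np.asarray(meta["phi"]),
                   feature_center=center, feature_whiten=whiten)


def shared_knowledge(model: EnsembleModel) -> np.ndarray:
    """Mean of the KL barycenter of the per-scorer parameter posteriors.

    With posteriors modeled as isotropic Gaussians N(theta_i, sigma^2 I),
    the Gaussian minimizing sum_i phi_i KL(P_i || Q) has mean
    sum_i phi_i theta_i (sigma cancels), which is returned.
    """
    thetas = np.stack([clf.theta for clf in model.classifiers])
    return model.phi @ thetas


def remove_shared(model: EnsembleModel) -> EnsembleModel:
    """Subtract tau * shared knowledge from every scorer, in place.

    Applied exactly once, after training and before evaluation; repeated
    application keeps shifting the parameters (not idempotent).
    """
    rho = shared_knowledge(model)
    for clf in model.classifiers:
        clf.set_theta(clf.theta - model.hyper.tau * rho)
    return model


def predict(model: EnsembleModel, F) -> str:
    """Class symbol of the highest-scoring mini-classifier.

    Ties break toward the lowest class index (argmax convention).
    """
    if isinstance(F, FeatureVector):
        F = F.values
    return model.predict_features(np.atleast_2d(F))[0]
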