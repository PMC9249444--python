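"""Training/evaluation protocol: 6:2:2 split, one-class training, metrics.

The dataset is split 6:2:2 into train/validation/test (stratified by
beat label, largest-remainder rounding so the totals are exact).  The
extractor and all mini-classifiers are trained jointly with Adam: each
step draws one batch per class, pushes all of them through the shared
extractor, and sums the per-class one-class losses (classifier i only
ever sees class-i beats).  The validation set is used solely to retain
the best-accuracy parameters; shared-knowledge removal is applied once
after training.  Metrics are percent-scale precision, recall, F1
(harmonic mean) per class plus overall accuracy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix

from .autodiff import Adam, Tensor
from .ensemble import (
    EnsembleHyper,
    EnsembleModel,
    MiniClassifier,
    init_from_previous,
    one_class_loss,
    remove_shared,
)
from .features import ExtractorConfig, forward_batch, init_extractor
from .records import BeatSlice

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "TrainLog",
    "MetricsReport",
    "split_dataset",
    "train",
    "evaluate",
    "compute_f1",
    "metrics_from_confusion",
    "slices_to_matrix",
]

_CLASS_ORDER = {"N": 0, "S": 1, "V": 2}


def _symbol_order(symbols) -> list[str]:
    return sorted(set(symbols), key=lambda s: (_CLASS_ORDER.get(s, 99), s))


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be positive and sum to 1")


def _largest_remainder(total: int, fractions) -> list[int]:
    quota = np.asarray(fractions) * total
    base = np.floor(quota).astype(int)
    rem = quota - base
    for _ in range(total - int(base.sum())):
        j = int(np.argmax(rem))
        base[j] += 1
        rem[j] = -1.0
    return base.tolist()


def split_dataset(
    slices: list[BeatSlice], spec: SplitSpec = SplitSpec()
) -> tuple[list[BeatSlice], list[BeatSlice], list[BeatSlice]]:
    """Partition slices into train/val/test at the spec fractions.

    Global split sizes come from largest-remainder rounding, so they are
    exact (100 beats -> 60/20/20).  With stratification, per-class
    quotas are rounded the same way under the fixed global sizes, which
    keeps every class's proportions within one beat of the fractions.
    """
    n = len(slices)
    sizes = _largest_remainder(n, spec.fractions)
    rng = np.random.default_rng(spec.seed)

    if not spec.stratified:
        order = rng.permutation(n)
        a, b = sizes[0], sizes[0] + sizes[1]
        pick = lambda idx: [slices[i] for i in idx]
        return pick(order[:a]), pick(order[a:b]), pick(order[b:])

    labels = [s.label for s in slices]
    symbols = _symbol_order(labels)
    queues = {}
    for sym in symbols:
        idx = np.asarray([i for i, l in enumerate(labels) if l == sym])
        if len(idx) < 3:
            raise ValueError(
                f"class {sym!r} has {len(idx)} examples, fewer than the "
                f"3 stratification slots"
            )
        queues[sym] = list(rng.permutation(idx))

    counts = {sym: len(queues[sym]) for sym in symbols}
    remaining = dict(counts)
    out: list[list[BeatSlice]] = [[], [], []]
    for split_i in (0, 1):
        frac = spec.fractions[split_i]
        quota = {sym: counts[sym] * frac for sym in symbols}
        take = {sym: int(np.floor(quota[sym])) for sym in symbols}
        leftover = sizes[split_i] - sum(take.values())
        rems = sorted(symbols, key=lambda s: quota[s] - take[s], reverse=True)
        for sym in rems:
            if leftover <= 0:
                break
            if take[sym] < remaining[sym]:
                take[sym] += 1
                leftover -= 1
        for sym in symbols:
            k = min(take[sym], remaining[sym])
            for _ in range(k):
                out[split_i].append(slices[queues[sym].pop()])
            remaining[sym] -= k
    for sym in symbols:
        for i in queues[sym]:
            out[2].append(slices[i])
    return out[0], out[1], out[2]


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 32
    # Train the extractor jointly with the scorers.  With purely
    # one-class losses the only gradient the extractor receives says
    # "raise every score", whose cheapest solution collapses all beats
    # to one feature point; the default keeps the seeded extractor fixed
    # so class geometry is preserved.
    train_extractor: bool = False


@dataclass
class TrainLog:
    class_symbols: tuple[str, ...]
    epoch_loss: list[dict[str, float]] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def total_loss(self, epoch: int) -> float:
        return float(sum(self.epoch_loss[epoch].values()))

    def to_lines(self) -> list[str]:
        lines = []
        for e, (losses, acc) in enumerate(zip(self.epoch_loss, self.val_accuracy)):
            parts = " ".join(f"loss[{s}]={losses[s]:.6f}" for s in self.class_symbols)
            lines.append(f"epoch={e} {parts} val_acc={acc:.2f}")
        lines.append(f"best_epoch={self.best_epoch}")
        return lines


def _fit_feature_transform(model: EnsembleModel, F: np.ndarray,
                           shrink: float = 0.1) -> None:
    """Fit centering + shrinkage-regularized ZCA whitening on training
    features.  Whitening equalizes the between-class axes so that a
    close class pair is not drowned by the dominant axis; shrinkage
    (lambda + shrink*mean(lambda)) bounds the amplification of
    low-variance noise directions."""
    center = F.mean(axis=0)
    Fc = F - center
    cov = Fc.T @ Fc / max(len(Fc) - 1, 1)
    lam, V = np.linalg.eigh(cov)
    lam = np.maximum(lam, 0.0) + shrink * lam.mean()
    model.feature_center = center
    model.feature_whiten = V @ np.diag(1.0 / np.sqrt(lam)) @ V.T


def slices_to_matrix(slices: list[BeatSlice]) -> tuple[np.ndarray, list[str]]:
    X = np.stack([s.values for s in slices])
    return X, [s.label for s in slices]


def train(
    train_set: list[BeatSlice],
    val_set: list[BeatSlice],
    config: ExtractorConfig = ExtractorConfig(),
    hyper: EnsembleHyper = EnsembleHyper(),
    train_cfg: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> tuple[EnsembleModel, TrainLog]:
    """Jointly train extractor and per-class scorers; fully seeded.

    Scorers are initialized sequentially (scorer i from the mean of
    scorers 1..i-1 plus a small perturbation); each optimization step
    sums the per-class one-class losses over one batch per class; the
    parameters with the best validation accuracy are retained, then
    shared knowledge is removed once.
    """
    X_tr, y_tr = slices_to_matrix(train_set)
    X_va, y_va = slices_to_matrix(val_set)
    symbols = _symbol_order(y_tr)
    missing = sorted(set(y_va) - set(symbols))
    if missing:
        raise ValueError(f"validation set contains unseen classes: {missing}")

    config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(seed)
    ext = init_extractor(config)
    classifiers: list[MiniClassifier] = []
    for i, _sym in enumerate(symbols):
        clf = MiniClassifier(
            i, config.m, hyper.h1, hyper.h2, hyper.activation,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
        if i > 0:
            theta0, _ = init_from_previous([c.theta for c in classifiers], rng)
            clf.set_theta(theta0)
        classifiers.append(clf)

    model = EnsembleModel(config, ext, classifiers, hyper, tuple(symbols))
    params = list(ext.values()) if train_cfg.train_extractor else []
    for clf in classifiers:
        params += clf.param_list()
    opt = Adam(params, lr=train_cfg.lr)

    cls_idx = {sym: np.flatnonzero(np.asarray(y_tr) == sym) for sym in symbols}
    bs = train_cfg.batch_size
    log = TrainLog(tuple(symbols))
    best_acc, best_state = -1.0, None
    frozen = not train_cfg.train_extractor
    if frozen:
        F_tr = model.features_of(X_tr)
        F_va = model.features_of(X_va)
        _fit_feature_transform(model, F_tr)
        F_tr = model.transform_features(F_tr)

    for epoch in range(train_cfg.epochs):
        order = {sym: rng.permutation(cls_idx[sym]) for sym in symbols}
        n_steps = max(-(-len(cls_idx[sym]) // bs) for sym in symbols)
        ep_loss = {sym: 0.0 for sym in symbols}
        for step in range(n_steps):
            batches = {}
            for sym in symbols:
                nb = -(-len(order[sym]) // bs)
                j = step % nb
                batches[sym] = order[sym][j * bs : (j + 1) * bs]
            if frozen:
                per_class = {sym: Tensor(F_tr[batches[sym]]) for sym in symbols}
            else:
                Xb = np.concatenate([X_tr[batches[sym]] for sym in symbols])
                feats = forward_batch(Xb, config, ext)
                per_class, ofs = {}, 0
                for sym in symbols:
                    k = len(batches[sym])
                    per_class[sym] = feats[ofs : ofs + k]
                    ofs += k
            loss = None
            for i, sym in enumerate(symbols):
                mu_prev = (
                    np.mean([classifiers[j].theta for j in range(i)], axis=0)
                    if i > 0 else None
                )
                li = one_class_loss(classifiers[i], per_class[sym], hyper, mu_prev)
                ep_loss[sym] += float(li.data) / n_steps
                loss = li if loss is None else loss + li
            opt.zero_grad()
            loss.backward()
            opt.step()

        if frozen:
            preds = model.predict_features(F_va)
        else:
            preds = model.predict_slices(X_va)
        acc = 100.0 * np.mean([p == t for p, t in zip(preds, y_va)])
        log.epoch_loss.append(ep_loss)
        log.val_accuracy.append(float(acc))
        if acc > best_acc:
            best_acc = acc
            log.best_epoch = epoch
            best_state = (
                {k: t.data.copy() for k, t in ext.items()},
                [clf.theta for clf in classifiers],
            )

    if best_state is not None:
        for k, arr in best_state[0].items():
            ext[k].data = arr.copy()
        for clf, th in zip(classifiers, best_state[1]):
            clf.set_theta(th)
    if not frozen:
        _fit_feature_transform(model, model.features_of(X_tr))
    remove_shared(model)
    return model, log


# ---------------------------------------------------------------------------
# metrics


def compute_f1(pre: float, rec: float) -> float:
    """Harmonic mean of precision and recall, on the percent scale.

    Defined as 0 when both inputs are 0.
    """
    if not (0.0 <= pre <= 100.0 and 0.0 <= rec <= 100.0):
        raise ValueError("precision and recall must lie in [0, 100]")
    if pre + rec == 0.0:
        return 0.0
    return 2.0 * pre * rec / (pre + rec)


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1 (percent), accuracy and confusion.

    Confusion rows are true classes, columns predicted.  Classes with no
    predicted positives report precision 0 and are listed in
    `zero_prediction_classes`.
    """

    class_symbols: tuple[str, ...]
    confusion: np.ndarray
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    support: dict[str, int]
    zero_prediction_classes: tuple[str, ...] = ()

    def __post_init__(self):
        self.confusion = np.asarray(self.confusion, dtype=int)
        row_sums = self.confusion.sum(axis=1)
        for sym, rs in zip(self.class_symbols, row_sums):
            assert rs == self.support[sym], "confusion rows must equal supports"
        total = self.confusion.sum()
        if total:
            assert abs(self.accuracy -
                       100.0 * np.trace(self.confusion) / total) < 1e-9
        for sym in self.class_symbols:
            assert abs(self.f1[sym] -
                       compute_f1(self.precision[sym], self.recall[sym])) < 1e-9

    def to_table(self):
        """Metrics as a one-row table mirroring the usual report layout."""
        import pandas as pd

        row: dict[str, float] = {"ACC": round(self.accuracy, 1)}
        for sym in self.class_symbols:
            row[f"{sym}_Pre"] = round(self.precision[sym], 1)
            row[f"{sym}_Rec"] = round(self.recall[sym], 1)
            row[f"{sym}_F1"] = round(self.f1[sym], 1)
        return pd.DataFrame([row])

    def to_kv(self) -> dict[str, float]:
        kv = {"accuracy": self.accuracy}
        for sym in self.class_symbols:
            kv[f"precision_{sym}"] = self.precision[sym]
            kv[f"recall_{sym}"] = self.recall[sym]
            kv[f"f1_{sym}"] = self.f1[sym]
            kv[f"support_{sym}"] = self.support[sym]
        return kv


def metrics_from_confusion(
    confusion: np.ndarray, class_symbols: tuple[str, ...]
) -> MetricsReport:
    cm = np.asarray(confusion, dtype=int)
    T = len(class_symbols)
    assert cm.shape == (T, T)
    pre, rec, f1, support = {}, {}, {}, {}
    zero_pred = []
    for i, sym in enumerate(class_symbols):
        tp = cm[i, i]
        pred_pos = cm[:, i].sum()
        true_pos = cm[i, :].sum()
        if pred_pos == 0:
            zero_pred.append(sym)
        pre[sym] = 100.0 * tp / pred_pos if pred_pos else 0.0
        rec[sym] = 100.0 * tp / true_pos if true_pos else 0.0
        f1[sym] = compute_f1(pre[sym], rec[sym])
        support[sym] = int(true_pos)
    total = cm.sum()
    acc = 100.0 * np.trace(cm) / total if total else 0.0
    return MetricsReport(
        tuple(class_symbols), cm, pre, rec, f1, float(acc), support,
        tuple(zero_pred),
    )


def evaluate(model: EnsembleModel, test_set: list[BeatSlice]) -> MetricsReport:
    """Confusion matrix and percent-scale metrics over a test set."""
    if not test_set:
        raise ValueError("evaluate requires a nonempty test set")
    X, y_true = slices_to_matrix(test_set)
    y_pred = model.predict_slices(X)
    cm = confusion_matrix(y_true, y_pred, labels=list(model.class_symbols))
    return metrics_from_confusion(cm, model.class_symbols)
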