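"""Skill classification of motion time series with the residual network.

Trials arrive as 6-channel multivariate time series [x, y, t, v, a, MJ]
labelled 0 (novice), 1 (intermediate) or 2 (expert). Each series is cut
into fixed-length sliding windows; the network is trained on windows and a
trial's label is the majority vote over its windows' predictions (ties
break toward the lower label code). Evaluation follows the
leave-one-super-trial-out (LOSO) protocol: fold i holds out trial i of
every subject, the whole 5-fold procedure is repeated over several seeded
runs and the mean accuracy is reported. Per-channel z-score
standardization uses statistics of the training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import MotionSeries
from .resnet import Adam, ResNet1D, ResNetSpec, build_resnet

__all__ = [
    "MTSSample",
    "WindowedBatch",
    "TrainingConfig",
    "EvalReport",
    "TrainedClassifier",
    "LOSOResult",
    "sliding_window",
    "train_classifier",
    "predict_trial",
    "evaluate",
    "contingency_metrics",
    "loso_cross_validate",
]

LABEL_NAMES = {0: "novice", 1: "intermediate", 2: "expert"}


@dataclass
class MTSSample:
    """One trial: a MotionSeries plus its label and LOSO bookkeeping."""

    series: MotionSeries
    label: int
    subject_id: str
    trial_index: int  # 1..5

    def __post_init__(self):
        if not np.all(np.isfinite(self.series.data)):
            raise ValueError("non-finite values in motion series")
        if self.label not in (0, 1, 2):
            raise ValueError(f"label must be 0/1/2, got {self.label}")


@dataclass
class WindowedBatch:
    """Sliding windows from one or more trials, with provenance."""

    windows: np.ndarray              # (count, window_length, 6)
    labels: np.ndarray               # (count,)
    provenance: list[tuple[str, int]]  # (sample id, start index) per window

    def __len__(self) -> int:
        return len(self.windows)

    @staticmethod
    def concat(batches: Sequence["WindowedBatch"]) -> "WindowedBatch":
        keep = [b for b in batches if len(b)]
        if not keep:
            raise ValueError("no windows to concatenate")
        return WindowedBatch(
            windows=np.concatenate([b.windows for b in keep]),
            labels=np.concatenate([b.labels for b in keep]),
            provenance=[p for b in keep for p in b.provenance])


def sliding_window(sample: MTSSample, window_length: int,
                   stride: int) -> WindowedBatch:
    """Cut a trial into windows: floor((L - window) / stride) + 1 of them.

    A trial shorter than the window yields an empty batch (skipped with the
    count formula's zero); every window inherits the trial label and records
    its (sample id, start index) provenance.
    """
    if stride < 1 or window_length < 1:
        raise ValueError("window_length and stride must be >= 1")
    data = sample.series.data
    L = len(data)
    sid = f"{sample.subject_id}:{sample.trial_index}"
    if L < window_length:
        return WindowedBatch(np.empty((0, window_length, 6)),
                             np.empty(0, dtype=int), [])
    starts = range(0, L - window_length + 1, stride)
    win = np.stack([data[s:s + window_length] for s in starts])
    return WindowedBatch(windows=win,
                         labels=np.full(len(win), sample.label, dtype=int),
                         provenance=[(sid, s) for s in starts])


@dataclass
class TrainingConfig:
    """Optimization hyper-parameters (defaults follow common practice for
    this task: Adam at 1e-3, batches of 24, at most 100 epochs, five
    repeated runs)."""

    learning_rate: float = 1e-3
    batch_size: int = 24
    max_epochs: int = 100
    seed: int = 0
    runs: int = 5
    spec: ResNetSpec = field(default_factory=ResNetSpec)

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.runs) <= 0:
            raise ValueError("training config values must be positive")


@dataclass
class TrainedClassifier:
    """A fitted network plus the frozen training-fold standardization."""

    net: ResNet1D
    mean: np.ndarray  # (6,)
    std: np.ndarray   # (6,)
    loss_history: list[float]

    def standardize(self, windows: np.ndarray) -> np.ndarray:
        return (windows - self.mean) / self.std

    def predict_windows(self, windows: np.ndarray) -> np.ndarray:
        if len(windows) == 0:
            return np.empty(0, dtype=int)
        return self.net.predict(self.standardize(windows))


def train_classifier(train: WindowedBatch, cfg: TrainingConfig,
                     n_classes: Optional[int] = None) -> TrainedClassifier:
    """Train the residual network from scratch on a windowed batch.

    Standardization statistics (per-channel mean/sd over all training
    windows) are computed here and frozen into the returned classifier, so
    no test-fold information can leak into them.
    """
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise ValueError("training set must contain at least two classes")
    if n_classes is None:
        n_classes = int(classes.max()) + 1
    mean = train.windows.mean(axis=(0, 1))
    std = train.windows.std(axis=(0, 1))
    std = np.where(std < 1e-12, 1.0, std)
    X = (train.windows - mean) / std
    y = train.labels

    spec = ResNetSpec(**{**cfg.spec.__dict__, "n_classes": n_classes})
    net = build_resnet(spec, seed=cfg.seed)
    opt = Adam(net, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    losses = []
    n = len(X)
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            net.forward(X[idx], training=True)
            epoch_loss += net.loss_and_backward(y[idx]) * len(idx)
            opt.step()
        losses.append(epoch_loss / n)
    return TrainedClassifier(net=net, mean=mean, std=std, loss_history=losses)


def predict_trial(model: TrainedClassifier, sample: MTSSample,
                  window_length: int, stride: int) -> int:
    """Majority vote over the trial's window predictions (ties -> lower code)."""
    batch = sliding_window(sample, window_length, stride)
    if len(batch) == 0:
        raise ValueError(
            f"trial {sample.subject_id}:{sample.trial_index} shorter than window")
    preds = model.predict_windows(batch.windows)
    return int(np.bincount(preds).argmax())  # argmax ties -> lowest index


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def contingency_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Accuracy, precision, recall and F1 from one 2x2 contingency table."""
    total = tp + fp + fn + tn
    acc = (tp + tn) / total if total else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * rec * prec / (rec + prec) if rec + prec else 0.0
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


@dataclass
class EvalReport:
    """Confusion matrix (rows = truth) and the derived per-class metrics."""

    confusion: np.ndarray
    accuracy: float
    precision: np.ndarray      # per class, one-vs-rest
    recall: np.ndarray
    f1: np.ndarray
    undefined: np.ndarray      # flags: zero-denominator precision/recall
    n_classes: int

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }


def evaluate(predictions: Sequence[int], truths: Sequence[int],
             n_classes: Optional[int] = None) -> EvalReport:
    """Confusion matrix plus accuracy and one-vs-rest precision/recall/F1.

    Accuracy is correct / total. For each class, precision = Tp/(Tp+Fp) and
    recall = Tp/(Tp+Fn); an empty denominator reports 0 and raises the
    class's ``undefined`` flag. F1 is the harmonic mean of the two.
    """
    pred = np.asarray(predictions, dtype=int)
    true = np.asarray(truths, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("predictions and truths must have equal length")
    if pred.size == 0:
        raise ValueError("empty evaluation input")
    if n_classes is None:
        n_classes = int(max(pred.max(), true.max())) + 1
    conf = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(conf, (true, pred), 1)
    acc = float(np.trace(conf) / conf.sum())
    tp = np.diag(conf).astype(float)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    undefined = ((tp + fp) == 0) | ((tp + fn) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        rec = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec
                      / np.maximum(prec + rec, 1e-300), 0.0)
    return EvalReport(confusion=conf, accuracy=acc, precision=prec,
                      recall=rec, f1=f1, undefined=undefined,
                      n_classes=n_classes)


# --------------------------------------------------------------------------
# LOSO protocol
# --------------------------------------------------------------------------

@dataclass
class LOSOResult:
    """Per-run, per-fold reports of a leave-one-super-trial-out experiment."""

    fold_reports: list[list[EvalReport]]  # [run][fold]
    run_seeds: list[int]
    classes: int
    window_length: int
    stride: int

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([[r.accuracy for r in run] for run in self.fold_reports])

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def pooled(self) -> EvalReport:
        """Report recomputed from the summed confusion over runs and folds."""
        conf = sum(r.confusion for run in self.fold_reports for r in run)
        true, pred = [], []
        for i in range(conf.shape[0]):
            for j in range(conf.shape[1]):
                true += [i] * conf[i, j]
                pred += [j] * conf[i, j]
        return evaluate(pred, true, n_classes=conf.shape[0])

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "window_length": self.window_length,
            "stride": self.stride,
            "run_seeds": self.run_seeds,
            "mean_accuracy": self.mean_accuracy,
            "fold_accuracies": self.fold_accuracies.tolist(),
            "pooled": self.pooled.to_dict(),
            "per_fold": [[r.to_dict() for r in run]
                         for run in self.fold_reports],
        }


def _relabel_two_class(samples: list[MTSSample]) -> list[MTSSample]:
    """Drop the intermediates and map expert (2) to code 1."""
    out = []
    for s in samples:
        if s.label == 1:
            continue
        out.append(MTSSample(series=s.series, label=0 if s.label == 0 else 1,
                             subject_id=s.subject_id,
                             trial_index=s.trial_index))
    return out


def loso_cross_validate(dataset: list[MTSSample], cfg: TrainingConfig,
                        window_length: int = 90, stride: int = 30,
                        classes: int = 3,
                        trials_per_subject: int = 5) -> LOSOResult:
    """Leave-one-super-trial-out cross-validation, repeated over seeded runs.

    Fold i trains on every trial except trial i of each subject and tests on
    those held-out trials, so train and test never share a trial. With
    ``classes=2`` the intermediate class is dropped entirely and experts are
    recoded as 1. Each run draws its own seed from the master seed.
    """
    if classes == 2:
        dataset = _relabel_two_class(dataset)
    elif classes != 3:
        raise ValueError("classes must be 2 or 3")
    by_subject: dict[str, set[int]] = {}
    for s in dataset:
        by_subject.setdefault(s.subject_id, set()).add(s.trial_index)
    expected = set(range(1, trials_per_subject + 1))
    for subj, idx in by_subject.items():
        if idx != expected:
            raise ValueError(f"subject {subj} has trials {sorted(idx)}, "
                             f"expected 1..{trials_per_subject}")

    seeds = [int(ss.generate_state(1)[0] % (2 ** 31))
             for ss in np.random.SeedSequence(cfg.seed).spawn(cfg.runs)]
    fold_reports: list[list[EvalReport]] = []
    for run_seed in seeds:
        run_cfg = TrainingConfig(
            learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
            max_epochs=cfg.max_epochs, seed=run_seed, runs=1, spec=cfg.spec)
        reports = []
        for fold in range(1, trials_per_subject + 1):
            train_samples = [s for s in dataset if s.trial_index != fold]
            test_samples = [s for s in dataset if s.trial_index == fold]
            train_batch = WindowedBatch.concat(
                [sliding_window(s, window_length, stride)
                 for s in train_samples])
            model = train_classifier(train_batch, run_cfg, n_classes=classes)
            preds = [predict_trial(model, s, window_length, stride)
                     for s in test_samples]
            truths = [s.label for s in test_samples]
            reports.append(evaluate(preds, truths, n_classes=classes))
        fold_reports.append(reports)
    return LOSOResult(fold_reports=fold_reports, run_seeds=seeds,
                      classes=classes, window_length=window_length,
                      stride=stride)
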