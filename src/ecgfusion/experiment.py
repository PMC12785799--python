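"""Cross-validated training, metrics and ablation experiments.

Evaluation follows one-vs-rest confusion accounting per class: accuracy
(TP+TN)/n, sensitivity TP/(TP+FN), precision TP/(TP+FP) and the harmonic
F1, averaged as unweighted (macro) means, plus micro/macro ROC AUC and
per-class average precision.  Cross-validation is stratified by class
(k = 5 by default, not subject-wise); rebalancing runs inside each
training fold only, and early stopping monitors a 10% fold-internal
validation split so the test fold never leaks into training decisions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import fuse
from .heartbeats import detect_rpeaks, segment_beats, zscore
from .imbalance import ResampleSpec, smote_enn
from .nn.losses import FocalLossParams, focal_loss_with_grad
from .nn.model import ArchitectureSpec, LightResAttNet, build_model, softmax
from .nn.optim import Adam
from .synthetic import SyntheticRecord

logger = logging.getLogger(__name__)

ABLATION_VARIANTS = ("morl_only", "mexh_only", "sift_only", "hybrid")

#: channel index of each role in a fused image
_ROLE_INDEX = {"mexh_only": 0, "morl_only": 1, "sift_only": 2}


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 10
    seed: int = 0
    focal: FocalLossParams = field(default_factory=FocalLossParams)

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.early_stop_patience) <= 0:
            raise ValueError("training configuration values must be positive")


@dataclass
class FoldPlan:
    k: int
    assignments: np.ndarray  # record index -> fold id
    stratified: bool
    seed: int


@dataclass
class ConfusionCounts:
    """One-vs-rest per-class counts; TP+FP+FN+TN = n for every class."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    matrix: np.ndarray  # full K x K confusion matrix (rows = truth)


@dataclass
class MetricReport:
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    roc_auc_micro: float
    roc_auc_macro: float
    ap_per_class: dict[str, float]
    ap_macro: float
    undefined_recall_classes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class AblationConfig:
    variant: str = "hybrid"

    def __post_init__(self) -> None:
        if self.variant not in ABLATION_VARIANTS:
            raise ValueError(f"unknown ablation variant {self.variant!r}")

    def select(self, images: np.ndarray) -> np.ndarray:
        """Slice fused (N,128,128,3) images down to this variant's channels."""
        if self.variant == "hybrid":
            return images
        i = _ROLE_INDEX[self.variant]
        return images[..., i : i + 1]

    def n_channels(self) -> int:
        return 3 if self.variant == "hybrid" else 1


# ---------------------------------------------------------------------------
# Dataset preparation
# ---------------------------------------------------------------------------


def records_to_segments(
    records: list[SyntheticRecord], use_true_rpeaks: bool = True
) -> tuple[list, list[str]]:
    """Segment every record into z-scored beats with the record's label."""
    segments, labels = [], []
    for rec in records:
        rpeaks = rec.true_rpeaks if use_true_rpeaks else detect_rpeaks(rec.samples, rec.fs).indices
        for seg in segment_beats(rec.samples, rec.fs, rpeaks, label=rec.label):
            segments.append(zscore(seg))
            labels.append(rec.label)
    return segments, labels


def segments_to_images(segments: list) -> np.ndarray:
    """Fused (N, 128, 128, 3) float32 feature tensor."""
    return np.stack([fuse(s).channels for s in segments]).astype(np.float32)


# ---------------------------------------------------------------------------
# Folds, metrics
# ---------------------------------------------------------------------------


def build_demo_dataset(
    classes: tuple[str, ...] = ("N", "MI", "BBB"),
    n_per_class: int = 100,
    seed: int = 7,
    records_per_class: int = 12,
    duration: float = 10.0,
):
    """Scaled-down labelled feature set: denoise -> detect -> segment -> fuse.

    Generates noisy synthetic records for morphologically well-separated
    classes and runs the full feature pipeline, keeping ``n_per_class``
    beats per class.  Returns ``(images, labels)``.
    """
    from .preprocess import bandpass, wavelet_denoise
    from .synthetic import NoiseSpec, default_profiles, make_dataset

    profiles = default_profiles()
    records = make_dataset(profiles, {c: records_per_class for c in classes},
                           duration=duration, fs=128.0, noise=NoiseSpec(), seed=seed)
    segments, labels = [], []
    quota = {c: 0 for c in classes}
    for rec in records:
        x = wavelet_denoise(bandpass(rec.samples, rec.fs))
        peaks = detect_rpeaks(x, rec.fs)
        for seg in segment_beats(x, rec.fs, peaks, label=rec.label):
            if quota[rec.label] < n_per_class:
                segments.append(zscore(seg))
                labels.append(rec.label)
                quota[rec.label] += 1
    short = {c: n for c, n in quota.items() if n < n_per_class}
    if short:
        logger.warning("build_demo_dataset: classes under quota: %s", short)
    return segments_to_images(segments), np.asarray(labels)


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> FoldPlan:
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise ValueError(f"class(es) {small.tolist()} have fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, stratified=True, seed=seed)


def confusion_and_metrics(
    y_true: np.ndarray,
    y_pred_probs: np.ndarray,
    class_names: list[str] | None = None,
) -> tuple[ConfusionCounts, MetricReport]:
    """Argmax predictions -> one-vs-rest counts -> the four metrics + curves."""
    y_true = np.asarray(y_true)
    p = np.asarray(y_pred_probs, dtype=float)
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-4):
        raise ValueError("probability rows must sum to 1")
    n, k = p.shape
    names = class_names or [str(i) for i in range(k)]
    y_pred = p.argmax(axis=1)

    matrix = np.zeros((k, k), dtype=int)
    for t, q in zip(y_true, y_pred):
        matrix[t, q] += 1
    tp = np.diag(matrix).astype(int)
    fp = matrix.sum(axis=0) - tp
    fn = matrix.sum(axis=1) - tp
    tn = n - tp - fp - fn
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, matrix=matrix)

    per_class: dict[str, dict[str, float]] = {}
    undefined: list[str] = []
    for i, name in enumerate(names):
        support = tp[i] + fn[i]
        prec = tp[i] / (tp[i] + fp[i]) if tp[i] + fp[i] else 0.0
        rec = tp[i] / support if support else float("nan")
        if support == 0:
            undefined.append(name)
            logger.warning("class %r absent from y_true; recall undefined", name)
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[name] = {
            "accuracy": (tp[i] + tn[i]) / n,
            "precision": prec,
            "recall": rec,
            "f1": f1,
        }
    valid = [nm for nm in names if nm not in undefined]
    macro = {
        m: float(np.mean([per_class[nm][m] for nm in valid])) for m in
        ("accuracy", "precision", "recall", "f1")
    }

    onehot = np.eye(k)[y_true]
    present = [i for i in range(k) if onehot[:, i].any() and not onehot[:, i].all()]
    try:
        roc_micro = float(roc_auc_score(onehot.ravel(), p.ravel()))
        roc_macro = float(np.mean([roc_auc_score(onehot[:, i], p[:, i]) for i in present]))
    except ValueError:
        roc_micro = roc_macro = float("nan")
    ap = {names[i]: float(average_precision_score(onehot[:, i], p[:, i])) for i in present}
    ap_macro = float(np.mean(list(ap.values()))) if ap else float("nan")

    return counts, MetricReport(
        per_class=per_class,
        macro=macro,
        roc_auc_micro=roc_micro,
        roc_auc_macro=roc_macro,
        ap_per_class=ap,
        ap_macro=ap_macro,
        undefined_recall_classes=undefined,
    )


def report_table(report: MetricReport):
    """Per-class metric table (pandas DataFrame) with a macro-average row."""
    import pandas as pd

    rows = {name: stats for name, stats in report.per_class.items()}
    rows["Average"] = report.macro
    df = pd.DataFrame(rows).T[["accuracy", "precision", "recall", "f1"]]
    return (100.0 * df).round(2)


def plot_curves(y_true: np.ndarray, probs: np.ndarray, out_prefix: str,
                class_names: list[str] | None = None) -> list[str]:
    """Export per-class ROC and PR curves as PNGs (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import precision_recall_curve, roc_curve

    k = probs.shape[1]
    names = class_names or [str(i) for i in range(k)]
    onehot = np.eye(k)[np.asarray(y_true)]
    paths = []
    for kind in ("roc", "pr"):
        fig, ax = plt.subplots(figsize=(6, 5))
        for i, name in enumerate(names):
            if not onehot[:, i].any():
                continue
            if kind == "roc":
                xs, ys, _ = roc_curve(onehot[:, i], probs[:, i])
                ax.set_xlabel("false positive rate")
                ax.set_ylabel("true positive rate")
            else:
                ys, xs, _ = precision_recall_curve(onehot[:, i], probs[:, i])
                ax.set_xlabel("recall")
                ax.set_ylabel("precision")
            ax.plot(xs, ys, label=name, lw=1)
        ax.legend(fontsize=7)
        path = f"{out_prefix}_{kind}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def run_fold(
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    model_spec: ArchitectureSpec,
    training_config: TrainingConfig = TrainingConfig(),
) -> tuple[LightResAttNet, dict[str, list[float]]]:
    """Train one model with Adam + early stopping on validation accuracy.

    The best-validation-epoch weights are restored before returning.
    History records per-epoch train/val loss and accuracy.
    """
    Xtr, ytr = train_data
    Xval, yval = val_data
    k = model_spec.n_classes
    eye = np.eye(k, dtype=np.float32)
    model = build_model(model_spec, seed=training_config.seed)
    opt = Adam(model.params(), lr=training_config.learning_rate)
    rng = np.random.default_rng(training_config.seed)
    bs = training_config.batch_size

    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
    }
    best_acc, best_state, since_best = -1.0, None, 0
    for epoch in range(training_config.max_epochs):
        order = rng.permutation(len(Xtr))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), bs):
            sel = order[i : i + bs]
            xb, yb = Xtr[sel], ytr[sel]
            logits = model.forward(xb, training=True)
            loss, dlogits = focal_loss_with_grad(logits, eye[yb], training_config.focal)
            if not np.isfinite(loss):
                raise FloatingPointError(f"divergent loss at epoch {epoch}: {loss}")
            model.backward(dlogits)
            opt.step(model.params(), model.grads())
            ep_loss += loss * len(sel)
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
        history["train_loss"].append(ep_loss / len(Xtr))
        history["train_acc"].append(ep_correct / len(Xtr))

        pval = model.predict_proba(Xval, batch_size=bs)
        from .nn.losses import focal_loss as _fl

        history["val_loss"].append(_fl(pval, eye[yval], training_config.focal))
        val_acc = float((pval.argmax(axis=1) == yval).mean())
        history["val_acc"].append(val_acc)

        if val_acc > best_acc + 1e-12:
            best_acc, best_state, since_best = val_acc, model.get_state(), 0
        else:
            since_best += 1
            if since_best >= training_config.early_stop_patience:
                logger.info("early stop at epoch %d (best val acc %.4f)", epoch, best_acc)
                break
    if best_state is not None:
        model.set_state(best_state)
    return model, history


def run_experiment(
    images: np.ndarray,
    labels: np.ndarray,
    ablation: AblationConfig = AblationConfig("hybrid"),
    resample: ResampleSpec | None = None,
    model_spec: ArchitectureSpec | None = None,
    training: TrainingConfig = TrainingConfig(),
    n_folds: int = 5,
    max_folds: int | None = None,
    val_fraction: float = 0.1,
    class_names: list[str] | None = None,
    seed: int = 0,
    save_model: str | None = None,
):
    """Stratified k-fold evaluation of one feature-channel configuration.

    Per fold: (optional) SMOTE-ENN rebalancing of the training images,
    training with early stopping on a fold-internal validation split, then
    prediction on the held-out fold.  Confusion counts are pooled (summed)
    across the folds actually run; ``max_folds`` allows a scaled-down run.
    Returns ``(ConfusionCounts, MetricReport, histories)``.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    names = class_names or [str(c) for c in classes]
    y = np.searchsorted(classes, labels)
    X = ablation.select(np.asarray(images, dtype=np.float32))
    if model_spec is None:
        model_spec = ArchitectureSpec(
            input_shape=(128, 128, ablation.n_channels()), n_classes=len(classes)
        )

    plan = stratified_kfold(y, k=n_folds, seed=seed)
    all_probs = np.zeros((len(y), len(classes)))
    used = np.zeros(len(y), dtype=bool)
    histories = []
    for fold in range(min(n_folds, max_folds or n_folds)):
        test = plan.assignments == fold
        tr_idx = np.nonzero(~test)[0]
        rng = np.random.default_rng(seed + fold)
        rng.shuffle(tr_idx)
        n_val = max(int(round(val_fraction * len(tr_idx))), len(classes))
        val_idx, fit_idx = tr_idx[:n_val], tr_idx[n_val:]

        Xfit, yfit = X[fit_idx], y[fit_idx]
        if resample is not None and resample.apply_within_fold:
            flat = Xfit.reshape(len(Xfit), -1)
            flat_rs, yfit = smote_enn(flat, yfit, resample)
            Xfit = flat_rs.reshape(-1, *Xfit.shape[1:])
        cfg = TrainingConfig(
            learning_rate=training.learning_rate, batch_size=training.batch_size,
            max_epochs=training.max_epochs, early_stop_patience=training.early_stop_patience,
            seed=seed + fold, focal=training.focal,
        )
        model, hist = run_fold((Xfit, yfit), (X[val_idx], y[val_idx]), model_spec, cfg)
        histories.append(hist)
        all_probs[test] = model.predict_proba(X[test], batch_size=training.batch_size)
        used |= test

    if save_model is not None:
        model.save(save_model)
    counts, report = confusion_and_metrics(y[used], all_probs[used], class_names=names)
    return counts, report, histories
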