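"""Training protocol and evaluation suite.

Training follows the reference protocol: Adam (lr 1e-4 by default),
batch size 16, up to 50 epochs, early stopping on validation loss with
patience 5 and best-weight restoration, a best-model checkpoint saved on
every validation-loss improvement, and an every-epoch state checkpoint
that allows exact resume from the last completed epoch.

All per-epoch randomness (shuffling, augmentation, dropout masks) is
derived from ``SeedSequence([seed, epoch, stream])``, so an interrupted
run resumed from its epoch checkpoint replays the identical stream and —
in deterministic (single-threaded) mode — reproduces the uninterrupted
run bit for bit.

Evaluation: accuracy, per-class precision/recall/F1 from the confusion
matrix (P = TP/(TP+FP), R = TP/(TP+FN), F1 their harmonic mean, with a
return-0-and-flag convention for empty denominators), and one-vs-rest
ROC-AUC with micro and macro averaging.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _sk_auc, roc_curve as _sk_roc_curve

from . import data_pipeline as dp
from .fusion_model import LeafFusionNet, sparse_ce_loss
from .nn import Adam, recalibrate_batchnorm, seed_dropout
from .nn import tensor as T

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 50
    early_stop_patience: int = 5
    min_delta: float = 0.0
    seed: int = 0
    augment: bool = True
    checkpoint_dir: str | None = None
    restore_best: bool = True

    def __post_init__(self):
        if min(self.lr, self.batch_size, self.max_epochs, self.early_stop_patience) <= 0:
            raise ValueError("lr, batch_size, max_epochs and patience must be positive")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass
class History:
    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def append(self, **kw):
        for k, v in kw.items():
            getattr(self, k).append(v)

    def to_csv(self, path):
        import csv
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "train_acc", "val_loss", "val_acc"])
            for row in zip(self.epoch, self.train_loss, self.train_acc,
                           self.val_loss, self.val_acc):
                w.writerow(row)


def _config_hash(model_cfg: dict, train_cfg: TrainConfig) -> str:
    blob = json.dumps({"model": model_cfg, "train": asdict(train_cfg)},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_checkpoint(path: str | Path, model: LeafFusionNet, optim: Adam | None,
                    meta: dict):
    arrays = {f"model/{k}": v for k, v in model.state_dict().items()}
    if optim is not None:
        arrays.update({f"optim/{k}": v for k, v in optim.state_dict().items()})
    arrays["meta"] = np.frombuffer(
        json.dumps(meta, default=str).encode(), dtype=np.uint8)
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path, model: LeafFusionNet | None = None,
                    optim: Adam | None = None) -> dict:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if model is not None:
            model.load_state_dict(
                {k[len("model/"):]: z[k] for k in z.files if k.startswith("model/")})
        if optim is not None:
            optim.load_state_dict(
                {k[len("optim/"):]: z[k] for k in z.files if k.startswith("optim/")})
    return meta


def _augment_batch(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(X)
    for i, im in enumerate(X):
        out[i] = dp.augment(im, rng).astype(X.dtype)
    return out


def train(model: LeafFusionNet, data: dict, cfg: TrainConfig,
          resume: bool = False, interrupt_after: int | None = None,
          ) -> tuple[LeafFusionNet, History]:
    """Train ``model`` on ``data`` = {"train": (X, y), "val": (X, y)}.

    ``resume=True`` restarts from the last completed epoch recorded in the
    epoch checkpoint (``cfg.checkpoint_dir`` required, config hash must
    match).  ``interrupt_after=k`` stops after completing epoch k (1-based)
    — the hook the resume-fidelity check uses to simulate an interruption.
    """
    X_tr, y_tr = data["train"]
    X_va, y_va = data["val"]
    optim = Adam(model.parameters(), lr=cfg.lr)
    history = History()
    chash = _config_hash(model.cfg.to_dict(), cfg)
    ckdir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckdir:
        ckdir.mkdir(parents=True, exist_ok=True)
    start_epoch = 1
    best_val = np.inf
    best_state = None
    since_improve = 0

    if resume:
        if ckdir is None or not (ckdir / "last.npz").exists():
            raise FileNotFoundError("resume requested but no epoch checkpoint found")
        meta = load_checkpoint(ckdir / "last.npz", model, optim)
        if meta["config_hash"] != chash:
            raise ValueError("resume requested with an incompatible configuration "
                             f"(hash {meta['config_hash']} != {chash})")
        start_epoch = meta["epoch"] + 1
        best_val = meta["best_val"]
        since_improve = meta["since_improve"]
        for k, v in meta["history"].items():
            getattr(history, k).extend(v)
        if (ckdir / "best.npz").exists():
            with np.load(ckdir / "best.npz") as z:
                best_state = {k[len("model/"):]: z[k].copy()
                              for k in z.files if k.startswith("model/")}

    n = len(X_tr)
    for epoch in range(start_epoch, cfg.max_epochs + 1):
        t0 = time.time()
        rng_shuffle = np.random.default_rng(np.random.SeedSequence([cfg.seed, epoch, 0]))
        rng_aug = np.random.default_rng(np.random.SeedSequence([cfg.seed, epoch, 1]))
        seed_dropout(model, [cfg.seed, epoch, 2])
        perm = rng_shuffle.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, cfg.batch_size):
            sel = perm[i:i + cfg.batch_size]
            Xb, yb = X_tr[sel], y_tr[sel]
            if cfg.augment:
                Xb = _augment_batch(Xb, rng_aug)
            out = model(Xb, training=True)
            loss = T.cross_entropy_with_logits(out.logits, yb)
            optim.zero_grad()
            loss.backward()
            optim.step()
            losses.append(loss.item() * len(sel))
            correct += int((out.probs.data.argmax(1) == yb).sum())
        train_loss = float(np.sum(losses) / n)
        train_acc = correct / n

        # install exact BatchNorm inference statistics for this epoch's weights
        recalibrate_batchnorm(model, lambda xb: model(xb, training=True), X_tr,
                              batch_size=32, max_samples=512)
        probs_va = model.predict_proba(X_va, batch_size=32)
        val_loss = sparse_ce_loss(np.clip(probs_va, 1e-12, None), y_va)
        val_acc = float((probs_va.argmax(1) == y_va).mean())
        history.append(epoch=epoch, train_loss=train_loss, train_acc=train_acc,
                       val_loss=val_loss, val_acc=val_acc)
        log.info("epoch %d | train loss %.4f acc %.4f | val loss %.4f acc %.4f "
                 "| lr %.2g | %.1fs", epoch, train_loss, train_acc, val_loss,
                 val_acc, cfg.lr, time.time() - t0)

        if val_loss < best_val - cfg.min_delta:
            best_val = val_loss
            since_improve = 0
            best_state = model.state_dict()
            if ckdir:
                save_checkpoint(ckdir / "best.npz", model, None,
                                {"epoch": epoch, "val_loss": val_loss,
                                 "config_hash": chash})
        else:
            since_improve += 1

        if ckdir:
            save_checkpoint(ckdir / "last.npz", model, optim, {
                "epoch": epoch, "config_hash": chash, "seed": cfg.seed,
                "best_val": best_val, "since_improve": since_improve,
                "history": asdict(history), "model_config": model.cfg.to_dict(),
            })

        if since_improve >= cfg.early_stop_patience:
            log.info("early stopping at epoch %d (no val-loss improvement "
                     "for %d epochs)", epoch, since_improve)
            break
        if interrupt_after is not None and epoch >= interrupt_after:
            break

    if cfg.restore_best and best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


# ---------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------

def precision_recall_f1(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    """P, R, F1 from per-class counts; empty denominators yield 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, k: int) -> np.ndarray:
    """K x K integer matrix, rows = true class, cols = predicted class."""
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (np.asarray(y_true), np.asarray(y_pred)), 1)
    return cm


def per_class_metrics(cm: np.ndarray) -> dict:
    k = cm.shape[0]
    precision = np.zeros(k)
    recall = np.zeros(k)
    f1 = np.zeros(k)
    degenerate = np.zeros(k, dtype=bool)
    for c in range(k):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        precision[c], recall[c], f1[c] = precision_recall_f1(tp, fp, fn)
        degenerate[c] = (tp + fp == 0) or (tp + fn == 0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "degenerate": degenerate}


def roc_auc(scores: np.ndarray, labels: np.ndarray, mode: str = "macro",
            ) -> tuple[float, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """One-vs-rest ROC-AUC with curves.

    micro: pooled binary problem over all (sample, class) pairs;
    macro: unweighted mean of per-class AUCs (absent classes skipped with
    a warning).  Curves are (FPR, TPR) point lists per class (plus the
    pooled curve under key "micro" in micro mode).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n, k = scores.shape
    present = np.unique(labels)
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if mode == "micro":
        if len(present) < 2:
            raise ValueError("micro-averaged ROC needs at least two classes present")
        onehot = np.zeros((n, k))
        onehot[np.arange(n), labels] = 1.0
        fpr, tpr, _ = _sk_roc_curve(onehot.ravel(), scores.ravel())
        curves["micro"] = (fpr, tpr)
        return float(_sk_auc(fpr, tpr)), curves
    if mode != "macro":
        raise ValueError(f"mode must be 'micro' or 'macro', got {mode!r}")
    aucs = []
    for c in range(k):
        if c not in present or len(present) < 2 or (labels == c).all():
            log.warning("macro ROC: class %d absent or degenerate; skipped", c)
            continue
        fpr, tpr, _ = _sk_roc_curve((labels == c).astype(int), scores[:, c])
        curves[str(c)] = (fpr, tpr)
        aucs.append(_sk_auc(fpr, tpr))
    return float(np.mean(aucs)), curves


@dataclass
class EvalReport:
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    degenerate: np.ndarray
    accuracy: float
    macro_f1: float
    weighted_f1: float
    auc_micro: float
    auc_macro: float
    roc_curves: dict
    batch_loss: list[float]
    batch_acc: list[float]

    def to_json(self, path=None) -> str:
        d = {
            "accuracy": self.accuracy, "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1, "auc_micro": self.auc_micro,
            "auc_macro": self.auc_macro,
            "confusion": self.confusion.tolist(),
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "degenerate_classes": self.degenerate.tolist(),
        }
        s = json.dumps(d, indent=2)
        if path:
            Path(path).write_text(s)
        return s


def evaluate(model: LeafFusionNet, X: np.ndarray, y: np.ndarray,
             batch_size: int = 64) -> EvalReport:
    if len(X) == 0:
        raise ValueError("cannot evaluate an empty split")
    y = np.asarray(y)
    k = model.cfg.n_classes
    probs = []
    batch_loss, batch_acc = [], []
    with T.no_grad():
        for i in range(0, len(X), batch_size):
            p = model(X[i:i + batch_size], training=False).probs.data
            probs.append(p)
            yb = y[i:i + batch_size]
            batch_loss.append(sparse_ce_loss(np.clip(p, 1e-12, None), yb))
            batch_acc.append(float((p.argmax(1) == yb).mean()))
    probs = np.concatenate(probs, axis=0)
    pred = probs.argmax(1)
    cm = confusion_matrix(y, pred, k)
    pcm = per_class_metrics(cm)
    weights = cm.sum(axis=1) / cm.sum()
    auc_mi, curves_mi = roc_auc(probs, y, "micro")
    auc_ma, curves_ma = roc_auc(probs, y, "macro")
    curves = {**curves_ma, **curves_mi}
    return EvalReport(
        confusion=cm, precision=pcm["precision"], recall=pcm["recall"],
        f1=pcm["f1"], degenerate=pcm["degenerate"],
        accuracy=float((pred == y).mean()),
        macro_f1=float(pcm["f1"].mean()),
        weighted_f1=float((weights * pcm["f1"]).sum()),
        auc_micro=auc_mi, auc_macro=auc_ma, roc_curves=curves,
        batch_loss=batch_loss, batch_acc=batch_acc)
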