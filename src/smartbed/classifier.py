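"""Posture classification with a compact convolutional-recurrent network.

A multi-input ConvLSTM: each 20x10 pooled pressure grid in a short window is
embedded by a small CNN (two 3x3 valid convolutions + global average
pooling); the embedding sequence, fused with a parallel per-slat raw summary
(the 20 slat means), is consumed by an LSTM whose final hidden state feeds a
softmax over the 10 posture classes.  The network is pure numpy with
hand-written reverse-mode gradients and Adam, which keeps training
deterministic for a fixed seed and fast at the bed's 20x10 sensor geometry.

Evaluation produces a confusion matrix plus per-class and class-weighted
precision/recall/F1 via scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .preprocess import N_HOPB, SENSORS_PER_HOPB, pool_frame, split_dataset
from .synthetic import PostureLabel, _draw_body, generate_sequence

N_CLASSES = 10


@dataclass
class ClassifierConfig:
    window_length: int = 5
    conv_channels: tuple[int, int] = (8, 16)
    recurrent_units: int = 32
    n_classes: int = N_CLASSES
    learning_rate: float = 3e-3
    epochs: int = 20
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != N_CLASSES:
            raise ValueError(f"n_classes is fixed at {N_CLASSES}")
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if len(self.conv_channels) != 2 or any(c < 1 for c in self.conv_channels):
            raise ValueError("conv_channels must be two positive ints")


@dataclass
class EvalReport:
    """Confusion matrix and per-class / class-weighted metrics."""

    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    accuracy: float

    def to_frame(self):
        """Per-class rows plus a weighted-average row, as a DataFrame."""
        import pandas as pd

        rows = [
            {"posture": c, "precision": self.precision[c], "recall": self.recall[c],
             "f1": self.f1[c], "support": int(self.support[c])}
            for c in range(N_CLASSES)
        ]
        rows.append({"posture": "WA", "precision": self.weighted_precision,
                     "recall": self.weighted_recall, "f1": self.weighted_f1,
                     "support": int(self.support.sum())})
        return pd.DataFrame(rows)


# --- primitive layers (numpy autodiff by hand) ------------------------------


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, Ho*Wo) patch matrix for a valid convolution."""
    n, c, h, w = x.shape
    ho, wo = h - k + 1, w - k + 1
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i:i + ho, j:j + wo]
    return cols.reshape(n, c * k * k, ho * wo)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int], k: int = 3) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the image."""
    n, c, h, w = shape
    ho, wo = h - k + 1, w - k + 1
    dcols = dcols.reshape(n, c, k, k, ho, wo)
    dx = np.zeros(shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + ho, j:j + wo] += dcols[:, :, i, j]
    return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class ConvLSTMClassifier:
    """CNN-embedding + LSTM posture classifier over pooled-grid windows."""

    def __init__(self, config: ClassifierConfig | None = None) -> None:
        self.config = config or ClassifierConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        c1, c2 = cfg.conv_channels
        h = cfg.recurrent_units
        d_in = c2 + N_HOPB  # CNN embedding fused with the 20 slat means

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)

        self.params: dict[str, np.ndarray] = {
            "W1": he((c1, 1 * 9), 9), "b1": np.zeros(c1),
            "W2": he((c2, c1 * 9), c1 * 9), "b2": np.zeros(c2),
            "Wx": he((d_in, 4 * h), d_in), "Wh": he((h, 4 * h), h),
            "bl": np.zeros(4 * h),
            "Wo": he((h, N_CLASSES), h), "bo": np.zeros(N_CLASSES),
        }
        # forget-gate bias starts at 1 for stable early training
        self.params["bl"][h:2 * h] = 1.0
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self.loss_history: list[float] = []

    # --- forward ---------------------------------------------------------

    def _forward(self, X: np.ndarray, want_cache: bool = False):
        """X: (B, T, 20, 10) -> class probabilities (B, 10)."""
        cfg = self.config
        if X.ndim != 4 or X.shape[2:] != (N_HOPB, SENSORS_PER_HOPB):
            raise ValueError(
                f"expected windows of shape (B, T, {N_HOPB}, {SENSORS_PER_HOPB})"
            )
        B, T = X.shape[:2]
        c1, c2 = cfg.conv_channels
        H = cfg.recurrent_units
        p = self.params

        frames = X.reshape(B * T, 1, N_HOPB, SENSORS_PER_HOPB)
        cols1 = _im2col(frames)                                  # (BT, 9, 144)
        a1 = np.einsum("oc,ncl->nol", p["W1"], cols1) + p["b1"][:, None]
        r1 = np.maximum(a1, 0.0)
        r1_img = r1.reshape(B * T, c1, N_HOPB - 2, SENSORS_PER_HOPB - 2)
        cols2 = _im2col(r1_img)
        a2 = np.einsum("oc,ncl->nol", p["W2"], cols2) + p["b2"][:, None]
        r2 = np.maximum(a2, 0.0)
        emb = r2.mean(axis=2)                                    # (BT, c2)

        raw = X.mean(axis=3)                                     # (B, T, 20)
        feats = np.concatenate(
            [emb.reshape(B, T, c2), raw], axis=2)                # (B, T, d_in)

        h = np.zeros((B, H))
        c = np.zeros((B, H))
        gates_cache, h_cache, c_cache = [], [np.zeros((B, H))], [np.zeros((B, H))]
        for t in range(T):
            a = feats[:, t] @ p["Wx"] + h @ p["Wh"] + p["bl"]
            i, f, o = (_sigmoid(a[:, :H]), _sigmoid(a[:, H:2 * H]),
                       _sigmoid(a[:, 2 * H:3 * H]))
            g = np.tanh(a[:, 3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            if want_cache:
                gates_cache.append((i, f, o, g))
                h_cache.append(h)
                c_cache.append(c)

        logits = h @ p["Wo"] + p["bo"]
        probs = _softmax(logits)
        if not want_cache:
            return probs
        cache = dict(X=X, frames=frames, cols1=cols1, a1=a1, r1_img=r1_img,
                     cols2=cols2, a2=a2, r2=r2, feats=feats,
                     gates=gates_cache, hs=h_cache, cs=c_cache, probs=probs)
        return probs, cache

    # --- backward --------------------------------------------------------

    def _backward(self, cache: dict, y: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        p = self.params
        c1, c2 = cfg.conv_channels
        H = cfg.recurrent_units
        X = cache["X"]
        B, T = X.shape[:2]

        probs = cache["probs"]
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        h_last = cache["hs"][-1]
        grads["Wo"] = h_last.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)

        dh = dlogits @ p["Wo"].T
        dc = np.zeros_like(dh)
        dfeats = np.zeros_like(cache["feats"])
        for t in range(T - 1, -1, -1):
            i, f, o, g = cache["gates"][t]
            c_t, c_prev = cache["cs"][t + 1], cache["cs"][t]
            h_prev = cache["hs"][t]
            tanh_c = np.tanh(c_t)
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o),
                 dg * (1 - g ** 2)], axis=1)
            grads["Wx"] += cache["feats"][:, t].T @ da
            grads["Wh"] += h_prev.T @ da
            grads["bl"] += da.sum(axis=0)
            dfeats[:, t] = da @ p["Wx"].T
            dh = da @ p["Wh"].T
            dc = dc * f

        demb = dfeats[:, :, :c2].reshape(B * T, c2)
        # raw-summary branch has no parameters; its gradient dies at the input

        L2 = (N_HOPB - 4) * (SENSORS_PER_HOPB - 4)
        dr2 = np.repeat(demb[:, :, None] / L2, L2, axis=2)
        da2 = dr2 * (cache["a2"] > 0)
        grads["W2"] = np.einsum("nol,ncl->oc", da2, cache["cols2"])
        grads["b2"] = da2.sum(axis=(0, 2))
        dcols2 = np.einsum("oc,nol->ncl", p["W2"], da2)
        dr1 = _col2im(dcols2, cache["r1_img"].shape)
        da1 = dr1.reshape(B * T, c1, -1) * (cache["a1"] > 0)
        grads["W1"] = np.einsum("nol,ncl->oc", da1, cache["cols1"])
        grads["b1"] = da1.sum(axis=(0, 2))
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            m_hat = self._adam_m[k] / (1 - b1 ** t)
            v_hat = self._adam_v[k] / (1 - b2 ** t)
            self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    # --- public API ------------------------------------------------------

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        probs = self._forward(X)
        return float(-np.log(probs[np.arange(len(y)), y] + 1e-12).mean())

    def train(self, X: np.ndarray, y: np.ndarray,
              epochs: int | None = None) -> list[float]:
        """Minibatch Adam on cross-entropy; returns the per-epoch loss history.

        Shuffling is driven by the config seed, so two runs with the same
        seed and data produce identical loss histories.
        """
        if len(X) == 0:
            raise ValueError("training set is empty")
        y = np.asarray(y, dtype=int)
        epochs = epochs if epochs is not None else self.config.epochs
        bs = self.config.batch_size
        rng = np.random.default_rng(self.config.seed + 1)
        for _ in range(epochs):
            order = rng.permutation(len(X))
            losses = []
            for start in range(0, len(X), bs):
                idx = order[start:start + bs]
                probs, cache = self._forward(X[idx], want_cache=True)
                losses.append(
                    -np.log(probs[np.arange(len(idx)), y[idx]] + 1e-12).mean())
                self._adam_step(self._backward(cache, y[idx]))
            self.loss_history.append(float(np.mean(losses)))
        return self.loss_history

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        single = X.ndim == 3
        if single:
            X = X[None]
        probs = self._forward(np.asarray(X, dtype=float))
        return probs[0] if single else probs

    def predict(self, X: np.ndarray) -> np.ndarray | int:
        """Most probable posture index; ties break toward the lowest index."""
        probs = self.predict_proba(X)
        if probs.ndim == 1:
            return int(np.argmax(probs))
        return np.argmax(probs, axis=1)

    def save(self, path: str) -> None:
        np.savez(path, **self.params,
                 _config=np.array([self.config.window_length,
                                   *self.config.conv_channels,
                                   self.config.recurrent_units,
                                   self.config.seed]))

    @classmethod
    def load(cls, path: str) -> "ConvLSTMClassifier":
        data = np.load(path)
        wl, c1, c2, h, seed = (int(v) for v in data["_config"])
        model = cls(ClassifierConfig(window_length=wl, conv_channels=(c1, c2),
                                     recurrent_units=h, seed=seed))
        for k in model.params:
            model.params[k] = data[k]
        return model


def build_model(config: ClassifierConfig | None = None) -> ConvLSTMClassifier:
    return ConvLSTMClassifier(config)


def evaluation_report(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    """Confusion matrix plus per-class and support-weighted metrics.

    Classes absent from the test set get zero metrics with a warning and are
    excluded from the weighted averages (zero support drops out of the
    support-weighted mean by construction).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty test set")
    labels = np.arange(N_CLASSES)
    conf = confusion_matrix(y_true, y_pred, labels=labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, support = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=0)
    absent = labels[support == 0]
    if absent.size:
        warnings.warn(
            f"classes {absent.tolist()} absent from the test set; their "
            "metrics are reported as 0 and excluded from weighted averages")
    w = support / support.sum()
    return EvalReport(
        confusion=conf, precision=prec, recall=rec, f1=f1, support=support,
        weighted_precision=float((w * prec).sum()),
        weighted_recall=float((w * rec).sum()),
        weighted_f1=float((w * f1).sum()),
        accuracy=float((y_true == y_pred).mean()),
    )


def evaluate(model: ConvLSTMClassifier, X: np.ndarray, y: np.ndarray) -> EvalReport:
    if len(X) == 0:
        raise ValueError("empty test set")
    return evaluation_report(y, model.predict(np.asarray(X, dtype=float)))


def make_window_dataset(
    n_per_class: int, window_length: int = 5, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced pooled-grid windows from the synthetic generator.

    Each sample is one subject's window_length-period single-posture sequence,
    pooled frame-by-frame onto the slat grid: X (N, T, 20, 10), y (N,).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    X = np.empty((10 * n_per_class, window_length, N_HOPB, SENSORS_PER_HOPB))
    y = np.empty(10 * n_per_class, dtype=int)
    k = 0
    for cls in range(10):
        for _ in range(n_per_class):
            body = _draw_body(rng)
            frames = generate_sequence([(cls, window_length)], body,
                                       int(rng.integers(0, 2**31 - 1)))
            X[k] = np.stack([pool_frame(f).values for f in frames])
            y[k] = cls
            k += 1
    return X, y


def train_test_windows(
    n_per_class: int, window_length: int = 5, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Windows split 80/20 with the five-partition dataset splitter."""
    X, y = make_window_dataset(n_per_class, window_length, seed)
    train_idx, test_idx = split_dataset(len(X), seed=seed)
    return X[train_idx], y[train_idx], X[test_idx], y[test_idx]
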