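"""Neural text classifiers: FFNN, 1D CNN and BiLSTM over static word
embeddings, each ending in a sigmoid output head trained with binary
cross-entropy on one-hot targets (a multilabel head: predicted score vectors
are not normalized to sum to 1).

All three share the skeleton  embed → architecture body → dense(ReLU) →
dropout → K sigmoid units  and are trained with mini-batch Adam.  The
implementation is pure NumPy with hand-written backpropagation; given a seed
and single-threaded execution, initialization and training are bit-identical
across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import (Adam, bce_loss_and_grad, conv1d_backward, conv1d_forward,
                  dense_backward, dense_forward, glorot, lstm_backward,
                  lstm_forward, sigmoid)
from .features import EmbeddingMatrix, EncodedBatch

__all__ = ["NeuralModelSpec", "FfnnClassifier", "CnnClassifier",
           "BilstmClassifier", "build_model", "train", "predict"]


@dataclass(frozen=True)
class NeuralModelSpec:
    """Architecture description: ``arch`` ∈ {ffnn, cnn, bilstm} plus keyword
    arguments forwarded to the matching estimator."""

    arch: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arch not in ("ffnn", "cnn", "bilstm"):
            raise ValueError(f"unknown architecture {self.arch!r}")


def _resolve_batch(X) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, EncodedBatch):
        return X.ids, X.mask
    ids, mask = X
    return np.asarray(ids), np.asarray(mask, np.float64)


class _NeuralTextClassifier(BaseEstimator, ClassifierMixin):
    """Shared training/prediction machinery; subclasses provide the body."""

    def __init__(self, embedding=None, n_classes=None, dropout_rate=0.5,
                 epochs=10, batch_size=64, learning_rate=1e-3,
                 trainable_embedding=False, random_state=0):
        self.embedding = embedding
        self.n_classes = n_classes
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.trainable_embedding = trainable_embedding
        self.random_state = random_state

    # -- architecture hooks -------------------------------------------------
    def _init_body(self, rng, dim, n_classes, max_len) -> dict:
        raise NotImplementedError

    def _body_forward(self, x, mask, train, rng):
        """Return (features (B, F), cache)."""
        raise NotImplementedError

    def _body_backward(self, dfeat, cache):
        """Return (dx, grads dict)."""
        raise NotImplementedError

    # -- plumbing -----------------------------------------------------------
    def _embedding_table(self) -> np.ndarray:
        if self.embedding is None:
            raise ValueError("an embedding matrix is required")
        vecs = (self.embedding.vectors
                if isinstance(self.embedding, EmbeddingMatrix)
                else np.asarray(self.embedding, np.float64))
        table = np.vstack([vecs, np.zeros((1, vecs.shape[1]))])  # pad row
        return table

    def initialize(self, n_classes: int, max_len: int | None = None):
        """Allocate seeded initial weights without training."""
        if n_classes < 2:
            raise ValueError("output_units must be >= 2")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        table = self._embedding_table()
        rng = np.random.Generator(np.random.PCG64(int(self.random_state)))
        self.params_ = {"E": table.copy()}
        self.params_.update(self._init_body(rng, table.shape[1], n_classes,
                                            max_len))
        self.n_classes_ = n_classes
        self.classes_ = np.arange(n_classes)
        self.history_ = []
        self._rng = rng
        return self

    def _dropout(self, h, train, rng):
        if not train or self.dropout_rate == 0.0:
            return h, None
        keep = 1.0 - self.dropout_rate
        m = (rng.random(h.shape) < keep) / keep
        return h * m, m

    def _forward(self, ids, mask, train, rng):
        x = self.params_["E"][ids]
        feat, body_cache = self._body_forward(x, mask, train, rng)
        feat_d, drop_mask = self._dropout(feat, train, rng)
        logits = dense_forward(feat_d, self.params_["W_out"],
                               self.params_["b_out"])
        probs = sigmoid(logits)
        return probs, (ids, x, body_cache, feat_d, drop_mask)

    def _backward(self, dlogits, cache):
        ids, x, body_cache, feat_d, drop_mask = cache
        dfeat, dw_out, db_out = dense_backward(dlogits, feat_d,
                                               self.params_["W_out"])
        if drop_mask is not None:
            dfeat = dfeat * drop_mask
        dx, grads = self._body_backward(dfeat, body_cache)
        grads["W_out"] = dw_out
        grads["b_out"] = db_out
        if self.trainable_embedding and dx is not None:
            de = np.zeros_like(self.params_["E"])
            np.add.at(de, ids, dx)
            de[-1] = 0.0  # pad row stays zero
            grads["E"] = de
        return grads

    def fit(self, X, y=None, validation=None):
        """Train on an :class:`EncodedBatch` (or ``(ids, mask)`` pair).

        ``y`` may be integer labels or one-hot rows; omitted, it is taken
        from the batch's own labels.  ``validation`` is an optional
        ``(batch, y)`` pair evaluated after each epoch.
        """
        ids, mask = _resolve_batch(X)
        if y is None:
            if not (isinstance(X, EncodedBatch) and X.labels is not None):
                raise ValueError("labels are required for training")
            y1h = X.labels
        else:
            y = np.asarray(y)
            if y.ndim == 1:
                n_cls = self.n_classes or int(y.max()) + 1
                y1h = np.zeros((len(y), n_cls))
                y1h[np.arange(len(y)), y.astype(int)] = 1.0
            else:
                y1h = y.astype(np.float64)
        n_classes = self.n_classes or y1h.shape[1]
        if y1h.shape[1] != n_classes:
            raise ValueError(
                f"label dimension {y1h.shape[1]} != output units {n_classes}")
        self.initialize(n_classes, max_len=ids.shape[1])
        rng = self._rng
        opt = Adam(self.params_, lr=self.learning_rate)
        n = ids.shape[0]
        for epoch in range(int(self.epochs)):
            perm = rng.permutation(n)
            epoch_loss = 0.0
            n_correct = 0
            for start in range(0, n, self.batch_size):
                sl = perm[start:start + self.batch_size]
                probs, cache = self._forward(ids[sl], mask[sl], True, rng)
                loss, dlogits = bce_loss_and_grad(probs, y1h[sl])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}: {loss}")
                grads = self._backward(dlogits, cache)
                opt.step(grads)
                epoch_loss += loss * len(sl)
                n_correct += int(np.sum(np.argmax(probs, axis=1)
                                        == np.argmax(y1h[sl], axis=1)))
            entry = {"epoch": epoch, "train_loss": epoch_loss / n,
                     "train_acc": n_correct / n}
            if validation is not None:
                vb, vy = validation
                vp = self.predict_proba(vb)
                vy = np.asarray(vy)
                vy1h = vy if vy.ndim == 2 else np.eye(n_classes)[vy.astype(int)]
                vloss, _ = bce_loss_and_grad(vp, vy1h)
                entry["val_loss"] = vloss
                entry["val_acc"] = float(np.mean(
                    np.argmax(vp, axis=1) == np.argmax(vy1h, axis=1)))
            self.history_.append(entry)
        return self

    def predict_proba(self, X) -> np.ndarray:
        ids, mask = _resolve_batch(X)
        probs, _ = self._forward(ids, mask, False, None)
        return probs

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    @property
    def n_parameters_(self) -> int:
        skip = () if self.trainable_embedding else ("E",)
        return int(sum(v.size for k, v in self.params_.items()
                       if k not in skip))

    # -- single-file checkpoint --------------------------------------------
    def save(self, path: str) -> None:
        spec = {"class": type(self).__name__,
                "params": {k: v for k, v in self.get_params().items()
                           if k != "embedding"},
                "n_classes": self.n_classes_}
        np.savez(path, __spec__=np.frombuffer(
            json.dumps(spec).encode(), dtype=np.uint8),
            **self.params_)

    def load_weights(self, path: str):
        with np.load(path) as data:
            spec = json.loads(bytes(data["__spec__"]).decode())
            self.params_ = {k: data[k] for k in data.files if k != "__spec__"}
        self.n_classes_ = spec["n_classes"]
        self.classes_ = np.arange(self.n_classes_)
        if not hasattr(self, "history_"):
            self.history_ = []
        return self


class FfnnClassifier(_NeuralTextClassifier):
    """Feed-forward net over mask-aware mean-pooled embeddings.

    Body: mean pool → dense stack (ReLU, dropout between layers).
    """

    def __init__(self, embedding=None, hidden=(128, 64), n_classes=None,
                 dropout_rate=0.5, epochs=10, batch_size=64,
                 learning_rate=1e-3, trainable_embedding=False,
                 random_state=0):
        super().__init__(embedding, n_classes, dropout_rate, epochs,
                         batch_size, learning_rate, trainable_embedding,
                         random_state)
        self.hidden = hidden

    def _init_body(self, rng, dim, n_classes, max_len):
        params = {}
        prev = dim
        for li, h in enumerate(self.hidden):
            params[f"W{li}"] = glorot(rng, prev, h)
            params[f"b{li}"] = np.zeros(h)
            prev = h
        params["W_out"] = glorot(rng, prev, n_classes)
        params["b_out"] = np.zeros(n_classes)
        return params

    def _body_forward(self, x, mask, train, rng):
        denom = np.maximum(mask.sum(axis=1, keepdims=True), 1.0)
        pooled = (x * mask[:, :, None]).sum(axis=1) / denom
        h = pooled
        layers = []
        for li in range(len(self.hidden)):
            pre = dense_forward(h, self.params_[f"W{li}"],
                                self.params_[f"b{li}"])
            act = np.maximum(pre, 0.0)
            if li < len(self.hidden) - 1:
                act, dm = self._dropout(act, train, rng)
            else:
                dm = None
            layers.append((h, pre, dm))
            h = act
        return h, (mask, denom, x.shape, layers)

    def _body_backward(self, dfeat, cache):
        mask, denom, x_shape, layers = cache
        grads = {}
        dh = dfeat
        for li in range(len(self.hidden) - 1, -1, -1):
            inp, pre, dm = layers[li]
            if dm is not None:
                dh = dh * dm
            dh = dh * (pre > 0)
            dh, grads[f"W{li}"], grads[f"b{li}"] = dense_backward(
                dh, inp, self.params_[f"W{li}"])
        dx = (dh[:, None, :] * mask[:, :, None]) / denom[:, :, None]
        return dx, grads


class CnnClassifier(_NeuralTextClassifier):
    """1D convolutional classifier.

    Body: valid conv (ReLU) → global max pool over valid window positions →
    dense (ReLU).
    """

    def __init__(self, embedding=None, filter_count=128, kernel_size=3,
                 dense_units=64, n_classes=None, dropout_rate=0.5, epochs=10,
                 batch_size=64, learning_rate=1e-3, trainable_embedding=False,
                 random_state=0):
        super().__init__(embedding, n_classes, dropout_rate, epochs,
                         batch_size, learning_rate, trainable_embedding,
                         random_state)
        self.filter_count = filter_count
        self.kernel_size = kernel_size
        self.dense_units = dense_units

    def _init_body(self, rng, dim, n_classes, max_len):
        if max_len is not None and self.kernel_size > max_len:
            raise ValueError(
                f"kernel_size {self.kernel_size} exceeds max_len {max_len}")
        params = {
            "W_conv": glorot(rng, self.kernel_size * dim, self.filter_count),
            "b_conv": np.zeros(self.filter_count),
            "W_dense": glorot(rng, self.filter_count, self.dense_units),
            "b_dense": np.zeros(self.dense_units),
            "W_out": glorot(rng, self.dense_units, n_classes),
            "b_out": np.zeros(n_classes),
        }
        return params

    def _body_forward(self, x, mask, train, rng):
        conv, windows = conv1d_forward(x, self.params_["W_conv"],
                                       self.params_["b_conv"])
        relu = np.maximum(conv, 0.0)
        lengths = mask.sum(axis=1)
        n_valid = np.maximum(lengths - self.kernel_size + 1, 1.0)
        pos = np.arange(relu.shape[1])
        invalid = pos[None, :] >= n_valid[:, None]
        masked = np.where(invalid[:, :, None], -np.inf, relu)
        arg = np.argmax(masked, axis=1)                      # (B, F)
        pooled = np.take_along_axis(masked, arg[:, None, :], axis=1)[:, 0, :]
        pooled = np.where(np.isfinite(pooled), pooled, 0.0)
        pre = dense_forward(pooled, self.params_["W_dense"],
                            self.params_["b_dense"])
        feat = np.maximum(pre, 0.0)
        return feat, (x.shape, windows, conv, arg, pooled, pre)

    def _body_backward(self, dfeat, cache):
        x_shape, windows, conv, arg, pooled, pre = cache
        grads = {}
        dpre = dfeat * (pre > 0)
        dpool, grads["W_dense"], grads["b_dense"] = dense_backward(
            dpre, pooled, self.params_["W_dense"])
        dconv = np.zeros_like(conv)
        np.put_along_axis(dconv, arg[:, None, :], dpool[:, None, :], axis=1)
        dconv *= conv > 0
        dx, grads["W_conv"], grads["b_conv"] = conv1d_backward(
            dconv, windows, self.params_["W_conv"], x_shape)
        return dx, grads


class BilstmClassifier(_NeuralTextClassifier):
    """Bidirectional LSTM classifier.

    Body: masked LSTM run forward and backward over the sequence; the two
    final hidden states are concatenated and passed through a dense (ReLU)
    layer.
    """

    def __init__(self, embedding=None, hidden_units=64, dense_units=64,
                 n_classes=None, dropout_rate=0.5, epochs=10, batch_size=64,
                 learning_rate=1e-3, trainable_embedding=False,
                 random_state=0):
        super().__init__(embedding, n_classes, dropout_rate, epochs,
                         batch_size, learning_rate, trainable_embedding,
                         random_state)
        self.hidden_units = hidden_units
        self.dense_units = dense_units

    def _init_body(self, rng, dim, n_classes, max_len):
        h = self.hidden_units
        params = {}
        for tag in ("fw", "bw"):
            params[f"Wx_{tag}"] = glorot(rng, dim, 4 * h, (dim, 4 * h))
            params[f"Wh_{tag}"] = glorot(rng, h, 4 * h, (h, 4 * h))
            b = np.zeros(4 * h)
            b[h:2 * h] = 1.0  # forget-gate bias
            params[f"b_{tag}"] = b
        params["W_dense"] = glorot(rng, 2 * h, self.dense_units)
        params["b_dense"] = np.zeros(self.dense_units)
        params["W_out"] = glorot(rng, self.dense_units, n_classes)
        params["b_out"] = np.zeros(n_classes)
        return params

    def _body_forward(self, x, mask, train, rng):
        h_fw, cache_fw = lstm_forward(x, mask, self.params_["Wx_fw"],
                                      self.params_["Wh_fw"],
                                      self.params_["b_fw"])
        x_rev = x[:, ::-1, :]
        m_rev = mask[:, ::-1]
        h_bw, cache_bw = lstm_forward(x_rev, m_rev, self.params_["Wx_bw"],
                                      self.params_["Wh_bw"],
                                      self.params_["b_bw"])
        concat = np.concatenate([h_fw, h_bw], axis=1)
        pre = dense_forward(concat, self.params_["W_dense"],
                            self.params_["b_dense"])
        feat = np.maximum(pre, 0.0)
        return feat, (cache_fw, cache_bw, concat, pre)

    def _body_backward(self, dfeat, cache):
        cache_fw, cache_bw, concat, pre = cache
        h = self.hidden_units
        grads = {}
        dpre = dfeat * (pre > 0)
        dconcat, grads["W_dense"], grads["b_dense"] = dense_backward(
            dpre, concat, self.params_["W_dense"])
        dx_fw, grads["Wx_fw"], grads["Wh_fw"], grads["b_fw"] = lstm_backward(
            dconcat[:, :h], cache_fw, self.params_["Wx_fw"],
            self.params_["Wh_fw"])
        dx_bw, grads["Wx_bw"], grads["Wh_bw"], grads["b_bw"] = lstm_backward(
            dconcat[:, h:], cache_bw, self.params_["Wx_bw"],
            self.params_["Wh_bw"])
        dx = dx_fw + dx_bw[:, ::-1, :]
        return dx, grads


_ARCH_CLASSES = {"ffnn": FfnnClassifier, "cnn": CnnClassifier,
                 "bilstm": BilstmClassifier}


def build_model(spec: NeuralModelSpec) -> _NeuralTextClassifier:
    """Instantiate an untrained classifier from an architecture spec."""
    return _ARCH_CLASSES[spec.arch](**spec.params)


def train(model: _NeuralTextClassifier, train_batch: EncodedBatch,
          val_batch=None, epochs: int | None = None,
          batch_size: int | None = None, learning_rate: float | None = None,
          seed: int | None = None) -> _NeuralTextClassifier:
    """Functional wrapper: (re)configure and fit a classifier."""
    if epochs is not None:
        model.epochs = epochs
    if batch_size is not None:
        model.batch_size = batch_size
    if learning_rate is not None:
        model.learning_rate = learning_rate
    if seed is not None:
        model.random_state = seed
    validation = None
    if val_batch is not None:
        validation = (val_batch, np.argmax(val_batch.labels, axis=1))
    return model.fit(train_batch, validation=validation)


def predict(model: _NeuralTextClassifier, batch) -> tuple[np.ndarray, np.ndarray]:
    """Per-class sigmoid scores and argmax hard labels (ties → smallest)."""
    scores = model.predict_proba(batch)
    return scores, np.argmax(scores, axis=1)
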