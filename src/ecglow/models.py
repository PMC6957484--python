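"""Per-beat CNN and CNN+LSTM sequence classifiers with the training protocol.

The per-beat model maps the 53-point z-normalised beat plus an activity scalar
to P(low glucose): 15 length-preserving conv layers (50 filters of size 3,
batch-norm, ReLU, no pooling), a 30-unit dense layer whose activation is
concatenated with the z-scored activity, dropout 0.5, and a softmax head.
The sequence model encodes each of 200 consecutive beats with a shared
5-layer conv stack (global average pooling to a 50-vector), feeds the
sequence to an LSTM with 400 units and classifies from the final hidden
state.  Training uses Adam at 1e-4 on cross-entropy with Xavier init,
validation AUC every 100 steps and early stopping after 10 non-improving
evaluations, keeping the best-AUC snapshot.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, BatchNorm, Conv1DSame, Dense, Dropout, LSTM, ReLU, softmax, softmax_xent

FULL_PROTOCOL_MAX_STEPS = 25_000  # full-scale training cap; desk default is far smaller


@dataclass(frozen=True)
class CNNConfig:
    n_conv_layers: int = 15
    filters_per_layer: int = 50
    kernel_size: int = 3
    fc_units: int = 30
    activity_neuron: bool = True
    dropout_rate: float = 0.5
    n_classes: int = 2
    input_len: int = 53


@dataclass(frozen=True)
class CRNNConfig:
    cnn_layers: int = 5
    filters: int = 50
    kernel: int = 3
    lstm_units: int = 400
    time_steps: int = 200
    dropout_rate: float = 0.6
    batch_size: int = 30
    n_classes: int = 2
    input_len: int = 53


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-4
    batch_size: int = 200
    max_steps: int = 3000
    eval_every: int = 100
    patience: int = 10
    seed: int = 0
    auc_improvement_eps: float = 1e-6


@dataclass
class TrainingHistory:
    steps: list[int] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    best_step: int = 0
    best_auc: float = 0.0
    stopped_early: bool = False


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic (midranks for ties)."""
    from scipy.stats import rankdata

    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


class BeatCNN:
    """15-layer 1-D CNN over 53-point beats with an activity covariate."""

    architecture = "cnn"

    def __init__(self, config: CNNConfig = CNNConfig(), seed: int = 0):
        if config.kernel_size < 1 or min(config.n_conv_layers, config.filters_per_layer,
                                         config.fc_units, config.n_classes) < 1:
            raise ValueError("invalid CNN configuration")
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.filters_per_layer
        self.convs, self.bns, self.relus = [], [], []
        c_in = 1
        for _ in range(config.n_conv_layers):
            self.convs.append(Conv1DSame(c_in, c, config.kernel_size, rng))
            self.bns.append(BatchNorm(c))
            self.relus.append(ReLU())
            c_in = c
        flat = config.input_len * c
        self.fc1 = Dense(flat, config.fc_units, rng)
        self.fc1_relu = ReLU()
        head_in = config.fc_units + (1 if config.activity_neuron else 0)
        self.dropout = Dropout(config.dropout_rate)
        self.fc2 = Dense(head_in, config.n_classes, rng)
        self._dropout_rng = np.random.default_rng((seed, 7))
        self.act_mean = 0.0
        self.act_sd = 1.0
        self._last_A = None  # post-ReLU feature maps of the last conv layer

    # -- parameters / state ------------------------------------------------
    def params(self):
        out = []
        for conv, bn in zip(self.convs, self.bns):
            out += conv.params() + bn.params()
        return out + self.fc1.params() + self.fc2.params()

    def n_params(self) -> int:
        return int(sum(p.v.size for p in self.params()))

    def get_state(self) -> dict:
        return {
            "params": [p.v.copy() for p in self.params()],
            "bn": [(bn.running_mean.copy(), bn.running_var.copy()) for bn in self.bns],
            "act": (self.act_mean, self.act_sd),
        }

    def set_state(self, state: dict) -> None:
        for p, v in zip(self.params(), state["params"]):
            p.v[...] = v
        for bn, (m, v) in zip(self.bns, state["bn"]):
            bn.running_mean[...] = m
            bn.running_var[...] = v
        self.act_mean, self.act_sd = state["act"]

    # -- forward / backward ------------------------------------------------
    def _scale_act(self, activity: np.ndarray) -> np.ndarray:
        sd = self.act_sd if self.act_sd > 0 else 1.0
        return ((np.asarray(activity, dtype=np.float32) - self.act_mean) / sd)

    def forward(self, x: np.ndarray, activity: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 2 or x.shape[1] != self.config.input_len:
            raise ValueError(f"expected beats of length {self.config.input_len}")
        h = np.ascontiguousarray(x.T)[:, :, None]  # time-first (L, B, 1)
        for conv, bn, relu in zip(self.convs, self.bns, self.relus):
            h = relu.forward(bn.forward(conv.forward(h), training))
        self._last_A = h  # (L, B, C)
        B = h.shape[1]
        flat = np.ascontiguousarray(h.transpose(1, 0, 2)).reshape(B, -1)
        emb = self.fc1_relu.forward(self.fc1.forward(flat))
        self._embedding = emb
        if self.config.activity_neuron:
            z = np.concatenate([emb, self._scale_act(activity)[:, None]], axis=1)
        else:
            z = emb
        z = self.dropout.forward(z, training, self._dropout_rng)
        return self.fc2.forward(z)

    def _backward_head(self, dlogits: np.ndarray, to_feature_maps_only: bool = False):
        dz = self.dropout.backward(self.fc2.backward(dlogits))
        if self.config.activity_neuron:
            dz = dz[:, :-1]
        demb = self.fc1_relu.backward(dz)
        dflat = self.fc1.backward(demb)
        L, B, C = self._last_A.shape
        dA = dflat.reshape(B, L, C).transpose(1, 0, 2)  # back to time-first
        if to_feature_maps_only:
            return dA
        dh = np.ascontiguousarray(dA)
        for conv, bn, relu in zip(reversed(self.convs), reversed(self.bns), reversed(self.relus)):
            dh = conv.backward(bn.backward(relu.backward(dh)))
        return dh

    def loss_and_grads(self, x, activity, labels) -> float:
        logits = self.forward(x, activity, training=True)
        loss, dlogits, _ = softmax_xent(logits, labels)
        self._backward_head(dlogits)
        return loss

    # -- inference ---------------------------------------------------------
    def predict_proba(self, x, activity, batch_size: int = 1024) -> np.ndarray:
        """(n, 2) class probabilities [normal, low]; deterministic, batch-size independent."""
        x = np.asarray(x, dtype=np.float32)
        activity = np.asarray(activity, dtype=np.float32)
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size], activity[i:i + batch_size], training=False)
            out.append(softmax(logits))
        return np.concatenate(out) if out else np.empty((0, self.config.n_classes))

    def embed(self, x, activity, batch_size: int = 1024) -> np.ndarray:
        """Pre-dropout 30-unit dense activations (the learned beat embedding)."""
        x = np.asarray(x, dtype=np.float32)
        out = []
        for i in range(0, len(x), batch_size):
            self.forward(x[i:i + batch_size], np.asarray(activity)[i:i + batch_size],
                         training=False)
            out.append(self._embedding.copy())
        return np.concatenate(out) if out else np.empty((0, self.config.fc_units))

    def feature_maps_and_grads(self, x, activity, target_class: int):
        """Last-conv post-ReLU maps A and dy^c/dA for the (pre-softmax) class score."""
        x = np.asarray(x, dtype=np.float32)
        logits = self.forward(x, activity, training=False)
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        dA = self._backward_head(dlogits, to_feature_maps_only=True)
        # expose batch-first (B, L, C)
        return (np.ascontiguousarray(self._last_A.transpose(1, 0, 2)),
                np.ascontiguousarray(dA.transpose(1, 0, 2)))


class BeatCRNN:
    """Shared per-beat conv encoder + LSTM over 200-beat sequences."""

    architecture = "crnn"

    def __init__(self, config: CRNNConfig = CRNNConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.filters
        self.convs, self.bns, self.relus = [], [], []
        c_in = 1
        for _ in range(config.cnn_layers):
            self.convs.append(Conv1DSame(c_in, c, config.kernel, rng))
            self.bns.append(BatchNorm(c))
            self.relus.append(ReLU())
            c_in = c
        self.lstm = LSTM(c, config.lstm_units, rng)
        self.dropout = Dropout(config.dropout_rate)
        self.fc = Dense(config.lstm_units, config.n_classes, rng)
        self._dropout_rng = np.random.default_rng((seed, 7))

    def params(self):
        out = []
        for conv, bn in zip(self.convs, self.bns):
            out += conv.params() + bn.params()
        return out + self.lstm.params() + self.fc.params()

    def get_state(self) -> dict:
        return {
            "params": [p.v.copy() for p in self.params()],
            "bn": [(bn.running_mean.copy(), bn.running_var.copy()) for bn in self.bns],
        }

    def set_state(self, state: dict) -> None:
        for p, v in zip(self.params(), state["params"]):
            p.v[...] = v
        for bn, (m, v) in zip(self.bns, state["bn"]):
            bn.running_mean[...] = m
            bn.running_var[...] = v

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[1] != self.config.time_steps:
            raise ValueError(f"expected (batch, {self.config.time_steps}, "
                             f"{self.config.input_len}) sequences")
        B, T, L = x.shape
        h = np.ascontiguousarray(x.reshape(B * T, L).T)[:, :, None]  # (L, B*T, 1)
        for conv, bn, relu in zip(self.convs, self.bns, self.relus):
            h = relu.forward(bn.forward(conv.forward(h), training))
        self._enc_len = h.shape[0]
        enc = h.mean(axis=0)  # global average pooling -> (B*T, filters)
        seq = enc.reshape(B, T, self.config.filters)
        hT = self.lstm.forward(seq)
        z = self.dropout.forward(hT, training, self._dropout_rng)
        return self.fc.forward(z)

    def loss_and_grads(self, x, labels) -> float:
        logits = self.forward(x, training=True)
        loss, dlogits, _ = softmax_xent(logits, labels)
        dhT = self.dropout.backward(self.fc.backward(dlogits))
        dseq = self.lstm.backward(dhT)
        B, T, C = dseq.shape
        n_pos = self._enc_len
        dh = np.broadcast_to(dseq.reshape(1, B * T, C) / n_pos, (n_pos, B * T, C))
        for conv, bn, relu in zip(reversed(self.convs), reversed(self.bns), reversed(self.relus)):
            dh = conv.backward(bn.backward(relu.backward(dh)))
        return loss

    def predict_proba(self, x, batch_size: int = 16) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i:i + batch_size], training=False)))
        return np.concatenate(out) if out else np.empty((0, self.config.n_classes))


# ----------------------------------------------------------------------------
# Construction and training
# ----------------------------------------------------------------------------

def build_cnn(config: CNNConfig = CNNConfig(), seed: int = 0) -> BeatCNN:
    return BeatCNN(config, seed=seed)


def build_crnn(config: CRNNConfig = CRNNConfig(), seed: int = 0) -> BeatCRNN:
    return BeatCRNN(config, seed=seed)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    """Endless shuffled epoch iterator over indices."""
    while True:
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            if idx.size:
                yield idx


def train(detector, train_data: dict, val_data: dict,
          tcfg: TrainingConfig = TrainingConfig()) -> TrainingHistory:
    """Seeded Adam/cross-entropy loop with validation-AUC early stopping.

    ``train_data``/``val_data`` hold ``x`` (beats or sequences), integer ``y``
    (1 = low) and, for the CNN, ``act``.  The detector is left holding the
    best-validation-AUC snapshot.
    """
    y_train = np.asarray(train_data["y"])
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    if len(val_data["y"]) == 0:
        raise ValueError("validation set must be non-empty")
    is_cnn = detector.architecture == "cnn"
    if is_cnn:
        act = np.asarray(train_data["act"], dtype=np.float64)
        detector.act_mean = float(act.mean())
        detector.act_sd = float(act.std()) or 1.0

    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(detector.params(), lr=tcfg.learning_rate)
    history = TrainingHistory()
    best_state = detector.get_state()
    best_auc = -np.inf
    since_best = 0
    x = np.asarray(train_data["x"], dtype=np.float32)
    batches = _batches(len(x), tcfg.batch_size, rng)

    for step in range(1, tcfg.max_steps + 1):
        idx = next(batches)
        opt.zero_grad()
        if is_cnn:
            loss = detector.loss_and_grads(x[idx], np.asarray(train_data["act"])[idx], y_train[idx])
        else:
            loss = detector.loss_and_grads(x[idx], y_train[idx])
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at step {step}")
        opt.step()

        if step % tcfg.eval_every == 0:
            if is_cnn:
                p = detector.predict_proba(val_data["x"], val_data["act"])[:, 1]
            else:
                p = detector.predict_proba(val_data["x"])[:, 1]
            auc = _rank_auc(p, np.asarray(val_data["y"]))
            history.steps.append(step)
            history.val_auc.append(auc)
            if np.isfinite(auc) and auc > best_auc + tcfg.auc_improvement_eps:
                best_auc = auc
                best_state = detector.get_state()
                history.best_step = step
                since_best = 0
            else:
                since_best += 1
                if since_best >= tcfg.patience:
                    history.stopped_early = True
                    break

    detector.set_state(best_state)
    history.best_auc = float(best_auc) if np.isfinite(best_auc) else float("nan")
    return history


def predict(detector, x, activity=None) -> np.ndarray:
    """P(low) per input beat or segment (inference mode, deterministic)."""
    if detector.architecture == "cnn":
        return detector.predict_proba(x, activity)[:, 1]
    return detector.predict_proba(x)[:, 1]


def save_detector(detector, path) -> None:
    """Portable checkpoint: config + parameter arrays + batch-norm state."""
    import dataclasses
    import json

    state = detector.get_state()
    arrays = {f"p{i}": v for i, v in enumerate(state["params"])}
    for i, (m, v) in enumerate(state["bn"]):
        arrays[f"bnm{i}"], arrays[f"bnv{i}"] = m, v
    meta = {"architecture": detector.architecture,
            "config": dataclasses.asdict(detector.config)}
    if detector.architecture == "cnn":
        meta["act"] = list(state["act"])
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_detector(path):
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["architecture"] == "cnn":
            det = build_cnn(CNNConfig(**meta["config"]))
        else:
            det = build_crnn(CRNNConfig(**meta["config"]))
        state = {
            "params": [data[f"p{i}"] for i in range(len(det.params()))],
            "bn": [(data[f"bnm{i}"], data[f"bnv{i}"]) for i in range(len(det.bns))],
        }
        if meta["architecture"] == "cnn":
            state["act"] = tuple(meta["act"])
        det.set_state(state)
    return det
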