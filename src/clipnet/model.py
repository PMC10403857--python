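"""Sequence-to-signal profile model with additive signal/bias deconvolution.

The network maps a one-hot RNA sequence of length L to per-position
probability vectors of crosslink counts.  Architecture: a 1-D convolution
(128 filters, width 12) followed by 9 residual blocks, each a dilated
convolution (128 filters, width 6, dilation 2^i) → batch normalisation →
ReLU → dropout(0.25) with an identity skip connection.  Same padding and no
pooling keep a one-to-one correspondence between input positions and
outputs, so the trained model applies to sequences of arbitrary length.

Each output head is a transposed convolution with a single width-20 filter
producing a length-L score vector, normalised over positions into a
probability vector.  In paired mode the observed CLIP distribution is modelled
as an additive multinomial mixture

    p_total = pi * p_target + (1 - pi) * p_control,

where ``p_control`` is fit to the control library (e.g. SMInput) and ``pi``,
the mixing coefficient, is predicted from sequence via global average pooling
of the bottleneck and a single logistic unit.  Training minimises the summed
multinomial negative log-likelihoods of the observed signal counts under
``p_total`` and the control counts under ``p_control``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .autodiff import Tensor
from .genomic_io import one_hot_encode
from .nn import Adam, BatchNorm1D, Conv1D, Dense, Dropout

__all__ = [
    "ModelConfig", "TrainConfig", "CountWindow", "ProfilePrediction",
    "LossBreakdown", "multinomial_nll", "combined_loss", "ProfileNet",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters; defaults are the full-size model."""

    filters: int = 128
    first_conv_width: int = 12
    n_blocks: int = 9
    conv_width: int = 6
    dilation_base: int = 2
    dropout: float = 0.25
    head_width: int = 20
    paired: bool = True

    def __post_init__(self):
        for name in ("filters", "first_conv_width", "n_blocks", "conv_width",
                     "head_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def dilation(self, block_index: int) -> int:
        """Dilation of residual block ``block_index`` (0-based): base^(i+1)."""
        return self.dilation_base ** (block_index + 1)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.004
    max_epochs: int = 50
    early_stopping_patience: int = 10
    lr_patience: int = 6
    batch_size: int = 128
    seed: int | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.early_stopping_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class CountWindow:
    """One training instance: sequence plus observed count vectors."""

    sequence: np.ndarray          # (L, 4) one-hot
    signal_counts: np.ndarray     # (L,) CLIP counts
    control_counts: np.ndarray | None = None  # (L,) control-library counts

    @property
    def n_signal(self) -> int:
        return int(self.signal_counts.sum())

    @property
    def n_control(self) -> int | None:
        return None if self.control_counts is None else int(self.control_counts.sum())


@dataclass
class ProfilePrediction:
    """Per-position count-probability vectors for one window.

    ``p_total`` always satisfies the additive mixture identity with ``pi``;
    for a single-track model ``p_target``/``p_control``/``pi`` are None.
    """

    p_total: np.ndarray
    p_target: np.ndarray | None = None
    p_control: np.ndarray | None = None
    pi: float | None = None

    def track(self, name: str) -> np.ndarray:
        vec = {"total": self.p_total, "target": self.p_target,
               "control": self.p_control}[name]
        if vec is None:
            raise ValueError(f"track {name!r} unavailable for a single-track model")
        return vec


@dataclass(frozen=True)
class LossBreakdown:
    l_signal: float
    l_control: float

    @property
    def l_total(self) -> float:
        return self.l_signal + self.l_control


def multinomial_nll(p: np.ndarray, c: np.ndarray) -> float:
    """Multinomial negative log-likelihood −Σ c_i log p_i in nats.

    The count-only multinomial coefficient log(n!/Πc_i!) is constant in the
    model parameters and is dropped; the value is therefore 0 for an all-zero
    count vector and non-negative otherwise.
    """
    p = np.asarray(p, dtype=float)
    c = np.asarray(c, dtype=float)
    if p.shape != c.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs c {c.shape}")
    if np.any(p <= 0):
        raise ValueError("p must be strictly positive")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    return float(-(c * np.log(p)).sum())


def combined_loss(pred: ProfilePrediction, window: CountWindow) -> LossBreakdown:
    """Combined signal + control loss for one window.

    Paired mode scores the observed CLIP counts under ``p_total`` and the
    control counts under ``p_control``; a single-track model contributes no
    control term.
    """
    if pred.p_control is not None:
        if window.control_counts is None:
            raise ValueError("paired model requires control counts")
        l_sig = multinomial_nll(pred.p_total, window.signal_counts)
        l_ctl = multinomial_nll(pred.p_control, window.control_counts)
        return LossBreakdown(l_sig, l_ctl)
    return LossBreakdown(multinomial_nll(pred.p_total, window.signal_counts), 0.0)


class _Network:
    """The layer stack; forward returns log-probability tensors."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        c = config
        self.conv0 = Conv1D(4, c.filters, c.first_conv_width, rng=rng)
        self.blocks = []
        for i in range(c.n_blocks):
            conv = Conv1D(c.filters, c.filters, c.conv_width,
                          dilation=c.dilation(i), rng=rng)
            bn = BatchNorm1D(c.filters)
            drop = Dropout(c.dropout)
            self.blocks.append((conv, bn, drop))
        if c.paired:
            self.head_target = Conv1D(c.filters, 1, c.head_width, rng=rng)
            self.head_control = Conv1D(c.filters, 1, c.head_width, rng=rng)
            self.pi_dense = Dense(c.filters, 1, rng=rng)
            self._heads = [self.head_target, self.head_control]
        else:
            self.head_total = Conv1D(c.filters, 1, c.head_width, rng=rng)
            self._heads = [self.head_total]
            self.pi_dense = None

    @property
    def layers(self):
        out = [self.conv0]
        for conv, bn, _ in self.blocks:
            out.extend([conv, bn])
        out.extend(self._heads)
        if self.pi_dense is not None:
            out.append(self.pi_dense)
        return out

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def state(self):
        return [layer.state() for layer in self.layers]

    def load_state(self, states):
        for layer, st in zip(self.layers, states):
            layer.load_state(st)

    def forward(self, x: Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> dict:
        """Run the network; ``x`` is a (B, L, 4) tensor.

        Returns a dict of tensors: ``logp_target``/``logp_control``/
        ``logp_total`` (paired) or ``logp_total`` (single), plus ``pi``
        (probability) and ``bottleneck``.
        """
        L = x.shape[1]
        if L < self.config.first_conv_width:
            raise ValueError(
                f"input length {L} shorter than the first convolution width "
                f"{self.config.first_conv_width}"
            )
        h = self.conv0(x).relu()
        for conv, bn, drop in self.blocks:
            r = bn(conv(h), training).relu()
            r = drop(r, training, rng)
            h = h + r  # identity skip
        bottleneck = h
        out: dict = {"bottleneck": bottleneck}
        if self.config.paired:
            logit_t = self.head_target(h).reshape(-1, L)
            logit_c = self.head_control(h).reshape(-1, L)
            logp_t = logit_t.log_softmax(axis=1)
            logp_c = logit_c.log_softmax(axis=1)
            pooled = bottleneck.mean(axis=1)           # (B, F)
            pi_logit = self.pi_dense(pooled)           # (B, 1)
            zero = Tensor(np.zeros_like(pi_logit.data))
            log_pi = -Tensor.logaddexp(zero, -pi_logit)       # log sigmoid
            log_1mpi = -Tensor.logaddexp(zero, pi_logit)      # log (1-sigmoid)
            logp_total = Tensor.logaddexp(log_pi + logp_t, log_1mpi + logp_c)
            out.update(
                logp_target=logp_t, logp_control=logp_c, logp_total=logp_total,
                pi=pi_logit.sigmoid(), log_pi=log_pi, log_1mpi=log_1mpi,
            )
        else:
            logit = self.head_total(h).reshape(-1, L)
            out["logp_total"] = logit.log_softmax(axis=1)
        return out


def _batch_loss(out: dict, signal: np.ndarray, control: np.ndarray | None,
                paired: bool) -> Tensor:
    """Mean-per-window combined NLL, computed in log space."""
    b = signal.shape[0]
    loss = -(Tensor(signal) * out["logp_total"]).sum() * (1.0 / b)
    if paired:
        loss = loss + -(Tensor(control) * out["logp_control"]).sum() * (1.0 / b)
    return loss


class ProfileNet(BaseEstimator):
    """Scikit-learn style estimator for crosslink-profile prediction.

    Parameters mirror :class:`ModelConfig` and :class:`TrainConfig`.  ``fit``
    expects ``X`` of shape (n, L, 4) (or a list of equal-length sequences) and
    ``y`` of shape (n, L) for a single-track model or (n, L, 2) with the CLIP
    counts in channel 0 and control counts in channel 1 for a paired model.

    Examples
    --------
    >>> from clipnet.simulate import SyntheticConfig, simulate_windows
    >>> data = simulate_windows(SyntheticConfig(n_windows=64, seed=0))
    >>> net = ProfileNet(filters=16, n_blocks=2, max_epochs=2, random_state=0)
    >>> net = net.fit(data.sequences, data.stacked_counts())
    >>> net.predict(data.sequences[:4]).shape
    (4, 300)
    """

    def __init__(self, filters: int = 128, first_conv_width: int = 12,
                 n_blocks: int = 9, conv_width: int = 6, dilation_base: int = 2,
                 dropout: float = 0.25, head_width: int = 20, paired: bool = True,
                 learning_rate: float = 0.004, max_epochs: int = 50,
                 early_stopping_patience: int = 10, lr_patience: int = 6,
                 batch_size: int = 128, validation_fraction: float = 0.1,
                 length_cap: int = 100_000, random_state: int | None = None,
                 verbose: int = 0):
        self.filters = filters
        self.first_conv_width = first_conv_width
        self.n_blocks = n_blocks
        self.conv_width = conv_width
        self.dilation_base = dilation_base
        self.dropout = dropout
        self.head_width = head_width
        self.paired = paired
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.early_stopping_patience = early_stopping_patience
        self.lr_patience = lr_patience
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.length_cap = length_cap
        self.random_state = random_state
        self.verbose = verbose

    # -- plumbing ------------------------------------------------------------

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            filters=self.filters, first_conv_width=self.first_conv_width,
            n_blocks=self.n_blocks, conv_width=self.conv_width,
            dilation_base=self.dilation_base, dropout=self.dropout,
            head_width=self.head_width, paired=self.paired,
        )

    @staticmethod
    def _encode_X(X) -> np.ndarray:
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], str):
            X = np.stack([one_hot_encode(s) for s in X])
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[-1] != 4:
            raise ValueError(f"X must be (n, L, 4) one-hot, got shape {X.shape}")
        return X

    def _split_y(self, y, n, L):
        y = np.asarray(y, dtype=np.float32)
        if self.paired:
            if y.ndim != 3 or y.shape != (n, L, 2):
                raise ValueError(
                    "paired model requires y of shape (n, L, 2) "
                    "(signal counts, control counts)"
                )
            return y[..., 0], y[..., 1]
        if y.shape != (n, L):
            raise ValueError(f"y must be (n, L), got {y.shape}")
        return y, None

    def _init_network(self, rng) -> "_Network":
        return _Network(self._model_config(), rng)

    # -- training ------------------------------------------------------------

    def fit(self, X, y, validation_data=None):
        """Train with Adam, plateau LR halving and early stopping.

        ``validation_data`` is an optional ``(X_val, y_val)`` pair; when
        absent, ``validation_fraction`` of the data is held out at random.
        Training restores the best-validation-loss weights before returning.
        """
        X = self._encode_X(X)
        n, L, _ = X.shape
        signal, control = self._split_y(y, n, L)
        master = np.random.default_rng(self.random_state)
        init_rng = np.random.default_rng(master.integers(2**31))
        shuffle_rng = np.random.default_rng(master.integers(2**31))
        drop_rng = np.random.default_rng(master.integers(2**31))

        if validation_data is not None:
            Xv = self._encode_X(validation_data[0])
            sig_v, ctl_v = self._split_y(validation_data[1], Xv.shape[0], Xv.shape[1])
        else:
            idx = shuffle_rng.permutation(n)
            n_val = max(1, int(round(self.validation_fraction * n)))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            Xv, sig_v = X[val_idx], signal[val_idx]
            ctl_v = None if control is None else control[val_idx]
            X, signal = X[tr_idx], signal[tr_idx]
            control = None if control is None else control[tr_idx]
            n = len(tr_idx)
        if n == 0 or len(Xv) == 0:
            raise ValueError("both train and validation sets must be non-empty")

        net = self._init_network(init_rng)
        opt = Adam(net.params, lr=self.learning_rate)
        history = {"train_loss": [], "val_loss": [], "lr": []}
        best_val = np.inf
        best_state = net.state()
        best_epoch = 0
        since_improve = 0
        since_lr_drop = 0

        for epoch in range(1, self.max_epochs + 1):
            order = shuffle_rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for lo in range(0, n, self.batch_size):
                sel = order[lo: lo + self.batch_size]
                out = net.forward(Tensor(X[sel]), training=True, rng=drop_rng)
                loss = _batch_loss(out, signal[sel],
                                   None if control is None else control[sel],
                                   self.paired)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "training aborted (try a lower learning rate)"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            val_loss = self._eval_loss(net, Xv, sig_v, ctl_v)
            history["train_loss"].append(epoch_loss / max(n_batches, 1))
            history["val_loss"].append(val_loss)
            history["lr"].append(opt.lr)
            if self.verbose:
                print(f"epoch {epoch:3d}  train {history['train_loss'][-1]:.4f}  "
                      f"val {val_loss:.4f}  lr {opt.lr:.2e}")
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_state = net.state()
                best_epoch = epoch
                since_improve = 0
                since_lr_drop = 0
            else:
                since_improve += 1
                since_lr_drop += 1
                if since_improve >= self.early_stopping_patience:
                    break
                if since_lr_drop >= self.lr_patience:
                    opt.lr *= 0.5
                    since_lr_drop = 0

        net.load_state(best_state)
        self.network_ = net
        self.config_ = self._model_config()
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.n_epochs_ = len(history["train_loss"])
        self.n_features_in_ = 4
        return self

    def _eval_loss(self, net, X, signal, control) -> float:
        total = 0.0
        n = len(X)
        for lo in range(0, n, self.batch_size):
            sel = slice(lo, lo + self.batch_size)
            out = net.forward(Tensor(X[sel]), training=False)
            b = X[sel].shape[0]
            loss = _batch_loss(out, signal[sel],
                               None if control is None else control[sel],
                               self.paired)
            total += float(loss.data) * b
        return total / n

    # -- inference -----------------------------------------------------------

    def _forward_eval(self, X: np.ndarray) -> dict:
        """Inference forward pass returning float64 numpy log-probabilities."""
        check_is_fitted(self, "network_")
        if X.shape[1] > self.length_cap:
            raise ValueError(
                f"input length {X.shape[1]} exceeds length_cap "
                f"({self.length_cap}); raise the cap explicitly if intended"
            )
        net_out = self.network_.forward(Tensor(X), training=False)
        result = {}
        if self.paired:
            # renormalise in float64 so probability sums are exact to ~1e-15
            logp_t = _log_softmax64(net_out["logp_target"].data)
            logp_c = _log_softmax64(net_out["logp_control"].data)
            pi = net_out["pi"].data.astype(np.float64).reshape(-1, 1)
            p_t = np.exp(logp_t)
            p_c = np.exp(logp_c)
            result.update(
                p_target=p_t, p_control=p_c,
                p_total=pi * p_t + (1.0 - pi) * p_c, pi=pi.reshape(-1),
            )
        else:
            p = np.exp(_log_softmax64(net_out["logp_total"].data))
            result.update(p_total=p)
        return result

    def predict(self, X) -> np.ndarray:
        """Predicted total-track probability vectors, shape (n, L)."""
        X = self._encode_X(X)
        parts = []
        for lo in range(0, len(X), self.batch_size):
            parts.append(self._forward_eval(X[lo: lo + self.batch_size])["p_total"])
        return np.concatenate(parts) if parts else np.empty((0, X.shape[1]))

    def predict_profiles(self, X) -> list[ProfilePrediction]:
        """Per-window :class:`ProfilePrediction` objects."""
        X = self._encode_X(X)
        preds: list[ProfilePrediction] = []
        for lo in range(0, len(X), self.batch_size):
            out = self._forward_eval(X[lo: lo + self.batch_size])
            for i in range(out["p_total"].shape[0]):
                if self.paired:
                    preds.append(ProfilePrediction(
                        p_total=out["p_total"][i], p_target=out["p_target"][i],
                        p_control=out["p_control"][i], pi=float(out["pi"][i]),
                    ))
                else:
                    preds.append(ProfilePrediction(p_total=out["p_total"][i]))
        return preds

    def predict_profile(self, sequence) -> ProfilePrediction:
        """Predict one window; accepts a string or a (L, 4) one-hot matrix."""
        if isinstance(sequence, str):
            X = one_hot_encode(sequence)[None]
        else:
            X = np.asarray(sequence, dtype=np.float32)[None]
        return self.predict_profiles(X)[0]

    def predict_pi(self, X) -> np.ndarray:
        """Predicted mixing coefficients, shape (n,); paired models only."""
        if not self.paired:
            raise ValueError("mixing coefficient undefined for single-track model")
        X = self._encode_X(X)
        parts = []
        for lo in range(0, len(X), self.batch_size):
            parts.append(self._forward_eval(X[lo: lo + self.batch_size])["pi"])
        return np.concatenate(parts)

    # -- persistence ---------------------------------------------------------

    def save(self, path, manifest: dict | None = None) -> None:
        """Save weights + configuration (+ optional run manifest) to one file."""
        check_is_fitted(self, "network_")
        flat = {}
        for li, layer_state in enumerate(self.network_.state()):
            for ai, arr in enumerate(layer_state):
                flat[f"layer{li}_{ai}"] = arr
        meta = {"params": self.get_params(), "manifest": manifest or {}}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **flat)

    @classmethod
    def load(cls, path) -> "ProfileNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            est = cls(**meta["params"])
            net = est._init_network(np.random.default_rng(0))
            states = []
            for li, layer in enumerate(net.layers):
                n_arrays = len(layer.state())
                states.append([data[f"layer{li}_{ai}"] for ai in range(n_arrays)])
            net.load_state(states)
        est.network_ = net
        est.config_ = est._model_config()
        est.history_ = {"train_loss": [], "val_loss": [], "lr": []}
        est.n_features_in_ = 4
        return est


def _log_softmax64(logits: np.ndarray) -> np.ndarray:
    z = logits.astype(np.float64)
    z = z - z.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))
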