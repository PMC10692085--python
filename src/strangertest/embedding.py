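"""Movement-space embedding via a 1-D convolutional autoencoder.

The encoder is a fixed layer sequence: convolution (window 3,
same padding) -> ReLU -> dropout (p = 0.1) -> max-pooling (window 2);
the decoder mirrors it (upsample-by-repeat -> convolution back to the
4 input channels).  Training minimizes mean-absolute-error
reconstruction loss with Adam; hyperparameters (number of filters,
learning rate) are chosen by grid search on a held-out validation
split.  Each trial's "movement space" vector is the flattened encoder
output, of length ``floor(m_time / 2) * n_filters``.

Implemented directly in numpy (forward and backward passes are a few
einsums) so training is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .trajio import TrajectoryDataset

#: architecture constants fixed by design: conv window, dropout rate,
#: pool window
CONV_WINDOW = 3
DROPOUT_P = 0.1
POOL_WINDOW = 2


@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture + training hyperparameters.

    ``conv_window``, ``dropout_p`` and ``pool_window`` are part of the
    method definition and rejected if changed, unless
    ``allow_override=True``.
    """

    input_length: int
    input_channels: int = 4
    conv_window: int = CONV_WINDOW
    dropout_p: float = DROPOUT_P
    pool_window: int = POOL_WINDOW
    n_filters: int = 8
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 200
    patience: int = 20
    seed: int = 0
    allow_override: bool = False

    def __post_init__(self) -> None:
        if self.input_length < 4:
            raise ValueError("input_length must be >= 4")
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if not self.allow_override:
            if self.conv_window != CONV_WINDOW:
                raise ValueError(
                    f"conv_window is fixed at {CONV_WINDOW}; set allow_override to change it")
            if self.dropout_p != DROPOUT_P:
                raise ValueError(
                    f"dropout_p is fixed at {DROPOUT_P}; set allow_override to change it")
            if self.pool_window != POOL_WINDOW:
                raise ValueError(
                    f"pool_window is fixed at {POOL_WINDOW}; set allow_override to change it")

    @property
    def latent_time(self) -> int:
        return self.input_length // self.pool_window

    @property
    def latent_length(self) -> int:
        """Flattened embedding length per trial."""
        return self.latent_time * self.n_filters


@dataclass
class Autoencoder:
    """Parameterized model: weights plus the per-channel standardization."""

    spec: AutoencoderSpec
    W_enc: np.ndarray  # (n_filters, channels, window)
    b_enc: np.ndarray  # (n_filters,)
    W_dec: np.ndarray  # (channels, n_filters, window)
    b_dec: np.ndarray  # (channels,)
    channel_mean: np.ndarray  # (channels,)
    channel_sd: np.ndarray    # (channels,)
    log: pd.DataFrame | None = None

    def parameters(self) -> list[np.ndarray]:
        return [self.W_enc, self.b_enc, self.W_dec, self.b_dec]

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    def save(self, path) -> None:
        doc = {
            "spec": {k: getattr(self.spec, k) for k in (
                "input_length", "input_channels", "conv_window", "dropout_p",
                "pool_window", "n_filters", "learning_rate", "batch_size",
                "epochs", "patience", "seed", "allow_override")},
            "weights": {
                "W_enc": self.W_enc.tolist(), "b_enc": self.b_enc.tolist(),
                "W_dec": self.W_dec.tolist(), "b_dec": self.b_dec.tolist(),
            },
            "channel_mean": self.channel_mean.tolist(),
            "channel_sd": self.channel_sd.tolist(),
            "log": None if self.log is None else self.log.to_dict("list"),
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path) -> "Autoencoder":
        doc = json.loads(Path(path).read_text())
        w = doc["weights"]
        return cls(
            spec=AutoencoderSpec(**doc["spec"]),
            W_enc=np.array(w["W_enc"]), b_enc=np.array(w["b_enc"]),
            W_dec=np.array(w["W_dec"]), b_dec=np.array(w["b_dec"]),
            channel_mean=np.array(doc["channel_mean"]),
            channel_sd=np.array(doc["channel_sd"]),
            log=None if doc["log"] is None else pd.DataFrame(doc["log"]),
        )


def build_autoencoder(spec: AutoencoderSpec) -> Autoencoder:
    """Initialize a model (Glorot-uniform weights) from a spec."""
    rng = np.random.default_rng(spec.seed)
    c, f, k = spec.input_channels, spec.n_filters, spec.conv_window
    lim_e = np.sqrt(6.0 / (c * k + f * k))
    lim_d = np.sqrt(6.0 / (f * k + c * k))
    return Autoencoder(
        spec=spec,
        W_enc=rng.uniform(-lim_e, lim_e, size=(f, c, k)),
        b_enc=np.zeros(f),
        W_dec=rng.uniform(-lim_d, lim_d, size=(c, f, k)),
        b_dec=np.zeros(c),
        channel_mean=np.zeros(c),
        channel_sd=np.ones(c),
    )


def _conv_same(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded 1-D convolution.  X: (B,C,M), W: (F,C,K) -> (B,F,M)."""
    k = W.shape[2]
    pad = k // 2
    Xp = np.pad(X, ((0, 0), (0, 0), (pad, pad)))
    Xw = sliding_window_view(Xp, k, axis=2)  # (B, C, M, K)
    return np.einsum("bcmk,fck->bfm", Xw, W, optimize=True) + b[None, :, None], Xw


def _conv_same_backward(dH, Xw, W, M):
    dW = np.einsum("bcmk,bfm->fck", Xw, dH, optimize=True)
    db = dH.sum(axis=(0, 2))
    k = W.shape[2]
    pad = k // 2
    B, C = Xw.shape[0], Xw.shape[1]
    dXp = np.zeros((B, C, M + 2 * pad))
    for j in range(k):
        dXp[:, :, j:j + M] += np.einsum("bfm,fc->bcm", dH, W[:, :, j], optimize=True)
    return dXp[:, :, pad:pad + M], dW, db


def _forward(model: Autoencoder, Xz: np.ndarray, train: bool,
             rng: np.random.Generator | None = None):
    """Full forward pass on standardized input Xz (B, C, M)."""
    spec = model.spec
    M = Xz.shape[2]
    L = M // spec.pool_window
    H, Xw = _conv_same(Xz, model.W_enc, model.b_enc)
    A = np.maximum(H, 0.0)
    if train and spec.dropout_p > 0:
        mask = (rng.random(A.shape) >= spec.dropout_p) / (1.0 - spec.dropout_p)
        A = A * mask
    else:
        mask = None
    A2 = A[:, :, :L * spec.pool_window].reshape(A.shape[0], A.shape[1], L, spec.pool_window)
    P = A2.max(axis=3)
    arg = A2.argmax(axis=3)
    U = np.repeat(P, spec.pool_window, axis=2)
    if U.shape[2] < M:  # odd input length: repeat final column
        U = np.concatenate([U, np.repeat(U[:, :, -1:], M - U.shape[2], axis=2)], axis=2)
    Y, Uw = _conv_same(U, model.W_dec, model.b_dec)
    cache = {"Xw": Xw, "H": H, "mask": mask, "arg": arg, "Uw": Uw,
             "L": L, "M": M, "P_shape": P.shape}
    return Y, P, cache


def _backward(model: Autoencoder, dY: np.ndarray, cache: dict):
    spec = model.spec
    M, L = cache["M"], cache["L"]
    dU, dW_dec, db_dec = _conv_same_backward(dY, cache["Uw"], model.W_dec, M)
    core = L * spec.pool_window
    dP = dU[:, :, :core].reshape(dU.shape[0], dU.shape[1], L, spec.pool_window).sum(axis=3)
    if core < M:
        dP[:, :, -1] += dU[:, :, core:].sum(axis=2)
    dA2 = np.zeros((dP.shape[0], dP.shape[1], L, spec.pool_window))
    np.put_along_axis(dA2, cache["arg"][..., None], dP[..., None], axis=3)
    dA = np.zeros_like(cache["H"])
    dA[:, :, :core] = dA2.reshape(dP.shape[0], dP.shape[1], core)
    if cache["mask"] is not None:
        dA = dA * cache["mask"]
    dH = dA * (cache["H"] > 0)
    _, dW_enc, db_enc = _conv_same_backward(dH, cache["Xw"], model.W_enc, M)
    return [dW_enc, db_enc, dW_dec, db_dec]


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _mae_original_units(model: Autoencoder, Xz: np.ndarray) -> float:
    """Reconstruction MAE in meters (inverse of the z-scoring)."""
    Y, _, _ = _forward(model, Xz, train=False)
    sd = model.channel_sd[None, :, None]
    return float(np.mean(np.abs(Y - Xz) * sd))


DEFAULT_GRID = tuple(
    {"n_filters": f, "learning_rate": lr} for f in (4, 8, 16) for lr in (1e-3, 1e-4)
)


def _as_channels(data) -> np.ndarray:
    if isinstance(data, TrajectoryDataset):
        return data.as_channels()
    X = np.asarray(data, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected (n_trials, channels, m_time) array")
    return X


def train_autoencoder(
    data,
    grid=None,
    seed: int = 0,
    val_fraction: float = 0.25,
    epochs: int = 200,
    batch_size: int = 8,
    patience: int = 20,
) -> tuple[Autoencoder, pd.DataFrame]:
    """Grid-search + train the autoencoder on a trajectory dataset.

    Inputs are z-scored per channel across the whole cohort; each grid
    point trains with Adam on MAE reconstruction loss with early
    stopping on a 25%-by-trial validation split; the grid point with
    the lowest validation MAE (original units) wins.  Fully
    deterministic given ``seed``.  Returns the winning model and a log
    with one row per (grid point, epoch).
    """
    X = _as_channels(data)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 trials for a train/validation split")
    if grid is None:
        grid = DEFAULT_GRID
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")

    mean = X.mean(axis=(0, 2))
    sd = X.std(axis=(0, 2))
    sd = np.where(sd < 1e-12, 1.0, sd)
    Xz = (X - mean[None, :, None]) / sd[None, :, None]

    split_rng = np.random.default_rng(seed)
    perm = split_rng.permutation(n)
    n_val = max(int(round(n * val_fraction)), 1)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xtr, Xval = Xz[train_idx], Xz[val_idx]

    best = None
    rows = []
    for gi, point in enumerate(grid):
        spec = AutoencoderSpec(
            input_length=X.shape[2], input_channels=X.shape[1],
            n_filters=int(point["n_filters"]),
            learning_rate=float(point["learning_rate"]),
            batch_size=batch_size, epochs=epochs, patience=patience, seed=seed)
        model = build_autoencoder(spec)
        model.channel_mean, model.channel_sd = mean.copy(), sd.copy()
        rng = np.random.default_rng([seed, gi])
        opt = _Adam(model.parameters(), spec.learning_rate)
        sdw = sd[None, :, None]

        best_val, best_weights, best_epoch, stale = np.inf, None, -1, 0
        for epoch in range(epochs):
            order = rng.permutation(len(Xtr))
            train_maes = []
            for start in range(0, len(order), batch_size):
                batch = Xtr[order[start:start + batch_size]]
                Y, _, cache = _forward(model, batch, train=True, rng=rng)
                err = Y - batch
                train_maes.append(float(np.mean(np.abs(err) * sdw)))
                dY = np.sign(err) / err.size
                opt.step(_backward(model, dY, cache))
            val_mae = _mae_original_units(model, Xval)
            rows.append({"grid_point": gi, "n_filters": spec.n_filters,
                         "learning_rate": spec.learning_rate, "epoch": epoch,
                         "train_mae": float(np.mean(train_maes)),
                         "val_mae": val_mae})
            if val_mae < best_val - 1e-9:
                best_val = val_mae
                best_weights = [p.copy() for p in model.parameters()]
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
        model.W_enc, model.b_enc, model.W_dec, model.b_dec = best_weights
        if best is None or best_val < best[0]:
            best = (best_val, gi, model, best_epoch)

    log = pd.DataFrame(rows)
    _, gi, model, best_epoch = best
    log.attrs["selected_grid_point"] = gi
    log.attrs["selected_epoch"] = best_epoch
    model.log = log
    return model, log


@dataclass
class MovementEmbedding:
    """Per-trial movement-space vectors (flattened encoder output)."""

    trial_ids: list[str]
    vectors: np.ndarray  # (n, latent_length)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.vectors,
                          columns=[f"z{i}" for i in range(self.vectors.shape[1])])
        df.insert(0, "trial_id", self.trial_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MovementEmbedding":
        cols = [c for c in df.columns if c != "trial_id"]
        return cls(trial_ids=list(df["trial_id"]),
                   vectors=df[cols].to_numpy(dtype=float))


def encode(model: Autoencoder, data, trial_ids: list[str] | None = None) -> MovementEmbedding:
    """Map trials into movement space (encoder only, dropout inactive)."""
    X = _as_channels(data)
    if X.shape[2] != model.spec.input_length:
        raise ValueError(
            f"input length {X.shape[2]} != model input_length {model.spec.input_length}")
    if trial_ids is None:
        trial_ids = (data.trial_ids if isinstance(data, TrajectoryDataset)
                     else [f"trial{i:03d}" for i in range(X.shape[0])])
    Xz = (X - model.channel_mean[None, :, None]) / model.channel_sd[None, :, None]
    _, P, _ = _forward(model, Xz, train=False)
    return MovementEmbedding(trial_ids=list(trial_ids),
                             vectors=P.reshape(P.shape[0], -1))
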