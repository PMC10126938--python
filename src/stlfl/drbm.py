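"""Hybrid discriminative restricted Boltzmann machine for P300 scoring.

The model is an RBM with a class layer: visible units x (the STLFL features,
real-valued, z-scored and modeled as Gaussian with unit variance), binary
hidden units h, and a one-hot class unit y over K=2 classes (P300 vs
non-P300).  Energy:

    E(x, y, h) = ||x - b||^2 / 2 - c'h - d_y - x'Wh - h'U[y]

Because the hidden units are conditionally independent, the class posterior
is available in closed form,

    p(y|x)  propto  exp(d_y) * prod_j (1 + exp(c_j + U_yj + W[:,j]'x)),

so the discriminative objective -sum log p(y|x) has an exact gradient.  The
hybrid objective adds a generative term,  L = L_disc + gamma * L_gen,  with
L_gen = -sum log p(x, y) approximated by contrastive divergence (CD-k):
one (or k) Gibbs sweep(s) h -> (x, y) -> h from the data configuration.
Training is plain seeded mini-batch gradient descent.

Class index 0 corresponds to label 1 (P300); index 1 to label 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import TARGET_LABEL


@dataclass(frozen=True)
class DrbmTrainConfig:
    """Training hyperparameters; the seed fixes init, batch order and CD noise."""

    seed: int
    learning_rate: float = 0.05
    n_epochs: int = 500
    batch_size: int = 32
    generative_weight: float = 0.01
    cd_steps: int = 1
    weight_init_sd: float = 0.01

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.weight_init_sd) <= 0:
            raise ValueError("learning_rate and weight_init_sd must be positive")
        if min(self.n_epochs, self.batch_size, self.cd_steps) < 1:
            raise ValueError("n_epochs, batch_size and cd_steps must be >= 1")
        if self.generative_weight < 0:
            raise ValueError("generative_weight must be >= 0")


@dataclass
class DrbmModel:
    Wvh: np.ndarray  # (d, H)
    Uyh: np.ndarray  # (K, H)
    b_v: np.ndarray  # (d,)
    c_h: np.ndarray  # (H,)
    d_y: np.ndarray  # (K,)
    feat_mean: np.ndarray  # z-scoring of inputs
    feat_sd: np.ndarray
    loss_trace: list = field(default_factory=list)

    @property
    def n_hidden(self) -> int:
        return self.Wvh.shape[1]

    @property
    def n_classes(self) -> int:
        return self.Uyh.shape[0]

    def standardize(self, features: np.ndarray) -> np.ndarray:
        return (features - self.feat_mean) / self.feat_sd


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _class_log_scores(model: DrbmModel, x: np.ndarray) -> np.ndarray:
    """Unnormalized log p(y|x): (n, K).  x already standardized."""
    # activations a[n, k, j] = c_j + U_kj + (x W)_nj
    act = model.c_h[None, None, :] + model.Uyh[None, :, :] \
        + (x @ model.Wvh)[:, None, :]
    return model.d_y[None, :] + _softplus(act).sum(axis=2)


def posterior(model: DrbmModel, features: np.ndarray) -> np.ndarray:
    """Exact class posterior p(y|x), rows summing to 1.

    Computed in log space from the closed form above; column 0 is the P300
    class.  Features are standardized with the model's stored scaler.
    """
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if features.shape[1] != model.Wvh.shape[0]:
        raise ValueError(
            f"expected {model.Wvh.shape[0]} features, got {features.shape[1]}"
        )
    if not np.isfinite(model.Wvh).all():
        raise ValueError("model parameters are not finite")
    log_s = _class_log_scores(model, model.standardize(features))
    log_s -= log_s.max(axis=1, keepdims=True)
    p = np.exp(log_s)
    return p / p.sum(axis=1, keepdims=True)


def _disc_grads(model: DrbmModel, x: np.ndarray, y: np.ndarray):
    """Exact gradient of mean log p(y|x) w.r.t. (Wvh, Uyh, c_h, d_y).

    x standardized, y class indices.  Returns gradients for ascent.
    """
    n, _ = x.shape
    k = model.n_classes
    act = model.c_h[None, None, :] + model.Uyh[None, :, :] \
        + (x @ model.Wvh)[:, None, :]  # (n, K, H)
    s = _sigmoid(act)
    log_s = model.d_y[None, :] + _softplus(act).sum(axis=2)
    log_s -= log_s.max(axis=1, keepdims=True)
    p = np.exp(log_s)
    p /= p.sum(axis=1, keepdims=True)  # (n, K)

    onehot = np.zeros((n, k))
    onehot[np.arange(n), y] = 1.0
    s_y = s[np.arange(n), y, :]  # (n, H)
    s_exp = np.einsum("nk,nkh->nh", p, s)  # posterior-averaged activations

    g_d = (onehot - p).mean(axis=0)
    g_u = np.einsum("nk,nkh->kh", onehot, s) / n - np.einsum("nk,nkh->kh", p, s) / n
    g_w = x.T @ (s_y - s_exp) / n
    g_c = (s_y - s_exp).mean(axis=0)
    return g_w, g_u, g_c, g_d


def _cd_grads(model: DrbmModel, x: np.ndarray, y: np.ndarray, k_steps: int,
              rng: np.random.Generator):
    """CD-k gradient of mean log p(x, y) (ascent direction), Gaussian visibles."""
    n = x.shape[0]
    k = model.n_classes
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y] = 1.0

    h_data = _sigmoid(model.c_h + x @ model.Wvh + onehot @ model.Uyh)
    xk, yk, hk = x, onehot, h_data
    for _ in range(k_steps):
        h_samp = (rng.random(hk.shape) < hk).astype(np.float64)
        xk = model.b_v + h_samp @ model.Wvh.T \
            + rng.standard_normal((n, x.shape[1]))
        logits = model.d_y[None, :] + h_samp @ model.Uyh.T
        logits -= logits.max(axis=1, keepdims=True)
        py = np.exp(logits)
        py /= py.sum(axis=1, keepdims=True)
        draw = (rng.random(n)[:, None] < np.cumsum(py, axis=1)).argmax(axis=1)
        yk = np.zeros((n, k))
        yk[np.arange(n), draw] = 1.0
        hk = _sigmoid(model.c_h + xk @ model.Wvh + yk @ model.Uyh)

    g_w = (x.T @ h_data - xk.T @ hk) / n
    g_u = (onehot.T @ h_data - yk.T @ hk) / n
    g_c = (h_data - hk).mean(axis=0)
    g_d = (onehot - yk).mean(axis=0)
    g_b = (x - xk).mean(axis=0)
    return g_w, g_u, g_c, g_d, g_b


def fit_drbm(features: np.ndarray, labels: np.ndarray,
             config: DrbmTrainConfig, n_hidden: int = 5) -> DrbmModel:
    """Train the hybrid DRBM by seeded mini-batch gradient descent.

    Minimizes ``-sum log p(y|x) - gamma * sum log p(x, y)``: the
    discriminative part with its exact gradient, the generative part with
    CD-k.  Inputs are z-scored internally; the default of five hidden units
    matches the small feature dimension (h^2 = 16) coming out of STLFL.
    Raises if the loss diverges, naming the offending training epoch.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    y = np.where(labels == TARGET_LABEL, 0, 1)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    n, d = features.shape
    mean = features.mean(axis=0)
    sd = features.std(axis=0)
    sd[sd < 1e-12] = 1.0

    rng = np.random.default_rng(config.seed)
    model = DrbmModel(
        Wvh=rng.normal(0.0, config.weight_init_sd, size=(d, n_hidden)),
        Uyh=rng.normal(0.0, config.weight_init_sd, size=(2, n_hidden)),
        b_v=np.zeros(d),
        c_h=np.zeros(n_hidden),
        d_y=np.zeros(2),
        feat_mean=mean,
        feat_sd=sd,
    )
    x_all = (features - mean) / sd
    lr, gamma = config.learning_rate, config.generative_weight

    for epoch in range(config.n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_all[idx], y[idx]
            g_w, g_u, g_c, g_d = _disc_grads(model, xb, yb)
            g_b = np.zeros(d)
            if gamma > 0:
                c_w, c_u, c_c, c_d, c_b = _cd_grads(model, xb, yb,
                                                    config.cd_steps, rng)
                g_w = g_w + gamma * c_w
                g_u = g_u + gamma * c_u
                g_c = g_c + gamma * c_c
                g_d = g_d + gamma * c_d
                g_b = gamma * c_b
            model.Wvh += lr * g_w
            model.Uyh += lr * g_u
            model.c_h += lr * g_c
            model.d_y += lr * g_d
            model.b_v += lr * g_b
        log_s = _class_log_scores(model, x_all)
        norm = np.logaddexp.reduce(log_s, axis=1)
        loss = float(-(log_s[np.arange(n), y] - norm).mean())
        if not np.isfinite(loss):
            raise RuntimeError(f"DRBM training diverged at epoch {epoch}")
        model.loss_trace.append(loss)
    return model


def score_p300(model: DrbmModel, features: np.ndarray) -> np.ndarray:
    """Per-epoch probability that the epoch contains a P300 (in (0, 1))."""
    return posterior(model, features)[:, 0]
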