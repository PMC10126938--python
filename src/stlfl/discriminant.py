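"""Linear feature learning (LFL) and its bilinear spatial-temporal extension.

The classic Fisher linear discriminant maximizes the ratio of between-class
to within-class scatter,

    J(w) = (w' S_B w) / (w' S_W w).

LFL modifies the numerator two ways: the between-class scatter is split per
class around the grand mean, S_BN = S_b1 + alpha * S_b2 with
S_bi = (m_i - m)(m_i - m)', and a within-class penalty is subtracted,

    J_LFL(w) = (w' (S_BN - beta * S_W) w) / (w' S_W w),

solved as the generalized eigenproblem (S_BN - beta S_W) w = lambda S_W w.
alpha reweights the non-target class's between term (class 1 = P300 keeps
weight 1) and beta trades off within-class spread inside the numerator.

The spatial-temporal version (STLFL) learns a spatial projection W (C x h)
and temporal projection V (T x h) for epochs X (C x T) by alternating the
same eigenproblem over the two modes.  With V fixed the spatial pencil is
built from the C x T difference matrices sandwiching V V':

    S_BN^(V) = sum_i alpha_i (m_i - m) V V' (m_i - m)',
    S_W^(V)  = < (X_n - m_class(n)) V V' (X_n - m_class(n))' >_n,

and symmetrically (transposed differences, W W') for the temporal step.
Iteration starts from V = the first h columns of the identity and stops when
both ||W - W_prev||_2 and ||V - V_prev||_2 fall below ``tol`` (after
deterministic sign alignment) or ``max_iter`` is reached.  Features are
f = vec(W' X V), vectorized column-major, of dimension h^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sp_linalg

from .epochs import EpochSet, TARGET_LABEL


@dataclass
class ScatterSet:
    """Class means and unreduced difference matrices of an epoch set.

    ``Db1``/``Db2`` are the per-class between-class differences ``m_i - m``;
    ``Dw`` stacks the within-class differences ``X_n - m_class(n)``.  Outer
    products are formed later, per projection step, so both the spatial and
    temporal pencils can be built from the same object.
    """

    m1: np.ndarray
    m2: np.ndarray
    m: np.ndarray
    Db1: np.ndarray
    Db2: np.ndarray
    Dw: np.ndarray  # (n_epochs, C, T)


@dataclass
class StlflModel:
    W: np.ndarray  # (C, h) spatial projection
    V: np.ndarray  # (T, h) temporal projection
    alpha: float
    beta: float
    h: int
    eigvals_spatial: np.ndarray
    eigvals_temporal: np.ndarray
    n_iter: int
    converged: bool
    ridge_eps: float
    convergence_trace: list  # [(||dW||_2, ||dV||_2), ...]


@dataclass
class FeatureSet:
    features: np.ndarray  # (n, h*h)
    labels: np.ndarray
    provenance: tuple  # (alpha, beta, h)


def compute_scatters(epochs: EpochSet) -> ScatterSet:
    """Class means, grand mean and difference matrices (label 1 = P300)."""
    mask1 = epochs.labels == TARGET_LABEL
    if mask1.all() or not mask1.any():
        raise ValueError("both classes must be present")
    x = epochs.data
    m1 = x[mask1].mean(axis=0)
    m2 = x[~mask1].mean(axis=0)
    m = x.mean(axis=0)
    dw = np.where(mask1[:, None, None], x - m1, x - m2)
    return ScatterSet(m1=m1, m2=m2, m=m, Db1=m1 - m, Db2=m2 - m, Dw=dw)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (deterministic sign)."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def lfl_direction(SB_N: np.ndarray, SW: np.ndarray, beta: float, h: int,
                  ridge_eps: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Solve (S_BN - beta S_W) w = lambda (S_W + eps I) w for the top-h pairs.

    Returns ``(directions, eigenvalues)`` with directions as columns, unit
    2-norm, deterministic sign (largest-|entry| positive), ordered by
    descending algebraic eigenvalue (ties keep original index order).
    """
    SB_N = np.asarray(SB_N, dtype=np.float64)
    SW = np.asarray(SW, dtype=np.float64)
    d = SB_N.shape[0]
    if SB_N.shape != (d, d) or SW.shape != (d, d):
        raise ValueError("SB_N and SW must be square with matching dimension")
    for name, mat in (("SB_N", SB_N), ("SW", SW)):
        scale = max(1.0, np.abs(mat).max())
        if np.abs(mat - mat.T).max() > 1e-8 * scale:
            raise ValueError(f"{name} is not symmetric")
    if not 1 <= h <= d:
        raise ValueError(f"h must be in 1..{d}")
    lhs = 0.5 * ((SB_N - beta * SW) + (SB_N - beta * SW).T)
    rhs = 0.5 * (SW + SW.T) + ridge_eps * np.eye(d)
    evals, evecs = sp_linalg.eigh(lhs, rhs)
    order = np.argsort(-evals, kind="stable")[:h]
    vecs = evecs[:, order]
    vecs = vecs / np.linalg.norm(vecs, axis=0, keepdims=True)
    return _fix_signs(vecs), evals[order]


def _pencil(scat: ScatterSet, proj: np.ndarray, alpha: float,
            spatial: bool) -> tuple[np.ndarray, np.ndarray]:
    """Build (S_BN, S_W) over one mode, the other mode compressed by `proj`."""
    if spatial:
        b1, b2, dw = scat.Db1 @ proj, scat.Db2 @ proj, scat.Dw @ proj
    else:
        b1, b2 = scat.Db1.T @ proj, scat.Db2.T @ proj
        dw = np.einsum("nct,ch->nth", scat.Dw, proj)
    sb = b1 @ b1.T + alpha * (b2 @ b2.T)
    sw = np.einsum("nah,nbh->ab", dw, dw) / len(dw)
    return sb, sw


def fit_stlfl(epochs: EpochSet, alpha: float = 1.0, beta: float = 0.0,
              h: int = 4, tol: float = 1e-5, max_iter: int = 500,
              ridge_scale: float = 1e-6, seed: int | None = None) -> StlflModel:
    """Fit the bilinear spatial-temporal projections by alternating eigensolves.

    Parameters
    ----------
    alpha, beta:
        LFL hyperparameters (alpha reweights the non-target between-class
        term; beta penalizes within-class scatter in the numerator).
    h:
        Projection rank; features have dimension ``h**2``.  Default 4.
    tol, max_iter:
        Convergence: both projection updates' spectral norms below ``tol``
        (default 1e-5), or ``max_iter`` (default 500) iterations.
    ridge_scale:
        Each pencil's right-hand side gets a ridge
        ``ridge_scale * trace(S_W) / d`` so rank-deficient within-class
        scatter (n_epochs < C*T) stays solvable.
    seed:
        Accepted for interface uniformity; the fit is deterministic and the
        value is unused.

    Returns a :class:`StlflModel` with the convergence trace recorded.
    """
    del seed
    if np.isnan(epochs.data).any():
        raise ValueError("epoch data contains NaN")
    c, t = epochs.n_channels, epochs.n_times
    if not 1 <= h <= min(c, t):
        raise ValueError(f"h must be in 1..min(C, T) = {min(c, t)}")
    scat = compute_scatters(epochs)

    v = np.eye(t)[:, :h]
    w = np.zeros((c, h))
    ev_s = ev_t = np.zeros(h)
    trace: list[tuple[float, float]] = []
    converged = False
    n_iter = 0
    eps_used = 0.0
    for n_iter in range(1, max_iter + 1):
        sb_s, sw_s = _pencil(scat, v, alpha, spatial=True)
        eps_s = ridge_scale * np.trace(sw_s) / c
        w_new, ev_s = lfl_direction(sb_s, sw_s, beta, h, ridge_eps=eps_s)

        sb_t, sw_t = _pencil(scat, w_new, alpha, spatial=False)
        eps_t = ridge_scale * np.trace(sw_t) / t
        v_new, ev_t = lfl_direction(sb_t, sw_t, beta, h, ridge_eps=eps_t)

        dw_norm = np.linalg.norm(w_new - w, 2)
        dv_norm = np.linalg.norm(v_new - v, 2)
        trace.append((float(dw_norm), float(dv_norm)))
        w, v = w_new, v_new
        eps_used = eps_s
        if dw_norm < tol and dv_norm < tol:
            converged = True
            break

    return StlflModel(W=w, V=v, alpha=alpha, beta=beta, h=h,
                      eigvals_spatial=ev_s, eigvals_temporal=ev_t,
                      n_iter=n_iter, converged=converged,
                      ridge_eps=float(eps_used), convergence_trace=trace)


def transform(model: StlflModel, epochs: EpochSet) -> FeatureSet:
    """Project epochs to ``vec(W' X V)`` features (column-major vec)."""
    c, t = epochs.n_channels, epochs.n_times
    if model.W.shape[0] != c or model.V.shape[0] != t:
        raise ValueError(
            f"model expects (C, T) = ({model.W.shape[0]}, {model.V.shape[0]}), "
            f"epochs have ({c}, {t})"
        )
    proj = np.einsum("ch,nct,tk->nhk", model.W, epochs.data, model.V)
    feats = proj.transpose(0, 2, 1).reshape(epochs.n_epochs, -1)  # column-major vec
    return FeatureSet(features=feats, labels=epochs.labels.copy(),
                      provenance=(model.alpha, model.beta, model.h))


def fit_fld_baseline(epochs: EpochSet, ridge_scale: float = 1e-6) -> np.ndarray:
    """Classic Fisher discriminant on vectorized epochs (the RAW+LDA-style scorer).

    Solves (S_W + eps I) w = (m1 - m2) on the C*T-dimensional vectorized
    data — the top eigenvector of the Fisher pencil for a rank-one
    between-class scatter — and orients w so target epochs project higher.
    The ridge handles singular S_W (always the case when n < C*T).
    """
    mask1 = epochs.labels == TARGET_LABEL
    if mask1.all() or not mask1.any():
        raise ValueError("both classes must be present")
    x = epochs.data.reshape(epochs.n_epochs, -1)
    m1 = x[mask1].mean(axis=0)
    m2 = x[~mask1].mean(axis=0)
    xc = np.where(mask1[:, None], x - m1, x - m2)
    sw = xc.T @ xc
    eps = ridge_scale * np.trace(sw) / sw.shape[0]
    if eps == 0:
        eps = ridge_scale
    w = sp_linalg.solve(sw + eps * np.eye(sw.shape[0]), m1 - m2,
                        assume_a="pos")
    w /= np.linalg.norm(w)
    if (m1 - m2) @ w < 0:  # orient toward the P300 class
        w = -w
    return w


def fld_scores(direction: np.ndarray, epochs: EpochSet) -> np.ndarray:
    """Project vectorized epochs onto a Fisher direction."""
    return epochs.data.reshape(epochs.n_epochs, -1) @ direction
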