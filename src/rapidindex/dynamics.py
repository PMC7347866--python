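"""Windowed vector-autoregressive models and model dissimilarities.

Each conditioned window is summarised by a VAR(p) model
``x_t = c + A_1 x_{t-1} + ... + A_p x_{t-p} + e_t``, ``e_t ~ N(0, Sigma)``,
fitted by least squares.  The model captures how a patient's channels
interact over the window; a cohort of such models is compared through a
dissimilarity between their Gaussian one-step predictive distributions,
evaluated over a shared set of reference windows and symmetrised:

    d(m1, m2) = 1/2 [ KL(N1 || N2) + KL(N2 || N1) ]   (averaged over
                reference lag vectors)

This is a pseudo-metric (non-negative, symmetric, zero on identical
models); the triangle inequality is *not* claimed — symmetrised KL does
not satisfy it in general.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: ridge jitter applied to a rank-deficient regressor Gram matrix,
#: relative to its mean diagonal
RIDGE_JITTER = 1e-6
#: jitter applied to a singular residual covariance, relative to trace/k
COV_JITTER = 1e-6


@dataclass(frozen=True)
class DynamicsModel:
    """A fitted VAR(p): lag matrices, intercept and residual covariance."""

    coeffs: np.ndarray  # (p, k, k); coeffs[i] multiplies x_{t-1-i}
    intercept: np.ndarray  # (k,)
    sigma: np.ndarray  # (k, k) symmetric PSD
    session_id: str = ""
    start_minute: int = -1

    def __post_init__(self) -> None:
        p, k, k2 = self.coeffs.shape
        if p < 1 or k != k2:
            raise ValueError("coeffs must be (p, k, k) with p >= 1")
        if self.intercept.shape != (k,) or self.sigma.shape != (k, k):
            raise ValueError("intercept/sigma shape mismatch")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("sigma must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() < -1e-8:
            raise ValueError("sigma must be PSD")

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def predict(self, history: np.ndarray) -> np.ndarray:
        """One-step conditional mean given ``history`` (last row = most recent).

        ``history`` is (p, k) or (n, p, k) with lag 1 at the last row.
        """
        h = np.asarray(history, dtype=float)
        single = h.ndim == 2
        if single:
            h = h[None]
        p = self.order
        mu = np.broadcast_to(self.intercept, (len(h), self.n_channels)).copy()
        for i in range(p):
            mu += h[:, p - 1 - i, :] @ self.coeffs[i].T
        return mu[0] if single else mu


def _design(values: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Lagged regression design: Y = rows t >= p, X = [1, x_{t-1}, ..., x_{t-p}]."""
    T, k = values.shape
    Y = values[p:]
    X = np.ones((T - p, 1 + k * p))
    for i in range(p):
        X[:, 1 + i * k : 1 + (i + 1) * k] = values[p - 1 - i : T - 1 - i]
    return Y, X


def fit_var(values: np.ndarray, order: int = 2, *, session_id: str = "", start_minute: int = -1) -> DynamicsModel:
    """Least-squares VAR(p) fit to one window (rows = minutes).

    A rank-deficient regressor matrix (constant input, short window)
    falls back to ridge regression with a small stated jitter and warns.
    The residual covariance is the one-step residual second moment.
    """
    values = np.asarray(values, dtype=float)
    T, k = values.shape
    if T <= order + 1:
        raise ValueError(f"window length {T} too short for VAR({order})")
    Y, X = _design(values, order)
    G = X.T @ X
    d = G.shape[0]
    eig = np.linalg.eigvalsh(G)
    if eig[0] <= 1e-10 * max(eig[-1], 1.0):
        warnings.warn("rank-deficient regressor matrix; ridge fallback", stacklevel=2)
        G = G + RIDGE_JITTER * max(np.trace(G) / d, 1.0) * np.eye(d)
    B = np.linalg.solve(G, X.T @ Y)  # (1 + kp, k)
    resid = Y - X @ B
    sigma = resid.T @ resid / len(Y)
    sigma = 0.5 * (sigma + sigma.T)
    coeffs = np.stack([B[1 + i * k : 1 + (i + 1) * k].T for i in range(order)])
    return DynamicsModel(
        coeffs=coeffs,
        intercept=B[0],
        sigma=sigma,
        session_id=session_id,
        start_minute=start_minute,
    )


def fit_var_batch(windows: np.ndarray, order: int = 2) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched VAR(p) fit over a (n, L, k) stack of windows.

    Returns ``(coeffs (n,p,k,k), intercepts (n,k), sigmas (n,k,k))``;
    degenerate windows get the same ridge fallback as :func:`fit_var`
    (without the per-window warning).
    """
    n, T, k = windows.shape
    if T <= order + 1:
        raise ValueError(f"window length {T} too short for VAR({order})")
    p = order
    Y = windows[:, p:, :]
    X = np.ones((n, T - p, 1 + k * p))
    for i in range(p):
        X[:, :, 1 + i * k : 1 + (i + 1) * k] = windows[:, p - 1 - i : T - 1 - i, :]
    G = np.einsum("nti,ntj->nij", X, X)
    d = G.shape[-1]
    eig = np.linalg.eigvalsh(G)
    bad = eig[:, 0] <= 1e-10 * np.maximum(eig[:, -1], 1.0)
    if bad.any():
        tr = np.einsum("nii->n", G)[bad]
        G[bad] += (RIDGE_JITTER * np.maximum(tr / d, 1.0))[:, None, None] * np.eye(d)
    B = np.linalg.solve(G, np.einsum("nti,ntj->nij", X, Y))
    resid = Y - np.einsum("nti,nij->ntj", X, B)
    sigmas = np.einsum("nti,ntj->nij", resid, resid) / (T - p)
    sigmas = 0.5 * (sigmas + sigmas.transpose(0, 2, 1))
    coeffs = np.stack(
        [B[:, 1 + i * k : 1 + (i + 1) * k, :].transpose(0, 2, 1) for i in range(p)], axis=1
    )
    return coeffs, B[:, 0, :], sigmas


def one_step_residuals(model: DynamicsModel, values: np.ndarray) -> tuple[np.ndarray, float]:
    """Residuals of a model's one-step predictions on a window.

    Returns ``(residuals (T-p, k), mean squared residual)`` where the MSR
    is the mean over time of the squared residual norm — equal to
    ``trace(Sigma)`` when the model is applied to its own training window.
    """
    values = np.asarray(values, dtype=float)
    p = model.order
    if len(values) <= p:
        raise ValueError("window shorter than model order")
    Y, X = _design(values, p)
    B = np.concatenate(
        [model.intercept[None, :], np.concatenate([A.T for A in model.coeffs], axis=0)]
    )
    resid = Y - X @ B
    return resid, float(np.mean(np.sum(resid**2, axis=1)))


def _safe_cov(sigma: np.ndarray, warn: bool = True) -> np.ndarray:
    """Regularize a singular covariance with the stated relative jitter."""
    k = sigma.shape[0]
    eig = np.linalg.eigvalsh(sigma)
    if eig[0] <= 1e-12 * max(eig[-1], 1.0):
        if warn:
            warnings.warn("singular residual covariance; regularizing", stacklevel=3)
        sigma = sigma + COV_JITTER * max(np.trace(sigma) / k, 1e-12) * np.eye(k)
    return sigma


def gaussian_kl(mu1: np.ndarray, s1: np.ndarray, mu2: np.ndarray, s2: np.ndarray) -> float:
    """KL(N(mu1, s1) || N(mu2, s2)) in closed form."""
    k = len(mu1)
    s1 = _safe_cov(np.asarray(s1, dtype=float), warn=False)
    s2 = _safe_cov(np.asarray(s2, dtype=float), warn=False)
    s2_inv = np.linalg.inv(s2)
    diff = np.asarray(mu2, dtype=float) - np.asarray(mu1, dtype=float)
    _, ld1 = np.linalg.slogdet(s1)
    _, ld2 = np.linalg.slogdet(s2)
    return 0.5 * float(np.trace(s2_inv @ s1) + diff @ s2_inv @ diff - k + ld2 - ld1)


def _lag_vectors(reference: np.ndarray | list[np.ndarray], p: int) -> np.ndarray:
    """Stack all (p, k) lag histories available in the reference windows."""
    if isinstance(reference, np.ndarray) and reference.ndim == 2:
        reference = [reference]
    hists = []
    for win in reference:
        win = np.asarray(win, dtype=float)
        for t in range(p, len(win) + 1):
            hists.append(win[t - p : t])
    if not hists:
        raise ValueError("reference windows shorter than model order")
    return np.stack(hists)


def model_dissimilarity(
    m1: DynamicsModel,
    m2: DynamicsModel,
    reference_windows: np.ndarray | list[np.ndarray],
) -> float:
    """Symmetrised Gaussian KL between one-step predictive distributions.

    For each lag history in the shared reference windows both models give
    a Gaussian prediction; the two KL divergences are averaged over
    histories and symmetrised (mean of the two directions).
    """
    if m1.order != m2.order or m1.n_channels != m2.n_channels:
        raise ValueError("models must share order and channel layout")
    k = m1.n_channels
    s1 = _safe_cov(m1.sigma)
    s2 = _safe_cov(m2.sigma)
    s1_inv = np.linalg.inv(s1)
    s2_inv = np.linalg.inv(s2)
    _, ld1 = np.linalg.slogdet(s1)
    _, ld2 = np.linalg.slogdet(s2)
    const_12 = 0.5 * (np.trace(s2_inv @ s1) - k + ld2 - ld1)
    const_21 = 0.5 * (np.trace(s1_inv @ s2) - k + ld1 - ld2)

    hists = _lag_vectors(reference_windows, m1.order)
    diff = m2.predict(hists) - m1.predict(hists)  # (n, k)
    quad_12 = 0.5 * np.mean(np.einsum("ni,ij,nj->n", diff, s2_inv, diff))
    quad_21 = 0.5 * np.mean(np.einsum("ni,ij,nj->n", diff, s1_inv, diff))
    kl12 = const_12 + quad_12
    kl21 = const_21 + quad_21
    return float(0.5 * (kl12 + kl21))


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric non-negative dissimilarities with zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("diagonal must be zero")
        if (v < -1e-10).any():
            raise ValueError("dissimilarities must be non-negative")


def build_dissimilarity_matrix(
    models: list[DynamicsModel],
    reference_windows: np.ndarray | list[np.ndarray],
) -> DissimilarityMatrix:
    """Pairwise symmetrised-KL dissimilarity matrix over a model cohort.

    Vectorized over pairs by precomputing each model's predictions on the
    shared lag histories; agrees with pairwise :func:`model_dissimilarity`.
    """
    n = len(models)
    if n < 2:
        raise ValueError("need at least two models")
    p, k = models[0].order, models[0].n_channels
    hists = _lag_vectors(reference_windows, p)
    preds = np.stack([m.predict(hists) for m in models])  # (n, H, k)
    sigmas = np.stack([_safe_cov(m.sigma) for m in models])
    invs = np.linalg.inv(sigmas)
    lds = np.linalg.slogdet(sigmas)[1]

    values = np.zeros((n, n))
    for i in range(n):
        diff = preds - preds[i]  # (n, H, k)
        # KL(i || j): trace(S_j^-1 S_i) + quad under S_j^-1
        tr_ij = np.einsum("jab,ba->j", invs, sigmas[i])
        quad_ij = np.einsum("jha,jab,jhb->j", diff, invs, diff) / diff.shape[1]
        kl_i_to_all = 0.5 * (tr_ij - k + lds - lds[i] + quad_ij)
        values[i] = kl_i_to_all
    sym = 0.5 * (values + values.T)
    np.fill_diagonal(sym, 0.0)
    sym = np.maximum(sym, 0.0)
    ids = tuple(m.session_id + f"@{m.start_minute}" if m.session_id else f"m{i}" for i, m in enumerate(models))
    return DissimilarityMatrix(ids=ids, values=sym)
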