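"""NeuroScale-style topographic projection with metric-tensor queries.

A radial-basis-function network maps model-descriptor vectors to a 2-D
visualisation space, trained to preserve a supplied dissimilarity
structure by minimising the Sammon-type stress

    S(W) = sum_{i<j} ( d_ij - || y_i - y_j || )^2 ,   y = Phi(x) W ,

where Phi holds Gaussian basis responses (plus a bias).  Unlike plain
multidimensional scaling, the trained network is a *function*: new
descriptors project out-of-sample, and the map's Jacobian gives a local
metric tensor G = J J^T whose magnification factor sqrt(det G) measures
how the map stretches or collapses descriptor space at a point — the
geometric signal used by the surprise index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .dynamics import DynamicsModel, DissimilarityMatrix


#: lower clip on the singular values of (I - sum A_i) when converting the
#: VAR between intercept and mean form; near-unit-root window fits would
#: otherwise send the implied level to infinity
_MEAN_FORM_CLIP = 0.05


def _lag_sum(model: DynamicsModel) -> np.ndarray:
    return np.eye(model.n_channels) - model.coeffs.sum(axis=0)


def _implied_mean(model: DynamicsModel) -> np.ndarray:
    """Stationary level mu solving (I - sum A_i) mu = c, clipped-stable."""
    M = _lag_sum(model)
    u, s, vt = np.linalg.svd(M)
    s = np.maximum(s, _MEAN_FORM_CLIP)
    return vt.T @ ((u.T @ model.intercept) / s)


def descriptor(model: DynamicsModel) -> np.ndarray:
    """Flatten a VAR model into a fixed-length numeric vector.

    Layout: lag matrices row-major, the model's location parameter, then
    the lower triangle of the Cholesky factor of Sigma (positive
    diagonal).  Length ``k^2 p + k + k(k+1)/2`` (27 for three channels at
    order 2).

    The location slot stores the *mean-form* parameter mu (the stationary
    level implied by intercept and lag matrices) rather than the raw
    intercept: for persistent vital signs the intercept c = (I - sum A) mu
    attenuates level differences between patients by an order of
    magnitude, whereas mu carries them at full scale — which is what makes
    one patient's model comparable to another's in descriptor space.  The
    map is injective up to the Cholesky sign convention and the
    singular-value clip on near-unit-root fits.
    """
    k = model.n_channels
    sigma = model.sigma
    eig_min = np.linalg.eigvalsh(sigma)[0]
    if eig_min < 1e-12:
        sigma = sigma + (1e-12 - min(eig_min, 0.0) + 1e-12) * np.eye(k)
    L = np.linalg.cholesky(sigma)
    tril = L[np.tril_indices(k)]
    return np.concatenate([model.coeffs.ravel(), _implied_mean(model), tril])


def model_from_descriptor(vec: np.ndarray, order: int, n_channels: int) -> DynamicsModel:
    """Inverse of :func:`descriptor` (round-trip reconstruction).

    Exact whenever the lag-matrix sum is safely away from a unit root
    (the singular-value clip untouched).
    """
    k = n_channels
    n_coef = k * k * order
    coeffs = vec[:n_coef].reshape(order, k, k)
    mu = vec[n_coef : n_coef + k]
    intercept = (np.eye(k) - coeffs.sum(axis=0)) @ mu
    L = np.zeros((k, k))
    L[np.tril_indices(k)] = vec[n_coef + k :]
    return DynamicsModel(coeffs=coeffs.copy(), intercept=intercept.copy(), sigma=L @ L.T)


@dataclass(frozen=True)
class NeuroscaleConfig:
    n_centres: int = 50
    basis: str = "gaussian"
    max_iter: int = 2000
    tol: float = 1e-6
    #: basis width = width_factor * median inter-centre distance; smaller
    #: factors sharpen the map's response to local descriptor movement
    width_factor: float = 1.0
    #: optimisation restarts (classical-MDS init plus seeded random inits);
    #: raw stress is multimodal, a handful of restarts avoids poor optima
    n_restarts: int = 4

    def __post_init__(self) -> None:
        if self.basis != "gaussian":
            raise ValueError("only the Gaussian basis is implemented")
        if self.n_centres < 1 or self.max_iter < 1 or self.tol <= 0 or self.n_restarts < 1:
            raise ValueError("invalid NeuroScale configuration")
        if self.width_factor <= 0:
            raise ValueError("width_factor must be positive")


@dataclass
class NeuroscaleMap:
    """A trained RBF projection from descriptor space to 2-D.

    ``weights`` has shape (m+1, 2): one output-weight row per centre plus
    a final bias row.  ``mean``/``sd`` standardize descriptors before the
    basis is evaluated.  ``stress_history`` records the training
    objective, which is non-increasing by construction.
    """

    centres: np.ndarray  # (m, D) in standardized descriptor space
    width: float
    weights: np.ndarray  # (m + 1, 2)
    mean: np.ndarray
    sd: np.ndarray
    stress: float
    training_projections: np.ndarray  # (n, 2)
    seed: int
    stress_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stress < 0 or not np.isfinite(self.weights).all():
            raise ValueError("invalid trained map")

    # -- basis ---------------------------------------------------------

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def _phi(self, z: np.ndarray) -> np.ndarray:
        """Gaussian basis responses + bias column for standardized inputs."""
        d2 = ((z[:, None, :] - self.centres[None, :, :]) ** 2).sum(axis=2)
        phi = np.exp(-0.5 * d2 / self.width**2)
        return np.concatenate([phi, np.ones((len(z), 1))], axis=1)

    # -- queries ---------------------------------------------------------

    def project(self, descriptors: np.ndarray) -> np.ndarray:
        """Project one (D,) or many (n, D) descriptors to 2-D."""
        x = np.asarray(descriptors, dtype=float)
        single = x.ndim == 1
        if single:
            x = x[None]
        if x.shape[1] != len(self.mean):
            raise ValueError(
                f"descriptor dimension {x.shape[1]} != map dimension {len(self.mean)}"
            )
        y = self._phi(self._standardize(x)) @ self.weights
        return y[0] if single else y

    def jacobian(self, descriptor_vec: np.ndarray) -> np.ndarray:
        """Analytic Jacobian dy/dx (2 x D) at one raw descriptor.

        For Gaussian bases, d phi_j / dz = -phi_j (z - c_j) / width^2;
        the chain rule through standardization contributes 1/sd.
        """
        z = self._standardize(descriptor_vec)[None]
        d2 = ((z[:, None, :] - self.centres[None, :, :]) ** 2).sum(axis=2)
        phi = np.exp(-0.5 * d2 / self.width**2)[0]  # (m,)
        dphi_dz = -(phi[:, None] * (z[0] - self.centres)) / self.width**2  # (m, D)
        # bias row has zero derivative
        J_z = self.weights[:-1].T @ dphi_dz  # (2, D)
        return J_z / self.sd

    def local_metric(self, descriptor_vec: np.ndarray) -> tuple[np.ndarray, float]:
        """Metric tensor G = J J^T (2x2, PSD) and magnification sqrt(det G)."""
        J = self.jacobian(descriptor_vec)
        G = J @ J.T
        det = max(float(np.linalg.det(G)), 0.0)
        return G, float(np.sqrt(det))

    def magnification(self, descriptors: np.ndarray) -> np.ndarray:
        """Vectorized magnification factor for (n, D) descriptors."""
        x = np.asarray(descriptors, dtype=float)
        z = self._standardize(x)
        d2 = ((z[:, None, :] - self.centres[None, :, :]) ** 2).sum(axis=2)
        phi = np.exp(-0.5 * d2 / self.width**2)  # (n, m)
        diff = z[:, None, :] - self.centres[None, :, :]  # (n, m, D)
        dphi = -(phi[:, :, None] * diff) / self.width**2
        J = np.einsum("mo,nmd->nod", self.weights[:-1], dphi)  # (n, 2, D)
        J = J / self.sd[None, None, :]
        G = np.einsum("nod,npd->nop", J, J)
        det = np.clip(G[:, 0, 0] * G[:, 1, 1] - G[:, 0, 1] * G[:, 1, 0], 0.0, None)
        return np.sqrt(det)

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "centres": self.centres.tolist(),
            "width": self.width,
            "weights": self.weights.tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "stress": self.stress,
            "training_projections": self.training_projections.tolist(),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NeuroscaleMap":
        p = json.loads(Path(path).read_text())
        return cls(
            centres=np.asarray(p["centres"], dtype=float),
            width=float(p["width"]),
            weights=np.asarray(p["weights"], dtype=float),
            mean=np.asarray(p["mean"], dtype=float),
            sd=np.asarray(p["sd"], dtype=float),
            stress=float(p["stress"]),
            training_projections=np.asarray(p["training_projections"], dtype=float),
            seed=int(p["seed"]),
        )


def stress_value(dissim: np.ndarray, projections: np.ndarray) -> float:
    """Sammon-type raw stress sum_{i<j} (d_ij - ||y_i - y_j||)^2."""
    diff = projections[:, None, :] - projections[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(len(projections), k=1)
    return float(((dissim[iu] - dist[iu]) ** 2).sum())


def classical_mds(dissim: np.ndarray, ndim: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS embedding used to initialise training."""
    n = len(dissim)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dissim**2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:ndim]
    pos = np.clip(vals[idx], 0.0, None)
    Y = vecs[:, idx] * np.sqrt(pos)
    if Y.shape[1] < ndim:
        Y = np.pad(Y, ((0, 0), (0, ndim - Y.shape[1])))
    return Y


def _stress_grad_Y(dissim: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Gradient of the raw stress with respect to the projections."""
    diff = Y[:, None, :] - Y[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(dist, 1.0)
    w = (dist - dissim) / dist
    np.fill_diagonal(w, 0.0)
    return 2.0 * (w[:, :, None] * diff).sum(axis=1)


def train_neuroscale(
    descriptors: np.ndarray,
    dissim: DissimilarityMatrix | np.ndarray,
    config: NeuroscaleConfig | None = None,
    seed: int = 0,
) -> NeuroscaleMap:
    """Train the RBF projection on a descriptor cohort.

    Centres come from seeded k-means on standardized descriptors; the
    basis width is the median inter-centre distance.  Output weights are
    initialised from a classical-MDS embedding (least-squares fit through
    the basis) and refined by gradient descent with backtracking line
    search, so the recorded stress sequence is monotone non-increasing.
    Deterministic given (data, seed).
    """
    config = config or NeuroscaleConfig()
    X = np.asarray(descriptors, dtype=float)
    D = dissim.values if isinstance(dissim, DissimilarityMatrix) else np.asarray(dissim, dtype=float)
    n = len(X)
    if n < 4:
        raise ValueError("need at least 4 descriptors")
    if D.shape != (n, n):
        raise ValueError("dissimilarity shape mismatch")
    if not np.isfinite(D).all():
        raise ValueError("non-finite dissimilarities")
    if not np.isfinite(X).all():
        raise ValueError("non-finite descriptors")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    Z = (X - mean) / sd

    m = min(n, config.n_centres)
    if m < n:
        km = KMeans(n_clusters=m, random_state=seed, n_init=4)
        centres = km.fit(Z).cluster_centers_
    else:
        centres = Z.copy()
    if m > 1:
        cd = np.sqrt(((centres[:, None] - centres[None]) ** 2).sum(axis=2))
        width = float(np.median(cd[np.triu_indices(m, k=1)])) * config.width_factor
        if width <= 1e-12:
            width = 1.0
    else:
        width = 1.0

    tmp = NeuroscaleMap(
        centres=centres,
        width=width,
        weights=np.zeros((m + 1, 2)),
        mean=mean,
        sd=sd,
        stress=0.0,
        training_projections=np.zeros((n, 2)),
        seed=seed,
    )
    Phi = tmp._phi(Z)  # (n, m+1)

    from scipy.optimize import minimize

    shape = (Phi.shape[1], 2)

    def optimise(W0: np.ndarray) -> tuple[np.ndarray, float, list[float]]:
        scale = max(stress_value(D, Phi @ W0), 1.0)  # scale-free tolerances

        def objective(w_flat: np.ndarray):
            W_ = w_flat.reshape(shape)
            Y_ = Phi @ W_
            return (
                stress_value(D, Y_) / scale,
                (Phi.T @ _stress_grad_Y(D, Y_)).ravel() / scale,
            )

        hist = [stress_value(D, Phi @ W0)]

        def record(w_flat: np.ndarray) -> None:
            # the line search enforces decrease; clip numerical jitter so
            # the recorded sequence is monotone
            hist.append(min(stress_value(D, Phi @ w_flat.reshape(shape)), hist[-1]))

        res = minimize(
            objective,
            W0.ravel(),
            jac=True,
            method="L-BFGS-B",
            callback=record,
            options={"maxiter": config.max_iter, "ftol": config.tol, "gtol": 1e-12},
        )
        W_fin = res.x.reshape(shape)
        s_fin = stress_value(D, Phi @ W_fin)
        if s_fin > hist[0]:
            W_fin, s_fin = W0, hist[0]
        hist.append(min(s_fin, hist[-1]))
        return W_fin, s_fin, hist

    rng = np.random.default_rng(seed)
    d_scale = float(D[D > 0].mean()) if (D > 0).any() else 1.0
    inits = [classical_mds(D)]
    for _ in range(config.n_restarts - 1):
        inits.append(rng.normal(scale=d_scale / 2, size=(n, 2)))

    W = s = history = None
    for Y0 in inits:
        W0, *_ = np.linalg.lstsq(Phi, Y0, rcond=None)
        W_c, s_c, hist_c = optimise(W0)
        if s is None or s_c < s:
            W, s, history = W_c, s_c, hist_c

    return NeuroscaleMap(
        centres=centres,
        width=width,
        weights=W,
        mean=mean,
        sd=sd,
        stress=float(s),
        training_projections=Phi @ W,
        seed=seed,
        stress_history=history,
    )
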