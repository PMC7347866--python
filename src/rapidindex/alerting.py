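"""The per-minute surprise index, alarm generation, phenotypes and imputation.

Pipeline per minute t: the window ending at t is conditioned, summarised
by a VAR model, flattened to a descriptor and projected through the
trained topographic map.  The index measures how *surprising* that
projection is, as a sum of non-negative robust z-scores:

* the absolute deviation of the log magnification factor from its
  training median — with a Gaussian basis the Jacobian decays away from
  the training manifold, so both collapse and inflation of the local
  metric mark departure from learned behaviour;
* a training-density deficit at the projected point,
  ``max(0, (median_train_logdensity - logdensity) / MAD)`` (config,
  default on); and
* a patient-adaptive term, ``max(0, (movement - median) / MAD)`` of the
  projection's distance from the patient's own trailing-median position
  — surprise relative to the patient's recent behaviour, which fires
  even when deterioration moves an atypical patient *toward* the
  population manifold (config, default on; scale calibrated on training
  sessions).

All components are non-negative, so the index is non-negative, is
comparable across sessions scored by the same trained model, and rises
when a patient's dynamics project into novel or sparse regions or walk
away from their own established position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .dynamics import DynamicsModel, build_dissimilarity_matrix, fit_var_batch
from .features import ChannelStandardizer, svd_condition_batch, windowed_array
from .neuroscale import NeuroscaleConfig, NeuroscaleMap, descriptor, train_neuroscale
from .vitals import INDEX_CHANNELS, MonitoringSession, ValidityConfig, filter_session

_Z_CAP = 50.0
_MAD_FLOOR = 1e-6
#: log-scale robust-spread floor: ratios below ~e^0.2 are treated as noise,
#: preventing a near-constant training distribution from making one index
#: component hypersensitive
_LOG_MAD_FLOOR = 0.2


@dataclass(frozen=True)
class RapidConfig:
    """Tunable parameters of the index pipeline."""

    window_len: int = 15
    stride: int = 1
    carry_forward_limit: int = 5
    completeness_floor: float = 0.8
    svd_rank: int = 2
    var_order: int = 2
    #: isotropic floor added to residual covariances (standardized units):
    #: rank-truncated conditioning leaves the discarded direction with zero
    #: residual variance, which would make predictive densities degenerate
    sigma_floor: float = 1e-3
    warmup_min: int = 5
    density_augment: bool = True
    #: patient-adaptive component: distance of the current projection from
    #: the patient's own trailing-median projection — surprise relative to
    #: the patient's recent behaviour, directionless in map space
    adaptive_augment: bool = True
    adapt_lag: int = 60
    adapt_window: int = 300
    adapt_min_periods: int = 30
    #: imputation level source: "phenotype" reverts gaps to the cluster
    #: mean (a constant, patient-independent reference whose bias cancels
    #: in longitudinal contrasts); "patient" reverts to the patient's own
    #: trailing mean
    impute_level: str = "phenotype"
    #: condition imputed values on channels still live at that minute via
    #: the phenotype's cross-channel correlation; off by default — it
    #: couples the imputed channel's level to the live channels' offsets,
    #: which blurs longitudinal contrasts for patients away from their
    #: cluster centre
    impute_cross: bool = False
    threshold_percentile: float = 95.0
    max_impute_gap: int = 15
    train_stride: int = 1
    #: cap on training window models (the study scale: ~400 models echoes
    #: its ~410 training sessions); a seeded subsample is taken above it
    max_train_models: int = 400
    n_reference: int = 30
    phenotype_k_range: tuple[int, int] = (2, 10)
    neuroscale: NeuroscaleConfig = field(default_factory=NeuroscaleConfig)


@dataclass(frozen=True)
class AlarmEvent:
    """A maximal contiguous super-threshold run of the index."""

    session_id: str
    start_minute: int
    end_minute: int
    peak_index: float

    def __post_init__(self) -> None:
        if self.start_minute > self.end_minute:
            raise ValueError("start_minute must be <= end_minute")

    @property
    def duration(self) -> int:
        return self.end_minute - self.start_minute + 1


@dataclass
class RapidIndexSeries:
    """Per-minute index values with availability flags.

    ``frame`` is indexed by minute from the warm-up onward with columns
    ``index`` (float, NaN when unavailable) and ``flag`` (one of
    ``warmup``, ``direct``, ``imputed``, ``unavailable``).
    """

    session_id: str
    frame: pd.DataFrame
    threshold: float | None = None

    def values(self) -> pd.Series:
        return self.frame["index"]


@dataclass
class PhenotypeModel:
    """Clusters of training projections with representative channel behaviour.

    Each cluster carries the mean, sd and lag-1 autocorrelation of every
    raw channel across its member windows; these AR(1) summaries drive
    gap imputation.
    """

    centroids: np.ndarray  # (k, 2)
    channels: tuple[str, ...]
    means: np.ndarray  # (k, C)
    sds: np.ndarray  # (k, C)
    phis: np.ndarray  # (k, C)
    assignments: np.ndarray  # (n,)
    k: int
    #: within-cluster cross-channel correlation of minute values; identity
    #: when no window statistics were supplied
    corrs: np.ndarray | None = None

    def corr(self, cluster: int) -> np.ndarray:
        if self.corrs is None:
            return np.eye(len(self.channels))
        return self.corrs[cluster]

    def assign(self, projections: np.ndarray) -> np.ndarray:
        """Nearest-centroid cluster for one (2,) or many (n, 2) points."""
        p = np.atleast_2d(np.asarray(projections, dtype=float))
        d2 = ((p[:, None, :] - self.centroids[None]) ** 2).sum(axis=2)
        out = d2.argmin(axis=1)
        return out[0] if np.asarray(projections).ndim == 1 else out


def fit_phenotypes(
    projections: np.ndarray,
    *,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    channels=INDEX_CHANNELS,
    window_stats: np.ndarray | None = None,
    window_corr: np.ndarray | None = None,
) -> PhenotypeModel:
    """Cluster training projections; choose k by best silhouette.

    ``window_stats`` is an optional (n, C, 3) array of per-window raw
    channel (mean, sd, lag-1 autocorrelation) and ``window_corr`` an
    optional (n, C, C) array of per-window cross-channel correlations;
    together they build each cluster's representative multichannel signal
    model.  All-identical projections degrade to a single cluster with a
    warning.
    """
    P = np.asarray(projections, dtype=float)
    n = len(P)
    if np.allclose(P, P[0], atol=1e-12):
        warnings.warn("degenerate projections; single phenotype", stacklevel=2)
        labels = np.zeros(n, dtype=int)
        centroids = P[:1].copy()
        k = 1
    else:
        best = None
        for k_try in range(k_range[0], min(k_range[1], n - 1) + 1):
            km = KMeans(n_clusters=k_try, random_state=seed, n_init=10)
            lab = km.fit_predict(P)
            if len(np.unique(lab)) < 2:
                continue
            score = silhouette_score(P, lab)
            if best is None or score > best[0]:
                best = (score, k_try, lab, km.cluster_centers_)
        if best is None:
            raise ValueError("could not cluster projections")
        _, k, labels, centroids = best

    C = len(channels)
    means = np.zeros((k, C))
    sds = np.zeros((k, C))
    phis = np.zeros((k, C))
    corrs = None
    if window_stats is not None:
        ws = np.asarray(window_stats, dtype=float)
        for c in range(k):
            member = ws[labels == c]
            means[c] = member[:, :, 0].mean(axis=0)
            sds[c] = np.sqrt((member[:, :, 1] ** 2).mean(axis=0))
            phis[c] = np.clip(member[:, :, 2].mean(axis=0), 0.0, 0.999)
    if window_corr is not None:
        wc = np.asarray(window_corr, dtype=float)
        corrs = np.stack(
            [
                np.clip(wc[labels == c].mean(axis=0), -0.99, 0.99) if (labels == c).any() else np.eye(C)
                for c in range(k)
            ]
        )
        for c in range(k):
            np.fill_diagonal(corrs[c], 1.0)
    return PhenotypeModel(
        centroids=centroids,
        channels=tuple(channels),
        means=means,
        sds=sds,
        phis=phis,
        assignments=labels,
        k=k,
        corrs=corrs,
    )


def window_channel_stats(windows: np.ndarray) -> np.ndarray:
    """Per-window raw channel (mean, sd, lag-1 autocorrelation), (n, C, 3)."""
    mean = windows.mean(axis=1)
    sd = windows.std(axis=1)
    x0 = windows[:, :-1, :] - mean[:, None, :]
    x1 = windows[:, 1:, :] - mean[:, None, :]
    num = (x0 * x1).mean(axis=1)
    den = np.maximum((x0**2).mean(axis=1), 1e-12)
    phi = np.clip(num / den, -0.999, 0.999)
    return np.stack([mean, sd, phi], axis=2)


def window_channel_corr(windows: np.ndarray) -> np.ndarray:
    """Per-window cross-channel correlation matrices, (n, C, C)."""
    centred = windows - windows.mean(axis=1, keepdims=True)
    cov = np.einsum("ntc,ntd->ncd", centred, centred) / windows.shape[1]
    sd = np.sqrt(np.maximum(np.einsum("ncc->nc", cov), 1e-12))
    return cov / (sd[:, :, None] * sd[:, None, :])


def impute_missing(
    frame: pd.DataFrame,
    phenotype: PhenotypeModel,
    cluster: int,
    *,
    max_gap: int = 15,
    channels=INDEX_CHANNELS,
    noise: bool = True,
    level: str = "phenotype",
    cross: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill per-channel gaps up to ``max_gap`` minutes from a phenotype.

    A missing channel is reconstructed from the phenotype's multichannel
    signal model conditioned on everything still observable:

    * the per-minute target follows the channels that *are* live at that
      minute through the phenotype's cross-channel correlation (the index
      keeps monitoring on one sensor by reading the other);
    * the level each channel reverts to is the patient's own trailing
      mean, not the population mean — imputing toward a cluster centre
      would manufacture excursions for any patient sitting away from it;
    * an AR(1) pull (phenotype autocorrelation) plus innovation noise at
      the conditional spread (on by default) keeps imputed stretches
      statistically realistic rather than unnaturally smooth; draws are
      deterministic, seeded from the gap position.

    With no history the level falls back to the phenotype mean; a
    zero-variance phenotype imputes its mean exactly.  Gaps longer than
    ``max_gap`` are refused and stay missing.  Returns the filled frame
    and a boolean imputed mask.
    """
    import zlib

    if not 0 <= cluster < phenotype.k:
        raise ValueError(f"unknown phenotype cluster {cluster}")
    out = frame.copy()
    imputed = pd.DataFrame(False, index=frame.index, columns=frame.columns)
    ci = {ch: i for i, ch in enumerate(phenotype.channels)}
    corr = phenotype.corr(cluster)
    level_window = 120  # minutes of history defining each channel's own level
    raw = {ch: frame[ch].to_numpy(dtype=float) for ch in channels}

    def trailing_level(ch: str, t: int) -> float:
        if level == "phenotype":
            return float(phenotype.means[cluster, ci[ch]])
        hist = raw[ch][max(0, t - level_window) : t]
        hist = hist[np.isfinite(hist)]
        return float(hist.mean()) if len(hist) else float(phenotype.means[cluster, ci[ch]])

    def live_z(t: int, skip: str, levels: dict[str, float]) -> dict[str, float]:
        z = {}
        for o in channels:
            if o == skip:
                continue
            v = raw[o][t]
            sd_o = phenotype.sds[cluster, ci[o]]
            if np.isfinite(v) and sd_o > 1e-12:
                z[o] = (v - levels[o]) / sd_o
        return z

    for ch in channels:
        col = out[ch].to_numpy(dtype=float, copy=True)
        mu_ph = phenotype.means[cluster, ci[ch]]
        sd = phenotype.sds[cluster, ci[ch]]
        phi = phenotype.phis[cluster, ci[ch]]
        isna = np.isnan(col)
        t = 0
        n = len(col)
        while t < n:
            if not isna[t]:
                t += 1
                continue
            run_end = t
            while run_end < n and isna[run_end]:
                run_end += 1
            gap = run_end - t
            if gap <= max_gap:
                rng = np.random.default_rng(zlib.crc32(f"{ch}:{t}".encode()))
                levels = {o: trailing_level(o, t) for o in channels}
                mu = levels[ch]
                last = col[t - 1] if t > 0 else np.nan
                prev = last
                prev_target = mu
                for h in range(gap):
                    if sd <= 1e-12:
                        col[t + h] = mu_ph
                        continue
                    z = live_z(t + h, ch, levels) if cross else {}
                    if z:
                        pred = float(np.mean([corr[ci[ch], ci[o]] * zv for o, zv in z.items()]))
                    else:
                        pred = 0.0
                    target = mu + sd * pred
                    if not np.isfinite(last):
                        step = target
                    else:
                        step = target + phi * (prev - prev_target)
                        if noise:
                            step += rng.normal(0.0, sd * np.sqrt(1.0 - phi**2))
                    col[t + h] = step
                    prev, prev_target = step, target
                imputed.iloc[t : t + gap, imputed.columns.get_loc(ch)] = True
            t = run_end
        out[ch] = col
    return out, imputed


# ---------------------------------------------------------------------
# trained model


@dataclass
class RapidModel:
    """Everything needed to score new sessions: trained map + calibration."""

    config: RapidConfig
    standardizer: ChannelStandardizer
    nsmap: NeuroscaleMap
    logmag_median: float
    logmag_mad: float
    logdens_median: float
    logdens_mad: float
    kde_dataset: np.ndarray  # (2, n) training projections for the KDE
    threshold: float | None = None
    phenotypes: PhenotypeModel | None = None
    training_index_values: np.ndarray | None = None
    #: robust scale of trailing-median projection movement on training data
    adapt_median: float | None = None
    adapt_mad: float | None = None

    def _kde(self) -> gaussian_kde:
        return gaussian_kde(self.kde_dataset)

    def index_from_descriptors(self, descriptors: np.ndarray) -> np.ndarray:
        """Population surprise for a batch of (n, D) descriptors.

        Covers the magnification and training-density components; the
        patient-adaptive trajectory component needs a whole session and
        is added by :func:`compute_rapid_index`.
        """
        mags = self.nsmap.magnification(descriptors)
        logmag = np.log(np.maximum(mags, 1e-300))
        z_mag = np.minimum(np.abs(logmag - self.logmag_median) / self.logmag_mad, _Z_CAP)
        if not self.config.density_augment:
            return z_mag
        proj = self.nsmap.project(descriptors)
        logdens = np.log(np.maximum(self._kde()(proj.T), 1e-300))
        z_dens = np.clip((self.logdens_median - logdens) / self.logdens_mad, 0.0, _Z_CAP)
        return z_mag + z_dens


def _embed_order(coeffs: np.ndarray, target_order: int) -> np.ndarray:
    """Zero-pad lag matrices of a lower-order fit up to the target order."""
    p, k, _ = coeffs.shape
    if p == target_order:
        return coeffs
    out = np.zeros((target_order, k, k))
    out[:p] = coeffs
    return out


def _models_from_windows(
    conditioned: np.ndarray, order: int, session_id: str = "", starts: np.ndarray | None = None
) -> list[DynamicsModel]:
    coeffs, intercepts, sigmas = fit_var_batch(conditioned, order)
    models = []
    for i in range(len(conditioned)):
        models.append(
            DynamicsModel(
                coeffs=coeffs[i],
                intercept=intercepts[i],
                sigma=_psd(sigmas[i]),
                session_id=session_id,
                start_minute=int(starts[i]) if starts is not None else -1,
            )
        )
    return models


def _psd(sigma: np.ndarray, floor: float = 0.0) -> np.ndarray:
    if floor > 0:
        sigma = sigma + floor * np.eye(len(sigma))
    eig = np.linalg.eigvalsh(sigma)[0]
    if eig < 0:
        sigma = sigma + (1e-12 - eig) * np.eye(len(sigma))
    return sigma


def _descriptors_from_batch(coeffs, intercepts, sigmas, floor=0.0) -> np.ndarray:
    descs = []
    for i in range(len(coeffs)):
        m = DynamicsModel(coeffs=coeffs[i], intercept=intercepts[i], sigma=_psd(sigmas[i], floor))
        descs.append(descriptor(m))
    return np.asarray(descs)


def train_rapid(
    sessions: list[MonitoringSession],
    config: RapidConfig | None = None,
    seed: int = 0,
    validity: ValidityConfig | None = None,
) -> RapidModel:
    """Train the full index pipeline on a cohort of stable sessions.

    Stages: validity filtering, frozen channel standardization, strided
    windowing, SVD conditioning, per-window VAR fits, symmetrised-KL
    dissimilarities over shared reference windows, topographic map
    training, phenotype clustering, and calibration of the index scale
    and alarm threshold on the training windows themselves.
    """
    config = config or RapidConfig()
    rng = np.random.default_rng(seed)
    filtered = []
    for s in sessions:
        if s.validity_mask is None:
            s, _ = filter_session(s, validity)
        filtered.append(s)

    standardizer = ChannelStandardizer.fit([s.valid_frame() for s in filtered])

    all_windows, all_raw, owners, starts = [], [], [], []
    for s in filtered:
        st, wins, _, usable = windowed_array(
            s,
            config.window_len,
            config.train_stride,
            carry_forward_limit=config.carry_forward_limit,
            completeness_floor=config.completeness_floor,
        )
        if usable.any():
            all_raw.append(wins[usable])
            all_windows.append(standardizer.transform(wins[usable]))
            owners.extend([s.session_id] * int(usable.sum()))
            starts.append(st[usable])
    if not all_windows:
        raise ValueError("no usable training windows")
    W = np.concatenate(all_windows)
    W_raw = np.concatenate(all_raw)
    starts = np.concatenate(starts)
    owners = np.asarray(owners)

    if len(W) > config.max_train_models:
        keep = np.sort(rng.choice(len(W), size=config.max_train_models, replace=False))
        W, W_raw, starts, owners = W[keep], W_raw[keep], starts[keep], owners[keep]

    conditioned, _ = svd_condition_batch(W, config.svd_rank)
    coeffs, intercepts, sigmas = fit_var_batch(conditioned, config.var_order)
    models = [
        DynamicsModel(
            coeffs=coeffs[i],
            intercept=intercepts[i],
            sigma=_psd(sigmas[i], config.sigma_floor),
            session_id=str(owners[i]),
            start_minute=int(starts[i]),
        )
        for i in range(len(conditioned))
    ]
    descriptors = np.asarray([descriptor(m) for m in models])

    n_ref = min(config.n_reference, len(conditioned))
    ref_idx = np.sort(rng.choice(len(conditioned), size=n_ref, replace=False))
    reference = conditioned[ref_idx]

    dissim = build_dissimilarity_matrix(models, list(reference))
    nsmap = train_neuroscale(descriptors, dissim, config.neuroscale, seed=seed)

    mags = nsmap.magnification(descriptors)
    logmag = np.log(np.maximum(mags, 1e-300))
    logmag_median = float(np.median(logmag))
    logmag_mad = float(max(np.median(np.abs(logmag - logmag_median)), _LOG_MAD_FLOOR))

    proj = nsmap.training_projections
    kde_dataset = proj.T.copy()
    logdens = np.log(np.maximum(gaussian_kde(kde_dataset)(proj.T), 1e-300))
    logdens_median = float(np.median(logdens))
    logdens_mad = float(max(np.median(np.abs(logdens - logdens_median)), _LOG_MAD_FLOOR))

    phenotypes = fit_phenotypes(
        proj,
        k_range=config.phenotype_k_range,
        seed=seed,
        window_stats=window_channel_stats(W_raw),
        window_corr=window_channel_corr(W_raw),
    )

    model = RapidModel(
        config=config,
        standardizer=standardizer,
        nsmap=nsmap,
        logmag_median=logmag_median,
        logmag_mad=logmag_mad,
        logdens_median=logdens_median,
        logdens_mad=logdens_mad,
        kde_dataset=kde_dataset,
        phenotypes=phenotypes,
    )

    # calibrate the patient-adaptive movement scale and the alarm threshold
    # by replaying the training sessions through the trained map
    scored_sessions = [_score_population(s, model) for s in filtered]
    if config.adaptive_augment:
        movements = pd.concat(
            [_adaptive_movement(sc, config) for sc in scored_sessions]
        ).dropna()
        if len(movements):
            model.adapt_median = float(np.median(movements))
            model.adapt_mad = float(
                max(np.median(np.abs(movements - model.adapt_median)), _MAD_FLOOR)
            )
    training_values = (
        pd.concat([_total_index(sc, model) for sc in scored_sessions]).dropna().to_numpy()
    )
    model.training_index_values = training_values
    if len(training_values) >= 100:
        model.threshold = calibrate_threshold(training_values, config.threshold_percentile)
    return model


# ---------------------------------------------------------------------
# scoring


def _session_frame_with_imputation(
    session: MonitoringSession, model: RapidModel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Valid-value frame with phenotype gap imputation applied.

    The phenotype is assigned from a preliminary pass: the session's
    earliest usable windows are projected and the nearest centroid taken.
    During warm-up (no usable window yet) gaps are left to the windowing
    carry-forward only.
    """
    cfg = model.config
    frame = session.valid_frame()[list(INDEX_CHANNELS)]
    frame = frame.reindex(pd.RangeIndex(session.intended_start, session.intended_end))
    imputed = pd.DataFrame(False, index=frame.index, columns=frame.columns)
    if model.phenotypes is None:
        return frame, imputed
    _, wins, _, usable = windowed_array(
        session,
        cfg.window_len,
        cfg.stride,
        carry_forward_limit=cfg.carry_forward_limit,
        completeness_floor=cfg.completeness_floor,
    )
    if not usable.any():
        return frame, imputed
    first = wins[usable][:5]
    conditioned, _ = svd_condition_batch(model.standardizer.transform(first), cfg.svd_rank)
    coeffs, intercepts, sigmas = fit_var_batch(conditioned, cfg.var_order)
    descs = _descriptors_from_batch(coeffs, intercepts, sigmas, cfg.sigma_floor)
    proj = model.nsmap.project(descs).mean(axis=0)
    cluster = int(model.phenotypes.assign(proj))
    return impute_missing(
        frame,
        model.phenotypes,
        cluster,
        max_gap=cfg.max_impute_gap,
        level=cfg.impute_level,
        cross=cfg.impute_cross,
    )


def _score_population(
    session: MonitoringSession,
    model: RapidModel,
    *,
    validity: ValidityConfig | None = None,
) -> pd.DataFrame:
    """Per-minute population surprise plus the projection trajectory.

    Returns a frame indexed by minute with columns ``pop`` (magnification
    and density components), ``proj_x``/``proj_y`` and ``flag``.
    """
    cfg = model.config
    if session.validity_mask is None:
        session, _ = filter_session(session, validity)
    frame, imputed_mask = _session_frame_with_imputation(session, model)

    T = session.intended_minutes
    start0 = session.intended_start
    minutes = np.arange(start0 + cfg.warmup_min, start0 + T)
    pop = np.full(len(minutes), np.nan)
    proj = np.full((len(minutes), 2), np.nan)
    flags = np.array(["unavailable"] * len(minutes), dtype=object)

    starts, wins, completeness, usable = windowed_array(
        session,
        cfg.window_len,
        1,
        carry_forward_limit=cfg.carry_forward_limit,
        completeness_floor=cfg.completeness_floor,
        frame=frame,
    )
    ends = starts + cfg.window_len - 1
    obs_mask = frame.notna().to_numpy() & ~imputed_mask.to_numpy()

    # full windows (session minute >= window_len - 1)
    if usable.any():
        cond, _ = svd_condition_batch(model.standardizer.transform(wins[usable]), cfg.svd_rank)
        coeffs, intercepts, sigmas = fit_var_batch(cond, cfg.var_order)
        descs = _descriptors_from_batch(coeffs, intercepts, sigmas, cfg.sigma_floor)
        vals = model.index_from_descriptors(descs)
        projections = model.nsmap.project(descs)
        imp = np.lib.stride_tricks.sliding_window_view(
            imputed_mask.to_numpy().any(axis=1), cfg.window_len, axis=0
        ).any(axis=1)
        for j, (e, v) in enumerate(zip(ends[usable], vals)):
            row = e - (start0 + cfg.warmup_min)
            if 0 <= row < len(minutes):
                pop[row] = v
                proj[row] = projections[j]
                flags[row] = "imputed" if imp[starts[usable][j] - start0] else "direct"

    # warm-up: expanding windows ending before the first full window
    filled = frame.ffill(limit=cfg.carry_forward_limit).to_numpy()
    for t in range(cfg.warmup_min, min(cfg.window_len - 1, T)):
        w = filled[: t + 1]
        if np.isnan(w).any():
            continue
        comp = obs_mask[: t + 1].mean()
        if comp < cfg.completeness_floor:
            continue
        z = model.standardizer.transform(w)
        cond, _, _ = _condition_single(z, cfg.svd_rank)
        order = cfg.var_order if len(cond) >= 4 * cfg.var_order + 2 else 1
        coeffs, intercepts, sigmas = fit_var_batch(cond[None], order)
        m = DynamicsModel(
            coeffs=_embed_order(coeffs[0], cfg.var_order),
            intercept=intercepts[0],
            sigma=_psd(sigmas[0], cfg.sigma_floor),
        )
        desc = descriptor(m)[None]
        row = t - cfg.warmup_min
        pop[row] = model.index_from_descriptors(desc)[0]
        proj[row] = model.nsmap.project(desc)[0]
        flags[row] = "warmup"

    return pd.DataFrame(
        {"pop": pop, "proj_x": proj[:, 0], "proj_y": proj[:, 1], "flag": flags},
        index=pd.Index(minutes, name="minute"),
    )


def _adaptive_movement(scored: pd.DataFrame, cfg: RapidConfig) -> pd.Series:
    """Distance of each projection from the patient's trailing median.

    The baseline is the componentwise median projection over the window
    ``[t - adapt_lag - adapt_window + 1, t - adapt_lag]``, lagged so the
    current excursion does not contaminate its own reference; NaN until
    enough history exists.
    """
    bx = scored["proj_x"].shift(cfg.adapt_lag).rolling(
        cfg.adapt_window, min_periods=cfg.adapt_min_periods
    ).median()
    by = scored["proj_y"].shift(cfg.adapt_lag).rolling(
        cfg.adapt_window, min_periods=cfg.adapt_min_periods
    ).median()
    return np.hypot(scored["proj_x"] - bx, scored["proj_y"] - by)


def _total_index(scored: pd.DataFrame, model: RapidModel) -> pd.Series:
    cfg = model.config
    total = scored["pop"].copy()
    if cfg.adaptive_augment and model.adapt_mad is not None:
        dist = _adaptive_movement(scored, cfg)
        z_adapt = np.clip((dist - model.adapt_median) / model.adapt_mad, 0.0, _Z_CAP)
        total = total + z_adapt.fillna(0.0)
    return total


def compute_rapid_index(
    session: MonitoringSession,
    model: RapidModel,
    *,
    validity: ValidityConfig | None = None,
) -> RapidIndexSeries:
    """Score one session minute-by-minute.

    The first value appears at ``warmup_min`` (default minute 5) from an
    expanding window; full-length sliding windows take over once
    available.  The index sums the population surprise (magnification and
    training-density deficit at the projection) and, once enough history
    exists, a patient-adaptive term scoring movement of the projection
    away from the patient's own trailing behaviour.  Minutes whose window
    required phenotype imputation are flagged ``imputed``; minutes with
    no usable window are ``unavailable`` with a NaN index.
    """
    scored = _score_population(session, model, validity=validity)
    out = pd.DataFrame(
        {"index": _total_index(scored, model), "flag": scored["flag"]},
        index=scored.index,
    )
    return RapidIndexSeries(session_id=session.session_id, frame=out, threshold=model.threshold)


def _condition_single(values: np.ndarray, rank: int):
    from .features import svd_condition_array

    return svd_condition_array(values, rank)


def calibrate_threshold(values: np.ndarray, percentile: float = 95.0) -> float:
    """Empirical nearest-rank percentile of training index values."""
    vals = np.sort(np.asarray(values, dtype=float))
    vals = vals[np.isfinite(vals)]
    if len(vals) < 100:
        raise ValueError(f"need >= 100 index values to calibrate, got {len(vals)}")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    rank = int(np.ceil(percentile / 100.0 * len(vals)))
    return float(vals[rank - 1])


def generate_alerts(series: RapidIndexSeries, threshold: float | None = None) -> list[AlarmEvent]:
    """Maximal contiguous runs of index >= threshold."""
    thr = threshold if threshold is not None else series.threshold
    if thr is None:
        raise ValueError("no threshold available")
    if series.frame.empty:
        raise ValueError("empty index series")
    vals = series.frame["index"].to_numpy()
    minutes = series.frame.index.to_numpy()
    above = np.nan_to_num(vals, nan=-np.inf) >= thr
    events: list[AlarmEvent] = []
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1] and minutes[j + 1] == minutes[j] + 1:
            j += 1
        events.append(
            AlarmEvent(
                session_id=series.session_id,
                start_minute=int(minutes[i]),
                end_minute=int(minutes[j]),
                peak_index=float(np.nanmax(vals[i : j + 1])),
            )
        )
        i = j + 1
    return events
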