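"""Windowing and singular-vector conditioning of multichannel vital streams.

The adaptive index works on short sliding windows (default 15 min) of the
three index channels (HR, RR, SpO2).  Each window is standardized with
per-channel statistics frozen from the training cohort, then denoised by
truncated SVD: keeping the leading singular directions removes the
smallest-variance component, which on per-minute telemetry is dominated
by unphysical high-frequency events rather than physiology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vitals import INDEX_CHANNELS, MonitoringSession


@dataclass(frozen=True)
class ChannelStandardizer:
    """Per-channel z-score transform with statistics frozen at training time.

    New patients must be comparable to the training phenotype space, so
    the mean/sd are estimated once on the training cohort and reused for
    every later session.
    """

    channels: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, frames: list[pd.DataFrame], channels=INDEX_CHANNELS) -> "ChannelStandardizer":
        stacked = pd.concat([f[list(channels)] for f in frames], axis=0)
        mean = stacked.mean().to_numpy()
        sd = stacked.std(ddof=0).to_numpy()
        sd = np.where(sd > 1e-12, sd, 1.0)
        return cls(channels=tuple(channels), mean=mean, sd=sd)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.sd

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return values * self.sd + self.mean


@dataclass(frozen=True)
class WindowMatrix:
    """One contiguous window of the index channels.

    ``values`` is a (length x n_channels) float matrix with short gaps
    carried forward; ``completeness`` is the fraction of cells actually
    observed before gap filling; ``usable`` is False when the window
    still contains missing cells or falls below the completeness floor.
    """

    session_id: str
    start_minute: int
    length: int
    channels: tuple[str, ...]
    values: np.ndarray
    completeness: float
    usable: bool

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("window length must be >= 2")
        if not 0 <= self.completeness <= 1:
            raise ValueError("completeness outside [0, 1]")


@dataclass(frozen=True)
class FeatureVector:
    """Rank-k conditioned window ready for dynamics modelling."""

    window: WindowMatrix
    values: np.ndarray
    retained_rank: int
    discarded_energy: float

    def __post_init__(self) -> None:
        if not 0 <= self.discarded_energy <= 1 + 1e-12:
            raise ValueError("discarded_energy outside [0, 1]")


def windowed_array(
    session: MonitoringSession,
    window_len: int = 15,
    stride: int = 1,
    *,
    carry_forward_limit: int = 5,
    completeness_floor: float = 0.8,
    channels=INDEX_CHANNELS,
    frame: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized windowing over the whole intended interval.

    Returns ``(starts, windows, completeness, usable)`` where ``windows``
    has shape (n_windows, window_len, n_channels).  Invalid values are
    treated as missing; gaps are last-observation-carried-forward up to
    ``carry_forward_limit`` minutes.  An optional pre-built ``frame``
    (e.g. with phenotype imputation applied) overrides the session's own
    valid values.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    data = frame if frame is not None else session.valid_frame()
    full_index = pd.RangeIndex(session.intended_start, session.intended_end)
    data = data.reindex(full_index)[list(channels)]
    observed = data.notna().to_numpy()
    filled = data.ffill(limit=carry_forward_limit).to_numpy()

    T = len(full_index)
    n_win = max(0, (T - window_len) // stride + 1)
    if n_win == 0:
        empty = np.empty((0, window_len, len(channels)))
        return np.empty(0, dtype=int), empty, np.empty(0), np.empty(0, dtype=bool)

    sl = np.lib.stride_tricks.sliding_window_view(filled, window_len, axis=0)
    ob = np.lib.stride_tricks.sliding_window_view(observed, window_len, axis=0)
    idx = np.arange(0, T - window_len + 1, stride)
    windows = np.ascontiguousarray(sl[idx].transpose(0, 2, 1))
    obs = ob[idx].transpose(0, 2, 1)
    completeness = obs.mean(axis=(1, 2))
    has_nan = np.isnan(windows).any(axis=(1, 2))
    usable = (completeness >= completeness_floor) & ~has_nan
    starts = session.intended_start + idx
    return starts, windows, completeness, usable


def make_windows(
    session: MonitoringSession,
    window_len: int = 15,
    stride: int = 1,
    *,
    carry_forward_limit: int = 5,
    completeness_floor: float = 0.8,
    channels=INDEX_CHANNELS,
) -> list[WindowMatrix]:
    """Sliding windows over the session's valid values (object view)."""
    starts, windows, completeness, usable = windowed_array(
        session,
        window_len,
        stride,
        carry_forward_limit=carry_forward_limit,
        completeness_floor=completeness_floor,
        channels=channels,
    )
    return [
        WindowMatrix(
            session_id=session.session_id,
            start_minute=int(s),
            length=window_len,
            channels=tuple(channels),
            values=w,
            completeness=float(c),
            usable=bool(u),
        )
        for s, w, c, u in zip(starts, windows, completeness, usable)
    ]


def svd_condition_array(values: np.ndarray, rank: int) -> tuple[np.ndarray, int, float]:
    """Best rank-``rank`` approximation of one window (least squares).

    Returns ``(reconstruction, retained_rank, discarded_energy)`` with
    ``discarded_energy = 1 - sum_{i<=k} s_i^2 / sum_i s_i^2``.  An
    (all-zero / all-constant-after-standardization) window has no energy
    to truncate and is returned unchanged.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    u, s, vt = np.linalg.svd(values, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 1e-300:
        return values.copy(), 0, 0.0
    k = min(rank, len(s))
    recon = (u[:, :k] * s[:k]) @ vt[:k]
    discarded = max(0.0, 1.0 - float(np.sum(s[:k] ** 2)) / total)
    return recon, k, discarded


def svd_condition(
    window: WindowMatrix,
    rank: int = 2,
    standardizer: ChannelStandardizer | None = None,
) -> FeatureVector:
    """Standardize (if a standardizer is given) and truncate one window."""
    if not window.usable:
        warnings.warn(
            f"conditioning an unusable window at minute {window.start_minute}", stacklevel=2
        )
    values = window.values
    if standardizer is not None:
        values = standardizer.transform(values)
    recon, k, discarded = svd_condition_array(values, rank)
    return FeatureVector(window=window, values=recon, retained_rank=k, discarded_energy=discarded)


def svd_condition_batch(windows: np.ndarray, rank: int) -> tuple[np.ndarray, np.ndarray]:
    """Truncated-SVD reconstruction of a (n, L, C) stack of windows.

    Returns ``(reconstructions, discarded_energy)``; matches the
    single-window routine exactly (batched LAPACK SVD).
    """
    if windows.size == 0:
        return windows.copy(), np.empty(0)
    u, s, vt = np.linalg.svd(windows, full_matrices=False)
    k = min(rank, s.shape[-1])
    recon = np.einsum("nij,nj,njk->nik", u[:, :, :k], s[:, :k], vt[:, :k, :])
    total = (s**2).sum(axis=1)
    kept = (s[:, :k] ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        discarded = np.where(total > 1e-300, np.clip(1.0 - kept / total, 0.0, 1.0), 0.0)
    # zero-energy windows are passed through untruncated
    recon[total <= 1e-300] = windows[total <= 1e-300]
    return recon, discarded
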