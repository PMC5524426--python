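"""Delay-coordinate (Takens) nonparametric prediction.

A scalar series x(0..T) is embedded as delay vectors
``[x(t), x(t - tau), ..., x(t - d*tau)]`` collected into a library; the
*direct* forecast of lead i looks up the kappa nearest library vectors to
the current delay vector and averages their stored i-step futures (a
locally constant model).  The same lead-1 predictor, used as the state
advancement inside an unscented Kalman filter whose state is the delay
vector itself, yields the model-free Kalman-Takens smoother used here to
denoise training data before libraries are built from them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import cached_property
from typing import Sequence

import numpy as np

__all__ = [
    "EmbeddingConfig",
    "DelayLibrary",
    "build_delay_library",
    "knn_lookup",
    "local_constant_predict",
    "predict_batch",
    "direct_forecast",
    "kalman_takens_denoise",
    "select_embedding_cv",
    "library_to_frame",
    "library_from_frame",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Embedding and neighborhood settings.

    d is the number of delays (vectors have d+1 coordinates), tau the delay
    in samples, kappa the neighbor count.  ``theiler`` excludes neighbors
    within that many samples of the query's own time (0 = off: the library
    never contains prediction-interval data, so temporal self-matches are
    benign here).
    """

    d: int = 9
    tau: int = 1
    kappa: int = 20
    weighting: str = "uniform"  # "uniform" | "inverse-distance"
    theiler: int = 0

    def __post_init__(self):
        if self.d < 0 or self.tau < 1 or self.kappa < 1:
            raise ValueError("require d >= 0, tau >= 1, kappa >= 1")
        if self.weighting not in ("uniform", "inverse-distance"):
            raise ValueError("weighting must be 'uniform' or 'inverse-distance'")

    @property
    def dim(self) -> int:
        return self.d + 1

    @property
    def window(self) -> int:
        """Number of consecutive samples spanned by one delay vector."""
        return self.d * self.tau + 1


@dataclass(frozen=True)
class DelayLibrary:
    """Delay vectors harvested from a training series plus their futures.

    Row r corresponds to base time t = d*tau + r; ``vectors[r]`` is the
    delay vector at t and ``futures[r, i-1]`` the known value x(t + i) for
    leads i = 1..max_lead (NaN where t + i runs past the series, which
    removes that row from the searchable set).
    """

    vectors: np.ndarray       # (rows, d+1)
    futures: np.ndarray       # (rows, max_lead)
    source_times: np.ndarray  # (rows,)
    d: int
    tau: int

    @property
    def n_rows(self) -> int:
        return self.vectors.shape[0]

    @property
    def max_lead(self) -> int:
        return self.futures.shape[1]

    @cached_property
    def searchable(self) -> np.ndarray:
        """Indices of rows with a complete set of stored futures."""
        return np.flatnonzero(~np.isnan(self.futures).any(axis=1))

    @cached_property
    def _search_cache(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(vectors, squared norms, source times) of the searchable rows."""
        V = self.vectors[self.searchable]
        return V, np.einsum("ri,ri->r", V, V), self.source_times[self.searchable]


def build_delay_library(series: np.ndarray, cfg: EmbeddingConfig,
                        max_lead: int = 1) -> DelayLibrary:
    """Collect every delay vector of ``series`` together with its futures."""
    x = np.asarray(series, dtype=float).ravel()
    span = cfg.d * cfg.tau
    if x.size <= span + max_lead:
        raise ValueError(
            f"series of length {x.size} too short for d={cfg.d}, tau={cfg.tau}, "
            f"max_lead={max_lead}")
    times = np.arange(span, x.size)
    lags = np.arange(0, span + 1, cfg.tau)
    vectors = x[times[:, None] - lags[None, :]]
    fut_idx = times[:, None] + np.arange(1, max_lead + 1)[None, :]
    futures = np.where(fut_idx < x.size, x[np.minimum(fut_idx, x.size - 1)], np.nan)
    return DelayLibrary(vectors=vectors, futures=futures, source_times=times,
                        d=cfg.d, tau=cfg.tau)


def knn_lookup(queries: np.ndarray, lib: DelayLibrary, kappa: int,
               theiler: int = 0, query_times: np.ndarray | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Indices (into library rows) and distances of the kappa nearest rows.

    Exact Euclidean nearest neighbors over the searchable rows; distance
    ties are broken deterministically in favor of the earlier source time.
    Returns ``(idx, dist)`` of shape (n_queries, kappa).
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    cand = lib.searchable
    if cand.size < kappa:
        raise ValueError(f"library has {cand.size} usable rows < kappa={kappa}")
    V, vnorm2, st = lib._search_cache
    # full distance matrix; libraries here are a few thousand rows at most
    diff2 = queries @ (-2.0 * V.T)
    diff2 += np.einsum("qi,qi->q", queries, queries)[:, None]
    diff2 += vnorm2[None, :]
    np.maximum(diff2, 0.0, out=diff2)
    if theiler > 0 and query_times is not None:
        mask = np.abs(st[None, :] - query_times[:, None]) <= theiler
        diff2[mask] = np.inf
    B = queries.shape[0]
    # fast path: per-row top-kappa then a stable (distance, source-time) sort
    part = np.argpartition(diff2, kappa - 1, axis=1)[:, :kappa]
    pd = np.take_along_axis(diff2, part, axis=1)
    order = np.lexsort((st[part], pd), axis=-1)
    sel = np.take_along_axis(part, order, axis=1)
    kth = np.take_along_axis(diff2, sel[:, -1:], axis=1)
    tied = (diff2 <= kth).sum(axis=1) > kappa
    for b in np.flatnonzero(tied):  # boundary ties: earlier source time wins
        row = diff2[b]
        cut = np.flatnonzero(row <= kth[b, 0])
        o = np.lexsort((st[cut], row[cut]))
        sel[b] = cut[o[:kappa]]
    return cand[sel], np.sqrt(np.take_along_axis(diff2, sel, axis=1))


def _neighbor_weights(dist: np.ndarray, weighting: str) -> np.ndarray:
    """(B, kappa) weights summing to 1 per row."""
    if weighting == "uniform":
        return np.full_like(dist, 1.0 / dist.shape[1])
    w = np.empty_like(dist)
    zero = dist <= 0.0
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        w = 1.0 / np.where(zero, np.inf, dist)
    w[any_zero] = zero[any_zero].astype(float)  # all mass on exact matches
    return w / w.sum(axis=1, keepdims=True)


def predict_batch(queries: np.ndarray, lib: DelayLibrary, cfg: EmbeddingConfig,
                  lead: int = 1) -> np.ndarray:
    """Locally constant prediction for a batch of delay-vector queries."""
    if not 1 <= lead <= lib.max_lead:
        raise ValueError(f"lead {lead} outside stored range 1..{lib.max_lead}")
    idx, dist = knn_lookup(queries, lib, cfg.kappa, cfg.theiler)
    w = _neighbor_weights(dist, cfg.weighting)
    return np.sum(w * lib.futures[idx, lead - 1], axis=1)


def local_constant_predict(query: np.ndarray, lib: DelayLibrary,
                           cfg: EmbeddingConfig, lead: int = 1) -> float:
    """Weighted average of the kappa nearest neighbors' ``lead``-step futures."""
    return float(predict_batch(np.atleast_2d(query), lib, cfg, lead)[0])


def terminal_delay_vector(series: np.ndarray, cfg: EmbeddingConfig) -> np.ndarray:
    x = np.asarray(series, dtype=float).ravel()
    span = cfg.d * cfg.tau
    if x.size <= span:
        raise ValueError("series too short to embed")
    return x[-1 - np.arange(0, span + 1, cfg.tau)]


def direct_forecast(series: np.ndarray, cfg: EmbeddingConfig, horizon: int,
                    lib: DelayLibrary | None = None) -> np.ndarray:
    """Direct (non-iterated) forecast of leads 1..horizon.

    Every lead is predicted independently from the *same* terminal delay
    vector, using the neighbors' i-step futures; errors therefore do not
    compound through iteration.
    """
    if lib is None:
        lib = build_delay_library(series, cfg, max_lead=horizon)
    elif lib.max_lead < horizon:
        raise ValueError("library does not store futures out to the horizon")
    q = np.atleast_2d(terminal_delay_vector(series, cfg))
    idx, dist = knn_lookup(q, lib, cfg.kappa, cfg.theiler)
    w = _neighbor_weights(dist, cfg.weighting)
    return np.sum(w[0][:, None] * lib.futures[idx[0], :horizon], axis=0)


# ---------------------------------------------------------------------------
# Kalman-Takens denoising


def _denoise_1d(x: np.ndarray, cfg: EmbeddingConfig, q: float, r: float,
                lam: float | None, smoothing_lag: int | None) -> np.ndarray:
    from .ukf import GaussianBelief, UKFConfig, ukf_step  # local: avoid cycle

    span = cfg.d * cfg.tau
    lib = build_delay_library(x, cfg, max_lead=1)
    stride = np.arange(0, span + 1, cfg.tau)
    L = min(5, span) if smoothing_lag is None else min(smoothing_lag, span)

    def advance(points: np.ndarray) -> np.ndarray:
        pred = predict_batch(points[:, stride], lib, cfg, lead=1)
        out = np.empty_like(points)
        out[:, 0] = pred
        out[:, 1:] = points[:, :-1]
        return out

    ucfg = UKFConfig(Q=np.eye(span + 1) * q, R=np.array([[r]]),
                     P0=np.eye(span + 1) * max(r, q), obs_indices=np.array([0]),
                     lam=lam)
    belief = GaussianBelief(mean=x[span::-1].copy(), cov=ucfg.P0)
    out = x.copy()
    for k in range(span + 1, x.size):
        belief = ukf_step(belief, advance, x[k : k + 1], ucfg)
        if not np.all(np.isfinite(belief.mean)):
            raise RuntimeError(f"Kalman-Takens filter diverged at sample {k}")
        # fixed-lag smoothed output: the lag-L coordinate of the delay-vector
        # state is the estimate of sample k-L refined by L later observations
        # (a purely causal output both lags the signal by a fraction of a
        # sample and shrinks its peaks)
        out[k - L] = belief.mean[L]
    for j in range(L):
        out[x.size - 1 - j] = belief.mean[j]
    return out


def kalman_takens_denoise(noisy: np.ndarray, cfg: EmbeddingConfig,
                          q: float | None = None, r: float = 1.0,
                          lam: float | None = 0.0,
                          smoothing_lag: int | None = None) -> np.ndarray:
    """Model-free filtering of a (possibly multivariate) series.

    Each variable is embedded separately; an unscented filter whose state
    is the delay vector and whose advancement is the lead-1 local-constant
    predictor (library drawn from the noisy series itself) assimilates the
    samples in order.  ``q`` is the white process-noise variance standing in
    for nonparametric model error, ``r`` the observation-noise variance.
    Output has the same shape and timestamps as the input; the first
    d*tau + 1 samples (one embedding window) pass through unfiltered.
    """
    if q is None:
        q = r
    arr = np.asarray(noisy, dtype=float)
    if arr.ndim == 1:
        return _denoise_1d(arr, cfg, q, r, lam, smoothing_lag)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[:, j] = _denoise_1d(arr[:, j], cfg, q, r, lam, smoothing_lag)
    return out


# ---------------------------------------------------------------------------
# Cross-validated embedding selection


def select_embedding_cv(series: np.ndarray, d_grid: Sequence[int],
                        tau_grid: Sequence[int], kappa_grid: Sequence[int],
                        validation_fraction: float = 0.25,
                        horizon: int = 10,
                        weighting: str = "uniform") -> EmbeddingConfig:
    """Grid search over (d, tau, kappa) by within-sample direct prediction.

    The series is split into an earlier sub-training block and a later
    validation block; each grid point builds its library from the sub-train
    block only and direct-forecasts from every anchor in the validation
    block.  The configuration with the smallest mean normalized RMS error
    over leads 1..horizon wins; ties go to the earlier grid point, so the
    selection is deterministic.
    """
    x = np.asarray(series, dtype=float).ravel()
    if not (d_grid and tau_grid and kappa_grid):
        raise ValueError("grids must be nonempty")
    n_val = max(int(round(validation_fraction * x.size)), horizon + 1)
    split = x.size - n_val
    train = x[:split]
    sd = float(np.std(train))
    if sd == 0:
        sd = 1.0
    best: tuple[float, EmbeddingConfig] | None = None
    for d in d_grid:
        for tau in tau_grid:
            span = d * tau
            for kappa in kappa_grid:
                cfg = EmbeddingConfig(d=d, tau=tau, kappa=kappa, weighting=weighting)
                try:
                    lib = build_delay_library(train, cfg, max_lead=horizon)
                    if lib.searchable.size < kappa:
                        continue
                except ValueError:
                    continue
                # anchors: every time in the validation block from which all
                # `horizon` targets exist
                anchors = np.arange(max(split - 1, span), x.size - horizon)
                lags = np.arange(0, span + 1, tau)
                Qs = x[anchors[:, None] - lags[None, :]]
                idx, dist = knn_lookup(Qs, lib, kappa, cfg.theiler)
                w = _neighbor_weights(dist, weighting)
                preds = np.einsum("bk,bkl->bl", w, lib.futures[idx, :horizon])
                truth = x[anchors[:, None] + np.arange(1, horizon + 1)[None, :]]
                score = float(np.sqrt(np.mean(((preds - truth) / sd) ** 2)))
                if best is None or score < best[0] - 1e-15:
                    best = (score, cfg)
    if best is None:
        raise ValueError("no feasible grid point: series too short")
    return best[1]


# ---------------------------------------------------------------------------
# flat CSV export for inspection / fixtures


def library_to_frame(lib: DelayLibrary):
    import pandas as pd

    cols = {"row": np.arange(lib.n_rows), "source_time": lib.source_times}
    for j in range(lib.vectors.shape[1]):
        cols[f"coord_{j}"] = lib.vectors[:, j]
    for i in range(lib.max_lead):
        cols[f"future_{i + 1}"] = lib.futures[:, i]
    return pd.DataFrame(cols)


def library_from_frame(frame) -> DelayLibrary:
    coord_cols = [c for c in frame.columns if c.startswith("coord_")]
    fut_cols = [c for c in frame.columns if c.startswith("future_")]
    vectors = frame[coord_cols].to_numpy(dtype=float)
    futures = frame[fut_cols].to_numpy(dtype=float)
    st = frame["source_time"].to_numpy(dtype=int)
    tau = int(st[1] - st[0]) if st.size > 1 else 1
    # source times step by one sample; tau is recovered from the lag structure
    d = vectors.shape[1] - 1
    tau = int(st[0] // d) if d > 0 else 1
    return DelayLibrary(vectors=vectors, futures=futures, source_times=st,
                        d=d, tau=max(tau, 1))
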