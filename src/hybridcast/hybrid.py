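"""Hybrid mechanistic/nonparametric state-space engine.

A hybrid model keeps a subset of a mechanistic model's equations and
replaces the remaining (observed) variables with delay-coordinate
nonparametric advancement.  The filter state is

    [mechanistic values | per replaced variable: its last d*tau+1 samples |
     retained parameters]

Mechanistic variables advance one sample through the integrator with the
replaced variables held at their current values; each replaced variable
advances by a lead-1 local-constant (k-NN) prediction from a library built
on Kalman-Takens-denoised training data, its lag entries shifting by one
slot.  Parameters whose equations were replaced drop out of the estimation
problem entirely, which is the source of the method's robustness to large
initial parameter uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .models import ModelSpec, Trajectory, rk4_step
from .takens import (DelayLibrary, EmbeddingConfig, build_delay_library,
                     kalman_takens_denoise, predict_batch)
from .ukf import (FilterDivergence, GaussianBelief, UKFConfig, ukf_step)

__all__ = [
    "HybridSpec",
    "HybridLayout",
    "make_hybrid_spec",
    "hybrid_advance_points",
    "hybrid_advance",
    "run_hybrid_ukf",
    "hybrid_forecast",
    "HybridUKFResult",
]


@dataclass(frozen=True)
class HybridSpec:
    """Partition of a model into retained, replaced and dropped variables.

    ``dropped_vars`` are unobserved variables whose equations are neither
    retained nor replaceable and which no retained equation reads (e.g. the
    recovery variables of neurons represented purely by their membrane
    potential's delay coordinates); they simply leave the state.
    """

    model: ModelSpec
    mechanistic_vars: tuple[str, ...]
    nonparametric_vars: tuple[str, ...]
    dropped_vars: tuple[str, ...]
    retained_params: tuple[str, ...]
    embedding: Mapping[str, EmbeddingConfig]

    def __post_init__(self):
        groups = (set(self.mechanistic_vars), set(self.nonparametric_vars),
                  set(self.dropped_vars))
        if set.union(*groups) != set(self.model.state_names) or \
                sum(len(g) for g in groups) != self.model.n_state:
            raise ValueError("mechanistic/nonparametric/dropped must partition the state")
        unobs = set(self.nonparametric_vars) - set(self.model.observed)
        if unobs:
            raise ValueError(
                f"cannot replace unobserved variables {sorted(unobs)}: nonparametric "
                "advancement needs observations that map directly to them")
        for v in self.mechanistic_vars:
            bad = set(self.model.state_deps.get(v, ())) & set(self.dropped_vars)
            if bad:
                raise ValueError(f"retained equation {v} reads dropped vars {sorted(bad)}")


def make_hybrid_spec(model: ModelSpec, replace: Sequence[str],
                     embedding: EmbeddingConfig | Mapping[str, EmbeddingConfig],
                     free_params: Sequence[str] | None = None) -> HybridSpec:
    """Build a hybrid spec replacing ``replace`` variables nonparametrically.

    The retained mechanistic block is the dependency closure of the
    observed, non-replaced variables: equations are kept only while some
    kept equation needs them.  Unobserved variables outside that closure are
    dropped (their dynamics are subsumed by the replaced variables' delay
    coordinates).  Retained parameters are the free parameters appearing in
    at least one retained equation; parameters owned solely by replaced or
    dropped equations leave the estimation problem.
    """
    replace = tuple(replace)
    unknown = set(replace) - set(model.state_names)
    if unknown:
        raise ValueError(f"unknown state variables: {sorted(unknown)}")
    if set(model.observed) <= set(replace):
        raise ValueError("cannot replace every observed equation; "
                         "use the nonparametric method")
    keep = {v for v in model.observed if v not in replace}
    frontier = set(keep)
    while frontier:
        nxt = set()
        for v in frontier:
            for dep in model.state_deps.get(v, ()):
                if dep not in keep and dep not in replace:
                    nxt.add(dep)
        keep |= nxt
        frontier = nxt
    mech = tuple(s for s in model.state_names if s in keep)
    nonp = tuple(s for s in model.state_names if s in replace)
    dropped = tuple(s for s in model.state_names if s not in keep and s not in replace)
    free = tuple(free_params) if free_params is not None else model.free_params
    needed = set()
    for s in mech:
        needed |= set(model.param_deps.get(s, ()))
    retained = tuple(p for p in model.param_names if p in needed and p in free)
    if isinstance(embedding, EmbeddingConfig):
        embedding = {v: embedding for v in nonp}
    return HybridSpec(model=model, mechanistic_vars=mech, nonparametric_vars=nonp,
                      dropped_vars=dropped, retained_params=retained,
                      embedding=dict(embedding))


@dataclass(frozen=True)
class HybridLayout:
    """Index bookkeeping for the flattened hybrid filter state."""

    spec: HybridSpec
    n_params: int

    @property
    def mech_slice(self) -> slice:
        return slice(0, len(self.spec.mechanistic_vars))

    def block_slice(self, var: str) -> slice:
        start = len(self.spec.mechanistic_vars)
        for v in self.spec.nonparametric_vars:
            emb = self.spec.embedding[v]
            size = emb.d * emb.tau + 1
            if v == var:
                return slice(start, start + size)
            start += size
        raise KeyError(var)

    @property
    def param_slice(self) -> slice:
        start = len(self.spec.mechanistic_vars)
        for v in self.spec.nonparametric_vars:
            emb = self.spec.embedding[v]
            start += emb.d * emb.tau + 1
        return slice(start, start + self.n_params)

    @property
    def dim(self) -> int:
        return self.param_slice.stop

    @property
    def mech_state_idx(self) -> np.ndarray:
        names = self.spec.model.state_names
        return np.array([names.index(v) for v in self.spec.mechanistic_vars], dtype=int)

    @property
    def nonp_state_idx(self) -> np.ndarray:
        names = self.spec.model.state_names
        return np.array([names.index(v) for v in self.spec.nonparametric_vars], dtype=int)

    @property
    def obs_indices(self) -> np.ndarray:
        """Hybrid-state positions of the model's observed variables, in
        the model's observation order."""
        out = []
        for v in self.spec.model.observed:
            if v in self.spec.mechanistic_vars:
                out.append(self.spec.mechanistic_vars.index(v))
            else:
                out.append(self.block_slice(v).start)
        return np.array(out, dtype=int)


def _full_params(spec: HybridSpec, layout: HybridLayout,
                 points: np.ndarray) -> np.ndarray:
    model = spec.model
    B = points.shape[0]
    full = np.broadcast_to(model.true_params, (B, model.true_params.size)).copy()
    if layout.n_params:
        idx = [model.param_names.index(p) for p in spec.retained_params]
        full[:, idx] = points[:, layout.param_slice]
    return full


def hybrid_advance_points(points: np.ndarray, spec: HybridSpec,
                          libs: Mapping[str, DelayLibrary],
                          layout: HybridLayout,
                          pinned: np.ndarray | None = None) -> np.ndarray:
    """Advance a batch of hybrid states one sample interval.

    Replaced variables advance by the lead-1 local-constant prediction of
    their own delay vector (lag rings shift); mechanistic components then
    integrate one step (RK4 for continuous systems, the map for discrete
    ones) with the replaced variables interpolated across the step.

    ``pinned``, when given, is a (2, n_nonparametric) array of (current,
    next) values of the replaced variables taken from the training data;
    the retained equations are then driven by these observed values instead
    of each sigma point's own delay coordinates (used while fitting, where
    the replaced variables' samples are known; forecasting always couples
    through the state).
    """
    model = spec.model
    points = np.atleast_2d(points)
    B = points.shape[0]
    out = points.copy()
    mech_idx = layout.mech_state_idx
    nonp_idx = layout.nonp_state_idx
    full_params = _full_params(spec, layout, points)
    h = model.sample_interval

    # replaced variables advance first: lead-1 local-constant prediction of
    # each one's own delay vector, lag ring shifting by one slot.  When the
    # next sample is pinned from training data the neighbor lookup is moot
    # (every sigma point would be overridden by the same known value), so
    # the ring simply shifts the pinned sample in.
    current = np.empty((B, nonp_idx.size))
    predicted = np.empty((B, nonp_idx.size))
    for j, v in enumerate(spec.nonparametric_vars):
        emb = spec.embedding[v]
        sl = layout.block_slice(v)
        ring = points[:, sl]
        if pinned is None:
            stride = np.arange(0, emb.d * emb.tau + 1, emb.tau)
            pred = predict_batch(ring[:, stride], libs[v], emb, lead=1)
        else:
            pred = np.full(B, pinned[1, j])
        current[:, j] = ring[:, 0]
        predicted[:, j] = pred
        out[:, sl.start] = pred
        out[:, sl.start + 1 : sl.stop] = ring[:, :-1]
    if pinned is not None:
        current = np.broadcast_to(pinned[0], current.shape)

    if mech_idx.size:
        if model.kind == "continuous":
            # replaced variables enter the retained equations interpolated
            # linearly between their current value and their one-step
            # prediction; a zero-order hold would alias their fast motion
            # into the retained parameters.
            def rhs_mech(t, mech_vals, params):
                # dropped variables stay 0: no retained equation reads them
                fs = np.zeros(mech_vals.shape[:-1] + (model.n_state,))
                fs[..., mech_idx] = mech_vals
                frac = t / h
                fs[..., nonp_idx] = (1.0 - frac) * current + frac * predicted
                return model.rhs_or_map(t, fs, params)[..., mech_idx]

            out[:, layout.mech_slice] = rk4_step(
                rhs_mech, 0.0, points[:, layout.mech_slice], h, full_params)
        else:
            full_state = np.zeros((B, model.n_state))
            full_state[:, mech_idx] = points[:, layout.mech_slice]
            full_state[:, nonp_idx] = current
            nxt = model.rhs_or_map(0.0, full_state, full_params)
            out[:, layout.mech_slice] = nxt[:, mech_idx]
    return out


def hybrid_advance(hstate: np.ndarray, spec: HybridSpec,
                   libs: Mapping[str, DelayLibrary],
                   layout: HybridLayout | None = None) -> np.ndarray:
    """Single-state convenience wrapper around :func:`hybrid_advance_points`."""
    if layout is None:
        layout = HybridLayout(spec=spec, n_params=len(spec.retained_params))
    return hybrid_advance_points(np.atleast_2d(hstate), spec, libs, layout)[0]


@dataclass
class HybridUKFResult:
    final_belief: GaussianBelief
    param_history: np.ndarray
    estimate_names: tuple[str, ...]
    spec: HybridSpec
    layout: HybridLayout
    libs: dict[str, DelayLibrary]
    start_index: int

    @property
    def final_params(self) -> np.ndarray:
        return self.param_history[-1]


def default_hybrid_config(spec: HybridSpec, layout: HybridLayout,
                          init_params: np.ndarray, noise_variance: float,
                          uncertainty: float, lam: float | None = 0.0,
                          q_state: float | None = None,
                          q_nonp: float | None = None,
                          q_param_rel: float = 1e-6,
                          param_scale: np.ndarray | None = None) -> UKFConfig:
    """Covariance defaults mirroring the fully parametric filter.

    The replaced variables' current coordinates get a larger process noise
    ``q_nonp`` reflecting one-step nonparametric prediction error; their lag
    entries shift deterministically and get a negligible floor.
    """
    model = spec.model
    init_params = np.asarray(init_params, dtype=float)
    scale = np.abs(init_params) if param_scale is None else np.abs(np.asarray(param_scale, dtype=float))
    if q_state is None:
        base = 1e-4 * model.sample_interval if model.kind == "continuous" else 1e-4
        q_state = np.full(len(spec.mechanistic_vars), base)
        for v in spec.mechanistic_vars:
            if v in model.observed:
                q_state[spec.mechanistic_vars.index(v)] = max(noise_variance, base)
    if q_nonp is None:
        q_nonp = max(noise_variance, 1e-8)
    q = np.zeros(layout.dim)
    q[layout.mech_slice] = q_state
    p0 = np.ones(layout.dim)
    obs_in_mech = [v for v in spec.mechanistic_vars if v in model.observed]
    for v in obs_in_mech:
        p0[spec.mechanistic_vars.index(v)] = max(noise_variance, 1e-8)
    for v in spec.nonparametric_vars:
        sl = layout.block_slice(v)
        q[sl] = 1e-10
        q[sl.start] = q_nonp
        p0[sl] = max(noise_variance, 1e-8)
    ps = layout.param_slice
    q[ps] = np.maximum(q_param_rel * scale**2, 1e-12)
    p0[ps] = np.maximum((uncertainty * scale) ** 2, 1e-8)
    return UKFConfig(Q=np.diag(q), R=np.eye(model.obs_indices.size) * max(noise_variance, 1e-12),
                     P0=np.diag(p0), obs_indices=layout.obs_indices, lam=lam)


def run_hybrid_ukf(noisy: Trajectory, spec: HybridSpec, init_params: np.ndarray,
                   cfg: UKFConfig | None = None, *,
                   noise_variance: float | None = None,
                   uncertainty: float | None = None,
                   denoise: bool = True, kt_q: float | None = None,
                   lam: float | None = 0.0,
                   training_series: Mapping[str, np.ndarray] | None = None,
                   coupling: str = "obs",
                   build_libraries: bool = True) -> HybridUKFResult:
    """Joint UKF over the hybrid state on one training series.

    Libraries for nonparametric advancement are built (per replaced
    variable) from the Kalman-Takens-denoised training data; the filter then
    assimilates the raw noisy observations in order, starting once a full
    embedding window is available.

    ``coupling`` controls how replaced variables enter the retained
    equations during fitting.  Within the training window the replaced
    variables' samples are known, so the retained equations can be driven
    by the raw observed samples (``"obs"``, default) or by the denoised
    samples (``"data"``); with ``"state"`` each sigma point's own delay
    coordinates drive the retained equations, exactly as in forecasting.
    Observation-driven coupling is the least biased: the locally constant
    predictor and the smoother both regress toward the attractor mean, and
    that shrinkage leaks into the retained parameters as a multiplicative
    inflation, whereas the raw samples are unbiased in the regressor.
    """
    if coupling not in ("obs", "data", "state"):
        raise ValueError("coupling must be 'obs', 'data' or 'state'")
    if coupling == "state" and not build_libraries:
        raise ValueError("state coupling requires libraries")
    model = spec.model
    init_params = np.asarray(init_params, dtype=float)
    if init_params.shape != (len(spec.retained_params),):
        raise ValueError("init_params must cover exactly the retained parameters")
    layout = HybridLayout(spec=spec, n_params=len(spec.retained_params))
    if cfg is None:
        if noise_variance is None or uncertainty is None:
            raise ValueError("either cfg or (noise_variance, uncertainty) required")
        cfg = default_hybrid_config(spec, layout, init_params, noise_variance,
                                    uncertainty, lam=lam)
    libs: dict[str, DelayLibrary] = {}
    series: dict[str, np.ndarray] = {}
    r_var = float(cfg.R[0, 0])
    want_filtered = build_libraries or coupling == "data"
    for v in spec.nonparametric_vars:
        emb = spec.embedding[v]
        if training_series is not None and v in training_series:
            filtered = np.asarray(training_series[v], dtype=float)
        elif denoise and want_filtered:
            filtered = kalman_takens_denoise(noisy.column(v), emb, q=kt_q,
                                             r=r_var, lam=lam)
        else:
            filtered = noisy.column(v).copy()
        series[v] = filtered
        if build_libraries:
            libs[v] = build_delay_library(filtered, emb, max_lead=1)

    k0 = max((spec.embedding[v].d * spec.embedding[v].tau
              for v in spec.nonparametric_vars), default=0)
    mean0 = np.zeros(layout.dim)
    if model.default_state_guess is not None:
        mean0[layout.mech_slice] = model.default_state_guess[layout.mech_state_idx]
    for v in spec.mechanistic_vars:
        if v in model.observed:
            mean0[spec.mechanistic_vars.index(v)] = noisy.column(v)[k0]
    for v in spec.nonparametric_vars:
        sl = layout.block_slice(v)
        mean0[sl] = series[v][k0::-1][: sl.stop - sl.start]
    mean0[layout.param_slice] = init_params
    belief = GaussianBelief(mean=mean0, cov=cfg.P0)
    T = noisy.values.shape[0]

    obs_seq = noisy.values[:, model.obs_indices]
    history = np.empty((T - k0, len(spec.retained_params)))
    history[0] = init_params
    source = noisy.column if coupling == "obs" else series.__getitem__
    data_track = (np.stack([source(v) for v in spec.nonparametric_vars], axis=1)
                  if spec.nonparametric_vars else np.zeros((T, 0)))
    for k in range(k0 + 1, T):
        pinned = data_track[k - 1 : k + 1] if coupling != "state" else None

        def advance(points: np.ndarray) -> np.ndarray:
            return hybrid_advance_points(points, spec, libs, layout, pinned=pinned)

        belief = ukf_step(belief, advance, obs_seq[k], cfg)
        if not (np.all(np.isfinite(belief.mean)) and np.all(np.isfinite(belief.cov))):
            raise FilterDivergence(k)
        history[k - k0] = belief.mean[layout.param_slice]
    return HybridUKFResult(final_belief=belief, param_history=history,
                           estimate_names=spec.retained_params, spec=spec,
                           layout=layout, libs=libs, start_index=k0)


def hybrid_forecast(result: HybridUKFResult, horizon: int) -> np.ndarray:
    """Iterate the hybrid advancement from the final state estimate.

    Parameters stay frozen at their final estimates and libraries at their
    training contents.  Returns forecasts of all model state variables for
    steps T+1..T+horizon (shape (horizon, n_state), model state order).
    If the iteration blows up, the remaining horizon is filled with the
    last finite values and a warning is logged.
    """
    import logging
    spec, layout = result.spec, result.layout
    model = spec.model
    state = result.final_belief.mean.copy()
    out = np.empty((horizon, model.n_state))
    last_good = None
    for i in range(horizon):
        state = hybrid_advance_points(state[None, :], spec, result.libs, layout)[0]
        if not np.all(np.isfinite(state)):
            logging.getLogger(__name__).warning(
                "hybrid forecast blow-up at lead %d; holding last finite value", i + 1)
            fill = out[i - 1] if i > 0 else np.full(model.n_state, np.nan)
            out[i:] = fill
            break
        row = np.full(model.n_state, np.nan)  # dropped variables have no estimate
        row[layout.mech_state_idx] = state[layout.mech_slice]
        for v in spec.nonparametric_vars:
            row[model.state_names.index(v)] = state[layout.block_slice(v).start]
        out[i] = row
    return out
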