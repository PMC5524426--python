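"""Unscented Kalman filtering with joint state-parameter estimation.

The filter maintains a Gaussian belief (mean, covariance) over a possibly
augmented state.  Sigma points are generated symmetrically along the
columns of an SVD square root of the covariance, propagated through the
(nonlinear) one-step advancement, and recombined with the standard
unscented weights.  Parameters are estimated jointly by appending them to
the state with trivial dynamics p(k+1) = p(k) plus a small random-walk
covariance, which is what lets the filter keep adapting them.

The observation model throughout is a selection of state components
(direct, possibly partial, observation) with additive Gaussian noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .models import ModelSpec, Trajectory, rk4_step

__all__ = [
    "GaussianBelief",
    "UKFConfig",
    "SigmaEnsemble",
    "FilterDivergence",
    "generate_sigma_points",
    "ukf_step",
    "draw_initial_parameters",
    "run_joint_ukf",
    "default_ukf_config",
    "parametric_forecast",
    "JointUKFResult",
]

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-10


class FilterDivergence(RuntimeError):
    """Raised when the filter state or covariance becomes non-finite."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"filter diverged at step {step}")


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return 0.5 * (P + P.T)


@dataclass
class GaussianBelief:
    """Mean and covariance of the (augmented) filter state."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        P = np.asarray(self.cov, dtype=float)
        if P.ndim == 1:
            P = np.diag(P)
        if P.shape != (self.mean.size, self.mean.size):
            raise ValueError("mean and cov dimensions disagree")
        self.cov = _symmetrize(P)

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass
class UKFConfig:
    """Noise covariances and sigma-point scaling for one filter run.

    Q and R may be given as full matrices or diagonal vectors.  ``lam`` is
    the unscented scaling parameter: sigma points sit at sqrt(n + lam)
    times the covariance square-root columns, with center weight
    lam/(n+lam).  ``lam=None`` uses the common lam = 3 - n convention;
    ``lam=0.0`` gives the equally weighted symmetric set (no center mass),
    which is markedly more robust for high-dimensional augmented states
    and is what the experiment presets use.
    """

    Q: np.ndarray
    R: np.ndarray
    P0: np.ndarray
    obs_indices: np.ndarray
    lam: float | None = None

    def __post_init__(self):
        self.obs_indices = np.asarray(self.obs_indices, dtype=int)
        for name in ("Q", "R", "P0"):
            M = np.asarray(getattr(self, name), dtype=float)
            if M.ndim == 1:
                M = np.diag(M)
            setattr(self, name, M)
        if self.R.shape[0] != self.obs_indices.size:
            raise ValueError("R dimension must equal the number of observations")


@dataclass(frozen=True)
class SigmaEnsemble:
    points: np.ndarray        # (2n+1, n)
    mean_weights: np.ndarray  # (2n+1,)
    cov_weights: np.ndarray   # (2n+1,)


def generate_sigma_points(belief: GaussianBelief, lam: float | None = None) -> SigmaEnsemble:
    """Symmetric 2n+1 sigma points along SVD square-root columns.

    The SVD is applied to the symmetrized covariance; numerically negative
    directions are clipped at zero (with a warning) rather than failing.
    """
    n = belief.dim
    if lam is None:
        lam = 3.0 - n
    P = _symmetrize(belief.cov)
    U, s, _ = np.linalg.svd(P, hermitian=True)
    if np.any(s < -_SYM_TOL):
        logger.warning("covariance repair: clipping negative spectrum %.3e", s.min())
    s = np.clip(s, 0.0, None)
    root = U * np.sqrt(s)
    spread = np.sqrt(n + lam)
    pts = np.empty((2 * n + 1, n))
    pts[0] = belief.mean
    pts[1 : n + 1] = belief.mean + spread * root.T
    pts[n + 1 :] = belief.mean - spread * root.T
    w = np.full(2 * n + 1, 1.0 / (2.0 * (n + lam)))
    w[0] = lam / (n + lam)
    return SigmaEnsemble(points=pts, mean_weights=w, cov_weights=w.copy())


def _weighted_cov(dev_a: np.ndarray, dev_b: np.ndarray, w: np.ndarray) -> np.ndarray:
    return (dev_a * w[:, None]).T @ dev_b


def ukf_step(belief: GaussianBelief, advance: Callable[[np.ndarray], np.ndarray],
             obs: np.ndarray, cfg: UKFConfig) -> GaussianBelief:
    """One predict-update cycle of the unscented filter.

    ``advance`` maps the (2n+1, n) sigma matrix one sample interval forward,
    row-wise.  The prior mean is the weighted ensemble mean and the prior
    covariance the weighted ensemble covariance plus Q.  Because the
    observation operator is a plain component selection, the observation
    statistics of the Q-inflated prior are available in closed form
    (y- = x-[H], Py = P-[H,H] + R, Pxy = P-[:,H]), which is exactly what a
    second unscented pass through the linear h would produce; the gain
    K = Pxy (Py)^-1 then folds in the observation.
    """
    sig = generate_sigma_points(belief, cfg.lam)
    # overflow in a diverging sigma point surfaces as a non-finite belief,
    # which callers detect; the intermediate warnings are suppressed
    with np.errstate(over="ignore", invalid="ignore"):
        X = np.asarray(advance(sig.points))
        obs = np.asarray(obs, dtype=float).ravel()
        wm, wc = sig.mean_weights, sig.cov_weights
        xm = wm @ X
        Dx = X - xm
        P_prior = _symmetrize(_weighted_cov(Dx, Dx, wc) + cfg.Q)
    H = cfg.obs_indices
    ym = xm[H]
    Py = _symmetrize(P_prior[np.ix_(H, H)] + cfg.R)
    Pxy = P_prior[:, H]
    try:
        K = np.linalg.solve(Py, Pxy.T).T
    except np.linalg.LinAlgError:
        logger.warning("singular innovation covariance (cond=%.3e); using pseudo-inverse",
                       np.linalg.cond(Py))
        K = Pxy @ np.linalg.pinv(Py)
    mean = xm + K @ (obs - ym)
    cov = _symmetrize(P_prior - K @ Py @ K.T)
    return GaussianBelief(mean=mean, cov=cov)


def draw_initial_parameters(true_params: np.ndarray, uncertainty: float,
                            seed: int | np.random.Generator) -> np.ndarray:
    """Draw starting parameter guesses from N(p, (u*p)^2) componentwise.

    ``uncertainty`` is the fractional standard deviation relative to the
    true value; u = 0 returns the truth exactly.
    """
    if uncertainty < 0:
        raise ValueError("uncertainty must be nonnegative")
    p = np.asarray(true_params, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(p, np.abs(uncertainty * p))


def default_ukf_config(model: ModelSpec, estimate_params: Sequence[str],
                       init_params: np.ndarray, noise_variance: float,
                       uncertainty: float, lam: float | None = None,
                       q_state: float | None = None,
                       q_param_rel: float = 1e-6,
                       param_scale: np.ndarray | None = None) -> UKFConfig:
    """Covariance defaults for a joint filter run on ``model``.

    Process noise: a small diagonal state block (scaled by the sample
    interval for continuous systems) plus a parameter random walk of
    relative size ``q_param_rel`` * p^2.  R is the known observation noise.
    P0 puts (u*p)^2 on parameter entries, the observation-noise variance on
    observed states and 1.0 on unobserved states.  ``param_scale`` sets the
    magnitude p used for the parameter blocks; it defaults to |init_params|,
    but when the generative prior is known (simulation studies) the true
    parameter magnitudes should be passed so that a draw near zero does not
    freeze its own entry.
    """
    n, l = model.n_state, len(estimate_params)
    init_params = np.asarray(init_params, dtype=float)
    scale = np.abs(init_params) if param_scale is None else np.abs(np.asarray(param_scale, dtype=float))
    q = np.empty(n + l)
    if q_state is None:
        # coarse-sampling model error on observed components is absorbed by a
        # process noise of the same size as the measurement noise; unobserved
        # components keep a small floor
        base = 1e-4 * model.sample_interval if model.kind == "continuous" else 1e-4
        q[:n] = base
        q[model.obs_indices] = max(noise_variance, base)
    else:
        q[:n] = q_state
    q[n:] = np.maximum(q_param_rel * scale**2, 1e-12)
    p0 = np.ones(n + l)
    p0[model.obs_indices] = max(noise_variance, 1e-8)
    p0[n:] = np.maximum((uncertainty * scale) ** 2, 1e-8)
    return UKFConfig(Q=np.diag(q), R=np.eye(model.obs_indices.size) * max(noise_variance, 1e-12),
                     P0=np.diag(p0), obs_indices=model.obs_indices, lam=lam)


@dataclass
class JointUKFResult:
    final_belief: GaussianBelief
    param_history: np.ndarray  # (steps, n_estimated) posterior parameter means
    estimate_names: tuple[str, ...]

    @property
    def final_params(self) -> np.ndarray:
        return self.param_history[-1]


def _make_joint_advance(model: ModelSpec, estimate_idx: np.ndarray):
    """Row-wise advancement of [state; estimated params] by one sample."""
    n = model.n_state
    h = model.sample_interval
    true_p = model.true_params

    def advance(points: np.ndarray) -> np.ndarray:
        states = points[:, :n]
        est = points[:, n:]
        full = np.broadcast_to(true_p, (points.shape[0], true_p.size)).copy()
        full[:, estimate_idx] = est
        if model.kind == "continuous":
            new_states = rk4_step(model.rhs_or_map, 0.0, states, h, full)
        else:
            new_states = model.rhs_or_map(0.0, states, full)
        return np.hstack([new_states, est])

    return advance


def run_joint_ukf(noisy: Trajectory, model: ModelSpec,
                  estimate_params: Sequence[str], init_params: np.ndarray,
                  cfg: UKFConfig | None = None, *,
                  noise_variance: float | None = None,
                  uncertainty: float | None = None,
                  init_state: np.ndarray | None = None) -> JointUKFResult:
    """Process a training series with the joint (state + parameter) UKF.

    The augmented state is [model state; estimated parameters]; parameters
    advance by the identity and adapt only through the Kalman gain.  The
    first sample initializes the observed state components; the filter then
    assimilates samples 1..T-1 in order.  Returns the final belief and the
    per-step posterior parameter means.
    """
    estimate_params = tuple(estimate_params)
    unknown = set(estimate_params) - set(model.param_names)
    if unknown:
        raise ValueError(f"cannot estimate unknown parameters: {unknown}")
    estimate_idx = np.array([model.param_names.index(p) for p in estimate_params])
    init_params = np.asarray(init_params, dtype=float)
    if init_params.shape != (len(estimate_params),):
        raise ValueError("init_params length must match estimate_params")
    if cfg is None:
        if noise_variance is None or uncertainty is None:
            raise ValueError("either cfg or (noise_variance, uncertainty) required")
        cfg = default_ukf_config(model, estimate_params, init_params,
                                 noise_variance, uncertainty)
    n = model.n_state
    mean0 = np.zeros(n + len(estimate_params))
    if init_state is not None:
        mean0[:n] = init_state
    elif model.default_state_guess is not None:
        mean0[:n] = model.default_state_guess
    mean0[model.obs_indices] = noisy.values[0, model.obs_indices]
    mean0[n:] = init_params
    belief = GaussianBelief(mean=mean0, cov=cfg.P0)
    advance = _make_joint_advance(model, estimate_idx)
    T = noisy.values.shape[0]
    history = np.empty((T, len(estimate_params)))
    history[0] = init_params
    obs_seq = noisy.values[:, model.obs_indices]
    for k in range(1, T):
        belief = ukf_step(belief, advance, obs_seq[k], cfg)
        if not (np.all(np.isfinite(belief.mean)) and np.all(np.isfinite(belief.cov))):
            raise FilterDivergence(k)
        history[k] = belief.mean[n:]
    return JointUKFResult(final_belief=belief, param_history=history,
                          estimate_names=estimate_params)


def parametric_forecast(model: ModelSpec, result: JointUKFResult,
                        horizon: int) -> np.ndarray:
    """Forward-solve the model from the final state estimate.

    Parameters are frozen at their final estimates; returns the forecast
    values for steps T+1 .. T+horizon (shape (horizon, n_state)).
    """
    n = model.n_state
    params = model.true_params.copy()
    idx = np.array([model.param_names.index(p) for p in result.estimate_names])
    params[idx] = result.final_params
    x = result.final_belief.mean[:n]
    out = np.empty((horizon, n))
    for i in range(horizon):
        if model.kind == "continuous":
            x = rk4_step(model.rhs_or_map, 0.0, x, model.sample_interval, params)
        else:
            x = model.rhs_or_map(0.0, x, params)
        out[i] = x
    return out
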