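"""Built-in dynamical systems, integration, and synthetic training data.

Three testbed systems are provided through a small registry:

``lorenz63``
    The classical three-variable chaotic convection model.
``hindmarsh_rose``
    A network of M Hindmarsh-Rose neurons coupled through a sigmoidal
    gating function of the presynaptic membrane potential.
``lpa``
    The discrete-time larva-pupa-adult (LPA) map for flour beetle
    (*Tribolium castaneum*) population dynamics with cannibalism.

Continuous systems are sampled with a fourth-order Adams-Moulton
predictor-corrector (RK4 bootstrapped); discrete systems iterate their map
once per census step.  All right-hand sides are vectorized over leading
axes of both the state and the parameter vector so that filter ensembles
can be propagated in a single call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "ModelSpec",
    "NetworkSpec",
    "LPAParams",
    "BlowupError",
    "lorenz63_rhs",
    "hindmarsh_rose_rhs",
    "lpa_step",
    "lorenz63_model",
    "hindmarsh_rose_model",
    "lpa_model",
    "random_network",
    "get_model",
    "rk4_step",
    "integrate",
    "generate_training_data",
    "MODEL_REGISTRY",
]


class BlowupError(RuntimeError):
    """Raised when a trajectory leaves the finite range during integration."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite state at step {step}")


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled multivariate time series.

    Attributes
    ----------
    times : (T,) array of sample times, strictly increasing, constant spacing.
    values : (T, n) array, one column per state variable.
    state_names : column labels.
    """

    times: np.ndarray
    values: np.ndarray
    state_names: tuple[str, ...]

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if values.shape[0] != times.shape[0]:
            raise ValueError("times and values row counts differ")
        if len(self.state_names) != values.shape[1]:
            raise ValueError("state_names length does not match value columns")
        if times.size > 1:
            dt = np.diff(times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
                raise ValueError("times must be strictly increasing on a uniform grid")

    @property
    def sample_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.state_names.index(name)]


@dataclass(frozen=True)
class NetworkSpec:
    """Connectivity of a neuronal network.

    ``adjacency[i, m]`` is the coupling strength beta_im from neuron m onto
    neuron i.  Self connections are disallowed (zero diagonal).
    """

    size: int
    adjacency: np.ndarray

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=float)
        object.__setattr__(self, "adjacency", adj)
        if adj.shape != (self.size, self.size):
            raise ValueError("adjacency must be size x size")
        if np.any(adj < 0):
            raise ValueError("connection strengths must be nonnegative")
        if np.any(np.diag(adj) != 0):
            raise ValueError("self connections are not allowed (nonzero diagonal)")

    @property
    def n_connections(self) -> int:
        return int(np.count_nonzero(self.adjacency))


@dataclass(frozen=True)
class LPAParams:
    """Parameters of the discrete LPA map.

    b is the adult fecundity; c_el and c_ea the rates at which larvae and
    adults cannibalize eggs; c_pa the rate at which adults cannibalize
    pupae; mu_l and mu_a the larval and adult mortality fractions.
    """

    b: float
    c_el: float
    c_ea: float
    c_pa: float
    mu_l: float
    mu_a: float

    def __post_init__(self):
        for name in ("mu_l", "mu_a"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.b, self.c_el, self.c_ea, self.c_pa, self.mu_l, self.mu_a])


@dataclass(frozen=True)
class ModelSpec:
    """A mechanistic dynamical system usable by the simulators and filters.

    ``rhs_or_map(t, state, params)`` returns the state derivative for
    continuous systems or the next state for discrete ones; it must accept
    arrays with arbitrary leading axes for both ``state`` (..., n) and
    ``params`` (..., l).  ``param_deps`` records which parameters appear in
    each state equation and ``state_deps`` which state variables it reads;
    the hybrid engine uses them to drop parameters (and unobserved
    variables) whose equations were replaced.  ``free_params`` are the
    parameters treated as unknown when fitting (the rest are assumed
    known).
    """

    name: str
    state_names: tuple[str, ...]
    param_names: tuple[str, ...]
    true_params: np.ndarray
    kind: str  # "continuous" | "discrete"
    rhs_or_map: Callable[[float, np.ndarray, np.ndarray], np.ndarray]
    observed: tuple[str, ...]
    sample_interval: float
    param_deps: Mapping[str, frozenset]
    state_deps: Mapping[str, frozenset]
    free_params: tuple[str, ...]
    init_sampler: Callable[[np.random.Generator], np.ndarray]
    default_state_guess: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "true_params", np.asarray(self.true_params, dtype=float))
        if self.kind not in ("continuous", "discrete"):
            raise ValueError("kind must be 'continuous' or 'discrete'")
        if self.true_params.shape != (len(self.param_names),):
            raise ValueError("true_params length does not match param_names")
        unknown = set(self.observed) - set(self.state_names)
        if unknown:
            raise ValueError(f"observed names not in state: {unknown}")

    @property
    def n_state(self) -> int:
        return len(self.state_names)

    @property
    def obs_indices(self) -> np.ndarray:
        return np.array([self.state_names.index(s) for s in self.observed])

    def obs_map(self, state: np.ndarray) -> np.ndarray:
        """Observation function h: identity on the observed components."""
        return np.asarray(state)[..., self.obs_indices]

    def params_from(self, values: Mapping[str, float] | Sequence[float] | None) -> np.ndarray:
        """Full parameter vector with overrides applied on top of the truth."""
        p = self.true_params.copy()
        if values is None:
            return p
        if isinstance(values, Mapping):
            for k, v in values.items():
                p[self.param_names.index(k)] = v
        else:
            p = np.asarray(values, dtype=float)
            if p.shape != self.true_params.shape:
                raise ValueError("parameter vector has wrong length")
        return p


# ---------------------------------------------------------------------------
# Lorenz-63


def lorenz63_rhs(t, state, params):
    """Lorenz-63 vector field (sigma, rho, beta)."""
    state = np.asarray(state, dtype=float)
    params = np.asarray(params, dtype=float)
    x, y, z = state[..., 0], state[..., 1], state[..., 2]
    sig, rho, beta = params[..., 0], params[..., 1], params[..., 2]
    return np.stack([sig * (y - x), x * (rho - z) - y, x * y - beta * z], axis=-1)


def lorenz63_model(sample_interval: float = 0.05) -> ModelSpec:
    return ModelSpec(
        name="lorenz63",
        state_names=("x", "y", "z"),
        param_names=("sigma", "rho", "beta"),
        true_params=np.array([10.0, 28.0, 8.0 / 3.0]),
        kind="continuous",
        rhs_or_map=lorenz63_rhs,
        observed=("x", "y", "z"),
        sample_interval=sample_interval,
        param_deps={
            "x": frozenset({"sigma"}),
            "y": frozenset({"rho"}),
            "z": frozenset({"beta"}),
        },
        state_deps={
            "x": frozenset({"x", "y"}),
            "y": frozenset({"x", "y", "z"}),
            "z": frozenset({"x", "y", "z"}),
        },
        free_params=("sigma", "rho", "beta"),
        init_sampler=lambda rng: rng.normal([0.0, 0.0, 25.0], [5.0, 5.0, 10.0]),
    )


# ---------------------------------------------------------------------------
# Hindmarsh-Rose network


def _gating(x: np.ndarray) -> np.ndarray:
    """Sigmoidal gate g(x) = x / (1 + 9 exp(-10 x)); ~0 at rest, ~x at spike."""
    # exp argument clipped: for x << 0 the gate underflows to 0 anyway.
    e = np.exp(np.minimum(-10.0 * x, 60.0))
    out = x / (1.0 + 9.0 * e)
    return np.where(-10.0 * x > 60.0, 0.0, out)


def hindmarsh_rose_rhs(t, states, params, net: NetworkSpec):
    """Hindmarsh-Rose network vector field with a fixed connectivity matrix.

    ``states`` is grouped per neuron as (x_i, y_i, z_i); ``params`` is
    grouped per neuron as (a_i, b_i, c_i).  Coupling strengths come from
    ``net.adjacency``.
    """
    states = np.asarray(states, dtype=float)
    m = net.size
    if states.shape[-1] != 3 * m:
        raise ValueError("state dimension does not match network size")
    params = np.asarray(params, dtype=float)
    flat_beta = net.adjacency[~np.eye(m, dtype=bool)]
    full = np.concatenate(
        [params, np.broadcast_to(flat_beta, params.shape[:-1] + flat_beta.shape)], axis=-1
    )
    return _hr_full_rhs(t, states, full, m)


def _hr_full_rhs(t, states, full_params, m: int):
    """HR network with per-evaluation parameters [a_i,b_i,c_i]*M + off-diag beta.

    The beta block lists adjacency[i, m] row-major with the diagonal removed.
    """
    states = np.asarray(states, dtype=float)
    full_params = np.asarray(full_params, dtype=float)
    lead = np.broadcast_shapes(states.shape[:-1], full_params.shape[:-1])
    states = np.broadcast_to(states, lead + states.shape[-1:])
    full_params = np.broadcast_to(full_params, lead + full_params.shape[-1:])
    x = states[..., 0::3]
    y = states[..., 1::3]
    z = states[..., 2::3]
    abc = full_params[..., : 3 * m]
    a = abc[..., 0::3]
    b = abc[..., 1::3]
    c = abc[..., 2::3]
    beta_flat = full_params[..., 3 * m :]
    adj = np.zeros(lead + (m, m))
    adj[..., ~np.eye(m, dtype=bool)] = beta_flat
    g = _gating(x)
    coupling = np.einsum("...im,...m->...i", adj, g)
    # divergent sigma points can overflow the cubic; the filter detects and
    # reports non-finite states, so the warnings are just noise
    with np.errstate(over="ignore", invalid="ignore"):
        dx = y - a * x**3 + b * x**2 - z + 1.2 + coupling
        dy = 1.0 - c * x**2 - y
        dz = 5e-5 * (4.0 * (x + 8.0 / 5.0) - z)
    out = np.empty_like(states)
    out[..., 0::3] = dx
    out[..., 1::3] = dy
    out[..., 2::3] = dz
    return out


def random_network(size: int, n_connections: int, rng: np.random.Generator,
                   strength: float = 1.0) -> NetworkSpec:
    """Place ``n_connections`` directed links uniformly among off-diagonal slots."""
    slots = size * size - size
    if n_connections > slots:
        raise ValueError("more connections than off-diagonal slots")
    pick = rng.choice(slots, size=n_connections, replace=False)
    adj = np.zeros((size, size))
    off = np.argwhere(~np.eye(size, dtype=bool))
    adj[off[pick, 0], off[pick, 1]] = strength
    return NetworkSpec(size=size, adjacency=adj)


def hindmarsh_rose_model(net: NetworkSpec, sample_interval: float = 0.08) -> ModelSpec:
    """HR network model whose parameter vector includes the connectivity.

    Parameters are a_i, b_i, c_i for each neuron followed by the off-diagonal
    connection strengths beta_im (row-major).  Only the membrane potentials
    x_i are observed.
    """
    m = net.size
    state_names = tuple(f"{v}{i+1}" for i in range(m) for v in ("x", "y", "z"))
    abc_names = tuple(f"{p}{i+1}" for i in range(m) for p in ("a", "b", "c"))
    off = np.argwhere(~np.eye(m, dtype=bool))
    beta_names = tuple(f"beta_{i+1}{j+1}" for i, j in off)
    true_abc = np.tile([1.0, 3.0, 5.0], m)
    true_beta = net.adjacency[~np.eye(m, dtype=bool)]
    deps: dict[str, frozenset] = {}
    sdeps: dict[str, frozenset] = {}
    for i in range(m):
        deps[f"x{i+1}"] = frozenset({f"a{i+1}", f"b{i+1}"} |
                                    {f"beta_{i+1}{j+1}" for j in range(m) if j != i})
        deps[f"y{i+1}"] = frozenset({f"c{i+1}"})
        deps[f"z{i+1}"] = frozenset()
        sdeps[f"x{i+1}"] = frozenset({f"x{j+1}" for j in range(m)} |
                                     {f"y{i+1}", f"z{i+1}"})
        sdeps[f"y{i+1}"] = frozenset({f"x{i+1}", f"y{i+1}"})
        sdeps[f"z{i+1}"] = frozenset({f"x{i+1}", f"z{i+1}"})

    def rhs(t, state, params):
        return _hr_full_rhs(t, state, params, m)

    def init(rng: np.random.Generator) -> np.ndarray:
        s = np.empty(3 * m)
        s[0::3] = rng.uniform(-1.5, 1.5, m)
        s[1::3] = rng.uniform(-6.0, -2.0, m)
        # z is quasi-static over a 240 ms window and acts as a bias current;
        # this range puts the coupled network in the ~6 ms tonic-spiking regime
        s[2::3] = rng.uniform(-0.5, -0.3, m)
        return s

    guess = np.zeros(3 * m)
    guess[1::3] = -3.0
    guess[2::3] = -0.4
    return ModelSpec(
        name="hindmarsh_rose",
        state_names=state_names,
        param_names=abc_names + beta_names,
        true_params=np.concatenate([true_abc, true_beta]),
        kind="continuous",
        rhs_or_map=rhs,
        observed=tuple(f"x{i+1}" for i in range(m)),
        sample_interval=sample_interval,
        param_deps=deps,
        state_deps=sdeps,
        free_params=abc_names + beta_names,
        init_sampler=init,
        default_state_guess=guess,
    )


# ---------------------------------------------------------------------------
# LPA map


DEFAULT_LPA = LPAParams(b=6.598, c_el=1.209e-2, c_ea=1.155e-2, c_pa=0.35,
                        mu_l=0.2055, mu_a=0.96)


def _lpa_map(t, pop, params):
    pop = np.asarray(pop, dtype=float)
    params = np.asarray(params, dtype=float)
    L, P, A = pop[..., 0], pop[..., 1], pop[..., 2]
    b, c_el, c_ea, c_pa, mu_l, mu_a = (params[..., i] for i in range(6))
    L1 = b * A * np.exp(-c_el * L - c_ea * A)
    P1 = L * (1.0 - mu_l)
    A1 = P * np.exp(-c_pa * A) + A * (1.0 - mu_a)
    return np.stack([L1, P1, A1], axis=-1)


def lpa_step(pop, params: LPAParams | np.ndarray):
    """One census step (two weeks) of the LPA map.

    Larval recruitment is adult fecundity suppressed by egg cannibalism from
    larvae and adults; pupae are surviving larvae; adults are pupae that
    escape cannibalism plus surviving adults.
    """
    pop = np.asarray(pop, dtype=float)
    if np.any(pop < 0):
        raise ValueError("populations must be nonnegative")
    if isinstance(params, LPAParams):
        params = params.as_array()
    return _lpa_map(0, pop, params)


def lpa_model(params: LPAParams = DEFAULT_LPA, sample_interval: float = 1.0) -> ModelSpec:
    return ModelSpec(
        name="lpa",
        state_names=("L", "P", "A"),
        param_names=("b", "c_el", "c_ea", "c_pa", "mu_l", "mu_a"),
        true_params=params.as_array(),
        kind="discrete",
        rhs_or_map=_lpa_map,
        observed=("L", "P", "A"),
        sample_interval=sample_interval,
        param_deps={
            "L": frozenset({"b", "c_el", "c_ea"}),
            "P": frozenset({"mu_l"}),
            "A": frozenset({"c_pa", "mu_a"}),
        },
        state_deps={
            "L": frozenset({"L", "A"}),
            "P": frozenset({"L"}),
            "A": frozenset({"P", "A"}),
        },
        # c_pa and mu_a are set experimentally, so only the remaining four
        # are treated as unknown when fitting.
        free_params=("b", "c_el", "c_ea", "mu_l"),
        init_sampler=lambda rng: rng.uniform([50.0, 20.0, 50.0], [250.0, 120.0, 150.0]),
    )


MODEL_REGISTRY: dict[str, Callable[..., ModelSpec]] = {
    "lorenz63": lorenz63_model,
    "hindmarsh_rose": hindmarsh_rose_model,
    "lpa": lpa_model,
}


def get_model(name: str, **kwargs) -> ModelSpec:
    """Instantiate a registered model by name."""
    try:
        factory = MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; known: {sorted(MODEL_REGISTRY)}")
    return factory(**kwargs)


# ---------------------------------------------------------------------------
# Integration


def rk4_step(rhs, t, y, h, params):
    """One classical Runge-Kutta step, vectorized over leading axes."""
    k1 = rhs(t, y, params)
    k2 = rhs(t + h / 2, y + h / 2 * k1, params)
    k3 = rhs(t + h / 2, y + h / 2 * k2, params)
    k4 = rhs(t + h, y + h * k3, params)
    return y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


# Adams-Bashforth-4 predictor and Adams-Moulton-4 corrector coefficients.
_AB4 = np.array([55.0, -59.0, 37.0, -9.0]) / 24.0
_AM4 = np.array([9.0, 19.0, -5.0, 1.0]) / 24.0


def _am4_path(rhs, t0, y0, h, params, n_steps, check=True):
    """Sample y at t0 + i*h, i = 0..n_steps-1, AM4 predictor-corrector."""
    n = int(n_steps)
    out = np.empty((n,) + np.shape(y0))
    out[0] = y0
    hist: list[np.ndarray] = [np.asarray(rhs(t0, y0, params))]
    for i in range(1, n):
        t = t0 + (i - 1) * h
        y = out[i - 1]
        if len(hist) < 4:
            y_new = rk4_step(rhs, t, y, h, params)
        else:
            f3, f2, f1, f0 = hist[-4], hist[-3], hist[-2], hist[-1]
            pred = y + h * (_AB4[0] * f0 + _AB4[1] * f1 + _AB4[2] * f2 + _AB4[3] * f3)
            f_pred = rhs(t + h, pred, params)
            y_new = y + h * (_AM4[0] * f_pred + _AM4[1] * f0 + _AM4[2] * f1 + _AM4[3] * f2)
        if check and not np.all(np.isfinite(y_new)):
            raise BlowupError(i)
        out[i] = y_new
        hist.append(np.asarray(rhs(t + h, y_new, params)))
        if len(hist) > 4:
            hist.pop(0)
    return out


def integrate(model: ModelSpec, x0, params=None, n_steps: int = 100,
              t0: float = 0.0) -> Trajectory:
    """Sample a model trajectory at its native interval.

    Continuous systems use the Adams-Moulton predictor-corrector (order 4,
    RK4 start-up); discrete systems iterate their map once per sample.
    Returns ``n_steps`` rows starting at the initial condition.
    """
    p = model.params_from(params) if params is None or not isinstance(params, np.ndarray) \
        else np.asarray(params, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    h = model.sample_interval
    if model.kind == "continuous":
        vals = _am4_path(model.rhs_or_map, t0, x0, h, p, n_steps)
    else:
        vals = np.empty((n_steps, x0.shape[-1]))
        vals[0] = x0
        for i in range(1, n_steps):
            vals[i] = model.rhs_or_map(t0 + (i - 1) * h, vals[i - 1], p)
            if not np.all(np.isfinite(vals[i])):
                raise BlowupError(i)
    times = t0 + h * np.arange(n_steps)
    return Trajectory(times=times, values=vals, state_names=model.state_names)


def generate_training_data(model: ModelSpec, n_samples: int, noise_variance: float,
                           seed: int | np.random.Generator,
                           burn_in: int = 1000) -> tuple[Trajectory, Trajectory]:
    """Simulate a model realization and observation noise.

    A transient of ``burn_in`` steps from a randomized initial condition is
    discarded so recorded samples lie on the attractor; i.i.d. zero-mean
    Gaussian noise of the stated variance is then added to every observed
    component.  Returns ``(clean, noisy)`` trajectories of ``n_samples`` rows.
    """
    if noise_variance < 0:
        raise ValueError("noise_variance must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x0 = model.init_sampler(rng)
    warm = integrate(model, x0, None, n_steps=burn_in + 1)
    clean = integrate(model, warm.values[-1], None, n_steps=n_samples)
    noisy_vals = clean.values.copy()
    if noise_variance > 0:
        idx = model.obs_indices
        noisy_vals[:, idx] += rng.normal(
            0.0, np.sqrt(noise_variance), size=(n_samples, idx.size))
    noisy = Trajectory(times=clean.times, values=noisy_vals,
                       state_names=model.state_names)
    return clean, noisy
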