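"""Continuous-time leaky rate RNN: dynamics, Euler discretization, readouts.

The model is the standard "vanilla" leaky RNN of systems neuroscience,

    T dr/dt = -r + f(W_rec r + b + W_inp h_ext + eta),    y = g(W_out r)

where ``r`` is the vector of unit rates (the hidden state), ``T`` a diagonal
matrix of membrane time constants (ms), ``f`` the input-output nonlinearity
(ReLU by default) and ``eta`` additive Gaussian noise inside the activation
argument.  In the absence of input a unit's rate decays passively with time
constant tau, so memory over behavioural timescales must emerge from
recurrent population dynamics — this leak is what makes training on
long-term-dependency tasks hard, and what the surrogate integrators in
:mod:`timeskip.surrogates` work around during training only.

Simulation uses the forward Euler map ``r <- r + (dr/dt) dt``.  Per-step
noise is drawn with standard deviation ``sigma_noise * sqrt(2 tau / dt)`` so
that the accumulated trajectory noise variance does not depend on the
discretization step — essential when comparing the same network simulated at
different effective step sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkParams",
    "StateTrajectory",
    "DivergenceError",
    "ACTIVATIONS",
    "activation",
    "activation_grad",
    "compute_derivative",
    "euler_step",
    "simulate_base",
    "readout",
    "init_network",
    "noise_std",
    "save_checkpoint",
    "load_checkpoint",
]

DEFAULT_TAU_MS = 100.0
DEFAULT_DT_MS = 5.0
DEFAULT_SIGMA_NOISE = 0.01
DEFAULT_N_UNITS = 256
DESK_N_UNITS = 80
#: |r| beyond this marks a trajectory as dynamically runaway in analyses.
#: Ring-task networks operate with rates well below 1 (targets peak at
#: 0.85); stable surrogate simulations stay in that regime while unstable
#: coarse discretizations grow geometrically past it by orders of
#: magnitude, so any threshold in the wide gap between ~1 and ~100
#: separates the two regimes.
RATE_DIVERGENCE_BOUND = 50.0


class DivergenceError(FloatingPointError):
    """Raised when a simulated state becomes non-finite.

    Carries the Euler step index at which the divergence was detected and,
    where relevant, the surrogate method tag.
    """

    def __init__(self, step: int, method: str = "base"):
        self.step = int(step)
        self.method = method
        super().__init__(
            f"non-finite state at step {step} (method={method})"
        )


# ---------------------------------------------------------------------------
# activations and readouts
# ---------------------------------------------------------------------------

def _relu(x):
    return np.maximum(x, 0.0)


def _softplus(x):
    # overflow-safe log(1+exp(x))
    return np.logaddexp(x, 0.0)


ACTIVATIONS = {
    "relu": _relu,
    "tanh": np.tanh,
    "softplus": _softplus,
    "identity": lambda x: x,
}

_ACT_GRADS = {
    "relu": lambda x: (x > 0.0).astype(x.dtype),
    "tanh": lambda x: 1.0 - np.tanh(x) ** 2,
    "softplus": lambda x: 1.0 / (1.0 + np.exp(-x)),
    "identity": lambda x: np.ones_like(x),
}


def activation(tag: str, x: np.ndarray) -> np.ndarray:
    """Apply the named input-output function f elementwise."""
    try:
        return ACTIVATIONS[tag](x)
    except KeyError:
        raise ValueError(f"unknown activation {tag!r}") from None


def activation_grad(tag: str, x: np.ndarray) -> np.ndarray:
    """Elementwise derivative f'(x) of the named activation."""
    try:
        return _ACT_GRADS[tag](x)
    except KeyError:
        raise ValueError(f"unknown activation {tag!r}") from None


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(x, axis=-1):
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------

@dataclass
class NetworkParams:
    """All trainable and fixed parameters of one leaky RNN.

    Shapes: ``W_rec`` is (n_units, n_units), ``W_inp`` (n_units, n_inputs),
    ``W_out`` (n_outputs, n_units), ``b`` and ``tau`` (n_units,).  ``tau`` is
    in milliseconds and must be strictly positive.  ``sigma_noise`` is the
    nominal noise standard deviation before the variance-preserving
    ``sqrt(2 tau / dt)`` per-step scaling.
    """

    n_units: int
    W_rec: np.ndarray
    W_inp: np.ndarray
    W_out: np.ndarray
    b: np.ndarray
    tau: np.ndarray = field(default=None)  # type: ignore[assignment]
    sigma_noise: float = DEFAULT_SIGMA_NOISE
    activation: str = "relu"
    readout: str = "sigmoid"

    def __post_init__(self):
        if self.tau is None:
            self.tau = np.full(self.n_units, DEFAULT_TAU_MS)
        self.W_rec = np.asarray(self.W_rec, dtype=float)
        self.W_inp = np.asarray(self.W_inp, dtype=float)
        self.W_out = np.asarray(self.W_out, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        n = self.n_units
        if self.W_rec.shape != (n, n):
            raise ValueError(
                f"W_rec shape {self.W_rec.shape} != ({n}, {n})"
            )
        if self.W_inp.ndim != 2 or self.W_inp.shape[0] != n:
            raise ValueError(f"W_inp shape {self.W_inp.shape} inconsistent")
        if self.W_out.ndim != 2 or self.W_out.shape[1] != n:
            raise ValueError(f"W_out shape {self.W_out.shape} inconsistent")
        if self.b.shape != (n,):
            raise ValueError(f"b shape {self.b.shape} != ({n},)")
        if self.tau.shape != (n,):
            raise ValueError(f"tau shape {self.tau.shape} != ({n},)")
        if np.any(self.tau <= 0):
            raise ValueError("tau must be strictly positive elementwise")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be nonnegative")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.readout not in ("sigmoid", "softmax"):
            raise ValueError(f"unknown readout {self.readout!r}")

    @property
    def n_inputs(self) -> int:
        return self.W_inp.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.W_out.shape[0]

    def copy(self) -> "NetworkParams":
        return replace(
            self,
            W_rec=self.W_rec.copy(),
            W_inp=self.W_inp.copy(),
            W_out=self.W_out.copy(),
            b=self.b.copy(),
            tau=self.tau.copy(),
        )


@dataclass
class StateTrajectory:
    """Time-indexed matrix of hidden rates from a forward simulation.

    ``rates`` has ``n_steps + 1`` rows: the initial state plus one row per
    Euler step.  ``time_index`` holds the *fine-grid* step index of each row,
    so a coarse (CD) trajectory records which fine times its rows represent.
    ``dt`` is the fine step in ms; ``dt_effective`` the macro step actually
    simulated (``theta * dt`` for CD, else ``dt``).
    """

    dt: float
    rates: np.ndarray
    time_index: np.ndarray
    dt_effective: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.dt_effective is None:
            self.dt_effective = self.dt
        self.rates = np.asarray(self.rates, dtype=float)
        self.time_index = np.asarray(self.time_index, dtype=int)
        if self.rates.shape[0] != self.time_index.shape[0]:
            raise ValueError("rates rows and time_index length differ")

    @property
    def n_steps(self) -> int:
        return self.rates.shape[0] - 1


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def noise_std(sigma_noise: float, tau, dt: float) -> np.ndarray:
    """Per-step noise s.d. with variance-preserving sqrt(2 tau / dt) scaling."""
    return sigma_noise * np.sqrt(2.0 * np.asarray(tau, dtype=float) / dt)


def compute_derivative(
    params: NetworkParams,
    r: np.ndarray,
    h_ext: np.ndarray,
    noise: np.ndarray,
) -> np.ndarray:
    """dr/dt = (-r + f(W_rec r + b + W_inp h_ext + noise)) / tau.

    ``r`` and ``noise`` may carry leading batch dimensions; ``h_ext`` must
    broadcast against them.  Units are rate per ms.  The noise vector is
    supplied by the caller (already scaled), enabling shared-noise paired
    simulations.
    """
    r = np.asarray(r, dtype=float)
    h_ext = np.asarray(h_ext, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if r.shape[-1] != params.n_units:
        raise ValueError(
            f"rate vector has {r.shape[-1]} units, expected {params.n_units}"
        )
    if h_ext.shape[-1] != params.n_inputs:
        raise ValueError(
            f"input vector has {h_ext.shape[-1]} channels, "
            f"expected {params.n_inputs}"
        )
    pre = r @ params.W_rec.T + params.b + h_ext @ params.W_inp.T + noise
    return (-r + activation(params.activation, pre)) / params.tau


def euler_step(r: np.ndarray, deriv: np.ndarray, dt: float) -> np.ndarray:
    """One forward Euler update r + deriv * dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    r = np.asarray(r, dtype=float)
    deriv = np.asarray(deriv, dtype=float)
    if r.shape != deriv.shape:
        raise ValueError(f"shape mismatch {r.shape} vs {deriv.shape}")
    return r + deriv * dt


def simulate_base(
    params: NetworkParams,
    input_seq: np.ndarray,
    dt: float = DEFAULT_DT_MS,
    r0: np.ndarray | None = None,
    noise_seq: np.ndarray | None = None,
    seed: int | None = None,
) -> StateTrajectory:
    """Simulate the unmodified ("true") dynamics on the fine Euler grid.

    ``input_seq`` has shape (n_steps, n_inputs); ``input_seq[k]`` drives the
    transition from step k to k+1.  If ``noise_seq`` is None and
    ``params.sigma_noise > 0``, per-step noise is drawn from a generator
    seeded with ``seed`` using the variance-preserving scaling.
    """
    input_seq = np.asarray(input_seq, dtype=float)
    if input_seq.ndim != 2 or input_seq.shape[1] != params.n_inputs:
        raise ValueError(
            f"input_seq shape {input_seq.shape} incompatible with "
            f"{params.n_inputs} input channels"
        )
    n_steps = input_seq.shape[0]
    if r0 is None:
        r0 = np.zeros(params.n_units)
    r0 = np.asarray(r0, dtype=float)
    if noise_seq is None:
        if params.sigma_noise > 0:
            rng = np.random.default_rng(seed)
            noise_seq = rng.standard_normal((n_steps, params.n_units))
            noise_seq = noise_seq * noise_std(params.sigma_noise, params.tau, dt)
        else:
            noise_seq = np.zeros((n_steps, params.n_units))
    else:
        noise_seq = np.asarray(noise_seq, dtype=float)
        if noise_seq.shape != (n_steps, params.n_units):
            raise ValueError(
                f"noise_seq shape {noise_seq.shape} != "
                f"({n_steps}, {params.n_units})"
            )
    rates = np.empty((n_steps + 1, params.n_units))
    rates[0] = r0
    r = r0
    for k in range(n_steps):
        deriv = compute_derivative(params, r, input_seq[k], noise_seq[k])
        r = euler_step(r, deriv, dt)
        if not np.all(np.isfinite(r)):
            raise DivergenceError(k + 1)
        rates[k + 1] = r
    return StateTrajectory(
        dt=dt, rates=rates, time_index=np.arange(n_steps + 1)
    )


def readout(params: NetworkParams, r: np.ndarray) -> np.ndarray:
    """Output y = g(W_out r); g is per-channel sigmoid or across-channel softmax."""
    r = np.asarray(r, dtype=float)
    logits = r @ params.W_out.T
    if params.readout == "sigmoid":
        return _sigmoid(logits)
    return _softmax(logits, axis=-1)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_network(
    n_units: int,
    n_inputs: int,
    n_outputs: int,
    seed=None,
    spectral_radius: float = 0.8,
    sigma_noise: float = DEFAULT_SIGMA_NOISE,
    tau: float = DEFAULT_TAU_MS,
    activation: str = "relu",
    readout: str = "sigmoid",
) -> NetworkParams:
    """Random initialization: W_rec Gaussian rescaled to the given spectral
    radius (contractive by default), W_inp / W_out Gaussian with variance
    1/fan-in, zero bias."""
    rng = np.random.default_rng(seed)
    W_rec = rng.standard_normal((n_units, n_units)) / np.sqrt(n_units)
    rho = np.max(np.abs(np.linalg.eigvals(W_rec)))
    W_rec *= spectral_radius / rho
    W_inp = rng.standard_normal((n_units, n_inputs)) / np.sqrt(n_inputs)
    W_out = rng.standard_normal((n_outputs, n_units)) / np.sqrt(n_units)
    return NetworkParams(
        n_units=n_units,
        W_rec=W_rec,
        W_inp=W_inp,
        W_out=W_out,
        b=np.zeros(n_units),
        tau=np.full(n_units, float(tau)),
        sigma_noise=sigma_noise,
        activation=activation,
        readout=readout,
    )


# ---------------------------------------------------------------------------
# checkpoint I/O (NPZ with embedded JSON metadata)
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: NetworkParams, dt: float = DEFAULT_DT_MS,
                    seed=None, extra_meta: dict | None = None) -> None:
    meta = {
        "activation": params.activation,
        "readout": params.readout,
        "sigma_noise": params.sigma_noise,
        "dt": dt,
        "seed": seed,
    }
    if extra_meta:
        meta.update(extra_meta)
    np.savez(
        path,
        W_rec=params.W_rec,
        W_inp=params.W_inp,
        W_out=params.W_out,
        b=params.b,
        tau=params.tau,
        meta_json=np.array(json.dumps(meta)),
    )


def load_checkpoint(path) -> tuple[NetworkParams, dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta_json"]))
        params = NetworkParams(
            n_units=z["W_rec"].shape[0],
            W_rec=z["W_rec"],
            W_inp=z["W_inp"],
            W_out=z["W_out"],
            b=z["b"],
            tau=z["tau"],
            sigma_noise=float(meta.get("sigma_noise", DEFAULT_SIGMA_NOISE)),
            activation=meta.get("activation", "relu"),
            readout=meta.get("readout", "sigmoid"),
        )
    return params, meta
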