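"""Training-time surrogate integrators: CD, SCTT and DASC.

All three methods modify the forward simulation *during training only* to
shorten the effective path for backpropagation through time, and are
annealed away over the first part of training so that the unmodified leaky
RNN is recovered at test time:

* **CD** (coarsened discretization) simulates on a coarse grid with a single
  Euler step of size ``theta * dt`` per macro step, annealing ``theta -> 1``.
* **SCTT** (skip connections through time) simulates the fine grid but, at
  the end of every length-``theta`` segment, replaces the state with the
  convex mix ``(1-beta) r_start + beta r_base_end``; ``beta -> 1``.
* **DASC** (dynamics-aligned skip connections) replaces the zeroth-order
  bypass of SCTT with one coarse Euler step from the segment start:
  ``(1-beta) r_cd_end + beta r_base_end``; ``beta -> 1``.  The bypass branch
  is a first-order approximation of the segment, keeping the mixed state
  close to the true dynamics.

Skip segments are half-open index intervals ``(start, end)`` on the fine
grid.  Periodic segments span ``theta`` steps; *strategic* segments span
whole trials in multi-trial episodes and coexist with the periodic ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    DivergenceError,
    NetworkParams,
    StateTrajectory,
    compute_derivative,
    euler_step,
    noise_std,
    simulate_base,
)

__all__ = [
    "AnnealSchedule",
    "SurrogateSpec",
    "cd_macro_step",
    "sctt_mix",
    "dasc_mix",
    "schedule_value",
    "strategic_skip_positions",
    "segment_list",
    "simulate_with_surrogate",
]

ANNEAL_HORIZON_DEFAULT = 20_000


@dataclass
class AnnealSchedule:
    """Piecewise-constant annealing of beta (SCTT/DASC) or theta (CD).

    The schedule takes ``step_count + 1`` plateau values over the first
    ``horizon`` training steps in equal intervals, starting at
    ``initial_value`` and ending at the terminal value 1; it is exactly 1
    for every training step at or beyond ``horizon``.  ``kind`` is ``beta``
    (real-valued plateaus) or ``theta`` (plateaus rounded to integers >= 1);
    ``auto`` infers ``theta`` when ``initial_value > 1``.
    """

    step_count: int
    initial_value: float
    horizon: int = ANNEAL_HORIZON_DEFAULT
    terminal_value: float = 1.0
    kind: str = "auto"

    def __post_init__(self):
        if self.step_count < 1:
            raise ValueError("step_count must be >= 1")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.kind == "auto":
            self.kind = "theta" if self.initial_value > 1 else "beta"
        if self.kind not in ("beta", "theta"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "beta" and not (0.0 < self.initial_value <= 1.0):
            raise ValueError("beta schedule needs initial_value in (0, 1]")
        if self.kind == "theta" and self.initial_value < 1:
            raise ValueError("theta schedule needs initial_value >= 1")

    def plateaus(self) -> list[float]:
        """The step_count + 1 plateau values, first to last."""
        s = self.step_count
        v0, v1 = self.initial_value, self.terminal_value
        vals = [v0 + k * (v1 - v0) / s for k in range(s + 1)]
        if self.kind == "theta":
            vals = [max(1, int(round(v))) for v in vals]
        return vals


def schedule_value(sched: AnnealSchedule, training_step: int) -> float:
    """Scheduled beta (or theta) at a given training step.

    Equal-length intervals partition ``[0, horizon)`` among the plateau
    values; the value is exactly the terminal value for
    ``training_step >= horizon``.
    """
    if training_step < 0:
        raise ValueError("training_step must be >= 0")
    vals = sched.plateaus()
    if training_step >= sched.horizon:
        return vals[-1]
    k = min(len(vals) - 1,
            (training_step * len(vals)) // sched.horizon)
    return vals[k]


# ---------------------------------------------------------------------------
# skip-segment bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class SurrogateSpec:
    """Which surrogate is active, with its skip geometry and mixing ratio.

    ``skip_positions`` are fine-grid step indices where periodic segments
    start (default every ``theta`` steps from 0).  ``strategic_segments``
    are extra (start, end) spans added on top — typically trial boundaries
    from :func:`strategic_skip_positions`.  ``beta`` is unused for
    ``base``/``cd``.
    """

    method: str = "base"
    theta: int = 1
    beta: float = 1.0
    skip_positions: list[int] | None = None
    strategic_segments: list[tuple[int, int]] = field(default_factory=list)
    anneal: AnnealSchedule | None = None

    def __post_init__(self):
        if self.method not in ("base", "cd", "sctt", "dasc"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.theta < 1:
            raise ValueError("theta must be >= 1")
        if self.method in ("sctt", "dasc") and not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must lie in (0, 1]")
        if self.skip_positions is not None:
            sp = list(self.skip_positions)
            if any(b <= a for a, b in zip(sp, sp[1:])):
                raise ValueError("skip_positions must be strictly increasing")

    def at_step(self, training_step: int) -> "SurrogateSpec":
        """Resolve the annealed spec active at a given training step."""
        if self.anneal is None:
            return self
        v = schedule_value(self.anneal, training_step)
        if self.method == "cd":
            return SurrogateSpec(
                method="cd", theta=int(v), beta=1.0,
                skip_positions=self.skip_positions,
                strategic_segments=self.strategic_segments,
            )
        return SurrogateSpec(
            method=self.method, theta=self.theta, beta=float(v),
            skip_positions=self.skip_positions,
            strategic_segments=self.strategic_segments,
        )


def strategic_skip_positions(
    trial_boundaries: list[int],
) -> list[tuple[int, int]]:
    """Long-range skip segments spanning consecutive trial starts.

    Given the step indices at which trials begin, returns one segment from
    the start of each trial to the start of the next (n boundaries -> n-1
    segments; irregular spans allowed).  These are merged with, not a
    replacement for, the periodic every-theta segments.
    """
    tb = list(trial_boundaries)
    if any(b <= a for a, b in zip(tb, tb[1:])):
        raise ValueError("trial_boundaries must be strictly increasing")
    segs = [(a, b) for a, b in zip(tb, tb[1:])]
    return list(dict.fromkeys(segs))


def segment_list(spec: SurrogateSpec, n_steps: int) -> list[tuple[int, int]]:
    """All mix segments for a trial of n_steps fine steps, sorted by end.

    Periodic segments start at ``spec.skip_positions`` (default every theta
    from 0) and span theta steps; a trailing partial segment that would
    extend past n_steps is dropped (those steps run plain base Euler).
    Strategic segments are merged in; duplicates removed.  Segments sharing
    an end are ordered shorter first so the trial-spanning strategic mix is
    applied last.
    """
    if spec.method in ("base", "cd"):
        return []
    if spec.skip_positions is None:
        starts = range(0, n_steps, spec.theta)
    else:
        starts = spec.skip_positions
    segs = [(s, s + spec.theta) for s in starts if s + spec.theta <= n_steps]
    for a, b in spec.strategic_segments:
        if b <= n_steps and (a, b) not in segs:
            segs.append((a, b))
    segs.sort(key=lambda se: (se[1], se[1] - se[0]))
    return segs


# ---------------------------------------------------------------------------
# the three surrogate primitives
# ---------------------------------------------------------------------------

def cd_macro_step(
    params: NetworkParams,
    r: np.ndarray,
    h_ext: np.ndarray,
    noise: np.ndarray,
    theta: int,
    dt: float,
) -> np.ndarray:
    """One coarse Euler step of effective size theta * dt."""
    if theta < 1:
        raise ValueError("theta must be >= 1")
    deriv = compute_derivative(params, r, h_ext, noise)
    return euler_step(r, deriv, dt * theta)


def sctt_mix(r_t: np.ndarray, r_base_end: np.ndarray, beta: float) -> np.ndarray:
    """Skip-connection state mix (1-beta) r_t + beta r_base_end."""
    if not (0.0 < beta <= 1.0):
        raise ValueError("beta must lie in (0, 1]")
    return (1.0 - beta) * np.asarray(r_t, float) + beta * np.asarray(
        r_base_end, float
    )


def dasc_mix(
    r_cd_end: np.ndarray, r_base_end: np.ndarray, beta: float
) -> np.ndarray:
    """Dynamics-aligned mix (1-beta) r_cd_end + beta r_base_end.

    ``beta = 0`` is accepted here (pure CD limit, useful for testing) even
    though the training schedule never visits it.
    """
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must lie in [0, 1]")
    return (1.0 - beta) * np.asarray(r_cd_end, float) + beta * np.asarray(
        r_base_end, float
    )


# ---------------------------------------------------------------------------
# full forward simulation under a surrogate
# ---------------------------------------------------------------------------

def _draw_noise(rng, shape, sigma, tau, dt_eff):
    if rng is None or sigma == 0:
        return np.zeros(shape)
    return rng.standard_normal(shape) * noise_std(sigma, tau, dt_eff)


def simulate_with_surrogate(
    params: NetworkParams,
    input_seq: np.ndarray,
    dt: float,
    spec: SurrogateSpec,
    r0: np.ndarray | None = None,
    seed: int | None = None,
    noise_seq: np.ndarray | None = None,
) -> StateTrajectory:
    """Simulate the modified (training-time) dynamics of one network.

    For ``base`` this is :func:`simulate_base`.  For ``cd`` the trajectory
    lives on a coarse grid of ``ceil(n_steps / theta)`` macro steps with
    ``dt_effective = theta * dt`` recorded and ``time_index`` giving the
    fine times represented.  For ``sctt``/``dasc`` the returned grid matches
    the fine grid (n_steps + 1 rows); states at segment ends hold the mixed
    value, which seeds the following steps.

    Noise, when enabled, is drawn per simulated step with the
    variance-preserving scaling for that step's effective dt; pass
    ``noise_seq`` (fine grid) or leave ``sigma_noise = 0`` for paired
    true-vs-modified comparisons.
    """
    input_seq = np.asarray(input_seq, dtype=float)
    n_steps = input_seq.shape[0]
    if r0 is None:
        r0 = np.zeros(params.n_units)
    r0 = np.asarray(r0, dtype=float)

    if spec.method == "base":
        return simulate_base(params, input_seq, dt, r0, noise_seq, seed)

    rng = (
        np.random.default_rng(seed)
        if (noise_seq is None and params.sigma_noise > 0)
        else None
    )

    if spec.method == "cd":
        theta = spec.theta
        m = math.ceil(n_steps / theta)
        rates = np.empty((m + 1, params.n_units))
        tindex = np.empty(m + 1, dtype=int)
        rates[0] = r0
        tindex[0] = 0
        r = r0
        for j in range(m):
            t_cur = j * theta
            t_next = min((j + 1) * theta, n_steps)
            theta_j = t_next - t_cur
            if noise_seq is not None:
                noise = noise_seq[t_cur]
            else:
                noise = _draw_noise(
                    rng, (params.n_units,), params.sigma_noise,
                    params.tau, dt * theta_j,
                )
            r = cd_macro_step(params, r, input_seq[t_cur], noise, theta_j, dt)
            if not np.all(np.isfinite(r)):
                raise DivergenceError(t_next, "cd")
            rates[j + 1] = r
            tindex[j + 1] = t_next
        return StateTrajectory(
            dt=dt, rates=rates, time_index=tindex,
            dt_effective=theta * dt,
        )

    # sctt / dasc: fine grid with mixes at segment ends
    segs = segment_list(spec, n_steps)
    ends: dict[int, list[tuple[int, int]]] = {}
    for s, e in segs:
        ends.setdefault(e, []).append((s, e))

    if noise_seq is None:
        noise_seq_fine = _draw_noise(
            rng, (n_steps, params.n_units), params.sigma_noise,
            params.tau, dt,
        )
    else:
        noise_seq_fine = np.asarray(noise_seq, dtype=float)

    rates = np.empty((n_steps + 1, params.n_units))
    rates[0] = r0
    r = r0
    for k in range(n_steps):
        deriv = compute_derivative(
            params, r, input_seq[k], noise_seq_fine[k]
        )
        r = euler_step(r, deriv, dt)
        if not np.all(np.isfinite(r)):
            raise DivergenceError(k + 1, spec.method)
        if (k + 1) in ends:
            for (s, e) in ends[k + 1]:
                r_start = rates[s]
                if spec.method == "sctt":
                    r = sctt_mix(r_start, r, spec.beta)
                else:
                    span = e - s
                    if noise_seq is not None:
                        branch_noise = noise_seq_fine[s]
                    else:
                        branch_noise = _draw_noise(
                            rng, (params.n_units,), params.sigma_noise,
                            params.tau, dt * span,
                        )
                    r_cd = cd_macro_step(
                        params, r_start, input_seq[s], branch_noise,
                        span, dt,
                    )
                    r = dasc_mix(r_cd, r, spec.beta)
                if not np.all(np.isfinite(r)):
                    raise DivergenceError(k + 1, spec.method)
        rates[k + 1] = r
    return StateTrajectory(
        dt=dt, rates=rates, time_index=np.arange(n_steps + 1)
    )
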