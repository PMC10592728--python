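"""True-vs-modified dynamics discrepancy and induced performance gap.

The "true" dynamics of a network are its fine-grid Euler trajectories with
no surrogate machinery; the "modified" dynamics are those produced under
CD, SCTT or DASC.  The discrepancy is summarized as a normalized
mean-squared trajectory error (normalized by the time-and-unit variance of
the true trajectory, making it invariant to additive rate offsets and to
overall rate scale), and as the difference in behavioural performance under
modified versus true dynamics.  Comparisons use zero noise and identical
initial states so that all discrepancy is attributable to the surrogate.

CD trajectories contain no intermediate states, so CD is compared on the
coarse time points only; interpolation would inject error not caused by the
method.  A trajectory whose rates leave a generous bound (or go non-finite)
is marked unstable rather than reported as a number — with
``theta * dt > tau`` the CD macro step's leak multiplier ``1 - theta dt/tau``
turns negative, which is the mechanism behind CD's instability at large
skip lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    DivergenceError,
    NetworkParams,
    RATE_DIVERGENCE_BOUND,
    StateTrajectory,
    readout,
    simulate_base,
)
from .surrogates import SurrogateSpec, simulate_with_surrogate
from .tasks import TaskTensor, score_batch

__all__ = [
    "DiscrepancyReport",
    "paired_simulation",
    "normalized_mse",
    "trajectory_unstable",
    "sweep_report",
    "THETA_SWEEP",
]

THETA_SWEEP = (5, 10, 20, 30, 40)


@dataclass
class DiscrepancyReport:
    method: str
    theta: int
    beta: float
    nmse: float | None            # None when the modified dynamics diverged
    perf_gap: float | None        # performance(modified) - performance(true)
    n_networks: int
    task_id: str
    unstable: bool = False


def trajectory_unstable(traj: StateTrajectory,
                        bound: float = RATE_DIVERGENCE_BOUND) -> bool:
    """Non-finite rates or rates beyond ``bound`` count as divergence."""
    r = traj.rates
    return bool(not np.all(np.isfinite(r)) or np.max(np.abs(r)) > bound)


def paired_simulation(params: NetworkParams, trial: TaskTensor,
                      spec: SurrogateSpec, dt: float | None = None):
    """Simulate true and modified dynamics from identical initial state.

    Noise is forced to zero so the pair differs only through the surrogate.
    Returns two trajectories on a shared comparison grid: for CD the true
    trajectory is subsampled at the coarse time points.
    """
    dt = trial.meta.dt if dt is None else dt
    n_steps = trial.inputs.shape[0]
    zero_noise = np.zeros((n_steps, params.n_units))
    true = simulate_base(params, trial.inputs, dt, noise_seq=zero_noise)
    modified = simulate_with_surrogate(
        params, trial.inputs, dt, spec, noise_seq=zero_noise
    )
    if modified.time_index.shape != true.time_index.shape or np.any(
        modified.time_index != true.time_index
    ):
        true = StateTrajectory(
            dt=dt,
            rates=true.rates[modified.time_index],
            time_index=modified.time_index.copy(),
        )
    return true, modified


def normalized_mse(true: StateTrajectory, modified: StateTrajectory) -> float:
    """Mean squared trajectory difference over the variance of the truth."""
    a, b = true.rates, modified.rates
    if a.shape != b.shape:
        raise ValueError("trajectories are not on a common grid")
    var = float(np.var(a))
    if var == 0.0:
        raise ValueError("zero-variance true trajectory")
    return float(np.mean((b - a) ** 2) / var)


def _performance(params: NetworkParams, traj: StateTrajectory,
                 trial: TaskTensor) -> float:
    """Score one trial from a trajectory (coarse grids handled)."""
    y = readout(params, traj.rates[1:])
    r0, r1 = trial.meta.response_epoch
    if traj.time_index.shape[0] != trial.inputs.shape[0] + 1:
        # coarse grid: expand to the fine time base by zero-order hold so
        # the scorer sees the states at the times they represent
        fine = np.zeros((trial.inputs.shape[0], y.shape[-1]))
        t_prev = 0
        for row, t in zip(y, traj.time_index[1:]):
            fine[t_prev:t] = row
            t_prev = t
        y = fine
    target = (np.nan if trial.meta.target_direction is None
              else trial.meta.target_direction)
    return float(score_batch(y, np.array(target), (r0, r1))[()])


def sweep_report(
    networks: list[NetworkParams],
    trials: list[TaskTensor],
    methods=("cd", "sctt", "dasc"),
    thetas=THETA_SWEEP,
    beta: float = 0.5,
    include_perf: bool = True,
) -> list[DiscrepancyReport]:
    """Average discrepancy per (method, theta) cell over networks x trials.

    Cells where a majority of simulations diverge are flagged unstable and
    carry no numeric nmse.  ``networks`` may be trained checkpoints (the
    protocol of record) or random contractive networks for fast property
    checks; ``trials`` supplies the input drive.
    """
    reports = []
    for method in methods:
        for theta in thetas:
            nmses, gaps, n_div = [], [], 0
            for params in networks:
                for trial in trials:
                    spec = SurrogateSpec(method=method, theta=int(theta),
                                         beta=beta)
                    try:
                        true, mod = paired_simulation(params, trial, spec)
                    except DivergenceError:
                        n_div += 1
                        continue
                    if trajectory_unstable(mod):
                        n_div += 1
                        continue
                    nmses.append(normalized_mse(true, mod))
                    if include_perf:
                        gaps.append(
                            _performance(params, mod, trial)
                            - _performance(params, true, trial)
                        )
            n_total = len(networks) * len(trials)
            unstable = n_div > n_total // 2
            reports.append(DiscrepancyReport(
                method=method, theta=int(theta), beta=beta,
                nmse=float(np.mean(nmses)) if (nmses and not unstable) else None,
                perf_gap=(float(np.mean(gaps))
                          if (gaps and not unstable and include_perf) else None),
                n_networks=len(networks),
                task_id=trials[0].meta.task_id if trials else "",
                unstable=unstable,
            ))
    return reports
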