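"""BPTT training engine: cohorts, stopping criterion, resource accounting.

Gradients are computed by hand-written reverse-mode backpropagation through
time over the Euler-simulated dynamics, vectorized across a cohort of
independently initialized networks (a leading cohort axis on every
parameter array).  The backward pass honours the skip-connection gradient
contract: at each skip segment the (1-beta) bypass branch routes gradient
directly from the segment end to the segment start, skipping the theta
recurrent Jacobian factors, while the beta branch backpropagates through
the fine chain.  For CD the whole graph lives on the coarse grid, so the
unrolled length shrinks by the current discretization factor.

Training follows the cohort protocol: networks are trained in parallel on
freshly sampled trial batches, evaluated on a frozen held-out batch at a
fixed cadence, and stopped when the mean performance of the cohort members
ranked between the 10th and 90th percentile reaches 0.99 (or a step cap is
hit, in which case a plateau check verifies that performance has
converged).
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .model import (
    DEFAULT_DT_MS,
    DEFAULT_SIGMA_NOISE,
    NetworkParams,
    init_network,
    noise_std,
)
from .surrogates import (
    ANNEAL_HORIZON_DEFAULT,
    AnnealSchedule,
    SurrogateSpec,
    segment_list,
    strategic_skip_positions,
)
from . import tasks
from .tasks import (
    DESK_TIMING,
    N_INPUTS,
    N_OUTPUTS,
    RULE_N_INPUTS,
    RULE_N_OUTPUTS,
    generate_batch,
    population_masks,
)

__all__ = [
    "TrainConfig",
    "CohortResult",
    "masked_mse_loss",
    "percentile_band_criterion",
    "band_mean",
    "train_network",
    "train_cohort",
    "flop_estimate",
    "desk_preset",
]

STATE_DIVERGENCE_BOUND = 1e6   # |r| beyond this marks a training divergence
PLATEAU_SLOPE_TOL = 1e-4       # band-mean slope per evaluation


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Everything needed to train one cohort.

    Full-scale defaults follow the study protocol (cohorts of 100, batch 64,
    40,000-step cap, annealing over the first 20,000 steps, Adam at 1e-3
    with gradient-norm clipping at 1.0, evaluation every 100 steps on a
    frozen 512-trial batch).  ``timing`` overrides trial epoch durations
    (in steps) for desk-scale runs; see :func:`desk_preset`.
    """

    task_id: str = "go"
    method: str = "base"                 # base | cd | sctt | dasc
    theta: int = 10                      # skip length (SCTT/DASC) or theta0 (CD)
    beta0: float = 0.5
    step_count: int = 5
    horizon: int = ANNEAL_HORIZON_DEFAULT
    strategic: bool = False              # add trial-boundary skip segments
    cohort_size: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    max_training_steps: int = 40_000
    eval_every: int = 100
    eval_batch: int = 512
    criterion: float = 0.99
    seed_base: int = 0
    n_units: int = 256
    sigma_noise: float = DEFAULT_SIGMA_NOISE
    dt: float = DEFAULT_DT_MS
    grad_clip: float = 1.0
    rate_penalty: float = 1e-3    # L2 penalty on rates; keeps dynamics tame
    dtype: str = "float32"        # simulation precision inside training
    timing: dict | None = None
    n_directions: int | None = None   # discrete stimulus directions (desk)
    gamma_scale: float = 1.0          # stimulus magnitude multiplier (desk)
    n_trials: int = 5                    # rule-reversal episodes only
    rule_trial_steps: dict | None = None

    def __post_init__(self):
        if self.method not in ("base", "cd", "sctt", "dasc"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method != "base" and self.max_training_steps < self.horizon:
            raise ValueError("max_training_steps must cover the anneal horizon")

    @property
    def is_rule_task(self) -> bool:
        return self.task_id == "rulerev"

    def surrogate_spec(self, n_steps: int,
                       trial_boundaries=None) -> SurrogateSpec:
        """Resolved surrogate spec with anneal schedule and skip geometry."""
        strategic = []
        if self.strategic and trial_boundaries is not None:
            strategic = strategic_skip_positions(list(trial_boundaries))
        if self.method == "base":
            return SurrogateSpec(method="base")
        if self.method == "cd":
            sched = AnnealSchedule(self.step_count, float(self.theta),
                                   self.horizon, kind="theta")
            return SurrogateSpec(method="cd", theta=self.theta, anneal=sched)
        sched = AnnealSchedule(self.step_count, self.beta0,
                               self.horizon, kind="beta")
        return SurrogateSpec(
            method=self.method, theta=self.theta, beta=self.beta0,
            strategic_segments=strategic, anneal=sched,
        )


def desk_preset(task_id: str, method: str = "base", **overrides) -> TrainConfig:
    """Small-scale preset: 80 units, short trials, cohorts of 8.

    Desk trials keep the task structure (fixation -> stimulus -> [delay] ->
    response) at ~300 steps instead of 1500-2500, with the anneal horizon
    and step cap shrunk proportionally.  Intended for laptop-scale
    experiments and the test suite; full-scale protocol numbers require the
    defaults in :class:`TrainConfig`.
    """
    cfg = dict(
        task_id=task_id,
        method=method,
        theta=10,
        beta0=0.5,
        step_count=5,
        horizon=400,
        cohort_size=8,
        batch_size=16,
        learning_rate=3e-3,
        max_training_steps=800,
        eval_every=25,
        eval_batch=64,
        n_units=80,
        timing=dict(DESK_TIMING),
        rule_trial_steps={"stim": 50, "resp": 30, "feedback": 20},
    )
    cfg.update(overrides)
    return TrainConfig(**cfg)


@dataclass
class CohortResult:
    steps_to_criterion: int | None
    reached_criterion: bool
    per_network_perf: np.ndarray      # (n_evaluations, cohort_size)
    eval_steps: np.ndarray            # training step of each evaluation
    band_means: np.ndarray
    wall_time_s: float
    flops_estimate: float
    final_params: list
    failed: np.ndarray                # per-network divergence flags
    plateaued: bool | None            # only set for failed cohorts
    losses: np.ndarray = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# loss and criterion
# ---------------------------------------------------------------------------

def masked_mse_loss(outputs, targets, mask):
    """Weighted mean-squared error sum(mask * (o - t)^2) / sum(mask)."""
    outputs = np.asarray(outputs, float)
    targets = np.asarray(targets, float)
    mask = np.asarray(mask, float)
    denom = mask.sum()
    if denom == 0:
        raise ValueError("all-zero loss mask")
    return float(np.sum(mask * (outputs - targets) ** 2) / denom)


def band_mean(perf, lo: float = 10.0, hi: float = 90.0) -> float:
    """Mean of cohort performances ranked in the [lo, hi] percentile band.

    For cohort size n the band holds sorted ranks
    ``ceil(n * lo / 100) + 1 .. floor(n * hi / 100)`` (1-indexed), i.e.
    ranks 11..90 for n = 100 — the bottom and top deciles are excluded.
    """
    perf = np.sort(np.asarray(perf, float))
    n = perf.size
    a = math.ceil(n * lo / 100.0)          # skip this many from the bottom
    b = math.floor(n * hi / 100.0)         # keep through this rank
    if b <= a:                             # tiny cohorts: plain mean
        return float(perf.mean())
    return float(perf[a:b].mean())


def percentile_band_criterion(perf, lo: float = 10.0, hi: float = 90.0,
                              threshold: float = 0.99) -> bool:
    """True when the percentile-band mean performance reaches threshold."""
    return band_mean(perf, lo, hi) >= threshold


# ---------------------------------------------------------------------------
# stacked cohort parameters
# ---------------------------------------------------------------------------

def _stack_cohort(members: list[NetworkParams]) -> dict:
    return {
        "W_rec": np.stack([m.W_rec for m in members]),
        "W_inp": np.stack([m.W_inp for m in members]),
        "W_out": np.stack([m.W_out for m in members]),
        "b": np.stack([m.b for m in members]),
    }


def _unstack_cohort(stack: dict, template: NetworkParams
                    ) -> list[NetworkParams]:
    out = []
    for c in range(stack["W_rec"].shape[0]):
        out.append(replace(
            template,
            W_rec=stack["W_rec"][c].copy(),
            W_inp=stack["W_inp"][c].copy(),
            W_out=stack["W_out"][c].copy(),
            b=stack["b"][c].copy(),
            tau=template.tau.copy(),
        ))
    return out


class _Adam:
    """Adam over a dict of stacked arrays (cohort axis leading)."""

    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def update(self, params: dict, grads: dict, freeze=None):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            upd = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if freeze is not None and freeze.any():
                upd[freeze] = 0.0      # diverged members stay put
            params[k] -= upd


def _clip_grads(grads: dict, clip: float):
    """Per-member global-norm clipping."""
    C = grads["W_rec"].shape[0]
    sq = np.zeros(C)
    for g in grads.values():
        sq += (g.reshape(C, -1) ** 2).sum(axis=1)
    norm = np.sqrt(sq)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(norm > clip, clip / np.maximum(norm, 1e-30), 1.0)
    scale = np.nan_to_num(scale, nan=0.0)
    for k, g in grads.items():
        g *= scale.reshape((C,) + (1,) * (g.ndim - 1))
    return grads


# ---------------------------------------------------------------------------
# forward/backward core (ring tasks, masked MSE on sigmoid readout)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fwd_range(r, states, fprime, W_rec_T, proj, noise, alpha, k0, k1,
               theta_scale):
    """Euler-simulate fine steps [k0, k1) with no segment mixes.

    ``r`` (C, B, N) is the running state, updated in place; per-step states
    and ReLU derivative indicators are written into the tapes.
    """
    C, B, N = r.shape
    for k in range(k0, k1):
        ts = theta_scale[k]
        for c in range(C):
            u = np.dot(r[c], W_rec_T[c])
            for i in range(B):
                for j in range(N):
                    v = u[i, j] + proj[c, i, k, j] + noise[c, i, k, j]
                    if v > 0.0:
                        fprime[c, i, k, j] = 1.0
                    else:
                        fprime[c, i, k, j] = 0.0
                        v = 0.0
                    rn = (1.0 - ts * alpha) * r[c, i, j] + (ts * alpha) * v
                    r[c, i, j] = rn
                    states[c, i, k + 1, j] = rn


@njit(cache=True)
def _bwd_range(carry, delta_states, fprime, states, W_rec, dW_rec, dproj,
               alpha, k0, k1, theta_scale):
    """Reverse-mode pass over fine steps (k1 .. k0+1], no segment mixes.

    ``carry`` (C, B, N) is dL/d(state) flowing backward, updated in place;
    per-step adjoints accumulate into ``dproj`` and ``dW_rec``.
    """
    C, B, N = carry.shape
    g = np.empty((B, N), dtype=carry.dtype)
    d = np.empty((B, N), dtype=carry.dtype)
    for k in range(k1, k0, -1):
        ts = theta_scale[k - 1]
        for c in range(C):
            for i in range(B):
                for j in range(N):
                    dv = carry[c, i, j] + delta_states[c, i, k - 1, j]
                    d[i, j] = dv
                    gv = (ts * alpha) * fprime[c, i, k - 1, j] * dv
                    g[i, j] = gv
                    dproj[c, i, k - 1, j] += gv
            r_prev = np.ascontiguousarray(states[c, :, k - 1, :])
            dW_rec[c] += np.dot(g.T, r_prev)
            gw = np.dot(g, W_rec[c])
            for i in range(B):
                for j in range(N):
                    carry[c, i, j] = (1.0 - ts * alpha) * d[i, j] + gw[i, j]


def _chain_forward(stack, alpha, inp_proj, noise, segments, beta, method,
                   theta_scale):
    """Simulate the (possibly surrogate-modified) chain for the cohort.

    ``inp_proj`` is (C, B, T_sim, N) with bias already added, ``noise``
    likewise; ``theta_scale`` (T_sim,) multiplies the per-step leak factor
    (all ones on the fine grid; the span of each macro step for CD).
    Returns states (C, B, T_sim+1, N), relu-derivative tape, and per-segment
    branch tapes for DASC.
    """
    W_rec = stack["W_rec"]
    dtype = inp_proj.dtype
    C, B, T, N = inp_proj.shape
    states = np.empty((C, B, T + 1, N), dtype=dtype)
    fprime = np.empty((C, B, T, N), dtype=dtype)
    states[:, :, 0, :] = 0.0
    r = np.zeros((C, B, N), dtype=dtype)
    ends: dict[int, list[tuple[int, int]]] = {}
    for s, e in segments:
        ends.setdefault(e, []).append((s, e))
    branch_tapes = {}
    W_rec_T = np.ascontiguousarray(W_rec.transpose(0, 2, 1))
    theta_scale = np.ascontiguousarray(theta_scale, dtype=dtype)
    alpha_s = dtype.type(alpha)
    # numba kernel simulates between segment boundaries; mixes in numpy
    breakpoints = sorted({e for _s, e in segments} | {T})
    k_cur = 0
    for bp in breakpoints:
        if bp > k_cur:
            _fwd_range(r, states, fprime, W_rec_T, inp_proj, noise,
                       alpha_s, k_cur, bp, theta_scale)
            k_cur = bp
        for (s, e) in ends.get(bp, []):
            r_s = states[:, :, s, :]
            if method == "sctt":
                r = (1.0 - beta) * r_s + beta * r
            else:  # dasc
                span = e - s
                u_cd = (np.matmul(r_s, W_rec_T)
                        + inp_proj[:, :, s, :] + noise[:, :, s, :])
                fp_cd = (u_cd > 0.0)
                a_cd = np.where(fp_cd, u_cd, 0.0)
                sa = span * alpha
                r_cd = (1.0 - sa) * r_s + sa * a_cd
                branch_tapes[(s, e)] = fp_cd
                r = (1.0 - beta) * r_cd + beta * r
            states[:, :, bp, :] = r
            r = np.ascontiguousarray(r.astype(dtype, copy=False))
    return states, fprime, branch_tapes


def _chain_backward(stack, alpha, delta_states, fprime, states, segments,
                    beta, method, branch_tapes, theta_scale):
    """Reverse-mode pass; returns grads for W_rec, b and the inp-projection
    delta buffer (used to form W_inp gradients with one matmul)."""
    W_rec = stack["W_rec"]
    dtype = fprime.dtype
    C, B, T, N = fprime.shape
    dW_rec = np.zeros_like(W_rec)
    dproj = np.zeros((C, B, T, N), dtype=dtype)
    pending: dict[int, np.ndarray] = {}
    ends: dict[int, list[tuple[int, int]]] = {}
    for s, e in segments:
        ends.setdefault(e, []).append((s, e))
    carry = np.zeros((C, B, N), dtype=dtype)
    theta_scale = np.ascontiguousarray(theta_scale, dtype=dtype)
    alpha_s = dtype.type(alpha)

    def numpy_step(k):
        # one fully general backward step (segment adjoint splits happen
        # only at these boundary indices)
        nonlocal carry, dW_rec
        delta = carry + delta_states[:, :, k - 1, :]
        if k in pending:
            delta = delta + pending.pop(k)
        if k in ends:
            for (s, e) in reversed(ends[k]):
                if method == "sctt":
                    pending[s] = pending.get(s, 0.0) + (1.0 - beta) * delta
                else:
                    span = e - s
                    sa = span * alpha
                    d_cd = (1.0 - beta) * delta
                    g_cd = sa * (branch_tapes[(s, e)] * d_cd)
                    back = (1.0 - sa) * d_cd + np.matmul(g_cd, W_rec)
                    pending[s] = pending.get(s, 0.0) + back
                    dproj[:, :, s, :] += g_cd
                    r_s = states[:, :, s, :]
                    dW_rec += np.matmul(g_cd.transpose(0, 2, 1), r_s)
                delta = beta * delta
        ts = theta_scale[k - 1]
        g = (ts * alpha) * (fprime[:, :, k - 1, :] * delta)
        dproj[:, :, k - 1, :] += g
        r_prev = states[:, :, k - 1, :]
        dW_rec += np.matmul(g.transpose(0, 2, 1), r_prev)
        carry = ((1.0 - ts * alpha) * delta
                 + np.matmul(g, W_rec)).astype(dtype, copy=False)
        carry = np.ascontiguousarray(carry)

    boundaries = sorted(
        ({e for _s, e in segments} | {s for s, _e in segments if s >= 1})
        & set(range(1, T + 1)),
        reverse=True,
    )
    k_cur = T
    for bp in boundaries:
        if bp < k_cur:
            _bwd_range(carry, delta_states, fprime, states, W_rec, dW_rec,
                       dproj, alpha_s, bp, k_cur, theta_scale)
            k_cur = bp
        numpy_step(bp)
        k_cur = bp - 1
    if k_cur > 0:
        _bwd_range(carry, delta_states, fprime, states, W_rec, dW_rec,
                   dproj, alpha_s, 0, k_cur, theta_scale)
    if 0 in pending:
        carry = carry + pending.pop(0)
    return dW_rec, dproj, carry


def _cast_stack(stack, dtype):
    if stack["W_rec"].dtype == dtype:
        return stack
    return {k: v.astype(dtype) for k, v in stack.items()}


def _bptt_ring_step(stack, cfg: TrainConfig, spec_t: SurrogateSpec,
                    inputs, targets, loss_mask, alpha, rng):
    """One training step's loss and gradients for ring tasks.

    Simulation and backprop run in ``cfg.dtype`` (single precision by
    default — the training signal is far above float32 resolution);
    gradients are returned in float64 for the optimizer accumulators.
    """
    dtype = np.dtype(cfg.dtype)
    stack = _cast_stack(stack, dtype)
    inputs = inputs.astype(dtype, copy=False)
    targets = targets.astype(dtype, copy=False)
    loss_mask = loss_mask.astype(dtype, copy=False)
    alpha = dtype.type(alpha)
    C = stack["W_rec"].shape[0]
    B, T, _ = inputs.shape
    method = spec_t.method
    theta = spec_t.theta

    if method == "cd" and theta > 1:
        m = math.ceil(T / theta)
        idx = np.minimum(np.arange(m) * theta, T - 1)
        end_idx = np.minimum((np.arange(m) + 1) * theta, T)
        theta_scale = (end_idx - idx).astype(float)
        inp = inputs[:, idx, :]
        tgt = targets[:, end_idx - 1, :]
        msk = loss_mask[end_idx - 1, :]
        segments, beta = [], 1.0
        T_sim = m
    else:
        inp, tgt, msk = inputs, targets, loss_mask
        theta_scale = np.ones(T)
        segments = segment_list(spec_t, T) if method in ("sctt", "dasc") else []
        beta = spec_t.beta
        T_sim = T

    # input projection + bias
    W_inp = stack["W_inp"]
    proj = np.matmul(
        inp.reshape(1, B * T_sim, -1), W_inp.transpose(0, 2, 1)
    ).reshape(C, B, T_sim, -1)
    proj += stack["b"][:, None, None, :]

    theta_scale = theta_scale.astype(dtype)
    if cfg.sigma_noise > 0:
        std = noise_std(cfg.sigma_noise, 100.0, cfg.dt)  # scalar tau network
        scale = (std / np.sqrt(theta_scale))[None, None, :, None]
        noise = rng.standard_normal(proj.shape, dtype=dtype)
        noise *= scale.astype(dtype)
    else:
        noise = np.zeros_like(proj)

    states, fprime, btapes = _chain_forward(
        stack, alpha, proj, noise, segments, beta,
        method if method in ("sctt", "dasc") else "base", theta_scale,
    )

    # loss on sigmoid readout against (possibly coarse) targets
    W_out = stack["W_out"]
    logits = np.matmul(
        states[:, :, 1:, :].reshape(C, B * T_sim, -1),
        W_out.transpose(0, 2, 1),
    ).reshape(C, B, T_sim, -1)
    # sigmoid + masked-MSE adjoint, computed with minimal temporaries
    with np.errstate(over="ignore", invalid="ignore"):
        np.negative(logits, out=logits)
        np.exp(logits, out=logits)
        logits += 1.0
        y = np.reciprocal(logits, out=logits)     # y = sigmoid(original)
    denom = msk.sum() * B
    err = y - tgt[None]
    losses = np.einsum("cbto,cbto,to->c", err, err, msk) / denom
    ygrad = y * (1.0 - y)
    dlog = np.multiply(err, ygrad, out=ygrad)
    dlog *= msk[None, None]
    dlog *= dtype.type(2.0 / denom)
    dW_out = np.matmul(
        dlog.reshape(C, B * T_sim, -1).transpose(0, 2, 1),
        states[:, :, 1:, :].reshape(C, B * T_sim, -1),
    )
    delta_states = np.matmul(
        dlog.reshape(C, B * T_sim, -1), W_out
    ).reshape(C, B, T_sim, -1)
    if cfg.rate_penalty > 0:
        # L2 activity regularization, standard for leaky rate RNNs: keeps
        # the sigmoid readout from being satisfied by runaway rates
        n_el = states[:, :, 1:, :].size // C
        losses = losses + cfg.rate_penalty * np.einsum(
            "cbtn,cbtn->c", states[:, :, 1:, :], states[:, :, 1:, :]
        ) / n_el
        delta_states = delta_states + (
            2.0 * cfg.rate_penalty / n_el
        ) * states[:, :, 1:, :]

    dW_rec, dproj, _dr0 = _chain_backward(
        stack, alpha, delta_states, fprime, states, segments, beta,
        method if method in ("sctt", "dasc") else "base", btapes,
        theta_scale,
    )
    db = dproj.sum(axis=(1, 2))
    dW_inp = np.matmul(
        dproj.reshape(C, B * T_sim, -1).transpose(0, 2, 1),
        inp.reshape(B * T_sim, -1),
    )
    grads = {"W_rec": dW_rec.astype(np.float64),
             "W_inp": dW_inp.astype(np.float64),
             "W_out": dW_out.astype(np.float64),
             "b": db.astype(np.float64)}
    losses = losses.astype(np.float64)
    max_rate = np.abs(states).reshape(C, -1).max(axis=1)
    diverged = ~np.isfinite(losses) | (max_rate > STATE_DIVERGENCE_BOUND)
    return losses, grads, diverged, states


# ---------------------------------------------------------------------------
# evaluation (ring tasks)
# ---------------------------------------------------------------------------

def _eval_ring(stack, cfg, spec_t, inputs, target_dirs, resp_epoch,
               alpha, rng):
    """Per-member performance on a fixed batch under the current spec."""
    dtype = np.dtype(cfg.dtype)
    stack = _cast_stack(stack, dtype)
    inputs = inputs.astype(dtype, copy=False)
    alpha = dtype.type(alpha)
    C = stack["W_rec"].shape[0]
    B, T, _ = inputs.shape
    method, theta = spec_t.method, spec_t.theta
    if method == "cd" and theta > 1:
        m = math.ceil(T / theta)
        idx = np.minimum(np.arange(m) * theta, T - 1)
        tindex = np.minimum((np.arange(m) + 1) * theta, T)
        theta_scale = (tindex - np.minimum(np.arange(m) * theta, T)).astype(float)
        inp = inputs[:, idx, :]
        segments, beta = [], 1.0
        T_sim = m
    else:
        inp = inputs
        tindex = np.arange(1, T + 1)
        theta_scale = np.ones(T)
        segments = segment_list(spec_t, T) if method in ("sctt", "dasc") else []
        beta = spec_t.beta
        T_sim = T

    W_inp = stack["W_inp"]
    proj = np.matmul(
        inp.reshape(1, B * T_sim, -1), W_inp.transpose(0, 2, 1)
    ).reshape(C, B, T_sim, -1)
    proj += stack["b"][:, None, None, :]
    theta_scale = theta_scale.astype(dtype)
    if cfg.sigma_noise > 0:
        std = noise_std(cfg.sigma_noise, 100.0, cfg.dt)
        noise = rng.standard_normal(proj.shape, dtype=dtype)
        noise *= (std / np.sqrt(theta_scale))[None, None, :, None].astype(dtype)
    else:
        noise = np.zeros_like(proj)
    states, _, _ = _chain_forward(
        stack, alpha, proj, noise, segments, beta,
        method if method in ("sctt", "dasc") else "base", theta_scale,
    )
    W_out = stack["W_out"]
    logits = np.matmul(
        states[:, :, 1:, :].reshape(C, B * T_sim, -1),
        W_out.transpose(0, 2, 1),
    ).reshape(C, B, T_sim, -1)
    with np.errstate(over="ignore", invalid="ignore"):
        y = 1.0 / (1.0 + np.exp(-logits))
    y = np.nan_to_num(y, nan=0.0)

    r0, r1 = resp_epoch
    resp_sel = (tindex > r0) & (tindex <= r1)
    pre_sel = (tindex >= tasks.GRACE_STEPS) & (tindex <= r0)
    ring = y[:, :, resp_sel, 1:].mean(axis=2) - tasks.TARGET_BASELINE
    vx = ring @ np.cos(tasks.RING_PREFS)
    vy = ring @ np.sin(tasks.RING_PREFS)
    dec = np.arctan2(vy, vx) % (2 * np.pi)
    has_dir = np.hypot(vx, vy) >= tasks.DECODE_MIN_NORM
    broken = np.any(y[:, :, pre_sel, 0] < tasks.FIX_THRESHOLD, axis=2)
    saccade = y[:, :, resp_sel, 0].mean(axis=2) < tasks.FIX_THRESHOLD

    needs = ~np.isnan(target_dirs)
    tgt = np.where(needs, target_dirs, 0.0)
    err = np.abs((dec - tgt + np.pi) % (2 * np.pi) - np.pi)
    ok_sac = needs & saccade & has_dir & (err < tasks.DECODE_TOL_RAD)
    ok_hold = ~needs & ~saccade
    correct = (~broken) & (ok_sac | ok_hold)
    return correct.mean(axis=1)


# ---------------------------------------------------------------------------
# rule-reversal task (softmax readout, cross-entropy, closed loop)
# ---------------------------------------------------------------------------

def _rule_batch(cfg: TrainConfig, rng):
    """Sample stimuli/rules for a batch of episodes (no feedback yet)."""
    B, nt = cfg.batch_size, cfg.n_trials
    stimuli = rng.integers(0, 2, size=(B, nt))
    rules = np.empty((B, nt), dtype=int)
    start = rng.integers(1, 3, size=B)
    switch_at = np.where(
        rng.random(B) < 0.8, rng.integers(1, max(nt, 2), size=B), -1
    )
    for i in range(nt):
        flip = (switch_at == i).astype(int)
        start = np.where(flip, 3 - start, start)
        rules[:, i] = start
    correct = np.where(rules == 1, stimuli, 1 - stimuli)
    return stimuli, rules, correct


def _rule_forward(stack, cfg, spec_t, stimuli, correct, alpha, rng,
                  want_grads=True):
    """Closed-loop episode simulation with softmax/cross-entropy loss.

    Feedback inputs for each trial are set from the member's own response
    (argmax of mean response-epoch logits), so rule switches are only
    observable through feedback, as in the behaving-animal task.
    """
    dtype = np.dtype(cfg.dtype)
    stack = _cast_stack(stack, dtype)
    alpha = dtype.type(alpha)
    C = stack["W_rec"].shape[0]
    B, nt = stimuli.shape
    ts = dict(tasks.RULE_TRIAL_STEPS)
    if cfg.rule_trial_steps:
        ts.update(cfg.rule_trial_steps)
    L = ts["stim"] + ts["resp"] + ts["feedback"]
    T = nt * L
    boundaries = np.arange(nt) * L
    segments = (segment_list(spec_t, T)
                if spec_t.method in ("sctt", "dasc") else [])
    beta = spec_t.beta
    method = spec_t.method
    N = stack["W_rec"].shape[1]

    W_rec_T = stack["W_rec"].transpose(0, 2, 1)
    W_inp_T = stack["W_inp"].transpose(0, 2, 1)
    W_out = stack["W_out"]

    if cfg.sigma_noise > 0:
        std = noise_std(cfg.sigma_noise, 100.0, cfg.dt)
        noise = rng.standard_normal((C, B, T, N), dtype=dtype)
        noise *= dtype.type(std)
    else:
        noise = np.zeros((C, B, T, N), dtype=dtype)

    inputs = np.zeros((C, B, T, RULE_N_INPUTS), dtype=dtype)
    for i, t0 in enumerate(boundaries):
        sl = slice(t0, t0 + ts["stim"] + ts["resp"])
        onehot = np.eye(2, dtype=dtype)[stimuli[:, i]]   # (B, 2)
        inputs[:, :, sl, 0:2] = onehot[None, :, None, :]

    states = np.empty((C, B, T + 1, N), dtype=dtype)
    fprime = np.empty((C, B, T, N), dtype=bool)
    states[:, :, 0, :] = 0.0
    r = np.zeros((C, B, N), dtype=dtype)
    ends: dict[int, list[tuple[int, int]]] = {}
    for s, e in segments:
        ends.setdefault(e, []).append((s, e))
    btapes = {}
    responses = np.zeros((C, B, nt), dtype=int)
    fb_starts = {int(t0 + ts["stim"] + ts["resp"]): i
                 for i, t0 in enumerate(boundaries)}
    b_bias = stack["b"][:, None, :]

    for k in range(T):
        if k in fb_starts:
            i = fb_starts[k]
            r0_, r1_ = (boundaries[i] + ts["stim"],
                        boundaries[i] + ts["stim"] + ts["resp"])
            mean_logits = np.matmul(
                states[:, :, r0_ + 1: r1_ + 1, :].mean(axis=2),
                W_out.transpose(0, 2, 1),
            )
            resp = np.argmax(mean_logits, axis=-1)      # (C, B)
            responses[:, :, i] = resp
            fb_pos = (resp == correct[None, :, i])
            # channel 2 = positive feedback, 3 = negative
            fb = np.stack([fb_pos, ~fb_pos], axis=-1).astype(dtype)
            inputs[:, :, k: k + ts["feedback"], 2:4] = fb[:, :, None, :]
        h = inputs[:, :, k, :]
        u = (np.matmul(r, W_rec_T) + np.matmul(h, W_inp_T)
             + b_bias + noise[:, :, k, :])
        fp = u > 0.0
        a = np.where(fp, u, 0.0)
        fprime[:, :, k, :] = fp
        r = (1.0 - alpha) * r + alpha * a
        if (k + 1) in ends:
            for (s, e) in ends[k + 1]:
                r_s = states[:, :, s, :]
                if method == "sctt":
                    r = (1.0 - beta) * r_s + beta * r
                else:
                    span = e - s
                    u_cd = (np.matmul(r_s, W_rec_T)
                            + np.matmul(inputs[:, :, s, :], W_inp_T)
                            + b_bias + noise[:, :, s, :])
                    fp_cd = u_cd > 0.0
                    a_cd = np.where(fp_cd, u_cd, 0.0)
                    sa = span * alpha
                    r_cd = (1.0 - sa) * r_s + sa * a_cd
                    btapes[(s, e)] = fp_cd
                    r = (1.0 - beta) * r_cd + beta * r
        states[:, :, k + 1, :] = r

    # cross-entropy over response-epoch steps
    delta_states = np.zeros((C, B, T, N), dtype=dtype)
    loss = np.zeros(C)
    n_terms = nt * ts["resp"] * B
    for i, t0 in enumerate(boundaries):
        r0_, r1_ = t0 + ts["stim"], t0 + ts["stim"] + ts["resp"]
        seg = states[:, :, r0_ + 1: r1_ + 1, :]
        logits = np.matmul(
            seg.reshape(C, -1, N), W_out.transpose(0, 2, 1)
        ).reshape(C, B, ts["resp"], RULE_N_OUTPUTS)
        z = logits - logits.max(axis=-1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=-1, keepdims=True)
        onehot = np.eye(RULE_N_OUTPUTS)[correct[:, i]]   # (B, 2)
        p_correct = (p * onehot[None, :, None, :]).sum(axis=-1)
        loss += -np.log(np.maximum(p_correct, 1e-12)).sum(axis=(1, 2)) / n_terms
        if want_grads:
            dlog = (p - onehot[None, :, None, :]) / n_terms
            delta_states[:, :, r0_: r1_, :] += np.matmul(
                dlog.reshape(C, -1, RULE_N_OUTPUTS), W_out
            ).reshape(C, B, ts["resp"], N)

    if cfg.rate_penalty > 0:
        n_el = states[:, :, 1:, :].size // C
        loss = loss + cfg.rate_penalty * np.einsum(
            "cbtn,cbtn->c", states[:, :, 1:, :], states[:, :, 1:, :]
        ) / n_el
        if want_grads:
            delta_states += (2.0 * cfg.rate_penalty / n_el) * states[:, :, 1:, :]

    accuracy = (responses == correct[None]).mean(axis=(1, 2))
    if not want_grads:
        return loss, None, responses, accuracy, states

    # dW_out over all response steps
    dW_out = np.zeros_like(W_out)
    for i, t0 in enumerate(boundaries):
        r0_, r1_ = t0 + ts["stim"], t0 + ts["stim"] + ts["resp"]
        seg = states[:, :, r0_ + 1: r1_ + 1, :]
        logits = np.matmul(
            seg.reshape(C, -1, N), W_out.transpose(0, 2, 1)
        ).reshape(C, B, ts["resp"], RULE_N_OUTPUTS)
        z = logits - logits.max(axis=-1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=-1, keepdims=True)
        onehot = np.eye(RULE_N_OUTPUTS)[correct[:, i]]
        dlog = (p - onehot[None, :, None, :]) / n_terms
        dW_out += np.matmul(
            dlog.reshape(C, -1, RULE_N_OUTPUTS).transpose(0, 2, 1),
            seg.reshape(C, -1, N),
        )

    theta_scale = np.ones(T, dtype=dtype)
    dW_rec, dproj, _dr0 = _chain_backward(
        stack, alpha, delta_states, fprime.astype(dtype), states, segments,
        beta, method if method in ("sctt", "dasc") else "base", btapes,
        theta_scale,
    )
    db = dproj.sum(axis=(1, 2))
    dW_inp = np.matmul(
        dproj.reshape(C, B * T, N).transpose(0, 2, 1),
        inputs.reshape(C, B * T, RULE_N_INPUTS),
    )
    grads = {"W_rec": dW_rec.astype(np.float64),
             "W_inp": dW_inp.astype(np.float64),
             "W_out": dW_out.astype(np.float64),
             "b": db.astype(np.float64)}
    return np.asarray(loss, dtype=np.float64), grads, responses, accuracy, states


# ---------------------------------------------------------------------------
# cohort training
# ---------------------------------------------------------------------------

def flop_estimate(config: TrainConfig, steps: int) -> float:
    """Analytic FLOP count for ``steps`` training steps.

    Per simulated Euler step and trial the dominant cost is
    ``2 n^2 + 2 n (n_in + n_out)`` multiply-adds; forward plus backward is
    counted as 3x that, times batch size and the number of simulated steps,
    which CD divides by the discretization factor active at each training
    step.
    """
    if steps <= 0:
        return 0.0
    n = config.n_units
    if config.is_rule_task:
        ts = dict(tasks.RULE_TRIAL_STEPS)
        if config.rule_trial_steps:
            ts.update(config.rule_trial_steps)
        n_steps = config.n_trials * sum(ts.values())
        n_io = RULE_N_INPUTS + RULE_N_OUTPUTS
    else:
        if config.timing:
            t = dict(DESK_TIMING)
            t.update(config.timing)
            n_steps = sum(t.values())
        else:
            n_steps = 2000  # nominal mid-range trial length
        n_io = N_INPUTS + N_OUTPUTS
    per_sim_step = 3.0 * config.batch_size * (2.0 * n * n + 2.0 * n * n_io)
    spec = config.surrogate_spec(n_steps)
    total = 0.0
    for t_step in range(steps):
        if config.method == "cd":
            th = spec.at_step(t_step).theta
            total += per_sim_step * math.ceil(n_steps / th)
        else:
            total += per_sim_step * n_steps
    return float(total)


def train_cohort(config: TrainConfig) -> CohortResult:
    """Train a cohort of independently initialized networks in lockstep.

    Members share the task stream (fresh batch each training step) but have
    independent initializations and noise.  Evaluation happens every
    ``eval_every`` steps on a frozen held-out batch under the currently
    annealed surrogate (the pure base model once past the horizon); the
    cohort stops at the percentile-band criterion or at the step cap, in
    which case a plateau check runs on the band-mean curve.
    """
    t_start = time.perf_counter()
    C = config.cohort_size
    ss = np.random.SeedSequence(config.seed_base)
    init_ss, task_ss, noise_ss, eval_ss = ss.spawn(4)
    init_seeds = init_ss.spawn(C)

    is_rule = config.is_rule_task
    n_inputs = RULE_N_INPUTS if is_rule else N_INPUTS
    n_outputs = RULE_N_OUTPUTS if is_rule else N_OUTPUTS
    members = [
        init_network(
            config.n_units, n_inputs, n_outputs,
            seed=np.random.default_rng(s),
            sigma_noise=config.sigma_noise,
            readout="softmax" if is_rule else "sigmoid",
        )
        for s in init_seeds
    ]
    template = members[0].copy()
    stack = _stack_cohort(members)
    alpha = config.dt / 100.0  # scalar: uniform tau = 100 ms

    pmask = None
    if not is_rule:
        n_pop = max(1, config.n_units // 4)
        pmask = population_masks(config.n_units, n_pop, n_pop)
        stack["W_inp"] *= pmask.inp_mask[None]
        stack["W_out"] *= pmask.out_mask[None]

    task_rng = np.random.default_rng(task_ss)
    noise_rng = np.random.default_rng(noise_ss)
    eval_batch_ss, eval_noise_ss = eval_ss.spawn(2)

    # frozen evaluation batch
    if is_rule:
        eval_rng = np.random.default_rng(eval_batch_ss)
        ecfg = replace(config, batch_size=config.eval_batch)
        e_stim, _e_rules, e_correct = _rule_batch(ecfg, eval_rng)
        trial_boundaries = None
        ts = dict(tasks.RULE_TRIAL_STEPS)
        if config.rule_trial_steps:
            ts.update(config.rule_trial_steps)
        L = ts["stim"] + ts["resp"] + ts["feedback"]
        trial_boundaries = list(np.arange(config.n_trials) * L)
        n_steps = config.n_trials * L
    else:
        eval_rng = np.random.default_rng(eval_batch_ss)
        e_inputs, _et, _em, e_dirs, e_resp = generate_batch(
            config.task_id, eval_rng, config.eval_batch, config.timing,
            config.n_directions, config.gamma_scale,
        )
        trial_boundaries = None
        n_steps = e_inputs.shape[1]

    spec = config.surrogate_spec(n_steps, trial_boundaries)

    failed = np.zeros(C, dtype=bool)
    perf_rows, eval_steps, band_means, loss_rows = [], [], [], []
    adam = _Adam({k: v.shape for k, v in stack.items()},
                 config.learning_rate)
    steps_to_criterion = None
    reached = False
    steps_run = 0

    def evaluate(t_step):
        spec_t = spec.at_step(t_step)
        ev_rng = np.random.default_rng(eval_noise_ss)  # frozen noise stream
        if is_rule:
            _l, _g, _r, acc, _s = _rule_forward(
                stack, replace(config, batch_size=config.eval_batch),
                spec_t, e_stim, e_correct, alpha, ev_rng, want_grads=False,
            )
            perf = acc
        else:
            perf = _eval_ring(
                stack, config, spec_t, e_inputs, e_dirs, e_resp,
                alpha, ev_rng,
            )
        perf = np.where(failed, 0.0, np.nan_to_num(perf, nan=0.0))
        return perf

    for t_step in range(config.max_training_steps + 1):
        if t_step % config.eval_every == 0 or t_step == config.max_training_steps:
            perf = evaluate(t_step)
            perf_rows.append(perf)
            eval_steps.append(t_step)
            bm = band_mean(perf)
            band_means.append(bm)
            if bm >= config.criterion:
                steps_to_criterion = t_step
                reached = True
                break
        if t_step == config.max_training_steps:
            break
        spec_t = spec.at_step(t_step)
        if is_rule:
            stim, _rules, correct = _rule_batch(config, task_rng)
            losses, grads, _resp, _acc, states = _rule_forward(
                stack, config, spec_t, stim, correct, alpha, noise_rng,
            )
            max_rate = np.abs(states).reshape(C, -1).max(axis=1)
            diverged = ~np.isfinite(losses) | (max_rate > STATE_DIVERGENCE_BOUND)
        else:
            inputs, targets, loss_mask, _dirs, _resp_ep = generate_batch(
                config.task_id, task_rng, config.batch_size, config.timing,
                config.n_directions, config.gamma_scale,
            )
            losses, grads, diverged, _states = _bptt_ring_step(
                stack, config, spec_t, inputs, targets, loss_mask,
                alpha, noise_rng,
            )
        failed |= diverged
        loss_rows.append(np.where(failed, np.nan, losses))
        for g in grads.values():
            np.nan_to_num(g, copy=False, nan=0.0, posinf=0.0, neginf=0.0)
        _clip_grads(grads, config.grad_clip)
        adam.update(stack, grads, freeze=failed)
        if pmask is not None:
            stack["W_inp"] *= pmask.inp_mask[None]
            stack["W_out"] *= pmask.out_mask[None]
        steps_run = t_step + 1

    per_network_perf = np.array(perf_rows)
    band_arr = np.array(band_means)
    plateaued = None
    if not reached and len(band_arr) >= 3:
        tail = max(2, len(band_arr) // 10)
        seg = band_arr[-tail:]
        slope = np.polyfit(np.arange(seg.size), seg, 1)[0]
        plateaued = bool(abs(slope) < PLATEAU_SLOPE_TOL)

    final_steps = (steps_to_criterion if steps_to_criterion is not None
                   else steps_run)
    return CohortResult(
        steps_to_criterion=steps_to_criterion,
        reached_criterion=reached,
        per_network_perf=per_network_perf,
        eval_steps=np.array(eval_steps),
        band_means=band_arr,
        wall_time_s=time.perf_counter() - t_start,
        flops_estimate=flop_estimate(config, final_steps),
        final_params=_unstack_cohort(stack, template),
        failed=failed,
        plateaued=plateaued,
        losses=np.array(loss_rows) if loss_rows else np.empty((0, C)),
    )


def train_network(config: TrainConfig, network_seed: int):
    """Train a single network (cohort machinery with cohort_size 1).

    Returns ``(params, perf_curve, eval_steps)``.  The stopping criterion
    degenerates to the single network's own performance.
    """
    cfg = replace(config, cohort_size=1, seed_base=int(network_seed))
    res = train_cohort(cfg)
    return res.final_params[0], res.per_network_perf[:, 0], res.eval_steps
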