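"""Result serialization, content-hashed manifests, deterministic fixtures."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import DiscrepancyReport
from .model import NetworkParams, init_network, save_checkpoint
from .surrogates import SurrogateSpec, simulate_with_surrogate
from .tasks import TaskTensor, RuleEpisode, generate_rule_episode, generate_trial
from .training import CohortResult

__all__ = ["write_results", "verify_manifest", "make_fixtures", "FixtureBundle"]


def _atomic_write(path: Path, data: bytes) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=".tmp-")
    try:
        with os.fdopen(fd, "wb") as f:
            f.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(result, out_dir) -> dict:
    """Write CSV tables, a JSON summary and checkpoints; return the manifest.

    ``result`` is a :class:`CohortResult` or a list of
    :class:`DiscrepancyReport`.  Files are written atomically (temp file +
    rename) and the manifest lists every artifact with a sha256 content
    hash; wall-time goes only in the summary so reruns are byte-identical
    otherwise.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = []

    def emit(name: str, data: bytes):
        p = out / name
        _atomic_write(p, data)
        artifacts.append({"name": name, "sha256": _sha256(p)})

    if isinstance(result, CohortResult):
        df = pd.DataFrame(
            result.per_network_perf,
            index=pd.Index(result.eval_steps, name="training_step"),
            columns=[f"net{i}" for i in
                     range(result.per_network_perf.shape[1])],
        )
        df["band_mean"] = result.band_means
        emit("performance.csv", df.to_csv().encode())
        summary = {
            "steps_to_criterion": result.steps_to_criterion,
            "reached_criterion": result.reached_criterion,
            "flops_estimate": result.flops_estimate,
            "n_failed": int(result.failed.sum()),
            "plateaued": result.plateaued,
            "wall_time_s": result.wall_time_s,
        }
        emit("summary.json", (json.dumps(summary, indent=2) + "\n").encode())
        ckpt_dir = out / "checkpoints"
        ckpt_dir.mkdir(exist_ok=True)
        for i, params in enumerate(result.final_params):
            p = ckpt_dir / f"net{i}.npz"
            save_checkpoint(p, params)
            artifacts.append(
                {"name": f"checkpoints/net{i}.npz", "sha256": _sha256(p)}
            )
    elif isinstance(result, list) and all(
        isinstance(r, DiscrepancyReport) for r in result
    ):
        rows = [dataclasses.asdict(r) for r in result]
        df = pd.DataFrame(
            rows, columns=["method", "theta", "beta", "nmse", "perf_gap",
                           "n_networks", "task_id", "unstable"],
        )
        emit("discrepancy.csv", df.to_csv(index=False).encode())
        emit("summary.json", (json.dumps(
            {"n_cells": len(rows),
             "n_unstable": int(sum(r["unstable"] for r in rows))},
            indent=2) + "\n").encode())
    else:
        raise TypeError(f"cannot serialize result of type {type(result)!r}")

    manifest = {"artifacts": artifacts}
    _atomic_write(out / "manifest.json",
                  (json.dumps(manifest, indent=2) + "\n").encode())
    return manifest


def verify_manifest(out_dir) -> bool:
    """Re-hash every artifact; False on any mismatch or missing file."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    for a in manifest["artifacts"]:
        p = out / a["name"]
        if not p.exists() or _sha256(p) != a["sha256"]:
            return False
    return True


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

FIXTURE_THETA = 4
FIXTURE_BETA = 0.5


@dataclass
class FixtureBundle:
    """Tiny deterministic instances used as regression anchors in tests."""

    params: NetworkParams
    trial: TaskTensor
    episode: RuleEpisode
    golden: dict            # method -> StateTrajectory at theta=4, beta=0.5
    seed: int


def make_fixtures(seed: int = 0) -> FixtureBundle:
    """Deterministic 4-unit network, 200-step go trial, 3-trial episode and
    golden base/CD/SCTT/DASC trajectories (theta=4, beta=0.5, zero noise)."""
    ss = np.random.SeedSequence(seed)
    net_ss, trial_ss, ep_ss = ss.spawn(3)
    params = init_network(
        4, 65, 33, seed=np.random.default_rng(net_ss), sigma_noise=0.0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # desk-length trial is intentional
        trial = generate_trial(
            "go", np.random.default_rng(trial_ss),
            timing_overrides={"fix": 40, "stim": 60, "resp": 100},
        )
    episode = generate_rule_episode(
        3, rng_seed=np.random.default_rng(ep_ss),
        trial_steps={"stim": 30, "resp": 20, "feedback": 10},
    )
    golden = {}
    for method in ("base", "cd", "sctt", "dasc"):
        spec = SurrogateSpec(method=method, theta=FIXTURE_THETA,
                             beta=FIXTURE_BETA)
        golden[method] = simulate_with_surrogate(
            params, trial.inputs, trial.meta.dt, spec, seed=seed
        )
    return FixtureBundle(params=params, trial=trial, episode=episode,
                         golden=golden, seed=seed)
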