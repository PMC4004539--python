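"""Seeded reproductions of the model's four numerical studies.

Each experiment is a pure function of its parameters and master seed: the
master seed deterministically spawns independent substreams per grid point
and replicate, so any single replicate can be re-run in isolation.

The studies:

* :func:`trajectory_experiment` — one run with the full group-size history
  (spontaneous coalescence of a 30-agent society from a sparse start).
* :func:`gamma_comparison` — outcome-class frequencies as the congruity
  exponent gamma varies (gamma > 1 fragments the society into several
  tight clusters; gamma <= 1 favors one large coalition).
* :func:`checkerboard_experiment` — a two-agent slice of the initial
  configuration space, classifying the basin of attraction of each
  composite start (unified vs ostracism vs fragmented).
* :func:`philanthropist_sweep` — Monte Carlo statistics of minimum group
  size and outcast probabilities with and without a sole philanthropist
  (gamma = 0), swept over the initial friendliness ratio p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import LABELS, classify_outcome, clusters, min_group_size
from .model import (
    AgentParameters,
    FeelingConfiguration,
    ParameterError,
    Trajectory,
    UpdateSchedule,
    init_random,
    run_dynamics,
)

__all__ = [
    "SweepResult",
    "CheckerboardResult",
    "trajectory_experiment",
    "gamma_comparison",
    "checkerboard_experiment",
    "philanthropist_sweep",
    "CLASS_CODES",
]

#: Integer codes used in checkerboard matrices and their PGM rendering
#: (white = unified, black = ostracism, gray = fragmented).
CLASS_CODES = {"unified": 0, "ostracism": 1, "fragmented": 2}


def _replicate_seeds(master_seed: int, *key: int) -> tuple:
    """Two child seed sequences (initial config, dynamics) for one replicate."""
    ss = np.random.SeedSequence(master_seed, spawn_key=key)
    init_ss, dyn_ss = ss.spawn(2)
    return init_ss, dyn_ss


def _seed_int(ss: np.random.SeedSequence) -> int:
    # init_random takes a plain integer seed so runs are easy to replay by hand
    return int(ss.generate_state(1, np.uint32)[0])


@dataclass
class SweepResult:
    """Tabular summary of a Monte Carlo parameter sweep.

    ``table`` holds one row per grid point; ``replicates`` and ``seed``
    record how the statistics were produced.
    """

    table: pd.DataFrame
    replicates: int
    seed: int
    metadata: dict = field(default_factory=dict)


@dataclass
class CheckerboardResult:
    """Outcome-class matrix over a two-agent slice of configuration space.

    ``codes[a, b]`` classifies the run started from candidate vector ``a``
    for agent 1 and ``b`` for agent 2 (0 unified, 1 ostracism, 2 fragmented).
    """

    codes: np.ndarray
    base_seed: int
    p_base: float
    metadata: dict = field(default_factory=dict)


def trajectory_experiment(
    n_agents: int = 30,
    p_friend: float = 0.4,
    gamma: float = 1.0,
    horizon: int = 20,
    seed: int = 0,
    penalty_lambda: float = 0.0,
    update_rule: str = "synchronous",
):
    """Single seeded run; returns the trajectory and a tidy group-size table.

    The table has one row per (time, agent) pair with that agent's ego-group
    size, agents numbered from 1.
    """
    init_ss, dyn_ss = _replicate_seeds(seed, 0, 0)
    config = init_random(n_agents, p_friend, _seed_int(init_ss))
    params = AgentParameters.uniform(n_agents, gamma=gamma, penalty_lambda=penalty_lambda)
    schedule = UpdateSchedule(rule=update_rule, rng_seed=_seed_int(dyn_ss))
    traj = run_dynamics(config, params, schedule, horizon=horizon)

    n_times = traj.group_sizes.shape[0]
    table = pd.DataFrame(
        {
            "t": np.repeat(np.arange(n_times), n_agents),
            "agent": np.tile(np.arange(1, n_agents + 1), n_times),
            "group_size": traj.group_sizes.ravel(),
        }
    )
    return traj, table


def _run_replicate(
    n_agents: int,
    p_friend: float,
    params: AgentParameters,
    horizon: int,
    master_seed: int,
    key: tuple,
    update_rule: str = "synchronous",
) -> FeelingConfiguration:
    init_ss, dyn_ss = _replicate_seeds(master_seed, *key)
    config = init_random(n_agents, p_friend, _seed_int(init_ss))
    schedule = UpdateSchedule(rule=update_rule, rng_seed=_seed_int(dyn_ss))
    traj = run_dynamics(config, params, schedule, horizon=horizon)
    return traj.final


def gamma_comparison(
    n_agents: int = 30,
    p_friend: float = 1.0 / 3.0,
    gamma_values: Sequence[float] = (1.0, 1.5),
    replicates: int = 200,
    seed: int = 0,
    horizon: int = 40,
) -> pd.DataFrame:
    """Outcome-class frequencies and mean cluster count per gamma.

    Initial configurations are matched across gamma values (replicate k uses
    the same start for every gamma), isolating the effect of the exponent.
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    rows = []
    for g_idx, gamma in enumerate(gamma_values):
        params = AgentParameters.uniform(n_agents, gamma=gamma)
        counts = {lab: 0 for lab in LABELS}
        n_clusters_total = 0
        for rep in range(replicates):
            # spawn key omits gamma so starts are paired across gamma values
            final = _run_replicate(
                n_agents, p_friend, params, horizon, seed, (0, rep)
            )
            outcome = classify_outcome(final)
            counts[outcome.label] += 1
            n_clusters_total += len(outcome.cluster_sizes)
        row = {"gamma": gamma}
        row.update({f"frac_{lab}": counts[lab] / replicates for lab in LABELS})
        row["mean_n_clusters"] = n_clusters_total / replicates
        row["replicates"] = replicates
        rows.append(row)
    return pd.DataFrame(rows)


def checkerboard_experiment(
    n_agents: int = 30,
    base_seed: int = 0,
    p_base: float = 0.3,
    states_per_agent: int = 64,
    horizon: int = 40,
) -> CheckerboardResult:
    """Classify the dynamics' outcome over a two-agent slice of start space.

    The feeling vectors of agents 3..N are drawn once with friendliness
    probability ``p_base`` and frozen.  ``states_per_agent`` candidate
    vectors are drawn (same ``p_base``) for agent 1 and for agent 2; cell
    (a, b) runs the dynamics from the composite start and stores the outcome
    class code.  Fixed seeds make the matrix bit-reproducible.
    """
    if states_per_agent < 1:
        raise ParameterError("states_per_agent must be >= 1")
    ss = np.random.SeedSequence(base_seed, spawn_key=(1,))
    bg_ss, cand1_ss, cand2_ss, dyn_ss = ss.spawn(4)

    background = init_random(n_agents, p_base, _seed_int(bg_ss)).matrix

    def draw_candidates(child_ss):
        rng = np.random.default_rng(child_ss)
        rows = np.where(
            rng.random((states_per_agent, n_agents)) < p_base, 1, -1
        ).astype(np.int8)
        return rows

    cand1 = draw_candidates(cand1_ss)
    cand2 = draw_candidates(cand2_ss)
    cand1[:, 0] = 1  # self-entries stay +1
    cand2[:, 1] = 1

    params = AgentParameters.uniform(n_agents, gamma=1.0)
    dyn_seed = _seed_int(dyn_ss)
    codes = np.empty((states_per_agent, states_per_agent), dtype=np.int8)
    for a in range(states_per_agent):
        for b in range(states_per_agent):
            matrix = background.copy()
            matrix[0] = cand1[a]
            matrix[1] = cand2[b]
            config = FeelingConfiguration(matrix)
            schedule = UpdateSchedule(
                rule="synchronous",
                rng_seed=int(
                    np.random.SeedSequence(
                        dyn_seed, spawn_key=(a, b)
                    ).generate_state(1, np.uint32)[0]
                ),
            )
            traj = run_dynamics(config, params, schedule, horizon=horizon)
            codes[a, b] = CLASS_CODES[classify_outcome(traj.final).label]
    return CheckerboardResult(
        codes=codes,
        base_seed=base_seed,
        p_base=p_base,
        metadata={
            "n_agents": n_agents,
            "states_per_agent": states_per_agent,
            "horizon": horizon,
        },
    )


def philanthropist_sweep(
    n_agents: int = 30,
    p_grid: Optional[Sequence[float]] = None,
    replicates: int = 1000,
    horizon: int = 40,
    seed: int = 0,
    philanthropist_present: bool = True,
) -> SweepResult:
    """Monte Carlo sweep over the initial friendliness ratio p.

    With ``philanthropist_present`` agent 1 has gamma = 0 and agents 2..N
    have gamma = 1; otherwise all agents have gamma = 1.  For each p the
    sweep reports the mean minimum group size at the horizon, the outcast
    probability of agent 1 and of the other agents (pooled), and the
    outcome-class frequencies.  Replicate starts are matched between the
    philanthropist and baseline arms (the spawn keys do not depend on the
    agent parameters), enabling paired comparisons.
    """
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    if p_grid is None:
        p_grid = np.round(np.arange(0.05, 0.951, 0.05), 2)
    if philanthropist_present:
        params = AgentParameters.with_philanthropist(n_agents, gamma_others=1.0)
    else:
        params = AgentParameters.uniform(n_agents, gamma=1.0)

    rows = []
    for p_idx, p in enumerate(p_grid):
        min_sizes = np.empty(replicates)
        agent1_out = np.empty(replicates, dtype=bool)
        others_out_frac = np.empty(replicates)
        counts = {lab: 0 for lab in LABELS}
        for rep in range(replicates):
            final = _run_replicate(
                n_agents, float(p), params, horizon, seed, (p_idx, rep)
            )
            sizes = final.group_sizes()
            min_sizes[rep] = sizes.min()
            agent1_out[rep] = sizes[0] == 1
            others_out_frac[rep] = (sizes[1:] == 1).mean()
            counts[classify_outcome(final).label] += 1
        row = {
            "p_friend": float(p),
            "mean_min_group_size": min_sizes.mean(),
            "outcast_prob_agent1": agent1_out.mean(),
            "outcast_prob_other": others_out_frac.mean(),
        }
        row.update({f"frac_{lab}": counts[lab] / replicates for lab in LABELS})
        row["replicates"] = replicates
        rows.append(row)

    return SweepResult(
        table=pd.DataFrame(rows),
        replicates=replicates,
        seed=seed,
        metadata={
            "n_agents": n_agents,
            "horizon": horizon,
            "philanthropist_present": philanthropist_present,
        },
    )
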