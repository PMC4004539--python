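"""Core state, payoff, and best-response dynamics of the ostracism-formation model.

The model describes ``N`` agents, each holding a binary *feeling vector*
``f_i`` with components in ``{+1, -1}``: ``f_i[j] = +1`` means agent ``i``
is friendly toward agent ``j``.  The full system state is the ``N x N``
feeling matrix (row ``i`` is ``f_i``); the diagonal is fixed at ``+1``.

Agent ``i``'s *ego-group* is itself plus everyone it exchanges mutual ``+1``
attitudes with.  Its *congruity* ``c_i`` is one minus the average distance
between ``f_i`` and the feeling vectors of its group peers, where the
distance is the Euclidean distance between feeling vectors scaled to unit
range: two vectors disagreeing on ``k`` of the ``N`` components are at
distance ``sqrt(k / N)``, so ``d = 0`` for perfectly synchronized vectors
and ``d = 1`` for completely desynchronized ones, and ``c_i = 1`` means the
group is perfectly synchronized.  The payoff each agent maximizes is the
sense of belonging

    S_i = n_i * c_i**gamma_i - lambda_i * m_i

where ``n_i`` is the ego-group size (self included), ``gamma_i >= 0`` tunes
how strongly congruity is rewarded, and the optional penalty term charges
``lambda_i`` per agent that ``i`` dislikes (``m_i`` dislikes in total).

Dynamics are single-flip best responses with inertia: at a revision
opportunity an agent flips the sign of exactly one off-diagonal component
of its vector if and only if some flip is strictly better than staying put;
ties among equally good best flips are broken uniformly at random with a
seeded generator.  Updates can be applied synchronously, sequentially in
index order, or to uniformly drawn agents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "ParameterError",
    "FeelingConfiguration",
    "AgentParameters",
    "UpdateSchedule",
    "Trajectory",
    "init_random",
    "mutual_group",
    "congruity",
    "payoff",
    "best_response",
    "step",
    "run_dynamics",
]

#: Relative tolerance for comparing candidate payoffs.  Payoffs are sums of
#: O(N) square-root terms of magnitude <= 1 evaluated in float64, so exact
#: ties (symmetric candidates) survive this tolerance with orders of
#: magnitude to spare, while genuinely distinct candidates essentially never
#: fall inside it at practical population sizes.
PAYOFF_TIE_TOL = 1e-9


class ParameterError(ValueError):
    """Raised when a simulation parameter is outside its admissible range."""


class ConfigurationError(ValueError):
    """Raised when a feeling matrix violates the model's structural rules."""


def _validate_matrix(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ConfigurationError(
            f"feeling matrix must be square, got shape {matrix.shape}"
        )
    n = matrix.shape[0]
    if n < 2:
        raise ConfigurationError("the model needs at least 2 agents")
    if not np.isin(matrix, (-1, 1)).all():
        bad = np.argwhere(~np.isin(matrix, (-1, 1)))[0]
        raise ConfigurationError(
            f"entry ({bad[0]}, {bad[1]}) is not +1 or -1: {matrix[tuple(bad)]!r}"
        )
    if (np.diagonal(matrix) != 1).any():
        i = int(np.flatnonzero(np.diagonal(matrix) != 1)[0])
        raise ConfigurationError(f"diagonal entry ({i}, {i}) must be +1")
    return matrix.astype(np.int8, copy=True)


@dataclass
class FeelingConfiguration:
    """The N x N matrix of pairwise attitudes; the full system state.

    ``matrix[i, j]`` is agent ``i``'s attitude toward agent ``j`` (+1 friendly,
    -1 hostile).  Diagonal entries are identically +1 and are never touched by
    the dynamics.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = _validate_matrix(self.matrix)

    @property
    def n_agents(self) -> int:
        return self.matrix.shape[0]

    def copy(self) -> "FeelingConfiguration":
        out = object.__new__(FeelingConfiguration)
        out.matrix = self.matrix.copy()
        return out

    def key(self) -> bytes:
        """Byte string identifying the configuration (for cycle detection)."""
        return self.matrix.tobytes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeelingConfiguration):
            return NotImplemented
        return np.array_equal(self.matrix, other.matrix)

    def mutual_adjacency(self) -> np.ndarray:
        """Boolean adjacency of the undirected mutual-friendship graph.

        ``adj[i, j]`` is True iff ``i != j`` and both attitudes are +1.
        """
        m = self.matrix
        adj = (m == 1) & (m.T == 1)
        np.fill_diagonal(adj, False)
        return adj

    def group_sizes(self) -> np.ndarray:
        """Ego-group size ``n_i`` (self included) for every agent."""
        return self.mutual_adjacency().sum(axis=1) + 1


@dataclass
class AgentParameters:
    """Per-agent payoff parameters.

    ``gamma`` is the congruity exponent (gamma = 0 defines a philanthropist,
    whose payoff depends on group size only); ``penalty_lambda`` weights the
    optional per-dislike penalty (0 disables it).
    """

    gamma: np.ndarray
    penalty_lambda: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        self.penalty_lambda = np.atleast_1d(
            np.asarray(self.penalty_lambda, dtype=float)
        )
        if self.gamma.shape != self.penalty_lambda.shape:
            raise ParameterError("gamma and penalty_lambda must have equal length")
        if (self.gamma < 0).any():
            raise ParameterError("gamma must be nonnegative")
        if (self.penalty_lambda < 0).any():
            raise ParameterError("penalty_lambda must be nonnegative")

    @classmethod
    def uniform(
        cls, n_agents: int, gamma: float = 1.0, penalty_lambda: float = 0.0
    ) -> "AgentParameters":
        """All agents share one gamma and one penalty weight."""
        return cls(
            gamma=np.full(n_agents, gamma),
            penalty_lambda=np.full(n_agents, penalty_lambda),
        )

    @classmethod
    def with_philanthropist(
        cls,
        n_agents: int,
        gamma_others: float = 1.0,
        penalty_lambda: float = 0.0,
        philanthropist: int = 0,
    ) -> "AgentParameters":
        """One philanthropist (gamma = 0) among otherwise identical agents."""
        gamma = np.full(n_agents, gamma_others)
        gamma[philanthropist] = 0.0
        return cls(gamma=gamma, penalty_lambda=np.full(n_agents, penalty_lambda))

    def is_philanthropist(self, i: int) -> bool:
        return self.gamma[i] == 0.0


_RULES = ("synchronous", "sequential", "random")


@dataclass
class UpdateSchedule:
    """How revision opportunities are handed out within one time step.

    * ``synchronous`` — every agent best-responds to the same configuration
      and all new vectors are applied at once.
    * ``sequential`` — agents are visited in index order, each response
      applied before the next agent is visited.
    * ``random`` — N sub-steps per time step, each visiting one uniformly
      drawn agent (with replacement), responses applied immediately.

    ``rng_seed`` seeds both tie-breaking and (for ``random``) agent draws.
    """

    rule: str = "synchronous"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.rule not in _RULES:
            raise ParameterError(f"rule must be one of {_RULES}, got {self.rule!r}")

    def step_rng(self, t: int) -> np.random.Generator:
        """Deterministic per-step generator derived from the schedule seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.rng_seed, spawn_key=(t,))
        )


@dataclass
class Trajectory:
    """Time-ordered record of one dynamics run.

    ``configurations[t]`` is the state after ``t`` steps (index 0 is the
    initial state); ``group_sizes[t, i]`` is ``n_i`` at time ``t``.
    ``terminal_status`` is ``"fixed_point"``, ``"cycle"`` or
    ``"horizon_reached"``; ``cycle_length`` is set only for cycles.
    """

    configurations: list
    group_sizes: np.ndarray
    terminal_status: str
    cycle_length: Optional[int] = None

    @property
    def final(self) -> FeelingConfiguration:
        return self.configurations[-1]

    @property
    def n_steps(self) -> int:
        return len(self.configurations) - 1


# ---------------------------------------------------------------------------
# Elementary operations


def init_random(
    n_agents: int, p_friend: float, rng_seed: int
) -> FeelingConfiguration:
    """Draw a random configuration with i.i.d. Bernoulli(p_friend) friendliness.

    Every off-diagonal entry is +1 with probability ``p_friend`` and -1
    otherwise, independently; the diagonal is +1.  The same seed always
    yields the same matrix.
    """
    if not 0.0 <= p_friend <= 1.0:
        raise ParameterError(f"p_friend must be in [0, 1], got {p_friend}")
    if n_agents < 2:
        raise ParameterError(f"n_agents must be >= 2, got {n_agents}")
    rng = np.random.default_rng(rng_seed)
    matrix = np.where(
        rng.random((n_agents, n_agents)) < p_friend, 1, -1
    ).astype(np.int8)
    np.fill_diagonal(matrix, 1)
    return FeelingConfiguration(matrix)


def _check_index(config: FeelingConfiguration, i: int) -> None:
    if not 0 <= i < config.n_agents:
        raise IndexError(f"agent index {i} out of range for N={config.n_agents}")


def mutual_group(config: FeelingConfiguration, i: int) -> frozenset:
    """Ego-group of agent ``i``: itself plus all mutual friends."""
    _check_index(config, i)
    m = config.matrix
    peers = np.flatnonzero((m[i] == 1) & (m[:, i] == 1))
    return frozenset(peers.tolist()) | {i}


def congruity(config: FeelingConfiguration, i: int) -> float:
    """Congruity ``c_i`` in [0, 1]: 1 minus the mean normalized Hamming
    distance between ``f_i`` and the vectors of its group peers.

    The pairwise distance is the scaled Euclidean distance between feeling
    vectors, ``sqrt(k / N)`` for ``k`` disagreeing components, which runs
    from 0 (synchronized) to 1 (fully desynchronized).  An agent with no
    peers (singleton ego-group) has congruity 1 by convention: with no one
    to differ from, it is perfectly in tune with its own group.
    """
    _check_index(config, i)
    m = config.matrix
    n = config.n_agents
    peers = np.flatnonzero((m[i] == 1) & (m[:, i] == 1))
    peers = peers[peers != i]
    if peers.size == 0:
        return 1.0
    dist = np.sqrt((m[peers] != m[i]).sum(axis=1) / n)
    return float(1.0 - dist.mean())


def dislike_count(config: FeelingConfiguration, i: int) -> int:
    """Number of agents that ``i`` dislikes (off-diagonal -1 entries)."""
    _check_index(config, i)
    return int((config.matrix[i] == -1).sum())


def payoff(config: FeelingConfiguration, i: int, params: AgentParameters) -> float:
    """Sense of belonging ``S_i = n_i * c_i**gamma_i - lambda_i * m_i``.

    ``0**0`` evaluates to 1, so a philanthropist in a singleton group with
    zero congruity still scores its group size.
    """
    _check_index(config, i)
    n_i = len(mutual_group(config, i))
    c_i = congruity(config, i)
    m_i = dislike_count(config, i)
    return float(n_i * c_i ** params.gamma[i] - params.penalty_lambda[i] * m_i)


# ---------------------------------------------------------------------------
# Candidate evaluation (vectorized over the N-1 possible single flips)


def _all_candidate_payoffs(matrix: np.ndarray, gamma: np.ndarray, lam: np.ndarray):
    """Payoffs of every agent under every single-component flip and no change.

    Returns ``(flip_payoffs, stay_payoffs)``: ``flip_payoffs[i, j]`` is agent
    ``i``'s payoff after flipping component ``j`` of ``f_i`` with all other
    rows held fixed (``-inf`` on the diagonal: the self-entry is never
    flipped), and ``stay_payoffs[i]`` its payoff under no change.

    The whole evaluation reduces to dense N x N arithmetic.  Flipping
    component ``j`` of ``f_i`` changes the disagreement count with each
    peer ``k`` by exactly +1 (where the rows agree at ``j``) or -1 (where
    they disagree), so the flipped distance is ``up[i, k]`` or ``dn[i, k]``
    and the peer-summed distance decomposes into a j-independent part plus
    ``F[i, j] * ((P * (up - dn) / 2) @ F)[i, j]`` with ``P`` the peer
    indicator matrix — one matrix product for all (i, j) pairs at once.
    """
    n = matrix.shape[0]
    fw = matrix.astype(np.float64)
    peers = (matrix == 1) & (matrix.T == 1)
    np.fill_diagonal(peers, False)
    pw = peers.astype(np.float64)
    # disagreement counts and scaled Euclidean distances between rows
    ham = (n - fw @ fw.T) / 2.0
    dist = np.sqrt(ham / n)
    up = np.sqrt(np.minimum(ham + 1.0, n) / n)  # distance after one more
    dn = np.sqrt(np.maximum(ham - 1.0, 0.0) / n)  # ... one fewer disagreement
    n_peers = pw.sum(axis=1)
    likes = matrix == 1
    dislikes = n - likes.sum(axis=1)  # off-diagonal -1 count

    base_sum = (pw * dist).sum(axis=1)
    sym = pw * (up + dn) / 2.0
    skew = pw * (up - dn) / 2.0
    sum_new = sym.sum(axis=1)[:, None] + fw * (skew @ fw)
    # distance from i to j once component j of f_i has been flipped
    # (component j compares against f_j[j] = +1)
    new_dist_j = np.where(likes, up, dn)

    accepts = matrix.T == 1  # accepts[i, j]: j already holds +1 toward i
    added = accepts & ~likes  # flip j -> +1 creates a new mutual pair
    removed = accepts & likes  # flip j -> -1 severs one (incl. the diagonal)

    sum_new += np.where(added, new_dist_j, 0.0)
    sum_new -= np.where(removed, new_dist_j, 0.0)
    k_new = n_peers[:, None] + added.astype(np.float64) - removed.astype(np.float64)

    c_new = np.where(k_new > 0, 1.0 - sum_new / np.maximum(k_new, 1.0), 1.0)
    np.clip(c_new, 0.0, 1.0, out=c_new)

    m_new = dislikes[:, None] + np.where(likes, 1, -1)
    flip_payoffs = (k_new + 1.0) * c_new ** gamma[:, None] - lam[:, None] * m_new
    np.fill_diagonal(flip_payoffs, -np.inf)

    c0 = np.where(n_peers > 0, 1.0 - base_sum / np.maximum(n_peers, 1.0), 1.0)
    stay_payoffs = (n_peers + 1.0) * c0 ** gamma - lam * dislikes
    return flip_payoffs, stay_payoffs


def _pick_response(flip_payoffs, stay_payoff, rng):
    """Inertial best response: flip only if strictly better than staying.

    Returns the flipped component index, or ``None`` for no change.  When
    several flips tie for the strict maximum, one is drawn uniformly from
    the supplied generator.
    """
    best = float(flip_payoffs.max())
    tol = PAYOFF_TIE_TOL * max(1.0, abs(best))
    if best <= stay_payoff + tol:
        return None
    winners = np.flatnonzero(flip_payoffs >= best - tol)
    if winners.size == 1:
        return int(winners[0])
    return int(winners[rng.integers(winners.size)])


def _pick_all_responses(flips, stays, rng):
    """Vectorized inertial selection for every agent at once.

    Returns an int array with the flipped component per agent, or -1 for no
    change.  Agents with tied best flips consume the generator in index
    order, so the result is reproducible for a given seed.
    """
    best = flips.max(axis=1)
    tol = PAYOFF_TIE_TOL * np.maximum(1.0, np.abs(best))
    moving = best > stays + tol
    win = flips >= (best - tol)[:, None]
    n_win = win.sum(axis=1)
    choice = np.where(moving, win.argmax(axis=1), -1)
    for i in np.flatnonzero(moving & (n_win > 1)):
        w = np.flatnonzero(win[i])
        choice[i] = int(w[rng.integers(w.size)])
    return choice


def best_response(
    config: FeelingConfiguration,
    i: int,
    params: AgentParameters,
    rng: np.random.Generator,
):
    """Best single-flip response of agent ``i``, with inertia.

    Evaluates the payoff of keeping ``f_i`` and of each of the N-1 sign flips
    of its off-diagonal components, with all other rows held fixed, and
    returns ``(new_vector, flipped_index)``.  The agent flips only when some
    flip is strictly better than staying put (``flipped_index`` is None
    otherwise); among exactly tied best flips one is selected uniformly at
    random from ``rng``.
    """
    _check_index(config, i)
    matrix = config.matrix
    flips, stays = _all_candidate_payoffs(
        matrix, params.gamma, params.penalty_lambda
    )
    j = _pick_response(flips[i], float(stays[i]), rng)
    new_row = matrix[i].copy()
    if j is not None:
        new_row[j] = -new_row[j]
    return new_row, j


def step(
    config: FeelingConfiguration,
    params: AgentParameters,
    schedule: UpdateSchedule,
    rng: Optional[np.random.Generator] = None,
) -> FeelingConfiguration:
    """Advance the configuration by one time step under the given schedule.

    The input configuration is never mutated.  When ``rng`` is omitted a
    fresh generator seeded with ``schedule.rng_seed`` is used, so repeated
    calls with the same arguments return identical results.
    """
    if rng is None:
        rng = np.random.default_rng(schedule.rng_seed)
    matrix = config.matrix
    n = matrix.shape[0]

    if schedule.rule == "synchronous":
        flips, stays = _all_candidate_payoffs(
            matrix, params.gamma, params.penalty_lambda
        )
        choices = _pick_all_responses(flips, stays, rng)
        new_matrix = matrix.copy()
        movers = np.flatnonzero(choices >= 0)
        new_matrix[movers, choices[movers]] = -new_matrix[movers, choices[movers]]
    else:
        if schedule.rule == "sequential":
            order = range(n)
        else:  # random: N uniform draws with replacement per step
            order = rng.integers(n, size=n)
        new_matrix = matrix.copy()
        for i in order:
            i = int(i)
            flips, stays = _all_candidate_payoffs(
                new_matrix, params.gamma, params.penalty_lambda
            )
            j = _pick_response(flips[i], float(stays[i]), rng)
            if j is not None:
                new_matrix[i, j] = -new_matrix[i, j]

    out = object.__new__(FeelingConfiguration)
    out.matrix = new_matrix
    return out


def run_dynamics(
    initial: FeelingConfiguration,
    params: AgentParameters,
    schedule: UpdateSchedule,
    horizon: int = 40,
    cycle_window: int = 4,
) -> Trajectory:
    """Iterate the dynamics for up to ``horizon`` steps, recording every state.

    Stops early at a fixed point (the step reproduced its input) or when the
    new configuration repeats one seen within the last ``cycle_window`` steps
    (a cycle; its length is reported).  Group sizes ``n_i(t)`` are recorded
    for every stored configuration.
    """
    if horizon < 1:
        raise ParameterError(f"horizon must be >= 1, got {horizon}")
    configs = [initial.copy()]
    sizes = [initial.group_sizes()]
    recent = {initial.key(): 0}
    status = "horizon_reached"
    cycle_length = None

    current = configs[0]
    for t in range(1, horizon + 1):
        nxt = step(current, params, schedule, rng=schedule.step_rng(t))
        configs.append(nxt)
        sizes.append(nxt.group_sizes())
        if np.array_equal(nxt.matrix, current.matrix):
            status = "fixed_point"
            break
        key = nxt.key()
        if key in recent and t - recent[key] <= cycle_window:
            status = "cycle"
            cycle_length = t - recent[key]
            break
        recent[key] = t
        recent = {k: v for k, v in recent.items() if t - v <= cycle_window}
        current = nxt

    return Trajectory(
        configurations=configs,
        group_sizes=np.vstack(sizes),
        terminal_status=status,
        cycle_length=cycle_length,
    )
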