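"""Shared fixtures and an independent brute-force oracle.

The oracle computes ego-groups, congruity, and payoffs straight from their
definitions with plain Python loops and ``math.sqrt``; it shares no code
path with the package's vectorized implementation.
"""

import itertools
import math

import numpy as np
import pytest

from ostrasim.model import AgentParameters, FeelingConfiguration


def oracle_payoff(matrix, i, gamma, lam):
    """Sense of belonging computed literally from the definitions."""
    n = len(matrix)
    peers = [
        k for k in range(n) if k != i and matrix[i][k] == 1 and matrix[k][i] == 1
    ]
    group_size = len(peers) + 1
    if peers:
        dists = [
            math.sqrt(sum(matrix[i][c] != matrix[k][c] for c in range(n)) / n)
            for k in peers
        ]
        c = 1.0 - sum(dists) / len(dists)
    else:
        c = 1.0
    m = sum(1 for k in range(n) if k != i and matrix[i][k] == -1)
    return group_size * c**gamma - lam * m


def oracle_candidates(matrix, i, gamma, lam):
    """Payoffs of all single flips plus no change, by explicit enumeration."""
    n = len(matrix)
    flips = {}
    for j in range(n):
        if j == i:
            continue
        virtual = [row[:] for row in matrix]
        virtual[i][j] = -virtual[i][j]
        flips[j] = oracle_payoff(virtual, i, gamma, lam)
    return flips, oracle_payoff(matrix, i, gamma, lam)


def oracle_best_flips(matrix, i, gamma, lam, tol=1e-9):
    """Inertial best response set: tied best flips, or empty if staying wins."""
    flips, stay = oracle_candidates(matrix, i, gamma, lam)
    best = max(flips.values())
    cut = tol * max(1.0, abs(best))
    if best <= stay + cut:
        return set()
    return {j for j, v in flips.items() if v >= best - cut}


def all_matrices(n):
    """Every feeling matrix on n agents (2^(n(n-1)) of them)."""
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    for bits in itertools.product((1, -1), repeat=len(off)):
        m = np.ones((n, n), dtype=np.int8)
        for (i, j), b in zip(off, bits):
            m[i, j] = b
        yield m


def random_matrix(n, p, seed):
    rng = np.random.default_rng(seed)
    m = np.where(rng.random((n, n)) < p, 1, -1).astype(np.int8)
    np.fill_diagonal(m, 1)
    return m


@pytest.fixture
def all_friendly_30():
    return FeelingConfiguration(np.ones((30, 30), dtype=np.int8))


@pytest.fixture
def all_hostile_4():
    m = -np.ones((4, 4), dtype=np.int8)
    np.fill_diagonal(m, 1)
    return FeelingConfiguration(m)


@pytest.fixture
def triangle():
    """Three agents: f_1=(+,+,+), f_2=(+,+,-), f_3=(+,-,+)."""
    return FeelingConfiguration(
        np.array([[1, 1, 1], [1, 1, -1], [1, -1, 1]], dtype=np.int8)
    )


@pytest.fixture
def uniform_params():
    def make(n, gamma=1.0, lam=0.0):
        return AgentParameters.uniform(n, gamma=gamma, penalty_lambda=lam)

    return make
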