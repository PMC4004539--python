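"""Derived observables on configurations: clusters, outcasts, outcome labels.

For outcome reporting a *cluster* is a connected component of the undirected
mutual-friendship graph (an edge wherever two agents exchange +1 attitudes).
Ego-groups overlap mid-run and need not be transitive, so components are the
natural global notion of "the groups"; at fixed points they are typically
cliques, and clique-ness is reported rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .model import FeelingConfiguration, _check_index

__all__ = [
    "Cluster",
    "OutcomeClassification",
    "clusters",
    "classify_outcome",
    "min_group_size",
    "is_outcast",
    "ego_group_sizes",
]

LABELS = ("unified", "ostracism", "fragmented")


@dataclass(frozen=True)
class Cluster:
    """One connected component of the mutual-friendship graph."""

    members: frozenset
    is_clique: bool

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OutcomeClassification:
    """Terminal-state label with its supporting structure.

    Labels, applied with this precedence:

    * ``unified`` — every agent's ego-group is the whole population
      (equivalently, a single cluster of size N).
    * ``ostracism`` — at least one outcast (singleton ego-group) while all
      remaining agents form one cluster.
    * ``fragmented`` — everything else (two or more non-trivial clusters,
      possibly alongside singletons).
    """

    label: str
    cluster_sizes: tuple
    outcast_ids: frozenset

    def to_record(self, config: FeelingConfiguration) -> dict:
        """JSON-ready summary (agent ids reported 1-based)."""
        return {
            "label": self.label,
            "cluster_sizes": sorted(self.cluster_sizes, reverse=True),
            "outcast_ids": sorted(i + 1 for i in self.outcast_ids),
            "min_group_size": min_group_size(config),
        }


def ego_group_sizes(config: FeelingConfiguration) -> np.ndarray:
    """Vector of ego-group sizes ``n_i`` (self included)."""
    return config.group_sizes()


def clusters(config: FeelingConfiguration) -> List[Cluster]:
    """Connected components of the mutual graph, with a clique diagnostic.

    Component sizes always sum to N; every agent belongs to exactly one
    component.
    """
    adj = config.mutual_adjacency()
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=False, return_labels=True
    )
    out = []
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        k = members.size
        block = adj[np.ix_(members, members)]
        is_clique = bool(block.sum() == k * (k - 1))
        out.append(Cluster(members=frozenset(members.tolist()), is_clique=is_clique))
    return out


def is_outcast(config: FeelingConfiguration, i: int) -> bool:
    """True iff agent ``i``'s ego-group is a singleton."""
    _check_index(config, i)
    m = config.matrix
    peers = (m[i] == 1) & (m[:, i] == 1)
    peers[i] = False
    return not peers.any()


def min_group_size(config: FeelingConfiguration) -> int:
    """Minimum ego-group size over all agents (1 iff someone is an outcast)."""
    return int(config.group_sizes().min())


def classify_outcome(config: FeelingConfiguration) -> OutcomeClassification:
    """Deterministic outcome label of a configuration (see
    :class:`OutcomeClassification` for the precedence rule)."""
    n = config.n_agents
    sizes = config.group_sizes()
    comps = clusters(config)
    cluster_sizes = tuple(sorted((c.size for c in comps), reverse=True))
    outcasts = frozenset(np.flatnonzero(sizes == 1).tolist())

    if (sizes == n).all():
        label = "unified"
    elif outcasts:
        non_outcast_comps = [c for c in comps if not c.members <= outcasts]
        label = "ostracism" if len(non_outcast_comps) == 1 else "fragmented"
    else:
        label = "fragmented"
    return OutcomeClassification(
        label=label, cluster_sizes=cluster_sizes, outcast_ids=outcasts
    )
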