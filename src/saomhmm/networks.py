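"""Core network and panel containers plus discordance accounting.

Networks are binary digraphs (or symmetric graphs) on a fixed node set,
stored as dense 0/1 adjacency matrices with an all-zero diagonal.  A
:class:`NetworkPanel` is an ordered sequence of such networks observed at
strictly increasing times; its ``role`` records whether the panel is the
observed series or a latent (true-network) series.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DirectedNetwork",
    "NetworkPanel",
    "DiscordanceCounts",
    "discordance_counts",
    "hamming",
    "jaccard",
    "panel_summary",
]


@dataclasses.dataclass(frozen=True)
class DirectedNetwork:
    """A binary network on ``n_nodes`` vertices without self-ties.

    ``directed=False`` stores an undirected graph as a symmetric matrix;
    all pairwise accounting then runs over the upper triangle only.
    """

    adjacency: np.ndarray
    directed: bool = True

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=np.int8)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {adj.shape}")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.diagonal(adj).any():
            raise ValueError("self-ties are not allowed (diagonal must be 0)")
        if not self.directed and not np.array_equal(adj, adj.T):
            raise ValueError("undirected network requires a symmetric adjacency")
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_dyads(self) -> int:
        n = self.n_nodes
        return n * (n - 1) if self.directed else n * (n - 1) // 2

    def edge_count(self) -> int:
        e = int(self.adjacency.sum())
        return e if self.directed else e // 2

    def edge_set(self) -> set[tuple[int, int]]:
        ii, jj = np.nonzero(self.adjacency)
        if self.directed:
            return set(zip(ii.tolist(), jj.tolist()))
        return {(i, j) for i, j in zip(ii.tolist(), jj.tolist()) if i < j}

    def copy(self) -> "DirectedNetwork":
        return DirectedNetwork(self.adjacency.copy(), self.directed)


@dataclasses.dataclass
class NetworkPanel:
    """Ordered networks on a shared node set with observation times."""

    networks: list[DirectedNetwork]
    times: np.ndarray
    role: str = "observed"  # "observed" or "latent"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.networks) != len(self.times):
            raise ValueError("len(times) must equal the number of networks")
        if len(self.networks) < 2:
            raise ValueError("a panel needs at least two waves")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        n0 = self.networks[0].n_nodes
        d0 = self.networks[0].directed
        for net in self.networks[1:]:
            if net.n_nodes != n0 or net.directed != d0:
                raise ValueError("all waves must share node count and directedness")
        if self.role not in ("observed", "latent"):
            raise ValueError(f"unknown panel role {self.role!r}")

    @property
    def n_waves(self) -> int:
        return len(self.networks)

    @property
    def n_nodes(self) -> int:
        return self.networks[0].n_nodes

    @property
    def directed(self) -> bool:
        return self.networks[0].directed

    def durations(self) -> np.ndarray:
        return np.diff(self.times)

    def as_array(self) -> np.ndarray:
        """Stack the waves into an ``(M, n, n)`` int8 array."""
        return np.stack([net.adjacency for net in self.networks])


@dataclasses.dataclass(frozen=True)
class DiscordanceCounts:
    """Cross-tabulation of true vs observed edge status over all dyads:
    ``a`` true edges observed, ``b`` false negatives, ``c`` false
    positives, ``d`` true non-edges observed as non-edges.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _dyad_mask(n: int, directed: bool) -> np.ndarray:
    if directed:
        return ~np.eye(n, dtype=bool)
    return np.triu(np.ones((n, n), dtype=bool), k=1)


def discordance_counts(u: DirectedNetwork, y: DirectedNetwork) -> DiscordanceCounts:
    """Count dyad agreement between a true network ``u`` and an observed
    network ``y`` (upper triangle only for undirected networks)."""
    if u.n_nodes != y.n_nodes or u.directed != y.directed:
        raise ValueError("networks must share shape and directedness")
    mask = _dyad_mask(u.n_nodes, u.directed)
    ut = u.adjacency[mask].astype(bool)
    yt = y.adjacency[mask].astype(bool)
    return DiscordanceCounts(
        a=int((ut & yt).sum()),
        b=int((ut & ~yt).sum()),
        c=int((~ut & yt).sum()),
        d=int((~ut & ~yt).sum()),
    )


def hamming(y1: DirectedNetwork, y2: DirectedNetwork) -> int:
    """Number of dyads whose edge status differs (equals b + c)."""
    dc = discordance_counts(y1, y2)
    return dc.b + dc.c


def jaccard(y1: DirectedNetwork, y2: DirectedNetwork) -> float:
    """Edge-set overlap |E1 ∩ E2| / |E1 ∪ E2|.

    Two empty networks have an undefined coefficient; ``nan`` is returned
    so summaries of sparse panels never abort.
    """
    dc = discordance_counts(y1, y2)
    union = dc.a + dc.b + dc.c
    if union == 0:
        return float("nan")
    return dc.a / union


@dataclasses.dataclass
class PanelSummary:
    waves: pd.DataFrame
    stability: pd.DataFrame


def panel_summary(panel: NetworkPanel) -> PanelSummary:
    """Per-wave degree summaries and inter-wave stability measures.

    Degrees are out-degrees for directed panels.  Stability rows compare
    consecutive waves via the Jaccard coefficient and Hamming distance.
    """
    rows = []
    for m, net in enumerate(panel.networks):
        deg = net.adjacency.sum(axis=1)
        q1, q3 = np.percentile(deg, [25, 75])
        rows.append({
            "wave": m + 1,
            "time": panel.times[m],
            "edges": net.edge_count(),
            "mean_degree": float(deg.mean()),
            "degree_q1": float(q1),
            "degree_q3": float(q3),
        })
    stab = []
    for m in range(panel.n_waves - 1):
        y1, y2 = panel.networks[m], panel.networks[m + 1]
        stab.append({
            "from_wave": m + 1,
            "to_wave": m + 2,
            "jaccard": jaccard(y1, y2),
            "hamming": hamming(y1, y2),
        })
    return PanelSummary(waves=pd.DataFrame(rows), stability=pd.DataFrame(stab))
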