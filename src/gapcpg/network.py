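"""Gap-junction connectivity: random graphs, planar-lattice graphs, currents.

Gap junctions are bidirectional ohmic contacts, so the network is an
undirected graph; each unordered neuron pair is drawn at most once.  Two
generators are provided: uniform random coupling (every pair wired with a
fixed probability) and planar coupling on a square lattice with unit spacing,
where only pairs within a Euclidean radius are candidates — an idealization
of a slice preparation, with hard (non-wrapping) boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GapNetwork", "random_coupling", "planar_coupling", "gap_currents"]

DEFAULT_G_GAP = 0.003  # uS per junction


@dataclass
class GapNetwork:
    """Undirected gap-junction graph with a uniform per-edge conductance.

    ``edges`` is an (E, 2) int array with edges[:, 0] < edges[:, 1]; no
    self-edges.  ``positions`` (N, 2) lattice coordinates are present only
    for planar networks, in which case every edge spans at most the
    generating radius.
    """

    n_neurons: int
    edges: np.ndarray
    g_gap: float = DEFAULT_G_GAP
    positions: np.ndarray | None = None
    seed: int | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size:
            lo, hi = self.edges.min(), self.edges.max()
            if lo < 0 or hi >= self.n_neurons:
                raise ValueError("edge index out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-edges are not allowed")
            self.edges = np.sort(self.edges, axis=1)
        if self.g_gap < 0:
            raise ValueError("g_gap must be non-negative")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_neurons, dtype=np.int64)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def neighbor_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Adjacency in CSR form (indptr, indices) with both directions."""
        src = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        dst = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        order = np.argsort(src, kind="stable")
        src, dst = src[order], dst[order]
        indptr = np.zeros(self.n_neurons + 1, dtype=np.int64)
        np.add.at(indptr, src + 1, 1)
        np.cumsum(indptr, out=indptr)
        return indptr, dst.astype(np.int64)

    def count_edges_between(self, group_a: np.ndarray,
                            group_b: np.ndarray | None = None) -> int:
        """Edges within group_a (group_b None) or between the two index sets."""
        in_a = np.zeros(self.n_neurons, dtype=bool)
        in_a[np.asarray(group_a)] = True
        a0, a1 = in_a[self.edges[:, 0]], in_a[self.edges[:, 1]]
        if group_b is None:
            return int(np.sum(a0 & a1))
        in_b = np.zeros(self.n_neurons, dtype=bool)
        in_b[np.asarray(group_b)] = True
        b0, b1 = in_b[self.edges[:, 0]], in_b[self.edges[:, 1]]
        return int(np.sum((a0 & b1) | (b0 & a1)))

    # -- plain-text round trip: '#'-prefixed JSON header + 2-column edge list
    def to_edgelist(self, path: str | Path) -> None:
        header = {
            "n_neurons": int(self.n_neurons),
            "g_gap": float(self.g_gap),
            "seed": self.seed,
            "radius": self.radius,
            "positions": None if self.positions is None
            else np.asarray(self.positions).tolist(),
        }
        lines = ["# " + json.dumps(header)]
        lines += [f"{i} {j}" for i, j in self.edges]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_edgelist(cls, path: str | Path) -> "GapNetwork":
        text = Path(path).read_text().strip().splitlines()
        if not text or not text[0].startswith("#"):
            raise ValueError("missing header line")
        header = json.loads(text[0].lstrip("# "))
        edges = np.array([[int(a) for a in ln.split()] for ln in text[1:]],
                         dtype=np.int64).reshape(-1, 2)
        pos = header.get("positions")
        return cls(n_neurons=header["n_neurons"], edges=edges,
                   g_gap=header["g_gap"], seed=header.get("seed"),
                   radius=header.get("radius"),
                   positions=None if pos is None else np.asarray(pos, float))


def random_coupling(n_neurons: int, connect_prob: float,
                    seed: int, g_gap: float = DEFAULT_G_GAP) -> GapNetwork:
    """Erdos-Renyi gap-junction graph: each unordered pair wired i.i.d.

    ``connect_prob`` is the per-pair probability (gap junctions are
    bidirectional, so a pair is drawn once, not once per direction).
    """
    if not 0.0 <= connect_prob <= 1.0:
        raise ValueError("connect_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_neurons, k=1)
    mask = rng.random(iu.size) < connect_prob
    edges = np.column_stack([iu[mask], ju[mask]])
    return GapNetwork(n_neurons, edges, g_gap=g_gap, seed=seed)


def lattice_positions(grid_rows: int, grid_cols: int) -> np.ndarray:
    """Unit-spaced square lattice coordinates, row-major neuron order."""
    r, c = np.divmod(np.arange(grid_rows * grid_cols), grid_cols)
    return np.column_stack([r, c]).astype(float)


def planar_coupling(grid_rows: int, grid_cols: int, radius: float,
                    connect_prob: float, seed: int,
                    g_gap: float = DEFAULT_G_GAP) -> GapNetwork:
    """Planar gap-junction graph on a hard-boundary square lattice.

    Candidate pairs are those at Euclidean distance <= radius (non-diagonal
    neighbours at distance 1); each candidate is wired with probability
    ``connect_prob``.
    """
    if not 0.0 <= connect_prob <= 1.0:
        raise ValueError("connect_prob must be in [0, 1]")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    pos = lattice_positions(grid_rows, grid_cols)
    n = pos.shape[0]
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    d2 = np.sum((pos[iu] - pos[ju]) ** 2, axis=1)
    cand = d2 <= radius * radius + 1e-12
    iu, ju = iu[cand], ju[cand]
    mask = rng.random(iu.size) < connect_prob
    edges = np.column_stack([iu[mask], ju[mask]])
    return GapNetwork(n, edges, g_gap=g_gap, positions=pos, seed=seed,
                      radius=radius)


def gap_currents(V: np.ndarray, network: GapNetwork) -> np.ndarray:
    """Total gap current leaving each neuron, I_i = sum_j g_gap (V_i - V_j).

    Antisymmetric per edge, so the vector sums to zero: gap junctions move
    charge between neurons, never create it.
    """
    V = np.asarray(V, dtype=float)
    if V.shape != (network.n_neurons,):
        raise ValueError(
            f"V has shape {V.shape}, expected ({network.n_neurons},)")
    out = np.zeros(network.n_neurons)
    if network.n_edges:
        i, j = network.edges[:, 0], network.edges[:, 1]
        dv = network.g_gap * (V[i] - V[j])
        np.add.at(out, i, dv)
        np.add.at(out, j, -dv)
    return out
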