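"""The four model descriptors and their supporting graph matrices.

The regression model uses four 2D descriptors of the hydrogen-suppressed
molecular graph:

``Rww``
    Reciprocal hyper-detour index.  The detour matrix Δ holds the number of
    edges on the *longest* simple path between each pair of atoms; the
    hyper-detour entry for a pair is ½(Δ² + Δ), and Rww sums the reciprocal
    of that quantity over unordered pairs.  It grows with molecular size and
    cyclicity.

``Mats3e``
    Moran spatial autocorrelation at topological distance (lag) 3, with atoms
    weighted by carbon-scaled Sanderson electronegativity.  Positive values
    mean that atoms three bonds apart tend to deviate from the mean
    electronegativity in the same direction.

``BELe4``
    4th lowest eigenvalue of the Burden connectivity matrix whose diagonal
    carries the carbon-scaled Sanderson electronegativities and whose
    off-diagonal entries encode nominal bond types.

``nCs``
    Count of secondary sp³ carbons (aliphatic C bound to exactly two carbon
    neighbours and no other heavy atom).

Exact vendor conventions for Rww normalisation and the Burden off-diagonal
constants are not published; the choices here follow the open descriptor
literature and are isolated behind :class:`BurdenConstants` and the module
functions so they can be calibrated against any externally supplied
reference descriptor table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .molgraph import BOND_ORDER, MolecularGraph

__all__ = [
    "WeightScheme",
    "SANDERSON",
    "BurdenConstants",
    "DescriptorVector",
    "DESCRIPTOR_NAMES",
    "topological_distance_matrix",
    "detour_matrix",
    "reciprocal_hyper_detour",
    "moran_autocorrelation",
    "burden_matrix",
    "burden_lowest_eigenvalues",
    "count_secondary_sp3_carbons",
    "descriptor_vector",
    "descriptor_table",
]

DESCRIPTOR_NAMES = ("Rww", "Mats3e", "BELe4", "nCs")

#: Sanderson electronegativities (standard literature constants)
SANDERSON = {
    "H": 2.592,
    "C": 2.746,
    "N": 3.194,
    "O": 3.654,
    "F": 4.000,
    "S": 2.957,
    "Cl": 3.475,
    "Br": 3.219,
    "I": 2.778,
    "P": 2.515,
}


@dataclass(frozen=True)
class WeightScheme:
    """Element → atomic weight table, optionally scaled on carbon."""

    name: str = "sanderson_e"
    table: dict = field(default_factory=lambda: dict(SANDERSON))
    carbon_scaled: bool = True

    def weight(self, element: str) -> float:
        try:
            w = self.table[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} has no entry in weight scheme "
                f"{self.name!r}"
            ) from None
        return w / self.table["C"] if self.carbon_scaled else w

    def weights(self, g: MolecularGraph) -> np.ndarray:
        return np.array([self.weight(a.element) for a in g.atoms])


SANDERSON_SCHEME = WeightScheme()


@dataclass(frozen=True)
class BurdenConstants:
    """Off-diagonal constants of the Burden matrix (original Burden scheme)."""

    bond_factor: float = 0.1  # times conventional bond order
    terminal_bonus: float = 0.01  # added when either endpoint has degree 1
    non_bonded: float = 0.001


DEFAULT_BURDEN = BurdenConstants()


@dataclass(frozen=True)
class DescriptorVector:
    """The four model descriptors for one compound."""

    Rww: float
    Mats3e: float
    BELe4: float
    nCs: int

    def as_dict(self) -> dict[str, float]:
        return {
            "Rww": self.Rww,
            "Mats3e": self.Mats3e,
            "BELe4": self.BELe4,
            "nCs": float(self.nCs),
        }

    def as_array(self) -> np.ndarray:
        return np.array([self.Rww, self.Mats3e, self.BELe4, float(self.nCs)])


# ---------------------------------------------------------------------------
# graph matrices
# ---------------------------------------------------------------------------

def topological_distance_matrix(g: MolecularGraph) -> np.ndarray:
    """Shortest-path edge counts between all atom pairs (BFS)."""
    n = g.n_atoms
    D = np.zeros((n, n), dtype=int)
    for i, lengths in nx.all_pairs_shortest_path_length(g.to_networkx()):
        for j, d in lengths.items():
            D[i, j] = d
    return D


def _longest_simple_path(adj: dict[int, list[int]], u: int, v: int) -> int:
    """Edge count of the longest simple u–v path, by DFS enumeration."""
    best = -1
    visited = {u}

    def dfs(x: int, length: int) -> None:
        nonlocal best
        if x == v:
            if length > best:
                best = length
            return
        for y in adj[x]:
            if y not in visited:
                visited.add(y)
                dfs(y, length + 1)
                visited.remove(y)

    dfs(u, 0)
    return best


def _detour_naive(g: MolecularGraph) -> np.ndarray:
    adj = {i: sorted(g.neighbors(i)) for i in range(g.n_atoms)}
    n = g.n_atoms
    D = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = _longest_simple_path(adj, i, j)
    return D


def _detour_blocks(g: MolecularGraph) -> np.ndarray:
    """Detour matrix by block–cut-tree decomposition.

    Any simple path between two vertices passes through the same sequence of
    biconnected components and cut vertices, so the detour distance is the
    sum of within-block longest paths along that sequence.  Longest paths are
    enumerated only inside blocks, which for molecules are individual ring
    systems and single edges.
    """
    G = g.to_networkx()
    n = g.n_atoms
    D = np.zeros((n, n), dtype=int)
    blocks = [frozenset(b) for b in nx.biconnected_components(G)]
    cuts = set(nx.articulation_points(G))

    tree = nx.Graph()
    tree.add_nodes_from(blocks)
    for c in cuts:
        tree.add_node(("cut", c))
        for b in blocks:
            if c in b:
                tree.add_edge(("cut", c), b)

    home_block: dict[int, frozenset] = {}
    for b in blocks:
        for x in b:
            if x not in cuts:
                home_block[x] = b

    block_adj = {
        b: {i: sorted(set(G.neighbors(i)) & b) for i in b} for b in blocks
    }
    cache: dict[tuple, int] = {}

    def within(b: frozenset, x: int, y: int) -> int:
        key = (b, x, y) if x < y else (b, y, x)
        if key not in cache:
            cache[key] = _longest_simple_path(block_adj[b], x, y)
        return cache[key]

    def tree_node(x: int):
        return ("cut", x) if x in cuts else home_block[x]

    for i, j in itertools.combinations(range(n), 2):
        ti, tj = tree_node(i), tree_node(j)
        if ti == tj:
            D[i, j] = D[j, i] = within(ti, i, j)
            continue
        path = nx.shortest_path(tree, ti, tj)
        total = 0
        cur = i
        for k, node in enumerate(path):
            if isinstance(node, frozenset):
                nxt = path[k + 1] if k + 1 < len(path) else None
                exit_v = nxt[1] if nxt is not None else j
                if cur != exit_v:
                    total += within(node, cur, exit_v)
                cur = exit_v
        D[i, j] = D[j, i] = total
    return D


def detour_matrix(
    g: MolecularGraph, method: str = "blocks", max_atoms: int = 64
) -> np.ndarray:
    """Longest-simple-path edge counts between all atom pairs.

    ``method="blocks"`` (default) decomposes over biconnected components;
    ``method="naive"`` enumerates simple paths on the whole graph and serves
    as the brute-force oracle.  Both return identical matrices.  On acyclic
    graphs the detour matrix equals the distance matrix.
    """
    if g.n_atoms > max_atoms:
        raise ValueError(
            f"graph has {g.n_atoms} atoms; detour computation is limited to "
            f"{max_atoms} (raise max_atoms to override)"
        )
    if method == "naive":
        return _detour_naive(g)
    if method == "blocks":
        return _detour_blocks(g)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# the four descriptors
# ---------------------------------------------------------------------------

def reciprocal_hyper_detour(
    g: MolecularGraph, delta: np.ndarray | None = None
) -> float:
    """Rww = Σ_{i<j} 1 / (½·(Δij² + Δij)) over unordered atom pairs.

    A single-atom graph has no pairs and returns 0.
    """
    if g.n_atoms < 2:
        return 0.0
    if delta is None:
        delta = detour_matrix(g)
    iu = np.triu_indices(g.n_atoms, k=1)
    d = delta[iu].astype(float)
    return float(np.sum(1.0 / (0.5 * (d * d + d))))


def moran_autocorrelation(
    g: MolecularGraph,
    scheme: WeightScheme = SANDERSON_SCHEME,
    lag: int = 3,
    dist: np.ndarray | None = None,
) -> float:
    """Moran spatial autocorrelation of atomic weights at a topological lag.

    I(k) = [ (1/P_k) Σ_{d_ij=k} (w_i − w̄)(w_j − w̄) ] / [ (1/A) Σ (w_i − w̄)² ]

    with P_k the number of unordered pairs at distance k and A the atom
    count.  Returns 0 when no pair sits at the lag or when the weights are
    constant (zero variance), by convention.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    w = scheme.weights(g)
    dev = w - w.mean()
    denom = float(np.mean(dev**2))
    if denom == 0.0:
        return 0.0
    if dist is None:
        dist = topological_distance_matrix(g)
    iu = np.triu_indices(g.n_atoms, k=1)
    at_lag = dist[iu] == lag
    p_k = int(at_lag.sum())
    if p_k == 0:
        return 0.0
    num = float(np.sum(dev[iu[0]][at_lag] * dev[iu[1]][at_lag])) / p_k
    return num / denom


def burden_matrix(
    g: MolecularGraph,
    scheme: WeightScheme = SANDERSON_SCHEME,
    constants: BurdenConstants = DEFAULT_BURDEN,
) -> np.ndarray:
    """Burden connectivity matrix with weighted diagonal.

    Diagonal: carbon-scaled atomic weight.  Bonded pairs: 0.1 × conventional
    bond order (aromatic 1.5 → 0.15), plus 0.01 if either endpoint is
    terminal.  Non-bonded pairs: 0.001.  Symmetric by construction.
    """
    n = g.n_atoms
    B = np.full((n, n), constants.non_bonded)
    np.fill_diagonal(B, scheme.weights(g))
    for b in g.bonds:
        v = constants.bond_factor * BOND_ORDER[b.order]
        if g.degree(b.i) == 1 or g.degree(b.j) == 1:
            v += constants.terminal_bonus
        B[b.i, b.j] = B[b.j, b.i] = v
    return B


def burden_lowest_eigenvalues(
    g: MolecularGraph,
    scheme: WeightScheme = SANDERSON_SCHEME,
    k: int = 4,
    constants: BurdenConstants = DEFAULT_BURDEN,
) -> np.ndarray:
    """The k smallest eigenvalues of the Burden matrix, ascending.

    BELe4 is element 4 (index 3) for k=4.  Raises for graphs with fewer than
    k atoms, for which the eigenvalue is undefined.
    """
    if g.n_atoms < k:
        raise ValueError(f"BELe{k} undefined for {g.n_atoms} atoms")
    eig = np.linalg.eigvalsh(burden_matrix(g, scheme, constants))
    return np.sort(eig)[:k]


def count_secondary_sp3_carbons(g: MolecularGraph) -> int:
    """nCs: aliphatic sp³ carbons bound to exactly two carbons.

    A carbon counts when it is non-aromatic, all of its bonds are single,
    and its heavy neighbours are exactly two carbon atoms (any number of
    implicit hydrogens).
    """
    count = 0
    for a in g.atoms:
        if a.element != "C" or a.is_aromatic:
            continue
        nbrs = list(g.neighbors(a.index))
        if len(nbrs) != 2:
            continue
        if any(g.bond_order(a.index, j) != "single" for j in nbrs):
            continue
        if all(g.atoms[j].element == "C" for j in nbrs):
            count += 1
    return count


def descriptor_vector(
    g: MolecularGraph,
    scheme: WeightScheme = SANDERSON_SCHEME,
    constants: BurdenConstants = DEFAULT_BURDEN,
    max_atoms: int = 64,
) -> DescriptorVector:
    """Assemble (Rww, Mats3e, BELe4, nCs) for one molecular graph."""
    if g.n_atoms < 4:
        raise ValueError("descriptor vector requires at least 4 atoms")
    delta = detour_matrix(g, max_atoms=max_atoms)
    dist = topological_distance_matrix(g)
    return DescriptorVector(
        Rww=reciprocal_hyper_detour(g, delta),
        Mats3e=moran_autocorrelation(g, scheme, lag=3, dist=dist),
        BELe4=float(burden_lowest_eigenvalues(g, scheme, 4, constants)[3]),
        nCs=count_secondary_sp3_carbons(g),
    )


def descriptor_table(compound_set, **kwargs):
    """Per-compound descriptor DataFrame for a CompoundSet (indexed by id)."""
    import pandas as pd

    rows = {
        r.id: descriptor_vector(r.graph(), **kwargs).as_dict()
        for r in compound_set
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df[list(DESCRIPTOR_NAMES)]
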