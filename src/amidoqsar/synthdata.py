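"""Seeded generators for every statistical structure the analysis assumes.

Three generators make the full pipeline testable without any external data:

* linear descriptor/response datasets with a planted regression
  y = b0 + Xβ + N(0, σ²), mirroring the study geometry (29 training rows,
  4 informative descriptors) when asked;
* random valence-legal molecular graphs (trees with optional ring closures)
  for exercising the graph-descriptor code, including the detour = distance
  identity on acyclic graphs;
* logistic dose–response curves with replicate noise for the IC50 fitter.

All generators are bit-reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import DoseResponse
from .molgraph import Atom, Bond, MolecularGraph
from .qsar import QsarDataset

__all__ = [
    "LinearSimSpec",
    "GraphSimSpec",
    "DoseSimSpec",
    "gen_linear_dataset",
    "gen_random_graphs",
    "gen_dose_response",
    "MAX_VALENCE",
    "validate_valences",
]

MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1}


@dataclass(frozen=True)
class LinearSimSpec:
    """Planted linear model: y = beta[0] + X[:, informative] @ beta[1:] + ε."""

    n: int = 29
    p: int = 4
    beta: tuple = (-3.90, 0.06, 1.25, 3.81, -0.94)
    sigma: float = 0.1
    informative: tuple | None = None  # defaults to the first len(beta)-1 cols
    seed: int = 0

    def __post_init__(self) -> None:
        m = len(self.beta) - 1
        if self.p < m:
            raise ValueError("p smaller than number of informative columns")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.informative is not None and len(self.informative) != m:
            raise ValueError("informative indices must match beta length - 1")


def gen_linear_dataset(spec: LinearSimSpec) -> QsarDataset:
    """Standard-normal descriptor columns with a planted linear response.

    Columns beyond the informative set are pure distractors (β = 0).
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n, spec.p))
    m = len(spec.beta) - 1
    idx = list(spec.informative) if spec.informative is not None else list(range(m))
    y = spec.beta[0] + X[:, idx] @ np.asarray(spec.beta[1:], dtype=float)
    if spec.sigma > 0:
        y = y + rng.normal(0.0, spec.sigma, size=spec.n)
    ids = [f"s{i+1}" for i in range(spec.n)]
    cols = [f"x{j}" for j in range(spec.p)]
    return QsarDataset(
        ids=ids,
        X=pd.DataFrame(X, index=ids, columns=cols),
        y=pd.Series(y, index=ids, name="y"),
    )


@dataclass(frozen=True)
class GraphSimSpec:
    """Random valence-legal molecular graphs (trees plus optional rings)."""

    n_graphs: int = 10
    min_atoms: int = 4
    max_atoms: int = 12
    ring_prob: float = 0.3  # chance of closing one extra ring edge
    elements: tuple = ("C", "C", "C", "C", "N", "O", "S", "F", "Cl")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ring_prob <= 1:
            raise ValueError("ring_prob must be in [0, 1]")
        if self.min_atoms < 1 or self.max_atoms < self.min_atoms:
            raise ValueError("invalid atom-count range")


def validate_valences(g: MolecularGraph) -> bool:
    """True when every atom's heavy-atom degree respects its max valence."""
    return all(g.degree(a.index) <= MAX_VALENCE[a.element] for a in g.atoms)


def _random_graph(rng: np.random.Generator, spec: GraphSimSpec) -> MolecularGraph:
    n = int(rng.integers(spec.min_atoms, spec.max_atoms + 1))
    elements = []
    # the root must accept at least one neighbour when n > 1
    pool = list(spec.elements)
    root_pool = [e for e in pool if MAX_VALENCE[e] >= 2] if n > 1 else pool
    elements.append(root_pool[int(rng.integers(len(root_pool)))])
    degrees = [0]
    bonds: list[Bond] = []
    for i in range(1, n):
        open_slots = [
            j for j in range(i) if degrees[j] < MAX_VALENCE[elements[j]]
        ]
        j = int(rng.choice(open_slots))
        # if attaching consumes the last free slot and more atoms follow,
        # the new atom itself must be able to carry the growth
        free_after = sum(
            MAX_VALENCE[elements[q]] - degrees[q] for q in range(i)
        ) - 1
        if i < n - 1 and free_after == 0:
            el_pool = [e for e in pool if MAX_VALENCE[e] >= 2]
        else:
            el_pool = pool
        el = el_pool[int(rng.integers(len(el_pool)))]
        elements.append(el)
        bonds.append(Bond(j, i, "single"))
        degrees[j] += 1
        degrees.append(1)
    if n >= 3 and rng.random() < spec.ring_prob:
        free = [i for i in range(n) if degrees[i] < MAX_VALENCE[elements[i]]]
        adjacent = {(b.i, b.j) for b in bonds} | {(b.j, b.i) for b in bonds}
        candidates = [
            (i, j)
            for k, i in enumerate(free)
            for j in free[k + 1:]
            if (i, j) not in adjacent
        ]
        if candidates:
            i, j = candidates[int(rng.integers(len(candidates)))]
            bonds.append(Bond(i, j, "single"))
            degrees[i] += 1
            degrees[j] += 1
    atoms = [
        Atom(
            index=i,
            element=elements[i],
            is_aromatic=False,
            implicit_h=MAX_VALENCE[elements[i]] - degrees[i],
        )
        for i in range(n)
    ]
    return MolecularGraph(atoms=atoms, bonds=bonds)


def gen_random_graphs(spec: GraphSimSpec) -> list[MolecularGraph]:
    """Generate ``spec.n_graphs`` random connected valence-legal graphs."""
    rng = np.random.default_rng(spec.seed)
    return [_random_graph(rng, spec) for _ in range(spec.n_graphs)]


@dataclass(frozen=True)
class DoseSimSpec:
    """Logistic dose–response: % inh = 100 / (1 + (IC50/c)^h) + noise."""

    ic50: float = 10.0
    hill: float = 1.0
    concentrations: tuple = (0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0)
    noise_sd: float = 0.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")


def gen_dose_response(
    spec: DoseSimSpec, aggregate: str = "mean"
) -> DoseResponse:
    """Simulate replicate dose–response points and return replicate means.

    With ``aggregate="none"`` the individual replicate points are returned
    (concentration list repeated per replicate).
    """
    rng = np.random.default_rng(spec.seed)
    c = np.asarray(spec.concentrations, dtype=float)
    truth = 100.0 / (1.0 + (spec.ic50 / c) ** spec.hill)
    reps = np.tile(truth, (spec.replicates, 1))
    if spec.noise_sd > 0:
        reps = reps + rng.normal(0.0, spec.noise_sd, size=reps.shape)
    if aggregate == "mean":
        return DoseResponse(
            concentrations=tuple(c),
            pct_inh=tuple(reps.mean(axis=0)),
            replicates=spec.replicates,
        )
    if aggregate == "none":
        return DoseResponse(
            concentrations=tuple(np.tile(c, spec.replicates)),
            pct_inh=tuple(reps.ravel()),
            replicates=spec.replicates,
        )
    raise ValueError(f"unknown aggregate {aggregate!r}")
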