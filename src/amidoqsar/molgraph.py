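"""Hydrogen-suppressed labelled molecular graphs.

All descriptors in this package are 2D/topological and derive from a single
connected, hydrogen-suppressed graph whose vertices carry an element symbol,
an aromaticity flag and an implicit-hydrogen count, and whose edges carry a
conventional bond order.  SMILES parsing and aromaticity perception are
delegated to RDKit; the rest of the package works on the plain
:class:`MolecularGraph` container so that descriptor code stays independent
of any particular chemistry toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "SmilesParseError",
    "parse_smiles",
    "canonical_smiles",
    "BOND_ORDER",
]

#: conventional bond orders used throughout (aromatic treated as 1.5)
BOND_ORDER = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be turned into a usable graph."""


@dataclass(frozen=True)
class Atom:
    """A heavy atom: 0-based index, element symbol, aromaticity, implicit H."""

    index: int
    element: str
    is_aromatic: bool = False
    implicit_h: int = 0

    def __post_init__(self) -> None:
        if self.implicit_h < 0:
            raise ValueError(f"atom {self.index}: implicit_h must be >= 0")


@dataclass(frozen=True)
class Bond:
    """An edge between heavy atoms i < j with a named bond order."""

    i: int
    j: int
    order: str = "single"

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError(f"self-bond on atom {self.i}")
        if self.order not in BOND_ORDER:
            raise ValueError(f"unknown bond order {self.order!r}")


@dataclass
class MolecularGraph:
    """Connected hydrogen-suppressed molecular graph.

    Invariants enforced at construction: at least one atom, no duplicate
    bonds, bond endpoints in range, and connectivity (for >1 atom).
    """

    atoms: list[Atom]
    bonds: list[Bond]
    _nx: nx.Graph = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("molecular graph needs at least one atom")
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) references missing atom")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((b.i, b.j, {"order": b.order}) for b in self.bonds)
        if n > 1 and not nx.is_connected(g):
            raise ValueError("molecular graph must be connected")
        object.__setattr__(self, "_nx", g)

    # -- container conveniences -------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> Iterator[int]:
        return iter(self._nx.neighbors(i))

    def degree(self, i: int) -> int:
        return self._nx.degree(i)

    def bond_order(self, i: int, j: int) -> str:
        return self._nx.edges[i, j]["order"]

    def to_networkx(self) -> nx.Graph:
        """View of the topology as a networkx graph (do not mutate)."""
        return self._nx

    # -- RDKit bridges ----------------------------------------------------
    @classmethod
    def from_rdkit(cls, mol) -> "MolecularGraph":
        from rdkit import Chem

        order_name = {
            Chem.BondType.SINGLE: "single",
            Chem.BondType.DOUBLE: "double",
            Chem.BondType.TRIPLE: "triple",
            Chem.BondType.AROMATIC: "aromatic",
        }
        atoms = [
            Atom(
                index=a.GetIdx(),
                element=a.GetSymbol(),
                is_aromatic=a.GetIsAromatic(),
                implicit_h=a.GetTotalNumHs(),
            )
            for a in mol.GetAtoms()
        ]
        bonds = []
        for b in mol.GetBonds():
            bt = b.GetBondType()
            if bt not in order_name:
                raise SmilesParseError(f"unsupported bond type {bt}")
            bonds.append(
                Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order_name[bt])
            )
        return cls(atoms=atoms, bonds=bonds)

    def to_rdkit(self):
        from rdkit import Chem

        order_type = {
            "single": Chem.BondType.SINGLE,
            "double": Chem.BondType.DOUBLE,
            "triple": Chem.BondType.TRIPLE,
            "aromatic": Chem.BondType.AROMATIC,
        }
        rw = Chem.RWMol()
        for a in self.atoms:
            at = Chem.Atom(a.element)
            at.SetIsAromatic(a.is_aromatic)
            # pin hydrogen counts so aromatic systems re-kekulize correctly
            at.SetNumExplicitHs(a.implicit_h)
            at.SetNoImplicit(True)
            rw.AddAtom(at)
        for b in self.bonds:
            rw.AddBond(b.i, b.j, order_type[b.order])
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a connected hydrogen-suppressed graph.

    Aromaticity perception is applied.  Disconnected inputs (e.g. salts with
    a counter-ion) are rejected: encode structures as neutral free bases.
    """
    from rdkit import Chem

    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(
            f"could not parse SMILES {smiles!r}; check ring closures and "
            "atom symbols"
        )
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise SmilesParseError(
            f"SMILES {smiles!r} encodes {len(frags)} disconnected fragments; "
            "use the free-base convention (drop counter-ions)"
        )
    return MolecularGraph.from_rdkit(mol)


def canonical_smiles(g: MolecularGraph) -> str:
    """Canonical SMILES of the graph (round-trips through RDKit)."""
    from rdkit import Chem

    return Chem.MolToSmiles(g.to_rdkit())
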