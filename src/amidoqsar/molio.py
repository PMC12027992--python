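"""Compound-table I/O and the packaged 36-compound study set.

The study set comprises 36 amidino-substituted 2-aryl benzimidazoles assayed
against human dipeptidyl peptidase III at 30 µM: 12 unsubstituted-amidine
derivatives (group ``a``), 13 2-imidazolinyl derivatives (group ``b``) and
11 1,4,5,6-tetrahydropyrimidin-2-yl derivatives (group ``c``).  Structures
are encoded as neutral free bases, drawn as the 5-substituted regioisomer
with the benzimidazole NH on N1 and amidine-type groups in the neutral
amidine tautomer — one documented convention applied uniformly, because the
topological descriptors differ between the 5- and 6-substituted drawings.

Activity provenance: the source publication quotes roughly two thirds of
the % inhibition values verbatim; the remainder are reconstructed here from
its qualitative statements (inhibition-band membership, "complete"/"nearly
complete" inhibition, reported IC50 values).  The ``pct_provenance`` column
distinguishes ``reported`` from ``reconstructed`` rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .molgraph import MolecularGraph, parse_smiles

__all__ = [
    "CompoundRecord",
    "CompoundSet",
    "ASSAY_CONSTANTS",
    "load_compound_table",
    "packaged_dataset",
    "write_descriptor_table",
    "read_descriptor_table",
    "read_smiles_file",
    "read_sdf",
]

#: documentation-only assay constants of the inhibition screen
ASSAY_CONSTANTS = {
    "enzyme_nM": 0.75,
    "substrate_uM": 40.0,
    "inhibitor_uM": 30.0,
    "substrate": "Arg-Arg-2-naphthylamide",
}

REQUIRED_COLUMNS = ("id", "name", "smiles", "group", "pct_inh_30uM", "ic50_uM")


@dataclass(frozen=True)
class CompoundRecord:
    """One assayed compound: identity, structure and activity."""

    id: str
    name: str
    smiles: str
    group: str
    pct_inh_30uM: float
    ic50_uM: float | None = None
    ic50_se_uM: float | None = None
    pct_provenance: str = "reported"

    def __post_init__(self) -> None:
        if self.group not in {"a", "b", "c"}:
            raise ValueError(f"{self.id}: unknown group {self.group!r}")
        if not self.id.startswith(self.group):
            raise ValueError(
                f"record {self.id!r}: id prefix does not match group "
                f"{self.group!r}"
            )
        if not 0.0 <= self.pct_inh_30uM <= 100.0:
            raise ValueError(
                f"{self.id}: pct_inh_30uM {self.pct_inh_30uM} outside [0, 100]"
            )
        if self.ic50_uM is not None and self.ic50_uM <= 0:
            raise ValueError(f"{self.id}: IC50 must be positive")

    def graph(self) -> MolecularGraph:
        return parse_smiles(self.smiles)


@dataclass
class CompoundSet:
    """Ordered collection of compound records with unique ids."""

    records: list[CompoundRecord]
    metadata: dict = field(default_factory=lambda: dict(ASSAY_CONSTANTS))

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate compound ids: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, cid: str) -> CompoundRecord:
        for r in self.records:
            if r.id == cid:
                return r
        raise KeyError(cid)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def group(self, label: str) -> list[CompoundRecord]:
        members = [r for r in self.records if r.group == label]
        if not members:
            raise KeyError(f"no compounds in group {label!r}")
        return members

    def subset(self, ids: Iterable[str]) -> "CompoundSet":
        wanted = list(ids)
        return CompoundSet(
            records=[self[i] for i in wanted], metadata=dict(self.metadata)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "name": [r.name for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "group": [r.group for r in self.records],
                "pct_inh_30uM": [r.pct_inh_30uM for r in self.records],
                "ic50_uM": [r.ic50_uM for r in self.records],
                "ic50_se_uM": [r.ic50_se_uM for r in self.records],
                "pct_provenance": [r.pct_provenance for r in self.records],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _float_or_none(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def load_compound_table(path: str | Path) -> CompoundSet:
    """Read a compound CSV (columns id,name,smiles,group,pct_inh_30uM,ic50_uM).

    Rows are preserved in file order.  Raises ``ValueError`` listing the
    offending rows for missing columns, non-numeric activities or duplicate
    ids, and for empty files.
    """
    df = pd.read_csv(path, dtype={"id": str, "group": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if df.empty:
        raise ValueError("no records in compound table")
    dup_rows = df.index[df["id"].duplicated(keep=False)].tolist()
    if dup_rows:
        ids = sorted(set(df.loc[dup_rows, "id"]))
        raise ValueError(f"duplicate ids {ids} at rows {dup_rows}")
    bad = df.index[pd.to_numeric(df["pct_inh_30uM"], errors="coerce").isna()]
    if len(bad):
        raise ValueError(f"non-numeric pct_inh_30uM at rows {bad.tolist()}")
    records = []
    for _, row in df.iterrows():
        records.append(
            CompoundRecord(
                id=row["id"],
                name=row["name"],
                smiles=row["smiles"],
                group=row["group"],
                pct_inh_30uM=float(row["pct_inh_30uM"]),
                ic50_uM=_float_or_none(row.get("ic50_uM")),
                ic50_se_uM=_float_or_none(row.get("ic50_se_uM")),
                pct_provenance=str(row.get("pct_provenance", "reported")),
            )
        )
    return CompoundSet(records=records)


def packaged_dataset() -> CompoundSet:
    """The packaged 36-compound study set (12 a / 13 b / 11 c)."""
    with resources.as_file(
        resources.files("amidoqsar").joinpath("data/compounds.csv")
    ) as p:
        cs = load_compound_table(p)
    counts = {g: len(cs.group(g)) for g in "abc"}
    assert counts == {"a": 12, "b": 13, "c": 11}, counts
    return cs


def write_descriptor_table(
    compound_set: CompoundSet, descriptors, path: str | Path
) -> None:
    """Write a per-compound descriptor CSV.

    ``descriptors`` maps compound id to a
    :class:`~amidoqsar.descriptors.DescriptorVector` (or is a list aligned
    with the record order).  Columns: id, Rww, Mats3e, BELe4, nCs,
    log_pct_inh; floats at 12 significant digits so the file round-trips.
    """
    if not isinstance(descriptors, dict):
        if len(descriptors) != len(compound_set):
            raise ValueError(
                f"{len(descriptors)} descriptor vectors for "
                f"{len(compound_set)} records"
            )
        descriptors = dict(zip(compound_set.ids, descriptors))
    missing = [r.id for r in compound_set if r.id not in descriptors]
    if missing:
        raise ValueError(f"no descriptor vector for ids {missing}")
    rows = []
    for r in compound_set:
        d = descriptors[r.id]
        rows.append(
            {
                "id": r.id,
                "Rww": d.Rww,
                "Mats3e": d.Mats3e,
                "BELe4": d.BELe4,
                "nCs": d.nCs,
                "log_pct_inh": math.log10(r.pct_inh_30uM)
                if r.pct_inh_30uM > 0
                else float("nan"),
            }
        )
    df = pd.DataFrame(
        rows, columns=["id", "Rww", "Mats3e", "BELe4", "nCs", "log_pct_inh"]
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    """Read a descriptor CSV back into a DataFrame indexed by compound id."""
    df = pd.read_csv(path, dtype={"id": str})
    return df.set_index("id")


def read_smiles_file(path: str | Path) -> dict[str, MolecularGraph]:
    """Read a one-per-line ``.smi`` file (``SMILES [name]``)."""
    out: dict[str, MolecularGraph] = {}
    for k, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        name = parts[1].strip() if len(parts) > 1 else f"mol{k + 1}"
        out[name] = parse_smiles(parts[0])
    return out


def read_sdf(path: str | Path) -> dict[str, MolecularGraph]:
    """Read a V2000 SDF (read-only convenience; uses RDKit)."""
    from rdkit import Chem

    out: dict[str, MolecularGraph] = {}
    for k, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{k + 1}"
        out[name or f"mol{k + 1}"] = MolecularGraph.from_rdkit(mol)
    return out
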