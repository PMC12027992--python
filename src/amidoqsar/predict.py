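"""Apply a fitted model to new structures and propose improved analogues.

The published regression for log10(% inhibition of human DPP III at 30 µM)
is

    log % inh. = −3.90 + 0.06·Rww + 1.25·Mats3e + 3.81·BELe4 − 0.94·nCs

(descriptors in order of standardized importance).  This module exposes that
equation as a fixture model, predicts new compounds from their recomputed
descriptors, and enumerates hydroxyl/amino analogues on the benzimidazole
carbocycle (positions 4–7) of a parent compound — the design rule being that
electronegative substituents at topological distances 3–4 raise Rww and
Mats3e while leaving nCs unchanged.

Every prediction carries a leverage and an in-domain flag whenever the model
holds a training descriptor matrix; out-of-domain predictions are labelled,
never suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import DESCRIPTOR_NAMES, DescriptorVector, descriptor_vector
from .molgraph import MolecularGraph, parse_smiles
from .qsar import MlrModel, _design

__all__ = [
    "PUBLISHED_COEFFICIENTS",
    "Prediction",
    "AnalogueProposal",
    "published_model",
    "predict_log_inhibition",
    "predict_smiles",
    "screen_analogues",
    "benzimidazole_free_sites",
]

PUBLISHED_INTERCEPT = -3.90
PUBLISHED_COEFFICIENTS = {
    "Rww": 0.06,
    "Mats3e": 1.25,
    "BELe4": 3.81,
    "nCs": -0.94,
}


def published_model(training_X: pd.DataFrame | None = None) -> MlrModel:
    """The published four-descriptor equation as a fixture model.

    Optionally attach a training descriptor matrix (e.g. the packaged
    training compounds) so that leverages and domain flags can be computed.
    """
    return MlrModel(
        intercept=PUBLISHED_INTERCEPT,
        coefficients=dict(PUBLISHED_COEFFICIENTS),
        training_ids=list(training_X.index) if training_X is not None else [],
        training_X=training_X,
    )


@dataclass(frozen=True)
class Prediction:
    """Model output for one compound."""

    compound_id: str
    descriptors: DescriptorVector
    log_pct_inh: float
    pct_inh: float
    leverage: float | None = None
    in_domain: bool | None = None


def _leverage(model: MlrModel, x: np.ndarray) -> tuple[float, bool]:
    names = model.descriptor_names
    Xtr = model.training_X[names].to_numpy(dtype=float)
    A = _design(Xtr)
    xtx_inv = np.linalg.inv(A.T @ A)
    row = np.concatenate([[1.0], x])
    h = float(row @ xtx_inv @ row)
    h_star = 3.0 * model.p_prime / len(Xtr)
    return h, h <= h_star


def predict_log_inhibition(
    model: MlrModel, dv: DescriptorVector, compound_id: str = ""
) -> Prediction:
    """Predicted log10(% inh) (and 10^value on the percent scale)."""
    d = dv.as_dict()
    missing = [c for c in model.coefficients if c not in d]
    if missing:
        raise KeyError(f"descriptor(s) {missing} absent from vector")
    x = np.array([d[c] for c in model.descriptor_names])
    val = float(model.intercept + x @ np.array(
        [model.coefficients[c] for c in model.descriptor_names]
    ))
    lev = dom = None
    if model.training_X is not None:
        lev, dom = _leverage(model, x)
    return Prediction(
        compound_id=compound_id,
        descriptors=dv,
        log_pct_inh=val,
        pct_inh=float(10.0**val),
        leverage=lev,
        in_domain=dom,
    )


def predict_smiles(model: MlrModel, smiles: str, compound_id: str = "") -> Prediction:
    """Parse, compute the four descriptors, and predict."""
    return predict_log_inhibition(
        model, descriptor_vector(parse_smiles(smiles)), compound_id
    )


# ---------------------------------------------------------------------------
# analogue enumeration on the benzimidazole carbocycle
# ---------------------------------------------------------------------------

# benzimidazole with the protonated ring nitrogen as N1:
# indices 0..8 = N1, C2, N3, C3a, C4, C5, C6, C7, C7a
_BENZIMIDAZOLE_SMARTS = "[nH]1cnc2ccccc12"
_SITE_INDEX = {4: 4, 5: 5, 6: 6, 7: 7}

_SUBSTITUENT_ATOM = {"OH": "O", "NH2": "N"}


def benzimidazole_free_sites(smiles: str) -> dict[int, int]:
    """Map carbocyclic ring position (4–7) → atom index for free positions.

    A position is free when its carbon still bears a hydrogen.  When the
    molecule contains several benzimidazole moieties the one whose C2 is
    substituted (the scaffold core of this series) is used.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse {smiles!r}")
    patt = Chem.MolFromSmarts(_BENZIMIDAZOLE_SMARTS)
    matches = mol.GetSubstructMatches(patt)
    if not matches:
        return {}
    # prefer a core whose C2 carries the aryl substituent
    matches = sorted(
        matches, key=lambda m: -mol.GetAtomWithIdx(m[1]).GetDegree()
    )
    match = matches[0]
    sites = {}
    for pos, k in _SITE_INDEX.items():
        atom = mol.GetAtomWithIdx(match[k])
        if atom.GetTotalNumHs() > 0:
            sites[pos] = match[k]
    return sites


@dataclass(frozen=True)
class AnalogueProposal:
    """A single-substituent analogue of a parent compound."""

    parent_id: str
    substituent: str  # "OH" or "NH2"
    site: int  # benzimidazole ring position 4-7
    smiles: str
    prediction: Prediction


def _add_substituent(smiles: str, atom_idx: int, substituent: str) -> str:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    rw = Chem.RWMol(mol)
    new = rw.AddAtom(Chem.Atom(_SUBSTITUENT_ATOM[substituent]))
    rw.AddBond(atom_idx, new, Chem.BondType.SINGLE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def screen_analogues(
    parent,
    model: MlrModel | None = None,
    substituents: tuple[str, ...] = ("OH", "NH2"),
    sites: tuple[int, ...] = (4, 5, 6, 7),
) -> list[AnalogueProposal]:
    """Enumerate single OH/NH2 additions on the benzimidazole carbocycle.

    ``parent`` is a CompoundRecord or a (id, smiles) pair.  One proposal is
    generated per free (substituent, site) combination; descriptors are
    recomputed for each analogue and proposals are returned ranked by
    predicted log(% inh), best first.  Parents with no free site yield an
    empty list.
    """
    if model is None:
        model = published_model()
    if hasattr(parent, "smiles"):
        pid, smiles = parent.id, parent.smiles
    else:
        pid, smiles = parent
    for s in substituents:
        if s not in _SUBSTITUENT_ATOM:
            raise ValueError(f"unsupported substituent {s!r}")
    free = benzimidazole_free_sites(smiles)
    proposals = []
    for site in sites:
        if site not in free:
            continue
        for sub in substituents:
            new_smiles = _add_substituent(smiles, free[site], sub)
            dv = descriptor_vector(parse_smiles(new_smiles))
            pred = predict_log_inhibition(model, dv, f"{pid}+{sub}@{site}")
            proposals.append(
                AnalogueProposal(
                    parent_id=pid,
                    substituent=sub,
                    site=site,
                    smiles=new_smiles,
                    prediction=pred,
                )
            )
    proposals.sort(key=lambda p: -p.prediction.log_pct_inh)
    return proposals
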