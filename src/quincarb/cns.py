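"""CNS/blood-brain-barrier descriptor screen.

Passive BBB permeation is screened with the rule set recommended for
CNS-active drugs: MW < 450 g/mol, logP < 5, HBD < 3, HBA < 7, RB < 8 and
PSA < 70 Å² (all strict upper bounds).  Descriptors are computed from
structure with RDKit — topological polar surface area by Ertl's fragment
contributions, donor hydrogens for HBD, N+O (excluding quaternary
positively-charged nitrogen) for HBA, strict rotatable bonds for RB, and
Crippen's atom-contribution estimate as the default logP backend — or taken
from a user-supplied descriptor table, with provenance recorded per field.

Quaternary ammonium salts are profiled as the drawn cation: the halide
counterion is stripped (and logged) before descriptor calculation, matching
how per-compound descriptor platforms report such species.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from .formulas import molecular_weight, parse_formula

__all__ = [
    "CompoundDescriptors",
    "CNSRanges",
    "RuleReport",
    "DEFAULT_CNS_RANGES",
    "acquire_descriptors",
    "descriptors_from_smiles",
    "cns_rule_check",
    "export_radar",
]

logger = logging.getLogger(__name__)

DESCRIPTOR_FIELDS = ("MW", "logP", "PSA", "HBD", "HBA", "RB")

# Ertl fragment contributions for the nitro group: the published table scores
# the neutral pentavalent form N(=O)=O at 11.68 + 2*17.07 = 45.82 A^2, while
# the charge-separated [N+](=O)[O-] that RDKit normalises to scores
# 11.68 + 17.07 + 14.39(? charged O-) = 43.14 A^2.  Descriptor platforms
# report the neutral-form value; we add the difference per nitro group.
_NITRO = Chem.MolFromSmarts("[N+](=O)[O-]")
_NITRO_NEUTRAL_TPSA = 45.82
_NITRO_CHARGED_TPSA = 43.14


@dataclass
class CompoundDescriptors:
    compound_id: str
    MW: Optional[float] = None  # g/mol
    logP: Optional[float] = None
    PSA: Optional[float] = None  # A^2
    HBD: Optional[int] = None  # donor hydrogens (N-H, O-H)
    HBA: Optional[int] = None  # N + O, quaternary N+ excluded
    RB: Optional[int] = None  # rotatable bonds, strict definition
    provenance: Dict[str, str] = field(default_factory=dict)

    def get(self, name: str):
        return getattr(self, name)


@dataclass(frozen=True)
class Bound:
    upper: Optional[float] = None
    lower: Optional[float] = None
    strict_upper: bool = True
    strict_lower: bool = True

    def __post_init__(self):
        if self.upper is not None and self.lower is not None and self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


@dataclass(frozen=True)
class CNSRanges:
    """Per-descriptor recommended ranges; lower bounds are optional and
    disabled by default (the literature states them only qualitatively)."""

    bounds: Mapping[str, Bound]

    def __iter__(self):
        return iter(self.bounds.items())


DEFAULT_CNS_RANGES = CNSRanges(bounds={
    "MW": Bound(upper=450.0),
    "logP": Bound(upper=5.0),
    "HBD": Bound(upper=3.0),
    "HBA": Bound(upper=7.0),
    "RB": Bound(upper=8.0),
    "PSA": Bound(upper=70.0),
})


@dataclass
class RuleReport:
    compound_id: str
    statuses: Dict[str, str]  # within | below_lower | above_upper | unknown
    violated: List[str]

    @property
    def verdict(self) -> bool:
        """Pass iff no enabled bound is violated (unknowns excluded)."""
        return not self.violated


def _strip_counterion(mol: Chem.Mol, compound_id: str) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) == 1:
        return mol
    main = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    dropped = [Chem.MolToSmiles(f) for f in frags if f is not main]
    logger.info("compound %s: stripped counterion(s) %s", compound_id, dropped)
    return main


def _tpsa(mol: Chem.Mol) -> float:
    base = Descriptors.TPSA(mol)
    n_nitro = len(mol.GetSubstructMatches(_NITRO))
    return base + n_nitro * (_NITRO_NEUTRAL_TPSA - _NITRO_CHARGED_TPSA)


def _hba(mol: Chem.Mol) -> int:
    count = 0
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ("N", "O"):
            continue
        if (atom.GetSymbol() == "N" and atom.GetFormalCharge() > 0
                and atom.GetTotalDegree() == 4):
            continue  # quaternary ammonium nitrogen: no lone pair
        count += 1
    return count


def descriptors_from_smiles(
    smiles: str,
    compound_id: str,
    hbd_convention: str = "donor_hydrogens",
    logp_backend=Crippen.MolLogP,
) -> CompoundDescriptors:
    """Compute the six screen descriptors from a SMILES string.

    ``hbd_convention`` is ``donor_hydrogens`` (each N-H/O-H hydrogen counts,
    the dominant platform convention) or ``donor_groups`` (each N/O atom
    bearing hydrogens counts once).  ``logp_backend`` may be None to leave
    logP absent, or any callable Mol -> float.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {compound_id!r}: {smiles!r}")
    mol = _strip_counterion(mol, compound_id)
    # drop any net-charge suffix the formula writer appends (e.g. '+', '-2')
    formula = re.sub(r"[+-]\d*$", "", Chem.rdMolDescriptors.CalcMolFormula(mol))
    mw = molecular_weight(parse_formula(formula))
    if hbd_convention == "donor_hydrogens":
        hbd = int(Descriptors.NHOHCount(mol))
    elif hbd_convention == "donor_groups":
        hbd = int(Descriptors.NumHDonors(mol))
    else:
        raise ValueError(f"unknown HBD convention {hbd_convention!r}")
    d = CompoundDescriptors(
        compound_id=compound_id,
        MW=round(mw, 2),
        PSA=round(_tpsa(mol), 2),
        HBD=hbd,
        HBA=_hba(mol),
        RB=int(Descriptors.NumRotatableBonds(mol)),
        provenance={k: "computed" for k in ("MW", "PSA", "HBD", "HBA", "RB")},
    )
    if logp_backend is not None:
        d.logP = round(float(logp_backend(mol)), 2)
        d.provenance["logP"] = "computed"
    else:
        d.provenance["logP"] = "absent"
    return d


def acquire_descriptors(
    structures: Optional[Iterable[Tuple[str, str]]] = None,
    table: Optional[pd.DataFrame] = None,
    hbd_convention: str = "donor_hydrogens",
    logp_backend=Crippen.MolLogP,
) -> List[CompoundDescriptors]:
    """Build descriptor records from SMILES records and/or a supplied table.

    ``structures`` yields (compound_id, smiles) pairs; ``table`` is indexed
    or keyed by ``compound_id`` with any subset of the descriptor columns.
    Supplied values override computed ones and are marked as such.  A record
    whose structure fails to parse is reported and skipped; the run
    continues.
    """
    records: Dict[str, CompoundDescriptors] = {}
    if structures is not None:
        for compound_id, smiles in structures:
            try:
                records[compound_id] = descriptors_from_smiles(
                    smiles, compound_id, hbd_convention, logp_backend
                )
            except ValueError as exc:
                logger.error("skipping %s: %s", compound_id, exc)
    if table is not None:
        df = table.set_index("compound_id") if "compound_id" in table.columns else table
        for compound_id, row in df.iterrows():
            cid = str(compound_id)
            rec = records.get(cid) or CompoundDescriptors(compound_id=cid)
            for name in DESCRIPTOR_FIELDS:
                if name in row.index and pd.notna(row[name]):
                    value = row[name]
                    setattr(rec, name, int(value) if name in ("HBD", "HBA", "RB")
                            else float(value))
                    rec.provenance[name] = "supplied"
            records[cid] = rec
    if not records:
        raise ValueError("no structures or descriptor rows provided")
    return list(records.values())


def cns_rule_check(
    d: CompoundDescriptors, ranges: CNSRanges = DEFAULT_CNS_RANGES
) -> RuleReport:
    """Compare a compound's descriptors with the recommended CNS ranges.

    Strict inequalities per the printed rules; a missing descriptor yields
    status ``unknown`` and is excluded from the verdict with a warning.
    """
    if not any(b.upper is not None or b.lower is not None for _, b in ranges):
        raise ValueError("at least one bound must be enabled")
    statuses: Dict[str, str] = {}
    violated: List[str] = []
    for name, bound in ranges:
        value = d.get(name)
        if value is None:
            statuses[name] = "unknown"
            logger.warning(
                "compound %s: descriptor %s missing, excluded from verdict",
                d.compound_id, name,
            )
            continue
        status = "within"
        if bound.upper is not None:
            over = value >= bound.upper if bound.strict_upper else value > bound.upper
            if over:
                status = "above_upper"
        if status == "within" and bound.lower is not None:
            under = value <= bound.lower if bound.strict_lower else value < bound.lower
            if under:
                status = "below_lower"
        statuses[name] = status
        if status != "within":
            violated.append(name)
    return RuleReport(compound_id=d.compound_id, statuses=statuses, violated=violated)


def export_radar(
    ds: Sequence[CompoundDescriptors], ranges: CNSRanges = DEFAULT_CNS_RANGES
) -> pd.DataFrame:
    """Bound-normalised descriptor table for radar plotting.

    Each descriptor is divided by its recommended upper bound, so 1.0 marks
    the edge of the CNS-favourable region.  Axes without an upper bound are
    skipped with a warning.
    """
    if not ds:
        raise ValueError("empty descriptor list")
    axes = []
    for name, bound in ranges:
        if bound.upper is None:
            logger.warning("radar axis %s skipped: no upper bound", name)
            continue
        axes.append((name, bound.upper))
    rows = []
    for d in ds:
        row = {"compound_id": d.compound_id}
        for name, upper in axes:
            value = d.get(name)
            row[name] = np.nan if value is None else float(value) / upper
        rows.append(row)
    return pd.DataFrame(rows).set_index("compound_id")
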