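"""Lightweight molecular container for field calculations.

A :class:`Molecule` carries exactly the per-atom annotations the grid-field
engine needs — 3D coordinates, partial charges, van-der-Waals radii,
atomic hydrophobicity contributions and H-bond donor/acceptor flags — as
plain numpy arrays, plus an optional back-reference to the RDKit ``Mol``
it was built from (used for substructure matching during alignment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

logger = logging.getLogger(__name__)

#: simple perception rules, documented: a donor is N/O/S bearing >=1 hydrogen;
#: an acceptor is N or O without positive formal charge.
_DONOR_ELEMENTS = {"N", "O", "S"}
_ACCEPTOR_ELEMENTS = {"N", "O"}


@dataclass
class Molecule:
    """A small molecule with per-atom field-engine annotations.

    Coordinates are in Å, partial charges in elementary charge units,
    van-der-Waals radii in Å. ``hydrophobic`` holds atomic logP
    contributions (Wildman–Crippen scheme). ``bonds`` is a list of
    ``(i, j, order)`` tuples.
    """

    name: str
    symbols: list
    coords: np.ndarray
    charges: np.ndarray
    vdw_radii: np.ndarray
    hydrophobic: np.ndarray
    is_donor: np.ndarray
    is_acceptor: np.ndarray
    bonds: list = field(default_factory=list)
    charge_source: str = "file"
    rdmol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("a Molecule needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.name}: non-finite coordinates")
        for attr in ("charges", "vdw_radii", "hydrophobic"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{self.name}: {attr} length {arr.shape} != {n} atoms")
            setattr(self, attr, arr)
        self.is_donor = np.asarray(self.is_donor, dtype=bool)
        self.is_acceptor = np.asarray(self.is_acceptor, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule":
        """Return a copy with coordinates mapped through x -> R x + t."""
        new_coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        out = Molecule(
            name=self.name,
            symbols=list(self.symbols),
            coords=new_coords,
            charges=self.charges.copy(),
            vdw_radii=self.vdw_radii.copy(),
            hydrophobic=self.hydrophobic.copy(),
            is_donor=self.is_donor.copy(),
            is_acceptor=self.is_acceptor.copy(),
            bonds=list(self.bonds),
            charge_source=self.charge_source,
            rdmol=self.rdmol,
        )
        return out

    def translated(self, shift: Sequence[float]) -> "Molecule":
        return self.transformed(np.eye(3), np.asarray(shift, dtype=float))

    def to_rdkit(self) -> Chem.Mol:
        """RDKit view of this molecule (cached if built from one)."""
        if self.rdmol is not None:
            return self.rdmol
        rw = Chem.RWMol()
        for sym in self.symbols:
            rw.AddAtom(Chem.Atom(sym))
        for i, j, order in self.bonds:
            rw.AddBond(int(i), int(j), _bond_type(order))
        conf = Chem.Conformer(self.n_atoms)
        for i, xyz in enumerate(self.coords):
            conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
        mol = rw.GetMol()
        mol.AddConformer(conf)
        try:
            Chem.SanitizeMol(mol)
        except Exception:  # keep unsanitized graph usable for matching
            logger.warning("%s: sanitization failed on reconstructed graph", self.name)
        self.rdmol = mol
        return mol


def _bond_type(order: float) -> Chem.BondType:
    return {
        1.0: Chem.BondType.SINGLE,
        2.0: Chem.BondType.DOUBLE,
        3.0: Chem.BondType.TRIPLE,
        1.5: Chem.BondType.AROMATIC,
    }.get(float(order), Chem.BondType.SINGLE)


def _bond_order(bond: Chem.Bond) -> float:
    if bond.GetIsAromatic():
        return 1.5
    return float(bond.GetBondTypeAsDouble())


def mmff94_charges(mol: Chem.Mol) -> Optional[np.ndarray]:
    """MMFF94 partial charges, or None when the force field cannot type the molecule."""
    props = AllChem.MMFFGetMoleculeProperties(mol)
    if props is None:
        return None
    return np.array([props.GetMMFFPartialCharge(i) for i in range(mol.GetNumAtoms())])


def from_rdkit(
    mol: Chem.Mol,
    name: Optional[str] = None,
    charges: Optional[np.ndarray] = None,
    conf_id: int = -1,
) -> Molecule:
    """Annotate an RDKit molecule (with a 3D conformer) into a :class:`Molecule`.

    Partial charges supplied by the caller (typically read from the input
    file) take precedence; otherwise MMFF94 charges are computed, with a
    Gasteiger fallback for molecules outside MMFF94 coverage. The charge
    provenance is recorded in ``charge_source``.
    """
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D conformer")
    conf = mol.GetConformer(conf_id)
    coords = np.array(conf.GetPositions(), dtype=float)
    if name is None:
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else "unnamed"

    if charges is not None:
        charges = np.asarray(charges, dtype=float)
        source = "file"
    else:
        charges = mmff94_charges(mol)
        source = "mmff94"
        if charges is None:
            gm = Chem.Mol(mol)
            AllChem.ComputeGasteigerCharges(gm)
            charges = np.array(
                [float(a.GetProp("_GasteigerCharge")) for a in gm.GetAtoms()]
            )
            charges = np.nan_to_num(charges)
            source = "gasteiger"
    logger.debug("%s: partial charges from %s", name, source)

    total_formal = float(Chem.GetFormalCharge(mol))
    if abs(charges.sum() - total_formal) > 1e-3:
        logger.warning(
            "%s: charges sum to %.4f but formal charge is %.0f",
            name, charges.sum(), total_formal,
        )

    pt = Chem.GetPeriodicTable()
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    vdw = np.array([pt.GetRvdw(a.GetAtomicNum()) for a in mol.GetAtoms()])
    crippen = rdMolDescriptors._CalcCrippenContribs(mol)
    hydrophobic = np.array([c[0] for c in crippen])

    donors = np.zeros(len(symbols), dtype=bool)
    acceptors = np.zeros(len(symbols), dtype=bool)
    for i, atom in enumerate(mol.GetAtoms()):
        sym = atom.GetSymbol()
        if sym in _DONOR_ELEMENTS and atom.GetTotalNumHs(includeNeighbors=True) > 0:
            donors[i] = True
        if sym in _ACCEPTOR_ELEMENTS and atom.GetFormalCharge() <= 0:
            acceptors[i] = True

    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _bond_order(b))
        for b in mol.GetBonds()
    ]
    return Molecule(
        name=name,
        symbols=symbols,
        coords=coords,
        charges=charges,
        vdw_radii=vdw,
        hydrophobic=hydrophobic,
        is_donor=donors,
        is_acceptor=acceptors,
        bonds=bonds,
        charge_source=source,
        rdmol=mol,
    )
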