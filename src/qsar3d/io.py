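"""Structure and activity-table I/O.

Reads SDF (V2000) and Tripos MOL2 structure files into
:class:`~qsar3d.molecule.Molecule` objects, converts IC50 (μM) to pIC50,
and manages the train/test partition of a congeneric series.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from rdkit import Chem

from .molecule import Molecule, from_rdkit

logger = logging.getLogger(__name__)

CHARGE_PROP = "PARTIAL_CHARGES"

#: default held-out compounds for the bundled 46-member thienopyridine series
DEFAULT_TEST_IDS = ("2", "3", "9", "10", "12", "21", "34", "36", "37", "38", "44")


@dataclass
class CompoundRecord:
    """One member of the series: activity plus subset label.

    ``ic50`` is in μM (> 0); ``pic50`` is −log10 of the molar IC50 and is
    stored at full precision — truncation to the two decimals used in
    printed tables is a formatting concern (:func:`format_pic50`).
    """

    compound_id: str
    ic50: float
    pic50: float
    subset: str = "train"
    structure_ref: Optional[Molecule] = None

    def __post_init__(self):
        if self.ic50 <= 0:
            raise ValueError(f"{self.compound_id}: IC50 must be positive")
        if self.subset not in ("train", "test"):
            raise ValueError(f"{self.compound_id}: subset must be train|test")


def to_pic50(ic50_uM: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """pIC50 = −log10(IC50 in mol/L) for an IC50 given in μM.

    >>> round(to_pic50(1.0), 4)
    6.0
    """
    arr = np.asarray(ic50_uM, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("IC50 must be finite and > 0")
    out = -np.log10(arr * 1e-6)
    return float(out) if np.isscalar(ic50_uM) or arr.ndim == 0 else out


def from_pic50(pic50: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Inverse transform: pIC50 back to IC50 in μM."""
    arr = np.asarray(pic50, dtype=float)
    out = np.power(10.0, -arr) * 1e6
    return float(out) if np.isscalar(pic50) or arr.ndim == 0 else out


def format_pic50(pic50: float, decimals: int = 2) -> str:
    """Truncate (floor) to ``decimals`` places, the convention of the printed tables."""
    scale = 10 ** decimals
    return f"{math.floor(pic50 * scale) / scale:.{decimals}f}"


# ---------------------------------------------------------------------------
# structure files


def _sdf_charges(mol: Chem.Mol) -> Optional[np.ndarray]:
    if mol.HasProp(CHARGE_PROP):
        vals = [float(x) for x in mol.GetProp(CHARGE_PROP).split()]
        if len(vals) == mol.GetNumAtoms():
            return np.array(vals)
        logger.warning("charge property length mismatch; ignoring")
    return None


def _is_3d(mol: Chem.Mol) -> bool:
    if mol.GetNumConformers() == 0:
        return False
    conf = mol.GetConformer()
    if conf.Is3D():
        return True
    # some writers forget the 3D flag; accept any non-planar z spread
    z = np.array(conf.GetPositions())[:, 2]
    return bool(np.ptp(z) > 1e-6)


def read_structures(path: Union[str, Path], format: Optional[str] = None) -> List[Molecule]:
    """Read an SDF or MOL2 file into Molecules.

    Records without 3D coordinates (or that fail to parse) are rejected
    individually with a logged reason; the rest survive. Partial charges in
    the file win over computed MMFF94 charges.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("sdf", "mol2"):
        raise ValueError(f"unsupported structure format: {fmt}")
    if path.stat().st_size == 0 or not path.read_text().strip():
        logger.warning("%s: empty structure file", path)
        return []

    molecules: List[Molecule] = []
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for idx, mol in enumerate(supplier):
            if mol is None:
                logger.warning("%s: record %d failed to parse; rejected", path, idx)
                continue
            if not _is_3d(mol):
                logger.warning("%s: record %d has no 3D coordinates; rejected", path, idx)
                continue
            molecules.append(from_rdkit(mol, charges=_sdf_charges(mol)))
    else:
        for idx, block in enumerate(_split_mol2(path.read_text())):
            mol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=True)
            if mol is None:
                mol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=False)
            if mol is None:
                logger.warning("%s: MOL2 record %d failed to parse; rejected", path, idx)
                continue
            if not _is_3d(mol):
                logger.warning("%s: MOL2 record %d not 3D; rejected", path, idx)
                continue
            charges = None
            if all(a.HasProp("_TriposPartialCharge") for a in mol.GetAtoms()):
                charges = np.array(
                    [float(a.GetProp("_TriposPartialCharge")) for a in mol.GetAtoms()]
                )
                if np.allclose(charges, 0.0):
                    charges = None  # NO_CHARGES placeholder
            molecules.append(from_rdkit(mol, charges=charges))
    return molecules


def _split_mol2(text: str) -> List[str]:
    blocks, current = [], []
    for line in text.splitlines(keepends=True):
        if line.startswith("@<TRIPOS>MOLECULE"):
            if current:
                blocks.append("".join(current))
            current = [line]
        elif current:
            current.append(line)
    if current:
        blocks.append("".join(current))
    return blocks


def write_structures(
    path: Union[str, Path], molecules: Sequence[Molecule], format: Optional[str] = None
) -> None:
    """Write Molecules to SDF (charges as an SD tag) or Tripos MOL2."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        writer.SetKekulize(False)
        for m in molecules:
            rdmol = Chem.Mol(m.to_rdkit())
            rdmol.SetProp("_Name", m.name)
            rdmol.SetProp(CHARGE_PROP, " ".join(f"{c:.6f}" for c in m.charges))
            writer.write(rdmol)
        writer.close()
    elif fmt == "mol2":
        path.write_text("".join(_mol2_block(m) for m in molecules))
    else:
        raise ValueError(f"unsupported structure format: {fmt}")


def _mol2_block(m: Molecule) -> str:
    lines = ["@<TRIPOS>MOLECULE", m.name,
             f"{m.n_atoms:d} {len(m.bonds):d} 0 0 0", "SMALL", "USER_CHARGES", "",
             "@<TRIPOS>ATOM"]
    for i in range(m.n_atoms):
        x, y, z = m.coords[i]
        lines.append(
            f"{i + 1:>7d} {m.symbols[i]:<4s} {x:>10.4f} {y:>10.4f} {z:>10.4f} "
            f"{m.symbols[i]:<5s} 1 UNL {m.charges[i]:>9.4f}"
        )
    lines.append("@<TRIPOS>BOND")
    for b, (i, j, order) in enumerate(m.bonds):
        bt = {1.0: "1", 2.0: "2", 3.0: "3", 1.5: "ar"}.get(float(order), "1")
        lines.append(f"{b + 1:>6d} {i + 1:>5d} {j + 1:>5d} {bt:>4s}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# activity tables


def read_activity_table(path: Union[str, Path]) -> List[CompoundRecord]:
    """Read a ``compound_id,ic50_uM[,subset]`` CSV into CompoundRecords.

    Rows with missing or non-positive IC50 are rejected (logged); a
    duplicated compound_id is an error. Without a subset column every
    record is labelled ``train``.
    """
    df = pd.read_csv(path, dtype={"compound_id": str})
    required = {"compound_id", "ic50_uM"}
    if not required.issubset(df.columns):
        raise ValueError(f"activity table needs columns {sorted(required)}")
    dupes = df["compound_id"][df["compound_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate compound_id values: {sorted(set(dupes))}")
    records: List[CompoundRecord] = []
    for _, row in df.iterrows():
        ic50 = row["ic50_uM"]
        if pd.isna(ic50) or ic50 <= 0:
            logger.warning("row %s rejected: IC50 %r not positive", row["compound_id"], ic50)
            continue
        subset = row.get("subset", "train")
        if pd.isna(subset):
            subset = "train"
        records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                ic50=float(ic50),
                pic50=to_pic50(float(ic50)),
                subset=str(subset),
            )
        )
    return records


def write_activity_table(path: Union[str, Path], records: Iterable[CompoundRecord]) -> None:
    pd.DataFrame(
        [{"compound_id": r.compound_id, "ic50_uM": r.ic50, "subset": r.subset}
         for r in records]
    ).to_csv(path, index=False)


def split_train_test(
    records: Sequence[CompoundRecord], test_ids: Sequence[str]
) -> Tuple[List[CompoundRecord], List[CompoundRecord]]:
    """Partition records by membership of ``test_ids`` (order preserved).

    Every test id must name an existing record; the partition is disjoint
    and exhaustive by construction.
    """
    known = {r.compound_id for r in records}
    for tid in test_ids:
        if str(tid) not in known:
            raise KeyError(f"unknown compound id in test_ids: {tid!r}")
    test_set = {str(t) for t in test_ids}
    train, test = [], []
    for r in records:
        target = test if r.compound_id in test_set else train
        r.subset = "test" if r.compound_id in test_set else "train"
        target.append(r)
    return train, test
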