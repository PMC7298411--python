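"""Synthetic congeneric series and orbital fixtures with planted ground truth.

The generator emulates the statistical shape of a 3D-QSAR study on a
congeneric inhibitor series: a fused thienopyridine-like bicyclic
scaffold decorated at two positions from a small substituent vocabulary,
embedded once in 3D and aligned by construction (every analogue's
scaffold atoms carry identical coordinates), with activity planted as a
linear function of grid-field values plus Gaussian noise and rescaled
into a realistic pIC50 window (4.77–7.38 by default, matching the
activity span of the series this package models). The planted
coefficients, influential columns and noiseless response are always
emitted next to the data so recovery tests never re-derive them.

Orbital fixtures pair frontier energies drawn from a chemically
plausible window (−8…0 eV) with population vectors that conserve the
electron count by construction, plus their exact μ, η, S, ω.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from . import fields as field_engine
from .align import kabsch_superpose
from .cdft import OrbitalData, descriptors_from_mu_eta, orbital_energies_from_mu_eta
from .io import CompoundRecord, from_pic50
from .molecule import Molecule, from_rdkit

logger = logging.getLogger(__name__)

#: fused bicyclic scaffold with two substitution sites (thieno[2,3-b]pyridine-like)
DEFAULT_SCAFFOLD_TEMPLATE = "c1c({r4})c2cc({r6})sc2nc1"
DEFAULT_CORE_SMILES = "c1cc2ccsc2nc1"
DEFAULT_VOCABULARY = (
    "[H]", "C", "CC", "CCC", "C(C)C", "OC", "O", "N", "F", "Cl", "C#N", "CO",
)


@dataclass
class SyntheticSeriesSpec:
    """Conditions for one synthetic series.

    ``noise_sd`` is in log (pIC50) units; ``activity_range`` is the window
    the noiseless response is rescaled into.
    """

    n_compounds: int = 46
    scaffold_template: str = DEFAULT_SCAFFOLD_TEMPLATE
    core_smiles: str = DEFAULT_CORE_SMILES
    substituent_vocabulary: Tuple[str, ...] = DEFAULT_VOCABULARY
    influential_field: str = "steric"
    method: str = "comfa"
    n_influential_columns: int = 8
    noise_sd: float = 0.1
    activity_range: Tuple[float, float] = (4.77, 7.38)
    grid_spacing: float = 2.0
    grid_margin: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds < 6:
            raise ValueError("n_compounds must be >= 6")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.substituent_vocabulary:
            raise ValueError("substituent vocabulary must be non-empty")


def _embed(smiles: str, seed: int) -> Optional[Chem.Mol]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    mol = Chem.AddHs(mol)
    if AllChem.EmbedMolecule(mol, randomSeed=int(seed % (2**31 - 1))) != 0:
        return None
    AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    return mol


def make_aligned_series(spec: SyntheticSeriesSpec) -> List[Molecule]:
    """Deterministic congeneric series with exactly shared scaffold coordinates.

    Each analogue is embedded in 3D, superposed onto the reference
    scaffold conformation over the core match, and its core atoms are
    then snapped exactly onto the reference coordinates. Substituent
    combinations that fail to parse or embed are skipped with a log line.
    """
    rng = np.random.default_rng([spec.seed, 0])
    core = Chem.MolFromSmiles(spec.core_smiles)
    ref = _embed(
        spec.scaffold_template.format(r4="[H]", r6="[H]"), seed=spec.seed + 7
    )
    if ref is None:
        raise ValueError("scaffold template failed to embed")
    ref_match = ref.GetSubstructMatch(core)
    ref_coords = np.array(ref.GetConformer().GetPositions())[list(ref_match)]

    vocab = list(spec.substituent_vocabulary)
    molecules: List[Molecule] = []
    embedded: Dict[str, Optional[Chem.Mol]] = {}
    skipped = 0
    i = 0
    while len(molecules) < spec.n_compounds:
        i += 1
        if i > 20 * spec.n_compounds:
            raise RuntimeError("too many invalid decorations; check the vocabulary")
        r4 = vocab[int(rng.integers(len(vocab)))]
        r6 = vocab[int(rng.integers(len(vocab)))]
        smiles = spec.scaffold_template.format(r4=r4, r6=r6)
        # one conformer per decoration: duplicates are bit-identical molecules
        if smiles not in embedded:
            embedded[smiles] = _embed(
                smiles, seed=spec.seed * 1009 + zlib.crc32(smiles.encode()) % 100003
            )
        mol = Chem.Mol(embedded[smiles]) if embedded[smiles] is not None else None
        if mol is None:
            skipped += 1
            logger.warning("decoration (%s, %s) invalid or unembeddable; skipped", r4, r6)
            continue
        match = mol.GetSubstructMatch(core)
        if not match:
            skipped += 1
            continue
        conf = mol.GetConformer()
        coords = np.array(conf.GetPositions())
        res, _ = kabsch_superpose(ref_coords, coords[list(match)])
        moved = res.apply(coords)
        moved[list(match)] = ref_coords  # exact shared scaffold frame
        for k, xyz in enumerate(moved):
            conf.SetAtomPosition(k, tuple(float(v) for v in xyz))
        mol.SetProp("_Name", str(len(molecules) + 1))
        molecules.append(from_rdkit(mol))
    if skipped:
        logger.info("series built with %d skipped decorations", skipped)
    return molecules


def make_field_activity(
    molecules: Sequence[Molecule], spec: SyntheticSeriesSpec
) -> Tuple[List[CompoundRecord], Dict]:
    """Plant pIC50 = Σ β_j X_j + ε on the series' own grid fields.

    X is the field matrix of ``spec.method``; the β support lives in the
    highest-variance columns of the ``spec.influential_field`` block. The
    noiseless response is rescaled into ``spec.activity_range`` before
    noise is added, and the effective β (after rescaling), intercept,
    column indices and clean response are returned as the truth record.
    """
    grid = field_engine.build_grid(molecules, spec.grid_margin, spec.grid_spacing)
    blocks = field_engine.assemble_descriptor_matrix(
        molecules, grid, method=spec.method
    )
    kinds = [b.field_kind for b in blocks]
    if spec.influential_field not in kinds:
        raise ValueError(f"influential field {spec.influential_field!r} not in {kinds}")
    block_pos = kinds.index(spec.influential_field)
    Xb = blocks[block_pos].values
    sd = Xb.std(axis=0, ddof=1)
    order = np.argsort(sd)[::-1]
    cols = np.sort(order[: spec.n_influential_columns])
    if sd[cols].max() <= 0:
        raise ValueError("degenerate field matrix: no varying columns to plant on")

    rng = np.random.default_rng([spec.seed, 1])
    beta = rng.standard_normal(cols.size)
    raw = Xb[:, cols] @ beta
    span = raw.max() - raw.min()
    if span <= 0:
        raise ValueError("planted response is constant; enlarge the vocabulary")
    lo, hi = spec.activity_range
    scale = (hi - lo) / span
    intercept = lo - scale * raw.min()
    y_clean = intercept + scale * raw
    noise = rng.normal(0.0, spec.noise_sd, size=len(y_clean))
    y = y_clean + noise

    records = [
        CompoundRecord(
            compound_id=m.name,
            ic50=from_pic50(val),
            pic50=float(val),
            subset="train",
        )
        for m, val in zip(molecules, y)
    ]
    truth = {
        "influential_field": spec.influential_field,
        "block_position": block_pos,
        "column_indices": cols.tolist(),
        "beta": (scale * beta).tolist(),
        "intercept": float(intercept),
        "y_clean": y_clean.tolist(),
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "grid": {"origin": list(grid.origin), "spacing": grid.spacing,
                 "dims": list(grid.dims)},
    }
    return records, truth


def make_series_bundle(
    spec: SyntheticSeriesSpec,
) -> Tuple[List[Molecule], List[CompoundRecord], Dict]:
    """Convenience: aligned series + planted activity + truth in one call."""
    molecules = make_aligned_series(spec)
    records, truth = make_field_activity(molecules, spec)
    return molecules, records, truth


# ---------------------------------------------------------------------------
# orbital fixtures


class OrbitalFixture(NamedTuple):
    data: OrbitalData
    truth: Dict


def make_orbital_fixtures(
    n: int, seed: int, n_atoms: int = 12
) -> List[OrbitalFixture]:
    """Orbital fixtures with exact planted μ, η, S, ω and conserving populations.

    Frontier energies are drawn in the −8…0 eV window with a gap of at
    least 0.5 eV; f⁺/f⁻ are Dirichlet-distributed so Σf± = 1 holds by
    construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([seed, 2])
    fixtures: List[OrbitalFixture] = []
    for i in range(n):
        e_homo = rng.uniform(-8.0, -1.0)
        gap = rng.uniform(0.5, min(5.0, -e_homo))
        e_lumo = e_homo + gap
        pops_n = rng.uniform(0.5, 7.0, size=n_atoms)
        f_plus = rng.dirichlet(np.ones(n_atoms))
        f_minus = rng.dirichlet(np.ones(n_atoms))
        data = OrbitalData(
            compound_id=f"synth{i + 1}",
            e_homo=e_homo,
            e_lumo=e_lumo,
            populations_N=pops_n,
            populations_Nplus1=pops_n + f_plus,
            populations_Nminus1=pops_n - f_minus,
            atom_labels=[f"C{k + 1}" for k in range(n_atoms)],
        )
        mu = (e_homo + e_lumo) / 2.0
        eta = e_lumo - e_homo
        truth = {
            "mu": mu,
            "eta": eta,
            "softness": 1.0 / eta,
            "omega": mu * mu / (2.0 * eta),
            "f_plus": f_plus.tolist(),
            "f_minus": f_minus.tolist(),
        }
        fixtures.append(OrbitalFixture(data=data, truth=truth))
    return fixtures


def orbital_fixture_from_mu_eta(
    mu: float, eta: float, compound_id: str = "planted"
) -> OrbitalFixture:
    """Fixture whose frontier energies reproduce a given (μ, η) pair exactly."""
    e_homo, e_lumo = orbital_energies_from_mu_eta(mu, eta)
    desc = descriptors_from_mu_eta(mu, eta, compound_id)
    data = OrbitalData(compound_id=compound_id, e_homo=e_homo, e_lumo=e_lumo)
    truth = {
        "mu": mu,
        "eta": eta,
        "softness": desc.softness,
        "omega": desc.electrophilicity,
    }
    return OrbitalFixture(data=data, truth=truth)


def write_orbital_fixture(path: Union[str, Path], fixture: OrbitalFixture) -> None:
    """Emit one fixture in the native JSON schema (truth under ``truth``)."""
    data = fixture.data
    doc = {
        "compound_id": data.compound_id,
        "e_homo_eV": data.e_homo,
        "e_lumo_eV": data.e_lumo,
        "atom_labels": data.atom_labels,
        "truth": fixture.truth,
    }
    if data.populations_N is not None:
        doc["populations"] = {
            "N": data.populations_N.tolist(),
            "N_plus_1": data.populations_Nplus1.tolist(),
            "N_minus_1": data.populations_Nminus1.tolist(),
        }
    Path(path).write_text(json.dumps(doc, indent=2))
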