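"""CoMFA interaction fields and CoMSIA similarity-index fields.

A probe atom is evaluated on a shared rectilinear grid around the aligned
series. CoMFA fields are physical probe energies (kcal/mol): a
Lennard-Jones 12-6 steric term and a Coulombic electrostatic term with a
distance-dependent dielectric, both truncated at ±30 kcal/mol, with the
electrostatic value at sterically truncated points replaced by the column
mean across compounds (the conventional treatment of points inside the
molecular envelope). CoMSIA fields are Gaussian-attenuated similarity
indices A_k(q) = −Σ_i w_ik exp(−α r_iq²), which are smooth everywhere and
need no cutoff.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial.distance import cdist

from .molecule import Molecule

logger = logging.getLogger(__name__)

COULOMB_CONSTANT = 332.0  # kcal·Å/(mol·e²)
BOHR_PER_ANGSTROM = 1.0 / 0.52917721092

COMFA_KINDS = ("steric", "electrostatic")
COMSIA_KINDS = ("steric", "electrostatic", "hydrophobic", "donor", "acceptor")

#: Tripos-style 12-6 parameters per element: (vdW radius Å, well depth kcal/mol).
LJ_PARAMS: Dict[str, Tuple[float, float]] = {
    "H": (1.50, 0.042),
    "C": (1.70, 0.107),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "F": (1.47, 0.109),
    "P": (1.80, 0.314),
    "S": (1.80, 0.314),
    "Cl": (1.75, 0.314),
    "Br": (1.85, 0.434),
    "I": (1.98, 0.623),
}
_LJ_DEFAULT = (1.70, 0.107)


@dataclass(frozen=True)
class ProbeParams:
    """CoMFA probe: an sp3 carbon with +1 charge by convention."""

    vdw_radius: float = 1.70
    epsilon: float = 0.107
    charge: float = 1.0


DEFAULT_PROBE = ProbeParams()


@dataclass(frozen=True)
class Grid:
    """Axis-aligned rectilinear grid: origin (Å), isotropic spacing, dims."""

    origin: Tuple[float, float, float]
    spacing: float
    dims: Tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must each be >= 1")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def axes(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = np.asarray(self.origin)
        return tuple(
            o[a] + self.spacing * np.arange(self.dims[a]) for a in range(3)
        )

    def points(self) -> np.ndarray:
        """All grid points, (N, 3), z varying fastest (cube-file order)."""
        xs, ys, zs = self.axes()
        g = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack(g, axis=-1).reshape(-1, 3)

    def translated(self, shift: Sequence[float]) -> "Grid":
        o = tuple(float(a + b) for a, b in zip(self.origin, shift))
        return Grid(origin=o, spacing=self.spacing, dims=self.dims)


@dataclass
class FieldBlock:
    """compounds × grid-points matrix for one field kind."""

    field_kind: str
    method: str
    values: np.ndarray
    grid: Grid
    compound_ids: Optional[List[str]] = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.grid.n_points:
            raise ValueError("field matrix width does not match grid point count")


def build_grid(
    molecules: Sequence[Molecule], margin: float = 4.0, spacing: float = 0.6
) -> Grid:
    """Bounding box of the aligned series extended by ``margin`` on every side.

    Point count per axis is ceil(span/spacing) + 1, so the box is covered
    with the last point at or beyond the far face.
    """
    if not molecules:
        raise ValueError("need at least one molecule to build a grid")
    if margin <= 0 or spacing <= 0:
        raise ValueError("margin and spacing must be positive")
    all_coords = np.vstack([m.coords for m in molecules])
    lo = all_coords.min(axis=0) - margin
    hi = all_coords.max(axis=0) + margin
    dims = tuple(int(math.ceil((h - l) / spacing - 1e-9)) + 1 for l, h in zip(lo, hi))
    return Grid(origin=tuple(float(v) for v in lo), spacing=float(spacing), dims=dims)


def _lj_params(symbols: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
    radii = np.array([LJ_PARAMS.get(s, _LJ_DEFAULT)[0] for s in symbols])
    eps = np.array([LJ_PARAMS.get(s, _LJ_DEFAULT)[1] for s in symbols])
    return radii, eps


def lennard_jones_field(
    mol: Molecule,
    grid: Grid,
    probe: ProbeParams = DEFAULT_PROBE,
    cutoff: float = 30.0,
) -> np.ndarray:
    """12-6 steric probe energy per grid point, clamped to [−cutoff, +cutoff].

    Lorentz–Berthelot combining: r_min_ij = r_i + r_probe,
    ε_ij = sqrt(ε_i ε_probe); E = Σ_i ε_ij [(r_min/r)¹² − 2 (r_min/r)⁶],
    so E(r_min) = −ε_ij and the zero crossing sits at r_min / 2^(1/6).
    Points coincident with an atom clamp to +cutoff instead of diverging.
    """
    radii, eps = _lj_params(mol.symbols)
    r_min = radii + probe.vdw_radius
    eps_ij = np.sqrt(eps * probe.epsilon)
    d = cdist(mol.coords, grid.points())
    d = np.maximum(d, 1e-12)
    ratio6 = (r_min[:, None] / d) ** 6
    with np.errstate(over="ignore"):
        energy = (eps_ij[:, None] * (ratio6**2 - 2.0 * ratio6)).sum(axis=0)
    return np.clip(energy, -cutoff, cutoff)


def coulomb_field(
    mol: Molecule,
    grid: Grid,
    probe_charge: float = 1.0,
    dielectric: Union[str, float] = "r",
    cutoff: Optional[float] = None,
) -> np.ndarray:
    """Coulombic probe energy per grid point, kcal/mol.

    E(q) = Σ_i k z_i z_probe / (D(r) r) with k = 332.0 kcal·Å/(mol·e²).
    ``dielectric="r"`` selects the distance-dependent dielectric D(r) = r
    (the conventional choice); a float selects a constant dielectric.
    The bare field is unclamped (``cutoff`` optionally clips it); grid
    points inside the molecular envelope are instead handled by the
    column-mean replacement during CoMFA assembly.
    """
    if mol.charges is None:
        raise ValueError("molecule has no partial charges")
    d = cdist(mol.coords, grid.points())
    d = np.maximum(d, 1e-12)
    if dielectric == "r":
        denom = d * d
    else:
        denom = float(dielectric) * d
    with np.errstate(over="ignore"):
        energy = (COULOMB_CONSTANT * probe_charge * mol.charges[:, None] / denom).sum(axis=0)
    if cutoff is not None:
        energy = np.clip(energy, -cutoff, cutoff)
    return energy


def _comsia_weights(mol: Molecule, field_kind: str) -> np.ndarray:
    if field_kind == "steric":
        return mol.vdw_radii**3
    if field_kind == "electrostatic":
        return mol.charges
    if field_kind == "hydrophobic":
        return mol.hydrophobic
    if field_kind == "donor":
        return mol.is_donor.astype(float)
    if field_kind == "acceptor":
        return mol.is_acceptor.astype(float)
    raise ValueError(f"unknown CoMSIA field kind: {field_kind!r}")


def comsia_field(
    mol: Molecule, grid: Grid, field_kind: str, alpha: float = 0.3
) -> np.ndarray:
    """Gaussian similarity index A_k(q) = −Σ_i w_ik exp(−α r_iq²), unit probe.

    α (Å⁻²) is the attenuation factor, default 0.3. Values are finite and
    bounded by Σ|w_ik| in magnitude.
    """
    w = _comsia_weights(mol, field_kind)
    d2 = cdist(mol.coords, grid.points(), metric="sqeuclidean")
    return -(w[:, None] * np.exp(-alpha * d2)).sum(axis=0)


def assemble_descriptor_matrix(
    molecules: Sequence[Molecule],
    grid: Grid,
    method: str = "comfa",
    field_kinds: Optional[Sequence[str]] = None,
    probe: ProbeParams = DEFAULT_PROBE,
    alpha: float = 0.3,
    cutoff: float = 30.0,
    electrostatic_mean_fill: bool = True,
) -> List[FieldBlock]:
    """One FieldBlock per field kind; rows follow compound order.

    For CoMFA, the electrostatic value at grid points where a compound's
    steric energy hit the +cutoff (points inside that molecule) is
    replaced by the mean of that column over the unaffected compounds.
    """
    if not molecules:
        raise ValueError("no molecules given")
    if method not in ("comfa", "comsia"):
        raise ValueError(f"unknown method: {method!r}")
    kinds = tuple(field_kinds) if field_kinds else (
        COMFA_KINDS if method == "comfa" else COMSIA_KINDS
    )
    ids = [m.name for m in molecules]
    blocks: List[FieldBlock] = []
    if method == "comfa":
        steric = np.vstack([lennard_jones_field(m, grid, probe, cutoff) for m in molecules])
        inside = steric >= cutoff - 1e-9
        for kind in kinds:
            if kind == "steric":
                vals = steric
            elif kind == "electrostatic":
                vals = np.vstack(
                    [coulomb_field(m, grid, probe.charge) for m in molecules]
                )
                if electrostatic_mean_fill:
                    vals = _mean_fill(vals, inside)
            else:
                raise ValueError(f"CoMFA has no field kind {kind!r}")
            blocks.append(FieldBlock(kind, "comfa", vals, grid, ids))
    else:
        for kind in kinds:
            vals = np.vstack([comsia_field(m, grid, kind, alpha) for m in molecules])
            blocks.append(FieldBlock(kind, "comsia", vals, grid, ids))
    return blocks


def _mean_fill(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked entries by their column mean over unmasked rows (0 if none)."""
    out = values.copy()
    n_ok = (~mask).sum(axis=0)
    col_sum = np.where(mask, 0.0, values).sum(axis=0)
    col_mean = np.divide(col_sum, n_ok, out=np.zeros_like(col_sum), where=n_ok > 0)
    rows, cols = np.nonzero(mask)
    out[rows, cols] = col_mean[cols]
    return out


def stack_blocks(blocks: Sequence[FieldBlock]) -> Tuple[np.ndarray, np.ndarray]:
    """Concatenate blocks column-wise into (X, block_index)."""
    X = np.hstack([b.values for b in blocks])
    block_index = np.concatenate(
        [np.full(b.values.shape[1], i, dtype=int) for i, b in enumerate(blocks)]
    )
    return X, block_index


# ---------------------------------------------------------------------------
# persistence


def save_fields(directory: Union[str, Path], blocks: Sequence[FieldBlock]) -> None:
    """Persist blocks as .npy arrays plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "grid": {
            "origin": list(blocks[0].grid.origin),
            "spacing": blocks[0].grid.spacing,
            "dims": list(blocks[0].grid.dims),
        },
        "compound_ids": blocks[0].compound_ids,
        "blocks": [],
    }
    for b in blocks:
        fname = f"{b.method}_{b.field_kind}.npy"
        np.save(directory / fname, b.values)
        manifest["blocks"].append(
            {"field_kind": b.field_kind, "method": b.method, "file": fname}
        )
    (directory / "fields.json").write_text(json.dumps(manifest, indent=2))


def load_fields(directory: Union[str, Path]) -> List[FieldBlock]:
    directory = Path(directory)
    manifest = json.loads((directory / "fields.json").read_text())
    grid = Grid(
        origin=tuple(manifest["grid"]["origin"]),
        spacing=manifest["grid"]["spacing"],
        dims=tuple(manifest["grid"]["dims"]),
    )
    return [
        FieldBlock(
            entry["field_kind"],
            entry["method"],
            np.load(directory / entry["file"]),
            grid,
            manifest.get("compound_ids"),
        )
        for entry in manifest["blocks"]
    ]


# ---------------------------------------------------------------------------
# Gaussian cube export


def write_cube(
    path: Union[str, Path],
    grid: Grid,
    values: np.ndarray,
    molecule: Optional[Molecule] = None,
    comment: str = "qsar3d field",
) -> None:
    """Write one scalar grid as a Gaussian cube file (lengths in bohr)."""
    values = np.asarray(values, dtype=float).reshape(grid.n_points)
    b = BOHR_PER_ANGSTROM
    lines = [comment, "generated by qsar3d"]
    natoms = molecule.n_atoms if molecule is not None else 0
    o = np.asarray(grid.origin) * b
    lines.append(f"{natoms:5d} {o[0]:11.6f} {o[1]:11.6f} {o[2]:11.6f}")
    s = grid.spacing * b
    lines.append(f"{grid.dims[0]:5d} {s:11.6f} {0.0:11.6f} {0.0:11.6f}")
    lines.append(f"{grid.dims[1]:5d} {0.0:11.6f} {s:11.6f} {0.0:11.6f}")
    lines.append(f"{grid.dims[2]:5d} {0.0:11.6f} {0.0:11.6f} {s:11.6f}")
    if molecule is not None:
        pt_nums = {sym: i for i, sym in enumerate(
            ["X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne"])}
        from rdkit import Chem as _Chem
        pt = _Chem.GetPeriodicTable()
        for sym, xyz in zip(molecule.symbols, molecule.coords):
            z = pt.GetAtomicNumber(sym) if sym not in pt_nums else pt_nums[sym]
            c = xyz * b
            lines.append(f"{z:5d} {0.0:11.6f} {c[0]:11.6f} {c[1]:11.6f} {c[2]:11.6f}")
    flat = values  # already z-fastest
    for start in range(0, flat.size, 6):
        chunk = flat[start:start + 6]
        lines.append(" ".join(f"{v:13.5e}" for v in chunk))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path: Union[str, Path]) -> Tuple[Grid, np.ndarray]:
    """Read back a cube file written by :func:`write_cube` (orthogonal axes)."""
    text = Path(path).read_text().splitlines()
    natoms = int(text[2].split()[0])
    origin = np.array([float(v) for v in text[2].split()[1:4]]) / BOHR_PER_ANGSTROM
    dims, spacing = [], None
    for i in range(3):
        parts = text[3 + i].split()
        dims.append(int(parts[0]))
        vec = np.array([float(v) for v in parts[1:4]]) / BOHR_PER_ANGSTROM
        step = float(np.linalg.norm(vec))
        if spacing is None:
            spacing = step
    data_lines = text[6 + abs(natoms):]
    flat = np.array([float(v) for line in data_lines for v in line.split()])
    grid = Grid(origin=tuple(origin), spacing=spacing, dims=tuple(dims))
    return grid, flat
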