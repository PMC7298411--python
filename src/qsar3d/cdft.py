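"""Conceptual-DFT global and local reactivity descriptors.

Global descriptors are finite-difference approximations of the energy
derivatives with respect to electron number at fixed external potential,
evaluated from frontier orbital energies through Koopmans' theorem
(I = −E_HOMO, A = −E_LUMO):

    μ = −(I + A)/2      chemical potential (χ = −μ, electronegativity)
    η = I − A           hardness
    S = 1/η             softness
    ω = μ²/(2η)         electrophilicity index

Local reactivity is the condensed Fukui function, the finite difference
of per-atom electron populations between the N- and (N±1)-electron
states: f⁺(k) = q_k(N+1) − q_k(N) marks susceptibility to nucleophilic
attack, f⁻(k) = q_k(N) − q_k(N−1) to electrophilic attack. q_k here is
an electron *population* (as from natural population analysis); if NPA
partial charges are supplied instead, set ``populations_are_charges`` and
the differences are negated, since the two conventions flip sign.

All energies are in eV internally; hartree inputs are converted at parse
time. Quantum-chemistry runs themselves are out of scope — this module
consumes their outputs (a native JSON schema or a Gaussian-style text
log).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HARTREE_TO_EV = 27.211386


@dataclass
class OrbitalData:
    """Frontier orbital energies plus optional N/N±1 electron populations (eV)."""

    compound_id: str
    e_homo: float
    e_lumo: float
    populations_N: Optional[np.ndarray] = None
    populations_Nplus1: Optional[np.ndarray] = None
    populations_Nminus1: Optional[np.ndarray] = None
    atom_labels: Optional[List[str]] = None
    populations_are_charges: bool = False

    def __post_init__(self):
        if not (np.isfinite(self.e_homo) and np.isfinite(self.e_lumo)):
            raise ValueError(f"{self.compound_id}: non-finite orbital energies")
        if self.e_lumo < self.e_homo:
            raise ValueError(f"{self.compound_id}: E_LUMO below E_HOMO")
        pops = {
            "populations_N": self.populations_N,
            "populations_Nplus1": self.populations_Nplus1,
            "populations_Nminus1": self.populations_Nminus1,
        }
        lengths = set()
        for name, p in pops.items():
            if p is not None:
                arr = np.asarray(p, dtype=float)
                setattr(self, name, arr)
                lengths.add(arr.size)
        if len(lengths) > 1:
            raise ValueError(f"{self.compound_id}: population vectors differ in length")

    @property
    def has_fukui_data(self) -> bool:
        return (
            self.populations_N is not None
            and self.populations_Nplus1 is not None
            and self.populations_Nminus1 is not None
        )

    def conserves_electrons(self, tol: float = 1e-3) -> bool:
        """Σq(N+1) − Σq(N) = 1 and Σq(N) − Σq(N−1) = 1 within tolerance."""
        if not self.has_fukui_data:
            return False
        sign = -1.0 if self.populations_are_charges else 1.0
        up = sign * (self.populations_Nplus1.sum() - self.populations_N.sum())
        down = sign * (self.populations_N.sum() - self.populations_Nminus1.sum())
        return abs(up - 1.0) <= tol and abs(down - 1.0) <= tol


@dataclass
class ReactivityDescriptors:
    """Global (and optionally local) reactivity descriptors of one compound."""

    ionization_potential: float
    electron_affinity: float
    chemical_potential: float
    electronegativity: float
    hardness: float
    softness: float
    electrophilicity: float
    compound_id: str = ""
    fukui_plus: Optional[np.ndarray] = None
    fukui_minus: Optional[np.ndarray] = None


def koopmans_ia(e_homo: float, e_lumo: float) -> Tuple[float, float]:
    """Koopmans' theorem: I = −E_HOMO, A = −E_LUMO (energies in eV)."""
    if not (np.isfinite(e_homo) and np.isfinite(e_lumo)):
        raise ValueError("orbital energies must be finite")
    return -float(e_homo), -float(e_lumo)


def global_descriptors(
    ionization_potential: float,
    electron_affinity: float,
    compound_id: str = "",
) -> ReactivityDescriptors:
    """μ, χ, η, S, ω from I and A (finite-difference forms)."""
    I, A = float(ionization_potential), float(electron_affinity)
    mu = -(I + A) / 2.0
    eta = I - A
    if eta == 0:
        raise ZeroDivisionError("hardness is zero: softness and ω undefined")
    return ReactivityDescriptors(
        ionization_potential=I,
        electron_affinity=A,
        chemical_potential=mu,
        electronegativity=-mu,
        hardness=eta,
        softness=1.0 / eta,
        electrophilicity=mu * mu / (2.0 * eta),
        compound_id=compound_id,
    )


def descriptors_from_orbitals(data: OrbitalData) -> ReactivityDescriptors:
    I, A = koopmans_ia(data.e_homo, data.e_lumo)
    desc = global_descriptors(I, A, compound_id=data.compound_id)
    if data.has_fukui_data:
        desc.fukui_plus, desc.fukui_minus = fukui_functions(data)
    return desc


def descriptors_from_mu_eta(
    mu: float, eta: float, compound_id: str = ""
) -> ReactivityDescriptors:
    """Descriptors from (μ, η) directly — I = −μ + η/2, A = −μ − η/2."""
    return global_descriptors(-mu + eta / 2.0, -mu - eta / 2.0, compound_id)


def orbital_energies_from_mu_eta(mu: float, eta: float) -> Tuple[float, float]:
    """Invert the finite-difference forms: (E_HOMO, E_LUMO) = (μ − η/2, μ + η/2)."""
    return mu - eta / 2.0, mu + eta / 2.0


def fukui_functions(data: OrbitalData) -> Tuple[np.ndarray, np.ndarray]:
    """Condensed Fukui functions (f⁺, f⁻) per atom.

    f⁺(k) = q_k(N+1) − q_k(N), f⁻(k) = q_k(N) − q_k(N−1), with both
    differences negated when the populations are NPA charges.
    """
    missing = [
        name
        for name, p in (
            ("populations_N", data.populations_N),
            ("populations_Nplus1", data.populations_Nplus1),
            ("populations_Nminus1", data.populations_Nminus1),
        )
        if p is None
    ]
    if missing:
        raise ValueError(f"{data.compound_id}: missing {', '.join(missing)}")
    sign = -1.0 if data.populations_are_charges else 1.0
    f_plus = sign * (data.populations_Nplus1 - data.populations_N)
    f_minus = sign * (data.populations_N - data.populations_Nminus1)
    return f_plus, f_minus


def attack_sites(data: OrbitalData) -> Dict[str, int]:
    """Preferred attack sites: argmax f⁺ (nucleophilic), argmax f⁻ (electrophilic)."""
    f_plus, f_minus = fukui_functions(data)
    return {
        "nucleophilic": int(np.argmax(f_plus)),
        "electrophilic": int(np.argmax(f_minus)),
    }


# ---------------------------------------------------------------------------
# parsing


def parse_orbital_file(
    path: Union[str, Path], format: str = "native-json"
) -> OrbitalData:
    """Read orbital/population data from the native JSON schema or a QM text log.

    The JSON schema accepts energies in eV (``e_homo_eV``) or hartree
    (``e_homo_hartree``); hartree values are converted with
    1 Eh = 27.211386 eV. The qm-log adapter understands Gaussian-style
    orbital eigenvalue lines and the natural-population summary block.
    """
    path = Path(path)
    if format == "native-json":
        return _parse_native_json(path)
    if format == "qm-log":
        return _parse_qm_log(path)
    raise ValueError(f"unknown orbital file format: {format!r}")


def _parse_native_json(path: Path) -> OrbitalData:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON ({exc})") from exc

    def energy(key: str) -> float:
        if f"{key}_eV" in doc:
            return float(doc[f"{key}_eV"])
        if f"{key}_hartree" in doc:
            return float(doc[f"{key}_hartree"]) * HARTREE_TO_EV
        raise ValueError(f"{path}: missing {key}")

    pops = doc.get("populations", {}) or {}

    def pop(key: str):
        return np.asarray(pops[key], dtype=float) if key in pops else None

    return OrbitalData(
        compound_id=str(doc.get("compound_id", path.stem)),
        e_homo=energy("e_homo"),
        e_lumo=energy("e_lumo"),
        populations_N=pop("N"),
        populations_Nplus1=pop("N_plus_1"),
        populations_Nminus1=pop("N_minus_1"),
        atom_labels=doc.get("atom_labels"),
        populations_are_charges=bool(doc.get("populations_are_charges", False)),
    )


_OCC_RE = re.compile(r"Alpha\s+occ\. eigenvalues\s*--\s*(.*)")
_VIRT_RE = re.compile(r"Alpha\s*virt\. eigenvalues\s*--\s*(.*)")


def _parse_qm_log(path: Path) -> OrbitalData:
    """Minimal adapter for Gaussian-style logs: eigenvalues + NPA summary."""
    occ: List[float] = []
    virt: List[float] = []
    pops: List[float] = []
    labels: List[str] = []
    in_npa = False
    for line in path.read_text().splitlines():
        m = _OCC_RE.search(line)
        if m:
            occ.extend(float(v) for v in m.group(1).split())
            continue
        m = _VIRT_RE.search(line)
        if m:
            virt.extend(float(v) for v in m.group(1).split())
            continue
        if "Summary of Natural Population Analysis" in line:
            in_npa = True
            pops, labels = [], []
            continue
        if in_npa:
            stripped = line.strip()
            if stripped.startswith("=") or stripped.startswith("* Total"):
                in_npa = False
                continue
            parts = stripped.split()
            # "  C  1  -0.123  2.0  3.9  0.01  6.123" → symbol, index, charge,
            # core, valence, rydberg, total population
            if len(parts) >= 7 and parts[1].isdigit():
                labels.append(parts[0] + parts[1])
                pops.append(float(parts[-1]))
    if not occ or not virt:
        raise ValueError(f"{path}: could not locate HOMO/LUMO eigenvalues")
    return OrbitalData(
        compound_id=path.stem,
        e_homo=max(occ) * HARTREE_TO_EV,
        e_lumo=min(virt) * HARTREE_TO_EV,
        populations_N=np.asarray(pops) if pops else None,
        atom_labels=labels or None,
    )


# ---------------------------------------------------------------------------
# reporting


def descriptor_table(
    data: Sequence[Union[OrbitalData, ReactivityDescriptors]],
    decimals: int = 4,
) -> pd.DataFrame:
    """One row per compound with μ, η, S, ω rounded to ``decimals`` places.

    Rounding is round-half-even on the full-precision values; the row with
    the largest electrophilicity is flagged in ``max_omega``.
    """
    if len(data) == 0:
        raise ValueError("no records")
    descs = [
        d if isinstance(d, ReactivityDescriptors) else descriptors_from_orbitals(d)
        for d in data
    ]
    df = pd.DataFrame(
        {
            "Compound": [d.compound_id for d in descs],
            "C. Potential (mu)": np.round([d.chemical_potential for d in descs], decimals),
            "Hardness (eta)": np.round([d.hardness for d in descs], decimals),
            "Softness (S = 1/eta)": np.round([d.softness for d in descs], decimals),
            "Electrophilicity (omega)": np.round([d.electrophilicity for d in descs], decimals),
        }
    )
    omegas = np.array([d.electrophilicity for d in descs])
    df["max_omega"] = False
    df.loc[int(np.argmax(omegas)), "max_omega"] = True
    return df


def fukui_table(data: OrbitalData) -> pd.DataFrame:
    """Per-atom f⁺/f⁻ with the preferred attack sites flagged."""
    f_plus, f_minus = fukui_functions(data)
    labels = data.atom_labels or [f"atom{i}" for i in range(f_plus.size)]
    sites = attack_sites(data)
    df = pd.DataFrame({"atom": labels, "f_plus": f_plus, "f_minus": f_minus})
    df["nucleophilic_site"] = [i == sites["nucleophilic"] for i in range(len(df))]
    df["electrophilic_site"] = [i == sites["electrophilic"] for i in range(len(df))]
    return df
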