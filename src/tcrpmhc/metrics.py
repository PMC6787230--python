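"""Model quality metrics against a native structure.

All superpositions are least-squares optimal rigid fits (Kabsch, via SVD
with a proper-rotation constraint).  Residues are paired between model
and native by (role, dense residue index); anything lacking the required
atoms on either side is excluded from the pairing.

Metrics
-------
* Component Cα RMSD — superpose on a component's Cα pairs (full complex,
  TCR, pMHC, or peptide) and report the RMSD over those same pairs.
* TM-score — after the single global Cα superposition,
  ``TM = (1/L_N) Σ 1/(1 + (d_i/d0)²)`` with ``L_N`` the native residue
  count and ``d0 = max(1.24·(L_N−15)^⅓ − 1.8, 0.5)`` (Zhang & Skolnick's
  normalization); unpaired native residues contribute 0.
* DockQ — the CAPRI-standard interface quality score combining Fnat
  (fraction of native interface contacts recovered, 5 Å heavy-atom
  cutoff), LRMS (ligand backbone RMSD after receptor-only superposition)
  and iRMS (backbone RMSD over native interface residues, 10 Å cutoff):
  ``DockQ = (Fnat + 1/(1+(iRMS/1.5)²) + 1/(1+(LRMS/8.5)²)) / 3`` (Basu &
  Wallner's constants), classed Incorrect < 0.23 ≤ Acceptable < 0.49 ≤
  Medium < 0.80 ≤ High.

The receptor is the pMHC (MHC + peptide) and the ligand is the TCR,
following the docking convention for this complex.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core import (
    ComplexStructure,
    GeometryError,
    InputError,
    PairingError,
    Role,
    UndefinedInterfaceError,
)

__all__ = [
    "BACKBONE_ATOMS",
    "FNAT_CUTOFF",
    "INTERFACE_CUTOFF",
    "DOCKQ_IRMS_SCALE",
    "DOCKQ_LRMS_SCALE",
    "Component",
    "DockQClass",
    "Superposition",
    "ComponentRMSDReport",
    "DockQReport",
    "map_common_residues",
    "kabsch",
    "component_rmsd",
    "subset_rmsd",
    "tm_score",
    "tm_d0",
    "interface_contacts",
    "fnat",
    "lrms",
    "irms",
    "dockq",
    "dockq_class",
    "dockq_report",
    "evaluate_model",
]

#: backbone atom names used for LRMS / iRMS
BACKBONE_ATOMS = ("N", "CA", "C", "O")
#: heavy-atom distance defining a native interface contact (CAPRI convention)
FNAT_CUTOFF = 5.0
#: heavy-atom distance defining interface residues for iRMS (CAPRI convention)
INTERFACE_CUTOFF = 10.0
#: DockQ RMSD scaling constants (Basu & Wallner)
DOCKQ_IRMS_SCALE = 1.5
DOCKQ_LRMS_SCALE = 8.5

#: roles forming the docking receptor and ligand
RECEPTOR_ROLES = (Role.MHC, Role.PEPTIDE)
LIGAND_ROLES = (Role.TCRA, Role.TCRB)


class Component(str, enum.Enum):
    """A structural component over which an RMSD is reported."""

    TCRPMHC = "TCRPMHC"
    TCR = "TCR"
    PMHC = "PMHC"
    PEPTIDE = "PEPTIDE"

    @property
    def roles(self) -> tuple[Role, ...]:
        return {
            Component.TCRPMHC: (Role.MHC, Role.PEPTIDE, Role.TCRA, Role.TCRB),
            Component.TCR: (Role.TCRA, Role.TCRB),
            Component.PMHC: (Role.MHC, Role.PEPTIDE),
            Component.PEPTIDE: (Role.PEPTIDE,),
        }[self]


class DockQClass(str, enum.Enum):
    INCORRECT = "Incorrect"
    ACCEPTABLE = "Acceptable"
    MEDIUM = "Medium"
    HIGH = "High"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class Superposition:
    """Optimal rigid map ``x -> R (x - com_mobile) + com_ref``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ComponentRMSDReport:
    tcr_pmhc: float
    tcr: float
    pmhc: float
    peptide: float

    def as_dict(self) -> dict[str, float]:
        return {
            "tcr_pmhc_rmsd": self.tcr_pmhc,
            "tcr_rmsd": self.tcr,
            "pmhc_rmsd": self.pmhc,
            "peptide_rmsd": self.peptide,
        }


@dataclass
class DockQReport:
    fnat: float
    lrms: float
    irms: float
    dockq: float
    quality: DockQClass

    def as_dict(self) -> dict[str, float | str]:
        return {
            "fnat": self.fnat,
            "lrms": self.lrms,
            "irms": self.irms,
            "dockq": self.dockq,
            "quality": str(self.quality),
        }


# ---------------------------------------------------------------------------
# Pairing and superposition
# ---------------------------------------------------------------------------

def map_common_residues(
    model: ComplexStructure,
    native: ComplexStructure,
    roles: Sequence[Role] | None = None,
    atoms: Sequence[str] = ("CA",),
) -> tuple[np.ndarray, np.ndarray]:
    """Paired coordinate arrays over residues common to model and native.

    Residues are matched by (role, dense index), ordered role-major then
    by index; a residue pair contributes each requested atom both sides
    possess.  Raises :class:`PairingError` when nothing pairs.
    """
    if roles is None:
        roles = [r for r in model.roles if r in native.chains]
    xs, ys = [], []
    for role in roles:
        mchain = model.chains.get(role)
        nchain = native.chains.get(role)
        if mchain is None or nchain is None:
            raise PairingError(f"role {role} absent from model or native")
        n_shared = min(len(mchain), len(nchain))
        for idx in range(n_shared):
            mres, nres = mchain.residues[idx], nchain.residues[idx]
            for atom in atoms:
                if atom in mres.atoms and atom in nres.atoms:
                    xs.append(mres.atoms[atom])
                    ys.append(nres.atoms[atom])
    if not xs:
        raise PairingError("no common residues between model and native")
    return np.vstack(xs), np.vstack(ys)


def kabsch(coords_mobile: np.ndarray, coords_ref: np.ndarray) -> Superposition:
    """Least-squares optimal rigid superposition (proper rotation only).

    Returns the transform that moves ``coords_mobile`` onto
    ``coords_ref`` and the post-fit RMSD.
    """
    A = np.asarray(coords_mobile, dtype=float)
    B = np.asarray(coords_ref, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise GeometryError("coordinate arrays must both be (n, 3)")
    n = A.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 atom pairs")
    com_a, com_b = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - com_a, B - com_b
    H = Ac.T @ Bc
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10:  # rank < 2: collinear or coincident points
        raise GeometryError("degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = Ac @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Bc) ** 2, axis=1))))
    return Superposition(
        rotation=R,
        translation=com_b - R @ com_a,
        rmsd=rmsd,
        n_atoms=n,
    )


def component_rmsd(
    model: ComplexStructure,
    native: ComplexStructure,
    component: Component | str,
) -> float:
    """Cα RMSD after superposing on the component's own residues."""
    component = Component(component)
    coords_m, coords_n = map_common_residues(
        model, native, roles=component.roles
    )
    return kabsch(coords_m, coords_n).rmsd


def subset_rmsd(
    model: ComplexStructure,
    native: ComplexStructure,
    residues: Iterable[tuple[Role, int]],
    atoms: Sequence[str] = ("CA",),
) -> float:
    """RMSD over an arbitrary residue subset (e.g. a loop definition).

    ``residues`` is an iterable of (role, dense index) pairs; the subset
    is superposed on itself before the RMSD is taken.
    """
    wanted = set(residues)
    xs, ys = [], []
    for role, idx in sorted(wanted, key=lambda t: (t[0].value, t[1])):
        mchain = model.chains.get(role)
        nchain = native.chains.get(role)
        if mchain is None or nchain is None:
            continue
        if idx >= len(mchain) or idx >= len(nchain):
            continue
        mres, nres = mchain.residues[idx], nchain.residues[idx]
        for atom in atoms:
            if atom in mres.atoms and atom in nres.atoms:
                xs.append(mres.atoms[atom])
                ys.append(nres.atoms[atom])
    if not xs:
        raise PairingError("residue subset pairs no atoms")
    return kabsch(np.vstack(xs), np.vstack(ys)).rmsd


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------

def tm_d0(normalization_length: int) -> float:
    """Zhang-Skolnick d0 with a 0.5 Å floor."""
    if normalization_length < 1:
        raise InputError("normalization length must be positive")
    return max(1.24 * (normalization_length - 15) ** (1.0 / 3.0) - 1.8, 0.5) \
        if normalization_length > 15 else 0.5


def tm_score(
    model: ComplexStructure,
    native: ComplexStructure,
    d0: float | None = None,
) -> float:
    """TM-score over all Cα atoms after the global superposition.

    Normalized by the native residue count; native residues with no
    counterpart in the model contribute zero.
    """
    coords_m, coords_n = map_common_residues(model, native)
    sup = kabsch(coords_m, coords_n)
    L_native = sum(
        1
        for chain in native.chains.values()
        for res in chain
        if res.ca is not None
    )
    if d0 is None:
        d0 = tm_d0(L_native)
    d = np.linalg.norm(sup.apply(coords_m) - coords_n, axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_native)


# ---------------------------------------------------------------------------
# Interface metrics (Fnat / LRMS / iRMS / DockQ)
# ---------------------------------------------------------------------------

def _heavy_atoms(res) -> list[np.ndarray]:
    return [
        xyz
        for name, xyz in res.atoms.items()
        if not name.strip().startswith("H")
    ]


def _side_atoms(
    complex_: ComplexStructure, roles: Sequence[Role]
) -> tuple[list[tuple[Role, int]], np.ndarray, np.ndarray]:
    """Residue keys, stacked heavy-atom coords, and per-atom residue index."""
    keys: list[tuple[Role, int]] = []
    coords: list[np.ndarray] = []
    owner: list[int] = []
    for role in roles:
        chain = complex_.chains.get(role)
        if chain is None:
            continue
        for res in chain:
            atoms = _heavy_atoms(res)
            if not atoms:
                continue
            keys.append((role, res.seq_index))
            idx = len(keys) - 1
            coords.extend(atoms)
            owner.extend([idx] * len(atoms))
    if not coords:
        return keys, np.zeros((0, 3)), np.zeros(0, dtype=int)
    return keys, np.vstack(coords), np.asarray(owner, dtype=int)


def interface_contacts(
    complex_: ComplexStructure,
    cutoff: float = FNAT_CUTOFF,
) -> set[tuple[tuple[Role, int], tuple[Role, int]]]:
    """(pMHC residue, TCR residue) pairs with heavy atoms within cutoff.

    The boundary is inclusive: a closest-approach of exactly ``cutoff``
    counts as a contact.
    """
    rkeys, rcoords, rowner = _side_atoms(complex_, RECEPTOR_ROLES)
    lkeys, lcoords, lowner = _side_atoms(complex_, LIGAND_ROLES)
    contacts: set[tuple[tuple[Role, int], tuple[Role, int]]] = set()
    if len(rcoords) == 0 or len(lcoords) == 0:
        return contacts
    close = cdist(rcoords, lcoords) <= cutoff
    for i, j in zip(*np.nonzero(close)):
        contacts.add((rkeys[rowner[i]], lkeys[lowner[j]]))
    return contacts


def fnat(
    model: ComplexStructure,
    native: ComplexStructure,
    cutoff: float = FNAT_CUTOFF,
) -> float:
    """Fraction of native interface contacts present in the model."""
    native_contacts = interface_contacts(native, cutoff)
    if not native_contacts:
        raise UndefinedInterfaceError(
            "native structure has no interface contacts"
        )
    model_contacts = interface_contacts(model, cutoff)
    return len(model_contacts & native_contacts) / len(native_contacts)


def lrms(model: ComplexStructure, native: ComplexStructure) -> float:
    """Ligand (TCR) backbone RMSD after receptor-only superposition."""
    rec_m, rec_n = map_common_residues(
        model, native, roles=list(RECEPTOR_ROLES), atoms=BACKBONE_ATOMS
    )
    sup = kabsch(rec_m, rec_n)
    lig_m, lig_n = map_common_residues(
        model, native, roles=list(LIGAND_ROLES), atoms=BACKBONE_ATOMS
    )
    moved = sup.apply(lig_m)
    return float(np.sqrt(np.mean(np.sum((moved - lig_n) ** 2, axis=1))))


def _native_interface_residues(
    native: ComplexStructure, cutoff: float
) -> set[tuple[Role, int]]:
    rkeys, rcoords, rowner = _side_atoms(native, RECEPTOR_ROLES)
    lkeys, lcoords, lowner = _side_atoms(native, LIGAND_ROLES)
    residues: set[tuple[Role, int]] = set()
    if len(rcoords) == 0 or len(lcoords) == 0:
        return residues
    close = cdist(rcoords, lcoords) <= cutoff
    ri, lj = np.nonzero(close)
    for i in np.unique(rowner[ri]):
        residues.add(rkeys[i])
    for j in np.unique(lowner[lj]):
        residues.add(lkeys[j])
    return residues


def irms(
    model: ComplexStructure,
    native: ComplexStructure,
    interface_cutoff: float = INTERFACE_CUTOFF,
) -> float:
    """Backbone RMSD over native interface residues after their own fit.

    Interface residues are defined on the native structure: any residue
    of either side with a heavy atom within ``interface_cutoff`` of the
    other side.
    """
    residues = _native_interface_residues(native, interface_cutoff)
    if not residues:
        raise UndefinedInterfaceError("native structure has no interface")
    xs, ys = [], []
    for role, idx in sorted(residues, key=lambda t: (t[0].value, t[1])):
        mchain = model.chains.get(role)
        nchain = native.chains.get(role)
        if mchain is None or nchain is None or idx >= len(mchain):
            continue
        mres, nres = mchain.residues[idx], nchain.residues[idx]
        for atom in BACKBONE_ATOMS:
            if atom in mres.atoms and atom in nres.atoms:
                xs.append(mres.atoms[atom])
                ys.append(nres.atoms[atom])
    if not xs:
        raise PairingError("no backbone atoms pair over the interface")
    return kabsch(np.vstack(xs), np.vstack(ys)).rmsd


def dockq(
    fnat_value: float,
    lrms_value: float,
    irms_value: float,
    irms_scale: float = DOCKQ_IRMS_SCALE,
    lrms_scale: float = DOCKQ_LRMS_SCALE,
) -> tuple[float, DockQClass]:
    """Combine Fnat, LRMS and iRMS into the DockQ score and class."""
    if lrms_value < 0 or irms_value < 0:
        raise InputError("RMSD inputs must be non-negative")
    if not 0.0 <= fnat_value <= 1.0:
        raise InputError("fnat must be in [0, 1]")
    score = (
        fnat_value
        + 1.0 / (1.0 + (irms_value / irms_scale) ** 2)
        + 1.0 / (1.0 + (lrms_value / lrms_scale) ** 2)
    ) / 3.0
    return score, dockq_class(score)


def dockq_class(score: float) -> DockQClass:
    """Quality class from a DockQ score: boundaries 0.23 / 0.49 / 0.80,
    each lower-inclusive for the class above it."""
    if not 0.0 <= score <= 1.0:
        raise InputError("DockQ score must be in [0, 1]")
    if score < 0.23:
        return DockQClass.INCORRECT
    if score < 0.49:
        return DockQClass.ACCEPTABLE
    if score < 0.80:
        return DockQClass.MEDIUM
    return DockQClass.HIGH


def dockq_report(
    model: ComplexStructure,
    native: ComplexStructure,
    fnat_cutoff: float = FNAT_CUTOFF,
    interface_cutoff: float = INTERFACE_CUTOFF,
) -> DockQReport:
    """Full interface quality report for a model-vs-native pair."""
    f = fnat(model, native, fnat_cutoff)
    l = lrms(model, native)
    i = irms(model, native, interface_cutoff)
    score, quality = dockq(f, l, i)
    return DockQReport(fnat=f, lrms=l, irms=i, dockq=score, quality=quality)


def evaluate_model(
    model: ComplexStructure,
    native: ComplexStructure,
    include_dockq: bool | None = None,
) -> dict:
    """Component RMSDs, TM-score, and (for full complexes) DockQ."""
    roles = set(model.roles) & set(native.roles)
    has_tcr = Role.TCRA in roles and Role.TCRB in roles
    has_pmhc = Role.MHC in roles and Role.PEPTIDE in roles
    out: dict = {}
    if has_pmhc:
        out["pmhc_rmsd"] = component_rmsd(model, native, Component.PMHC)
        out["peptide_rmsd"] = component_rmsd(model, native, Component.PEPTIDE)
    if has_tcr:
        out["tcr_rmsd"] = component_rmsd(model, native, Component.TCR)
    if has_tcr and has_pmhc:
        out["tcr_pmhc_rmsd"] = component_rmsd(model, native, Component.TCRPMHC)
    out["tm_score"] = tm_score(model, native)
    if include_dockq is None:
        include_dockq = has_tcr and has_pmhc
    if include_dockq:
        out.update(dockq_report(model, native).as_dict())
    return out
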