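"""Core domain types for TCR-pMHC comparative modelling.

A complex is decomposed into up to four role-typed chains: the MHC class I
heavy chain (restricted to the groove-forming α1-α2 region), the bound
peptide (8-11 residues), and the TCR α and β chains.  Internally residues
are indexed densely from 0 within each chain; author numbering from the
source coordinate file is carried along as metadata only, so alignment and
superposition math never has to reason about insertion codes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "Role",
    "Kind",
    "Residue",
    "Chain",
    "ComplexStructure",
    "TcrPmhcError",
    "FormatError",
    "MappingError",
    "KindError",
    "InputError",
    "AlignmentError",
    "NoTemplateError",
    "InsufficientTemplateError",
    "BackendError",
    "ContractError",
    "PairingError",
    "GeometryError",
    "UndefinedInterfaceError",
    "InsufficientDataError",
    "AA3_TO_1",
    "AA1_TO_3",
    "AMINO_ACIDS",
    "PEPTIDE_LENGTH_RANGE",
    "seq1",
    "seq3",
]

#: inclusive range of peptide lengths the modelling machinery accepts;
#: class I grooves accommodate 8-11mers and templates outside this range
#: do not exist in a length-matched form.
PEPTIDE_LENGTH_RANGE = (8, 11)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


def seq1(name3: str) -> str:
    """3-letter residue name to 1-letter code; unknown names become 'X'."""
    return AA3_TO_1.get(name3.upper(), "X")


def seq3(code1: str) -> str:
    """1-letter code to 3-letter residue name; 'X' maps to UNK."""
    return AA1_TO_3.get(code1.upper(), "UNK")


class TcrPmhcError(Exception):
    """Base class for all package errors."""


class FormatError(TcrPmhcError):
    """Unparseable structure or sequence text."""


class MappingError(TcrPmhcError):
    """A role map references a chain absent from the file."""


class KindError(TcrPmhcError):
    """A structure kind's required roles are not all present."""


class InputError(TcrPmhcError):
    """Invalid user-supplied input (sequences, MSAs, parameters)."""


class AlignmentError(TcrPmhcError):
    """Profile alignment failed or alignments live in different spaces."""


class NoTemplateError(TcrPmhcError):
    """No candidate template survives filtering for a target."""


class InsufficientTemplateError(TcrPmhcError):
    """Selected templates cover too little of the target to build from."""


class BackendError(TcrPmhcError):
    """An external model-building backend failed."""


class ContractError(TcrPmhcError):
    """A backend returned a structure violating the stage contract."""


class PairingError(TcrPmhcError):
    """No common residues between model and native."""


class GeometryError(TcrPmhcError):
    """Too few or degenerate points for superposition."""


class UndefinedInterfaceError(TcrPmhcError):
    """The native structure has no interface contacts to compare against."""


class InsufficientDataError(TcrPmhcError):
    """Too few paired observations for a statistical comparison."""


class Role(str, enum.Enum):
    """Chain role within a TCR-pMHC complex."""

    MHC = "MHC"
    PEPTIDE = "PEPTIDE"
    TCRA = "TCRA"
    TCRB = "TCRB"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: deterministic chain order used everywhere a complex is serialized
ROLE_ORDER = (Role.MHC, Role.PEPTIDE, Role.TCRA, Role.TCRB)


class Kind(str, enum.Enum):
    """Structure kind: which subunits a complex contains."""

    PMHC = "PMHC"
    TCR = "TCR"
    TCRPMHC = "TCRPMHC"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def required_roles(self) -> tuple[Role, ...]:
        return KIND_ROLES[self]


KIND_ROLES: dict[Kind, tuple[Role, ...]] = {
    Kind.PMHC: (Role.MHC, Role.PEPTIDE),
    Kind.TCR: (Role.TCRA, Role.TCRB),
    Kind.TCRPMHC: (Role.MHC, Role.PEPTIDE, Role.TCRA, Role.TCRB),
}


@dataclass
class Residue:
    """One residue: 3-letter name, dense index, author numbering, atoms.

    ``atoms`` maps atom name (e.g. "CA", "N") to a 3-vector in Å.
    """

    name: str
    seq_index: int
    author_number: int
    insertion_code: str = ""
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def ca(self) -> np.ndarray | None:
        return self.atoms.get("CA")

    @property
    def code1(self) -> str:
        return seq1(self.name)

    def copy(self) -> "Residue":
        return Residue(
            name=self.name,
            seq_index=self.seq_index,
            author_number=self.author_number,
            insertion_code=self.insertion_code,
            atoms={k: v.copy() for k, v in self.atoms.items()},
        )

    def validate(self) -> None:
        for name, xyz in self.atoms.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise FormatError(
                    f"atom {name!r} of residue {self.name}{self.author_number} "
                    "has a non-finite or malformed coordinate"
                )


@dataclass
class Chain:
    """An ordered run of residues with a single role.

    ``n_missing_residues`` counts residues declared in the source (SEQRES)
    or present without a Cα atom — i.e. positions that cannot serve as
    modelling coordinates.
    """

    chain_id: str
    role: Role
    residues: list[Residue] = field(default_factory=list)
    n_missing_residues: int = 0

    @property
    def sequence(self) -> str:
        return "".join(r.code1 for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def copy(self) -> "Chain":
        return Chain(
            chain_id=self.chain_id,
            role=self.role,
            residues=[r.copy() for r in self.residues],
            n_missing_residues=self.n_missing_residues,
        )

    def reindex(self) -> None:
        """Make seq_index dense 0..n-1 in storage order."""
        for i, res in enumerate(self.residues):
            res.seq_index = i

    def ca_array(self) -> np.ndarray:
        """(n, 3) array of Cα coordinates for residues that have one."""
        cas = [r.ca for r in self.residues if r.ca is not None]
        if not cas:
            return np.zeros((0, 3))
        return np.vstack(cas)

    def validate(self) -> None:
        for i, res in enumerate(self.residues):
            if res.seq_index != i:
                raise FormatError(
                    f"chain {self.chain_id}: seq_index not dense at {i}"
                )
            res.validate()


@dataclass
class ComplexStructure:
    """A role-typed multi-chain structure (pMHC, TCR, or full complex)."""

    id: str
    kind: Kind
    chains: dict[Role, Chain] = field(default_factory=dict)
    resolution: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate_kind()

    def validate_kind(self) -> None:
        missing = [r for r in self.kind.required_roles if r not in self.chains]
        if missing:
            raise KindError(
                f"structure {self.id!r} of kind {self.kind} lacks role(s): "
                + ", ".join(str(m) for m in missing)
            )

    @property
    def roles(self) -> tuple[Role, ...]:
        return tuple(r for r in ROLE_ORDER if r in self.chains)

    def chain(self, role: Role) -> Chain:
        return self.chains[role]

    @property
    def peptide_length(self) -> int | None:
        pep = self.chains.get(Role.PEPTIDE)
        return len(pep) if pep is not None else None

    def sequences(self) -> dict[Role, str]:
        return {role: self.chains[role].sequence for role in self.roles}

    def copy(self, new_id: str | None = None) -> "ComplexStructure":
        return ComplexStructure(
            id=new_id if new_id is not None else self.id,
            kind=self.kind,
            chains={r: c.copy() for r, c in self.chains.items()},
            resolution=self.resolution,
            provenance=self.provenance,
        )

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> None:
        """Apply ``x -> R x + t`` to every atom, in place."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for chain in self.chains.values():
            for res in chain:
                for name in res.atoms:
                    res.atoms[name] = R @ res.atoms[name] + t

    def validate(self) -> None:
        self.validate_kind()
        for role, chain in self.chains.items():
            if chain.role != role:
                raise KindError(
                    f"chain {chain.chain_id} stored under role {role} "
                    f"but typed {chain.role}"
                )
            chain.validate()
        if self.resolution is not None and not math.isfinite(self.resolution):
            raise FormatError(f"structure {self.id}: non-finite resolution")


def concatenated_sequence(sequences: Mapping[Role, str]) -> str:
    """Chain sequences joined in the fixed role order (used for dedup)."""
    return "/".join(sequences[r] for r in ROLE_ORDER if r in sequences)
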