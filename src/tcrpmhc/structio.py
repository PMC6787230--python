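"""Structure and sequence I/O.

PDB parsing and writing is delegated to :mod:`gemmi`; this module adds the
role typing layer (which chain is the MHC, the peptide, the TCR α / β) and
the dense internal residue indexing the rest of the package relies on.

Conventions
-----------
* Only the first model of a multi-model file is read; alternate locations
  other than blank/"A" are discarded.
* A residue without a Cα atom cannot anchor modelling and is dropped from
  the chain but counted in ``Chain.n_missing_residues``, together with
  SEQRES-declared residues that have no coordinates at all.
* Written files list chains in the fixed order MHC, PEPTIDE, TCRA, TCRB so
  output is deterministic regardless of input order.

FASTA records use role-tagged headers ``>id|ROLE`` with ROLE one of
MHC, PEPTIDE, TCRA, TCRB.
"""

from __future__ import annotations

import io
from typing import TYPE_CHECKING, Mapping

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    ROLE_ORDER,
    Chain,
    ComplexStructure,
    FormatError,
    InputError,
    Kind,
    KindError,
    MappingError,
    PEPTIDE_LENGTH_RANGE,
    Residue,
    Role,
)

if TYPE_CHECKING:  # pragma: no cover
    from .profiles import SequenceProfile

__all__ = [
    "parse_structure",
    "extract_sequences",
    "write_structure",
    "read_fasta",
    "write_fasta",
    "assign_roles",
    "structures_equal",
]


def parse_structure(
    pdb_text: str,
    role_map: Mapping[str, Role | str],
    kind: Kind | str,
) -> ComplexStructure:
    """Parse PDB text into a role-typed :class:`ComplexStructure`.

    Parameters
    ----------
    pdb_text:
        PDB-format text (ATOM/HETATM records; SEQRES and the REMARK 2
        resolution record are honoured when present).
    role_map:
        Map from chain identifier in the file to a :class:`Role`.  Every
        role required by ``kind`` must be covered.
    kind:
        Which subunits the structure is expected to contain.

    Raises
    ------
    FormatError
        If the text is not parseable PDB.
    MappingError
        If ``role_map`` names a chain absent from the file.
    KindError
        If a role required by ``kind`` is missing from ``role_map``.
    """
    kind = Kind(kind)
    roles = {cid: Role(r) for cid, r in role_map.items()}

    assigned = set(roles.values())
    missing_roles = [r for r in kind.required_roles if r not in assigned]
    if missing_roles:
        raise KindError(
            f"role_map does not provide role(s) required by {kind}: "
            + ", ".join(str(r) for r in missing_roles)
        )
    if len(assigned) != len(roles):
        raise MappingError("role_map assigns the same role to multiple chains")

    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"unparseable PDB text: {exc}") from exc
    if len(st) == 0:
        raise FormatError("PDB text contains no model")

    # SEQRES lengths, captured before entity setup mutates anything
    seqres_len = {ent.name: len(ent.full_sequence) for ent in st.entities}

    resolution = st.resolution if st.resolution > 0 else None
    model = st[0]
    present_ids = {ch.name for ch in model}
    absent = sorted(set(roles) - present_ids)
    if absent:
        raise MappingError(
            f"role_map references chain(s) absent from the file: {absent}"
        )

    chains: dict[Role, Chain] = {}
    for gchain in model:
        role = roles.get(gchain.name)
        if role is None:
            continue  # untyped chains (e.g. β2m) are ignored
        residues: list[Residue] = []
        n_missing = 0
        n_observed = 0
        for gres in gchain:
            atoms: dict[str, np.ndarray] = {}
            for atom in gres:
                # gemmi reports "no altloc" as the NUL character
                if atom.altloc not in ("\0", "", " ", "A"):
                    continue
                if atom.name not in atoms:
                    atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                    )
            n_observed += 1
            if "CA" not in atoms:
                n_missing += 1
                continue
            residues.append(
                Residue(
                    name=gres.name,
                    seq_index=len(residues),
                    author_number=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    atoms=atoms,
                )
            )
        declared = seqres_len.get(gchain.name, n_observed)
        n_missing += max(declared - n_observed, 0)
        chains[role] = Chain(
            chain_id=gchain.name,
            role=role,
            residues=residues,
            n_missing_residues=n_missing,
        )

    cs = ComplexStructure(
        id=st.name or "structure",
        kind=kind,
        chains=chains,
        resolution=resolution,
    )
    cs.validate()
    return cs


def extract_sequences(complex_: ComplexStructure) -> dict[Role, str]:
    """1-letter sequences per role; non-standard residue names become 'X'."""
    return complex_.sequences()


def write_structure(complex_: ComplexStructure) -> str:
    """Serialize a complex to PDB text.

    Chains are emitted in the fixed role order (MHC, PEPTIDE, TCRA, TCRB);
    re-parsing the output reproduces roles, residue names, author numbering
    and coordinates at the PDB fixed-width precision of 3 decimals.
    """
    st = gemmi.Structure()
    st.name = complex_.id
    if complex_.resolution is not None:
        st.resolution = complex_.resolution
    model = gemmi.Model(1)
    for role in ROLE_ORDER:
        chain = complex_.chains.get(role)
        if chain is None:
            continue
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.author_number, res.insertion_code or " ")
            for atom_name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(_element_of(atom_name))
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                atom.b_iso = 0.0
                gres.add_atom(atom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    # populate entity sequences so SEQRES records are written
    chain_seqres = {
        complex_.chains[role].chain_id: [
            res.name for res in complex_.chains[role]
        ]
        for role in complex_.roles
    }
    for ent in st.entities:
        names = chain_seqres.get(ent.name)
        if names:
            ent.full_sequence = names
    opts = gemmi.PdbWriteOptions(seqres_records=True)
    header = ""
    if complex_.resolution is not None:
        header = f"REMARK   2 RESOLUTION. {complex_.resolution:7.2f} ANGSTROMS.\n"
    body = st.make_pdb_string(opts)
    # gemmi emits its own REMARK 2 only in some paths; ensure one is present
    if complex_.resolution is not None and "REMARK   2 RESOLUTION" not in body:
        body = header + body
    return body


def _element_of(atom_name: str) -> str:
    """Element symbol from a PDB atom name (protein heavy atoms + H)."""
    stripped = atom_name.strip()
    for sym in ("CL", "BR", "FE", "ZN", "MG", "NA"):  # unlikely but safe
        if stripped.upper() == sym:
            return sym.capitalize()
    return stripped[0].upper()


def structures_equal(
    a: ComplexStructure,
    b: ComplexStructure,
    coord_tol: float = 1.5e-3,
) -> bool:
    """Structural equality: roles, residue names, author numbers, and
    coordinates within ``coord_tol`` Å (default: PDB 3-decimal precision)."""
    if a.kind != b.kind or a.roles != b.roles:
        return False
    for role in a.roles:
        ca, cb = a.chain(role), b.chain(role)
        if len(ca) != len(cb):
            return False
        for ra, rb in zip(ca, cb):
            if (
                ra.name != rb.name
                or ra.author_number != rb.author_number
                or set(ra.atoms) != set(rb.atoms)
            ):
                return False
            for name in ra.atoms:
                if np.max(np.abs(ra.atoms[name] - rb.atoms[name])) > coord_tol:
                    return False
    return True


# ---------------------------------------------------------------------------
# FASTA with role-tagged headers
# ---------------------------------------------------------------------------

def read_fasta(text: str) -> dict[Role, str]:
    """Read role-tagged FASTA (``>id|ROLE``) into a role→sequence map."""
    sequences: dict[Role, str] = {}
    for record in SeqIO.parse(io.StringIO(text), "fasta"):
        parts = record.id.split("|")
        if len(parts) < 2:
            raise InputError(
                f"FASTA header {record.id!r} lacks a |ROLE tag "
                "(expected '>id|ROLE')"
            )
        try:
            role = Role(parts[-1].upper())
        except ValueError as exc:
            raise InputError(f"unknown role tag in header {record.id!r}") from exc
        if role in sequences:
            raise InputError(f"duplicate FASTA record for role {role}")
        sequences[role] = str(record.seq).upper()
    if not sequences:
        raise InputError("no FASTA records found")
    return sequences


def write_fasta(sequences: Mapping[Role, str], name: str = "target") -> str:
    """Write a role→sequence map as role-tagged FASTA text."""
    records = [
        SeqRecord(Seq(sequences[role]), id=f"{name}|{role}", description="")
        for role in ROLE_ORDER
        if role in sequences
    ]
    handle = io.StringIO()
    SeqIO.write(records, handle, "fasta")
    return handle.getvalue()


# ---------------------------------------------------------------------------
# Automatic role assignment
# ---------------------------------------------------------------------------

def assign_roles(
    chain_sequences: Mapping[str, str],
    profiles: Mapping[Role, "SequenceProfile"],
) -> dict[str, Role]:
    """Assign roles to chains by profile alignment score.

    The peptide is the chain of length 8-11 with no profile to call its
    own; every other chain takes the role whose profile aligns it best.
    Ambiguous inputs (several peptide-length chains, several chains won by
    the same profile) require an explicit role map and raise
    :class:`MappingError`.
    """
    from .profiles import align_to_profile

    lo, hi = PEPTIDE_LENGTH_RANGE
    assignment: dict[str, Role] = {}
    peptide_candidates = [
        cid for cid, seq in chain_sequences.items() if lo <= len(seq) <= hi
    ]
    if len(peptide_candidates) > 1:
        raise MappingError(
            "multiple peptide-length chains; supply an explicit role_map"
        )
    if peptide_candidates:
        assignment[peptide_candidates[0]] = Role.PEPTIDE

    for cid, seq in chain_sequences.items():
        if cid in assignment:
            continue
        scored = sorted(
            (
                (align_to_profile(seq, prof).score, role)
                for role, prof in profiles.items()
                if role is not Role.PEPTIDE
            ),
            key=lambda t: (-t[0], t[1].value),
        )
        if not scored:
            raise MappingError(f"no profile available to type chain {cid!r}")
        assignment[cid] = scored[0][1]

    seen: dict[Role, str] = {}
    for cid, role in assignment.items():
        if role in seen:
            raise MappingError(
                f"chains {seen[role]!r} and {cid!r} both assign to {role}; "
                "supply an explicit role_map"
            )
        seen[role] = cid
    return assignment
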