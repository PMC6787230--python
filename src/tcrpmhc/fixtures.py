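"""Deterministic synthetic complexes, template universes and decoy ladders.

Every stage of the pipeline is testable without downloading a single
structure: this module generates schematic but geometrically well-formed
toy complexes (two antiparallel Cα helices as the MHC groove walls, an
extended peptide strand in the groove, two TCR helices docked above it
with a genuine heavy-atom interface), template universes whose entries
have engineered sequence identities to a designated probe, and decoy
ladders for the interface metrics.

The geometry is schematic, not physical: the point is that selection,
assembly and metric algorithms can be exercised against constructions
whose correct answers are known by design.  Coordinate noise in a
template universe scales with (1 − intended identity), so sequence
identity genuinely predicts structural closeness — the property the
selection methods exploit on real data.

All randomness flows from a single seed per fixture; identical seeds
give byte-identical PDB output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import (
    AMINO_ACIDS,
    Chain,
    ComplexStructure,
    InputError,
    Kind,
    Residue,
    Role,
    seq3,
)
from .profiles import SequenceProfile, build_profile
from .selection import Candidate, IdentityBreakdown, TCRPMHC_SCHEME
from .structio import write_structure
from .templatedb import TemplateDB, build_db

__all__ = [
    "FixtureSpec",
    "make_toy_complex",
    "mutate_to_identity",
    "make_decoy_ladder",
    "make_template_universe",
    "to_pdb_text",
    "brute_force_select_multi",
    "TOY_MHC_LENGTH",
    "TOY_TCR_LENGTH",
]

#: toy MHC chain length; matches the match-position count of the class I
#: α1-α2 profile so the test profile has the full production length
TOY_MHC_LENGTH = 181
TOY_TCR_LENGTH = 30

_CA_SPACING = 3.8
_HELIX_RISE = 1.5
_HELIX_TURN = np.deg2rad(100.0)
# radius chosen so consecutive helical Cα atoms sit exactly 3.8 Å apart
_HELIX_RADIUS = float(
    np.sqrt(_CA_SPACING**2 - _HELIX_RISE**2) / (2.0 * np.sin(_HELIX_TURN / 2.0))
)


@dataclass
class FixtureSpec:
    """Parameters of a synthetic template universe."""

    seed: int = 0
    n_entries: int = 20
    #: peptide length -> number of entries of that length; lengths must
    #: lie in [8, 11] and counts sum to n_entries
    peptide_lengths: dict[int, int] = field(
        default_factory=lambda: {8: 4, 9: 8, 10: 5, 11: 3}
    )
    #: intended identity of each entry to the probe of its length class,
    #: cycled over entries; engineered spread from near-duplicate to remote
    identity_targets: tuple[float, ...] = (
        0.99, 0.95, 0.90, 0.85, 0.80, 0.75, 0.70, 0.65, 0.60, 0.55,
    )
    #: maximum coordinate noise (Å); an entry at identity i is perturbed
    #: with per-atom Gaussian noise of σ = noise_max · (1 − i)
    noise_max: float = 2.5
    #: TCR displacement magnitudes (Å) for decoy ladders
    perturbation_ladder: tuple[float, ...] = (
        0.0, 1.0, 2.0, 4.0, 6.0, 9.0, 13.0, 18.0, 25.0, 40.0,
    )

    def __post_init__(self) -> None:
        if sum(self.peptide_lengths.values()) != self.n_entries:
            raise InputError("peptide length counts must sum to n_entries")
        if any(not 8 <= L <= 11 for L in self.peptide_lengths):
            raise InputError("peptide lengths must lie in [8, 11]")
        if any(not 0.0 <= t <= 1.0 for t in self.identity_targets):
            raise InputError("identity targets must lie in [0, 1]")


def _helix(n: int, origin: np.ndarray, axis_sign: float = 1.0) -> np.ndarray:
    """Cα trace of an ideal helix along ±x with 3.8 Å Cα spacing."""
    i = np.arange(n)
    x = origin[0] + axis_sign * i * _HELIX_RISE
    y = origin[1] + _HELIX_RADIUS * np.cos(i * _HELIX_TURN)
    z = origin[2] + _HELIX_RADIUS * np.sin(i * _HELIX_TURN)
    return np.column_stack([x, y, z])


def _strand(n: int, origin: np.ndarray) -> np.ndarray:
    """Extended zigzag strand (β-like pleat, never collinear)."""
    i = np.arange(n)
    pleat = 0.8
    dx = np.sqrt(_CA_SPACING**2 - (2.0 * pleat) ** 2)
    out = np.tile(origin, (n, 1)).astype(float)
    out[:, 0] += (i - (n - 1) / 2.0) * dx
    out[:, 1] += pleat * (-1.0) ** i
    return out


def _backbone_residues(
    cas: np.ndarray, sequence: str, start_number: int = 1
) -> list[Residue]:
    """Decorate a Cα trace with schematic N/C/O (and CB) atoms."""
    n = len(cas)
    residues = []
    for i in range(n):
        prev_ca = cas[max(i - 1, 0)]
        next_ca = cas[min(i + 1, n - 1)]
        d = next_ca - prev_ca
        norm = np.linalg.norm(d)
        d = d / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(d, ref)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        p = np.cross(d, ref)
        p /= np.linalg.norm(p)
        q = np.cross(d, p)
        ca = cas[i]
        atoms = {
            "N": ca - 1.2 * d,
            "CA": ca.copy(),
            "C": ca + 1.2 * d,
            "O": ca + 1.2 * d + 1.2 * p,
        }
        if sequence[i] != "G":
            atoms["CB"] = ca + 1.5 * q
        residues.append(
            Residue(
                name=seq3(sequence[i]),
                seq_index=i,
                author_number=start_number + i,
                atoms=atoms,
            )
        )
    return residues


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def make_toy_complex(
    seed: int,
    peptide_length: int = 9,
    mhc_length: int = TOY_MHC_LENGTH,
    tcr_length: int = TOY_TCR_LENGTH,
    complex_id: str | None = None,
) -> ComplexStructure:
    """Idealized TCR-pMHC complex with a genuine 5 Å interface.

    The MHC is laid out as two long antiparallel helices flanking a
    groove, the peptide as an extended strand inside it, and the two TCR
    chains as helices docked above the groove so that at least ten
    heavy-atom contacts at 5 Å exist between the pMHC and the TCR.
    Consecutive Cα atoms are 3.8 Å apart by construction.
    """
    lo, hi = 8, 11
    if not lo <= peptide_length <= hi:
        raise InputError(f"peptide length must lie in [{lo}, {hi}]")
    rng = np.random.default_rng(seed)

    # groove wall 1, a 3-residue cross-groove connector, groove wall 2;
    # the connector preserves the 3.8 Å consecutive Cα spacing
    n_conn = 3
    n1 = (mhc_length - n_conn) // 2
    n2 = mhc_length - n_conn - n1
    span1 = _helix(n1, np.array([-n1 * _HELIX_RISE / 2.0, -5.5, 0.0]))
    jump = np.array([0.0, (n_conn + 1) * _CA_SPACING, 0.0])
    q0 = span1[-1] + jump
    connector = np.vstack(
        [span1[-1] + jump * f for f in ((1 / 4), (2 / 4), (3 / 4))]
    )
    span2 = _helix(n2, np.zeros(3), axis_sign=-1.0)
    span2 = span2 + (q0 - span2[0])
    mhc_cas = np.vstack([span1, connector, span2])
    pep_cas = _strand(peptide_length, np.array([0.0, 0.0, 1.5]))
    tcra_cas = _helix(
        tcr_length, np.array([-tcr_length * _HELIX_RISE / 2.0, -2.0, 5.4])
    )
    tcrb_cas = _helix(
        tcr_length, np.array([-tcr_length * _HELIX_RISE / 2.0 + 1.9, 2.0, 5.4])
    )

    # sequences drawn in a fixed role order from the single seeded stream
    seqs = {
        Role.MHC: _random_sequence(rng, mhc_length),
        Role.PEPTIDE: _random_sequence(rng, peptide_length),
        Role.TCRA: _random_sequence(rng, tcr_length),
        Role.TCRB: _random_sequence(rng, tcr_length),
    }
    traces = {
        Role.MHC: mhc_cas,
        Role.PEPTIDE: pep_cas,
        Role.TCRA: tcra_cas,
        Role.TCRB: tcrb_cas,
    }
    chain_ids = {Role.MHC: "A", Role.PEPTIDE: "P", Role.TCRA: "D", Role.TCRB: "E"}
    chains = {
        role: Chain(
            chain_id=chain_ids[role],
            role=role,
            residues=_backbone_residues(traces[role], seqs[role]),
        )
        for role in traces
    }
    return ComplexStructure(
        id=complex_id or f"toy{seed:04d}",
        kind=Kind.TCRPMHC,
        chains=chains,
        resolution=1.8,
        provenance=f"synthetic toy complex, seed={seed}",
    )


def mutate_to_identity(
    structure: ComplexStructure,
    role: Role,
    target_identity: float,
    seed: int,
) -> ComplexStructure:
    """Substitute residue types (never coordinates) on one chain so its
    identity to the source lands within 1/length of ``target_identity``."""
    if not 0.0 <= target_identity <= 1.0:
        raise InputError("target identity must lie in [0, 1]")
    out = structure.copy()
    chain = out.chain(role)
    n = len(chain)
    k = int(round((1.0 - target_identity) * n))
    if k == 0:
        return out
    rng = np.random.default_rng(seed)
    positions = rng.choice(n, size=k, replace=False)
    for pos in positions:
        res = chain.residues[int(pos)]
        current = res.code1
        alternatives = [aa for aa in AMINO_ACIDS if aa != current]
        res.name = seq3(str(rng.choice(alternatives)))
    return out


def make_decoy_ladder(
    native: ComplexStructure,
    displacements: Sequence[float],
    direction: np.ndarray | None = None,
) -> list[ComplexStructure]:
    """Decoys with the TCR rigidly translated by increasing magnitudes.

    Displacements must be sorted ascending; the translation direction is
    fixed (default +z, straight off the pMHC surface).
    """
    if list(displacements) != sorted(displacements):
        raise InputError("displacements must be sorted ascending")
    if direction is None:
        direction = np.array([0.0, 0.0, 1.0])
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    decoys = []
    for d in displacements:
        decoy = native.copy(new_id=f"{native.id}_d{d:g}")
        shift = direction * float(d)
        for role in (Role.TCRA, Role.TCRB):
            for res in decoy.chain(role):
                for name in res.atoms:
                    res.atoms[name] = res.atoms[name] + shift
        decoys.append(decoy)
    return decoys


def to_pdb_text(structure: ComplexStructure, defect: str | None = None) -> str:
    """PDB text for a fixture, optionally with a named defect.

    ``defect="missing_peptide_residue"`` deletes the ATOM records of the
    central peptide residue while keeping it in SEQRES, so parsing flags
    one missing peptide residue; ``defect="no_resolution"`` drops the
    resolution record.
    """
    if defect == "no_resolution":
        stripped = structure.copy()
        stripped.resolution = None
        return write_structure(stripped)
    text = write_structure(structure)
    if defect is None:
        return text
    if defect == "missing_peptide_residue":
        pep = structure.chain(Role.PEPTIDE)
        victim = pep.residues[len(pep) // 2]
        cid = pep.chain_id
        keep = []
        for line in text.splitlines(keepends=True):
            if line.startswith(("ATOM", "HETATM")):
                chain_id = line[21]
                resnum = int(line[22:26])
                if chain_id == cid and resnum == victim.author_number:
                    continue
            keep.append(line)
        return "".join(keep)
    raise InputError(f"unknown defect {defect!r}")


# ---------------------------------------------------------------------------
# Template universes
# ---------------------------------------------------------------------------

def _positional_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def brute_force_select_multi(
    scores: Mapping[str, float],
    pairwise: Mapping[tuple[str, str], float],
    redundancy_cutoff: float = 0.95,
    relative_floor: float = 0.80,
) -> list[str]:
    """Reference implementation of the ranked redundancy-aware selection.

    Straight transliteration of the two admission rules, independent of
    the selection module: rank by score (ties lexicographic), always keep
    the top candidate, then admit a candidate iff it is < cutoff
    identical to everything kept and ≥ floor × top score.
    """
    ranked = sorted(scores, key=lambda cid: (-scores[cid], cid))
    chosen = [ranked[0]]
    top = scores[ranked[0]]
    for cid in ranked[1:]:
        if scores[cid] < relative_floor * top:
            continue
        redundant = False
        for kept in chosen:
            key = (cid, kept) if (cid, kept) in pairwise else (kept, cid)
            if pairwise[key] >= redundancy_cutoff:
                redundant = True
                break
        if not redundant:
            chosen.append(cid)
    return chosen


def make_template_universe(
    spec: FixtureSpec,
) -> tuple[TemplateDB, TemplateDB, TemplateDB, dict]:
    """pMHC, TCR and TCR-pMHC databases with engineered identity spectra.

    For each peptide length class a probe complex is generated; entries
    are sequence-mutated copies of the probe with intended identities
    cycled from ``spec.identity_targets`` and per-atom coordinate noise
    of σ = noise_max · (1 − identity).  The manifest records, per entry,
    the intended identity, the realized per-chain identities to the
    probe, the expected ranking for the probe of its length class, and
    the expected redundancy-aware (weighted) chosen set computed with the
    brute-force reference selector on raw positional identities.
    """
    rng = np.random.default_rng(spec.seed)
    probes: dict[int, ComplexStructure] = {}
    entries: list[ComplexStructure] = []
    manifest: dict = {
        "seed": spec.seed,
        "noise_max": spec.noise_max,
        "entries": {},
        "probes": {},
    }

    k = 0
    for length in sorted(spec.peptide_lengths):
        probe = make_toy_complex(
            seed=spec.seed * 1000 + length,
            peptide_length=length,
            complex_id=f"probe{length}",
        )
        probes[length] = probe
        manifest["probes"][str(length)] = {
            "sequences": {str(r): s for r, s in probe.sequences().items()}
        }
        for _ in range(spec.peptide_lengths[length]):
            target_identity = spec.identity_targets[
                k % len(spec.identity_targets)
            ]
            eid = f"e{k:03d}"
            entry = probe.copy(new_id=eid)
            for role in (Role.MHC, Role.PEPTIDE, Role.TCRA, Role.TCRB):
                entry = mutate_to_identity(
                    entry, role, target_identity, seed=spec.seed * 9973 + 17 * k + int(role.value.encode()[0])
                )
            sigma = spec.noise_max * (1.0 - target_identity)
            if sigma > 0:
                entry_rng = np.random.default_rng(spec.seed * 7919 + k)
                for chain in entry.chains.values():
                    for res in chain:
                        for name in res.atoms:
                            res.atoms[name] = res.atoms[name] + entry_rng.normal(
                                0.0, sigma, size=3
                            )
            entry.resolution = round(1.5 + 0.05 * k, 2)
            entries.append(entry)
            manifest["entries"][eid] = {
                "peptide_length": length,
                "intended_identity": target_identity,
                "resolution": entry.resolution,
                "identity_to_probe": {
                    str(role): _positional_identity(
                        entry.chain(role).sequence,
                        probe.chain(role).sequence,
                    )
                    for role in entry.roles
                },
            }
            k += 1

    # profiles from the universe's own ungapped sequence families
    def _msa(role: Role) -> list[str]:
        return [e.chain(role).sequence for e in entries] + [
            p.chain(role).sequence for p in probes.values()
        ]

    profiles: dict[Role, SequenceProfile] = {
        role: build_profile(_msa(role), role)
        for role in (Role.MHC, Role.TCRA, Role.TCRB)
    }

    def _portion(entry: ComplexStructure, kind: Kind) -> ComplexStructure:
        return ComplexStructure(
            id=entry.id,
            kind=kind,
            chains={
                r: entry.chain(r).copy() for r in kind.required_roles
            },
            resolution=entry.resolution,
        )

    pmhc_db = build_db(
        [_portion(e, Kind.PMHC) for e in entries],
        Kind.PMHC,
        {Role.MHC: profiles[Role.MHC]},
    )
    tcr_db = build_db(
        [_portion(e, Kind.TCR) for e in entries],
        Kind.TCR,
        {Role.TCRA: profiles[Role.TCRA], Role.TCRB: profiles[Role.TCRB]},
    )
    tcrpmhc_db = build_db(entries, Kind.TCRPMHC, profiles)

    # expected probe-ranking and chosen set per length class, from the
    # brute-force reference on raw positional identities
    scheme = TCRPMHC_SCHEME
    for length, probe in probes.items():
        class_ids = [
            e.id for e in entries if e.peptide_length == length
        ]
        scores = {}
        for eid in class_ids:
            entry = next(e for e in entries if e.id == eid)
            scores[eid] = sum(
                scheme[role]
                * _positional_identity(
                    probe.chain(role).sequence, entry.chain(role).sequence
                )
                for role in scheme.roles
            )
        pairwise = {}
        for i, a in enumerate(class_ids):
            ea = next(e for e in entries if e.id == a)
            for b in class_ids[i + 1:]:
                eb = next(e for e in entries if e.id == b)
                pairwise[(a, b)] = sum(
                    scheme[role]
                    * _positional_identity(
                        ea.chain(role).sequence, eb.chain(role).sequence
                    )
                    for role in scheme.roles
                )
        ranking = sorted(scores, key=lambda cid: (-scores[cid], cid))
        manifest["probes"][str(length)].update(
            {
                "expected_ranking": ranking,
                "expected_multiweighted_chosen": brute_force_select_multi(
                    scores, pairwise
                ),
                "scores": scores,
            }
        )
    return pmhc_db, tcr_db, tcrpmhc_db, manifest


def probe_candidates(
    manifest: dict, peptide_length: int
) -> list[Candidate]:
    """Manifest scores as Candidate objects (for oracle comparisons)."""
    info = manifest["probes"][str(peptide_length)]
    out = []
    for eid, score in info["scores"].items():
        breakdown = IdentityBreakdown(per_chain={}, weighted=score)
        out.append(Candidate(id=eid, breakdown=breakdown, score=score))
    return out


def save_universe(
    dbs: tuple[TemplateDB, TemplateDB, TemplateDB],
    manifest: dict,
    out_dir: str | Path,
) -> None:
    """Persist the three databases plus the manifest to a directory."""
    from .templatedb import save_db

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, db in zip(("pmhc", "tcr", "tcrpmhc"), dbs):
        save_db(db, out_dir / name)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
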