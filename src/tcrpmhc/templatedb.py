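"""Template databases for pMHC, TCR and TCR-pMHC modelling.

Three databases back the three modelling stages.  Each is built from
parsed structures by an ordered chain of filters, mirroring the curation
applied to the source repositories:

* ``peptide_complete`` — drop entries without a peptide chain or with
  missing peptide residues;
* ``resolution`` — drop entries solved worse than a cutoff (boundary
  kept: "above" the cutoff is removed) and entries with no recorded
  resolution;
* ``dedup`` — greedy redundancy removal on concatenated chain sequences;
  at a threshold of 1.0 this removes exact sequence duplicates only,
  keeping the better-resolved copy.

Profile-bearing chains (MHC and, when profiles are provided, the TCR
V-domains) are truncated to the region that aligns to their profile
before any downstream use; the peptide is stored unaligned.

Externally produced profile-search hit tables can be pre-filtered with
:func:`filter_hit_table` (E-value <= 1e-5 and bit score > 250, the
documented discovery thresholds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .core import (
    ComplexStructure,
    InputError,
    Kind,
    Role,
    concatenated_sequence,
)
from .profiles import (
    ProfileAlignment,
    SequenceProfile,
    align_to_profile,
    read_profile,
    write_profile,
)
from .structio import parse_structure, write_structure

__all__ = [
    "TemplateEntry",
    "TemplateDB",
    "FilterStep",
    "filter_peptide_complete",
    "filter_resolution",
    "deduplicate",
    "build_db",
    "query_by_peptide_length",
    "make_entry",
    "filter_hit_table",
    "save_db",
    "load_db",
    "HIT_EVALUE_MAX",
    "HIT_BITSCORE_MIN",
]

#: discovery-step thresholds for externally supplied profile-search hits
HIT_EVALUE_MAX = 1e-5
HIT_BITSCORE_MIN = 250.0


@dataclass
class TemplateEntry:
    """One template: structure plus per-role profile alignments."""

    structure: ComplexStructure
    alignments: dict[Role, ProfileAlignment] = field(default_factory=dict)

    @property
    def id(self) -> str:
        return self.structure.id

    @property
    def peptide_length(self) -> int | None:
        return self.structure.peptide_length

    @property
    def sequences(self) -> dict[Role, str]:
        return self.structure.sequences()


@dataclass
class TemplateDB:
    """Identifier-keyed template collection with a peptide-length index."""

    kind: Kind
    entries: dict[str, TemplateEntry] = field(default_factory=dict)
    profiles: dict[Role, SequenceProfile] = field(default_factory=dict)
    report: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def length_index(self) -> dict[int, list[str]]:
        index: dict[int, list[str]] = {}
        for eid, entry in self.entries.items():
            L = entry.peptide_length
            if L is not None:
                index.setdefault(L, []).append(eid)
        for ids in index.values():
            ids.sort()
        return index

    def ids(self) -> list[str]:
        return sorted(self.entries)


def truncate_to_alignment(
    structure: ComplexStructure,
    profiles: Mapping[Role, SequenceProfile],
) -> tuple[ComplexStructure, dict[Role, ProfileAlignment]]:
    """Trim profile-bearing chains to their aligned core and re-align.

    Residues the aligner reports as trimmed termini (outside the profile)
    are removed from the chain, indices are re-densified, and the
    truncated sequence is aligned again so the stored alignment has zero
    trimmed residues.
    """
    out = structure.copy()
    alignments: dict[Role, ProfileAlignment] = {}
    for role, profile in profiles.items():
        chain = out.chains.get(role)
        if chain is None or role is Role.PEPTIDE:
            continue
        aln = align_to_profile(chain.sequence, profile)
        if aln.n_matched == 0:
            raise InputError(
                f"chain {role} of {structure.id!r} does not align to "
                "its profile"
            )
        lo = aln.trimmed_prefix
        hi = len(chain) - aln.trimmed_suffix
        if lo > 0 or hi < len(chain):
            chain.residues = [r.copy() for r in chain.residues[lo:hi]]
            chain.reindex()
            aln = align_to_profile(chain.sequence, profile)
        alignments[role] = aln
    return out, alignments


def make_entry(
    structure: ComplexStructure,
    profiles: Mapping[Role, SequenceProfile],
) -> TemplateEntry:
    """Wrap a structure as a template: truncate and align its chains."""
    truncated, alignments = truncate_to_alignment(structure, profiles)
    return TemplateEntry(structure=truncated, alignments=alignments)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_peptide_complete(
    entries: Sequence[ComplexStructure],
) -> list[ComplexStructure]:
    """Keep entries whose peptide chain exists and has no missing residue."""
    kept = []
    for entry in entries:
        pep = entry.chains.get(Role.PEPTIDE)
        if pep is not None and pep.n_missing_residues == 0 and len(pep) > 0:
            kept.append(entry)
    return kept


def filter_resolution(
    entries: Sequence[ComplexStructure],
    max_resolution: float = 3.0,
) -> list[ComplexStructure]:
    """Keep entries solved at ``max_resolution`` Å or better.

    Entries with no recorded resolution cannot be vetted and are removed.
    """
    return [
        e
        for e in entries
        if e.resolution is not None and e.resolution <= max_resolution
    ]


def _global_identity(seq_a: str, seq_b: str) -> float:
    """Global (Needleman-Wunsch) identity between concatenated sequences."""
    if seq_a == seq_b:
        return 1.0
    if not seq_a or not seq_b:
        return 0.0
    dist = edlib.align(seq_a, seq_b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(seq_a), len(seq_b))


def deduplicate(
    entries: Sequence[ComplexStructure],
    identity_threshold: float = 1.0,
) -> list[ComplexStructure]:
    """Greedy redundancy removal on concatenated chain sequences.

    Entries are visited best resolution first (absent resolution last,
    ties by identifier); an entry is dropped when its global identity to
    any already-retained entry reaches ``identity_threshold``.  At the
    default threshold of 1.0 only exact sequence duplicates are removed.
    The retained list preserves the input order.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise InputError("identity_threshold must be in (0, 1]")
    order = sorted(
        range(len(entries)),
        key=lambda i: (
            entries[i].resolution is None,
            entries[i].resolution if entries[i].resolution is not None else 0.0,
            entries[i].id,
        ),
    )
    seqs = [concatenated_sequence(e.sequences()) for e in entries]
    retained: set[int] = set()
    for i in order:
        if any(
            _global_identity(seqs[i], seqs[j]) >= identity_threshold
            for j in retained
        ):
            continue
        retained.add(i)
    return [entries[i] for i in range(len(entries)) if i in retained]


@dataclass
class FilterStep:
    """A named filter with its parameters, applied in configured order."""

    name: str
    params: dict = field(default_factory=dict)

    def apply(self, entries: list[ComplexStructure]) -> list[ComplexStructure]:
        try:
            fn: Callable = _FILTERS[self.name]
        except KeyError as exc:
            raise InputError(f"unknown filter {self.name!r}") from exc
        return fn(entries, **self.params)


_FILTERS: dict[str, Callable] = {
    "peptide_complete": filter_peptide_complete,
    "resolution": filter_resolution,
    "dedup": deduplicate,
}


DEFAULT_FILTERS: dict[Kind, tuple[FilterStep, ...]] = {
    Kind.PMHC: (
        FilterStep("peptide_complete"),
        FilterStep("dedup", {"identity_threshold": 1.0}),
    ),
    Kind.TCR: (FilterStep("dedup", {"identity_threshold": 1.0}),),
    Kind.TCRPMHC: (
        FilterStep("peptide_complete"),
        FilterStep("resolution", {"max_resolution": 3.0}),
        FilterStep("dedup", {"identity_threshold": 1.0}),
    ),
}


def build_db(
    entries: Iterable[ComplexStructure],
    kind: Kind | str,
    profiles: Mapping[Role, SequenceProfile],
    filters: Sequence[FilterStep] | None = None,
) -> TemplateDB:
    """Filter structures and assemble a template database.

    The build report (part of the returned database) records survivor
    counts before and after each filter plus per-entry rejection reasons
    for structures that fail the kind's role requirements.  Redundancy is
    assessed on chains concatenated in the fixed role order.
    """
    kind = Kind(kind)
    if filters is None:
        filters = DEFAULT_FILTERS[kind]
    report: list[dict] = []

    pool: list[ComplexStructure] = []
    rejected: list[dict] = []
    for entry in entries:
        missing = [r for r in kind.required_roles if r not in entry.chains]
        if missing:
            rejected.append(
                {
                    "id": entry.id,
                    "reason": "missing role(s): "
                    + ",".join(str(m) for m in missing),
                }
            )
        else:
            pool.append(entry)
    report.append(
        {
            "filter": "role_requirements",
            "params": {"kind": str(kind)},
            "before": len(pool) + len(rejected),
            "after": len(pool),
            "rejected": rejected,
        }
    )

    for step in filters:
        before = len(pool)
        survivors = step.apply(pool)
        surv_ids = {e.id for e in survivors}
        report.append(
            {
                "filter": step.name,
                "params": dict(step.params),
                "before": before,
                "after": len(survivors),
                "rejected": [
                    {"id": e.id, "reason": step.name}
                    for e in pool
                    if e.id not in surv_ids
                ],
            }
        )
        pool = survivors

    db = TemplateDB(kind=kind, profiles=dict(profiles), report=report)
    for entry in pool:
        if entry.id in db.entries:
            raise InputError(f"duplicate entry identifier {entry.id!r}")
        db.entries[entry.id] = make_entry(entry, profiles)
    return db


def query_by_peptide_length(db: TemplateDB, length: int) -> list[str]:
    """Identifiers of entries whose peptide has exactly ``length`` residues."""
    if length < 1:
        raise InputError("peptide length must be >= 1")
    return db.length_index.get(length, [])


def filter_hit_table(
    table: pd.DataFrame,
    evalue_max: float = HIT_EVALUE_MAX,
    bitscore_min: float = HIT_BITSCORE_MIN,
) -> pd.DataFrame:
    """Apply the discovery thresholds to an external profile-search table.

    Expects columns ``entry_id``, ``evalue``, ``bitscore``; keeps rows
    with E-value <= ``evalue_max`` and bit score strictly greater than
    ``bitscore_min``.
    """
    required = {"entry_id", "evalue", "bitscore"}
    if not required.issubset(table.columns):
        raise InputError(f"hit table must have columns {sorted(required)}")
    mask = (table["evalue"] <= evalue_max) & (table["bitscore"] > bitscore_min)
    return table.loc[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Persistence: directory with manifest + per-entry PDB + alignments
# ---------------------------------------------------------------------------

def _alignment_to_json(aln: ProfileAlignment) -> dict:
    return {
        "sequence": aln.sequence,
        "profile_length": aln.profile_length,
        "mapping": aln.mapping,
        "trimmed_prefix": aln.trimmed_prefix,
        "trimmed_suffix": aln.trimmed_suffix,
        "score": aln.score,
    }


def _alignment_from_json(data: dict) -> ProfileAlignment:
    return ProfileAlignment(
        sequence=data["sequence"],
        profile_length=data["profile_length"],
        mapping=[m if m is None else int(m) for m in data["mapping"]],
        trimmed_prefix=data["trimmed_prefix"],
        trimmed_suffix=data["trimmed_suffix"],
        score=data["score"],
    )


def save_db(db: TemplateDB, path: str | Path) -> None:
    """Persist a database as a directory of text files."""
    path = Path(path)
    (path / "entries").mkdir(parents=True, exist_ok=True)
    manifest = {
        "kind": str(db.kind),
        "report": db.report,
        "entries": {},
    }
    for role, profile in db.profiles.items():
        (path / f"profile_{role}.tsv").write_text(write_profile(profile))
    for eid in db.ids():
        entry = db.entries[eid]
        (path / "entries" / f"{eid}.pdb").write_text(
            write_structure(entry.structure)
        )
        manifest["entries"][eid] = {
            "kind": str(entry.structure.kind),
            "resolution": entry.structure.resolution,
            "peptide_length": entry.peptide_length,
            "chain_ids": {
                str(role): entry.structure.chain(role).chain_id
                for role in entry.structure.roles
            },
            "alignments": {
                str(role): _alignment_to_json(aln)
                for role, aln in entry.alignments.items()
            },
        }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_db(path: str | Path) -> TemplateDB:
    """Load a database persisted by :func:`save_db`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    kind = Kind(manifest["kind"])
    profiles: dict[Role, SequenceProfile] = {}
    for pfile in sorted(path.glob("profile_*.tsv")):
        profile = read_profile(pfile.read_text())
        profiles[profile.role] = profile
    db = TemplateDB(kind=kind, profiles=profiles, report=manifest["report"])
    for eid, meta in manifest["entries"].items():
        pdb_text = (path / "entries" / f"{eid}.pdb").read_text()
        role_map = {cid: Role(r) for r, cid in meta["chain_ids"].items()}
        structure = parse_structure(pdb_text, role_map, Kind(meta["kind"]))
        structure.id = eid
        structure.resolution = meta["resolution"]
        alignments = {
            Role(r): _alignment_from_json(a)
            for r, a in meta["alignments"].items()
        }
        db.entries[eid] = TemplateEntry(structure=structure, alignments=alignments)
    return db
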