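"""Model building: pMHC and TCR sub-models, then full-complex assembly.

The pipeline mirrors the comparative-modelling flow for this complex:
model the pMHC and the TCR separately against their own template
databases, then assemble the full complex using the two sub-models as the
sole source of internal geometry and one or more full-complex templates
as the sole source of the relative TCR/pMHC orientation.

The default backend is a deterministic coordinate-graft builder:

* every target residue with a profile column takes its backbone (N, CA,
  C, O) as the identity-weighted average over the selected templates
  covering that column, after all templates have been mutually superposed
  onto the top-ranked one;
* side-chain atoms are copied from the highest-identity covering template
  only when its residue type equals the target's;
* residues covered by no template are marked UNSUPPORTED and receive a
  linearly interpolated Cα.

Assembly places each sub-model rigidly: for every chosen complex
template, the sub-model is superposed onto the template's corresponding
portion (Cα Kabsch in profile coordinates); the per-template placements
are combined by identity-weighted averaging of the placed Cα clouds, and
the sub-model is then rigidly fitted onto the averaged cloud, so its
internal geometry is never distorted.  Strongly disagreeing placements
(pairwise Cα discrepancy above 5 Å) are flagged in the run report.

An adapter seam (``register_backend``) lets an external
restraint-satisfaction builder take over model construction from the same
PIR alignment contract.
"""

from __future__ import annotations

import enum
import io
import time
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import (
    BackendError,
    ComplexStructure,
    Chain,
    ContractError,
    InputError,
    InsufficientTemplateError,
    Kind,
    PEPTIDE_LENGTH_RANGE,
    Residue,
    Role,
    seq3,
)
from .metrics import BACKBONE_ATOMS, kabsch
from .profiles import ProfileAlignment, SequenceProfile, align_to_profile
from .selection import (
    SelectionConfig,
    SelectionResult,
    default_scheme,
    query_from_sequences,
    select_templates,
)
from .structio import read_fasta
from .templatedb import TemplateDB, TemplateEntry, truncate_to_alignment

__all__ = [
    "Stage",
    "ModellingJob",
    "BuiltModel",
    "UNSUPPORTED",
    "build_alignment_file",
    "parse_alignment_file",
    "graft_build",
    "model_pmhc",
    "model_tcr",
    "assemble_complex",
    "run_pipeline",
    "extract_submodel",
    "register_backend",
    "PLACEMENT_DISCREPANCY_WARN",
]

#: marker for residues no template could support
UNSUPPORTED = "UNSUPPORTED"

#: pairwise Cα placement discrepancy (Å) above which assembly warns
PLACEMENT_DISCREPANCY_WARN = 5.0


class Stage(str, enum.Enum):
    PMHC = "PMHC"
    TCR = "TCR"
    ASSEMBLY = "ASSEMBLY"

    @property
    def kind(self) -> Kind:
        return {
            Stage.PMHC: Kind.PMHC,
            Stage.TCR: Kind.TCR,
            Stage.ASSEMBLY: Kind.TCRPMHC,
        }[self]


@dataclass
class ModellingJob:
    """Everything one build needs: sequences, selection, templates."""

    target_sequences: dict[Role, str]
    stage: Stage
    selection: SelectionResult
    templates: dict[str, TemplateEntry]
    profiles: dict[Role, SequenceProfile]
    backend: str = "graft"
    model_id: str = "model"
    #: optional precomputed target alignments (must cover the sequences
    #: with zero trimmed termini); skips the alignment step when present
    target_alignments: dict[Role, ProfileAlignment] | None = None

    def __post_init__(self) -> None:
        missing = [
            cid for cid in self.selection.chosen if cid not in self.templates
        ]
        if missing:
            raise InputError(f"chosen templates not resolved: {missing}")
        for role in self.stage.kind.required_roles:
            if role not in self.target_sequences:
                raise InputError(f"stage {self.stage} requires role {role}")


@dataclass
class BuiltModel:
    """A built structure plus per-residue provenance."""

    structure: ComplexStructure
    stage: Stage
    templates_used: list[str]
    per_residue_support: dict[tuple[Role, int], list[str] | str] = field(
        default_factory=dict
    )
    column_maps: dict[Role, dict[int, int]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# PIR alignment files
# ---------------------------------------------------------------------------

def _profile_row(
    aln: ProfileAlignment, length: int
) -> str:
    """Sequence projected onto profile columns ('-' for absent columns)."""
    row = ["-"] * length
    for col, idx in aln.column_to_residue().items():
        row[col] = aln.sequence[idx]
    return "".join(row)


def build_alignment_file(
    target_sequences: Mapping[Role, str],
    templates: Sequence[TemplateEntry],
    profiles: Mapping[Role, SequenceProfile],
    kind: Kind | str,
    target_id: str = "target",
) -> str:
    """PIR-format target/templates alignment in profile coordinates.

    Each record concatenates the kind's chains in the fixed role order,
    separated by '/' chain breaks; profile-bearing chains are projected
    onto profile columns (gaps where a sequence does not occupy a
    column; insertions are not representable in profile coordinates and
    are omitted), and the peptide block is ungapped.
    """
    kind = Kind(kind)
    roles = kind.required_roles
    pep_len = None
    if Role.PEPTIDE in roles:
        pep_len = len(target_sequences[Role.PEPTIDE])
        for t in templates:
            if t.peptide_length != pep_len:
                raise InputError(
                    f"template {t.id} has peptide length {t.peptide_length}, "
                    f"target has {pep_len}"
                )

    def record_blocks(
        seqs: Mapping[Role, str],
        alignments: Mapping[Role, ProfileAlignment],
        label: str,
    ) -> list[str]:
        blocks = []
        for role in roles:
            if role is Role.PEPTIDE:
                blocks.append(seqs[Role.PEPTIDE])
                continue
            aln = alignments.get(role)
            if aln is None or aln.n_matched == 0:
                raise InputError(
                    f"{label}: chain {role} has no usable profile alignment"
                )
            blocks.append(_profile_row(aln, profiles[role].length))
        return blocks

    target_alignments = {
        role: align_to_profile(target_sequences[role], profiles[role])
        for role in roles
        if role is not Role.PEPTIDE
    }
    lines = [">P1;" + target_id, f"sequence:{target_id}::::::::"]
    lines.append(
        "/".join(record_blocks(target_sequences, target_alignments, target_id))
        + "*"
    )
    for t in templates:
        lines.append(">P1;" + t.id)
        lines.append(f"structureX:{t.id}::::::::")
        lines.append("/".join(record_blocks(t.sequences, t.alignments, t.id)) + "*")
    return "\n".join(lines) + "\n"


def parse_alignment_file(text: str) -> dict[str, list[str]]:
    """Parse PIR text back to per-record chain blocks (round-trip aid)."""
    records: dict[str, list[str]] = {}
    name: str | None = None
    buffer: list[str] = []
    skip_next = False
    for line in io.StringIO(text):
        line = line.strip()
        if line.startswith(">P1;"):
            if name is not None:
                records[name] = "".join(buffer).rstrip("*").split("/")
            name = line[4:]
            buffer = []
            skip_next = True
        elif skip_next:
            skip_next = False  # the description line
        elif line:
            buffer.append(line)
    if name is not None:
        records[name] = "".join(buffer).rstrip("*").split("/")
    return records


# ---------------------------------------------------------------------------
# Graft backend
# ---------------------------------------------------------------------------

def _stage_column_pairs(
    entry_a: TemplateEntry | None,
    maps_a: Mapping[Role, Mapping[int, int]],
    struct_a: ComplexStructure,
    entry_b: TemplateEntry,
    roles: Sequence[Role],
) -> tuple[np.ndarray, np.ndarray]:
    """Paired Cα coords of two structures at shared profile columns."""
    xs, ys = [], []
    maps_b = {
        role: entry_b.alignments[role].column_to_residue()
        for role in roles
        if role is not Role.PEPTIDE and role in entry_b.alignments
    }
    for role in roles:
        chain_a = struct_a.chains.get(role)
        chain_b = entry_b.structure.chains.get(role)
        if chain_a is None or chain_b is None:
            continue
        if role is Role.PEPTIDE:
            for i in range(min(len(chain_a), len(chain_b))):
                ca_a = chain_a.residues[i].ca
                ca_b = chain_b.residues[i].ca
                if ca_a is not None and ca_b is not None:
                    xs.append(ca_a)
                    ys.append(ca_b)
            continue
        col_map_a = maps_a.get(role, {})
        inv_a = {c: i for i, c in col_map_a.items()}
        col_map_b = maps_b.get(role, {})
        for col, idx_b in col_map_b.items():
            idx_a = inv_a.get(col)
            if idx_a is None or idx_a >= len(chain_a):
                continue
            ca_a = chain_a.residues[idx_a].ca
            ca_b = chain_b.residues[idx_b].ca
            if ca_a is not None and ca_b is not None:
                xs.append(ca_a)
                ys.append(ca_b)
    if len(xs) < 3:
        raise InsufficientTemplateError(
            "fewer than 3 shared positions for superposition"
        )
    return np.vstack(xs), np.vstack(ys)


def graft_build(job: ModellingJob) -> BuiltModel:
    """Deterministic coordinate-graft model construction.

    See the module docstring for the algorithm.  Raises
    :class:`InsufficientTemplateError` when no template covers more than
    half of some target chain.
    """
    if job.backend != "graft":
        return _run_external_backend(job)
    if not job.selection.chosen:
        raise InsufficientTemplateError("selection chose no template")

    kind = job.stage.kind
    roles = kind.required_roles
    weights = {
        c.id: max(c.score, 1e-9)
        for c in job.selection.ranked
        if c.id in job.selection.chosen
    }

    # target alignments and per-role column maps (core residues only)
    target_alignments: dict[Role, ProfileAlignment] = {}
    core_seqs: dict[Role, str] = {}
    column_maps: dict[Role, dict[int, int]] = {}
    for role in roles:
        seq = job.target_sequences[role]
        if role is Role.PEPTIDE:
            core_seqs[role] = seq
            column_maps[role] = {i: i for i in range(len(seq))}
            continue
        profile = job.profiles.get(role)
        if profile is None:
            raise InputError(f"no profile for role {role}")
        pre = (job.target_alignments or {}).get(role)
        if (
            pre is not None
            and pre.sequence == seq
            and pre.trimmed_prefix == 0
            and pre.trimmed_suffix == 0
        ):
            aln = pre
        else:
            aln = align_to_profile(seq, profile)
        if aln.n_matched == 0:
            raise InsufficientTemplateError(
                f"target chain {role} does not align to its profile"
            )
        lo = aln.trimmed_prefix
        hi = len(seq) - aln.trimmed_suffix
        core = seq[lo:hi]
        aln = align_to_profile(core, profile) if (lo or hi < len(seq)) else aln
        target_alignments[role] = aln
        core_seqs[role] = core
        column_maps[role] = {
            i: c for i, c in enumerate(aln.mapping) if c is not None
        }

    # mutual superposition of chosen templates onto the top-ranked one
    chosen = list(job.selection.chosen)
    ref_entry = job.templates[chosen[0]]
    placed: dict[str, ComplexStructure] = {chosen[0]: ref_entry.structure.copy()}
    ref_maps = {
        role: {
            idx: col
            for col, idx in ref_entry.alignments[role].column_to_residue().items()
        }
        for role in roles
        if role is not Role.PEPTIDE and role in ref_entry.alignments
    }
    for cid in chosen[1:]:
        entry = job.templates[cid]
        ref_xyz, ent_xyz = _stage_column_pairs(
            None, ref_maps, ref_entry.structure, entry, roles
        )
        sup = kabsch(ent_xyz, ref_xyz)  # maps entry coords onto reference
        copy = entry.structure.copy()
        copy.transform(sup.rotation, sup.translation)
        placed[cid] = copy

    # per-template residue lookup: role -> column -> Residue
    template_residues: dict[str, dict[Role, dict[int, Residue]]] = {}
    for cid in chosen:
        entry = job.templates[cid]
        struct = placed[cid]
        lookup: dict[Role, dict[int, Residue]] = {}
        for role in roles:
            chain = struct.chains.get(role)
            if chain is None:
                continue
            if role is Role.PEPTIDE:
                lookup[role] = {
                    i: chain.residues[i] for i in range(len(chain))
                }
            else:
                aln = entry.alignments.get(role)
                if aln is None:
                    continue
                lookup[role] = {
                    col: chain.residues[idx]
                    for col, idx in aln.column_to_residue().items()
                    if idx < len(chain)
                }
        template_residues[cid] = lookup

    # coverage check: some template must cover > 50% of every chain
    for role in roles:
        n_core = len(core_seqs[role])
        covered_best = 0
        for cid in chosen:
            cols = template_residues[cid].get(role, {})
            covered = sum(
                1 for c in column_maps[role].values() if c in cols
            )
            covered_best = max(covered_best, covered)
        if n_core == 0 or covered_best <= 0.5 * n_core:
            raise InsufficientTemplateError(
                f"no selected template covers more than half of chain {role}"
            )

    chain_ids = {Role.MHC: "A", Role.PEPTIDE: "P", Role.TCRA: "D", Role.TCRB: "E"}
    chains: dict[Role, Chain] = {}
    support: dict[tuple[Role, int], list[str] | str] = {}
    for role in roles:
        seq = core_seqs[role]
        residues: list[Residue] = []
        for i, aa in enumerate(seq):
            col = column_maps[role].get(i)
            atoms: dict[str, np.ndarray] = {}
            contributors: list[str] = []
            if col is not None:
                sidechain_donor: tuple[float, Residue] | None = None
                backbone_acc: dict[str, list[tuple[float, np.ndarray]]] = {}
                for cid in chosen:
                    res = template_residues[cid].get(role, {}).get(col)
                    if res is None:
                        continue
                    w = weights[cid]
                    contributors.append(cid)
                    for name in BACKBONE_ATOMS:
                        if name in res.atoms:
                            backbone_acc.setdefault(name, []).append(
                                (w, res.atoms[name])
                            )
                    if res.name == seq3(aa):
                        if sidechain_donor is None or w > sidechain_donor[0]:
                            sidechain_donor = (w, res)
                for name, contribs in backbone_acc.items():
                    total = sum(w for w, _ in contribs)
                    atoms[name] = sum(
                        (w * xyz for w, xyz in contribs),
                        np.zeros(3),
                    ) / total
                if sidechain_donor is not None:
                    for name, xyz in sidechain_donor[1].atoms.items():
                        if name not in BACKBONE_ATOMS and name not in atoms:
                            atoms[name] = xyz.copy()
            residue = Residue(
                name=seq3(aa),
                seq_index=i,
                author_number=i + 1,
                atoms=atoms,
            )
            residues.append(residue)
            support[(role, i)] = contributors if contributors else UNSUPPORTED
        chains[role] = Chain(
            chain_id=chain_ids[role], role=role, residues=residues
        )

    _interpolate_unsupported(chains, support)

    structure = ComplexStructure(
        id=job.model_id, kind=kind, chains=chains, provenance="graft backend"
    )
    return BuiltModel(
        structure=structure,
        stage=job.stage,
        templates_used=chosen,
        per_residue_support=support,
        column_maps=column_maps,
    )


def _interpolate_unsupported(
    chains: Mapping[Role, Chain],
    support: Mapping[tuple[Role, int], list[str] | str],
) -> None:
    """Give unsupported residues a linearly interpolated Cα."""
    for role, chain in chains.items():
        anchors = [
            (i, res.ca)
            for i, res in enumerate(chain.residues)
            if support[(role, i)] != UNSUPPORTED and res.ca is not None
        ]
        if not anchors:
            continue
        idxs = np.array([i for i, _ in anchors], dtype=float)
        cas = np.vstack([ca for _, ca in anchors])
        for i, res in enumerate(chain.residues):
            if support[(role, i)] != UNSUPPORTED:
                continue
            ca = np.array(
                [np.interp(i, idxs, cas[:, k]) for k in range(3)]
            )
            if i < idxs[0] and len(anchors) >= 2:
                step = cas[0] - cas[1]
                ca = cas[0] + step * (idxs[0] - i) / max(idxs[1] - idxs[0], 1)
            elif i > idxs[-1] and len(anchors) >= 2:
                step = cas[-1] - cas[-2]
                ca = cas[-1] + step * (i - idxs[-1]) / max(
                    idxs[-1] - idxs[-2], 1
                )
            res.atoms["CA"] = ca


# ---------------------------------------------------------------------------
# External backend seam
# ---------------------------------------------------------------------------

_BACKENDS: dict[str, Callable[[ModellingJob], ComplexStructure]] = {}


def register_backend(
    name: str, fn: Callable[[ModellingJob], ComplexStructure]
) -> None:
    """Register an external model builder under ``external:<name>``."""
    _BACKENDS[name] = fn


def _run_external_backend(job: ModellingJob) -> BuiltModel:
    if not job.backend.startswith("external:"):
        raise BackendError(f"unknown backend {job.backend!r}")
    name = job.backend.split(":", 1)[1]
    fn = _BACKENDS.get(name)
    if fn is None:
        raise BackendError(
            f"external backend {name!r} is not registered; available: "
            f"{sorted(_BACKENDS)}"
        )
    try:
        structure = fn(job)
    except Exception as exc:  # noqa: BLE001 - diagnostics belong to caller
        raise BackendError(f"backend {name!r} failed: {exc}") from exc
    missing = [
        r for r in job.stage.kind.required_roles if r not in structure.chains
    ]
    if missing:
        raise ContractError(
            f"backend {name!r} returned a structure missing role(s) "
            + ", ".join(str(m) for m in missing)
        )
    structure.validate()
    maps: dict[Role, dict[int, int]] = {}
    for role in job.stage.kind.required_roles:
        seq = structure.chains[role].sequence
        if role is Role.PEPTIDE:
            maps[role] = {i: i for i in range(len(seq))}
        else:
            aln = align_to_profile(seq, job.profiles[role])
            maps[role] = {
                aln.trimmed_prefix + i: c
                for i, c in enumerate(aln.mapping)
                if c is not None
            }
    return BuiltModel(
        structure=structure,
        stage=job.stage,
        templates_used=list(job.selection.chosen),
        column_maps=maps,
    )


# ---------------------------------------------------------------------------
# Stage drivers
# ---------------------------------------------------------------------------

def _stage_model(
    target_sequences: Mapping[Role, str],
    db: TemplateDB,
    config: SelectionConfig,
    stage: Stage,
    backend: str,
    exclude: Sequence[str] = (),
) -> BuiltModel:
    sequences = {
        role: target_sequences[role]
        for role in stage.kind.required_roles
    }
    query = query_from_sequences(sequences, db.profiles)
    selection = select_templates(
        query, db, config, scheme=default_scheme(db.kind), exclude=exclude
    )
    job = ModellingJob(
        target_sequences=dict(sequences),
        stage=stage,
        selection=selection,
        templates={cid: db.entries[cid] for cid in selection.chosen},
        profiles=db.profiles,
        backend=backend,
        model_id=f"{str(stage.kind).lower()}_model",
    )
    return graft_build(job)


def model_pmhc(
    target_sequences: Mapping[Role, str],
    pmhc_db: TemplateDB,
    config: SelectionConfig | None = None,
    backend: str = "graft",
    exclude: Sequence[str] = (),
) -> BuiltModel:
    """Build the pMHC sub-model (length-filter, score, cap, select, graft)."""
    return _stage_model(
        target_sequences,
        pmhc_db,
        config or SelectionConfig(),
        Stage.PMHC,
        backend,
        exclude,
    )


def model_tcr(
    target_sequences: Mapping[Role, str],
    tcr_db: TemplateDB,
    config: SelectionConfig | None = None,
    backend: str = "graft",
    exclude: Sequence[str] = (),
) -> BuiltModel:
    """Build the TCR sub-model.

    When an external TCR builder is registered and requested it is
    invoked through the backend seam and its output validated against the
    TCR contract; otherwise the generic graft machinery is used with the
    equal-weight two-chain scheme.
    """
    return _stage_model(
        target_sequences,
        tcr_db,
        config or SelectionConfig(),
        Stage.TCR,
        backend,
        exclude,
    )


def extract_submodel(
    complex_: ComplexStructure,
    kind: Kind | str,
    profiles: Mapping[Role, SequenceProfile],
) -> BuiltModel:
    """View a portion of an existing complex as a built sub-model.

    Used to seed assembly from crystal sub-structures and by tests.
    """
    kind = Kind(kind)
    stage = {Kind.PMHC: Stage.PMHC, Kind.TCR: Stage.TCR}.get(kind)
    if stage is None:
        raise InputError("sub-models are pMHC or TCR only")
    sub = ComplexStructure(
        id=f"{complex_.id}_{str(kind).lower()}",
        kind=kind,
        chains={
            role: complex_.chain(role).copy()
            for role in kind.required_roles
        },
        resolution=complex_.resolution,
    )
    truncated, alignments = truncate_to_alignment(sub, profiles)
    maps: dict[Role, dict[int, int]] = {}
    for role in kind.required_roles:
        if role is Role.PEPTIDE:
            maps[role] = {
                i: i for i in range(len(truncated.chain(role)))
            }
        else:
            aln = alignments[role]
            maps[role] = {
                i: c for i, c in enumerate(aln.mapping) if c is not None
            }
    return BuiltModel(
        structure=truncated,
        stage=stage,
        templates_used=[complex_.id],
        column_maps=maps,
    )


def assemble_complex(
    tcr_model: BuiltModel,
    pmhc_model: BuiltModel,
    tcrpmhc_db: TemplateDB,
    config: SelectionConfig | None = None,
    exclude: Sequence[str] = (),
) -> BuiltModel:
    """Assemble the full complex from sub-models plus complex templates.

    Complex templates are selected with the full-complex weight scheme;
    each sub-model is rigidly placed by identity-weighted averaging of
    its per-template placements (see module docstring).
    """
    config = config or SelectionConfig()
    target_sequences = {
        **pmhc_model.structure.sequences(),
        **tcr_model.structure.sequences(),
    }
    query = query_from_sequences(target_sequences, tcrpmhc_db.profiles)
    selection = select_templates(
        query,
        tcrpmhc_db,
        config,
        scheme=default_scheme(Kind.TCRPMHC),
        exclude=exclude,
    )
    chosen = list(selection.chosen)
    weights = {
        c.id: max(c.score, 1e-9)
        for c in selection.ranked
        if c.id in chosen
    }

    # bring all complex templates into the frame of the top-ranked one
    ref_entry = tcrpmhc_db.entries[chosen[0]]
    placed_templates: dict[str, ComplexStructure] = {
        chosen[0]: ref_entry.structure.copy()
    }
    ref_maps = {
        role: {
            idx: col
            for col, idx in ref_entry.alignments[role].column_to_residue().items()
        }
        for role in ref_entry.alignments
    }
    for cid in chosen[1:]:
        entry = tcrpmhc_db.entries[cid]
        # register templates in a common frame via the receptor (pMHC)
        # portion only, so each template's TCR placement relative to the
        # groove is preserved
        ref_xyz, ent_xyz = _stage_column_pairs(
            None,
            ref_maps,
            ref_entry.structure,
            entry,
            (Role.MHC, Role.PEPTIDE),
        )
        sup = kabsch(ent_xyz, ref_xyz)
        copy = entry.structure.copy()
        copy.transform(sup.rotation, sup.translation)
        placed_templates[cid] = copy

    warnings: list[str] = []
    merged: dict[Role, Chain] = {}
    for sub in (pmhc_model, tcr_model):
        placements: list[tuple[float, np.ndarray]] = []
        sub_cas, sub_keys = _submodel_cas(sub)
        per_template_clouds: dict[str, np.ndarray] = {}
        for cid in chosen:
            entry = tcrpmhc_db.entries[cid]
            pairs_sub, pairs_tpl = _submodel_template_pairs(
                sub, entry, placed_templates[cid]
            )
            sup = kabsch(pairs_sub, pairs_tpl)
            cloud = sup.apply(sub_cas)
            placements.append((weights[cid], cloud))
            per_template_clouds[cid] = cloud
        ids = list(per_template_clouds)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                gap = float(
                    np.sqrt(
                        np.mean(
                            np.sum(
                                (
                                    per_template_clouds[ids[i]]
                                    - per_template_clouds[ids[j]]
                                )
                                ** 2,
                                axis=1,
                            )
                        )
                    )
                )
                if gap > PLACEMENT_DISCREPANCY_WARN:
                    warnings.append(
                        f"{sub.stage} placements from {ids[i]} and {ids[j]} "
                        f"disagree by {gap:.2f} Å Cα RMSD"
                    )
        total_w = sum(w for w, _ in placements)
        average = sum(w * cloud for w, cloud in placements) / total_w
        # rigid fit of the sub-model onto its averaged placement
        sup = kabsch(sub_cas, average)
        moved = sub.structure.copy()
        moved.transform(sup.rotation, sup.translation)
        for role in moved.roles:
            merged[role] = moved.chain(role)

    structure = ComplexStructure(
        id="assembled",
        kind=Kind.TCRPMHC,
        chains=merged,
        provenance="rigid assembly from sub-models",
    )
    support: dict[tuple[Role, int], list[str] | str] = {}
    for sub in (pmhc_model, tcr_model):
        for key, val in sub.per_residue_support.items():
            support[key] = val
    return BuiltModel(
        structure=structure,
        stage=Stage.ASSEMBLY,
        templates_used=[pmhc_model.structure.id, tcr_model.structure.id]
        + chosen,
        per_residue_support=support,
        column_maps={**pmhc_model.column_maps, **tcr_model.column_maps},
        warnings=warnings,
    )


def _submodel_cas(sub: BuiltModel) -> tuple[np.ndarray, list[tuple[Role, int]]]:
    xs, keys = [], []
    for role in sub.structure.roles:
        for res in sub.structure.chain(role):
            if res.ca is not None:
                xs.append(res.ca)
                keys.append((role, res.seq_index))
    return np.vstack(xs), keys


def _submodel_template_pairs(
    sub: BuiltModel,
    entry: TemplateEntry,
    placed: ComplexStructure,
) -> tuple[np.ndarray, np.ndarray]:
    """Cα pairs between a sub-model and (the placed copy of) a template."""
    xs, ys = [], []
    for role in sub.structure.roles:
        chain_t = placed.chains.get(role)
        if chain_t is None:
            continue
        if role is Role.PEPTIDE:
            tpl_cols = {i: i for i in range(len(chain_t))}
        else:
            aln = entry.alignments.get(role)
            if aln is None:
                continue
            tpl_cols = {
                c: i for c, i in aln.column_to_residue().items()
                if i < len(chain_t)
            }
        sub_map = sub.column_maps.get(role, {})
        chain_s = sub.structure.chain(role)
        for idx_s, col in sub_map.items():
            idx_t = tpl_cols.get(col)
            if idx_t is None or idx_s >= len(chain_s):
                continue
            ca_s = chain_s.residues[idx_s].ca
            ca_t = chain_t.residues[idx_t].ca
            if ca_s is not None and ca_t is not None:
                xs.append(ca_s)
                ys.append(ca_t)
    if len(xs) < 3:
        raise InsufficientTemplateError(
            "sub-model shares fewer than 3 positions with a complex template"
        )
    return np.vstack(xs), np.vstack(ys)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    fasta_text: str,
    pmhc_db: TemplateDB,
    tcr_db: TemplateDB,
    tcrpmhc_db: TemplateDB,
    config: SelectionConfig | None = None,
    backend: str = "graft",
    exclude: Sequence[str] = (),
) -> tuple[BuiltModel, dict]:
    """Sequences in, full-complex model out.

    Runs pMHC modelling, TCR modelling, then assembly, and returns the
    final model together with a run report (selections, identities,
    timings, backend, seed).
    """
    config = config or SelectionConfig()
    sequences = read_fasta(fasta_text)
    missing = [
        str(r) for r in Kind.TCRPMHC.required_roles if r not in sequences
    ]
    if missing:
        raise InputError("FASTA lacks required role(s): " + ", ".join(missing))
    lo, hi = PEPTIDE_LENGTH_RANGE
    pep_len = len(sequences[Role.PEPTIDE])
    if not lo <= pep_len <= hi:
        raise InputError(
            f"peptide length {pep_len} outside the modellable range "
            f"[{lo}, {hi}]"
        )

    report: dict = {"backend": backend, "seed": config.seed, "stages": {}}

    def _timed(stage: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        report["stages"][stage] = {"seconds": time.perf_counter() - t0}
        return result

    pmhc = _timed(
        "pmhc",
        lambda: model_pmhc(sequences, pmhc_db, config, backend, exclude),
    )
    report["stages"]["pmhc"]["selection"] = pmhc.templates_used
    tcr = _timed(
        "tcr",
        lambda: model_tcr(sequences, tcr_db, config, backend, exclude),
    )
    report["stages"]["tcr"]["selection"] = tcr.templates_used
    final = _timed(
        "assembly",
        lambda: assemble_complex(tcr, pmhc, tcrpmhc_db, config, exclude),
    )
    report["stages"]["assembly"]["selection"] = final.templates_used
    report["warnings"] = final.warnings
    return final, report
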