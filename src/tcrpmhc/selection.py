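"""Template scoring and selection.

Target-template similarity is a composite sequence identity computed in
profile coordinates.  Each profile-bearing chain contributes the count of
identical residues at match positions occupied by both sequences
(insertions excluded); the peptide contributes an ungapped positional
identity over its full length (templates are pre-filtered to the target's
peptide length, so peptides always compare position by position).

Two composites exist:

* unweighted — pooled ratio, Σ matches / Σ compared lengths;
* weighted — Σ w(role) · identity(role) with the stage weight scheme:
  peptide ½ + MHC ½ for the pMHC stage, and peptide ⅓ + MHC ⅓ +
  TCRα ⅙ + TCRβ ⅙ for the full complex.

Selection methods: a single best template (One*), a Hobohm-style
multi-template set (Multi*: the top template is always kept; further
candidates are admitted while < 95% identical to everything already
chosen and ≥ 80% of the top score), and a seeded uniform Random baseline.
A leave-one-out identity cap retains only candidates scoring strictly
below the cap.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import (
    InputError,
    Kind,
    NoTemplateError,
    Role,
)
from .profiles import ProfileAlignment, SequenceProfile, align_to_profile
from .templatedb import TemplateDB, TemplateEntry

__all__ = [
    "Method",
    "WeightScheme",
    "PMHC_SCHEME",
    "TCR_SCHEME",
    "TCRPMHC_SCHEME",
    "ChainIdentity",
    "IdentityBreakdown",
    "SelectionConfig",
    "Candidate",
    "SelectionResult",
    "Query",
    "query_from_sequences",
    "query_from_entry",
    "chain_identity",
    "peptide_identity",
    "score_candidate",
    "apply_identity_cap",
    "select_one",
    "select_multi",
    "select_random",
    "select_templates",
    "default_scheme",
]


class Method(str, enum.Enum):
    """Template selection method."""

    ONE_UNWEIGHTED = "OneUnweighted"
    ONE_WEIGHTED = "OneWeighted"
    MULTI_UNWEIGHTED = "MultiUnweighted"
    MULTI_WEIGHTED = "MultiWeighted"
    RANDOM = "Random"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def weighted(self) -> bool:
        return self in (Method.ONE_WEIGHTED, Method.MULTI_WEIGHTED)

    @property
    def multi(self) -> bool:
        return self in (Method.MULTI_UNWEIGHTED, Method.MULTI_WEIGHTED)


@dataclass(frozen=True)
class WeightScheme:
    """Per-role contribution weights; must sum to 1."""

    weights: Mapping[Role, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise InputError(f"weights sum to {total}, expected 1")
        if any(w < 0 for w in self.weights.values()):
            raise InputError("weights must be non-negative")

    def __getitem__(self, role: Role) -> float:
        return self.weights[role]

    @property
    def roles(self) -> tuple[Role, ...]:
        return tuple(self.weights)


#: pMHC stage: peptide and MHC contribute equally
PMHC_SCHEME = WeightScheme({Role.PEPTIDE: 0.5, Role.MHC: 0.5})
#: TCR stage: the two chains contribute equally
TCR_SCHEME = WeightScheme({Role.TCRA: 0.5, Role.TCRB: 0.5})
#: full complex: peptide 1/3, MHC 1/3, TCR α and β 1/6 each
TCRPMHC_SCHEME = WeightScheme(
    {
        Role.PEPTIDE: 1.0 / 3.0,
        Role.MHC: 1.0 / 3.0,
        Role.TCRA: 1.0 / 6.0,
        Role.TCRB: 1.0 / 6.0,
    }
)

_DEFAULT_SCHEMES = {
    Kind.PMHC: PMHC_SCHEME,
    Kind.TCR: TCR_SCHEME,
    Kind.TCRPMHC: TCRPMHC_SCHEME,
}


def default_scheme(kind: Kind | str) -> WeightScheme:
    """The published weight scheme for a modelling stage."""
    return _DEFAULT_SCHEMES[Kind(kind)]


@dataclass(frozen=True)
class ChainIdentity:
    matches: int
    compared_length: int

    @property
    def identity(self) -> float:
        if self.compared_length == 0:
            return 0.0
        return self.matches / self.compared_length


@dataclass
class IdentityBreakdown:
    """Per-chain identities plus the two composites."""

    per_chain: dict[Role, ChainIdentity]
    weighted: float | None = None

    @property
    def unweighted(self) -> float:
        total_m = sum(c.matches for c in self.per_chain.values())
        total_l = sum(c.compared_length for c in self.per_chain.values())
        return total_m / total_l if total_l else 0.0

    def score(self, weighted: bool) -> float:
        if weighted:
            if self.weighted is None:
                raise InputError("no weighted identity was computed")
            return self.weighted
        return self.unweighted


@dataclass
class SelectionConfig:
    """Method, leave-one-out cap, Hobohm parameters, and random seed."""

    method: Method | str = Method.MULTI_WEIGHTED
    identity_cap: float | None = None
    redundancy_cutoff: float = 0.95
    relative_floor: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        self.method = Method(self.method)
        if not 0.0 < self.redundancy_cutoff <= 1.0:
            raise InputError("redundancy_cutoff must be in (0, 1]")
        if not 0.0 < self.relative_floor <= 1.0:
            raise InputError("relative_floor must be in (0, 1]")


@dataclass
class Candidate:
    id: str
    breakdown: IdentityBreakdown
    score: float


@dataclass
class SelectionResult:
    """Ranked candidates and the chosen subset for one selection run."""

    ranked: list[Candidate]
    chosen: list[str]
    config: SelectionConfig

    def to_json(self) -> str:
        payload = {
            "config": {
                "method": str(self.config.method),
                "identity_cap": self.config.identity_cap,
                "redundancy_cutoff": self.config.redundancy_cutoff,
                "relative_floor": self.config.relative_floor,
                "seed": self.config.seed,
            },
            "chosen": self.chosen,
            "ranked": [
                {
                    "id": c.id,
                    "score": c.score,
                    "unweighted": c.breakdown.unweighted,
                    "weighted": c.breakdown.weighted,
                    "per_chain": {
                        str(role): {
                            "matches": ci.matches,
                            "compared_length": ci.compared_length,
                            "identity": ci.identity,
                        }
                        for role, ci in c.breakdown.per_chain.items()
                    },
                }
                for c in self.ranked
            ],
        }
        return json.dumps(payload, indent=1)


@dataclass
class Query:
    """Alignment view of a target or template used for identity scoring."""

    alignments: dict[Role, ProfileAlignment] = field(default_factory=dict)
    peptide: str | None = None


def query_from_sequences(
    sequences: Mapping[Role, str],
    profiles: Mapping[Role, SequenceProfile],
) -> Query:
    """Align target sequences to the stage profiles."""
    alignments = {
        role: align_to_profile(seq, profiles[role])
        for role, seq in sequences.items()
        if role is not Role.PEPTIDE and role in profiles
    }
    return Query(alignments=alignments, peptide=sequences.get(Role.PEPTIDE))


def query_from_entry(entry: TemplateEntry) -> Query:
    pep = entry.structure.chains.get(Role.PEPTIDE)
    return Query(
        alignments=dict(entry.alignments),
        peptide=pep.sequence if pep is not None else None,
    )


# ---------------------------------------------------------------------------
# Identity primitives
# ---------------------------------------------------------------------------

def chain_identity(
    target_aln: ProfileAlignment,
    template_aln: ProfileAlignment,
) -> tuple[int, int]:
    """(matches, compared_length) at shared profile match positions.

    Only match positions occupied by *both* sequences are compared;
    insertions contribute to neither count.  ``compared_length`` is the
    number of match positions the target occupies.
    """
    if target_aln.profile_length != template_aln.profile_length:
        raise InputError(
            "alignments live in different profile spaces "
            f"({target_aln.profile_length} vs {template_aln.profile_length})"
        )
    target_cols = target_aln.column_to_residue()
    template_cols = template_aln.column_to_residue()
    matches = 0
    for col, t_idx in target_cols.items():
        s_idx = template_cols.get(col)
        if s_idx is None:
            continue
        if target_aln.sequence[t_idx] == template_aln.sequence[s_idx]:
            matches += 1
    return matches, len(target_cols)


def peptide_identity(target_pep: str, template_pep: str) -> tuple[int, int]:
    """Ungapped positional identity over equal-length peptides."""
    if len(target_pep) != len(template_pep):
        raise InputError(
            f"peptide lengths differ ({len(target_pep)} vs "
            f"{len(template_pep)}); length-mismatched templates must be "
            "excluded before scoring"
        )
    matches = sum(a == b for a, b in zip(target_pep, template_pep))
    return matches, len(target_pep)


def score_candidate(
    target: Query,
    template: Query | TemplateEntry,
    scheme: WeightScheme | None,
    kind: Kind | str,
) -> IdentityBreakdown:
    """Composite identity of one template against the target."""
    kind = Kind(kind)
    if isinstance(template, TemplateEntry):
        template = query_from_entry(template)
    per_chain: dict[Role, ChainIdentity] = {}
    for role in kind.required_roles:
        if role is Role.PEPTIDE:
            if target.peptide is None or template.peptide is None:
                raise InputError("peptide sequence missing on one side")
            m, n = peptide_identity(target.peptide, template.peptide)
        else:
            if role not in target.alignments or role not in template.alignments:
                raise InputError(f"no profile alignment for role {role}")
            m, n = chain_identity(target.alignments[role], template.alignments[role])
        per_chain[role] = ChainIdentity(m, n)

    breakdown = IdentityBreakdown(per_chain=per_chain)
    if scheme is not None:
        breakdown.weighted = sum(
            scheme[role] * per_chain[role].identity for role in scheme.roles
        )
    return breakdown


# ---------------------------------------------------------------------------
# Selection methods
# ---------------------------------------------------------------------------

def apply_identity_cap(
    candidates: Sequence[Candidate],
    cap: float | None,
) -> list[Candidate]:
    """Retain candidates scoring strictly below ``cap`` (None keeps all)."""
    if cap is None:
        return list(candidates)
    return [c for c in candidates if c.score < cap]


def _ranked(candidates: Sequence[Candidate]) -> list[Candidate]:
    return sorted(candidates, key=lambda c: (-c.score, c.id))


def select_one(
    candidates: Sequence[Candidate],
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Single top-scoring template; score ties break lexicographically."""
    if not candidates:
        raise NoTemplateError("no candidate template available")
    ranked = _ranked(candidates)
    return SelectionResult(
        ranked=ranked,
        chosen=[ranked[0].id],
        config=config or SelectionConfig(method=Method.ONE_WEIGHTED),
    )


def select_multi(
    candidates: Sequence[Candidate],
    template_identity: Callable[[str, str], float],
    redundancy_cutoff: float = 0.95,
    relative_floor: float = 0.80,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Hobohm-style multi-template selection.

    The top-ranked candidate is always chosen.  Scanning down the ranking,
    a candidate is added iff (1) its identity to every already-chosen
    template is strictly below ``redundancy_cutoff`` and (2) its identity
    to the target is at least ``relative_floor`` times the top score.
    ``template_identity(a, b)`` supplies pairwise template-template
    identity in the same composite the ranking uses.
    """
    if not candidates:
        raise NoTemplateError("no candidate template available")
    ranked = _ranked(candidates)
    top = ranked[0]
    chosen = [top.id]
    floor = relative_floor * top.score
    for cand in ranked[1:]:
        if cand.score < floor:
            continue
        if all(
            template_identity(cand.id, cid) < redundancy_cutoff
            for cid in chosen
        ):
            chosen.append(cand.id)
    return SelectionResult(
        ranked=ranked,
        chosen=chosen,
        config=config
        or SelectionConfig(
            method=Method.MULTI_WEIGHTED,
            redundancy_cutoff=redundancy_cutoff,
            relative_floor=relative_floor,
        ),
    )


def select_random(
    candidates: Sequence[Candidate],
    seed: int,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """One uniformly drawn candidate; reproducible for a given seed."""
    if not candidates:
        raise NoTemplateError("no candidate template available")
    ranked = _ranked(candidates)
    rng = np.random.default_rng(seed)
    pick = ranked[int(rng.integers(len(ranked)))]
    return SelectionResult(
        ranked=ranked,
        chosen=[pick.id],
        config=config or SelectionConfig(method=Method.RANDOM, seed=seed),
    )


# ---------------------------------------------------------------------------
# End-to-end selection against a database
# ---------------------------------------------------------------------------

def select_templates(
    target: Query,
    db: TemplateDB,
    config: SelectionConfig,
    scheme: WeightScheme | None = None,
    exclude: Sequence[str] = (),
) -> SelectionResult:
    """Length-filter, score, cap and select templates from a database.

    ``exclude`` removes identifiers from the candidate pool before
    scoring (used by the leave-one-out protocol).  The identity cap and
    the ranking both use the method's own score: the weighted composite
    for *Weighted methods, the pooled unweighted composite otherwise.
    """
    method = config.method
    if scheme is None and (method.weighted or db.kind is Kind.TCR):
        scheme = default_scheme(db.kind)

    pool = [
        db.entries[eid]
        for eid in db.ids()
        if eid not in set(exclude)
    ]
    if db.kind is not Kind.TCR:
        if target.peptide is None:
            raise InputError("target has no peptide sequence")
        L = len(target.peptide)
        pool = [e for e in pool if e.peptide_length == L]
        if not pool:
            raise NoTemplateError(
                f"no template with peptide length {L} in the "
                f"{db.kind} database"
            )
    if not pool:
        raise NoTemplateError(f"the {db.kind} database is empty")

    use_weighted = method.weighted
    candidates = []
    for entry in pool:
        breakdown = score_candidate(target, entry, scheme, db.kind)
        candidates.append(
            Candidate(
                id=entry.id,
                breakdown=breakdown,
                score=breakdown.score(use_weighted)
                if (not use_weighted or breakdown.weighted is not None)
                else breakdown.unweighted,
            )
        )

    candidates = apply_identity_cap(_ranked(candidates), config.identity_cap)
    if not candidates:
        raise NoTemplateError(
            f"no candidate survives the identity cap {config.identity_cap}"
        )

    if method is Method.RANDOM:
        return select_random(candidates, config.seed, config)
    if not method.multi:
        return select_one(candidates, config)

    queries = {e.id: query_from_entry(e) for e in pool}
    pair_cache: dict[tuple[str, str], float] = {}

    def template_identity(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in pair_cache:
            breakdown = score_candidate(
                queries[a], queries[b], scheme, db.kind
            )
            pair_cache[key] = breakdown.score(use_weighted)
        return pair_cache[key]

    return select_multi(
        candidates,
        template_identity,
        redundancy_cutoff=config.redundancy_cutoff,
        relative_floor=config.relative_floor,
        config=config,
    )
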