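"""Fixed-length sequence profiles and profile alignment.

The MHC class I α1-α2 region (and optionally the TCR V-domains) is
described by a fixed-length profile of match positions.  Chain sequences
are aligned to the profile once and all downstream sequence-identity math
happens in profile coordinates: two chains are compared at the match
positions both of them occupy, insertions are excluded, and residues that
fall outside the profile at either terminus are trimmed.

The aligner is a position-specific scoring matrix (PSSM) with affine gap
penalties and free terminal gaps.  It emits the same alignment contract a
profile-HMM aligner would (match-position mapping, insertion flags,
terminal trimming), and an A2M reader is provided so externally produced
HMM alignments can be ingested verbatim.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import AMINO_ACIDS, AlignmentError, InputError, Role

__all__ = [
    "INSERTION",
    "SequenceProfile",
    "ProfileAlignment",
    "build_profile",
    "align_to_profile",
    "write_profile",
    "read_profile",
    "read_a2m",
    "GAP_OPEN",
    "GAP_EXTEND",
]

#: sentinel marking a residue that sits between match positions
INSERTION = None

#: affine gap penalties, in score units: a k-long gap costs
#: GAP_OPEN + (k - 1) * GAP_EXTEND
GAP_OPEN = 10.0
GAP_EXTEND = 1.0

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class SequenceProfile:
    """Positional scoring profile for one chain role.

    ``columns`` is an (length, 20) array of per-position log-odds scores in
    the amino-acid order of :data:`tcrpmhc.core.AMINO_ACIDS`.
    """

    role: Role
    length: int
    columns: np.ndarray
    consensus: str

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.length <= 0:
            raise InputError("profile length must be positive")
        if self.columns.shape != (self.length, len(AMINO_ACIDS)):
            raise InputError(
                f"columns shape {self.columns.shape} does not match "
                f"length {self.length}"
            )
        if not np.all(np.isfinite(self.columns)):
            raise InputError("profile scores must be finite")
        if len(self.consensus) != self.length:
            raise InputError("consensus length mismatch")

    def score(self, position: int, aa: str) -> float:
        """Score of placing 1-letter residue ``aa`` at a match position.

        Unknown residues ('X' etc.) score 0, the background log-odds.
        """
        idx = _AA_INDEX.get(aa)
        if idx is None:
            return 0.0
        return float(self.columns[position, idx])


@dataclass
class ProfileAlignment:
    """A chain sequence mapped onto profile match positions.

    ``mapping`` covers the non-trimmed residues, i.e. residue
    ``trimmed_prefix + i`` of ``sequence`` maps to ``mapping[i]``, which is
    either a match-position index (strictly increasing) or
    :data:`INSERTION`.
    """

    sequence: str
    profile_length: int
    mapping: list[int | None] = field(default_factory=list)
    trimmed_prefix: int = 0
    trimmed_suffix: int = 0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.trimmed_prefix < 0 or self.trimmed_suffix < 0:
            raise AlignmentError("trimmed counts must be non-negative")
        n_core = len(self.sequence) - self.trimmed_prefix - self.trimmed_suffix
        if len(self.mapping) != n_core:
            raise AlignmentError(
                f"mapping covers {len(self.mapping)} residues but "
                f"{n_core} are non-trimmed"
            )
        cols = [m for m in self.mapping if m is not None]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise AlignmentError("match positions must be strictly increasing")
        if cols and (cols[0] < 0 or cols[-1] >= self.profile_length):
            raise AlignmentError("match position outside profile")

    @property
    def n_matched(self) -> int:
        return sum(1 for m in self.mapping if m is not None)

    @property
    def n_insertions(self) -> int:
        return sum(1 for m in self.mapping if m is None)

    def column_to_residue(self) -> dict[int, int]:
        """Match position -> absolute residue index within ``sequence``."""
        out: dict[int, int] = {}
        for i, m in enumerate(self.mapping):
            if m is not None:
                out[m] = self.trimmed_prefix + i
        return out

    def residue_for_column(self, position: int) -> str | None:
        """1-letter residue occupying a match position, or None."""
        for i, m in enumerate(self.mapping):
            if m == position:
                return self.sequence[self.trimmed_prefix + i]
        return None


def build_profile(
    msa: Sequence[str],
    role: Role | str,
    match_threshold: float = 0.0,
) -> SequenceProfile:
    """Build a scoring profile from a gapped multiple sequence alignment.

    Columns whose non-gap fraction is >= ``match_threshold`` become match
    positions; the default of 0 keeps every column (the behaviour of
    building with all alignment columns retained).  Scores are log-odds
    (base 2) of add-one-smoothed observed frequencies against a uniform
    background of 1/20.
    """
    if len(msa) == 0:
        raise InputError("MSA is empty")
    if len(msa) < 2:
        raise InputError("profile construction needs at least 2 sequences")
    width = len(msa[0])
    if any(len(s) != width for s in msa):
        raise InputError("ragged MSA: sequences have unequal gapped lengths")
    if width == 0:
        raise InputError("MSA has zero columns")

    columns: list[np.ndarray] = []
    consensus: list[str] = []
    n_seq = len(msa)
    for j in range(width):
        residues = [s[j].upper() for s in msa if s[j] not in "-."]
        if len(residues) / n_seq < match_threshold:
            continue
        counts = np.zeros(len(AMINO_ACIDS))
        for aa in residues:
            idx = _AA_INDEX.get(aa)
            if idx is not None:
                counts[idx] += 1
        total = counts.sum()
        freqs = (counts + 1.0) / (total + len(AMINO_ACIDS))
        columns.append(np.log2(freqs * len(AMINO_ACIDS)))
        if total > 0:
            consensus.append(AMINO_ACIDS[int(np.argmax(counts))])
        else:
            consensus.append("X")

    if not columns:
        raise InputError("no column passes the match threshold")
    return SequenceProfile(
        role=Role(role),
        length=len(columns),
        columns=np.vstack(columns),
        consensus="".join(consensus),
    )


def align_to_profile(seq: str, profile: SequenceProfile) -> ProfileAlignment:
    """Optimal free-terminal-gaps alignment of a sequence to a profile.

    Dynamic programming over three affine states (match, insertion,
    deletion).  Leading/trailing residues outside the aligned core are
    reported as trimmed at no cost; internal unmatched residues are flagged
    as insertions and charged the affine gap penalty, as are skipped match
    positions.  Ties are resolved preferring match over insertion over
    deletion, then the leftmost cell.
    """
    if not seq:
        raise InputError("cannot align an empty sequence")
    n, L = len(seq), profile.length
    NEG = -math.inf

    # per-residue substitution rows as plain lists (fast scalar access)
    col_matrix = profile.columns
    zero_row = [0.0] * L
    sub: list[list[float]] = []
    for aa in seq:
        idx = _AA_INDEX.get(aa)
        sub.append(list(col_matrix[:, idx]) if idx is not None else zero_row)

    # DP over three affine states; row i = prefix seq[:i]
    M_prev = [NEG] * (L + 1)
    I_prev = [NEG] * (L + 1)
    # traceback: 0=start, 1=M, 2=I, 3=D
    tb_M = [[0] * (L + 1) for _ in range(n + 1)]
    tb_I = [[0] * (L + 1) for _ in range(n + 1)]
    tb_D = [[0] * (L + 1) for _ in range(n + 1)]

    best_score, best_i, best_j = 0.0, 0, 0
    for i in range(1, n + 1):
        srow = sub[i - 1]
        M_cur = [NEG] * (L + 1)
        I_cur = [NEG] * (L + 1)
        D_cur = [NEG] * (L + 1)
        tbM_row, tbI_row, tbD_row = tb_M[i], tb_I[i], tb_D[i]
        d_left = NEG
        for j in range(1, L + 1):
            # match state: preference M > I > D > fresh start
            best, state = 0.0, 0
            v = M_prev[j - 1]
            if v > best:
                best, state = v, 1
            v = I_prev[j - 1]
            if v > best:
                best, state = v, 2
            v = D_prev[j - 1] if i > 1 else NEG
            if v > best:
                best, state = v, 3
            m = best + srow[j - 1]
            M_cur[j] = m
            tbM_row[j] = state
            if m > best_score + 1e-12:
                best_score, best_i, best_j = m, i, j

            # insertion: consumes a residue between match positions
            best, state = M_prev[j] - GAP_OPEN, 1
            v = I_prev[j] - GAP_EXTEND
            if v > best:
                best, state = v, 2
            I_cur[j] = best
            tbI_row[j] = state

            # deletion: skips a match position
            best, state = M_cur[j - 1] - GAP_OPEN, 1
            v = I_cur[j - 1] - GAP_OPEN
            if v > best:
                best, state = v, 2
            v = d_left - GAP_EXTEND
            if v > best:
                best, state = v, 3
            D_cur[j] = best
            d_left = best
            tbD_row[j] = state
        M_prev, I_prev, D_prev = M_cur, I_cur, D_cur

    if best_i == 0:  # nothing aligns: everything trimmed
        return ProfileAlignment(
            sequence=seq,
            profile_length=L,
            mapping=[],
            trimmed_prefix=n,
            trimmed_suffix=0,
            score=0.0,
        )

    # traceback from (best_i, best_j) in state M until a fresh start
    events: list[tuple[str, int | None]] = []  # per consumed residue
    i, j, state = best_i, best_j, 1
    while True:
        if state == 1:
            events.append(("M", j - 1))
            prev = tb_M[i][j]
            i, j = i - 1, j - 1
            if prev == 0:
                break
            state = prev
        elif state == 2:
            events.append(("I", None))
            prev = tb_I[i][j]
            i = i - 1
            state = prev
        else:  # deletion consumes a column only
            prev = tb_D[i][j]
            j = j - 1
            state = prev

    events.reverse()
    first_residue = i  # residues [0, first_residue) are trimmed
    mapping: list[int | None] = [col for kind, col in events]
    trimmed_prefix = first_residue
    trimmed_suffix = n - best_i
    return ProfileAlignment(
        sequence=seq,
        profile_length=L,
        mapping=mapping,
        trimmed_prefix=trimmed_prefix,
        trimmed_suffix=trimmed_suffix,
        score=float(best_score),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_profile(profile: SequenceProfile) -> str:
    """Tabular text format: header + one row per match position."""
    lines = [f"# role={profile.role}\tlength={profile.length}"]
    lines.append("# pos\tconsensus\t" + "\t".join(AMINO_ACIDS))
    for j in range(profile.length):
        scores = "\t".join(f"{s:.6f}" for s in profile.columns[j])
        lines.append(f"{j}\t{profile.consensus[j]}\t{scores}")
    return "\n".join(lines) + "\n"


def read_profile(text: str) -> SequenceProfile:
    """Inverse of :func:`write_profile`."""
    role: Role | None = None
    length = 0
    rows: list[np.ndarray] = []
    consensus: list[str] = []
    for line in io.StringIO(text):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("# role="):
            fields = dict(
                part.split("=", 1) for part in line[2:].split("\t")
            )
            role = Role(fields["role"])
            length = int(fields["length"])
            continue
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        consensus.append(parts[1])
        rows.append(np.array([float(x) for x in parts[2:]]))
    if role is None or len(rows) != length:
        raise InputError("malformed profile text")
    return SequenceProfile(
        role=role, length=length, columns=np.vstack(rows),
        consensus="".join(consensus),
    )


def read_a2m(text: str, profile_length: int) -> dict[str, ProfileAlignment]:
    """Read A2M-style aligned FASTA into :class:`ProfileAlignment` objects.

    Uppercase letters consume a match position, lowercase letters are
    insertions, '-' is a deletion (consumes a match position without a
    residue) and '.' is padding.  Leading and trailing insertions are
    reported as trimmed termini.
    """
    alignments: dict[str, ProfileAlignment] = {}
    name: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if name is None:
            return
        aligned = "".join(chunks)
        seq_chars: list[str] = []
        raw_mapping: list[int | None] = []
        col = 0
        for ch in aligned:
            if ch == ".":
                continue
            if ch == "-":
                col += 1
            elif ch.isupper():
                seq_chars.append(ch)
                raw_mapping.append(col)
                col += 1
            else:
                seq_chars.append(ch.upper())
                raw_mapping.append(INSERTION)
        if col != profile_length:
            raise InputError(
                f"record {name!r} spans {col} match columns, "
                f"expected {profile_length}"
            )
        first = next(
            (k for k, m in enumerate(raw_mapping) if m is not None), None
        )
        if first is None:
            prefix, suffix, core = len(raw_mapping), 0, []
        else:
            last = max(k for k, m in enumerate(raw_mapping) if m is not None)
            prefix, suffix = first, len(raw_mapping) - 1 - last
            core = raw_mapping[first:last + 1]
        alignments[name] = ProfileAlignment(
            sequence="".join(seq_chars),
            profile_length=profile_length,
            mapping=core,
            trimmed_prefix=prefix,
            trimmed_suffix=suffix,
            score=float("nan"),
        )

    for line in io.StringIO(text):
        line = line.strip()
        if line.startswith(">"):
            _flush()
            name = line[1:].split()[0]
            chunks = []
        elif line:
            chunks.append(line)
    _flush()
    if not alignments:
        raise InputError("no A2M records found")
    return alignments
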