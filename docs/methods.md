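# Methods

This note records the modelling assumptions, numerical choices and
limitations of the package — the decisions a maintainer or careful user
would want spelled out.

## Problem setting and scope

The package models αβ TCR – peptide – MHC class I ternary complexes by
comparative modelling.  The MHC is represented by its groove-forming
α1-α2 region only; β2-microglobulin and the α3 domain are ignored
throughout, and MHC chains are truncated to the region that aligns to
the α1-α2 profile before any downstream use.  Peptides must be 8–11
residues: template transfer requires a length-matched peptide, so
targets outside that range are rejected before modelling.  Binding
energetics, side-chain repacking, loop refinement and docking are out of
scope.

## Sequence profiles and alignment

Chains are aligned to fixed-length profiles of match positions.  The
production-scale MHC class I profile has 181 match positions; synthetic
test universes build their profiles at the same length.

The aligner is a position-specific scoring matrix with affine gap
penalties, not a full profile-HMM.  This is a deliberate simplification:
the downstream contract needs exactly three things — a monotone,
injective mapping of residues onto match positions, insertion flags, and
trimmed termini — and a PSSM with free terminal gaps provides all three
deterministically.  An A2M reader ingests externally produced HMM
alignments into the same `ProfileAlignment` contract, so an external
aligner can be substituted without touching anything downstream.

Numerical choices:

* Column scores are base-2 log-odds of add-one-smoothed residue
  frequencies against a uniform 1/20 background; unknown residues (`X`)
  score 0 (the background).
* Gap penalties are open 10, extend 1, in score units; a k-long gap
  costs `10 + (k−1)·1`.  The exhaustive-enumeration oracle in the test
  suite uses the same convention, so the DP and the oracle agree by
  definition of the scoring scheme, and the tests check the DP finds the
  optimum of that scheme.
* Terminal gaps on both sequence and profile are free; residues outside
  the aligned core are reported as trimmed.
* Traceback ties prefer match over insertion over deletion, then the
  leftmost cell.  This makes alignments deterministic.
* The match-column threshold when building a profile from an MSA
  defaults to 0: every column becomes a match position.

## Template databases

Three databases (pMHC, TCR, TCR-pMHC) are built by an ordered filter
chain with a per-stage build report:

* peptide completeness — entries whose peptide chain is absent or has
  missing residues are removed.  Missing residues are detected from the
  SEQRES-vs-ATOM difference plus residues lacking a Cα.
* resolution — entries above the cutoff (default 3 Å) are removed; the
  boundary value is kept.  Entries with no recorded resolution cannot be
  vetted and are removed.
* redundancy — a deterministic greedy pass over entries ordered best
  resolution first (ties by identifier) removes entries whose global
  identity on concatenated chain sequences reaches the threshold
  (default 100%, i.e. exact sequence duplicates only).  Chains are
  concatenated in the fixed role order; general global identity is
  computed with an edit-distance alignment (edlib).

Which duplicate to keep is not dictated by the redundancy concept; the
package keeps the best-resolved copy, ties broken by smallest
identifier.  Externally supplied profile-search hit tables can be
pre-filtered at E ≤ 1e-5 and bit score > 250, the documented discovery
thresholds; the package does not itself scan sequence databases.

## Identity scoring and template selection

Per-chain identity compares residues only at match positions occupied by
both sequences; insertions count for neither matches nor length, and the
denominator is the number of match positions the *target* occupies.
Peptides are compared ungapped over their full (equal) length — the only
consistent reading given that no peptide profile exists and templates
are length-filtered.

The weighted composites are ½/½ (pMHC), ⅓/⅓/⅙/⅙ (full complex) and,
for the TCR stage's internal use, ½/½ over the two TCR chains.

Design choices where the rules left room:

* The pairwise identity used in the 95% redundancy test between
  templates is the same composite (weighted when the method is weighted)
  used for target scoring — one identity definition per method.
* The leave-one-out identity cap applies to the method's own ranking
  score: weighted for *Weighted methods, unweighted otherwise.
* The cap is strict (`score < cap`), so a 100%-identical template is
  excluded at a cap of 99.9%.
* No limit on how many templates the Multi* methods may admit.
* The Random baseline draws uniformly from the same length-filtered,
  cap-filtered candidate pool as the other methods, so it differs only
  in the choice rule.
* Score ties anywhere resolve lexicographically by identifier.

## Model building

The default backend is a coordinate graft chosen for determinism and
exact testability; it is described as what it is, a rigid-transfer
builder, and sits behind a backend interface so an external
restraint-satisfaction program can be plugged in via the written
PIR alignment and the `register_backend` seam.

* Selected templates are first mutually superposed onto the top-ranked
  one (Cα Kabsch over shared profile columns across all stage chains).
* Each target residue with a profile column takes backbone atoms
  (N, CA, C, O) as the weighted average over covering templates; weights
  are the templates' composite identities, renormalized per column.
* Side-chain atoms are copied from the highest-identity covering
  template only when the template residue type equals the target's.
* Residues covered by no template are marked UNSUPPORTED and receive a
  linearly interpolated (or terminally extrapolated) Cα only.
* If no single template covers more than half of some chain the build
  fails rather than extrapolating a mostly-unsupported chain.

Assembly treats the sub-models as the sole source of internal geometry
and the complex templates as the sole source of relative orientation.
Complex templates are registered into a common frame by their *receptor*
(pMHC) portion only — registering on all chains would absorb part of the
very TCR-placement signal the templates carry.  Each sub-model is
superposed onto each chosen template's corresponding portion; the placed
Cα clouds are averaged with identity weights; and the sub-model is then
rigidly fitted (Kabsch) onto the averaged cloud.  Fitting the rigid
sub-model to the averaged cloud, rather than keeping the raw average,
preserves intra-component geometry exactly (a raw average of two
differently-rotated copies is not rigid) while reproducing the intuitive
midpoint placement when templates disagree by a pure translation.
Placements that disagree by more than 5 Å pairwise Cα RMSD are flagged
in the run report; they are still averaged, which is exactly the failure
mode to expect for targets with non-canonical binding orientations (see
Limitations).

The TCR stage uses the same graft machinery with the ½/½ scheme; a
canonical-structure CDR-grafting builder is not re-implemented, and an
external TCR builder can be attached through the backend seam, with its
output validated against the TCR stage contract.

## Evaluation metrics

* Superposition is closed-form Kabsch via SVD with the determinant
  correction, so reflections are never returned.  Geometry with fewer
  than 3 pairs or collinear points is rejected.
* Component RMSDs superpose on the component's own Cα pairs and report
  the RMSD over those same pairs.  Residues are paired by (role, dense
  index).
* TM-score is computed after the single global Cα superposition (no
  TM-align-style rotation search), normalized by the native residue
  count; unpaired native residues contribute 0.  `d0` uses the standard
  `1.24·(L−15)^⅓ − 1.8` with a 0.5 Å floor.
* DockQ: receptor = pMHC, ligand = TCR.  Fnat uses a 5 Å heavy-atom
  contact cutoff (inclusive boundary); interface residues for iRMS use
  10 Å; the combination constants are 1.5 Å (iRMS) and 8.5 Å (LRMS).
  These four constants are the cited community conventions, are not
  derivable from this package's own data, and are exposed as overridable
  parameters.  Class boundaries 0.23/0.49/0.80 are lower-inclusive.
* Backbone = {N, CA, C, O}; heavy atoms = all non-hydrogen.
* A generic residue-subset RMSD is provided for loop-level analyses; no
  CDR boundary definition is shipped, since none is pinned down by the
  available inputs.

## Leave-one-out benchmark

Each database entry is remodelled with itself excluded from the
candidate pool, at identity caps of 99.9/95/90/80% (and optionally
uncapped), and evaluated against its held-out native.  Targets are
modelled in a single comparative stage against their own database
(a pMHC database yields pMHC grafts, the complex database yields direct
complex grafts); the three-stage pipeline is exercised separately, and
this choice keeps each database's benchmark self-contained.  Records
with no surviving candidate are emitted as SKIPPED and excluded from
medians and statistics.  Per-cell seeds derive deterministically from
the run seed, so reruns are byte-identical.

Wilcoxon signed-rank comparisons are delegated to scipy with the
zero-discard convention; all-tied comparisons are reported as degenerate
with p = 1 rather than an error.  Summaries report per-(method,
threshold) medians/IQRs and also pool thresholds per method, since both
poolings are in common use.

## Synthetic data

The fixture generator emulates the *algorithmic* structure of the
problem, not biophysics.  A toy complex has: an MHC of 181 residues laid
out as two long antiparallel helices joined by a short cross-groove
connector (consecutive Cα spacing exactly 3.8 Å), an 8–11mer peptide as
a pleated extended strand in the groove, and two 30-residue TCR helices
docked above it with a genuine ≥10-contact heavy-atom interface at 5 Å.
Backbone N/C/O (and CB) atoms are placed schematically around each Cα.

Template universes derive entries from a per-length probe complex by
(a) mutating sequences to engineered identities (default spectrum 0.99
down to 0.55, cycled) and (b) adding per-atom Gaussian coordinate noise
with σ = 2.5 Å · (1 − identity).  The σ scaling is the one substantive
modelling assumption in the fixtures: it makes sequence identity
genuinely predictive of structural closeness, which is the property
template selection exploits on real data.  Under it, the benchmark
orderings (weighted multi-template beating random; tighter identity caps
never hurting) emerge from the method rather than being wired into the
data.  Default universe size is 20 entries over peptide lengths
{8: 4, 9: 8, 10: 5, 11: 3} — large enough for paired statistics, small
enough that the full suite runs in well under a minute.

What passing on fixtures does *not* show: accuracy on real complexes.
The fixtures have no real fold, no canonical/non-canonical docking
geometry dichotomy, uniform residue usage, and noise that is honest
about rank order but not about magnitudes.  Absolute RMSD values from
fixture benchmarks are meaningless; only identities, orderings and
invariances transfer.

Named defect options (`missing_peptide_residue`, `no_resolution`)
deliberately break single properties so each database filter can be
tested in isolation.

## Determinism

Every stochastic step (sequence draws, mutations, noise, the random
baseline) flows from explicit integer seeds; fixture PDB output is
byte-identical across runs.  All tie-breaks are pinned (lexicographic
identifiers, match>insertion>deletion, leftmost cell), so selection and
building are deterministic given a database.

## Known limitations

* The graft backend transfers template geometry rigidly: it cannot
  relieve clashes, close loops across unsupported gaps, or adapt CDR
  conformations to the groove.  Models inherit every template artifact.
* TCR modelling lacks canonical-structure awareness; accuracy on real
  TCRs rests entirely on template availability.
* Assembly averages placements even when complex templates fundamentally
  disagree (non-canonical binding orientations); the report flags but
  does not resolve such cases.
* Peptides are modelled only at identical template length; no indel
  modelling in the groove.
* The PSSM aligner does not reproduce any specific external HMM
  aligner's alignments; exact reproduction of externally built MSAs is
  not claimed.
* mmCIF, glycans, waters, ions, altloc ensembles beyond the first, and
  B-factor semantics are not handled.
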