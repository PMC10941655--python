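# Methods

## Problem setting

A shared subunit S participates in two alternative complexes: state 1 with
a specific partner P₁ (plus possibly shared components) and state 2 with
partner P₂. The goal is a set of mutations in S that abolishes state 1
while preserving state 2. The pipeline's premise is geometric: residues of
S that touch P₁ but no component of state 2 can be mutated freely with
respect to state 2, and mutating them to bulky or charge-enlarged residues
that sterically clash with P₁ should selectively block state-1 assembly.

## Model building by coordinate grafting

Full homology modelling is replaced by deterministic alignment-guided
grafting: the target sequence is globally aligned to the template chain's
sequence (Needleman–Wunsch, affine gaps, BLOSUM62, gap open 11 / extend 1
— standard protein defaults), and each aligned target residue inherits
the template backbone coordinates while carrying the target identity.
Identical residues keep the template side chain; mismatches are truncated
to N, CA, C, O, CB, with CB rebuilt at ideal tetrahedral geometry
(CA–CB 1.53 Å, N–CA–CB 110.4°, C–N–CA–CB −122.5°) when the template lacks
it. Unaligned target residues are recorded as unmodelled, never invented.
This is sufficient because the differential-interface decision depends on
backbone-scale proximity, not on side-chain detail; avoiding loop building
and energy minimisation keeps the whole pipeline bit-reproducible.

Assembly superposes every grafted chain onto its template counterpart
with the Kabsch algorithm (SVD with determinant correction; CA anchors
only, which is robust to side-chain differences) and then relieves
residual inter-chain overlap by translating each partner chain rigidly
along the axis from the fixed chains' interface centroid to its own
interface centroid, in 0.25 Å steps up to 5 Å, until the heavy-atom
soft-sphere overlap score reaches zero. The step never increases overlap;
chains not in contact within 8 Å are left untouched with a warning.

## Differential interface

A residue pair is a *contact* when the minimum distance over heavy-atom
pairs is ≤ a cutoff (default 4.5 Å; typical heavy-atom interface contacts
span 3.2–4.5 Å, and no specific threshold is canonical, so the value is a
config knob and sweeps are cheap). The differential interface keeps
shared-subunit residues that contact the included partner in model 1 and
whose minimum distance to *every* excluded partner exceeds cutoff +
exclusion margin (default 1.5 Å). The margin is a safety buffer: grafted
models carry coordinate error, so "does not bind" is asserted only with
slack. The margin makes the differential set shrink monotonically as it
grows — there are no re-inclusion paths.

Residue correspondence between the two models is by author residue
number, which the grafting stage preserves from the target sequence;
residues present in only one model are dropped from consideration and
reported. Mapping is therefore exact and symmetric, and a residue-identity
disagreement aborts the run (the models must derive from the same target
sequence).

## Orthologue-gap ("unique loop") regions

Partner regions present in the reference species but absent from all
orthologues in an alignment are candidate species-specific assembly
determinants. They are detected as maximal runs of ≥ `min_len` (default 3)
alignment columns where the reference row has residues and all other rows
have gaps, mapped to half-open residue intervals on the ungapped
reference. Sub-triplet gap blocks are treated as alignment noise.
Differential residues with at least one contact inside such a region are
flagged; the flag is annotation, not a filter.

## Mutation rules and geometric checks

Residue classes: hydrophobic {A,V,L,I,M,F,W,Y}, positive {K,R}, negative
{D,E}, polar uncharged {S,T,N,Q}, special {G,P,C,H}. G and P shape the
backbone, C may form disulfides and H's charge is pH-dependent, so none
is handled by an automatic rule. Rules: hydrophobic → Q (aromatic
targets are marked "aggressive" in the proposal notes); K → R and D → E
(the only larger standard residues of the same charge — R and E have no
size-up option and are flagged for manual choice with the wild type
retained, as are polar-uncharged and special residues).

The designed clash is scored with mutant side chains built at ideal
internal coordinates over a small fixed rotamer library (χ ∈ {−60°, 60°,
180°} for up to three rotatable bonds, further χ extended; ≤ 27 rotamers —
coverage, not energy ranking, is the goal; ring closures are idealised).
Overlap per rotamer is Σ max(0, rᵢ + rⱼ − d)² over mutant-atom /
partner-heavy-atom pairs with a fixed embedded Bondi-style radius table;
the score is zero iff no pair interpenetrates, and any monotone overlap
measure serves the qualitative clash criterion. The report keeps the
min-over-rotamers (0 required to call "no clash") and max-over-rotamers
(> 0 for every rotamer required to call the clash unavoidable).

Exposure: the mutated residue's SASA is computed on the shared subunit
alone (partners removed, mutant side chain in the extended rotamer) by
Shrake–Rupley counting on a deterministic golden-spiral quadrature
(default 960 points; the binary exposure decision uses 240 points, whose
<2% quadrature error is immaterial at a 0.2 threshold), normalised by
fixed Gly-X-Gly theoretical maxima. Proposals below 0.2 relative SASA are
dropped by default — a buried polar mutation risks destabilising the fold
rather than the targeted interface.

Grouping merges proposals within a 10-residue sequence window (an
explicit partition can be supplied instead); all 2ᵍ − 1 non-empty unions
of the g groups are enumerated with canonical names K1, K2, …, K12…g. For
the canonical nine-residue Tor2 target set this reconstruction yields
{740,742}, {768–781}, {817,818} and the seven combinations K1…K123; the
window grouping is a reconstruction of a partition that is not derivable
from sequence alone, hence the explicit-partition escape hatch.

## Synthetic fixtures and what they do (not) show

Fixtures are ideal helices (CA rise 1.5 Å, 100°/residue, radius 2.3 Å;
N/C on the same curve at ∓0.35-residue phase, O axial, CB radial), with
partner chains placed as one residue per focal residue of a declared
interval, on the outward radial ray through the focal CB at exactly the
approach distance (default 4.0 Å). Backbone atoms of the comb are offset
along the helix axis only, so the construction's reach toward residues
outside the interval is minimal: the nearest out-of-interval focal atom
sits ≥ ~6.5 Å from the partner. Ground-truth interface and differential
sets are therefore the declared intervals and their set differences —
derived from the construction, never re-measured — and recovery at the
default cutoffs is exact for arbitrary (including overlapping and
abutting) footprints.

Noise robustness is bounded by the construction margins: with planted
contacts at 3.5 Å and at least a two-residue gap between interval edges,
per-atom Gaussian noise of σ = 0.3 Å leaves ≥ 95% of seeded fixtures
exactly recovered (the planted-contact margin to the 4.5 Å cutoff is
~2.4σ of a pair distance). Abutting footprints under noise sit on a
~0.5 Å margin and are legitimately ambiguous; the robustness property is
claimed only in the documented regime.

Fixtures are analytic helices, not folded domains: they exercise the
geometry, bookkeeping and rule logic of the pipeline, not the accuracy of
grafted models for real proteins. Passing fixture tests shows the method
computes its stated definitions exactly; it does not validate the
biological premise that a geometric differential interface predicts
assembly specificity — that validation is experimental by nature.

## Numerical choices

- Alignment ties are broken by taking the aligner's canonical first
  traceback; scores are oracle-checked against an independent Gotoh DP.
- Percent identity is reported under three denominators (aligned pairs,
  columns, shorter sequence) because printed identities rarely state one.
- Kabsch refuses < 3 pairs or collinear anchor sets (rotation ill-posed).
- Altloc handling keeps the highest-occupancy conformer (ties by letter);
  hydrogens and waters are dropped on read; first model only.
- Contact search uses a k-d tree and is property-tested against the
  brute-force all-pairs oracle; SASA is validated against the closed-form
  isolated-atom area and a constructed fully-buried cage.
- Problem sizes in tests and the acceptance script (50–100 seeds,
  60-residue fixtures, 100-atom contact oracles) were chosen as the
  smallest sizes at which every property is exercised across many random
  geometries; all are seeded and reproducible.

## Limitations

- No energetics: no ΔΔG, no repacking, no stability or expression
  prediction — a design can clash perfectly and still destabilise the
  protein (combinations stacking many mutations are flagged by count, not
  by physics).
- Grafted backbones inherit template error; the exclusion margin absorbs
  some of it but cannot rescue a wrong template or register shift.
- The rotamer library is coarse; a partner could in principle avoid a
  clash through backbone flexibility invisible to rigid models.
- Unique-region detection depends entirely on the supplied orthologue
  alignment's quality and taxon sampling.
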