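# Methods

This package analyses the architecture of the eukaryotic 2-oxoglutarate
dehydrogenase complex (OGDHC) — an octahedral core of 24 E2o subunits
(8 trimers) decorated with E1o dimers, E3 dimers and the adaptor protein
MRPS36 — using three complementary kinds of evidence: cross-linking MS
distance restraints, complexome-profiling co-migration, and homolog
conservation. Every computation is exercised end to end on synthetic data
with recorded ground truth; this note describes the models behind each
stage, the parameters that matter, and what the synthetic validation does
and does not establish.

## Structures and numbering

Structures are held as a chain → residue → atom hierarchy read from
PDB/mmCIF via gemmi. Author residue numbering is authoritative and is never
rewritten on read: cross-link tables address residues in author numbering,
and any renumbering would silently shift every restraint. Modified residues
and cofactors (lipoyllysine, TPP, FAD) are retained as ordinary residues so
distances to them can be measured; waters are dropped by default
(`keep_waters=True` retains them). Where a file carries alternate
conformations, only the highest-occupancy conformer is kept — distance
thresholds are single-conformer quantities. On write, mmCIF is selected
automatically when a structure exceeds the 62 single-character chain ids
the PDB format can express.

Sequence masses are **average** (not monoisotopic) masses from the IUPAC
average residue-mass table plus one water (18.0153 Da). MDa-scale
stoichiometric masses are compared against gel-derived apparent masses,
which are average-mass quantities; monoisotopic masses would be wrong by
design here. The implementation agrees with Biopython's average-mass
computation to < 0.005 Da per residue (checked in a unit test); the small
discrepancy reflects the atomic-weight revisions behind the two tables.

## Cross-link restraint mapping

A cross-link identifies a residue pair in **precursor numbering**, i.e.
including the mitochondrial transit peptide that is absent from the mature,
modelled protein. A per-component integer offset (`NumberingMap`) converts
table numbering to structure numbering; offsets default to 0 and are
user-supplied, since deposited tables rarely state them.

On a multi-copy structure the pair is ambiguous over copies. The restraint
distance is defined as the **minimum Euclidean Cα–Cα distance over all
ordered chain pairs whose component labels match the cross-link's protein
names**. This minimum rule is the standard resolution for homo-oligomers
and the only rule consistent with validating a model whose core alone has
24 identical copies: a cross-link is explained if *any* copy pair explains
it. A single 30 Å cutoff is applied to all three linker chemistries (DSSO,
PhoX, DMTMM), overridable per call; the conventional Cα–Cα criterion for
DSSO-class linkers. Solvent-accessible surface distances are out of scope.

Degenerate self-links (same protein, same residue on both sides) are
rejected as invalid input at parse time and raise if passed to mapping
directly — in table terms such a row is indistinguishable from a trivial
zero-distance pair. A cross-link naming an unknown component or a residue
outside the modelled range is reported `unmapped` with a reason, never a
hard failure: real tables always contain links into unmodelled flexible
regions.

Summaries report counts, the satisfied fraction, and the **median and
maximum distance over mapped restraints only**, both pooled and per linker
chemistry (whether published medians pool chemistries is usually unstated,
so both views are computed). Zero mapped restraints yields `None`
statistics, not an error.

## Rigid-body assembly

The full model is assembled the way hybrid-modelling studies do it: each
pairwise interface sub-model (an E1o dimer bound to one E2o subunit, or an
E3 dimer plus MRPS36 bound to another) carries one **anchor chain** whose
component matches a designated chain of the reference core. The anchor is
superposed onto the core chain over their **common residues' Cα atoms**
(intersection by author number — prediction-derived sub-models and
experimental cores differ in modelled ranges), the resulting rigid
transform is applied to the whole sub-model, the anchor chain itself is
discarded (the core's copy is kept), and the remaining chains enter the
model under fresh ids. Placing two sub-models on one core chain, mismatched
component labels, or fewer than 3 shared Cα positions are errors.

Superposition is the closed-form Kabsch solution: SVD of the
cross-covariance of the centred point sets, with the smallest singular
direction sign-corrected so the returned rotation is proper (det +1);
reflections are never returned. Collinear point sets are rejected (the
rotation about the line is undetermined). The implementation is verified
three ways: exact recovery of known transforms, agreement with an
exhaustive 0.1° rotation-grid oracle on a planar three-point case, and
agreement with scipy's independent `Rotation.align_vectors`.

The default recipe is data, not code: 8 peripheral-dimer sub-models
anchored on one chain of each core trimer and 6 dimer+adaptor sub-models
anchored on a second chain of six trimers, reproducing the 24 : 16 : 12 : 6
chain stoichiometry. Which specific core chains serve as anchors is an
explicit, editable part of the recipe.

A component ledger (name, copies, monomer mass in kDa) is validated against
actual chain counts after every assembly; the stoichiometric mass is
Σ copies × monomer mass. With the rounded monomer masses 111 (E1o),
41 (E2o), 50 (E3) and 11 (MRPS36) kDa the default stoichiometry gives
3426 kDa = 3.426 MDa; full-sequence masses of the same stoichiometry land
slightly higher (≈3.45 MDa), and both figures are reported where relevant
rather than reconciled, since they answer with different inputs.

Clash detection reports all heavy-atom pairs from **different rigid
bodies** (core vs each placement) closer than a cutoff, default 2.0 Å — a
conventional hard-sphere overlap criterion; contacts involving annotated
flexible regions (e.g. the E2o linkers connecting the lipoyl domain to the
catalytic core, which are known to clash in rigid placements) can be
excluded and are counted separately. The k-d-tree search is held equal to
an O(n²) brute force in tests. Remodelling clashing loops is out of scope;
clashes are flagged, not fixed.

## Complexome profiling

Migration profiles (protein × gel slice intensity, 56 slices by default,
1-based slice numbering) are normalized per protein to maximum 1 (sum
normalization available); all-zero rows are flagged, not divided. BN-PAGE
migration is log-linear in complex mass, so calibration is a least-squares
fit of log₁₀(mass/kDa) against slice index over ≥ 2 markers; the fit form
is the package's choice, as published apparent masses rarely state their
calibration. Peaks are local maxima above a relative height floor
(default 0.2) refined to sub-slice positions by 3-point parabolic
interpolation, with no smoothing by default (optional window-3 moving
average); apparent mass is the calibration evaluated at the refined
position. Co-migration is scored as pairwise Pearson correlation of
normalized profiles; zero-variance profiles have undefined correlations,
reported as NaN.

## Homolog selection and conservation

BLAST hits are filtered for phylogenetic analysis in a fixed rule order:
(1) rank by bitscore (ties broken by e-value, then subject id — making the
filter permutation-invariant) and truncate to the top 500; (2) keep hits
with query coverage strictly above 50% and identity strictly below 90%;
(3) collapse to the best hit per species; (4) keep at most 4 species per
genus. The order matters to the counts and is therefore explicit and
configurable. Hits without parseable taxonomy are excluded and counted.
One consequence of the genus cap worth noting: deleting a selected hit
from the input can promote the next-best species of that genus, so the
filter is monotone in the sense that the output never grows and surviving
selections persist — not in the stronger sense of set containment.

Alignment conservation counts invariant columns: identical non-gap residue
in every row, with a strict policy (any gap disqualifies, the default,
matching curated gap-free alignment blocks) and a lenient one (gaps
ignored; all-gap columns never count). The fraction is n_invariant over
total columns.

## Synthetic data: what it emulates, and what it does not

The generators produce, deterministically per seed:

* **Toy complexes** — CA-only pseudo-helical chains (2.3 Å radius, 1.5 Å
  rise, 100°/residue), core copies on a sphere with near-uniform spacing.
  The miniature preset places 8 trimers of 30-residue chains at cube
  corners (radius 55 Å) with peripheral 25-residue dimers 30 Å further
  out, mirroring the octahedral core + antenna layout at toy scale. Each
  sub-model is emitted in its own random rigid frame so assembly must
  genuinely recover the superposition. CA-only is deliberate: every
  in-scope distance is CA- or whole-residue-level, so side chains would
  add nothing testable.
* **Cross-links** — true links drawn uniformly from residue pairs whose
  minimum-over-copies CA distance (jittered by Gaussian noise of chosen σ)
  is within the linker reach, default 25 Å; decoys, default 5% of rows
  matching the FDR cross-link identification is controlled at, drawn
  uniformly over all pairs. The recorded true distance is the
  minimum-over-copies value, exactly what mapping should recover, and
  per-component offsets can be added to exercise numbering maps.
* **Profiles** — each member of a complex of known mass gets a Gaussian
  peak (σ = 1.5 slices, resembling observed complexome peak widths) at the
  slice given by inverting a log-linear calibration spanning 5 MDa to
  10 kDa over the gel, optional monomer peaks, and multiplicative
  log-normal noise.
* **BLAST hits** — genera with a known number of qualifying species
  (identity/coverage drawn inside the passing ranges) plus per-genus
  disqualified species failing one threshold each.

Passing recovery tests on these fixtures establishes the *computational*
correctness of the pipeline — the minimum rule equals brute force, true
links are fully satisfied and decoys less often, apparent masses are
recovered within 5% at σ = 0.05 and 15% at σ = 0.2, the genus cap retains
exactly min(4, qualifying). It does **not** establish anything about real
data quirks the generators omit: side-chain geometry and SASD effects,
non-Gaussian gel peak shapes, baseline and carry-over between slices,
incorrect taxonomy strings, or identification-score structure. One
emergent property of the synthetic geometry worth knowing: because decoy
distance is also minimized over many copies of a compact complex, decoy
satisfaction on the miniature assembly is high in absolute terms (~80% at
30 Å) — the discriminating signal is the *gap* to the 100% of true links,
which is the property asserted.

## Problem sizes and determinism

All shipped analyses and checks run on the miniature complex (58 chains,
~1600 CA atoms), 200 simulated cross-links, 56-slice profiles and ≤ 50-row
hit tables — sizes chosen so the complete pipeline, test suite and
reproduction script finish in seconds while still exercising the 24-copy
ambiguity, the 14-placement recipe and the genus cap at full structural
complexity. Every stochastic step takes an explicit integer seed
(`numpy.random.default_rng`); identical seeds reproduce identical bytes in
all generator outputs.

## Known limitations

* No solvent-accessible surface distances; the 30 Å Euclidean criterion is
  conservative for buried residue pairs.
* Transit-peptide offsets must be supplied by the user; they are not
  inferred from sequence databases.
* Clash handling flags and optionally excludes; it never remodels.
* The comigration peak caller assumes reasonably isolated peaks; heavily
  overlapping species closer than ~2 slices merge into one call.
* Validation against the published depositions (the 24-chain core entry
  and the deposited full model with its cross-link table) requires placing
  those third-party files under `data/external/`; they are not
  redistributed, and the corresponding acceptance tests fail with
  instructions in their absence.
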