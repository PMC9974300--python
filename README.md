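# ogdhc

Integrative structural-MS analysis of the eukaryotic 2-oxoglutarate
dehydrogenase complex (OGDHC), the megadalton TCA-cycle enzyme built from
E1o (OGDH), E2o (DLST), E3 (DLD) and the small adaptor protein MRPS36.
The package implements, as a tested pipeline with a synthetic-data
generator, the computational steps by which cross-linking mass spectrometry
(XL-MS), complexome profiling (CP) and rigid-body modelling establish a
subunit's membership in a complex and assemble a full-complex model:

* **Cross-link restraint mapping** — residue pairs identified by XL-MS
  (DSSO, PhoX, DMTMM chemistry) are mapped onto a multi-copy structure.
  For a homo-oligomer the pair is ambiguous over copies, so the restraint
  distance is the minimum Cα–Cα Euclidean distance over all chain pairs
  whose component labels match; a restraint is satisfied when
  *d* ≤ 30 Å. Summaries report counts, satisfied fraction, and the median
  distance over mapped restraints, pooled and per linker.
* **Rigid-body assembly** — pairwise interface sub-models (E1o dimer on an
  E2o subunit; E3 dimer + MRPS36 on an E2o subunit) are placed onto a
  24-copy E2o core by Kabsch least-squares superposition
  (SVD of the cross-covariance matrix with determinant correction, proper
  rotations only) of shared Cα positions. A component ledger tracks
  copies and monomer masses; heavy-atom clashes between rigid bodies are
  detected with a k-d tree verified against brute force.
* **Stoichiometry and mass accounting** — the full assembly carries
  24 E2o + 16 E1o + 12 E3 + 6 MRPS36 chains; with monomer masses
  111/41/50/11 kDa the stoichiometric mass is
  16·111 + 24·41 + 12·50 + 6·11 = 3426 kDa ≈ 3.4 MDa.
* **Complexome profiling** — BN-PAGE migration profiles are
  max-normalized; gel slices are calibrated to mass by a log-linear fit
  log₁₀(mass) = a·slice + b; peaks are called as local maxima with 3-point
  parabolic interpolation and converted to apparent masses; co-migration is
  scored by pairwise Pearson correlation.
* **Homolog selection** — BLAST hits are filtered for phylogenetic
  analysis: top 500 by bitscore, query coverage > 50%, identity < 90%,
  best hit per species, at most 4 species per genus; curated alignments
  are summarized by their invariant-site fraction.

Every stage has a synthetic generator with recorded ground truth (toy
multi-chain complexes, cross-link tables with a 5% decoy fraction matching
the identification FDR, Gaussian migration profiles on a log-mass axis,
hit tables with known genus structure), so the whole pipeline runs and is
validated offline.

## Worked example

The numbered drivers under `analysis/` run the pipeline on synthetic data:

```sh
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_assemble_model.py
python analysis/03_map_crosslinks.py
python analysis/04_comigration.py
python analysis/05_homolog_selection.py
```

which prints (seed 1):

```
assembled 58 chains from 14 placements
worst placement RMSD: 3.05e-07 Å
stoichiometric mass: 3426 kDa = 3.426 MDa
...
200/200 mapped, 191 satisfied (95.5%), median 13.2 Å, max 40.0 Å
  true links: 100.0% satisfied
  decoys: 82.0% satisfied
...
untreated: ... E2o: peak at slice 7.5 -> 2406 kDa
crosslinked: ... E2o: peak at slice 4.4 -> 3387 kDa
...
48 hits -> ... -> 24 selected
curated alignment: 5 invariant of 128 sites (3.9%)
```

Reading: the 14 sub-models land on their designated core chains
essentially exactly (RMSD ~10⁻⁷ Å, limited by coordinate round-trip
precision), giving the 24/16/12/6 chain stoichiometry and 3.426 MDa.
Simulated cross-links within the 25 Å linker reach are all satisfied at
30 Å, while decoys are satisfied only as often as chance places a random
pair within reach of *some* copy — strictly less often. The complexome
profiles recover the 2.4 MDa (partially assembled) versus 3.4 MDa (fully
stabilized) apparent-mass shift, and the genus cap retains exactly 4 of 6
qualifying species per genus.

The same operations are available as a CLI (`ogdhc structure info`,
`ogdhc map-xl`, `ogdhc assemble`, `ogdhc cp`, `ogdhc filter-hits`,
`ogdhc simulate`).

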