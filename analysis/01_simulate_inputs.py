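#!/usr/bin/env python
"""Generate every input the downstream analyses consume.

Writes, under results/inputs/:
  core.cif / submodel_XX.cif / recipe.yaml / components.yaml — the miniature
    24-copy core with its 14 peripheral sub-models and assembly recipe;
  crosslinks.csv — 200 simulated cross-links (25 Å reach, 25% decoys) drawn
    on the ground-truth assembled complex;
  profiles_untreated.tsv / profiles_crosslinked.tsv / markers.tsv — synthetic
    complexome profiles for a 2.4 MDa partially assembled and a 3.4 MDa fully
    stabilized complex;
  blast_hits.tsv — a simulated homology hit table with genus structure.
"""

import argparse
from pathlib import Path

import yaml

from ogdhc import synthetic_data as sd
from ogdhc.structure_io import write_structure


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/inputs"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    mini = sd.make_mini_ogdhc(seed=args.seed)
    write_structure(mini.core, out / "core.cif")
    for i, sm in enumerate(mini.submodels):
        write_structure(sm, out / f"submodel_{i:02d}.cif")
    (out / "recipe.yaml").write_text(yaml.safe_dump([list(e) for e in mini.recipe]))
    # chain ids are only unique within one file, so component labels are
    # recorded per structure
    components = {
        "core": {c.id: c.component for c in mini.core.chains},
        "submodels": [{c.id: c.component for c in sm.chains} for sm in mini.submodels],
    }
    (out / "components.yaml").write_text(yaml.safe_dump(components))
    write_structure(mini.assembled_reference, out / "reference_model.cif")
    ref_components = {c.id: c.component for c in mini.assembled_reference.chains}
    (out / "reference_components.yaml").write_text(yaml.safe_dump(ref_components))
    print(f"core: 24 chains in 8 trimers; {len(mini.submodels)} sub-models")

    sim = sd.simulate_crosslinks(
        mini.assembled_reference, n=200, max_dist=25.0, decoy_frac=0.25, seed=args.seed
    )
    sim.write(out / "crosslinks.csv")
    print(f"crosslinks: {len(sim.crosslinks)} rows, {sum(sim.is_decoy)} decoys")

    for label, mass, members in [
        ("untreated", 2400.0, ["E1o", "E2o"]),
        ("crosslinked", 3400.0, ["E1o", "E2o", "E3", "MRPS36"]),
    ]:
        matrix, markers = sd.simulate_cp_profiles(
            [sd.CPComplexSpec(members, mass)], noise_sd=0.05, seed=args.seed
        )
        matrix.to_csv(out / f"profiles_{label}.tsv", sep="\t")
    with open(out / "markers.tsv", "w") as fh:
        fh.write("slice\tmass_kda\n")
        for s, m in markers:
            fh.write(f"{s:.4f}\t{m:.4f}\n")
    print("profiles: 56 slices, untreated (2.4 MDa) and crosslinked (3.4 MDa)")

    blast = sd.simulate_blast_hits(n_genera=6, species_per_genus=6, seed=args.seed)
    with open(out / "blast_hits.tsv", "w") as fh:
        for h in blast.hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity * 100:.2f}\t0\t0\t0\t0\t0\t0\t0\t"
                f"{h.evalue:.3g}\t{h.bitscore:.1f}\t{h.species}\t{h.query_coverage * 100:.1f}\n"
            )
    print(f"blast hits: {len(blast.hits)} rows across 6 genera")


if __name__ == "__main__":
    main()
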