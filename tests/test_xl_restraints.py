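"""Cross-link parsing, multi-copy mapping (vs brute force) and summaries."""

import itertools

import numpy as np
import pytest

from ogdhc import synthetic_data as sd
from ogdhc.structure_io import Structure
from ogdhc.xl_restraints import (
    CrossLink,
    MappedRestraint,
    NumberingMap,
    map_restraints,
    measure_distance,
    parse_crosslink_table,
    summarize_restraints,
)


def brute_force_min_distance(structure, link, numbering=None, atom="CA"):
    """Independent oracle: exhaustive minimum over all ordered chain pairs."""
    numbering = numbering or NumberingMap()
    na = numbering.to_structure(link.protein_a, link.residue_a)
    nb = numbering.to_structure(link.protein_b, link.residue_b)
    best = None
    for ca, cb in itertools.product(structure.chains, structure.chains):
        if ca.component != link.protein_a or cb.component != link.protein_b:
            continue
        if ca.id == cb.id and na == nb:
            continue
        ra, rb = ca.residue(na), cb.residue(nb)
        if ra is None or rb is None:
            continue
        aa, ab = ra.atom(atom), rb.atom(atom)
        if aa is None or ab is None:
            continue
        d = float(np.linalg.norm(np.subtract(aa.position, ab.position)))
        if best is None or d < best:
            best = d
    return best


class TestParse:
    HEADER = "protein_a,residue_a,protein_b,residue_b,linker,score\n"

    def test_three_rows(self, tmp_path):
        p = tmp_path / "xl.csv"
        p.write_text(self.HEADER + "E2o,43,E3,100,DSSO,90\nE2o,57,MRPS36,12,PhoX,80\nE1o,5,E2o,160,DMTMM,70\n")
        report = parse_crosslink_table(p)
        assert len(report.crosslinks) == 3
        assert report.n_duplicates == 0 and not report.invalid_rows

    def test_duplicate_row_collapsed_and_counted(self, tmp_path):
        p = tmp_path / "xl.csv"
        p.write_text(self.HEADER + "E2o,43,E3,100,DSSO,90\nE2o,43,E3,100,DSSO,90\nE1o,5,E2o,160,DMTMM,70\n")
        report = parse_crosslink_table(p)
        assert len(report.crosslinks) == 2
        assert report.n_duplicates == 1

    def test_invalid_rows_reported_not_dropped_silently(self, tmp_path):
        p = tmp_path / "xl.csv"
        p.write_text(self.HEADER + "E2o,0,E3,100,DSSO,90\nE2o,58,E2o,58,DSSO,90\nE1o,5,E2o,160,DMTMM,70\n")
        report = parse_crosslink_table(p)
        assert len(report.crosslinks) == 1
        assert len(report.invalid_rows) == 2
        reasons = " ".join(r for _, r in report.invalid_rows)
        assert "degenerate" in reasons

    def test_missing_column_lists_available(self, tmp_path):
        p = tmp_path / "xl.csv"
        p.write_text("protein_a,residue_a\nE2o,43\n")
        with pytest.raises(ValueError, match="protein_b"):
            parse_crosslink_table(p)

    def test_column_map_remaps_names(self, tmp_path):
        p = tmp_path / "xl.tsv"
        p.write_text("ProtA\tPosA\tProtB\tPosB\nE2o\t43\tE3\t100\n")
        report = parse_crosslink_table(
            p,
            column_map={
                "protein_a": "ProtA", "residue_a": "PosA",
                "protein_b": "ProtB", "residue_b": "PosB",
            },
        )
        assert report.crosslinks[0] == CrossLink("E2o", 43, "E3", 100)

    def test_generator_table_roundtrips(self, tmp_path, mini_complex):
        sim = sd.simulate_crosslinks(mini_complex.assembled_reference, n=100, seed=7)
        p = tmp_path / "sim.csv"
        sim.write(p)
        report = parse_crosslink_table(p)
        assert report.crosslinks == sim.crosslinks


class TestMapping:
    def test_minimum_over_copies(self, homodimer):
        # copy-pair A-A gives 50 Å but A-B gives 15 Å -> 15 Å, satisfied
        link = CrossLink("sub", 1, "sub", 2)
        (m,) = map_restraints(homodimer, [link])
        assert m.distance == pytest.approx(15.0)
        assert m.status == "satisfied"
        assert set(m.chain_pair) == {"A", "B"}

    def test_residue_beyond_modelled_range_unmapped(self, homodimer):
        (m,) = map_restraints(homodimer, [CrossLink("sub", 1, "sub", 99)])
        assert m.status == "unmapped" and m.distance is None

    def test_unknown_component_unmapped_not_fatal(self, homodimer):
        (m,) = map_restraints(homodimer, [CrossLink("sub", 1, "nosuch", 2)])
        assert m.status == "unmapped"
        assert "nosuch" in m.reason

    def test_degenerate_self_link_rejected(self, homodimer):
        with pytest.raises(ValueError, match="self-link"):
            map_restraints(homodimer, [CrossLink("sub", 1, "sub", 1)])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_toys(self, seed):
        spec = sd.ToyComplexSpec(
            [("alpha", 4, 10), ("beta", 3, 8)], core_radius=25.0, inter_body_spacing=12.0, seed=seed
        )
        structure = sd.make_toy_complex(spec)
        sim = sd.simulate_crosslinks(structure, n=40, max_dist=40.0, decoy_frac=0.2, seed=seed)
        mapped = map_restraints(structure, sim.crosslinks)
        for m in mapped:
            oracle = brute_force_min_distance(structure, m.crosslink)
            if oracle is None:
                assert m.status == "unmapped"
            else:
                assert m.distance == pytest.approx(oracle, abs=1e-9)

    def test_offset_correctness(self, mini_complex):
        """Shifting table numbering by k and supplying the matching map is a no-op."""
        structure = mini_complex.assembled_reference
        offsets = {"E1o": 27, "E2o": 67, "E3": 35, "MRPS36": 0}
        plain = sd.simulate_crosslinks(structure, n=60, seed=11)
        shifted = sd.simulate_crosslinks(structure, n=60, seed=11, offsets=offsets)
        d_plain = [m.distance for m in map_restraints(structure, plain.crosslinks)]
        d_shift = [
            m.distance
            for m in map_restraints(structure, shifted.crosslinks, NumberingMap(offsets))
        ]
        assert d_plain == d_shift

    def test_cutoff_monotonicity(self, mini_complex):
        structure = mini_complex.assembled_reference
        sim = sd.simulate_crosslinks(structure, n=100, decoy_frac=0.3, seed=5)
        mapped = map_restraints(structure, sim.crosslinks)
        counts = [
            summarize_restraints(mapped, cutoff).n_satisfied
            for cutoff in [5, 10, 20, 30, 50, 100]
        ]
        assert counts == sorted(counts)

    def test_zero_noise_links_fully_satisfied_decoys_not(self, mini_complex):
        structure = mini_complex.assembled_reference
        sim = sd.simulate_crosslinks(
            structure, n=200, max_dist=25.0, noise_sd=0.0, decoy_frac=0.3, seed=1
        )
        mapped = map_restraints(structure, sim.crosslinks, cutoff=30.0)
        true_sat = [m.status == "satisfied" for m, dec in zip(mapped, sim.is_decoy) if not dec]
        decoy_sat = [m.status == "satisfied" for m, dec in zip(mapped, sim.is_decoy) if dec]
        assert all(true_sat)
        assert np.mean(decoy_sat) < np.mean(true_sat)


class TestSummary:
    def _mk(self, distances, cutoff=30.0):
        mapped = []
        for d in distances:
            link = CrossLink("a", 1, "b", 2)
            status = "satisfied" if d <= cutoff else "violated"
            mapped.append(MappedRestraint(link, ("A", "B"), d, status))
        return mapped

    def test_hand_computed_summary(self):
        s = summarize_restraints(self._mk([10.0, 20.0, 40.0]), cutoff=30.0)
        assert s.n_total == s.n_mapped == 3
        assert s.n_satisfied == 2
        assert s.satisfied_fraction == pytest.approx(2 / 3, abs=1e-3)
        assert s.median_distance == pytest.approx(20.0)
        assert s.max_distance == pytest.approx(40.0)

    def test_empty_input_is_flagged_not_fatal(self):
        s = summarize_restraints([])
        assert s.n_mapped == 0
        assert s.median_distance is None and s.satisfied_fraction is None

    def test_per_linker_breakdown(self, mini_complex):
        structure = mini_complex.assembled_reference
        sim = sd.simulate_crosslinks(structure, n=90, seed=3)
        mapped = map_restraints(structure, sim.crosslinks)
        s = summarize_restraints(mapped)
        assert set(s.per_linker) == {"DSSO", "PhoX", "DMTMM"}
        assert sum(sub.n_total for sub in s.per_linker.values()) == s.n_total


class TestMeasureDistance:
    def test_same_atom_zero(self, homodimer):
        assert measure_distance(homodimer, ("A", 1, "CA"), ("A", 1, "CA")) == 0.0

    def test_unit_cube_diagonal(self, point_chain_factory):
        ch = point_chain_factory("A", "x", [(0, 0, 0), (1, 1, 1)])
        s = Structure(chains=[ch])
        assert measure_distance(s, ("A", 1, "CA"), ("A", 2, "CA")) == pytest.approx(
            np.sqrt(3), abs=1e-3
        )

    def test_whole_residue_selector_takes_minimum(self, point_chain_factory):
        from ogdhc.structure_io import Atom, Chain, Residue

        cofactor = Residue(
            1, "TPP",
            atoms=[Atom("C1", "C", (100.0, 0, 0)), Atom("C2", "C", (8.0, 0, 0))],
        )
        chains = [
            Chain(id="A", residues=[cofactor], component="other"),
            point_chain_factory("B", "x", [(0, 0, 0)]),
        ]
        s = Structure(chains=chains)
        assert measure_distance(s, ("B", 1, "CA"), ("A", 1, None)) == pytest.approx(8.0)

    def test_empty_selector_names_itself(self, homodimer):
        with pytest.raises(ValueError, match="no residue 9"):
            measure_distance(homodimer, ("A", 9, "CA"), ("B", 1, "CA"))
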