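"""Synthetic fixtures with ground truth for every pipeline stage.

Everything the tests and analyses need can be generated here, offline and
seed-deterministically:

* toy multi-chain complexes (CA-only pseudo-helices; a core laid out with
  point-group-like regularity on a sphere plus peripheral copies), including
  a "mini complex" preset mirroring the 24-copy core / 16+12+6 peripheral
  stoichiometry of the dehydrogenase assembly;
* simulated cross-link tables: true links drawn from residue pairs within a
  linker-reachable distance, plus a decoy fraction drawn uniformly over all
  pairs (default 5%, matching the identification FDR cross-link searches are
  controlled at), with per-row ground truth;
* synthetic complexome profiles: Gaussian peaks on a log-mass gel axis at
  the slice a complex of known mass would migrate to, with multiplicative
  log-normal noise, plus calibration markers;
* synthetic BLAST hit tables with known genus/species structure and known
  counts of hits that qualify under the homolog-selection rules.

CA-only structures are deliberate: every in-scope distance is measured
between CA atoms (or whole hetero-residues), so side chains would add
nothing testable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .comigration import MassCalibration
from .homolog_filter import BlastHit
from .structure_io import Atom, Chain, Residue, Structure, fresh_chain_ids
from .xl_restraints import CrossLink, NumberingMap

__all__ = [
    "ToyComplexSpec",
    "SimulatedCrosslinkSet",
    "MiniComplex",
    "CPComplexSpec",
    "SimulatedBlastSet",
    "make_toy_complex",
    "make_mini_ogdhc",
    "simulate_crosslinks",
    "simulate_cp_profiles",
    "simulate_blast_hits",
    "DEFAULT_STOICHIOMETRY",
    "MONOMER_MASSES_KDA",
]

# Full-complex stoichiometry and rounded monomer masses (kDa) of the
# dehydrogenase subunits used throughout the analyses.
DEFAULT_STOICHIOMETRY = {"E2o": 24, "E1o": 16, "E3": 12, "MRPS36": 6}
MONOMER_MASSES_KDA = {"E1o": 111.0, "E2o": 41.0, "E3": 50.0, "MRPS36": 11.0}

_AA_CYCLE = "ALA GLY SER VAL LEU THR ASP GLU LYS ARG ASN GLN ILE PHE TYR HIS MET PRO TRP CYS".split()


def _component_sequence(component: str, n: int) -> list[str]:
    """Deterministic per-component residue-name sequence (same for all copies)."""
    start = zlib.crc32(component.encode()) % len(_AA_CYCLE)
    return [_AA_CYCLE[(start + i) % len(_AA_CYCLE)] for i in range(n)]


def _helix_coords(n: int) -> np.ndarray:
    """CA trace of an idealised alpha-helix along +z (rise 1.5 Å, 100°/res)."""
    idx = np.arange(n)
    theta = np.deg2rad(100.0) * idx
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * idx])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def _make_chain(
    chain_id: str, component: str, n_res: int, rotation: np.ndarray, origin: np.ndarray
) -> Chain:
    coords = _helix_coords(n_res) @ rotation.T + origin
    names = _component_sequence(component, n_res)
    residues = [
        Residue(number=i + 1, name=names[i], atoms=[Atom("CA", "C", tuple(coords[i]))])
        for i in range(n_res)
    ]
    return Chain(id=chain_id, residues=residues, component=component)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (golden-spiral construction)."""
    idx = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * idx / n)
    theta = np.pi * (1 + 5**0.5) * idx
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


@dataclass
class ToyComplexSpec:
    """Layout for a toy complex: (name, copies, residues_per_chain) per component.

    The first component is the core, laid out on a sphere of ``core_radius``;
    every other component sits on a sphere ``inter_body_spacing`` further out.
    """

    components: list[tuple[str, int, int]]
    core_radius: float = 50.0
    inter_body_spacing: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("need at least one component")
        for name, copies, n_res in self.components:
            if copies < 1:
                raise ValueError(f"{name}: copies must be >= 1")
            if n_res < 3:
                raise ValueError(f"{name}: residues_per_chain must be >= 3")
        if self.inter_body_spacing <= 0:
            raise ValueError("inter_body_spacing must be > 0")
        if self.core_radius <= 0:
            raise ValueError("core_radius must be > 0")


def make_toy_complex(spec: ToyComplexSpec) -> Structure:
    """Build a CA-only toy complex per the spec; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    chains: list[Chain] = []
    id_gen = fresh_chain_ids([])
    radius = spec.core_radius
    for level, (name, copies, n_res) in enumerate(spec.components):
        r = radius if level == 0 else radius + spec.inter_body_spacing * level
        directions = _fibonacci_sphere(copies)
        for k in range(copies):
            origin = directions[k] * r
            chains.append(_make_chain(next(id_gen), name, n_res, _random_rotation(rng), origin))
    return Structure(chains=chains, title=f"toy complex (seed {spec.seed})")


# ---------------------------------------------------------------------------
# mini dehydrogenase-like preset: 24-chain core + peripheral dimer sub-models


@dataclass
class MiniComplex:
    """A core, its peripheral sub-models and the recipe that assembles them.

    ``assembled_reference`` is the ground-truth assembly built directly in
    the core frame (what ``assemble_complex`` should reproduce).
    """

    core: Structure
    submodels: list[Structure]
    recipe: list[tuple[int, str, str]]
    assembled_reference: Structure


def _transformed_copy(chain: Chain, new_id: str, rotation: np.ndarray, translation: np.ndarray) -> Chain:
    residues = []
    for r in chain.residues:
        atoms = [
            Atom(a.name, a.element, tuple(rotation @ np.asarray(a.position) + translation))
            for a in r.atoms
        ]
        residues.append(Residue(r.number, r.name, r.insertion_code, atoms))
    return Chain(id=new_id, residues=residues, component=chain.component)


def make_mini_ogdhc(
    seed: int = 0,
    n_res_core: int = 30,
    n_res_peripheral: int = 25,
    core_radius: float = 55.0,
    peripheral_spacing: float = 30.0,
) -> MiniComplex:
    """Miniature analogue of the full dehydrogenase assembly problem.

    The core is 24 copies of the core component in 8 trimers at the corners
    of a cube (the octahedral-core layout at toy scale).  Eight dimer
    sub-models of the first peripheral component anchor on one chain of each
    trimer; six sub-models carrying a peripheral dimer plus a single adaptor
    chain anchor on a second chain of six trimers — reproducing the
    24 : 16 : 12 : 6 chain stoichiometry.  Each sub-model is handed out in
    its own random rigid frame so assembly must actually recover the
    superposition (expected placement RMSD ~0).
    """
    rng = np.random.default_rng(seed)
    corners = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
    ) / np.sqrt(3.0)
    chains: list[Chain] = []
    id_gen = fresh_chain_ids([])
    trimer_chain_ids: list[list[str]] = []
    for corner in corners:
        # local orthonormal frame at the corner for the in-trimer triangle
        z = corner / np.linalg.norm(corner)
        ref = np.array([0.0, 0.0, 1.0]) if abs(z[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        u = np.cross(z, ref)
        u /= np.linalg.norm(u)
        v = np.cross(z, u)
        ids = []
        for j in range(3):
            ang = 2 * np.pi * j / 3
            origin = corner * core_radius + 9.0 * (np.cos(ang) * u + np.sin(ang) * v)
            cid = next(id_gen)
            chains.append(_make_chain(cid, "E2o", n_res_core, _random_rotation(rng), origin))
            ids.append(cid)
        trimer_chain_ids.append(ids)
    core = Structure(chains=chains, title="mini core (24 E2o)")

    submodels: list[Structure] = []
    recipe: list[tuple[int, str, str]] = []
    reference_chains = [c for c in core.copy().chains]
    ref_id_gen = fresh_chain_ids([c.id for c in core.chains])

    def build_submodel(anchor_core_id: str, peripherals: list[str]) -> None:
        """One sub-model: copy of the designated core chain + peripheral chains,
        emitted in a random rigid frame; ground-truth chains recorded in the
        core frame."""
        anchor_core = core.chain(anchor_core_id)
        centroid = np.mean(
            [a.position for r in anchor_core.residues for a in r.atoms], axis=0
        )
        outward = centroid / np.linalg.norm(centroid)
        # ground-truth peripheral chains in the core frame
        truth_chains = []
        for k, comp in enumerate(peripherals):
            lateral = _random_rotation(rng)[:, 0] * 8.0
            origin = centroid + outward * peripheral_spacing + lateral + k * outward * 12.0
            truth_chains.append(
                _make_chain(f"tmp{k}", comp, n_res_peripheral, _random_rotation(rng), origin)
            )
        # emit the sub-model in its own random frame
        rot = _random_rotation(rng)
        trans = rng.uniform(-100, 100, size=3)
        sm_chains = [_transformed_copy(anchor_core, "A", rot, trans)]
        for k, tc in enumerate(truth_chains):
            sm_chains.append(_transformed_copy(tc, "BCD"[k], rot, trans))
        submodels.append(Structure(chains=sm_chains, title=f"submodel {len(submodels)}"))
        recipe.append((len(submodels) - 1, "A", anchor_core_id))
        for tc in truth_chains:
            reference_chains.append(
                Chain(id=next(ref_id_gen), residues=tc.residues, component=tc.component)
            )

    for trimer in trimer_chain_ids:  # 8 peripheral-dimer sub-models
        build_submodel(trimer[0], ["E1o", "E1o"])
    for trimer in trimer_chain_ids[:6]:  # 6 dimer+adaptor sub-models
        build_submodel(trimer[1], ["E3", "E3", "MRPS36"])

    reference = Structure(chains=reference_chains, title="mini complex reference")
    return MiniComplex(core=core, submodels=submodels, recipe=recipe, assembled_reference=reference)


# ---------------------------------------------------------------------------
# cross-link simulation


@dataclass
class SimulatedCrosslinkSet:
    """Simulated cross-link table plus per-row ground truth."""

    crosslinks: list[CrossLink]
    true_distance: list[float]
    is_decoy: list[bool]
    numbering: NumberingMap = field(default_factory=NumberingMap)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for link, d, decoy in zip(self.crosslinks, self.true_distance, self.is_decoy):
            rows.append(
                {
                    "protein_a": link.protein_a,
                    "residue_a": link.residue_a,
                    "protein_b": link.protein_b,
                    "residue_b": link.residue_b,
                    "linker": link.linker,
                    "score": link.score,
                    "dataset": link.dataset,
                    "true_distance": round(d, 3),
                    "is_decoy": int(decoy),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "protein_a", "residue_a", "protein_b", "residue_b",
                "linker", "score", "dataset", "true_distance", "is_decoy",
            ],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _residue_index(structure: Structure):
    """Flat list of (component, residue_number, CA position) over all chains."""
    entries = []
    for c in structure.chains:
        for r in c.residues:
            ca = r.atom("CA")
            if ca is not None:
                entries.append((c.component, r.number, np.asarray(ca.position)))
    return entries


def simulate_crosslinks(
    structure: Structure,
    n: int,
    max_dist: float = 25.0,
    noise_sd: float = 0.0,
    decoy_frac: float = 0.05,
    seed: int = 0,
    offsets: Mapping[str, int] | None = None,
    linkers: Sequence[str] = ("DSSO", "PhoX", "DMTMM"),
) -> SimulatedCrosslinkSet:
    """Draw ``n`` cross-links from a structure with known ground truth.

    True links are sampled uniformly from residue pairs whose CA–CA distance,
    jittered by N(0, ``noise_sd``), is at most ``max_dist`` — at zero noise
    every true link is genuinely within reach of the linker.  Decoys
    (``decoy_frac`` of rows, the analogue of the identification FDR) are
    drawn uniformly over ALL residue pairs regardless of distance.  Reported
    residue numbers are precursor-style: the per-component ``offsets``
    (transit-peptide lengths) are ADDED, so mapping back requires the
    matching :class:`NumberingMap`.

    Pairs that would be ambiguous in table terms (same component, same
    residue number — indistinguishable across copies) are never emitted.
    The recorded ``true_distance`` for a pair is the minimum over copies,
    i.e. exactly what restraint mapping should recover.
    """
    rng = np.random.default_rng(seed)
    offsets = dict(offsets or {})
    entries = _residue_index(structure)
    if len(entries) < 2:
        raise ValueError("structure must contain at least 2 residues with CA atoms")
    if n == 0:
        return SimulatedCrosslinkSet([], [], [], NumberingMap(offsets))

    coords = np.asarray([e[2] for e in entries])
    labels = [(e[0], e[1]) for e in entries]
    dmat = squareform(pdist(coords))

    # minimum distance over copies for each (component, resnum) label pair
    label_ids = {}
    for lab in labels:
        label_ids.setdefault(lab, len(label_ids))
    lab_index = np.asarray([label_ids[lab] for lab in labels])
    n_labels = len(label_ids)
    min_d = np.full((n_labels, n_labels), np.inf)
    row_lab = np.broadcast_to(lab_index[:, None], dmat.shape)
    col_lab = np.broadcast_to(lab_index[None, :], dmat.shape)
    np.minimum.at(min_d, (row_lab.ravel(), col_lab.ravel()), dmat.ravel())
    labels_unique = [None] * n_labels
    for lab, k in label_ids.items():
        labels_unique[k] = lab

    iu, ju = np.triu_indices(n_labels, k=1)
    pair_d = min_d[iu, ju]
    noisy = pair_d + (rng.normal(0.0, noise_sd, size=pair_d.shape) if noise_sd > 0 else 0.0)
    within = np.flatnonzero(noisy <= max_dist)
    if within.size == 0:
        raise ValueError(f"no residue pair within max_dist={max_dist} Å")

    n_decoy = int(round(n * decoy_frac))
    n_true = n - n_decoy
    chosen_true = rng.choice(within, size=n_true, replace=True)
    chosen_decoy = rng.integers(0, iu.size, size=n_decoy)

    links: list[CrossLink] = []
    true_d: list[float] = []
    decoy_flags: list[bool] = []
    order = list(chosen_true) + list(chosen_decoy)
    flags = [False] * n_true + [True] * n_decoy
    for pair_idx, decoy in zip(order, flags):
        (comp_a, res_a) = labels_unique[iu[pair_idx]]
        (comp_b, res_b) = labels_unique[ju[pair_idx]]
        links.append(
            CrossLink(
                protein_a=comp_a,
                residue_a=res_a + offsets.get(comp_a, 0),
                protein_b=comp_b,
                residue_b=res_b + offsets.get(comp_b, 0),
                linker=str(rng.choice(list(linkers))),
                score=float(np.round(rng.uniform(40, 200), 2)),
                dataset="synthetic",
            )
        )
        true_d.append(float(pair_d[pair_idx]))
        decoy_flags.append(decoy)
    return SimulatedCrosslinkSet(links, true_d, decoy_flags, NumberingMap(offsets))


# ---------------------------------------------------------------------------
# complexome-profile simulation


@dataclass
class CPComplexSpec:
    """One migrating species: member components, complex mass, peak abundance."""

    components: list[str]
    mass_kda: float
    abundance: float = 1.0
    label: str = ""


def simulate_cp_profiles(
    complexes: Sequence[CPComplexSpec],
    n_slices: int = 56,
    calibration: MassCalibration | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    peak_width: float = 1.5,
    monomer_masses_kda: Mapping[str, float] | None = None,
    monomer_abundance: float = 0.15,
) -> tuple[pd.DataFrame, list[tuple[float, float]]]:
    """Simulate a protein × slice complexome-profiling matrix.

    Every member of a complex receives a Gaussian peak (σ = ``peak_width``
    slices) centred at the slice its complex mass migrates to under the
    calibration (default: 5 MDa at slice 1 down to 10 kDa at the last
    slice, the log-linear behaviour of a 3–10% BN-PAGE gradient gel).
    Optional monomer peaks add a smaller Gaussian at each component's
    monomer mass.  Noise is multiplicative log-normal.  Returns the raw
    (un-normalized) matrix with 1-based slice columns, and the marker list
    for round-trip calibration.

    A complex whose mass falls outside the calibrated gel range is an
    error naming it.
    """
    if calibration is None:
        # slice 1 -> 5000 kDa, slice n -> 10 kDa
        slope = (np.log10(10.0) - np.log10(5000.0)) / (n_slices - 1)
        intercept = np.log10(5000.0) - slope * 1.0
        calibration = MassCalibration(slope, intercept)
    rng = np.random.default_rng(seed)
    slices = np.arange(1, n_slices + 1, dtype=float)

    proteins: list[str] = []
    for cx in complexes:
        for comp in cx.components:
            if comp not in proteins:
                proteins.append(comp)
    matrix = pd.DataFrame(0.0, index=proteins, columns=slices.astype(int))

    def peak(center: float, amplitude: float) -> np.ndarray:
        return amplitude * np.exp(-0.5 * ((slices - center) / peak_width) ** 2)

    for cx in complexes:
        center = calibration.slice_for_mass(cx.mass_kda)
        if not (1.0 <= center <= n_slices):
            label = cx.label or "+".join(cx.components)
            raise ValueError(
                f"complex {label!r} ({cx.mass_kda} kDa) migrates to slice {center:.1f}, "
                f"outside the gel (1..{n_slices})"
            )
        for comp in cx.components:
            matrix.loc[comp] += peak(center, cx.abundance)
    if monomer_masses_kda:
        for comp, mass in monomer_masses_kda.items():
            if comp in matrix.index:
                center = calibration.slice_for_mass(mass)
                if 1.0 <= center <= n_slices:
                    matrix.loc[comp] += peak(center, monomer_abundance)
    if noise_sd > 0:
        matrix *= np.exp(rng.normal(0.0, noise_sd, size=matrix.shape))

    marker_slices = np.linspace(2, n_slices - 1, 8)
    markers = [(float(s), float(calibration.mass_kda(s))) for s in marker_slices]
    return matrix, markers


# ---------------------------------------------------------------------------
# BLAST-hit simulation


@dataclass
class SimulatedBlastSet:
    hits: list[BlastHit]
    qualifying_per_genus: dict[str, int]


def simulate_blast_hits(
    n_genera: int,
    species_per_genus: int | Sequence[int] = 6,
    n_disqualified_per_genus: int = 2,
    identity_range: tuple[float, float] = (0.35, 0.85),
    coverage_range: tuple[float, float] = (0.6, 1.0),
    seed: int = 0,
    query_id: str = "query",
) -> SimulatedBlastSet:
    """Hit table with known genus structure for filter-recovery tests.

    Each genus gets ``species_per_genus`` qualifying species (identity and
    coverage drawn inside the passing ranges) plus ``n_disqualified_per_genus``
    species that fail a threshold (half low coverage, half high identity).
    Ground truth records how many species per genus qualify.
    """
    if n_genera < 1:
        raise ValueError("n_genera must be >= 1")
    rng = np.random.default_rng(seed)
    per_genus = (
        [species_per_genus] * n_genera
        if isinstance(species_per_genus, int)
        else list(species_per_genus)
    )
    if len(per_genus) != n_genera:
        raise ValueError("species_per_genus sequence length must equal n_genera")
    hits: list[BlastHit] = []
    truth: dict[str, int] = {}
    serial = 0
    for g in range(n_genera):
        genus = f"Genus{g:03d}"
        truth[genus] = per_genus[g]
        for s in range(per_genus[g]):
            serial += 1
            hits.append(
                BlastHit(
                    query_id=query_id,
                    subject_id=f"SUBJ{serial:05d}",
                    species=f"{genus} species{s:03d}",
                    genus=genus,
                    identity=float(rng.uniform(*identity_range)),
                    query_coverage=float(rng.uniform(*coverage_range)),
                    bitscore=float(np.round(rng.uniform(200, 900), 1)),
                    evalue=float(10 ** rng.uniform(-120, -20)),
                )
            )
        for s in range(n_disqualified_per_genus):
            serial += 1
            if s % 2 == 0:
                identity = float(rng.uniform(*identity_range))
                coverage = float(rng.uniform(0.05, 0.45))  # fails coverage
            else:
                identity = float(rng.uniform(0.92, 0.99))  # fails identity
                coverage = float(rng.uniform(*coverage_range))
            hits.append(
                BlastHit(
                    query_id=query_id,
                    subject_id=f"SUBJ{serial:05d}",
                    species=f"{genus} badspecies{s:03d}",
                    genus=genus,
                    identity=identity,
                    query_coverage=coverage,
                    bitscore=float(np.round(rng.uniform(200, 900), 1)),
                    evalue=float(10 ** rng.uniform(-120, -20)),
                )
            )
    return SimulatedBlastSet(hits=hits, qualifying_per_genus=truth)
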