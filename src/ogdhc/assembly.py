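"""Rigid-body assembly of a full complex onto a reference core.

The full-complex model is built the way hybrid-modelling studies build it:
pairwise interface sub-models (e.g. an E1o dimer bound to one E2o subunit,
or an E3 dimer plus adaptor bound to another) are superposed, one at a time,
onto designated chains of a reference core by least-squares (Kabsch)
alignment of shared Cα positions.  The anchor chain itself is discarded —
the core's copy is kept — and the remaining chains of the sub-model are
added under fresh chain ids.  A component ledger (name, copies, monomer
mass) is maintained so the stoichiometric mass of the assembly is always
consistent with the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Atom, Chain, Residue, Structure, chain_mass, fresh_chain_ids

__all__ = [
    "Transform",
    "Placement",
    "LedgerEntry",
    "AssembledModel",
    "Clash",
    "ClashReport",
    "kabsch_superpose",
    "assemble_complex",
    "detect_clashes",
    "composition_mass",
]


@dataclass
class Transform:
    """Proper rigid transform: y = R @ x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (max deviation {err:.2e})")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1); reflections are not rigid motions")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class Placement:
    submodel_id: str
    anchor_chain: str
    target_chain: str
    transform: Transform
    rmsd: float
    n_aligned: int

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")


@dataclass
class LedgerEntry:
    component: str
    copies: int
    monomer_mass_kda: float | None


@dataclass
class AssembledModel:
    structure: Structure
    ledger: list[LedgerEntry]
    placements: list[Placement]
    # chain id -> rigid-body label ("core" or submodel placement id)
    rigid_bodies: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        """Ledger copies must equal actual per-component chain counts."""
        counts = self.structure.component_counts()
        for entry in self.ledger:
            actual = counts.get(entry.component, 0)
            if actual != entry.copies:
                raise ValueError(
                    f"ledger inconsistency for {entry.component}: "
                    f"ledger says {entry.copies}, structure has {actual}"
                )

    def total_mass_kda(self) -> float:
        missing = [e.component for e in self.ledger if e.monomer_mass_kda is None]
        if missing:
            raise ValueError(f"no monomer mass for component(s): {missing}")
        return sum(e.copies * e.monomer_mass_kda for e in self.ledger)


@dataclass
class Clash:
    """Two heavy atoms from different rigid bodies closer than the cutoff."""

    chain_a: str
    residue_a: int
    atom_a: str
    chain_b: str
    residue_b: int
    atom_b: str
    distance: float


@dataclass
class ClashReport:
    clashes: list[Clash]
    n_excluded: int  # contacts skipped because a partner lies in an excluded range
    cutoff: float


# ---------------------------------------------------------------------------
# Kabsch superposition


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[Transform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Closed-form solution via SVD of the cross-covariance matrix, with the
    determinant sign corrected so only proper rotations are returned.
    Returns the optimal transform and the RMSD (Å) after applying it.

    Both inputs are ordered (N, 3) arrays of corresponding points, N >= 3,
    and the points must not be all collinear (a collinear set leaves a
    rotation about the line undetermined).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"point sets differ in shape: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("expected (N, 3) coordinate arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a unique superposition")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    x = mobile - mu_m
    y = reference - mu_r
    # collinearity check: rank of the centred mobile set
    if np.linalg.matrix_rank(x, tol=1e-9) < 2:
        raise ValueError("points are collinear; rotation is not uniquely determined")
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = mu_r - rot @ mu_m
    tf = Transform(rot, trans)
    moved = tf.apply(mobile)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return tf, rmsd


# ---------------------------------------------------------------------------
# assembly


def _common_ca(anchor: Chain, target: Chain) -> tuple[np.ndarray, np.ndarray, int]:
    """Paired CA coordinates over residues present in both chains."""
    target_by_key = {r.key: r for r in target.residues}
    mob, ref = [], []
    for r in anchor.residues:
        tr = target_by_key.get(r.key)
        if tr is None:
            continue
        a, b = r.atom("CA"), tr.atom("CA")
        if a is None or b is None:
            continue
        mob.append(a.position)
        ref.append(b.position)
    n = len(mob)
    if n < 3:
        raise ValueError(
            f"anchor {anchor.id} and target {target.id} share only {n} CA residues (need >= 3)"
        )
    return np.asarray(mob), np.asarray(ref), n


def _transform_chain(chain: Chain, tf: Transform, new_id: str) -> Chain:
    residues = []
    for r in chain.residues:
        atoms = [
            Atom(a.name, a.element, tuple(tf.apply(np.asarray(a.position)[None, :])[0]))
            for a in r.atoms
        ]
        residues.append(Residue(r.number, r.name, r.insertion_code, atoms))
    return Chain(id=new_id, residues=residues, component=chain.component)


def assemble_complex(
    core: Structure,
    submodels: Sequence[Structure],
    recipe: Sequence[tuple[int, str, str]],
    monomer_masses_kda: Mapping[str, float] | None = None,
) -> AssembledModel:
    """Place pairwise sub-models onto a reference core by Kabsch superposition.

    ``recipe`` entries are ``(submodel_index, anchor_chain_id, core_chain_id)``.
    For each entry the sub-model's anchor chain is superposed onto the core
    chain over their common CA residues; the anchor chain is NOT copied into
    the model (the core copy is kept) and every other sub-model chain is
    added under a fresh id.  Anchor and core chain must carry the same
    component label.  Placing two sub-models on the same core chain is an
    error, as is an anchor/target pair sharing fewer than 3 CA residues.

    Monomer masses (kDa) per component may be supplied; otherwise they are
    computed from chain sequences where possible.
    """
    model_structure = core.copy()
    placements: list[Placement] = []
    rigid_bodies = {c.id: "core" for c in model_structure.chains}
    id_gen = fresh_chain_ids([c.id for c in model_structure.chains])
    used_targets: set[str] = set()

    for entry_no, (sm_index, anchor_id, target_id) in enumerate(recipe):
        if target_id in used_targets:
            raise ValueError(f"recipe entry {entry_no}: core chain {target_id} already used")
        used_targets.add(target_id)
        try:
            submodel = submodels[sm_index]
        except IndexError:
            raise ValueError(f"recipe entry {entry_no}: no sub-model with index {sm_index}") from None
        anchor = submodel.chain(anchor_id)
        target = model_structure.chain(target_id)
        if anchor is None:
            raise ValueError(f"recipe entry {entry_no}: sub-model has no chain {anchor_id!r}")
        if target is None:
            raise ValueError(f"recipe entry {entry_no}: core has no chain {target_id!r}")
        if anchor.component != target.component:
            raise ValueError(
                f"recipe entry {entry_no}: anchor component {anchor.component!r} "
                f"!= target component {target.component!r}"
            )
        mob, ref, n_aligned = _common_ca(anchor, target)
        tf, rmsd = kabsch_superpose(mob, ref)
        placement_id = f"placement_{entry_no}"
        for chain in submodel.chains:
            if chain.id == anchor_id:
                continue  # the core's copy of the anchor component is kept
            new_id = next(id_gen)
            model_structure.chains.append(_transform_chain(chain, tf, new_id))
            rigid_bodies[new_id] = placement_id
        placements.append(
            Placement(
                submodel_id=f"submodel_{sm_index}",
                anchor_chain=anchor_id,
                target_chain=target_id,
                transform=tf,
                rmsd=rmsd,
                n_aligned=n_aligned,
            )
        )

    # rebuild to re-run invariant checks (unique chain ids)
    model_structure = Structure(
        chains=model_structure.chains,
        title=core.title + " (assembled)" if core.title else "assembled model",
        source_format=core.source_format,
    )
    ledger = _build_ledger(model_structure, monomer_masses_kda)
    model = AssembledModel(model_structure, ledger, placements, rigid_bodies)
    model.validate()
    return model


def _build_ledger(
    structure: Structure, monomer_masses_kda: Mapping[str, float] | None
) -> list[LedgerEntry]:
    entries = []
    for component, copies in sorted(structure.component_counts().items()):
        if monomer_masses_kda and component in monomer_masses_kda:
            mass = float(monomer_masses_kda[component])
        else:
            chains = structure.chains_of(component)
            try:
                mass = chain_mass(chains[0]) / 1000.0
            except Exception:
                mass = None
        entries.append(LedgerEntry(component, copies, mass))
    return entries


# ---------------------------------------------------------------------------
# clash detection


def _heavy_atoms(structure: Structure) -> list[tuple[str, int, str, np.ndarray]]:
    out = []
    for c in structure.chains:
        for r in c.residues:
            for a in r.atoms:
                if a.element.upper() != "H":
                    out.append((c.id, r.number, a.name, np.asarray(a.position)))
    return out


def detect_clashes(
    model: AssembledModel,
    cutoff: float = 2.0,
    exclude: Iterable[tuple[str, int, int]] = (),
) -> ClashReport:
    """All heavy-atom pairs from different rigid bodies closer than ``cutoff``.

    Neighbour search uses a k-d tree; tests hold it equal to the O(n²)
    brute force.  ``exclude`` is a list of ``(chain_id, first, last)``
    residue ranges (e.g. flexible linkers known to clash); contacts with
    either partner inside a range are skipped and counted separately.
    """
    if len(set(model.rigid_bodies.values())) < 2:
        raise ValueError("clash detection needs at least two rigid bodies")
    excluded_ranges = list(exclude)

    def is_excluded(chain_id: str, resnum: int) -> bool:
        return any(c == chain_id and lo <= resnum <= hi for c, lo, hi in excluded_ranges)

    atoms = _heavy_atoms(model.structure)
    coords = np.asarray([a[3] for a in atoms])
    bodies = [model.rigid_bodies.get(a[0], "core") for a in atoms]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    clashes: list[Clash] = []
    n_excluded = 0
    for i, j in pairs:
        if bodies[i] == bodies[j]:
            continue
        ca, ra, na, pa = atoms[i]
        cb, rb, nb, pb = atoms[j]
        if is_excluded(ca, ra) or is_excluded(cb, rb):
            n_excluded += 1
            continue
        d = float(np.linalg.norm(pa - pb))
        if d < cutoff:
            clashes.append(Clash(ca, ra, na, cb, rb, nb, d))
    clashes.sort(key=lambda c: (c.chain_a, c.residue_a, c.atom_a, c.chain_b, c.residue_b, c.atom_b))
    return ClashReport(clashes=clashes, n_excluded=n_excluded, cutoff=cutoff)


# ---------------------------------------------------------------------------
# stoichiometric mass


def composition_mass(
    ledger: Sequence[LedgerEntry] | AssembledModel,
    monomer_masses_kda: Mapping[str, float] | None = None,
) -> tuple[float, float]:
    """Total complex mass from the component ledger.

    ``total = Σ copies × monomer mass``; returns ``(kDa, MDa)``.  Masses are
    taken from ``monomer_masses_kda`` when given, else from the ledger; a
    component without any mass is an error naming it.
    """
    entries = ledger.ledger if isinstance(ledger, AssembledModel) else list(ledger)
    total_kda = 0.0
    for e in entries:
        if monomer_masses_kda and e.component in monomer_masses_kda:
            mass = float(monomer_masses_kda[e.component])
        else:
            mass = e.monomer_mass_kda
        if mass is None:
            raise ValueError(f"no monomer mass for component {e.component!r}")
        total_kda += e.copies * mass
    return total_kda, total_kda / 1000.0
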