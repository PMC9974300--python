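"""Macromolecular structure I/O and sequence-mass accounting.

Provides a light hierarchical model (Structure -> Chain -> Residue -> Atom)
with the author numbering preserved verbatim from the file, which is the
addressing every downstream module (restraint mapping, assembly, distance
measurement) relies on.  Parsing and serialisation of PDB/mmCIF are delegated
to gemmi; this module owns the in-memory representation and the conversion.

Conventions
-----------
* Author residue numbering is authoritative; nothing is renumbered on read,
  because cross-link tables reference author numbering.
* Modified residues and cofactors (lipoyllysine, TPP, FAD, ...) are kept as
  ordinary residues so distances to them can be measured.
* Waters are dropped on read unless ``keep_waters=True``.
* For alternate conformations only the highest-occupancy conformer is kept:
  distance thresholds assume a single conformer.
* Masses are average (not monoisotopic): MDa-scale complex-mass accounting
  compares against gel-derived apparent masses, which are average quantities.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gemmi

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "read_structure",
    "write_structure",
    "sequence_mass",
    "WATER_MASS",
    "fresh_chain_ids",
]

WATER_MASS = 18.0153  # average mass of one water, Da

# 3-letter -> 1-letter for the 20 standard residues; used when deriving a
# sequence from residue names for mass accounting.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(ValueError):
    """Raised for unreadable files, invalid structures or bad selectors."""


@dataclass
class Atom:
    """A single atom: name (e.g. ``CA``), element symbol and position in Å."""

    name: str
    element: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.name:
            raise StructureError("atom name must be non-empty")
        if not all(math.isfinite(c) for c in self.position):
            raise StructureError(f"non-finite coordinates for atom {self.name!r}")


@dataclass
class Residue:
    """One residue, addressed by author number + insertion code.

    ``name`` is the 3-letter code; modified residues (e.g. lipoyllysine) and
    cofactors (TPP, FAD) are plain residues here.
    """

    number: int
    name: str
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise StructureError(
                f"residue {self.name} {self.number}{self.insertion_code}: duplicate atom names"
            )

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)


@dataclass
class Chain:
    """A chain with a logical component label (E1o | E2o | E3 | MRPS36 | other)."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    component: str = "other"

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise StructureError(f"chain {self.id}: duplicate residue numbers")

    def residue(self, number: int, insertion_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.insertion_code == insertion_code:
                return r
        return None

    def one_letter_sequence(self, unknown: str = "skip") -> str:
        """Sequence from residue names; non-standard names skipped or 'X'."""
        out = []
        for r in self.residues:
            code = THREE_TO_ONE.get(r.name.upper())
            if code is None:
                if unknown == "x":
                    out.append("X")
            else:
                out.append(code)
        return "".join(out)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


@dataclass
class Structure:
    """A set of chains; the object restraint mapping and assembly act on."""

    chains: list[Chain] = field(default_factory=list)
    title: str = ""
    source_format: str = "PDB"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise StructureError(f"duplicate chain ids: {dup}")

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.id == chain_id:
                return c
        return None

    def chains_of(self, component: str) -> list[Chain]:
        return [c for c in self.chains if c.component == component]

    def component_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.chains:
            counts[c.component] = counts.get(c.component, 0) + 1
        return counts

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(c.n_atoms for c in self.chains)

    def copy(self) -> "Structure":
        return Structure(
            chains=[
                Chain(
                    id=c.id,
                    component=c.component,
                    residues=[
                        Residue(
                            number=r.number,
                            name=r.name,
                            insertion_code=r.insertion_code,
                            atoms=[Atom(a.name, a.element, tuple(a.position)) for a in r.atoms],
                        )
                        for r in c.residues
                    ],
                )
                for c in self.chains
            ],
            title=self.title,
            source_format=self.source_format,
        )


# ---------------------------------------------------------------------------
# reading / writing


def _guess_format(path: Path, override: str | None) -> str:
    if override is not None:
        fmt = override.upper().replace("MMCIF", "MMCIF")
        if fmt in {"PDB", "MMCIF", "CIF"}:
            return "PDB" if fmt == "PDB" else "mmCIF"
        raise StructureError(f"unsupported format {override!r} (use 'pdb' or 'mmcif')")
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmCIF"
    if suffix in {".pdb", ".ent"}:
        return "PDB"
    raise StructureError(f"cannot infer format from suffix {suffix!r}; pass format=")


def read_structure(
    path: str | Path,
    format: str | None = None,
    components: Mapping[str, str] | None = None,
    keep_waters: bool = False,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path:
        File to read. Format inferred from the suffix unless ``format`` given.
    components:
        Optional mapping chain id -> component label (``E1o``/``E2o``/``E3``/
        ``MRPS36``); unlisted chains get ``other``.
    keep_waters:
        Retain water residues (dropped by default).

    Heteroatom residues (cofactors, modified residues) are kept; only the
    highest-occupancy alternate conformer is retained per atom name.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = _guess_format(path, format)
    try:
        if fmt == "PDB":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models found")
    model = st[0]

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if not keep_waters and gres.name in _WATER_NAMES:
                continue
            # keep one atom per name: highest occupancy wins among altlocs
            best: dict[str, gemmi.Atom] = {}
            for gatom in gres:
                prev = best.get(gatom.name)
                if prev is None or gatom.occ > prev.occ:
                    best[gatom.name] = gatom
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    position=(ga.pos.x, ga.pos.y, ga.pos.z),
                )
                for ga in best.values()
            ]
            icode = gres.seqid.icode.strip()
            residues.append(
                Residue(number=gres.seqid.num, name=gres.name, insertion_code=icode, atoms=atoms)
            )
        if residues:
            comp = components.get(gchain.name, "other") if components else "other"
            chains.append(Chain(id=gchain.name, residues=residues, component=comp))
    return Structure(chains=chains, title=st.name or path.stem, source_format=fmt)


def fresh_chain_ids(existing: Iterable[str]) -> Iterator[str]:
    """Yield chain ids not in ``existing``: single chars first, then pairs."""
    used = set(existing)
    alphabet = string.ascii_uppercase + string.ascii_lowercase + string.digits
    for ch in alphabet:
        if ch not in used:
            used.add(ch)
            yield ch
    for a in alphabet:
        for b in alphabet:
            cid = a + b
            if cid not in used:
                used.add(cid)
                yield cid


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.title or "model"
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            if res.name not in THREE_TO_ONE:
                gres.het_flag = "H"
            else:
                gres.het_flag = "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = 1.0
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path, format: str | None = None) -> Path:
    """Write a structure as PDB or mmCIF.

    mmCIF is chosen automatically when the structure has more than 62 chains
    or any multi-character chain id (PDB's single-column chain field cannot
    represent those).  An explicit ``format='pdb'`` on such a structure is an
    error listing the offending ids.
    """
    if not structure.chains:
        raise StructureError("refusing to write an empty structure")
    path = Path(path)
    long_ids = [c.id for c in structure.chains if len(c.id) != 1]
    needs_cif = len(structure.chains) > 62 or bool(long_ids)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in {".cif", ".mmcif"}:
            fmt = "mmCIF"
        elif suffix in {".pdb", ".ent"}:
            fmt = "mmCIF" if needs_cif else "PDB"
        else:
            fmt = "mmCIF" if needs_cif else "PDB"
    else:
        fmt = _guess_format(path, format)
    if fmt == "PDB" and needs_cif:
        raise StructureError(
            "structure cannot be written as PDB: "
            + (f"multi-character chain ids {long_ids}" if long_ids else ">62 chains")
        )
    if fmt == "mmCIF" and path.suffix.lower() not in {".cif", ".mmcif"}:
        path = path.with_suffix(path.suffix + ".cif")
    st = _to_gemmi(structure)
    if fmt == "PDB":
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))
    return path


# ---------------------------------------------------------------------------
# masses

# IUPAC average residue masses, Da (residue = amino acid minus one water).
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}


def sequence_mass(sequence: str) -> float:
    """Average molecular mass in Da of a 1-letter amino-acid sequence.

    Sum of average residue masses plus one water (18.0153 Da), i.e. the mass
    of the intact unmodified polypeptide.  Raises on an empty sequence or any
    character outside the 20 standard residues (including ``X``).
    """
    if not sequence:
        raise StructureError("empty sequence has no mass")
    total = WATER_MASS
    for i, ch in enumerate(sequence.upper()):
        try:
            total += AVERAGE_RESIDUE_MASS[ch]
        except KeyError:
            raise StructureError(f"unknown residue {ch!r} at position {i + 1}") from None
    return total


def chain_mass(chain: Chain) -> float:
    """Average mass in Da of a chain from its standard residues."""
    seq = chain.one_letter_sequence()
    if not seq:
        raise StructureError(f"chain {chain.id}: no standard residues to compute a mass from")
    return sequence_mass(seq)
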