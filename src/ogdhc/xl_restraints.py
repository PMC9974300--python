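"""Cross-link restraint parsing, mapping and satisfaction summaries.

A cross-linking MS experiment yields residue pairs (in full precursor
numbering, i.e. including mitochondrial transit peptides) that were close
enough in the native complex for the linker to bridge.  Mapping those pairs
onto a multi-copy structural model turns each identification into a distance
restraint: for a homo-oligomer the pair is ambiguous over the copies, and
the conventional resolution — used here — is the MINIMUM Euclidean Cα–Cα
distance over all chain pairs whose component labels match.  A restraint is
satisfied when that distance is at or below the linker cutoff (30 Å default,
the standard criterion for DSSO-class linkers).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .structure_io import Chain, Structure

__all__ = [
    "CrossLink",
    "NumberingMap",
    "MappedRestraint",
    "RestraintSummary",
    "ParseReport",
    "parse_crosslink_table",
    "map_restraints",
    "summarize_restraints",
    "measure_distance",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 30.0  # Å, Cα–Cα satisfaction threshold

# expected residue chemistry per linker; mismatches warn, never error
LINKER_CHEMISTRY = {
    "DSSO": ({"LYS"}, {"LYS"}),
    "PhoX": ({"LYS"}, {"LYS"}),
    "DMTMM": ({"LYS"}, {"ASP", "GLU"}),
}


@dataclass(frozen=True)
class CrossLink:
    """One identified residue-pair cross-link in precursor numbering."""

    protein_a: str
    residue_a: int
    protein_b: str
    residue_b: int
    linker: str = "DSSO"
    score: float = 0.0
    dataset: str = ""

    def __post_init__(self) -> None:
        if self.residue_a < 1 or self.residue_b < 1:
            raise ValueError(f"residue numbers must be >= 1, got {self.residue_a}, {self.residue_b}")

    @property
    def is_intra(self) -> bool:
        return self.protein_a == self.protein_b

    @property
    def is_degenerate(self) -> bool:
        """Same protein, same residue: not a usable restraint."""
        return self.is_intra and self.residue_a == self.residue_b


@dataclass
class NumberingMap:
    """Per-component offsets converting precursor numbering to structure numbering.

    The offset is the transit-peptide length: subtracting it from the table's
    residue number yields the number used in the structure file.  Components
    absent from the map have offset 0.
    """

    offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.offsets.items() if v < 0}
        if bad:
            raise ValueError(f"offsets must be >= 0: {bad}")

    def to_structure(self, component: str, residue: int) -> int:
        return residue - self.offsets.get(component, 0)


@dataclass
class MappedRestraint:
    """A cross-link realised on a structure as a minimal inter-copy distance."""

    crosslink: CrossLink
    chain_pair: tuple[str, str] | None
    distance: float | None
    status: str  # satisfied | violated | unmapped
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status not in {"satisfied", "violated", "unmapped"}:
            raise ValueError(f"bad status {self.status!r}")
        if (self.distance is None) != (self.status == "unmapped"):
            raise ValueError("distance must be present exactly when mapped")
        if self.distance is not None and self.distance < 0:
            raise ValueError("negative distance")


@dataclass
class RestraintSummary:
    n_total: int
    n_mapped: int
    n_satisfied: int
    satisfied_fraction: float | None
    median_distance: float | None
    max_distance: float | None
    cutoff: float
    per_linker: dict[str, "RestraintSummary"] = field(default_factory=dict)
    violations: list[MappedRestraint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.n_satisfied <= self.n_mapped <= self.n_total):
            raise ValueError("counts must satisfy n_satisfied <= n_mapped <= n_total")


@dataclass
class ParseReport:
    """Outcome of parsing a cross-link table: links plus rejected/duplicate rows."""

    crosslinks: list[CrossLink]
    n_duplicates: int
    invalid_rows: list[tuple[int, str]]  # (0-based row index, reason)


DEFAULT_COLUMNS = {
    "protein_a": "protein_a",
    "residue_a": "residue_a",
    "protein_b": "protein_b",
    "residue_b": "residue_b",
    "linker": "linker",
    "score": "score",
    "dataset": "dataset",
}


def parse_crosslink_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> ParseReport:
    """Parse a delimited cross-link table into unique :class:`CrossLink` rows.

    ``column_map`` maps the canonical field names (keys of
    ``DEFAULT_COLUMNS``) to the table's column names.  Duplicate rows are
    collapsed and counted; rows failing validation (bad residue number,
    degenerate self-link) are reported in ``invalid_rows``, never silently
    dropped.  A missing required column raises, listing the available ones.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    required = ["protein_a", "residue_a", "protein_b", "residue_b"]
    missing = [cols[k] for k in required if cols[k] not in df.columns]
    if missing:
        raise ValueError(
            f"missing required columns {missing}; available: {list(df.columns)}"
        )

    links: list[CrossLink] = []
    seen: dict[CrossLink, int] = {}
    invalid: list[tuple[int, str]] = []
    n_dup = 0
    for idx, row in df.iterrows():
        try:
            link = CrossLink(
                protein_a=str(row[cols["protein_a"]]),
                residue_a=int(row[cols["residue_a"]]),
                protein_b=str(row[cols["protein_b"]]),
                residue_b=int(row[cols["residue_b"]]),
                linker=str(row[cols["linker"]]) if cols["linker"] in df.columns else "DSSO",
                score=float(row[cols["score"]]) if cols["score"] in df.columns else 0.0,
                dataset=str(row[cols["dataset"]]) if cols["dataset"] in df.columns else "",
            )
        except (ValueError, TypeError) as exc:
            invalid.append((int(idx), str(exc)))
            continue
        if link.is_degenerate:
            invalid.append((int(idx), "degenerate self-link (same protein, same residue)"))
            continue
        if link in seen:
            n_dup += 1
        else:
            seen[link] = 1
            links.append(link)
    return ParseReport(crosslinks=links, n_duplicates=n_dup, invalid_rows=invalid)


# ---------------------------------------------------------------------------
# mapping


def _atom_position(chain: Chain, residue_number: int, atom: str) -> np.ndarray | None:
    res = chain.residue(residue_number)
    if res is None:
        return None
    a = res.atom(atom)
    if a is None:
        return None
    return np.asarray(a.position)


def map_restraints(
    structure: Structure,
    crosslinks: Iterable[CrossLink],
    numbering: NumberingMap | None = None,
    atom: str = "CA",
    cutoff: float = DEFAULT_CUTOFF,
) -> list[MappedRestraint]:
    """Map cross-links onto a (possibly multi-copy) structure.

    For each cross-link, candidate chains on either side are all chains whose
    component label equals the cross-link's protein name.  The restraint
    distance is the minimum atom–atom distance over all ordered chain pairs;
    for intra-protein links the identical chain may pair with itself only
    because the residues differ (same-residue self-links are rejected as
    invalid input).  Residues absent from every candidate chain after the
    numbering offset leave the restraint ``unmapped`` with a reason — an
    unknown component name is also ``unmapped``, never a hard failure.
    """
    numbering = numbering or NumberingMap()
    out: list[MappedRestraint] = []
    by_component: dict[str, list[Chain]] = {}
    for ch in structure.chains:
        by_component.setdefault(ch.component, []).append(ch)

    for link in crosslinks:
        if link.is_degenerate:
            raise ValueError(
                f"degenerate self-link {link.protein_a} {link.residue_a}: not a valid restraint"
            )
        chains_a = by_component.get(link.protein_a, [])
        chains_b = by_component.get(link.protein_b, [])
        if not chains_a or not chains_b:
            missing = link.protein_a if not chains_a else link.protein_b
            out.append(
                MappedRestraint(link, None, None, "unmapped", f"no chain with component {missing!r}")
            )
            continue
        num_a = numbering.to_structure(link.protein_a, link.residue_a)
        num_b = numbering.to_structure(link.protein_b, link.residue_b)
        best: tuple[float, tuple[str, str]] | None = None
        for ca, cb in itertools.product(chains_a, chains_b):
            if ca.id == cb.id and num_a == num_b:
                continue  # unreachable for valid links, kept as a guard
            pa = _atom_position(ca, num_a, atom)
            pb = _atom_position(cb, num_b, atom)
            if pa is None or pb is None:
                continue
            d = float(np.linalg.norm(pa - pb))
            if best is None or d < best[0]:
                best = (d, (ca.id, cb.id))
        if best is None:
            out.append(
                MappedRestraint(
                    link, None, None, "unmapped",
                    f"residue {num_a} or {num_b} (structure numbering) absent from all candidate chains",
                )
            )
            continue
        d, pair = best
        status = "satisfied" if d <= cutoff else "violated"
        out.append(MappedRestraint(link, pair, d, status))
    return out


def summarize_restraints(
    mapped: Sequence[MappedRestraint],
    cutoff: float = DEFAULT_CUTOFF,
    _nested: bool = True,
) -> RestraintSummary:
    """Counts, satisfied fraction, median and max distance over mapped restraints.

    The median and max are over mapped restraints only (the convention used
    when quoting a model's agreement with XL-MS data).  Reported both pooled
    and per linker chemistry.  Zero mapped restraints is not an error: the
    median/max/fraction are ``None``.
    """
    mapped = list(mapped)
    distances = [m.distance for m in mapped if m.distance is not None]
    n_mapped = len(distances)
    n_satisfied = sum(1 for d in distances if d <= cutoff)
    violations = [m for m in mapped if m.status != "unmapped" and m.distance > cutoff]
    per_linker: dict[str, RestraintSummary] = {}
    if _nested:
        for linker in sorted({m.crosslink.linker for m in mapped}):
            per_linker[linker] = summarize_restraints(
                [m for m in mapped if m.crosslink.linker == linker], cutoff, _nested=False
            )
    return RestraintSummary(
        n_total=len(mapped),
        n_mapped=n_mapped,
        n_satisfied=n_satisfied,
        satisfied_fraction=(n_satisfied / n_mapped) if n_mapped else None,
        median_distance=float(np.median(distances)) if distances else None,
        max_distance=float(max(distances)) if distances else None,
        cutoff=cutoff,
        per_linker=per_linker,
        violations=violations,
    )


def restraints_to_frame(mapped: Sequence[MappedRestraint]) -> pd.DataFrame:
    """Tabular view of mapped restraints (one row per cross-link)."""
    rows = []
    for m in mapped:
        rows.append(
            {
                "protein_a": m.crosslink.protein_a,
                "residue_a": m.crosslink.residue_a,
                "protein_b": m.crosslink.protein_b,
                "residue_b": m.crosslink.residue_b,
                "linker": m.crosslink.linker,
                "chain_a": m.chain_pair[0] if m.chain_pair else "",
                "chain_b": m.chain_pair[1] if m.chain_pair else "",
                "distance": m.distance if m.distance is not None else float("nan"),
                "status": m.status,
                "reason": m.reason,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# point distance measurements (cofactor geometry etc.)


def _resolve_selector(
    structure: Structure, selector: tuple[str, int, str | None]
) -> list[np.ndarray]:
    chain_id, residue_number, atom_name = selector
    chain = structure.chain(chain_id)
    if chain is None:
        raise ValueError(f"selector {selector}: no chain {chain_id!r}")
    res = chain.residue(residue_number)
    if res is None:
        raise ValueError(f"selector {selector}: no residue {residue_number} in chain {chain_id}")
    if atom_name is None:
        atoms = res.atoms
    else:
        a = res.atom(atom_name)
        atoms = [a] if a is not None else []
    if not atoms:
        raise ValueError(f"selector {selector}: no atoms matched")
    return [np.asarray(a.position) for a in atoms]


def measure_distance(
    structure: Structure,
    selector_a: tuple[str, int, str | None],
    selector_b: tuple[str, int, str | None],
) -> float:
    """Minimum pairwise distance (Å) between two atom selections.

    A selector is ``(chain_id, residue_number, atom_name_or_None)``; ``None``
    selects every atom of the residue, so a whole cofactor (TPP, FAD,
    lipoyl group) can stand on one side.  Deterministic: the minimum over
    all cross pairs.
    """
    pts_a = _resolve_selector(structure, selector_a)
    pts_b = _resolve_selector(structure, selector_b)
    best = math.inf
    for pa in pts_a:
        for pb in pts_b:
            best = min(best, float(np.linalg.norm(pa - pb)))
    return best
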