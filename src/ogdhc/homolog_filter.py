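"""Homolog selection from BLAST hit tables and alignment conservation.

Phylogenetic analyses of a protein family start from a BLAST search whose
raw hit list is redundant: many strains of one species, many species of one
genus.  The selection rule applied here keeps, among the top hits by
bitscore, at most a few species per genus, subject to query-coverage and
identity thresholds (coverage strictly above 50%, identity strictly below
90% by default) — near-identical hits carry no phylogenetic signal and
low-coverage hits are unreliable homologs.

The curated-alignment statistic computed here is the invariant-site count:
columns with the same residue in every sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "BlastHit",
    "AlignmentBlock",
    "FilterResult",
    "filter_blast_hits",
    "alignment_conservation",
    "read_blast_tabular",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYBXZJUO")
GAP_CHARS = set("-.")


@dataclass(frozen=True)
class BlastHit:
    """One homology hit with the taxonomy needed for per-genus capping."""

    query_id: str
    subject_id: str
    species: str
    genus: str
    identity: float  # fraction, 0-1
    query_coverage: float  # fraction, 0-1
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 1:
            raise ValueError(f"identity must be a fraction in [0, 1], got {self.identity}")
        if not 0 <= self.query_coverage <= 1:
            raise ValueError(f"coverage must be a fraction in [0, 1], got {self.query_coverage}")
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")


@dataclass
class AlignmentBlock:
    """Equal-length gapped sequences (one multiple alignment)."""

    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        for s in self.sequences:
            bad = set(s.upper()) - AMINO_ACIDS - GAP_CHARS
            if bad:
                raise ValueError(f"non-amino-acid characters in alignment: {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])


@dataclass
class FilterResult:
    selected: list[BlastHit]
    n_input: int
    n_after_truncation: int
    n_after_thresholds: int
    n_missing_taxonomy: int


def _sort_key(hit: BlastHit):
    # bitscore descending; ties: e-value ascending, then subject id lexicographic
    return (-hit.bitscore, hit.evalue, hit.subject_id)


def filter_blast_hits(
    hits: Sequence[BlastHit],
    top_n: int = 500,
    min_coverage: float = 0.5,
    max_identity: float = 0.9,
    max_species_per_genus: int = 4,
) -> FilterResult:
    """Rule-based homolog selection from a BLAST hit list.

    Pipeline, in fixed order:

    1. sort by bitscore (desc; ties e-value asc, then subject id) and
       truncate to the top ``top_n``;
    2. drop hits with coverage <= ``min_coverage`` or identity >=
       ``max_identity`` (strict inequalities retained);
    3. collapse to the best hit per species;
    4. keep at most ``max_species_per_genus`` species per genus, best first.

    Hits without taxonomy (empty species or genus) are excluded and counted.
    Deterministic: shuffling the input leaves the output identical.
    """
    n_input = len(hits)
    with_tax = [h for h in hits if h.species and h.genus]
    n_missing = n_input - len(with_tax)
    ranked = sorted(with_tax, key=_sort_key)
    truncated = ranked[:top_n]
    passed = [
        h for h in truncated if h.query_coverage > min_coverage and h.identity < max_identity
    ]
    best_per_species: dict[tuple[str, str], BlastHit] = {}
    for h in passed:  # already in rank order; first seen is the best
        key = (h.genus, h.species)
        if key not in best_per_species:
            best_per_species[key] = h
    per_genus: dict[str, list[BlastHit]] = {}
    for h in best_per_species.values():
        per_genus.setdefault(h.genus, []).append(h)
    selected: list[BlastHit] = []
    for genus in per_genus:
        kept = sorted(per_genus[genus], key=_sort_key)[:max_species_per_genus]
        selected.extend(kept)
    selected.sort(key=_sort_key)
    return FilterResult(
        selected=selected,
        n_input=n_input,
        n_after_truncation=len(truncated),
        n_after_thresholds=len(passed),
        n_missing_taxonomy=n_missing,
    )


def alignment_conservation(
    block: AlignmentBlock, gap_policy: str = "strict"
) -> tuple[int, float]:
    """Count invariant columns of an alignment.

    An invariant column has the identical non-gap residue in every row.
    ``gap_policy='strict'``: any gap disqualifies the column;
    ``'lenient'``: gaps are ignored and the non-gap residues must agree
    (an all-gap column is not invariant).  Returns
    ``(n_invariant, n_invariant / n_columns)``.
    """
    if gap_policy not in {"strict", "lenient"}:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    n_invariant = 0
    for col in zip(*[s.upper() for s in block.sequences]):
        residues = [c for c in col if c not in GAP_CHARS]
        has_gap = len(residues) < len(col)
        if not residues:
            continue
        if len(set(residues)) == 1 and not (gap_policy == "strict" and has_gap):
            n_invariant += 1
    return n_invariant, n_invariant / block.n_columns


# ---------------------------------------------------------------------------
# I/O

#: BLAST outfmt 6 default columns, extended with subject scientific name
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _parse_taxonomy(name: str) -> tuple[str, str]:
    """Leading 'Genus species' tokens from a scientific-name string."""
    tokens = str(name).split()
    if len(tokens) >= 2:
        return tokens[0], f"{tokens[0]} {tokens[1]}"
    if len(tokens) == 1 and tokens[0]:
        return tokens[0], tokens[0]
    return "", ""


def read_blast_tabular(
    path: str | Path,
    columns: Sequence[str] | None = None,
    query_length: int | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[BlastHit]:
    """Read BLAST tabular output (outfmt 6, optionally with ``ssciname``/``qcovs``).

    ``columns`` names the file's columns (default: outfmt 6 standard set +
    any extras appended, commonly ``ssciname`` and ``qcovs``).  Coverage is
    taken from a ``qcovs`` column (percent) when present, otherwise computed
    from the aligned query range and ``query_length``.  Species/genus come
    from ``ssciname`` ("Genus species" leading tokens).  A generic CSV with
    explicit ``column_map`` (canonical name -> file column) is also accepted.
    """
    path = Path(path)
    if column_map is not None:
        df = pd.read_csv(path, sep=None, engine="python")
        hits = []
        for _, row in df.iterrows():
            def get(name, default=None):
                col = column_map.get(name)
                return row[col] if col and col in df.columns else default

            species = str(get("species", ""))
            genus = str(get("genus", "")) or _parse_taxonomy(species)[0]
            hits.append(
                BlastHit(
                    query_id=str(get("query_id", "")),
                    subject_id=str(get("subject_id", "")),
                    species=species,
                    genus=genus,
                    identity=float(get("identity", 0.0)),
                    query_coverage=float(get("query_coverage", 0.0)),
                    bitscore=float(get("bitscore", 0.0)),
                    evalue=float(get("evalue", 0.0)),
                )
            )
        return hits

    names = list(columns) if columns else OUTFMT6_COLUMNS + ["ssciname", "qcovs"]
    df = pd.read_csv(path, sep="\t", names=names, comment="#")
    hits = []
    for _, row in df.iterrows():
        sci = str(row["ssciname"]) if "ssciname" in names else ""
        genus, species = _parse_taxonomy(sci)
        if "qcovs" in names and not pd.isna(row.get("qcovs")):
            coverage = float(row["qcovs"]) / 100.0
        elif query_length:
            coverage = (abs(int(row["qend"]) - int(row["qstart"])) + 1) / query_length
        else:
            raise ValueError("no qcovs column and no query_length to compute coverage from")
        hits.append(
            BlastHit(
                query_id=str(row["qseqid"]),
                subject_id=str(row["sseqid"]),
                species=species,
                genus=genus,
                identity=float(row["pident"]) / 100.0,
                query_coverage=coverage,
                bitscore=float(row["bitscore"]),
                evalue=float(row["evalue"]),
            )
        )
    return hits
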