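"""Sequence, alignment and table I/O.

Everything downstream (ANI engines, marker screening, taxonomy audits) consumes
the containers defined here: :class:`SequenceRecord` for raw FASTA records,
:class:`GeneAlignment` for one aligned marker gene, and :class:`StrainPanel`
binding strains, species labels, genomes and gene alignments together.

FASTA parsing goes through Biopython; newick parsing through dendropy. ANI
matrices are written as full symmetric TSV tables (strain ids as row/column
headers) so they round-trip exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO as _BioSeqIO

__all__ = [
    "SequenceRecord",
    "GeneAlignment",
    "StrainRecord",
    "StrainPanel",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "alignment_from_fasta",
    "concatenate",
    "read_newick",
    "read_labels",
    "write_labels",
    "write_ani_table",
    "read_ani_table",
]

# IUPAC nucleotide one-letter codes plus gap.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")
UNAMBIGUOUS = frozenset("ACGT")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (empty, duplicate ids, bad characters)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single nucleotide sequence with its identifier."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaParseError("empty sequence id")
        if not self.seq:
            raise FastaParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq.upper()) - IUPAC_CHARS
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )


@dataclass
class GeneAlignment:
    """One gene's multiple alignment: strain id -> aligned row."""

    gene_name: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError(f"alignment {self.gene_name!r}: needs >=2 rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(
                f"alignment {self.gene_name!r}: unequal row lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def strain_ids(self) -> list[str]:
        return list(self.rows)

    def ungapped_length(self) -> int:
        """Alignment length excluding columns that are gap in every row."""
        n = self.length
        all_gap = 0
        rows = list(self.rows.values())
        for j in range(n):
            if all(r[j] == "-" for r in rows):
                all_gap += 1
        return n - all_gap


@dataclass(frozen=True)
class StrainRecord:
    id: str
    species: str
    is_type_strain: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty strain id")
        if not self.species or not self.species.strip():
            raise ValueError(f"strain {self.id!r}: empty species label")


def _norm_species(label: str) -> str:
    """Species labels compare case-insensitively after trimming."""
    return label.strip().lower()


@dataclass
class StrainPanel:
    """Strains with species labels plus optional genomes and gene alignments."""

    strains: list[StrainRecord]
    genomes: dict[str, str] = field(default_factory=dict)
    gene_alignments: list[GeneAlignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.strains]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate strain ids in panel")
        known = set(ids)
        for aln in self.gene_alignments:
            extra = set(aln.rows) - known
            if extra:
                raise ValueError(
                    f"alignment {aln.gene_name!r}: unknown strains {sorted(extra)}"
                )
        names = [a.gene_name for a in self.gene_alignments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in panel")
        # at most one type strain per species
        seen: dict[str, str] = {}
        for s in self.strains:
            if s.is_type_strain:
                key = _norm_species(s.species)
                if key in seen:
                    raise ValueError(
                        f"species {s.species!r}: multiple type strains "
                        f"({seen[key]!r}, {s.id!r})"
                    )
                seen[key] = s.id

    @property
    def labels(self) -> dict[str, str]:
        return {s.id: s.species for s in self.strains}

    def alignment(self, gene_name: str) -> GeneAlignment:
        for a in self.gene_alignments:
            if a.gene_name == gene_name:
                return a
        raise KeyError(f"no alignment for gene {gene_name!r}")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Whitespace inside sequences is stripped; case is preserved. Duplicate ids,
    empty files and non-IUPAC characters raise :class:`FastaParseError`.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        seq = re.sub(r"\s+", "", str(rec.seq))
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, seq, rec.description))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def alignment_from_fasta(path: str | Path, gene_name: str | None = None) -> GeneAlignment:
    """Load an aligned FASTA as a :class:`GeneAlignment` (name defaults to the stem)."""
    path = Path(path)
    recs = read_fasta(path)
    return GeneAlignment(gene_name or path.stem, {r.id: r.seq for r in recs})


def concatenate(alignments: Sequence[GeneAlignment], order: Sequence[str] | None = None) -> GeneAlignment:
    """Concatenate gene alignments row-wise in the given gene order.

    Every gene must cover exactly the same strain set; a strain missing from
    one gene is an error (no silent padding), because the concatenate ANI is
    defined only over strains sequenced for all member genes. The result's
    ``offsets`` attribute records each gene's starting column.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    by_name = {a.gene_name: a for a in alignments}
    if len(by_name) != len(alignments):
        raise ValueError("duplicate gene names among alignments")
    if order is None:
        order = [a.gene_name for a in alignments]
    if sorted(order) != sorted(by_name):
        raise ValueError(f"order {list(order)} does not list each gene exactly once")

    ref_ids = set(alignments[0].rows)
    for a in alignments:
        missing = ref_ids - set(a.rows)
        extra = set(a.rows) - ref_ids
        if missing or extra:
            which = sorted(missing or extra)
            raise ValueError(
                f"gene {a.gene_name!r}: strain set mismatch (offending: {which})"
            )

    offsets: dict[str, int] = {}
    pos = 0
    for name in order:
        offsets[name] = pos
        pos += by_name[name].length
    rows = {
        sid: "".join(by_name[name].rows[sid] for name in order)
        for sid in alignments[0].rows
    }
    cat = GeneAlignment("+".join(order), rows)
    cat.offsets = offsets  # type: ignore[attr-defined]
    return cat


def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a newick tree; duplicate leaf names and syntax errors raise ValueError."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"{path}: newick parse error: {exc}") from exc
    names = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate leaf names")
    return tree


def read_labels(path: str | Path) -> StrainPanel:
    """Read a labels TSV (strain_id, species, is_type_strain) into a bare panel."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"strain_id", "species"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: labels TSV needs columns {sorted(required)}")
    strains = []
    for _, row in df.iterrows():
        flag = str(row.get("is_type_strain", "0")).strip().lower() in {"1", "true", "yes"}
        strains.append(StrainRecord(row["strain_id"], row["species"], flag))
    return StrainPanel(strains=strains)


def write_labels(panel: StrainPanel, path: str | Path) -> None:
    pd.DataFrame(
        {
            "strain_id": [s.id for s in panel.strains],
            "species": [s.species for s in panel.strains],
            "is_type_strain": [int(s.is_type_strain) for s in panel.strains],
        }
    ).to_csv(path, sep="\t", index=False)


def write_ani_table(table, path: str | Path) -> None:
    """Write a PairwiseANITable as a full symmetric TSV matrix (ids as headers)."""
    ids = table.ids
    df = pd.DataFrame(
        [[table.get(a, b) for b in ids] for a in ids], index=ids, columns=ids
    )
    with open(path, "w") as fh:
        fh.write(f"# source={table.source}\n")
        df.to_csv(fh, sep="\t", float_format="%.6f")


def read_ani_table(path: str | Path):
    """Read a TSV ANI matrix written by :func:`write_ani_table`."""
    from .ani import PairwiseANITable  # local import to avoid a cycle

    source = "genome"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# source="):
            source = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    table = PairwiseANITable(source=source)
    ids = list(df.index)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            table.set(a, b, float(df.loc[a, b]))
    return table
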