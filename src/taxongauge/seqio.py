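"""Sequence and table IO plus basic replicon statistics.

Conventions used throughout the package:

* coordinates are 0-based, half-open; strand is encoded as ``+``/``-``;
* sequence comparisons are case-insensitive (RefSeq assemblies mix case);
* IUPAC ambiguity codes are accepted in nucleotide input, counted in
  sequence length but excluded from GC content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from skbio import TreeNode

NUCLEOTIDE_ALPHABET = set("ACGTURYSWKMBDHVN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A single named sequence with a declared alphabet."""

    id: str
    sequence: str
    description: str = ""
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence of record {self.id!r} is empty")
        allowed = NUCLEOTIDE_ALPHABET if self.alphabet == "nucleotide" else PROTEIN_ALPHABET
        bad = set(self.sequence.upper()) - allowed - {"-", "."}
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters outside the "
                f"{self.alphabet} alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeRecord:
    """A strain's assembly: one or more contigs plus taxonomy metadata."""

    strain_id: str
    contigs: list[SeqRecord]
    current_genus: str = ""
    current_species: str = ""
    type_strain: bool = False
    phylotype: str | None = None

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError(f"genome {self.strain_id!r} has no contigs")
        if self.total_length == 0:
            raise ValueError(f"genome {self.strain_id!r} has zero total length")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass
class GenomeStats:
    total_length: int
    gc_percent: float
    n_contigs: int
    gc_defined: bool = True


def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects.

    Line wrapping is collapsed; original case is preserved. Characters
    outside the declared IUPAC alphabet raise a ``ValueError`` naming the
    offending record.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path} is empty")
    if not text.lstrip().startswith(">"):
        raise ValueError(f"{path} is not FASTA: no '>' header found")
    records = [
        SeqRecord(
            id=rec.id,
            sequence=str(rec.seq),
            description=rec.description[len(rec.id):].strip(),
            alphabet=alphabet,
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path} contains no sequence records")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def genome_stats(genome: GenomeRecord) -> GenomeStats:
    """Length / GC summary of a nucleotide genome.

    ``gc_percent = 100 * (G + C) / (A + C + G + T)``; ambiguity codes are
    excluded from both numerator and denominator while ``total_length``
    counts every residue. A genome with no unambiguous base gets
    ``gc_percent = nan`` with ``gc_defined=False``.
    """
    gc = at = 0
    for contig in genome.contigs:
        seq = contig.sequence.upper()
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    total = genome.total_length
    if gc + at == 0:
        return GenomeStats(total, float("nan"), len(genome.contigs), gc_defined=False)
    return GenomeStats(total, 100.0 * gc / (gc + at), len(genome.contigs))


METADATA_COLUMNS = ["strain_id", "current_genus", "current_species", "type_strain", "phylotype"]


def read_tsv_metadata(path: str | Path) -> list[GenomeRecord]:
    """Read the strain metadata table into genome stubs (no contigs attached).

    The stubs carry a single placeholder contig so downstream code can rely
    on the ``GenomeRecord`` invariants; replace ``contigs`` after loading
    sequence data.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    dupes = df["strain_id"][df["strain_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate strain ids in metadata: {dupes}")
    stubs = []
    for row in df.itertuples(index=False):
        stubs.append(
            GenomeRecord(
                strain_id=row.strain_id,
                contigs=[SeqRecord(id=row.strain_id, sequence="N")],
                current_genus=row.current_genus,
                current_species=row.current_species,
                type_strain=str(row.type_strain).strip().lower() in {"1", "true", "yes"},
                phylotype=row.phylotype or None,
            )
        )
    return stubs


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a square labelled matrix as TSV (row/column labels preserved)."""
    matrix.to_csv(path, sep="\t", index=True)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    return df


def read_newick(path: str | Path) -> TreeNode:
    """Read newick; numeric internal-node labels become bootstrap supports."""
    tree = TreeNode.read(str(path), format="newick")
    tree.assign_supports()
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    # skbio's writer emits the ``support`` attribute as the internal label
    tree.write(str(path), format="newick")
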