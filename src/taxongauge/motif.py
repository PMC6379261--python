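"""Degenerate-consensus motif scanning with mismatch tolerance.

Scans genomes for replication features written as IUPAC consensus
strings — DnaA boxes near chromosomal origins and RepA/TrfA iterons on
plasmid-type replicons — reporting every window (on either strand) whose
number of IUPAC-class violations stays within the allowance.  Whole
replicons are scanned; restricting to an origin-proximal window is left
to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import GenomeRecord, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class MotifPattern:
    name: str
    consensus: str  # IUPAC nucleotide codes
    max_mismatches: int = 0
    search_both_strands: bool = True

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        if len(self.consensus) < 4:
            raise ValueError("consensus must be at least 4 bases long")
        bad = set(self.consensus) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC codes in consensus: {sorted(bad)}")


@dataclass
class MotifHit:
    contig: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    mismatches: int
    matched_sequence: str


def normalize_alternatives(consensus: str) -> str:
    """Convert ``(A/T)``-style alternative groups to IUPAC codes."""
    out = []
    i = 0
    inv = {frozenset(v): k for k, v in IUPAC.items()}
    while i < len(consensus):
        if consensus[i] == "(":
            j = consensus.index(")", i)
            bases = frozenset(consensus[i + 1 : j].upper().split("/"))
            out.append(inv[bases])
            i = j + 1
        else:
            out.append(consensus[i].upper())
            i += 1
    return "".join(out)


def _mismatch_table(pattern: MotifPattern) -> np.ndarray:
    """(pattern length, 5) boolean table; column 4 = non-ACGT genome chars.
    A genome N (or other ambiguity code) never matches a non-N pattern
    class; the fully unconstrained N class matches anything."""
    table = np.ones((len(pattern.consensus), 5), dtype=bool)
    for i, code in enumerate(pattern.consensus):
        for base in IUPAC[code]:
            table[i, _BASE_CODE[base]] = False
        if code == "N":
            table[i, 4] = False
    return table


def _scan_strand(seq_codes: np.ndarray, table: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    m = table.shape[0]
    n_windows = len(seq_codes) - m + 1
    if n_windows <= 0:
        return []
    mismatches = np.zeros(n_windows, dtype=np.int32)
    for i in range(m):
        mismatches += table[i][seq_codes[i : i + n_windows]]
    starts = np.nonzero(mismatches <= max_mm)[0]
    return [(int(s), int(mismatches[s])) for s in starts]


def scan(genome: GenomeRecord, pattern: MotifPattern) -> list[MotifHit]:
    """All windows matching the consensus within the mismatch allowance.

    Both strands are searched when the pattern allows it; a minus-strand
    hit is reported in plus-strand coordinates.  Overlapping hits are all
    reported.  Output is sorted by (contig, start, strand).
    """
    table = _mismatch_table(pattern)
    m = len(pattern.consensus)
    hits: list[MotifHit] = []
    for contig in genome.contigs:
        seq = contig.sequence.upper()
        codes = np.array([_BASE_CODE.get(c, 4) for c in seq], dtype=np.int64)
        for start, mm in _scan_strand(codes, table, pattern.max_mismatches):
            hits.append(MotifHit(contig.id, start, start + m, "+", mm, seq[start : start + m]))
        if pattern.search_both_strands:
            rc = reverse_complement(seq).upper()
            rc_codes = np.array([_BASE_CODE.get(c, 4) for c in rc], dtype=np.int64)
            for rc_start, mm in _scan_strand(rc_codes, table, pattern.max_mismatches):
                start = len(seq) - rc_start - m
                hits.append(MotifHit(contig.id, start, start + m, "-", mm, seq[start : start + m]))
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def builtin_patterns() -> list[MotifPattern]:
    """The replication-feature consensi this package ships.

    DnaA box TT(A/T)TNCACA with at most one mismatch; RepA and TrfA
    iterons with a default allowance of two mismatches (the iteron
    allowance is a package default, configurable on the pattern).
    """
    return [
        MotifPattern("DnaA_box", normalize_alternatives("TT(A/T)TNCACA"), max_mismatches=1),
        MotifPattern(
            "RepA_iteron",
            normalize_alternatives("CGC(A/T)GA(A/T)(A/T)(C/T)(A/C/G)GGT(A/T)CG(C/G)"),
            max_mismatches=2,
        ),
        MotifPattern(
            "TrfA_iteron",
            normalize_alternatives("(A/C/G)(A/C/T)GCCCC(C/T)CA(A/T)GTGTCA"),
            max_mismatches=2,
        ),
    ]
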