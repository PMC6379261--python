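"""Percentage of conserved proteins (POCP) and the genus-assignment rule.

POCP between proteomes a and b is ``100 * (C1 + C2) / (T1 + T2)`` where
``C1`` counts proteins of a with a qualifying best BLASTP-style hit in b
(E-value < 1e-5, identity >= 40%, alignable region of the query >= 50%)
and ``C2`` is the symmetric count (Qin et al.'s definition, with the
filter values this package adopts as defaults).  A 60% POCP boundary
separates genera.

Alignments use BLOSUM62 with affine gaps via Bio.Align; the E-value is a
Karlin-Altschul approximation (ungapped-regime constants K=0.041,
lambda=0.267) with search space = query length x total target residues.
At the 40%/50% cut-offs the identity and coverage filters dominate, so
the approximation is benign; no external BLAST is invoked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SeqRecord


@dataclass
class POCPConfig:
    max_evalue: float = 1e-5
    min_identity: float = 40.0
    min_coverage: float = 0.50
    gap_open: float = -11.0
    gap_extend: float = -1.0
    karlin_k: float = 0.041
    karlin_lambda: float = 0.267

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        return aligner


@dataclass
class ProteomeRecord:
    strain_id: str
    proteins: list[SeqRecord]

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"proteome {self.strain_id!r} is empty")

    @property
    def total(self) -> int:
        return len(self.proteins)

    @property
    def total_residues(self) -> int:
        return sum(len(p) for p in self.proteins)


@dataclass
class POCPResult:
    id_a: str
    id_b: str
    C1: int
    C2: int
    T1: int
    T2: int

    @property
    def pocp(self) -> float:
        return 100.0 * (self.C1 + self.C2) / (self.T1 + self.T2)


@dataclass
class GenusCall:
    strain_id: str
    mean_pocp_by_genus: dict[str, float]
    call: str  # genus label | "neither" | "ambiguous"


def protein_best_hit(
    query: SeqRecord,
    target_proteome: ProteomeRecord,
    config: POCPConfig | None = None,
) -> tuple[float, float, float] | None:
    """Best local alignment of a query protein against a target proteome.

    Returns ``(identity %, query coverage fraction, E-value)`` for the
    highest-scoring target, or ``None`` for an empty target.  Identity is
    computed over alignment columns (gap columns count against it);
    coverage is aligned query residues / query length.
    """
    config = config or POCPConfig()
    if not target_proteome.proteins:
        return None
    aligner = config.aligner()
    qseq = query.sequence.upper()
    scores = [aligner.score(qseq, t.sequence.upper()) for t in target_proteome.proteins]
    best_idx = int(np.argmax(scores))
    alignments = aligner.align(qseq, target_proteome.proteins[best_idx].sequence.upper())
    alignment = alignments[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    qstart, qend = alignment.aligned[0][0][0], alignment.aligned[0][-1][1]
    coverage = (qend - qstart) / len(qseq)
    search_space = len(qseq) * target_proteome.total_residues
    evalue = config.karlin_k * search_space * math.exp(-config.karlin_lambda * alignment.score)
    return identity, float(coverage), evalue


def _conserved_count(a: ProteomeRecord, b: ProteomeRecord, config: POCPConfig) -> int:
    count = 0
    for protein in a.proteins:
        hit = protein_best_hit(protein, b, config)
        if hit is None:
            continue
        identity, coverage, evalue = hit
        if identity >= config.min_identity and coverage >= config.min_coverage and evalue < config.max_evalue:
            count += 1
    return count


def pocp_pair(a: ProteomeRecord, b: ProteomeRecord, config: POCPConfig | None = None) -> POCPResult:
    """POCP between two proteomes; symmetric in its arguments.

    Each direction counts query proteins with one qualifying best hit in
    the other proteome ("alignable region of the query" is interpreted
    per-direction); no reciprocal-best requirement.
    """
    config = config or POCPConfig()
    return POCPResult(
        id_a=a.strain_id,
        id_b=b.strain_id,
        C1=_conserved_count(a, b, config),
        C2=_conserved_count(b, a, config),
        T1=a.total,
        T2=b.total,
    )


def mean_pocp_vs_group(
    strain: ProteomeRecord,
    group: list[ProteomeRecord],
    config: POCPConfig | None = None,
) -> float:
    """Arithmetic mean POCP of a strain against a group of proteomes.

    Self-comparisons (same strain id) are excluded from the mean.
    """
    others = [p for p in group if p.strain_id != strain.strain_id]
    if not others:
        raise ValueError("group contains no proteomes other than the strain itself")
    return float(np.mean([pocp_pair(strain, other, config).pocp for other in others]))


def genus_call(
    strain_id: str,
    mean_by_genus: dict[str, float],
    threshold: float = 60.0,
) -> GenusCall:
    """Assign a genus from mean POCP values at the genus boundary (60%).

    Exactly one genus at/above threshold names the genus; none ->
    ``"neither"``; more than one -> ``"ambiguous"``.
    """
    if not mean_by_genus:
        raise ValueError("mean_by_genus must name at least one genus")
    above = sorted(g for g, v in mean_by_genus.items() if v >= threshold)
    if len(above) == 1:
        call = above[0]
    elif not above:
        call = "neither"
    else:
        call = "ambiguous"
    return GenusCall(strain_id, dict(mean_by_genus), call)
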