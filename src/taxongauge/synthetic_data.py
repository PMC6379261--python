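"""Synthetic genomes, proteomes, marker alignments and evidence panels.

Every generator returns its ground truth alongside the data and is
bit-reproducible for a given seed, so each pipeline stage can be tested
at desk scale without downloading assemblies.  Sequence evolution is
Jukes-Cantor-style (uniform choice among the three alternative bases);
indels default to off for ANI-calibration fixtures so that the expected
ungapped identity stays analytic at 1 - substitution_rate.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from . import consensus
from .motif import IUPAC, MotifPattern
from .phylo import MarkerAlignment
from .pocp import ProteomeRecord
from .seqio import GenomeRecord, SeqRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# checksum of the packaged strain-panel evidence table (guards against
# accidental edits to hand-transcribed reference data)
EVIDENCE_SHA256 = "46349ddfb01569ebd5c75983fa6bd31be26c90adea2531af82d44aa1f06ef685"


@dataclass
class CladeDesign:
    clade_id: str
    n_strains: int
    within_identity: float  # expected pairwise identity inside the clade
    between_identity: float  # expected identity to strains of other clades


@dataclass
class SimConfig:
    seed: int
    genome_length: int = 50_000
    gc: float = 0.655
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    mean_indel_length: int = 3
    panel: list[CladeDesign] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.indel_rate):
            if not (0.0 <= rate < 1.0):
                raise ValueError("rates must lie in [0, 1)")
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must lie in [0, 1]")


def _seq_to_array(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.encode(), dtype=np.uint8)


def generate_ancestor(length: int, gc: float, seed: int) -> GenomeRecord:
    """Random genome with i.i.d. bases, P(G or C) = gc."""
    if length < 4:
        raise ValueError("length must be >= 4")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = rng.choice(_BASES, size=length, p=probs).tobytes().decode()
    return GenomeRecord(strain_id=f"anc_{seed}", contigs=[SeqRecord(id="contig_1", sequence=seq)])


def evolve(
    genome: GenomeRecord,
    substitution_rate: float,
    indel_rate: float = 0.0,
    seed: int = 0,
    mean_indel_length: int = 3,
    strain_id: str | None = None,
) -> GenomeRecord:
    """Mutate a genome site-wise; substitutions pick uniformly among the
    three alternative bases, indels are geometric-length events."""
    rng = np.random.default_rng(seed)
    contigs = []
    for contig in genome.contigs:
        arr = _seq_to_array(contig.sequence.upper()).copy()
        if substitution_rate > 0:
            mask = rng.random(len(arr)) < substitution_rate
            idx = np.nonzero(mask)[0]
            if len(idx):
                base_index = np.searchsorted(_BASES, arr[idx])
                shift = rng.integers(1, 4, size=len(idx))
                arr[idx] = _BASES[(base_index + shift) % 4]
        seq = arr.tobytes().decode()
        if indel_rate > 0:
            out = []
            p_geom = 1.0 / mean_indel_length
            i = 0
            while i < len(seq):
                if rng.random() < indel_rate:
                    size = int(rng.geometric(p_geom))
                    if rng.random() < 0.5:  # deletion
                        i += size
                        continue
                    out.append(rng.choice(_BASES, size=size).tobytes().decode())
                out.append(seq[i])
                i += 1
            seq = "".join(out)
        contigs.append(SeqRecord(id=contig.id, sequence=seq))
    return GenomeRecord(strain_id=strain_id or f"{genome.strain_id}_mut", contigs=contigs)


def generate_panel(config: SimConfig) -> tuple[list[GenomeRecord], dict[str, str]]:
    """Strain panel with planted clade structure.

    Each clade descends from a clade ancestor; strains diverge
    independently so that expected within-clade identity is
    ``within_identity`` and identity between clades is
    ``between_identity``.  Returns (genomes, strain -> clade id truth).
    """
    if not config.panel:
        raise ValueError("panel design is empty")
    for design in config.panel:
        if design.within_identity <= design.between_identity:
            raise ValueError(
                f"clade {design.clade_id!r}: within-identity must exceed between-identity"
            )
    rng = np.random.default_rng(config.seed)
    root = generate_ancestor(config.genome_length, config.gc, int(rng.integers(2**31)))
    genomes, truth = [], {}
    for design in config.panel:
        # split divergence between root->clade and clade->strain branches
        strain_rate = (1.0 - design.within_identity) / 2.0
        clade_rate = max((1.0 - design.between_identity) / 2.0 - strain_rate, 0.0)
        clade_ancestor = evolve(root, clade_rate, seed=int(rng.integers(2**31)))
        for s in range(design.n_strains):
            strain_id = f"{design.clade_id}_{s + 1}"
            strain = evolve(
                clade_ancestor,
                strain_rate,
                indel_rate=config.indel_rate,
                seed=int(rng.integers(2**31)),
                strain_id=strain_id,
            )
            genomes.append(strain)
            truth[strain_id] = design.clade_id
    return genomes, truth


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AMINO_ACIDS), size=length))


def mutate_protein(rng: np.random.Generator, sequence: str, divergence: float) -> str:
    out = []
    for residue in sequence:
        if rng.random() < divergence:
            out.append(rng.choice([a for a in _AMINO_ACIDS if a != residue]))
        else:
            out.append(residue)
    return "".join(out)


def generate_proteome_pair(
    n_proteins: int,
    shared_fraction: float,
    divergence: float = 0.05,
    length_range: tuple[int, int] = (120, 250),
    seed: int = 0,
) -> tuple[ProteomeRecord, ProteomeRecord, float]:
    """Two proteomes sharing a planted fraction of diverged orthologs.

    The remaining proteins are strain-specific random sequences, so the
    planted POCP equals ``100 * shared_fraction``.
    """
    rng = np.random.default_rng(seed)
    n_shared = round(n_proteins * shared_fraction)
    proteins_a, proteins_b = [], []
    for i in range(n_shared):
        length = int(rng.integers(*length_range))
        ancestor = random_protein(rng, length)
        proteins_a.append(SeqRecord(f"a_{i}", mutate_protein(rng, ancestor, divergence), alphabet="protein"))
        proteins_b.append(SeqRecord(f"b_{i}", mutate_protein(rng, ancestor, divergence), alphabet="protein"))
    for i in range(n_shared, n_proteins):
        proteins_a.append(
            SeqRecord(f"a_{i}", random_protein(rng, int(rng.integers(*length_range))), alphabet="protein")
        )
        proteins_b.append(
            SeqRecord(f"b_{i}", random_protein(rng, int(rng.integers(*length_range))), alphabet="protein")
        )
    planted_pocp = 100.0 * n_shared / n_proteins
    return ProteomeRecord("sim_a", proteins_a), ProteomeRecord("sim_b", proteins_b), planted_pocp


def generate_markers(
    tree: TreeNode,
    gene_lengths: dict[str, int],
    rate: float = 1.0,
    gc: float = 0.5,
    seed: int = 0,
) -> dict[str, MarkerAlignment]:
    """Evolve one alignment per marker gene along a known tree.

    Sites substitute independently on each branch with probability
    ``(3/4)(1 - exp(-4 d r / 3))`` for branch length ``d`` (Jukes-Cantor),
    so branch lengths are expected substitutions per site at ``rate=1``.
    Sequences come back aligned (no indels are simulated).
    """
    rng = np.random.default_rng(seed)
    alignments = {}
    for gene, length in gene_lengths.items():
        root_seq = _seq_to_array(
            generate_ancestor(length, gc, int(rng.integers(2**31))).contigs[0].sequence
        )
        rows: dict[str, str] = {}

        def descend(node: TreeNode, sequence: np.ndarray) -> None:
            for child in node.children:
                d = (child.length or 0.0) * rate
                p_sub = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
                arr = sequence.copy()
                mask = rng.random(length) < p_sub
                idx = np.nonzero(mask)[0]
                if len(idx):
                    base_index = np.searchsorted(_BASES, arr[idx])
                    shift = rng.integers(1, 4, size=len(idx))
                    arr[idx] = _BASES[(base_index + shift) % 4]
                if child.is_tip():
                    rows[child.name] = arr.tobytes().decode()
                else:
                    descend(child, arr)

        descend(tree, root_seq)
        alignments[gene] = MarkerAlignment(gene, rows)
    return alignments


def plant_motifs(
    genome: GenomeRecord,
    pattern: MotifPattern,
    positions: list[int],
    mismatches_per_site: int = 0,
    seed: int = 0,
) -> tuple[GenomeRecord, list[tuple[str, int, int, int]]]:
    """Overwrite windows of the first contig with realisations of a
    consensus; returns the genome plus a (contig, start, end, mismatches)
    truth table."""
    rng = np.random.default_rng(seed)
    contig = genome.contigs[0]
    seq = list(contig.sequence.upper())
    m = len(pattern.consensus)
    truth = []
    for start in sorted(positions):
        if start + m > len(seq):
            raise ValueError(f"motif at {start} exceeds contig length")
        site = [rng.choice(list(IUPAC[c])) for c in pattern.consensus]
        mm_positions = rng.choice(m, size=mismatches_per_site, replace=False)
        for p in mm_positions:
            allowed = set(IUPAC[pattern.consensus[p]])
            site[p] = rng.choice(sorted(set("ACGT") - allowed)) if set("ACGT") - allowed else site[p]
        seq[start : start + m] = site
        truth.append((contig.id, start, start + m, int(mismatches_per_site)))
    mutated = GenomeRecord(
        strain_id=genome.strain_id,
        contigs=[SeqRecord(contig.id, "".join(seq))] + genome.contigs[1:],
    )
    return mutated, truth


def generate_evidence_fixture() -> list[consensus.EvidenceRecord]:
    """The packaged 150-strain evidence panel (46 Cupriavidus + 104
    Ralstonia) transcribed from the study's strain and reclassification
    tables; checksum-verified on load."""
    data = consensus.PACKAGED_EVIDENCE.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != EVIDENCE_SHA256:
        raise ValueError(
            "packaged evidence table does not match its recorded checksum "
            f"(got {digest})"
        )
    return consensus.load_evidence(consensus.PACKAGED_EVIDENCE)
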