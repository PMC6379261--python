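"""Tetranucleotide signature profiling and PCA-based clustering.

Genome signatures are the frequencies of all 256 DNA 4-mers counted in
sliding windows (step 1, forward strand, per contig — the compseq
default); the centered frequency matrix is decomposed by PCA and the
low-dimensional scores are clustered by average-linkage agglomeration,
a reproducible surrogate for by-eye cluster assignment on a 3-D plot.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .seqio import GenomeRecord, reverse_complement

K = 4
KMERS = ["".join(p) for p in itertools.product("ACGT", repeat=K)]  # lexicographic
_KMER_INDEX = {kmer: i for i, kmer in enumerate(KMERS)}


@dataclass
class TetraProfile:
    strain_id: str
    counts: np.ndarray  # 256-long, lexicographic A<C<G<T order

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total


@dataclass
class PCAEmbedding:
    strain_order: list[str]
    scores: np.ndarray  # n x k
    explained_variance_fraction: np.ndarray  # k-vector, non-increasing
    loadings: np.ndarray  # k x 256


def tetra_counts(genome: GenomeRecord, both_strands: bool = False) -> TetraProfile:
    """Count all 256 tetranucleotides over a genome.

    Windows containing any non-ACGT character are skipped; counts are
    summed over contigs.  ``both_strands=True`` additionally counts the
    reverse complement of every contig (off by default, matching the
    forward-strand compseq convention).
    """
    counts = np.zeros(256, dtype=np.int64)
    for contig in genome.contigs:
        sequences = [contig.sequence.upper()]
        if both_strands:
            sequences.append(reverse_complement(contig.sequence).upper())
        for seq in sequences:
            codes = np.frombuffer(seq.encode(), dtype=np.uint8)
            lut = np.full(256, -1, dtype=np.int64)
            for i, base in enumerate(b"ACGT"):
                lut[base] = i
            coded = lut[codes]
            if len(coded) < K:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(coded, K)
            valid = (windows >= 0).all(axis=1)
            idx = windows[valid] @ np.array([64, 16, 4, 1])
            counts += np.bincount(idx, minlength=256)
    if counts.sum() == 0:
        raise ValueError(f"genome {genome.strain_id!r} has no countable 4-mer windows")
    return TetraProfile(genome.strain_id, counts)


def pca_embed(profiles: list[TetraProfile], k: int = 3) -> PCAEmbedding:
    """PCA of the 4-mer frequency matrix (column-centered, unscaled)."""
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles for PCA")
    X = np.vstack([p.frequencies for p in profiles])
    n_components = min(len(profiles) - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    all_scores = pca.fit_transform(X)
    return PCAEmbedding(
        strain_order=[p.strain_id for p in profiles],
        scores=all_scores[:, :k],
        explained_variance_fraction=pca.explained_variance_ratio_[:k],
        loadings=pca.components_[:k],
    )


def full_variance_fractions(profiles: list[TetraProfile]) -> np.ndarray:
    """Explained-variance fractions of all min(n-1, 256) components."""
    X = np.vstack([p.frequencies for p in profiles])
    pca = PCA(n_components=min(len(profiles) - 1, X.shape[1]), svd_solver="full")
    pca.fit(X)
    return pca.explained_variance_ratio_


def _alpha_labels(n: int) -> list[str]:
    # A, B, ..., Z, AA, AB, ...
    labels = []
    for i in range(n):
        label = ""
        i += 1
        while i:
            i, rem = divmod(i - 1, 26)
            label = string.ascii_uppercase[rem] + label
        labels.append(label)
    return labels


def cluster_embedding(embedding: PCAEmbedding, linkage_cut: float) -> dict[str, str]:
    """Average-linkage clustering of PCA scores cut at a linkage height.

    Labels are assigned A, B, ... by cluster size descending, ties broken
    by first-seen strain order.
    """
    n = len(embedding.strain_order)
    if n == 1:
        return {embedding.strain_order[0]: "A"}
    Z = linkage(pdist(embedding.scores), method="average")
    assignment = fcluster(Z, t=linkage_cut, criterion="distance")
    order = {}
    for i, cid in enumerate(assignment):
        order.setdefault(cid, []).append(i)
    ranked = sorted(order.items(), key=lambda kv: (-len(kv[1]), kv[1][0]))
    labels = _alpha_labels(len(ranked))
    result: dict[str, str] = {}
    for label, (_, members) in zip(labels, ranked):
        for i in members:
            result[embedding.strain_order[i]] = label
    return result
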