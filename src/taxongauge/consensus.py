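"""UPGMA clustering on (1 - ANI) and the reclassification decision engine.

The engine formalises the reasoning that taxonomists apply when
reconciling whole-genome and phylogenetic evidence for a strain panel:

* **Genus** comes from the POCP call (60% boundary).  A strain below the
  boundary against every genus belongs to neither ("Other"); an
  ambiguous or missing call falls back to the majority genus of the 16S
  and MLSA clades.
* **Species** comes from the strain's ANI cluster.  A cluster containing
  a type strain is that type strain's species.  When the type strain is
  absent from the panel, a species can still anchor the cluster holding
  a strict plurality (at least two) of the strains currently carrying
  that name.  Within the R. solanacearum species complex, the cluster's
  phylotype decides: I/III -> R. pseudosolanacearum, II ->
  R. solanacearum, IV -> R. syzygii.  A strain in an unanchored cluster
  keeps its current species unless the evidence contradicts it (its
  species anchors elsewhere, or both phylogenies place it outside);
  unnamed strains in singleton clusters may be promoted by a 2-of-3
  majority of 16S / MLSA / tetranucleotide evidence, since a singleton
  ANI cluster carries no grouping information of its own.
* ANI species thresholds are context dependent: 90% for Cupriavidus and
  for clusters containing the R. pickettii type strain, 95% for other
  Ralstonia (used when clusters are cut from a genome-derived ANI
  matrix; transcribed evidence carries precomputed cluster ids).

Conflicts are flagged per method, never silently dropped; ANI evidence
takes precedence in species-level conflicts.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .phylo import DistanceMatrixP

SOLANACEARUM_COMPLEX = {"solanacearum", "pseudosolanacearum", "syzygii"}
PHYLOTYPE_SPECIES = {"I": "pseudosolanacearum", "II": "solanacearum", "III": "pseudosolanacearum", "IV": "syzygii"}


@dataclass
class ThresholdConfig:
    ani_species_threshold_by_context: dict[str, float] = field(
        default_factory=lambda: {"Cupriavidus": 90.0, "R_pickettii": 90.0, "Ralstonia_default": 95.0}
    )
    pocp_genus_threshold: float = 60.0


@dataclass
class EvidenceRecord:
    """Per-strain evidence feeding the decision engine.

    Clade fields hold ``(genus, species)`` where species ``None`` means
    the analysis was unavailable for the strain and ``"sp."`` means the
    strain was placed in the genus but not within a named species clade.
    """

    strain_id: str
    current_genus: str
    current_species: str  # "sp." for unnamed
    type_strain: bool = False
    phylotype: str | None = None
    ani_cluster: str | None = None
    tna_cluster: str | None = None
    pocp_call: str | None = None  # genus | "neither" | "ambiguous" | None
    r16s_genus: str | None = None
    r16s_species: str | None = None
    mlsa_genus: str | None = None
    mlsa_species: str | None = None


@dataclass
class Decision:
    strain_id: str
    current_genus: str
    current_species: str
    proposed_genus: str
    proposed_species: str  # named species or "sp."; "" when genus is "Other"
    changed: bool
    evidence_agreement: dict[str, str] = field(default_factory=dict)  # method -> agree|conflict|unavailable

    @property
    def proposed_label(self) -> str:
        if self.proposed_genus == "Other":
            return "Other"
        return f"{self.proposed_genus} {self.proposed_species}"


def normalize_phylotype(raw: str | None) -> str | None:
    """Collapse sequevar-qualified phylotypes (I-18, IIA-7, IIB-4...) to I/II/III/IV."""
    if raw is None:
        return None
    value = raw.strip().upper()
    if value in {"", "-", "NA"}:
        return None
    head = value.split("-")[0]
    if head.startswith("III"):
        return "III"
    if head.startswith("II"):
        return "II"
    if head in {"I", "IV"}:
        return head
    raise ValueError(f"unrecognised phylotype {raw!r}")


# ---------------------------------------------------------------------------
# ANI-matrix path: UPGMA on (1 - ANI) and threshold cutting.

def ani_to_distance(ani_values: pd.DataFrame) -> DistanceMatrixP:
    """Fractional distance d = 1 - ANI/100; errors on missing entries."""
    if ani_values.isna().any().any():
        missing = [
            (i, j) for i in ani_values.index for j in ani_values.columns if pd.isna(ani_values.loc[i, j])
        ]
        raise ValueError(f"ANI matrix has missing entries (no-signal pairs): {missing[:5]}")
    d = 1.0 - ani_values.to_numpy(dtype=float) / 100.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrixP(list(ani_values.index), d, "p-distance")


def cut_clusters(tree: TreeNode, threshold: float) -> dict[str, int]:
    """Cut a UPGMA tree built on (1 - ANI) at an ANI percent threshold.

    Clusters are the maximal subtrees whose merge distance (cophenetic,
    i.e. twice the node height) is below ``1 - threshold/100``; cluster
    ids are assigned by size descending, ties by first-seen tip order.
    """
    cut = 1.0 - threshold / 100.0
    clusters: list[list[str]] = []

    def visit(node: TreeNode) -> None:
        height = getattr(node, "height", 0.0)
        if node.is_tip():
            clusters.append([node.name])
        elif 2.0 * height < cut:
            clusters.append([t.name for t in node.tips()])
        else:
            for child in node.children:
                visit(child)

    visit(tree)
    first_seen = {name: i for i, name in enumerate(t.name for t in tree.tips())}
    clusters.sort(key=lambda members: (-len(members), min(first_seen[m] for m in members)))
    assignment: dict[str, int] = {}
    for cid, members in enumerate(clusters, start=1):
        for member in members:
            assignment[member] = cid
    return assignment


# ---------------------------------------------------------------------------
# Decision engine.

class _PanelContext:
    """Panel-wide aggregates the per-strain decision needs."""

    def __init__(self, records: list[EvidenceRecord]):
        ids = [r.strain_id for r in records]
        dupes = [i for i, n in Counter(ids).items() if n > 1]
        if dupes:
            raise ValueError(f"duplicate strain ids in evidence: {dupes}")
        self.records = records
        self.cluster_members: dict[str, list[EvidenceRecord]] = defaultdict(list)
        for r in records:
            if r.ani_cluster is not None:
                self.cluster_members[r.ani_cluster].append(r)
        self.anchors = self._species_anchors()
        self.cluster_species: dict[str, list[tuple[str, str]]] = defaultdict(list)
        for (genus, species), cluster in self.anchors.items():
            self.cluster_species[cluster].append((genus, species))
        self.cluster_phylotype = self._cluster_phylotypes()
        self.tna_majority = self._tna_majorities()

    def _species_anchors(self) -> dict[tuple[str, str], str]:
        """(genus, species) -> ANI cluster anchoring that species."""
        anchors: dict[tuple[str, str], str] = {}
        counts: dict[tuple[str, str], Counter] = defaultdict(Counter)
        for r in self.records:
            if r.current_species == "sp." or r.ani_cluster is None:
                continue
            key = (r.current_genus, r.current_species)
            counts[key][r.ani_cluster] += 1
            if r.type_strain:
                anchors[key] = r.ani_cluster  # type strain wins outright
        for key, per_cluster in counts.items():
            if key in anchors:
                continue
            ranked = per_cluster.most_common()
            best_cluster, best_n = ranked[0]
            runner_up = ranked[1][1] if len(ranked) > 1 else 0
            if best_n >= 2 and best_n > runner_up:
                anchors[key] = best_cluster
        return anchors

    def _cluster_phylotypes(self) -> dict[str, str]:
        result = {}
        for cluster, members in self.cluster_members.items():
            votes = Counter(
                p for p in (normalize_phylotype(m.phylotype) for m in members) if p is not None
            )
            if not votes:
                continue
            ranked = votes.most_common()
            if len(ranked) == 1 or ranked[0][1] > ranked[1][1]:
                result[cluster] = ranked[0][0]
            else:
                # phylotypes tie -> fall back to the species they imply
                species_votes = Counter(PHYLOTYPE_SPECIES[p] for p in votes.elements())
                sranked = species_votes.most_common()
                if len(sranked) == 1 or sranked[0][1] > sranked[1][1]:
                    for phylotype, species in PHYLOTYPE_SPECIES.items():
                        if species == sranked[0][0]:
                            result[cluster] = phylotype
                            break
        return result

    def _tna_majorities(self) -> dict[str, tuple[str, str]]:
        result = {}
        per_cluster: dict[str, Counter] = defaultdict(Counter)
        for r in self.records:
            if r.tna_cluster is not None and r.current_species != "sp.":
                per_cluster[r.tna_cluster][(r.current_genus, r.current_species)] += 1
        for cluster, votes in per_cluster.items():
            ranked = votes.most_common()
            if len(ranked) == 1 or ranked[0][1] > ranked[1][1]:
                result[cluster] = ranked[0][0]
        return result


def _decide_genus(e: EvidenceRecord) -> str:
    if e.pocp_call not in (None, "neither", "ambiguous"):
        return e.pocp_call
    if e.pocp_call == "neither":
        return "Other"
    votes = Counter(g for g in (e.r16s_genus, e.mlsa_genus) if g)
    if not votes:
        raise ValueError(f"strain {e.strain_id!r}: no usable genus evidence")
    return votes.most_common(1)[0][0]


def _phylo_contradicts(e: EvidenceRecord) -> bool:
    available = [s for s in (e.r16s_species, e.mlsa_species) if s is not None]
    return bool(available) and e.current_species not in available


def _decide_species(e: EvidenceRecord, genus: str, ctx: _PanelContext) -> tuple[str, str | None]:
    """Return (proposed species, species the ANI cluster itself implies)."""
    cluster = e.ani_cluster
    ani_species: str | None = None

    if cluster is not None:
        # solanacearum-complex phylotype override
        phylotype = normalize_phylotype(e.phylotype) or ctx.cluster_phylotype.get(cluster)
        in_complex = e.current_species in SOLANACEARUM_COMPLEX or any(
            m.current_species in SOLANACEARUM_COMPLEX for m in ctx.cluster_members[cluster]
        )
        if phylotype is not None and in_complex and genus == "Ralstonia":
            ani_species = PHYLOTYPE_SPECIES[phylotype]
            return ani_species, ani_species

        anchored = sorted(s for g, s in ctx.cluster_species.get(cluster, []) if g == genus)
        if len(anchored) == 1:
            ani_species = anchored[0]
            return ani_species, ani_species
        if len(anchored) > 1:
            # multiple species anchor here (indistinguishable at the ANI
            # threshold); keep the current name when it is among them
            ani_species = e.current_species if e.current_species in anchored else anchored[0]
            return ani_species, ani_species

    # unanchored (or missing) cluster
    if (
        e.current_species != "sp."
        and e.current_genus == genus
        and (e.current_genus, e.current_species) not in ctx.anchors
        and not _phylo_contradicts(e)
    ):
        return e.current_species, None

    singleton = cluster is None or len(ctx.cluster_members.get(cluster, [])) <= 1
    if singleton and (e.current_species == "sp." or e.current_genus != genus or True):
        votes = Counter()
        for candidate in (
            e.r16s_species if e.r16s_genus == genus else None,
            e.mlsa_species if e.mlsa_genus == genus else None,
        ):
            if candidate and candidate != "sp.":
                votes[candidate] += 1
        if e.tna_cluster in ctx.tna_majority:
            tg, ts = ctx.tna_majority[e.tna_cluster]
            if tg == genus:
                votes[ts] += 1
        if votes:
            species, n = votes.most_common(1)[0]
            if n >= 2:
                return species, None
    return "sp.", None


def decide(e: EvidenceRecord, ctx: _PanelContext, thresholds: ThresholdConfig | None = None) -> Decision:
    """Propose a classification for one strain given panel context.

    Precedence: POCP names the genus; the ANI cluster names the species
    (phylotype override within the R. solanacearum complex); phylogenies
    and TNA fill in only where ANI is uninformative.  Deterministic and
    independent of strain order.
    """
    thresholds = thresholds or ThresholdConfig()
    flags: dict[str, str] = {}
    genus = _decide_genus(e)
    if genus == "Other":
        species, ani_species = "", None
    else:
        species, ani_species = _decide_species(e, genus, ctx)

    changed = (genus != e.current_genus) or (genus != "Other" and species != e.current_species)

    def clade_flag(clade_genus: str | None, clade_species: str | None) -> str:
        if clade_genus is None and clade_species is None:
            return "unavailable"
        if genus == "Other":
            return "conflict" if clade_genus else "agree"
        if clade_genus != genus:
            return "conflict"
        if species and species != "sp.":
            return "agree" if clade_species == species else "conflict"
        return "agree"

    flags["16S"] = clade_flag(e.r16s_genus, e.r16s_species)
    flags["MLSA"] = clade_flag(e.mlsa_genus, e.mlsa_species)
    if e.ani_cluster is None:
        flags["ANI"] = "unavailable"
    elif genus == "Other":
        flags["ANI"] = "agree"
    elif species != "sp." and ani_species != species:
        flags["ANI"] = "conflict"
    else:
        flags["ANI"] = "agree"
    if e.tna_cluster is None:
        flags["TNA"] = "unavailable"
    else:
        tna = ctx.tna_majority.get(e.tna_cluster)
        if genus == "Other" or species == "sp." or species == "":
            flags["TNA"] = "agree"
        elif tna is None:
            flags["TNA"] = "agree"
        else:
            flags["TNA"] = "agree" if tna == (genus, species) else "conflict"
    if e.pocp_call is None:
        flags["POCP"] = "unavailable"
    elif e.pocp_call == "ambiguous":
        flags["POCP"] = "conflict"
    else:
        flags["POCP"] = "agree" if (e.pocp_call == genus or (e.pocp_call == "neither" and genus == "Other")) else "conflict"

    return Decision(
        strain_id=e.strain_id,
        current_genus=e.current_genus,
        current_species=e.current_species,
        proposed_genus=genus,
        proposed_species=species,
        changed=changed,
        evidence_agreement=flags,
    )


def classify_panel(
    records: list[EvidenceRecord], thresholds: ThresholdConfig | None = None
) -> list[Decision]:
    """Run the decision engine over a whole evidence panel."""
    ctx = _PanelContext(records)
    return [decide(e, ctx, thresholds) for e in records]


def count_reclassified(decisions: list[Decision]) -> int:
    ids = [d.strain_id for d in decisions]
    dupes = [i for i, n in Counter(ids).items() if n > 1]
    if dupes:
        raise ValueError(f"duplicate decisions for strains: {dupes}")
    return sum(d.changed for d in decisions)


# ---------------------------------------------------------------------------
# Evidence IO.


def _parse_clade(value: str) -> tuple[str | None, str | None]:
    value = value.strip()
    if not value:
        return None, None
    genus, _, species = value.partition(" ")
    return genus, species or "sp."


def load_evidence(path: str | Path) -> list[EvidenceRecord]:
    """Load an evidence TSV (columns mirroring :class:`EvidenceRecord`)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for row in df.itertuples(index=False):
        r16s = _parse_clade(row.r16s_clade)
        mlsa = _parse_clade(row.mlsa_clade)
        records.append(
            EvidenceRecord(
                strain_id=row.strain_id,
                current_genus=row.current_genus,
                current_species=row.current_species,
                type_strain=row.type_strain.strip() in {"1", "true", "True"},
                phylotype=row.phylotype or None,
                ani_cluster=None if row.ani_cluster.strip() in {"", "NA"} else row.ani_cluster.strip(),
                tna_cluster=row.tna_cluster.strip() or None,
                pocp_call=row.pocp_call.strip() or None,
                r16s_genus=r16s[0],
                r16s_species=r16s[1],
                mlsa_genus=mlsa[0],
                mlsa_species=mlsa[1],
            )
        )
    return records


PACKAGED_EVIDENCE = Path(__file__).parent / "data" / "evidence_cupriavidus_ralstonia.tsv"


def write_decisions(decisions: list[Decision], path: str | Path) -> None:
    rows = []
    for d in decisions:
        rows.append(
            {
                "strain_id": d.strain_id,
                "current": f"{d.current_genus} {d.current_species}",
                "proposed": d.proposed_label,
                "changed": int(d.changed),
                **{f"flag_{k}": v for k, v in d.evidence_agreement.items()},
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
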