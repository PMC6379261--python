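"""ANI clustering, threshold cutting, and the reclassification engine."""

import numpy as np
import pandas as pd
import pytest

from taxongauge import ani, consensus, phylo, pocp
from taxongauge import synthetic_data as sd
from taxongauge.consensus import EvidenceRecord
from taxongauge.seqio import SeqRecord


def _forced_ani_frame():
    ids = list("abcd")
    values = np.array(
        [
            [100.0, 96.0, 80.0, 80.0],
            [96.0, 100.0, 80.0, 80.0],
            [80.0, 80.0, 100.0, 96.0],
            [80.0, 80.0, 96.0, 100.0],
        ]
    )
    return pd.DataFrame(values, index=ids, columns=ids)


class TestDistanceAndCutting:
    def test_ani_to_distance_values(self):
        frame = pd.DataFrame(
            [[100.0, 91.16], [91.16, 100.0]], index=["q", "r"], columns=["q", "r"]
        )
        d = consensus.ani_to_distance(frame)
        assert d.values[0, 1] == pytest.approx(0.0884, abs=1e-9)
        assert d.values[0, 0] == 0.0
        np.testing.assert_allclose(d.values, d.values.T)
        assert (d.values >= 0).all()

    def test_missing_entries_rejected(self):
        frame = _forced_ani_frame()
        frame.iloc[0, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            consensus.ani_to_distance(frame)

    def test_cut_clusters_forced_heights(self):
        tree = phylo.upgma_tree(consensus.ani_to_distance(_forced_ani_frame()))
        at95 = consensus.cut_clusters(tree, 95.0)
        assert sorted(at95.values()) == [1, 1, 2, 2]
        assert at95["a"] == at95["b"] and at95["c"] == at95["d"]
        at99 = consensus.cut_clusters(tree, 99.0)
        assert sorted(at99.values()) == [1, 2, 3, 4]

    def test_raising_threshold_never_merges(self):
        rng = np.random.default_rng(5)
        points = rng.uniform(size=(8, 2))
        dist = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1)) / 10
        ani_values = 100 * (1 - dist)
        frame = pd.DataFrame(ani_values, index=[f"s{i}" for i in range(8)], columns=[f"s{i}" for i in range(8)])
        np.fill_diagonal(frame.values, 100.0)
        frame.iloc[:, :] = (frame.values + frame.values.T) / 2
        tree = phylo.upgma_tree(consensus.ani_to_distance(frame))
        previous = None
        for threshold in [90.0, 93.0, 96.0, 99.0]:
            clusters = consensus.cut_clusters(tree, threshold)
            n = len(set(clusters.values()))
            if previous is not None:
                assert n >= previous
            previous = n

    def test_cut_is_partition(self):
        tree = phylo.upgma_tree(consensus.ani_to_distance(_forced_ani_frame()))
        clusters = consensus.cut_clusters(tree, 95.0)
        assert sorted(clusters) == list("abcd")  # every strain exactly once


class TestPhylotypes:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("I", "I"),
            ("I-18", "I"),
            ("IIA-7", "II"),
            ("IIB-4", "II"),
            ("IIB", "II"),
            ("III-48", "III"),
            ("IV", "IV"),
            ("NA", None),
            ("-", None),
            (None, None),
        ],
    )
    def test_normalisation(self, raw, expected):
        assert consensus.normalize_phylotype(raw) == expected


@pytest.fixture(scope="module")
def decisions():
    records = sd.generate_evidence_fixture()
    return {d.strain_id: d for d in consensus.classify_panel(records)}


class TestDecideOnTranscribedEvidence:
    def test_nh9_confirmed_as_necator(self, decisions):
        d = decisions["NH9"]
        assert d.proposed_label == "Cupriavidus necator"
        assert not d.changed
        assert all(v == "agree" for v in d.evidence_agreement.values())

    def test_dtp0602_moved_to_cupriavidus_sp(self, decisions):
        d = decisions["DTP0602"]
        assert d.proposed_label == "Cupriavidus sp."
        assert d.changed

    def test_pba_assigned_to_neither_genus(self, decisions):
        d = decisions["PBA"]
        assert d.proposed_genus == "Other"
        assert d.changed

    def test_singleton_clusters_resolved_by_phylogeny_and_tna(self, decisions):
        assert decisions["MD27"].proposed_label == "Ralstonia insidiosa"
        assert decisions["A12"].proposed_label == "Ralstonia insidiosa"
        assert decisions["BIS7"].proposed_label == "Cupriavidus sp."

    def test_phylotype_override(self, decisions):
        assert decisions["CQPS-1"].proposed_label == "Ralstonia pseudosolanacearum"
        assert decisions["KACC 10722"].proposed_label == "Ralstonia syzygii"
        assert decisions["UW551"].proposed_label == "Ralstonia solanacearum"
        assert not decisions["UW551"].changed

    def test_total_reclassified_count(self, decisions):
        assert consensus.count_reclassified(list(decisions.values())) == 41

    def test_partition_identity(self, decisions):
        changed = consensus.count_reclassified(list(decisions.values()))
        unchanged = sum(not d.changed for d in decisions.values())
        assert changed + unchanged == len(decisions) == 150

    def test_order_independence(self):
        records = sd.generate_evidence_fixture()
        forward = {d.strain_id: d.proposed_label for d in consensus.classify_panel(records)}
        backward = {d.strain_id: d.proposed_label for d in consensus.classify_panel(records[::-1])}
        assert forward == backward


class TestDecideEdgeCases:
    def test_no_usable_evidence_rejected(self):
        record = EvidenceRecord("x", "Cupriavidus", "sp.")
        with pytest.raises(ValueError, match="no usable"):
            consensus.classify_panel([record])

    def test_duplicate_strains_rejected(self):
        record = EvidenceRecord("x", "Cupriavidus", "sp.", pocp_call="Cupriavidus")
        with pytest.raises(ValueError, match="duplicate"):
            consensus.classify_panel([record, record])

    def test_duplicate_decisions_rejected(self):
        records = [EvidenceRecord("x", "Cupriavidus", "sp.", pocp_call="Cupriavidus")]
        decisions = consensus.classify_panel(records)
        with pytest.raises(ValueError, match="duplicate"):
            consensus.count_reclassified(decisions * 2)

    def test_genus_fallback_to_phylogeny(self):
        record = EvidenceRecord(
            "x",
            "Ralstonia",
            "sp.",
            pocp_call="ambiguous",
            r16s_genus="Cupriavidus",
            r16s_species="sp.",
            mlsa_genus="Cupriavidus",
            mlsa_species="sp.",
        )
        decision = consensus.classify_panel([record])[0]
        assert decision.proposed_genus == "Cupriavidus"


def _planted_panel(seed=33):
    """Two genera, two species each, ANI 96 within / 87 between species,
    POCP ~75 within genus / ~45 between genera; type strains marked."""
    rng = np.random.default_rng(seed)
    design = {
        "G1": ["alpha", "beta"],
        "G2": ["gamma", "delta"],
    }
    # genomes: one panel per genus (between-genus pairs fall far below 90)
    genomes = {}
    for genus in design:
        config = sd.SimConfig(
            seed=int(rng.integers(2**31)),
            genome_length=6120,
            panel=[sd.CladeDesign(sp, 2, 0.96, 0.87) for sp in design[genus]],
        )
        panel, _ = sd.generate_panel(config)
        for g in panel:
            genomes[f"{genus}_{g.strain_id}"] = g
    # proteomes: 9/20 orthologs shared across genera, 15/20 within genus
    shared_all = [sd.random_protein(rng, int(rng.integers(120, 200))) for _ in range(9)]
    proteomes = {}
    for genus in design:
        genus_specific = [sd.random_protein(rng, int(rng.integers(120, 200))) for _ in range(6)]
        for species in design[genus]:
            for i in (1, 2):
                name = f"{genus}_{species}_{i}"
                seqs = [sd.mutate_protein(rng, s, 0.03) for s in shared_all + genus_specific]
                seqs += [sd.random_protein(rng, int(rng.integers(120, 200))) for _ in range(5)]
                proteomes[name] = pocp.ProteomeRecord(
                    name,
                    [SeqRecord(f"{name}_{j}", s, alphabet="protein") for j, s in enumerate(seqs)],
                )
    truth = {
        name: (name.split("_")[0], name.split("_")[1]) for name in genomes
    }
    return design, genomes, proteomes, truth


def test_end_to_end_planted_truth_recovery():
    """Full pipeline on a planted two-genus panel recovers >=95% of names."""
    design, genome_map, proteomes, truth = _planted_panel()
    names = sorted(genome_map)

    # POCP genus calls
    groups = {
        genus: [proteomes[n] for n in names if n.startswith(genus)] for genus in design
    }
    pocp_calls = {}
    for name in names:
        means = {
            genus: pocp.mean_pocp_vs_group(proteomes[name], group)
            for genus, group in groups.items()
        }
        pocp_calls[name] = pocp.genus_call(name, means).call
        own_genus = name.split("_")[0]
        other = [g for g in design if g != own_genus][0]
        assert means[own_genus] > 60.0 > means[other]

    # ANI clusters per genus at the 90% context threshold
    cluster_of = {}
    for genus in design:
        members = [n for n in names if n.startswith(genus)]
        matrix = ani.ani_matrix([genome_map[n] for n in members])
        matrix.values.index = matrix.values.columns = members
        tree = phylo.upgma_tree(consensus.ani_to_distance(matrix.values))
        for strain, cid in consensus.cut_clusters(tree, 90.0).items():
            cluster_of[strain] = f"{genus}:{cid}"

    records = []
    for name in names:
        genus, species, idx = name.split("_")
        is_type = idx == "1"
        records.append(
            EvidenceRecord(
                strain_id=name,
                current_genus=genus,
                current_species=species if is_type else "sp.",
                type_strain=is_type,
                ani_cluster=cluster_of[name],
                pocp_call=pocp_calls[name],
            )
        )
    decisions = consensus.classify_panel(records)
    correct = sum(
        (d.proposed_genus, d.proposed_species) == truth[d.strain_id] for d in decisions
    )
    assert correct / len(decisions) >= 0.95
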