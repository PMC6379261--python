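# taxongauge

Genome-based taxonomy for bacterial strain panels.

Closely related genera such as *Cupriavidus* and *Ralstonia*
(β-proteobacteria, *Burkholderiaceae*) have a tangled taxonomic history:
strains deposited in GenBank under one name often turn out, once their
genomes are compared, to belong to a different species or even a
different genus. `taxongauge` implements the whole-genome comparison
toolbox that taxonomists use to sort this out, as a tested, reusable
Python library with a thin CLI:

- **ANI** — fragment-based average nucleotide identity. The query genome
  is cut into 1,020-bp fragments, each is aligned locally against both
  strands of the reference (BLASTN-like scoring; hits kept at identity
  ≥ 30% and alignable fraction ≥ 0.70), and

  `ANI(Q, R) = mean identity of qualifying fragment hits`,

  with the two-way value weighting both directions by hit count.
  Species boundary ~95–96%, relaxed to **90%** for diverse groups
  (*Cupriavidus*, *R. pickettii*).
- **POCP** — percentage of conserved proteins,
  `POCP = 100·(C1 + C2)/(T1 + T2)`, where `Cᵢ` counts proteins with a
  BLASTP-style best hit in the other proteome passing E < 1e−5,
  identity ≥ 40%, query coverage ≥ 50%. Genus boundary **60%**.
- **TNA** — tetranucleotide signatures: frequencies of all 256 DNA
  4-mers, compared by PCA and average-linkage clustering.
- **Phylogenetics** — 16S and four-gene MLSA
  (*atpD*–*leuS*–*rplB*–*gyrB*) with complete gap elimination,
  p/Jukes–Cantor distances, neighbor joining and UPGMA, bootstrap
  support.
- **Consensus engine** — combines POCP genus calls, ANI clusters (UPGMA
  on 1 − ANI cut at the context threshold), type-strain anchoring, the
  *R. solanacearum* phylotype mapping (I/III → *R. pseudosolanacearum*,
  II → *R. solanacearum*, IV → *R. syzygii*), and 16S/MLSA/TNA clades
  into a per-strain reclassification decision with per-method
  agreement flags.
- **Extras** — degenerate replication-motif scanning (DnaA boxes,
  RepA/TrfA iterons) and Fisher-exact + Benjamini–Hochberg comparison of
  COG category counts between replicons.
- **Synthetic data** — seeded generators for genomes with planted ANI
  structure, proteomes with planted ortholog fractions, marker genes
  evolved along known trees, and planted motifs, so every stage is
  testable at desk scale.

## Worked example

ANI between a simulated ancestor and a descendant mutated at 5% of
sites (substitutions only):

```python
from taxongauge import ani, synthetic_data as sd

ancestor = sd.generate_ancestor(51_000, gc=0.655, seed=42)
sibling = sd.evolve(ancestor, substitution_rate=0.05, seed=43, strain_id="sibling")
r = ani.two_way_ani(ancestor, sibling)
print(f"{r.query_id} vs {r.ref_id}: ANI = {r.ani_two_way:.2f}% "
      f"({r.n_hits_qr}+{r.n_hits_rq} fragment hits)")
```

```
anc_42 vs sibling: ANI = 95.00% (50+50 fragment hits)
```

The recovered ANI matches the expected identity `100·(1 − 0.05)`; the
two genomes would be called conspecific at the 90% threshold and
distinct at 95% — exactly the regime where the choice of threshold
matters.

Running the consensus engine over the packaged 150-strain
*Cupriavidus*/*Ralstonia* evidence panel (46 + 104 strains, with ANI
clusters, TNA clusters, phylotypes, POCP calls and type-strain flags):

```bash
taxongauge classify --evidence src/taxongauge/data/evidence_cupriavidus_ralstonia.tsv \
    --out decisions.tsv
```

```
strains 150
reclassified    41
```

`decisions.tsv` lists, per strain, the current and proposed names, a
changed flag, and agree/conflict/unavailable flags for each line of
evidence, e.g.

```
strain_id  current                 proposed         changed  flag_16S  flag_MLSA  flag_ANI  flag_TNA  flag_POCP
KF708      Cupriavidus basilensis  Cupriavidus sp.  1        agree     agree      agree     agree     agree
```

41 of the 150 strains change name at genus or species level; the
3-chlorobenzoate degrader NH9 is confirmed as *Cupriavidus necator*,
and strain PBA falls below the 60% POCP boundary against both genera.

## Layout

```
src/taxongauge/
  seqio.py           FASTA/TSV/newick IO, genome statistics
  ani.py             fragment ANI (seeded local alignment)
  pocp.py            conserved-protein percentages, genus rule
  tna_pca.py         4-mer signatures, PCA, cluster extraction
  phylo.py           alignments, distances, NJ/UPGMA, bootstrap
  consensus.py       ANI clustering + reclassification engine
  motif.py           IUPAC consensus scanning
  cogstats.py        Fisher + BH replicon comparisons
  synthetic_data.py  seeded generators and the evidence panel
  cli.py             `taxongauge` command group
```
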