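# lantimine

Mining annotated bacterial genomes for **type 1 lantibiotic gene clusters**.

Lantibiotics are ribosomally synthesised, post-translationally modified
antimicrobial peptides. A type 1 cluster centres on three genes: the small
structural gene *lanA* encoding a prepropeptide (an N-terminal leader that
is cleaved off plus a C-terminal propeptide), a dehydratase *lanB* that
converts propeptide Ser/Thr to dehydroalanine/dehydrobutyrine, and a cyclase
*lanC* that closes the (methyl)lanthionine thioether rings onto propeptide
cysteines. Because LanB and LanC are large and well conserved they make good
homology-screen handles, while *lanA* genes are short and frequently missing
from genome annotation — they often have to be recovered by translating the
intergenic DNA next to a *lanB*/*lanC* hit.

`lantimine` implements that mining strategy as a reusable library + CLI for
anyone screening genome collections for lanthipeptide biosynthesis:

1. **Homology screen** — Smith–Waterman alignment under BLOSUM62 (gap open
   11 / extend 1) with Karlin–Altschul E-values; a target is a homolog when
   E ≤ 10⁻⁷ and identity > 20%. Newly found LanA/B/C proteins are promoted
   to drivers and the screen repeats until no new homolog appears.
2. **Precursor discovery** — candidate *lanA* genes are scored among
   annotated small CDS and among six-frame ORFs of intergenic DNA within
   10 kb of an anchor hit. The score uses length (20–120 aa around the
   ~60 aa mode), ≥1 Cys, and the uneven Ser/Thr/Cys distribution between
   propeptide and leader; the leader/propeptide boundary is placed where
   the S/T/C density contrast is maximal.
3. **Cluster assembly** — single-linkage grouping within a 10-kb window;
   clusters are classified `COMPLETE` (lanA+lanB+lanC), `NO_LANA`,
   `MULTI_LANC_NO_A`, or `ORPHAN`. Dehydratase genes split across two
   adjacent ORFs by an apparent frameshift (e.g. an 80 aa + ~940 aa pair)
   are recognised and merged; accessory genes (LanT transporter, LanP
   protease, LanEFG immunity, LanKR regulation, LanD, O-methyltransferases)
   are annotated from exemplar families.
4. **Conservation & phylogeny** — a builtin progressive aligner (NJ guide
   tree on k-mer distances, profile–profile global affine DP) feeds motif
   conservation tables anchored to NisB/NisC residue numbering (YxxR, GxG,
   GRF, …; WCYG, CHG, GxAHGxxG, …) and neighbor-joining cladograms with
   phylogroup extraction.
5. **Synthetic genomes** — a generator plants clusters (including an
   unannotated intergenic *lanA* and a frameshift-split *lanB*) with full
   ground truth, so the whole pipeline is testable offline.

## Worked example

Generate a synthetic genome with one complete cluster (whose *lanA* is
deliberately left unannotated), one lanA-less cluster and three decoy
genes, then run the full screen:

```bash
lantimine simulate --seed 7 --n-complete 1 --n-nolana 1 --decoys 3 \
    --intergenic-lana --out demo/genome
# wrote SYN0000007 (172441 nt) to demo/genome

printf 'genomes:\n  - demo/genome/SYN0000007.gbk\n' > demo/config.yaml
lantimine run --config demo/config.yaml --out demo/results
# {"n_clusters": 2, "n_complete": 1, "n_multi_lanc_no_a": 0,
#  "n_nolana": 1, "n_orphan": 0, "n_total_hits": 4, "rounds_used": 1}
```

Both planted clusters are recovered with their correct labels. The cluster
report shows the hidden precursor recovered from raw intergenic DNA — its
member id is a coordinate ORF id, not a locus tag, because no annotation
exists for it:

```
genome      cluster        classification  member                   role  identity_pct
SYN0000007  SYN0000007.c1  COMPLETE        SYN0000007:1503-1686(+)  LanA
SYN0000007  SYN0000007.c1  COMPLETE        SYN0000007_0001          LanB  100.0
SYN0000007  SYN0000007.c1  COMPLETE        SYN0000007_0002          LanC  100.0
SYN0000007  SYN0000007.c2  NO_LANA         SYN0000007_0005          LanB  100.0
SYN0000007  SYN0000007.c2  NO_LANA         SYN0000007_0006          LanC  100.0
```

The run directory also contains per-role FASTA files, conservation tables
(`conservation_LanC.tsv` reports e.g. the zinc-ligand `CHG` motif at NisC
positions 330–332, 100% conserved in this toy family) and, when a family
has at least three members, a Newick tree per role.

The same analyses are available as library calls (`align_pair`,
`screen_proteome`, `find_lana_candidates`, `assemble_clusters`,
`motif_conservation`, `nj_tree`, `run_pipeline`, …); see the module
docstrings.

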