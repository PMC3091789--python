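# Methods

This note documents the models, heuristics and numerical choices behind
`lantimine`, what the synthetic data emulate, and what the test results do
and do not establish about real genomes.

## Homology screen

The screen treats a default-parameter protein BLAST as its model:
Smith–Waterman local alignment (global Needleman–Wunsch is available) under
BLOSUM62 with affine gaps, open 11 / extend 1. Alignment itself is
delegated to Biopython's `PairwiseAligner` (an exact C implementation);
identity and significance are computed by this package:

* **Identity** = 100 × identical columns / all alignment columns. Gap
  columns count in the denominator and `X` never counts as identical. An
  alternative normalisation by query length is available
  (`ScreenConfig.identity_over_query`) because "percent identity" is
  ambiguous between tools; alignment-length normalisation is the default.
* **E-value** = K·m·n·exp(−λS) with the published gapped-BLAST constants
  for BLOSUM62/11/1, λ = 0.267 and K = 0.041; n defaults to the summed
  length of the screened proteome. This reproduces BLAST's statistics well
  enough for thresholding at E ≤ 10⁻⁷, which — together with identity >
  20% — defines a homolog.
* **Iterative expansion** promotes each round's newly found proteins to
  drivers (deduplicated by sequence) and stops at a fixed point or after
  `max_rounds`. Inside `run_pipeline` the expansion is run per genome so
  that results for one genome can never depend on which other genomes are
  in the input set; expansion across a whole collection is available by
  calling `iterative_expand` with several genomes.

Tie-breaking between co-optimal alignments follows the aligner's
deterministic first-path traceback, so all downstream numbers are
reproducible bit-for-bit.

## Precursor (LanA) heuristic

A type 1 precursor is modelled as leader + propeptide with three
measurable signatures: short length, at least one cysteine (the thioether
acceptor), and a propeptide markedly richer in Ser/Thr/Cys than the
leader. Defaults, with rationale:

| parameter | default | rationale |
|---|---|---|
| `min_aa` / `max_aa` | 20 / 120 | known type 1 precursors span ~43–86 aa around a ~60 aa mode; bounds kept generous, the composite score ranks |
| split window | 25–60% of length (≥10 aa each side) | type 1 leaders occupy roughly a quarter to a half of the prepropeptide |
| `stc_fraction_min` | 0.30 | known propeptides are ≥ ~⅓ S/T/C (nisin A: 14/34 = 0.41); see below |
| `stc_skew_min` | 0.10 | propeptide S/T/C density must exceed the leader's by 10 points |
| `min_cys` | 1 | thioether chemistry requires a cysteine |

The leader/propeptide split is placed where S/T/C(propeptide) −
S/T/C(leader) is maximal over the allowed window (ties to the smallest
index). On the packaged 57-aa nisin A prepropeptide this lands at residue
24, one position from the real cleavage site (23).

Because the split is *chosen to maximise* the contrast, the skew statistic
is selection-biased upward on random sequences; the propeptide-density
bound therefore carries most of the discrimination. With the defaults
above, 3.2% of 1000 uniform-random 60-aa peptides pass, while planted
precursors mutated to 70% identity (with their propeptide S/T/C intact)
pass with wide margins (minimum observed fraction 0.359, skew 0.131).
Leader DLD, a leader leucine and a propeptide `C.{2,4}C` pattern add
bonuses to the composite ranking score but are never required.

Six-frame ORF calling accepts ATG/GTG/TTG starts (translated as Met),
requires an in-frame stop inside the scanned region, and reports maximal
start→stop ORFs only. Overlapping passing candidates (alternate frames or
strands of the same locus) are resolved to the best composite score.

## Cluster assembly and classification

Single-linkage grouping joins two elements when their intervals are within
`window_nt` (default 10 kb — "close association" made concrete; the same
window bounds the precursor search around anchors). Classification
precedence is COMPLETE > NO_LANA > MULTI_LANC_NO_A > ORPHAN; the
multi-LanC label (≥2 LanC, no LanA) is kept separate rather than folded
into NO_LANA because it is a recurrent arrangement worth reporting.

**Frameshift merging.** A dehydratase split across two adjacent ORFs is
accepted as one gene when the parts are same-strand with ≤100 nt between
them, the combined length is 80–120% of an intact reference, the upstream
part aligns N-terminally and the downstream part C-terminally, spans
overlap by <10% of the reference, and — critically — each part is itself a
significant homolog (E ≤ 10⁻³) contributing ≥4% of the reference that the
other part does not. The novel-coverage requirement is what prevents an
intact full-length hit from absorbing an unrelated neighbouring small gene
on the strength of an incidental local alignment.

**Accessory annotation** screens unassigned genes inside a cluster span
against exemplar LanT/P/E/F/G/K/R/D and O-methyltransferase families with
the same thresholds as the main screen; genes with no passing hit are
reported as `other`.

## Conservation analysis

The builtin multiple aligner is progressive: an NJ guide tree on
fractional-common-k-mer distances (k = 3), merges by profile–profile
global affine DP where a column–column score is the average BLOSUM62 score
over residue pairs (gaps contribute 0). For two sequences this reduces to
the optimal global alignment (tested against the DP oracle). Pre-aligned
FASTA from any external tool is accepted interchangeably.

Motif conservation is anchored to a reference row: a motif's reference
positions (1-based, NisB/NisC numbering convention) are mapped to
alignment columns through the reference's gap structure, a row carries the
motif iff it matches every non-wildcard letter at those columns, and the
percentage is over **all** rows, reference included, rounded to integers
(matching how such tables are conventionally printed). A per-letter
breakdown supports partially conserved motifs. The packaged motif tables
(`data/lanb_motifs.tsv`, `data/lanc_motifs.tsv`) list the canonical
dehydratase and cyclase motifs and single residues; one printed span in
the dehydratase table (RxTPFG) is internally inconsistent with its
6-letter pattern, and is anchored at its start position (87–92) so that
pattern length equals span.

## Phylogenetics

Distances from an MSA are p-distances (mismatches over shared non-gap
columns; a pair with no shared column is an error) or Poisson-corrected
−ln(1−p) with p capped at 1−10⁻⁶ to keep saturated pairs finite. Trees are
standard Saitou–Nei neighbor joining, implemented here to guarantee two
determinism contracts: Q-matrix ties break by the lexicographically
smallest pair of node keys (a node's key is the smallest leaf name under
it), and negative branch lengths are clamped to zero with the deficit
moved to the sibling so the pair's summed length is preserved. On additive
matrices the implementation reproduces the generating topology and all
path lengths to 1e-9, and agrees topologically with scikit-bio's
independent NJ. Phylogroups are extracted by cutting the k−1 longest
internal edges (longest first, ties by smallest subtree leaf name; leaf
edges are used only in the degenerate k ≈ leaf-count regime), or every
internal edge above a length threshold.

## Synthetic data

The generator emulates annotated replicons as a mining pipeline sees them:
planted clusters whose genes sit 50–500 nt apart, separated by ≥3
clustering windows so distinct elements can never merge; random decoy
genes (150–400 aa, deliberately longer than `max_aa` so they cannot be
precursor candidates); i.i.d. uniform intergenic background; uniform
synonymous codon choice. Two real-world complications are reproduced on
demand: a *lanA* written into the DNA with no CDS feature, guarded by an
upstream in-frame stop so the planted ORF has exact boundaries, and a
*lanB* split into 80 aa + remainder ORFs on one strand with a short gap.

Template proteins are synthetic: deterministic random sequences with the
canonical motifs planted at their reference coordinates (LanB-like,
1020 aa; LanC-like, 420 aa), short precursors with DLD leaders and
S/T/C-rich propeptides, and random accessory exemplars. The only real
sequence shipped is the published nisin A prepropeptide. Mutation to a
target identity substitutes BLOSUM-weighted residues at uniformly chosen
positions, optionally protecting motif columns (LanB/LanC) or the
propeptide S/T/C content and leader DLD (LanA) — the generator's model of
purifying selection on functional residues.

Intergenic background is post-processed so no six-frame ORF of ≥20 codons
survives in pure background (stops are planted at random codons of each
offender until none remain; random sites are needed because overlapping
ORFs on opposite strands can overwrite each other's planted stops). As a
result, false precursor calls can only arise from annotated genes, which
is what the false-pass property measures.

**What passing tests show — and don't.** Perfect recovery on this
generator demonstrates the pipeline's logic: threshold semantics,
coordinate bookkeeping, intergenic ORF recovery, frameshift merging,
classification. It does not demonstrate performance on real genomes,
where annotation quality, GC and codon bias, paralogy, degraded pseudogene
clusters, and homologs below 20% identity all matter; the generator's
protein families are star-shaped (template + independent mutations), not
phylogenetically structured.

## Problem sizes

The default evaluation cohort is 20 replicons (~100–250 kb each, 1–2
planted elements plus decoys), half at mutation 0 and half at mutation
0.3; oracle checks use 100 random 3-kb sequences for ORF calling, 20
constructed pairs for identity, and additive matrices from random 4–8
taxon trees for NJ. The full test suite runs in well under a minute on
one CPU; `scripts/acceptance.py` takes ~20 seconds.

## Known limitations

* E-values use fixed Karlin–Altschul constants for the default scheme;
  other matrices/gap costs reuse them and are therefore approximate.
* The progressive aligner is O(L²) per merge without refinement passes;
  for large families an external MSA tool via the aligned-FASTA adapter is
  the better choice.
* The precursor heuristic is a composition filter, not a learned
  classifier; propeptides with atypically low S/T/C would be missed, as
  would precursors further than `window_nt` from their enzymes.
* `--threads` is accepted for interface compatibility but execution is
  serial (deterministic order); per-genome independence makes external
  parallelisation trivial.
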