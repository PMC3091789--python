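"""Synthetic annotated genomes with planted lantibiotic gene clusters.

The generator emulates the study conditions of a type 1 lantibiotic screen:
annotated replicons carrying COMPLETE (lanA+lanB+lanC) clusters, clusters
lacking a lanA, orphan homologs, decoy genes, and the two awkward real-world
cases — a lanA written into intergenic DNA with *no* CDS annotation, and a
lanB frameshifted into two adjacent ORFs (80 aa + ~940 aa). Every planted
element is recorded in a :class:`GroundTruth` table so each pipeline stage
can be scored against truth.

Within a cluster, genes are separated by 50–500 nt; distinct planted
elements are separated by at least three clustering windows so they can
never merge. Intergenic background is i.i.d. uniform DNA post-processed so
that no six-frame ORF of >= 20 codons survives in pure background — spurious
precursor calls can then only arise from annotated decoys, which is what the
false-pass property test measures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome_io import (
    CdsFeature,
    GenomeRecord,
    ProteinRecord,
    write_fasta_proteins,
    write_genbank,
    extract_proteome,
)
from .lana import six_frame_orfs
from .templates import TemplateLibrary

_CLUSTER_WINDOW_NT = 10_000
_MIN_ORF_AA = 20


@dataclass
class GenomeSpec:
    """Parameters of one synthetic replicon."""

    seed: int
    length_nt: int = 0  # 0 -> auto-size to fit the requested content
    n_complete_clusters: int = 1
    n_nolana_clusters: int = 0
    n_orphans: int = 0
    intergenic_lana: bool = False
    frameshift_lanb: bool = False
    decoy_gene_count: int = 5
    mutation_rate: float = 0.0
    accession: str = ""

    def __post_init__(self) -> None:
        for name in (
            "n_complete_clusters", "n_nolana_clusters", "n_orphans",
            "decoy_gene_count",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.mutation_rate < 0.8):
            raise ValueError("mutation_rate must be in [0, 0.8)")
        if not self.accession:
            self.accession = f"SYN{self.seed:07d}"


@dataclass
class PlantedElement:
    role: str          # LanA | LanB | LanC | LanT | OMT | decoy ...
    locus_tag: str | None  # None for deliberately unannotated genes
    start: int
    end: int
    strand: int
    template_id: str
    cluster_id: str | None
    annotated: bool


@dataclass
class GroundTruth:
    genome: str
    elements: list[PlantedElement] = field(default_factory=list)
    cluster_classifications: dict[str, str] = field(default_factory=dict)

    def elements_in_cluster(self, cluster_id: str) -> list[PlantedElement]:
        return [e for e in self.elements if e.cluster_id == cluster_id]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "genome": self.genome,
                    "elements": [asdict(e) for e in self.elements],
                    "cluster_classifications": self.cluster_classifications,
                },
                fh,
                indent=1,
            )


# --------------------------------------------------------------------------
# protein mutation

_BLOSUM_SOFTMAX_T = 2.0


def _substitution_weights():
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    aas = "ACDEFGHIKLMNPQRSTVWY"
    weights = {}
    for a in aas:
        others = [b for b in aas if b != a]
        w = np.array(
            [np.exp(mat[a, b] / _BLOSUM_SOFTMAX_T) for b in others]
        )
        weights[a] = (others, w / w.sum())
    return weights


_SUB_WEIGHTS = None


def mutate_protein(
    seq: str,
    target_identity_pct: float,
    seed: int,
    protected: set[int] | None = None,
) -> str:
    """Substitute residues until identity to ``seq`` is ~target.

    Exactly round((100 − target)/100 × L) positions are substituted,
    uniformly at random among unprotected positions, each replaced by a
    BLOSUM62-weighted different residue — so global-alignment identity to
    the original is within ±2 points of the target for any L >= 25.
    Raises if the protection set leaves too few mutable positions.
    """
    global _SUB_WEIGHTS
    if not (20 <= target_identity_pct <= 100):
        raise ValueError("target identity must be in [20, 100]")
    protected = protected or set()
    n = len(seq)
    k = round((100.0 - target_identity_pct) / 100.0 * n)
    if k == 0:
        return seq
    free = [i for i in range(n) if i not in protected]
    if k > len(free):
        raise ValueError(
            f"cannot reach {target_identity_pct}% identity: only "
            f"{len(free)} of {n} positions are mutable"
        )
    if _SUB_WEIGHTS is None:
        _SUB_WEIGHTS = _substitution_weights()
    rng = np.random.default_rng(seed)
    sites = rng.choice(len(free), size=k, replace=False)
    chars = list(seq)
    for s in sorted(sites):
        i = free[int(s)]
        orig = chars[i]
        others, w = _SUB_WEIGHTS.get(orig, _SUB_WEIGHTS["A"])
        chars[i] = str(rng.choice(others, p=w))
    return "".join(chars)


# --------------------------------------------------------------------------
# DNA assembly

_BACK_TABLE: dict[str, list[str]] | None = None


def _codon_choices() -> dict[str, list[str]]:
    global _BACK_TABLE
    if _BACK_TABLE is None:
        table = CodonTable.unambiguous_dna_by_id[11]
        back: dict[str, list[str]] = {}
        for codon, aa in sorted(table.forward_table.items()):
            back.setdefault(aa, []).append(codon)
        _BACK_TABLE = back
    return _BACK_TABLE


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """DNA for a protein: ATG start, uniform synonymous codons, TAA stop."""
    back = _codon_choices()
    codons = ["ATG"]
    for aa in protein[1:]:
        codons.append(str(rng.choice(back[aa])))
    codons.append("TAA")
    return "".join(codons)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _clean_background(dna: str, rng: np.random.Generator) -> str:
    """Disrupt every six-frame ORF of >= _MIN_ORF_AA codons.

    Stops are planted at random codons of each offending ORF (overlapping
    ORFs on opposite strands can overwrite one another's planted stops, so
    fixed positions could cycle; random sites converge).
    """
    if len(dna) < 3 * _MIN_ORF_AA:
        return dna
    chars = list(dna)
    for _ in range(60):
        orfs = six_frame_orfs("".join(chars), min_aa=_MIN_ORF_AA, max_aa=10**9)
        if not orfs:
            break
        for orf in orfs:
            aa_len = (orf.end - orf.start) // 3 - 1
            picks = {int(rng.integers(1, aa_len)) for _ in range(2)}
            for j in picks:
                if orf.strand == 1:
                    pos = orf.start + 3 * j
                    chars[pos: pos + 3] = list("TAA")
                else:
                    pos = orf.end - 3 * (j + 1)
                    chars[pos: pos + 3] = list("TTA")  # revcomp of TAA
    return "".join(chars)


@dataclass
class _Gene:
    role: str
    protein: str
    template_id: str
    cluster_id: str | None
    annotated: bool = True
    locus_prefix: str = "g"


def _mutated(
    lib_seq: str, template_id: str, role: str, spec: GenomeSpec,
    rng: np.random.Generator, lib: TemplateLibrary,
) -> str:
    if spec.mutation_rate == 0:
        return lib_seq
    target = 100.0 * (1.0 - spec.mutation_rate)
    protected = lib.protected_positions(role, lib_seq)
    return mutate_protein(
        lib_seq, target, seed=int(rng.integers(2**31 - 1)),
        protected=protected,
    )


def generate_genome(
    spec: GenomeSpec, lib: TemplateLibrary | None = None
) -> tuple[GenomeRecord, GroundTruth]:
    """Build one annotated replicon plus its ground truth."""
    lib = lib or TemplateLibrary.default()
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth(genome=spec.accession)

    # plan the elements --------------------------------------------------
    element_plans: list[list[_Gene]] = []
    cid = 0
    for _ in range(spec.n_complete_clusters):
        cid += 1
        cluster = f"{spec.accession}.cl{cid}"
        lana = lib.lanas[int(rng.integers(1, len(lib.lanas)))]
        genes = [
            _Gene("LanA", _mutated(lana.sequence, lana.id, "LanA", spec,
                                   rng, lib), lana.id, cluster),
            _Gene("LanB", _mutated(lib.lanb.sequence, lib.lanb.id, "LanB",
                                   spec, rng, lib), lib.lanb.id, cluster),
            _Gene("LanC", _mutated(lib.lanc.sequence, lib.lanc.id, "LanC",
                                   spec, rng, lib), lib.lanc.id, cluster),
        ]
        # one accessory transporter and one O-methyltransferase per cluster
        for role in ("LanT", "OMT"):
            ex = lib.accessory[role]
            genes.append(
                _Gene(role, _mutated(ex.sequence, ex.id, role, spec, rng,
                                     lib), ex.id, cluster)
            )
        truth.cluster_classifications[cluster] = "COMPLETE"
        element_plans.append(genes)
    for _ in range(spec.n_nolana_clusters):
        cid += 1
        cluster = f"{spec.accession}.cl{cid}"
        genes = [
            _Gene("LanB", _mutated(lib.lanb.sequence, lib.lanb.id, "LanB",
                                   spec, rng, lib), lib.lanb.id, cluster),
            _Gene("LanC", _mutated(lib.lanc.sequence, lib.lanc.id, "LanC",
                                   spec, rng, lib), lib.lanc.id, cluster),
        ]
        truth.cluster_classifications[cluster] = "NO_LANA"
        element_plans.append(genes)
    for _ in range(spec.n_orphans):
        cid += 1
        cluster = f"{spec.accession}.cl{cid}"
        genes = [
            _Gene("LanC", _mutated(lib.lanc.sequence, lib.lanc.id, "LanC",
                                   spec, rng, lib), lib.lanc.id, cluster),
        ]
        truth.cluster_classifications[cluster] = "ORPHAN"
        element_plans.append(genes)
    for d in range(spec.decoy_gene_count):
        length = int(rng.integers(150, 400))
        prot = "".join(
            rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length)
        )
        element_plans.append(
            [_Gene("decoy", prot, f"decoy{d}", None)]
        )

    # special cases ------------------------------------------------------
    intergenic_cluster: str | None = None
    frameshift_cluster: str | None = None
    complete_ids = [
        c for c, cl in truth.cluster_classifications.items()
        if cl == "COMPLETE"
    ]
    if spec.intergenic_lana:
        if not complete_ids:
            raise ValueError("intergenic_lana requires a complete cluster")
        intergenic_cluster = complete_ids[0]
    if spec.frameshift_lanb:
        if not complete_ids:
            raise ValueError("frameshift_lanb requires a complete cluster")
        frameshift_cluster = complete_ids[-1]

    # lay out the DNA ----------------------------------------------------
    margin = 1500
    separation = 3 * _CLUSTER_WINDOW_NT
    pieces: list[str] = []
    features: list[CdsFeature] = []
    cursor = 0
    tag_no = 0

    def emit_background(n: int) -> None:
        nonlocal cursor
        pieces.append(_clean_background(_random_dna(n, rng), rng))
        cursor += n

    def emit_gene(gene: _Gene) -> tuple[int, int, int]:
        nonlocal cursor, tag_no
        dna = reverse_translate(gene.protein, rng)
        strand = 1 if rng.random() < 0.7 else -1
        if strand == -1:
            dna = str(Seq(dna).reverse_complement())
        start, end = cursor, cursor + len(dna)
        pieces.append(dna)
        cursor = end
        if gene.annotated:
            tag_no += 1
            tag = f"{spec.accession}_{tag_no:04d}"
            features.append(
                CdsFeature(
                    locus_tag=tag, start=start, end=end, strand=strand,
                    translation=gene.protein,
                    product=f"{gene.role} homolog"
                    if gene.role != "decoy" else "hypothetical protein",
                )
            )
        else:
            tag = None
        truth.elements.append(
            PlantedElement(
                role=gene.role, locus_tag=tag, start=start, end=end,
                strand=strand, template_id=gene.template_id,
                cluster_id=gene.cluster_id, annotated=gene.annotated,
            )
        )
        return start, end, strand

    def emit_frameshift_lanb(gene: _Gene) -> None:
        """Split a lanB into two adjacent forward-strand ORFs (80 aa + rest),
        mirroring an apparently frameshifted dehydratase gene."""
        nonlocal cursor, tag_no
        part_a, part_b = gene.protein[:80], gene.protein[80:]
        gap = int(rng.integers(5, 60))
        for part, sub in (("a", part_a), ("b", part_b)):
            dna = reverse_translate(sub, rng)
            start, end = cursor, cursor + len(dna)
            pieces.append(dna)
            cursor = end
            tag_no += 1
            tag = f"{spec.accession}_{tag_no:04d}"
            features.append(
                CdsFeature(
                    locus_tag=tag, start=start, end=end, strand=1,
                    translation=sub, product="LanB fragment",
                )
            )
            truth.elements.append(
                PlantedElement(
                    role="LanB", locus_tag=tag, start=start, end=end,
                    strand=1, template_id=gene.template_id,
                    cluster_id=gene.cluster_id, annotated=True,
                )
            )
            if part == "a":
                emit_background(gap)

    def emit_unannotated_lana(gene: _Gene) -> None:
        """Write a lanA into the DNA with no CDS feature (forward strand,
        guarded by an in-frame upstream stop so the ORF cannot extend)."""
        nonlocal cursor
        pieces.append("TAA")
        cursor += 3
        dna = reverse_translate(gene.protein, rng)
        start, end = cursor, cursor + len(dna)
        pieces.append(dna)
        cursor = end
        truth.elements.append(
            PlantedElement(
                role="LanA", locus_tag=None, start=start, end=end,
                strand=1, template_id=gene.template_id,
                cluster_id=gene.cluster_id, annotated=False,
            )
        )

    emit_background(margin)
    for plan in element_plans:
        for gi, gene in enumerate(plan):
            if gi > 0:
                emit_background(int(rng.integers(50, 501)))
            if (
                gene.role == "LanA"
                and gene.cluster_id == intergenic_cluster
            ):
                emit_unannotated_lana(gene)
            elif (
                gene.role == "LanB"
                and gene.cluster_id == frameshift_cluster
            ):
                emit_frameshift_lanb(gene)
            else:
                emit_gene(gene)
        emit_background(separation + int(rng.integers(0, 2000)))
    emit_background(margin)

    sequence = "".join(pieces)
    if spec.length_nt:
        if spec.length_nt < len(sequence):
            raise ValueError(
                f"length_nt too short for requested content; need at least "
                f"{len(sequence)} nt"
            )
        pad = spec.length_nt - len(sequence)
        sequence += _clean_background(_random_dna(pad, rng), rng) if pad \
            else ""
    genome = GenomeRecord(
        accession=spec.accession, sequence=sequence, features=features
    )
    return genome, truth


def study_cohort(base_seed: int, n_genomes: int = 20) -> list[GenomeSpec]:
    """The default evaluation cohort of synthetic replicons.

    Cycles through layouts mixing COMPLETE, NO_LANA and ORPHAN content and
    the two hard cases (unannotated intergenic lanA, frameshift-split lanB);
    the first half of the cohort is unmutated, the second half mutates every
    planted family to ~70% identity (mutation rate 0.3).
    """
    rng = np.random.default_rng(base_seed)
    layouts = [
        dict(n_complete_clusters=1, n_nolana_clusters=1),
        dict(n_complete_clusters=1, n_orphans=1, intergenic_lana=True),
        dict(n_complete_clusters=1, frameshift_lanb=True),
        dict(n_complete_clusters=2),
        dict(n_complete_clusters=0, n_nolana_clusters=1, n_orphans=1),
    ]
    specs = []
    for i in range(n_genomes):
        seed = int(rng.integers(1, 2**31 - 1))
        specs.append(
            GenomeSpec(
                seed=seed,
                mutation_rate=0.0 if i < n_genomes // 2 else 0.3,
                decoy_gene_count=3,
                accession=f"SYNG{i:02d}",
                **layouts[i % len(layouts)],
            )
        )
    return specs


def match_clusters(
    clusters, truth: GroundTruth
) -> tuple[dict[str, str | None], list]:
    """Match reported clusters to planted ones by span overlap.

    Returns (cluster_id -> reported classification or None if missed,
    list of reported clusters overlapping no planted cluster).
    """
    spans: dict[str, tuple[int, int]] = {}
    for cid in truth.cluster_classifications:
        els = truth.elements_in_cluster(cid)
        spans[cid] = (min(e.start for e in els), max(e.end for e in els))
    assigned: dict[str, str | None] = {cid: None for cid in spans}
    false_clusters = []
    for c in clusters:
        hit_cid = None
        for cid, (s, e) in spans.items():
            if c.span[0] < e and c.span[1] > s:
                hit_cid = cid
                break
        if hit_cid is None:
            false_clusters.append(c)
        else:
            assigned[hit_cid] = c.classification
    return assigned, false_clusters


def write_outputs(
    genome: GenomeRecord, truth: GroundTruth, outdir: str | Path
) -> None:
    """GenBank + protein FASTA + ground-truth JSON for one genome."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genbank([genome], outdir / f"{genome.accession}.gbk")
    write_fasta_proteins(
        extract_proteome(genome), outdir / f"{genome.accession}.faa"
    )
    truth.to_json(outdir / f"{genome.accession}.truth.json")
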