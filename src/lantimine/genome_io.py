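"""Genome, proteome and intergenic-region I/O.

Reads annotated bacterial replicons from GenBank flat files (or paired
nucleotide/protein FASTA) into :class:`GenomeRecord` objects with 0-based,
half-open coordinates, and provides coordinate-consistent access to CDS
features and the CDS-free (intergenic) DNA between them.

GenBank's 1-based inclusive coordinates are converted at the I/O boundary
only; everything downstream works on 0-based half-open intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_NT = set("ACGTN")


@dataclass
class CdsFeature:
    """A protein-coding feature on a genome.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand; ``strand`` is +1 or -1. ``translation`` excludes the stop
    codon.
    """

    locus_tag: str
    start: int
    end: int
    strand: int
    translation: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """An annotated replicon: sequence plus ordered CDS features."""

    accession: str
    sequence: str
    features: list[CdsFeature] = field(default_factory=list)
    topology: str = "linear"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_NT
        if bad:
            raise ValueError(f"illegal nucleotide(s): {sorted(bad)}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"bad topology {self.topology!r}")
        self.features.sort(key=lambda f: (f.start, f.end, f.locus_tag))
        tags = [f.locus_tag for f in self.features]
        if len(tags) != len(set(tags)):
            raise ValueError("duplicate locus_tag in genome record")
        for f in self.features:
            if f.start < 0 or f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.locus_tag} outside sequence bounds"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_tag(self, locus_tag: str) -> CdsFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)


@dataclass
class ProteinRecord:
    """An amino-acid sequence with its provenance.

    ``source`` is either ``(genome_accession, locus_tag)`` or the string
    ``"external driver"`` for query proteins supplied from outside a genome.
    """

    id: str
    sequence: str
    source: tuple[str, str] | str = "external driver"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty protein sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class IntergenicRegion:
    """A maximal CDS-free interval, tagged with its flanking locus tags."""

    genome: str
    start: int
    end: int
    flanking_locus_tags: tuple[str | None, str | None]

    @property
    def length(self) -> int:
        return self.end - self.start


def _translate_cds(dna: str, strand: int) -> str:
    seq = Seq(dna)
    if strand == -1:
        seq = seq.reverse_complement()
    prot = str(seq.translate(table=11))
    if prot.endswith("*"):
        prot = prot[:-1]
    # Ambiguity or internal stops are tolerated (draft genomes); report stops.
    if "*" in prot:
        logger.warning("internal stop codon(s) in translated CDS")
    return prot.replace("*", "X")


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Read a GenBank flat file into one :class:`GenomeRecord` per contig.

    CDS features lacking a ``/translation`` qualifier are translated from
    their coordinates (bacterial table); ``join``/``complement`` locations are
    resolved by Biopython. CDS with out-of-range coordinates are skipped with
    a warning; a record without sequence is a hard error.
    """
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        if len(rec.seq) == 0:
            raise ValueError(f"record {rec.id} has no sequence")
        seq = str(rec.seq).upper()
        feats: list[CdsFeature] = []
        counter = 0
        for f in rec.features:
            if f.type != "CDS":
                continue
            start = int(f.location.start)
            end = int(f.location.end)
            if start < 0 or end > len(seq) or end <= start:
                logger.warning(
                    "skipping CDS with out-of-range location in %s", rec.id
                )
                continue
            strand = 1 if (f.location.strand or 1) >= 0 else -1
            tag = f.qualifiers.get("locus_tag", [None])[0]
            if tag is None:
                counter += 1
                tag = f"{rec.id}_cds{counter:04d}"
            translation = f.qualifiers.get("translation", [None])[0]
            if translation is None:
                parts = [
                    seq[int(p.start): int(p.end)] for p in f.location.parts
                ]
                if strand == -1 and len(parts) > 1:
                    parts = parts[::-1]
                translation = _translate_cds("".join(parts), strand)
            product = f.qualifiers.get("product", [""])[0]
            feats.append(
                CdsFeature(
                    locus_tag=tag,
                    start=start,
                    end=end,
                    strand=strand,
                    translation=translation.upper(),
                    product=product,
                )
            )
        topology = rec.annotations.get("topology", "linear")
        if topology not in ("linear", "circular"):
            topology = "linear"
        records.append(
            GenomeRecord(
                accession=rec.id, sequence=seq, features=feats,
                topology=topology,
            )
        )
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_genbank(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write GenomeRecords as a GenBank flat file (deterministic bytes)."""
    recs = []
    for g in genomes:
        rec = SeqRecord(
            Seq(g.sequence), id=g.accession, name=g.accession[:16],
            description="synthetic replicon",
        )
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = g.topology
        for f in g.features:
            rec.features.append(
                SeqFeature(
                    SimpleLocation(f.start, f.end, strand=f.strand),
                    type="CDS",
                    qualifiers={
                        "locus_tag": [f.locus_tag],
                        "translation": [f.translation],
                        "product": [f.product or "hypothetical protein"],
                    },
                )
            )
        recs.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "genbank")


def read_fasta_proteins(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta_proteins(
    proteins: Iterable[ProteinRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i: i + 60] + "\n")


def extract_proteome(g: GenomeRecord) -> list[ProteinRecord]:
    """One ProteinRecord per CDS, id = locus_tag, in feature order."""
    return [
        ProteinRecord(
            id=f.locus_tag,
            sequence=f.translation,
            source=(g.accession, f.locus_tag),
        )
        for f in g.features
        if f.translation
    ]


def intergenic_regions(
    g: GenomeRecord, min_len: int = 0
) -> list[IntergenicRegion]:
    """Maximal CDS-free intervals of length >= ``min_len``.

    Flanking locus tags name the CDS immediately left/right of the gap (None
    at linear ends). For a circular genome the wrap-around gap is included:
    the head and tail pieces are reported in linear coordinates but their
    flanking tags reflect the wrap (the head gap's left neighbour is the last
    CDS, the tail gap's right neighbour the first CDS).
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    n = len(g.sequence)
    if not g.features:
        return (
            [IntergenicRegion(g.accession, 0, n, (None, None))]
            if n >= min_len and n > 0
            else []
        )
    # merge overlapping CDS intervals (either strand occupies the locus)
    ivals: list[list[int]] = []
    for f in g.features:
        if ivals and f.start <= ivals[-1][1]:
            ivals[-1][1] = max(ivals[-1][1], f.end)
            ivals[-1][2].append(f.locus_tag)
        else:
            ivals.append([f.start, f.end, [f.locus_tag]])
    regions: list[IntergenicRegion] = []
    prev_end = 0
    prev_tag: str | None = None
    for start, end, tags in ivals:
        if start - prev_end >= max(min_len, 1):
            regions.append(
                IntergenicRegion(
                    g.accession, prev_end, start, (prev_tag, tags[0])
                )
            )
        prev_end = end
        prev_tag = tags[-1]
    if n - prev_end >= max(min_len, 1):
        right_flank = ivals[0][2][0] if g.topology == "circular" else None
        regions.append(
            IntergenicRegion(g.accession, prev_end, n, (prev_tag, right_flank))
        )
    if g.topology == "circular" and regions and regions[0].start == 0:
        # head gap of a circular replicon flanks the last CDS on its left
        head = regions[0]
        regions[0] = IntergenicRegion(
            g.accession, head.start, head.end,
            (ivals[-1][2][-1], head.flanking_locus_tags[1]),
        )
    regions.sort(key=lambda r: r.start)
    return regions
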