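"""End-to-end screen: homology → precursor discovery → clusters → reports.

`run_pipeline` drives the whole mining procedure over a set of annotated
genomes: iterative driver-based screening for LanB/LanC homologs, merging of
frameshift-split dehydratases, precursor (LanA) discovery in annotated and
intergenic DNA near the anchors, single-linkage cluster assembly and
classification, accessory-gene annotation, and — when enough members exist —
per-role conservation tables and neighbor-joining trees.

Each genome is processed independently (removing one genome never changes
another's rows); all steps are deterministic given the inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .clusters import (
    ClusterMember,
    GeneCluster,
    annotate_accessory,
    find_frameshift_partners,
)
from .clusters import assemble_clusters as _assemble
from .conservation import build_msa, motif_conservation
from .genome_io import (
    GenomeRecord,
    ProteinRecord,
    read_fasta_proteins,
    read_genbank,
    write_fasta_proteins,
)
from .homology import ScoringScheme, ScreenConfig, iterative_expand
from .lana import LanAConfig, find_lana_candidates
from .phylo import distance_matrix, nj_tree, write_newick
from .templates import TemplateLibrary, load_motif_definitions

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genomes: list[GenomeRecord]
    drivers: list[tuple[ProteinRecord, str]] | None = None
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    lana: LanAConfig = field(default_factory=LanAConfig)
    window_nt: int = 10_000
    max_rounds: int = 3
    outdir: str | Path | None = None
    seed: int = 0
    threads: int = 1  # accepted for interface compatibility; runs serial
    build_trees: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        genomes: list[GenomeRecord] = []
        for p in raw.get("genomes", []):
            genomes.extend(read_genbank(p))
        drivers = None
        if "drivers" in raw:
            drivers = []
            for entry in raw["drivers"]:
                for rec in read_fasta_proteins(entry["path"]):
                    drivers.append((rec, entry.get("role", "LanC")))
        screen = ScreenConfig(
            evalue_max=float(raw.get("evalue_max", 1e-7)),
            identity_min_pct=float(raw.get("identity_min_pct", 20.0)),
        )
        return cls(
            genomes=genomes,
            drivers=drivers,
            screen=screen,
            window_nt=int(raw.get("window_nt", 10_000)),
            max_rounds=int(raw.get("max_rounds", 3)),
            outdir=raw.get("outdir"),
            seed=int(raw.get("seed", 0)),
            threads=int(raw.get("threads", 1)),
        )


@dataclass
class ScreenReport:
    rows: list[dict]
    clusters: list[GeneCluster]
    n_complete: int
    n_nolana: int
    n_orphan: int
    n_multi_lanc_no_a: int
    n_total_hits: int
    rounds_used: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def summary(self) -> dict:
        return {
            "n_complete": self.n_complete,
            "n_nolana": self.n_nolana,
            "n_orphan": self.n_orphan,
            "n_multi_lanc_no_a": self.n_multi_lanc_no_a,
            "n_total_hits": self.n_total_hits,
            "rounds_used": self.rounds_used,
            "n_clusters": len(self.clusters),
        }


def run_pipeline(cfg: PipelineConfig) -> ScreenReport:
    if not cfg.genomes:
        raise ValueError("empty genome set")
    lib = TemplateLibrary.default()
    drivers = cfg.drivers if cfg.drivers is not None else lib.drivers()
    role_refs = {role: rec for rec, role in drivers}

    all_rows: list[dict] = []
    all_clusters: list[GeneCluster] = []
    role_seqs: dict[str, list[ProteinRecord]] = {}
    total_hits = 0
    max_rounds_used = 0

    for g in sorted(cfg.genomes, key=lambda x: x.accession):
        logger.info("screening %s", g.accession)
        try:
            hits, rounds = iterative_expand(
                drivers, [g], cfg.scoring, cfg.screen, cfg.max_rounds
            )
        except Exception:
            logger.exception("screen failed for %s; skipping", g.accession)
            continue
        max_rounds_used = max(max_rounds_used, rounds)
        total_hits += len(hits)

        # frameshift-split dehydratase/cyclase genes
        extra_members: list[ClusterMember] = []
        merged_peptides: dict[str, str] = {}
        partner_tags: set[str] = set()
        for role in ("LanB", "LanC"):
            ref = role_refs.get(role)
            if ref is None:
                continue
            role_hits = [h for h in hits if h.role_hypothesis == role]
            for merge, partner in find_frameshift_partners(
                g, role_hits, ref, cfg.scoring
            ):
                partner_tags.add(partner.locus_tag)
                extra_members.append(
                    ClusterMember(
                        member_id=partner.locus_tag, role=role,
                        start=partner.start, end=partner.end,
                        strand=partner.strand,
                    )
                )
                merged_peptides[merge.part_a] = merge.merged_peptide
                merged_peptides[merge.part_b] = ""
                logger.info(
                    "merged frameshift pair %s + %s (%s)",
                    merge.part_a, merge.part_b, role,
                )

        anchors = [
            h for h in hits if h.role_hypothesis in ("LanB", "LanC")
        ]
        exclude = {h.locus_tag for h in hits} | partner_tags
        lana_cands = find_lana_candidates(
            g, anchors, cfg.window_nt, cfg.lana, exclude_tags=exclude
        )
        logger.info(
            "%s: %d hits, %d precursor candidates",
            g.accession, len(hits), len(lana_cands),
        )

        clusters = _assemble(
            hits, lana_cands, g, cfg.window_nt, extra_members=extra_members
        )
        clusters = [
            annotate_accessory(
                c, g, list(lib.accessory.values()), cfg.scoring, cfg.screen
            )
            for c in clusters
        ]
        all_clusters.extend(clusters)

        by_tag = {f.locus_tag: f for f in g.features}
        lana_pep = {cand.id: cand.peptide for cand, _ in lana_cands}
        for ci, c in enumerate(clusters, start=1):
            for m in c.members:
                all_rows.append(
                    {
                        "genome": g.accession,
                        "cluster": f"{g.accession}.c{ci}",
                        "classification": c.classification,
                        "span_start": c.span[0],
                        "span_end": c.span[1],
                        "member": m.member_id,
                        "role": m.role,
                        "start": m.start,
                        "end": m.end,
                        "strand": m.strand,
                        "identity_pct": m.identity_pct,
                    }
                )
                if m.role in ("LanA", "LanB", "LanC"):
                    pep = merged_peptides.get(m.member_id)
                    if pep == "":
                        continue  # downstream half of a merged pair
                    if pep is None:
                        if m.member_id in by_tag:
                            pep = by_tag[m.member_id].translation
                        else:
                            pep = lana_pep.get(m.member_id)
                    if pep:
                        role_seqs.setdefault(m.role, []).append(
                            ProteinRecord(
                                id=f"{g.accession}.{m.member_id}",
                                sequence=pep,
                                source=(g.accession, m.member_id),
                            )
                        )

    counts = {"COMPLETE": 0, "NO_LANA": 0, "ORPHAN": 0, "MULTI_LANC_NO_A": 0}
    for c in all_clusters:
        counts[c.classification] += 1
    report = ScreenReport(
        rows=all_rows,
        clusters=all_clusters,
        n_complete=counts["COMPLETE"],
        n_nolana=counts["NO_LANA"],
        n_orphan=counts["ORPHAN"],
        n_multi_lanc_no_a=counts["MULTI_LANC_NO_A"],
        n_total_hits=total_hits,
        rounds_used=max_rounds_used,
    )

    if cfg.outdir is not None:
        _write_outputs(cfg, report, role_seqs, role_refs)
    return report


def _write_outputs(
    cfg: PipelineConfig,
    report: ScreenReport,
    role_seqs: dict[str, list[ProteinRecord]],
    role_refs: dict[str, ProteinRecord],
) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = report.to_dataframe()
    df.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report.summary(), fh, indent=1, sort_keys=True)
    for role, seqs in sorted(role_seqs.items()):
        write_fasta_proteins(seqs, outdir / f"{role}.faa")
        ref = role_refs.get(role)
        if ref is None or len(seqs) < 2:
            continue
        msa_in = [ref] + seqs
        msa = build_msa(msa_in)
        if role in ("LanB", "LanC"):
            defs = load_motif_definitions(role, reference_id=ref.id)
            table = motif_conservation(msa, defs)
            table.to_tsv(outdir / f"conservation_{role}.tsv")
        if cfg.build_trees and len(seqs) >= 3:
            dm = distance_matrix(msa, model="p")
            tree = nj_tree(dm)
            write_newick(tree, outdir / f"tree_{role}.nwk")
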