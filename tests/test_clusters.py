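"""Cluster assembly, classification, frameshift merging, accessory roles."""

import numpy as np
import pytest

from lantimine.clusters import (
    COMPLETE,
    MULTI_LANC_NO_A,
    NO_LANA,
    ORPHAN,
    ClusterMember,
    GeneCluster,
    annotate_accessory,
    assemble_clusters,
    classify_cluster,
    merge_frameshift,
)
from lantimine.genome_io import CdsFeature, GenomeRecord
from lantimine.homology import AlignmentResult, HomologHit
from lantimine.pipeline import PipelineConfig, run_pipeline
from lantimine.synthetic import GenomeSpec, generate_genome


def _hit(genome, tag, role):
    return HomologHit(
        alignment=AlignmentResult(
            query_id="drv", target_id=tag, score=500, identity_pct=80.0,
            aligned_cols=100, query_span=(0, 100), target_span=(0, 100),
            evalue=1e-50,
        ),
        genome_accession=genome,
        locus_tag=tag,
        role_hypothesis=role,
    )


@pytest.mark.parametrize(
    "roles,expected",
    [
        (["LanA", "LanB", "LanC"], COMPLETE),
        (["LanB", "LanC"], NO_LANA),
        (["LanC"], ORPHAN),
        (["LanB"], ORPHAN),
        (["LanA"], ORPHAN),
        (["LanC", "LanC"], MULTI_LANC_NO_A),
        (["LanB", "LanC", "LanC"], NO_LANA),
        (["LanA", "LanC", "LanC"], ORPHAN),
    ],
)
def test_classify_cluster(roles, expected):
    c = GeneCluster(
        genome="g", span=(0, 100),
        members=[
            ClusterMember(f"m{i}", r, i * 10, i * 10 + 5, 1)
            for i, r in enumerate(roles)
        ],
    )
    assert classify_cluster(c) == expected


def test_distant_hits_form_separate_orphan_clusters():
    g = GenomeRecord(
        accession="far",
        sequence="A" * 70_000,
        features=[
            CdsFeature("b1", 1000, 2000, 1, "M" + "K" * 100),
            CdsFeature("c1", 52_000, 53_000, 1, "M" + "K" * 100),
        ],
    )
    clusters = assemble_clusters(
        [_hit("far", "b1", "LanB"), _hit("far", "c1", "LanC")], [], g,
        window_nt=10_000,
    )
    assert len(clusters) == 2
    assert all(c.classification == ORPHAN for c in clusters)
    # with a window that spans the gap they merge into one NO_LANA cluster
    merged = assemble_clusters(
        [_hit("far", "b1", "LanB"), _hit("far", "c1", "LanC")], [], g,
        window_nt=60_000,
    )
    assert len(merged) == 1
    assert merged[0].classification == NO_LANA


def test_assemble_is_order_invariant_and_window_monotone():
    g = GenomeRecord(
        accession="ord",
        sequence="A" * 100_000,
        features=[
            CdsFeature(f"t{i}", p, p + 500, 1, "M" + "K" * 50)
            for i, p in enumerate([1000, 5000, 30_000, 60_000, 61_000])
        ],
    )
    hits = [_hit("ord", f"t{i}", "LanC") for i in range(5)]
    a = assemble_clusters(hits, [], g, window_nt=10_000)
    b = assemble_clusters(list(reversed(hits)), [], g, window_nt=10_000)
    assert [c.span for c in a] == [c.span for c in b]
    # elements partition: every hit appears exactly once
    members = [m.member_id for c in a for m in c.members]
    assert sorted(members) == [f"t{i}" for i in range(5)]
    prev = None
    for w in (1000, 5000, 10_000, 40_000, 80_000):
        k = len(assemble_clusters(hits, [], g, window_nt=w))
        if prev is not None:
            assert k <= prev
        prev = k


def test_merge_frameshift_accepts_split_lanb(lib):
    """An 80 aa + 940 aa adjacent pair merges against the intact reference."""
    prot = lib.lanb.sequence
    part_a = CdsFeature("fs_a", 1000, 1000 + 80 * 3 + 3, 1, prot[:80])
    part_b = CdsFeature(
        "fs_b", part_a.end + 20, part_a.end + 20 + (len(prot) - 80) * 3 + 3,
        1, prot[80:],
    )
    merge = merge_frameshift(part_a, part_b, lib.lanb)
    assert merge is not None
    assert merge.merged_peptide == prot
    cov_a, cov_b = merge.reference_coverage
    assert cov_a + cov_b >= 0.95
    assert cov_a < cov_b  # N-terminal fragment is the short one


def test_merge_frameshift_rejects_unrelated_and_opposite_strand(lib):
    rng = np.random.default_rng(4)
    junk = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=500))
    a = CdsFeature("x", 0, 1503, 1, junk)
    b = CdsFeature("y", 1520, 3023, 1, junk[::-1])
    assert merge_frameshift(a, b, lib.lanb) is None
    pa = CdsFeature("p", 0, 243, 1, lib.lanb.sequence[:80])
    pb = CdsFeature("q", 260, 3083, -1, lib.lanb.sequence[80:])
    assert merge_frameshift(pa, pb, lib.lanb) is None


def test_pipeline_handles_frameshift_lanb():
    """A frameshift-split dehydratase still yields a COMPLETE cluster with
    both fragments assigned the LanB role."""
    g, truth = generate_genome(
        GenomeSpec(seed=21, n_complete_clusters=1, frameshift_lanb=True,
                   decoy_gene_count=2)
    )
    fs_tags = {
        e.locus_tag for e in truth.elements
        if e.role == "LanB" and e.locus_tag
    }
    assert len(fs_tags) == 2
    report = run_pipeline(PipelineConfig(genomes=[g]))
    assert report.n_complete == 1
    lanb_members = {
        r["member"] for r in report.rows if r["role"] == "LanB"
    }
    assert fs_tags <= lanb_members


def test_annotate_accessory_assigns_roles(lib):
    g, truth = generate_genome(
        GenomeSpec(seed=22, n_complete_clusters=1, decoy_gene_count=0)
    )
    core_tags = {
        e.locus_tag for e in truth.elements
        if e.role in ("LanA", "LanB", "LanC") and e.locus_tag
    }
    span = (
        min(e.start for e in truth.elements),
        max(e.end for e in truth.elements),
    )
    c = GeneCluster(
        genome=g.accession, span=span,
        members=[
            ClusterMember(t, "LanB", g.feature_by_tag(t).start,
                          g.feature_by_tag(t).end, 1)
            for t in core_tags
        ],
    )
    out = annotate_accessory(c, g, list(lib.accessory.values()))
    roles = {m.member_id: m.role for m in out.members}
    for e in truth.elements:
        if e.role in ("LanT", "OMT"):
            assert roles[e.locus_tag] == e.role


def test_annotate_accessory_unmatched_gene_is_other(lib):
    rng = np.random.default_rng(17)
    junk = "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300))
    g = GenomeRecord(
        accession="oth", sequence="A" * 5000,
        features=[CdsFeature("u1", 1000, 1903, 1, junk)],
    )
    c = GeneCluster(
        genome="oth", span=(0, 5000),
        members=[ClusterMember("anchor", "LanC", 100, 200, 1)],
    )
    out = annotate_accessory(c, g, list(lib.accessory.values()))
    roles = {m.member_id: m.role for m in out.members}
    assert roles["u1"] == "other"
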