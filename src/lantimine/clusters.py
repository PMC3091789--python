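"""Assembly and classification of lantibiotic gene clusters.

Homolog hits (LanB/LanC), precursor candidates (LanA) and accessory genes
are grouped by single-linkage proximity: two elements join the same cluster
iff their intervals lie within a window (default 10 kb) of each other.
Clusters are classified as COMPLETE (lanA+lanB+lanC), NO_LANA (lanB+lanC,
no lanA), MULTI_LANC_NO_A (>= 2 lanC, no lanA — reported separately because
it is a recurrent arrangement), or ORPHAN (an isolated homolog with no other
lantibiotic-role gene in close association).

`merge_frameshift` recognises a dehydratase split across two adjacent ORFs —
an 80 aa fragment followed by a ~940 aa fragment is the motivating real-world
case — by requiring the two parts to align to complementary, essentially
non-overlapping regions of an intact reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .genome_io import CdsFeature, GenomeRecord, ProteinRecord
from .homology import (
    HomologHit,
    ScoringScheme,
    ScreenConfig,
    align_pair,
    screen_proteome,
)
from .lana import LanAScore, OrfCandidate

LANTIBIOTIC_ROLES = {
    "LanA", "LanB", "LanC", "LanT", "LanP", "LanE", "LanF", "LanG",
    "LanK", "LanR", "LanD", "OMT",
}
CORE_ROLES = {"LanA", "LanB", "LanC"}

COMPLETE = "COMPLETE"
NO_LANA = "NO_LANA"
ORPHAN = "ORPHAN"
MULTI_LANC_NO_A = "MULTI_LANC_NO_A"


@dataclass
class ClusterMember:
    member_id: str  # locus_tag or ORF id
    role: str
    start: int
    end: int
    strand: int
    identity_pct: float | None = None  # identity to the driver, if screened


@dataclass
class GeneCluster:
    genome: str
    span: tuple[int, int]
    members: list[ClusterMember]
    classification: str = ""

    def roles(self) -> list[str]:
        return [m.role for m in self.members]


@dataclass
class FrameshiftMerge:
    part_a: str
    part_b: str
    merged_peptide: str
    reference_coverage: tuple[float, float]


def classify_cluster(c: GeneCluster) -> str:
    """Classification from the member roles.

    Precedence: COMPLETE > NO_LANA > MULTI_LANC_NO_A > ORPHAN. The
    multi-LanC label requires >= 2 lanC and no lanA; LanB presence is not
    part of that condition, but a cluster with both lanB and lanC (and no
    lanA) is NO_LANA first.
    """
    roles = c.roles()
    has_a = "LanA" in roles
    has_b = "LanB" in roles
    n_c = roles.count("LanC")
    if has_a and has_b and n_c >= 1:
        return COMPLETE
    if has_b and n_c >= 1:
        return NO_LANA
    if n_c >= 2 and not has_a:
        return MULTI_LANC_NO_A
    return ORPHAN


def assemble_clusters(
    hits: list[HomologHit],
    lana: list[tuple[OrfCandidate, LanAScore]],
    g: GenomeRecord,
    window_nt: int = 10_000,
    extra_members: list[ClusterMember] | None = None,
) -> list[GeneCluster]:
    """Single-linkage grouping of hits + precursor candidates into clusters.

    Elements join one cluster iff their intervals are within ``window_nt``;
    the result is invariant to input order, and each element appears in
    exactly one cluster. ``extra_members`` lets callers inject elements with
    pre-assigned roles (e.g. merged frameshift partners).
    """
    members: dict[str, ClusterMember] = {}
    for h in hits:
        if h.genome_accession != g.accession:
            continue
        try:
            f = g.feature_by_tag(h.locus_tag)
        except KeyError:
            continue
        members[h.locus_tag] = ClusterMember(
            member_id=h.locus_tag, role=h.role_hypothesis,
            start=f.start, end=f.end, strand=f.strand,
            identity_pct=h.identity_pct,
        )
    for cand, _score in lana:
        if cand.genome != g.accession or cand.id in members:
            continue
        members[cand.id] = ClusterMember(
            member_id=cand.id, role="LanA",
            start=cand.start, end=cand.end, strand=cand.strand,
        )
    for m in extra_members or []:
        members.setdefault(m.member_id, m)
    if not members:
        return []
    ordered = sorted(members.values(), key=lambda m: (m.start, m.member_id))
    groups: list[list[ClusterMember]] = [[ordered[0]]]
    group_end = ordered[0].end
    for m in ordered[1:]:
        if m.start - group_end <= window_nt:
            groups[-1].append(m)
            group_end = max(group_end, m.end)
        else:
            groups.append([m])
            group_end = m.end
    clusters = []
    for grp in groups:
        c = GeneCluster(
            genome=g.accession,
            span=(min(m.start for m in grp), max(m.end for m in grp)),
            members=grp,
        )
        c.classification = classify_cluster(c)
        clusters.append(c)
    return clusters


def merge_frameshift(
    part_a: CdsFeature,
    part_b: CdsFeature,
    reference: ProteinRecord,
    s: ScoringScheme | None = None,
    max_gap_nt: int = 100,
    min_coverage: float = 0.70,
) -> FrameshiftMerge | None:
    """Try to merge two adjacent ORFs as one frameshift-split gene.

    The parts must be on the same strand with an intergenic gap of at most
    ``max_gap_nt``. The merge is accepted iff the upstream part (in reading
    order) aligns to the reference N-terminal region and the downstream part
    to the C-terminal region, each part is a significant homolog of its
    region (E <= 1e-3) contributing reference coverage the other part does
    not, their spans essentially do not overlap, union coverage is >=
    ``min_coverage`` of the reference, and the combined length is within
    80–120% of the reference. The novel-coverage requirement is what
    separates a genuine split gene from an intact hit flanked by an
    unrelated small ORF with an incidental local alignment.
    """
    if part_a.strand != part_b.strand:
        return None
    left, right = sorted((part_a, part_b), key=lambda f: f.start)
    gap = right.start - left.end
    if gap < 0 or gap > max_gap_nt:
        return None
    # reading order: upstream part contributes the N-terminus
    first, second = (left, right) if part_a.strand == 1 else (right, left)
    combined = len(first.translation) + len(second.translation)
    if not (0.8 * len(reference) <= combined <= 1.2 * len(reference)):
        return None
    s = s or ScoringScheme()
    res_a = align_pair(
        ProteinRecord(id="a", sequence=first.translation), reference, s,
        mode="local",
    )
    res_b = align_pair(
        ProteinRecord(id="b", sequence=second.translation), reference, s,
        mode="local",
    )
    if res_a.evalue > 1e-3 or res_b.evalue > 1e-3:
        return None
    span_a = res_a.target_span
    span_b = res_b.target_span
    overlap = max(0, min(span_a[1], span_b[1]) - max(span_a[0], span_b[0]))
    cov_a = (span_a[1] - span_a[0]) / len(reference)
    cov_b = (span_b[1] - span_b[0]) / len(reference)
    novel_a = (span_a[1] - span_a[0]) - overlap
    novel_b = (span_b[1] - span_b[0]) - overlap
    if span_a[0] >= span_b[0]:  # N-terminal part must map before C-terminal
        return None
    if overlap > 0.1 * len(reference):
        return None
    if min(novel_a, novel_b) < 0.04 * len(reference):
        return None
    union_cov = (novel_a + novel_b + overlap) / len(reference)
    if union_cov < min_coverage:
        return None
    return FrameshiftMerge(
        part_a=first.locus_tag,
        part_b=second.locus_tag,
        merged_peptide=first.translation + second.translation,
        reference_coverage=(round(cov_a, 3), round(cov_b, 3)),
    )


def find_frameshift_partners(
    g: GenomeRecord,
    hits: list[HomologHit],
    reference: ProteinRecord,
    s: ScoringScheme | None = None,
    max_gap_nt: int = 100,
) -> list[tuple[FrameshiftMerge, CdsFeature]]:
    """Locate frameshift partners of screened hits.

    For every hit whose neighbouring CDS (same strand, gap <= ``max_gap_nt``)
    is not itself a hit, attempt a frameshift merge against ``reference``;
    returns accepted merges with the partner feature.
    """
    s = s or ScoringScheme()
    hit_tags = {h.locus_tag for h in hits if h.genome_accession == g.accession}
    feats = g.features
    merges: list[tuple[FrameshiftMerge, CdsFeature]] = []
    for i, f in enumerate(feats):
        if f.locus_tag not in hit_tags:
            continue
        for j in (i - 1, i + 1):
            if not (0 <= j < len(feats)):
                continue
            partner = feats[j]
            if partner.locus_tag in hit_tags:
                continue
            merge = merge_frameshift(
                f, partner, reference, s, max_gap_nt=max_gap_nt
            )
            if merge is not None:
                merges.append((merge, partner))
    return merges


def annotate_accessory(
    c: GeneCluster,
    g: GenomeRecord,
    reference_families: list[ProteinRecord],
    s: ScoringScheme | None = None,
    cfg: ScreenConfig | None = None,
) -> GeneCluster:
    """Assign accessory roles to unassigned genes inside the cluster span.

    Each CDS within the span that is not already a member is screened
    against the exemplar family set (ids like ``LanT_ex``); the best hit
    passing the screen thresholds donates its role, otherwise the gene is
    annotated "other".
    """
    s = s or ScoringScheme()
    cfg = cfg or ScreenConfig()
    assigned = {m.member_id for m in c.members}
    new_members = list(c.members)
    for f in g.features:
        if f.locus_tag in assigned:
            continue
        if f.end <= c.span[0] or f.start >= c.span[1]:
            continue
        if not f.translation:
            continue
        best_role, best_e = "other", float("inf")
        query = ProteinRecord(
            id=f.locus_tag, sequence=f.translation,
            source=(g.accession, f.locus_tag),
        )
        for ref in reference_families:
            hits = screen_proteome(
                ref, [query], s, cfg,
                role_hypothesis=ref.id.split("_")[0],
            )
            if hits and hits[0].evalue < best_e:
                best_e = hits[0].evalue
                best_role = hits[0].role_hypothesis
        new_members.append(
            ClusterMember(
                member_id=f.locus_tag, role=best_role,
                start=f.start, end=f.end, strand=f.strand,
            )
        )
    new_members.sort(key=lambda m: (m.start, m.member_id))
    out = replace(c, members=new_members)
    out.classification = classify_cluster(out)
    return out
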