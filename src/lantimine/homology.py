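"""Driver-based protein homology screening.

The screen mirrors a default-parameter protein BLAST: optimal local
(Smith–Waterman) or global (Needleman–Wunsch) alignment under BLOSUM62 with
affine gaps (open 11, extend 1), a Karlin–Altschul E-value computed against
the screened database size, and the acceptance thresholds E <= 1e-7 and
identity > 20%.

Identity is computed over all alignment columns (gap columns count in the
denominator); 'X' never counts as an identity. Whether identity should
instead be normalised by query length is genuinely ambiguous in the screen's
description; alignment-length normalisation is the default and the choice is
configurable via ``ScreenConfig.identity_over_query``.

`iterative_expand` repeats the screen with every newly found homolog as an
additional driver until no new protein is recovered — the "use the new
LanA/B/C proteins as drivers in turn" strategy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import GenomeRecord, ProteinRecord, extract_proteome

_AA = set("ACDEFGHIKLMNPQRSTVWYX")

# Published gapped Karlin-Altschul constants for BLOSUM62, gap open 11 /
# extend 1 (the scheme's defaults).
_GAPPED_LAMBDA = 0.267
_GAPPED_K = 0.041


@dataclass
class ScoringScheme:
    """Substitution matrix + affine gap penalties + E-value constants."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_altschul: tuple[float, float] = (_GAPPED_LAMBDA, _GAPPED_K)

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")
        self._matrix = substitution_matrices.load(self.matrix_name)

    @property
    def matrix(self):
        return self._matrix

    def make_aligner(self, mode: str) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = self._matrix
        aligner.open_gap_score = -float(self.gap_open) - float(self.gap_extend)
        aligner.extend_gap_score = -float(self.gap_extend)
        aligner.mode = mode
        return aligner


@dataclass
class ScreenConfig:
    """Homolog acceptance thresholds."""

    evalue_max: float = 1e-7
    identity_min_pct: float = 20.0
    database_size_aa: int | None = None  # None -> summed proteome length
    identity_over_query: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.identity_min_pct <= 100):
            raise ValueError("identity_min_pct must be in [0, 100]")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")


@dataclass
class AlignmentResult:
    query_id: str
    target_id: str
    score: float
    identity_pct: float
    aligned_cols: int
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    evalue: float


@dataclass
class HomologHit:
    """An alignment that survived the screen thresholds."""

    alignment: AlignmentResult
    genome_accession: str
    locus_tag: str
    role_hypothesis: str  # LanA | LanB | LanC (inherited from the driver)

    @property
    def evalue(self) -> float:
        return self.alignment.evalue

    @property
    def identity_pct(self) -> float:
        return self.alignment.identity_pct


def _validate(seq: str, name: str) -> None:
    bad = set(seq.upper()) - _AA
    if bad:
        raise ValueError(
            f"illegal amino-acid symbol {sorted(bad)[0]!r} in {name}"
        )


def align_pair(
    a: ProteinRecord,
    b: ProteinRecord,
    s: ScoringScheme | None = None,
    mode: str = "local",
    database_size_aa: int | None = None,
) -> AlignmentResult:
    """Optimal pairwise alignment of two proteins.

    ``identity_pct`` = 100 × identical columns / total alignment columns
    (gap columns included in the denominator; X-X never identical). The
    E-value uses Karlin–Altschul statistics with ``database_size_aa`` as the
    search-space second dimension (defaults to len(b)).
    """
    if s is None:
        s = ScoringScheme()
    if mode not in ("local", "global"):
        raise ValueError("mode must be 'local' or 'global'")
    _validate(a.sequence, a.id)
    _validate(b.sequence, b.id)
    aligner = s.make_aligner(mode)
    aln = aligner.align(a.sequence, b.sequence)[0]
    row_q, row_t = str(aln[0]), str(aln[1])
    ident = 0
    cols = len(row_q)
    for x, y in zip(row_q, row_t):
        if x == y and x != "-" and x != "X":
            ident += 1
    identity_pct = 100.0 * ident / cols if cols else 0.0
    qs = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])) \
        if len(aln.aligned[0]) else (0, 0)
    ts = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])) \
        if len(aln.aligned[1]) else (0, 0)
    n = database_size_aa if database_size_aa is not None else len(b.sequence)
    lam, k = s.karlin_altschul
    evalue = k * len(a.sequence) * n * math.exp(-lam * aln.score)
    return AlignmentResult(
        query_id=a.id,
        target_id=b.id,
        score=float(aln.score),
        identity_pct=round(identity_pct, 1),
        aligned_cols=cols,
        query_span=qs,
        target_span=ts,
        evalue=evalue,
    )


def screen_proteome(
    driver: ProteinRecord,
    proteome: list[ProteinRecord],
    s: ScoringScheme | None = None,
    cfg: ScreenConfig | None = None,
    role_hypothesis: str = "LanC",
) -> list[HomologHit]:
    """All and only the targets passing the screen thresholds.

    Hits are sorted by ascending E-value (ties by target id). Identity is
    strict ("greater than"), matching the screen's acceptance wording.
    """
    if not proteome:
        raise ValueError("empty proteome")
    if s is None:
        s = ScoringScheme()
    if cfg is None:
        cfg = ScreenConfig()
    db = cfg.database_size_aa
    if db is None:
        db = sum(len(p.sequence) for p in proteome)
    hits: list[HomologHit] = []
    for target in proteome:
        res = align_pair(driver, target, s, mode="local", database_size_aa=db)
        ident = res.identity_pct
        if cfg.identity_over_query:
            ident = (
                res.identity_pct * res.aligned_cols / len(driver.sequence)
                if len(driver.sequence)
                else 0.0
            )
        if res.evalue <= cfg.evalue_max and ident > cfg.identity_min_pct:
            acc, tag = (
                target.source
                if isinstance(target.source, tuple)
                else ("external", target.id)
            )
            hits.append(
                HomologHit(
                    alignment=res,
                    genome_accession=acc,
                    locus_tag=tag,
                    role_hypothesis=role_hypothesis,
                )
            )
    hits.sort(key=lambda h: (h.evalue, h.locus_tag))
    return hits


def iterative_expand(
    seed_drivers: list[tuple[ProteinRecord, str]],
    genomes: list[GenomeRecord],
    s: ScoringScheme | None = None,
    cfg: ScreenConfig | None = None,
    max_rounds: int = 5,
) -> tuple[list[HomologHit], int]:
    """Screen iteratively, promoting each round's new hits to drivers.

    ``seed_drivers`` pairs each driver with its role hypothesis. Round r
    screens every genome proteome with the proteins first found in round
    r−1; iteration stops when a round adds no new (accession, locus_tag) or
    ``max_rounds`` is reached. Returns the deduplicated union of hits and the
    number of rounds actually used.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    if s is None:
        s = ScoringScheme()
    if cfg is None:
        cfg = ScreenConfig()
    proteomes = [(g, extract_proteome(g)) for g in genomes]
    by_tag: dict[tuple[str, str], ProteinRecord] = {}
    for g, prot in proteomes:
        for p in prot:
            by_tag[(g.accession, p.id)] = p
    seen: dict[tuple[str, str], HomologHit] = {}
    drivers = list(seed_drivers)
    used_driver_seqs = {p.sequence for p, _ in drivers}
    rounds_used = 0
    for _ in range(max_rounds):
        rounds_used += 1
        new_keys: list[tuple[str, str]] = []
        for driver, role in drivers:
            for g, proteome in proteomes:
                if not proteome:
                    continue
                for hit in screen_proteome(driver, proteome, s, cfg, role):
                    key = (hit.genome_accession, hit.locus_tag)
                    if key not in seen:
                        seen[key] = hit
                        new_keys.append(key)
        if not new_keys:
            break
        drivers = []
        for k in new_keys:
            if k not in by_tag:
                continue
            p = by_tag[k]
            if p.sequence in used_driver_seqs:
                continue  # identical to a driver already screened
            used_driver_seqs.add(p.sequence)
            drivers.append((p, seen[k].role_hypothesis))
        if not drivers:
            break
    hits = sorted(
        seen.values(), key=lambda h: (h.genome_accession, h.locus_tag)
    )
    return hits, rounds_used
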