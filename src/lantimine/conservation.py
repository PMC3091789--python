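"""Reference-anchored motif and residue conservation over protein MSAs.

Conservation of functional motifs (e.g. the zinc-ligand CHG of lanthionine
cyclases, or the WCYG motif essential for nisin/subtilin biosynthesis) is
reported as the percentage of aligned sequences carrying the motif at the
alignment columns occupied by a *reference* protein's residues, with motif
positions quoted in the reference's own 1-based numbering (the NisB/NisC
convention for type 1 lantibiotic enzymes).

The builtin aligner is a progressive multiple aligner: a neighbor-joining
guide tree on k-mer distances, with profile–profile steps by global
affine-gap dynamic programming under BLOSUM62. An external adapter accepts
any pre-aligned FASTA instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import ProteinRecord
from .homology import ScoringScheme


@dataclass
class Msa:
    """A multiple sequence alignment: rows of equal-length gapped sequences."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an MSA needs at least 2 rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError("MSA rows differ in length")
        ids = [i for i, _ in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sequence ids in MSA")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def row(self, seq_id: str) -> str:
        for i, s in self.rows:
            if i == seq_id:
                return s
        raise KeyError(seq_id)

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")


@dataclass
class MotifDefinition:
    """A motif pattern anchored to reference residue numbering.

    ``pattern`` uses amino-acid letters plus the wildcard 'x';
    ``reference_start``/``reference_end`` are 1-based inclusive positions in
    the reference protein, and must span exactly ``len(pattern)`` residues.
    """

    name: str
    pattern: str
    reference_id: str
    reference_start: int
    reference_end: int

    def __post_init__(self) -> None:
        if len(self.pattern) != self.reference_end - self.reference_start + 1:
            raise ValueError(
                f"pattern {self.pattern!r} length != reference span "
                f"{self.reference_start}-{self.reference_end}"
            )


@dataclass
class ConservationEntry:
    name: str
    pattern: str
    reference_start: int
    reference_end: int
    percent_conserved: int
    n_sequences: int
    per_letter: dict[str, int] = field(default_factory=dict)


@dataclass
class ConservationTable:
    entries: list[ConservationEntry]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "motif": e.name,
                    "pattern": e.pattern,
                    "reference_position": (
                        f"{e.reference_start}"
                        if e.reference_start == e.reference_end
                        else f"{e.reference_start}-{e.reference_end}"
                    ),
                    "percent_conserved": e.percent_conserved,
                    "n_sequences": e.n_sequences,
                }
                for e in self.entries
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class ReferenceMap:
    """Bidirectional map between alignment columns and reference residues."""

    reference_id: str
    column_to_residue: list[int]  # 0 where reference has a gap

    def column_of(self, residue_number: int) -> int:
        """Alignment column (0-based) of a 1-based reference residue."""
        for col, res in enumerate(self.column_to_residue):
            if res == residue_number:
                return col
        raise IndexError(
            f"reference residue {residue_number} beyond reference length"
        )


# --------------------------------------------------------------------------
# builtin progressive aligner


def _pairwise_gapped(a: str, b: str, s: ScoringScheme) -> tuple[str, str]:
    aligner = s.make_aligner("global")
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 0.0 if a == b else 1.0
    ka = {a[i: i + k] for i in range(len(a) - k + 1)}
    kb = {b[i: i + k] for i in range(len(b) - k + 1)}
    shared = len(ka & kb)
    return 1.0 - shared / min(len(ka), len(kb))


_PROFILE_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """Per-column symbol counts over the 21-letter profile alphabet."""
    idx = {c: k for k, c in enumerate(_PROFILE_ALPHABET)}
    out = np.zeros((len(rows[0]), len(_PROFILE_ALPHABET)))
    for row in rows:
        for col, c in enumerate(row):
            if c != "-":
                out[col, idx.get(c, idx["X"])] += 1
    return out


def _profile_align(
    pa: list[str], pb: list[str], s: ScoringScheme
) -> tuple[list[str], list[str]]:
    """Global affine-gap DP between two profiles (lists of gapped rows).

    Column–column score is the average substitution score over all residue
    pairs (gap characters contribute 0).
    """
    mat = s.matrix
    la, lb = len(pa[0]), len(pb[0])
    na, nb = len(pa), len(pb)
    sub = np.array(
        [
            [mat[x, y] for y in _PROFILE_ALPHABET]
            for x in _PROFILE_ALPHABET
        ],
        dtype=float,
    )
    fa = _profile_freqs(pa)
    fb = _profile_freqs(pb)
    colscores = fa @ sub @ fb.T / (na * nb)  # (la, lb)

    go = -(float(s.gap_open) + float(s.gap_extend))
    ge = -float(s.gap_extend)
    NEG = -1e30
    # M/X/Y affine DP; X = gap in profile B (consume A), Y = gap in A
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)
    Y = np.full((la + 1, lb + 1), NEG)
    M[0, 0] = 0.0
    X[1:, 0] = go + ge * np.arange(la)
    Y[0, 1:] = go + ge * np.arange(lb)
    for i in range(1, la + 1):
        M[i, 1:] = (
            np.maximum.reduce([M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]])
            + colscores[i - 1]
        )
        X[i, 1:] = np.maximum(M[i - 1, 1:] + go, X[i - 1, 1:] + ge)
        X[i, 0] = go + ge * (i - 1)
        y_prev = Y[i, 0]
        m_row = M[i]
        y_row = Y[i]
        for j in range(1, lb + 1):
            y_prev = max(m_row[j - 1] + go, y_prev + ge)
            y_row[j] = y_prev
    # traceback (prefer M, then X, then Y for determinism)
    out_a: list[list[str]] = [[] for _ in range(na)]
    out_b: list[list[str]] = [[] for _ in range(nb)]
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    while i > 0 or j > 0:
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        if state == 0:
            state = int(
                np.argmax([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]])
            )
            for r in range(na):
                out_a[r].append(pa[r][i - 1])
            for r in range(nb):
                out_b[r].append(pb[r][j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            # consume a column of A, gap in B
            state = 0 if M[i - 1, j] + go >= X[i - 1, j] + ge else 1
            for r in range(na):
                out_a[r].append(pa[r][i - 1])
            for r in range(nb):
                out_b[r].append("-")
            i -= 1
        else:
            state = 0 if M[i, j - 1] + go >= Y[i, j - 1] + ge else 2
            for r in range(na):
                out_a[r].append("-")
            for r in range(nb):
                out_b[r].append(pb[r][j - 1])
            j -= 1
    return (
        ["".join(reversed(r)) for r in out_a],
        ["".join(reversed(r)) for r in out_b],
    )


def _guide_order(
    seqs: list[ProteinRecord],
) -> list[tuple[list[int], list[int]]]:
    """Merge order for progressive alignment from an NJ guide tree."""
    from .phylo import DistanceMatrix, nj_tree

    n = len(seqs)
    ids = [p.id for p in seqs]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(
                seqs[i].sequence, seqs[j].sequence
            )
    tree = nj_tree(DistanceMatrix(ids=ids, d=d))
    index = {p.id: k for k, p in enumerate(seqs)}
    merges: list[tuple[list[int], list[int]]] = []

    def collect(node) -> list[int]:
        if node.is_tip():
            return [index[node.name]]
        groups = [collect(ch) for ch in node.children]
        acc = groups[0]
        for g in groups[1:]:
            merges.append((list(acc), list(g)))
            acc = acc + g
        return acc

    collect(tree)
    return merges


def build_msa(
    seqs: list[ProteinRecord],
    aligner: str = "builtin",
    aligned_fasta: str | Path | None = None,
    scoring: ScoringScheme | None = None,
) -> Msa:
    """Multiple alignment of protein sequences.

    ``aligner="builtin"`` runs the progressive aligner; ``"external"`` reads
    ``aligned_fasta`` (produced by any MSA tool) and checks that ungapping
    recovers the inputs.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [p.id for p in seqs]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids")
    if aligner == "external":
        if aligned_fasta is None:
            raise ValueError("external aligner requires aligned_fasta")
        return read_aligned_fasta(aligned_fasta)
    if aligner != "builtin":
        raise ValueError(f"unknown aligner {aligner!r}")
    scoring = scoring or ScoringScheme()
    if len(seqs) == 2:
        ga, gb = _pairwise_gapped(seqs[0].sequence, seqs[1].sequence, scoring)
        return Msa(rows=[(seqs[0].id, ga), (seqs[1].id, gb)])
    profiles: dict[int, str] = {}
    aligned: dict[int, str] = {i: p.sequence for i, p in enumerate(seqs)}
    for group_a, group_b in _guide_order(seqs):
        pa = [aligned[i] for i in group_a]
        pb = [aligned[i] for i in group_b]
        # pad within-group rows to equal length is guaranteed by construction
        new_a, new_b = _profile_align(pa, pb, scoring)
        for idx, row in zip(group_a, new_a):
            aligned[idx] = row
        for idx, row in zip(group_b, new_b):
            aligned[idx] = row
    # after the final merge every row has equal length
    return Msa(rows=[(p.id, aligned[i]) for i, p in enumerate(seqs)])


def read_aligned_fasta(path: str | Path) -> Msa:
    from Bio import SeqIO

    rows = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return Msa(rows=rows)


def write_aligned_fasta(m: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, row in m.rows:
            fh.write(f">{seq_id}\n{row}\n")


# --------------------------------------------------------------------------
# conservation


def map_to_reference(m: Msa, reference_id: str) -> ReferenceMap:
    """Column ↔ reference-residue map for the chosen reference row."""
    ref = m.row(reference_id)
    col2res: list[int] = []
    count = 0
    for c in ref:
        if c != "-":
            count += 1
            col2res.append(count)
        else:
            col2res.append(0)
    return ReferenceMap(reference_id=reference_id, column_to_residue=col2res)


def motif_conservation(
    m: Msa, defs: list[MotifDefinition]
) -> ConservationTable:
    """Percent of rows carrying each motif at the reference's columns.

    A row contains the motif iff its characters at the non-wildcard columns
    equal the pattern letters; percentages are over *all* rows (reference
    included) and rounded to the nearest integer. A per-letter breakdown is
    reported for partially conserved motifs.
    """
    entries: list[ConservationEntry] = []
    n = len(m.rows)
    for d in defs:
        ref_map = map_to_reference(m, d.reference_id)
        cols = [
            ref_map.column_of(p)
            for p in range(d.reference_start, d.reference_end + 1)
        ]
        checked = [
            (c, letter.upper())
            for c, letter in zip(cols, d.pattern)
            if letter.lower() != "x"
        ]
        full = 0
        per_letter_counts: dict[str, int] = {}
        for _, row in m.rows:
            ok = all(row[c] == letter for c, letter in checked)
            full += ok
            for c, letter in checked:
                key = f"{letter}{ref_map.column_to_residue[c]}"
                per_letter_counts[key] = per_letter_counts.get(key, 0) + (
                    row[c] == letter
                )
        entries.append(
            ConservationEntry(
                name=d.name,
                pattern=d.pattern,
                reference_start=d.reference_start,
                reference_end=d.reference_end,
                percent_conserved=round(100 * full / n),
                n_sequences=n,
                per_letter={
                    k: round(100 * v / n)
                    for k, v in per_letter_counts.items()
                },
            )
        )
    return ConservationTable(entries=entries)


def residue_conservation(
    m: Msa,
    reference_id: str,
    reference_positions: list[tuple[str, int]],
) -> ConservationTable:
    """Single-residue conservation at reference positions.

    ``reference_positions`` is a list of (expected letter, 1-based reference
    position) pairs.
    """
    defs = [
        MotifDefinition(
            name=f"{letter}{pos}",
            pattern=letter,
            reference_id=reference_id,
            reference_start=pos,
            reference_end=pos,
        )
        for letter, pos in reference_positions
    ]
    return motif_conservation(m, defs)
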