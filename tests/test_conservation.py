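"""MSA construction and reference-anchored conservation percentages."""

import pytest
from hypothesis import given, settings, strategies as st
from Bio import Align
from Bio.Align import substitution_matrices

from lantimine.conservation import (
    Msa,
    MotifDefinition,
    build_msa,
    map_to_reference,
    motif_conservation,
    residue_conservation,
)
from lantimine.genome_io import ProteinRecord
from lantimine.homology import ScoringScheme
from lantimine.templates import load_motif_definitions


def _recs(*seqs):
    return [ProteinRecord(id=f"s{i}", sequence=s)
            for i, s in enumerate(seqs)]


def test_identical_sequences_align_gap_free():
    m = build_msa(_recs("MKLVINS", "MKLVINS"))
    assert m.rows[0][1] == m.rows[1][1] == "MKLVINS"


def test_single_deletion_produces_one_gap_column():
    m = build_msa(_recs("ACDEFG", "ACEFG"))
    assert m.rows[0][1] == "ACDEFG"
    assert m.rows[1][1].count("-") == 1
    matches = sum(
        a == b for a, b in zip(m.rows[0][1], m.rows[1][1])
    )
    assert matches == 5


def test_pairwise_msa_score_equals_dp_oracle():
    """The 2-sequence builtin alignment is the optimal global alignment."""
    a, b = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ", "MKTAYIAKQRQISFVKSHFSRQ"
    s = ScoringScheme()
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    expected = aligner.align(a, b).score
    m = build_msa(_recs(a, b), scoring=s)
    mat = substitution_matrices.load("BLOSUM62")
    score, in_gap = 0.0, False
    for x, y in zip(m.rows[0][1], m.rows[1][1]):
        if x == "-" or y == "-":
            score += -1 if in_gap else -12
            in_gap = True
        else:
            score += mat[x, y]
            in_gap = False
    assert score == expected


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.lists(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=25),
        min_size=2, max_size=5, unique=True,
    )
)
def test_ungapping_recovers_inputs(seqs):
    recs = _recs(*seqs)
    m = build_msa(recs)
    for rec in recs:
        assert m.ungapped(rec.id) == rec.sequence


def test_map_to_reference_gap_free_and_leading_gap():
    m = Msa(rows=[("ref", "MKLV"), ("o", "MKLV")])
    rmap = map_to_reference(m, "ref")
    assert [rmap.column_of(i + 1) for i in range(4)] == [0, 1, 2, 3]
    m2 = Msa(rows=[("ref", "--LV"), ("o", "MKLV")])
    rmap2 = map_to_reference(m2, "ref")
    assert rmap2.column_of(1) == 2
    # cumulative-sum oracle on an arbitrary gapped row
    row = "-A-BC--D"
    m3 = Msa(rows=[("ref", row), ("o", "XXXXXXXX")])
    rmap3 = map_to_reference(m3, "ref")
    count = 0
    for col, ch in enumerate(row):
        if ch != "-":
            count += 1
            assert rmap3.column_of(count) == col


TOY = Msa(
    rows=[
        ("NisC", "ACHGLM"),
        ("r2", "ACHGLM"),
        ("r3", "TCHGLM"),
        ("r4", "GCHGIM"),
    ]
)


def test_motif_conservation_hand_counts():
    chg = MotifDefinition("CHG", "CHG", "NisC", 2, 4)
    table = motif_conservation(TOY, [chg])
    assert table.entries[0].percent_conserved == 100
    mutated = Msa(
        rows=[TOY.rows[0], TOY.rows[1], TOY.rows[2],
              ("r4", "GAHGIM")]  # C -> A at the anchor column
    )
    table2 = motif_conservation(mutated, [chg])
    assert table2.entries[0].percent_conserved == 75


def test_residue_conservation_hand_count():
    rows = [("ref", "ML")] + [(f"r{i}", "ML") for i in range(8)]
    rows.append(("r9", "MV"))
    m = Msa(rows=rows)
    table = residue_conservation(m, "ref", [("L", 2)])
    assert table.entries[0].percent_conserved == 90
    full = residue_conservation(m, "ref", [("M", 1)])
    assert full.entries[0].percent_conserved == 100


def test_all_wildcard_motif_is_always_conserved():
    d = MotifDefinition("xxx", "xxx", "NisC", 2, 4)
    assert motif_conservation(TOY, [d]).entries[0].percent_conserved == 100


def test_adding_a_carrier_row_never_decreases_percentage():
    chg = MotifDefinition("CHG", "CHG", "NisC", 2, 4)
    base = Msa(rows=[TOY.rows[0], TOY.rows[1], ("bad", "GAAGIM")])
    pct0 = motif_conservation(base, [chg]).entries[0].percent_conserved
    grown = Msa(rows=base.rows + [("new", "ACHGLM")])
    pct1 = motif_conservation(grown, [chg]).entries[0].percent_conserved
    assert pct1 >= pct0


def test_templates_carry_their_motifs(lib):
    """The packaged LanB/LanC exemplars contain every motif at its
    reference coordinate (so they can anchor conservation tables)."""
    for role, rec in (("LanB", lib.lanb), ("LanC", lib.lanc)):
        for d in load_motif_definitions(role, reference_id=rec.id):
            segment = rec.sequence[d.reference_start - 1: d.reference_end]
            for offset, letter in enumerate(d.pattern):
                if letter.lower() != "x":
                    assert segment[offset] == letter
    for a in lib.lanas:
        from lantimine.lana import score_lana

        assert score_lana(a.sequence).passes


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        build_msa(
            [ProteinRecord(id="a", sequence="MKL"),
             ProteinRecord(id="a", sequence="MKV")]
        )
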