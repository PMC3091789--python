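"""Homology screening: alignment identity, E-values, thresholds, expansion."""

import numpy as np
import pytest

from lantimine.genome_io import CdsFeature, GenomeRecord, ProteinRecord
from lantimine.homology import (
    ScreenConfig,
    align_pair,
    iterative_expand,
    screen_proteome,
)
from lantimine.synthetic import mutate_protein

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AA), size=n))


def test_self_alignment_is_identity_100(lib):
    res = align_pair(lib.lanc, lib.lanc, mode="local")
    assert res.identity_pct == 100.0
    assert res.evalue < 1e-100


def test_substitution_only_identity_matches_hamming_oracle():
    """Global identity on an indel-free pair equals the Hamming fraction."""
    rng = np.random.default_rng(42)
    seq = _random_protein(100, 1)
    chars = list(seq)
    sites = rng.choice(100, size=30, replace=False)
    for i in sites:
        choices = [c for c in AA if c != chars[i]]
        chars[i] = choices[int(rng.integers(len(choices)))]
    mutant = "".join(chars)
    hamming_ident = 100.0 * sum(a == b for a, b in zip(seq, mutant)) / 100
    assert hamming_ident == 70.0
    res = align_pair(
        ProteinRecord(id="a", sequence=seq),
        ProteinRecord(id="b", sequence=mutant),
        mode="global",
    )
    assert res.identity_pct == pytest.approx(70.0, abs=1.0)


@pytest.mark.parametrize("mode", ["local", "global"])
def test_alignment_symmetry(mode):
    a = ProteinRecord(id="a", sequence=_random_protein(80, 7))
    b = ProteinRecord(id="b", sequence=_random_protein(90, 8))
    r1 = align_pair(a, b, mode=mode, database_size_aa=1000)
    r2 = align_pair(b, a, mode=mode, database_size_aa=1000)
    assert r1.score == r2.score
    assert r1.identity_pct == pytest.approx(r2.identity_pct, abs=0.1)


def test_illegal_symbol_is_named():
    with pytest.raises(ValueError, match="'J'"):
        align_pair(
            ProteinRecord(id="a", sequence="MKJL"),
            ProteinRecord(id="b", sequence="MKLL"),
        )


def test_screen_matches_exhaustive_oracle(lib):
    """screen_proteome returns exactly the thresholds-passing targets."""
    driver = lib.lanc
    proteome = [
        ProteinRecord(
            id=f"hom", sequence=mutate_protein(driver.sequence, 40, seed=3),
            source=("G1", "hom"),
        )
    ] + [
        ProteinRecord(
            id=f"decoy{i}", sequence=_random_protein(300, 100 + i),
            source=("G1", f"decoy{i}"),
        )
        for i in range(50)
    ]
    cfg = ScreenConfig()
    hits = screen_proteome(driver, proteome, cfg=cfg)
    assert [h.locus_tag for h in hits] == ["hom"]
    # independent oracle: align every target, apply the thresholds manually
    db = sum(len(p.sequence) for p in proteome)
    expected = set()
    for t in proteome:
        r = align_pair(driver, t, mode="local", database_size_aa=db)
        if r.evalue <= cfg.evalue_max and r.identity_pct > cfg.identity_min_pct:
            expected.add(t.id)
    assert {h.locus_tag for h in hits} == expected
    evs = [h.evalue for h in hits]
    assert evs == sorted(evs)


def test_identity_threshold_100_keeps_only_duplicates(lib):
    driver = lib.lanas[1]
    proteome = [
        ProteinRecord(id="dup", sequence=driver.sequence,
                      source=("G", "dup")),
        ProteinRecord(
            id="near", sequence=mutate_protein(driver.sequence, 90, seed=1),
            source=("G", "near"),
        ),
    ]
    hits = screen_proteome(
        driver, proteome, cfg=ScreenConfig(identity_min_pct=99.9)
    )
    assert [h.locus_tag for h in hits] == ["dup"]


def test_threshold_monotonicity(lib):
    """Loosening either threshold never removes a hit."""
    driver = lib.lanc
    proteome = [
        ProteinRecord(
            id=f"m{t}", sequence=mutate_protein(driver.sequence, t, seed=t),
            source=("G", f"m{t}"),
        )
        for t in (30, 50, 70, 90)
    ]
    tight = {
        h.locus_tag
        for h in screen_proteome(
            driver, proteome, cfg=ScreenConfig(evalue_max=1e-20,
                                               identity_min_pct=40.0)
        )
    }
    loose = {
        h.locus_tag
        for h in screen_proteome(
            driver, proteome, cfg=ScreenConfig(evalue_max=1e-5,
                                               identity_min_pct=20.0)
        )
    }
    assert tight <= loose


def _chain_genome():
    """Three proteins where A~B and B~C share domains but A and C do not."""
    x = _random_protein(100, 21)
    w = _random_protein(100, 22)
    z = _random_protein(100, 23)
    y = _random_protein(100, 24)
    a = x + y
    b = mutate_protein(x, 90, seed=25) + w
    c = mutate_protein(w, 90, seed=26) + z
    feats = [
        CdsFeature("A", 0, 603, 1, a),
        CdsFeature("B", 700, 1303, 1, b),
        CdsFeature("C", 1400, 2003, 1, c),
    ]
    return GenomeRecord(accession="CHAIN", sequence="A" * 2100, features=feats)


def test_iterative_expand_reaches_transitive_homolog():
    """A two-step homology chain is only closed by the second round."""
    g = _chain_genome()
    a = ProteinRecord(id="seedA", sequence=g.features[0].translation)
    # direct screen from A finds B but not C
    hits1, rounds1 = iterative_expand([(a, "LanC")], [g], max_rounds=1)
    tags1 = {h.locus_tag for h in hits1}
    assert "B" in tags1 and "C" not in tags1
    hits2, rounds2 = iterative_expand([(a, "LanC")], [g], max_rounds=5)
    tags2 = {h.locus_tag for h in hits2}
    assert "C" in tags2
    assert rounds2 >= 2
    # monotone: more rounds never lose hits
    assert tags1 <= tags2


def test_iterative_expand_fixed_point(lib):
    """Once every reachable homolog is found the hit set is stable."""
    seq = lib.lanc.sequence
    feats = [
        CdsFeature("t1", 0, 1263, 1, seq),
        CdsFeature("t2", 1300, 2563, 1, mutate_protein(seq, 80, seed=9)),
    ]
    g = GenomeRecord(accession="FP", sequence="A" * 2600, features=feats)
    hits_a, _ = iterative_expand([(lib.lanc, "LanC")], [g], max_rounds=1)
    hits_b, _ = iterative_expand([(lib.lanc, "LanC")], [g], max_rounds=6)
    assert {h.locus_tag for h in hits_a} == {h.locus_tag for h in hits_b}
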