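"""Packaged exemplar proteins and motif tables.

Real LanB/LanC/accessory sequences cannot be shipped, so the exemplars here
are *synthetic*: deterministic random proteins with the canonical conserved
motifs of lanthionine dehydratases (LanB) and cyclases (LanC) planted at
their published NisB/NisC reference coordinates, plus short precursor
(LanA) exemplars with a DLD-bearing leader and an S/T/C-rich propeptide.
They serve as screen drivers, mutation templates for the synthetic-genome
generator, and reference rows for motif-conservation analysis. The only
real sequence in the package is the published 57-aa nisin A prepropeptide
(``data/nisa.faa``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .conservation import MotifDefinition
from .genome_io import ProteinRecord

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NO_STC = "ADEFGHIKLMNPQRVWY"  # residues outside the S/T/C heuristic

_TEMPLATE_SEED = 7919


def _data_text(name: str) -> str:
    return (
        resources.files("lantimine.data").joinpath(name).read_text()
    )


def load_motif_definitions(
    role: str, reference_id: str | None = None, kind: str | None = None
) -> list[MotifDefinition]:
    """Packaged motif tables for LanB (NisB numbering) or LanC (NisC).

    ``kind`` filters to "motif" (multi-residue) or "residue" (single
    residues); ``reference_id`` overrides the default reference row name.
    """
    fname = {"LanB": "lanb_motifs.tsv", "LanC": "lanc_motifs.tsv"}[role]
    default_ref = {"LanB": "NisB", "LanC": "NisC"}[role]
    ref = reference_id or default_ref
    import io

    df = pd.read_csv(io.StringIO(_data_text(fname)), sep="\t")
    if kind is not None:
        df = df[df["kind"] == kind]
    return [
        MotifDefinition(
            name=r["name"],
            pattern=r["pattern"],
            reference_id=ref,
            reference_start=int(r["ref_start"]),
            reference_end=int(r["ref_end"]),
        )
        for _, r in df.iterrows()
    ]


def nisa_prepropeptide() -> ProteinRecord:
    """The published 57-aa nisin A prepropeptide (leader 23 aa)."""
    lines = _data_text("nisa.faa").strip().splitlines()
    return ProteinRecord(id="NisA", sequence="".join(lines[1:]))


NISA_LEADER_LENGTH = 23


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def _plant_motifs(seq: str, defs: list[MotifDefinition]) -> str:
    chars = list(seq)
    for d in defs:
        for offset, letter in enumerate(d.pattern):
            if letter.lower() == "x":
                continue
            chars[d.reference_start - 1 + offset] = letter.upper()
    return "".join(chars)


def motif_positions(role: str) -> set[int]:
    """0-based template positions covered by non-wildcard motif letters."""
    out: set[int] = set()
    for d in load_motif_definitions(role):
        for offset, letter in enumerate(d.pattern):
            if letter.lower() != "x":
                out.add(d.reference_start - 1 + offset)
    return out


def _build_lanb(rng: np.random.Generator) -> ProteinRecord:
    seq = _plant_motifs(
        random_protein(1020, rng), load_motif_definitions("LanB")
    )
    return ProteinRecord(id="LanB_ref", sequence=seq)


def _build_lanc(rng: np.random.Generator) -> ProteinRecord:
    seq = _plant_motifs(
        random_protein(420, rng), load_motif_definitions("LanC")
    )
    return ProteinRecord(id="LanC_ref", sequence=seq)


def _build_lana(rng: np.random.Generator, ident: str) -> ProteinRecord:
    """A synthetic type 1 precursor: DLD leader + S/T/C-rich propeptide."""
    leader = list(rng.choice(list(_NO_STC), size=24))
    leader[7:10] = list("DLD")
    prop = []
    stc = list("STC")
    for _ in range(36):
        if rng.random() < 0.38:
            prop.append(str(rng.choice(stc)))
        else:
            prop.append(str(rng.choice(list(_NO_STC))))
    prop[5:10] = list("CTPGC")  # lipid II-binding-like propeptide motif
    seq = "M" + "".join(leader[1:]) + "".join(prop)
    return ProteinRecord(id=ident, sequence=seq)


_ACCESSORY_LENGTHS = {
    "LanT": 580,
    "LanP": 460,
    "LanE": 240,
    "LanF": 230,
    "LanG": 240,
    "LanK": 440,
    "LanR": 220,
    "LanD": 180,
    "OMT": 260,
}


@dataclass
class TemplateLibrary:
    """The deterministic synthetic exemplar set.

    Invariants (tested): the LanB/LanC templates contain every packaged
    motif at its reference position; every LanA template passes the
    precursor heuristic at default thresholds.
    """

    lanb: ProteinRecord
    lanc: ProteinRecord
    lanas: list[ProteinRecord]
    accessory: dict[str, ProteinRecord]

    @classmethod
    def default(cls) -> "TemplateLibrary":
        rng = np.random.default_rng(_TEMPLATE_SEED)
        lanb = _build_lanb(rng)
        lanc = _build_lanc(rng)
        lanas = [
            nisa_prepropeptide(),
            _build_lana(rng, "LanA_syn1"),
            _build_lana(rng, "LanA_syn2"),
        ]
        accessory = {
            role: ProteinRecord(
                id=f"{role}_ex", sequence=random_protein(length, rng)
            )
            for role, length in _ACCESSORY_LENGTHS.items()
        }
        return cls(lanb=lanb, lanc=lanc, lanas=lanas, accessory=accessory)

    def drivers(self) -> list[tuple[ProteinRecord, str]]:
        """Default screen drivers with their role hypotheses."""
        return [
            (self.lanc, "LanC"),
            (self.lanb, "LanB"),
            (self.lanas[1], "LanA"),
        ]

    def protected_positions(self, role: str, sequence: str) -> set[int]:
        """Positions to protect when mutating a planted copy of ``role``.

        LanB/LanC protect their motif columns; LanA protects the start Met,
        the leader DLD and every propeptide S/T/C (the composition the
        precursor heuristic relies on).
        """
        if role in ("LanB", "LanC"):
            return {p for p in motif_positions(role) if p < len(sequence)}
        if role == "LanA":
            protected = {0}
            k = max(10, len(sequence) // 3)
            dld = sequence.find("DLD")
            if dld != -1:
                protected |= {dld, dld + 1, dld + 2}
            for i, c in enumerate(sequence):
                if i >= k and c in "STC":
                    protected.add(i)
            return protected
        return set()
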