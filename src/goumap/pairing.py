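"""Base-opposition classification at stem and tertiary positions.

Orientation matters: structurally a GoU pair is not a UoG pair, so the
class of an opposition is a pure function of the *ordered* base pair,
with the first base taken from the strand carrying the lower Sprinzl
number (the 5' strand of the stem as drawn in cloverleaf diagrams).
Pseudouridine is not modelled; U stands for U or Psi, since the
modification does not prevent wobble pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .genes import TRNAGene
from .sprinzl import (
    STEM_PAIRS,
    PairPosition,
    TERTIARY_CATALOGUE,
    TertiaryPosition,
)

#: IUPAC degenerate nucleotide codes over the RNA alphabet.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "U": frozenset("U"),
    "R": frozenset("AG"), "Y": frozenset("CU"), "S": frozenset("CG"),
    "W": frozenset("AU"), "K": frozenset("GU"), "M": frozenset("AC"),
    "B": frozenset("CGU"), "D": frozenset("AGU"), "H": frozenset("ACU"),
    "V": frozenset("ACG"), "N": frozenset("ACGU"),
}


class PairClass(Enum):
    """Class of one ordered base opposition."""

    WC_GC = "G=C"
    WC_CG = "C=G"
    WC_AU = "A-U"
    WC_UA = "U-A"
    WOBBLE_GU = "GoU"
    WOBBLE_UG = "UoG"
    OTHER = "other"
    UNDEFINED = "undefined"

    @property
    def is_watson_crick(self) -> bool:
        return self in _WC_CLASSES

    @property
    def is_wobble(self) -> bool:
        return self in (PairClass.WOBBLE_GU, PairClass.WOBBLE_UG)


_WC_CLASSES = frozenset(
    {PairClass.WC_GC, PairClass.WC_CG, PairClass.WC_AU, PairClass.WC_UA}
)

_PAIR_TABLE: dict[tuple[str, str], PairClass] = {
    ("G", "C"): PairClass.WC_GC,
    ("C", "G"): PairClass.WC_CG,
    ("A", "U"): PairClass.WC_AU,
    ("U", "A"): PairClass.WC_UA,
    ("G", "U"): PairClass.WOBBLE_GU,
    ("U", "G"): PairClass.WOBBLE_UG,
}

_VALID = frozenset("ACGUN-")


def classify_pair(base5: str | None, base3: str | None) -> PairClass:
    """Classify the ordered opposition (5' base, 3' base).

    Watson-Crick and wobble classes keep their orientation (G,U) ->
    WOBBLE_GU versus (U,G) -> WOBBLE_UG; every other concrete base pair
    (e.g. C,A or G,G) is OTHER; a gap, N or missing residue on either
    side is UNDEFINED.
    """
    if base5 is None:
        base5 = "-"
    if base3 is None:
        base3 = "-"
    if base5 not in _VALID or base3 not in _VALID:
        raise ValueError(f"unknown base character in pair ({base5!r}, {base3!r})")
    if base5 in "N-" or base3 in "N-":
        return PairClass.UNDEFINED
    return _PAIR_TABLE.get((base5, base3), PairClass.OTHER)


@dataclass(frozen=True)
class TertiaryObservation:
    position: TertiaryPosition
    bases: tuple[str | None, ...]
    ok: bool


@dataclass(frozen=True)
class GenePairProfile:
    """Per-gene classification of all 21 canonical stem positions plus the
    tertiary-contact report."""

    gene_id: str
    pairs: Mapping[PairPosition, PairClass]
    tertiary: Mapping[str, TertiaryObservation]

    def bases_at(self, gene: TRNAGene, position: PairPosition) -> tuple[str | None, str | None]:
        return gene.residue(position.pos5), gene.residue(position.pos3)


def profile_gene(gene: TRNAGene) -> GenePairProfile:
    """Classify every canonical stem position of *gene* and check the
    tertiary catalogue (purine at 9, U33, the U8:A14/A14:A21 triple, the
    15:48 long-range pair, the trans U54oA58 pair, G18G19, U55, C56).

    Missing residues yield UNDEFINED stem entries; tertiary entries are
    flagged not-ok when a residue deviates from the expectation or is
    absent.
    """
    pairs = {
        pos: classify_pair(gene.residue(pos.pos5), gene.residue(pos.pos3))
        for pos in STEM_PAIRS
    }
    tertiary: dict[str, TertiaryObservation] = {}
    for contact in TERTIARY_CATALOGUE:
        bases = tuple(gene.residue(lab) for lab in contact.labels)
        if contact.name == "15:48":
            # the long-range pair is always G15oC48 or A15oU48
            ok = bases in (("G", "C"), ("A", "U"))
        else:
            ok = all(
                b is not None and b in IUPAC_SETS[exp]
                for b, exp in zip(bases, contact.expected)
            )
        tertiary[contact.name] = TertiaryObservation(contact, bases, ok)
    return GenePairProfile(gene.gene_id, pairs, tertiary)


def profile_all(genes) -> dict[str, GenePairProfile]:
    """Profile a gene collection, keyed by gene id."""
    return {g.gene_id: profile_gene(g) for g in genes}


def match_prefix_motif(gene: TRNAGene, motif: str, start: str) -> bool:
    """True iff the gene's residues, walking 5'->3' from Sprinzl position
    *start* over its occupied positions, match the IUPAC *motif*
    letter-by-letter. The empty motif matches vacuously.
    """
    if not motif:
        return True
    for ch in motif:
        if ch.upper() not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC letter {ch!r} in motif")
    occupied = gene.occupied_labels()
    try:
        i = occupied.index(start)
    except ValueError:
        raise ValueError(f"start position {start!r} not occupied in {gene.gene_id}")
    if i + len(motif) > len(occupied):
        raise ValueError(
            f"motif of length {len(motif)} from {start} extends past mapped "
            f"positions of {gene.gene_id}"
        )
    for off, ch in enumerate(motif):
        base = gene.residue(occupied[i + off])
        if base is None or base not in IUPAC_SETS[ch.upper()]:
            return False
    return True
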