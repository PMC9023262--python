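"""Consensus motifs, the conserved-wobble orientation map and its census.

Genes are grouped at three levels -- isotype (all tRNAs for one amino
acid), isoacceptor set, or isodecoder (one anticodon) -- optionally
restricted to a set of clades that must each independently show the
feature. A wobble orientation (GoU or UoG) at a stem position is called
conserved for a group when the within-clade fraction of genes carrying
that exact orientation reaches the threshold tau in *every* required
clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genes import TRNAGene
from .pairing import IUPAC_SETS, GenePairProfile, PairClass
from .sprinzl import (
    RARE_WOBBLE_POSITIONS,
    PairPosition,
    enumerate_stem_pairs,
    pair_position,
    sprinzl_sort_key,
)

GROUP_LEVELS = ("isotype", "isoacceptor-set", "isodecoder")

#: 5' strand Sprinzl labels per stem, defining motif length and order.
STEM_STRAND_LABELS: dict[str, list[str]] = {
    "AA": [str(i) for i in range(1, 8)],
    "D": [str(i) for i in range(10, 14)],
    "AC": [str(i) for i in range(27, 32)],
    "T": [str(i) for i in range(49, 54)],
}

ORIENTATIONS = ("GoU", "UoG")

_ORIENT_CLASS = {"GoU": PairClass.WOBBLE_GU, "UoG": PairClass.WOBBLE_UG}


@dataclass(frozen=True)
class GroupKey:
    """A gene grouping: level, isotype, optional anticodon (isodecoder
    level only) and the clades that must each show a feature."""

    level: str
    isotype: str
    anticodon: str | None = None
    clades: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.level not in GROUP_LEVELS:
            raise ValueError(f"unknown group level {self.level!r}")
        if self.level == "isodecoder" and not self.anticodon:
            raise ValueError("isodecoder groups require an anticodon")
        if not self.clades:
            raise ValueError("clade scope must be non-empty")

    def matches(self, gene: TRNAGene) -> bool:
        if gene.isotype != self.isotype:
            return False
        if self.level == "isodecoder" and gene.anticodon != self.anticodon:
            return False
        return gene.clade in self.clades

    @property
    def name(self) -> str:
        tag = self.isotype if self.anticodon is None else f"{self.isotype}-{self.anticodon}"
        return f"{tag}[{','.join(sorted(self.clades))}]"


# ---------------------------------------------------------------------------
# IUPAC consensus
# ---------------------------------------------------------------------------

_LETTER_ORDER = "ACGURYSWKMBDHVN"


def consensus_iupac(frequencies: Mapping[str, float], inclusion_floor: float = 0.05) -> str:
    """Smallest IUPAC letter covering every base whose frequency exceeds
    the inclusion floor (e.g. {G: 0.6, U: 0.4} -> K, 'G or U').

    Frequencies are over {A, C, G, U}; bases at or below the floor are
    treated as noise and omitted from the covering set.
    """
    kept = {b for b, f in frequencies.items() if f > inclusion_floor}
    bad = kept - set("ACGU")
    if bad:
        raise ValueError(f"non-RNA base(s) in frequencies: {sorted(bad)}")
    if not kept:
        raise ValueError("no base exceeds the inclusion floor; consensus undefined")
    for letter in _LETTER_ORDER:
        if kept <= IUPAC_SETS[letter]:
            return letter
    raise AssertionError("unreachable: N covers all bases")


@dataclass(frozen=True)
class ConsensusMotif:
    group: GroupKey
    stem: str
    motif: str
    frequencies: tuple[Mapping[str, float], ...]


def _column_frequencies(bases: Sequence[str]) -> dict[str, float]:
    counts: dict[str, int] = {}
    for b in bases:
        counts[b] = counts.get(b, 0) + 1
    total = sum(counts.values())
    return {b: c / total for b, c in counts.items()}


def stem_motifs(
    genes: Sequence[TRNAGene],
    group: GroupKey,
    inclusion_floor: float = 0.05,
    include_variable_arm: bool = True,
) -> list[ConsensusMotif]:
    """Per-stem 5'-strand consensus motifs for the genes matching *group*
    (AA 7, D 4, AC 5, T 5 letters), plus, for long-arm groups, the first
    and last terminal triplets of the variable-arm extension."""
    members = [g for g in genes if group.matches(g)]
    if not members:
        raise ValueError(f"no genes in group {group.name}")
    out: list[ConsensusMotif] = []
    for stem, labels in STEM_STRAND_LABELS.items():
        freqs = []
        letters = []
        for lab in labels:
            bases = [b for g in members if (b := g.residue(lab)) in IUPAC_SETS["N"]]
            if not bases:
                freqs.append({})
                letters.append("N")
                continue
            f = _column_frequencies(bases)
            freqs.append(f)
            letters.append(consensus_iupac(f, inclusion_floor))
        out.append(ConsensusMotif(group, stem, "".join(letters), tuple(freqs)))
    if include_variable_arm:
        arm_labels = sorted(
            {lab for g in members for lab in g.occupied_labels() if lab.startswith("e")},
            key=sprinzl_sort_key,
        )
        if len(arm_labels) >= 6:
            for stem_name, labels in (("V5", arm_labels[:3]), ("V3", arm_labels[-3:])):
                freqs = []
                letters = []
                for lab in labels:
                    bases = [b for g in members if (b := g.residue(lab)) in IUPAC_SETS["N"]]
                    if not bases:
                        freqs.append({})
                        letters.append("N")
                        continue
                    f = _column_frequencies(bases)
                    freqs.append(f)
                    letters.append(consensus_iupac(f, inclusion_floor))
                out.append(ConsensusMotif(group, stem_name, "".join(letters), tuple(freqs)))
    return out


# ---------------------------------------------------------------------------
# Conservation map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConservedEntry:
    group: GroupKey
    position: PairPosition
    orientation: str  # "GoU" | "UoG"
    fraction: float
    n_genes: int
    rare_position: bool = False


@dataclass
class ConservationMap:
    """Conserved wobble orientations per (group, position), the central
    summary object of the analysis."""

    tau: float
    entries: list[ConservedEntry] = field(default_factory=list)

    def positions(self, orientation: str | None = None, include_rare: bool = False):
        return sorted(
            {
                e.position.name
                for e in self.entries
                if (orientation is None or e.orientation == orientation)
                and (include_rare or not e.rare_position)
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": e.group.name,
                    "stem": e.position.stem,
                    "pos5": e.position.pos5,
                    "pos3": e.position.pos3,
                    "orientation": e.orientation,
                    "fraction": e.fraction,
                    "n_genes": e.n_genes,
                    "rare_position": e.rare_position,
                }
                for e in self.entries
            ]
        )


def build_conservation_map(
    profiles: Mapping[str, GenePairProfile],
    genes: Sequence[TRNAGene],
    groups: Iterable[GroupKey],
    tau: float = 0.9,
) -> ConservationMap:
    """Call conserved wobble orientations.

    For each group and canonical stem position, a GoU (resp. UoG) entry is
    emitted when the fraction of genes whose pair at that position is
    exactly WOBBLE_GU (resp. WOBBLE_UG) reaches *tau* within every
    required clade. Genes with an UNDEFINED pair at a position are
    excluded from that position's denominator; a group with no mapped
    genes at a position skips the position. Entries at positions where
    wobble occurs only rarely and non-specifically (31:39, 52:62) are
    flagged and excluded from the census.
    """
    if not 0.5 < tau <= 1.0:
        raise ValueError("tau must lie in (0.5, 1]")
    cmap = ConservationMap(tau=tau)
    for group in groups:
        members = [g for g in genes if group.matches(g)]
        if not members:
            continue
        for pos in enumerate_stem_pairs():
            per_clade: dict[str, list[PairClass]] = {c: [] for c in group.clades}
            for g in members:
                cls = profiles[g.gene_id].pairs[pos]
                if cls is not PairClass.UNDEFINED:
                    per_clade[g.clade].append(cls)
            if any(not v for v in per_clade.values()):
                continue  # a required clade has no informative gene here
            for orientation, wobble_cls in _ORIENT_CLASS.items():
                fracs = {
                    c: sum(x is wobble_cls for x in v) / len(v)
                    for c, v in per_clade.items()
                }
                if all(f >= tau for f in fracs.values()):
                    pooled = [x for v in per_clade.values() for x in v]
                    cmap.entries.append(
                        ConservedEntry(
                            group=group,
                            position=pos,
                            orientation=orientation,
                            fraction=sum(x is wobble_cls for x in pooled) / len(pooled),
                            n_genes=len(pooled),
                            rare_position=pos.name in RARE_WOBBLE_POSITIONS,
                        )
                    )
    return cmap


def summarize_map(cmap: ConservationMap) -> dict[str, int]:
    """Census of the conserved-wobble map over non-rare positions.

    Returns the number of distinct stem positions with any conserved
    wobble, with GoU, with UoG, with both orientations (via distinct
    groups), with a single orientation, and the count of
    position-orientation possibilities (2 x positions-with-any).
    """
    gou = set(cmap.positions("GoU"))
    uog = set(cmap.positions("UoG"))
    any_pos = gou | uog
    both = gou & uog
    return {
        "positions_any_wobble": len(any_pos),
        "positions_gou": len(gou),
        "positions_uog": len(uog),
        "positions_both_orientations": len(both),
        "positions_single_orientation": len(any_pos) - len(both),
        "position_orientation_possibilities": 2 * len(any_pos),
    }


# ---------------------------------------------------------------------------
# Packaged conserved-pair fixture (transcribed orientation map)
# ---------------------------------------------------------------------------

def load_reference_map(path=None) -> ConservationMap:
    """Load the packaged transcription of the published conserved GoU/UoG
    orientation map (stem, pos5, pos3, orientation, isotype, anticodon,
    clades) as a :class:`ConservationMap`.

    Rows carry fraction 1.0: the fixture records which (group, position,
    orientation) triples are conserved, not the underlying fractions.
    Isotype "." marks entries whose group label is not identified in the
    running text; they still contribute to the position census.
    """
    if path is None:
        ref = resources.files("goumap.data").joinpath("conserved_wobble_map.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cmap = ConservationMap(tau=1.0)
    for r in df.itertuples():
        clades = frozenset(
            {"M": "Mammalia", "I": "Insecta"}[c] for c in str(r.clades)
        )
        anticodon = None if r.anticodon in (".", None) or pd.isna(r.anticodon) else r.anticodon
        isotype = "unassigned" if r.isotype == "." else r.isotype
        group = GroupKey(
            level="isodecoder" if anticodon else "isotype",
            isotype=isotype,
            anticodon=anticodon,
            clades=clades,
        )
        pos = pair_position(f"{r.pos5}:{r.pos3}")
        if pos.stem != r.stem:
            raise ValueError(f"fixture stem mismatch at {pos.name}")
        cmap.entries.append(
            ConservedEntry(
                group=group,
                position=pos,
                orientation=r.orientation,
                fraction=1.0,
                n_genes=0,
                rare_position=pos.name in RARE_WOBBLE_POSITIONS,
            )
        )
    return cmap


# ---------------------------------------------------------------------------
# Stem combinatorics and the code wheel
# ---------------------------------------------------------------------------

def stem_combination_count(stem_length: int, pair_alphabet_size: int = 4) -> int:
    """Number of base-pair combinations for a stem of *stem_length* pairs:
    alphabet_size ** stem_length, with alphabet 4 (Watson-Crick only) or
    6 (adding GoU and UoG)."""
    if stem_length < 0:
        raise ValueError("stem_length must be >= 0")
    if pair_alphabet_size not in (4, 6):
        raise ValueError("pair alphabet is 4 (WC) or 6 (WC + wobble)")
    return pair_alphabet_size ** stem_length


@dataclass(frozen=True)
class WheelPlacement:
    """Placement of an anticodon on the codon:anticodon strength wheel:
    GC-rich triplets sit North, AU-rich triplets South."""

    anticodon: str
    strength: int  # count of G/C among the three positions
    sector: str    # North | intermediate | South


def wheel_placement(anticodon: str) -> WheelPlacement:
    ac = anticodon.upper().replace("T", "U")
    if len(ac) != 3 or set(ac) - set("ACGU"):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    strength = sum(b in "GC" for b in ac)
    sector = {3: "North", 0: "South"}.get(strength, "intermediate")
    return WheelPlacement(ac, strength, sector)
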