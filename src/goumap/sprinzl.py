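"""Sprinzl coordinate system and cloverleaf stem geometry.

The Sprinzl numbering is the canonical tRNA coordinate system: positions
1-76 cover the cloverleaf (acceptor stem 1-7/66-72, D-arm 10-25, anticodon
arm 27-43, variable region 44-48, T-arm 49-65, discriminator 73 and the
3' CCA at 74-76), with insertion labels "17a", "20a", "20b" in the D-loop
and "e1", "e2", ... for variable-arm extensions of long-arm tRNAs.
Labels are strings and are never treated arithmetically; cross-gene
position equivalence is always by label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

# ---------------------------------------------------------------------------
# Canonical label order
# ---------------------------------------------------------------------------

_D_LOOP_FULL = ["14", "15", "16", "17", "17a", "18", "19", "20", "20a", "20b", "21"]
_E_LABELS = [f"e{i}" for i in range(1, 20)]


def _canonical_order() -> list[str]:
    order: list[str] = []
    order += [str(i) for i in range(1, 14)]          # 1-13
    order += _D_LOOP_FULL                             # 14-21 with insertions
    order += [str(i) for i in range(22, 48)]          # 22-47
    order += _E_LABELS                                # variable-arm extensions
    order += [str(i) for i in range(48, 77)]          # 48-76
    return order


#: All recognised Sprinzl labels in 5'->3' order.
SPRINZL_ORDER: tuple[str, ...] = tuple(_canonical_order())

_ORDER_INDEX = {lab: i for i, lab in enumerate(SPRINZL_ORDER)}


def sprinzl_sort_key(label: str) -> int:
    """Rank of *label* in canonical 5'->3' order (insertions sort after
    their base label)."""
    try:
        return _ORDER_INDEX[label]
    except KeyError:
        raise ValueError(f"unknown Sprinzl label: {label!r}") from None


def is_sprinzl_label(label: str) -> bool:
    return label in _ORDER_INDEX


# ---------------------------------------------------------------------------
# Stem pairing positions
# ---------------------------------------------------------------------------

STEMS = ("AA", "D", "AC", "T", "V")


@dataclass(frozen=True, order=False)
class PairPosition:
    """One stem base-pairing position: stem name plus the Sprinzl labels of
    the 5' and 3' partners (e.g. the acceptor-stem pair 3:70)."""

    stem: str
    pos5: str
    pos3: str

    def __post_init__(self) -> None:
        if self.stem not in STEMS:
            raise ValueError(f"unknown stem: {self.stem!r}")

    @property
    def name(self) -> str:
        return f"{self.pos5}:{self.pos3}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.stem} {self.name}"


def _pairs(stem: str, five: Sequence[int], three: Sequence[int]) -> list[PairPosition]:
    return [PairPosition(stem, str(a), str(b)) for a, b in zip(five, three)]


#: The 21 canonical helical-stem pairing positions, 7 + 4 + 5 + 5 for the
#: acceptor (AA), dihydrouridine (D), anticodon (AC) and thymine (T) stems.
STEM_PAIRS: tuple[PairPosition, ...] = tuple(
    _pairs("AA", range(1, 8), range(72, 65, -1))
    + _pairs("D", range(10, 14), range(25, 21, -1))
    + _pairs("AC", range(27, 32), range(43, 38, -1))
    + _pairs("T", range(49, 54), range(65, 60, -1))
)

_PAIR_BY_NAME = {p.name: p for p in STEM_PAIRS}


def enumerate_stem_pairs(stem: str | None = None) -> list[PairPosition]:
    """Return the canonical stem pairing positions in fixed order
    (AA 1:72..7:66, D 10:25..13:22, AC 27:43..31:39, T 49:65..53:61).

    With *stem* given, restrict to that stem. Variable-arm (V) pairs are
    not part of the canonical 21 and are never returned here.
    """
    if stem is None:
        return list(STEM_PAIRS)
    if stem not in ("AA", "D", "AC", "T"):
        raise ValueError(f"unknown canonical stem: {stem!r}")
    return [p for p in STEM_PAIRS if p.stem == stem]


def pair_position(name: str) -> PairPosition:
    """Look up a canonical pair position by its "pos5:pos3" name."""
    try:
        return _PAIR_BY_NAME[name]
    except KeyError:
        raise ValueError(f"not a canonical stem pair position: {name!r}") from None


#: Positions where a wobble pair is seen only rarely and never tied to a
#: specific tRNA type; excluded from the conserved-map census and reported
#: separately.
RARE_WOBBLE_POSITIONS: frozenset[str] = frozenset({"31:39", "52:62"})


# ---------------------------------------------------------------------------
# Tertiary / invariant-position catalogue
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TertiaryPosition:
    """A tertiary contact or invariant single position checked per gene.

    ``expected`` is an IUPAC letter per involved position; ``kind`` is
    "pair" (two labels) or "single".
    """

    name: str
    labels: tuple[str, ...]
    expected: tuple[str, ...]

    @property
    def kind(self) -> str:
        return "pair" if len(self.labels) == 2 else "single"


#: Fixed catalogue of tertiary contacts and invariant residues: the
#: U8:A14:A21 triple, the long-range 15:48 pair (G15:C48 or A15:U48), the
#: trans 54:58 pair (U54 opposing A58), the D-loop G18G19 and T-loop
#: U55/C56 that form the D/T loop-loop contact, the purine at 9 and the
#: invariant U33 before the anticodon.
TERTIARY_CATALOGUE: tuple[TertiaryPosition, ...] = (
    TertiaryPosition("8:14", ("8", "14"), ("U", "A")),
    TertiaryPosition("14:21", ("14", "21"), ("A", "A")),
    TertiaryPosition("15:48", ("15", "48"), ("R", "Y")),
    TertiaryPosition("54:58", ("54", "58"), ("U", "A")),
    TertiaryPosition("18", ("18",), ("G",)),
    TertiaryPosition("19", ("19",), ("G",)),
    TertiaryPosition("55", ("55",), ("U",)),
    TertiaryPosition("56", ("56",), ("C",)),
    TertiaryPosition("9", ("9",), ("R",)),
    TertiaryPosition("33", ("33",), ("U",)),
)


# ---------------------------------------------------------------------------
# Structure-line driven column numbering
# ---------------------------------------------------------------------------

_OPEN = "(<[{"
_CLOSE = ")>]}"
_UNPAIRED = ".,:_-~"

#: Canonical 76-column consensus structure (no insertions, no intron).
CANONICAL_SS: str = (
    "(" * 7 + ".." + "(" * 4 + "." * 8 + ")" * 4 + "." + "(" * 5 + "." * 7
    + ")" * 5 + "." * 5 + "(" * 5 + "." * 7 + ")" * 5 + ")" * 7 + "." * 4
)


class StructureError(ValueError):
    """Raised when a consensus structure line cannot be interpreted as a
    tRNA cloverleaf."""


def _match_brackets(ss: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(ss):
        if c in _OPEN:
            stack.append(i)
        elif c in _CLOSE:
            if not stack:
                raise StructureError(f"unbalanced structure at column {i + 1}")
            pairs.append((stack.pop(), i))
        elif c not in _UNPAIRED:
            raise StructureError(f"unrecognised structure character {c!r}")
    if stack:
        raise StructureError("unbalanced structure: unclosed bracket")
    return sorted(pairs)


def _helices(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group base pairs into helices of contiguously stacked pairs."""
    helices: list[list[tuple[int, int]]] = []
    for p in pairs:
        if helices and p[0] == helices[-1][-1][0] + 1 and p[1] == helices[-1][-1][1] - 1:
            helices[-1].append(p)
        else:
            helices.append([p])
    return helices


def _take(labels: list[str], cols: list[int], mapping: dict[int, str]) -> None:
    for col, lab in zip(cols, labels):
        mapping[col] = lab


def _d_loop_labels(n: int) -> list[str]:
    """D-loop labels for a loop of *n* columns: the canonical eight
    (14-21) plus, in order, the insertions 17a, 20a, 20b."""
    if n <= 8:
        return ["14", "15", "16", "17", "18", "19", "20", "21"][:n]
    keep = ["14", "15", "16", "17", "17a", "18", "19", "20", "20a", "20b", "21"]
    drop_order = ["20b", "20a", "17a"]
    labels = list(keep)
    for lab in drop_order[: max(0, 11 - n)]:
        labels.remove(lab)
    return labels[:n]


def _loop7(base_labels: list[str], cols: list[int], mapping: dict[int, str]) -> None:
    """Number a 7-position loop region; with extra columns (intron or
    alignment insertions) the first six get the first six labels, the last
    column the final label, and middle columns stay unmapped."""
    n = len(cols)
    if n <= 7:
        _take(base_labels[:n], cols, mapping)
    else:
        _take(base_labels[:6], cols[:6], mapping)
        mapping[cols[-1]] = base_labels[6]


def assign_sprinzl(ss: str) -> dict[int, str]:
    """Derive the alignment-column -> Sprinzl-label map from a consensus
    secondary-structure line.

    Helices are identified by bracket matching and assigned, in 5' order,
    to the acceptor, D, anticodon, (optional variable-arm) and T stems.
    Loop and linker columns are numbered against the canonical cloverleaf;
    columns that cannot be assigned a canonical or insertion label (for
    example intron columns between 37 and 38) are left out of the map.

    Returns a dict of 0-based column -> Sprinzl label.
    """
    pairs = _match_brackets(ss)
    helices = _helices(pairs)
    if len(helices) not in (4, 5):
        raise StructureError(
            f"expected 4 cloverleaf helices (5 with a variable arm), found {len(helices)}"
        )
    # helices arrive sorted by 5' start: AA, D, AC, [V], T
    aa, d, ac = helices[0], helices[1], helices[2]
    v = helices[3] if len(helices) == 5 else None
    t = helices[-1]

    mapping: dict[int, str] = {}

    # acceptor stem
    _take([str(i) for i in range(1, 8)], [p[0] for p in aa][:7], mapping)
    for (c5, c3), lab3 in zip(aa[:7], [str(i) for i in range(72, 65, -1)]):
        mapping[c3] = lab3
    # positions 8, 9 between acceptor and D stems
    gap = list(range(aa[-1][0] + 1, d[0][0]))
    _take(["8", "9"], gap[:2], mapping)
    # D stem
    _take([str(i) for i in range(10, 14)], [p[0] for p in d][:4], mapping)
    for (c5, c3), lab3 in zip(d[:4], [str(i) for i in range(25, 21, -1)]):
        mapping[c3] = lab3
    # D loop
    d_loop = list(range(d[-1][0] + 1, d[-1][1]))
    _take(_d_loop_labels(len(d_loop)), d_loop, mapping)
    # position 26
    gap = list(range(d[0][1] + 1, ac[0][0]))
    _take(["26"], gap[:1], mapping)
    # anticodon stem
    _take([str(i) for i in range(27, 32)], [p[0] for p in ac][:5], mapping)
    for (c5, c3), lab3 in zip(ac[:5], [str(i) for i in range(43, 38, -1)]):
        mapping[c3] = lab3
    # anticodon loop; the intron insertion site lies between 37 and 38
    ac_loop = list(range(ac[-1][0] + 1, ac[-1][1]))
    _loop7([str(i) for i in range(32, 39)], ac_loop, mapping)
    # variable region (with optional long-arm helix)
    var = list(range(ac[0][1] + 1, t[0][0]))
    if v is not None:
        v_cols = {c for p in v for c in p}
        arm = [c for c in var if v[0][0] <= c <= v[0][1]]
        pre = [c for c in var if c < v[0][0]]
        post = [c for c in var if c > v[0][1]]
        _take(["44", "45", "46"], pre[:3], mapping)
        _take(_E_LABELS[: len(arm)], arm, mapping)
        _take(["47", "48"][-len(post):] if post else [], post[-2:], mapping)
        del v_cols
    else:
        n = len(var)
        if n <= 5:
            _take(["44", "45", "46", "47", "48"][:n], var, mapping)
        else:
            _take(["44", "45", "46", "47"], var[:4], mapping)
            _take(_E_LABELS[: n - 5], var[4:-1], mapping)
            mapping[var[-1]] = "48"
    # T stem
    _take([str(i) for i in range(49, 54)], [p[0] for p in t][:5], mapping)
    for (c5, c3), lab3 in zip(t[:5], [str(i) for i in range(65, 60, -1)]):
        mapping[c3] = lab3
    # T loop
    t_loop = list(range(t[-1][0] + 1, t[-1][1]))
    _loop7([str(i) for i in range(54, 61)], t_loop, mapping)
    # discriminator + CCA after the acceptor 3' strand
    tail = list(range(aa[0][1] + 1, len(ss)))
    _take(["73", "74", "75", "76"], tail[:4], mapping)
    return mapping


def iter_occupied(mapping: dict[int, str]) -> Iterator[tuple[int, str]]:
    """Yield (column, label) in canonical Sprinzl order."""
    yield from sorted(mapping.items(), key=lambda kv: sprinzl_sort_key(kv[1]))
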