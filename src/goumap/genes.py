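"""tRNA gene records and gene-set operations.

A :class:`TRNAGene` carries one structurally aligned tRNA gene: its
grouping labels (species, clade, isotype, anticodon), the gapped aligned
sequence, the tRNAscan-SE-style bit score, an optional intron span and
the per-column Sprinzl map. Gene-set operations cover intron stripping,
the bit-score >= 55 functional filter and unique-transcript counting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .sprinzl import is_sprinzl_label, sprinzl_sort_key

RNA_BASES = frozenset("ACGU")
VALID_RESIDUES = frozenset("ACGUN-")

#: Default functional bit-score threshold: genes scoring below 55 bits are
#: likely pseudogenes.
SCORE_THRESHOLD = 55.0

#: Genomic genes end at the discriminator; the CCA is added
#: post-transcriptionally, so 74-76 are excluded from mature sequences.
CCA_LABELS = frozenset({"74", "75", "76"})


class AnnotationError(ValueError):
    """Raised for inconsistent gene annotations (e.g. an intron span that
    overlaps canonical Sprinzl positions)."""


def normalize_rna(seq: str) -> str:
    """Uppercase, DNA->RNA (T becomes U); validates the residue alphabet."""
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"unknown residue character(s): {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class TRNAGene:
    """One aligned tRNA gene.

    ``sprinzl_map`` maps 0-based alignment columns to Sprinzl labels;
    columns not in the map are unmapped (intron or unassignable) and are
    excluded from all analyses. ``intron_span`` is a 0-based half-open
    column interval.
    """

    gene_id: str
    species: str
    clade: str
    isotype: str
    anticodon: str
    score: float
    aligned_seq: str
    sprinzl_map: Mapping[int, str]
    intron_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"{self.gene_id}: negative bit score")
        for col, lab in self.sprinzl_map.items():
            if not (0 <= col < len(self.aligned_seq)):
                raise ValueError(f"{self.gene_id}: column {col} outside alignment")
            if not is_sprinzl_label(lab):
                raise ValueError(f"{self.gene_id}: unknown Sprinzl label {lab!r}")

    # -- residue access ----------------------------------------------------

    @property
    def column_of(self) -> dict[str, int]:
        return {lab: col for col, lab in self.sprinzl_map.items()}

    def residue(self, label: str) -> str | None:
        """Base at a Sprinzl position, or None when the position is not
        mapped or is a gap in this gene."""
        col = self.column_of.get(label)
        if col is None:
            return None
        base = self.aligned_seq[col]
        return None if base == "-" else base

    def occupied_labels(self) -> list[str]:
        """Sprinzl labels with a residue in this gene, in 5'->3' order."""
        labs = [lab for col, lab in self.sprinzl_map.items() if self.aligned_seq[col] != "-"]
        return sorted(labs, key=sprinzl_sort_key)

    def mature_sequence(self, include_cca: bool = True) -> str:
        """Intron-removed gene sequence over mapped positions.

        With ``include_cca=False`` the 3' CCA positions (74-76) are also
        dropped; transcript identity is compared on the CCA-less sequence
        since genes are genomic and the CCA is enzymatically added.
        """
        out = []
        for col, lab in sorted(self.sprinzl_map.items()):
            if self.intron_span and self.intron_span[0] <= col < self.intron_span[1]:
                continue
            if not include_cca and lab in CCA_LABELS:
                continue
            base = self.aligned_seq[col]
            if base != "-":
                out.append(base)
        return "".join(out)

    @property
    def transcript(self) -> str:
        """Mature, CCA-less sequence used for transcript identity."""
        return self.mature_sequence(include_cca=False)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "species": self.species,
            "clade": self.clade,
            "isotype": self.isotype,
            "anticodon": self.anticodon,
            "score": self.score,
            "aligned_seq": self.aligned_seq,
            "sprinzl_map": {str(c): l for c, l in self.sprinzl_map.items()},
            "intron_span": list(self.intron_span) if self.intron_span else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TRNAGene":
        return cls(
            gene_id=d["gene_id"],
            species=d["species"],
            clade=d["clade"],
            isotype=d["isotype"],
            anticodon=d["anticodon"],
            score=float(d["score"]),
            aligned_seq=d["aligned_seq"],
            sprinzl_map={int(c): l for c, l in d["sprinzl_map"].items()},
            intron_span=tuple(d["intron_span"]) if d.get("intron_span") else None,
        )


# ---------------------------------------------------------------------------
# Gene-set operations
# ---------------------------------------------------------------------------

def strip_intron(gene: TRNAGene) -> TRNAGene:
    """Return an intronless copy of *gene* with the intron columns deleted
    from the aligned sequence and the Sprinzl map re-indexed.

    The intron insertion site in eukaryotic tRNA genes is always between
    Sprinzl 37 and 38; a span covering any mapped (canonical) column is an
    annotation error. Genes without an intron are returned unchanged.
    """
    if gene.intron_span is None:
        return gene
    start, end = gene.intron_span
    if not (0 <= start < end <= len(gene.aligned_seq)):
        raise AnnotationError(f"{gene.gene_id}: invalid intron span {gene.intron_span}")
    for col in range(start, end):
        if col in gene.sprinzl_map:
            raise AnnotationError(
                f"{gene.gene_id}: intron span overlaps Sprinzl position "
                f"{gene.sprinzl_map[col]}"
            )
    col37 = gene.column_of.get("37")
    col38 = gene.column_of.get("38")
    if col37 is not None and col38 is not None and not (col37 < start and end <= col38):
        raise AnnotationError(
            f"{gene.gene_id}: intron span not between Sprinzl 37 and 38"
        )
    new_seq = gene.aligned_seq[:start] + gene.aligned_seq[end:]
    width = end - start
    new_map = {c if c < start else c - width: lab for c, lab in gene.sprinzl_map.items()}
    return replace(gene, aligned_seq=new_seq, sprinzl_map=new_map, intron_span=None)


def filter_by_score(genes: Iterable[TRNAGene], threshold: float = SCORE_THRESHOLD) -> list[TRNAGene]:
    """Keep genes with bit score >= *threshold* (inclusive), order preserved."""
    return [g for g in genes if g.score >= threshold]


def unique_transcripts(
    genes: Iterable[TRNAGene],
    group_by: Sequence[str] = ("species", "anticodon"),
) -> dict[tuple, set[str]]:
    """Distinct mature (intron-removed, CCA-less) sequences per group.

    Identical gene copies collapse to a single set member; the default
    grouping (species, anticodon) yields per-species isodecoder sets.
    """
    out: dict[tuple, set[str]] = {}
    for g in genes:
        key = tuple(getattr(g, f) for f in group_by)
        out.setdefault(key, set()).add(g.transcript)
    return out
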