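"""Synthetic tRNA gene-family generator.

Emulates the four inputs the pipeline consumes -- structural alignments
of multi-species tRNA gene families, tRNAscan-SE-style annotations, a
SNP table and a per-position conservation-score table -- with the
statistical structure the analysis assumes: planted stem motifs sampled
within their IUPAC sets with compensatory Watson-Crick 3' strands,
wobble pairs planted per (group, position, orientation) at a stated
conservation rate, pseudogenes with broken stem pairs and sub-55 bit
scores, disrupting-SNP minor-allele frequencies drawn from a lower-mean
Beta distribution at wobble strands than elsewhere, and conservation
scores elevated at wobble strands. Species are exchangeable replicates
carrying clade labels; everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genes import TRNAGene
from .pairing import IUPAC_SETS, profile_gene
from .sprinzl import STEM_PAIRS, assign_sprinzl, pair_position
from .variation import SNPRecord

_BASES = "ACGU"
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class StemTemplate:
    """IUPAC motifs for the four stem 5' strands of one isotype
    (AA 7, D 4, AC 5, T 5 letters)."""

    aa: str
    d: str
    ac: str
    t: str

    def __post_init__(self) -> None:
        for motif, want in ((self.aa, 7), (self.d, 4), (self.ac, 5), (self.t, 5)):
            if len(motif) != want:
                raise ConfigError(f"stem motif {motif!r} must have {want} letters")
            for ch in motif:
                if ch not in IUPAC_SETS:
                    raise ConfigError(f"invalid IUPAC letter {ch!r} in {motif!r}")

    def letter_at(self, pos5: str) -> str:
        i = int(pos5)
        if 1 <= i <= 7:
            return self.aa[i - 1]
        if 10 <= i <= 13:
            return self.d[i - 10]
        if 27 <= i <= 31:
            return self.ac[i - 27]
        if 49 <= i <= 53:
            return self.t[i - 49]
        raise ValueError(f"{pos5} is not a stem 5' position")


@dataclass(frozen=True)
class PlantedWobble:
    """A planted conserved wobble: group (isotype, optional anticodon),
    canonical position name like "3:70", orientation and the per-gene
    conservation rate (non-conforming genes get a Watson-Crick pair)."""

    isotype: str
    anticodon: str | None
    position: str
    orientation: str
    rate: float = 1.0

    def __post_init__(self) -> None:
        if self.orientation not in ("GoU", "UoG"):
            raise ConfigError(f"orientation must be GoU or UoG, got {self.orientation!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ConfigError("conservation rate must lie in [0, 1]")
        pair_position(self.position)  # validates


# Stem templates mirroring the consensus landscape of mammalian/insect
# tRNA alignments ("." of published motif tables written as N).
DEFAULT_TEMPLATES: dict[str, StemTemplate] = {
    "Ala": StemTemplate("GGGGUUG", "GCUC", "CNNGC", "CCGGG"),
    "Gly": StemTemplate("GCRYUGG", "GUNC", "NNNGC", "CCGGG"),
    "Pro": StemTemplate("GGCKCGU", "GUCU", "CUCGC", "CCGGG"),
    "Val": StemTemplate("GUUUCCG", "GUGU", "UYYGC", "CCCGG"),
    "Thr": StemTemplate("GGCGCCG", "GCYN", "YYKGU", "CUGGG"),
    "Arg": StemTemplate("GNCCNNG", "GCNY", "YYKGM", "NNGGG"),
    "Leu": StemTemplate("GNNAGNR", "GCCG", "YYRNN", "GUGGG"),
    "Ser": StemTemplate("GNNGNNR", "GCCG", "WUGGA", "GYRGG"),
    "Glu": StemTemplate("UCCCWNR", "GUCU", "CCUGG", "CGGCG"),
    "Gln": StemTemplate("GGYYCCA", "GUGU", "CUGGA", "CCGAG"),
    "Ile": StemTemplate("GGGCCNR", "GCUC", "UGGUG", "GCGGG"),
    "Lys": StemTemplate("GCCCGGC", "GCUC", "UGAGA", "GUGGG"),
    "Asp": StemTemplate("UCYUCGU", "GUAU", "CCCGC", "CGGGG"),
    "His": StemTemplate("GCCGUGA", "GUMU", "CURCG", "CYMGG"),
    "Cys": StemTemplate("GGGGRUA", "GCUC", "WUYGA", "CCCGG"),
    "Trp": StemTemplate("GACYYCG", "GCGC", "UCUGA", "GCGUG"),
    "Asn": StemTemplate("GYCUCYG", "GCGC", "UUCGG", "GGUGG"),
    "Met": StemTemplate("GCCYYSK", "GCGC", "UMAGU", "SUGAG"),
    "Phe": StemTemplate("GCCGAAA", "GCUC", "UUAGA", "CCYGG"),
    "Tyr": StemTemplate("CCUUCGA", "GCUC", "GWGGA", "GCUGG"),
}

DEFAULT_SPECIES: tuple[tuple[str, str], ...] = (
    ("Homo_sapiens", "Mammalia"),
    ("Mus_musculus", "Mammalia"),
    ("Bombyx_mori", "Insecta"),
    ("Drosophila_melanogaster", "Insecta"),
)

DEFAULT_ISODECODERS: tuple[tuple[str, str], ...] = (
    ("Ala", "AGC"), ("Ala", "UGC"),
    ("Leu", "UAG"), ("Leu", "CAA"),
    ("Trp", "CCA"), ("Cys", "GCA"),
    ("Asp", "GUC"), ("Asn", "GUU"),
    ("Gly", "GCC"), ("Gly", "UCC"),
    ("Pro", "AGG"), ("His", "GUG"),
    ("Glu", "UUC"), ("Gln", "UUG"),
    ("Tyr", "GUA"), ("Ile", "AAU"),
    ("Phe", "GAA"), ("Arg", "UCU"),
    ("Val", "AAC"), ("Thr", "AGU"),
    ("Met", "CAU"), ("Lys", "CUU"),
    ("Ser", "AGA"),
)

# 24 planted (group, position, orientation) truths covering every stem,
# mirroring the catalogue of isotype- and isodecoder-specific wobble
# pairs seen in mammalian and insect tRNA families.
DEFAULT_PLANTED: tuple[PlantedWobble, ...] = (
    PlantedWobble("Ala", None, "3:70", "GoU"),
    PlantedWobble("Leu", "UAG", "3:70", "UoG"),
    PlantedWobble("Trp", None, "5:68", "UoG"),
    PlantedWobble("Cys", None, "6:67", "UoG"),
    PlantedWobble("Leu", "CAA", "6:67", "GoU"),
    PlantedWobble("Asp", None, "4:69", "UoG"),
    PlantedWobble("Asn", None, "4:69", "UoG"),
    PlantedWobble("Gly", None, "10:25", "GoU"),
    PlantedWobble("Pro", None, "10:25", "GoU"),
    PlantedWobble("His", None, "10:25", "GoU"),
    PlantedWobble("Glu", None, "13:22", "UoG"),
    PlantedWobble("Gln", None, "13:22", "UoG"),
    PlantedWobble("Tyr", None, "27:43", "GoU"),
    PlantedWobble("Gly", "UCC", "27:43", "GoU"),
    PlantedWobble("Cys", None, "27:43", "UoG"),
    PlantedWobble("Ala", None, "30:40", "GoU"),
    PlantedWobble("Ile", None, "30:40", "UoG"),
    PlantedWobble("Phe", None, "51:63", "UoG"),
    PlantedWobble("Tyr", None, "51:63", "UoG"),
    PlantedWobble("Arg", None, "2:71", "GoU"),
    PlantedWobble("Val", None, "7:66", "GoU"),
    PlantedWobble("Thr", None, "28:42", "UoG"),
    PlantedWobble("Met", None, "49:65", "GoU"),
    PlantedWobble("Lys", None, "50:64", "UoG"),
)

# fixed single-stranded template (Sprinzl label -> base); the D- and
# T-loops carry the invariants the tertiary checks expect (U8, A14, G18,
# G19, A21, U33, U54, U55, C56, A58).
_LOOP_TEMPLATE: dict[str, str] = {
    "8": "U", "9": "A",
    "14": "A", "15": "G", "16": "C", "17": "U",
    "18": "G", "19": "G", "20": "U", "21": "A",
    "26": "A",
    "32": "C", "33": "U", "37": "A", "38": "A",
    "44": "A", "45": "G", "46": "G", "47": "U", "48": "C",
    "54": "U", "55": "U", "56": "C", "57": "A", "58": "A", "59": "A", "60": "U",
    "73": "A", "74": "C", "75": "C", "76": "A",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset; all defaults define the
    standard conditions used throughout the test-suite and acceptance
    runs."""

    species: tuple[tuple[str, str], ...] = DEFAULT_SPECIES
    isodecoders: tuple[tuple[str, str], ...] = DEFAULT_ISODECODERS
    templates: Mapping[str, StemTemplate] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES)
    )
    planted_wobbles: tuple[PlantedWobble, ...] = DEFAULT_PLANTED
    copy_number: int = 3
    mutation_rate: float = 0.02
    pseudogene_fraction: float = 0.1
    functional_score: tuple[float, float] = (72.0, 6.0)   # mean, sd; clipped >= 55
    pseudogene_score: tuple[float, float] = (42.0, 6.0)   # mean, sd; clipped < 55
    snp_probability: float = 0.25
    maf_wobble_beta: tuple[float, float] = (1.0, 50.0)
    maf_control_beta: tuple[float, float] = (2.0, 20.0)
    score_wobble_normal: tuple[float, float] = (2.0, 0.5)
    score_background_normal: tuple[float, float] = (0.5, 0.5)
    intron_isodecoders: Mapping[str, int] = field(
        default_factory=lambda: {"Arg-UCU": 14}
    )

    def __post_init__(self) -> None:
        for frac in (self.mutation_rate, self.pseudogene_fraction, self.snp_probability):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("rates and fractions must lie in [0, 1]")
        for pw in self.planted_wobbles:
            tmpl = self.templates.get(pw.isotype)
            if tmpl is None:
                raise ConfigError(f"no template for planted isotype {pw.isotype}")
            pos = pair_position(pw.position)
            need5 = "G" if pw.orientation == "GoU" else "U"
            if need5 not in IUPAC_SETS[tmpl.letter_at(pos.pos5)]:
                raise ConfigError(
                    f"planted {pw.orientation} at {pw.position} conflicts with the "
                    f"{pw.isotype} motif letter {tmpl.letter_at(pos.pos5)!r}"
                )

    def groups(self, level_clades: frozenset[str] | None = None):
        """Group keys matching the planted truths (for map building and
        recovery checks)."""
        from .conserve import GroupKey

        clades = level_clades or frozenset(c for _, c in self.species)
        keys = []
        seen = set()
        for pw in self.planted_wobbles:
            key = GroupKey(
                level="isodecoder" if pw.anticodon else "isotype",
                isotype=pw.isotype,
                anticodon=pw.anticodon,
                clades=clades,
            )
            if key not in seen:
                seen.add(key)
                keys.append(key)
        return keys

    def planted_truth(self) -> set[tuple[str, str, str, str]]:
        """The planted (isotype, anticodon-or-'', position, orientation)
        truth set."""
        return {
            (pw.isotype, pw.anticodon or "", pw.position, pw.orientation)
            for pw in self.planted_wobbles
        }

    def expected_map_truth(self) -> set[tuple[str, str, str, str]]:
        """Planted truth closed under group refinement: an isotype-level
        plant holds in every isodecoder group of that isotype, so a map
        built over :meth:`groups` recovers it there too."""
        expected = set(self.planted_truth())
        group_keys = {(k.isotype, k.anticodon or "") for k in self.groups()}
        for pw in self.planted_wobbles:
            if pw.anticodon is None:
                for iso, ac in group_keys:
                    if iso == pw.isotype and ac:
                        expected.add((iso, ac, pw.position, pw.orientation))
        return expected


# ---------------------------------------------------------------------------
# Gene generation
# ---------------------------------------------------------------------------

def _structure_line(intron_len: int) -> str:
    """Canonical 76-column cloverleaf, with *intron_len* extra unpaired
    columns between Sprinzl 37 and 38 when any gene carries an intron."""
    ac_loop = "." * (7 + intron_len)
    return (
        "(" * 7 + ".." + "(" * 4 + "." * 8 + ")" * 4 + "." + "(" * 5 + ac_loop
        + ")" * 5 + "." * 5 + "(" * 5 + "." * 7 + ")" * 5 + ")" * 7 + "." * 4
    )


def generate_genes(
    config: SimulationConfig, seed: int = 0
) -> tuple[list[TRNAGene], pd.DataFrame, str]:
    """Generate the aligned gene set, its annotation table and the
    consensus structure line.

    Stem 5' strands are sampled within the isotype's IUPAC motif letters
    with compensatory Watson-Crick 3' bases; planted wobble entries
    override the pair at their position with probability equal to the
    conservation rate. Loops follow a fixed single-stranded template with
    point mutations at the configured rate (anticodon excluded).
    Pseudogenes get three broken stem pairs and a sub-55 bit score.
    """
    rng = np.random.default_rng(seed)
    intron_len = max(config.intron_isodecoders.values(), default=0)
    ss = _structure_line(intron_len)
    col_of = {lab: col for col, lab in assign_sprinzl(ss).items()}
    n_cols = len(ss)
    intron_cols = sorted(set(range(n_cols)) - set(col_of.values()))
    if intron_len:
        assert len(intron_cols) == intron_len

    planted_by_group: dict[tuple[str, str | None], list[PlantedWobble]] = {}
    for pw in config.planted_wobbles:
        planted_by_group.setdefault((pw.isotype, pw.anticodon), []).append(pw)

    genes: list[TRNAGene] = []
    rows: list[dict] = []
    for species, clade in config.species:
        for isotype, anticodon in config.isodecoders:
            tmpl = config.templates[isotype]
            has_intron = f"{isotype}-{anticodon}" in config.intron_isodecoders
            for copy in range(config.copy_number):
                cols = ["-"] * n_cols
                # single-stranded template + anticodon
                for lab, base in _LOOP_TEMPLATE.items():
                    cols[col_of[lab]] = base
                if isotype == "His":
                    cols[col_of["9"]] = "C"
                for lab, base in zip(("34", "35", "36"), anticodon):
                    cols[col_of[lab]] = base
                # stems: motif-sampled 5' strand, complementary 3' strand
                for pos in STEM_PAIRS:
                    letter = tmpl.letter_at(pos.pos5)
                    choices = sorted(IUPAC_SETS[letter])
                    b5 = choices[rng.integers(len(choices))]
                    cols[col_of[pos.pos5]] = b5
                    cols[col_of[pos.pos3]] = _COMPLEMENT[b5]
                # planted wobble pairs
                for pw in (
                    planted_by_group.get((isotype, None), [])
                    + planted_by_group.get((isotype, anticodon), [])
                ):
                    if rng.random() < pw.rate:
                        pos = pair_position(pw.position)
                        b5 = "G" if pw.orientation == "GoU" else "U"
                        cols[col_of[pos.pos5]] = b5
                        cols[col_of[pos.pos3]] = "U" if b5 == "G" else "G"
                # loop point mutations (anticodon untouched)
                if config.mutation_rate > 0:
                    for lab in _LOOP_TEMPLATE:
                        if rng.random() < config.mutation_rate:
                            cur = cols[col_of[lab]]
                            others = [b for b in _BASES if b != cur]
                            cols[col_of[lab]] = others[rng.integers(3)]
                # intron
                intron_span = None
                if has_intron:
                    for c in intron_cols:
                        cols[c] = _BASES[rng.integers(4)]
                    intron_span = (intron_cols[0], intron_cols[-1] + 1)
                # pseudogene status and bit score
                pseudo = rng.random() < config.pseudogene_fraction
                if pseudo:
                    broken = rng.choice(len(STEM_PAIRS), size=3, replace=False)
                    for idx in broken:
                        pos = STEM_PAIRS[idx]
                        cur = cols[col_of[pos.pos3]]
                        others = [b for b in _BASES if b != cur]
                        cols[col_of[pos.pos3]] = others[rng.integers(3)]
                    mu, sd = config.pseudogene_score
                    score = float(min(54.5, rng.normal(mu, sd)))
                else:
                    mu, sd = config.functional_score
                    score = float(max(55.5, rng.normal(mu, sd)))
                score = max(0.0, score)

                gene_id = f"{species}_tRNA-{isotype}-{anticodon}-{copy + 1}"
                gene_map = {c: l for l, c in col_of.items()}
                genes.append(
                    TRNAGene(
                        gene_id=gene_id,
                        species=species,
                        clade=clade,
                        isotype=isotype,
                        anticodon=anticodon,
                        score=round(score, 1),
                        aligned_seq="".join(cols),
                        sprinzl_map=gene_map,
                        intron_span=intron_span,
                    )
                )
                rows.append(
                    {
                        "gene_id": gene_id,
                        "species": species,
                        "clade": clade,
                        "isotype": isotype,
                        "anticodon": anticodon,
                        "score": round(score, 1),
                        "intron_start": intron_span[0] + 1 if intron_span else np.nan,
                        "intron_end": intron_span[1] if intron_span else np.nan,
                    }
                )
    return genes, pd.DataFrame(rows), ss


# ---------------------------------------------------------------------------
# SNP and score generation
# ---------------------------------------------------------------------------

def _wobble_strand_labels(gene: TRNAGene) -> set[str]:
    prof = profile_gene(gene)
    labs: set[str] = set()
    for pos, cls in prof.pairs.items():
        if cls.is_wobble:
            labs.update((pos.pos5, pos.pos3))
    return labs


def generate_snps(
    genes: Sequence[TRNAGene], config: SimulationConfig, seed: int = 0
) -> list[SNPRecord]:
    """Draw SNPs per occupied gene position: with the configured
    probability a SNP appears whose alternate allele is uniform over the
    three non-reference bases and whose minor-allele frequency comes from
    the wobble-strand Beta distribution when the position belongs to a
    wobble pair in that gene, else from the control Beta."""
    rng = np.random.default_rng(seed)
    out: list[SNPRecord] = []
    for g in genes:
        wobble_labs = _wobble_strand_labels(g)
        for lab in g.occupied_labels():
            if rng.random() >= config.snp_probability:
                continue
            ref = g.residue(lab)
            if ref not in _BASES:
                continue
            others = [b for b in _BASES if b != ref]
            alt = others[rng.integers(3)]
            a, b = (
                config.maf_wobble_beta if lab in wobble_labs else config.maf_control_beta
            )
            af = float(rng.beta(a, b)) if b > 0 else float(a)
            out.append(SNPRecord(g.gene_id, lab, ref, alt, round(af, 6)))
    return out


def generate_scores(
    genes: Sequence[TRNAGene], config: SimulationConfig, seed: int = 0
) -> dict[tuple[str, str], float]:
    """Per-position conservation scores from class-conditional normals:
    strands of a wobble pair draw from the elevated distribution, all
    other occupied positions from the background distribution."""
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str], float] = {}
    for g in genes:
        wobble_labs = _wobble_strand_labels(g)
        for lab in g.occupied_labels():
            mu, sd = (
                config.score_wobble_normal
                if lab in wobble_labs
                else config.score_background_normal
            )
            out[(g.gene_id, lab)] = round(float(rng.normal(mu, sd)), 4)
    return out
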