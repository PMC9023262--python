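"""Population-variation tests of wobble-pair constraint.

The central statistical question: are alleles that disrupt a conserved
GoU/UoG pair rarer than alleles disrupting the Watson-Crick pair at the
same Sprinzl position in other tRNAs? Each conserved map entry yields one
matched (focal, control) comparison of aggregated minor-allele
frequencies, and the signs of the differences enter an exact binomial
sign test. The analogous comparison on per-position conservation scores
uses the minimum score across the two paired positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .conserve import ConservationMap, ConservedEntry
from .genes import TRNAGene
from .pairing import GenePairProfile, PairClass, classify_pair
from .sprinzl import PairPosition

logger = logging.getLogger(__name__)

AGGREGATIONS = ("most-common", "average")


@dataclass(frozen=True)
class SNPRecord:
    """One SNP mapped to a tRNA gene at a Sprinzl position; ``af`` is the
    allele frequency of the alternate allele."""

    gene_id: str
    sprinzl: str
    ref: str
    alt: str
    af: float

    @property
    def maf(self) -> float:
        """Minor-allele frequency: frequencies above 0.5 are folded."""
        return self.af if self.af <= 0.5 else 1.0 - self.af


@dataclass(frozen=True)
class MatchedComparison:
    """One matched (focal, control) value pair entering the sign test.

    ``sign`` follows the focal-more-constrained convention of the
    comparison that produced it: for allele frequencies +1 means the
    disrupting allele is rarer in the focal (wobble-bearing) group; for
    conservation scores +1 means the focal positions score higher.
    """

    position: PairPosition
    group_name: str
    orientation: str
    focal: float
    control: float
    sign: int
    n_focal_genes: int = 0
    n_control_genes: int = 0


@dataclass(frozen=True)
class SignTestResult:
    n_nonzero: int
    n_positive: int
    one_sided_p: float
    two_sided_p: float


# ---------------------------------------------------------------------------
# Descriptive gene-count statistics
# ---------------------------------------------------------------------------

def gene_count_stats(counts: Mapping[str, int] | Sequence[int]) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator; 0.0 for a
    single observation) of per-species unique-gene counts."""
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    if not values:
        raise ValueError("no species counts given")
    mean = float(np.mean(values))
    sd = 0.0 if len(values) == 1 else float(np.std(values, ddof=1))
    return mean, sd


def unique_count_summary(genes: Sequence[TRNAGene]) -> "pd.DataFrame":
    """Per-anticodon mean and SD of unique transcript counts across
    species (the gene-family diversity summary)."""
    import pandas as pd

    from .genes import unique_transcripts

    sets = unique_transcripts(genes, group_by=("species", "anticodon"))
    species = sorted({g.species for g in genes})
    anticodons = sorted({g.anticodon for g in genes})
    rows = []
    for ac in anticodons:
        counts = [len(sets.get((sp, ac), set())) for sp in species]
        mean, sd = gene_count_stats(counts)
        rows.append({"anticodon": ac, "mean_unique": mean, "sd_unique": sd})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SNP disruption
# ---------------------------------------------------------------------------

def _category_set(cls: PairClass) -> frozenset[PairClass] | None:
    if cls.is_wobble:
        return frozenset({PairClass.WOBBLE_GU, PairClass.WOBBLE_UG})
    if cls.is_watson_crick:
        return frozenset(
            {PairClass.WC_GC, PairClass.WC_CG, PairClass.WC_AU, PairClass.WC_UA}
        )
    return None


def disrupting_snps(
    gene: TRNAGene,
    position: PairPosition,
    snps: Iterable[SNPRecord],
) -> list[SNPRecord]:
    """SNPs of *gene* at either strand of *position* whose alternate
    allele, substituted against the partner's reference base, moves the
    pair out of its current category (wobble pairs out of
    {GoU, UoG}; Watson-Crick pairs out of the WC set).

    Genes whose current pair is OTHER or UNDEFINED yield no records.
    """
    base5, base3 = gene.residue(position.pos5), gene.residue(position.pos3)
    current = classify_pair(base5, base3)
    allowed = _category_set(current)
    if allowed is None:
        return []
    out: list[SNPRecord] = []
    for s in snps:
        if s.gene_id != gene.gene_id:
            continue
        if s.sprinzl == position.pos5:
            ref, partner, new = base5, base3, classify_pair(s.alt, base3)
        elif s.sprinzl == position.pos3:
            ref, partner, new = base3, base5, classify_pair(base5, s.alt)
        else:
            continue
        if ref is not None and s.ref != ref:
            logger.warning(
                "SNP ref %s does not match gene %s base %s at %s; skipped",
                s.ref, gene.gene_id, ref, s.sprinzl,
            )
            continue
        if new not in allowed:
            out.append(s)
    return out


def _aggregate(values: Sequence[float], aggregation: str) -> float:
    if aggregation == "most-common":
        return max(values)
    if aggregation == "average":
        return float(np.mean(values))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def _dedupe_entries(entries: Sequence[ConservedEntry]) -> list[ConservedEntry]:
    """One entry per (isotype, position, orientation), preferring the
    broader isotype-level group when an isodecoder group repeats it."""
    chosen: dict[tuple[str, str, str], ConservedEntry] = {}
    for e in entries:
        key = (e.group.isotype, e.position.name, e.orientation)
        cur = chosen.get(key)
        if cur is None or (cur.group.anticodon and not e.group.anticodon):
            chosen[key] = e
    return list(chosen.values())


def matched_comparisons(
    genes: Sequence[TRNAGene],
    profiles: Mapping[str, GenePairProfile],
    cmap: ConservationMap,
    snps: Sequence[SNPRecord],
    aggregation: str = "most-common",
    include_rare: bool = False,
    dedupe: bool = True,
) -> list[MatchedComparison]:
    """One matched allele-frequency comparison per conserved map entry.

    Focal genes are the entry's group members whose pair at the position
    shows the conserved orientation; each contributes the frequency of its
    most common (highest-MAF) disrupting SNP. Control genes are all genes
    of *other* isotypes whose pair at the same position is Watson-Crick,
    contributing their maximum disrupting-SNP frequency likewise. The
    per-side aggregate is the maximum ("most-common") or the mean
    ("average"); entries lacking focal or control observations are
    skipped. Sign is +1 when the control value exceeds the focal one
    (disrupting the wobble is more constrained).
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
    by_gene: dict[str, list[SNPRecord]] = {}
    for s in snps:
        by_gene.setdefault(s.gene_id, []).append(s)

    wobble_cls = {"GoU": PairClass.WOBBLE_GU, "UoG": PairClass.WOBBLE_UG}
    entries = _dedupe_entries(cmap.entries) if dedupe else list(cmap.entries)
    out: list[MatchedComparison] = []
    for entry in entries:
        if entry.rare_position and not include_rare:
            continue
        pos = entry.position
        focal_vals: list[float] = []
        control_vals: list[float] = []
        n_focal = n_control = 0
        for g in genes:
            cls = profiles[g.gene_id].pairs[pos]
            gene_snps = by_gene.get(g.gene_id, [])
            if entry.group.matches(g) and cls is wobble_cls[entry.orientation]:
                n_focal += 1
                hits = disrupting_snps(g, pos, gene_snps)
                if hits:
                    focal_vals.append(max(h.maf for h in hits))
            elif g.isotype != entry.group.isotype and cls.is_watson_crick:
                n_control += 1
                hits = disrupting_snps(g, pos, gene_snps)
                if hits:
                    control_vals.append(max(h.maf for h in hits))
        if not focal_vals or not control_vals:
            logger.info(
                "skipping %s %s %s: %d focal / %d control observations",
                entry.group.name, pos.name, entry.orientation,
                len(focal_vals), len(control_vals),
            )
            continue
        focal = _aggregate(focal_vals, aggregation)
        control = _aggregate(control_vals, aggregation)
        sign = (control > focal) - (control < focal)
        out.append(
            MatchedComparison(
                position=pos,
                group_name=entry.group.name,
                orientation=entry.orientation,
                focal=focal,
                control=control,
                sign=sign,
                n_focal_genes=n_focal,
                n_control_genes=n_control,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Exact sign test
# ---------------------------------------------------------------------------

def sign_test(comparisons: Sequence[MatchedComparison] | Sequence[int]) -> SignTestResult:
    """Exact binomial sign test on matched differences.

    Ties (sign 0) are excluded; under the null the remaining signs are
    fair-coin Bernoulli. The one-sided value is the upper tail
    P(X >= k_positive); the two-sided value doubles the smaller tail,
    capped at 1. With no informative comparisons both p-values are 1.
    """
    signs = [
        c.sign if isinstance(c, MatchedComparison) else int(c) for c in comparisons
    ]
    if any(s not in (-1, 0, 1) for s in signs):
        raise ValueError("signs must be -1, 0 or +1")
    nonzero = [s for s in signs if s != 0]
    n = len(nonzero)
    k = sum(s > 0 for s in nonzero)
    if n == 0:
        return SignTestResult(0, 0, 1.0, 1.0)
    upper = float(binom.sf(k - 1, n, 0.5))   # P(X >= k)
    lower = float(binom.cdf(k, n, 0.5))      # P(X <= k)
    return SignTestResult(n, k, upper, min(1.0, 2.0 * min(upper, lower)))


# ---------------------------------------------------------------------------
# Matched minimum-score comparison
# ---------------------------------------------------------------------------

def matched_min_scores(
    genes: Sequence[TRNAGene],
    profiles: Mapping[str, GenePairProfile],
    cmap: ConservationMap,
    scores: Mapping[tuple[str, str], float],
    aggregation: str = "average",
    include_rare: bool = False,
    dedupe: bool = True,
) -> tuple[list[MatchedComparison], SignTestResult]:
    """Matched comparison of per-position conservation scores.

    Per gene the value is the *minimum* score over the two paired Sprinzl
    positions (a pair is only as conserved as its least conserved
    partner). Focal genes carry the entry's wobble orientation; control
    genes are Watson-Crick at the position in other isotypes. Values are
    aggregated across genes (mean by default) and the sign is +1 when the
    focal side scores higher (wobble positions more conserved). Returns
    the comparisons and their sign test.
    """
    wobble_cls = {"GoU": PairClass.WOBBLE_GU, "UoG": PairClass.WOBBLE_UG}
    entries = _dedupe_entries(cmap.entries) if dedupe else list(cmap.entries)
    out: list[MatchedComparison] = []
    for entry in entries:
        if entry.rare_position and not include_rare:
            continue
        pos = entry.position
        focal_vals: list[float] = []
        control_vals: list[float] = []
        n_focal = n_control = 0
        for g in genes:
            cls = profiles[g.gene_id].pairs[pos]
            s5 = scores.get((g.gene_id, pos.pos5))
            s3 = scores.get((g.gene_id, pos.pos3))
            if s5 is None or s3 is None:
                continue
            value = min(s5, s3)
            if entry.group.matches(g) and cls is wobble_cls[entry.orientation]:
                n_focal += 1
                focal_vals.append(value)
            elif g.isotype != entry.group.isotype and cls.is_watson_crick:
                n_control += 1
                control_vals.append(value)
        if not focal_vals or not control_vals:
            logger.info(
                "skipping %s %s %s: missing score observations",
                entry.group.name, pos.name, entry.orientation,
            )
            continue
        if aggregation == "average":
            focal, control = float(np.mean(focal_vals)), float(np.mean(control_vals))
        elif aggregation == "most-common":
            focal, control = max(focal_vals), max(control_vals)
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
        sign = (focal > control) - (focal < control)
        out.append(
            MatchedComparison(
                position=pos,
                group_name=entry.group.name,
                orientation=entry.orientation,
                focal=focal,
                control=control,
                sign=sign,
                n_focal_genes=n_focal,
                n_control_genes=n_control,
            )
        )
    return out, sign_test(out)
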