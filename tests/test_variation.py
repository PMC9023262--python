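"""Gene-count statistics, SNP disruption, matched comparisons, sign test."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from goumap.conserve import ConservationMap, ConservedEntry, GroupKey
from goumap.pairing import PairClass, classify_pair, profile_all
from goumap.sprinzl import STEM_PAIRS, pair_position
from goumap.variation import (
    MatchedComparison,
    SNPRecord,
    disrupting_snps,
    gene_count_stats,
    matched_comparisons,
    matched_min_scores,
    sign_test,
)

from conftest import build_gene

_CLADES = frozenset({"Mammalia"})


class TestGeneCountStats:
    @pytest.mark.parametrize(
        "counts,expected",
        [([2, 2, 2], (2.0, 0.0)), ([1, 2, 3], (2.0, 1.0)), ([5], (5.0, 0.0))],
    )
    def test_mean_and_sample_sd(self, counts, expected):
        assert gene_count_stats(counts) == pytest.approx(expected)

    def test_mapping_input(self):
        assert gene_count_stats({"hg": 1, "mm": 3}) == pytest.approx((2.0, 2**0.5))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_count_stats([])


class TestDisruptingSnps:
    def _snp(self, gene, label, alt, af=0.01):
        return SNPRecord(gene.gene_id, label, gene.residue(label), alt, af)

    def test_wobble_disruption_included(self):
        gene = build_gene(overrides={"70": "U"})  # G3oU70
        pos = pair_position("3:70")
        snps = [self._snp(gene, "3", "A"), self._snp(gene, "70", "C", 0.2)]
        hits = disrupting_snps(gene, pos, snps)
        assert hits == snps  # G3->A gives A-U; U70->C gives G=C: both leave wobble

    def test_control_wc_disruption_included(self):
        gene = build_gene()  # G3=C70
        pos = pair_position("3:70")
        snp = self._snp(gene, "70", "U")
        assert disrupting_snps(gene, pos, [snp]) == [snp]  # G=C -> GoU leaves WC

    def test_mismatched_ref_skipped(self):
        gene = build_gene()
        pos = pair_position("3:70")
        snp = SNPRecord(gene.gene_id, "3", "A", "C", 0.01)  # gene has G3
        assert disrupting_snps(gene, pos, [snp]) == []

    def test_other_category_yields_nothing(self):
        gene = build_gene(overrides={"70": "G"})  # GoG
        assert disrupting_snps(gene, pair_position("3:70"), []) == []

    def test_exhaustive_category_change_oracle(self):
        """Every returned SNP changes the pair's category set; every
        category-changing substitution is returned (all 3 alts x 2 strands
        per position, checked against classify_pair directly)."""
        for overrides in ({}, {"70": "U"}):  # a WC and a wobble gene
            gene = build_gene(overrides=overrides)
            for pos in STEM_PAIRS:
                b5, b3 = gene.residue(pos.pos5), gene.residue(pos.pos3)
                current = classify_pair(b5, b3)
                wobble = {PairClass.WOBBLE_GU, PairClass.WOBBLE_UG}
                cat = wobble if current in wobble else {
                    c for c in PairClass if c.is_watson_crick
                }
                snps, expected = [], []
                for label, ref, partner, side in (
                    (pos.pos5, b5, b3, "5"), (pos.pos3, b3, b5, "3"),
                ):
                    for alt in "ACGU":
                        if alt == ref:
                            continue
                        s = SNPRecord(gene.gene_id, label, ref, alt, 0.01)
                        snps.append(s)
                        new = (
                            classify_pair(alt, partner)
                            if side == "5"
                            else classify_pair(partner, alt)
                        )
                        if new not in cat:
                            expected.append(s)
                assert disrupting_snps(gene, pos, snps) == expected


class TestSignTest:
    def test_twenty_of_twentyfour(self):
        res = sign_test([1] * 20 + [-1] * 4)
        assert res.n_nonzero == 24 and res.n_positive == 20
        # exact tail: sum_{k=20..24} C(24,k) / 2^24 = 12951 / 16777216
        assert res.one_sided_p == pytest.approx(12951 / 2**24, rel=1e-12)

    def test_three_of_three_two_sided(self):
        res = sign_test([1, 1, 1])
        assert res.two_sided_p == pytest.approx(0.25)

    def test_no_comparisons_vacuous(self):
        res = sign_test([])
        assert (res.n_nonzero, res.one_sided_p, res.two_sided_p) == (0, 1.0, 1.0)

    def test_ties_excluded(self):
        assert sign_test([0, 0, 1, -1]).n_nonzero == 2
        assert sign_test([0, 0, 0]).one_sided_p == 1.0

    def test_matches_full_enumeration_oracle(self):
        """Exact binomial equals brute-force enumeration of all 2^n sign
        vectors for every n <= 12 and every k."""
        for n in range(1, 13):
            vectors = list(itertools.product([1, -1], repeat=n))
            for k in range(n + 1):
                upper = sum(1 for v in vectors if sum(s > 0 for s in v) >= k) / 2**n
                lower = sum(1 for v in vectors if sum(s > 0 for s in v) <= k) / 2**n
                res = sign_test([1] * k + [-1] * (n - k))
                assert res.one_sided_p == pytest.approx(upper, rel=1e-12)
                assert res.two_sided_p == pytest.approx(
                    min(1.0, 2 * min(upper, lower)), rel=1e-12
                )

    @given(
        signs=st.lists(st.sampled_from([-1, 0, 1]), min_size=0, max_size=30)
    )
    @settings(deadline=None, derandomize=True)
    def test_sign_flip_symmetry(self, signs):
        res = sign_test(signs)
        flipped = sign_test([-s for s in signs])
        assert flipped.n_positive == res.n_nonzero - res.n_positive
        assert flipped.two_sided_p == pytest.approx(res.two_sided_p, rel=1e-12)

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError):
            sign_test([2])


def _single_entry_setup(n_focal=2, n_control=3):
    """An Ala group with G3oU70 plus WC genes of another isotype."""
    focal = [
        build_gene(gene_id=f"ala{i}", overrides={"70": "U"}) for i in range(n_focal)
    ]
    control = [
        build_gene(gene_id=f"gly{i}", isotype="Gly", anticodon="GCC")
        for i in range(n_control)
    ]
    genes = focal + control
    profiles = profile_all(genes)
    cmap = ConservationMap(tau=0.9)
    cmap.entries.append(
        ConservedEntry(
            GroupKey("isotype", "Ala", None, _CLADES),
            pair_position("3:70"), "GoU", 1.0, n_focal,
        )
    )
    return genes, profiles, cmap


class TestMatchedComparisons:
    def test_focal_below_control_gives_positive_sign(self):
        genes, profiles, cmap = _single_entry_setup()
        snps = [
            SNPRecord("ala0", "3", "G", "A", 0.001),
            SNPRecord("gly0", "70", "C", "U", 0.05),
            SNPRecord("gly1", "3", "G", "C", 0.10),
        ]
        comps = matched_comparisons(genes, profiles, cmap, snps)
        assert len(comps) == 1
        c = comps[0]
        assert (c.focal, c.control, c.sign) == (0.001, 0.10, 1)

    def test_average_aggregation(self):
        genes, profiles, cmap = _single_entry_setup()
        snps = [
            SNPRecord("ala0", "3", "G", "A", 0.02),
            SNPRecord("ala1", "3", "G", "A", 0.04),
            SNPRecord("gly0", "3", "G", "A", 0.10),
        ]
        comps = matched_comparisons(genes, profiles, cmap, snps, aggregation="average")
        assert comps[0].focal == pytest.approx(0.03)

    def test_tie_gives_sign_zero(self):
        genes, profiles, cmap = _single_entry_setup()
        snps = [
            SNPRecord("ala0", "3", "G", "A", 0.05),
            SNPRecord("gly0", "3", "G", "A", 0.05),
        ]
        assert matched_comparisons(genes, profiles, cmap, snps)[0].sign == 0

    def test_entry_without_data_skipped(self):
        genes, profiles, cmap = _single_entry_setup()
        assert matched_comparisons(genes, profiles, cmap, []) == []

    def test_frequency_folding(self):
        genes, profiles, cmap = _single_entry_setup()
        snps = [
            SNPRecord("ala0", "3", "G", "A", 0.9),   # folded to 0.1
            SNPRecord("gly0", "3", "G", "A", 0.3),
        ]
        c = matched_comparisons(genes, profiles, cmap, snps)[0]
        assert c.focal == pytest.approx(0.1)
        assert c.sign == 1


class TestMatchedMinScores:
    def test_separated_scores_all_positive(self):
        genes, profiles, cmap = _single_entry_setup()
        scores = {}
        for g in genes:
            for lab in ("3", "70"):
                scores[(g.gene_id, lab)] = 2.0 if g.isotype == "Ala" else 0.5
        comps, res = matched_min_scores(genes, profiles, cmap, scores)
        assert [c.sign for c in comps] == [1]
        assert res.one_sided_p == pytest.approx(0.5)  # 0.5 ** n with n = 1

    def test_identical_scores_all_ties(self):
        genes, profiles, cmap = _single_entry_setup()
        scores = {(g.gene_id, lab): 1.0 for g in genes for lab in ("3", "70")}
        comps, res = matched_min_scores(genes, profiles, cmap, scores)
        assert [c.sign for c in comps] == [0]
        assert res.two_sided_p == 1.0

    def test_minimum_over_pair_strands(self):
        genes, profiles, cmap = _single_entry_setup(n_focal=1, n_control=1)
        scores = {
            ("ala0", "3"): 3.0, ("ala0", "70"): 0.1,
            ("gly0", "3"): 0.5, ("gly0", "70"): 0.5,
        }
        comps, _ = matched_min_scores(genes, profiles, cmap, scores)
        assert comps[0].focal == pytest.approx(0.1)
        assert comps[0].sign == -1

    def test_missing_scores_skip_entry(self):
        genes, profiles, cmap = _single_entry_setup()
        comps, res = matched_min_scores(genes, profiles, cmap, {})
        assert comps == [] and res.one_sided_p == 1.0
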