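"""Consensus motifs, conservation map, census, combinatorics, code wheel."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from goumap.conserve import (
    ConservationMap,
    ConservedEntry,
    GroupKey,
    build_conservation_map,
    consensus_iupac,
    load_reference_map,
    stem_combination_count,
    stem_motifs,
    summarize_map,
    wheel_placement,
)
from goumap.pairing import IUPAC_SETS, profile_all
from goumap.sprinzl import pair_position

from conftest import build_gene

_CLADES = frozenset({"Mammalia"})


class TestConsensusIupac:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ({"G": 1.0}, "G"),
            ({"C": 0.5, "U": 0.5}, "Y"),
            ({"G": 0.6, "U": 0.4}, "K"),   # K reads 'G or U'
            ({"A": 0.4, "G": 0.6}, "R"),
            ({"A": 0.3, "C": 0.3, "G": 0.2, "U": 0.2}, "N"),
        ],
    )
    def test_smallest_covering_letter(self, freqs, expected):
        assert consensus_iupac(freqs) == expected

    def test_floor_excludes_rare_base(self):
        assert consensus_iupac({"G": 0.97, "U": 0.03}, inclusion_floor=0.05) == "G"

    def test_all_below_floor_is_error(self):
        with pytest.raises(ValueError):
            consensus_iupac({"G": 0.3}, inclusion_floor=0.5)

    @given(letter=st.sampled_from(sorted(IUPAC_SETS)))
    @settings(deadline=None, derandomize=True)
    def test_idempotent_on_own_letter_set(self, letter):
        """Uniform frequencies over a letter's base set re-yield the letter."""
        bases = sorted(IUPAC_SETS[letter])
        freqs = {b: 1.0 / len(bases) for b in bases}
        assert consensus_iupac(freqs, inclusion_floor=0.0) == letter


class TestStemMotifs:
    def _group(self, **kw):
        defaults = dict(level="isotype", isotype="Ala", clades=_CLADES)
        defaults.update(kw)
        return GroupKey(**defaults)

    def test_identical_sequences_yield_their_own_strands(self):
        genes = [build_gene(gene_id=f"g{i}") for i in range(3)]
        motifs = {m.stem: m.motif for m in stem_motifs(genes, self._group(), 0.0)}
        assert motifs["AA"] == "GGGGUUG"
        assert motifs["D"] == "GCUC"
        assert motifs["AC"] == "CACGC"
        assert motifs["T"] == "CCGGG"

    def test_mixed_column_produces_degenerate_letter(self):
        genes = [
            build_gene(gene_id="a", overrides={"3": "C", "4": "C"}),
            build_gene(gene_id="b", overrides={"3": "U", "4": "U"}),
        ]
        motifs = {m.stem: m.motif for m in stem_motifs(genes, self._group())}
        assert motifs["AA"] == "GGYYUUG"  # mixed C/U at columns 3 and 4

    def test_planted_isotype_motifs_recovered(self, sim_config, functional_genes):
        clades = frozenset(c for _, c in sim_config.species)
        for isotype, stem, expected in [
            ("Ala", "AA", "GGGGUUG"),
            ("Gln", "AA", "GGYYCCA"),
            ("Asp", "AC", "CCCGC"),
        ]:
            group = GroupKey("isotype", isotype, None, clades)
            motifs = {m.stem: m.motif for m in stem_motifs(functional_genes, group)}
            got = motifs[stem]
            # planted wobble pairs may overwrite single motif columns
            mismatches = sum(a != b for a, b in zip(got, expected))
            assert mismatches <= 1, f"{isotype} {stem}: {got} vs {expected}"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stem_motifs([build_gene()], self._group(isotype="Trp"))


class TestConservationMap:
    def _map_for(self, genes, tau=0.9):
        profiles = profile_all(genes)
        groups = [GroupKey("isotype", "Ala", None, _CLADES)]
        return build_conservation_map(profiles, genes, groups, tau)

    def test_unanimous_wobble_conserved(self):
        genes = [build_gene(gene_id=f"g{i}", overrides={"70": "U"}) for i in range(4)]
        cmap = self._map_for(genes)
        assert [(e.position.name, e.orientation, e.fraction) for e in cmap.entries] == [
            ("3:70", "GoU", 1.0)
        ]

    def test_half_wobble_below_tau_not_conserved(self):
        genes = [
            build_gene(gene_id=f"g{i}", overrides={"70": "U"} if i % 2 else {})
            for i in range(4)
        ]
        assert self._map_for(genes, tau=0.9).entries == []

    def test_conservation_requires_every_clade(self):
        mam = [build_gene(gene_id=f"m{i}", overrides={"70": "U"}) for i in range(3)]
        ins = [
            build_gene(gene_id=f"i{i}", clade="Insecta", species="Bombyx_mori")
            for i in range(3)
        ]
        profiles = profile_all(mam + ins)
        both = [GroupKey("isotype", "Ala", None, frozenset({"Mammalia", "Insecta"}))]
        cmap = build_conservation_map(profiles, mam + ins, both, 0.9)
        assert cmap.entries == []  # Insecta genes are Watson-Crick at 3:70

    def test_tau_validated(self):
        with pytest.raises(ValueError):
            self._map_for([build_gene()], tau=0.4)


class TestSummarizeMap:
    def test_empty_map(self):
        counts = summarize_map(ConservationMap(tau=0.9))
        assert set(counts.values()) == {0}

    def test_single_gou_position(self):
        cmap = ConservationMap(tau=0.9)
        cmap.entries.append(
            ConservedEntry(
                GroupKey("isotype", "Ala", None, _CLADES),
                pair_position("3:70"), "GoU", 1.0, 4,
            )
        )
        counts = summarize_map(cmap)
        assert counts == {
            "positions_any_wobble": 1,
            "positions_gou": 1,
            "positions_uog": 0,
            "positions_both_orientations": 0,
            "positions_single_orientation": 1,
            "position_orientation_possibilities": 2,
        }

    def test_reference_map_census(self):
        counts = summarize_map(load_reference_map())
        assert counts["positions_any_wobble"] == 15
        assert counts["positions_gou"] == 10
        assert counts["positions_uog"] == 11
        assert counts["positions_both_orientations"] == 6
        assert counts["positions_single_orientation"] == 9
        assert counts["position_orientation_possibilities"] == 30

    def test_census_identities(self, conservation_map):
        """any = GoU + UoG - both and single = any - both on every map."""
        for cmap in (conservation_map, load_reference_map()):
            c = summarize_map(cmap)
            assert (
                c["positions_any_wobble"]
                == c["positions_gou"] + c["positions_uog"] - c["positions_both_orientations"]
            )
            assert (
                c["positions_single_orientation"]
                == c["positions_any_wobble"] - c["positions_both_orientations"]
            )


class TestCombinatorics:
    @pytest.mark.parametrize(
        "n,k,expected", [(7, 4, 16384), (5, 4, 1024), (5, 6, 7776), (0, 4, 1)]
    )
    def test_reported_counts(self, n, k, expected):
        assert stem_combination_count(n, k) == expected

    @pytest.mark.parametrize("n", range(6))
    @pytest.mark.parametrize("k", [4, 6])
    def test_matches_brute_force_enumeration(self, n, k):
        enumerated = sum(1 for _ in itertools.product(range(k), repeat=n))
        assert stem_combination_count(n, k) == enumerated

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            stem_combination_count(-1, 4)
        with pytest.raises(ValueError):
            stem_combination_count(5, 5)


class TestWheelPlacement:
    @pytest.mark.parametrize(
        "anticodon,strength,sector",
        [("GCC", 3, "North"), ("UUA", 0, "South"), ("GAA", 1, "intermediate"),
         ("AGC", 2, "intermediate")],
    )
    def test_sector_by_gc_count(self, anticodon, strength, sector):
        placement = wheel_placement(anticodon)
        assert (placement.strength, placement.sector) == (strength, sector)

    def test_invalid_anticodon(self):
        with pytest.raises(ValueError):
            wheel_placement("GC")
        with pytest.raises(ValueError):
            wheel_placement("GXC")
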