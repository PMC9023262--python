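"""Shared fixtures: a hand-built canonical tRNA gene and one seeded
synthetic dataset reused across modules."""

from __future__ import annotations

import pytest

from goumap.conserve import build_conservation_map
from goumap.genes import TRNAGene, filter_by_score
from goumap.pairing import profile_all
from goumap.simulate import SimulationConfig, generate_genes, generate_scores, generate_snps
from goumap.sprinzl import CANONICAL_SS, STEM_PAIRS, assign_sprinzl

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# single-stranded defaults of the canonical test gene (an Ala-AGC-like
# tRNA whose loops satisfy every tertiary expectation)
_SS_TEMPLATE = {
    "8": "U", "9": "A",
    "14": "A", "15": "G", "16": "C", "17": "U",
    "18": "G", "19": "G", "20": "U", "21": "A",
    "26": "A",
    "32": "C", "33": "U", "34": "A", "35": "G", "36": "C", "37": "A", "38": "A",
    "44": "A", "45": "G", "46": "G", "47": "U", "48": "C",
    "54": "U", "55": "U", "56": "C", "57": "A", "58": "A", "59": "A", "60": "U",
    "73": "A", "74": "C", "75": "C", "76": "A",
}

_STEM5 = {
    "AA": "GGGGUUG",
    "D": "GCUC",
    "AC": "CACGC",
    "T": "CCGGG",
}


def build_gene(overrides: dict[str, str] | None = None, **attrs) -> TRNAGene:
    """A gap-free 76-column canonical gene; *overrides* replaces bases at
    given Sprinzl labels ('-' makes a position a gap)."""
    mapping = assign_sprinzl(CANONICAL_SS)
    col_of = {lab: col for col, lab in mapping.items()}
    cols = ["-"] * 76
    for lab, base in _SS_TEMPLATE.items():
        cols[col_of[lab]] = base
    # stems: 5' strand per stem, complementary 3' strand
    strand_labels = {
        "AA": [str(i) for i in range(1, 8)],
        "D": [str(i) for i in range(10, 14)],
        "AC": [str(i) for i in range(27, 32)],
        "T": [str(i) for i in range(49, 54)],
    }
    for stem, labels in strand_labels.items():
        for lab, base in zip(labels, _STEM5[stem]):
            cols[col_of[lab]] = base
    for pos in STEM_PAIRS:
        cols[col_of[pos.pos3]] = _COMPLEMENT[cols[col_of[pos.pos5]]]
    for lab, base in (overrides or {}).items():
        cols[col_of[lab]] = base
    defaults = dict(
        gene_id="test-gene",
        species="Homo_sapiens",
        clade="Mammalia",
        isotype="Ala",
        anticodon="AGC",
        score=75.0,
        aligned_seq="".join(cols),
        sprinzl_map=mapping,
    )
    defaults.update(attrs)
    return TRNAGene(**defaults)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    genes, annotations, structure = generate_genes(sim_config, seed=1)
    return genes, annotations, structure


@pytest.fixture(scope="session")
def functional_genes(sim_dataset):
    genes, _, _ = sim_dataset
    return filter_by_score(genes)


@pytest.fixture(scope="session")
def profiles(functional_genes):
    return profile_all(functional_genes)


@pytest.fixture(scope="session")
def conservation_map(sim_config, functional_genes, profiles):
    return build_conservation_map(
        profiles, functional_genes, sim_config.groups(), tau=0.9
    )


@pytest.fixture(scope="session")
def sim_snps(sim_config, functional_genes):
    return generate_snps(functional_genes, sim_config, seed=2)


@pytest.fixture(scope="session")
def sim_scores(sim_config, functional_genes):
    return generate_scores(functional_genes, sim_config, seed=3)
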