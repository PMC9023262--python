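"""Readers and writers for the pipeline's file formats.

Alignments arrive as Stockholm (with a ``#=GC SS_cons`` consensus
structure line) or as aligned FASTA plus a separate structure string;
gene annotations, SNPs and per-position conservation scores are TSV
tables (SNPs alternatively as VCF). Parsed gene sets round-trip through
a JSON representation.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genes import TRNAGene, normalize_rna
from .sprinzl import assign_sprinzl
from .variation import SNPRecord

ANNOTATION_COLUMNS = [
    "gene_id", "species", "clade", "isotype", "anticodon",
    "score", "intron_start", "intron_end",
]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_annotations(path_or_buf) -> pd.DataFrame:
    """Read the tRNAscan-SE-style gene annotation table (TSV with header
    gene_id, species, clade, isotype, anticodon, score, intron_start,
    intron_end; intron columns 1-based inclusive, empty when absent)."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"gene_id": str})
    missing = set(ANNOTATION_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing column(s): {sorted(missing)}")
    return df


def write_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignments -> genes
# ---------------------------------------------------------------------------

def _structure_from_stockholm(aln) -> str | None:
    return aln.column_annotations.get("secondary_structure")


def parse_alignment(
    alignment,
    annotations: pd.DataFrame,
    structure_line: str | None = None,
    fmt: str = "stockholm",
) -> list[TRNAGene]:
    """Build :class:`TRNAGene` records from a structural alignment.

    *alignment* is a path, open text handle or string of Stockholm or
    aligned-FASTA text. For Stockholm the consensus structure is taken
    from the ``#=GC SS_cons`` line unless *structure_line* overrides it;
    for FASTA a *structure_line* is required. Every sequence id must
    appear in the *annotations* table.

    The Sprinzl map is derived once from the structure line by numbering
    paired and loop columns against the canonical cloverleaf; columns that
    cannot be assigned (e.g. intron columns between 37 and 38) stay
    unmapped and are excluded from analyses.
    """
    if isinstance(alignment, (str, Path)) and "\n" not in str(alignment):
        aln = AlignIO.read(str(alignment), fmt)
    elif isinstance(alignment, str):
        aln = AlignIO.read(_io.StringIO(alignment), fmt)
    elif isinstance(alignment, MultipleSeqAlignment):
        aln = alignment
    else:
        aln = AlignIO.read(alignment, fmt)

    if structure_line is None:
        structure_line = _structure_from_stockholm(aln)
    if structure_line is None:
        raise FormatError("no consensus structure line (SS_cons) available")
    if len(structure_line) != aln.get_alignment_length():
        raise FormatError(
            f"structure line length {len(structure_line)} != alignment "
            f"length {aln.get_alignment_length()}"
        )

    base_map = assign_sprinzl(structure_line)
    ann = annotations.set_index("gene_id")

    genes: list[TRNAGene] = []
    for rec in aln:
        if rec.id not in ann.index:
            raise KeyError(f"gene {rec.id!r} missing from annotation table")
        row = ann.loc[rec.id]
        seq = normalize_rna(str(rec.seq))
        if len(seq) != len(structure_line):
            raise FormatError(f"{rec.id}: sequence length != structure length")
        intron = None
        i0, i1 = row.get("intron_start"), row.get("intron_end")
        if pd.notna(i0) and pd.notna(i1) and int(i1) >= int(i0) > 0:
            intron = (int(i0) - 1, int(i1))  # 1-based inclusive -> 0-based half-open
        gene_map = dict(base_map)
        if intron:
            for col in range(*intron):
                gene_map.pop(col, None)
        genes.append(
            TRNAGene(
                gene_id=rec.id,
                species=str(row["species"]),
                clade=str(row["clade"]),
                isotype=str(row["isotype"]),
                anticodon=normalize_rna(str(row["anticodon"])),
                score=float(row["score"]),
                aligned_seq=seq,
                sprinzl_map=gene_map,
                intron_span=intron,
            )
        )
    return genes


def genes_to_alignment(genes: Sequence[TRNAGene], structure_line: str) -> MultipleSeqAlignment:
    """Assemble genes (all sharing one column layout) into a Biopython
    alignment carrying the consensus structure annotation."""
    records = [
        SeqRecord(Seq(g.aligned_seq), id=g.gene_id, description="") for g in genes
    ]
    aln = MultipleSeqAlignment(records)
    aln.column_annotations["secondary_structure"] = structure_line
    return aln


def write_stockholm(genes: Sequence[TRNAGene], structure_line: str, path) -> None:
    AlignIO.write(genes_to_alignment(genes, structure_line), str(path), "stockholm")


# ---------------------------------------------------------------------------
# Gene JSON round trip
# ---------------------------------------------------------------------------

def write_genes_json(genes: Iterable[TRNAGene], path) -> None:
    with open(path, "w") as fh:
        json.dump([g.to_dict() for g in genes], fh, indent=1)


def read_genes_json(path) -> list[TRNAGene]:
    with open(path) as fh:
        return [TRNAGene.from_dict(d) for d in json.load(fh)]


# ---------------------------------------------------------------------------
# SNP and score tables
# ---------------------------------------------------------------------------

def read_snps(path_or_buf) -> list[SNPRecord]:
    """Read a SNP TSV (gene_id, sprinzl, ref, alt, af)."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"gene_id": str, "sprinzl": str})
    need = {"gene_id", "sprinzl", "ref", "alt", "af"}
    if not need <= set(df.columns):
        raise FormatError(f"SNP table missing column(s): {sorted(need - set(df.columns))}")
    return [
        SNPRecord(
            gene_id=r.gene_id,
            sprinzl=str(r.sprinzl),
            ref=normalize_rna(str(r.ref)),
            alt=normalize_rna(str(r.alt)),
            af=float(r.af),
        )
        for r in df.itertuples()
    ]


def write_snps(snps: Iterable[SNPRecord], path) -> None:
    pd.DataFrame([s.__dict__ for s in snps]).to_csv(path, sep="\t", index=False)


def read_snps_vcf(path) -> list[SNPRecord]:
    """Read SNPs from a VCF whose CHROM is the gene id, with the Sprinzl
    label in the INFO field ``SPRINZL`` and the frequency in ``AF``."""
    import pysam

    out: list[SNPRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            sprinzl = rec.info.get("SPRINZL")
            af = rec.info.get("AF")
            if isinstance(af, tuple):
                af = af[0]
            if sprinzl is None or af is None:
                raise FormatError(f"VCF record {rec.chrom}:{rec.pos} lacks SPRINZL/AF")
            for alt in rec.alts or ():
                out.append(
                    SNPRecord(
                        gene_id=rec.chrom,
                        sprinzl=str(sprinzl),
                        ref=normalize_rna(rec.ref),
                        alt=normalize_rna(alt),
                        # htslib stores AF as float32; round off the noise
                        af=round(float(af), 6),
                    )
                )
    return out


def write_snps_vcf(snps: Iterable[SNPRecord], path) -> None:
    """Write SNPs as a minimal VCF (CHROM = gene id, POS = 1, Sprinzl label
    and frequency in INFO)."""
    snps = list(snps)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
        '##INFO=<ID=SPRINZL,Number=1,Type=String,Description="Sprinzl position">',
    ]
    lines += [
        f"##contig=<ID={gid}>" for gid in sorted({s.gene_id for s in snps})
    ]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for s in snps:
        ref = s.ref.replace("U", "T")
        alt = s.alt.replace("U", "T")
        lines.append(
            f"{s.gene_id}\t1\t.\t{ref}\t{alt}\t.\t.\tAF={s.af:.6g};SPRINZL={s.sprinzl}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_scores(path_or_buf) -> dict[tuple[str, str], float]:
    """Read a per-position conservation-score TSV (gene_id, sprinzl, score)
    into a (gene_id, sprinzl) -> score mapping."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"gene_id": str, "sprinzl": str})
    need = {"gene_id", "sprinzl", "score"}
    if not need <= set(df.columns):
        raise FormatError(f"score table missing column(s): {sorted(need - set(df.columns))}")
    return {(r.gene_id, str(r.sprinzl)): float(r.score) for r in df.itertuples()}


def write_scores(scores: dict[tuple[str, str], float], path) -> None:
    df = pd.DataFrame(
        [(g, s, v) for (g, s), v in scores.items()],
        columns=["gene_id", "sprinzl", "score"],
    )
    df.to_csv(path, sep="\t", index=False)
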