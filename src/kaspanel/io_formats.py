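"""Readers and writers for the standard formats the pipeline touches.

VCF parsing is delegated to cyvcf2 and VCF writing to pysam; FASTA goes
through Biopython and GFF3 through gffutils.  All conversion between the
1-based closed coordinates of VCF/GFF3 and the package's internal 0-based
half-open intervals happens here and nowhere else.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .model import (
    MISSING,
    GeneModel,
    Genome,
    GenomeSequence,
    GenotypeMatrix,
    VariantRecord,
    as_genome,
)


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_reference(fasta_path) -> dict[str, GenomeSequence]:
    """Load a reference genome; sequences are upper-cased.

    Raises :class:`FormatError` on an empty file or duplicate contig ids.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise FormatError(f"{fasta_path}: no FASTA records")
    try:
        return as_genome(
            GenomeSequence(r.id, str(r.seq).upper()) for r in records
        )
    except ValueError as exc:
        raise FormatError(f"{fasta_path}: {exc}") from exc


def write_reference(genome: Genome, fasta_path, width: int = 70) -> None:
    with open(fasta_path, "w") as fh:
        for rec in genome.values():
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def extract_flank(
    genome: Genome, contig: str, pos: int, width: int
) -> tuple[str, tuple[int, int]]:
    """Window of ``width`` bp either side of a 1-based position.

    Returns the sequence together with its 1-based closed interval, clipped
    at contig boundaries; the base at ``pos`` is always included.
    """
    if contig not in genome:
        raise KeyError(f"unknown contig {contig!r}")
    seq = genome[contig].sequence
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside contig {contig} (1..{len(seq)})")
    start = max(1, pos - width)
    end = min(len(seq), pos + width)
    return seq[start - 1 : end], (start, end)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gene_models(gff_path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into :class:`GeneModel` objects."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = [
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype="exon", order_by="start")
        ]
        cds = [
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype="CDS", order_by="start")
        ]
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig_id=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=cds,
            )
        )
    return models


def write_gene_models(models: Sequence[GeneModel], gff_path) -> None:
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(models, key=lambda m: (m.contig_id, m.start)):
            cols = [g.contig_id, "kaspanel", "gene", str(g.start + 1), str(g.end),
                    ".", g.strand, ".", f"ID={g.gene_id}"]
            fh.write("\t".join(cols) + "\n")
            mrna_id = f"{g.gene_id}.t1"
            cols[2], cols[8] = "mRNA", f"ID={mrna_id};Parent={g.gene_id}"
            fh.write("\t".join(cols) + "\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    "\t".join(
                        [g.contig_id, "kaspanel", "exon", str(s + 1), str(e),
                         ".", g.strand, ".",
                         f"ID={mrna_id}.exon{i};Parent={mrna_id}"]
                    ) + "\n"
                )
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    "\t".join(
                        [g.contig_id, "kaspanel", "CDS", str(s + 1), str(e),
                         ".", g.strand, "0",
                         f"ID={mrna_id}.cds;Parent={mrna_id}"]
                    ) + "\n"
                )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_INFO_FIELDS = (
    ("QD", "qd", "Variant Confidence/Quality by Depth"),
    ("MQ", "mq", "RMS Mapping Quality"),
    ("FS", "fs", "Phred-scaled p-value using Fisher's exact test for strand bias"),
    ("MQRankSum", "mq_rank_sum", "Mapping quality rank sum test"),
    ("ReadPosRankSum", "read_pos_rank_sum", "Read position rank sum test"),
)


def _check_vcf_header(vcf_path) -> None:
    """Cheap structural validation so errors can name the offending line."""
    with open(vcf_path) as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise FormatError(f"{vcf_path}: line 1 is not a ##fileformat line")
        for lineno, line in enumerate(fh, start=2):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 10 or cols[8] != "FORMAT":
                    raise FormatError(
                        f"{vcf_path}: line {lineno}: #CHROM line lacks "
                        "FORMAT/sample columns"
                    )
                return
            raise FormatError(
                f"{vcf_path}: line {lineno}: data before #CHROM header"
            )
    raise FormatError(f"{vcf_path}: no #CHROM header line")


def read_variants(vcf_path) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Read a multi-sample VCF into records plus a genotype matrix.

    Per-sample GT is required; ``./.`` and ``.`` become missing calls.
    ``mean_depth`` / ``mean_genotype_quality`` are averaged from FORMAT
    DP/GQ over samples with a non-missing genotype, when those fields are
    present.  Multiallelic records are retained.
    """
    from cyvcf2 import VCF

    _check_vcf_header(vcf_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    calls_rows: list[np.ndarray] = []
    for v in vcf:
        if "GT" not in (v.FORMAT or []):
            raise FormatError(
                f"{vcf_path}: {v.CHROM}:{v.POS}: record has no GT field"
            )
        gts = np.array([g[:2] for g in v.genotypes], dtype=np.int16)
        present = (gts >= 0).all(axis=1)
        mean_depth = None
        mean_gq = None
        for fmt, slot in (("DP", "mean_depth"), ("GQ", "mean_gq")):
            try:
                arr = v.format(fmt)
            except KeyError:
                arr = None
            if arr is not None:
                vals = arr.astype(float).ravel()[: len(samples)]
                ok = present & (vals >= 0) & np.isfinite(vals)
                if ok.any():
                    if fmt == "DP":
                        mean_depth = float(vals[ok].mean())
                    else:
                        mean_gq = float(vals[ok].mean())
        info = {}
        for vcf_key, attr, _ in _INFO_FIELDS:
            val = v.INFO.get(vcf_key)
            info[attr] = float(val) if val is not None else None
        rec = VariantRecord(
            contig_id=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alts=tuple(v.ALT),
            site_quality=float(v.QUAL) if v.QUAL is not None else None,
            mean_depth=mean_depth,
            mean_genotype_quality=mean_gq,
            **info,
        )
        records.append(rec)
        gts[~present] = MISSING
        calls_rows.append(gts)
    if calls_rows:
        calls = np.stack(calls_rows, axis=1)  # (n_samples, n_loci, 2)
    else:
        calls = np.empty((len(samples), 0, 2), dtype=np.int8)
    return records, GenotypeMatrix(samples, records, calls)


def write_variants(
    records: Sequence[VariantRecord],
    matrix: GenotypeMatrix,
    vcf_path,
    genome: Genome | None = None,
    depth: np.ndarray | None = None,
    genotype_quality: np.ndarray | None = None,
) -> None:
    """Write records + genotype matrix as an uncompressed VCF via pysam.

    ``depth``/``genotype_quality`` are optional per-sample integer arrays of
    shape (n_accessions, n_loci) emitted as FORMAT DP/GQ.
    """
    import pysam

    header = pysam.VariantHeader()
    contigs: dict[str, int | None] = {}
    for rec in records:
        if genome is not None and rec.contig_id in genome:
            contigs[rec.contig_id] = genome[rec.contig_id].length
        else:
            contigs.setdefault(rec.contig_id, None)
    for name, length in contigs.items():
        if length is not None:
            header.contigs.add(name, length=length)
        else:
            header.contigs.add(name)
    for vcf_key, _, desc in _INFO_FIELDS:
        header.info.add(vcf_key, 1, "Float", desc)
    header.formats.add("GT", 1, "String", "Genotype")
    if depth is not None:
        header.formats.add("DP", 1, "Integer", "Read depth")
    if genotype_quality is not None:
        header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for s in matrix.accession_ids:
        header.add_sample(s)

    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for j, rec in enumerate(records):
            jj = matrix.locus_index(rec.key)
            vrec = out.new_record(
                contig=rec.contig_id,
                start=rec.pos0,
                alleles=(rec.ref,) + rec.alts,
            )
            if rec.site_quality is not None:
                vrec.qual = rec.site_quality
            for vcf_key, attr, _ in _INFO_FIELDS:
                val = getattr(rec, attr)
                if val is not None:
                    vrec.info[vcf_key] = val
            for i, sample in enumerate(matrix.accession_ids):
                a, b = matrix.calls[i, jj]
                if a == MISSING:
                    vrec.samples[sample]["GT"] = (None, None)
                else:
                    vrec.samples[sample]["GT"] = (int(a), int(b))
                    if depth is not None:
                        vrec.samples[sample]["DP"] = int(depth[i, jj])
                    if genotype_quality is not None:
                        vrec.samples[sample]["GQ"] = int(genotype_quality[i, jj])
            out.write(vrec)


# ---------------------------------------------------------------------------
# Newick / tables
# ---------------------------------------------------------------------------

def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick if newick.endswith("\n") else newick + "\n")
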