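"""Lightweight functional annotation of SNPs against gene models.

Each locus gets exactly one genomic region label, with precedence
CDS > UTR/exon-noncoding > intron > upstream > downstream > intergenic
(a SNP overlapping several genes takes the highest-precedence label;
remaining ties go to the lexicographically smallest gene id).  Upstream
and downstream are strand-aware windows (default 2 kb) beyond the gene
span.  CDS SNPs are further classified by substituting the alternate base
into the affected codon and translating with the standard genetic code.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .model import MISSING, GeneModel, Genome, GenotypeMatrix, VariantRecord

REGION_LABELS = (
    "exonic_cds",
    "UTR_or_exon_noncds",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
)
_PRECEDENCE = {label: i for i, label in enumerate(REGION_LABELS)}

EFFECT_LABELS = ("synonymous", "nonsynonymous", "stop_gain", "stop_loss",
                 "not_coding")


def _region_for_gene(pos0: int, gene: GeneModel, window: int) -> str | None:
    for s, e in gene.cds:
        if s <= pos0 < e:
            return "exonic_cds"
    for s, e in gene.exons:
        if s <= pos0 < e:
            return "UTR_or_exon_noncds"
    if gene.start <= pos0 < gene.end:
        return "intronic"
    if gene.strand == "+":
        up = gene.start - window <= pos0 < gene.start
        down = gene.end <= pos0 < gene.end + window
    else:  # upstream of a minus-strand gene lies at larger coordinates
        up = gene.end <= pos0 < gene.end + window
        down = gene.start - window <= pos0 < gene.start
    if up:
        return "upstream"
    if down:
        return "downstream"
    return None


def classify_region(
    record: VariantRecord,
    gene_models: list[GeneModel],
    regulatory_window: int = 2000,
    return_gene: bool = False,
):
    """Single region label for a SNP (optionally with the deciding gene)."""
    best: tuple[int, str, GeneModel | None] = (len(REGION_LABELS) - 1,
                                               "intergenic", None)
    for gene in gene_models:
        if gene.contig_id != record.contig_id:
            continue
        label = _region_for_gene(record.pos0, gene, regulatory_window)
        if label is None:
            continue
        key = (_PRECEDENCE[label], gene.gene_id)
        if key < (best[0], best[2].gene_id if best[2] else "￿"):
            best = (_PRECEDENCE[label], label, gene)
    if return_gene:
        return best[1], best[2]
    return best[1]


def _cds_coordinate(pos0: int, gene: GeneModel) -> int | None:
    """Offset of a genomic position within the spliced CDS, in
    translation order (None if the position is not coding)."""
    ivs = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    offset = 0
    for s, e in ivs:
        if s <= pos0 < e:
            return offset + (pos0 - s if gene.strand == "+" else e - 1 - pos0)
        offset += e - s
    return None


def _spliced_cds(gene: GeneModel, genome: Genome) -> str:
    seq = genome[gene.contig_id].sequence
    parts = [seq[s:e] for s, e in gene.cds]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def classify_coding_effect(
    record: VariantRecord,
    gene_models: list[GeneModel],
    genome: Genome,
    regulatory_window: int = 2000,
    alt_index: int = 0,
) -> str:
    """Coding-effect label of a CDS SNP (``not_coding`` otherwise)."""
    region, gene = classify_region(record, gene_models, regulatory_window,
                                   return_gene=True)
    if region != "exonic_cds" or gene is None:
        return "not_coding"
    if gene.cds_length % 3 != 0:
        warnings.warn(
            f"CDS length of {gene.gene_id} not divisible by 3; model skipped"
        )
        return "not_coding"
    cpos = _cds_coordinate(record.pos0, gene)
    if cpos is None:
        return "not_coding"
    cds = _spliced_cds(gene, genome)
    alt = record.alts[alt_index]
    base = alt if gene.strand == "+" else str(Seq(alt).complement())
    codon_i = cpos // 3
    ref_codon = cds[codon_i * 3 : codon_i * 3 + 3]
    alt_codon = list(ref_codon)
    alt_codon[cpos % 3] = base
    alt_codon = "".join(alt_codon)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stop_gain"
    if ref_aa == "*":
        return "stop_loss"
    return "nonsynonymous"


# ---------------------------------------------------------------------------
# substitution spectrum
# ---------------------------------------------------------------------------

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass
class SubstitutionSpectrum:
    type_counts: Counter = field(default_factory=Counter)  # directed "C>T"
    transitions: int = 0
    transversions: int = 0
    ts_tv: float | None = None   # None when transversions == 0
    het_count: int = 0
    hom_count: int = 0

    def to_dict(self) -> dict:
        return {
            "type_counts": dict(sorted(self.type_counts.items())),
            "transitions": self.transitions,
            "transversions": self.transversions,
            "ts_tv": self.ts_tv,
            "het_count": self.het_count,
            "hom_count": self.hom_count,
        }


def substitution_spectrum(
    records: list[VariantRecord], matrix: GenotypeMatrix | None = None
) -> SubstitutionSpectrum:
    """Ts/Tv spectrum over biallelic SNPs, plus het/hom call counts.

    Het/hom counts cover non-missing calls carrying at least one alternate
    allele; ``ts_tv`` is left undefined (None) if no transversion occurs.
    """
    spec = SubstitutionSpectrum()
    for rec in records:
        if rec.is_multiallelic or not rec.is_snp:
            continue
        pair = frozenset((rec.ref, rec.alts[0]))
        spec.type_counts[f"{rec.ref}>{rec.alts[0]}"] += 1
        if pair in _TRANSITIONS:
            spec.transitions += 1
        else:
            spec.transversions += 1
        if matrix is not None:
            col = matrix.column(rec.key)
            present = col[:, 0] != MISSING
            carries_alt = present & (col > 0).any(axis=1)
            het = carries_alt & (col[:, 0] != col[:, 1])
            spec.het_count += int(het.sum())
            spec.hom_count += int((carries_alt & ~het).sum())
    if spec.transversions > 0:
        spec.ts_tv = spec.transitions / spec.transversions
    return spec


def annotate_all(
    records: list[VariantRecord],
    gene_models: list[GeneModel],
    genome: Genome,
    regulatory_window: int = 2000,
) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for rec in records:
        region = classify_region(rec, gene_models, regulatory_window)
        effect = (
            classify_coding_effect(rec, gene_models, genome, regulatory_window)
            if region == "exonic_cds"
            else "not_coding"
        )
        rows.append({"marker_id": rec.marker_id, "contig": rec.contig_id,
                     "pos": rec.pos, "region": region, "effect": effect})
    return pd.DataFrame(rows)
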