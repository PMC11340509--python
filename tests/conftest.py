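"""Shared fixtures: hand-built toy matrices and a small simulated panel."""

from __future__ import annotations

import numpy as np
import pytest

from kaspanel import io_formats
from kaspanel.model import GenotypeMatrix, VariantRecord
from kaspanel.synthetic_fixtures import (
    SimulationConfig,
    simulate_population,
    simulate_reference,
)


def make_matrix(genotype_rows, loci=None, ids=None):
    """Build a GenotypeMatrix from rows of allele-letter pairs.

    ``genotype_rows`` is a list (one per accession) of genotype strings like
    "AG", "AA" or ".." (missing); ``loci`` optionally supplies
    (contig, pos, ref, alts) tuples, else loci are auto-generated with the
    observed alleles (first-seen allele becomes ref).
    """
    rows = [
        [row[j : j + 2] for j in range(0, len(row), 2)]
        if isinstance(row, str)
        else list(row)
        for row in genotype_rows
    ]
    n_acc = len(rows)
    n_loci = len(rows[0])
    if loci is None:
        loci = []
        for j in range(n_loci):
            seen = []
            for row in rows:
                for ch in row[j]:
                    if ch != "." and ch not in seen:
                        seen.append(ch)
            ref = seen[0]
            alts = tuple(seen[1:]) if len(seen) > 1 else ("T" if ref != "T" else "C",)
            loci.append(("chr1", 100 * (j + 1), ref, alts))
    records = [
        VariantRecord(contig_id=c, pos=p, ref=r, alts=tuple(a))
        for c, p, r, a in loci
    ]
    calls = np.zeros((n_acc, n_loci, 2), dtype=np.int8)
    for i, row in enumerate(rows):
        for j, gt in enumerate(row):
            if "." in gt:
                calls[i, j] = -1
            else:
                alleles = records[j].alleles
                calls[i, j, 0] = alleles.index(gt[0])
                calls[i, j, 1] = alleles.index(gt[1])
    if ids is None:
        ids = [f"S{i + 1}" for i in range(n_acc)]
    return GenotypeMatrix(ids, records, calls)


SMALL_CONFIG = SimulationConfig(
    seed=5,
    n_accessions=20,
    n_subpops=3,
    n_snps=400,
    n_multiallelic=5,
    n_duplicates=2,
    contig_lengths=(50_000, 50_000),
)


@pytest.fixture(scope="session")
def small_panel(tmp_path_factory):
    """A 20-accession simulated panel with genome, VCF, truth and matrix."""
    outdir = tmp_path_factory.mktemp("small_panel")
    genome, gene_models = simulate_reference(SMALL_CONFIG)
    vcf = outdir / "panel.vcf"
    truth = simulate_population(SMALL_CONFIG, genome, vcf)
    records, matrix = io_formats.read_variants(vcf)
    return {
        "config": SMALL_CONFIG,
        "genome": genome,
        "gene_models": gene_models,
        "vcf": vcf,
        "truth": truth,
        "records": records,
        "matrix": matrix,
        "outdir": outdir,
    }
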