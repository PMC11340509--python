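"""Synthetic reference genome, gene models and structured SNP population.

The generator emulates the shape of a resequenced germplasm panel: 60
dikaryotic accessions drawn from 5 subpopulations, a few-hundred-kilobase
multi-contig reference, biallelic SNPs with GATK-style site QC annotations,
a sprinkle of multiallelic and deliberately QC-failing sites, uniform
missingness, and a couple of cloned accessions that are genuinely
indistinguishable (the hard case for fingerprinting).

Population model: Balding-Nichols.  Each locus has an ancestral allele
frequency p ~ Uniform(0.05, 0.5); each subpopulation draws its own
frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) with F the fixation index
(fst), and diploid genotypes are binomial draws from the subpopulation
frequency.  F -> 0 collapses to a panmictic population.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import write_variants
from .model import GeneModel, Genome, GenomeSequence, GenotypeMatrix, VariantRecord

#: passing / failing draw ranges for the GATK-style site annotations.
#: "pass" ranges sit comfortably inside the hard-filter thresholds; "fail"
#: ranges sit strictly outside them so injected failures are unambiguous.
DEFAULT_QC_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "qd": {"pass": (10.0, 35.0), "fail": (0.2, 1.9)},
    "mq": {"pass": (45.0, 60.0), "fail": (20.0, 39.5)},
    "fs": {"pass": (0.0, 20.0), "fail": (61.0, 120.0)},
    "mq_rank_sum": {"pass": (-3.0, 3.0), "fail": (-25.0, -12.6)},
    "read_pos_rank_sum": {"pass": (-3.0, 3.0), "fail": (-20.0, -8.1)},
    "depth": {"pass": (20, 60)},        # per-sample DP (integers)
    "gq": {"pass": (50, 99)},           # per-sample GQ (integers)
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic panel; defaults mirror the study design
    (60 accessions in 5 subpopulations, moderate differentiation, 5,000
    SNPs over 3 contigs, 2 cloned accessions, 2% missing calls)."""

    seed: int = 17
    n_accessions: int = 60
    n_subpops: int = 5
    fst: float = 0.3
    n_snps: int = 5000
    contig_lengths: tuple[int, ...] = (200_000, 200_000, 200_000)
    missing_rate: float = 0.02
    n_duplicates: int = 2
    n_multiallelic: int = 25
    fail_fraction: float = 0.05
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    qc_field_ranges: dict = field(default_factory=lambda: DEFAULT_QC_RANGES)

    def __post_init__(self) -> None:
        if not self.contig_lengths:
            raise ValueError("at least one contig required")
        if any(l < 1000 for l in self.contig_lengths):
            raise ValueError("contig lengths must be >= 1000 bp")
        if self.n_duplicates >= self.n_accessions:
            raise ValueError("n_duplicates must be < n_accessions")
        if self.n_subpops > self.n_accessions:
            raise ValueError("n_subpops must be <= n_accessions")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class TruthSet:
    """Latent values of a simulated panel, for truth-driven tests."""

    subpop_of: dict[str, int]
    ancestral_freq: list[float]
    subpop_freq: list[list[float]]          # loci x subpops
    expected_het: list[float]               # 2*pbar*(1-pbar), pooled
    duplicate_pairs: list[tuple[str, str]]
    failing_sites: list[str]                # marker ids removed by hard filter
    multiallelic_sites: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        d["duplicate_pairs"] = [tuple(p) for p in d["duplicate_pairs"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# reference genome + gene models
# ---------------------------------------------------------------------------

def simulate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, GenomeSequence], list[GeneModel]]:
    """Random DNA contigs tiled (~40%) with multi-exon genes on both strands.

    Gene models carry short UTR stubs on the terminal exons so that CDS,
    UTR/exon-noncoding, intron and flanking region classes all occur; total
    CDS length is always a multiple of 3.
    """
    rng = np.random.default_rng(config.seed)
    bases = np.array(list("ACGT"))
    genome: dict[str, GenomeSequence] = {}
    models: list[GeneModel] = []
    for ci, length in enumerate(config.contig_lengths):
        contig_id = f"ctg{ci + 1}"
        seq = "".join(rng.choice(bases, size=length))
        genome[contig_id] = GenomeSequence(contig_id, seq)
        cursor = int(rng.integers(500, 2500))
        k = 0
        while True:
            n_ex = int(rng.integers(2, 5))
            exon_lens = rng.integers(150, 600, size=n_ex)
            intron_lens = rng.integers(60, 200, size=n_ex - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            if cursor + span + 500 >= length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            p = cursor
            for i in range(n_ex):
                exons.append((p, p + int(exon_lens[i])))
                p += int(exon_lens[i])
                if i < n_ex - 1:
                    p += int(intron_lens[i])
            utr5 = int(rng.integers(30, 90))
            utr3 = int(rng.integers(30, 90))
            cds = [list(iv) for iv in exons]
            if strand == "+":
                cds[0][0] += utr5
                cds[-1][1] -= utr3
            else:
                cds[-1][1] -= utr5
                cds[0][0] += utr3
            total = sum(e - s for s, e in cds)
            rem = total % 3
            if rem:  # trim the translation 3' end
                if strand == "+":
                    cds[-1][1] -= rem
                else:
                    cds[0][0] += rem
            k += 1
            models.append(
                GeneModel(
                    gene_id=f"g{ci + 1}_{k:03d}",
                    contig_id=contig_id,
                    strand=strand,
                    exons=exons,
                    cds=[tuple(iv) for iv in cds],
                )
            )
            cursor += span + int(rng.integers(1000, 3200))
    return genome, models


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _accession_ids(n: int) -> list[str]:
    return [f"Gf-{i + 1:02d}" for i in range(n)]


def simulate_population(
    config: SimulationConfig, genome: Genome, vcf_path
) -> TruthSet:
    """Simulate the panel and write it as a multi-sample VCF.

    Returns the :class:`TruthSet` of latent frequencies, subpopulation
    memberships, duplicate pairs and injected hard-filter failures.
    Deterministic: the same config yields byte-identical VCF text.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_acc, n_sub = config.n_accessions, config.n_subpops
    n_total = config.n_snps + config.n_multiallelic

    # -- positions ------------------------------------------------------
    contigs = list(genome.values())
    total_len = sum(c.length for c in contigs)
    if n_total > total_len // 2:
        raise ValueError("n_snps exceeds available positions")
    loci_pos: list[tuple[str, int]] = []
    remaining = n_total
    for i, c in enumerate(contigs):
        want = (
            remaining
            if i == len(contigs) - 1
            else int(round(n_total * c.length / total_len))
        )
        want = min(want, remaining)
        pos = np.sort(rng.choice(np.arange(1, c.length + 1), size=want, replace=False))
        loci_pos.extend((c.contig_id, int(p)) for p in pos)
        remaining -= want
    multi_idx = set(
        rng.choice(n_total, size=config.n_multiallelic, replace=False).tolist()
    )
    bi_idx = [i for i in range(n_total) if i not in multi_idx]
    n_fail = int(round(config.fail_fraction * len(bi_idx)))
    fail_idx = set(rng.choice(bi_idx, size=n_fail, replace=False).tolist())

    # -- subpopulations & latent frequencies ----------------------------
    ids = _accession_ids(n_acc)
    sub_sizes = [n_acc // n_sub + (1 if i < n_acc % n_sub else 0) for i in range(n_sub)]
    subpop_of: dict[str, int] = {}
    i = 0
    for s, size in enumerate(sub_sizes):
        for _ in range(size):
            subpop_of[ids[i]] = s
            i += 1

    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=n_total)
    F = config.fst
    if F > 0:
        a = p_anc[:, None] * (1 - F) / F
        b = (1 - p_anc[:, None]) * (1 - F) / F
        p_sub = rng.beta(np.broadcast_to(a, (n_total, n_sub)),
                         np.broadcast_to(b, (n_total, n_sub)))
    else:
        p_sub = np.broadcast_to(p_anc[:, None], (n_total, n_sub)).copy()

    # -- genotypes ------------------------------------------------------
    sub_of_row = np.array([subpop_of[a] for a in ids])
    freq = p_sub[:, sub_of_row].T                      # (n_acc, n_total)
    dosage = rng.binomial(2, freq)                     # alt-allele dosage
    calls = np.zeros((n_acc, n_total, 2), dtype=np.int8)
    calls[:, :, 0] = (dosage == 2).astype(np.int8)
    calls[:, :, 1] = (dosage >= 1).astype(np.int8)

    # triallelic spike-ins: alleles drawn iid from (ref, alt1, alt2) freqs
    for j in sorted(multi_idx):
        p1 = float(p_anc[j])
        p2 = float(rng.uniform(0.05, 0.2))
        probs = np.array([1 - p1 - p2, p1, p2])
        probs /= probs.sum()
        calls[:, j, :] = rng.choice(3, size=(n_acc, 2), p=probs)

    # -- duplicate accessions (exact clones, pre-missingness) -----------
    duplicate_pairs: list[tuple[str, str]] = []
    if config.n_duplicates:
        donors = rng.choice(
            n_acc - config.n_duplicates, size=config.n_duplicates, replace=False
        )
        for d, donor in enumerate(donors):
            clone = n_acc - config.n_duplicates + d
            calls[clone] = calls[int(donor)]
            subpop_of[ids[clone]] = subpop_of[ids[int(donor)]]
            freq[clone] = freq[int(donor)]
            duplicate_pairs.append((ids[int(donor)], ids[clone]))

    # -- missingness ----------------------------------------------------
    miss = rng.random((n_acc, n_total)) < config.missing_rate
    calls[miss] = -1

    # -- per-sample DP/GQ and site QC fields ----------------------------
    qr = config.qc_field_ranges
    dp = rng.integers(qr["depth"]["pass"][0], qr["depth"]["pass"][1] + 1,
                      size=(n_acc, n_total))
    gq = rng.integers(qr["gq"]["pass"][0], qr["gq"]["pass"][1] + 1,
                      size=(n_acc, n_total))
    hard_fields = ["qd", "mq", "fs", "mq_rank_sum", "read_pos_rank_sum"]
    site_info = {
        f: np.round(rng.uniform(*qr[f]["pass"], size=n_total), 2)
        for f in hard_fields
    }
    which_fail = rng.integers(0, len(hard_fields), size=n_total)
    for j in sorted(fail_idx):
        f = hard_fields[which_fail[j]]
        site_info[f][j] = round(float(rng.uniform(*qr[f]["fail"])), 2)
    qual = np.round(rng.uniform(100, 2000, size=n_total), 1)

    # -- records --------------------------------------------------------
    base_order = "ACGT"
    records: list[VariantRecord] = []
    alt_pick = rng.integers(0, 3, size=(n_total, 2))
    for j, (contig, pos) in enumerate(loci_pos):
        ref = genome[contig].sequence[pos - 1]
        others = [b for b in base_order if b != ref]
        if j in multi_idx:
            a1 = others[alt_pick[j, 0]]
            others2 = [b for b in others if b != a1]
            alts = (a1, others2[alt_pick[j, 1] % 2])
        else:
            alts = (others[alt_pick[j, 0]],)
        present = calls[:, j, 0] >= 0
        records.append(
            VariantRecord(
                contig_id=contig,
                pos=pos,
                ref=ref,
                alts=alts,
                site_quality=float(qual[j]),
                qd=float(site_info["qd"][j]),
                mq=float(site_info["mq"][j]),
                fs=float(site_info["fs"][j]),
                mq_rank_sum=float(site_info["mq_rank_sum"][j]),
                read_pos_rank_sum=float(site_info["read_pos_rank_sum"][j]),
                mean_depth=float(dp[present, j].mean()) if present.any() else None,
                mean_genotype_quality=(
                    float(gq[present, j].mean()) if present.any() else None
                ),
            )
        )

    matrix = GenotypeMatrix(ids, records, calls)
    write_variants(records, matrix, vcf_path, genome=genome,
                   depth=dp, genotype_quality=gq)

    pbar = freq.mean(axis=0)  # pooled expected alt frequency per locus
    return TruthSet(
        subpop_of=subpop_of,
        ancestral_freq=[float(x) for x in p_anc],
        subpop_freq=[[float(x) for x in row] for row in p_sub],
        expected_het=[float(2 * p * (1 - p)) for p in pbar],
        duplicate_pairs=duplicate_pairs,
        failing_sites=[f"{c}_{p}" for j, (c, p) in enumerate(loci_pos)
                       if j in fail_idx],
        multiallelic_sites=[f"{c}_{p}" for j, (c, p) in enumerate(loci_pos)
                            if j in multi_idx],
    )
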