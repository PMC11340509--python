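"""The site-filter cascade that turns raw SNP calls into KASP-eligible loci.

Five stages, each a per-locus predicate (so the final survivor set does not
depend on stage order):

1. ``hard_filter``      -- GATK-style annotation thresholds (QD, MQ, FS,
                           MQRankSum, ReadPosRankSum).  An absent field
                           never triggers removal.
2. ``conservation_filter`` -- no *other* called variant within a window
                           either side of the site, judged against the full
                           pre-filter variant set (primer regions must be
                           variant-free regardless of variant quality).
3. ``quality_filter``   -- mean depth, MAF, mean genotype quality
                           (AverageQ) and call rate (integrity).
4. ``uniqueness_filter`` -- the flanking window must map to a single place
                           in the genome (exact-seed k-mer scan with
                           ungapped evaluation of candidate second hits).
5. ``kasp_eligibility_filter`` -- biallelic with PIC above threshold.

All comparators are strict exactly as configured: e.g. FS removal requires
FS strictly above ``fs_max``, MAF retention requires MAF strictly above
``maf_min``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import Genome, GenotypeMatrix, VariantRecord, revcomp
from . import popgen_stats


@dataclass
class FilterThresholds:
    """Cascade thresholds; defaults are the standard hard-filter and
    high-quality-SNP criteria for short-read fungal resequencing panels."""

    qd_min: float = 2.0
    mq_min: float = 40.0
    fs_max: float = 60.0
    mqrs_min: float = -12.5
    rprs_min: float = -8.0
    depth_min: float = 5.0
    maf_min: float = 0.05
    avgq_min: float = 30.0
    integrity_min: float = 0.90
    conservation_window: int = 50
    uniqueness_flank: int = 100
    uniqueness_min_identity: float = 0.90
    uniqueness_min_length: int = 100
    uniqueness_seed: int = 31
    pic_min: float = 0.20


@dataclass
class FilterReport:
    """Telescoping per-stage counts plus each locus' first failing stage."""

    stages: list[dict] = field(default_factory=list)
    first_fail: dict[str, str] = field(default_factory=dict)

    def add_stage(self, name: str, input_count: int, removed: Iterable[str]) -> None:
        removed = list(removed)
        self.stages.append(
            {
                "stage": name,
                "input_count": input_count,
                "removed_count": len(removed),
                "surviving_count": input_count - len(removed),
            }
        )
        for marker_id in removed:
            self.first_fail.setdefault(marker_id, name)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


# ---------------------------------------------------------------------------
# stage predicates
# ---------------------------------------------------------------------------

def _hard_filter_ok(rec: VariantRecord, t: FilterThresholds) -> bool:
    if rec.qd is not None and rec.qd < t.qd_min:
        return False
    if rec.mq is not None and rec.mq < t.mq_min:
        return False
    if rec.fs is not None and rec.fs > t.fs_max:
        return False
    if rec.mq_rank_sum is not None and rec.mq_rank_sum < t.mqrs_min:
        return False
    if rec.read_pos_rank_sum is not None and rec.read_pos_rank_sum < t.rprs_min:
        return False
    return True


def hard_filter(
    records: Sequence[VariantRecord],
    t: FilterThresholds = FilterThresholds(),
    report: FilterReport | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    report = report or FilterReport()
    survivors = [r for r in records if _hard_filter_ok(r, t)]
    report.add_stage(
        "hard_filter", len(records),
        (r.marker_id for r in records if not _hard_filter_ok(r, t)),
    )
    return survivors, report


def quality_filter(
    records: Sequence[VariantRecord],
    matrix: GenotypeMatrix,
    t: FilterThresholds = FilterThresholds(),
    report: FilterReport | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Mean depth, MAF, AverageQ and integrity (call rate) criteria.

    AverageQ is the mean per-sample GQ when FORMAT GQ was present, else the
    site QUAL.  MAF of a multiallelic locus is the frequency of the
    second-most-frequent allele.
    """
    report = report or FilterReport()
    survivors, removed = [], []
    for rec in records:
        j = matrix.locus_index(rec.key)  # KeyError if locus absent
        st = popgen_stats.locus_stats(matrix, j)
        avgq = (
            rec.mean_genotype_quality
            if rec.mean_genotype_quality is not None
            else rec.site_quality
        )
        ok = (
            st.defined
            and (rec.mean_depth is None or rec.mean_depth > t.depth_min)
            and st.maf > t.maf_min
            and (avgq is None or avgq > t.avgq_min)
            and (1.0 - st.missing_rate) > t.integrity_min
        )
        (survivors if ok else removed).append(rec)
    report.add_stage("quality_filter", len(records),
                     (r.marker_id for r in removed))
    return survivors, report


def conservation_filter(
    records: Sequence[VariantRecord],
    all_records: Sequence[VariantRecord] | None = None,
    window: int = 50,
    report: FilterReport | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Keep loci with no other called variant within ``window`` bp.

    ``all_records`` is the full pre-filter variant set to judge against
    (defaults to ``records`` itself)."""
    report = report or FilterReport()
    pool = records if all_records is None else all_records
    by_contig: dict[str, np.ndarray] = {}
    for contig in {r.contig_id for r in pool}:
        by_contig[contig] = np.sort(
            np.array([r.pos for r in pool if r.contig_id == contig])
        )
    survivors, removed = [], []
    for rec in records:
        pos = by_contig[rec.contig_id]
        lo = np.searchsorted(pos, rec.pos - window, side="left")
        hi = np.searchsorted(pos, rec.pos + window, side="right")
        n_in_window = hi - lo  # includes the record itself
        (survivors if n_in_window <= 1 else removed).append(rec)
    report.add_stage("conservation_filter", len(records),
                     (r.marker_id for r in removed))
    return survivors, report


def _kmer_index(genome: Genome, k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for rec in genome.values():
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((rec.contig_id, i))
    return index


def _window_identity(window: str, target: str) -> tuple[float, int]:
    n = min(len(window), len(target))
    if n == 0:
        return 0.0, 0
    matches = sum(a == b for a, b in zip(window[:n], target[:n]))
    return matches / n, n


def uniqueness_filter(
    records: Sequence[VariantRecord],
    genome: Genome,
    flank: int = 100,
    min_identity: float = 0.90,
    min_length: int = 100,
    seed_k: int = 31,
    report: FilterReport | None = None,
    _index: dict | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Remove loci whose flanking window maps to a second genomic location.

    The +-``flank`` window around each SNP (and its reverse complement) is
    scanned with exact ``seed_k``-mers against the genome; each seeded
    candidate placement is evaluated ungapped over the whole window and the
    locus is removed when a non-self placement reaches ``min_identity`` over
    at least ``min_length`` aligned bases.
    """
    report = report or FilterReport()
    index = _index if _index is not None else _kmer_index(genome, seed_k)
    survivors, removed = [], []
    for rec in records:
        if rec.contig_id not in genome:
            raise KeyError(f"contig {rec.contig_id!r} absent from genome")
        seq = genome[rec.contig_id].sequence
        start0 = max(0, rec.pos0 - flank)
        end0 = min(len(seq), rec.pos0 + flank + 1)
        window = seq[start0:end0]
        is_dup = False
        for strand_seq in (window, revcomp(window)):
            if is_dup:
                break
            seen: set[tuple[str, int]] = set()
            for off in range(0, len(strand_seq) - seed_k + 1):
                for contig_hit, g0 in index.get(
                    strand_seq[off : off + seed_k], ()
                ):
                    anchor = (contig_hit, g0 - off)
                    if anchor in seen:
                        continue
                    seen.add(anchor)
                    if strand_seq is window and contig_hit == rec.contig_id \
                            and g0 - off == start0:
                        continue  # the window's own location
                    tstart = g0 - off
                    tseq = genome[contig_hit].sequence
                    lo = max(0, tstart)
                    target = tseq[lo : tstart + len(strand_seq)]
                    query = strand_seq[lo - tstart :]
                    ident, n = _window_identity(query, target)
                    if n >= min_length and ident >= min_identity:
                        is_dup = True
                        break
                if is_dup:
                    break
        (removed if is_dup else survivors).append(rec)
    report.add_stage("uniqueness_filter", len(records),
                     (r.marker_id for r in removed))
    return survivors, report


def kasp_eligibility_filter(
    records: Sequence[VariantRecord],
    stats: dict[str, popgen_stats.LocusStats],
    t: FilterThresholds = FilterThresholds(),
    report: FilterReport | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Keep biallelic loci with PIC strictly above ``pic_min``."""
    report = report or FilterReport()
    survivors, removed = [], []
    for rec in records:
        st = stats[rec.marker_id]
        ok = (not rec.is_multiallelic) and st.defined and st.pic > t.pic_min
        (survivors if ok else removed).append(rec)
    report.add_stage("kasp_eligibility_filter", len(records),
                     (r.marker_id for r in removed))
    return survivors, report


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def run_cascade(
    records: Sequence[VariantRecord],
    matrix: GenotypeMatrix,
    genome: Genome,
    t: FilterThresholds = FilterThresholds(),
) -> tuple[list[VariantRecord], FilterReport]:
    """hard -> conservation -> quality -> uniqueness -> KASP eligibility.

    Conservation is judged against the full input set; per-locus stats for
    the PIC criterion are computed on the post-quality matrix.
    """
    report = FilterReport()
    s1, _ = hard_filter(records, t, report)
    s2, _ = conservation_filter(s1, all_records=records,
                                window=t.conservation_window, report=report)
    s3, _ = quality_filter(s2, matrix, t, report)
    s4, _ = uniqueness_filter(
        s3, genome, flank=t.uniqueness_flank,
        min_identity=t.uniqueness_min_identity,
        min_length=t.uniqueness_min_length,
        seed_k=t.uniqueness_seed, report=report,
    )
    stats = {r.marker_id: popgen_stats.locus_stats(matrix, r.key) for r in s4}
    s5, _ = kasp_eligibility_filter(s4, stats, t, report)
    return s5, report
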