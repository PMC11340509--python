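"""Core data model shared by every pipeline stage.

Coordinate conventions
----------------------
External formats (VCF, GFF3) are 1-based with closed intervals.  Internally
every interval is 0-based half-open and every conversion happens at the I/O
boundary; :class:`VariantRecord` keeps the familiar 1-based ``pos`` (as in a
VCF line) and exposes ``pos0`` for arithmetic.

Genotypes are unordered diploid allele pairs.  Dikaryotic fungal strains are
genotyped diploid-like, so heterozygous/homozygous calls are meaningful;
phase is discarded on input.  Missing calls are encoded as ``(-1, -1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = -1

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One reference contig: id plus upper-case sequence over {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


# A genome is an insertion-ordered mapping contig_id -> GenomeSequence.
Genome = Mapping[str, GenomeSequence]


def as_genome(sequences: Iterable[GenomeSequence]) -> dict[str, GenomeSequence]:
    genome: dict[str, GenomeSequence] = {}
    for rec in sequences:
        if rec.contig_id in genome:
            raise ValueError(f"duplicate contig id {rec.contig_id!r}")
        genome[rec.contig_id] = rec
    return genome


@dataclass
class GeneModel:
    """A protein-coding gene model.

    ``exons`` and ``cds`` are lists of 0-based half-open ``(start, end)``
    intervals in ascending genomic order regardless of strand; translation
    order for minus-strand genes is descending genomic order with each
    segment reverse-complemented.
    """

    gene_id: str
    contig_id: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        for name in ("exons", "cds"):
            ivs = getattr(self, name)
            ivs.sort()
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping {name} in {self.gene_id}")
            if any(s >= e for s, e in ivs):
                raise ValueError(f"empty {name} interval in {self.gene_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class VariantRecord:
    """One SNP locus with its site-level QC annotations.

    ``qd``/``mq``/``fs``/``mq_rank_sum``/``read_pos_rank_sum`` mirror the
    GATK INFO fields of the same names; ``None`` means the field was absent
    in the VCF, which is distinct from any numeric value and is never
    imputed as passing or failing.
    """

    contig_id: str
    pos: int  # 1-based, as printed in the VCF
    ref: str
    alts: tuple[str, ...]
    site_quality: float | None = None
    qd: float | None = None
    mq: float | None = None
    fs: float | None = None
    mq_rank_sum: float | None = None
    read_pos_rank_sum: float | None = None
    mean_depth: float | None = None
    mean_genotype_quality: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.alts:
            raise ValueError(f"{self.key}: no alternate allele")
        if self.ref in self.alts:
            raise ValueError(f"{self.key}: alt equals ref")
        if len(set(self.alts)) != len(self.alts):
            raise ValueError(f"{self.key}: duplicate alt alleles")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig_id, self.pos)

    @property
    def marker_id(self) -> str:
        return f"{self.contig_id}_{self.pos}"

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)


class GenotypeMatrix:
    """Accessions x loci diploid genotype calls with a missing-data mask.

    ``calls`` has shape ``(n_accessions, n_loci, 2)`` holding allele indices
    into each locus' ``(ref,) + alts`` tuple; ``-1`` marks a missing call
    (both slots are ``-1`` together).  Allele order within a call carries no
    meaning.
    """

    def __init__(
        self,
        accession_ids: Sequence[str],
        loci: Sequence[VariantRecord],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(accession_ids), len(loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(accession_ids)} accessions x {len(loci)} loci"
            )
        if len(set(accession_ids)) != len(accession_ids):
            raise ValueError("duplicate accession ids")
        # normalise: any half-missing call becomes fully missing; sort pairs
        miss = (calls < 0).any(axis=2)
        calls = np.sort(calls, axis=2)
        calls[miss] = MISSING
        for j, rec in enumerate(loci):
            hi = calls[:, j, :].max(initial=-1)
            if hi >= len(rec.alleles):
                raise ValueError(
                    f"{rec.marker_id}: allele index {hi} out of range"
                )
        self.accession_ids = list(accession_ids)
        self.loci = list(loci)
        self.calls = calls
        self._locus_index = {rec.key: j for j, rec in enumerate(loci)}
        self._by_marker_id = {rec.marker_id: j for j, rec in enumerate(loci)}

    # -- basic shape ----------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, key) -> int:
        """Index of a locus given ``(contig, pos)``, a marker id, or an int."""
        if isinstance(key, int):
            return key
        if isinstance(key, str):
            return self._by_marker_id[key]
        return self._locus_index[tuple(key)]

    # -- masks and column access ---------------------------------------
    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_accessions, n_loci): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def column(self, key) -> np.ndarray:
        """Calls at one locus, shape (n_accessions, 2)."""
        return self.calls[:, self.locus_index(key), :]

    def allele_counts(self, key) -> np.ndarray:
        """Observed allele counts at a locus over non-missing calls."""
        j = self.locus_index(key)
        col = self.calls[:, j, :].ravel()
        col = col[col >= 0]
        return np.bincount(col, minlength=len(self.loci[j].alleles))

    def allele_freqs(self, key) -> np.ndarray:
        counts = self.allele_counts(key)
        total = counts.sum()
        if total == 0:
            raise ValueError("all calls missing at locus")
        return counts / total

    # -- subsetting ------------------------------------------------------
    def subset_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.accession_ids.index(a) for a in ids]
        return GenotypeMatrix(list(ids), self.loci, self.calls[idx])

    def subset_loci(self, keys: Sequence) -> "GenotypeMatrix":
        idx = [self.locus_index(k) for k in keys]
        return GenotypeMatrix(
            self.accession_ids, [self.loci[j] for j in idx], self.calls[:, idx]
        )

    # -- equality (used by round-trip tests) -----------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and [r.key for r in self.loci] == [r.key for r in other.loci]
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_accessions} accessions x "
            f"{self.n_loci} loci)"
        )
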