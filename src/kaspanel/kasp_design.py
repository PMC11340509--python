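"""KASP assay design: tailed allele-specific forwards + a common reverse.

A KASP (Kompetitive Allele-Specific PCR) assay for a biallelic SNP consists
of two allele-specific forward primers, identical except at their 3'
terminal base (one per allele) and possibly in 5' length, each carrying a
universal fluorescent tail (FAM or VIC/HEX) at the 5' end, plus one common
reverse primer on the opposite strand.  Competitive annealing of the two
forwards at the SNP's 3' base reads out the genotype as a FAM/VIC
fluorescence ratio.

Design constraints follow common practice for short KASP amplicons: primer
cores of 18-30 nt with GC below 60% and nearest-neighbor melting
temperature in 55-61 degC (computed on the untailed core; the universal
tails are excluded), amplicons of at most 120 bp, and no other known
variant under any primer footprint.  Tm uses the SantaLucia unified NN
parameter set at 50 mM monovalent salt and 200 nM primer.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .model import Genome, VariantRecord, revcomp

FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
VIC_TAIL = "GAAGGTCGGAGTCAACGGATT"

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class DesignConstraints:
    gc_max: float = 60.0       # percent, strict upper bound
    tm_min: float = 55.0       # degC, on the untailed core
    tm_max: float = 61.0
    product_max: int = 120     # bp
    primer_len_min: int = 18
    primer_len_max: int = 30
    forbid_variants_under_primers: bool = True

    def __post_init__(self) -> None:
        if self.tm_min >= self.tm_max:
            raise ValueError("tm_min must be below tm_max")


@dataclass
class Primer:
    sequence: str   # tailed for forwards, plain for the reverse
    core: str       # untailed annealing portion
    gc: float
    tm: float


@dataclass
class PrimerSet:
    marker_id: str
    chr_position: str
    allele_pair: str          # e.g. "A/G" (FAM allele first)
    status: str               # "designed" or "failed(<reason>)"
    f1: Primer | None = None  # FAM-tailed, allele-1-specific
    f2: Primer | None = None  # VIC-tailed, allele-2-specific
    r: Primer | None = None   # common reverse
    product_len: int | None = None

    @property
    def designed(self) -> bool:
        return self.status == "designed"


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    """GC percentage of a DNA string (strict ACGT alphabet)."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT characters in {seq!r}")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temp(seq: str) -> float:
    """Nearest-neighbor Tm (degC), SantaLucia unified parameters,
    50 mM Na+, 200 nM primer, no template excess."""
    if len(seq) < 8:
        raise ValueError("sequence shorter than 8 nt")
    return float(
        _mt.Tm_NN(seq.upper(), nn_table=_mt.DNA_NN3, Na=50, dnac1=200,
                  dnac2=0, saltcorr=5)
    )


def _primer(core: str, tail: str = "") -> Primer:
    return Primer(sequence=tail + core, core=core,
                  gc=gc_content(core), tm=melting_temp(core))


def _core_ok(core: str, c: DesignConstraints) -> bool:
    return gc_content(core) < c.gc_max and c.tm_min <= melting_temp(core) <= c.tm_max


def _footprint_clean(
    contig: str, start0: int, end0: int,
    variant_positions: Iterable[tuple[str, int]], target_pos: int,
) -> bool:
    """True when no known variant other than the target lies in
    [start0, end0) (0-based half-open) on the contig."""
    for vc, vp in variant_positions:
        if vc == contig and vp != target_pos and start0 <= vp - 1 < end0:
            return False
    return True


# ---------------------------------------------------------------------------
# assay design
# ---------------------------------------------------------------------------

def design_kasp(
    record: VariantRecord,
    genome: Genome,
    variant_positions: Iterable[tuple[str, int]] = (),
    c: DesignConstraints = DesignConstraints(),
) -> PrimerSet:
    """Design one KASP assay for a biallelic SNP.

    Both allele-specific forwards lie on the plus strand and 3'-terminate
    exactly at the SNP with the respective allele base; their 5' ends are
    chosen independently (shortest length whose core meets the GC/Tm
    constraints and covers no other variant).  The common reverse is the
    first (closest, then shortest) window on the minus strand downstream of
    the SNP meeting all constraints within the amplicon budget.
    Deterministic: identical inputs give identical primers.
    """
    if record.is_multiallelic:
        raise ValueError(f"{record.marker_id}: not biallelic")
    chr_position = record.marker_id
    allele_pair = f"{record.ref}/{record.alts[0]}"
    contig = record.contig_id
    if contig not in genome:
        raise KeyError(f"contig {contig!r} absent from genome")
    seq = genome[contig].sequence
    pos0 = record.pos0
    variant_positions = [tuple(v) for v in variant_positions]
    near = [v for v in variant_positions
            if v[0] == contig and abs(v[1] - record.pos) <= c.product_max + 2]

    def fail(reason: str) -> PrimerSet:
        return PrimerSet(record.marker_id, chr_position, allele_pair,
                         status=f"failed({reason})")

    if pos0 < c.primer_len_min - 1 or pos0 + 1 + c.primer_len_min > len(seq):
        return fail("edge")

    # -- allele-specific forwards --------------------------------------
    forwards: list[Primer] = []
    saw_variant_block = False
    saw_other_block = False
    for allele, tail in zip((record.ref, record.alts[0]), (FAM_TAIL, VIC_TAIL)):
        chosen = None
        for length in range(c.primer_len_min, c.primer_len_max + 1):
            start0 = pos0 - length + 1
            if start0 < 0:
                break
            core = seq[start0:pos0] + allele
            if c.forbid_variants_under_primers and not _footprint_clean(
                contig, start0, pos0 + 1, near, record.pos
            ):
                saw_variant_block = True
                continue
            if not _core_ok(core, c):
                saw_other_block = True
                continue
            chosen = _primer(core, tail)
            break
        if chosen is None:
            if saw_variant_block and not saw_other_block:
                return fail("variant_under_primer")
            return fail("no_forward_primer")
        forwards.append(chosen)
    f1, f2 = forwards
    fwd_start0 = pos0 - max(len(f1.core), len(f2.core)) + 1

    # -- common reverse -------------------------------------------------
    for s0 in range(pos0 + 1, pos0 + c.product_max):
        if s0 + c.primer_len_min - fwd_start0 > c.product_max:
            break
        for length in range(c.primer_len_min, c.primer_len_max + 1):
            e0 = s0 + length
            if e0 > len(seq):
                break
            product_len = e0 - fwd_start0
            if product_len > c.product_max:
                break
            core = revcomp(seq[s0:e0])
            if c.forbid_variants_under_primers and not _footprint_clean(
                contig, s0, e0, near, record.pos
            ):
                continue
            if not _core_ok(core, c):
                continue
            return PrimerSet(
                record.marker_id, chr_position, allele_pair,
                status="designed", f1=f1, f2=f2, r=_primer(core),
                product_len=product_len,
            )
    return fail("no_reverse_site")


def design_panel(
    records: Sequence[VariantRecord],
    genome: Genome,
    variant_positions: Iterable[tuple[str, int]] = (),
    c: DesignConstraints = DesignConstraints(),
) -> list[PrimerSet]:
    vp = [tuple(v) for v in variant_positions]
    return [design_kasp(r, genome, vp, c) for r in records]


def conversion_rate(panel: Sequence[PrimerSet]) -> float:
    """Percent of assays with designed status."""
    if not panel:
        raise ValueError("empty panel")
    return 100.0 * sum(p.designed for p in panel) / len(panel)


def panel_table(panel: Sequence[PrimerSet]) -> pd.DataFrame:
    rows = []
    for p in panel:
        rows.append(
            {
                "marker_id": p.marker_id,
                "chr_position": p.chr_position,
                "allele_pair": p.allele_pair,
                "status": p.status,
                "f1": p.f1.sequence if p.f1 else "",
                "f2": p.f2.sequence if p.f2 else "",
                "r": p.r.sequence if p.r else "",
                "product_len": p.product_len if p.product_len else "",
                "f1_tm": round(p.f1.tm, 2) if p.f1 else "",
                "f2_tm": round(p.f2.tm, 2) if p.f2 else "",
                "r_tm": round(p.r.tm, 2) if p.r else "",
                "f1_gc": round(p.f1.gc, 2) if p.f1 else "",
                "f2_gc": round(p.f2.gc, 2) if p.f2 else "",
                "r_gc": round(p.r.gc, 2) if p.r else "",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published reference panel (structural validation)
# ---------------------------------------------------------------------------

def load_reference_panel() -> pd.DataFrame:
    """The published 12-assay core KASP panel for Grifola frondosa
    cultivar identification (tailed primer sequences as synthesised)."""
    path = importlib.resources.files("kaspanel.data") / "grifola_core_panel.tsv"
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def validate_assay_structure(
    f1: str, f2: str, r: str, allele_pair: str
) -> dict[str, bool]:
    """Structural checks on a tailed KASP assay.

    * the FAM/VIC universal tails prefix the two forwards verbatim;
    * the untailed forwards 3'-terminate in the assay's two alleles —
      directly, or both complemented when the assay was designed on the
      minus strand;
    * apart from the terminal base and 5' length adjustment, the two
      forward cores share their 3'-proximal sequence;
    * the reverse primer is tail-free.
    """
    a1, a2 = allele_pair.split("/")
    checks = {
        "fam_tail": f1.startswith(FAM_TAIL),
        "vic_tail": f2.startswith(VIC_TAIL),
    }
    c1 = f1[len(FAM_TAIL):] if checks["fam_tail"] else f1
    c2 = f2[len(VIC_TAIL):] if checks["vic_tail"] else f2
    ends = (c1[-1], c2[-1])
    checks["terminal_alleles"] = ends == (a1, a2) or ends == (
        _COMP[a1], _COMP[a2]
    )
    s1, s2 = c1[:-1], c2[:-1]
    m = min(len(s1), len(s2))
    checks["shared_core"] = m > 0 and s1[-m:] == s2[-m:]
    checks["reverse_untailed"] = not (
        r.startswith(FAM_TAIL) or r.startswith(VIC_TAIL)
    )
    return checks
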