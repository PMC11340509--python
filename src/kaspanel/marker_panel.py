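"""Candidate screening, identification efficiency, minimal core marker set
selection (greedy set cover with pruning) and DNA fingerprints.

"Identification efficiency" of a marker set is the fraction of all
accession pairs it distinguishes; a pair is distinguished by a marker when
both calls are present and the unordered genotypes differ (a missing call
never distinguishes, so fingerprints stay valid under assay dropout).
Finding the minimum fully-discriminating marker subset is set cover, hence
NP-hard; the selector is greedy maximum coverage followed by a pruning pass
that enforces superset-minimality, with deterministic tie-breaking (higher
PIC, then genomic position).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix
from .popgen_stats import LocusStats


@dataclass
class CandidateScreenCriteria:
    missing_max: float = 0.10
    pic_min: float = 0.30          # preferred; falls back to pic_fallback
    pic_fallback: float = 0.20
    maf_min: float = 0.20
    min_spacing: int = 1000        # bp between kept candidates per contig
    max_per_contig: int | None = None
    target_count: int = 50
    regions: tuple[str, ...] = ("exonic_cds",)


@dataclass
class SaturationCurve:
    marker_order: list[str]
    efficiency: list[float]   # cumulative, non-decreasing

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_markers": range(1, len(self.marker_order) + 1),
             "marker_id": self.marker_order,
             "identification_efficiency": self.efficiency}
        )


@dataclass
class FingerprintTable:
    accession_ids: list[str]
    marker_ids: list[str]
    codes: pd.DataFrame                # accessions x markers, e.g. "A/G", "."
    classes: pd.DataFrame              # "hom" / "het" / "missing"
    identical_groups: list[list[str]]  # indistinguishable accession groups

    @property
    def all_unique(self) -> bool:
        return not self.identical_groups


# ---------------------------------------------------------------------------
# candidate screening
# ---------------------------------------------------------------------------

def screen_candidates(
    stats: dict[str, LocusStats],
    annotations: dict[str, str],
    designed_ids: set[str],
    positions: dict[str, tuple[str, int]],
    c: CandidateScreenCriteria = CandidateScreenCriteria(),
) -> list[str]:
    """Rank designed, in-region markers by PIC under QC criteria.

    ``positions`` maps marker id -> (contig, pos) for spacing enforcement.
    Returns at most ``target_count`` marker ids; if fewer pass, all are
    returned with a warning.
    """

    def passing(pic_min: float) -> list[str]:
        out = []
        for mid in designed_ids:
            st = stats.get(mid)
            if st is None or not st.defined:
                continue
            if annotations.get(mid) not in c.regions:
                continue
            if st.missing_rate > c.missing_max:
                continue
            if st.maf < c.maf_min:
                continue
            if st.pic < pic_min:
                continue
            out.append(mid)
        return out

    chosen_pool = passing(c.pic_min)
    if len(chosen_pool) < c.target_count:
        chosen_pool = passing(c.pic_fallback)
    ranked = sorted(chosen_pool, key=lambda m: (-stats[m].pic, positions[m]))

    kept: list[str] = []
    per_contig: dict[str, int] = {}
    for mid in ranked:
        contig, pos = positions[mid]
        if c.max_per_contig is not None and per_contig.get(contig, 0) >= c.max_per_contig:
            continue
        if any(
            kc == contig and abs(kp - pos) < c.min_spacing
            for kc, kp in (positions[k] for k in kept)
        ):
            continue
        kept.append(mid)
        per_contig[contig] = per_contig.get(contig, 0) + 1
        if len(kept) == c.target_count:
            break
    if len(kept) < c.target_count:
        warnings.warn(
            f"only {len(kept)} candidate markers pass screening "
            f"(target {c.target_count})"
        )
    return kept


# ---------------------------------------------------------------------------
# pair discrimination
# ---------------------------------------------------------------------------

def _pair_id(i: int, k: int, n: int) -> int:
    return i * n + k  # i < k


def discrimination_sets(
    matrix: GenotypeMatrix, marker_ids
) -> dict[str, frozenset[int]]:
    """Per marker, the set of accession pairs it distinguishes."""
    n = matrix.n_accessions
    out: dict[str, frozenset[int]] = {}
    for mid in marker_ids:
        col = matrix.column(mid)
        present = col[:, 0] != MISSING
        pairs = set()
        for i, k in itertools.combinations(range(n), 2):
            if present[i] and present[k] and (
                col[i, 0] != col[k, 0] or col[i, 1] != col[k, 1]
            ):
                pairs.add(_pair_id(i, k, n))
        out[mid] = frozenset(pairs)
    return out


def identification_efficiency(matrix: GenotypeMatrix, marker_ids) -> float:
    """Fraction of all C(n,2) accession pairs resolved by the marker set."""
    n = matrix.n_accessions
    if n == 0:
        raise ValueError("empty accession set")
    total = n * (n - 1) // 2
    if total == 0:
        return 1.0
    marker_ids = list(marker_ids)
    if not marker_ids:
        return 0.0
    resolved: set[int] = set()
    for pairs in discrimination_sets(matrix, marker_ids).values():
        resolved |= pairs
    return len(resolved) / total


# ---------------------------------------------------------------------------
# core marker selection
# ---------------------------------------------------------------------------

def select_core_markers(
    matrix: GenotypeMatrix,
    candidates: list[str],
    pic_of: dict[str, float] | None = None,
) -> tuple[SaturationCurve, list[str], list[tuple[str, str]]]:
    """Greedy maximum-coverage marker selection with a pruning pass.

    Returns the greedy-order saturation curve, the pruned core marker list,
    and the accession pairs no candidate can resolve (e.g. clones).
    Ties among equally-covering markers go to the higher PIC, then the
    smaller (contig, position).
    """
    if not candidates:
        raise ValueError("no candidate markers")
    n = matrix.n_accessions
    pic_of = pic_of or {}
    pos_of = {
        m: matrix.loci[matrix.locus_index(m)].key for m in candidates
    }
    disc = discrimination_sets(matrix, candidates)
    all_pairs = {
        _pair_id(i, k, n) for i, k in itertools.combinations(range(n), 2)
    }
    resolvable = frozenset().union(*disc.values()) if disc else frozenset()
    unresolvable = sorted(all_pairs - resolvable)
    total = len(all_pairs)

    covered: set[int] = set()
    order: list[str] = []
    curve: list[float] = []
    remaining = list(candidates)
    while remaining and covered != set(resolvable):
        best = min(
            remaining,
            key=lambda m: (
                -len(disc[m] - covered),
                -pic_of.get(m, 0.0),
                pos_of[m],
            ),
        )
        gain = len(disc[best] - covered)
        if gain == 0:
            break
        covered |= disc[best]
        order.append(best)
        remaining.remove(best)
        curve.append(len(covered) / total)

    achieved = len(covered) / total

    # prune: drop any marker whose removal keeps coverage at the achieved set
    core = list(order)
    changed = True
    while changed and len(core) > 1:
        changed = False
        for m in sorted(core, key=lambda m: (pic_of.get(m, 0.0), pos_of[m])):
            trial = [x for x in core if x != m]
            cov = set().union(*(disc[x] for x in trial))
            if len(cov) == len(covered):
                core = trial
                changed = True
                break
    core.sort(key=lambda m: pos_of[m])

    pairs_named = [
        (matrix.accession_ids[p // n], matrix.accession_ids[p % n])
        for p in unresolvable
    ]
    return SaturationCurve(order, curve), core, pairs_named


def minimum_core_exhaustive(
    matrix: GenotypeMatrix, candidates: list[str]
) -> tuple[list[str] | None, float]:
    """Smallest fully-discriminating subset by exhaustive search
    (test-scale oracle); returns (subset or None, best efficiency)."""
    disc = discrimination_sets(matrix, candidates)
    resolvable = frozenset().union(*disc.values()) if disc else frozenset()
    n = matrix.n_accessions
    total = n * (n - 1) // 2
    best_eff = len(resolvable) / total if total else 1.0
    full = len(resolvable) == total
    for size in range(1, len(candidates) + 1):
        for sub in itertools.combinations(candidates, size):
            cov = set().union(*(disc[m] for m in sub))
            if full and len(cov) == total:
                return list(sub), 1.0
            if not full and len(cov) == len(resolvable):
                return list(sub), best_eff
    return None, best_eff


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

def build_fingerprint(
    matrix: GenotypeMatrix, core_markers: list[str]
) -> FingerprintTable:
    """Genotype-code table at the core markers plus a uniqueness report.

    Codes are "X/Y" with alleles in alphabetical order and "." for missing.
    The uniqueness report groups accessions that the marker set cannot tell
    apart (identical wherever both calls are present), so rows are unique
    exactly when identification efficiency is 1.
    """
    if not core_markers:
        raise ValueError("empty marker list")
    sub = matrix.subset_loci(core_markers)
    codes = np.empty((sub.n_accessions, sub.n_loci), dtype=object)
    classes = np.empty_like(codes)
    for j, rec in enumerate(sub.loci):
        alleles = rec.alleles
        for i in range(sub.n_accessions):
            a, b = sub.calls[i, j]
            if a == MISSING:
                codes[i, j], classes[i, j] = ".", "missing"
            else:
                pair = sorted((alleles[a], alleles[b]))
                codes[i, j] = f"{pair[0]}/{pair[1]}"
                classes[i, j] = "hom" if a == b else "het"
    ids = sub.accession_ids
    marker_ids = [r.marker_id for r in sub.loci]

    # indistinguishable groups under the missing-never-distinguishes rule
    n = sub.n_accessions
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    present = sub.calls[:, :, 0] != MISSING
    for i, k in itertools.combinations(range(n), 2):
        both = present[i] & present[k]
        same = (sub.calls[i, :, 0] == sub.calls[k, :, 0]) & (
            sub.calls[i, :, 1] == sub.calls[k, :, 1]
        )
        if not np.any(both & ~same):
            parent[find(i)] = find(k)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ids[i])
    identical = sorted(g for g in groups.values() if len(g) > 1)

    return FingerprintTable(
        accession_ids=list(ids),
        marker_ids=marker_ids,
        codes=pd.DataFrame(codes, index=ids, columns=marker_ids),
        classes=pd.DataFrame(classes, index=ids, columns=marker_ids),
        identical_groups=identical,
    )


#: Fig-6-style colour semantics for the fingerprint grid.
FINGERPRINT_COLOURS = {
    "C/C": "#f2d43f",  # yellow
    "A/A": "#58a85c",  # green
    "T/T": "#4a7fd4",  # blue
    "G/G": "#8d5bb8",  # purple
    "het": "#9c9c9c",  # grey
    "missing": "#ffffff",
}


def render_fingerprint(table: FingerprintTable, path) -> None:
    """Render the fingerprint grid as an image (homozygote classes in
    their genotype colours, heterozygotes grey, missing white)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    keys = ["missing", "A/A", "C/C", "G/G", "T/T", "het"]
    lut = {k: i for i, k in enumerate(keys)}
    grid = np.zeros((len(table.marker_ids), len(table.accession_ids)), dtype=int)
    for i, acc in enumerate(table.accession_ids):
        for j, mid in enumerate(table.marker_ids):
            code = table.codes.loc[acc, mid]
            cls = table.classes.loc[acc, mid]
            key = code if cls == "hom" else cls
            grid[j, i] = lut.get(key, lut["het"])
    cmap = ListedColormap([FINGERPRINT_COLOURS.get(k, "#9c9c9c") for k in keys])
    fig, ax = plt.subplots(
        figsize=(max(4, len(table.accession_ids) * 0.18),
                 max(2, len(table.marker_ids) * 0.3))
    )
    ax.imshow(grid, cmap=cmap, vmin=0, vmax=len(keys) - 1, aspect="auto")
    ax.set_xticks(range(len(table.accession_ids)))
    ax.set_xticklabels(table.accession_ids, rotation=90, fontsize=5)
    ax.set_yticks(range(len(table.marker_ids)))
    ax.set_yticklabels(table.marker_ids, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
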