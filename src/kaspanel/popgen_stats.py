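"""Per-locus diversity statistics, genetic distance, NJ trees and PCA.

The index set is the classic marker-diversity battery: observed (Na) and
effective (Ne = 1/Sum p^2) allele numbers, observed heterozygosity (Ho),
expected heterozygosity / Nei's gene diversity (He = H = 1 - Sum p^2,
uncorrected), Shannon's information index (I = -Sum p ln p), and Botstein's
polymorphic information content

    PIC = 1 - Sum_i p_i^2 - Sum_{i<j} 2 p_i^2 p_j^2 .

Pairwise genetic distance is one minus the allele-sharing proportion
(identity-by-state over unordered diploid genotypes) with pairwise deletion
of missing calls.  Trees use the Saitou-Nei neighbor-joining agglomeration;
PCA operates on mean-imputed, column-centred alt-allele dosages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------

def pic(allele_freqs) -> float:
    """Polymorphic information content of one locus.

    ``allele_freqs`` is a sequence (or dict) of allele frequencies that must
    sum to 1 within 1e-6.
    """
    if isinstance(allele_freqs, dict):
        p = np.asarray(list(allele_freqs.values()), dtype=float)
    else:
        p = np.asarray(list(allele_freqs), dtype=float)
    if p.size == 0 or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"allele frequencies must sum to 1, got {p.sum()!r}")
    p2 = p**2
    cross = (p2.sum() ** 2 - (p2**2).sum())  # 2 * Sum_{i<j} p_i^2 p_j^2
    return float(1.0 - p2.sum() - cross)


@dataclass
class LocusStats:
    marker_id: str
    maf: float
    na: int
    ne: float
    ho: float
    he: float
    shannon_i: float
    nei_h: float
    pic: float
    missing_rate: float
    allele_freqs: dict[str, float]
    defined: bool = True


def locus_stats(matrix: GenotypeMatrix, locus) -> LocusStats:
    """All diversity indices at one locus, from non-missing calls only."""
    j = matrix.locus_index(locus)
    rec = matrix.loci[j]
    col = matrix.calls[:, j, :]
    present = col[:, 0] != MISSING
    n = int(present.sum())
    missing_rate = 1.0 - n / matrix.n_accessions
    if n == 0:
        nan = float("nan")
        return LocusStats(
            marker_id=rec.marker_id, maf=nan, na=0, ne=nan, ho=nan, he=nan,
            shannon_i=nan, nei_h=nan, pic=nan, missing_rate=missing_rate,
            allele_freqs={}, defined=False)
    counts = np.bincount(col[present].ravel(), minlength=len(rec.alleles))
    freqs = counts / counts.sum()
    nz = freqs[freqs > 0]
    he = float(1.0 - (freqs**2).sum())
    ho = float((col[present, 0] != col[present, 1]).mean())
    sorted_f = np.sort(freqs)[::-1]
    maf = float(sorted_f[1]) if len(sorted_f) > 1 else 0.0
    return LocusStats(
        marker_id=rec.marker_id,
        maf=maf,
        na=int((counts > 0).sum()),
        ne=float(1.0 / (freqs**2).sum()),
        ho=ho,
        he=he,
        shannon_i=float(-(nz * np.log(nz)).sum()),
        nei_h=he,
        pic=pic(freqs),
        missing_rate=missing_rate,
        allele_freqs={a: float(f) for a, f in zip(rec.alleles, freqs)},
    )


def all_locus_stats(matrix: GenotypeMatrix) -> list[LocusStats]:
    return [locus_stats(matrix, j) for j in range(matrix.n_loci)]


def stats_table(stats: list[LocusStats]) -> pd.DataFrame:
    rows = [
        {k: getattr(s, k) for k in
         ("marker_id", "maf", "na", "ne", "ho", "he", "shannon_i",
          "nei_h", "pic", "missing_rate")}
        for s in stats
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    accession_ids: list[str]
    values: np.ndarray       # symmetric, zero diagonal, entries in [0, 1]
    pairwise_n: np.ndarray   # loci compared per pair

    def dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accession_ids,
                            columns=self.accession_ids)


def distance_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing distance d = 1 - IBS with pairwise deletion.

    Per locus the shared proportion of two unordered genotypes is the
    multiset-intersection size of their allele pairs divided by 2
    (AA vs AA -> 1, AA vs AG -> 0.5, AA vs GG -> 0).
    """
    n = matrix.n_accessions
    if n < 2:
        raise ValueError("need at least two accessions")
    calls = matrix.calls
    present = calls[:, :, 0] != MISSING
    values = np.zeros((n, n))
    pairwise_n = np.zeros((n, n), dtype=int)
    for i in range(n):
        a1, a2 = calls[i, :, 0], calls[i, :, 1]
        for k in range(i + 1, n):
            ok = present[i] & present[k]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable loci for pair "
                    f"({matrix.accession_ids[i]}, {matrix.accession_ids[k]})"
                )
            b1, b2 = calls[k, :, 0], calls[k, :, 1]
            straight = (a1 == b1).astype(np.int8) + (a2 == b2)
            crossed = (a1 == b2).astype(np.int8) + (a2 == b1)
            shared = np.maximum(straight, crossed)[ok] / 2.0
            d = 1.0 - shared.mean()
            values[i, k] = values[k, i] = d
            pairwise_n[i, k] = pairwise_n[k, i] = m
    np.fill_diagonal(pairwise_n, matrix.n_loci)
    return DistanceMatrix(list(matrix.accession_ids), values, pairwise_n)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _fmt_branch(x: float) -> str:
    return f"{x:.12g}"


def nj_tree(dist: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister edge (total path length preserved), the standard fix-up.
    """
    D = np.array(dist.values, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    labels = [str(x) for x in dist.accession_ids]
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    if n == 2:
        h = D[0, 1] / 2.0
        return f"({labels[0]}:{_fmt_branch(h)},{labels[1]}:{_fmt_branch(h)});"

    nodes = list(labels)  # current newick fragment per active node
    active = list(range(n))
    D = D.copy()
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        fi, fj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = dij / 2.0 + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, transferring the deficit to the sister edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = f"({nodes[fi]}:{_fmt_branch(li)},{nodes[fj]}:{_fmt_branch(lj)})"
        # distances from the new node u to every remaining k
        du = {}
        for k_ in active:
            if k_ in (fi, fj):
                continue
            du[k_] = 0.5 * (D[fi, k_] + D[fj, k_] - dij)
        u = fi  # reuse slot fi for the merged node
        nodes[u] = new
        for k_, v in du.items():
            D[u, k_] = D[k_, u] = max(v, 0.0)
        D[u, u] = 0.0
        active.remove(fj)
    a, b = active
    h = D[a, b]
    return f"({nodes[a]}:{_fmt_branch(h / 2)},{nodes[b]}:{_fmt_branch(h / 2)});"


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    accession_ids: list[str]
    coordinates: np.ndarray       # accessions x components
    variance_fraction: np.ndarray # over ALL components, sums to 1

    def dataframe(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.accession_ids,
                            columns=cols)


def dosage_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    """Alt-allele dosage in {0, 1, 2} with NaN for missing calls."""
    calls = matrix.calls
    dos = (calls > 0).sum(axis=2).astype(float)
    dos[calls[:, :, 0] == MISSING] = np.nan
    return dos


def pca(matrix: GenotypeMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of mean-imputed, column-centred genotype dosages.

    Components are ordered by decreasing explained variance; the variance
    fractions cover all components and sum to one.
    """
    if matrix.n_accessions < 2:
        raise ValueError("need at least two accessions")
    dos = dosage_matrix(matrix)
    col_mean = np.nanmean(dos, axis=0)
    inds = np.where(np.isnan(dos))
    dos[inds] = np.take(col_mean, inds[1])
    centred = dos - dos.mean(axis=0)
    if not np.any(centred != 0):
        raise ValueError("no polymorphic loci")
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    coords = u * s
    var = s**2
    frac = var / var.sum()
    if n_components is not None:
        coords = coords[:, :n_components]
    return PCAResult(list(matrix.accession_ids), coords, frac)
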