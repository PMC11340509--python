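"""Core germplasm collection: pick a maximally diverse accession subset.

The selector is a deterministic heuristic for the entry-to-nearest-entry
objective used by standard core-collection software: maximise the mean
distance from each selected accession to its nearest selected neighbour.
Greedy max-min seeding (start from the farthest pair, then repeatedly add
the accession farthest from the current set) is refined by steepest-ascent
single-swap local search until no swap improves the objective.  All ties
break on accession id order, so a fixed input yields a fixed core.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .model import MISSING, GenotypeMatrix
from .popgen_stats import DistanceMatrix, all_locus_stats, distance_matrix


@dataclass
class CoreSet:
    selected: list[str]
    ratio: float
    objective_value: float
    seed: int = 0


@dataclass
class CoreEvaluation:
    allele_coverage: float
    allele_coverage_min2: float   # ignoring singleton private alleles
    core_indices: dict[str, float]
    full_indices: dict[str, float]
    index_ratios: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "allele_coverage": self.allele_coverage,
            "allele_coverage_min2": self.allele_coverage_min2,
            "core_indices": self.core_indices,
            "full_indices": self.full_indices,
            "index_ratios": self.index_ratios,
        }


def core_objective(dist: np.ndarray, idx: list[int]) -> float:
    """Mean entry-to-nearest-entry distance of the selection ``idx``."""
    if len(idx) < 2:
        return 0.0
    sub = dist[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _core_size(ratio: float, n: int) -> int:
    return int(np.floor(ratio * n + 0.5))


def select_core(
    matrix: GenotypeMatrix,
    ratio: float,
    seed: int = 0,
    dist: DistanceMatrix | None = None,
) -> CoreSet:
    """Select ``round(ratio * n)`` accessions maximising diversity."""
    if not 0 < ratio <= 1:
        raise ValueError("ratio must lie in (0, 1]")
    n = matrix.n_accessions
    k = _core_size(ratio, n)
    if k < 2:
        raise ValueError(f"ratio {ratio} yields a core of {k} < 2 accessions")
    dm = dist if dist is not None else distance_matrix(matrix)
    D = dm.values
    ids = dm.accession_ids

    if k == n:
        return CoreSet(list(ids), ratio, core_objective(D, list(range(n))), seed)

    def complete_and_polish(start: list[int]) -> tuple[float, list[int]]:
        """Greedy farthest-from-set completion + steepest-ascent swaps."""
        selected = list(start)
        outside = [i for i in range(n) if i not in selected]
        while len(selected) < k:
            gains = [(D[i, selected].min(), ids[i], i) for i in outside]
            gains.sort(key=lambda g: (-g[0], g[1]))
            pick = gains[0][2]
            selected.append(pick)
            outside.remove(pick)
        obj = core_objective(D, selected)
        improved = True
        while improved:
            improved = False
            best = (obj, None)
            for si, s in enumerate(selected):
                for o in outside:
                    trial = selected.copy()
                    trial[si] = o
                    val = core_objective(D, trial)
                    if val > best[0] + 1e-12:
                        best = (val, (si, s, o))
            if best[1] is not None:
                si, s, o = best[1]
                selected[si] = o
                outside[outside.index(o)] = s
                obj = best[0]
                improved = True
        return obj, selected

    # multi-start: seed the search from the farthest pairs (all pairs on
    # small panels; the top pairs otherwise) to escape single-start optima
    pairs = sorted(
        itertools.combinations(range(n), 2),
        key=lambda ij: (-D[ij], ids[ij[0]], ids[ij[1]]),
    )
    n_starts = len(pairs) if n <= 16 else 8
    best_obj, best_sel = -1.0, None
    for start in pairs[:n_starts]:
        obj, sel = complete_and_polish(list(start))
        key = sorted(ids[i] for i in sel)
        if obj > best_obj + 1e-12 or (
            abs(obj - best_obj) <= 1e-12 and key < best_sel
        ):
            best_obj, best_sel = obj, key
    return CoreSet(best_sel, ratio, best_obj, seed)


def exhaustive_core(matrix_or_dist, k: int) -> tuple[list[str], float]:
    """Brute-force optimum of the same objective (test-scale oracle)."""
    if isinstance(matrix_or_dist, GenotypeMatrix):
        dm = distance_matrix(matrix_or_dist)
    else:
        dm = matrix_or_dist
    D, ids = dm.values, dm.accession_ids
    best_val, best_sub = -1.0, None
    for sub in itertools.combinations(range(len(ids)), k):
        val = core_objective(D, list(sub))
        if val > best_val + 1e-12:
            best_val, best_sub = val, sub
    return [ids[i] for i in best_sub], best_val


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _allele_census(matrix: GenotypeMatrix) -> dict[tuple[int, int], int]:
    """Counts of (locus, allele-index) observations over non-missing calls."""
    census: dict[tuple[int, int], int] = {}
    for j in range(matrix.n_loci):
        col = matrix.calls[:, j, :].ravel()
        col = col[col != MISSING]
        for allele, count in zip(*np.unique(col, return_counts=True)):
            census[(j, int(allele))] = int(count)
    return census


_INDEX_FIELDS = ("na", "ne", "shannon_i", "ho", "he", "pic", "nei_h")


def evaluate_core(matrix: GenotypeMatrix, core: CoreSet) -> CoreEvaluation:
    """Diversity indices and allele coverage of a core vs the full panel."""
    if not core.selected:
        raise ValueError("empty core")
    missing = set(core.selected) - set(matrix.accession_ids)
    if missing:
        raise ValueError(f"core accessions not in matrix: {sorted(missing)}")
    sub = matrix.subset_accessions(core.selected)
    full_census = _allele_census(matrix)
    core_census = _allele_census(sub)
    covered = sum(1 for key in full_census if key in core_census)
    coverage = covered / len(full_census) if full_census else 1.0
    common = {key for key, cnt in full_census.items() if cnt >= 2}
    covered2 = sum(1 for key in common if key in core_census)
    coverage2 = covered2 / len(common) if common else 1.0

    def mean_indices(m: GenotypeMatrix) -> dict[str, float]:
        stats = [s for s in all_locus_stats(m) if s.defined]
        return {
            f: float(np.mean([getattr(s, f) for s in stats])) for f in _INDEX_FIELDS
        }

    core_idx = mean_indices(sub)
    full_idx = mean_indices(matrix)
    ratios = {
        f: (core_idx[f] / full_idx[f] if full_idx[f] else float("nan"))
        for f in _INDEX_FIELDS
    }
    return CoreEvaluation(coverage, coverage2, core_idx, full_idx, ratios)


def ratio_sweep(
    matrix: GenotypeMatrix,
    ratios=tuple(r / 100 for r in range(5, 100, 5)),
    seed: int = 0,
) -> list[tuple[CoreSet, CoreEvaluation]]:
    """The classic 5%..95% sampling-ratio sweep (step 5)."""
    dm = distance_matrix(matrix)
    out = []
    for ratio in ratios:
        if _core_size(ratio, matrix.n_accessions) < 2:
            continue
        cs = select_core(matrix, ratio, seed=seed, dist=dm)
        out.append((cs, evaluate_core(matrix, cs)))
    return out
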