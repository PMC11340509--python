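"""Diversity indices, allele-sharing distance, NJ reconstruction and PCA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_matrix
from kaspanel.popgen_stats import (
    DistanceMatrix,
    distance_matrix,
    locus_stats,
    nj_tree,
    pca,
    pic,
)


class TestPic:
    @pytest.mark.parametrize(
        "freqs,expected",
        [([0.5, 0.5], 0.375), ([1.0], 0.0), ([0.8, 0.2], 0.2688)],
    )
    def test_values(self, freqs, expected):
        assert pic(freqs) == pytest.approx(expected, abs=1e-9)

    def test_rejects_non_simplex(self):
        with pytest.raises(ValueError):
            pic([0.5, 0.4])

    def test_accepts_dict(self):
        assert pic({"A": 0.5, "G": 0.5}) == pytest.approx(0.375)

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5))
    @settings(derandomize=True, max_examples=200)
    def test_bounded_by_expected_heterozygosity(self, raw):
        p = np.array(raw) / np.sum(raw)
        he = 1 - (p**2).sum()
        val = pic(p)
        assert -1e-12 <= val <= he + 1e-12

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5))
    @settings(derandomize=True, max_examples=100)
    def test_permutation_symmetric(self, raw):
        p = np.array(raw) / np.sum(raw)
        rng = np.random.default_rng(0)
        assert pic(p) == pytest.approx(pic(rng.permutation(p)), abs=1e-12)

    def test_biallelic_maximum_at_half(self):
        grid = [pic([q, 1 - q]) for q in np.linspace(0.05, 0.95, 19)]
        assert max(grid) == pytest.approx(pic([0.5, 0.5]))


class TestLocusStats:
    def test_all_het_column(self):
        m = make_matrix(["AG"] * 6, loci=[("chr1", 100, "A", ("G",))])
        s = locus_stats(m, 0)
        assert s.ho == pytest.approx(1.0)
        assert s.he == pytest.approx(0.5)
        assert s.ne == pytest.approx(2.0)
        assert s.shannon_i == pytest.approx(math.log(2), abs=1e-4)
        assert s.pic == pytest.approx(0.375)
        assert s.nei_h == s.he

    def test_monomorphic_column(self):
        m = make_matrix(["AA"] * 5, loci=[("chr1", 100, "A", ("G",))])
        s = locus_stats(m, 0)
        assert (s.na, s.ho, s.he, s.shannon_i, s.pic) == (1, 0, 0, 0, 0)

    def test_skewed_frequencies(self):
        # freqs 0.8 / 0.2
        m = make_matrix(["AA"] * 3 + ["AG"] * 2, loci=[("chr1", 100, "A", ("G",))])
        s = locus_stats(m, 0)
        assert s.he == pytest.approx(0.32)
        assert s.ne == pytest.approx(1.4706, abs=1e-4)
        assert s.shannon_i == pytest.approx(0.5004, abs=1e-4)
        assert s.maf == pytest.approx(0.2)

    def test_all_missing_flagged_undefined(self):
        m = make_matrix([".."] * 3, loci=[("chr1", 100, "A", ("G",))])
        assert not locus_stats(m, 0).defined

    def test_missing_rate_and_pairwise_exclusion(self):
        m = make_matrix(["AA", "AG", ".."], loci=[("chr1", 100, "A", ("G",))])
        s = locus_stats(m, 0)
        assert s.missing_rate == pytest.approx(1 / 3)
        assert s.maf == pytest.approx(0.25)


class TestDistance:
    def test_identical_rows_zero(self):
        m = make_matrix(["AGCA", "AGCA"])
        d = distance_matrix(m)
        assert d.values[0, 1] == 0.0

    def test_opposite_homozygotes_one(self):
        m = make_matrix(["AA", "GG"], loci=[("chr1", 100, "A", ("G",))])
        assert distance_matrix(m).values[0, 1] == 1.0

    def test_hom_vs_het_half(self):
        m = make_matrix(["AA", "AG"], loci=[("chr1", 100, "A", ("G",))])
        assert distance_matrix(m).values[0, 1] == 0.5

    def test_shared_allele_across_different_hets(self):
        # AG vs GT share exactly one allele (G) -> 0.5
        m = make_matrix(["AG", "GT"], loci=[("chr1", 100, "A", ("G", "T"))])
        assert distance_matrix(m).values[0, 1] == 0.5

    def test_missing_excluded_pairwise(self):
        m = make_matrix(
            ["AA..", "AAAA"],
            loci=[("chr1", 100, "A", ("G",)), ("chr1", 200, "A", ("G",))],
        )
        d = distance_matrix(m)
        assert d.pairwise_n[0, 1] == 1
        assert d.values[0, 1] == 0.0

    def test_no_comparable_loci_errors(self):
        m = make_matrix(["AA..", "..AA"],
                        loci=[("chr1", 100, "A", ("G",)),
                              ("chr1", 200, "A", ("G",))])
        with pytest.raises(ValueError, match="S1"):
            distance_matrix(m)


def _patristic(newick):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return taxa, pdm


class TestNeighborJoining:
    def test_two_taxa_midpoint(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]),
                           np.ones((2, 2), dtype=int))
        assert nj_tree(d) == "(A:0.2,B:0.2);"

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        D = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float
        )
        d = DistanceMatrix(list("ABCD"), D, np.ones((4, 4), dtype=int))
        taxa, pdm = _patristic(nj_tree(d))
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert pdm.patristic_distance(
                        taxa[a], taxa[b]
                    ) == pytest.approx(D[i, j], abs=1e-9)

    def test_three_identical_taxa_star(self):
        d = DistanceMatrix(list("ABC"), np.zeros((3, 3)),
                           np.ones((3, 3), dtype=int))
        nwk = nj_tree(d)
        taxa, pdm = _patristic(nwk)
        assert pdm.patristic_distance(taxa["A"], taxa["B"]) == 0.0

    def test_rejects_asymmetric_matrix(self):
        bad = DistanceMatrix(["A", "B"], np.array([[0, 1.0], [0.5, 0]]),
                             np.ones((2, 2), dtype=int))
        with pytest.raises(ValueError):
            nj_tree(bad)

    def test_matches_scikit_bio_on_additive_matrix(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        D, labels = random_additive_matrix(np.random.default_rng(7), 8)
        ours = nj_tree(DistanceMatrix(labels, D, np.ones_like(D, dtype=int)))
        theirs = skbio_nj(SkbioDM(D, ids=labels)).__str__()
        taxa_a, pdm_a = _patristic(ours)
        taxa_b, pdm_b = _patristic(theirs)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm_a.patristic_distance(
                        taxa_a[a], taxa_a[b]
                    ) == pytest.approx(
                        pdm_b.patristic_distance(taxa_b[a], taxa_b[b]),
                        abs=1e-9,
                    )


def random_additive_matrix(rng, n_taxa):
    """Leaf-to-leaf path lengths of a random binary tree with positive
    branch lengths (the generating-tree oracle for NJ)."""
    labels = [f"T{i}" for i in range(n_taxa)]
    nodes = list(range(n_taxa))
    parent: dict[int, tuple[int, float]] = {}
    nxt = n_taxa
    while len(nodes) > 1:
        i = rng.integers(len(nodes))
        a = nodes.pop(int(i))
        j = rng.integers(len(nodes))
        b = nodes.pop(int(j))
        for child in (a, b):
            parent[child] = (nxt, float(rng.uniform(0.1, 1.0)))
        nodes.append(nxt)
        nxt += 1

    def path_to_root(x):
        out = {}
        d = 0.0
        while x in parent:
            x, w = parent[x][0], parent[x][1]
            d += w
            out[x] = d
        return out

    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        pi = path_to_root(i)
        for j in range(i + 1, n_taxa):
            pj = path_to_root(j)
            best = min(pi[k] + pj[k] for k in pi if k in pj)
            D[i, j] = D[j, i] = best
    return D, labels


def test_nj_recovers_random_additive_trees():
    """On additive distances the NJ tree's patristic distances equal the
    input exactly, which (with positive branch lengths) pins the topology
    to the generating tree."""
    rng = np.random.default_rng(42)
    for trial in range(20):
        n = int(rng.integers(5, 13))
        D, labels = random_additive_matrix(rng, n)
        nwk = nj_tree(DistanceMatrix(labels, D, np.ones_like(D, dtype=int)))
        taxa, pdm = _patristic(nwk)
        for i in range(n):
            for j in range(i + 1, n):
                assert pdm.patristic_distance(
                    taxa[labels[i]], taxa[labels[j]]
                ) == pytest.approx(D[i, j], abs=1e-8)


class TestPca:
    def test_rank_one_matrix(self):
        m = make_matrix(["AA", "AG", "GG"], loci=[("chr1", 100, "A", ("G",))])
        res = pca(m)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_duplicated_accessions_coincide(self):
        m = make_matrix(["AGGA", "AGGA", "GGAA", "AAGG"])
        res = pca(m)
        assert np.allclose(res.coordinates[0], res.coordinates[1])

    def test_variance_fractions_sum_to_one(self, small_panel):
        res = pca(small_panel["matrix"])
        assert res.variance_fraction.sum() == pytest.approx(1.0)

    def test_no_polymorphism_errors(self):
        m = make_matrix(["AA", "AA"], loci=[("chr1", 100, "A", ("G",))])
        with pytest.raises(ValueError):
            pca(m)

    def test_subpopulations_separate_on_pc1(self, small_panel):
        res = pca(small_panel["matrix"])
        truth = small_panel["truth"]
        ids = res.accession_ids
        groups = {}
        for i, a in enumerate(ids):
            groups.setdefault(truth.subpop_of[a], []).append(
                res.coordinates[i, 0]
            )
        centroids = {g: np.mean(v) for g, v in groups.items()}
        spread = np.mean([np.std(v) for v in groups.values()])
        seps = [
            abs(centroids[a] - centroids[b])
            for a in centroids for b in centroids if a < b
        ]
        assert np.mean(seps) > spread
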