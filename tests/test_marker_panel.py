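"""Candidate screening, identification efficiency, greedy set-cover marker
selection vs the exhaustive oracle, and fingerprints."""

import itertools

import numpy as np
import pytest

from conftest import make_matrix
from kaspanel.marker_panel import (
    CandidateScreenCriteria,
    build_fingerprint,
    discrimination_sets,
    identification_efficiency,
    minimum_core_exhaustive,
    screen_candidates,
    select_core_markers,
)
from kaspanel.popgen_stats import LocusStats


def stats_stub(marker_id, pic=0.35, maf=0.3, missing=0.0):
    return LocusStats(
        marker_id=marker_id, maf=maf, na=2, ne=2.0, ho=0.5, he=0.5,
        shannon_i=0.69, nei_h=0.5, pic=pic, missing_rate=missing,
        allele_freqs={},
    )


class TestScreenCandidates:
    CRIT = CandidateScreenCriteria(target_count=3, min_spacing=1000)

    def _inputs(self, entries):
        """entries: list of (mid, contig, pos, pic, maf, missing)."""
        stats, ann, pos = {}, {}, {}
        for mid, contig, p, pic, maf, miss in entries:
            stats[mid] = stats_stub(mid, pic=pic, maf=maf, missing=miss)
            ann[mid] = "exonic_cds"
            pos[mid] = (contig, p)
        return stats, ann, set(stats), pos

    def test_high_missing_rate_excluded(self):
        stats, ann, designed, pos = self._inputs(
            [("m1", "c1", 100, 0.35, 0.3, 0.2),
             ("m2", "c1", 5000, 0.35, 0.3, 0.0)]
        )
        with pytest.warns(UserWarning):
            kept = screen_candidates(stats, ann, designed, pos, self.CRIT)
        assert kept == ["m2"]

    def test_spacing_drops_lower_pic_neighbour(self):
        stats, ann, designed, pos = self._inputs(
            [("m1", "c1", 100, 0.37, 0.3, 0.0),
             ("m2", "c1", 110, 0.30, 0.3, 0.0),
             ("m3", "c1", 9000, 0.33, 0.3, 0.0)]
        )
        with pytest.warns(UserWarning):
            kept = screen_candidates(stats, ann, designed, pos, self.CRIT)
        assert kept == ["m1", "m3"]

    def test_ranked_by_pic_and_truncated(self):
        entries = [(f"m{i}", "c1", 3000 * i, pic, 0.3, 0.0)
                   for i, pic in enumerate([0.31, 0.375, 0.33, 0.36, 0.32])]
        stats, ann, designed, pos = self._inputs(entries)
        kept = screen_candidates(stats, ann, designed, pos, self.CRIT)
        assert kept == ["m1", "m3", "m2"]  # PIC 0.375, 0.36, 0.33

    def test_region_and_design_status_enforced(self):
        stats, ann, designed, pos = self._inputs(
            [("m1", "c1", 100, 0.35, 0.3, 0.0),
             ("m2", "c1", 5000, 0.35, 0.3, 0.0),
             ("m3", "c1", 9000, 0.35, 0.3, 0.0)]
        )
        ann["m1"] = "intronic"
        designed.discard("m2")
        with pytest.warns(UserWarning):
            kept = screen_candidates(stats, ann, designed, pos, self.CRIT)
        assert kept == ["m3"]

    def test_pic_fallback_when_preferred_too_strict(self):
        stats, ann, designed, pos = self._inputs(
            [("m1", "c1", 100, 0.25, 0.3, 0.0),
             ("m2", "c1", 5000, 0.22, 0.3, 0.0),
             ("m3", "c1", 9000, 0.35, 0.3, 0.0)]
        )
        kept = screen_candidates(stats, ann, designed, pos, self.CRIT)
        assert kept == ["m3", "m1", "m2"]


class TestIdentificationEfficiency:
    def test_single_marker_two_groups(self):
        m = make_matrix(["AA", "AA", "GG", "GG"],
                        loci=[("chr1", 100, "A", ("G",))])
        assert identification_efficiency(m, ["chr1_100"]) == pytest.approx(4 / 6)

    def test_empty_marker_set_zero(self):
        m = make_matrix(["AA", "GG"], loci=[("chr1", 100, "A", ("G",))])
        assert identification_efficiency(m, []) == 0.0

    def test_all_pairwise_distinct_is_one(self):
        m = make_matrix(["AA", "AG", "GG"], loci=[("chr1", 100, "A", ("G",))])
        assert identification_efficiency(m, ["chr1_100"]) == 1.0

    def test_missing_call_never_distinguishes(self):
        m = make_matrix(["AA", ".."], loci=[("chr1", 100, "A", ("G",))])
        assert identification_efficiency(m, ["chr1_100"]) == 0.0


TOY_LOCI = [("c1", 100, "A", ("G",)), ("c1", 2000, "A", ("G",)),
            ("c1", 4000, "A", ("G",))]
# M1=[A,A,G,G], M2=[A,G,A,G], M3=[A,A,A,G] per accession (homozygous)
TOY_ROWS = ["AAAAAA", "AAGGAA", "GGAAAA", "GGGGGG"]


class TestSelectCoreMarkers:
    def test_toy_needs_exactly_two_markers(self):
        m = make_matrix(TOY_ROWS, loci=TOY_LOCI)
        curve, core, unresolved = select_core_markers(
            m, [r.marker_id for r in m.loci]
        )
        assert sorted(core) == ["c1_100", "c1_2000"]
        assert unresolved == []
        assert identification_efficiency(m, core) == 1.0
        # brute force: no single marker suffices, some pair does
        best, eff = minimum_core_exhaustive(m, [r.marker_id for r in m.loci])
        assert len(best) == 2 and eff == 1.0

    def test_duplicate_accessions_reported_unresolvable(self):
        m = make_matrix(["AAAA", "AAAA", "GGGG"],
                        loci=TOY_LOCI[:2])
        curve, core, unresolved = select_core_markers(
            m, [r.marker_id for r in m.loci]
        )
        assert ("S1", "S2") in unresolved
        assert curve.efficiency[-1] < 1.0

    def test_redundant_candidate_never_selected(self):
        # locus 2 duplicates locus 1's genotype column
        m = make_matrix(["AAAA", "GGGG"], loci=TOY_LOCI[:2])
        _, core, _ = select_core_markers(m, ["c1_100", "c1_2000"])
        assert core == ["c1_100"]

    def test_curve_non_decreasing_and_ends_at_full_efficiency(self, small_panel):
        m = small_panel["matrix"]
        cands = [r.marker_id for r in m.loci[:60]]
        curve, core, _ = select_core_markers(m, cands)
        assert all(b >= a - 1e-12 for a, b in
                   zip(curve.efficiency, curve.efficiency[1:]))
        assert curve.efficiency[-1] == pytest.approx(
            identification_efficiency(m, cands)
        )

    def test_pruned_core_is_superset_minimal(self, small_panel):
        m = small_panel["matrix"]
        cands = [r.marker_id for r in m.loci[:60]]
        _, core, _ = select_core_markers(m, cands)
        full_eff = identification_efficiency(m, core)
        for mid in core:
            reduced = [x for x in core if x != mid]
            assert identification_efficiency(m, reduced) < full_eff

    def test_no_candidates_rejected(self, small_panel):
        with pytest.raises(ValueError):
            select_core_markers(small_panel["matrix"], [])


def random_instance(rng):
    n_acc = int(rng.integers(4, 9))
    n_mark = int(rng.integers(3, 11))
    rows = []
    for _ in range(n_acc):
        rows.append(
            ["".join(sorted(rng.choice(["A", "G"], size=2)))
             for _ in range(n_mark)]
        )
    loci = [("c1", 1000 * (j + 1), "A", ("G",)) for j in range(n_mark)]
    return make_matrix(rows, loci=loci)


def test_greedy_plus_prune_against_exhaustive_oracle():
    """Greedy+prune reaches full discrimination whenever possible, stays
    superset-minimal, and is within one marker of the optimum size."""
    rng = np.random.default_rng(2024)
    for _ in range(60):
        m = random_instance(rng)
        cands = [r.marker_id for r in m.loci]
        _, core, _ = select_core_markers(m, cands)
        best, best_eff = minimum_core_exhaustive(m, cands)
        got_eff = identification_efficiency(m, core)
        assert got_eff == pytest.approx(best_eff)
        assert len(core) <= len(best) + 1


class TestFingerprint:
    def test_codes_and_classes(self):
        m = make_matrix(["CC", "AG", ".."], loci=[("chr1", 100, "C", ("A", "G"))])
        fp = build_fingerprint(m, ["chr1_100"])
        assert fp.codes.loc["S1", "chr1_100"] == "C/C"
        assert fp.classes.loc["S1", "chr1_100"] == "hom"
        assert fp.classes.loc["S2", "chr1_100"] == "het"
        assert fp.codes.loc["S3", "chr1_100"] == "."
        assert fp.classes.loc["S3", "chr1_100"] == "missing"

    def test_empty_marker_list_rejected(self, small_panel):
        with pytest.raises(ValueError):
            build_fingerprint(small_panel["matrix"], [])

    def test_rows_unique_iff_efficiency_one(self):
        distinct = make_matrix(["AA", "AG", "GG"],
                               loci=[("chr1", 100, "A", ("G",))])
        fp = build_fingerprint(distinct, ["chr1_100"])
        assert fp.all_unique
        assert identification_efficiency(distinct, ["chr1_100"]) == 1.0

        clones = make_matrix(["AA", "AA", "GG"],
                             loci=[("chr1", 100, "A", ("G",))])
        fp2 = build_fingerprint(clones, ["chr1_100"])
        assert not fp2.all_unique
        assert identification_efficiency(clones, ["chr1_100"]) < 1.0

    def test_missing_masked_pair_not_treated_as_unique(self):
        # S1 vs S2 differ only where S2 is missing -> indistinguishable
        m = make_matrix(["AAGG", "AA.."],
                        loci=[("chr1", 100, "A", ("G",)),
                              ("chr1", 200, "G", ("T",))])
        fp = build_fingerprint(m, ["chr1_100", "chr1_200"])
        assert fp.identical_groups == [["S1", "S2"]]

    def test_render_writes_image(self, small_panel, tmp_path):
        m = small_panel["matrix"]
        fp = build_fingerprint(m, [r.marker_id for r in m.loci[:8]])
        out = tmp_path / "fp.png"
        from kaspanel.marker_panel import render_fingerprint

        render_fingerprint(fp, out)
        assert out.stat().st_size > 0
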