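"""Interval arithmetic and annotation-matrix construction against per-base oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from funcarch.annotate import (
    AnnotationMatrix,
    ConservationTrack,
    GeneModel,
    IntervalSet,
    build_annotation_matrix,
    derive_conserved_classes,
    derive_exclusive_class,
    derive_splice_sites,
    filter_snps,
    union_all,
)
from funcarch.sldsr import SumStats

from conftest import CHROM_LEN, base_array, random_interval_set, toy_panel


class TestIntervalSet:
    def test_rejects_malformed_intervals(self):
        with pytest.raises(ValueError):
            IntervalSet("x", (("1", 10, 10),))
        with pytest.raises(ValueError):
            IntervalSet("x", (("1", -5, 10),))

    def test_normalize_merges_overlaps_and_bookends(self):
        s = IntervalSet("x", (("1", 0, 10), ("1", 5, 20), ("1", 20, 30), ("2", 0, 5)))
        assert s.normalized().intervals == (("1", 0, 30), ("2", 0, 5))

    @pytest.mark.parametrize("seed", range(10))
    def test_subtract_matches_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_interval_set(rng, "a", n=200)
        b = random_interval_set(rng, "b", n=200)
        got = base_array(a.subtract(b))
        want = base_array(a) & ~base_array(b)
        assert (got == want).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_union_intersect_match_base_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = random_interval_set(rng, "a")
        b = random_interval_set(rng, "b")
        assert (base_array(a.union(b)) == (base_array(a) | base_array(b))).all()
        assert (base_array(a.intersect(b)) == (base_array(a) & base_array(b))).all()

    def test_contains_points_boundary_convention(self):
        s = IntervalSet("x", (("1", 100, 101),))
        # 1-based SNP position p is inside [s, e) iff s < p <= e
        assert s.contains_points(["1"], np.array([100]))[0]  # p=101 -> pos0=100
        t = IntervalSet("x", (("1", 101, 102),))
        assert not t.contains_points(["1"], np.array([100]))[0]


FULL = ConservationTrack("cons", (("1", 0, CHROM_LEN, 1.0),))
LOW = ConservationTrack("cons", (("1", 0, CHROM_LEN, 0.3),))


class TestSpliceSites:
    def test_plus_strand_conserved_intron(self):
        genes = GeneModel((("1", 1000, 1200, "+"),))
        donor, acceptor = derive_splice_sites(genes, FULL, flank_nt=70)
        assert donor.intervals == (("1", 1000, 1070),)
        assert acceptor.intervals == (("1", 1130, 1200),)

    def test_minus_strand_reflects_flanks(self):
        genes = GeneModel((("1", 1000, 1200, "-"),))
        donor, acceptor = derive_splice_sites(genes, FULL, flank_nt=70)
        assert donor.intervals == (("1", 1130, 1200),)
        assert acceptor.intervals == (("1", 1000, 1070),)

    def test_unconserved_introns_yield_empty_sets(self):
        genes = GeneModel((("1", 1000, 1200, "+"),))
        donor, acceptor = derive_splice_sites(genes, LOW, flank_nt=70)
        assert donor.intervals == () and acceptor.intervals == ()

    def test_short_intron_overlapping_flanks_both_emitted(self):
        genes = GeneModel((("1", 500, 600, "+"),))  # length 100 < 2*70
        donor, acceptor = derive_splice_sites(genes, FULL, flank_nt=70)
        assert donor.intervals == (("1", 500, 570),)
        assert acceptor.intervals == (("1", 530, 600),)

    def test_empty_gene_model_is_not_an_error(self):
        donor, acceptor = derive_splice_sites(GeneModel(()), FULL)
        assert donor.intervals == () and acceptor.intervals == ()

    def test_malformed_strand_rejected_but_dot_warns(self):
        with pytest.raises(ValueError):
            GeneModel((("1", 0, 10, "?"),))
        g = GeneModel((("1", 0, 10, "."),))
        assert g.introns[0][3] == "+"

    def test_mean_mode_keeps_flank_iff_mean_score_clears_threshold(self):
        # flank [1000,1070): 40 bases at 0.9 -> mean 36/70 = 0.514 >= 0.5
        patchy = ConservationTrack("cons", (("1", 1000, 1040, 0.9),))
        genes = GeneModel((("1", 1000, 2000, "+"),))
        donor, _ = derive_splice_sites(genes, patchy, flank_nt=70)
        assert donor.intervals == (("1", 1000, 1070),)
        sparse = ConservationTrack("cons", (("1", 1000, 1030, 0.9),))  # mean 0.386
        donor, _ = derive_splice_sites(genes, sparse, flank_nt=70)
        assert donor.intervals == ()

    def test_intersect_mode_clips_to_conserved_bases(self):
        patchy = ConservationTrack("cons", (("1", 1000, 1040, 0.9),))
        genes = GeneModel((("1", 1000, 2000, "+"),))
        donor, _ = derive_splice_sites(genes, patchy, flank_nt=70, mode="intersect")
        assert donor.intervals == (("1", 1000, 1040),)


class TestExclusiveClass:
    def test_worked_example(self):
        src = IntervalSet("p", (("1", 0, 100),))
        out = derive_exclusive_class(src, [IntervalSet("q", (("1", 50, 60),))])
        assert out.intervals == (("1", 0, 50), ("1", 60, 100))

    def test_disjoint_exclusion_is_identity(self):
        src = IntervalSet("p", (("1", 0, 100),))
        out = derive_exclusive_class(src, [IntervalSet("q", (("1", 200, 300),))])
        assert base_array(out).sum() == 100
        assert (base_array(out) == base_array(src)).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_never_intersects_excluded(self, seed):
        rng = np.random.default_rng(200 + seed)
        src = random_interval_set(rng, "src", n=200)
        excl = [random_interval_set(rng, f"e{i}", n=60) for i in range(3)]
        out = derive_exclusive_class(src, excl)
        for e in excl:
            assert out.intersect(e).total_bases() == 0
        want = base_array(src) & ~base_array(union_all(excl, "u"))
        assert (base_array(out) == want).all()


class TestConservedClasses:
    def test_identical_tracks_leave_primate_empty(self):
        m, p, frac = derive_conserved_classes(FULL, FULL, [])
        assert p.intervals == ()
        assert frac == 1.0
        assert m.total_bases() == CHROM_LEN

    def test_disjoint_tracks_have_zero_overlap(self):
        mam = ConservationTrack("m", (("1", 0, 100, 0.9),))
        pri = ConservationTrack("p", (("1", 500, 700, 0.9),))
        m, p, frac = derive_conserved_classes(mam, pri, [])
        assert frac == 0.0
        assert p.total_bases() == 200

    def test_planned_twenty_percent_overlap_is_reported(self):
        # primate-conserved spans 1000 bases of which exactly 200 are also
        # mammal-conserved
        mam = ConservationTrack("m", (("1", 0, 200, 0.8),))
        pri = ConservationTrack("p", (("1", 0, 1000, 0.8),))
        m, p, frac = derive_conserved_classes(mam, pri, [])
        assert frac == pytest.approx(0.20)
        assert p.total_bases() == 800

    def test_mammal_and_primate_always_disjoint(self):
        rng = np.random.default_rng(7)
        mam = ConservationTrack(
            "m", tuple(("1", int(s), int(s) + 50, 0.7) for s in range(0, 5000, 120))
        )
        pri = ConservationTrack(
            "p", tuple(("1", int(s), int(s) + 80, 0.9) for s in range(30, 5000, 150))
        )
        others = [random_interval_set(rng, "o", n=30)]
        m, p, _ = derive_conserved_classes(mam, pri, others)
        assert m.intersect(p).total_bases() == 0

    def test_scores_below_threshold_ignored(self):
        mam = ConservationTrack("m", (("1", 0, 100, 0.49),))
        m, _, _ = derive_conserved_classes(mam, LOW, [])
        assert m.intervals == ()


class TestAnnotationMatrix:
    def test_boundary_membership(self, rng):
        panel = toy_panel(rng, M=3)
        panel.pos = np.array([101, 150, 300])
        cls = IntervalSet("c", (("1", 100, 101),))
        annot = build_annotation_matrix(panel, [cls])
        assert annot.matrix[:, 1].tolist() == [1, 0, 0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        panel = toy_panel(rng, M=50)
        classes = [random_interval_set(rng, f"c{i}", n=15) for i in range(4)]
        annot = build_annotation_matrix(panel, classes)
        for ci, cls in enumerate(classes):
            for j, p in enumerate(panel.pos):
                member = any(
                    s < p <= e for c, s, e in cls.intervals if c == "1"
                )
                assert annot.matrix[j, ci + 1] == member

    def test_empty_class_list_gives_base_only(self, rng):
        panel = toy_panel(rng, M=20)
        annot = build_annotation_matrix(panel, [])
        assert annot.class_names == ["base"]
        assert (annot.matrix == 1).all()
        assert annot.proportion_of_snps[0] == 1.0

    def test_column_sums_invariant_to_interval_order_and_duplicates(self, rng):
        panel = toy_panel(rng, M=40)
        ivs = random_interval_set(rng, "c", n=10)
        shuffled = IntervalSet("c", tuple(reversed(ivs.intervals)) + ivs.intervals[:3])
        a1 = build_annotation_matrix(panel, [ivs])
        a2 = build_annotation_matrix(panel, [shuffled])
        assert (a1.matrix == a2.matrix).all()

    def test_duplicate_and_reserved_names_rejected(self, rng):
        panel = toy_panel(rng, M=10)
        c = IntervalSet("c", (("1", 0, 50),))
        with pytest.raises(ValueError):
            build_annotation_matrix(panel, [c, c])
        with pytest.raises(ValueError):
            build_annotation_matrix(panel, [IntervalSet("base", (("1", 0, 5),))])

    def test_proportion_is_exact_column_mean(self, rng):
        panel = toy_panel(rng, M=30)
        classes = [random_interval_set(rng, "c", n=8)]
        annot = build_annotation_matrix(panel, classes)
        assert annot.proportion_of_snps[1] == annot.matrix[:, 1].sum() / 30


class TestFilterSnps:
    def _stats(self, panel):
        return SumStats(panel.snp_id, 1000.0, np.ones(len(panel.snp_id)))

    def test_empty_exclusion_is_identity(self, rng):
        panel = toy_panel(rng, M=10)
        stats = self._stats(panel)
        out = filter_snps(stats, panel, [])
        assert (out.snp_id == stats.snp_id).all()

    def test_single_snp_excluded(self, rng):
        panel = toy_panel(rng, M=10)
        p = int(panel.pos[3])
        out = filter_snps(self._stats(panel), panel,
                          [IntervalSet("mhc", (("1", p - 1, p),))])
        assert out.n_snps == 9
        assert panel.snp_id[3] not in out.snp_id

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_membership(self, seed):
        rng = np.random.default_rng(400 + seed)
        panel = toy_panel(rng, M=60)
        excl = [random_interval_set(rng, f"e{i}", n=25) for i in range(2)]
        out = filter_snps(self._stats(panel), panel, excl)
        mask = base_array(union_all(excl, "u"))
        keep = {sid for sid, p in zip(panel.snp_id, panel.pos) if not mask[p - 1]}
        assert set(out.snp_id) == keep

    def test_everything_excluded_is_an_error(self, rng):
        panel = toy_panel(rng, M=5)
        whole = IntervalSet("all", (("1", 0, CHROM_LEN),))
        with pytest.raises(ValueError, match="all SNPs"):
            filter_snps(self._stats(panel), panel, [whole])


@given(
    st.lists(
        st.tuples(st.integers(0, 900), st.integers(1, 100)), min_size=1, max_size=30
    ),
    st.lists(
        st.tuples(st.integers(0, 900), st.integers(1, 100)), min_size=0, max_size=30
    ),
)
@settings(max_examples=50, deadline=None)
def test_subtract_property_base_oracle(a_ivs, b_ivs):
    """Interval subtraction equals per-base boolean difference for any input."""
    a = IntervalSet("a", tuple(("1", s, s + l) for s, l in a_ivs))
    b = IntervalSet("b", tuple(("1", s, s + l) for s, l in b_ivs))
    got = base_array(a.subtract(b), length=1100)
    want = base_array(a, length=1100) & ~base_array(b, length=1100)
    assert (got == want).all()


def test_conservation_track_validation():
    with pytest.raises(ValueError):
        ConservationTrack("t", (("1", 0, 10, 1.5),))
    with pytest.raises(ValueError, match="overlap"):
        ConservationTrack("t", (("1", 0, 10, 0.5), ("1", 5, 15, 0.5)))
    t = ConservationTrack("t", (("1", 0, 10, 0.5), ("1", 10, 15, 0.2)))
    assert t.mean_score("1", 0, 20) == pytest.approx((10 * 0.5 + 5 * 0.2) / 20)
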