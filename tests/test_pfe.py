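"""The PFE filtering rules, exon anchoring, interval reports and the
two-proportion enrichment test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpseg.pfe import (
    Pfe,
    PfeCriteria,
    call_pfes,
    candidate_segments,
    exon_anchored_classes,
    overlap_report,
    proportion_ztest,
)
from cpseg.profiles import ClassProfile


def make_profile(prob_runs, gaps=None, n_classes=2, cons=(0.7, 0.4), start=0):
    """Build a single-chromosome two-class profile from a class-0
    probability vector; class 1 takes the complement."""
    p0 = np.asarray(prob_runs, dtype=float)
    n = p0.size
    probs = np.column_stack([p0, 1 - p0])
    if n_classes > 2:
        probs = np.column_stack([probs, np.zeros((n, n_classes - 2))])
    gap = np.zeros(n, dtype=np.int64)
    if gaps:
        for idx, val in gaps.items():
            gap[idx] = val
    return ClassProfile(
        probs=probs,
        chrom_names=["chr1"],
        chrom_idx=np.zeros(n, dtype=np.int32),
        pos=np.arange(start, start + n),
        gap_before=gap,
        conservation_means=np.asarray(cons[:n_classes], dtype=float),
    )


class TestCandidateSegments:
    def test_long_clean_run_accepted(self):
        profile = make_profile([0.95] * 150)
        out = candidate_segments(profile, 0, PfeCriteria())
        assert len(out) == 1
        assert out[0]["start"] == 0 and out[0]["end"] == 150
        assert out[0]["gap_cols"] == 0

    def test_run_below_minimum_length_rejected(self):
        profile = make_profile([0.95] * 99)
        assert candidate_segments(profile, 0, PfeCriteria()) == []

    def test_large_gap_run_splits_candidate(self):
        # 150 positions with a 25-column alignment gap after position 74
        profile = make_profile([0.95] * 300, gaps={150: 25})
        out = candidate_segments(profile, 0, PfeCriteria())
        assert len(out) == 2
        assert out[0]["end"] == 150 and out[1]["start"] == 150

    def test_split_pieces_rechecked_against_length(self):
        profile = make_profile([0.95] * 150, gaps={75: 25})
        # both pieces are 75 < 100 after the split
        assert candidate_segments(profile, 0, PfeCriteria()) == []

    def test_scattered_gap_fraction_rejects(self):
        # 20 scattered gap columns in a 150-position run: 13% >= 10%
        gaps = {int(i): 2 for i in np.arange(10, 150, 14)}
        total = sum(gaps.values())
        assert total / 150 >= 0.10
        profile = make_profile([0.95] * 150, gaps=gaps)
        assert candidate_segments(profile, 0, PfeCriteria()) == []

    def test_below_profile_threshold_breaks_run(self):
        p = [0.95] * 60 + [0.5] + [0.95] * 60
        profile = make_profile(p)
        assert candidate_segments(profile, 0, PfeCriteria()) == []

    def test_unknown_class_rejected(self):
        profile = make_profile([0.95] * 10)
        with pytest.raises(ValueError, match="unknown class"):
            candidate_segments(profile, 5, PfeCriteria())

    def test_allowed_mask_clips_and_rechecks(self):
        profile = make_profile([0.95] * 300)
        allowed = np.ones(300, dtype=bool)
        allowed[120:180] = False  # an exon in the middle
        out = candidate_segments(profile, 0, PfeCriteria(), allowed=allowed)
        assert [(o["start"], o["end"]) for o in out] == [(0, 120), (180, 300)]


class TestPfeCriteriaValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_length_nt": 0},
            {"min_profile": 1.5},
            {"max_gap_run_cols": 0},
            {"max_gap_fraction": 0.0},
            {"min_class_conservation": 1.0},
        ],
    )
    def test_invalid_thresholds(self, kwargs):
        with pytest.raises(ValueError):
            PfeCriteria(**kwargs)


class TestExonAnchoredClasses:
    def test_more_conserved_class_joins_exon_class(self):
        # exons fall in class X (0.71); class Y at 0.75 also qualifies
        beds = {0: [("chr1", 100, 200)], 1: [("chr1", 500, 600)]}
        exons = [("chr1", 150, 180)]
        got = exon_anchored_classes(beds, exons, [0.71, 0.75])
        assert got == {0, 1}

    def test_less_conserved_class_excluded(self):
        beds = {0: [("chr1", 100, 200)], 1: [("chr1", 500, 600)]}
        exons = [("chr1", 150, 180)]
        assert exon_anchored_classes(beds, exons, [0.71, 0.45]) == {0}

    def test_conservation_floor_excludes_exon_class(self):
        beds = {0: [("chr1", 100, 200)]}
        exons = [("chr1", 150, 180)]
        assert exon_anchored_classes(beds, exons, [0.48]) == set()

    def test_no_overlap_gives_empty_set(self):
        beds = {0: [("chr1", 100, 200)]}
        assert exon_anchored_classes(beds, [("chr1", 900, 950)], [0.71]) == set()


class TestCallPfes:
    def _profile(self):
        # class 0 (conserved, 0.7) strong over [50, 260) and [600, 800);
        # class 1 elsewhere
        p0 = np.full(1000, 0.02)
        p0[50:260] = 0.97
        p0[600:800] = 0.97
        return make_profile(p0, cons=(0.70, 0.45))

    def test_exon_clipping_keeps_long_remainder(self):
        profile = self._profile()
        genes = [("chr1", 0, 500, "g1")]
        exons = [("chr1", 50, 120, "g1")]  # overlaps candidate head by 70
        pfes = call_pfes(profile, genes, exons, PfeCriteria())
        intronic = [p for p in pfes if p.gene == "g1"]
        assert len(intronic) == 1
        assert (intronic[0].start, intronic[0].end) == (120, 260)
        assert intronic[0].length_nt == 140

    def test_intronic_pfe_inside_gene_outside_exons(self):
        profile = self._profile()
        genes = [("chr1", 0, 500, "g1")]
        exons = [("chr1", 40, 60, "g1")]
        pfes = call_pfes(profile, genes, exons, PfeCriteria())
        for p in pfes:
            if p.gene == "g1":
                assert p.start >= 0 and p.end <= 500
                assert p.end <= 40 or p.start >= 60

    def test_intergenic_from_most_conserved_class(self):
        profile = self._profile()
        genes = [("chr1", 0, 500, "g1")]
        exons = [("chr1", 55, 70, "g1")]
        pfes = call_pfes(profile, genes, exons, PfeCriteria())
        inter = [p for p in pfes if p.gene == "intergenic"]
        assert [(p.start, p.end) for p in inter] == [(600, 800)]
        assert inter[0].class_id == 0

    def test_deterministic_and_idempotent(self):
        profile = self._profile()
        genes = [("chr1", 0, 500, "g1")]
        exons = [("chr1", 55, 70, "g1")]
        a = call_pfes(profile, genes, exons, PfeCriteria())
        b = call_pfes(profile, genes, exons, PfeCriteria())
        assert [(p.chrom, p.start, p.end, p.gene, p.class_id) for p in a] == [
            (p.chrom, p.start, p.end, p.gene, p.class_id) for p in b
        ]

    def test_nested_genes_attribute_to_both(self):
        profile = self._profile()
        genes = [("chr1", 0, 500, "outer"), ("chr1", 10, 400, "inner")]
        exons = [("chr1", 55, 70, "outer"), ("chr1", 55, 70, "inner")]
        pfes = call_pfes(profile, genes, exons, PfeCriteria())
        by_gene = {p.gene for p in pfes if p.gene != "intergenic"}
        assert by_gene == {"outer", "inner"}

    def test_exclusion_list_removes_regions(self):
        profile = self._profile()
        genes = [("chr1", 0, 500, "g1")]
        exons = [("chr1", 55, 70, "g1")]
        pfes = call_pfes(
            profile,
            genes,
            exons,
            PfeCriteria(),
            exclusion_list=[("chr1", 0, 1000)],
        )
        assert pfes == []

    def test_chromosome_mismatch_raises(self):
        profile = self._profile()
        with pytest.raises(ValueError, match="absent"):
            call_pfes(profile, [("chr9", 0, 100, "g")], [], PfeCriteria())

    def test_no_anchored_class_logged_not_fatal(self):
        profile = self._profile()
        genes = [("chr1", 300, 500, "g1")]  # exons nowhere near class segments
        log = []
        pfes = call_pfes(profile, genes, [("chr1", 310, 320, "g1")], PfeCriteria(), log=log)
        assert [p for p in pfes if p.gene == "g1"] == []
        assert any("g1" in line for line in log)


@settings(max_examples=30, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    min_profile=st.sampled_from([0.8, 0.9, 0.95]),
    min_length=st.sampled_from([50, 100, 150]),
)
def test_call_count_monotone_in_thresholds(seed, min_profile, min_length):
    """Raising min_profile or min_length never increases the call count."""
    rng = np.random.default_rng(seed)
    # blocky random profile with plateaus
    p0 = np.repeat(rng.uniform(0, 1, size=12), rng.integers(30, 120, size=12))
    profile = make_profile(p0, cons=(0.7, 0.45))
    crit = PfeCriteria(min_length_nt=min_length, min_profile=min_profile)
    base = len(candidate_segments(profile, 0, crit))
    tighter_p = PfeCriteria(min_length_nt=min_length, min_profile=min(min_profile + 0.04, 1.0))
    tighter_l = PfeCriteria(min_length_nt=min_length + 50, min_profile=min_profile)
    assert len(candidate_segments(profile, 0, tighter_p)) <= base
    assert len(candidate_segments(profile, 0, tighter_l)) <= base


class TestOverlapReport:
    def _pfe(self, start, end):
        return Pfe(
            chrom="chr1", start=start, end=end, class_id=0, class_conservation=0.7
        )

    def test_contained_feature(self):
        table, summary, venn = overlap_report(
            [self._pfe(100, 300)], {"evo": [("chr1", 150, 200)]}
        )
        row = table.iloc[0]
        assert row["evo_overlap"] and row["evo_contained"]
        assert row["evo_bp"] == 50
        assert summary["evo"] == 1

    def test_near_miss_within_proximity(self):
        table, summary, _ = overlap_report(
            [self._pfe(100, 300)], {"evo": [("chr1", 310, 330)]}, proximity_nt=30
        )
        row = table.iloc[0]
        assert not row["evo_overlap"] and row["evo_near"]
        assert summary["evo"] == 0

    def test_disjoint_beyond_proximity(self):
        table, _, _ = overlap_report(
            [self._pfe(100, 300)], {"evo": [("chr1", 400, 420)]}, proximity_nt=30
        )
        row = table.iloc[0]
        assert not row["evo_overlap"] and not row["evo_near"]

    def test_venn_partition_sums_to_total(self):
        pfes = [self._pfe(0, 100), self._pfe(200, 300), self._pfe(400, 500)]
        tracks = {
            "a": [("chr1", 10, 20), ("chr1", 210, 220)],
            "b": [("chr1", 210, 220), ("chr1", 410, 420)],
        }
        _, _, venn = overlap_report(pfes, tracks)
        # exclusive cells partition the supported PFEs
        assert venn[("a",)] == 1
        assert venn[("b",)] == 1
        assert venn[("a", "b")] == 1


class TestProportionZTest:
    def test_printed_counts_give_large_z(self):
        """TF fraction among PFE genes vs the aligned-genome background."""
        z, p = proportion_ztest(79, 193, 1733, 16296)
        assert 79 / 193 == pytest.approx(0.409, abs=5e-4)
        assert 1733 / 16296 == pytest.approx(0.106, abs=5e-4)
        assert z == pytest.approx(13.4, abs=0.1)
        assert p < 1e-30

    def test_equal_proportions(self):
        z, p = proportion_ztest(10, 100, 10, 100)
        assert z == 0.0
        assert p == 1.0

    def test_degenerate_all_zero(self):
        z, p = proportion_ztest(0, 10, 0, 10)
        assert z == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ztest(1, 0, 1, 10)
        with pytest.raises(ValueError):
            proportion_ztest(11, 10, 1, 10)
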