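"""CCF estimation, clonality classification and shared-subclone detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesohet.clonality import (
    CCFEstimate,
    CopySegment,
    build_clonal_tree,
    classify_variant,
    cnv_ccf,
    detect_shared_subclone,
    estimate_ccf,
    is_damaging,
    match_and_classify_cnv,
    section_vaf_profile,
)

from conftest import make_obs


class TestIsDamaging:
    @pytest.mark.parametrize(
        "sift,polyphen,expected",
        [
            ("tolerated", "probably_damaging", True),
            ("tolerated", "benign", False),
            ("deleterious", "unknown", True),
            ("deleterious", "benign", True),
            ("tolerated", "possibly_damaging", True),
            ("unknown", "unknown", False),
            (None, None, False),
        ],
    )
    def test_at_least_one_tool(self, sift, polyphen, expected):
        assert is_damaging(sift, polyphen) is expected

    def test_unrecognized_label_lists_accepted_values(self):
        with pytest.raises(ValueError, match="deleterious"):
            is_damaging("damaging", "benign")
        with pytest.raises(ValueError, match="probably_damaging"):
            is_damaging("tolerated", "bad")


class TestEstimateCCF:
    def test_clonal_het_pure_diploid(self):
        est = estimate_ccf(make_obs(50, 100), purity=1.0)
        assert est.ccf == pytest.approx(1.0)
        assert est.multiplicity == 1

    def test_purity_corrected_clonal(self):
        # vaf 0.3, purity 0.6, diploid: raw = 0.3 * 2 / 0.6 = 1.0
        est = estimate_ccf(make_obs(30, 100), purity=0.6)
        assert est.ccf == pytest.approx(1.0, abs=1e-12)

    def test_copy_number_context(self):
        seg = CopySegment("S1", "chr1", 1, 1000, total_cn=3, major_cn=2, minor_cn=1)
        est = estimate_ccf(make_obs(10, 100), purity=0.8, segment=seg)
        # raw = 0.1 * (0.8*3 + 0.2*2) / 0.8 = 0.35
        assert est.ccf == pytest.approx(0.35, abs=1e-12)
        assert est.multiplicity == 1
        assert est.total_cn == 3

    def test_diploid_closed_form(self):
        # for diploid multiplicity-1 variants the estimate is 2*vaf/purity
        rng = np.random.default_rng(0)
        for _ in range(100):
            depth = int(rng.integers(30, 2000))
            alt = int(rng.integers(1, depth // 4 + 1))  # keep multiplicity 1
            purity = float(rng.uniform(0.3, 1.0))
            est = estimate_ccf(make_obs(alt, depth), purity=purity, ccf_cap=np.inf)
            assert est.ccf == pytest.approx(2 * (alt / depth) / purity, abs=1e-12)

    def test_ci_brackets_point_estimate_and_uses_same_transform(self):
        est = estimate_ccf(make_obs(25, 100), purity=0.5)
        assert est.ci_low < est.ccf < est.ci_high

    @given(
        depth=st.integers(50, 500),
        purity=st.floats(0.2, 1.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_alt_count(self, depth, purity):
        alts = range(1, depth // 4, max(depth // 20, 1))
        ccfs = [
            estimate_ccf(make_obs(a, depth), purity=purity, ccf_cap=np.inf).ccf
            for a in alts
        ]
        assert all(b > a for a, b in zip(ccfs, ccfs[1:]))

    def test_cap_warns_but_does_not_renormalize(self):
        with pytest.warns(UserWarning, match="cap"):
            est = estimate_ccf(make_obs(90, 100), purity=0.5)
        assert est.ccf == 1.5
        assert est.capped

    def test_errors(self):
        with pytest.raises(ValueError, match="purity"):
            estimate_ccf(make_obs(10, 100), purity=0.0)
        seg = CopySegment("S1", "chr1", 1, 1000, total_cn=0, major_cn=0, minor_cn=0)
        with pytest.raises(ValueError, match="zero|deleted"):
            estimate_ccf(make_obs(10, 100), purity=0.5, segment=seg)


def _est(ccf, ci_high=None, ci_low=0.0):
    return CCFEstimate(
        ccf=ccf, ci_low=min(ci_low, ccf),
        ci_high=ci_high if ci_high is not None else ccf + 0.1,
        multiplicity=1, purity=0.8, total_cn=2,
    )


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((1.0, 1.2), (0.98, 1.1), "clonal_shared"),
            ((0.30, 0.45), (0.25, 0.40), "subclonal_shared"),
            ((0.9, 1.2), None, "clonal_private"),
            ((0.3, 1.1), (0.3, 0.4), "clonal_shared"),  # CI rule fails in A
            ((0.6, 0.8), (0.3, 0.4), "clonal_shared"),  # CCF rule fails in A
            ((0.3, 0.45), None, "subclonal_private"),
            (None, (0.55, 0.9), "clonal_private"),
        ],
    )
    def test_rules(self, a, b, expected):
        est_a = _est(*a) if a else None
        est_b = _est(*b) if b else None
        assert classify_variant(est_a, est_b).category == expected

    def test_both_absent_is_an_error(self):
        with pytest.raises(ValueError):
            classify_variant(None, None)


class TestCnvCCF:
    def test_arithmetic(self):
        assert cnv_ccf(0.42, 0.6) == pytest.approx(0.7)
        assert cnv_ccf(0.6, 0.6) == pytest.approx(1.0)

    def test_over_unity_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            assert cnv_ccf(0.75, 0.6) == 1.0

    def test_zero_purity_error(self):
        with pytest.raises(ValueError):
            cnv_ccf(0.5, 0.0)


def _seg(sample, chrom, start, end, total, major, minor, cf):
    return CopySegment(sample, chrom, start, end, total, major, minor, cf)


class TestMatchAndClassifyCNV:
    def test_identical_lists_fully_clonal_shared(self):
        a = [_seg("A", "chr1", 1, 1000, 3, 2, 1, 0.6)]
        b = [_seg("B", "chr1", 1, 1000, 3, 2, 1, 0.7)]
        calls, homdels = match_and_classify_cnv(a, b, 0.6, 0.7)
        assert [c.category for c in calls] == ["clonal_shared"]
        assert homdels == []

    def test_private_subclonal_gain(self):
        a = [_seg("A", "chr2", 1, 1000, 3, 2, 1, 0.18)]
        calls, _ = match_and_classify_cnv(a, [], 0.6, 0.7)
        assert calls[0].category == "subclonal_private"

    def test_gain_vs_loss_do_not_match(self):
        a = [_seg("A", "chr1", 1, 1000, 3, 2, 1, 0.6)]
        b = [_seg("B", "chr1", 1, 1000, 1, 1, 0, 0.7)]
        calls, _ = match_and_classify_cnv(a, b, 0.6, 0.7)
        assert sorted(c.category for c in calls) == [
            "clonal_private", "clonal_private",
        ]

    def test_reciprocal_overlap_threshold(self):
        a = [_seg("A", "chr1", 1, 1000, 3, 2, 1, 0.6)]
        b = [_seg("B", "chr1", 900, 5000, 3, 2, 1, 0.7)]  # ~10% of A covered
        calls, _ = match_and_classify_cnv(a, b, 0.6, 0.7)
        assert all(c.category.endswith("private") for c in calls)

    def test_homozygous_deletions_reported_separately(self):
        a = [_seg("A", "chr9", 1, 1000, 0, 0, 0, 0.8)]
        calls, homdels = match_and_classify_cnv(a, [], 0.8, 0.7)
        assert calls == []
        assert len(homdels) == 1

    def test_overlapping_input_segmentation_rejected(self):
        a = [
            _seg("A", "chr1", 1, 1000, 3, 2, 1, 0.6),
            _seg("A", "chr1", 500, 2000, 1, 1, 0, 0.6),
        ]
        with pytest.raises(ValueError, match="overlap"):
            match_and_classify_cnv(a, [], 0.6, 0.7)


class TestDetectSharedSubclone:
    def _call(self, category, key, gene=None, cancer=False):
        from mesohet.clonality import ClonalityCall

        return ClonalityCall(
            key=key, category=category, gene=gene, cancer_gene=cancer
        )

    def test_six_supporters_with_cancer_gene(self):
        calls = [
            self._call("subclonal_shared", f"v{i}", gene="NF2" if i == 0 else None,
                       cancer=(i == 0))
            for i in range(6)
        ] + [self._call("clonal_shared", "t1")]
        rep = detect_shared_subclone(calls)
        assert rep.flag and len(rep.supporting_variants) == 6
        assert rep.cancer_gene_members == ["NF2"]

    def test_below_threshold(self):
        assert not detect_shared_subclone([]).flag
        one = [self._call("subclonal_shared", "v1")]
        assert not detect_shared_subclone(one, min_variants=2).flag
        assert detect_shared_subclone(one, min_variants=1).flag


class TestBuildClonalTree:
    def _call(self, category, key, a=True, b=True):
        from mesohet.clonality import ClonalityCall

        return ClonalityCall(
            key=key, category=category,
            site_a=_est(0.9) if a else None,
            site_b=_est(0.9) if b else None,
        )

    def test_only_clonal_shared_gives_single_node(self):
        tree = build_clonal_tree([self._call("clonal_shared", f"v{i}") for i in range(3)])
        assert tree["name"] == "trunk"
        assert tree["n_variants"] == 3
        assert tree["children"] == []

    def test_shared_subclone_node_with_counts(self):
        calls = [self._call("clonal_shared", f"t{i}") for i in range(4)]
        calls += [self._call("subclonal_shared", f"s{i}") for i in range(6)]
        calls += [self._call("clonal_private", "pA", a=True, b=False)]
        calls += [self._call("subclonal_private", "spB", a=False, b=True)]
        tree = build_clonal_tree(calls)
        names = {c["name"]: c for c in tree["children"]}
        assert names["shared_subclone"]["n_variants"] == 6
        assert names["branch_A"]["n_variants"] == 1
        assert names["branch_B"]["children"][0]["n_variants"] == 1


class TestSectionVafProfile:
    def test_query_equals_anchor(self):
        df = pd.DataFrame(
            {
                "section": range(4),
                "query_alt": [10, 20, 15, 12],
                "query_depth": [100, 200, 150, 120],
                "anchor_alt": [10, 20, 15, 12],
                "anchor_depth": [100, 200, 150, 120],
            }
        )
        _, summary = section_vaf_profile(df)
        assert summary["detection_fraction"] == 1.0
        assert summary["median_vaf_ratio"] == pytest.approx(1.0)

    def test_query_absent_everywhere(self):
        df = pd.DataFrame(
            {
                "section": range(3),
                "query_alt": [0, 0, 0],
                "query_depth": [100, 100, 100],
                "anchor_alt": [40, 50, 45],
                "anchor_depth": [100, 100, 100],
            }
        )
        _, summary = section_vaf_profile(df)
        assert summary["detection_fraction"] == 0.0

    def test_half_detected_at_third_of_anchor(self):
        n = 34
        rows = []
        for i in range(n):
            detected = i < 17
            rows.append(
                {
                    "section": i,
                    "query_alt": 15 if detected else 0,
                    "query_depth": 100,
                    "anchor_alt": 45,
                    "anchor_depth": 100,
                }
            )
        _, summary = section_vaf_profile(pd.DataFrame(rows))
        assert summary["detection_fraction"] == pytest.approx(0.5)
        # ratio summarized over detected sections: 0.15 / 0.45
        assert summary["median_vaf_ratio"] == pytest.approx(1 / 3)

    def test_zero_depth_sections_excluded_with_warning(self):
        df = pd.DataFrame(
            {
                "section": [0, 1],
                "query_alt": [5, 5],
                "query_depth": [0, 100],
                "anchor_alt": [40, 40],
                "anchor_depth": [100, 100],
            }
        )
        with pytest.warns(UserWarning, match="zero-depth"):
            out, summary = section_vaf_profile(df)
        assert summary["n_sections"] == 1
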