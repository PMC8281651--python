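"""Ground-truth generators: clone structures, reads, expression, methylation."""

import numpy as np
import pytest

from mesohet.expression import call_de_genes
from mesohet.methylation import call_dm_cpg
from mesohet.synthetic import (
    build_truth,
    simulate_clone_structure,
    simulate_expression_pair,
    simulate_methylation_pair,
    simulate_variant_reads,
)


def _truth(scenario, seed=7, **kw):
    defaults = dict(n_trunk_mut=6, n_subclones=2, muts_per_subclone=3)
    defaults.update(kw)
    tree, comps = simulate_clone_structure(scenario=scenario, seed=seed, **defaults)
    return build_truth(tree, comps)


class TestCloneStructure:
    def test_no_subclones_gives_single_clone(self):
        tree, comps = simulate_clone_structure(6, 0, 0, "mixed", seed=1)
        assert len(tree.clones) == 1
        for comp in comps:
            assert comp.clone_fractions == {"trunk": 1.0}

    def test_shared_subclone_below_half_at_both_sites(self):
        tree, comps = simulate_clone_structure(
            6, 1, 6, "shared_subclone", seed=7
        )
        fracs = [c.clone_fractions["sub1"] for c in comps]
        assert all(0 < f < 0.5 for f in fracs)

    def test_private_subclones_absent_at_exactly_one_site(self):
        tree, comps = simulate_clone_structure(
            6, 2, 3, "private_subclones", seed=7
        )
        for cid in ("sub1", "sub2"):
            present = [cid in c.clone_fractions for c in comps]
            assert sum(present) == 1

    def test_deterministic_given_seed(self):
        a = simulate_clone_structure(6, 2, 3, "mixed", seed=11)
        b = simulate_clone_structure(6, 2, 3, "mixed", seed=11)
        assert a[0] == b[0]
        assert [c.clone_fractions for c in a[1]] == [c.clone_fractions for c in b[1]]

    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_trunk_mut=0, n_subclones=1, muts_per_subclone=1),
            dict(n_trunk_mut=5, n_subclones=-1, muts_per_subclone=1),
            dict(n_trunk_mut=5, n_subclones=0, muts_per_subclone=1,
                 scenario="shared_subclone"),
            dict(n_trunk_mut=5, n_subclones=1, muts_per_subclone=1,
                 scenario="bogus"),
        ],
    )
    def test_parameter_errors(self, kw):
        kw.setdefault("scenario", "mixed")
        with pytest.raises(ValueError):
            simulate_clone_structure(seed=1, **kw)


class TestTruth:
    @pytest.mark.parametrize("scenario", ["shared_subclone", "private_subclones", "mixed"])
    def test_true_ccf_equals_sum_of_carrying_fractions(self, scenario):
        truth = _truth(scenario)
        for mut, per_site in truth.true_ccf.items():
            for comp in truth.compositions:
                expected = sum(
                    comp.clone_fractions.get(c.id, 0.0)
                    for c in truth.tree.clones
                    if mut in c.mutations
                )
                assert per_site[comp.site_id] == expected

    def test_trunk_mutations_fully_clonal_everywhere(self):
        truth = _truth("mixed")
        for mut in truth.tree.root.mutations:
            for site, ccf in truth.true_ccf[mut].items():
                assert ccf == pytest.approx(1.0, abs=1e-12)
            assert truth.true_category[mut] == "clonal_shared"

    def test_shared_subclone_category(self):
        truth = _truth("shared_subclone", n_subclones=1, muts_per_subclone=6)
        sub_muts = truth.tree.clones[1].mutations - truth.tree.root.mutations
        assert len(sub_muts) == 6
        for mut in sub_muts:
            assert truth.true_category[mut] == "subclonal_shared"


class TestVariantReads:
    def test_trunk_vaf_half_at_full_purity(self):
        tree, comps = simulate_clone_structure(
            50, 0, 0, "mixed", seed=3, purity_range=(1.0, 1.0)
        )
        truth = build_truth(tree, comps)
        reads = simulate_variant_reads(truth, mean_depth=10_000, seed=3)
        for site, obs in reads.items():
            vafs = [v.vaf for v in obs]
            assert np.mean(vafs) == pytest.approx(0.5, abs=0.02)

    def test_expected_vaf_matches_ccf_algebra(self):
        # trueCCF 0.3, purity 0.6, diploid -> expected VAF 0.09
        tree, comps = simulate_clone_structure(
            1, 1, 1000, "shared_subclone", seed=5, purity_range=(0.6, 0.6)
        )
        comp = comps[0]
        frac = comp.clone_fractions["sub1"]
        truth = build_truth(tree, comps)
        reads = simulate_variant_reads(truth, mean_depth=200, seed=5)
        sub_muts = tree.clones[1].mutations - tree.root.mutations
        obs = [v for v in reads[comp.site_id] if v.gene in sub_muts]
        expected_vaf = frac * 0.6 / (0.6 * 2 + 0.4 * 2)
        mean_vaf = np.mean([v.alt_count for v in obs]) / np.mean(
            [v.depth for v in obs]
        )
        se = np.sqrt(expected_vaf * (1 - expected_vaf) / (200 * len(obs)))
        assert abs(mean_vaf - expected_vaf) < 3 * se

    def test_absent_where_true_ccf_zero(self):
        tree, comps = simulate_clone_structure(
            2, 2, 50, "private_subclones", seed=9
        )
        truth = build_truth(tree, comps)
        reads = simulate_variant_reads(truth, mean_depth=500, seed=9)
        for comp in comps:
            called = {v.gene for v in reads[comp.site_id]}
            for mut, per_site in truth.true_ccf.items():
                if per_site[comp.site_id] == 0:
                    assert mut not in called

    def test_depth_floor_and_mean_depth_guard(self):
        with pytest.raises(ValueError):
            simulate_variant_reads(_truth("mixed"), mean_depth=10, seed=1)


class TestExpressionPair:
    def test_noise_free_equal_conditions_identical_columns(self):
        truth = _truth("mixed")
        pair = simulate_expression_pair(
            truth, n_genes=200, noise_sd=0.0, n_de=0, seed=1,
            es_scores={s: (0.5, 0.5) for s in truth.sites},
            immune=None,
        )
        # immune drawn once per site -> force equality
        pair = simulate_expression_pair(
            truth, n_genes=200, noise_sd=0.0, n_de=0, seed=1,
            es_scores={s: (0.5, 0.5) for s in truth.sites},
            immune={s: {} for s in truth.sites},
        )
        a, b = pair.sites
        assert (pair.vst[a] == pair.vst[b]).all()
        assert (pair.fpkm[a] == pair.fpkm[b]).all()

    def test_planted_de_genes_recovered_at_zero_noise(self):
        truth = _truth("mixed")
        pair = simulate_expression_pair(
            truth, n_genes=300, noise_sd=0.0, n_de=20, de_shift=1.5, seed=2,
            es_scores={s: (0.5, 0.5) for s in truth.sites},
            immune={s: {} for s in truth.sites},
        )
        de = call_de_genes(pair)
        recovered = set(de["gene"])
        planted = {
            g for g, sign in truth.de_genes.items()
            # genes silent in both biopsies are excluded by the FPKM filter
            if not (pair.fpkm.loc[g] < 1).all()
        }
        # exact set equality at zero noise: nothing but planted genes moves
        assert recovered == planted
        signs = dict(zip(de["gene"], de["sign"]))
        for g in planted:
            assert signs[g] == truth.de_genes[g]

    def test_deterministic(self):
        truth = _truth("mixed")
        p1 = simulate_expression_pair(truth, n_genes=100, seed=42)
        p2 = simulate_expression_pair(truth, n_genes=100, seed=42)
        assert p1.vst.equals(p2.vst)
        assert p1.fpkm.equals(p2.fpkm)


class TestMethylationPair:
    def test_no_planted_dm_gives_empty_call_set(self):
        truth = _truth("mixed")
        pair = simulate_methylation_pair(
            truth, n_cpg=500, n_dm=0, noise_sd=0.0, seed=1
        )
        assert len(call_dm_cpg(pair)) == 0

    def test_exact_point_two_shift_is_called(self):
        truth = _truth("mixed")
        pair = simulate_methylation_pair(
            truth, n_cpg=500, n_dm=50, delta=0.2, noise_sd=0.0, seed=2
        )
        called = set(call_dm_cpg(pair)["cpg"])
        assert truth.dm_cpgs == called

    def test_total_detection_failure_suppresses_all_calls(self):
        truth = _truth("mixed")
        pair = simulate_methylation_pair(
            truth, n_cpg=300, n_dm=100, delta=0.4, noise_sd=0.0,
            detection_failure_fraction=1.0, seed=3,
        )
        assert len(call_dm_cpg(pair)) == 0

    def test_betas_bounded_and_delta_validated(self):
        truth = _truth("mixed")
        pair = simulate_methylation_pair(truth, n_cpg=200, seed=4)
        assert ((pair.betas >= 0) & (pair.betas <= 1)).all().all()
        with pytest.raises(ValueError):
            simulate_methylation_pair(truth, n_cpg=10, n_dm=0, delta=1.5, seed=1)
        with pytest.raises(ValueError):
            simulate_methylation_pair(truth, n_cpg=10, n_dm=20, seed=1)
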