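import warnings

import numpy as np
import pytest

import vnsreact as v
from vnsreact.synth import null_config, planted_differential_cells

from .oracles import bh_stepup_direct, mann_whitney_exact_bruteforce


class TestMannWhitney:
    def test_textbook_separated_groups(self):
        u, p = v.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 * 1/C(6,3)

    def test_identical_groups_p_one_by_symmetry(self):
        _, p = v.mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_constant_data_warns_p_one(self):
        with pytest.warns(UserWarning, match="identical"):
            _, p = v.mann_whitney([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 5)
        _, p1 = v.mann_whitney(a, b)
        _, p2 = v.mann_whitney(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_agrees_with_bruteforce_enumeration(self):
        """Exact p equals full enumeration for tie-free combined n <= 10."""
        rng = np.random.default_rng(11)
        for na in range(2, 6):
            for nb in range(2, 11 - na):
                for _ in range(3):
                    pooled = rng.permutation(rng.normal(size=na + nb))
                    a, b = pooled[:na], pooled[na:]
                    u, p = v.mann_whitney(a, b)
                    u_bf, p_bf = mann_whitney_exact_bruteforce(a, b)
                    # implementation reports U for the first sample
                    assert p == pytest.approx(p_bf, abs=1e-12), (na, nb)


class TestFdr:
    def test_stepup_rejects_all_when_largest_passes(self):
        q = v.fdr_correct([0.005, 0.03, 0.04])
        assert np.all(q <= 0.05)

    def test_all_ones(self):
        assert np.allclose(v.fdr_correct([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_identity(self):
        assert v.fdr_correct([0.04])[0] == pytest.approx(0.04)

    def test_matches_direct_stepup_definition(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=19)
            assert np.allclose(v.fdr_correct(p), bh_stepup_direct(p))

    def test_bh_rejections_subset_of_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50) ** 2
        q = v.fdr_correct(p)
        assert np.all(p[q <= 0.05] <= 0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            v.fdr_correct([0.5, 1.2])


class TestWilcoxon:
    def test_uniform_positive_shift_significant(self):
        # all-positive vector of n=10: exact two-sided p = 2/2^10
        p = v.wilcoxon_vs_zero(np.full(10, 50.0) + np.arange(10))
        assert p == pytest.approx(2 / 2**10)

    def test_all_zero_warns_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            assert v.wilcoxon_vs_zero(np.zeros(8)) == 1.0

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            v.wilcoxon_vs_zero([1.0])


class TestGroupComparisonMap:
    def test_planted_effect_flags_concentrate_in_planted_cells(
            self, small_cohort):
        rpw, labels, cfg = small_cohort
        gmap = v.group_comparison_map(rpw, labels)
        planted = planted_differential_cells(cfg)
        flagged = gmap[gmap.significant]
        assert len(flagged) > 0
        in_planted = flagged.apply(
            lambda r: (r.band, r.condition) in planted, axis=1)
        assert in_planted.mean() > 0.9
        # the strongest planted contrast is detected
        hv_alpha = gmap[(gmap.band == "alpha") & (gmap.condition == "HV")]
        assert hv_alpha.significant.mean() > 0.5

    def test_permuted_labels_control_false_positives(self, small_cohort):
        rpw, labels, _ = small_cohort
        rng = np.random.default_rng(0)
        props = []
        sids = list(labels)
        for _ in range(10):
            perm = rng.permutation([labels[s] for s in sids])
            gmap = v.group_comparison_map(rpw, dict(zip(sids, perm)))
            props.append(gmap.significant.mean())
        assert np.mean(props) <= 0.05

    def test_identical_groups_no_systematic_flags(self):
        props = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(5):
                rpw, labels = v.generate_rpw_cohort(
                    null_config(seed, 10, 10))
                gmap = v.group_comparison_map(rpw, labels)
                props.append(gmap.significant.mean())
        assert np.mean(props) <= 0.05

    def test_single_class_rejected(self, small_cohort):
        rpw, labels, _ = small_cohort
        only_resp = {s: v.RESPONDER for s in labels}
        with pytest.raises(ValueError, match="both classes"):
            v.group_comparison_map(rpw, only_resp)

    def test_statmap_invariants(self, small_cohort):
        rpw, labels, _ = small_cohort
        gmap = v.group_comparison_map(rpw, labels)
        assert len(gmap) == 19 * 4 * 7
        assert gmap.p.between(0, 1).all()
        assert (gmap.q >= gmap.p - 1e-12).all()
        assert gmap.loc[gmap.significant, "q"].le(0.05).all()


class TestBaselineReactivityMap:
    def test_planted_within_group_reactivity_detected(self, small_cohort):
        rpw, labels, _ = small_cohort
        bmap = v.baseline_reactivity_map(rpw, labels)
        assert set(bmap.group) == {v.RESPONDER, v.NONRESPONDER}
        # the Berger alpha blockade is planted in both groups; at this
        # fixture size only the larger (responder) group has reliable
        # signed-rank power, so assert detection there
        berger = bmap[(bmap.band == "alpha")
                      & (bmap.condition == "OpenClose1")
                      & (bmap.group == v.RESPONDER)]
        assert berger["significant"].mean() > 0.5

    def test_tiny_group_rejected(self, small_cohort):
        rpw, labels, _ = small_cohort
        one_resp = {s: (v.RESPONDER if i == 0 else v.NONRESPONDER)
                    for i, s in enumerate(labels)}
        with pytest.raises(ValueError, match="at least 2"):
            v.baseline_reactivity_map(rpw, one_resp)
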