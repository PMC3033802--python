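"""Mann-Whitney machinery, overlap policies, and BH FDR control."""

import itertools

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from dafscan.scan import (
    GENOME_BACKGROUND,
    REPEAT_BACKGROUND,
    FDRReport,
    bh_adjusted,
    bh_report,
    mann_whitney,
    remove_overlap,
)


def exact_one_sided_p(x, y):
    """Full-enumeration oracle: P(U <= U_obs) over all C(n+m, n) equally
    likely assignments of the pooled (tie-free) values to the class."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        us.append(u)
    us = np.array(us)
    return np.mean(us <= u_obs)


class TestRemoveOverlap:
    def test_genome_policy_prunes_background_only(self):
        cls, bg = remove_overlap({"a", "b", "c"}, {"a", "b", "c", "d", "e"}, GENOME_BACKGROUND)
        assert cls == {"a", "b", "c"} and bg == {"d", "e"}

    def test_repeat_policy_prunes_both(self):
        cls, bg = remove_overlap({"a", "b", "c"}, {"b", "c", "d"}, REPEAT_BACKGROUND)
        assert cls == {"a"} and bg == {"d"}

    def test_disjoint_sets_unchanged(self):
        for policy in (GENOME_BACKGROUND, REPEAT_BACKGROUND):
            cls, bg = remove_overlap({"a"}, {"b"}, policy)
            assert cls == {"a"} and bg == {"b"}

    def test_degenerate_result_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            remove_overlap({"a"}, {"a"}, REPEAT_BACKGROUND)


class TestMannWhitney:
    def test_small_sample_exact_p(self):
        # class entirely below background: 1 of C(5,2)=10 assignments as extreme
        res = mann_whitney([0.1, 0.2], [0.3, 0.4, 0.5], alternative="less")
        assert res.method == "exact"
        assert res.p_raw == pytest.approx(0.1)
        assert res.U == 0.0

    def test_identical_multisets_two_sided_p_is_one(self):
        res = mann_whitney([0.1, 0.5, 0.9], [0.9, 0.1, 0.5], alternative="two-sided")
        assert res.p_raw == pytest.approx(1.0)

    def test_constant_data_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="identical"):
            res = mann_whitney([0.3, 0.3], [0.3, 0.3, 0.3])
        assert res.p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney([], [0.1])

    def test_u_statistic_within_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.random(8), rng.random(13)
            res = mann_whitney(x, y)
            assert 0 <= res.U <= res.n_class * res.n_background

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(2, 7))
            x = rng.random(n)
            y = rng.random(m)
            res = mann_whitney(x, y, method="exact")
            assert res.p_raw == pytest.approx(exact_one_sided_p(x, y), abs=1e-12)

    def test_genome_scale_background_refuses_exact(self):
        rng = np.random.default_rng(2)
        res = mann_whitney(rng.random(10), rng.random(6000), method="exact")
        assert res.method == "normal_approx"

    def test_auto_prefers_approximation_with_ties(self):
        grid = np.arange(1, 11) / 10.0
        rng = np.random.default_rng(3)
        res = mann_whitney(rng.choice(grid, 30), rng.choice(grid, 100))
        assert res.method == "normal_approx"

    def test_reported_p_floored(self):
        rng = np.random.default_rng(4)
        res = mann_whitney(rng.random(300) * 0.2, 0.5 + rng.random(300) * 0.2)
        assert res.p_value == 1e-8 and res.p_raw < 1e-8

    def test_label_permutation_p_values_uniform(self):
        # permuting class labels of a pooled neutral sample: one-sided p ~ U(0,1)
        rng = np.random.default_rng(8)
        pooled = rng.random(120)
        ps = []
        for _ in range(500):
            perm = rng.permutation(120)
            ps.append(mann_whitney(pooled[perm[:30]], pooled[perm[30:]]).p_raw)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBH:
    def test_critical_values_and_stepup_prefix(self):
        report = bh_report({"a": 0.001, "b": 0.026, "c": 0.03, "d": 0.9}, alpha=0.05, m=4)
        crit = [e.critical_value for e in report.entries]
        assert crit == pytest.approx([0.0125, 0.025, 0.0375, 0.05])
        assert crit[-1] == report.alpha
        # step-up: rank 2 (0.026 > 0.025) is rescued because rank 3 passes,
        # so the significant set is the prefix of length 3
        assert [e.significant for e in report.entries] == [True, True, True, False]
        adj = [e.adjusted_p for e in report.entries]
        assert adj == sorted(adj)

    def test_single_test(self):
        report = bh_report({"only": 0.05}, alpha=0.05, m=1)
        e = report.entries[0]
        assert e.critical_value == 0.05 and e.adjusted_p == 0.05 and e.significant

    def test_declared_m_exceeding_supplied_tests(self):
        report = bh_report({"a": 0.001}, alpha=0.05, m=44)
        assert report.entries[0].critical_value == pytest.approx(0.05 / 44)
        assert report.entries[0].adjusted_p == pytest.approx(0.044)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            bh_report({"a": 0.0})
        with pytest.raises(ValueError, match="smaller"):
            bh_report({"a": 0.1, "b": 0.2}, m=1)

    def test_adjusted_p_matches_statsmodels(self):
        # independent route: statsmodels fdr_bh with m = number of tests
        rng = np.random.default_rng(9)
        ps = rng.random(25) ** 2
        ours = bh_adjusted(ps)
        _, theirs, _, _ = multipletests(ps, alpha=0.05, method="fdr_bh")
        assert np.allclose(ours, theirs)
        report = bh_report({f"c{i}": p for i, p in enumerate(ps)}, alpha=0.05)
        reject, _, _, _ = multipletests(ps, alpha=0.05, method="fdr_bh")
        assert set(report.significant_labels()) == {
            f"c{i}" for i in range(25) if reject[i]
        }


def test_scan_of_background_copy_is_never_significant(demo_polarized, demo_bundle):
    """A class identical to the background is exchangeable with it."""
    from dafscan.classes import ClassCatalog, assign_snps_to_classes
    from dafscan.model import RegionSet
    from dafscan.scan import run_scan

    polarized, _ = demo_polarized
    catalog = ClassCatalog()
    catalog.add(RegionSet("copy", demo_bundle.region_sets["ancestral_repeats"].intervals))
    catalog.add(RegionSet("ancestral_repeats", demo_bundle.region_sets["ancestral_repeats"].intervals))
    membership = assign_snps_to_classes(polarized, catalog)
    res = run_scan(polarized, membership, catalog, "AFR", "ancestral_repeats",
                   class_labels=["copy"])
    # identical id sets: overlap removal empties both sides -> skipped
    assert res.results == []
    # against the genome the copy is a neutral subset: p stays unremarkable
    res = run_scan(polarized, membership, catalog, "AFR", "genome", class_labels=["copy"])
    assert res.results[0].p_raw > 0.05
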