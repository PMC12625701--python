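import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cnpskit.beta_diversity import DistanceMatrix, bray_curtis
from cnpskit.group_stats import (
    bh_adjust,
    differential_table,
    multi_group_tests,
    multivariate_tests,
    normality_gate,
    two_group_tests,
)
from cnpskit.ontology import CycleMapping, ProcessDef
from cnpskit.process_abundance import aggregate

from conftest import group_of, random_ko_table


class TestNormalityGate:
    def test_constant_group_forces_nonparametric(self):
        gate = normality_gate({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 2.5]})
        assert gate.recommended == "nonparametric"
        assert any("zero variance" in r for r in gate.reasons)

    def test_tiny_group_forces_nonparametric(self):
        gate = normality_gate({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0, 2.5]})
        assert gate.recommended == "nonparametric"
        assert any("n < 3" in r for r in gate.reasons)

    def test_normal_sample_passes_gate(self):
        x = np.random.default_rng(2024).standard_normal(50)
        gate = normality_gate({"a": x, "b": x + 1})
        assert gate.recommended == "parametric"

    def test_shapiro_w_matches_independent_reference(self):
        # W for this fixed sample computed once with R's shapiro.test (4.3.3)
        x = np.random.default_rng(2024).standard_normal(50)
        from scipy import stats

        w, _ = stats.shapiro(x)
        assert w == pytest.approx(0.977831452284, abs=1e-6)


def exact_wilcoxon_p(a, b):
    """Enumeration oracle: exact two-sided rank-sum p over all assignments."""
    pooled = sorted(list(a) + list(b))
    n1 = len(a)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    u_values = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        r1 = sum(ranks[i] for i in combo)
        u_values.append(r1 - n1 * (n1 + 1) / 2)
    u_values = np.array(u_values)
    obs_ranks = rankdata(list(a) + list(b))[:n1].sum()
    u_obs = obs_ranks - n1 * (n1 + 1) / 2
    lower = (u_values <= u_obs).mean()
    upper = (u_values >= u_obs).mean()
    return min(1.0, 2 * min(lower, upper))


class TestTwoGroupTests:
    def test_exact_wilcoxon_small_sample(self):
        res = two_group_tests([1.0, 2.0], [3.0, 4.0])
        assert res["wilcoxon_p"] == pytest.approx(1 / 3)

    def test_identical_samples_t_zero_p_one(self):
        res = two_group_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t_statistic"] == pytest.approx(0.0)
        assert res["t_p"] == pytest.approx(1.0)

    def test_all_tied_constant_data(self):
        res = two_group_tests([2.0, 2.0], [2.0, 2.0])
        assert math.isnan(res["t_statistic"])
        assert res["wilcoxon_p"] == 1.0

    def test_wilcoxon_matches_enumeration_for_small_n(self):
        """Exact p equals full enumeration for tie-free inputs, total n <= 8."""
        rng = np.random.default_rng(5)
        for n1 in (2, 3, 4):
            for n2 in (2, 3, 4):
                if n1 + n2 > 8:
                    continue
                for _ in range(10):
                    pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                    a, b = pooled[:n1], pooled[n1:]
                    res = two_group_tests(a, b)
                    assert res["wilcoxon_p"] == pytest.approx(
                        exact_wilcoxon_p(a, b)
                    ), (a, b)


class TestMultiGroupTests:
    def test_kruskal_wallis_closed_form(self):
        res = multi_group_tests({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        assert res["kw_H"] == pytest.approx(192 / 42, abs=1e-9)

    def test_anova_f_zero_for_identical_groups(self):
        res = multi_group_tests({"a": [1, 2], "b": [1, 2], "c": [1, 2]})
        assert res["anova_F"] == pytest.approx(0.0)

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError, match="two_group_tests"):
            multi_group_tests({"a": [1, 2], "b": [3, 4]})

    def test_kw_type_one_error_near_alpha(self):
        rng = np.random.default_rng(17)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = {g: rng.standard_normal(5) for g in "abc"}
            rejections += multi_group_tests(groups)["kw_p"] < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestBHAdjust:
    def test_step_up_hand_example(self):
        adjusted = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(20)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_nan_passthrough(self):
        adj = bh_adjust([0.01, float("nan"), 0.04])
        assert math.isnan(adj[1])
        assert not math.isnan(adj[0])


def _clouds_distance(seed=0, separation=10.0, n_per=4):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 0.1, size=(n_per, 3))
    b = rng.normal(separation, 0.1, size=(n_per, 3))
    x = np.abs(np.vstack([a, b]))
    samples = [f"s{i}" for i in range(2 * n_per)]
    frame = pd.DataFrame(x.T, columns=samples)
    return bray_curtis(frame), group_of(samples, ["A"] * n_per + ["B"] * n_per)


class TestMultivariate:
    def test_separated_clouds_attain_minimum_p(self):
        # clouds large enough that a random permutation essentially never
        # reproduces the observed partition, so the permutation p floors out
        d, group = _clouds_distance(n_per=10)
        for method in ("PERMANOVA", "ANOSIM", "MRPP"):
            res = multivariate_tests(d, group, method=method, n_permutations=999, seed=1)
            assert res.p == pytest.approx(1 / 1000)

    def test_single_group_rejected(self):
        d, group = _clouds_distance()
        one = group_of(d.sample_ids, ["A"] * len(d.sample_ids))
        with pytest.raises(ValueError):
            multivariate_tests(d, one, method="PERMANOVA")

    def test_permanova_statistic_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        d, group = _clouds_distance(seed=3, separation=1.0)
        res = multivariate_tests(d, group, method="PERMANOVA", n_permutations=9, seed=0)
        ref = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d.values, ids=d.sample_ids),
            grouping=list(group.assignments.values),
            permutations=9,
        )
        assert res.statistic == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_anosim_statistic_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        d, group = _clouds_distance(seed=4, separation=1.0)
        res = multivariate_tests(d, group, method="ANOSIM", n_permutations=9, seed=0)
        ref = skbio_stats.anosim(
            skbio_stats.DistanceMatrix(d.values, ids=d.sample_ids),
            grouping=list(group.assignments.values),
            permutations=9,
        )
        assert res.statistic == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_relabeling_invariance_with_same_seed(self):
        """Renaming samples (keeping group structure) leaves p unchanged."""
        d, group = _clouds_distance(seed=5, separation=1.0)
        renamed = DistanceMatrix(
            sample_ids=[f"x{i}" for i in range(len(d.sample_ids))], values=d.values
        )
        regrouped = group_of(renamed.sample_ids, list(group.assignments.values))
        for method in ("PERMANOVA", "ANOSIM", "MRPP"):
            r1 = multivariate_tests(d, group, method=method, n_permutations=99, seed=7)
            r2 = multivariate_tests(renamed, regrouped, method=method, n_permutations=99, seed=7)
            assert r1.p == r2.p
            assert r1.statistic == pytest.approx(r2.statistic)

    def test_mrpp_statistic_positive_for_clustered_data(self):
        d, group = _clouds_distance()
        res = multivariate_tests(d, group, method="MRPP", n_permutations=199, seed=2)
        assert res.statistic > 0  # within-group agreement better than chance


class TestDifferentialTable:
    @staticmethod
    def _setup(n_groups=2):
        procs = [ProcessDef(f"p{i}", f"P{i}", "C", (f"K{i:05d}",)) for i in range(1, 8)]
        mapping = CycleMapping(processes=procs)
        rng = np.random.default_rng(9)
        ko = random_ko_table(rng, [p.ko_ids[0] for p in procs], 4 * n_groups, 0.0)
        labels = [g for g in "ABCD"[:n_groups] for _ in range(4)]
        group = group_of(ko.sample_ids, labels)
        return mapping, ko, group

    def test_two_groups_carry_both_test_families(self):
        mapping, ko, group = self._setup()
        pam = aggregate(ko, mapping, "C")
        results = differential_table(pam, group)
        assert len(results) == 7
        for r in results:
            assert not math.isnan(r.parametric["p"])
            assert not math.isnan(r.nonparametric["p"])

    def test_three_groups_dispatch_to_anova_kw(self):
        mapping, ko, group = self._setup(n_groups=3)
        pam = aggregate(ko, mapping, "C")
        results = differential_table(pam, group)
        assert all(r.n_groups == 3 for r in results)
        assert all(not math.isnan(r.nonparametric["p"]) for r in results)

    def test_all_zero_process_reported_not_computed(self):
        mapping, ko, group = self._setup()
        ko.values.loc["K00001"] = 0.0
        pam = aggregate(ko, mapping, "C")
        res = {r.process_id: r for r in differential_table(pam, group)}
        assert res["p1"].p_raw == 1.0
        assert "not computed" in res["p1"].note

    def test_adjusted_p_at_least_raw(self):
        mapping, ko, group = self._setup()
        pam = aggregate(ko, mapping, "C")
        for r in differential_table(pam, group):
            assert r.p_adjusted >= r.p_raw - 1e-12

    def test_single_group_rejected(self):
        mapping, ko, group = self._setup()
        one = group_of(ko.sample_ids, ["A"] * len(ko.sample_ids))
        pam = aggregate(ko, mapping, "C")
        with pytest.raises(ValueError):
            differential_table(pam, one)
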