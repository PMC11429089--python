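"""Summary conventions, Kruskal-Wallis vs a permutation oracle, Dunn's test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mammoq.exceptions import MammoqError
from mammoq.stats import compare_groups, dunn_test, summarize


class TestSummarize:
    def test_five_values_reported_mean_sd(self):
        s = summarize([1.0, 2.0, 3.0, 4.0, 100.0])
        assert s.kind == "mean_sd"
        assert s.center == pytest.approx(22.0)
        assert s.spread[0] == pytest.approx(43.6, abs=0.05)

    def test_median_iqr_linear_quantiles(self):
        s = summarize([1, 2, 3, 4, 5, 6])
        assert s.kind == "median_iqr"
        assert s.center == pytest.approx(3.5)
        assert s.spread == (pytest.approx(2.25), pytest.approx(4.75))

    def test_constant_sample_zero_iqr(self):
        s = summarize([4.0] * 7)
        assert s.spread[1] - s.spread[0] == 0.0

    def test_rule_override(self):
        s = summarize([1.0, 2.0, 3.0, 4.0, 100.0], n_rule="median_iqr")
        assert s.kind == "median_iqr" and s.center == 3.0

    def test_empty_rejected(self):
        with pytest.raises(MammoqError):
            summarize([])


def _rank_with_ties(pooled):
    """Independent average-rank computation (test-local oracle)."""
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _kw_h(groups):
    """Tie-corrected Kruskal-Wallis H by direct rank arithmetic."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = _rank_with_ties(pooled)
    h, pos = 0.0, 0
    for g in groups:
        r = ranks[pos:pos + len(g)]
        h += sum(r) ** 2 / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    from collections import Counter
    t = sum(c ** 3 - c for c in Counter(pooled).values())
    return h / (1.0 - t / (n ** 3 - n)) if t else h


class TestKruskalWallis:
    @pytest.mark.parametrize("groups", [
        ([1.0, 5.0, 3.0], [2.0, 6.0, 4.0], [9.0, 7.0, 8.0]),
        ([1.0, 1.0, 2.0, 5.0], [3.0, 3.0, 3.0, 4.0], [2.0, 6.0, 6.0, 7.0]),
    ])
    def test_h_matches_rank_arithmetic_oracle(self, groups):
        df = pd.DataFrame([{"metric": "m", "group": gi, "replicate": ri, "value": v}
                           for gi, g in enumerate(groups) for ri, v in enumerate(g)])
        report = compare_groups(df, "m")
        assert report.kruskal_h == pytest.approx(_kw_h(groups), rel=1e-12)

    def test_h_quantile_matches_exhaustive_permutation_oracle(self):
        """The observed H sits where the exhaustive permutation null puts it."""
        groups = ([1.2, 3.4, 2.2], [4.1, 5.0, 3.9], [8.0, 6.5, 7.2])
        pooled = [v for g in groups for v in g]
        h_obs = _kw_h(groups)
        perm_h = []
        idx = set(range(9))
        for g1 in itertools.combinations(range(9), 3):
            rest = sorted(idx - set(g1))
            for g2 in itertools.combinations(rest, 3):
                g3 = sorted(set(rest) - set(g2))
                perm_h.append(_kw_h(([pooled[i] for i in g1],
                                     [pooled[i] for i in g2],
                                     [pooled[i] for i in g3])))
        assert len(perm_h) == 1680
        p_perm = float(np.mean([h >= h_obs - 1e-12 for h in perm_h]))
        df = pd.DataFrame([{"metric": "m", "group": gi, "replicate": ri, "value": v}
                           for gi, g in enumerate(groups) for ri, v in enumerate(g)])
        report = compare_groups(df, "m")
        assert report.kruskal_h == pytest.approx(h_obs, rel=1e-12)
        # chi-square approximation and exact p agree on the decision scale
        assert p_perm < 0.05 and report.kruskal_p < 0.05

    def test_null_configuration_no_pair_flagged(self):
        base = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0]
        rows = []
        for gi in range(3):  # each group is a permutation of the same sample
            rng = np.random.default_rng(gi)
            for ri, v in enumerate(rng.permutation(base)):
                rows.append({"metric": "m", "group": gi, "replicate": ri, "value": v})
        report = compare_groups(pd.DataFrame(rows), "m")
        assert report.kruskal_h == pytest.approx(_kw_h([base] * 3), rel=1e-12)
        assert not report.significant_pairs

    def test_shifted_group_flagged(self):
        rng = np.random.default_rng(7)
        rows = []
        for gi, shift in enumerate((0.0, 0.0, 3.0)):  # 3 sigma shift
            for ri in range(10):
                rows.append({"metric": "m", "group": gi, "replicate": ri,
                             "value": rng.normal(shift, 1.0)})
        report = compare_groups(pd.DataFrame(rows), "m")
        assert (0, 2) in report.significant_pairs
        assert (1, 2) in report.significant_pairs
        assert (0, 1) not in report.significant_pairs


class TestDunn:
    def test_hand_computed_fixture(self):
        # groups with ranks 1-3, 4-6, 7-9: mean ranks 2, 5, 8; no ties
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0], "c": [7.0, 8.0, 9.0]}
        table = dunn_test(groups)
        se = np.sqrt((9 * 10 / 12.0) * (2.0 / 3.0))
        z_ab = (2.0 - 5.0) / se
        p_ab = 2 * sps.norm.sf(abs(z_ab)) * 3
        row = table[(table.group1 == "a") & (table.group2 == "b")].iloc[0]
        assert row.z == pytest.approx(z_ab, rel=1e-12)
        assert row.p_corrected == pytest.approx(min(1.0, p_ab), rel=1e-12)
        row_ac = table[(table.group1 == "a") & (table.group2 == "c")].iloc[0]
        assert row_ac.p_corrected == pytest.approx(
            min(1.0, 2 * sps.norm.sf(6.0 / se) * 3), rel=1e-9)
        assert bool(row_ac.significant)

    def test_bonferroni_never_below_raw(self, rng):
        groups = {g: rng.normal(g, 1.0, 8) for g in range(4)}
        table = dunn_test(groups)
        assert (table.p_corrected >= table.p_raw - 1e-15).all()
        assert (table.p_corrected <= 1.0).all()

    def test_tie_correction_applied(self):
        # heavy ties: z must use the tie-corrected variance
        groups = {"a": [1.0, 1.0, 2.0], "b": [1.0, 2.0, 2.0]}
        pooled = [1.0, 1.0, 2.0, 1.0, 2.0, 2.0]
        ranks = _rank_with_ties(pooled)
        mean_a, mean_b = np.mean(ranks[:3]), np.mean(ranks[3:])
        tie = sum(c ** 3 - c for c in (3, 3)) / (12 * 5)
        se = np.sqrt((6 * 7 / 12.0 - tie) * (2.0 / 3.0))
        table = dunn_test(groups)
        assert table.iloc[0].z == pytest.approx((mean_a - mean_b) / se, rel=1e-12)


class TestCompareGroupsPlumbing:
    def test_small_groups_excluded_with_warning(self):
        rows = ([{"metric": "m", "group": "big", "replicate": i, "value": float(i)}
                 for i in range(6)]
                + [{"metric": "m", "group": "big2", "replicate": i, "value": i + 0.5}
                   for i in range(6)]
                + [{"metric": "m", "group": "tiny", "replicate": 0, "value": 1.0},
                   {"metric": "m", "group": "tiny", "replicate": 1, "value": 2.0}])
        with pytest.warns(UserWarning, match="tiny"):
            report = compare_groups(pd.DataFrame(rows), "m")
        assert report.excluded_groups == ["tiny"]
        assert "tiny" in report.group_summaries  # summary still reported

    def test_report_serialises(self, rng):
        rows = [{"metric": "m", "group": g, "replicate": i,
                 "value": float(rng.normal(g))}
                for g in (0, 1) for i in range(5)]
        d = compare_groups(pd.DataFrame(rows), "m").to_dict()
        import json
        json.dumps(d)  # must be JSON-clean
        assert set(d) >= {"metric", "groups", "kruskal_h", "dunn"}
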