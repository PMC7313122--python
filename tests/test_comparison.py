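import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from qutece_bbb.comparison import (
    benjamini_hochberg,
    compare_regions,
    split_tables,
    wilcoxon_rank_sum,
)


def enumeration_p(x, y):
    """Independent oracle: exact two-sided rank-sum p by complete enumeration.

    p = 2 * min(P(U <= u_obs), P(U >= u_obs)) over all C(n, n_x) rank splits,
    capped at 1. Tie-free data only.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n_x, n = len(x), len(x) + len(y)
    ranks = np.concatenate([x, y]).argsort().argsort() + 1.0
    u_obs = ranks[:n_x].sum() - n_x * (n_x + 1) / 2
    us = np.array([
        ranks[list(c)].sum() - n_x * (n_x + 1) / 2
        for c in itertools.combinations(range(n), n_x)
    ])
    total = len(us)
    return min(1.0, 2 * min((us <= u_obs).sum() / total, (us >= u_obs).sum() / total))


class TestWilcoxonRankSum:
    def test_identical_samples_no_separation(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_three_vs_three_complete_separation(self):
        # 2 of C(6,3)=20 equally likely splits are as extreme -> p = 0.1
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], method="exact")
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_seven_vs_eight_complete_separation(self):
        # smallest attainable two-sided exact p = 2 / C(15,7)
        _, p = wilcoxon_rank_sum(np.arange(7), np.arange(10, 18))
        assert p == pytest.approx(2 / 6435, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_with_ties_rejected(self):
        with pytest.raises(ValueError, match="tie"):
            wilcoxon_rank_sum([1, 1], [1, 2], method="exact")

    def test_ties_fall_back_to_normal_approximation(self):
        _, p = wilcoxon_rank_sum([1, 1, 2], [2, 3, 3])
        assert 0 < p <= 1

    @pytest.mark.parametrize("n_x,n_y", [(2, 3), (4, 4), (5, 7), (7, 8), (8, 8)])
    def test_exact_matches_enumeration_oracle(self, n_x, n_y):
        rng = np.random.default_rng(n_x * 100 + n_y)
        for _ in range(10):
            x, y = rng.normal(size=n_x), rng.normal(1.0, 1.0, size=n_y)
            _, p = wilcoxon_rank_sum(x, y, method="exact")
            assert p == pytest.approx(enumeration_p(x, y), abs=1e-12)

    @given(
        st.lists(st.integers(0, 1000), min_size=1, max_size=8),
        st.lists(st.integers(0, 1000), min_size=1, max_size=8),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry_and_u_complement(self, xs, ys):
        """Swapping samples mirrors U (U_x + U_y = n_x n_y) and keeps p."""
        x, y = np.array(xs, float), np.array(ys, float)
        ux, px = wilcoxon_rank_sum(x, y)
        uy, py = wilcoxon_rank_sum(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))
        assert px == pytest.approx(py, rel=1e-9)

    def test_null_rejection_rate_calibrated(self):
        """Exact test at alpha .05 rejects ~4.0% of continuous null data
        (the attainable level for n=7 vs 8 is 0.04009 by full enumeration)."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 600
        for _ in range(n_rep):
            _, p = wilcoxon_rank_sum(rng.normal(size=7), rng.normal(size=8))
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.065


class TestBenjaminiHochberg:
    def test_hand_stepup(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.04]), [0.02, 0.04])

    def test_flat_pvalues_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.05] * 10), 0.05)

    def test_single_p_is_its_own_q(self):
        np.testing.assert_allclose(benjamini_hochberg([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_q_dominates_p_and_is_order_invariant(self, ps):
        q = benjamini_hochberg(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1 + 1e-12)
        perm = np.random.default_rng(0).permutation(len(ps))
        q_perm = benjamini_hochberg(np.asarray(ps)[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)

    def test_monotone_in_p_rank(self):
        p = [0.001, 0.3, 0.02, 0.9, 0.04]
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


def _mode_table(region_specs, n_control=5, n_diabetic=5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for rid, (cm, dm, sd) in region_specs.items():
        for i in range(n_control):
            rows.append(dict(subject_id=f"c{i}", group="control", region_id=rid,
                             region_name=f"r{rid}", mode_value=rng.normal(cm, sd)))
        for i in range(n_diabetic):
            rows.append(dict(subject_id=f"d{i}", group="diabetic", region_id=rid,
                             region_name=f"r{rid}", mode_value=rng.normal(dm, sd)))
    return pd.DataFrame(rows)


class TestCompareRegions:
    def test_separated_region_flagged_ranked_first(self):
        table = _mode_table({1: (0.03, 0.50, 0.01), 2: (0.05, 0.05, 0.01)})
        comp = compare_regions(table)
        assert comp.iloc[0].region_id == 1
        assert bool(comp.iloc[0].significant)
        assert comp.loc[comp.region_id == 2, "significant"].iloc[0] == False  # noqa: E712
        assert comp.iloc[0].direction == "control<diabetic"

    def test_pvalues_ascending_and_q_dominates(self):
        specs = {rid: (0.03, 0.03 + 0.01 * rid, 0.02) for rid in range(1, 9)}
        comp = compare_regions(_mode_table(specs))
        assert (comp.p_value.diff().dropna() >= 0).all()
        assert (comp.q_value >= comp.p_value - 1e-12).all()

    def test_missing_group_errors(self):
        table = _mode_table({1: (0.03, 0.08, 0.01)})
        with pytest.raises(ValueError, match="missing"):
            compare_regions(table[table.group == "control"])

    def test_split_tables_partition(self):
        specs = {rid: (0.03, 0.03 + (0.3 if rid <= 3 else 0.0), 0.01) for rid in range(1, 10)}
        comp = compare_regions(_mode_table(specs))
        sig, nonsig = split_tables(comp)
        assert len(sig) + len(nonsig) == len(comp)
        assert set(sig.region_id) == {1, 2, 3}

    def test_all_or_none_significant(self):
        comp = compare_regions(_mode_table({1: (0.0, 0.9, 0.01), 2: (0.1, 0.95, 0.01)}))
        sig, nonsig = split_tables(comp)
        assert len(sig) == 2 and nonsig.empty
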