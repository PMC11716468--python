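"""Conditional independence engines: G² oracle checks, CMH, effect sizes."""

import numpy as np
import pytest
from scipy import stats

from ivdirect.citest import (
    cmh_test,
    conditional_mi_test,
    cramers_v,
    g2_from_counts,
    stratified_counts,
)
from ivdirect.errors import DegenerateTableError


def expand_counts(arr):
    """(K,R,C) count array -> aligned (z, y, strata) observation vectors."""
    z, y, s = [], [], []
    for k in range(arr.shape[0]):
        for i in range(arr.shape[1]):
            for j in range(arr.shape[2]):
                c = int(arr[k, i, j])
                z += [float(i)] * c
                y += [float(j + 1)] * c
                s += [float(k)] * c
    return np.array(z), np.array(y), np.array(s)


def brute_force_cmi(counts):
    """Conditional mutual information I(Z;Y|S) in nats by direct summation
    over the empirical joint distribution (independent of the G² code path).
    """
    n = counts.sum()
    p = counts / n
    mi = 0.0
    for k in range(p.shape[0]):
        ps = p[k].sum()
        if ps == 0:
            continue
        for i in range(p.shape[1]):
            for j in range(p.shape[2]):
                pij = p[k, i, j]
                if pij == 0:
                    continue
                pz = p[k, i, :].sum()
                py = p[k, :, j].sum()
                mi += pij * np.log(pij * ps / (pz * py))
    return mi


class TestConditionalMI:
    def test_exact_independence_single_stratum(self):
        z, y, s = expand_counts(np.array([[[20, 20], [30, 30]]]))
        res = conditional_mi_test(z, y, s)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_g2_equals_2n_mi_brute_force(self, rng):
        """G² = 2·N·I(Z;Y|S) for random small stratified tables."""
        for _ in range(100):
            counts = rng.integers(0, 31, size=(2, 2, 2)).astype(float)
            if counts.sum() == 0:
                continue
            g2, _ = g2_from_counts(counts)
            mi = brute_force_cmi(counts)
            assert g2 == pytest.approx(2 * counts.sum() * mi, rel=1e-9, abs=1e-9)

    def test_single_stratum_reduces_to_lr_statistic(self, rng):
        z = rng.integers(0, 2, 400).astype(float)
        y = rng.integers(1, 6, 400).astype(float)
        res = conditional_mi_test(z, y, np.zeros(400))
        ref, p_ref, df_ref, _ = stats.chi2_contingency(
            stratified_counts(z, y, np.zeros(400))[0], lambda_="log-likelihood"
        )
        assert res.statistic == pytest.approx(ref, rel=1e-12)
        assert res.df == df_ref and res.p_value == pytest.approx(p_ref)

    def test_invariant_to_stratum_relabeling_and_row_permutation(self, rng):
        z = rng.integers(0, 2, 500).astype(float)
        y = rng.integers(1, 6, 500).astype(float)
        s = rng.integers(0, 4, 500).astype(float)
        base = conditional_mi_test(z, y, s)
        perm = rng.permutation(500)
        relabeled = (3 - s)[perm]
        again = conditional_mi_test(z[perm], y[perm], relabeled)
        assert again.statistic == pytest.approx(base.statistic, rel=1e-12)
        assert again.df == base.df

    def test_df_counts_only_positive_marginals(self):
        # stratum 2 has a single observed y level -> contributes 0 df
        counts = np.zeros((2, 2, 3))
        counts[0] = [[5, 6, 7], [8, 9, 10]]
        counts[1] = [[4, 0, 0], [6, 0, 0]]
        _, df = g2_from_counts(counts)
        assert df == (2 - 1) * (3 - 1)

    def test_all_strata_degenerate_raises(self):
        z = np.ones(30)
        y = np.array([1.0, 2.0, 3.0] * 10)
        with pytest.raises(DegenerateTableError):
            conditional_mi_test(z, y, np.zeros(30))

    def test_missing_rows_excluded(self):
        z = np.array([0, 1, 0, 1, np.nan, 0, 1, 0, 1, 0])
        y = np.array([1, 2, 1, 2, 1, np.nan, 2, 1, 2, 1], dtype=float)
        s = np.zeros(10)
        res = conditional_mi_test(z, y, s)
        assert res.n == 8

    def test_calibration_under_conditional_null(self, rng):
        """p-values roughly uniform when Z ⊥ Y within every stratum."""
        ps = []
        for _ in range(300):
            n = 1000
            s = rng.integers(0, 5, n).astype(float)
            p_s = rng.uniform(0.3, 0.7, 5)
            z = (rng.random(n) < p_s[s.astype(int)]).astype(float)
            y = rng.choice([1.0, 2, 3, 4, 5], size=n, p=[0.1, 0.15, 0.2, 0.3, 0.25])
            ps.append(conditional_mi_test(z, y, s).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCMH:
    def test_matches_hand_evaluated_2x2x2(self):
        # U = (10-7) + (8-6.29032...) ; V = 2.032258 + 1.948075 ; Q = U^2/V
        arr = np.array([[[10, 6], [4, 12]], [[8, 7], [5, 11]]], dtype=float)
        z, y, s = expand_counts(arr)
        res = cmh_test(z, y, s)
        assert res.statistic == pytest.approx(5.572810457516341, rel=1e-12)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.01824145928629104, rel=1e-9)

    def test_matches_reference_general_association_2x3x2(self):
        # frozen from R stats::mantelhaen.test(correct=FALSE)
        arr = np.array(
            [[[12, 8, 6], [5, 9, 13]], [[10, 9, 5], [7, 8, 12]]], dtype=float
        )
        z, y, s = expand_counts(arr)
        res = cmh_test(z, y, s)
        assert res.statistic == pytest.approx(8.120775490359815, rel=1e-9)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.0172423321878219, rel=1e-6)

    def test_balanced_independent_strata_near_zero(self):
        counts = np.array(
            [[[25, 25], [25, 25]], [[40, 40], [40, 40]]], dtype=float
        )
        z, y, s = expand_counts(counts)
        res = cmh_test(z, y, s)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_engines_agree_in_decision_and_rank(self, rng):
        """Both engines are calibrated under the conditional null and track
        the same signal: decisions at alpha=0.05 agree on most null
        replicates, and p-values rank-correlate across an effect gradient.
        (The two statistics have different df, so their null p-values are
        only weakly coupled replicate-by-replicate; decision agreement and
        monotone co-movement with signal are the meaningful properties.)
        """
        p_g2, p_cmh = [], []
        for _ in range(200):
            n = 800
            s = rng.integers(0, 4, n).astype(float)
            z = rng.integers(0, 2, n).astype(float)
            y = rng.integers(1, 6, n).astype(float)
            p_g2.append(conditional_mi_test(z, y, s).p_value)
            p_cmh.append(cmh_test(z, y, s).p_value)
        p_g2, p_cmh = np.asarray(p_g2), np.asarray(p_cmh)
        for p in (p_g2, p_cmh):
            assert 0.01 <= (p < 0.05).mean() <= 0.10
        assert ((p_g2 < 0.05) == (p_cmh < 0.05)).mean() >= 0.85

        # effect gradient: shift the Y distribution with z by a varying amount
        grad_g2, grad_cmh = [], []
        for k in range(80):
            delta = 0.04 * (k % 10)
            n = 600
            s = rng.integers(0, 3, n).astype(float)
            z = rng.integers(0, 2, n).astype(float)
            base = rng.random(n)
            y = np.ceil(5 * np.clip(base + delta * z, 1e-9, 1.0)).astype(float)
            grad_g2.append(conditional_mi_test(z, y, s).p_value)
            grad_cmh.append(cmh_test(z, y, s).p_value)
        assert stats.spearmanr(grad_g2, grad_cmh).statistic > 0.5


class TestCramersV:
    def test_zero_statistic(self):
        v, label = cramers_v(0.0, 100, 2, 5)
        assert v == 0.0 and label == "negligible"

    def test_perfect_association(self):
        v, label = cramers_v(20.0, 20, 2, 2)
        assert v == pytest.approx(1.0) and label == "large"

    def test_direct_formula_2x5(self):
        v, label = cramers_v(9.6, 240, 2, 5)
        assert v == pytest.approx(0.2)
        assert label == "low"

    def test_requires_two_levels(self):
        with pytest.raises(ValueError):
            cramers_v(1.0, 10, 1, 5)

    def test_truncated_to_unit_interval(self):
        v, _ = cramers_v(1e6, 10, 2, 2)
        assert v == 1.0
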