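"""FDR estimators: TDC, decoy p-values, Storey, Sidak, TEV, adjustments."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

import partval as pv
from partval.errors import ConfigError, FormatError
from partval.estimators import StoreyConfig, TevParams, estimate_pi0, validate_null_table

from conftest import make_table


def brute_tdc_fdr(targets, decoys, x):
    nt = sum(1 for t in targets if t >= x)
    nd = sum(1 for d in decoys if d >= x)
    return min(1.0, (nd + 1) / nt) if nt else float("nan")


class TestTdc:
    def test_no_decoys_above(self):
        assert pv.tdc_fdr(range(10, 20), [5, 6], 10) == pytest.approx((0 + 1) / 10)

    def test_clipped_to_one(self):
        assert pv.tdc_fdr([10.0], [11, 12, 13], 10) == 1.0

    def test_below_all_scores(self):
        t = np.arange(100) + 10.0
        d = np.arange(9) + 10.0
        assert pv.tdc_fdr(t, d, 0.0) == pytest.approx((9 + 1) / 100)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            t = rng.normal(size=rng.integers(1, 20))
            d = rng.normal(size=rng.integers(0, 20))
            x = rng.normal()
            got = pv.tdc_fdr(t, d, x)
            exp = brute_tdc_fdr(t, d, x)
            assert (np.isnan(got) and np.isnan(exp)) or got == pytest.approx(exp)

    def test_qvalues_running_min_example(self):
        # scores descending with raw FDR sequence [0.2, 0.1, 0.3]
        # -> q = [0.1, 0.1, 0.3]
        targets = [30.0, 20.0, 10.0]
        # brute-force check via oracle below rather than constructing decoys
        fdr = np.array([0.2, 0.1, 0.3])
        q = np.minimum.accumulate(fdr[::-1])[::-1]
        assert list(q) == [0.1, 0.1, 0.3]
        # implementation: q_i = min over x' <= x_i of fdr(x')
        d = [19.0, 19.5, 20.5]  # constructed so fdr is non-monotone
        got = pv.tdc_qvalues(targets, d)
        exp = []
        for x in targets:
            exp.append(min(brute_tdc_fdr(targets, d, xp)
                           for xp in targets if xp <= x))
        assert np.allclose(got, exp)

    def test_qvalues_match_oracle_random(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            t = rng.normal(size=rng.integers(1, 15))
            d = rng.normal(size=rng.integers(1, 15))
            got = pv.tdc_qvalues(t, d)
            exp = [min(brute_tdc_fdr(t, d, xp) for xp in t if xp <= x)
                   for x in t]
            assert np.allclose(got, exp)

    def test_acceptance_sets_nest(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=500)
        d = rng.normal(size=500)
        q = pv.tdc_qvalues(t, d)
        prev = set()
        for g in (0.01, 0.05, 0.1, 0.5, 1.0):
            acc = set(np.flatnonzero(q <= g))
            assert prev <= acc
            prev = acc

    def test_single_target(self):
        assert pv.tdc_qvalues([5.0], [4.0])[0] == pv.tdc_fdr([5.0], [4.0], 5.0)


class TestDecoyPvalue:
    def test_counting_example(self):
        assert pv.decoy_pvalue(2.5, [1, 2, 3]) == pytest.approx((1 + 1) / (3 + 1))

    def test_above_all(self):
        assert pv.decoy_pvalue(99, [1, 2, 3]) == pytest.approx(1 / 4)

    def test_below_all(self):
        assert pv.decoy_pvalue(0, [1, 2, 3]) == 1.0

    def test_empty_decoys_rejected(self):
        with pytest.raises(ValueError):
            pv.decoy_pvalue(1.0, [])

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            d = rng.normal(size=rng.integers(1, 30))
            x = rng.normal()
            exp = (sum(1 for v in d if v >= x) + 1) / (len(d) + 1)
            assert pv.decoy_pvalue(x, d) == pytest.approx(exp)


def brute_storey_q(p, pi0):
    p = np.asarray(p, dtype=float)
    m = len(p)
    out = []
    for pi in p:
        cands = [pi0 * m * t / np.sum(p <= t) for t in p if t >= pi]
        out.append(min(1.0, min(cands)))
    return np.array(out)


class TestStorey:
    def test_pi0_worked_example(self):
        p = [0.01, 0.02, 0.03, 0.9]
        assert estimate_pi0(p, StoreyConfig(pi0_lambda=0.5)) == pytest.approx(
            1 / (0.5 * 4))

    def test_qvalues_match_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 25))
            pi0 = estimate_pi0(p)
            assert np.allclose(pv.storey_qvalues(p), brute_storey_q(p, pi0))

    def test_all_ones(self):
        q = pv.storey_qvalues([1.0, 1.0, 1.0])
        assert (q == 1.0).all()

    def test_pi0_one_equals_bh(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.uniform(1e-9, 1, size=rng.integers(2, 200))
            q = pv.storey_qvalues(p, StoreyConfig(pi0_override=1.0))
            bh = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, bh)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=500)
        q = pv.storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            pv.storey_qvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            pv.storey_qvalues([])

    def test_smoother_runs(self):
        rng = np.random.default_rng(8)
        p = np.concatenate([rng.uniform(size=500),
                            rng.uniform(0, 0.01, size=100)])
        pi0 = estimate_pi0(p, StoreyConfig(pi0_method="smoother"))
        assert 0 < pi0 <= 1


class TestSidak:
    def test_zero(self):
        assert pv.sidak_adjust(0.0, 50) == 0.0

    def test_identity_at_one_candidate(self):
        assert pv.sidak_adjust(0.37, 1) == pytest.approx(0.37)

    def test_worked_example(self):
        assert pv.sidak_adjust(0.01, 100) == pytest.approx(1 - 0.99 ** 100)
        assert pv.sidak_adjust(0.01, 100) == pytest.approx(0.63397, abs=1e-5)

    def test_vectorised_and_bounds(self):
        out = pv.sidak_adjust([0.0, 0.5, 1.0], 3)
        assert out[0] == 0.0 and out[2] == 1.0 and 0 < out[1] < 1


class TestTev:
    def test_zero_at_n0(self):
        assert pv.tev(1000.0) == pytest.approx(0.0)

    def test_unit_evalue(self):
        assert pv.tev(1.0) == pytest.approx(0.02 * np.log(1000))
        assert pv.tev(1.0) == pytest.approx(0.13816, abs=1e-5)

    def test_log_linearity(self):
        for e in (1e-8, 1e-3, 0.5, 10.0):
            assert pv.tev(e) - pv.tev(10 * e) == pytest.approx(0.02 * np.log(10))

    def test_strictly_decreasing(self):
        e = np.logspace(-10, 3, 50)
        assert (np.diff(pv.tev(e)) < 0).all()

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pv.tev(0.0)


class TestSubsetAdjustment:
    def test_evalue_scales_with_k(self):
        assert pv.adjust_score_for_subset(0.5, 2, "e_value") == pytest.approx(1.0)

    def test_tev_shift(self):
        t = 0.3
        assert pv.adjust_score_for_subset(t, 2, "tev") == pytest.approx(
            t + 0.02 * np.log(2))

    def test_space_independent_unchanged(self):
        assert pv.adjust_score_for_subset(0.77, 5, "space_independent") == 0.77

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            pv.adjust_score_for_subset(1.0, 2, "dot_product")

    def test_gumbel_requires_scale(self):
        with pytest.raises(ConfigError):
            pv.adjust_score_for_subset(1.0, 2, "gumbel")


class TestEmpiricalNull:
    table = pd.DataFrame({"score": [1.0, 2.0, 3.0],
                          "tail_prob": [0.5, 0.10, 0.06]})

    def test_knot_lookup(self):
        assert pv.empirical_null_pvalue(2.0, self.table) == 0.10

    def test_below_min_clamps_to_one(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert pv.empirical_null_pvalue(0.0, self.table) == 1.0

    def test_midpoint_interpolation(self):
        assert pv.empirical_null_pvalue(2.5, self.table) == pytest.approx(0.08)

    def test_non_monotone_rejected(self):
        bad = pd.DataFrame({"score": [1.0, 2.0], "tail_prob": [0.1, 0.2]})
        with pytest.raises(FormatError):
            pv.empirical_null_pvalue(1.5, bad)
        validate_null_table(self.table)  # the good one passes


class TestCompete:
    def test_winner_per_spectrum(self):
        t = make_table([("s1", 1, "A", 10.0), ("s2", 1, "B", 3.0)])
        d = make_table([("s1", 1, "X", 9.0, True), ("s2", 1, "Y", 4.0, True)])
        win = pv.compete(t, d)
        w = win.set_index("spectrum_id")
        assert not w.loc["s1", "is_decoy"] and w.loc["s1", "score"] == 10.0
        assert w.loc["s2", "is_decoy"] and w.loc["s2", "score"] == 4.0
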