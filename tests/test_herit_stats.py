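import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.stats import chi2

from beetol import herit_stats as hs


class TestChisq:
    def test_colony_mortality_table_with_yates(self):
        """69/247 vs 40/249 dead: the published Yates-corrected 9.510."""
        r = hs.chisq_test([[69, 178], [40, 209]], yates=True)
        assert r.statistic == pytest.approx(9.510, abs=5e-4)
        assert r.df == 1
        assert r.pvalue == pytest.approx(0.002, abs=5e-4)

    def test_uncorrected_matches_hand_computed_pearson(self):
        obs = np.array([[69, 178], [40, 209]], float)
        rows, cols = obs.sum(1), obs.sum(0)
        expected = np.outer(rows, cols) / obs.sum()
        oracle = ((obs - expected) ** 2 / expected).sum()
        r = hs.chisq_test(obs.astype(int), yates=False)
        assert r.statistic == pytest.approx(oracle, rel=1e-12)
        assert r.statistic == pytest.approx(10.19, abs=5e-3)

    def test_flat_table_stat_zero_p_one(self):
        r = hs.chisq_test([[5, 5], [5, 5]], monte_carlo_B=999, seed=0)
        assert r.statistic == 0.0
        assert r.pvalue == pytest.approx(1.0)
        assert r.monte_carlo_p == pytest.approx(1.0)

    def test_zero_margin_is_error(self):
        with pytest.raises(ValueError, match="margin"):
            hs.chisq_test([[0, 0], [3, 4]])

    def test_monte_carlo_p_in_valid_range(self):
        r = hs.chisq_test([[30, 5], [5, 30]], monte_carlo_B=499, seed=1)
        assert 1 / 500 <= r.monte_carlo_p <= 1.0

    def test_monte_carlo_converges_to_asymptotic(self):
        """100-per-cell null table: |MC p - asymptotic p| < 0.02 at B = 20000."""
        r = hs.chisq_test([[100, 100], [100, 100]], yates=False,
                          monte_carlo_B=20000, seed=3)
        assert abs(r.monte_carlo_p - r.pvalue) < 0.02

    def test_monte_carlo_rxc_matches_chi2_tail(self):
        """3x2 table: simulated tail agrees with the asymptotic chi2 tail."""
        r = hs.chisq_test(
            [[40, 60], [55, 45], [50, 50]], monte_carlo_B=2000, seed=4
        )
        assert abs(r.monte_carlo_p - r.pvalue) < 0.05


class TestFactorDeviance:
    def test_null_deviance_closed_form(self):
        # 5 deaths / 10 at p=0.5: deviance = 2*10*ln2
        y = [1] * 5 + [0] * 5
        fit = hs.fit_factor_logit(y, ["a"] * 10)
        assert fit.deviance == pytest.approx(20 * np.log(2), rel=1e-12)

    def test_perfect_separation_zero_deviance(self):
        y = [1, 1, 1, 0, 0]
        labels = ["a", "a", "a", "b", "b"]
        assert hs.fit_factor_logit(y, labels).deviance == pytest.approx(0.0)

    def test_equal_cell_rates_equal_pooled_null(self):
        y = [1, 0, 1, 0]
        two = hs.fit_factor_logit(y, ["a", "a", "b", "b"]).deviance
        one = hs.fit_factor_logit(y, ["x"] * 4).deviance
        assert two == pytest.approx(one, rel=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_closed_form_equals_irls(self, data):
        n = data.draw(st.integers(8, 40))
        y = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        labels = data.draw(
            st.lists(st.sampled_from("abc"), min_size=n, max_size=n)
        )
        closed = hs.fit_factor_logit(y, labels)
        irls = hs.fit_factor_logit_irls(y, labels)
        assert closed.deviance == pytest.approx(irls.deviance, abs=1e-8)


class TestPartition:
    def test_h2_doubling_rule(self):
        assert hs.h2_from_patriline_share(0.189) == pytest.approx(0.378)
        assert hs.h2_from_patriline_share(0.172) == pytest.approx(0.344)

    def test_null_structure_small_patriline_share(self, rng):
        n = 6000
        y = rng.random(n) < 0.25
        colony = rng.choice(["C1", "C2"], n)
        pat = np.char.add(colony, rng.choice([f":P{i}" for i in range(10)], n))
        part = hs.partition_deviance(y.astype(float), colony, pat)
        assert part.share_patriline < 0.01
        assert part.h2 < 0.02

    def test_shares_sum_to_one_and_nonnegative(self, rng):
        n = 400
        colony = rng.choice(["C1", "C2"], n)
        pat = np.char.add(colony, rng.choice([":Pa", ":Pb", ":Pc"], n))
        y = (rng.random(n) < 0.3).astype(float)
        part = hs.partition_deviance(y, colony, pat)
        assert sum(part.shares) == pytest.approx(1.0, abs=1e-10)
        assert all(s >= -1e-12 for s in part.shares)

    def test_shares_invariant_to_relabeling(self, rng):
        n = 300
        colony = rng.choice(["C1", "C2"], n)
        pat = np.char.add(colony, rng.choice([":Pa", ":Pb"], n))
        y = (rng.random(n) < 0.4).astype(float)
        a = hs.partition_deviance(y, colony, pat)
        remap = {"C1": "zebra", "C2": "ant"}
        colony2 = [remap[c] for c in colony]
        pat2 = [remap[p[:2]] + p[2:] for p in pat]
        b = hs.partition_deviance(y, colony2, pat2)
        assert a.shares == pytest.approx(b.shares, rel=1e-12)

    def test_patriline_spanning_colonies_rejected(self):
        with pytest.raises(ValueError, match="span"):
            hs.partition_deviance([1, 0, 1, 0], ["C1", "C1", "C2", "C2"],
                                  ["P1", "P1", "P1", "P2"])


class TestFilterMinWorkers:
    def _data(self, sizes):
        workers, pats = [], []
        k = 0
        for i, size in enumerate(sizes):
            for _ in range(size):
                workers.append(f"w{k}")
                pats.append(f"P{i}")
                k += 1
        assign = pd.DataFrame({"worker_id": workers, "patriline": pats})
        pheno = pd.DataFrame(
            {"worker_id": workers, "colony": "C1", "dose_group": "lethal",
             "survived": True, "consumed_fraction": 1.0}
        )
        return assign, pheno

    def test_at_least_five_rule(self):
        assign, pheno = self._data([6, 5, 4, 1])
        out = hs.filter_min_workers(assign, pheno, min_n=5)
        assert sorted(out["patriline"].unique()) == ["P0", "P1"]
        assert len(out) == 11

    def test_min_one_is_identity(self):
        assign, pheno = self._data([3, 2])
        assert len(hs.filter_min_workers(assign, pheno, min_n=1)) == 5

    def test_threshold_above_all_sizes_empty(self):
        assign, pheno = self._data([3, 2])
        assert hs.filter_min_workers(assign, pheno, min_n=10).empty


def _brute_force_deviance(data, terms, response, trials):
    """Direct likelihood maximization of the additive-logit binomial model,
    independent of IRLS: optimize coefficients with Nelder-Mead restarts."""
    X = np.ones((len(data), 1))
    for t in terms:
        d = pd.get_dummies(data[t], drop_first=True).to_numpy(float)
        X = np.hstack([X, d])
    s = data[response].to_numpy(float)
    n = data[trials].to_numpy(float)

    def negll(beta):
        eta = X @ beta
        return float(np.sum(n * np.log1p(np.exp(eta)) - s * eta))

    best = None
    for start in (np.zeros(X.shape[1]), np.full(X.shape[1], 0.3)):
        res = minimize(negll, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    p = 1 / (1 + np.exp(-(X @ best.x)))
    return hs.binomial_deviance(s, n, p)


class TestAnodev:
    def _agg(self, rng, nA=3, nB=2, rows=12):
        return pd.DataFrame({
            "A": rng.choice([f"a{i}" for i in range(nA)], rows),
            "B": rng.choice([f"b{i}" for i in range(nB)], rows),
            "n": rng.integers(5, 30, rows),
        }).assign(s=lambda d: rng.binomial(d["n"], 0.4))

    def test_single_term_equals_sequential(self, rng):
        d = self._agg(rng)
        rows = hs.anodev_type2(d, ["A"], response="s", trials="n")
        null = hs.binomial_deviance(d["s"], d["n"],
                                    np.full(len(d), d["s"].sum() / d["n"].sum()))
        grouped = d.groupby("A")[["s", "n"]].sum()
        p = d["A"].map(grouped["s"] / grouped["n"]).to_numpy()
        dev_A = hs.binomial_deviance(d["s"], d["n"], p)
        assert rows[0].lr_chi2 == pytest.approx(null - dev_A, abs=1e-6)

    def test_aliased_term_flagged(self, rng):
        d = self._agg(rng)
        d["A2"] = d["A"]  # exact alias
        rows = {r.term: r for r in hs.anodev_type2(d, ["A", "A2"], "s", trials="n")}
        assert rows["A2"].flagged and rows["A2"].df == 0 and rows["A2"].pvalue == 1.0

    def test_two_factor_lr_matches_brute_force(self, rng):
        d = self._agg(rng, rows=14)
        rows = {r.term: r for r in hs.anodev_type2(d, ["A", "B"], "s", trials="n")}
        dev_full = _brute_force_deviance(d, ["A", "B"], "s", "n")
        for term, other in (("A", "B"), ("B", "A")):
            dev_red = _brute_force_deviance(d, [other], "s", "n")
            assert rows[term].lr_chi2 == pytest.approx(dev_red - dev_full, abs=1e-3)

    def test_p_from_chi2_tail(self, rng):
        d = self._agg(rng)
        row = hs.anodev_type2(d, ["A"], "s", trials="n")[0]
        assert row.pvalue == pytest.approx(chi2.sf(row.lr_chi2, row.df), rel=1e-9)


class TestCorrelation:
    def test_t_from_r_identity_published_values(self):
        t, p = hs.t_from_r(-0.513, 18)
        assert t == pytest.approx(-2.537, abs=0.01)
        assert p == pytest.approx(0.021, abs=0.002)

    def test_perfect_positive(self):
        x = np.arange(10.0)
        r = hs.pearson_cor_test(x, 2 * x + 1)
        assert r.r == pytest.approx(1.0)
        assert r.pvalue == pytest.approx(0.0, abs=1e-12)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert hs.pearson_cor_test(x, -x).r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            hs.pearson_cor_test([1, 1, 1, 1], [1, 2, 3, 4])
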