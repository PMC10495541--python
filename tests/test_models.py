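import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from splicemir.categorize import PairUniverse, Setting
from splicemir.config import PipelineConfig
from splicemir.io import ExpressionMatrix, TargetSiteRecord, TranscriptCatalog, TranscriptModel
from splicemir.models import (
    OLSFit,
    benjamini_hochberg,
    cohens_f2,
    fit_ols,
    fit_pair,
    likelihood_ratio_test,
    rmse_on,
    select_covariate_mirna,
    split_samples,
)


class TestSplitSamples:
    def test_eighty_twenty(self, cfg):
        ids = [f"s{i}" for i in range(10)]
        sp = split_samples(ids, cfg)
        assert len(sp.train_ids) == 8 and len(sp.test_ids) == 2
        assert sorted(sp.train_ids + sp.test_ids) == sorted(ids)

    def test_deterministic_given_seed(self, cfg):
        ids = [f"s{i}" for i in range(25)]
        assert split_samples(ids, cfg).train_ids == split_samples(ids, cfg).train_ids

    def test_adjacent_seeds_differ(self):
        ids = [f"s{i}" for i in range(100)]
        distinct = 0
        for s in range(50):
            a = split_samples(ids, PipelineConfig(random_seed=s))
            b = split_samples(ids, PipelineConfig(random_seed=s + 1000))
            distinct += a.train_ids != b.train_ids
        assert distinct == 50

    def test_too_few_samples(self, cfg):
        with pytest.raises(ValueError):
            split_samples(["a"] * 5, cfg)


class TestFitOLS:
    def test_noiseless_line_recovered_exactly(self):
        t = np.linspace(0, 1, 20)
        fit = fit_ols(t, 2.0 * t + 1.0, predictor_ids=["t"])
        assert fit.coefficients["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert fit.coefficients["t"] == pytest.approx(2.0, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        fit = fit_ols(X, y)
        Xd = np.column_stack([np.ones(20), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        got = np.array([fit.coefficients["intercept"]] +
                       [fit.coefficients[f"x{i}"] for i in range(3)])
        assert np.allclose(got, beta, atol=1e-8)

    def test_duplicated_predictor_sets_degeneracy_flag(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(15)
        y = 0.5 * x + rng.standard_normal(15)
        dup = fit_ols(np.column_stack([x, x]), y)
        single = fit_ols(x[:, None], y)
        assert dup.degenerate and not single.degenerate
        # fitted values (hence RSS) agree: same column space
        assert dup.rss == pytest.approx(single.rss, abs=1e-9)


class TestRMSE:
    def test_perfect_fit_zero(self):
        t = np.arange(5.0)
        fit = fit_ols(t, 3 * t, predictor_ids=["t"])
        assert rmse_on(fit, t, 3 * t) == pytest.approx(0.0, abs=1e-10)

    def test_unit_residuals(self):
        fit = OLSFit({"intercept": 0.0, "t": 0.0}, ["t"], 0.0, 2, 2, 0.0)
        # predictions are 0; residuals (1, -1) -> RMSE 1
        assert rmse_on(fit, np.array([5.0, 6.0]), np.array([1.0, -1.0])) == pytest.approx(1.0)

    def test_empty_sample_set_rejected(self):
        fit = OLSFit({"intercept": 0.0, "t": 0.0}, ["t"], 0.0, 2, 2, 0.0)
        with pytest.raises(ValueError):
            rmse_on(fit, np.empty((0, 1)), np.array([]))


def _fit(rss, n_params, n_train=50, ids=None):
    ids = ids if ids is not None else [f"x{i}" for i in range(n_params - 1)]
    return OLSFit({pid: 0.0 for pid in ["intercept"] + ids}, ids, rss, n_train, n_params, 0.0)


class TestLRT:
    def test_equal_rss_gives_unit_p(self):
        lam, df, p = likelihood_ratio_test(_fit(5.0, 3), _fit(5.0, 2, ids=["x0"]))
        assert lam == 0.0 and df == 1 and p == 1.0

    def test_closed_form_statistic(self):
        full = _fit(5.0, 4, ids=["x0", "x1", "x2"])
        red = _fit(10.0, 2, ids=["x0"])
        lam, df, p = likelihood_ratio_test(full, red)
        assert lam == pytest.approx(50 * math.log(2), rel=1e-12)
        assert df == 2
        assert p == pytest.approx(stats.chi2.sf(50 * math.log(2), 2), rel=1e-12)

    def test_negative_statistic_clipped(self):
        # reduced RSS below full RSS can only be numerical error
        lam, _, p = likelihood_ratio_test(_fit(5.0, 3), _fit(4.999999, 2, ids=["x0"]))
        assert lam == 0.0 and p == 1.0

    def test_non_nested_rejected(self):
        full = _fit(5.0, 3, ids=["a", "b"])
        red = _fit(6.0, 2, ids=["z"])
        with pytest.raises(ValueError):
            likelihood_ratio_test(full, red)

    def test_p_monotone_in_statistic(self):
        ps = [likelihood_ratio_test(_fit(5.0, 3), _fit(r, 2, ids=["x0"]))[2]
              for r in (5.5, 6.5, 9.0)]
        assert ps[0] > ps[1] > ps[2]


def _bh_stepup_oracle(p):
    """Textbook BH: sort, multiply by m/i, enforce monotonicity, unsort."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestBenjaminiHochberg:
    def test_hand_applied_stepup(self):
        adj, flags = benjamini_hochberg([0.01, 0.02, 0.03], alpha=0.05)
        assert np.allclose(adj, [0.03, 0.03, 0.03])
        assert flags.all()

    def test_all_ones(self):
        adj, flags = benjamini_hochberg([1.0, 1.0, 1.0])
        assert np.all(adj == 1.0) and not flags.any()

    def test_single_p_unchanged(self):
        adj, _ = benjamini_hochberg([0.2])
        assert adj[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_stepup_oracle(self, pvals):
        adj, _ = benjamini_hochberg(pvals)
        assert np.allclose(adj, _bh_stepup_oracle(pvals), atol=1e-12)


class TestCohensF2:
    @pytest.mark.parametrize(
        "full,red,value,binname",
        [
            (0.3, 0.3, 0.0, "none"),
            (0.5, 0.2, 0.6, "large"),
            (0.1, 0.08, 0.02 / 0.9, "small"),
        ],
    )
    def test_formula_and_bins(self, full, red, value, binname):
        f2, b = cohens_f2(full, red)
        assert f2 == pytest.approx(value, rel=1e-12)
        assert b == binname

    @pytest.mark.parametrize("f2,binname", [(0.02, "small"), (0.15, "medium"), (0.35, "large")])
    def test_boundaries_inclusive(self, f2, binname):
        # choose adjR2 pair hitting the boundary exactly: full=0, reduced=-f2
        got, b = cohens_f2(0.0, -f2)
        assert got == pytest.approx(f2) and b == binname

    def test_full_r2_of_one_rejected(self):
        with pytest.raises(ValueError):
            cohens_f2(1.0, 0.5)


def _mirna_matrix(cols):
    df = pd.DataFrame(cols)
    df.index = [f"s{i}" for i in range(len(df))]
    return ExpressionMatrix("mirna", df)


class TestSelectCovariate:
    @staticmethod
    def _setup(noncoding_binders):
        cat = TranscriptCatalog()
        cat.add(TranscriptModel("t0", "g1", 1000, 100, 700))
        cat.add(TranscriptModel("t1", "g1", 1000, 100, 700))
        pair = PairUniverse("m1", "g1", Setting.TNBN, frozenset({"t0", "t1"}), frozenset({"t0"}))
        sites = [TargetSiteRecord(m, "t0", 800, 807, 0.7) for m in noncoding_binders]
        return pair, sites, cat

    def test_no_candidates_returns_none(self, cfg):
        pair, sites, cat = self._setup([])
        expr = _mirna_matrix({"m1": np.arange(5.0)})
        assert select_covariate_mirna(pair, sites, expr, cat, cfg) is None

    def test_highest_correlation_wins(self, cfg):
        pair, sites, cat = self._setup(["mA", "mB"])
        rng = np.random.default_rng(0)
        base = rng.standard_normal(50)
        expr = _mirna_matrix({
            "m1": base,
            "mA": base + 0.1 * rng.standard_normal(50),   # r ~ 0.99
            "mB": rng.standard_normal(50),                 # r ~ 0
        })
        assert select_covariate_mirna(pair, sites, expr, cat, cfg) == "mA"

    def test_tie_broken_lexicographically(self, cfg):
        pair, sites, cat = self._setup(["mB", "mA"])
        base = np.arange(10.0)
        expr = _mirna_matrix({"m1": base, "mA": 2 * base, "mB": 2 * base})
        assert select_covariate_mirna(pair, sites, expr, cat, cfg) == "mA"

    def test_coding_only_sites_not_candidates(self, cfg):
        pair, _, cat = self._setup([])
        sites = [TargetSiteRecord("mA", "t0", 150, 157, 0.9)]  # CDS only
        expr = _mirna_matrix({"m1": np.arange(5.0), "mA": np.arange(5.0)})
        assert select_covariate_mirna(pair, sites, expr, cat, cfg) is None


def _pair_data(n, effect, noise_sd, rng, mirna_sd=1.0):
    """One gene, transcripts tb (binding) and tn (escape), miRNA m1."""
    m = rng.standard_normal(n) * mirna_sd
    tb = -effect * m + noise_sd * rng.standard_normal(n)
    tn = noise_sd * rng.standard_normal(n)
    samples = [f"s{i}" for i in range(n)]
    tx = ExpressionMatrix("transcript", pd.DataFrame({"tb": tb, "tn": tn}, index=samples))
    mi = ExpressionMatrix("mirna", pd.DataFrame({"m1": m}, index=samples))
    return tx, mi


class TestFitPair:
    pair = PairUniverse("m1", "g1", Setting.TNBN, frozenset({"tb", "tn"}), frozenset({"tn"}))

    def test_planted_effect_detected(self, cfg):
        tx, mi = _pair_data(100, effect=1.0, noise_sd=0.05, rng=np.random.default_rng(1))
        split = split_samples(tx.sample_ids, cfg)
        res = fit_pair(self.pair, tx, mi, split, cfg)
        assert res.p < 0.01
        assert res.cohens_f2 > 0.35 and res.effect_bin == "large"
        assert res.k == 1 and res.l == 1 and res.df == 1

    def test_null_effect_p_roughly_uniform(self, cfg):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(200):
            tx, mi = _pair_data(60, effect=0.0, noise_sd=1.0, rng=rng)
            split = split_samples(tx.sample_ids, cfg)
            ps.append(fit_pair(self.pair, tx, mi, split, cfg).p)
        d = stats.kstest(ps, "uniform").statistic
        assert d < 0.12

    def test_covariate_equal_to_response_saturates(self, cfg):
        # m2 == m1: the reduced model is already (near) perfect, LRT gains nothing
        rng = np.random.default_rng(3)
        tx, mi = _pair_data(80, effect=1.0, noise_sd=0.1, rng=rng)
        mi.values["m2"] = mi.values["m1"]
        split = split_samples(tx.sample_ids, cfg)
        res = fit_pair(self.pair, tx, mi, split, cfg, covariate="m2")
        assert res.covariate_mirna == "m2"
        assert res.p > 0.5

    def test_insufficient_samples_skipped(self, cfg):
        tx, mi = _pair_data(12, effect=1.0, noise_sd=0.1, rng=np.random.default_rng(4))
        tiny = PipelineConfig(random_seed=0, train_fraction=0.25)
        split = split_samples(tx.sample_ids, tiny)  # 3 train samples < 4 params
        assert fit_pair(self.pair, tx, mi, split, tiny) is None

    def test_rmse_gate_requires_both_models(self, cfg):
        # strong effect, big miRNA sd: full fits well, reduced cannot
        tx, mi = _pair_data(100, effect=1.0, noise_sd=0.05,
                            rng=np.random.default_rng(5), mirna_sd=2.0)
        split = split_samples(tx.sample_ids, cfg)
        res = fit_pair(self.pair, tx, mi, split, cfg)
        assert res.rmse_full < cfg.rmse_threshold < res.rmse_reduced
        assert not res.passed_rmse_gate

    def test_nesting_rss_inequality(self, cfg):
        rng = np.random.default_rng(6)
        for _ in range(20):
            tx, mi = _pair_data(40, effect=rng.uniform(0, 1), noise_sd=0.5, rng=rng)
            split = split_samples(tx.sample_ids, cfg)
            res = fit_pair(self.pair, tx, mi, split, cfg)
            assert res.lrt_stat >= 0.0  # equivalent to rss_full <= rss_reduced
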