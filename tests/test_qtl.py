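"""Mapping-engine tests: scan oracles, stepwise selection, R2 partition,
epistasis bookkeeping and interval behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rilqtl import simdata
from rilqtl.qtl import (
    StepwiseQtlModel,
    epistasis_scan,
    partial_r2,
    qtl_interval,
    report_qtls,
    single_marker_scan,
    stepwise_multi_snp,
    total_r2,
)

from conftest import make_geno


def _greedy_forward_oracle(X, y, alpha):
    """Independent greedy-forward selection by exhaustive OLS refitting."""
    import statsmodels.api as sm

    selected = []
    while True:
        best = None
        for j in range(X.shape[1]):
            if j in selected:
                continue
            design = sm.add_constant(X[:, selected + [j]])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                continue
            fit = sm.OLS(y, design).fit()
            p = fit.pvalues[-1]
            if best is None or p < best[1]:
                best = (j, p)
        if best is None or best[1] >= alpha:
            return selected
        selected.append(best[0])


class TestSingleMarkerScan:
    def test_orthogonal_marker_has_zero_effect_and_p_one(self):
        # balanced marker, trait anti-symmetric within genotype classes
        calls = np.array([[0, 0, 0, 0, 2, 2, 2, 2]], dtype=np.int8).T
        y = np.array([1.0, -1.0, 2.0, -2.0, 1.0, -1.0, 2.0, -2.0])
        out = single_marker_scan(make_geno(calls), y)
        assert out["effect"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["neglog10p"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_group_regression_equals_pooled_t_test(self):
        rng = np.random.default_rng(3)
        a = 10 + rng.normal(0, 2, 5)
        b = 20 + rng.normal(0, 2, 5)
        calls = np.array([[0] * 5 + [2] * 5], dtype=np.int8).T
        y = np.concatenate([a, b])
        out = single_marker_scan(make_geno(calls), y)
        t, p = stats.ttest_ind(b, a)
        assert out["effect"].iloc[0] == pytest.approx(b.mean() - a.mean())
        assert out["neglog10p"].iloc[0] == pytest.approx(-np.log10(p), rel=1e-9)

    def test_matches_brute_force_least_squares(self):
        rng = np.random.default_rng(4)
        calls = rng.choice([-1, 0, 1, 2], size=(25, 10), p=[0.1, 0.4, 0.1, 0.4]).astype(np.int8)
        g = make_geno(calls)
        y = rng.normal(size=25)
        out = single_marker_scan(g, y)
        d = g.dosage()
        for j in range(10):
            ok = np.isfinite(d[:, j])
            x = d[ok, j]
            if len(np.unique(x)) < 2 or ok.sum() < 3:
                assert np.isnan(out["effect"].iloc[j])
                continue
            A = np.column_stack([np.ones(ok.sum()), x])
            coef = np.linalg.solve(A.T @ A, A.T @ y[ok])
            resid = y[ok] - A @ coef
            s2 = resid @ resid / (ok.sum() - 2)
            se = np.sqrt(s2 * np.linalg.inv(A.T @ A)[1, 1])
            p = 2 * stats.t.sf(abs(coef[1] / se), ok.sum() - 2)
            assert out["effect"].iloc[j] == pytest.approx(coef[1], rel=1e-9)
            assert out["neglog10p"].iloc[j] == pytest.approx(-np.log10(p), rel=1e-6)

    def test_constant_marker_gets_missing_result(self):
        calls = np.zeros((10, 1), dtype=np.int8)
        out = single_marker_scan(make_geno(calls), np.arange(10.0))
        assert np.isnan(out["effect"].iloc[0])


class TestStepwise:
    def test_noiseless_trait_selects_exactly_the_causal_marker(self, ril_geno):
        j = 37
        y = 5.0 + 12.0 * np.nan_to_num(ril_geno.dosage()[:, j], nan=0.5)
        res = StepwiseQtlModel(ril_geno, y).fit()
        assert res.selected_markers == [ril_geno.markers["marker"].iloc[j]]
        assert res.r2_total == pytest.approx(100.0, abs=1e-6)

    def test_selection_reproduces_greedy_forward_oracle(self):
        rng = np.random.default_rng(11)
        alpha = 0.05  # permissive so several rounds happen on tiny instances
        for trial in range(6):
            calls = rng.choice([0, 2], size=(30, 12)).astype(np.int8)
            g = make_geno(calls)
            d = g.dosage()
            beta = np.zeros(12)
            beta[rng.choice(12, 2, replace=False)] = [1.5, 1.0]
            y = d @ beta + rng.normal(0, 1.0, 30)
            res = StepwiseQtlModel(g, y, alpha=alpha).fit()
            oracle = _greedy_forward_oracle(d, y, alpha)
            assert [g.markers["marker"].iloc[j] for j in oracle] == res.selected_markers

    def test_two_unlinked_qtls_recovered_without_extras(self):
        gmap = simdata.GeneticMap.uniform([80, 80], 120)
        hits = 0
        for s in range(10):
            g = simdata.simulate_ril_genomes(gmap, 200, 7, seed=500 + s)
            spec = simdata.QtlSpec(
                qtls=[(1, 40_000_000, 8.0), (2, 40_000_000, 8.0)], heritability=0.9
            )
            tab = simdata.simulate_phenotypes(g, spec, seed=600 + s)
            from rilqtl import pheno

            trait = pheno.line_traits(tab).rename(columns={"rnrg": "value"})[["line", "value"]]
            rep = StepwiseQtlModel(g, trait).fit().report("T")
            if len(rep) == 2 and sorted(rep["chrom"]) == [1, 2]:
                hits += 1
        assert hits >= 9

    def test_alpha_validation(self, ril_geno):
        with pytest.raises(ValueError):
            StepwiseQtlModel(ril_geno, np.zeros(118), alpha=2.0)


class TestR2Partition:
    def test_orthogonal_focal_marker_has_zero_partial_r2(self):
        # factorial design: two orthogonal markers, trait depends on first only
        calls = np.array(
            [[0, 0], [0, 2], [2, 0], [2, 2]] * 5, dtype=np.int8
        )
        g = make_geno(calls)
        # perturbation follows the interaction contrast: orthogonal to both
        # main-effect columns, so the second marker explains nothing
        y = g.dosage()[:, 0] * 4.0 + np.tile([0.1, -0.1, -0.1, 0.1], 5)
        names = g.markers["marker"].tolist()
        assert partial_r2(g, y, names, names[1]) == pytest.approx(0.0, abs=1e-9)

    def test_single_marker_model_partial_equals_total(self):
        rng = np.random.default_rng(12)
        calls = rng.choice([0, 2], size=(40, 3)).astype(np.int8)
        g = make_geno(calls)
        y = g.dosage()[:, 0] * 2 + rng.normal(0, 1, 40)
        name = g.markers["marker"].iloc[0]
        r2p = partial_r2(g, y, [name], name)
        r2t = total_r2(g, y, [name])
        x = g.dosage()[:, 0]
        r2_simple = np.corrcoef(x, y)[0, 1] ** 2 * 100
        assert r2p == pytest.approx(r2t, rel=1e-9)
        assert r2t == pytest.approx(r2_simple, rel=1e-9)

    def test_matches_independent_full_reduced_refits(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        calls = rng.choice([0, 1, 2], size=(35, 6)).astype(np.int8)
        g = make_geno(calls)
        d = g.dosage()
        y = d[:, :4] @ np.array([2.0, -1.0, 0.5, 1.0]) + rng.normal(0, 1, 35)
        model = g.markers["marker"].tolist()[:4]
        for focal_i in range(4):
            sse_f = sm.OLS(y, sm.add_constant(d[:, :4])).fit().ssr
            keep = [k for k in range(4) if k != focal_i]
            sse_r = sm.OLS(y, sm.add_constant(d[:, keep])).fit().ssr
            expect = 100 * (1 - sse_f / sse_r)
            assert partial_r2(g, y, model, model[focal_i]) == pytest.approx(expect, rel=1e-9)

    def test_r2_total_nondecreasing_along_forward_path(self, ril_geno):
        rng = np.random.default_rng(14)
        y = rng.normal(50, 5, 118) + ril_geno.dosage()[:, 10] * 6
        y = np.nan_to_num(y, nan=50.0)
        res = StepwiseQtlModel(ril_geno, y, alpha=0.2).fit(max_qtls=5)
        path = res.selected_markers
        r2s = [total_r2(ril_geno, y, path[: k + 1]) for k in range(len(path))]
        assert all(b >= a - 1e-9 for a, b in zip(r2s, r2s[1:]))

    def test_orthogonal_design_partials_sum_to_total(self):
        # 2x2 factorial replicated: markers exactly orthogonal
        calls = np.array([[0, 0], [0, 2], [2, 0], [2, 2]] * 8, dtype=np.int8)
        g = make_geno(calls)
        rng = np.random.default_rng(15)
        y = g.dosage() @ np.array([3.0, 1.5]) + rng.normal(0, 0.5, 32)
        names = g.markers["marker"].tolist()
        r2p = [partial_r2(g, y, names, n) for n in names]
        r2t = total_r2(g, y, names)
        # in the exactly orthogonal case sum R2P relative to SST... the nested
        # definition divides by SSE(reduced), so sum >= additive share; check bound
        ss_shares = []
        d = g.dosage()
        sst = np.sum((y - y.mean()) ** 2)
        for k in range(2):
            x = d[:, k] - d[:, k].mean()
            b = x @ y / (x @ x)
            ss_shares.append(100 * b**2 * (x @ x) / sst)
        assert r2t == pytest.approx(sum(ss_shares), rel=1e-6)
        for got, share in zip(r2p, ss_shares):
            assert got >= share - 1e-6


class TestEpistasis:
    def test_pair_count_bookkeeping(self):
        rng = np.random.default_rng(16)
        calls = rng.choice([0, 2], size=(60, 50)).astype(np.int8)
        g = make_geno(calls)
        y = rng.normal(size=60)
        model = g.markers["marker"].tolist()[:3]
        res = epistasis_scan(g, y, model)
        assert res.n_pairs_eligible == 3 + 141
        assert res.n_pairs_tested == 144

    def test_purely_additive_noiseless_trait_has_no_interactions(self):
        rng = np.random.default_rng(17)
        calls = rng.choice([0, 2], size=(80, 20)).astype(np.int8)
        g = make_geno(calls)
        y = g.dosage()[:, 2] * 3 + g.dosage()[:, 9] * 2
        model = [g.markers["marker"].iloc[2], g.markers["marker"].iloc[9]]
        res = epistasis_scan(g, y, model, alpha=0.001)
        assert len(res.significant) == 0

    def test_planted_xor_interaction_detected(self):
        detected = 0
        for s in range(10):
            rng = np.random.default_rng(700 + s)
            calls = rng.choice([0, 2], size=(100, 15)).astype(np.int8)
            g = make_geno(calls)
            d = g.dosage()
            # trait depends only on allele mismatch of markers 3 and 7
            y = (d[:, 3] != d[:, 7]).astype(float) * 5 + rng.normal(0, 0.5, 100)
            model = [g.markers["marker"].iloc[3], g.markers["marker"].iloc[7]]
            res = epistasis_scan(g, y, model, alpha=0.001)
            sig = res.significant
            pair = {model[0], model[1]}
            if any({r.marker1, r.marker2} == pair for r in sig.itertuples()):
                detected += 1
        assert detected >= 9

    def test_empty_model_rejected(self, ril_geno):
        with pytest.raises(ValueError):
            epistasis_scan(ril_geno, np.zeros(118), [])


class TestInterval:
    def test_noiseless_interval_collapses_to_causal_marker(self):
        # markers 5 cM apart: with 118 lines every neighbour recombines, so
        # only the causal marker fits the trait exactly
        gmap = simdata.GeneticMap.uniform([100], 21)
        g = simdata.simulate_ril_genomes(gmap, 118, 7, seed=77)
        j = 10
        y = 10.0 * np.nan_to_num(g.dosage()[:, j], nan=0.5)
        name = g.markers["marker"].iloc[j]
        ci = qtl_interval(g, y, [name], name)
        pos_mbp = g.markers["pos"].iloc[j] / 1e6
        assert ci["peak_mbp"] == pytest.approx(pos_mbp)
        assert ci["ci_lo_mbp"] == pytest.approx(pos_mbp)
        assert ci["ci_hi_mbp"] == pytest.approx(pos_mbp)

    def test_interval_contains_peak_and_is_ordered(self, ril_geno):
        rng = np.random.default_rng(19)
        y = 6 * np.nan_to_num(ril_geno.dosage()[:, 60], nan=0.5) + rng.normal(0, 2, 118)
        name = ril_geno.markers["marker"].iloc[60]
        ci = qtl_interval(ril_geno, y, [name], name, drop=1.0)
        assert ci["ci_lo_mbp"] <= ci["peak_mbp"] <= ci["ci_hi_mbp"]

    def test_bootstrap_interval_covers_true_position(self):
        gmap = simdata.GeneticMap.uniform([60], 150)
        covered = 0
        n_sims = 20
        for s in range(n_sims):
            g = simdata.simulate_ril_genomes(gmap, 118, 7, seed=900 + s)
            d = np.nan_to_num(g.dosage(), nan=0.5)
            true_j = 75
            rng = np.random.default_rng(950 + s)
            # per-QTL heritability ~0.3
            gv = d[:, true_j] * 1.0
            noise = rng.normal(0, np.sqrt(np.var(gv) * 0.7 / 0.3), 118)
            y = gv + noise
            scan = single_marker_scan(g, y)
            peak = scan["neglog10p"].idxmax()
            name = g.markers["marker"].iloc[peak]
            ci = qtl_interval(g, y, [name], name, method="bootstrap", n_boot=100, seed=s)
            true_mbp = g.markers["pos"].iloc[true_j] / 1e6
            if ci["ci_lo_mbp"] <= true_mbp <= ci["ci_hi_mbp"]:
                covered += 1
        assert covered >= int(0.9 * n_sims) - 2


class TestReport:
    def test_empty_model_gives_header_only_table(self, ril_geno):
        rng = np.random.default_rng(20)
        res = StepwiseQtlModel(ril_geno, rng.normal(size=118), alpha=1e-9).fit()
        rep = res.report("ALT")
        assert len(rep) == 0
        assert list(rep.columns)[:4] == ["qtl", "snp_id", "chrom", "position_mbp"]

    def test_qtl_naming_follows_trait_and_chromosome(self, ril_geno):
        j = 250  # chromosome 2 marker
        y = 8.0 * np.nan_to_num(ril_geno.dosage()[:, j], nan=0.5) + 40
        rep = StepwiseQtlModel(ril_geno, y).fit().report("ALT")
        assert rep["qtl"].iloc[0] == "qALT2"
        assert rep["chrom"].iloc[0] == 2

    def test_ci_string_uses_two_decimal_mbp(self, ril_geno):
        rng = np.random.default_rng(21)
        y = 9 * np.nan_to_num(ril_geno.dosage()[:, 30], nan=0.5) + rng.normal(0, 2, 118)
        rep = StepwiseQtlModel(ril_geno, y).fit().report("ALT")
        assert len(rep) >= 1
        import re

        assert re.fullmatch(r"\d+\.\d{2} - \d+\.\d{2}", rep["ci"].iloc[0])

    def test_functional_wrapper_matches_class(self, ril_geno):
        y = 7 * np.nan_to_num(ril_geno.dosage()[:, 5], nan=0.5)
        a = stepwise_multi_snp(ril_geno, y)
        b = StepwiseQtlModel(ril_geno, y).fit()
        assert a.selected_markers == b.selected_markers


class TestNullBehaviour:
    def test_pure_noise_declaration_rate_matches_independent_oracle(self):
        """Without multiple-testing correction, the greedy search declares
        spurious QTLs at a rate set by the genome-wide minimum p; the
        package must agree with an independent implementation of the same
        procedure on unlinked markers."""
        rng = np.random.default_rng(22)
        n, m, sims = 60, 200, 60
        ours = 0
        oracle = 0
        for s in range(sims):
            calls = rng.choice([0, 2], size=(n, m)).astype(np.int8)
            g = make_geno(calls)
            y = rng.normal(size=n)
            res = StepwiseQtlModel(g, y, alpha=0.001).fit(max_qtls=3)
            ours += bool(len(res.qtls))
            # oracle: min single-marker p < alpha (first greedy round)
            d = g.dosage()
            xc = d - d.mean(0)
            yc = y - y.mean()
            r = (xc * yc[:, None]).sum(0) / np.sqrt((xc**2).sum(0) * (yc**2).sum())
            t = r * np.sqrt((n - 2) / (1 - r**2))
            pmin = (2 * stats.t.sf(np.abs(t), n - 2)).min()
            oracle += bool(pmin < 0.001)
        # binomial agreement band
        p_hat = oracle / sims
        se = np.sqrt(max(p_hat * (1 - p_hat), 0.01) / sims)
        assert abs(ours / sims - p_hat) <= 4 * se + 0.05
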