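import numpy as np
import pytest

from seqvpc import (CountMatrix, DispersionTrend, NBFeatureParams, OneWayLMM,
                    SizeFactorVector, estimate_dispersion_trend, fit_lmm_feature,
                    make_design, simulate_feature, voom_transform, vst_transform,
                    vst_values, write_transformed_tsv)


def _nb_matrix(alpha, phi, G, N, rng):
    r = 1 / phi
    mu = np.exp(alpha)
    return rng.negative_binomial(r, r / (r + mu), size=(G, N)).astype(float)


class TestDispersionTrend:
    def test_recovers_constant_dispersion(self, rng):
        # large means across a range, common phi = 0.4
        alphas = rng.uniform(4, 8, size=60)
        vals = np.vstack([_nb_matrix(a, 0.4, 1, 200, rng) for a in alphas])
        trend = estimate_dispersion_trend(vals)
        assert abs(trend.a0 - 0.4) < 0.1
        assert trend.a1 / np.exp(4) < 0.05  # negligible at these means

    def test_poisson_data_has_small_a0(self, rng):
        vals = rng.poisson(50.0, size=(80, 200)).astype(float)
        trend = estimate_dispersion_trend(vals)
        assert trend.a0 < 0.02

    def test_trend_evaluation_is_exact(self):
        trend = DispersionTrend(0.3, 2.0, np.zeros(10))
        assert trend.dispersion_at(10.0) == pytest.approx(0.3 + 0.2)

    def test_needs_enough_features(self, rng):
        with pytest.raises(ValueError):
            estimate_dispersion_trend(rng.poisson(5, size=(5, 20)).astype(float))


class TestVST:
    def test_strictly_increasing(self):
        trend = DispersionTrend(0.5, 1.0, np.zeros(1))
        x = np.linspace(0, 1e4, 2001)
        v = vst_values(x, trend)
        assert np.all(np.diff(v) > 0)

    def test_log2_spacing_at_large_counts(self):
        trend = DispersionTrend(0.5, 0.0, np.zeros(1))
        assert vst_values(2.0 ** 16, trend) - vst_values(2.0 ** 15, trend) == \
            pytest.approx(1.0, abs=0.01)

    def test_variance_stabilization(self, rng):
        # NB draws across a wide mean range: raw-scale variance spans orders
        # of magnitude; the transformed scale varies by < 25%
        trend = DispersionTrend(0.3, 1.0, np.zeros(1))
        mus = [10, 100, 1000, 10_000]
        raw_vars, tr_vars = [], []
        for mu in mus:
            phi = trend.dispersion_at(mu)
            r = 1 / phi
            x = rng.negative_binomial(r, r / (r + mu), size=20_000).astype(float)
            raw_vars.append(x.var())
            tr_vars.append(vst_values(x, trend).var())
        assert max(raw_vars) / min(raw_vars) > 10
        assert max(tr_vars) / min(tr_vars) < 1.25

    def test_zero_a0_falls_back_to_sqrt_scale(self):
        trend = DispersionTrend(0.0, 1.0, np.zeros(1))
        np.testing.assert_allclose(vst_values(np.array([0.0, 2.0]), trend),
                                   [0.0, 2 * np.sqrt(1.0)])

    def test_transformed_tsv_roundtrip_with_sidecar(self, small_nb_dataset,
                                                    tmp_path):
        import json

        import pandas as pd
        cm, _ = small_nb_dataset
        trend = estimate_dispersion_trend(cm.values)
        out = vst_transform(cm, trend)
        dest = tmp_path / "vst.tsv"
        write_transformed_tsv(dest, out, cm, "vst", trend=trend)
        back = pd.read_csv(dest, sep="\t", index_col=0)
        np.testing.assert_allclose(back.to_numpy(), out)
        meta = json.loads((tmp_path / "vst.tsv.meta.json").read_text())
        assert meta["transform"] == "vst"
        assert meta["a0"] == trend.a0 and meta["a1"] == trend.a1

    def test_whole_matrix_only(self, small_nb_dataset):
        cm, _ = small_nb_dataset
        trend = estimate_dispersion_trend(cm.values)
        out = vst_transform(cm, trend)
        assert out.shape == cm.values.shape
        with pytest.raises(ValueError, match="whole"):
            vst_transform(cm.values[0], trend)


class TestVoom:
    def _toy(self, rng, G=30, N=12):
        vals = rng.poisson(rng.uniform(5, 200, size=(G, 1)), size=(G, N)).astype(float)
        strains = np.repeat([f"s{i}" for i in range(N // 3)], 3)
        cm = CountMatrix(vals, [f"f{i}" for i in range(G)],
                         [f"c{j}" for j in range(N)], strains)
        return cm

    def test_zero_count_formula(self, rng):
        cm = self._toy(rng)
        cm.values[0, 0] = 0.0
        # size factors chosen so every effective library size equals 999,999
        totals = cm.values.sum(axis=0)
        geo = np.exp(np.mean(np.log(totals)))
        sf = SizeFactorVector(np.full(cm.n_samples, 999_999 / geo))
        lcpm, w = voom_transform(cm, sf)
        # (0 + 0.5) / (999999 + 1) * 1e6 = 0.5
        assert lcpm[0, 0] == pytest.approx(-1.0, abs=1e-9)

    def test_depth_scale_invariance_at_high_counts(self, rng):
        cm = self._toy(rng)
        cm.values += 100
        sf = SizeFactorVector(np.ones(cm.n_samples))
        a, _ = voom_transform(cm, sf)
        cm2 = CountMatrix(cm.values * 2, cm.feature_ids, cm.sample_ids,
                          cm.strain_of_sample)
        b, _ = voom_transform(cm2, sf)
        assert np.max(np.abs(a - b)) < 0.01

    def test_weights_positive_finite_even_for_zero_rows(self, rng):
        cm = self._toy(rng)
        cm.values[3] = 0.0
        lcpm, w = voom_transform(cm, SizeFactorVector(np.ones(cm.n_samples)))
        assert np.all(np.isfinite(lcpm))
        assert np.all(w > 0) and np.all(np.isfinite(w))


class TestOneWayLMM:
    def test_no_between_strain_signal_gives_zero(self, rng):
        groups = np.repeat(np.arange(5), 4)
        y = rng.normal(0, 1, 20)
        # remove strain means: every strain mean becomes exactly equal
        for s in range(5):
            y[groups == s] -= y[groups == s].mean()
        res = OneWayLMM(y, groups).fit()
        assert res.sigma2_g_star == 0.0

    def test_matches_balanced_anova_closed_form(self, rng):
        S, R = 12, 4
        groups = np.repeat(np.arange(S), R)
        y = rng.normal(0, 1, S * R) + np.repeat(rng.normal(0, 1.5, S), R)
        res = OneWayLMM(y, groups).fit(criterion="ML")
        ybar = y.mean()
        means = y.reshape(S, R).mean(axis=1)
        ssw = ((y.reshape(S, R) - means[:, None]) ** 2).sum()
        ssb = R * ((means - ybar) ** 2).sum()
        msw = ssw / (S * (R - 1))
        s2g_ml = (ssb / S - msw) / R
        assert res.alpha_star == pytest.approx(ybar, abs=1e-8)
        assert res.sigma2_eps_star == pytest.approx(msw, abs=1e-6)
        assert res.sigma2_g_star == pytest.approx(s2g_ml, abs=1e-6)

    def test_reml_larger_strain_variance_than_ml(self, rng):
        S, R = 10, 3
        groups = np.repeat(np.arange(S), R)
        y = rng.normal(0, 1, S * R) + np.repeat(rng.normal(0, 1.5, S), R)
        ml = OneWayLMM(y, groups).fit("ML")
        reml = OneWayLMM(y, groups).fit("REML")
        assert reml.sigma2_g_star > ml.sigma2_g_star

    def test_vpc_recovery_half(self, rng):
        # y = alpha + b + eps with equal variances: VPC = 0.5
        S, R, G = 50, 6, 200
        groups = np.repeat(np.arange(S), R)
        vpcs = []
        for _ in range(G):
            y = np.repeat(rng.normal(0, 1, S), R) + rng.normal(0, 1, S * R)
            vpcs.append(OneWayLMM(y, groups).fit().vpc.vpc)
        assert abs(np.mean(vpcs) - 0.5) < 0.05

    def test_weighted_fit_downweights_noisy_half(self, rng):
        S, R = 20, 4
        groups = np.repeat(np.arange(S), R)
        b = np.repeat(rng.normal(0, 1, S), R)
        noise_sd = np.where(np.arange(S * R) % 2 == 0, 1.0, 3.0)
        y = b + rng.normal(0, noise_sd)
        w = 1.0 / noise_sd ** 2
        res_w = OneWayLMM(y, groups, weights=w).fit()
        assert res_w.sigma2_eps_star > 0
        assert 0 <= res_w.vpc.vpc < 1

    def test_degenerate_feature_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            OneWayLMM(np.ones(12), np.repeat(np.arange(4), 3))

    def test_lrt_nonnegative_and_needs_ml(self, rng):
        S, R = 15, 3
        groups = np.repeat(np.arange(S), R)
        for _ in range(10):
            y = rng.normal(0, 1, S * R) + np.repeat(rng.normal(0, 0.5, S), R)
            res = fit_lmm_feature(y, groups, criterion="ML")
            stat, p = res.lrt()
            assert stat >= 0.0 and 0.0 <= p <= 1.0
        with pytest.raises(ValueError, match="ML"):
            fit_lmm_feature(y, groups, criterion="REML").lrt()
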