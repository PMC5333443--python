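"""Variance-stabilizing / voom transformations and the one-way Gaussian LMM.

Count data can be analyzed with ordinary linear mixed models after a
transformation that removes most of the mean-variance dependence.  Two
pipelines are provided:

* VST: a closed-form variance-stabilizing transform derived from a fitted
  dispersion-mean trend a(mu) = a0 + a1/mu (NB variance mu + a(mu)*mu^2),
  anchored to the log2 scale at large counts.
* voom: log2 counts-per-million with per-observation precision weights read
  off an empirically smoothed mean-variance trend.

Both act on a whole dataset: the trend estimation pools information across
features, so transforming a single feature in isolation is not meaningful
(the bootstrap code freezes a previously fitted trend instead).

The transformed values are then modeled per feature as

    y*_sr = alpha* + b*_s + eps*_sr,  b* ~ N(0, sigma2_g*), eps* ~ N(0, sigma2_eps*)

fitted by ML or REML via a profiled one-dimensional search over the
variance ratio; the VPC is sigma2_g* / (sigma2_g* + sigma2_eps*).
"""

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CountMatrix, SizeFactorVector
from .vpc import VPCResult, vpc_lmm


# ---------------------------------------------------------------------------
# dispersion trend + VST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DispersionTrend:
    """Fitted NB dispersion-mean trend a(mu) = a0 + a1/mu."""
    a0: float
    a1: float
    per_feature_dispersions: np.ndarray

    def dispersion_at(self, mu):
        return self.a0 + self.a1 / np.asarray(mu, dtype=float)


def estimate_dispersion_trend(cm: CountMatrix) -> DispersionTrend:
    """Method-of-moments dispersions with a trimmed least-squares trend fit.

    Per feature: phi_g = max(0, (s2_g - mean_g) / mean_g^2).  The trend
    a0 + a1/mean is fitted on features with mean > 1, refit once after
    dropping the 10% largest absolute residuals.  Both coefficients are
    constrained to be non-negative.
    """
    vals = cm.values if isinstance(cm, CountMatrix) else np.asarray(cm, dtype=float)
    if vals.shape[0] < 10:
        raise ValueError("dispersion trend estimation needs at least 10 features")
    means = vals.mean(axis=1)
    variances = vals.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(means > 0, (variances - means) / means ** 2, 0.0)
    disp = np.maximum(disp, 0.0)
    use = means > 1.0
    if use.sum() < 10:
        raise ValueError("fewer than 10 features with mean > 1; cannot fit a trend")

    def _fit(mask):
        X = np.column_stack([np.ones(mask.sum()), 1.0 / means[mask]])
        coef, *_ = np.linalg.lstsq(X, disp[mask], rcond=None)
        return np.maximum(coef, 0.0)

    coef = _fit(use)
    resid = np.abs(disp[use] - (coef[0] + coef[1] / means[use]))
    cutoff = np.quantile(resid, 0.9)
    trimmed = np.zeros_like(use)
    trimmed[use] = resid <= cutoff
    if trimmed.sum() >= 10:
        coef = _fit(trimmed)
    return DispersionTrend(float(coef[0]), float(coef[1]), disp)


def vst_values(counts, trend: DispersionTrend) -> np.ndarray:
    """Apply a *frozen* VST trend to raw values (used by the hybrid bootstrap)."""
    n = np.asarray(counts, dtype=float)
    a0, a1 = trend.a0, trend.a1
    if a0 < 1e-12:
        # no asymptotic dispersion: Poisson-type scale, 2*sqrt anchoring
        return 2.0 * np.sqrt(n / (1.0 + a1))
    # closed-form antiderivative of 1/sqrt((1+a1) mu + a0 mu^2), log2-anchored
    return np.log2((1.0 + a1 + 2.0 * a0 * n
                    + 2.0 * np.sqrt(a0 * n * (1.0 + a1 + a0 * n)))
                   / (4.0 * a0))


def vst_transform(cm: CountMatrix, trend: DispersionTrend) -> np.ndarray:
    """Variance-stabilizing transform of a normalized count matrix.

    Strictly increasing in the count; approaches log2(count) + const for
    large counts.  Whole-matrix only -- the trend is a dataset-level object.
    """
    vals = cm.values if isinstance(cm, CountMatrix) else np.asarray(cm, dtype=float)
    if vals.ndim != 2:
        raise ValueError("vst_transform expects the whole (features x samples) matrix")
    return vst_values(vals, trend)


def write_transformed_tsv(path, values: np.ndarray, cm: CountMatrix,
                          transform_type: str,
                          trend: "DispersionTrend | None" = None) -> None:
    """Write a transformed matrix as TSV plus a JSON sidecar.

    The sidecar (``<path>.meta.json``) records the transform type and, for
    the VST, the fitted trend coefficients, so the transform can be frozen
    and re-applied (e.g. by the hybrid bootstrap) without the original data.
    """
    import json
    from pathlib import Path

    path = Path(path)
    pd.DataFrame(values, index=cm.feature_ids, columns=cm.sample_ids
                 ).to_csv(path, sep="\t")
    meta = {"transform": transform_type}
    if trend is not None:
        meta["a0"] = trend.a0
        meta["a1"] = trend.a1
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# voom
# ---------------------------------------------------------------------------

def voom_transform(cm: CountMatrix, sf: SizeFactorVector
                   ) -> tuple[np.ndarray, np.ndarray]:
    """log2-CPM transform with precision weights from a mean-variance trend.

    Effective library size L_j = factor_j * exp(mean(log(column totals))):
    the size factors carry the relative depths, scaled back to the
    magnitude of the observed totals.  Returns (transformed, weights).
    """
    vals = cm.values
    totals = vals.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("library size <= 0; remove empty samples")
    lib = sf.factors * np.exp(np.mean(np.log(totals)))
    lcpm = np.log2((vals + 0.5) / (lib + 1.0)[np.newaxis, :] * 1e6)

    # one-way fitted values (strain means) and residual standard deviations
    strains = cm.strain_of_sample
    fitted = np.empty_like(lcpm)
    for s in np.unique(strains):
        idx = strains == s
        fitted[:, idx] = lcpm[:, idx].mean(axis=1, keepdims=True)
    df = vals.shape[1] - len(np.unique(strains))
    if df < 1:
        raise ValueError("no residual degrees of freedom for the voom trend")
    resid_sd = np.sqrt(((lcpm - fitted) ** 2).sum(axis=1) / df)
    sqrt_sd = np.sqrt(resid_sd)

    mean_logcount = lcpm.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    smooth = lowess(sqrt_sd, mean_logcount, frac=0.5, return_sorted=True)
    sx, sy = smooth[:, 0], np.maximum(smooth[:, 1], 1e-6)

    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[np.newaxis, :]
    pred = np.interp(np.clip(fitted_logcount, sx[0], sx[-1]), sx, sy)
    weights = pred ** -4.0
    return lcpm, weights


# ---------------------------------------------------------------------------
# one-way random-intercept LMM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LMMResults:
    alpha_star: float
    sigma2_g_star: float
    sigma2_eps_star: float
    llf: float
    llf_null: float          # ML loglik of the sigma2_g* = 0 model
    criterion: str           # "ML" or "REML"

    @property
    def vpc(self) -> VPCResult:
        return vpc_lmm(self.sigma2_g_star, self.sigma2_eps_star)

    def lrt(self) -> tuple[float, float]:
        from .inference import mixture_pvalue
        if self.criterion != "ML":
            raise ValueError("the boundary LRT requires an ML fit")
        stat = max(2.0 * (self.llf - self.llf_null), 0.0)
        return stat, mixture_pvalue(stat)


class OneWayLMM:
    """Gaussian one-way random-intercept model, optionally with precision weights.

    Estimation profiles the likelihood down to the variance ratio
    gamma = sigma2_g / sigma2_eps; per-strain block inverses are rank-one
    updates, so each profile evaluation is O(N).
    """

    def __init__(self, endog, groups, weights=None):
        y = np.asarray(endog, dtype=float).ravel()
        g = np.asarray(groups).ravel()
        if y.shape[0] != g.shape[0]:
            raise ValueError("endog and groups must have the same length")
        order = np.argsort(g, kind="stable")
        self.endog = y[order]
        self.groups = g[order]
        if weights is None:
            self.weights = np.ones_like(self.endog)
        else:
            w = np.asarray(weights, dtype=float).ravel()
            if np.any(w <= 0) or not np.all(np.isfinite(w)):
                raise ValueError("weights must be positive and finite")
            self.weights = w[order]
        uniq, idx = np.unique(self.groups, return_index=True)
        if uniq.shape[0] < 2:
            raise ValueError("at least 2 strains are required")
        self.n_samples = y.shape[0]
        self.n_strains = uniq.shape[0]
        if np.var(self.endog) <= 0:
            raise ValueError("degenerate feature: zero total variance")
        # per-strain sufficient statistics (blocks are contiguous after sorting)
        bounds = np.sort(idx)
        w, yy = self.weights, self.endog
        self._t = np.add.reduceat(w, bounds)                 # sum of weights
        self._swy = np.add.reduceat(w * yy, bounds)          # sum w*y
        self._swy2 = np.add.reduceat(w * yy * yy, bounds)    # sum w*y^2
        self._sumlogw = float(np.log(w).sum())

    def _profile(self, gamma: float, reml: bool):
        n = self.n_samples
        t, swy, swy2 = self._t, self._swy, self._swy2
        shrink = 1.0 + gamma * t
        alpha = (swy / shrink).sum() / (t / shrink).sum()
        den = (t / shrink).sum()
        swr = swy - alpha * t
        swr2 = swy2 - 2.0 * alpha * swy + alpha * alpha * t
        q = float((swr2 - gamma * swr * swr / shrink).sum())
        logdet = -self._sumlogw + float(np.log1p(gamma * t).sum())
        if reml:
            s2 = q / (n - 1)
            m2ll = ((n - 1) * np.log(2 * np.pi * s2) + logdet
                    + np.log(den) + (n - 1))
        else:
            s2 = q / n
            m2ll = n * np.log(2 * np.pi * s2) + logdet + n
        return -0.5 * m2ll, alpha, s2

    def fit(self, criterion: str = "ML") -> LMMResults:
        if criterion not in ("ML", "REML"):
            raise ValueError("criterion must be 'ML' or 'REML'")
        reml = criterion == "REML"

        def neg(u):
            return -self._profile(np.exp(u), reml)[0]

        res = minimize_scalar(neg, bounds=(-18.0, 14.0), method="bounded",
                              options={"xatol": 1e-10})
        ll_in, alpha_in, s2_in = self._profile(np.exp(res.x), reml)
        ll_0, alpha_0, s2_0 = self._profile(0.0, reml)
        if ll_0 >= ll_in:
            gamma, ll, alpha, s2 = 0.0, ll_0, alpha_0, s2_0
        else:
            gamma, ll, alpha, s2 = float(np.exp(res.x)), ll_in, alpha_in, s2_in
        if gamma * s2 < 1e-12:
            gamma = 0.0
        # ML loglik of the independent (gamma = 0) model, for the boundary LRT
        ll_null_ml = self._profile(0.0, False)[0]
        return LMMResults(float(alpha), float(gamma * s2), float(s2), float(ll),
                          float(ll_null_ml), criterion)


def fit_lmm_feature(y_star, groups, weights=None, criterion: str = "ML") -> LMMResults:
    """Functional wrapper around :class:`OneWayLMM`."""
    return OneWayLMM(y_star, groups, weights=weights).fit(criterion=criterion)
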