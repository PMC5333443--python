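"""One-way random-intercept GLMMs for a single sequencing feature.

The model for feature g observed on strains s = 1..S with replicates r:

    y_sr | b_s  ~  NB(mu_s, phi)   or   CP(mu_s, phi, p)
    log mu_s = alpha + b_s,   b_s ~ N(0, sigma2)

The strain effects factorize the marginal likelihood into S one-dimensional
integrals, each evaluated by mode-recentered (adaptive) Gauss-Hermite
quadrature.  Estimation is maximum likelihood throughout -- the boundary
likelihood-ratio test requires ML rather than REML-type criteria.

Usage follows the statsmodels convention::

    res = NegativeBinomialMixedModel(y, strains).fit()
    res.params.sigma2, res.llf, res.vpc
    stat, p = res.lrt()            # H0: sigma2 = 0 vs H1: sigma2 > 0

Optimization runs over (alpha, sqrt(phi), sqrt(sigma2)) for the NB and
(alpha, sqrt(phi), logit-scaled p, sqrt(sigma2)) for the CP model: the
square-root parameterization keeps the variance components non-negative
while leaving the sigma2 = 0 boundary reachable by the simplex.  Null
(sigma2 = 0) fits exploit that both families are exponential-dispersion
families, so the intercept MLE is log(ybar) for any dispersion.
"""

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from numpy.polynomial.hermite import hermgauss

from . import _kernels
from .vpc import VPCResult, vpc_cpmm, vpc_nbmm

_P_EPS = 0.01            # Tweedie power constrained to (1 + eps, 2 - eps)
_SIGMA2_BOUNDARY = 1e-8  # estimates below this are reported as exactly 0
_XATOL = 1e-4
_FATOL = 1e-6
_QUAD_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _quad_rule(n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    if n_quad not in _QUAD_CACHE:
        nodes, wts = hermgauss(n_quad)
        _QUAD_CACHE[n_quad] = (np.ascontiguousarray(nodes), np.log(wts))
    return _QUAD_CACHE[n_quad]


def _p_from_z(z: float) -> float:
    return 1.0 + _P_EPS + (1.0 - 2.0 * _P_EPS) / (1.0 + np.exp(-z))


def _z_from_p(p: float) -> float:
    frac = (p - 1.0 - _P_EPS) / (1.0 - 2.0 * _P_EPS)
    frac = min(max(frac, 1e-6), 1.0 - 1e-6)
    return float(np.log(frac / (1.0 - frac)))


@dataclass(frozen=True)
class NBFeatureParams:
    alpha: float
    phi: float
    sigma2: float


@dataclass(frozen=True)
class CPFeatureParams:
    alpha: float
    phi: float
    p: float
    sigma2: float


FeatureParams = Union[NBFeatureParams, CPFeatureParams]


class GLMMResults:
    """ML fit of a one-way count GLMM for a single feature."""

    def __init__(self, model, params: FeatureParams, llf: float, converged: bool,
                 null: bool = False):
        self.model = model
        self.params = params
        self.llf = llf
        self.converged = converged
        self.is_null = null
        self.n_strains = model.n_strains
        self.n_samples = model.n_samples
        self._null_res: Optional["GLMMResults"] = None

    @property
    def vpc(self) -> VPCResult:
        p = self.params
        if isinstance(p, NBFeatureParams):
            return vpc_nbmm(p.alpha, p.sigma2, p.phi)
        return vpc_cpmm(p.alpha, p.sigma2, p.phi, p.p)

    def lrt(self) -> tuple[float, float]:
        """Boundary LRT of sigma2 = 0; returns (stat, p) under 0.5*chi2_0 + 0.5*chi2_1."""
        from .inference import mixture_pvalue
        if self._null_res is None:
            self._null_res = self.model.fit_null()
        stat = 2.0 * (self.llf - self._null_res.llf)
        stat = max(stat, 0.0)
        return stat, mixture_pvalue(stat)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"{type(self.model).__name__} ML fit",
            f"  n_samples: {self.n_samples}   n_strains: {self.n_strains}",
            f"  alpha:  {p.alpha:.6g}",
            f"  phi:    {p.phi:.6g}",
        ]
        if isinstance(p, CPFeatureParams):
            lines.append(f"  p:      {p.p:.6g}")
        lines += [
            f"  sigma2: {p.sigma2:.6g}",
            f"  loglik: {self.llf:.6g}   converged: {self.converged}",
        ]
        if not self.is_null:
            v = self.vpc
            lines.append(f"  VPC ({v.model}): {v.vpc:.4f}   upper bound: {v.upper_bound:.4f}")
        return "\n".join(lines)


class _CountMixedModel:
    """Shared plumbing: sorting by strain, start offsets, starting values."""

    def __init__(self, endog, groups, n_quad: int = 25):
        y = np.asarray(endog, dtype=float).ravel()
        g = np.asarray(groups).ravel()
        if y.shape[0] != g.shape[0]:
            raise ValueError("endog and groups must have the same length")
        if np.any(y < 0):
            raise ValueError("counts must be non-negative")
        order = np.argsort(g, kind="stable")
        self.endog = np.ascontiguousarray(y[order])
        self.groups = g[order]
        uniq, idx = np.unique(self.groups, return_index=True)
        if uniq.shape[0] < 2:
            raise ValueError("at least 2 strains are required")
        self.starts = np.append(np.sort(idx), y.shape[0]).astype(np.int64)
        self.n_strains = uniq.shape[0]
        self.n_samples = y.shape[0]
        if not np.any(self.endog > 0):
            raise ValueError("feature unfittable (all counts zero), apply filtering")
        self.n_quad = int(n_quad)
        if self.n_quad < 1:
            raise ValueError("n_quad must be >= 1")
        self._nodes, self._logwts = _quad_rule(self.n_quad)

    def _starting_values(self):
        """Robust method-of-moments starts from per-strain summaries.

        The intercept starts at the mean of per-strain log means (the plain
        log of the grand mean is inflated by e^(sigma2/2) and by heavy
        tails); dispersions are medians of per-strain moment estimates so
        that a few extreme strains cannot blow the start up.
        """
        y, st = self.endog, self.starts
        strain_logmeans = []
        phi_nb, phi_cp = [], []
        for s in range(self.n_strains):
            blk = y[st[s]:st[s + 1]]
            m = blk.mean()
            strain_logmeans.append(np.log(m + 0.5))
            if blk.size > 1 and m > 0:
                v = blk.var(ddof=1)
                phi_nb.append((v - m) / m ** 2)
                phi_cp.append(v / m ** 1.5)
        alpha0 = float(np.mean(strain_logmeans))
        sigma2_0 = max(np.var(strain_logmeans, ddof=1), 1e-4)
        if phi_nb:
            phi0 = max(float(np.median(phi_nb)), 1e-2)
            phi0_cp = max(float(np.median(phi_cp)), 1e-3)
        else:  # single replicate per strain: fall back to pooled moments
            ybar, v = y.mean(), y.var(ddof=1)
            phi0 = max((v - ybar) / ybar ** 2, 1e-2)
            phi0_cp = max(v / ybar ** 1.5, 1e-3)
        return alpha0, phi0, phi0_cp, sigma2_0

    def _minimize(self, negll, x0, steps, maxfev=4000):
        x, f, nfev, conv = _kernels.neldermead(
            negll, np.asarray(x0, dtype=float), np.asarray(steps, dtype=float),
            self.endog, self.starts, self._nodes, self._logwts,
            _XATOL, _FATOL, maxfev)
        return x, f, conv


class NegativeBinomialMixedModel(_CountMixedModel):
    """NB mixed model; counts must be (rounded to) integers."""

    def __init__(self, endog, groups, n_quad: int = 25):
        super().__init__(endog, groups, n_quad)
        if not np.allclose(self.endog, np.round(self.endog)):
            raise ValueError("NB model requires integer counts; round normalized data first")

    def loglike(self, params: NBFeatureParams) -> float:
        return float(_kernels.nb_marginal_loglik(
            self.endog, self.starts, params.alpha, params.phi, params.sigma2,
            self._nodes, self._logwts))

    def _result_from_x(self, x, f, conv) -> GLMMResults:
        alpha, sphi, ssig = x
        sigma2 = float(ssig * ssig)
        if sigma2 < _SIGMA2_BOUNDARY:
            sigma2 = 0.0
        params = NBFeatureParams(float(alpha), float(sphi * sphi), sigma2)
        return GLMMResults(self, params, -float(f), bool(conv))

    def fit(self, maxiter: int = 500, compute_null: bool = True) -> GLMMResults:
        """ML fit; ``compute_null=False`` skips the sigma2 = 0 fit (and with it
        the nesting safeguard) when only the point estimate is needed."""
        alpha0, phi0, _, sigma2_0 = self._starting_values()
        x0 = np.array([alpha0, np.sqrt(phi0), np.sqrt(sigma2_0)])
        steps = np.array([0.2, 0.1, 0.2])
        x, f, conv = self._minimize(_kernels._nb_negll_x, x0, steps, maxfev=maxiter * 8)
        if not conv:
            x1 = x * np.array([1.0, 1.3, 0.7]) + np.array([0.05, 0.01, 0.01])
            x2, f2, conv2 = self._minimize(_kernels._nb_negll_x, x1, steps,
                                           maxfev=maxiter * 8)
            if f2 <= f:
                x, f, conv = x2, f2, conv2
        res = self._result_from_x(x, f, conv)
        return self._enforce_nesting(res) if compute_null else res

    def fit_null(self) -> GLMMResults:
        """ML fit with sigma2 fixed at 0 (intercept-only NB regression)."""
        y = self.endog
        alpha = float(np.log(y.mean()))
        sphi, f = _kernels.golden_min(_kernels.nb_null_negll_phi, 0.0, 6.5, y, alpha,
                                      1e-9)
        phi = float(sphi * sphi)
        if phi < 1e-10:
            phi = 0.0
            f = -_kernels.nb_glm_loglik(y, alpha, 0.0)
        params = NBFeatureParams(alpha, phi, 0.0)
        return GLMMResults(self, params, -float(f), True, null=True)

    def _enforce_nesting(self, alt: GLMMResults) -> GLMMResults:
        """Guarantee llf(alt) >= llf(null): refit from the null optimum if violated."""
        null = self.fit_null()
        if alt.llf >= null.llf - 1e-9:
            alt._null_res = null
            return alt
        x0 = np.array([null.params.alpha, np.sqrt(max(null.params.phi, 1e-4)), 1e-3])
        x, f, conv = self._minimize(_kernels._nb_negll_x, x0,
                                    np.array([0.05, 0.05, 0.05]))
        if -f >= alt.llf:
            alt = self._result_from_x(x, f, conv)
        if alt.llf < null.llf:
            # boundary solution: the null is the alternative's optimum
            alt = GLMMResults(self, NBFeatureParams(null.params.alpha, null.params.phi,
                                                    0.0), null.llf, True)
        alt._null_res = null
        return alt


class CompoundPoissonMixedModel(_CountMixedModel):
    """Tweedie compound Poisson mixed model for continuous non-negative data."""

    def loglike(self, params: CPFeatureParams) -> float:
        return float(_kernels.cp_marginal_loglik(
            self.endog, self.starts, params.alpha, params.phi, params.p,
            params.sigma2, self._nodes, self._logwts))

    def _result_from_x(self, x, conv) -> GLMMResults:
        alpha, sphi, zp, ssig = x
        sigma2 = float(ssig * ssig)
        if sigma2 < _SIGMA2_BOUNDARY:
            sigma2 = 0.0
        params = CPFeatureParams(float(alpha), float(max(sphi * sphi, 1e-10)),
                                 float(_p_from_z(zp)), sigma2)
        # the optimizer used the interpolated W series; report the exact loglik
        return GLMMResults(self, params, self.loglike(params), bool(conv))

    def fit(self, maxiter: int = 500, compute_null: bool = True) -> GLMMResults:
        alpha0, _, phi0_cp, sigma2_0 = self._starting_values()
        x0 = np.array([alpha0, np.sqrt(phi0_cp), _z_from_p(1.5), np.sqrt(sigma2_0)])
        steps = np.array([0.2, 0.1, 0.5, 0.2])
        x, f, conv = self._minimize(_kernels._cp_negll_x, x0, steps, maxfev=maxiter * 10)
        # The logit map for p has flat tails; a simplex that drifts onto a
        # tail can "converge" far from the optimum.  Restart from spread-out
        # p values and a moderate dispersion whenever the fitted power ends
        # up near its boundary.
        if not conv or not 1.08 < _p_from_z(x[2]) < 1.92:
            for p_alt in (1.3, 1.7):
                x1 = np.array([alpha0, np.sqrt(min(phi0_cp, 2.0)),
                               _z_from_p(p_alt), np.sqrt(sigma2_0)])
                x2, f2, conv2 = self._minimize(_kernels._cp_negll_x, x1, steps,
                                               maxfev=maxiter * 10)
                if f2 < f:
                    x, f, conv = x2, f2, conv2
        res = self._result_from_x(x, conv)
        return self._enforce_nesting(res) if compute_null else res

    def fit_null(self) -> GLMMResults:
        y = self.endog
        alpha = float(np.log(y.mean()))
        ybar = y.mean()
        phi0 = max(y.var(ddof=1) / ybar ** 1.5, 1e-3)
        x0 = np.array([np.sqrt(phi0), _z_from_p(1.5)])
        x, f, conv = self._minimize(_kernels._cp_null_negll_x, x0,
                                    np.array([0.1, 0.5]))
        params = CPFeatureParams(alpha, float(max(x[0] ** 2, 1e-10)),
                                 float(_p_from_z(x[1])), 0.0)
        llf = float(_kernels.cp_glm_loglik(y, alpha, params.phi, params.p))
        return GLMMResults(self, params, llf, bool(conv), null=True)

    def _enforce_nesting(self, alt: GLMMResults) -> GLMMResults:
        null = self.fit_null()
        if alt.llf >= null.llf - 1e-9:
            alt._null_res = null
            return alt
        x0 = np.array([null.params.alpha, np.sqrt(max(null.params.phi, 1e-4)),
                       _z_from_p(null.params.p), 1e-3])
        x, f, conv = self._minimize(_kernels._cp_negll_x, x0,
                                    np.array([0.05, 0.05, 0.2, 0.05]))
        cand = self._result_from_x(x, conv)
        if cand.llf >= alt.llf:
            alt = cand
        if alt.llf < null.llf:
            alt = GLMMResults(self, CPFeatureParams(null.params.alpha, null.params.phi,
                                                    null.params.p, 0.0), null.llf, True)
        alt._null_res = null
        return alt


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def marginal_loglik(y, groups, params: FeatureParams, model: str,
                    n_quad: int = 25) -> float:
    """Marginal log-likelihood of one feature under NB or CP observation model."""
    if model == "NB":
        m = NegativeBinomialMixedModel(y, groups, n_quad=n_quad)
        if not isinstance(params, NBFeatureParams):
            raise TypeError("NB model requires NBFeatureParams")
        return m.loglike(params)
    if model == "CP":
        m = CompoundPoissonMixedModel(y, groups, n_quad=n_quad)
        if not isinstance(params, CPFeatureParams):
            raise TypeError("CP model requires CPFeatureParams")
        return m.loglike(params)
    raise ValueError(f"unknown model {model!r}; use 'NB' or 'CP'")


def fit_glmm_feature(y, groups, model: str, n_quad: int = 25,
                     maxiter: int = 500) -> GLMMResults:
    cls = {"NB": NegativeBinomialMixedModel, "CP": CompoundPoissonMixedModel}.get(model)
    if cls is None:
        raise ValueError(f"unknown model {model!r}; use 'NB' or 'CP'")
    return cls(y, groups, n_quad=n_quad).fit(maxiter=maxiter)


def fit_null_feature(y, groups, model: str, n_quad: int = 25) -> GLMMResults:
    cls = {"NB": NegativeBinomialMixedModel, "CP": CompoundPoissonMixedModel}.get(model)
    if cls is None:
        raise ValueError(f"unknown model {model!r}; use 'NB' or 'CP'")
    return cls(y, groups, n_quad=n_quad).fit_null()
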