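"""Heritability testing and interval estimation.

* Boundary likelihood-ratio test of H0: sigma2_g = 0 against sigma2_g > 0.
  The null lies on the parameter-space boundary, so -2 log LR is distributed
  as a 50:50 mixture of chi2_0 and chi2_1 under H0; the p-value is
  0.5 * P(chi2_1 > stat), with the atom at 0 giving p = 1.
* Benjamini-Hochberg adjustment across features.
* Parametric bootstrap percentile confidence intervals for the VPC: simulate
  from the fitted family with the original strain design, refit, and take
  empirical percentiles of the refitted VPCs.  The "VST hybrid" variant
  simulates from the fitted NB model but refits each replicate with the
  (much faster) VST + LMM pipeline, freezing the dispersion trend estimated
  on the original dataset.
"""

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glmm import (CompoundPoissonMixedModel, GLMMResults, NBFeatureParams,
                   NegativeBinomialMixedModel)
from .io import CountMatrix, SizeFactorVector, compute_size_factors, normalize_counts
from .lmm import (DispersionTrend, OneWayLMM, estimate_dispersion_trend,
                  vst_values, voom_transform)

METHODS = ("nb", "cp", "vst", "voom")


def mixture_pvalue(lrt_stat: float) -> float:
    """p-value of the boundary LRT under the 50:50 chi2_0 / chi2_1 mixture."""
    if lrt_stat < -1e-6:
        raise ValueError(f"negative LRT statistic ({lrt_stat}); "
                         "the alternative fit did not reach its optimum")
    stat = max(float(lrt_stat), 0.0)
    if stat == 0.0:
        return 1.0
    return float(0.5 * stats.chi2.sf(stat, df=1))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs propagate."""
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if valid.sum():
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return out


@dataclass
class HeritabilityResult:
    feature_id: str
    method: str
    vpc: float
    vpc_upper_bound: float
    lrt_stat: float
    p_value: float
    converged: bool
    q_value: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


def lrt_heritability(y, groups, method: str, weights=None, n_quad: int = 25,
                     feature_id: str = "") -> HeritabilityResult:
    """Fit alternative and null for one feature and test sigma2_g = 0.

    For the GLMM methods ``y`` holds (normalized) counts; for "vst"/"voom"
    it holds the already-transformed values (the transforms are dataset-level
    and must be applied beforehand).
    """
    if method in ("nb", "cp"):
        cls = NegativeBinomialMixedModel if method == "nb" else CompoundPoissonMixedModel
        res = cls(y, groups, n_quad=n_quad).fit()
        stat, p = res.lrt()
        if not (res.converged and res._null_res.converged):
            p = np.nan
        v = res.vpc
        return HeritabilityResult(feature_id, method, v.vpc, v.upper_bound,
                                  stat, p, bool(res.converged))
    if method in ("vst", "voom"):
        res = OneWayLMM(y, groups, weights=weights).fit(criterion="ML")
        stat, p = res.lrt()
        v = res.vpc
        return HeritabilityResult(feature_id, method, v.vpc, v.upper_bound,
                                  stat, p, True)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


# ---------------------------------------------------------------------------
# parametric bootstrap confidence intervals
# ---------------------------------------------------------------------------

def bootstrap_ci(fit: GLMMResults, method: str, B: int = 200, level: float = 0.95,
                 rng: Optional[np.random.Generator] = None,
                 vst_trend: Optional[DispersionTrend] = None,
                 max_failure_rate: float = 0.2) -> tuple[float, float]:
    """Percentile parametric-bootstrap CI for one feature's VPC.

    ``method`` is the refitting route: "nb", "cp", or "vst-hybrid" (simulate
    from the fitted NB model, refit with the frozen-trend VST + LMM -- far
    cheaper than refitting a GLMM per replicate).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if B < int(np.ceil(2.0 / (1.0 - level))):
        raise ValueError(f"B={B} too small to resolve the {level:.0%} interval tails")
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    if rng is None:
        rng = np.random.default_rng()
    if method == "vst-hybrid":
        if not isinstance(fit.params, NBFeatureParams):
            raise ValueError("the VST hybrid bootstraps from a fitted NB model")
        if vst_trend is None:
            raise ValueError("vst-hybrid needs the dataset's frozen dispersion trend")
    from .simulate import simulate_feature
    starts = fit.model.starts
    groups = fit.model.groups
    vpcs = []
    failures = 0
    for _ in range(B):
        y = simulate_feature(fit.params, starts, rng)
        try:
            if method == "nb":
                res = NegativeBinomialMixedModel(y, groups).fit(compute_null=False)
                vpcs.append(res.vpc.vpc)
            elif method == "cp":
                res = CompoundPoissonMixedModel(y, groups).fit(compute_null=False)
                vpcs.append(res.vpc.vpc)
            elif method == "vst-hybrid":
                y_star = vst_values(y, vst_trend)
                res = OneWayLMM(y_star, groups).fit(criterion="ML")
                vpcs.append(res.vpc.vpc)
            else:
                raise ValueError(f"unknown bootstrap method {method!r}")
        except ValueError as exc:
            if "unknown bootstrap method" in str(exc):
                raise
            failures += 1
    if failures > max_failure_rate * B:
        raise RuntimeError(f"bootstrap refit failure rate {failures / B:.1%} "
                           f"exceeds {max_failure_rate:.0%}")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(vpcs, [tail, 1.0 - tail])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# dataset-level driver
# ---------------------------------------------------------------------------

def _one_feature_row(args):
    mat_row, groups, m, w, n_quad, fid = args
    try:
        return lrt_heritability(mat_row, groups, m, weights=w, n_quad=n_quad,
                                feature_id=fid)
    except ValueError:
        return HeritabilityResult(fid, m, np.nan, np.nan, np.nan, np.nan, False)


def heritability_table(cm: CountMatrix, methods=("nb", "cp", "vst"),
                       size_factors: Optional[SizeFactorVector] = None,
                       use_voom_weights: bool = False, n_quad: int = 25,
                       n_jobs: int = 1) -> pd.DataFrame:
    """Per-feature VPC estimates, LRT p-values and BH q-values.

    ``cm`` should already be filtered.  Size factors are estimated with
    median-of-ratios unless supplied (pass unit factors for simulated data
    with equal depths).  Features are fitted independently, so ``n_jobs``
    fans them out over processes; results do not depend on the worker count.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    if cm.n_features == 0:
        raise ValueError("empty count matrix; nothing to fit")
    sf = compute_size_factors(cm) if size_factors is None else size_factors
    groups = cm.strain_of_sample
    prepared: dict[str, tuple[np.ndarray, Optional[np.ndarray]]] = {}
    if "nb" in methods:
        prepared["nb"] = (normalize_counts(cm, sf, round_to_integer=True).values, None)
    if "cp" in methods or "vst" in methods:
        cont = normalize_counts(cm, sf, round_to_integer=False).values
        if "cp" in methods:
            prepared["cp"] = (cont, None)
        if "vst" in methods:
            trend = estimate_dispersion_trend(cont)
            prepared["vst"] = (vst_values(cont, trend), None)
    if "voom" in methods:
        lcpm, w = voom_transform(cm, sf)
        prepared["voom"] = (lcpm, w if use_voom_weights else None)

    jobs = []
    for m in methods:
        mat, wmat = prepared[m]
        for i, fid in enumerate(cm.feature_ids):
            w = wmat[i] if wmat is not None else None
            jobs.append((mat[i], groups, m, w, n_quad, fid))
    if n_jobs == 1:
        rows = [_one_feature_row(j) for j in jobs]
    else:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=n_jobs)(delayed(_one_feature_row)(j) for j in jobs)
    df = pd.DataFrame([vars(r) for r in rows])
    df["q_value"] = np.nan
    for m in methods:
        sel = df["method"] == m
        df.loc[sel, "q_value"] = bh_adjust(df.loc[sel, "p_value"].to_numpy())
    return df
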