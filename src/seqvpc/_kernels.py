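"""Low-level jitted numerical kernels.

Everything here is a plain function of scalars / contiguous arrays so that
numba can compile it.  Higher-level modules wrap these with validation and
friendlier signatures; tests compare them against independent scipy oracles.

Conventions used throughout:

* NB dispersion ``phi``: Var(Y) = mu + phi * mu**2 (size r = 1/phi,
  success prob r / (r + mu)).  ``phi`` below ~1e-12 is evaluated as the
  exact Poisson limit.
* Tweedie compound Poisson with power ``p`` in (1, 2):
  Var(Y) = phi * mu**p; Poisson rate lam = mu**(2-p) / (phi*(2-p)),
  gamma shape a = (2-p)/(p-1), gamma scale tau = phi*(p-1)*mu**(p-1).
* Observations of one feature are stored as a flat vector grouped by
  strain, with ``starts`` giving the offset of each strain's block
  (length S+1, starts[-1] == len(y)).

Performance notes: given (phi, p), both families are exponential-dispersion
families, so each strain's likelihood depends on the data only through the
replicate count and the replicate sum once the observation-level constants
(log-gamma terms for NB, the Tweedie series W(y) for CP) are accumulated.
The quadrature node loop is therefore O(1) per node.  The Tweedie series
is the per-evaluation bottleneck during optimization; for features with
many positive observations it is evaluated at Chebyshev nodes in log y and
interpolated (the final reported log-likelihood is always recomputed with
the exact series).
"""

import math

import numpy as np
from numba import njit

_PHI_POISSON = 1e-12  # below this the NB is evaluated as Poisson
_SERIES_DROP = 37.0   # stop the Tweedie series when terms fall this far below the peak
_NCHEB = 24           # Chebyshev nodes for the W-series interpolant
_CHEB_MIN_N = 49      # use the interpolant only above this many positive obs


# ---------------------------------------------------------------------------
# observation-level log densities
# ---------------------------------------------------------------------------

@njit(cache=True)
def nb_logpmf_scalar(y, mu, phi):
    if phi < _PHI_POISSON:
        return y * math.log(mu) - mu - math.lgamma(y + 1.0)
    r = 1.0 / phi
    return (math.lgamma(y + r) - math.lgamma(r) - math.lgamma(y + 1.0)
            + r * math.log(r / (r + mu))
            + y * (math.log(mu) - math.log(r + mu)))


@njit(cache=True)
def _cp_series_term(k, c, a, logy):
    # log of the k-th term of the mu-free part of the Poisson-gamma series
    return k * c + k * a * logy - math.lgamma(k + 1.0) - math.lgamma(k * a)


@njit(cache=True)
def _digamma_big(x):
    # asymptotic psi(x), adequate for x >= ~8 (callers shift as needed)
    return math.log(x) - 0.5 / x - 1.0 / (12.0 * x * x)


@njit(cache=True)
def _trigamma_big(x):
    return 1.0 / x + 0.5 / (x * x) + 1.0 / (6.0 * x * x * x)


@njit(cache=True)
def cp_logw(y, phi, p, allow_laplace=False):
    """log W(y; phi, p): the mu-independent series of the Tweedie density.

    log f(y; mu, phi, p) = log W - log y
                           + (y*mu**(1-p)/(1-p) - mu**(2-p)/(2-p)) / phi
    for y > 0.  Summation over the latent Poisson count k, windowed around
    the maximizing index (Dunn & Smyth style envelope).  When the envelope
    index is large the summand is nearly Gaussian in k; with
    ``allow_laplace`` the sum is then replaced by its Laplace approximation
    (relative error O(1/k), used only inside optimization loops).
    """
    a = (2.0 - p) / (p - 1.0)
    c = -(1.0 + a) * math.log(phi) - math.log(2.0 - p) - a * math.log(p - 1.0)
    logy = math.log(y)
    k_env = y ** (2.0 - p) / ((2.0 - p) * phi)
    if allow_laplace and k_env > 200.0:
        # continuous maximizer of t(k) = k*c + k*a*logy - lgamma(k+1) - lgamma(k*a)
        k = k_env
        for _ in range(8):
            grad = c + a * logy - _digamma_big(k + 1.0) - a * _digamma_big(k * a)
            curv = -_trigamma_big(k + 1.0) - a * a * _trigamma_big(k * a)
            step = -grad / curv
            if step > 0.5 * k:
                step = 0.5 * k
            elif step < -0.5 * k:
                step = -0.5 * k
            k += step
            if abs(step) < 1e-8 * k:
                break
        tpeak = _cp_series_term(k, c, a, logy)
        curv = -_trigamma_big(k + 1.0) - a * a * _trigamma_big(k * a)
        return tpeak + 0.5 * math.log(2.0 * math.pi / (-curv))
    k = int(k_env)
    if k < 1:
        k = 1
    # climb to the exact (integer) peak
    t = _cp_series_term(k, c, a, logy)
    while True:
        t_up = _cp_series_term(k + 1, c, a, logy)
        if t_up > t:
            k += 1
            t = t_up
        else:
            break
    while k > 1:
        t_dn = _cp_series_term(k - 1, c, a, logy)
        if t_dn > t:
            k -= 1
            t = t_dn
        else:
            break
    peak = t
    s = 1.0
    j = k + 1
    while True:
        tj = _cp_series_term(j, c, a, logy)
        if tj < peak - _SERIES_DROP:
            break
        s += math.exp(tj - peak)
        j += 1
    j = k - 1
    while j >= 1:
        tj = _cp_series_term(j, c, a, logy)
        if tj < peak - _SERIES_DROP:
            break
        s += math.exp(tj - peak)
        j -= 1
    return peak + math.log(s)


@njit(cache=True)
def cp_logpdf_scalar(y, mu, phi, p):
    """Tweedie log density (y>0) / log point mass (y==0)."""
    kappa = mu ** (2.0 - p) / (2.0 - p)
    if y == 0.0:
        return -kappa / phi
    theta_y = y * mu ** (1.0 - p) / (1.0 - p)
    return cp_logw(y, phi, p) - math.log(y) + (theta_y - kappa) / phi


@njit(cache=True)
def cp_wlog_sum(y, phi, p, approx):
    """sum over positive y of [log W(y_i) - log y_i].

    With ``approx`` true and many positive observations, log W is evaluated
    at Chebyshev nodes in log y and interpolated; otherwise exact.
    """
    n = y.shape[0]
    npos = 0
    lymin = 1e308
    lymax = -1e308
    for i in range(n):
        if y[i] > 0.0:
            npos += 1
            ly = math.log(y[i])
            if ly < lymin:
                lymin = ly
            if ly > lymax:
                lymax = ly
    if npos == 0:
        return 0.0
    if (not approx) or npos < _CHEB_MIN_N or (lymax - lymin) < 1e-8:
        tot = 0.0
        for i in range(n):
            if y[i] > 0.0:
                tot += cp_logw(y[i], phi, p, approx) - math.log(y[i])
        return tot
    # Chebyshev interpolant of logW as a function of log y
    nc = _NCHEB
    mid = 0.5 * (lymin + lymax)
    half = 0.5 * (lymax - lymin)
    fvals = np.empty(nc)
    for j in range(nc):
        t = math.cos(math.pi * (j + 0.5) / nc)
        fvals[j] = cp_logw(math.exp(mid + half * t), phi, p, True)
    coef = np.zeros(nc)
    for k in range(nc):
        s = 0.0
        for j in range(nc):
            s += fvals[j] * math.cos(math.pi * k * (j + 0.5) / nc)
        coef[k] = 2.0 * s / nc
    coef[0] *= 0.5
    tot = 0.0
    for i in range(n):
        if y[i] > 0.0:
            ly = math.log(y[i])
            t = (ly - mid) / half
            if t > 1.0:
                t = 1.0
            elif t < -1.0:
                t = -1.0
            # Clenshaw recurrence
            b1 = 0.0
            b2 = 0.0
            for k in range(nc - 1, 0, -1):
                b0 = 2.0 * t * b1 - b2 + coef[k]
                b2 = b1
                b1 = b0
            tot += t * b1 - b2 + coef[0] - ly
    return tot


# ---------------------------------------------------------------------------
# per-strain pieces (sufficient statistics given the dispersion parameters)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nb_strain_node(sy, nrep, alpha, r, poisson, b):
    """sum_r log NB(y_r | mu = e^(alpha+b)) minus the obs-level constants."""
    eta = alpha + b
    if poisson:
        return sy * eta - nrep * math.exp(eta)
    mu = math.exp(eta)
    lrm = math.log(r + mu)
    return nrep * r * (math.log(r) - lrm) + sy * (eta - lrm)


@njit(cache=True)
def _nb_strain_derivs(sy, nrep, alpha, r, poisson, sigma2, b):
    """(h, g, H) of the per-strain integrand exponent (constants dropped)."""
    h = _nb_strain_node(sy, nrep, alpha, r, poisson, b) - 0.5 * b * b / sigma2
    mu = math.exp(alpha + b)
    if poisson:
        g = sy - nrep * mu - b / sigma2
        hess = -nrep * mu - 1.0 / sigma2
    else:
        g = sy - mu * (sy + nrep * r) / (r + mu) - b / sigma2
        hess = -(sy + nrep * r) * r * mu / ((r + mu) * (r + mu)) - 1.0 / sigma2
    return h, g, hess


@njit(cache=True)
def _cp_strain_node(sy, nrep, alpha, phi, p, b):
    mu = math.exp(alpha + b)
    return (sy * mu ** (1.0 - p) / (1.0 - p) - nrep * mu ** (2.0 - p) / (2.0 - p)) / phi


@njit(cache=True)
def _cp_strain_derivs(sy, nrep, alpha, phi, p, sigma2, b):
    mu = math.exp(alpha + b)
    mu1 = mu ** (1.0 - p)
    mu2 = mu ** (2.0 - p)
    h = (sy * mu1 / (1.0 - p) - nrep * mu2 / (2.0 - p)) / phi - 0.5 * b * b / sigma2
    g = (sy * mu1 - nrep * mu2) / phi - b / sigma2
    hess = ((1.0 - p) * sy * mu1 - (2.0 - p) * nrep * mu2) / phi - 1.0 / sigma2
    return h, g, hess


@njit(cache=True)
def _strain_mode_nb(sy, nrep, alpha, r, poisson, sigma2, b0):
    b = b0
    h, g, hess = _nb_strain_derivs(sy, nrep, alpha, r, poisson, sigma2, b)
    for _ in range(60):
        step = -g / hess
        if step > 2.0:
            step = 2.0
        elif step < -2.0:
            step = -2.0
        bn = b + step
        hn, gn, hessn = _nb_strain_derivs(sy, nrep, alpha, r, poisson, sigma2, bn)
        nhalf = 0
        while hn < h and nhalf < 30:
            step *= 0.5
            bn = b + step
            hn, gn, hessn = _nb_strain_derivs(sy, nrep, alpha, r, poisson, sigma2, bn)
            nhalf += 1
        b, h, g, hess = bn, hn, gn, hessn
        if abs(step) < 1e-11:
            break
    return b, hess


@njit(cache=True)
def _strain_mode_cp(sy, nrep, alpha, phi, p, sigma2, b0):
    b = b0
    h, g, hess = _cp_strain_derivs(sy, nrep, alpha, phi, p, sigma2, b)
    for _ in range(60):
        step = -g / hess
        if step > 2.0:
            step = 2.0
        elif step < -2.0:
            step = -2.0
        bn = b + step
        hn, gn, hessn = _cp_strain_derivs(sy, nrep, alpha, phi, p, sigma2, bn)
        nhalf = 0
        while hn < h and nhalf < 30:
            step *= 0.5
            bn = b + step
            hn, gn, hessn = _cp_strain_derivs(sy, nrep, alpha, phi, p, sigma2, bn)
            nhalf += 1
        b, h, g, hess = bn, hn, gn, hessn
        if abs(step) < 1e-11:
            break
    return b, hess


# ---------------------------------------------------------------------------
# marginal log-likelihoods (adaptive Gauss-Hermite per strain)
# ---------------------------------------------------------------------------

@njit(cache=True)
def nb_glm_loglik(y, alpha, phi):
    """Independent (sigma2 = 0) NB log-likelihood with common mean e^alpha."""
    mu = math.exp(alpha)
    ll = 0.0
    for i in range(y.shape[0]):
        ll += nb_logpmf_scalar(y[i], mu, phi)
    return ll


@njit(cache=True)
def cp_glm_loglik(y, alpha, phi, p, approx=False):
    mu = math.exp(alpha)
    mu1 = mu ** (1.0 - p) / (1.0 - p)
    kappa = mu ** (2.0 - p) / (2.0 - p)
    ll = cp_wlog_sum(y, phi, p, approx)
    for i in range(y.shape[0]):
        ll += (y[i] * mu1 - kappa) / phi
    return ll


@njit(cache=True)
def _nb_constants(y, starts, r, poisson):
    """Observation-level log-gamma constants, summed per feature."""
    tot = 0.0
    for i in range(y.shape[0]):
        if poisson:
            tot -= math.lgamma(y[i] + 1.0)
        else:
            tot += math.lgamma(y[i] + r) - math.lgamma(r) - math.lgamma(y[i] + 1.0)
    return tot


@njit(cache=True)
def nb_marginal_loglik(y, starts, alpha, phi, sigma2, nodes, logwts):
    """log prod_s integral of prod_r NB(y | e^(alpha+b)) dN(b; 0, sigma2).

    One mode-recentered Gauss-Hermite quadrature per strain.  sigma2 == 0
    degenerates to the independent GLM log-likelihood.
    """
    if sigma2 <= 1e-12:
        return nb_glm_loglik(y, alpha, phi)
    poisson = phi < _PHI_POISSON
    r = 0.0 if poisson else 1.0 / phi
    total = _nb_constants(y, starts, r, poisson)
    n_strain = starts.shape[0] - 1
    nq = nodes.shape[0]
    const = -0.5 * math.log(2.0 * math.pi * sigma2)
    sqrt2 = math.sqrt(2.0)
    lim = 5.0 * math.sqrt(sigma2)
    for s in range(n_strain):
        lo = starts[s]
        hi = starts[s + 1]
        nrep = float(hi - lo)
        sy = 0.0
        for i in range(lo, hi):
            sy += y[i]
        b0 = math.log(sy / nrep + 0.5) - alpha
        if b0 > lim:
            b0 = lim
        elif b0 < -lim:
            b0 = -lim
        m, hess = _strain_mode_nb(sy, nrep, alpha, r, poisson, sigma2, b0)
        shat = 1.0 / math.sqrt(-hess)
        mx = -1e308
        terms = np.empty(nq)
        for i in range(nq):
            b = m + sqrt2 * shat * nodes[i]
            hv = _nb_strain_node(sy, nrep, alpha, r, poisson, b) - 0.5 * b * b / sigma2
            t = logwts[i] + nodes[i] * nodes[i] + hv
            terms[i] = t
            if t > mx:
                mx = t
        ssum = 0.0
        for i in range(nq):
            ssum += math.exp(terms[i] - mx)
        total += mx + math.log(ssum) + math.log(sqrt2 * shat) + const
    return total


@njit(cache=True)
def cp_marginal_loglik(y, starts, alpha, phi, p, sigma2, nodes, logwts, approx=False):
    if sigma2 <= 1e-12:
        return cp_glm_loglik(y, alpha, phi, p, approx)
    total = cp_wlog_sum(y, phi, p, approx)
    n_strain = starts.shape[0] - 1
    nq = nodes.shape[0]
    const = -0.5 * math.log(2.0 * math.pi * sigma2)
    sqrt2 = math.sqrt(2.0)
    lim = 5.0 * math.sqrt(sigma2)
    for s in range(n_strain):
        lo = starts[s]
        hi = starts[s + 1]
        nrep = float(hi - lo)
        sy = 0.0
        for i in range(lo, hi):
            sy += y[i]
        b0 = math.log(sy / nrep + 0.5) - alpha
        if b0 > lim:
            b0 = lim
        elif b0 < -lim:
            b0 = -lim
        m, hess = _strain_mode_cp(sy, nrep, alpha, phi, p, sigma2, b0)
        shat = 1.0 / math.sqrt(-hess)
        mx = -1e308
        terms = np.empty(nq)
        for i in range(nq):
            b = m + sqrt2 * shat * nodes[i]
            hv = _cp_strain_node(sy, nrep, alpha, phi, p, b) - 0.5 * b * b / sigma2
            t = logwts[i] + nodes[i] * nodes[i] + hv
            terms[i] = t
            if t > mx:
                mx = t
        ssum = 0.0
        for i in range(nq):
            ssum += math.exp(terms[i] - mx)
        total += mx + math.log(ssum) + math.log(sqrt2 * shat) + const
    return total


# ---------------------------------------------------------------------------
# Nelder-Mead drivers (run inside numba so that ~10^4-fit simulation studies
# stay cheap; objective conventions match glmm.py's parameterization)
# ---------------------------------------------------------------------------

_P_EPS = 0.01


@njit(cache=True)
def _p_from_z(z):
    return 1.0 + _P_EPS + (1.0 - 2.0 * _P_EPS) / (1.0 + math.exp(-z))


@njit(cache=True)
def _nb_negll_x(x, y, starts, nodes, logwts):
    # x = (alpha, sqrt(phi), sqrt(sigma2))
    return -nb_marginal_loglik(y, starts, x[0], x[1] * x[1], x[2] * x[2],
                               nodes, logwts)


@njit(cache=True)
def _cp_negll_x(x, y, starts, nodes, logwts):
    # x = (alpha, sqrt(phi), z_p, sqrt(sigma2)); Chebyshev-approximated W series
    phi = x[1] * x[1]
    if phi < 1e-10:
        phi = 1e-10
    return -cp_marginal_loglik(y, starts, x[0], phi, _p_from_z(x[2]),
                               x[3] * x[3], nodes, logwts, True)


@njit(cache=True)
def nb_null_negll_phi(sphi, y, alpha):
    # 1-D profile in sqrt(phi); the intercept MLE is log(ybar) for any phi
    return -nb_glm_loglik(y, alpha, sphi * sphi)


@njit(cache=True)
def golden_min(fun, lo, hi, y, alpha, tol):
    """Golden-section minimization of a unimodal scalar function on [lo, hi]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = fun(c, y, alpha)
    fd = fun(d, y, alpha)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c, y, alpha)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d, y, alpha)
    if fc < fd:
        return c, fc
    return d, fd


@njit(cache=True)
def _cp_null_negll_x(x, y, starts, nodes, logwts):
    # x = (sqrt(phi), z_p); alpha profiled out as log(mean) beforehand -- the
    # caller embeds alpha in ... actually alpha passed via starts hack is ugly;
    # instead the mean is recomputed here (exponential family => MLE of mu is ybar).
    n = y.shape[0]
    sy = 0.0
    for i in range(n):
        sy += y[i]
    alpha = math.log(sy / n)
    phi = x[0] * x[0]
    if phi < 1e-10:
        phi = 1e-10
    return -cp_glm_loglik(y, alpha, phi, _p_from_z(x[1]), True)


# no cache: specializations keyed on a function-typed argument do not pickle
@njit(cache=False)
def neldermead(fun, x0, steps, y, starts, nodes, logwts, xatol, fatol, maxfev):
    """Plain Nelder-Mead (reflection 1, expansion 2, contraction 0.5, shrink 0.5).

    Returns (xbest, fbest, nfev, converged).
    """
    n = x0.shape[0]
    m = n + 1
    sim = np.empty((m, n))
    fx = np.empty(m)
    for j in range(n):
        sim[0, j] = x0[j]
    fx[0] = fun(x0, y, starts, nodes, logwts)
    nfev = 1
    for i in range(n):
        for j in range(n):
            sim[i + 1, j] = x0[j]
        sim[i + 1, i] = x0[i] + steps[i]
        fx[i + 1] = fun(sim[i + 1], y, starts, nodes, logwts)
        nfev += 1
    converged = False
    xr = np.empty(n)
    xe = np.empty(n)
    xc = np.empty(n)
    cen = np.empty(n)
    while nfev < maxfev:
        # order
        order = np.argsort(fx)
        sim2 = sim[order]
        fx2 = fx[order]
        for i in range(m):
            for j in range(n):
                sim[i, j] = sim2[i, j]
            fx[i] = fx2[i]
        # convergence: simplex size and f spread
        xspread = 0.0
        fspread = 0.0
        for i in range(1, m):
            d = abs(fx[i] - fx[0])
            if d > fspread:
                fspread = d
            for j in range(n):
                d = abs(sim[i, j] - sim[0, j])
                if d > xspread:
                    xspread = d
        if xspread <= xatol and fspread <= fatol:
            converged = True
            break
        for j in range(n):
            c = 0.0
            for i in range(m - 1):
                c += sim[i, j]
            cen[j] = c / (m - 1)
        for j in range(n):
            xr[j] = cen[j] + (cen[j] - sim[m - 1, j])
        fr = fun(xr, y, starts, nodes, logwts)
        nfev += 1
        if fr < fx[0]:
            for j in range(n):
                xe[j] = cen[j] + 2.0 * (cen[j] - sim[m - 1, j])
            fe = fun(xe, y, starts, nodes, logwts)
            nfev += 1
            if fe < fr:
                for j in range(n):
                    sim[m - 1, j] = xe[j]
                fx[m - 1] = fe
            else:
                for j in range(n):
                    sim[m - 1, j] = xr[j]
                fx[m - 1] = fr
        elif fr < fx[m - 2]:
            for j in range(n):
                sim[m - 1, j] = xr[j]
            fx[m - 1] = fr
        else:
            if fr < fx[m - 1]:
                for j in range(n):
                    xc[j] = cen[j] + 0.5 * (xr[j] - cen[j])
            else:
                for j in range(n):
                    xc[j] = cen[j] + 0.5 * (sim[m - 1, j] - cen[j])
            fc = fun(xc, y, starts, nodes, logwts)
            nfev += 1
            if fc < min(fr, fx[m - 1]):
                for j in range(n):
                    sim[m - 1, j] = xc[j]
                fx[m - 1] = fc
            else:
                # shrink toward the best vertex
                for i in range(1, m):
                    for j in range(n):
                        sim[i, j] = sim[0, j] + 0.5 * (sim[i, j] - sim[0, j])
                    fx[i] = fun(sim[i], y, starts, nodes, logwts)
                    nfev += 1
    best = 0
    for i in range(1, m):
        if fx[i] < fx[best]:
            best = i
    return sim[best].copy(), fx[best], nfev, converged
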