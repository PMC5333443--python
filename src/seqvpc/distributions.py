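"""Observation models: negative binomial and Tweedie compound Poisson.

Both families are parameterized by their mean ``mu`` and a dispersion
``phi``; the NB has Var(Y) = mu + phi*mu**2 and the compound Poisson has
Var(Y) = phi*mu**p with power parameter 1 < p < 2.  The compound Poisson is
the distribution of a Poisson(lam) number of i.i.d. Gamma summands, so it is
continuous on (0, inf) with a point mass at zero -- a natural model for
library-size-normalized (non-integer) read counts.
"""

from dataclasses import dataclass

import numpy as np

from . import _kernels


@dataclass(frozen=True)
class NBObsParams:
    """Negative binomial observation parameters (mean / dispersion form)."""
    mu: float
    phi: float

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.phi < 0:
            raise ValueError(f"phi must be non-negative, got {self.phi}")


@dataclass(frozen=True)
class CPObsParams:
    """Compound Poisson (Tweedie) observation parameters."""
    mu: float
    phi: float
    p: float

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.phi <= 0:
            raise ValueError(f"phi must be positive, got {self.phi}")
        if not 1.0 < self.p < 2.0:
            raise ValueError(f"p must lie in (1, 2), got {self.p}")

    @property
    def poisson_rate(self) -> float:
        return self.mu ** (2.0 - self.p) / (self.phi * (2.0 - self.p))

    @property
    def gamma_shape(self) -> float:
        return (2.0 - self.p) / (self.p - 1.0)

    @property
    def gamma_scale(self) -> float:
        return self.phi * (self.p - 1.0) * self.mu ** (self.p - 1.0)


def nb_logpmf(y, params: NBObsParams):
    """Log probability mass of the NB at integer counts ``y``.

    phi == 0 is evaluated as the exact Poisson limit.
    """
    y_arr = np.asarray(y, dtype=float)
    if not np.all(np.isclose(y_arr, np.round(y_arr))):
        raise ValueError("NB log-pmf requires integer counts; round first")
    if np.any(y_arr < 0):
        raise ValueError("counts must be non-negative")
    out = np.empty_like(y_arr)
    flat = y_arr.ravel()
    oflat = out.ravel()
    for i in range(flat.size):
        oflat[i] = _kernels.nb_logpmf_scalar(flat[i], params.mu, params.phi)
    return out if out.ndim else float(out)


def cp_logpdf(y, params: CPObsParams):
    """Tweedie log density (log point mass at y == 0)."""
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0):
        raise ValueError("y must be non-negative")
    out = np.empty_like(y_arr)
    flat = y_arr.ravel()
    oflat = out.ravel()
    for i in range(flat.size):
        oflat[i] = _kernels.cp_logpdf_scalar(flat[i], params.mu, params.phi, params.p)
    return out if out.ndim else float(out)


def nb_sample(n: int, params: NBObsParams, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. NB draws (Poisson draws when phi == 0)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if params.phi < 1e-12:
        return rng.poisson(params.mu, size=n)
    r = 1.0 / params.phi
    return rng.negative_binomial(r, r / (r + params.mu), size=n)


def cp_sample(n: int, params: CPObsParams, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. compound Poisson draws via the Poisson-sum-of-gammas representation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = rng.poisson(params.poisson_rate, size=n)
    out = np.zeros(n)
    pos = counts > 0
    if np.any(pos):
        out[pos] = rng.gamma(counts[pos] * params.gamma_shape, params.gamma_scale)
    return out
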