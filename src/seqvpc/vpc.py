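"""Variance partition coefficients (VPC) for the three model families.

The VPC generalizes the intra-class correlation to non-linear mixed models:

    VPC = Var(E(y | strain)) / [ Var(E(y | strain)) + E(Var(y | strain)) ]

With a log link and strain effects b ~ N(0, sigma2), e^(alpha + b) is
log-normal, which yields closed forms:

* linear mixed model:      sigma2_g / (sigma2_g + sigma2_eps)
* NB mixed model:          (e^s2 - 1) / (e^s2 - 1 + phi e^s2 + e^(-alpha - s2/2))
* compound Poisson MM:     (e^s2 - 1) / (e^s2 - 1 + phi e^((p-2) alpha + (p^2/2 - 1) s2))

The NB VPC is bounded above by (e^s2 - 1)/(e^s2 - 1 + phi e^s2), whose
sigma2 -> inf limit is 1/(1 + phi): an overdispersed feature can never reach
a VPC of 1 under the NB model, which matters when comparing scores across
methods.  The LMM and CP VPCs have upper bound 1.
"""

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

_SIGMA2_BRACKET = (0.0, 60.0)


@dataclass(frozen=True)
class VPCResult:
    vpc: float
    model: str              # "LMM", "NBMM" or "CPMM"
    upper_bound: float      # sup over sigma2 of the model's VPC (1 for LMM/CPMM)


def vpc_lmm(sigma2_g_star: float, sigma2_eps_star: float) -> VPCResult:
    """Intra-class correlation of the one-way Gaussian mixed model."""
    if sigma2_g_star < 0:
        raise ValueError("sigma2_g_star must be non-negative")
    if sigma2_eps_star <= 0:
        if sigma2_g_star == 0:
            raise ValueError("both variance components are zero; VPC undefined")
        raise ValueError("sigma2_eps_star must be positive")
    return VPCResult(sigma2_g_star / (sigma2_g_star + sigma2_eps_star), "LMM", 1.0)


def _nb_vpc_value(alpha: float, sigma2: float, phi: float) -> float:
    # computed via expm1 / log-space pieces so that sigma2 up to 60 is safe
    em1 = np.expm1(sigma2)
    return float(em1 / (em1 + phi * np.exp(sigma2) + np.exp(-alpha - sigma2 / 2.0)))


def vpc_nbmm(alpha: float, sigma2: float, phi: float) -> VPCResult:
    """VPC of the NB mixed model, with its theoretical upper bound attached."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if phi < 0:
        raise ValueError("phi must be non-negative")
    if sigma2 == 0:
        # the bound reported is the sup over sigma2 for this phi
        return VPCResult(0.0, "NBMM", 1.0 / (1.0 + phi))
    em1 = np.expm1(sigma2)
    vpc = _nb_vpc_value(alpha, sigma2, phi)
    bound = float(em1 / (em1 + phi * np.exp(sigma2))) if phi > 0 else 1.0
    return VPCResult(vpc, "NBMM", bound)


def _cp_vpc_value(alpha: float, sigma2: float, phi: float, p: float) -> float:
    em1 = np.expm1(sigma2)
    denom_extra = phi * np.exp((p - 2.0) * alpha + (p * p / 2.0 - 1.0) * sigma2)
    return float(em1 / (em1 + denom_extra))


def vpc_cpmm(alpha: float, sigma2: float, phi: float, p: float) -> VPCResult:
    """VPC of the compound Poisson mixed model (upper bound 1)."""
    if not 1.0 < p < 2.0:
        raise ValueError(f"p must lie in (1, 2), got {p}")
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if phi <= 0:
        raise ValueError("phi must be positive")
    if sigma2 == 0:
        return VPCResult(0.0, "CPMM", 1.0)
    return VPCResult(_cp_vpc_value(alpha, sigma2, phi, p), "CPMM", 1.0)


def solve_sigma2_for_vpc(target_vpc: float, model: str, alpha: float,
                         phi: float, p: float | None = None) -> float:
    """Invert the VPC: the sigma2 producing ``target_vpc`` for fixed (alpha, phi[, p]).

    Used to pin simulated features at prescribed heritability levels.  The
    VPC is strictly increasing in sigma2, so a root bracketed on [0, 60] is
    unique; an infeasible target (at or above the supremum over sigma2)
    raises with the attainable supremum in the message.
    """
    if not 0.0 < target_vpc < 1.0:
        raise ValueError("target_vpc must lie strictly in (0, 1)")
    lo, hi = _SIGMA2_BRACKET
    if model == "NBMM":
        fun = lambda s2: _nb_vpc_value(alpha, s2, phi) - target_vpc
    elif model == "CPMM":
        if p is None:
            raise ValueError("CPMM requires the Tweedie power p")
        fun = lambda s2: _cp_vpc_value(alpha, s2, phi, p) - target_vpc
    else:
        raise ValueError(f"unknown model {model!r}; use 'NBMM' or 'CPMM'")
    sup = fun(hi) + target_vpc
    if target_vpc >= sup:
        raise ValueError(
            f"target VPC {target_vpc} is not attainable for {model} with these "
            f"parameters; the supremum over sigma2 is {sup:.6f}")
    return float(brentq(fun, lo, hi, xtol=1e-12, rtol=1e-14))
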