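"""Expected coalescent intervals and branch-length spectra.

Covers the standard constant-size coalescent, the general mapping from
expected coalescent intervals ``E[T_k]`` to the expected branch-length
spectrum ``E[tau_i]`` (valid for any coalescent tree with exchangeable
topology), and large-sample approximations for a population that has grown
exponentially to its present size.

Under exponential growth at coalescent-scale rate ``beta = N0 * r`` the
expected time for the ancestral lineage count to fall from ``n`` to ``k``
is ``(1/beta) log(2 beta (1/k - 1/n) + 1)``; differentiating in ``k/n``
gives the interval approximation, and carrying the same continuum
approximation through the branch-length sum yields a closed form for
``E[tau_i]`` in terms of the Gauss hypergeometric function 2F1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import gammaln, hyp2f1

from .poisson_model import BranchLengthSpectrum

__all__ = [
    "CoalescentIntervals",
    "GrowthModel",
    "intervals_constant",
    "intervals_growth",
    "tau_from_intervals",
    "tau_growth_hypergeometric",
    "growth_tau_spectrum",
    "growth_calibration",
    "star_tree_limit",
]

# below this beta/n the 2F1 series argument 1 - n/(2 beta) leaves the region
# where the scipy evaluation is reliably accurate; use quadrature instead
_HYP_BETA_OVER_N_MIN = 0.6


@dataclass(frozen=True)
class CoalescentIntervals:
    """Expected coalescent interval lengths ``E[T_k]`` for ``k = 2..n``.

    ``T_k`` is the time during which the sample had exactly ``k`` ancestral
    lineages, in coalescent units.  ``ET[k-2] = E[T_k]``.
    """

    n: int
    ET: np.ndarray

    def __post_init__(self) -> None:
        et = np.asarray(self.ET, dtype=float)
        if len(et) != self.n - 1:
            raise ValueError(f"need E[T_k] for k=2..{self.n}, got {len(et)} values")
        if np.any(et <= 0):
            raise ValueError("all E[T_k] must be > 0")
        object.__setattr__(self, "ET", et)

    def total_tree_length(self) -> float:
        """``sum_k k E[T_k]`` — expected total branch length of the genealogy."""
        k = np.arange(2, self.n + 1)
        return float(np.sum(k * self.ET))

    def total_height(self) -> float:
        """``sum_k E[T_k]`` — expected time to the most recent common ancestor."""
        return float(np.sum(self.ET))


@dataclass(frozen=True)
class GrowthModel:
    """Exponential growth: ``N(t) = N0 exp(-beta t)`` backward in time.

    ``beta = N0 * r`` where ``N0`` is the current haploid population size and
    ``r`` the per-generation growth rate; ``t`` is in coalescent units of
    ``N0`` generations.
    """

    beta: float
    n: int | None = None
    N0: float | None = None
    r: float | None = None
    generation_years: float | None = None

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.N0 is not None and self.r is not None:
            if abs(self.beta - self.N0 * self.r) > 1e-6 * self.beta:
                raise ValueError("beta must equal N0 * r when both are given")

    def size_at(self, t: float) -> float:
        """Population size at coalescent time ``t`` in the past."""
        if self.N0 is None:
            raise ValueError("N0 not set")
        return self.N0 * math.exp(-self.beta * t)

    def size_years_ago(self, years: float) -> float:
        """Population size ``years`` ago (needs N0 and generation_years)."""
        if self.N0 is None or self.generation_years is None:
            raise ValueError("N0 and generation_years required")
        t = years / (self.generation_years * self.N0)
        return self.size_at(t)


def intervals_constant(n: int) -> CoalescentIntervals:
    """Standard neutral coalescent: ``E[T_k] = 2 / (k (k - 1))``."""
    if n < 2:
        raise ValueError("n must be >= 2")
    k = np.arange(2, n + 1)
    return CoalescentIntervals(n=n, ET=2.0 / (k * (k - 1.0)))


def intervals_growth(
    n: int, beta: float, mode: str = "derivative"
) -> CoalescentIntervals:
    """Expected coalescent intervals under exponential growth (large ``n``).

    mode="derivative" evaluates ``E[T_k] = 2 / (k (2 beta (1 - k/n) + k))``,
    the derivative of the cumulative-time curve; mode="difference" takes
    exact finite differences of that curve instead.  The two agree up to
    discretization error and both recover ``2/(k(k-1))`` as ``beta -> 0``.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    if n < 1000:
        warnings.warn(
            f"intervals_growth is a large-n approximation; n={n} < 1000",
            stacklevel=2,
        )
    k = np.arange(2, n + 1, dtype=float)
    if mode == "derivative":
        ET = 2.0 / (k * (2.0 * beta * (1.0 - k / n) + k))
    elif mode == "difference":
        # cumulative expected time for lineages to drop from n to k
        def F(kk: np.ndarray) -> np.ndarray:
            return np.log(2.0 * beta * (1.0 / kk - 1.0 / n) + 1.0) / beta

        ET = F(k - 1.0) - F(k)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CoalescentIntervals(n=n, ET=ET)


def tau_from_intervals(
    intervals: CoalescentIntervals, i_max: int | None = None
) -> BranchLengthSpectrum:
    """Expected branch-length spectrum from expected coalescent intervals.

    ``E[tau_i] = sum_{k=2}^{n} k E[T_k] C(n-i-1, k-2) / C(n-1, k-1)`` — the
    probability that a branch present while ``k`` lineages exist subtends
    exactly ``i`` leaves is hypergeometric in the exchangeable coalescent
    topology.  Two conservation laws hold exactly:
    ``sum_i tau_i = sum_k k E[T_k]`` and ``sum_i i tau_i = n sum_k E[T_k]``.

    ``i_max`` limits the computed prefix (O(i_max * n) work); ``total_sum``
    always carries the full total length regardless of the prefix.
    """
    n = intervals.n
    if i_max is None:
        i_max = n - 1
    if not 1 <= i_max <= n - 1:
        raise ValueError(f"i_max must be in 1..{n - 1}")
    k = np.arange(2, n + 1, dtype=float)
    log_denom = gammaln(n) - gammaln(k) - gammaln(n - k + 1.0)  # log C(n-1, k-1)
    kET = k * intervals.ET
    tau = np.empty(i_max)
    for i in range(1, i_max + 1):
        top = n - i - 1.0
        valid = k - 2.0 <= top
        log_num = np.full(n - 1, -np.inf)
        kk = k[valid]
        log_num[valid] = gammaln(top + 1.0) - gammaln(kk - 1.0) - gammaln(
            top - kk + 3.0
        )
        with np.errstate(invalid="ignore"):
            ratio = np.exp(log_num - log_denom)
        tau[i - 1] = float(np.sum(kET * np.where(valid, ratio, 0.0)))
    return BranchLengthSpectrum(
        n=n, tau_bar=tau, total_sum=intervals.total_tree_length()
    )


def _tau_growth_integral(n: int, beta: float, i: int) -> float:
    """Quadrature evaluation of the growth branch-length integral.

    ``E[tau_i] = (n/beta) int_0^1 x (1-x)^{i-1} / (1 - (1 - n/(2 beta)) x) dx``,
    split at x = 0.5 to tame the ``(1-x)^{i-1}`` endpoint behavior.
    """
    z = 1.0 - n / (2.0 * beta)

    def integrand(x: float) -> float:
        return x * (1.0 - x) ** (i - 1) / (1.0 - z * x)

    a1, _ = integrate.quad(integrand, 0.0, 0.5, epsrel=1e-8, limit=200)
    a2, _ = integrate.quad(integrand, 0.5, 1.0, epsrel=1e-8, limit=200)
    return n / beta * (a1 + a2)


def tau_growth_hypergeometric(
    n: int, beta: float, i: int, mode: str = "auto"
) -> float:
    """Expected branch length ``E[tau_i]`` under exponential growth.

    Closed form ``(n/beta) / (i (i+1)) * 2F1(1, 2; i+2; 1 - n/(2 beta))``,
    with an adaptive-quadrature fallback on the equivalent integral when the
    hypergeometric argument is far outside the unit disk (``beta/n`` small).
    mode is "auto", "hyp" or "integral".
    """
    if not 1 <= i <= n - 1:
        raise ValueError(f"i must be in 1..{n - 1}")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if mode == "auto":
        mode = "hyp" if beta / n >= _HYP_BETA_OVER_N_MIN else "integral"
    if mode == "hyp":
        z = 1.0 - n / (2.0 * beta)
        val = n / beta / (i * (i + 1.0)) * float(hyp2f1(1.0, 2.0, i + 2.0, z))
        if np.isfinite(val) and val >= 0:
            return val
        mode = "integral"  # pragma: no cover - defensive
    if mode == "integral":
        return _tau_growth_integral(n, beta, i)
    raise ValueError(f"unknown mode {mode!r}")


def growth_tau_spectrum(
    n: int, beta: float, b: int = 40, mode: str = "auto"
) -> BranchLengthSpectrum:
    """Branch-length spectrum prefix ``i = 1..b`` under exponential growth.

    Individual ``E[tau_i]`` come from the hypergeometric/integral closed
    form; the full-total ``sum_{i=1}^{n-1} E[tau_i]`` is taken from the
    interval approximation's total tree length, which is all downstream
    formulas need beyond the prefix.
    """
    tau = np.array([tau_growth_hypergeometric(n, beta, i, mode) for i in range(1, b + 1)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        total = intervals_growth(n, beta).total_tree_length()
    return BranchLengthSpectrum(n=n, tau_bar=tau, total_sum=max(total, float(tau.sum())))


def star_tree_limit(n: int, beta: float, i: int) -> float:
    """Extreme-growth (star tree) limit of ``E[tau_i]``.

    ``(log(2 beta / n) - 1) / (beta / n)`` for ``i = 1`` and
    ``1 / (i (i - 1) beta / n)`` for ``i >= 2``: under extreme growth nearly
    all variants are singletons.
    """
    g = beta / n
    if i == 1:
        return (math.log(2.0 * g) - 1.0) / g
    return 1.0 / (i * (i - 1.0) * g)


def growth_calibration(
    N0: float, r: float, generation_years: float = 30.0, n: int | None = None
) -> GrowthModel:
    """Build a GrowthModel from demographic parameters: ``beta = N0 * r``."""
    if N0 <= 0 or r <= 0 or generation_years <= 0:
        raise ValueError("N0, r and generation_years must be > 0")
    return GrowthModel(
        beta=N0 * r, n=n, N0=N0, r=r, generation_years=generation_years
    )
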