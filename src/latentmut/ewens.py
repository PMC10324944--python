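"""Exact constant-size (equilibrium diffusion) results for latent mutations.

At a single site with parent-independent mutation among ``K`` alleles, the
equilibrium sampling probability of allele counts is an Ewens-type formula in
rising factorials of the scaled mutation rates ``theta * pi_i``.  Expanding a
rising factorial in unsigned Stirling numbers of the first kind introduces a
latent variable ``k_i``: the number of most-recent ("latent") mutations that
produced the ``n_i`` observed copies of allele ``i``.  Conditional on the
sample counts, each ``k_i`` is distributed like the number of alleles in the
Ewens sampling formula with parameter ``theta * pi_i``, independently across
alleles.

This module evaluates those exact formulas, their large-sample asymptotics,
and the root-conditioned ("augmented") refinement that quantifies how well an
independent-Poissons description matches the equilibrium diffusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp, polygamma

__all__ = [
    "MutationModel",
    "SampleCounts",
    "LatentDistribution",
    "stirling1_unsigned",
    "log_stirling1",
    "latent_mutation_pmf",
    "two_allele_sampling_pmf",
    "k_allele_ordered_prob",
    "k_allele_unordered_prob",
    "large_n_sampling_approx",
    "augmented_root_model",
    "augmented_error",
    "augmented_error_coefficient",
    "log_rising",
]

EULER_GAMMA = float(np.euler_gamma)


@dataclass(frozen=True)
class MutationModel:
    """Parent-independent mutation model.

    Parameters
    ----------
    theta
        Total scaled mutation rate (diffusion scale, dimensionless), > 0.
    pis
        Allele-production probabilities ``pi_1..pi_K``; each mutation produces
        an allele of type ``i`` with probability ``pi_i`` regardless of the
        parental state.  Must be positive and sum to one.
    """

    theta: float
    pis: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        pis = tuple(float(p) for p in self.pis)
        if len(pis) < 2:
            raise ValueError("need at least K=2 alleles")
        if any(p <= 0 for p in pis):
            raise ValueError("all pi_i must be > 0")
        if abs(sum(pis) - 1.0) > 1e-9:
            raise ValueError(f"pi_i must sum to 1, got {sum(pis)}")
        object.__setattr__(self, "pis", pis)

    @property
    def K(self) -> int:
        return len(self.pis)

    @property
    def thetas(self) -> np.ndarray:
        """Per-allele mutation parameters ``theta * pi_i``."""
        return self.theta * np.asarray(self.pis)


@dataclass(frozen=True)
class SampleCounts:
    """Allele counts ``n_1..n_K`` in a sample of total size ``n``."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if any(c < 0 for c in counts):
            raise ValueError("allele counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class LatentDistribution:
    """Distribution of the number of latent mutations ``k1`` for one allele.

    ``support`` is ``1..n1`` for ``n1 >= 1`` and ``{0}`` for ``n1 = 0``
    (no copies means no latent mutations, a point mass by convention).
    """

    n1: int
    theta1: float
    support: np.ndarray
    pmf: np.ndarray

    def mean(self) -> float:
        return float(np.dot(self.support, self.pmf))

    def as_dict(self) -> dict[int, float]:
        return {int(k): float(p) for k, p in zip(self.support, self.pmf)}


# ---------------------------------------------------------------------------
# Stirling numbers of the first kind (unsigned)
# ---------------------------------------------------------------------------

_STIRLING_ROWS: list[list[int]] = [[1]]  # row n holds |S(n, k)| for k = 0..n


def _extend_stirling_rows(n: int) -> None:
    while len(_STIRLING_ROWS) <= n:
        m = len(_STIRLING_ROWS)  # building row m from row m-1
        prev = _STIRLING_ROWS[m - 1]
        row = [0] * (m + 1)
        for k in range(1, m + 1):
            # |S(m,k)| = |S(m-1,k-1)| + (m-1)|S(m-1,k)|
            row[k] = prev[k - 1] + (m - 1) * (prev[k] if k < m else 0)
        _STIRLING_ROWS.append(row)


def stirling1_unsigned(n: int, k: int) -> int:
    """Unsigned Stirling number of the first kind, exact big integer.

    ``|S(n,k)|`` counts permutations of ``n`` elements with ``k`` cycles;
    here it weights the ways ``n`` observed copies of an allele partition
    among ``k`` latent mutations.
    """
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"require 0 <= k <= n, got n={n}, k={k}")
    _extend_stirling_rows(n)
    return _STIRLING_ROWS[n][k]


@lru_cache(maxsize=None)
def _log_stirling_row(n: int) -> np.ndarray:
    """log |S(n,k)| for k = 0..n (``-inf`` where the number is zero)."""
    _extend_stirling_rows(n)
    row = _STIRLING_ROWS[n]
    out = np.full(n + 1, -np.inf)
    for k, v in enumerate(row):
        if v > 0:
            out[k] = _log_bigint(v)
    return out


def _log_bigint(v: int) -> float:
    # math.log overflows float conversion beyond ~1e308; go via bit_length
    if v.bit_length() <= 1000:
        return math.log(v)
    shift = v.bit_length() - 53
    return math.log(v >> shift) + shift * math.log(2.0)


def log_stirling1(n: int, k: int) -> float:
    """Natural log of ``|S(n,k)|`` (``-inf`` if the value is zero)."""
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"require 0 <= k <= n, got n={n}, k={k}")
    return float(_log_stirling_row(n)[k])


# ---------------------------------------------------------------------------
# Rising factorials and sampling probabilities
# ---------------------------------------------------------------------------

def log_rising(x: float, m) -> float | np.ndarray:
    """log of the rising factorial (Pochhammer) ``x^(m) = x(x+1)...(x+m-1)``."""
    return gammaln(x + np.asarray(m, dtype=float)) - gammaln(x)


def latent_mutation_pmf(n1: int, theta1: float) -> LatentDistribution:
    """Distribution of the number of latent mutations given ``n1`` copies.

    ``P(k1 | n1) = |S_{n1}(k1)| theta1^{k1} / theta1^{(n1)}`` for
    ``k1 = 1..n1`` — the Ewens number-of-alleles distribution with parameter
    ``theta1 = theta * pi_1``.  Valid for a rare variant in a large sample,
    for any number of allelic types.  Computed in log space.
    """
    if theta1 <= 0:
        raise ValueError(f"theta1 must be > 0, got {theta1}")
    n1 = int(n1)
    if n1 < 0:
        raise ValueError(f"n1 must be >= 0, got {n1}")
    if n1 == 0:
        return LatentDistribution(0, theta1, np.array([0]), np.array([1.0]))
    ks = np.arange(1, n1 + 1)
    logs = _log_stirling_row(n1)[1:] + ks * math.log(theta1)
    logs = logs - log_rising(theta1, n1)
    # the identity theta^(n) = sum_k |S(n,k)| theta^k makes this exact;
    # renormalize in log space to absorb float rounding
    logs = logs - logsumexp(logs)
    return LatentDistribution(n1, theta1, ks, np.exp(logs))


def two_allele_sampling_pmf(
    n: int, model: MutationModel, condition_polymorphic: bool = False
) -> np.ndarray:
    """Equilibrium sampling pmf of the count ``n1`` of allele 1 when K=2.

    ``p(n1; n) = C(n, n1) (t1)^(n1) (t2)^(n-n1) / theta^(n)`` with
    ``t_i = theta * pi_i``.  If ``condition_polymorphic``, renormalized over
    ``n1 in {1..n-1}`` (entries 0 and n set to 0).
    """
    if model.K != 2:
        raise ValueError("two_allele_sampling_pmf requires K=2")
    if n < 1:
        raise ValueError("n must be >= 1")
    t1, t2 = model.thetas
    n1 = np.arange(n + 1)
    logp = (
        gammaln(n + 1)
        - gammaln(n1 + 1)
        - gammaln(n - n1 + 1)
        + log_rising(t1, n1)
        + log_rising(t2, n - n1)
        - log_rising(model.theta, n)
    )
    p = np.exp(logp)
    if condition_polymorphic:
        p[0] = 0.0
        p[n] = 0.0
        p /= p.sum()
    return p


def k_allele_ordered_prob(counts: SampleCounts, model: MutationModel) -> float:
    """Probability of an ordered sample with the given allele counts.

    ``p_o(n_1..n_K) = prod_i (theta pi_i)^(n_i) / theta^(n)``.
    """
    if len(counts.counts) != model.K:
        raise ValueError(
            f"counts have K={len(counts.counts)} but model has K={model.K}"
        )
    ni = np.asarray(counts.counts, dtype=float)
    logp = float(
        np.sum(log_rising_vec(model.thetas, ni)) - log_rising(model.theta, counts.n)
    )
    return math.exp(logp)


def log_rising_vec(xs: np.ndarray, ms: np.ndarray) -> np.ndarray:
    return gammaln(np.asarray(xs) + np.asarray(ms, dtype=float)) - gammaln(
        np.asarray(xs)
    )


def k_allele_unordered_prob(counts: SampleCounts, model: MutationModel) -> float:
    """Unordered sampling probability: ordered times the multinomial coefficient."""
    ni = np.asarray(counts.counts, dtype=float)
    log_multi = gammaln(counts.n + 1) - np.sum(gammaln(ni + 1))
    return math.exp(log_multi) * k_allele_ordered_prob(counts, model)


# ---------------------------------------------------------------------------
# Large-n asymptotics and the augmented (root-conditioned) model
# ---------------------------------------------------------------------------

def large_n_sampling_approx(n1: int, n: int, model: MutationModel) -> float:
    """Leading large-``n`` term of the two-allele sampling probability.

    ``p(n1; n) ~ (t1)^(n1)/n1! * exp(-t1 log n) * Gamma(theta)/Gamma(t2)``.
    The factor ``exp(-t1 log n)`` is (approximately) the probability of no
    extra type-1 mutations on the rest of the genealogy; the ratio to the
    exact pmf tends to 1 as ``n`` grows.
    """
    if model.K != 2:
        raise ValueError("large_n_sampling_approx requires K=2")
    t1, t2 = model.thetas
    logp = (
        float(log_rising(t1, n1))
        - gammaln(n1 + 1)
        - t1 * math.log(n)
        + gammaln(model.theta)
        - gammaln(t2)
    )
    return math.exp(logp)


def _harmonic_range(lo: int, hi: int) -> float:
    """sum_{i=lo}^{hi} 1/i, stable for large ranges (digamma difference)."""
    from scipy.special import digamma

    if hi < lo:
        return 0.0
    return float(digamma(hi + 1) - digamma(lo))


def augmented_root_model(r: int, n1: int, n: int, model: MutationModel) -> float:
    """Root-conditioned independent-Poissons probability of ``n1`` copies.

    Conditions on all ``r`` ancestral lineages being the common type at the
    first time there were ``r`` of them, then applies the Poisson model to
    the more recent part of the genealogy (coalescent intervals ``r+1..n``):

    ``[Gamma(theta)Gamma(t2+r) / (Gamma(t2)Gamma(theta+r))] *
    (t1)^(n1)/n1! * exp(-t1 * sum_{i=r}^{n-1} 1/i)``.

    With ``r = 1`` this is ``pi_2`` times the plain constant-size Poisson
    form of the count distribution.
    """
    if model.K != 2:
        raise ValueError("augmented_root_model requires K=2")
    if not 1 <= r < n:
        raise ValueError(f"require 1 <= r < n, got r={r}, n={n}")
    t1, t2 = model.thetas
    logp = (
        gammaln(model.theta)
        + gammaln(t2 + r)
        - gammaln(t2)
        - gammaln(model.theta + r)
        + float(log_rising(t1, n1))
        - gammaln(n1 + 1)
        - t1 * _harmonic_range(r, n - 1)
    )
    return math.exp(logp)


def augmented_error(r: int, model: MutationModel) -> float:
    """Limiting ratio of the exact sampling pmf to the augmented model.

    ``Gamma(theta+r)/Gamma(t2+r) * exp(-t1 (H_{r-1} - gamma))`` where
    ``gamma`` is Euler's constant; equals 1 + O(theta^2) and approaches 1 as
    ``r`` grows (conditioning deeper in the tree leaves less room for
    unmodeled ancient mutation).
    """
    if model.K != 2:
        raise ValueError("augmented_error requires K=2")
    if r < 1:
        raise ValueError("r must be >= 1")
    t1, t2 = model.thetas
    return math.exp(
        gammaln(model.theta + r)
        - gammaln(t2 + r)
        - t1 * (_harmonic_range(1, r - 1) - EULER_GAMMA)
    )


def augmented_error_coefficient(r: int, pi1: float) -> float:
    """Coefficient of ``theta^2`` in the small-theta expansion of the error.

    Equals ``(2 - pi1) pi1 / 2 * psi'(r)`` where ``psi'`` is the trigamma
    function, ``psi'(r) = pi^2/6 - sum_{j=1}^{r-1} 1/j^2``.  The rapid decay
    of the trigamma in ``r`` is why conditioning on even two root lineages
    (r=2) removes about 60% of the r=1 error.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    return float((2.0 - pi1) * pi1 / 2.0 * polygamma(1, r))
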