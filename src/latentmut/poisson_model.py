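"""Independent-Poissons model of latent mutations on general coalescent trees.

For a rare variant in a very large sample, the numbers ``a_i`` of latent
mutations whose descendants number ``i = 1, 2, ...`` in the sample are
independent Poisson random variables with means ``(theta1/2) * tau_bar_i``,
where ``tau_bar_i`` is the expected total length of genealogy branches with
``i`` descendants.  The variant's sample count is ``n1 = sum i * a_i`` and
its number of latent mutations is ``k1 = sum a_i``.  This holds for any
genealogy with finite expected height — constant size, growth, or an
arbitrary supplied branch-length spectrum — and reduces exactly to the
Ewens-type results when ``tau_bar_i = 2/i``.

The joint law of ``(n1, k1)`` factorizes: ``k1`` is Poisson with mean equal
to the expected number of mutations per site on the genealogy (the
"mutrate"), and given ``k1`` the count ``n1`` is the sum of ``k1`` iid draws
from the relative branch-length distribution — evaluated here by iterated
discrete convolution rather than explicit composition sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ewens import latent_mutation_pmf

__all__ = [
    "BranchLengthSpectrum",
    "RareVariantModel",
    "JointCountMutationPMF",
    "poisson_latent_counts",
    "count_given_k",
    "joint_pmf",
    "count_marginal",
    "k_given_count",
    "shifted_poisson_k",
]


@dataclass(frozen=True)
class BranchLengthSpectrum:
    """Expected branch lengths ``tau_bar_i`` for ``i = 1..b``.

    Parameters
    ----------
    n
        Sample size the spectrum refers to.
    tau_bar
        ``tau_bar[i-1] = E[tau_i]``, expected total length of branches with
        ``i`` descendants, in coalescent time units (or relative units).
    total_sum
        ``sum_{i=1}^{n-1} E[tau_i]`` over the FULL range, which may exceed
        the sum of the stored prefix.  Only this total (not individual
        ``tau_bar_i`` beyond ``b``) enters any downstream formula.
    is_relative
        If True, stored values are ``tau_bar_i / sum tau_bar`` and
        ``total_sum == 1``.
    """

    n: int
    tau_bar: np.ndarray
    total_sum: float
    is_relative: bool = False

    def __post_init__(self) -> None:
        tb = np.asarray(self.tau_bar, dtype=float)
        if np.any(tb < 0):
            raise ValueError("tau_bar entries must be >= 0")
        prefix = float(tb.sum())
        if self.total_sum < prefix - 1e-9 * max(prefix, 1.0):
            raise ValueError(
                f"total_sum {self.total_sum} smaller than stored prefix {prefix}"
            )
        object.__setattr__(self, "tau_bar", tb)

    @property
    def b(self) -> int:
        return len(self.tau_bar)

    @classmethod
    def constant_size(cls, n: int, b: int) -> "BranchLengthSpectrum":
        """Standard neutral coalescent: ``tau_bar_i = 2/i``; total ``2 H_{n-1}``."""
        i = np.arange(1, b + 1)
        from scipy.special import digamma

        total = 2.0 * float(digamma(n) + np.euler_gamma)
        return cls(n=n, tau_bar=2.0 / i, total_sum=total)

    def relative(self) -> "BranchLengthSpectrum":
        """Normalize to relative branch lengths (total_sum = 1)."""
        if self.is_relative:
            return self
        return BranchLengthSpectrum(
            n=self.n,
            tau_bar=self.tau_bar / self.total_sum,
            total_sum=1.0,
            is_relative=True,
        )

    def weights(self) -> np.ndarray:
        """Relative branch lengths ``tau_bar_i / sum tau_bar`` for i = 1..b."""
        return self.tau_bar / self.total_sum


@dataclass(frozen=True)
class RareVariantModel:
    """Independent-Poissons model for one rare variant.

    ``mutrate = (theta1 / 2) * sum tau_bar`` is the expected number of latent
    mutations per site on the genealogy; ``b`` caps the modeled variant count
    and ``kmax`` the modeled number of mutations (tail mass is reported, not
    dropped).
    """

    tau: BranchLengthSpectrum
    mutrate: float
    b: int = 40
    kmax: int = 7

    def __post_init__(self) -> None:
        if self.mutrate <= 0:
            raise ValueError("mutrate must be > 0")
        if self.kmax < 1 or self.b < 1:
            raise ValueError("kmax and b must be >= 1")
        if self.b > self.tau.b:
            raise ValueError(
                f"b={self.b} exceeds stored branch-length prefix {self.tau.b}"
            )

    @classmethod
    def from_theta1(
        cls, tau: BranchLengthSpectrum, theta1: float, b: int = 40, kmax: int = 7
    ) -> "RareVariantModel":
        if tau.is_relative:
            raise ValueError("need an absolute spectrum to convert theta1 to mutrate")
        return cls(tau=tau, mutrate=theta1 / 2.0 * tau.total_sum, b=b, kmax=kmax)

    @property
    def theta1(self) -> float:
        """Variant-specific mutation parameter implied by mutrate (absolute tau)."""
        return 2.0 * self.mutrate / self.tau.total_sum


@dataclass(frozen=True)
class JointCountMutationPMF:
    """Joint probability table over (variant count n1, mutation number k1).

    ``table[n1, k1]`` for ``n1 = 0..b``, ``k1 = 0..kmax``; entries are zero
    unless ``n1 >= k1 >= 1`` or ``n1 = k1 = 0``.  ``truncation_mass`` is the
    probability excluded by the ``b`` and ``kmax`` truncations, so the table
    plus the truncation mass sums to one.
    """

    table: np.ndarray
    b: int
    kmax: int
    mutrate: float
    truncation_mass: float

    def marginal_count(self) -> np.ndarray:
        """p(n1) for n1 = 0..b (not renormalized; excludes truncated mass)."""
        return self.table.sum(axis=1)

    def conditional_count(self) -> np.ndarray:
        """p(n1 | n1 in {1..b}): figure-style conditioning on a rare polymorphism."""
        p = self.table.sum(axis=1)
        p = p.copy()
        p[0] = 0.0
        return p / p.sum()


def poisson_latent_counts(model: RareVariantModel) -> tuple[np.ndarray, float]:
    """Truncated Poisson pmf of the number of latent mutations ``k1``.

    Returns ``(pmf over k1 = 0..kmax, tail mass P(k1 > kmax))``.
    """
    k = np.arange(model.kmax + 1)
    pmf = stats.poisson.pmf(k, model.mutrate)
    tail = float(stats.poisson.sf(model.kmax, model.mutrate))
    return pmf, tail


def count_given_k(
    tau: BranchLengthSpectrum, k1: int, b: int | None = None
) -> np.ndarray:
    """pmf of the variant count ``n1`` given ``k1`` latent mutations.

    Given ``k1`` mutations, ``n1`` is the sum of ``k1`` independent draws
    from the relative branch-length distribution ``tau_bar_i / sum tau_bar``;
    the composition sum over ordered descendant counts is evaluated as a
    ``k1``-fold convolution.  Returns the pmf over ``n1 = 0..b``; mass beyond
    ``b`` (or on branch sizes beyond the stored prefix) is simply absent, so
    the vector sums to <= 1 with equality only when nothing is truncated.

    ``k1 = 0`` is a point mass at ``n1 = 0``; ``k1 = 1`` is the classical
    single-mutation site-frequency spectrum ``tau_bar_{n1} / sum tau_bar``.
    """
    if b is None:
        b = tau.b
    if k1 < 0:
        raise ValueError("k1 must be >= 0")
    out = np.zeros(b + 1)
    if k1 == 0:
        out[0] = 1.0
        return out
    if k1 > b:
        warnings.warn(
            f"k1={k1} > b={b}: n1 = sum of {k1} positive counts cannot be <= {b}",
            stacklevel=2,
        )
        return out
    w = tau.weights()[:b]  # weight of branch size i at index i-1
    # pmf over n1 = 0..b of one mutation's descendant count
    single = np.zeros(b + 1)
    single[1 : b + 1] = w
    acc = single
    for _ in range(k1 - 1):
        acc = np.convolve(acc, single)[: b + 1]
    out[: len(acc)] = acc
    return out


def joint_pmf(model: RareVariantModel) -> JointCountMutationPMF:
    """Joint pmf of (n1, k1) under the independent-Poissons model.

    ``p(n1, k1) = Poisson(k1; mutrate) * p(n1 | k1)``.
    """
    pk, k_tail = poisson_latent_counts(model)
    table = np.zeros((model.b + 1, model.kmax + 1))
    for k1 in range(model.kmax + 1):
        if k1 > model.b:
            break
        table[:, k1] = pk[k1] * count_given_k(model.tau, k1, model.b)
    trunc = 1.0 - float(table.sum())
    return JointCountMutationPMF(
        table=table,
        b=model.b,
        kmax=model.kmax,
        mutrate=model.mutrate,
        truncation_mass=trunc,
    )


def count_marginal(model: RareVariantModel) -> np.ndarray:
    """Marginal pmf of the variant count, p(n1) for n1 = 0..b."""
    return joint_pmf(model).marginal_count()


def k_given_count(model: RareVariantModel, n1: int) -> np.ndarray:
    """Posterior pmf of the number of latent mutations given the count ``n1``.

    Column-normalized joint over ``k1 = 0..kmax``.  For the constant-size
    spectrum ``tau_bar_i = 2/i`` this coincides with the Ewens
    number-of-alleles distribution (``latent_mutation_pmf``).
    """
    if not 0 <= n1 <= model.b:
        raise ValueError(f"n1 must be in 0..{model.b}")
    row = joint_pmf(model).table[n1]
    tot = row.sum()
    if tot <= 0:
        raise ValueError(f"n1={n1} has zero probability under kmax={model.kmax}")
    return row / tot


def shifted_poisson_k(mutrate: float, kmax: int = 7) -> np.ndarray:
    """Large-count limit of the number of latent mutations.

    For a variant observed in many copies, ``k1 - 1`` is approximately
    Poisson with mean ``mutrate``; returns the pmf over ``k1 = 0..kmax``
    (zero at ``k1 = 0``).
    """
    if mutrate <= 0:
        raise ValueError("mutrate must be > 0")
    k = np.arange(kmax + 1)
    pmf = np.zeros(kmax + 1)
    pmf[1:] = stats.poisson.pmf(k[1:] - 1, mutrate)
    return pmf


def constant_size_reference(
    theta1: float, n: int, n1: int
) -> np.ndarray:
    """Ewens-form posterior of k1 given n1 for tau_bar_i = 2/i (cross-check).

    Thin wrapper re-exposing the exact constant-size result on the same
    support layout (k1 = 0..n1) as ``k_given_count``.
    """
    dist = latent_mutation_pmf(n1, theta1)
    out = np.zeros(n1 + 1)
    out[dist.support] = dist.pmf
    return out
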