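"""Monte-Carlo simulation of the conditional ancestral process.

Tracing a sample conditioned on its allele counts backward in time, each
lineage of allele ``i`` is followed only to its first mutation.  Per ancestral
event the involved allele is chosen with probability ``n_i / n``; the event is
a mutation with probability ``theta pi_i / (theta pi_i + n_i - 1)`` and a
coalescence otherwise, and either way ``n_i`` decreases by one.  The number of
mutations accumulated for allele ``i`` is therefore a sum of ``n_i`` Bernoulli
variables with success probabilities ``theta pi_i / (theta pi_i + j - 1)``,
``j = n_i .. 1`` — the Ewens number-of-alleles law — independently across
alleles.  These simulators provide an independent oracle for the analytic
latent-mutation distributions.

The large-sample variant additionally models the common allele's lineage
count (which decays by coalescence at total rate ~ nK^2/2 between the rare
allele's events) and the waiting times to those events; empty mutations
(common type to itself) are not counted, matching the large-n process in
which they vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, polygamma

from .ewens import MutationModel, SampleCounts

__all__ = [
    "SimulationConfig",
    "AncestryRealization",
    "LargeNResult",
    "simulate_exact",
    "simulate_large_n",
    "trace_realization",
    "expected_first_event_time",
    "expected_common_lineages",
]


@dataclass(frozen=True)
class SimulationConfig:
    reps: int
    seed: int
    variant: str = "exact"  # "exact" | "large_n"

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.variant not in ("exact", "large_n"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class AncestryRealization:
    """Single traced realization: ordered events and per-allele mutation counts.

    ``events`` is a list of ``(allele_index, kind, order)`` with kind in
    {"mutation", "coalescence", "common-lump"}.
    """

    events: list[tuple[int, str, int]]
    k_counts: np.ndarray
    rng_seed: int


@dataclass
class LargeNResult:
    """Output of the large-n conditional ancestral process simulator."""

    k1: np.ndarray  # (reps,) latent mutation counts of the rare allele
    common_lineages: np.ndarray | None  # (reps, n1) N2 at each rare event
    event_times: np.ndarray | None  # (reps, n1) times of rare events

    def k1_pmf(self) -> dict[int, float]:
        vals, counts = np.unique(self.k1, return_counts=True)
        return {int(v): float(c) / len(self.k1) for v, c in zip(vals, counts)}


def _bernoulli_chain_counts(
    ni: int, theta_i: float, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized draw of the latent-mutation count for one allele.

    Sum of ni Bernoullis with success probs theta/(theta+j-1), j = ni..1.
    """
    k = np.zeros(reps, dtype=np.int64)
    for j in range(ni, 0, -1):
        p = theta_i / (theta_i + j - 1.0)
        k += rng.random(reps) < p
    return k


def simulate_exact(
    counts: SampleCounts, model: MutationModel, config: SimulationConfig
) -> np.ndarray:
    """Empirical latent-mutation counts under the exact conditional process.

    Returns an array of shape (reps, K): per repetition, the number of latent
    mutations of each allele.  The order in which alleles' events interleave
    does not affect the counts, so each allele's mutation/coalescence chain
    is drawn independently (from a per-allele substream of the seeded
    generator), exactly as the conditional ancestral process prescribes.
    """
    if len(counts.counts) != model.K:
        raise ValueError("counts/model dimension mismatch")
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(model.K)
    out = np.empty((config.reps, model.K), dtype=np.int64)
    for i, (ni, ss) in enumerate(zip(counts.counts, streams)):
        rng = np.random.default_rng(ss)
        theta_i = model.theta * model.pis[i]
        out[:, i] = _bernoulli_chain_counts(ni, theta_i, config.reps, rng)
    return out


def trace_realization(
    counts: SampleCounts, model: MutationModel, seed: int
) -> AncestryRealization:
    """Trace one full event-ordered realization of the conditional process."""
    rng = np.random.default_rng(seed)
    ni = np.array(counts.counts, dtype=np.int64)
    thetas = model.thetas
    k = np.zeros(model.K, dtype=np.int64)
    events: list[tuple[int, str, int]] = []
    order = 0
    while ni.sum() > 0:
        n = ni.sum()
        i = rng.choice(model.K, p=ni / n)
        p_mut = thetas[i] / (thetas[i] + ni[i] - 1.0)
        if rng.random() < p_mut:
            k[i] += 1
            events.append((i, "mutation", order))
        else:
            events.append((i, "coalescence", order))
        ni[i] -= 1
        order += 1
    return AncestryRealization(events=events, k_counts=k, rng_seed=seed)


def _log_falling(m: np.ndarray, j: np.ndarray) -> np.ndarray:
    """log of m! / (m - j)! = m (m-1) ... (m-j+1)."""
    return gammaln(m + 1.0) - gammaln(m - j + 1.0)


def _sample_common_decrements(
    m: np.ndarray, a: int, rng: np.random.Generator
) -> np.ndarray:
    """Number of common-allele events before the next rare-allele event.

    With ``a`` rare and ``m`` common lineages, each event involves the rare
    allele with probability ``a / m_cur`` and otherwise decrements the common
    count.  The survival function of the decrement count j is
    ``S(j) = prod_{l=0}^{j-1} (1 - a / (m - l))``, sampled by inverting a
    uniform with a vectorized binary search (log-gamma evaluation of S).
    """
    u = rng.random(len(m))
    lo = np.zeros(len(m), dtype=np.int64)
    hi = (m - a).astype(np.int64)  # S(m - a + ...) = 0: rare event forced

    def log_surv(j: np.ndarray) -> np.ndarray:
        # S(j) = [ (m-a)! / (m-j-a)! ] / [ m! / (m-j)! ]
        return _log_falling(m - a, j.astype(float)) - _log_falling(
            m.astype(float), j.astype(float)
        )

    # smallest j such that S(j + 1) <= u  (i.e. rare event at step j + 1)
    while np.any(lo < hi):
        mid = (lo + hi) // 2
        s = np.exp(log_surv(mid + 1))
        take_hi = s <= u
        hi = np.where(take_hi, mid, hi)
        lo = np.where(take_hi, lo, mid + 1)
    return lo


def simulate_large_n(
    n1: int,
    nK: int,
    theta1: float,
    config: SimulationConfig,
    record_lineages: bool = False,
    record_times: bool = False,
) -> LargeNResult:
    """Large-sample conditional ancestral process for one rare allele.

    Simulates the three-jump process (rare mutation, rare coalescence,
    common-lineage decrement) for a rare allele in ``n1`` copies against
    ``nK`` copies of the common allele, with mutation parameter
    ``theta1 = theta * pi_1``.  Empty mutations are absent by construction.

    With ``record_lineages``, stores the number of common-allele ancestral
    lineages remaining at each of the ``n1`` rare-allele events; with
    ``record_times``, additionally draws the exponential waiting times
    (instantaneous total rate ``m^2 / 2`` at ``m`` common lineages) and
    stores the cumulative time of each rare event.
    """
    if nK <= n1:
        raise ValueError(f"need nK >> n1, got nK={nK} <= n1={n1}")
    if n1 < 1:
        raise ValueError("n1 must be >= 1")
    rng = np.random.default_rng(config.seed)
    reps = config.reps

    k1 = np.zeros(reps, dtype=np.int64)
    lineages = (
        np.empty((reps, n1), dtype=np.int64) if (record_lineages or record_times) else None
    )

    m = np.full(reps, nK, dtype=np.int64)
    for stage in range(n1):
        a = n1 - stage  # current rare-lineage count, same across reps
        j = _sample_common_decrements(m, a, rng)
        m = m - j
        if lineages is not None:
            lineages[:, stage] = m
        is_mut = rng.random(reps) < theta1 / (theta1 + a - 1.0)
        k1 += is_mut
        # a rare mutation turns the lineage into the common type
        m = m + is_mut

    times = None
    if record_times:
        times = _event_times(lineages, nK, rng)

    return LargeNResult(
        k1=k1,
        common_lineages=lineages if record_lineages else None,
        event_times=times,
    )


def _event_times(
    lineages: np.ndarray, nK: int, rng: np.random.Generator, chunk: int = 256
) -> np.ndarray:
    """Cumulative times of rare events given common-lineage counts at them.

    Each step of the common-lineage count from ``m`` costs an exponential
    waiting time with rate ``m^2 / 2``; the time of the i-th rare event is
    the sum of the waits down to the recorded lineage count.  Drawn in
    chunks to bound memory.
    """
    reps, n1 = lineages.shape
    m_grid = np.arange(nK, 0, -1)  # waiting occurs at counts nK, nK-1, ...
    scale = 2.0 / (m_grid.astype(float) ** 2)
    out = np.empty((reps, n1))
    for start in range(0, reps, chunk):
        stop = min(start + chunk, reps)
        waits = rng.exponential(scale=scale, size=(stop - start, nK))
        cum = np.cumsum(waits, axis=1)  # cum[:, idx] = time to reach count nK-idx-1
        for i in range(n1):
            # waits elapsed at counts nK down to the recorded count inclusive
            idx = nK - lineages[start:stop, i] + 1
            idx = np.clip(idx, 1, nK)
            out[start:stop, i] = cum[np.arange(stop - start), idx - 1]
    return out


def expected_first_event_time(n1: int, n2: int) -> float:
    """Closed-form mean time to the first rare-allele event.

    ``~ 2 log(n2) / n2`` for a singleton and ``~ 2 / (n2 (n1 - 1))``
    otherwise; vanishes as the common count grows.
    """
    if n1 < 1 or n2 <= n1:
        raise ValueError("require n2 > n1 >= 1")
    if n1 == 1:
        return 2.0 * np.log(n2) / n2
    return 2.0 / (n2 * (n1 - 1.0))


def expected_common_lineages(n1: int, i: int, n2: int) -> float:
    """Expected common-allele lineages remaining at the i-th rare event.

    ``E[N2(T_i)] ~ n2 (n1 - i + 1) / (n1 + 1)``: even at the last
    (``i = n1``-th) event a fraction ``1/(n1+1)`` of the common lineages
    remains, which is what licenses the large-n approximation throughout
    the rare allele's ancestry.
    """
    if not 1 <= i <= n1:
        raise ValueError(f"require 1 <= i <= n1, got i={i}, n1={n1}")
    return n2 * (n1 - i + 1.0) / (n1 + 1.0)
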