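"""Synthetic binned site-frequency data with the model's exact structure.

Each site independently draws latent-mutation counts ``a_i ~ Poisson(mutrate
* rel_tau_i)`` for descendant-count classes ``i = 1..b`` (plus a lumped
remainder class for branch sizes beyond ``b``); the site's variant count is
``sum i * a_i``.  The generator samples these Poissons directly — never
trees — so that a pipeline failure on generated data isolates a pipeline
bug rather than model misspecification.  True per-site mutation numbers can
be emitted as a clearly non-observable side channel for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import growth_tau_spectrum
from .pipeline import BinnedDataset, SFSBin
from .poisson_model import BranchLengthSpectrum

__all__ = ["GeneratorSpec", "generate_dataset", "make_realistic_spec"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Specification of a synthetic binned dataset.

    ``bins`` is a list of ``(bin_id, L, mutrate)``; ``rel_tau`` holds the
    relative branch lengths for counts ``1..b`` and may sum to less than one,
    the remainder being branch sizes above ``b`` (sites hit there leave the
    modeled range).  ``kmax_sim`` caps only the width of the emitted truth
    table; the Poisson draws themselves are untruncated.
    """

    bins: tuple[tuple[str, int, float], ...]
    rel_tau: np.ndarray
    seed: int
    kmax_sim: int = 12

    def __post_init__(self) -> None:
        rt = np.asarray(self.rel_tau, dtype=float)
        if np.any(rt < 0):
            raise ValueError("rel_tau must be nonnegative")
        if rt.sum() > 1.0 + 1e-9:
            raise ValueError("rel_tau must sum to <= 1")
        if self.kmax_sim < 12:
            raise ValueError("kmax_sim must be >= 12")
        for bid, L, m in self.bins:
            if L < 1:
                raise ValueError(f"bin {bid}: L must be >= 1")
            if m < 0:
                raise ValueError(f"bin {bid}: mutrate must be >= 0")
        object.__setattr__(self, "rel_tau", rt)
        object.__setattr__(
            self, "bins", tuple((str(b), int(L), float(m)) for b, L, m in self.bins)
        )

    @property
    def b(self) -> int:
        return len(self.rel_tau)


def _simulate_bin(
    L: int,
    mutrate: float,
    rel_tau: np.ndarray,
    rng: np.random.Generator,
    kmax_sim: int,
    chunk: int = 200_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin site counts S_0..S_b and the true (n1, k1) joint histogram.

    Returns ``(S, truth)`` where ``truth[n1, k]`` counts sites with modeled
    variant count ``n1`` and ``k`` latent mutations (k capped at kmax_sim;
    remainder-class sites excluded from both).
    """
    b = len(rel_tau)
    rates = mutrate * rel_tau
    rate_rem = mutrate * max(0.0, 1.0 - float(rel_tau.sum()))
    i_vec = np.arange(1, b + 1)
    S = np.zeros(b + 1, dtype=np.int64)
    truth = np.zeros((b + 1, kmax_sim + 1), dtype=np.int64)
    done = 0
    while done < L:
        m = min(chunk, L - done)
        A = rng.poisson(lam=rates, size=(m, b))
        n1 = A @ i_vec
        k = A.sum(axis=1)
        if rate_rem > 0:
            a_rem = rng.poisson(lam=rate_rem, size=m)
            in_range = (n1 <= b) & (a_rem == 0)
        else:
            in_range = n1 <= b
        vals, cnts = np.unique(n1[in_range], return_counts=True)
        S[vals] += cnts
        kk = np.minimum(k[in_range], kmax_sim)
        np.add.at(truth, (n1[in_range], kk), 1)
        done += m
    return S, truth


def generate_dataset(
    spec: GeneratorSpec, emit_truth: bool = False
) -> BinnedDataset | tuple[BinnedDataset, dict[str, np.ndarray]]:
    """Draw a synthetic binned dataset; deterministic given the spec's seed.

    With ``emit_truth``, also returns per-bin joint histograms of the true
    variant count and latent mutation number — information an observer of
    real data would not have.
    """
    rng = np.random.default_rng(spec.seed)
    bins = []
    truths: dict[str, np.ndarray] = {}
    for bid, L, mutrate in spec.bins:
        if mutrate == 0.0:
            S = np.zeros(spec.b + 1, dtype=np.int64)
            S[0] = L
            truth = np.zeros((spec.b + 1, spec.kmax_sim + 1), dtype=np.int64)
            truth[0, 0] = L
        else:
            S, truth = _simulate_bin(L, mutrate, spec.rel_tau, rng, spec.kmax_sim)
        bins.append(SFSBin(bin_id=bid, L=L, S=S))
        truths[bid] = truth
    ds = BinnedDataset(bins=bins, b=spec.b, source="latentmut.simulate")
    if emit_truth:
        return ds, truths
    return ds


def write_truth_tsv(truths: dict[str, np.ndarray], path) -> None:
    """Write true (n1, k) joint histograms; non-observable oracle data."""
    rows = []
    for bid, t in truths.items():
        n1s, ks = np.nonzero(t)
        for n1, k in zip(n1s, ks):
            rows.append(
                {"bin_id": bid, "allele_count": int(n1), "k_true": int(k), "n_sites": int(t[n1, k])}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def make_realistic_spec(
    style: str,
    n: int,
    mutrate_grid: np.ndarray,
    L_grid: np.ndarray,
    seed: int,
    beta: float | None = None,
    b: int = 40,
) -> GeneratorSpec:
    """Convenience spec mirroring real binned data: many low-rate bins with
    most of the sites, a thinning tail of fast-mutating bins.

    ``style`` is "constant" (``tau_bar_i = 2/i``) or "growth" (exponential
    growth with parameter ``beta``); relative branch lengths are normalized
    against the analytic total tree length, so the stored prefix sums to
    less than one and the rest is the explicit above-``b`` remainder.
    """
    mutrate_grid = np.asarray(mutrate_grid, dtype=float)
    L_grid = np.asarray(L_grid)
    if len(mutrate_grid) != len(L_grid):
        raise ValueError("mutrate_grid and L_grid must have equal length")
    if style == "constant":
        tau = BranchLengthSpectrum.constant_size(n, b)
    elif style == "growth":
        if beta is None:
            raise ValueError("growth style requires beta")
        tau = growth_tau_spectrum(n, beta, b)
    else:
        raise ValueError(f"unknown style {style!r}")
    rel = tau.weights()
    bins = tuple(
        (f"bin{j + 1:03d}", int(L), float(m))
        for j, (L, m) in enumerate(zip(L_grid, mutrate_grid))
    )
    return GeneratorSpec(bins=bins, rel_tau=rel, seed=seed)
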