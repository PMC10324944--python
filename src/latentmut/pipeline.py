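"""Empirical fitting of mutation-rate-binned site-frequency spectra.

Sites are presorted into bins by mutation rate; within a bin each site is
treated as having the same rate.  The fitting procedure is deliberately
simple and fully empirical:

1. Per bin, estimate the expected number of latent mutations per site
   ("mutrate") from the monomorphic fraction as ``-log(S0 / L)`` — the
   inverse of the Poisson zero class.
2. Pool the lowest-rate bins, where nearly every polymorphism reflects a
   single mutation, to estimate the relative branch lengths directly as
   ``S_i / (L - S0)``; assume these hold for all bins.
3. Per bin, combine the Poisson mutation-number distribution with the
   convolution count distribution to produce recurrence-corrected expected
   counts ``E[S_i] = L * P(N1 = i)``, posterior latent-mutation tables, and
   an infinite-sites comparison quantifying the singleton deficit at
   fast-mutating sites.

No demographic model is fitted; whatever shaped the branch lengths (growth,
structure, ...) is absorbed into the empirical relative spectrum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .poisson_model import (
    BranchLengthSpectrum,
    RareVariantModel,
    count_given_k,
    joint_pmf,
    k_given_count,
    shifted_poisson_k,
)

__all__ = [
    "SFSBin",
    "BinnedDataset",
    "FitResult",
    "estimate_mutrate",
    "estimate_rel_tau",
    "expected_counts",
    "group_small_cells",
    "infinite_sites_comparison",
    "posterior_k_table",
    "fit_dataset",
    "read_binned_tsv",
    "write_binned_tsv",
]


@dataclass(frozen=True)
class SFSBin:
    """Binned site-frequency data: counts of sites by rare-variant count.

    ``S[i]`` is the number of sites where the variant is observed in ``i``
    copies (``S[0]`` = monomorphic sites); sites with counts above ``b``
    are inside ``L`` but not in ``S``, forming an unmodeled remainder.
    Each rare variant at a site is an independent record, so multi-allelic
    sites contribute once per rare variant.
    """

    bin_id: str
    L: int
    S: np.ndarray
    n_nominal: int | None = None

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=np.int64)
        if np.any(S < 0):
            raise ValueError("site counts must be nonnegative")
        if S.sum() > self.L:
            raise ValueError(
                f"bin {self.bin_id}: sum(S)={S.sum()} exceeds L={self.L}"
            )
        object.__setattr__(self, "S", S)

    @property
    def b(self) -> int:
        return len(self.S) - 1

    @property
    def S0(self) -> int:
        return int(self.S[0])

    @property
    def n_polymorphic(self) -> int:
        """Polymorphic sites among those with modeled counts (1..b)."""
        return int(self.S[1:].sum())

    @property
    def remainder(self) -> int:
        """Sites with variant count above b (in L, outside S)."""
        return int(self.L - self.S.sum())


@dataclass
class BinnedDataset:
    bins: list[SFSBin]
    b: int
    n: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        ids = [bn.bin_id for bn in self.bins]
        if len(set(ids)) != len(ids):
            raise ValueError("bin_ids must be unique")
        for bn in self.bins:
            if bn.b != self.b:
                raise ValueError(f"bin {bn.bin_id} has b={bn.b}, expected {self.b}")

    def __iter__(self):
        return iter(self.bins)

    def __len__(self) -> int:
        return len(self.bins)

    def get(self, bin_id: str) -> SFSBin:
        for bn in self.bins:
            if bn.bin_id == bin_id:
                return bn
        raise KeyError(bin_id)


@dataclass
class FitResult:
    """Fitted recurrence-aware model for a binned dataset."""

    bin_ids: list[str]
    mutrates: np.ndarray  # per bin
    rel_tau: np.ndarray  # shared, i = 1..b
    low_rate_bins: list[str]
    b: int
    kmax: int
    expected: dict[str, np.ndarray] = field(default_factory=dict)  # E[S_0..S_b]
    posterior_k: dict[str, np.ndarray] = field(default_factory=dict)
    monomorphic_flags: dict[str, bool] = field(default_factory=dict)

    def expected_frame(self, dataset: BinnedDataset) -> pd.DataFrame:
        rows = []
        for bn in dataset:
            exp = self.expected[bn.bin_id]
            for i in range(self.b + 1):
                rows.append(
                    {
                        "bin_id": bn.bin_id,
                        "allele_count": i,
                        "observed": int(bn.S[i]),
                        "expected": float(exp[i]),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def estimate_mutrate(bn: SFSBin) -> float:
    """Expected latent mutations per site from the monomorphic fraction.

    ``mutrate = -log(S0 / L)``: under the independent-Poissons model a site
    is monomorphic exactly when it carries zero latent mutations, so the
    monomorphic fraction estimates the Poisson zero class ``exp(-mutrate)``.
    """
    if bn.S0 == 0:
        raise ValueError(
            f"bin {bn.bin_id}: no monomorphic sites, mutrate unidentifiable"
        )
    if bn.S0 > bn.L:
        raise ValueError(f"bin {bn.bin_id}: S0 > L")
    return float(-np.log(bn.S0 / bn.L))


def mutrate_standard_error(mutrate: float, L: int) -> float:
    """Delta-method s.e. of the mutrate estimator: sqrt((e^m - 1) / L)."""
    return float(np.sqrt((np.exp(mutrate) - 1.0) / L))


def estimate_rel_tau(bins: list[SFSBin], b: int | None = None) -> np.ndarray:
    """Relative branch lengths from pooled low-mutation-rate bins.

    At low rates essentially every polymorphism descends from one mutation,
    so the fraction of polymorphic sites at count ``i`` estimates
    ``tau_bar_i / sum tau_bar`` directly: pooled ``S_i / (L - S0)``.
    """
    if not bins:
        raise ValueError("need at least one bin")
    if b is None:
        b = bins[0].b
    S = np.zeros(b + 1, dtype=np.int64)
    poly = 0
    for bn in bins:
        if bn.b < b:
            raise ValueError(f"bin {bn.bin_id} has b={bn.b} < {b}")
        S += bn.S[: b + 1]
        poly += bn.L - bn.S0
    if poly == 0:
        raise ValueError("no polymorphic sites in the pooled low-rate bins")
    return S[1:] / poly


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

def _variant_model(mutrate: float, rel_tau: np.ndarray, kmax: int) -> RareVariantModel:
    b = len(rel_tau)
    tau = BranchLengthSpectrum(
        n=b + 1, tau_bar=rel_tau, total_sum=1.0, is_relative=True
    )
    return RareVariantModel(tau=tau, mutrate=mutrate, b=b, kmax=kmax)


def expected_counts(
    bn: SFSBin, mutrate: float, rel_tau: np.ndarray, kmax: int = 7
) -> np.ndarray:
    """Recurrence-corrected expected site counts ``E[S_0..S_b] = L p(n1)``."""
    model = _variant_model(mutrate, rel_tau, kmax)
    p = joint_pmf(model).marginal_count()
    return bn.L * p


def group_small_cells(
    expected: np.ndarray, observed: np.ndarray, threshold: float = 1.0
) -> pd.DataFrame:
    """Merge polymorphic count cells with ``E[S_i] < threshold`` into one tail.

    Returns a frame with one row per kept cell (count i >= 1) plus a final
    grouped row; observed counts are merged identically to expected ones.
    """
    rows = []
    tail_exp = 0.0
    tail_obs = 0
    tail_members: list[int] = []
    for i in range(1, len(expected)):
        if expected[i] >= threshold:
            rows.append(
                {"cell": str(i), "observed": int(observed[i]), "expected": float(expected[i])}
            )
        else:
            tail_exp += float(expected[i])
            tail_obs += int(observed[i])
            tail_members.append(i)
    if tail_members:
        rows.append(
            {
                "cell": f"{tail_members[0]}+",
                "observed": tail_obs,
                "expected": tail_exp,
            }
        )
    return pd.DataFrame(rows)


def infinite_sites_comparison(
    mutrate: float, rel_tau: np.ndarray, L: int, kmax: int = 7
) -> pd.DataFrame:
    """Infinite-sites vs recurrence-corrected expected counts per cell.

    The infinite-sites prediction for count ``i`` is linear in the rate,
    ``L * mutrate * rel_tau_i`` — one mutation per polymorphism, no
    saturation — and can exceed ``L`` at high rates (flagged impossible).
    The recurrence prediction comes from the independent-Poissons model.
    """
    b = len(rel_tau)
    rec = expected_counts(SFSBin("is", L, np.zeros(b + 1, dtype=int)), mutrate, rel_tau, kmax)
    i = np.arange(1, b + 1)
    is_pred = L * mutrate * rel_tau
    return pd.DataFrame(
        {
            "allele_count": i,
            "infinite_sites": is_pred,
            "recurrence": rec[1:],
            "deficit": is_pred - rec[1:],
            "impossible": is_pred > L,
        }
    )


def posterior_k_table(
    mutrate: float, rel_tau: np.ndarray, kmax: int = 7
) -> pd.DataFrame:
    """Posterior P(k | i) of the latent mutation number for each count i.

    One row per variant count ``i = 1..b`` with columns ``k=1..kmax`` plus
    the shifted-Poisson large-count reference (``k - 1 ~ Poisson(mutrate)``)
    as the final rows' limiting comparison column set.
    """
    model = _variant_model(mutrate, rel_tau, kmax)
    b = len(rel_tau)
    rows = []
    for i in range(1, b + 1):
        post = k_given_count(model, i)
        row = {"allele_count": i}
        row.update({f"k{k}": float(post[k]) for k in range(1, kmax + 1)})
        rows.append(row)
    ref = shifted_poisson_k(mutrate, kmax)
    rows.append(
        {"allele_count": -1, **{f"k{k}": float(ref[k]) for k in range(1, kmax + 1)}}
    )
    df = pd.DataFrame(rows)
    df["allele_count"] = df["allele_count"].astype(int)
    return df


# ---------------------------------------------------------------------------
# End-to-end fit
# ---------------------------------------------------------------------------

def fit_dataset(
    dataset: BinnedDataset,
    low_rate_bins: list[str] | None = None,
    kmax: int = 7,
    min_polymorphic: int = 100,
    min_pool_polymorphic: int = 100_000,
) -> FitResult:
    """Fit mutrates and a shared relative branch-length spectrum.

    ``low_rate_bins`` names the bins pooled for the relative-branch-length
    estimate; by default the smallest-mutrate bins are accumulated until the
    pool holds at least ``min_pool_polymorphic`` polymorphic sites.  Bins
    with fewer than ``min_polymorphic`` polymorphic sites are excluded from
    the fit output (their mutrate is still reported).
    """
    mutrates = {}
    flags = {}
    for bn in dataset:
        if bn.S0 == bn.L:
            mutrates[bn.bin_id] = 0.0
            flags[bn.bin_id] = True
        else:
            mutrates[bn.bin_id] = estimate_mutrate(bn)
            flags[bn.bin_id] = False

    usable = [bn for bn in dataset if bn.L - bn.S0 >= min_polymorphic]
    if not usable:
        raise ValueError("no bin passes the min_polymorphic filter")

    if low_rate_bins is None:
        ranked = sorted(usable, key=lambda bn: mutrates[bn.bin_id])
        pool: list[SFSBin] = []
        acc = 0
        for bn in ranked:
            pool.append(bn)
            acc += bn.L - bn.S0
            if acc >= min_pool_polymorphic:
                break
        low_rate_bins = [bn.bin_id for bn in pool]
    pool_bins = [dataset.get(bid) for bid in low_rate_bins]
    rel_tau = estimate_rel_tau(pool_bins, dataset.b)

    result = FitResult(
        bin_ids=[bn.bin_id for bn in usable],
        mutrates=np.array([mutrates[bn.bin_id] for bn in usable]),
        rel_tau=rel_tau,
        low_rate_bins=list(low_rate_bins),
        b=dataset.b,
        kmax=kmax,
        monomorphic_flags=flags,
    )
    for bn in usable:
        m = mutrates[bn.bin_id]
        if m <= 0:
            result.expected[bn.bin_id] = np.concatenate(
                [[bn.L], np.zeros(dataset.b)]
            )
            continue
        result.expected[bn.bin_id] = expected_counts(bn, m, rel_tau, kmax)
        result.posterior_k[bn.bin_id] = posterior_k_table(
            m, rel_tau, kmax
        ).to_numpy()
    return result


# ---------------------------------------------------------------------------
# TSV I/O (long format)
# ---------------------------------------------------------------------------

def read_binned_tsv(data_path, meta_path, b: int = 40) -> BinnedDataset:
    """Read a binned dataset from long-format TSVs.

    ``data_path``: columns ``bin_id  allele_count  n_sites`` with
    ``allele_count = 0`` rows carrying monomorphic counts.  ``meta_path``:
    columns ``bin_id  L  n_chromosomes``.  Tab-separated, header row.
    """
    data = pd.read_csv(data_path, sep="\t", dtype={"bin_id": str})
    meta = pd.read_csv(meta_path, sep="\t", dtype={"bin_id": str})
    bins = []
    has_n = "n_chromosomes" in meta.columns
    n_vals = meta["n_chromosomes"].dropna().unique() if has_n else []
    for _, mrow in meta.iterrows():
        bid = mrow["bin_id"]
        sub = data[data["bin_id"] == bid]
        S = np.zeros(b + 1, dtype=np.int64)
        for _, row in sub.iterrows():
            i = int(row["allele_count"])
            if 0 <= i <= b:
                S[i] = int(row["n_sites"])
        n_nom = None
        if has_n and pd.notna(mrow["n_chromosomes"]):
            n_nom = int(mrow["n_chromosomes"])
        bins.append(SFSBin(bin_id=bid, L=int(mrow["L"]), S=S, n_nominal=n_nom))
    n = int(n_vals[0]) if len(n_vals) else None
    return BinnedDataset(bins=bins, b=b, n=n)


def write_binned_tsv(dataset: BinnedDataset, data_path, meta_path) -> None:
    """Write a binned dataset in the long TSV format of ``read_binned_tsv``."""
    rows = []
    meta_rows = []
    for bn in dataset:
        for i in range(bn.b + 1):
            if bn.S[i] > 0 or i == 0:
                rows.append(
                    {"bin_id": bn.bin_id, "allele_count": i, "n_sites": int(bn.S[i])}
                )
        meta_rows.append(
            {
                "bin_id": bn.bin_id,
                "L": bn.L,
                "n_chromosomes": bn.n_nominal if bn.n_nominal is not None else dataset.n,
            }
        )
    pd.DataFrame(rows).to_csv(data_path, sep="\t", index=False)
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)


def write_fit_result(
    result: FitResult, dataset: BinnedDataset, out_dir, manifest: dict | None = None
) -> None:
    """Write a FitResult as TSVs plus a JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"bin_id": result.bin_ids, "mutrate": result.mutrates}
    ).to_csv(out / "mutrates.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"i": np.arange(1, result.b + 1), "rel_tau": result.rel_tau}
    ).to_csv(out / "rel_tau.tsv", sep="\t", index=False)
    result.expected_frame(dataset).to_csv(
        out / "expected_vs_observed.tsv", sep="\t", index=False
    )
    for bid in result.bin_ids:
        if bid in result.posterior_k:
            df = pd.DataFrame(
                result.posterior_k[bid],
                columns=["allele_count"] + [f"k{k}" for k in range(1, result.kmax + 1)],
            )
            df.to_csv(out / f"posterior_k_{bid}.tsv", sep="\t", index=False)
    payload = {
        "low_rate_bins": result.low_rate_bins,
        "b": result.b,
        "kmax": result.kmax,
        "n_bins": len(result.bin_ids),
    }
    if manifest:
        payload.update(manifest)
    (out / "manifest.json").write_text(json.dumps(payload, indent=2))
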