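"""TSV readers/writers for branch-length spectra."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .poisson_model import BranchLengthSpectrum

__all__ = ["read_tau_tsv", "write_tau_tsv"]


def read_tau_tsv(path, n: int | None = None) -> BranchLengthSpectrum:
    """Read a branch-length spectrum TSV.

    Two tab-separated columns ``i`` and ``tau_bar`` with a header row; an
    optional leading metadata line ``# total_sum=<float>`` supplies the full
    ``sum_{i=1}^{n-1} tau_bar_i`` when it exceeds the stored prefix.
    """
    path = Path(path)
    total = None
    with path.open() as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        for token in first.lstrip("#").split():
            if token.startswith("total_sum="):
                total = float(token.split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    df = df.sort_values("i")
    idx = df["i"].to_numpy()
    if not (idx == range(1, len(idx) + 1)).all():
        raise ValueError("tau TSV must list consecutive i = 1..b")
    tau = df["tau_bar"].to_numpy(dtype=float)
    if total is None:
        total = float(tau.sum())
    is_rel = abs(total - 1.0) < 1e-12
    return BranchLengthSpectrum(
        n=n if n is not None else len(tau) + 1,
        tau_bar=tau,
        total_sum=total,
        is_relative=is_rel,
    )


def write_tau_tsv(tau: BranchLengthSpectrum, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# total_sum={float(tau.total_sum)!r}\n")
        fh.write("i\ttau_bar\n")
        for i, t in enumerate(tau.tau_bar, start=1):
            fh.write(f"{i}\t{float(t)!r}\n")
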