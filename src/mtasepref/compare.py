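"""Comparison of preference profiles across replicates and enzyme variants.

Two standard summaries: the Pearson correlation of two flattened o/e profiles
(position x base) and their root-mean-square deviation (RMSD), plus pairwise
Pearson r over flanking-bin methylation tables to decide whether replicate
experiments may be pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .preference import OEProfile


@dataclass
class ProfileComparison:
    pearson_r: float  # NaN when either flattened profile is constant
    rmsd: float
    n_points: int


def _flatten(profile: OEProfile, positions: list[int]) -> np.ndarray:
    missing = [p for p in positions if p not in profile.oe.index]
    if missing:
        raise ValueError(f"profile missing positions {missing}")
    return profile.oe.loc[positions].to_numpy(float).ravel()


def compare_profiles(
    a: OEProfile, b: OEProfile, positions: list[int] | None = None
) -> ProfileComparison:
    """Pearson r and RMSD over the flattened o/e vectors of two profiles.

    Default window: the positions shared by both profiles.  Entries missing
    (NaN) in either profile are excluded pairwise; ``n_points`` reports how
    many position-base entries were compared.
    """
    if positions is None:
        positions = [p for p in a.oe.index if p in b.oe.index]
        if not positions:
            raise ValueError("profiles share no positions")
    va, vb = _flatten(a, positions), _flatten(b, positions)
    ok = ~(np.isnan(va) | np.isnan(vb))
    va, vb = va[ok], vb[ok]
    n = int(ok.sum())
    if n == 0:
        return ProfileComparison(np.nan, np.nan, 0)
    rmsd = float(np.sqrt(np.mean((va - vb) ** 2)))
    if np.allclose(va, va[0]) or np.allclose(vb, vb[0]):
        # constant vector: r undefined; identical profiles still get rmsd 0
        r = np.nan
    else:
        r = float(pearsonr(va, vb).statistic)
    return ProfileComparison(pearson_r=r, rmsd=rmsd, n_points=n)


def replicate_correlation(
    bin_tables: list[pd.DataFrame],
    merge_threshold: float = 0.8,
    min_coverage: int = 1,
) -> tuple[pd.DataFrame, bool]:
    """Pairwise Pearson r over replicate flanking-bin methylation tables.

    Tables must share the same bin index (e.g. the 256 NN-X-NN contexts).
    Bins with coverage below ``min_coverage`` in either replicate of a pair
    are excluded pairwise; constant vectors yield NaN.  Returns the r matrix
    and a merge recommendation (all off-diagonal r above
    ``merge_threshold``).
    """
    if len(bin_tables) < 2:
        raise ValueError("need at least two replicate tables")
    index = bin_tables[0].index
    for t in bin_tables[1:]:
        if not t.index.equals(index):
            raise ValueError("replicate tables have different bin keys")
    n = len(bin_tables)
    r = np.full((n, n), np.nan)
    np.fill_diagonal(r, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = bin_tables[i], bin_tables[j]
            ok = (
                (ti["coverage"] >= min_coverage)
                & (tj["coverage"] >= min_coverage)
                & ti["mean_methylation"].notna()
                & tj["mean_methylation"].notna()
            )
            x = ti.loc[ok, "mean_methylation"].to_numpy(float)
            y = tj.loc[ok, "mean_methylation"].to_numpy(float)
            if len(x) >= 2 and np.ptp(x) > 0 and np.ptp(y) > 0:
                r[i, j] = r[j, i] = pearsonr(x, y).statistic
    labels = [f"rep{i}" for i in range(n)]
    matrix = pd.DataFrame(r, index=labels, columns=labels)
    off = matrix.to_numpy()[~np.eye(n, dtype=bool)]
    merge = bool(np.all(np.nan_to_num(off, nan=-1.0) >= merge_threshold))
    return matrix, merge


def pooled_bins(bin_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Coverage-weighted combination of per-replicate bin tables: identical to
    profiling the pooled reads directly."""
    index = bin_tables[0].index
    cov = sum(t["coverage"] for t in bin_tables)
    met = sum(t["methylated"] for t in bin_tables)
    out = pd.DataFrame({"coverage": cov, "methylated": met}, index=index)
    with np.errstate(invalid="ignore"):
        out["mean_methylation"] = np.where(
            out["coverage"] > 0, out["methylated"] / out["coverage"], np.nan
        )
    return out[["mean_methylation", "coverage", "methylated"]]
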