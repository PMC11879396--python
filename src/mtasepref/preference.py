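"""Flanking sequence preference analysis.

The central statistic is the observed/expected (o/e) enrichment: for each
flank position i and base N, the frequency of N at i among *methylated* reads
divided by its frequency at i in the full read pool.  Values above 1 mark
bases the enzyme prefers next to its target site, values below 1 bases it
disfavours.  Derived quantities:

* per-position effect size ``E_i`` — Euclidean magnitude of the four o/e
  deviations from 1,
* methylation averages in NN-X-NN / NNN-X-NNN flanking bins,
* a closed-form upper bound on the methylation level of bins with zero
  observed methylation events,
* the multiplicative expansion of the profile into relative activities for
  all 4^(2m) N_m-X-N_m contexts,
* a rank-based scan for combinatorial (non-multiplicative) sequence effects.

``FlankingPreferenceModel`` wraps these in a statsmodels-style fit interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .design import SubstrateDesign
from .dna import BASES, encode_matrix
from .readproc import ProcessedRead


class ProfileError(ValueError):
    """Profile undefined or incomplete for the requested operation."""


def default_positions(m: int) -> list[int]:
    """Flank positions -m..-1, +1..+m (no position 0)."""
    return [p for p in range(-m, m + 1) if p != 0]


@dataclass
class OEProfile:
    """Observed/expected base enrichment around a target motif.

    ``oe``: DataFrame indexed by flank position with columns A,C,G,T
    (NaN where the pool frequency is zero).  ``pool_freq`` holds the
    denominator frequencies; ``methylated_counts``/``total_counts`` the raw
    base counts for uncertainty bookkeeping.
    """

    motif: str
    target_index: int
    oe: pd.DataFrame
    pool_freq: pd.DataFrame
    methylated_counts: pd.DataFrame
    total_counts: pd.DataFrame
    n_methylated: int
    n_total: int

    @property
    def positions(self) -> list[int]:
        return list(self.oe.index)

    def effect_size(self, position: int, printed_variant: bool = False) -> float:
        return effect_size(self, position, printed_variant)

    def effect_sizes(self, printed_variant: bool = False) -> pd.Series:
        return pd.Series(
            {p: effect_size(self, p, printed_variant) for p in self.positions},
            name="effect_size",
        )

    def flank_factors(self) -> dict[int, dict[str, float]]:
        """o/e values keyed as a rate-model factor map (f_i(N) = o/e)."""
        return {
            int(p): {b: float(self.oe.at[p, b]) for b in BASES}
            for p in self.positions
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# motif={self.motif} target_index={self.target_index} "
                f"n_methylated={self.n_methylated} n_total={self.n_total}\n"
            )
            self.oe.rename_axis("position").to_csv(fh, sep="\t")

    def plot(self, ax=None):
        """Grouped bar chart of o/e values per position (one bar per base)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.0 + 0.6 * len(self.positions), 3))
        x = np.arange(len(self.positions))
        for k, b in enumerate(BASES):
            ax.bar(x + (k - 1.5) * 0.2, self.oe[b].to_numpy(), width=0.2, label=b)
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_xticks(x, [str(p) for p in self.positions])
        ax.set_xlabel("flank position")
        ax.set_ylabel("o/e")
        ax.legend(ncol=4, fontsize="small")
        return ax


def _window_matrix(reads: list[ProcessedRead]) -> np.ndarray:
    return encode_matrix([r.original_sequence for r in reads])


def oe_profile(
    reads: list[ProcessedRead],
    design: SubstrateDesign,
    motif: str,
    target_index: int = 1,
    positions: list[int] | None = None,
    min_methylated: int = 1,
) -> OEProfile:
    """Compute the o/e profile from reads carrying the given motif variant.

    Only reads whose analysis frame equals ``motif`` enter the pool; the o/e
    denominator is the base composition of that full pool (methylated plus
    unmethylated).  Raises :class:`ProfileError` when fewer than
    ``min_methylated`` methylated reads are available.
    """
    if positions is None:
        positions = default_positions(6)
    offsets = {
        p: design.flank_offset(p, motif, target_index) for p in positions
    }
    frame = design.frame_offsets(motif, target_index)
    pool = [
        r
        for r in reads
        if "".join(r.original_sequence[i] for i in frame) == motif
    ]
    if not pool:
        raise ProfileError(f"no reads match motif {motif!r}")
    meth = [r for r in pool if r.target_methylated]
    if len(meth) < min_methylated:
        raise ProfileError(
            f"only {len(meth)} methylated reads (< {min_methylated}); "
            "o/e profile undefined"
        )
    mat_all = _window_matrix(pool)
    mat_meth = _window_matrix(meth)
    total = pd.DataFrame(0, index=positions, columns=list(BASES))
    methylated = pd.DataFrame(0, index=positions, columns=list(BASES))
    for p, off in offsets.items():
        total.loc[p] = np.bincount(mat_all[:, off], minlength=4)[:4]
        methylated.loc[p] = np.bincount(mat_meth[:, off], minlength=4)[:4]
    pool_freq = total.div(total.sum(axis=1), axis=0)
    meth_freq = methylated.div(methylated.sum(axis=1), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = meth_freq / pool_freq
    oe = oe.where(pool_freq > 0)  # zero pool frequency -> missing, not inf
    return OEProfile(
        motif=motif,
        target_index=target_index,
        oe=oe.astype(float),
        pool_freq=pool_freq.astype(float),
        methylated_counts=methylated,
        total_counts=total,
        n_methylated=len(meth),
        n_total=len(pool),
    )


def effect_size(
    profile: OEProfile, position: int, printed_variant: bool = False
) -> float:
    """Overall preference magnitude at one flank position.

    E_i = sqrt((A_i-1)^2 + (C_i-1)^2 + (G_i-1)^2 + (T_i-1)^2) over the four
    o/e values.  ``printed_variant=True`` reproduces a historical variant in
    which the T term is duplicated and the G term absent (kept for audit).
    """
    if position not in profile.oe.index:
        raise ProfileError(f"position {position} not in profile")
    row = profile.oe.loc[position]
    if row.isna().any():
        raise ProfileError(f"missing o/e value at position {position}")
    a, c, g, t = (row[b] for b in "ACGT")
    if printed_variant:
        return float(np.sqrt((a - 1) ** 2 + 2 * (t - 1) ** 2 + (c - 1) ** 2))
    return float(np.sqrt((a - 1) ** 2 + (c - 1) ** 2 + (g - 1) ** 2 + (t - 1) ** 2))


def bin_methylation(
    reads: list[ProcessedRead],
    design: SubstrateDesign,
    motif: str,
    target_index: int = 1,
    half_width: int = 3,
) -> pd.DataFrame:
    """Average methylation per N_m-X-N_m flanking bin.

    Returns a DataFrame with exactly 4^(2m) rows indexed by the flanking
    context (left flank + right flank concatenated, 5'->3'), columns
    ``mean_methylation`` (NaN for zero coverage), ``coverage`` and
    ``methylated``.
    """
    positions = default_positions(half_width)
    offsets = [design.flank_offset(p, motif, target_index) for p in positions]
    frame = design.frame_offsets(motif, target_index)
    contexts = ["".join(c) for c in product(BASES, repeat=2 * half_width)]
    cov = dict.fromkeys(contexts, 0)
    met = dict.fromkeys(contexts, 0)
    for r in reads:
        if "".join(r.original_sequence[i] for i in frame) != motif:
            continue
        key = "".join(r.original_sequence[o] for o in offsets)
        cov[key] += 1
        met[key] += int(r.target_methylated)
    table = pd.DataFrame(
        {
            "coverage": pd.Series(cov),
            "methylated": pd.Series(met),
        }
    )
    table.index.name = "context"
    with np.errstate(invalid="ignore"):
        table["mean_methylation"] = np.where(
            table["coverage"] > 0, table["methylated"] / table["coverage"], np.nan
        )
    return table[["mean_methylation", "coverage", "methylated"]]


def zero_bin_upper_bound(coverage: int, alpha: float = 0.05) -> float:
    """Largest methylation probability consistent with 0 events in ``coverage``
    reads at confidence ``alpha``:  p = 1 - alpha**(1/n)."""
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return 1.0 - alpha ** (1.0 / coverage)


def relative_activity(
    profile: OEProfile, half_width: int = 4
) -> pd.Series:
    """Multiplicative expansion of the profile into relative activities.

    Act(context) = prod over flank positions -m..-1, +1..+m of the o/e value
    of the base present.  Index keys are full N_m + motif + N_m sequences;
    the vector covers all 4^(2m) contexts.
    """
    positions = default_positions(half_width)
    missing = [p for p in positions if p not in profile.oe.index]
    if missing:
        raise ProfileError(f"profile missing positions {missing}")
    if profile.oe.loc[positions].isna().any().any():
        raise ProfileError("profile has missing o/e values in the window")
    factors = [profile.oe.loc[p, list(BASES)].to_numpy(float) for p in positions]
    act = factors[0]
    for f in factors[1:]:
        act = np.multiply.outer(act, f)
    act = act.ravel()
    m = half_width
    keys = [
        "".join(c[:m]) + profile.motif + "".join(c[m:])
        for c in product(BASES, repeat=2 * m)
    ]
    return pd.Series(act, index=keys, name="activity")


def complex_effect_scan(
    bins: pd.DataFrame,
    activity: pd.Series,
    motif: str,
    quantile: float = 0.99,
    min_coverage: int = 10,
) -> pd.DataFrame:
    """Detect combinatorial (non-multiplicative) sequence effects.

    The observed bin methylation implies an apparent rate k proportional to
    -ln(1 - m); under a purely multiplicative preference model log k differs
    from log(predicted activity) only by a constant.  Bins whose centred
    log-rate residual lies beyond the ``quantile`` of the residual
    distribution are flagged; rank columns and a ``spearman_r`` attribute
    (observed-vs-predicted rank correlation) are reported as diagnostics.
    Bins under ``min_coverage`` (or with zero coverage) are excluded.
    """
    from scipy.stats import rankdata, spearmanr

    # activity keys are full sequences; bin keys are flank contexts
    m = (len(activity.index[0]) - len(motif)) // 2
    act = pd.Series(
        activity.to_numpy(),
        index=[k[:m] + k[m + len(motif):] for k in activity.index],
    )
    table = bins.join(act.rename("predicted_activity"))
    table = table[table["coverage"] >= max(min_coverage, 1)].copy()
    if table.empty:
        table.attrs["spearman_r"] = np.nan
        return table
    # apparent log rate; clip m away from {0, 1} by half an event
    half = 0.5 / table["coverage"]
    m_clip = table["mean_methylation"].clip(lower=half, upper=1 - half)
    log_k = np.log(-np.log1p(-m_clip))
    log_act = np.log(table["predicted_activity"].clip(lower=1e-300))
    resid = log_k - log_act
    table["log_rate_residual"] = resid - resid.median()
    table["rank_observed"] = rankdata(table["mean_methylation"])
    table["rank_predicted"] = rankdata(table["predicted_activity"])
    cut = table["log_rate_residual"].abs().quantile(quantile)
    table["flagged"] = table["log_rate_residual"].abs() > cut
    r = spearmanr(table["mean_methylation"], table["predicted_activity"]).statistic
    table.attrs["spearman_r"] = float(r)
    return table


# ---------------------------------------------------------------------------
# model/results presentation
# ---------------------------------------------------------------------------

class FlankingPreferenceModel:
    """Flanking-preference analysis of processed reads for one motif.

    Parameters
    ----------
    reads
        Processed (reconstructed) reads.
    design
        The substrate design the reads came from.
    motif, target_index
        Analysis frame: recognition motif and 1-based index of its target C.
    positions
        Flank positions to profile (default -6..+6).
    """

    def __init__(
        self,
        reads: list[ProcessedRead],
        design: SubstrateDesign,
        motif: str,
        target_index: int = 1,
        positions: list[int] | None = None,
    ):
        self.reads = reads
        self.design = design
        self.motif = motif
        self.target_index = target_index
        self.positions = positions or default_positions(6)

    def fit(self, min_methylated: int = 1) -> "FlankingPreferenceResults":
        profile = oe_profile(
            self.reads,
            self.design,
            self.motif,
            self.target_index,
            self.positions,
            min_methylated=min_methylated,
        )
        return FlankingPreferenceResults(self, profile)


class FlankingPreferenceResults:
    """Fitted flanking-preference profile with derived tables."""

    def __init__(self, model: FlankingPreferenceModel, profile: OEProfile):
        self.model = model
        self.profile = profile

    @property
    def oe(self) -> pd.DataFrame:
        return self.profile.oe

    def effect_sizes(self, printed_variant: bool = False) -> pd.Series:
        return self.profile.effect_sizes(printed_variant)

    def bins(self, half_width: int = 3) -> pd.DataFrame:
        return bin_methylation(
            self.model.reads,
            self.model.design,
            self.model.motif,
            self.model.target_index,
            half_width,
        )

    def activity(self, half_width: int = 4) -> pd.Series:
        return relative_activity(self.profile, half_width)

    def summary(self) -> str:
        p = self.profile
        lines = [
            "Flanking sequence preference profile",
            "=" * 44,
            f"motif: {p.motif} (target C at position {p.target_index})",
            f"reads in pool: {p.n_total}   methylated: {p.n_methylated}"
            f"   ({p.n_methylated / p.n_total:.1%})",
            "",
            "o/e enrichment (rows: flank position):",
            p.oe.round(3).to_string(),
            "",
            "effect size per position:",
            self.effect_sizes().round(3).to_string(),
        ]
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        return self.profile.plot(ax=ax)
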