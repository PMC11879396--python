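"""Target-motif specificity: cognate vs near-cognate methylation and fold rates.

Near-cognate sites differ from the recognition motif at exactly one position.
Endpoint methylation levels are converted to apparent first-order rates via
k proportional to -ln(1 - m); independent endpoint experiments are placed on a
shared *virtual time axis* defined by the cognate site's progress
(pseudo-t_j = -ln(1 - m_cognate,j)), which makes the cognate fit exact by
construction and lets variant rates be estimated jointly.  Variants with zero
observed methylation yield lower bounds on the fold specificity via the
binomial zero-count bound p = 1 - alpha**(1/n).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SubstrateDesign
from .preference import zero_bin_upper_bound
from .readproc import ProcessedRead


def near_cognate_variants(cognate: str) -> list[str]:
    """All motifs differing from the cognate at exactly one position (3L,
    lexicographic within each position, excluding the cognate)."""
    out = []
    for i in range(len(cognate)):
        for b in "ACGT":
            if b != cognate[i]:
                out.append(cognate[:i] + b + cognate[i + 1:])
    return out


@dataclass
class NearCognateSet:
    """Per-variant methylation of the cognate and all 1-bp-off motifs.

    ``table``: DataFrame indexed by motif with per-experiment columns
    ``mean_<j>`` / ``coverage_<j>`` plus pooled ``mean_methylation``,
    ``coverage`` and ``methylated``.  ``other`` aggregates reads whose frame
    differs from the cognate by more than one base (reported only as a
    no-detectable-methylation check).
    """

    cognate: str
    target_index: int
    table: pd.DataFrame
    n_experiments: int
    other: pd.Series = field(default=None)

    @property
    def variants(self) -> list[str]:
        return [m for m in self.table.index if m != self.cognate]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# cognate={self.cognate} target_index={self.target_index} "
                f"n_experiments={self.n_experiments}\n"
            )
            self.table.rename_axis("motif").to_csv(fh, sep="\t")


def extract_motif_table(
    experiments: list[list[ProcessedRead]] | list[ProcessedRead],
    design: SubstrateDesign,
    cognate: str,
    target_index: int,
) -> NearCognateSet:
    """Tabulate methylation of the cognate and every near-cognate motif.

    Reads (from a CN-type library) are assigned to the motif occupying the
    analysis frame around the fixed target C.  ``experiments`` may be a single
    read list or a list of per-experiment read lists.
    """
    if experiments and isinstance(experiments[0], ProcessedRead):
        experiments = [experiments]
    frame = design.frame_offsets(cognate, target_index)
    motifs = [cognate] + near_cognate_variants(cognate)
    idx = {m: i for i, m in enumerate(motifs)}
    n_exp = len(experiments)
    cov = np.zeros((len(motifs), n_exp), dtype=int)
    met = np.zeros((len(motifs), n_exp), dtype=int)
    other_cov = np.zeros(n_exp, dtype=int)
    other_met = np.zeros(n_exp, dtype=int)
    for j, reads in enumerate(experiments):
        for r in reads:
            m = "".join(r.original_sequence[i] for i in frame)
            i = idx.get(m)
            if i is None:
                other_cov[j] += 1
                other_met[j] += int(r.target_methylated)
            else:
                cov[i, j] += 1
                met[i, j] += int(r.target_methylated)
    data = {}
    for j in range(n_exp):
        with np.errstate(invalid="ignore"):
            data[f"mean_{j}"] = np.where(cov[:, j] > 0, met[:, j] / cov[:, j], np.nan)
        data[f"coverage_{j}"] = cov[:, j]
    total_cov = cov.sum(axis=1)
    total_met = met.sum(axis=1)
    with np.errstate(invalid="ignore"):
        pooled = np.where(total_cov > 0, total_met / total_cov, np.nan)
    data["mean_methylation"] = pooled
    data["coverage"] = total_cov
    data["methylated"] = total_met
    table = pd.DataFrame(data, index=pd.Index(motifs, name="motif"))
    other = pd.Series(
        {
            "coverage": int(other_cov.sum()),
            "methylated": int(other_met.sum()),
        },
        name="other_2plus_mismatch",
    )
    return NearCognateSet(
        cognate=cognate,
        target_index=target_index,
        table=table,
        n_experiments=n_exp,
        other=other,
    )


def fit_progress(
    points: list[tuple[float, float]],
    amplitude: float | None = None,
) -> tuple[float, float]:
    """Least-squares fit of m(t) = A * (1 - exp(-k t)); returns (A, k).

    With ``amplitude`` given, A is fixed and only k fitted (closed form for a
    single point).  Emits a warning when pseudo-times are non-monotone with
    the responses.
    """
    pts = [(t, m) for t, m in points]
    if len(pts) < 1 or (amplitude is None and len(pts) < 2):
        raise ValueError("not enough points for the requested fit")
    t = np.array([p[0] for p in pts], float)
    m = np.array([p[1] for p in pts], float)
    if np.all(m == 0):
        return (amplitude if amplitude is not None else float("nan")), 0.0
    order = np.argsort(t)
    if np.any(np.diff(m[order]) < -0.25 * (m.max() - m.min() + 1e-12)):
        warnings.warn("progress points strongly non-monotone in pseudo-time")
    from scipy.optimize import curve_fit

    if amplitude is not None:
        if len(pts) == 1:
            tt, mm = t[0], m[0]
            return amplitude, float(-math.log(1.0 - mm / amplitude) / tt)
        k0 = max(
            1e-9, float(np.mean(-np.log1p(-np.clip(m / amplitude, 0, 1 - 1e-12)) / np.maximum(t, 1e-12)))
        )
        popt, _ = curve_fit(
            lambda tt, k: amplitude * -np.expm1(-k * tt),
            t,
            m,
            p0=[k0],
            bounds=(0, np.inf),
            maxfev=10000,
        )
        return amplitude, float(popt[0])
    a0 = max(m.max(), 1e-9)
    k0 = max(1e-9, float(-np.log1p(-min(m[0] / a0, 1 - 1e-9)) / max(t[0], 1e-12)))
    popt, _ = curve_fit(
        lambda tt, a, k: a * -np.expm1(-k * tt),
        t,
        m,
        p0=[a0, k0],
        bounds=(0, np.inf),
        maxfev=10000,
    )
    return float(popt[0]), float(popt[1])


def virtual_time_axis(cognate_levels) -> np.ndarray:
    """Pseudo-times from cognate endpoint methylation: t_j = -ln(1 - m_j)."""
    m = np.asarray(cognate_levels, float)
    if np.any((m < 0) | (m >= 1)):
        raise ValueError("cognate methylation levels must be in [0, 1)")
    return -np.log1p(-m)


@dataclass
class SpecificityResult:
    """Fold specificities k_cognate / k_variant per near-cognate motif.

    ``table`` columns: mean_methylation, coverage, k, fold, lower_bound
    (True where the variant had zero methylation events and the fold is a
    '> X' bound from the binomial zero-count limit).
    """

    cognate: str
    table: pd.DataFrame
    alpha: float = 0.05

    def fold(self, variant: str) -> float:
        return float(self.table.at[variant, "fold"])


def specificity_folds(
    ncs: NearCognateSet, alpha: float = 0.05
) -> SpecificityResult:
    """Rate-based fold specificity of the cognate over each near-cognate site.

    Multi-experiment sets are fitted on the virtual time axis (cognate rate 1
    by construction); a single pooled endpoint reduces to the closed form
    fold = ln(1 - m_cognate) / ln(1 - m_variant).  Zero-methylation variants
    get a lower bound from p = 1 - alpha**(1/n).
    """
    cog = ncs.table.loc[ncs.cognate]
    if not cog["coverage"] or cog["methylated"] == 0:
        raise ValueError("cognate methylation is zero; specificity undefined")
    n_exp = ncs.n_experiments
    cog_levels = np.array(
        [ncs.table.at[ncs.cognate, f"mean_{j}"] for j in range(n_exp)], float
    )
    usable = ~np.isnan(cog_levels) & (cog_levels < 1.0)
    pseudo_t = virtual_time_axis(cog_levels[usable])
    k_cog = 1.0  # exact by construction of the virtual axis

    rows = []
    for motif in ncs.table.index:
        row = ncs.table.loc[motif]
        cov = int(row["coverage"])
        meth = int(row["methylated"])
        if cov == 0:
            rows.append((motif, np.nan, 0, np.nan, np.nan, False))
            continue
        if meth == 0:
            p_bound = zero_bin_upper_bound(cov, alpha)
            k_bound = -math.log1p(-p_bound) / max(pseudo_t.max(), 1e-300)
            rows.append(
                (motif, 0.0, cov, k_bound, k_cog / k_bound, True)
            )
            continue
        levels = np.array([row[f"mean_{j}"] for j in range(n_exp)], float)[usable]
        ok = ~np.isnan(levels)
        if ok.sum() >= 1 and len(pseudo_t) >= 1:
            _, k = fit_progress(
                list(zip(pseudo_t[ok], levels[ok])), amplitude=1.0
            )
        else:
            k = np.nan
        fold = k_cog / k if k > 0 else np.inf
        rows.append((motif, float(row["mean_methylation"]), cov, k, fold, False))
    table = pd.DataFrame(
        rows,
        columns=["motif", "mean_methylation", "coverage", "k", "fold", "lower_bound"],
    ).set_index("motif")
    return SpecificityResult(cognate=ncs.cognate, table=table, alpha=alpha)


def endpoint_fold(m_cognate: float, m_variant: float) -> float:
    """Single-time-point rate ratio: ln(1-m_cog)/ln(1-m_var)."""
    if not 0 <= m_cognate < 1 or not 0 < m_variant < 1:
        raise ValueError("methylation levels must be in [0, 1) (variant > 0)")
    return math.log1p(-m_cognate) / math.log1p(-m_variant)


def specificity_change(
    mutant: SpecificityResult, wt: SpecificityResult
) -> pd.DataFrame:
    """Per-variant relative-activity ratio mutant vs wild type.

    ratio = (k_variant/k_cognate)_mutant / (k_variant/k_cognate)_WT; values
    above 1 mark variants where the mutant's specificity is relaxed.  Rows
    with undefined WT activity are flagged ``undefined``.
    """
    if mutant.cognate != wt.cognate:
        raise ValueError("specificity results are for different cognate motifs")
    idx = wt.table.index
    rel_mut = 1.0 / mutant.table.loc[idx, "fold"]
    rel_wt = 1.0 / wt.table.loc[idx, "fold"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = rel_mut / rel_wt
    out = pd.DataFrame(
        {
            "ratio": ratio,
            "undefined": (~np.isfinite(rel_wt)) | (rel_wt == 0) | rel_wt.isna(),
        },
        index=idx,
    )
    out.loc[out["undefined"], "ratio"] = np.nan
    return out.drop(index=wt.cognate)
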