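"""Monoexponential progress-curve fitting for radioactive methylation assays.

The incorporated-label signal follows CPM(t) = A * (1 - exp(-k t)) with A the
maximal signal and k the first-order rate constant; the reaction rate is
v(t) = A k exp(-k t), so v(0) = A k is the initial methylation rate.  Fits
are unweighted nonlinear least squares; replicate reactions are fitted
separately and their initial rates averaged afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class FitError(RuntimeError):
    """Nonlinear fit failed to converge."""


def _monoexp(t, a, k):
    return a * -np.expm1(-k * t)


@dataclass
class ProgressCurveResults:
    """Fitted progress curve: amplitude A (CPM), rate k (1/min), v0 = A*k."""

    t: np.ndarray
    signal: np.ndarray
    amplitude: float
    rate: float
    amplitude_se: float
    rate_se: float
    all_zero: bool = False

    @property
    def initial_rate(self) -> float:
        """v(0) = A * k (CPM per minute)."""
        return self.amplitude * self.rate

    @property
    def residuals(self) -> np.ndarray:
        return self.signal - self.fitted

    @property
    def fitted(self) -> np.ndarray:
        return _monoexp(self.t, self.amplitude, self.rate)

    def rate_at(self, t: float) -> float:
        """Instantaneous rate v(t) = A k exp(-k t)."""
        return self.amplitude * self.rate * float(np.exp(-self.rate * t))

    def summary(self) -> str:
        lines = [
            "Monoexponential progress curve fit",
            "=" * 40,
            f"n points:        {len(self.t)}",
            f"A (max signal):  {self.amplitude:.6g} +/- {self.amplitude_se:.2g}",
            f"k (rate):        {self.rate:.6g} +/- {self.rate_se:.2g} per min",
            f"v0 = A*k:        {self.initial_rate:.6g} per min",
            f"residual SD:     {np.std(self.residuals):.4g}",
        ]
        if self.all_zero:
            lines.append("note: all-zero signal; k = 0, A undefined")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t, self.signal, "o", label="data")
        tt = np.linspace(0, float(self.t.max()) * 1.05, 200)
        ax.plot(tt, _monoexp(tt, self.amplitude, self.rate), "-", label="fit")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("signal (CPM)")
        ax.legend()
        return ax


class ProgressCurveModel:
    """Progress-curve model for one reaction: signal(t) = A (1 - e^{-k t})."""

    def __init__(self, t, signal):
        self.t = np.asarray(t, float)
        self.signal = np.asarray(signal, float)
        if len(self.t) != len(self.signal):
            raise ValueError("t and signal lengths differ")
        if len(self.t) < 3:
            raise ValueError("need at least 3 points to fit A and k")
        if np.any(self.t < 0):
            raise ValueError("time points must be nonnegative")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, t_col="t", signal_col="cpm"):
        return cls(df[t_col].to_numpy(), df[signal_col].to_numpy())

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls.from_dataframe(df, df.columns[0], df.columns[1])

    def fit(self) -> ProgressCurveResults:
        t, y = self.t, self.signal
        if np.all(y == 0):
            return ProgressCurveResults(
                t=t, signal=y, amplitude=np.nan, rate=0.0,
                amplitude_se=np.nan, rate_se=np.nan, all_zero=True,
            )
        a0 = float(max(y.max(), 1e-12))
        # k0 from a log-linear fit of the early, sub-saturation points
        frac = np.clip(y / (1.05 * a0), 1e-9, 1 - 1e-9)
        early = t > 0
        if early.sum() >= 2:
            slope = np.polyfit(t[early], np.log1p(-frac[early]), 1)[0]
            k0 = max(1e-9, -float(slope))
        else:
            k0 = 1e-3
        try:
            popt, pcov = curve_fit(
                _monoexp, t, y, p0=[a0, k0], bounds=(0, np.inf), maxfev=20000
            )
        except RuntimeError as exc:
            raise FitError(
                f"progress-curve fit did not converge (p0=A:{a0:.3g}, k:{k0:.3g})"
            ) from exc
        se = np.sqrt(np.diag(pcov))
        return ProgressCurveResults(
            t=t, signal=y,
            amplitude=float(popt[0]), rate=float(popt[1]),
            amplitude_se=float(se[0]), rate_se=float(se[1]),
        )


def fit_monoexponential(points) -> ProgressCurveResults:
    """Functional wrapper: fit A, k from a list of (t, CPM) points."""
    pts = list(points)
    return ProgressCurveModel([p[0] for p in pts], [p[1] for p in pts]).fit()


def fit_replicates(curves: list[list[tuple[float, float]]]) -> pd.DataFrame:
    """Fit each replicate curve separately; returns per-replicate A, k, v0
    plus a ``mean``/``sd`` summary row pair for v0 averaging after fitting."""
    rows = []
    for i, pts in enumerate(curves):
        res = fit_monoexponential(pts)
        rows.append((f"rep{i}", res.amplitude, res.rate, res.initial_rate))
    df = pd.DataFrame(rows, columns=["replicate", "A", "k", "v0"]).set_index(
        "replicate"
    )
    df.attrs["v0_mean"] = float(df["v0"].mean())
    df.attrs["v0_sd"] = float(df["v0"].std(ddof=1)) if len(df) > 1 else np.nan
    return df
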