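"""Exponential kinetics of radiation-induced chromosomal aberration yield.

The yield of chromatid breaks and gaps per 100 cells, measured at fixed
hours after ex-vivo irradiation of G2-phase lymphocytes, decays roughly
exponentially as the damage is processed.  The model is

    y(t) = k * exp(-t / T)   for t >= 0,   y(t) = 0 for t < 0

with gain ``k`` (aberrations/100 cells; the initial induction level) and
time constant ``T`` (hours; the speed of decay).  Each biological
replicate is fitted independently by Levenberg-Marquardt nonlinear least
squares; per-strain parameters are the arithmetic means over replicates.
The area under the fitted curve over the observation window (AUF) serves
as a second, integral summary of radiosensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "TimeCourse",
    "KineticParams",
    "predict",
    "auf",
    "fit_replicate",
    "average_replicates",
    "relative_residua",
    "fit_strains",
]

DEFAULT_T_END = 5.0


@dataclass(frozen=True)
class TimeCourse:
    """One strain/replicate time course of relative aberration yields.

    ``yields`` are differences between post- and pre-irradiation counts
    per 100 cells, so negative values are tolerated.
    """

    strain_id: str
    replicate_id: str
    times: np.ndarray
    yields: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.yields, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("times and yields must be 1-D arrays of equal length")
        if len(t) < 3:
            raise ValueError("need at least 3 timepoints to fit 2 parameters")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "yields", y)


@dataclass
class KineticParams:
    """Fitted kinetic parameters for one replicate or one strain.

    ``residua`` holds per-timepoint absolute relative residua in percent
    (NaN where the observed yield is zero and the ratio is undefined).
    """

    k: float
    T: float
    auf: float
    converged: bool
    residua: np.ndarray | None = None
    strain_id: str | None = None
    n_replicates: int = 1
    sse: float = float("nan")

    @property
    def mean_residuum(self) -> float:
        """Mean absolute relative residuum (%), undefined points excluded."""
        if self.residua is None or np.all(np.isnan(self.residua)):
            return float("nan")
        return float(np.nanmean(self.residua))


def predict(k: float, T: float, t) -> np.ndarray | float:
    """Model yield k*exp(-t/T) for t >= 0, and 0 for t < 0."""
    if k <= 0 or T <= 0:
        raise ValueError(f"k and T must be positive (got k={k}, T={T})")
    t_arr = np.asarray(t, dtype=float)
    out = np.where(t_arr >= 0, k * np.exp(-np.clip(t_arr, 0, None) / T), 0.0)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def auf(k: float, T: float, t_end: float = DEFAULT_T_END) -> float:
    """Area under the yield-time curve from 0 to ``t_end``.

    Closed form of the integral of k*exp(-t/T):  k*T*(1 - exp(-t_end/T)).
    """
    if k <= 0 or T <= 0 or t_end <= 0:
        raise ValueError("k, T and t_end must be positive")
    return k * T * (1.0 - math.exp(-t_end / T))


def _sse(logp: np.ndarray, t: np.ndarray, y: np.ndarray) -> float:
    k, T = np.exp(logp)
    return float(np.sum((k * np.exp(-t / T) - y) ** 2))


def fit_replicate(
    tc: TimeCourse,
    init: tuple[float, float] | None = None,
    t_end: float = DEFAULT_T_END,
) -> KineticParams:
    """Fit the exponential model to one replicate by Levenberg-Marquardt.

    Optimisation runs in (log k, log T) space, which enforces positivity
    and keeps LM well conditioned.  If the default start (k0 = first
    observed yield, T0 = 2 h) fails to converge, a small log-spaced
    multi-start grid is tried and the best optimum kept.  All-zero (or
    all non-positive) yields cannot identify the model and are reported
    as a non-converged fit rather than raised.
    """
    t, y = tc.times, tc.yields
    if not np.any(y > 0):
        return KineticParams(
            k=float("nan"), T=float("nan"), auf=float("nan"),
            converged=False, strain_id=tc.strain_id,
        )

    def resid(logp: np.ndarray) -> np.ndarray:
        k, T = np.exp(logp)
        return k * np.exp(-t / T) - y

    starts: list[tuple[float, float]] = []
    if init is not None:
        starts.append(init)
    k0 = y[0] if y[0] > 0 else float(np.max(y))
    starts.append((k0, 2.0))

    best: optimize.OptimizeResult | None = None
    for k_s, T_s in starts:
        res = optimize.least_squares(resid, x0=np.log([k_s, T_s]), method="lm")
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        # multi-start over a log-spaced grid
        kmax = float(np.max(y))
        for k_s in np.geomspace(max(kmax / 10, 1e-3), kmax * 10, 5):
            for T_s in np.geomspace(0.2, 20.0, 5):
                res = optimize.least_squares(
                    resid, x0=np.log([k_s, T_s]), method="lm"
                )
                if res.success and (best is None or res.cost < best.cost):
                    best = res
    if best is None:
        return KineticParams(
            k=float("nan"), T=float("nan"), auf=float("nan"),
            converged=False, strain_id=tc.strain_id,
        )

    k_hat, T_hat = np.exp(best.x)
    params = KineticParams(
        k=float(k_hat),
        T=float(T_hat),
        auf=auf(k_hat, T_hat, t_end),
        converged=True,
        strain_id=tc.strain_id,
        sse=float(2 * best.cost),
    )
    params.residua = relative_residua(params, tc)
    return params


def relative_residua(fit: KineticParams, tc: TimeCourse) -> np.ndarray:
    """Per-timepoint absolute relative residuum, 100*|y - yhat|/|y|.

    Timepoints with observed yield 0 are undefined and returned as NaN;
    ``KineticParams.mean_residuum`` excludes them from the mean.
    """
    if not fit.converged:
        raise ValueError("relative residua require a converged fit")
    yhat = predict(fit.k, fit.T, tc.times)
    y = tc.yields
    with np.errstate(divide="ignore", invalid="ignore"):
        res = 100.0 * np.abs(y - yhat) / np.abs(y)
    return np.where(y == 0, np.nan, res)


def average_replicates(fits: Sequence[KineticParams]) -> KineticParams:
    """Per-strain parameters as arithmetic means over converged replicate fits.

    AUF is averaged at the replicate level (mean of per-replicate AUFs),
    not recomputed from the averaged k and T; the two orders of operation
    differ because AUF is nonlinear in (k, T).
    """
    conv = [f for f in fits if f.converged]
    if not conv:
        raise ValueError("average_replicates requires at least one converged fit")
    residua = [f.residua for f in conv if f.residua is not None]
    return KineticParams(
        k=float(np.mean([f.k for f in conv])),
        T=float(np.mean([f.T for f in conv])),
        auf=float(np.mean([f.auf for f in conv])),
        converged=True,
        residua=np.concatenate(residua) if residua else None,
        strain_id=conv[0].strain_id,
        n_replicates=len(conv),
    )


def fit_strains(
    timecourses: Iterable[TimeCourse] | pd.DataFrame,
    t_end: float = DEFAULT_T_END,
) -> pd.DataFrame:
    """Fit every replicate and average per strain.

    Accepts either an iterable of :class:`TimeCourse` or a long-format
    frame with columns (strain, replicate, time_h, yield).  Returns a
    frame with columns (strain, k, T, auf, mean_rel_residuum_pct,
    n_replicates).
    """
    if isinstance(timecourses, pd.DataFrame):
        timecourses = frame_to_timecourses(timecourses)
    by_strain: dict[str, list[KineticParams]] = {}
    for tc in timecourses:
        by_strain.setdefault(tc.strain_id, []).append(fit_replicate(tc, t_end=t_end))
    rows = []
    for strain, fits in by_strain.items():
        avg = average_replicates(fits)
        rows.append(
            {
                "strain": strain,
                "k": avg.k,
                "T": avg.T,
                "auf": avg.auf,
                "mean_rel_residuum_pct": avg.mean_residuum,
                "n_replicates": avg.n_replicates,
            }
        )
    return pd.DataFrame(rows)


def frame_to_timecourses(df: pd.DataFrame) -> list[TimeCourse]:
    """Split a long-format (strain, replicate, time_h, yield) frame."""
    required = {"strain", "replicate", "time_h", "yield"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"time-course table is missing columns: {sorted(missing)}")
    out = []
    for (strain, rep), grp in df.groupby(["strain", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            TimeCourse(
                strain_id=str(strain),
                replicate_id=str(rep),
                times=grp["time_h"].to_numpy(float),
                yields=grp["yield"].to_numpy(float),
            )
        )
    return out
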