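"""Gaussian-mixture decomposition of kinetic parameters and strain classification.

With only 14 inbred strains, the distributions of the gain k, the time
constant T and the area under the yield-time curve (AUF) are decomposed
into univariate Gaussian mixtures fitted by expectation-maximisation,
with the number of components chosen by BIC.  When a parameter supports
two components, the classification threshold is the maximum-conditional-
probability point: the value between the component means at which the
two weighted component densities (hence the two posteriors) are equal.
A strain is called radiosensitive when its k OR its AUF exceeds the
respective threshold.

The EM here is written for exactly this small-sample univariate use:
quantile-based initialisation with random jitter, many restarts, a
variance floor to reject single-point components, and a per-iteration
check that the likelihood never decreases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MixtureModel",
    "ClassificationRule",
    "DegenerateMixtureError",
    "em_fit",
    "select_by_bic",
    "posterior_threshold",
    "classify",
    "derive_rule",
]

_LOG_2PI = math.log(2.0 * math.pi)


class DegenerateMixtureError(RuntimeError):
    """Every EM restart collapsed a component below the variance floor."""


@dataclass(frozen=True)
class MixtureModel:
    """A fitted univariate Gaussian mixture, components sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    n: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(np.asarray(self.sds, float) <= 0):
            raise ValueError("component sds must be positive")

    @property
    def n_components(self) -> int:
        return len(self.means)

    @property
    def n_params(self) -> int:
        # g means + g sds + (g-1) free weights
        return 3 * self.n_components - 1

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * math.log(self.n)

    def logpdf(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        lp = (
            np.log(self.weights)[:, None]
            - np.log(self.sds)[:, None]
            - 0.5 * _LOG_2PI
            - 0.5 * ((x[None, :] - self.means[:, None]) / self.sds[:, None]) ** 2
        )
        m = lp.max(axis=0)
        return m + np.log(np.exp(lp - m).sum(axis=0))

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(np.atleast_1d(x)))


@dataclass(frozen=True)
class ClassificationRule:
    """OR rule: radiosensitive iff k > threshold_k or AUF > threshold_auf."""

    threshold_k: float
    threshold_auf: float


def _component_logpdf(x, w, mu, sd):
    return (
        np.log(w)[:, None]
        - np.log(sd)[:, None]
        - 0.5 * _LOG_2PI
        - 0.5 * ((x[None, :] - mu[:, None]) / sd[:, None]) ** 2
    )


def _em_once(x, g, rng, var_floor, max_iter, tol):
    """One EM run; returns (weights, means, sds, loglik) or None if degenerate."""
    n = len(x)
    qs = np.quantile(x, (np.arange(g) + 0.5) / g)
    mu = qs + rng.normal(0.0, np.std(x) * 0.5, size=g)
    var = np.full(g, np.var(x))
    w = np.full(g, 1.0 / g)
    ll_old = -np.inf
    for it in range(max_iter):
        lp = _component_logpdf(x, w, mu, np.sqrt(var))
        m = lp.max(axis=0)
        lse = m + np.log(np.exp(lp - m).sum(axis=0))
        ll = float(lse.sum())
        # EM guarantees monotone likelihood; a decrease signals a bug
        assert ll >= ll_old - 1e-8, "EM log-likelihood decreased"
        resp = np.exp(lp - lse)
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-12):
            return None
        w = nk / n
        mu = (resp * x).sum(axis=1) / nk
        var = (resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk
        if np.any(var < var_floor):
            return None  # collapsing onto too few points
        if ll - ll_old < tol and it > 2:
            break
        ll_old = ll
    order = np.argsort(mu)
    return w[order], mu[order], np.sqrt(var[order]), ll


def em_fit(
    values: Sequence[float],
    g: int,
    seed: int | None = None,
    n_restarts: int = 50,
    var_floor_frac: float = 1e-3,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> MixtureModel:
    """Fit a g-component univariate Gaussian mixture by EM, best of restarts.

    Restarts that drive any component's variance below
    ``var_floor_frac * var(values)`` are discarded as degenerate; if all
    restarts degenerate, :class:`DegenerateMixtureError` is raised.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) <= g:
        raise ValueError("need more observations than mixture components")
    if g < 1:
        raise ValueError("g must be >= 1")
    if g == 1:
        # closed-form MLE; no latent structure
        mu, sd = float(np.mean(x)), float(np.std(x))
        if sd <= 0:
            raise DegenerateMixtureError("constant sample")
        ll = float(np.sum(-np.log(sd) - 0.5 * _LOG_2PI - 0.5 * ((x - mu) / sd) ** 2))
        return MixtureModel(np.array([1.0]), np.array([mu]), np.array([sd]), ll, len(x))

    rng = np.random.default_rng(seed)
    var_floor = var_floor_frac * np.var(x)
    best = None
    for _ in range(n_restarts):
        fit = _em_once(x, g, rng, var_floor, max_iter, tol)
        if fit is not None and (best is None or fit[3] > best[3]):
            best = fit
    if best is None:
        raise DegenerateMixtureError(
            f"all {n_restarts} EM restarts degenerated for g={g} on n={len(x)} points"
        )
    w, mu, sd, ll = best
    return MixtureModel(w, mu, sd, ll, len(x))


def select_by_bic(
    values: Sequence[float],
    g_max: int = 3,
    seed: int | None = None,
    n_restarts: int = 50,
    **kwargs,
) -> MixtureModel:
    """Fit g = 1..g_max and return the fit minimising BIC.

    BIC = -2*loglik + (3g-1)*ln(n).  Component counts for which every
    restart degenerates (more components than the sample supports) are
    excluded from the comparison.  Ties within 1e-6 go to the smaller g.
    """
    x = np.asarray(values, dtype=float)
    if len(x) <= g_max:
        raise ValueError("need more observations than g_max")
    fits: list[MixtureModel] = []
    for g in range(1, g_max + 1):
        try:
            fits.append(em_fit(x, g, seed=seed, n_restarts=n_restarts, **kwargs))
        except DegenerateMixtureError:
            continue
    if not fits:
        raise DegenerateMixtureError("no component count could be fitted")
    best = fits[0]
    for f in fits[1:]:
        if f.bic < best.bic - 1e-6:
            best = f
    return best


def posterior_threshold(m: MixtureModel) -> float:
    """Equal-posterior crossing point of a 2-component mixture.

    Solves w1*phi(x; mu1, sd1) = w2*phi(x; mu2, sd2) as a quadratic in x
    and returns the root strictly between the component means.  Below it
    the lower component's posterior dominates, above it the upper's.
    """
    if m.n_components != 2:
        raise ValueError(
            "threshold requires exactly 2 components; "
            f"model has {m.n_components} (single-component model has no threshold)"
        )
    (w1, w2), (m1, m2), (s1, s2) = m.weights, m.means, m.sds
    a = 0.5 * (1.0 / s1**2 - 1.0 / s2**2)
    b = m2 / s2**2 - m1 / s1**2
    c = 0.5 * (m1**2 / s1**2 - m2**2 / s2**2) - math.log(w1 * s2 / (w2 * s1))
    if abs(a) < 1e-300:  # equal variances: linear equation
        return float(-c / b)
    roots = np.roots([a, b, c])
    roots = roots[np.abs(roots.imag) < 1e-9].real
    between = [r for r in roots if m1 < r < m2]
    if not between:
        raise RuntimeError("no equal-posterior crossing between the component means")
    return float(between[0])


def derive_rule(
    params: pd.DataFrame,
    g_max: int = 3,
    seed: int | None = None,
    n_restarts: int = 50,
) -> tuple[ClassificationRule, dict[str, MixtureModel]]:
    """Fit mixtures to the k and auf columns and derive the OR-rule thresholds.

    Returns the rule plus the selected mixture per parameter (including
    T, for which a single-component model is the expected outcome and no
    threshold is produced).
    """
    models = {
        col: select_by_bic(params[col].to_numpy(float), g_max=g_max,
                           seed=seed, n_restarts=n_restarts)
        for col in ("k", "T", "auf")
        if col in params.columns
    }
    for col in ("k", "auf"):
        if models[col].n_components < 2:
            raise DegenerateMixtureError(
                f"BIC selected a single-component model for {col}; "
                "no classification threshold exists"
            )
    rule = ClassificationRule(
        threshold_k=posterior_threshold(models["k"]),
        threshold_auf=posterior_threshold(models["auf"]),
    )
    return rule, models


def classify(params: pd.DataFrame, rule: ClassificationRule) -> pd.DataFrame:
    """Label strains radiosensitive/regular by the OR rule.

    Strains with a missing k or auf value are flagged ``unclassified``.
    """
    out = params.copy()
    k = out["k"].to_numpy(float)
    a = out["auf"].to_numpy(float)
    labels = np.where(
        np.isnan(k) | np.isnan(a),
        "unclassified",
        np.where((k > rule.threshold_k) | (a > rule.threshold_auf),
                 "radiosensitive", "regular"),
    )
    out["label"] = labels
    out["threshold_k"] = rule.threshold_k
    out["threshold_auf"] = rule.threshold_auf
    return out
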