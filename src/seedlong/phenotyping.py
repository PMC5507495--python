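"""Seed physiology traits: germination, longevity (P50) and sugar ratios.

Longevity of a seed lot is measured by controlled deterioration: seeds are
stored at 35 degC / 75% RH and germination is assayed at intervals.  The
summary statistic is P50, the storage time at which germination falls to
half of the initial (t=0) viability.  The loss-of-viability curve is
sigmoid, so P50 is estimated as the midpoint of a logistic decay fitted by
binomial maximum likelihood on pooled replicate counts,

    G(t) = G0 / (1 + exp((t - p50) / scale)),

which crosses G0/2 exactly at t = p50.  A linear-interpolation fallback is
used when the optimiser fails, and lots whose fitted/observed curve never
crosses half-viability within the assayed window are reported as censored
(P50 bounded below by the last storage time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = [
    "StorageViabilityCurve",
    "P50Estimate",
    "estimate_p50",
    "estimate_p50_table",
    "germination_summary",
    "rfo_suc_ratio",
]


@dataclass
class StorageViabilityCurve:
    """Germination counts over storage time for one developmental stage.

    ``observations`` columns: time_d, replicate, n_seeds, n_germinated.
    Storage conditions default to the controlled-deterioration regime
    (35 degC, 75% RH).
    """

    stage_label: str
    observations: pd.DataFrame
    temperature_c: float = 35.0
    rh_percent: float = 75.0

    def __post_init__(self) -> None:
        obs = pd.DataFrame(self.observations)
        required = {"time_d", "replicate", "n_seeds", "n_germinated"}
        missing = required - set(obs.columns)
        if missing:
            raise ValueError(f"observations missing columns: {sorted(missing)}")
        if (obs["time_d"] < 0).any():
            raise ValueError("storage times must be non-negative")
        if ((obs["n_germinated"] < 0) | (obs["n_germinated"] > obs["n_seeds"])).any():
            raise ValueError("germinated counts must lie in [0, n_seeds]")
        self.observations = obs.sort_values("time_d").reset_index(drop=True)

    def pooled(self) -> pd.DataFrame:
        """Replicates pooled per storage time (n, germinated, fraction)."""
        g = self.observations.groupby("time_d")[["n_seeds", "n_germinated"]].sum()
        g["fraction"] = g["n_germinated"] / g["n_seeds"]
        return g.reset_index()


@dataclass
class P50Estimate:
    stage_label: str
    p50: float
    scale: float
    censored: bool
    method: str  # "mle", "interpolation" or "censored"
    deviance: float = float("nan")
    g0: float = float("nan")
    diagnostics: dict = field(default_factory=dict)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        val = f"> {self.p50:.1f}" if self.censored else f"{self.p50:.1f}"
        return f"P50[{self.stage_label}] = {val} d ({self.method})"


def _binomial_nll(params: np.ndarray, t: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    g0 = expit(params[0])
    p50 = params[1]
    scale = np.exp(params[2])
    q = g0 / (1.0 + np.exp(np.clip((t - p50) / scale, -500, 500)))
    q = np.clip(q, 1e-12, 1 - 1e-12)
    return float(-np.sum(k * np.log(q) + (n - k) * np.log(1 - q)))


def _interpolate_crossing(t: np.ndarray, frac: np.ndarray, target: float) -> float | None:
    """Earliest linear-interpolated crossing of ``target`` (first time frac <= target)."""
    for i in range(len(t)):
        if frac[i] <= target:
            if i == 0:
                return float(t[0])
            f0, f1 = frac[i - 1], frac[i]
            if f1 == f0:
                return float(t[i])
            return float(t[i - 1] + (f0 - target) / (f0 - f1) * (t[i] - t[i - 1]))
    return None


def estimate_p50(curve: StorageViabilityCurve) -> P50Estimate:
    """Estimate longevity (P50) from a storage-viability curve.

    Fits the logistic decay by binomial MLE on pooled replicate counts; the
    reported P50 is the time at which fitted germination reaches 50% of the
    initial (t=0) level.  Flat segments at exactly 50% resolve to the
    earliest crossing.  Raises on fewer than two distinct storage times or
    on a lot that is already dead at t=0.
    """
    pooled = curve.pooled()
    t = pooled["time_d"].to_numpy(float)
    n = pooled["n_seeds"].to_numpy(float)
    k = pooled["n_germinated"].to_numpy(float)
    frac = k / n
    if len(t) < 2:
        raise ValueError("need at least 2 distinct storage times to estimate P50")
    if 0.0 in t and frac[t == 0][0] == 0.0:
        raise ValueError(f"stage {curve.stage_label}: no germination at t=0 (non-viable lot)")

    g0_obs = frac[0] if t[0] == 0 else float(frac.max())
    target = 0.5 * g0_obs

    # Censored: viability never falls to half of initial within the assay.
    if frac.min() > target:
        return P50Estimate(curve.stage_label, float(t.max()), float("nan"),
                           censored=True, method="censored", g0=g0_obs)

    t_cross = _interpolate_crossing(t, frac, target)
    x0 = np.array([logit(np.clip(g0_obs, 1e-3, 1 - 1e-3)),
                   t_cross if t_cross is not None else float(np.median(t)),
                   np.log(max(np.ptp(t) / 10.0, 1e-3))])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(_binomial_nll, x0, args=(t, n, k), method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-9})
    if res.success and np.isfinite(res.fun):
        g0 = float(expit(res.x[0]))
        p50 = float(res.x[1])
        scale = float(np.exp(res.x[2]))
        # Saturated log-likelihood for residual deviance.
        qs = np.clip(frac, 1e-12, 1 - 1e-12)
        ll_sat = float(np.sum(k * np.log(qs) + (n - k) * np.log(1 - qs)))
        deviance = 2.0 * (ll_sat + res.fun)
        if p50 > t.max():
            return P50Estimate(curve.stage_label, float(t.max()), scale,
                               censored=True, method="censored", deviance=deviance, g0=g0)
        return P50Estimate(curve.stage_label, max(p50, 0.0), scale, censored=False,
                           method="mle", deviance=deviance, g0=g0,
                           diagnostics={"nll": float(res.fun)})
    if t_cross is None:  # pragma: no cover - guarded by censoring test above
        return P50Estimate(curve.stage_label, float(t.max()), float("nan"),
                           censored=True, method="censored", g0=g0_obs)
    return P50Estimate(curve.stage_label, float(t_cross), float("nan"),
                       censored=False, method="interpolation", g0=g0_obs)


def estimate_p50_table(curves: list[StorageViabilityCurve]) -> pd.DataFrame:
    """P50 estimates for a set of stages as a tidy table."""
    rows = []
    for c in curves:
        est = estimate_p50(c)
        rows.append({"stage": est.stage_label, "p50_days": est.p50,
                     "scale_days": est.scale, "censored": est.censored,
                     "method": est.method})
    return pd.DataFrame(rows)


def germination_summary(replicates) -> tuple[float, float | None]:
    """Mean germination percentage and SE over replicate (n_seeds, n_germinated).

    ``replicates`` is an iterable of (n_seeds, n_germinated) pairs or a
    DataFrame with those columns.  The SE is the standard deviation of
    per-replicate percentages over sqrt(r); with a single replicate it is
    undefined and reported as None.
    """
    if isinstance(replicates, pd.DataFrame):
        pairs = list(zip(replicates["n_seeds"], replicates["n_germinated"]))
    else:
        pairs = list(replicates)
    if not pairs:
        raise ValueError("at least one replicate required")
    pct = np.array([100.0 * g / n for n, g in pairs])
    mean = float(pct.mean())
    if len(pct) < 2:
        return mean, None
    se = float(pct.std(ddof=1) / np.sqrt(len(pct)))
    return mean, se


def rfo_suc_ratio(raf: float, sta: float, ver: float, suc: float) -> float:
    """Raffinose-family-oligosaccharide to sucrose ratio, (Raf+Sta+Ver)/Suc.

    The RFO/Suc ratio in the embryonic axis rises together with longevity
    during maturation and serves as a biochemical longevity indicator.
    Returns NaN (with a warning) when sucrose is zero.
    """
    if min(raf, sta, ver, suc) < 0:
        raise ValueError("sugar contents must be non-negative")
    if suc == 0:
        warnings.warn("sucrose content is zero; RFO/Suc ratio undefined")
        return float("nan")
    return (raf + sta + ver) / suc
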