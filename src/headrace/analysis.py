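"""Descriptive behavioral analyses of heading-discrimination trial tables.

Covers the standard battery for this task: cumulative-Gaussian psychometric
fits (PSE and slope), Gaussian fits to the reaction-time peak and the
confidence trough as functions of heading, cue weights recovered from the
conflict-induced psychometric bias, the static optimal-combination
benchmark, and confidence broken down by RT quantile within
|heading| x modality groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize
from scipy.stats import norm

from .evidence import mle_combined_sigma, mle_weights

__all__ = [
    "PsychometricFit",
    "CurveFit",
    "CueWeights",
    "MLEComparison",
    "fit_psychometric",
    "fit_curve",
    "weights_from_conflict",
    "confidence_by_rt_quantile",
    "mle_comparison",
    "analyze_trials",
]


# ---------------------------------------------------------------------------
# Psychometric fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsychometricFit:
    """Cumulative-Gaussian fit of P(rightward) against heading.

    ``pse`` is the 50% point (bias), ``sigma`` the slope parameter
    (discrimination threshold), ``lapse`` a symmetric lapse rate.
    ``flagged`` marks degenerate fits (e.g. complete separation driving
    sigma to the optimizer bound).
    """

    pse: float
    sigma: float
    lapse: float
    loglik: float
    n_trials: int
    flagged: bool = False


_SIGMA_LO = 1e-3


def fit_psychometric(
    heading_deg,
    choice,
    fit_lapse: bool = False,
    lapse_max: float = 0.1,
) -> PsychometricFit:
    """Binomial maximum-likelihood cumulative-Gaussian psychometric fit.

    ``P(right | h) = lapse + (1 - 2 lapse) * Phi((h - pse) / sigma)``; the
    lapse is fixed at 0 unless ``fit_lapse``.  Deterministic: a fixed set
    of starting points is explored with L-BFGS-B and the best optimum kept.

    Raises ``ValueError`` for fewer than two distinct headings or when only
    one response type is present (no slope information).
    """
    h = np.asarray(heading_deg, float)
    y = np.asarray(choice, float)
    if h.shape != y.shape or h.size == 0:
        raise ValueError("heading_deg and choice must be equal-length, non-empty")
    if len(np.unique(h)) < 2:
        raise ValueError("need at least two distinct headings")
    if y.min() == y.max():
        raise ValueError("both responses (left and right) must be present")

    span = float(h.max() - h.min())
    sigma_hi = 10.0 * span

    def nll(theta):
        pse, log_sigma = theta[0], theta[1]
        lapse = theta[2] if fit_lapse else 0.0
        sigma = np.exp(log_sigma)
        p = lapse + (1.0 - 2.0 * lapse) * norm.cdf((h - pse) / sigma)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return -np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))

    starts = [
        (0.0, np.log(max(span / 4.0, 10 * _SIGMA_LO))),
        (float(np.median(h)), np.log(max(span / 8.0, 10 * _SIGMA_LO))),
        (0.0, np.log(max(span, 10 * _SIGMA_LO))),
    ]
    bounds = [(h.min(), h.max()), (np.log(_SIGMA_LO), np.log(sigma_hi))]
    if fit_lapse:
        starts = [s + (0.02,) for s in starts]
        bounds = bounds + [(0.0, lapse_max)]

    best = None
    for s0 in starts:
        res = minimize(nll, np.asarray(s0), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    pse = float(best.x[0])
    sigma = float(np.exp(best.x[1]))
    lapse = float(best.x[2]) if fit_lapse else 0.0
    flagged = sigma <= _SIGMA_LO * 1.01 or sigma >= sigma_hi * 0.99
    return PsychometricFit(
        pse=pse, sigma=sigma, lapse=lapse, loglik=-float(best.fun),
        n_trials=int(h.size), flagged=flagged,
    )


# ---------------------------------------------------------------------------
# Gaussian peak/trough fits for RT and confidence vs heading
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CurveFit:
    """Least-squares Gaussian ``baseline + amplitude exp(-(x-center)^2 / 2 width^2)``.

    Positive amplitude describes a peak (reaction time is longest near the
    hardest heading); negative amplitude a trough (confidence is lowest
    there).  ``flagged`` marks non-convergence or unidentifiable centers.
    """

    baseline: float
    amplitude: float
    center: float
    width: float
    rmse: float
    flagged: bool = False


def fit_curve(x, y, inverted: bool = False) -> CurveFit:
    """Fit a Gaussian peak (or trough, with ``inverted=True``) to condition means."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4:
        raise ValueError("need at least 4 points for a Gaussian curve fit")

    span = float(x.max() - x.min())
    amp0 = float(y.max() - y.min())
    if amp0 < 1e-12 * max(1.0, abs(float(np.mean(y)))) or amp0 == 0.0:
        return CurveFit(
            baseline=float(np.mean(y)), amplitude=0.0, center=np.nan,
            width=span, rmse=float(np.std(y)), flagged=True,
        )

    def model(x, baseline, amplitude, center, width):
        return baseline + amplitude * np.exp(-0.5 * ((x - center) / width) ** 2)

    if inverted:
        p0 = (float(y.max()), -amp0, float(x[np.argmin(y)]), span / 4.0)
        lo = (-np.inf, -np.inf, x.min(), 1e-6)
        hi = (np.inf, 0.0, x.max(), 10.0 * span)
    else:
        p0 = (float(y.min()), amp0, float(x[np.argmax(y)]), span / 4.0)
        lo = (-np.inf, 0.0, x.min(), 1e-6)
        hi = (np.inf, np.inf, x.max(), 10.0 * span)
    try:
        popt, _ = curve_fit(model, x, y, p0=p0, bounds=(lo, hi), maxfev=20_000)
        flagged = False
    except RuntimeError:
        popt = p0
        flagged = True
    resid = y - model(x, *popt)
    return CurveFit(
        baseline=float(popt[0]), amplitude=float(popt[1]), center=float(popt[2]),
        width=float(popt[3]), rmse=float(np.sqrt(np.mean(resid**2))), flagged=flagged,
    )


# ---------------------------------------------------------------------------
# Cue weights from conflict bias, and the static optimal benchmark
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CueWeights:
    w_ves: float
    w_vis: float


def weights_from_conflict(pse: float, delta: float) -> CueWeights:
    """Empirical vestibular weight from the conflict-induced psychometric bias.

    With the vestibular cue at ``h + delta/2`` and the visual cue at
    ``h - delta/2``, the perceived heading is
    ``w_ves (h + delta/2) + w_vis (h - delta/2)``; setting it to zero at
    the PSE gives ``w_ves = 0.5 - pse / delta``.
    """
    if delta == 0:
        raise ValueError("delta must be nonzero to estimate weights")
    w_ves = 0.5 - pse / delta
    return CueWeights(w_ves=w_ves, w_vis=1.0 - w_ves)


@dataclass(frozen=True)
class MLEComparison:
    sigma_pred: float
    ratio: float  # observed combined sigma / optimal prediction
    w_ves_pred: float


def mle_comparison(
    fit_ves: PsychometricFit, fit_vis: PsychometricFit, fit_comb: PsychometricFit
) -> MLEComparison:
    """Compare the combined-condition threshold with the optimal prediction."""
    for f in (fit_ves, fit_vis, fit_comb):
        if f.flagged or not np.isfinite(f.sigma) or f.sigma <= 0:
            raise ValueError("all three psychometric fits must be valid")
    sigma_pred = mle_combined_sigma(fit_ves.sigma, fit_vis.sigma)
    w_ves_pred, _ = mle_weights(fit_ves.sigma, fit_vis.sigma)
    return MLEComparison(
        sigma_pred=sigma_pred,
        ratio=fit_comb.sigma / sigma_pred,
        w_ves_pred=w_ves_pred,
    )


# ---------------------------------------------------------------------------
# Confidence by RT quantile
# ---------------------------------------------------------------------------


def confidence_by_rt_quantile(
    trials: pd.DataFrame,
    n_quantiles: int = 5,
    include_censored: bool = False,
) -> pd.DataFrame:
    """Mean confidence per RT-quantile bin within |heading| x modality groups.

    Left/right headings are pooled by magnitude.  Groups with fewer trials
    than quantile bins are skipped with a warning.  Censored trials are
    excluded by default (their RT is the deadline, not a decision time).

    Returns a tidy table (modality, abs_heading, quantile, mean_conf, sem, n).
    """
    df = trials
    if not include_censored and "censored" in df.columns:
        df = df[df["censored"] == 0]
    df = df.assign(abs_heading=df["heading_deg"].abs())
    rows = []
    for (mod, ah), g in df.groupby(["modality", "abs_heading"], sort=True):
        if len(g) < n_quantiles:
            warnings.warn(
                f"group (modality={mod}, |hdg|={ah}) has {len(g)} trials "
                f"< {n_quantiles} quantile bins; skipped",
                stacklevel=2,
            )
            continue
        q = pd.qcut(g["rt_s"].rank(method="first"), n_quantiles, labels=False)
        for qi in range(n_quantiles):
            c = g.loc[q == qi, "conf"]
            rows.append(
                {
                    "modality": mod,
                    "abs_heading": ah,
                    "quantile": qi,
                    "mean_conf": float(c.mean()),
                    "sem": float(c.sem()) if len(c) > 1 else np.nan,
                    "n": int(len(c)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-table battery
# ---------------------------------------------------------------------------


def analyze_trials(trials: pd.DataFrame, n_quantiles: int = 5) -> dict[str, pd.DataFrame]:
    """Run the full descriptive battery on a trial table.

    Returns per-cell psychometric fits, Gaussian RT-peak and
    confidence-trough fits on per-heading means (censored trials excluded
    from those means), conflict-derived cue weights, and the
    confidence-by-RT-quantile table.  Cells pool subjects.
    """
    psych_rows, curve_rows, weight_rows = [], [], []
    for (mod, coh, delta), g in trials.groupby(["modality", "coherence", "delta_deg"]):
        try:
            pf = fit_psychometric(g["heading_deg"], g["choice"])
        except ValueError:
            continue
        psych_rows.append(
            {
                "modality": mod, "coherence": coh, "delta_deg": delta,
                "pse": pf.pse, "sigma": pf.sigma, "lapse": pf.lapse,
                "loglik": pf.loglik, "n": pf.n_trials, "flagged": pf.flagged,
            }
        )
        if delta != 0:
            w = weights_from_conflict(pf.pse, delta)
            weight_rows.append(
                {
                    "modality": mod, "coherence": coh, "delta_deg": delta,
                    "w_ves": w.w_ves, "w_vis": w.w_vis,
                }
            )
        ok = g[g["censored"] == 0]
        means = ok.groupby("heading_deg")[["rt_s", "conf"]].mean()
        if len(means) >= 4:
            rt_fit = fit_curve(means.index.values, means["rt_s"].values, inverted=False)
            cf_fit = fit_curve(means.index.values, means["conf"].values, inverted=True)
            for name, f in (("rt", rt_fit), ("conf", cf_fit)):
                curve_rows.append(
                    {
                        "modality": mod, "coherence": coh, "delta_deg": delta,
                        "measure": name, "baseline": f.baseline,
                        "amplitude": f.amplitude, "center": f.center,
                        "width": f.width, "rmse": f.rmse, "flagged": f.flagged,
                    }
                )
    return {
        "psychometric": pd.DataFrame(psych_rows),
        "curves": pd.DataFrame(curve_rows),
        "weights": pd.DataFrame(weight_rows),
        "quantiles": confidence_by_rt_quantile(trials, n_quantiles=n_quantiles),
    }
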