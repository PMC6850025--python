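"""Progressive-Change BACIPS model selection.

A BACIPS analysis operates on the annual difference series delta_t between
the impact (heated) and control (reference) areas.  The progressive-change
extension fits four candidate shapes of the post-impact response,

    delta_t = beta0 + alpha * f(t),        f(t) = 0 before impact,

and for after-years with s = t - impact_year:

    step:        f = 1
    linear:      f = s
    asymptotic:  f = s / (s + gamma)
    sigmoid:     f = 1 / (1 + exp(-(s - tau) / gamma))

compared by small-sample corrected AIC (AICc) weights; the model with the
highest weight is the most parsimonious description of the impact.  The
step model is equivalent to the classical before/after t-test comparison:
its fitted alpha equals the after-mean minus before-mean of delta exactly.

Least squares throughout: step and linear in closed form; asymptotic and
sigmoid by profiling (beta0, alpha) over a shape-parameter grid
{0.5, 1, 2, 4, 8, 16} followed by full nonlinear refinement.  The error
variance counts as an estimated parameter in k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from warmgrowth.growthstats import DifferenceSeries

__all__ = [
    "MODEL_ORDER",
    "ImpactModelFit",
    "ModelComparison",
    "StationarityCheck",
    "TrendComparison",
    "fit_impact_model",
    "aicc",
    "akaike_weights",
    "compare_models",
    "test_stationarity",
    "compare_warming_trends",
]

MODEL_ORDER = ("step", "linear", "asymptotic", "sigmoid")

# mean-structure parameter count per model (beta0, alpha, shape...)
_N_MEAN_PARAMS = {"step": 2, "linear": 2, "asymptotic": 3, "sigmoid": 4}

_SHAPE_GRID = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)

RSS_FLOOR_PER_POINT = 1e-12  # floor on rss/n, prevents -inf AICc on exact fits


@dataclass
class ImpactModelFit:
    """One fitted impact-response model."""

    model: str
    params: dict
    k: int  # estimated parameters including the error variance
    rss: float
    n: int
    aicc: float
    fitted: np.ndarray = field(repr=False)
    converged: bool = True


@dataclass
class ModelComparison:
    """AICc-weight comparison across the candidate impact models."""

    fits: list
    delta_aicc: np.ndarray
    weights: np.ndarray
    best: ImpactModelFit
    r_squared: float
    p_value: float

    def summary(self) -> dict:
        return {
            "best_model": self.best.model,
            "weight": float(self.weights[self._best_index()]),
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "alpha": float(self.best.params.get("alpha", np.nan)),
        }

    def _best_index(self) -> int:
        return [f.model for f in self.fits].index(self.best.model)


@dataclass
class StationarityCheck:
    """Pre-impact trend test of the difference series."""

    slope: float
    p_value: float
    passed: bool
    alpha_level: float = 0.05
    n: int = 0


@dataclass
class TrendComparison:
    """Test for differing temperature trends between the two areas."""

    slope: float
    f_statistic: float
    p_value: float
    r_squared: float
    n: int


# ---------------------------------------------------------------------------
# model machinery
# ---------------------------------------------------------------------------


def _basis(model: str, s: np.ndarray, after: np.ndarray, shape: tuple) -> np.ndarray:
    """Regressor f(t); zero before impact."""
    f = np.zeros_like(s, dtype=float)
    sa = s[after]
    if model == "step":
        f[after] = 1.0
    elif model == "linear":
        f[after] = sa
    elif model == "asymptotic":
        (gamma,) = shape
        f[after] = sa / (sa + gamma)
    elif model == "sigmoid":
        tau, gamma = shape
        z = np.clip((sa - tau) / gamma, -50.0, 50.0)
        f[after] = 1.0 / (1.0 + np.exp(-z))
    else:
        raise ValueError(f"unknown model {model!r}")
    return f


def _profile_ls(delta: np.ndarray, f: np.ndarray) -> tuple[float, float, float]:
    """Closed-form LS of delta = beta0 + alpha*f; returns (beta0, alpha, rss)."""
    n = delta.size
    sf = f.sum()
    sff = float(f @ f)
    sd = delta.sum()
    sdf = float(f @ delta)
    det = n * sff - sf * sf
    if det <= 1e-12 * max(n * sff, 1.0):
        # degenerate regressor (f constant): alpha not identifiable
        beta0 = sd / n
        rss = float(((delta - beta0) ** 2).sum())
        return beta0, 0.0, rss
    alpha = (n * sdf - sf * sd) / det
    beta0 = (sd - alpha * sf) / n
    rss = float(((delta - beta0 - alpha * f) ** 2).sum())
    return beta0, alpha, rss


def fit_impact_model(
    series: DifferenceSeries, model_name: str, init_strategy: str = "grid"
) -> ImpactModelFit:
    """Least-squares fit of one candidate impact-response model.

    Step and linear are solved in closed form.  Asymptotic and sigmoid use
    multi-start initialization (profiled linear parameters over the shape
    grid) refined by ``scipy.optimize.least_squares``; a non-converged
    refinement is flagged on the returned fit, never silently replaced.
    """
    if model_name not in MODEL_ORDER:
        raise ValueError(f"unknown model {model_name!r}")
    delta = series.delta
    after = series.after
    s = (series.years - series.impact_year).astype(float)
    n = delta.size
    converged = True

    if model_name in ("step", "linear"):
        f = _basis(model_name, s, after, ())
        beta0, alpha, rss = _profile_ls(delta, f)
        params = {"beta0": beta0, "alpha": alpha}
        fitted = beta0 + alpha * f
    else:
        if model_name == "asymptotic":
            shapes = [(g,) for g in _SHAPE_GRID]
        else:
            shapes = [(t, g) for t in _SHAPE_GRID for g in _SHAPE_GRID]
        best = None
        for shape in shapes:
            f = _basis(model_name, s, after, shape)
            beta0, alpha, rss = _profile_ls(delta, f)
            if best is None or rss < best[0]:
                best = (rss, beta0, alpha, shape)
        rss, beta0, alpha, shape = best

        def residuals(theta):
            b0, a = theta[0], theta[1]
            f = _basis(model_name, s, after, tuple(theta[2:]))
            return delta - b0 - a * f

        # identifiability bounds: the asymptotic half-saturation time and the
        # sigmoid transition width cannot be resolved below the annual
        # sampling step (an arbitrarily sharp sigmoid would duplicate the
        # step candidate and chase single-year noise), and the sigmoid
        # inflection must lie in or near the observed post-impact window
        s_max = float(s[after].max()) if after.any() else 1.0
        if model_name == "asymptotic":
            lower, upper = [-np.inf, -np.inf, 0.5], [np.inf, np.inf, 100.0]
        else:
            lower = [-np.inf, -np.inf, 0.0, 1.0]
            upper = [np.inf, np.inf, s_max + 5.0, 50.0]
        shape = tuple(np.clip(shape, lower[2:], upper[2:]))
        f = _basis(model_name, s, after, shape)
        beta0, alpha, rss = _profile_ls(delta, f)
        x0 = np.array([beta0, alpha, *shape])
        try:
            res = optimize.least_squares(
                residuals, x0, bounds=(lower, upper), method="trf", xtol=1e-14,
                ftol=1e-14, gtol=1e-14, max_nfev=400,
            )
            refined_rss = float(res.fun @ res.fun)
            if refined_rss <= rss + 1e-12:
                beta0, alpha = res.x[0], res.x[1]
                shape = tuple(res.x[2:])
                rss = refined_rss
            converged = bool(res.success)
        except Exception:
            converged = False
        if model_name == "asymptotic":
            params = {"beta0": beta0, "alpha": alpha, "gamma": shape[0]}
        else:
            params = {"beta0": beta0, "alpha": alpha, "tau": shape[0], "gamma": shape[1]}
        fitted = beta0 + alpha * _basis(model_name, s, after, shape)

    k = _N_MEAN_PARAMS[model_name] + 1  # + error variance
    return ImpactModelFit(
        model=model_name,
        params=params,
        k=k,
        rss=rss,
        n=n,
        aicc=aicc(rss, n, k),
        fitted=fitted,
        converged=converged,
    )


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected AIC for a Gaussian least-squares fit.

    AICc = n*ln(max(rss, eps)/n) + 2k + 2k(k+1)/(n-k-1), with the RSS
    floored at ``RSS_FLOOR_PER_POINT * n`` so exact fits stay finite.
    """
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    rss = max(rss, RSS_FLOOR_PER_POINT * n)
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights: w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one AICc value")
    d = a - a.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def compare_models(
    series: DifferenceSeries, models: tuple = MODEL_ORDER, alpha_level: float = 0.05
) -> ModelComparison:
    """Fit all candidate models, select by Akaike weight, test the best.

    R^2 is 1 - RSS/TSS of the best model; the p-value is an F-test of the
    best model against the constant-difference null (equivalently the
    slope t-test for the linear model and the t-test for the step model).
    Ties in AICc break toward fewer parameters, then canonical model
    order.  Comparison requires at least two converged fits.
    """
    fits = [fit_impact_model(series, m) for m in models]
    ok = [f for f in fits if f.converged]
    if len(ok) < 2:
        raise RuntimeError("fewer than two candidate models converged")
    a = np.array([f.aicc for f in ok])
    weights = akaike_weights(a)
    delta_aicc = a - a.min()
    # best: max weight; ties toward fewer parameters, then canonical order
    order = sorted(
        range(len(ok)),
        key=lambda i: (-weights[i], ok[i].k, MODEL_ORDER.index(ok[i].model)),
    )
    best = ok[order[0]]

    delta = series.delta
    tss = float(((delta - delta.mean()) ** 2).sum())
    rss = best.rss
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    q = _N_MEAN_PARAMS[best.model] - 1
    df2 = best.n - _N_MEAN_PARAMS[best.model]
    if rss <= RSS_FLOOR_PER_POINT * best.n:
        p = 0.0 if tss > rss else 1.0
    elif tss <= rss:
        p = 1.0
    else:
        f_stat = ((tss - rss) / q) / (rss / df2)
        p = float(stats.f.sf(f_stat, q, df2))

    # weights/delta reported in the order fits were made (converged only)
    return ModelComparison(
        fits=ok,
        delta_aicc=delta_aicc,
        weights=weights,
        best=best,
        r_squared=r2,
        p_value=p,
    )


def test_stationarity(
    series: DifferenceSeries, alpha_level: float = 0.05
) -> StationarityCheck:
    """OLS trend test of delta on year over the before-impact years.

    The BACIPS design assumes the difference series is stationary before
    impact; the check passes when the pre-impact slope is not significant.
    """
    mask = ~series.after
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 before-impact years for the stationarity check, "
            f"found {int(mask.sum())}"
        )
    fit = stats.linregress(series.years[mask].astype(float), series.delta[mask])
    p_value = float(fit.pvalue)
    if not np.isfinite(p_value):
        # degenerate (exactly collinear) before-period: an exactly zero
        # slope is trivially stationary, a nonzero exact trend is not
        p_value = 1.0 if abs(fit.slope) < 1e-12 else 0.0
    return StationarityCheck(
        slope=float(fit.slope),
        p_value=p_value,
        passed=bool(p_value >= alpha_level),
        alpha_level=alpha_level,
        n=int(mask.sum()),
    )


def compare_warming_trends(
    temp_heated, temp_reference, years=None
) -> TrendComparison:
    """Test whether the two areas warm at different rates.

    OLS of the annual heated-minus-reference temperature difference on
    year, over the common years (optionally restricted to ``years``, e.g.
    the post-impact window).  Reports the slope's F statistic, p-value and
    r^2; a non-significant slope supports the paired design's assumption
    that background warming is shared.
    """
    h = temp_heated.temps if hasattr(temp_heated, "temps") else pd.Series(temp_heated)
    r = (
        temp_reference.temps
        if hasattr(temp_reference, "temps")
        else pd.Series(temp_reference)
    )
    diff = (h - r).dropna()
    if years is not None:
        diff = diff[diff.index.isin(list(years))]
    if len(diff) < 4:
        raise ValueError(f"need >= 4 common years, found {len(diff)}")
    fit = stats.linregress(diff.index.to_numpy(dtype=float), diff.to_numpy())
    f_stat = float(fit.slope / fit.stderr) ** 2 if fit.stderr > 0 else np.inf
    return TrendComparison(
        slope=float(fit.slope),
        f_statistic=f_stat,
        p_value=float(fit.pvalue),
        r_squared=float(fit.rvalue**2),
        n=len(diff),
    )
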