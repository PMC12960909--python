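"""Molecular-clock model fitting and AICc model selection.

Two stochastic models describe how mutation counts spread through a
population over time t (measured in interval units):

* null (Brownian / normal diffusion):       <m(t)> = m0 + kappa*t,
  Var m(t) = D*t
* challenging (fractional Brownian motion): <m(t)> = m0 + kappa*t,
  Var m(t) = D*t**alpha

Both share the mean structure, so the evolution rate kappa and initial
mutational load m0 come from a single weighted straight-line fit to the
per-bin means. The models differ only in the variance law. Before fitting,
the variance series is rescaled — the initial variance sigma0^2 is subtracted
and time shifted so the series starts at (0, 0) — because the stochastic
processes assume a sharp initial condition while real populations start with
standing variation.

The null diffusivity D is the weighted through-origin slope of the rescaled
variance; the challenging (D, alpha) come from weighted nonlinear least
squares on D*t**alpha via Levenberg-Marquardt. The winner is the model with
the smaller corrected Akaike information criterion

    AICc_i = n*ln(2*pi) + n*ln(RSS_i/n) + n + 2*p_i + 2*p_i*(p_i+1)/(n-p_i-1)

with RSS_i the *weighted* residual sum of squares, p_1=1 and p_2=2, and n the
number of variance points. Both RSS values are computed over the identical
point set (t > 0, since t=0 carries no information about a power law), so the
comparison is valid. Exact ties go to the simpler null model, as does a
challenging fit that fails to converge.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import DegenerateInputError, InsufficientDataError
from .stats_binning import BinnedSeries

__all__ = [
    "ConfidenceInterval",
    "MeanFit",
    "RescaledVariance",
    "NullVarianceFit",
    "PowerLawFit",
    "ModelParams",
    "ModelFit",
    "SelectionResult",
    "ClockAnalysis",
    "fit_mean",
    "rescale_variance",
    "fit_variance_null",
    "fit_variance_challenging",
    "aicc",
    "select_model",
    "analyze_series",
]

logger = logging.getLogger(__name__)

CONFIDENCE_LEVEL = 0.95


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float = CONFIDENCE_LEVEL

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    def to_list(self) -> list[float]:
        return [self.lower, self.upper]


@dataclass
class MeanFit:
    """Weighted straight-line fit mu_k ~ m0 + kappa * t_k."""

    kappa: float
    kappa_ci: ConfidenceInterval
    m0: float
    m0_ci: ConfidenceInterval
    n: int


@dataclass
class RescaledVariance:
    """Variance series shifted to start at (t, sigma2) = (0, 0)."""

    t: np.ndarray
    y: np.ndarray
    w: np.ndarray
    sigma2_0: float
    t0: float

    def pairs(self) -> list[tuple[float, float]]:
        return list(zip(self.t.tolist(), self.y.tolist()))


@dataclass
class NullVarianceFit:
    D: float
    D_ci: ConfidenceInterval
    rss_weighted: float
    n: int


@dataclass
class PowerLawFit:
    D: float
    D_ci: ConfidenceInterval
    alpha: float
    alpha_ci: ConfidenceInterval
    rss_weighted: float
    n: int
    converged: bool = True


@dataclass
class ModelParams:
    kappa: float
    m0: float
    D: float
    alpha: float  # fixed at 1 for the null model
    sigma2_0: float


@dataclass
class ModelFit:
    model: str  # "null" | "challenging"
    params: ModelParams
    cis: dict[str, ConfidenceInterval]
    rss_weighted: float
    n: int
    p: int
    aicc: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {
                "kappa": self.params.kappa,
                "m0": self.params.m0,
                "D": self.params.D,
                "alpha": self.params.alpha,
                "sigma2_0": self.params.sigma2_0,
            },
            "ci95": {k: ci.to_list() for k, ci in self.cis.items()},
            "rss_weighted": self.rss_weighted,
            "n": self.n,
            "p": self.p,
            "aicc": self.aicc,
            "warnings": list(self.warnings),
        }


@dataclass
class SelectionResult:
    null_fit: ModelFit
    challenging_fit: ModelFit
    selected: str
    delta_aicc: float  # aicc(unselected) - aicc(selected), >= 0

    def selected_fit(self) -> ModelFit:
        return self.null_fit if self.selected == "null" else self.challenging_fit

    def to_dict(self) -> dict:
        return {
            "null": self.null_fit.to_dict(),
            "challenging": self.challenging_fit.to_dict(),
            "selected": self.selected,
            "delta_aicc": self.delta_aicc,
        }


@dataclass
class ClockAnalysis:
    """Everything inferred for one mutation category."""

    category: str
    mean_fit: MeanFit
    rescaled: RescaledVariance
    selection: SelectionResult

    def to_dict(self) -> dict:
        d = self.selection.to_dict()
        d["category"] = self.category
        d["mean_fit"] = {
            "kappa": self.mean_fit.kappa,
            "kappa_ci95": self.mean_fit.kappa_ci.to_list(),
            "m0": self.mean_fit.m0,
            "m0_ci95": self.mean_fit.m0_ci.to_list(),
            "n": self.mean_fit.n,
        }
        return d


def _t_ci(estimate: float, se: float, df: int) -> ConfidenceInterval:
    tval = stats.t.ppf(0.5 + CONFIDENCE_LEVEL / 2, df)
    return ConfidenceInterval(estimate - tval * se, estimate + tval * se)


def fit_mean(series: BinnedSeries) -> MeanFit:
    """Weighted least-squares line through (t_k, mu_k): slope kappa, intercept m0.

    95% CIs use the t distribution with n-2 degrees of freedom and weighted
    standard errors.
    """
    t = np.array([b.t for b in series.bins])
    mu = np.array([b.mu for b in series.bins])
    w = np.array([b.w for b in series.bins])
    if t.size < 3:
        raise InsufficientDataError(f"mean fit needs >= 3 bins, got {t.size}")
    res = sm.WLS(mu, sm.add_constant(t), weights=w).fit()
    m0, kappa = res.params
    se_m0, se_kappa = res.bse
    df = int(res.df_resid)
    return MeanFit(
        kappa=float(kappa),
        kappa_ci=_t_ci(float(kappa), float(se_kappa), df),
        m0=float(m0),
        m0_ci=_t_ci(float(m0), float(se_m0), df),
        n=int(t.size),
    )


def rescale_variance(series: BinnedSeries) -> RescaledVariance:
    """Subtract the initial variance and shift time so the series starts at (0,0).

    sigma0^2 is the variance of the earliest bin that has one defined (the
    first bin may hold a single sample). Negative rescaled values are
    retained — clamping them would bias the diffusivity downward.
    """
    vbins = series.variance_bins()
    if len(vbins) < 3:
        raise InsufficientDataError(
            f"variance rescaling needs >= 3 variance bins, got {len(vbins)}"
        )
    t0, sigma2_0 = vbins[0].t, vbins[0].sigma2
    t = np.array([b.t - t0 for b in vbins])
    y = np.array([b.sigma2 - sigma2_0 for b in vbins])
    w = np.array([b.w for b in vbins])
    return RescaledVariance(t=t, y=y, w=w, sigma2_0=float(sigma2_0), t0=float(t0))


def fit_variance_null(
    t: np.ndarray, y: np.ndarray, w: np.ndarray
) -> NullVarianceFit:
    """Weighted through-origin regression y ~ D * t.

    Closed form D = sum(w t y) / sum(w t^2); CI from the t distribution with
    n-1 degrees of freedom.
    """
    t, y, w = map(np.asarray, (t, y, w))
    if t.size < 2:
        raise InsufficientDataError("through-origin fit needs >= 2 points")
    if np.all(t == 0):
        raise DegenerateInputError("all time points are zero; slope unidentifiable")
    res = sm.WLS(y, t[:, None], weights=w).fit()
    D = float(res.params[0])
    rss = float(np.sum(w * (y - D * t) ** 2))
    return NullVarianceFit(
        D=D,
        D_ci=_t_ci(D, float(res.bse[0]), int(res.df_resid)),
        rss_weighted=rss,
        n=int(t.size),
    )


def _power_law(t: np.ndarray, D: float, alpha: float) -> np.ndarray:
    return D * np.power(t, alpha)


def fit_variance_challenging(
    t: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    d_init: float | None = None,
) -> PowerLawFit:
    """Weighted power-law fit y ~ D * t**alpha by Levenberg-Marquardt.

    Points at t=0 contribute no information about a power law and must be
    excluded by the caller. Initialized at the null-model slope and alpha=1.
    Standard errors come from the estimated covariance of the nonlinear fit;
    CIs use the t distribution with n-2 degrees of freedom. alpha is
    unconstrained; alpha <= 0 or alpha > 3 is flagged as degenerate by the
    selection layer. Non-convergence returns ``converged=False`` with
    infinite RSS so selection falls back to the null model.
    """
    t, y, w = map(np.asarray, (t, y, w))
    if np.any(t <= 0):
        raise DegenerateInputError("power-law fit requires strictly positive times")
    if t.size < 3:
        raise InsufficientDataError("power-law fit needs >= 3 points")
    if d_init is None:
        d_init = float(np.sum(w * t * y) / np.sum(w * t * t))
        if not math.isfinite(d_init) or d_init <= 0:
            d_init = 1.0
    nan_ci = ConfidenceInterval(math.nan, math.nan)
    try:
        popt, pcov = optimize.curve_fit(
            _power_law,
            t,
            y,
            p0=[d_init, 1.0],
            sigma=1.0 / np.sqrt(w),
            absolute_sigma=False,
            method="lm",
            maxfev=10000,
        )
    except RuntimeError as exc:
        logger.warning("power-law fit did not converge: %s", exc)
        return PowerLawFit(
            D=math.nan, D_ci=nan_ci, alpha=math.nan, alpha_ci=nan_ci,
            rss_weighted=math.inf, n=int(t.size), converged=False,
        )
    D, alpha = map(float, popt)
    rss = float(np.sum(w * (y - _power_law(t, D, alpha)) ** 2))
    se = np.sqrt(np.diag(pcov))
    df = int(t.size) - 2
    if not np.all(np.isfinite(se)):
        d_ci = alpha_ci = nan_ci
    else:
        d_ci = _t_ci(D, float(se[0]), df)
        alpha_ci = _t_ci(alpha, float(se[1]), df)
    return PowerLawFit(
        D=D, D_ci=d_ci, alpha=alpha, alpha_ci=alpha_ci,
        rss_weighted=rss, n=int(t.size), converged=True,
    )


def aicc(rss_weighted: float, n: int, p: int) -> float:
    """Corrected Akaike information criterion for a least-squares fit.

    Returns -inf when RSS is exactly 0 (perfect fit sentinel).
    """
    if n <= p + 1:
        raise InsufficientDataError(
            f"AICc undefined for n={n}, p={p} (needs n > p + 1)"
        )
    if rss_weighted < 0:
        raise DegenerateInputError("negative residual sum of squares")
    if rss_weighted == 0:
        return -math.inf
    return (
        n * math.log(2 * math.pi)
        + n * math.log(rss_weighted / n)
        + n
        + 2 * p
        + 2 * p * (p + 1) / (n - p - 1)
    )


def select_model(null_fit: ModelFit, challenging_fit: ModelFit) -> SelectionResult:
    """Pick the model with smaller AICc; ties and failed fits go to null."""
    if null_fit.n != challenging_fit.n:
        raise DegenerateInputError(
            "AICc comparison requires both fits on the same point set"
        )
    if challenging_fit.aicc < null_fit.aicc:
        selected, delta = "challenging", null_fit.aicc - challenging_fit.aicc
    else:
        selected, delta = "null", challenging_fit.aicc - null_fit.aicc
    return SelectionResult(
        null_fit=null_fit,
        challenging_fit=challenging_fit,
        selected=selected,
        delta_aicc=float(delta),
    )


def analyze_series(series: BinnedSeries) -> ClockAnalysis:
    """Full inference for one binned category: mean fit, both variance fits,
    AICc selection."""
    mean = fit_mean(series)
    rv = rescale_variance(series)
    positive = rv.t > 0
    t, y, w = rv.t[positive], rv.y[positive], rv.w[positive]
    if t.size < 4:
        raise InsufficientDataError(
            f"model selection needs >= 4 positive-time variance points, got {t.size}"
        )
    null = fit_variance_null(t, y, w)
    chal = fit_variance_challenging(t, y, w, d_init=null.D)

    null_warnings: list[str] = []
    if null.D < 0:
        null_warnings.append("fitted diffusivity is negative (degenerate)")
    null_fit = ModelFit(
        model="null",
        params=ModelParams(
            kappa=mean.kappa, m0=mean.m0, D=null.D, alpha=1.0, sigma2_0=rv.sigma2_0
        ),
        cis={"kappa": mean.kappa_ci, "m0": mean.m0_ci, "D": null.D_ci},
        rss_weighted=null.rss_weighted,
        n=null.n,
        p=1,
        aicc=aicc(null.rss_weighted, null.n, 1),
        warnings=null_warnings,
    )

    chal_warnings: list[str] = []
    if not chal.converged:
        chal_warnings.append(
            "Levenberg-Marquardt did not converge; selection falls back to null"
        )
    elif chal.alpha <= 0 or chal.alpha > 3:
        chal_warnings.append(
            f"fitted diffusion exponent alpha={chal.alpha:.3g} outside (0, 3] (degenerate)"
        )
    if chal.converged and chal.D < 0:
        chal_warnings.append("fitted diffusivity is negative (degenerate)")
    chal_fit = ModelFit(
        model="challenging",
        params=ModelParams(
            kappa=mean.kappa, m0=mean.m0, D=chal.D, alpha=chal.alpha,
            sigma2_0=rv.sigma2_0,
        ),
        cis={
            "kappa": mean.kappa_ci,
            "m0": mean.m0_ci,
            "D": chal.D_ci,
            "alpha": chal.alpha_ci,
        },
        rss_weighted=chal.rss_weighted,
        n=chal.n,
        p=2,
        aicc=(
            aicc(chal.rss_weighted, chal.n, 2) if chal.converged else math.inf
        ),
        warnings=chal_warnings,
    )
    return ClockAnalysis(
        category=series.category,
        mean_fit=mean,
        rescaled=rv,
        selection=select_model(null_fit, chal_fit),
    )
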