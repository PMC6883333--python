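"""Monoculture/co-culture interaction strengths and growth-curve fitting.

When two organisms are phenotyped both in isolation (monoculture values
``u_L``, ``u_S``) and together (co-culture values ``w_L >= w_S``, which
defines the L/S labels), the change from isolation to co-culture measures
the strength of their interaction directly:

* ``M_u = (w_L/u_L + w_S/u_S) / 2`` — mutualism strength: the mean relative
  phenotype change; above 1 the pair cooperates, below 1 it competes;
* ``A_g = (w_L/w_S) / (u_L/u_S)`` — L's aggression toward S: how much the
  size ratio widens in co-culture;
* ``A_l = (w_S/u_S) / (w_L/u_L)`` — L's altruism toward S; identically
  ``1 / A_g``.

These strengths serve to validate the descriptor-only measures of
:mod:`socialqtl.descriptors` (which need no monoculture arm): the pairwise
descriptors ``z_ag``, ``z_mu``, ``z_al`` should correlate with ``A_g``,
``M_u``, ``A_l`` across pairs.  For microbial time-series data the
comparison is made per growth phase, obtained by fitting a growth law to
each strain's abundance series and partitioning it into lag, linear and
asymptotic phases at the extrema of the fitted curve's second derivative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CocultureRecord",
    "mutualism_strength",
    "aggression_strength",
    "altruism_strength",
    "GrowthCurveModel",
    "GrowthCurveResults",
    "GrowthFitError",
    "partition_phases",
    "descriptor_strength_correlation",
]


@dataclass(frozen=True)
class CocultureRecord:
    """Paired monoculture/co-culture phenotypes for one pair.

    L and S are labelled by the *co-culture* phenotypes (``w_L >= w_S``);
    ``u_L`` need not exceed ``u_S``.
    """

    u_L: float
    u_S: float
    w_L: float
    w_S: float

    def __post_init__(self):
        for name in ("u_L", "u_S", "w_L", "w_S"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name}={v!r} must be positive and finite")
        if self.w_L < self.w_S:
            raise ValueError(
                f"w_L={self.w_L} < w_S={self.w_S}: L/S labels are assigned "
                "by co-culture phenotype"
            )


def mutualism_strength(rec: CocultureRecord) -> float:
    """M_u = (w_L/u_L + w_S/u_S)/2; >1 cooperation, <1 competition."""
    return (rec.w_L / rec.u_L + rec.w_S / rec.u_S) / 2.0


def aggression_strength(rec: CocultureRecord) -> float:
    """A_g = (w_L/w_S)/(u_L/u_S): widening of the size ratio in co-culture."""
    return (rec.w_L / rec.w_S) / (rec.u_L / rec.u_S)


def altruism_strength(rec: CocultureRecord) -> float:
    """A_l = (w_S/u_S)/(w_L/u_L) = 1/A_g exactly."""
    return (rec.w_S / rec.u_S) / (rec.w_L / rec.u_L)


# ---------------------------------------------------------------------------
# growth-curve fitting
# ---------------------------------------------------------------------------

class GrowthFitError(RuntimeError):
    """Raised when no restart converges; carries the best RSS reached."""

    def __init__(self, message: str, best_rss: float):
        super().__init__(message)
        self.best_rss = best_rss


def _logistic(t, a, b, r):
    return a / (1.0 + b * np.exp(-r * t))


def _gompertz(t, a, b, r):
    return a * np.exp(-b * np.exp(-r * t))


_MODELS = {"logistic": _logistic, "gompertz": _gompertz}


class GrowthCurveModel:
    """Sigmoidal growth model for a time-abundance series.

    The default growth law is the logistic ``g(t) = a / (1 + b e^(-r t))``
    with asymptote ``a`` (abundance units), shape ``b > 0`` and rate
    ``r > 0`` (per time unit); a Gompertz alternative is selectable and
    ``select_model`` picks between them by AIC.

    Parameters
    ----------
    times, abundance
        Observation times and nonnegative abundances; at least 5 points.
    model
        ``"logistic"`` (default) or ``"gompertz"``.
    """

    def __init__(self, times, abundance, model: str = "logistic"):
        self.times = np.asarray(times, dtype=float)
        self.abundance = np.asarray(abundance, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.abundance.shape:
            raise ValueError("times and abundance must be 1-D and equal length")
        if self.times.size < 5:
            raise ValueError("need at least 5 time points to fit a growth curve")
        if np.any(self.abundance < 0):
            raise ValueError("abundance must be nonnegative")
        if model not in _MODELS:
            raise ValueError(f"unknown growth model {model!r}")
        self.model = model
        self._fun = _MODELS[model]

    def _initial_guesses(self, rng: np.random.Generator, n_restarts: int):
        t, y = self.times, self.abundance
        a0 = max(y.max(), 1e-12) * 1.05
        span = t.max() - t.min() or 1.0
        r0 = 4.0 / span
        # b from the midpoint crossing: g(t_mid) = a/2 -> b = e^{r t_mid}
        mid = t[np.argmin(np.abs(y - a0 / 2.0))]
        b0 = float(np.exp(np.clip(r0 * mid, -50, 50)))
        guesses = [(a0, b0, r0)]
        for _ in range(n_restarts):
            guesses.append((
                a0 * rng.uniform(0.8, 1.5),
                b0 * rng.uniform(0.2, 5.0) + 1e-6,
                r0 * rng.uniform(0.2, 5.0),
            ))
        return guesses

    def fit(self, init_strategy: str = "auto", seed: int = 0,
            n_restarts: int = 8) -> "GrowthCurveResults":
        """Bounded least squares with a data-driven start plus restarts.

        Deterministic for fixed ``seed`` and data.  Raises
        :class:`GrowthFitError` when no restart converges.
        """
        if init_strategy not in ("auto",):
            raise ValueError(f"unknown init strategy {init_strategy!r}")
        rng = np.random.default_rng(seed)
        t, y = self.times, self.abundance
        yscale = max(float(np.ptp(y)), 1e-12)

        def resid(p):
            return self._fun(t, *p) - y

        lower = np.array([1e-12, 1e-12, 1e-9])
        upper = np.array([np.inf, np.inf, np.inf])
        best = None
        for guess in self._initial_guesses(rng, n_restarts):
            try:
                sol = optimize.least_squares(
                    resid, np.clip(guess, lower, upper), bounds=(lower, upper),
                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:  # singular jacobian etc.
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success:
            rss = 2 * best.cost if best is not None else float("inf")
            raise GrowthFitError("growth-curve fit did not converge", rss)
        a, b, r = best.x
        rss = float(2 * best.cost)
        # constant series / no sigmoidal signal: rate pinned at its floor or
        # the fit no better than a flat mean
        rss_const = float(np.sum((y - y.mean()) ** 2))
        degenerate = bool(r <= 1e-8 or rss >= rss_const * (1 - 1e-9))
        return GrowthCurveResults(self, a=a, b=b, r=r, rss=rss,
                                  degenerate=degenerate)

    @staticmethod
    def select_model(times, abundance, candidates=("logistic", "gompertz"),
                     seed: int = 0) -> "GrowthCurveResults":
        """Fit each candidate growth law and keep the lowest-AIC fit."""
        times = np.asarray(times, dtype=float)
        best = None
        for name in candidates:
            try:
                res = GrowthCurveModel(times, abundance, model=name).fit(seed=seed)
            except GrowthFitError:
                continue
            if best is None or res.aic < best.aic:
                best = res
        if best is None:
            raise GrowthFitError("no candidate growth model converged",
                                 float("inf"))
        return best


@dataclass
class GrowthCurveResults:
    """Fitted growth curve with its phase decomposition."""

    model: GrowthCurveModel
    a: float
    b: float
    r: float
    rss: float
    degenerate: bool = False

    @property
    def nobs(self) -> int:
        return self.model.times.size

    @property
    def aic(self) -> float:
        n = self.nobs
        return n * np.log(max(self.rss, 1e-300) / n) + 2 * 3

    @property
    def t_inflection(self) -> float:
        """Time of maximum growth rate: ln(b)/r for the logistic."""
        if self.model.model == "logistic":
            return float(np.log(self.b) / self.r)
        return self._numeric_infl()

    def _numeric_infl(self) -> float:
        t = np.linspace(self.model.times.min(), self.model.times.max(), 2001)
        g = self.predict(t)
        return float(t[np.argmax(np.gradient(g, t))])

    def predict(self, times) -> np.ndarray:
        return self.model._fun(np.asarray(times, dtype=float),
                               self.a, self.b, self.r)

    def summary(self) -> str:
        lag, asym = partition_phases(self)
        lines = [
            f"Growth-curve fit ({self.model.model}), n={self.nobs}",
            f"  a (asymptote) = {self.a:.6g}",
            f"  b (shape)     = {self.b:.6g}",
            f"  r (rate)      = {self.r:.6g}",
            f"  rss           = {self.rss:.6g}",
            f"  inflection t  = {self.t_inflection:.6g}",
            f"  lag ends      = {lag:.6g}",
            f"  asymptotic from {asym:.6g}",
        ]
        if self.degenerate:
            lines.append("  [degenerate fit: no sigmoidal signal]")
        return "\n".join(lines)


#: half-width factor of the linear phase: the logistic second derivative has
#: extrema at t_infl +/- ln(2+sqrt(3))/r.
_PHASE_HALF_WIDTH = float(np.log(2.0 + np.sqrt(3.0)))


def partition_phases(fit: GrowthCurveResults) -> tuple[float, float]:
    """Phase boundaries (end of lag, start of asymptote) of a fitted curve.

    Boundaries sit at the extrema of the fitted curve's second derivative;
    for the logistic these are ``ln(b)/r ± ln(2+sqrt(3))/r`` in closed form,
    for other growth laws they are located numerically.
    """
    if fit.model.model == "logistic":
        t_infl = np.log(fit.b) / fit.r
        half = _PHASE_HALF_WIDTH / fit.r
        return float(t_infl - half), float(t_infl + half)
    t = np.linspace(fit.model.times.min(), fit.model.times.max(), 4001)
    g = fit.predict(t)
    d2 = np.gradient(np.gradient(g, t), t)
    return float(t[np.argmax(d2)]), float(t[np.argmin(d2)])


def label_phases(fit: GrowthCurveResults, times) -> np.ndarray:
    """Assign each observation time to 'lag', 'linear' or 'asymptotic'."""
    lag_end, asym_start = partition_phases(fit)
    times = np.asarray(times, dtype=float)
    labels = np.where(times < lag_end, "lag",
                      np.where(times <= asym_start, "linear", "asymptotic"))
    return labels


# ---------------------------------------------------------------------------
# descriptor vs strength correlation
# ---------------------------------------------------------------------------

_PAIRINGS = [("z_ag", "A_g"), ("z_mu", "M_u"), ("z_al", "A_l")]


def descriptor_strength_correlation(
    records: pd.DataFrame,
    method: str = "pearson",
    min_per_stratum: int = 3,
) -> pd.DataFrame:
    """Correlate pairwise descriptors with co-culture interaction strengths.

    ``records`` needs columns ``z_ag, z_mu, z_al, A_g, M_u, A_l`` and
    optionally ``phase``; one row per pair (or pair x time point).  Returns
    a table with one row per (phase | pooled) x descriptor pairing carrying
    the correlation coefficient and its two-sided p value.  Strata with
    fewer than ``min_per_stratum`` complete records are skipped with a
    warning.
    """
    if method == "pearson":
        corr = stats.pearsonr
    elif method == "spearman":
        corr = stats.spearmanr
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    strata = [("pooled", records)]
    if "phase" in records.columns:
        strata += [(str(ph), sub) for ph, sub in records.groupby("phase")]

    rows = []
    for name, sub in strata:
        for z_col, s_col in _PAIRINGS:
            if z_col not in sub.columns or s_col not in sub.columns:
                continue
            ok = sub[[z_col, s_col]].dropna()
            if len(ok) < min_per_stratum:
                warnings.warn(
                    f"stratum {name!r}: only {len(ok)} records for "
                    f"{z_col} vs {s_col}; skipped"
                )
                continue
            r, p = corr(ok[z_col], ok[s_col])
            rows.append((name, z_col, s_col, len(ok), float(r), float(p)))
    return pd.DataFrame(
        rows, columns=["stratum", "descriptor", "strength", "n", "r", "p"]
    )
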