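"""Bi-substrate steady-state kinetics: Michaelis-Menten fits, mechanism
discrimination and constant extraction for an acetyltransferase.

The sequential (ternary-complex) rate law for histidine (S) and acetyl-CoA
(A) is

    v0 = Vmax * S * A / (Ki_His * Km_AcCoA + Km_AcCoA * S + Km_His * A + S * A)

At each fixed A the law collapses to a Michaelis-Menten curve in S with

    Vmax_app(A) = Vmax * A / (Km_AcCoA + A)
    Km_app(A)   = (Ki_His * Km_AcCoA + Km_His * A) / (Km_AcCoA + A)

Hanes primary plots (S/v0 vs S, slope 1/Vmax_app, intercept
Km_app/Vmax_app) for different fixed A intersect at S = -Ki_His for a
sequential mechanism but on the ordinate axis (S = 0) for a substituted-
enzyme (ping-pong) mechanism, which is how the mechanism is called.  True
constants then come from double-reciprocal secondary plots: OLS of
1/Vmax_app on 1/A gives Vmax and Km_AcCoA, and OLS of Km_app/Vmax_app on
1/A gives Km_His (intercept * Vmax) plus a slope-derived Ki_His estimate.
kcat is Vmax divided by the total enzyme concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TernaryModel",
    "MMFit",
    "HanesLine",
    "MechanismCall",
    "SecondaryFitResult",
    "KineticConstants",
    "MichaelisMentenRegressor",
    "TernaryGlobalFit",
    "ternary_rate",
    "ping_pong_rate",
    "fit_mm",
    "hanes_transform",
    "classify_mechanism",
    "exclude_inhibited_series",
    "secondary_vmax_fit",
    "secondary_km_his_fit",
    "global_fit_ternary",
    "compare_routes",
    "estimate_constants",
]


# ---------------------------------------------------------------------------
# rate laws

@dataclass(frozen=True)
class TernaryModel:
    """Four-parameter sequential (ternary-complex) rate law.

    Parameters are Vmax (µM/s), Km_AcCoA (µM), Km_His (µM) and Ki_His (µM),
    the dissociation-type constant of histidine from the binary enzyme-His
    complex.
    """

    vmax: float
    km_accoa: float
    km_his: float
    ki_his: float

    def __post_init__(self) -> None:
        for name in ("vmax", "km_accoa", "km_his", "ki_his"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @classmethod
    def from_kcat(
        cls, kcat: float, enzyme_uM: float, km_accoa: float, km_his: float,
        ki_his: float,
    ) -> "TernaryModel":
        """Build from turnover number (s^-1) and enzyme concentration (µM)."""
        return cls(kcat * enzyme_uM, km_accoa, km_his, ki_his)

    def rate(self, his, accoa):
        """Initial rate v0 (µM/s) at the given substrate concentrations (µM)."""
        return ternary_rate(self, his, accoa)

    def vmax_app(self, accoa):
        """Apparent Vmax at fixed Ac-CoA: Vmax * A / (Km_AcCoA + A)."""
        accoa = np.asarray(accoa, dtype=float)
        out = self.vmax * accoa / (self.km_accoa + accoa)
        return out if np.ndim(out) else float(out)

    def km_app(self, accoa):
        """Apparent His Km at fixed Ac-CoA."""
        accoa = np.asarray(accoa, dtype=float)
        out = (self.ki_his * self.km_accoa + self.km_his * accoa) / (
            self.km_accoa + accoa
        )
        return out if np.ndim(out) else float(out)


def ternary_rate(model: TernaryModel, his, accoa):
    """Evaluate the sequential rate law; his/accoa in µM, result in µM/s."""
    s = np.asarray(his, dtype=float)
    a = np.asarray(accoa, dtype=float)
    if np.any(s < 0) or np.any(a < 0):
        raise ValueError("substrate concentrations must be >= 0")
    denom = (
        model.ki_his * model.km_accoa
        + model.km_accoa * s
        + model.km_his * a
        + s * a
    )
    v = model.vmax * s * a / denom
    return v if np.ndim(v) else float(v)


def ping_pong_rate(vmax: float, km_accoa: float, km_s: float, his, accoa):
    """Substituted-enzyme (ping-pong) rate law, used as a contrast mechanism.

    v = Vmax*S*A / (Km_A*S + Km_S*A + S*A); its Hanes lines share the
    ordinate intercept Km_S/Vmax.
    """
    s = np.asarray(his, dtype=float)
    a = np.asarray(accoa, dtype=float)
    v = vmax * s * a / (km_accoa * s + km_s * a + s * a)
    return v if np.ndim(v) else float(v)


# ---------------------------------------------------------------------------
# Michaelis-Menten fit at one fixed co-substrate concentration

@dataclass
class MMFit:
    """Apparent Michaelis-Menten parameters at one fixed Ac-CoA concentration."""

    accoa_fixed: float
    vmax_app: float
    km_app: float
    vmax_app_se: float = np.nan
    km_app_se: float = np.nan
    n_points: int = 0
    series: str = ""
    excluded: bool = False
    exclusion_reason: str = ""


class MichaelisMentenRegressor(RegressorMixin, BaseEstimator):
    """Unweighted nonlinear least-squares fit of v = Vmax*S / (Km + S).

    scikit-learn style: ``fit(X, y)`` with X a single column of substrate
    concentrations (µM) and y the initial rates (µM/s).  Fitted attributes
    are ``vmax_app_``, ``km_app_`` and their standard errors.

    Parameters
    ----------
    weighted : bool
        If True, weight residuals by 1/v (off by default; the study's fits
        were plain least squares and reciprocal weighting distorts the error
        structure of transformed data).
    """

    def __init__(self, weighted: bool = False):
        self.weighted = weighted

    @staticmethod
    def _mm(s, vmax, km):
        return vmax * s / (km + s)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single column of concentrations")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape:
            raise ValueError("X and y lengths differ")
        pos = X > 0
        s, v = X[pos], y[pos]
        if len(np.unique(s)) < 4:
            raise ValueError(
                "need >= 4 distinct positive substrate concentrations, "
                f"got {len(np.unique(s))}"
            )
        if not np.any(v > 0):
            raise ValueError("no positive rates to fit")
        vmax0 = float(np.max(v)) * 1.2
        half = vmax0 / 2.4
        km0 = float(s[np.argmin(np.abs(v - half))])
        km0 = max(km0, 1e-6)
        sigma = np.maximum(np.abs(v), 1e-12) if self.weighted else None
        popt, pcov = curve_fit(
            self._mm, s, v, p0=[vmax0, km0], sigma=sigma, maxfev=20000
        )
        if not np.all(np.isfinite(popt)) or popt[0] <= 0 or popt[1] <= 0:
            raise RuntimeError(
                f"Michaelis-Menten fit rejected: parameters {popt}"
            )
        perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (np.nan,) * 2
        self.vmax_app_ = float(popt[0])
        self.km_app_ = float(popt[1])
        self.vmax_app_se_ = float(perr[0])
        self.km_app_se_ = float(perr[1])
        self.n_points_ = int(len(s))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return self._mm(X, self.vmax_app_, self.km_app_)


def fit_mm(his, v0, accoa_fixed: float, series: str = "",
           weighted: bool = False) -> MMFit:
    """Fit the Michaelis-Menten curve to one fixed-Ac-CoA histidine series.

    Points at S = 0 are dropped (they validate the blank, not the fit).
    Non-convergence or non-positive parameter estimates raise.
    """
    est = MichaelisMentenRegressor(weighted=weighted).fit(
        np.asarray(his, dtype=float), np.asarray(v0, dtype=float)
    )
    return MMFit(
        accoa_fixed=float(accoa_fixed),
        vmax_app=est.vmax_app_,
        km_app=est.km_app_,
        vmax_app_se=est.vmax_app_se_,
        km_app_se=est.km_app_se_,
        n_points=est.n_points_,
        series=series,
    )


# ---------------------------------------------------------------------------
# Hanes primary plots and mechanism discrimination

@dataclass(frozen=True)
class HanesLine:
    """Hanes line S/v0 = intercept + slope*S at one fixed Ac-CoA.

    slope = 1/Vmax_app (s/µM per µM, i.e. s·µM^-1), intercept =
    Km_app/Vmax_app (s).
    """

    accoa_fixed: float
    slope: float
    intercept: float

    @property
    def km_app(self) -> float:
        return self.intercept / self.slope


def hanes_transform(fit: MMFit) -> HanesLine:
    """Hanes line of an apparent Michaelis-Menten fit."""
    if fit.vmax_app <= 0:
        raise ValueError("vmax_app must be positive")
    return HanesLine(
        accoa_fixed=fit.accoa_fixed,
        slope=1.0 / fit.vmax_app,
        intercept=fit.km_app / fit.vmax_app,
    )


@dataclass
class MechanismCall:
    """Verdict of the Hanes-plot intersection test.

    ``ternary_complex``: lines meet left of the ordinate axis (common
    abscissa -Ki_His).  ``substituted_enzyme``: lines share the ordinate
    intercept, meeting at S = 0.  ``indeterminate``: neither pattern within
    tolerance.
    """

    verdict: str
    intersection_abscissa: float
    dispersion: float
    tolerance: float
    n_pairs: int
    abscissae: list = field(default_factory=list)


def _pairwise_intersections(lines):
    xs = []
    skipped = 0
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            ds = lines[i].slope - lines[j].slope
            scale = max(abs(lines[i].slope), abs(lines[j].slope))
            if abs(ds) <= 1e-12 * scale:
                skipped += 1
                continue
            xs.append((lines[j].intercept - lines[i].intercept) / ds)
    return np.asarray(xs), skipped


def classify_mechanism(lines, tol: float | None = None) -> MechanismCall:
    """Call the bi-substrate mechanism from >= 2 Hanes lines.

    If every line passes through one point (x0, y0) then intercept_i =
    y0 - x0 * slope_i, so the common intersection abscissa x0 is estimated
    (with a standard error) by OLS of the Hanes intercepts on the Hanes
    slopes — far more stable under noise than pairwise intersections, which
    are still computed for the reported dispersion.  Verdict:
    ``ternary_complex`` when x0 lies below -threshold,
    ``substituted_enzyme`` within +/- threshold of zero, else
    ``indeterminate``, with threshold = max(tol, 2 * SE(x0)) and tol
    defaulting to 0.05 * median apparent Km of the lines.  Near-parallel
    pairs are skipped with a warning.
    """
    lines = list(lines)
    if len(lines) < 2:
        raise ValueError("need >= 2 Hanes lines at distinct Ac-CoA")
    if tol is None:
        tol = 0.05 * float(np.median([ln.km_app for ln in lines]))
    xs, skipped = _pairwise_intersections(lines)
    if skipped:
        warnings.warn(f"skipped {skipped} near-parallel line pair(s)", stacklevel=2)
    if len(xs) == 0:
        raise ValueError("all line pairs are parallel; no intersections")
    slopes = np.array([ln.slope for ln in lines])
    intercepts = np.array([ln.intercept for ln in lines])
    beta, _y0 = np.polyfit(slopes, intercepts, 1)
    center = float(-beta)
    if len(lines) > 2:
        resid = intercepts - np.polyval([beta, _y0], slopes)
        s2 = float(resid @ resid) / (len(lines) - 2)
        sxx = float(np.sum((slopes - slopes.mean()) ** 2))
        se = np.sqrt(s2 / sxx) if sxx > 0 else np.inf
    else:
        se = 0.0
    threshold = max(float(tol), 2.0 * se)
    dispersion = float(np.std(xs))
    if center < -threshold:
        verdict = "ternary_complex"
    elif abs(center) <= threshold:
        verdict = "substituted_enzyme"
    else:
        verdict = "indeterminate"
    return MechanismCall(
        verdict=verdict,
        intersection_abscissa=center,
        dispersion=dispersion,
        tolerance=float(threshold),
        n_pairs=int(len(xs)),
        abscissae=list(map(float, xs)),
    )


# ---------------------------------------------------------------------------
# substrate-inhibition exclusion

def exclude_inhibited_series(
    fits,
    accoa_cutoff: float | None = None,
    automatic: bool = True,
    monotone_rtol: float = 0.02,
):
    """Flag apparent fits distorted by co-substrate (Ac-CoA) inhibition.

    Without inhibition Vmax_app(A) is non-decreasing in A; a declining tail
    at high A is the inhibition signature and those fits are excluded from
    the secondary regressions.  Two rules, applied as a union when both are
    configured:

    * cutoff mode — exclude fits with fixed Ac-CoA above ``accoa_cutoff`` µM;
    * automatic mode — exclude fits past the Vmax_app peak whose Vmax_app
      falls more than ``monotone_rtol`` (relative) below the running maximum.

    Returns a new list of :class:`MMFit` with exclusion flags; excluding
    every fit is an error.
    """
    fits = sorted(fits, key=lambda f: f.accoa_fixed)
    out = []
    running_max = -np.inf
    for f in fits:
        reasons = []
        if accoa_cutoff is not None and f.accoa_fixed > accoa_cutoff:
            reasons.append(f"accoa {f.accoa_fixed} uM above cutoff {accoa_cutoff} uM")
        if automatic:
            if f.vmax_app < running_max * (1.0 - monotone_rtol):
                reasons.append(
                    "vmax_app declines with Ac-CoA (substrate-inhibition signature)"
                )
            running_max = max(running_max, f.vmax_app)
        if reasons:
            out.append(replace(f, excluded=True, exclusion_reason="; ".join(reasons)))
        else:
            out.append(replace(f, excluded=False, exclusion_reason=""))
    if all(f.excluded for f in out):
        raise ValueError("exclusion rule removed every fit")
    return out


# ---------------------------------------------------------------------------
# secondary plots

@dataclass
class SecondaryFitResult:
    """Constants extracted from the two double-reciprocal secondary plots."""

    vmax: float
    km_accoa: float
    km_his: float
    ki_his_slope_estimate: float
    n_fits: int


def _accepted(fits):
    kept = [f for f in fits if not f.excluded]
    if len(kept) < 3:
        raise ValueError(f"need >= 3 accepted apparent fits, got {len(kept)}")
    return kept


def secondary_vmax_fit(fits):
    """OLS of 1/Vmax_app on 1/[Ac-CoA]: Vmax = 1/intercept, Km_AcCoA =
    slope/intercept (the negative inverse abscissa intercept).
    """
    kept = _accepted(fits)
    x = 1.0 / np.array([f.accoa_fixed for f in kept])
    y = 1.0 / np.array([f.vmax_app for f in kept])
    slope, intercept = np.polyfit(x, y, 1)
    if intercept <= 0:
        raise ValueError(
            "non-positive ordinate intercept in 1/Vmax_app secondary plot: "
            "inconsistent apparent values"
        )
    return float(1.0 / intercept), float(slope / intercept)


def secondary_km_his_fit(fits, vmax: float):
    """OLS of Km_app/Vmax_app on 1/[Ac-CoA].

    Km_His = intercept * Vmax; the slope yields a Ki_His estimate via
    slope = Ki_His * Km_AcCoA / Vmax (reported, not a headline constant).
    Returns (km_his, slope).
    """
    kept = _accepted(fits)
    x = 1.0 / np.array([f.accoa_fixed for f in kept])
    y = np.array([f.km_app / f.vmax_app for f in kept])
    slope, intercept = np.polyfit(x, y, 1)
    if intercept < 0:
        raise ValueError(
            "negative ordinate intercept in Km_app/Vmax_app secondary plot: "
            "inconsistent apparent values"
        )
    return float(intercept * vmax), float(slope)


def secondary_plots(fits) -> SecondaryFitResult:
    """Run both secondary regressions on the accepted apparent fits."""
    vmax, km_accoa = secondary_vmax_fit(fits)
    km_his, slope = secondary_km_his_fit(fits, vmax)
    ki_est = slope * vmax / km_accoa if km_accoa > 0 else np.nan
    return SecondaryFitResult(
        vmax=vmax,
        km_accoa=km_accoa,
        km_his=km_his,
        ki_his_slope_estimate=float(ki_est),
        n_fits=len([f for f in fits if not f.excluded]),
    )


# ---------------------------------------------------------------------------
# global fit of the four-parameter law

class TernaryGlobalFit(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the full sequential rate law.

    ``fit(X, y)`` with X of shape (n, 2) — columns [His], [Ac-CoA] in µM —
    and y the rates in µM/s.  Fitted attributes: ``model_``
    (:class:`TernaryModel`), ``param_se_`` (standard errors in the order
    vmax, km_accoa, km_his, ki_his).  Serves as the cross-check of the
    secondary-plot route.

    Parameters
    ----------
    init : TernaryModel or None
        Starting point, typically the secondary-plot estimates; a crude
        data-driven start is used when None.
    """

    _names = ("vmax", "km_accoa", "km_his", "ki_his")

    def __init__(self, init: TernaryModel | None = None):
        self.init = init

    @staticmethod
    def _law(X, vmax, km_a, km_s, ki_s):
        s, a = X[:, 0], X[:, 1]
        return vmax * s * a / (ki_s * km_a + km_a * s + km_s * a + s * a)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: [His], [Ac-CoA]")
        keep = (X[:, 0] > 0) & (X[:, 1] > 0)
        X, y = X[keep], y[keep]
        if len(y) < 8:
            raise ValueError("need >= 8 points with both substrates present")
        n_s = len(np.unique(X[:, 0]))
        n_a = len(np.unique(X[:, 1]))
        self.unidentifiable_ = []
        if n_a < 2:
            # one co-substrate level: Ki_His and Km_His enter only through
            # Km_app at that level and cannot be separated
            self.unidentifiable_.append("ki_his")
        if n_s < 3 or n_a < 3:
            warnings.warn(
                "fewer than 3 levels of a substrate: parameters may be "
                "poorly determined", stacklevel=2,
            )
        if self.init is not None:
            p0 = [self.init.vmax, self.init.km_accoa, self.init.km_his,
                  self.init.ki_his]
        else:
            vmax0 = float(np.max(y)) * 1.5
            p0 = [vmax0, float(np.median(X[:, 1])), float(np.median(X[:, 0])),
                  float(np.median(X[:, 0]))]
        if self.unidentifiable_:
            raise ValueError(
                "rank-deficient design: unidentifiable parameter(s) "
                + ", ".join(self.unidentifiable_)
            )
        popt, pcov = curve_fit(self._law, X, y, p0=p0, maxfev=50000)
        if not np.all(popt > 0):
            raise RuntimeError(f"global fit produced non-positive parameters {popt}")
        self.model_ = TernaryModel(*map(float, popt))
        self.param_cov_ = pcov
        with np.errstate(invalid="ignore"):
            self.param_se_ = dict(zip(self._names, np.sqrt(np.diag(pcov))))
        self.n_points_ = int(len(y))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        m = self.model_
        return self._law(X, m.vmax, m.km_accoa, m.km_his, m.ki_his)


def global_fit_ternary(his, accoa, v0, init: TernaryModel | None = None):
    """Fit the four-parameter sequential law to all rate points at once.

    Returns the fitted :class:`TernaryGlobalFit` (``.model_``,
    ``.param_se_``).
    """
    X = np.column_stack([np.asarray(his, float), np.asarray(accoa, float)])
    return TernaryGlobalFit(init=init).fit(X, np.asarray(v0, float))


def compare_routes(series_points: dict, enzyme_uM: float,
                   constants: "KineticConstants | None" = None,
                   level: float = 0.95):
    """Cross-check the secondary-plot route against the global fit.

    Pools the rate points of all series, fits the four-parameter law
    initialized from the secondary-plot estimates, and tests whether the
    three headline constants (kcat, Km_AcCoA, Km_His) from the two routes
    agree within a joint confidence region: the quadratic form of the
    difference under the combined covariance (global-fit covariance plus
    the across-series standard error of the secondary route) compared to
    the chi-square quantile at 3 degrees of freedom.

    Returns a dict with both estimate sets, the chi-square statistic and
    the ``agree`` flag.
    """
    from scipy.stats import chi2

    if constants is None:
        constants = estimate_constants(series_points, enzyme_uM)
    n_series = len(constants.per_series)
    ki0 = float(np.mean([
        v["ki_his_slope_estimate"] for v in constants.per_series.values()
    ]))
    init = TernaryModel(
        constants.mean["kcat"] * enzyme_uM,
        constants.mean["km_accoa"],
        constants.mean["km_his"],
        max(ki0, 1e-3),
    )
    his = np.concatenate([np.asarray(p["his_uM"], float) for p in series_points.values()])
    accoa = np.concatenate([np.asarray(p["accoa_uM"], float) for p in series_points.values()])
    v0 = np.concatenate([np.asarray(p["v0_uM_s"], float) for p in series_points.values()])
    gf = global_fit_ternary(his, accoa, v0, init=init)
    sec = np.array([init.vmax, init.km_accoa, init.km_his])
    glo = np.array([gf.model_.vmax, gf.model_.km_accoa, gf.model_.km_his])
    sec_se = np.array([
        constants.sd["kcat"] * enzyme_uM,
        constants.sd["km_accoa"],
        constants.sd["km_his"],
    ]) / max(np.sqrt(n_series), 1.0)
    cov = gf.param_cov_[:3, :3] + np.diag(sec_se ** 2)
    d = sec - glo
    stat = float(d @ np.linalg.solve(cov, d))
    return {
        "secondary": {"kcat": sec[0] / enzyme_uM, "km_accoa": sec[1],
                      "km_his": sec[2]},
        "global": {"kcat": glo[0] / enzyme_uM, "km_accoa": glo[1],
                   "km_his": glo[2], "ki_his": gf.model_.ki_his},
        "chi2": stat,
        "threshold": float(chi2.ppf(level, 3)),
        "agree": stat <= float(chi2.ppf(level, 3)),
    }


# ---------------------------------------------------------------------------
# top-level constant extraction

@dataclass
class KineticConstants:
    """Headline constants, per series and aggregated across series.

    ``per_series`` maps series id -> dict with kcat (s^-1), km_accoa (µM),
    km_his (µM) and the two kcat/Km ratios (s^-1 µM^-1).  ``mean``/``sd``
    aggregate across series; ratio rows carry both the mean of per-series
    ratios and the ratio of the mean constants (the two differ once
    series-level constants vary).
    """

    enzyme_uM: float
    per_series: dict
    mean: dict
    sd: dict
    ratio_of_means: dict

    FIELDS = ("kcat", "km_accoa", "kcat_over_km_accoa", "km_his",
              "kcat_over_km_his")

    def as_table(self):
        import pandas as pd

        rows = []
        for key in self.FIELDS:
            rows.append({
                "constant": key,
                "mean": self.mean[key],
                "sd": self.sd[key],
                **{f"series_{s}": vals[key]
                   for s, vals in self.per_series.items()},
            })
        return pd.DataFrame(rows)


def estimate_constants(
    series_points: dict,
    enzyme_uM: float,
    accoa_cutoff: float | None = None,
    automatic_exclusion: bool = True,
    weighted: bool = False,
) -> KineticConstants:
    """Full secondary-plot pipeline over one or more independent series.

    ``series_points`` maps a series id to a record array / DataFrame-like
    with fields his_uM, accoa_uM, v0_uM_s.  Per series: Michaelis-Menten fit
    at each fixed Ac-CoA, substrate-inhibition exclusion, secondary plots,
    kcat = Vmax / E.  Ratios are computed per series; across-series mean and
    SD are reported alongside the ratios of the mean constants.
    """
    if enzyme_uM <= 0:
        raise ValueError("enzyme concentration must be positive")
    per_series = {}
    for sid, pts in series_points.items():
        his = np.asarray(pts["his_uM"], dtype=float)
        accoa = np.asarray(pts["accoa_uM"], dtype=float)
        v0 = np.asarray(pts["v0_uM_s"], dtype=float)
        fits = []
        for a in np.unique(accoa[accoa > 0]):
            sel = accoa == a
            fits.append(fit_mm(his[sel], v0[sel], a, series=str(sid),
                               weighted=weighted))
        fits = exclude_inhibited_series(
            fits, accoa_cutoff=accoa_cutoff, automatic=automatic_exclusion
        )
        sec = secondary_plots(fits)
        kcat = sec.vmax / enzyme_uM
        per_series[sid] = {
            "kcat": kcat,
            "km_accoa": sec.km_accoa,
            "km_his": sec.km_his,
            "kcat_over_km_accoa": kcat / sec.km_accoa,
            "kcat_over_km_his": kcat / sec.km_his,
            "ki_his_slope_estimate": sec.ki_his_slope_estimate,
            "n_fits_used": sec.n_fits,
            "excluded_accoa": [f.accoa_fixed for f in fits if f.excluded],
        }
    keys = KineticConstants.FIELDS
    mean = {k: float(np.mean([v[k] for v in per_series.values()])) for k in keys}
    sd = {k: float(np.std([v[k] for v in per_series.values()], ddof=1))
          if len(per_series) > 1 else 0.0 for k in keys}
    ratio_of_means = {
        "kcat_over_km_accoa": mean["kcat"] / mean["km_accoa"],
        "kcat_over_km_his": mean["kcat"] / mean["km_his"],
    }
    return KineticConstants(
        enzyme_uM=float(enzyme_uM),
        per_series=per_series,
        mean=mean,
        sd=sd,
        ratio_of_means=ratio_of_means,
    )
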