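"""Saturation-binding kinetics: apparent Kd and Bmax from EMSA titrations.

One-site binding of a protein complex to a labeled DNA probe follows the
rectangular hyperbola bound = Bmax * x / (Kd + x); the generalized
four-parameter form adds a baseline and a Hill coefficient,
bound = y0 + (Bmax - y0) * x^h / (Kd^h + x^h). Parameters are estimated by
(optionally 1/y-weighted) nonlinear least squares with positivity
constraints; standard errors come from the curvature of the objective at the
optimum. Parameter equality across series is tested with the
extra-sum-of-squares F test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from socmap.simulate import BindingSeries


@dataclass
class BindingFit:
    bmax: float
    kd: float
    bmax_se: float
    kd_se: float
    y0: float = 0.0
    hill: float = 1.0
    y0_se: float = 0.0
    hill_se: float = 0.0
    model: str = "hyperbola"
    rss: float = 0.0
    n: int = 0
    converged: bool = True
    extrapolated: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "hyperbola":
            return self.bmax * x / (self.kd + x)
        xh = x**self.hill
        return self.y0 + (self.bmax - self.y0) * xh / (self.kd**self.hill + xh)


@dataclass
class FitComparison:
    parameter: str
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    rss_full: float
    rss_reduced: float
    shared_value: float


def _flatten(series: BindingSeries) -> tuple[np.ndarray, np.ndarray]:
    n_rep = series.signals.shape[1]
    x = np.repeat(series.concentrations, n_rep)
    y = series.signals.ravel()
    return x, y


def _hyperbola(x, bmax, kd):
    return bmax * x / (kd + x)


def _four_param(x, y0, bmax, kd, h):
    xh = np.power(x, h)
    return y0 + (bmax - y0) * xh / (np.power(kd, h) + xh)


def fit_saturation(
    series: BindingSeries, model: str = "hyperbola", weighting: str | None = None
) -> BindingFit:
    """Fit a saturation-binding model to one titration series.

    ``model`` is "hyperbola" (one-site, 2 parameters) or "four_param"
    (baseline + Hill slope). ``weighting=None`` is unweighted least squares;
    ``"1/y"`` weights residuals by the inverse predicted signal. A fitted Kd
    more than 10x outside the sampled concentration range raises an
    extrapolation warning; non-convergence returns a flagged fit.
    """
    x, y = _flatten(series)
    n_distinct = len(np.unique(series.concentrations))
    if model == "hyperbola":
        if n_distinct < 3:
            raise ValueError("hyperbola fit needs >= 3 distinct concentrations")
        func = _hyperbola
        ymax = max(y.max(), 1e-12)
        p0 = [ymax, max(float(np.median(x)), 1e-6)]
        bounds = ([1e-12, 1e-12], [np.inf, np.inf])
        names = ["bmax", "kd"]
    elif model == "four_param":
        if n_distinct < 5:
            raise ValueError("four_param fit needs >= 5 distinct concentrations")
        func = _four_param
        ymax = max(y.max(), 1e-12)
        p0 = [0.0, ymax, max(float(np.median(x)), 1e-6), 1.0]
        bounds = ([-np.inf, 1e-12, 1e-12, 0.1], [np.inf, np.inf, np.inf, 10.0])
        names = ["y0", "bmax", "kd", "h"]
    else:
        raise ValueError(f"unknown model {model!r}")

    sigma = None
    if weighting == "1/y":
        sigma = np.sqrt(np.maximum(y, 1e-6 * y.max() if y.max() > 0 else 1.0))
    try:
        popt, pcov = optimize.curve_fit(
            func, x, y, p0=p0, bounds=bounds, sigma=sigma, maxfev=20000
        )
        converged = np.all(np.isfinite(popt))
    except RuntimeError as exc:
        warnings.warn(f"saturation fit did not converge: {exc}")
        nanfit = dict.fromkeys(names, np.nan)
        return BindingFit(
            nanfit.get("bmax", np.nan), nanfit.get("kd", np.nan), np.nan, np.nan,
            model=model, rss=np.nan, n=len(y), converged=False,
        )
    resid = y - func(x, *popt)
    rss = float((resid**2).sum())
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    params = dict(zip(names, popt))
    ses = dict(zip(names, se))
    kd = float(params["kd"])
    extrapolated = kd > 10 * x.max() or kd < x.min() / 10
    if extrapolated:
        warnings.warn(
            f"fitted Kd {kd:.3g} nM is >10x outside the sampled range "
            f"[{x.min():.3g}, {x.max():.3g}] nM"
        )
    return BindingFit(
        float(params["bmax"]),
        kd,
        float(ses["bmax"]),
        float(ses["kd"]),
        y0=float(params.get("y0", 0.0)),
        hill=float(params.get("h", 1.0)),
        y0_se=float(ses.get("y0", 0.0)),
        hill_se=float(ses.get("h", 0.0)),
        model=model,
        rss=rss,
        n=len(y),
        converged=bool(converged),
        extrapolated=extrapolated,
    )


def _joint_rss(series_list, parameter: str, shared: bool) -> tuple[float, int, float]:
    """Least-squares RSS for hyperbola fits across series.

    ``shared=True`` constrains ``parameter`` ("Kd" or "Bmax") to one common
    value across series; the other parameter stays series-specific. Returns
    (rss, n_parameters, shared_parameter_value).
    """
    data = [_flatten(s) for s in series_list]
    k = len(series_list)
    param = parameter.lower()

    def unpack(theta):
        if shared:
            common = theta[0]
            others = theta[1:]
            if param == "kd":
                return [(others[i], common) for i in range(k)]
            return [(common, others[i]) for i in range(k)]
        return [(theta[2 * i], theta[2 * i + 1]) for i in range(k)]

    def residuals(theta):
        th = np.abs(theta)  # positivity via reflection
        out = []
        for (x, y), (bmax, kd) in zip(data, unpack(th)):
            out.append(y - _hyperbola(x, bmax, kd + 1e-300))
        return np.concatenate(out)

    inits = []
    for x, y in data:
        inits.append((max(y.max(), 1e-9), max(float(np.median(x)), 1e-9)))
    if shared:
        if param == "kd":
            theta0 = [float(np.mean([kd for _, kd in inits]))] + [b for b, _ in inits]
        else:
            theta0 = [float(np.mean([b for b, _ in inits]))] + [kd for _, kd in inits]
    else:
        theta0 = [v for pair in inits for v in pair]
    sol = optimize.least_squares(residuals, theta0, method="lm", max_nfev=20000)
    if not sol.success:
        raise RuntimeError(f"joint saturation fit failed: {sol.message}")
    rss = float(2 * sol.cost)
    shared_value = float(abs(sol.x[0])) if shared else np.nan
    return rss, len(theta0), shared_value


def compare_fits(series_list, parameter: str = "Kd") -> FitComparison:
    """Extra-sum-of-squares F test: does ``parameter`` differ among series?

    The full model fits Bmax and Kd separately per series; the reduced model
    shares ``parameter`` across series. F = ((RSS_r - RSS_f) / d_df) /
    (RSS_f / df_f) with d_df = k - 1 extra constraints.
    """
    if len(series_list) < 2:
        raise ValueError("need >= 2 series to compare")
    if parameter.lower() not in {"kd", "bmax"}:
        raise ValueError("parameter must be 'Kd' or 'Bmax'")
    n_obs = sum(s.signals.size for s in series_list)
    rss_full, p_full, _ = _joint_rss(series_list, parameter, shared=False)
    rss_red, p_red, shared_value = _joint_rss(series_list, parameter, shared=True)
    d_df = p_full - p_red
    df_resid = n_obs - p_full
    if df_resid < 1:
        raise ValueError("no residual df for the full model")
    rss_red = max(rss_red, rss_full)  # numerical guard: reduced is nested
    if rss_full <= 0:
        f_stat = np.inf if rss_red > 0 else 0.0
        p = 0.0 if rss_red > 0 else 1.0
    else:
        f_stat = ((rss_red - rss_full) / d_df) / (rss_full / df_resid)
        p = float(stats.f.sf(f_stat, d_df, df_resid))
    return FitComparison(
        parameter, float(f_stat), (d_df, df_resid), p, rss_full, rss_red, shared_value
    )


def relative_binding(
    series: BindingSeries, by: str = "bmax", fit: BindingFit | None = None
) -> BindingSeries:
    """Normalize a binding series to its maximum.

    ``by="bmax"`` divides by the fitted Bmax (fitting a hyperbola if no fit
    is supplied); ``by="observed_max"`` divides by the largest observed
    signal, so the output maximum is exactly 1.
    """
    if series.signals.size == 0 or series.signals.max() <= 0:
        raise ValueError("series has no positive signal")
    if by == "bmax":
        if fit is None:
            fit = fit_saturation(series, model="hyperbola")
        scale = fit.bmax
    elif by == "observed_max":
        scale = float(series.signals.max())
    else:
        raise ValueError("by must be 'bmax' or 'observed_max'")
    return BindingSeries(
        series.concentrations.copy(),
        series.signals / scale,
        series.complex_label,
        series.genotype_label,
    )
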