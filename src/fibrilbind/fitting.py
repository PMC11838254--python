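"""Nonlinear regression of cooperative binding models to assay data.

Fits the cooperative saturation isotherm (CPM vs radioligand concentration)
and the saturated competition isotherm (CPM vs inhibitor concentration) to
concentration-response curves, plus the empirical Hill equation for
effective-steepness readouts.  Least squares, covariances and standard
errors come from lmfit; the model functions are the fibril isotherms.

A central identifiability fact of the saturated competition assay: the data
determine only (IC50, beta).  IC50 cannot be decomposed into the two
standalone midpoints, nor beta into the three stacking factors —
:func:`identifiability_profile` makes this ridge explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import t as t_dist

from .isotherms import competition_fraction, saturation_fraction

__all__ = [
    "BindingCurve",
    "SignalModel",
    "FitResult",
    "fit_hill",
    "hill_protocol_points",
    "fit_hill_to_isotherm",
    "fit_saturation",
    "fit_competition",
    "identifiability_profile",
]

#: points / occupancy window for the fixed Hill-fit protocol on theory curves
HILL_PROTOCOL_N = 200
HILL_PROTOCOL_F = (0.01, 0.99)


@dataclass
class BindingCurve:
    """A concentration-response dataset (saturation or competition), CPM signal."""

    assay_type: str
    concentrations: np.ndarray
    signal: np.ndarray
    radioligand_conc: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.assay_type not in ("saturation", "competition"):
            raise ValueError(
                f"assay_type must be 'saturation' or 'competition', got {self.assay_type!r}"
            )
        conc = np.asarray(self.concentrations, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        if conc.shape != sig.shape or conc.ndim != 1:
            raise ValueError("concentrations and signal must be 1-D arrays of equal length")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        order = np.argsort(conc)
        conc, sig = conc[order], sig[order]
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be distinct")
        self.concentrations, self.signal = conc, sig
        if self.assay_type == "competition":
            if self.radioligand_conc is None or not (self.radioligand_conc > 0):
                raise ValueError("competition curves require radioligand_conc > 0")

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class SignalModel:
    """Linear detector model: specific plateau, non-specific slope, baseline.

    ``bmax`` (CPM) aggregates decay rate, site count and detector efficiency;
    ``ns_slope`` (CPM/M) is the linear non-specific term; ``baseline`` (CPM)
    a constant offset.
    """

    bmax: float
    ns_slope: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not (self.bmax > 0):
            raise ValueError(f"bmax must be positive, got {self.bmax}")
        if not (self.ns_slope >= 0):
            raise ValueError(f"ns_slope must be non-negative, got {self.ns_slope}")


@dataclass
class FitResult:
    """Parameter estimates with uncertainties and diagnostics.

    Positive scale parameters (dissociation constants, stacking factors,
    plateaus) are fitted on the log scale; for those, ``log_standard_errors``
    holds the standard error of the natural log and confidence intervals are
    computed there and exponentiated, which respects positivity and the
    strong (KD, alpha_L) anti-correlation.
    """

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    covariance: pd.DataFrame | None
    residuals: np.ndarray
    converged: bool
    objective: float
    message: str = ""
    flags: list[str] = field(default_factory=list)
    n_varying: int | None = None
    log_standard_errors: dict[str, float] = field(default_factory=dict)

    @property
    def params(self) -> dict[str, float]:
        return self.estimates

    def conf_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Wald interval with a t critical value on n - p degrees of freedom;
        log-scale (hence asymmetric) for log-fitted parameters."""
        p = self.n_varying if self.n_varying is not None else len(self.estimates)
        dof = max(len(self.residuals) - p, 1)
        crit = t_dist.ppf(0.5 + level / 2.0, dof)
        est = self.estimates[name]
        se_log = self.log_standard_errors.get(name)
        if se_log is not None and np.isfinite(se_log) and est > 0:
            return (est * np.exp(-crit * se_log), est * np.exp(crit * se_log))
        se = self.standard_errors.get(name)
        if se is None or not np.isfinite(se):
            return (-np.inf, np.inf)
        return (est - crit * se, est + crit * se)


def _result_from_lmfit(out: lmfit.minimizer.MinimizerResult, varying: list[str],
                       fixed: dict[str, float]) -> FitResult:
    estimates = {name: float(out.params[name].value) for name in out.params}
    stderr = {}
    for name in out.params:
        p = out.params[name]
        stderr[name] = float(p.stderr) if (p.vary and p.stderr is not None) else np.nan
    cov = None
    if getattr(out, "covar", None) is not None:
        cov = pd.DataFrame(out.covar, index=out.var_names, columns=out.var_names)
    return FitResult(
        estimates=estimates,
        standard_errors=stderr,
        covariance=cov,
        residuals=np.asarray(out.residual, dtype=float),
        converged=bool(out.success),
        objective=float(np.sum(np.asarray(out.residual) ** 2)),
        message=str(getattr(out, "message", "")),
    )


def fit_hill(concentrations, response, descending: bool = False,
             weights=None) -> FitResult:
    """Least-squares fit of the empirical Hill equation.

    Ascending form ``f = x^n / (EC50^n + x^n)``; descending (competition)
    form ``f = IC50^n / (IC50^n + x^n)``.  Returns estimates for ``midpoint``
    and ``hill_n``.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 points for a Hill fit")
    if np.any(x <= 0):
        raise ValueError("Hill fit requires strictly positive concentrations")

    ymid = 0.5 * (y.min() + y.max())
    # crude midpoint bracket for the start value
    mid0 = float(np.exp(np.interp(ymid, y, np.log(x)) if not descending
                        else np.interp(-ymid, -y, np.log(x))))
    if not np.isfinite(mid0) or mid0 <= 0:
        mid0 = float(np.sqrt(x.min() * x.max()))

    params = lmfit.Parameters()
    params.add("midpoint", value=mid0, min=x.min() / 1e3, max=x.max() * 1e3)
    params.add("hill_n", value=1.5, min=0.05, max=20.0)

    def resid(p):
        m, n = p["midpoint"].value, p["hill_n"].value
        xn = (x / m) ** n
        f = 1.0 / (1.0 + xn) if descending else xn / (1.0 + xn)
        r = f - y
        return r if weights is None else r * weights

    out = lmfit.minimize(resid, params, method="least_squares")
    res = _result_from_lmfit(out, ["midpoint", "hill_n"], {})
    span = y.max() - y.min()
    if not (y.min() < ymid < y.max()) or span < 0.2:
        res.converged = False
        res.flags.append("midpoint not bracketed by the data")
    return res


def hill_protocol_points(fraction_func, descending: bool = False,
                         search=(1e-10, 1e10)) -> tuple[np.ndarray, np.ndarray]:
    """Concentration grid of the fixed Hill-fit protocol for theory curves.

    200 log-spaced points spanning the concentration window where the
    fractional response runs from 0.01 to 0.99 (found by root bracketing).
    Pinning the window makes effective Hill coefficients comparable across
    isotherms: the fitted steepness depends on the fitted range.
    """
    f_lo, f_hi = HILL_PROTOCOL_F
    lo_target, hi_target = (f_hi, f_lo) if descending else (f_lo, f_hi)

    def root(target: float) -> float:
        return brentq(lambda lx: fraction_func(np.exp(lx)) - target,
                      np.log(search[0]), np.log(search[1]), xtol=1e-12)

    lx_lo, lx_hi = root(lo_target), root(hi_target)
    x = np.exp(np.linspace(min(lx_lo, lx_hi), max(lx_lo, lx_hi), HILL_PROTOCOL_N))
    return x, np.asarray(fraction_func(x), dtype=float)


def fit_hill_to_isotherm(fraction_func, descending: bool = False) -> FitResult:
    """Effective Hill coefficient of a theoretical isotherm under the fixed
    protocol (200 log-spaced points, f in [0.01, 0.99], unweighted)."""
    x, f = hill_protocol_points(fraction_func, descending=descending)
    return fit_hill(x, f, descending=descending)


#: solver tolerances; tight because the (KD, alpha_L) valley is shallow
_SOLVER_KWS = dict(ftol=1e-14, xtol=1e-14, gtol=1e-14)


def _multistart_minimize(resid, param_sets: list[lmfit.Parameters]) -> lmfit.minimizer.MinimizerResult:
    best = None
    for params in param_sets:
        try:
            out = lmfit.minimize(resid, params, method="least_squares", **_SOLVER_KWS)
        except Exception:
            continue
        if best is None or np.sum(out.residual**2) < np.sum(best.residual**2):
            best = out
    if best is None:
        raise RuntimeError("all optimization starts failed")
    return best


def _log_scale_result(out, log_names: dict[str, str], linear_names: list[str]) -> FitResult:
    """Translate an lmfit result with log-scale parameters back to natural scale.

    ``log_names`` maps reported name -> internal log-parameter name; standard
    errors on the natural scale come from the delta method.
    """
    estimates: dict[str, float] = {}
    stderr: dict[str, float] = {}
    log_se: dict[str, float] = {}
    for name, internal in log_names.items():
        p = out.params[internal]
        val = float(np.exp(p.value))
        estimates[name] = val
        if p.vary and p.stderr is not None:
            log_se[name] = float(p.stderr)
            stderr[name] = val * float(p.stderr)
        else:
            stderr[name] = np.nan if p.vary else 0.0
    for name in linear_names:
        p = out.params[name]
        estimates[name] = float(p.value)
        stderr[name] = float(p.stderr) if (p.vary and p.stderr is not None) else (
            np.nan if p.vary else 0.0)
    cov = None
    if getattr(out, "covar", None) is not None:
        # transform log rows/cols to natural scale: d x / d ln x = x
        names = list(out.var_names)
        jac = np.ones(len(names))
        display = []
        inv_log = {v: k for k, v in log_names.items()}
        for i, nm in enumerate(names):
            if nm in inv_log:
                jac[i] = estimates[inv_log[nm]]
                display.append(inv_log[nm])
            else:
                display.append(nm)
        cov = pd.DataFrame(out.covar * np.outer(jac, jac), index=display,
                           columns=display)
    return FitResult(
        estimates=estimates,
        standard_errors=stderr,
        covariance=cov,
        residuals=np.asarray(out.residual, dtype=float),
        converged=bool(out.success),
        objective=float(np.sum(np.asarray(out.residual) ** 2)),
        message=str(getattr(out, "message", "")),
        n_varying=len(out.var_names),
        log_standard_errors=log_se,
    )


def fit_saturation(
    curve: BindingCurve,
    fix_alpha: float | None = None,
    fix_ns: float | None = None,
    fix_baseline: float | None = None,
    n_starts: int = 5,
    weighting: str = "proportional",
) -> FitResult:
    """Fit ``CPM = Bmax f(L/KD, alpha_L) + ns L + baseline`` to a saturation curve.

    Multi-start bounded least squares; KD, alpha_L and Bmax are fitted on the
    log scale, which conditions the shallow (KD, alpha_L) valley (only their
    ratio EC50 = KD/alpha_L is pinned by the midpoint; the steepness beyond
    it identifies alpha_L).  ``weighting='proportional'`` divides residuals
    by the model value, matching counting-type noise whose spread scales with
    the signal; ``'none'`` gives ordinary least squares.
    """
    if curve.assay_type != "saturation":
        raise ValueError("fit_saturation requires a saturation curve")
    if len(curve) < 5:
        raise ValueError("need at least 5 points")
    if weighting not in ("proportional", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    conc, sig = curve.concentrations, curve.signal
    pos = conc[conc > 0]
    if len(pos) == 0:
        raise ValueError("need positive concentrations")
    bmax0 = float(sig.max() - sig.min()) or 1.0
    base0 = float(sig.min())
    ec50_0 = float(np.exp(np.interp(0.5 * (sig.min() + sig.max()), sig,
                                    np.log(np.maximum(conc, pos.min() * 1e-3)))))

    alpha_starts = [1.0, 3.0, 10.0, 0.3, 30.0][:n_starts]
    param_sets = []
    for a0 in alpha_starts:
        params = lmfit.Parameters()
        params.add("log_kd", value=np.log(ec50_0 * a0),
                   min=np.log(pos.min() * 1e-6), max=np.log(pos.max() * 1e6))
        if fix_alpha is not None:
            params.add("log_alpha", value=np.log(fix_alpha), vary=False)
        else:
            params.add("log_alpha", value=np.log(a0),
                       min=np.log(1e-3), max=np.log(1e4))
        params.add("log_bmax", value=np.log(bmax0),
                   min=np.log(bmax0 * 1e-3), max=np.log(bmax0 * 1e3))
        if fix_ns is not None:
            params.add("ns_slope", value=fix_ns, vary=False)
        else:
            params.add("ns_slope", value=0.0, min=0.0, max=bmax0 / pos.min())
        if fix_baseline is not None:
            params.add("baseline", value=fix_baseline, vary=False)
        else:
            params.add("baseline", value=base0)
        param_sets.append(params)

    floor = 1e-3 * bmax0

    def resid(p):
        f = saturation_fraction(conc / np.exp(p["log_kd"].value),
                                np.exp(p["log_alpha"].value))
        model = (np.exp(p["log_bmax"].value) * f
                 + p["ns_slope"].value * conc + p["baseline"].value)
        r = model - sig
        if weighting == "proportional":
            r = r / np.maximum(np.abs(model), floor)
        return r

    out = _multistart_minimize(resid, param_sets)
    res = _log_scale_result(
        out, {"kd": "log_kd", "alpha_l": "log_alpha", "bmax": "log_bmax"},
        ["ns_slope", "baseline"])
    if getattr(out, "covar", None) is None:
        res.flags.append(
            "singular covariance: (kd, alpha_l) may be degenerate "
            "(only the ratio EC50 = kd/alpha_l is identified near the midpoint)"
        )
    return res


def fit_competition(curve: BindingCurve, n_starts: int = 5,
                    fix_beta: float | None = None) -> FitResult:
    """Fit ``CPM = Bmax f([I]/IC50, beta) + baseline`` to a competition curve.

    Only (IC50, beta) are estimable from a saturated competition assay; no
    decomposition into standalone midpoints or stacking factors is attempted.
    IC50, beta and Bmax are fitted on the log scale; ``beta`` pinned at its
    bounds (1e-3, 1e3) is flagged.
    """
    if curve.assay_type != "competition":
        raise ValueError("fit_competition requires a competition curve")
    if len(curve) < 5:
        raise ValueError("need at least 5 points")
    conc, sig = curve.concentrations, curve.signal
    pos = conc[conc > 0]
    bmax0 = float(sig.max() - sig.min()) or 1.0
    base0 = float(sig.min())
    ic50_0 = float(np.exp(np.interp(-0.5 * (sig.min() + sig.max()), -sig,
                                    np.log(np.maximum(conc, pos.min() * 1e-3)))))

    beta_starts = [1.0, 0.1, 10.0, 100.0, 0.01][:n_starts]
    param_sets = []
    for b0 in beta_starts:
        params = lmfit.Parameters()
        params.add("log_ic50", value=np.log(ic50_0),
                   min=np.log(pos.min() * 1e-6), max=np.log(pos.max() * 1e6))
        if fix_beta is not None:
            params.add("log_beta", value=np.log(fix_beta), vary=False)
        else:
            params.add("log_beta", value=np.log(b0), min=np.log(1e-3), max=np.log(1e3))
        params.add("log_bmax", value=np.log(bmax0),
                   min=np.log(bmax0 * 1e-3), max=np.log(bmax0 * 1e3))
        params.add("baseline", value=base0)
        param_sets.append(params)

    def resid(p):
        f = competition_fraction(conc / np.exp(p["log_ic50"].value),
                                 np.exp(p["log_beta"].value))
        return np.exp(p["log_bmax"].value) * f + p["baseline"].value - sig

    out = _multistart_minimize(resid, param_sets)
    res = _log_scale_result(
        out, {"ic50": "log_ic50", "beta": "log_beta", "bmax": "log_bmax"},
        ["baseline"])
    beta_hat = res.estimates["beta"]
    if beta_hat <= 1e-3 * 1.01 or beta_hat >= 1e3 * 0.99:
        res.flags.append("beta estimate at bound; steepness poorly constrained")
    return res


def identifiability_profile(
    curve: BindingCurve,
    ec50_l: float,
    alpha_grid,
    ec50_i: float | None = None,
    beta: float | None = None,
) -> pd.DataFrame:
    """Profile of the fit objective along the (KD, alpha_L) ridge.

    Walks ``alpha_l`` over ``alpha_grid`` holding the ratio
    ``kd/alpha_l = ec50_l`` fixed, refitting the linear signal parameters
    (Bmax, baseline, and non-specific slope for saturation) at each point by
    ordinary linear least squares.  For a saturated competition curve the
    objective is flat to machine precision — the data cannot decompose IC50
    — while a wide-range saturation curve breaks the degeneracy through its
    steepness.

    Returns a DataFrame with columns ``kd``, ``alpha_l``, ``objective``.
    """
    alpha_grid = np.atleast_1d(np.asarray(alpha_grid, dtype=float))
    conc, sig = curve.concentrations, curve.signal
    rows = []
    for alpha in alpha_grid:
        kd = ec50_l * alpha
        if curve.assay_type == "saturation":
            f = saturation_fraction(conc / kd, alpha)
            design = np.column_stack([f, conc, np.ones_like(conc)])
        else:
            if ec50_i is None:
                raise ValueError("competition profile requires ec50_i")
            b = 1.0 if beta is None else beta
            ic50 = ec50_i * curve.radioligand_conc / ec50_l
            f = competition_fraction(conc / ic50, b)
            design = np.column_stack([f, np.ones_like(conc)])
        coef, *_ = np.linalg.lstsq(design, sig, rcond=None)
        obj = float(np.sum((design @ coef - sig) ** 2))
        rows.append({"kd": kd, "alpha_l": alpha, "objective": obj})
    return pd.DataFrame(rows)
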