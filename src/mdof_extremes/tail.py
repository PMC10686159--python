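"""Confidence intervals, parametric tail fitting and return-level solving.

The empirical conditional exceedance rate p_k(lambda) is only observable
where the record contains exceedances.  To reach design and beyond-design
levels the sub-asymptotic tail class

    p(lambda) ~= q * exp(-a * (lambda - b)^c),    a > 0, c > 0, b < lambda

is fitted, in log space, to the empirical curve above a cut-off lambda_0,
each point weighted by the inverse squared width of its log-scale
confidence band.  The fitted tail is then extrapolated and inverted to
find the return level lambda* expected to be exceeded once over a given
horizon.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .core import ExceedanceCurve

__all__ = [
    "TailFit",
    "Prediction",
    "attach_confidence_intervals",
    "fit_tail",
    "extrapolate",
    "predict_return_level",
]


def _tail_eval(params: tuple[float, float, float, float], lam: np.ndarray) -> np.ndarray:
    q, a, b, c = params
    lam = np.asarray(lam, dtype=np.float64)
    if np.any(lam <= b):
        raise ValueError(f"tail form undefined at lambda <= b = {b!r}")
    return q * np.exp(-a * np.power(lam - b, c))


@dataclass(frozen=True)
class TailFit:
    """Fitted parametric tail of p(lambda) above the cut-off.

    ``params`` is (q, a, b, c); ``ci_params`` optionally holds the same
    form fitted to the lower and upper confidence series, giving the
    extrapolated confidence band.
    """

    params: tuple[float, float, float, float]
    cutoff: float
    fit_range: tuple[float, float]
    residual: float
    N: int
    k: int
    n_points: int
    form: str = "naess-gaidai"
    ci_params: dict | None = None

    def __post_init__(self) -> None:
        q, a, b, c = self.params
        if not (a > 0 and c > 0):
            raise ValueError("tail parameters require a > 0 and c > 0")
        if b >= self.fit_range[0]:
            raise ValueError("tail offset b must lie below the fitted range")

    def __call__(self, lam: np.ndarray) -> np.ndarray:
        return _tail_eval(self.params, lam)

    def to_dict(self) -> dict:
        q, a, b, c = self.params
        out = {
            "form": self.form,
            "q": q,
            "a": a,
            "b": b,
            "c": c,
            "cutoff": self.cutoff,
            "fit_range": list(self.fit_range),
            "residual": self.residual,
            "N": self.N,
            "k": self.k,
            "n_points": self.n_points,
        }
        if self.ci_params is not None:
            out["ci_params"] = {key: list(val) for key, val in self.ci_params.items()}
        return out


@dataclass(frozen=True)
class Prediction:
    """A solved return level and its mapping back to a rate in %."""

    lambda_star: float
    rate_percent: float
    horizon_years: float
    criterion: str
    p_target: float
    maxima_per_year: float
    ci_lo: float | None = None
    ci_hi: float | None = None

    def __post_init__(self) -> None:
        if self.ci_lo is not None and self.ci_hi is not None:
            if not (self.ci_lo <= self.rate_percent <= self.ci_hi):
                raise ValueError("prediction CI must bracket the point estimate")

    def to_dict(self) -> dict:
        return {
            "lambda_star": self.lambda_star,
            "rate_percent": self.rate_percent,
            "horizon_years": self.horizon_years,
            "criterion": self.criterion,
            "p_target": self.p_target,
            "maxima_per_year": self.maxima_per_year,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
        }


# ---------------------------------------------------------------------------
# confidence intervals


def attach_confidence_intervals(
    curve: ExceedanceCurve, confidence: float = 0.95
) -> ExceedanceCurve:
    """Attach count-based confidence bands p*(1 +/- z/sqrt(n_exc)).

    This is the Poisson approximation to the exceedance count: the
    relative error of p-hat is ~ 1/sqrt(number of exceedances).  Points
    without exceedances carry no interval (NaN) and are excluded from
    tail fitting.  Bounds are clipped to [0, 1].
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        half = z / np.sqrt(curve.n_exc.astype(float))
        lo = np.clip(curve.p * (1.0 - half), 0.0, 1.0)
        hi = np.clip(curve.p * (1.0 + half), 0.0, 1.0)
    no_ci = curve.n_exc <= 0
    lo[no_ci] = np.nan
    hi[no_ci] = np.nan
    return replace(curve, ci_lo=lo, ci_hi=hi)


# ---------------------------------------------------------------------------
# tail fitting


def _profile_residual(
    b: float, c: float, lam: np.ndarray, lnp: np.ndarray, w: np.ndarray
) -> tuple[float, float, float]:
    """Weighted least squares for (ln q, a) at fixed (b, c).

    ln p = ln q - a * (lam - b)^c is linear in (ln q, a); returns
    (weighted residual sum, ln q, a), with an infinite residual when the
    profile solution violates a > 0.
    """
    g = np.power(lam - b, c)
    sw = np.sqrt(w)
    design = np.column_stack([sw, -sw * g])
    coef, *_ = np.linalg.lstsq(design, sw * lnp, rcond=None)
    lnq, a = float(coef[0]), float(coef[1])
    if not np.isfinite(a) or a <= 0:
        return np.inf, lnq, a
    resid = float(np.sum(w * (lnp - (lnq - a * g)) ** 2))
    return resid, lnq, a


def _fit_log_series(
    lam: np.ndarray,
    lnp: np.ndarray,
    w: np.ndarray,
    cutoff: float,
    form: str,
) -> tuple[tuple[float, float, float, float], float]:
    """Multi-start fit of ln p ~= ln q - a (lam - b)^c.

    (ln q, a) are profiled out exactly; Nelder-Mead searches (b, c) from a
    deterministic 8-point start grid, c in [0.5, 3] x b in {0, 0.9*b_max}.
    Ties in the residual are broken toward c closest to 1 (the plain
    exponential member of the family).
    """
    lam_min = float(lam.min())
    b_max = 0.9 * min(cutoff, lam_min)

    if form == "exponential":
        resid, lnq, a = _profile_residual(0.0, 1.0, lam, lnp, w)
        if not np.isfinite(resid):
            raise RuntimeError("exponential tail fit failed (nonpositive slope)")
        return (float(np.exp(lnq)), a, 0.0, 1.0), resid
    if form != "naess-gaidai":
        raise ValueError(f"unknown tail form {form!r}")

    # the offset b is confined to [0, 0.9*cutoff]: rates are nonnegative,
    # and an offset approaching the cut-off degenerates the form
    b_hi = max(min(b_max, lam_min - 1e-9), 0.0)

    def objective(x: np.ndarray) -> float:
        b, c = x
        if not (0.0 <= b <= b_hi and 0.05 <= c <= 10.0):
            return 1e12
        resid, _, _ = _profile_residual(b, c, lam, lnp, w)
        return resid if np.isfinite(resid) else 1e12

    candidates: list[tuple[float, float, float]] = []  # (resid, b, c)
    starts = list(itertools.product((0.0, b_hi), (0.5, 1.0, 1.8, 3.0)))
    for b0, c0 in starts:
        res = optimize.minimize(
            objective,
            x0=np.array([b0, c0]),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
        )
        b, c = res.x
        r = objective(res.x)
        if np.isfinite(r) and r < 1e12:
            candidates.append((r, float(b), float(c)))
    if not candidates:
        raise RuntimeError("tail fit failed to converge from every start")
    best = min(r for r, _, _ in candidates)
    tie_tol = 1e-12 + 1e-9 * best
    tied = [(b, c) for r, b, c in candidates if r <= best + tie_tol]
    b, c = min(tied, key=lambda bc: abs(bc[1] - 1.0))
    resid, lnq, a = _profile_residual(b, c, lam, lnp, w)
    return (float(np.exp(lnq)), a, b, c), resid


def fit_tail(
    curve: ExceedanceCurve,
    cutoff: float,
    form: str = "naess-gaidai",
    fit_ci: bool = True,
) -> TailFit:
    """Fit the parametric tail to the empirical curve above the cut-off.

    Only supported points (positive conditioning count, positive p) at
    lambda >= cutoff are used; at least 5 are required.  When the curve
    carries confidence bands the weights are the normalized inverse
    squared log-band widths, otherwise all points weigh equally (the
    noiseless self-consistency case).  With ``fit_ci`` the same form is
    fitted to the lower/upper confidence series to give extrapolated
    bands.
    """
    lam = curve.lambdas
    mask = (lam >= cutoff) & (curve.n_cond > 0) & (curve.p > 0)
    has_ci = curve.ci_lo is not None and curve.ci_hi is not None
    if has_ci:
        ci_ok = (
            np.isfinite(curve.ci_lo)
            & np.isfinite(curve.ci_hi)
            & (curve.ci_lo > 0)
            & (curve.ci_hi > curve.ci_lo)
        )
    if int(mask.sum()) < 5:
        raise ValueError(
            f"need at least 5 usable grid points above the cutoff {cutoff!r}; "
            f"got {int(mask.sum())}"
        )
    lam_fit = lam[mask]
    lnp = np.log(curve.p[mask])
    if has_ci and bool(np.all(ci_ok[mask])):
        width = np.log(curve.ci_hi[mask]) - np.log(curve.ci_lo[mask])
        w = 1.0 / width**2
    else:
        w = np.ones(lam_fit.size)
    w = w / w.sum()

    params, resid = _fit_log_series(lam_fit, lnp, w, cutoff, form)
    ci_params = None
    if fit_ci and has_ci:
        band_mask = mask & ci_ok
        if int(band_mask.sum()) >= 5:
            lam_b = lam[band_mask]
            w_b = w[ci_ok[mask]] if lam_b.size == int(np.sum(ci_ok[mask])) else None
            if w_b is None or w_b.size != lam_b.size:
                w_b = np.ones(lam_b.size) / lam_b.size
            lo_params, _ = _fit_log_series(
                lam_b, np.log(curve.ci_lo[band_mask]), w_b, cutoff, form
            )
            hi_params, _ = _fit_log_series(
                lam_b, np.log(curve.ci_hi[band_mask]), w_b, cutoff, form
            )
            ci_params = {"lo": lo_params, "hi": hi_params}
    return TailFit(
        params=params,
        cutoff=float(cutoff),
        fit_range=(float(lam_fit.min()), float(lam_fit.max())),
        residual=float(resid),
        N=curve.N,
        k=curve.k,
        n_points=int(lam_fit.size),
        form=form,
        ci_params=ci_params,
    )


def extrapolate(
    fit: TailFit, lambdas: np.ndarray, with_ci: bool = True
) -> dict[str, np.ndarray]:
    """Evaluate the fitted tail (and its confidence band) on a grid.

    Levels below the cut-off are refused: in the data region the
    empirical curve, not the fit, is authoritative.
    """
    lambdas = np.atleast_1d(np.asarray(lambdas, dtype=np.float64))
    if np.any(lambdas < fit.cutoff - 1e-12):
        raise ValueError("extrapolation below the cut-off is not supported")
    p = _tail_eval(fit.params, lambdas)
    out = {"lambda": lambdas, "p": p}
    if with_ci and fit.ci_params is not None:
        lo = _tail_eval(fit.ci_params["lo"], lambdas)
        hi = _tail_eval(fit.ci_params["hi"], lambdas)
        # fitted bands can cross the point fit slightly; keep them nested
        out["ci_lo"] = np.minimum(lo, p)
        out["ci_hi"] = np.maximum(hi, p)
    return out


# ---------------------------------------------------------------------------
# return levels


def _bisect_level(
    params: tuple[float, float, float, float],
    p_target: float,
    lo: float,
    rtol: float = 1e-12,
) -> float:
    """Bisection for p(lambda*) = p_target on the monotone fitted tail."""
    q, a, b, c = params
    f = lambda lam: _tail_eval(params, np.array([lam]))[0] - p_target
    if f(lo) < 0:
        raise ValueError(
            "target exceedance rate lies above the fitted tail at the cut-off "
            "(the solved level would fall inside the data region)"
        )
    # closed-form bracket: the form inverts analytically (p_target < q here)
    lam_closed = b + ((np.log(q) - np.log(p_target)) / a) ** (1.0 / c)
    hi = max(lam_closed * 1.5 + 0.5, lo + 1.0)
    expand = 0
    while f(hi) > 0:
        hi = lo + (hi - lo) * 2
        expand += 1
        if expand > 200:
            raise ValueError("target exceedance rate is below the fitted tail range")
    a_, b_ = lo, hi
    while (b_ - a_) > rtol * max(1.0, abs(b_)):
        mid = 0.5 * (a_ + b_)
        if f(mid) > 0:
            a_ = mid
        else:
            b_ = mid
    return 0.5 * (a_ + b_)


def predict_return_level(
    fit: TailFit,
    maxima_per_year: float,
    horizon_years: float = 100.0,
    target: str | float = "one_expected_exceedance",
    reference_eta: float = 1.0,
) -> Prediction:
    """Solve for the return level lambda* over a prediction horizon.

    The default criterion asks for one expected exceedance over the
    horizon: p(lambda*) = 1 / (maxima_per_year * horizon_years).  Passing
    a float ``target`` instead solves for a survival probability:
    exp(-maxima_per_year * horizon_years * p(lambda*)) = target.  The
    solved dimensionless level maps back to a rate in % of population via
    ``reference_eta``; the confidence interval comes from applying the
    same solve to the fitted confidence-band curves.
    """
    if not maxima_per_year > 0:
        raise ValueError("maxima_per_year must be positive")
    if not horizon_years > 0:
        raise ValueError("horizon_years must be positive")
    n_eff = maxima_per_year * horizon_years
    if target == "one_expected_exceedance":
        p_target = 1.0 / n_eff
        criterion = (
            f"p(lambda*) = 1/(maxima_per_year*horizon) = {p_target:.6g} "
            "(one expected exceedance over the horizon)"
        )
    else:
        prob = float(target)
        if not 0.0 < prob < 1.0:
            raise ValueError("explicit target probability must lie in (0, 1)")
        p_target = -np.log(prob) / n_eff
        criterion = (
            f"exp(-maxima_per_year*horizon*p(lambda*)) = {prob:.6g} "
            f"=> p(lambda*) = {p_target:.6g}"
        )
    lam_star = _bisect_level(fit.params, p_target, lo=fit.cutoff)
    ci_lo = ci_hi = None
    if fit.ci_params is not None:
        b_lo = fit.ci_params["lo"][2]
        b_hi = fit.ci_params["hi"][2]
        try:
            # the lower p band crosses the target earlier (smaller level)
            lam_lo = _bisect_level(fit.ci_params["lo"], p_target, lo=max(b_lo + 1e-9, 1e-9))
            lam_hi = _bisect_level(fit.ci_params["hi"], p_target, lo=max(b_hi + 1e-9, 1e-9))
            lo_level = min(lam_lo, lam_hi, lam_star)
            hi_level = max(lam_lo, lam_hi, lam_star)
            ci_lo = lo_level * reference_eta
            ci_hi = hi_level * reference_eta
        except ValueError:
            ci_lo = ci_hi = None
    return Prediction(
        lambda_star=float(lam_star),
        rate_percent=float(lam_star * reference_eta),
        horizon_years=float(horizon_years),
        criterion=criterion,
        p_target=float(p_target),
        maxima_per_year=float(maxima_per_year),
        ci_lo=ci_lo,
        ci_hi=ci_hi,
    )
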