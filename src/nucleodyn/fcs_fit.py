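"""Diffusion + two-binding-population ACF model: evaluation and fitting.

The model describes the normalized fluorescence autocorrelation of a
transcription factor that diffuses through a 3-D Gaussian observation
volume and exchanges with two classes of immobile chromatin sites::

    G(tau) = 1/(2^{3/2} N) * [ f_D (1 + tau/tau_D)^{-1} (1 + tau/(omega^2 tau_D))^{-1/2}
                               + f_short exp(-tau/tau_short)
                               + f_long  exp(-tau/tau_long) ]

N is the mean number of molecules in the confocal volume, tau_D the
characteristic diffusion time, omega = w_z/w_r the waist ratio, and the
three f terms are the population fractions (freely diffusing, short-lived
bound, long-lived bound) with residence times tau_short < tau_long whose
reciprocals are the dissociation rates k_off.

Fitting is weighted nonlinear least squares with the fractions
parameterized on the simplex (stick-breaking), characteristic times in log
space, and a multi-start grid over (tau_short, tau_long) to avoid the local
minima of the two-exponential branch. omega is a fixed calibration input —
it is degenerate with tau_D and is never fitted.
"""

from __future__ import annotations

import math
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .types import CorrelationCurve, FcsParams, FitResult

__all__ = [
    "evaluate_acf_model",
    "AcfModelFitter",
    "fit_acf",
    "bootstrap_se",
]

_AMPLITUDE = 2.0 ** -1.5  # geometric factor of the 3-D Gaussian volume


def evaluate_acf_model(params: FcsParams, lags) -> np.ndarray:
    """Evaluate G(tau) of the diffusion + two-binding-population model.

    Parameters
    ----------
    params : FcsParams
        Model parameters (validated on construction).
    lags : array-like
        Lag times in seconds, >= 0.

    Returns
    -------
    ndarray
        G values; finite, strictly positive, non-increasing in tau.
    """
    tau = np.asarray(lags, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lags must be >= 0")
    diff = (1.0 + tau / params.tau_diff) ** -1.0 * (
        1.0 + tau / (params.omega**2 * params.tau_diff)
    ) ** -0.5
    g = (
        params.f_diff * diff
        + params.f_short * np.exp(-tau / params.tau_short)
        + params.f_long * np.exp(-tau / params.tau_long)
    )
    return _AMPLITUDE / params.n_molecules * g


def _model_curve(
    n_molecules: float,
    fractions: Tuple[float, float, float],
    tau_diff: float,
    omega: float,
    tau_short: float,
    tau_long: float,
    tau: np.ndarray,
) -> np.ndarray:
    # unchecked fast path used inside the optimizer (no FcsParams validation)
    f_d, f_s, f_l = fractions
    g = np.zeros_like(tau)
    if f_d:
        g += f_d * (1.0 + tau / tau_diff) ** -1.0 * (
            1.0 + tau / (omega**2 * tau_diff)
        ) ** -0.5
    if f_s:
        g += f_s * np.exp(-tau / tau_short)
    if f_l:
        g += f_l * np.exp(-tau / tau_long)
    return _AMPLITUDE / n_molecules * g


class AcfModelFitter(BaseEstimator):
    """Weighted least-squares fitter for the diffusion + binding ACF model.

    scikit-learn-style estimator: configure in ``__init__``, call
    :meth:`fit` on a correlation curve, read fitted attributes
    (``params_``, ``se_``, ``rss_``, ``converged_``).

    Parameters
    ----------
    omega : float, default 5.0
        Axial/radial waist ratio; fixed calibration input, never fitted.
    components : sequence of {"diffusion", "short", "long"}
        Model branches to include. The default full model has all three;
        ``("diffusion",)`` fits pure diffusion, ``("diffusion", "long")``
        diffusion plus a single exponential.
    fixed_tau_diff : float or None
        If given, the diffusion time is frozen at this value (s).
    tau_short_grid, tau_long_grid : sequence of float
        Multi-start initial values for the residence times (s); the
        Cartesian product of the grids seeds the restarts, best residual
        sum of squares wins, ties broken by the smaller tau_long.
    weights : {"sd", "uniform"}
        "sd" uses 1/SD(tau) residual weights when the curve carries per-lag
        standard deviations (falling back to uniform otherwise).
    lag_range : (float, float) or None
        If given, only lags inside [lo, hi] (s) enter the fit.

    Attributes
    ----------
    params_ : FcsParams
        Best-fit parameters, residence times ordered tau_short < tau_long.
    se_ : dict
        Per-parameter standard errors from the curvature at the optimum
        (delta method for the simplex-derived fractions and the
        log-parameterized times).
    rss_ : float
        Weighted residual sum of squares at the optimum.
    converged_ : bool
        False when no restart converged (best attempt is still reported).
    n_restarts_used_ : int
        Number of optimizer starts attempted.
    """

    def __init__(
        self,
        omega: float = 5.0,
        components: Sequence[str] = ("diffusion", "short", "long"),
        fixed_tau_diff: Optional[float] = None,
        tau_short_grid: Sequence[float] = (1e-3, 1e-2, 1e-1),
        tau_long_grid: Sequence[float] = (1e-1, 1.0, 10.0),
        weights: str = "sd",
        lag_range: Optional[Tuple[float, float]] = None,
    ) -> None:
        self.omega = omega
        self.components = components
        self.fixed_tau_diff = fixed_tau_diff
        self.tau_short_grid = tau_short_grid
        self.tau_long_grid = tau_long_grid
        self.weights = weights
        self.lag_range = lag_range

    # -- internal parameter packing ------------------------------------

    def _validate(self) -> None:
        comps = tuple(self.components)
        bad = set(comps) - {"diffusion", "short", "long"}
        if bad:
            raise ValueError(f"unknown components: {sorted(bad)}")
        if not comps:
            raise ValueError("at least one model component required")
        if not self.omega > 0:
            raise ValueError("omega must be > 0")
        self._comps = comps

    def _free_names(self):
        names = ["log_n"]
        k = len(self._comps)
        names += [f"stick_{i}" for i in range(k - 1)]
        if "diffusion" in self._comps and self.fixed_tau_diff is None:
            names.append("log_tau_diff")
        if "short" in self._comps:
            names.append("log_tau_short")
        if "long" in self._comps:
            names.append("log_tau_long")
        return names

    def _unpack(self, theta: np.ndarray):
        """theta -> (N, fractions(D,S,L), tau_diff, tau_short, tau_long)."""
        names = self._names
        vals = dict(zip(names, theta))
        n_mol = math.exp(vals["log_n"])
        # stick-breaking over the included components, in (D, S, L) order
        remaining = 1.0
        comp_frac = {}
        sticks = [vals[f"stick_{i}"] for i in range(len(self._comps) - 1)]
        for comp, s in zip(self._comps[:-1], sticks):
            comp_frac[comp] = remaining * s
            remaining -= comp_frac[comp]
        comp_frac[self._comps[-1]] = remaining
        fractions = (
            comp_frac.get("diffusion", 0.0),
            comp_frac.get("short", 0.0),
            comp_frac.get("long", 0.0),
        )
        tau_diff = (
            self.fixed_tau_diff
            if self.fixed_tau_diff is not None
            else math.exp(vals.get("log_tau_diff", 0.0))
        )
        tau_short = math.exp(vals.get("log_tau_short", math.log(1e-2)))
        tau_long = math.exp(vals.get("log_tau_long", math.log(1.0)))
        return n_mol, fractions, tau_diff, tau_short, tau_long

    # -- fitting -------------------------------------------------------

    def fit(self, curve, g=None, sd=None):
        """Fit the model to a correlation curve.

        Accepts either a :class:`CorrelationCurve` or ``(lags, g[, sd])``
        arrays. Returns ``self``.
        """
        if isinstance(curve, CorrelationCurve):
            lags, gv, sdv = curve.lags, curve.g, curve.sd
        else:
            lags = np.asarray(curve, dtype=float).ravel()
            gv = np.asarray(g, dtype=float)
            sdv = None if sd is None else np.asarray(sd, dtype=float)
        self._validate()
        self._names = self._free_names()

        if self.lag_range is not None:
            lo, hi = self.lag_range
            keep = (lags >= lo) & (lags <= hi)
            lags, gv = lags[keep], gv[keep]
            sdv = None if sdv is None else sdv[keep]
        if lags.size < 10:
            raise ValueError("need >= 10 lags to fit the ACF model")
        if lags[-1] / lags[0] < 1e3:
            raise ValueError("lag grid must span >= 3 decades")

        amp0 = float(np.mean(gv[: max(3, lags.size // 50)]))
        if amp0 <= 0:
            raise ValueError("curve amplitude must be positive")

        if self.weights == "sd" and sdv is not None and np.all(sdv > 0):
            w = 1.0 / sdv
        else:
            w = np.ones_like(gv)

        def residuals(theta):
            n_mol, fr, td, ts, tl = self._unpack(theta)
            return w * (_model_curve(n_mol, fr, td, self.omega, ts, tl, lags) - gv)

        # bounds: sticks in [0,1]; log-times generously bracketed by the grid
        lo_b, hi_b = [], []
        for name in self._names:
            if name.startswith("stick"):
                lo_b.append(0.0)
                hi_b.append(1.0)
            elif name == "log_n":
                lo_b.append(math.log(1e-6))
                hi_b.append(math.log(1e9))
            else:
                lo_b.append(math.log(1e-8))
                hi_b.append(math.log(1e4))

        n0 = max(_AMPLITUDE / amp0, 1e-6)
        tau_d0 = self.fixed_tau_diff or self._guess_tau_half(lags, gv, amp0)

        starts = []
        ts_grid = self.tau_short_grid if "short" in self._comps else [None]
        tl_grid = self.tau_long_grid if "long" in self._comps else [None]
        for ts0 in ts_grid:
            for tl0 in tl_grid:
                start = {}
                start["log_n"] = math.log(n0)
                k = len(self._comps)
                for i in range(k - 1):
                    # equal fractions: stick i = 1/(k - i)
                    start[f"stick_{i}"] = 1.0 / (k - i)
                if "log_tau_diff" in self._names:
                    start["log_tau_diff"] = math.log(tau_d0)
                if ts0 is not None:
                    start["log_tau_short"] = math.log(ts0)
                if tl0 is not None:
                    start["log_tau_long"] = math.log(tl0)
                starts.append([start[n] for n in self._names])

        best = None
        for x0 in starts:
            try:
                res = least_squares(
                    residuals,
                    x0,
                    bounds=(lo_b, hi_b),
                    method="trf",
                    xtol=1e-15,
                    ftol=1e-15,
                    gtol=1e-15,
                    max_nfev=4000,
                )
            except Exception:
                continue
            rss = float(2 * res.cost)
            if best is None:
                best = (rss, res)
                continue
            rel = abs(rss - best[0]) / max(best[0], 1e-300)
            if rss < best[0] and rel > 1e-9:
                best = (rss, res)
            elif rel <= 1e-9:
                # tie on RSS: prefer the smaller fitted tau_long
                if self._tau_long_of(res.x) < self._tau_long_of(best[1].x):
                    best = (rss, res)

        if best is None:
            raise RuntimeError("all optimizer restarts failed")
        rss, res = best
        self._finalize(res, rss, lags, w, len(starts))
        return self

    def _tau_long_of(self, theta):
        return self._unpack(theta)[4]

    @staticmethod
    def _guess_tau_half(lags, gv, amp0) -> float:
        """Lag at which the curve first drops below half its amplitude."""
        below = np.nonzero(gv < 0.5 * amp0)[0]
        return float(lags[below[0]]) if below.size else float(lags[lags.size // 2])

    def _finalize(self, res, rss, lags, w, n_starts) -> None:
        theta = res.x
        n_mol, (f_d, f_s, f_l), tau_d, tau_s, tau_l = self._unpack(theta)

        # covariance from the Jacobian at the optimum
        dof = max(lags.size - theta.size, 1)
        sigma2 = rss / dof
        jtj = res.jac.T @ res.jac
        try:
            cov = sigma2 * np.linalg.pinv(jtj)
        except np.linalg.LinAlgError:
            cov = np.full((theta.size, theta.size), np.nan)

        idx = {n: i for i, n in enumerate(self._names)}

        def _grad_se(grad: dict) -> float:
            gvec = np.zeros(theta.size)
            for name, val in grad.items():
                if name in idx:
                    gvec[idx[name]] = val
            v = float(gvec @ cov @ gvec)
            return math.sqrt(v) if v > 0 else 0.0

        # delta method: d/d(log x) -> x * SE(log x); fractions via the
        # stick-breaking chain rule in (comps) order
        se = {
            "n_molecules": _grad_se({"log_n": n_mol}),
            "tau_diff": (
                0.0
                if "log_tau_diff" not in idx
                else _grad_se({"log_tau_diff": tau_d})
            ),
            "tau_short": _grad_se({"log_tau_short": tau_s}) if "short" in self._comps else 0.0,
            "tau_long": _grad_se({"log_tau_long": tau_l}) if "long" in self._comps else 0.0,
        }
        frac_grads = self._fraction_gradients(theta)
        for comp, key in (("diffusion", "f_diff"), ("short", "f_short"), ("long", "f_long")):
            se[key] = _grad_se(frac_grads.get(comp, {}))

        fractions = {"f_diff": f_d, "f_short": f_s, "f_long": f_l}
        # order residence times: the two exponentials are exchangeable,
        # relabel so tau_short < tau_long
        if "short" in self._comps and "long" in self._comps and tau_s > tau_l:
            tau_s, tau_l = tau_l, tau_s
            fractions["f_short"], fractions["f_long"] = (
                fractions["f_long"],
                fractions["f_short"],
            )
            se["tau_short"], se["tau_long"] = se["tau_long"], se["tau_short"]
            se["f_short"], se["f_long"] = se["f_long"], se["f_short"]
        if tau_s >= tau_l:  # degenerate single-component cases
            tau_l = tau_s * (1 + 1e-9) if tau_s == tau_l else tau_l
            if tau_s > tau_l:
                tau_s, tau_l = tau_l, tau_s

        self.params_ = FcsParams(
            n_molecules=n_mol,
            f_diff=min(max(fractions["f_diff"], 0.0), 1.0),
            f_short=min(max(fractions["f_short"], 0.0), 1.0),
            f_long=min(max(fractions["f_long"], 0.0), 1.0),
            tau_diff=tau_d,
            omega=self.omega,
            tau_short=tau_s,
            tau_long=tau_l,
        )
        self.se_ = se
        self.rss_ = rss
        self.converged_ = bool(res.success)
        self.n_restarts_used_ = n_starts

    def _fraction_gradients(self, theta):
        """d(fraction)/d(stick) for each included component (chain rule)."""
        names = self._names
        vals = dict(zip(names, theta))
        sticks = [vals[f"stick_{i}"] for i in range(len(self._comps) - 1)]
        grads = {}
        remaining = 1.0
        d_remaining = {}  # d(remaining)/d(stick_j)
        for i, comp in enumerate(self._comps):
            if i < len(sticks):
                s = sticks[i]
                g = {f"stick_{i}": remaining}
                for k, dv in d_remaining.items():
                    g[k] = g.get(k, 0.0) + s * dv
                grads[comp] = g
                new_d = {k: dv * (1 - s) for k, dv in d_remaining.items()}
                new_d[f"stick_{i}"] = new_d.get(f"stick_{i}", 0.0) - remaining
                remaining *= 1 - s
                d_remaining = new_d
            else:
                grads[comp] = dict(d_remaining)
        return grads

    # -- sklearn conveniences ------------------------------------------

    def predict(self, lags) -> np.ndarray:
        """Evaluate the fitted model on a lag grid."""
        if not hasattr(self, "params_"):
            raise RuntimeError("fitter is not fitted")
        return evaluate_acf_model(self.params_, lags)

    def result(self) -> FitResult:
        """Package the fitted state as a FitResult record."""
        if not hasattr(self, "params_"):
            raise RuntimeError("fitter is not fitted")
        return FitResult(
            params=self.params_,
            se=dict(self.se_),
            rss=self.rss_,
            converged=self.converged_,
            n_restarts_used=self.n_restarts_used_,
        )


def fit_acf(
    curve: CorrelationCurve,
    omega: float = 5.0,
    fixed_tau_diff: Optional[float] = None,
    components: Sequence[str] = ("diffusion", "short", "long"),
    lag_range: Optional[Tuple[float, float]] = None,
    **kwargs,
) -> FitResult:
    """Fit the ACF model to one curve; thin wrapper over AcfModelFitter."""
    fitter = AcfModelFitter(
        omega=omega,
        fixed_tau_diff=fixed_tau_diff,
        components=components,
        lag_range=lag_range,
        **kwargs,
    )
    fitter.fit(curve)
    return fitter.result()


def bootstrap_se(
    samples,
    statistic: Callable = np.median,
    n_reps: int = 1000,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """Bootstrap standard error and variance of a statistic.

    Resamples ``samples`` with replacement ``n_reps`` times, evaluates the
    statistic on each resample and returns (SE, variance) where SE is the
    standard deviation of the bootstrap distribution and variance = SE².

    Parameters
    ----------
    samples : array-like, length >= 2
    statistic : callable
        Reduces a 1-D array to a scalar (default: median). Callables that
        accept an ``axis`` keyword (numpy reductions) are evaluated in one
        vectorized pass.
    n_reps : int, >= 2 (>= 100 recommended)
    seed : int or None
        Seed for the resampling RNG; fixed seed gives identical output.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sample of length >= 2")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_reps, x.size))
    resampled = x[idx]
    try:
        stats = np.asarray(statistic(resampled, axis=1), dtype=float)
        if stats.shape != (n_reps,):
            raise TypeError
    except TypeError:
        stats = np.array([statistic(row) for row in resampled], dtype=float)
    se = float(np.std(stats, ddof=0))
    return se, se * se
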