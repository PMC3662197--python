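"""Two-step series thermal-deactivation kinetics.

Thermal inactivation of many thermostable enzymes does not follow a single
exponential: the native enzyme ``E0`` first converts, with first-order rate
constant ``k1``, into a partially active intermediate ``E1`` (specific-activity
ratio ``alpha1 = E1/E0``), which in turn decays with constant ``k2`` into a
fully inactive state ``E2``::

    E0 --k1--> E1 --k2--> E2,        alpha2 = E2/E0 = 0

The observed residual activity (fraction of the activity at time zero) is the
biexponential

    alpha(t) = (1 + c) * exp(-k1 t) - c * exp(-k2 t),
    c = alpha1 * k1 / (k2 - k1)

which degenerates to ``alpha(t) = (1 + alpha1 k1 t) exp(-k1 t)`` as
``k2 -> k1``.  This module provides the closed-form curve, a bounded
multistart nonlinear least-squares model for it (:class:`TwoStepDeactivation`),
the nested single-exponential comparison model
(:class:`FirstOrderDeactivation`), AIC-based model comparison and half-life
computation.  Time is in minutes and rate constants in 1/min throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "DeactParams",
    "TimeCourse",
    "FitComparison",
    "FitError",
    "residual_activity",
    "TwoStepDeactivation",
    "TwoStepDeactivationResults",
    "FirstOrderDeactivation",
    "FirstOrderResults",
    "fit_two_step",
    "fit_first_order",
    "compare_models",
    "half_life",
    "read_timecourse_csv",
    "write_timecourse_csv",
]

# relative tolerance below which the k1 ~= k2 analytic limit is used
_SINGULAR_RTOL = 1e-8


class FitError(RuntimeError):
    """Raised when no multistart attempt converges; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def residual_activity(t, alpha1: float, k1: float, k2: float):
    """Residual-activity fraction alpha(t) of the two-step series model.

    Parameters
    ----------
    t : float or array-like
        Time in minutes, nonnegative.
    alpha1 : float
        Specific-activity ratio of the intermediate state, in [0, 1].
    k1, k2 : float
        First-order deactivation constants (1/min), positive.

    Returns
    -------
    float or ndarray
        alpha(t); exactly 1 at t = 0.  Near the removable singularity
        ``k1 == k2`` the analytic limit ``(1 + alpha1 k1 t) exp(-k1 t)``
        is evaluated instead of the ill-conditioned difference form.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    if not 0.0 <= alpha1 <= 1.0:
        raise ValueError(f"alpha1 must lie in [0, 1], got {alpha1}")
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rate constants must be positive")
    out = _alpha_curve(t_arr, alpha1, k1, k2)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _alpha_curve(t: np.ndarray, alpha1: float, k1: float, k2: float) -> np.ndarray:
    # internal, no validation: used inside optimizer loops
    if abs(k2 - k1) < _SINGULAR_RTOL * k1:
        return (1.0 + alpha1 * k1 * t) * np.exp(-k1 * t)
    c = alpha1 * k1 / (k2 - k1)
    return (1.0 + c) * np.exp(-k1 * t) - c * np.exp(-k2 * t)


@dataclass(frozen=True)
class DeactParams:
    """Point estimates and diagnostics of a two-step deactivation fit."""

    alpha1: float
    k1: float
    k2: float
    se_alpha1: float = np.nan
    se_k1: float = np.nan
    se_k2: float = np.nan
    ssr: float = np.nan
    r2: float = np.nan
    n_obs: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha1 <= 1.0:
            raise ValueError("alpha1 must lie in [0, 1]")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")


@dataclass
class TimeCourse:
    """Residual-activity observations of one enzyme at one temperature.

    ``observations`` is a tidy DataFrame with columns ``time_min``,
    ``replicate`` and ``residual_activity`` (fractions of the t = 0
    activity; the curves are assumed pre-normalized so alpha(0) = 1).
    """

    enzyme_id: str
    temperature_c: float
    observations: pd.DataFrame = field(repr=False)
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        obs = self.observations
        required = {"time_min", "replicate", "residual_activity"}
        missing = required - set(obs.columns)
        if missing:
            raise ValueError(f"observations missing columns: {sorted(missing)}")
        t = obs["time_min"].to_numpy(dtype=float)
        y = obs["residual_activity"].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)) or np.any(t < 0):
            raise ValueError("times must be finite and nonnegative")
        if np.any(y < 0) and not self.meta.get("truncated_at_zero", False):
            # negative fractions can only arise from noise; they are legal
            # observations for fitting but flag them in metadata
            self.meta["has_negative_observations"] = True

    @property
    def time(self) -> np.ndarray:
        return self.observations["time_min"].to_numpy(dtype=float)

    @property
    def activity(self) -> np.ndarray:
        return self.observations["residual_activity"].to_numpy(dtype=float)

    @property
    def n_distinct_times(self) -> int:
        return int(np.unique(self.time).size)

    @classmethod
    def from_arrays(cls, enzyme_id, temperature_c, time, activity, replicate=None,
                    meta=None) -> "TimeCourse":
        time = np.asarray(time, dtype=float)
        activity = np.asarray(activity, dtype=float)
        if replicate is None:
            replicate = np.zeros(time.size, dtype=int)
        obs = pd.DataFrame({
            "time_min": time,
            "replicate": np.asarray(replicate),
            "residual_activity": activity,
        })
        return cls(enzyme_id, float(temperature_c), obs, dict(meta or {}))


def read_timecourse_csv(path_or_buf) -> list[TimeCourse]:
    """Read tidy time-course CSV (enzyme_id, temperature_C, replicate,
    time_min, residual_activity) into one TimeCourse per (enzyme, T)."""
    df = pd.read_csv(path_or_buf)
    df = df.rename(columns={"temperature_C": "temperature_c"})
    out = []
    for (enz, temp), grp in df.groupby(["enzyme_id", "temperature_c"], sort=True):
        obs = grp[["time_min", "replicate", "residual_activity"]].reset_index(drop=True)
        out.append(TimeCourse(str(enz), float(temp), obs))
    return out


def write_timecourse_csv(timecourses: Sequence[TimeCourse], path_or_buf) -> None:
    frames = []
    for tc in timecourses:
        f = tc.observations.copy()
        f.insert(0, "enzyme_id", tc.enzyme_id)
        f.insert(1, "temperature_C", tc.temperature_c)
        frames.append(f[["enzyme_id", "temperature_C", "replicate",
                         "time_min", "residual_activity"]])
    pd.concat(frames, ignore_index=True).to_csv(path_or_buf, index=False)


def _as_time_activity(data, activity=None):
    """Accept a TimeCourse or (time, activity) arrays."""
    if isinstance(data, TimeCourse):
        return data.time, data.activity
    return np.asarray(data, dtype=float), np.asarray(activity, dtype=float)


class TwoStepDeactivation:
    """Bounded nonlinear least-squares model for two-step deactivation.

    Parameters
    ----------
    time, activity : array-like
        Observation times (min) and residual-activity fractions.  Replicates
        appear as repeated time values.

    The fit minimizes the unweighted sum of squared residuals subject to
    ``alpha1 in [0, 1]`` and ``k1, k2 > 0`` (no ordering of k1 and k2 is
    imposed).  A multistart strategy guards against the local minima of the
    biexponential surface: the first start is data-driven (k1 from the
    initial slope of ln alpha, k2 from the final slope, alpha1 from the
    mid-course level) and the remainder perturb it over +-2 decades in the
    rate constants.  Among converged starts within a relative SSR tolerance
    of the best, the solution with the smaller k1 is preferred, which
    resolves the instantaneous-drop mirror mode of the curve.
    """

    _LOWER = np.array([0.0, 1e-12, 1e-12])
    _UPPER = np.array([1.0, np.inf, np.inf])

    def __init__(self, time, activity=None):
        self.time, self.activity = _as_time_activity(time, activity)
        if self.time.shape != self.activity.shape:
            raise ValueError("time and activity must have matching shapes")
        if np.unique(self.time).size < 4:
            raise ValueError(
                "two-step fit needs at least 4 distinct time points "
                f"(got {np.unique(self.time).size}); the model has 3 free parameters"
            )

    @classmethod
    def from_timecourse(cls, tc: TimeCourse) -> "TwoStepDeactivation":
        model = cls(tc.time, tc.activity)
        model._source = tc
        return model

    def _residuals(self, params: np.ndarray) -> np.ndarray:
        return _alpha_curve(self.time, *params) - self.activity

    def _initial_guess(self) -> np.ndarray:
        ut = np.unique(self.time)
        means = np.array([self.activity[self.time == u].mean() for u in ut])
        means = np.clip(means, 1e-6, None)
        k1_0 = -np.log(means[1] / means[0]) / (ut[1] - ut[0])
        k2_0 = -np.log(means[-1] / means[-2]) / (ut[-1] - ut[-2])
        k1_0 = float(np.clip(k1_0, 1e-6, 1e3))
        k2_0 = float(np.clip(k2_0, 1e-8, 1e3))
        alpha1_0 = float(np.clip(means[len(means) // 2], 0.01, 1.0))
        return np.array([alpha1_0, k1_0, k2_0])

    def fit(self, multistart: int = 16, seed=None) -> "TwoStepDeactivationResults":
        """Fit by multistart bounded least squares; returns the best solution."""
        if multistart < 1:
            raise ValueError("multistart must be >= 1")
        x0 = self._initial_guess()
        starts = [x0]
        if multistart > 1:
            rng = np.random.default_rng(seed)
            n = multistart - 1
            f1 = 10.0 ** rng.uniform(-2, 2, n)
            f2 = 10.0 ** rng.uniform(-2, 2, n)
            a = rng.uniform(0.05, 0.95, n)
            for i in range(n):
                starts.append(np.array([a[i], x0[1] * f1[i], x0[2] * f2[i]]))
        solutions = []
        failures = []
        for s in starts:
            s = np.clip(s, self._LOWER + 1e-12, [1.0, 1e6, 1e6])
            try:
                sol = least_squares(
                    self._residuals, s, bounds=(self._LOWER, self._UPPER),
                    x_scale=np.maximum(np.abs(x0), 1e-8), method="trf",
                )
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(str(exc))
                continue
            if sol.success and np.all(np.isfinite(sol.x)):
                solutions.append(sol)
            else:
                failures.append(sol.message)
        if not solutions:
            raise FitError(
                "no multistart attempt converged",
                {"n_starts": len(starts), "messages": failures},
            )
        best_cost = min(sol.cost for sol in solutions)
        near = [s for s in solutions if s.cost <= best_cost * (1 + 1e-6) + 1e-300]
        best = min(near, key=lambda s: s.x[1])  # tie-break toward smaller k1
        return TwoStepDeactivationResults(self, best)


def _linearized_cov(jac: np.ndarray, ssr: float, n: int, p: int) -> np.ndarray:
    """Jacobian-based covariance of a least-squares optimum (pinv for the
    rank-deficient boundary/ridge cases)."""
    dof = max(n - p, 1)
    s2 = ssr / dof
    jtj = jac.T @ jac
    return s2 * np.linalg.pinv(jtj)


class _DeactivationResultsBase:
    """Shared diagnostics: SSR, R^2, AIC from a Gaussian likelihood."""

    @property
    def nobs(self) -> int:
        return int(self.model.activity.size)

    @property
    def ssr(self) -> float:
        return float(2.0 * self._sol.cost)

    @property
    def rsquared(self) -> float:
        y = self.model.activity
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss == 0:
            return 0.0 if self.ssr > 0 else 1.0
        return 1.0 - self.ssr / tss

    @property
    def aic(self) -> float:
        n = self.nobs
        # SSR at rounding-error level is a perfect fit; its Gaussian AIC is
        # the -inf limit rather than an arbitrary large negative number
        if self.ssr <= n * 1e-24:
            return -np.inf
        return n * np.log(self.ssr / n) + 2 * self.k_params


class TwoStepDeactivationResults(_DeactivationResultsBase):
    """Results of a :class:`TwoStepDeactivation` fit.

    Attributes
    ----------
    params : pandas.Series
        ``alpha1``, ``k1``, ``k2`` point estimates.
    bse : pandas.Series
        Linearized (Jacobian-based) standard errors.
    """

    k_params = 3
    _names = ["alpha1", "k1", "k2"]

    def __init__(self, model: TwoStepDeactivation, sol):
        self.model = model
        self._sol = sol
        self.params = pd.Series(sol.x, index=self._names)
        cov = _linearized_cov(sol.jac, self.ssr, self.nobs, self.k_params)
        self.cov_params = pd.DataFrame(cov, index=self._names, columns=self._names)
        self.bse = pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)),
                             index=self._names)

    @property
    def alpha1(self) -> float:
        return float(self.params["alpha1"])

    @property
    def k1(self) -> float:
        return float(self.params["k1"])

    @property
    def k2(self) -> float:
        return float(self.params["k2"])

    def predict(self, t) -> np.ndarray:
        return residual_activity(np.asarray(t, dtype=float), *self.params.to_numpy())

    def half_life(self) -> float:
        return half_life(self.to_deact_params())

    def to_deact_params(self) -> DeactParams:
        return DeactParams(
            alpha1=min(max(self.alpha1, 0.0), 1.0), k1=self.k1, k2=self.k2,
            se_alpha1=float(self.bse["alpha1"]), se_k1=float(self.bse["k1"]),
            se_k2=float(self.bse["k2"]), ssr=self.ssr, r2=self.rsquared,
            n_obs=self.nobs,
        )

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("Two-step deactivation fit (E0 -k1-> E1 -k2-> E2, alpha2 = 0)\n")
        buf.write(f"n_obs = {self.nobs}, SSR = {self.ssr:.6g}, "
                  f"R^2 = {self.rsquared:.4f}, AIC = {self.aic:.2f}\n")
        buf.write(f"{'param':<8}{'estimate':>12}{'std err':>12}\n")
        for name in self._names:
            buf.write(f"{name:<8}{self.params[name]:>12.4g}{self.bse[name]:>12.2g}\n")
        buf.write(f"half-life = {self.half_life():.4g} min\n")
        return buf.getvalue()


class FirstOrderDeactivation:
    """Single-exponential comparison model ``alpha(t) = exp(-k t)``."""

    _K_FLOOR = 1e-12

    def __init__(self, time, activity=None):
        self.time, self.activity = _as_time_activity(time, activity)
        if np.unique(self.time).size < 2:
            raise ValueError("first-order fit needs at least 2 distinct time points")

    @classmethod
    def from_timecourse(cls, tc: TimeCourse) -> "FirstOrderDeactivation":
        return cls(tc.time, tc.activity)

    def fit(self) -> "FirstOrderResults":
        t, y = self.time, self.activity
        pos = (y > 0) & (t > 0)
        if pos.any():
            k0 = float(np.clip(np.median(-np.log(y[pos]) / t[pos]), 1e-6, 1e3))
        else:
            k0 = 0.1
        sol = least_squares(lambda p: np.exp(-p[0] * t) - y, [k0],
                            bounds=([self._K_FLOOR], [np.inf]), method="trf")
        if not sol.success:
            raise FitError("first-order fit failed", {"message": sol.message})
        return FirstOrderResults(self, sol)


class FirstOrderResults(_DeactivationResultsBase):
    k_params = 1

    def __init__(self, model: FirstOrderDeactivation, sol):
        self.model = model
        self._sol = sol
        self.k = float(sol.x[0])
        cov = _linearized_cov(sol.jac, self.ssr, self.nobs, 1)
        self.se_k = float(np.sqrt(max(cov[0, 0], 0.0)))
        # negligible fitted decay over the whole observed span means the data
        # carry no decay signal and k is effectively at its lower bound
        t_span = float(np.max(model.time) - np.min(model.time))
        self.non_identifiable = bool(self.k * max(t_span, 1e-300) < 1e-3)

    def predict(self, t) -> np.ndarray:
        return np.exp(-self.k * np.asarray(t, dtype=float))

    def summary(self) -> str:
        flag = "  [non-identifiable: k at lower bound]" if self.non_identifiable else ""
        return (f"First-order deactivation fit: k = {self.k:.4g} 1/min "
                f"(se {self.se_k:.2g}), SSR = {self.ssr:.6g}, "
                f"R^2 = {self.rsquared:.4f}{flag}\n")


@dataclass
class FitComparison:
    """AIC comparison of the two-step model against first-order decay."""

    two_step: TwoStepDeactivationResults
    first_order: FirstOrderResults
    delta_aic: float  # AIC(first_order) - AIC(two_step)
    preferred: str    # "two_step" or "first_order"


def fit_two_step(tc, multistart: int = 16, seed=None) -> DeactParams:
    """Convenience wrapper: fit the two-step model to a TimeCourse (or
    (time, activity) pair) and return the DeactParams record."""
    model = (TwoStepDeactivation.from_timecourse(tc)
             if isinstance(tc, TimeCourse) else TwoStepDeactivation(*tc))
    return model.fit(multistart=multistart, seed=seed).to_deact_params()


def fit_first_order(tc) -> FirstOrderResults:
    model = (FirstOrderDeactivation.from_timecourse(tc)
             if isinstance(tc, TimeCourse) else FirstOrderDeactivation(*tc))
    return model.fit()


def compare_models(tc, multistart: int = 16, seed=None,
                   delta_aic_threshold: float = 10.0) -> FitComparison:
    """Fit both deactivation models and prefer the two-step one only when it
    improves the AIC by more than ``delta_aic_threshold``.

    AIC uses the Gaussian-likelihood form ``n ln(SSR/n) + 2p``; a perfect
    two-step fit (SSR = 0) yields AIC = -inf and an infinite delta.
    """
    if isinstance(tc, TimeCourse):
        time, activity = tc.time, tc.activity
    else:
        time, activity = tc
    two = TwoStepDeactivation(time, activity).fit(multistart=multistart, seed=seed)
    one = FirstOrderDeactivation(time, activity).fit()
    delta = one.aic - two.aic
    preferred = "two_step" if delta > delta_aic_threshold else "first_order"
    return FitComparison(two_step=two, first_order=one,
                         delta_aic=float(delta), preferred=preferred)


def half_life(params: DeactParams | Sequence[float]) -> float:
    """Time at which the two-step curve crosses alpha = 1/2.

    The curve is strictly decreasing to 0 for alpha1 in [0, 1], so the
    crossing exists and is unique; it is found by expanding a bracket
    geometrically and polishing with Brent's method.
    """
    if isinstance(params, DeactParams):
        a1, k1, k2 = params.alpha1, params.k1, params.k2
    else:
        a1, k1, k2 = params
    f = lambda t: residual_activity(t, a1, k1, k2) - 0.5
    hi = 1.0 / max(k1, k2)
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - alpha -> 0 guarantees a crossing
            raise FitError("failed to bracket the half-life")
    return float(brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-12))
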