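"""Arrhenius activation-energy estimation for deactivation rate constants.

For a first-order rate constant measured at several temperatures, the
Arrhenius law ``k(T) = A exp(-Ea / (R T))`` is linear in reciprocal absolute
temperature: ``ln k = ln A - (Ea/R) (1/T)``.  The activation energy is
estimated from the ordinary least-squares slope of ln k on 1/T
(``Ea = -slope * R``), with an optional 1/SE^2-weighted variant for rate
constants carrying very unequal regression errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["R_GAS", "ArrheniusFit", "ArrheniusRegression", "fit_arrhenius",
           "predict_k"]

#: gas constant, J mol^-1 K^-1
R_GAS = 8.314

_KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class ArrheniusFit:
    """Results of an Arrhenius regression.

    ``ea`` is in kJ/mol; ``ln_a`` is the intercept (ln of a rate in 1/min);
    ``degenerate`` flags a zero-variance regression (all k equal), for which
    r2 is reported as 0.
    """

    ea: float
    ln_a: float
    r2: float
    n_temps: int
    se_ea: float = np.nan
    degenerate: bool = False

    def predict_k(self, temp_c: float) -> float:
        """Rate constant (1/min) at a temperature in Celsius."""
        t_k = np.asarray(temp_c, dtype=float) + _KELVIN_OFFSET
        out = np.exp(self.ln_a - self.ea * 1000.0 / (R_GAS * t_k))
        return float(out) if out.ndim == 0 else out

    def summary(self) -> str:
        note = "  [degenerate: zero slope variance]" if self.degenerate else ""
        return (f"Arrhenius fit over {self.n_temps} temperatures: "
                f"Ea = {self.ea:.2f} kJ/mol (se {self.se_ea:.2g}), "
                f"ln A = {self.ln_a:.3f}, R^2 = {self.r2:.4f}{note}\n")


class ArrheniusRegression:
    """OLS (optionally weighted) regression of ln k on 1/T.

    Parameters
    ----------
    temps_c : array-like
        Temperatures in Celsius; at least 2 distinct values.
    ks : array-like
        Rate constants in 1/min, strictly positive.
    k_ses : array-like, optional
        Standard errors of the ks; when given and ``weighted=True`` at fit
        time, the regression uses 1/SE(ln k)^2 weights.
    """

    def __init__(self, temps_c, ks, k_ses=None):
        self.temps_c = np.asarray(temps_c, dtype=float)
        self.ks = np.asarray(ks, dtype=float)
        if self.temps_c.shape != self.ks.shape:
            raise ValueError("temps_c and ks must have matching shapes")
        if np.any(self.ks <= 0):
            raise ValueError("rate constants must be strictly positive")
        if np.any(self.temps_c + _KELVIN_OFFSET <= 0):
            raise ValueError("temperatures must be above absolute zero")
        if np.unique(self.temps_c).size < 2:
            raise ValueError("need at least 2 distinct temperatures")
        self.k_ses = None if k_ses is None else np.asarray(k_ses, dtype=float)

    def fit(self, weighted: bool = False) -> ArrheniusFit:
        x = 1.0 / (self.temps_c + _KELVIN_OFFSET)
        y = np.log(self.ks)
        n = int(np.unique(self.temps_c).size)
        if np.ptp(y) == 0.0:
            # all rate constants identical: slope 0, r2 undefined -> 0
            return ArrheniusFit(ea=0.0, ln_a=float(y[0]), r2=0.0,
                                n_temps=n, se_ea=0.0, degenerate=True)
        if weighted:
            if self.k_ses is None:
                raise ValueError("weighted fit requires k standard errors")
            # delta method: SE(ln k) = SE(k)/k
            w = (self.ks / self.k_ses) ** 2
            wls = np.polyfit(x, y, 1, w=np.sqrt(w))
            slope, intercept = float(wls[0]), float(wls[1])
            resid = y - (intercept + slope * x)
            ybar = np.average(y, weights=w)
            r2 = 1.0 - (np.sum(w * resid ** 2)
                        / np.sum(w * (y - ybar) ** 2))
            se_slope = np.nan  # not reported for the weighted variant
        else:
            reg = stats.linregress(x, y)
            slope, intercept = float(reg.slope), float(reg.intercept)
            r2 = float(reg.rvalue) ** 2
            se_slope = float(reg.stderr)
        return ArrheniusFit(
            ea=-slope * R_GAS / 1000.0,
            ln_a=intercept,
            r2=float(r2),
            n_temps=n,
            se_ea=se_slope * R_GAS / 1000.0 if np.isfinite(se_slope) else np.nan,
        )


def fit_arrhenius(temps_c, ks, k_ses=None, weighted: bool = False) -> ArrheniusFit:
    """Convenience wrapper around :class:`ArrheniusRegression`."""
    return ArrheniusRegression(temps_c, ks, k_ses=k_ses).fit(weighted=weighted)


def predict_k(fit: ArrheniusFit, temp_c: float) -> float:
    """Rate constant predicted by an Arrhenius fit at a Celsius temperature."""
    return fit.predict_k(temp_c)
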