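"""pH and temperature activity profiles.

An activity profile is a set of (x, activity) measurements of one enzyme over
a pH or temperature grid.  Optima are reported on the measurement grid only —
no interpolation between assayed points — matching how bench
characterizations state "optimal activity at 70-80 degC and pH 8-9".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ActivityProfile", "OptimumResult", "normalize_profile",
           "find_optimum", "fraction_retained"]


@dataclass(frozen=True)
class ActivityProfile:
    """Activity of one enzyme along a pH or temperature axis.

    ``activity`` is either absolute (nkat/mL) or relative (% of maximum,
    after :func:`normalize_profile`); ``sd`` holds optional triplicate SDs.
    """

    enzyme_id: str
    axis: str  # "pH" or "temperature_C"
    x: np.ndarray
    activity: np.ndarray
    sd: np.ndarray | None = None
    relative: bool = False

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "activity", y)
        if self.sd is not None:
            object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if x.size == 0:
            raise ValueError("profile must have at least one point")
        if x.shape != y.shape:
            raise ValueError("x and activity must have matching shapes")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("activities must be >= 0")


@dataclass(frozen=True)
class OptimumResult:
    x: float
    activity: float
    tie: bool = False        # several grid points share the maximum
    boundary: bool = False   # maximum sits on the edge of the assayed range

    def __float__(self):
        return float(self.x)


def normalize_profile(p: ActivityProfile) -> ActivityProfile:
    """Rescale to percent of the maximum activity (max becomes 100).

    Idempotent; an all-zero profile has no defined optimum and is rejected.
    """
    peak = float(p.activity.max())
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    scale = 100.0 / peak
    sd = None if p.sd is None else p.sd * scale
    return replace(p, activity=p.activity * scale, sd=sd, relative=True)


def find_optimum(p: ActivityProfile) -> OptimumResult:
    """Grid point of maximal measured activity.

    Ties are broken toward the lower x and flagged; an optimum at either end
    of the grid is flagged as a boundary optimum (the true peak may lie
    outside the assayed range).
    """
    peak = float(p.activity.max())
    hits = np.flatnonzero(p.activity == peak)
    idx = int(hits[0])
    return OptimumResult(
        x=float(p.x[idx]),
        activity=peak,
        tie=hits.size > 1,
        boundary=idx in (0, p.x.size - 1),
    )


def fraction_retained(p: ActivityProfile, x: float) -> float:
    """Normalized activity (% of maximum) at an assayed grid point.

    The point must be on the measurement grid; no interpolation is done.
    """
    norm = p if p.relative else normalize_profile(p)
    match = np.flatnonzero(np.isclose(norm.x, float(x), rtol=0.0, atol=1e-9))
    if match.size == 0:
        raise ValueError(f"x = {x} is not an assayed grid point of {p.enzyme_id}")
    return float(norm.activity[int(match[0])])
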