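"""Synthetic screening tables and deactivation time courses.

The generators emulate the statistical structure the analysis assumes:
triplicate residual-activity time courses following the two-step deactivation
curve with additive Gaussian measurement noise, Arrhenius-consistent rate
constant series, and screening tables with the three liquid-activity classes
(none / low / significant) plus independently drawn halo scores so that
plate/liquid discordance occurs.  All randomness flows through explicit
seeds; the same seed reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .arrhenius import R_GAS, _KELVIN_OFFSET
from .kinetics import TimeCourse, _alpha_curve
from .screening import Halo, NOT_DETECTED, ScreeningRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_time_grid",
    "design_time_grid",
    "simulate_timecourse",
    "simulate_arrhenius_series",
    "simulate_screen",
]


def default_time_grid() -> np.ndarray:
    """0-60 min at 5-min steps: the 1-h observation window of a routine
    thermostability check."""
    return np.arange(0.0, 61.0, 5.0)


def design_time_grid(k1: float, k2: float, n_points: int = 13,
                     t_max: float | None = None) -> np.ndarray:
    """Sampling times spanning both decay phases of a two-step curve.

    Emulates how a stability experiment is scheduled when the fast and slow
    phases live on different time scales: roughly half the points are linear
    over the fast phase (out to ~3/k1, where the native-state exponential has
    decayed to ~5%), the rest geometric out to ~2/k2 so the intermediate's
    decay is observed too.  Without slow-phase coverage the triple
    (alpha1, k1, k2) sits on a likelihood ridge and is not identifiable.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rate constants must be positive")
    if n_points < 4:
        raise ValueError("need at least 4 time points for a 3-parameter model")
    t_fast = 3.0 / k1
    t_slow = 2.0 / min(k1, k2)
    if t_max is not None:
        t_slow = min(t_slow, float(t_max))
    n_fast = max(n_points // 2, 2)
    fast = np.linspace(0.0, t_fast, n_fast + 1)
    if t_slow <= t_fast * (1 + 1e-9):
        grid = np.linspace(0.0, max(t_fast, t_slow), n_points)
    else:
        slow = np.geomspace(t_fast, t_slow, n_points - n_fast)
        grid = np.concatenate([fast, slow[1:]])
    return np.unique(np.round(grid, 6))


@dataclass(frozen=True)
class SimulationConfig:
    """Controls for time-course simulation.

    noise_sd is the SD of additive Gaussian noise on the activity fraction
    (0.02 by default, a typical triplicate scatter for the pNPP assay);
    truncation at zero is off by default so that fits to simulated data stay
    unbiased.
    """

    seed: int
    n_replicates: int = 3
    time_grid: np.ndarray = field(default_factory=default_time_grid)
    noise_sd: float = 0.02
    truncate_at_zero: bool = False

    def __post_init__(self):
        grid = np.asarray(self.time_grid, dtype=float)
        object.__setattr__(self, "time_grid", grid)
        if grid.size < 1 or grid[0] != 0.0:
            raise ValueError("time_grid must start at 0")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("time_grid must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """True (alpha1, k1, k2) used to generate a time course."""

    alpha1: float
    k1: float
    k2: float
    label: str = ""

    def __post_init__(self):
        if not 0.0 <= self.alpha1 <= 1.0:
            raise ValueError("alpha1 must lie in [0, 1]")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")


def simulate_timecourse(truth: GroundTruth, config: SimulationConfig,
                        enzyme_id: str | None = None,
                        temperature_c: float = np.nan) -> TimeCourse:
    """Simulate replicate residual-activity observations.

    Each observation is the closed-form two-step curve at the grid time plus
    independent Gaussian(0, noise_sd) noise, optionally truncated at zero.
    The returned TimeCourse records the ground truth and seed in its
    metadata.
    """
    rng = np.random.default_rng(config.seed)
    t = config.time_grid
    clean = _alpha_curve(t, truth.alpha1, truth.k1, truth.k2)
    rows = []
    for rep in range(config.n_replicates):
        noisy = clean + rng.normal(0.0, config.noise_sd, t.size)
        if config.truncate_at_zero:
            noisy = np.clip(noisy, 0.0, None)
        rows.append(pd.DataFrame({
            "time_min": t, "replicate": rep, "residual_activity": noisy,
        }))
    obs = pd.concat(rows, ignore_index=True)
    return TimeCourse(
        enzyme_id=enzyme_id or (truth.label or "sim"),
        temperature_c=float(temperature_c),
        observations=obs,
        meta={
            "truth": {"alpha1": truth.alpha1, "k1": truth.k1, "k2": truth.k2},
            "seed": config.seed,
            "noise_sd": config.noise_sd,
            "truncated_at_zero": config.truncate_at_zero,
        },
    )


def simulate_arrhenius_series(ea_kj_mol: float, k_ref: float, t_ref_k: float,
                              temps_k: Sequence[float]) -> np.ndarray:
    """Rate constants on an exact Arrhenius line.

    k(T) = k_ref * exp(-Ea/R * (1/T - 1/T_ref)), temperatures in Kelvin.
    """
    temps = np.asarray(temps_k, dtype=float)
    if np.any(temps <= 0) or t_ref_k <= 0:
        raise ValueError("temperatures must be positive (Kelvin)")
    if k_ref <= 0:
        raise ValueError("k_ref must be positive")
    ea_j = ea_kj_mol * 1000.0
    return k_ref * np.exp(-ea_j / R_GAS * (1.0 / temps - 1.0 / t_ref_k))


# --- screening-table simulation -------------------------------------------

# activity draws per class, nkat/mL: low strains sit in (0, 0.05] so the
# 48/72-h mean stays at or below the significance threshold; significant
# strains are log-uniform over a Table-1-like range
_LOW_MAX = 0.05
_SIG_RANGE = (0.055, 2.5)


def simulate_screen(n_strains: int,
                    class_proportions: Sequence[float] = (0.26, 0.19, 0.55),
                    seed: int | None = None,
                    halo_rate: float = 0.17,
                    prefix: str = "SIM") -> list[ScreeningRecord]:
    """Generate a screening table with requested liquid-class proportions.

    ``class_proportions`` is (none, low, significant) and must sum to 1;
    class labels are drawn from the corresponding multinomial, then
    activities are drawn so the generated class matches the label.  Halo
    scores are drawn independently at ``halo_rate`` (split 4:1 between "+"
    and "++"), so the plate and liquid phenotypes can disagree, as observed
    in real dual-mode screens.
    """
    props = np.asarray(class_proportions, dtype=float)
    if props.size != 3 or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("class_proportions must be a 3-simplex (none, low, significant)")
    if n_strains < 0:
        raise ValueError("n_strains must be >= 0")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_strains):
        label = rng.choice(3, p=props)
        if label == 0:
            a48 = a72 = NOT_DETECTED
        elif label == 1:
            # both draws below the threshold keep the 48/72-h mean below it
            a48, a72 = (float(v) for v in rng.uniform(0.0, _LOW_MAX, 2))
        else:
            lo, hi = np.log(_SIG_RANGE[0]), np.log(_SIG_RANGE[1])
            a48 = float(np.exp(rng.uniform(lo, hi)))
            a72 = float(np.exp(rng.uniform(lo, hi)))
            if (a48 + a72) / 2 <= _LOW_MAX:  # pragma: no cover - range excludes it
                a48 = _LOW_MAX * 2.2
        if rng.random() < halo_rate:
            halo48 = Halo.FULL if rng.random() < 0.2 else Halo.PARTIAL
            halo24 = halo48 if rng.random() < 0.5 else Halo.NONE
            if halo24 is Halo.NONE and rng.random() < 0.1:
                halo24, halo48 = halo48, Halo.NONE
        else:
            halo24 = halo48 = Halo.NONE
        records.append(ScreeningRecord(
            strain_id=f"{prefix}{i + 1}",
            halo_24h=halo24, halo_48h=halo48,
            act_48h=a48, act_72h=a72,
        ))
    return records
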