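"""Dual-mode lipolytic screening analysis.

A strain collection is screened for extracellular lipase production two ways:
qualitatively on Rhodamine-B/olive-oil agar (an orange fluorescent halo under
UV marks free fatty-acid release; scored -, + or ++ at 24 h and 48 h) and
quantitatively in olive-oil liquid cultures, where supernatant activity is
measured at 48 h and 72 h by the chromogenic pNPP assay and expressed in
nkat/mL.  This module converts assay absorbances to activities, classifies
strains from either read-out, summarizes a screen and applies the
high-producer selection rule.

A printed activity of 0.000 is a measured zero and enters the mean; a "-"
entry (NOT_DETECTED) means the activity was not detected at all.  A strain is
class "none" only when both liquid time points are non-detections.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NOT_DETECTED",
    "Halo",
    "LiquidClass",
    "ScreeningRecord",
    "ScreenSummary",
    "AssayConfig",
    "activity_from_absorbance",
    "classify_liquid",
    "classify_halo",
    "summarize_screen",
    "select_strains",
    "SelectionResult",
    "read_screening_csv",
    "write_screening_csv",
]

#: sentinel for a "-" liquid-culture entry (no detectable activity, as
#: opposed to a measured 0.000 nkat/mL)
NOT_DETECTED = None


class Halo(enum.Enum):
    """Ordinal fluorescence-halo score on Rhodamine-olive-oil agar."""

    NONE = "-"
    PARTIAL = "+"     # partial coverage of the well
    FULL = "++"       # full coverage of the well

    @classmethod
    def parse(cls, token: str) -> "Halo":
        token = str(token).strip()
        for member in cls:
            if member.value == token:
                return member
        # tolerate unicode minus from table transcriptions
        if token in {"−", ""}:
            return cls.NONE
        raise ValueError(f"unrecognized halo score {token!r}")


class LiquidClass(enum.Enum):
    NONE = "none"
    LOW = "low"
    SIGNIFICANT = "significant"


@dataclass(frozen=True)
class ScreeningRecord:
    """One strain's halo scores and liquid-culture activities."""

    strain_id: str
    halo_24h: Halo = Halo.NONE
    halo_48h: Halo = Halo.NONE
    act_48h: float | None = NOT_DETECTED
    act_72h: float | None = NOT_DETECTED

    def __post_init__(self):
        for value in (self.act_48h, self.act_72h):
            if value is not NOT_DETECTED:
                if not np.isfinite(value) or value < 0:
                    raise ValueError(
                        f"{self.strain_id}: activities must be finite and >= 0"
                    )

    @property
    def mean_activity(self) -> float | None:
        """Mean of the available numeric time points; None if both are
        non-detections (a measured 0.000 does contribute)."""
        vals = [v for v in (self.act_48h, self.act_72h) if v is not NOT_DETECTED]
        if not vals:
            return None
        return float(np.mean(vals))


@dataclass(frozen=True)
class AssayConfig:
    """pNPP assay geometry and calibration.

    Defaults follow the standard protocol: 950 uL substrate solution plus
    50 uL sample (1 mL reaction), 15 min incubation at the assay temperature,
    pNP quantified at 410 nm against a per-pH calibration curve whose slope is
    in absorbance units per nmol of pNP in the reaction.
    """

    reaction_volume_ml: float = 1.0
    sample_volume_ml: float = 0.05
    incubation_time_s: float = 900.0
    calib_slope: float = 0.01  # AU per nmol pNP

    def __post_init__(self):
        for name in ("reaction_volume_ml", "sample_volume_ml",
                     "incubation_time_s", "calib_slope"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def activity_from_absorbance(a410: float, blank: float,
                             config: AssayConfig = AssayConfig()) -> float:
    """Convert a blank-corrected A410 reading to lipase activity in nkat/mL.

    nkat is nmol of pNP released per second; the released amount
    ``(a410 - blank) / calib_slope`` is divided by the incubation time and by
    the sample volume.  Readings below the blank are clamped to zero (the
    physically meaningful floor for a hydrolysis assay).
    """
    delta = max(float(a410) - float(blank), 0.0)
    pnp_nmol = delta / config.calib_slope
    return pnp_nmol / config.incubation_time_s / config.sample_volume_ml


def classify_liquid(record: ScreeningRecord,
                    significant_threshold: float = 0.05) -> LiquidClass:
    """Classify a strain from its liquid-culture activities.

    ``none`` if both time points are non-detections; otherwise ``significant``
    when the mean of the available values exceeds the threshold (strictly),
    else ``low``.
    """
    mean = record.mean_activity
    if mean is None:
        return LiquidClass.NONE
    return (LiquidClass.SIGNIFICANT if mean > significant_threshold
            else LiquidClass.LOW)


def classify_halo(record: ScreeningRecord) -> bool:
    """True when the strain produced any fluorescent halo (+ or ++) at
    either 24 h or 48 h."""
    return (record.halo_24h is not Halo.NONE) or (record.halo_48h is not Halo.NONE)


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal."""
    raw = Decimal(count) * 100 / Decimal(total)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScreenSummary:
    """Counts and percentages of a dual-mode screen."""

    n_total: int
    n_halo: int
    n_significant: int
    n_low: int
    n_none: int

    @property
    def pct_halo(self) -> float:
        return _pct(self.n_halo, self.n_total)

    @property
    def pct_significant(self) -> float:
        return _pct(self.n_significant, self.n_total)

    @property
    def pct_low(self) -> float:
        return _pct(self.n_low, self.n_total)

    @property
    def pct_none(self) -> float:
        return _pct(self.n_none, self.n_total)

    @property
    def n_detectable(self) -> int:
        """Strains with any detectable liquid activity (significant + low)."""
        return self.n_significant + self.n_low

    @property
    def pct_detectable(self) -> float:
        return _pct(self.n_detectable, self.n_total)

    def __str__(self) -> str:
        return (
            f"screened {self.n_total} strains: "
            f"{self.n_halo} halo producers ({self.pct_halo}%), "
            f"{self.n_significant} significant ({self.pct_significant}%), "
            f"{self.n_low} low ({self.pct_low}%), "
            f"{self.n_none} none ({self.pct_none}%)"
        )


def summarize_screen(records: Sequence[ScreeningRecord]) -> ScreenSummary:
    """Tally liquid classes and halo producers over a screen."""
    if not records:
        raise ValueError("cannot summarize an empty screen")
    ids = [r.strain_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate strain ids: {dupes}")
    classes = [classify_liquid(r) for r in records]
    return ScreenSummary(
        n_total=len(records),
        n_halo=sum(classify_halo(r) for r in records),
        n_significant=sum(c is LiquidClass.SIGNIFICANT for c in classes),
        n_low=sum(c is LiquidClass.LOW for c in classes),
        n_none=sum(c is LiquidClass.NONE for c in classes),
    )


def _strain_sort_key(strain_id: str):
    """Natural ordering: alphabetic prefix, then numeric suffix (SP2 < SP14)."""
    prefix = strain_id.rstrip("0123456789")
    digits = strain_id[len(prefix):]
    return (prefix, int(digits) if digits else -1, strain_id)


@dataclass(frozen=True)
class SelectionResult:
    """Strains passing the high-producer rule, with per-criterion detail."""

    selected: tuple[str, ...]
    by_activity: tuple[str, ...]
    by_halo: tuple[str, ...]

    def __iter__(self):
        return iter(self.selected)

    def __len__(self):
        return len(self.selected)

    def __contains__(self, strain_id):
        return strain_id in self.selected


def select_strains(records: Iterable[ScreeningRecord],
                   activity_threshold: float = 0.75,
                   require_full_halo: bool = True) -> SelectionResult:
    """Apply the high-producer selection rule.

    A strain is selected when its mean liquid activity strictly exceeds
    ``activity_threshold`` (default 0.75 nkat/mL) or when it produced an
    intense halo — "++" at either time point when ``require_full_halo`` is
    set, any halo otherwise.  Returns the union, naturally sorted by strain
    id, with the two criterion subsets exposed for inspection.
    """
    by_activity, by_halo = [], []
    for r in records:
        mean = r.mean_activity
        if mean is not None and mean > activity_threshold:
            by_activity.append(r.strain_id)
        halos = (r.halo_24h, r.halo_48h)
        if require_full_halo:
            hit = Halo.FULL in halos
        else:
            hit = any(h is not Halo.NONE for h in halos)
        if hit:
            by_halo.append(r.strain_id)
    selected = sorted(set(by_activity) | set(by_halo), key=_strain_sort_key)
    return SelectionResult(
        selected=tuple(selected),
        by_activity=tuple(sorted(by_activity, key=_strain_sort_key)),
        by_halo=tuple(sorted(by_halo, key=_strain_sort_key)),
    )


# ---------------------------------------------------------------------------
# CSV dialect: strain, roa_24h, roa_48h, olm_48h, olm_72h with "ND" sentinel

def _parse_activity(token) -> float | None:
    if pd.isna(token):
        return NOT_DETECTED
    token = str(token).strip()
    if token in {"ND", "-", "−", ""}:
        return NOT_DETECTED
    return float(token)


def read_screening_csv(path_or_buf) -> list[ScreeningRecord]:
    """Read a screening table (columns strain, roa_24h, roa_48h, olm_48h,
    olm_72h; "ND" marks a liquid non-detection)."""
    df = pd.read_csv(path_or_buf, dtype=str)
    required = {"strain", "roa_24h", "roa_48h", "olm_48h", "olm_72h"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"screening CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(ScreeningRecord(
            strain_id=str(row.strain).strip(),
            halo_24h=Halo.parse(row.roa_24h),
            halo_48h=Halo.parse(row.roa_48h),
            act_48h=_parse_activity(row.olm_48h),
            act_72h=_parse_activity(row.olm_72h),
        ))
    return records


def write_screening_csv(records: Sequence[ScreeningRecord], path_or_buf) -> None:
    fmt = lambda v: "ND" if v is NOT_DETECTED else f"{v:.3f}"
    df = pd.DataFrame({
        "strain": [r.strain_id for r in records],
        "roa_24h": [r.halo_24h.value for r in records],
        "roa_48h": [r.halo_48h.value for r in records],
        "olm_48h": [fmt(r.act_48h) for r in records],
        "olm_72h": [fmt(r.act_72h) for r in records],
    })
    df.to_csv(path_or_buf, index=False)
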