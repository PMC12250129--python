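"""Radiochemical purity and serum-stability analysis from count profiles.

A labelled radiometal conjugate is checked by instant thin-layer
chromatography (iTLC) or radio-HPLC: the activity profile along the strip
(or retention time axis) is partitioned into windows and the product peak's
share of total counts is the radiochemical purity.  With an EDTA mobile
phase the product stays at the origin while free radiometal (as its EDTA
complex) travels with the solvent front, so purity is simply the
origin-window fraction.

Windows are explicit half-open intervals ``[lo, hi)``; they are supplied by
the operator (or run configuration), never auto-detected, so that a set of
windows tiling the axis always sums to exactly 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, InputError

__all__ = [
    "CountProfile",
    "StabilityRecord",
    "window_fraction",
    "radiochemical_purity",
    "stability_summary",
    "read_profile",
]

#: Minimum purity (%) for a labelling run to be released for use.
ACCEPTANCE_PURITY_PCT = 90.0


@dataclass
class CountProfile:
    """An activity trace along a chromatographic axis.

    ``positions`` are strip positions (mm) for iTLC or retention times
    (min) for radio-HPLC, strictly increasing; ``counts`` are the
    non-negative detector counts in each bin.
    """

    positions: np.ndarray
    counts: np.ndarray
    kind: str = "iTLC"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.counts.shape:
            raise InputError("positions and counts must be 1-D and the same length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise InputError("positions must be strictly increasing")
        if np.any(self.counts < 0):
            raise InputError("counts must be >= 0")
        if self.kind not in ("iTLC", "radio-HPLC"):
            raise InputError(f"unknown profile kind {self.kind!r}")


@dataclass(frozen=True)
class StabilityRecord:
    """Free-radiometal percentage at one (temperature, time) condition."""

    temperature_c: float
    time_h: float
    free_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.free_pct <= 100.0:
            raise InputError(f"free fraction must be in [0, 100], got {self.free_pct}")


def window_fraction(profile: CountProfile, window: tuple[float, float]) -> float:
    """Percent of total counts inside the half-open window ``[lo, hi)``."""
    lo, hi = window
    if not lo < hi:
        raise InputError(f"empty window [{lo}, {hi})")
    total = float(profile.counts.sum())
    if total <= 0:
        raise AnalysisError("profile has zero total counts")
    inside = (profile.positions >= lo) & (profile.positions < hi)
    return 100.0 * float(profile.counts[inside].sum()) / total


def radiochemical_purity(
    profile: CountProfile, product_window: tuple[float, float]
) -> float:
    """Radiochemical purity (%): product-window share of total counts."""
    return window_fraction(profile, product_window)


def stability_summary(records: list[StabilityRecord]) -> pd.DataFrame:
    """Pivot stability records to a temperature x time table of free %.

    Missing cells stay NaN (absent), never imputed.  Duplicate
    (temperature, time) keys are an input error.
    """
    if not records:
        return pd.DataFrame()
    keys = [(r.temperature_c, r.time_h) for r in records]
    if len(set(keys)) != len(keys):
        raise InputError("duplicate (temperature, time) keys in stability records")
    df = pd.DataFrame(
        {
            "temperature_c": [r.temperature_c for r in records],
            "time_h": [r.time_h for r in records],
            "free_pct": [r.free_pct for r in records],
        }
    )
    return df.pivot(index="temperature_c", columns="time_h", values="free_pct")


def read_profile(path: str, kind: str = "iTLC") -> CountProfile:
    """Read a ``position,counts`` CSV into a :class:`CountProfile`."""
    df = pd.read_csv(path, comment="#")
    if not {"position", "counts"} <= set(df.columns):
        raise InputError(f"profile CSV {path} must have columns position,counts")
    return CountProfile(df["position"].to_numpy(), df["counts"].to_numpy(), kind=kind)
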