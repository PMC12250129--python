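"""Gamma-counter worksheets to %IA/g tables and tumor-to-normal ratios.

A biodistribution worksheet records, for one animal, the dissected organ
samples (mass, counts, counting time) together with at least one counting
standard — an aliquot containing a known fraction ``f_std`` of the injected
activity counted in the same sessions.  Dividing decay-referenced sample
counts by the decay-referenced full-activity standard gives the percent of
injected activity (%IA) in the sample, and dividing by sample mass gives
%IA/g (identically %ID/g, percent injected dose per gram).

Convention: %IA/g values in this module are decay-referenced to injection
time, i.e. they describe the biological distribution only.  Physical decay
is re-applied downstream by the dosimetry stage when disintegration
integrals are needed.  When sample and standard share a counting time the
two decay factors cancel exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median

import numpy as np
import pandas as pd

from .errors import AnalysisError, DataError, InputError
from .nuclide import Nuclide, decay_factor

__all__ = [
    "OrganRecord",
    "StandardRecord",
    "CountWorksheet",
    "percent_ia_per_gram",
    "summarize",
    "tn_ratios",
    "read_worksheet",
    "write_worksheet",
]

#: Maximum sample-to-standard counting-time gap (h) before pairing is refused.
MAX_STANDARD_GAP_H = 24.0
#: Tolerated clock slack (h) for counts timestamped before injection.
NEGATIVE_ELAPSED_TOL_H = 1e-6


@dataclass(frozen=True)
class OrganRecord:
    organ: str
    mass_g: float
    cpm: float
    count_time_h: float

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise InputError(f"mass must be positive for {self.organ!r}")
        if self.cpm < 0:
            raise InputError(f"counts must be >= 0 for {self.organ!r}")


@dataclass(frozen=True)
class StandardRecord:
    """Counts of a known fraction ``f_std`` of the injected activity."""

    f_std: float
    cpm: float
    count_time_h: float

    def __post_init__(self) -> None:
        if not 0 < self.f_std <= 1:
            raise InputError(f"f_std must be in (0, 1], got {self.f_std}")
        if self.cpm < 0:
            raise InputError("standard counts must be >= 0")


@dataclass
class CountWorksheet:
    """One animal's gamma-counting worksheet."""

    animal_id: str
    injection_time_h: float
    injected_activity_mbq: float
    records: list[OrganRecord] = field(default_factory=list)
    standards: list[StandardRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.injected_activity_mbq < 0:
            raise InputError("injected activity must be >= 0")

    @property
    def nominal_time_h(self) -> float:
        """Nominal sacrifice timepoint: median organ counting time minus
        injection time."""
        if not self.records:
            raise InputError("worksheet has no organ records")
        return median(r.count_time_h for r in self.records) - self.injection_time_h


def _nearest_standard(
    standards: list[StandardRecord], count_time_h: float
) -> StandardRecord:
    best = min(standards, key=lambda s: abs(s.count_time_h - count_time_h))
    if abs(best.count_time_h - count_time_h) > MAX_STANDARD_GAP_H:
        raise AnalysisError(
            f"no standard within {MAX_STANDARD_GAP_H} h of sample counted at "
            f"t={count_time_h} h"
        )
    return best


def percent_ia_per_gram(w: CountWorksheet, nuclide: Nuclide) -> dict[str, float]:
    """Per-organ %IA/g for one worksheet, decay-referenced to injection.

    Each organ record is normalised against the standard counted nearest
    in time; both sample and standard counts are back-corrected to
    injection time before the ratio is taken, so cross-session decay drops
    out of the result.
    """
    if not w.standards:
        raise AnalysisError(f"worksheet {w.animal_id}: no counting standard")
    out: dict[str, float] = {}
    for rec in w.records:
        for t in (rec.count_time_h,):
            if t - w.injection_time_h < -NEGATIVE_ELAPSED_TOL_H:
                raise InputError(
                    f"{rec.organ!r} counted before injection (t={t} h)"
                )
        std = _nearest_standard(w.standards, rec.count_time_h)
        if std.cpm == 0:
            raise AnalysisError(f"worksheet {w.animal_id}: zero-count standard")
        sample_ref = rec.cpm / decay_factor(
            rec.count_time_h - w.injection_time_h, nuclide
        )
        std_ref = (
            std.cpm
            / decay_factor(std.count_time_h - w.injection_time_h, nuclide)
            / std.f_std
        )
        pia = 100.0 * sample_ref / std_ref
        key = rec.organ.strip().lower()
        out[key] = pia / rec.mass_g
    return out


def summarize(
    per_animal: list[tuple[float, dict[str, float]]],
    time_decimals: int = 6,
) -> pd.DataFrame:
    """Group per-animal %IA/g results into a mean +/- SD table.

    ``per_animal`` is a list of ``(timepoint_h, {organ: %IA/g})`` pairs.
    Returns a tidy frame with columns ``organ, time_h, mean_pia_g, sd, n``;
    the sample SD (n-1 denominator) is NaN when n = 1.  Cells with no
    animal simply do not appear (absent, never zero).
    """
    rows: dict[tuple[str, float], list[float]] = {}
    for time_h, values in per_animal:
        t = round(float(time_h), time_decimals)
        for organ, pia_g in values.items():
            rows.setdefault((organ, t), []).append(pia_g)
    records = []
    for (organ, t), vals in sorted(rows.items()):
        n = len(vals)
        records.append(
            {
                "organ": organ,
                "time_h": t,
                "mean_pia_g": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if n > 1 else math.nan,
                "n": n,
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["organ", "time_h", "mean_pia_g", "sd", "n"]
    )


def tn_ratios(table: pd.DataFrame, tumor_label: str = "tumor") -> pd.DataFrame:
    """Tumor-to-normal-tissue uptake ratios per timepoint.

    For every non-tumor organ and timepoint where the tumor mean exists,
    ``ratio = tumor mean %IA/g / organ mean %IA/g``.  Organ means of zero
    give an absent cell (NaN) with a warning rather than an infinity.
    """
    tumor_label = tumor_label.strip().lower()
    tumor = table[table["organ"] == tumor_label].set_index("time_h")["mean_pia_g"]
    if tumor.empty:
        raise AnalysisError(f"no {tumor_label!r} rows in biodistribution table")
    rows = []
    for _, row in table[table["organ"] != tumor_label].iterrows():
        t = row["time_h"]
        if t not in tumor.index:
            continue
        if row["mean_pia_g"] == 0:
            import warnings

            warnings.warn(
                f"zero {row['organ']} uptake at t={t} h; ratio undefined",
                stacklevel=2,
            )
            ratio = math.nan
        else:
            ratio = float(tumor.loc[t] / row["mean_pia_g"])
        rows.append({"organ": row["organ"], "time_h": t, "ratio": ratio})
    return pd.DataFrame.from_records(rows, columns=["organ", "time_h", "ratio"])


# ---------------------------------------------------------------------------
# Worksheet CSV I/O
#
# Layout: three header rows (key,value), then one row per organ sample
# "organ,mass_g,cpm,count_time" and one per standard
# "STANDARD,f_std,cpm,count_time".


def write_worksheet(w: CountWorksheet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"animal_id,{w.animal_id}\n")
        fh.write(f"injection_time,{w.injection_time_h!r}\n")
        fh.write(f"injected_activity_MBq,{w.injected_activity_mbq!r}\n")
        for r in w.records:
            fh.write(f"{r.organ},{r.mass_g!r},{r.cpm!r},{r.count_time_h!r}\n")
        for s in w.standards:
            fh.write(f"STANDARD,{s.f_std!r},{s.cpm!r},{s.count_time_h!r}\n")


def read_worksheet(path: str) -> CountWorksheet:
    header: dict[str, str] = {}
    records: list[OrganRecord] = []
    standards: list[StandardRecord] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) == 2:
                header[parts[0]] = parts[1]
            elif len(parts) == 4:
                if parts[0].upper() == "STANDARD":
                    standards.append(
                        StandardRecord(float(parts[1]), float(parts[2]), float(parts[3]))
                    )
                else:
                    records.append(
                        OrganRecord(parts[0], float(parts[1]), float(parts[2]), float(parts[3]))
                    )
            else:
                raise DataError(f"malformed worksheet line {line!r} in {path}")
    try:
        return CountWorksheet(
            animal_id=header["animal_id"],
            injection_time_h=float(header["injection_time"]),
            injected_activity_mbq=float(header["injected_activity_MBq"]),
            records=records,
            standards=standards,
        )
    except KeyError as exc:
        raise DataError(f"worksheet {path} missing header row {exc}") from exc
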