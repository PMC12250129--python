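"""Cellular uptake quantification and receptor-binding parameter estimation.

Covers the three classical plate-assay analyses for a radioligand:

* surface-bound vs internalized activity per million cells (%IA/1e6 cells),
  from acid-strip / lysate gamma counts against a counting standard;
* one-site saturation binding, ``B(c) = Bmax * c / (Kd + c)``, fitted to
  specific binding (total minus nonspecific) to estimate the dissociation
  constant Kd and capacity Bmax;
* one-site competition ("displacement") binding,
  ``B(c) = Bottom + (Top - Bottom) / (1 + c / IC50)``, fitted on a log
  concentration axis to estimate the half-maximal inhibitory concentration,
  and the Cheng-Prusoff conversion
  ``Ki = IC50 / (1 + [radioligand]/Kd)``.

Both fits use bounded least squares started from a deterministic log-spaced
grid (best sum of squared errors wins; ties break toward the smaller
Kd/IC50), so repeated runs on the same data give identical estimates.
The Hill slope is fixed at 1 (one-site models).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import AnalysisError, FitError, InputError

__all__ = [
    "UptakeRecord",
    "SaturationAssay",
    "CompetitionAssay",
    "BindingParams",
    "uptake_per_million_cells",
    "fit_saturation",
    "fit_competition",
    "cheng_prusoff",
]


@dataclass(frozen=True)
class UptakeRecord:
    """Gamma counts from one uptake well plus its counting standard.

    ``standard_counts`` are the counts of the full applied activity when
    ``f_std`` is 1, or of a known fraction ``f_std`` of it.
    """

    cell_line: str
    time_h: float
    surface_counts: float
    internalized_counts: float
    standard_counts: float
    f_std: float = 1.0
    cells: float = 1e5

    def __post_init__(self) -> None:
        if min(self.surface_counts, self.internalized_counts, self.standard_counts) < 0:
            raise InputError("counts must be >= 0")
        if not 0 < self.f_std <= 1:
            raise InputError(f"f_std must be in (0, 1], got {self.f_std}")
        if self.cells <= 0:
            raise InputError("cell count must be positive")


@dataclass
class SaturationAssay:
    """Total and nonspecific bound counts over a ladder of concentrations (nM)."""

    concentrations_nm: np.ndarray
    total_cpm: np.ndarray
    nonspecific_cpm: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations_nm = np.asarray(self.concentrations_nm, dtype=float)
        self.total_cpm = np.asarray(self.total_cpm, dtype=float)
        self.nonspecific_cpm = np.asarray(self.nonspecific_cpm, dtype=float)
        if not (
            self.concentrations_nm.shape
            == self.total_cpm.shape
            == self.nonspecific_cpm.shape
        ):
            raise InputError("saturation assay arrays must be aligned")
        if np.any(self.concentrations_nm <= 0):
            raise InputError("concentrations must be positive")
        if np.any(np.diff(self.concentrations_nm) <= 0):
            raise InputError("concentrations must be strictly increasing")


@dataclass
class CompetitionAssay:
    """Bound counts of a fixed radioligand against a competitor ladder (nM)."""

    competitor_nm: np.ndarray
    bound_cpm: np.ndarray
    radioligand_nm: float = 0.75

    def __post_init__(self) -> None:
        self.competitor_nm = np.asarray(self.competitor_nm, dtype=float)
        self.bound_cpm = np.asarray(self.bound_cpm, dtype=float)
        if self.competitor_nm.shape != self.bound_cpm.shape:
            raise InputError("competition assay arrays must be aligned")
        if np.any(self.competitor_nm <= 0):
            raise InputError("competitor concentrations must be positive")
        if np.any(self.bound_cpm < 0):
            raise InputError("bound counts must be >= 0")
        if self.radioligand_nm <= 0:
            raise InputError("radioligand concentration must be positive")


@dataclass
class BindingParams:
    """Estimated binding parameters with standard errors where available."""

    kd_nm: float | None = None
    bmax_cpm: float | None = None
    ic50_nm: float | None = None
    ki_nm: float | None = None
    se: dict[str, float] = field(default_factory=dict)
    sse: float | None = None


def uptake_per_million_cells(r: UptakeRecord) -> tuple[float, float]:
    """(surface, internalized) uptake as %IA per 1e6 cells.

    %IA is counts relative to the full applied activity
    (``standard_counts / f_std``); the per-cell normalisation assumes all
    counts were acquired in the same counting session (no decay term).
    """
    if r.standard_counts == 0:
        raise AnalysisError("standard counts are zero; cannot normalise")
    full_activity_counts = r.standard_counts / r.f_std
    scale = 100.0 / full_activity_counts * (1e6 / r.cells)
    return r.surface_counts * scale, r.internalized_counts * scale


def _multistart_least_squares(residual, starts, bounds, x_scale=None):
    """Run bounded least squares from each start; return (best_x, sse, jac).

    Deterministic: starts are tried in order, the smallest SSE wins, and
    ties (within 1e-9 relative) break toward the start earlier in the list
    after sorting candidates by the first parameter of interest.
    """
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                residual,
                x0,
                bounds=bounds,
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                x_scale=x_scale if x_scale is not None else "jac",
            )
        except Exception:  # singular jacobian at a bad start, keep going
            continue
        sse = float(2 * res.cost)
        if res.success or np.isfinite(sse):
            cand = (sse, res)
            if best is None or sse < best[0] * (1 - 1e-9):
                best = cand
    if best is None:
        raise FitError("all least-squares starts failed")
    return best[1]


def _standard_errors(res, n_obs: int) -> dict[int, float]:
    """Asymptotic SEs from the jacobian at the solution; NaN if singular."""
    n_par = res.x.size
    dof = max(n_obs - n_par, 1)
    sse = float(2 * res.cost)
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * (sse / dof)
        return {i: float(np.sqrt(max(cov[i, i], 0.0))) for i in range(n_par)}
    except np.linalg.LinAlgError:
        return {i: float("nan") for i in range(n_par)}


def fit_saturation(a: SaturationAssay) -> BindingParams:
    """Fit ``B(c) = Bmax*c/(Kd+c)`` to specific binding; returns Kd, Bmax.

    Specific binding is total minus nonspecific, computed pointwise;
    negative values are floored at zero with a warning (design points are
    kept, not excluded).  Requires at least 4 concentrations.
    """
    c = a.concentrations_nm
    if c.size < 4:
        raise InputError("saturation fit needs >= 4 concentration points")
    specific = a.total_cpm - a.nonspecific_cpm
    if np.any(specific < 0):
        warnings.warn(
            "negative specific binding floored at 0", stacklevel=2
        )
        specific = np.maximum(specific, 0.0)
    if specific.max() <= 0:
        raise FitError("specific binding is zero everywhere")

    def residual(p):
        bmax, kd = p
        return bmax * c / (kd + c) - specific

    b_ref = float(specific.max())
    starts = [
        np.array([b_ref * fb, kd0])
        for kd0 in np.logspace(-2, 3, 5)  # 0.01 nM .. 1 uM, 5 decades
        for fb in np.logspace(-0.5, 0.5, 5)
    ]
    # try smaller Kd starts first so SSE ties resolve toward smaller Kd
    starts.sort(key=lambda x: (x[1], x[0]))
    res = _multistart_least_squares(
        residual, starts, bounds=([0.0, 1e-12], [np.inf, np.inf])
    )
    bmax, kd = res.x
    ses = _standard_errors(res, c.size)
    return BindingParams(
        kd_nm=float(kd),
        bmax_cpm=float(bmax),
        se={"bmax_cpm": ses[0], "kd_nm": ses[1]},
        sse=float(2 * res.cost),
    )


def fit_competition(a: CompetitionAssay, free_slope: bool = False) -> BindingParams:
    """Fit one-site competition on log-concentration; returns IC50.

    ``B(c) = Bottom + (Top - Bottom)/(1 + (c/IC50)^h)`` with Top and
    Bottom free and the Hill slope ``h`` fixed at 1 unless
    ``free_slope=True``.  Requires >= 5 points whose bound counts actually
    span a transition; a flat curve is unidentifiable and raises
    :class:`~rltkit.errors.FitError`, as does a fitted IC50 outside the
    measured concentration range (transition not bracketed).
    """
    c = a.competitor_nm
    y = a.bound_cpm
    if c.size < 5:
        raise InputError("competition fit needs >= 5 points")
    span = float(y.max() - y.min())
    if y.max() <= 0 or span < 0.05 * y.max():
        raise FitError("bound counts are flat; IC50 unidentifiable")

    def residual(p):
        top, bottom, log_ic50 = p[0], p[1], p[2]
        h = p[3] if free_slope else 1.0
        return bottom + (top - bottom) / (1.0 + (c / 10.0**log_ic50) ** h) - y

    top0, bot0 = float(y.max()), float(y.min())
    starts = [
        np.array([top0 * f, bot0 * f if bot0 > 0 else 0.0, lg])
        for lg in np.linspace(-2, 3, 5)
        for f in np.linspace(0.8, 1.2, 5)
    ]
    starts.sort(key=lambda x: (x[2], x[0]))
    lower, upper = [0.0, 0.0, -12.0], [np.inf, np.inf, 12.0]
    scale = [max(top0, 1.0), max(bot0, 1.0), 1.0]
    if free_slope:
        starts = [np.append(x, 1.0) for x in starts]
        lower, upper, scale = lower + [0.1], upper + [10.0], scale + [1.0]
    res = _multistart_least_squares(
        residual, starts, bounds=(lower, upper), x_scale=np.array(scale)
    )
    top, bottom, log_ic50 = res.x[0], res.x[1], res.x[2]
    ic50 = 10.0**log_ic50
    if not (c.min() <= ic50 <= c.max()):
        raise FitError(
            f"fitted IC50 {ic50:.3g} nM lies outside the measured range "
            f"[{c.min():.3g}, {c.max():.3g}] nM; transition not bracketed"
        )
    ses = _standard_errors(res, c.size)
    # delta method: SE(IC50) = ln(10) * IC50 * SE(log10 IC50)
    return BindingParams(
        ic50_nm=float(ic50),
        se={"ic50_nm": float(np.log(10.0) * ic50 * ses[2])},
        sse=float(2 * res.cost),
    )


def cheng_prusoff(ic50_nm: float, radioligand_nm: float, kd_nm: float) -> float:
    """Inhibition constant ``Ki = IC50 / (1 + [radioligand]/Kd)`` in nM."""
    if kd_nm <= 0:
        raise InputError(f"Kd must be positive, got {kd_nm}")
    if ic50_nm <= 0:
        raise InputError(f"IC50 must be positive, got {ic50_nm}")
    if radioligand_nm < 0:
        raise InputError("radioligand concentration must be >= 0")
    return ic50_nm / (1.0 + radioligand_nm / kd_nm)
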