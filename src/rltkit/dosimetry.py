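"""Mouse-to-human extrapolation, biokinetic fitting and MIRD-style dosimetry.

The chain implemented here turns a rodent biodistribution table into a
human organ-dose estimate:

1. *Relative organ-mass scaling.*  For each organ and timepoint,

       (%IA/organ)_human = (%IA/g)_animal x (kg TB)_animal
                           x (g_organ / kg TB)_human

   Because the %IA/g tables upstream are decay-referenced to injection
   (biology only), the extrapolated curves are multiplied back by the
   physical decay factor so that they describe physical activity — the
   quantity whose time integral counts disintegrations.

2. *Biokinetic fitting.*  Each organ curve is fitted with a mono- or
   bi-exponential, with every disappearance rate bounded below by the
   physical decay constant (biological clearance can only speed up,
   never slow down, physical disappearance).  ``model="auto"`` selects the
   order by corrected AIC (ties prefer mono).

3. *Time-integrated activity.*  The residence time (h) of an organ is the
   analytic integral of the fitted curve, tau = sum(c_i / rate_i) with
   coefficients as fractions of injected activity; a trapezoid-plus-
   physical-tail fallback covers curves that resist fitting.  Whole-body
   minus the organs gives the "remainder of body" region.

4. *MIRD dose sum.*  Absorbed dose per unit injected activity is
   D(target) = sum_source tau_source x S(target <- source) in mGy/MBq,
   with the S-matrix supplied as data.  With a radiation weighting factor
   of 1 for beta/gamma emitters the equivalent dose (mSv/MBq) is
   numerically equal, and the effective dose is the tissue-weighted sum
   over organs using ICRP-60-style weights.

The packaged S-matrix is a toy demonstration fixture; for the self-dose
terms a simplified closed form is also available (:func:`build_smatrix`):
``S_self = 0.5767 x E_beta(MeV) / m(kg)`` mGy/(MBq h), which is
3.6e9 decays per MBq h times the mean beta energy converted to mGy in the
organ mass, plus optional photon cross-organ terms from user-supplied
absorbed fractions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, nnls

from .errors import AnalysisError, DataError, FitError, InputError
from .nuclide import Nuclide, decay_factor

__all__ = [
    "PhantomMasses",
    "HumanTimeActivity",
    "ExpFit",
    "ResidenceTimeSet",
    "SMatrix",
    "DoseReport",
    "extrapolate_to_human",
    "fit_time_activity",
    "cumulated_activity",
    "cumulated_activity_trapezoid",
    "remainder_of_body",
    "organ_doses",
    "effective_dose",
    "build_smatrix",
    "load_phantom",
    "load_smatrix",
    "load_tissue_weights",
]

#: Default adult mouse total-body mass (kg), config-overridable.
DEFAULT_ANIMAL_BODY_KG = 0.025


@dataclass
class PhantomMasses:
    """Reference-phantom organ masses (g) and total-body mass (kg)."""

    organ_g: dict[str, float]
    total_body_kg: float

    def __post_init__(self) -> None:
        if self.total_body_kg <= 0:
            raise InputError("total-body mass must be positive")
        for organ, m in self.organ_g.items():
            if m <= 0:
                raise InputError(f"phantom mass must be positive for {organ!r}")
        if sum(self.organ_g.values()) > self.total_body_kg * 1000.0:
            raise InputError("phantom organ masses exceed total-body mass")


@dataclass
class HumanTimeActivity:
    """Whole-organ activity curve, %IA (physical, not decay-corrected)."""

    organ: str
    times_h: np.ndarray
    pct_ia: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.pct_ia = np.asarray(self.pct_ia, dtype=float)
        if self.times_h.shape != self.pct_ia.shape:
            raise InputError("times and activities must be aligned")
        if np.any(self.times_h < 0):
            raise InputError("times must be >= 0")
        if self.times_h.size > 1 and np.any(np.diff(self.times_h) <= 0):
            raise InputError("times must be strictly increasing")
        if np.any(self.pct_ia < 0):
            raise InputError("%IA must be >= 0")


@dataclass
class ExpFit:
    """Sum-of-exponentials fit: ``sum_i c_i * exp(-rate_i * t)`` in %IA."""

    organ: str
    terms: list[tuple[float, float]]  # (coefficient %IA, rate 1/h)
    model: str  # "mono" | "bi" | "zero"
    sse: float = 0.0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c, r in self.terms:
            out = out + c * np.exp(-r * t)
        return out


@dataclass
class ResidenceTimeSet:
    """Residence times tau (h per unit injected activity) per source region."""

    taus_h: dict[str, float]

    def __post_init__(self) -> None:
        for organ, tau in self.taus_h.items():
            if tau < 0:
                raise InputError(f"residence time must be >= 0 for {organ!r}")

    def total(self) -> float:
        return float(sum(self.taus_h.values()))


@dataclass
class SMatrix:
    """Dose factors S(target <- source) in mGy/(MBq h).

    ``table`` is a DataFrame with target organs as the index and source
    organs as columns.
    """

    table: pd.DataFrame
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        if (self.table.to_numpy() < 0).any():
            raise InputError("S-values must be >= 0")
        for organ in set(self.table.index) & set(self.table.columns):
            if self.table.loc[organ, organ] <= 0:
                raise InputError(f"self-dose S must be positive for {organ!r}")


@dataclass
class DoseReport:
    """Absorbed organ doses (mGy/MBq); equivalent doses are numerically
    equal (radiation weighting 1 for beta/gamma)."""

    absorbed_mgy_per_mbq: dict[str, float]
    effective_msv_per_mbq: float | None = None

    @property
    def equivalent_msv_per_mbq(self) -> dict[str, float]:
        return dict(self.absorbed_mgy_per_mbq)


# ---------------------------------------------------------------------------
# 1. extrapolation


def extrapolate_to_human(
    biodist: pd.DataFrame,
    animal_total_body_kg: float,
    phantom: PhantomMasses,
    nuclide: Nuclide,
) -> tuple[list[HumanTimeActivity], list[str]]:
    """Relative organ-mass scaling of a %IA/g table to human organ curves.

    ``biodist`` is the tidy ``organ,time_h,mean_pia_g,...`` table.  Organs
    absent from the phantom (e.g. the xenograft tumor) are excluded and
    returned in the second element.  The returned curves are physical
    activities: the decay-corrected %IA/g values are multiplied back by
    ``decay_factor(t)``.
    """
    if animal_total_body_kg <= 0:
        raise InputError("animal total-body mass must be positive")
    curves: list[HumanTimeActivity] = []
    excluded: list[str] = []
    for organ, group in biodist.groupby("organ", sort=True):
        key = str(organ).strip().lower()
        if key not in phantom.organ_g:
            excluded.append(key)
            continue
        g_per_kg = phantom.organ_g[key] / phantom.total_body_kg
        group = group.sort_values("time_h")
        t = group["time_h"].to_numpy(dtype=float)
        pct = (
            group["mean_pia_g"].to_numpy(dtype=float)
            * animal_total_body_kg
            * g_per_kg
            * np.array([decay_factor(ti, nuclide) for ti in t])
        )
        curves.append(HumanTimeActivity(organ=key, times_h=t, pct_ia=pct))
    return curves, excluded


# ---------------------------------------------------------------------------
# 2. biokinetic fitting


def _fit_fixed_order(t, y, n_terms: int, lam: float) -> tuple[np.ndarray, float]:
    """Best-fit (coeffs, rates) packed as [c..., r...] with SSE, multistart."""
    rate_grid = np.geomspace(lam, 1.0, 6)
    if n_terms == 1:
        rate_sets = [(r,) for r in rate_grid]
    else:
        rate_sets = [
            (r1, r2) for i, r1 in enumerate(rate_grid) for r2 in rate_grid[i + 1 :]
        ]

    def residual(p):
        c, r = p[:n_terms], p[n_terms:]
        return (c[None, :] * np.exp(-np.outer(t, r))).sum(axis=1) - y

    best: tuple[float, np.ndarray] | None = None
    for rates in rate_sets:
        design = np.exp(-np.outer(t, rates))
        coeffs, _ = nnls(design, y)
        x0 = np.concatenate([coeffs, rates])
        lower = np.concatenate([np.zeros(n_terms), np.full(n_terms, lam)])
        upper = np.full(2 * n_terms, np.inf)
        x0 = np.clip(x0, lower + 1e-15, None)
        try:
            res = least_squares(
                residual, x0, bounds=(lower, upper),
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except Exception:
            continue
        sse = float(2 * res.cost)
        if best is None or sse < best[0] * (1 - 1e-12):
            best = (sse, res.x)
    if best is None:
        raise FitError("time-activity fit did not converge from any start")
    return best[1], best[0]


def _aicc(sse: float, n: int, k: int) -> float:
    sse = max(sse, 1e-300)
    aic = n * math.log(sse / n) + 2 * k
    return aic + 2 * k * (k + 1) / (n - k - 1)


def fit_time_activity(
    c: HumanTimeActivity, nuclide: Nuclide, model: str = "auto"
) -> ExpFit:
    """Fit an exponential biokinetic model to a whole-organ activity curve.

    Rates are bounded below by the physical decay constant.  ``model`` is
    ``"mono"``, ``"bi"`` or ``"auto"`` (AICc selection; bi-exponential is
    only eligible when it leaves at least one residual degree of freedom,
    and ties prefer mono).  An all-zero curve returns a zero-term fit.
    """
    t, y = c.times_h, c.pct_ia
    lam = nuclide.lambda_phys
    if np.all(y == 0):
        return ExpFit(organ=c.organ, terms=[], model="zero", sse=0.0)
    if model not in ("mono", "bi", "auto"):
        raise InputError(f"unknown model {model!r}")
    if model == "mono" and t.size < 2:
        raise InputError("mono-exponential fit needs >= 2 points")
    if model == "bi" and t.size < 4:
        raise InputError("bi-exponential fit needs >= 4 points")

    candidates: list[tuple[str, np.ndarray, float, int]] = []
    orders = {"mono": [1], "bi": [2], "auto": [1, 2]}[model]
    for n_terms in orders:
        if t.size < 2 * n_terms:
            continue
        if model == "auto" and n_terms == 2 and t.size - 2 * n_terms - 1 <= 0:
            continue  # AICc undefined; bi ineligible for selection
        params, sse = _fit_fixed_order(t, y, n_terms, lam)
        candidates.append(
            ("mono" if n_terms == 1 else "bi", params, sse, 2 * n_terms)
        )
    if not candidates:
        raise FitError(f"no fittable model for organ {c.organ!r}")
    if model == "auto" and len(candidates) == 2:
        scores = [_aicc(sse, t.size, k) for _, _, sse, k in candidates]
        # strict improvement required: ties go to the simpler (mono) model
        chosen = candidates[1] if scores[1] < scores[0] - 1e-12 else candidates[0]
    else:
        chosen = candidates[0]
    tag, params, sse, k = chosen
    n_terms = k // 2
    terms = sorted(
        zip(params[:n_terms].tolist(), params[n_terms:].tolist()),
        key=lambda cr: -cr[1],
    )
    terms = [(float(ci), float(ri)) for ci, ri in terms if ci > 0]
    if not terms:
        return ExpFit(organ=c.organ, terms=[], model="zero", sse=float(sse))
    return ExpFit(organ=c.organ, terms=terms, model=tag, sse=float(sse))


# ---------------------------------------------------------------------------
# 3. residence times


def cumulated_activity(f: ExpFit) -> float:
    """Residence time tau (h): analytic integral of the fitted curve.

    Coefficients are %IA, so each term contributes ``(c/100)/rate`` hours
    per unit injected activity.
    """
    return float(sum((c / 100.0) / r for c, r in f.terms))


def cumulated_activity_trapezoid(c: HumanTimeActivity, nuclide: Nuclide) -> float:
    """Fallback tau: trapezoid over the samples plus a physical-decay tail.

    Used when an organ curve cannot be fitted; the integral beyond the last
    sample assumes pure physical decay (no further biological clearance),
    which is conservative.
    """
    if c.times_h.size == 0:
        return 0.0
    frac = c.pct_ia / 100.0
    body = float(np.trapezoid(frac, c.times_h)) if c.times_h.size > 1 else 0.0
    tail = float(frac[-1] / nuclide.lambda_phys)
    return body + tail


def remainder_of_body(
    organ_taus: ResidenceTimeSet, whole_body_tau_h: float
) -> ResidenceTimeSet:
    """Add the remainder-of-body region: whole-body tau minus organ taus.

    If the organ sum exceeds the whole-body value (inconsistent inputs)
    the remainder is clamped at zero with a warning.
    """
    organ_sum = organ_taus.total()
    remainder = whole_body_tau_h - organ_sum
    if remainder < 0:
        warnings.warn(
            f"organ residence times ({organ_sum:.4g} h) exceed whole-body "
            f"({whole_body_tau_h:.4g} h); remainder clamped to 0",
            stacklevel=2,
        )
        remainder = 0.0
    taus = dict(organ_taus.taus_h)
    taus["remainder"] = remainder
    return ResidenceTimeSet(taus_h=taus)


# ---------------------------------------------------------------------------
# 4. dose engine


def organ_doses(taus: ResidenceTimeSet, s: SMatrix) -> DoseReport:
    """MIRD sum ``D(target) = sum_source tau_source * S(target <- source)``."""
    sources = [o for o in taus.taus_h if o in s.table.columns]
    missing = [o for o in taus.taus_h if o not in s.table.columns]
    if missing:
        warnings.warn(
            f"source regions missing from S-matrix, excluded: {missing}",
            stacklevel=2,
        )
    if not sources:
        raise InputError("no residence-time source appears in the S-matrix")
    tau_vec = np.array([taus.taus_h[o] for o in sources])
    sub = s.table[sources].to_numpy()
    doses = sub @ tau_vec
    return DoseReport(
        absorbed_mgy_per_mbq={
            str(t): float(d) for t, d in zip(s.table.index, doses)
        }
    )


def effective_dose(
    d: DoseReport,
    weights: dict[str, float],
    masses_g: dict[str, float] | None = None,
) -> float:
    """Tissue-weighted effective dose (mSv/MBq).

    ``weights`` maps tissue names to ICRP weighting factors and must
    include a ``REMAINDER`` entry; explicit weights plus remainder must sum
    to 1 within 1e-6.  The remainder tissue dose is the mass-weighted mean
    equivalent dose of report organs not explicitly weighted (plain mean if
    masses are not given; mean over all organs if every report organ is
    explicitly weighted).  Weighted tissues absent from the report are
    assigned the remainder dose, keeping the weights normalised.
    """
    w = {k.strip().lower(): v for k, v in weights.items()}
    w_rem = w.pop("remainder", None)
    if w_rem is None:
        raise InputError("weights must include a REMAINDER entry")
    total = sum(w.values()) + w_rem
    if abs(total - 1.0) > 1e-6:
        raise InputError(f"tissue weights must sum to 1, got {total}")
    doses = {k.strip().lower(): v for k, v in d.absorbed_mgy_per_mbq.items()}
    unweighted = [o for o in doses if o not in w]
    pool = unweighted if unweighted else list(doses)
    if not pool:
        raise InputError("dose report is empty")
    if masses_g:
        m = {k.strip().lower(): v for k, v in masses_g.items()}
        wts = np.array([m.get(o, 0.0) for o in pool])
        if wts.sum() > 0:
            h_rem = float(np.average([doses[o] for o in pool], weights=wts))
        else:
            h_rem = float(np.mean([doses[o] for o in pool]))
    else:
        h_rem = float(np.mean([doses[o] for o in pool]))
    e = w_rem * h_rem
    for tissue, wt in w.items():
        e += wt * doses.get(tissue, h_rem)
    return float(e)


def build_smatrix(
    organ_masses_g: dict[str, float],
    nuclide: Nuclide,
    photon_fractions: dict[tuple[str, str], float] | None = None,
) -> SMatrix:
    """Simplified S-matrix: electron self-dose plus optional photon terms.

    Self-dose assumes complete local absorption of the mean beta energy:
    ``S_self = 0.5767 * E_beta(MeV) / m(kg)`` mGy/(MBq h).  Photon
    cross-dose terms are added as
    ``0.5767 * E_photon(MeV) * phi / m_target(kg)`` for each user-supplied
    absorbed fraction ``phi`` keyed by ``(target, source)``.
    """
    organs = sorted(organ_masses_g)
    table = pd.DataFrame(0.0, index=organs, columns=organs)
    for organ in organs:
        m_kg = organ_masses_g[organ] / 1000.0
        if m_kg <= 0:
            raise InputError(f"organ mass must be positive for {organ!r}")
        table.loc[organ, organ] = 0.5767 * nuclide.beta_mean_mev / m_kg
    for (target, source), phi in (photon_fractions or {}).items():
        if not 0 <= phi <= 1:
            raise InputError("absorbed fractions must be in [0, 1]")
        m_kg = organ_masses_g[target] / 1000.0
        table.loc[target, source] += 0.5767 * nuclide.photon_energy_mev * phi / m_kg
    return SMatrix(table=table, provenance="simplified closed-form builder")


# ---------------------------------------------------------------------------
# data-file loaders


def _packaged(name: str) -> str:
    return str(resources.files("rltkit.data") / name)


def load_phantom(path: str | None = None) -> PhantomMasses:
    """Load ``organ,mass_g`` phantom CSV (TOTAL_BODY_KG row for body mass)."""
    df = pd.read_csv(path or _packaged("phantom_adult70.csv"), comment="#")
    organs: dict[str, float] = {}
    total = None
    for _, row in df.iterrows():
        name = str(row["organ"]).strip()
        if name.upper() == "TOTAL_BODY_KG":
            total = float(row["mass_g"])
        else:
            organs[name.lower()] = float(row["mass_g"])
    if total is None:
        raise DataError("phantom file lacks a TOTAL_BODY_KG row")
    return PhantomMasses(organ_g=organs, total_body_kg=total)


def load_smatrix(path: str | None = None) -> SMatrix:
    """Load a ``target,source,S_mGy_per_MBq_h`` CSV into an S-matrix."""
    df = pd.read_csv(path or _packaged("smatrix_toy.csv"), comment="#")
    table = df.pivot(index="target", columns="source", values="S_mGy_per_MBq_h")
    table = table.fillna(0.0)
    return SMatrix(table=table, provenance=path or "packaged toy fixture")


def load_tissue_weights(path: str | None = None) -> dict[str, float]:
    """Load ``tissue,wT`` weighting factors (REMAINDER row included)."""
    df = pd.read_csv(path or _packaged("tissue_weights_icrp60.csv"), comment="#")
    return {str(r["tissue"]).strip(): float(r["wT"]) for _, r in df.iterrows()}
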