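"""Radioactive-decay arithmetic, units and nuclide constants.

Internal unit conventions, used everywhere downstream:

* time — hours (configuration files may declare half-lives in days);
* activity — MBq (molar activity is reported in GBq/umol only at the
  reporting boundary);
* energies — MeV per decay for the mean beta energy, keV for photon lines.

The default nuclide is lutetium-177, a medium-energy beta emitter with a
physical half-life of 6.73 days and low-abundance gamma lines at
208 keV (11%) and 113 keV (6%) that make it usable for both therapy and
SPECT imaging.  Its constants ship in the editable ``data/nuclides.csv``
table; the mean beta energy there (0.1335 MeV/decay) is the standard
evaluated value for Lu-177, not a fitted quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

from .errors import DataError, InputError

LN2 = math.log(2.0)

__all__ = [
    "Nuclide",
    "ActivityMeasurement",
    "decay_factor",
    "decay_correct",
    "molar_activity",
    "load_nuclides",
    "lu177",
]


@dataclass(frozen=True)
class Nuclide:
    """Physical constants of a radionuclide.

    Parameters
    ----------
    name:
        Display name, e.g. ``"Lu-177"``.
    half_life_h:
        Physical half-life in hours; must be positive.
    beta_mean_mev:
        Mean beta (electron) energy emitted per decay, MeV.
    photon_emissions:
        Tuple of ``(energy_keV, yield_fraction)`` pairs; yields in [0, 1].
    """

    name: str
    half_life_h: float
    beta_mean_mev: float = 0.0
    photon_emissions: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not (self.half_life_h > 0 and math.isfinite(self.half_life_h)):
            raise InputError(f"half-life must be positive, got {self.half_life_h}")
        if self.beta_mean_mev < 0:
            raise InputError("mean beta energy must be >= 0")
        for energy, frac in self.photon_emissions:
            if energy <= 0:
                raise InputError(f"photon energy must be positive, got {energy}")
            if not 0.0 <= frac <= 1.0:
                raise InputError(f"photon yield must lie in [0, 1], got {frac}")

    @property
    def lambda_phys(self) -> float:
        """Physical decay constant, 1/h."""
        return LN2 / self.half_life_h

    @property
    def photon_energy_mev(self) -> float:
        """Yield-weighted total photon energy per decay, MeV."""
        return sum(e * y for e, y in self.photon_emissions) / 1000.0


@dataclass(frozen=True)
class ActivityMeasurement:
    """An activity reading at a known time.

    ``time_h`` is hours on the experiment clock (injection is usually 0).
    """

    value_mbq: float
    time_h: float

    def __post_init__(self) -> None:
        if self.value_mbq < 0:
            raise InputError(f"activity must be >= 0, got {self.value_mbq}")
        if not math.isfinite(self.time_h):
            raise InputError("measurement time must be finite")


def decay_factor(elapsed_h: float, nuclide: Nuclide) -> float:
    """Fraction of activity remaining after ``elapsed_h`` hours.

    Evaluates ``2**(-elapsed/half_life)``.  Negative elapsed times are
    allowed and yield factors > 1 (back-correction to an earlier reference).
    """
    if not math.isfinite(elapsed_h):
        raise InputError(f"elapsed time must be finite, got {elapsed_h}")
    return 2.0 ** (-elapsed_h / nuclide.half_life_h)


def decay_correct(
    m: ActivityMeasurement, reference_time_h: float, nuclide: Nuclide
) -> float:
    """Activity (MBq) the sample had/will have at ``reference_time_h``.

    Dividing by the decay factor over ``t_meas - t_ref`` makes this the
    exact inverse of forward decay: correcting a decayed measurement back
    to its reference recovers the original value.
    """
    if not math.isfinite(reference_time_h):
        raise InputError("reference time must be finite")
    return m.value_mbq / decay_factor(m.time_h - reference_time_h, nuclide)


def molar_activity(activity_gbq: float, amount_nmol: float) -> float:
    """Molar activity in GBq/umol from activity (GBq) and amount (nmol)."""
    if amount_nmol <= 0:
        raise InputError(f"amount must be positive, got {amount_nmol} nmol")
    if activity_gbq < 0:
        raise InputError("activity must be >= 0")
    return activity_gbq / (amount_nmol * 1e-3)


def _parse_photons(field: str) -> tuple[tuple[float, float], ...]:
    field = field.strip()
    if not field:
        return ()
    pairs = []
    for token in field.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            energy, yield_ = token.split(":")
            pairs.append((float(energy), float(yield_)))
        except ValueError as exc:
            raise DataError(f"malformed photon emission token {token!r}") from exc
    return tuple(pairs)


def load_nuclides(path: str | None = None) -> dict[str, Nuclide]:
    """Load a nuclide constants table.

    The file is delimited text with columns ``name``, ``half_life_days``,
    ``beta_mean_MeV`` and ``photon_keV_yield`` (the last a ``;``-separated
    list of ``keV:yield`` pairs).  With ``path=None`` the packaged table is
    used.
    """
    if path is None:
        text = (resources.files("rltkit.data") / "nuclides.csv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DataError("empty nuclide table")
    header = [c.strip() for c in lines[0].split(",")]
    expected = ["name", "half_life_days", "beta_mean_MeV", "photon_keV_yield"]
    if header[: len(expected)] != expected:
        raise DataError(f"unexpected nuclide table header {header!r}")
    out: dict[str, Nuclide] = {}
    for ln in lines[1:]:
        # photon field may itself contain no commas (";"-separated)
        parts = ln.split(",")
        if len(parts) < 3:
            raise DataError(f"malformed nuclide row {ln!r}")
        name = parts[0].strip()
        half_life_days = float(parts[1])
        beta = float(parts[2])
        photons = _parse_photons(parts[3]) if len(parts) > 3 else ()
        out[name] = Nuclide(
            name=name,
            half_life_h=half_life_days * 24.0,
            beta_mean_mev=beta,
            photon_emissions=photons,
        )
    return out


def lu177() -> Nuclide:
    """The packaged lutetium-177 constants."""
    return load_nuclides()["Lu-177"]
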