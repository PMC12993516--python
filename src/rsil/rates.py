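"""Rate estimation, unit normalization and the sulfate electron balance.

Rates are estimated from produced-CO2 (or sulfate) time series either by the
endpoint difference or by an ordinary least-squares slope, annualized with a
365-day year. Per-microcosm concentration rates (mM/yr) are converted to
amount rates (mmol/yr) through the aqueous volume and normalized per gram of
oil, per mole of CH2, or per oil-water-contact area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, model_validator

from rsil.errors import (
    ConfigurationError,
    InsufficientDataError,
    UnitMismatchError,
)
from rsil.mineralization import ProducedCO2Point

DAYS_PER_YEAR = 365.0

# Unit labels used throughout report tables.
UNIT_MM_PER_YR = "mM/yr"
UNIT_MMOL_PER_YR = "mmol/yr"
UNIT_MMOL_PER_G_YR = "mmol/g/yr"
UNIT_MMOL_PER_MOL_CH2_YR = "mmol/mol_CH2/yr"
UNIT_G_CH2_PER_M2_YR = "g_CH2/m2/yr"
UNIT_MMOL_SO4_PER_YR = "mmol_SO4/yr"

VALID_UNITS = frozenset(
    {
        UNIT_MM_PER_YR,
        UNIT_MMOL_PER_YR,
        UNIT_MMOL_PER_G_YR,
        UNIT_MMOL_PER_MOL_CH2_YR,
        UNIT_G_CH2_PER_M2_YR,
        UNIT_MMOL_SO4_PER_YR,
    }
)

ENDPOINT = "endpoint"
OLS = "ols"


class MicrocosmConfig(BaseModel):
    """Experiment constants for one microcosm series.

    Defaults reflect a 120 mL serum-bottle incubation with 100 mL aqueous
    phase, one ~0.33 g oil drop, a 7.58 mM bicarbonate buffer at 10 atom%
    13C, substrate at 1.075 atom% and a 16.61 cm2 oil-water contact area.
    """

    aqueous_volume: float = 0.100  # L
    oil_mass: float = 0.33  # g
    buffer_total_co2: float = 7.58  # mM
    buffer_atom_pct: float = 10.0  # %
    substrate_atom_pct: float = 1.075  # %
    owc_area: float = 16.61e-4  # m2
    ch2_molar_mass: float = 14.0266  # g/mol
    electrons_per_carbon: int = 6  # C(-II) -> C(+IV)
    electrons_per_sulfate: int = 8  # SO4(2-) -> H2S

    @model_validator(mode="after")
    def _check(self) -> "MicrocosmConfig":
        for name in (
            "aqueous_volume",
            "oil_mass",
            "buffer_total_co2",
            "buffer_atom_pct",
            "substrate_atom_pct",
            "owc_area",
            "ch2_molar_mass",
            "electrons_per_carbon",
            "electrons_per_sulfate",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if not self.buffer_atom_pct > self.substrate_atom_pct:
            raise ConfigurationError(
                "buffer_atom_pct must exceed substrate_atom_pct "
                f"({self.buffer_atom_pct} <= {self.substrate_atom_pct})"
            )
        return self


@dataclass(frozen=True)
class RateEstimate:
    """A rate with units, estimation interval, method and provenance."""

    value: float
    units: str
    interval: Tuple[float, float]
    method: str
    replicate_id: str = "pooled"
    sd: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if self.units not in VALID_UNITS:
            raise UnitMismatchError(
                f"unknown units {self.units!r}; expected one of {sorted(VALID_UNITS)}"
            )
        if not self.interval[0] < self.interval[1]:
            raise ConfigurationError(
                f"interval start must precede end, got {self.interval}"
            )


@dataclass(frozen=True)
class SulfateReduction:
    """Total sulfate reduced (mmol) plus the annualized rate."""

    total_mmol: float
    rate: RateEstimate
    increased: bool  # sulfate went up over the interval (flag, not error)


@dataclass(frozen=True)
class ElectronBalanceResult:
    """Electron inventories for substrate oxidation vs sulfate reduction.

    Inventories are in milli-electron-equivalents per litre (mM of
    transferred electrons). The fraction not accounted for by sulfate
    reduction is attributed to biomass synthesis.
    """

    donor_electrons: float
    acceptor_electrons: float
    fraction_to_sulfate: float
    fraction_to_biomass: float
    inconsistent: bool = False  # donor = 0 with acceptor > 0
    out_of_range: bool = False  # acceptor exceeds donor


def _interval_points(
    series: Sequence[ProducedCO2Point], interval: Tuple[float, float]
) -> list[ProducedCO2Point]:
    lo, hi = interval
    return sorted(
        (p for p in series if lo <= p.day <= hi), key=lambda p: p.day
    )


def estimate_rate(
    series: Sequence[ProducedCO2Point],
    interval: Tuple[float, float],
    method: str = ENDPOINT,
    replicate_id: str = "pooled",
    units: str = UNIT_MM_PER_YR,
) -> RateEstimate:
    """Estimate a production rate (mM/yr) over ``interval`` days.

    ``endpoint``: (last - first) / elapsed days * 365.
    ``ols``: least-squares slope of produced_mM vs day * 365.
    Both coincide exactly on noiseless linear series.
    """
    if method not in (ENDPOINT, OLS):
        raise ConfigurationError(f"unknown rate method {method!r}")
    pts = _interval_points(series, interval)
    if len(pts) < 2:
        raise InsufficientDataError(
            f"need >= 2 points inside interval {interval}, got {len(pts)}"
        )
    days = np.array([p.day for p in pts])
    vals = np.array([p.produced_mM for p in pts])
    if method == ENDPOINT:
        slope = (vals[-1] - vals[0]) / (days[-1] - days[0])
    else:
        slope = np.polyfit(days, vals, 1)[0]
    return RateEstimate(
        value=float(slope * DAYS_PER_YEAR),
        units=units,
        interval=(float(interval[0]), float(interval[1])),
        method=method,
        replicate_id=replicate_id,
        n=len(pts),
    )


def mean_replicate_rate(rates: Sequence[RateEstimate]) -> RateEstimate:
    """Arithmetic mean of replicate rates, with the sample standard deviation.

    All inputs must share units, interval and method.
    """
    if not rates:
        raise InsufficientDataError("no rates to average")
    first = rates[0]
    for r in rates[1:]:
        if r.units != first.units:
            raise UnitMismatchError(
                f"mixed units: {first.units!r} vs {r.units!r}"
            )
        if r.interval != first.interval:
            raise UnitMismatchError(
                f"mixed intervals: {first.interval} vs {r.interval}"
            )
        if r.method != first.method:
            raise UnitMismatchError(
                f"mixed methods: {first.method!r} vs {r.method!r}"
            )
    values = np.array([r.value for r in rates])
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return RateEstimate(
        value=float(np.mean(values)),
        units=first.units,
        interval=first.interval,
        method=first.method,
        replicate_id="pooled",
        sd=sd,
        n=len(values),
    )


def _replace(rate: RateEstimate, value: float, units: str) -> RateEstimate:
    sd = None
    if rate.sd is not None and rate.value != 0:
        sd = rate.sd * abs(value / rate.value)
    return RateEstimate(
        value=value,
        units=units,
        interval=rate.interval,
        method=rate.method,
        replicate_id=rate.replicate_id,
        sd=sd,
        n=rate.n,
    )


def to_amount_rate(rate: RateEstimate, config: MicrocosmConfig) -> RateEstimate:
    """Convert a concentration rate (mM/yr) to an amount rate (mmol/yr)."""
    if rate.units != UNIT_MM_PER_YR:
        raise UnitMismatchError(f"expected {UNIT_MM_PER_YR!r}, got {rate.units!r}")
    return _replace(rate, rate.value * config.aqueous_volume, UNIT_MMOL_PER_YR)


PER_G_OIL = "per_g_oil"
PER_MOL_CH2 = "per_mol_ch2"
PER_OWC_AREA = "per_owc_area"


def normalize_rate(
    rate: RateEstimate, config: MicrocosmConfig, basis: str
) -> RateEstimate:
    """Normalize an amount rate (mmol/yr) to one of three reference bases.

    * ``per_g_oil``: divide by the oil mass -> mmol per g oil per yr.
    * ``per_mol_ch2``: divide by oil_mass / ch2_molar_mass (moles of CH2
      supplied) -> mmol CO2 per mol CH2 per yr.
    * ``per_owc_area``: convert mmol CO2/yr to g CH2/yr (1 mol CO2 per mol
      CH2 oxidized) and divide by the oil-water contact area in m2.
    """
    if rate.units != UNIT_MMOL_PER_YR:
        raise UnitMismatchError(f"expected {UNIT_MMOL_PER_YR!r}, got {rate.units!r}")
    if basis == PER_G_OIL:
        return _replace(rate, rate.value / config.oil_mass, UNIT_MMOL_PER_G_YR)
    if basis == PER_MOL_CH2:
        mol_ch2 = config.oil_mass / config.ch2_molar_mass
        return _replace(rate, rate.value / mol_ch2, UNIT_MMOL_PER_MOL_CH2_YR)
    if basis == PER_OWC_AREA:
        grams_per_yr = rate.value * config.ch2_molar_mass / 1000.0
        return _replace(rate, grams_per_yr / config.owc_area, UNIT_G_CH2_PER_M2_YR)
    raise ConfigurationError(f"unknown normalization basis {basis!r}")


def sulfate_reduced(
    series: Sequence[Tuple[float, float]],
    config: MicrocosmConfig,
    replicate_id: str = "pooled",
) -> SulfateReduction:
    """Total sulfate reduced and the annualized reduction rate.

    ``series`` is a sequence of (day, sulfate mM) pairs. Total reduced =
    (first - last) mM times the aqueous volume; a sulfate increase is
    flagged, not raised.
    """
    pts = sorted(series, key=lambda p: p[0])
    if len(pts) < 2:
        raise InsufficientDataError(
            f"need >= 2 sulfate points, got {len(pts)}"
        )
    (day0, s0), (day1, s1) = pts[0], pts[-1]
    delta_mM = s0 - s1
    total_mmol = delta_mM * config.aqueous_volume
    rate = RateEstimate(
        value=total_mmol / (day1 - day0) * DAYS_PER_YEAR,
        units=UNIT_MMOL_SO4_PER_YR,
        interval=(float(day0), float(day1)),
        method=ENDPOINT,
        replicate_id=replicate_id,
        n=len(pts),
    )
    return SulfateReduction(total_mmol=total_mmol, rate=rate, increased=delta_mM < 0)


def electron_balance(
    co2_evolved_mM: float,
    sulfate_reduced_mM: float,
    config: MicrocosmConfig,
) -> ElectronBalanceResult:
    """Close the electron balance between CO2 evolution and sulfate reduction.

    Donor electrons = CO2 (mM) * electrons per carbon (CH2 -> CO2 releases
    6 e-); acceptor electrons = sulfate (mM) * electrons per sulfate
    (SO4 -> H2S consumes 8 e-). The residual fraction is attributed to
    biomass synthesis.
    """
    if co2_evolved_mM < 0 or sulfate_reduced_mM < 0:
        raise ConfigurationError("electron balance inputs must be >= 0")
    donor = co2_evolved_mM * config.electrons_per_carbon
    acceptor = sulfate_reduced_mM * config.electrons_per_sulfate
    if donor == 0:
        return ElectronBalanceResult(
            donor_electrons=donor,
            acceptor_electrons=acceptor,
            fraction_to_sulfate=math.nan if acceptor > 0 else 0.0,
            fraction_to_biomass=math.nan if acceptor > 0 else 1.0,
            inconsistent=acceptor > 0,
        )
    frac_sulfate = acceptor / donor
    return ElectronBalanceResult(
        donor_electrons=donor,
        acceptor_electrons=acceptor,
        fraction_to_sulfate=frac_sulfate,
        fraction_to_biomass=1.0 - frac_sulfate,
        out_of_range=frac_sulfate > 1.0,
    )


def oil_consumed_mass(co2_total_mmol: float, config: MicrocosmConfig) -> float:
    """Oil consumed (mg) from total CO2 evolved, at one CH2 unit per CO2."""
    if co2_total_mmol < 0:
        raise ConfigurationError(
            f"co2_total_mmol must be >= 0, got {co2_total_mmol}"
        )
    return co2_total_mmol * config.ch2_molar_mass
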