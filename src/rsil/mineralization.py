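"""Two-pool label-dilution model for reverse stable isotope labelling.

A 13C-enriched bicarbonate buffer (pool ``T`` at atom percent ``A_b``) is
diluted by CO2 produced from a substrate at natural abundance (``A_s``).
The forward model gives the measured atom percent of the mixed pool; its
exact inversion recovers the produced CO2 from a measurement.

Accounting is aqueous-phase only (headspace CO2 neglected) and ``T`` is a
per-experiment constant by default; an optional cumulative mode re-anchors
the buffer pool at each timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from rsil.errors import (
    DegeneratePoolError,
    InvalidLabelError,
    InvalidMeasurementError,
    SingularInversionError,
)
from rsil.isotopes import (
    IsotopeConstants,
    atom_percent,
    delta_to_atom_fraction,
)

#: Measured atom percents closer than this to the substrate signature are
#: treated as singular (denominator of the inversion collapses).
_SINGULAR_TOL = 1e-12


@dataclass(frozen=True)
class CarbonPool:
    """An amount of CO2/DIC together with its 13C atom percent.

    ``amount`` is a concentration in mM (or an amount in mmol once a volume
    is bound); ``atom_pct`` is the 13C atom percent of the pool.
    """

    amount: float
    atom_pct: float

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise InvalidMeasurementError(f"pool amount must be >= 0, got {self.amount}")
        if not (0.0 <= self.atom_pct < 100.0):
            raise InvalidMeasurementError(
                f"atom percent must lie in [0, 100), got {self.atom_pct}"
            )


@dataclass(frozen=True)
class DeltaMeasurement:
    """One delta-13C reading (permil vs VPDB) at a timepoint for one microcosm."""

    day: float
    delta_permil: float
    microcosm_id: Optional[str] = None


@dataclass(frozen=True)
class ProducedCO2Point:
    """CO2 evolved from the substrate at one timepoint (mM, aqueous phase).

    ``flagged_negative`` is true iff ``produced_mM < 0`` — measurement noise
    pushed the atom percent outside the physically attainable band. Negative
    values are retained, never clipped, so downstream rate estimates stay
    unbiased.
    """

    day: float
    produced_mM: float
    flagged_negative: bool

    def __post_init__(self) -> None:
        if self.day < 0:
            raise InvalidMeasurementError(f"day must be >= 0, got {self.day}")


def forward_mix(buffer: CarbonPool, produced_mM: float, substrate_atom_pct: float) -> float:
    """Atom percent of the buffer pool after dilution with produced CO2.

    Returns ``A_mix = (T*A_b + P*A_s) / (T + P)``, the amount-weighted mean
    of the buffer and substrate signatures. For ``A_s < A_b`` and any
    ``P >= 0`` the result lies in ``(A_s, A_b]``.

    Raises
    ------
    DegeneratePoolError
        If ``T + P == 0``.
    InvalidMeasurementError
        If ``produced_mM < 0`` or the substrate atom percent is out of range.
    """
    if produced_mM < 0:
        raise InvalidMeasurementError(f"produced_mM must be >= 0, got {produced_mM}")
    if not (0.0 <= substrate_atom_pct < 100.0):
        raise InvalidMeasurementError(
            f"substrate atom percent must lie in [0, 100), got {substrate_atom_pct}"
        )
    total = buffer.amount + produced_mM
    if total == 0:
        raise DegeneratePoolError("total carbon pool is empty (T + P = 0)")
    return (buffer.amount * buffer.atom_pct + produced_mM * substrate_atom_pct) / total


def produced_co2(
    measured_atom_pct: float,
    buffer: CarbonPool,
    substrate_atom_pct: float,
    day: float = 0.0,
) -> ProducedCO2Point:
    """Invert the two-pool mixing model: measured atom percent -> produced CO2.

    ``P = T * (A_b - A) / (A - A_s)``, the exact inverse of
    :func:`forward_mix`. ``P > 0`` iff ``A_s < A < A_b``; measurements above
    the buffer signature yield negative P and are flagged, not clipped.

    Raises
    ------
    SingularInversionError
        If the measured atom percent equals the substrate signature.
    InvalidMeasurementError
        If the measured atom percent lies outside [0, 100).
    """
    a = measured_atom_pct
    if not (0.0 <= a < 100.0):
        raise InvalidMeasurementError(
            f"measured atom percent must lie in [0, 100), got {a}"
        )
    denom = a - substrate_atom_pct
    if abs(denom) < _SINGULAR_TOL:
        raise SingularInversionError(
            "measured atom percent equals the substrate signature "
            f"({substrate_atom_pct}%); produced CO2 is unbounded"
        )
    p = buffer.amount * (buffer.atom_pct - a) / denom
    return ProducedCO2Point(day=day, produced_mM=p, flagged_negative=p < 0)


def produced_series(
    measurements: Iterable[DeltaMeasurement],
    buffer: CarbonPool,
    substrate_atom_pct: float,
    constants: IsotopeConstants = IsotopeConstants(),
    cumulative_pool: bool = False,
) -> list[ProducedCO2Point]:
    """Convert a delta-13C time series into produced-CO2 points, ordered by day.

    Each point runs the chain delta -> atom fraction -> atom percent ->
    mixing-model inversion. With ``cumulative_pool=True`` the buffer pool is
    re-anchored at each timepoint to the previously inferred mixed state
    (total grows with produced CO2); the default keeps ``T`` constant.
    """
    points: list[ProducedCO2Point] = []
    ordered = sorted(measurements, key=lambda m: m.day)
    pool = buffer
    cumulative = 0.0
    for m in ordered:
        try:
            a = atom_percent(delta_to_atom_fraction(m.delta_permil, constants))
            point = produced_co2(a, pool, substrate_atom_pct, day=m.day)
        except (InvalidMeasurementError, SingularInversionError) as exc:
            raise type(exc)(
                f"microcosm={m.microcosm_id!r} day={m.day}: {exc}"
            ) from exc
        if cumulative_pool:
            increment = point.produced_mM
            cumulative += increment
            point = ProducedCO2Point(
                day=m.day, produced_mM=cumulative, flagged_negative=cumulative < 0
            )
            pool = CarbonPool(amount=pool.amount + increment, atom_pct=a)
        points.append(point)
    return points


def detection_limit(
    buffer: CarbonPool, substrate_atom_pct: float, sigma_atom_pct: float
) -> float:
    """Minimal detectable produced CO2 (mM) near P = 0.

    Linearizing the inversion at P = 0 gives
    ``dP/dA = -T / (A_b - A_s)``, so a 1-sigma atom-percent noise maps to
    ``sigma_atom_pct * T / (A_b - A_s)`` mM. Strictly increasing in ``T``:
    a large unlabelled DIC background degrades sensitivity.

    Raises
    ------
    InvalidLabelError
        If the buffer signature does not exceed the substrate signature.
    InvalidMeasurementError
        If ``sigma_atom_pct`` is not positive.
    """
    if buffer.atom_pct <= substrate_atom_pct:
        raise InvalidLabelError(
            f"buffer atom percent ({buffer.atom_pct}) must exceed "
            f"substrate atom percent ({substrate_atom_pct})"
        )
    if sigma_atom_pct <= 0:
        raise InvalidMeasurementError(
            f"sigma_atom_pct must be > 0, got {sigma_atom_pct}"
        )
    return sigma_atom_pct * buffer.amount / (buffer.atom_pct - substrate_atom_pct)
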