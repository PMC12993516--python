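"""End-to-end analysis: measurement table -> rates, electron balance, report.

The report is a plain JSON-able dict; every number in it is produced by one
of the documented operations (label-dilution inversion, rate estimation,
normalization, sulfate accounting, electron balance). Live and autoclaved
microcosms are analyzed identically and reported separately; pooling never
crosses treatment groups.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel

import rsil
from rsil.errors import InsufficientDataError
from rsil.isotopes import (
    VPDB_RATIO,
    IsotopeConstants,
    atom_percent,
    delta_to_atom_fraction,
)
from rsil.mineralization import (
    CarbonPool,
    DeltaMeasurement,
    ProducedCO2Point,
    detection_limit,
    produced_series,
)
from rsil.rates import (
    ENDPOINT,
    PER_G_OIL,
    PER_MOL_CH2,
    PER_OWC_AREA,
    MicrocosmConfig,
    RateEstimate,
    electron_balance,
    estimate_rate,
    mean_replicate_rate,
    normalize_rate,
    oil_consumed_mass,
    sulfate_reduced,
    to_amount_rate,
)

logger = logging.getLogger(__name__)

BASELINE_DAY_ZERO = "day_zero"
BASELINE_FIRST_POINT = "first_point"


class AnalysisOptions(BaseModel):
    """Tuning knobs for :func:`run_analysis`."""

    method: str = ENDPOINT
    phase_break_day: float = 122.0
    baseline: str = BASELINE_DAY_ZERO
    cumulative_pool: bool = False
    sigma_delta: float = 0.5  # permil; used only for control-activity flagging
    r_vpdb: float = VPDB_RATIO


def _as_frame(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
    else:  # sequence of MeasurementRecord (pydantic) or dicts
        df = pd.DataFrame(
            [m.model_dump() if hasattr(m, "model_dump") else dict(m) for m in measurements]
        )
    for col in ("sulfate_mM", "cells_per_ml", "delta13c_permil"):
        if col not in df.columns:
            df[col] = np.nan
    return df.sort_values(["microcosm_id", "day"], kind="mergesort").reset_index(
        drop=True
    )


def _apply_baseline(
    points: list[ProducedCO2Point], baseline: str
) -> list[ProducedCO2Point]:
    """Anchor the series: day 0 is 0 mM by definition (undiluted buffer)."""
    if not points:
        return points
    if baseline == BASELINE_FIRST_POINT:
        offset = points[0].produced_mM
        out = [
            ProducedCO2Point(p.day, p.produced_mM - offset, p.produced_mM - offset < 0)
            for p in points
        ]
        out[0] = ProducedCO2Point(points[0].day, 0.0, False)
        return out
    # day_zero: replace (or insert) the day-0 point with exactly 0 mM
    if points[0].day == 0:
        return [ProducedCO2Point(0.0, 0.0, False)] + points[1:]
    return [ProducedCO2Point(0.0, 0.0, False)] + points


def _rate_row(rate: RateEstimate, treatment: str, basis: str) -> dict:
    return {
        "microcosm_id": rate.replicate_id,
        "treatment": treatment,
        "interval_start_day": rate.interval[0],
        "interval_end_day": rate.interval[1],
        "method": rate.method,
        "basis": basis,
        "value": rate.value,
        "units": rate.units,
        "sd": rate.sd,
        "n": rate.n,
    }


def _rate_dict(rate: RateEstimate) -> dict:
    return {
        "value": rate.value,
        "units": rate.units,
        "interval": list(rate.interval),
        "method": rate.method,
        "replicate_id": rate.replicate_id,
        "sd": rate.sd,
        "n": rate.n,
    }


def run_analysis(
    measurements: Union[pd.DataFrame, Sequence],
    config: Optional[MicrocosmConfig] = None,
    options: Optional[AnalysisOptions] = None,
) -> dict:
    """Run the full pipeline on a measurement table; returns the report dict.

    Per microcosm: delta series -> produced-CO2 series -> per-replicate rates
    over the full interval and the early phase. Per treatment group: pooled
    rates, amount conversion and normalizations (live), sulfate accounting,
    electron balance and oil consumed. Flags record negative produced-CO2
    points, sulfate increases and active controls.
    """
    config = config or MicrocosmConfig()
    options = options or AnalysisOptions()
    constants = IsotopeConstants(r_vpdb=options.r_vpdb)
    df = _as_frame(measurements)

    buffer = CarbonPool(config.buffer_total_co2, config.buffer_atom_pct)
    flags: list[dict] = []
    warnings: list[str] = []
    series_by_mid: dict[str, list[ProducedCO2Point]] = {}
    treatment_by_mid: dict[str, str] = {}

    for mid, grp in df.groupby("microcosm_id", sort=True):
        treatment_by_mid[mid] = str(grp["treatment"].iloc[0])
        deltas = grp.dropna(subset=["delta13c_permil"])
        if deltas.empty:
            continue
        meas = [
            DeltaMeasurement(float(r.day), float(r.delta13c_permil), mid)
            for r in deltas.itertuples()
        ]
        pts = produced_series(
            meas,
            buffer,
            config.substrate_atom_pct,
            constants,
            cumulative_pool=options.cumulative_pool,
        )
        pts = _apply_baseline(pts, options.baseline)
        series_by_mid[mid] = pts
        for p in pts:
            if p.flagged_negative:
                flags.append(
                    {
                        "flag": "negative_produced_co2",
                        "microcosm_id": mid,
                        "day": p.day,
                        "detail": f"produced {p.produced_mM:.4g} mM < 0",
                    }
                )

    rate_rows: list[dict] = []
    pooled: dict[str, dict] = {}
    by_treatment_last: dict[str, list[float]] = {}

    for treatment in ("live", "autoclaved"):
        mids = sorted(
            m for m, t in treatment_by_mid.items() if t == treatment and m in series_by_mid
        )
        usable = [m for m in mids if len(series_by_mid[m]) >= 2]
        if not usable:
            if treatment == "live":
                warnings.append("no live replicates with >= 2 delta-13C timepoints")
            continue
        last_day = max(series_by_mid[m][-1].day for m in usable)
        full_iv = (0.0, float(last_day))
        early_iv = (0.0, float(options.phase_break_day))

        full_rates, early_rates = [], []
        for m in usable:
            r_full = estimate_rate(
                series_by_mid[m], full_iv, options.method, replicate_id=m
            )
            full_rates.append(r_full)
            rate_rows.append(_rate_row(r_full, treatment, "concentration"))
            try:
                r_early = estimate_rate(
                    series_by_mid[m], early_iv, options.method, replicate_id=m
                )
                early_rates.append(r_early)
                rate_rows.append(_rate_row(r_early, treatment, "concentration"))
            except InsufficientDataError:
                logger.debug("no early-phase points for %s", m)
            by_treatment_last.setdefault(treatment, []).append(
                series_by_mid[m][-1].produced_mM
            )

        group: dict = {"replicates": usable}
        pooled_full = mean_replicate_rate(full_rates)
        group["full_rate_mM_yr"] = _rate_dict(pooled_full)
        rate_rows.append(_rate_row(pooled_full, treatment, "concentration"))
        if early_rates:
            pooled_early = mean_replicate_rate(early_rates)
            group["early_rate_mM_yr"] = _rate_dict(pooled_early)
            rate_rows.append(_rate_row(pooled_early, treatment, "concentration"))

        amount = to_amount_rate(pooled_full, config)
        group["full_rate_mmol_yr"] = _rate_dict(amount)
        rate_rows.append(_rate_row(amount, treatment, "amount"))
        for basis in (PER_G_OIL, PER_MOL_CH2, PER_OWC_AREA):
            norm = normalize_rate(amount, config, basis)
            group[f"rate_{basis}"] = _rate_dict(norm)
            rate_rows.append(_rate_row(norm, treatment, basis))
        pooled[treatment] = group

    # Sulfate accounting per replicate, pooled within treatment.
    sulfate_report: dict[str, dict] = {}
    delta_sulfate_live_mM: Optional[float] = None
    for treatment in ("live", "autoclaved"):
        rows = []
        totals, rates, deltas_mM = [], [], []
        for mid, grp in df[df["treatment"] == treatment].groupby("microcosm_id"):
            s = grp.dropna(subset=["sulfate_mM"])
            if len(s) < 2:
                continue
            pairs = list(zip(s["day"].astype(float), s["sulfate_mM"].astype(float)))
            red = sulfate_reduced(pairs, config, replicate_id=str(mid))
            rows.append(
                {
                    "microcosm_id": str(mid),
                    "total_mmol": red.total_mmol,
                    "rate": _rate_dict(red.rate),
                    "increased": red.increased,
                }
            )
            rate_rows.append(_rate_row(red.rate, treatment, "sulfate"))
            totals.append(red.total_mmol)
            rates.append(red.rate.value)
            deltas_mM.append(red.total_mmol / config.aqueous_volume)
            if red.increased:
                flags.append(
                    {
                        "flag": "sulfate_increase",
                        "microcosm_id": str(mid),
                        "day": None,
                        "detail": f"sulfate rose by {-red.total_mmol:.4g} mmol",
                    }
                )
        if rows:
            sulfate_report[treatment] = {
                "replicates": rows,
                "mean_total_mmol": float(np.mean(totals)),
                "mean_rate_mmol_yr": float(np.mean(rates)),
            }
            if treatment == "live":
                delta_sulfate_live_mM = float(np.mean(deltas_mM))

    # Electron balance + oil consumed from pooled live endpoints.
    eb_dict = None
    oil_mg = None
    co2_mM = None
    if by_treatment_last.get("live"):
        co2_mM = float(np.mean(by_treatment_last["live"]))
        total_mmol = co2_mM * config.aqueous_volume
        oil_mg = oil_consumed_mass(max(total_mmol, 0.0), config)
        if delta_sulfate_live_mM is not None:
            eb = electron_balance(
                max(co2_mM, 0.0), max(delta_sulfate_live_mM, 0.0), config
            )
            eb_dict = {
                "donor_electrons_mM": eb.donor_electrons,
                "acceptor_electrons_mM": eb.acceptor_electrons,
                "fraction_to_sulfate": eb.fraction_to_sulfate,
                "fraction_to_biomass": eb.fraction_to_biomass,
                "inconsistent": eb.inconsistent,
                "out_of_range": eb.out_of_range,
            }
            if eb.out_of_range:
                flags.append(
                    {
                        "flag": "electron_balance_out_of_range",
                        "microcosm_id": "pooled",
                        "day": None,
                        "detail": "acceptor electrons exceed donor electrons",
                    }
                )
        else:
            warnings.append("no sulfate data; electron balance skipped")

    # Control-activity flag: cumulative CO2 in a control beyond 3x the
    # detection limit implied by the delta-space noise scale.
    buffer_delta = _buffer_delta(config, constants)
    sigma_pct = abs(
        atom_percent(delta_to_atom_fraction(buffer_delta + options.sigma_delta, constants))
        - config.buffer_atom_pct
    )
    limit = detection_limit(buffer, config.substrate_atom_pct, sigma_pct)
    for mid in sorted(series_by_mid):
        if treatment_by_mid[mid] != "autoclaved":
            continue
        final = series_by_mid[mid][-1].produced_mM
        if final > 3 * limit:
            flags.append(
                {
                    "flag": "control_activity",
                    "microcosm_id": mid,
                    "day": series_by_mid[mid][-1].day,
                    "detail": (
                        f"control produced {final:.4g} mM CO2 "
                        f"(> 3x detection limit {limit:.3g} mM)"
                    ),
                }
            )

    report = {
        "version": rsil.__version__,
        "config": config.model_dump(),
        "options": options.model_dump(),
        "produced_series": {
            mid: [
                {
                    "day": p.day,
                    "produced_mM": p.produced_mM,
                    "flagged_negative": p.flagged_negative,
                }
                for p in pts
            ]
            for mid, pts in sorted(series_by_mid.items())
        },
        "rates": rate_rows,
        "pooled": pooled,
        "sulfate": sulfate_report,
        "electron_balance": eb_dict,
        "co2_evolved_mM": co2_mM,
        "oil_consumed_mg": oil_mg,
        "detection_limit_mM": limit,
        "flags": flags,
        "warnings": warnings,
    }
    return report


def _buffer_delta(config: MicrocosmConfig, constants: IsotopeConstants) -> float:
    from rsil.isotopes import atom_fraction_to_delta

    return atom_fraction_to_delta(config.buffer_atom_pct / 100.0, constants)
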