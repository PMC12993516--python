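"""Synthetic label-dilution microcosm experiments with known ground truth.

The simulator produces the same long-format measurement table the analysis
commands consume, plus a truth sidecar, so the whole pipeline can be
validated end to end without external data. Cumulative CO2 follows a
two-phase piecewise-linear trajectory (a first-order option exists for
robustness tests), sulfate is depleted stoichiometrically with a configurable
biomass electron sink, and measurement noise is Gaussian in delta space —
the instrument domain.

Randomness is drawn from one stream per replicate, derived from the master
seed, so adding replicates never perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from rsil.errors import ConfigurationError, SimulationInfeasibleError
from rsil.isotopes import IsotopeConstants, atom_fraction_to_delta
from rsil.mineralization import CarbonPool, forward_mix
from rsil.rates import DAYS_PER_YEAR, MicrocosmConfig

PIECEWISE = "piecewise"
FIRST_ORDER = "first_order"

# Control-stream offset: keeps control RNG streams disjoint from live ones
# regardless of n_live.
_CONTROL_STREAM_OFFSET = 10_000

# Cell-count fixture trajectory (no growth model is fitted downstream).
_CELLS_LIVE_START = 4.0e5
_CELLS_LIVE_END = 1.4e6
_CELLS_CONTROL = 1.8e5
_CELLS_LOGISTIC_RATE = 0.05  # 1/day


class SimulationParams(BaseModel):
    """Knobs of the synthetic experiment.

    ``late_rate=None`` derives the post-break rate so that the cumulative
    CO2 at the last scheduled day equals ``total_at_end``.
    """

    n_live: int = 4
    n_control: int = 2
    schedule: list[float] = [0.0, 30.0, 60.0, 91.0, 122.0, 857.0]
    early_rate: float = 17.6  # mM/yr before phase_break
    phase_break: float = 122.0  # day
    late_rate: Optional[float] = None  # mM/yr after phase_break
    total_at_end: float = 8.3  # mM, used only when late_rate is None
    replicate_cv: float = 0.1
    sigma_delta: float = 0.5  # permil
    biomass_fraction: float = 0.12
    sulfate_initial: float = 20.6  # mM
    control_rate: float = 0.0  # mM/yr
    kinetics: str = PIECEWISE
    first_order_cmax: Optional[float] = None  # mM, defaults to total_at_end
    emit_cells: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationParams":
        sched = self.schedule
        if not sched or sched[0] != 0:
            raise ConfigurationError("schedule must start at day 0")
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ConfigurationError("schedule must be strictly increasing")
        if self.early_rate < 0 or self.control_rate < 0:
            raise ConfigurationError("rates must be >= 0")
        if self.late_rate is not None and self.late_rate < 0:
            raise ConfigurationError("late_rate must be >= 0")
        if not 0 <= self.biomass_fraction <= 1:
            raise ConfigurationError("biomass_fraction must lie in [0, 1]")
        if self.replicate_cv < 0 or self.sigma_delta < 0:
            raise ConfigurationError("dispersion parameters must be >= 0")
        if self.kinetics not in (PIECEWISE, FIRST_ORDER):
            raise ConfigurationError(f"unknown kinetics {self.kinetics!r}")
        return self

    def resolved_late_rate(self) -> float:
        """Late-phase rate, derived from ``total_at_end`` when unset."""
        if self.late_rate is not None:
            return self.late_rate
        end = self.schedule[-1]
        if end <= self.phase_break:
            return 0.0
        early_total = self.early_rate * self.phase_break / DAYS_PER_YEAR
        late = (
            (self.total_at_end - early_total)
            * DAYS_PER_YEAR
            / (end - self.phase_break)
        )
        if late < 0:
            raise ConfigurationError(
                "total_at_end is below the early-phase cumulative CO2; "
                "late_rate would be negative"
            )
        return late


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated experiment.

    ``replicates`` maps microcosm id to its true early/late rates (mM/yr)
    and multiplier; ``table`` holds per-(microcosm, day) true cumulative CO2,
    sulfate and noise-free delta-13C.
    """

    replicates: dict
    table: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "replicates": self.replicates,
            "table": self.table.to_dict(orient="records"),
        }


def _cumulative_co2(
    t: np.ndarray, base_rate: float, late_rate: float, params: SimulationParams
) -> np.ndarray:
    if params.kinetics == FIRST_ORDER:
        cmax = params.first_order_cmax or params.total_at_end
        if cmax <= 0:
            return np.zeros_like(t)
        k = base_rate / DAYS_PER_YEAR / cmax  # matches initial slope
        return cmax * (1.0 - np.exp(-k * t))
    per_day_early = base_rate / DAYS_PER_YEAR
    per_day_late = late_rate / DAYS_PER_YEAR
    early = np.minimum(t, params.phase_break) * per_day_early
    late = np.maximum(t - params.phase_break, 0.0) * per_day_late
    return early + late


def _replicate_rows(
    mid: str,
    treatment: str,
    rng: np.random.Generator,
    early: float,
    late: float,
    params: SimulationParams,
    config: MicrocosmConfig,
    constants: IsotopeConstants,
) -> tuple[list[dict], list[dict], dict]:
    days = np.asarray(params.schedule, dtype=float)
    mult = max(0.0, 1.0 + params.replicate_cv * rng.standard_normal())
    cum = _cumulative_co2(days, early * mult, late * mult, params)

    sink = (1.0 - params.biomass_fraction) * (
        config.electrons_per_carbon / config.electrons_per_sulfate
    )
    sulfate = params.sulfate_initial - sink * cum
    if np.any(sulfate < 0):
        bad_day = days[np.argmax(sulfate < 0)]
        raise SimulationInfeasibleError(
            f"sulfate would become negative at day {bad_day:g} in {mid}"
        )

    buffer = CarbonPool(config.buffer_total_co2, config.buffer_atom_pct)
    true_pct = np.array(
        [forward_mix(buffer, p, config.substrate_atom_pct) for p in cum]
    )
    true_delta = np.array(
        [atom_fraction_to_delta(pct / 100.0, constants) for pct in true_pct]
    )
    noise = rng.normal(0.0, params.sigma_delta, size=days.size)
    observed_delta = true_delta + noise

    if treatment == "live":
        frac = 1.0 - np.exp(-_CELLS_LOGISTIC_RATE * days)
        cells = _CELLS_LIVE_START + (_CELLS_LIVE_END - _CELLS_LIVE_START) * frac
    else:
        cells = np.full(days.size, _CELLS_CONTROL)

    rows = []
    truth_rows = []
    for i, day in enumerate(days):
        rows.append(
            {
                "day": day,
                "microcosm_id": mid,
                "treatment": treatment,
                "delta13c_permil": observed_delta[i],
                "sulfate_mM": sulfate[i],
                "cells_per_ml": cells[i] if params.emit_cells else None,
            }
        )
        truth_rows.append(
            {
                "microcosm_id": mid,
                "day": day,
                "cum_co2_mM": cum[i],
                "sulfate_mM": sulfate[i],
                "delta13c_true_permil": true_delta[i],
            }
        )
    rep_truth = {
        "treatment": treatment,
        "multiplier": mult,
        "early_rate_mM_yr": early * mult,
        "late_rate_mM_yr": late * mult,
    }
    return rows, truth_rows, rep_truth


def simulate(
    params: SimulationParams,
    config: Optional[MicrocosmConfig] = None,
    constants: IsotopeConstants = IsotopeConstants(),
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate one experiment; returns (measurement table, truth).

    The measurement table uses the same schema the analysis reads:
    day, microcosm_id, treatment, delta13c_permil, sulfate_mM, cells_per_ml.
    Identical parameters (including seed) give identical output.
    """
    config = config or MicrocosmConfig()
    late = params.resolved_late_rate()
    rows: list[dict] = []
    truth_rows: list[dict] = []
    replicates: dict = {}

    for i in range(params.n_live):
        mid = f"live_{i + 1}"
        rng = np.random.default_rng([params.seed, i])
        r, tr, rep = _replicate_rows(
            mid, "live", rng, params.early_rate, late, params, config, constants
        )
        rows += r
        truth_rows += tr
        replicates[mid] = rep

    for j in range(params.n_control):
        mid = f"ctrl_{j + 1}"
        rng = np.random.default_rng([params.seed, _CONTROL_STREAM_OFFSET + j])
        r, tr, rep = _replicate_rows(
            mid,
            "autoclaved",
            rng,
            params.control_rate,
            params.control_rate,
            params,
            config,
            constants,
        )
        rows += r
        truth_rows += tr
        replicates[mid] = rep

    table = pd.DataFrame(
        rows,
        columns=[
            "day",
            "microcosm_id",
            "treatment",
            "delta13c_permil",
            "sulfate_mM",
            "cells_per_ml",
        ],
    )
    truth = SimulationTruth(
        replicates=replicates, table=pd.DataFrame(truth_rows)
    )
    return table, truth


def parameter_recovery_trial(
    params: SimulationParams,
    config: Optional[MicrocosmConfig] = None,
    n_seeds: int = 1,
) -> dict:
    """Simulate + analyze across seeds; summarize estimator quality.

    For each seed the full analysis pipeline is run on the simulated table
    and the pooled live early rate and electron-balance split are compared
    with the configured truth. Returns bias/RMSE summaries.
    """
    from rsil.analysis import AnalysisOptions, run_analysis

    if n_seeds < 1:
        raise ConfigurationError(f"n_seeds must be >= 1, got {n_seeds}")
    config = config or MicrocosmConfig()
    options = AnalysisOptions(phase_break_day=params.phase_break)
    est_rates = np.empty(n_seeds)
    frac_sulfate = np.full(n_seeds, np.nan)
    for i in range(n_seeds):
        p = params.model_copy(update={"seed": params.seed + i})
        table, _ = simulate(p, config)
        report = run_analysis(table, config, options)
        est_rates[i] = report["pooled"]["live"]["early_rate_mM_yr"]["value"]
        eb = report.get("electron_balance")
        if eb is not None:
            frac_sulfate[i] = eb["fraction_to_sulfate"]

    true_rate = params.early_rate
    bias = float(np.mean(est_rates) - true_rate)
    rmse = float(np.sqrt(np.mean((est_rates - true_rate) ** 2)))
    return {
        "n_seeds": n_seeds,
        "true_early_rate_mM_yr": true_rate,
        "mean_estimated_rate_mM_yr": float(np.mean(est_rates)),
        "bias_mM_yr": bias,
        "relative_bias": bias / true_rate if true_rate else math.nan,
        "rmse_mM_yr": rmse,
        "mean_fraction_to_sulfate": float(np.nanmean(frac_sulfate)),
        "expected_fraction_to_sulfate": 1.0 - params.biomass_fraction,
        "estimated_rates_mM_yr": est_rates.tolist(),
    }
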