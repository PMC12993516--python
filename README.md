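# rsil

Analysis pipeline for **reverse stable isotope labelling (RSIL)** microcosm
experiments. In RSIL, the dissolved inorganic carbon (DIC) buffer is enriched
in ¹³C (≈10 atom%) so that mineralization of a substrate at natural ¹³C
abundance dilutes the label; the decline in δ¹³C of the DIC quantifies the
CO₂ produced from the substrate.

The package provides:

- **`rsil.isotopes`** — exact, invertible arithmetic between δ¹³C (‰ vs
  VPDB), isotope ratios and ¹³C atom fractions / atom percent.
- **`rsil.mineralization`** — the forward two-pool label-dilution model and
  its closed-form inversion from measured atom percent to produced CO₂,
  plus a detection-limit diagnostic.
- **`rsil.rates`** — endpoint / OLS rate estimation from time series,
  replicate pooling, unit conversion (mM/yr → mmol/yr) and normalization
  per gram of oil, per mole of CH₂ and per oil–water-contact (OWC) area;
  sulfate accounting and the donor/acceptor electron balance
  (6 e⁻ per CH₂ carbon oxidized, 8 e⁻ per sulfate reduced).
- **`rsil.simulate`** — a synthetic-microcosm generator with known ground
  truth (two-phase kinetics, stoichiometrically coupled sulfate depletion,
  configurable biomass electron sink, Gaussian δ-space noise) and a
  Monte-Carlo parameter-recovery harness.
- **`rsil.analysis` / `rsil.cli`** — the end-to-end pipeline: long-format
  measurement CSV in, JSON report and tidy rate/flag CSVs out.

## CLI

```sh
# simulate a synthetic experiment (4 live + 2 autoclaved replicates)
rsil simulate --seed 1 --out measurements.csv --truth-out truth.json

# analyze a measurement CSV
rsil analyze measurements.csv --out report.json

# human-readable summary
rsil report report.json
```

`analyze` writes `report.json` (sorted keys, config + version embedded for
provenance) plus `rates.csv` (`microcosm_id, treatment, interval_start_day,
interval_end_day, method, basis, value, units`) and `flags.csv` (negative
produced-CO₂ points, sulfate increases, active controls). Logging goes to
stderr; use `--log-level INFO` for progress messages.

### Input schema

Long-format CSV, UTF-8, `.` decimal, one row per (day, microcosm) with
columns `day, microcosm_id, treatment, delta13c_permil, sulfate_mM,
cells_per_ml`. `treatment` is `live` or `autoclaved`; the three measurement
columns are nullable but at least one must be populated per row. Unknown
columns are rejected with `--strict`, warned about otherwise.

### Configuration

A flat YAML/JSON file passed via `--config` overrides any experiment
constant or simulation parameter, e.g.:

```yaml
oil_mass: 0.33        # g
buffer_total_co2: 7.58  # mM
buffer_atom_pct: 10.0
substrate_atom_pct: 1.075
sigma_delta: 0.5      # permil, simulation noise
n_live: 4
```

Defaults describe a 120 mL serum-bottle incubation: 100 mL aqueous phase,
one 0.33 g oil drop, 7.58 mM buffer DIC at 10 atom% ¹³C, substrate at
1.075 atom%, 16.61 cm² OWC area, 20.6 mM initial sulfate, sampling at days
0, 30, 60, 91, 122 and 857.

## Notes on arithmetic choices

- δ¹³C is converted with `x = R′/(1+R′)`, `R′ = (δ/1000 + 1) · R_VPDB`,
  `R_VPDB = 0.0111802` (configurable).
- The buffer DIC pool is held constant during inversion (the default
  matches the published calculation); a cumulative-pool mode is available.
- Negative produced-CO₂ values (noise pushing δ above the buffer signature)
  are flagged and retained, never clipped, to keep rate estimates unbiased.
- Rates are annualized with a 365-day year; the endpoint method is the
  default, OLS is available for noisy series.
- Day-0 produced CO₂ is anchored at 0 mM by definition (undiluted buffer);
  an optional first-point baseline subtraction exists for series that do
  not start at day 0.
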