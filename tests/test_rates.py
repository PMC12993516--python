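import math

import pytest

from rsil.errors import (
    ConfigurationError,
    InsufficientDataError,
    UnitMismatchError,
)
from rsil.mineralization import ProducedCO2Point
from rsil.rates import (
    ENDPOINT,
    OLS,
    PER_G_OIL,
    PER_MOL_CH2,
    PER_OWC_AREA,
    UNIT_MM_PER_YR,
    UNIT_MMOL_PER_YR,
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


def pts(*pairs):
    return [ProducedCO2Point(d, v, v < 0) for d, v in pairs]


def mk_rate(value, units=UNIT_MM_PER_YR, interval=(0.0, 857.0)):
    return RateEstimate(value=value, units=units, interval=interval, method=ENDPOINT)


class TestEstimateRate:
    def test_endpoint_full_incubation(self):
        r = estimate_rate(pts((0, 0.0), (857, 8.31)), (0, 857), ENDPOINT)
        assert r.value == pytest.approx(8.31 / 857 * 365, rel=1e-12)  # 3.539

    def test_flat_series(self):
        r = estimate_rate(pts((0, 1.0), (100, 1.0)), (0, 100))
        assert r.value == 0.0

    def test_ols_recovers_slope(self):
        series = pts(*[(d, 0.05 * d) for d in (0, 10, 50, 100)])
        r = estimate_rate(series, (0, 100), OLS)
        assert r.value == pytest.approx(18.25, rel=1e-10)

    def test_endpoint_equals_ols_on_noiseless_line(self):
        series = pts(*[(d, 0.02 * d + 1.0) for d in (0, 30, 60, 122)])
        e = estimate_rate(series, (0, 122), ENDPOINT)
        o = estimate_rate(series, (0, 122), OLS)
        assert e.value == pytest.approx(o.value, rel=1e-10)

    def test_interval_filtering(self):
        series = pts((0, 0.0), (122, 6.0), (857, 8.3))
        r = estimate_rate(series, (0, 122))
        assert r.value == pytest.approx(6.0 / 122 * 365, rel=1e-12)

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            estimate_rate(pts((0, 0.0)), (0, 100))

    def test_unknown_method(self):
        with pytest.raises(ConfigurationError):
            estimate_rate(pts((0, 0.0), (1, 1.0)), (0, 1), "spline")


class TestMeanReplicateRate:
    def test_four_replicates(self):
        rates = [mk_rate(v) for v in (18.17, 15.27, 19.29, 17.61)]
        pooled = mean_replicate_rate(rates)
        assert pooled.value == pytest.approx(17.585, rel=1e-12)
        assert pooled.replicate_id == "pooled"
        assert pooled.sd > 0 and pooled.n == 4

    def test_single_element(self):
        pooled = mean_replicate_rate([mk_rate(5.0)])
        assert pooled.value == 5.0
        assert pooled.sd == 0.0

    def test_two_elements(self):
        assert mean_replicate_rate([mk_rate(1.0), mk_rate(3.0)]).value == 2.0

    def test_mixed_units_rejected(self):
        with pytest.raises(UnitMismatchError):
            mean_replicate_rate([mk_rate(1.0), mk_rate(1.0, UNIT_MMOL_PER_YR)])

    def test_mixed_intervals_rejected(self):
        with pytest.raises(UnitMismatchError):
            mean_replicate_rate([mk_rate(1.0), mk_rate(1.0, interval=(0.0, 122.0))])

    def test_empty(self):
        with pytest.raises(InsufficientDataError):
            mean_replicate_rate([])


class TestUnitConversions:
    def test_to_amount(self, config):
        r = to_amount_rate(mk_rate(8.31 / 857 * 365), config)
        assert r.value == pytest.approx(0.35392, abs=5e-5)
        assert r.units == UNIT_MMOL_PER_YR

    def test_to_amount_zero(self, config):
        assert to_amount_rate(mk_rate(0.0), config).value == 0.0

    def test_to_amount_hand_value(self, config):
        assert to_amount_rate(mk_rate(17.6), config).value == pytest.approx(1.76)

    def test_to_amount_wrong_units(self, config):
        with pytest.raises(UnitMismatchError):
            to_amount_rate(mk_rate(1.0, UNIT_MMOL_PER_YR), config)

    def test_per_g_oil(self, config):
        r = normalize_rate(mk_rate(0.35, UNIT_MMOL_PER_YR), config, PER_G_OIL)
        assert r.value == pytest.approx(1.061, abs=5e-4)

    def test_per_mol_ch2(self, config):
        r = normalize_rate(mk_rate(0.35, UNIT_MMOL_PER_YR), config, PER_MOL_CH2)
        assert r.value == pytest.approx(0.35 / (0.33 / 14.0266), rel=1e-12)
        assert r.value == pytest.approx(14.88, abs=5e-3)

    def test_per_owc_area(self, config):
        r = normalize_rate(mk_rate(0.354, UNIT_MMOL_PER_YR), config, PER_OWC_AREA)
        assert r.value == pytest.approx(0.354 * 14.0266 / 1000 / 16.61e-4, rel=1e-12)
        assert r.value == pytest.approx(2.99, abs=5e-3)

    def test_normalize_wrong_units(self, config):
        with pytest.raises(UnitMismatchError):
            normalize_rate(mk_rate(1.0), config, PER_G_OIL)

    def test_unknown_basis(self, config):
        with pytest.raises(ConfigurationError):
            normalize_rate(mk_rate(1.0, UNIT_MMOL_PER_YR), config, "per_parsec")

    def test_unit_algebra_closes(self, config):
        amount = mk_rate(0.4321, UNIT_MMOL_PER_YR)
        per_g = normalize_rate(amount, config, PER_G_OIL)
        per_mol = normalize_rate(amount, config, PER_MOL_CH2)
        assert per_g.value * config.oil_mass == pytest.approx(
            amount.value, rel=1e-12
        )
        assert per_mol.value * (config.oil_mass / config.ch2_molar_mass) == (
            pytest.approx(amount.value, rel=1e-12)
        )


class TestSulfate:
    def test_total_reduced(self, config):
        red = sulfate_reduced([(0, 20.6), (857, 15.2)], config)
        assert red.total_mmol == pytest.approx(0.54, rel=1e-12)
        assert not red.increased

    def test_rate(self, config):
        red = sulfate_reduced([(0, 20.6), (857, 15.2)], config)
        assert red.rate.value == pytest.approx(0.54 / 857 * 365, rel=1e-12)  # 0.230

    def test_no_change(self, config):
        red = sulfate_reduced([(0, 20.6), (857, 20.6)], config)
        assert red.total_mmol == 0.0

    def test_increase_flagged_not_raised(self, config):
        red = sulfate_reduced([(0, 15.0), (857, 16.0)], config)
        assert red.increased
        assert red.total_mmol < 0

    def test_insufficient(self, config):
        with pytest.raises(InsufficientDataError):
            sulfate_reduced([(0, 20.6)], config)


class TestElectronBalance:
    def test_experiment_scale_inputs(self, config):
        # transparent arithmetic: (5.4*8)/(8.3*6)
        eb = electron_balance(8.3, 5.4, config)
        assert eb.fraction_to_sulfate == pytest.approx(0.867, abs=5e-4)
        assert eb.fraction_to_biomass == pytest.approx(1 - 43.2 / 49.8, rel=1e-12)

    def test_no_sulfate(self, config):
        assert electron_balance(8.0, 0.0, config).fraction_to_sulfate == 0.0

    def test_exact_balance(self, config):
        eb = electron_balance(8.0, 6.0, config)
        assert eb.fraction_to_sulfate == 1.0
        assert not eb.out_of_range

    def test_fractions_sum_to_one(self, config):
        for co2, so4 in [(8.3, 5.4), (1.0, 0.2), (0.5, 0.5)]:
            eb = electron_balance(co2, so4, config)
            assert eb.fraction_to_sulfate + eb.fraction_to_biomass == 1.0

    def test_inconsistent_flag(self, config):
        eb = electron_balance(0.0, 1.0, config)
        assert eb.inconsistent
        assert math.isnan(eb.fraction_to_sulfate)

    def test_out_of_range_flag(self, config):
        assert electron_balance(1.0, 6.0, config).out_of_range

    def test_negative_rejected(self, config):
        with pytest.raises(ConfigurationError):
            electron_balance(-1.0, 0.0, config)


class TestOilConsumed:
    def test_cumulative(self, config):
        assert oil_consumed_mass(0.83, config) == pytest.approx(11.64, abs=5e-3)

    def test_zero(self, config):
        assert oil_consumed_mass(0.0, config) == 0.0

    def test_molar_mass(self, config):
        assert oil_consumed_mass(1.0, config) == pytest.approx(14.0266, rel=1e-12)

    def test_negative_rejected(self, config):
        with pytest.raises(ConfigurationError):
            oil_consumed_mass(-0.1, config)


class TestMicrocosmConfig:
    def test_defaults(self, config):
        assert config.aqueous_volume == 0.100
        assert config.buffer_total_co2 == 7.58
        assert config.substrate_atom_pct == 1.075

    @pytest.mark.parametrize(
        "field", ["aqueous_volume", "oil_mass", "owc_area", "ch2_molar_mass"]
    )
    def test_positive_required(self, field):
        with pytest.raises((ConfigurationError, ValueError)):
            MicrocosmConfig(**{field: 0.0})

    def test_label_must_exceed_substrate(self):
        with pytest.raises((ConfigurationError, ValueError)):
            MicrocosmConfig(buffer_atom_pct=1.0, substrate_atom_pct=1.075)

    def test_bad_rate_units(self):
        with pytest.raises(UnitMismatchError):
            RateEstimate(1.0, "furlongs/fortnight", (0.0, 1.0), ENDPOINT)

    def test_bad_interval(self):
        with pytest.raises(ConfigurationError):
            RateEstimate(1.0, UNIT_MM_PER_YR, (5.0, 5.0), ENDPOINT)
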