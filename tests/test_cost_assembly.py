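"""Micro-costing rules: unit values, truncation at retirement, method ordering."""

import pytest
from hypothesis import given, strategies as st

import strokeburden as sb
from strokeburden.cost_assembly import assemble_annual_cost, training_cost_2008


def wages(**kw):
    defaults = dict(
        annual_wage_by_gender_age={
            sb.GenderAgeBandKey(sb.Gender(g), b): (24000.0 if b < 65 else 0.0)
            for g in ("male", "female")
            for b in sb.BANDS
        }
    )
    defaults.update(kw)
    return sb.WageInputs(**defaults)


class TestUninsured:
    def test_inverts_proportion_of_total(self):
        # f of total => uninsured = insured * f/(1-f) per setting
        assert sb.uninsured_cost(705, 848) == pytest.approx(295 + 152)
        assert sb.uninsured_cost(1000, 0) == pytest.approx(418.4, abs=0.1)
        assert sb.uninsured_cost(0, 0) == 0


class TestCaregiverAndTransport:
    def test_inpatient_days_at_daily_wage(self):
        profile = sb.UtilizationProfile(inpatient_days=10)
        assert sb.caregiver_cost(profile, wages(), 50) == pytest.approx(568.09)

    def test_outpatient_third_of_day(self):
        profile = sb.UtilizationProfile(outpatient_visits=3)
        assert sb.caregiver_cost(profile, wages(), 50) == pytest.approx(56.809)

    def test_companion_transport_only_past_65(self):
        profile = sb.UtilizationProfile(admissions=1, outpatient_visits=2)
        young = sb.caregiver_cost(profile, wages(), 50)
        old = sb.caregiver_cost(profile, wages(), 70)
        assert old - young == pytest.approx(2.896 + 2 * 0.891)

    def test_transport_unit_values(self):
        assert sb.transport_cost(sb.UtilizationProfile(), wages()) == 0
        assert sb.transport_cost(
            sb.UtilizationProfile(outpatient_visits=10, admissions=1), wages()
        ) == pytest.approx(11.806)
        assert sb.transport_cost(
            sb.UtilizationProfile(outpatient_visits=1), wages()
        ) == pytest.approx(0.891)


class TestOutOfPocket:
    @pytest.mark.parametrize("oop,ratio,expect", [(1000, 0.13, 130), (0, 0.2, 0), (1000, 0.38, 380)])
    def test_second_year_ratio(self, oop, ratio, expect):
        assert sb.second_year_out_of_pocket(oop, ratio) == pytest.approx(expect)

    def test_ratio_outside_published_range(self):
        with pytest.raises(ValueError):
            sb.second_year_out_of_pocket(1000, 0.5)


class TestHumanCapital:
    def test_zero_at_retirement(self, life_table):
        assert sb.human_capital_premature_cost("male", 65, life_table, wages()) == 0
        assert sb.human_capital_premature_cost("male", 70, life_table, wages()) == 0

    def test_flat_wage_counts_working_years(self, life_table):
        # death at 45, PYLL 32.16 -> earnings years 45..64 inclusive
        got = sb.human_capital_premature_cost("male", 45, life_table, wages())
        assert got == pytest.approx(20 * 24000.0)

    def test_truncation_at_retirement(self, life_table):
        got = sb.human_capital_premature_cost("male", 63, life_table, wages())
        assert got == pytest.approx(2 * 24000.0)

    def test_short_pyll_limits_horizon(self):
        life = sb.GeneralPopulationLifeTable(
            values={(sb.Gender.male, b): le for b, le in zip(sb.BANDS, (2.5, 2.0, 1.5, 1.0, 0.5))}
        )
        got = sb.human_capital_premature_cost("male", 45, life, wages())
        assert got == pytest.approx(2.5 * 24000.0)  # fractional final year pro rata

    def test_missing_wage_band_is_configuration_error(self, life_table):
        with pytest.raises(KeyError):
            sb.human_capital_premature_cost(
                "male", 45, life_table, sb.WageInputs(annual_wage_by_gender_age={})
            )


class TestAbsenteeismAndFriction:
    def test_absenteeism(self):
        w = wages()
        assert sb.absenteeism_cost(5, 0, w, 40) == pytest.approx(284.045)
        assert sb.absenteeism_cost(5, 8, w, 70) == 0
        assert sb.absenteeism_cost(0, 8, w, 40) == pytest.approx(56.809)  # 8h at daily/8

    def test_training_component(self, config):
        assert training_cost_2008(config) == pytest.approx(362 * 1.293 * 1.2, abs=0.01)

    def test_friction_half_year_wage_plus_training(self, config):
        got = sb.friction_premature_cost("male", 45, wages(), config)
        assert got == pytest.approx(12000.0 + 561.7, abs=0.1)
        assert sb.friction_premature_cost("male", 65, wages(), config) == 0

    @given(wage=st.floats(1000, 500000), age=st.integers(45, 64))
    def test_friction_never_exceeds_human_capital(self, life_table, config, wage, age):
        w = wages(
            annual_wage_by_gender_age={
                sb.GenderAgeBandKey(sb.Gender(g), b): wage
                for g in ("male", "female")
                for b in sb.BANDS
            }
        )
        hc = sb.human_capital_premature_cost("male", age, life_table, w)
        fr = sb.friction_premature_cost("male", age, w, config)
        # holds whenever at least one working year remains and training cost
        # is small next to a year's wage
        assert fr <= hc + sb.cost_assembly.training_cost_2008(config)


class TestHomogeneity:
    def test_degree_one_in_monetary_inputs(self):
        profile = sb.UtilizationProfile(
            inpatient_days=12,
            admissions=2,
            outpatient_visits=20,
            insured_cost_inpatient=4000,
            insured_cost_outpatient=1500,
            out_of_pocket_outside_first_year=800,
        )
        w1 = wages()
        lam = 3.0
        w2 = sb.WageInputs(
            daily_wage_caregiver=w1.daily_wage_caregiver * lam,
            transport_outpatient=w1.transport_outpatient * lam,
            transport_admission=w1.transport_admission * lam,
            annual_wage_by_gender_age={k: v * lam for k, v in w1.annual_wage_by_gender_age.items()},
            second_year_oop_ratio=w1.second_year_oop_ratio,
        )
        scaled_profile = sb.UtilizationProfile(
            inpatient_days=12,
            admissions=2,
            outpatient_visits=20,
            insured_cost_inpatient=4000 * lam,
            insured_cost_outpatient=1500 * lam,
            out_of_pocket_outside_first_year=800 * lam,
        )
        base = assemble_annual_cost(profile, w1, 70)
        scaled = assemble_annual_cost(scaled_profile, w2, 70)
        for name, value in base.items():
            assert scaled[name] == pytest.approx(lam * value, rel=1e-12)


class TestFrictionCostTable:
    def test_replaces_only_premature_costs(self, cost_table, config):
        table = sb.friction_cost_table(cost_table, wages(), config)
        for k, base in cost_table.items():
            new = table[k]
            assert new.cost_first_year == base.cost_first_year
            assert new.cost_fatal == base.cost_fatal
            if k.band >= 65:
                assert new.cost_premature_death == 0
            else:
                assert new.cost_premature_death == pytest.approx(12000.0 + 561.7, abs=0.1)
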