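"""Lexis-diagonal hazard integration, inversion and rate-table IO."""

import numpy as np
import pytest

from lexisurv.errors import RateRangeError, SaturationError, ValidationError
from lexisurv.rates import (
    LexisPosition,
    RateTable,
    read_rate_table,
    write_rate_table,
)

from _oracles import riemann_cumulative_hazard
from conftest import make_table, pos


class TestCumulativeHazard:
    def test_constant_hazard_is_linear(self, const_table):
        assert const_table.cumulative_hazard(pos(age=44.3, year=1966.5), 10.0) == pytest.approx(0.1)
        assert const_table.cumulative_hazard(pos(), 0.0) == 0.0

    def test_piecewise_age_boundary_split(self, piecewise_table):
        # entry at exact age 48: two years in the 0.01 band, three in 0.02
        lam = piecewise_table.cumulative_hazard(pos(age=48.0), 5.0)
        assert lam == pytest.approx(0.01 * 2 + 0.02 * 3, abs=1e-12)

    def test_expected_survival(self, const_table, piecewise_table):
        assert const_table.expected_survival(pos(), 10.0) == pytest.approx(np.exp(-0.1))
        assert const_table.expected_survival(pos(), 0.0) == 1.0
        assert piecewise_table.expected_survival(pos(age=48.0), 5.0) == pytest.approx(np.exp(-0.08))

    def test_matches_riemann_oracle_on_random_queries(self, random_table):
        rng = np.random.default_rng(5)
        for _ in range(100):
            sex = "male" if rng.random() < 0.5 else "female"
            a0 = rng.uniform(15, 70)
            y0 = rng.uniform(1966, 1995)
            t = rng.uniform(0.1, 12.0)
            got = random_table.cumulative_hazard(LexisPosition(sex, a0, y0), t)
            want = riemann_cumulative_hazard(random_table, sex, a0, y0, t)
            assert got == pytest.approx(want, rel=1e-6)

    def test_additivity_along_the_diagonal(self, random_table):
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = LexisPosition("female", rng.uniform(20, 60), rng.uniform(1967, 1990))
            t1, t2 = rng.uniform(0.1, 8.0, size=2)
            whole = random_table.cumulative_hazard(p, t1 + t2)
            split = random_table.cumulative_hazard(p, t1) + random_table.cumulative_hazard(
                p.advanced(t1), t2
            )
            assert abs(whole - split) < 1e-10

    def test_vectorised_times(self, const_table):
        t = np.array([0.0, 1.0, 5.0, 10.0])
        np.testing.assert_allclose(const_table.cumulative_hazard(pos(), t), 0.01 * t)

    def test_negative_time_rejected(self, const_table):
        with pytest.raises(ValidationError):
            const_table.cumulative_hazard(pos(), -1.0)


class TestInversion:
    def test_exponential_median(self):
        table = make_table(0.02)
        t = table.invert_cumulative_hazard(pos(age=30.0), np.log(2))
        assert t == pytest.approx(np.log(2) / 0.02, rel=1e-9)

    def test_zero_maps_to_zero(self, const_table):
        assert const_table.invert_cumulative_hazard(pos(), 0.0) == 0.0

    def test_round_trips(self, piecewise_table, random_table):
        rng = np.random.default_rng(7)
        for table in (piecewise_table, random_table):
            p = pos(age=41.7, year=1968.2)
            zmax = table.cumulative_hazard(p, 40.0)
            z = rng.uniform(0, zmax, size=20)
            t = table.invert_cumulative_hazard(p, z)
            np.testing.assert_allclose(table.cumulative_hazard(p, t), z, atol=1e-9)
            # forward then back
            tt = rng.uniform(0, 40, size=20)
            z2 = table.cumulative_hazard(p, tt)
            np.testing.assert_allclose(table.invert_cumulative_hazard(p, z2), tt, atol=1e-8)

    def test_monotone_in_z(self, random_table):
        p = pos(age=35.0)
        z = np.linspace(0.01, 1.0, 25)
        t = random_table.invert_cumulative_hazard(p, z)
        assert np.all(np.diff(t) > 0)

    def test_saturation_beyond_ceiling(self, const_table):
        # hazard 0.01/yr up to the age cap: Lambda cannot exceed ~(cap-age)*max
        with pytest.raises(SaturationError):
            const_table.invert_cumulative_hazard(pos(age=80.0), 1e6)


class TestExtrapolation:
    def test_range_error_names_missing_cell(self, const_table):
        strict = const_table.with_policy(extrapolate=False)
        with pytest.raises(RateRangeError) as err:
            strict.cumulative_hazard(pos(age=40.0, year=2006.5), 5.0)
        assert "2008" in str(err.value)

    def test_calendar_years_clamp_to_edge_columns(self):
        # rates fall by year; before the first year the first column is reused
        table = make_table(lambda a, y: 0.02 - 0.0001 * (y - 1966))
        lam_pre = table.cumulative_hazard(pos(age=40.0, year=1950.0), 1.0)
        lam_first = table.cumulative_hazard(pos(age=40.0, year=1966.0), 1.0)
        assert lam_pre == pytest.approx(lam_first)
        lam_post = table.cumulative_hazard(pos(age=40.0, year=2030.0), 1.0)
        lam_last = table.cumulative_hazard(pos(age=40.0, year=2007.0), 1.0)
        assert lam_post == pytest.approx(lam_last)

    def test_gompertz_tail_continues_log_linear_growth(self):
        table = make_table(lambda a, y: 1e-5 * np.exp(0.09 * a))
        ext = table._extended("male")
        # the extension continues exp growth until the 1.0/yr cap
        ratios = ext[101:110, 0] / ext[100:109, 0]
        uncapped = ext[101:110, 0] < 1.0
        np.testing.assert_allclose(ratios[uncapped], np.exp(0.09), rtol=1e-3)
        assert ext.max() <= 1.0

    def test_age_rule_applies_above_grid(self):
        table = make_table(0.01, ages=(0, 89))
        lam = table.cumulative_hazard(pos(age=88.0), 4.0)
        assert lam > 0.04 * 0.9  # flat Gompertz fit keeps ~0.01


class TestValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            make_table(-0.01)

    def test_axis_gap_rejected(self):
        a = np.array([0, 1, 3])
        y = np.array([1966, 1967])
        with pytest.raises(ValidationError):
            RateTable({"male": np.full((3, 2), 0.01)}, a, y)


class TestIO:
    def test_round_trip(self, tmp_path):
        table = make_table(lambda a, y: 0.001 + 0.0001 * a + 1e-5 * (y - 1966),
                           ages=(40, 42), years=(1966, 1967))
        path = tmp_path / "rates.csv"
        write_rate_table(table, path)
        back = read_rate_table(path)
        assert back.cause == table.cause
        for sex in table.sexes:
            np.testing.assert_array_equal(back.rates[sex], table.rates[sex])
        np.testing.assert_array_equal(back.ages, table.ages)
        np.testing.assert_array_equal(back.years, table.years)

    def test_negative_rate_cites_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("[male]\nage,1966,1967\n40,0.01,0.02\n41,-0.5,0.02\n")
        with pytest.raises(ValidationError) as err:
            read_rate_table(path)
        assert ":4:" in str(err.value)

    def test_missing_year_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("[male]\nage,1966,1968\n40,0.01,0.02\n")
        with pytest.raises(ValidationError) as err:
            read_rate_table(path)
        assert "consecutive" in str(err.value)

    def test_ragged_row_cites_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("[male]\nage,1966,1967\n40,0.01\n")
        with pytest.raises(ValidationError) as err:
            read_rate_table(path)
        assert ":3:" in str(err.value)

    def test_age_gap_cites_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("[male]\nage,1966\n40,0.01\n42,0.01\n")
        with pytest.raises(ValidationError) as err:
            read_rate_table(path)
        assert "unit-step" in str(err.value)
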