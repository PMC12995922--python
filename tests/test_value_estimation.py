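"""Moving-window discounting against closed-form annuity/Faustmann oracles."""

import numpy as np
import pandas as pd
import pytest

from standres.disturbance import make_draw_streams
from standres.pipeline import simulate_regime
from standres.stand_model import clearcut_baseline
from standres.value_estimation import (
    DiscountSpec,
    aggregate_by_state,
    collect_value_samples,
    discounted_window_sum,
    sev_distribution,
)

FIN = DiscountSpec(rate=0.015, horizon=1000)


def clearcut_cash_flow_stream(params, series_years=2000, rotation=85):
    """Independent oracle: the deterministic zero-hazard clear-cut cash-flow
    stream, built directly from the yield table and the valuation functions
    (plant at phase 0, thinnings per table, harvest + replant at rotation)."""
    table, val = params.growth, params.valuation
    price, cost = val.price_fn, val.cost_fn
    times = np.arange(0, series_years + 5, 5)
    cf = np.zeros_like(times, dtype=float)
    for i, t in enumerate(times):
        phase = t % rotation
        if phase == 0:
            cf[i] -= val.planting_cost_regular
            if t > 0:
                dbh = table.dbh(rotation)
                cf[i] += table.volume(rotation) * (price(dbh) - cost(dbh))
        elif table.thinning(phase) > 0:
            dbh = table.thinning_dbh(phase)
            cf[i] += table.thinning(phase) * (price(dbh) - cost(dbh))
    return times, cf


def faustmann_sev(params, rate=0.015, rotation=85):
    """Closed-form Faustmann value: one cycle NPV over 1 - (1+r)^-u."""
    table, val = params.growth, params.valuation
    price, cost = val.price_fn, val.cost_fn
    npv = -val.planting_cost_regular
    for a in range(5, rotation + 5, 5):
        if a == rotation:
            dbh = table.dbh(a)
            npv += table.volume(a) * (price(dbh) - cost(dbh)) * (1 + rate) ** -a
        elif table.thinning(a) > 0:
            dbh = table.thinning_dbh(a)
            npv += table.thinning(a) * (price(dbh) - cost(dbh)) * (1 + rate) ** -a
    return npv / (1.0 - (1.0 + rate) ** -rotation)


class TestWindowSum:
    def test_all_zero_provisions(self):
        times = np.arange(0, 2005, 5)
        assert discounted_window_sum(times, np.zeros_like(times), 0, FIN) == 0.0

    def test_single_provision_at_window_start_undiscounted(self):
        times = np.arange(0, 2005, 5)
        values = np.zeros_like(times, dtype=float)
        values[40] = 123.0  # t = 200
        assert discounted_window_sum(times, values, 200, FIN) == pytest.approx(123.0)

    def test_annuity_closed_form(self):
        """A 1 EUR/yr annuity on an annual grid discounted over 1000 years
        matches (1 - (1+r)^-H) / r to 1e-9 relative, i.e. ~1/r ~ 66.667."""
        times = np.arange(0, 1001)
        values = np.r_[0.0, np.ones(1000)]
        got = discounted_window_sum(times, values, 0, FIN)
        expected = (1 - 1.015 ** -1000) / 0.015
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(1 / 0.015, rel=4e-7)

    def test_window_overshoot_refused(self):
        times = np.arange(0, 1005, 5)
        with pytest.raises(ValueError, match="overshoot"):
            discounted_window_sum(times, np.zeros_like(times), 5, FIN)

    def test_truncation_bound_for_bounded_provisions(self):
        """|V_truncated - V_infinite| <= M * (1+r)^-H / (1 - (1+r)^-5)."""
        M = 7.0
        times = np.arange(0, 2005, 5)
        v_trunc = discounted_window_sum(times, np.full_like(times, M, dtype=float), 0, FIN)
        step_disc = 1.015 ** -5
        v_inf = M / (1 - step_disc)
        assert abs(v_trunc - v_inf) <= M * 1.015 ** -1000 / (1 - step_disc)


class TestSampleCollection:
    def _dummy_keys(self, n_runs, n_times):
        return np.zeros((n_runs, n_times, 2), dtype=int)

    def test_sample_count_on_2000yr_series(self):
        times = np.arange(0, 2005, 5)
        values = np.zeros((3, len(times)))
        df = collect_value_samples(times, values, self._dummy_keys(3, len(times)), FIN)
        assert len(df) == 3 * 201
        assert df["t"].max() == 1000

    def test_boundary_series_equal_to_horizon(self):
        times = np.arange(0, 1005, 5)
        values = np.zeros((1, len(times)))
        df = collect_value_samples(times, values, self._dummy_keys(1, len(times)), FIN)
        assert len(df) == 1 and df["t"].iloc[0] == 0

    def test_series_shorter_than_horizon_rejected(self):
        times = np.arange(0, 505, 5)
        with pytest.raises(ValueError, match="shorter"):
            collect_value_samples(
                times, np.zeros((1, len(times))), self._dummy_keys(1, len(times)), FIN
            )

    def test_linearity_in_provisions(self):
        rng = np.random.default_rng(3)
        times = np.arange(0, 1505, 5)
        values = rng.normal(size=(2, len(times)))
        keys = self._dummy_keys(2, len(times))
        a = collect_value_samples(times, values, keys, FIN)
        b = collect_value_samples(times, 3.5 * values, keys, FIN)
        assert np.allclose(b["value"], 3.5 * a["value"], rtol=1e-12)

    def test_windows_match_direct_sum(self):
        rng = np.random.default_rng(4)
        times = np.arange(0, 1505, 5)
        values = rng.normal(size=(1, len(times)))
        df = collect_value_samples(times, values, self._dummy_keys(1, len(times)), FIN)
        for t0 in (0, 250, 500):
            direct = discounted_window_sum(times, values[0], t0, FIN)
            assert df.loc[df["t"] == t0, "value"].iloc[0] == pytest.approx(direct)


class TestAggregation:
    def test_mean_and_count(self):
        df = pd.DataFrame(
            {"run": [0, 0], "t": [0, 5], "lead_age": [5, 5], "gap_age": [-1, -1],
             "value": [10.0, 20.0]}
        )
        out = aggregate_by_state(df)
        assert len(out) == 1
        assert out["mean"].iloc[0] == 15.0 and out["n"].iloc[0] == 2

    def test_states_do_not_cross_contaminate(self):
        df = pd.DataFrame(
            {"run": [0, 0], "t": [0, 5], "lead_age": [5, 10], "gap_age": [-1, -1],
             "value": [10.0, 20.0]}
        )
        out = aggregate_by_state(df).sort_values("lead_age")
        assert list(out["mean"]) == [10.0, 20.0]

    def test_sparse_states_flagged(self):
        df = pd.DataFrame(
            {"run": [0], "t": [0], "lead_age": [5], "gap_age": [-1], "value": [1.0]}
        )
        assert aggregate_by_state(df, min_samples=5)["sparse"].iloc[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_by_state(pd.DataFrame(columns=["lead_age", "gap_age", "value"]))


@pytest.fixture(scope="module")
def zero_hazard_samples(params):
    regime = clearcut_baseline()
    streams = make_draw_streams(1, seed=0, n_steps=401)
    sim = simulate_regime(regime, params, streams, 2000, zero_hazard=True)
    return collect_value_samples(sim.times, sim.cf, sim.state_keys(), FIN)


class TestZeroHazardClearcut:
    def test_pipeline_matches_independent_cash_flow_oracle(self, params, zero_hazard_samples):
        times, cf = clearcut_cash_flow_stream(params)
        oracle_sev = discounted_window_sum(times, cf, 0, FIN)
        got = zero_hazard_samples.loc[zero_hazard_samples["t"] == 0, "value"].iloc[0]
        assert got == pytest.approx(oracle_sev, rel=1e-9)

    def test_sev_matches_faustmann_within_truncation_bound(self, params, zero_hazard_samples):
        sev = sev_distribution(zero_hazard_samples)["value"].iloc[0]
        closed = faustmann_sev(params)
        # Tail of the periodic stream beyond the 1000-yr horizon.
        _, cf = clearcut_cash_flow_stream(params, series_years=85)
        bound = np.abs(cf).sum() * 1.015 ** -(1000 + 5 - 85) / (1 - 1.015 ** -85)
        assert abs(sev - closed) <= bound
        assert sev == pytest.approx(closed, rel=1e-4)

    def test_samples_of_one_state_agree_up_to_truncation_error(self, zero_hazard_samples):
        # The deterministic sawtooth revisits each state with identical
        # futures; samples differ only by the truncated far tail.
        max_cf = zero_hazard_samples["value"].abs().max()
        bound = max_cf * 1.015 ** -1000 / (1 - 1.015 ** -5)
        spread = zero_hazard_samples.groupby(["lead_age", "gap_age"])["value"].agg(np.ptp)
        assert (spread <= bound + 1e-9).all()

    def test_all_sev_values_identical_without_hazard(self, params):
        regime = clearcut_baseline()
        streams = make_draw_streams(3, seed=0, n_steps=401)
        sim = simulate_regime(regime, params, streams, 2000, zero_hazard=True)
        samples = collect_value_samples(sim.times, sim.cf, sim.state_keys(), FIN)
        sev = sev_distribution(samples)
        assert len(sev) == 3 and sev["value"].nunique() == 1

    def test_sev_requires_bare_soil_start(self, zero_hazard_samples):
        shifted = zero_hazard_samples.copy()
        shifted["lead_age"] = 40
        with pytest.raises(ValueError, match="bare"):
            sev_distribution(shifted)
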