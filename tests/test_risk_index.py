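"""Normalization, layer construction, index combination and categorization."""

import numpy as np
import pandas as pd
import pytest

from wtflari import (
    RiskConfig,
    build_ev_layer,
    build_event_layer,
    categorize,
    compute_flari,
    derive_thresholds,
    minmax_normalize,
)
from wtflari.risk_index import RiskThresholds, event_rate_weights


class TestMinMax:
    def test_endpoints_map_to_unit_interval(self, exposure):
        layer = minmax_normalize(exposure["population_density"])
        assert layer.normalized["Basilicata"] == 0.0   # minimum, 57
        assert layer.normalized["Campania"] == 1.0     # maximum, 422
        assert layer.normalized.between(0, 1).all()

    def test_three_point_example(self):
        layer = minmax_normalize(pd.Series({"a": 0.0, "b": 5.0, "c": 10.0}))
        assert layer.normalized.tolist() == [0.0, 0.5, 1.0]

    def test_single_key_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            minmax_normalize(pd.Series({"a": 10.0}))

    def test_constant_layer_degenerates_to_zero_with_warning(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            layer = minmax_normalize(pd.Series({"a": 3.0, "b": 3.0}))
        assert (layer.normalized == 0).all()


class TestEVLayer:
    def test_two_region_identity(self):
        exp = pd.DataFrame({"population_density": [1.0, 2.0],
                            "river_surface": [10.0, 20.0],
                            "non_plain_surface": [5.0, 50.0]},
                           index=["A", "B"])
        layer = build_ev_layer(exp)
        assert layer.normalized.tolist() == [0.0, 1.0]

    def test_region_dominating_all_layers_scores_one(self, exposure):
        layer = build_ev_layer(exposure)
        assert layer.normalized.between(0, 1).all()
        assert layer.normalized.min() == 0.0 and layer.normalized.max() == 1.0
        # Molise is the raw minimum of river and non-plain surface and nearly
        # of population density: it anchors the bottom of the layer
        assert layer.normalized.idxmin() == "Molise"

    def test_weights_must_sum_to_one(self, exposure):
        with pytest.raises(ValueError):
            build_ev_layer(exposure, layer_weights=(0.5, 0.5, 0.5))


class TestEventLayer:
    def test_matrix_maximum_anchors_one(self, share_matrix):
        layer = build_event_layer(share_matrix, scope="annual")
        top = layer.normalized.stack().idxmax()
        assert layer.normalized.loc[top] == 1.0
        # the 5.56 WT6 tie is the verbatim matrix maximum
        assert set(layer.normalized[6][layer.normalized[6] == 1.0].index) == {
            "Abruzzo", "Calabria"}
        assert layer.hi == pytest.approx(5.56)

    def test_all_zero_weights_degenerate(self):
        weights = pd.DataFrame(0.0, index=["A", "B"], columns=range(1, 9))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            layer = build_event_layer(weights, scope="annual")
        assert (layer.normalized == 0).all().all()

    def test_seasonal_requires_annual_anchors(self, share_matrix):
        with pytest.raises(ValueError, match="annual"):
            build_event_layer(share_matrix, scope="winter")

    def test_seasonal_exceeding_annual_max_clipped(self, share_matrix):
        annual = build_event_layer(share_matrix, scope="annual")
        with pytest.warns(RuntimeWarning, match="clipped"):
            layer = build_event_layer(2 * share_matrix, scope="winter",
                                      annual_norm=annual)
        assert layer.normalized.to_numpy().max() == 1.0

    def test_rate_weights_divide_by_wt_days(self):
        counts = pd.DataFrame([[4, 0], [0, 2]], index=["A", "B"], columns=[1, 2])
        days = pd.Series({1: 8, 2: 0})
        with pytest.warns(RuntimeWarning, match="zero days"):
            rates = event_rate_weights(counts, days)
        assert rates.loc["A", 1] == 0.5
        assert rates.loc["B", 2] == 0.0


class TestFlari:
    @staticmethod
    def _layers(event_value, ev_value):
        regions = ["A", "B"]
        event = build_event_layer(
            pd.DataFrame([[0.0, event_value], [0.0, 1.0]],
                         index=regions, columns=[1, 2]), scope="annual")
        raw_ev = pd.Series({"A": ev_value, "B": 1.0})
        from wtflari.risk_index import Layer
        ev = Layer(raw=raw_ev, normalized=raw_ev, label="ev", lo=0, hi=1)
        return event, ev

    def test_limit_weights(self, share_matrix, exposure):
        event = build_event_layer(share_matrix, scope="annual")
        ev = build_ev_layer(exposure)
        only_event = compute_flari(event, ev, w_event=1.0)
        pd.testing.assert_frame_equal(only_event, event.normalized)
        only_ev = compute_flari(event, ev, w_event=0.0)
        for w in only_ev.columns:
            assert np.allclose(only_ev[w], ev.normalized)

    @pytest.mark.parametrize("event,ev,expected", [
        (1.0, 1.0, 1.0), (0.0, 1.0, 0.25), (1.0, 0.0, 0.75)])
    def test_weighted_combination(self, event, ev, expected):
        from wtflari.risk_index import Layer
        regions = ["A", "B"]
        evl = Layer(raw=pd.Series(ev, index=regions),
                    normalized=pd.Series(ev, index=regions),
                    label="ev", lo=0, hi=1)
        evtl = Layer(raw=pd.DataFrame(event, index=regions, columns=[1]),
                     normalized=pd.DataFrame(event, index=regions, columns=[1]),
                     label="event", lo=0, hi=1)
        ri = compute_flari(evtl, evl)
        assert ri.loc["A", 1] == pytest.approx(expected)

    def test_region_mismatch_lists_differences(self, share_matrix, exposure):
        event = build_event_layer(share_matrix.drop(index="Molise"), scope="annual")
        ev = build_ev_layer(exposure)
        with pytest.raises(ValueError, match="Molise"):
            compute_flari(event, ev)

    def test_monotone_in_event_weight(self, share_matrix, exposure):
        ev = build_ev_layer(exposure)
        base = compute_flari(build_event_layer(share_matrix, "annual"), ev)
        bumped_raw = share_matrix.copy()
        bumped_raw.loc["Umbria", 3] += 0.5  # stays below the matrix max
        bumped = compute_flari(build_event_layer(bumped_raw, "annual"), ev)
        assert bumped.loc["Umbria", 3] > base.loc["Umbria", 3]

    def test_permutation_of_regions_permutes_output(self, share_matrix, exposure):
        ev = build_ev_layer(exposure)
        event = build_event_layer(share_matrix, "annual")
        ri = compute_flari(event, ev)
        perm = list(reversed(share_matrix.index))
        event_p = build_event_layer(share_matrix.loc[perm], "annual")
        ev_p = build_ev_layer(exposure.loc[perm])
        ri_p = compute_flari(event_p, ev_p)
        pd.testing.assert_frame_equal(ri_p.loc[ri.index], ri)


class TestThresholds:
    def test_closed_form_linear_interpolation(self):
        values = pd.DataFrame(np.arange(1, 101).reshape(10, 10) / 100.0)
        thr = derive_thresholds(values)
        assert thr.q90 == pytest.approx(0.901)
        assert thr.q95 == pytest.approx(0.9505)
        assert thr.q99 == pytest.approx(0.9901)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.random((8, 4)))
        thr = derive_thresholds(values)
        shifted = derive_thresholds(values + 0.1)
        assert shifted.q90 == pytest.approx(thr.q90 + 0.1)
        assert shifted.q99 == pytest.approx(thr.q99 + 0.1)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="10"):
            derive_thresholds(pd.DataFrame(np.ones((3, 3))))

    def test_all_equal_cells_make_everything_low(self):
        values = pd.DataFrame(0.4, index=range(4), columns=range(4))
        thr = derive_thresholds(values)
        assert thr.q90 == thr.q95 == thr.q99 == 0.4
        cats = categorize(values, thr)
        assert (cats == "low").all().all()


class TestCategorize:
    def test_boundaries_fall_to_lower_category(self):
        thr = RiskThresholds(q90=0.3, q95=0.5, q99=0.7)
        values = pd.DataFrame({1: [0.0, 0.3, 0.5, 0.7, 0.700001]})
        cats = categorize(values, thr)[1].tolist()
        assert cats == ["low", "low", "moderate", "high", "very_high"]

    def test_annual_category_counts_respect_quantiles(self, share_matrix, exposure):
        ev = build_ev_layer(exposure)
        ri = compute_flari(build_event_layer(share_matrix, "annual"), ev)
        thr = derive_thresholds(ri)
        cats = categorize(ri, thr)
        n = ri.size
        flat = cats.to_numpy().ravel()
        assert (flat == "very_high").sum() <= int(np.ceil(0.01 * n)) + 1
        assert (flat != "low").sum() <= int(np.ceil(0.10 * n)) + 1
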