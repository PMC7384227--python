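import numpy as np
import pandas as pd
import pytest

from fcavisits.decay import DecaySpec
from fcavisits.fca import (
    FactorizationError,
    closest_provider_predict,
    compute_ai,
    factorize,
    huff_probabilities,
    ifca_weights,
    predict_visits,
    run_method,
    weights_from_partials,
)
from fcavisits.io import PipelineConfig
from fcavisits.synthetic import DiagnosisSpec, ScenarioSpec, generate_scenario
from fcavisits.disaggregation import disaggregate_need
from fcavisits.types import TravelTimeMatrix

from .conftest import random_instance
from .oracles import oracle_closest, oracle_huff, oracle_ifca, oracle_two_step

DECAY = DecaySpec.log_logistic()


def _single_pair(minutes=10.0, beds=50.0, need=100.0):
    cells = pd.DataFrame(
        {"cell_id": [0], "x_km": [0.5], "y_km": [0.5], "population": [1000.0],
         "municipality_id": [0], "district_id": [0]}
    )
    hospitals = pd.DataFrame(
        {"hospital_id": [0], "x_km": [5.5], "y_km": [0.5]}
    )
    travel = TravelTimeMatrix(
        table=pd.DataFrame({"cell_id": [0], "hospital_id": [0], "minutes": [minutes]})
    )
    return cells, hospitals, travel, np.array([need]), np.array([beds])


class TestHuff:
    def test_single_hospital_probability_one(self):
        assert huff_probabilities([50.0], [0.8])[0] == pytest.approx(1.0)

    def test_symmetric_hospitals_split_evenly(self):
        p = huff_probabilities([40.0, 40.0], [0.6, 0.6])
        assert np.allclose(p, [0.5, 0.5])

    def test_attractiveness_ratio_drives_probabilities(self):
        p = huff_probabilities([20.0, 10.0], [0.7, 0.7])
        assert np.allclose(p, [2 / 3, 1 / 3])

    def test_all_zero_products_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            huff_probabilities([0.0, 0.0], [0.5, 0.5])

    def test_matches_oracle_on_random_cells(self, rng):
        for _ in range(10):
            cells, hospitals, travel, P, S, d = random_instance(rng, 6, 4)
            minutes, reachable = travel.dense(
                cells["cell_id"].to_numpy(), hospitals["hospital_id"].to_numpy()
            )
            for x in range(6):
                expect = oracle_huff(x, list(range(4)), dict(enumerate(S)), d, DECAY.weight)
                cols = np.nonzero(reachable[x])[0]
                got = huff_probabilities(S[cols], DECAY.weight(minutes[x, cols]))
                for j, y in enumerate(cols):
                    assert got[j] == pytest.approx(expect[y], abs=1e-12)


class TestIfcaWeights:
    def test_single_hospital_weight_equals_decay(self):
        cells, hospitals, travel, P, S = _single_pair(minutes=13.39)
        W = ifca_weights(cells, hospitals, S, travel, DECAY)
        assert W.weights[0, 0] == pytest.approx(0.5, abs=1e-12)  # Huff term is 1

    def test_colocated_single_hospital_full_weight(self):
        cells, hospitals, travel, P, S = _single_pair(minutes=0.0)
        W = ifca_weights(cells, hospitals, S, travel, DECAY)
        assert W.weights[0, 0] == pytest.approx(1.0)

    def test_weight_bounded_by_decay(self, rng):
        cells, hospitals, travel, P, S, d = random_instance(rng, 8, 4)
        W = ifca_weights(cells, hospitals, S, travel, DECAY)
        minutes, reachable = travel.dense(
            cells["cell_id"].to_numpy(), hospitals["hospital_id"].to_numpy()
        )
        F = np.where(reachable, DECAY.weight(np.where(reachable, minutes, 0.0)), 0.0)
        assert np.all(W.weights <= F + 1e-12)

    def test_huff_rows_sum_to_one(self, rng):
        cells, hospitals, travel, P, S, d = random_instance(rng, 8, 4)
        W = ifca_weights(cells, hospitals, S, travel, DECAY)
        minutes, reachable = travel.dense(
            cells["cell_id"].to_numpy(), hospitals["hospital_id"].to_numpy()
        )
        F = np.where(reachable, DECAY.weight(np.where(reachable, minutes, 0.0)), 0.0)
        huff = np.divide(W.weights, F, out=np.zeros_like(F), where=F > 0)
        assert np.allclose(huff.sum(axis=1), 1.0, atol=1e-9)


class TestAccessibilityIndex:
    def test_unit_decay_collapses_to_supply_demand_ratio(self):
        # one cell, one co-located hospital: all decay terms are 1 and both
        # methods reduce to AI = S / P
        cells, hospitals, travel, P, S = _single_pair(minutes=0.0, beds=40.0, need=80.0)
        for method in ("m2sfca", "e2sfca"):
            ai = compute_ai(cells, hospitals, S, P, travel, DECAY, method)
            assert ai.ai[0] == pytest.approx(0.5, abs=1e-12)

    def test_half_decay_distinguishes_methods(self):
        # f = 0.5 everywhere: M2SFCA gives 0.25*S/(0.5*P) = 0.5*S/P while
        # E2SFCA keeps S/P — the squared decay is the only difference
        cells, hospitals, travel, P, S = _single_pair(minutes=13.39, beds=40.0, need=80.0)
        m2 = compute_ai(cells, hospitals, S, P, travel, DECAY, "m2sfca")
        e2 = compute_ai(cells, hospitals, S, P, travel, DECAY, "e2sfca")
        assert m2.ai[0] == pytest.approx(0.25, abs=1e-12)
        assert e2.ai[0] == pytest.approx(0.5, abs=1e-12)

    def test_isolated_hospital_named_in_error(self):
        cells, hospitals, travel, P, S = _single_pair()
        with pytest.raises(Exception, match="0"):
            compute_ai(cells, hospitals, S, np.array([0.0]), travel, DECAY, "m2sfca")

    @pytest.mark.parametrize("method", ["m2sfca", "e2sfca"])
    @pytest.mark.parametrize("variant", ["as_printed", "decay_consistent"])
    def test_matches_nested_loop_oracle(self, rng, method, variant):
        for _ in range(5):
            cells, hospitals, travel, P, S, d = random_instance(rng, 6, 4)
            ai = compute_ai(cells, hospitals, S, P, travel, DECAY, method, variant)
            o_ai, o_partial, o_W, o_V = oracle_two_step(
                list(range(6)), list(range(4)), dict(enumerate(S)), dict(enumerate(P)),
                d, DECAY.weight, method, variant,
            )
            for x in range(6):
                assert ai.ai[x] == pytest.approx(o_ai[x], abs=1e-12)
                for y in range(4):
                    assert ai.partials[x, y] == pytest.approx(
                        o_partial.get((x, y), 0.0), abs=1e-12
                    )


class TestWeightsFromPartials:
    def test_single_reachable_hospital_weight_one(self):
        cells, hospitals, travel, P, S = _single_pair(minutes=20.0)
        ai = compute_ai(cells, hospitals, S, P, travel, DECAY, "m2sfca", "decay_consistent")
        W = weights_from_partials(ai)
        assert W.weights[0, 0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("method", ["m2sfca", "e2sfca"])
    def test_decay_consistent_rows_sum_to_one(self, rng, method):
        cells, hospitals, travel, P, S, d = random_instance(rng, 8, 4)
        ai = compute_ai(cells, hospitals, S, P, travel, DECAY, method, "decay_consistent")
        W = weights_from_partials(ai)
        assert np.allclose(W.row_sums(), 1.0, atol=1e-9)

    def test_as_printed_two_by_two_hand_fixture(self):
        # 2 cells x 2 hospitals, every pair reachable; hand-evaluated
        # published partial formulas (single decay for M2SFCA)
        cells = pd.DataFrame(
            {"cell_id": [0, 1], "x_km": [0.5, 1.5], "y_km": [0.5, 0.5],
             "population": [100.0, 100.0], "municipality_id": [0, 0], "district_id": [0, 0]}
        )
        hospitals = pd.DataFrame({"hospital_id": [0, 1], "x_km": [0.0, 0.0], "y_km": [0.0, 0.0]})
        travel = TravelTimeMatrix(
            table=pd.DataFrame(
                {"cell_id": [0, 0, 1, 1], "hospital_id": [0, 1, 0, 1],
                 "minutes": [10.0, 20.0, 20.0, 10.0]}
            )
        )
        P = np.array([2.0, 3.0])
        S = np.array([30.0, 50.0])
        f10, f20 = DECAY.weight(10.0), DECAY.weight(20.0)
        D0 = 2.0 * f10 + 3.0 * f20
        D1 = 2.0 * f20 + 3.0 * f10
        ai0 = 30.0 * f10 * f10 / D0 + 50.0 * f20 * f20 / D1
        partial00 = 30.0 * f10 / D0
        ai = compute_ai(cells, hospitals, S, P, travel, DECAY, "m2sfca", "as_printed")
        W = weights_from_partials(ai)
        assert ai.ai[0] == pytest.approx(ai0, abs=1e-12)
        assert W.weights[0, 0] == pytest.approx(partial00 / ai0, abs=1e-12)


class TestPredictAndFactorize:
    def test_unit_weight_identity(self):
        cells, hospitals, travel, P, S = _single_pair(minutes=0.0, need=100.0)
        W = ifca_weights(cells, hospitals, S, travel, DECAY)
        pred = predict_visits(W, P)
        assert pred.visits.iloc[0] == pytest.approx(100.0)

    def test_matches_double_loop_on_random_instance(self, rng):
        cells, hospitals, travel, P, S, d = random_instance(rng, 7, 3)
        W = ifca_weights(cells, hospitals, S, travel, DECAY)
        pred = predict_visits(W, P)
        _, o_V = oracle_ifca(
            list(range(7)), list(range(3)), dict(enumerate(S)), dict(enumerate(P)),
            d, DECAY.weight,
        )
        for y in range(3):
            assert pred.visits[y] == pytest.approx(o_V[y], abs=1e-12)

    def test_factorize_ratio_and_conservation(self, rng):
        cells, hospitals, travel, P, S, d = random_instance(rng, 7, 3)
        pred = predict_visits(ifca_weights(cells, hospitals, S, travel, DECAY), P)
        actual = pd.Series(rng.uniform(10, 300, 3), index=pred.visits.index)
        out = factorize(pred, actual)
        assert out.factorized
        assert out.scale_factor == pytest.approx(actual.sum() / pred.visits.sum())
        assert out.visits.sum() == pytest.approx(actual.sum(), rel=1e-9)

    def test_factorize_identity_when_totals_match(self):
        cells, hospitals, travel, P, S = _single_pair(minutes=0.0, need=100.0)
        pred = predict_visits(ifca_weights(cells, hospitals, S, travel, DECAY), P)
        out = factorize(pred, pd.Series([100.0], index=pred.visits.index))
        assert out.scale_factor == pytest.approx(1.0)
        assert np.allclose(out.visits, pred.visits)

    def test_zero_prediction_total_raises(self):
        cells, hospitals, travel, P, S = _single_pair()
        pred_like = predict_visits(
            ifca_weights(cells, hospitals, S, travel, DECAY), np.array([0.0])
        )
        with pytest.raises(FactorizationError):
            factorize(pred_like, pd.Series([10.0], index=pred_like.visits.index))


class TestClosestProvider:
    def test_all_need_to_nearer_hospital(self):
        cells = pd.DataFrame(
            {"cell_id": [0], "x_km": [0.5], "y_km": [0.5], "population": [10.0],
             "municipality_id": [0], "district_id": [0]}
        )
        hospitals = pd.DataFrame({"hospital_id": [0, 1], "x_km": [0, 0], "y_km": [0, 0]})
        travel = TravelTimeMatrix(
            table=pd.DataFrame({"cell_id": [0, 0], "hospital_id": [0, 1], "minutes": [20.0, 10.0]})
        )
        pred = closest_provider_predict(cells, hospitals, travel, np.array([7.0]))
        assert pred.visits[1] == pytest.approx(7.0) and pred.visits[0] == 0.0

    def test_exact_tie_goes_to_lowest_id(self):
        cells = pd.DataFrame(
            {"cell_id": [0], "x_km": [0.5], "y_km": [0.5], "population": [10.0],
             "municipality_id": [0], "district_id": [0]}
        )
        hospitals = pd.DataFrame({"hospital_id": [3, 1], "x_km": [0, 0], "y_km": [0, 0]})
        travel = TravelTimeMatrix(
            table=pd.DataFrame({"cell_id": [0, 0], "hospital_id": [3, 1], "minutes": [10.0, 10.0]})
        )
        pred = closest_provider_predict(cells, hospitals, travel, np.array([5.0]))
        assert pred.visits[1] == pytest.approx(5.0) and pred.visits[3] == 0.0

    def test_conserves_reachable_need_and_matches_oracle(self, rng):
        cells, hospitals, travel, P, S, d = random_instance(rng, 9, 4)
        pred = closest_provider_predict(cells, hospitals, travel, P)
        assert pred.visits.sum() == pytest.approx(P.sum(), rel=1e-12)
        o_V = oracle_closest(list(range(9)), list(range(4)), dict(enumerate(P)), d)
        for y in range(4):
            assert pred.visits[y] == pytest.approx(o_V[y], abs=1e-12)


class TestScaleAndMonotonicity:
    def test_need_scaling_scales_unfactorized_visits(self, rng):
        cells, hospitals, travel, P, S, d = random_instance(rng, 6, 3)
        base = predict_visits(ifca_weights(cells, hospitals, S, travel, DECAY), P)
        scaled = predict_visits(ifca_weights(cells, hospitals, S, travel, DECAY), 3.0 * P)
        assert np.allclose(scaled.visits, 3.0 * base.visits, rtol=1e-12)

    def test_attractiveness_scaling_leaves_ifca_weights_unchanged(self, rng):
        cells, hospitals, travel, P, S, d = random_instance(rng, 6, 3)
        W1 = ifca_weights(cells, hospitals, S, travel, DECAY)
        W2 = ifca_weights(cells, hospitals, 5.0 * S, travel, DECAY)
        assert np.allclose(W1.weights, W2.weights, atol=1e-12)

    def test_attractiveness_scaling_rescales_ai_linearly(self, rng):
        cells, hospitals, travel, P, S, d = random_instance(rng, 6, 3)
        ai1 = compute_ai(cells, hospitals, S, P, travel, DECAY, "e2sfca")
        ai2 = compute_ai(cells, hospitals, 5.0 * S, P, travel, DECAY, "e2sfca")
        assert np.allclose(ai2.ai, 5.0 * ai1.ai, rtol=1e-12)

    @pytest.mark.parametrize("method", ["ifca", "m2sfca", "e2sfca"])
    def test_more_attractive_hospital_never_loses_visits(self, rng, method):
        cells, hospitals, travel, P, S, d = random_instance(rng, 8, 4)

        def visits_for(S_vec):
            if method == "ifca":
                W = ifca_weights(cells, hospitals, S_vec, travel, DECAY)
            else:
                W = weights_from_partials(
                    compute_ai(cells, hospitals, S_vec, P, travel, DECAY, method)
                )
            return predict_visits(W, P).visits

        # increasing S of hospital 2 must not decrease its own visits
        base = visits_for(S)
        S_up = S.copy()
        S_up[2] *= 2.0
        up = visits_for(S_up)
        assert up[2] >= base[2] - 1e-9


@pytest.fixture(scope="module")
def small_scenario():
    spec = ScenarioSpec(
        grid_rows=10, grid_cols=10, n_districts=4, municipalities_per_district=4,
        n_hospitals=5,
        diagnoses=(DiagnosisSpec(name="I48", base_rate=0.05, gradient_axis="ns"),),
        seed=3,
    )
    return disaggregate_need(generate_scenario(spec).scenario)


class TestRunMethod:
    def test_single_hospital_all_methods_agree_after_factorization(self):
        spec = ScenarioSpec(
            grid_rows=5, grid_cols=5, n_districts=1, municipalities_per_district=1,
            n_hospitals=1,
            diagnoses=(DiagnosisSpec(name="I48", base_rate=0.05),),
            seed=5,
        )
        scenario = disaggregate_need(generate_scenario(spec).scenario)
        results = {
            m: run_method(scenario, "I48", m) for m in ("ifca", "m2sfca", "e2sfca", "closest")
        }
        ref = results["ifca"].visits
        for m, res in results.items():
            assert np.allclose(res.visits, ref, rtol=1e-9), m

    def test_method_label_and_factorization_recorded(self, small_scenario):
        res = run_method(small_scenario, "I48", "m2sfca", "beds")
        assert res.method == "m2sfca"
        assert res.factorized and res.scale_factor > 0
        assert res.attractiveness_source == "beds"

    def test_factorized_totals_match_included_actuals(self, small_scenario):
        from fcavisits.io import exclude_hospitals
        from fcavisits.types import visits_column

        marked = exclude_hospitals(small_scenario.hospitals, "I48", "internal_medicine")
        actual_total = marked.loc[marked["included"], visits_column("I48")].sum()
        for m in ("ifca", "m2sfca", "e2sfca", "closest"):
            res = run_method(small_scenario, "I48", m)
            assert res.visits.sum() == pytest.approx(actual_total, rel=1e-9), m

    def test_unknown_method_rejected(self, small_scenario):
        with pytest.raises(ValueError, match="unknown method"):
            run_method(small_scenario, "I48", "3sfca")
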