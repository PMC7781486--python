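import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bladesim.circuits import CircuitDesign, Gene, ideal_vector
from bladesim.metrics import (
    UndefinedAngleError,
    adapted_metric,
    angular_metric,
    l1_errors,
    score_circuit,
)

vectors = st.lists(
    st.floats(min_value=0.0, max_value=100.0, allow_nan=False), min_size=8, max_size=8
).filter(lambda v: sum(v) > 0)


class TestAngularMetric:
    def test_published_values(self, worked_example):
        theta = angular_metric(worked_example["observed"], worked_example["ideal"])
        if worked_example["theta_tol"] is not None:
            assert theta == pytest.approx(worked_example["theta"], abs=worked_example["theta_tol"])
        else:
            assert theta == pytest.approx(worked_example["theta"], rel=0.015)

    def test_identical_vectors_score_zero(self):
        v = [10, 0, 30, 40, 0, 60, 70, 80]
        assert angular_metric(v, v) == pytest.approx(0.0, abs=1e-5)

    def test_orthogonal_vectors_score_ninety(self):
        a = [100, 0, 0, 0, 0, 0, 0, 0]
        b = [0, 100, 0, 0, 0, 0, 0, 0]
        assert angular_metric(a, b) == pytest.approx(90.0)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(UndefinedAngleError):
            angular_metric([0] * 8, [100] * 8)
        with pytest.raises(UndefinedAngleError):
            angular_metric([100] * 8, [0] * 8)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            angular_metric([1, 2, 3], [100] * 8)

    @settings(derandomize=True, max_examples=60)
    @given(v=vectors, w=vectors, c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance_symmetry_and_range(self, v, w, c):
        theta = angular_metric(v, w)
        assert 0.0 <= theta <= 90.0
        assert angular_metric(w, v) == pytest.approx(theta, abs=1e-9)
        assert angular_metric(np.multiply(v, c), w) == pytest.approx(theta, abs=1e-6)

    @settings(derandomize=True, max_examples=30)
    @given(v=vectors, c=st.floats(min_value=1e-3, max_value=1e3))
    def test_zero_iff_proportional(self, v, c):
        assert angular_metric(v, np.multiply(v, c)) == pytest.approx(0.0, abs=1e-5)


class TestAdaptedMetric:
    @pytest.mark.parametrize(
        "theta,n,expected", [(11.58, 8, 1.4475), (8.2, 4, 2.05), (0.0, 3, 0.0)]
    )
    def test_divides_by_expected_on_count(self, theta, n, expected):
        assert adapted_metric(theta, n) == pytest.approx(expected, abs=1e-4)

    def test_division_by_zero_for_all_stop(self):
        with pytest.raises(ZeroDivisionError):
            adapted_metric(5.0, 0)


class TestL1Errors:
    def test_published_total_errors(self):
        total, avg = l1_errors([42, 53, 34, 46, 44, 59, 55, 69], [100] * 8)
        assert total == pytest.approx(398.0)  # printed 397.97 from unrounded data
        assert avg == pytest.approx(398.0 / 8)
        total2, avg2 = l1_errors([0, 0, 0, 2, 0, 0, 0, 89], [0] * 7 + [100])
        assert (total2, avg2) == (13.0, 1.625)  # printed 13.22 / 1.63

    def test_perfect_output_has_zero_error(self):
        v = [100, 0, 0, 100, 0, 0, 0, 100]
        assert l1_errors(v, v) == (0.0, 0.0)


class TestScoreCircuit:
    def test_full_record_for_published_circuits(self, worked_example):
        rec = score_circuit(worked_example["observed"], worked_example["circuit"])
        assert rec.n == worked_example["n"]
        assert rec.theta_bar == pytest.approx(worked_example["theta_bar"], rel=0.015)
        assert rec.average_error == pytest.approx(rec.total_error / 8)

    def test_perfect_observation_scores_zero(self):
        circuit = CircuitDesign((Gene.GFP, Gene.MCHERRY, Gene.STOP, Gene.GFP_MCHERRY))
        rec = score_circuit(ideal_vector(circuit).as_array(), circuit)
        assert rec.theta == 0.0
        assert rec.theta_bar == 0.0
        assert rec.total_error == 0.0

    def test_all_stop_circuit_rejected(self):
        with pytest.raises(UndefinedAngleError):
            score_circuit([1] * 8, CircuitDesign((Gene.STOP,) * 4))
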