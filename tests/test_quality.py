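"""Quality scoring: normalization, capping, aggregation, weight renormalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caredesign import (ConfigurationError, DEFAULT_WEIGHTS, DomainWeights,
                        DesignParameterSpec, ImpactMatrix,
                        ModelSpecificationError, aggregate_score,
                        renormalize_weights, score_domain)

TABLE_WEIGHTS = DomainWeights(DEFAULT_WEIGHTS)


def _specs(zs):
    return [DesignParameterSpec(f"p{i}", f"p{i}", "u", z, "hospital", "length_of_stay")
            for i, z in enumerate(zs)]


def _matrix(cols, pids=None):
    """Single-domain matrix: cols maps 'dom' -> list of q values."""
    pids = pids or [f"p{i}" for i in range(len(next(iter(cols.values()))))]
    return ImpactMatrix.from_dict(
        {pid: {d: q[i] for d, q in cols.items()} for i, pid in enumerate(pids)},
        domains=list(cols))


def brute_force_score(x, z, q, cap=True):
    """Independent summation oracle for the normalized domain score."""
    num = 0.0
    den = 0.0
    for xi, zi, qi in zip(x, z, q):
        r = xi / zi
        if cap and r > 1:
            r = 1.0
        num += qi * r
        den += qi
    return 100.0 * num / den


class TestScoreDomain:
    def test_all_parameters_at_maximum_scores_100(self):
        specs = _specs([2.0, 5.0, 7.0])
        m = _matrix({"safe": [1.0, 3.0, 0.5]})
        values = {"p0": 2.0, "p1": 5.0, "p2": 7.0}
        assert score_domain(values, specs, m, "safe") == pytest.approx(100.0)

    def test_zero_provision_scores_zero(self):
        specs = _specs([2.0, 5.0])
        m = _matrix({"safe": [1.0, 3.0]})
        assert score_domain({"p0": 0.0, "p1": 0.0}, specs, m, "safe") == 0.0

    def test_hand_arithmetic_two_parameters(self):
        # q = (2, 1), x/z = (0.5, 1.0) -> 100*(2*0.5 + 1*1.0)/3
        specs = _specs([1.0, 1.0])
        m = _matrix({"safe": [2.0, 1.0]})
        s = score_domain({"p0": 0.5, "p1": 1.0}, specs, m, "safe")
        assert s == pytest.approx(100.0 * (2 * 0.5 + 1 * 1.0) / 3)

    def test_over_provision_is_capped(self):
        # x/z = (1.5, 1.0): the 1.5 caps to 1, so the score stays 100
        specs = _specs([1.0, 1.0])
        m = _matrix({"safe": [2.0, 1.0]})
        assert score_domain({"p0": 1.5, "p1": 1.0}, specs, m, "safe") == \
            pytest.approx(100.0)

    def test_uncapped_mode_exceeds_100(self):
        specs = _specs([1.0, 1.0])
        m = _matrix({"safe": [2.0, 1.0]})
        s = score_domain({"p0": 1.5, "p1": 1.0}, specs, m, "safe", cap=False)
        assert s == pytest.approx(100.0 * (2 * 1.5 + 1 * 1.0) / 3)

    def test_zero_column_sum_is_a_model_error(self):
        specs = _specs([1.0])
        m = _matrix({"safe": [0.0]})
        with pytest.raises(ModelSpecificationError, match="safe"):
            score_domain({"p0": 1.0}, specs, m, "safe")

    def test_missing_value_is_a_configuration_error(self):
        specs = _specs([1.0])
        m = _matrix({"safe": [1.0]})
        with pytest.raises(ConfigurationError, match="p0"):
            score_domain({}, specs, m, "safe")

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.0, 10.0), st.floats(0.01, 10.0),
                              st.floats(0.0, 5.0)),
                    min_size=1, max_size=5)
           .filter(lambda rows: sum(r[2] for r in rows) > 1e-6))
    def test_matches_brute_force_oracle(self, rows):
        x = [r[0] for r in rows]
        z = [r[1] for r in rows]
        q = [r[2] for r in rows]
        specs = _specs(z)
        m = _matrix({"safe": q})
        values = {f"p{i}": xi for i, xi in enumerate(x)}
        assert score_domain(values, specs, m, "safe") == \
            pytest.approx(brute_force_score(x, z, q), abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.0, 20.0), st.floats(0.01, 10.0),
                              st.floats(0.0, 5.0)),
                    min_size=1, max_size=6)
           .filter(lambda rows: sum(r[2] for r in rows) > 1e-6))
    def test_bounded_0_100_under_capping(self, rows):
        specs = _specs([r[1] for r in rows])
        m = _matrix({"safe": [r[2] for r in rows]})
        values = {f"p{i}": r[0] for i, r in enumerate(rows)}
        s = score_domain(values, specs, m, "safe")
        assert -1e-9 <= s <= 100.0 + 1e-9

    def test_affine_below_cap(self):
        """Doubling x_i from a/2*z to a*z (a <= 1) doubles that contribution."""
        specs = _specs([4.0, 4.0])
        m = _matrix({"safe": [3.0, 1.0]})
        base = score_domain({"p0": 0.0, "p1": 2.0}, specs, m, "safe")
        half = score_domain({"p0": 1.0, "p1": 2.0}, specs, m, "safe")
        full = score_domain({"p0": 2.0, "p1": 2.0}, specs, m, "safe")
        assert full - base == pytest.approx(2 * (half - base), abs=1e-12)


class TestAggregateScore:
    def test_uniform_scores_aggregate_to_same(self):
        scores = {d: 100.0 for d in TABLE_WEIGHTS.as_dict()}
        assert aggregate_score(scores, TABLE_WEIGHTS) == pytest.approx(100.0)

    def test_hand_arithmetic(self):
        scores = {"safe": 80, "effective": 60, "timely": 40,
                  "equitable": 40, "person_centred": 70}
        assert aggregate_score(scores, TABLE_WEIGHTS) == pytest.approx(69.0)

    def test_degenerate_weight_selects_single_domain(self):
        w = DomainWeights({"safe": 1.0, "effective": 0.0})
        assert aggregate_score({"safe": 42.0, "effective": 7.0}, w) == 42.0

    def test_invalid_weights_rejected_at_construction(self):
        with pytest.raises(ModelSpecificationError, match="sum"):
            DomainWeights({"safe": 0.5, "effective": 0.4})
        with pytest.raises(ModelSpecificationError, match="negative"):
            DomainWeights({"safe": 1.5, "effective": -0.5})

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.0, 100.0), st.floats(0.01, 1.0)),
                    min_size=2, max_size=6))
    def test_within_score_range_and_permutation_invariant(self, rows):
        total = sum(w for _, w in rows)
        weights = DomainWeights({f"d{i}": w / total
                                 for i, (_, w) in enumerate(rows)})
        scores = {f"d{i}": s for i, (s, _) in enumerate(rows)}
        agg = aggregate_score(scores, weights)
        assert min(scores.values()) - 1e-9 <= agg <= max(scores.values()) + 1e-9
        shuffled = DomainWeights(dict(reversed(list(weights.items()))))
        assert aggregate_score(scores, shuffled) == pytest.approx(agg, abs=1e-12)


class TestRenormalizeWeights:
    def test_safety_move_from_half_to_point_six(self):
        out = renormalize_weights(TABLE_WEIGHTS, "safe", 0.6)
        assert out.as_dict() == pytest.approx({
            "safe": 0.6, "effective": 0.24, "timely": 0.04,
            "equitable": 0.04, "person_centred": 0.08}, abs=1e-12)

    def test_identity_when_unchanged(self):
        out = renormalize_weights(TABLE_WEIGHTS, "safe", 0.5)
        assert out.as_dict() == TABLE_WEIGHTS.as_dict()

    def test_full_weight_limit(self):
        out = renormalize_weights(TABLE_WEIGHTS, "safe", 1.0)
        assert out.as_dict() == pytest.approx(
            {"safe": 1.0, "effective": 0.0, "timely": 0.0,
             "equitable": 0.0, "person_centred": 0.0}, abs=1e-12)

    def test_undefined_split_from_degenerate_weights(self):
        w = DomainWeights({"safe": 1.0, "effective": 0.0})
        with pytest.raises(ModelSpecificationError):
            renormalize_weights(w, "safe", 0.5)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0.0, 1.0))
    def test_sum_and_ratios_preserved(self, new_weight):
        out = renormalize_weights(TABLE_WEIGHTS, "effective", new_weight)
        assert abs(sum(out.as_dict().values()) - 1.0) <= 1e-9
        # ratios among untouched domains survive (safe:person_centred = 5)
        if new_weight < 1.0:
            assert out["safe"] / out["person_centred"] == pytest.approx(5.0)


class TestImpactMatrixValidation:
    def test_unknown_parameter_is_reported(self):
        m = _matrix({"safe": [1.0]}, pids=["x99"])
        assert any("x99" in v for v in m.violations(_specs([1.0])))

    def test_negative_entries_warn_but_pass(self, caplog):
        m = ImpactMatrix.from_dict(
            {"p0": {"safe": -1.0}, "p1": {"safe": 3.0}}, domains=["safe"])
        import logging
        with caplog.at_level(logging.WARNING, logger="caredesign.quality"):
            violations = m.violations(_specs([1.0, 1.0]))
        assert violations == []
        assert any("negative" in r.message for r in caplog.records)

    def test_nonpositive_column_sum_is_a_violation(self):
        m = ImpactMatrix.from_dict(
            {"p0": {"safe": -2.0}, "p1": {"safe": 1.0}}, domains=["safe"])
        assert any("safe" in v for v in m.violations())
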