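"""Sensitivity analysis: weight sweeps with renormalization, parameter sweeps."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caredesign import (ConfigurationError, DEFAULT_WEIGHTS, DomainWeights,
                        aggregate_score, annual_cost, derive_parameter_values,
                        parameter_sweep, renormalize_weights, score_profile,
                        weight_sweep)

TABLE_WEIGHTS = DomainWeights(DEFAULT_WEIGHTS)


def _sweep(bundle, **kwargs):
    return weight_sweep(bundle.options["A"], bundle.options["B"], bundle.specs,
                        bundle.matrix, bundle.weights, bundle.unit_costs,
                        bundle.categories, **kwargs)


class TestWeightSweep:
    def test_zero_perturbation_reproduces_baseline(self, bundle):
        res = _sweep(bundle, domains=("safe",), deltas=(0.0,))
        (row,) = res.rows
        for cat, base in res.baseline_deltas.items():
            assert row.aggregate_deltas[cat] == pytest.approx(base, abs=1e-12)

    def test_every_emitted_weight_vector_is_valid(self, bundle):
        res = _sweep(bundle)
        for row in res.rows:
            total = sum(row.weights.as_dict().values())
            assert abs(total - 1.0) <= 1e-9
            assert all(w >= 0 for w in row.weights.as_dict().values())
            assert 0.0 <= bundle.weights[row.domain] + row.delta <= 1.0

    def test_out_of_range_perturbation_skipped_with_warning(self, bundle, caplog):
        with caplog.at_level(logging.WARNING, logger="caredesign.sensitivity"):
            res = _sweep(bundle, domains=("timely",), deltas=(-0.2, 0.1))
        # timely weight is 0.05; -0.2 would be negative and must be skipped
        assert [r.delta for r in res.rows] == [0.1]
        assert any("skipping" in r.message for r in caplog.records)

    def test_hand_arithmetic_on_synthetic_domain_deltas(self):
        """Domain deltas (10, 6, 4, 4, 7): original weights give
        0.5*10 + 0.3*6 + 0.05*4 + 0.05*4 + 0.1*7 = +7.9; moving safety
        0.5 -> 0.6 with proportional renormalization gives
        0.6*10 + 0.24*6 + 0.04*4 + 0.04*4 + 0.08*7 = +8.32."""
        deltas = {"safe": 10.0, "effective": 6.0, "timely": 4.0,
                  "equitable": 4.0, "person_centred": 7.0}
        assert aggregate_score(deltas, TABLE_WEIGHTS) == pytest.approx(7.9)
        perturbed = renormalize_weights(TABLE_WEIGHTS, "safe", 0.6)
        assert aggregate_score(deltas, perturbed) == pytest.approx(8.32)

    def test_equal_domain_deltas_are_weight_invariant(self):
        """If every domain improves by d, any weight vector aggregates to d."""
        deltas = {d: 5.5 for d in TABLE_WEIGHTS.as_dict()}
        for dom in ("safe", "effective"):
            for move in (0.1, 0.2, -0.1):
                w = renormalize_weights(TABLE_WEIGHTS, dom,
                                        TABLE_WEIGHTS[dom] + move)
                assert aggregate_score(deltas, w) == pytest.approx(5.5)

    def test_fixture_conclusion_is_robust(self, bundle):
        res = _sweep(bundle)
        assert res.rows  # sweep actually ran
        assert all(res.robustness.values())

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.1, 20.0), min_size=5, max_size=5),
           st.booleans())
    def test_shared_sign_implies_robust(self, magnitudes, negative):
        """Convexity: when all per-domain deltas share one sign, no convex
        weight combination can flip it, so the robustness flag must be true."""
        sign = -1.0 if negative else 1.0
        deltas = {d: sign * m for d, m in zip(TABLE_WEIGHTS.as_dict(), magnitudes)}
        values = [aggregate_score(deltas, TABLE_WEIGHTS)]
        for dom in ("safe", "effective", "person_centred"):
            for move in (-0.2, -0.1, 0.1, 0.2):
                target = TABLE_WEIGHTS[dom] + move
                if 0.0 <= target <= 1.0:
                    w = renormalize_weights(TABLE_WEIGHTS, dom, target)
                    values.append(aggregate_score(deltas, w))
        assert all(np.sign(v) == sign for v in values)


class TestParameterSweep:
    def test_unknown_parameter_rejected(self, bundle, option_a):
        with pytest.raises(ConfigurationError, match="nope"):
            parameter_sweep(option_a, "nope", [1.0], bundle.specs, bundle.matrix,
                            bundle.weights, bundle.unit_costs, bundle.categories)

    def test_grid_at_current_value_reproduces_baseline(self, bundle, option_a):
        x = derive_parameter_values(option_a, bundle.specs)
        current = x["1"]["home_visits"]
        df = parameter_sweep(option_a, "home_visits", [current], bundle.specs,
                             bundle.matrix, bundle.weights, bundle.unit_costs,
                             bundle.categories, category_id="1")
        profile = score_profile(x, bundle.specs, bundle.matrix, bundle.weights)
        cost = annual_cost(option_a, bundle.categories, bundle.unit_costs)
        row = df.iloc[0]
        assert row["aggregate"] == pytest.approx(profile.aggregates["1"])
        assert row["annual_cost"] == pytest.approx(
            cost.per_category["1"].annual_total)

    def test_scores_monotone_on_increasing_grid(self, bundle, option_a):
        df = parameter_sweep(option_a, "home_visits", [0, 2, 4, 6], bundle.specs,
                             bundle.matrix, bundle.weights, bundle.unit_costs,
                             bundle.categories, category_id="2&3")
        sub = df[df.category == "2&3"].sort_values("value")
        assert (sub["aggregate"].diff().dropna() >= -1e-12).all()
        assert (sub["annual_cost"].diff().dropna() >= -1e-9).all()

    def test_rows_match_one_at_a_time_recomputation(self, bundle, option_a):
        """Each row equals an independent single-point recomputation."""
        from caredesign import apply_parameter_value
        spec = next(s for s in bundle.specs if s.id == "home_visits")
        grid = [1.0, 3.0, 5.0]
        df = parameter_sweep(option_a, "home_visits", grid, bundle.specs,
                             bundle.matrix, bundle.weights, bundle.unit_costs,
                             bundle.categories, category_id="2&3")
        for value in grid:
            modified = apply_parameter_value(option_a, spec, "2&3", value)
            x = derive_parameter_values(modified, bundle.specs)
            profile = score_profile(x, bundle.specs, bundle.matrix,
                                    bundle.weights)
            cost = annual_cost(modified, bundle.categories, bundle.unit_costs)
            row = df[(df.value == value) & (df.category == "2&3")].iloc[0]
            assert row["aggregate"] == pytest.approx(profile.aggregates["2&3"],
                                                     abs=1e-12)
            assert row["annual_cost"] == pytest.approx(
                cost.per_category["2&3"].annual_total, abs=1e-9)
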