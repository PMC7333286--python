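import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funcan import (
    ComponentDef,
    ForcingProfile,
    ParameterSet,
    SpecError,
    SystemSpec,
    TermDef,
    build_reference_model,
    calibrate_by_phenomena,
    evaluate_rhs,
    validate_spec,
)
from funcan.system_spec import DEFAULT_PARAMETERS


class TestComponentAndTermDefs:
    def test_unknown_role_rejected(self):
        with pytest.raises(SpecError, match="role"):
            ComponentDef("x", role="parameter")

    def test_constant_decay_normalizes_sign_and_source(self):
        term = TermDef("x", "constant_decay", ["x"], "lam")
        assert term.sign == -1
        with pytest.raises(SpecError, match="source must be the target"):
            TermDef("x", "constant_decay", ["y"], "lam")

    def test_source_arity_enforced(self):
        with pytest.raises(SpecError, match="needs 2 sources"):
            TermDef("x", "bilinear", ["x"], "c")
        with pytest.raises(SpecError, match="needs 1 source"):
            TermDef("x", "linear", ["x", "y"], "c")

    def test_modulated_linear_requires_gain(self):
        with pytest.raises(SpecError, match="gain"):
            TermDef("x", "modulated_linear", ["u", "v"], "c")


class TestParameterSet:
    def test_missing_parameter_raises(self):
        ps = ParameterSet({"a": 1.0})
        with pytest.raises(SpecError, match="'b'"):
            ps["b"]

    def test_provenance_tracked(self):
        ps = ParameterSet({"a": 1.0}, default_provenance="calibrated")
        ps.set("b", 2.0, provenance="user")
        assert ps.provenance == {"a": "calibrated", "b": "user"}

    def test_updated_returns_copy(self):
        ps = ParameterSet({"a": 1.0})
        ps2 = ps.updated({"a": 3.0})
        assert ps["a"] == 1.0 and ps2["a"] == 3.0


class TestForcingProfile:
    def test_constant(self):
        f = ForcingProfile("constant", level=2.5)
        assert f.value(0.0) == 2.5
        assert f.value(123.0) == 2.5

    def test_pulses(self):
        f = ForcingProfile("pulses", level=1.0, pulses=[(1.0, 2.0), (5.0, 6.0)])
        assert f.value(0.5) == 0.0
        assert f.value(1.0) == 1.0
        assert f.value(2.0) == 0.0  # half-open window
        assert f.value(5.5) == 1.0
        assert sorted(f.discontinuities()) == [1.0, 2.0, 5.0, 6.0]

    def test_piecewise_holds_last_level(self):
        f = ForcingProfile("piecewise", breakpoints=[(0.0, 0.0), (10.0, 0.7)])
        assert f.value(9.99) == 0.0
        assert f.value(10.0) == 0.7
        assert f.value(50.0) == 0.7

    @given(st.floats(min_value=0.0, max_value=1e3),
           st.floats(min_value=0.0, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_everywhere(self, level, t):
        for f in (
            ForcingProfile("constant", level=level),
            ForcingProfile("pulses", level=level, pulses=[(1.0, 4.0)]),
            ForcingProfile("piecewise", breakpoints=[(0.0, level)]),
        ):
            assert f.value(t) >= 0.0


class TestReferenceModel:
    def test_scenario1_component_set(self):
        spec = build_reference_model(variant="scenario1")
        assert spec.exogenous_names == ["Sd"]
        assert spec.state_names == ["Rc", "Re", "Rb", "benefits", "costs", "cred_cat"]

    def test_prey_predator_signs(self):
        """Panic behaves as prey, avoidance as predator."""
        spec = build_reference_model()
        re_terms = [t for t in spec.terms
                    if t.target == "Re" and t.form == "bilinear"
                    and set(t.sources) == {"Re", "Rb"}]
        rb_terms = [t for t in spec.terms
                    if t.target == "Rb" and t.form == "bilinear"
                    and set(t.sources) == {"Re", "Rb"}]
        assert len(re_terms) == 1 and re_terms[0].sign == -1
        assert len(rb_terms) == 1 and rb_terms[0].sign == +1

    def test_augmented_adds_inhibition(self):
        spec = build_reference_model(variant="reappraisal_augmented")
        assert spec.has_component("cred_fun")
        inhib = [t for t in spec.terms
                 if t.target == "Rc" and "cred_fun" in t.sources]
        assert len(inhib) == 1 and inhib[0].sign == -1

    def test_increasing_cred_fun_strictly_decreases_rc_derivative(self):
        spec = build_reference_model(variant="reappraisal_augmented")
        names = spec.state_names
        state = np.ones(len(names))
        lo = np.array(state)
        hi = np.array(state)
        lo[names.index("cred_fun")] = 0.2
        hi[names.index("cred_fun")] = 0.8
        d_lo = evaluate_rhs(spec, lo, 1.0)
        d_hi = evaluate_rhs(spec, hi, 1.0)
        assert d_hi[names.index("Rc")] < d_lo[names.index("Rc")]

    def test_zero_couplings_zero_forcing_rhs_is_pure_decay(self):
        zeroed = {
            name: 0.0 for name in DEFAULT_PARAMETERS
            if not name.endswith("_decay")
        }
        params = ParameterSet({**DEFAULT_PARAMETERS, **zeroed})
        spec = build_reference_model(params=params, stimulus_level=0.0)
        decays = np.array([
            spec.parameters["catastrophizing_decay"],
            spec.parameters["panic_decay"],
            spec.parameters["avoidance_decay"],
            spec.parameters["benefit_decay"],
            spec.parameters["cost_decay"],
            spec.parameters["cred_cat_decay"],
        ])
        state = np.array([0.5, 0.4, 0.3, 0.2, 0.1, 0.6])
        np.testing.assert_allclose(
            evaluate_rhs(spec, state, 0.0), -decays * state, rtol=1e-12
        )
        np.testing.assert_allclose(
            evaluate_rhs(spec, np.zeros(6), 0.0), np.zeros(6), atol=0.0
        )

    def test_unknown_variant(self):
        with pytest.raises(SpecError, match="variant"):
            build_reference_model(variant="scenario9")

    def test_missing_coefficient_rejected(self):
        params = ParameterSet(
            {k: v for k, v in DEFAULT_PARAMETERS.items() if k != "panic_drive"}
        )
        with pytest.raises(SpecError, match="panic_drive"):
            build_reference_model(params=params)


class TestValidateSpec:
    def test_reference_specs_self_validate(self):
        for variant in ("scenario1", "reappraisal_augmented"):
            assert validate_spec(build_reference_model(variant=variant)) == []

    def test_term_targeting_exogenous_is_violation(self):
        spec = build_reference_model()
        spec.terms.append(TermDef("Sd", "linear", ["Rc"], "panic_drive"))
        violations = validate_spec(spec)
        assert any("Sd" in v for v in violations)

    def test_negative_decay_is_violation(self):
        spec = build_reference_model()
        spec.parameters.set("panic_decay", -0.5)
        violations = validate_spec(spec)
        assert any("panic_decay" in v for v in violations)

    def test_duplicate_component_name(self):
        spec = build_reference_model()
        spec.components.append(ComponentDef("Re"))
        assert any("more than once" in v for v in validate_spec(spec))

    def test_initial_value_outside_bounds(self):
        spec = build_reference_model()
        spec.component("cred_cat").initial_value = 1.5
        assert any("cred_cat" in v and "bounds" in v for v in validate_spec(spec))


class TestSerialization:
    @pytest.mark.parametrize("variant", ["scenario1", "reappraisal_augmented"])
    def test_round_trip_byte_identical(self, variant):
        spec = build_reference_model(variant=variant)
        once = spec.serialize()
        twice = SystemSpec.deserialize(once).serialize()
        assert once == twice

    def test_round_trip_preserves_semantics(self):
        spec = build_reference_model()
        clone = SystemSpec.deserialize(spec.serialize())
        assert clone == spec
        assert clone.parameters.provenance == spec.parameters.provenance
        assert clone.initial_state() == spec.initial_state()

    @given(st.floats(min_value=1e-3, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_round_trip_with_arbitrary_parameter_values(self, value):
        spec = build_reference_model(
            params=ParameterSet({**DEFAULT_PARAMETERS, "panic_drive": value})
        )
        once = spec.serialize()
        assert SystemSpec.deserialize(once).serialize() == once

    def test_spec_hash_stable_and_sensitive(self):
        a = build_reference_model()
        b = build_reference_model()
        assert a.spec_hash() == b.spec_hash()
        c = build_reference_model(
            params=ParameterSet({**DEFAULT_PARAMETERS, "panic_drive": 1.23})
        )
        assert c.spec_hash() != a.spec_hash()


class TestCalibration:
    def test_point_ranges_return_point_values(self):
        spec = build_reference_model()
        ranges = {"panic_drive": (1.0, 1.0), "panic_decay": (0.8, 0.8)}
        out = calibrate_by_phenomena(spec, ranges, budget=1, seed=0,
                                     t_max=10.0, dt_out=0.1)
        assert out["panic_drive"] == 1.0
        assert out["panic_decay"] == 0.8
        assert out.provenance["panic_drive"] == "calibrated"

    def test_deterministic_given_seed(self):
        spec = build_reference_model()
        ranges = {"panic_drive": (0.5, 1.5)}
        a = calibrate_by_phenomena(spec, ranges, budget=3, seed=42,
                                   t_max=10.0, dt_out=0.1)
        b = calibrate_by_phenomena(spec, ranges, budget=3, seed=42,
                                   t_max=10.0, dt_out=0.1)
        assert a.values == b.values

    def test_empty_ranges_rejected(self):
        spec = build_reference_model()
        with pytest.raises(SpecError, match="empty"):
            calibrate_by_phenomena(spec, {}, budget=5, seed=0)
        with pytest.raises(SpecError, match="budget"):
            calibrate_by_phenomena(spec, {"panic_drive": (0.5, 1.0)},
                                   budget=0, seed=0)

    def test_hopeless_spec_sets_warning_flag(self):
        # a system without the case-model components can never pass a
        # baseline check, so every evaluation scores zero
        spec = SystemSpec(
            components=[ComponentDef("x", initial_value=1.0)],
            terms=[TermDef("x", "constant_decay", ["x"], "lam")],
            parameters=ParameterSet({"lam": 0.5}),
        )
        out = calibrate_by_phenomena(spec, {"lam": (0.1, 1.0)}, budget=2,
                                     seed=1, t_max=10.0, dt_out=0.1)
        assert out.warning
        assert 0.1 <= out["lam"] <= 1.0

    def test_math_isfinite_guard(self):
        # degenerate spec must not crash the search
        spec = build_reference_model()
        ranges = {"avoidance_growth": (0.0, 0.0)}
        out = calibrate_by_phenomena(spec, ranges, budget=1, seed=0,
                                     t_max=5.0, dt_out=0.1)
        assert math.isfinite(out["avoidance_growth"])
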