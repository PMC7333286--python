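"""Declarative specification of idiographic dynamical systems.

A :class:`SystemSpec` bundles components (state or exogenous), interaction
terms drawn from a small term grammar (linear, bilinear, modulated linear,
constant decay), a named parameter set, and forcing profiles for exogenous
components.  :func:`build_reference_model` constructs the bundled
panic-disorder case model in two variants: the plain avoidance-maintenance
system and the reappraisal-augmented system that adds a competing functional
interpretation.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "ComponentDef",
    "Modulator",
    "TermDef",
    "ParameterSet",
    "ForcingProfile",
    "SystemSpec",
    "SpecError",
    "build_reference_model",
    "validate_spec",
    "calibrate_by_phenomena",
    "DEFAULT_PARAMETERS",
    "DEFAULT_INITIAL_VALUES",
    "CALIBRATION_NOTE",
]

TERM_FORMS = ("linear", "bilinear", "modulated_linear", "constant_decay")
ROLES = ("state", "exogenous")
PROVENANCES = ("supplement", "calibrated", "user")


class SpecError(ValueError):
    """Raised for malformed system specifications or parameter sets."""


@dataclass
class ComponentDef:
    """One system variable: a dynamic state or an exogenously forced input."""

    name: str
    label: str = ""
    role: str = "state"
    initial_value: float = 0.0
    lower_bound: float | None = None
    upper_bound: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SpecError(f"component {self.name!r}: unknown role {self.role!r}")
        if not self.label:
            self.label = self.name

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "label": self.label, "role": self.role}
        if self.lower_bound is not None:
            d["lower_bound"] = float(self.lower_bound)
        if self.upper_bound is not None:
            d["upper_bound"] = float(self.upper_bound)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ComponentDef":
        return cls(
            name=d["name"],
            label=d.get("label", d["name"]),
            role=d.get("role", "state"),
            lower_bound=d.get("lower_bound"),
            upper_bound=d.get("upper_bound"),
        )


@dataclass
class Modulator:
    """Multiplicative gain on a term: contributes ``sign * gain * value(source)``
    inside the factor ``max(0, 1 + sum(...))``."""

    source: str
    gain: str  # parameter name
    sign: int = 1

    def to_dict(self) -> dict:
        return {"source": self.source, "gain": self.gain, "sign": int(self.sign)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Modulator":
        return cls(source=d["source"], gain=d["gain"], sign=int(d.get("sign", 1)))


@dataclass
class TermDef:
    """One additive contribution to the derivative of ``target``.

    Forms:

    ``linear``
        ``sign * coeff * value(sources[0])``
    ``bilinear``
        ``sign * coeff * value(sources[0]) * value(sources[1])``
    ``modulated_linear``
        ``sign * coeff * value(sources[0]) * (1 + gain * value(sources[1]))``
    ``constant_decay``
        sugar for a negative linear self-term; ``sources = [target]``.

    Any form may additionally carry ``modulators``; their joint factor
    ``max(0, 1 + sum(sign_m * gain_m * value_m))`` scales the term, so
    modulation can silence but never reverse it.
    """

    target: str
    form: str
    sources: Sequence[str]
    coefficient: str  # parameter name
    sign: int = 1
    gain: str | None = None  # parameter name, modulated_linear only
    modulators: list[Modulator] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.form not in TERM_FORMS:
            raise SpecError(f"term on {self.target!r}: unknown form {self.form!r}")
        self.sources = list(self.sources)
        n = len(self.sources)
        if self.form in ("linear", "constant_decay") and n != 1:
            raise SpecError(f"term on {self.target!r}: {self.form} needs 1 source")
        if self.form in ("bilinear", "modulated_linear") and n != 2:
            raise SpecError(f"term on {self.target!r}: {self.form} needs 2 sources")
        if self.form == "modulated_linear" and self.gain is None:
            raise SpecError(f"term on {self.target!r}: modulated_linear needs a gain")
        if self.form == "constant_decay":
            self.sign = -1
            if self.sources != [self.target]:
                raise SpecError(
                    f"term on {self.target!r}: constant_decay source must be the target"
                )
        if self.sign not in (1, -1):
            raise SpecError(f"term on {self.target!r}: sign must be +1 or -1")

    def to_dict(self) -> dict:
        d: dict = {
            "target": self.target,
            "form": self.form,
            "sources": list(self.sources),
            "coefficient": self.coefficient,
            "sign": int(self.sign),
        }
        if self.gain is not None:
            d["gain"] = self.gain
        if self.modulators:
            d["modulators"] = [m.to_dict() for m in self.modulators]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TermDef":
        return cls(
            target=d["target"],
            form=d["form"],
            sources=list(d["sources"]),
            coefficient=d["coefficient"],
            sign=int(d.get("sign", 1)),
            gain=d.get("gain"),
            modulators=[Modulator.from_dict(m) for m in d.get("modulators", [])],
        )


class ParameterSet:
    """Named parameter values with per-value provenance tags."""

    def __init__(
        self,
        values: Mapping[str, float] | None = None,
        provenance: Mapping[str, str] | None = None,
        default_provenance: str = "user",
    ) -> None:
        self.values: dict[str, float] = {k: float(v) for k, v in (values or {}).items()}
        self.provenance: dict[str, str] = {}
        for name in self.values:
            tag = (provenance or {}).get(name, default_provenance)
            if tag not in PROVENANCES:
                raise SpecError(f"parameter {name!r}: unknown provenance {tag!r}")
            self.provenance[name] = tag
        #: set by calibrate_by_phenomena when no evaluated set passed any check
        self.warning: bool = False

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def __getitem__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise SpecError(f"parameter {name!r} is not defined") from None

    def set(self, name: str, value: float, provenance: str = "user") -> None:
        if provenance not in PROVENANCES:
            raise SpecError(f"parameter {name!r}: unknown provenance {provenance!r}")
        self.values[name] = float(value)
        self.provenance[name] = provenance

    def updated(self, values: Mapping[str, float], provenance: str = "user") -> "ParameterSet":
        """Return a copy with ``values`` overriding the current entries."""
        out = self.copy()
        for k, v in values.items():
            out.set(k, v, provenance)
        return out

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values), dict(self.provenance))

    def to_dict(self) -> dict:
        return {
            name: {"value": float(self.values[name]), "provenance": self.provenance[name]}
            for name in self.values
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        values, prov = {}, {}
        for name, entry in d.items():
            if isinstance(entry, Mapping):
                values[name] = float(entry["value"])
                prov[name] = entry.get("provenance", "user")
            else:
                values[name] = float(entry)
                prov[name] = "user"
        return cls(values, prov)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ParameterSet) and self.values == other.values

    def __repr__(self) -> str:
        return f"ParameterSet({self.values!r})"


@dataclass
class ForcingProfile:
    """Time course of an exogenous component.

    ``constant``: ``level`` for all t.  ``pulses``: ``level`` inside any
    ``[onset, offset)`` window, else 0.  ``piecewise``: step function holding
    the level of the latest breakpoint at or before t (0 before the first).
    """

    kind: str = "constant"
    level: float = 0.0
    pulses: list[tuple[float, float]] = field(default_factory=list)
    breakpoints: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "pulses", "piecewise"):
            raise SpecError(f"unknown forcing kind {self.kind!r}")
        self.pulses = [(float(a), float(b)) for a, b in self.pulses]
        self.breakpoints = sorted((float(t), float(v)) for t, v in self.breakpoints)

    def value(self, t: float) -> float:
        if self.kind == "constant":
            return self.level
        if self.kind == "pulses":
            for on, off in self.pulses:
                if on <= t < off:
                    return self.level
            return 0.0
        out = 0.0
        for bt, lv in self.breakpoints:
            if bt <= t:
                out = lv
            else:
                break
        return out

    def discontinuities(self) -> list[float]:
        """Times where the profile jumps (integration breakpoints)."""
        if self.kind == "pulses":
            return sorted({t for p in self.pulses for t in p})
        if self.kind == "piecewise":
            return [t for t, _ in self.breakpoints]
        return []

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.kind in ("constant", "pulses"):
            d["level"] = float(self.level)
        if self.kind == "pulses":
            d["pulses"] = [[float(a), float(b)] for a, b in self.pulses]
        if self.kind == "piecewise":
            d["breakpoints"] = [[float(t), float(v)] for t, v in self.breakpoints]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ForcingProfile":
        return cls(
            kind=d.get("kind", "constant"),
            level=float(d.get("level", 0.0)),
            pulses=[tuple(p) for p in d.get("pulses", [])],
            breakpoints=[tuple(b) for b in d.get("breakpoints", [])],
        )


class SystemSpec:
    """A full declarative system: components, terms, parameters, forcing."""

    def __init__(
        self,
        components: Iterable[ComponentDef],
        terms: Iterable[TermDef],
        parameters: ParameterSet,
        forcings: Mapping[str, ForcingProfile] | None = None,
        nonneg_clip: bool = True,
    ) -> None:
        self.components = list(components)
        self.terms = list(terms)
        self.parameters = parameters
        self.forcings = dict(forcings or {})
        self.nonneg_clip = bool(nonneg_clip)

    # -- component views -------------------------------------------------
    @property
    def state_components(self) -> list[ComponentDef]:
        return [c for c in self.components if c.role == "state"]

    @property
    def exogenous_components(self) -> list[ComponentDef]:
        return [c for c in self.components if c.role == "exogenous"]

    @property
    def state_names(self) -> list[str]:
        return [c.name for c in self.state_components]

    @property
    def exogenous_names(self) -> list[str]:
        return [c.name for c in self.exogenous_components]

    def component(self, name: str) -> ComponentDef:
        for c in self.components:
            if c.name == name:
                return c
        raise SpecError(f"unknown component {name!r}")

    def has_component(self, name: str) -> bool:
        return any(c.name == name for c in self.components)

    def initial_state(self) -> list[float]:
        return [c.initial_value for c in self.state_components]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "components": [c.to_dict() for c in self.components],
            "terms": [t.to_dict() for t in self.terms],
            "parameters": self.parameters.to_dict(),
            "initial_values": {
                c.name: float(c.initial_value) for c in self.state_components
            },
            "forcing": {name: f.to_dict() for name, f in self.forcings.items()},
            "nonneg_clip": self.nonneg_clip,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SystemSpec":
        components = [ComponentDef.from_dict(c) for c in d.get("components", [])]
        initial = d.get("initial_values", {})
        for c in components:
            if c.name in initial:
                c.initial_value = float(initial[c.name])
        return cls(
            components=components,
            terms=[TermDef.from_dict(t) for t in d.get("terms", [])],
            parameters=ParameterSet.from_dict(d.get("parameters", {})),
            forcings={
                name: ForcingProfile.from_dict(f)
                for name, f in d.get("forcing", {}).items()
            },
            nonneg_clip=bool(d.get("nonneg_clip", True)),
        )

    def serialize(self) -> str:
        """Canonical YAML text; write -> read -> write is byte-identical."""
        return yaml.safe_dump(self.to_dict(), sort_keys=False, default_flow_style=False)

    @classmethod
    def deserialize(cls, text: str) -> "SystemSpec":
        return cls.from_dict(yaml.safe_load(text) or {})

    def spec_hash(self) -> str:
        return hashlib.sha256(self.serialize().encode()).hexdigest()[:12]

    def copy(self) -> "SystemSpec":
        return SystemSpec.deserialize(self.serialize())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SystemSpec) and self.serialize() == other.serialize()


# ---------------------------------------------------------------------------
# Reference panic-disorder case model
# ---------------------------------------------------------------------------

#: Bundled defaults.  No authoritative parameterization is available for this
#: case model (units are arbitrary by design), so these values were obtained
#: by calibration: tuned until the full scenario check suite passes (see
#: CALIBRATION_NOTE), hence provenance "calibrated".
DEFAULT_PARAMETERS: dict[str, float] = {
    "catastrophizing_drive": 0.28,  # stimulus -> catastrophizing
    "cred_cat_gain": 8.0,           # amplification of that drive by belief
    "catastrophizing_decay": 0.8,
    "panic_drive": 1.0,             # catastrophizing -> panic
    "avoidance_relief": 0.1,        # panic removed per unit panic*avoidance
    "panic_decay": 0.8,
    "avoidance_growth": 0.55,       # panic*avoidance growth rate
    "benefit_gain": 0.05,           # perceived benefits amplify growth
    "cost_gain": 0.6,               # perceived costs damp growth
    "avoidance_decay": 0.08,
    "benefit_growth": 0.3,
    "benefit_decay": 2.0,
    "cost_growth": 0.36,
    "cost_decay": 0.35,
    "cred_cat_growth": 1.2,         # avoidance blocks falsification
    "cred_cat_decay": 0.4,
    "cred_competition": 1.2,        # functional belief erodes catastrophic one
    "cred_fun_growth": 0.9,         # reappraisal work builds functional belief
    "cred_fun_decay": 0.9,
    "reappraisal_inhibition": 2.6,  # functional belief inhibits catastrophizing
}

DEFAULT_INITIAL_VALUES: dict[str, float] = {
    "Rc": 0.0,
    "Re": 0.0,
    # bilinear growth cannot lift avoidance off exactly zero
    "Rb": 0.01,
    "benefits": 0.0,
    "costs": 0.0,
    # the patient enters with partial belief in the catastrophic
    # interpretation; amplification is active from the start
    "cred_cat": 0.4,
    "cred_fun": 0.0,
}

CALIBRATION_NOTE = (
    "defaults calibrated by phenomena: hand-guided search plus local refinement "
    "until all four scenario check suites pass with margin, the no-intervention "
    "run settles to a stable amplified state, and adaptive-RK/Euler trajectories "
    "agree within 1e-3"
)

VARIANTS = ("scenario1", "reappraisal_augmented")


def build_reference_model(
    params: ParameterSet | None = None,
    variant: str = "scenario1",
    initial_values: Mapping[str, float] | None = None,
    stimulus_level: float = 1.0,
) -> SystemSpec:
    """Build the bundled panic-disorder case model.

    ``scenario1`` contains the exogenous stimulus ``Sd`` plus states
    ``Rc`` (catastrophizing), ``Re`` (panic), ``Rb`` (avoidant coping),
    ``benefits``, ``costs`` and ``cred_cat`` (credibility of the catastrophic
    interpretation).  ``reappraisal_augmented`` adds ``cred_fun`` (credibility
    of a competing functional interpretation), the exogenous reappraisal
    input that builds it, an inhibitive term on catastrophizing, and a
    competition term on ``cred_cat``.
    """
    if variant not in VARIANTS:
        raise SpecError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if params is None:
        params = ParameterSet(DEFAULT_PARAMETERS, default_provenance="calibrated")
    init = dict(DEFAULT_INITIAL_VALUES)
    init.update(initial_values or {})

    components = [
        ComponentDef("Sd", "discriminant stimulus (heart racing)", "exogenous"),
        ComponentDef("Rc", "catastrophizing", "state", init["Rc"]),
        ComponentDef("Re", "panic", "state", init["Re"]),
        ComponentDef("Rb", "avoidant coping", "state", init["Rb"]),
        ComponentDef("benefits", "perceived benefits of avoidance", "state", init["benefits"]),
        ComponentDef("costs", "perceived costs of avoidance", "state", init["costs"]),
        ComponentDef(
            "cred_cat", "credibility of catastrophic interpretation", "state",
            init["cred_cat"], lower_bound=0.0, upper_bound=1.0,
        ),
    ]
    terms = [
        TermDef("Rc", "modulated_linear", ["Sd", "cred_cat"],
                "catastrophizing_drive", +1, gain="cred_cat_gain"),
        TermDef("Rc", "constant_decay", ["Rc"], "catastrophizing_decay"),
        TermDef("Re", "linear", ["Rc"], "panic_drive", +1),
        TermDef("Re", "bilinear", ["Re", "Rb"], "avoidance_relief", -1),
        TermDef("Re", "constant_decay", ["Re"], "panic_decay"),
        TermDef("Rb", "bilinear", ["Re", "Rb"], "avoidance_growth", +1,
                modulators=[
                    Modulator("benefits", "benefit_gain", +1),
                    Modulator("costs", "cost_gain", -1),
                ]),
        TermDef("Rb", "constant_decay", ["Rb"], "avoidance_decay"),
        TermDef("benefits", "bilinear", ["Re", "Rb"], "benefit_growth", +1),
        TermDef("benefits", "constant_decay", ["benefits"], "benefit_decay"),
        TermDef("costs", "linear", ["Rb"], "cost_growth", +1),
        TermDef("costs", "constant_decay", ["costs"], "cost_decay"),
        TermDef("cred_cat", "linear", ["Rb"], "cred_cat_growth", +1),
        TermDef("cred_cat", "constant_decay", ["cred_cat"], "cred_cat_decay"),
    ]
    forcings = {"Sd": ForcingProfile("constant", level=float(stimulus_level))}

    if variant == "reappraisal_augmented":
        components.append(
            ComponentDef(
                "cred_fun", "credibility of functional interpretation", "state",
                init["cred_fun"], lower_bound=0.0, upper_bound=1.0,
            )
        )
        components.append(
            ComponentDef("reappraisal_input", "reappraisal work intensity", "exogenous")
        )
        terms.extend([
            TermDef("Rc", "bilinear", ["cred_fun", "Sd"], "reappraisal_inhibition", -1),
            TermDef("cred_cat", "linear", ["cred_fun"], "cred_competition", -1),
            TermDef("cred_fun", "linear", ["reappraisal_input"], "cred_fun_growth", +1),
            TermDef("cred_fun", "constant_decay", ["cred_fun"], "cred_fun_decay"),
        ])
        forcings["reappraisal_input"] = ForcingProfile("constant", level=0.0)

    spec = SystemSpec(components, terms, params, forcings, nonneg_clip=True)
    violations = validate_spec(spec)
    if violations:
        raise SpecError("reference model failed validation: " + "; ".join(violations))
    return spec


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_spec(spec: SystemSpec) -> list[str]:
    """Return a list of invariant violations (empty iff the spec is valid)."""
    violations: list[str] = []
    names = [c.name for c in spec.components]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            violations.append(f"component {n!r} is defined more than once")
        seen.add(n)
    roles = {c.name: c.role for c in spec.components}

    for c in spec.components:
        lb = c.lower_bound if c.lower_bound is not None else -math.inf
        ub = c.upper_bound if c.upper_bound is not None else math.inf
        if lb > ub:
            violations.append(f"component {c.name!r}: lower_bound exceeds upper_bound")
        elif not (lb <= c.initial_value <= ub):
            violations.append(
                f"component {c.name!r}: initial value {c.initial_value} outside bounds"
            )
        if c.role == "state" and c.initial_value < 0 and spec.nonneg_clip:
            violations.append(f"component {c.name!r}: negative initial value")
        if c.role == "exogenous" and c.name not in spec.forcings:
            violations.append(f"exogenous component {c.name!r} has no forcing profile")

    targeted: set[str] = set()
    for t in spec.terms:
        targeted.add(t.target)
        if t.target not in roles:
            violations.append(f"term targets unknown component {t.target!r}")
        elif roles[t.target] != "state":
            violations.append(
                f"term targets exogenous component {t.target!r}; exogenous components "
                "are driven by forcing only"
            )
        for s in list(t.sources) + [m.source for m in t.modulators]:
            if s not in roles:
                violations.append(
                    f"term on {t.target!r} references unknown component {s!r}"
                )
        refs = [t.coefficient] + ([t.gain] if t.gain else []) + [m.gain for m in t.modulators]
        for p in refs:
            if p not in spec.parameters:
                violations.append(f"term on {t.target!r}: parameter {p!r} is undefined")
        if t.coefficient in spec.parameters:
            value = spec.parameters[t.coefficient]
            if t.form == "constant_decay":
                if value <= 0:
                    violations.append(
                        f"decay parameter {t.coefficient!r} must be strictly positive "
                        f"(got {value})"
                    )
            elif value < 0:
                violations.append(
                    f"coupling parameter {t.coefficient!r} must be non-negative "
                    f"(got {value})"
                )

    for c in spec.state_components:
        if c.name not in targeted:
            violations.append(
                f"state component {c.name!r} has no terms (declare it exogenous "
                "or give it dynamics)"
            )
    return violations


# ---------------------------------------------------------------------------
# Calibration fallback
# ---------------------------------------------------------------------------

def calibrate_by_phenomena(
    spec: SystemSpec,
    search_ranges: Mapping[str, tuple[float, float]],
    budget: int,
    seed: int,
    t_max: float = 50.0,
    dt_out: float = 0.05,
) -> ParameterSet:
    """Random-search parameters to maximize passed baseline phenomena checks.

    Samples each parameter in ``search_ranges`` uniformly (others keep their
    current value), simulates the no-intervention scenario and counts passed
    checks from the scenario-1 suite.  Returns the best parameter set, ties
    broken by earliest evaluation; deterministic given ``seed``.  If no
    evaluation passes a single check, the best-found set is returned with its
    ``warning`` flag set.
    """
    import numpy as np

    from .dynamics import integrate
    from .interventions import InterventionPlan
    from .phenomena import extract_features, run_checks

    if budget < 1:
        raise SpecError("calibration budget must be >= 1")
    if not search_ranges:
        raise SpecError("empty search ranges")
    for name, (lo, hi) in search_ranges.items():
        if hi < lo:
            raise SpecError(f"search range for {name!r} is empty ({lo} > {hi})")

    rng = np.random.default_rng(seed)
    plan = InterventionPlan.baseline()
    names = list(search_ranges)
    best_score = -1
    best_values: dict[str, float] | None = None
    for _ in range(budget):
        draw = {
            n: float(rng.uniform(*search_ranges[n])) if search_ranges[n][0] != search_ranges[n][1]
            else float(search_ranges[n][0])
            for n in names
        }
        candidate = spec.parameters.updated(draw, provenance="calibrated")
        trial = spec.copy()
        trial.parameters = candidate
        try:
            traj = integrate(trial, plan, t_max=t_max, dt_out=dt_out)
            report = extract_features(traj, plan)
            score = sum(r.passed for r in run_checks(report, "baseline"))
        except Exception:
            score = 0
        if score > best_score:
            best_score = score
            best_values = draw
    assert best_values is not None
    result = spec.parameters.updated(best_values, provenance="calibrated")
    result.warning = best_score == 0
    return result
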