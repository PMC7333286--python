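"""Formalized clinical interventions and the bundled scenario definitions.

Exposure is a behavioral prescription: the avoidant-coping state ``Rb`` is
clamped (default to 0) from its onset, enforced exactly by the integrator.
Cognitive reappraisal drives the credibility of a competing functional
interpretation (``cred_fun``) via a stepped exogenous input from its onset.
``cbt`` composes both.  The two transformations touch disjoint structure, so
they commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .system_spec import (
    DEFAULT_PARAMETERS,
    ForcingProfile,
    ParameterSet,
    SpecError,
    SystemSpec,
    build_reference_model,
)

__all__ = [
    "ExposureSettings",
    "ReappraisalSettings",
    "InterventionPlan",
    "apply_exposure",
    "apply_reappraisal",
    "make_scenario",
    "SCENARIO_NAMES",
    "DEFAULT_ONSET",
]

SCENARIO_NAMES = ("baseline", "exposure", "reappraisal", "cbt")

#: Default intervention onset: one quarter of the default 50-unit horizon,
#: leaving room for pre-intervention buildup and long-term follow-up.
DEFAULT_ONSET = 12.5

EXPOSURE_MODES = ("clamp", "disable_growth")


@dataclass
class ExposureSettings:
    active: bool = False
    onset: float = DEFAULT_ONSET
    offset: float | None = None  # None = permanent from onset
    clamp_value: float = 0.0
    mode: str = "clamp"

    def __post_init__(self) -> None:
        if self.mode not in EXPOSURE_MODES:
            raise SpecError(f"unknown exposure mode {self.mode!r}")

    def to_dict(self) -> dict:
        d: dict = {
            "active": bool(self.active),
            "onset": float(self.onset),
            "clamp_value": float(self.clamp_value),
            "mode": self.mode,
        }
        if self.offset is not None:
            d["offset"] = float(self.offset)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExposureSettings":
        return cls(
            active=bool(d.get("active", False)),
            onset=float(d.get("onset", DEFAULT_ONSET)),
            offset=None if d.get("offset") is None else float(d["offset"]),
            clamp_value=float(d.get("clamp_value", 0.0)),
            mode=d.get("mode", "clamp"),
        )


@dataclass
class ReappraisalSettings:
    active: bool = False
    onset: float = DEFAULT_ONSET
    input_level: float = 1.0

    def to_dict(self) -> dict:
        return {
            "active": bool(self.active),
            "onset": float(self.onset),
            "input_level": float(self.input_level),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReappraisalSettings":
        return cls(
            active=bool(d.get("active", False)),
            onset=float(d.get("onset", DEFAULT_ONSET)),
            input_level=float(d.get("input_level", 1.0)),
        )


@dataclass
class InterventionPlan:
    """Which interventions are active, when, and with what settings."""

    scenario_name: str = "baseline"
    exposure: ExposureSettings = field(default_factory=ExposureSettings)
    reappraisal: ReappraisalSettings = field(default_factory=ReappraisalSettings)

    def __post_init__(self) -> None:
        if self.scenario_name not in SCENARIO_NAMES:
            raise SpecError(f"unknown scenario {self.scenario_name!r}")

    # -- constructors ----------------------------------------------------
    @classmethod
    def baseline(cls) -> "InterventionPlan":
        return cls("baseline")

    @classmethod
    def for_scenario(
        cls,
        name: str,
        onset: float = DEFAULT_ONSET,
        offset: float | None = None,
        clamp_value: float = 0.0,
        input_level: float = 1.0,
        exposure_mode: str = "clamp",
    ) -> "InterventionPlan":
        if name not in SCENARIO_NAMES:
            raise SpecError(f"unknown scenario {name!r}")
        exp = ExposureSettings(
            active=name in ("exposure", "cbt"),
            onset=onset, offset=offset, clamp_value=clamp_value, mode=exposure_mode,
        )
        rea = ReappraisalSettings(
            active=name in ("reappraisal", "cbt"), onset=onset, input_level=input_level,
        )
        return cls(name, exp, rea)

    # -- queries ---------------------------------------------------------
    def active_onsets(self) -> list[float]:
        out = []
        if self.exposure.active:
            out.append(self.exposure.onset)
        if self.reappraisal.active:
            out.append(self.reappraisal.onset)
        return out

    def earliest_onset(self) -> float | None:
        onsets = self.active_onsets()
        return min(onsets) if onsets else None

    def breakpoints(self, t_max: float) -> list[float]:
        """Intervention discontinuity times inside (0, t_max)."""
        pts = set(self.active_onsets())
        if self.exposure.active and self.exposure.offset is not None:
            pts.add(self.exposure.offset)
        return sorted(p for p in pts if 0.0 < p < t_max)

    def validate(self, t_max: float) -> list[str]:
        violations = []
        if self.scenario_name == "baseline" and (
            self.exposure.active or self.reappraisal.active
        ):
            violations.append("baseline plan must have no active interventions")
        for label, active, onset in (
            ("exposure", self.exposure.active, self.exposure.onset),
            ("reappraisal", self.reappraisal.active, self.reappraisal.onset),
        ):
            if active and not (0.0 < onset < t_max):
                violations.append(
                    f"{label} onset {onset} must lie strictly inside (0, {t_max})"
                )
        if self.exposure.active and self.exposure.offset is not None:
            if self.exposure.offset <= self.exposure.onset:
                violations.append("exposure offset must exceed onset")
        return violations

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "scenario_name": self.scenario_name,
            "exposure": self.exposure.to_dict(),
            "reappraisal": self.reappraisal.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "InterventionPlan":
        return cls(
            scenario_name=d.get("scenario_name", "baseline"),
            exposure=ExposureSettings.from_dict(d.get("exposure", {})),
            reappraisal=ReappraisalSettings.from_dict(d.get("reappraisal", {})),
        )


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def apply_exposure(spec: SystemSpec, plan: InterventionPlan) -> SystemSpec:
    """Validate and attach the exposure rule.

    Exposure is a *state rule* carried by the plan (clamp ``Rb`` from onset),
    enforced exactly at integration time, so the spec itself is returned
    unchanged.  Raises if the plan is active but the spec has no avoidance
    component to clamp.
    """
    if not plan.exposure.active:
        return spec
    if not spec.has_component("Rb"):
        raise SpecError("exposure requires an avoidance component 'Rb' in the spec")
    return spec


def apply_reappraisal(spec: SystemSpec, plan: InterventionPlan) -> SystemSpec:
    """Return a spec in which reappraisal work drives ``cred_fun`` from onset.

    The spec must be (or be upgradable to) the reappraisal-augmented variant.
    A plain reference spec is upgraded by rebuilding with the augmented term
    set under the same parameters and initial values.  The reappraisal input
    is a step: 0 before onset, ``input_level`` from onset on.
    """
    if not plan.reappraisal.active:
        return spec
    if not (spec.has_component("cred_fun") and spec.has_component("reappraisal_input")):
        reference_names = {"Sd", "Rc", "Re", "Rb", "benefits", "costs", "cred_cat"}
        if not reference_names <= {c.name for c in spec.components}:
            raise SpecError(
                "reappraisal requires the augmented variant (cred_fun), and this "
                "spec cannot be upgraded automatically"
            )
        init = {c.name: c.initial_value for c in spec.state_components}
        stim = spec.forcings["Sd"].level if "Sd" in spec.forcings else 1.0
        spec = build_reference_model(
            params=spec.parameters.copy(),
            variant="reappraisal_augmented",
            initial_values=init,
            stimulus_level=stim,
        )
    out = spec.copy()
    out.parameters = spec.parameters.copy()
    out.forcings["reappraisal_input"] = ForcingProfile(
        "piecewise",
        breakpoints=[(0.0, 0.0), (plan.reappraisal.onset, plan.reappraisal.input_level)],
    )
    return out


# ---------------------------------------------------------------------------
# Bundled scenarios
# ---------------------------------------------------------------------------

_OVERRIDE_KEYS = {
    "onset", "offset", "clamp_value", "input_level", "exposure_mode",
    "parameters", "initial_values", "stimulus_level",
}


def make_scenario(
    name: str, overrides: Mapping | None = None
) -> tuple[SystemSpec, InterventionPlan]:
    """Resolve a bundled scenario to a (spec, plan) pair.

    ``overrides`` may set intervention settings (``onset``, ``offset``,
    ``clamp_value``, ``input_level``, ``exposure_mode``), ``parameters``
    (mapping of existing parameter names to values), ``initial_values``,
    and ``stimulus_level``.
    """
    if name not in SCENARIO_NAMES:
        raise SpecError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    overrides = dict(overrides or {})
    unknown = set(overrides) - _OVERRIDE_KEYS
    if unknown:
        raise SpecError(f"unknown scenario override(s): {sorted(unknown)}")

    params = ParameterSet(dict(DEFAULT_PARAMETERS), default_provenance="calibrated")
    new_values = overrides.get("parameters", {})
    for pname in new_values:
        if pname not in params:
            raise SpecError(f"parameter override references unknown parameter {pname!r}")
    params = params.updated(new_values, provenance="user")

    variant = "scenario1" if name in ("baseline", "exposure") else "reappraisal_augmented"
    spec = build_reference_model(
        params=params,
        variant=variant,
        initial_values=overrides.get("initial_values"),
        stimulus_level=overrides.get("stimulus_level", 1.0),
    )
    plan = InterventionPlan.for_scenario(
        name,
        onset=overrides.get("onset", DEFAULT_ONSET),
        offset=overrides.get("offset"),
        clamp_value=overrides.get("clamp_value", 0.0),
        input_level=overrides.get("input_level", 1.0),
        exposure_mode=overrides.get("exposure_mode", "clamp"),
    )
    spec = apply_exposure(spec, plan)
    spec = apply_reappraisal(spec, plan)
    return spec, plan
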