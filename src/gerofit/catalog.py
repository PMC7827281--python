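"""Exercise catalog: movement templates and elderly-adapted tolerance profiles.

The shipped catalog holds 52 parameterized exercises — 29 for the shoulder
(flexion, abduction, rotation and isometric scapular retraction) and 23 for
the knee (double-leg squat, extension, retraction, protraction) — generated
systematically as template instances (movement × side × target variant).
Two tolerance profiles are shipped: ``elderly`` (torso tilt up to 20°, knee
deviation up to 10 cm) and ``strict`` (5° and 0 cm, the margins for young
adults without injury).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .errors import CatalogError
from .skeleton import JointId

CATALOG_FORMAT_VERSION = 1

Family = Literal["shoulder", "knee"]
Template = Literal["concentric_angle", "isometric_hold", "posture_constrained_squat"]

_SHOULDER_JOINTS = {
    "SHOULDER_LEFT", "SHOULDER_RIGHT", "ELBOW_LEFT", "ELBOW_RIGHT",
    "WRIST_LEFT", "WRIST_RIGHT", "HAND_LEFT", "HAND_RIGHT", "SPINE_SHOULDER",
}
_KNEE_JOINTS = {
    "HIP_LEFT", "HIP_RIGHT", "KNEE_LEFT", "KNEE_RIGHT",
    "ANKLE_LEFT", "ANKLE_RIGHT", "FOOT_LEFT", "FOOT_RIGHT",
}


class ToleranceProfile(BaseModel):
    """Margins within which posture deviations do not invalidate a repetition.

    ``retraction_k`` is the time shift (in frames) of the isometric
    scapular-retraction conditions and ``retraction_epsilon`` the symmetry
    allowance between the two shoulder–sternum distances; small values make
    the rules demanding, larger values more permissive.
    """

    name: str
    torso_tilt_limit_deg: float = Field(ge=0)
    knee_deviation_limit_cm: float = Field(ge=0)
    angular_goal_tolerance_deg: float = Field(ge=0)
    retraction_k_frames: int = Field(gt=0)
    retraction_epsilon_m: float = Field(gt=0)


#: Margins relaxed for the reduced body competence of older users.
ELDERLY = ToleranceProfile(
    name="elderly",
    torso_tilt_limit_deg=20.0,
    knee_deviation_limit_cm=10.0,
    angular_goal_tolerance_deg=5.0,
    retraction_k_frames=10,
    retraction_epsilon_m=0.03,
)

#: Margins for young adults without injury.
STRICT = ToleranceProfile(
    name="strict",
    torso_tilt_limit_deg=5.0,
    knee_deviation_limit_cm=0.0,
    angular_goal_tolerance_deg=2.0,
    retraction_k_frames=10,
    retraction_epsilon_m=0.03,
)

_PROFILES = {"elderly": ELDERLY, "strict": STRICT}


def get_profile(name: str) -> ToleranceProfile:
    try:
        return _PROFILES[name]
    except KeyError:
        raise CatalogError(
            f"unknown tolerance profile {name!r}; available: {sorted(_PROFILES)}"
        ) from None


class ExerciseSpec(BaseModel):
    """One catalog entry: a movement template with its control parameters.

    ``target`` is degrees for angular templates and seconds for isometric
    holds.  ``repetitions`` follows the standard prescription of 10–15
    repetitions per series, three series per session.
    """

    id: str
    name: str
    family: Family
    template: Template
    controlled_joints: list[str]
    side: Literal["left", "right", "both"] = "both"
    target: float = Field(gt=0)
    repetitions: int = Field(ge=10, le=15)
    series: int = Field(default=3, ge=1)
    tolerance: ToleranceProfile = ELDERLY

    @field_validator("controlled_joints")
    @classmethod
    def _joints_exist(cls, joints: list[str]) -> list[str]:
        for j in joints:
            if j not in JointId.__members__:
                raise ValueError(f"unknown joint {j!r}")
        return joints

    @model_validator(mode="after")
    def _family_consistent(self) -> "ExerciseSpec":
        allowed = _SHOULDER_JOINTS if self.family == "shoulder" else _KNEE_JOINTS
        bad = [j for j in self.controlled_joints if j not in allowed]
        if bad:
            raise ValueError(f"joints {bad} inconsistent with family {self.family!r}")
        if self.template == "posture_constrained_squat" and self.family != "knee":
            raise ValueError("posture_constrained_squat is a knee-family template")
        if self.template == "concentric_angle" and self.side == "both":
            raise ValueError("concentric_angle exercises are single-sided")
        return self


def _arm_joints(side: str) -> list[str]:
    s = side.upper()
    return [f"SHOULDER_{s}", f"ELBOW_{s}", f"WRIST_{s}"]


def _leg_joints(side: str) -> list[str]:
    s = side.upper()
    return [f"HIP_{s}", f"KNEE_{s}", f"ANKLE_{s}"]


def default_catalog(tolerance: ToleranceProfile = ELDERLY) -> list[ExerciseSpec]:
    """The shipped catalog of 52 exercises (29 shoulder + 23 knee).

    The individual prescriptions are systematically generated placeholder
    instances of the three templates, faithful to the movement families and
    counts of the implemented exercise set.
    """
    entries: list[ExerciseSpec] = []

    def add(**kw) -> None:
        entries.append(ExerciseSpec(tolerance=tolerance, **kw))

    # Shoulder: 3 concentric movements × 2 sides × 4 targets = 24
    for movement in ("flexion", "abduction", "rotation"):
        for side in ("left", "right"):
            for target in (60.0, 90.0, 120.0, 150.0):
                add(
                    id=f"shoulder_{movement}_{side}_{int(target)}",
                    name=f"Shoulder {movement} ({side}, {int(target)}°)",
                    family="shoulder",
                    template="concentric_angle",
                    controlled_joints=_arm_joints(side) + ["SPINE_SHOULDER"],
                    side=side,
                    target=target,
                    repetitions=12,
                )
    # Shoulder: 5 isometric scapular-retraction holds → 29 total
    for hold in (10.0, 15.0, 20.0, 25.0, 30.0):
        add(
            id=f"scapular_retraction_{int(hold)}s",
            name=f"Scapular retraction (hold {int(hold)} s)",
            family="shoulder",
            template="isometric_hold",
            controlled_joints=["SHOULDER_LEFT", "SPINE_SHOULDER", "SHOULDER_RIGHT"],
            side="both",
            target=hold,
            repetitions=10,
        )

    # Knee: 5 double-leg squats
    for target in (90.0, 100.0, 110.0, 120.0, 130.0):
        add(
            id=f"double_leg_squat_{int(target)}",
            name=f"Double leg squat (to {int(target)}°)",
            family="knee",
            template="posture_constrained_squat",
            controlled_joints=_leg_joints("left") + _leg_joints("right"),
            side="both",
            target=target,
            repetitions=12,
        )
    # Knee: extension 2 sides × 4 targets = 8
    for side in ("left", "right"):
        for target in (120.0, 135.0, 150.0, 165.0):
            add(
                id=f"knee_extension_{side}_{int(target)}",
                name=f"Knee extension ({side}, {int(target)}°)",
                family="knee",
                template="concentric_angle",
                controlled_joints=_leg_joints(side),
                side=side,
                target=target,
                repetitions=12,
            )
    # Knee: retraction 2 × 3 = 6, protraction 2 × 2 = 4 → 23 total
    for side in ("left", "right"):
        for target in (100.0, 120.0, 140.0):
            add(
                id=f"knee_retraction_{side}_{int(target)}",
                name=f"Knee retraction ({side}, {int(target)}°)",
                family="knee",
                template="concentric_angle",
                controlled_joints=_leg_joints(side),
                side=side,
                target=target,
                repetitions=10,
            )
    for side in ("left", "right"):
        for target in (110.0, 130.0):
            add(
                id=f"knee_protraction_{side}_{int(target)}",
                name=f"Knee protraction ({side}, {int(target)}°)",
                family="knee",
                template="concentric_angle",
                controlled_joints=_leg_joints(side),
                side=side,
                target=target,
                repetitions=10,
            )
    return entries


# ---------------------------------------------------------------------------
# Catalog (de)serialization
# ---------------------------------------------------------------------------


def load_catalog(source: "str | Path | dict | None") -> list[ExerciseSpec]:
    """Load a catalog from a YAML path or an already-parsed document.

    An empty document yields an empty catalog.  A malformed entry raises
    :class:`CatalogError` naming the entry and field.
    """
    if isinstance(source, (str, Path)):
        doc = yaml.safe_load(Path(source).read_text())
    else:
        doc = source
    if doc is None:
        return []
    if not isinstance(doc, dict) or "exercises" not in doc:
        raise CatalogError("catalog document must contain an 'exercises' list")
    version = doc.get("version", CATALOG_FORMAT_VERSION)
    if version != CATALOG_FORMAT_VERSION:
        raise CatalogError(f"unsupported catalog version {version!r}")
    specs = []
    for i, entry in enumerate(doc["exercises"] or []):
        try:
            specs.append(ExerciseSpec.model_validate(entry))
        except ValidationError as exc:
            label = entry.get("id", f"#{i}") if isinstance(entry, dict) else f"#{i}"
            fields = ", ".join(
                ".".join(str(p) for p in err["loc"]) or "(entry)"
                for err in exc.errors()
            )
            raise CatalogError(
                f"invalid catalog entry {label!r}: field(s) {fields}: {exc}"
            ) from exc
    return specs


def save_catalog(specs: list[ExerciseSpec], path: "str | Path") -> None:
    doc = {
        "version": CATALOG_FORMAT_VERSION,
        "exercises": [s.model_dump() for s in specs],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def find_exercise(specs: list[ExerciseSpec], exercise_id: str) -> ExerciseSpec:
    for s in specs:
        if s.id == exercise_id:
            return s
    raise CatalogError(f"exercise {exercise_id!r} not in catalog")
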