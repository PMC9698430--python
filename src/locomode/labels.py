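"""Closed label vocabularies for locomotion classification.

Three vocabularies are used throughout the pipeline:

* **Locomotion modes** — the seven steady-state activities: sitting (S),
  standing (ST), level-ground walking (W), ramp ascent/descent (RA/RD) and
  stair ascent/descent (SA/SD).  Sitting and standing are *static* modes and
  carry no gait-phase information.
* **Transitions** — ordered mode pairs such as ``W-S`` (walking to sitting).
  Which transitions exist is a property of a data set, not of the taxonomy,
  so a :class:`LabelSchema` enumerates an explicit allowed set.  Two schema
  instances ship as constants: :data:`ENABL3S_SCHEMA` (12 transitions, 27
  gait phases) and :data:`MYLEG_SCHEMA` (19 transitions, no phase labels).
* **Gait phases** — sub-intervals of the gait cycle per non-static mode:
  walking has seven (``W1``..``W7``), each ramp/stair mode has five.

Composite labels join an activity (steady mode or transition) with a gait
phase of the activity's *starting* mode, rendered e.g. ``"W to ST-W6"``.
Plain ASCII hyphens are used in all rendered labels for file-format safety.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping


class SchemaError(ValueError):
    """A label or mode is not part of the schema in use."""


class LocomotionMode(Enum):
    """The seven locomotion modes, identified by their short code."""

    SITTING = "S"
    STANDING = "ST"
    WALKING = "W"
    RAMP_ASCENT = "RA"
    RAMP_DESCENT = "RD"
    STAIR_ASCENT = "SA"
    STAIR_DESCENT = "SD"

    @property
    def code(self) -> str:
        return self.value

    @property
    def is_static(self) -> bool:
        """True for modes without gait phases (sitting, standing)."""
        return self in (LocomotionMode.SITTING, LocomotionMode.STANDING)

    @classmethod
    def from_code(cls, code: str) -> "LocomotionMode":
        try:
            return cls(code)
        except ValueError:
            raise SchemaError(f"unknown locomotion mode code {code!r}") from None

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True, order=True)
class TransitionLabel:
    """An ordered transition between two distinct locomotion modes."""

    from_mode: LocomotionMode
    to_mode: LocomotionMode

    def __post_init__(self) -> None:
        if self.from_mode == self.to_mode:
            raise SchemaError(
                f"transition endpoints must differ, got {self.from_mode.code!r} twice"
            )

    def __str__(self) -> str:
        return f"{self.from_mode.code}-{self.to_mode.code}"

    @classmethod
    def parse(cls, text: str) -> "TransitionLabel":
        parts = text.split("-")
        if len(parts) != 2:
            raise SchemaError(f"cannot parse transition label {text!r}")
        return cls(LocomotionMode.from_code(parts[0]), LocomotionMode.from_code(parts[1]))


@dataclass(frozen=True, order=True)
class GaitPhaseLabel:
    """Gait phase ``index`` (1-based) of a non-static locomotion mode."""

    mode: LocomotionMode
    index: int

    def __post_init__(self) -> None:
        if self.mode.is_static:
            raise SchemaError(f"static mode {self.mode.code} has no gait phases")
        if self.index < 1:
            raise SchemaError(f"gait phase index must be >= 1, got {self.index}")

    def __str__(self) -> str:
        return f"{self.mode.code}{self.index}"

    @classmethod
    def parse(cls, text: str) -> "GaitPhaseLabel":
        head = text.rstrip("0123456789")
        tail = text[len(head):]
        if not tail:
            raise SchemaError(f"cannot parse gait phase label {text!r}")
        return cls(LocomotionMode.from_code(head), int(tail))


@dataclass(frozen=True)
class ActivityLabel:
    """A steady mode (``from_mode == to_mode``) or a transition.

    Level-1 and level-2A classification treat steady modes and transitions
    uniformly: a steady walking window is the activity ``W-W`` while a
    walking-to-standing transition window is ``W-ST``.
    """

    from_mode: LocomotionMode
    to_mode: LocomotionMode

    @property
    def is_steady(self) -> bool:
        return self.from_mode == self.to_mode

    @property
    def level1_mode(self) -> LocomotionMode:
        """The mode this activity maps to in the level-1 pre-classifier."""
        return self.from_mode

    def __str__(self) -> str:
        return f"{self.from_mode.code}-{self.to_mode.code}"

    @classmethod
    def steady(cls, mode: LocomotionMode) -> "ActivityLabel":
        return cls(mode, mode)

    @classmethod
    def parse(cls, text: str) -> "ActivityLabel":
        parts = text.split("-")
        if len(parts) != 2:
            raise SchemaError(f"cannot parse activity label {text!r}")
        return cls(LocomotionMode.from_code(parts[0]), LocomotionMode.from_code(parts[1]))


@dataclass(frozen=True)
class CompositeLabel:
    """Final system output: an activity plus (optionally) a gait phase.

    Rendered as ``"W to ST-W6"`` for a walking-to-standing transition in
    walking gait phase 6, or ``"S to S"`` for steady sitting (static modes
    carry no phase).
    """

    activity: ActivityLabel
    phase: GaitPhaseLabel | None = None

    def __post_init__(self) -> None:
        if self.phase is not None and self.phase.mode != self.activity.from_mode:
            raise SchemaError(
                f"phase {self.phase} does not belong to the activity's starting "
                f"mode {self.activity.from_mode.code}"
            )

    def __str__(self) -> str:
        head = f"{self.activity.from_mode.code} to {self.activity.to_mode.code}"
        if self.phase is None:
            return head
        return f"{head}-{self.phase}"

    @classmethod
    def parse(cls, text: str) -> "CompositeLabel":
        try:
            from_part, rest = text.split(" to ")
        except ValueError:
            raise SchemaError(f"cannot parse composite label {text!r}") from None
        if "-" in rest:
            to_part, phase_part = rest.split("-", 1)
            phase = GaitPhaseLabel.parse(phase_part)
        else:
            to_part, phase = rest, None
        activity = ActivityLabel(
            LocomotionMode.from_code(from_part), LocomotionMode.from_code(to_part)
        )
        return cls(activity, phase)


def compose_label(activity: ActivityLabel, phase: GaitPhaseLabel | None = None) -> CompositeLabel:
    """Join an activity with a gait phase into a composite label.

    The phase, when given, must belong to the activity's starting mode;
    static starting modes take no phase.
    """
    if phase is not None and activity.from_mode.is_static:
        raise SchemaError(
            f"static mode {activity.from_mode.code} cannot carry gait phase {phase}"
        )
    return CompositeLabel(activity, phase)


# Default phase counts: walking has 7 phases, ramps and stairs 5 each.
_DEFAULT_PHASE_COUNTS: dict[LocomotionMode, int] = {
    LocomotionMode.WALKING: 7,
    LocomotionMode.RAMP_ASCENT: 5,
    LocomotionMode.RAMP_DESCENT: 5,
    LocomotionMode.STAIR_ASCENT: 5,
    LocomotionMode.STAIR_DESCENT: 5,
}


@dataclass(frozen=True)
class LabelSchema:
    """A dataset's label vocabulary: modes, allowed transitions, phase counts.

    ``transitions`` is an explicit ordered set; its declaration order fixes
    the softmax class order of every level-2A network (steady label first,
    then that mode's transitions in declaration order), so it must be stable.
    ``phases_per_mode`` maps each non-static mode to its number of gait
    phases; an empty mapping means the dataset carries no phase labels and
    level 2B is skipped.
    """

    name: str
    modes: tuple[LocomotionMode, ...]
    transitions: tuple[TransitionLabel, ...]
    phases_per_mode: Mapping[LocomotionMode, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.modes)) != len(self.modes):
            raise SchemaError("duplicate modes in schema")
        for t in self.transitions:
            if t.from_mode not in self.modes or t.to_mode not in self.modes:
                raise SchemaError(f"transition {t} uses a mode outside the schema")
        if len(set(self.transitions)) != len(self.transitions):
            raise SchemaError("duplicate transitions in schema")
        for mode, n in self.phases_per_mode.items():
            if mode.is_static:
                raise SchemaError(f"static mode {mode.code} cannot have gait phases")
            if mode not in self.modes or n < 1:
                raise SchemaError(f"invalid phase count {n} for mode {mode.code}")

    # -- membership ---------------------------------------------------------

    def require_mode(self, mode: LocomotionMode) -> None:
        if mode not in self.modes:
            raise SchemaError(f"mode {mode.code} is not part of schema {self.name!r}")

    def allows_transition(self, from_mode: LocomotionMode, to_mode: LocomotionMode) -> bool:
        return TransitionLabel(from_mode, to_mode) in self.transitions

    @property
    def has_phases(self) -> bool:
        return bool(self.phases_per_mode)

    def n_phases(self, mode: LocomotionMode) -> int:
        return 0 if mode.is_static else self.phases_per_mode.get(mode, 0)

    def gait_phases(self, mode: LocomotionMode) -> list[GaitPhaseLabel]:
        """All gait phases of ``mode`` in temporal order (empty if none)."""
        return [GaitPhaseLabel(mode, i) for i in range(1, self.n_phases(mode) + 1)]

    # -- serialization ------------------------------------------------------

    def to_config(self) -> dict:
        return {
            "name": self.name,
            "modes": [m.code for m in self.modes],
            "transitions": [str(t) for t in self.transitions],
            "phases_per_mode": {m.code: n for m, n in self.phases_per_mode.items()},
        }

    @classmethod
    def from_config(cls, config: Mapping) -> "LabelSchema":
        return cls(
            name=config["name"],
            modes=tuple(LocomotionMode.from_code(c) for c in config["modes"]),
            transitions=tuple(TransitionLabel.parse(t) for t in config["transitions"]),
            phases_per_mode={
                LocomotionMode.from_code(c): int(n)
                for c, n in config.get("phases_per_mode", {}).items()
            },
        )


def enumerate_level2a_classes(schema: LabelSchema, mode: LocomotionMode) -> list[ActivityLabel]:
    """Class list of the level-2A network in charge of ``mode``.

    The steady activity ``m-m`` comes first, followed by every allowed
    transition departing from ``m`` in the schema's declaration order.  The
    lists across all modes partition {steady labels} ∪ {transitions}.
    """
    schema.require_mode(mode)
    classes = [ActivityLabel.steady(mode)]
    classes += [
        ActivityLabel(t.from_mode, t.to_mode)
        for t in schema.transitions
        if t.from_mode == mode
    ]
    return classes


def count_labels(schema: LabelSchema) -> tuple[int, int, int]:
    """Return ``(n_modes, n_transitions, n_gait_phases)`` of the schema."""
    n_phases = sum(schema.n_phases(m) for m in schema.modes)
    return len(schema.modes), len(schema.transitions), n_phases


_ALL_MODES = tuple(LocomotionMode)


def _transitions(*pairs: str) -> tuple[TransitionLabel, ...]:
    return tuple(TransitionLabel.parse(p) for p in pairs)


#: Schema of the ten-healthy-subject benchmark recordings: 7 modes, 12
#: transitions (declaration order follows the source distribution tables),
#: and 27 gait phases (7 walking + 4 x 5 ramp/stair).
ENABL3S_SCHEMA = LabelSchema(
    name="enabl3s",
    modes=_ALL_MODES,
    transitions=_transitions(
        "S-ST", "ST-W", "W-SA", "SA-W", "W-RD", "RD-W",
        "W-ST", "ST-S", "W-RA", "RA-W", "W-SD", "SD-W",
    ),
    phases_per_mode=dict(_DEFAULT_PHASE_COUNTS),
)

#: Schema of the single-amputee recordings: 7 modes, 19 transitions, and no
#: gait-phase labels (level 2B is skipped for this schema).
MYLEG_SCHEMA = LabelSchema(
    name="myleg",
    modes=_ALL_MODES,
    transitions=_transitions(
        "S-W", "S-ST", "ST-SD", "ST-SA", "ST-S", "ST-W", "ST-RA", "ST-RD",
        "W-SA", "W-RA", "W-S", "W-SD", "W-ST", "SA-ST", "SA-W", "SD-ST",
        "SD-W", "RA-RD", "RD-W",
    ),
)

_BUILTIN_SCHEMAS = {"enabl3s": ENABL3S_SCHEMA, "myleg": MYLEG_SCHEMA}


def get_schema(name: str) -> LabelSchema:
    """Look up a bundled schema by name (``"enabl3s"`` or ``"myleg"``)."""
    try:
        return _BUILTIN_SCHEMAS[name.lower()]
    except KeyError:
        raise SchemaError(
            f"unknown schema {name!r}; bundled schemas: {sorted(_BUILTIN_SCHEMAS)}"
        ) from None
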