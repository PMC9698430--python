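"""The multi-level classifier: level 1 routes, levels 2A/2B specialize.

Level 1 is one network over the seven locomotion modes (transition windows
count as their *starting* mode there).  Its argmax routes the encoded
window to the per-mode level-2A network — which separates the steady mode
from the transitions departing from it — and, for non-static modes of a
phase-bearing schema, to the per-mode level-2B gait-phase network.  2A and
2B are independent of each other (and of whether the window truly is a
transition), so they can run in parallel; here they run sequentially but
batched per routed mode.

A level-1 misroute is not caught downstream: the wrong sub-models classify
the window and the error propagates into the composite label, exactly what
the end-to-end evaluation is meant to measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .labels import (
    ActivityLabel,
    CompositeLabel,
    GaitPhaseLabel,
    LabelSchema,
    LocomotionMode,
    compose_label,
    enumerate_level2a_classes,
)
from .networks import TrainedModel, load_model, predict, save_model

#: Windows per forward pass during batched classification; keeps the
#: convolution's im2col working memory bounded.
PREDICT_CHUNK = 256


def _predict_probs(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [predict(model, x[lo:lo + PREDICT_CHUNK])
         for lo in range(0, len(x), PREDICT_CHUNK)],
        axis=0,
    )


class SystemConfigError(ValueError):
    """The system's sub-models do not cover the schema's routing targets."""


@dataclass
class MultiLevelSystem:
    """Level-1 net, seven level-2A nets, and (optionally) five level-2B nets.

    ``level2a``/``level2b`` are keyed by mode code.  ``level2b`` is empty
    for schemas without gait-phase labels; then composite labels reduce to
    the activity alone.
    """

    schema: LabelSchema
    level1: TrainedModel
    level2a: dict[str, TrainedModel]
    level2b: dict[str, TrainedModel]

    def __post_init__(self) -> None:
        mode_codes = [m.code for m in self.schema.modes]
        if sorted(self.level1.class_order) != sorted(mode_codes):
            raise SystemConfigError(
                f"level-1 class order {self.level1.class_order} does not "
                f"cover the schema modes {mode_codes}"
            )
        missing = [c for c in mode_codes if c not in self.level2a]
        if missing:
            raise SystemConfigError(f"no level-2A model for modes {missing}")
        for mode in self.schema.modes:
            expected = [str(a) for a in enumerate_level2a_classes(self.schema, mode)]
            got = self.level2a[mode.code].class_order
            if got != expected:
                raise SystemConfigError(
                    f"level-2A class order for {mode.code} is {got}, expected {expected}"
                )
        if self.schema.has_phases:
            phase_modes = [m.code for m in self.schema.modes if not m.is_static]
            missing = [c for c in phase_modes if c not in self.level2b]
            if missing:
                raise SystemConfigError(f"no level-2B model for modes {missing}")


def classify(system: MultiLevelSystem, encoded: np.ndarray) -> CompositeLabel:
    """Classify one encoded window (n_channels, 10, 50) end to end."""
    return classify_batch(system, encoded[None])[0]


def classify_batch(
    system: MultiLevelSystem, encoded: np.ndarray
) -> list[CompositeLabel]:
    """Element-wise classification with sub-model calls batched per route.

    Argmax ties break to the earliest class in ``class_order``.  Results
    preserve input order; a batch of identical windows yields identical
    labels.
    """
    encoded = np.asarray(encoded)
    if encoded.ndim != 4:
        raise ValueError("expected a (batch, channels, 10, 50) tensor")
    n = encoded.shape[0]
    if n == 0:
        return []
    p1 = _predict_probs(system.level1, encoded)
    routed = np.argmax(p1, axis=1)
    out: list[CompositeLabel | None] = [None] * n
    for mode_idx in np.unique(routed):
        mode_code = system.level1.class_order[int(mode_idx)]
        mode = LocomotionMode.from_code(mode_code)
        idx = np.flatnonzero(routed == mode_idx)
        sub = encoded[idx]
        m2a = system.level2a.get(mode_code)
        if m2a is None:
            raise SystemConfigError(f"no level-2A model for routed mode {mode_code}")
        acts = np.argmax(_predict_probs(m2a, sub), axis=1)
        phases: list[GaitPhaseLabel | None] = [None] * len(idx)
        if system.schema.has_phases and not mode.is_static:
            m2b = system.level2b.get(mode_code)
            if m2b is None:
                raise SystemConfigError(
                    f"no level-2B model for routed mode {mode_code}"
                )
            ph = np.argmax(_predict_probs(m2b, sub), axis=1)
            phases = [
                GaitPhaseLabel.parse(m2b.class_order[int(j)]) for j in ph
            ]
        for pos, a, phase in zip(idx, acts, phases):
            activity = ActivityLabel.parse(m2a.class_order[int(a)])
            out[int(pos)] = compose_label(activity, phase)
    return out  # type: ignore[return-value]


def save_system(system: MultiLevelSystem, path: str | Path) -> None:
    """Persist every sub-model plus the schema under one directory."""
    import json

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "schema.json").write_text(json.dumps(system.schema.to_config(), indent=2))
    save_model(system.level1, path / "level1")
    for code, model in system.level2a.items():
        save_model(model, path / f"level2a_{code}")
    for code, model in system.level2b.items():
        save_model(model, path / f"level2b_{code}")


def load_system(path: str | Path) -> MultiLevelSystem:
    """Load a system saved by :func:`save_system`."""
    import json

    path = Path(path)
    schema = LabelSchema.from_config(json.loads((path / "schema.json").read_text()))
    level1 = load_model(path / "level1")
    level2a = {
        p.name.removeprefix("level2a_"): load_model(p)
        for p in sorted(path.glob("level2a_*"))
    }
    level2b = {
        p.name.removeprefix("level2b_"): load_model(p)
        for p in sorted(path.glob("level2b_*"))
    }
    return MultiLevelSystem(
        schema=schema, level1=level1, level2a=level2a, level2b=level2b
    )
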