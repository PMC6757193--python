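"""Activation schedules for forward-simulation tasks.

A schedule maps muscle names (or muscle group names) to piecewise-linear
time series of activation in [0, 1].  Entries addressed to a group apply
to every muscle in it unless the muscle has its own entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ActivationSchedule"]


@dataclass
class ActivationSchedule:
    name: str
    entries: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def set(self, key: str, points):
        pts = sorted((float(t), float(a)) for t, a in points)
        for _, a in pts:
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"activation {a} outside [0, 1] in schedule {self.name!r}")
        self.entries[key] = pts
        return self

    def value(self, t: float, muscle_name: str, group: str = "") -> float:
        key = muscle_name if muscle_name in self.entries else group
        pts = self.entries.get(key)
        if not pts:
            return 0.0
        ts = np.array([p[0] for p in pts])
        vs = np.array([p[1] for p in pts])
        return float(np.interp(t, ts, vs))

    def activations(self, t: float, muscles) -> dict[str, float]:
        return {m.name: self.value(t, m.name, m.group) for m in muscles}

    def to_dict(self):
        return {k: [[t, a] for t, a in v] for k, v in self.entries.items()}

    @classmethod
    def from_dict(cls, name, d):
        s = cls(name)
        for k, pts in d.items():
            s.set(k, pts)
        return s
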