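"""Block-design experimental paradigm: trial onsets, durations, conditions.

The default design mirrors a two-finger motor experiment: a 20 s initial
rest, then ten trials of 10 s task + 20 s rest, five trials per condition
("little", "thumb") in seeded random order — 320 s in total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

DEFAULT_CONDITIONS = ("little", "thumb")


@dataclass(frozen=True)
class Trial:
    onset_s: float
    duration_s: float
    condition: str


@dataclass(frozen=True)
class Paradigm:
    trials: tuple[Trial, ...]
    initial_rest_s: float = 20.0
    trial_rest_s: float = 20.0

    def __post_init__(self) -> None:
        onsets = [t.onset_s for t in self.trials]
        if sorted(onsets) != onsets:
            raise ConfigError("trial onsets must be non-decreasing")

    @property
    def total_duration_s(self) -> float:
        if not self.trials:
            return self.initial_rest_s
        last = self.trials[-1]
        return last.onset_s + last.duration_s + self.trial_rest_s

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.trials:
            if t.condition not in seen:
                seen.append(t.condition)
        return tuple(seen)

    def onsets(self, condition: str | None = None) -> list[float]:
        return [
            t.onset_s for t in self.trials if condition is None or t.condition == condition
        ]

    def boxcar(self, fs_hz: float, n_samples: int, condition: str | None = None) -> np.ndarray:
        """Task indicator (1 during task, 0 during rest) sampled at fs."""
        box = np.zeros(n_samples)
        for t in self.trials:
            if condition is not None and t.condition != condition:
                continue
            i0 = int(round(t.onset_s * fs_hz))
            i1 = int(round((t.onset_s + t.duration_s) * fs_hz))
            box[max(i0, 0) : min(i1, n_samples)] = 1.0
        return box

    def to_dict(self) -> dict:
        return {
            "initial_rest_s": self.initial_rest_s,
            "trial_rest_s": self.trial_rest_s,
            "trials": [
                {"onset_s": t.onset_s, "duration_s": t.duration_s, "condition": t.condition}
                for t in self.trials
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Paradigm":
        return cls(
            trials=tuple(
                Trial(float(t["onset_s"]), float(t["duration_s"]), str(t["condition"]))
                for t in d["trials"]
            ),
            initial_rest_s=float(d.get("initial_rest_s", 20.0)),
            trial_rest_s=float(d.get("trial_rest_s", 20.0)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Paradigm":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def generate_paradigm(
    seed: int,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    trials_per_condition: int = 5,
    task_s: float = 10.0,
    rest_s: float = 20.0,
    initial_rest_s: float = 20.0,
) -> Paradigm:
    """Balanced randomized block design under a seed.

    Defaults give onsets at 20 + 30k s (k = 0..9), five trials per condition
    in a seeded permutation, and a 320 s total duration.
    """
    rng = np.random.default_rng(seed)
    labels = [c for c in conditions for _ in range(trials_per_condition)]
    order = rng.permutation(len(labels))
    trials = []
    for k, idx in enumerate(order):
        onset = initial_rest_s + k * (task_s + rest_s)
        trials.append(Trial(onset_s=onset, duration_s=task_s, condition=labels[idx]))
    return Paradigm(trials=tuple(trials), initial_rest_s=initial_rest_s, trial_rest_s=rest_s)
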