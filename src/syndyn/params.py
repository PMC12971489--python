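"""Parameter containers, imaging schedules and their (de)serialization.

Units are fixed package-wide: time in hours, length in micrometres (µm).
Birth rates are synapses per µm per hour; all hazards are per hour.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "ModelParams2S",
    "ModelParams1S",
    "StationaryState",
    "ImagingSchedule",
    "LifetimeCategory",
    "ModelParams",
    "load_params",
    "save_params",
]


def _check_rate(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class ModelParams2S:
    """Parameters of the two-state synapse model.

    Attributes
    ----------
    b_n : float
        Birth rate of new synapses, synapses per µm per hour.
    d_n : float
        Decay hazard while in the new state, per hour.
    c_ns : float
        Stabilization hazard (new -> stable), per hour.
    d_s : float
        Decay hazard while in the stable state, per hour.
    """

    b_n: float
    d_n: float
    c_ns: float
    d_s: float

    model_tag = "two_state"
    free_names = ("b_n", "d_n", "c_ns", "d_s")

    def __post_init__(self) -> None:
        for name in self.free_names:
            object.__setattr__(self, name, _check_rate(name, getattr(self, name)))

    @property
    def total_new_hazard(self) -> float:
        """Total hazard of leaving the new state, ``d_n + c_ns``."""
        return self.d_n + self.c_ns

    def as_vector(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in self.free_names)

    @classmethod
    def from_vector(cls, vec) -> "ModelParams2S":
        return cls(*map(float, vec))

    def to_dict(self) -> dict:
        return {"model": self.model_tag, **{n: getattr(self, n) for n in self.free_names}}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams2S":
        return cls(**{n: d[n] for n in cls.free_names})

    def scaled(self, *, b_n: float = 1.0, d_n: float = 1.0, c_ns: float = 1.0,
               d_s: float = 1.0) -> "ModelParams2S":
        """Return a copy with each parameter multiplied by the given factor."""
        return ModelParams2S(self.b_n * b_n, self.d_n * d_n,
                             self.c_ns * c_ns, self.d_s * d_s)


@dataclass(frozen=True)
class ModelParams1S:
    """Parameters of the one-state (pure immigration-death) model."""

    b: float
    d: float

    model_tag = "one_state"
    free_names = ("b", "d")

    def __post_init__(self) -> None:
        for name in self.free_names:
            object.__setattr__(self, name, _check_rate(name, getattr(self, name)))

    def to_two_state(self) -> ModelParams2S:
        """Exact embedding: one state == two states with ``c_ns = 0``."""
        return ModelParams2S(b_n=self.b, d_n=self.d, c_ns=0.0, d_s=0.0)

    def as_vector(self) -> tuple[float, ...]:
        return (self.b, self.d)

    @classmethod
    def from_vector(cls, vec) -> "ModelParams1S":
        return cls(*map(float, vec))

    def to_dict(self) -> dict:
        return {"model": self.model_tag, "b": self.b, "d": self.d}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams1S":
        return cls(b=d["b"], d=d["d"])


ModelParams = Union[ModelParams2S, ModelParams1S]


@dataclass(frozen=True)
class StationaryState:
    """Stationary per-µm densities of the two pools."""

    n_star: float
    s_star: float

    @property
    def total(self) -> float:
        return self.n_star + self.s_star


@dataclass(frozen=True)
class ImagingSchedule:
    """Ordered imaging times ``t_0 = 0 < t_1 < ... < t_K`` in hours."""

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        if len(times) < 2:
            raise ValueError("schedule needs at least two imaging times")
        if times[0] != 0.0:
            raise ValueError(f"first imaging time must be 0, got {times[0]}")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"imaging times must be strictly increasing: {times}")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def last_index(self) -> int:
        """K, the index of the final imaging time."""
        return len(self.times) - 1

    @property
    def horizon(self) -> float:
        return self.times[-1]

    def index_of(self, t: float) -> int:
        t = float(t)
        try:
            return self.times.index(t)
        except ValueError:
            raise ValueError(f"{t} h is not an imaging time of {self.times}") from None


@dataclass(frozen=True)
class LifetimeCategory:
    """First/last-detection index pair over a schedule."""

    first: int
    last: int

    def __post_init__(self) -> None:
        if not (0 <= self.first <= self.last):
            raise ValueError(f"need 0 <= first <= last, got {self}")

    def validate(self, schedule: ImagingSchedule) -> None:
        if self.last > schedule.last_index:
            raise ValueError(f"category {self} out of range for K={schedule.last_index}")


_PARAMS_HEADER = (
    "# Model parameters. Units: b_n / b in synapses per um per hour;\n"
    "# all other rates in 1/hour.\n"
)


def params_from_mapping(d: dict) -> ModelParams:
    """Build a parameter object from a flat mapping with a ``model`` tag."""
    model = d.get("model")
    if model == "two_state":
        return ModelParams2S.from_dict(d)
    if model == "one_state":
        return ModelParams1S.from_dict(d)
    raise ValueError(f"unknown model tag {model!r} (expected 'two_state' or 'one_state')")


def load_params(path: Union[str, Path]) -> ModelParams:
    """Load parameters from a YAML or JSON mapping file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping, got {type(data).__name__}")
    return params_from_mapping(data)


def save_params(params: ModelParams, path: Union[str, Path]) -> None:
    """Write parameters as a flat YAML/JSON mapping with a units header."""
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(_PARAMS_HEADER + yaml.safe_dump(d, sort_keys=False))
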