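"""Exact, seeded stochastic simulation of synapse tracks on dendrites.

Events are sampled in continuous time with no discretization: births form
a homogeneous Poisson process along the dendrite and over time, and each
synapse's fate is drawn from competing exponential clocks (stabilization
vs decay from the new state, then decay from the stable state), which is
exact for constant hazards.

Reproducibility: each dendrite gets its own random substream derived from
the master seed by a counter-based scheme,
``SeedSequence(entropy=seed, spawn_key=(fish_index, dendrite_index))``,
so results are invariant to execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_model import stationary_density
from .params import ModelParams, ModelParams1S, ModelParams2S

__all__ = [
    "SimDesign",
    "simulate_dendrite",
    "simulate_study",
    "write_tracks",
    "read_tracks",
    "TRACK_COLUMNS",
]

TRACK_COLUMNS = [
    "fish_id",
    "dendrite_id",
    "synapse_id",
    "position_um",
    "origin",
    "t_birth_h",
    "t_stabilize_h",
    "t_death_h",
    "dendrite_length_um",
]

ORIGINS = ("initial_new", "initial_stable", "born")


@dataclass(frozen=True)
class SimDesign:
    """Study design: hierarchy sizes, dendrite lengths, horizon and seed."""

    n_fish: int
    dendrites_per_fish: int
    dendrite_length: Union[float, Sequence[float]]
    horizon: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_fish < 1 or self.dendrites_per_fish < 1:
            raise ValueError("counts must be >= 1")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        lengths = self.lengths()
        if len(lengths) != self.n_fish * self.dendrites_per_fish:
            raise ValueError(
                f"need {self.n_fish * self.dendrites_per_fish} dendrite lengths, "
                f"got {len(lengths)}"
            )
        if any(length <= 0 for length in lengths):
            raise ValueError("dendrite lengths must be > 0")

    def lengths(self) -> list[float]:
        """Per-dendrite lengths, expanded if a single scalar was given."""
        if np.isscalar(self.dendrite_length):
            return [float(self.dendrite_length)] * (self.n_fish * self.dendrites_per_fish)
        return [float(x) for x in self.dendrite_length]


def _as_two_state(params: ModelParams) -> ModelParams2S:
    if isinstance(params, ModelParams1S):
        return params.to_two_state()
    return params


def _exponential(rng: np.random.Generator, rate: float, size: int) -> np.ndarray:
    """Exp(rate) draws; rate 0 gives +inf (the event never fires)."""
    if rate <= 0.0:
        return np.full(size, np.inf)
    return rng.exponential(1.0 / rate, size=size)


def dendrite_rng(seed: int, fish_index: int, dendrite_index: int) -> np.random.Generator:
    """The per-dendrite substream of the master seed (order-invariant)."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(fish_index, dendrite_index))
    return np.random.default_rng(ss)


def simulate_dendrite(
    params: ModelParams,
    length: float,
    horizon: float,
    rng: np.random.Generator,
    *,
    fish_id: str = "f1",
    dendrite_id: str = "f1d1",
    initial_counts: Optional[tuple[int, int]] = None,
) -> pd.DataFrame:
    """Simulate every synapse track on one dendrite over ``[0, horizon]``.

    The initial population is drawn from the stationary count
    distribution (independent Poisson counts with means ``n* length`` and
    ``s* length``) unless ``initial_counts=(n_new, n_stable)`` pins it.
    Births are Poisson with mean ``b_n length horizon``, times uniform on
    ``(0, horizon]``, positions uniform on ``[0, length)``.

    Returns a DataFrame with :data:`TRACK_COLUMNS`; ``t_stabilize_h`` and
    ``t_death_h`` are NaN when the event did not occur by the horizon.
    """
    p = _as_two_state(params)
    if length <= 0 or horizon <= 0:
        raise ValueError("length and horizon must be > 0")

    if initial_counts is not None:
        n0, s0 = (int(x) for x in initial_counts)
        if n0 < 0 or s0 < 0:
            raise ValueError("initial counts must be >= 0")
    else:
        stat = stationary_density(p)  # raises for degenerate parameters
        n0 = rng.poisson(stat.n_star * length)
        s0 = rng.poisson(stat.s_star * length)
    m = rng.poisson(p.b_n * length * horizon)

    # birth times: 0 for the initial population, uniform for born synapses
    t_birth = np.concatenate([
        np.zeros(n0 + s0),
        horizon * (1.0 - rng.random(m)),  # uniform on (0, horizon]
    ])
    origin = np.array(
        ["initial_new"] * n0 + ["initial_stable"] * s0 + ["born"] * m, dtype=object
    )
    n_total = n0 + s0 + m
    position = length * rng.random(n_total)

    in_new = origin != "initial_stable"
    n_new = int(in_new.sum())

    # competing clocks out of the new state
    w_stab = _exponential(rng, p.c_ns, n_new)
    w_die = _exponential(rng, p.d_n, n_new)
    stabilizes = w_stab < w_die

    t_stabilize = np.full(n_total, np.nan)
    t_death = np.full(n_total, np.nan)

    new_idx = np.flatnonzero(in_new)
    t_stab_abs = t_birth[new_idx] + w_stab
    t_die_new_abs = t_birth[new_idx] + w_die
    t_death[new_idx[~stabilizes]] = t_die_new_abs[~stabilizes]
    t_stabilize[new_idx[stabilizes]] = t_stab_abs[stabilizes]

    # stable-state death clocks: stabilized new synapses + initial stable pool
    stab_idx = new_idx[stabilizes]
    t_death[stab_idx] = t_stabilize[stab_idx] + _exponential(rng, p.d_s, stab_idx.size)
    init_stable_idx = np.flatnonzero(origin == "initial_stable")
    t_death[init_stable_idx] = _exponential(rng, p.d_s, init_stable_idx.size)

    # censor everything past the horizon
    t_death[t_death > horizon] = np.nan
    t_stabilize[t_stabilize > horizon] = np.nan

    order = np.argsort(t_birth, kind="stable")
    df = pd.DataFrame(
        {
            "fish_id": fish_id,
            "dendrite_id": dendrite_id,
            "synapse_id": [f"{dendrite_id}s{k}" for k in range(n_total)],
            "position_um": position[order],
            "origin": origin[order],
            "t_birth_h": t_birth[order],
            "t_stabilize_h": t_stabilize[order],
            "t_death_h": t_death[order],
            "dendrite_length_um": float(length),
        },
        columns=TRACK_COLUMNS,
    )
    return df


def simulate_study(params: ModelParams, design: SimDesign) -> pd.DataFrame:
    """Concatenate independent dendrite simulations with hierarchical ids."""
    lengths = design.lengths()
    frames = []
    k = 0
    for fi in range(design.n_fish):
        fish_id = f"f{fi + 1}"
        for di in range(design.dendrites_per_fish):
            dendrite_id = f"{fish_id}d{di + 1}"
            rng = dendrite_rng(design.seed, fi, di)
            frames.append(
                simulate_dendrite(
                    params,
                    lengths[k],
                    design.horizon,
                    rng,
                    fish_id=fish_id,
                    dendrite_id=dendrite_id,
                )
            )
            k += 1
    return pd.concat(frames, ignore_index=True)


def write_tracks(tracks: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a track table as TSV; missing events become empty fields."""
    tracks.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.10g")


def read_tracks(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"fish_id": str, "dendrite_id": str,
                                            "synapse_id": str})
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing track columns {missing}")
    return df[TRACK_COLUMNS]
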