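"""Closed-form quantities of the one- and two-state synapse models.

The two-state model: synapses are born on a dendrite by a homogeneous
Poisson process with intensity ``b_n`` (per µm per hour) into a *new*
state, from which they either stabilize (hazard ``c_ns``) or decay
(hazard ``d_n``); stable synapses decay with the slower hazard ``d_s``.
All hazards are constant, so the per-synapse dynamics are a
continuous-time Markov chain and every quantity below has a closed
exponential form.

Writing ``a = d_n + c_ns`` for the total hazard of leaving the new
state, the probability that a synapse that entered the new state at
time 0 is still present (in either state) at time ``t`` is

    S_new(t) = (1 - beta) * exp(-a t) + beta * exp(-d_s t),
    beta = c_ns / (a - d_s),

with the degenerate limit ``(1 + c_ns t) exp(-a t)`` when ``a == d_s``.
Stable synapses survive as ``S_s(t) = exp(-d_s t)``.

Because births are Poisson and fates independent, the pool is a linear
immigration-death system: the stationary state has Poisson-distributed
counts with per-µm means ``n* = b_n / a`` and ``s* = b_n c_ns / (a d_s)``,
and the expected density of synapses falling in any lifetime category of
an imaging schedule is an explicit integral of ``S_new`` / ``S_s``.
"""

from __future__ import annotations

import math
from typing import Iterable, Literal, Union

import numpy as np
from scipy import integrate

from .params import (
    ImagingSchedule,
    LifetimeCategory,
    ModelParams,
    ModelParams1S,
    ModelParams2S,
    StationaryState,
)

__all__ = [
    "stationary_density",
    "survival_new",
    "survival_stable",
    "survival_cohort",
    "survival_new_integral",
    "expected_category_density",
    "expected_category_table",
    "expected_window_rates",
    "category_pairs",
]

#: relative tolerance below which ``a`` and ``d_s`` are treated as equal
DEGENERATE_RTOL = 1e-10

CohortInit = Literal["stationary", "all_stable"]


def _as_two_state(params: ModelParams) -> ModelParams2S:
    if isinstance(params, ModelParams1S):
        return params.to_two_state()
    return params


def _is_degenerate(a: float, d_s: float) -> bool:
    return abs(a - d_s) <= DEGENERATE_RTOL * max(a, d_s)


def stationary_density(params: ModelParams) -> StationaryState:
    """Stationary per-µm densities ``(n*, s*)`` of the two pools.

    ``n* = b_n / (d_n + c_ns)`` and ``s* = b_n c_ns / ((d_n + c_ns) d_s)``;
    these satisfy the balance identities ``b_n = (d_n + c_ns) n*`` and
    ``c_ns n* = d_s s*``.

    Raises
    ------
    ValueError
        If ``d_n + c_ns == 0`` (new pool diverges) or ``c_ns > 0`` with
        ``d_s == 0`` (stable pool diverges).
    """
    p = _as_two_state(params)
    a = p.total_new_hazard
    if a <= 0:
        raise ValueError("d_n + c_ns must be > 0 for a stationary state")
    n_star = p.b_n / a
    if p.c_ns > 0:
        if p.d_s <= 0:
            raise ValueError("stable pool diverges: c_ns > 0 requires d_s > 0")
        s_star = p.b_n * p.c_ns / (a * p.d_s)
    else:
        s_star = 0.0
    return StationaryState(n_star=n_star, s_star=s_star)


def _check_nonnegative_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return t


def survival_new(params: ModelParams, t) -> Union[float, np.ndarray]:
    """P(alive at ``t`` | entered the new state at time 0), either state.

    Vectorized over ``t``. Uses the cancellation-safe limit form
    ``(1 + c_ns t) exp(-a t)`` when ``a`` and ``d_s`` coincide to within
    :data:`DEGENERATE_RTOL`.
    """
    p = _as_two_state(params)
    t = _check_nonnegative_time(t)
    a = p.total_new_hazard
    if _is_degenerate(a, p.d_s):
        out = (1.0 + p.c_ns * t) * np.exp(-a * t)
    else:
        beta = p.c_ns / (a - p.d_s)
        out = (1.0 - beta) * np.exp(-a * t) + beta * np.exp(-p.d_s * t)
    return out if out.ndim else float(out)


def survival_stable(params: ModelParams, t) -> Union[float, np.ndarray]:
    """P(alive at ``t`` | in the stable state at time 0): ``exp(-d_s t)``."""
    p = _as_two_state(params)
    t = _check_nonnegative_time(t)
    out = np.exp(-p.d_s * t)
    return out if out.ndim else float(out)


def survival_cohort(params: ModelParams, t, *,
                    cohort_init: CohortInit = "stationary") -> Union[float, np.ndarray]:
    """Survival of the population present at the first imaging time.

    With ``cohort_init="stationary"`` (default) the t=0 population is the
    stationary mixture of the two pools:

        S_0(t) = (n* S_new(t) + s* S_s(t)) / (n* + s*).

    With ``cohort_init="all_stable"`` every t=0 synapse is taken to be in
    the stable state, so ``S_0 = S_s``.
    """
    p = _as_two_state(params)
    if cohort_init == "all_stable":
        return survival_stable(p, t)
    if cohort_init != "stationary":
        raise ValueError(f"unknown cohort_init {cohort_init!r}")
    stat = stationary_density(p)
    if stat.total <= 0:
        raise ValueError("cohort survival undefined: stationary density is 0")
    num = stat.n_star * np.asarray(survival_new(p, t)) \
        + stat.s_star * np.asarray(survival_stable(p, t))
    out = num / stat.total
    return out if out.ndim else float(out)


def _exp_integral(r: float, lo: float, hi: float) -> float:
    """∫_lo^hi exp(-r u) du with a cancellation-safe ``expm1`` form."""
    if hi < lo:
        raise ValueError("integration bounds must satisfy lo <= hi")
    if r == 0.0:
        return hi - lo
    return math.exp(-r * lo) * (-math.expm1(-r * (hi - lo))) / r


def survival_new_integral(params: ModelParams, lo: float, hi: float) -> float:
    """∫_lo^hi S_new(u) du in closed form (exact exponential antiderivatives)."""
    p = _as_two_state(params)
    lo, hi = float(lo), float(hi)
    if lo < 0:
        raise ValueError("integration bounds must be >= 0")
    a = p.total_new_hazard
    if _is_degenerate(a, p.d_s):
        if a == 0.0:
            # c_ns <= a = 0 so S_new == 1
            return hi - lo
        c = p.c_ns

        def antider(u: float) -> float:
            return -math.exp(-a * u) * ((1.0 + c * u) / a + c / a**2)

        return antider(hi) - antider(lo)
    beta = p.c_ns / (a - p.d_s)
    return (1.0 - beta) * _exp_integral(a, lo, hi) + beta * _exp_integral(p.d_s, lo, hi)


def category_pairs(schedule: ImagingSchedule) -> list[tuple[int, int]]:
    """All valid (first, last) index pairs for a schedule, row-major in first."""
    K = schedule.last_index
    return [(i, j) for i in range(K + 1) for j in range(i, K + 1)]


def expected_category_density(
    params: ModelParams,
    schedule: ImagingSchedule,
    category: LifetimeCategory | tuple[int, int],
    *,
    method: Literal["closed_form", "quad"] = "closed_form",
    cohort_init: CohortInit = "stationary",
) -> float:
    """Expected per-µm density of synapses with the given lifetime category.

    A lifetime category (i, j) collects synapses first detected at
    schedule time ``t_i`` and last detected at ``t_j``. For the t=0
    cohort (i = 0)

        D_{0,j} = n* [S_new(t_j) - S_new(t_{j+1})] + s* [S_s(t_j) - S_s(t_{j+1})]

    and for synapses first seen at ``t_i`` with i >= 1 (born in
    ``(t_{i-1}, t_i]``)

        D_{i,j} = b_n ∫_{t_{i-1}}^{t_i} [S_new(t_j - τ) - S_new(t_{j+1} - τ)] dτ,

    where the subtracted term is dropped when ``j = K`` (right-censored:
    still present at the final imaging time). Because death is absorbing
    and detection perfect, categories with internal gaps have density 0.

    Parameters
    ----------
    method
        ``"closed_form"`` (default) uses exact exponential
        antiderivatives; ``"quad"`` integrates the birth-time integral by
        adaptive quadrature at relative tolerance 1e-9 (cross-check path).
    """
    if isinstance(category, tuple):
        category = LifetimeCategory(*category)
    category.validate(schedule)
    p = _as_two_state(params)
    times = schedule.times
    K = schedule.last_index
    i, j = category.first, category.last
    censored = j == K

    if i == 0:
        if cohort_init == "all_stable":
            total = stationary_density(p).total
            mass = total * survival_stable(p, times[j])
            if not censored:
                mass -= total * survival_stable(p, times[j + 1])
            return float(mass)
        stat = stationary_density(p)
        mass = stat.n_star * survival_new(p, times[j]) \
            + stat.s_star * survival_stable(p, times[j])
        if not censored:
            mass -= stat.n_star * survival_new(p, times[j + 1]) \
                + stat.s_star * survival_stable(p, times[j + 1])
        return float(mass)

    t_lo, t_hi = times[i - 1], times[i]
    if method == "quad":
        def integrand(tau: float) -> float:
            val = survival_new(p, times[j] - tau)
            if not censored:
                val -= survival_new(p, times[j + 1] - tau)
            return val

        val, _ = integrate.quad(integrand, t_lo, t_hi, epsrel=1e-9, epsabs=0.0)
        return float(p.b_n * val)
    if method != "closed_form":
        raise ValueError(f"unknown method {method!r}")
    # substitute u = t_j - tau: tau in (t_{i-1}, t_i] -> u in [t_j - t_i, t_j - t_{i-1})
    mass = survival_new_integral(p, times[j] - t_hi, times[j] - t_lo)
    if not censored:
        mass -= survival_new_integral(p, times[j + 1] - t_hi, times[j + 1] - t_lo)
    return float(p.b_n * mass)


def expected_category_table(
    params: ModelParams,
    schedule: ImagingSchedule,
    *,
    method: Literal["closed_form", "quad"] = "closed_form",
    cohort_init: CohortInit = "stationary",
) -> dict[tuple[int, int], float]:
    """Expected density for every (first, last) category of a schedule."""
    return {
        (i, j): expected_category_density(
            params, schedule, (i, j), method=method, cohort_init=cohort_init
        )
        for i, j in category_pairs(schedule)
    }


def expected_window_rates(
    params: ModelParams, window: float, *, cohort_init: CohortInit = "stationary"
):
    """Expected per-µm densities over a two-time-point window at stationarity.

    Returns
    -------
    (newly_observed, lost, stable) : tuple of float
        ``newly_observed = b_n ∫_0^w S_new(u) du`` (born during the window
        and alive at its end), ``lost = (n* + s*) (1 - S_0(w))`` and
        ``stable = (n* + s*) S_0(w)``.
    """
    window = float(window)
    if window <= 0:
        raise ValueError("window must be > 0")
    p = _as_two_state(params)
    stat = stationary_density(p)
    total = stat.total
    if total > 0:
        s0 = float(survival_cohort(p, window, cohort_init=cohort_init))
    else:
        s0 = 1.0
    newly = p.b_n * survival_new_integral(p, 0.0, window)
    lost = total * (1.0 - s0)
    stable = total * s0
    return newly, lost, stable
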