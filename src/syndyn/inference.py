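"""Likelihoods, maximum-likelihood fitting, model comparison and bootstrap.

The data are lifetime-category counts per dendrite. Under the model the
count in category (i, j) on a dendrite of length L is Poisson with mean
``L * D_ij`` where ``D_ij`` is the expected per-µm category density
(exact for the linear immigration-death system: Poisson births thinned
by independent fates stay Poisson, and disjoint categories are
independent). The negative log-likelihood keeps the full ``log y!``
constants so values are comparable across models on identical data.

Fitting minimizes the NLL over log-transformed parameters with
multi-start L-BFGS-B from a fixed coarse grid; models are compared by
AIC. Uncertainty comes from resampling fish (or dendrites) with
replacement and refitting.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core_model import category_pairs, expected_category_table
from .observation import CategoryCounts
from .params import ModelParams, ModelParams1S, ModelParams2S

__all__ = [
    "FitConfig",
    "FitResult",
    "BootstrapResult",
    "negative_log_likelihood",
    "fit",
    "compare_models",
    "bootstrap_fit",
    "percent_change",
    "ranksum",
]

MODEL_CLASSES = {"two_state": ModelParams2S, "one_state": ModelParams1S}

#: fixed coarse multi-start values applied to every free parameter
DEFAULT_START_GRID = (1e-4, 1e-2, 1.0)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings; defaults are the documented reproducible ones."""

    start_grid: tuple[float, ...] = DEFAULT_START_GRID
    extra_starts: tuple[tuple[float, ...], ...] = ()
    bounds: tuple[float, float] = (1e-8, 10.0)
    tol: float = 1e-8
    max_iter: int = 500

    def starts(self, n_params: int) -> list[tuple[float, ...]]:
        grid = [tuple(v) for v in itertools.product(self.start_grid, repeat=n_params)]
        return list(self.extra_starts) + grid


@dataclass(frozen=True)
class FitResult:
    model: str
    params: ModelParams
    nll: float
    aic: float
    n_free_params: int
    converged: bool
    n_starts_used: int
    best_start: tuple[float, ...]
    data_fingerprint: str

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {k: v for k, v in self.params.to_dict().items() if k != "model"},
            "nll": self.nll,
            "aic": self.aic,
            "n_free_params": self.n_free_params,
            "converged": self.converged,
            "n_starts": self.n_starts_used,
            "best_start": list(self.best_start),
            "data_fingerprint": self.data_fingerprint,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FitResult":
        d = json.loads(Path(path).read_text())
        params = MODEL_CLASSES[d["model"]](**d["params"])
        return cls(
            model=d["model"],
            params=params,
            nll=d["nll"],
            aic=d["aic"],
            n_free_params=d["n_free_params"],
            converged=d["converged"],
            n_starts_used=d["n_starts"],
            best_start=tuple(d["best_start"]),
            data_fingerprint=d["data_fingerprint"],
        )


def _params_from_vector(model: str, vec) -> ModelParams:
    return MODEL_CLASSES[model].from_vector(vec)


@dataclass
class _SufficientStats:
    """Pooled sufficient statistics for fast repeated NLL evaluation.

    For Poisson counts with means ``L_d * D_ij`` the NLL separates as
    ``L_tot * sum(D) - sum_ij Y_ij log D_ij + const`` where the constant
    collects the ``-y log L_d`` and ``log y!`` terms; it is computed once.
    """

    pairs: list[tuple[int, int]]
    y_pooled: np.ndarray
    total_length: float
    const: float
    schedule: object

    @classmethod
    def from_counts(cls, data: CategoryCounts) -> "_SufficientStats":
        pairs = category_pairs(data.schedule)
        index = {p: k for k, p in enumerate(pairs)}
        y_pooled = np.zeros(len(pairs))
        const = 0.0
        lengths = {
            (r.fish_id, r.dendrite_id): float(r.length_um)
            for r in data.lengths.itertuples()
        }
        for r in data.counts.itertuples():
            key = (int(r.first_idx), int(r.last_idx))
            if key not in index:
                raise ValueError(f"category {key} invalid for schedule "
                                 f"{data.schedule.times}")
            y = float(r.count)
            y_pooled[index[key]] += y
            L = lengths[(r.fish_id, r.dendrite_id)]
            const += special.gammaln(y + 1.0) - y * math.log(L)
        return cls(pairs=pairs, y_pooled=y_pooled,
                   total_length=data.total_length, const=const,
                   schedule=data.schedule)

    def nll(self, params: ModelParams) -> float:
        table = expected_category_table(params, self.schedule)
        D = np.array([table[p] for p in self.pairs])
        if not np.all(np.isfinite(D)):
            return math.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            logD = np.log(D)
        term = np.where(self.y_pooled > 0, -self.y_pooled * logD, 0.0)
        if not np.all(np.isfinite(term)):
            return math.inf  # positive count in a zero-mean category
        return float(self.total_length * D.sum() + term.sum() + self.const)


def negative_log_likelihood(model: str, params: ModelParams,
                            data: CategoryCounts) -> float:
    """Full Poisson NLL of category counts, summed over dendrites.

    Reference implementation: iterates every (dendrite, category) cell,
    treating categories absent from the table as observed zeros. Returns
    ``+inf`` for parameter values with zero predicted mass in a non-empty
    category.
    """
    if model not in MODEL_CLASSES:
        raise ValueError(f"unknown model {model!r}")
    table = expected_category_table(params, data.schedule)
    observed = {
        (r.fish_id, r.dendrite_id, int(r.first_idx), int(r.last_idx)): float(r.count)
        for r in data.counts.itertuples()
    }
    nll = 0.0
    for r in data.lengths.itertuples():
        L = float(r.length_um)
        for (i, j), dens in table.items():
            y = observed.get((r.fish_id, r.dendrite_id, i, j), 0.0)
            lam = L * dens
            if lam <= 0.0:
                if y > 0:
                    return math.inf
                continue
            nll += lam - y * math.log(lam) + float(special.gammaln(y + 1.0))
    return nll


def fit(model: str, data: CategoryCounts,
        config: Optional[FitConfig] = None) -> FitResult:
    """Maximum-likelihood fit of a model to lifetime-category counts.

    Minimizes the NLL over log-transformed parameters with L-BFGS-B,
    multi-started from the fixed coarse grid of :class:`FitConfig`
    (every combination of ``start_grid`` values per free parameter).
    Ties between equally good optima are broken by the lexicographically
    smallest log-parameter vector.
    """
    if model not in MODEL_CLASSES:
        raise ValueError(f"unknown model {model!r}")
    if data.total == 0:
        raise ValueError("empty category table: nothing to fit")
    if config is None:
        config = FitConfig()

    stats_ = _SufficientStats.from_counts(data)
    n_params = len(MODEL_CLASSES[model].free_names)
    lo, hi = config.bounds
    log_bounds = [(math.log(lo), math.log(hi))] * n_params

    def objective(x: np.ndarray) -> float:
        try:
            params = _params_from_vector(model, np.exp(x))
        except ValueError:
            return math.inf
        val = stats_.nll(params)
        return val if math.isfinite(val) else math.inf

    best = None
    best_x = None
    best_start = None
    any_success = False
    starts = config.starts(n_params)
    for start in starts:
        x0 = np.log(np.clip(start, lo, hi))
        try:
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B", bounds=log_bounds,
                options={"maxiter": config.max_iter, "ftol": config.tol,
                         "gtol": 1e-10},
            )
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if not math.isfinite(res.fun):
            continue
        any_success = any_success or bool(res.success)
        better = (
            best is None
            or res.fun < best - 1e-9
            or (abs(res.fun - best) <= 1e-9 and tuple(res.x) < tuple(best_x))
        )
        if better:
            best, best_x, best_start = float(res.fun), res.x, start

    if best is None or not math.isfinite(best):
        raise RuntimeError("all optimizer starts failed; no fit available")

    params = _params_from_vector(model, np.exp(best_x))
    aic = 2.0 * n_params + 2.0 * best
    return FitResult(
        model=model,
        params=params,
        nll=best,
        aic=aic,
        n_free_params=n_params,
        converged=any_success,
        n_starts_used=len(starts),
        best_start=tuple(best_start),
        data_fingerprint=data.fingerprint(),
    )


def compare_models(fit_two_state: FitResult, fit_one_state: FitResult) -> float:
    """ΔAIC = AIC(one-state) − AIC(two-state); positive favours two-state."""
    if fit_two_state.model != "two_state" or fit_one_state.model != "one_state":
        raise ValueError("expected a two_state and a one_state fit, in that order")
    if fit_two_state.data_fingerprint != fit_one_state.data_fingerprint:
        raise ValueError("fits were not run on identical data "
                         "(fingerprint mismatch)")
    return fit_one_state.aic - fit_two_state.aic


@dataclass(frozen=True)
class BootstrapResult:
    model: str
    unit: str
    param_names: tuple[str, ...]
    draws: np.ndarray  # (n_ok, n_params)
    sd: np.ndarray
    n_requested: int
    n_failed: int

    @property
    def flagged(self) -> bool:
        """True when more than 20% of refits failed."""
        return self.n_failed > 0.2 * self.n_requested

    def to_dict(self, include_draws: bool = True) -> dict:
        d = {
            "model": self.model,
            "unit": self.unit,
            "param_names": list(self.param_names),
            "sd": {n: float(s) for n, s in zip(self.param_names, self.sd)},
            "n_requested": self.n_requested,
            "n_failed": self.n_failed,
            "flagged": self.flagged,
        }
        if include_draws:
            d["draws"] = self.draws.tolist()
        return d


def _subset_counts(data: CategoryCounts, unit: str,
                   chosen: Sequence[str]) -> CategoryCounts:
    """Rebuild a CategoryCounts from resampled units (duplicates relabelled)."""
    count_frames = []
    length_frames = []
    for k, uid in enumerate(chosen):
        sub_c = data.counts[data.counts[unit] == uid].copy()
        sub_l = data.lengths[data.lengths[unit] == uid].copy()
        prefix = f"r{k}_"
        for frame in (sub_c, sub_l):
            frame["fish_id"] = prefix + frame["fish_id"].astype(str)
            frame["dendrite_id"] = prefix + frame["dendrite_id"].astype(str)
        count_frames.append(sub_c)
        length_frames.append(sub_l)
    return CategoryCounts(
        counts=pd.concat(count_frames, ignore_index=True),
        lengths=pd.concat(length_frames, ignore_index=True),
        schedule=data.schedule,
    )


def bootstrap_fit(model: str, data: CategoryCounts, B: int,
                  unit: str = "fish_id", seed: int = 0,
                  config: Optional[FitConfig] = None,
                  point_fit: Optional[FitResult] = None) -> BootstrapResult:
    """Resample units with replacement, refit, and summarize parameter spread.

    Refits are warm-started at the full-data fit (plus the coarse grid of
    ``config`` if given). Failed refits are dropped and counted, never
    imputed.
    """
    if B <= 0:
        raise ValueError("B must be >= 1")
    if unit not in ("fish_id", "dendrite_id"):
        raise ValueError("unit must be 'fish_id' or 'dendrite_id'")
    units = sorted(data.lengths[unit].unique())
    if len(units) < 2:
        raise ValueError(f"need >= 2 resampling units, found {len(units)}")

    if point_fit is None:
        point_fit = fit(model, data, config)
    refit_config = FitConfig(
        start_grid=(),
        extra_starts=(point_fit.params.as_vector(),)
        + (config.extra_starts if config else ()),
        bounds=(config.bounds if config else FitConfig().bounds),
    )

    rng = np.random.default_rng(seed)
    draws = []
    n_failed = 0
    for _ in range(B):
        chosen = rng.choice(units, size=len(units), replace=True)
        sample = _subset_counts(data, unit, chosen)
        try:
            res = fit(model, sample, refit_config)
            draws.append(res.params.as_vector())
        except (RuntimeError, ValueError):
            n_failed += 1

    names = MODEL_CLASSES[model].free_names
    arr = np.array(draws) if draws else np.empty((0, len(names)))
    sd = arr.std(axis=0, ddof=1) if len(arr) > 1 else np.full(len(names), np.nan)
    return BootstrapResult(
        model=model, unit=unit, param_names=names, draws=arr, sd=sd,
        n_requested=B, n_failed=n_failed,
    )


def percent_change(fit_ctrl: FitResult, fit_mut: FitResult, param: str) -> float:
    """Percent change of a fitted parameter, mutant relative to control.

    ``100 * (theta_mut / theta_ctrl - 1)``; reductions are negative.
    """
    if fit_ctrl.model != fit_mut.model:
        raise ValueError(
            f"model tags differ: {fit_ctrl.model!r} vs {fit_mut.model!r}"
        )
    ref = getattr(fit_ctrl.params, param)
    if ref == 0:
        raise ValueError(f"reference value of {param!r} is 0")
    return 100.0 * (getattr(fit_mut.params, param) / ref - 1.0)


def _u_statistic(ranks: np.ndarray, idx_a: Sequence[int], n_a: int) -> float:
    return float(ranks[list(idx_a)].sum() - n_a * (n_a + 1) / 2.0)


def ranksum(sample_a, sample_b) -> tuple[float, float]:
    """Mann-Whitney U test with average-rank ties, two-sided.

    Returns ``(U, p)`` with U the statistic of ``sample_a``. Uses exact
    enumeration of all rank assignments when both samples have n <= 8,
    otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = _u_statistic(ranks, range(n_a), n_a)
    mu = n_a * n_b / 2.0

    if n_a <= 8 and n_b <= 8:
        dev = abs(u_obs - mu)
        hits = 0
        total = 0
        for idx in itertools.combinations(range(n), n_a):
            u = _u_statistic(ranks, idx, n_a)
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        return u_obs, hits / total

    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)  # continuity correction
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return u_obs, min(1.0, p)
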