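"""Rate-constant estimation from observed consumption series.

The consumption rate constants of curcumin (k_C) and curcumin monoacrylate
(k_CM) are the only free parameters; the initiator decomposition and
radical elimination rates are fixed from literature. Fitting minimizes the
pooled sum of squared errors between observed series (normalized to the
initial value, or absolute µM) and the model prediction, using
derivative-free Nelder–Mead simplex over log-transformed parameters (which
enforces positivity without constraints). The quasi-steady-radical mode is
used inside the loop for speed; the optimum is re-evaluated in full-stiff
mode as a consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .model import ModelConfig, RateConstants, Trajectory, simulate

__all__ = [
    "ObservedSeries",
    "FitResult",
    "predict_observable",
    "sse",
    "r_squared",
    "fit_rate_constants",
    "OBSERVABLE_SPECIES",
]

#: Species labels an observed series may carry. ``total_signal`` is the
#: UV-Vis-style readout, the sum of both absorbing scavengers.
OBSERVABLE_SPECIES = ("curcumin", "curcumin_monoacrylate", "total_signal")

#: Default initial guesses for free parameters, µM⁻¹·min⁻¹.
DEFAULT_INITIAL_GUESS = {"k_C": 100.0, "k_CM": 10.0}


@dataclass(frozen=True)
class ObservedSeries:
    """One sampled consumption curve.

    ``scale`` is ``"normalized"`` (dimensionless fraction of the initial
    signal, 1.0 at the first sample) or ``"uM"`` (absolute concentration).
    ``sigma`` optionally records the observation noise level on the same
    scale.
    """

    species: str
    times: np.ndarray
    values: np.ndarray
    scale: str = "normalized"
    sigma: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.species not in OBSERVABLE_SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.scale not in ("normalized", "uM"):
            raise ValueError(f"scale must be 'normalized' or 'uM', got {self.scale!r}")
        if self.times.size < 3:
            raise ValueError("an observed series needs at least 3 points")
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times[0] < 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("values must be finite and >= 0")
        if self.scale == "normalized" and np.any(self.values > 1.5):
            raise ValueError("normalized values above 1.5 look like a scale error")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class FitResult:
    """Outcome of a rate-constant fit."""

    rate_constants: RateConstants
    sse: float
    sse_full_stiff: float
    r_squared: dict[str, float]
    n_iterations: int
    converged: bool
    free_params: tuple[str, ...]
    initial_guess: dict[str, float]
    xtol: float
    ftol: float

    @property
    def modes_consistent(self) -> bool:
        """Quasi-steady vs full-stiff SSE agreement within 0.5% (relative)."""
        scale = max(self.sse, self.sse_full_stiff, 1e-12)
        return abs(self.sse - self.sse_full_stiff) <= 5e-3 * scale

    def as_flat_dict(self) -> dict[str, float | int | bool | str]:
        d: dict[str, float | int | bool | str] = {
            "k_C_per_uM_min": self.rate_constants.k_C,
            "k_CM_per_uM_min": self.rate_constants.k_CM,
            "sse": self.sse,
            "sse_full_stiff": self.sse_full_stiff,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "free_params": ",".join(self.free_params),
            "xtol": self.xtol,
            "ftol": self.ftol,
        }
        for sp, r2 in self.r_squared.items():
            d[f"r_squared_{sp}"] = r2
        for name, v in self.initial_guess.items():
            d[f"initial_{name}"] = v
        return d


def predict_observable(
    config: ModelConfig,
    species: str,
    times: Sequence[float],
    scale: str = "normalized",
) -> np.ndarray:
    """Model prediction sampled at ``times``, on the observed series' scale.

    In normalized mode the trajectory is divided by the model value at the
    first observation time; in absolute mode values are µM.
    """
    if species not in OBSERVABLE_SPECIES:
        raise ValueError(f"unknown species {species!r}")
    times = np.asarray(times, dtype=float)
    if times[-1] > config.horizon + 1e-9:
        raise ValueError("observation times extend beyond the simulation horizon")
    traj = simulate(config, t_eval=times)
    values = traj.species(species).copy()
    if scale == "normalized":
        ref = values[0]
        if ref <= 0:
            raise ValueError(
                f"cannot normalize: model {species} is {ref} at t={times[0]} min"
            )
        values /= ref
    elif scale != "uM":
        raise ValueError(f"scale must be 'normalized' or 'uM', got {scale!r}")
    return values


def _as_series_list(
    observed: ObservedSeries | Iterable[ObservedSeries],
) -> list[ObservedSeries]:
    if isinstance(observed, ObservedSeries):
        return [observed]
    return list(observed)


def sse(
    observed: ObservedSeries | Iterable[ObservedSeries],
    predicted: np.ndarray | Sequence[np.ndarray],
) -> float:
    """Pooled sum of squared errors over one or more series."""
    series = _as_series_list(observed)
    if len(series) == 1 and not isinstance(predicted, (list, tuple)):
        predicted = [np.asarray(predicted)]
    if len(series) != len(predicted):
        raise ValueError("number of predicted series must match observed")
    total = 0.0
    for obs, pred in zip(series, predicted):
        pred = np.asarray(pred, dtype=float)
        if pred.shape != obs.values.shape:
            raise ValueError(
                f"length mismatch for {obs.species}: {pred.shape} vs {obs.values.shape}"
            )
        total += float(np.sum((obs.values - pred) ** 2))
    return total


def r_squared(observed: ObservedSeries, predicted: np.ndarray) -> float:
    """Coefficient of determination, 1 − SSE/SST about the observed mean."""
    predicted = np.asarray(predicted, dtype=float)
    if observed.values.size < 2:
        raise ValueError("r_squared needs at least 2 observations")
    sst = float(np.sum((observed.values - observed.values.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("r_squared undefined: observed values have zero variance")
    return 1.0 - sse(observed, predicted) / sst


def _config_with(config: ModelConfig, mode: str, **rate_updates: float) -> ModelConfig:
    k = replace(config.rate_constants, **rate_updates)
    return replace(config, rate_constants=k, mode=mode)


def fit_rate_constants(
    observed: ObservedSeries | Iterable[ObservedSeries],
    config_template: ModelConfig,
    free_params: Sequence[str] = ("k_C",),
    initial_guess: dict[str, float] | None = None,
    xtol: float = 1e-6,
    ftol: float = 1e-6,
    max_iter: int = 2000,
) -> FitResult:
    """Fit consumption rate constants by simplex SSE minimization.

    ``free_params`` is a non-empty subset of {"k_C", "k_CM"}; all observed
    series contribute to one pooled SSE with equal weight. Parameters are
    optimized in log-space (positivity by construction); ``xtol`` is the
    simplex tolerance on log-parameters (hence relative on the parameters)
    and ``ftol`` the relative objective tolerance. Non-convergence within
    ``max_iter`` iterations returns ``converged=False`` rather than raising.
    """
    series = _as_series_list(observed)
    if not series:
        raise ValueError("need at least one observed series")
    free = tuple(free_params)
    if not free or any(p not in ("k_C", "k_CM") for p in free):
        raise ValueError("free_params must be a non-empty subset of {'k_C', 'k_CM'}")
    guess = dict(DEFAULT_INITIAL_GUESS)
    if initial_guess:
        guess.update(initial_guess)

    def predictions(mode: str, **updates: float) -> list[np.ndarray]:
        cfg = _config_with(config_template, mode, **updates)
        return [
            predict_observable(cfg, s.species, s.times, s.scale) for s in series
        ]

    def objective(log_x: np.ndarray) -> float:
        updates = {p: float(np.exp(v)) for p, v in zip(free, log_x)}
        try:
            return sse(series, predictions("quasi-steady-radical", **updates))
        except (ValueError, RuntimeError):
            return 1e30  # infeasible region: let the simplex back away

    x0 = np.log([guess[p] for p in free])
    f0 = objective(x0)
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": xtol,
            "fatol": ftol * max(f0, 1e-12),
            "maxiter": max_iter,
            "adaptive": False,
        },
    )
    updates = {p: float(np.exp(v)) for p, v in zip(free, res.x)}
    fitted_k = replace(config_template.rate_constants, **updates)

    pred_qssa = predictions("quasi-steady-radical", **updates)
    pred_full = predictions("full-stiff", **updates)
    r2 = {}
    for s, p in zip(series, pred_full):
        try:
            r2[s.species] = r_squared(s, p)
        except ValueError:
            r2[s.species] = float("nan")  # flat series: R² undefined

    return FitResult(
        rate_constants=fitted_k,
        sse=float(res.fun),
        sse_full_stiff=sse(series, pred_full),
        r_squared=r2,
        n_iterations=int(res.nit),
        converged=bool(res.success),
        free_params=free,
        initial_guess={p: guess[p] for p in free},
        xtol=xtol,
        ftol=ftol,
    )
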