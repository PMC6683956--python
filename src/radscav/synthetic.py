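"""Synthetic consumption curves generated from the model itself.

The raw experimental consumption data behind the fitted constants exist
only as published figures, so the estimation stage is exercised on
model-generated observations: UV-Vis-style single-signal curves (free
curcumin, normalized to the initial absorbance, sampled every 2 h over
24 h) and HPLC-style per-species curves for the released curcumin /
curcumin-monoacrylate mixture. Observation noise is additive i.i.d.
Gaussian on the normalized scale, optionally clipped at zero; every
generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import ObservedSeries, predict_observable
from .model import ModelConfig, RateConstants, SpeciesState
from .units import ug_per_ml_to_uM, mM_to_uM

__all__ = [
    "NoiseModel",
    "generate_observed_series",
    "generate_release_product_series",
    "generate_fixture_suite",
    "default_sample_times",
    "DEFAULT_CURCUMIN_UG_PER_ML",
    "DEFAULT_MONOACRYLATE_FRACTION",
]

#: Free-curcumin working concentration, µg/ml (≈ 135.7 µM).
DEFAULT_CURCUMIN_UG_PER_ML = 50.0
#: Fraction of released molecules carrying a residual acrylate group.
DEFAULT_MONOACRYLATE_FRACTION = 0.4
#: Observation noise on the normalized scale (comparable to published
#: error bars; an assumption, not a measured value).
DEFAULT_SIGMA = 0.02


def default_sample_times(horizon: float = 1440.0, interval: float = 120.0) -> np.ndarray:
    """Sampling every 2 h over 24 h: 13 points including t = 0."""
    return np.arange(0.0, horizon + 0.5 * interval, interval)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian observation noise on the normalized scale."""

    sigma: float = DEFAULT_SIGMA
    clip_at_zero: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        noisy = values + rng.normal(0.0, self.sigma, size=values.shape) \
            if self.sigma > 0 else values.copy()
        if self.clip_at_zero:
            noisy = np.clip(noisy, 0.0, None)
        return noisy


def generate_observed_series(
    config: ModelConfig,
    sample_times: Sequence[float],
    noise: NoiseModel,
    species: str = "curcumin",
    rng: np.random.Generator | None = None,
) -> ObservedSeries:
    """Normalized model prediction at the sample times plus observation noise."""
    sample_times = np.asarray(sample_times, dtype=float)
    clean = predict_observable(config, species, sample_times, scale="normalized")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    return ObservedSeries(
        species=species,
        times=sample_times,
        values=noise.apply(clean, rng),
        scale="normalized",
        sigma=noise.sigma,
    )


def release_products_config(
    k: RateConstants,
    total_uM: float,
    aaph_mM: float,
    monoacrylate_fraction: float = DEFAULT_MONOACRYLATE_FRACTION,
    horizon: float = 1440.0,
    mode: str = "quasi-steady-radical",
) -> ModelConfig:
    """Fully degraded supernatant: both release products present at t = 0."""
    if not 0.0 <= monoacrylate_fraction <= 1.0:
        raise ValueError("monoacrylate_fraction must be in [0, 1]")
    return ModelConfig(
        rate_constants=k,
        initial_state=SpeciesState(
            C_A=mM_to_uM(aaph_mM),
            C_C=total_uM * (1.0 - monoacrylate_fraction),
            C_CM=total_uM * monoacrylate_fraction,
        ),
        horizon=horizon,
        mode=mode,
    )


def generate_release_product_series(
    k: RateConstants,
    sample_times: Sequence[float],
    noise: NoiseModel,
    total_uM: float | None = None,
    aaph_mM: float = 10.0,
    monoacrylate_fraction: float = DEFAULT_MONOACRYLATE_FRACTION,
) -> tuple[ObservedSeries, ...]:
    """Per-species noisy curves for the released curcumin/monoacrylate mixture.

    The two species start in solution together (fully degraded carrier),
    share the radical pool, and are consumed at their respective
    second-order rates. With a zero monoacrylate fraction this reduces to
    the single-species generator. Returns (curcumin series[, monoacrylate
    series]); noise draws for the two series come from one seeded stream.
    """
    if total_uM is None:
        total_uM = ug_per_ml_to_uM(DEFAULT_CURCUMIN_UG_PER_ML)
    config = release_products_config(k, total_uM, aaph_mM, monoacrylate_fraction)
    rng = np.random.default_rng(noise.seed)
    out = [generate_observed_series(config, sample_times, noise, "curcumin", rng)]
    if monoacrylate_fraction > 0.0:
        out.append(
            generate_observed_series(
                config, sample_times, noise, "curcumin_monoacrylate", rng
            )
        )
    return tuple(out)


def _write_series_csv(path: Path, series: Sequence[ObservedSeries]) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_min": s.times,
                "species": s.species,
                "value": s.values,
                "scale": s.scale,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def generate_fixture_suite(out_dir, base_seed: int = 0) -> list[dict]:
    """Write the deterministic CSV fixture set and its manifest.

    Fixtures: free curcumin at 10 and 100 mM AAPH (k_C = 200) and release
    products at both AAPH levels (k_C = 75, k_CM = 25), each noiseless and
    at σ = 0.02. Returns the manifest records; also writes
    ``manifest.txt`` (one ``key=value ...`` line per fixture).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    times = default_sample_times()
    curcumin_uM = ug_per_ml_to_uM(DEFAULT_CURCUMIN_UG_PER_ML)
    free_k = RateConstants(k_C=200.0)
    release_k = RateConstants(k_C=75.0, k_CM=25.0)
    manifest: list[dict] = []
    index = 0
    for aaph_mM in (10.0, 100.0):
        for sigma in (0.0, DEFAULT_SIGMA):
            seed = base_seed + index
            index += 1
            noise = NoiseModel(sigma=sigma, seed=seed)
            name = f"free_curcumin_aaph{aaph_mM:g}mM_sigma{sigma:g}.csv"
            config = ModelConfig(
                rate_constants=free_k,
                initial_state=SpeciesState(C_A=mM_to_uM(aaph_mM), C_C=curcumin_uM),
                mode="quasi-steady-radical",
            )
            series = [generate_observed_series(config, times, noise)]
            _write_series_csv(out_dir / name, series)
            manifest.append(
                dict(file=name, kind="free_curcumin", aaph_mM=aaph_mM,
                     curcumin_uM=curcumin_uM, k_C=free_k.k_C, sigma=sigma,
                     seed=seed, n_species=1)
            )
    for aaph_mM in (10.0, 100.0):
        for sigma in (0.0, DEFAULT_SIGMA):
            seed = base_seed + index
            index += 1
            noise = NoiseModel(sigma=sigma, seed=seed)
            name = f"release_products_aaph{aaph_mM:g}mM_sigma{sigma:g}.csv"
            series = generate_release_product_series(
                release_k, times, noise, aaph_mM=aaph_mM
            )
            _write_series_csv(out_dir / name, series)
            manifest.append(
                dict(file=name, kind="release_products", aaph_mM=aaph_mM,
                     total_uM=curcumin_uM,
                     monoacrylate_fraction=DEFAULT_MONOACRYLATE_FRACTION,
                     k_C=release_k.k_C, k_CM=release_k.k_CM, sigma=sigma,
                     seed=seed, n_species=2)
            )
    with open(out_dir / "manifest.txt", "w") as fh:
        for rec in manifest:
            fh.write(" ".join(f"{k}={v}" for k, v in rec.items()) + "\n")
    return manifest
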