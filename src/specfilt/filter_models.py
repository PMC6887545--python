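"""Analytic filter models and the single-parameter sweep experiment.

Cut-off ("blue-blocking") filters are modelled by a sigmoid transmittance

    T(λ) = L / (1 + exp(−k (λ − λ₀)))

with cut-off wavelength λ₀ (nm), upper asymptote L ∈ (0, 1] and slope k > 0
(per nm). Neutral-density and notch models complete the common filter
shapes. Sweeping one sigmoid parameter while holding the others fixed shows
how each aspect of a transmittance curve drives the four retinal metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .metrics import FilterMetrics, compute_filter_metrics
from .spectra import GridSpec, SpectralSamples
from .standards import StandardsBundle

__all__ = [
    "SigmoidFilterParams",
    "SweepResult",
    "sigmoid_filter",
    "nd_filter",
    "notch_filter",
    "run_parameter_sweep",
    "SWEEP_PARAMETERS",
]

SWEEP_PARAMETERS = ("lambda0_nm", "upper_asymptote", "slope")


@dataclass(frozen=True)
class SigmoidFilterParams:
    lambda0_nm: float
    upper_asymptote: float = 0.9
    slope: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.upper_asymptote <= 1.0):
            raise ValueError(f"upper asymptote must be in (0, 1], got {self.upper_asymptote}")
        if not self.slope > 0:
            raise ValueError(f"slope must be positive, got {self.slope}")


@dataclass
class SweepResult:
    varied_parameter: str
    values: np.ndarray
    metrics: list[FilterMetrics]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.metrics):
            raise ValueError("values and metrics must align")

    def column(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.metrics])


def sigmoid_filter(p: SigmoidFilterParams, grid: Optional[GridSpec] = None) -> SpectralSamples:
    """Long-pass sigmoid transmittance; T(λ₀) = L/2, sup T = L."""
    grid = grid or GridSpec()
    lam = grid.wavelengths()
    if not (grid.start_nm <= p.lambda0_nm <= grid.end_nm):
        raise ValueError(
            f"cut-off {p.lambda0_nm} nm outside grid span {grid.start_nm}–{grid.end_nm} nm"
        )
    # exp(-k(λ-λ0)) can overflow harmlessly far below the cut-off; compute in
    # a clipped exponent for exactness of the asymptotes
    z = np.clip(-p.slope * (lam - p.lambda0_nm), -700.0, 700.0)
    t = p.upper_asymptote / (1.0 + np.exp(z))
    return SpectralSamples(lam, t, kind="transmittance", cleaned=True)


def nd_filter(transmittance: float, grid: Optional[GridSpec] = None) -> SpectralSamples:
    """Spectrally flat (neutral-density) filter. Density d ⇔ T = 10^−d."""
    grid = grid or GridSpec()
    if not (0.0 < transmittance <= 1.0):
        raise ValueError(f"transmittance must be in (0, 1], got {transmittance}")
    lam = grid.wavelengths()
    return SpectralSamples(lam, np.full_like(lam, transmittance), kind="transmittance", cleaned=True)


def notch_filter(
    center_nm: float,
    width_nm: float,
    depth: float,
    grid: Optional[GridSpec] = None,
    edge_nm: float = 10.0,
) -> SpectralSamples:
    """Band-stop filter: T = 1 outside the band, 1 − depth inside.

    The band covers center ± width/2 with raised-cosine transitions of
    ``edge_nm`` width on either side (an analytic stand-in for real notch
    coatings, which roll off smoothly).
    """
    grid = grid or GridSpec()
    if not width_nm > 0:
        raise ValueError(f"width must be positive, got {width_nm}")
    if not (0.0 <= depth <= 1.0):
        raise ValueError(f"depth must be in [0, 1], got {depth}")
    lam = grid.wavelengths()
    half = width_nm / 2.0
    lo, hi = center_nm - half, center_nm + half
    attenuation = np.zeros_like(lam)
    attenuation[(lam >= lo) & (lam <= hi)] = 1.0
    if edge_nm > 0:
        left = (lam >= lo - edge_nm) & (lam < lo)
        attenuation[left] = 0.5 * (1.0 + np.cos(np.pi * (lo - lam[left]) / edge_nm))
        right = (lam > hi) & (lam <= hi + edge_nm)
        attenuation[right] = 0.5 * (1.0 + np.cos(np.pi * (lam[right] - hi) / edge_nm))
    t = 1.0 - depth * attenuation
    return SpectralSamples(lam, t, kind="transmittance", cleaned=True)


def run_parameter_sweep(
    base: SigmoidFilterParams,
    parameter: str,
    values: Sequence[float],
    bundle: StandardsBundle,
) -> SweepResult:
    """Metrics of a family of sigmoid filters varying one parameter in isolation."""
    if parameter not in SWEEP_PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}; choose from {SWEEP_PARAMETERS}")
    metrics = []
    for v in values:
        p = replace(base, **{parameter: float(v)})
        metrics.append(compute_filter_metrics(sigmoid_filter(p, bundle.grid), bundle))
    return SweepResult(varied_parameter=parameter, values=np.asarray(values, float), metrics=metrics)


def default_sweep_values(parameter: str) -> np.ndarray:
    """Default parameter ranges for the three sweeps (configurable at call sites)."""
    if parameter == "lambda0_nm":
        return np.arange(450.0, 601.0, 10.0)
    if parameter == "upper_asymptote":
        return np.arange(0.1, 0.95, 0.1)
    if parameter == "slope":
        return np.geomspace(0.05, 1.0, 10)
    raise ValueError(f"unknown parameter {parameter!r}")
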