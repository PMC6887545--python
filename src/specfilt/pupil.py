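"""Light-adapted pupil diameter and retinal illuminance under filters.

Uses the unified light-adapted pupil-size formula of Watson & Yellott
(2012): the Stanley–Davies luminance term evaluated at the *corneal flux
density* F = L·a·M(e) — luminance (cd/m²) × field area (deg²) × a monocular
attenuation factor (0.1 for one eye, 1 for two) — plus a linear age
correction:

    D_SD(F) = 7.75 − 5.75 · (F/846)^0.41 / ((F/846)^0.41 + 2)
    D(F, y) = D_SD(F) + (y − 28.58) · (0.02132 − 0.009562 · D_SD(F))

Retinal illuminance in trolands is luminance × pupil area (mm²). Because
pupil area spans at most ~16× (2 mm – 8 mm diameter), a neutral-density
filter's effect on retinal illuminance is dominated by its transmittance,
not by pupil dilation — the log–log retinal-illuminance curves for ND
filters are near-parallel.

Only spectrally uniform (neutral-density) filters are treated here;
melanopsin-driven contributions to steady-state pupil size are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ViewingConditions",
    "RetinalIlluminanceCurve",
    "PupilModelDomainError",
    "pupil_diameter",
    "retinal_illuminance_curve",
    "default_luminance_grid",
]

# Unified-formula constants (one auditable block)
_STANLEY_DAVIES_MAX_MM = 7.75      # dark asymptote of D_SD
_STANLEY_DAVIES_RANGE_MM = 5.75    # D_SD bright asymptote = 7.75 - 5.75 = 2.0
_FLUX_SCALE = 846.0                # corneal flux density scale (cd/m² · deg²)
_FLUX_EXPONENT = 0.41
_AGE_REFERENCE_YEARS = 28.58
_AGE_SLOPE_A = 0.02132             # mm per year
_AGE_SLOPE_B = 0.009562            # per year, multiplies D_SD
_MONOCULAR_FACTOR = 0.1
_AGE_VALIDITY = (20.0, 80.0)
_DIAMETER_PLAUSIBLE_MM = (2.0, 9.0)


class PupilModelDomainError(ValueError):
    """Input outside the pupil model's validity range."""


@dataclass(frozen=True)
class ViewingConditions:
    """Defaults approximate real-world viewing: full-field, adult, both eyes."""

    field_diameter_deg: float = 150.0
    age_years: float = 32.0
    n_eyes: str = "binocular"

    def __post_init__(self) -> None:
        if not self.field_diameter_deg > 0:
            raise PupilModelDomainError(
                f"field diameter must be positive, got {self.field_diameter_deg}"
            )
        lo, hi = _AGE_VALIDITY
        if not (lo <= self.age_years <= hi):
            raise PupilModelDomainError(
                f"age {self.age_years} outside model validity range {lo}–{hi} years"
            )
        if self.n_eyes not in ("monocular", "binocular"):
            raise PupilModelDomainError(f"n_eyes must be monocular or binocular, got {self.n_eyes!r}")

    @property
    def field_area_deg2(self) -> float:
        return float(np.pi * (self.field_diameter_deg / 2.0) ** 2)

    @property
    def eye_factor(self) -> float:
        return 1.0 if self.n_eyes == "binocular" else _MONOCULAR_FACTOR


def _stanley_davies(flux: np.ndarray) -> np.ndarray:
    g = np.power(flux / _FLUX_SCALE, _FLUX_EXPONENT)
    return _STANLEY_DAVIES_MAX_MM - _STANLEY_DAVIES_RANGE_MM * g / (g + 2.0)


def pupil_diameter(
    luminance_cd_m2: float | np.ndarray,
    vc: ViewingConditions = ViewingConditions(),
    clamp: bool = True,
) -> float | np.ndarray:
    """Light-adapted pupil diameter (mm) from the unified formula.

    Diameters outside the plausible 2–9 mm range are clamped with a warning
    (``clamp=False`` returns the raw model value). Scalar in → scalar out.
    """
    lum = np.asarray(luminance_cd_m2, dtype=float)
    if np.any(lum <= 0) or not np.all(np.isfinite(lum)):
        raise PupilModelDomainError("luminance must be positive and finite (cd/m²)")
    flux = lum * vc.field_area_deg2 * vc.eye_factor
    d_sd = _stanley_davies(flux)
    d = d_sd + (vc.age_years - _AGE_REFERENCE_YEARS) * (_AGE_SLOPE_A - _AGE_SLOPE_B * d_sd)
    lo, hi = _DIAMETER_PLAUSIBLE_MM
    if clamp and np.any((d < lo) | (d > hi)):
        warnings.warn(
            "pupil diameter outside plausible range clamped to [2, 9] mm", stacklevel=2
        )
        d = np.clip(d, lo, hi)
    return float(d) if np.isscalar(luminance_cd_m2) else d


@dataclass
class RetinalIlluminanceCurve:
    """Retinal illuminance (trolands = cd/m² × mm²) across a luminance sweep."""

    luminances_cd_m2: np.ndarray
    pupil_diameters_mm: np.ndarray
    retinal_illuminances_td: np.ndarray
    filter_transmittance: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.luminances_cd_m2)
        if not (len(self.pupil_diameters_mm) == n == len(self.retinal_illuminances_td)):
            raise ValueError("curve arrays must align")


def retinal_illuminance_curve(
    luminances: Sequence[float] | np.ndarray,
    vc: ViewingConditions = ViewingConditions(),
    filter_transmittance: float = 1.0,
) -> RetinalIlluminanceCurve:
    """Pupil and retinal illuminance over a luminance sweep, through an ND filter.

    The filter attenuates the corneal stimulus, so the pupil adapts to the
    *effective* luminance L·T; retinal illuminance is L·T × pupil area.
    """
    if not (0.0 < filter_transmittance <= 1.0):
        raise ValueError(f"filter transmittance must be in (0, 1], got {filter_transmittance}")
    lum = np.asarray(luminances, dtype=float)
    effective = lum * filter_transmittance
    d = pupil_diameter(effective, vc)
    area_mm2 = np.pi * (np.asarray(d) / 2.0) ** 2
    return RetinalIlluminanceCurve(
        luminances_cd_m2=lum,
        pupil_diameters_mm=np.asarray(d),
        retinal_illuminances_td=effective * area_mm2,
        filter_transmittance=filter_transmittance,
    )


def default_luminance_grid(n: int = 50) -> np.ndarray:
    """10⁻³…10⁴ cd/m², log-spaced — full scotopic-to-bright-daylight span."""
    return np.logspace(-3, 4, n)
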