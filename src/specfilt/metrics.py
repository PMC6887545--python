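"""The four retinally referenced filter metrics.

Given a filter transmittance F(λ) and a standards bundle, compute:

* **luminous transmittance** — Σ F·E_D65·V₁₀ Δλ / Σ E_D65·V₁₀ Δλ over
  380–780 nm: the fraction of D65 luminance surviving the filter;
* **melanopsin transmittance** — the same ratio with the melanopic spectral
  sensitivity in place of V₁₀;
* **colour shift** — Euclidean distance Δu′v′ between the chromaticity of
  D65 seen through the filter and without it, in the CIE 1976 u′₁₀v′₁₀
  uniform chromaticity space (CIE 1964 10° observer);
* **gamut ratio** — area of the convex hull of the u′₁₀v′₁₀ chromaticities
  of a fixed reflectance set under filtered D65, divided by the hull area
  under unfiltered D65.

Integration is a plain rectangle (Riemann) sum with Δλ equal to the grid
step, matching the defining formulas; at 1 nm the difference from higher
order rules is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .spectra import GridSpec, SpectralSamples
from .standards import ObserverSet, StandardsBundle

__all__ = [
    "Chromaticity",
    "FilterMetrics",
    "GridMismatchError",
    "weighted_transmittance",
    "tristimulus10",
    "uv_prime",
    "gamut_hull_area",
    "compute_filter_metrics",
]


class GridMismatchError(ValueError):
    """Spectra combined in one integral must share one wavelength grid."""


@dataclass(frozen=True)
class Chromaticity:
    u_prime: float
    v_prime: float

    def distance(self, other: "Chromaticity") -> float:
        return float(np.hypot(self.u_prime - other.u_prime, self.v_prime - other.v_prime))


@dataclass
class FilterMetrics:
    """Per-filter outcomes. Transmittances and gamut ratio are fractions."""

    luminous_transmittance: float
    melanopsin_transmittance: float
    colour_shift: float
    gamut_ratio: float
    white_point_filtered: Chromaticity
    #: reflectances whose filtered spectral distribution was numerically zero
    #: and were excluded from the hull
    n_degenerate_reflectances: int = 0
    degenerate_gamut: bool = False

    def as_dict(self, percent: bool = False) -> dict:
        d = {
            "luminous_transmittance": self.luminous_transmittance,
            "melanopsin_transmittance": self.melanopsin_transmittance,
            "colour_shift": self.colour_shift,
            "gamut_ratio": self.gamut_ratio,
        }
        if percent:
            d = {
                k: (v * 100.0 if k != "colour_shift" else v) for k, v in d.items()
            }
        return d


def _check_shared_grid(*spectra: SpectralSamples) -> np.ndarray:
    w0 = spectra[0].wavelengths_nm
    for s in spectra[1:]:
        if len(s) != len(w0) or not np.allclose(s.wavelengths_nm, w0, atol=1e-9):
            raise GridMismatchError("spectra are not on a shared wavelength grid")
    return w0


def _delta_lambda(w: np.ndarray) -> float:
    steps = np.diff(w)
    if not np.allclose(steps, steps[0], atol=1e-9):
        raise GridMismatchError("integration requires a uniform grid")
    return float(steps[0])


def weighted_transmittance(
    filt: SpectralSamples,
    illuminant: SpectralSamples,
    sensitivity: SpectralSamples,
) -> float:
    """Fraction of sensitivity-weighted illuminant power passed by the filter.

    Σ F(λ)E(λ)S(λ)Δλ / Σ E(λ)S(λ)Δλ, rectangle rule on the shared grid.
    """
    w = _check_shared_grid(filt, illuminant, sensitivity)
    dl = _delta_lambda(w)
    weight = illuminant.values * sensitivity.values
    denom = float(np.sum(weight) * dl)
    if denom <= 0:
        raise ValueError("degenerate sensitivity/illuminant: weighting integral is zero")
    num = float(np.sum(filt.values * weight) * dl)
    return num / denom


def tristimulus10(spd: SpectralSamples, observer: ObserverSet) -> tuple[float, float, float]:
    """CIE 1964 10° tristimulus values of a spectral power distribution."""
    w = _check_shared_grid(spd, observer.xbar10, observer.ybar10, observer.zbar10)
    dl = _delta_lambda(w)
    X = float(np.sum(spd.values * observer.xbar10.values) * dl)
    Y = float(np.sum(spd.values * observer.ybar10.values) * dl)
    Z = float(np.sum(spd.values * observer.zbar10.values) * dl)
    return X, Y, Z


def uv_prime(X: float, Y: float, Z: float) -> Chromaticity:
    """CIE 1976 u′v′ chromaticity: u′ = 4X/(X+15Y+3Z), v′ = 9Y/(X+15Y+3Z)."""
    denom = X + 15.0 * Y + 3.0 * Z
    if denom <= 0:
        raise ValueError("degenerate stimulus: X + 15Y + 3Z must be positive")
    return Chromaticity(4.0 * X / denom, 9.0 * Y / denom)


def gamut_hull_area(chromaticities: list[Chromaticity] | np.ndarray) -> float:
    """Area of the 2-D convex hull of chromaticity points; degenerate sets → 0."""
    pts = np.asarray(
        [(c.u_prime, c.v_prime) for c in chromaticities]
        if chromaticities and isinstance(chromaticities[0], Chromaticity)
        else chromaticities,
        dtype=float,
    )
    if len(pts) < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear or coincident points
        return 0.0
    # for 2-D input, ConvexHull.volume is the enclosed area
    return float(hull.volume)


def _reflectance_chromaticities(
    illuminant_values: np.ndarray, bundle: StandardsBundle
) -> tuple[list[Chromaticity], int]:
    grid_w = bundle.grid.wavelengths()
    chroma: list[Chromaticity] = []
    n_degenerate = 0
    for refl in bundle.reflectances.samples:
        spd = SpectralSamples(grid_w, illuminant_values * refl.values, kind="power")
        X, Y, Z = tristimulus10(spd, bundle.observer)
        if X + 15.0 * Y + 3.0 * Z <= 1e-300:
            n_degenerate += 1
            continue
        chroma.append(uv_prime(X, Y, Z))
    return chroma, n_degenerate


def compute_filter_metrics(filt: SpectralSamples, bundle: StandardsBundle) -> FilterMetrics:
    """All four metrics of one cleaned filter transmittance under the bundle.

    Near-black filtered reflectances (numerically zero stimulus) are dropped
    from the hull with their count recorded; if fewer than three distinct
    chromaticities remain the gamut is flagged degenerate and the ratio is 0.
    """
    if not filt.on_grid(bundle.grid):
        raise GridMismatchError("filter is not on the bundle grid; run clean_and_resample first")

    lum = weighted_transmittance(filt, bundle.d65, bundle.observer.v10)
    mel = weighted_transmittance(filt, bundle.d65, bundle.melanopic.s_mel)

    white = uv_prime(*tristimulus10(bundle.d65, bundle.observer))
    filtered_d65 = bundle.d65.with_values(bundle.d65.values * filt.values)
    try:
        white_f = uv_prime(*tristimulus10(filtered_d65, bundle.observer))
        shift = white.distance(white_f)
    except ValueError:  # fully opaque filter: no transmitted white point
        white_f = white
        shift = 0.0

    chroma_ref, _ = _reflectance_chromaticities(bundle.d65.values, bundle)
    area_ref = gamut_hull_area(chroma_ref)
    chroma_filt, n_deg = _reflectance_chromaticities(filtered_d65.values, bundle)
    area_filt = gamut_hull_area(chroma_filt)

    degenerate = len(chroma_filt) < 3 or area_filt == 0.0
    ratio = 0.0 if degenerate or area_ref <= 0 else area_filt / area_ref

    return FilterMetrics(
        luminous_transmittance=lum,
        melanopsin_transmittance=mel,
        colour_shift=shift,
        gamut_ratio=ratio,
        white_point_filtered=white_f,
        n_degenerate_reflectances=n_deg,
        degenerate_gamut=degenerate,
    )
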