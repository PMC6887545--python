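"""Fixed reference functions for the retinally referenced filter metrics.

The metrics weight a filter's transmittance against:

* the CIE 1964 10° colour-matching functions (x̄₁₀, ȳ₁₀, z̄₁₀), with ȳ₁₀
  serving as the large-field luminosity function V₁₀(λ) — bundled as the
  standard 10 nm tabulation and resampled to the working grid;
* the D65 daylight illuminant (CCT 6500 K), bundled likewise;
* a melanopic spectral sensitivity constructed from the Govardovskii A1
  visual-pigment template at λ_max = 480 nm, converted from quantal to
  energy units and weighted by an ocular-media (lens) transmittance model —
  the construction underlying the standardized melanopic action spectrum;
* a set of 99 surface reflectances used to span a colour gamut. The IES
  TM-30 Color Evaluation Samples are not redistributable here, so the
  default set is a seeded synthetic stand-in of 99 smooth reflectances
  (``source_id`` records this).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .spectra import GridSpec, SpectralSamples, clean_and_resample, read_spectrum

__all__ = [
    "ObserverSet",
    "MelanopicSensitivity",
    "ReflectanceSet",
    "StandardsBundle",
    "govardovskii_template",
    "lens_transmittance",
    "melanopic_sensitivity",
    "synthetic_reflectances",
    "load_standards",
]

#: λ_max validity range of the pigment template (nm)
GOVARDOVSKII_LAMBDA_RANGE = (400.0, 620.0)

MELANOPSIN_LAMBDA_MAX_NM = 480.0

LENS_MODELS = ("standard-adult", "none")


@dataclass
class ObserverSet:
    """CIE 1964 10° colour-matching functions on the working grid."""

    xbar10: SpectralSamples
    ybar10: SpectralSamples
    zbar10: SpectralSamples

    @property
    def v10(self) -> SpectralSamples:
        """Large-field luminosity function V₁₀(λ) ≡ ȳ₁₀(λ)."""
        return self.ybar10


@dataclass
class MelanopicSensitivity:
    s_mel: SpectralSamples
    lambda_max_nm: float
    lens_model_id: str
    #: wavelength of the constructed function's peak; sits a few nm long of
    #: λ_max because the lens absorbs short wavelengths and the quantal→energy
    #: conversion weights long wavelengths up
    peak_nm: float = 0.0


@dataclass
class ReflectanceSet:
    samples: list[SpectralSamples]
    source_id: str

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class StandardsBundle:
    grid: GridSpec
    observer: ObserverSet
    d65: SpectralSamples
    melanopic: MelanopicSensitivity
    reflectances: ReflectanceSet


def govardovskii_template(lambda_max_nm: float, grid: Optional[GridSpec] = None) -> SpectralSamples:
    """Alpha-band A1 visual-pigment absorbance template, peak-normalized.

    S(λ) = 1 / (e^{A(a−x)} + e^{B(b−x)} + e^{C(c−x)} + D) with x = λ_max/λ,
    A = 69.7, B = 28, C = −14.9, D = 0.674, b = 0.922, c = 1.104 and
    a = 0.8795 + 0.0459·e^{−(λ_max−300)²/11940}. This is the standard
    analytic nomogram for vertebrate A1 pigments, valid for λ_max roughly
    in the 400–620 nm range. The template is quantal-referenced.
    """
    lo, hi = GOVARDOVSKII_LAMBDA_RANGE
    if not (lo <= lambda_max_nm <= hi):
        raise ValueError(
            f"lambda_max {lambda_max_nm} nm outside template validity range {lo}–{hi} nm"
        )
    grid = grid or GridSpec()
    lam = grid.wavelengths()
    x = lambda_max_nm / lam
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max_nm - 300.0) ** 2) / 11940.0)
    s = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    s /= s.max()
    return SpectralSamples(lam, s, kind="sensitivity", cleaned=True)


def lens_transmittance(grid: Optional[GridSpec] = None, model_id: str = "standard-adult") -> SpectralSamples:
    """Ocular-media spectral transmittance of an adult standard observer.

    ``standard-adult`` is a simplified analytic model written for this
    package: optical density D(λ) = 0.48·e^{−(λ−400)/60} for λ ≥ 400 nm,
    rising linearly below 400 nm, T = 10^{−D}. It reproduces the gross
    behaviour of adult ocular media — strong short-wavelength absorption
    (T ≈ 0.33 at 400 nm, ≈ 0.62 at 450 nm) and near-transparency beyond
    600 nm. ``none`` is the identity (no pre-receptoral filtering).
    """
    grid = grid or GridSpec()
    lam = grid.wavelengths()
    if model_id == "none":
        return SpectralSamples(lam, np.ones_like(lam), kind="transmittance", cleaned=True)
    if model_id != "standard-adult":
        raise ValueError(f"unknown lens model {model_id!r}; available: {LENS_MODELS}")
    density = 0.48 * np.exp(-(lam - 400.0) / 60.0)
    below = lam < 400.0
    # steeper rise into the UV; exact shape immaterial above the 380 nm cut
    density[below] = 0.48 * (1.0 + (400.0 - lam[below]) / 40.0)
    t = np.power(10.0, -density)
    return SpectralSamples(lam, t, kind="transmittance", cleaned=True)


def melanopic_sensitivity(
    grid: Optional[GridSpec] = None,
    lens_model_id: str = "standard-adult",
    quantal_to_energy: bool = True,
) -> MelanopicSensitivity:
    """Melanopic spectral sensitivity, peak-normalized, energy-referenced.

    Constructed as the Govardovskii template at λ_max = 480 nm (quantal),
    multiplied by λ (quantal → energy conversion, up to a constant) and by
    the ocular-media transmittance, then renormalized to peak 1. With the
    default adult lens the peak lands near 490 nm, as expected for the
    standardized melanopic function; with ``lens_model_id="none"`` and
    ``quantal_to_energy=False`` the result is exactly the retinal template.
    """
    grid = grid or GridSpec()
    template = govardovskii_template(MELANOPSIN_LAMBDA_MAX_NM, grid)
    lam = grid.wavelengths()
    s = template.values.copy()
    if quantal_to_energy:
        s = s * lam
    lens = lens_transmittance(grid, lens_model_id)
    s = s * lens.values
    s /= s.max()
    peak = float(lam[np.argmax(s)])
    return MelanopicSensitivity(
        s_mel=SpectralSamples(lam, s, kind="sensitivity", cleaned=True),
        lambda_max_nm=MELANOPSIN_LAMBDA_MAX_NM,
        lens_model_id=lens_model_id,
        peak_nm=peak,
    )


def synthetic_reflectances(
    grid: Optional[GridSpec] = None, n: int = 99, seed: int = 20990
) -> ReflectanceSet:
    """Seeded synthetic stand-in for the 99 colour-evaluation reflectances.

    Each sample is a smooth spectral reflectance: a neutral base plus one to
    three Gaussian bumps of varying centre, width and sign, clipped to
    [0.02, 0.95]. The set spans a wide chromaticity region so convex-hull
    gamut areas are well conditioned, but it is synthetic — it does not
    reproduce the statistics of measured object colours.
    """
    grid = grid or GridSpec()
    lam = grid.wavelengths()
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n):
        base = rng.uniform(0.15, 0.65)
        r = np.full_like(lam, base)
        for _ in range(rng.integers(1, 4)):
            center = rng.uniform(400.0, 700.0)
            width = rng.uniform(30.0, 120.0)
            amp = rng.uniform(-0.6, 0.7)
            r = r + amp * np.exp(-0.5 * ((lam - center) / width) ** 2)
        r = np.clip(r, 0.02, 0.95)
        samples.append(SpectralSamples(lam, r, kind="reflectance", cleaned=True))
    return ReflectanceSet(samples=samples, source_id=f"synthetic-{n}(seed={seed})")


def _load_bundled(name: str, value_col: str, kind: str, grid: GridSpec) -> SpectralSamples:
    ref = resources.files("specfilt").joinpath("data", name)
    try:
        with resources.as_file(ref) as path:
            raw = read_spectrum(path, column_map={"value": value_col}, kind=kind)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"bundled reference table missing: {name}") from exc
    # reference tables cover the full working span; interpolation only, the
    # zero-fill branch of the cleaner is never reached for the default grid
    return clean_and_resample(raw, grid)


def load_standards(
    grid: Optional[GridSpec] = None,
    lens_model_id: str = "standard-adult",
    reflectance_seed: int = 20990,
    n_reflectances: int = 99,
) -> StandardsBundle:
    """Assemble the observer, illuminant, melanopic and reflectance set on one grid."""
    grid = grid or GridSpec()
    observer = ObserverSet(
        xbar10=_load_bundled("cie1964_observer_10nm.csv", "xbar10", "sensitivity", grid),
        ybar10=_load_bundled("cie1964_observer_10nm.csv", "ybar10", "sensitivity", grid),
        zbar10=_load_bundled("cie1964_observer_10nm.csv", "zbar10", "sensitivity", grid),
    )
    d65 = _load_bundled("d65_10nm.csv", "relative_power", "power", grid)
    mel = melanopic_sensitivity(grid, lens_model_id)
    refl = synthetic_reflectances(grid, n=n_reflectances, seed=reflectance_seed)
    return StandardsBundle(grid=grid, observer=observer, d65=d65, melanopic=mel, reflectances=refl)
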