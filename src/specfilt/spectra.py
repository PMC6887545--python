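"""Spectral sample containers, file I/O, and the digitized-curve cleaning pipeline.

Everything downstream works with :class:`SpectralSamples` — a wavelength grid
(nm) with one value per wavelength — whether the values are a filter
transmittance, a photoreceptor sensitivity, an illuminant power distribution,
or a surface reflectance.

Digitized transmittance curves (extracted from published graphs) arrive on
irregular grids, may miss the short- and long-wavelength ends of the visible
range, and carry small digitization errors including negative dips.
:func:`clean_and_resample` applies the standard post-processing: PCHIP
interpolation to the working grid, zero-fill outside the measured span, and
clipping of out-of-range values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "SpectralSamples",
    "GridSpec",
    "SpectralDataError",
    "SpectralFormatError",
    "TransmittanceClippedWarning",
    "read_spectrum",
    "clean_and_resample",
    "write_spectrum",
]

VALID_KINDS = ("transmittance", "sensitivity", "power", "reflectance")

#: kinds whose values are physically bounded to [0, 1] after cleaning
BOUNDED_KINDS = ("transmittance", "reflectance")


class SpectralDataError(ValueError):
    """Raised when spectral data is unusable (too short, disjoint span, ...)."""


class SpectralFormatError(ValueError):
    """Raised when a spectral file's layout cannot be interpreted."""


class TransmittanceClippedWarning(UserWarning):
    """Emitted when values above 1 are clipped during cleaning."""


@dataclass(frozen=True)
class GridSpec:
    """Uniform wavelength grid, default 380–780 nm at 1 nm.

    The default span matches the integration bounds of the transmittance
    metrics; the 1 nm step matches the resolution digitized spectra are
    interpolated to.
    """

    start_nm: float = 380.0
    end_nm: float = 780.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not (self.start_nm < self.end_nm):
            raise ValueError(f"grid start {self.start_nm} must be < end {self.end_nm}")
        if not self.step_nm > 0:
            raise ValueError(f"grid step must be positive, got {self.step_nm}")
        n = (self.end_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"span {self.start_nm}–{self.end_nm} not divisible by step {self.step_nm}"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    @classmethod
    def parse(cls, text: str) -> "GridSpec":
        """Parse ``"380:780:1"`` shorthand."""
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"expected start:end:step, got {text!r}")
        return cls(float(parts[0]), float(parts[1]), float(parts[2]))


@dataclass
class SpectralSamples:
    """A spectrum: strictly increasing wavelengths (nm) with one value each."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "transmittance"
    #: set by clean_and_resample; bounded kinds are guaranteed in [0,1] only then
    cleaned: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if self.wavelengths_nm.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if len(self.wavelengths_nm) != len(self.values):
            raise ValueError(
                f"length mismatch: {len(self.wavelengths_nm)} wavelengths, "
                f"{len(self.values)} values"
            )
        if not (np.all(np.isfinite(self.wavelengths_nm)) and np.all(np.isfinite(self.values))):
            raise ValueError("non-finite entries in spectral data")
        if len(self.wavelengths_nm) > 1 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return len(self.wavelengths_nm)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def with_values(self, values: np.ndarray, kind: Optional[str] = None) -> "SpectralSamples":
        """Same grid, new values (used for filter × illuminant products etc.)."""
        return SpectralSamples(
            self.wavelengths_nm.copy(),
            np.asarray(values, dtype=float),
            kind or self.kind,
            cleaned=self.cleaned,
        )

    def on_grid(self, grid: GridSpec, atol: float = 1e-9) -> bool:
        w = grid.wavelengths()
        return len(self) == len(w) and bool(np.allclose(self.wavelengths_nm, w, atol=atol))


_WL_NAMES = ("wavelength", "wavelength_nm", "lambda", "lambda_nm", "wl", "nm")


def read_spectrum(
    path: str | Path,
    column_map: Optional[dict] = None,
    kind: str = "transmittance",
) -> SpectralSamples:
    """Read a two-column delimited spectrum (CSV or TSV, header optional).

    Wavelength column is found by name (``wavelength``/``lambda``/``nm``
    variants) or taken as the first column; the value column via
    ``column_map={"wavelength": ..., "value": ...}`` or the second column.
    Rows are sorted by wavelength; duplicate wavelengths are collapsed by
    averaging (robust against digitization double-clicks).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - passthrough of pandas errors
        raise SpectralFormatError(f"cannot parse {path}: {exc}") from exc

    # headerless files: first row parsed as header of numbers
    try:
        float(str(df.columns[0]))
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
        df.columns = ["wavelength_nm", "value"][: len(df.columns)] + [
            f"col{i}" for i in range(2, len(df.columns))
        ]
    except ValueError:
        pass

    if column_map:
        wl_col = column_map.get("wavelength")
        val_col = column_map.get("value")
    else:
        wl_col = val_col = None

    cols_lower = {str(c).strip().lower(): c for c in df.columns}
    if wl_col is None:
        for name in _WL_NAMES:
            if name in cols_lower:
                wl_col = cols_lower[name]
                break
        else:
            wl_col = df.columns[0]
    if val_col is None:
        candidates = [c for c in df.columns if c != wl_col]
        if not candidates:
            raise SpectralFormatError(
                f"{path}: no value column besides wavelength; columns = {list(df.columns)}"
            )
        if len(candidates) > 1 and column_map is None and len(df.columns) > 2:
            raise SpectralFormatError(
                f"{path}: ambiguous value column, candidates = {candidates}; "
                "pass column_map={'value': <name>}"
            )
        val_col = candidates[0]

    sub = df[[wl_col, val_col]].apply(pd.to_numeric, errors="coerce").dropna()
    if len(sub) < 2:
        raise SpectralDataError(f"{path}: fewer than 2 usable rows")
    collapsed = sub.groupby(wl_col, sort=True)[val_col].mean()
    return SpectralSamples(collapsed.index.to_numpy(), collapsed.to_numpy(), kind=kind)


def clean_and_resample(raw: SpectralSamples, grid: GridSpec | None = None) -> SpectralSamples:
    """Resample a raw spectrum onto the working grid with standard cleaning.

    Within the raw wavelength span the spectrum is PCHIP-interpolated (shape
    preserving, reproduces knots exactly); strictly outside the span values
    are set to exactly 0, so unmeasured spectral edges contribute nothing to
    downstream integrals. Negative values — digitization artefacts — are set
    to exactly 0. For bounded kinds (transmittance, reflectance) values above
    1 are clipped to 1 and a :class:`TransmittanceClippedWarning` is emitted.

    The operation is idempotent: cleaning an already-clean spectrum on the
    same grid returns it unchanged.
    """
    grid = grid or GridSpec()
    if len(raw) < 2:
        raise SpectralDataError("need at least 2 samples to interpolate")
    lo, hi = raw.span
    if hi < grid.start_nm or lo > grid.end_nm:
        raise SpectralDataError(
            f"raw span {lo}–{hi} nm lies entirely outside grid "
            f"{grid.start_nm}–{grid.end_nm} nm"
        )

    w = grid.wavelengths()
    out = np.zeros_like(w)
    inside = (w >= lo - 1e-12) & (w <= hi + 1e-12)
    interp = PchipInterpolator(raw.wavelengths_nm, raw.values, extrapolate=False)
    out[inside] = interp(np.clip(w[inside], lo, hi))

    out[out < 0] = 0.0
    if raw.kind in BOUNDED_KINDS and np.any(out > 1.0):
        n_over = int(np.sum(out > 1.0))
        warnings.warn(
            f"{n_over} value(s) above 1 clipped to 1 (max {out.max():.4f})",
            TransmittanceClippedWarning,
            stacklevel=2,
        )
        out[out > 1.0] = 1.0
    return SpectralSamples(w, out, kind=raw.kind, cleaned=True)


def write_spectrum(s: SpectralSamples, path: str | Path) -> None:
    """Write a spectrum as a two-column CSV with header; round-trips exactly."""
    path = Path(path)
    df = pd.DataFrame({"wavelength_nm": s.wavelengths_nm, s.kind: s.values})
    df.to_csv(path, index=False, float_format="%.12g")
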