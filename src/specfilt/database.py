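"""Batch analysis of a filter database: metrics, category summaries, correlations.

A database is a list of :class:`FilterRecord` — one cleaned transmittance
spectrum plus a category label (medical, safety, or one of four task
subcategories). The analyses mirror a survey of commercial short-wavelength
filters: per-filter metrics, per-category medians/IQRs, and the correlation
matrix among the four metrics across the database.

:func:`generate_synthetic_database` emulates such a survey assembled by
digitizing published transmittance graphs: a mixture of sigmoid cut-offs,
notch filters and flat "plateau" tints, sampled on irregular wavelength
grids with truncated spectral edges and additive digitization noise
(sd ≈ 0.01) that occasionally dips below zero — so every generated spectrum
genuinely needs the cleaning pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .filter_models import SigmoidFilterParams, sigmoid_filter, notch_filter
from .metrics import FilterMetrics, compute_filter_metrics
from .spectra import GridSpec, SpectralSamples, clean_and_resample
from .standards import StandardsBundle

__all__ = [
    "CATEGORIES",
    "DEFAULT_CATEGORY_COUNTS",
    "FilterRecord",
    "CorrelationMatrix",
    "METRIC_NAMES",
    "generate_synthetic_database",
    "compute_database_metrics",
    "correlation_matrix",
    "summarize_by_category",
    "metrics_table",
]

CATEGORIES = ("medical", "safety", "task_sport", "task_driving", "task_vdu", "task_other")

#: survey composition: 76 medical, 11 safety, 34 task-specific
#: (10 sport + 4 driving + 12 VDU + 8 other) = 121 filters
DEFAULT_CATEGORY_COUNTS = {
    "medical": 76,
    "safety": 11,
    "task_sport": 10,
    "task_driving": 4,
    "task_vdu": 12,
    "task_other": 8,
}

METRIC_NAMES = (
    "luminous_transmittance",
    "melanopsin_transmittance",
    "colour_shift",
    "gamut_ratio",
)


@dataclass
class FilterRecord:
    id: str
    category: str
    spectrum: SpectralSamples
    metrics: Optional[FilterMetrics] = None
    source_note: str = ""
    raw_spectrum: Optional[SpectralSamples] = field(default=None, repr=False)
    error: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category {self.category!r} not in {CATEGORIES}")


@dataclass
class CorrelationMatrix:
    variables: tuple[str, ...]
    r: np.ndarray
    n: int
    method: str = "pearson"

    def entry(self, a: str, b: str) -> float:
        return float(self.r[self.variables.index(a), self.variables.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variables, columns=self.variables)


def _largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    total = sum(proportions.values())
    quotas = {k: n * v / total for k, v in proportions.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    remainder = n - sum(counts.values())
    by_frac = sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in by_frac[:remainder]:
        counts[k] += 1
    return counts


def _raw_wavelength_grid(rng: np.random.Generator) -> np.ndarray:
    """Irregular digitization grid, sometimes missing spectral edges."""
    start = 380.0 if rng.random() < 0.6 else rng.uniform(390.0, 450.0)
    end = 780.0 if rng.random() < 0.6 else rng.uniform(690.0, 770.0)
    step = rng.uniform(2.0, 5.0)
    w = np.arange(start, end + 1e-9, step)
    w = w + rng.uniform(-0.3, 0.3, size=len(w))  # digitization jitter
    w[0], w[-1] = start, min(end, 780.0)
    return np.sort(w)


def generate_synthetic_database(
    n: int = 121,
    category_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    grid: Optional[GridSpec] = None,
    noise_sd: float = 0.01,
) -> list[FilterRecord]:
    """Seeded synthetic filter survey requiring the cleaning pipeline.

    Medical filters are drawn with longer cut-off wavelengths (deep
    blue-blockers used in ocular and circadian indications) than safety and
    task filters; each category contains a minority of notch and plateau
    shapes. Records carry both the noisy raw spectrum and its cleaned
    version.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(category_mix or DEFAULT_CATEGORY_COUNTS)
    if any(v < 0 for v in mix.values()) or sum(mix.values()) <= 0:
        raise ValueError("category mix proportions must be nonnegative and sum > 0")
    unknown = set(mix) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories in mix: {sorted(unknown)}")
    grid = grid or GridSpec()
    rng = np.random.default_rng(seed)
    counts = _largest_remainder_counts(n, mix)

    records: list[FilterRecord] = []
    idx = 0
    for cat in CATEGORIES:
        for _ in range(counts.get(cat, 0)):
            idx += 1
            w = _raw_wavelength_grid(rng)
            shape_draw = rng.random()
            if shape_draw < 0.70:  # sigmoid cut-off
                if cat == "medical":
                    lam0 = rng.uniform(470.0, 600.0)
                else:
                    lam0 = rng.uniform(420.0, 540.0)
                p = SigmoidFilterParams(
                    lambda0_nm=lam0,
                    upper_asymptote=rng.uniform(0.4, 0.98),
                    slope=float(np.exp(rng.uniform(np.log(0.05), np.log(1.0)))),
                )
                z = np.clip(-p.slope * (w - p.lambda0_nm), -700, 700)
                t = p.upper_asymptote / (1.0 + np.exp(z))
                note = f"sigmoid lambda0={p.lambda0_nm:.1f} L={p.upper_asymptote:.2f} k={p.slope:.3f}"
            elif shape_draw < 0.85:  # notch
                center = rng.uniform(440.0, 510.0)
                width = rng.uniform(20.0, 60.0)
                depth = rng.uniform(0.5, 1.0)
                half = width / 2.0
                t = 1.0 - depth * np.exp(-0.5 * ((w - center) / (half / 1.5)) ** 2)
                t *= rng.uniform(0.8, 0.98)
                note = f"notch center={center:.1f} width={width:.1f} depth={depth:.2f}"
            else:  # plateau (broad flat tint)
                level = rng.uniform(0.2, 0.9)
                tilt = rng.uniform(-0.0005, 0.0008)
                t = level + tilt * (w - 560.0)
                note = f"plateau level={level:.2f}"
            t = t + rng.normal(0.0, noise_sd, size=len(w))  # digitization noise
            raw = SpectralSamples(w, t, kind="transmittance")
            records.append(
                FilterRecord(
                    id=f"synth-{idx:03d}",
                    category=cat,
                    spectrum=clean_and_resample(raw, grid),
                    raw_spectrum=raw,
                    source_note=note,
                )
            )
    return records


def compute_database_metrics(
    db: Sequence[FilterRecord], bundle: StandardsBundle
) -> list[FilterRecord]:
    """Fill metrics for every record; per-record failures are recorded, not raised."""
    if not db:
        raise ValueError("empty database")
    for rec in db:
        try:
            rec.metrics = compute_filter_metrics(rec.spectrum, bundle)
        except Exception as exc:  # keep the batch going
            rec.error = str(exc)
    return list(db)


def metrics_table(db: Sequence[FilterRecord]) -> pd.DataFrame:
    rows = []
    for rec in db:
        if rec.metrics is None:
            continue
        row = {"id": rec.id, "category": rec.category}
        row.update(rec.metrics.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_matrix(
    db: Sequence[FilterRecord], method: str = "pearson"
) -> CorrelationMatrix:
    """Pairwise correlations among the four metrics across the database.

    Zero-variance variables yield NaN in their row/column (marked undefined,
    not silently zero). Metrics are used on their natural scales; Pearson
    and Spearman are both invariant to the fraction-vs-percent choice.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be pearson or spearman, got {method!r}")
    table = metrics_table(db)
    if len(table) < 3:
        raise ValueError("need at least 3 records with metrics")
    data = table[list(METRIC_NAMES)].to_numpy()
    k = len(METRIC_NAMES)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = data[:, i], data[:, j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                r[i, j] = r[j, i] = np.nan
                continue
            if method == "pearson":
                r[i, j] = r[j, i] = stats.pearsonr(xi, xj).statistic
            else:
                r[i, j] = r[j, i] = stats.spearmanr(xi, xj).statistic
    return CorrelationMatrix(variables=METRIC_NAMES, r=r, n=len(table), method=method)


def summarize_by_category(db: Sequence[FilterRecord]) -> pd.DataFrame:
    """Per-category n and median / IQR of each metric."""
    table = metrics_table(db)
    rows = []
    for cat in CATEGORIES:
        sub = table[table["category"] == cat]
        row: dict = {"category": cat, "n": len(sub)}
        for name in METRIC_NAMES:
            if len(sub):
                q1, q2, q3 = np.percentile(sub[name], [25, 50, 75])
            else:
                q1 = q2 = q3 = np.nan
            row[f"{name}_median"] = q2
            row[f"{name}_iqr"] = q3 - q1
        rows.append(row)
    return pd.DataFrame(rows)
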