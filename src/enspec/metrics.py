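"""Reconstruction-quality and convergence metrics.

All metrics are L1-type relative integral changes evaluated by trapezoidal
quadrature on the target's grid; they are invariant to the cross-section
prefactor convention since the constant cancels in every ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .discrete_nea import BandSpectrum, FullSpectrum
from .errors import ValidationError

__all__ = [
    "MetricResult",
    "THRESHOLD_PRESETS",
    "ric",
    "bric",
    "bric_seq",
]

#: Named stopping thresholds for the sequential convergence metric.
THRESHOLD_PRESETS = {"loose": 0.1, "standard": 0.05, "tight": 0.025}


@dataclass
class MetricResult:
    value: float
    per_band: dict[int, float] | None = None
    excluded_bands: list[int] = field(default_factory=list)
    grid: np.ndarray | None = field(default=None, repr=False)


def _as_xy(spec):
    """Accept BandSpectrum / FullSpectrum / (energies, values) pairs."""
    if isinstance(spec, BandSpectrum):
        return spec.grid.energies, spec.sigma
    if isinstance(spec, FullSpectrum):
        return spec.grid.energies, spec.total
    x, y = spec
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def _align(spec_r, spec_t):
    """Interpolate the reconstruction onto the target grid when needed."""
    xr, yr = _as_xy(spec_r)
    xt, yt = _as_xy(spec_t)
    if len(xr) == len(xt) and np.allclose(xr, xt):
        return xt, yr, yt
    return xt, np.interp(xt, xr, yr, left=0.0, right=0.0), yt


def ric(spec_r, spec_t) -> MetricResult:
    """Relative integral change: ||r - t||_1 / ||t||_1 on the target grid."""
    x, yr, yt = _align(spec_r, spec_t)
    area_t = np.trapezoid(np.abs(yt), x)
    if area_t <= 0:
        raise ValidationError("target spectrum has zero area; metric undefined")
    value = np.trapezoid(np.abs(yr - yt), x) / area_t
    return MetricResult(value=float(value), grid=x)


def _match_bands(bands_r: Sequence, bands_t: Sequence):
    def keyed(bands):
        out = {}
        for i, b in enumerate(bands):
            key = b.state if isinstance(b, BandSpectrum) else i
            out[key] = b
        return out

    r, t = keyed(bands_r), keyed(bands_t)
    if set(r) != set(t):
        raise ValidationError(
            f"band sets differ: {sorted(r)} vs {sorted(t)}"
        )
    return r, t


def bric(bands_r: Sequence, bands_t: Sequence) -> MetricResult:
    """Unweighted mean of per-band relative integral changes.

    Every band contributes equally irrespective of its strength; target bands
    with zero area (dark bands) are excluded from the mean and reported.
    """
    r, t = _match_bands(bands_r, bands_t)
    per_band: dict[int, float] = {}
    excluded: list[int] = []
    for key in sorted(r):
        x, yt = _as_xy(t[key])
        if np.trapezoid(np.abs(yt), x) <= 0:
            excluded.append(key)
            continue
        per_band[key] = ric(r[key], t[key]).value
    if not per_band:
        raise ValidationError("every target band has zero area; metric undefined")
    return MetricResult(
        value=float(np.mean(list(per_band.values()))),
        per_band=per_band,
        excluded_bands=excluded,
    )


def bric_seq(
    bands_old: Sequence, bands_new: Sequence, threshold: float
) -> tuple[MetricResult, bool]:
    """Sequential convergence metric for batch-wise ensemble growth.

    Per band: integral |new - old| divided by the integral of the *new*
    spectrum (the better-sampled estimate); averaged over bands.  Returns the
    metric and a stop decision ``value < threshold``.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    old, new = _match_bands(bands_old, bands_new)
    per_band: dict[int, float] = {}
    excluded: list[int] = []
    for key in sorted(new):
        x, yn = _as_xy(new[key])
        area_n = np.trapezoid(np.abs(yn), x)
        if area_n <= 0:
            excluded.append(key)
            continue
        _, yo, yn2 = _align(old[key], new[key])
        per_band[key] = float(np.trapezoid(np.abs(yn2 - yo), x) / area_n)
    if not per_band:
        raise ValidationError("every new band has zero area; metric undefined")
    result = MetricResult(
        value=float(np.mean(list(per_band.values()))),
        per_band=per_band,
        excluded_bands=excluded,
    )
    return result, bool(result.value < threshold)
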