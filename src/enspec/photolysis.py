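"""Photolysis rates from cross sections, quantum yields and actinic fluxes.

``J = integral over wavelength of phi(lambda) * sigma(lambda) * F(lambda)``,
evaluated by trapezoidal quadrature over the overlap of the spectrum and flux
supports.  The cross section must be in cm^2 (physical prefactor mode); the
flux in quanta s^-1 cm^-2 nm^-1; J comes out in s^-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .discrete_nea import FullSpectrum
from .errors import ConfigError, FormatError, ValidationError

__all__ = [
    "EV_NM",
    "ActinicFlux",
    "WavelengthSpectrum",
    "PhotolysisJob",
    "read_flux",
    "spectrum_to_wavelength",
    "photolysis_rate",
]

logger = logging.getLogger(__name__)

#: hc expressed in eV*nm: E[eV] = EV_NM / lambda[nm].
EV_NM = 1239.841984


@dataclass
class ActinicFlux:
    """Solar spectral actinic flux on a wavelength grid."""

    wavelength_nm: np.ndarray
    flux: np.ndarray
    metadata: str = ""

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.flux = np.asarray(self.flux, dtype=float)
        if len(self.wavelength_nm) != len(self.flux):
            raise ValidationError("wavelength and flux arrays must match")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValidationError("flux wavelengths must be strictly increasing")
        if np.any(self.flux < 0):
            raise ValidationError("actinic flux must be nonnegative")


@dataclass
class WavelengthSpectrum:
    """Cross section re-indexed on an increasing wavelength axis (nm)."""

    wavelength_nm: np.ndarray
    sigma: np.ndarray
    prefactor_mode: str = "arbitrary"


@dataclass
class PhotolysisJob:
    """Everything needed to integrate one photolysis rate."""

    spectrum: WavelengthSpectrum
    flux: ActinicFlux
    quantum_yield: Callable[[np.ndarray], np.ndarray] | float = 1.0
    coverage: float = field(default=np.nan, init=False)


def read_flux(path, metadata: str = "") -> ActinicFlux:
    """Two-column flux file: wavelength [nm], flux [quanta s^-1 cm^-2 nm^-1].

    Whitespace- or comma-delimited; lines starting with '#' are comments.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such flux file: {path}")
    frame = pd.read_csv(
        path, sep=r"[,\s]+", engine="python", comment="#", header=None
    )
    if frame.shape[1] < 2:
        raise FormatError("flux file must have two columns (wavelength, flux)")
    return ActinicFlux(
        wavelength_nm=frame.iloc[:, 0].to_numpy(dtype=float),
        flux=frame.iloc[:, 1].to_numpy(dtype=float),
        metadata=metadata,
    )


def spectrum_to_wavelength(spec: FullSpectrum, prefactor_mode: str = "arbitrary"):
    """Pointwise change of axis: sigma(lambda) = sigma(E = hc/lambda).

    No Jacobian is applied — the cross section is a pointwise function of the
    photon energy, not a density.
    """
    e = spec.grid.energies
    wl = EV_NM / e
    return WavelengthSpectrum(
        wavelength_nm=wl[::-1],
        sigma=np.asarray(spec.total, dtype=float)[::-1],
        prefactor_mode=prefactor_mode,
    )


def photolysis_rate(job: PhotolysisJob) -> float:
    """Trapezoid integral of phi * sigma * F over the overlap of supports."""
    if job.spectrum.prefactor_mode != "physical":
        raise ConfigError(
            "photolysis rates require a cm^2 spectrum; rebuild the spectrum "
            "with prefactor_mode='physical'"
        )
    wl = job.spectrum.wavelength_nm
    lo = max(wl[0], job.flux.wavelength_nm[0])
    hi = min(wl[-1], job.flux.wavelength_nm[-1])
    if hi <= lo:
        raise ValidationError(
            "spectrum and actinic flux have no overlapping wavelength support"
        )
    mask = (wl >= lo) & (wl <= hi)
    wl_i = wl[mask]
    sigma_i = job.spectrum.sigma[mask]
    flux_i = np.interp(wl_i, job.flux.wavelength_nm, job.flux.flux)
    phi = job.quantum_yield
    phi_i = phi(wl_i) if callable(phi) else float(phi) * np.ones_like(wl_i)
    job.coverage = (hi - lo) / (wl[-1] - wl[0])
    logger.info(
        "photolysis integration over [%.1f, %.1f] nm (%.0f%% of spectrum span)",
        lo, hi, 100.0 * job.coverage,
    )
    return float(np.trapezoid(phi_i * sigma_i * flux_i, wl_i))
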