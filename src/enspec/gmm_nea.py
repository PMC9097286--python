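"""Bandwidth-free band spectra from fitted (energy, dipole) mixtures.

For each transition the joint distribution of (delta_E [eV], M [a.u.]) over
the geometry ensemble is modeled as a point mass ``theta0`` at M = 0 (dark
geometries) plus a bivariate Gaussian mixture fitted on the remaining pairs.
The broadened discrete sum then collapses, in the zero-width limit, to the
closed form

    sigma(E) = C(E) * (2/3) * E * E_Ha * sum_k pi'_k * phi(E; mu_k1, s_k1^2)
                                          * (mu_cond_k(E)^2 + var_cond_k)

where ``E`` is in eV, ``E_Ha = E / 27.211386...`` the same energy in Hartree,
``phi`` the marginal normal density of the energy coordinate (per eV),
``pi'_k = (1 - theta0) pi_k`` the rescaled weights, and ``mu_cond/var_cond``
the conditional moments of M given delta_E = E.  ``C(E)`` is the identical
prefactor convention used by the discrete module, so both routes agree
exactly as the broadening goes to zero — no bandwidth appears anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .discrete_nea import (
    BandSpectrum,
    BootstrapSpec,
    EnergyGrid,
    FullSpectrum,
    _percentile_bounds,
)
from .ensemble_io import (
    EV_PER_HARTREE,
    PhysicalConstants,
    TransitionSample,
)
from .errors import FitError, ValidationError
from .gmm_engine import FitConfig, GMMParams, em_fit, select_model

__all__ = [
    "BandGMM",
    "conditional_moments",
    "fit_band_gmm",
    "band_spectrum_gmm",
    "full_spectrum_gmm",
    "bootstrap_ci_gmm",
    "transform_dipole_scale",
]

MIN_BRIGHT_POINTS = 8


@dataclass
class BandGMM:
    """Zero-dipole mass plus a mixture over the bright (delta_E, M) pairs."""

    state: int
    theta0: float
    gmm: GMMParams | None
    n_geoms: int
    n_zero: int

    def __post_init__(self):
        if not 0.0 <= self.theta0 <= 1.0:
            raise ValidationError("theta0 must lie in [0, 1]")

    @property
    def dark(self) -> bool:
        return self.gmm is None

    @property
    def weights_rescaled(self) -> np.ndarray:
        """pi'_k = (1 - theta0) * pi_k, summing to 1 - theta0."""
        if self.dark:
            return np.zeros(0)
        return (1.0 - self.theta0) * self.gmm.weights


def conditional_moments(gmm: GMMParams, energies):
    """Per-component conditional mean/variance of M given delta_E = E.

    Returns ``(mu_cond, var_cond)`` with shapes (K, n_E) and (K,).
    """
    e = np.atleast_1d(np.asarray(energies, dtype=float))
    s1 = gmm.sigma1
    s2 = gmm.sigma2
    rho = gmm.rho
    mu_cond = (
        gmm.means[:, 1][:, None]
        + (rho * s2 / s1)[:, None] * (e[None, :] - gmm.means[:, 0][:, None])
    )
    var_cond = s2**2 * (1.0 - rho**2)
    return mu_cond, var_cond


def fit_band_gmm(
    sample: TransitionSample,
    config: FitConfig = FitConfig(),
    f_tol: float = 0.0,
) -> BandGMM:
    """Estimate theta0 and fit a mixture on the bright pairs of one band.

    Geometries with ``f <= f_tol`` count toward theta0 and are removed before
    fitting.  A band with no bright geometry at all is returned dark; between
    1 and 7 bright geometries is an error (too few to fit anything).
    """
    n = len(sample)
    if n == 0:
        raise ValidationError("cannot fit an empty sample")
    bright = sample.f > f_tol
    n_zero = int(n - bright.sum())
    theta0 = n_zero / n
    if bright.sum() == 0:
        return BandGMM(sample.state, 1.0, None, n, n_zero)
    if bright.sum() < MIN_BRIGHT_POINTS:
        raise ValidationError(
            f"band {sample.state}: only {int(bright.sum())} bright geometries; "
            f"need >= {MIN_BRIGHT_POINTS} to fit a mixture"
        )
    X = np.column_stack([sample.delta_E[bright], sample.M[bright]])
    gmm = select_model(X, config)
    _warn_negative_mass(gmm, sample.state)
    return BandGMM(sample.state, theta0, gmm, n, n_zero)


def _warn_negative_mass(gmm: GMMParams, state: int, tol: float = 0.01):
    """The mixture lives on the real plane; flag visible leakage past zero."""
    for dim, name in ((0, "delta_E"), (1, "M")):
        sd = np.sqrt(gmm.covariances[:, dim, dim])
        mass = float(np.sum(gmm.weights * stats.norm.cdf(-gmm.means[:, dim] / sd)))
        if mass > tol:
            warnings.warn(
                f"band {state}: fitted mixture puts {mass:.1%} mass at "
                f"negative {name}",
                stacklevel=3,
            )


def band_spectrum_gmm(
    band: BandGMM,
    grid: EnergyGrid,
    constants: PhysicalConstants = PhysicalConstants(),
) -> BandSpectrum:
    """Evaluate the closed-form band cross section (no broadening parameter)."""
    e = grid.energies
    if band.dark:
        return BandSpectrum(band.state, grid, np.zeros(len(e)))
    gmm = band.gmm
    mu_cond, var_cond = conditional_moments(gmm, e)
    marg = stats.norm.pdf(
        e[None, :], loc=gmm.means[:, 0][:, None], scale=gmm.sigma1[:, None]
    )
    second_moment = mu_cond**2 + var_cond[:, None]
    mix = np.sum(band.weights_rescaled[:, None] * marg * second_moment, axis=0)
    sigma = (
        constants.energy_prefactor(e)
        * (2.0 / 3.0)
        * e * (e / EV_PER_HARTREE)
        * mix
    )
    return BandSpectrum(band.state, grid, np.maximum(sigma, 0.0))


def full_spectrum_gmm(
    bands: list[BandGMM],
    grid: EnergyGrid,
    constants: PhysicalConstants = PhysicalConstants(),
) -> FullSpectrum:
    """Incoherent sum of closed-form band spectra."""
    comps = [band_spectrum_gmm(b, grid, constants) for b in bands]
    return FullSpectrum.from_components(comps)


def transform_dipole_scale(band: BandGMM, c: float) -> BandGMM:
    """Analytic reparameterization for M -> sqrt(c) * M (refit suppressed).

    Scales the dipole coordinate of every component; the resulting spectrum
    scales by exactly ``c`` pointwise.
    """
    if c <= 0:
        raise ValidationError("scale factor must be > 0")
    if band.dark:
        return band
    root = np.sqrt(c)
    means = band.gmm.means.copy()
    covs = band.gmm.covariances.copy()
    means[:, 1] *= root
    covs[:, 1, 1] *= c
    covs[:, 0, 1] *= root
    covs[:, 1, 0] *= root
    gmm = replace(band.gmm, means=means, covariances=covs)
    return replace(band, gmm=gmm)


def bootstrap_ci_gmm(
    sample: TransitionSample,
    band: BandGMM,
    grid: EnergyGrid,
    boot: BootstrapSpec,
    constants: PhysicalConstants = PhysicalConstants(),
    refit_config: FitConfig | None = None,
    reselect: bool = False,
    max_failure_fraction: float = 0.10,
) -> BandSpectrum:
    """Percentile-bootstrap CI band for a fitted mixture spectrum.

    Each replica resamples geometries with replacement, recomputes theta0 and
    refits a mixture with (K, family) *fixed* to the original selection
    (``reselect=True`` reruns the full selection per replica instead).
    Replicas whose fit fails are redrawn; more than ``max_failure_fraction``
    failures aborts with a diagnostic.
    """
    if band.dark:
        raise ValidationError("cannot bootstrap a dark band")
    cfg = refit_config or FitConfig(restarts=2, tol=1e-7, max_iter=300)
    rng = np.random.default_rng(boot.seed)
    n = len(sample)
    point = band_spectrum_gmm(band, grid, constants)
    reps = np.zeros((boot.B, len(grid)))
    failures = 0
    max_failures = int(np.ceil(max_failure_fraction * boot.B))
    b = 0
    while b < boot.B:
        idx = rng.integers(0, n, size=n)
        rep_sample = sample.resample(idx)
        try:
            if reselect:
                rep_band = fit_band_gmm(rep_sample, cfg)
            else:
                bright = rep_sample.f > 0
                if bright.sum() < max(MIN_BRIGHT_POINTS, band.gmm.K + 1):
                    raise FitError("too few bright geometries in replica")
                X = np.column_stack(
                    [rep_sample.delta_E[bright], rep_sample.M[bright]]
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gmm = em_fit(
                        X, band.gmm.K, band.gmm.model, cfg,
                        rng=np.random.default_rng(rng.integers(2**63)),
                    )
                theta0 = 1.0 - bright.sum() / n
                rep_band = BandGMM(band.state, theta0, gmm, n,
                                   int(n - bright.sum()))
        except (FitError, ValidationError) as exc:
            failures += 1
            if failures > max_failures:
                raise FitError(
                    f"band {band.state}: {failures} bootstrap replicas failed "
                    f"(> {max_failure_fraction:.0%} of B={boot.B}); "
                    f"last failure: {exc}"
                ) from exc
            continue
        reps[b] = band_spectrum_gmm(rep_band, grid, constants).sigma
        b += 1
    if failures:
        warnings.warn(
            f"band {band.state}: redrew {failures} failed bootstrap replicas",
            stacklevel=2,
        )
    lo, hi = _percentile_bounds(reps, boot.alpha)
    return BandSpectrum(band.state, grid, point.sigma, ci_low=lo, ci_high=hi)
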