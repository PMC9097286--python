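"""Seeded fixture generator: ensembles drawn from known per-band mixtures.

Every downstream module is testable without external data by sampling
(delta_E, M) clouds from declared ground-truth mixtures — including a
zero-dipole mass and injectable anomalies — and converting back to
oscillator strengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble_io import EnsembleTable, strength_from_dipole
from .errors import ValidationError
from .gmm_engine import GMMParams
from .gmm_nea import BandGMM

__all__ = [
    "BandTruth",
    "make_truth",
    "truth_band_gmm",
    "sample_ensemble",
    "inject_outliers",
    "demo_truths",
]


@dataclass
class BandTruth:
    """Ground-truth mixture for one band over (delta_E [eV], M [a.u.])."""

    state: int
    theta0: float
    weights: np.ndarray
    means: np.ndarray        # (K, 2)
    covariances: np.ndarray  # (K, 2, 2)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if not 0.0 <= self.theta0 < 1.0:
            raise ValidationError("theta0 must lie in [0, 1)")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValidationError("truth weights must sum to 1")
        sd = np.sqrt(
            np.stack([self.covariances[:, 0, 0], self.covariances[:, 1, 1]], axis=1)
        )
        if np.any(self.means < 4.0 * sd):
            raise ValidationError(
                "component means must sit >= 4 sd from zero in both coordinates "
                "(keeps the rejection rate below 1%)"
            )

    @property
    def K(self) -> int:
        return len(self.weights)


def make_truth(state, components, theta0=0.0) -> BandTruth:
    """Build a truth from tuples (weight, mu_E, mu_M, sd_E, sd_M, rho)."""
    comps = np.asarray(components, dtype=float)
    w = comps[:, 0] / comps[:, 0].sum()
    means = comps[:, 1:3]
    covs = np.zeros((len(comps), 2, 2))
    covs[:, 0, 0] = comps[:, 3] ** 2
    covs[:, 1, 1] = comps[:, 4] ** 2
    covs[:, 0, 1] = covs[:, 1, 0] = comps[:, 5] * comps[:, 3] * comps[:, 4]
    return BandTruth(state=state, theta0=theta0, weights=w, means=means,
                     covariances=covs)


def truth_band_gmm(truth: BandTruth) -> BandGMM:
    """Recast a truth as a fitted-band object for analytic spectra."""
    gmm = GMMParams(
        model="VVV",
        K=truth.K,
        weights=truth.weights,
        means=truth.means,
        covariances=truth.covariances,
        loglik=np.nan,
        n=0,
    )
    n_zero = 0
    return BandGMM(truth.state, truth.theta0, gmm, n_geoms=0, n_zero=n_zero)


def _draw_band(truth: BandTruth, n: int, rng: np.random.Generator):
    """Mixture draws with rejection of nonpositive coordinates."""
    out = np.empty((n, 2))
    filled = 0
    rejected = 0
    chol = np.linalg.cholesky(truth.covariances)
    while filled < n:
        todo = n - filled
        comps = rng.choice(truth.K, size=todo, p=truth.weights)
        z = rng.standard_normal((todo, 2))
        draws = truth.means[comps] + np.einsum("nij,nj->ni", chol[comps], z)
        ok = np.all(draws > 0, axis=1)
        rejected += int((~ok).sum())
        keep = draws[ok]
        out[filled:filled + len(keep)] = keep
        filled += len(keep)
        if rejected > 0.1 * (filled + rejected) and filled + rejected > 100:
            raise ValidationError(
                f"band {truth.state}: rejection rate above 10%; the truth "
                "violates the positive-placement invariant"
            )
    return out


def sample_ensemble(truths, n_geoms: int, seed=None) -> EnsembleTable:
    """Draw a complete (geometry x band) ensemble from ground-truth mixtures.

    Per geometry and band: with probability theta0 the transition is dark
    (f = 0); otherwise (delta_E, M) is drawn from the band's mixture (with
    rejection of nonpositive draws) and f is recovered by inverting the
    dipole relation.  Deterministic under ``seed``.
    """
    if n_geoms < 1:
        raise ValidationError("n_geoms must be >= 1")
    rng = np.random.default_rng(seed)
    geom_ids = np.array([f"g{i:05d}" for i in range(n_geoms)])
    parts = []
    for truth in truths:
        dark = rng.random(n_geoms) < truth.theta0
        n_bright = int((~dark).sum())
        delta_E = np.empty(n_geoms)
        f = np.zeros(n_geoms)
        if n_bright:
            draws = _draw_band(truth, n_bright, rng)
            delta_E[~dark] = draws[:, 0]
            f[~dark] = strength_from_dipole(draws[:, 0], draws[:, 1])
        if dark.any():
            # dark transitions still need a positive vertical energy; use
            # marginal-energy draws so the grid stays complete
            comps = rng.choice(truth.K, size=int(dark.sum()), p=truth.weights)
            e = truth.means[comps, 0] + np.sqrt(
                truth.covariances[comps, 0, 0]
            ) * rng.standard_normal(int(dark.sum()))
            delta_E[dark] = np.abs(e)
        parts.append(
            pd.DataFrame(
                {
                    "geom_id": geom_ids,
                    "state": truth.state,
                    "delta_E": delta_E,
                    "f": f,
                }
            )
        )
    return EnsembleTable(pd.concat(parts, ignore_index=True))


def inject_outliers(
    table: EnsembleTable, band: int, k: int, magnitude: float, seed=None
):
    """Inflate the dipole of ``k`` random geometries in one band.

    The chosen geometries get ``M = median + magnitude * robust_sd`` (robust
    sd = 1.4826 * MAD) and their f recomputed.  Returns the modified table
    and the list of altered geometry ids (ground truth for screening tests).
    """
    sample = table.band(band)  # raises KeyError for unknown bands
    n_g = table.n_geoms
    if k < 0 or k >= n_g / 10:
        raise ValidationError("k must satisfy 0 <= k < N_g/10")
    if k == 0:
        return table, []
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_g, size=k, replace=False)
    chosen_ids = set(sample.geom_ids[chosen])
    med = np.median(sample.M)
    robust_sd = 1.4826 * np.median(np.abs(sample.M - med))
    if robust_sd <= 0:
        robust_sd = sample.M.std() or 1.0
    new_m = med + magnitude * robust_sd

    frame = table.frame.copy()
    hit = frame["geom_id"].isin(chosen_ids) & (frame["state"] == band)
    frame.loc[hit, "f"] = strength_from_dipole(
        frame.loc[hit, "delta_E"].to_numpy(), new_m
    )
    return EnsembleTable(frame), sorted(chosen_ids)


def demo_truths():
    """Three-band demo fixture: unimodal, bimodal, and partially dark."""
    return [
        make_truth(
            1,
            [(1.0, 4.20, 0.90, 0.16, 0.10, 0.35)],
        ),
        make_truth(
            2,
            [
                (0.55, 5.40, 0.70, 0.14, 0.09, -0.20),
                (0.45, 5.95, 1.05, 0.17, 0.11, 0.25),
            ],
        ),
        make_truth(
            3,
            [(1.0, 6.80, 0.55, 0.20, 0.07, 0.0)],
            theta0=0.3,
        ),
    ]
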