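"""Anomaly screening of ensemble records via robust Mahalanobis distances.

Location is the coordinatewise median and scatter is the covariance of the
median-centered observations; squared distances are referred to a chi-squared
distribution with p degrees of freedom and flagged with a step-up false
discovery rate rule at level q (default 0.001, i.e. <0.1% false detections).

The default screening space is per-band (p=2 pairs of (delta_E, M) per
transition, with a geometry flagged if any of its bands flags it); a joint
space over the concatenated multiband vector is available when the geometry
count comfortably exceeds the dimension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble_io import EnsembleTable
from .errors import ConfigError, ValidationError

__all__ = [
    "RobustEstimates",
    "OutlierReport",
    "robust_estimates",
    "robust_mahalanobis_sq",
    "fdr_screen",
    "screen_ensemble",
]


@dataclass
class RobustEstimates:
    """Coordinatewise-median location and median-centered scatter."""

    location: np.ndarray
    scatter: np.ndarray


@dataclass
class OutlierReport:
    """Screening outcome for one observation matrix (or one ensemble)."""

    d2: np.ndarray
    pvalues: np.ndarray
    ranks: np.ndarray
    flagged: np.ndarray
    q: float
    mode: str = "array"
    table: pd.DataFrame | None = field(default=None, repr=False)
    flagged_geoms: list = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return int(np.sum(self.flagged))


def robust_estimates(X) -> RobustEstimates:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("expected an (n, p) observation matrix")
    med = np.median(X, axis=0)
    centered = X - med
    scatter = centered.T @ centered / (len(X) - 1)
    return RobustEstimates(location=med, scatter=scatter)


def robust_mahalanobis_sq(X, estimates: RobustEstimates | None = None) -> np.ndarray:
    """Squared Mahalanobis distances to the robust center/scatter."""
    X = np.asarray(X, dtype=float)
    est = estimates if estimates is not None else robust_estimates(X)
    p = X.shape[1]
    rank = np.linalg.matrix_rank(est.scatter)
    if rank < p:
        raise ValidationError(
            f"robust scatter is singular (rank {rank} < dimension {p}); "
            "consider per-band screening instead of the joint space"
        )
    centered = X - est.location
    sol = np.linalg.solve(est.scatter, centered.T)
    return np.einsum("ij,ji->i", centered, sol)


def _step_up_flags(pvalues: np.ndarray, q: float, step_up: bool) -> np.ndarray:
    n = len(pvalues)
    order = np.argsort(pvalues, kind="mergesort")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    thresholds = ranks * q / n
    if step_up:
        passing = pvalues[order] <= np.arange(1, n + 1) * q / n
        flags = np.zeros(n, dtype=bool)
        if passing.any():
            cutoff = np.max(np.nonzero(passing)[0]) + 1  # largest passing rank
            flags[order[:cutoff]] = True
        return flags, ranks
    return pvalues <= thresholds, ranks


def fdr_screen(X, q: float = 0.001, step_up: bool = True) -> OutlierReport:
    """Screen one (n, p) matrix: chi-squared p-values + FDR labeling.

    ``step_up=True`` (default) flags every observation up to the largest rank
    i with ``p_(i) <= i*q/n``; ``step_up=False`` applies the literal per-rank
    threshold instead.
    """
    X = np.asarray(X, dtype=float)
    if not 0.0 < q <= 1.0:
        raise ConfigError("q must lie in (0, 1]")
    n, p = X.shape
    if n < p + 2:
        raise ValidationError(
            f"need at least p+2={p + 2} observations in a {p}-dim space, got {n}"
        )
    d2 = robust_mahalanobis_sq(X)
    pvalues = stats.chi2.sf(d2, df=p)
    flags, ranks = _step_up_flags(pvalues, q, step_up)
    return OutlierReport(d2=d2, pvalues=pvalues, ranks=ranks, flagged=flags, q=q)


def screen_ensemble(
    table: EnsembleTable,
    q: float = 0.001,
    mode: str = "per-band",
    step_up: bool = True,
) -> OutlierReport:
    """Screen a whole ensemble; returns a per-(geometry, band) report.

    In ``"per-band"`` mode each transition is screened in its own
    (delta_E, M) plane and a geometry's flag is the union over bands.  In
    ``"joint"`` mode the concatenated multiband vector is screened at once;
    if the geometry count is too small for that the call falls back to
    per-band with a warning.
    """
    if mode not in ("per-band", "joint"):
        raise ConfigError(f"unknown screening mode {mode!r}")
    samples = table.bands()
    geom_ids = samples[0].geom_ids

    if mode == "joint":
        p = 2 * len(samples)
        if table.n_geoms < p + 2:
            warnings.warn(
                f"joint mode needs >= {p + 2} geometries for a {p}-dim space "
                f"(got {table.n_geoms}); falling back to per-band screening",
                stacklevel=2,
            )
            mode = "per-band"
        else:
            X = np.column_stack(
                sum([[s.delta_E, s.M] for s in samples], [])
            )
            rep = fdr_screen(X, q=q, step_up=step_up)
            rep.mode = "joint"
            rep.table = pd.DataFrame(
                {
                    "geom_id": geom_ids,
                    "band": "joint",
                    "d2": rep.d2,
                    "p_value": rep.pvalues,
                    "rank": rep.ranks,
                    "flagged": rep.flagged,
                }
            )
            rep.flagged_geoms = list(geom_ids[rep.flagged])
            return rep

    rows = []
    flagged_union = np.zeros(len(geom_ids), dtype=bool)
    for s in samples:
        X = np.column_stack([s.delta_E, s.M])
        band_rep = fdr_screen(X, q=q, step_up=step_up)
        flagged_union |= band_rep.flagged
        rows.append(
            pd.DataFrame(
                {
                    "geom_id": s.geom_ids,
                    "band": s.state,
                    "d2": band_rep.d2,
                    "p_value": band_rep.pvalues,
                    "rank": band_rep.ranks,
                    "flagged": band_rep.flagged,
                }
            )
        )
    combined = pd.concat(rows, ignore_index=True)
    return OutlierReport(
        d2=combined["d2"].to_numpy(),
        pvalues=combined["p_value"].to_numpy(),
        ranks=combined["rank"].to_numpy(),
        flagged=combined["flagged"].to_numpy(),
        q=q,
        mode="per-band",
        table=combined,
        flagged_geoms=list(geom_ids[flagged_union]),
    )
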