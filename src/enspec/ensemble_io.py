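"""Ensemble data model: per-geometry, per-transition excitation records.

The canonical interchange format is a long-format CSV with columns
``geom_id,state,delta_E,f`` (UTF-8, header row, '.' decimal separator).
Energies are carried in eV at every interface; conversion to Hartree happens
only inside dipole and prefactor computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "EV_PER_HARTREE",
    "PhysicalConstants",
    "TransitionSample",
    "EnsembleTable",
    "dipole_from_strength",
    "strength_from_dipole",
    "read_ensemble",
    "write_ensemble",
    "extract_band",
]

#: CODATA 2018 Hartree energy expressed in eV.
EV_PER_HARTREE = 27.211386245988

CANONICAL_COLUMNS = ("geom_id", "state", "delta_E", "f")


def dipole_from_strength(delta_E, f):
    """Convert oscillator strengths to transition dipole moments (a.u.).

    Uses ``M = sqrt(3 f / (2 dE_Ha))`` with ``dE_Ha`` the excitation energy
    in Hartree.  ``f = 0`` maps to ``M = 0`` exactly.

    Parameters
    ----------
    delta_E : array_like
        Vertical excitation energies in eV, strictly positive.
    f : array_like
        Oscillator strengths, nonnegative and dimensionless.

    Returns
    -------
    numpy.ndarray or float
        Transition dipole moments in atomic units.
    """
    delta_E = np.asarray(delta_E, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(delta_E <= 0):
        raise ValidationError("dipole_from_strength requires delta_E > 0")
    if np.any(f < 0):
        raise ValidationError("dipole_from_strength requires f >= 0")
    m = np.sqrt(1.5 * f * EV_PER_HARTREE / delta_E)
    return m if m.ndim else float(m)


def strength_from_dipole(delta_E, m):
    """Inverse of :func:`dipole_from_strength`: ``f = (2/3) dE_Ha M**2``."""
    delta_E = np.asarray(delta_E, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.any(delta_E <= 0):
        raise ValidationError("strength_from_dipole requires delta_E > 0")
    f = (2.0 / 3.0) * (delta_E / EV_PER_HARTREE) * m**2
    return f if f.ndim else float(f)


@dataclass(frozen=True)
class PhysicalConstants:
    """Cross-section prefactor convention.

    ``prefactor_mode="arbitrary"`` uses a unit prefactor so that only the
    spectral shape is meaningful; ``"physical"`` folds the electron charge and
    mass, c, hbar, the vacuum permittivity and the refractive index into a
    constant such that spectra come out in cm^2.
    """

    prefactor_mode: str = "arbitrary"
    refractive_index: float = 1.0

    def __post_init__(self):
        if self.prefactor_mode not in ("arbitrary", "physical"):
            raise ValidationError(
                f"unknown prefactor_mode {self.prefactor_mode!r}"
            )
        if self.refractive_index <= 0:
            raise ValidationError("refractive_index must be > 0")

    def prefactor(self) -> float:
        """Constant part of the prefactor, in cm^2*eV (or 1 in arbitrary mode)."""
        if self.prefactor_mode == "arbitrary":
            return 1.0
        from scipy import constants as sc

        val_si = (
            np.pi * sc.e**2 * sc.hbar
            / (2.0 * sc.m_e * sc.c * sc.epsilon_0 * self.refractive_index)
        )  # m^2 * J
        return val_si * 1e4 / sc.e  # -> cm^2 * eV

    def energy_prefactor(self, energy_ev):
        """Full energy-dependent prefactor C(E) = prefactor / E."""
        energy_ev = np.asarray(energy_ev, dtype=float)
        return self.prefactor() / energy_ev


@dataclass
class TransitionSample:
    """All records of one transition, aligned over the geometry order."""

    state: int
    geom_ids: np.ndarray
    delta_E: np.ndarray
    f: np.ndarray
    M: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.geom_ids = np.asarray(self.geom_ids)
        self.delta_E = np.asarray(self.delta_E, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.M is None:
            self.M = dipole_from_strength(self.delta_E, self.f)
        else:
            self.M = np.asarray(self.M, dtype=float)
        n = len(self.delta_E)
        if not (len(self.f) == len(self.M) == len(self.geom_ids) == n):
            raise ValidationError("TransitionSample arrays must share one length")

    def __len__(self) -> int:
        return len(self.delta_E)

    def resample(self, indices) -> "TransitionSample":
        """Row-subset/bootstrap view used by resampling procedures."""
        idx = np.asarray(indices)
        return TransitionSample(
            state=self.state,
            geom_ids=self.geom_ids[idx],
            delta_E=self.delta_E[idx],
            f=self.f[idx],
            M=self.M[idx],
        )


class EnsembleTable:
    """Complete (geometry x state) grid of excitation records.

    Wraps a validated long-format DataFrame sorted by ``(geom_id, state)``.
    """

    def __init__(self, frame: pd.DataFrame):
        self._frame = _validate_frame(frame)

    # -- accessors ---------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def geom_ids(self) -> np.ndarray:
        return self._frame["geom_id"].unique()

    @property
    def states(self) -> np.ndarray:
        return np.sort(self._frame["state"].unique())

    @property
    def n_geoms(self) -> int:
        return len(self.geom_ids)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EnsembleTable):
            return NotImplemented
        return self._frame.reset_index(drop=True).equals(
            other._frame.reset_index(drop=True)
        )

    def band(self, state: int) -> TransitionSample:
        return extract_band(self, state)

    def bands(self) -> list[TransitionSample]:
        return [self.band(int(s)) for s in self.states]

    def subset_geoms(self, geom_ids: Sequence) -> "EnsembleTable":
        """Table restricted to the given geometries (e.g. after QC removal)."""
        keep = self._frame["geom_id"].isin(list(geom_ids))
        if not keep.any():
            raise ValidationError("subset_geoms would produce an empty table")
        return EnsembleTable(self._frame[keep].copy())

    def drop_geoms(self, geom_ids: Sequence) -> "EnsembleTable":
        drop = set(geom_ids)
        return self.subset_geoms([g for g in self.geom_ids if g not in drop])

    @classmethod
    def from_bands(cls, samples: Sequence[TransitionSample]) -> "EnsembleTable":
        """Reassemble a table from per-band samples (inverse of extraction)."""
        parts = [
            pd.DataFrame(
                {
                    "geom_id": s.geom_ids,
                    "state": s.state,
                    "delta_E": s.delta_E,
                    "f": s.f,
                }
            )
            for s in samples
        ]
        return cls(pd.concat(parts, ignore_index=True))


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    if len(frame) == 0:
        raise FormatError("ensemble table has no rows")
    frame = frame.loc[:, list(CANONICAL_COLUMNS)].copy()
    frame["state"] = frame["state"].astype(int)
    frame["delta_E"] = frame["delta_E"].astype(float)
    frame["f"] = frame["f"].astype(float)

    if (frame["state"] < 1).any():
        bad = frame.index[frame["state"] < 1][0]
        raise ValidationError(f"state index must be >= 1 (row {bad})")

    dup = frame.duplicated(subset=["geom_id", "state"])
    if dup.any():
        pairs = frame.loc[dup, ["geom_id", "state"]].values[:5].tolist()
        raise FormatError(f"duplicate (geom_id, state) pairs: {pairs}")

    bad_e = frame["delta_E"] <= 0
    if bad_e.any():
        row = frame[bad_e].iloc[0]
        raise ValidationError(
            f"delta_E must be > 0; offending row (geom_id={row['geom_id']!r}, "
            f"state={row['state']})"
        )
    bad_f = frame["f"] < 0
    if bad_f.any():
        row = frame[bad_f].iloc[0]
        raise ValidationError(
            f"f must be >= 0; offending row (geom_id={row['geom_id']!r}, "
            f"state={row['state']})"
        )

    # complete-grid check: every geometry must carry every state
    states = set(frame["state"].unique())
    counts = frame.groupby("geom_id")["state"].apply(set)
    missing_pairs = [
        (gid, s) for gid, have in counts.items() for s in sorted(states - have)
    ]
    if missing_pairs:
        raise ValidationError(
            f"incomplete state grid; missing (geom_id, state) pairs: "
            f"{missing_pairs[:10]}"
        )

    return frame.sort_values(["geom_id", "state"], kind="mergesort").reset_index(
        drop=True
    )


def read_ensemble(path, dialect: Mapping[str, str] | None = None) -> EnsembleTable:
    """Read and validate an ensemble CSV.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    dialect : mapping, optional
        Map from *file* column names to the canonical names
        ``geom_id, state, delta_E, f`` for files with other headers.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path)
    if dialect:
        frame = frame.rename(columns=dict(dialect))
    return EnsembleTable(frame)


def write_ensemble(table: EnsembleTable, path) -> None:
    """Write a table in the canonical CSV dialect (round-trips exactly)."""
    table.frame.to_csv(path, index=False)


def extract_band(table: EnsembleTable, state: int) -> TransitionSample:
    """Pull one transition out of the grid, aligned by geometry order."""
    if state not in set(int(s) for s in table.states):
        raise KeyError(
            f"state {state} not present; available: {table.states.tolist()}"
        )
    sub = table.frame[table.frame["state"] == state]
    return TransitionSample(
        state=int(state),
        geom_ids=sub["geom_id"].to_numpy(),
        delta_E=sub["delta_E"].to_numpy(),
        f=sub["f"].to_numpy(),
    )
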