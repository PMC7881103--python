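"""Equipartition test: effective degrees of freedom per midge.

In equilibrium each degree of freedom carries ½ k_B*T of mean energy, so
if equipartition holds for swarms, the total energy normalized by the
effective temperature should grow linearly with swarm size N, with slope
half the per-midge degree-of-freedom count.  For a virial-balanced swarm
with Gaussian moments the large-N slope is 3/ln 2 ≈ 4.33, read as ~9/2 —
i.e. 9 effective d.o.f. per midge (3 translational + 3 potential modes,
times the ln 2 bookkeeping of the temperature definition; 6 after
discounting that factor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InsufficientDataError
from .state import LN2, SpringLaw, StateSeries, centre_of_mass

__all__ = [
    "energy_ratio_curve",
    "Equipartition",
    "EquipartitionResult",
    "fit_dof",
    "anisotropy_report",
    "AnisotropyReport",
]


def energy_ratio_curve(series) -> pd.DataFrame:
    """Mean E/(k_B*T) per swarm size N, with standard errors.

    Frames are grouped by instantaneous N; returns a table with columns
    ``N, ratio, se, count`` sorted by N.
    """
    df = series.data if isinstance(series, StateSeries) else series
    e = df["E"].to_numpy(dtype=float)
    t = df["T"].to_numpy(dtype=float)
    n = df["N"].to_numpy(dtype=float)
    valid = np.isfinite(e) & np.isfinite(t) & (t > 0) & (n >= 1)
    if not valid.any():
        raise InsufficientDataError("no frames with defined E and T")
    ratio = e[valid] / t[valid]
    n = n[valid].astype(int)
    out = (
        pd.DataFrame({"N": n, "ratio": ratio})
        .groupby("N")["ratio"]
        .agg(["mean", "sem", "count"])
        .reset_index()
        .rename(columns={"mean": "ratio", "sem": "se"})
        .sort_values("N")
        .reset_index(drop=True)
    )
    return out


@dataclass
class EquipartitionResult:
    """Fitted E/(k_B*T) vs N line through the origin.

    ``dof`` = 2·slope is the effective degrees of freedom per midge;
    ``dof_int`` its nearest integer; ``dof_ln2`` = 2·slope·ln 2 discounts
    the ln 2 factor in the temperature definition.
    """

    slope: float
    slope_se: float
    n_bins: int
    per_axis_energy: np.ndarray | None = None

    @property
    def dof(self) -> float:
        return 2.0 * self.slope

    @property
    def dof_int(self) -> int:
        return int(round(self.dof))

    @property
    def dof_ln2(self) -> float:
        return self.dof * LN2

    def summary(self) -> str:
        return (
            "Equipartition fit: E/(kB*T) = slope * N (through origin)\n"
            f"  slope        = {self.slope:.4f} +/- {self.slope_se:.4f}"
            f"  ({self.n_bins} N-bins)\n"
            f"  d.o.f./midge = {self.dof:.3f}  (nearest integer {self.dof_int};"
            f" {self.dof_ln2:.3f} after the ln2 discount)"
        )


class Equipartition:
    """Model object: weighted line through the origin for E/(k_B*T) vs N."""

    def __init__(self, series_or_curve):
        if isinstance(series_or_curve, pd.DataFrame) and "ratio" in series_or_curve:
            self.curve = series_or_curve
        else:
            self.curve = energy_ratio_curve(series_or_curve)

    def fit(self) -> EquipartitionResult:
        """Inverse-variance-weighted least squares, no intercept.

        Bins with undefined/zero SE (single-frame bins, exact synthetic
        data) fall back to equal weights.
        """
        curve = self.curve
        if len(curve) < 3:
            raise InsufficientDataError("need >= 3 distinct N values")
        n = curve["N"].to_numpy(dtype=float)
        y = curve["ratio"].to_numpy(dtype=float)
        se = curve["se"].to_numpy(dtype=float) if "se" in curve else np.full_like(y, np.nan)
        w = np.where(np.isfinite(se) & (se > 0), 1.0 / se**2, np.nan)
        if not np.isfinite(w).all():
            w = np.ones_like(y)
        res = sm.WLS(y, n[:, None], weights=w).fit()
        return EquipartitionResult(
            slope=float(res.params[0]),
            slope_se=float(res.bse[0]),
            n_bins=len(curve),
        )


def fit_dof(curve: pd.DataFrame) -> EquipartitionResult:
    """Functional wrapper: ``Equipartition(curve).fit()``."""
    return Equipartition(curve).fit()


@dataclass
class AnisotropyReport:
    """Per-axis mean kinetic and potential mode energies (per midge)."""

    kinetic: np.ndarray      # mean ½v_c² per axis
    potential: np.ndarray    # mean ½k x_c² per axis (about the COM)
    max_rel_diff_kinetic: float
    max_rel_diff_potential: float
    max_rel_diff_overall: float

    @property
    def per_axis_energy(self) -> np.ndarray:
        """Concatenated 6-vector: (kinetic x,y,z, potential x,y,z)."""
        return np.concatenate([self.kinetic, self.potential])


def _max_pairwise_rel_diff(vals: np.ndarray) -> float:
    m = float(np.mean(vals))
    if m == 0:
        return np.nan
    return float((vals.max() - vals.min()) / m)


def anisotropy_report(snapshots, spring_law: SpringLaw) -> AnisotropyReport:
    """Per-axis mean mode energies over a series of snapshots.

    Accumulates ½v_c² and ½k(N)·x_c² per axis over all (frame, midge)
    samples (positions about the per-frame centre of mass) and reports the
    maximum pairwise relative differences within and across the two
    triplets.  Isotropic equipartition predicts all six means equal.
    """
    kin = np.zeros(3)
    pot = np.zeros(3)
    count = 0
    for snap in snapshots:
        if snap.n < 2 or snap.velocities is None:
            continue
        x_rel = snap.positions - centre_of_mass(snap)
        k = float(spring_law(snap.n))
        kin += 0.5 * np.sum(snap.velocities**2, axis=0)
        pot += 0.5 * k * np.sum(x_rel**2, axis=0)
        count += snap.n
    if count == 0:
        raise InsufficientDataError("no valid snapshots")
    kin /= count
    pot /= count
    allsix = np.concatenate([kin, pot])
    return AnisotropyReport(
        kinetic=kin,
        potential=pot,
        max_rel_diff_kinetic=_max_pairwise_rel_diff(kin),
        max_rel_diff_potential=_max_pairwise_rel_diff(pot),
        max_rel_diff_overall=_max_pairwise_rel_diff(allsix),
    )
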