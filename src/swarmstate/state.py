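"""Per-frame thermodynamic state variables for swarms.

A swarm at one instant is characterised by the number of flying midges N,
the convex-hull volume V, a virial pressure P, a Shannon entropy S (bits),
an effective temperature k_B*T, and kinetic/potential/total energies.  All
energies, P and T are per unit midge mass; the effective Boltzmann constant
is absorbed (k_B* = 1 in package units, mm and s).

The emergent harmonic well that binds midges to the swarm centre has an
effective spring constant k that decreases with swarm size as a power law
k(N) = a N^b.  Per-frame spring estimates ⟨-a_i·r̂_i / r_i⟩ (r̂_i the outward
unit vector from the swarm centre of mass to midge i) are averaged per N
and fitted in log-log space to obtain that law; the fitted law, evaluated
at the instantaneous N, then enters the pressure

    P = (1 / 3NV) Σ_i ( v_i² − ½ ⟨k⟩ r_i² ),

the difference between kinetic energy and harmonic potential energy per
volume.  Using the fitted law rather than the doubly-differentiated
per-frame estimate suppresses position-noise amplification; both are
computed and stored for comparison.

With near-Gaussian, near-independent position and velocity marginals the
entropy has the closed form S = (3N/ln 2)·ln(2πe σ_x σ_v) bits, and the
energy added per bit of entropy at fixed σ_x and N defines the temperature
k_B*T = (3/2) σ_v² N (2^{2/(3N)} − 1), which tends to σ_v² ln 2 for large N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import ConvexHull, QhullError

from .errors import InsufficientDataError
from .trajectory import FrameSnapshot, SwarmRecording

__all__ = [
    "SpringLaw",
    "GaussianMoments",
    "StateSeries",
    "centre_of_mass",
    "convex_hull_volume",
    "instantaneous_spring",
    "fit_spring_law",
    "spring_by_size",
    "virial_pressure",
    "gaussian_moments",
    "entropy",
    "temperature",
    "energies",
    "compute_state_series",
]

LN2 = np.log(2.0)

#: state-series serialization column order
STATE_COLUMNS = [
    "time", "N", "V", "P", "S", "T", "Ek", "Ep", "E", "sigma_x", "sigma_v",
    "k", "k_inst",
]


@dataclass
class SpringLaw:
    """Power law k(N) = a·N^b for the emergent spring constant.

    ``a`` is in 1/s² (the spring constant at N = 1), ``b`` dimensionless
    (negative for swarms: larger swarms are more loosely bound).
    """

    a: float
    b: float
    fit_range: tuple[float, float] | None = None
    residual: float | None = None
    stderr: tuple[float, float] | None = None

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("spring-law prefactor a must be positive")

    def __call__(self, n):
        return self.a * np.asarray(n, dtype=float) ** self.b

    @classmethod
    def constant(cls, k: float) -> "SpringLaw":
        """A size-independent spring constant (b = 0)."""
        return cls(a=k, b=0.0)


@dataclass
class GaussianMoments:
    """Position/velocity scale parameters of the Gaussian approximation.

    ``sigma_v`` is the average over frames of the mean of the three
    per-component rms velocities (about zero); ``sigma_x`` is computed
    identically from positions relative to the per-frame centre of mass.
    """

    sigma_x: float
    sigma_v: float
    sigma_x_components: np.ndarray | None = None
    sigma_v_components: np.ndarray | None = None
    n_frames: int = 0

    def __post_init__(self):
        if self.sigma_x <= 0 or self.sigma_v <= 0:
            raise ValueError("sigma_x and sigma_v must be positive")


class StateSeries:
    """Per-frame time series of swarm state variables.

    Thin wrapper around a :class:`pandas.DataFrame` with columns
    ``time, N, V, P, S, T, Ek, Ep, E, sigma_x, sigma_v, k, k_inst``;
    undefined entries (degenerate hull, N = 0, window edges) are NaN.
    """

    def __init__(self, data: pd.DataFrame, frame_rate: float = 100.0, meta: dict | None = None):
        self.data = data.reset_index(drop=True)
        for col in STATE_COLUMNS:
            if col not in self.data.columns:
                self.data[col] = np.nan
        self.frame_rate = float(frame_rate)
        self.meta = meta or {}

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, col: str) -> np.ndarray:
        return self.data[col].to_numpy(dtype=float)

    @property
    def time(self):
        return self["time"]

    def to_csv(self, path) -> None:
        self.data[STATE_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_rate: float | None = None) -> "StateSeries":
        df = pd.read_csv(path)
        if frame_rate is None:
            t = df["time"].to_numpy(dtype=float)
            dt = np.median(np.diff(t)) if len(t) > 1 else 0.01
            frame_rate = 1.0 / dt if dt > 0 else 100.0
        return cls(df, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# Per-snapshot quantities


def centre_of_mass(snapshot: FrameSnapshot) -> np.ndarray:
    """Arithmetic mean of midge positions (mm)."""
    if snapshot.n < 1:
        raise ValueError("centre of mass undefined for an empty snapshot")
    return snapshot.positions.mean(axis=0)


def convex_hull_volume(snapshot: FrameSnapshot) -> float:
    """Volume (mm³) of the convex hull of midge positions.

    Returns NaN for degenerate configurations (N < 4 or coplanar points);
    such frames are flagged and skipped by downstream fits.
    """
    if snapshot.n < 4:
        return np.nan
    try:
        return float(ConvexHull(snapshot.positions).volume)
    except QhullError:
        return np.nan


def instantaneous_spring(snapshot: FrameSnapshot, r_cutoff: float = 1e-6) -> float:
    """Per-frame spring-constant estimate ⟨−a_i·r̂_i / r_i⟩ (1/s²).

    r̂_i is the outward radial unit vector from the swarm centre of mass to
    midge i, so a pure restoring acceleration a_i = −k r_i r̂_i yields
    exactly k.  Midges closer than ``r_cutoff`` mm to the centre are
    excluded (division by r_i).
    """
    if snapshot.n < 1:
        raise ValueError("spring estimate undefined for an empty snapshot")
    if snapshot.accelerations is None:
        raise ValueError("snapshot has no accelerations; differentiate first")
    x_rel = snapshot.positions - centre_of_mass(snapshot)
    r2 = np.einsum("ij,ij->i", x_rel, x_rel)
    mask = r2 > r_cutoff**2
    if not mask.any():
        raise ValueError("all midges at the centre of mass; spring undefined")
    proj = -np.einsum("ij,ij->i", snapshot.accelerations[mask], x_rel[mask])
    return float(np.mean(proj / r2[mask]))


def fit_spring_law(n_values, k_values) -> SpringLaw:
    """Least-squares power-law fit ⟨k|N⟩ = a·N^b in log-log space.

    ``n_values``/``k_values`` are per-swarm-size mean spring constants.
    Requires ≥ 3 distinct N and strictly positive k.
    """
    n_values = np.asarray(n_values, dtype=float)
    k_values = np.asarray(k_values, dtype=float)
    if np.unique(n_values).size < 3:
        raise InsufficientDataError("need >= 3 distinct swarm sizes to fit a power law")
    if np.any(k_values <= 0):
        raise ValueError("all spring constants must be positive for a log-log fit")
    X = sm.add_constant(np.log(n_values))
    res = sm.OLS(np.log(k_values), X).fit()
    loga, b = res.params
    resid = float(np.sqrt(np.mean(res.resid**2)))
    return SpringLaw(
        a=float(np.exp(loga)),
        b=float(b),
        fit_range=(float(n_values.min()), float(n_values.max())),
        residual=resid,
        stderr=(float(res.bse[0]), float(res.bse[1])),
    )


def spring_by_size(recordings, r_cutoff: float = 1e-6) -> pd.DataFrame:
    """Mean per-frame spring estimate ⟨k|N⟩ grouped by instantaneous N.

    Accepts one or more differentiated recordings; returns a table with
    columns ``N, k, count`` (frames per size), the input expected by
    :func:`fit_spring_law`.
    """
    if isinstance(recordings, SwarmRecording):
        recordings = [recordings]
    n_list, k_list = [], []
    for rec in recordings:
        frames, pos, _, acc = _frame_table(rec)
        uniq, starts = np.unique(frames, return_index=True)
        stops = np.append(starts[1:], len(frames))
        for s, e in zip(starts, stops):
            n = e - s
            if n < 1:
                continue
            p = pos[s:e]
            x_rel = p - p.mean(axis=0)
            r2 = np.einsum("ij,ij->i", x_rel, x_rel)
            mask = r2 > r_cutoff**2
            if not mask.any():
                continue
            proj = -np.einsum("ij,ij->i", acc[s:e][mask], x_rel[mask])
            n_list.append(n)
            k_list.append(np.mean(proj / r2[mask]))
    if not n_list:
        raise InsufficientDataError("no frames with a defined spring estimate")
    df = pd.DataFrame({"N": n_list, "k": k_list})
    return (
        df.groupby("N")["k"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "k"})
    )


def virial_pressure(snapshot: FrameSnapshot, k: float, volume: float) -> float:
    """Virial pressure P = (1/3NV)·Σ(v_i² − ½ k r_i²), in mm⁻¹·s⁻² per unit mass.

    r_i is the distance of midge i from the snapshot's centre of mass; may
    be negative (potential-dominated frames).
    """
    if snapshot.n < 1:
        raise ValueError("pressure undefined for an empty snapshot")
    if not volume > 0:
        raise ValueError("pressure requires a positive volume")
    if snapshot.velocities is None:
        raise ValueError("snapshot has no velocities; differentiate first")
    x_rel = snapshot.positions - centre_of_mass(snapshot)
    r2 = np.einsum("ij,ij->i", x_rel, x_rel)
    v2 = np.einsum("ij,ij->i", snapshot.velocities, snapshot.velocities)
    return float(np.sum(v2 - 0.5 * k * r2) / (3.0 * snapshot.n * volume))


def _component_rms(arr: np.ndarray) -> np.ndarray:
    """Per-component rms about zero of an (N, 3) array."""
    return np.sqrt(np.mean(arr**2, axis=0))


def gaussian_moments(snapshots) -> GaussianMoments:
    """Average per-frame component-rms position and velocity scales.

    For each snapshot with N ≥ 2, the rms of each velocity component (about
    zero) and of each position component (about the frame's centre of mass)
    is computed; per-frame values are the mean of the three components, and
    the result averages these over frames.
    """
    sx, sv = [], []
    sxc, svc = [], []
    for snap in snapshots:
        if snap.n < 2 or snap.velocities is None:
            continue
        x_rel = snap.positions - centre_of_mass(snap)
        cx = _component_rms(x_rel)
        cv = _component_rms(snap.velocities)
        sxc.append(cx)
        svc.append(cv)
        sx.append(cx.mean())
        sv.append(cv.mean())
    if not sx:
        raise InsufficientDataError("no snapshots with N >= 2 and velocities")
    return GaussianMoments(
        sigma_x=float(np.mean(sx)),
        sigma_v=float(np.mean(sv)),
        sigma_x_components=np.mean(sxc, axis=0),
        sigma_v_components=np.mean(svc, axis=0),
        n_frames=len(sx),
    )


# ---------------------------------------------------------------------------
# Closed forms


def entropy(moments, n: int) -> float:
    """Extensive Shannon entropy S = (3N/ln 2)·ln(2πe σ_x σ_v), in bits.

    ``moments`` is a :class:`GaussianMoments` or an (σ_x, σ_v) pair.  The
    closed form is the differential entropy of 3N independent Gaussian
    (position, velocity) pairs, converted to bits.
    """
    if isinstance(moments, GaussianMoments):
        sx, sv = moments.sigma_x, moments.sigma_v
    else:
        sx, sv = moments
    if sx <= 0 or sv <= 0:
        raise ValueError("entropy requires positive sigma_x and sigma_v")
    if n < 1:
        raise ValueError("entropy requires N >= 1")
    return 3.0 * n / LN2 * np.log(2.0 * np.pi * np.e * sx * sv)


def temperature(sigma_v: float, n: int) -> float:
    """Effective temperature k_B*T = (3/2) σ_v² N (2^{2/(3N)} − 1), mm²/s².

    The energy added by one bit of entropy at fixed σ_x and N.  Decreases
    monotonically with N toward the intensive limit σ_v²·ln 2, which is
    approached within 2% already for N ≳ 20.
    """
    if n < 1:
        raise ValueError("temperature requires N >= 1")
    if sigma_v <= 0:
        raise ValueError("temperature requires positive sigma_v")
    n = float(n)
    return 1.5 * sigma_v**2 * n * (2.0 ** (2.0 / (3.0 * n)) - 1.0)


def energies(snapshot: FrameSnapshot, k: float) -> tuple[float, float, float]:
    """(E_k, E_p, E): extensive kinetic, potential and total energy, mm²/s².

    E_k = Σ ½ v_i², E_p = Σ ½ k r_i² with r_i the distance from the centre
    of mass; per unit midge mass.
    """
    if snapshot.n < 1:
        raise ValueError("energies undefined for an empty snapshot")
    if snapshot.velocities is None:
        raise ValueError("snapshot has no velocities; differentiate first")
    x_rel = snapshot.positions - centre_of_mass(snapshot)
    ek = 0.5 * float(np.einsum("ij,ij->", snapshot.velocities, snapshot.velocities))
    ep = 0.5 * k * float(np.einsum("ij,ij->", x_rel, x_rel))
    return ek, ep, ek + ep


# ---------------------------------------------------------------------------
# Full series


def _nan_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered NaN-aware moving average, truncated at the ends."""
    window = min(window, len(x))
    if window <= 1:
        return x.copy()
    good = np.isfinite(x)
    filled = np.where(good, x, 0.0)
    kernel = np.ones(window)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(good.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def _frame_table(recording: SwarmRecording):
    """Concatenate all tracks into frame-sorted arrays for fast grouping."""
    frames, pos, vel, acc = [], [], [], []
    for tr in recording.tracks:
        if tr.velocities is None or tr.accelerations is None:
            raise ValueError("recording must be differentiated first")
        frames.append(tr.frames)
        pos.append(tr.positions)
        vel.append(tr.velocities)
        acc.append(tr.accelerations)
    frames = np.concatenate(frames)
    order = np.argsort(frames, kind="stable")
    return (
        frames[order],
        np.concatenate(pos)[order],
        np.concatenate(vel)[order],
        np.concatenate(acc)[order],
    )


def compute_state_series(
    recording: SwarmRecording,
    spring_law: SpringLaw,
    sigma_window: float = 1.0,
    r_cutoff: float = 1e-6,
) -> StateSeries:
    """Compute the per-frame state-variable series of a recording.

    The recording must be differentiated (and normally flight-filtered).
    Per frame: N; convex-hull volume V (NaN-flagged if degenerate);
    k = spring_law(N); virial pressure P; energies E_k, E_p, E; and the
    per-frame spring estimate ``k_inst``.  σ_x, σ_v are centered moving
    averages of per-frame component-rms values over ``sigma_window``
    seconds (default 1 s), from which S and T follow per frame.

    The series covers every frame in the recording's range; frames with no
    flying midges carry N = 0 and NaNs elsewhere.
    """
    if not recording.tracks:
        raise InsufficientDataError("empty recording")
    frames, pos, vel, acc = _frame_table(recording)
    lo, hi = recording.frame_range
    all_frames = np.arange(lo, hi)
    starts = np.searchsorted(frames, all_frames, side="left")
    stops = np.searchsorted(frames, all_frames, side="right")

    nf = len(all_frames)
    cols = {
        name: np.full(nf, np.nan)
        for name in ("V", "P", "Ek", "Ep", "E", "k", "k_inst", "_sx", "_sv")
    }
    n_arr = np.zeros(nf, dtype=int)

    for i in range(nf):
        s, e = starts[i], stops[i]
        n = e - s
        n_arr[i] = n
        if n == 0:
            continue
        p = pos[s:e]
        v = vel[s:e]
        a = acc[s:e]
        com = p.mean(axis=0)
        x_rel = p - com
        r2 = np.einsum("ij,ij->i", x_rel, x_rel)
        v2 = np.einsum("ij,ij->i", v, v)
        k = float(spring_law(n))
        cols["k"][i] = k
        ek = 0.5 * v2.sum()
        ep = 0.5 * k * r2.sum()
        cols["Ek"][i] = ek
        cols["Ep"][i] = ep
        cols["E"][i] = ek + ep
        mask = r2 > r_cutoff**2
        if mask.any():
            proj = -np.einsum("ij,ij->i", a[mask], x_rel[mask])
            cols["k_inst"][i] = np.mean(proj / r2[mask])
        if n >= 4:
            try:
                vol = ConvexHull(p).volume
            except QhullError:
                vol = np.nan
            cols["V"][i] = vol
            if np.isfinite(vol) and vol > 0:
                cols["P"][i] = np.sum(v2 - 0.5 * k * r2) / (3.0 * n * vol)
        if n >= 2:
            cols["_sx"][i] = np.mean(np.sqrt(np.mean(x_rel**2, axis=0)))
            cols["_sv"][i] = np.mean(np.sqrt(np.mean(v**2, axis=0)))

    w = max(1, int(round(sigma_window * recording.frame_rate)))
    sigma_x = _nan_moving_average(cols["_sx"], w)
    sigma_v = _nan_moving_average(cols["_sv"], w)

    with np.errstate(invalid="ignore", divide="ignore"):
        nf_arr = n_arr.astype(float)
        valid = (n_arr >= 1) & (sigma_x > 0) & (sigma_v > 0)
        S = np.where(
            valid, 3.0 * nf_arr / LN2 * np.log(2.0 * np.pi * np.e * sigma_x * sigma_v), np.nan
        )
        T = np.where(
            valid,
            1.5 * sigma_v**2 * nf_arr * (2.0 ** (2.0 / (3.0 * nf_arr)) - 1.0),
            np.nan,
        )

    df = pd.DataFrame(
        {
            "time": all_frames / recording.frame_rate,
            "N": n_arr,
            "V": cols["V"],
            "P": cols["P"],
            "S": S,
            "T": T,
            "Ek": cols["Ek"],
            "Ep": cols["Ep"],
            "E": cols["E"],
            "sigma_x": sigma_x,
            "sigma_v": sigma_v,
            "k": cols["k"],
            "k_inst": cols["k_inst"],
        }
    )
    return StateSeries(df, frame_rate=recording.frame_rate, meta=dict(recording.meta))
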