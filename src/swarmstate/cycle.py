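"""Perturbation-cycle analysis: phase averaging and P–V loops.

Swarms are driven through a periodic four-state light/sound protocol
("light-high/sound-on" → "light-high/sound-off" → "light-low/sound-off" →
"light-low/sound-on", 40-s period by default).  State-variable series are
phase-averaged over the cycle, optionally smoothed with a circular moving
window (3.5 s by default, matching the presentation smoothing of the
laboratory analysis), and plotted as closed loops in the P–V plane.  The
equation of state fitted on unperturbed data is used to reconstruct the
pressure around the cycle from V, T and N alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.ndimage import uniform_filter1d
from scipy.stats import pearsonr

from .eos import EosFit
from .errors import InsufficientDataError
from .state import StateSeries

__all__ = [
    "PerturbationSchedule",
    "PhaseAveragedCycle",
    "phase_average",
    "phase_average_array",
    "smooth_cycle",
    "pv_loop",
    "PVLoop",
    "compare_cycle_reconstruction",
    "CycleComparison",
]

DEFAULT_STATES = (
    "light-high/sound-on",
    "light-high/sound-off",
    "light-low/sound-off",
    "light-low/sound-on",
)


@dataclass(frozen=True)
class PerturbationSchedule:
    """Periodic four-state light/sound protocol.

    ``switch_times`` are the four phase offsets (s) within one period at
    which the states begin, strictly increasing in [0, period).
    """

    period: float = 40.0
    switch_times: tuple = (0.0, 10.0, 20.0, 30.0)
    states: tuple = DEFAULT_STATES
    start_time: float = 0.0

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        st = tuple(float(s) for s in self.switch_times)
        if len(st) != 4 or len(self.states) != 4:
            raise ValueError("schedule must have exactly 4 switch times and 4 states")
        if any(not (0 <= s < self.period) for s in st):
            raise ValueError("switch offsets must lie in [0, period)")
        if any(b <= a for a, b in zip(st, st[1:])):
            raise ValueError("switch offsets must be strictly increasing")
        object.__setattr__(self, "switch_times", st)

    def phase(self, t) -> np.ndarray:
        return np.mod(np.asarray(t, dtype=float) - self.start_time, self.period)

    def state_index(self, t) -> np.ndarray:
        """Index (0..3) of the protocol state active at time(s) t."""
        ph = self.phase(t)
        idx = np.searchsorted(np.asarray(self.switch_times), ph, side="right") - 1
        return np.where(idx < 0, 3, idx)  # before first offset: wrap to last state

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "period": self.period,
                    "switch_times": list(self.switch_times),
                    "states": list(self.states),
                    "start_time": self.start_time,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "PerturbationSchedule":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            period=float(d["period"]),
            switch_times=tuple(d["switch_times"]),
            states=tuple(d.get("states", DEFAULT_STATES)),
            start_time=float(d.get("start_time", 0.0)),
        )


@dataclass
class PhaseAveragedCycle:
    """Per-phase-bin means ⟨·⟩_φ of the state variables over a full cycle."""

    phase: np.ndarray          # bin centres, s in [0, period)
    mean_P: np.ndarray
    mean_V: np.ndarray
    mean_T: np.ndarray
    mean_N: np.ndarray
    counts: np.ndarray         # frames per bin
    period: float
    schedule: PerturbationSchedule | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.phase)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "phase": self.phase,
                "P": self.mean_P,
                "V": self.mean_V,
                "T": self.mean_T,
                "N": self.mean_N,
                "count": self.counts,
            }
        ).to_csv(path, index=False)


def _bin_means(phase, values, n_bins, period):
    """NaN-aware per-bin means; returns (means, finite counts per bin)."""
    bins = np.minimum((phase / period * n_bins).astype(int), n_bins - 1)
    good = np.isfinite(values)
    num = np.bincount(bins[good], weights=values[good], minlength=n_bins)
    cnt = np.bincount(bins[good], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = num / cnt
    means[cnt == 0] = np.nan
    return means, cnt


def phase_average_array(
    t, values, schedule: PerturbationSchedule, n_bins: int = 400
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phase-average an arbitrary time series; returns (phase, means, counts)."""
    t = np.asarray(t, dtype=float)
    ph = schedule.phase(t)
    means, cnt = _bin_means(ph, np.asarray(values, dtype=float), n_bins, schedule.period)
    centres = (np.arange(n_bins) + 0.5) * schedule.period / n_bins
    return centres, means, cnt


def phase_average(
    series, schedule: PerturbationSchedule, n_bins: int = 400
) -> PhaseAveragedCycle:
    """Phase-average a state series over the perturbation cycle.

    Each frame is assigned the phase (t − start_time) mod period and the
    per-bin mean of P, V, T and N is taken (NaN frames skipped per
    variable).  Requires the series to span at least two full periods.
    """
    df = series.data if isinstance(series, StateSeries) else series
    t = df["time"].to_numpy(dtype=float)
    dt_est = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    if t.max() - t.min() + dt_est < 2.0 * schedule.period:
        raise InsufficientDataError(
            "series must span at least 2 full perturbation periods"
        )
    ph = schedule.phase(t)
    out = {}
    for col in ("P", "V", "T", "N"):
        out[col], _ = _bin_means(ph, df[col].to_numpy(dtype=float), n_bins, schedule.period)
    counts = np.bincount(
        np.minimum((ph / schedule.period * n_bins).astype(int), n_bins - 1),
        minlength=n_bins,
    )
    centres = (np.arange(n_bins) + 0.5) * schedule.period / n_bins
    return PhaseAveragedCycle(
        phase=centres,
        mean_P=out["P"],
        mean_V=out["V"],
        mean_T=out["T"],
        mean_N=out["N"],
        counts=counts,
        period=schedule.period,
        schedule=schedule,
    )


def _circular_boxcar(x: np.ndarray, size: int) -> np.ndarray:
    return uniform_filter1d(x, size=size, mode="wrap") * size


def _smooth_var(values, counts, size):
    """Count-weighted circular moving average; NaN bins carry zero weight."""
    w = counts.astype(float) * np.isfinite(values)
    v = np.where(np.isfinite(values), values, 0.0)
    num = _circular_boxcar(v * w, size)
    den = _circular_boxcar(w, size)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def smooth_cycle(cycle: PhaseAveragedCycle, window: float = 3.5) -> PhaseAveragedCycle:
    """Circular (wrap-around) moving average over phase.

    ``window`` is in seconds (default 3.5 s); must be shorter than the
    period.  The average is weighted by per-bin frame counts, so the
    count-weighted cycle mean is conserved exactly.
    """
    if window >= cycle.period:
        raise ValueError("smoothing window must be shorter than the period")
    size = max(1, int(round(window / cycle.period * cycle.n_bins)))
    return replace(
        cycle,
        mean_P=_smooth_var(cycle.mean_P, cycle.counts, size),
        mean_V=_smooth_var(cycle.mean_V, cycle.counts, size),
        mean_T=_smooth_var(cycle.mean_T, cycle.counts, size),
        mean_N=_smooth_var(cycle.mean_N, cycle.counts, size),
    )


@dataclass
class PVLoop:
    """Closed phase-ordered loop in the pressure–volume plane."""

    V: np.ndarray
    P: np.ndarray
    area: float
    interpolated: np.ndarray  # bins whose values were filled in


def _circular_interp(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fill NaN bins by linear interpolation with wrap-around."""
    bad = ~np.isfinite(values)
    if not bad.any():
        return values, bad
    if bad.all():
        raise InsufficientDataError("all phase bins empty")
    n = len(values)
    idx = np.arange(n)
    good = ~bad
    filled = values.copy()
    filled[bad] = np.interp(idx[bad], idx[good], values[good], period=n)
    return filled, bad


def pv_loop(cycle: PhaseAveragedCycle) -> PVLoop:
    """Phase-ordered (V, P) curve closed by wrap-around, with signed area.

    The signed enclosed area is computed with the shoelace formula;
    reversing the phase direction flips its sign.  Empty bins are linearly
    interpolated across (circularly) and flagged.
    """
    if cycle.n_bins < 8:
        raise ValueError("need at least 8 phase bins for a loop")
    v, bad_v = _circular_interp(cycle.mean_V)
    p, bad_p = _circular_interp(cycle.mean_P)
    vn = np.roll(v, -1)
    pn = np.roll(p, -1)
    area = 0.5 * float(np.sum(v * pn - vn * p))
    return PVLoop(V=v, P=p, area=area, interpolated=bad_v | bad_p)


@dataclass
class CycleComparison:
    """Phase-wise agreement of measured vs EOS-reconstructed pressure."""

    correlation: float
    nrmse: float
    per_state: list            # dicts: state, n_bins, correlation, nrmse
    n_bins: int
    phase: np.ndarray
    measured: np.ndarray
    reconstructed: np.ndarray


def _nrmse(a, b):
    denom = float(np.sqrt(np.mean(a**2)))
    return float(np.sqrt(np.mean((b - a) ** 2)) / denom) if denom > 0 else np.nan


def compare_cycle_reconstruction(
    measured: PhaseAveragedCycle,
    fit: EosFit,
    series,
    schedule: PerturbationSchedule | None = None,
    smooth_window: float | None = 3.5,
) -> CycleComparison:
    """Compare ⟨P⟩_φ against the EOS reconstruction phase-averaged identically.

    ``fit`` should come from unperturbed data; ``series`` is the perturbed
    recording's state series.  The reconstruction P̂ = c4 V^c1 T^c2 N^c3 is
    evaluated per frame, phase-averaged with the same schedule and bin
    count as ``measured`` (and smoothed with the same window), and compared
    bin-wise overall and per protocol state.
    """
    if schedule is None:
        schedule = measured.schedule
    if schedule is None:
        raise ValueError("a PerturbationSchedule is required")
    if not np.isclose(schedule.period, measured.period):
        raise ValueError("schedule period does not match the measured cycle")
    df = series.data if isinstance(series, StateSeries) else series
    t = df["time"].to_numpy(dtype=float)
    phat = fit.predict(series)
    _, rec_means, rec_counts = phase_average_array(t, phat, schedule, measured.n_bins)
    rec_cycle = PhaseAveragedCycle(
        phase=measured.phase,
        mean_P=rec_means,
        mean_V=measured.mean_V,
        mean_T=measured.mean_T,
        mean_N=measured.mean_N,
        counts=rec_counts,
        period=measured.period,
        schedule=schedule,
    )
    meas = measured
    if smooth_window is not None:
        meas = smooth_cycle(measured, smooth_window)
        rec_cycle = smooth_cycle(rec_cycle, smooth_window)
    pm = meas.mean_P
    pr = rec_cycle.mean_P
    valid = np.isfinite(pm) & np.isfinite(pr)
    if valid.sum() < 8:
        raise InsufficientDataError("too few overlapping phase bins")
    corr = float(pearsonr(pm[valid], pr[valid]).statistic)
    per_state = []
    state_idx = schedule.state_index(meas.phase + schedule.start_time)
    for s, label in enumerate(schedule.states):
        m = valid & (state_idx == s)
        entry = {"state": label, "n_bins": int(m.sum())}
        if m.sum() >= 3:
            entry["correlation"] = float(pearsonr(pm[m], pr[m]).statistic)
            entry["nrmse"] = _nrmse(pm[m], pr[m])
        else:
            entry["correlation"] = np.nan
            entry["nrmse"] = np.nan
        per_state.append(entry)
    return CycleComparison(
        correlation=corr,
        nrmse=_nrmse(pm[valid], pr[valid]),
        per_state=per_state,
        n_bins=int(valid.sum()),
        phase=meas.phase,
        measured=pm,
        reconstructed=pr,
    )
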