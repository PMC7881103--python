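"""Equation of state for swarms: P = c4·V^c1·(k_B*T)^c2·N^c3.

To leading order of a virial-like expansion, the swarm pressure is modelled
as a single product of powers of the other state variables.  Before
fitting, all four variables are normalized by their rms values so they are
of the same order of magnitude; the normalization factors are absorbed
into the prefactor c4 and do not change the exponents.

The fit is nonlinear least squares of P on the model surface, started from
the neutral guess (c1, c2, c3, c4) = (−1, 1, 1, 1).  Frames with negative
P are retained (the positive model surface can only approach them from
above, but they carry information); an ordinary linear regression of log P
on (log V, log T, log N), restricted to P > 0 frames, is returned as an
independent cross-check.  Temporal correlation between frames is handled
by a configurable subsampling stride; exponent standard errors are
reported both from the strided fit and naively (as if all frames were
independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares
from scipy.stats import ks_2samp, pearsonr

from .errors import DegenerateSeriesError, FitConvergenceError, InsufficientDataError
from .state import StateSeries

__all__ = [
    "EquationOfState",
    "EosFit",
    "normalize_rms",
    "fit_eos",
    "reconstruct_pressure",
    "goodness_of_fit",
    "GoodnessReport",
]

_EOS_VARS = ("P", "V", "T", "N")


def _get_columns(series) -> pd.DataFrame:
    if isinstance(series, StateSeries):
        return series.data
    return series


def normalize_rms(series) -> tuple[pd.DataFrame, dict]:
    """Normalize P, V, T, N by their rms over jointly-defined frames.

    Returns the normalized table (other columns untouched) and a dict of
    the rms factors, for later de-normalization.
    """
    df = _get_columns(series).copy()
    vals = {c: df[c].to_numpy(dtype=float) for c in _EOS_VARS}
    valid = np.all([np.isfinite(vals[c]) for c in _EOS_VARS], axis=0)
    if valid.sum() < 10:
        raise InsufficientDataError(
            f"need >= 10 frames with P, V, T, N all defined (got {int(valid.sum())})"
        )
    norms = {}
    for c in _EOS_VARS:
        rms = float(np.sqrt(np.mean(vals[c][valid] ** 2)))
        if rms == 0:
            raise DegenerateSeriesError(f"rms of {c} is zero; cannot normalize")
        norms[c] = rms
        df[c] = vals[c] / rms
    return df, norms


@dataclass
class GoodnessReport:
    """Agreement between measured and reconstructed pressure."""

    correlation: float
    nrmse: float
    ks_distance: float
    ks_pvalue: float
    n: int


@dataclass
class EosFit:
    """Results of an equation-of-state fit.

    ``params`` = (c1, c2, c3, c4) in rms-normalized units; ``bse`` their
    standard errors from the (stride-decorrelated) fit covariance and
    ``bse_naive`` the same scaled as if every frame were independent.
    ``loglog_params``/``loglog_bse`` hold the log-space linear cross-check
    (c1, c2, c3, log c4).  ``norms`` are the rms normalization factors.
    """

    params: np.ndarray
    bse: np.ndarray
    bse_naive: np.ndarray
    norms: dict
    loglog_params: np.ndarray | None = None
    loglog_bse: np.ndarray | None = None
    stride: int = 1
    n_used: int = 0
    resid_rms: float = np.nan
    nfev: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def c1(self) -> float:
        return float(self.params[0])

    @property
    def c2(self) -> float:
        return float(self.params[1])

    @property
    def c3(self) -> float:
        return float(self.params[2])

    @property
    def c4(self) -> float:
        return float(self.params[3])

    def predict(self, series) -> np.ndarray:
        """Reconstructed pressure P̂(t) in original (de-normalized) units."""
        df = _get_columns(series)
        v = df["V"].to_numpy(dtype=float) / self.norms["V"]
        t = df["T"].to_numpy(dtype=float) / self.norms["T"]
        n = df["N"].to_numpy(dtype=float) / self.norms["N"]
        with np.errstate(invalid="ignore"):
            phat = self.c4 * v**self.c1 * t**self.c2 * n**self.c3
        phat[~(np.isfinite(v) & np.isfinite(t) & (n > 0))] = np.nan
        return phat * self.norms["P"]

    def summary(self) -> str:
        lines = [
            "Equation of state: P = c4 V^c1 (kB*T)^c2 N^c3  (rms-normalized)",
            f"  frames used: {self.n_used}  (stride {self.stride})",
            f"  residual rms: {self.resid_rms:.4g}",
            "  param     value      SE (strided)  SE (naive)",
        ]
        for name, p, se, sen in zip(
            ("c1", "c2", "c3", "c4"), self.params, self.bse, self.bse_naive
        ):
            lines.append(f"  {name:4s} {p:10.4f}    {se:10.4f}  {sen:10.4f}")
        if self.loglog_params is not None:
            c1, c2, c3, logc4 = self.loglog_params
            lines.append(
                "  log-space cross-check (P>0 frames): "
                f"c1={c1:.4f} c2={c2:.4f} c3={c3:.4f} log c4={logc4:.4f}"
            )
        lines.append(
            "  norms: "
            + " ".join(f"{k}={v:.4g}" for k, v in self.norms.items())
        )
        return "\n".join(lines)

    def to_text(self, path) -> None:
        """Serialize as a small key-value text file."""
        with open(path, "w") as fh:
            for name, p, se in zip(("c1", "c2", "c3", "c4"), self.params, self.bse):
                fh.write(f"{name} = {p!r}\n{name}_se = {se!r}\n")
            for k, v in self.norms.items():
                fh.write(f"norm_{k} = {v!r}\n")
            fh.write(f"stride = {self.stride}\nn_used = {self.n_used}\n")
            fh.write(f"resid_rms = {self.resid_rms!r}\n")

    def plot_reconstruction(self, series, ax=None):
        """Overlay measured and reconstructed pressure time series."""
        import matplotlib.pyplot as plt

        df = _get_columns(series)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(df["time"], df["P"], label="measured P", lw=0.8)
        ax.plot(df["time"], self.predict(series), label="EOS reconstruction", lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("P (mm$^{-1}$ s$^{-2}$)")
        ax.legend()
        return ax


class EquationOfState:
    """Model object: fit the power-law equation of state to a state series.

    Parameters
    ----------
    series : StateSeries or DataFrame
        Must contain columns P, V, T, N; frames where any is undefined are
        skipped.
    """

    def __init__(self, series):
        self.series = series

    def fit(
        self,
        stride: int = 10,
        p0: tuple = (-1.0, 1.0, 1.0, 1.0),
        max_iter: int = 10_000,
        xtol: float = 1e-12,
    ) -> EosFit:
        """Nonlinear least-squares fit; see the module docstring.

        ``stride`` subsamples frames to reduce temporal correlation
        (default 10; use 1 for independent samples).  Raises
        :class:`FitConvergenceError` (carrying the last iterate) on
        non-convergence and :class:`InsufficientDataError` below 50 usable
        frames.
        """
        if stride < 1:
            raise ValueError("stride must be >= 1")
        df, norms = normalize_rms(self.series)
        P = df["P"].to_numpy(dtype=float)
        V = df["V"].to_numpy(dtype=float)
        T = df["T"].to_numpy(dtype=float)
        N = df["N"].to_numpy(dtype=float)
        valid = (
            np.isfinite(P) & np.isfinite(V) & np.isfinite(T)
            & (V > 0) & (T > 0) & (N > 0)
        )
        idx = np.flatnonzero(valid)[::stride]
        if idx.size < 50:
            raise InsufficientDataError(
                f"only {idx.size} usable frames after striding (need >= 50)"
            )
        p, v, t, n = P[idx], V[idx], T[idx], N[idx]
        lv, lt, ln = np.log(v), np.log(t), np.log(n)

        def model(params):
            c1, c2, c3, c4 = params
            return c4 * np.exp(c1 * lv + c2 * lt + c3 * ln)

        def resid(params):
            return model(params) - p

        def jac(params):
            c1, c2, c3, c4 = params
            m = np.exp(c1 * lv + c2 * lt + c3 * ln)
            f = c4 * m
            return np.column_stack([f * lv, f * lt, f * ln, m])

        sol = least_squares(
            resid, np.asarray(p0, dtype=float), jac=jac,
            xtol=xtol, ftol=xtol, gtol=None, max_nfev=max_iter,
        )
        if not sol.success:
            raise FitConvergenceError(
                f"equation-of-state fit did not converge: {sol.message}",
                last_params=sol.x,
            )
        res = sol.fun
        dof = max(idx.size - 4, 1)
        J = sol.jac
        try:
            # heteroscedasticity-robust (sandwich) covariance: multiplicative
            # noise makes the residual variance scale with P, so the naive
            # s^2 (J'J)^-1 form would understate the exponent uncertainties
            H = np.linalg.inv(J.T @ J)
            meat = (J * res[:, None] ** 2).T @ J
            cov = H @ meat @ H * (idx.size / dof)
            bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            bse = np.full(4, np.nan)
        n_all = int(valid.sum())
        bse_naive = bse * np.sqrt(idx.size / n_all)

        # independent cross-check: linear regression in log space (P > 0)
        loglog_params = loglog_bse = None
        pos = p > 0
        if pos.sum() >= 10:
            X = sm.add_constant(np.column_stack([lv[pos], lt[pos], ln[pos]]))
            ols = sm.OLS(np.log(p[pos]), X).fit()
            logc4, c1, c2, c3 = ols.params
            loglog_params = np.array([c1, c2, c3, logc4])
            loglog_bse = np.array([ols.bse[1], ols.bse[2], ols.bse[3], ols.bse[0]])

        return EosFit(
            params=sol.x,
            bse=bse,
            bse_naive=bse_naive,
            norms=norms,
            loglog_params=loglog_params,
            loglog_bse=loglog_bse,
            stride=stride,
            n_used=int(idx.size),
            resid_rms=float(np.sqrt(np.mean(res**2))),
            nfev=int(sol.nfev),
            diagnostics={"cost": float(sol.cost), "message": sol.message},
        )


def fit_eos(series, subsample_stride: int = 10, **kwargs) -> EosFit:
    """Functional wrapper: ``EquationOfState(series).fit(stride=...)``."""
    return EquationOfState(series).fit(stride=subsample_stride, **kwargs)


def reconstruct_pressure(fit: EosFit, series) -> np.ndarray:
    """P̂(t) = c4 V^c1 T^c2 N^c3 in original units; NaN where inputs are."""
    return fit.predict(series)


def goodness_of_fit(series, reconstruction) -> GoodnessReport:
    """Correlation, normalized rms error and KS distance of P̂ against P."""
    df = _get_columns(series)
    p = df["P"].to_numpy(dtype=float)
    phat = np.asarray(reconstruction, dtype=float)
    valid = np.isfinite(p) & np.isfinite(phat)
    if valid.sum() < 50:
        raise InsufficientDataError(
            f"only {int(valid.sum())} overlapping defined frames (need >= 50)"
        )
    p, phat = p[valid], phat[valid]
    r = float(pearsonr(p, phat).statistic)
    denom = float(np.sqrt(np.mean(p**2)))
    nrmse = float(np.sqrt(np.mean((phat - p) ** 2)) / denom) if denom > 0 else np.nan
    ks = ks_2samp(p, phat)
    return GoodnessReport(
        correlation=r,
        nrmse=nrmse,
        ks_distance=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        n=int(valid.sum()),
    )
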