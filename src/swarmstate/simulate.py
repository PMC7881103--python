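"""Synthetic swarm generator: damped stochastic oscillators in a harmonic well.

Laboratory midge swarms behave statistically as if each individual were
trapped in an emergent harmonic potential well centred on the swarm, with
near-Gaussian, near-isotropic position and velocity marginals and a spring
constant that falls off with swarm size as a power law.  The minimal
stochastic process with exactly those stationary properties is the damped
harmonic Langevin oscillator, integrated here per midge and per component:

    dv = (−k x − γ v) dt + sqrt(2 γ) σ_v dW,    dx = v dt

whose stationary distribution is Gaussian with Var(v) = σ_v² and
Var(x) = σ_v²/k — virial-balanced by construction (k σ_x² = σ_v²).  This
is an explicit statistical stand-in for the laboratory system, not a
behavioural model of midges: it reproduces the moment structure the
analysis relies on (well-binding, Gaussianity, isotropy, virial balance,
100 Hz sampling) and nothing else.

Default conditions mirror the laboratory regime: N in the tens, σ_v =
200 mm/s (swarm rms speeds of a few hundred mm/s), damping γ = 2 s⁻¹
(velocity correlation time ~0.5 s), spring law k(N) = 25·N^(−1/2) s⁻²
(k ≈ 3.5 s⁻² and σ_x ≈ 107 mm at N = 50, a decimetre-scale swarm), dt =
0.01 s (100 Hz).  N is constant within a recording — it varies much more
slowly than the dynamics — and varies across the recordings of an
ensemble.

Perturbed recordings emulate the four-state light/sound protocol: at each
state switch the velocity-scale target jumps by a startle factor and
relaxes exponentially back to the per-state baseline, driving the swarm
around a loop in the P–V plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import expm

from .cycle import PerturbationSchedule
from .errors import StabilityError
from .state import SpringLaw, StateSeries
from .trajectory import MidgeTrack, SwarmRecording

__all__ = [
    "SimulationConfig",
    "EosSampleConfig",
    "simulate_swarm",
    "simulate_ensemble",
    "simulate_perturbed",
    "generate_eos_samples",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic swarm generator.

    ``sigma_v_target`` (mm/s) and ``spring_law`` set the stationary
    velocity and position scales (σ_x = σ_v/√k); ``gamma`` (1/s) the
    damping rate; ``dt`` the integration/sampling step (s).  ``startle``
    behaviour is (amplitude factor, relaxation time s): at each protocol
    switch the σ_v target jumps to amplitude×baseline and relaxes with the
    given time constant.  ``kinetic_boost`` β scales the dynamical spring
    to β²·k(N) so that analyses using the nominal law see a kinetic/
    potential imbalance of β² (stress-testing; default 1 = balanced).
    ``position_noise`` adds Gaussian measurement jitter (mm) after
    integration.  ``exact_updates`` switches from Euler–Maruyama to the
    exact Gaussian transition of the linear process (oracle mode).
    """

    n_midges: int = 50
    gamma: float = 2.0
    sigma_v_target: float = 200.0
    spring_law: SpringLaw = field(default_factory=lambda: SpringLaw(a=25.0, b=-0.5))
    dt: float = 0.01
    duration: float = 100.0
    seed: int = 0
    startle: tuple = (1.5, 2.0)
    state_sigma_multipliers: tuple = (1.0, 1.0, 1.0, 1.0)
    state_k_multipliers: tuple = (1.0, 1.0, 1.0, 1.0)
    position_noise: float = 0.0
    marker_offset: tuple = (0.0, 0.0, 1000.0)
    kinetic_boost: float = 1.0
    exact_updates: bool = False

    def __post_init__(self):
        if self.dt <= 0 or self.gamma <= 0 or self.sigma_v_target <= 0:
            raise ValueError("dt, gamma and sigma_v_target must be positive")
        if self.duration < 10 * self.dt:
            raise ValueError("duration must be at least 10 time steps")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "spring_law" in d:
            sl = d["spring_law"]
            d["spring_law"] = SpringLaw(a=float(sl["a"]), b=float(sl.get("b", 0.0)))
        for key in ("startle", "state_sigma_multipliers", "state_k_multipliers",
                    "marker_offset"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class EosSampleConfig:
    """Generator of (P, V, T, N) samples obeying a known power-law EOS.

    V, T, N are drawn log-uniformly within the given ranges (defaults span
    the laboratory regime: decimetre-scale hull volumes, σ_v of 100–300
    mm/s, N of 10–100); P = g4·V^g1·T^g2·N^g3 times mean-one log-normal
    noise with coefficient of variation ``noise_cv``.
    """

    g1: float = -1.7
    g2: float = 2.0
    g3: float = 1.0
    g4: float = 1.0
    n_samples: int = 5000
    noise_cv: float = 0.05
    v_range: tuple = (1e5, 1e7)
    t_range: tuple = (5e3, 5e4)
    n_range: tuple = (10, 100)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 10:
            raise ValueError("need at least 10 samples")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        for rng in (self.v_range, self.t_range, self.n_range):
            if rng[0] <= 0 or rng[1] <= rng[0]:
                raise ValueError("ranges must be positive and increasing")


def _check_stability(gamma: float, k_max: float, dt: float) -> None:
    if gamma * dt > 0.1 or k_max * dt**2 > 0.1:
        raise StabilityError(
            f"dt={dt} too large: need gamma*dt <= 0.1 (got {gamma * dt:.3g}) "
            f"and k*dt^2 <= 0.1 (got {k_max * dt**2:.3g})"
        )


def _exact_propagator(k: float, gamma: float, sigma_v: float, dt: float):
    """Exact one-step transition (M, chol) of the linear (x, v) process."""
    A = np.array([[0.0, 1.0], [-k, -gamma]])
    M = expm(A * dt)
    Sinf = np.diag([sigma_v**2 / k, sigma_v**2])
    Q = Sinf - M @ Sinf @ M.T
    # guard tiny negative eigenvalues from roundoff
    w, U = np.linalg.eigh(Q)
    chol = U @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    return M, chol


def _integrate(
    n: int,
    k_frames: np.ndarray,
    sigma_frames: np.ndarray,
    gamma: float,
    dt: float,
    rng: np.random.Generator,
    exact: bool = False,
) -> np.ndarray:
    """Integrate N independent 3D oscillators; returns positions (T, N, 3).

    ``k_frames`` and ``sigma_frames`` give the spring constant and noise
    scale at every output frame (constant arrays for stationary runs).
    Initial conditions are drawn from the stationary distribution of the
    frame-0 parameters.
    """
    n_frames = len(k_frames)
    k0, s0 = k_frames[0], sigma_frames[0]
    x = rng.normal(0.0, s0 / np.sqrt(k0), size=(n, 3))
    v = rng.normal(0.0, s0, size=(n, 3))
    out = np.empty((n_frames, n, 3))
    out[0] = x
    if exact:
        if not (np.all(k_frames == k0) and np.all(sigma_frames == s0)):
            raise ValueError("exact_updates supports constant parameters only")
        M, chol = _exact_propagator(k0, gamma, s0, dt)
        for t in range(1, n_frames):
            noise = rng.standard_normal((n, 3, 2))
            z_x = M[0, 0] * x + M[0, 1] * v
            z_v = M[1, 0] * x + M[1, 1] * v
            eta = noise @ chol.T
            x = z_x + eta[:, :, 0]
            v = z_v + eta[:, :, 1]
            out[t] = x
        return out
    sq2g = np.sqrt(2.0 * gamma * dt)
    for t in range(1, n_frames):
        k = k_frames[t - 1]
        s = sigma_frames[t - 1]
        dv = (-k * x - gamma * v) * dt + sq2g * s * rng.standard_normal((n, 3))
        x = x + v * dt
        v = v + dv
        out[t] = x
    return out


def _to_recording(
    positions: np.ndarray, config: SimulationConfig, rng: np.random.Generator,
    schedule: PerturbationSchedule | None = None, meta: dict | None = None,
) -> SwarmRecording:
    if config.position_noise > 0:
        positions = positions + rng.normal(0.0, config.position_noise, positions.shape)
    positions = positions + np.asarray(config.marker_offset, dtype=float)
    n = positions.shape[1]
    width = len(str(max(n - 1, 1)))
    tracks = [
        MidgeTrack(f"m{j:0{width}d}", 0, positions[:, j, :]) for j in range(n)
    ]
    base_meta = {
        "generator": "swarmstate.simulate",
        "n_midges": n,
        "gamma": config.gamma,
        "sigma_v_target": config.sigma_v_target,
        "seed": config.seed,
    }
    base_meta.update(meta or {})
    return SwarmRecording(
        frame_rate=1.0 / config.dt, tracks=tracks, schedule=schedule, meta=base_meta
    )


def simulate_swarm(config: SimulationConfig) -> SwarmRecording:
    """Generate one stationary synthetic swarm recording.

    N midges evolve independently in the harmonic well k(N) from the
    configured spring law (scaled by ``kinetic_boost``²), with stationary
    σ_v = ``sigma_v_target`` and σ_x = σ_v/√k.  Reproducible from
    ``config.seed``.
    """
    n_frames = int(round(config.duration / config.dt))
    k_dyn = float(config.spring_law(config.n_midges)) * config.kinetic_boost**2
    _check_stability(config.gamma, k_dyn, config.dt)
    rng = np.random.default_rng(config.seed)
    k_frames = np.full(n_frames, k_dyn)
    s_frames = np.full(n_frames, config.sigma_v_target)
    pos = _integrate(
        config.n_midges, k_frames, s_frames, config.gamma, config.dt, rng,
        exact=config.exact_updates,
    )
    return _to_recording(pos, config, rng, meta={"k_dyn": k_dyn})


def simulate_ensemble(base: SimulationConfig, n_values) -> list[SwarmRecording]:
    """One stationary recording per swarm size, with independent seeds.

    Emulates swarm-to-swarm variability: the spring constant follows the
    base config's spring law at each N.  Child seeds are spawned
    deterministically from ``base.seed``.
    """
    n_values = list(n_values)
    if not n_values:
        raise ValueError("n_values must be non-empty")
    children = np.random.SeedSequence(base.seed).spawn(len(n_values))
    out = []
    for n, child in zip(n_values, children):
        seed = int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        cfg = replace(base, n_midges=int(n), seed=seed)
        out.append(simulate_swarm(cfg))
    return out


def _perturbed_profiles(
    config: SimulationConfig, schedule: PerturbationSchedule, n_frames: int
):
    """Per-frame σ_v target and spring constant under the protocol."""
    t = np.arange(n_frames) * config.dt
    state = schedule.state_index(t)
    sig_mult = np.asarray(config.state_sigma_multipliers, dtype=float)[state]
    k_mult = np.asarray(config.state_k_multipliers, dtype=float)[state]
    amp, tau = config.startle
    # time since the most recent switch (any of the 4 per period)
    ph = schedule.phase(t)
    offsets = np.asarray(schedule.switch_times)
    prev = offsets[np.maximum(np.searchsorted(offsets, ph, side="right") - 1, 0)]
    since = np.where(ph >= offsets[0], ph - prev, ph + schedule.period - offsets[-1])
    startle = 1.0 + (amp - 1.0) * np.exp(-since / tau)
    k_base = float(config.spring_law(config.n_midges)) * config.kinetic_boost**2
    return config.sigma_v_target * sig_mult * startle, k_base * k_mult


def simulate_perturbed(
    config: SimulationConfig, schedule: PerturbationSchedule
) -> SwarmRecording:
    """Generate a recording driven by the four-state light/sound protocol.

    At each state switch the σ_v target jumps by the startle amplitude
    factor and relaxes exponentially (time constant ``config.startle[1]``)
    to the per-state baseline multiplier; the spring constant follows the
    per-state multiplier table.  With amplitude 1 and unit multipliers the
    output is identical to :func:`simulate_swarm` at the same seed.
    """
    n_frames = int(round(config.duration / config.dt))
    sigma_frames, k_frames = _perturbed_profiles(config, schedule, n_frames)
    _check_stability(config.gamma, float(k_frames.max()), config.dt)
    rng = np.random.default_rng(config.seed)
    pos = _integrate(
        config.n_midges, k_frames, sigma_frames, config.gamma, config.dt, rng,
        exact=config.exact_updates,
    )
    return _to_recording(pos, config, rng, schedule=schedule)


def generate_eos_samples(config: EosSampleConfig) -> StateSeries:
    """Draw (V, T, N) and compute P from a known power-law EOS, plus noise.

    Returns a :class:`StateSeries`-shaped table (S and the energies are
    left undefined) suitable for :func:`swarmstate.eos.fit_eos` validation:
    with ``noise_cv = 0`` the samples satisfy the law exactly.
    """
    rng = np.random.default_rng(config.seed)

    def log_uniform(lo, hi, size):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))

    m = config.n_samples
    V = log_uniform(*config.v_range, m)
    T = log_uniform(*config.t_range, m)
    N = np.round(log_uniform(*config.n_range, m)).astype(int)
    P = config.g4 * V**config.g1 * T**config.g2 * N.astype(float)**config.g3
    if config.noise_cv > 0:
        s = np.sqrt(np.log1p(config.noise_cv**2))
        P = P * np.exp(rng.normal(0.0, s, m) - 0.5 * s**2)  # mean-one noise
    df = pd.DataFrame({"time": np.arange(m, dtype=float), "N": N, "V": V, "P": P, "T": T})
    return StateSeries(df, frame_rate=1.0, meta={"generator": "generate_eos_samples",
                                                 "truth": (config.g1, config.g2, config.g3, config.g4)})
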