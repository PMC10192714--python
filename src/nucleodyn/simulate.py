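"""Brownian-dynamics generator of FCS photon-count traces with known truth.

Point particles diffuse in a periodic cube containing a 3D Gaussian
observation volume at its centre.  Each particle switches between three
states -- free, bound to a short-lived site, bound to a long-lived site --
with pseudo-first-order rates (site concentrations folded into the on-rates;
no direct short<->long exchange).  Bound particles are immobile but remain
fluorescent at their fixed position, which is what produces the exponential
terms of the model ACF.  Photon counts per sampling bin are Poisson with
mean

    dt * brightness * sum_particles exp(-2 x^2/w_xy^2 - 2 y^2/w_xy^2 - 2 z^2/w_z^2).

The mapping from generative rates to the observable model parameters is
closed-form (:func:`expected_params_from_config`), so simulated traces act
as ground truth for the correlator and the fitting routine.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .correlate import IntensityTrace
from .errors import ConfigurationError
from .model import FCSParams

__all__ = ["SimConfig", "SimOutput", "expected_params_from_config", "simulate_trace"]

_FREE, _SHORT, _LONG = 0, 1, 2
_MAX_SUBSTEPS = 64


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated FCS acquisition.

    Defaults emulate the acquisition regime used throughout the package's
    tests: 50 kHz sampling for 162 s (2.7 min), tau_D = 1 ms, residence
    times 0.1 s and 2 s with equilibrium occupancies 0.5/0.3/0.2, and a
    concentration of ~1 molecule in the effective observation volume (the
    bound-term amplitudes (f_short+f_long)/N must stay well below 1 for the
    sum-to-one model convention to represent the curve, and the sampling
    noise of the slow binding component shrinks with particle number).
    """

    n_particles: int = 36
    box_size: float = 2.5            # um, periodic cube edge
    d_free: float = 15.625           # um^2/s -> tau_D = w_xy^2/(4 D) = 1 ms
    w_xy: float = 0.25               # um, radial waist
    w_z: float = 1.25                # um, axial waist (omega = 5)
    brightness: float = 37_500.0     # counts/s per molecule at beam centre
    rate_hz: float = 50_000.0
    duration_s: float = 162.0
    kon_short: float = 6.0           # s^-1, pseudo-first-order
    koff_short: float = 10.0         # s^-1 -> tau_short = 0.1 s
    kon_long: float = 0.2
    koff_long: float = 0.5           # s^-1 -> tau_long = 2 s
    seed: int = 0
    init_positions: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ConfigurationError("n_particles must be >= 1")
        for name in ("box_size", "w_xy", "w_z", "brightness", "rate_hz", "duration_s"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.d_free < 0:
            raise ConfigurationError("d_free must be >= 0")
        for name in ("kon_short", "koff_short", "kon_long", "koff_long"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.box_size < 10 * self.w_xy:
            raise ConfigurationError("box_size must be >= 10 * w_xy")
        if self.kon_short > 0 and self.koff_short == 0:
            raise ConfigurationError("koff_short = 0 with kon_short > 0: absorbing state")
        if self.kon_long > 0 and self.koff_long == 0:
            raise ConfigurationError("koff_long = 0 with kon_long > 0: absorbing state")
        if self.init_positions is not None and len(self.init_positions) != self.n_particles:
            raise ConfigurationError("init_positions must list one (x, y, z) per particle")

    @property
    def omega(self) -> float:
        return self.w_z / self.w_xy

    @property
    def effective_volume(self) -> float:
        """V_eff = pi^{3/2} w_xy^2 w_z (um^3)."""
        return float(np.pi ** 1.5 * self.w_xy**2 * self.w_z)


@dataclass
class SimOutput:
    trace: IntensityTrace
    truth: FCSParams
    occupancy_log: tuple[float, float, float]  # time fractions free/short/long

    def __post_init__(self) -> None:
        if abs(sum(self.occupancy_log) - 1.0) > 1e-9:
            raise ConfigurationError("occupancy fractions must sum to 1")


def _equilibrium(cfg: SimConfig) -> tuple[float, float, float]:
    """Stationary probabilities of the free/short/long chain (detailed balance)."""
    w_free = 1.0
    w_short = cfg.kon_short / cfg.koff_short if cfg.kon_short > 0 else 0.0
    w_long = cfg.kon_long / cfg.koff_long if cfg.kon_long > 0 else 0.0
    total = w_free + w_short + w_long
    return (w_free / total, w_short / total, w_long / total)


def expected_params_from_config(cfg: SimConfig) -> FCSParams:
    """Model parameters implied by a simulation configuration.

    tau_diff = w_xy^2/(4 D); residence times are reciprocal off-rates; the
    f fractions are the equilibrium occupancies of the three-state chain;
    N is the particle concentration times the effective volume.  Note that
    under the literal amplitude convention these f values are occupancies,
    which fitted curves report as :attr:`FitResult.population_fractions`.
    """
    if cfg.d_free <= 0:
        raise ConfigurationError("d_free must be > 0 to define tau_diff")
    f_free, f_short, f_long = _equilibrium(cfg)
    tau_short = 1.0 / cfg.koff_short if cfg.koff_short > 0 else 1e-4
    tau_long = 1.0 / cfg.koff_long if cfg.koff_long > 0 else 1e3
    if tau_short >= tau_long:
        raise ConfigurationError("configuration must satisfy tau_short < tau_long")
    return FCSParams(
        n_molecules=cfg.n_particles * cfg.effective_volume / cfg.box_size**3,
        f_diff=f_free,
        tau_diff=cfg.w_xy**2 / (4.0 * cfg.d_free),
        omega=cfg.omega,
        f_short=f_short,
        tau_short=tau_short,
        f_long=f_long,
        tau_long=tau_long,
    )


def _substep_factor(cfg: SimConfig, dt: float) -> int:
    """Smallest integer split of the sampling interval that resolves the dynamics."""
    max_rate = max(cfg.kon_short + cfg.kon_long, cfg.koff_short, cfg.koff_long)
    k_kin = int(np.ceil(max_rate * dt / 0.1)) if max_rate > 0 else 1
    k_dif = 1
    if cfg.d_free > 0:
        # step std must stay below w_xy/4
        k_dif = int(np.ceil(2.0 * cfg.d_free * dt / (cfg.w_xy / 4.0) ** 2))
    k = max(1, k_kin, k_dif)
    if k > _MAX_SUBSTEPS:
        raise ConfigurationError(
            f"dynamics require {k} sub-steps per bin (cap {_MAX_SUBSTEPS}); "
            "lower the rates/diffusion coefficient or raise rate_hz"
        )
    return k


def _sample_states(
    rng: np.random.Generator, cfg: SimConfig, n_steps: int, dt: float
) -> np.ndarray:
    """Per-step state sequence of one particle (exponential waiting times)."""
    probs = _equilibrium(cfg)
    state = int(rng.choice(3, p=probs))
    kon_total = cfg.kon_short + cfg.kon_long
    if kon_total == 0 and state == _FREE:
        return np.full(n_steps, _FREE, dtype=np.int8)
    states: list[int] = []
    lengths: list[int] = []
    t_edge = 0.0
    filled = 0
    while filled < n_steps:
        if state == _FREE:
            if kon_total == 0:
                t_edge = n_steps * dt
            else:
                t_edge += rng.exponential(1.0 / kon_total)
            next_state = (
                _SHORT if rng.random() < cfg.kon_short / kon_total else _LONG
            ) if kon_total > 0 else _FREE
        elif state == _SHORT:
            t_edge += rng.exponential(1.0 / cfg.koff_short)
            next_state = _FREE
        else:
            t_edge += rng.exponential(1.0 / cfg.koff_long)
            next_state = _FREE
        end = min(n_steps, int(round(t_edge / dt)))
        if end > filled:
            states.append(state)
            lengths.append(end - filled)
            filled = end
        state = next_state
    return np.repeat(np.asarray(states, dtype=np.int8), lengths)


@njit(cache=True)
def _accumulate_particle(
    lam: np.ndarray,
    normals: np.ndarray,
    free: np.ndarray,
    x0: np.ndarray,
    sigma: float,
    box: float,
    inv_wx2: float,
    inv_wy2: float,
    inv_wz2: float,
) -> None:
    """Fused trajectory + observation-profile pass for one particle.

    Positions are advanced sequentially in double precision (free steps only),
    wrapped periodically, and the Gaussian observation weight is accumulated
    into ``lam``.
    """
    half = box / 2.0
    px, py, pz = x0[0], x0[1], x0[2]
    for t in range(lam.size):
        if free[t]:
            px = (px + sigma * normals[t, 0]) % box
            py = (py + sigma * normals[t, 1]) % box
            pz = (pz + sigma * normals[t, 2]) % box
        dx = px - half
        dy = py - half
        dz = pz - half
        lam[t] += np.exp(-2.0 * (dx * dx * inv_wx2 + dy * dy * inv_wy2 + dz * dz * inv_wz2))


def simulate_trace(cfg: SimConfig) -> SimOutput:
    """Simulate one photon-count trace; the seed fully determines the output."""
    dt_bin = 1.0 / cfg.rate_hz
    n_bins = int(round(cfg.duration_s * cfg.rate_hz))
    if n_bins < 1:
        raise ConfigurationError("duration_s * rate_hz must be >= 1 bin")
    k_sub = _substep_factor(cfg, dt_bin)
    n_steps = n_bins * k_sub
    dt = dt_bin / k_sub

    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_particles + 1)
    sigma = float(np.sqrt(2.0 * cfg.d_free * dt))

    lam = np.zeros(n_steps, dtype=np.float64)
    occupancy = np.zeros(3, dtype=np.int64)
    for p in range(cfg.n_particles):
        rng = np.random.default_rng(children[p])
        if cfg.init_positions is not None:
            x0 = np.asarray(cfg.init_positions[p], dtype=float)
        else:
            x0 = rng.uniform(0.0, cfg.box_size, size=3)
        states = _sample_states(rng, cfg, n_steps, dt)
        occupancy += np.bincount(states, minlength=3)
        free = states == _FREE
        if sigma > 0:
            normals = rng.standard_normal((n_steps, 3), dtype=np.float32)
        else:
            normals = np.zeros((1, 3), dtype=np.float32)
            free = np.zeros(n_steps, dtype=bool)  # immobile regardless of state
        _accumulate_particle(
            lam,
            normals,
            free,
            x0,
            sigma,
            cfg.box_size,
            1.0 / cfg.w_xy**2,
            1.0 / cfg.w_xy**2,
            1.0 / cfg.w_z**2,
        )

    lam *= cfg.brightness * dt
    if k_sub > 1:
        lam = lam.reshape(n_bins, k_sub).sum(axis=1)
    counts = np.random.default_rng(children[-1]).poisson(lam)

    occ = occupancy / occupancy.sum()
    occ = tuple(float(v) for v in (occ / occ.sum()))
    truth_cfg = cfg if cfg.d_free > 0 else replace(cfg, d_free=1e-12)
    return SimOutput(
        trace=IntensityTrace(counts=counts, bin_width=dt_bin),
        truth=expected_params_from_config(truth_cfg),
        occupancy_log=occ,
    )
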