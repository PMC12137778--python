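"""Steady-state non-balanced SSFP signals for two-pool magnetization-transfer systems.

Implements an extended-phase-graph (EPG) engine with a coupled macromolecular
bound pool for the two non-balanced SSFP observables:

* SSFP-FID (FISP): the post-pulse free-induction pathway, ``|F_0|`` sampled
  immediately after the RF pulse;
* SSFP-Echo (PSIF): the refocusing pathway, the ``F_{-1}`` configuration
  sampled immediately before the next pulse (after the spoiler it has
  rephased into ``F_0``).

MT contrast is generated *on resonance*: the imaging pulse itself saturates
the bound pool. For a hard (rectangular) pulse of flip angle ``alpha`` and
width ``tau`` the mean RF amplitude is ``omega_1 = alpha / tau`` (rad/s) and
the bound pool is attenuated once per TR by ``exp(-W tau)`` with saturation
rate ``W = pi * omega_1**2 * G(0)``, where ``G(0)`` is the absorption
lineshape of the bound pool evaluated on resonance. Varying either the flip
angle or the pulse width therefore modulates the MT weighting while the free
pool sees matched direct-saturation conditions.

A brute-force isochromat simulator (`isochromat_oracle`) provides an
independent ground truth for the EPG engine: N isochromats uniformly spanning
2*pi of spoiler dephasing per TR, evolved by time-stepped Bloch-McConnell
dynamics.

Units at the public interface: milliseconds for TR and T1/T2 of the free
pool, microseconds for pulse width and bound-pool T2, degrees for flip
angles. Internally radians and seconds are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm

__all__ = [
    "Lineshape",
    "SequenceKind",
    "SweepKind",
    "TissueParams",
    "SequenceProtocol",
    "FieldConditions",
    "EPGState",
    "SteadyStateSignal",
    "SweepCurve",
    "ConvergenceError",
    "epg_rf_rotation",
    "bound_pool_saturation_factor",
    "relax_exchange_interval",
    "ssfp_steady_state",
    "isochromat_oracle",
    "flip_angle_sweep",
    "pulse_width_sweep",
    "predict_mtr",
    "default_flip_angles",
    "default_pulse_widths",
    "DEFAULT_N_STATES",
    "CONVERGENCE_TOL",
    "MAX_ITERATIONS",
    "SUPER_LORENTZIAN_CUTOFF_HZ",
]

# ---------------------------------------------------------------------------
# Solver configuration
# ---------------------------------------------------------------------------

#: Number of retained EPG configuration orders (states k = 0..K).
DEFAULT_N_STATES = 40

#: Relative fixed-point tolerance on both observables.
CONVERGENCE_TOL = 1e-10

#: Iteration cap for the fixed-point steady-state search.
MAX_ITERATIONS = 10_000

#: Offset (Hz) at which the super-Lorentzian lineshape is evaluated in place
#: of its divergent on-resonance value.
SUPER_LORENTZIAN_CUTOFF_HZ = 1_000.0


class ConvergenceError(RuntimeError):
    """Steady-state iteration failed to converge; carries diagnostics."""

    def __init__(self, message: str, n_iterations: int, last_change: float):
        super().__init__(
            f"{message} (iterations={n_iterations}, last relative change={last_change:.3e})"
        )
        self.n_iterations = n_iterations
        self.last_change = last_change


class Lineshape(str, Enum):
    GAUSSIAN = "gaussian"
    SUPER_LORENTZIAN = "super_lorentzian"


class SequenceKind(str, Enum):
    PSIF_ECHO = "psif_echo"
    FID = "fid"


class SweepKind(str, Enum):
    FLIP_ANGLE = "flip_angle"
    PULSE_WIDTH = "pulse_width"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueParams:
    """Two-pool relaxation and exchange description of one material.

    Parameters
    ----------
    t1_free, t2_free : float
        Free-pool relaxation times, ms.
    bound_fraction : float
        Fraction ``f`` of total equilibrium magnetization in the bound pool,
        in [0, 1). ``f = 0`` selects a pure single-pool computation.
    exchange_rate : float
        Fundamental exchange rate ``k`` in 1/s. Forward rate ``k_f = k*f``,
        reverse ``k_b = k*(1-f)`` (detailed balance).
    t1_bound : float
        Bound-pool longitudinal relaxation time, ms.
    t2_bound : float
        Bound-pool transverse relaxation time, microseconds.
    lineshape : Lineshape
        Absorption lineshape of the bound pool.
    proton_density : float
        Equilibrium magnetization scale, arbitrary units.
    """

    t1_free: float
    t2_free: float
    bound_fraction: float = 0.0
    exchange_rate: float = 0.0
    t1_bound: float = 300.0
    t2_bound: float = 10.0
    lineshape: Lineshape = Lineshape.GAUSSIAN
    proton_density: float = 1.0
    label: str = ""

    def __post_init__(self):
        for name in ("t1_free", "t2_free", "t1_bound", "t2_bound"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 <= self.bound_fraction < 1.0:
            raise ValueError(f"bound_fraction must be in [0, 1), got {self.bound_fraction}")
        if self.exchange_rate < 0:
            raise ValueError(f"exchange_rate must be >= 0, got {self.exchange_rate}")
        if self.proton_density < 0:
            raise ValueError(f"proton_density must be >= 0, got {self.proton_density}")
        object.__setattr__(self, "lineshape", Lineshape(self.lineshape))

    @property
    def kf(self) -> float:
        """Forward exchange rate free -> bound, 1/s."""
        return self.exchange_rate * self.bound_fraction

    @property
    def kb(self) -> float:
        """Reverse exchange rate bound -> free, 1/s."""
        return self.exchange_rate * (1.0 - self.bound_fraction)

    @property
    def m0_free(self) -> float:
        return (1.0 - self.bound_fraction) * self.proton_density

    @property
    def m0_bound(self) -> float:
        return self.bound_fraction * self.proton_density


@dataclass(frozen=True)
class SequenceProtocol:
    """Non-balanced SSFP acquisition parameters.

    TR in ms, flip angle in degrees (values above 360 permitted), RF pulse
    width in microseconds. FOV and voxel in mm; the matrix size along each
    axis must come out as a whole number of voxels. Bandwidth is metadata.
    """

    tr: float = 12.03
    flip_angle: float = 60.0
    pulse_width: float = 220.0
    sequence: SequenceKind = SequenceKind.PSIF_ECHO
    fov: tuple[float, float, float] = (180.0, 220.0, 200.0)
    voxel: tuple[float, float, float] = (2.0, 2.0, 5.0)
    bandwidth_khz: float = 18.0
    n_epg_states: int = DEFAULT_N_STATES

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not 0.0 < self.flip_angle <= 420.0:
            raise ValueError(f"flip_angle must be in (0, 420] degrees, got {self.flip_angle}")
        if self.pulse_width <= 0 or self.pulse_width * 1e-3 >= self.tr:
            raise ValueError(
                f"pulse_width must be positive and shorter than TR, got {self.pulse_width} us"
            )
        if self.n_epg_states < 4:
            raise ValueError(f"n_epg_states must be >= 4, got {self.n_epg_states}")
        object.__setattr__(self, "sequence", SequenceKind(self.sequence))
        for ext, vox in zip(self.fov, self.voxel):
            n = ext / vox
            if vox <= 0 or abs(n - round(n)) > 1e-9 or round(n) < 1:
                raise ValueError(
                    f"fov/voxel must be a positive integer per axis, got {ext}/{vox}"
                )

    @property
    def matrix(self) -> tuple[int, int, int]:
        return tuple(int(round(e / v)) for e, v in zip(self.fov, self.voxel))


@dataclass(frozen=True)
class FieldConditions:
    """Transmit/static field conditions. ``b1_scale`` multiplies the nominal flip angle."""

    b1_scale: float = 1.0
    b0_mt: float = 64.0

    def __post_init__(self):
        if self.b1_scale <= 0:
            raise ValueError(f"b1_scale must be > 0, got {self.b1_scale}")


@dataclass
class EPGState:
    """Configuration-state representation of the free pool plus bound-pool Mz.

    ``f_plus[k]`` holds the transverse configuration ``F_k`` for k = 0..K,
    ``f_minus[k]`` holds ``F_{-k}`` (so ``f_minus[0] == f_plus[0]``),
    ``z_free[k]`` the longitudinal configurations ``Z_k`` and ``z_bound`` the
    scalar bound-pool longitudinal magnetization.
    """

    f_plus: np.ndarray
    f_minus: np.ndarray
    z_free: np.ndarray
    z_bound: complex

    @classmethod
    def equilibrium(cls, tissue: TissueParams, n_states: int = DEFAULT_N_STATES) -> "EPGState":
        k = n_states + 1
        z = np.zeros(k, dtype=complex)
        z[0] = tissue.m0_free
        return cls(
            f_plus=np.zeros(k, dtype=complex),
            f_minus=np.zeros(k, dtype=complex),
            z_free=z,
            z_bound=complex(tissue.m0_bound),
        )

    def copy(self) -> "EPGState":
        return EPGState(
            self.f_plus.copy(), self.f_minus.copy(), self.z_free.copy(), self.z_bound
        )

    @property
    def n_states(self) -> int:
        return len(self.f_plus) - 1


@dataclass(frozen=True)
class SteadyStateSignal:
    """Converged steady-state observables (arbitrary units, >= 0)."""

    s_fid: float
    s_echo: float
    converged: bool
    n_iterations: int

    def observable(self, sequence: SequenceKind) -> float:
        return self.s_echo if SequenceKind(sequence) is SequenceKind.PSIF_ECHO else self.s_fid


@dataclass(frozen=True)
class SweepCurve:
    """Signal magnitude versus flip angle or pulse width."""

    x_values: np.ndarray
    signals: np.ndarray
    sweep_kind: SweepKind
    tissue_label: str = ""
    protocol: SequenceProtocol | None = None

    def __post_init__(self):
        x = np.asarray(self.x_values, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if x.shape != s.shape:
            raise ValueError("x_values and signals must have matching length")
        order = np.argsort(x, kind="stable")
        x, s = x[order], s[order]
        if np.any(np.diff(x) <= 0):
            raise ValueError("x_values must be strictly increasing after sorting")
        object.__setattr__(self, "x_values", x)
        object.__setattr__(self, "signals", s)
        object.__setattr__(self, "sweep_kind", SweepKind(self.sweep_kind))


# ---------------------------------------------------------------------------
# Elementary operators
# ---------------------------------------------------------------------------


def epg_rf_rotation(state: EPGState, alpha_eff: float) -> EPGState:
    """Apply an RF pulse of effective flip ``alpha_eff`` (degrees) about a fixed axis.

    Mixes each configuration triple (F_k, conj(F_{-k}), Z_k) by the standard
    unitary RF transition matrix; the bound pool carries no transverse
    magnetization and is untouched by the rotation itself.
    """
    if not np.isfinite(alpha_eff):
        raise ValueError("alpha_eff must be finite")
    a = math.radians(alpha_eff)
    c2 = math.cos(a / 2.0) ** 2
    s2 = math.sin(a / 2.0) ** 2
    s = math.sin(a)
    c = math.cos(a)

    fp = state.f_plus
    fmc = np.conj(state.f_minus)
    z = state.z_free

    new_fp = c2 * fp + s2 * fmc + 1j * s * z
    new_fmc = s2 * fp + c2 * fmc - 1j * s * z
    new_z = 0.5j * s * fp - 0.5j * s * fmc + c * z

    return EPGState(
        f_plus=new_fp,
        f_minus=np.conj(new_fmc),
        z_free=new_z,
        z_bound=state.z_bound,
    )


def _lineshape_g0(tissue: TissueParams) -> float:
    """On-resonance absorption lineshape value G(0) in seconds."""
    t2b_s = tissue.t2_bound * 1e-6
    if t2b_s <= 0:
        raise ValueError("t2_bound must be positive")
    if tissue.lineshape is Lineshape.GAUSSIAN:
        return t2b_s / math.sqrt(2.0 * math.pi)
    return _super_lorentzian(SUPER_LORENTZIAN_CUTOFF_HZ, t2b_s)


def _super_lorentzian(offset_hz: float, t2b_s: float) -> float:
    """Super-Lorentzian absorption lineshape G(offset) in seconds.

    Diverges at zero offset, hence evaluated at a finite cutoff offset when
    used on resonance.
    """
    two_pi_d_t2 = 2.0 * math.pi * offset_hz * t2b_s
    magic = math.acos(1.0 / math.sqrt(3.0))

    def integrand(theta):
        u = abs(3.0 * math.cos(theta) ** 2 - 1.0)
        if u < 1e-12:
            return 0.0
        return math.sin(theta) / u * math.exp(-2.0 * (two_pi_d_t2 / u) ** 2)

    val, _ = quad(integrand, 0.0, math.pi / 2.0, points=[magic], limit=200)
    return math.sqrt(2.0 / math.pi) * t2b_s * val


def bound_pool_saturation_factor(
    flip_angle: float, pulse_width: float, tissue: TissueParams
) -> float:
    """Per-pulse attenuation of the bound pool, in (0, 1].

    A hard pulse of flip ``flip_angle`` (degrees) and width ``pulse_width``
    (microseconds) has mean amplitude ``omega_1 = alpha_rad / tau``; the
    saturation rate is ``W = pi * omega_1**2 * G(0)`` and the factor is
    ``exp(-W * tau)``.
    """
    if pulse_width <= 0:
        raise ValueError("pulse_width must be positive")
    if flip_angle < 0:
        raise ValueError("flip_angle must be >= 0")
    tau_s = pulse_width * 1e-6
    omega1 = math.radians(flip_angle) / tau_s
    w = math.pi * omega1**2 * _lineshape_g0(tissue)
    return math.exp(-w * tau_s)


def _longitudinal_propagator(
    tissue: TissueParams, dt_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact propagator of the coupled (Z_free0, Z_bound) Bloch-McConnell pair.

    Returns (E, c) such that Z(dt) = E @ Z(0) + c.
    """
    dt = dt_ms * 1e-3
    r1f = 1e3 / tissue.t1_free
    r1b = 1e3 / tissue.t1_bound
    kf, kb = tissue.kf, tissue.kb
    a = np.array([[-r1f - kf, kb], [kf, -r1b - kb]])
    b = np.array([tissue.m0_free * r1f, tissue.m0_bound * r1b])
    e = expm(a * dt)
    # steady state of dZ/dt = A Z + b is -A^{-1} b; A is invertible (r1 > 0)
    z_ss = np.linalg.solve(a, -b)
    c = z_ss - e @ z_ss
    return e, c


def relax_exchange_interval(state: EPGState, dt: float, tissue: TissueParams) -> EPGState:
    """Free relaxation, recovery and two-pool exchange over ``dt`` ms.

    The (Z_0, Z_b) pair follows the exact matrix-exponential solution of the
    longitudinal Bloch-McConnell equations with recovery; higher-order Z_k
    decay and lose magnetization to exchange without a recovery source;
    transverse configurations decay with T2 of the free pool.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    e2 = math.exp(-dt / tissue.t2_free)
    e, c = _longitudinal_propagator(tissue, dt)
    ezk = math.exp(-dt * 1e-3 * (1e3 / tissue.t1_free + tissue.kf))

    z = state.z_free * ezk
    z0b = e @ np.array([state.z_free[0], state.z_bound]) + c
    z[0] = z0b[0]
    return EPGState(
        f_plus=state.f_plus * e2,
        f_minus=state.f_minus * e2,
        z_free=z,
        z_bound=z0b[1],
    )


def _spoiler_shift(state: EPGState) -> EPGState:
    """Ideal gradient spoiler: shift transverse orders F_k -> F_{k+1}.

    Longitudinal configurations are unaffected; the highest positive order is
    truncated and the vacated most-negative order set to zero.
    """
    fp = np.empty_like(state.f_plus)
    fm = np.empty_like(state.f_minus)
    fp[1:] = state.f_plus[:-1]
    fp[0] = state.f_minus[1]
    fm[:-1] = state.f_minus[1:]
    fm[-1] = 0.0
    fm[0] = fp[0]
    return EPGState(f_plus=fp, f_minus=fm, z_free=state.z_free, z_bound=state.z_bound)


# ---------------------------------------------------------------------------
# Steady-state solvers
# ---------------------------------------------------------------------------


def ssfp_steady_state(
    protocol: SequenceProtocol,
    tissue: TissueParams,
    field: FieldConditions = FieldConditions(),
    initial_state: EPGState | None = None,
) -> SteadyStateSignal:
    """Converged non-balanced SSFP steady state for one tissue and protocol.

    Each TR applies: bound-pool saturation (over the pulse width tau) and
    instantaneous free-pool RF rotation at the pulse center (effective flip =
    b1_scale x nominal) -> relaxation/exchange over TR -> ideal spoiler
    shift. ``s_fid`` is |F_0| right after the
    pulse (FISP observable); ``s_echo`` is the refocused F_{-1} pathway
    sampled immediately before the next pulse (PSIF observable). The result
    is independent of the initial state.
    """
    alpha_eff = field.b1_scale * protocol.flip_angle
    single_pool = tissue.bound_fraction == 0.0
    sat = 1.0 if single_pool else bound_pool_saturation_factor(
        alpha_eff, protocol.pulse_width, tissue
    )
    # free-pool rotation is instantaneous at the pulse center, so relaxation
    # runs over the full TR; only the bound-pool saturation sees tau
    dt = protocol.tr

    a = math.radians(alpha_eff)
    c2 = math.cos(a / 2.0) ** 2
    s2 = math.sin(a / 2.0) ** 2
    s = math.sin(a)
    c = math.cos(a)
    e2 = math.exp(-dt / tissue.t2_free)
    e_l, c_l = _longitudinal_propagator(tissue, dt)

    state = (
        initial_state.copy()
        if initial_state is not None
        else EPGState.equilibrium(tissue, protocol.n_epg_states)
    )
    fp, fm, z = state.f_plus, state.f_minus, state.z_free
    # Bound-pool longitudinal configuration orders. Exchange with the
    # phase-dependent free-pool Mz populates orders k >= 1 of the bound pool
    # as well; tracking them keeps the two-pool propagation exact per order.
    zb = np.zeros_like(z)
    zb[0] = state.z_bound

    floor = 1e-14 * max(tissue.proton_density, 1e-30)
    prev_fid = prev_echo = math.inf
    change = math.inf
    prev_change = math.inf
    for it in range(1, MAX_ITERATIONS + 1):
        zb = zb * sat
        fmc = np.conj(fm)
        new_fp = c2 * fp + s2 * fmc + 1j * s * z
        new_fmc = s2 * fp + c2 * fmc - 1j * s * z
        z = 0.5j * s * fp - 0.5j * s * fmc + c * z
        fp, fm = new_fp, np.conj(new_fmc)

        s_fid = abs(fp[0])

        # relaxation + exchange; recovery feeds order 0 only
        fp *= e2
        fm *= e2
        z, zb = e_l[0, 0] * z + e_l[0, 1] * zb, e_l[1, 0] * z + e_l[1, 1] * zb
        z[0] += c_l[0]
        zb[0] += c_l[1]

        # spoiler shift of transverse orders
        fp[1:] = fp[:-1]
        fp[0] = fm[1]
        fm[:-1] = fm[1:]
        fm[-1] = 0.0
        fm[0] = fp[0]

        s_echo = abs(fp[0])

        d_fid = abs(s_fid - prev_fid) / max(s_fid, floor)
        d_echo = abs(s_echo - prev_echo) / max(s_echo, floor)
        change = max(d_fid, d_echo)
        # geometric extrapolation of the remaining distance to the fixed
        # point: for a linear contraction with ratio rho the true error is
        # ~ change * rho / (1 - rho), not the last per-iteration change
        if math.isfinite(change) and math.isfinite(prev_change) and prev_change > 0:
            rho = change / prev_change
        else:
            rho = 0.0 if change == 0.0 else math.inf
        err_est = change * rho / (1.0 - rho) if rho < 1.0 else math.inf
        if max(change, err_est) < CONVERGENCE_TOL:
            return SteadyStateSignal(float(s_fid), float(s_echo), True, it)
        prev_fid, prev_echo = s_fid, s_echo
        prev_change = change

    raise ConvergenceError(
        f"EPG steady state did not converge for flip={protocol.flip_angle} deg, "
        f"tau={protocol.pulse_width} us, tissue '{tissue.label or 'unnamed'}'",
        MAX_ITERATIONS,
        change,
    )


def isochromat_oracle(
    protocol: SequenceProtocol,
    tissue: TissueParams,
    field: FieldConditions = FieldConditions(),
    n_isochromats: int = 2000,
    n_substeps: int = 16,
    tol: float = 1e-10,
    max_iterations: int = MAX_ITERATIONS,
) -> SteadyStateSignal:
    """Brute-force isochromat ground truth for `ssfp_steady_state`.

    ``n_isochromats`` spins uniformly span 2*pi of spoiler dephasing per TR
    and evolve by time-stepped Bloch-McConnell dynamics (rotation about the
    spoiler axis, T2 decay and exact longitudinal exchange per substep). The
    FID signal is the mean transverse magnetization just after the pulse, the
    Echo the mean just before the next pulse.
    """
    if n_isochromats < 2:
        raise ValueError("n_isochromats must be >= 2")
    alpha_eff = field.b1_scale * protocol.flip_angle
    single_pool = tissue.bound_fraction == 0.0
    sat = 1.0 if single_pool else bound_pool_saturation_factor(
        alpha_eff, protocol.pulse_width, tissue
    )
    dt = protocol.tr

    a = math.radians(alpha_eff)
    ca, sa = math.cos(a), math.sin(a)

    phi = 2.0 * math.pi * np.arange(n_isochromats) / n_isochromats
    dphi = phi / n_substeps
    cos_d, sin_d = np.cos(dphi), np.sin(dphi)
    e2_sub = math.exp(-dt / n_substeps / tissue.t2_free)
    e_sub, c_sub = _longitudinal_propagator(tissue, dt / n_substeps)

    mx = np.zeros(n_isochromats)
    my = np.zeros(n_isochromats)
    mzf = np.full(n_isochromats, tissue.m0_free)
    zb = np.full(n_isochromats, tissue.m0_bound)

    floor = 1e-14 * max(tissue.proton_density, 1e-30)
    prev_fid = prev_echo = math.inf
    change = math.inf
    prev_change = math.inf
    for it in range(1, max_iterations + 1):
        zb *= sat
        # instantaneous rotation about x
        my, mzf = ca * my + sa * mzf, -sa * my + ca * mzf

        s_fid = abs(np.mean(mx) + 1j * np.mean(my))

        for _ in range(n_substeps):
            mx, my = (
                (cos_d * mx - sin_d * my) * e2_sub,
                (sin_d * mx + cos_d * my) * e2_sub,
            )
            mzf, zb = (
                e_sub[0, 0] * mzf + e_sub[0, 1] * zb + c_sub[0],
                e_sub[1, 0] * mzf + e_sub[1, 1] * zb + c_sub[1],
            )

        s_echo = abs(np.mean(mx) + 1j * np.mean(my))

        d_fid = abs(s_fid - prev_fid) / max(s_fid, floor)
        d_echo = abs(s_echo - prev_echo) / max(s_echo, floor)
        change = max(d_fid, d_echo)
        if math.isfinite(change) and math.isfinite(prev_change) and prev_change > 0:
            rho = change / prev_change
        else:
            rho = 0.0 if change == 0.0 else math.inf
        err_est = change * rho / (1.0 - rho) if rho < 1.0 else math.inf
        if max(change, err_est) < tol:
            return SteadyStateSignal(float(s_fid), float(s_echo), True, it)
        prev_fid, prev_echo = s_fid, s_echo
        prev_change = change

    raise ConvergenceError(
        f"isochromat simulation did not converge for flip={protocol.flip_angle} deg",
        max_iterations,
        change,
    )


# ---------------------------------------------------------------------------
# Sweeps and MTR prediction
# ---------------------------------------------------------------------------


def default_flip_angles() -> np.ndarray:
    """The 43-point flip-angle grid: 1 degree plus 10..420 in steps of 10."""
    return np.concatenate(([1.0], np.arange(10.0, 421.0, 10.0)))


def default_pulse_widths() -> np.ndarray:
    """Pulse-width grid 40..220 us in steps of 20 (10 points)."""
    return np.arange(40.0, 221.0, 20.0)


def flip_angle_sweep(
    angles: Sequence[float] | None,
    protocol: SequenceProtocol,
    tissue: TissueParams,
    field: FieldConditions = FieldConditions(),
) -> SweepCurve:
    """Steady-state signal at each flip angle, other parameters fixed."""
    angles = default_flip_angles() if angles is None else np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("angles must be non-empty")
    signals = np.empty(angles.size)
    for i, alpha in enumerate(angles):
        try:
            sig = ssfp_steady_state(replace(protocol, flip_angle=float(alpha)), tissue, field)
        except ConvergenceError as err:
            raise ConvergenceError(
                f"flip-angle sweep failed at alpha={alpha} deg: {err}",
                err.n_iterations,
                err.last_change,
            ) from err
        signals[i] = sig.observable(protocol.sequence)
    return SweepCurve(angles, signals, SweepKind.FLIP_ANGLE, tissue.label, protocol)


def pulse_width_sweep(
    widths: Sequence[float] | None,
    protocol: SequenceProtocol,
    tissue: TissueParams,
    field: FieldConditions = FieldConditions(),
) -> SweepCurve:
    """Steady-state signal at each RF pulse width, flip angle and TR fixed."""
    widths = default_pulse_widths() if widths is None else np.asarray(widths, dtype=float)
    if widths.size == 0:
        raise ValueError("widths must be non-empty")
    if np.any(widths * 1e-3 >= protocol.tr):
        bad = widths[widths * 1e-3 >= protocol.tr]
        raise ValueError(f"pulse widths must be < TR; offending values (us): {bad.tolist()}")
    signals = np.empty(widths.size)
    for i, tau in enumerate(widths):
        sig = ssfp_steady_state(replace(protocol, pulse_width=float(tau)), tissue, field)
        signals[i] = sig.observable(protocol.sequence)
    return SweepCurve(widths, signals, SweepKind.PULSE_WIDTH, tissue.label, protocol)


def predict_mtr(
    pair: tuple[float, float],
    protocol: SequenceProtocol,
    tissue: TissueParams,
    field: FieldConditions = FieldConditions(),
) -> float:
    """Predicted MTR (percent) for a (low, high) flip-angle pair.

    MTR = (S_low - S_high) / S_low x 100, with both signals computed at
    steady state under the same TR and pulse width.
    """
    low, high = pair
    s_low = ssfp_steady_state(replace(protocol, flip_angle=float(low)), tissue, field)
    s_high = ssfp_steady_state(replace(protocol, flip_angle=float(high)), tissue, field)
    num = s_low.observable(protocol.sequence)
    den = s_high.observable(protocol.sequence)
    if num <= 0:
        raise ValueError(f"signal at low flip angle {low} deg is not positive")
    return (num - den) / num * 100.0
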