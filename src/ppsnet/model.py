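"""Core audio-tactile network: unisensory maps, multisensory unit, dynamics.

The model consists of two unisensory areas — a tactile map covering the
hand surface and an auditory map covering the space on and around the
hand — plus a single multisensory (peripersonal-space) unit.  Unisensory
neurons are leaky first-order rate units with a logistic activation,
hand-centered Gaussian receptive fields, and Mexican-hat (difference of
Gaussians) lateral connectivity.  The unisensory maps project to the
multisensory unit through feedforward synapses ``W_t`` / ``W_a`` and
receive excitatory feedback ``B_t`` / ``B_a`` arranged like the
feedforward sets.  The tactile feedforward weights are uniform at their
saturation value; the auditory feedforward weights fall off with the
distance of the neuron's receptive-field center from the hand, which
confines the auditory receptive field of the multisensory unit to the
space near the hand.

Integration is explicit Euler on ``tau * dz/dt = -z + u`` with
``y = phi(z)``; activities are bounded in (0, 1) by the logistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np


class ConfigurationError(ValueError):
    """Invalid network geometry, dynamics or protocol configuration."""


class DomainError(ValueError):
    """A spatial query outside the model's grids."""


# --------------------------------------------------------------------------
# geometry

@dataclass(frozen=True)
class SpatialGrid2D:
    """Regular 2D lattice of neuron positions, in cm.

    ``x`` grows away from the body along the sound axis, ``y`` across it.
    Nodes sit on lattice points ``0, spacing, ..., extent`` along each axis
    (both endpoints included).
    """

    extent_x: float
    extent_y: float
    spacing: float

    def __post_init__(self) -> None:
        if not (self.extent_x > 0 and self.extent_y > 0 and self.spacing > 0):
            raise ConfigurationError(
                "grid extents and spacing must be positive "
                f"(got extent_x={self.extent_x}, extent_y={self.extent_y}, "
                f"spacing={self.spacing})"
            )
        if self.spacing > min(self.extent_x, self.extent_y):
            raise ConfigurationError("grid spacing exceeds an extent")
        for ext in (self.extent_x, self.extent_y):
            if abs(ext / self.spacing - round(ext / self.spacing)) > 1e-9:
                raise ConfigurationError(
                    f"extent {ext} is not a multiple of spacing {self.spacing}"
                )

    @property
    def n_x(self) -> int:
        return round(self.extent_x / self.spacing) + 1

    @property
    def n_y(self) -> int:
        return round(self.extent_y / self.spacing) + 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_x, self.n_y)

    @cached_property
    def xs(self) -> np.ndarray:
        return np.arange(self.n_x) * self.spacing

    @cached_property
    def ys(self) -> np.ndarray:
        return np.arange(self.n_y) * self.spacing

    @cached_property
    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid ``(X, Y)`` of node coordinates, shape ``(n_x, n_y)``."""
        return np.meshgrid(self.xs, self.ys, indexing="ij")

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.extent_x and 0.0 <= y <= self.extent_y


@dataclass(frozen=True)
class HandRegion:
    """Rectangle of the auditory frame occupied by the hand, in cm."""

    x_interval: tuple[float, float] = (0.0, 20.0)
    y_interval: tuple[float, float] = (0.0, 10.0)

    def distance(self, x, y):
        """Euclidean distance from ``(x, y)`` to the nearest hand point."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        dx = np.maximum(np.maximum(self.x_interval[0] - x, x - self.x_interval[1]), 0.0)
        dy = np.maximum(np.maximum(self.y_interval[0] - y, y - self.y_interval[1]), 0.0)
        return np.hypot(dx, dy)


def distance_from_hand(x: float, y: float, hand: HandRegion,
                       grid: SpatialGrid2D | None = None) -> float:
    """Distance (cm) of an auditory-frame point from the hand region.

    For points level with the hand (``y`` inside the hand's y-interval)
    this reduces to ``max(0, x - x_hand_far_edge)``.
    """
    if grid is not None and not grid.contains(x, y):
        raise DomainError(f"point ({x}, {y}) lies outside the auditory grid")
    return float(hand.distance(x, y))


# --------------------------------------------------------------------------
# lateral connectivity

@dataclass(frozen=True)
class LateralKernelParams:
    """Mexican-hat lateral weights: near excitation, far inhibition."""

    L_ex: float
    sigma_ex: float
    L_in: float
    sigma_in: float

    def __post_init__(self) -> None:
        if self.sigma_ex <= 0 or self.sigma_in <= 0:
            raise ConfigurationError("lateral sigmas must be positive")
        if self.sigma_in <= self.sigma_ex:
            raise ConfigurationError("sigma_in must exceed sigma_ex")
        if self.L_ex <= self.L_in:
            raise ConfigurationError("net weight at d=0 must be excitatory")


def lateral_kernel(d, k: LateralKernelParams):
    """Difference-of-Gaussians lateral weight at inter-neuron distance ``d``."""
    d = np.asarray(d, dtype=float)
    return (k.L_ex * np.exp(-d ** 2 / (2.0 * k.sigma_ex ** 2))
            - k.L_in * np.exp(-d ** 2 / (2.0 * k.sigma_in ** 2)))


class _LateralConv:
    """Mexican-hat lateral input as two separable Gaussian convolutions.

    The difference-of-Gaussians kernel factorizes along the grid axes
    (``d^2 = dx^2 + dy^2``), so the lateral input is computed exactly with
    four small matrix products; the self-connection (``d = 0`` weight,
    ``L_ex - L_in``) is subtracted.  Trailing two axes are the grid;
    leading axes broadcast as batch.
    """

    def __init__(self, grid: SpatialGrid2D, k: LateralKernelParams):
        self._k = k

        def gauss_1d(n: int, sigma: float) -> np.ndarray:
            d = (np.arange(n)[:, None] - np.arange(n)[None, :]) * grid.spacing
            return np.exp(-d ** 2 / (2.0 * sigma ** 2))

        self._Ax_ex = gauss_1d(grid.n_x, k.sigma_ex)
        self._Ay_ex = gauss_1d(grid.n_y, k.sigma_ex)
        self._Ax_in = gauss_1d(grid.n_x, k.sigma_in)
        self._Ay_in = gauss_1d(grid.n_y, k.sigma_in)
        self._w0 = k.L_ex - k.L_in  # self term, excluded

    def __call__(self, y: np.ndarray) -> np.ndarray:
        ex = self._Ax_ex @ (y @ self._Ay_ex)
        inh = self._Ax_in @ (y @ self._Ay_in)
        return self._k.L_ex * ex - self._k.L_in * inh - self._w0 * y


# --------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class AreaParams:
    """Geometry, receptive fields and dynamics of one unisensory map."""

    extent_x: float
    extent_y: float
    spacing: float
    rf_width: float          # Gaussian RF std, cm
    tau: float = 20.0        # membrane time constant, ms
    slope: float = 2.0       # logistic slope (1/input-unit)
    theta: float = 4.5       # logistic center (input units)
    lateral: LateralKernelParams = field(
        default_factory=lambda: LateralKernelParams(0.15, 1.0, 0.02, 3.0))

    def __post_init__(self) -> None:
        if self.rf_width <= 0 or self.tau <= 0 or self.slope <= 0:
            raise ConfigurationError("rf_width, tau and slope must be positive")


@dataclass(frozen=True)
class MSUnitParams:
    tau: float = 20.0
    slope: float = 0.12
    theta: float = 35.0


@dataclass(frozen=True)
class SynapseParams:
    """Feedforward / feedback synapse configuration.

    The basal auditory feedforward profile is a radial plateau that decays
    smoothly with distance from the hand: ``w(d) = s((d0 - d)/width) /
    s(d0/width)`` with ``s`` the logistic, normalized so that neurons whose
    receptive-field centers touch the hand carry exactly ``w_max``.
    """

    w_max: float = 1.0
    profile_d0: float = 54.0     # cm, half-decay distance of basal W_a
    profile_width: float = 4.0   # cm, softness of the decay
    feedback_gain_t: float = 2.0
    feedback_gain_a: float = 2.0

    def __post_init__(self) -> None:
        if self.w_max <= 0:
            raise ConfigurationError("w_max must be positive")
        if self.profile_d0 <= 0 or self.profile_width <= 0:
            raise ConfigurationError("basal auditory profile must be positive")

    def basal_auditory_profile(self, d):
        d = np.asarray(d, dtype=float)
        num = 1.0 / (1.0 + np.exp(-(self.profile_d0 - d) / self.profile_width))
        den = 1.0 / (1.0 + np.exp(-self.profile_d0 / self.profile_width))
        return self.w_max * num / den


@dataclass(frozen=True)
class NetworkParams:
    """Full parameterization of the audio-tactile network."""

    tactile: AreaParams = field(default_factory=lambda: AreaParams(
        extent_x=20.0, extent_y=10.0, spacing=0.5, rf_width=0.5,
        lateral=LateralKernelParams(0.15, 1.0, 0.02, 3.0)))
    auditory: AreaParams = field(default_factory=lambda: AreaParams(
        extent_x=200.0, extent_y=30.0, spacing=2.0, rf_width=6.0,
        lateral=LateralKernelParams(0.20, 3.0, 0.015, 12.0)))
    ms_unit: MSUnitParams = field(default_factory=MSUnitParams)
    synapses: SynapseParams = field(default_factory=SynapseParams)
    hand: HandRegion = field(default_factory=HandRegion)
    dt: float = 0.5              # ms, default Euler step
    steady_tol: float = 1e-5     # max |dy| per ms for steady-state detection

    def __post_init__(self) -> None:
        if self.auditory.rf_width <= self.tactile.rf_width:
            raise ConfigurationError(
                "auditory RF width must exceed tactile RF width "
                "(low auditory spatial resolution)")


# --------------------------------------------------------------------------
# stimuli

@dataclass(frozen=True)
class StimulusSpec:
    """Spatially localized external stimulus in one modality.

    ``intensity_noise`` is the half-width ``a`` of the multiplicative
    uniform noise on the intensity: one draw from ``U(1-a, 1+a)`` per
    presentation.
    """

    modality: str                 # "tactile" | "auditory"
    center: tuple[float, float]   # cm in the modality's grid frame
    spatial_sigma: float = 2.0    # cm
    intensity: float = 10.0       # input units
    intensity_noise: float = 0.0
    onset: float = 0.0            # ms
    duration: float = 400.0       # ms

    def __post_init__(self) -> None:
        if self.modality not in ("tactile", "auditory"):
            raise ConfigurationError(f"unknown modality {self.modality!r}")
        if self.duration <= 0:
            raise ConfigurationError("stimulus duration must be positive")
        if self.intensity < 0:
            raise ConfigurationError("stimulus intensity must be >= 0")
        if not (0.0 <= self.intensity_noise < 1.0):
            raise ConfigurationError("intensity_noise must lie in [0, 1)")


def draw_intensity(stim: StimulusSpec, rng: np.random.Generator | None) -> float:
    """One noisy intensity per presentation; never negative."""
    if stim.intensity_noise == 0.0 or rng is None:
        return stim.intensity
    factor = 1.0 + stim.intensity_noise * rng.uniform(-1.0, 1.0)
    return max(0.0, stim.intensity * factor)


# --------------------------------------------------------------------------
# runtime state

class UnisensoryArea:
    """One unisensory neuron map with its lateral operator and state."""

    def __init__(self, modality: str, params: AreaParams):
        self.modality = modality
        self.params = params
        self.grid = SpatialGrid2D(params.extent_x, params.extent_y, params.spacing)
        self._conv = _LateralConv(self.grid, params.lateral)
        self.z = np.zeros(self.grid.shape)
        self.y = self.phi(self.z)

    def phi(self, z):
        p = self.params
        return 1.0 / (1.0 + np.exp(-p.slope * (z - p.theta)))

    def reset(self) -> None:
        self.z = np.zeros(self.grid.shape)
        self.y = self.phi(self.z)

    def lateral_input(self) -> np.ndarray:
        return self._conv(self.y)

    @property
    def n_neurons(self) -> int:
        return self.grid.n_x * self.grid.n_y


class MultisensoryUnit:
    """The single audio-tactile (peripersonal-space) unit."""

    def __init__(self, params: MSUnitParams):
        self.params = params
        self.z = 0.0
        self.y = self.phi(0.0)

    def phi(self, z: float) -> float:
        p = self.params
        return 1.0 / (1.0 + math.exp(-p.slope * (z - p.theta)))

    def reset(self) -> None:
        self.z = 0.0
        self.y = self.phi(0.0)


@dataclass
class SynapseSet:
    """Feedforward (plastic) and feedback (fixed) synapse arrays."""

    W_t: np.ndarray
    W_a: np.ndarray
    B_t: np.ndarray
    B_a: np.ndarray
    w_max: float

    def copy(self) -> "SynapseSet":
        return SynapseSet(self.W_t.copy(), self.W_a.copy(),
                          self.B_t.copy(), self.B_a.copy(), self.w_max)

    def validate(self) -> None:
        for name in ("W_t", "W_a"):
            W = getattr(self, name)
            if np.any(W < -1e-12) or np.any(W > self.w_max + 1e-12):
                raise ConfigurationError(f"{name} outside [0, w_max]")


class Network:
    """Assembled audio-tactile network (tactile + auditory maps, MS unit)."""

    def __init__(self, params: NetworkParams):
        self.params = params
        self.tactile = UnisensoryArea("tactile", params.tactile)
        self.auditory = UnisensoryArea("auditory", params.auditory)
        self.ms_unit = MultisensoryUnit(params.ms_unit)
        self.hand = params.hand

        sp = params.synapses
        self.synapses = SynapseSet(
            W_t=np.full(self.tactile.grid.shape, sp.w_max),
            W_a=sp.basal_auditory_profile(
                self.hand.distance(*self.auditory.grid.coords)),
            B_t=np.full(self.tactile.grid.shape, sp.feedback_gain_t),
            B_a=sp.feedback_gain_a / sp.w_max * sp.basal_auditory_profile(
                self.hand.distance(*self.auditory.grid.coords)),
            w_max=sp.w_max,
        )
        self.synapses.validate()

    def reset(self) -> None:
        self.tactile.reset()
        self.auditory.reset()
        self.ms_unit.reset()

    def copy(self) -> "Network":
        other = Network(self.params)
        other.synapses = self.synapses.copy()
        return other


def build_network(params: NetworkParams | None = None) -> Network:
    """Build an untrained (basal) network from its parameterization."""
    return Network(params if params is not None else NetworkParams())


# --------------------------------------------------------------------------
# inputs and integration

def unisensory_input(area: UnisensoryArea, stim: StimulusSpec,
                     rng: np.random.Generator | None = None,
                     intensity: float | None = None) -> np.ndarray:
    """Per-neuron external drive for a stimulus filtered by the RFs.

    The stimulus Gaussian (std ``spatial_sigma``) composed with the
    Gaussian receptive fields (std ``rf_width``) gives a net Gaussian
    drive of variance ``rf_width**2 + spatial_sigma**2``: the same
    physical stimulus produces a wider footprint on the auditory map
    because of its larger receptive fields.
    """
    if stim.modality != area.modality:
        raise ConfigurationError(
            f"stimulus modality {stim.modality!r} does not match area "
            f"{area.modality!r}")
    I = draw_intensity(stim, rng) if intensity is None else intensity
    X, Y = area.grid.coords
    var = area.params.rf_width ** 2 + stim.spatial_sigma ** 2
    cx, cy = stim.center
    return I * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2.0 * var))


def step(net: Network, ext_tactile: np.ndarray | float,
         ext_auditory: np.ndarray | float, dt: float) -> None:
    """Advance every neuron one explicit Euler step (synchronous update)."""
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    min_tau = min(net.tactile.params.tau, net.auditory.params.tau,
                  net.ms_unit.params.tau)
    if dt > min_tau / 5.0:
        raise ConfigurationError(
            f"dt={dt} too large for stability (must be <= min(tau)/5 = "
            f"{min_tau / 5.0})")

    y_m = net.ms_unit.y
    u_t = ext_tactile + net.tactile.lateral_input() + net.synapses.B_t * y_m
    u_a = ext_auditory + net.auditory.lateral_input() + net.synapses.B_a * y_m
    u_m = float(np.sum(net.synapses.W_t * net.tactile.y)
                + np.sum(net.synapses.W_a * net.auditory.y))

    net.tactile.z += dt / net.tactile.params.tau * (u_t - net.tactile.z)
    net.auditory.z += dt / net.auditory.params.tau * (u_a - net.auditory.z)
    net.ms_unit.z += dt / net.ms_unit.params.tau * (u_m - net.ms_unit.z)

    net.tactile.y = net.tactile.phi(net.tactile.z)
    net.auditory.y = net.auditory.phi(net.auditory.z)
    net.ms_unit.y = net.ms_unit.phi(net.ms_unit.z)


@dataclass
class SimulationResult:
    """Trajectory summary of one network simulation.

    ``tactile_sum`` / ``auditory_sum`` are the per-step aggregate (summed)
    activities of the two maps; ``ms_activity`` is the multisensory unit's
    activity.  ``converged`` reports whether the steady-state criterion
    (max activity change per ms below tolerance after the last stimulus
    event) was met within the allotted duration.
    """

    times: np.ndarray
    tactile_sum: np.ndarray
    auditory_sum: np.ndarray
    ms_activity: np.ndarray
    final_tactile: np.ndarray
    final_auditory: np.ndarray
    final_ms: float
    converged: bool
    steady_time: float | None
    dt: float


def simulate(net: Network, stimuli: Sequence[StimulusSpec], duration: float,
             dt: float | None = None, rng: np.random.Generator | None = None,
             hebb=None, stop_at_steady: bool = True,
             reset: bool = True) -> SimulationResult:
    """Integrate the network under a set of stimuli.

    Intensities are drawn once per stimulus presentation.  When ``hebb``
    (a :class:`ppsnet.plasticity.HebbParams`) is given, the feedforward
    weights are updated at every step and early stopping is disabled so
    the plastic exposure matches the nominal stimulus timing.
    """
    dt = net.params.dt if dt is None else dt
    if reset:
        net.reset()

    intensities = [draw_intensity(s, rng) for s in stimuli]
    field_cache = [
        unisensory_input(net.tactile if s.modality == "tactile" else net.auditory,
                         s, intensity=I)
        for s, I in zip(stimuli, intensities)
    ]
    events = [0.0]
    for s in stimuli:
        events += [s.onset, s.onset + s.duration]
    last_event = max(e for e in events if e < duration) if events else 0.0

    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    t_sum = np.empty(n_steps + 1)
    a_sum = np.empty(n_steps + 1)
    m_act = np.empty(n_steps + 1)
    t_sum[0] = net.tactile.y.sum()
    a_sum[0] = net.auditory.y.sum()
    m_act[0] = net.ms_unit.y

    tol = net.params.steady_tol * dt  # max |dy| per step
    converged = False
    steady_time = None
    k_end = n_steps

    from . import plasticity as _plasticity  # local import avoids a cycle

    for k in range(1, n_steps + 1):
        t = (k - 1) * dt
        ext_t = np.zeros(net.tactile.grid.shape)
        ext_a = np.zeros(net.auditory.grid.shape)
        for s, f in zip(stimuli, field_cache):
            if s.onset <= t < s.onset + s.duration:
                if s.modality == "tactile":
                    ext_t += f
                else:
                    ext_a += f
        prev_t = net.tactile.y
        prev_a = net.auditory.y
        prev_m = net.ms_unit.y
        step(net, ext_t, ext_a, dt)
        if hebb is not None:
            _plasticity.apply_hebbian_step(net, hebb, dt)
        t_sum[k] = net.tactile.y.sum()
        a_sum[k] = net.auditory.y.sum()
        m_act[k] = net.ms_unit.y

        if t >= last_event:
            dmax = max(np.abs(net.tactile.y - prev_t).max(),
                       np.abs(net.auditory.y - prev_a).max(),
                       abs(net.ms_unit.y - prev_m))
            if dmax < tol:
                converged = True
                steady_time = times[k]
                if stop_at_steady and hebb is None:
                    k_end = k
                    break

    return SimulationResult(
        times=times[:k_end + 1], tactile_sum=t_sum[:k_end + 1],
        auditory_sum=a_sum[:k_end + 1], ms_activity=m_act[:k_end + 1],
        final_tactile=net.tactile.y.copy(), final_auditory=net.auditory.y.copy(),
        final_ms=float(net.ms_unit.y), converged=converged,
        steady_time=steady_time, dt=dt)


@dataclass
class BatchResult:
    """Vectorized repetitions of one stimulus configuration.

    All repetitions share stimulus geometry and timing and differ only in
    their per-presentation intensity draws, so they can be integrated as
    one batch.  ``tactile_sum`` and ``ms_activity`` have shape
    ``(n_rep, n_steps + 1)``.
    """

    times: np.ndarray
    tactile_sum: np.ndarray
    auditory_sum: np.ndarray
    ms_activity: np.ndarray
    final_ms: np.ndarray           # (n_rep,)
    converged: np.ndarray          # (n_rep,) bool
    dt: float


def simulate_batch(net: Network, stimuli: Sequence[StimulusSpec],
                   duration: float, n_rep: int,
                   dt: float | None = None,
                   rng: np.random.Generator | None = None) -> BatchResult:
    """Integrate ``n_rep`` independent repetitions of one trial at once.

    Each repetition starts from rest and draws its own noisy intensity
    per stimulus.  Dynamics are identical to :func:`simulate`; the batch
    stops early once every repetition has reached steady state.
    """
    dt = net.params.dt if dt is None else dt
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    min_tau = min(net.tactile.params.tau, net.auditory.params.tau,
                  net.ms_unit.params.tau)
    if dt > min_tau / 5.0:
        raise ConfigurationError(
            f"dt={dt} too large for stability (must be <= min(tau)/5)")

    intensities = np.empty((len(stimuli), n_rep))
    for i, s in enumerate(stimuli):
        intensities[i] = [draw_intensity(s, rng) for _ in range(n_rep)]
    base_fields = [
        unisensory_input(net.tactile if s.modality == "tactile" else net.auditory,
                         s, intensity=1.0)
        for s in stimuli
    ]

    t_shape = net.tactile.grid.shape
    a_shape = net.auditory.grid.shape
    z_t = np.zeros((n_rep,) + t_shape)
    z_a = np.zeros((n_rep,) + a_shape)
    z_m = np.zeros(n_rep)
    p_t, p_a, p_m = net.tactile.params, net.auditory.params, net.ms_unit.params

    def phi_t(z):
        return 1.0 / (1.0 + np.exp(-p_t.slope * (z - p_t.theta)))

    def phi_a(z):
        return 1.0 / (1.0 + np.exp(-p_a.slope * (z - p_a.theta)))

    def phi_m(z):
        return 1.0 / (1.0 + np.exp(-p_m.slope * (z - p_m.theta)))

    y_t, y_a, y_m = phi_t(z_t), phi_a(z_a), phi_m(z_m)
    W_t, W_a = net.synapses.W_t, net.synapses.W_a
    B_t, B_a = net.synapses.B_t, net.synapses.B_a

    events = [0.0]
    for s in stimuli:
        events += [s.onset, s.onset + s.duration]
    last_event = max(e for e in events if e < duration) if events else 0.0

    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    t_sum = np.empty((n_rep, n_steps + 1))
    a_sum = np.empty((n_rep, n_steps + 1))
    m_act = np.empty((n_rep, n_steps + 1))
    t_sum[:, 0] = y_t.sum(axis=(1, 2))
    a_sum[:, 0] = y_a.sum(axis=(1, 2))
    m_act[:, 0] = y_m

    tol = net.params.steady_tol * dt
    converged = np.zeros(n_rep, dtype=bool)
    k_end = n_steps

    for k in range(1, n_steps + 1):
        t = (k - 1) * dt
        ext_t = np.zeros((n_rep,) + t_shape)
        ext_a = np.zeros((n_rep,) + a_shape)
        for i, s in enumerate(stimuli):
            if s.onset <= t < s.onset + s.duration:
                scaled = intensities[i][:, None, None] * base_fields[i]
                if s.modality == "tactile":
                    ext_t += scaled
                else:
                    ext_a += scaled
        u_t = ext_t + net.tactile._conv(y_t) + B_t * y_m[:, None, None]
        u_a = ext_a + net.auditory._conv(y_a) + B_a * y_m[:, None, None]
        u_m = (W_t * y_t).sum(axis=(1, 2)) + (W_a * y_a).sum(axis=(1, 2))

        z_t += dt / p_t.tau * (u_t - z_t)
        z_a += dt / p_a.tau * (u_a - z_a)
        z_m += dt / p_m.tau * (u_m - z_m)
        new_t, new_a, new_m = phi_t(z_t), phi_a(z_a), phi_m(z_m)

        t_sum[:, k] = new_t.sum(axis=(1, 2))
        a_sum[:, k] = new_a.sum(axis=(1, 2))
        m_act[:, k] = new_m

        if t >= last_event:
            d_t = np.abs(new_t - y_t).max(axis=(1, 2))
            d_a = np.abs(new_a - y_a).max(axis=(1, 2))
            d_m = np.abs(new_m - y_m)
            converged |= np.maximum(np.maximum(d_t, d_a), d_m) < tol
            if converged.all():
                y_t, y_a, y_m = new_t, new_a, new_m
                k_end = k
                break
        y_t, y_a, y_m = new_t, new_a, new_m

    return BatchResult(times=times[:k_end + 1],
                       tactile_sum=t_sum[:, :k_end + 1],
                       auditory_sum=a_sum[:, :k_end + 1],
                       ms_activity=m_act[:, :k_end + 1],
                       final_ms=y_m.copy(), converged=converged, dt=dt)
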