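"""Hebbian plasticity of the feedforward synapses and training protocols.

During stimulus presentation the feedforward weights onto the
multisensory unit change according to a Hebbian rule with a saturation
ceiling and an activity-gated forgetting term:

``dW/dt = gamma_pot * y_pre * y_post * (w_max - W)
        - gamma_forget * W * y_post * (1 - y_pre)``

Correlated pre/post activity potentiates a synapse up to ``w_max``;
post-synaptic activity paired with a silent pre-synaptic neuron slowly
erodes it.  Feedback weights are not plastic.

Tool use is emulated as repeated pairing of a tactile stimulus on the
hand with an auditory stimulus in the far space.  In the synchronous
protocol the two stimuli share onset and duration; in the asynchronous
control they are separated by a random non-null stimulus onset
asynchrony so that overlap is rare and brief, leaving the weights close
to basal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import (ConfigurationError, Network, StimulusSpec, simulate)


class ProtocolError(ValueError):
    """A training protocol used inconsistently with its mode."""


@dataclass(frozen=True)
class HebbParams:
    """Potentiation / forgetting rates (1/ms) and weight ceiling."""

    gamma_pot: float = 2.4e-4
    gamma_forget: float = 1e-6
    w_max: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma_pot < 0 or self.gamma_forget < 0 or self.w_max <= 0:
            raise ConfigurationError("Hebbian rates must be >= 0, w_max > 0")


def hebbian_update(W: np.ndarray, pre: np.ndarray, post: float,
                   p: HebbParams, dt: float) -> np.ndarray:
    """One Euler step of the Hebbian rule; weights stay in [0, w_max]."""
    dW = dt * (p.gamma_pot * pre * post * (p.w_max - W)
               - p.gamma_forget * W * post * (1.0 - pre))
    return np.clip(W + dW, 0.0, p.w_max)


def apply_hebbian_step(net: Network, p: HebbParams, dt: float) -> None:
    """In-place Hebbian step on both feedforward sets of a network."""
    post = net.ms_unit.y
    net.synapses.W_t = hebbian_update(net.synapses.W_t, net.tactile.y, post, p, dt)
    net.synapses.W_a = hebbian_update(net.synapses.W_a, net.auditory.y, post, p, dt)


_DEFAULT_TACTILE = StimulusSpec("tactile", (10.0, 5.0), spatial_sigma=2.0,
                                intensity=10.0, intensity_noise=0.0,
                                onset=0.0, duration=300.0)
_DEFAULT_AUDITORY = StimulusSpec("auditory", (100.0, 5.0), spatial_sigma=2.0,
                                 intensity=10.0, intensity_noise=0.0,
                                 onset=0.0, duration=300.0)


@dataclass(frozen=True)
class TrainingProtocol:
    """Repeated audio-tactile pairing emulating tool-use sensory input.

    ``soa_range`` bounds the magnitude of the random stimulus onset
    asynchrony in the asynchronous mode; the sign is random, so the
    sound can lead or lag the touch, partially overlapping it or missing
    it entirely.
    """

    n_presentations: int = 30
    tactile_stim: StimulusSpec = field(default_factory=lambda: _DEFAULT_TACTILE)
    auditory_stim: StimulusSpec = field(default_factory=lambda: _DEFAULT_AUDITORY)
    soa_mode: str = "synchronous"          # "synchronous" | "asynchronous"
    soa_range: tuple[float, float] = (250.0, 750.0)  # ms, |SOA| bounds
    inter_presentation_gap: float = 1000.0  # ms (activity fully decays)
    settle_margin: float = 100.0            # ms simulated past stimulus offset

    def __post_init__(self) -> None:
        if self.n_presentations < 0:
            raise ConfigurationError("n_presentations must be >= 0")
        if self.soa_mode not in ("synchronous", "asynchronous"):
            raise ConfigurationError(f"unknown soa_mode {self.soa_mode!r}")
        if self.soa_mode == "synchronous":
            if self.tactile_stim.duration != self.auditory_stim.duration:
                raise ConfigurationError(
                    "synchronous pairing requires equal stimulus durations")
        else:
            lo, hi = self.soa_range
            if not (0 < lo < hi):
                raise ConfigurationError("soa_range must satisfy 0 < lo < hi")


def sample_soa(protocol: TrainingProtocol, rng: np.random.Generator) -> float:
    """Signed non-null SOA (ms) for one asynchronous presentation."""
    if protocol.soa_mode != "asynchronous":
        raise ProtocolError("SOA is only sampled in asynchronous mode")
    lo, hi = protocol.soa_range
    magnitude = rng.uniform(lo, hi)
    sign = 1.0 if rng.uniform() < 0.5 else -1.0
    return sign * magnitude


def run_training(net: Network, protocol: TrainingProtocol, p: HebbParams,
                 rng: np.random.Generator | None = None) -> Network:
    """Train a copy of ``net`` and return it; the input network is untouched.

    Each presentation starts from rest (activity decays fully in the
    inter-presentation gap, during which the silent multisensory unit
    drives no plasticity, so the gap itself is not integrated).
    """
    if rng is None:
        rng = np.random.default_rng()
    trained = net.copy()
    for _ in range(protocol.n_presentations):
        if protocol.soa_mode == "synchronous":
            soa = 0.0
        else:
            soa = sample_soa(protocol, rng)
        t_onset = max(0.0, -soa)
        a_onset = max(0.0, soa)
        tact = replace(protocol.tactile_stim, onset=t_onset)
        aud = replace(protocol.auditory_stim, onset=a_onset)
        duration = max(t_onset + tact.duration, a_onset + aud.duration) \
            + protocol.settle_margin
        simulate(trained, [tact, aud], duration=duration, rng=rng, hebb=p,
                 stop_at_steady=False)
    trained.reset()
    return trained
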