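"""Test batteries: auditory RF mapping of the multisensory unit and
network reaction times under audio-tactile stimulation.

The RF mapping presents a unimodal auditory stimulus at increasing
distances from the hand and records the settled multisensory activation.
The reaction-time protocol pairs a tactile stimulus on the hand with a
simultaneous sound at a given distance and measures the time for the
tactile map's aggregate activity to climb to 90% of its settled rise —
the network's analogue of a speeded tactile detection response.  Both
batteries start every presentation from rest and draw a fresh noisy
intensity per repetition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import Network, StimulusSpec, simulate, simulate_batch


class UndefinedRTError(RuntimeError):
    """The tactile map never rose above rest, so no RT is defined."""


DEFAULT_RF_DISTANCES: tuple[float, ...] = tuple(float(d) for d in range(0, 150, 10))
#: 15 sound distances, 140 cm down to 0 cm from the hand, 10-cm steps
DEFAULT_RT_DISTANCES: tuple[float, ...] = tuple(float(d) for d in range(140, -10, -10))

_TEST_TACTILE = StimulusSpec("tactile", (10.0, 5.0), spatial_sigma=2.0,
                             intensity=10.0, intensity_noise=0.1,
                             onset=0.0, duration=400.0)
_TEST_AUDITORY = StimulusSpec("auditory", (100.0, 5.0), spatial_sigma=2.0,
                              intensity=60.0, intensity_noise=0.1,
                              onset=0.0, duration=400.0)

HAND_EDGE_X = 20.0  # cm; sound at hand distance d sits at x = HAND_EDGE_X + d


def _auditory_at_distance(distance: float, template: StimulusSpec) -> StimulusSpec:
    return replace(template, center=(HAND_EDGE_X + distance, template.center[1]))


@dataclass
class RFMapResult:
    """Multisensory activation vs sound distance (repetition level)."""

    distances: np.ndarray          # cm from the hand
    activations: np.ndarray        # shape (n_distances, n_rep)

    @property
    def mean(self) -> np.ndarray:
        return self.activations.mean(axis=1)

    @property
    def sem(self) -> np.ndarray:
        n = self.activations.shape[1]
        if n < 2:
            return np.full(len(self.distances), np.nan)
        return self.activations.std(axis=1, ddof=1) / np.sqrt(n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_cm": self.distances,
                             "mean_activation": self.mean,
                             "sem_activation": self.sem,
                             "n_rep": self.activations.shape[1]})


@dataclass
class RTCurve:
    """Network tactile RTs vs sound distance (repetition level)."""

    distances: np.ndarray          # cm from the hand
    rts: np.ndarray                # ms, shape (n_distances, n_rep)
    censored: np.ndarray           # bool, same shape

    @property
    def mean(self) -> np.ndarray:
        return self.rts.mean(axis=1)

    @property
    def sem(self) -> np.ndarray:
        n = self.rts.shape[1]
        if n < 2:
            return np.full(len(self.distances), np.nan)
        return self.rts.std(axis=1, ddof=1) / np.sqrt(n)

    def to_frame(self) -> pd.DataFrame:
        n_rep = self.rts.shape[1]
        return pd.DataFrame({
            "distance_cm": np.repeat(self.distances, n_rep),
            "repetition": np.tile(np.arange(n_rep), len(self.distances)),
            "rt_ms": self.rts.ravel(),
            "censored": self.censored.ravel(),
        })

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_cm": self.distances,
                             "mean_rt_ms": self.mean,
                             "sem_rt_ms": self.sem,
                             "n_rep": self.rts.shape[1]})


def map_auditory_rf(net: Network,
                    distances: Sequence[float] = DEFAULT_RF_DISTANCES,
                    n_rep: int = 30,
                    rng: np.random.Generator | None = None,
                    auditory_stim: StimulusSpec = _TEST_AUDITORY,
                    duration: float = 400.0) -> RFMapResult:
    """Unimodal-auditory receptive-field map of the multisensory unit."""
    if rng is None:
        rng = np.random.default_rng()
    distances = np.asarray(list(distances), dtype=float)
    acts = np.empty((len(distances), n_rep))
    for i, d in enumerate(distances):
        stim = _auditory_at_distance(d, replace(auditory_stim, duration=duration))
        res = simulate_batch(net, [stim], duration=duration, n_rep=n_rep, rng=rng)
        acts[i] = res.final_ms
    return RFMapResult(distances=distances, activations=acts)


def network_rt(net: Network, sound_distance: float,
               rng: np.random.Generator | None = None,
               tactile_stim: StimulusSpec = _TEST_TACTILE,
               auditory_stim: StimulusSpec = _TEST_AUDITORY,
               duration: float = 400.0,
               rise_fraction: float = 0.9) -> tuple[float, bool]:
    """Simulated tactile RT (ms) with a concurrent sound at ``sound_distance``.

    Returns ``(rt_ms, censored)``; ``censored`` flags a run that did not
    reach steady state within ``duration``.  The RT is the first time the
    tactile aggregate activity covers ``rise_fraction`` of its total rise
    above rest (linear interpolation between integrator steps).
    """
    tact = replace(tactile_stim, duration=duration)
    aud = _auditory_at_distance(sound_distance,
                                replace(auditory_stim, duration=duration))
    res = simulate(net, [tact, aud], duration=duration, rng=rng)
    rt = _rt_from_trace(res.times, res.tactile_sum, rise_fraction)
    return rt, not res.converged


def _rt_from_trace(times: np.ndarray, agg: np.ndarray,
                   rise_fraction: float) -> float:
    rise = agg[-1] - agg[0]
    if rise <= 0.5:  # less than half of one neuron's activity above rest
        raise UndefinedRTError(
            f"tactile activation never rose (rise={rise:g})")
    target = agg[0] + rise_fraction * rise
    idx = int(np.argmax(agg >= target))
    if idx == 0:
        return 0.0
    t0, t1 = times[idx - 1], times[idx]
    a0, a1 = agg[idx - 1], agg[idx]
    return float(t0 + (target - a0) / (a1 - a0) * (t1 - t0))


def rt_vs_distance(net: Network,
                   distances: Sequence[float] = DEFAULT_RT_DISTANCES,
                   n_rep: int = 30,
                   rng: np.random.Generator | None = None,
                   **kwargs) -> RTCurve:
    """Full RT-vs-sound-distance battery (fresh rest state per repetition)."""
    if rng is None:
        rng = np.random.default_rng()
    distances = np.asarray(list(distances), dtype=float)
    rts = np.empty((len(distances), n_rep))
    cens = np.zeros((len(distances), n_rep), dtype=bool)
    duration = kwargs.get("duration", 400.0)
    rise_fraction = kwargs.get("rise_fraction", 0.9)
    tactile_stim = kwargs.get("tactile_stim", _TEST_TACTILE)
    auditory_stim = kwargs.get("auditory_stim", _TEST_AUDITORY)
    tact = replace(tactile_stim, duration=duration)
    for i, d in enumerate(distances):
        aud = _auditory_at_distance(d, replace(auditory_stim, duration=duration))
        res = simulate_batch(net, [tact, aud], duration=duration,
                             n_rep=n_rep, rng=rng)
        for r in range(n_rep):
            rts[i, r] = _rt_from_trace(res.times, res.tactile_sum[r],
                                       rise_fraction)
        cens[i] = ~res.converged
    return RTCurve(distances=distances, rts=rts, censored=cens)


def rf_extent(rf_map: RFMapResult, threshold: float = 0.5) -> float:
    """Largest tested distance whose mean activation reaches
    ``threshold`` times the maximum mean activation."""
    if rf_map.activations.size == 0:
        raise ValueError("empty RF map")
    means = rf_map.mean
    peak = means.max()
    if peak <= 0.0:
        raise ValueError("RF map is all zero; extent undefined")
    above = rf_map.distances[means >= threshold * peak]
    return float(above.max())
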