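"""Geometry, inputs and dynamics of the audio-tactile network."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppsnet import (ConfigurationError, DomainError, HandRegion,
                    LateralKernelParams, NetworkParams, SpatialGrid2D,
                    StimulusSpec, build_network, distance_from_hand,
                    lateral_kernel, simulate, step, unisensory_input)
from ppsnet.model import AreaParams, SynapseParams, simulate_batch
import ppsnet.experiments as ex


# ---------------------------------------------------------------- geometry

@pytest.mark.parametrize("kwargs", [
    dict(extent_x=20.0, extent_y=10.0, spacing=0.0),
    dict(extent_x=-5.0, extent_y=10.0, spacing=0.5),
    dict(extent_x=20.0, extent_y=10.0, spacing=15.0),
    dict(extent_x=20.0, extent_y=10.0, spacing=0.7),
])
def test_invalid_grid_geometry_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        SpatialGrid2D(**kwargs)


def test_default_grid_shapes():
    net = build_network()
    assert net.tactile.grid.shape == (41, 21)
    assert net.auditory.grid.shape == (101, 16)


@pytest.mark.parametrize("point, expected", [
    ((50.0, 5.0), 30.0),
    ((100.0, 5.0), 80.0),
    ((20.0, 5.0), 0.0),
    ((10.0, 5.0), 0.0),
])
def test_distance_from_hand(point, expected):
    hand = HandRegion()
    assert distance_from_hand(*point, hand) == pytest.approx(expected)


def test_distance_from_hand_outside_grid_raises():
    grid = SpatialGrid2D(200.0, 30.0, 2.0)
    with pytest.raises(DomainError):
        distance_from_hand(250.0, 5.0, HandRegion(), grid=grid)


def test_distance_from_hand_diagonal():
    # off the hand corner the distance is Euclidean, not axis-aligned
    assert distance_from_hand(23.0, 14.0, HandRegion()) == pytest.approx(5.0)


# ---------------------------------------------------------------- lateral

def test_lateral_kernel_mexican_hat_shape():
    k = LateralKernelParams(0.20, 3.0, 0.015, 12.0)
    d = np.linspace(0.0, 80.0, 400)
    w = lateral_kernel(d, k)
    assert w[0] > 0                      # near excitation
    assert np.any(w < 0)                 # far inhibition band exists
    assert abs(lateral_kernel(200.0, k)) < 1e-12   # vanishes at infinity
    # closed form at a hand-picked distance
    expect = 0.20 * np.exp(-16.0 / (2 * 9.0)) - 0.015 * np.exp(-16.0 / (2 * 144.0))
    assert lateral_kernel(4.0, k) == pytest.approx(expect, rel=1e-12)


def test_lateral_kernel_invalid_params():
    with pytest.raises(ConfigurationError):
        LateralKernelParams(0.1, 3.0, 0.2, 12.0)   # net inhibitory at d=0
    with pytest.raises(ConfigurationError):
        LateralKernelParams(0.2, 12.0, 0.1, 3.0)   # sigma_in < sigma_ex


# ---------------------------------------------------------------- stimuli

def test_unisensory_input_modality_mismatch(basal_net):
    stim = StimulusSpec("auditory", (50.0, 5.0))
    with pytest.raises(ConfigurationError):
        unisensory_input(basal_net.tactile, stim)


def test_unisensory_input_zero_intensity(basal_net):
    stim = StimulusSpec("tactile", (10.0, 5.0), intensity=0.0)
    assert not unisensory_input(basal_net.tactile, stim).any()


def test_unisensory_input_deterministic_without_noise(basal_net):
    stim = StimulusSpec("auditory", (50.0, 5.0), intensity_noise=0.0)
    rng = np.random.default_rng(0)
    a = unisensory_input(basal_net.auditory, stim, rng)
    b = unisensory_input(basal_net.auditory, stim, rng)
    assert np.array_equal(a, b)


def test_auditory_footprint_wider_than_tactile(basal_net):
    """The same physical stimulus activates a wider patch (in cm^2) of the
    auditory map than of the tactile map, because auditory RFs are larger."""
    areas = {}
    for modality, center in (("tactile", (10.0, 5.0)), ("auditory", (30.0, 5.0))):
        stim = StimulusSpec(modality, center, spatial_sigma=2.0,
                            intensity=10.0, intensity_noise=0.0)
        res = simulate(basal_net, [stim], duration=400.0)
        area_obj = getattr(basal_net, modality)
        final = res.final_tactile if modality == "tactile" else res.final_auditory
        n_active = int((final > 0.5 * final.max()).sum())
        areas[modality] = n_active * area_obj.grid.spacing ** 2
    assert areas["auditory"] > areas["tactile"]


# ---------------------------------------------------------------- dynamics

def test_step_rejects_large_dt(basal_net):
    basal_net.reset()
    with pytest.raises(ConfigurationError):
        step(basal_net, 0.0, 0.0, dt=10.0)


def test_isolated_neuron_settles_to_closed_form(coarse_params):
    """With lateral and feedback couplings off, each neuron settles to
    z = u0 and y = phi(u0) under constant drive."""
    tiny = LateralKernelParams(1e-9, 2.0, 0.0, 6.0)
    params = NetworkParams(
        tactile=replace(coarse_params.tactile, lateral=tiny),
        auditory=replace(coarse_params.auditory,
                         lateral=LateralKernelParams(1e-9, 10.0, 0.0, 30.0)),
        synapses=SynapseParams(feedback_gain_t=0.0, feedback_gain_a=0.0),
    )
    net = build_network(params)
    stim = StimulusSpec("tactile", (10.0, 5.0), intensity=8.0,
                        intensity_noise=0.0, duration=600.0)
    u0 = unisensory_input(net.tactile, stim)
    res = simulate(net, [stim], duration=600.0)
    assert res.converged
    assert np.allclose(net.tactile.z, u0, atol=1e-3)
    assert np.allclose(net.tactile.y, net.tactile.phi(u0), atol=1e-3)


def test_rest_is_a_fixed_point(basal_net):
    """From rest with no input the network stays (essentially) at rest:
    all activities remain at their spontaneous levels."""
    res = simulate(basal_net, [], duration=100.0)
    assert res.converged
    assert np.all(res.final_tactile < 1e-3)
    assert np.all(res.final_auditory < 1e-3)
    assert res.final_ms < 0.05
    assert abs(res.tactile_sum[-1] - res.tactile_sum[0]) < 0.05


def test_steady_state_is_self_consistent(basal_net):
    """At convergence the settled state satisfies z = u(y) for every
    neuron (fixed-point residual of the rate equations)."""
    stim = StimulusSpec("auditory", (50.0, 5.0), intensity=60.0,
                        intensity_noise=0.0, duration=400.0)
    res = simulate(basal_net, [stim], duration=400.0)
    assert res.converged
    net = basal_net
    ext_a = unisensory_input(net.auditory, stim)
    u_t = net.tactile.lateral_input() + net.synapses.B_t * net.ms_unit.y
    u_a = ext_a + net.auditory.lateral_input() + net.synapses.B_a * net.ms_unit.y
    u_m = float((net.synapses.W_t * net.tactile.y).sum()
                + (net.synapses.W_a * net.auditory.y).sum())
    assert np.abs(net.tactile.z - u_t).max() < 1e-2
    assert np.abs(net.auditory.z - u_a).max() < 1e-2
    assert abs(net.ms_unit.z - u_m) / max(1.0, abs(u_m)) < 1e-3


def test_fine_timestep_integrator_agreement(coarse_params):
    """Trajectories at the default step agree with a 10x finer-step
    integration at matched times (Euler convergence oracle)."""
    stim = StimulusSpec("auditory", (100.0, 15.0), intensity=20.0,
                        intensity_noise=0.0, duration=150.0)
    net = build_network(coarse_params)
    res_a = simulate(net, [stim], duration=150.0, dt=0.5,
                     stop_at_steady=False)
    res_b = simulate(net, [stim], duration=150.0, dt=0.05,
                     stop_at_steady=False)
    coarse_ms = res_a.ms_activity
    fine_ms = res_b.ms_activity[::10]
    assert np.abs(coarse_ms - fine_ms).max() < 0.02
    assert np.abs(res_a.auditory_sum - res_b.auditory_sum[::10]).max() < 1.0


def _coarse_params() -> NetworkParams:
    return NetworkParams(
        tactile=AreaParams(extent_x=20.0, extent_y=10.0, spacing=2.0,
                           rf_width=1.0,
                           lateral=LateralKernelParams(0.15, 2.0, 0.02, 6.0)),
        auditory=AreaParams(extent_x=200.0, extent_y=30.0, spacing=10.0,
                            rf_width=6.0,
                            lateral=LateralKernelParams(0.20, 10.0, 0.015, 30.0)),
    )


@settings(max_examples=10, deadline=None, derandomize=True)
@given(amp_t=st.floats(0.0, 50.0), amp_a=st.floats(0.0, 50.0),
       seed=st.integers(0, 2**16))
def test_activities_bounded_for_arbitrary_inputs(amp_t, amp_a, seed):
    """Activities stay in [0, 1] for arbitrary admissible input fields."""
    net = build_network(_coarse_params())
    rng = np.random.default_rng(seed)
    ext_t = amp_t * rng.uniform(-1.0, 1.0, net.tactile.grid.shape)
    ext_a = amp_a * rng.uniform(-1.0, 1.0, net.auditory.grid.shape)
    for _ in range(40):
        step(net, ext_t, ext_a, dt=0.5)
        assert np.all(net.tactile.y >= 0.0) and np.all(net.tactile.y <= 1.0)
        assert np.all(net.auditory.y >= 0.0) and np.all(net.auditory.y <= 1.0)
        assert 0.0 <= net.ms_unit.y <= 1.0


def test_translation_covariance_along_y(basal_net):
    """Shifting an auditory stimulus across the sound axis shifts the
    activation pattern without changing its peak (edge cells excluded)."""
    base = dict(intensity=10.0, intensity_noise=0.0, duration=400.0)
    r1 = simulate(basal_net, [StimulusSpec("auditory", (100.0, 12.0), **base)],
                  duration=400.0)
    r2 = simulate(basal_net, [StimulusSpec("auditory", (100.0, 18.0), **base)],
                  duration=400.0)
    shift = int(round(6.0 / basal_net.auditory.grid.spacing))  # 3 nodes
    a1, a2 = r1.final_auditory, r2.final_auditory
    assert a1.max() == pytest.approx(a2.max(), abs=1e-3)
    # interior columns of the shifted pattern line up with the original
    assert np.allclose(a2[:, 6:15], a1[:, 6 - shift:15 - shift], atol=0.02)


def test_batched_simulation_matches_single(basal_net):
    tact = replace(ex._TEST_TACTILE, intensity_noise=0.0)
    aud = replace(ex._TEST_AUDITORY, intensity_noise=0.0)
    aud = replace(aud, center=(70.0, 5.0))
    res_one = simulate(basal_net, [tact, aud], duration=400.0)
    res_batch = simulate_batch(basal_net, [tact, aud], duration=400.0, n_rep=2)
    n = min(len(res_one.tactile_sum), res_batch.tactile_sum.shape[1])
    assert np.allclose(res_batch.tactile_sum[0, :n],
                       res_one.tactile_sum[:n], atol=1e-8)
    assert np.allclose(res_batch.final_ms, res_one.final_ms, atol=1e-6)


# ---------------------------------------------------------------- weights

def test_basal_weight_patterns():
    net = build_network()
    sp = net.params.synapses
    assert np.allclose(net.synapses.W_t, sp.w_max)        # uniform tactile
    X, Y = net.auditory.grid.coords
    d = net.hand.distance(X, Y)
    on_hand = net.synapses.W_a[d == 0.0]
    assert np.allclose(on_hand, sp.w_max)                 # w_max on the hand
    far = net.synapses.W_a[np.isclose(d, 80.0) & np.isclose(Y, 5.0)]
    assert np.all(far < 0.05 * sp.w_max)                  # decayed far away
    # profile decreases monotonically with distance along the sound axis
    row = net.synapses.W_a[:, 2]
    assert np.all(np.diff(row) <= 1e-12)
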