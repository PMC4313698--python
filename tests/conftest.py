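"""Shared fixtures: default networks, a coarse fast network, and the
session-scoped training/test battery used by the acceptance tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from ppsnet import (HebbParams, NetworkParams, TrainingProtocol,
                    build_network, fit_sigmoid, run_training)
from ppsnet.model import AreaParams, LateralKernelParams
import ppsnet.experiments as ex


@pytest.fixture(scope="session")
def basal_net():
    return build_network()


@pytest.fixture()
def coarse_params() -> NetworkParams:
    """A small, fast network with the same architecture (for dynamics tests)."""
    return NetworkParams(
        tactile=AreaParams(extent_x=20.0, extent_y=10.0, spacing=2.0,
                           rf_width=1.0,
                           lateral=LateralKernelParams(0.15, 2.0, 0.02, 6.0)),
        auditory=AreaParams(extent_x=200.0, extent_y=30.0, spacing=10.0,
                            rf_width=6.0,
                            lateral=LateralKernelParams(0.20, 10.0, 0.015, 30.0)),
    )


@dataclass
class Battery:
    """Basal / synchronously / asynchronously trained networks with their
    RF maps, RT curves and boundary fits (full 15 x 30 protocols)."""

    basal: object
    sync: object
    asyn: object
    rf: dict
    curve: dict
    fit: dict

    def extent(self, key: str) -> float:
        return ex.rf_extent(self.rf[key])


@pytest.fixture(scope="session")
def battery() -> Battery:
    basal = build_network()
    hebb = HebbParams()
    sync = run_training(basal, TrainingProtocol(soa_mode="synchronous"),
                        hebb, rng=np.random.default_rng(2))
    asyn = run_training(basal, TrainingProtocol(soa_mode="asynchronous"),
                        hebb, rng=np.random.default_rng(3))
    rf, curve, fit = {}, {}, {}
    for key, net in (("basal", basal), ("sync", sync), ("async", asyn)):
        rf[key] = ex.map_auditory_rf(net, n_rep=30,
                                     rng=np.random.default_rng(10))
        curve[key] = ex.rt_vs_distance(net, n_rep=30,
                                       rng=np.random.default_rng(11))
        df = curve[key].to_frame()
        fit[key] = fit_sigmoid(df["distance_cm"], df["rt_ms"])
    return Battery(basal=basal, sync=sync, asyn=asyn, rf=rf, curve=curve,
                   fit=fit)
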