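"""Shared fixtures: small simulated FRAP experiments with known ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from frapconn.network import CompartmentNetwork, build_network, default_rois
from frapconn.render import render_series
from frapconn.series_io import FrapSeries, RoiSet
from frapconn.simulate import AcquisitionParams, GroundTruth, simulate_concentrations

SMALL_IMAGE = (160, 160)


@dataclass
class SimExperiment:
    network: CompartmentNetwork
    params: AcquisitionParams
    truth: GroundTruth
    series: FrapSeries
    rois: RoiSet


def simulate_experiment(
    style: str,
    n_compartments: int = 3,
    seed: int = 1,
    noise_model: str = "none",
    n_postbleach: int = 60,
    image_size: tuple[int, int] = SMALL_IMAGE,
    bleach_depth: float = 0.6,
    geometry_params: dict | None = None,
    bleach_target: int = 0,
) -> SimExperiment:
    """One end-to-end simulated FRAP experiment on a small image."""
    network = build_network(
        style,
        n_compartments,
        geometry_params=geometry_params,
        seed=seed,
        image_size=image_size,
        with_neighbor=True,
    )
    params = AcquisitionParams(
        n_postbleach=n_postbleach,
        bleach_depth=bleach_depth,
        image_size=image_size,
        noise_model=noise_model,
        rng_seed=seed,
    )
    truth = simulate_concentrations(network, params, bleach_target=bleach_target)
    series = render_series(network, truth, params)
    rois = default_rois(network, bleach_target=bleach_target)
    return SimExperiment(network, params, truth, series, rois)


@pytest.fixture(scope="session")
def tubular_experiment() -> SimExperiment:
    return simulate_experiment("tubular", n_compartments=4, seed=11, noise_model="poisson")


@pytest.fixture(scope="session")
def fragmented_experiment() -> SimExperiment:
    return simulate_experiment("fragmented", n_compartments=3, seed=12, noise_model="poisson")


@pytest.fixture(scope="session")
def noiseless_two_compartment() -> SimExperiment:
    # pairwise relaxation half-time of 1 s: the classic fitting target
    return simulate_experiment(
        "constricted",
        n_compartments=2,
        seed=13,
        noise_model="none",
        geometry_params={"edge_half_time_s": 1.0},
        n_postbleach=80,
    )
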