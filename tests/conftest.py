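"""Shared fixtures and fast simulation helpers.

The heavy acceptance simulations use a reduced but faithful setting:
only the six grid channels per subject, 100 Hz sampling and ~30 s
sessions, which keeps epoch counts above the connectivity minimum while
making hundreds of simulated studies affordable.
"""

from __future__ import annotations

import numpy as np
import pytest

from dyadsync import interbrain, preprocess, synth
from dyadsync.datatypes import BandSpec, GroupConnectivity, MatchedDyadEpochs, PairGrid

GRID6 = ("C3", "C4", "T7", "T8", "P7", "P8")


def quick_sim_config(
    coupling: dict[tuple[str, str, str], float],
    n_dyads: int = 10,
    duration: float = 32.0,
    sampling_rate: float = 100.0,
    seed: int = 0,
    layout: tuple[str, ...] = GRID6,
    **extra,
) -> synth.SimulationConfig:
    return synth.SimulationConfig(
        n_dyads=n_dyads,
        duration=duration,
        sampling_rate=sampling_rate,
        channel_layout=layout,
        coupling_table=coupling,
        seed=seed,
        **extra,
    )


def dyad_matched_epochs(
    config: synth.SimulationConfig, dyad_index: int, condition: str
) -> MatchedDyadEpochs:
    """simulate -> epoch -> match, skipping filtering/rejection (clean data)."""
    infant, adult = synth.simulate_dyad(config, dyad_index, condition)
    return preprocess.match_epochs(preprocess.epoch(infant), preprocess.epoch(adult))


def dyad_wpli_map(config, dyad_index, condition, grid=None, band=None):
    m = dyad_matched_epochs(config, dyad_index, condition)
    cross = interbrain.epoch_cross_spectra(m, grid or PairGrid(), band or BandSpec())
    return interbrain.wpli(cross)


def simulate_study_group(config: synth.SimulationConfig) -> GroupConnectivity:
    """Full-study wPLI group array over all dyads and conditions."""
    maps = []
    for d in range(config.n_dyads):
        for cond in config.conditions:
            maps.append(dyad_wpli_map(config, d, cond))
    return interbrain.group_connectivity(maps)


def constant_lag_epochs(
    n_epochs: int = 30,
    n_samples: int = 100,
    fs: float = 100.0,
    freqs: tuple[float, ...] = (4.0, 5.0, 6.0, 7.0),
    lag: float = np.pi / 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free epoch pair with a constant phase lag at every component.

    x is a sum of tones at the band frequencies with random phases per
    epoch; y carries the same tones shifted by ``lag`` radians.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    x = np.zeros((n_epochs, n_samples))
    y = np.zeros((n_epochs, n_samples))
    for f in freqs:
        phases = rng.uniform(0, 2 * np.pi, n_epochs)
        x += np.cos(2 * np.pi * f * t[None, :] + phases[:, None])
        y += np.cos(2 * np.pi * f * t[None, :] + phases[:, None] - lag)
    return x, y


def cross_from_pair(x: np.ndarray, y: np.ndarray, fs: float = 100.0, band: BandSpec | None = None):
    """Wrap two single-channel epoch arrays into a 1x1-grid CrossSpectra."""
    band = band or BandSpec()
    S, freqs = interbrain.cross_spectra_from_arrays(x, y, fs, band)
    return interbrain.CrossSpectra(
        values=S[:, None, :],
        freqs=freqs,
        band=band,
        grid=PairGrid(("C4",), ("P8",)),
        dyad_id="fixture",
        condition="fixture",
    )


@pytest.fixture(scope="session")
def default_sim() -> synth.SimulationConfig:
    return quick_sim_config({("BO", "C4", "P8"): 0.8, ("blank", "C4", "P8"): 0.0})
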