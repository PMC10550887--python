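"""Shared fixtures: reference parameter sets and block-raster constructions."""

from __future__ import annotations

import numpy as np
import pytest

from aglif import SpikeRaster, complete_parameters, make_reference_cell


@pytest.fixture(scope="session")
def reference_params():
    """A consistent parameter set with the simple textbook-style constants
    (K = 700 pA, C_m = 100 pF, E_L = -70 mV gives k_2 = 0.1 / ms)."""
    return complete_parameters(
        dict(
            E_L=-70.0, V_r=-60.0, V_th=-50.0, C_m=100.0, tau_m=20.0,
            I_th=140.0, K=700.0, k_1=0.05, I_dep_start=1.0, I_dep0=30.0,
        )
    )


@pytest.fixture(scope="session")
def adapting_cell():
    return make_reference_cell("adapting", seed=1)


def make_train(t_last: float, isi_last: float, n: int = 6, start: float = 20.0) -> np.ndarray:
    """Strictly increasing spike train ending with a prescribed final ISI."""
    earlier = np.linspace(start, t_last - isi_last, n - 1)
    return np.append(earlier, t_last)


@pytest.fixture(scope="session")
def blocking_raster_two_intervals():
    """Interneuron-like raster with two block intervals.

    Anchor times (last spike + half final ISI): 259.95 ms at 200 pA,
    396.10 ms at 400 pA, 277.85 ms at 600 pA and 244.35 ms at 800 pA; the
    train at 400 pA runs to the end of the 400 ms stimulus and 1000 pA is
    silent (depolarization block from the first moment).
    """
    return SpikeRaster(
        trains={
            200.0: make_train(239.95, 40.0),
            400.0: make_train(386.10, 20.0),
            600.0: make_train(257.85, 40.0),
            800.0: make_train(229.35, 30.0),
            1000.0: np.array([]),
        },
        T=400.0,
    )


@pytest.fixture(scope="session")
def blocking_raster_single_interval():
    """Interneuron-like raster with one block interval [400, 600] pA.

    Anchors 220.50 ms at 400 pA and 315.15 ms at 600 pA; the cell is silent
    at 200 pA and fires to the end of the stimulus at 800 and 1000 pA.
    """
    return SpikeRaster(
        trains={
            200.0: np.array([]),
            400.0: make_train(200.50, 40.0),
            600.0: make_train(295.15, 40.0),
            800.0: make_train(380.0, 25.0),
            1000.0: make_train(385.0, 20.0),
        },
        T=400.0,
    )
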