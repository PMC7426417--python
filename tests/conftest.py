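import dataclasses

import numpy as np
import pytest

from synieg.circuit_model import (
    KineticParams,
    get_circuit_preset,
    get_stimulus_preset,
    make_stimulus,
    simulate_circuit,
)
from synieg.movie_synth import CellGeometry, OpticsNoise, render_movie


@pytest.fixture(scope="session")
def params():
    return KineticParams()


@pytest.fixture(scope="session")
def serum_trajectory(params):
    """Default fos-btg2 circuit under 10% serum with a 10-min starvation lead-in."""
    program = dataclasses.replace(
        get_stimulus_preset("serum10"),
        drug_addition_time_min=10.0, duration_min=190.0,
    )
    return simulate_circuit(get_circuit_preset("fos-btg2"), params,
                            make_stimulus(program, params.k_damage))


@pytest.fixture(scope="session")
def geometry():
    return CellGeometry.random(n_sites=8, seed=11)


@pytest.fixture(scope="session")
def serum_movie(serum_trajectory, geometry):
    return render_movie(serum_trajectory, geometry, OpticsNoise(), seed=5)


@pytest.fixture(scope="session")
def noiseless_movie(serum_trajectory, geometry):
    return render_movie(serum_trajectory, geometry, OpticsNoise(), seed=5,
                        noise=False)


def simulate_preset(circuit, stimulus, params=None, **kwargs):
    """Convenience used across test modules."""
    params = params or KineticParams()
    program = (get_stimulus_preset(stimulus)
               if isinstance(stimulus, str) else stimulus)
    signals = make_stimulus(program, params.k_damage)
    spec = (get_circuit_preset(circuit) if isinstance(circuit, str) else circuit)
    return simulate_circuit(spec, params, signals, **kwargs)


def endpoint_fold_percent(traj):
    p = traj.protein
    baseline = 0.5 * (p[0] + p[1])
    return 100.0 * (p[-1] / baseline - 1.0)
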