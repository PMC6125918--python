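import pytest

from hawkdove import (
    GameParams,
    build_strategy_set,
    integrate_to_equilibrium,
    sample_game_params,
    sample_initial_state,
)


@pytest.fixture(scope="session")
def n1_set():
    """The single classic hawk-dove game, V=1, C=2."""
    return build_strategy_set(GameParams(V=[1.0], C=[2.0]))


@pytest.fixture(scope="session")
def n3_params():
    # moderate-asymmetry regime (V below the coverability bound C(N-1)/N),
    # the default conditions of the 8-species experiment batteries
    return sample_game_params(3, v_max=4 / 3, seed=1234)


@pytest.fixture(scope="session")
def n3_set(n3_params):
    return build_strategy_set(n3_params)


@pytest.fixture(scope="session")
def n3_equilibrium(n3_params, n3_set):
    """A converged interior equilibrium of an N=3 community."""
    start = sample_initial_state(3, "uniform_random", seed=99)
    traj = integrate_to_equilibrium(start, n3_set)
    assert traj.converged
    return traj


@pytest.fixture(scope="session")
def n8_params():
    return sample_game_params(8, seed=4321)


@pytest.fixture(scope="session")
def n8_equilibrium(n8_params):
    sset = build_strategy_set(n8_params)
    start = sample_initial_state(8, "uniform_random", seed=7)
    traj = integrate_to_equilibrium(start, sset)
    assert traj.converged
    return traj
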