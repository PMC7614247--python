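import numpy as np
import pytest

import memnet as mn


@pytest.fixture(scope="session")
def bistable2():
    return mn.build_model("bistable2")


@pytest.fixture(scope="session")
def bistable2_fps(bistable2):
    """Fixed points of the two-node switch, ordered [low, saddle, high] by x1."""
    fps = mn.find_fixed_points(bistable2, [(0, 10)] * 2, system="full")
    return sorted(fps, key=lambda fp: fp.location[0])


@pytest.fixture(scope="session")
def bistable2_calc(bistable2):
    return mn.MemoryCalculator(bistable2, bistable2.partition)


@pytest.fixture(scope="session")
def tetrastable():
    return mn.build_model("multistable_or", N=3, a=4, n=2)


@pytest.fixture(scope="session")
def repressilator():
    return mn.build_model("repressilator", a=5, n=3)


@pytest.fixture(scope="session")
def linear_bulk():
    return mn.build_model("linear_bulk_demo")


@pytest.fixture(scope="session")
def neural_tube():
    return mn.build_model("neural_tube4")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
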