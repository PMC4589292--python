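import pytest
from hypothesis import settings

import tileassay as ta

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def counter2():
    """Cooperative 3-bit counter with its arithmetic target oracle."""
    return ta.binary_counter(3, tau=2)


@pytest.fixture(scope="session")
def counter1():
    """The same counter run noncooperatively."""
    return ta.binary_counter(3, tau=1)


@pytest.fixture(scope="session")
def rgb8():
    return ta.rgb_system(8, tau=2)


@pytest.fixture(scope="session")
def rgb8_report(rgb8):
    system, targets = rgb8
    return ta.analyze(system, targets, n_max=targets.max_size)


@pytest.fixture(scope="session")
def counter2_report(counter2):
    system, targets = counter2
    return ta.analyze(system, targets, n_max=6)


@pytest.fixture(scope="session")
def dkca_small():
    """Depth-capped DKCA(0.7, 0.8) tiling on a width-5 seed row."""
    return ta.dkca_tileset(0.7, 0.8, [1, 0, 1, 1, 0], max_depth=3)


def make_line_system(tau=1):
    """Two-tile line: seed A at the origin, B attaches east via glue x,
    then C-chain continues east forever via glue y (bounded by n_max)."""
    tiles = {
        "A": ta.TileType("A", E="x", label="A"),
        "B": ta.TileType("B", W="x", E="y", label="B"),
        "C": ta.TileType("C", W="y", E="y", label="C"),
    }
    glue = ta.GlueFunction({"x": tau, "y": tau})
    return ta.TileSystem(
        tiles=tiles,
        seed={(0, 0): tiles["A"]},
        temperature=tau,
        glue_function=glue,
        name="line system",
    )
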