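import numpy as np
import pytest

import rangedec as rd


def make_system(n: int, adjacency=None) -> rd.AreaSystem:
    """Area system with codes A, B, C, ... and optional adjacency matrix."""
    areas = [rd.Area(chr(65 + i), f"area-{chr(65 + i)}", i) for i in range(n)]
    return rd.AreaSystem(areas, adjacency)


def path_adjacency(n: int) -> np.ndarray:
    adj = np.eye(n, dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj


def tip_table(system: rd.AreaSystem, **ranges: str) -> rd.TipRangeTable:
    """Tip ranges from code strings, e.g. tip_table(sys, a='AB', b='C')."""
    return rd.TipRangeTable(
        system, {k: rd.Range(system.bits_of(v)) for k, v in ranges.items()}
    )


@pytest.fixture(scope="session")
def sys2():
    return make_system(2)


@pytest.fixture(scope="session")
def sys3():
    return make_system(3)


@pytest.fixture(scope="session")
def sys3_path():
    return make_system(3, path_adjacency(3))


@pytest.fixture(scope="session")
def sys4_path():
    return make_system(4, path_adjacency(4))


@pytest.fixture(scope="session")
def liolaemus():
    return rd.load_bundled_area_system()


@pytest.fixture(scope="session")
def cherry():
    """((a:1,b:1):1,(c:1.5,d:1.5):0.5); — 4 tips, height 2."""
    return rd.read_newick("((a:1,b:1):1,(c:1.5,d:1.5):0.5);")
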