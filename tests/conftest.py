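import numpy as np
import pytest

from rotorprobe import simulate as sim


@pytest.fixture(scope="session")
def dihedral1_series():
    """Bistable ring-torsion potential with planar/orthogonal barriers of
    7 and 3 kcal/mol (four minima near +/-51 and +/-129 deg)."""
    return sim.make_bistable_series(7.0, 3.0)


@pytest.fixture(scope="session")
def dihedral23_series():
    """The reversed case: 2.5 kcal/mol at the planar geometry, 5.0 at the
    orthogonal one."""
    return sim.make_bistable_series(2.5, 5.0)


@pytest.fixture(scope="session")
def scan_grid():
    """The nonuniform relaxed-scan grid (denser near the minima), both
    periodic endpoints included."""
    half = [30, 50, 60, 90, 120, 135, 150, 180]
    return np.array(sorted([-a for a in half] + [0] + half), dtype=float)


@pytest.fixture(scope="session")
def membrane_frames():
    """Small ordered bilayer: 72 lipids, no tilt spread, 3.8 nm phosphate
    separation."""
    return sim.gen_membrane_snapshot(72, 0.0, 3.8, 6.0, seed=11)
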