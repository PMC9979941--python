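import numpy as np
import pytest

import tmatsphere as tms


@pytest.fixture(scope="session")
def beam200():
    """200 keV axial beam, the standard operating point."""
    return tms.relativistic_beam(200.0)


def make_linear(beam, N, kd, ka, n_ref, l_max=None):
    geom = tms.generate_linear_array(N, kd, ka, n_ref, beam)
    return tms.build_array(geom, beam, l_max=l_max)


@pytest.fixture(scope="session")
def two_sphere(beam200):
    """Carbon-like two-body fixture: ka = 2, n - 1 = 1e-3, kd = 30."""
    return make_linear(beam200, 2, 30.0, 2.0, 1.001)


@pytest.fixture(scope="session")
def two_sphere_solutions(two_sphere):
    arr = two_sphere
    system = tms.assemble_system(arr)
    return {
        "array": arr,
        "full": tms.solve_full(arr, system),
        "forward": tms.solve_forward(arr, system),
        "kinematic": tms.solve_kinematic(arr, system),
    }


@pytest.fixture(scope="session")
def perpendicular_pair(beam200):
    """Two spheres along x, beam along z: exercises the general-m path."""
    k = beam200.k
    tm = tms.soft_sphere_tmatrix(2.0, 1.001, 6, k=k)
    d = 30.0 / k
    return tms.ScattererArray(
        scatterers=[
            tms.Scatterer(np.array([-d / 2, 0.0, 0.0]), tm),
            tms.Scatterer(np.array([d / 2, 0.0, 0.0]), tm),
        ],
        beam=beam200,
        l_max=6,
    )
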