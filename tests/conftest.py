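import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cutoffmd as md

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def water8():
    """Eight rigid waters on a jittered lattice (24 atoms)."""
    return md.build_water_box(8, 1.24, seed=1)


@pytest.fixture(scope="session")
def water27():
    """27 waters in a box large enough for a 1.4 nm cutoff."""
    return md.build_water_box(27, 2.9, seed=2)


@pytest.fixture(scope="session")
def water50():
    """50 waters, dilute, for scheme-degeneracy checks at 1.4 nm."""
    return md.build_water_box(50, 3.0, seed=3)


@pytest.fixture(scope="session")
def rf61():
    return md.RFParams(eps_rf=61.0, r_rf=1.4)


@pytest.fixture(scope="session")
def rf78():
    return md.RFParams(eps_rf=78.0, r_rf=1.4)


def brute_force_nonbonded(system, scheme, params):
    """Independent O(N^2) double-loop oracle for the nonbonded energies and
    forces: entity classification by minimum-image center distance, atomic
    pair terms, exclusions honored. Pure numpy/python, no kernel code."""
    from cutoffmd.pairlist import make_entities

    ents = make_entities(system, scheme)
    centers = ents.centers(system.positions)
    box = system.box

    def mi(d):
        return d - box * np.rint(d / box)

    excl = {
        (min(i, j), max(i, j)) for i, j in map(tuple, system.exclusion_pairs.tolist())
    }
    e_el = np.zeros(3)
    e_lj = np.zeros(3)
    forces = np.zeros_like(system.positions)
    virial_sum = 0.0
    k1 = params.k1
    rrf = params.r_rf
    for a in range(len(ents)):
        for b in range(a + 1, len(ents)):
            if np.linalg.norm(mi(centers[a] - centers[b])) >= scheme.r_long:
                continue
            for i in ents[a].atoms:
                for j in ents[b].atoms:
                    if i == j or (min(i, j), max(i, j)) in excl:
                        continue
                    rvec = mi(system.positions[i] - system.positions[j])
                    r = np.linalg.norm(rvec)
                    qq = 138.935458 * system.charges[i] * system.charges[j]
                    bucket = system.subsystem[i] + system.subsystem[j]
                    e_el[bucket] += qq * (
                        (1 / r - 1 / rrf) - 0.5 * k1 * (r**2 - rrf**2)
                    )
                    fscal = qq * (1 / r**3 + k1)
                    c6 = system.lj_table.c6[system.lj_type[i], system.lj_type[j]]
                    c12 = system.lj_table.c12[system.lj_type[i], system.lj_type[j]]
                    e_lj[bucket] += c12 / r**12 - c6 / r**6
                    fscal += (12 * c12 / r**12 - 6 * c6 / r**6) / r**2
                    fvec = fscal * rvec
                    forces[i] += fvec
                    forces[j] -= fvec
                    virial_sum += rvec @ fvec
    return e_el, e_lj, forces, -0.5 * virial_sum
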