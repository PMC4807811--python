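import numpy as np
import pytest

import barreldyn as bd


def random_ca_model(
    n: int, seed: int, box: float = 1.6, min_sep: float = 0.3,
    unit_masses: bool = True,
) -> bd.CaModel:
    """Random connected blob of Cα atoms with a minimum separation.

    All pairs fall inside the force field's positive-stiffness range, so
    the all-pairs network is connected with probability one.
    """
    rng = np.random.default_rng(seed)
    coords = []
    while len(coords) < n:
        p = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(p - q) >= min_sep for q in coords):
            coords.append(p)
    return bd.CaModel.from_coords(np.array(coords), unit_masses=unit_masses)


def finite_difference_hessian(network, h: float = 1e-6) -> np.ndarray:
    """Central-difference Hessian of the pair potential (Cartesian)."""
    x0 = network.model.coords.ravel().copy()
    dim = x0.size

    def v(x):
        return bd.potential_energy(network, x)

    hess = np.empty((dim, dim))
    for a in range(dim):
        for b in range(a, dim):
            xa = np.zeros(dim)
            xa[a] = h
            xb = np.zeros(dim)
            xb[b] = h
            val = (v(x0 + xa + xb) - v(x0 + xa - xb)
                   - v(x0 - xa + xb) + v(x0 - xa - xb)) / (4 * h * h)
            hess[a, b] = hess[b, a] = val
    return hess


def mass_weight(hess: np.ndarray, masses: np.ndarray) -> np.ndarray:
    w = 1.0 / np.sqrt(np.repeat(masses, 3))
    return hess * w[:, None] * w[None, :]


@pytest.fixture(scope="session")
def barrel():
    """Default synthetic barrel with modes (shared; treat as read-only)."""
    model, sse = bd.make_barrel(bd.BarrelSpec(seed=7))
    network = bd.build_network(model)
    modes = bd.normal_modes(network)
    return model, sse, network, modes


@pytest.fixture(scope="session")
def small_barrel():
    """~50-residue barrel for oracle comparisons (unit masses)."""
    spec = bd.BarrelSpec(n_repeats=4, strand_length=3, helix_length=4,
                         loop_length=3, seed=3)
    model, sse = bd.make_barrel(spec)
    model = model.with_unit_masses()
    network = bd.build_network(model)
    modes = bd.normal_modes(network)
    return model, sse, network, modes
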