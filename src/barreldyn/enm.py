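"""Cα elastic network model and normal mode analysis.

Each residue is reduced to a point mass at its Cα position.  Pairs of Cα
atoms interact through harmonic springs whose rest length is the pair
distance in the input configuration, with distance-dependent force
constants (Hinsen's Cα force field): a linear branch below the branch
distance ``d`` (covalently linked neighbours along the backbone) and an
inverse-sixth-power decay above it.  Normal modes are eigenvectors of the
mass-weighted Hessian of the total potential; the six zero-frequency
modes are the rigid-body translations and rotations.

Internal units: nanometres, atomic mass units, kJ/mol.  Force constants
are kJ mol^-1 nm^-2, eigenvalues kJ mol^-1 nm^-2 amu^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph

__all__ = [
    "RESIDUE_MASSES",
    "CaModel",
    "ForceFieldParams",
    "ElasticNetwork",
    "ModeSet",
    "pair_force_constant",
    "build_network",
    "hessian",
    "cartesian_hessian",
    "potential_energy",
    "normal_modes",
    "write_modes",
    "read_modes",
]

#: Average residue masses (amino acid minus water), atomic mass units.
RESIDUE_MASSES: dict[str, float] = {
    "ALA": 71.08, "ARG": 156.19, "ASN": 114.10, "ASP": 115.09,
    "CYS": 103.14, "GLN": 128.13, "GLU": 129.12, "GLY": 57.05,
    "HIS": 137.14, "ILE": 113.16, "LEU": 113.16, "LYS": 128.17,
    "MET": 131.19, "PHE": 147.18, "PRO": 97.12, "SER": 87.08,
    "THR": 101.10, "TRP": 186.21, "TYR": 163.18, "VAL": 99.13,
}
_DEFAULT_MASS = 110.0  # unknown residue: average amino-acid residue mass


@dataclass
class CaModel:
    """Cα-only structure: one node per residue.

    atoms   -- list of (chain id, residue number, insertion code, residue name)
    coords  -- (N, 3) positions in nm
    masses  -- (N,) masses in amu
    label   -- free-text identifier
    """

    atoms: list[tuple[str, int, str, str]]
    coords: np.ndarray
    masses: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.atoms)
        if n < 2:
            raise ValueError("CaModel requires at least 2 atoms")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if self.masses.shape != (n,):
            raise ValueError("masses length does not match atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        keys = [(a[0], a[1], a[2]) for a in self.atoms]
        if len(set(keys)) != n:
            raise ValueError("duplicate (chain, residue number, insertion code)")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @classmethod
    def from_coords(
        cls,
        coords: np.ndarray,
        residue_names: list[str] | None = None,
        label: str = "",
        chain: str = "A",
        unit_masses: bool = False,
    ) -> "CaModel":
        """Build a single-chain model with sequential residue numbering."""
        coords = np.asarray(coords, dtype=float)
        n = coords.shape[0]
        if residue_names is None:
            residue_names = ["ALA"] * n
        atoms = [(chain, i + 1, "", residue_names[i]) for i in range(n)]
        if unit_masses:
            masses = np.ones(n)
        else:
            masses = np.array(
                [RESIDUE_MASSES.get(rn, _DEFAULT_MASS) for rn in residue_names]
            )
        return cls(atoms=atoms, coords=coords, masses=masses, label=label)

    def with_unit_masses(self) -> "CaModel":
        return CaModel(self.atoms, self.coords.copy(), np.ones(self.n_atoms),
                       self.label)


@dataclass(frozen=True)
class ForceFieldParams:
    """Cα force-field constants.

    k(r0) = a*r0 - b for r0 < d, and c*r0**-6 for r0 >= d, with r0 in nm.
    """

    a: float = 8.6e5   # kJ mol^-1 nm^-3
    b: float = 2.39e5  # kJ mol^-1 nm^-2
    c: float = 128.0   # kJ mol^-1 nm^4
    d: float = 0.4     # nm
    cutoff: float | None = None  # nm; None = all pairs interact

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0 or self.d <= 0:
            raise ValueError("a, c, d must be positive")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be positive or None")


@dataclass
class ElasticNetwork:
    """Spring network: unordered pairs (i, j, k_ij, r_ij0), i < j."""

    model: CaModel
    pairs: np.ndarray  # structured-free: (M, 4) float array [i, j, k, r0]

    @property
    def n_atoms(self) -> int:
        return self.model.n_atoms


def pair_force_constant(r0, params: ForceFieldParams = ForceFieldParams()):
    """Force constant (kJ mol^-1 nm^-2) for a spring of rest length r0 nm.

    Scalar or array r0.  The linear branch applies strictly below the
    branch distance d; exactly at d the inverse-sixth branch applies.
    Negative linear-branch values are clamped to zero with a warning.
    """
    r0 = np.asarray(r0, dtype=float)
    scalar = r0.ndim == 0
    if np.any(r0 <= 0):
        raise ValueError("pair distance must be positive")
    k = np.where(r0 < params.d, params.a * r0 - params.b, params.c * r0 ** -6)
    if np.any(k < 0):
        warnings.warn(
            "linear-branch force constant negative at short range; clamped to 0",
            stacklevel=2,
        )
        k = np.maximum(k, 0.0)
    return float(k) if scalar else k


def build_network(
    model: CaModel, params: ForceFieldParams = ForceFieldParams()
) -> ElasticNetwork:
    """Connect every Cα pair within the cutoff (all pairs if cutoff is None)."""
    x = model.coords
    n = model.n_atoms
    ii, jj = np.triu_indices(n, k=1)
    r0 = np.linalg.norm(x[ii] - x[jj], axis=1)
    if np.any(r0 == 0):
        bad = np.argmax(r0 == 0)
        raise ValueError(
            f"coincident atoms {int(ii[bad])} and {int(jj[bad])} (zero distance)"
        )
    if params.cutoff is not None:
        keep = r0 <= params.cutoff
        ii, jj, r0 = ii[keep], jj[keep], r0[keep]
    k = pair_force_constant(r0, params)
    pairs = np.column_stack([ii, jj, k, r0])
    return ElasticNetwork(model=model, pairs=pairs)


def potential_energy(network: ElasticNetwork, coords: np.ndarray) -> float:
    """Total spring energy of an arbitrary configuration (kJ/mol)."""
    coords = np.asarray(coords, dtype=float).reshape(network.n_atoms, 3)
    ii = network.pairs[:, 0].astype(int)
    jj = network.pairs[:, 1].astype(int)
    k = network.pairs[:, 2]
    r0 = network.pairs[:, 3]
    r = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    return float(np.sum(0.5 * k * (r - r0) ** 2))


def cartesian_hessian(network: ElasticNetwork) -> np.ndarray:
    """3N x 3N Hessian of the potential at the input configuration (no masses).

    At the rest configuration each spring contributes k * u u^T on the
    bond direction u only; the tangential block vanishes because the
    spring is at its rest length.
    """
    n = network.n_atoms
    x = network.model.coords
    ii = network.pairs[:, 0].astype(int)
    jj = network.pairs[:, 1].astype(int)
    k = network.pairs[:, 2]
    r0 = network.pairs[:, 3]
    u = (x[ii] - x[jj]) / r0[:, None]
    blocks = k[:, None, None] * u[:, :, None] * u[:, None, :]  # (M, 3, 3)

    h4 = np.zeros((n, n, 3, 3))
    np.subtract.at(h4, (ii, jj), blocks)
    np.subtract.at(h4, (jj, ii), blocks)
    np.add.at(h4, (ii, ii), blocks)
    np.add.at(h4, (jj, jj), blocks)
    h = h4.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    return (h + h.T) / 2.0  # exact symmetry


def hessian(network: ElasticNetwork) -> np.ndarray:
    """Mass-weighted Hessian M^-1/2 H M^-1/2 (symmetric, PSD)."""
    h = cartesian_hessian(network)
    w = 1.0 / np.sqrt(np.repeat(network.model.masses, 3))
    return h * w[:, None] * w[None, :]


@dataclass
class ModeSet:
    """Eigendecomposition of the mass-weighted Hessian.

    eigenvalues   -- (3N,) ascending; squared angular frequencies
    eigenvectors  -- (3N, 3N), column m is mode m, orthonormal
    displacements -- (3N, 3N), column m = M^-1/2 v_m renormalised to unit
                     Euclidean length (Cartesian displacement fields)
    n_trivial     -- number of near-zero (rigid-body) modes
    tolerance     -- relative zero threshold used to flag trivial modes
    masses        -- (N,) masses used in the weighting
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    displacements: np.ndarray
    n_trivial: int
    tolerance: float
    masses: np.ndarray
    label: str = ""
    mass_convention: str = "residue"
    displacement_convention: str = "mass-deweighted-unit"
    meta: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    @property
    def nontrivial(self) -> np.ndarray:
        """Indices of the non-trivial modes (ascending eigenvalue)."""
        return np.arange(self.n_trivial, len(self.eigenvalues))


class DisconnectedNetworkError(ValueError):
    def __init__(self, components: list[list[int]]):
        self.components = components
        sizes = [len(c) for c in components]
        super().__init__(
            f"elastic network is disconnected: {len(components)} components "
            f"of sizes {sizes}"
        )


def _components(network: ElasticNetwork) -> list[list[int]]:
    n = network.n_atoms
    ii = network.pairs[:, 0].astype(int)
    jj = network.pairs[:, 1].astype(int)
    k = network.pairs[:, 2]
    live = k > 0
    from scipy.sparse import coo_matrix

    adj = coo_matrix(
        (np.ones(live.sum()), (ii[live], jj[live])), shape=(n, n)
    )
    ncomp, labels = scipy.sparse.csgraph.connected_components(
        adj, directed=False
    )
    return [list(np.flatnonzero(labels == c)) for c in range(ncomp)]


def normal_modes(
    network: ElasticNetwork, zero_tolerance: float = 1e-9
) -> ModeSet:
    """Diagonalise the mass-weighted Hessian into a ModeSet.

    Modes with eigenvalue below ``zero_tolerance * max(eigenvalue)`` are
    flagged trivial.  A connected three-dimensional network must have
    exactly six (rigid translations + rotations; five for the collinear
    degenerate case, where one rotation axis is lost); any other count
    raises (more: disconnected network, fewer: tolerance too tight).
    """
    h = hessian(network)
    evals, evecs = scipy.linalg.eigh(h)
    lam_max = float(evals[-1])
    if lam_max <= 0:
        raise ValueError("network has no positive stiffness")
    thresh = zero_tolerance * lam_max
    if evals[0] < -thresh:
        raise ValueError(
            f"negative eigenvalue {evals[0]:.3e} beyond tolerance; "
            "configuration is not a potential minimum"
        )
    n_trivial = int(np.sum(evals < thresh))
    x = network.model.coords
    rank = np.linalg.matrix_rank(x - x.mean(axis=0), tol=1e-9)
    expected = 5 if rank <= 1 else 6
    if n_trivial > expected:
        comps = _components(network)
        if len(comps) > 1:
            raise DisconnectedNetworkError(comps)
        raise ValueError(
            f"{n_trivial} near-zero modes on a connected network (expected "
            f"{expected}): the configuration supports floppy internal "
            "mechanisms (e.g. exactly planar geometry)"
        )
    if n_trivial < expected:
        raise ValueError(
            f"only {n_trivial} near-zero modes found (expected {expected}); "
            "zero_tolerance too tight for this system"
        )
    w = 1.0 / np.sqrt(np.repeat(network.model.masses, 3))
    disp = evecs * w[:, None]
    disp = disp / np.linalg.norm(disp, axis=0, keepdims=True)
    uniform = np.allclose(network.model.masses, network.model.masses[0])
    return ModeSet(
        eigenvalues=evals,
        eigenvectors=evecs,
        displacements=disp,
        n_trivial=n_trivial,
        tolerance=zero_tolerance,
        masses=network.model.masses.copy(),
        label=network.model.label,
        mass_convention="unit" if uniform and network.model.masses[0] == 1.0
        else "residue",
    )


# ---------------------------------------------------------------------------
# plain-text ModeSet serialization (lossless round trip)

def write_modes(modes: ModeSet, path_or_file) -> None:
    """Write a ModeSet to the documented plain-text block format."""
    own = isinstance(path_or_file, (str, bytes)) or hasattr(path_or_file, "__fspath__")
    fh = open(path_or_file, "w") if own else path_or_file
    try:
        n = modes.n_atoms
        fh.write("# barreldyn ModeSet v1\n")
        fh.write(f"n_atoms\t{n}\n")
        fh.write(f"label\t{modes.label}\n")
        fh.write(f"mass_convention\t{modes.mass_convention}\n")
        fh.write(f"displacement_convention\t{modes.displacement_convention}\n")
        fh.write(f"n_trivial\t{modes.n_trivial}\n")
        fh.write(f"tolerance\t{float(modes.tolerance)!r}\n")
        fh.write("masses\t" + "\t".join(repr(float(m)) for m in modes.masses) + "\n")
        for m in range(3 * n):
            fh.write(f"mode\t{m}\t{float(modes.eigenvalues[m])!r}\n")
            fh.write("\t".join(repr(float(v)) for v in modes.eigenvectors[:, m]) + "\n")
    finally:
        if own:
            fh.close()


def read_modes(path_or_file) -> ModeSet:
    own = isinstance(path_or_file, (str, bytes)) or hasattr(path_or_file, "__fspath__")
    fh = open(path_or_file) if own else path_or_file
    try:
        header = fh.readline()
        if "ModeSet" not in header:
            raise ValueError("not a barreldyn ModeSet file")
        meta = {}
        for _ in range(7):
            key, _, val = fh.readline().rstrip("\n").partition("\t")
            meta[key] = val
        n = int(meta["n_atoms"])
        masses = np.array([float(v) for v in meta["masses"].split("\t")])
        evals = np.empty(3 * n)
        evecs = np.empty((3 * n, 3 * n))
        for m in range(3 * n):
            tag, idx, lam = fh.readline().split("\t")
            if tag != "mode" or int(idx) != m:
                raise ValueError(f"malformed mode block at index {m}")
            evals[m] = float(lam)
            evecs[:, m] = [float(v) for v in fh.readline().split("\t")]
        w = 1.0 / np.sqrt(np.repeat(masses, 3))
        disp = evecs * w[:, None]
        disp = disp / np.linalg.norm(disp, axis=0, keepdims=True)
        return ModeSet(
            eigenvalues=evals,
            eigenvectors=evecs,
            displacements=disp,
            n_trivial=int(meta["n_trivial"]),
            tolerance=float(meta["tolerance"]),
            masses=masses,
            label=meta["label"],
            mass_convention=meta["mass_convention"],
            displacement_convention=meta["displacement_convention"],
        )
    finally:
        if own:
            fh.close()
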