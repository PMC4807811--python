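"""Per-residue flexibility descriptors from a normal-mode decomposition.

Normalised fluctuations (theoretical B-factors), per-residue deformation
energies, the dynamic cross-correlation matrix, and significance-filtered
correlation networks (percentile-rank score threshold combined with a
minimum spatial separation, grouped into connected "objects").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .enm import CaModel, ElasticNetwork, ModeSet

__all__ = [
    "FluctuationProfile",
    "DeformationProfile",
    "CorrelationMatrix",
    "SignificantPairSet",
    "fluctuations",
    "deformation_energies",
    "correlations",
    "significant_pairs",
    "strand_short_range_pairs",
]


@dataclass
class FluctuationProfile:
    values: np.ndarray      # normalised F_i
    raw: np.ndarray         # unnormalised F_i
    normalization: str = "unit-mean"


@dataclass
class DeformationProfile:
    raw: np.ndarray         # D_i, mean deformation energy over non-trivial modes
    normalized: np.ndarray  # min-max scaled to [0, 1]


@dataclass
class CorrelationMatrix:
    values: np.ndarray  # (N, N), symmetric, unit diagonal, in [-1, 1]

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SignificantPairSet:
    """Residue pairs surviving the percentile + distance filters.

    pairs: (i, j, C_ij, distance_nm) with i < j; threshold is the
    nearest-rank percentile value of |C| over all pairs; objects are the
    connected components of the residue-sharing graph of retained pairs.
    """

    pairs: list[tuple[int, int, float, float]]
    percentile: float
    min_distance: float
    threshold: float
    objects: list[set[int]] = field(default_factory=list)
    object_ids: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


def _mode_displacements(modes: ModeSet, use_raw_eigenvectors: bool):
    cols = modes.nontrivial
    if use_raw_eigenvectors:
        return modes.eigenvectors[:, cols], modes.eigenvalues[cols]
    return modes.displacements[:, cols], modes.eigenvalues[cols]


def fluctuations(
    modes: ModeSet,
    normalization: str = "unit-mean",
    use_raw_eigenvectors: bool = False,
) -> FluctuationProfile:
    """Inverse-eigenvalue-weighted mean-square displacement per residue.

    F_i = sum over non-trivial modes of ||[d_m]_i||^2 / lambda_m, then
    normalised: "unit-mean" divides by the profile mean, "unit-sum" by
    the profile sum.
    """
    if modes.n_trivial >= len(modes.eigenvalues):
        raise ValueError("ModeSet has no non-trivial modes")
    d, lam = _mode_displacements(modes, use_raw_eigenvectors)
    n = modes.n_atoms
    per_atom = (d ** 2).reshape(n, 3, -1).sum(axis=1)  # (N, modes)
    raw = per_atom @ (1.0 / lam)
    if normalization == "unit-mean":
        values = raw / raw.mean()
    elif normalization == "unit-sum":
        values = raw / raw.sum()
    elif normalization in (None, "none"):
        values = raw.copy()
        normalization = "none"
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return FluctuationProfile(values=values, raw=raw, normalization=normalization)


def deformation_energy_single(
    network: ElasticNetwork, disp: np.ndarray
) -> np.ndarray:
    """Per-residue deformation energy of one displacement field.

    E_i = (N / sum_j ||d_j||^2) * 1/2 sum_j k_ij ((d_i - d_j).u_ij)^2,
    with u_ij the unit rest-bond vector; zero for any rigid-body field.
    """
    n = network.n_atoms
    d = np.asarray(disp, dtype=float).reshape(n, 3)
    ii = network.pairs[:, 0].astype(int)
    jj = network.pairs[:, 1].astype(int)
    k = network.pairs[:, 2]
    r0 = network.pairs[:, 3]
    x = network.model.coords
    u = (x[ii] - x[jj]) / r0[:, None]
    proj = np.einsum("pk,pk->p", d[ii] - d[jj], u)
    contrib = 0.5 * k * proj ** 2
    e = np.zeros(n)
    np.add.at(e, ii, contrib)
    np.add.at(e, jj, contrib)
    norm = float(np.sum(d ** 2))
    if norm == 0:
        raise ValueError("zero displacement field")
    return e * (n / norm)


def deformation_energies(
    modes: ModeSet, network: ElasticNetwork
) -> DeformationProfile:
    """Mean per-residue deformation energy over all non-trivial modes.

    The raw profile D_i averages the single-mode energies; the
    normalised copy is min-max scaled to [0, 1] for display.
    """
    if modes.n_atoms != network.n_atoms:
        raise ValueError("ModeSet and network sizes differ")
    d, _ = _mode_displacements(modes, use_raw_eigenvectors=False)
    n_modes = d.shape[1]
    acc = np.zeros(network.n_atoms)
    for m in range(n_modes):
        acc += deformation_energy_single(network, d[:, m])
    raw = acc / n_modes
    span = raw.max() - raw.min()
    normalized = (raw - raw.min()) / span if span > 0 else np.zeros_like(raw)
    return DeformationProfile(raw=raw, normalized=normalized)


def correlations(modes: ModeSet) -> CorrelationMatrix:
    """Dynamic cross-correlation map from the non-trivial modes.

    C_ij is the expected inner product of the displacements of atoms i
    and j under the mode covariance sum_m lambda_m^-1 v_m v_m^T,
    normalised so C_ii = 1 (values in [-1, 1] by Cauchy-Schwarz).
    """
    if modes.n_trivial >= len(modes.eigenvalues):
        raise ValueError("ModeSet has no non-trivial modes")
    cols = modes.nontrivial
    v = modes.eigenvectors[:, cols]
    lam = modes.eigenvalues[cols]
    n = modes.n_atoms
    vw = v / np.sqrt(lam)[None, :]          # (3N, M)
    vw3 = vw.reshape(n, 3, -1)
    cov = np.einsum("iam,jam->ij", vw3, vw3)  # block traces of covariance
    diag = np.sqrt(np.diag(cov))
    c = cov / diag[:, None] / diag[None, :]
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(values=c)


def _nearest_rank_threshold(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile (no interpolation) of a 1-D multiset."""
    v = np.sort(values)
    m = len(v)
    rank = max(1, math.ceil(percentile / 100.0 * m))
    return float(v[rank - 1])


def significant_pairs(
    corr: CorrelationMatrix,
    model: CaModel,
    percentile: float = 95.0,
    min_distance: float = 0.8,
) -> SignificantPairSet:
    """Filter residue pairs by correlation rank and spatial separation.

    The score threshold is the nearest-rank ``percentile`` of |C_ij| over
    all i<j pairs; retained pairs satisfy |C_ij| >= threshold AND
    Cα-Cα distance >= min_distance (nm, input configuration).  Ties at
    either threshold are retained.  Retained pairs are grouped into
    connected objects over shared residues.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    if min_distance < 0:
        raise ValueError("min_distance must be non-negative")
    n = corr.n
    if model.n_atoms != n:
        raise ValueError("model size does not match correlation matrix")
    iu, ju = np.triu_indices(n, k=1)
    absC = np.abs(corr.values[iu, ju])
    threshold = _nearest_rank_threshold(absC, percentile)
    dist = np.linalg.norm(model.coords[iu] - model.coords[ju], axis=1)
    keep = (absC >= threshold) & (dist >= min_distance)
    pairs = [
        (int(i), int(j), float(corr.values[i, j]), float(dd))
        for i, j, dd in zip(iu[keep], ju[keep], dist[keep])
    ]
    g = nx.Graph()
    g.add_edges_from((p[0], p[1]) for p in pairs)
    objects = [set(c) for c in nx.connected_components(g)]
    objects.sort(key=min)
    obj_of = {res: oid for oid, comp in enumerate(objects) for res in comp}
    object_ids = [obj_of[p[0]] for p in pairs]
    return SignificantPairSet(
        pairs=pairs,
        percentile=percentile,
        min_distance=min_distance,
        threshold=threshold,
        objects=objects,
        object_ids=object_ids,
    )


def strand_short_range_pairs(
    corr: CorrelationMatrix,
    model: CaModel,
    sse,
    percentile: float = 97.5,
    min_distance: float = 0.4,
) -> SignificantPairSet:
    """Short-range strand-anchored variant of the significance filter.

    Uses a tighter score threshold (97.5th percentile) and a reduced
    separation floor (0.4 nm, the Cα spacing of adjacent strands), then
    keeps only pairs with at least one residue on a β-strand.
    """
    strand_idx: set[int] = set()
    for el in sse.elements:
        if el.kind == "strand":
            strand_idx.update(int(i) for i in el.indices)
    if not strand_idx:
        raise ValueError("SSE annotation contains no strands")
    full = significant_pairs(corr, model, percentile, min_distance)
    pairs = [p for p in full.pairs if p[0] in strand_idx or p[1] in strand_idx]
    g = nx.Graph()
    g.add_edges_from((p[0], p[1]) for p in pairs)
    objects = [set(c) for c in nx.connected_components(g)]
    objects.sort(key=min)
    obj_of = {res: oid for oid, comp in enumerate(objects) for res in comp}
    object_ids = [obj_of[p[0]] for p in pairs]
    return SignificantPairSet(
        pairs=pairs,
        percentile=percentile,
        min_distance=min_distance,
        threshold=full.threshold,
        objects=objects,
        object_ids=object_ids,
    )
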