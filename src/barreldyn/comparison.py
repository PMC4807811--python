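"""Alignment-aware comparison of intrinsic dynamics.

Conserved (gap-free) columns of a multiple structure alignment define
the comparable Cα positions of a protein family.  Each structure's
low-frequency mode covariance, restricted to those positions and
trace-normalised, is compared pairwise through the Bhattacharyya
coefficient (BC): 1 for identical effective dynamics, approaching 0 for
disjoint ones.  Rank reduction happens twice: per structure, keeping
the lowest-frequency modes carrying a set fraction of the covariance
trace (default 95%), and jointly, projecting both covariances onto the
leading eigenvectors of their average (default 75% of its variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from Bio import AlignIO

from .enm import ModeSet

__all__ = [
    "AlignmentMap",
    "BCConfig",
    "BCResult",
    "read_alignment",
    "alignment_map_from_strings",
    "sequence_identity",
    "aligned_covariance",
    "bc_score",
    "bc_matrix",
    "cluster_bc",
    "dendrogram_newick",
]

GAP_CHARS = frozenset("-.")


@dataclass
class AlignmentMap:
    """Columns of a multiple alignment mapped to per-structure residues.

    sequences -- list of (label, aligned string), equal lengths
    columns   -- (L, S) int array of 0-based residue indices, -1 for gap
    conserved -- 0-based indices of gap-free columns
    """

    sequences: list[tuple[str, str]]
    columns: np.ndarray
    conserved: np.ndarray

    @property
    def labels(self) -> list[str]:
        return [s[0] for s in self.sequences]

    @property
    def length(self) -> int:
        return self.columns.shape[0]

    def conserved_indices(self, label: str) -> np.ndarray:
        """Residue indices of one structure at the conserved columns."""
        s = self.labels.index(label)
        return self.columns[self.conserved, s]

    def subset(self, labels: list[str]) -> "AlignmentMap":
        """Sub-alignment over the given structures, conserved columns
        recomputed (never reuse the superset's gap-free set)."""
        keep = [self.labels.index(lb) for lb in labels]
        return alignment_map_from_strings(
            [(self.sequences[s][0], self.sequences[s][1]) for s in keep]
        )


def alignment_map_from_strings(
    records: list[tuple[str, str]]
) -> AlignmentMap:
    if len(records) < 2:
        raise ValueError("alignment needs at least 2 records")
    labels = [r[0] for r in records]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate record labels in alignment")
    lengths = {len(r[1]) for r in records}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    length = lengths.pop()
    cols = np.full((length, len(records)), -1, dtype=int)
    for s, (_, seq) in enumerate(records):
        idx = -1
        for c, ch in enumerate(seq):
            if ch not in GAP_CHARS:
                idx += 1
                cols[c, s] = idx
    conserved = np.flatnonzero((cols >= 0).all(axis=1))
    return AlignmentMap(sequences=list(records), columns=cols,
                        conserved=conserved)


def read_alignment(path) -> AlignmentMap:
    """Read a FASTA multiple alignment ('-' or '.' gaps)."""
    aln = AlignIO.read(path, "fasta")
    return alignment_map_from_strings([(r.id, str(r.seq)) for r in aln])


def sequence_identity(a: str, b: str) -> float:
    """Percent identity over the full alignment length, gaps included.

    100 * I / L where I counts columns with identical non-gap characters
    and L is the alignment length including gap columns.
    """
    if len(a) != len(b):
        raise ValueError("aligned strings differ in length")
    if not a:
        raise ValueError("empty alignment")
    ident = sum(
        1 for x, y in zip(a, b)
        if x == y and x not in GAP_CHARS
    )
    return 100.0 * ident / len(a)


@dataclass(frozen=True)
class BCConfig:
    mode_variance: float = 0.95   # per-structure covariance trace retained
    joint_variance: float = 0.75  # variance of (A+B)/2 retained

    def __post_init__(self) -> None:
        for v in (self.mode_variance, self.joint_variance):
            if not 0 < v <= 1:
                raise ValueError("variance fractions must be in (0, 1]")


@dataclass
class BCResult:
    labels: list[str]
    matrix: np.ndarray
    ranks: dict = field(default_factory=dict)  # (label_a, label_b) -> (n, m, s)


def _n_modes_for_variance(lam: np.ndarray, fraction: float) -> int:
    """Smallest count of lowest-frequency modes whose cumulative 1/lambda
    reaches the fraction of the total (ties toward fewer modes)."""
    inv = 1.0 / lam
    cum = np.cumsum(inv)
    total = cum[-1]
    return int(np.searchsorted(cum, fraction * total - 1e-12 * total) + 1)


def aligned_covariance(
    modes: ModeSet,
    aligned_atoms: np.ndarray,
    mode_variance: float = 0.95,
) -> tuple[np.ndarray, int]:
    """Trace-normalised mode covariance on the aligned coordinates.

    Sum over the n lowest-frequency non-trivial modes of
    lambda^-1 v v^T, restricted to the 3*|aligned| coordinates of
    ``aligned_atoms``, then divided by its trace.  Returns (cov, n).
    """
    sel = np.asarray(aligned_atoms, dtype=int)
    if sel.size == 0:
        raise ValueError("empty aligned-atom selection")
    if sel.min() < 0 or sel.max() >= modes.n_atoms:
        raise ValueError("aligned atom index out of range")
    cols = modes.nontrivial
    lam = modes.eigenvalues[cols]
    n = _n_modes_for_variance(lam, mode_variance)
    coord_idx = (3 * sel[:, None] + np.arange(3)[None, :]).ravel()
    v = modes.eigenvectors[np.ix_(coord_idx, cols[:n])]
    cov = (v / lam[:n]) @ v.T
    tr = np.trace(cov)
    if tr <= 0:
        raise ValueError("covariance has non-positive trace")
    return cov / tr, n


def bc_score(
    covA: np.ndarray, covB: np.ndarray, joint_variance: float = 0.75
) -> tuple[float, int]:
    """Bhattacharyya coefficient of two trace-normalised covariances.

    Both are projected onto the s leading eigenvectors of (A+B)/2 that
    capture ``joint_variance`` of its variance; the coefficient is then
    exp(-1/2 [ ln|.5(Ã+B̃)| - .5(ln|Ã| + ln|B̃|) ]), evaluated through
    eigenvalue log-determinants.  Returns (BC, s).
    """
    if covA.shape != covB.shape:
        raise ValueError("covariance dimensions differ")
    mean = 0.5 * (covA + covB)
    w, u = np.linalg.eigh(mean)
    w = w[::-1]
    u = u[:, ::-1]
    cum = np.cumsum(w)
    s = int(np.searchsorted(cum, joint_variance * cum[-1] - 1e-12 * cum[-1]) + 1)
    p = u[:, :s]
    at = p.T @ covA @ p
    bt = p.T @ covB @ p
    mt = 0.5 * (at + bt)

    def logdet(x: np.ndarray) -> float:
        ev = np.linalg.eigvalsh(x)
        ev = np.clip(ev, 1e-300, None)  # tiny negatives are numerical zero
        return float(np.sum(np.log(ev)))

    val = float(np.exp(-0.5 * (logdet(mt) - 0.5 * (logdet(at) + logdet(bt)))))
    return min(val, 1.0), s


def bc_matrix(
    modesets: dict[str, ModeSet],
    alignment: AlignmentMap,
    config: BCConfig = BCConfig(),
) -> BCResult:
    """Pairwise BC over the alignment's conserved-column atoms."""
    labels = alignment.labels
    missing = [lb for lb in labels if lb not in modesets]
    if missing:
        raise KeyError(f"no ModeSet for alignment records: {missing}")
    if len(alignment.conserved) == 0:
        raise ValueError("alignment has no gap-free (conserved) columns")
    covs: dict[str, np.ndarray] = {}
    nmodes: dict[str, int] = {}
    for lb in labels:
        atoms = alignment.conserved_indices(lb)
        ms = modesets[lb]
        if atoms.max() >= ms.n_atoms:
            raise ValueError(
                f"alignment row {lb!r} implies more residues than its ModeSet"
            )
        covs[lb], nmodes[lb] = aligned_covariance(
            ms, atoms, config.mode_variance
        )
    k = len(labels)
    mat = np.eye(k)
    ranks: dict = {}
    for i in range(k):
        for j in range(i + 1, k):
            bc, s = bc_score(covs[labels[i]], covs[labels[j]],
                             config.joint_variance)
            mat[i, j] = mat[j, i] = bc
            ranks[(labels[i], labels[j])] = (
                nmodes[labels[i]], nmodes[labels[j]], s
            )
    return BCResult(labels=list(labels), matrix=mat, ranks=ranks)


def cluster_bc(result: BCResult, method: str = "average") -> np.ndarray:
    """Agglomerative clustering on dissimilarity 1 - BC.

    Returns a scipy linkage matrix; label order gives deterministic
    tie-breaking (pairs are enumerated in input order).
    """
    if len(result.labels) < 2:
        raise ValueError("clustering needs at least 2 items")
    d = 1.0 - result.matrix
    np.fill_diagonal(d, 0.0)
    condensed = ssd.squareform(np.maximum(d, 0.0), checks=False)
    return sch.linkage(condensed, method=method)


def dendrogram_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Newick string for a hierarchical clustering (branch lengths from
    merge heights)."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage, labels)
    return str(tree)
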