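"""Idealised collective displacements and their overlap with normal modes.

A (βα)₈ barrel is summarised by two secondary-structure groups: the
inner β-barrel core (8 strands) and the outer α-helical bundle
(8 helices).  Each group supports two idealised rigid motions —
translation along, and rotation about, its principal axis of inertia.
Each individual helix additionally supports five idealised motions:
vertical (along its own axis), horizontal (radially away from the
structure's centre of mass), tilt, and bending of the N- or C-terminal
half.  The eigenvalue-weighted overlap

    Omega_w = sum_m lambda_m (z . v_m)^2      (non-trivial modes m)

scores how expensive a unit displacement z is: low values mean the
motion is carried by soft modes and is energetically favourable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enm import CaModel, ModeSet

__all__ = [
    "SSElement",
    "SSEAnnotation",
    "IdealDisplacement",
    "OverlapResult",
    "principal_axis",
    "barrel_axis",
    "group_displacement",
    "helix_displacement",
    "omega_w",
    "overlap_report",
    "HELIX_MOTIONS",
]

HELIX_MOTIONS = ("vertical", "horizontal", "tilt", "bend_N", "bend_C")


@dataclass(frozen=True)
class SSElement:
    kind: str               # "strand" | "helix" | "accessory"
    ordinal: int | None     # 1-8 for core elements
    indices: tuple[int, ...]  # 0-based atom indices, ascending


@dataclass
class SSEAnnotation:
    """Ordered secondary-structure elements of one structure."""

    elements: list[SSElement]
    n_atoms: int | None = None

    def __post_init__(self) -> None:
        for kind in ("strand", "helix"):
            seen: set[int] = set()
            ords = [e.ordinal for e in self.elements
                    if e.kind == kind and e.ordinal is not None]
            if len(ords) != len(set(ords)):
                raise ValueError(f"duplicate {kind} ordinals")
            for e in self.elements:
                if e.kind != kind:
                    continue
                if seen & set(e.indices):
                    raise ValueError(f"overlapping {kind} ranges")
                seen.update(e.indices)

    @classmethod
    def from_ranges(
        cls,
        strands: list[tuple[int, int]],
        helices: list[tuple[int, int]],
        accessory: list[tuple[int, int]] | None = None,
        n_atoms: int | None = None,
        one_based: bool = False,
    ) -> "SSEAnnotation":
        """Build from inclusive residue-index ranges."""
        off = 1 if one_based else 0
        els: list[SSElement] = []
        for ordn, (a, b) in enumerate(strands, start=1):
            els.append(SSElement("strand", ordn,
                                 tuple(range(a - off, b - off + 1))))
        for ordn, (a, b) in enumerate(helices, start=1):
            els.append(SSElement("helix", ordn,
                                 tuple(range(a - off, b - off + 1))))
        for a, b in accessory or []:
            els.append(SSElement("accessory", None,
                                 tuple(range(a - off, b - off + 1))))
        return cls(elements=els, n_atoms=n_atoms)

    def _kind(self, kind: str) -> list[SSElement]:
        return sorted(
            (e for e in self.elements if e.kind == kind),
            key=lambda e: (e.ordinal if e.ordinal is not None else 99),
        )

    @property
    def strands(self) -> list[SSElement]:
        return self._kind("strand")

    @property
    def helices(self) -> list[SSElement]:
        return self._kind("helix")

    @property
    def barrel_set(self) -> np.ndarray:
        """All strand atom indices (the β-barrel core)."""
        return np.sort(np.concatenate(
            [np.array(e.indices, dtype=int) for e in self.strands]))

    @property
    def bundle_set(self) -> np.ndarray:
        """All helix atom indices (the α-helical bundle)."""
        return np.sort(np.concatenate(
            [np.array(e.indices, dtype=int) for e in self.helices]))

    def loop_indices(self, n_atoms: int | None = None) -> np.ndarray:
        """Atom indices on no annotated element (loops/termini)."""
        n = n_atoms if n_atoms is not None else self.n_atoms
        if n is None:
            raise ValueError("n_atoms unknown")
        used: set[int] = set()
        for e in self.elements:
            used.update(e.indices)
        return np.array(sorted(set(range(n)) - used), dtype=int)

    def helix(self, ordinal: int) -> SSElement:
        for e in self.elements:
            if e.kind == "helix" and e.ordinal == ordinal:
                return e
        raise KeyError(f"no helix with ordinal {ordinal}")


@dataclass
class IdealDisplacement:
    vector: np.ndarray          # (3N,), unit norm, zero outside target
    motion: str
    target: str
    geometry: dict = field(default_factory=dict)
    convention: str = "cartesian"  # or "mass_weighted"


@dataclass
class OverlapResult:
    motion: str
    target: str
    omega_w: float


def principal_axis(
    model: CaModel, selection: np.ndarray, degeneracy_rtol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Long principal axis of inertia and centre of mass of a selection.

    Returns the inertia-tensor eigenvector with the smallest moment (the
    long axis), sign-fixed to point toward the C-terminal (last) atom of
    the selection.  A degenerate smallest moment triggers a warning and
    a deterministic tie-break (first eigenvector in coordinate order).
    """
    sel = np.asarray(selection, dtype=int)
    if len(sel) < 3:
        raise ValueError("selection must contain at least 3 atoms")
    x = model.coords[sel]
    m = model.masses[sel]
    com = np.average(x, axis=0, weights=m)
    dx = x - com
    r2 = np.einsum("ia,ia->i", dx, dx)
    inertia = np.einsum("i,ab->ab", m * r2, np.eye(3)) - np.einsum(
        "i,ia,ib->ab", m, dx, dx
    )
    moments, axes = np.linalg.eigh(inertia)
    if moments[1] - moments[0] <= degeneracy_rtol * max(moments[-1], 1e-300):
        warnings.warn(
            "degenerate inertia spectrum; long axis chosen by coordinate "
            "order tie-break",
            stacklevel=2,
        )
    axis = axes[:, 0]
    toward_c = model.coords[sel[-1]] - com
    s = float(axis @ toward_c)
    if s < 0:
        axis = -axis
    return axis, com


def _embed(n: int, selection: np.ndarray, field3: np.ndarray) -> np.ndarray:
    z = np.zeros((n, 3))
    z[np.asarray(selection, dtype=int)] = field3
    z = z.ravel()
    nrm = np.linalg.norm(z)
    if nrm == 0:
        raise ValueError("zero displacement field")
    return z / nrm


def barrel_axis(model: CaModel, sse: SSEAnnotation) -> np.ndarray:
    """Symmetry axis of the β-barrel: mean of the strands' unit
    end-to-end (N→C) vectors.

    For ring-like selections (the barrel, the bundle) the inertia
    tensor is oblate and its smallest moment lies in the equatorial
    plane, so the inertia axis does not identify the cylinder axis;
    the strand directions do, unambiguously.
    """
    vecs = []
    for el in sse.strands:
        v = model.coords[el.indices[-1]] - model.coords[el.indices[0]]
        vecs.append(v / np.linalg.norm(v))
    if not vecs:
        raise ValueError("annotation has no strands")
    axis = np.mean(vecs, axis=0)
    return axis / np.linalg.norm(axis)


_barrel_symmetry_axis = barrel_axis  # alias usable where the name is shadowed


def group_displacement(
    model: CaModel,
    selection: np.ndarray,
    motion: str,
    target: str = "group",
    axis: np.ndarray | None = None,
    centre: np.ndarray | None = None,
) -> IdealDisplacement:
    """Rigid translation along, or rotation about, a group axis.

    By default the axis is the group's smallest-moment inertia axis and
    the centre its centre of mass; for cylinder-shell groups pass the
    barrel symmetry axis explicitly (see :func:`barrel_axis`).
    """
    sel = np.asarray(selection, dtype=int)
    if axis is None or centre is None:
        pa, pcom = principal_axis(model, sel)
        axis = pa if axis is None else axis
        centre = pcom if centre is None else centre
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    com = np.asarray(centre, dtype=float)
    if motion == "translation":
        field3 = np.tile(axis, (len(sel), 1))
    elif motion == "rotation":
        field3 = np.cross(axis, model.coords[sel] - com)
    else:
        raise ValueError(f"unknown group motion {motion!r}")
    vec = _embed(model.n_atoms, sel, field3)
    return IdealDisplacement(
        vector=vec,
        motion=f"group_{motion}",
        target=target,
        geometry={"axis": axis, "centre": com},
    )


def _half_split(length: int) -> tuple[np.ndarray, np.ndarray, float]:
    """N-half / C-half positions within a helix and the midpoint offset.

    The N-half takes the extra residue for odd lengths; the linear ramp
    is measured from the continuous midpoint (length-1)/2.
    """
    mid = (length - 1) / 2.0
    pos = np.arange(length)
    n_half = pos < np.ceil(length / 2)
    return n_half, ~n_half, mid


def helix_displacement(
    model: CaModel,
    sse: SSEAnnotation,
    helix_ordinal: int,
    motion: str,
    barrel_axis: np.ndarray | None = None,
) -> IdealDisplacement:
    """One of the five idealised motions of a single helix.

    vertical   -- uniform translation along the helix's own long axis;
    horizontal -- uniform translation along the radial direction (from
                  the structure's centre of mass toward the helix centre
                  of mass, orthogonalised against the barrel axis);
    tilt       -- the two halves move in opposite radial directions with
                  magnitude growing linearly from the helix midpoint;
    bend_N / bend_C -- only the named half moves radially, magnitude
                  growing linearly from the midpoint.
    """
    el = sse.helix(helix_ordinal)
    sel = np.array(el.indices, dtype=int)
    if len(sel) < 4:
        raise ValueError(f"helix {helix_ordinal} too short (<4 residues)")
    if barrel_axis is None:
        barrel_axis = _barrel_symmetry_axis(model, sse)
    helix_axis, helix_com = principal_axis(model, sel)
    struct_com = np.average(model.coords, axis=0, weights=model.masses)
    radial = helix_com - struct_com
    radial = radial - (radial @ barrel_axis) * barrel_axis
    rn = np.linalg.norm(radial)
    if rn < 1e-12:
        raise ValueError("radial direction undefined: helix COM at structure COM")
    radial = radial / rn

    length = len(sel)
    n_half, c_half, mid = _half_split(length)
    ramp = np.arange(length) - mid  # negative on N-half, positive on C-half

    if motion == "vertical":
        field3 = np.tile(helix_axis, (length, 1))
    elif motion == "horizontal":
        field3 = np.tile(radial, (length, 1))
    elif motion == "tilt":
        # bend_N - bend_C pattern: N-half +radial, C-half -radial
        field3 = (-ramp)[:, None] * radial[None, :]
    elif motion == "bend_N":
        mag = np.where(n_half, -ramp, 0.0)
        field3 = mag[:, None] * radial[None, :]
    elif motion == "bend_C":
        mag = np.where(c_half, ramp, 0.0)
        field3 = mag[:, None] * radial[None, :]
    else:
        raise ValueError(f"unknown helix motion {motion!r}")

    vec = _embed(model.n_atoms, sel, field3)
    return IdealDisplacement(
        vector=vec,
        motion=f"helix_{motion}",
        target=f"helix_{helix_ordinal}",
        geometry={
            "helix_axis": helix_axis,
            "radial": radial,
            "barrel_axis": barrel_axis,
            "centre": helix_com,
        },
    )


def omega_w(
    modes: ModeSet, z, convention: str | None = None, label: str | None = None
) -> OverlapResult:
    """Eigenvalue-weighted overlap of a unit displacement with all modes.

    Omega_w = sum over non-trivial modes of lambda_m (z . v_m)^2.  A
    Cartesian z is converted to the mass-weighted eigenvector space
    (component-wise sqrt(m_i) scaling, renormalised) before projection;
    a mass-weighted z is used as is.  Equals z^T H z (mass-weighted
    Hessian) for any unit z orthogonal to the trivial modes.
    """
    if isinstance(z, IdealDisplacement):
        vec = z.vector
        conv = convention or z.convention
        motion, target = z.motion, z.target
    else:
        vec = np.asarray(z, dtype=float)
        conv = convention or "mass_weighted"
        motion, target = label or "custom", label or "custom"
    if vec.shape != (3 * modes.n_atoms,):
        raise ValueError("displacement length does not match ModeSet")
    if conv == "cartesian":
        vec = vec * np.sqrt(np.repeat(modes.masses, 3))
        vec = vec / np.linalg.norm(vec)
    elif conv != "mass_weighted":
        raise ValueError(f"unknown convention {conv!r}")
    nrm = np.linalg.norm(vec)
    if abs(nrm - 1.0) > 1e-8:
        warnings.warn("non-unit displacement vector; normalising", stacklevel=2)
        vec = vec / nrm
    cols = modes.nontrivial
    proj = modes.eigenvectors[:, cols].T @ vec
    val = float(np.sum(modes.eigenvalues[cols] * proj ** 2))
    return OverlapResult(motion=motion, target=target, omega_w=val)


def overlap_report(
    modes: ModeSet, model: CaModel, sse: SSEAnnotation
) -> pd.DataFrame:
    """Omega_w table: barrel/bundle rotation+translation and 5 x 8 helix rows.

    Group motions use the barrel symmetry axis (strand-derived) and the
    structure's centre of mass, matching the cylinder scheme of the
    idealised motions.
    """
    rows = []
    axis = barrel_axis(model, sse)
    com = np.average(model.coords, axis=0, weights=model.masses)
    for target, selection in (("barrel", sse.barrel_set),
                              ("bundle", sse.bundle_set)):
        for motion in ("translation", "rotation"):
            disp = group_displacement(model, selection, motion,
                                      target=target, axis=axis, centre=com)
            res = omega_w(modes, disp)
            rows.append({"target": target, "motion": motion,
                         "ordinal": None, "omega_w": res.omega_w})
    for el in sse.helices:
        for motion in HELIX_MOTIONS:
            disp = helix_displacement(model, sse, el.ordinal, motion,
                                      barrel_axis=axis)
            res = omega_w(modes, disp)
            rows.append({"target": "helix", "motion": motion,
                         "ordinal": el.ordinal, "omega_w": res.omega_w})
    return pd.DataFrame(rows)
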