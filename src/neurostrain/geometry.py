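"""3D neurite space curves and their local Frenet-style frames.

Neuron skeletons are represented as ordered polylines in micrometres
(:class:`Curve3D`), grouped per cell into a :class:`NeuronGeometry`.  The
local orientation of a neurite is captured by a per-point orthonormal frame
{t, n, b} (:class:`FrenetFrame`): the tangent defines the axial direction of
the neurite cross-section, and the normal/binormal span the cross-sectional
plane.  Strain projections downstream depend only on the tangent, so the
normal is completed by parallel transport, which stays well defined on
straight segments where the classical Frenet normal degenerates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Curve3D",
    "FrenetFrame",
    "NeuronGeometry",
    "resample_arclength",
    "tangent_frames",
]

_COINCIDENT_TOL = 1e-12


@dataclass(frozen=True)
class Curve3D:
    """An ordered 3D polyline with cumulative arc-length parameterisation.

    Parameters
    ----------
    points : (n, 3) array
        Vertex coordinates in micrometres, ordered along the curve.

    Attributes
    ----------
    arclengths : (n,) array
        Cumulative arc length per vertex, starting at 0 (µm).
    """

    points: np.ndarray
    arclengths: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("curve requires an (n>=2, 3) point array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("curve points must be finite")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= _COINCIDENT_TOL):
            raise ValueError("consecutive curve points must not coincide")
        object.__setattr__(self, "points", pts)
        object.__setattr__(
            self, "arclengths", np.concatenate(([0.0], np.cumsum(seg)))
        )

    @property
    def length(self) -> float:
        """Total arc length (µm)."""
        return float(self.arclengths[-1])

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def reversed(self) -> "Curve3D":
        """The same curve traversed in the opposite direction."""
        return Curve3D(self.points[::-1].copy())


@dataclass(frozen=True)
class FrenetFrame:
    """Per-point orthonormal frame {t, n, b} along a curve.

    Each row of ``t``, ``n`` and ``b`` is a unit vector; the triple is
    right-handed (b = t × n).
    """

    t: np.ndarray
    n: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "n", "b"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
        if not (self.t.shape == self.n.shape == self.b.shape):
            raise ValueError("frame vector arrays must share a shape")

    def rotation_matrices(self) -> np.ndarray:
        """Stack of per-point rotation matrices Q with rows (t, n, b).

        Q maps global coordinates into the local frame; the local strain
        tensor is Q E Qᵀ.
        """
        return np.stack([self.t, self.n, self.b], axis=1)


@dataclass(frozen=True)
class NeuronGeometry:
    """A segmented cell: soma position plus neurite space curves."""

    soma: np.ndarray
    neurites: tuple[Curve3D, ...]
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        object.__setattr__(self, "soma", np.asarray(self.soma, dtype=float))
        object.__setattr__(self, "neurites", tuple(self.neurites))
        if self.soma.shape != (3,):
            raise ValueError("soma must be a 3-vector")
        if len(self.neurites) == 0:
            raise ValueError("a neuron needs at least one neurite")

    @property
    def total_length(self) -> float:
        return float(sum(c.length for c in self.neurites))


def resample_arclength(curve: Curve3D, spacing: float) -> Curve3D:
    """Resample a curve to uniform arc-length spacing.

    The number of intervals is chosen so the actual spacing is the closest
    value <= ``spacing`` that divides the total length evenly; endpoints are
    preserved exactly.

    Parameters
    ----------
    curve : Curve3D
    spacing : float
        Target arc-length spacing (µm); must be positive and smaller than
        the total curve length.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    total = curve.length
    if spacing >= total:
        raise ValueError(
            f"spacing {spacing} must be smaller than curve length {total}"
        )
    n_seg = int(np.ceil(total / spacing))
    s_new = np.linspace(0.0, total, n_seg + 1)
    pts = np.column_stack(
        [
            np.interp(s_new, curve.arclengths, curve.points[:, k])
            for k in range(3)
        ]
    )
    return Curve3D(pts)


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norm <= _COINCIDENT_TOL):
        raise ValueError("cannot normalise a zero vector")
    return v / norm


def tangent_frames(curve: Curve3D, initial_normal: np.ndarray | None = None) -> FrenetFrame:
    """Compute per-point orthonormal frames along a curve.

    Tangents use centred finite differences in arc length (one-sided at the
    endpoints).  Normals are completed by parallel transport: the previous
    normal is projected onto the plane orthogonal to the current tangent and
    renormalised.  This is frame-continuous and well defined on straight
    segments; the initial normal is arbitrary, and quantities that depend
    only on the tangent (axial and shear strain projections) are unaffected
    by the choice.

    Parameters
    ----------
    curve : Curve3D
    initial_normal : array-like, optional
        Seed normal for the transport; any vector not parallel to the first
        tangent. Defaults to a fixed axis pick.
    """
    pts = curve.points
    n_pts = pts.shape[0]
    s = curve.arclengths

    tangents = np.empty_like(pts)
    tangents[1:-1] = (pts[2:] - pts[:-2]) / (s[2:] - s[:-2])[:, None]
    tangents[0] = (pts[1] - pts[0]) / (s[1] - s[0])
    tangents[-1] = (pts[-1] - pts[-2]) / (s[-1] - s[-2])
    tangents = _unit(tangents)

    normals = np.empty_like(tangents)
    if initial_normal is None:
        # pick the global axis least aligned with the first tangent
        axis = np.zeros(3)
        axis[np.argmin(np.abs(tangents[0]))] = 1.0
    else:
        axis = np.asarray(initial_normal, dtype=float)
    n0 = axis - np.dot(axis, tangents[0]) * tangents[0]
    if np.linalg.norm(n0) <= 1e-9:
        raise ValueError("initial normal is parallel to the first tangent")
    normals[0] = n0 / np.linalg.norm(n0)
    for i in range(1, n_pts):
        proj = normals[i - 1] - np.dot(normals[i - 1], tangents[i]) * tangents[i]
        nrm = np.linalg.norm(proj)
        if nrm <= 1e-9:
            # tangent flipped nearly 180°; restart transport from a fixed axis
            axis = np.zeros(3)
            axis[np.argmin(np.abs(tangents[i]))] = 1.0
            proj = axis - np.dot(axis, tangents[i]) * tangents[i]
            nrm = np.linalg.norm(proj)
        normals[i] = proj / nrm

    binormals = np.cross(tangents, normals)
    return FrenetFrame(t=tangents, n=normals, b=binormals)
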