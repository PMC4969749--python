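"""Far-field strain tensors, strain fields, and projection onto neurites.

The compression device imposes a nominally uniform uniaxial Lagrangian
strain E∞ on the collagen gel, with x3 the loading axis.  A neurite senses
this far-field tensor through its local orientation: expressing E∞ in the
frame attached to the curve gives a local axial (tangent-aligned) strain

    E_c = t · E∞ · t

and a local axial shear strain, defined here as the magnitude of the
transverse part of the strain traction on the neurite cross-section,

    E_s = ‖E∞ t − (t · E∞ · t) t‖.

Both are quadratic/even in t, hence independent of curve orientation and of
the choice of normal/binormal.  Cell-level summaries are arc-length averages
over all neurites of the cell.  When a measured displacement field is
available instead of a constant tensor, the Green–Lagrange strain
E = (FᵀF − I)/2 with F = I + ∇u is computed on the grid and interpolated
onto the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .geometry import Curve3D, FrenetFrame, NeuronGeometry, tangent_frames

__all__ = [
    "FarFieldStrain",
    "DisplacementField",
    "StrainField",
    "LocalStrainProfile",
    "CellStrainSummary",
    "uniform_compression_tensor",
    "project_strain",
    "local_strain_profile",
    "mean_strains",
    "green_lagrange_from_displacement",
    "sample_strain_at_curve",
    "bleb_local_strain",
]

_SYM_TOL = 1e-12


@dataclass(frozen=True)
class FarFieldStrain:
    """A constant symmetric 3×3 Lagrangian strain tensor (dimensionless)."""

    E: np.ndarray

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        if E.shape != (3, 3):
            raise ValueError("strain tensor must be 3x3")
        if np.max(np.abs(E - E.T)) >= _SYM_TOL:
            raise ValueError("strain tensor must be symmetric")
        object.__setattr__(self, "E", E)


@dataclass(frozen=True)
class DisplacementField:
    """Displacement 3-vectors on a regular lattice.

    ``u`` has shape (nx, ny, nz, 3) in µm; ``spacing`` is the per-axis grid
    step (µm); ``origin`` the coordinate of node (0, 0, 0).
    """

    u: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        if u.ndim != 4 or u.shape[-1] != 3:
            raise ValueError("displacement array must have shape (nx, ny, nz, 3)")
        if min(u.shape[:3]) < 2:
            raise ValueError("grid needs at least 2 nodes per axis")
        if not np.all(np.isfinite(u)):
            raise ValueError("displacement values must be finite")
        spacing = tuple(float(h) for h in self.spacing)
        if len(spacing) != 3 or min(spacing) <= 0:
            raise ValueError("spacing must be three positive lengths")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.u.shape[k])
            for k in range(3)
        )


@dataclass(frozen=True)
class StrainField:
    """Symmetric 3×3 strain tensor per node of a regular lattice.

    ``E`` has shape (nx, ny, nz, 3, 3).
    """

    E: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        if E.ndim != 5 or E.shape[-2:] != (3, 3):
            raise ValueError("strain array must have shape (nx, ny, nz, 3, 3)")
        if np.max(np.abs(E - np.swapaxes(E, -1, -2))) >= 1e-9:
            raise ValueError("per-node strain tensors must be symmetric")
        object.__setattr__(self, "E", E)
        object.__setattr__(self, "spacing", tuple(float(h) for h in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.E.shape[k])
            for k in range(3)
        )


@dataclass(frozen=True)
class LocalStrainProfile:
    """Per-point local strain along one neurite.

    ``E_local`` holds the full tensor rotated into the curve frame (Q E Qᵀ);
    ``E_c`` the signed axial component, ``E_s`` the non-negative shear
    magnitude, indexed by ``arclengths`` (µm).
    """

    arclengths: np.ndarray
    E_local: np.ndarray
    E_c: np.ndarray
    E_s: np.ndarray

    def __post_init__(self) -> None:
        for name in ("arclengths", "E_local", "E_c", "E_s"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.E_s < -1e-15):
            raise ValueError("shear strain must be non-negative")


@dataclass(frozen=True)
class CellStrainSummary:
    """Cell-averaged strain magnitudes for one neuron.

    ``mean_Ec`` is the compressive magnitude of the length-averaged axial
    strain; ``mean_Es`` the length-averaged shear strain; ``length_um`` the
    total neurite length used as quadrature weight.
    """

    cell_id: str
    mean_Ec: float
    mean_Es: float
    length_um: float

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("total length must be positive")
        if self.mean_Es < 0:
            raise ValueError("mean shear strain must be non-negative")


def uniform_compression_tensor(
    applied_strain: float, transverse_ratio: float = 0.0
) -> FarFieldStrain:
    """Uniaxial far-field compression along x3.

    ``applied_strain`` is the engineering compressive strain of the gel
    height (positive, < 1); the tensor carries E_33 = −applied_strain and
    transverse components transverse_ratio × applied_strain (small-strain
    convention).  The device's dynamic loading corresponds to 0.30,
    quasistatic to up to 0.38, with a near-zero transverse ratio measured
    in the gel.
    """
    if not 0 <= applied_strain < 1:
        raise ValueError("applied engineering strain must be in [0, 1)")
    lat = transverse_ratio * applied_strain
    return FarFieldStrain(np.diag([lat, lat, -applied_strain]))


def project_strain(t: np.ndarray, E: FarFieldStrain | np.ndarray) -> tuple[float, float]:
    """Project a strain tensor onto a unit tangent.

    Returns ``(E_c, E_s)``: the signed axial strain tᵀE t and the shear
    magnitude ‖E t − (tᵀE t) t‖.
    """
    t = np.asarray(t, dtype=float)
    Em = E.E if isinstance(E, FarFieldStrain) else np.asarray(E, dtype=float)
    if abs(np.linalg.norm(t) - 1.0) > 1e-9:
        raise ValueError("tangent must be a unit vector")
    traction = Em @ t
    e_c = float(t @ traction)
    e_s = float(np.linalg.norm(traction - e_c * t))
    return e_c, e_s


def _tensors_along_curve(
    curve: Curve3D, strain_source: FarFieldStrain | StrainField
) -> np.ndarray:
    if isinstance(strain_source, FarFieldStrain):
        return np.broadcast_to(
            strain_source.E, (curve.n_points, 3, 3)
        ).copy()
    return sample_strain_at_curve(strain_source, curve)


def local_strain_profile(
    curve: Curve3D,
    strain_source: FarFieldStrain | StrainField,
    frames: FrenetFrame | None = None,
) -> LocalStrainProfile:
    """Local strain tensor, axial and shear components along one neurite."""
    if frames is None:
        frames = tangent_frames(curve)
    tensors = _tensors_along_curve(curve, strain_source)
    Q = frames.rotation_matrices()
    E_local = Q @ tensors @ np.swapaxes(Q, -1, -2)
    traction = np.einsum("pij,pj->pi", tensors, frames.t)
    e_c = np.einsum("pi,pi->p", frames.t, traction)
    e_s = np.linalg.norm(traction - e_c[:, None] * frames.t, axis=1)
    return LocalStrainProfile(
        arclengths=curve.arclengths, E_local=E_local, E_c=e_c, E_s=e_s
    )


def mean_strains(
    geometry: NeuronGeometry | Curve3D,
    strain_source: FarFieldStrain | StrainField,
    cell_id: str | None = None,
) -> CellStrainSummary:
    """Length-weighted mean axial and shear strain for a whole cell.

    ⟨E_c⟩ and ⟨E_s⟩ are trapezoidal arc-length averages over every neurite,
    weighted by neurite length.  The axial mean is computed on the signed
    axial strain and reported as a compressive magnitude, matching the
    convention that cell-level axial strains are quoted as positive
    compression.
    """
    if isinstance(geometry, Curve3D):
        geometry = NeuronGeometry(
            soma=geometry.points[0], neurites=(geometry,),
            cell_id=cell_id or "cell",
        )
    int_ec = 0.0
    int_es = 0.0
    total = 0.0
    for curve in geometry.neurites:
        profile = local_strain_profile(curve, strain_source)
        int_ec += float(np.trapezoid(profile.E_c, curve.arclengths))
        int_es += float(np.trapezoid(profile.E_s, curve.arclengths))
        total += curve.length
    return CellStrainSummary(
        cell_id=cell_id or geometry.cell_id,
        mean_Ec=abs(int_ec) / total,
        mean_Es=int_es / total,
        length_um=total,
    )


def green_lagrange_from_displacement(field: DisplacementField) -> StrainField:
    """Green–Lagrange strain field from a gridded displacement field.

    The displacement gradient uses central differences interior and
    second-order one-sided stencils at the boundary (exact for affine
    fields); then F = I + ∇u and E = (FᵀF − I)/2, symmetric by construction.
    """
    grads = [
        np.stack(np.gradient(field.u[..., i], *field.spacing), axis=-1)
        for i in range(3)
    ]
    gradu = np.stack(grads, axis=-2)  # (..., i, j) = du_i/dx_j
    F = gradu + np.eye(3)
    E = 0.5 * (np.swapaxes(F, -1, -2) @ F - np.eye(3))
    E = 0.5 * (E + np.swapaxes(E, -1, -2))  # scrub round-off asymmetry
    return StrainField(E=E, spacing=field.spacing, origin=field.origin)


def sample_strain_at_curve(field: StrainField, curve: Curve3D) -> np.ndarray:
    """Trilinearly interpolate a strain field at each curve point.

    Returns an (n_points, 3, 3) array; exact for componentwise-linear
    fields.  Raises ``ValueError`` naming the first offending point index if
    any point falls outside the grid hull.
    """
    axes = field.axes()
    pts = curve.points
    for k in range(3):
        bad = (pts[:, k] < axes[k][0] - 1e-9) | (pts[:, k] > axes[k][-1] + 1e-9)
        if np.any(bad):
            idx = int(np.argmax(bad))
            raise ValueError(
                f"curve point {idx} at {pts[idx]} lies outside the strain grid"
            )
    interp = RegularGridInterpolator(
        axes, field.E.reshape(field.E.shape[:3] + (9,)), method="linear",
        bounds_error=False, fill_value=None,
    )
    vals = interp(pts).reshape(-1, 3, 3)
    return 0.5 * (vals + np.swapaxes(vals, -1, -2))


def bleb_local_strain(
    profile: LocalStrainProfile,
    bleb_positions: np.ndarray,
    window: float = 2.0,
) -> np.ndarray:
    """Strain extrema in the immediate proximity of each bleb.

    For each bleb arc-length position, the maxima of |E_c| and E_s over a
    window of ±``window`` µm centred on the bleb (truncated at the curve
    ends).  Returns an (n_blebs, 2) array of (max |E_c|, max E_s).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    s = profile.arclengths
    length = s[-1]
    out = np.empty((len(bleb_positions), 2))
    for i, pos in enumerate(np.asarray(bleb_positions, dtype=float)):
        if pos < -1e-9 or pos > length + 1e-9:
            raise ValueError(
                f"bleb position {pos} outside curve arc length [0, {length}]"
            )
        sel = (s >= pos - window) & (s <= pos + window)
        out[i, 0] = np.max(np.abs(profile.E_c[sel]))
        out[i, 1] = np.max(profile.E_s[sel])
    return out
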