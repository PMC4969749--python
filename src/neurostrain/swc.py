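"""Reading and writing neuron morphologies in SWC format.

SWC is the standard plain-text morphology format: one sample per line with
columns ``id type x y z radius parent`` (µm), ``parent = -1`` for roots and
``#`` comment lines.  For strain analysis each root-to-leaf path of the
sample tree becomes one :class:`~neurostrain.geometry.Curve3D`; the root
sample position is taken as the soma.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import Curve3D, NeuronGeometry

__all__ = ["read_swc", "write_swc", "SWCFormatError"]


class SWCFormatError(ValueError):
    """Malformed SWC content (duplicate ids, bad parents, cycles)."""


def read_swc(path: str | Path, cell_id: str | None = None) -> NeuronGeometry:
    """Parse an SWC file into a neuron geometry.

    Raises :class:`SWCFormatError` with the offending line number for
    duplicate ids, forward/missing parent references, or cyclic links.
    """
    path = Path(path)
    samples: dict[int, tuple[np.ndarray, int]] = {}
    children: dict[int, list[int]] = {}
    roots: list[int] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCFormatError(
                    f"{path}:{lineno}: expected 7 columns, got {len(fields)}"
                )
            try:
                sid = int(fields[0])
                xyz = np.array([float(fields[2]), float(fields[3]), float(fields[4])])
                parent = int(fields[6])
            except ValueError as exc:
                raise SWCFormatError(f"{path}:{lineno}: {exc}") from None
            if sid in samples:
                raise SWCFormatError(f"{path}:{lineno}: duplicate sample id {sid}")
            if parent == sid:
                raise SWCFormatError(f"{path}:{lineno}: sample {sid} is its own parent")
            if parent != -1 and parent not in samples:
                raise SWCFormatError(
                    f"{path}:{lineno}: parent {parent} of sample {sid} not yet "
                    "defined (forward or missing reference)"
                )
            samples[sid] = (xyz, parent)
            if parent == -1:
                roots.append(sid)
            else:
                children.setdefault(parent, []).append(sid)
    if not samples:
        raise SWCFormatError(f"{path}: no samples")
    if not roots:
        raise SWCFormatError(f"{path}: no root sample (parent -1)")

    # parent-precedes-child was enforced above, so the graph is acyclic
    soma = samples[roots[0]][0]
    curves: list[Curve3D] = []
    for root in roots:
        stack = [(root, [root])]
        while stack:
            node, trail = stack.pop()
            kids = children.get(node, [])
            if not kids:
                if len(trail) >= 2:
                    pts = np.array([samples[i][0] for i in trail])
                    curves.append(Curve3D(pts))
                continue
            for kid in reversed(kids):  # preserve file order depth-first
                stack.append((kid, trail + [kid]))
    if not curves:
        raise SWCFormatError(f"{path}: morphology has no paths with >= 2 samples")
    return NeuronGeometry(
        soma=soma, neurites=tuple(curves), cell_id=cell_id or path.stem
    )


def write_swc(geometry: NeuronGeometry, path: str | Path, radius: float = 0.5) -> None:
    """Write a neuron geometry as SWC, one root per neurite path.

    Each neurite is emitted as an unbranched chain rooted at its first
    point; the soma sample (type 1) heads the file.  Shared soma-adjacent
    points are not merged, so ``read_swc(write_swc(g))`` reproduces the
    same set of curves.
    """
    path = Path(path)
    lines = ["# id type x y z radius parent"]
    next_id = 1
    soma_id = next_id
    sx, sy, sz = geometry.soma
    lines.append(f"{soma_id} 1 {sx:.6f} {sy:.6f} {sz:.6f} {radius:.3f} -1")
    next_id += 1
    for curve in geometry.neurites:
        parent = -1
        start = 0
        # attach to the soma sample when the curve starts at the soma
        if np.allclose(curve.points[0], geometry.soma, atol=1e-9):
            parent = soma_id
            start = 1
        for pt in curve.points[start:]:
            lines.append(
                f"{next_id} 3 {pt[0]:.6f} {pt[1]:.6f} {pt[2]:.6f} "
                f"{radius:.3f} {parent}"
            )
            parent = next_id
            next_id += 1
    path.write_text("\n".join(lines) + "\n")
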