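"""Synthetic tetrahedral phantoms for simulation, planning and testing.

Every geometry is a box subdivided into a structured hexahedral grid, with
each hex cell split into six tetrahedra along the main diagonal (the
Freudenthal/Kuhn decomposition, which is conforming across neighbouring
cells).  Region labels are assigned per tetrahedron from the feature that
contains its centroid — a deliberately simple scheme whose discretisation
error shrinks with the cell size.  Supported features: homogeneous box,
stacked slabs, a sphere embedded in the box (tumour-like), and a cylinder
with an optional concentric wall (vessel-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .mesh import TetraMesh, build_tetra_mesh

__all__ = ["PhantomSpec", "generate_phantom", "generate_tumor_oar_phantom"]

_KINDS = ("box", "slab_stack", "sphere_in_box", "vessel_in_box")

# Six tetrahedra per hex: vertex paths (0,0,0) -> (1,1,1), one per axis order.
_KUHN_PATHS = []
for perm in sorted(permutations(range(3))):
    corner = np.zeros(3, dtype=int)
    path = [corner.copy()]
    for ax in perm:
        corner = corner.copy()
        corner[ax] = 1
        path.append(corner)
    _KUHN_PATHS.append(np.array(path))


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom.

    extents/cells define the box (mm) and its structured subdivision; the
    remaining fields parameterise the optional embedded feature.  The
    background is always region 0.
    """

    kind: str
    extents: tuple = (60.0, 60.0, 60.0)
    cells: tuple = (10, 10, 10)
    # sphere_in_box
    sphere_center: tuple = None   # defaults to the box centre
    sphere_radius: float = 0.0
    sphere_label: int = 1
    shell_thickness: float = 0.0  # optional concentric shell around the sphere
    shell_label: int = 2
    # vessel_in_box: infinite cylinder clipped to the box
    vessel_point: tuple = None    # point on the axis; defaults to box centre
    vessel_axis: tuple = (0.0, 0.0, 1.0)
    vessel_radius: float = 0.0
    vessel_label: int = 1
    wall_thickness: float = 0.0
    wall_label: int = 2
    # slab_stack: layers along z
    layer_boundaries: tuple = ()  # interior z planes (mm), ascending
    layer_labels: tuple = ()      # len(layer_boundaries) + 1 labels

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; expected one of {_KINDS}")
        ex = np.asarray(self.extents, dtype=float)
        if ex.shape != (3,) or np.any(ex <= 0):
            raise ValueError("extents must be three positive lengths (mm)")
        cells = np.asarray(self.cells, dtype=int)
        if cells.shape != (3,) or np.any(cells < 1):
            raise ValueError("cells must be three positive subdivision counts")
        center = ex / 2.0
        if self.kind == "sphere_in_box":
            c = np.asarray(self.sphere_center if self.sphere_center is not None else center)
            r = self.sphere_radius + self.shell_thickness
            if r < 0 or self.sphere_radius < 0:
                raise ValueError("sphere radius and shell thickness must be >= 0")
            if np.any(c - r < 0) or np.any(c + r > ex):
                raise ValueError("sphere (plus shell) does not fit inside the box")
            self.sphere_center = tuple(c)
        elif self.kind == "vessel_in_box":
            p = np.asarray(self.vessel_point if self.vessel_point is not None else center)
            a = np.asarray(self.vessel_axis, dtype=float)
            if np.linalg.norm(a) == 0:
                raise ValueError("vessel axis must be a nonzero vector")
            r = self.vessel_radius + self.wall_thickness
            if self.vessel_radius < 0 or self.wall_thickness < 0:
                raise ValueError("vessel radius and wall thickness must be >= 0")
            # crude fit check: the axis point must keep the full radius inside
            if np.any(p - r < -1e-9) or np.any(p + r > ex + 1e-9):
                raise ValueError("vessel does not fit inside the box")
            self.vessel_point = tuple(p)
            self.vessel_axis = tuple(a / np.linalg.norm(a))
        elif self.kind == "slab_stack":
            zb = np.asarray(self.layer_boundaries, dtype=float)
            if np.any(np.diff(zb) <= 0):
                raise ValueError("layer boundaries must be strictly ascending")
            if len(zb) and (zb[0] <= 0 or zb[-1] >= ex[2]):
                raise ValueError("layer boundaries must lie strictly inside the box")
            if len(self.layer_labels) != len(zb) + 1:
                raise ValueError("need len(layer_boundaries)+1 layer labels")


def _box_tets(extents, cells):
    nx, ny, nz = (int(c) for c in cells)
    ex = np.asarray(extents, dtype=float)
    xs = np.linspace(0.0, ex[0], nx + 1)
    ys = np.linspace(0.0, ex[1], ny + 1)
    zs = np.linspace(0.0, ex[2], nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    vertices = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                base = np.array([i, j, k])
                for path in _KUHN_PATHS:
                    tets.append([vid(*(base + p)) for p in path])
    return vertices, np.array(tets, dtype=np.int32)


def _classify(spec: PhantomSpec, centroids: np.ndarray) -> np.ndarray:
    region = np.zeros(len(centroids), dtype=np.int32)
    if spec.kind == "box":
        return region
    if spec.kind == "sphere_in_box":
        d = np.linalg.norm(centroids - np.asarray(spec.sphere_center), axis=1)
        if spec.shell_thickness > 0:
            region[d < spec.sphere_radius + spec.shell_thickness] = spec.shell_label
        region[d < spec.sphere_radius] = spec.sphere_label
        return region
    if spec.kind == "vessel_in_box":
        p = np.asarray(spec.vessel_point)
        a = np.asarray(spec.vessel_axis)
        rel = centroids - p
        d = np.linalg.norm(rel - np.outer(rel @ a, a), axis=1)
        if spec.wall_thickness > 0:
            region[d < spec.vessel_radius + spec.wall_thickness] = spec.wall_label
        region[d < spec.vessel_radius] = spec.vessel_label
        return region
    if spec.kind == "slab_stack":
        labels = np.asarray(spec.layer_labels, dtype=np.int32)
        idx = np.searchsorted(np.asarray(spec.layer_boundaries), centroids[:, 2], side="right")
        return labels[idx]
    raise AssertionError(spec.kind)


def generate_phantom(spec: PhantomSpec) -> TetraMesh:
    """Build the tetrahedral mesh for ``spec`` (deterministic per spec)."""
    vertices, tets = _box_tets(spec.extents, spec.cells)
    centroids = vertices[tets].mean(axis=1)
    region = _classify(spec, centroids)
    return build_tetra_mesh(vertices, tets, region)


def generate_tumor_oar_phantom(
    tumor_radius: float,
    oar_shell_thickness: float,
    extents=(60.0, 60.0, 60.0),
    cells=(20, 20, 20),
) -> TetraMesh:
    """Sphere tumour (region 1) wrapped in an organ-at-risk shell (region 2).

    The standard planning test bed: background tissue is region 0, the
    tumour a centred sphere, and the OAR a concentric shell of the given
    thickness directly outside it.
    """
    spec = PhantomSpec(
        kind="sphere_in_box",
        extents=tuple(extents),
        cells=tuple(cells),
        sphere_radius=float(tumor_radius),
        sphere_label=1,
        shell_thickness=float(oar_shell_thickness),
        shell_label=2,
    )
    return generate_phantom(spec)
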