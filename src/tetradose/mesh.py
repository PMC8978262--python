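"""Tetrahedral mesh data model, legacy-VTK I/O and geometric queries.

The mesh is the geometric substrate for photon transport: a set of vertices
(millimetres, the package's canonical unit), four-vertex cells, and a
per-cell integer region label that keys into the optical-property table.
On construction every tetrahedron is canonically oriented (positive signed
volume), per-face outward plane equations are precomputed for ray traversal,
and face adjacency is built so the transport kernel can walk from cell to
cell in O(1) per face crossing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "TetraMesh",
    "MeshDiagnostics",
    "MeshFormatError",
    "GeometryError",
    "read_tetra_mesh_vtk",
    "write_fluence_vtk",
    "build_tetra_mesh",
    "locate_tetra",
    "exit_face",
]

# Traversal tolerances (mm): face hits closer than EXIT_TOL are treated as
# zero distance; packets are nudged NUDGE past a crossed face so they land
# strictly inside the neighbouring cell.
EXIT_TOL = 1e-9
NUDGE = 1e-7
# Cells smaller than this (mm^3) break the per-volume fluence estimator.
DEGENERATE_VOLUME = 1e-12

VTK_TETRA = 10


class MeshFormatError(ValueError):
    """Raised for files that are not legacy-VTK tetrahedral unstructured grids."""


class GeometryError(RuntimeError):
    """Raised when ray traversal finds no forward face intersection."""


@dataclass
class MeshDiagnostics:
    n_tets: int
    n_vertices: int
    n_regions: int
    n_boundary_faces: int
    degenerate_tets: list
    unit_declared: str

    def log_lines(self):
        return [
            f"n_tets={self.n_tets}",
            f"n_vertices={self.n_vertices}",
            f"n_regions={self.n_regions}",
            f"n_boundary_faces={self.n_boundary_faces}",
            f"degenerate_tets={len(self.degenerate_tets)}",
            f"unit_declared={self.unit_declared}",
        ]


@dataclass
class TetraMesh:
    """Tetrahedral mesh with per-cell region labels (coordinates in mm).

    Derived fields (volumes, outward face planes, adjacency, boundary-face
    table) are filled in by :func:`build_tetra_mesh`.
    """

    vertices: np.ndarray          # (nv, 3) float64, mm
    tets: np.ndarray              # (nt, 4) int32
    region: np.ndarray            # (nt,)  int32
    unit_declared: str = "mm"
    volume: np.ndarray = field(default=None, repr=False)        # (nt,) mm^3
    adjacency: np.ndarray = field(default=None, repr=False)     # (nt, 4) int32, -1 = boundary
    face_normal: np.ndarray = field(default=None, repr=False)   # (nt, 4, 3) outward unit
    face_offset: np.ndarray = field(default=None, repr=False)   # (nt, 4)  n.x = offset on face
    boundary_face_id: np.ndarray = field(default=None, repr=False)  # (nt, 4) int32, -1 interior
    boundary_faces: np.ndarray = field(default=None, repr=False)    # (nbf, 2) (tet, local face)
    boundary_area: np.ndarray = field(default=None, repr=False)     # (nbf,) mm^2
    _kdtree: object = field(default=None, repr=False, compare=False)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_boundary_faces(self) -> int:
        return len(self.boundary_faces)

    @property
    def centroids(self) -> np.ndarray:
        return self.vertices[self.tets].mean(axis=1)

    def regions_present(self) -> np.ndarray:
        return np.unique(self.region)

    def diagnostics(self) -> MeshDiagnostics:
        degen = np.nonzero(self.volume < DEGENERATE_VOLUME)[0].tolist()
        return MeshDiagnostics(
            n_tets=self.n_tets,
            n_vertices=self.n_vertices,
            n_regions=len(self.regions_present()),
            n_boundary_faces=self.n_boundary_faces,
            degenerate_tets=degen,
            unit_declared=self.unit_declared,
        )

    def kdtree(self):
        if self._kdtree is None:
            from scipy.spatial import cKDTree

            self._kdtree = cKDTree(self.centroids)
        return self._kdtree


def _signed_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a, b, c, d = (vertices[tets[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def build_tetra_mesh(
    vertices, tets, region, unit: str = "mm", *, allow_degenerate: bool = False
) -> TetraMesh:
    """Assemble a :class:`TetraMesh`, orienting cells and building adjacency.

    ``unit`` declares the coordinate unit of the *input* arrays; ``cm``
    coordinates are converted to the internal mm representation.
    """
    vertices = np.ascontiguousarray(vertices, dtype=np.float64)
    tets = np.ascontiguousarray(tets, dtype=np.int32)
    region = np.ascontiguousarray(region, dtype=np.int32)
    if unit not in ("mm", "cm"):
        raise ValueError(f"unit must be 'mm' or 'cm', got {unit!r}")
    if unit == "cm":
        vertices = vertices * 10.0
    if tets.ndim != 2 or tets.shape[1] != 4:
        raise MeshFormatError("tets must be an (n, 4) index array")
    if len(region) != len(tets):
        raise MeshFormatError("region array length must equal the cell count")
    if tets.size and (tets.min() < 0 or tets.max() >= len(vertices)):
        raise MeshFormatError("tet vertex index out of range")
    if np.any(region < 0):
        raise ValueError("region labels must be >= 0")

    # Canonical orientation: positive signed volume (swap last two vertices).
    sv = _signed_volumes(vertices, tets)
    flip = sv < 0
    if np.any(flip):
        tets = tets.copy()
        tets[flip, 2], tets[flip, 3] = tets[flip, 3], tets[flip, 2]
        sv = np.abs(sv)
    volume = np.abs(sv)
    if not allow_degenerate and np.any(volume < DEGENERATE_VOLUME):
        bad = np.nonzero(volume < DEGENERATE_VOLUME)[0]
        raise MeshFormatError(
            f"{len(bad)} degenerate tetrahedra (volume < {DEGENERATE_VOLUME} mm^3), "
            f"first indices {bad[:5].tolist()}"
        )

    mesh = TetraMesh(vertices=vertices, tets=tets, region=region, unit_declared=unit, volume=volume)
    _build_faces(mesh)
    return mesh


# Local face f is the triangle opposite local vertex f.
_FACE_OPP = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))


def _build_faces(mesh: TetraMesh) -> None:
    nt = mesh.n_tets
    verts, tets = mesh.vertices, mesh.tets

    normal = np.empty((nt, 4, 3))
    offset = np.empty((nt, 4))
    for f, (i, j, k) in enumerate(_FACE_OPP):
        a, b, c = verts[tets[:, i]], verts[tets[:, j]], verts[tets[:, k]]
        d = verts[tets[:, f]]  # opposite vertex
        n = np.cross(b - a, c - a)
        # orient outward: away from the opposite vertex
        s = np.einsum("ij,ij->i", n, d - a)
        n[s > 0] *= -1.0
        norm = np.linalg.norm(n, axis=1)
        norm[norm == 0] = 1.0
        n /= norm[:, None]
        normal[:, f, :] = n
        offset[:, f] = np.einsum("ij,ij->i", n, a)

    adjacency = np.full((nt, 4), -1, dtype=np.int32)
    face_map: dict = {}
    for t in range(nt):
        tv = tets[t]
        for f, (i, j, k) in enumerate(_FACE_OPP):
            key = tuple(sorted((int(tv[i]), int(tv[j]), int(tv[k]))))
            other = face_map.pop(key, None)
            if other is None:
                face_map[key] = (t, f)
            else:
                ot, of = other
                adjacency[t, f] = ot
                adjacency[ot, of] = t

    boundary = np.array(sorted(face_map.values()), dtype=np.int32).reshape(-1, 2)
    boundary_face_id = np.full((nt, 4), -1, dtype=np.int32)
    areas = np.empty(len(boundary))
    for bi, (t, f) in enumerate(boundary):
        boundary_face_id[t, f] = bi
        i, j, k = _FACE_OPP[f]
        a, b, c = verts[tets[t, i]], verts[tets[t, j]], verts[tets[t, k]]
        areas[bi] = 0.5 * np.linalg.norm(np.cross(b - a, c - a))

    mesh.adjacency = adjacency
    mesh.face_normal = np.ascontiguousarray(normal)
    mesh.face_offset = np.ascontiguousarray(offset)
    mesh.boundary_face_id = boundary_face_id
    mesh.boundary_faces = boundary
    mesh.boundary_area = areas


# ---------------------------------------------------------------------------
# Legacy VTK I/O
# ---------------------------------------------------------------------------

def read_tetra_mesh_vtk(path, unit: str = "mm", region_array: str = "region") -> TetraMesh:
    """Read a legacy-ASCII VTK unstructured grid of tetrahedra.

    ``unit`` declares the coordinate unit of the file ('mm' or 'cm'); cm
    files are converted to mm.  The per-cell integer array named
    ``region_array`` supplies the region labels.
    """
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.split("#")[0] if line.startswith("#") and "vtk" not in line else line
            tokens.extend(line.split())
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take(n=1):
        nonlocal pos
        out = tokens[pos : pos + n]
        if len(out) < n:
            raise MeshFormatError("unexpected end of VTK file")
        pos += n
        return out if n > 1 else out[0]

    points = None
    cells = None
    cell_types = None
    cell_arrays: dict[str, np.ndarray] = {}
    n_cells_declared = 0
    in_cell_data = False

    while pos < len(tokens):
        tok = take().upper()
        if tok == "DATASET":
            kind = take().upper()
            if kind != "UNSTRUCTURED_GRID":
                raise MeshFormatError(f"expected UNSTRUCTURED_GRID dataset, got {kind}")
        elif tok == "POINTS":
            n = int(take())
            take()  # dtype
            vals = [float(take()) for _ in range(3 * n)]
            points = np.array(vals).reshape(n, 3)
        elif tok == "CELLS":
            n = int(take())
            size = int(take())
            data = [int(take()) for _ in range(size)]
            cells, i = [], 0
            for _ in range(n):
                k = data[i]
                cells.append(data[i + 1 : i + 1 + k])
                i += k + 1
            n_cells_declared = n
        elif tok == "CELL_TYPES":
            n = int(take())
            cell_types = [int(take()) for _ in range(n)]
        elif tok == "CELL_DATA":
            in_cell_data = True
            take()  # count
        elif tok == "POINT_DATA":
            in_cell_data = False
            take()
        elif tok == "SCALARS":
            name = take()
            dtype = take().lower()
            # optional numComp then LOOKUP_TABLE
            if peek() and peek().upper() != "LOOKUP_TABLE":
                take()
            if peek() and peek().upper() == "LOOKUP_TABLE":
                take(2)
            n = n_cells_declared if in_cell_data else (len(points) if points is not None else 0)
            vals = [take() for _ in range(n)]
            arr = np.array(vals, dtype=np.int64 if dtype in ("int", "long", "short") else np.float64)
            if in_cell_data:
                cell_arrays[name] = arr
        # other tokens (version comment, ASCII, field data) are skipped

    if points is None or cells is None:
        raise MeshFormatError("VTK file lacks POINTS or CELLS sections")
    if cell_types is not None:
        bad = set(ct for ct in cell_types if ct != VTK_TETRA)
        if bad:
            raise MeshFormatError(
                f"mesh contains non-tetrahedral VTK cell types {sorted(bad)}; "
                f"only type {VTK_TETRA} (tetra) is supported"
            )
    for c in cells:
        if len(c) != 4:
            raise MeshFormatError(f"cell with {len(c)} vertices found; expected tetrahedra")
    if region_array not in cell_arrays:
        raise MeshFormatError(
            f"no per-cell region array named {region_array!r} found "
            f"(available: {sorted(cell_arrays)}); pass region_array= to select one"
        )
    region = cell_arrays[region_array].astype(np.int32)
    return build_tetra_mesh(points, np.array(cells, dtype=np.int32), region, unit=unit)


def write_fluence_vtk(mesh: TetraMesh, cell_arrays: dict, path) -> None:
    """Write the mesh and named per-cell arrays as a legacy-ASCII VTK file.

    Integer arrays are written as ``int`` scalars, everything else as
    double-precision floats at full (%.17g) precision so a round-trip read
    recovers them exactly.
    """
    for name, arr in cell_arrays.items():
        if len(arr) != mesh.n_tets:
            raise ValueError(
                f"cell array {name!r} has length {len(arr)}, expected n_tets={mesh.n_tets}"
            )
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("tetradose output\n")
        fh.write("ASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write("%.17g %.17g %.17g\n" % tuple(v))
        nt = mesh.n_tets
        fh.write(f"CELLS {nt} {5 * nt}\n")
        for t in mesh.tets:
            fh.write("4 %d %d %d %d\n" % tuple(t))
        fh.write(f"CELL_TYPES {nt}\n")
        for _ in range(nt):
            fh.write(f"{VTK_TETRA}\n")
        fh.write(f"CELL_DATA {nt}\n")
        for name, arr in cell_arrays.items():
            arr = np.asarray(arr)
            if np.issubdtype(arr.dtype, np.integer):
                fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
                for x in arr:
                    fh.write(f"{int(x)}\n")
            else:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for x in arr:
                    fh.write("%.17g\n" % float(x))


# ---------------------------------------------------------------------------
# Point location and ray-exit queries
# ---------------------------------------------------------------------------

@njit(cache=True)
def _inside(face_normal, face_offset, tet, p, tol):
    for f in range(4):
        s = (
            face_normal[tet, f, 0] * p[0]
            + face_normal[tet, f, 1] * p[1]
            + face_normal[tet, f, 2] * p[2]
            - face_offset[tet, f]
        )
        if s > tol:
            return False
    return True


@njit(cache=True)
def _walk(face_normal, face_offset, adjacency, start, p, tol, max_steps):
    t = start
    for _ in range(max_steps):
        worst = -1.0
        worst_f = -1
        for f in range(4):
            s = (
                face_normal[t, f, 0] * p[0]
                + face_normal[t, f, 1] * p[1]
                + face_normal[t, f, 2] * p[2]
                - face_offset[t, f]
            )
            if s > worst:
                worst = s
                worst_f = f
        if worst <= tol:
            return t
        nxt = adjacency[t, worst_f]
        if nxt < 0:
            return -1
        t = nxt
    return -1


@njit(cache=True)
def _locate_many(face_normal, face_offset, adjacency, starts, points, tol, max_steps):
    out = np.empty(len(points), dtype=np.int64)
    for i in range(len(points)):
        out[i] = _walk(face_normal, face_offset, adjacency, starts[i], points[i], tol, max_steps)
    return out


def locate_points(mesh: TetraMesh, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Vectorised point location: tet index per point, -1 if outside.

    Walks the adjacency graph from the nearest-centroid cell; points the
    walk cannot resolve (possible on slivers or exactly-on-boundary points)
    fall back to an exhaustive half-space scan.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    _, starts = mesh.kdtree().query(points)
    out = _locate_many(
        mesh.face_normal, mesh.face_offset, mesh.adjacency,
        starts.astype(np.int64), points, tol, max(64, mesh.n_tets),
    )
    missing = np.nonzero(out < 0)[0]
    for i in missing:
        out[i] = _brute_locate(mesh, points[i], tol)
    return out


def _brute_locate(mesh: TetraMesh, p: np.ndarray, tol: float) -> int:
    s = np.einsum("tfj,j->tf", mesh.face_normal, p) - mesh.face_offset
    ok = np.nonzero((s <= tol).all(axis=1))[0]
    return int(ok[0]) if len(ok) else -1


def locate_tetra(mesh: TetraMesh, point, tol: float = 1e-9):
    """Return the index of a tet whose closed interior contains ``point``, or None."""
    idx = locate_points(mesh, np.asarray(point, dtype=np.float64)[None, :], tol=tol)[0]
    return None if idx < 0 else int(idx)


@njit(cache=True)
def _exit_face_kernel(face_normal, face_offset, tet, p, u, tol):
    best_t = np.inf
    best_f = -1
    for f in range(4):
        denom = (
            face_normal[tet, f, 0] * u[0]
            + face_normal[tet, f, 1] * u[1]
            + face_normal[tet, f, 2] * u[2]
        )
        if denom <= 1e-12:
            continue  # moving away from (or parallel to) this face plane
        s = face_offset[tet, f] - (
            face_normal[tet, f, 0] * p[0]
            + face_normal[tet, f, 1] * p[1]
            + face_normal[tet, f, 2] * p[2]
        )
        t = s / denom
        if t < -tol:
            continue
        if t < 0.0:
            t = 0.0
        if t < best_t:
            best_t = t
            best_f = f
    return best_f, best_t


def exit_face(mesh: TetraMesh, tet: int, position, direction, tol: float = EXIT_TOL):
    """First face crossed by the ray from ``position`` along ``direction``.

    Returns ``(local_face, distance_mm)``.  Raises :class:`GeometryError`
    when no forward intersection exists, which signals a corrupted packet
    position rather than a recoverable condition.
    """
    p = np.asarray(position, dtype=np.float64)
    u = np.asarray(direction, dtype=np.float64)
    f, t = _exit_face_kernel(mesh.face_normal, mesh.face_offset, tet, p, u, tol)
    if f < 0 or not math.isfinite(t):
        raise GeometryError(
            f"no forward face intersection from tet {tet} at {p.tolist()} along {u.tolist()}"
        )
    return int(f), float(t)
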