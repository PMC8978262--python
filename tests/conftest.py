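import numpy as np
import pytest

import tetradose as td


@pytest.fixture(scope="session")
def small_box_mesh():
    """20 mm homogeneous box, 4^3 cells (384 tets)."""
    return td.generate_phantom(
        td.PhantomSpec(kind="box", extents=(20, 20, 20), cells=(4, 4, 4))
    )


@pytest.fixture(scope="session")
def unit_tet_mesh():
    """Single right tetrahedron: origin plus the three unit axis points."""
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    return td.build_tetra_mesh(verts, np.array([[0, 1, 2, 3]]), np.array([0]))


@pytest.fixture
def single_tet_vtk(tmp_path):
    """Minimal legacy-VTK file: one tetra cell, region 0."""
    path = tmp_path / "single_tet.vtk"
    path.write_text(
        "# vtk DataFile Version 3.0\n"
        "single tet\n"
        "ASCII\n"
        "DATASET UNSTRUCTURED_GRID\n"
        "POINTS 4 double\n"
        "0 0 0\n1 0 0\n0 1 0\n0 0 1\n"
        "CELLS 1 5\n"
        "4 0 1 2 3\n"
        "CELL_TYPES 1\n"
        "10\n"
        "CELL_DATA 1\n"
        "SCALARS region int 1\n"
        "LOOKUP_TABLE default\n"
        "0\n"
    )
    return path


@pytest.fixture(scope="session")
def clear_material():
    return {0: td.Material(0, "clear", 0.0, 0.0, 0.0, 1.0)}


@pytest.fixture(scope="session")
def soft_tissue():
    """Soft-tissue optics, matched to ambient so boundaries are invisible."""
    return {0: td.Material.from_reduced(0, "tissue", 0.02, 2.0, 0.0, 1.0)}
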