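"""Triangulated membrane meshes.

The membrane is a flat elastic disk discretized as a triangle mesh with
disk topology (a single boundary loop).  Vertices carry role flags:

* ``tethered``  -- in-plane radius > r_free; held by nonspecific adhesion
  springs of rest length equal to the far-field separation.
* ``force_loaded`` -- in-plane radius within the active-force disk of
  radius ``a``; receives an equal share of the total protrusive force.
* ``receptor`` -- the single vertex nearest the disk center, whose height
  (or separation from its partner on the opposing membrane) is the
  observable of interest.

Internal units are nm / us / pN throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TriMesh:
    """Lagrangian membrane state.

    Attributes
    ----------
    vertices : (N, 3) float array, positions [nm]
    triangles : (F, 3) int array, CCW-wound index triples
    ref_area_per_face : (F,) float array, face areas at initialization [nm^2]
    ref_edge_lengths : (E,) float array, unique-edge rest lengths [nm]
    edges : (E, 2) int array, unique edges (i < j)
    tethered, force_loaded : bool masks over vertices
    receptor : int, index of the receptor vertex
    boundary : bool mask over vertices (on the single boundary loop)
    """

    vertices: np.ndarray
    triangles: np.ndarray
    ref_area_per_face: np.ndarray = field(default=None)  # type: ignore[assignment]
    ref_edge_lengths: np.ndarray = field(default=None)  # type: ignore[assignment]
    edges: np.ndarray = field(default=None)  # type: ignore[assignment]
    tethered: np.ndarray = field(default=None)  # type: ignore[assignment]
    force_loaded: np.ndarray = field(default=None)  # type: ignore[assignment]
    receptor: int = 0
    boundary: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.edges is None:
            self.edges = unique_edges(self.triangles)
        if self.ref_area_per_face is None:
            self.ref_area_per_face = face_areas(self.vertices, self.triangles)
        if self.ref_edge_lengths is None:
            d = self.vertices[self.edges[:, 0]] - self.vertices[self.edges[:, 1]]
            self.ref_edge_lengths = np.linalg.norm(d, axis=1)
        n = len(self.vertices)
        if self.tethered is None:
            self.tethered = np.zeros(n, dtype=bool)
        if self.force_loaded is None:
            self.force_loaded = np.zeros(n, dtype=bool)
        if self.boundary is None:
            self.boundary = boundary_vertices(self.triangles)
        if not np.all(self.ref_area_per_face > 0):
            bad = int(np.argmin(self.ref_area_per_face))
            raise ValueError(f"degenerate face {bad}: zero or negative area")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def copy(self) -> "TriMesh":
        return TriMesh(
            vertices=self.vertices.copy(),
            triangles=self.triangles,
            ref_area_per_face=self.ref_area_per_face,
            ref_edge_lengths=self.ref_edge_lengths,
            edges=self.edges,
            tethered=self.tethered,
            force_loaded=self.force_loaded,
            receptor=self.receptor,
            boundary=self.boundary,
        )

    def vertex_areas(self) -> np.ndarray:
        """Lumped (one-third barycentric) vertex areas [nm^2]."""
        A = face_areas(self.vertices, self.triangles)
        va = np.zeros(self.n_vertices)
        np.add.at(va, self.triangles.ravel(), np.repeat(A / 3.0, 3))
        return va

    def vertex_areas_ref(self) -> np.ndarray:
        """Lumped vertex areas of the reference configuration [nm^2].

        Constant over a run; used where a configuration-independent
        area (hence mobility) is wanted, e.g. the permeable-slip law.
        """
        va = np.zeros(self.n_vertices)
        np.add.at(va, self.triangles.ravel(), np.repeat(self.ref_area_per_face / 3.0, 3))
        return va


def face_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a, b, c = (vertices[triangles[:, k]] for k in range(3))
    n = np.cross(b - a, c - a)
    return 0.5 * np.linalg.norm(n, axis=1)


def unique_edges(triangles: np.ndarray) -> np.ndarray:
    e = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def edge_face_counts(triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique edges and the number of faces adjacent to each."""
    e = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    e = np.sort(e, axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return uniq, counts


def boundary_vertices(triangles: np.ndarray) -> np.ndarray:
    uniq, counts = edge_face_counts(triangles)
    n = int(triangles.max()) + 1
    mask = np.zeros(n, dtype=bool)
    mask[uniq[counts == 1].ravel()] = True
    return mask


def count_boundary_loops(triangles: np.ndarray) -> int:
    """Number of closed boundary loops (0 for a closed surface, 1 for a disk)."""
    uniq, counts = edge_face_counts(triangles)
    bed = uniq[counts == 1]
    if len(bed) == 0:
        return 0
    # boundary edges form disjoint cycles; count connected components
    nbr: dict[int, list[int]] = {}
    for i, j in bed:
        nbr.setdefault(int(i), []).append(int(j))
        nbr.setdefault(int(j), []).append(int(i))
    seen: set[int] = set()
    loops = 0
    for v0 in nbr:
        if v0 in seen:
            continue
        loops += 1
        stack = [v0]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(w for w in nbr[v] if w not in seen)
    return loops


def build_disk_mesh(
    radius: float,
    target_edge: float,
    *,
    r_free: float | None = None,
    a_force: float | None = None,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> TriMesh:
    """Roughly uniform triangulation of a flat disk at height z = center[2].

    Vertices are laid out on concentric rings spaced by ``target_edge``,
    with ~2*pi*r/target_edge points on the ring of radius r, then
    Delaunay-triangulated in the plane.  Edge lengths stay within +-30%
    of ``target_edge``.  Role flags are assigned from ``r_free`` (tethers
    outside) and ``a_force`` (active-force disk at the center).

    Parameters are lengths in nm.
    """
    if not (radius > target_edge > 0):
        raise ValueError(
            f"need radius > target_edge > 0, got radius={radius}, target_edge={target_edge}"
        )
    from scipy.spatial import Delaunay

    # hexagonal lattice clipped to the disk, plus an explicit boundary circle
    e = target_edge
    nmax = int(np.ceil(radius / e)) + 2
    ii, jj = np.meshgrid(np.arange(-nmax, nmax + 1), np.arange(-nmax, nmax + 1),
                         indexing="ij")
    px = (ii + 0.5 * (jj % 2)) * e
    py = jj * (np.sqrt(3.0) / 2.0) * e
    pts = np.column_stack([px.ravel(), py.ravel()])
    r = np.linalg.norm(pts, axis=1)
    pts = pts[r <= radius - 0.6 * e]  # leave room for the boundary ring
    mb = max(6, int(round(2 * np.pi * radius / e)))
    th = 2 * np.pi * np.arange(mb) / mb
    xy = np.concatenate([pts, np.column_stack([radius * np.cos(th), radius * np.sin(th)])])
    n_int = len(pts)
    # distmesh-style relaxation: edge springs at rest length ~e equalize the
    # lattice/boundary transition; the boundary ring stays fixed
    for _ in range(100):
        tri = Delaunay(xy)
        ed = np.concatenate([tri.simplices[:, [0, 1]], tri.simplices[:, [1, 2]],
                             tri.simplices[:, [2, 0]]])
        ed = np.unique(np.sort(ed, axis=1), axis=0)
        d = xy[ed[:, 0]] - xy[ed[:, 1]]
        L = np.linalg.norm(d, axis=1)
        fmag = (1.0 * e - L) / L
        F = np.zeros_like(xy)
        np.add.at(F, ed[:, 0], fmag[:, None] * d)
        np.add.at(F, ed[:, 1], -fmag[:, None] * d)
        xy[:n_int] += 0.15 * F[:n_int]
        rr = np.linalg.norm(xy[:n_int], axis=1)
        cap = radius - 0.55 * e
        out = rr > cap
        xy[:n_int][out] *= (cap / rr[out])[:, None]
    tri = Delaunay(xy)
    faces = tri.simplices.copy()
    # enforce CCW winding in the plane (outward normal +z)
    a, b, c = xy[faces[:, 0]], xy[faces[:, 1]], xy[faces[:, 2]]
    signed = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    flip = signed < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    # drop slivers that Delaunay can create between boundary points
    area = 0.5 * np.abs(signed)
    faces = faces[area > 1e-6 * target_edge**2]

    verts = np.column_stack([xy, np.zeros(len(xy))]) + np.asarray(center)
    mesh = TriMesh(vertices=verts, triangles=faces)

    rad = np.linalg.norm(xy, axis=1)
    mesh.receptor = int(np.argmin(rad))
    if r_free is not None:
        mesh.tethered = rad > r_free
    if a_force is not None:
        med = float(np.median(mesh.ref_edge_lengths))
        # the force disk is resolved by at least the receptor one-ring
        mesh.force_loaded = rad <= max(a_force, 1.05 * med)
    return mesh


def sphere_mesh(radius: float, subdivisions: int = 3) -> TriMesh:
    """Closed icosphere (fixture for curvature / bending-energy checks)."""
    import trimesh as _tm

    s = _tm.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriMesh(vertices=np.asarray(s.vertices, float), triangles=np.asarray(s.faces))


def write_vtk(path, mesh: TriMesh) -> None:
    """Legacy-ASCII VTK polydata snapshot with vertex roles as point data."""
    v, f = mesh.vertices, mesh.triangles
    roles = (
        mesh.tethered.astype(int)
        + 2 * mesh.force_loaded.astype(int)
    )
    roles = roles.copy()
    roles[mesh.receptor] += 4
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nibmem membrane snapshot\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} double\n")
        for p in v:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        for t in f:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"POINT_DATA {len(v)}\nSCALARS roles int 1\nLOOKUP_TABLE default\n")
        for r in roles:
            fh.write(f"{int(r)}\n")
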