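"""Conforming linear-tetrahedral meshing of the lumbar stack.

The vertebral bodies and discs form a generalized elliptical cylinder, which
is meshed by a structured extrusion: a single triangulated elliptical
cross-section (concentric rings of points, Delaunay-connected, with one ring
snapped exactly onto the nucleus outline) is swept along the axial direction,
scaled at every station to the local endplate/disc outline, and every
triangular prism between consecutive stations is split into three tetrahedra
with an index-ordering rule that keeps shared quad faces conforming
(Dompierre-style subdivision).  Because every station reuses the same
triangulation, vertebra-disc and annulus-nucleus interfaces share nodes -
tie constraints are realized by mesh conformity.

Ligament cables snap to the nearest outer-surface node of their vertebra and
become 2-node elements sharing those nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .ct import LABEL_VERTEBRA
from .errors import MeshError, ValidationError
from .geometry import LigamentCable, LigamentSet, SpineGeometry
from .materials import REGION_ANNULUS, REGION_NUCLEUS

EDGE_VERT_RANGE = (0.5, 6.0)
EDGE_IVD_RANGE = (0.25, 3.0)


@dataclass
class CableElement:
    """A ligament cable snapped onto two mesh nodes."""

    node_upper: int
    node_lower: int
    E: float  # MPa
    area: float  # mm^2
    ltype: str
    gap: int


@dataclass
class TetMesh:
    """4-node tetrahedral mesh with region tags and boundary node sets."""

    nodes: np.ndarray  # (N, 3) mm
    elems: np.ndarray  # (M, 4) int
    region: np.ndarray  # (M,) int: 1..5 vertebrae, 6 annulus, 7 nucleus
    inferior_nodes: np.ndarray  # bottom (fixed) surface
    superior_nodes: np.ndarray  # top (loaded) surface
    surface_nodes: dict[str, np.ndarray] = field(default_factory=dict)
    cables: list[CableElement] = field(default_factory=list)
    edge_vert: float = np.nan
    edge_ivd: float = np.nan

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elems)

    def element_coords(self) -> np.ndarray:
        return self.nodes[self.elems]

    def element_volumes(self) -> np.ndarray:
        c = self.element_coords()
        v = c[:, 1:] - c[:, :1]
        return np.linalg.det(v) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.element_coords().mean(axis=1)

    def validate(self) -> None:
        vols = self.element_volumes()
        if vols.min() <= 0:
            bad = int(np.argmin(vols))
            raise MeshError(
                f"non-positive element volume at element {bad} "
                f"(V = {vols.min():.3e} mm^3)"
            )
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.elems.ravel()] = True
        if not used.all():
            raise MeshError(f"{int((~used).sum())} orphan node(s) in mesh")


@dataclass
class MeshQualityReport:
    min_volume: float
    max_aspect: float
    n_nodes: int
    n_elements: int
    counts_by_region: dict[int, int]
    ok: bool

    def __str__(self) -> str:
        status = "OK" if self.ok else "FAILED (non-positive volume)"
        return (
            f"mesh quality: {status}\n"
            f"  nodes={self.n_nodes} elements={self.n_elements}\n"
            f"  min volume = {self.min_volume:.4g} mm^3, "
            f"max aspect = {self.max_aspect:.2f}\n"
            f"  per region: {self.counts_by_region}"
        )


def mesh_quality(mesh: TetMesh) -> MeshQualityReport:
    """Volume/aspect diagnostics; flags inverted elements instead of raising."""
    vols = mesh.element_volumes()
    c = mesh.element_coords()
    # longest edge
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    edges = np.stack([np.linalg.norm(c[:, i] - c[:, j], axis=1) for i, j in pairs])
    lmax = edges.max(axis=0)
    # smallest altitude = 3V / largest face area
    faces = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
    areas = np.stack([
        0.5 * np.linalg.norm(
            np.cross(c[:, b] - c[:, a], c[:, d] - c[:, a]), axis=1
        )
        for a, b, d in faces
    ])
    amax = areas.max(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        aspect = lmax * amax / np.maximum(3.0 * np.abs(vols), 1e-300)
    codes, counts = np.unique(mesh.region, return_counts=True)
    return MeshQualityReport(
        min_volume=float(vols.min()),
        max_aspect=float(aspect.max()),
        n_nodes=mesh.n_nodes,
        n_elements=mesh.n_elements,
        counts_by_region={int(k): int(v) for k, v in zip(codes, counts)},
        ok=bool(vols.min() > 0),
    )


# ---------------------------------------------------------------------------
# cross-section template
# ---------------------------------------------------------------------------

def _unit_disk_points(n_rings: int, snap_radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Concentric-ring point set on the unit disk.

    One interior ring is placed exactly at ``snap_radius`` (the nucleus
    outline in unit coordinates) so the annulus-nucleus interface is a mesh
    line at every resolution.  Returns (points (P,2), outer_ring_ids).
    """
    k_star = int(np.clip(round(snap_radius * n_rings), 1, n_rings - 1))
    inner = np.linspace(0.0, snap_radius, k_star + 1)[1:]
    outer = np.linspace(snap_radius, 1.0, n_rings - k_star + 1)[1:]
    radii = np.concatenate([inner, outer])

    pts = [np.zeros((1, 2))]
    for k, r in enumerate(radii, start=1):
        n_k = 6 * k
        th = 2 * np.pi * np.arange(n_k) / n_k + (k % 2) * np.pi / n_k
        pts.append(np.column_stack([r * np.cos(th), r * np.sin(th)]))
    points = np.vstack(pts)
    n_outer = 6 * n_rings
    outer_ids = np.arange(len(points) - n_outer, len(points))
    return points, outer_ids


def _triangulate(points: np.ndarray) -> np.ndarray:
    tri = Delaunay(points)
    t = tri.simplices.copy()
    # enforce counterclockwise orientation
    v1 = points[t[:, 1]] - points[t[:, 0]]
    v2 = points[t[:, 2]] - points[t[:, 0]]
    flip = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0] < 0
    t[flip] = t[flip][:, [0, 2, 1]]
    return t


def _split_prisms(bot: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Split triangular prisms (bot (P,3), top (P,3) global ids) into 3 tets.

    Quad faces are cut through their smallest global node id, which makes the
    diagonals agree between neighbouring prisms, so the result is conforming.
    """
    prisms = np.concatenate([bot, top], axis=1)  # v0 v1 v2 | v3 v4 v5
    rot = np.argmin(prisms[:, :3], axis=1)
    idx = np.empty_like(prisms)
    for r, perm in enumerate(((0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3),
                              (2, 0, 1, 5, 3, 4))):
        sel = rot == r
        idx[sel] = prisms[sel][:, perm]
    v = idx
    case_a = np.minimum(v[:, 1], v[:, 5]) < np.minimum(v[:, 2], v[:, 4])
    tets = np.empty((len(v), 3, 4), dtype=v.dtype)
    a = v[case_a]
    tets[case_a] = np.stack([
        a[:, [0, 1, 2, 5]], a[:, [0, 1, 5, 4]], a[:, [0, 4, 5, 3]],
    ], axis=1)
    b = v[~case_a]
    tets[~case_a] = np.stack([
        b[:, [0, 1, 2, 4]], b[:, [0, 4, 2, 5]], b[:, [0, 4, 5, 3]],
    ], axis=1)
    return tets.reshape(-1, 4)


def _fix_orientation(nodes: np.ndarray, elems: np.ndarray) -> np.ndarray:
    c = nodes[elems]
    vols = np.linalg.det(c[:, 1:] - c[:, :1])
    flip = vols < 0
    elems = elems.copy()
    elems[flip] = elems[flip][:, [0, 1, 3, 2]]
    return elems


# ---------------------------------------------------------------------------
# spine tetrahedralization
# ---------------------------------------------------------------------------

def tetrahedralize(
    geom: SpineGeometry, edge_vert: float = 3.0, edge_ivd: float = 1.5
) -> TetMesh:
    """Mesh the whole lumbar stack with linear tetrahedra (C3D4).

    ``edge_vert`` controls the in-plane resolution and the axial layer height
    inside vertebral bodies; ``edge_ivd`` the layer height inside discs.
    """
    if not (EDGE_VERT_RANGE[0] <= edge_vert <= EDGE_VERT_RANGE[1]):
        raise ValidationError(
            f"edge_vert = {edge_vert} outside {EDGE_VERT_RANGE}"
        )
    if not (EDGE_IVD_RANGE[0] <= edge_ivd <= EDGE_IVD_RANGE[1]):
        raise ValidationError(f"edge_ivd = {edge_ivd} outside {EDGE_IVD_RANGE}")

    # ring count from the nominal anthropometry (not the jittered per-level
    # values) so all subjects of a cohort share one cross-section template
    p = geom.params
    mean_semi = 0.5 * (p.body_ap + p.body_ml) * (1.0 + 2.0 * p.level_gradient)
    n_rings = max(2, int(round(mean_semi / edge_vert)))
    snap = float(np.sqrt(geom.params.nucleus_fraction))
    disk, outer_ids = _unit_disk_points(n_rings, snap)
    tris = _triangulate(disk)
    n_sec = len(disk)
    tri_r = np.linalg.norm(disk[tris].mean(axis=1), axis=1)
    tri_in_nucleus = tri_r <= snap

    # axial stations, segment by segment (bottom-up)
    segments = sorted(
        [("vertebra", v) for v in geom.vertebrae]
        + [("disc", d) for d in geom.discs],
        key=lambda kv: kv[1].z_inferior,
    )
    z_stations = [segments[0][1].z_inferior]
    layer_segment: list[tuple[str, object]] = []
    for kind, obj in segments:
        edge = edge_vert if kind == "vertebra" else edge_ivd
        n_layers = max(1, int(round(obj.height / edge)))
        zs = np.linspace(obj.z_inferior, obj.z_inferior + obj.height,
                         n_layers + 1)[1:]
        z_stations.extend(zs.tolist())
        layer_segment.extend([(kind, obj)] * n_layers)
    z_stations = np.asarray(z_stations)
    n_stations = len(z_stations)

    # nodes: the template scaled to the local outline at every station
    nodes = np.empty((n_stations * n_sec, 3))
    for s, z in enumerate(z_stations):
        # evaluate the outline inside the owning segment (stations sit on
        # interfaces where both neighbours agree by construction)
        kind, obj = layer_segment[min(s, n_stations - 2)]
        if kind == "vertebra":
            a, b = obj.a_ap, obj.a_ml
        else:
            a, b = obj.semi_axes_at(z)
        block = slice(s * n_sec, (s + 1) * n_sec)
        nodes[block, 0] = a * disk[:, 0]
        nodes[block, 1] = b * disk[:, 1]
        nodes[block, 2] = z

    # elements layer by layer
    elems_parts, region_parts = [], []
    for s, (kind, obj) in enumerate(layer_segment):
        bot = tris + s * n_sec
        top = tris + (s + 1) * n_sec
        tets = _split_prisms(bot, top)
        elems_parts.append(tets)
        if kind == "vertebra":
            codes = np.full(len(tris), LABEL_VERTEBRA[obj.level])
        else:
            codes = np.where(tri_in_nucleus, REGION_NUCLEUS, REGION_ANNULUS)
        region_parts.append(np.repeat(codes, 3))
    elems = np.vstack(elems_parts)
    region = np.concatenate(region_parts)
    elems = _fix_orientation(nodes, elems)

    # boundary node sets
    inferior = np.arange(n_sec)
    superior = np.arange((n_stations - 1) * n_sec, n_stations * n_sec)
    surface: dict[str, np.ndarray] = {}
    for v in geom.vertebrae:
        sel = (z_stations >= v.z_inferior - 1e-9) & (
            z_stations <= v.z_superior + 1e-9
        )
        ids = [s * n_sec + outer_ids for s in np.flatnonzero(sel)]
        surface[v.level] = np.concatenate(ids)

    mesh = TetMesh(
        nodes=nodes, elems=elems, region=region,
        inferior_nodes=inferior, superior_nodes=superior,
        surface_nodes=surface, edge_vert=edge_vert, edge_ivd=edge_ivd,
    )
    mesh.validate()
    return mesh


def snap_ligaments(mesh: TetMesh, ligaments: LigamentSet) -> list[CableElement]:
    """Attach each ligament cable to the nearest vertebral surface nodes.

    The snapped cables are stored on the mesh and returned.  Snapping two
    endpoints of one cable onto the same node would produce a zero-length
    element and raises instead.
    """
    trees = {
        level: cKDTree(mesh.nodes[ids]) for level, ids in mesh.surface_nodes.items()
    }
    cables: list[CableElement] = []
    for c in ligaments.cables:
        up_ids = mesh.surface_nodes[c.upper_level]
        low_ids = mesh.surface_nodes[c.lower_level]
        iu = int(up_ids[trees[c.upper_level].query(c.p_upper)[1]])
        il = int(low_ids[trees[c.lower_level].query(c.p_lower)[1]])
        if iu == il or np.allclose(mesh.nodes[iu], mesh.nodes[il]):
            raise MeshError(
                f"{c.ltype} cable at segment {c.gap} snapped to a zero length"
            )
        cables.append(
            CableElement(node_upper=iu, node_lower=il, E=c.E, area=c.area,
                         ltype=c.ltype, gap=c.gap)
        )
    mesh.cables = cables
    return cables


# ---------------------------------------------------------------------------
# structured box meshes (fixtures / verification oracles)
# ---------------------------------------------------------------------------

def structured_box_mesh(
    lengths: tuple[float, float, float],
    divisions: tuple[int, int, int],
    region_code: int = 1,
) -> TetMesh:
    """Kuhn (6-tet) subdivision of a box grid; conforming across cubes.

    The bottom (z=0) face becomes the inferior node set and the top face the
    superior set, matching the loading convention of the spine meshes.
    """
    lx, ly, lz = lengths
    nx, ny, nz = divisions
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    corner = {}
    for bit in range(8):
        di, dj, dk = bit & 1, (bit >> 1) & 1, (bit >> 2) & 1
        corner[bit] = nid(I + di, J + dj, K + dk)
    kuhn = [(0, 1, 3, 7), (0, 3, 2, 7), (0, 2, 6, 7),
            (0, 6, 4, 7), (0, 4, 5, 7), (0, 5, 1, 7)]
    elems = np.vstack([
        np.column_stack([corner[a], corner[b], corner[c], corner[d]])
        for a, b, c, d in kuhn
    ])
    elems = _fix_orientation(nodes, elems)

    inferior = np.flatnonzero(np.isclose(nodes[:, 2], 0.0))
    superior = np.flatnonzero(np.isclose(nodes[:, 2], lz))
    mesh = TetMesh(
        nodes=nodes, elems=elems,
        region=np.full(len(elems), region_code),
        inferior_nodes=inferior, superior_nodes=superior,
    )
    mesh.validate()
    return mesh


def convergence_study(subject, edge_lengths, tolerance: float = 0.05, **sim_kwargs):
    """Mesh-sensitivity ladder for the failure-load simulation.

    Thin wrapper kept here for discoverability; the implementation lives in
    :mod:`spinefe.simulate` because it drives full compression runs.
    """
    from .simulate import convergence_study as _impl

    return _impl(subject, edge_lengths, tolerance=tolerance, **sim_kwargs)
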