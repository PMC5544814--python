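"""Triangulated meshes of head scenarios.

Meshing strategy: an interface-conforming point cloud (points sampled along
every material boundary at the local target spacing, plus graded hexagonal
background lattices whose spacing follows the local wavelength) is
triangulated with ``scipy.spatial.Delaunay``.  The computational domain is
the full disk bounded by the outer truncation circle, so the Delaunay convex
hull *is* the domain boundary; hull edges are classified into port planes,
metal wall ends (treated as natural/PEC) and the absorbing arc.  Each
triangle is labelled with the region of its centroid.

Local target size is lambda_material / elements_per_wavelength at the
maximum frequency, with an absolute cap (geometric fidelity in air) and
floor.  Air and metal use a pseudo-permittivity so that refinement scales
cleanly with ``elements_per_wavelength``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .dielectrics import C0, MaterialSet
from .geometry import REGIONS, REGION_MATERIAL, ScenarioGeometry

__all__ = ["Mesh", "generate_mesh", "structured_rectangle_mesh", "region_target_sizes"]

#: effective permittivity used only to set mesh density in field-free regions
_PSEUDO_EPS = {"air": 9.0, "metal": 9.0}

H_CAP = 0.006  # m, absolute cap for geometric fidelity
H_FLOOR = 0.0008  # m, cost guard


class MeshError(RuntimeError):
    pass


@dataclass
class Mesh:
    """Conforming triangle mesh with material labels and boundary edge sets."""

    nodes: np.ndarray  # (N, 2) m
    triangles: np.ndarray  # (M, 3) node indices, positively oriented
    labels: np.ndarray  # (M,) region indices into region_names
    region_names: tuple[str, ...]
    boundary_edges: dict[str, np.ndarray]  # name -> (E, 2) node index pairs

    def __post_init__(self) -> None:
        areas = self.triangle_areas()
        if np.any(areas <= 0):
            raise MeshError("mesh contains non-positively-oriented triangles")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def label_name(self, idx) -> np.ndarray:
        return np.asarray(self.region_names, dtype=object)[idx]

    def export_gmsh(self, path) -> None:
        """Write the mesh in Gmsh v2.2 ASCII format for inspection."""
        with open(path, "w") as fh:
            fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
            fh.write(f"$Nodes\n{self.n_nodes}\n")
            for i, (x, y) in enumerate(self.nodes, start=1):
                fh.write(f"{i} {x:.9g} {y:.9g} 0\n")
            fh.write("$EndNodes\n")
            fh.write(f"$Elements\n{self.n_triangles}\n")
            for i, (tri, lab) in enumerate(zip(self.triangles, self.labels), start=1):
                fh.write(
                    f"{i} 2 2 {lab + 1} {lab + 1} "
                    f"{tri[0] + 1} {tri[1] + 1} {tri[2] + 1}\n"
                )
            fh.write("$EndElements\n")


def region_target_sizes(
    max_frequency: float,
    elements_per_wavelength: int,
    materials: MaterialSet | None = None,
) -> dict[str, float]:
    """Target element size per region: lambda/|sqrt(eps)|/EPW, capped and floored."""
    if elements_per_wavelength < 5:
        raise ValueError("elements_per_wavelength must be >= 5")
    ms = materials if materials is not None else MaterialSet()
    sizes: dict[str, float] = {}
    for region in REGIONS:
        if region in _PSEUDO_EPS:
            n_eff = math.sqrt(_PSEUDO_EPS[region])
        else:
            n_eff = math.sqrt(abs(ms.eps(REGION_MATERIAL[region], max_frequency)))
        lam = C0 / (max_frequency * n_eff)
        sizes[region] = min(max(lam / elements_per_wavelength, H_FLOOR), H_CAP)
    return sizes


def _hex_lattice(h: float, radius: float) -> np.ndarray:
    """Hexagonal lattice covering the disk, mirror-symmetric about both axes."""
    dy = h * math.sqrt(3.0) / 2.0
    rows = int(math.ceil(radius / dy))
    pts = []
    nx = int(math.ceil(radius / h)) + 1
    for j in range(-rows, rows + 1):
        y = j * dy
        if j % 2 == 0:
            xs = np.arange(-nx, nx + 1) * h
        else:
            xs = (np.arange(-nx, nx) + 0.5) * h
        pts.append(np.column_stack([xs, np.full(len(xs), y)]))
    p = np.vstack(pts)
    return p[np.hypot(p[:, 0], p[:, 1]) <= radius]


def _boundary_points(geometry: ScenarioGeometry, h: dict[str, float]):
    """Points on the outer circle plus per-point port/wall/absorbing tags."""
    cfg = geometry.config
    rb = cfg.boundary_radius
    half_ap = math.asin(0.5 * cfg.aperture_width / rb)
    half_wall = math.asin((0.5 * cfg.aperture_width + cfg.wall_thickness) / rb)
    h_port = h["port"]
    h_arc = min(h["air"] * 1.5, H_CAP)

    angles: list[np.ndarray] = []
    for k in range(cfg.n_ports):
        phi = cfg.port_angles[k]
        npt = max(5, int(math.ceil(cfg.aperture_width / h_port)) + 1)
        angles.append(phi + np.linspace(-half_ap, half_ap, npt))
        angles.append(phi + np.array([-half_wall, half_wall]))
        # absorbing arc to the next port
        phi_next = cfg.port_angles[(k + 1) % cfg.n_ports] + (
            2 * np.pi if k + 1 == cfg.n_ports else 0.0
        )
        a0, a1 = phi + half_wall, phi_next - half_wall
        narc = max(3, int(math.ceil((a1 - a0) * rb / h_arc)) + 1)
        angles.append(np.linspace(a0, a1, narc)[1:-1])
    ang = np.concatenate(angles) % (2.0 * np.pi)
    ang = np.unique(np.round(ang, 12))
    pts = rb * np.column_stack([np.cos(ang), np.sin(ang)])

    def classify_mid(a_mid: np.ndarray) -> list[str]:
        tags = []
        for a in a_mid:
            d = np.abs((a - cfg.port_angles + np.pi) % (2 * np.pi) - np.pi)
            kmin = int(np.argmin(d))
            if d[kmin] <= half_ap + 1e-12:
                tags.append(f"port:{kmin}")
            elif d[kmin] <= half_wall + 1e-12:
                tags.append("wall")
            else:
                tags.append("absorbing")
        return tags

    return pts, ang, classify_mid


def generate_mesh(
    geometry: ScenarioGeometry,
    max_frequency: float,
    elements_per_wavelength: int = 8,
    materials: MaterialSet | None = None,
) -> Mesh:
    """Triangulate a head scenario for solution up to ``max_frequency``."""
    h = region_target_sizes(max_frequency, elements_per_wavelength, materials)
    cfg = geometry.config
    rb = cfg.boundary_radius

    bpts, bang, classify_mid = _boundary_points(geometry, h)
    ipts, isp = geometry.interface_points(h)
    # keep interface points inside the domain, clear of the boundary ring
    keep = np.hypot(ipts[:, 0], ipts[:, 1]) < rb - 0.6 * min(h["port"], h["air"])
    ipts, isp = ipts[keep], isp[keep]

    # deduplicate interface points (curve crossings produce near-coincident
    # points); greedy: of any pair closer than 0.45x the finer local spacing,
    # drop the later point
    if len(ipts) > 1:
        pairs = cKDTree(ipts).query_pairs(
            r=float(np.max(isp)) * 0.45, output_type="ndarray"
        )
        drop = np.zeros(len(ipts), dtype=bool)
        for a, b in pairs[np.argsort(pairs[:, 1])]:
            if drop[a] or drop[b]:
                continue
            lim = 0.45 * min(isp[a], isp[b])
            if np.hypot(*(ipts[a] - ipts[b])) < lim:
                drop[max(a, b)] = True
        ipts, isp = ipts[~drop], isp[~drop]

    # background lattices, one per distinct target size
    fixed = np.vstack([bpts, ipts])
    fixed_sp = np.concatenate([np.full(len(bpts), h["port"]), isp])
    fixed_tree = cKDTree(fixed)
    bg_list = []
    for level in sorted(set(h.values())):
        lat = _hex_lattice(level, rb - 0.55 * level)
        if not len(lat):
            continue
        regions = geometry.classify(lat)
        target = np.array([h[REGIONS[r]] for r in regions])
        lat = lat[np.isclose(target, level)]
        if not len(lat):
            continue
        d, j = fixed_tree.query(lat, k=1)
        lat = lat[d > 0.7 * np.minimum(level, fixed_sp[j])]
        if len(lat):
            bg_list.append(lat)
    pts = np.vstack([fixed] + bg_list)

    try:
        tri = Delaunay(pts)
    except Exception as exc:  # pragma: no cover
        raise MeshError(f"triangulation failure: {exc}\n{geometry.to_json()}") from exc

    triangles = tri.simplices.copy()
    nodes = pts
    # orient positively
    p = nodes[triangles]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    flip = area2 < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]
    good = np.abs(area2) > 1e-16
    triangles = triangles[good]

    labels = geometry.classify(nodes[triangles].mean(axis=1)).astype(np.int16)

    # boundary (convex hull) edges, classified by midpoint angle
    hull = tri.convex_hull
    mids = nodes[hull].mean(axis=1)
    a_mid = np.arctan2(mids[:, 1], mids[:, 0]) % (2 * np.pi)
    tags = classify_mid(a_mid)
    boundary_edges: dict[str, list] = {}
    for edge, tag in zip(hull, tags):
        if tag == "wall":
            continue  # metal wall end: natural (PEC) boundary
        boundary_edges.setdefault(tag, []).append(edge)
    out_edges = {k: np.asarray(v, dtype=int) for k, v in boundary_edges.items()}

    return Mesh(
        nodes=nodes,
        triangles=triangles,
        labels=labels,
        region_names=REGIONS,
        boundary_edges=out_edges,
    )


def structured_rectangle_mesh(
    length: float,
    width: float,
    h: float,
    region: str = "port",
    left: str | None = "port:0",
    right: str | None = "port:1",
) -> Mesh:
    """Structured right-triangle mesh of ``[0, length] x [0, width]``.

    The left/right edges can be tagged as port planes (or ``None`` for a
    natural/PEC termination); the long walls are natural (PEC).  Used for
    waveguide verification against the closed-form dispersion relation.
    """
    nx = max(2, int(round(length / h)) + 1)
    ny = max(2, int(round(width / h)) + 1)
    xs = np.linspace(0.0, length, nx)
    ys = np.linspace(0.0, width, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * ny + j

    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            n00, n10 = nid(i, j), nid(i + 1, j)
            n01, n11 = nid(i, j + 1), nid(i + 1, j + 1)
            tris.append([n00, n10, n11])
            tris.append([n00, n11, n01])
    triangles = np.asarray(tris, dtype=int)
    labels = np.full(len(triangles), REGIONS.index(region), dtype=np.int16)

    boundary_edges: dict[str, np.ndarray] = {}
    left_edges = [[nid(0, j), nid(0, j + 1)] for j in range(ny - 1)]
    right_edges = [[nid(nx - 1, j), nid(nx - 1, j + 1)] for j in range(ny - 1)]
    if left is not None:
        boundary_edges[left] = np.asarray(left_edges, dtype=int)
    if right is not None:
        boundary_edges[right] = np.asarray(right_edges, dtype=int)

    return Mesh(
        nodes=nodes,
        triangles=triangles,
        labels=labels,
        region_names=REGIONS,
        boundary_edges=boundary_edges,
    )
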