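"""Parametric L4-L5 intervertebral-disc geometry and hexahedral meshing.

The disc is an extruded elliptical cylinder (flat endplates) partitioned into
a nucleus pulposus (NP) core and an annulus fibrosus (AF) ring. The NP is a
similar ellipse scaled so that its cross-section area -- and hence, for an
extrusion, its volume -- equals the requested volume fraction (default 44%),
and is shifted posteriorly relative to the geometric disc center. The AF is
split radially into ``n_af_layers`` layers of equal local thickness
(layer 1 = outermost) and circumferentially into ``n_subregions`` equal
angular sectors from the anterior to the posterior midline, mirrored
left/right (A = anterior ... E = posterior).

Meshing uses a butterfly (O-grid) topology: a transfinite-interpolated core
block inside the NP, surrounded by structured rings out to the disc boundary,
extruded in ``z``. All elements are 8-node hexahedra.

Coordinate convention (fixed for the whole package): x = left-lateral,
y = posterior, z = cranial; the disc occupies z in [0, disc_height]. Load
cases apply pure moments about x (flexion +, extension -), y (lateral
bending) and z (axial rotation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscGeometryParams",
    "RegionLabel",
    "HexMesh",
    "GeometryError",
    "build_disc",
    "region_volume_fractions",
    "mesh_convergence_study",
    "hex_volumes",
    "write_vtk",
    "write_text_mesh",
]

SUBREGION_LETTERS = "ABCDE"


class GeometryError(ValueError):
    """Infeasible geometry parameter combination."""


@dataclass(frozen=True)
class DiscGeometryParams:
    """Disc geometry and meshing parameters (lengths in mm).

    ``lateral_width`` and ``ap_depth`` are literature-plausible defaults for
    an average L4-L5 disc, not measured values; ``disc_height`` = 14 mm and
    ``np_volume_fraction`` = 0.44 follow established average-geometry models.
    """

    disc_height: float = 14.0
    lateral_width: float = 50.0
    ap_depth: float = 36.0
    np_volume_fraction: float = 0.44
    np_posterior_offset: float = 1.5
    n_af_layers: int = 5
    n_subregions: int = 5
    mesh_density: int = 1
    # fine-grained mesh overrides (None -> derived from mesh_density)
    n_theta: int | None = None
    n_z: int | None = None
    n_np_rings: int | None = None
    n_af_radial: int | None = None

    def __post_init__(self):
        if self.disc_height <= 0 or self.lateral_width <= 0 or self.ap_depth <= 0:
            raise ValueError("disc dimensions must be positive")
        if not 0.0 < self.np_volume_fraction < 1.0:
            raise ValueError("np_volume_fraction must lie in (0, 1)")
        if self.np_posterior_offset < 0:
            raise ValueError("np_posterior_offset must be non-negative")
        if self.n_af_layers < 1 or self.n_subregions < 1:
            raise ValueError("need at least one AF layer and one subregion")
        if self.n_subregions > len(SUBREGION_LETTERS):
            raise ValueError("at most five subregions are supported")
        if self.mesh_density < 1:
            raise ValueError("mesh_density must be a positive integer")

    def resolved(self):
        """Resolved mesh discretization (n_theta, n_z, n_np_rings, n_af_radial)."""
        d = self.mesh_density
        nt = self.n_theta if self.n_theta is not None else 16 * d
        nz = self.n_z if self.n_z is not None else 2 * d
        nnp = self.n_np_rings if self.n_np_rings is not None else 2 * d
        naf = self.n_af_radial if self.n_af_radial is not None else d
        if nt % 8 != 0:
            raise ValueError("n_theta must be a multiple of 8 (O-grid corners)")
        if nz < 2:
            raise ValueError("n_z must be >= 2 (one free node plane is required)")
        return nt, nz, nnp, naf

    @classmethod
    def from_dict(cls, d: dict) -> "DiscGeometryParams":
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class RegionLabel:
    """Region tag of one element: NP, or AF with (layer, subregion).

    ``layer`` runs 1..n_af_layers with 1 the outermost layer; ``subregion``
    is a letter A (anterior) .. E (posterior).
    """

    kind: str  # "NP" | "AF"
    layer: int | None = None
    subregion: str | None = None

    def __post_init__(self):
        if self.kind == "NP":
            if self.layer is not None or self.subregion is not None:
                raise ValueError("NP labels carry no layer/subregion")
        elif self.kind == "AF":
            if self.layer is None or self.subregion is None:
                raise ValueError("AF labels need layer and subregion")
        else:
            raise ValueError("kind must be 'NP' or 'AF'")


class HexMesh:
    """Hexahedral mesh with per-element region labels.

    Attributes
    ----------
    node_coords : (N, 3) float array, mm
    elements : (E, 8) int array, trilinear hex connectivity (VTK ordering)
    region_kind : (E,) array of 0 (NP) / 1 (AF)
    region_layer : (E,) int array (0 for NP)
    region_subregion : (E,) int array (subregion index, -1 for NP)
    """

    def __init__(self, node_coords, elements, region_kind, region_layer,
                 region_subregion, metadata=None):
        self.node_coords = np.asarray(node_coords, dtype=float)
        self.elements = np.asarray(elements, dtype=np.int64)
        self.region_kind = np.asarray(region_kind, dtype=np.int8)
        self.region_layer = np.asarray(region_layer, dtype=np.int16)
        self.region_subregion = np.asarray(region_subregion, dtype=np.int16)
        self.metadata = metadata or {}
        if self.elements.max() >= len(self.node_coords) or self.elements.min() < 0:
            raise ValueError("element connectivity indices out of range")

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def element_regions(self) -> list[RegionLabel]:
        labels = []
        for k, lay, sub in zip(self.region_kind, self.region_layer,
                               self.region_subregion):
            if k == 0:
                labels.append(RegionLabel("NP"))
            else:
                labels.append(RegionLabel("AF", int(lay), SUBREGION_LETTERS[sub]))
        return labels

    def nodes_at_z(self, z: float, tol: float = 1e-9) -> np.ndarray:
        return np.where(np.abs(self.node_coords[:, 2] - z) < tol)[0]

    def top_nodes(self) -> np.ndarray:
        return self.nodes_at_z(self.node_coords[:, 2].max())

    def bottom_nodes(self) -> np.ndarray:
        return self.nodes_at_z(self.node_coords[:, 2].min())


# Gauss points of the trilinear hex (2x2x2) and shape-function helpers -------

_GP1 = 1.0 / np.sqrt(3.0)
HEX_GAUSS = np.array(
    [[sx * _GP1, sy * _GP1, sz * _GP1]
     for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]
)
# natural coordinates of the 8 nodes (VTK ordering)
HEX_XI = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    dtype=float,
)


def hex_shape_grad(xi) -> np.ndarray:
    """dN/dxi, shape (n_pts, 8, 3), for points xi of shape (n_pts, 3)."""
    xi = np.atleast_2d(xi)
    g = np.empty((len(xi), 8, 3))
    for n in range(8):
        a, b, c = HEX_XI[n]
        g[:, n, 0] = 0.125 * a * (1 + b * xi[:, 1]) * (1 + c * xi[:, 2])
        g[:, n, 1] = 0.125 * b * (1 + a * xi[:, 0]) * (1 + c * xi[:, 2])
        g[:, n, 2] = 0.125 * c * (1 + a * xi[:, 0]) * (1 + b * xi[:, 1])
    return g


def hex_volumes(mesh: HexMesh) -> np.ndarray:
    """Element volumes by 8-point Gauss quadrature; errors on degeneracy."""
    X = mesh.node_coords[mesh.elements]  # (E, 8, 3)
    grads = hex_shape_grad(HEX_GAUSS)  # (8gp, 8, 3)
    J = np.einsum("eni,gnj->egij", X, grads)  # dX/dxi
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        bad = int(np.argwhere(np.any(detJ <= 0, axis=1))[0, 0])
        raise GeometryError(
            f"element {bad} has non-positive Jacobian (degenerate or inverted)"
        )
    return detJ.sum(axis=1)


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------


def _subregion_index(xy_centroids: np.ndarray, n_sub: int) -> np.ndarray:
    """Subregion index from the angle off the anterior (-y) midline, mirrored."""
    x, y = xy_centroids[:, 0], xy_centroids[:, 1]
    phi = np.arctan2(np.abs(x), -y)  # 0 at anterior, pi at posterior
    idx = np.minimum((phi / (np.pi / n_sub)).astype(int), n_sub - 1)
    return idx


def build_disc(params: DiscGeometryParams):
    """Build the disc mesh and loading reference points.

    Returns ``(mesh, ref_points)`` where ``ref_points`` is a dict with the
    load point 10 mm above the top-surface centroid and the fixation point
    10 mm below the bottom surface.
    """
    nt, nz, n_np, n_af = params.resolved()
    a = params.lateral_width / 2.0
    b = params.ap_depth / 2.0
    s = np.sqrt(params.np_volume_fraction)
    np_center = np.array([0.0, params.np_posterior_offset])
    h = params.disc_height
    n_layers = params.n_af_layers

    theta = 2.0 * np.pi * np.arange(nt) / nt
    outer = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
    np_ring = np_center + np.column_stack([s * a * np.cos(theta),
                                           s * b * np.sin(theta)])
    # feasibility: NP boundary strictly inside the outer ellipse
    enorm = (np_ring[:, 0] / a) ** 2 + (np_ring[:, 1] / b) ** 2
    if np.any(enorm >= 0.98):
        raise GeometryError(
            "NP boundary reaches the outer disc surface: requested "
            "np_volume_fraction is unreachable with this posterior offset"
        )

    # core block boundary: square mapped onto ring angles, at half NP size
    denom = np.maximum(np.abs(np.cos(theta)), np.abs(np.sin(theta)))
    core_b = np_center + 0.5 * np.column_stack(
        [s * a * np.cos(theta) / denom, s * b * np.sin(theta) / denom]
    )

    m = nt // 4  # grid cells per core-square side
    c1, c2, c3, c4 = nt // 8, 3 * nt // 8, 5 * nt // 8, 7 * nt // 8

    def core_boundary_ring_index(i: int, j: int) -> int:
        if j == m:
            return c2 - i
        if j == 0:
            return c3 + i
        if i == 0:
            return c3 - j
        if i == m:
            return (c4 + j) % nt
        raise AssertionError

    # transfinite (Coons) interpolation for core interior nodes
    T = core_b[[c2 - i for i in range(m + 1)]]
    B = core_b[[c3 + i for i in range(m + 1)]]
    L = core_b[[c3 - j for j in range(m + 1)]]
    R = core_b[[(c4 + j) % nt for j in range(m + 1)]]
    fi = np.arange(m + 1) / m
    fj = np.arange(m + 1) / m
    core_grid = (
        (1 - fj)[None, :, None] * B[:, None, :]
        + fj[None, :, None] * T[:, None, :]
        + (1 - fi)[:, None, None] * L[None, :, :]
        + fi[:, None, None] * R[None, :, :]
        - np.einsum("i,j,k->ijk", 1 - fi, 1 - fj, B[0])
        - np.einsum("i,j,k->ijk", fi, 1 - fj, B[m])
        - np.einsum("i,j,k->ijk", 1 - fi, fj, T[0])
        - np.einsum("i,j,k->ijk", fi, fj, T[m])
    )  # (m+1, m+1, 2), indexed [i, j]

    n_rings = n_np + n_layers * n_af  # radial cell count outside the core
    plane_interior = (m - 1) ** 2
    plane_size = plane_interior + (n_rings + 1) * nt

    # node coordinates for one plane
    plane_xy = np.empty((plane_size, 2))
    idx = 0
    for i in range(1, m):
        for j in range(1, m):
            plane_xy[idx] = core_grid[i, j]
            idx += 1
    for r in range(n_rings + 1):
        if r <= n_np:
            t = r / n_np
            ring = (1 - t) * core_b + t * np_ring
        else:
            t = (r - n_np) / (n_layers * n_af)
            ring = (1 - t) * np_ring + t * outer
        plane_xy[idx: idx + nt] = ring
        idx += nt

    def interior_id(i, j):
        return (i - 1) * (m - 1) + (j - 1)

    def ring_id(r, k):
        return plane_interior + r * nt + (k % nt)

    def core_node(i, j):
        if 0 < i < m and 0 < j < m:
            return interior_id(i, j)
        return ring_id(0, core_boundary_ring_index(i, j))

    nodes = np.empty(((nz + 1) * plane_size, 3))
    for iz in range(nz + 1):
        nodes[iz * plane_size: (iz + 1) * plane_size, :2] = plane_xy
        nodes[iz * plane_size: (iz + 1) * plane_size, 2] = h * iz / nz

    # element connectivity (per plane quads, extruded)
    quads = []
    quad_region = []  # (kind, ring_cell r or -1)
    for i in range(m):
        for j in range(m):
            quads.append([core_node(i, j), core_node(i + 1, j),
                          core_node(i + 1, j + 1), core_node(i, j + 1)])
            quad_region.append(-1)
    for r in range(n_rings):
        for k in range(nt):
            quads.append([ring_id(r, k), ring_id(r + 1, k),
                          ring_id(r + 1, k + 1), ring_id(r, k + 1)])
            quad_region.append(r)
    quads = np.asarray(quads, dtype=np.int64)
    quad_region = np.asarray(quad_region)

    elems = np.empty((nz * len(quads), 8), dtype=np.int64)
    for iz in range(nz):
        lo, hi = iz * plane_size, (iz + 1) * plane_size
        blk = slice(iz * len(quads), (iz + 1) * len(quads))
        elems[blk, :4] = quads + lo
        elems[blk, 4:] = quads + hi

    # region labels
    ring_cell = np.tile(quad_region, nz)
    is_af = ring_cell >= n_np
    kind = is_af.astype(np.int8)
    layer = np.zeros(len(elems), dtype=np.int16)
    layer[is_af] = n_layers - (ring_cell[is_af] - n_np) // n_af
    centroids = nodes[elems].mean(axis=1)
    sub = np.full(len(elems), -1, dtype=np.int16)
    sub[is_af] = _subregion_index(centroids[is_af, :2], params.n_subregions)

    # quad faces on the outer boundary surface of each AF layer (for rebar
    # membranes); oriented with outward normal
    layer_surface = {}
    for lay in range(1, n_layers + 1):
        r_out = n_np + (n_layers - lay + 1) * n_af  # outer ring of this layer
        faces = []
        for iz in range(nz):
            lo, hi = iz * plane_size, (iz + 1) * plane_size
            for k in range(nt):
                faces.append([ring_id(r_out, k) + lo, ring_id(r_out, k + 1) + lo,
                              ring_id(r_out, k + 1) + hi, ring_id(r_out, k) + hi])
        layer_surface[lay] = np.asarray(faces, dtype=np.int64)

    mesh = HexMesh(
        nodes, elems, kind, layer, sub,
        metadata={
            "params": params,
            "layer_surface_quads": layer_surface,
            "n_theta": nt, "n_z": nz,
            "np_center": np.array([np_center[0], np_center[1], h / 2.0]),
            "np_half_width": s * a,
        },
    )
    hex_volumes(mesh)  # raises GeometryError on inverted/degenerate elements

    top_c = np.array([0.0, 0.0, h])
    ref_points = {
        "load": top_c + np.array([0.0, 0.0, 10.0]),
        "fix": np.array([0.0, 0.0, -10.0]),
    }
    return mesh, ref_points


def region_volume_fractions(mesh: HexMesh) -> dict:
    """Volume fraction of NP and AF; fractions sum to 1 (within roundoff)."""
    vols = hex_volumes(mesh)
    total = vols.sum()
    np_vol = vols[mesh.region_kind == 0].sum()
    return {"NP": np_vol / total, "AF": (total - np_vol) / total}


def mesh_convergence_study(params: DiscGeometryParams, density_levels,
                           element_order: int = 1,
                           moment_nm: float = 5.0,
                           material_config=None,
                           n_increments: int = 2,
                           newton_tol: float = 1e-5):
    """Flexion range of motion at 5 Nm across mesh refinement levels.

    Returns a pandas DataFrame with one row per density level: node count,
    element count, RoM (degrees) and solver statistics. Materials default
    to the literature medians (HGO fiber model). The residual tolerance is
    slightly relaxed by default: inter-density RoM differences are O(1%),
    far above the equilibrium error at 1e-5.
    """
    import pandas as pd

    from . import model as _model
    from .solver import LOAD_CASES, SolveSettings, solve_static

    if element_order != 1:
        raise NotImplementedError("only 8-node (order 1) hexahedra are supported")
    if len(density_levels) < 2:
        raise ValueError("need at least two density levels")
    if material_config is None:
        material_config = _model.MaterialConfig.median("hgo")

    rows = []
    for d in sorted(float(x) for x in density_levels):
        # fractional levels interpolate the integer refinement rule
        # (n_theta = 16 d, n_z = 2 d, ... rounded to admissible values)
        p = dataclasses.replace(
            params, mesh_density=1,
            n_theta=8 * max(2, round(2 * d)),
            n_z=max(2, round(2 * d)),
            n_np_rings=max(1, round(2 * d)),
            n_af_radial=max(1, round(d)))
        disc = _model.build_disc_model(p, material_config)
        settings = SolveSettings(max_moment=moment_nm * 1000.0,
                                 n_increments=n_increments,
                                 newton_tol=newton_tol)
        res = solve_static(disc, LOAD_CASES["flexion"], settings)
        if not res.converged[-1]:
            rows.append({"density": d, "nodes": disc.mesh.n_nodes,
                         "elements": disc.mesh.n_elements,
                         "rom_deg": np.nan, "converged": False,
                         "newton_iters": res.stats.get("newton_iters", -1)})
            continue
        rows.append({"density": d, "nodes": disc.mesh.n_nodes,
                     "elements": disc.mesh.n_elements,
                     "rom_deg": res.rom[-1], "converged": True,
                     "newton_iters": res.stats.get("newton_iters", -1)})
    df = pd.DataFrame(rows)
    finest = df.loc[df["density"].idxmax(), "rom_deg"]
    df["deviation_pct"] = 100.0 * np.abs(df["rom_deg"] - finest) / abs(finest)
    return df


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_vtk(mesh: HexMesh, path, cell_data: dict | None = None,
              cell_vectors: dict | None = None,
              point_vectors: dict | None = None) -> None:
    """Write a legacy-ASCII VTK unstructured grid with region cell data.

    ``cell_vectors`` (e.g. fiber directions) and ``point_vectors`` (e.g.
    displacements) are optional named (N, 3) arrays.
    """
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nivdfem disc mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.node_coords, fmt="%.9g")
        E = mesh.n_elements
        f.write(f"CELLS {E} {E * 9}\n")
        np.savetxt(f, np.column_stack([np.full(E, 8), mesh.elements]), fmt="%d")
        f.write(f"CELL_TYPES {E}\n")
        np.savetxt(f, np.full(E, 12), fmt="%d")
        f.write(f"CELL_DATA {E}\n")
        data = {"region_kind": mesh.region_kind,
                "af_layer": mesh.region_layer,
                "af_subregion": mesh.region_subregion}
        data.update(cell_data or {})
        for name, arr in data.items():
            arr = np.asarray(arr)
            dtype = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
            fmt = "%d" if dtype == "int" else "%.9g"
            f.write(f"SCALARS {name} {dtype} 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, arr, fmt=fmt)
        for name, arr in (cell_vectors or {}).items():
            f.write(f"VECTORS {name} double\n")
            np.savetxt(f, np.asarray(arr), fmt="%.9g")
        if point_vectors:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_vectors.items():
                f.write(f"VECTORS {name} double\n")
                np.savetxt(f, np.asarray(arr), fmt="%.9g")


def write_text_mesh(mesh: HexMesh, path) -> None:
    """Plain-text node/element format: coordinates, connectivity, labels."""
    with open(path, "w") as f:
        f.write(f"# ivdfem mesh: {mesh.n_nodes} nodes, {mesh.n_elements} hexes\n")
        f.write("NODES\n")
        for i, xyz in enumerate(mesh.node_coords):
            f.write(f"{i} {xyz[0]:.9g} {xyz[1]:.9g} {xyz[2]:.9g}\n")
        f.write("ELEMENTS kind layer subregion n1..n8\n")
        for e in range(mesh.n_elements):
            kind = "NP" if mesh.region_kind[e] == 0 else "AF"
            sub = ("-" if mesh.region_subregion[e] < 0
                   else SUBREGION_LETTERS[mesh.region_subregion[e]])
            conn = " ".join(str(n) for n in mesh.elements[e])
            f.write(f"{e} {kind} {mesh.region_layer[e]} {sub} {conn}\n")
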