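"""Triangular deme grids and sample-to-deme assignment.

The spatial substrate of the model is a triangular lattice of demes.  In
planar mode the lattice is a regular triangular grid in km coordinates
(rows offset by half the spacing, row height spacing*sqrt(3)/2).  In
spherical mode it is an icosahedral geodesic subdivision of the sphere at
the frequency whose mean edge length is closest to the requested spacing,
with vertices in lon/lat degrees.  Either grid is clipped to a region
(bounding box or polygon) and reduced to its largest connected component,
since disconnected fragments would make resistance distances infinite.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from shapely.geometry import Point, Polygon, box, shape

EARTH_RADIUS_KM = 6371.0

#: Deme spacings (km) used for continental-scale panels, coarse to fine.
PRESET_SPACINGS_KM = (500.0, 240.0, 120.0)


def haversine_km(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix (km) between lon/lat arrays (degrees)."""
    a = np.radians(np.atleast_2d(a))
    b = np.radians(np.atleast_2d(b))
    lon1, lat1 = a[:, 0][:, None], a[:, 1][:, None]
    lon2, lat2 = b[:, 0][None, :], b[:, 1][None, :]
    h = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclasses.dataclass
class DemeGraph:
    """Triangular lattice of demes.

    Attributes
    ----------
    coords:
        ``(V, 2)`` vertex coordinates — km in planar mode, lon/lat degrees
        in spherical mode.
    edges:
        ``(E, 2)`` int array of undirected vertex pairs, each with u < v.
    spacing_km:
        Nominal inter-deme distance.
    mode:
        ``"planar"`` or ``"spherical"``.
    """

    coords: np.ndarray
    edges: np.ndarray
    spacing_km: float
    mode: str = "planar"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.mode not in ("planar", "spherical"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if (self.edges[:, 0] == self.edges[:, 1]).any():
            raise ValueError("self-loop edge")
        self.edges = np.sort(self.edges, axis=1)
        if len(np.unique(self.edges, axis=0)) != len(self.edges):
            raise ValueError("duplicate edges")

    @property
    def n_vertices(self) -> int:
        return len(self.coords)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def distance_matrix(self, points: np.ndarray | None = None) -> np.ndarray:
        """Distances from ``points`` (default: vertices) to all vertices."""
        pts = self.coords if points is None else np.atleast_2d(points)
        if self.mode == "spherical":
            return haversine_km(pts, self.coords)
        return cdist(pts, self.coords)

    def edge_lengths(self) -> np.ndarray:
        u, v = self.edges.T
        if self.mode == "spherical":
            d = haversine_km(self.coords[u], self.coords[v])
            return np.diag(d) if d.ndim == 2 else d
        return np.linalg.norm(self.coords[u] - self.coords[v], axis=1)

    def adjacency(self) -> coo_matrix:
        u, v = self.edges.T
        n = self.n_vertices
        data = np.ones(2 * len(u))
        return coo_matrix((data, (np.r_[u, v], np.r_[v, u])), shape=(n, n))

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()

    def is_connected(self) -> bool:
        if self.n_vertices == 0:
            return False
        n_comp, _ = connected_components(self.adjacency(), directed=False)
        return n_comp == 1

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mode": self.mode,
            "spacing_km": self.spacing_km,
            "vertices": self.coords.tolist(),
            "edges": self.edges.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "DemeGraph":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["vertices"]),
            np.array(d["edges"]),
            d["spacing_km"],
            d["mode"],
        )


@dataclasses.dataclass
class SampleAssignment:
    """Mapping sample -> deme vertex, with per-vertex occupancy counts."""

    vertex_of_sample: np.ndarray  # (n,) int
    counts: np.ndarray  # (V,) int

    @property
    def observed_vertices(self) -> np.ndarray:
        """Sorted vertex indices that hold at least one sample."""
        return np.flatnonzero(self.counts > 0)


def _as_polygon(region) -> Polygon:
    if isinstance(region, Polygon):
        return region
    if isinstance(region, dict):  # GeoJSON geometry
        return shape(region)
    region = np.asarray(region, dtype=float).ravel()
    if region.size == 4:  # (minx, miny, maxx, maxy)
        return box(*region)
    raise ValueError("region must be a Polygon, GeoJSON dict, or 4-number bbox")


def _triangular_lattice(poly: Polygon, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    minx, miny, maxx, maxy = poly.bounds
    row_h = spacing * np.sqrt(3) / 2
    n_rows = int(np.floor((maxy - miny) / row_h + 1e-9)) + 1
    pts = []
    for j in range(n_rows):
        y = miny + j * row_h
        x0 = minx + (spacing / 2 if j % 2 else 0.0)
        n_cols = int(np.floor((maxx - x0) / spacing + 1e-9)) + 1
        for i in range(n_cols):
            pts.append((x0 + i * spacing, y))
    pts = np.array(pts)
    keep = np.array([poly.intersects(Point(*p)) for p in pts])
    pts = pts[keep]
    if len(pts) < 2:
        raise ValueError("region too small to contain at least 2 demes")
    d = cdist(pts, pts)
    iu, iv = np.nonzero(np.triu(d <= spacing * 1.01, k=1))
    return pts, np.c_[iu, iv]


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1 + np.sqrt(5)) / 2
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts[0])
    faces = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ]
    )
    return verts, faces


def _geodesic_sphere(freq: int) -> tuple[np.ndarray, np.ndarray]:
    """Class-I geodesic subdivision: each icosa face split into freq^2 triangles."""
    verts, faces = _icosahedron()
    vert_index: dict[tuple, int] = {}
    points: list[np.ndarray] = []
    edges: set[tuple[int, int]] = set()

    def get_index(p: np.ndarray) -> int:
        p = p / np.linalg.norm(p)
        key = tuple(np.round(p, 9))
        if key not in vert_index:
            vert_index[key] = len(points)
            points.append(p)
        return vert_index[key]

    for a, b, c in faces:
        A, B, C = verts[a], verts[b], verts[c]
        # barycentric lattice on the face
        idx = {}
        for i in range(freq + 1):
            for j in range(freq + 1 - i):
                k = freq - i - j
                p = (i * A + j * B + k * C) / freq
                idx[(i, j)] = get_index(p)
        for i in range(freq):
            for j in range(freq - i):
                v0, v1, v2 = idx[(i, j)], idx[(i + 1, j)], idx[(i, j + 1)]
                for e in ((v0, v1), (v0, v2), (v1, v2)):
                    edges.add(tuple(sorted(e)))
    return np.array(points), np.array(sorted(edges))


def _xyz_to_lonlat(xyz: np.ndarray) -> np.ndarray:
    lon = np.degrees(np.arctan2(xyz[:, 1], xyz[:, 0]))
    lat = np.degrees(np.arcsin(np.clip(xyz[:, 2], -1, 1)))
    return np.c_[lon, lat]


def _geodesic_frequency(spacing_km: float) -> int:
    # icosahedron edge arc = atan(2) rad; subdividing at frequency f gives
    # edges of roughly that arc / f
    edge_km = EARTH_RADIUS_KM * np.arctan(2.0)
    return max(1, int(round(edge_km / spacing_km)))


def largest_component(coords: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Restrict a vertex/edge set to its largest connected component."""
    n = len(coords)
    if len(edges) == 0:
        raise ValueError("grid has no edges after clipping")
    adj = coo_matrix(
        (np.ones(2 * len(edges)), (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n, n),
    )
    _, labels = connected_components(adj, directed=False)
    keep_label = np.bincount(labels).argmax()
    keep = np.flatnonzero(labels == keep_label)
    remap = -np.ones(n, dtype=int)
    remap[keep] = np.arange(len(keep))
    mask = np.isin(edges[:, 0], keep) & np.isin(edges[:, 1], keep)
    return coords[keep], remap[edges[mask]]


def build_grid(region, spacing_km: float, mode: str = "planar") -> DemeGraph:
    """Build a triangular deme grid over ``region``.

    Parameters
    ----------
    region:
        Bounding box ``(minx, miny, maxx, maxy)``, shapely Polygon, or
        GeoJSON geometry dict.  Planar coordinates are km; spherical are
        lon/lat degrees.
    spacing_km:
        Nominal inter-deme distance; continental panels typically use one
        of :data:`PRESET_SPACINGS_KM`.
    mode:
        ``"planar"`` (regular lattice) or ``"spherical"`` (icosahedral
        geodesic subdivision).
    """
    if spacing_km <= 0:
        raise ValueError("spacing_km must be positive")
    poly = _as_polygon(region)
    if poly.is_empty or poly.area <= 0:
        raise ValueError("region is degenerate")
    if mode == "planar":
        pts, edges = _triangular_lattice(poly, spacing_km)
    elif mode == "spherical":
        freq = _geodesic_frequency(spacing_km)
        xyz, all_edges = _geodesic_sphere(freq)
        lonlat = _xyz_to_lonlat(xyz)
        keep = np.array([poly.intersects(Point(*p)) for p in lonlat])
        keep_idx = np.flatnonzero(keep)
        remap = -np.ones(len(lonlat), dtype=int)
        remap[keep_idx] = np.arange(len(keep_idx))
        mask = keep[all_edges[:, 0]] & keep[all_edges[:, 1]]
        pts, edges = lonlat[keep_idx], remap[all_edges[mask]]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(pts) < 2:
        raise ValueError("region too small to contain at least 2 demes")
    pts, edges = largest_component(pts, edges)
    if len(pts) < 2:
        raise ValueError("region too small to contain at least 2 demes")
    return DemeGraph(pts, edges, spacing_km, mode)


def assign_samples(coords: np.ndarray, graph: DemeGraph,
                   sample_ids: Sequence | None = None) -> SampleAssignment:
    """Assign each sample to its nearest deme vertex.

    Nearest is great-circle distance in spherical mode, Euclidean in planar
    mode; exact ties go to the lowest vertex index.  The rule is
    unconditional: samples outside the clipped region still map to the
    nearest retained vertex.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    bad = np.flatnonzero(~np.isfinite(coords).all(axis=1))
    if bad.size:
        name = sample_ids[bad[0]] if sample_ids is not None else bad[0]
        raise ValueError(f"non-finite coordinate for sample {name!r}")
    if graph.n_vertices == 0:
        raise ValueError("empty graph")
    d = graph.distance_matrix(coords)
    vertex = d.argmin(axis=1)  # argmin takes the lowest index on ties
    counts = np.bincount(vertex, minlength=graph.n_vertices)
    return SampleAssignment(vertex, counts)
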