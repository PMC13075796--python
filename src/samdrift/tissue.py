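"""Fixed 2D meristem tissue templates.

A tissue is a dome-shaped longitudinal section of a shoot apical meristem,
tessellated into cells.  Cell centres are first spread by relaxing a
spring network (springs connect Delaunay neighbours; a boundary penalty
keeps cells inside the dome), then regularized by Lloyd's algorithm on the
Voronoi diagram.  The final Voronoi polygons (clipped to the dome), their
areas and shared-edge lengths are stored and never change during
development.

Cells are labelled by zone (central zone CZ, organizing centre OC, their
overlap, or "other") via centroid-in-box tests, and the epidermal L1 layer
is marked as the set of cells whose polygon touches the curved dome
surface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, Voronoi
from shapely.geometry import Polygon, Point

from .config import TissueConfig, FitnessConfig

log = logging.getLogger(__name__)

TISSUE_FORMAT_VERSION = 1

ZONES = ("CZ", "CZ_OC", "OC", "other")


@dataclass
class Cell:
    centroid: tuple[float, float]
    polygon: np.ndarray  # (k, 2) vertex array, closed implicitly
    area: float
    zone: str = "other"
    is_l1: bool = False


@dataclass
class Tissue:
    cells: list[Cell]
    #: adjacency as an edge list: (i, j, omega) with i < j, omega the shared
    #: Voronoi edge length.
    edges: list[tuple[int, int, float]]
    config: TissueConfig = field(default_factory=TissueConfig)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([c.centroid for c in self.cells])

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.cells])

    @property
    def l1_mask(self) -> np.ndarray:
        return np.array([c.is_l1 for c in self.cells], dtype=bool)

    @property
    def zones(self) -> list[str]:
        return [c.zone for c in self.cells]

    def neighbour_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Adjacency in CSR form: (indptr, neighbour index, edge length)."""
        n = self.n_cells
        nbrs: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for i, j, w in self.edges:
            nbrs[i].append((j, w))
            nbrs[j].append((i, w))
        indptr = np.zeros(n + 1, dtype=np.int64)
        idx, wts = [], []
        for c in range(n):
            for j, w in sorted(nbrs[c]):
                idx.append(j)
                wts.append(w)
            indptr[c + 1] = len(idx)
        return indptr, np.asarray(idx, dtype=np.int64), np.asarray(wts)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": TISSUE_FORMAT_VERSION,
            "cells": [
                {
                    "centroid": list(map(float, c.centroid)),
                    "polygon": np.asarray(c.polygon, dtype=float).tolist(),
                    "area": float(c.area),
                    "zone": c.zone,
                    "is_l1": bool(c.is_l1),
                }
                for c in self.cells
            ],
            "edges": [[int(i), int(j), float(w)] for i, j, w in self.edges],
        }

    @classmethod
    def from_dict(cls, d: dict, config: TissueConfig | None = None) -> "Tissue":
        cells = [
            Cell(
                centroid=tuple(c["centroid"]),
                polygon=np.asarray(c["polygon"], dtype=float),
                area=c["area"],
                zone=c["zone"],
                is_l1=c["is_l1"],
            )
            for c in d["cells"]
        ]
        edges = [(i, j, w) for i, j, w in d["edges"]]
        return cls(cells=cells, edges=edges, config=config or TissueConfig())

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "Tissue":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Dome geometry
# ---------------------------------------------------------------------------

def dome_profile(x: np.ndarray, cfg: TissueConfig) -> np.ndarray:
    """Height of the dome surface above the base at abscissa x."""
    return cfg.height - cfg.curvature * np.asarray(x) ** 2


def dome_polygon(cfg: TissueConfig, n_arc: int = 240) -> Polygon:
    xs = np.linspace(-cfg.x_max, cfg.x_max, n_arc)
    arc = np.column_stack([xs, dome_profile(xs, cfg)])
    # close along the base from right to left
    ring = np.vstack([arc, [[cfg.x_max, 0.0], [-cfg.x_max, 0.0]]])
    return Polygon(ring)


def _sample_in_dome(rng: np.random.Generator, n: int, cfg: TissueConfig) -> np.ndarray:
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        x = rng.uniform(-cfg.x_max, cfg.x_max, size=2 * n)
        y = rng.uniform(0.0, cfg.height, size=2 * n)
        ok = y <= dome_profile(x, cfg)
        take = min(n - got, int(ok.sum()))
        pts[got: got + take] = np.column_stack([x[ok], y[ok]])[:take]
        got += take
    return pts


def domain_area(cfg: TissueConfig) -> float:
    # integral of (h - c x^2) over [-x_max, x_max]
    return 2 * (cfg.height * cfg.x_max - cfg.curvature * cfg.x_max**3 / 3)


# ---------------------------------------------------------------------------
# Spring relaxation
# ---------------------------------------------------------------------------

def spring_energy(l: float, l_r: float, k: float) -> float:
    """Potential energy of one spring: U = 1/2 (l - l_r)^2 k."""
    return 0.5 * (l - l_r) ** 2 * k


def _boundary_force(pts: np.ndarray, cfg: TissueConfig) -> np.ndarray:
    """Constant-magnitude inward restoring force on cells outside the dome.

    The boundary term penalizes the penetration depth q of a cell outside
    the domain; its gradient is a unit inward push scaled by the force
    magnitude (default 10)."""
    f = np.zeros_like(pts)
    x, y = pts[:, 0], pts[:, 1]
    mag = cfg.boundary_force
    # below the base
    below = y < 0
    f[below, 1] += mag
    # outside the parabolic cap: push along the inward surface normal
    top = y > dome_profile(x, cfg)
    gx = 2 * cfg.curvature * x[top]  # gradient of (y - profile) is (c', 1)
    norm = np.hypot(gx, 1.0)
    f[top, 0] += -mag * gx / norm
    f[top, 1] += -mag / norm
    # beyond the lateral extent
    f[x > cfg.x_max, 0] -= mag
    f[x < -cfg.x_max, 0] += mag
    return f


def _relax_springs(pts: np.ndarray, cfg: TissueConfig, l_r: float) -> np.ndarray:
    pts = pts.copy()
    for _ in range(cfg.relax_steps):
        tri = Delaunay(pts)
        # unique Delaunay edges
        e = np.vstack([tri.simplices[:, [0, 1]], tri.simplices[:, [1, 2]],
                       tri.simplices[:, [0, 2]]])
        e.sort(axis=1)
        e = np.unique(e, axis=0)
        d = pts[e[:, 1]] - pts[e[:, 0]]
        l = np.linalg.norm(d, axis=1)
        l = np.where(l < 1e-12, 1e-12, l)
        # force on i from spring (i, j): k (l - l_r) * unit(i -> j)
        fmag = cfg.spring_k * (l - l_r)
        fvec = (fmag / l)[:, None] * d
        force = np.zeros_like(pts)
        np.add.at(force, e[:, 0], fvec)
        np.add.at(force, e[:, 1], -fvec)
        force += _boundary_force(pts, cfg)
        pts += cfg.relax_dt * force
    return pts


# ---------------------------------------------------------------------------
# Voronoi / Lloyd
# ---------------------------------------------------------------------------

def _ghost_ring(cfg: TissueConfig, n: int = 64) -> np.ndarray:
    """Far-away ghost sites guaranteeing every real Voronoi region is finite."""
    r = 6.0 * max(cfg.x_max, cfg.height)
    a = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(a), cfg.height / 2 + r * np.sin(a)])


def _clipped_regions(pts: np.ndarray, dome: Polygon, cfg: TissueConfig):
    """Voronoi polygons of the real sites clipped to the dome.

    Returns (list of shapely polygons, Voronoi object, n_real)."""
    ghosts = _ghost_ring(cfg)
    vor = Voronoi(np.vstack([pts, ghosts]))
    polys = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            polys.append(None)
            continue
        poly = Polygon(vor.vertices[region])
        if not poly.is_valid:
            poly = poly.buffer(0)
        clipped = poly.intersection(dome)
        polys.append(clipped if not clipped.is_empty else None)
    return polys, vor


def _lloyd(pts: np.ndarray, cfg: TissueConfig, dome: Polygon,
           rng: np.random.Generator) -> np.ndarray:
    pts = pts.copy()
    for _ in range(cfg.lloyd_steps):
        polys, _ = _clipped_regions(pts, dome, cfg)
        for i, poly in enumerate(polys):
            if poly is None or poly.area <= 0:
                # degenerate region: re-jitter inside the dome and retry
                log.debug("degenerate Voronoi region for cell %d; re-jittered", i)
                pts[i] = _sample_in_dome(rng, 1, cfg)[0]
                continue
            c = poly.centroid
            pts[i] = (c.x, c.y)
    return pts


def generate_tissue(seed: int, config: TissueConfig | None = None,
                    fitness_config: FitnessConfig | None = None) -> Tissue:
    """Generate one tissue template.

    Random points in the dome are relaxed on a spring network, regularized
    with Lloyd's algorithm, and the final clipped Voronoi tessellation is
    stored together with zone and L1 labels."""
    cfg = config or TissueConfig()
    rng = np.random.default_rng(seed)
    dome = dome_polygon(cfg)
    l_r = cfg.relaxed_length
    if l_r is None:
        l_r = float(np.sqrt(domain_area(cfg) / cfg.n_cells))

    for attempt in range(5):
        pts = _sample_in_dome(rng, cfg.n_cells, cfg)
        pts = _relax_springs(pts, cfg, l_r)
        # clamp back inside before the Voronoi stage
        inside = np.array([dome.contains(Point(p)) for p in pts])
        if not inside.all():
            pts[~inside] = _sample_in_dome(rng, int((~inside).sum()), cfg)
        pts = _lloyd(pts, cfg, dome, rng)
        polys, vor = _clipped_regions(pts, dome, cfg)
        if all(p is not None and p.area > 0 for p in polys):
            break
        log.warning("degenerate tessellation on attempt %d; retrying", attempt)
    else:
        raise RuntimeError("could not generate a non-degenerate tissue")

    cells = []
    for poly in polys:
        if poly.geom_type != "Polygon":  # keep the largest piece if split
            poly = max(poly.geoms, key=lambda g: g.area)
        verts = np.asarray(poly.exterior.coords)[:-1]
        c = poly.centroid
        cells.append(Cell(centroid=(c.x, c.y), polygon=verts, area=poly.area))

    # shared-edge lengths from clipped polygons, candidate pairs from ridges
    edges = []
    shapely_polys = [Polygon(c.polygon) for c in cells]
    n = len(cells)
    seen = set()
    for (a, b) in vor.ridge_points:
        if a >= n or b >= n:
            continue
        i, j = (a, b) if a < b else (b, a)
        if (i, j) in seen:
            continue
        seen.add((i, j))
        shared = shapely_polys[i].buffer(1e-9).intersection(
            shapely_polys[j].buffer(1e-9))
        w = shared.length / 2.0 if not shared.is_empty else 0.0
        if w > 1e-6:
            edges.append((i, j, float(w)))

    tissue = Tissue(cells=cells, edges=edges, config=cfg)
    assign_zones(tissue, fitness_config or FitnessConfig())
    mark_l1(tissue)
    return tissue


# ---------------------------------------------------------------------------
# Labelling
# ---------------------------------------------------------------------------

def assign_zones(tissue: Tissue, zone_config: FitnessConfig) -> Tissue:
    """Label each cell CZ / CZ_OC / OC / other by a centroid-in-box test."""
    for cell in tissue.cells:
        x, y = cell.centroid
        if zone_config.cz_box.contains(x, y):
            cell.zone = "CZ"
        elif zone_config.cz_oc_box.contains(x, y):
            cell.zone = "CZ_OC"
        elif zone_config.oc_box.contains(x, y):
            cell.zone = "OC"
        else:
            cell.zone = "other"
    return tissue


def mark_l1(tissue: Tissue, tol: float = 0.35) -> Tissue:
    """Mark the epidermal layer: cells whose polygon touches the curved dome
    surface (the flat base is excluded unless configured otherwise)."""
    cfg = tissue.config
    include_base = cfg.l1_include_base
    for cell in tissue.cells:
        verts = np.asarray(cell.polygon)
        x, y = verts[:, 0], verts[:, 1]
        on_arc = np.abs(y - dome_profile(x, cfg)) < tol
        on_side = np.abs(np.abs(x) - cfg.x_max) < tol
        on_base = np.abs(y) < tol
        touches = on_arc | on_side
        if include_base:
            touches = touches | on_base
        cell.is_l1 = bool(touches.sum() >= 2)  # a whole edge, not a corner
    return tissue


def generate_pool(n: int, config: TissueConfig, fitness_config: FitnessConfig,
                  rng: np.random.Generator) -> list[Tissue]:
    """Pre-generate a pool of distinct tissue templates."""
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [generate_tissue(int(s), config, fitness_config) for s in seeds]
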