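"""Voronoi tessellation of z-projected centroids and clone calling.

All microglia (Confetti+ and Confetti-) and all plaques of one image are
z-projected onto the xy-plane and tessellated; unbounded outer polygons are
clipped to the image bounding box.  Clones are the connected components of
same-colored Confetti+ cells under tessellation adjacency; Confetti- cells
and plaques shape the mesh (and can break contact between labeled cells)
but are never clone members.  Clone territory is the summed polygon area of
the members, and a clone contacts a plaque when any member polygon shares an
edge with the plaque polygon.

Implementation: the diagram is computed on the seeds plus their mirror
images across the four box edges, which yields polygons exactly clipped to
the box (the mirror of a seed across an edge cuts its polygon at that edge),
so polygon areas tile the box to numerical precision.  Two seeds are
adjacent when they share a Voronoi ridge of length > 1e-9 um; degenerate
point contacts do not count.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon

from .config import COLOR_NONE
from .tables import ImageMeta

EDGE_EPS = 1e-9  # um, minimum shared-edge length for adjacency
_JITTER = 1e-6   # um, deterministic perturbation of coincident seeds

KIND_CELL = "cell"
KIND_PLAQUE = "plaque"


@dataclass
class Tessellation:
    """Clipped 2D Voronoi mesh of one image."""

    image_id: str
    box: tuple[float, float]          # (Lx, Ly)
    kinds: np.ndarray                 # 'cell' / 'plaque' per seed
    ids: list[str]                    # cell_id or plaque_id per seed
    points: np.ndarray                # (n, 2) possibly jittered seed positions
    polygons: list[Polygon]
    adjacency: set[tuple[int, int]]   # (i, j) with i < j

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.adjacency:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    @property
    def cell_index(self) -> dict[str, int]:
        return {self.ids[i]: i for i in range(len(self.ids))
                if self.kinds[i] == KIND_CELL}

    @property
    def plaque_index(self) -> dict[str, int]:
        return {self.ids[i]: i for i in range(len(self.ids))
                if self.kinds[i] == KIND_PLAQUE}


def _dedupe(points: np.ndarray) -> np.ndarray:
    """Perturb coincident seeds by deterministic ~1e-6 um offsets."""
    pts = points.copy()
    for _ in range(100):
        _, inverse, counts = np.unique(
            np.round(pts / _JITTER).astype(np.int64), axis=0,
            return_inverse=True, return_counts=True)
        if counts.max() <= 1:
            return pts
        for g in np.flatnonzero(counts > 1):
            dup = np.flatnonzero(inverse == g)
            for j, idx in enumerate(dup[1:], start=1):
                ang = 2 * np.pi * j / 8.0
                pts[idx] += _JITTER * (j // 8 + 1) * np.array(
                    [np.cos(ang), np.sin(ang)])
    raise RuntimeError("could not separate coincident seeds")


def _clipped_voronoi(points: np.ndarray, box: tuple[float, float]):
    """Polygons clipped to [0,Lx]x[0,Ly] plus ridge adjacency, via mirroring."""
    n = len(points)
    lx, ly = box
    mirrors = [points * [-1, 1], points * [1, -1],
               np.column_stack([2 * lx - points[:, 0], points[:, 1]]),
               np.column_stack([points[:, 0], 2 * ly - points[:, 1]])]
    vor = Voronoi(np.vstack([points] + mirrors))
    polygons = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            raise RuntimeError(f"unbounded region for seed {i} (seed outside box?)")
        verts = vor.vertices[region]
        ang = np.arctan2(verts[:, 1] - points[i, 1], verts[:, 0] - points[i, 0])
        polygons.append(Polygon(verts[np.argsort(ang)]))
    adjacency: set[tuple[int, int]] = set()
    for (p, q), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if p < n and q < n and -1 not in rv:
            length = np.linalg.norm(vor.vertices[rv[0]] - vor.vertices[rv[1]])
            if length > EDGE_EPS:
                adjacency.add((min(p, q), max(p, q)))
    return polygons, adjacency


def build_tessellation(cells: pd.DataFrame, plaques: pd.DataFrame,
                       meta: ImageMeta, plaque_seed: str = "point") -> Tessellation:
    """Tessellate one image from its cell and plaque tables.

    ``plaque_seed='point'`` (default) enters each plaque as a single
    centroid seed; ``'disc'`` approximates the plaque footprint by a ring of
    12 perimeter seeds at the equivalent-sphere radius whose polygons are
    merged afterwards.  Requires >= 3 non-collinear seeds.
    """
    cc = cells[cells["image_id"] == meta.image_id]
    pl = plaques[plaques["image_id"] == meta.image_id] if len(plaques) else plaques
    pts = [cc[["x_um", "y_um"]].to_numpy(float)]
    kinds = [KIND_CELL] * len(cc)
    ids = [str(c) for c in cc["cell_id"]]
    seed_owner = list(range(len(cc)))  # merged-seed owner for disc mode
    n_owner = len(cc)
    for p in pl.itertuples():
        if plaque_seed == "point":
            pts.append(np.array([[p.x_um, p.y_um]]))
            kinds.append(KIND_PLAQUE)
            ids.append(str(p.plaque_id))
            seed_owner.append(n_owner)
            n_owner += 1
        elif plaque_seed == "disc":
            r = (3.0 * p.volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0)
            ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
            ring = np.column_stack([p.x_um + r * np.cos(ang),
                                    p.y_um + r * np.sin(ang)])
            ring = np.clip(ring, [0, 0], [meta.lx_um, meta.ly_um])
            pts.append(np.vstack([[p.x_um, p.y_um], ring]))
            kinds += [KIND_PLAQUE] * (1 + len(ring))
            ids += [str(p.plaque_id)] * (1 + len(ring))
            seed_owner += [n_owner] * (1 + len(ring))
            n_owner += 1
        else:
            raise ValueError("plaque_seed must be 'point' or 'disc'")
    points = np.vstack([a for a in pts if len(a)]) if any(len(a) for a in pts) \
        else np.zeros((0, 2))
    if len(points) < 3:
        raise ValueError("tessellation requires at least 3 seeds")
    if np.linalg.matrix_rank(points - points.mean(axis=0), tol=1e-9) < 2:
        raise ValueError("all seeds are collinear; cannot tessellate")
    out = (points < -1e-9).any() or \
        (points[:, 0] > meta.lx_um + 1e-9).any() or \
        (points[:, 1] > meta.ly_um + 1e-9).any()
    if out:
        raise ValueError("seeds outside the image bounding box")
    # keep seeds strictly inside the box so no seed coincides with its mirror
    margin = 1e-6
    points = _dedupe(np.clip(points, [margin, margin],
                             [meta.lx_um - margin, meta.ly_um - margin]))
    polys, adj = _clipped_voronoi(points, (meta.lx_um, meta.ly_um))
    if plaque_seed == "disc" and len(pl):
        polys, adj, points, kinds, ids = _merge_owned(
            polys, adj, points, kinds, ids, seed_owner)
    return Tessellation(image_id=meta.image_id,
                        box=(meta.lx_um, meta.ly_um),
                        kinds=np.array(kinds, dtype=object), ids=list(ids),
                        points=points, polygons=polys, adjacency=adj)


def _merge_owned(polys, adj, points, kinds, ids, owner):
    """Collapse multi-seed plaques (disc mode) into single merged seeds."""
    from shapely.ops import unary_union

    owner = np.asarray(owner)
    n_merged = owner.max() + 1
    new_polys, new_pts, new_kinds, new_ids = [], [], [], []
    for o in range(n_merged):
        members = np.flatnonzero(owner == o)
        merged = unary_union([polys[m] for m in members])
        new_polys.append(merged)
        new_pts.append(points[members[0]])
        new_kinds.append(kinds[members[0]])
        new_ids.append(ids[members[0]])
    new_adj = set()
    for a, b in adj:
        oa, ob = int(owner[a]), int(owner[b])
        if oa != ob:
            new_adj.add((min(oa, ob), max(oa, ob)))
    return new_polys, new_adj, np.array(new_pts), new_kinds, new_ids


@dataclass
class Clone:
    clone_id: str
    color: str
    member_ids: list[str]          # cell ids
    n_cells: int
    territory_um2: float
    plaque_ids: list[str]
    touches_border: bool


@dataclass
class CloneSet:
    image_id: str
    subset: str
    clones: list[Clone]
    unassigned: list[str]          # Confetti- (or out-of-subset) cell ids


def _touches_border(poly: Polygon, box: tuple[float, float],
                    tol: float = 1e-7) -> bool:
    minx, miny, maxx, maxy = poly.bounds
    return (minx <= tol or miny <= tol
            or maxx >= box[0] - tol or maxy >= box[1] - tol)


def call_clones(tess: Tessellation, cells: pd.DataFrame,
                subset: str = "all") -> CloneSet:
    """Connected components of same-colored Confetti+ cells under adjacency.

    ``subset`` optionally restricts membership to PAM or nonPAM cells
    (requires a ``state`` column); excluded and unlabeled cells still shape
    the mesh.  Every eligible Confetti+ cell belongs to exactly one clone
    (singletons allowed).
    """
    cc = cells[cells["image_id"] == tess.image_id]
    color_of = dict(zip(cc["cell_id"].astype(str), cc["confetti_color"]))
    state_of = dict(zip(cc["cell_id"].astype(str), cc["state"])) \
        if "state" in cc.columns else {}
    if subset != "all" and "state" not in cc.columns:
        raise ValueError("subset clone calling requires a 'state' column")
    eligible = []
    unassigned = []
    for cid, i in tess.cell_index.items():
        col = color_of.get(cid, COLOR_NONE)
        ok = col != COLOR_NONE and (subset == "all" or state_of.get(cid) == subset)
        (eligible if ok else unassigned).append(i)
    elig = set(eligible)
    g = nx.Graph()
    g.add_nodes_from(eligible)
    for a, b in tess.adjacency:
        if a in elig and b in elig and \
                color_of[tess.ids[a]] == color_of[tess.ids[b]]:
            g.add_edge(a, b)
    comps = sorted(nx.connected_components(g), key=min)
    clones = []
    for k, comp in enumerate(comps):
        members = sorted(comp)
        plaque_contacts = set()
        for a, b in tess.adjacency:
            if a in comp and tess.kinds[b] == KIND_PLAQUE:
                plaque_contacts.add(tess.ids[b])
            elif b in comp and tess.kinds[a] == KIND_PLAQUE:
                plaque_contacts.add(tess.ids[a])
        clones.append(Clone(
            clone_id=f"{tess.image_id}:clone{k}",
            color=str(color_of[tess.ids[members[0]]]),
            member_ids=[tess.ids[m] for m in members],
            n_cells=len(members),
            territory_um2=float(sum(tess.polygons[m].area for m in members)),
            plaque_ids=sorted(plaque_contacts),
            touches_border=any(_touches_border(tess.polygons[m], tess.box)
                               for m in members)))
    return CloneSet(image_id=tess.image_id, subset=subset, clones=clones,
                    unassigned=[tess.ids[i] for i in sorted(unassigned)])


def clone_territory(clone: Clone, tess: Tessellation) -> float:
    """Summed member polygon area (um^2); multiply by Lz for a volume."""
    idx = tess.cell_index
    return float(sum(tess.polygons[idx[cid]].area for cid in clone.member_ids))


def clone_plaque_contacts(clone_set: CloneSet, tess: Tessellation):
    """(clone, plaque) contact pairs and per-side contact counts.

    Returns ``(pairs, summary)`` where ``pairs`` is a DataFrame of contact
    pairs and ``summary`` holds plaques-per-clone, clones-per-plaque (zero
    rows included) and the fraction of plaques contacted by >= 2 clones
    (NaN with zero plaques).
    """
    pairs = [(c.clone_id, pid) for c in clone_set.clones for pid in c.plaque_ids]
    pairs_df = pd.DataFrame(pairs, columns=["clone_id", "plaque_id"])
    plaque_ids = sorted(tess.plaque_index)
    per_clone = pd.Series({c.clone_id: len(c.plaque_ids)
                           for c in clone_set.clones}, dtype=int,
                          name="n_plaques")
    per_plaque = pd.Series(0, index=plaque_ids, dtype=int, name="n_clones")
    if len(pairs_df):
        counts = pairs_df.groupby("plaque_id").size()
        per_plaque.loc[counts.index] = counts
    frac_multi = float((per_plaque >= 2).mean()) if plaque_ids else float("nan")
    return pairs_df, {"plaques_per_clone": per_clone,
                      "clones_per_plaque": per_plaque,
                      "frac_plaques_multi_clone": frac_multi}


def clones_to_frame(clone_set: CloneSet, group: str = "",
                    replicate_id: str = "") -> pd.DataFrame:
    """Flatten a CloneSet for CSV output."""
    rows = [{
        "group": group, "replicate_id": replicate_id,
        "image_id": clone_set.image_id, "clone_id": c.clone_id,
        "color": c.color, "n_cells": c.n_cells,
        "territory_um2": c.territory_um2,
        "n_plaques_contacted": len(c.plaque_ids),
        "plaque_ids": ";".join(c.plaque_ids),
        "touches_border": c.touches_border,
    } for c in clone_set.clones]
    return pd.DataFrame(rows, columns=[
        "group", "replicate_id", "image_id", "clone_id", "color", "n_cells",
        "territory_um2", "n_plaques_contacted", "plaque_ids", "touches_border"])
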