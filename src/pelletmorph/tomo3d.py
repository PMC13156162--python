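"""Per-pellet 3D micromorphology from binary voxel volumes.

A pellet volume is a binary voxel grid (solid = hyphae + embedded spores/talcum)
with a known voxel edge length in micrometres.  From it this module derives the
quantities used to describe inner pellet architecture:

* radial solid-fraction profile (inner 50 µm sphere + 15 µm shells),
* porosity against the pellet envelope (convex hull of solid voxels),
* a skeleton graph of the hyphal network with tip / branch-point census,
  total hyphal length and average branch length (ABL),
* hyphal diameter from the Euclidean distance transform along the skeleton,
* volume-equivalent diameter of the envelope,
* density-based (DBSCAN) clustering of spore centre coordinates.

Spore detection itself is out of scope: spore coordinates come in as ground
truth from the synthetic generator or from an external detector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize
from sklearn.cluster import DBSCAN

__all__ = [
    "PelletVolume",
    "SkeletonGraph",
    "RadialProfile",
    "PelletMetrics3D",
    "binarize",
    "radial_solid_fraction",
    "pellet_envelope",
    "porosity",
    "skeletonize_volume",
    "skeleton_metrics",
    "estimate_hyphal_diameter",
    "volume_equivalent_diameter",
    "sphericity",
    "cluster_spores",
    "compute_metrics",
]

# 26-connectivity structuring element for solids (background pairs with 6).
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PelletVolume:
    """Binary voxel grid of one pellet.

    ``grid`` is boolean with solid voxels True; ``voxel_size`` is the voxel
    edge length in µm; ``origin`` the world coordinate (µm) of the grid's
    lower corner, so the centre of voxel ``(i, j, k)`` sits at
    ``origin + (i+0.5, j+0.5, k+0.5) * voxel_size``.
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def n_solid(self) -> int:
        return int(self.grid.sum())

    def solid_coords(self) -> np.ndarray:
        """World coordinates (µm) of solid voxel centres, shape (n, 3)."""
        idx = np.argwhere(self.grid)
        return self.origin + (idx + 0.5) * self.voxel_size


@dataclass
class SkeletonGraph:
    """Topological graph of a 1-voxel-wide skeleton.

    Nodes carry ``pos`` (world µm) and are tips (degree 1) or branch points
    (degree ≥ 3); edges carry ``length`` (µm) and the voxel-index ``path``.
    """

    graph: nx.MultiGraph
    voxel_size: float

    @property
    def n_tips(self) -> int:
        return sum(1 for _, d in self.graph.degree() if d == 1)

    @property
    def n_branch_points(self) -> int:
        return sum(1 for _, d in self.graph.degree() if d >= 3)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_lengths(self) -> np.ndarray:
        return np.array(
            [data["length"] for _, _, data in self.graph.edges(data=True)], dtype=float
        )


@dataclass
class RadialProfile:
    """Solid fraction per spherical shell around the pellet mass centre.

    The first region is the inner core sphere (radius ``core_radius``); the
    following half-open shells ``[r, r + shell_width)`` continue out to the
    farthest solid voxel.  ``shell_inner_radii[0]`` is 0 (the core).
    """

    shell_inner_radii: np.ndarray
    solid_fraction_per_shell: np.ndarray
    mass_centre: np.ndarray
    core_radius: float
    shell_width: float
    voxels_per_shell: np.ndarray
    solid_voxels_per_shell: np.ndarray

    @property
    def centre_solid_fraction(self) -> float:
        return float(self.solid_fraction_per_shell[0])


@dataclass
class PelletMetrics3D:
    """Per-pellet micromorphology record."""

    total_hyphal_length: float  # m
    n_tips: int
    n_branch_points: int
    n_branch_segments: int  # secondary reading of "number of branches"
    avg_branch_length: float | None  # µm, None when the skeleton has no edges
    porosity: float
    hyphal_diameter: float | None  # µm
    n_spore_clusters: int | None
    volume_equivalent_diameter: float  # µm
    centre_solid_fraction: float
    sphericity: float
    envelope_degenerate: bool = False
    pellet_id: str | int | None = None


def binarize(
    volume: np.ndarray,
    voxel_size: float,
    min_component_voxels: int = 27,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> PelletVolume:
    """Threshold a grayscale stack and keep the pellet's connected solids.

    Automatic global (Otsu) threshold, then the largest 26-connected
    component plus any component of at least ``min_component_voxels`` is
    retained.  Already-binary input passes through unchanged apart from the
    component filter.
    """
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("expected a 3D stack")
    if vol.dtype == bool or set(np.unique(vol)).issubset({0, 1}):
        mask = vol.astype(bool)
    else:
        thr = threshold_otsu(vol)
        # solid phase is the brighter one in reconstructed volumes
        mask = vol > thr
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    if n == 0:
        raise ValueError("no solid voxels after thresholding")
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero((sizes >= min_component_voxels) | (sizes == sizes.max())) + 1
    mask = np.isin(labels, keep)
    return PelletVolume(mask, voxel_size, np.asarray(origin, dtype=float))


def _radius_grid(vol: PelletVolume, centre_idx: np.ndarray) -> np.ndarray:
    """Distance (µm) of every voxel centre from ``centre_idx`` (index units)."""
    nx_, ny, nz = vol.grid.shape
    xi = (np.arange(nx_, dtype=np.float32) - centre_idx[0]) ** 2
    yi = (np.arange(ny, dtype=np.float32) - centre_idx[1]) ** 2
    zi = (np.arange(nz, dtype=np.float32) - centre_idx[2]) ** 2
    r2 = xi[:, None, None] + yi[None, :, None] + zi[None, None, :]
    return np.sqrt(r2) * vol.voxel_size


def radial_solid_fraction(
    vol: PelletVolume, core_radius: float = 50.0, shell_width: float = 15.0
) -> RadialProfile:
    """Solid fraction in the inner sphere and concentric 15 µm shells.

    The mass centre is the unweighted centroid of solid voxels.  Each region's
    fraction is (solid voxels in region) / (grid voxels in region); regions
    entirely outside the grid are omitted rather than reported as NaN.
    """
    if vol.n_solid == 0:
        raise ValueError("volume has no solid voxels")
    idx = np.argwhere(vol.grid)
    centre_idx = idx.mean(axis=0) + 0.5 - 0.5  # centroid in index units
    r = _radius_grid(vol, centre_idx)
    r_solid = r[vol.grid]
    r_max = float(r_solid.max())
    edges = [0.0, core_radius]
    while edges[-1] < r_max:
        edges.append(edges[-1] + shell_width)
    edges = np.array(edges)
    total, _ = np.histogram(r, bins=edges)
    solid, _ = np.histogram(r_solid, bins=edges)
    nonempty = total > 0
    frac = np.zeros(nonempty.sum())
    frac = solid[nonempty] / total[nonempty]
    mass_centre = vol.origin + (idx.mean(axis=0) + 0.5) * vol.voxel_size
    return RadialProfile(
        shell_inner_radii=edges[:-1][nonempty],
        solid_fraction_per_shell=frac,
        mass_centre=mass_centre,
        core_radius=core_radius,
        shell_width=shell_width,
        voxels_per_shell=total[nonempty],
        solid_voxels_per_shell=solid[nonempty],
    )


@dataclass
class Envelope:
    """Pellet envelope: convex hull of solid voxels (or a fallback sphere)."""

    n_voxels_inside: int
    volume: float  # µm³ (voxel count × voxel volume)
    hull_volume: float  # µm³ continuous hull volume
    hull_area: float  # µm² continuous hull area
    degenerate: bool


def pellet_envelope(vol: PelletVolume) -> Envelope:
    """Convex hull of the solid voxels, evaluated on the voxel grid.

    Degenerate point sets (coplanar / collinear solids) fall back to the
    bounding sphere around the solid centroid and are flagged.
    """
    if vol.n_solid == 0:
        raise ValueError("volume has no solid voxels")
    idx = np.argwhere(vol.grid)
    # hull of boundary voxels only, for speed on large solids
    eroded = ndimage.binary_erosion(vol.grid, structure=np.ones((3, 3, 3)))
    surf = np.argwhere(vol.grid & ~eroded)
    pts = surf if len(surf) >= 4 else idx
    try:
        hull = ConvexHull(pts.astype(float))
    except QhullError:
        centre = idx.mean(axis=0)
        radius = np.sqrt(((idx - centre) ** 2).sum(axis=1)).max() + 0.5
        r = _radius_grid(vol, centre)
        inside = int((r <= radius * vol.voxel_size).sum())
        vv = vol.voxel_size**3
        sphere_vol = 4.0 / 3.0 * np.pi * (radius * vol.voxel_size) ** 3
        sphere_area = 4.0 * np.pi * (radius * vol.voxel_size) ** 2
        return Envelope(inside, inside * vv, sphere_vol, sphere_area, True)
    # voxel-centre-in-hull test on the bounding box, chunked; the envelope is
    # the union of the hull interior with the solid itself (the hull of voxel
    # centres is inscribed, so boundary solid voxels may fall just outside it)
    lo = np.floor(pts.min(axis=0)).astype(int)
    hi = np.ceil(pts.max(axis=0)).astype(int)
    normals = hull.equations[:, :3].astype(np.float32)
    offsets = hull.equations[:, 3].astype(np.float32)
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0] + 1),
        np.arange(lo[1], hi[1] + 1),
        np.arange(lo[2], hi[2] + 1),
        indexing="ij",
    )
    coords = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(np.float32)
    solid_flat = vol.grid[
        lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1
    ].ravel()
    inside_count = 0
    tol = 1e-5
    # sphere pre-classification: voxels inside the inscribed sphere need no
    # facet test, voxels beyond the circumscribed sphere are outside
    centre = pts.mean(axis=0).astype(np.float32)
    r_in = float(np.min(-(normals @ centre + offsets)))
    r_out = float(np.sqrt(((pts - centre) ** 2).sum(axis=1).max()))
    for start in range(0, len(coords), 2_000_000):
        sl = slice(start, start + 2_000_000)
        chunk = coords[sl]
        d = np.sqrt(((chunk - centre) ** 2).sum(axis=1))
        ok = d <= r_in
        maybe = np.flatnonzero((d > r_in) & (d <= r_out))
        if len(maybe):
            sub = chunk[maybe]
            sub_ok = np.ones(len(sub), dtype=bool)
            for a, b in zip(normals, offsets):
                sub_ok &= sub @ a + b <= tol
                if not sub_ok.any():
                    break
            ok[maybe] = sub_ok
        ok |= solid_flat[sl]
        inside_count += int(ok.sum())
    vv = vol.voxel_size**3
    return Envelope(
        inside_count,
        inside_count * vv,
        float(hull.volume) * vv,
        float(hull.area) * vol.voxel_size**2,
        False,
    )


def porosity(vol: PelletVolume, envelope: Envelope | None = None) -> float:
    """1 − (solid voxels / voxels inside the pellet envelope)."""
    env = envelope if envelope is not None else pellet_envelope(vol)
    if env.n_voxels_inside == 0:
        raise ValueError("empty envelope")
    return 1.0 - vol.n_solid / env.n_voxels_inside


def volume_equivalent_diameter(
    vol: PelletVolume, envelope: Envelope | None = None
) -> float:
    """Diameter (µm) of the sphere with the envelope's volume.

    Uses the same envelope (convex hull of solid voxels) as the porosity, so
    the value is comparable to the 2D projected-outline diameter.
    """
    env = envelope if envelope is not None else pellet_envelope(vol)
    return float((6.0 * env.volume / np.pi) ** (1.0 / 3.0))


def sphericity(envelope: Envelope) -> float:
    """Compactness π^(1/3)·(6V)^(2/3)/A of the envelope (1 for a sphere)."""
    if envelope.hull_area <= 0:
        return float("nan")
    return float(
        np.pi ** (1.0 / 3.0)
        * (6.0 * envelope.hull_volume) ** (2.0 / 3.0)
        / envelope.hull_area
    )


# ---------------------------------------------------------------------------
# Skeletonization and graph construction
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
)
_STEP_LENGTHS = np.sqrt((_NEIGHBOR_OFFSETS**2).sum(axis=1))


def _path_length(path: np.ndarray, voxel_size: float, chord: int = 3) -> float:
    """Length of a voxel path in µm, by chords over ``chord``-voxel windows.

    Summing per-voxel 1/√2/√3 steps overestimates oblique runs by the
    staircase effect; chords over a few voxels follow the centre line with
    far less bias while still tracking curvature.
    """
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        return 0.0
    idx = np.arange(0, len(path), chord)
    if idx[-1] != len(path) - 1:
        idx = np.append(idx, len(path) - 1)
    sub = path[idx]
    return float(np.linalg.norm(np.diff(sub, axis=0), axis=1).sum() * voxel_size)


def _build_raw_graph(skel: np.ndarray, voxel_size: float) -> nx.MultiGraph:
    """Turn a 1-voxel-wide skeleton into a node/edge graph.

    Voxels with ≠2 skeleton neighbours are node voxels; 26-connected clusters
    of node voxels collapse into single graph nodes.  Runs of degree-2 voxels
    between node clusters become edges whose length is the sum of axis/face/
    corner step lengths (1, √2, √3 × voxel_size).
    """
    g = nx.MultiGraph()
    coords = np.argwhere(skel)
    if len(coords) == 0:
        return g
    pad = np.pad(skel, 1)
    # neighbour count per skeleton voxel
    nb = np.zeros(len(coords), dtype=int)
    cpad = coords + 1
    for off in _NEIGHBOR_OFFSETS:
        nb += pad[cpad[:, 0] + off[0], cpad[:, 1] + off[1], cpad[:, 2] + off[2]]
    node_mask_flat = nb != 2
    node_vox = coords[node_mask_flat]
    node_grid = np.zeros(skel.shape, dtype=bool)
    node_grid[tuple(node_vox.T)] = True
    labels, n_clusters = ndimage.label(node_grid, structure=_STRUCT26)

    for lab in range(1, n_clusters + 1):
        vox = np.argwhere(labels == lab)
        g.add_node(lab, pos=(vox.mean(axis=0) + 0.5) * voxel_size, voxels=vox)

    def neighbours(p):
        out = []
        for off, sl in zip(_NEIGHBOR_OFFSETS, _STEP_LENGTHS):
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if (
                0 <= q[0] < skel.shape[0]
                and 0 <= q[1] < skel.shape[1]
                and 0 <= q[2] < skel.shape[2]
                and skel[q]
            ):
                out.append((q, sl))
        return out

    visited_path = np.zeros(skel.shape, dtype=bool)
    path_grid = skel & ~node_grid

    def trace(start_node_vox, first_path_vox, step0):
        """Walk a degree-2 run starting one step away from a node cluster."""
        path = [tuple(start_node_vox), first_path_vox]
        length = step0
        prev, cur = tuple(start_node_vox), first_path_vox
        visited_path[cur] = True
        while True:
            nxt = None
            for q, sl in neighbours(cur):
                if q == prev:
                    continue
                if labels[q] > 0:
                    path.append(q)
                    return path, length + sl, labels[q]
                if path_grid[q] and not visited_path[q]:
                    nxt = (q, sl)
            if nxt is None:
                # dead-ends into already visited voxels (tiny loop); close here
                return path, length, None
            prev, cur = cur, nxt[0]
            visited_path[cur] = True
            length += nxt[1]
            path.append(cur)

    # edges through degree-2 runs
    for lab in range(1, n_clusters + 1):
        for v in g.nodes[lab]["voxels"]:
            for q, sl in neighbours(v):
                if path_grid[q] and not visited_path[q]:
                    path, length, end_lab = trace(v, q, sl)
                    if end_lab is None:
                        end_lab = lab  # loop back
                    arr = np.array(path)
                    g.add_edge(lab, end_lab, length=_path_length(arr, voxel_size), path=arr)
    # direct node-cluster to node-cluster adjacencies (no path voxels between)
    seen_pairs = set()
    for lab in range(1, n_clusters + 1):
        for v in g.nodes[lab]["voxels"]:
            for q, sl in neighbours(v):
                lq = labels[q]
                if lq > 0 and lq != lab:
                    key = (min(lab, lq), max(lab, lq), tuple(v) if lab < lq else q)
                    pair = frozenset([(tuple(v)), q])
                    if (min(lab, lq), max(lab, lq), pair) in seen_pairs:
                        continue
                    seen_pairs.add((min(lab, lq), max(lab, lq), pair))
                    if g.number_of_edges(lab, lq) == 0:
                        arr = np.array([list(v), list(q)])
                        g.add_edge(lab, lq, length=_path_length(arr, voxel_size), path=arr)
    # leftover pure cycles of degree-2 voxels
    remaining = np.argwhere(path_grid & ~visited_path)
    for p in remaining:
        p = tuple(p)
        if visited_path[p]:
            continue
        lab = labels.max() + 1 if labels.max() else n_clusters + 1
        labels[p] = lab
        g.add_node(lab, pos=(np.array(p) + 0.5) * voxel_size, voxels=np.array([p]))
        for q, sl in neighbours(p):
            if path_grid[q] and not visited_path[q]:
                path, length, end_lab = trace(np.array(p), q, sl)
                if end_lab is None:
                    end_lab = lab
                arr = np.array(path)
                g.add_edge(lab, end_lab, length=_path_length(arr, voxel_size), path=arr)
                break
    return g


def _merge_degree2(g: nx.MultiGraph) -> bool:
    """Splice out degree-2 nodes, concatenating their two edges."""
    changed = False
    for n in list(g.nodes):
        if g.degree(n) != 2:
            continue
        edges = list(g.edges(n, keys=True, data=True))
        if len(edges) != 2:
            continue  # self-loop counts degree 2 with one edge
        (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
        a = v1 if u1 == n else u1
        b = v2 if u2 == n else u2
        if a == n or b == n:
            continue
        p1 = d1["path"]
        p2 = d2["path"]
        # orient both paths away from n
        if not np.array_equal(p1[0], p1[0]):  # pragma: no cover
            pass
        # path arrays start at one endpoint; orient p1 to end at n, p2 to start at n
        new_path = None
        if p1 is not None and p2 is not None:
            q1 = p1 if _closer(p1[-1], g, n) else p1[::-1]
            q2 = p2 if _closer(p2[0], g, n) else p2[::-1]
            new_path = np.vstack([q1, q2[1:]])
        g.remove_node(n)
        vs = None
        length = d1["length"] + d2["length"]
        g.add_edge(a, b, length=length, path=new_path)
        changed = True
    return changed


def _closer(vox, g: nx.MultiGraph, node) -> bool:
    vx = g.nodes[node]["voxels"]
    return bool(np.abs(vx - np.asarray(vox)).max(axis=1).min() <= 1)


def skeletonize_volume(
    vol: PelletVolume, prune_length: float = 6.0, tip_correction: bool = True
) -> SkeletonGraph:
    """3D thinning to a 1-voxel skeleton, then graph build and spur pruning.

    Spur (leaf) edges shorter than ``prune_length`` µm — thinning artifacts at
    junctions and surface bumps — are removed; short junction-junction edges
    and self-loops below ``prune_length`` are contracted, which consolidates
    the multi-voxel junction clusters thinning sometimes produces.

    Thinning retracts every free tube end by about the tube radius; with
    ``tip_correction`` each terminal edge is lengthened by the distance
    transform value at its endpoint, which restores the eroded cap.
    """
    if vol.n_solid == 0:
        return SkeletonGraph(nx.MultiGraph(), vol.voxel_size)
    skel = skeletonize(vol.grid)
    g = _build_raw_graph(skel, vol.voxel_size)
    # handle isolated single-voxel components lost by thinning gracefully
    changed = True
    while changed:
        changed = False
        # 1. prune short spurs at junctions
        for n in list(g.nodes):
            if n in g and g.degree(n) == 1:
                (u, v, k, d) = list(g.edges(n, keys=True, data=True))[0]
                other = v if u == n else u
                if d["length"] < prune_length and g.degree(other) >= 3:
                    g.remove_node(n)
                    changed = True
        # 2. contract short junction-junction edges
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            if u not in g or v not in g:
                continue
            if u != v and d["length"] < prune_length and g.degree(u) >= 3 and g.degree(v) >= 3:
                _contract(g, u, v, k)
                changed = True
        # 3. drop short self-loops (junction artifacts)
        for u, v, k, d in list(g.edges(keys=True, data=True)):
            if u == v and d["length"] < 2 * prune_length:
                g.remove_edge(u, v, k)
                changed = True
        # 4. splice out degree-2 nodes created by the above
        if _merge_degree2(g):
            changed = True
    if tip_correction and g.number_of_edges() > 0:
        edt = ndimage.distance_transform_edt(vol.grid, sampling=vol.voxel_size)
        for n in g.nodes:
            if g.degree(n) != 1:
                continue
            vox = g.nodes[n]["voxels"][0]
            (u, v, k, d) = list(g.edges(n, keys=True, data=True))[0]
            d["length"] += float(edt[tuple(vox)])
    return SkeletonGraph(g, vol.voxel_size)


def _contract(g: nx.MultiGraph, u, v, key) -> None:
    """Merge node v into u, removing the (u, v, key) edge."""
    d = g.get_edge_data(u, v, key)
    g.remove_edge(u, v, key)
    for a, b, k, data in list(g.edges(v, keys=True, data=True)):
        other = b if a == v else a
        if other == v:
            g.add_edge(u, u, **data)
        else:
            g.add_edge(u, other, **data)
    pu, pv = g.nodes[u]["pos"], g.nodes[v]["pos"]
    nu, nv = len(g.nodes[u]["voxels"]), len(g.nodes[v]["voxels"])
    g.nodes[u]["pos"] = (pu * nu + pv * nv) / (nu + nv)
    g.nodes[u]["voxels"] = np.vstack([g.nodes[u]["voxels"], g.nodes[v]["voxels"]])
    g.remove_node(v)


def skeleton_metrics(
    sg: SkeletonGraph,
) -> tuple[float, int, int, float | None]:
    """(total length m, n_tips, n_branch_points, average branch length µm).

    ABL is the mean edge length — the distance between two branching points or
    a branching point and a tip.  Empty graphs give zeros and an absent ABL.
    """
    lengths = sg.edge_lengths()
    if len(lengths) == 0:
        return 0.0, 0, 0, None
    total_m = float(lengths.sum()) * 1e-6
    return total_m, sg.n_tips, sg.n_branch_points, float(lengths.mean())


def estimate_hyphal_diameter(
    vol: PelletVolume, sg: SkeletonGraph, junction_exclusion: float = 6.0
) -> float | None:
    """2 × mean distance-to-background along the skeleton, in µm.

    Skeleton voxels within ``junction_exclusion`` µm of a branch point are
    excluded: there the distance transform reads the junction blob, not the
    tube radius.
    """
    if sg.graph.number_of_edges() == 0:
        return None
    edt = ndimage.distance_transform_edt(vol.grid, sampling=vol.voxel_size)
    samples = []
    junctions = np.array(
        [sg.graph.nodes[n]["pos"] for n, d in sg.graph.degree() if d >= 3]
    )
    for _, _, data in sg.graph.edges(data=True):
        path = data.get("path")
        if path is None or len(path) == 0:
            continue
        pos = (path + 0.5) * vol.voxel_size
        keep = np.ones(len(pos), dtype=bool)
        if len(junctions):
            for j in junctions:
                keep &= np.linalg.norm(pos - j, axis=1) > junction_exclusion
        samples.append(edt[tuple(path[keep].T)])
    if not samples:
        return None
    vals = np.concatenate(samples)
    vals = vals[vals > 0]
    if len(vals) == 0:
        return None
    return float(2.0 * vals.mean())


def cluster_spores(
    points: np.ndarray, eps: float = 10.0, min_pts: int = 3
) -> tuple[np.ndarray, int]:
    """Density-based clustering of spore coordinates (µm).

    DBSCAN with the convention that a core point has at least ``min_pts``
    points (itself included) within ``eps``; isolated points are labelled −1
    (noise) and not counted as clusters.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be at least 1")
    points = np.asarray(points, dtype=float).reshape(-1, 3) if np.size(points) else np.empty((0, 3))
    if len(points) == 0:
        return np.empty(0, dtype=int), 0
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(points)
    n_clusters = int(labels.max()) + 1 if (labels >= 0).any() else 0
    return labels, n_clusters


def compute_metrics(
    vol: PelletVolume,
    spore_points: np.ndarray | None = None,
    prune_length: float = 6.0,
    dbscan_eps: float = 10.0,
    dbscan_min_pts: int = 3,
    pellet_id: str | int | None = None,
) -> PelletMetrics3D:
    """Full micromorphology record for one binary pellet volume."""
    env = pellet_envelope(vol)
    if env.degenerate:
        warnings.warn("degenerate envelope; bounding-sphere fallback used")
    sg = skeletonize_volume(vol, prune_length=prune_length)
    total_m, n_tips, n_branch, abl = skeleton_metrics(sg)
    profile = radial_solid_fraction(vol)
    n_clusters: int | None = None
    if spore_points is not None:
        _, n_clusters = cluster_spores(spore_points, eps=dbscan_eps, min_pts=dbscan_min_pts)
    return PelletMetrics3D(
        total_hyphal_length=total_m,
        n_tips=n_tips,
        n_branch_points=n_branch,
        n_branch_segments=sg.n_edges,
        avg_branch_length=abl,
        porosity=porosity(vol, env),
        hyphal_diameter=estimate_hyphal_diameter(vol, sg, junction_exclusion=prune_length),
        n_spore_clusters=n_clusters,
        volume_equivalent_diameter=volume_equivalent_diameter(vol, env),
        centre_solid_fraction=profile.centre_solid_fraction,
        sphericity=sphericity(env),
        envelope_degenerate=env.degenerate,
        pellet_id=pellet_id,
    )
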