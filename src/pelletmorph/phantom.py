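"""Synthetic fungal pellets, populations, volumes and projection images.

Every analysis stage in this package is exercised against pellets with known
ground truth.  The generator emulates the biology of coagulative *Aspergillus
niger* pellets: spores agglomerate (the spore-to-talcum ratio sets the number
of agglomerates), each spore germinates a small number of tubes, hyphal tips
extend apically as persistent random walks and branch laterally so that the
expected distance between consecutive branch points matches a target average
branch length.  Shear-induced breakage is modelled as a planar cut; fusion as
hull-contact union of two pellets.

The ground-truth hyphal network is stored as a graph (µm coordinates) so that
tip/branch counts, total length and spore-cluster counts are exact, and can
be compared against what the voxel-based 3D pipeline recovers.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence


import networkx as nx
import numpy as np

from .tomo3d import PelletVolume
from .image2d import Image2D

__all__ = [
    "PelletSpec",
    "SyntheticPellet",
    "PelletRecord",
    "SyntheticPopulation",
    "grow_pellet",
    "apply_breakage",
    "apply_fusion",
    "voxelize",
    "render_projection",
    "simulate_population",
    "simulate_growth_series",
]

PelletClass = Literal["I", "II", "III", "IV"]


@dataclass(frozen=True)
class PelletSpec:
    """Parameters of one simulated pellet.

    Lengths in µm, durations in h, speeds in µm/h.  ``n_agglomerates`` is the
    number of spore agglomerates seeding the pellet (set in culture by the
    spore-to-talcum ratio); ``direction_persistence`` ∈ (0, 1] controls how
    straight tips grow (1 = perfectly straight).  ``min_branch_spacing`` is a
    refractory distance after each node below which no lateral branch is
    placed; the next branch distance is drawn as
    ``min_branch_spacing + Exp(target_branch_length − min_branch_spacing)`` so
    the expected spacing equals ``target_branch_length`` exactly.
    """

    n_agglomerates: int = 1
    spores_per_agglomerate: int = 5
    agglomerate_spread: float = 60.0
    spore_spread: float = 8.0
    growth_duration: float = 2.0
    tip_speed: float = 40.0
    target_branch_length: float = 80.0
    hyphal_radius: float = 1.5
    spore_radius: float = 2.0
    germ_tubes_per_spore: int = 2
    direction_persistence: float = 0.9
    branching_enabled: bool = True
    min_branch_spacing: float = 10.0
    self_avoidance: bool = True
    avoidance_clearance: float = 6.0
    branch_angle_deg: tuple[float, float] = (45.0, 85.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agglomerates < 1:
            raise ValueError("n_agglomerates must be >= 1")
        if self.spores_per_agglomerate < 1:
            raise ValueError("spores_per_agglomerate must be >= 1")
        if self.germ_tubes_per_spore < 1:
            raise ValueError("germ_tubes_per_spore must be >= 1")
        for name in (
            "agglomerate_spread",
            "spore_spread",
            "growth_duration",
            "tip_speed",
            "target_branch_length",
            "hyphal_radius",
            "spore_radius",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.direction_persistence <= 1:
            raise ValueError("direction_persistence must be in (0, 1]")
        if not 0 <= self.min_branch_spacing < self.target_branch_length:
            raise ValueError("min_branch_spacing must be in [0, target_branch_length)")


@dataclass
class SyntheticPellet:
    """Ground-truth twin of a tomography-derived pellet record.

    ``graph`` is a MultiGraph whose nodes carry ``pos`` (µm) and ``kind``
    (root / branch / tip / cut); edges carry ``path`` polylines (µm) and
    ``length`` (µm).  ``true_total_length`` is in metres to match how total
    hyphal length per pellet is conventionally reported.
    """

    graph: nx.MultiGraph
    spore_points: np.ndarray  # (n, 3) µm
    spore_agglomerates: np.ndarray  # (n,) agglomerate id per spore
    hyphal_radius: float
    spore_radius: float
    true_total_length: float  # m
    true_tips: int
    true_branch_points: int
    true_clusters: int
    true_class: PelletClass
    provenance: dict = field(default_factory=dict)

    @property
    def segments(self) -> list[np.ndarray]:
        """All hyphal polylines (µm), one per graph edge."""
        return [d["path"] for _, _, d in self.graph.edges(data=True)]

    def census(self) -> tuple[int, int]:
        """(tips, branch points) of the degree-2-suppressed ground-truth graph.

        This is the census a topological skeleton of the rasterised pellet
        should recover: degree-1 nodes are tips, degree ≥ 3 nodes are branch
        points, and degree-2 markers (e.g. a root with two germ tubes, or cut
        bookkeeping nodes) are invisible to a skeleton.
        """
        deg = dict(self.graph.degree())
        tips = sum(1 for d in deg.values() if d == 1)
        branch = sum(1 for d in deg.values() if d >= 3)
        return tips, branch

    def all_points(self) -> np.ndarray:
        parts = [p for p in self.segments if len(p)] + (
            [self.spore_points] if len(self.spore_points) else []
        )
        if not parts:
            return np.zeros((0, 3))
        return np.vstack(parts)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        pts = self.all_points()
        return pts.min(axis=0), pts.max(axis=0)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of unit vector v about unit axis."""
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * np.dot(axis, v) * (1 - np.cos(angle))
    )


class _Tip:
    __slots__ = (
        "pos",
        "direction",
        "origin_node",
        "points",
        "dist_to_branch",
        "tid",
        "n_laid",
        "alive",
    )

    def __init__(self, pos, direction, origin_node, dist_to_branch, tid):
        self.pos = np.asarray(pos, dtype=float)
        self.direction = np.asarray(direction, dtype=float)
        self.origin_node = origin_node
        self.points = [self.pos.copy()]
        self.dist_to_branch = dist_to_branch
        self.tid = tid
        self.n_laid = 0
        self.alive = True


def _spread_directions(rng: np.random.Generator, n: int, min_angle_deg: float = 30.0):
    """Random unit directions with a minimum pairwise angular separation."""
    cos_max = np.cos(np.deg2rad(min_angle_deg))
    dirs: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(200):
            d = _random_unit(rng)[0]
            if all(np.dot(d, e) < cos_max for e in dirs):
                dirs.append(d)
                break
        else:  # crowded sphere; accept the last draw
            dirs.append(_random_unit(rng)[0])
    return np.array(dirs)


def census_pellet_spec(seed: int = 0) -> PelletSpec:
    """A small, collision-free pellet for skeleton-census validation.

    Sparse geometry (three germ tubes, wide branch angles, self-avoidance on)
    so that a noiseless voxelization at 1 µm resolves every tip and branch
    point of the ground-truth graph.
    """
    return PelletSpec(
        n_agglomerates=1,
        spores_per_agglomerate=1,
        germ_tubes_per_spore=3,
        growth_duration=1.5,
        tip_speed=40.0,
        target_branch_length=40.0,
        min_branch_spacing=16.0,
        direction_persistence=0.97,
        rng_seed=seed,
    )


def dense_pellet_spec(seed: int = 0, spores: int = 120) -> PelletSpec:
    """A dense class-I-like pellet whose envelope fill matches real pellets.

    120 spores × 3 germ tubes growing radially give a convex-hull solid
    fraction near 5% — the ~0.95 porosity regime typical of submerged
    *A. niger* pellets.  Self-avoidance is off: hyphal overlap contributes to
    the realistic dense core.
    """
    return PelletSpec(
        n_agglomerates=1,
        spores_per_agglomerate=spores,
        germ_tubes_per_spore=3,
        spore_spread=20.0,
        growth_duration=2.0,
        tip_speed=40.0,
        target_branch_length=80.0,
        min_branch_spacing=10.0,
        direction_persistence=0.95,
        self_avoidance=False,
        rng_seed=seed,
    )


def _next_branch_distance(rng: np.random.Generator, spec: PelletSpec) -> float:
    scale = spec.target_branch_length - spec.min_branch_spacing
    return spec.min_branch_spacing + rng.exponential(scale)


def grow_pellet(spec: PelletSpec) -> SyntheticPellet:
    """Grow one pellet off-lattice from its spore agglomerates.

    Spores are placed in ``n_agglomerates`` Gaussian clusters, each spore
    emits ``germ_tubes_per_spore`` tips (with a minimum angular separation so
    sibling tubes do not run on top of each other), tips advance at
    ``tip_speed`` with angular diffusion set by ``direction_persistence`` and
    branch laterally with the refractory-exponential spacing law.  Tips avoid
    existing hyphae (negative autotropism): a step that would bring a tip
    within ``avoidance_clearance`` of a non-adjacent hypha is deflected, or
    the tip is arrested if no clear direction exists.  All ground-truth
    counts are recorded exactly from the generated graph.
    """
    rng = np.random.default_rng(spec.rng_seed)
    g = nx.MultiGraph()
    next_id = [0]

    def add_node(pos, kind):
        nid = next_id[0]
        next_id[0] += 1
        g.add_node(nid, pos=np.asarray(pos, dtype=float), kind=kind)
        return nid

    # --- seeding: agglomerate centres, spores, germ tubes -----------------
    if spec.n_agglomerates == 1:
        centres = np.zeros((1, 3))
    else:
        centres = rng.normal(scale=spec.agglomerate_spread, size=(spec.n_agglomerates, 3))
        centres -= centres.mean(axis=0)
    spores = []
    spore_aggl = []
    for a, c in enumerate(centres):
        pts = c + rng.normal(scale=spec.spore_spread, size=(spec.spores_per_agglomerate, 3))
        spores.append(pts)
        spore_aggl.extend([a] * spec.spores_per_agglomerate)
    spore_points = np.vstack(spores)
    spore_aggl = np.array(spore_aggl)

    tips: list[_Tip] = []
    node_pos: dict[int, np.ndarray] = {}
    for sp in spore_points:
        root = add_node(sp, "root")
        node_pos[root] = np.asarray(sp, dtype=float)
        for d in _spread_directions(rng, spec.germ_tubes_per_spore):
            tips.append(_Tip(sp, d, root, _next_branch_distance(rng, spec), tid=len(tips)))

    # --- apical growth ----------------------------------------------------
    step = min(2.0, spec.target_branch_length / 8.0)
    total_length = spec.growth_duration * spec.tip_speed
    n_steps = max(1, int(round(total_length / step)))
    step = total_length / n_steps  # exact per-tip length for tips present at t=0
    sigma = (1.0 - spec.direction_persistence) * 0.9
    clearance = spec.avoidance_clearance
    junction_free = max(2.0 * clearance, 12.0)
    own_tail = int(np.ceil(clearance / step)) + 2
    n_branch_events = 0

    # laid centre-line points for the avoidance test (growable buffers)
    cap = 4096
    laid_pts = np.empty((cap, 3))
    laid_tid = np.empty(cap, dtype=int)
    laid_idx = np.empty(cap, dtype=int)
    n_laid_total = 0

    def lay_raw(pos: np.ndarray, tid: int, idx: int) -> None:
        nonlocal cap, laid_pts, laid_tid, laid_idx, n_laid_total
        if n_laid_total == cap:
            cap *= 2
            laid_pts = np.concatenate([laid_pts, np.empty((cap // 2, 3))])
            laid_tid = np.concatenate([laid_tid, np.empty(cap // 2, dtype=int)])
            laid_idx = np.concatenate([laid_idx, np.empty(cap // 2, dtype=int)])
        laid_pts[n_laid_total] = pos
        laid_tid[n_laid_total] = tid
        laid_idx[n_laid_total] = idx
        n_laid_total += 1

    for t in tips:
        lay_raw(t.pos, t.tid, 0)

    def conflicts(tip: _Tip, candidate: np.ndarray) -> bool:
        pts = laid_pts[:n_laid_total]
        d2 = ((pts - candidate) ** 2).sum(axis=1)
        close = np.flatnonzero(d2 < clearance**2)
        if len(close) == 0:
            return False
        origin = node_pos[tip.origin_node]
        for i in close:
            if laid_tid[i] == tip.tid and tip.n_laid - laid_idx[i] <= own_tail:
                continue  # the tip's own recent trail
            if np.linalg.norm(pts[i] - origin) < junction_free:
                continue  # shared junction region with parent/siblings
            return True
        return False

    def lay(tip: _Tip, pos: np.ndarray) -> None:
        tip.n_laid += 1
        lay_raw(pos, tip.tid, tip.n_laid)

    for istep in range(n_steps):
        remaining = (n_steps - istep) * step
        for tip in list(tips):
            if not tip.alive:
                continue
            direction = tip.direction
            if sigma > 0:
                direction = _unit(direction + rng.normal(scale=sigma, size=3))
            if spec.self_avoidance:
                candidate = tip.pos + direction * step
                if conflicts(tip, candidate):
                    ok = False
                    for _try in range(12):
                        axis = _unit(np.cross(tip.direction, _random_unit(rng)[0]))
                        alt = _rotate_about(tip.direction, axis, rng.uniform(0.5, 1.2))
                        if not conflicts(tip, tip.pos + alt * step):
                            direction, ok = alt, True
                            break
                    if not ok:
                        tip.alive = False  # arrested against another hypha
                        continue
            tip.direction = direction
            tip.pos = tip.pos + direction * step
            tip.points.append(tip.pos.copy())
            lay(tip, tip.pos)
            tip.dist_to_branch -= step
            if (
                spec.branching_enabled
                and tip.dist_to_branch <= 0
                and remaining - step >= spec.min_branch_spacing
            ):
                node = add_node(tip.pos, "branch")
                node_pos[node] = tip.pos.copy()
                n_branch_events += 1
                path = np.array(tip.points)
                g.add_edge(tip.origin_node, node, path=path, length=_polyline_length(path))
                # continuing tip restarts its polyline at the branch node
                tip.origin_node = node
                tip.points = [tip.pos.copy()]
                tip.dist_to_branch = _next_branch_distance(rng, spec)
                # daughter branch leaves at an angle off the parent axis
                axis = _unit(np.cross(tip.direction, _random_unit(rng)[0]))
                a0, a1 = spec.branch_angle_deg
                angle = rng.uniform(np.deg2rad(a0), np.deg2rad(a1))
                daughter_dir = _rotate_about(tip.direction, axis, angle)
                daughter = _Tip(
                    tip.pos, daughter_dir, node, _next_branch_distance(rng, spec), tid=len(tips)
                )
                tips.append(daughter)
                lay(daughter, daughter.pos)

    # --- finalize: close tip edges, discard degenerate arrested stubs -----
    kept_tips = 0
    for tip in tips:
        path = np.array(tip.points)
        length = _polyline_length(path)
        if length < spec.min_branch_spacing and not tip.alive:
            # arrested almost immediately: drop the stub and demote its
            # branch node if that leaves it with only two hyphal passes
            origin = tip.origin_node
            if g.nodes.get(origin, {}).get("kind") == "branch" and g.degree(origin) == 2:
                edges = list(g.edges(origin, keys=True, data=True))
                if len(edges) == 2:
                    (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
                    a = v1 if u1 == origin else u1
                    b = v2 if u2 == origin else u2
                    p1 = d1["path"] if np.allclose(d1["path"][-1], node_pos[origin]) else d1["path"][::-1]
                    p2 = d2["path"] if np.allclose(d2["path"][0], node_pos[origin]) else d2["path"][::-1]
                    g.remove_node(origin)
                    g.add_edge(a, b, path=np.vstack([p1, p2[1:]]),
                               length=d1["length"] + d2["length"])
                    n_branch_events -= 1
            continue
        node = add_node(tip.pos, "tip")
        g.add_edge(tip.origin_node, node, path=path, length=length)
        kept_tips += 1

    total = sum(d["length"] for _, _, d in g.edges(data=True))
    true_class: PelletClass = "I" if spec.n_agglomerates == 1 else "II"
    return SyntheticPellet(
        graph=g,
        spore_points=spore_points,
        spore_agglomerates=spore_aggl,
        hyphal_radius=spec.hyphal_radius,
        spore_radius=spec.spore_radius,
        true_total_length=total * 1e-6,
        true_tips=kept_tips,
        true_branch_points=n_branch_events,
        true_clusters=spec.n_agglomerates,
        true_class=true_class,
        provenance={"spec": spec, "events": []},
    )


def _polyline_length(path: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())


def _recount(pellet: SyntheticPellet) -> None:
    """Refresh structural counts from the stored graph after surgery."""
    g = pellet.graph
    deg = dict(g.degree())
    kinds = nx.get_node_attributes(g, "kind")
    pellet.true_tips = sum(
        1 for n, d in deg.items() if d == 1 and kinds.get(n) != "root"
    )
    pellet.true_branch_points = sum(
        1 for n, d in deg.items() if d >= 3 and kinds.get(n) != "root"
    )
    pellet.true_total_length = (
        sum(d["length"] for _, _, d in g.edges(data=True)) * 1e-6
    )


def apply_breakage(
    pellet: SyntheticPellet,
    plane_point: Sequence[float],
    plane_normal: Sequence[float],
) -> list[SyntheticPellet]:
    """Cut a pellet with a plane; fragments are flagged class IV.

    Every hyphal polyline is split exactly at its plane crossings, so the sum
    of fragment lengths equals the parent length.  Each fragment keeps the
    spores on its side of the plane.  A plane that misses the pellet returns
    the unmodified pellet as a single-element list.
    """
    p0 = np.asarray(plane_point, dtype=float)
    n = _unit(np.asarray(plane_normal, dtype=float))
    pts = pellet.all_points()
    if len(pts) == 0:
        return [pellet]
    eps = 1e-9  # vertices exactly on the plane count as the positive side
    side = (pts - p0) @ n
    if side.min() > -eps or side.max() < eps:
        return [pellet]

    g = nx.MultiGraph()
    for node, data in pellet.graph.nodes(data=True):
        g.add_node(node, **data)
    cut_id = [max(pellet.graph.nodes, default=-1) + 1]

    def new_cut_node(pos):
        nid = cut_id[0]
        cut_id[0] += 1
        g.add_node(nid, pos=pos, kind="cut")
        return nid

    for u, v, data in pellet.graph.edges(data=True):
        path = data["path"]
        d = (path - p0) @ n
        d[d == 0] = eps
        cross = np.flatnonzero(np.sign(d[:-1]) * np.sign(d[1:]) < 0)
        if len(cross) == 0:
            g.add_edge(u, v, path=path, length=data["length"])
            continue
        # build sub-paths with interpolated crossing points
        pieces = []
        start = 0
        prev_xp = None
        for i in cross:
            t = d[i] / (d[i] - d[i + 1])
            xp = path[i] + t * (path[i + 1] - path[i])
            seg = path[start : i + 1]
            if prev_xp is not None:
                seg = np.vstack([prev_xp, seg])
            pieces.append(np.vstack([seg, xp]))
            start = i + 1
            prev_xp = xp
        pieces.append(np.vstack([prev_xp, path[start:]]))
        # endpoints: first piece keeps u, last keeps v, cut points become tips
        # orient: path runs from the node stored first in the polyline
        ends = [u] + [None] * (len(pieces) - 1)
        ends_tail = [None] * (len(pieces) - 1) + [v]
        prev_cut = None
        for k, piece in enumerate(pieces):
            a = ends[k] if ends[k] is not None else prev_cut
            if ends_tail[k] is not None:
                b = ends_tail[k]
            else:
                b = new_cut_node(piece[-1].copy())
            # crossing point is shared by two pieces but the graph must NOT
            # reconnect them: give each side its own cut node
            if k < len(pieces) - 1:
                prev_cut = new_cut_node(piece[-1].copy())
            g.add_edge(a, b, path=piece, length=_polyline_length(piece))

    # group graph components by plane side: a fragment is everything that
    # remains physically entangled on one side of the cut
    half: dict[int, set] = {-1: set(), 1: set()}
    for comp in nx.connected_components(g):
        positions = np.array([g.nodes[c]["pos"] for c in comp])
        dmean = ((positions - p0) @ n).mean()
        half[1 if dmean >= 0 else -1].update(comp)
    sides = [s for s in (-1, 1) if half[s]]
    if len(sides) < 2:
        return [pellet]

    spore_side = (pellet.spore_points - p0) @ n if len(pellet.spore_points) else np.zeros(0)
    fragments = []
    event = {
        "type": "breakage",
        "plane_point": p0.tolist(),
        "plane_normal": n.tolist(),
    }
    for s in sides:
        sub = nx.MultiGraph(g.subgraph(half[s]).copy())
        keep = (spore_side >= 0) if s == 1 else (spore_side < 0)
        frag = SyntheticPellet(
            graph=sub,
            spore_points=pellet.spore_points[keep],
            spore_agglomerates=pellet.spore_agglomerates[keep],
            hyphal_radius=pellet.hyphal_radius,
            spore_radius=pellet.spore_radius,
            true_total_length=0.0,
            true_tips=0,
            true_branch_points=0,
            true_clusters=int(len(np.unique(pellet.spore_agglomerates[keep]))),
            true_class="IV",
            provenance={
                **copy.deepcopy(pellet.provenance),
                "events": pellet.provenance.get("events", []) + [event],
            },
        )
        _recount(frag)
        fragments.append(frag)
    return fragments


def apply_fusion(
    a: SyntheticPellet, b: SyntheticPellet, overlap: float = 10.0
) -> SyntheticPellet:
    """Fuse two pellets into a loosely entangled class III aggregate.

    ``b`` is translated along the line of centres so that the gap between the
    two hulls equals ``-overlap`` (their envelopes interpenetrate by
    ``overlap`` µm).  Graphs and spore sets are unioned; the spore-cluster
    count and total length are additive.
    """
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    pa, pb = a.all_points(), b.all_points()
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    u = _unit(cb - ca)
    gap = (pb @ u).min() - (pa @ u).max()
    shift = (-gap - overlap) * u

    g = nx.MultiGraph()
    for node, data in a.graph.nodes(data=True):
        g.add_node(("a", node), **data)
    for node, data in b.graph.nodes(data=True):
        d = dict(data)
        d["pos"] = d["pos"] + shift
        g.add_node(("b", node), **d)
    for uu, vv, data in a.graph.edges(data=True):
        g.add_edge(("a", uu), ("a", vv), **data)
    for uu, vv, data in b.graph.edges(data=True):
        d = dict(data)
        d["path"] = d["path"] + shift
        g.add_edge(("b", uu), ("b", vv), **d)

    aggl_offset = int(a.spore_agglomerates.max()) + 1 if len(a.spore_agglomerates) else 0
    fused = SyntheticPellet(
        graph=g,
        spore_points=np.vstack([a.spore_points, b.spore_points + shift])
        if len(a.spore_points) or len(b.spore_points)
        else np.zeros((0, 3)),
        spore_agglomerates=np.concatenate(
            [a.spore_agglomerates, b.spore_agglomerates + aggl_offset]
        ),
        hyphal_radius=a.hyphal_radius,
        spore_radius=a.spore_radius,
        true_total_length=a.true_total_length + b.true_total_length,
        true_tips=a.true_tips + b.true_tips,
        true_branch_points=a.true_branch_points + b.true_branch_points,
        true_clusters=a.true_clusters + b.true_clusters,
        true_class="III",
        provenance={
            "events": a.provenance.get("events", [])
            + b.provenance.get("events", [])
            + [{"type": "fusion", "overlap": overlap}],
        },
    )
    return fused


def voxelize(pellet: SyntheticPellet, voxel_size: float = 2.0) -> PelletVolume:
    """Rasterise a pellet: hyphae as tubes, spores as spheres.

    Each polyline is sampled at half-voxel spacing and a ball of the hyphal
    radius stamped at every sample, yielding a capsule-union approximation of
    the tube; spores are stamped with the spore radius.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if voxel_size > 2 * pellet.hyphal_radius:
        warnings.warn(
            "voxel_size exceeds the hyphal diameter; skeleton recovery is not guaranteed"
        )
    pts = pellet.all_points()
    if len(pts) == 0:
        raise ValueError("pellet has no geometry to voxelize")
    margin = pellet.hyphal_radius + pellet.spore_radius + 2 * voxel_size
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    shape = np.ceil((hi - lo) / voxel_size).astype(int) + 1
    grid = np.zeros(shape, dtype=bool)

    def stamp(points: np.ndarray, radius: float) -> None:
        if len(points) == 0:
            return
        r_vox = radius / voxel_size
        b = int(np.ceil(r_vox + 0.5))
        offs = np.array(
            [
                (i, j, k)
                for i in range(-b, b + 1)
                for j in range(-b, b + 1)
                for k in range(-b, b + 1)
            ]
        )
        idx_f = (points - lo) / voxel_size - 0.5  # fractional index of the point
        base = np.round(idx_f).astype(int)
        for chunk_start in range(0, len(points), 20000):
            sl = slice(chunk_start, chunk_start + 20000)
            cand = base[sl][:, None, :] + offs[None, :, :]
            centre = cand.astype(float)
            d2 = ((centre - idx_f[sl][:, None, :]) ** 2).sum(axis=2)
            hit = cand[d2 <= r_vox**2]
            hit = hit[
                (hit >= 0).all(axis=1) & (hit < shape).all(axis=1)
            ]
            grid[hit[:, 0], hit[:, 1], hit[:, 2]] = True

    for path in pellet.segments:
        if len(path) < 2:
            continue
        seg_len = np.linalg.norm(np.diff(path, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        n_samples = max(2, int(np.ceil(cum[-1] / (voxel_size / 2.0))) + 1)
        s = np.linspace(0.0, cum[-1], n_samples)
        samples = np.column_stack(
            [np.interp(s, cum, path[:, k]) for k in range(3)]
        )
        stamp(samples, pellet.hyphal_radius)
    stamp(pellet.spore_points, pellet.spore_radius)
    return PelletVolume(grid, voxel_size, origin=lo)


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------


@dataclass
class PelletRecord:
    """Lightweight per-pellet state for population-scale simulation."""

    diameter: float  # µm
    pellet_class: PelletClass
    n_clusters: int


@dataclass
class SyntheticPopulation:
    """A sampled pellet population at one timepoint."""

    pellets: list[PelletRecord]
    timepoint: float  # h
    event_log: list[dict]
    sampled_volume: float  # mL

    def __post_init__(self) -> None:
        if not self.sampled_volume > 0:
            raise ValueError("sampled_volume must be positive")

    @property
    def diameters(self) -> np.ndarray:
        return np.array([p.diameter for p in self.pellets])

    @property
    def concentration(self) -> float:
        return len(self.pellets) / self.sampled_volume

    def mean_clusters(self) -> float:
        return float(np.mean([p.n_clusters for p in self.pellets]))


_DEFAULT_CLASS_MIX = {"I": 0.7, "II": 0.3}


def _sample_clusters(rng: np.random.Generator, cls: str) -> int:
    if cls == "I":
        return int(rng.integers(1, 4))
    if cls == "II":
        return int(4 + rng.poisson(3.0))
    if cls == "III":
        return int(5 + rng.poisson(6.0))
    return 1


def simulate_population(
    n: int,
    diameter_median: float = 609.0,
    diameter_gcv: float = 0.33,
    class_mix: dict[str, float] | None = None,
    breakage_rate: float = 0.0,
    fusion_rate: float = 0.0,
    n_steps: int = 1,
    sampled_volume: float = 1.0,
    timepoint: float = 0.0,
    seed: int = 0,
) -> SyntheticPopulation:
    """Sample a pellet population and apply breakage/fusion event schedules.

    Diameters follow a lognormal law with the given median and coefficient of
    variation.  Per step, ``max(1, round(rate·count))`` events fire for each
    nonzero rate: breakage replaces a (size-biased) pellet by two volume-
    conserving class IV fragments; fusion merges two pellets into one class
    III pellet with summed spore clusters.  A breakage-dominated schedule
    therefore strictly increases pellet count and pushes the median down; a
    fusion-dominated schedule does the reverse.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(class_mix) if class_mix else dict(_DEFAULT_CLASS_MIX)
    total = sum(mix.values())
    if not np.isclose(total, 1.0):
        raise ValueError("class_mix shares must sum to 1")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(diameter_gcv**2))
    diam = diameter_median * np.exp(rng.normal(0.0, sigma, size=n))
    classes = rng.choice(list(mix.keys()), size=n, p=list(mix.values()))
    pellets = [
        PelletRecord(float(d), str(c), _sample_clusters(rng, str(c)))
        for d, c in zip(diam, classes)
    ]
    event_log: list[dict] = []

    for step in range(n_steps):
        if breakage_rate > 0:
            k = max(1, int(round(breakage_rate * len(pellets))))
            for _ in range(k):
                w = np.array([p.diameter**2 for p in pellets])
                i = int(rng.choice(len(pellets), p=w / w.sum()))
                parent = pellets.pop(i)
                f = rng.uniform(0.25, 0.5)
                d1 = parent.diameter * f ** (1 / 3)
                d2 = parent.diameter * (1 - f) ** (1 / 3)
                c1 = int(rng.binomial(parent.n_clusters, f)) if parent.n_clusters else 0
                frag1 = PelletRecord(d1, "IV", max(c1, 1 if parent.n_clusters else 0))
                frag2 = PelletRecord(d2, "IV", max(parent.n_clusters - frag1.n_clusters, 0))
                pellets.extend([frag1, frag2])
                event_log.append(
                    {"step": step, "type": "breakage", "parent_d": parent.diameter,
                     "fragments": [d1, d2]}
                )
        if fusion_rate > 0:
            k = max(1, int(round(fusion_rate * len(pellets))))
            for _ in range(k):
                if len(pellets) < 2:
                    break
                i, j = rng.choice(len(pellets), size=2, replace=False)
                i, j = sorted((int(i), int(j)))
                b = pellets.pop(j)
                a = pellets.pop(i)
                d = (a.diameter**3 + b.diameter**3) ** (1 / 3)
                pellets.append(PelletRecord(d, "III", a.n_clusters + b.n_clusters))
                event_log.append(
                    {"step": step, "type": "fusion",
                     "parents": [a.diameter, b.diameter], "merged_d": d}
                )
    return SyntheticPopulation(pellets, timepoint, event_log, sampled_volume)


def render_projection(
    pop: SyntheticPopulation,
    field: tuple[float, float] = (10000.0, 10000.0),
    pixel_size: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 0.85,
    foreground: float = 0.15,
    min_gap: float = 20.0,
    max_tries: int = 20000,
) -> tuple[Image2D, "np.ndarray"]:
    """Orthographic projection of a pellet population in a dish.

    Pellets appear as dark antialiased disks on a bright background with
    additive Gaussian noise of ``noise_sd`` (intensity units, image scale
    0–1).  Pellets are placed without overlap (dispersal with surfactant
    keeps them separate in the emulated protocol).  Returns the image and a
    ground-truth array of (x µm, y µm, diameter µm) per pellet.

    Raises a placement error when the field cannot host the requested pellets.
    """
    w, h = field
    rng = np.random.default_rng(seed)
    diams = pop.diameters
    order = np.argsort(diams)[::-1]  # place large pellets first
    px_arr = np.empty(len(diams))
    py_arr = np.empty(len(diams))
    pr_arr = np.empty(len(diams))
    n_placed = 0
    for i in order:
        d = diams[i]
        r = d / 2.0
        if 2 * r + 2 * min_gap > min(w, h):
            raise ValueError("field too small for the largest pellet")
        ok = False
        for _ in range(max_tries):
            x = rng.uniform(r + min_gap, w - r - min_gap)
            y = rng.uniform(r + min_gap, h - r - min_gap)
            if n_placed == 0 or np.all(
                (x - px_arr[:n_placed]) ** 2 + (y - py_arr[:n_placed]) ** 2
                > (r + pr_arr[:n_placed] + min_gap) ** 2
            ):
                px_arr[n_placed], py_arr[n_placed], pr_arr[n_placed] = x, y, r
                n_placed += 1
                ok = True
                break
        if not ok:
            raise ValueError("field too small for the requested pellet count")
    placed = list(zip(px_arr[:n_placed], py_arr[:n_placed], pr_arr[:n_placed]))
    nx_, ny = int(round(w / pixel_size)), int(round(h / pixel_size))
    img = np.full((ny, nx_), background, dtype=float)
    xs = (np.arange(nx_) + 0.5) * pixel_size
    ys = (np.arange(ny) + 0.5) * pixel_size
    for x, y, r in placed:
        # local window around the disk
        j0, j1 = np.searchsorted(xs, [x - r - 2 * pixel_size, x + r + 2 * pixel_size])
        i0, i1 = np.searchsorted(ys, [y - r - 2 * pixel_size, y + r + 2 * pixel_size])
        gx, gy = np.meshgrid(xs[j0:j1], ys[i0:i1])
        dist = np.sqrt((gx - x) ** 2 + (gy - y) ** 2)
        cover = np.clip((r - dist) / pixel_size + 0.5, 0.0, 1.0)
        img[i0:i1, j0:j1] -= (background - foreground) * cover
    if noise_sd > 0:
        img = img + rng.normal(scale=noise_sd, size=img.shape)
    truth = np.array([(x, y, 2 * r) for x, y, r in placed])
    return Image2D(img, pixel_size, pop.sampled_volume), truth


def simulate_growth_series(
    mu: float = 0.15,
    y_xs: float = 0.65,
    cdw0: float = 0.8,
    glucose0: float = 8.0,
    t_end: float = 20.0,
    dt: float = 2.0,
    lag: float = 2.0,
    noise: float = 0.02,
    seed: int = 0,
):
    """Synthetic batch cultivation: exponential growth until glucose runs out.

    CDW grows at rate ``mu`` after a lag, glucose falls as the biomass gain
    divided by the yield ``y_xs``, and both signals get multiplicative
    Gaussian noise.  Returns a :class:`pelletmorph.kinetics.GrowthSeries`.
    """
    from .kinetics import GrowthSeries

    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_end + dt / 2, dt)
    cdw = np.empty_like(times)
    glucose = np.empty_like(times)
    for i, t in enumerate(times):
        x = cdw0 * np.exp(mu * max(t - lag, 0.0))
        s = glucose0 - (x - cdw0) / y_xs
        if s <= 0:
            # growth stops when glucose is exhausted
            x = cdw0 + glucose0 * y_xs
            s = 0.0
        cdw[i] = x
        glucose[i] = s
    if noise > 0:
        cdw = cdw * (1 + rng.normal(scale=noise, size=cdw.shape))
        glucose = np.maximum(glucose * (1 + rng.normal(scale=noise, size=glucose.shape)), 0.0)
    return GrowthSeries(times=times, cdw=cdw, glucose=glucose, replicate="synthetic")
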