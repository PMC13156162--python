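import numpy as np
import pytest

from pelletmorph import tomo3d


def make_ball(radius: float, voxel_size: float = 1.0, pad: int = 10) -> tomo3d.PelletVolume:
    """Solid ball phantom with the given physical radius (µm)."""
    n = int(2 * (radius / voxel_size + pad))
    x, y, z = np.indices((n, n, n))
    c = (n - 1) / 2
    grid = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= (radius / voxel_size) ** 2
    return tomo3d.PelletVolume(grid, voxel_size)


def make_tube(length: float, radius: float, voxel_size: float = 1.0) -> tomo3d.PelletVolume:
    """Straight tube along z with the given physical length and radius (µm)."""
    r_vox = radius / voxel_size
    nxy = int(2 * r_vox + 13)
    nz = int(length / voxel_size + 20)
    x, y, z = np.indices((nxy, nxy, nz))
    c = nxy // 2  # integer centre: keeps the discretized tube asymmetric-free
    z0 = 10
    grid = ((x - c) ** 2 + (y - c) ** 2 <= r_vox**2) & (z >= z0) & (
        z < z0 + length / voxel_size
    )
    return tomo3d.PelletVolume(grid, voxel_size)


def make_y_phantom(arm: float = 60.0, radius: float = 1.5, voxel_size: float = 1.0):
    """Three straight arms of equal length meeting at one junction."""
    from scipy.spatial import cKDTree

    n = int(2 * arm / voxel_size + 20)
    c = np.array([n / 2, n / 2, n / 2], dtype=float)
    dirs = [
        np.array([1.0, 0.0, 0.0]),
        np.array([-0.5, np.sqrt(3) / 2, 0.0]),
        np.array([-0.5, -np.sqrt(3) / 2, 0.0]),
    ]
    samples = np.vstack(
        [c + d * np.linspace(0, arm / voxel_size, int(4 * arm))[:, None] for d in dirs]
    )
    idx = np.indices((n, n, n)).reshape(3, -1).T.astype(float)
    dist, _ = cKDTree(samples).query(idx, workers=-1)
    grid = (dist <= radius / voxel_size).reshape((n, n, n))
    return tomo3d.PelletVolume(grid, voxel_size)


def disk_image(
    centers, radii_um, pixel_size=1.0, shape=(400, 400), bg=0.9, fg=0.1, sampled_volume=0.1
):
    """Antialiased dark disks on a bright background."""
    from pelletmorph.image2d import Image2D

    arr = np.full(shape, bg, dtype=float)
    yy, xx = np.indices(shape)
    for (cx, cy), r in zip(centers, radii_um):
        dist = np.sqrt((xx * pixel_size - cx) ** 2 + (yy * pixel_size - cy) ** 2)
        cover = np.clip((r - dist) / pixel_size + 0.5, 0.0, 1.0)
        arr -= (bg - fg) * cover
    return Image2D(np.clip(arr, 0, 1), pixel_size, sampled_volume)


@pytest.fixture(scope="session")
def ball100():
    return make_ball(100.0, 1.0)


def dbscan_oracle(points: np.ndarray, eps: float, min_pts: int):
    """Brute-force density clustering: O(n²) eps-graph over core points.

    A point is core when at least ``min_pts`` points (itself included) lie
    within ``eps``; clusters are the connected components of core points
    under the eps relation, with non-core points attached to any cluster
    that has a core point within eps (border) or labelled noise.
    Returns (core_mask, labels, n_clusters); border labels may legitimately
    differ from another implementation when a border point neighbours
    several clusters.
    """
    n = len(points)
    if n == 0:
        return np.zeros(0, bool), np.empty(0, int), 0
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    neigh = dist <= eps
    core = neigh.sum(axis=1) >= min_pts
    labels = -np.ones(n, dtype=int)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(neigh[j] & core):
                if labels[k] == -1:
                    labels[k] = cid
                    stack.append(k)
        cid += 1
    for i in range(n):
        if core[i] or not neigh[i][core].any():
            continue
        labels[i] = labels[np.flatnonzero(neigh[i] & core)[0]]
    return core, labels, cid
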