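"""Independent brute-force oracles for the defect detector.

These deliberately re-derive the rasterization and component labeling by
dense enumeration (every cell against every atom and every periodic image;
pure flood fill on the torus) so the optimized implementations can be
checked for bit-identical output on small inputs.
"""

from __future__ import annotations

import numpy as np

from fuse_kinetics.defects import DEEP, POLAR, SHALLOW, UNCOVERED, DEEP_THRESHOLD


def brute_force_defect_grid(snapshot, leaflet, classifier, cell_size=1.0):
    """Dense per-cell re-derivation of the defect classification grid."""
    sel = snapshot.leaflets == leaflet
    sign = 1.0 if leaflet == "upper" else -1.0
    names = snapshot.names[sel]
    resnames = snapshot.resnames[sel]
    xyz = snapshot.xyz[sel]
    classes = np.array(
        [classifier.classify(rn, nm) for rn, nm in zip(resnames, names)], dtype=object
    )
    radii = np.array(
        [classifier.radius(rn, nm) for rn, nm in zip(resnames, names)], dtype=float
    )
    ref_sel = np.array(
        [classifier.is_ref(rn, nm) for rn, nm in zip(resnames, names)], dtype=bool
    )
    if ref_sel.any():
        ref_z = float(xyz[ref_sel, 2].mean())
    else:
        ref_z = float(xyz[:, 2].mean())

    box_x, box_y = float(snapshot.box[0]), float(snapshot.box[1])
    nx = int(np.ceil(box_x / cell_size))
    ny = int(np.ceil(box_y / cell_size))
    centers_x = (np.arange(nx) + 0.5) * cell_size
    centers_y = (np.arange(ny) + 0.5) * cell_size

    # all 9 periodic images of every atom, flattened
    images_x, images_y, heights, is_polar, r2 = [], [], [], [], []
    base_heights = sign * xyz[:, 2] + radii
    for i in range(xyz.shape[0]):
        for kx in (-1.0, 0.0, 1.0):
            for ky in (-1.0, 0.0, 1.0):
                images_x.append(xyz[i, 0] + kx * box_x)
                images_y.append(xyz[i, 1] + ky * box_y)
                heights.append(base_heights[i])
                is_polar.append(classes[i] == "polar")
                r2.append(radii[i] * radii[i])
    images_x = np.array(images_x)
    images_y = np.array(images_y)
    heights = np.array(heights)
    is_polar = np.array(is_polar)
    r2 = np.array(r2)

    grid = np.full((nx, ny), UNCOVERED, dtype=np.int8)
    ref_h = sign * ref_z
    for ix in range(nx):
        dx = centers_x[ix] - images_x
        dx2 = dx * dx
        for iy in range(ny):
            dy = centers_y[iy] - images_y
            covering = dx2 + dy * dy <= r2
            if not covering.any():
                continue
            hp = heights[covering & is_polar]
            hh = heights[covering & ~is_polar]
            best_p = hp.max() if hp.size else -np.inf
            best_h = hh.max() if hh.size else -np.inf
            if best_p >= best_h:
                grid[ix, iy] = POLAR
            elif best_h <= ref_h - DEEP_THRESHOLD:
                grid[ix, iy] = DEEP
            else:
                grid[ix, iy] = SHALLOW
    return grid, ref_z


def flood_fill_component_sizes(mask, connectivity=4, periodic=True):
    """Component sizes (descending) by explicit BFS flood fill on the torus."""
    nx, ny = mask.shape
    if connectivity == 4:
        offsets = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        offsets = [
            (1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1), (-1, 1), (-1, -1),
        ]
    seen = np.zeros_like(mask, dtype=bool)
    sizes = []
    for sx in range(nx):
        for sy in range(ny):
            if not mask[sx, sy] or seen[sx, sy]:
                continue
            stack = [(sx, sy)]
            seen[sx, sy] = True
            count = 0
            while stack:
                x, y = stack.pop()
                count += 1
                for dx, dy in offsets:
                    qx, qy = x + dx, y + dy
                    if periodic:
                        qx %= nx
                        qy %= ny
                    elif not (0 <= qx < nx and 0 <= qy < ny):
                        continue
                    if mask[qx, qy] and not seen[qx, qy]:
                        seen[qx, qy] = True
                        stack.append((qx, qy))
            sizes.append(count)
    return sorted(sizes, reverse=True)


def random_snapshot(rng, max_atoms=200, box_max=50.0, leaflet="upper"):
    """A random labeled bead snapshot plus a matching classifier."""
    from fuse_kinetics.defects import AtomClassifier, BilayerSnapshot

    n = int(rng.integers(20, max_atoms + 1))
    box = float(rng.uniform(15.0, box_max))
    xyz = np.column_stack(
        [
            rng.uniform(0, box, n),
            rng.uniform(0, box, n),
            rng.uniform(10.0, 16.0, n) * (1.0 if leaflet == "upper" else -1.0),
        ]
    )
    names = np.array([f"A{i:03d}" for i in range(n)], dtype=object)
    polar = rng.random(n) < 0.5
    polar[0] = True  # guarantee one glycerol reference atom
    names[0] = "REF"
    classes = {
        str(nm): ("polar" if p else "hydrophobic") for nm, p in zip(names, polar)
    }
    radii = {str(nm): float(r) for nm, r in zip(names, rng.uniform(0.7, 2.5, n))}
    classifier = AtomClassifier(
        atom_classes={"RND": classes}, glycerol_ref={"RND": "REF"}, radii=radii
    )
    snapshot = BilayerSnapshot(
        names=names,
        resnames=np.full(n, "RND", dtype=object),
        resids=np.arange(1, n + 1),
        xyz=xyz,
        box=np.array([box, box, 60.0]),
        leaflets=np.full(n, leaflet, dtype=object),
    )
    return snapshot, classifier
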