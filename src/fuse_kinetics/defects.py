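"""Hydrophobic (packing) defect detection on flat bilayer snapshots.

A packing defect is a patch of membrane surface where the first atoms met
when looking at the bilayer perpendicularly from the water phase belong to
the acyl chains rather than to the polar heads.  The detector rasterizes one
leaflet onto a square x/y grid (1 A cells by default), ranks, for every cell,
the atoms whose van der Waals disk covers the cell center by the height of
their top surface along the viewing direction, and classifies the cell:

* ``polar``          - the topmost covering atom is polar;
* ``shallow_defect`` - the topmost atom is hydrophobic, its top surface less
                       than 1 A below the leaflet-mean central glycerol
                       carbon;
* ``deep_defect``    - hydrophobic and at least 1 A below that reference;
* ``uncovered``      - no atom covers the cell center (water gap).

Deep and shallow cells merge into the ``all`` category.  Contiguous defect
cells form defect components (4-connectivity by default, stitched across the
periodic x/y boundaries), and the headline statistic is the fraction of the
membrane area occupied by defect cells, averaged over frames.

Only flat bilayers are supported; leaflets are split by the sign of each
lipid's reference-atom height relative to the bilayer midplane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .errors import ClassificationError, DomainError

__all__ = [
    "UNCOVERED",
    "POLAR",
    "SHALLOW",
    "DEEP",
    "CATEGORY_NAMES",
    "BilayerSnapshot",
    "AtomClassifier",
    "DefectMap",
    "DefectComponent",
    "DefectStats",
    "toy_classifier",
    "assign_leaflets",
    "rasterize_leaflet",
    "find_defects",
    "defect_surface_fraction",
    "defect_series_vs_composition",
]

UNCOVERED, POLAR, SHALLOW, DEEP = 0, 1, 2, 3
CATEGORY_NAMES = {UNCOVERED: "uncovered", POLAR: "polar", SHALLOW: "shallow_defect", DEEP: "deep_defect"}

#: Default van der Waals radii (A) by element symbol.
DEFAULT_RADII = {"C": 1.7, "H": 1.2, "N": 1.55, "O": 1.52, "P": 1.8, "S": 1.8}

#: Depth (A) below the central glycerol carbon separating deep from shallow.
DEEP_THRESHOLD = 1.0


@dataclass
class BilayerSnapshot:
    """Atom records of one flat-bilayer frame.

    Coordinates are in Angstrom; ``box`` holds the periodic x/y (and z)
    lengths; ``leaflets`` holds 'upper'/'lower' per atom ('' = unassigned).
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    xyz: np.ndarray
    box: np.ndarray
    leaflets: np.ndarray | None = None
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        n = self.names.size
        if self.xyz.shape != (n, 3):
            raise DomainError(f"coordinates must be ({n}, 3), got {self.xyz.shape}")
        if not (self.box[0] > 0 and self.box[1] > 0):
            raise DomainError(f"box x/y lengths must be positive, got {self.box[:2]}")
        if self.leaflets is None:
            self.leaflets = np.full(n, "", dtype=object)
        else:
            self.leaflets = np.asarray(self.leaflets, dtype=object)

    @property
    def n_atoms(self) -> int:
        return int(self.names.size)


@dataclass
class AtomClassifier:
    """Polar/hydrophobic atom classification with vdW radii.

    ``atom_classes`` maps residue name -> atom name -> 'polar'|'hydrophobic';
    ``glycerol_ref`` names, per residue, the central glycerol carbon used as
    the depth reference; ``radii`` maps atom names (looked up first) or
    element symbols to vdW radii in Angstrom.
    """

    atom_classes: dict
    glycerol_ref: dict = field(default_factory=dict)
    radii: dict = field(default_factory=lambda: dict(DEFAULT_RADII))

    def classify(self, resname: str, name: str) -> str:
        try:
            return self.atom_classes[resname][name]
        except KeyError:
            raise ClassificationError(
                f"atom {name!r} of residue {resname!r} is not in the classifier"
            ) from None

    def radius(self, resname: str, name: str) -> float:
        if name in self.radii:
            r = self.radii[name]
        else:
            element = next((c for c in name if c.isalpha()), "").upper()
            if element not in self.radii:
                raise ClassificationError(
                    f"no vdW radius for atom {name!r} of residue {resname!r}"
                )
            r = self.radii[element]
        if not r > 0:
            raise ClassificationError(f"non-positive radius for atom {name!r}")
        return float(r)

    def is_ref(self, resname: str, name: str) -> bool:
        return self.glycerol_ref.get(resname) == name

    @classmethod
    def from_yaml(cls, path) -> "AtomClassifier":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            atom_classes=raw["atom_classes"],
            glycerol_ref=raw.get("glycerol_ref", {}),
            radii={**DEFAULT_RADII, **raw.get("radii", {})},
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "atom_classes": self.atom_classes,
                    "glycerol_ref": self.glycerol_ref,
                    "radii": self.radii,
                },
                fh,
            )


def toy_classifier(bead_radius: float = 0.9) -> AtomClassifier:
    """Classifier for the toy bead bilayers built by the synthetic module."""
    return AtomClassifier(
        atom_classes={"TOY": {"HD": "polar", "TL": "hydrophobic"}},
        glycerol_ref={"TOY": "HD"},
        radii={"HD": bead_radius, "TL": bead_radius},
    )


@dataclass
class DefectMap:
    """Per-cell classification grid for one leaflet of one frame.

    ``grid`` is indexed [ix, iy] with values in {UNCOVERED, POLAR, SHALLOW,
    DEEP}; ``ref_z`` is the leaflet-mean z of the central glycerol carbon.
    """

    grid: np.ndarray
    cell_size: float
    leaflet: str
    ref_z: float
    box_xy: tuple[float, float]
    frame_id: int = 0

    def category_mask(self, category: str) -> np.ndarray:
        if category == "deep":
            return self.grid == DEEP
        if category == "shallow":
            return self.grid == SHALLOW
        if category == "all":
            return (self.grid == DEEP) | (self.grid == SHALLOW)
        if category == "polar":
            return self.grid == POLAR
        if category == "uncovered":
            return self.grid == UNCOVERED
        raise DomainError(f"unknown defect category {category!r}")


def assign_leaflets(
    snapshot: BilayerSnapshot, classifier: AtomClassifier | None = None
) -> BilayerSnapshot:
    """Label every atom 'upper' or 'lower' by its lipid's side of the midplane.

    The midplane is the mean z of all atoms; each lipid's reference height is
    the z of its central glycerol carbon when the classifier names one, else
    the mean z of the residue.  The whole residue inherits the label.
    """
    z = snapshot.xyz[:, 2]
    midplane = float(z.mean())
    leaflets = np.full(snapshot.n_atoms, "", dtype=object)
    for resid in np.unique(snapshot.resids):
        sel = snapshot.resids == resid
        ref_z = None
        if classifier is not None:
            resname = snapshot.resnames[sel][0]
            ref_name = classifier.glycerol_ref.get(resname)
            if ref_name is not None:
                hit = sel & (snapshot.names == ref_name)
                if hit.any():
                    ref_z = float(z[hit].mean())
        if ref_z is None:
            ref_z = float(z[sel].mean())
        leaflets[sel] = "upper" if ref_z > midplane else "lower"
    if len(set(leaflets)) < 2:
        raise DomainError(
            "degenerate bilayer: all lipids fall on one side of the midplane"
        )
    return BilayerSnapshot(
        names=snapshot.names,
        resnames=snapshot.resnames,
        resids=snapshot.resids,
        xyz=snapshot.xyz,
        box=snapshot.box,
        leaflets=leaflets,
        frame_id=snapshot.frame_id,
    )


def _leaflet_atoms(snapshot: BilayerSnapshot, leaflet: str):
    sel = snapshot.leaflets == leaflet
    if not sel.any():
        raise DomainError(f"no atoms assigned to the {leaflet!r} leaflet")
    return sel


def rasterize_leaflet(
    snapshot: BilayerSnapshot,
    leaflet: str,
    classifier: AtomClassifier,
    cell_size: float = 1.0,
) -> DefectMap:
    """Classify every grid cell of one leaflet by its topmost covering atom.

    An atom covers a cell when the cell center lies inside the atom's vdW
    disk in x/y, with periodic wrapping.  Atoms are ranked by the height of
    their top surface along the viewing direction (z + radius for the upper
    leaflet, mirrored for the lower); ties between a polar and a hydrophobic
    atom at identical height go to polar, which conservatively underestimates
    defects.  A hydrophobic top surface at least 1 A below the leaflet-mean
    central glycerol carbon makes the cell a deep defect, else shallow.
    """
    if not cell_size > 0:
        raise DomainError(f"cell_size must be positive, got {cell_size}")
    sel = _leaflet_atoms(snapshot, leaflet)
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
        # no glycerol reference in this leaflet (e.g. headless slabs):
        # fall back to the leaflet-mean atom height
        ref_z = float(xyz[:, 2].mean())

    box_x, box_y = float(snapshot.box[0]), float(snapshot.box[1])
    nx = int(np.ceil(box_x / cell_size))
    ny = int(np.ceil(box_y / cell_size))
    centers_x = (np.arange(nx) + 0.5) * cell_size
    centers_y = (np.arange(ny) + 0.5) * cell_size

    best_polar = np.full((nx, ny), -np.inf)
    best_hydro = np.full((nx, ny), -np.inf)

    heights = sign * xyz[:, 2] + radii
    for i in range(xyz.shape[0]):
        rho = radii[i]
        r2 = rho * rho
        h = heights[i]
        target = best_polar if classes[i] == "polar" else best_hydro
        for kx in (-1.0, 0.0, 1.0):
            ax = xyz[i, 0] + kx * box_x
            ix_lo = max(int(np.ceil((ax - rho) / cell_size - 0.5)), 0)
            ix_hi = min(int(np.floor((ax + rho) / cell_size - 0.5)), nx - 1)
            if ix_hi < ix_lo:
                continue
            dx = centers_x[ix_lo : ix_hi + 1] - ax
            for ky in (-1.0, 0.0, 1.0):
                ay = xyz[i, 1] + ky * box_y
                iy_lo = max(int(np.ceil((ay - rho) / cell_size - 0.5)), 0)
                iy_hi = min(int(np.floor((ay + rho) / cell_size - 0.5)), ny - 1)
                if iy_hi < iy_lo:
                    continue
                dy = centers_y[iy_lo : iy_hi + 1] - ay
                mask = dx[:, None] ** 2 + dy[None, :] ** 2 <= r2
                block = target[ix_lo : ix_hi + 1, iy_lo : iy_hi + 1]
                np.maximum(block, np.where(mask, h, -np.inf), out=block)

    grid = np.full((nx, ny), UNCOVERED, dtype=np.int8)
    covered = (best_polar > -np.inf) | (best_hydro > -np.inf)
    polar_wins = covered & (best_polar >= best_hydro)
    hydro_wins = covered & ~polar_wins
    grid[polar_wins] = POLAR
    ref_h = sign * ref_z
    deep = hydro_wins & (best_hydro <= ref_h - DEEP_THRESHOLD)
    grid[hydro_wins] = SHALLOW
    grid[deep] = DEEP
    return DefectMap(
        grid=grid,
        cell_size=cell_size,
        leaflet=leaflet,
        ref_z=ref_z,
        box_xy=(box_x, box_y),
        frame_id=snapshot.frame_id,
    )


@dataclass(frozen=True)
class DefectComponent:
    """One connected patch of defect cells."""

    n_cells: int
    area: float


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def find_defects(
    dmap: DefectMap,
    category: str = "all",
    connectivity: int = 4,
    periodic: bool = True,
) -> list[DefectComponent]:
    """Connected components of defect cells, largest first.

    Components are merged across the periodic x/y box edges by default.
    ``connectivity`` is 4 (edge neighbors) or 8 (edges + diagonals).
    """
    if connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
        offsets = [(1, 0), (0, 1)]
    elif connectivity == 8:
        structure = ndimage.generate_binary_structure(2, 2)
        offsets = [(1, 0), (0, 1), (1, 1), (1, -1)]
    else:
        raise DomainError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = dmap.category_mask(category)
    labels, n_labels = ndimage.label(mask, structure=structure)
    if n_labels == 0:
        return []
    if periodic:
        uf = _UnionFind(n_labels + 1)
        for dx, dy in offsets:
            shifted = np.roll(labels, shift=(-dx, -dy), axis=(0, 1))
            both = (labels > 0) & (shifted > 0)
            if both.any():
                pairs = np.unique(
                    np.stack([labels[both], shifted[both]], axis=1), axis=0
                )
                for a, b in pairs:
                    uf.union(int(a), int(b))
        roots = np.array([uf.find(i) for i in range(n_labels + 1)])
        labels = roots[labels]
    counts = np.bincount(labels.ravel())[1:]
    counts = counts[counts > 0]
    area = dmap.cell_size**2
    comps = [DefectComponent(n_cells=int(c), area=float(c * area)) for c in counts]
    return sorted(comps, key=lambda c: c.n_cells, reverse=True)


@dataclass(frozen=True)
class DefectStats:
    """Surface fraction occupied by defects of one category.

    ``fraction`` is the across-frame mean of (cells in category)/(denominator
    cells); ``sem`` the standard error across frames (None for one frame).
    """

    category: str
    fraction: float
    sem: float | None
    per_frame: tuple
    n_frames: int
    denominator: str
    components: tuple


def defect_surface_fraction(
    maps: Sequence[DefectMap],
    category: str = "all",
    denominator: str = "box",
    connectivity: int = 4,
) -> DefectStats:
    """Fraction of membrane area occupied by a defect category.

    ``denominator="box"`` divides by all grid cells (the full membrane
    area); ``"covered"`` divides by lipid-covered cells only, excluding
    water gaps.  Maps must share a common grid.
    """
    maps = list(maps)
    if not maps:
        raise DomainError("defect_surface_fraction requires at least one map")
    shape = maps[0].grid.shape
    cell = maps[0].cell_size
    for m in maps[1:]:
        if m.grid.shape != shape or m.cell_size != cell:
            raise DomainError(
                f"mismatched grids: {m.grid.shape}@{m.cell_size} vs {shape}@{cell}"
            )
    if denominator not in ("box", "covered"):
        raise DomainError(f"denominator must be 'box' or 'covered', got {denominator!r}")
    fractions = []
    components: list[DefectComponent] = []
    for m in maps:
        n_cat = int(m.category_mask(category).sum())
        if denominator == "box":
            denom = m.grid.size
        else:
            denom = int((m.grid != UNCOVERED).sum())
            if denom == 0:
                raise DomainError("no covered cells: covered-area fraction undefined")
        fractions.append(n_cat / denom)
        components.extend(find_defects(m, category=category, connectivity=connectivity))
    arr = np.asarray(fractions)
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None
    return DefectStats(
        category=category,
        fraction=float(arr.mean()),
        sem=sem,
        per_frame=tuple(float(v) for v in arr),
        n_frames=arr.size,
        denominator=denominator,
        components=tuple(components),
    )


def defect_series_vs_composition(
    groups: Mapping[str, Iterable[DefectMap]],
    category: str = "all",
    denominator: str = "box",
) -> pd.DataFrame:
    """Tidy table of defect fraction against composition label.

    One row per group with columns ``label``, ``fraction``, ``sem`` and
    ``n_frames``; intended for plotting defect density against, e.g., the
    conical-lipid fraction of a series of bilayers.
    """
    if len(groups) < 2:
        raise DomainError(
            f"a composition series needs at least 2 groups, got {len(groups)}"
        )
    rows = []
    for label, maps in groups.items():
        stats = defect_surface_fraction(list(maps), category=category, denominator=denominator)
        rows.append(
            {
                "label": label,
                "fraction": stats.fraction,
                "sem": stats.sem,
                "n_frames": stats.n_frames,
            }
        )
    return pd.DataFrame(rows)
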