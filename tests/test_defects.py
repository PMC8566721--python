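"""Defect rasterization, component labeling and surface-fraction statistics."""

import numpy as np
import pytest
from oracles import brute_force_defect_grid, flood_fill_component_sizes, random_snapshot

from fuse_kinetics.defects import (
    DEEP,
    POLAR,
    SHALLOW,
    UNCOVERED,
    BilayerSnapshot,
    assign_leaflets,
    defect_series_vs_composition,
    defect_surface_fraction,
    find_defects,
    rasterize_leaflet,
    toy_classifier,
)
from fuse_kinetics.errors import ClassificationError, DomainError
from fuse_kinetics.synthetic import ToyBilayerSpec, build_toy_bilayer


def two_leaflet_slab(n_side=16, z_head=15.0, z_tail=12.0):
    """A symmetric slab: n_side^2 lipids per leaflet, 2 beads per lipid."""
    xs = (np.arange(n_side) + 0.5) * 1.0
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()
    names, resnames, resids, xyz = [], [], [], []
    rid = 0
    for sign in (1.0, -1.0):
        for x, y in zip(gx, gy):
            rid += 1
            names += ["HD", "TL"]
            resnames += ["TOY", "TOY"]
            resids += [rid, rid]
            xyz += [[x, y, sign * z_head], [x, y, sign * z_tail]]
    return BilayerSnapshot(
        names=np.array(names, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids),
        xyz=np.array(xyz, dtype=float),
        box=np.array([float(n_side), float(n_side), 60.0]),
    )


class TestAssignLeaflets:
    def test_symmetric_slab_splits_evenly(self):
        snap = assign_leaflets(two_leaflet_slab(), toy_classifier())
        upper = np.unique(snap.resids[snap.leaflets == "upper"])
        lower = np.unique(snap.resids[snap.leaflets == "lower"])
        assert len(upper) == len(lower) == 256

    def test_mirroring_swaps_labels(self):
        snap = two_leaflet_slab()
        labeled = assign_leaflets(snap, toy_classifier())
        mirrored = BilayerSnapshot(
            names=snap.names,
            resnames=snap.resnames,
            resids=snap.resids,
            xyz=snap.xyz * np.array([1.0, 1.0, -1.0]),
            box=snap.box,
        )
        flipped = assign_leaflets(mirrored, toy_classifier())
        swap = {"upper": "lower", "lower": "upper"}
        assert all(
            flipped.leaflets[i] == swap[labeled.leaflets[i]]
            for i in range(snap.n_atoms)
        )

    def test_single_sided_snapshot_rejected(self):
        # keep only the upper half of a slab: every lipid's head reference
        # then sits above the midplane and no split is possible
        snap = two_leaflet_slab()
        keep = snap.xyz[:, 2] > 0
        one_sided = BilayerSnapshot(
            names=snap.names[keep],
            resnames=snap.resnames[keep],
            resids=snap.resids[keep],
            xyz=snap.xyz[keep],
            box=snap.box,
        )
        with pytest.raises(DomainError, match="degenerate"):
            assign_leaflets(one_sided, toy_classifier())

    def test_toy_bilayer_is_prelabeled_upper(self):
        snap = build_toy_bilayer(ToyBilayerSpec(box_x=10.0, box_y=10.0))
        assert set(snap.leaflets) == {"upper"}


class TestRasterize:
    def test_intact_polar_cap_has_no_defects(self):
        snap = build_toy_bilayer(ToyBilayerSpec(box_x=20.0, box_y=20.0))
        dmap = rasterize_leaflet(snap, "upper", toy_classifier(), 1.0)
        assert dmap.category_mask("all").sum() == 0
        assert dmap.category_mask("polar").all()

    def test_headless_slab_is_all_defect_over_covered(self):
        spec = ToyBilayerSpec(box_x=20.0, box_y=20.0, hole_rects=((0.0, 0.0, 20.0, 20.0),))
        snap = build_toy_bilayer(spec)
        dmap = rasterize_leaflet(snap, "upper", toy_classifier(), 1.0)
        covered = dmap.grid != UNCOVERED
        assert covered.any()
        assert np.all(dmap.category_mask("all")[covered])

    def test_constructed_hole_yields_exact_deep_cell_count(self):
        spec = ToyBilayerSpec(
            box_x=100.0, box_y=100.0, hole_rects=((10.0, 10.0, 15.0, 15.0),)
        )
        snap = build_toy_bilayer(spec)
        dmap = rasterize_leaflet(snap, "upper", toy_classifier(spec.bead_radius), 1.0)
        # tail tops sit 2.1 A below the head reference: all hole cells deep
        assert int((dmap.grid == DEEP).sum()) == 25
        assert int((dmap.grid == SHALLOW).sum()) == 0

    def test_unclassifiable_atom_is_reported(self):
        snap = build_toy_bilayer(ToyBilayerSpec(box_x=10.0, box_y=10.0))
        snap.names[3] = "XX"
        with pytest.raises(ClassificationError, match="XX"):
            rasterize_leaflet(snap, "upper", toy_classifier(), 1.0)

    def test_category_fractions_partition_the_grid(self, rng):
        snap, classifier = random_snapshot(rng)
        dmap = rasterize_leaflet(snap, "upper", classifier, 1.0)
        total = dmap.grid.size
        parts = sum(
            int((dmap.grid == cat).sum()) for cat in (UNCOVERED, POLAR, SHALLOW, DEEP)
        )
        assert parts == total

    @pytest.mark.parametrize("leaflet", ["upper", "lower"])
    def test_matches_brute_force_oracle(self, rng, leaflet):
        for _ in range(8):
            snap, classifier = random_snapshot(rng, max_atoms=120, box_max=30.0, leaflet=leaflet)
            dmap = rasterize_leaflet(snap, leaflet, classifier, 1.0)
            oracle_grid, oracle_ref = brute_force_defect_grid(snap, leaflet, classifier, 1.0)
            assert dmap.ref_z == oracle_ref
            assert np.array_equal(dmap.grid, oracle_grid)

    def test_quarter_turn_preserves_fractions_and_components(self, rng):
        # dyadic coordinates keep the rotated geometry exact in binary floats
        n = 40
        box = 32.0
        xyz = np.column_stack(
            [
                rng.integers(0, 256, n) / 8.0,
                rng.integers(0, 256, n) / 8.0,
                10.0 + rng.integers(0, 32, n) / 8.0,
            ]
        )
        names = np.array([f"A{i:03d}" for i in range(n)], dtype=object)
        names[0] = "REF"
        classes = {str(nm): ("polar" if i % 3 else "hydrophobic") for i, nm in enumerate(names)}
        classes["REF"] = "polar"
        radii = {str(nm): float(r) for nm, r in zip(names, rng.integers(6, 20, n) / 8.0)}
        from fuse_kinetics.defects import AtomClassifier

        classifier = AtomClassifier({"RND": classes}, {"RND": "REF"}, radii)

        def snap_from(coords):
            return BilayerSnapshot(
                names=names,
                resnames=np.full(n, "RND", dtype=object),
                resids=np.arange(1, n + 1),
                xyz=coords,
                box=np.array([box, box, 60.0]),
                leaflets=np.full(n, "upper", dtype=object),
            )

        rotated = np.column_stack([xyz[:, 1], box - xyz[:, 0], xyz[:, 2]])
        a = rasterize_leaflet(snap_from(xyz), "upper", classifier, 1.0)
        b = rasterize_leaflet(snap_from(rotated), "upper", classifier, 1.0)
        for cat in ("polar", "shallow", "deep", "uncovered"):
            assert a.category_mask(cat).sum() == b.category_mask(cat).sum()
        sizes_a = sorted(c.n_cells for c in find_defects(a, "all"))
        sizes_b = sorted(c.n_cells for c in find_defects(b, "all"))
        assert sizes_a == sizes_b

    def test_cell_refinement_within_discretization_bound(self):
        spec = ToyBilayerSpec(
            box_x=100.0, box_y=100.0, hole_rects=((10.0, 10.0, 15.0, 15.0),)
        )
        snap = build_toy_bilayer(spec)
        classifier = toy_classifier(spec.bead_radius)
        fractions = {}
        for cell in (2.0, 0.5):
            dmap = rasterize_leaflet(snap, "upper", classifier, cell)
            fractions[cell] = dmap.category_mask("all").mean()
        perimeter = 4 * 5.0
        bound = 2 * perimeter * 2.0 / (100.0 * 100.0)
        assert abs(fractions[2.0] - fractions[0.5]) <= bound

    def test_enlarging_a_hole_never_shrinks_the_defect_fraction(self):
        classifier = toy_classifier()
        previous = -1.0
        for size in (3.0, 5.0, 9.0):
            spec = ToyBilayerSpec(
                box_x=40.0, box_y=40.0, hole_rects=((10.0, 10.0, 10.0 + size, 10.0 + size),)
            )
            snap = build_toy_bilayer(spec)
            dmap = rasterize_leaflet(snap, "upper", classifier, 1.0)
            fraction = dmap.category_mask("all").mean()
            assert fraction >= previous
            previous = fraction


class TestComponents:
    def make_map(self, holes, box=50.0):
        spec = ToyBilayerSpec(box_x=box, box_y=box, hole_rects=tuple(holes))
        snap = build_toy_bilayer(spec)
        return rasterize_leaflet(snap, "upper", toy_classifier(), 1.0)

    def test_two_disjoint_holes_two_components(self):
        dmap = self.make_map([(10.0, 10.0, 12.0, 12.0), (30.0, 30.0, 32.0, 32.0)])
        comps = find_defects(dmap, "all")
        assert [c.n_cells for c in comps] == [4, 4]
        assert comps[0].area == pytest.approx(4.0)

    def test_hole_across_periodic_boundary_is_one_component(self):
        dmap = self.make_map([(0.0, 10.0, 3.0, 12.0), (47.0, 10.0, 50.0, 12.0)])
        periodic = find_defects(dmap, "all", periodic=True)
        assert len(periodic) == 1
        assert periodic[0].n_cells == 12
        broken = find_defects(dmap, "all", periodic=False)
        assert sorted(c.n_cells for c in broken) == [6, 6]
        # independent check: rolling the torus moves the seam away, after
        # which plain (non-periodic) labeling must see the same single patch
        rolled = dmap.grid.take(range(-10, 40), axis=0, mode="wrap")
        from scipy import ndimage

        _, n_rolled = ndimage.label((rolled == DEEP) | (rolled == SHALLOW))
        assert n_rolled == 1

    def test_empty_category_empty_list(self):
        dmap = self.make_map([])
        assert find_defects(dmap, "all") == []

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_component_sizes_match_flood_fill_oracle(self, rng, connectivity):
        for _ in range(10):
            mask = rng.random((rng.integers(8, 30), rng.integers(8, 30))) < 0.35
            sizes_oracle = flood_fill_component_sizes(mask, connectivity, periodic=True)
            from fuse_kinetics.defects import DefectMap

            dmap = DefectMap(
                grid=np.where(mask, DEEP, POLAR).astype(np.int8),
                cell_size=1.0,
                leaflet="upper",
                ref_z=0.0,
                box_xy=(float(mask.shape[0]), float(mask.shape[1])),
            )
            sizes = sorted(
                (c.n_cells for c in find_defects(dmap, "deep", connectivity)),
                reverse=True,
            )
            assert sizes == sizes_oracle


class TestStats:
    def test_counting_fraction(self):
        spec = ToyBilayerSpec(
            box_x=100.0, box_y=100.0, hole_rects=((10.0, 10.0, 15.0, 15.0),)
        )
        snap = build_toy_bilayer(spec)
        dmap = rasterize_leaflet(snap, "upper", toy_classifier(), 1.0)
        stats = defect_surface_fraction([dmap], category="all")
        assert stats.fraction == pytest.approx(0.0025, abs=1e-12)
        assert stats.sem is None

    def test_duplicate_frames_zero_sem(self):
        spec = ToyBilayerSpec(box_x=30.0, box_y=30.0, hole_rects=((5.0, 5.0, 8.0, 8.0),))
        snap = build_toy_bilayer(spec)
        dmap = rasterize_leaflet(snap, "upper", toy_classifier(), 1.0)
        stats = defect_surface_fraction([dmap, dmap], category="all")
        assert stats.sem == pytest.approx(0.0, abs=1e-15)
        assert stats.n_frames == 2

    def test_all_category_is_union_of_deep_and_shallow(self, rng):
        snap, classifier = random_snapshot(rng, max_atoms=150, box_max=30.0)
        dmap = rasterize_leaflet(snap, "upper", classifier, 1.0)
        n_deep = int(dmap.category_mask("deep").sum())
        n_shallow = int(dmap.category_mask("shallow").sum())
        n_all = int(dmap.category_mask("all").sum())
        assert n_all == n_deep + n_shallow
        assert n_all >= max(n_deep, n_shallow)

    def test_covered_denominator_excludes_water_gaps(self):
        spec = ToyBilayerSpec(
            box_x=30.0,
            box_y=30.0,
            hole_rects=((5.0, 5.0, 8.0, 8.0), (15.0, 15.0, 20.0, 20.0)),
        )
        snap = build_toy_bilayer(spec)
        # strip the tail beads under the second hole too: that region has no
        # lipid coverage at all and must rasterize as uncovered water gap
        in_gap = (
            (snap.names == "TL")
            & (snap.xyz[:, 0] >= 15.0)
            & (snap.xyz[:, 0] < 20.0)
            & (snap.xyz[:, 1] >= 15.0)
            & (snap.xyz[:, 1] < 20.0)
        )
        keep = ~in_gap
        trimmed = BilayerSnapshot(
            names=snap.names[keep],
            resnames=snap.resnames[keep],
            resids=snap.resids[keep],
            xyz=snap.xyz[keep],
            box=snap.box,
            leaflets=snap.leaflets[keep],
        )
        dmap = rasterize_leaflet(trimmed, "upper", toy_classifier(), 1.0)
        assert dmap.category_mask("uncovered").sum() > 0
        box_stats = defect_surface_fraction([dmap], "all", denominator="box")
        covered_stats = defect_surface_fraction([dmap], "all", denominator="covered")
        assert covered_stats.fraction > box_stats.fraction

    def test_mismatched_grids_rejected(self):
        a = rasterize_leaflet(
            build_toy_bilayer(ToyBilayerSpec(box_x=20.0, box_y=20.0)),
            "upper",
            toy_classifier(),
            1.0,
        )
        b = rasterize_leaflet(
            build_toy_bilayer(ToyBilayerSpec(box_x=30.0, box_y=30.0)),
            "upper",
            toy_classifier(),
            1.0,
        )
        with pytest.raises(DomainError, match="mismatched"):
            defect_surface_fraction([a, b])


class TestCompositionSeries:
    def test_growing_holes_give_increasing_fractions(self):
        classifier = toy_classifier()
        groups = {}
        for label, size in [("none", 0.0), ("small", 4.0), ("large", 8.0)]:
            holes = () if size == 0 else ((10.0, 10.0, 10.0 + size, 10.0 + size),)
            snap = build_toy_bilayer(ToyBilayerSpec(box_x=40.0, box_y=40.0, hole_rects=holes))
            groups[label] = [rasterize_leaflet(snap, "upper", classifier, 1.0)]
        table = defect_series_vs_composition(groups)
        fractions = table.set_index("label")["fraction"]
        assert fractions["none"] < fractions["small"] < fractions["large"]

    def test_identical_groups_equal_fractions(self):
        snap = build_toy_bilayer(
            ToyBilayerSpec(box_x=30.0, box_y=30.0, hole_rects=((5.0, 5.0, 9.0, 9.0),))
        )
        dmap = rasterize_leaflet(snap, "upper", toy_classifier(), 1.0)
        table = defect_series_vs_composition({"a": [dmap], "b": [dmap]})
        assert table["fraction"].nunique() == 1

    def test_single_group_rejected(self):
        snap = build_toy_bilayer(ToyBilayerSpec(box_x=20.0, box_y=20.0))
        dmap = rasterize_leaflet(snap, "upper", toy_classifier(), 1.0)
        with pytest.raises(DomainError):
            defect_series_vs_composition({"only": [dmap]})
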