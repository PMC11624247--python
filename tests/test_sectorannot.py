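"""Sector annotation: boundary decomposition, purity, purity correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psicic import sectorannot as sa
from psicic.masks import BACKGROUND, RED, WHITE
from tests.conftest import make_colony_mask


class TestSplitBoundaryInterior:
    def test_disk_boundary_is_thin_closed_ring(self, colony_mask):
        m = colony_mask(71, 30, [])
        skel, interior = sa.split_boundary_interior(m)
        colony = m != BACKGROUND
        # partition: every colony pixel is boundary-skeleton or interior
        assert int(skel.sum() + interior.sum()) == int(colony.sum())
        assert not (skel & interior).any()
        # ring is unit width: every skeleton pixel has exactly 2 skeleton neighbors
        counts = sa._neighbor_counts(skel)[skel]
        assert (counts == 2).all()

    def test_single_pixel_colony(self):
        m = np.zeros((9, 9), np.uint8)
        m[4, 4] = WHITE
        skel, interior = sa.split_boundary_interior(m)
        assert skel[4, 4] and skel.sum() == 1 and not interior.any()

    def test_labels_preserved_on_ring(self, colony_mask):
        m = colony_mask(71, 30, [(0, 180)])
        skel, _ = sa.split_boundary_interior(m)
        ring_colors = set(np.unique(m[skel]))
        assert ring_colors == {RED, WHITE}

    def test_empty_mask_is_unquantifiable(self):
        with pytest.raises(sa.Unquantifiable, match="empty"):
            sa.split_boundary_interior(np.zeros((32, 32), np.uint8))


class TestBoundaryComponents:
    def test_all_white_ring_single_closed_component(self, colony_mask):
        m = colony_mask(71, 30, [])
        skel, _ = sa.split_boundary_interior(m)
        comps = sa.boundary_components(skel, m)
        assert len(comps) == 1
        assert comps[0].color == WHITE
        assert comps[0].endpoints == []

    def test_one_red_arc_gives_one_component_per_color(self, colony_mask):
        m = colony_mask(71, 30, [(30, 120)])
        skel, _ = sa.split_boundary_interior(m)
        comps = sa.boundary_components(skel, m)
        assert sorted(c.color for c in comps) == [RED, WHITE]
        for c in comps:
            assert len(c.endpoints) == 2

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_k_alternating_arcs(self, colony_mask, k):
        sectors = [(i * 360 / k, i * 360 / k + 360 / (2 * k)) for i in range(k)]
        m = make_colony_mask(101, 42, sectors)
        skel, _ = sa.split_boundary_interior(m)
        comps = sa.boundary_components(skel, m)
        assert sum(c.color == RED for c in comps) == k
        assert sum(c.color == WHITE for c in comps) == k


class TestFindEndpoints:
    def test_horizontal_segment_ends(self):
        m = np.zeros((7, 9), np.uint8)
        m[3, 2:7] = WHITE
        comp = sa.BoundaryComponent(WHITE, np.argwhere(m == WHITE), m.shape)
        assert sorted(sa.find_endpoints(comp)) == [(3, 2), (3, 6)]

    def test_closed_ring_has_no_endpoints(self, colony_mask):
        m = colony_mask(41, 17, [])
        skel, _ = sa.split_boundary_interior(m)
        comp = sa.BoundaryComponent(WHITE, np.argwhere(skel), skel.shape)
        assert sa.find_endpoints(comp) == []

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_union_superset_of_bruteforce_on_random_arcs(self, seed):
        """The endpoint union contains every degree-1 pixel of a random arc."""
        rng = np.random.default_rng(seed)
        shape = (24, 24)
        m = np.zeros(shape, bool)
        r, c = 12, 12
        m[r, c] = True
        pixels = [(r, c)]
        for _ in range(rng.integers(3, 30)):
            dr, dc = rng.integers(-1, 2), rng.integers(-1, 2)
            r2, c2 = min(max(r + dr, 1), 22), min(max(c + dc, 1), 22)
            m[r2, c2] = True
            pixels.append((r2, c2))
            r, c = r2, c2
        # analyze the component containing the walk's start
        from scipy import ndimage as ndi

        labels, _ = ndi.label(m, structure=np.ones((3, 3)))
        comp_mask = labels == labels[12, 12]
        comp = sa.BoundaryComponent(WHITE, np.argwhere(comp_mask), shape)
        brute = set(
            map(tuple, np.argwhere(comp_mask & (sa._neighbor_counts(comp_mask) == 1)))
        )
        try:
            union = set(sa.find_endpoints(comp))
        except sa.Unquantifiable:
            assert len(brute) > 2  # only branched arcs may be rejected
            return
        assert brute <= union


class TestBuildRegions:
    def test_all_white_disk_single_pure_region(self, colony_mask):
        ann = sa.annotate_colony(colony_mask(71, 30, []), correct=False)
        assert ann.ok and (ann.a, ann.b) == (0, 1)
        assert ann.regions[0].purity == 1.0
        assert ann.weighted_purity == 1.0

    def test_half_and_half_disk(self, colony_mask):
        ann = sa.annotate_colony(colony_mask(101, 40, [(0, 180)]), correct=False)
        assert ann.ok and (ann.a, ann.b) == (1, 1)
        for r in ann.regions:
            assert r.purity >= 0.95
        assert ann.weighted_purity >= 0.95

    def test_four_alternating_quadrants_weights(self):
        m = make_colony_mask(121, 50, [(0, 90), (180, 270)])
        ann = sa.annotate_colony(m, correct=False)
        assert ann.ok and (ann.a, ann.b) == (2, 2)
        for r in ann.regions:
            assert r.weight == pytest.approx(0.25, abs=0.03)

    def test_partition_and_weight_normalization(self, colony_mask):
        m = colony_mask(101, 40, [(10, 80), (200, 290)])
        ann = sa.annotate_colony(m, correct=False)
        colony_pixels = int((m != BACKGROUND).sum())
        assert sum(r.size for r in ann.regions) == colony_pixels
        assert sum(r.weight for r in ann.regions) == pytest.approx(1.0, abs=1e-12)
        assert ann.N_R + ann.N_W == colony_pixels

    def test_alternation_invariant(self, colony_mask, rng):
        for _ in range(10):
            k = int(rng.integers(1, 4))
            starts = np.sort(rng.uniform(0, 360, k))
            widths = rng.uniform(15, min(60, 300 / k), k)
            sectors = []
            ok = True
            for i in range(k):
                end = starts[i] + widths[i]
                nxt = starts[(i + 1) % k] + (360 if i == k - 1 else 0)
                if end >= nxt - 10:
                    ok = False
            if not ok:
                continue
            m = make_colony_mask(101, 40, [(s, s + w) for s, w in zip(starts, widths)])
            ann = sa.annotate_colony(m, correct=False)
            if ann.ok and ann.a >= 1 and ann.b >= 1:
                assert ann.a == ann.b


class TestPurity:
    def test_direct_ratio(self):
        comp = sa.BoundaryComponent(RED, np.zeros((1, 2), int), (1, 1))
        r = sa.Region(RED, comp, 80, 20, 0.0, 1.0, (0.0, 360.0))
        assert sa.purity(r) == pytest.approx(0.8)

    def test_all_red_region_is_pure(self):
        comp = sa.BoundaryComponent(RED, np.zeros((1, 2), int), (1, 1))
        r = sa.Region(RED, comp, 50, 0, 0.0, 1.0, (0.0, 360.0))
        assert sa.purity(r) == 1.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            sa.purity_from_counts(RED, 0, 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_weighted_equals_pooled_purity(self, seed):
        """The size-weighted average of region purities equals the pooled
        matching-pixel fraction, to floating-point accuracy."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 8))
        comp = sa.BoundaryComponent(RED, np.zeros((1, 2), int), (1, 1))
        regions = []
        total = 0
        for _ in range(k):
            color = RED if rng.random() < 0.5 else WHITE
            n_red, n_white = int(rng.integers(0, 500)), int(rng.integers(0, 500))
            if n_red + n_white == 0:
                n_red = 1
            regions.append(sa.Region(color, comp, n_red, n_white, 0.0, 0.0, (0.0, 1.0)))
            total += n_red + n_white
        for r in regions:
            r.weight = r.size / total
            r.purity = sa.purity(r)
        assert sa.weighted_purity(regions) == pytest.approx(sa.pooled_purity(regions), abs=1e-12)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_mediant_inequality_on_random_counts(self, seed):
        """Pooled purity of merged regions lies within [min, max] of members."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 10))
        reds = rng.integers(0, 1000, k)
        whites = rng.integers(0, 1000, k)
        totals = reds + whites
        keep = totals > 0
        if not keep.any():
            return
        reds, totals = reds[keep], totals[keep]
        purities = reds / totals
        pooled = reds.sum() / totals.sum()
        assert purities.min() - 1e-12 <= pooled <= purities.max() + 1e-12


class TestPurityCorrect:
    def _impure_mask(self):
        """White disk whose outer boundary carries a red arc with no red
        interior behind it: that region's purity is far below 0.5."""
        m = make_colony_mask(101, 40, [])
        yy, xx = np.mgrid[0:101, 0:101].astype(float)
        c = 50.0
        d = np.hypot(yy - c, xx - c)
        ang = np.degrees(np.arctan2(yy - c, xx - c)) % 360
        m[(d <= 40) & (d > 38) & (ang < 40)] = RED
        return m

    def test_fixed_point_returned_unchanged(self, colony_mask):
        ann = sa.annotate_colony(colony_mask(101, 40, [(0, 90)]), correct=False)
        assert all(r.purity >= 0.5 for r in ann.regions)
        center = (50.0, 50.0)
        ann2 = sa.purity_correct(ann, colony_mask(101, 40, [(0, 90)]), center)
        assert ann2 is ann

    def test_impure_arc_flipped_and_merged(self):
        m = self._impure_mask()
        un = sa.annotate_colony(m, correct=False)
        assert un.a == 1 and un.b == 1
        assert min(r.purity for r in un.regions) < 0.5
        ann = sa.annotate_colony(m, correct=True)
        assert ann.ok
        assert len(ann.regions) < len(un.regions)
        assert (ann.a, ann.b) == (0, 1)  # corrected to a homogeneous white colony
        assert ann.correction_iterations >= 1
        assert all(r.purity >= 0.5 for r in ann.regions)

    def test_idempotence(self):
        m = self._impure_mask()
        ann = sa.annotate_colony(m, correct=True)
        again = sa.purity_correct(ann, m, (50.0, 50.0))
        assert again is ann

    def test_postcondition_on_random_noisy_colonies(self, rng):
        """After correction every region of a quantifiable colony has p >= 0.5."""
        for _ in range(25):
            sectors = []
            if rng.random() < 0.7:
                start = float(rng.uniform(0, 360))
                sectors.append((start, start + float(rng.uniform(20, 120))))
            m = make_colony_mask(81, 32, sectors)
            # pixel-level label noise inside the colony
            noise = (rng.random(m.shape) < 0.06) & (m != BACKGROUND)
            m[noise & (m == WHITE)] = RED
            m[noise & (m == RED)] = WHITE
            ann = sa.annotate_colony(m, correct=True)
            if ann.ok:
                assert all(r.purity >= 0.5 for r in ann.regions)
                assert sum(r.weight for r in ann.regions) == pytest.approx(1.0, abs=1e-9)

    def test_merged_purity_within_mediant_bounds(self):
        # three red regions with p >= 0.5 pooled: bound check via counts
        reds = np.array([60, 80, 55])
        whites = np.array([40, 20, 45])
        purities = reds / (reds + whites)
        pooled = reds.sum() / (reds.sum() + whites.sum())
        assert purities.min() <= pooled <= purities.max()
        assert pooled >= 0.5


class TestFidelity:
    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_exact_region_counts_on_ideal_colonies(self, k):
        """Noise-free k-sector colonies annotate to exactly k red regions."""
        if k == 0:
            sectors = []
        else:
            sectors = [(i * 360 / k + 10, i * 360 / k + 10 + max(30, 360 / (2 * k))) for i in range(k)]
            sectors = [(s, min(e, s + 120)) for s, e in sectors]
        m = make_colony_mask(121, 50, sectors)
        ann = sa.annotate_colony(m)
        assert ann.ok
        assert ann.a == k
        assert ann.b == (1 if k == 0 else k)


class TestSelectCentralColony:
    def test_neighbor_fragment_discarded(self, colony_mask):
        m = colony_mask(71, 25, [(0, 90)])
        m[0:8, 0:8] = WHITE  # clipped fragment of a neighboring colony
        ann = sa.annotate_colony(m)
        assert ann.ok and (ann.a, ann.b) == (1, 1)
        kept = sa.select_central_colony(m, (35.0, 35.0))
        assert (kept[0:8, 0:8] == BACKGROUND).all()
        assert kept[35, 35] == m[35, 35]

    def test_single_component_untouched(self, colony_mask):
        m = colony_mask(71, 25, [])
        np.testing.assert_array_equal(sa.select_central_colony(m, (35.0, 35.0)), m)

    def test_background_center_falls_back_to_nearest(self):
        m = np.zeros((41, 41), np.uint8)
        m[5:15, 5:15] = WHITE  # off-center colony, center pixel is background
        m[35:40, 35:40] = RED  # farther fragment
        kept = sa.select_central_colony(m, (20.0, 20.0))
        assert (kept[5:15, 5:15] == WHITE).all()
        assert (kept[35:40, 35:40] == BACKGROUND).all()


def test_bresenham_line_endpoints_and_connectivity():
    line = sa.bresenham_line((2, 3), (10, 17))
    assert line[0] == (2, 3) and line[-1] == (10, 17)
    for (r0, c0), (r1, c1) in zip(line, line[1:]):
        assert max(abs(r1 - r0), abs(c1 - c0)) == 1


def test_render_annotation_shapes(colony_mask):
    m = colony_mask(71, 30, [(0, 90)])
    ann = sa.annotate_colony(m)
    overlay = sa.render_annotation(m, ann)
    assert overlay.shape == (71, 71, 3)
    assert overlay.any()


def test_sector_annotator_estimator(colony_mask):
    masks = [colony_mask(71, 30, []), colony_mask(71, 30, [(0, 90)])]
    annot = sa.SectorAnnotator()
    anns = annot.fit_transform(masks)
    assert [a.ok for a in anns] == [True, True]
    assert annot.predict(masks) == ["PSI+", "S1"]
    assert "correct" in annot.get_params()
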