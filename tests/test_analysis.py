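"""Information measure, selectivity counting, segmentation, tuning heatmaps.

Each numerical read-out is checked against an independent brute-force
oracle on small random tables.
"""

import math

import numpy as np
import pandas as pd
import pytest

from boundarynet import analysis, stimuli
from boundarynet.analysis import (BoundarySegment, TuningHeatmap,
                                  count_heatmap_peaks, count_selective_cells,
                                  make_response_table, segment_boundary,
                                  single_cell_information, tuning_heatmap,
                                  v4_model_correlation)


def table_from_matrix(mat, objects):
    """cells x objects rate matrix -> response table (single transform)."""
    records = []
    for ci in range(mat.shape[0]):
        for oi, obj in enumerate(objects):
            records.append((ci, 3, obj, 0, 0, 0.0, float(mat[ci, oi])))
    return make_response_table(records)


# ---------------------------------------------------------------------------
# information

def oracle_information(rates, masks, n_bins):
    """Brute-force probability-table computation of I(s, R) per category."""
    out = []
    bins = np.minimum((np.clip(rates, 0, 1) * n_bins).astype(int), n_bins - 1)
    for mask in masks:
        info = 0.0
        for r in range(n_bins):
            p_r = np.mean(bins == r)
            p_r_s = np.mean(bins[mask] == r)
            if p_r_s > 0:
                info += p_r_s * math.log2(p_r_s / p_r)
        out.append(info)
    return np.array(out)


class TestSingleCellInformation:
    def test_perfect_selective_cell_scores_log2_p(self):
        # p = 2 design: 8 objects, the cell fires 1 iff the object's first
        # side is concave -> exactly log2(2) = 1 bit
        fam = stimuli.ShapeFamilySpec(3, 2)
        shapes = stimuli.enumerate_shapes(fam)
        membership = {s.object_id: frozenset(s.element_labels()) for s in shapes}
        target = (fam.side_names[0], "concave")
        rates = np.array([[1.0 if target in membership[s.object_id] else 0.0
                           for s in shapes]])
        table = table_from_matrix(rates, [s.object_id for s in shapes])
        info = single_cell_information(table, lambda o: membership[o])
        assert info.max_info[0] == pytest.approx(1.0, abs=1e-12)

    def test_constant_cell_carries_zero_bits(self, shapes32):
        membership = {s.object_id: frozenset(s.element_labels())
                      for s in shapes32}
        rates = np.full((1, 8), 0.4)
        table = table_from_matrix(rates, [s.object_id for s in shapes32])
        info = single_cell_information(table, lambda o: membership[o])
        assert np.allclose(info.per_category, 0.0, atol=1e-12)

    def test_matches_bruteforce_oracle_on_random_tables(self, rng):
        objects = [f"o{i}" for i in range(8)]
        cats = {f"o{i}": [f"c{i % 2}", f"d{i % 4}"] for i in range(8)}
        rates = rng.random((5, 8))
        table = table_from_matrix(rates, objects)
        res = single_cell_information(table, lambda o: cats[o], n_bins=10)
        # oracle per cell and category
        for ci in range(5):
            masks = []
            for cat in res.categories:
                masks.append(np.array([cat in cats[o] for o in objects]))
            expected = oracle_information(rates[ci], masks, 10)
            assert np.allclose(res.per_category[ci], expected, atol=1e-12)

    def test_info_bounded_by_log2_bins(self, rng):
        objects = [f"o{i}" for i in range(16)]
        cats = {o: [f"c{i % 4}"] for i, o in enumerate(objects)}
        rates = rng.random((20, 16))
        table = table_from_matrix(rates, objects)
        res = single_cell_information(table, lambda o: cats[o], n_bins=8)
        assert (res.per_category >= 0).all()
        assert (res.per_category <= 3.0 + 1e-12).all()


# ---------------------------------------------------------------------------
# selectivity

def oracle_selectivity(rates, memberships, elements, hi, lo):
    counts = {e: 0 for e in elements}
    n_cells, n_obj = rates.shape
    for ci in range(n_cells):
        for e in elements:
            ok = True
            for oi in range(n_obj):
                if e in memberships[oi]:
                    if rates[ci, oi] < hi:
                        ok = False
                        break
                else:
                    if rates[ci, oi] >= lo:
                        ok = False
                        break
            if ok:
                counts[e] += 1
    return counts


class TestSelectivityCounting:
    def test_single_perfect_cell(self, shapes32):
        membership = {s.object_id: frozenset(s.element_labels())
                      for s in shapes32}
        target = ("top", "concave")
        rates = np.array([[1.0 if target in membership[s.object_id] else 0.0
                           for s in shapes32]])
        table = table_from_matrix(rates, [s.object_id for s in shapes32])
        counts = count_selective_cells(table, lambda o: membership[o])
        assert counts[target] == 1
        assert sum(counts.values()) == 1

    def test_rate_just_below_window_not_counted(self, shapes32):
        membership = {s.object_id: frozenset(s.element_labels())
                      for s in shapes32}
        target = ("top", "concave")
        rates = np.array([[1.0 if target in membership[s.object_id] else 0.0
                           for s in shapes32]])
        rates[0, next(i for i, s in enumerate(shapes32)
                      if target in membership[s.object_id])] = 0.9991
        table = table_from_matrix(rates, [s.object_id for s in shapes32])
        counts = count_selective_cells(table, lambda o: membership[o])
        assert sum(counts.values()) == 0

    def test_agrees_with_bruteforce_oracle(self, rng):
        objects = [f"o{i}" for i in range(6)]
        memberships = [frozenset(rng.choice(["a", "b", "c"],
                                            size=rng.integers(1, 3),
                                            replace=False))
                       for _ in objects]
        lookup = dict(zip(objects, memberships))
        # rates concentrated at the extremes so the strict window is exercised
        rates = rng.choice([0.0, 0.99996, 1.0, 0.5, 0.00004], size=(30, 6))
        table = table_from_matrix(rates, objects)
        got = count_selective_cells(table, lambda o: lookup[o],
                                    elements=["a", "b", "c"])
        want = oracle_selectivity(rates, memberships, ["a", "b", "c"],
                                  analysis.SELECTIVE_HI, analysis.SELECTIVE_LO)
        assert got == want


# ---------------------------------------------------------------------------
# backtracing

class TestBacktrace:
    def test_single_path_product(self):
        from boundarynet.gabor import build_bank
        from boundarynet.netcore import LayerConfig, LateralFilterSpec, \
            Network, SigmoidSpec, SynapticMap
        bank = build_bank(4)  # 4x4 retina, 8 kernels
        cfg = LayerConfig((1, 1), 1, 1.0, LateralFilterSpec(),
                          SigmoidSpec(50, 1))
        m1 = SynapticMap((4, 4, 8), np.array([[5]]), np.array([[0.5]]),
                         np.zeros((1, 1, 2), dtype=np.int32), 1.0)
        m2 = SynapticMap((1, 1), np.array([[0]]), np.array([[0.4]]),
                         np.zeros((1, 1, 2), dtype=np.int32), 1.0)
        net = Network(bank, [cfg, cfg], [m1, m2], seed=0)
        eff = analysis.backtrace_receptive_field(net, 0)
        assert eff.ravel()[5] == pytest.approx(0.2)
        assert eff.sum() == pytest.approx(0.2)

    def test_nonnegative_and_cell_range(self):
        from boundarynet.netcore import build_network
        net = build_network("test_small", n_layers=2, seed=0)
        eff = analysis.backtrace_receptive_field(net, 100)
        assert (eff >= 0).all()
        with pytest.raises(ValueError, match="out of range"):
            analysis.backtrace_receptive_field(net, 10**6)


# ---------------------------------------------------------------------------
# segmentation

class TestSegmentation:
    def test_circle_is_single_constant_curvature_segment(self):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        contour = 10.0 * np.stack([np.cos(t), np.sin(t)], axis=1)
        segs = segment_boundary(contour)
        assert len(segs) == 1
        assert segs[0].curvature == pytest.approx(1 / 10.0, rel=0.05)

    def test_square_splits_into_four_sides(self):
        fam = stimuli.ShapeFamilySpec(4, 3)
        square = stimuli.ShapeSpec(fam, ("straight",) * 4)
        contour = stimuli.contour_points(square, radius=20.0)
        segs = segment_boundary(contour)
        assert len(segs) == 4
        angles = sorted(s.angle_deg for s in segs)
        gaps = np.diff(angles + [angles[0] + 360.0])
        assert np.allclose(gaps, 90.0, atol=10.0)
        assert all(abs(s.curvature) < 0.02 for s in segs)

    def test_rotation_equivariance_of_segment_angles(self):
        fam = stimuli.ShapeFamilySpec(4, 3)
        spec = stimuli.ShapeSpec(fam, ("convex", "straight", "straight",
                                       "straight"))
        c0 = stimuli.contour_points(spec, radius=20.0)
        th = np.pi / 2
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c90 = c0 @ rot.T
        a0 = sorted(s.angle_deg for s in segment_boundary(c0))
        a90 = sorted((s.angle_deg - 90.0) % 360.0
                     for s in segment_boundary(c90))
        assert np.allclose(np.sort(a0), np.sort(a90), atol=3.0)

    def test_open_contour_rejected(self):
        t = np.linspace(0, np.pi, 100)  # half circle
        arc = np.stack([np.cos(t), np.sin(t)], axis=1) * 10
        with pytest.raises(ValueError, match="open"):
            segment_boundary(arc)

    def test_convex_side_has_positive_curvature(self):
        fam = stimuli.ShapeFamilySpec(4, 3)
        spec = stimuli.ShapeSpec(fam, ("convex", "concave", "straight",
                                       "straight"))
        segs = segment_boundary(stimuli.contour_points(spec, radius=20.0))
        by_angle = {min(segs, key=lambda s: abs((s.angle_deg - a) % 360))
                    for a in ()}
        top = min(segs, key=lambda s: abs(((s.angle_deg - 90) + 180) % 360 - 180))
        left = min(segs, key=lambda s: abs(((s.angle_deg - 180) + 180) % 360 - 180))
        assert top.curvature > 0.005      # convex on top
        assert left.curvature < -0.005    # concave on left


# ---------------------------------------------------------------------------
# tuning heatmaps and peaks

def grid_heatmap(values):
    arr = np.asarray(values, dtype=float)
    counts = np.where(np.isnan(arr), 0, 1).astype(int)
    return TuningHeatmap(arr, counts,
                         np.linspace(-1, 1, arr.shape[0] + 1),
                         np.linspace(0, 360, arr.shape[1] + 1))


class TestTuningHeatmap:
    def test_single_hot_bin(self):
        segs_hot = [BoundarySegment(0.5, 70.0, 5.0)]
        segs_cold = [BoundarySegment(-0.5, 200.0, 5.0)]
        hm = tuning_heatmap([(1.0, segs_hot), (0.0, segs_cold)],
                            angle_bins=18, curvature_bins=4)
        hot = np.nanmax(hm.mean)
        assert hot == 1.0
        assert hm.counts.sum() == 2
        assert np.isnan(hm.mean[hm.counts == 0]).all()

    def test_permutation_invariant_and_matches_oracle(self, rng):
        pres = []
        for _ in range(50):
            segs = [BoundarySegment(float(rng.uniform(-1, 1)),
                                    float(rng.uniform(0, 360)), 1.0)
                    for _ in range(3)]
            pres.append((float(rng.random()), segs))
        hm1 = tuning_heatmap(pres, curvature_range=(-1, 1))
        order = rng.permutation(len(pres))
        hm2 = tuning_heatmap([pres[i] for i in order], curvature_range=(-1, 1))
        assert np.array_equal(hm1.counts, hm2.counts)
        assert np.allclose(np.nan_to_num(hm1.mean), np.nan_to_num(hm2.mean))
        # brute-force accumulation oracle
        total = np.zeros_like(hm1.mean)
        count = np.zeros_like(hm1.counts)
        for rate, segs in pres:
            for s in segs:
                ci = min(int((s.curvature + 1) / 2 * 8), 7)
                ai = min(int(s.angle_deg / 360 * 16), 15)
                total[ci, ai] += rate
                count[ci, ai] += 1
        with np.errstate(invalid="ignore"):
            mean = total / count
        assert np.allclose(np.nan_to_num(hm1.mean), np.nan_to_num(mean))


class TestPeakCounting:
    def test_single_bump(self):
        y, x = np.mgrid[0:8, 0:16]
        bump = np.exp(-((y - 4) ** 2 + (x - 8) ** 2) / 4.0)
        assert count_heatmap_peaks(grid_heatmap(bump)) == 1

    def test_two_separated_equal_bumps(self):
        y, x = np.mgrid[0:8, 0:16]
        b1 = np.exp(-((y - 4) ** 2 + (x - 3) ** 2) / 1.5)
        b2 = np.exp(-((y - 4) ** 2 + (x - 12) ** 2) / 1.5)
        assert count_heatmap_peaks(grid_heatmap(b1 + b2)) == 2

    def test_flat_map_has_no_peaks(self):
        assert count_heatmap_peaks(grid_heatmap(np.ones((8, 16)))) == 0

    def test_wraps_across_angle_axis(self):
        m = np.zeros((4, 12))
        m[2, 0] = 1.0
        m[2, 11] = 2.0  # higher neighbor across the wrap: only one peak
        assert count_heatmap_peaks(grid_heatmap(m)) == 1

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            m = rng.integers(0, 5, size=(6, 10)).astype(float)
            hm = grid_heatmap(m)
            got = count_heatmap_peaks(hm, fraction=0.6)
            # oracle: plateau flood fill by enumeration
            ref = 0.6 * m.mean()
            seen = np.zeros(m.shape, bool)
            want = 0
            for c in range(6):
                for a in range(10):
                    if seen[c, a]:
                        continue
                    val = m[c, a]
                    comp = [(c, a)]
                    seen[c, a] = True
                    qi = 0
                    peak = val > ref
                    lower = False
                    while qi < len(comp):
                        cc, aa = comp[qi]
                        qi += 1
                        for dc in (-1, 0, 1):
                            for da in (-1, 0, 1):
                                if dc == da == 0:
                                    continue
                                c2, a2 = cc + dc, (aa + da) % 10
                                if not 0 <= c2 < 6:
                                    continue
                                if m[c2, a2] == val and not seen[c2, a2]:
                                    seen[c2, a2] = True
                                    comp.append((c2, a2))
                                elif m[c2, a2] > val:
                                    peak = False
                                elif m[c2, a2] < val:
                                    lower = True
                    if peak and lower:
                        want += 1
            assert got == want


class TestV4ModelCorrelation:
    def test_identical_surface_gives_one(self):
        y, x = np.mgrid[0:8, 0:16]
        curv_c = np.linspace(-1, 1, 9)
        curv_c = 0.5 * (curv_c[:-1] + curv_c[1:])
        ang_c = np.linspace(0, 360, 17)
        ang_c = 0.5 * (ang_c[:-1] + ang_c[1:])
        model = np.exp(-0.5 * (((curv_c[:, None] - 0.5) / 0.1) ** 2
                               + (((ang_c[None, :] - 70 + 180) % 360 - 180)
                                  / 45.0) ** 2))
        hm = grid_heatmap(model)
        r = v4_model_correlation(hm, 0.5, 70.0, widths=(0.1, 45.0))
        assert r == pytest.approx(1.0)

    def test_affine_rescaling_invariance(self, rng):
        m = rng.random((8, 16))
        hm1 = grid_heatmap(m)
        hm2 = grid_heatmap(3.0 * m + 0.2)
        r1 = v4_model_correlation(hm1, 0.3, 100.0)
        r2 = v4_model_correlation(hm2, 0.3, 100.0)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_anticorrelated_surface(self):
        y, x = np.mgrid[0:8, 0:16]
        curv_c = np.linspace(-1, 1, 9)
        curv_c = 0.5 * (curv_c[:-1] + curv_c[1:])
        ang_c = np.linspace(0, 360, 17)
        ang_c = 0.5 * (ang_c[:-1] + ang_c[1:])
        model = np.exp(-0.5 * (((curv_c[:, None] - 0.5) / 0.1) ** 2
                               + (((ang_c[None, :] - 70 + 180) % 360 - 180)
                                  / 45.0) ** 2))
        hm = grid_heatmap(model.max() - model)
        assert v4_model_correlation(hm, 0.5, 70.0) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            v4_model_correlation(grid_heatmap(np.ones((4, 8))), 0.0, 0.0)


class TestFeatureMap:
    def test_clustered_block_scores_below_null(self):
        info = np.zeros((81, 1))
        block = [i * 9 + j for i in range(3) for j in range(3)]  # 3x3 corner
        info[block, 0] = 1.0
        res = analysis.feature_map(
            analysis.InfoResult(np.arange(81), ["e"], info, 10), (9, 9))
        assert res["e"]["score"] < res["e"]["null_mean"]
        assert not res["e"]["empty"]

    def test_zero_info_flagged_empty(self):
        info = np.zeros((16, 1))
        res = analysis.feature_map(
            analysis.InfoResult(np.arange(16), ["e"], info, 10), (4, 4))
        assert res["e"]["empty"]
        assert len(res["e"]["coords"]) == 0
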