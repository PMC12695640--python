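"""Compartment calling, scA/B scores, proximity frequencies, radial scores,
polarization index and hull volumes."""

import numpy as np
import pandas as pd
import pytest

import chromtrace as ct
from chromtrace import metrics as m
from chromtrace.metrics.geometry import convex_hull_intersection_volume
from chromtrace.simulate import reference_profile_from_truth
from conftest import make_cell


@pytest.fixture(scope="module")
def wt_compartments(wt_population, codebook):
    cells, truth = wt_population
    ds = m.distance_summary(cells, codebook)
    ref = reference_profile_from_truth(truth, seed=0)
    return cells, truth, ds, m.compartment_scores(ds, codebook, ref)


class TestCompartmentScores:
    def _checkerboard_summary(self):
        # 6 alternating regions; within-block normalized distance 0.8,
        # between-block 1.2.  Build a raw mean matrix whose power-law
        # normalization returns exactly that pattern by using distances
        # d = pattern * A * g**alpha with A=100, alpha=0.
        n = 6
        labels = np.array([i % 2 == 0 for i in range(n)])
        mids = np.arange(n) * 5.0
        ds = m.DistanceSummary(group="g", min_pairs=1)
        mean = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                pat = 0.8 if labels[i] == labels[j] else 1.2
                g = abs(mids[i] - mids[j])
                mean[i, j] = pat * 100.0 * g ** 0.1
        ds.mean[1] = mean
        ds.count[1] = np.full((n, n), 99)
        ds.cov[1] = np.full((n, n), np.nan)
        ds.region_indices[1] = np.arange(n)
        ds.midpoints_mb[1] = mids
        return ds, labels

    def _toy_codebook6(self):
        return ct.synthetic_codebook(n_regions=6, n_chroms=1)

    def test_checkerboard_pc1_splits_blocks(self):
        ds, labels = self._checkerboard_summary()
        cb = self._toy_codebook6()
        ref = ct.ReferenceProfile(values=np.where(labels, 1.0, -1.0))
        res = m.compartment_scores(ds, cb, ref)
        assert (res.is_a == labels).all()
        # independent eigendecomposition of the centered correlation matrix
        mids = ds.midpoints_mb[1]
        fit = m.fit_power_law(ds, 1)
        seps = np.abs(mids[:, None] - mids[None, :])
        with np.errstate(invalid="ignore"):
            normed = ds.mean[1] / fit.expected(seps)
        corr = pd.DataFrame(normed).corr().to_numpy()
        centered = corr - corr.mean(axis=0, keepdims=True)
        w, v = np.linalg.eigh(centered.T @ centered)
        pc1 = v[:, -1]
        signs = np.sign(pc1)
        assert (signs == signs[0])[labels].all()
        assert (signs == -signs[0])[~labels].all()

    def test_reference_sign_flip(self):
        ds, labels = self._checkerboard_summary()
        cb = self._toy_codebook6()
        ref = ct.ReferenceProfile(values=np.where(labels, 1.0, -1.0))
        flipped = ct.ReferenceProfile(values=-ref.values)
        a = m.compartment_scores(ds, cb, ref)
        b = m.compartment_scores(ds, cb, flipped)
        assert np.allclose(a.scores, -b.scores)

    def test_recovery_on_default_simulation(self, wt_compartments):
        _, truth, _, comp = wt_compartments
        ok = np.isfinite(comp.scores)
        agreement = (comp.is_a[ok] == truth.region_a[ok]).mean()
        assert agreement >= 0.95


class TestScAB:
    def test_single_neighbor_inherits_score(self, small_codebook):
        scores = np.zeros(len(small_codebook))
        scores[1] = 0.8
        scores[0] = -0.3
        comp = m.CompartmentResult(scores=scores)
        cell = make_cell("c", "s", {(1, 0): [(0, 0, 0, 0),
                                             (1, 500, 0, 0)]},
                         small_codebook)
        scab = m.scab_scores([cell], comp, radius=1200.0)
        assert scab.values.loc["c", 0] == pytest.approx(0.8)
        assert scab.values.loc["c", 1] == pytest.approx(-0.3)

    def test_symmetric_neighbors_cancel(self, small_codebook):
        scores = np.zeros(len(small_codebook))
        scores[1], scores[2] = 1.0, -1.0
        comp = m.CompartmentResult(scores=scores)
        cell = make_cell("c", "s", {(1, 0): [(0, 0, 0, 0), (1, 100, 0, 0),
                                             (2, 0, 100, 0)]},
                         small_codebook)
        scab = m.scab_scores([cell], comp, radius=1200.0)
        assert scab.values.loc["c", 0] == pytest.approx(0.0)

    def test_strict_radius_boundary(self, small_codebook):
        scores = np.full(len(small_codebook), 0.5)
        comp = m.CompartmentResult(scores=scores)
        at_boundary = make_cell("c", "s",
                                {(1, 0): [(0, 0, 0, 0), (1, 1200.0, 0, 0)]},
                                small_codebook)
        scab = m.scab_scores([at_boundary], comp, radius=1200.0)
        assert np.isnan(scab.values.loc["c", 0])   # exactly at radius: out
        inside = make_cell("c", "s",
                           {(1, 0): [(0, 0, 0, 0), (1, 1199.9, 0, 0)]},
                           small_codebook)
        scab = m.scab_scores([inside], comp, radius=1200.0)
        assert scab.values.loc["c", 0] == pytest.approx(0.5)

    def test_matches_brute_force(self, small_codebook):
        st = ct.StateParams(label="s", n_cells=12)
        cells, truth = ct.simulate_population([st], small_codebook, seed=61)
        rng = np.random.default_rng(3)
        scores = rng.normal(size=len(small_codebook))
        comp = m.CompartmentResult(scores=scores)
        scab = m.scab_scores(cells, comp)
        for cell in cells:
            regs, xyz, _ = cell.loci_arrays()
            n = len(regs)
            d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
            per_locus = np.full(n, np.nan)
            for i in range(n):
                nbr = [scores[regs[j]] for j in range(n)
                       if j != i and d[i, j] < scab.radius]
                if nbr:
                    per_locus[i] = np.mean(nbr)
            expect = np.full(len(small_codebook), np.nan)
            for ri in np.unique(regs):
                v = per_locus[regs == ri]
                v = v[np.isfinite(v)]
                if len(v):
                    expect[ri] = v.mean()
            got = scab.values.loc[cell.cell_id].to_numpy()
            assert np.allclose(np.nan_to_num(expect, nan=-9e9),
                               np.nan_to_num(got, nan=-9e9))


class TestProximity:
    def test_all_coincident_gives_unit_frequencies(self, small_codebook):
        scores = np.where(np.arange(len(small_codebook)) % 2 == 0, 1.0, -1.0)
        comp = m.CompartmentResult(scores=scores)
        r2 = int(small_codebook.region_indices_on(2)[0])
        r3 = int(small_codebook.region_indices_on(3)[0])
        cell = make_cell("c", "s", {(1, 0): [(0, 0, 0, 0)],
                                    (2, 0): [(r2, 0, 0, 0)],
                                    (3, 0): [(r3, 0, 0, 0)]},
                         small_codebook)
        freqs = m.trans_proximity_frequencies([cell], comp, small_codebook,
                                              cutoff=10.0)
        for k in ("AA", "AB", "BB"):
            if freqs[f"n_{k}"]:
                assert freqs[k] == 1.0

    def test_small_cutoff_gives_zero(self, wt_population, codebook):
        cells, truth = wt_population
        comp = m.CompartmentResult(
            scores=np.where(truth.region_a, 1.0, -1.0))
        freqs = m.trans_proximity_frequencies(cells[:5], comp, codebook,
                                              cutoff=1e-6)
        for k in ("AA", "AB", "BB"):
            assert freqs[k] == 0.0

    def test_counts_match_brute_force_and_partition(self, small_codebook):
        st = ct.StateParams(label="s", n_cells=8)
        cells, truth = ct.simulate_population([st], small_codebook, seed=71)
        comp = m.CompartmentResult(
            scores=np.where(truth.region_a, 1.0, -1.0))
        cutoff = 1500.0
        freqs = m.trans_proximity_frequencies(cells, comp, small_codebook,
                                              cutoff=cutoff)
        labels = truth.region_a
        within = {"AA": 0, "AB": 0, "BB": 0}
        total = {"AA": 0, "AB": 0, "BB": 0}
        for cell in cells:
            regs, xyz, chroms = cell.loci_arrays()
            n = len(regs)
            for i in range(n):
                for j in range(i + 1, n):
                    if chroms[i] == chroms[j]:
                        continue
                    la, lb = labels[regs[i]], labels[regs[j]]
                    key = "AA" if la and lb else (
                        "BB" if not la and not lb else "AB")
                    total[key] += 1
                    if np.linalg.norm(xyz[i] - xyz[j]) < cutoff:
                        within[key] += 1
        for k in ("AA", "AB", "BB"):
            assert freqs[f"n_{k}"] == total[k]
            assert freqs[k] == pytest.approx(within[k] / total[k])
        # the three strata partition all counted pairs
        regs_counts = sum(total.values())
        assert regs_counts == sum(freqs[f"n_{k}"] for k in ("AA", "AB", "BB"))

    def test_invalid_cutoff(self, small_codebook):
        comp = m.CompartmentResult(scores=np.ones(len(small_codebook)))
        with pytest.raises(ValueError):
            m.trans_proximity_frequencies([], comp, small_codebook,
                                          cutoff=0.0)


class TestRadial:
    def test_hand_computed_scores(self, small_codebook):
        cell = make_cell("c", "s", {(1, 0): [(0, 1, 0, 0), (1, -1, 0, 0)],
                                    (1, 1): [(0, 0, 2, 0), (1, 0, -2, 0)]},
                         small_codebook)
        scores, per_region = m.radial_scores(cell)
        assert sorted(scores) == pytest.approx([2 / 3, 2 / 3, 4 / 3, 4 / 3])
        assert per_region[0] == pytest.approx(1.0)   # mean of 2/3 and 4/3

    def test_scores_average_to_one(self, wt_population):
        cells, _ = wt_population
        for cell in cells[:10]:
            scores, _ = m.radial_scores(cell)
            assert scores.mean() == pytest.approx(1.0)

    def test_rigid_motion_invariance(self, small_codebook):
        st = ct.StateParams(label="s", n_cells=1)
        cells, _ = ct.simulate_population([st], small_codebook, seed=81)
        cell = cells[0]
        scores, _ = m.radial_scores(cell)
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.normal(scale=2000, size=3)
        traces = [ct.ChromatinTrace(
            chrom=tr.chrom, copy_id=tr.copy_id,
            loci=[ct.Locus3D(region_index=int(r), x=p[0], y=p[1], z=p[2])
                  for r, p in zip(tr.region_indices, tr.xyz @ q.T + shift)])
            for tr in cell.traces]
        moved = ct.CellRecord(cell_id="m", state="s", traces=traces)
        scores2, _ = m.radial_scores(moved)
        assert np.allclose(scores, scores2)

    def test_negative_correlation_with_compartment(self, wt_compartments):
        cells, truth, _, comp = wt_compartments
        acc = {}
        for cell in cells[:60]:
            _, per_region = m.radial_scores(cell)
            for ri, v in per_region.items():
                acc.setdefault(ri, []).append(v)
        regions = sorted(acc)
        mean_radial = np.array([np.mean(acc[r]) for r in regions])
        sc = comp.scores[regions]
        ok = np.isfinite(sc)
        r = np.corrcoef(mean_radial[ok], sc[ok])[0, 1]
        assert r < -0.3


class TestHullsAndPolarization:
    def test_tetrahedron_volume(self, small_codebook):
        pts = [(0, 0, 0, 0), (1, 1, 0, 0), (2, 0, 1, 0), (3, 0, 0, 1)]
        cell = make_cell("c", "s", {(1, i): [pts[i]] for i in range(2)} | {
            (2, i): [pts[i + 2]] for i in range(2)}, small_codebook)
        # volume computed on 4 unit-tetrahedron vertices; trace-count filter
        # relaxed for the fixture
        vol = m.nuclear_volume(cell, min_traces=1)
        assert vol == pytest.approx((1.0 / 6.0) / 1e9)

    def test_interior_point_and_monotonicity(self, small_codebook):
        rng = np.random.default_rng(2)
        pts = rng.normal(scale=500, size=(20, 3))
        from scipy.spatial import ConvexHull
        v0 = ConvexHull(pts).volume
        centroid = pts.mean(axis=0)
        v1 = ConvexHull(np.vstack([pts, centroid])).volume
        assert v1 == pytest.approx(v0)
        for _ in range(5):
            extra = rng.normal(scale=700, size=(3, 3))
            v2 = ConvexHull(np.vstack([pts, extra])).volume
            assert v2 >= v0 - 1e-9
            pts = np.vstack([pts, extra])
            v0 = v2

    def test_min_traces_filter(self, wt_population):
        cells, _ = wt_population
        assert np.isnan(m.nuclear_volume(cells[0], min_traces=100))
        assert np.isfinite(m.nuclear_volume(cells[0], min_traces=10))

    def _cube(self, shift=0.0):
        base = np.array([[x, y, z] for x in (0, 1.0) for y in (0, 1.0)
                         for z in (0, 1.0)])
        return base + [shift, 0, 0]

    def test_hull_intersection_shifted_cube(self):
        vs = convex_hull_intersection_volume(self._cube(), self._cube(0.5))
        assert vs == pytest.approx(0.5, rel=1e-6)
        # dense-grid Monte Carlo oracle
        rng = np.random.default_rng(0)
        pts = rng.random((200_000, 3)) * [1.5, 1.0, 1.0]
        in_a = (pts[:, 0] <= 1.0)
        in_b = (pts[:, 0] >= 0.5)
        mc = (in_a & in_b).mean() * 1.5
        assert vs == pytest.approx(mc, rel=0.02)

    def test_polarization_limit_cases(self):
        a = self._cube()
        trace = ct.ChromatinTrace(chrom=1, copy_id=0, loci=[
            ct.Locus3D(region_index=i, x=p[0], y=p[1], z=p[2])
            for i, p in enumerate(np.vstack([a, a + [10.0, 0, 0]]))])
        is_a = np.array([True] * 8 + [False] * 8)
        assert m.polarization_index(trace, is_a) == pytest.approx(1.0)
        # identical point sets: PI = 0
        trace2 = ct.ChromatinTrace(chrom=1, copy_id=0, loci=[
            ct.Locus3D(region_index=i, x=p[0], y=p[1], z=p[2])
            for i, p in enumerate(np.vstack([a, a + [1e-9, 0, 0]]))])
        assert m.polarization_index(trace2, is_a) == pytest.approx(0.0,
                                                                   abs=1e-6)

    def test_polarization_shifted_cube_half(self):
        a = self._cube()
        b = self._cube(0.5)
        trace = ct.ChromatinTrace(chrom=1, copy_id=0, loci=[
            ct.Locus3D(region_index=i, x=p[0], y=p[1], z=p[2])
            for i, p in enumerate(np.vstack([a, b]))])
        is_a = np.array([True] * 8 + [False] * 8)
        assert m.polarization_index(trace, is_a) == pytest.approx(0.5,
                                                                  rel=1e-6)

    def test_insufficient_loci_flagged(self):
        trace = ct.ChromatinTrace(chrom=1, copy_id=0, loci=[
            ct.Locus3D(region_index=i, x=float(i), y=0, z=0)
            for i in range(5)])
        is_a = np.array([True, True, True, False, False])
        assert np.isnan(m.polarization_index(trace, is_a))
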