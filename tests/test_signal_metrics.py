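"""Pole-difference, SCF, sensor-area asymmetry, daughter partitioning,
population summaries and association statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polasym import geometry, signal_metrics as sm, synthetic_data as syn
from polasym.geometry import ConstrictionCall, PoleRegions


def _manual_regions(shape, cols1, cols2, rows=slice(None)):
    p1 = np.zeros(shape, dtype=bool)
    p2 = np.zeros(shape, dtype=bool)
    p1[rows, cols1] = True
    p2[rows, cols2] = True
    return PoleRegions(p1, p2)


class TestNormalizedPoleDifference:
    def test_uniform_is_exactly_zero(self, straight_cell):
        mask, _, axis = straight_cell
        regs = geometry.pole_regions(mask, axis)
        img = np.where(mask > 0, 500.0, 0.0)
        assert sm.normalized_pole_difference(img, regs, mask > 0) == 0.0

    def test_piecewise_constant_arithmetic(self):
        # three equal thirds at 50 / 100 / 150: cell mean 100, pole means
        # 50 and 150 -> difference is exactly +/-1
        img = np.zeros((10, 30))
        img[:, :10], img[:, 10:20], img[:, 20:] = 50.0, 100.0, 150.0
        cell = np.ones((10, 30), dtype=bool)
        regs = _manual_regions((10, 30), slice(0, 10), slice(20, 30))
        v = sm.normalized_pole_difference(img, regs, cell, "pole1_first")
        assert v == -1.0
        v2 = sm.normalized_pole_difference(img, regs, cell, "pole2_first")
        assert v2 == 1.0

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, c):
        img = np.zeros((10, 30))
        img[:, :10], img[:, 10:20], img[:, 20:] = 30.0, 90.0, 120.0
        cell = np.ones((10, 30), dtype=bool)
        regs = _manual_regions((10, 30), slice(0, 10), slice(20, 30))
        v1 = sm.normalized_pole_difference(img, regs, cell)
        v2 = sm.normalized_pole_difference(img * c, regs, cell)
        assert np.isclose(v1, v2)

    def test_random_orientation_is_seeded_and_flippable(self, straight_cell):
        mask, _, axis = straight_cell
        regs = geometry.pole_regions(mask, axis)
        img = np.where(mask > 0, 1.0, 0.0) * np.linspace(1, 2, mask.shape[1])
        vals = {
            sm.normalized_pole_difference(
                img, regs, mask > 0, "random", np.random.default_rng(s)
            )
            for s in range(20)
        }
        assert len(vals) == 2  # both signs occur, nothing else
        a, b = sorted(vals)
        assert np.isclose(a, -b)


class TestSCF:
    def test_identical_channels(self, straight_cell):
        mask, _, axis = straight_cell
        rng = np.random.default_rng(0)
        a = np.where(mask > 0, rng.uniform(10, 100, mask.shape), 0.0)
        assert sm.scf(a, a, mask, axis) == pytest.approx(1.0)

    def test_negative_affine_channel(self, straight_cell):
        mask, _, axis = straight_cell
        rng = np.random.default_rng(0)
        a = np.where(mask > 0, rng.uniform(10, 100, mask.shape), 0.0)
        assert sm.scf(a, -2.0 * a + 100.0, mask, axis) == pytest.approx(-1.0)

    def test_affine_invariance(self, straight_cell):
        mask, _, axis = straight_cell
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, mask.shape)
        b = rng.uniform(0, 1, mask.shape)
        v1 = sm.scf(a, b, mask, axis)
        v2 = sm.scf(3.0 * a + 7.0, 0.5 * b + 2.0, mask, axis)
        assert np.isclose(v1, v2)

    def test_white_noise_null_distribution(self, straight_cell):
        """|SCF| of independent noise rarely exceeds 3/sqrt(n)."""
        mask, _, axis = straight_cell
        strip = sm._strip_mask(mask, axis, 1, 4.0, 5.0)
        n = int(strip.sum())
        rng = np.random.default_rng(42)
        exceed = 0
        trials = 300
        for _ in range(trials):
            a = rng.normal(size=mask.shape)
            b = rng.normal(size=mask.shape)
            if abs(sm.scf(a, b, mask, axis)) > 3.0 / np.sqrt(n):
                exceed += 1
        assert exceed / trials <= 0.01

    def test_undersized_strip_flagged(self, straight_cell):
        mask, _, axis = straight_cell
        a = np.ones(mask.shape)
        assert np.isnan(sm.scf(a, a, mask, axis, pole_trim_px=100.0))


class TestGlycogenPoleAreaDifference:
    def test_no_signal_gives_zero(self, straight_cell):
        mask, _, axis = straight_cell
        flat = np.where(mask > 0, 10.0, 0.0)
        a1, a2, d = sm.glycogen_pole_area_difference(flat, mask, axis)
        assert (a1, a2, d) == (0.0, 0.0, 0.0)

    def test_single_polar_blob_normalized_difference(self):
        mask, gt = syn.make_cell_mask(70, 12, 0, None, 0, seed=5)
        gt.noise_sigma, gt.psf_sigma_px = 10.0, 1.0
        gt.true_glycogen_pole_areas_px = (120.0, 0.0)
        sen = syn.render_fluorescence(mask, gt, "glycogen_sensor")
        axis = geometry.compute_medial_axis(mask)
        a1, a2, d = sm.glycogen_pole_area_difference(sen, mask, axis)
        expected = gt.true_glycogen_pole_areas_px[0] / (mask > 0).sum()
        assert abs(d - expected) <= 0.02

    def test_equal_blobs_cancel(self):
        mask, gt = syn.make_cell_mask(70, 12, 0, None, 0, seed=5)
        gt.noise_sigma, gt.psf_sigma_px = 10.0, 1.0
        gt.true_glycogen_pole_areas_px = (100.0, 100.0)
        sen = syn.render_fluorescence(mask, gt, "glycogen_sensor")
        axis = geometry.compute_medial_axis(mask)
        _, _, d = sm.glycogen_pole_area_difference(sen, mask, axis)
        assert abs(d) <= 0.02


class TestSplitAtConstriction:
    def _analyzed(self, rel, depth=0.5):
        mask, gt = syn.make_cell_mask(80, 14, 0, rel, depth, seed=1)
        axis = geometry.compute_medial_axis(mask)
        call = geometry.detect_constriction(geometry.width_profiles(mask, axis))
        assert call.present
        return mask, gt, axis, call

    def test_areas_sum_exactly(self):
        mask, _, axis, call = self._analyzed(0.6)
        out = sm.split_at_constriction(mask, axis, call)
        assert out["daughter1_area_px"] + out["daughter2_area_px"] == (mask > 0).sum()

    def test_symmetric_split_balanced(self):
        mask, _, axis, call = self._analyzed(0.5)
        out = sm.split_at_constriction(mask, axis, call)
        total = out["daughter1_area_px"] + out["daughter2_area_px"]
        assert abs(out["daughter1_area_px"] - total / 2) <= 0.03 * total

    def test_offcenter_split_fraction(self):
        mask, _, axis, call = self._analyzed(0.6)
        out = sm.split_at_constriction(mask, axis, call)
        total = out["daughter1_area_px"] + out["daughter2_area_px"]
        larger = max(out["daughter1_area_px"], out["daughter2_area_px"])
        assert abs(larger / total - 0.6) <= 0.03

    def test_one_sided_sensor_signal(self):
        mask, gt, axis, call = self._analyzed(0.6)
        gt.noise_sigma, gt.psf_sigma_px = 0.0, 0.0
        gt.true_glycogen_pole_areas_px = (80.0, 0.0)
        sen = syn.render_fluorescence(mask, gt, "glycogen_sensor")
        out = sm.split_at_constriction(mask, axis, call, sensor_channel=sen)
        total = out["daughter1_sensor_area_px"] + out["daughter2_sensor_area_px"]
        assert abs(out["daughter_sensor_area_diff_px"]) == total > 0

    def test_absent_constriction_rejected(self, straight_cell):
        mask, _, axis = straight_cell
        with pytest.raises(ValueError):
            sm.split_at_constriction(mask, axis, ConstrictionCall(False))


class TestPopulationSummary:
    def _records(self, n, frac_con, group, rng):
        rows = []
        for i in range(n):
            con = rng.random() < frac_con
            rows.append(
                {
                    "group": group,
                    "area_px": rng.uniform(400, 900),
                    "nucleoid_area_px": rng.uniform(100, 300),
                    "nucleoid_count": rng.integers(1, 4),
                    "constriction_present": con,
                    "constriction_norm_offset": rng.uniform(0, 0.2) if con else np.nan,
                }
            )
        return rows

    def test_low_constricting_fraction_suppressed(self):
        rng = np.random.default_rng(0)
        recs = self._records(100, 0.0, "od1", rng)
        recs[0]["constriction_present"] = True
        recs[0]["constriction_norm_offset"] = 0.1  # 1/100 = 0.01 <= 0.05
        out = sm.population_summary(pd.DataFrame(recs), "group")
        assert bool(out["division_asymmetry_suppressed"][0])
        assert np.isnan(out["mean_division_asymmetry"][0])

    def test_identical_cells_mean_equals_value(self):
        rec = {
            "group": "g", "area_px": 600.0, "nucleoid_area_px": 200.0,
            "nucleoid_count": 1, "constriction_present": True,
            "constriction_norm_offset": 0.12,
        }
        out = sm.population_summary(pd.DataFrame([rec] * 5), "group")
        assert out["mean_cell_area_px"][0] == 600.0
        assert out["mean_division_asymmetry"][0] == pytest.approx(0.12)
        assert out["fraction_single_nucleoid"][0] == 1.0

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(7)
        recs = self._records(25, 0.4, "a", rng) + self._records(25, 0.2, "b", rng)
        df = pd.DataFrame(recs)
        out = sm.population_summary(df, "group").set_index("group")
        for g in ("a", "b"):
            sub = [r for r in recs if r["group"] == g]
            assert out.loc[g, "n_cells"] == len(sub)
            assert out.loc[g, "mean_cell_area_px"] == np.mean([r["area_px"] for r in sub])
            frac = np.mean([r["constriction_present"] for r in sub])
            assert out.loc[g, "fraction_constricting"] == frac
            if frac > 0.05:
                cons = [r["constriction_norm_offset"] for r in sub if r["constriction_present"]]
                assert out.loc[g, "mean_division_asymmetry"] == np.mean(cons)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sm.population_summary(pd.DataFrame(), "group")


def _brute_force_spearman(x, y):
    """Pearson correlation of mid-ranks, computed from first principles."""

    def midranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2.0 + 1.0
            i = j
        return ranks

    rx, ry = midranks(np.asarray(x, float)), midranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestAssociationStats:
    def test_monotone_gives_unit_rho(self):
        x = np.arange(20.0)
        rho, _, _ = sm.association_stats(x, np.exp(x / 5.0))
        assert rho == 1.0

    def test_tls_on_exact_line(self):
        x = np.linspace(-3, 5, 30)
        rho, slope, intercept = sm.association_stats(x, 2.0 * x + 1.0)
        assert slope == pytest.approx(2.0, abs=1e-12)
        assert intercept == pytest.approx(1.0, abs=1e-12)

    def test_tls_symmetric_in_axes(self):
        # TLS treats x and y symmetrically: slopes of (x, y) and (y, x)
        # are reciprocal, unlike ordinary least squares
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        y = 1.5 * x + rng.normal(scale=0.5, size=200)
        _, s_xy, _ = sm.association_stats(x, y)
        _, s_yx, _ = sm.association_stats(y, x)
        assert s_xy == pytest.approx(1.0 / s_yx, rel=1e-9)

    def test_spearman_matches_rank_formula_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.integers(0, 8, 20).astype(float)  # heavy ties
            y = rng.normal(size=20)
            rho, _, _ = sm.association_stats(x, y)
            assert abs(rho - _brute_force_spearman(x, y)) < 1e-12

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            sm.association_stats(np.ones(10), np.arange(10.0))
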