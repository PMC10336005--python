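import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pcmassembly import minflux
from conftest import make_table


class TestFilterTraces:
    def test_boundary_at_five_localizations(self):
        rows = [(1, 0.0, 0.0, 0.0, 0.0, 10.0)] * 4 + [(2, 0.0, 0.0, 0.0, 0.0, 10.0)] * 5
        rep = minflux.filter_traces(make_table(rows))
        assert rep.n_traces_discarded == 1
        assert rep.n_traces_kept == 1
        assert set(rep.table.trace_id) == {2}

    def test_empty_input(self):
        rep = minflux.filter_traces(make_table([]))
        assert rep.n_traces_kept == 0 and rep.n_traces_discarded == 0
        assert rep.table.empty

    def test_length_ladder(self):
        rows = []
        for tid in range(1, 11):
            rows += [(tid, 0.0, 0.0, 0.0, 0.0, 1.0)] * tid
        rep = minflux.filter_traces(make_table(rows))
        assert rep.n_traces_kept == 6  # lengths 5..10
        assert rep.n_traces_discarded == 4

    def test_missing_trace_id_column(self):
        with pytest.raises(ValueError):
            minflux.filter_traces(pd.DataFrame({"x_nm": [1.0]}))

    @given(threshold=st.integers(1, 12))
    @settings(max_examples=12, derandomize=True)
    def test_raising_threshold_never_keeps_more(self, threshold):
        rows = []
        for tid in range(1, 11):
            rows += [(tid, 0.0, 0.0, 0.0, 0.0, 1.0)] * tid
        table = make_table(rows)
        kept = minflux.filter_traces(table, threshold).n_traces_kept
        kept_higher = minflux.filter_traces(table, threshold + 1).n_traces_kept
        assert kept_higher <= kept


class TestCollapseTraces:
    def test_equal_photons_gives_arithmetic_mean(self):
        rows = [(1, 0.0, 0.0, 0.0, 0.0, 50.0), (1, 0.1, 2.0, 4.0, 6.0, 50.0)]
        mol = minflux.collapse_traces(make_table(rows))
        assert mol.loc[0, ["x_nm", "y_nm", "z_nm"]].tolist() == [1.0, 2.0, 3.0]

    def test_single_bright_localization_dominates(self):
        rows = [(1, 0.0, 1.0, 2.0, 3.0, 500.0), (1, 0.1, 9.0, 9.0, 9.0, 0.0)]
        mol = minflux.collapse_traces(make_table(rows))
        assert mol.loc[0, ["x_nm", "y_nm", "z_nm"]].tolist() == [1.0, 2.0, 3.0]

    def test_hand_computed_weighted_mean(self):
        # (0,0,0) w=100 and (10,0,0) w=300 -> (7.5, 0, 0)
        rows = [(7, 0.0, 0.0, 0.0, 0.0, 100.0), (7, 0.1, 10.0, 0.0, 0.0, 300.0)]
        mol = minflux.collapse_traces(make_table(rows))
        assert mol.loc[0, "x_nm"] == pytest.approx(7.5)
        assert mol.loc[0, "total_photons"] == 400.0
        assert mol.loc[0, "n_localizations"] == 2

    def test_zero_photon_trace_warns_and_uses_unweighted_mean(self):
        rows = [(1, 0.0, 0.0, 0.0, 0.0, 0.0), (1, 0.1, 4.0, 0.0, 0.0, 0.0)]
        with pytest.warns(UserWarning, match="zero total photons"):
            mol = minflux.collapse_traces(make_table(rows))
        assert mol.loc[0, "x_nm"] == pytest.approx(2.0)

    @given(seed=st.integers(0, 50))
    @settings(max_examples=25, derandomize=True)
    def test_position_inside_trace_bounding_box(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for tid in range(3):
            for i in range(rng.integers(2, 8)):
                x, y, z = rng.normal(size=3) * 20
                rows.append((tid, 0.01 * i, x, y, z, float(rng.integers(1, 500))))
        mols = minflux.collapse_traces(make_table(rows))
        table = make_table(rows)
        for _, m in mols.iterrows():
            grp = table[table.trace_id == m.trace_id]
            for ax in ("x_nm", "y_nm", "z_nm"):
                assert grp[ax].min() - 1e-9 <= m[ax] <= grp[ax].max() + 1e-9


class TestEstimatePrecision:
    def test_identical_localizations_give_zero(self):
        rows = [(1, 0.01 * i, 5.0, 5.0, 5.0, 10.0) for i in range(6)]
        assert minflux.estimate_precision(make_table(rows)) == 0.0

    def test_median_of_two_traces_is_midpoint(self):
        # per-axis sample s.d. of two points [p, -p] is p*sqrt(2);
        # choose p so each axis gives exactly 5 nm (trace 1) and 9 nm (trace 2)
        rows = []
        for tid, sd in ((1, 5.0), (2, 9.0)):
            p = sd / math.sqrt(2.0)
            rows.append((tid, 0.0, p, p, p, 1.0))
            rows.append((tid, 0.1, -p, -p, -p, 1.0))
        assert minflux.estimate_precision(make_table(rows)) == pytest.approx(7.0)

    def test_recovers_injected_sigma(self):
        rng = np.random.default_rng(0)
        rows = []
        for tid in range(500):
            pts = rng.normal(0.0, 13.0, size=(25, 3))
            rows += [(tid, 0.01 * i, *pts[i], 100.0) for i in range(25)]
        assert minflux.estimate_precision(make_table(rows)) == pytest.approx(13.0, abs=1.0)

    def test_all_single_localization_traces_error(self):
        rows = [(1, 0.0, 0.0, 0.0, 0.0, 1.0), (2, 0.0, 1.0, 1.0, 1.0, 1.0)]
        with pytest.raises(ValueError):
            minflux.estimate_precision(make_table(rows))


def circumcircle(p1, p2, p3):
    """Closed-form circumcenter/radius of a triangle (oracle)."""
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = (
        (ax**2 + ay**2) * (by - cy)
        + (bx**2 + by**2) * (cy - ay)
        + (cx**2 + cy**2) * (ay - by)
    ) / d
    uy = (
        (ax**2 + ay**2) * (cx - bx)
        + (bx**2 + by**2) * (ax - cx)
        + (cx**2 + cy**2) * (bx - ax)
    ) / d
    return ux, uy, math.hypot(ax - ux, ay - uy)


class TestFitCircle:
    def test_exact_circle_recovered(self):
        theta = np.linspace(0, 2 * math.pi, 40, endpoint=False)
        xy = np.column_stack([30 + 192 * np.cos(theta), -12 + 192 * np.sin(theta)])
        fit = minflux.fit_circle(xy)
        assert fit.center_x_nm == pytest.approx(30.0, abs=1e-9)
        assert fit.center_y_nm == pytest.approx(-12.0, abs=1e-9)
        assert fit.radius_nm == pytest.approx(192.0, abs=1e-9)
        assert fit.rms_residual_nm < 1e-9

    def test_three_points_give_circumcircle(self):
        pts = [(0.0, 0.0), (4.0, 0.0), (1.0, 3.0)]
        cx, cy, r = circumcircle(*pts)
        fit = minflux.fit_circle(np.array(pts))
        assert fit.center_x_nm == pytest.approx(cx, abs=1e-8)
        assert fit.center_y_nm == pytest.approx(cy, abs=1e-8)
        assert fit.radius_nm == pytest.approx(r, abs=1e-8)

    def test_noisy_ring_radius_within_tolerance(self):
        rng = np.random.default_rng(7)
        theta = rng.uniform(0, 2 * math.pi, 500)
        xy = np.column_stack([192 * np.cos(theta), 192 * np.sin(theta)])
        xy += rng.normal(0, 13.0, xy.shape)
        fit = minflux.fit_circle(xy)
        assert fit.radius_nm == pytest.approx(192.0, abs=3.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            minflux.fit_circle(np.array([[0.0, 0.0], [1.0, 1.0]]))
        line = np.column_stack([np.arange(5.0), 2.0 * np.arange(5.0)])
        with pytest.raises(ValueError):
            minflux.fit_circle(line)


def molecules_frame(x, y, z):
    return pd.DataFrame({"x_nm": x, "y_nm": y, "z_nm": z})


class TestCylinderStats:
    def test_recovers_uniform_shell_geometry(self):
        rng = np.random.default_rng(21)
        n = 500
        r = np.sqrt(rng.uniform(137.5**2, 246.5**2, n))
        th = rng.uniform(0, 2 * math.pi, n)
        z = rng.uniform(-131.0, 131.0, n)
        mols = molecules_frame(r * np.cos(th), r * np.sin(th), z)
        fit = minflux.fit_circle(mols[["x_nm", "y_nm"]].to_numpy())
        cs = minflux.cylinder_stats(mols, fit)
        # mean radius of a uniform-in-area annulus: (2/3)(Ro^3-Ri^3)/(Ro^2-Ri^2)
        r_mean = (2.0 / 3.0) * (246.5**3 - 137.5**3) / (246.5**2 - 137.5**2)
        assert cs.mean_diameter_nm == pytest.approx(2 * r_mean, rel=0.05)
        assert cs.p5p95_width_nm == pytest.approx(0.9 * 109.0, rel=0.15)
        assert cs.p5p95_height_nm == pytest.approx(0.9 * 262.0, rel=0.15)
        assert cs.outlier_fraction < 0.05

    def test_single_radius_collapses_whiskers(self):
        th = np.linspace(0, 2 * math.pi, 50, endpoint=False)
        mols = molecules_frame(100 * np.cos(th), 100 * np.sin(th), np.zeros(50))
        cs = minflux.cylinder_stats(mols, minflux.CircleFit(0.0, 0.0, 100.0, 0.0))
        assert cs.p5p95_width_nm == pytest.approx(0.0, abs=1e-9)
        assert cs.whisker_width_nm == pytest.approx(0.0, abs=1e-9)
        assert cs.concentration_m == 0.0  # degenerate shell has no volume

    def test_hand_computed_quartiles_on_20_points(self):
        # radial distances 1..20 from the origin along +x, all z = 0
        r = np.arange(1.0, 21.0)
        mols = molecules_frame(r, np.zeros(20), np.zeros(20))
        cs = minflux.cylinder_stats(mols, minflux.CircleFit(0.0, 0.0, 10.0, 0.0))
        # linear-interpolation quartiles of 1..20: Q1=5.75, Q3=15.25, IQR=9.5
        assert cs.whisker_radius_nm[0] == pytest.approx(5.75 - 14.25)
        assert cs.whisker_radius_nm[1] == pytest.approx(15.25 + 14.25)
        assert cs.n_outliers == 0
        assert cs.p5_radius_nm == pytest.approx(1.95)
        assert cs.p95_radius_nm == pytest.approx(19.05)
        assert cs.p5p95_width_nm == pytest.approx(17.1)
        # p5-p95 width can never exceed the whisker range
        assert cs.p5p95_width_nm <= cs.whisker_width_nm

    def test_low_confidence_flag(self):
        mols = molecules_frame([0.0, 1.0, 2.0, 3.0], [1.0, 0.0, 1.0, 2.0], [0.0] * 4)
        cs = minflux.cylinder_stats(mols, minflux.CircleFit(0.0, 0.0, 1.0, 0.0))
        assert cs.low_confidence


class TestConcentration:
    def test_one_molecule_per_cubic_micron(self):
        # 1/(6.022e23 * 1e-15 L) ~ 1.66 nM
        conc = minflux.concentration_in_shell(1, 1e9)
        assert conc == pytest.approx(1.66e-9, rel=0.01)

    def test_zero_molecules(self):
        assert minflux.concentration_in_shell(0, 1e9) == 0.0

    def test_pcm_shell_consistency(self):
        # ~270 molecules in the measured pericentriolar shell volume is
        # on the order of 16 uM
        conc = minflux.concentration_in_shell(270, 2.80e7)
        assert conc * 1e6 == pytest.approx(16.0, rel=0.05)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            minflux.concentration_in_shell(5, 0.0)


class TestRenderDensity:
    def test_single_point_blob_centred(self):
        vol = minflux.render_density(np.array([[1.0, 2.0, 3.0]]))
        idx = np.unravel_index(np.argmax(vol.intensity), vol.intensity.shape)
        centre = vol.origin_nm + (np.array(idx) + 0.5) * vol.voxel_nm
        assert np.allclose(centre, [1.0, 2.0, 3.0], atol=vol.voxel_nm)

    def test_intensity_sum_preserved(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 10, size=(100, 3))
        vol = minflux.render_density(pts)
        assert vol.intensity.sum() == pytest.approx(100.0, rel=1e-6)

    def test_linearity_for_distant_points(self):
        a = minflux.render_density(np.array([[0.0, 0.0, 0.0]]))
        b = minflux.render_density(np.array([[0.0, 0.0, 0.0], [200.0, 0.0, 0.0]]))
        # each blob carries unit mass; far-apart blobs just add
        assert b.intensity.sum() == pytest.approx(2 * a.intensity.sum(), rel=1e-6)
        assert b.intensity.max() == pytest.approx(a.intensity.max(), rel=1e-6)

    def test_invalid_parameters(self):
        pts = np.zeros((1, 3))
        with pytest.raises(ValueError):
            minflux.render_density(pts, voxel_nm=0.0)
        with pytest.raises(ValueError):
            minflux.render_density(pts, sigma_nm=-1.0)


class TestLabelingStatistics:
    def test_pore_complex_control_arithmetic(self):
        s = minflux.labeling_statistics(81, 24, 16, 93)
        assert s.label_fraction == pytest.approx(0.21, abs=0.005)
        assert s.single_trace_fraction == pytest.approx(0.955, abs=0.005)
        assert s.expected_traces == 85
        assert s.overcount_fraction == pytest.approx(0.09, abs=0.005)

    def test_no_clusters(self):
        s = minflux.labeling_statistics(0, 24, 16, 0)
        assert s.label_fraction == 0.0
        assert s.single_trace_fraction == 1.0
        assert s.expected_traces == 0

    def test_full_labeling(self):
        s = minflux.labeling_statistics(384, 24, 16, 800)
        assert s.label_fraction == 1.0
        assert s.single_trace_fraction == 0.0

    def test_observed_without_expected_rejected(self):
        with pytest.raises(ValueError):
            minflux.labeling_statistics(0, 24, 16, 5)


class TestPipelineDeterminism:
    def test_identical_table_identical_outputs(self, simple_table):
        from pcmassembly.cli import minflux_run_report

        rows = []
        rng = np.random.default_rng(5)
        for tid in range(40):
            th = rng.uniform(0, 2 * math.pi)
            cx, cy, cz = 192 * math.cos(th), 192 * math.sin(th), rng.uniform(-130, 130)
            for i in range(8):
                rows.append(
                    (tid, 0.01 * i, cx + rng.normal(0, 13), cy + rng.normal(0, 13),
                     cz + rng.normal(0, 13), float(rng.integers(50, 500)))
                )
        table = make_table(rows)
        rep1, mol1 = minflux_run_report(table.copy())
        rep2, mol2 = minflux_run_report(table.copy())
        pd.testing.assert_frame_equal(mol1, mol2)
        assert rep1["cylinder_stats"] == rep2["cylinder_stats"]
        assert rep1["precision_nm"] == rep2["precision_nm"]
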