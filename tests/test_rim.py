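"""Detergent corona: box sampling, geometric selection, contrast bookkeeping."""

import numpy as np
import pytest
from scipy.stats import chisquare

from beltsas import (
    DetergentSpec,
    MidplaneCurve,
    RimParams,
    SolventSpec,
    assign_contrasts,
    hydration_layer,
    rim_composition,
    sample_box,
    select_rim,
)
from conftest import solid_model

BOUNDS = np.array([[-50.0, -50, -50], [50.0, 50, 50]])


def brute_force_select(points, curve, protein_pos, p, clearance=3.0):
    """Literal restatement of the selection rules with plain loops.

    Tails: anisotropically scaled distance to the curve < 1, not within
    3 Å of the protein.  Heads: scaled shell distance <= 1, not a tail,
    clear of the protein, and connected to the hydrocarbon core —
    within the (D_xy, D_z)-scaled unit distance of a sampled tail point
    or of the continuum core surface along the ray to the nearest curve
    point.
    """
    n = len(points)
    tails = np.zeros(n, bool)
    outer = np.zeros(n, bool)
    min_core = np.full(n, np.inf)
    arg_core = np.zeros(n, int)
    for i in range(n):
        for j, c in enumerate(curve):
            dxy = (points[i, 0] - c[0]) ** 2 + (points[i, 1] - c[1]) ** 2
            dz = (points[i, 2] - c[2]) ** 2
            score = dxy / p.R_xy**2 + dz / p.R_z**2
            if score < min_core[i]:
                min_core[i] = score
                arg_core[i] = j
            if dxy / (p.R_xy + p.D_xy) ** 2 + dz / (p.R_z + p.D_z) ** 2 <= 1.0:
                outer[i] = True
        clear = True
        if protein_pos is not None:
            for q in protein_pos:
                if np.linalg.norm(points[i] - q) < clearance:
                    clear = False
                    break
        tails[i] = min_core[i] < 1.0 and clear
        outer[i] &= clear
    heads = np.zeros(n, bool)
    tp = points[tails]
    for i in np.flatnonzero(outer & ~tails):
        connected = False
        for t in tp:
            d = points[i] - t
            if (d[0] ** 2 + d[1] ** 2) / p.D_xy**2 + d[2] ** 2 / p.D_z**2 <= 1.0:
                connected = True
                break
        if not connected and len(tp):
            c = curve[arg_core[i]]
            off = points[i] - c
            u = np.sqrt(min_core[i])
            d_scaled = np.sqrt(
                (off[0] ** 2 + off[1] ** 2) / p.D_xy**2 + off[2] ** 2 / p.D_z**2
            )
            connected = (1.0 - 1.0 / max(u, 1.0)) * d_scaled <= 1.0
        heads[i] = connected and len(tp) > 0
    return tails, heads


class TestSampleBox:
    def test_zero_points(self):
        pts, dens = sample_box(BOUNDS, 0, seed=1)
        assert pts.shape == (0, 3) and dens == 0.0

    def test_deterministic(self):
        a, _ = sample_box(BOUNDS, 1000, seed=7)
        b, _ = sample_box(BOUNDS, 1000, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_uniformity_per_octant(self):
        pts, dens = sample_box(BOUNDS, 100_000, seed=3)
        octant = (
            (pts[:, 0] > 0).astype(int) * 4
            + (pts[:, 1] > 0).astype(int) * 2
            + (pts[:, 2] > 0).astype(int)
        )
        counts = np.bincount(octant, minlength=8)
        assert chisquare(counts).pvalue > 0.001
        assert dens == pytest.approx(100_000 / 100.0**3)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sample_box(np.array([[0.0, 0, 0], [0.0, 1, 1]]), 10, seed=0)


class TestSelectRim:
    @pytest.mark.parametrize("with_protein", [False, True])
    @pytest.mark.parametrize("params", [
        RimParams(12.0, 8.0, 4.0, 3.0),
        RimParams(18.0, 18.0, 6.0, 6.0),
        RimParams(25.0, 9.0, 9.5, 2.0),
    ])
    def test_matches_brute_force_oracle(self, params, with_protein):
        """Production selection equals the literal distance-rule oracle
        on instances up to 2000 points."""
        rng = np.random.default_rng(42)
        points = -40 + 80 * rng.random((2000, 3))
        ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        curve = np.column_stack(
            [10 * np.cos(ang), 10 * np.sin(ang), np.zeros_like(ang)])
        protein = None
        protein_pos = None
        if with_protein:
            protein_pos = -8 + 16 * rng.random((60, 3))
            protein = solid_model(protein_pos)
        tails, heads = select_rim(
            points, MidplaneCurve(points=curve), protein, params)
        bt, bh = brute_force_select(points, curve, protein_pos, params)
        np.testing.assert_array_equal(tails, bt)
        np.testing.assert_array_equal(heads, bh)

    def test_degenerate_radius_selects_nothing(self):
        rng = np.random.default_rng(0)
        points = -10 + 20 * rng.random((500, 3))
        tails, heads = select_rim(
            points, MidplaneCurve(points=np.zeros((1, 3))), None,
            RimParams(0.01, 0.01, 0.01, 0.01))
        assert not tails.any() and not heads.any()

    def test_single_curve_point_is_ball_membership(self):
        rng = np.random.default_rng(1)
        points = -20 + 40 * rng.random((1500, 3))
        p = RimParams(9.0, 9.0, 4.0, 4.0)
        tails, heads = select_rim(
            points, MidplaneCurve(points=np.zeros((1, 3))), None, p)
        r = np.linalg.norm(points, axis=1)
        np.testing.assert_array_equal(tails, r < 9.0)
        np.testing.assert_array_equal(heads, (r >= 9.0) & (r <= 13.0))

    def test_disconnected_head_candidate_excluded(self):
        """A shell point beyond D of both the sampled tails and the
        continuum core surface is rejected; a ray-connected one stays."""
        p = RimParams(10.0, 2.0, 1.0, 1.0)
        curve = np.zeros((1, 3))
        points = np.array([
            [5.0, 0.0, 0.0],     # tail (inside core)
            [10.8, 0.0, 0.45],   # shell, ray distance > D -> excluded
            [9.0, 0.0, 1.2],     # shell, ray distance < D -> kept
        ])
        tails, heads = select_rim(points, MidplaneCurve(points=curve), None, p)
        assert list(tails) == [True, False, False]
        assert list(heads) == [False, False, True]


class TestComposition:
    def test_paper_scale_arithmetic(self):
        v, n = rim_composition(14_112, 0.5, DetergentSpec())
        assert v == pytest.approx(28_224.0)
        assert n == 96

    def test_zero_points(self):
        assert rim_composition(0, 0.5, DetergentSpec()) == (0.0, 0)

    @pytest.mark.parametrize("count,density", [(100, 0.1), (9999, 0.5), (294, 1.0)])
    def test_floor_property(self, count, density):
        spec = DetergentSpec()
        v, n = rim_composition(count, density, spec)
        assert n * spec.tail_volume <= v < (n + 1) * spec.tail_volume

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            rim_composition(10, 0.0, DetergentSpec())


class TestContrasts:
    def test_per_molecule_excess_from_constants(self):
        spec = DetergentSpec()
        assert spec.tail_excess(0.340) == pytest.approx(-18.96, abs=1e-10)
        assert spec.head_excess(0.340) == pytest.approx(62.0, abs=1e-10)

    def test_density_ordering(self):
        spec = DetergentSpec()
        tail_density = spec.tail_electrons / spec.tail_volume
        head_density = spec.head_electrons / spec.head_dry_volume
        assert tail_density < 0.340 < head_density

    def test_contrast_match_limit(self):
        spec = DetergentSpec()
        assert spec.tail_excess(81.0 / 294.0) == pytest.approx(0.0, abs=1e-12)

    def test_totals_distributed_uniformly(self):
        rng = np.random.default_rng(5)
        rim = assign_contrasts(
            rng.random((500, 3)), rng.random((300, 3)), 42, 0.2,
            DetergentSpec(), SolventSpec())
        assert rim.tail_b.sum() == pytest.approx(42 * -18.96)
        assert rim.head_b.sum() == pytest.approx(42 * 62.0)
        assert np.ptp(rim.tail_b) == 0 and np.ptp(rim.head_b) == 0

    def test_empty_class_with_molecules_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assign_contrasts(np.empty((0, 3)), np.ones((5, 3)), 3, 0.2,
                             DetergentSpec(), SolventSpec())


class TestHydration:
    def test_single_atom_shell_volume(self):
        # one-atom toy solid: the hydration shell is the analytic
        # spherical layer between clearance and clearance + thickness
        rng = np.random.default_rng(2)
        points = -20 + 40 * rng.random((400_000, 3))
        density = 400_000 / 40.0**3
        solvent = SolventSpec(hydration_thickness=3.0)
        atom = solid_model(np.zeros((1, 3)))
        pos, b = hydration_layer(atom, points, None, solvent, density)
        vol = len(pos) / density
        expected = 4 / 3 * np.pi * (6.0**3 - 3.0**3)
        assert vol == pytest.approx(expected, rel=0.10)
        d = np.linalg.norm(pos, axis=1)
        assert d.min() > 3.0 and d.max() <= 6.0

    def test_rim_mask_excludes_points(self, sphere_model):
        rng = np.random.default_rng(2)
        points = -30 + 60 * rng.random((5000, 3))
        solvent = SolventSpec()
        all_pos, _ = hydration_layer(sphere_model, points, None, solvent, 0.02)
        none_pos, _ = hydration_layer(
            sphere_model, points, np.ones(len(points), bool), solvent, 0.02)
        assert len(none_pos) == 0 and len(all_pos) > 0

    def test_zero_contrast_scatters_nothing(self, sphere_model):
        rng = np.random.default_rng(2)
        points = -30 + 60 * rng.random((5000, 3))
        solvent = SolventSpec(hydration_contrast=0.0)
        _, b = hydration_layer(sphere_model, points, None, solvent, 0.02)
        assert np.all(b == 0.0)


def test_monte_carlo_volume_convergence():
    """Doubling the box density moves V_tail by < 3% (micelle mode)."""
    spec = DetergentSpec()
    p = RimParams(18.0, 18.0, 6.0, 6.0)
    curve = MidplaneCurve(points=np.zeros((1, 3)))
    vols = []
    for n in (60_000, 120_000):
        pts, dens = sample_box(np.array([[-30.0] * 3, [30.0] * 3]), n, seed=11)
        tails, _ = select_rim(pts, curve, None, p)
        vols.append(rim_composition(int(tails.sum()), dens, spec)[0])
    assert abs(vols[1] - vols[0]) / vols[0] < 0.03


def test_rim_point_cloud_serialization(tmp_path):
    """The corona is writable as a plain-text (x y z b) point cloud."""
    rng = np.random.default_rng(3)
    rim = assign_contrasts(rng.random((40, 3)), rng.random((20, 3)), 5, 0.2,
                           DetergentSpec(), SolventSpec())
    path = tmp_path / "rim.txt"
    rim.save_points(path)
    data = np.loadtxt(path)
    assert data.shape == (60, 4)
    assert data[:, 3].sum() == pytest.approx(5 * (-18.96 + 62.0), rel=1e-6)
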