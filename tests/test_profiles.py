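import numpy as np
import pytest

from cytomap import gli, profiles


def straight_contours(length=300.0, thickness=80.0, y0=10.0, n=40):
    x = np.linspace(5.0, 5.0 + length, n)
    outer = np.column_stack([x, np.full(n, y0)])
    inner = np.column_stack([x, np.full(n, y0 + thickness)])
    return profiles.ContourPair(outer, inner, pixel_size=1.0)


def concentric_contours(r_out=120.0, r_in=60.0, span=np.pi / 2, n=200):
    """Outer cortical surface on the larger radius, center at the origin
    shifted into positive coordinates."""
    c = np.array([150.0, 150.0])
    th = np.linspace(-span / 2, span / 2, n) - np.pi / 2
    outer = c + r_out * np.column_stack([np.cos(th), np.sin(th)])
    inner = c + r_in * np.column_stack([np.cos(th), np.sin(th)])
    return profiles.ContourPair(outer, inner, pixel_size=1.0), c


class TestBuildTraverses:
    def test_straight_ribbon_gives_parallel_vertical_traverses(self):
        cp = straight_contours(length=200.0, thickness=60.0)
        travs = profiles.build_traverses(cp, spacing=20.0, grid_step=2.0)
        assert len(travs) == int(200.0 / 20.0) + 1
        for t in travs:
            # start on outer, end on inner, essentially constant x
            assert t[0, 1] == pytest.approx(10.0, abs=0.5)
            assert t[-1, 1] == pytest.approx(70.0, abs=1.0)
            assert np.ptp(t[:, 0]) < 1.5

    def test_concentric_arcs_give_radial_traverses(self):
        """Between concentric circles the harmonic field is log-radial, so
        streamlines are radial to within 1 degree."""
        cp, center = concentric_contours()
        travs = profiles.build_traverses(cp, spacing=15.0, grid_step=1.5)
        for t in travs[2:-2]:
            # compare the chord direction with the radial direction at the
            # traverse midpoint
            chord = t[-1] - t[0]
            chord = chord / np.linalg.norm(chord)
            radial = center - t[len(t) // 2]
            radial = radial / np.linalg.norm(radial)
            angle = np.degrees(np.arccos(np.clip(abs(chord @ radial), -1, 1)))
            assert angle < 1.0

    def test_orientation_reversal_gives_reversed_traverses(self):
        cp = straight_contours(length=100.0, thickness=40.0)
        rev = profiles.ContourPair(cp.outer[::-1], cp.inner[::-1], cp.pixel_size)
        fwd_travs = profiles.build_traverses(cp, spacing=25.0, grid_step=2.0)
        rev_travs = profiles.build_traverses(rev, spacing=25.0, grid_step=2.0)
        assert len(fwd_travs) == len(rev_travs)
        for a, b in zip(fwd_travs, rev_travs[::-1]):
            assert np.allclose(a[0], b[0], atol=1e-6)
            assert abs(a[-1, 0] - b[-1, 0]) < 1.5

    def test_crossing_contours_rejected(self):
        outer = np.array([[0.0, 0.0], [100.0, 50.0]])
        inner = np.array([[0.0, 50.0], [100.0, 0.0]])
        cp = profiles.ContourPair(outer, inner)
        with pytest.raises(ValueError, match="cross"):
            profiles.build_traverses(cp, spacing=10.0)

    def test_degenerate_thickness_rejected(self):
        outer = np.array([[0.0, 10.0], [100.0, 10.0]])
        inner = np.array([[0.0, 10.4], [100.0, 10.4]])
        cp = profiles.ContourPair(outer, inner)
        with pytest.raises(ValueError, match="degenerate"):
            profiles.build_traverses(cp, spacing=10.0, grid_step=1.0)

    def test_traverses_never_cross_on_curved_section(self, archetypes):
        from cytomap import synthetic

        spec = synthetic.RibbonSpec(
            archetypes=(archetypes["granular"],),
            geometry="sinusoidal",
            cortical_thickness=400.0,
            arc_length=1600.0,
            pixel_size=4.0,
            seed=2,
        )
        section = synthetic.make_section(spec)
        cp = profiles.ContourPair(
            section.outer_contour, section.inner_contour, spec.pixel_size
        )
        travs = profiles.build_traverses(cp, spacing=60.0, grid_step=2.0)
        assert len(travs) > 10
        assert not profiles.traverses_cross(travs)


class TestExtractProfile:
    def test_uniform_gli_gives_constant_profile(self):
        g = gli.GLIImage(np.full((20, 20), 37.0), field_size=4.0, source_pixel_size=1.0)
        trav = np.column_stack([np.full(30, 40.0), np.linspace(5, 75, 30)])
        p = profiles.extract_profile(g, trav, D=51)
        np.testing.assert_allclose(p.values, 37.0, atol=1e-9)
        assert p.raw_length == pytest.approx(70.0)

    def test_length_normalization_is_thickness_invariant(self):
        """The same laminar pattern in relative depth yields the same
        normalized profile at cortical thickness t and 2t."""
        def make_gli(thickness):
            rows = np.linspace(0, 1, thickness)
            pattern = 20 + 30 * np.exp(-((rows - 0.55) ** 2) / 0.01)
            values = np.tile(pattern[:, None], (1, 30))
            return gli.GLIImage(values, field_size=1.0, source_pixel_size=1.0)

        out = []
        for thickness in (80, 160):
            g = make_gli(thickness)
            trav = np.column_stack(
                [np.full(200, 15.0), np.linspace(0.5, thickness - 0.5, 200)]
            )
            out.append(profiles.extract_profile(g, trav, D=101))
        np.testing.assert_allclose(out[0].values, out[1].values, atol=0.8)

    def test_radial_step_pattern_lands_at_mid_depth(self):
        """An annular ribbon with 30% stain above mid-depth and 60% below
        produces a normalized profile stepping at 50 ± 2 % depth."""
        cp, center = concentric_contours(r_out=120.0, r_in=60.0)
        yy, xx = np.mgrid[0:300, 0:300]
        rr = np.hypot(xx - center[0], yy - center[1])
        values = np.where(rr > 90.0, 30.0, 60.0)  # outer half 30, inner half 60
        g = gli.GLIImage(values.astype(float), field_size=1.0, source_pixel_size=1.0)
        travs = profiles.build_traverses(cp, spacing=20.0, grid_step=1.5)
        p = profiles.extract_profile(g, travs[len(travs) // 2], D=201)
        crossing = p.depths[np.argmin(np.abs(p.values - 45.0))]
        assert crossing == pytest.approx(50.0, abs=2.0)

    def test_traverse_outside_domain_rejected(self):
        g = gli.GLIImage(np.full((4, 4), 10.0), field_size=4.0, source_pixel_size=1.0)
        trav = np.array([[2.0, 2.0], [2.0, 400.0]])
        with pytest.raises(ValueError, match="arc position 7"):
            profiles.extract_profile(g, trav, arc_position=7)


def brute_force_features(values, depths, rectify=True):
    """Independent weighted-moment calculator (plain Python loops)."""
    def block(vals):
        total = sum(vals)
        if total <= 0:
            return [0.0] * 5
        mean = total / len(vals)
        if max(vals) - min(vals) <= 1e-12 * max(max(abs(v) for v in vals), 1.0):
            cog = sum(v * d for v, d in zip(vals, depths)) / total
            return [mean, cog, 0.0, 0.0, 0.0]
        cog = sum(v * d for v, d in zip(vals, depths)) / total
        var = sum(v * (d - cog) ** 2 for v, d in zip(vals, depths)) / total
        sd = var**0.5
        skew = sum(v * (d - cog) ** 3 for v, d in zip(vals, depths)) / total / sd**3
        kurt = sum(v * (d - cog) ** 4 for v, d in zip(vals, depths)) / total / sd**4
        return [mean, cog, sd, skew, kurt]

    deriv = np.gradient(np.asarray(values, dtype=float), np.asarray(depths))
    if rectify:
        deriv = np.abs(deriv)
    return np.array(block(list(values)) + block(list(deriv)))


class TestFeatureVector:
    def test_constant_profile(self):
        d = np.linspace(0, 100, 101)
        p = profiles.Profile(depths=d, values=np.full(101, 30.0))
        fv = profiles.feature_vector(p)
        np.testing.assert_allclose(fv, [30, 50, 0, 0, 0, 0, 0, 0, 0, 0], atol=1e-9)

    def test_symmetric_profile_has_central_cog(self):
        d = np.linspace(0, 100, 101)
        v = 10 + np.exp(-((d - 50) ** 2) / 50.0)
        fv = profiles.feature_vector(profiles.Profile(depths=d, values=v))
        assert fv[1] == pytest.approx(50.0, abs=1e-9)
        assert fv[3] == pytest.approx(0.0, abs=1e-9)  # skewness

    def test_linear_ramp_matches_closed_form(self):
        """v(d) = d: mean 50, cog → 200/3 in the continuum; the discrete
        D = 101 value is within 0.5 of the integral limit."""
        d = np.linspace(0, 100, 101)
        fv = profiles.feature_vector(profiles.Profile(depths=d, values=d.copy()))
        assert fv[0] == pytest.approx(50.0)
        assert fv[1] == pytest.approx(200 / 3, abs=0.5)

    def test_matches_brute_force_on_random_profiles(self, rng):
        """Vectorized moments equal an independent loop-based calculator to
        10⁻¹⁰ relative error on 100 random profiles."""
        d = np.linspace(0, 100, 101)
        for _ in range(100):
            v = rng.random(101) * 60
            p = profiles.Profile(depths=d, values=v)
            fast = profiles.feature_vector(p)
            slow = brute_force_features(v, d)
            np.testing.assert_allclose(fast, slow, rtol=1e-10, atol=1e-10)

    def test_all_zero_profile_is_all_zero_features(self):
        d = np.linspace(0, 100, 11)
        p = profiles.Profile(depths=d, values=np.zeros(11))
        np.testing.assert_array_equal(profiles.feature_vector(p), np.zeros(10))

    def test_value_weighting_mode(self, rng):
        d = np.linspace(0, 100, 101)
        v = rng.random(101) * 50 + 5
        fv = profiles.feature_vector(
            profiles.Profile(depths=d, values=v), weighting="value"
        )
        assert fv[2] == pytest.approx(v.std())

    def test_feature_thickness_invariance(self):
        """Feature vectors of the same pattern at thickness t and 2t agree
        within 1% per feature."""
        def section_features(thickness):
            rows = np.linspace(0, 1, thickness)
            pattern = 15 + 25 * np.exp(-((rows - 0.5) ** 2) / 0.02)
            g = gli.GLIImage(
                np.tile(pattern[:, None], (1, 20)),
                field_size=1.0,
                source_pixel_size=1.0,
            )
            trav = np.column_stack(
                [np.full(400, 10.0), np.linspace(0.5, thickness - 0.5, 400)]
            )
            return profiles.feature_vector(profiles.extract_profile(g, trav, D=101))

        f1 = section_features(100)
        f2 = section_features(200)
        scale = np.maximum(np.abs(f1), 1e-6)
        assert np.all(np.abs(f1 - f2) / scale < 0.01)
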