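"""Catches, opponent statistics, tetra space, and RNL discriminability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camovis.simulate import make_dowel_spectrum
from camovis.spectra import GRID_SIZE
from camovis.vision import (
    CATCH_FLOOR,
    CHROMATIC_CONES,
    TETRA_RADIUS,
    TETRA_VERTICES,
    ConeCatchVector,
    ConeSensitivity,
    achromatic_jnd,
    catch_vector,
    chromatic_jnd,
    classify_jnd,
    dichromat_jnd,
    discriminate,
    greenness,
    luminance,
    quantum_catch,
    receptor_noise,
    tetra_coords,
)

from .conftest import catches, flat_spectrum

positive = st.floats(0.01, 100.0, allow_nan=False)


def spike_cone(index: int = 200) -> ConeSensitivity:
    """Single-point spike: peak 1, trapezoidal area exactly 1."""
    s = np.zeros(GRID_SIZE)
    s[index] = 1.0
    return ConeSensitivity("X", 300.0 + index, s)


class TestQuantumCatch:
    def test_unit_area_identity(self, ideal_viewer):
        q = quantum_catch(flat_spectrum(1.0), spike_cone(), ideal_viewer.illuminant)
        assert q == pytest.approx(1.0)

    def test_zero_reflectance_floors(self, viewer):
        q = quantum_catch(flat_spectrum(0.0), viewer.sensitivities["LW"], viewer.illuminant)
        assert q == CATCH_FLOOR

    def test_linearity_in_reflectance(self, viewer):
        full = quantum_catch(flat_spectrum(1.0), viewer.sensitivities["MW"], viewer.illuminant)
        half = quantum_catch(flat_spectrum(0.5), viewer.sensitivities["MW"], viewer.illuminant)
        assert half == pytest.approx(full / 2)


class TestCatchVector:
    def test_flat_spectrum_all_positive(self, viewer):
        c = catch_vector(flat_spectrum(0.5), viewer)
        assert min(c.q_uv, c.q_sw, c.q_mw, c.q_lw, c.q_dd) > 0

    def test_identical_spectra_identical_vectors(self, viewer):
        a = catch_vector(flat_spectrum(0.42), viewer)
        b = catch_vector(flat_spectrum(0.42), viewer)
        assert (a.q_uv, a.q_sw, a.q_mw, a.q_lw, a.q_dd) == (
            b.q_uv, b.q_sw, b.q_mw, b.q_lw, b.q_dd,
        )

    def test_green_fixture_greener_than_brown(self, viewer):
        green = catch_vector(make_dowel_spectrum("green"), viewer)
        brown = catch_vector(make_dowel_spectrum("brown"), viewer)
        assert green.q_mw / green.q_lw > brown.q_mw / brown.q_lw

    def test_nonpositive_catch_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            ConeCatchVector(0.0, 1.0, 1.0, 1.0, 1.0)


class TestGreennessLuminance:
    def test_equal_catches_half(self):
        assert greenness(catches(1, 1, 2, 2)) == 0.5

    def test_three_to_one(self):
        assert greenness(catches(1, 1, 3, 1)) == 0.75

    @given(positive, positive, positive)
    def test_greenness_monotone_in_mw(self, q_mw, dq, q_lw):
        low = greenness(catches(1, 1, q_mw, q_lw))
        high = greenness(catches(1, 1, q_mw + dq, q_lw))
        assert high > low

    def test_luminance_is_projection(self):
        assert luminance(catches(1, 1, 1, 1, q_dd=0.42)) == 0.42

    def test_doubling_spectrum_doubles_luminance(self, viewer):
        lo = luminance(catch_vector(flat_spectrum(0.3), viewer))
        hi = luminance(catch_vector(flat_spectrum(0.6), viewer))
        assert hi == pytest.approx(2 * lo)

    def test_white_brighter_than_black(self, viewer):
        assert luminance(catch_vector(flat_spectrum(0.8), viewer)) > luminance(
            catch_vector(flat_spectrum(0.05), viewer)
        )


class TestTetraCoords:
    def test_equal_catches_at_origin(self):
        p = tetra_coords(catches(1, 1, 1, 1))
        np.testing.assert_allclose(p.as_array(), 0.0, atol=1e-15)

    def test_pure_uv_at_vertex(self):
        p = tetra_coords(catches(1e6, 1e-9, 1e-9, 1e-9))
        np.testing.assert_allclose(p.as_array(), TETRA_VERTICES["UV"], atol=1e-9)
        assert np.linalg.norm(TETRA_VERTICES["UV"]) == pytest.approx(TETRA_RADIUS)

    def test_vertices_regular_and_centred(self):
        vs = np.stack(list(TETRA_VERTICES.values()))
        np.testing.assert_allclose(vs.sum(axis=0), 0.0, atol=1e-15)
        norms = np.linalg.norm(vs, axis=1)
        np.testing.assert_allclose(norms, TETRA_RADIUS)
        dists = [np.linalg.norm(vs[i] - vs[j]) for i in range(4) for j in range(i + 1, 4)]
        np.testing.assert_allclose(dists, dists[0])

    @settings(max_examples=200)
    @given(positive, positive, positive, positive)
    def test_simplex_norm_bounded(self, a, b, c, d):
        p = tetra_coords(catches(a, b, c, d))
        assert np.linalg.norm(p.as_array()) <= TETRA_RADIUS + 1e-12

    def test_affine_on_midpoints(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ra = rng.dirichlet(np.ones(4))
            rb = rng.dirichlet(np.ones(4))
            pa = tetra_coords(catches(*ra)).as_array()
            pb = tetra_coords(catches(*rb)).as_array()
            pm = tetra_coords(catches(*((ra + rb) / 2))).as_array()
            np.testing.assert_allclose(pm, (pa + pb) / 2, atol=1e-12)


def oracle_rnl(df: np.ndarray, e: np.ndarray) -> float:
    """Loop-built general RNL quadratic form, independent of the implementation."""
    n = len(df)
    num = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            prod = 1.0
            for k in range(n):
                if k not in (i, j):
                    prod *= e[k]
            num += prod**2 * (df[i] - df[j]) ** 2
    den = 0.0
    for i in range(n):
        prod = 1.0
        for k in range(n):
            if k != i:
                prod *= e[k]
        den += prod**2
    return np.sqrt(num / den)


class TestChromaticJnd:
    def test_identical_is_zero(self, viewer):
        a = catches(1, 2, 3, 4)
        assert chromatic_jnd(a, a, viewer) == 0.0

    def test_uniform_scaling_is_zero(self, viewer):
        a = catches(1, 2, 3, 4)
        b = catches(2.5, 5, 7.5, 10)
        assert chromatic_jnd(a, b, viewer) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric(self, viewer):
        a, b = catches(1, 2, 3, 4), catches(4, 3, 2, 1)
        assert chromatic_jnd(a, b, viewer) == pytest.approx(chromatic_jnd(b, a, viewer))

    def test_matches_loop_oracle(self, viewer):
        rng = np.random.default_rng(11)
        e = np.array([receptor_noise(viewer)[c] for c in CHROMATIC_CONES])
        for _ in range(200):
            qa, qb = rng.uniform(0.01, 10, 4), rng.uniform(0.01, 10, 4)
            a, b = catches(*qa), catches(*qb)
            expected = oracle_rnl(np.log(qa / qb), e)
            assert chromatic_jnd(a, b, viewer) == pytest.approx(expected, rel=1e-10)

    def test_deterministic(self, viewer):
        a, b = catches(1, 2, 3, 4), catches(4, 1, 2, 3)
        assert chromatic_jnd(a, b, viewer) == chromatic_jnd(a, b, viewer)


class TestDichromat:
    def test_closed_form(self):
        qa, qb, e = (2.0, 1.0), (1.0, 1.0), (0.05, 0.1)
        expected = abs(np.log(2.0)) / np.sqrt(0.05**2 + 0.1**2)
        assert dichromat_jnd(qa, qb, e) == pytest.approx(expected, rel=1e-12)

    def test_matches_two_receptor_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            qa, qb = rng.uniform(0.1, 10, 2), rng.uniform(0.1, 10, 2)
            e = rng.uniform(0.01, 0.2, 2)
            expected = oracle_rnl(np.log(qa / qb), e)
            assert dichromat_jnd(tuple(qa), tuple(qb), tuple(e)) == pytest.approx(
                expected, rel=1e-10
            )


class TestAchromaticJnd:
    def test_equal_dd_zero(self, viewer):
        a = catches(1, 1, 1, 1, q_dd=2.0)
        assert achromatic_jnd(a, a, viewer) == 0.0

    def test_exp_weber_ratio_is_one(self, viewer):
        a = catches(1, 1, 1, 1, q_dd=np.exp(0.05))
        b = catches(1, 1, 1, 1, q_dd=1.0)
        assert viewer.weber_dd == 0.05
        assert achromatic_jnd(a, b, viewer) == pytest.approx(1.0, rel=1e-12)

    def test_symmetric(self, viewer):
        a = catches(1, 1, 1, 1, q_dd=3.7)
        b = catches(1, 1, 1, 1, q_dd=0.4)
        assert achromatic_jnd(a, b, viewer) == pytest.approx(
            achromatic_jnd(b, a, viewer), rel=1e-12
        )


class TestClassify:
    @pytest.mark.parametrize(
        "jnd,expected",
        [
            (0.5, "indiscriminable"),
            (2.0, "conditional"),
            (7.3, "discriminable"),
            (1.0, "conditional"),
            (3.0, "conditional"),
            (0.999, "indiscriminable"),
            (3.0001, "discriminable"),
        ],
    )
    def test_thresholds(self, jnd, expected):
        assert classify_jnd(jnd) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_jnd(-0.1)


def test_discriminate_bundle(viewer):
    a = catches(1, 2, 3, 4, q_dd=2.0, label="a")
    b = catches(2, 2, 2, 2, q_dd=1.0, label="b")
    res = discriminate(a, b, viewer)
    assert res.id_a == "a" and res.id_b == "b"
    assert set(res.delta_f) == set(CHROMATIC_CONES)
    assert res.class_chromatic == classify_jnd(res.jnd_chromatic)
    assert res.class_achromatic == classify_jnd(res.jnd_achromatic)


def test_jnd_invariant_to_illuminant_scale(viewer):
    """The catch floor aside, scaling the illuminant leaves JND unchanged."""
    from camovis.vision import Illuminant, ViewerModel

    scaled = ViewerModel(
        sensitivities=viewer.sensitivities,
        abundances=dict(viewer.abundances),
        illuminant=Illuminant("scaled", viewer.illuminant.irradiance * 7.0),
    )
    s1, s2 = make_dowel_spectrum("green"), make_dowel_spectrum("brown")
    j1 = chromatic_jnd(catch_vector(s1, viewer), catch_vector(s2, viewer), viewer)
    j2 = chromatic_jnd(catch_vector(s1, scaled), catch_vector(s2, scaled), scaled)
    assert j2 == pytest.approx(j1, rel=1e-12)
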