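"""Receptor-noise visual model: templates, catches, colour space, JNDs."""

import numpy as np
import pytest

from iriscale import (
    CatchVector,
    Spectrum,
    achromatic_jnd,
    builtin_visual_systems,
    chromatic_jnd,
    colour_point,
    d65,
    default_grid,
    derive_abundances,
    forest_shade,
    get_illuminant,
    pairwise_discriminability,
    pigment_sensitivity,
    quantum_catches,
    rnl_distance,
)
from iriscale.synthetic import gen_comimic_groups, gen_gaussian_spectrum
from iriscale.vision import GRID, VisualSystem, summarize_jnds


def rnl_matrix_oracle(delta_f, noise):
    """Generalized noise-weighted distance: Mahalanobis length of delta_f
    projected off the achromatic (1,...,1) direction, noise cov diag(e^2)."""
    df = np.asarray(delta_f, float)
    e2 = np.asarray(noise, float) ** 2
    winv = np.diag(1.0 / e2)
    ones = np.ones_like(df)
    proj = winv - np.outer(winv @ ones, ones @ winv) / (ones @ winv @ ones)
    return float(np.sqrt(df @ proj @ df))


def catches(values, system="test"):
    return CatchVector(np.asarray(values, float), system, von_kries=False)


@pytest.fixture(scope="module")
def systems():
    return builtin_visual_systems()


@pytest.fixture(scope="module")
def illum():
    return d65()


class TestPigmentTemplate:
    def test_unit_peak_at_lambda_max(self):
        for lmax in (355, 390, 416, 470, 555, 607):
            s = pigment_sensitivity(lmax, GRID)
            assert s.max() == pytest.approx(1.0)
            assert abs(GRID[np.argmax(s)] - lmax) <= 2

    def test_positive_everywhere(self):
        s = pigment_sensitivity(470, GRID)
        assert np.all(s > 0)

    def test_halfmax_bandwidth_of_blue_pigment(self):
        s = pigment_sensitivity(470, GRID)
        above = GRID[s >= 0.5]
        width = above.max() - above.min()
        assert 80 <= width <= 120

    def test_lambda_max_domain(self):
        with pytest.raises(ValueError):
            pigment_sensitivity(290)
        with pytest.raises(ValueError):
            pigment_sensitivity(700)


class TestBuiltinSystems:
    def test_catalogue_has_five_systems(self, systems):
        assert set(systems) == {"avian_vs", "heli_i", "heli_ii", "heli_iii",
                                "heli_iv"}

    def test_avian_parameters(self, systems):
        vs = systems["avian_vs"]
        assert vs.lambda_max == (416, 478, 542, 607)
        assert vs.weber_fraction == 0.06
        assert vs.relative_abundances == (0.25, 0.5, 1, 1)
        assert vs.n_receptors == 4

    def test_heliconius_abundances(self, systems):
        assert systems["heli_i"].relative_abundances == (0.09, 0.07, 0.17, 1)
        assert systems["heli_ii"].relative_abundances == (0.13, 0.2, 1)
        assert systems["heli_iii"].relative_abundances == (0.09, 0.13, 0.2, 1)
        assert systems["heli_iv"].relative_abundances == (0.07, 0.26, 1)

    def test_weber_fractions(self, systems):
        for name, vs in systems.items():
            assert vs.weber_fraction == (0.06 if name == "avian_vs" else 0.05)

    def test_noise_of_reference_receptor_is_weber(self, systems):
        for vs in systems.values():
            i = vs.labels.index("L")
            assert vs.noise()[i] == pytest.approx(vs.weber_fraction)

    def test_reference_abundance_must_be_one(self):
        with pytest.raises(ValueError):
            VisualSystem("bad", ("UV", "B", "L"), (355.0, 470.0, 555.0),
                         0.05, (0.1, 0.2, 0.5))


class TestDeriveAbundances:
    def test_single_type_normalizes(self):
        eta = derive_abundances([1.0], [{"L": 0.5, "B": 0.5}])
        assert eta == {"L": 1.0, "B": 1.0}

    def test_two_pure_types(self):
        eta = derive_abundances([0.5, 0.5], [{"L": 1.0}, {"B": 1.0}])
        assert eta == {"L": 1.0, "B": 1.0}

    def test_hand_computed_mixture(self):
        eta = derive_abundances([0.6, 0.4],
                                [{"L": 0.5, "B": 0.5}, {"L": 1.0}])
        assert eta["L"] == 1.0
        assert eta["B"] == pytest.approx(0.3 / 0.7, abs=1e-4)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            derive_abundances([1.0], [{"B": 1.0}])


class TestQuantumCatches:
    def test_von_kries_white_gives_unit_catches(self, systems):
        white = Spectrum(default_grid(), np.full(GRID.size, 100.0))
        for vs in systems.values():
            for ill in (d65(), forest_shade()):
                q = quantum_catches(white, vs, ill, von_kries=True)
                assert np.allclose(q.values, 1.0, atol=1e-12)

    def test_linearity_without_von_kries(self, systems, illum):
        spec = gen_gaussian_spectrum(450, 90, 15.0)
        double = spec.with_values(2.0 * spec.reflectance_pct)
        q1 = quantum_catches(spec, systems["heli_i"], illum, von_kries=False)
        q2 = quantum_catches(double, systems["heli_i"], illum, von_kries=False)
        assert np.allclose(q2.values, 2.0 * q1.values, rtol=1e-12)

    def test_narrow_blue_band_dominates_b_receptor(self, systems, illum):
        spec = gen_gaussian_spectrum(470, 10, 20.0)
        for name in ("heli_i", "heli_ii", "heli_iii", "heli_iv"):
            vs = systems[name]
            q = quantum_catches(spec, vs, illum, von_kries=True)
            assert vs.labels[int(np.argmax(q.values))] == "B"

    def test_degenerate_stimulus_rejected(self, systems, illum):
        grid = default_grid()
        with pytest.raises(ValueError):
            quantum_catches(Spectrum(grid, np.zeros(grid.size)),
                            systems["heli_i"], illum)


class TestColourPoint:
    def test_equal_catches_at_centroid(self):
        pt = colour_point(catches([1, 1, 1, 1]))
        assert np.allclose(pt.coordinates, 0.0, atol=1e-12)
        assert np.allclose(pt.relative_catches, 0.25)

    def test_scale_invariance(self):
        a = colour_point(catches([7, 7, 7, 7]))
        b = colour_point(catches([1, 1, 1, 1]))
        assert np.allclose(a.coordinates, b.coordinates)

    def test_single_receptor_hits_vertex_at_0_75(self):
        for n in (3, 4):
            for k in range(n):
                v = np.full(n, 1e-9)
                v[k] = 1.0
                pt = colour_point(catches(v))
                assert np.linalg.norm(pt.coordinates) == pytest.approx(
                    0.75, abs=1e-6)

    def test_simplex_membership(self, systems, illum):
        spec = gen_gaussian_spectrum(400, 80, 25.0)
        q = quantum_catches(spec, systems["avian_vs"], illum)
        pt = colour_point(q)
        assert np.all(pt.relative_catches >= 0)
        assert pt.relative_catches.sum() == pytest.approx(1.0)
        assert np.linalg.norm(pt.coordinates) <= 0.75 + 1e-9


class TestRnlDistance:
    def test_dichromat_closed_form_on_random_pairs(self):
        rng = np.random.default_rng(99)
        e = np.array([0.1, 0.05])
        worst = 0.0
        for _ in range(1000):
            qa, qb = rng.uniform(0.05, 5.0, (2, 2))
            df = np.log(qa / qb)
            got = rnl_distance(df, e)
            want = abs(df[0] - df[1]) / np.hypot(*e)
            worst = max(worst, abs(got - want))
        assert worst < 1e-10

    @pytest.mark.parametrize("n", [3, 4])
    def test_closed_forms_match_matrix_oracle(self, n, systems):
        rng = np.random.default_rng(7)
        vs = systems["heli_ii"] if n == 3 else systems["heli_i"]
        e = vs.noise()
        for _ in range(500):
            df = rng.normal(0, 1, n)
            assert rnl_distance(df, e) == pytest.approx(
                rnl_matrix_oracle(df, e), abs=1e-10)

    def test_achromatic_direction_is_invisible(self, systems):
        # a pure intensity change (equal df on all receptors) costs 0 JND
        for vs in systems.values():
            df = np.full(vs.n_receptors, 0.37)
            assert rnl_distance(df, vs.noise()) == pytest.approx(0.0,
                                                                 abs=1e-12)


class TestJnds:
    def test_identical_stimuli_are_indiscriminable(self, systems):
        q = catches([1.0, 2.0, 0.5, 1.5], "heli_i")
        vs = systems["heli_i"]
        assert chromatic_jnd(q, q, vs) == 0.0
        assert achromatic_jnd(q, q, vs) == 0.0

    def test_symmetry(self, systems):
        vs = systems["heli_iii"]
        a = catches([1.0, 2.0, 0.5, 1.5], vs.name)
        b = catches([1.2, 1.8, 0.7, 1.1], vs.name)
        assert chromatic_jnd(a, b, vs) == pytest.approx(
            chromatic_jnd(b, a, vs), rel=1e-12)
        assert achromatic_jnd(a, b, vs) == pytest.approx(
            achromatic_jnd(b, a, vs), rel=1e-12)

    def test_chromatic_intensity_invariance(self, systems):
        vs = systems["avian_vs"]
        a = catches([1.0, 2.0, 0.5, 1.5], vs.name)
        b = catches([1.2, 1.8, 0.7, 1.1], vs.name)
        b_scaled = catches(3.7 * b.values, vs.name)
        assert chromatic_jnd(a, b, vs) == pytest.approx(
            chromatic_jnd(a, b_scaled, vs), rel=1e-12)

    def test_one_weber_step_is_one_achromatic_jnd(self, systems):
        vs = systems["heli_i"]
        a = catches([1, 1, 1, np.exp(0.05)], vs.name)
        b = catches([1, 1, 1, 1.0], vs.name)
        assert achromatic_jnd(a, b, vs) == pytest.approx(1.0, rel=1e-12)

    def test_achromatic_ratio_invariance(self, systems):
        vs = systems["heli_i"]
        a = catches([1, 1, 1, 2.0], vs.name)
        b = catches([1, 1, 1, 1.0], vs.name)
        a2 = catches([1, 1, 1, 4.0], vs.name)
        b2 = catches([1, 1, 1, 2.0], vs.name)
        assert achromatic_jnd(a, b, vs) == pytest.approx(
            achromatic_jnd(a2, b2, vs), rel=1e-12)

    def test_larger_weber_fraction_gives_smaller_jnd(self):
        base = dict(labels=("UV1", "B", "L"), lambda_max=(355.0, 470.0, 555.0),
                    relative_abundances=(0.07, 0.26, 1.0))
        lo = VisualSystem("lo", weber_fraction=0.05, **base)
        hi = VisualSystem("hi", weber_fraction=0.12, **base)
        a = catches([1.0, 2.0, 0.5])
        b = catches([1.2, 1.8, 0.7])
        assert chromatic_jnd(a, b, hi) < chromatic_jnd(a, b, lo)
        assert achromatic_jnd(a, b, hi) < achromatic_jnd(a, b, lo)

    def test_receptor_count_mismatch_rejected(self, systems):
        with pytest.raises(ValueError):
            chromatic_jnd(catches([1, 2, 3]), catches([1, 2, 3, 4]),
                          systems["heli_i"])


class TestPairwise:
    def test_four_by_four_gives_sixteen_pairs(self, systems, illum):
        ga, gb = gen_comimic_groups(seed=5)
        res = pairwise_discriminability(ga, gb, systems["heli_i"], illum)
        assert len(res) == 16

    def test_identical_singletons_give_zero(self, systems, illum):
        spec = gen_gaussian_spectrum(450, 90, 15.0)
        res = pairwise_discriminability([spec], [spec], systems["heli_ii"],
                                        illum)
        assert len(res) == 1
        assert res[0].chromatic_jnd == pytest.approx(0.0, abs=1e-12)
        assert res[0].achromatic_jnd == pytest.approx(0.0, abs=1e-12)

    def test_group_vs_itself_has_zero_diagonal(self, systems, illum):
        ga, _ = gen_comimic_groups(seed=5)
        res = pairwise_discriminability(ga, ga, systems["heli_i"], illum)
        diag = [r for r in res if r.pair[0] == r.pair[1]]
        assert len(diag) == 4
        assert all(r.chromatic_jnd == pytest.approx(0, abs=1e-12)
                   for r in diag)

    def test_empty_group_rejected(self, systems, illum):
        with pytest.raises(ValueError):
            pairwise_discriminability([], [gen_gaussian_spectrum(450, 90, 15)],
                                      systems["heli_i"], illum)

    def test_summary_quartiles_ordered(self, systems, illum):
        ga, gb = gen_comimic_groups(seed=5)
        res = pairwise_discriminability(ga, gb, systems["avian_vs"], illum)
        summ = summarize_jnds(res)
        c = summ["chromatic"]
        assert c["q1"] <= c["median"] <= c["q3"]
        assert summ["n_pairs"] == 16


class TestIlluminants:
    def test_catalogue_and_unknown_name(self):
        assert get_illuminant("D65").name == "D65"
        assert get_illuminant("forestshade").name == "forestshade"
        with pytest.raises(KeyError):
            get_illuminant("moonlight")

    def test_forest_shade_is_uv_poor_and_green_shifted(self):
        sun = d65().irradiance
        shade = forest_shade().irradiance
        ratio = shade / np.maximum(sun, 1e-9)
        uv = ratio[(GRID >= 300) & (GRID <= 400)].mean()
        green = ratio[(GRID >= 520) & (GRID <= 580)].mean()
        assert green > 3 * uv
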