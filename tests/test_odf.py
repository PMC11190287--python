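"""ODF kernel density, Texture Index, pole figures and pfJ."""

import numpy as np
import pytest

from biotex.odf import (
    ODFModel,
    build_odf,
    fibonacci_sphere,
    kappa_from_halfwidth,
    kernel_constant,
    pfj,
    pole_density,
    texture_index,
    texture_index_mc,
    _A_AXIS,
    _C_AXIS,
)
from biotex.orientation import (
    Orientation,
    qmul,
    random_uniform_orientations,
)


def rotate_all(ori, axis, deg):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    h = np.radians(deg) / 2.0
    q = np.concatenate([[np.cos(h)], np.sin(h) * axis])
    return Orientation(qmul(q[None, :], ori.quat))


class TestKernel:
    def test_halfwidth_is_hwhm(self):
        """psi falls to half its peak exactly at the halfwidth angle."""
        for hw in (4.0, 10.0, 25.0):
            kappa = kappa_from_halfwidth(hw)
            ratio = np.cos(np.radians(hw) / 2.0) ** (2 * kappa)
            assert ratio == pytest.approx(0.5, rel=1e-12)

    def test_kappa_for_4_degrees(self):
        expected = np.log(0.5) / (2 * np.log(np.cos(np.radians(2.0))))
        assert kappa_from_halfwidth(4.0) == pytest.approx(expected)

    def test_halfwidth_domain(self):
        for bad in (0.0, -1.0, 90.0):
            with pytest.raises(ValueError):
                kappa_from_halfwidth(bad)

    def test_kernel_constant_normalizes_on_so3(self):
        """C(kappa) makes psi integrate to 1 against the Haar angle
        density (2/pi) sin^2(w/2) — checked by direct 1D quadrature."""
        from scipy.integrate import quad

        for hw in (4.0, 15.0):
            kappa = kappa_from_halfwidth(hw)
            C = kernel_constant(kappa)
            val, _ = quad(
                lambda w: C * np.cos(w / 2) ** (2 * kappa)
                * (2 / np.pi) * np.sin(w / 2) ** 2, 0, np.pi)
            assert val == pytest.approx(1.0, rel=1e-8)


class TestODFModel:
    def test_empty_input_rejected(self, hex_sym):
        with pytest.raises(Exception):
            build_odf(Orientation(np.zeros((0, 4))), hex_sym)

    def test_unit_mass_by_quadrature(self, hex_sym):
        """Quadrature mass within 0.5% of 1 for assorted inputs."""
        for seed, n in ((1, 1), (2, 10), (3, 400)):
            odf = build_odf(random_uniform_orientations(n, seed), hex_sym)
            assert odf.mass() == pytest.approx(1.0, abs=5e-3)

    def test_peak_value_matches_normalization_constant(self, hex_sym):
        """A single-component ODF evaluated at its center equals the
        constant that gives the symmetrized kernel unit mass (the SO(3)
        kernel constant divided by the group order for a sharp kernel)."""
        center = random_uniform_orientations(1, 4)
        odf = build_odf(center, hex_sym, halfwidth=4.0)
        peak = odf.evaluate(center.quat)[0]
        expected = kernel_constant(odf.kappa) / hex_sym.order
        assert peak == pytest.approx(expected, rel=1e-6)
        assert odf.mass() == pytest.approx(1.0, abs=5e-3)

    def test_nonnegative_everywhere(self, hex_sym):
        odf = build_odf(random_uniform_orientations(20, 5), hex_sym)
        sample = random_uniform_orientations(2000, 6)
        assert np.all(odf.evaluate(sample.quat) >= 0.0)


class TestTextureIndex:
    def test_uniform_odf_gives_one(self, hex_sym):
        odf = ODFModel(Orientation.identity(), np.array([0.0]), 4.0,
                       hex_sym, uniform_fraction=1.0)
        assert texture_index(odf) == pytest.approx(1.0, abs=1e-9)

    def test_single_component_against_mc_oracle(self, hex_sym):
        """Quadrature TI of one 4-degree component vs the Monte-Carlo
        integral of psi^2 (tolerance covers the MC sampling error of a
        sharp single kernel at this sample size)."""
        odf = build_odf(random_uniform_orientations(1, 9), hex_sym, 4.0)
        ti_q = texture_index(odf)
        ti_mc = texture_index_mc(odf, n_samples=10**6, seed=5)
        assert ti_q == pytest.approx(ti_mc, rel=0.15)
        # and the grid-free closed-form series route agrees tightly
        assert ti_q == pytest.approx(texture_index(odf, method="series"),
                                     rel=0.005)

    def test_distant_half_half_mixture_halves_ti(self, hex_sym):
        """Two sharp components far apart in the fundamental zone at
        weights 1/2 each give half the single-component TI."""
        single = build_odf(Orientation.identity(), hex_sym, 4.0)
        q2 = Orientation.from_euler([0.0, 45.0, 30.0])
        two = ODFModel(
            Orientation(np.vstack([single.orientations.quat, q2.quat])),
            np.array([0.5, 0.5]), 4.0, hex_sym)
        assert texture_index(two) == pytest.approx(
            0.5 * texture_index(single), rel=0.02)

    def test_quadrature_matches_series_on_mixtures(self, hex_sym):
        rng = np.random.default_rng(8)
        for seed in range(4):
            n = int(rng.integers(5, 40))
            w = rng.dirichlet(np.ones(n))
            odf = ODFModel(random_uniform_orientations(n, seed), w, 4.0,
                           hex_sym)
            assert texture_index(odf) == pytest.approx(
                texture_index(odf, method="series"), rel=0.02)

    def test_global_rotation_invariance(self, hex_sym):
        ori = random_uniform_orientations(300, 15)
        ti0 = texture_index(build_odf(ori, hex_sym))
        rot = rotate_all(ori, [1.0, 2.0, 0.5], 37.0)
        ti1 = texture_index(build_odf(rot, hex_sym))
        assert abs(ti1 - ti0) / ti0 < 0.01

    def test_ti_decreases_with_halfwidth(self, hex_sym):
        ori = random_uniform_orientations(100, 16)
        tis = [texture_index(build_odf(ori, hex_sym, hw))
               for hw in (4.0, 10.0, 20.0)]
        assert tis[0] > tis[1] > tis[2]

    def test_ti_at_least_one(self, hex_sym):
        """Cauchy-Schwarz: TI >= 1 (up to quadrature slack) always."""
        for seed in range(3):
            odf = build_odf(random_uniform_orientations(500, seed), hex_sym)
            assert texture_index(odf) >= 1.0 - 5e-3


class TestPoleDensity:
    def test_uniform_mud_near_one(self, hex_sym):
        ori = random_uniform_orientations(2 * 10**4, 19)
        pd = pole_density(ori, _A_AXIS, sym=hex_sym)
        assert pd.mud.mean() == pytest.approx(1.0, abs=5e-3)
        assert np.abs(pd.mud - 1.0).mean() < 0.1

    def test_total_mass_is_one(self, hex_sym):
        ori = random_uniform_orientations(200, 23)
        pd = pole_density(ori, _C_AXIS, sym=hex_sym)
        assert pd.mud.mean() == pytest.approx(1.0, abs=5e-3)

    def test_identity_peaks_at_specimen_z(self, hex_sym):
        pd = pole_density(Orientation.identity(), _C_AXIS, sym=hex_sym)
        peak = pd.nodes[np.argmax(pd.mud)]
        assert abs(peak[2]) > 0.999  # c-axis of identity maps to +-Z
        assert pd.max_mud > 100.0

    def test_antipodal_symmetry(self, hex_sym):
        """MUD is antipodally symmetric by construction: evaluating a
        single orientation's density, +z and -z nodes match."""
        pd = pole_density(Orientation.identity(), _C_AXIS, sym=hex_sym)
        top = pd.mud[pd.nodes[:, 2] > 0.9999]
        bottom = pd.mud[pd.nodes[:, 2] < -0.9999]
        if top.size and bottom.size:
            assert top.max() == pytest.approx(bottom.max(), rel=0.05)

    def test_upper_hemisphere_export(self, hex_sym):
        pd = pole_density(random_uniform_orientations(50, 29), _C_AXIS,
                          sym=hex_sym)
        az, polar, mud = pd.upper_hemisphere()
        assert np.all((polar >= 0) & (polar <= 90.0 + 1e-9))
        assert az.shape == mud.shape


class TestPfj:
    def test_uniform_gives_one(self, hex_sym):
        ori = random_uniform_orientations(2 * 10**4, 31)
        assert pfj(pole_density(ori, _A_AXIS, sym=hex_sym)) == pytest.approx(
            1.0, abs=0.05)

    def test_at_least_one(self, hex_sym):
        for seed in (1, 2):
            ori = random_uniform_orientations(300, seed)
            for fam in (_C_AXIS, _A_AXIS):
                assert pfj(pole_density(ori, fam, sym=hex_sym)) >= 1 - 5e-3

    def test_delta_concentration_matches_mc_oracle(self, hex_sym):
        """pfJ of a single orientation equals the Monte-Carlo surface
        integral of the squared spherical kernel density."""
        ori = Orientation.identity()
        pd = pole_density(ori, _C_AXIS, sym=hex_sym, grid_n=32768)
        val = pfj(pd)
        # MC oracle: mean of MUD^2 over uniform random sphere points
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((2 * 10**5, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        kappa = kappa_from_halfwidth(4.0)
        dirs = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
        cos_t = pts @ dirs.T
        dens = ((kappa + 1.0) * ((1.0 + cos_t) / 2.0) ** kappa).mean(axis=1)
        mc = float(np.mean(dens**2))
        assert val == pytest.approx(mc, rel=0.05)

    def test_sharper_textures_rank_higher(self, hex_sym):
        """Smaller c-axis dispersion must give larger pfJ_c, TI, max MUD."""
        from biotex.synthetic import TextureRecipe, generate_map
        from biotex.odf import summarize_texture

        stats = []
        for disp in (14.0, 7.0, 3.0):
            recipe = TextureRecipe(c_dispersion=disp,
                                   a_rotation_model=("dispersed", disp),
                                   patch_noise=2.0, unindexed_fraction=0.2)
            emap, _ = generate_map(recipe, 40, 40, seed=77)
            stats.append(summarize_texture(emap.indexed_orientations(),
                                           hex_sym, grid_n=4096))
        tis = [s.ti for s in stats]
        pjc = [s.pfj_c for s in stats]
        muds = [s.max_mud for s in stats]
        assert tis[0] < tis[1] < tis[2]
        assert pjc[0] < pjc[1] < pjc[2]
        assert muds[0] < muds[1] < muds[2]


def test_fibonacci_sphere_is_unit_and_balanced():
    pts = fibonacci_sphere(4096)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
    assert np.abs(pts.mean(axis=0)).max() < 0.01
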