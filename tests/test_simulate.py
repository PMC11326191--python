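"""Forward-model physics: isotropy of puncta, directionality of edges,
volume-conserving morphs, and population sampling."""

import dataclasses
import math

import numpy as np
import pytest

from qdf import simulate as sim
from qdf.qdf_core import edge_image


def noise_free(scene, **extra):
    return dataclasses.replace(scene, read_noise_sigma=0.0, shot_noise=False,
                               phase_noise_sigma=0.0, **extra)


def puncta_only_scene(amplitude=4000.0, seed=0):
    field = 64
    p = sim.Punctum(position_um=(16.0, 16.0), scatter_amplitude=amplitude)
    return noise_free(
        sim.SceneSpec(field_size=(field, field), puncta=(p,), seed=seed),
        background_poly_coeffs=((0.0,),),
    )


class TestRenderQuadrants:
    def test_puncta_identical_across_quadrants(self, optics):
        """Isotropy: with noise off, a punctum renders bit-identically in TL/TR/BL/BR."""
        q = sim.render_quadrants(puncta_only_scene(), optics)
        np.testing.assert_array_equal(q.tl, q.tr)
        np.testing.assert_array_equal(q.tl, q.bl)
        np.testing.assert_array_equal(q.tl, q.br)

    def test_edge_image_exactly_zero_on_puncta(self, optics):
        """The anti-symmetric combination nulls isotropic scatter exactly."""
        q = sim.render_quadrants(puncta_only_scene(), optics)
        assert edge_image(q).max() == 0.0

    def test_punctum_flux_splits_into_quarters(self, optics):
        """A punctum of amplitude A integrates to A/4 counts in each quadrant."""
        amplitude = 4000.0
        q = sim.render_quadrants(puncta_only_scene(amplitude), optics)
        total = q.tl.sum() / q.meta.container_divisor
        assert total == pytest.approx(amplitude / 4.0, rel=0.02)

    def test_edge_arc_opposes_illumination(self, optics):
        """Top-left illumination lights the bottom-right arc of a bead, and the
        TL-lit and BR-lit pixel sets of a convex body are disjoint."""
        bead = noise_free(sim.bead_phantom(imperfection=False),
                          background_poly_coeffs=((0.0,),))
        q = sim.render_quadrants(bead, optics)
        thr = 0.05 * q.tl.max()
        lit_tl = q.tl > thr
        lit_br = q.br > thr
        assert not np.any(lit_tl & lit_br)
        # centre of mass of the TL-lit signal sits below-right of the bead centre
        yy, xx = np.mgrid[0 : q.shape[0], 0 : q.shape[1]]
        cx = (xx * q.tl).sum() / q.tl.sum() - q.shape[1] / 2
        cy = (yy * q.tl).sum() / q.tl.sum() - q.shape[0] / 2
        assert cx > 1 and cy > 1

    def test_deterministic_under_seed(self, optics):
        scene = sim.adherent_cell(seed=5, field_size=64, radius_um=8.0, n_puncta=20)
        a = sim.render_quadrants(scene, optics)
        b = sim.render_quadrants(scene, optics)
        np.testing.assert_array_equal(a.tl, b.tl)
        np.testing.assert_array_equal(a.br, b.br)
        other = sim.render_quadrants(dataclasses.replace(scene, seed=6), optics)
        assert not np.array_equal(a.tl, other.tl)

    def test_rejects_body_outside_field(self, optics):
        body = sim.BodySpec(center_um=(10.0, 10.0), radius_um=30.0, height_um=3.0)
        scene = sim.SceneSpec(field_size=(32, 32), bodies=(body,))
        with pytest.raises(ValueError, match="field too small"):
            sim.render_quadrants(scene, optics)

    def test_rejects_punctum_outside_field(self, optics):
        p = sim.Punctum(position_um=(100.0, 5.0))
        scene = sim.SceneSpec(field_size=(32, 32), puncta=(p,))
        with pytest.raises(ValueError, match="outside"):
            sim.render_quadrants(scene, optics)


class TestRenderPhaseAndReference:
    def test_uniform_slab_phase(self, optics):
        """h = 1 um, dn = 0.05, lambda = 0.5 um -> interior phase 2*pi*0.1 rad."""
        body = sim.BodySpec(center_um=(16.0, 16.0), radius_um=10.0, height_um=1.0,
                            refractive_contrast=0.05)
        scene = noise_free(sim.SceneSpec(field_size=(64, 64), bodies=(body,)),
                           phase_background_coeffs=((0.0,),))
        phase = sim.render_phase(scene, optics).phase
        assert phase[32, 32] == pytest.approx(2 * math.pi * 0.05 * 1.0 / 0.5, rel=1e-6)

    def test_empty_scene_phase_is_background(self, optics):
        scene = noise_free(sim.SceneSpec(field_size=(32, 32)),
                           phase_background_coeffs=((0.0,),))
        assert np.all(sim.render_phase(scene, optics).phase == 0.0)

    def test_ground_truth_mass_matches_closed_form(self, optics):
        """Pixel-sum ground truth agrees with dn*V/alpha for each body."""
        bodies = (
            sim.BodySpec(center_um=(20.0, 20.0), radius_um=10.0, height_um=2.0),
            sim.BodySpec(center_um=(44.0, 44.0), radius_um=6.0, height_um=1.0),
        )
        scene = noise_free(sim.SceneSpec(field_size=(128, 128), bodies=bodies))
        gt = sim.scene_ground_truth(scene, optics)
        for body, mass in zip(bodies, gt["mass_pg"]):
            expected = body.refractive_contrast * body.volume_um3() * 1e-3 / sim.ALPHA_M3_PER_KG
            assert mass == pytest.approx(expected, rel=0.01)

    def test_reference_noise_free_equals_background(self, optics):
        coeffs = ((20.0, 5.0), (3.0, 0.0))
        scene = noise_free(sim.SceneSpec(field_size=(32, 32)),
                           background_poly_coeffs=coeffs)
        ref = sim.render_reference(scene, optics) / optics.container_scale
        surface = sim._background_surface(coeffs, (32, 32))
        np.testing.assert_allclose(ref, np.rint(surface), atol=0.5)

    def test_reference_subtraction_leaves_zero_mean_noise(self, optics):
        scene = sim.SceneSpec(field_size=(64, 64), seed=3)
        frame = sim.render_reference(scene, optics, "ref_tl") / optics.container_scale
        other = sim.render_reference(dataclasses.replace(scene, seed=4), optics,
                                     "ref_tl") / optics.container_scale
        resid = frame - other
        assert abs(resid.mean()) < 3 * resid.std() / math.sqrt(resid.size)


class TestMorphRoundness:
    def test_identity_at_zero(self):
        scene = sim.adherent_cell(seed=0)
        assert sim.morph_roundness(scene, 0.0) is scene

    @pytest.mark.parametrize("roundness", [0.25, 0.5, 0.75, 1.0])
    def test_volume_conserved(self, roundness):
        scene = sim.adherent_cell(seed=0)
        morphed = sim.morph_roundness(scene, roundness)
        v0 = scene.bodies[0].volume_um3()
        assert morphed.bodies[0].volume_um3() == pytest.approx(v0, rel=1e-3)

    def test_full_roundness_is_hemispherical_cap(self):
        """A 20 um radius, 3 um flat disc rounds to radius (3V/2pi)^(1/3)."""
        scene = sim.adherent_cell(seed=0, radius_um=20.0, height_um=3.0)
        v0 = math.pi * 20.0**2 * 3.0
        expected_radius = (3.0 * v0 / (2.0 * math.pi)) ** (1.0 / 3.0)
        body = sim.morph_roundness(scene, 1.0).bodies[0]
        assert body.radius_um == pytest.approx(expected_radius, rel=1e-9)
        assert body.height_um == pytest.approx(expected_radius, rel=1e-9)
        assert body.roundness == 1.0

    def test_footprint_strictly_decreases(self):
        scene = sim.adherent_cell(seed=0)
        radii = [sim.morph_roundness(scene, r).bodies[0].radius_um
                 for r in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)]
        assert all(a > b for a, b in zip(radii, radii[1:]))

    def test_puncta_conserved_and_interior(self):
        scene = sim.adherent_cell(seed=2, n_puncta=100)
        morphed = sim.morph_roundness(scene, 1.0)
        assert len(morphed.puncta) == len(scene.puncta)
        total = sum(p.scatter_amplitude for p in morphed.puncta)
        assert total == sum(p.scatter_amplitude for p in scene.puncta)
        body = morphed.bodies[0]
        assert all(body.contains(*p.position_um) for p in morphed.puncta)

    def test_rejects_invalid_roundness(self):
        with pytest.raises(ValueError):
            sim.morph_roundness(sim.adherent_cell(seed=0), 1.5)


class TestSamplePopulation:
    def test_reproducible_under_seed(self):
        template = sim.adherent_cell(seed=0)
        a = sim.sample_population(template, 3, (0.1, 1.0), 2.0, seed=42)
        b = sim.sample_population(template, 3, (0.1, 1.0), 2.0, seed=42)
        assert a == b

    def test_zero_rate_gives_punctum_free_cells(self):
        template = sim.adherent_cell(seed=0)
        scenes = sim.sample_population(template, 5, (0.1, 1.0), 0.0, seed=1)
        assert all(len(s.puncta) == 0 for s in scenes)

    def test_rejects_degenerate_inputs(self):
        template = sim.adherent_cell(seed=0)
        with pytest.raises(ValueError):
            sim.sample_population(template, 1, (0.1, 1.0), 2.0, seed=1)
        with pytest.raises(ValueError, match="degenerate"):
            sim.sample_population(template, 5, (1.0, 1.0), 2.0, seed=1)

    def test_puncta_amplitude_tracks_mass(self):
        """Organelle content proportional to mass: ground-truth Pearson R > 0.95."""
        template = sim.adherent_cell(seed=0)
        scenes = sim.sample_population(template, 300, (0.1, 1.0), 2.0, seed=9)
        amplitude = np.array([sum(p.scatter_amplitude for p in s.puncta) for s in scenes])
        mass = np.array([
            s.bodies[0].refractive_contrast * s.bodies[0].volume_um3() * 1e-3 / sim.ALPHA_M3_PER_KG
            for s in scenes
        ])
        assert np.corrcoef(amplitude, mass)[0, 1] > 0.95
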