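"""Phantom scenes, the degradation forward model, and dataset writing."""

import hashlib
from fractions import Fraction

import numpy as np
import pytest
from scipy import ndimage

from anetsr.preprocess import OpticalModel
from anetsr.synthetic_phantom import (
    FilamentScene,
    NoiseModel,
    PhantomConfig,
    centerline_mask,
    curve_length,
    degrade,
    generate_scene,
    make_dataset,
    make_pairs,
    render_truth,
)

QUIET = NoiseModel(gaussian_sigma=0.0, poisson=False, offset=0.0)
# optics with negligible blur at the supersample pitch (delta-like PSF)
DELTA_OPTICS = OpticalModel(lambda_e=10.0, na=1.4, n=1.515)


class TestGenerateScene:
    def test_same_seed_reproduces_scene(self):
        a = generate_scene(4, 8000.0, seed=11)
        b = generate_scene(4, 8000.0, seed=11)
        assert len(a.curves) == len(b.curves)
        for ca, cb in zip(a.curves, b.curves):
            assert np.array_equal(ca, cb)

    def test_empty_scene_renders_zero_and_degrades_to_noise(self):
        scene = generate_scene(0, 8000.0, seed=0)
        truth = render_truth(scene, Fraction(125, 4))
        assert truth.intensity.sum() == 0
        noise = NoiseModel(gaussian_sigma=5.0, poisson=True, offset=100.0)
        obs = degrade(truth, OpticalModel(), noise, Fraction(250), seed=1)
        # pure background: mean ~ offset (Poisson mean preserved)
        assert obs.pixels.mean() == pytest.approx(100.0, rel=0.05)

    def test_curves_stay_inside_field(self):
        scene = generate_scene(6, 4000.0, seed=3)
        for c in scene.curves:
            assert c.min() >= 0 and c.max() <= 4000.0

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_scene(-1, 8000.0)
        with pytest.raises(ValueError):
            generate_scene(2, 0.0)

    def test_component_count_matches_filament_count(self):
        # five parallel, well-separated lines: flood-fill count is exact
        curves = [
            np.column_stack([np.linspace(1000, 7000, 50),
                             np.full(50, 1500.0 + 1200.0 * i)])
            for i in range(5)
        ]
        scene = FilamentScene(curves=curves, field_nm=8000.0)
        truth = render_truth(scene, Fraction(125, 4))
        _, n = ndimage.label(truth.centerline)
        assert n == 5


class TestRenderTruth:
    def test_horizontal_line_mask_is_one_pixel_wide(self):
        pitch = Fraction(125, 4)
        curve = np.column_stack([np.linspace(1000, 7000, 100),
                                 np.full(100, 4000.0)])
        scene = FilamentScene(curves=[curve], field_nm=8000.0)
        truth = render_truth(scene, pitch)
        rows = np.unique(np.argwhere(truth.centerline)[:, 0])
        assert len(rows) == 1  # single row: a 1-px-wide line
        ncols = truth.centerline.sum()
        assert ncols == pytest.approx(6000.0 / float(pitch), rel=0.02)

    def test_integrated_intensity_matches_length(self):
        scene = generate_scene(3, 8000.0, seed=2)
        pitch = Fraction(125, 4)
        truth = render_truth(scene, pitch)
        expect = scene.amplitude * sum(map(curve_length, scene.curves)) / float(pitch)
        assert truth.intensity.sum() == pytest.approx(expect, rel=0.02)

    def test_supersample_pitch_capped(self, arc_scene):
        with pytest.raises(ValueError):
            render_truth(arc_scene, Fraction(100))


class TestDegrade:
    def test_delta_psf_no_binning_is_identity(self, arc_scene):
        truth = render_truth(arc_scene, Fraction(125, 4))
        obs = degrade(truth, DELTA_OPTICS, QUIET, Fraction(125, 4), seed=0)
        assert np.array_equal(obs.pixels,
                              np.clip(np.floor(truth.intensity + 0.5), 0, 65535))

    def test_flux_conserved_without_noise(self, arc_scene):
        truth = render_truth(arc_scene, Fraction(125, 4))
        obs = degrade(truth, OpticalModel(), QUIET, Fraction(125, 2), seed=0)
        assert obs.pixels.sum() == pytest.approx(truth.intensity.sum(), rel=0.005)

    def test_poisson_mean_is_noiseless_value(self, arc_scene):
        truth = render_truth(arc_scene, Fraction(125, 4))
        clean = degrade(truth, OpticalModel(), QUIET, Fraction(125, 2), seed=0)
        r, c = np.unravel_index(clean.pixels.argmax(), clean.shape)
        lam = float(clean.pixels[r, c])
        rng = np.random.default_rng(42)
        noisy = NoiseModel(gaussian_sigma=0.0, poisson=True, offset=0.0)
        vals = [float(degrade(truth, OpticalModel(), noisy, Fraction(125, 2),
                              rng=rng).pixels[r, c]) for _ in range(500)]
        se = np.sqrt(lam / 500)
        assert abs(np.mean(vals) - lam) < 3 * se

    def test_linear_in_amplitude_without_noise(self, arc_scene):
        import dataclasses

        t1 = render_truth(arc_scene, Fraction(125, 4))
        s2 = dataclasses.replace(arc_scene, amplitude=2 * arc_scene.amplitude)
        t2 = render_truth(s2, Fraction(125, 4))
        o1 = degrade(t1, OpticalModel(), QUIET, Fraction(125, 2), seed=0)
        o2 = degrade(t2, OpticalModel(), QUIET, Fraction(125, 2), seed=0)
        big = o1.pixels > 50  # away from quantization floor
        ratio = o2.pixels[big].astype(float) / o1.pixels[big]
        assert np.allclose(ratio, 2.0, atol=0.02)

    def test_observed_peak_registered_to_centerline(self):
        # straight horizontal line, zero noise: along every column the
        # brightest pixel is within 1 px of the true row
        curve = np.column_stack([np.linspace(500, 7500, 100),
                                 np.full(100, 3700.0)])
        scene = FilamentScene(curves=[curve], field_nm=8000.0)
        truth = render_truth(scene, Fraction(125, 4))
        obs = degrade(truth, OpticalModel(), QUIET, Fraction(125, 2), seed=0)
        true_row = 3700.0 / 62.5 - 0.5
        cols = range(20, obs.shape[1] - 20)
        for c in cols:
            assert abs(obs.pixels[:, c].argmax() - true_row) <= 1.0

    def test_psf_wider_than_field_rejected(self, arc_scene):
        import dataclasses

        small = dataclasses.replace(arc_scene, field_nm=8000.0)
        truth = render_truth(small, Fraction(125, 4))
        truth.intensity = truth.intensity[:16, :16]  # 500 nm field
        truth.centerline = truth.centerline[:16, :16]
        with pytest.raises(ValueError):
            degrade(truth, OpticalModel(), QUIET, Fraction(125, 4), seed=0)

    def test_non_integer_pitch_ratio_rejected(self, arc_scene):
        truth = render_truth(arc_scene, Fraction(125, 4))
        with pytest.raises(ValueError):
            degrade(truth, OpticalModel(), QUIET, Fraction(100), seed=0)


class TestMakeDataset:
    def _config(self):
        return PhantomConfig(field_nm=4000.0, out_pitch_nm=Fraction(250),
                             supersample_pitch_nm=Fraction(125, 2))

    def test_manifest_rows_and_determinism(self, tmp_path):
        cfg = self._config()
        m1 = make_dataset(3, 2, cfg, seed=5, out_dir=tmp_path / "a")
        m2 = make_dataset(3, 2, cfg, seed=5, out_dir=tmp_path / "b")
        rows1 = m1.read_text().strip().splitlines()
        assert len(rows1) - 1 == 5  # header + n_train + n_test
        for f1 in sorted((tmp_path / "a").rglob("*.tif")):
            f2 = tmp_path / "b" / f1.relative_to(tmp_path / "a")
            h1 = hashlib.sha256(f1.read_bytes()).hexdigest()
            h2 = hashlib.sha256(f2.read_bytes()).hexdigest()
            assert h1 == h2, f"{f1.name} differs between identical-seed runs"

    def test_existing_dir_requires_force(self, tmp_path):
        cfg = self._config()
        make_dataset(1, 1, cfg, seed=0, out_dir=tmp_path / "d")
        with pytest.raises(FileExistsError):
            make_dataset(1, 1, cfg, seed=0, out_dir=tmp_path / "d")
        make_dataset(1, 1, cfg, seed=0, out_dir=tmp_path / "d", force=True)

    def test_paper_scale_counts_accepted(self, tmp_path):
        # the full composition (200/50) is valid configuration; generating
        # two pairs here just checks the schema path
        with pytest.raises(ValueError):
            make_dataset(0, 1, self._config(), seed=0, out_dir=tmp_path / "x")

    def test_pairs_are_registered(self):
        pairs = make_pairs(2, self._config(), seed=9)
        for p in pairs:
            assert p.label.shape == p.observed.shape
            assert p.observed.pitch_xy == Fraction(250)
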