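import numpy as np
import pytest

from glossprobe import stimuli as st


class TestHeightfield:
    def test_flat_limit(self):
        hf = st.make_heightfield(0, seed=1, size=64, amplitude=0.0)
        assert np.allclose(hf.heights, 0.0)
        assert np.allclose(hf.normals, [0.0, 0.0, 1.0])
        assert np.allclose(hf.curvature, 0.0)

    def test_determinism(self):
        a = st.make_heightfield(2, seed=5, size=64)
        b = st.make_heightfield(2, seed=5, size=64)
        np.testing.assert_array_equal(a.heights, b.heights)
        np.testing.assert_array_equal(a.normals, b.normals)

    def test_seed_sensitivity(self):
        a = st.make_heightfield(2, seed=5, size=64)
        b = st.make_heightfield(2, seed=6, size=64)
        assert not np.allclose(a.heights, b.heights)

    def test_single_wave_matches_direct_formula(self):
        # oracle: independent scalar evaluation of the synthesis formula,
        # including the slope renormalization applied by the generator
        size = 64
        hf = st.make_heightfield(1, seed=7, size=size, n_waves=1)
        freqs, thetas, phases, amps = st.wave_parameters(1, 7, n_waves=1)
        r, c = 13, 40
        x, y = (c + 0.5) / size, (r + 0.5) / size
        expected = amps[0] * np.sin(
            2 * np.pi * freqs[0] * (x * np.cos(thetas[0]) + y * np.sin(thetas[0]))
            + phases[0])
        ratio = hf.heights[r, c] / expected
        # every grid point shares the same renormalization constant
        grid = st.evaluate_waves(*st.pixel_grid(size), freqs, thetas, phases, amps)
        np.testing.assert_allclose(hf.heights, grid * ratio, rtol=1e-9)

    def test_normals_unit_length(self):
        hf = st.make_heightfield(3, seed=2, size=64)
        norms = np.linalg.norm(hf.normals, axis=-1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)

    def test_bad_size_rejected(self):
        with pytest.raises(st.ConfigurationError):
            st.make_heightfield(0, seed=1, size=100)

    def test_dominant_frequency_doubles(self):
        # the mean sampled frequency should double per scale step
        means = []
        for lvl in range(4):
            freqs, *_ = st.wave_parameters(lvl, seed=3)
            means.append(freqs.mean())
        ratios = np.diff(np.log2(means))
        np.testing.assert_allclose(ratios, 1.0, atol=1e-9)


class TestShading:
    def test_flat_lambert_closed_form(self):
        # flat surface, single light sample: shading proportional to max(0, n.l)
        size = 64
        hf = st.make_heightfield(0, seed=1, size=size, amplitude=0.0)
        spec = st.SceneSpec(scene_id=0, scale_level=0, seed=1, image_size=size,
                            light_center=(0.3, 0.4), light_height=5.0,
                            light_half_width=0.25)
        comps = st.shade_components(hf, spec, n_light_samples=1)
        x, y = st.pixel_grid(size)
        p = np.stack([x, y, hf.heights], axis=-1)
        l = np.array([0.3, 0.4, 5.0]) - p
        d2 = np.sum(l * l, axis=-1)
        l /= np.sqrt(d2)[..., None]
        lambert = np.maximum(0.0, l[..., 2]) / d2
        # proportional wherever the per-scene normalization has not clipped
        unclipped = comps.shading < 1.0
        assert unclipped.mean() > 0.8
        ratio = comps.shading[unclipped] / lambert[unclipped]
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_flat_mirror_argmax(self):
        # light sample in the mirror direction of the view ray -> specular max
        size = 64
        hf = st.make_heightfield(0, seed=1, size=size, amplitude=0.0)
        # flat normals: mirror ray from pixel (0.5, 0.5) points along
        # (0, cos45, sin45); place the light center on that ray.
        h = 4.0
        spec = st.SceneSpec(scene_id=0, scale_level=0, seed=1, image_size=size,
                            light_center=(0.5, 0.5 + h), light_height=h,
                            light_half_width=0.2)
        comps = st.shade_components(hf, spec, n_light_samples=3)
        center = size // 2
        assert comps.specular.max() > 0
        # the mirror-aligned pixel sits on the global maximum (possibly a
        # saturated plateau)
        assert comps.specular[center, center] == comps.specular.max()
        # far corners are off the highlight entirely
        assert comps.specular[0, 0] < comps.specular[center, center]

    def test_degenerate_normal_reported(self):
        hf = st.make_heightfield(0, seed=1, size=64, amplitude=0.0)
        hf.normals[3, 4] = 0.0
        spec = st.sample_scene(0, 0, seed=1, size=64)
        with pytest.raises(FloatingPointError, match=r"\(3, 4\)"):
            st.shade_components(hf, spec)

    def test_specular_nonnegative_finite(self, small_catalog):
        for rec in small_catalog[:15]:
            assert np.all(rec.components.specular >= 0)
            assert np.all(np.isfinite(rec.components.specular))
            assert np.all(np.isfinite(rec.components.shading))


class TestCalibration:
    def test_specular_fraction_near_three_percent(self):
        # stochastic calibration contract over scenes balanced across levels
        fracs = []
        for sid in range(80):
            spec = st.sample_scene(sid, sid % 4, seed=21, size=64)
            _, comps = st.render_scene(spec)
            fracs.append(st.specular_pixel_fraction(comps.specular))
        assert 0.015 <= np.mean(fracs) <= 0.045


class TestTextures:
    def test_checker_two_values_balanced(self):
        tex = st.make_texture("checker", 1, seed=9, size=64)
        vals = np.unique(tex)
        assert len(vals) == 2
        frac = np.mean(tex == vals[0])
        assert abs(frac - 0.5) <= (64 / 64 ** 2)  # one row/column tolerance

    def test_determinism(self):
        for kind in st.TEXTURE_KINDS:
            a = st.make_texture(kind, 2, seed=4, size=64)
            b = st.make_texture(kind, 2, seed=4, size=64)
            np.testing.assert_array_equal(a, b)

    def test_texture_range(self):
        for kind in st.TEXTURE_KINDS:
            tex = st.make_texture(kind, 0, seed=3, size=64)
            assert tex.min() >= 0.1 - 1e-12
            assert np.isclose(tex.max(), 1.0)

    def test_voronoi_matches_brute_force_labelling(self):
        # oracle: brute-force nearest-site distances on the same seeded sites
        size, tex_scale, seed = 128, 0, 7
        sites = st.voronoi_sites(tex_scale, seed)
        x, y = st.pixel_grid(size)
        pts = np.stack([x.ravel(), y.ravel()], axis=1)
        d = np.sqrt(((pts[:, None, :] - sites[None]) ** 2).sum(-1))
        brute_nearest = d.argmin(axis=1)
        brute_dist = d.min(axis=1).reshape(size, size)
        tex = st.make_texture("voronoi", tex_scale, seed, size)
        lo, hi = brute_dist.min(), brute_dist.max()
        expected = 0.1 + (brute_dist - lo) / (hi - lo) * 0.9
        np.testing.assert_allclose(tex, expected, atol=1e-9)
        # same number of distinct occupied cells under both labellings
        assert len(np.unique(brute_nearest)) >= 1


class TestFalseHighlights:
    def test_zero_donor_reduces_to_plain(self):
        donor = np.zeros((64, 64))
        tex = st.make_false_highlight_texture(donor)
        np.testing.assert_allclose(tex, 1.0)

    def test_monotone_in_donor(self):
        rng = np.random.default_rng(0)
        donor = rng.random((64, 64))
        tex = st.make_false_highlight_texture(donor)
        assert np.argmax(tex) == np.argmax(donor)

    def test_bright_patches_at_donor_positions(self):
        # centroid of bright texture mass tracks the donor's highlights,
        # not the target's own specular map, across generated pairs
        displaced = 0
        n_pairs = 0
        cat = st.build_catalog(8, size=64, seed=31)
        for rec in cat:
            if not rec.condition.startswith("false_highlight"):
                continue
            n_pairs += 1
            tex = rec.texture_map
            own = rec.components.specular
            tw = tex - tex.min()
            if tw.sum() == 0 or own.sum() == 0:
                continue
            rr, cc = np.indices(tex.shape)
            tex_c = np.array([(rr * tw).sum() / tw.sum(), (cc * tw).sum() / tw.sum()])
            own_c = np.array([(rr * own).sum() / own.sum(), (cc * own).sum() / own.sum()])
            if np.linalg.norm(tex_c - own_c) > 0:
                displaced += 1
        assert n_pairs >= 16
        assert displaced == n_pairs


class TestCompose:
    def test_plain_is_shading_when_no_specular(self):
        size = 64
        comps = st.RenderComponents(
            shading=np.random.default_rng(0).random((size, size)),
            specular=np.zeros((size, size)),
            depth=np.ones((size, size)))
        spec = st.SceneSpec(0, 0, 1, size)
        rec = st.compose(comps, np.ones((size, size)), "plain", spec)
        np.testing.assert_allclose(rec.image, comps.shading, atol=1e-7)

    def test_clip_contract(self, small_catalog):
        for rec in small_catalog[:30]:
            assert rec.image.min() >= 0.0
            assert rec.image.max() <= 1.0

    def test_shape_mismatch(self):
        comps = st.RenderComponents(shading=np.ones((64, 64)),
                                    specular=np.zeros((64, 64)),
                                    depth=np.ones((64, 64)))
        with pytest.raises(ValueError, match="shape"):
            st.compose(comps, np.ones((32, 32)), "plain", st.SceneSpec(0, 0, 1, 64))

    def test_conditions_share_components(self, small_catalog):
        by_scene = {}
        for rec in small_catalog:
            by_scene.setdefault(rec.scene.scene_id, []).append(rec)
        for recs in by_scene.values():
            assert len(recs) == 15
            ref = recs[0].components
            for rec in recs[1:]:
                assert rec.components is ref or np.array_equal(
                    rec.components.specular, ref.specular)

    def test_image_recomposes_from_components(self, small_catalog):
        for rec in small_catalog[:20]:
            expected = np.clip(
                rec.components.shading * rec.texture_map
                + rec.components.specular, 0, 1)
            np.testing.assert_allclose(rec.image, expected, atol=1e-6)


class TestCatalog:
    def test_full_grid_count(self, small_catalog):
        assert len(small_catalog) == 12 * 15

    def test_no_false_highlights_count(self):
        cat = st.build_catalog(1, size=64, seed=1, include_false_highlights=False)
        assert len(cat) == 13

    def test_single_scene_with_false_rejected(self):
        with pytest.raises(st.ConfigurationError, match="donor"):
            st.build_catalog(1, size=64, seed=1)

    def test_paper_scale_enumeration(self):
        cat = st.build_catalog(10_939, size=256, seed=0, render=False)
        assert len(cat) == 164_085

    def test_scale_levels_balanced(self):
        cat = st.build_catalog(4, size=64, seed=2)
        levels = sorted({r.scene.scale_level for r in cat})
        assert levels == [0, 1, 2, 3]
        per = {lvl: sum(1 for r in cat if r.scene.scale_level == lvl) // 15
               for lvl in levels}
        assert all(v == 1 for v in per.values())

    def test_determinism(self):
        a = st.build_catalog(4, size=64, seed=9)
        b = st.build_catalog(4, size=64, seed=9)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.image, rb.image)

    def test_light_height_invariant(self, small_catalog):
        lo = 3.8 * st.camera_vertical_distance()
        hi = 4.8 * st.camera_vertical_distance()
        for rec in small_catalog:
            assert lo <= rec.scene.light_height <= hi

    def test_split_validation_balanced(self, small_catalog):
        train, val = small_catalog.split_validation(30, seed=0)
        assert len(val) == 30
        assert len(train) + len(val) == len(small_catalog)
        assert not set(train) & set(val)

    def test_manifest_roundtrip(self, small_catalog, tmp_path):
        path = tmp_path / "manifest.jsonl"
        small_catalog.save_manifest(path)
        import json
        rows = [json.loads(line) for line in path.read_text().splitlines()]
        assert len(rows) == len(small_catalog)
        assert rows[0]["condition"] == "plain"


class TestRotateSpecular:
    def test_identity(self, plain_records):
        rec = plain_records[0]
        out = st.rotate_specular(rec, 0)
        np.testing.assert_array_equal(out.image, rec.image)

    def test_group_closure(self, plain_records):
        rec = plain_records[1]
        out = rec
        for _ in range(4):
            out = st.rotate_specular(out, 90)
        np.testing.assert_allclose(out.components.specular,
                                   rec.components.specular, atol=1e-7)

    def test_index_permutation_oracle(self, plain_records):
        # 90 deg CCW: output[i, j] == input[j, n-1-i]
        rec = plain_records[2]
        spec = rec.components.specular
        n = spec.shape[0]
        out = st.rotate_specular(rec, 90).components.specular
        i, j = 5, 17
        assert out[i, j] == spec[j, n - 1 - i]
        expected = np.empty_like(spec)
        for ii in range(n):
            expected[ii] = spec[:, n - 1 - ii]
        np.testing.assert_array_equal(out, expected)

    def test_rejects_texture_and_bad_angle(self, small_catalog, plain_records):
        textured = next(r for r in small_catalog if r.condition == "checker0")
        with pytest.raises(ValueError, match="plain"):
            st.rotate_specular(textured, 90)
        with pytest.raises(ValueError, match="90"):
            st.rotate_specular(plain_records[0], 45)

    def test_recomposition_uses_rotated_map(self, plain_records):
        rec = plain_records[0]
        out = st.rotate_specular(rec, 180)
        np.testing.assert_array_equal(out.components.specular,
                                      np.rot90(rec.components.specular, 2))
        expected = np.clip(rec.components.shading * 1.0
                           + out.components.specular, 0, 1)
        np.testing.assert_allclose(out.image, expected, atol=1e-6)
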