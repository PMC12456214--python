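"""Synthetic tissue generator: diameter sampling, packing, rendering,
cohort output."""

import json

import numpy as np
import pytest
from scipy import ndimage

from adipo3d import (
    CohortDesign,
    SampleSpec,
    TissuePreset,
    generate_cohort,
    measure_regions,
    pack_ex_situ,
    pack_in_situ,
    render_channels,
    sample_diameters,
)
from adipo3d.errors import GeometryError, ParameterError
from conftest import SPACING


class TestSampleDiameters:
    def test_empty_draw(self):
        preset = TissuePreset("p", 60, 0.3)
        assert sample_diameters(preset, 0, seed=1).size == 0

    def test_lognormal_moment_matching(self):
        # closed-form parameterization: µ = ln m − σ²/2, σ² = ln(1+cv²)
        preset = TissuePreset("p", 81.32, 0.3)
        d = sample_diameters(preset, 100_000, seed=7)
        assert d.mean() == pytest.approx(81.32, rel=0.01)
        assert d.std() / d.mean() == pytest.approx(0.3, rel=0.02)

    def test_mixture_mean(self):
        preset = TissuePreset("m", mixture=((0.5, 38.0, 0.1), (0.5, 50.0, 0.1)))
        d = sample_diameters(preset, 100_000, seed=7)
        assert d.mean() == pytest.approx(44.0, rel=0.01)
        assert preset.mean_diameter == pytest.approx(44.0)

    def test_deterministic(self):
        preset = TissuePreset("p", 60, 0.3)
        a = sample_diameters(preset, 100, seed=5)
        b = sample_diameters(preset, 100, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            TissuePreset("p", -1, 0.3)
        with pytest.raises(ValueError):
            TissuePreset("p", 60, 0.0)
        with pytest.raises(ValueError):
            TissuePreset("m", mixture=((0.5, 38, 0.1), (0.6, 50, 0.1)))
        with pytest.raises(ParameterError):
            sample_diameters(TissuePreset("p", 60, 0.3), -1, seed=0)


class TestPackInSitu:
    def test_single_cell_diameter(self):
        stack = pack_in_situ([60.0], (128, 128, 128), SPACING, seed=1)
        assert stack.n_labels == 1
        row = measure_regions(stack).iloc[0]
        assert row.equivalent_diameter == pytest.approx(60.0, rel=0.10)

    def test_labels_disjoint_and_bounded(self, packed_pair):
        stack = packed_pair["in_situ"]
        assert stack.n_labels <= len(packed_pair["diameters"])
        # each label is one 26-connected component
        for lab in stack.ids[:5]:
            _, n = ndimage.label(stack.labels == lab, structure=np.ones((3, 3, 3)))
            assert n == 1

    def test_deterministic(self):
        d = [40.0, 50.0, 45.0]
        a = pack_in_situ(d, (96, 96, 96), SPACING, seed=9)
        b = pack_in_situ(d, (96, 96, 96), SPACING, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_geometry_error_when_cell_cannot_fit(self):
        with pytest.raises(GeometryError):
            pack_in_situ([200.0], (32, 32, 32), SPACING, seed=0)

    def test_volume_fidelity(self, packed_pair):
        # packed cell volumes track the target sphere volumes
        measured = packed_pair["in_situ_table"].equivalent_diameter.mean()
        assert measured == pytest.approx(packed_pair["diameters"].mean(), rel=0.03)


class TestPackExSitu:
    def test_single_sphere_is_round(self):
        stack = pack_ex_situ([40.0], (96, 96, 96), SPACING, seed=3)
        assert stack.n_labels == 1
        assert measure_regions(stack).iloc[0].sphericity >= 0.95

    def test_labels_never_touch(self, packed_pair):
        from scipy.spatial import cKDTree

        stack = packed_pair["ex_situ"]
        voxel = max(stack.spacing)
        coords = np.argwhere(stack.labels > 0) * np.asarray(stack.spacing)
        ids = stack.labels[stack.labels > 0]
        tree = cKDTree(coords)
        # at least one empty voxel between any two cells: no cross-label
        # voxel pair closer than two pitches
        for i, j in tree.query_pairs(1.99 * voxel):
            assert ids[i] == ids[j]

    def test_geometry_error_reports_placed_count(self):
        with pytest.raises(GeometryError) as err:
            pack_ex_situ([40.0] * 50, (48, 48, 48), SPACING, seed=1, max_tries=50)
        assert err.value.placed is not None
        assert 0 <= err.value.placed < 50

    def test_rounder_than_in_situ(self, packed_pair):
        # extracted cells lose the polyhedral constraints of the tissue
        in_sph = packed_pair["in_situ_table"].sphericity.mean()
        ex_sph = packed_pair["ex_situ_table"].sphericity.mean()
        assert ex_sph > in_sph


class TestRenderChannels:
    def _slab(self, nz=120):
        return np.ones((nz, 10, 10), np.int32)

    def test_no_attenuation_uniform_in_depth(self):
        preset = TissuePreset("p", 60, 0.3, packing="ex_situ")
        stack = render_channels(
            __import__("adipo3d").LabelStack(self._slab(), SPACING), preset, seed=0
        )
        lipid = stack.channel("lipid")
        assert lipid[0].mean() == pytest.approx(lipid[-1].mean(), rel=1e-12)

    def test_exponential_decay_reaches_1_over_e(self):
        from adipo3d import LabelStack

        L = 115.0  # 100 planes at 1.15 µm
        preset = TissuePreset("p", 60, 0.3, packing="ex_situ", attenuation_length=L)
        stack = render_channels(LabelStack(self._slab(), SPACING), preset, seed=0)
        lipid = stack.channel("lipid")
        assert lipid[100].mean() / lipid[0].mean() == pytest.approx(
            np.exp(-1), rel=1e-9
        )

    def test_depth_profile_monotone_noise_free(self):
        from adipo3d import LabelStack

        preset = TissuePreset("p", 60, 0.3, packing="ex_situ", attenuation_length=80.0)
        stack = render_channels(LabelStack(self._slab(), SPACING), preset, seed=0)
        profile = stack.channel("lipid").mean(axis=(1, 2))
        assert np.all(np.diff(profile) <= 0)

    def test_channel_layout_and_noise_floor(self, packed_pair):
        in_preset = TissuePreset("p", 60, 0.3, packing="in_situ", noise_sd=5.0,
                                 background=2.0)
        rendered = render_channels(packed_pair["in_situ"], in_preset, seed=4)
        assert rendered.n_channels == 2
        assert rendered.channel_names == ["ecm", "lipid"]
        assert rendered.intensities.min() >= 0.0  # noise clipped
        ex_preset = TissuePreset("p", 60, 0.3, packing="ex_situ")
        assert render_channels(packed_pair["ex_situ"], ex_preset, seed=4).n_channels == 1

    def test_ecm_shell_sits_on_background(self, packed_pair):
        preset = TissuePreset("p", 60, 0.3, packing="in_situ")
        rendered = render_channels(packed_pair["in_situ"], preset, seed=0)
        ecm = rendered.channel("ecm")
        assert (ecm[packed_pair["in_situ"].labels > 0] == 0).all()
        assert ecm.max() > 0


class TestGenerateCohort:
    def _design(self):
        preset = TissuePreset("tiny", 40.0, 0.2, packing="ex_situ")
        return CohortDesign(
            [
                SampleSpec("s1", "f1", "VAT", "ex_situ", preset, 5, seed=11),
                SampleSpec("s2", "f1", "SCAT", "ex_situ", preset, 5, seed=12),
            ]
        )

    def test_file_count_and_manifest(self, tmp_path):
        manifest = generate_cohort(self._design(), tmp_path)
        assert len(manifest["samples"]) == 2
        files = sorted(p.name for p in tmp_path.iterdir())
        assert sum(f.endswith("_stack.tif") for f in files) == 2
        assert sum(f.endswith("_truth_labels.tif") for f in files) == 2
        assert sum(f.endswith("_truth_cells.csv") for f in files) == 2
        assert "manifest.json" in files
        loaded = json.loads((tmp_path / "manifest.json").read_text())
        assert [s["seed"] for s in loaded["samples"]] == [11, 12]

    def test_ground_truth_tables_reproducible(self, tmp_path):
        generate_cohort(self._design(), tmp_path / "a")
        generate_cohort(self._design(), tmp_path / "b")
        for name in ("s1_truth_cells.csv", "s2_truth_cells.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_duplicate_sample_ids_rejected(self):
        preset = TissuePreset("tiny", 40.0, 0.2, packing="ex_situ")
        with pytest.raises(ValueError):
            CohortDesign(
                [
                    SampleSpec("s1", "f1", "VAT", "ex_situ", preset, 3, seed=1),
                    SampleSpec("s1", "f2", "VAT", "ex_situ", preset, 3, seed=2),
                ]
            )
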