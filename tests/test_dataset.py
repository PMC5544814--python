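"""Scenario sampling design, feature vector layout, dataset containers."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from subwave.dataset import (
    LabeledDataset,
    build_dataset,
    build_validation_dataset,
    channel_order,
    class_names_for,
    featurize,
    sample_scenarios,
    validation_head_scales,
    validation_thicknesses,
)
from subwave.fem import SParameterSet
from subwave.geometry import HeadModelConfig
from conftest import FAST_FREQS, FAST_EPW

CFG = HeadModelConfig()


class TestChannelLayout:
    @given(st.integers(min_value=1, max_value=12), st.integers(min_value=1, max_value=9))
    def test_feature_length_formula(self, n, F):
        chans = channel_order(n)
        assert len(chans) == n * (n + 1) // 2
        rng = np.random.default_rng(0)
        s = rng.standard_normal((F, n, n)) + 1j * rng.standard_normal((F, n, n))
        s = 0.5 * (s + s.transpose(0, 2, 1))
        fv = featurize(SParameterSet(np.linspace(1e9, 2e9, F), s))
        assert len(fv.values) == n * (n + 1) // 2 * F

    def test_ten_antennas_measurement_layout(self):
        # the helmet instrument: 10 antennas, 401 frequencies
        assert len(channel_order(10)) == 55
        F = 401
        rng = np.random.default_rng(1)
        s = rng.standard_normal((F, 10, 10)) * (1 + 0j)
        s = 0.5 * (s + s.transpose(0, 2, 1))
        fv = featurize(SParameterSet(np.linspace(0.1e9, 3e9, F), s))
        assert len(fv.values) == 22_055

    def test_canonical_order_frequencies_contiguous(self):
        freqs = np.array([1e9, 2e9, 3e9])
        s = np.zeros((3, 2, 2), dtype=complex)
        s[:, 0, 0] = [11, 12, 13]
        s[:, 0, 1] = s[:, 1, 0] = [21, 22, 23]
        s[:, 1, 1] = [31, 32, 33]
        fv = featurize(SParameterSet(freqs, s))
        np.testing.assert_array_equal(
            fv.values.real, [11, 12, 13, 21, 22, 23, 31, 32, 33]
        )
        assert fv.channels == [(1, 1), (1, 2), (2, 2)]
        assert fv.channel_index_map[0] == (1, 1, 1e9)

    def test_single_port_single_frequency(self):
        fv = featurize(SParameterSet([1e9], np.full((1, 1, 1), 0.5 + 0j)))
        assert len(fv.values) == 1
        assert fv.channels == [(1, 1)]

    def test_nonreciprocal_input_rejected(self):
        s = np.zeros((1, 3, 3), dtype=complex)
        s[0, 0, 1] = 1.0  # S12 != S21
        with pytest.raises(ValueError):
            featurize(SParameterSet([1e9], s))

    def test_nan_rejected(self):
        s = np.full((1, 2, 2), np.nan + 0j)
        with pytest.raises(ValueError):
            featurize(SParameterSet([1e9], s))


class TestSampling:
    def test_full_design_size(self):
        scen = sample_scenarios(250, config=CFG, seed=0)
        assert len(scen) == 1500

    def test_deterministic_under_seed(self):
        a = sample_scenarios(20, config=CFG, seed=5)
        b = sample_scenarios(20, config=CFG, seed=5)
        assert a == b
        c = sample_scenarios(20, config=CFG, seed=6)
        assert a != c

    def test_position_counts_balanced_within_class(self):
        scen = sample_scenarios(250, config=CFG, seed=1)
        for t in CFG.class_thicknesses[1:]:
            pos = [p.position_index for p in scen if p.bleeding_thickness == t]
            counts = np.bincount(pos, minlength=11)[1:]
            assert np.all(np.abs(counts - 25) <= 1)

    def test_sides_and_scales_balanced(self):
        scen = sample_scenarios(140, config=CFG, seed=2)
        bleeding = [p for p in scen if p.bleeding_thickness > 0]
        per_class = 140
        for t in CFG.class_thicknesses[1:]:
            cls = [p for p in bleeding if p.bleeding_thickness == t]
            sides = sum(1 for p in cls if p.side == "left")
            assert abs(sides - per_class / 2) <= 1
            scales = np.array([p.head_scale for p in cls])
            counts = [np.sum(np.isclose(scales, s)) for s in CFG.head_scales]
            assert max(counts) - min(counts) <= 1

    def test_continuous_parameters_within_ranges(self):
        scen = sample_scenarios(60, config=CFG, seed=3)
        for p in scen:
            assert CFG.csf_range[0] <= p.csf_thickness <= CFG.csf_range[1]
            assert abs(p.rotation_deg) <= CFG.rotation_max_deg

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            sample_scenarios(0, config=CFG)


class TestValidationDesign:
    def test_values_disjoint_from_training(self):
        for t in validation_thicknesses():
            assert all(abs(t - tt) > 1e-9 for tt in CFG.class_thicknesses)
        for s in validation_head_scales():
            assert all(abs(s - ss) > 1e-9 for ss in CFG.head_scales)

    def test_values_span_training_ranges(self):
        assert min(validation_thicknesses()) > min(CFG.class_thicknesses)
        assert max(validation_thicknesses()) < max(CFG.class_thicknesses)
        for s in validation_head_scales():
            assert min(CFG.head_scales) <= s <= max(CFG.head_scales)

    def test_overlapping_config_rejected(self):
        with pytest.raises(ValueError):
            build_validation_dataset(thicknesses=[0.005])  # a training value
        with pytest.raises(ValueError):
            build_validation_dataset(head_scales=[1.0])


@pytest.fixture(scope="module")
def tiny_dataset(head_config_module=None):
    """2 scenarios/class on a 4-frequency coarse grid (bookkeeping checks)."""
    scen = sample_scenarios(2, config=CFG, seed=11)
    return build_dataset(
        scen, FAST_FREQS, CFG, elements_per_wavelength=FAST_EPW
    ), scen


class TestBuildDataset:
    def test_bookkeeping(self, tiny_dataset):
        ds, scen = tiny_dataset
        assert len(ds) == 12
        assert ds.X.shape[1] == 36 * len(FAST_FREQS)
        assert np.array_equal(ds.class_counts(), np.full(6, 2))
        assert ds.class_names == class_names_for(CFG.class_thicknesses)
        assert len(np.unique(ds.groups)) == 12  # simulated scenarios are singletons

    def test_rebuild_is_bit_identical(self, tiny_dataset):
        ds, scen = tiny_dataset
        ds2 = build_dataset(scen, FAST_FREQS, CFG, elements_per_wavelength=FAST_EPW)
        np.testing.assert_array_equal(ds.X, ds2.X)

    def test_noise_option_changes_data_deterministically(self, tiny_dataset):
        ds, scen = tiny_dataset
        noisy1 = build_dataset(
            scen, FAST_FREQS, CFG, elements_per_wavelength=FAST_EPW,
            noise_std=1e-4, noise_seed=3,
        )
        noisy2 = build_dataset(
            scen, FAST_FREQS, CFG, elements_per_wavelength=FAST_EPW,
            noise_std=1e-4, noise_seed=3,
        )
        assert not np.array_equal(ds.X, noisy1.X)
        np.testing.assert_array_equal(noisy1.X, noisy2.X)
        # injected power matches the configured level
        resid = noisy1.X - ds.X
        rms = np.sqrt(np.mean(np.abs(resid) ** 2))
        assert rms == pytest.approx(1e-4, rel=0.1)

    def test_hdf5_roundtrip_bit_exact(self, tiny_dataset, tmp_path):
        ds, _ = tiny_dataset
        path = tmp_path / "ds.h5"
        ds.to_hdf5(path)
        back = LabeledDataset.from_hdf5(path)
        np.testing.assert_array_equal(ds.X, back.X)
        np.testing.assert_array_equal(ds.y, back.y)
        assert back.class_names == ds.class_names
        assert back.channels == ds.channels
        assert back.scenario_params == ds.scenario_params

    def test_left_side_features_equal_mirrored_right(self, materials):
        """A left-side lesion's features are the port-permuted right-side ones."""
        from subwave.dataset import _label_for  # noqa: F401
        from subwave.fem import mirror_sparams, sweep_scenario
        from subwave.geometry import ScenarioGeometry, ScenarioParams
        from dataclasses import replace

        pl = ScenarioParams(
            bleeding_thickness=0.02, position_index=4, rotation_deg=2.0, side="left"
        )
        ds = build_dataset([pl], FAST_FREQS, CFG, elements_per_wavelength=FAST_EPW)
        pr = replace(pl, side="right", rotation_deg=-2.0)
        sps = mirror_sparams(
            sweep_scenario(
                ScenarioGeometry(pr, CFG), FAST_FREQS, materials,
                elements_per_wavelength=FAST_EPW,
            ),
            CFG.mirror_permutation(),
        )
        np.testing.assert_allclose(ds.X[0], featurize(sps).values, rtol=1e-12)


class TestMeasuredImport:
    def make_files(self, tmp_path, n_obs=6, n_ports=4, F=5):
        from subwave.touchstone import write_touchstone

        rng = np.random.default_rng(21)
        freqs = np.linspace(0.5e9, 1.5e9, F)
        files, labels, groups = [], [], []
        for i in range(n_obs):
            s = rng.standard_normal((F, n_ports, n_ports)) * 0.1
            s = s + 1j * rng.standard_normal((F, n_ports, n_ports)) * 0.1
            s = 0.5 * (s + s.transpose(0, 2, 1))  # instrument-grade reciprocity
            path = tmp_path / f"obs{i}.s{n_ports}p"
            write_touchstone(path, freqs, s)
            files.append(path)
            labels.append(i % 2)
            groups.append(i // 3)  # replicate triplets
        return files, labels, groups, freqs

    def test_dataset_from_touchstone(self, tmp_path):
        from subwave.dataset import dataset_from_touchstone

        files, labels, groups, freqs = self.make_files(tmp_path)
        ds = dataset_from_touchstone(files, labels, ["healthy", "bleeding"], groups)
        assert len(ds) == 6
        assert ds.X.shape[1] == 10 * len(freqs)  # 4 ports -> 10 channels
        np.testing.assert_array_equal(ds.groups, [0, 0, 0, 1, 1, 1])

    def test_dataset_from_manifest(self, tmp_path):
        from subwave.dataset import dataset_from_manifest

        files, labels, groups, _ = self.make_files(tmp_path)
        manifest = tmp_path / "manifest.csv"
        lines = ["file,label,group"] + [
            f"{f.name},{l},{g}" for f, l, g in zip(files, labels, groups)
        ]
        manifest.write_text("\n".join(lines) + "\n")
        ds = dataset_from_manifest(manifest, ["healthy", "bleeding"])
        assert len(ds) == 6
        assert ds.provenance["role"] == "measured"

    def test_mismatched_grid_rejected(self, tmp_path):
        from subwave.dataset import dataset_from_touchstone
        from subwave.touchstone import write_touchstone

        files, labels, groups, freqs = self.make_files(tmp_path, n_obs=2)
        bad = tmp_path / "bad.s4p"
        write_touchstone(bad, freqs * 1.1, np.zeros((5, 4, 4), dtype=complex))
        with pytest.raises(ValueError):
            dataset_from_touchstone(
                list(files) + [bad], list(labels) + [0], ["a", "b"]
            )
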