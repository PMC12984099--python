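"""Phantom generator: layer structure, determinism, dataset splitting."""
import numpy as np
import pytest

from imflight.datasets import load_dataset, save_dataset, stratified_split_sizes
from imflight.emd import find_extrema
from imflight.errors import ConfigurationError
from imflight.phantoms import PhantomSpec, generate_dataset, generate_phantom


class TestGeneratePhantom:
    def test_degenerate_layers_zero(self):
        """With no illumination and no noise the composite is the structure."""
        spec = PhantomSpec(
            height=64, width=64, background_level=0.0, illum_amplitude=0.0,
            noise_sigma=0.0, n_vessels=0, illum_scale=48.0,
            lesion_radius_range=(3.0, 6.0),
            lesion_counts_per_class={1: (3, 0)},  # bright-only: no clipping at 0
        )
        ph = generate_phantom(spec, 1, np.random.default_rng(0))
        assert np.array_equal(ph.composite, ph.layers["structure"])
        assert not ph.layers["illumination"].any()
        assert not ph.layers["noise"].any()

    def test_seeded_determinism_bit_identical(self, small_spec):
        a = generate_phantom(small_spec, 1, np.random.default_rng([5, 1, 0]))
        b = generate_phantom(small_spec, 1, np.random.default_rng([5, 1, 0]))
        assert np.array_equal(a.composite, b.composite)
        for k in a.layers:
            assert np.array_equal(a.layers[k], b.layers[k])

    def test_empty_structure(self, small_spec):
        spec = PhantomSpec(
            **{**small_spec.__dict__, "n_vessels": 0,
               "lesion_counts_per_class": {0: (0, 0)}}
        )
        ph = generate_phantom(spec, 0, np.random.default_rng(2))
        assert not ph.layers["structure"].any()
        expected = np.clip(ph.layers["illumination"] + ph.layers["noise"], 0, 1)
        assert np.array_equal(ph.composite, expected)

    def test_layer_additivity_where_unclipped(self, small_spec):
        ph = generate_phantom(small_spec, 2, np.random.default_rng(7))
        total = sum(ph.layers.values())
        inside = (total >= 0) & (total <= 1)
        assert inside.mean() > 0.5
        assert np.allclose(ph.composite[inside], total[inside])
        assert np.all((ph.composite >= 0) & (ph.composite <= 1))

    def test_spectral_separation_by_extrema_density(self):
        """Extrema density orders noise > structure > illumination."""
        spec = PhantomSpec(seed=0)
        ph = generate_phantom(spec, 2, np.random.default_rng(0))
        dens = {
            k: find_extrema(ph.layers[k]).n_extrema
            for k in ("illumination", "structure", "noise")
        }
        assert dens["illumination"] < dens["structure"] < dens["noise"]

    @pytest.mark.parametrize(
        "bad",
        [
            {"height": 4},
            {"illum_amplitude": 1.5},
            {"lesion_radius_range": (0.5, 3.0)},
            {"lesion_radius_range": (3.0, 30.0)},
            {"illum_scale": 10.0},
        ],
    )
    def test_invalid_spec_rejected(self, bad):
        spec = PhantomSpec(**bad)
        with pytest.raises(ConfigurationError):
            spec.validate()

    def test_class_encoded_only_in_structure(self, small_spec):
        """Same stream, different label: only the structure layer changes."""
        a = generate_phantom(small_spec, 0, np.random.default_rng([9]))
        b = generate_phantom(small_spec, 2, np.random.default_rng([9]))
        assert np.array_equal(a.layers["illumination"], b.layers["illumination"])
        assert not np.array_equal(a.layers["structure"], b.layers["structure"])


class TestGenerateDataset:
    def test_split_sizes_two_classes_of_ten(self, small_spec):
        ds = generate_dataset(small_spec, 10, ["normal", "diseased"])
        assert len(ds) == 20
        assert ds.split_sizes() == {"train": 14, "val": 3, "test": 3}

    def test_split_allocation_conserves_class_totals(self):
        for n_per_class, n_classes in [(10, 2), (5, 6), (3, 2), (7, 4), (50, 3)]:
            alloc = stratified_split_sizes(n_per_class, n_classes)
            assert (alloc.sum(axis=1) == n_per_class).all()
            assert (alloc >= 1).all()

    def test_every_class_in_every_split_six_classes(self, small_spec):
        names = [f"c{i}" for i in range(6)]
        ds = generate_dataset(small_spec, 5, names)
        for split in ("train", "val", "test"):
            labels = {ds.labels[i] for i in ds.indices(split)}
            assert labels == set(range(6))

    def test_too_small_for_stratification(self, small_spec):
        with pytest.raises(ConfigurationError, match="3"):
            generate_dataset(small_spec, 1, ["a", "b"])

    def test_dataset_determinism(self, small_spec):
        a = generate_dataset(small_spec, 4, ["a", "b"])
        b = generate_dataset(small_spec, 4, ["a", "b"])
        assert a.split == b.split
        for x, y in zip(a.images, b.images):
            assert np.array_equal(x, y)

    def test_class_count_bounds(self, small_spec):
        with pytest.raises(ConfigurationError):
            generate_dataset(small_spec, 5, ["only"])
        with pytest.raises(ConfigurationError):
            generate_dataset(small_spec, 5, [f"c{i}" for i in range(7)])


class TestDatasetIO:
    def test_save_load_roundtrip(self, tmp_path, small_spec):
        ds = generate_dataset(small_spec, 3, ["healthy", "sick"])
        save_dataset(ds, tmp_path / "data")
        back = load_dataset(tmp_path / "data")
        assert back.class_names == ["healthy", "sick"]
        assert back.labels == ds.labels
        assert back.split == ds.split
        # 8-bit quantization on write
        for a, b in zip(ds.images, back.images):
            assert np.abs(a - b).max() <= 1.0 / 255.0 + 1e-12
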