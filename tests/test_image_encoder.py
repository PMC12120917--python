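"""Normalization, channel layouts A-F, canvas policies, full encoder."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rgbchem.descriptors import (
    bond_order_matrix,
    coulomb_matrix,
    distance_matrix,
    ionization_diag,
)
from rgbchem.image_encoder import (
    CanvasSizeError,
    ConfigError,
    EncodingConfig,
    bilinear_resize,
    compose_channels,
    encode,
    normalize_matrix,
    place_on_canvas,
)
from rgbchem.xyz_io import Molecule

GEN_TYPES = "ABCDEF"

# Adjacent generation types differ in exactly one colour plane (0=R,1=G,2=B).
LATTICE = {("A", "C"): 0, ("A", "B"): 1, ("B", "F"): 2, ("E", "F"): 0, ("C", "D"): 2}


class TestNormalize:
    def test_constant_matrix_maps_to_zero(self):
        assert (normalize_matrix(np.zeros((4, 4))) == 0).all()
        assert (normalize_matrix(np.full((4, 4), 7.0)) == 0).all()

    def test_per_image_endpoints(self):
        out = normalize_matrix(np.array([[0.0, 5.0], [5.0, 10.0]]))
        np.testing.assert_array_equal(out, [[0.0, 127.5], [127.5, 255.0]])

    def test_fixed_range_scalar_oracle(self, rng):
        m = rng.random((6, 6)) * 9
        lo, hi = 0.0, 2 * m.max()
        out = normalize_matrix(m, "fixed", (lo, hi))
        for i in range(6):
            for j in range(6):
                assert out[i, j] == pytest.approx(255.0 * (m[i, j] - lo) / (hi - lo), rel=1e-14)

    def test_fixed_range_clips(self):
        out = normalize_matrix(np.array([[-1.0, 5.0]] * 2), "fixed", (0.0, 2.0))
        np.testing.assert_array_equal(out, [[0.0, 255.0]] * 2)

    def test_degenerate_fixed_range_rejected(self):
        with pytest.raises(ConfigError):
            normalize_matrix(np.zeros((2, 2)), "fixed", (1.0, 1.0))

    @given(
        vals=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
            min_size=1,
            max_size=36,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_per_image_range_property(self, vals):
        """Output always lies in [0,255]; observed extrema hit the endpoints."""
        out = normalize_matrix(np.array(vals).reshape(1, -1))
        assert out.min() >= 0.0 and out.max() <= 255.0
        if max(vals) > min(vals):
            assert out.min() == 0.0 and out.max() == 255.0


class TestConfig:
    def test_random_offset_with_resize_rejected(self):
        with pytest.raises(ConfigError):
            EncodingConfig(margin_mode="resize", offset_mode="random")

    def test_fingerprint_distinguishes_configs(self):
        a = EncodingConfig(gen_type="A")
        b = EncodingConfig(gen_type="B")
        assert a.fingerprint() != b.fingerprint()
        assert a.fingerprint() == EncodingConfig(gen_type="A").fingerprint()


class TestComposeChannels:
    @pytest.fixture()
    def raw_planes(self, elements, pair_params, random_molecule_factory, rng):
        mol = random_molecule_factory(rng, n_heavy=5)
        return {
            t: compose_channels(mol, elements, pair_params, EncodingConfig(gen_type=t))
            for t in GEN_TYPES
        }

    @pytest.mark.parametrize("pair,channel", list(LATTICE.items()))
    def test_channel_identity_lattice(self, raw_planes, pair, channel):
        a, b = (raw_planes[t] for t in pair)
        for c in range(3):
            if c == channel:
                assert not np.array_equal(a[:, :, c], b[:, :, c])
            else:
                np.testing.assert_array_equal(a[:, :, c], b[:, :, c])

    def test_type_e_red_is_pure_diagonal(self, raw_planes):
        red = raw_planes["E"][:, :, 0]
        off = ~np.eye(red.shape[0], dtype=bool)
        assert (red[off] == 0).all()
        assert red.diagonal().max() == 255.0

    def test_combined_red_channel_cellwise(self, elements, pair_params, water):
        # Type A red: distance (normalized) off-diagonal, ionization
        # (normalized independently) on the diagonal.
        raw = compose_channels(water, elements, pair_params, EncodingConfig(gen_type="A"))
        dist = normalize_matrix(distance_matrix(water).values)
        ion = normalize_matrix(ionization_diag(water).values)
        n = water.n_atoms
        for i in range(n):
            for j in range(n):
                expected = ion[i, j] if i == j else dist[i, j]
                assert raw[i, j, 0] == expected

    def test_green_channel_is_coulomb(self, elements, pair_params, water):
        raw = compose_channels(water, elements, pair_params, EncodingConfig(gen_type="B"))
        np.testing.assert_array_equal(
            raw[:, :, 1], normalize_matrix(coulomb_matrix(water, "full", elements).values)
        )

    def test_all_planes_in_range(self, raw_planes):
        for t, raw in raw_planes.items():
            assert raw.min() >= 0 and raw.max() <= 255, t


class TestCanvas:
    def _raw(self, rng, n):
        return rng.random((n, n, 3)) * 255

    @pytest.mark.parametrize("mode", ["resize", "black", "average"])
    def test_n_equals_s_is_identity(self, rng, mode):
        raw = self._raw(rng, 16)
        cfg = EncodingConfig(canvas_size=16, margin_mode=mode)
        np.testing.assert_allclose(place_on_canvas(raw, cfg, rng), raw)

    def test_black_fixed_margin_is_zero(self, rng):
        raw = self._raw(rng, 5)
        cfg = EncodingConfig(canvas_size=32, margin_mode="black", offset_mode="fixed")
        out = place_on_canvas(raw, cfg)
        np.testing.assert_array_equal(out[:5, :5], raw)
        mask = np.ones((32, 32), dtype=bool)
        mask[:5, :5] = False
        assert (out[mask] == 0).all()

    def test_average_fill_matches_loop_mean(self, rng):
        raw = self._raw(rng, 5)
        cfg = EncodingConfig(canvas_size=32, margin_mode="average")
        out = place_on_canvas(raw, cfg)
        for c in range(3):
            mean = sum(raw[i, j, c] for i in range(5) for j in range(5)) / 25.0
            assert out[10, 10, c] == pytest.approx(mean, rel=1e-12)

    def test_random_offsets_uniform(self, rng):
        # Offsets over the (S-N+1)^2 grid should be uniform (chi^2 sanity).
        n, s, draws = 5, 8, 10_000
        cfg = EncodingConfig(canvas_size=s, margin_mode="black", offset_mode="random")
        raw = np.full((n, n, 3), 255.0)
        counts = np.zeros((s - n + 1, s - n + 1))
        for _ in range(draws):
            out = place_on_canvas(raw, cfg, rng)
            r, c = np.argwhere(out[:, :, 0] == 255.0)[0]
            counts[r, c] += 1
        chi2 = ((counts - draws / counts.size) ** 2 / (draws / counts.size)).sum()
        assert chi2 < stats.chi2.ppf(0.999, counts.size - 1)

    def test_molecule_larger_than_canvas_rejected(self, rng):
        cfg = EncodingConfig(canvas_size=4, margin_mode="black")
        with pytest.raises(CanvasSizeError, match="4"):
            place_on_canvas(self._raw(rng, 6), cfg)

    def test_resize_accepts_larger_molecule(self, rng):
        cfg = EncodingConfig(canvas_size=4, margin_mode="resize")
        assert place_on_canvas(self._raw(rng, 6), cfg).shape == (4, 4, 3)


class TestBilinearResize:
    def test_identity_at_same_size(self, rng):
        plane = rng.random((7, 7))
        np.testing.assert_array_equal(bilinear_resize(plane, 7), plane)

    def test_constant_preserved(self):
        np.testing.assert_allclose(bilinear_resize(np.full((3, 3), 42.0), 10), 42.0)

    def test_matches_skimage_oracle(self, rng):
        skimage = pytest.importorskip("skimage.transform")
        plane = rng.random((5, 5))
        ours = bilinear_resize(plane, 12)
        theirs = skimage.resize(
            plane, (12, 12), order=1, mode="edge", anti_aliasing=False
        )
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_range_never_exceeds_input(self, rng):
        plane = rng.random((6, 6)) * 255
        out = bilinear_resize(plane, 17)
        assert out.min() >= plane.min() - 1e-9 and out.max() <= plane.max() + 1e-9


class TestEncode:
    def test_deterministic(self, elements, pair_params, random_molecule_factory):
        mol = random_molecule_factory(np.random.default_rng(7))
        cfg = EncodingConfig(margin_mode="black", offset_mode="random")
        a = encode(mol, elements, pair_params, cfg, np.random.default_rng(3))
        b = encode(mol, elements, pair_params, cfg, np.random.default_rng(3))
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_quantized_outputs_integral(self, elements, pair_params, water):
        img = encode(water, elements, pair_params, EncodingConfig(quantize=True))
        assert img.pixels.dtype == np.uint8

    def test_diagonal_red_pixels_are_normalized_ionization(self, elements, pair_params, water):
        # N = S, type A, no quantization: red diagonal == normalized IEs.
        cfg = EncodingConfig(gen_type="A", canvas_size=3, quantize=False)
        img = encode(water, elements, pair_params, cfg)
        ion = np.array([elements.lookup(s).ionization_energy for s in water.symbols])
        expected = 255.0 * ion / ion.max()
        np.testing.assert_allclose(np.diagonal(img.pixels[:, :, 0]), expected)

    def test_hand_assembled_three_atom_oracle(self, elements, pair_params, water):
        """End-to-end check against a naive per-pixel reference."""
        cfg = EncodingConfig(gen_type="C", canvas_size=3, quantize=False)
        img = encode(water, elements, pair_params, cfg)
        planes = [
            normalize_matrix(distance_matrix(water).values),
            normalize_matrix(coulomb_matrix(water, "reduced", elements).values),
            normalize_matrix(bond_order_matrix(water, pair_params).values),
        ]
        for c in range(3):
            for i in range(3):
                for j in range(3):
                    assert img.pixels[i, j, c] == planes[c][i, j]

    def test_blockwise_permutation_equivariance(
        self, elements, pair_params, random_molecule_factory, rng
    ):
        """encode(perm . mol) equals the row/col-permuted encode(mol) within
        the molecular block (black margin, fixed offset, no resize)."""
        mol = random_molecule_factory(rng, n_heavy=4)
        n = mol.n_atoms
        perm = rng.permutation(n)
        cfg = EncodingConfig(
            gen_type="A", canvas_size=32, margin_mode="black", quantize=False
        )
        base = encode(mol, elements, pair_params, cfg).pixels
        permuted = encode(mol.permuted(perm), elements, pair_params, cfg).pixels
        np.testing.assert_array_equal(
            permuted[:n, :n], base[np.ix_(perm, perm)]
        )

    @pytest.mark.parametrize("gen_type", list(GEN_TYPES))
    @pytest.mark.parametrize("margin", ["resize", "black", "average"])
    def test_pixel_range_everywhere(
        self, elements, pair_params, random_molecule_factory, rng, gen_type, margin
    ):
        mol = random_molecule_factory(rng)
        cfg = EncodingConfig(gen_type=gen_type, canvas_size=32, margin_mode=margin)
        img = encode(mol, elements, pair_params, cfg, rng)
        assert img.pixels.min() >= 0 and img.pixels.max() <= 255

    def test_fixed_normalization_requires_all_ranges(self, elements, pair_params, water):
        cfg = EncodingConfig(
            gen_type="C", normalization="fixed", fixed_ranges={"distance": (0, 10)}
        )
        with pytest.raises(ConfigError, match="coulomb_reduced|bond_order"):
            encode(water, elements, pair_params, cfg)

    def test_joint_combined_normalization_differs(self, elements, pair_params, water):
        indep = compose_channels(water, elements, pair_params, EncodingConfig(gen_type="A"))
        joint = compose_channels(
            water, elements, pair_params,
            EncodingConfig(gen_type="A", combined_joint_norm=True),
        )
        assert not np.array_equal(indep[:, :, 0], joint[:, :, 0])
        np.testing.assert_array_equal(indep[:, :, 1], joint[:, :, 1])
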