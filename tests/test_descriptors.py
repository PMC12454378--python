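"""Oriented-gradient descriptors: polar gradients, soft-binned cell
histograms, 128-dim assembly, orientation-shift codes and pooling."""

import numpy as np
import pytest

import brainstage as bs
from brainstage.descriptors import (
    CellHistogram,
    DESCRIPTOR_LEN,
    N_BINS,
    default_cell_pairing,
    patch_cell_histograms,
)


# ------------------------------------------------------------------- oracles


def cell_histogram_oracle(mu, theta, n_bins=8):
    """Per-pixel loop implementing circular two-bin soft voting."""
    width = 2.0 * np.pi / n_bins
    bins = np.zeros(n_bins)
    for m, t in zip(mu.ravel(), theta.ravel()):
        p = t / width - 0.5
        b0 = int(np.floor(p))
        frac = p - b0
        bins[b0 % n_bins] += m * (1.0 - frac)
        bins[(b0 + 1) % n_bins] += m * frac
    return bins


def binarize_oracle(v1, v2):
    out = np.zeros((8, 8), dtype=np.uint8)
    for k in range(8):
        for e in range(8):
            out[k, e] = 1 if v1[k] >= v2[(k + e) % 8] else 0
    return out


# ------------------------------------------------------------ polar gradients


def test_polar_axis_conventions():
    # ramp with gradient pointing along +x: theta = 0
    f = bs.polar_gradients(bs.gradient_fixture(0.0, 1.0).pixels)
    inner = np.s_[1:-1, 1:-1]
    np.testing.assert_allclose(f.angle[inner], 0.0, atol=1e-12)
    np.testing.assert_allclose(f.magnitude[inner], 1.0, atol=1e-12)
    # gradient along +y (up): theta = pi/2
    f = bs.polar_gradients(bs.gradient_fixture(np.pi / 2, 1.0).pixels)
    np.testing.assert_allclose(f.angle[inner], np.pi / 2, atol=1e-12)


def test_polar_three_four_five():
    # patch engineered so one pixel sees gx=3, gy=4
    patch = np.zeros((16, 16))
    patch[8, 9], patch[8, 7] = 1.5, -1.5  # gx at (8,8): 3
    patch[7, 8], patch[9, 8] = 2.0, -2.0  # gy at (8,8): 4
    f = bs.polar_gradients(patch)
    assert f.magnitude[8, 8] == pytest.approx(5.0)


def test_polar_round_trip(random_patch):
    from brainstage.harris import image_gradients

    g = image_gradients(random_patch)
    f = bs.polar_gradients(random_patch)
    np.testing.assert_allclose(f.magnitude * np.cos(f.angle), g.gx, atol=1e-9)
    np.testing.assert_allclose(f.magnitude * np.sin(f.angle), g.gy, atol=1e-9)
    assert np.all(f.angle >= 0.0) and np.all(f.angle < 2 * np.pi)


# ------------------------------------------------------------ cell histogram


def test_cell_histogram_pure_and_split_bins():
    width = 2 * np.pi / N_BINS
    field = bs.GradientPolarField(
        magnitude=np.ones((4, 4)), angle=np.full((4, 4), 0.5 * width)
    )  # exactly at bin-0 centre
    h = bs.cell_histogram(field)
    np.testing.assert_allclose(h.bins, [16.0] + [0.0] * 7, atol=1e-12)
    field_mid = bs.GradientPolarField(
        magnitude=np.ones((4, 4)), angle=np.full((4, 4), 1.0 * width)
    )  # midway between bin 0 and bin 1 centres
    h = bs.cell_histogram(field_mid)
    np.testing.assert_allclose(h.bins[:2], [8.0, 8.0], atol=1e-12)
    np.testing.assert_allclose(h.bins[2:], 0.0, atol=1e-12)


def test_cell_histogram_matches_oracle_and_conserves(rng):
    for _ in range(100):
        mu = rng.random((4, 4))
        theta = rng.random((4, 4)) * 2 * np.pi
        field = bs.GradientPolarField(magnitude=mu, angle=theta)
        h = bs.cell_histogram(field)
        np.testing.assert_allclose(h.bins, cell_histogram_oracle(mu, theta), atol=1e-12)
        assert h.bins.sum() == pytest.approx(mu.sum(), abs=1e-9)
        assert np.all(h.bins >= 0)


def test_vectorised_cell_histograms_equal_per_cell_calls(random_patch):
    field = bs.polar_gradients(random_patch)
    fast = patch_cell_histograms(random_patch)
    for h in fast:
        slow = bs.cell_histogram(field, h.cell_origin)
        np.testing.assert_allclose(h.bins, slow.bins, atol=1e-12)


# ----------------------------------------------------------------- assembly


def test_descriptor_length_and_zero_patch(rng):
    for _ in range(5):
        d = bs.assemble_descriptor(rng.random((16, 16)))
        assert d.vector.shape == (DESCRIPTOR_LEN,)
    d0 = bs.assemble_descriptor(np.full((16, 16), 0.42))
    np.testing.assert_allclose(d0.vector, 0.0, atol=1e-12)


def test_descriptor_block_norm_bound(random_patch):
    d = bs.assemble_descriptor(random_patch)
    blocks = d.vector.reshape(4, 4, 8)
    for br in (0, 2):
        for bc in (0, 2):
            norm = np.sqrt(np.sum(blocks[br : br + 2, bc : bc + 2] ** 2))
            assert norm <= 1.0 + 1e-9


def test_descriptor_rotation_equivariance(random_patch):
    """90° patch rotation remaps the 4×4 cell grid and shifts bins by 2
    (90° / 45° per bin); exact with clipping disabled."""
    d = bs.assemble_descriptor(random_patch, clip=None)
    rot = bs.assemble_descriptor(np.rot90(random_patch, 3), clip=None)
    cells = d.vector.reshape(4, 4, 8)
    expected = np.roll(np.rot90(cells, 3, axes=(0, 1)), -2, axis=2)
    np.testing.assert_allclose(rot.vector, expected.reshape(-1), atol=1e-6)


# -------------------------------------------------------------- shift & bits


def test_shift_histogram_rotations():
    h = CellHistogram(bins=np.arange(1.0, 9.0))
    np.testing.assert_array_equal(bs.shift_histogram(h, 0).bins, h.bins)
    np.testing.assert_array_equal(
        bs.shift_histogram(h, 2).bins, [3, 4, 5, 6, 7, 8, 1, 2]
    )
    round_trip = bs.shift_histogram(bs.shift_histogram(h, 7), 1)
    np.testing.assert_array_equal(round_trip.bins, h.bins)
    with pytest.raises(ValueError):
        bs.shift_histogram(h, 8)


def test_binarize_reflexive_and_dominant():
    h = CellHistogram(bins=np.arange(8.0))
    bits = bs.binarize_pair(h, h)
    assert np.all(bits[:, 0] == 1)  # v(k) >= v(k) for eps=0
    big = CellHistogram(bins=np.full(8, 9.0))
    assert np.all(bs.binarize_pair(big, h) == 1)


def test_binarize_matches_double_loop_oracle(rng):
    for _ in range(100):
        v1, v2 = rng.random(8), rng.random(8)
        bits = bs.binarize_pair(CellHistogram(bins=v1), CellHistogram(bins=v2))
        np.testing.assert_array_equal(bits, binarize_oracle(v1, v2))


def test_binarize_totality(rng):
    # for any (k, eps): bit(c1,c2,k,eps) OR bit(c2,c1,(k+eps)%8,(8-eps)%8) = 1
    for _ in range(50):
        c1 = CellHistogram(bins=rng.random(8))
        c2 = CellHistogram(bins=rng.random(8))
        b12 = bs.binarize_pair(c1, c2)
        b21 = bs.binarize_pair(c2, c1)
        for k in range(8):
            for e in range(8):
                assert b12[k, e] | b21[(k + e) % 8, (8 - e) % 8] == 1


def test_patch_shift_code_pairing(random_patch):
    cells = patch_cell_histograms(random_patch)
    code = bs.patch_shift_code(cells)
    assert len(code.pairs) == 24  # 2 * 4 * 3 horizontal + vertical adjacencies
    assert code.bits.shape == (24, 8, 8)
    same = [CellHistogram(bins=np.arange(8.0))] * 16
    code_same = bs.patch_shift_code(same)
    assert np.all(code_same.bits[:, :, 0] == 1)
    single = bs.patch_shift_code(cells, pairing=[(0, 5)])
    np.testing.assert_array_equal(single.bits[0], bs.binarize_pair(cells[0], cells[5]))
    with pytest.raises(ValueError):
        bs.patch_shift_code(cells, pairing=[(0, 16)])


# ------------------------------------------------------------------- pooling


def test_aggregate_definitions(rng):
    a = bs.PatchDescriptor(vector=rng.random(128))
    b = bs.PatchDescriptor(vector=rng.random(128))
    one = bs.aggregate_image_features([a])
    np.testing.assert_array_equal(one.values[:128], a.vector)
    np.testing.assert_array_equal(one.values[128:], a.vector)
    two = bs.aggregate_image_features([a, b])
    np.testing.assert_allclose(two.values[:128], (a.vector + b.vector) / 2)
    np.testing.assert_allclose(two.values[128:], np.maximum(a.vector, b.vector))
    assert two.values.shape == (256,)


def test_aggregate_permutation_invariant(rng):
    descs = [bs.PatchDescriptor(vector=rng.random(128)) for _ in range(9)]
    ref = bs.aggregate_image_features(descs).values
    for _ in range(5):
        perm = [descs[i] for i in rng.permutation(len(descs))]
        np.testing.assert_array_equal(bs.aggregate_image_features(perm).values, ref)


def test_aggregate_empty_warns_zero():
    with pytest.warns(UserWarning):
        fv = bs.aggregate_image_features([])
    assert fv.n_patches == 0
    np.testing.assert_array_equal(fv.values, np.zeros(256))


# ------------------------------------------------------- property tests


from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

finite_mags = hnp.arrays(np.float64, (4, 4), elements=st.floats(0.0, 100.0))
angles = hnp.arrays(
    np.float64, (4, 4), elements=st.floats(0.0, 2 * np.pi, exclude_max=True)
)


@settings(max_examples=50, derandomize=True)
@given(finite_mags, angles)
def test_property_vote_mass_conserved(mu, theta):
    h = bs.cell_histogram(bs.GradientPolarField(magnitude=mu, angle=theta))
    assert h.bins.sum() == pytest.approx(mu.sum(), abs=1e-9)
    assert np.all(h.bins >= -1e-15)


@settings(max_examples=50, derandomize=True)
@given(
    hnp.arrays(np.float64, (8,), elements=st.floats(0.0, 10.0)),
    hnp.arrays(np.float64, (8,), elements=st.floats(0.0, 10.0)),
)
def test_property_binarize_totality(v1, v2):
    b12 = bs.binarize_pair(CellHistogram(bins=v1), CellHistogram(bins=v2))
    b21 = bs.binarize_pair(CellHistogram(bins=v2), CellHistogram(bins=v1))
    for k in range(8):
        for e in range(8):
            assert b12[k, e] | b21[(k + e) % 8, (8 - e) % 8] == 1
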