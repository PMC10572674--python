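"""Descriptor correctness: length contracts, brute-force oracle
equivalence, invariances, and degenerate inputs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import dermtex
from dermtex import DESCRIPTOR_LENGTHS, Descriptor, DescriptorConfig
from dermtex.descriptors import kirsch_masks, kirsch_responses, lbp, ldip, ldn, mbc, phog
from dermtex.errors import ConfigError, SizeError
from oracles import (
    KIRSCH_MASKS,
    kirsch_oracle,
    lbp_oracle,
    ldip_oracle,
    ldn_oracle,
    mbc_oracle,
    phog_oracle,
)

DESCRIPTOR_FNS = {
    Descriptor.LBP: lbp,
    Descriptor.LDN: ldn,
    Descriptor.LDIP: ldip,
    Descriptor.PHOG: phog,
    Descriptor.MBC: mbc,
}


# ---------------------------------------------------------------------------
# Kirsch masks


def test_kirsch_masks_match_literature():
    np.testing.assert_array_equal(kirsch_masks(), np.stack(KIRSCH_MASKS))


def test_kirsch_masks_are_zero_sum():
    assert (kirsch_masks().sum(axis=(1, 2)) == 0).all()


def test_kirsch_constant_plane_gives_zero_responses():
    resp = kirsch_responses(np.full((6, 5), 42, dtype=np.uint8))
    assert resp.shape == (8, 4, 3)
    assert (resp == 0).all()


def test_kirsch_responses_are_linear(rng):
    plane = rng.integers(0, 64, size=(6, 6))
    np.testing.assert_array_equal(kirsch_responses(3 * plane), 3 * kirsch_responses(plane))


def test_kirsch_matches_bruteforce(rng):
    plane = rng.integers(0, 256, size=(5, 5)).astype(np.uint8)
    np.testing.assert_array_equal(kirsch_responses(plane), kirsch_oracle(plane))


# ---------------------------------------------------------------------------
# length contract and dispatch


@pytest.mark.parametrize("shape", [(8, 8), (9, 13), (16, 12)])
@pytest.mark.parametrize("d", list(Descriptor))
def test_length_contract(rng, shape, d):
    plane = rng.integers(0, 256, size=shape).astype(np.uint8)
    fv = dermtex.extract(plane, d)
    assert len(fv) == DESCRIPTOR_LENGTHS[d]
    assert (fv.values >= 0).all()


def test_extract_unknown_descriptor_is_config_error(random_plane):
    with pytest.raises(ConfigError):
        dermtex.extract(random_plane, "SIFT")


def test_bad_mbc_config_is_config_error(random_plane):
    with pytest.raises(ConfigError):
        mbc(np.zeros((8, 8)), cfg=DescriptorConfig(mbc_bins=128))


@pytest.mark.parametrize("d", list(Descriptor))
def test_too_small_plane_is_size_error(d):
    with pytest.raises(SizeError):
        DESCRIPTOR_FNS[d](np.zeros((2, 2), dtype=np.uint8))


# ---------------------------------------------------------------------------
# oracle equivalence


@pytest.mark.parametrize(
    "fn,oracle,min_side",
    [(lbp, lbp_oracle, 3), (ldn, ldn_oracle, 3), (ldip, ldip_oracle, 3), (phog, phog_oracle, 4)],
)
def test_descriptor_matches_bruteforce(rng, fn, oracle, min_side):
    for _ in range(20):
        h = rng.integers(min_side, 9)
        w = rng.integers(min_side, 9)
        plane = rng.integers(0, 256, size=(h, w)).astype(np.uint8)
        np.testing.assert_allclose(fn(plane), oracle(plane), atol=1e-12)


def test_mbc_matches_direct_dft_bruteforce(rng):
    plane = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
    np.testing.assert_allclose(mbc(plane), mbc_oracle(plane), atol=1e-9)


def test_mbc_block_mass_counts_coded_pixels(rng):
    # 16x16 plane -> 14x14 code map -> four 7x7 blocks of 49 pixels each
    plane = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
    vec = mbc(plane, normalize=False).reshape(3, 4, 256)
    np.testing.assert_array_equal(vec.sum(axis=2), np.full((3, 4), 49.0))


# ---------------------------------------------------------------------------
# degenerate inputs forced by the tie-break rules


def test_constant_plane_codes():
    const = np.full((5, 7), 9, dtype=np.uint8)
    h = lbp(const)
    assert h[255] == 1.0 and h.sum() == 1.0  # every neighbor >= center
    h = ldn(const)
    assert h[0] == 1.0  # i_max=0, i_min reassigned to 1 -> compact code 0
    h = ldip(const)
    valid = [c for c in range(256) if bin(c).count("1") == 3]
    assert h[valid.index(7)] == 1.0  # ties pick directions {0,1,2} -> code 7
    np.testing.assert_array_equal(phog(const), np.zeros(168))  # no gradient


def test_phog_step_edge_mass_in_horizontal_bins():
    plane = np.full((8, 8), 10.0)
    plane[:, 4:] = 200.0  # vertical step edge -> gradients along +x (0°)
    vec = phog(plane)
    assert vec.sum() == pytest.approx(1.0)
    nz = np.flatnonzero(vec)
    assert ((nz % 8 == 0) | (nz % 8 == 4)).all()  # only 0° / 180° bins


# ---------------------------------------------------------------------------
# invariances


@settings(deadline=None, max_examples=25, derandomize=True)
@given(arrays(np.uint8, (7, 7), elements=st.integers(0, 199)))
def test_lbp_invariant_under_monotone_intensity_maps(plane):
    # x -> x**2 + 3x + 7 is strictly increasing on [0, 255]
    transformed = plane.astype(np.int64) ** 2 + 3 * plane.astype(np.int64) + 7
    np.testing.assert_array_equal(lbp(plane), lbp(transformed))


@pytest.mark.parametrize("fn", [ldn, ldip])
def test_directional_codes_invariant_under_positive_affine(rng, fn):
    plane = rng.integers(0, 100, size=(9, 9))
    np.testing.assert_array_equal(fn(plane), fn(2 * plane + 31))


def test_unnormalized_mass_equals_interior_pixel_count(rng):
    plane = rng.integers(0, 256, size=(11, 14)).astype(np.uint8)
    for fn in (lbp, ldn, ldip):
        assert fn(plane, normalize=False).sum() == 9 * 12


def test_descriptors_are_deterministic(rng):
    plane = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
    for d in Descriptor:
        a = dermtex.extract(plane, d).values
        b = dermtex.extract(plane.copy(), d).values
        np.testing.assert_array_equal(a, b)


def test_mbc_multiscale_keeps_length_and_normalization(rng):
    plane = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
    vec = mbc(plane, cfg=DescriptorConfig(mbc_scales=2))
    assert vec.shape == (3072,)
    np.testing.assert_allclose(vec.reshape(3, 4, 256).sum(axis=2), 1.0)
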