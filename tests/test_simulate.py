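"""Synthetic-barcode generator: PSF statistics, noise calibration, and exact
cut-and-paste ground truth for every SV type."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodesv.barcode import Barcode, znormalize
from barcodesv.simulate import (
    GroundTruthAlignment,
    NoiseConfig,
    SVSpec,
    add_noise,
    apply_svs,
    generate_random_barcode,
    make_benchmark_pair,
)


class TestGenerateRandomBarcode:
    def test_basic_properties(self):
        bc = generate_random_barcode(500, psf_px=2.0, seed=1)
        assert len(bc) == 500
        assert bc.length_kb == pytest.approx(250.0)
        assert bc.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert bc.values.std() == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        a = generate_random_barcode(200, seed=7)
        b = generate_random_barcode(200, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        c = generate_random_barcode(200, seed=8)
        assert not np.array_equal(a.values, c.values)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"length_px": 0},
            {"length_px": 100, "psf_px": -1.0},
            {"length_px": 100, "kb_per_px": 0.0},
            {"length_px": 15, "psf_px": 2.0},  # shorter than 10 * psf
        ],
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            generate_random_barcode(**kwargs)

    def test_autocorrelation_matches_gaussian_kernel_theory(self):
        # white noise filtered with a Gaussian kernel of sd s has
        # autocorrelation exp(-k^2 / (4 s^2)) at lag k
        psf = 2.0
        lags = (1, 2, 4)
        acc = {k: [] for k in lags}
        for seed in range(200):
            v = generate_random_barcode(500, psf_px=psf, seed=seed).values
            for k in lags:
                acc[k].append(np.mean(v[:-k] * v[k:]))
        for k in lags:
            theory = np.exp(-(k**2) / (4.0 * psf**2))
            assert np.mean(acc[k]) == pytest.approx(theory, abs=0.02)


class TestAddNoise:
    def test_zero_noise_is_identity(self):
        bc = generate_random_barcode(300, seed=0)
        out = add_noise(bc, NoiseConfig(0.0, seed=5))
        np.testing.assert_array_equal(out.values, bc.values)

    @pytest.mark.parametrize("nl", [0.05, 0.10, 0.25])
    def test_calibration_mean_correlation(self, nl):
        # expected Pearson(noisy, clean) = 1 - noise_level
        rs = []
        for seed in range(100):
            bc = generate_random_barcode(500, seed=seed)
            noisy = add_noise(bc, NoiseConfig(nl, seed=10_000 + seed))
            rs.append(np.corrcoef(bc.values, noisy.values)[0, 1])
        assert np.mean(rs) == pytest.approx(1.0 - nl, abs=0.02)

    def test_white_noise_option_also_calibrated(self):
        rs = []
        for seed in range(100):
            bc = generate_random_barcode(500, seed=seed)
            noisy = add_noise(
                bc, NoiseConfig(0.1, convolve_noise_with_psf=False, seed=seed)
            )
            rs.append(np.corrcoef(bc.values, noisy.values)[0, 1])
        assert np.mean(rs) == pytest.approx(0.9, abs=0.02)

    @pytest.mark.parametrize("nl", [-0.1, 1.0, 1.5])
    def test_invalid_noise_level(self, nl):
        with pytest.raises(ValueError):
            NoiseConfig(nl)


def _identity_truth_map(truth):
    return {
        (int(q), int(r), int(o))
        for q, r, o in zip(truth.query_px, truth.ref_px, truth.orientation)
    }


class TestApplySVs:
    def test_empty_sv_list_is_identity(self):
        bc = generate_random_barcode(100, seed=3)
        out, truth = apply_svs(bc, [])
        np.testing.assert_array_equal(out.values, bc.values)
        assert _identity_truth_map(truth) == {(i, i, 1) for i in range(100)}

    def test_deletion_drops_interval(self):
        bc = generate_random_barcode(500, seed=4)
        out, truth = apply_svs(bc, [SVSpec("deletion", 200, 50)])
        assert len(out) == 450
        mapped_refs = set(truth.ref_px.tolist())
        assert mapped_refs == set(range(200)) | set(range(250, 500))
        # left flank identity, right flank shifted by -50
        m = dict(zip(truth.ref_px, truth.query_px))
        assert m[0] == 0 and m[199] == 199
        assert m[250] == 200 and m[499] == 449

    def test_insertion_adds_fresh_material(self):
        bc = generate_random_barcode(500, seed=5)
        out, truth = apply_svs(bc, [SVSpec("insertion", 200, 50)])
        assert len(out) == 550
        assert len(truth) == 500  # inserted pixels carry no truth rows
        covered = set(truth.query_px.tolist())
        assert covered == set(range(200)) | set(range(250, 550))

    def test_inversion_index_arithmetic(self):
        # brute-force bookkeeping: reversing [100, 150) means
        # output position j maps to source 100 + 149 - j
        bc = generate_random_barcode(500, seed=6)
        out, truth = apply_svs(bc, [SVSpec("inversion", 100, 50)])
        assert len(out) == 500
        pairs = {(q, r): o for q, r, o in zip(truth.query_px, truth.ref_px,
                                              truth.orientation)}
        for j in range(500):
            if 100 <= j < 150:
                assert pairs[(j, 249 - j)] == -1
            else:
                assert pairs[(j, j)] == 1

    def test_repeat_duplicates_interval(self):
        bc = generate_random_barcode(300, seed=7)
        out, truth = apply_svs(bc, [SVSpec("repeat", 100, 40, extra=3)])
        assert len(out) == 300 + 2 * 40
        # one-to-many: each repeated source pixel appears three times
        counts = np.bincount(truth.ref_px, minlength=300)
        assert np.all(counts[100:140] == 3)
        assert np.all(counts[:100] == 1) and np.all(counts[140:] == 1)

    def test_translocation_preserves_length_and_content(self):
        bc = generate_random_barcode(300, seed=8)
        out, truth = apply_svs(bc, [SVSpec("translocation", 100, 40, extra=220)])
        assert len(out) == 300
        assert len(truth) == 300
        m = dict(zip(truth.ref_px, truth.query_px))
        # the moved block stays contiguous and in order
        block_positions = [m[r] for r in range(100, 140)]
        assert block_positions == list(
            range(block_positions[0], block_positions[0] + 40)
        )

    def test_cut_and_paste_exactness(self):
        # before noise, every truth pair points at an identical value
        bc = generate_random_barcode(400, seed=9)
        svs = [
            SVSpec("inversion", 50, 40),
            SVSpec("deletion", 150, 30),
            SVSpec("repeat", 250, 30, extra=2),
        ]
        out, truth = apply_svs(bc, svs)
        np.testing.assert_array_equal(
            out.values[truth.query_px], bc.values[truth.ref_px]
        )

    @pytest.mark.parametrize(
        "svs",
        [
            [SVSpec("deletion", 10, 50), SVSpec("inversion", 30, 50)],
            [SVSpec("deletion", 480, 50)],
            [SVSpec("translocation", 100, 50, extra=120)],
        ],
    )
    def test_invalid_svs_rejected(self, svs):
        bc = generate_random_barcode(500, seed=10)
        with pytest.raises(ValueError):
            apply_svs(bc, svs)


class TestMakeBenchmarkPair:
    def test_insertion_pair_geometry(self):
        query, reference, truth = make_benchmark_pair(
            500, ["insertion"], 50, 0.1, seed=1
        )
        assert len(query) == 500
        assert len(reference) == 550
        assert len(truth) == 500  # every query pixel has a true partner

    def test_no_sv_no_noise_identity(self):
        query, reference, truth = make_benchmark_pair(500, [], 0, 0.0, seed=2)
        np.testing.assert_allclose(query.values, reference.values, atol=1e-12)
        assert _identity_truth_map(truth) == {(i, i, 1) for i in range(500)}

    def test_length_conservation_by_type(self):
        for sv_type, expect in [
            ("insertion", 550), ("deletion", 450), ("inversion", 500),
            ("translocation", 500), ("repeat", 550),
        ]:
            _, reference, _ = make_benchmark_pair(
                500, [sv_type], 50, 0.1, seed=3
            )
            assert len(reference) == expect, sv_type

    def test_inversion_translocation_truth_blocks(self):
        _, _, truth = make_benchmark_pair(
            500, ["inversion", "translocation"], 50, 0.1, seed=4
        )
        neg = truth.orientation < 0
        assert neg.sum() == 50  # one reversed block
        # the translocated block is displaced: some + pairs far off-diagonal
        disp = truth.query_px[~neg] - truth.ref_px[~neg]
        assert np.abs(disp).max() >= 40

    def test_deterministic(self):
        a = make_benchmark_pair(500, ["deletion"], 50, 0.1, seed=5)
        b = make_benchmark_pair(500, ["deletion"], 50, 0.1, seed=5)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)
        np.testing.assert_array_equal(a[2].query_px, b[2].query_px)

    def test_swap_roles(self):
        q1, r1, t1 = make_benchmark_pair(500, ["deletion"], 50, 0.1, seed=6)
        q2, r2, t2 = make_benchmark_pair(
            500, ["deletion"], 50, 0.1, seed=6, swap_roles=True
        )
        np.testing.assert_array_equal(q1.values, r2.values)
        np.testing.assert_array_equal(r1.values, q2.values)
        assert set(zip(t1.query_px, t1.ref_px)) == set(zip(t2.ref_px, t2.query_px))


@st.composite
def _sv_layouts(draw):
    """Non-overlapping single-SV layouts on a 200-px barcode."""
    sv_type = draw(st.sampled_from(["insertion", "deletion", "inversion",
                                    "repeat", "translocation"]))
    length = draw(st.integers(5, 40))
    pos = draw(st.integers(10, 150 - length))
    extra = None
    if sv_type == "repeat":
        extra = draw(st.integers(2, 3))
    elif sv_type == "translocation":
        extra = draw(st.sampled_from([2, pos + length + 5, 195]))
    return SVSpec(sv_type, pos, length, extra)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(sv=_sv_layouts(), seed=st.integers(0, 2**16))
def test_sv_editing_conserves_length_and_content(sv, seed):
    """For any single SV, the edited barcode has the predicted length and
    every ground-truth pair points at an identical pre-noise value."""
    bc = generate_random_barcode(200, seed=seed)
    out, truth = apply_svs(bc, [sv], seed=seed + 1)
    delta = {
        "insertion": sv.length_px,
        "deletion": -sv.length_px,
        "inversion": 0,
        "translocation": 0,
        "repeat": (sv.extra - 1) * sv.length_px if sv.extra else 0,
    }[sv.sv_type]
    assert len(out) == 200 + delta
    np.testing.assert_array_equal(
        out.values[truth.query_px], bc.values[truth.ref_px]
    )
    # indices in range, orientation -1 only for inversions
    assert truth.query_px.min() >= 0 and truth.query_px.max() < len(out)
    assert truth.ref_px.min() >= 0 and truth.ref_px.max() < 200
    if sv.sv_type != "inversion":
        assert np.all(truth.orientation == 1)


def test_ground_truth_frame_round_trip():
    truth = GroundTruthAlignment(
        np.array([0, 1, 2]), np.array([5, 4, 3]), np.array([-1, -1, -1])
    )
    back = GroundTruthAlignment.from_frame(truth.to_frame())
    np.testing.assert_array_equal(back.query_px, truth.query_px)
    np.testing.assert_array_equal(back.ref_px, truth.ref_px)
    np.testing.assert_array_equal(back.orientation, truth.orientation)
    # serialized form is 1-based
    assert truth.to_frame()["query_px"].min() == 1
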