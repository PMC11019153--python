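"""GLCM correctness: hand-derived cases, naive-oracle equivalence, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from senotex.synthesis import CONDITION_DEFAULTS, ConditionParams, Image2D, generate_nucleus_detail
from senotex.texture import (
    AUX_FEATURES,
    GLCMParams,
    compute_glcm,
    extract_features,
    features_to_frame,
    glcm_props,
    quantize,
)

PI2 = math.pi / 2


# ---------------------------------------------------------------------------
# independent oracle: naive double-loop pair enumeration + direct formulas
# ---------------------------------------------------------------------------


def naive_glcm_stats(qimg, mask, d, angle, levels):
    """Brute-force masked, symmetrized, normalized GLCM statistics."""
    if angle == 0.0:
        off = (0, d)
    elif angle == PI2:
        off = (d, 0)
    else:
        raise ValueError("oracle covers the two canonical angles only")
    H, W = qimg.shape
    P = np.zeros((levels, levels))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + off[0], c + off[1]
            if r2 < H and c2 < W and mask[r, c] and mask[r2, c2]:
                P[qimg[r, c], qimg[r2, c2]] += 1
                P[qimg[r2, c2], qimg[r, c]] += 1  # symmetrize
    total = P.sum()
    if total == 0:
        return None
    P /= total
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    stats = {
        "contrast": (P * (i - j) ** 2).sum(),
        "dissimilarity": (P * np.abs(i - j)).sum(),
        "homogeneity": (P / (1 + (i - j) ** 2)).sum(),
        "ASM": (P**2).sum(),
    }
    stats["energy"] = math.sqrt(stats["ASM"])
    pi_, pj_ = P.sum(axis=1), P.sum(axis=0)
    mi = (np.arange(levels) * pi_).sum()
    mj = (np.arange(levels) * pj_).sum()
    vi = (((np.arange(levels) - mi) ** 2) * pi_).sum()
    vj = (((np.arange(levels) - mj) ** 2) * pj_).sum()
    if vi <= 0 or vj <= 0:
        stats["correlation"] = 1.0
    else:
        stats["correlation"] = (P * (i - mi) * (j - mj)).sum() / math.sqrt(vi * vj)
    return stats


class TestQuantize:
    def test_boundary_conventions(self):
        q = quantize(np.array([[0.0, 1.0], [0.49, 0.51]]), levels=2)
        np.testing.assert_array_equal(q, [[0, 1], [0, 1]])

    def test_one_maps_to_top_level(self):
        assert quantize(np.array([[1.0]]), levels=64)[0, 0] == 63

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.array([[1.2]]), levels=4)
        with pytest.raises(ValueError):
            quantize(np.array([[-0.2]]), levels=4)

    def test_uniform_image_fills_bins_uniformly(self):
        rng = np.random.default_rng(0)
        vals = rng.random(200_000)
        q = quantize(vals.reshape(400, 500), levels=16)
        counts = np.bincount(q.ravel(), minlength=16)
        expect = len(vals) / 16
        sd = math.sqrt(len(vals) * (1 / 16) * (15 / 16))
        assert np.all(np.abs(counts - expect) < 5 * sd)


class TestHandDerivedCases:
    """The 2x2 checker image enumerated by hand."""

    IMG = np.array([[0, 0], [1, 1]])
    FULL = np.ones((2, 2), dtype=bool)

    def params(self):
        return GLCMParams(distances=(1,), angles=(0.0, PI2), levels=2)

    def test_horizontal_slice_matrix(self):
        t = compute_glcm(self.IMG, self.FULL, self.params())
        P = t.P[:, :, 0, 0]
        np.testing.assert_allclose(P, [[0.5, 0.0], [0.0, 0.5]])

    def test_vertical_slice_matrix(self):
        t = compute_glcm(self.IMG, self.FULL, self.params())
        P = t.P[:, :, 0, 1]
        np.testing.assert_allclose(P, [[0.0, 0.5], [0.5, 0.0]])

    def test_horizontal_statistics(self):
        props = glcm_props(compute_glcm(self.IMG, self.FULL, self.params()))
        assert props[("contrast", 1, 0.0)] == 0.0
        assert props[("ASM", 1, 0.0)] == 0.5
        assert props[("energy", 1, 0.0)] == pytest.approx(math.sqrt(0.5))
        assert props[("correlation", 1, 0.0)] == 1.0

    def test_vertical_statistics(self):
        props = glcm_props(compute_glcm(self.IMG, self.FULL, self.params()))
        assert props[("contrast", 1, PI2)] == 1.0
        assert props[("dissimilarity", 1, PI2)] == 1.0
        assert props[("homogeneity", 1, PI2)] == 0.5
        assert props[("correlation", 1, PI2)] == -1.0

    def test_constant_image_single_diagonal_cell(self):
        img = np.full((4, 4), 2)
        p = GLCMParams(distances=(1, 2), angles=(0.0, PI2), levels=4)
        t = compute_glcm(img, np.ones((4, 4), bool), p)
        props = glcm_props(t)
        for d in (1, 2):
            for a in (0.0, PI2):
                assert t.P[2, 2, p.distances.index(d), p.angles.index(a)] == 1.0
                assert props[("contrast", d, a)] == 0.0
                assert props[("homogeneity", d, a)] == 1.0
                assert props[("ASM", d, a)] == 1.0
                assert props[("energy", d, a)] == 1.0
                assert props[("correlation", d, a)] == 1.0


class TestOracleEquivalence:
    def test_random_masked_images_match_naive_enumeration(self):
        rng = np.random.default_rng(123)
        p = GLCMParams(distances=(1, 2, 3, 5, 16), angles=(0.0, PI2), levels=8)
        n_checked = 0
        for trial in range(100):
            qimg = rng.integers(0, 8, size=(16, 16))
            mask = rng.random((16, 16)) < 0.7
            t = compute_glcm(qimg, mask, p)
            props = glcm_props(t)
            for di, d in enumerate(p.distances):
                for ai, a in enumerate(p.angles):
                    oracle = naive_glcm_stats(qimg, mask, d, a, 8)
                    if oracle is None:
                        assert t.valid_pairs[di, ai] == 0
                        assert math.isnan(props[("contrast", d, a)])
                        continue
                    for s, v in oracle.items():
                        assert props[(s, d, a)] == pytest.approx(v, abs=1e-12)
                        n_checked += 1
        assert n_checked > 1000

    def test_unnormalized_tensor_rejected_by_props(self):
        p = GLCMParams(distances=(1,), angles=(0.0,), levels=4, normed=False)
        t = compute_glcm(np.zeros((4, 4), int), np.ones((4, 4), bool), p)
        with pytest.raises(ValueError):
            glcm_props(t)


class TestInvariants:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_and_cauchy_schwarz(self, seed):
        rng = np.random.default_rng(seed)
        qimg = rng.integers(0, 6, size=(12, 12))
        mask = rng.random((12, 12)) < 0.8
        p = GLCMParams(distances=(1, 3), angles=(0.0, PI2), levels=6)
        t = compute_glcm(qimg, mask, p)
        props = glcm_props(t)
        for di, d in enumerate(p.distances):
            for ai, a in enumerate(p.angles):
                if t.valid_pairs[di, ai] == 0:
                    continue
                # normalization
                assert t.P[:, :, di, ai].sum() == pytest.approx(1.0, abs=1e-9)
                assert 0.0 < props[("homogeneity", d, a)] <= 1.0
                assert 0.0 < props[("ASM", d, a)] <= 1.0
                assert 0.0 < props[("energy", d, a)] <= 1.0
                assert props[("contrast", d, a)] >= 0.0
                assert props[("dissimilarity", d, a)] >= 0.0
                assert -1.0 <= props[("correlation", d, a)] <= 1.0 + 1e-12
                # Cauchy-Schwarz: E|i-j|^2 <= E[(i-j)^2]
                assert (
                    props[("dissimilarity", d, a)] ** 2
                    <= props[("contrast", d, a)] + 1e-12
                )

    def test_features_invariant_to_pixels_outside_mask(self):
        img, truth = generate_nucleus_detail(
            CONDITION_DEFAULTS["proliferating"], seed=17
        )
        mask = truth.nucleus_masks[0]
        qb = tuple(np.quantile(img.pixels, [0.025, 0.995]))
        rec1 = extract_features(img, mask, "sted", q_bounds=qb)
        tampered = img.pixels.copy()
        tampered[~mask] = np.random.default_rng(5).random((~mask).sum()) * 3
        rec2 = extract_features(Image2D(tampered), mask, "sted", q_bounds=qb)
        for name, v in rec1.features.items():
            if name.startswith("glcm_") or name in (
                "mean_fg_intensity_raw", "sd_fg_intensity", "area_px",
            ):
                assert rec2.features[name] == pytest.approx(v, rel=1e-12), name

    def test_homogeneity_rises_with_texture_correlation_length(self):
        means = []
        for corr in (1.0, 2.0, 4.0):
            params = ConditionParams(
                area_mean_px=3000, area_sd_px=100, texture_corr_len_px=corr,
                foci_density=0.0, foci_contrast=0.0, noise_sd=0.0,
            )
            p = GLCMParams(distances=(2,), angles=(0.0,))
            vals = []
            for s in range(50):
                img, truth = generate_nucleus_detail(params, shape=(128, 128), seed=s)
                mask = truth.nucleus_masks[0]
                norm = img.pixels / img.pixels.max()
                props = glcm_props(compute_glcm(quantize(norm, p.levels), mask, p))
                vals.append(props[("homogeneity", 2, 0.0)])
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0]


class TestFeatureRecord:
    def test_sted_profile_has_seventy_features(self):
        img, truth = generate_nucleus_detail(CONDITION_DEFAULTS["senescent"], seed=2)
        rec = extract_features(img, truth.nucleus_masks[0], "sted")
        assert len(rec.features) == 70
        assert sum(k.startswith("glcm_") for k in rec.features) == 60
        assert AUX_FEATURES < set(rec.features)

    def test_confocal_profile_has_fifty_one_features(self):
        img, truth = generate_nucleus_detail(CONDITION_DEFAULTS["senescent"], seed=2)
        rec = extract_features(img, truth.nucleus_masks[0], "confocal")
        assert len(rec.features) == 51
        assert sum(k.startswith("glcm_") for k in rec.features) == 48
        assert {"area_px", "eccentricity", "mean_intensity"} < set(rec.features)

    def test_blank_rows_counted_on_raw_image(self):
        img, truth = generate_nucleus_detail(CONDITION_DEFAULTS["proliferating"], seed=3)
        pix = img.pixels.copy()
        pix[40:52, :] = 0.0
        rec = extract_features(Image2D(pix), truth.nucleus_masks[0], "sted")
        assert rec.features["n_blank_rows"] == 12

    def test_empty_mask_yields_sentinels_and_hint(self):
        img, _ = generate_nucleus_detail(CONDITION_DEFAULTS["proliferating"], seed=4)
        rec = extract_features(img, np.zeros(img.shape, bool), "sted")
        assert rec.qc_hint == "empty-mask"
        assert all(
            math.isnan(v) for k, v in rec.features.items() if k.startswith("glcm_")
        )
        assert rec.features["area_px"] == 0

    def test_frame_carries_provenance_columns(self):
        img, truth = generate_nucleus_detail(CONDITION_DEFAULTS["proliferating"], seed=5)
        rec = extract_features(
            img, truth.nucleus_masks[0], "sted", provenance={"cell_id": 7}
        )
        df = features_to_frame([rec])
        assert df.loc[0, "meta_cell_id"] == 7
        assert df.shape == (1, 71)
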