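import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from forestagb.features import (
    DEFAULT_OFFSETS,
    INDEX_NAMES,
    OPTICAL_BANDS,
    OPTICAL_TEXTURES,
    SAR_BANDS,
    SAR_TEXTURES,
    TERRAIN_NAMES,
    assemble_catalogue,
    catalogue_names,
    glcm_from_window,
    quantize,
    texture_measures,
    vegetation_indices,
)
from forestagb.mapping import RasterStack


def brute_force_glcm(window, levels, offsets):
    """Independent oracle: explicit pair enumeration, symmetrized per offset."""
    acc = np.zeros((levels, levels))
    for dr, dc in offsets:
        counts = np.zeros((levels, levels))
        rows, cols = window.shape
        for r, c in itertools.product(range(rows), range(cols)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                counts[window[r, c], window[rr, cc]] += 1
                counts[window[rr, cc], window[r, c]] += 1
        acc += counts / counts.sum()
    return acc / len(offsets)


def brute_force_measures(p):
    """Hand-summed Haralick statistics over all GLCM cells."""
    n = p.shape[0]
    mean = sum(i * p[i, j] for i in range(n) for j in range(n))
    mu_j = sum(j * p[i, j] for i in range(n) for j in range(n))
    var = sum((i - mean) ** 2 * p[i, j] for i in range(n) for j in range(n))
    var_j = sum((j - mu_j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    out = {
        "Mean": mean,
        "Variance": var,
        "Contrast": sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n)),
        "Dissimilarity": sum(abs(i - j) * p[i, j] for i in range(n) for j in range(n)),
        "Homogeneity": sum(p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n)),
        "Entropy": -sum(
            p[i, j] * np.log(p[i, j]) for i in range(n) for j in range(n) if p[i, j] > 0
        ),
        "SecondMoment": sum(p[i, j] ** 2 for i in range(n) for j in range(n)),
        "MAX": p.max(),
    }
    cov = sum((i - mean) * (j - mu_j) * p[i, j] for i in range(n) for j in range(n))
    out["Correlation"] = cov / np.sqrt(var * var_j) if var * var_j > 0 else 1.0
    out["ASM"] = out["SecondMoment"]
    out["Energy"] = np.sqrt(out["SecondMoment"])
    return out


class TestVegetationIndices:
    def test_equal_bands_give_neutral_indices(self):
        vi = vegetation_indices(0.05, 0.3, 0.3, 0.2)
        assert vi.ndvi == 0.0
        assert vi.dvi == 0.0
        assert vi.rvi == 1.0

    def test_direct_evaluation(self):
        # BLUE=0.04, RED=0.1, NIR=0.5, SWIR=0.2
        vi = vegetation_indices(0.04, 0.1, 0.5, 0.2)
        assert vi.ndvi == pytest.approx(0.4 / 0.6, rel=1e-12)
        assert vi.savi == pytest.approx(1.5 * 0.4 / 1.1, rel=1e-12)
        assert vi.dvi == pytest.approx(0.4, rel=1e-12)
        assert vi.rvi == pytest.approx(5.0, rel=1e-12)
        assert vi.arvi == pytest.approx((0.5 - 0.2 - 0.04) / (0.5 + 0.2 - 0.04), rel=1e-12)
        assert vi.evi == pytest.approx(2.5 * 0.4 / (0.5 + 0.6 - 0.28 + 1.0), rel=1e-12)

    def test_ndpi_weighted_mix(self):
        vi = vegetation_indices(0.04, 0.1, 0.5, 0.2)
        assert vi.ndpi == pytest.approx(0.597444089456869, rel=1e-12)

    def test_zero_denominator_flags_nan(self):
        vi = vegetation_indices(0.0, 0.0, 0.0, 0.0)
        assert np.isnan(vi.ndvi) and np.isnan(vi.rvi)

    def test_printed_vs_standard_forms_differ(self):
        printed = vegetation_indices(0.04, 0.1, 0.5, 0.2)
        std = vegetation_indices(0.04, 0.1, 0.5, 0.2, standard=True)
        assert printed.evi != std.evi
        assert printed.arvi != std.arvi

    @given(
        nir=st.floats(0.01, 1.0),
        red=st.floats(0.01, 1.0),
        swir=st.floats(0.01, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_normalized_indices_bounded(self, nir, red, swir):
        vi = vegetation_indices(0.05, red, nir, swir)
        assert -1.0 <= vi.ndvi <= 1.0
        assert -1.0 <= vi.ndpi <= 1.0
        assert vi.rvi >= 0.0


class TestGLCM:
    def test_constant_window_single_cell(self):
        g = glcm_from_window(np.zeros((4, 4), dtype=int), levels=4)
        assert g[0, 0] == pytest.approx(1.0)
        assert g.sum() == pytest.approx(1.0)

    def test_checkerboard_matches_hand_count(self):
        win = np.array([[0, 1], [1, 0]])
        g = glcm_from_window(win, levels=2, offsets=((0, 1),))
        assert g[0, 1] == pytest.approx(0.5)
        assert g[1, 0] == pytest.approx(0.5)
        assert g[0, 0] == g[1, 1] == 0.0

    def test_transpose_invariance_with_symmetric_offsets(self, rng):
        win = rng.integers(0, 5, (6, 6))
        offs = ((0, 1), (1, 0))
        a = glcm_from_window(win, 5, offs)
        b = glcm_from_window(win.T, 5, offs)
        assert np.allclose(a, b)

    def test_window_smaller_than_offset_reach_raises(self):
        with pytest.raises(ValueError):
            glcm_from_window(np.zeros((1, 1), dtype=int), 2, offsets=((0, 1),))

    def test_out_of_range_levels_raise(self):
        with pytest.raises(ValueError):
            glcm_from_window(np.array([[0, 3], [1, 0]]), levels=2)

    @given(
        win=arrays(np.int64, (4, 4), elements=st.integers(0, 3)),
    )
    @settings(max_examples=60, deadline=None)
    def test_normalization_and_symmetry(self, win):
        g = glcm_from_window(win, 4)
        assert g.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(g, g.T)

    @given(win=arrays(np.int64, (4, 4), elements=st.integers(0, 3)))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, win):
        ours = glcm_from_window(win, 4, DEFAULT_OFFSETS)
        oracle = brute_force_glcm(win, 4, DEFAULT_OFFSETS)
        assert np.allclose(ours, oracle, atol=1e-12)

    def test_matches_skimage(self, rng):
        from skimage.feature import graycomatrix

        win = rng.integers(0, 8, (7, 7)).astype(np.uint8)
        ours = glcm_from_window(win, 8, offsets=((0, 1),))
        ref = graycomatrix(win, [1], [0], levels=8, symmetric=True, normed=True)[:, :, 0, 0]
        assert np.allclose(ours, ref, atol=1e-12)


class TestTextureMeasures:
    def test_delta_distribution(self):
        g = glcm_from_window(np.full((4, 4), 2, dtype=int), levels=4)
        tm = texture_measures(g)
        assert tm["Contrast"] == 0.0
        assert tm["Dissimilarity"] == 0.0
        assert tm["Entropy"] == pytest.approx(0.0, abs=1e-15)
        assert tm["SecondMoment"] == pytest.approx(1.0)
        assert tm["Energy"] == pytest.approx(1.0)
        assert tm["MAX"] == pytest.approx(1.0)
        assert tm["Mean"] == pytest.approx(2.0)

    @pytest.mark.parametrize("levels", [2, 4, 8])
    def test_uniform_glcm_closed_forms(self, levels):
        g = np.full((levels, levels), 1.0 / levels**2)
        tm = texture_measures(g)
        assert tm["Entropy"] == pytest.approx(2 * np.log(levels), rel=1e-12)
        assert tm["SecondMoment"] == pytest.approx(1.0 / levels**2, rel=1e-12)

    def test_checkerboard_hand_summed_values(self):
        g = glcm_from_window(np.array([[0, 1], [1, 0]]), 2, offsets=((0, 1),))
        tm = texture_measures(g)
        assert tm["Mean"] == pytest.approx(0.5)
        assert tm["Variance"] == pytest.approx(0.25)
        assert tm["Contrast"] == pytest.approx(1.0)
        assert tm["Dissimilarity"] == pytest.approx(1.0)
        assert tm["Homogeneity"] == pytest.approx(0.5)
        assert tm["Entropy"] == pytest.approx(np.log(2))
        assert tm["SecondMoment"] == pytest.approx(0.5)
        assert tm["Energy"] == pytest.approx(np.sqrt(0.5))
        assert tm["MAX"] == pytest.approx(0.5)
        assert tm["Correlation"] == pytest.approx(-1.0)

    @given(win=arrays(np.int64, (4, 4), elements=st.integers(0, 3)))
    @settings(max_examples=30, deadline=None)
    def test_measures_match_brute_force(self, win):
        g = glcm_from_window(win, 4)
        ours = texture_measures(g)
        oracle = brute_force_measures(g)
        for k, v in oracle.items():
            assert ours[k] == pytest.approx(v, abs=1e-10), k

    def test_measures_match_skimage_graycoprops(self, rng):
        from skimage.feature import graycomatrix, graycoprops

        win = rng.integers(0, 8, (7, 7)).astype(np.uint8)
        g4 = graycomatrix(win, [1], [0], levels=8, symmetric=True, normed=True)
        ours = texture_measures(glcm_from_window(win, 8, offsets=((0, 1),)))
        for skname, name in [
            ("contrast", "Contrast"),
            ("dissimilarity", "Dissimilarity"),
            ("homogeneity", "Homogeneity"),
            ("ASM", "SecondMoment"),
            ("energy", "Energy"),
            ("correlation", "Correlation"),
        ]:
            assert ours[name] == pytest.approx(float(graycoprops(g4, skname)[0, 0]), abs=1e-10)


class TestCatalogue:
    def test_exactly_86_named_variables(self, small_raster):
        _, (trees, plots, truth), stack, pixels = small_raster
        cat = assemble_catalogue(plots.merge(pixels, on="plot_id"), stack)
        assert len(cat.columns) == 87  # plot_id + 86
        assert list(cat.columns[1:]) == catalogue_names()
        assert not cat.isna().any().any()

    def test_catalogue_decomposition(self):
        names = catalogue_names()
        assert len(names) == 86
        assert len(set(names)) == 86
        assert len(OPTICAL_BANDS) == 6
        assert len(INDEX_NAMES) == 7
        assert len(OPTICAL_BANDS) * len(OPTICAL_TEXTURES) == 48
        assert len(SAR_BANDS) == 2
        assert len(SAR_BANDS) * len(SAR_TEXTURES) == 20
        assert len(TERRAIN_NAMES) == 3

    def test_constant_rasters_give_identical_vectors(self, small_raster):
        _, (trees, plots, truth), stack, pixels = small_raster
        const = RasterStack(bands={k: np.full(stack.shape, 0.3) for k in stack.bands})
        meta = plots.merge(pixels, on="plot_id").assign(altitude=500.0, slope=5.0, canopy_closure=0.5)
        cat = assemble_catalogue(meta, const)
        assert (cat.drop(columns="plot_id").nunique() == 1).all()

    def test_edge_plots_excluded_with_log(self, small_raster):
        _, (trees, plots, truth), stack, pixels = small_raster
        meta = plots.merge(pixels, on="plot_id").copy()
        meta.loc[meta.index[0], ["row", "col"]] = [0, 0]  # no full 7x7 window
        cat = assemble_catalogue(meta, stack)
        assert len(cat) == len(meta) - 1
        assert cat.attrs["excluded"] == [meta["plot_id"].iloc[0]]
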