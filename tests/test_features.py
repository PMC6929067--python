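"""The 452-feature descriptor: registry, window geometry, per-category
contracts and phantom-level sanity properties."""

import dataclasses

import numpy as np
import pytest

from ermmap.core import BScan, ConfigurationError, DataError, ILMContour
from ermmap.features import (
    REGISTRY,
    PCABasis,
    ScanFeatureExtractor,
    WindowGeometry,
    WindowOutOfBounds,
    extract_features,
    extract_window,
    fit_pca_basis,
)
from ermmap.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="module")
def basis():
    rng = np.random.default_rng(0)
    return fit_pca_basis(rng.random((40, 75, 15)))


@pytest.fixture(scope="module")
def erm_scan_setup(erm_phantom):
    vol = erm_phantom.volume()
    contour = ILMContour(erm_phantom.true_ilm[2], 2)
    scan = vol.scan(2)
    geom = WindowGeometry()
    wins = [
        extract_window(scan, contour, c, geom)[0] for c in range(20, 60)
    ]
    return scan, contour, geom, fit_pca_basis(wins)


class TestRegistry:
    def test_total_is_452(self):
        assert len(REGISTRY) == 452
        assert len(REGISTRY.names) == 452
        assert len(set(REGISTRY.names)) == 452

    def test_category_counts(self):
        assert REGISTRY.category_counts() == {
            "pca": 10,
            "glcm": 16,
            "gabor": 160,
            "lbp": 64,
            "laws": 28,
            "window": 75,
            "intensity_global": 13,
            "glih": 5,
            "hog": 81,
        }


class TestWindowGeometry:
    def test_centering_arithmetic(self):
        scan = BScan(np.zeros((200, 100)))
        contour = ILMContour(np.full(100, 120.0))
        geom = WindowGeometry(sub_side=15)
        assert geom.bounds(120.0, 60) == (83, 53)
        window, subs = extract_window(scan, contour, 60, geom)
        assert window.shape == (75, 15)
        assert len(subs) == 5 and all(s.shape == (15, 15) for s in subs)

    def test_border_column_skipped(self):
        scan = BScan(np.zeros((200, 100)))
        contour = ILMContour(np.full(100, 120.0))
        with pytest.raises(WindowOutOfBounds):
            extract_window(scan, contour, 3, WindowGeometry(sub_side=15))

    def test_constant_image_gives_constant_subpatches(self):
        scan = BScan(np.full((200, 100), 0.7))
        contour = ILMContour(np.full(100, 100.0))
        _, subs = extract_window(scan, contour, 50, WindowGeometry())
        assert all(np.all(s == 0.7) for s in subs)

    def test_even_sub_side_rejected(self):
        with pytest.raises(ConfigurationError):
            WindowGeometry(sub_side=14)


class TestPCABasis:
    def test_components_orthonormal(self, basis):
        gram = basis.components @ basis.components.T
        assert np.allclose(gram, np.eye(10), atol=1e-8)

    def test_mean_window_projects_to_zero(self, basis):
        mean_win = basis.mean.reshape(75, 15)
        assert np.allclose(basis.project(mean_win), 0.0, atol=1e-9)

    def test_more_components_reconstruct_better(self):
        rng = np.random.default_rng(3)
        train = rng.random((60, 75, 15))
        held = rng.random((15, 75, 15)).reshape(15, -1)
        errs = {}
        for k in (5, 10):
            b = fit_pca_basis(train, n_components=k)
            proj = (held - b.mean) @ b.components.T
            recon = proj @ b.components + b.mean
            errs[k] = float(((held - recon) ** 2).sum())
        assert errs[10] <= errs[5]

    def test_too_few_windows_rejected(self):
        with pytest.raises(DataError, match="at least 10"):
            fit_pca_basis(np.random.default_rng(0).random((5, 75, 15)))


class TestFeatureVector:
    def test_length_and_finiteness(self, erm_scan_setup):
        scan, contour, geom, basis = erm_scan_setup
        vec = extract_features(scan, contour, 60, geom, basis)
        assert vec.shape == (452,)
        assert np.all(np.isfinite(vec))

    def test_untrained_pca_basis_is_an_error(self, erm_scan_setup):
        scan, contour, geom, _ = erm_scan_setup
        with pytest.raises(ConfigurationError, match="PCA basis"):
            extract_features(scan, contour, 60, geom, None)

    def test_constant_window_glih_one_hot_and_hog_zero(self, basis):
        scan = BScan(np.full((200, 100), 0.5))
        contour = ILMContour(np.full(100, 100.0))
        vec = extract_features(scan, contour, 50, WindowGeometry(), basis)
        glih = vec[REGISTRY.category_slices["glih"]]
        assert np.array_equal(glih, [0, 0, 1, 0, 0])
        assert np.allclose(vec[REGISTRY.category_slices["hog"]], 0.0)

    def test_mirror_invariance_of_histogram_statistics(self, basis):
        rng = np.random.default_rng(7)
        img = rng.random((200, 101))
        mirrored = img[:, ::-1].copy()
        contour = ILMContour(np.full(101, 100.0))
        v1 = extract_features(BScan(img), contour, 50, WindowGeometry(), basis)
        v2 = extract_features(
            BScan(mirrored), contour, 50, WindowGeometry(), basis
        )
        for cat in ("glih", "intensity_global"):
            sl = REGISTRY.category_slices[cat]
            assert np.allclose(v1[sl], v2[sl], atol=1e-12)

    def test_histogram_features_sum_to_one(self, erm_scan_setup):
        scan, contour, geom, basis = erm_scan_setup
        vec = extract_features(scan, contour, 40, geom, basis)
        assert abs(vec[REGISTRY.category_slices["glih"]].sum() - 1.0) < 1e-9
        assert abs(vec[REGISTRY.category_slices["lbp"]].sum() - 1.0) < 1e-9
        win = vec[REGISTRY.category_slices["window"]].reshape(5, 15)
        hists = win[:, 10:]  # the 5-bin histogram block of each sub-window
        assert np.allclose(hists.sum(axis=1), 1.0, atol=1e-9)


class TestPhantomSeparation:
    def test_brighter_erm_raises_above_surface_intensity_features(self):
        """Raising erm_level increases the mean intensity of the sub-windows
        straddling the ILM (where the attached band lies) at ERM points."""
        name = "win3_mean"  # the sub-window straddling the surface
        idx = REGISTRY.names.index(name)
        means = []
        for level in (180.0, 230.0):
            spec = PhantomSpec(
                n_slices=2,
                speckle_sigma=0.0,
                erm_regions=[(0, 2, 30, 95, 0)],
                erm_level=level,
                rng_seed=17,
            )
            ph = generate_phantom(spec)
            vol = ph.volume()
            contour = ILMContour(ph.true_ilm[0], 0)
            scan = vol.scan(0)
            geom = WindowGeometry()
            wins = [
                extract_window(scan, contour, c, geom)[0]
                for c in range(35, 55)
            ]
            ext = ScanFeatureExtractor(scan, geom, fit_pca_basis(wins))
            vals = [
                ext.features_at(contour, c)[idx] for c in range(35, 90, 5)
            ]
            means.append(np.mean(vals))
        assert means[1] > means[0]

    def test_single_window_feature_separates_classes(self, erm_phantom):
        """A threshold on the best single sub-window mean achieves > 0.8
        accuracy between ERM and non-ERM points on a noiseless phantom."""
        vol = erm_phantom.volume()
        geom = WindowGeometry()
        idx = REGISTRY.names.index("win3_mean")
        values, labels = [], []
        for s in (1, 3):
            contour = ILMContour(erm_phantom.true_ilm[s], s)
            scan = vol.scan(s)
            wins = [
                extract_window(scan, contour, c, geom)[0]
                for c in range(10, 50)
            ]
            ext = ScanFeatureExtractor(scan, geom, fit_pca_basis(wins))
            for c in range(8, 120, 2):
                values.append(ext.features_at(contour, c)[idx])
                labels.append(int(erm_phantom.true_map.grid[s, c]))
        values = np.asarray(values)
        labels = np.asarray(labels)
        best_acc = max(
            max(
                np.mean((values > t) == labels),
                np.mean((values <= t) == labels),
            )
            for t in np.quantile(values, np.linspace(0.05, 0.95, 19))
        )
        assert best_acc > 0.8
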