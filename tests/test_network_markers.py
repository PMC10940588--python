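"""Connectivity, centralities and the 21-marker registry.

The Welch coherence implementation is cross-checked against
scipy.signal.coherence; centralities are checked against brute-force row
sums and dense eigendecompositions.
"""

import numpy as np
import pytest
from scipy import signal as sps

from sozmark.io_formats import Recording
from sozmark.network_markers import (
    ConnectivityMatrix,
    band_coherence_matrix,
    centrality_map,
    coherence_band_stack,
    correlation_matrix,
    degree_centrality,
    eigenvector_centrality,
    marker_registry,
    SEVEN_HYBRID_MARKERS,
)
from sozmark.preprocess import windows
from sozmark.spectral_markers import default_bands

RATE = 512.0
BANDS = default_bands(RATE)


class TestCorrelation:
    def test_diagonal_is_unit(self, rng):
        c = correlation_matrix(rng.standard_normal((3, 100)))
        assert np.allclose(np.diag(c.values), 1.0)

    def test_anticorrelated_pair(self, rng):
        x = rng.standard_normal(200)
        c = correlation_matrix(np.vstack([x, -x]))
        assert c.values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_noise_nearly_uncorrelated(self):
        rng = np.random.default_rng(42)
        c = correlation_matrix(rng.standard_normal((2, 1280)))
        assert abs(c.values[0, 1]) < 0.1

    def test_zero_variance_channel_warns_and_zeroes(self, rng):
        sig = np.vstack([rng.standard_normal(100), np.full(100, 2.0)])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            c = correlation_matrix(sig)
        assert c.values[0, 1] == 0.0 and c.values[1, 1] == 1.0


class TestCoherence:
    def test_identical_channels_fully_coherent(self, rng):
        x = rng.standard_normal(1280)
        c = band_coherence_matrix(np.vstack([x, x]), BANDS["alpha"], RATE)
        assert c.values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_values_bounded(self, rng):
        c = band_coherence_matrix(rng.standard_normal((4, 1280)), BANDS["beta"], RATE)
        assert np.all(c.values >= 0) and np.all(c.values <= 1)
        assert np.allclose(c.values, c.values.T)

    def test_shared_alpha_component_raises_alpha_coherence(self):
        rng = np.random.default_rng(3)
        t = np.arange(1280) / RATE
        shared = np.sin(2 * np.pi * 10 * t)
        sig = np.vstack(
            [shared + 0.8 * rng.standard_normal(1280),
             shared + 0.8 * rng.standard_normal(1280)]
        )
        stack = coherence_band_stack(sig, [BANDS["alpha"], BANDS["gamma"]], RATE)
        assert stack["alpha"][0, 1] > stack["gamma"][0, 1]

    def test_matches_scipy_welch_oracle(self, rng):
        """Hand-rolled segment-averaged coherence equals scipy's estimator."""
        sig = rng.standard_normal((3, 1280))
        stack = coherence_band_stack(sig, list(BANDS.values()), RATE)
        freqs, cxy = sps.coherence(
            sig[0], sig[2], fs=RATE, nperseg=256, noverlap=128, window="hann"
        )
        for name, band in BANDS.items():
            mask = band.bin_mask(freqs, RATE / 2)
            assert stack[name][0, 2] == pytest.approx(cxy[mask].mean(), rel=1e-9)

    def test_too_short_window_rejected(self, rng):
        with pytest.raises(ValueError, match="segments"):
            band_coherence_matrix(rng.standard_normal((2, 300)), BANDS["alpha"], RATE)


class TestDegreeCentrality:
    def _conn(self, w):
        return ConnectivityMatrix(values=np.asarray(w, float), basis="coherence")

    def test_complete_unit_graph(self):
        w = np.ones((4, 4))
        assert np.allclose(degree_centrality(self._conn(w)), 1.0)

    def test_star_graph(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        np.fill_diagonal(w, 1.0)
        dc = degree_centrality(self._conn(w))
        assert dc[0] == pytest.approx(1.0)
        assert np.allclose(dc[1:], 1 / 3)

    def test_matches_row_sum_oracle(self, rng):
        w = rng.random((7, 7))
        w = (w + w.T) / 2
        dc = degree_centrality(self._conn(w))
        oracle = np.array(
            [sum(w[i, j] for j in range(7) if j != i) / 6 for i in range(7)]
        )
        assert np.allclose(dc, oracle, atol=1e-12)

    def test_correlation_basis_uses_absolute_weights(self):
        conn = ConnectivityMatrix(
            values=np.array([[1.0, -0.5], [-0.5, 1.0]]), basis="correlation"
        )
        assert degree_centrality(conn) == pytest.approx([0.5, 0.5])

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            degree_centrality(self._conn(np.ones((1, 1))))


class TestEigenvectorCentrality:
    def test_two_node_symmetric(self):
        v, lam = eigenvector_centrality(
            np.array([[0.0, 1.0], [1.0, 0.0]]), return_eigenvalue=True
        )
        assert np.allclose(v, 1 / np.sqrt(2))
        assert lam == pytest.approx(1.0)

    def test_star_center_dominates(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        v = eigenvector_centrality(w)
        assert np.all(v[0] > v[1:])
        evals, evecs = np.linalg.eigh(w)
        assert np.allclose(v, np.abs(evecs[:, -1]), atol=1e-8)

    def test_matches_dense_eigendecomposition(self, rng):
        w = rng.random((10, 10))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        v, lam = eigenvector_centrality(w, return_eigenvalue=True)
        evals, evecs = np.linalg.eigh(w)
        assert lam == pytest.approx(evals[-1], abs=1e-8)
        assert np.allclose(v, np.abs(evecs[:, -1]), atol=1e-8)

    def test_fixed_point_residual(self, rng):
        w = rng.random((8, 8))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        v, lam = eigenvector_centrality(w, return_eigenvalue=True)
        assert np.linalg.norm(w @ v - lam * v) < 1e-8


class TestCentralityMap:
    def _ws(self, sig):
        rec = Recording(signal=sig, rate=RATE,
                        channel_labels=[f"c{i}" for i in range(sig.shape[0])])
        return windows(rec, 2500.0, 500.0)

    def test_degree_map_normalized_columns(self, rng):
        spec = next(s for s in marker_registry() if s.marker_id == "dc_coh_beta")
        mm = centrality_map(self._ws(rng.standard_normal((4, 1280 + 512))), spec)
        assert mm.normalized
        for col in mm.values.T:
            assert col.min() == 0.0 and col.max() == 1.0

    def test_eigenvector_map_unit_norm_columns(self, rng):
        spec = next(s for s in marker_registry() if s.marker_id == "evc_corr")
        mm = centrality_map(self._ws(rng.standard_normal((4, 1280 + 512))), spec)
        assert not mm.normalized
        assert np.allclose(np.linalg.norm(mm.values, axis=0), 1.0)

    def test_permutation_equivariance(self, rng):
        sig = rng.standard_normal((5, 1280))
        perm = np.array([3, 0, 4, 1, 2])
        for mid in ("dc_corr", "evc_coh_gamma"):
            spec = next(s for s in marker_registry() if s.marker_id == mid)
            base = centrality_map(self._ws(sig), spec).values
            swapped = centrality_map(self._ws(sig[perm]), spec).values
            assert np.allclose(swapped, base[perm], atol=1e-8)

    def test_soz_gamma_coherence_degree_elevated(self, tiny_patient):
        from sozmark.pipeline import compute_marker_matrices, preprocess_recording

        rec, _ = tiny_patient
        mm = compute_marker_matrices(rec, ["dc_coh_gamma"])["dc_coh_gamma"]
        _, _, ws = preprocess_recording(rec)
        onset_sample = int(round(ws.source.onset_s * ws.source.rate))
        post = [i for i, (s, e) in enumerate(ws.windows) if s >= onset_sample]
        soz = rec.soz_mask
        assert mm.values[soz][:, post].mean() > mm.values[~soz][:, post].mean()


class TestRegistry:
    def test_exactly_21_markers_with_expected_families(self):
        specs = marker_registry()
        assert len(specs) == 21
        ids = [s.marker_id for s in specs]
        assert len(set(ids)) == 21
        families = {}
        for s in specs:
            families[s.family] = families.get(s.family, 0) + 1
        assert families == {
            "fragility": 1,
            "spectral": 6,
            "degree_centrality": 7,
            "eigenvector_centrality": 7,
        }

    def test_eigenvector_family_exempt_from_normalization(self):
        for s in marker_registry():
            assert s.normalized == (s.family != "eigenvector_centrality")

    def test_147_combinations_enumerable(self):
        from sozmark.gnn_classifier import MODEL_IDS

        combos = [(s.marker_id, m) for s in marker_registry() for m in MODEL_IDS]
        assert len(combos) == 147
        assert len(set(combos)) == 147

    def test_seven_hybrid_markers_are_fragility_plus_bands(self):
        assert len(SEVEN_HYBRID_MARKERS) == 7
        assert SEVEN_HYBRID_MARKERS[0] == "fragility"
        assert all(m.startswith("pow_") for m in SEVEN_HYBRID_MARKERS[1:])
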