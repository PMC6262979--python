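"""PCA/ICA detectors: spectra, null thresholds, rotation, thresholding."""

import numpy as np
import pytest

import assemblybench as ab
from assemblybench.detectors.ica import (
    circular_shift_null,
    ica_rotate,
    ks_filter,
    mp_threshold,
    threshold_vectors,
    zscore_rows,
)


def _planted_dff(rng, n=60, p=1200, members=(range(0, 10), range(10, 20)), amp=3.0):
    """Noise plus two coactive blocks firing in disjoint random bins."""
    x = rng.standard_normal((n, p))
    for block in members:
        bins = rng.choice(p, 30, replace=False)
        x[np.ix_(list(block), bins)] += amp
    return x


class TestZscore:
    def test_rows_standardised(self):
        X, kept = zscore_rows(np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 7.0]]))
        np.testing.assert_allclose(X.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(X.std(axis=1), 1, atol=1e-12)
        np.testing.assert_array_equal(kept, [0, 1])

    def test_constant_row_dropped(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            X, kept = zscore_rows(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))
        assert X.shape[0] == 1 and list(kept) == [1]

    def test_autocorrelation_diagonal_is_one(self, rng):
        X, _ = zscore_rows(rng.standard_normal((5, 100)))
        diag = np.diag(X @ X.T / X.shape[1])
        np.testing.assert_allclose(diag, 1.0, atol=1e-12)


class TestMpThreshold:
    def test_limit_small_ratio(self):
        assert mp_threshold(1, 10**8) == pytest.approx(1.0, abs=1e-3)

    def test_benchmark_geometry(self):
        assert mp_threshold(469, 7200) == pytest.approx(1.576, abs=0.002)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            mp_threshold(10, 0)
        with pytest.raises(ValueError):
            mp_threshold(100, 50)

    def test_iid_spectrum_below_edge(self, rng):
        X, _ = zscore_rows(rng.standard_normal((100, 2000)))
        top = np.linalg.eigvalsh(X @ X.T / 2000).max()
        assert top <= mp_threshold(100, 2000) * 1.02


class TestCircularShiftNull:
    def test_shift_preserves_row_autocorrelation(self, rng):
        # circular shifts leave each row's circular autocorrelation intact
        x = rng.standard_normal(64)
        shifted = np.roll(x, 17)
        ac = lambda v: np.fft.ifft(np.abs(np.fft.fft(v)) ** 2).real
        np.testing.assert_allclose(ac(x), ac(shifted), atol=1e-9)

    def test_iid_data_yields_no_significant_components(self, rng):
        X, _ = zscore_rows(rng.standard_normal((40, 800)))
        thr = circular_shift_null(X, n_rounds=100, rng_seed=0)
        eig = np.linalg.eigvalsh(X @ X.T / 800)
        # bulk-percentile null: only level-alpha false positives expected
        assert (eig > thr).sum() <= int(0.05 * len(eig)) + 2

    def test_planted_assembly_exceeds_threshold(self, rng):
        x = _planted_dff(rng, members=(range(0, 15),), amp=4.0)
        X, _ = zscore_rows(x)
        thr = circular_shift_null(X, n_rounds=100, rng_seed=0)
        assert np.linalg.eigvalsh(X @ X.T / X.shape[1]).max() > thr


class TestIcaRotate:
    def test_single_component_spans_same_line(self, rng):
        x = _planted_dff(rng, members=(range(0, 12),))
        X, _ = zscore_rows(x)
        ev, evec = np.linalg.eigh(X @ X.T / X.shape[1])
        comp = evec[:, -1:]
        out = ica_rotate(comp, X, rng_seed=0)
        cos = abs(out[0] @ comp[:, 0])
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_assemblies_unmixed(self, rng):
        x = _planted_dff(rng, amp=4.0)
        X, kept = zscore_rows(x)
        ev, evec = np.linalg.eigh(X @ X.T / X.shape[1])
        comps = evec[:, -2:]
        vecs = ica_rotate(comps, X, rng_seed=1)
        cfg = threshold_vectors(vecs, neuron_indices=kept)
        found = sorted(cfg.member_sets(), key=min)
        assert found[0] <= frozenset(range(0, 10)) or found[0] == frozenset(range(0, 10))
        assert len(found) == 2
        # each recovered vector loads on exactly one planted block
        assert found[0] & found[1] == frozenset()

    def test_vectors_stay_in_component_span(self, rng):
        x = _planted_dff(rng)
        X, _ = zscore_rows(x)
        ev, evec = np.linalg.eigh(X @ X.T / X.shape[1])
        comps = evec[:, -2:]
        vecs = ica_rotate(comps, X, rng_seed=2)
        proj = comps @ (comps.T @ vecs.T)
        assert np.linalg.norm(proj - vecs.T) < 1e-8


class TestThresholdVectors:
    def test_one_hot_vector(self):
        v = np.zeros(100)
        v[1] = 1.0
        cfg = threshold_vectors(v[None, :])
        assert cfg.member_sets() == [frozenset({1})]

    def test_constant_vector_dropped(self):
        cfg = threshold_vectors(np.ones((1, 50)))
        assert len(cfg) == 0

    def test_scale_invariance(self, rng):
        v = rng.standard_normal(80)
        v[:5] += 6.0
        a = threshold_vectors(v[None, :]).member_sets()
        b = threshold_vectors(10.0 * v[None, :]).member_sets()
        assert a == b


class TestKsFilter:
    def test_gaussian_vector_dropped(self, rng):
        v = rng.standard_normal((1, 469))
        assert len(ks_filter(v, alpha=1e-10)) == 0

    def test_assembly_like_vector_retained(self, rng):
        # realistic unit-norm assembly vector: 16 strong loadings over a
        # tightly concentrated noise floor
        v = 0.02 * rng.standard_normal(469)
        v[:16] = 0.25
        assert len(ks_filter(v[None, :], alpha=1e-10)) == 1

    def test_alpha_one_keeps_all(self, rng):
        v = rng.standard_normal((3, 100))
        assert len(ks_filter(v, alpha=1.0)) == 3


class TestDetectIca:
    def test_pure_noise_finds_nothing(self, rng):
        x = rng.standard_normal((50, 1000))
        cfg = ab.detect_ica(x, variant="MP", rng_seed=0)
        assert len(cfg) == 0

    def test_duplicated_bins_give_identical_result(self, rng):
        x = _planted_dff(rng, n=40, p=600, amp=4.0)
        a = ab.detect_ica(x, variant="MP", rng_seed=0)
        b = ab.detect_ica(np.hstack([x, x]), variant="MP", rng_seed=0)
        assert sorted(a.member_sets(), key=min) == sorted(b.member_sets(), key=min)

    def test_neuron_permutation_equivariance(self, rng):
        x = _planted_dff(rng, n=40, p=600, amp=4.0)
        perm = rng.permutation(40)
        a = ab.detect_ica(x, variant="MP", rng_seed=0)
        b = ab.detect_ica(x[perm], variant="MP", rng_seed=0)
        inv = np.empty(40, dtype=int)
        inv[perm] = np.arange(40)
        remapped = sorted(
            (frozenset(int(perm[i]) for i in s) for s in b.member_sets()), key=min
        )
        assert remapped == sorted(a.member_sets(), key=min)

    def test_cs_and_mp_agree_on_planted_data(self, rng):
        x = _planted_dff(rng, n=40, p=800, amp=4.0)
        a = ab.detect_ica(x, variant="CS", rng_seed=0, n_rounds=100)
        b = ab.detect_ica(x, variant="MP", rng_seed=0)
        assert abs(len(a) - len(b)) <= 1

    def test_report_counts_significant(self, rng):
        x = _planted_dff(rng, amp=4.0)
        cfg, report = ab.detect_ica(x, variant="MP", rng_seed=0, return_report=True)
        assert report.n_significant >= 2
        assert report.eigenvalues[0] >= report.eigenvalues[1]
        assert report.significant_components.shape[1] == report.n_significant
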