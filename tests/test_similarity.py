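import math

import numpy as np
import pytest

from npscreen.chem_core import Fingerprint
from npscreen.similarity import (
    SmsfWeights,
    baseline_fingerprint_predictor,
    cosine_similarity,
    fp_similarity,
    optimize_weights,
    simplex_grid,
    smsf,
    top_n_jaccard,
    top_peaks,
)


def _fp(bits):
    arr = np.array(bits, dtype=float)
    return Fingerprint(arr, "binary", len(arr))


def _random_spectrum(rng, make_spectrum, n_peaks=12, max_mz=700):
    bins = rng.choice(np.arange(1, max_mz + 1), size=n_peaks, replace=False)
    intens = rng.uniform(0.01, 1.0, size=n_peaks)
    return make_spectrum({int(b): float(i) for b, i in zip(bins, intens)})


class TestCosine:
    def test_identical_is_one(self, make_spectrum):
        s = make_spectrum({50: 1.0, 77: 0.4})
        assert cosine_similarity(s, s) == pytest.approx(1.0)

    def test_disjoint_is_zero(self, make_spectrum):
        a = make_spectrum({50: 1.0})
        b = make_spectrum({77: 1.0})
        assert cosine_similarity(a, b) == 0.0

    def test_partial_overlap(self, make_spectrum):
        a = make_spectrum({50: 1.0})
        b = make_spectrum({50: 1.0, 77: 1.0})
        assert cosine_similarity(a, b) == pytest.approx(1 / math.sqrt(2))

    def test_empty_spectrum_error(self, make_spectrum):
        from npscreen.spectra import MassSpectrum

        a = make_spectrum({50: 1.0})
        empty = MassSpectrum(np.zeros(701))
        with pytest.raises(ValueError):
            cosine_similarity(a, empty)


class TestTopNJaccard:
    def test_identical_is_one(self, make_spectrum):
        s = make_spectrum({105: 1.0, 77: 0.8, 51: 0.5, 150: 0.3, 39: 0.1})
        assert top_n_jaccard(s, s) == 1.0

    def test_disjoint_top4_is_zero(self, make_spectrum):
        a = make_spectrum({10: 1.0, 20: 0.9, 30: 0.8, 40: 0.7})
        b = make_spectrum({11: 1.0, 21: 0.9, 31: 0.8, 41: 0.7})
        assert top_n_jaccard(a, b) == 0.0

    def test_two_of_six(self, make_spectrum):
        # T(a)={105,77,51,150}, T(b)={105,77,91,120}: |I|=2, |U|=6
        a = make_spectrum({105: 1.0, 77: 0.9, 51: 0.8, 150: 0.7, 39: 0.1})
        b = make_spectrum({105: 1.0, 77: 0.9, 91: 0.8, 120: 0.7, 65: 0.1})
        assert top_n_jaccard(a, b) == pytest.approx(2 / 6)

    def test_tie_broken_by_lower_mz(self, make_spectrum):
        s = make_spectrum({10: 1.0, 20: 0.5, 30: 0.5, 40: 0.5, 50: 0.5})
        assert top_peaks(s, 2) == frozenset({10, 20})

    def test_fewer_peaks_than_n(self, make_spectrum):
        a = make_spectrum({50: 1.0, 60: 0.5})
        assert top_peaks(a, 4) == frozenset({50, 60})
        assert top_n_jaccard(a, a) == 1.0

    def test_matches_brute_force_on_random_pairs(self, make_spectrum):
        """1000 random spectrum pairs against an independent sort/slice/set
        computation."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            a = _random_spectrum(rng, make_spectrum, n_peaks=int(rng.integers(2, 15)))
            b = _random_spectrum(rng, make_spectrum, n_peaks=int(rng.integers(2, 15)))
            def brute_top(s, n=4):
                pairs = sorted(
                    ((inten, -mz) for mz, inten in s.peaks()), reverse=True
                )
                return {-negmz for _, negmz in pairs[:n]}
            ta, tb = brute_top(a), brute_top(b)
            expected = len(ta & tb) / len(ta | tb)
            assert top_n_jaccard(a, b) == pytest.approx(expected)


class TestFpSimilarity:
    def test_identical_is_one(self):
        p = _fp([1, 1, 0, 0])
        assert fp_similarity(p, p) == 1.0

    def test_disjoint_is_zero(self):
        assert fp_similarity(_fp([1, 1, 0, 0]), _fp([0, 0, 1, 1])) == 0.0

    def test_one_third(self):
        assert fp_similarity(_fp([1, 1, 0, 0]), _fp([1, 0, 1, 0])) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_zero(self):
        assert fp_similarity(_fp([0, 0]), _fp([0, 0])) == 0.0

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError, match="length"):
            fp_similarity(_fp([1, 0]), _fp([1, 0, 1]))

    def test_probabilistic_binarized_at_half(self):
        p = Fingerprint(np.array([0.6, 0.4, 0.5, 0.1]), "probabilistic", 4)
        q = _fp([1, 0, 1, 0])
        assert fp_similarity(p, q) == 1.0


class TestSmsf:
    def test_all_ones(self):
        assert smsf(1.0, 1.0, 1.0, SmsfWeights(0.2, 0.3, 0.5)) == pytest.approx(1.0)

    def test_degenerate_weights_return_cosine(self):
        assert smsf(0.8, 0.1, 0.2, SmsfWeights(1.0, 0.0, 0.0)) == 0.8

    def test_equal_thirds(self):
        w = SmsfWeights()
        assert smsf(0.8, 0.5, 0.6, w) == pytest.approx(0.6333, abs=1e-4)

    def test_component_out_of_range_error(self):
        with pytest.raises(ValueError):
            smsf(1.2, 0.5, 0.5)

    def test_weights_must_be_convex(self):
        with pytest.raises(ValueError):
            SmsfWeights(0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            SmsfWeights(-0.2, 0.6, 0.6)

    def test_monotone_in_each_component(self):
        rng = np.random.default_rng(3)
        w = SmsfWeights(0.5, 0.3, 0.2)
        for _ in range(200):
            c, j, f = rng.uniform(0, 1, 3)
            base = smsf(c, j, f, w)
            bump = rng.uniform(0, 1 - max(c, j, f))
            assert smsf(min(c + bump, 1), j, f, w) >= base
            assert smsf(c, min(j + bump, 1), f, w) >= base
            assert smsf(c, j, min(f + bump, 1), w) >= base


class TestMetricProperties:
    def test_symmetry_and_bounds(self, make_spectrum):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = _random_spectrum(rng, make_spectrum)
            b = _random_spectrum(rng, make_spectrum)
            for metric in (cosine_similarity, top_n_jaccard):
                ab, ba = metric(a, b), metric(b, a)
                assert ab == pytest.approx(ba)
                assert 0.0 <= ab <= 1.0
            bits_a = _fp(rng.integers(0, 2, 64))
            bits_b = _fp(rng.integers(0, 2, 64))
            assert fp_similarity(bits_a, bits_b) == pytest.approx(
                fp_similarity(bits_b, bits_a)
            )

    def test_self_similarity_is_one(self, make_spectrum):
        rng = np.random.default_rng(13)
        s = _random_spectrum(rng, make_spectrum)
        assert cosine_similarity(s, s) == pytest.approx(1.0)
        assert top_n_jaccard(s, s) == 1.0


class TestBaselineFingerprintPredictor:
    def test_exact_match_k1(self, make_spectrum):
        ref_s = make_spectrum({50: 1.0, 77: 0.5})
        other = make_spectrum({200: 1.0})
        fp1, fp2 = _fp([1, 0, 1, 0]), _fp([0, 1, 0, 1])
        predict = baseline_fingerprint_predictor([(ref_s, fp1), (other, fp2)], k=1)
        out = predict(ref_s)
        assert np.array_equal(out.binarized().bits, fp1.bits)

    def test_equal_weights_give_mean(self, make_spectrum):
        s = make_spectrum({50: 1.0})
        fp1, fp2 = _fp([1, 0, 1, 0]), _fp([1, 1, 0, 0])
        predict = baseline_fingerprint_predictor([(s, fp1), (s, fp2)], k=2)
        out = predict(s)
        assert out.mode == "probabilistic"
        assert np.allclose(out.bits, [1.0, 0.5, 0.5, 0.0])

    def test_zero_similarity_reference_gets_zero_weight(self, make_spectrum):
        near = make_spectrum({50: 1.0})
        far = make_spectrum({300: 1.0})
        fp1, fp2 = _fp([1, 0, 0, 0]), _fp([0, 0, 0, 1])
        predict = baseline_fingerprint_predictor([(near, fp1), (far, fp2)], k=2)
        out = predict(make_spectrum({50: 1.0}))
        assert np.allclose(out.bits, fp1.bits)

    def test_empty_reference_error(self):
        with pytest.raises(ValueError):
            baseline_fingerprint_predictor([], k=1)


class TestOptimizeWeights:
    def test_simplex_grid_half_step_has_six_points(self):
        grid = simplex_grid(0.5)
        assert len(grid) == 6
        assert all(abs(sum(p) - 1) < 1e-12 for p in grid)

    def _query(self, make_spectrum, flip_fp=False):
        analyte = make_spectrum({100: 1.0, 50: 0.5})
        analyte_fp = _fp([1, 1, 0, 0])
        truth = ("truth", make_spectrum({100: 1.0, 50: 0.5}),
                 _fp([0, 0, 1, 1]) if flip_fp else _fp([1, 1, 0, 0]))
        decoy = ("decoy", make_spectrum({200: 1.0, 150: 0.5}),
                 _fp([1, 1, 0, 0]) if flip_fp else _fp([0, 0, 1, 1]))
        return (analyte, analyte_fp, [truth, decoy], "truth")

    def test_spectrum_discriminative_fixture(self, make_spectrum):
        # only the spectrum metrics rank truth first; fingerprint is misleading
        w = optimize_weights([self._query(make_spectrum, flip_fp=True)], grid_step=0.5)
        assert w.w_fp < 1.0
        # check the returned weights actually rank truth first
        from npscreen.evaluation import RankOutcome
        analyte, afp, cands, true_id = self._query(make_spectrum, flip_fp=True)
        scores = {
            cid: smsf(
                cosine_similarity(analyte, cs), top_n_jaccard(analyte, cs),
                fp_similarity(afp, cf), w,
            )
            for cid, cs, cf in cands
        }
        assert scores["truth"] > scores["decoy"]

    def test_tie_break_toward_cosine(self, make_spectrum):
        # every metric ranks truth first: all grid points tie, cosine-heavy wins
        w = optimize_weights([self._query(make_spectrum)], grid_step=0.5)
        assert (w.w_cos, w.w_jac, w.w_fp) == (1.0, 0.0, 0.0)

    def test_true_candidate_must_be_present(self, make_spectrum):
        analyte, afp, cands, _ = self._query(make_spectrum)
        with pytest.raises(ValueError, match="absent"):
            optimize_weights([(analyte, afp, cands, "missing")], grid_step=0.5)

    def test_no_queries_error(self):
        with pytest.raises(ValueError):
            optimize_weights([], grid_step=0.5)
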