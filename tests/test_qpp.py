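import numpy as np
import pytest

import braindyn as bd
from braindyn.errors import DegenerateInputError, InvalidArgumentError


def planted_motif_scan(n_rois=20, n_trs=1200, window=28, period=84,
                       amplitude=3.0, noise=0.3, seed=0):
    """Low-noise scan with a strong traveling motif tiled every ``period`` TRs."""
    rng = np.random.default_rng(seed)
    x = noise * rng.normal(size=(n_rois, n_trs))
    t = np.arange(window)
    centers = window * (0.2 + 0.6 * np.arange(n_rois) / (n_rois - 1))
    motif = np.exp(-((t[None] - rng.permutation(centers)[:, None]) ** 2)
                   / (2 * (window / 8) ** 2))
    motif *= np.where(rng.random(n_rois) < 0.5, -1, 1)[:, None]
    for start in range(window, n_trs - window, period):
        x[:, start:start + window] += amplitude * motif
    return x, motif


def aligned_corr(a, b):
    return bd.align_templates(a, b)[1]


class TestFindQPP:
    def test_recovers_planted_motif(self):
        # contiguous tiling: any template phase is a circular shift of the motif
        x, motif = planted_motif_scan(period=28)
        q = bd.find_qpp(x, tr=0.72, window_s=28 * 0.72, seed=1)
        assert q.window == 28
        assert aligned_corr(q.template, motif) > 0.95

    def test_peak_spacing_matches_planting_period(self):
        x, _ = planted_motif_scan(period=84)
        q = bd.find_qpp(x, tr=0.72, window_s=28 * 0.72, seed=1)
        spacings = np.diff(np.sort(q.peaks))
        # dominant spacing within +-2 TRs of the planted period
        assert abs(np.median(spacings) - 84) <= 2

    def test_constant_signal_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            bd.find_qpp(np.ones((5, 300)), tr=0.72, seed=0)

    def test_white_noise_rarely_exceeds_final_threshold(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 1200))
        q = bd.find_qpp(x, tr=0.72, seed=3)
        assert (q.corr_vector > 0.2).mean() < 0.05

    def test_short_scan_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bd.find_qpp(np.random.default_rng(0).normal(size=(5, 100)),
                        tr=0.72, window_s=20.0, seed=0)

    def test_deterministic_per_seed(self):
        x, _ = planted_motif_scan(seed=5)
        a = bd.find_qpp(x, tr=0.72, seed=9)
        b = bd.find_qpp(x, tr=0.72, seed=9)
        assert np.array_equal(a.template, b.template)
        assert np.array_equal(a.peaks, b.peaks)


class TestAlignTemplates:
    def test_self_alignment_at_planted_shift(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(6, 20))
        b = np.roll(a, -5, axis=1)
        shift, corr = bd.align_templates(a, b)
        assert shift == 5
        assert corr == pytest.approx(1.0)

    def test_negated_template_anticorrelates(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(4, 15))
        shift, corr = bd.align_templates(a, -a)
        # best achievable shift found by exhaustive loop
        best = max(
            np.corrcoef(a.ravel(), np.roll(-a, s, axis=1).ravel())[0, 1]
            for s in range(15)
        )
        assert corr == pytest.approx(best, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_shift_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(5, 12))
        b = rng.normal(size=(5, 12))
        shift, corr = bd.align_templates(a, b)
        oracle = [
            np.corrcoef(a.ravel(), np.roll(b, s, axis=1).ravel())[0, 1]
            for s in range(12)
        ]
        assert corr == pytest.approx(max(oracle), abs=1e-12)
        assert shift == int(np.argmax(oracle))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bd.align_templates(np.zeros((3, 5)), np.zeros((3, 6)))


class TestOccurrenceStats:
    def _result(self, v):
        from braindyn.qpp import QPPResult
        return QPPResult(template=np.zeros((2, 4)), corr_vector=np.asarray(v),
                         peaks=np.array([], dtype=int), n_iterations=1,
                         seed_start=0, converged=True)

    def test_identical_vectors_ks_zero(self):
        v = np.linspace(-0.5, 0.8, 500)
        out = bd.template_occurrence_stats([self._result(v), self._result(v)])
        assert out["ks"][(0, 1)]["statistic"] == pytest.approx(0.0)

    def test_shifted_uniforms_ks_half(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, 40000)
        b = rng.uniform(0.5, 1.5, 40000)
        out = bd.template_occurrence_stats([self._result(a), self._result(b)])
        assert out["ks"][(0, 1)]["statistic"] == pytest.approx(0.5, abs=0.02)

    def test_statistic_is_symmetric(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=300), rng.normal(1, 1, size=300)
        ab = bd.template_occurrence_stats([self._result(a), self._result(b)])
        ba = bd.template_occurrence_stats([self._result(b), self._result(a)])
        assert ab["ks"][(0, 1)]["statistic"] == ba["ks"][(0, 1)]["statistic"]

    def test_empty_vector_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bd.template_occurrence_stats([self._result([]), self._result([0.1])])
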