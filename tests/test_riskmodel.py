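import warnings

import numpy as np
import pytest
from scipy.special import expit

from fallrisk.embedding import EmbeddingConfig
from fallrisk.mcmc import PosteriorFit, SamplerConfig, SamplingError, sample_logistic_posterior, split_rhat
from fallrisk.riskmodel import (
    LogisticRiskModel,
    ModelError,
    OversampleConfig,
    PipelineConfig,
    Scaler,
    SignificanceTally,
    fit_bayesian_logistic,
    marginal_significance,
    oversample_minority,
    predict_risk,
    run_bisection_ensemble,
    select_vocabulary,
    significant_words,
)

from conftest import make_corpus, patient, record

FAST = SamplerConfig(warmup=100, draws=300, seed=0)


def _manual_model(weights, intercept=0.0, samples=None):
    p = len(weights)
    if samples is None:
        samples = np.tile(np.r_[intercept, weights], (100, 1))
    fit = PosteriorFit(
        samples=samples, chains=2, map_estimate=np.r_[intercept, weights],
        rhat=np.ones(p + 1), accept_rate=1.0, converged=True,
    )
    return LogisticRiskModel(
        vocabulary=tuple(f"w{i}" for i in range(p)),
        intercept=intercept,
        weights=np.asarray(weights, dtype=float),
        posterior=fit,
        prior_sd=1.0,
        scaler=Scaler(mean=np.zeros(p), sd=np.ones(p)),
    )


class TestSmote:
    def test_balanced_input_unchanged(self):
        X = np.arange(12.0).reshape(6, 2)
        y = np.array([0, 0, 0, 1, 1, 1])
        Xo, yo = oversample_minority(X, y, OversampleConfig(k_neighbors=2))
        assert np.array_equal(Xo, X) and np.array_equal(yo, y)

    def test_minority_resampled_to_majority_count(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(3, 1, (40, 3))])
        y = np.r_[np.ones(10), np.zeros(40)]
        Xo, yo = oversample_minority(X, y, OversampleConfig(k_neighbors=5, seed=1))
        assert (yo == 1).sum() == (yo == 0).sum() == 40
        # originals retained, majority untouched
        assert np.array_equal(Xo[:50], X)

    def test_synthetic_rows_lie_on_minority_segments(self):
        rng = np.random.default_rng(2)
        X_min = rng.standard_normal((8, 2))
        X = np.vstack([X_min, rng.standard_normal((20, 2)) + 5])
        y = np.r_[np.ones(8), np.zeros(20)]
        Xo, yo = oversample_minority(X, y, OversampleConfig(k_neighbors=3, seed=4))
        synth = Xo[28:]
        for s in synth:
            on_segment = False
            for i in range(8):
                for j in range(8):
                    if i == j:
                        continue
                    d = X_min[j] - X_min[i]
                    t = np.dot(s - X_min[i], d) / np.dot(d, d)
                    if 0 <= t <= 1 and np.allclose(X_min[i] + t * d, s, atol=1e-9):
                        on_segment = True
            assert on_segment

    def test_single_class_rejected(self):
        with pytest.raises(ModelError, match="both classes"):
            oversample_minority(np.zeros((4, 2)), np.zeros(4))

    def test_tiny_minority_advises_smaller_k(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        y = np.r_[np.ones(3), np.zeros(7)]
        with pytest.raises(ModelError, match="smaller k"):
            oversample_minority(X, y, OversampleConfig(k_neighbors=5))


class TestFit:
    def test_prior_only_posterior_matches_prior(self):
        # constant likelihood in beta when its feature is all zero
        rng = np.random.default_rng(1)
        X = np.zeros((200, 1))
        y = rng.integers(0, 2, 200).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sample_logistic_posterior(X, y, prior_sd=1.0, cfg=FAST)
        assert abs(fit.mean[1]) < 0.2
        assert 0.85 < fit.sd[1] < 1.15

    def test_separated_data_shrunk_by_prior(self):
        X = np.r_[-np.ones(10), np.ones(10)][:, None]
        y = np.r_[np.zeros(10), np.ones(10)]
        model = fit_bayesian_logistic(X, y, prior_sd=1.0, sampler=FAST)
        assert np.isfinite(model.weights[0])
        assert abs(model.weights[0]) < 3.0  # ~3 * prior_sd bound

    def test_separated_posterior_matches_quadrature_oracle(self):
        # 1 feature + intercept: integrate the 2-D posterior on a grid
        X = np.r_[-np.ones(10), np.ones(10)][:, None]
        y = np.r_[np.zeros(10), np.ones(10)]
        Xs = (X - X.mean()) / X.std()
        b0g, b1g = np.meshgrid(np.linspace(-8, 8, 401), np.linspace(-8, 8, 401), indexing="ij")
        z = b0g[..., None] + b1g[..., None] * Xs.ravel()[None, None, :]
        loglik = (y * z - np.logaddexp(0, z)).sum(axis=-1)
        logpost = loglik - (b0g**2 + b1g**2) / 2.0
        post = np.exp(logpost - logpost.max())
        post /= post.sum()
        oracle_mean = (post * b1g).sum()
        model = fit_bayesian_logistic(X, y, prior_sd=1.0, sampler=SamplerConfig(warmup=200, draws=1000, seed=3))
        assert model.weights[0] == pytest.approx(oracle_mean, abs=0.1)

    def test_shrinkage_monotone_in_prior_sd(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((300, 2))
        y = (rng.random(300) < expit(1.5 * X[:, 0])).astype(float)
        norms = []
        for psd in (0.1, 1.0, 10.0):
            m = fit_bayesian_logistic(X, y, prior_sd=psd, sampler=FAST)
            norms.append(np.abs(m.weights).sum())
        assert norms[0] < norms[1] < norms[2]

    def test_input_validation(self):
        with pytest.raises(SamplingError):
            sample_logistic_posterior(np.zeros((4, 1)), np.array([0, 0, 0, 0.0]))
        with pytest.raises(SamplingError):
            sample_logistic_posterior(np.zeros((2, 1)), np.array([0.0, 2.0]))


class TestPredict:
    def test_zero_model_gives_half(self):
        m = _manual_model([0.0, 0.0])
        assert predict_risk(m, np.array([[3.0, -2.0]]))[0] == pytest.approx(0.5)

    def test_closed_form_sigma_one(self):
        m = _manual_model([1.0, -1.0], intercept=0.0)
        p = predict_risk(m, np.array([[2.0, 1.0]]))[0]
        assert p == pytest.approx(0.7311, abs=1e-4)

    def test_monotone_in_positive_weight_feature(self):
        m = _manual_model([0.7, -0.2], intercept=0.1)
        base = predict_risk(m, np.array([[1.0, 1.0]]))[0]
        more = predict_risk(m, np.array([[2.0, 1.0]]))[0]
        assert more >= base

    def test_sign_symmetry(self):
        rng = np.random.default_rng(7)
        rows = rng.standard_normal((5, 3))
        m_pos = _manual_model([0.5, -1.0, 2.0], intercept=0.3)
        m_neg = _manual_model([-0.5, 1.0, -2.0], intercept=-0.3)
        assert np.allclose(predict_risk(m_pos, rows), 1 - predict_risk(m_neg, rows))

    def test_probabilities_in_open_interval(self):
        m = _manual_model([50.0], intercept=0.0)
        p = predict_risk(m, np.array([[100.0], [-100.0]]))
        assert np.all(p > 0) and np.all(p < 1)

    def test_degenerate_rows_get_half(self):
        m = _manual_model([1.0])
        p = predict_risk(m, np.array([[2.0], [0.0]]), degenerate=np.array([False, True]))
        assert p[1] == pytest.approx(0.5)

    def test_width_mismatch_rejected(self):
        m = _manual_model([1.0, 2.0])
        with pytest.raises(ModelError, match="width"):
            predict_risk(m, np.array([[1.0, 2.0, 3.0]]))


class TestSignificance:
    def test_all_positive_samples_significant(self):
        samples = np.column_stack([np.zeros(100), np.abs(np.random.default_rng(0).standard_normal(100)) + 0.1])
        m = _manual_model([1.0], samples=samples)
        assert significant_words(m) == ["w0"]

    def test_symmetric_posterior_not_significant(self):
        rng = np.random.default_rng(1)
        samples = np.column_stack([np.zeros(500), rng.standard_normal(500)])
        m = _manual_model([0.0], samples=samples)
        assert significant_words(m) == []

    def test_agrees_with_sorted_quantile_oracle(self):
        rng = np.random.default_rng(2)
        sam = rng.standard_normal((400, 4)) + np.array([0.0, 0.5, 2.0, -2.0])
        m = _manual_model([0.0, 0.5, 2.0, -2.0], samples=np.column_stack([np.zeros(400), sam]))
        got = set(significant_words(m, level=0.95))
        oracle = set()
        for j, w in enumerate(m.vocabulary):
            srt = np.sort(sam[:, j])
            lo = np.quantile(srt, 0.025)
            hi = np.quantile(srt, 0.975)
            if lo > 0 or hi < 0:
                oracle.add(w)
        assert got == oracle

    def test_too_few_samples_rejected(self):
        m = _manual_model([1.0], samples=np.ones((10, 2)))
        with pytest.raises(ModelError):
            significant_words(m, level=0.999)

    def test_marginal_screen_null_calibration_and_power(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((500, 40))
        y = (rng.random(500) < expit(2.0 * X[:, 0])).astype(float)
        mask = marginal_significance(X, y, prior_sd=1.0, level=0.95)
        assert mask[0]
        assert mask[1:].mean() < 0.15  # null columns fire near the 5% level


class TestSelection:
    def _tally(self, counts, n_models=6):
        return SignificanceTally(words=tuple(counts), counts=counts, n_models=n_models)

    def test_threshold_examples(self):
        t = self._tally({"a": 6, "b": 4, "c": 3})
        assert select_vocabulary(t, min_models=4) == ["a", "b"]

    def test_min_models_above_ensemble_size_warns_empty(self):
        t = self._tally({"a": 6})
        with pytest.warns(UserWarning):
            assert select_vocabulary(t, min_models=7) == []

    def test_equals_brute_force_filter(self):
        rng = np.random.default_rng(4)
        counts = {f"w{i}": int(rng.integers(0, 7)) for i in range(50)}
        t = self._tally(counts)
        assert select_vocabulary(t, 4) == [w for w in counts if counts[w] >= 4]


class TestEnsemble:
    def _corpus(self, n=16, seed=0):
        rng = np.random.default_rng(seed)
        pats, recs = [], []
        for i in range(n):
            lab = "faller" if i % 2 == 0 else "nonfaller"
            pats.append(patient(f"P{i:02d}", lab, falls=(5,) if lab == "faller" else ()))
            for d in range(4):
                base = ["tok%d" % t for t in rng.integers(0, 12, size=15)]
                if lab == "faller":
                    base += ["riskword"] * 3
                recs.append(record(f"P{i:02d}", d, tuple(base)))
        return make_corpus(pats, recs)

    CFG = PipelineConfig(
        embedding=EmbeddingConfig(k=8, epochs=4, top_k=20, seed=1),
        sampler=FAST,
        smote_k=2,
    )

    def test_tally_counts_in_range_and_deterministic(self):
        c = self._corpus()
        t1 = run_bisection_ensemble(c, self.CFG, seed=5)
        t2 = run_bisection_ensemble(c, self.CFG, seed=5)
        assert t1.counts == t2.counts
        assert t1.n_models == 6
        assert all(0 <= v <= 6 for v in t1.counts.values())

    def test_planted_word_reaches_full_tally(self):
        c = self._corpus(n=24)
        t = run_bisection_ensemble(c, self.CFG, seed=5)
        assert t.counts.get("riskword", 0) >= 4

    def test_lost_class_raises(self):
        # one faller among many: an unstratified bisection half must lose it
        rng = np.random.default_rng(1)
        pats = [patient("F0", "faller", falls=(2,))] + [patient(f"N{i}") for i in range(11)]
        recs = [record(p.patient_id, d, tuple("tok%d" % t for t in rng.integers(0, 6, 10)))
                for p in pats for d in range(3)]
        c = make_corpus(pats, recs)
        cfg = PipelineConfig(
            embedding=EmbeddingConfig(k=4, epochs=2, top_k=10, seed=1),
            sampler=FAST, smote_k=1, stratified_split=False,
        )
        with pytest.raises(ModelError, match="lost a class"):
            run_bisection_ensemble(c, cfg, seed=3)


class TestRhat:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal((500, 3))
        stacked = np.vstack([draws, draws + 0.001 * rng.standard_normal((500, 3))])
        r = split_rhat(stacked, chains=2)
        assert np.all(r < 1.02)

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((500, 2))
        b = rng.standard_normal((500, 2)) + 3.0
        r = split_rhat(np.vstack([a, b]), chains=2)
        assert np.all(r > 1.05)
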