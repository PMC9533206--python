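import math

import numpy as np
import pytest

import thememiner as tm
from thememiner.topic_model import _HAVE_NUMBA, _gibbs_python
from helpers import cv_oracle


@pytest.fixture(scope="module")
def toy_bow():
    rng = np.random.default_rng(0)
    vocab = [f"w{i}" for i in range(12)]
    texts = [" ".join(rng.choice(vocab, size=25)) for _ in range(15)]
    return tm.build_bow(texts)


def _two_group_texts(n_per_group=20, seed=0):
    rng = np.random.default_rng(seed)
    a = [" ".join(rng.choice([f"a{i}" for i in range(12)], size=30)) for _ in range(n_per_group)]
    b = [" ".join(rng.choice([f"b{i}" for i in range(12)], size=30)) for _ in range(n_per_group)]
    return a + b


class TestBuildBow:
    def test_shared_vocabulary_union(self):
        bow = tm.build_bow(["apple pear", "pear apple"])
        assert set(bow.vocabulary) == {"apple", "pear"}

    def test_min_count_drops_hapaxes(self):
        bow = tm.build_bow(["apple apple pear", "apple plum"], min_count=2)
        assert set(bow.vocabulary) == {"apple"}

    def test_hand_tally(self):
        bow = tm.build_bow(["x x y", "y z", "z z z"])
        # frequency desc then alphabetical: z=4, x=2, y=2
        assert bow.vocabulary == ("z", "x", "y")
        counts = {bow.vocabulary[i]: c for i, c in bow.docs[0]}
        assert counts == {"x": 2, "y": 1}
        assert bow.n_tokens == 8

    def test_stopwords_removed(self):
        bow = tm.build_bow(["the apple the pear"], stopwords={"the"})
        assert set(bow.vocabulary) == {"apple", "pear"}

    def test_empty_vocabulary_errors(self):
        with pytest.raises(ValueError, match="empty vocabulary"):
            tm.build_bow(["the the"], stopwords={"the"})

    def test_accepts_pretokenized(self):
        bow = tm.build_bow([["a", "b"], ["b"]])
        assert bow.vocabulary == ("b", "a")


class TestFitLdaGibbs:
    def test_k1_closed_form(self, toy_bow):
        beta = 0.01
        fit = tm.fit_lda_gibbs(toy_bow, K=1, beta=beta, n_iter=3, seed=9)
        assert np.all(fit.theta == 1.0)
        counts = toy_bow.word_counts()
        expected = (counts + beta) / (counts.sum() + len(counts) * beta)
        assert np.array_equal(fit.phi[0], expected)

    def test_seeded_determinism_bit_exact(self, toy_bow):
        a = tm.fit_lda_gibbs(toy_bow, K=3, n_iter=40, seed=123)
        b = tm.fit_lda_gibbs(toy_bow, K=3, n_iter=40, seed=123)
        assert np.array_equal(a.phi, b.phi) and np.array_equal(a.theta, b.theta)

    def test_different_seeds_differ(self, toy_bow):
        a = tm.fit_lda_gibbs(toy_bow, K=3, n_iter=40, seed=1)
        b = tm.fit_lda_gibbs(toy_bow, K=3, n_iter=40, seed=2)
        assert not np.array_equal(a.phi, b.phi)

    def test_rows_sum_to_one_and_positive(self, toy_bow):
        fit = tm.fit_lda_gibbs(toy_bow, K=4, n_iter=30, seed=0)
        assert np.allclose(fit.phi.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(fit.theta.sum(axis=1), 1.0, atol=1e-9)
        assert (fit.phi > 0).all() and (fit.theta > 0).all()

    def test_disjoint_vocabulary_separation(self):
        bow = tm.build_bow(_two_group_texts())
        idx_a = [i for i, w in enumerate(bow.vocabulary) if w.startswith("a")]
        ok = 0
        for seed in range(5):
            fit = tm.fit_lda_gibbs(bow, K=2, n_iter=200, seed=seed)
            mass_a = fit.phi[:, idx_a].sum(axis=1)
            if max(mass_a) >= 0.95 and min(mass_a) <= 0.05:
                ok += 1
        assert ok >= 4

    def test_k_exceeding_tokens_errors(self):
        bow = tm.build_bow(["a b"])
        with pytest.raises(ValueError, match="exceeds"):
            tm.fit_lda_gibbs(bow, K=3, n_iter=1)

    @pytest.mark.parametrize("bad", [dict(K=0), dict(K=1, n_iter=0)])
    def test_bad_args(self, toy_bow, bad):
        with pytest.raises(ValueError):
            tm.fit_lda_gibbs(toy_bow, n_iter=bad.get("n_iter", 1), K=bad["K"])

    @pytest.mark.skipif(not _HAVE_NUMBA, reason="numba unavailable")
    def test_python_kernel_lockstep_with_numba(self):
        from thememiner.topic_model import _gibbs_numba

        bow = tm.build_bow(_two_group_texts(n_per_group=5))
        K = 3

        def run(kernel):
            doc_ids, word_ids = [], []
            for d, doc in enumerate(bow.docs):
                for idx, cnt in doc:
                    doc_ids += [d] * cnt
                    word_ids += [idx] * cnt
            doc_ids = np.array(doc_ids, dtype=np.int64)
            word_ids = np.array(word_ids, dtype=np.int64)
            z = np.zeros(len(doc_ids), dtype=np.int64)
            n_dt = np.zeros((bow.n_docs, K), dtype=np.int64)
            n_tw = np.zeros((K, len(bow.vocabulary)), dtype=np.int64)
            n_t = np.zeros(K, dtype=np.int64)
            kernel(doc_ids, word_ids, z, n_dt, n_tw, n_t, 1.0 / K, 0.01, 25, 77)
            return z, n_tw

        z_py, ntw_py = run(_gibbs_python)
        z_nb, ntw_nb = run(_gibbs_numba)
        assert np.array_equal(z_py, z_nb) and np.array_equal(ntw_py, ntw_nb)


class TestTopWords:
    def test_topn_and_tie_break(self):
        fit = _fit_from_phi(np.array([[0.4, 0.3, 0.3]]), counts=np.array([4, 3, 3]))
        assert tm.top_words(fit, topn=2) == [["u", "v"]]  # tie 0.3/0.3 -> alphabetical


def _fit_from_phi(phi, counts, vocab=("u", "v", "w")):
    K = phi.shape[0]
    theta = np.full((1, K), 1.0 / K)
    return tm.TopicModelFit(
        K=K, alpha=1.0 / K, beta=0.01, phi=phi, theta=theta, seed=0, n_iter=1,
        vocabulary=tuple(vocab[: phi.shape[1]]), corpus_word_counts=np.asarray(counts),
    )


class TestCvCoherence:
    def test_duplicate_topics_identical_scores(self):
        texts = _two_group_texts(n_per_group=10)
        topics = [["a0", "a1", "a2"], ["a0", "a1", "a2"]]
        res = tm.cv_coherence(topics, texts, topn=3, window=10)
        assert res.per_topic[0] == res.per_topic[1]
        assert res.cv == pytest.approx(res.per_topic[0])

    def test_toy_corpus_matches_brute_force_oracle(self):
        # 3 short docs, window larger than each doc -> 3 boolean windows
        docs = [["cat", "dog", "cat"], ["dog", "fish"], ["cat", "fish", "bird"]]
        topics = [["cat", "dog"], ["fish", "bird"]]
        mine = tm.cv_coherence(topics, docs, topn=2, window=110)
        assert mine.cv == pytest.approx(cv_oracle(topics, docs, 110), abs=1e-12)

    def test_sliding_windows_match_oracle(self):
        rng = np.random.default_rng(4)
        docs = [list(rng.choice(["a", "b", "c", "d", "e"], size=30)) for _ in range(6)]
        topics = [["a", "b", "c"], ["d", "e", "a"]]
        mine = tm.cv_coherence(topics, docs, topn=3, window=7)
        assert mine.cv == pytest.approx(cv_oracle(topics, docs, 7), abs=1e-9)

    def test_fifty_doc_synthetic_corpus_matches_oracle(self):
        cfg = tm.SyntheticConfig(n_posts=50, n_latent_topics=3, topic_vocab_size=15, seed=21)
        corpus, _ = tm.generate_corpus(cfg)
        texts = [tm.tokenize(p.text) for p in corpus]
        bow = tm.build_bow(texts)
        fit = tm.fit_lda_gibbs(bow, K=3, n_iter=150, seed=1)
        mine = tm.cv_coherence(fit, texts, topn=8, window=110)
        topics = tm.top_words(fit, topn=8)
        assert mine.cv == pytest.approx(cv_oracle(topics, texts, 110), abs=1e-6)

    def test_absent_top_word_warns(self):
        docs = [["a", "b"], ["a", "c"]]
        with pytest.warns(UserWarning, match="absent"):
            res = tm.cv_coherence([["a", "ghost"]], docs, topn=2, window=5)
        assert math.isfinite(res.cv)

    def test_topn_validation(self):
        with pytest.raises(ValueError, match="topn"):
            tm.cv_coherence([["a", "b"]], [["a", "b"]], topn=1)


class TestSelectNumTopics:
    # toy grids legitimately leave some top words out of the tiny references
    @pytest.mark.filterwarnings("ignore:top words absent")
    def test_singleton_grid(self, toy_bow):
        texts = [["w0", "w1", "w2"]] * 5
        best, results = tm.select_num_topics(toy_bow, texts, k_grid=[3], n_iter=10, topn=3)
        assert best == 3 and len(results) == 1

    @pytest.mark.filterwarnings("ignore:top words absent")
    def test_one_result_per_grid_element(self, toy_bow):
        texts = [["w0", "w1", "w2", "w3"]] * 5
        best, results = tm.select_num_topics(toy_bow, texts, k_grid=[2, 3, 4], n_iter=10, topn=3)
        assert [r.K for r in results] == [2, 3, 4]

    def test_planted_four_topic_recovery(self):
        hits = 0
        for seed in range(5):
            cfg = tm.SyntheticConfig(
                n_posts=160, n_latent_topics=4, topic_vocab_size=20,
                tokens_per_post_lognormal=(3.3, 0.4), seed=seed,
            )
            corpus, _ = tm.generate_corpus(cfg)
            texts = [tm.tokenize(p.text) for p in corpus]
            bow = tm.build_bow(texts)
            best, _ = tm.select_num_topics(
                bow, texts, k_grid=[2, 4, 6, 8], n_iter=300, seed=seed, topn=12
            )
            hits += best == 4
        assert hits >= 4

    def test_planted_topic_cosine_recovery(self):
        ok = 0
        for seed in range(5):
            cfg = tm.SyntheticConfig(
                n_posts=160, n_latent_topics=4, topic_vocab_size=20,
                tokens_per_post_lognormal=(3.3, 0.4), seed=100 + seed,
            )
            corpus, truth = tm.generate_corpus(cfg)
            texts = [tm.tokenize(p.text) for p in corpus]
            bow = tm.build_bow(texts)
            fit = tm.fit_lda_gibbs(bow, K=4, n_iter=300, seed=seed)
            # truth word distributions from the planted assignments
            vocab_index = {w: i for i, w in enumerate(bow.vocabulary)}
            true_phi = np.zeros((4, len(bow.vocabulary)))
            for post, toks in zip(corpus, texts):
                t = truth.topic_of[post.post_id]
                for tok in toks:
                    true_phi[t, vocab_index[tok]] += 1
            true_phi /= true_phi.sum(axis=1, keepdims=True)
            sims = []
            remaining = list(range(4))
            for t in range(4):  # greedy matching
                cos = [
                    float(fit.phi[t] @ true_phi[u])
                    / (np.linalg.norm(fit.phi[t]) * np.linalg.norm(true_phi[u]))
                    for u in remaining
                ]
                j = int(np.argmax(cos))
                sims.append(cos[j])
                remaining.pop(j)
            ok += np.mean(sims) >= 0.9
        assert ok >= 3  # majority of seeds


class TestRelevanceRank:
    def test_lambda_one_equals_phi_order(self):
        phi = np.array([[0.2, 0.5, 0.3]])
        fit = _fit_from_phi(phi, counts=np.array([1, 8, 1]))
        ranking = tm.relevance_rank(fit, lam=1.0, n_terms=3)
        assert [w for w, _ in ranking.topics[0]] == ["v", "w", "u"]

    def test_lambda_zero_equals_lift_order(self):
        phi = np.array([[0.2, 0.5, 0.3]])
        counts = np.array([1, 80, 10])  # lift: u=0.2/(1/91), v=0.5/(80/91), w=0.3/(10/91)
        fit = _fit_from_phi(phi, counts=counts)
        p = counts / counts.sum()
        lift_order = [fit.vocabulary[i] for i in np.argsort(-(phi[0] / p))]
        ranking = tm.relevance_rank(fit, lam=0.0, n_terms=3)
        assert [w for w, _ in ranking.topics[0]] == lift_order

    def test_hand_computed_example(self):
        fit = _fit_from_phi(np.array([[0.5, 0.3, 0.2]]), counts=np.array([60, 20, 20]))
        ranking = tm.relevance_rank(fit, lam=0.6, n_terms=3)
        words = [w for w, _ in ranking.topics[0]]
        values = [v for _, v in ranking.topics[0]]
        assert words == ["u", "v", "w"]
        assert values == pytest.approx([-0.489, -0.560, -0.966], abs=1e-3)

    def test_relevance_non_increasing(self, toy_bow):
        fit = tm.fit_lda_gibbs(toy_bow, K=3, n_iter=30, seed=5)
        ranking = tm.relevance_rank(fit, lam=0.6, n_terms=5)
        for topic in ranking.topics:
            vals = [v for _, v in topic]
            assert vals == sorted(vals, reverse=True)

    def test_lambda_validation(self, toy_bow):
        fit = tm.fit_lda_gibbs(toy_bow, K=2, n_iter=5, seed=0)
        with pytest.raises(ValueError):
            tm.relevance_rank(fit, lam=1.5)


class TestKeywordOverlap:
    def test_sleep_overlaps(self, lex):
        ranking = tm.RelevanceRanking(0.6, ((("sleep", 0.0),),))
        report = tm.keyword_overlap(ranking, lex)
        assert "sleep" in report.overlapping_terms
        assert "Sleep disturbances" in report.matched_themes["sleep"]

    def test_work_overlaps_via_phrase_word(self, lex):
        ranking = tm.RelevanceRanking(0.6, ((("work", 0.0),),))
        report = tm.keyword_overlap(ranking, lex)
        assert report.n_overlap == 1

    def test_no_overlap(self, lex):
        ranking = tm.RelevanceRanking(0.6, ((("zzz", 0.0),),))
        assert tm.keyword_overlap(ranking, lex).n_overlap == 0

    def test_two_of_fiftysix_is_four_percent(self, lex):
        from thememiner.synthetic import _pattern_tokens, _screened_words

        rng = np.random.default_rng(0)
        filler = _screened_words(rng, 54, _pattern_tokens(lex), set())
        terms = ["sleep", "work"] + filler
        topics = tuple(
            tuple((t, 0.0) for t in terms[i * 7 : (i + 1) * 7]) for i in range(8)
        )
        report = tm.keyword_overlap(tm.RelevanceRanking(0.6, topics), lex)
        assert report.n_overlap == 2 and report.n_terms == 56
        assert report.percent == 4
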