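"""Latent Dirichlet allocation by collapsed Gibbs sampling, with
sliding-window C_V coherence, coherence-driven topic-number selection,
lambda-weighted relevance ranking of topic terms, and overlap comparison
against a keyword lexicon.

The Gibbs sampler uses its own xorshift64* stream so that a fixed seed
yields bit-identical fits regardless of platform or numba availability.
phi and theta are smoothed point estimates from the final sample:

    phi[t, w]  = (n_tw + beta)  / (n_t + V*beta)
    theta[d, t] = (n_dt + alpha) / (n_d + K*alpha)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .scoring import tokenize

if TYPE_CHECKING:  # pragma: no cover
    from .corpus_io import Corpus
    from .lexicon import Lexicon

__all__ = [
    "BowCorpus",
    "TopicModelFit",
    "CoherenceResult",
    "RelevanceRanking",
    "OverlapReport",
    "build_bow",
    "fit_lda_gibbs",
    "top_words",
    "cv_coherence",
    "select_num_topics",
    "relevance_rank",
    "keyword_overlap",
]

_MASK64 = (1 << 64) - 1
_DOUBLE_UNIT = 1.0 / 9007199254740992.0  # 2**-53


def _gibbs_python(doc_ids, word_ids, z, n_dt, n_tw, n_t, alpha, beta, n_iter, seed):
    """Pure-python collapsed Gibbs kernel (reference / fallback).

    Must stay in exact lockstep with the numba kernel: same PRNG, same
    update order.
    """
    K, V = n_tw.shape
    n_tokens = doc_ids.shape[0]
    # splitmix64 seed scrambling
    s = (seed + 0x9E3779B97F4A7C15) & _MASK64
    s = ((s ^ (s >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    s = ((s ^ (s >> 27)) * 0x94D049BB133111EB) & _MASK64
    s = s ^ (s >> 31)
    if s == 0:
        s = 0x9E3779B97F4A7C15

    def nxt(state):
        state ^= state >> 12
        state = (state ^ (state << 25)) & _MASK64
        state ^= state >> 27
        out = (state * 0x2545F4914F6CDD1D) & _MASK64
        return state, (out >> 11) * _DOUBLE_UNIT

    for i in range(n_tokens):
        s, u = nxt(s)
        t = min(int(u * K), K - 1)
        z[i] = t
        n_dt[doc_ids[i], t] += 1
        n_tw[t, word_ids[i]] += 1
        n_t[t] += 1
    vbeta = V * beta
    p = np.empty(K)
    for _ in range(n_iter):
        for i in range(n_tokens):
            d, w, t = doc_ids[i], word_ids[i], z[i]
            n_dt[d, t] -= 1
            n_tw[t, w] -= 1
            n_t[t] -= 1
            total = 0.0
            for k in range(K):
                pk = (n_dt[d, k] + alpha) * (n_tw[k, w] + beta) / (n_t[k] + vbeta)
                p[k] = pk
                total += pk
            s, u = nxt(s)
            u *= total
            acc = 0.0
            tnew = K - 1
            for k in range(K):
                acc += p[k]
                if u < acc:
                    tnew = k
                    break
            z[i] = tnew
            n_dt[d, tnew] += 1
            n_tw[tnew, w] += 1
            n_t[tnew] += 1


try:  # numba gives ~100x on the kernel; the fallback is exact lockstep
    import numba as _numba

    @_numba.njit(cache=False)
    def _gibbs_numba(doc_ids, word_ids, z, n_dt, n_tw, n_t, alpha, beta, n_iter, seed):  # pragma: no cover
        K = n_tw.shape[0]
        V = n_tw.shape[1]
        n_tokens = doc_ids.shape[0]
        s = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
        s = (s ^ (s >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        s = (s ^ (s >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        s = s ^ (s >> np.uint64(31))
        if s == np.uint64(0):
            s = np.uint64(0x9E3779B97F4A7C15)
        for i in range(n_tokens):
            s = s ^ (s >> np.uint64(12))
            s = s ^ (s << np.uint64(25))
            s = s ^ (s >> np.uint64(27))
            u = np.float64((s * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)) * _DOUBLE_UNIT
            t = min(int(u * K), K - 1)
            z[i] = t
            n_dt[doc_ids[i], t] += 1
            n_tw[t, word_ids[i]] += 1
            n_t[t] += 1
        vbeta = V * beta
        p = np.empty(K, dtype=np.float64)
        for _ in range(n_iter):
            for i in range(n_tokens):
                d = doc_ids[i]
                w = word_ids[i]
                t = z[i]
                n_dt[d, t] -= 1
                n_tw[t, w] -= 1
                n_t[t] -= 1
                total = 0.0
                for k in range(K):
                    pk = (n_dt[d, k] + alpha) * (n_tw[k, w] + beta) / (n_t[k] + vbeta)
                    p[k] = pk
                    total += pk
                s = s ^ (s >> np.uint64(12))
                s = s ^ (s << np.uint64(25))
                s = s ^ (s >> np.uint64(27))
                u = np.float64((s * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)) * _DOUBLE_UNIT
                u *= total
                acc = 0.0
                tnew = K - 1
                for k in range(K):
                    acc += p[k]
                    if u < acc:
                        tnew = k
                        break
                z[i] = tnew
                n_dt[d, tnew] += 1
                n_tw[tnew, w] += 1
                n_t[tnew] += 1

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class BowCorpus:
    """Bag-of-words view: ordered vocabulary plus per-doc (index, count) pairs."""

    vocabulary: tuple[str, ...]
    docs: tuple[tuple[tuple[int, int], ...], ...]

    def __post_init__(self):
        V = len(self.vocabulary)
        for doc in self.docs:
            for idx, cnt in doc:
                if not (0 <= idx < V):
                    raise ValueError(f"word index {idx} out of range")
                if cnt <= 0:
                    raise ValueError("counts must be positive")

    @property
    def n_docs(self) -> int:
        return len(self.docs)

    @property
    def n_tokens(self) -> int:
        return sum(c for doc in self.docs for _, c in doc)

    def word_counts(self) -> np.ndarray:
        counts = np.zeros(len(self.vocabulary), dtype=np.int64)
        for doc in self.docs:
            for idx, cnt in doc:
                counts[idx] += cnt
        return counts


def build_bow(
    corpus: "Corpus | Iterable[Sequence[str] | str]",
    stopwords: Iterable[str] = (),
    min_count: int = 1,
) -> BowCorpus:
    """Tokenize (if needed), drop stopwords and rare words, index the rest.

    Vocabulary order is corpus frequency descending, then alphabetical —
    deterministic for a given corpus.
    """
    sw = frozenset(stopwords)
    token_docs: list[list[str]] = []
    texts = corpus.texts() if hasattr(corpus, "texts") else corpus
    for item in texts:
        toks = tokenize(item) if isinstance(item, str) else list(item)
        token_docs.append([t for t in toks if t not in sw])
    freq: dict[str, int] = {}
    for doc in token_docs:
        for t in doc:
            freq[t] = freq.get(t, 0) + 1
    kept = [w for w, c in freq.items() if c >= min_count]
    if not kept:
        raise ValueError("empty vocabulary after filtering")
    vocabulary = tuple(sorted(kept, key=lambda w: (-freq[w], w)))
    index = {w: i for i, w in enumerate(vocabulary)}
    docs = []
    for doc in token_docs:
        counts: dict[int, int] = {}
        for t in doc:
            i = index.get(t)
            if i is not None:
                counts[i] = counts.get(i, 0) + 1
        docs.append(tuple(sorted(counts.items())))
    return BowCorpus(vocabulary, tuple(docs))


@dataclass(frozen=True)
class TopicModelFit:
    K: int
    alpha: float
    beta: float
    phi: np.ndarray  # K x V
    theta: np.ndarray  # D x K
    seed: int
    n_iter: int
    vocabulary: tuple[str, ...]
    corpus_word_counts: np.ndarray  # V, term frequencies of the training bow

    def __post_init__(self):
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("phi rows must sum to 1")
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("theta rows must sum to 1")
        if (self.phi <= 0).any() or (self.theta <= 0).any():
            raise ValueError("probabilities must be strictly positive (smoothed)")


def fit_lda_gibbs(
    bow: BowCorpus,
    K: int,
    alpha: float | None = None,
    beta: float = 0.01,
    n_iter: int = 1000,
    seed: int = 0,
) -> TopicModelFit:
    """Collapsed Gibbs sampling; estimates taken from the final sample.

    ``alpha=None`` selects the symmetric default ``1/K``.  A fixed seed
    gives bit-identical output.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if alpha is None:
        alpha = 1.0 / K
    n_tokens = bow.n_tokens
    if K > n_tokens:
        raise ValueError(f"K={K} exceeds total token count {n_tokens}")
    V = len(bow.vocabulary)
    D = bow.n_docs
    doc_ids = np.empty(n_tokens, dtype=np.int64)
    word_ids = np.empty(n_tokens, dtype=np.int64)
    pos = 0
    for d, doc in enumerate(bow.docs):
        for idx, cnt in doc:
            doc_ids[pos : pos + cnt] = d
            word_ids[pos : pos + cnt] = idx
            pos += cnt
    z = np.zeros(n_tokens, dtype=np.int64)
    n_dt = np.zeros((D, K), dtype=np.int64)
    n_tw = np.zeros((K, V), dtype=np.int64)
    n_t = np.zeros(K, dtype=np.int64)
    kernel = _gibbs_numba if _HAVE_NUMBA else _gibbs_python
    kernel(doc_ids, word_ids, z, n_dt, n_tw, n_t, float(alpha), float(beta), int(n_iter), int(seed) & _MASK64)
    phi = (n_tw + beta) / (n_t[:, None] + V * beta)
    n_d = n_dt.sum(axis=1)
    theta = (n_dt + alpha) / (n_d[:, None] + K * alpha)
    return TopicModelFit(
        K=K,
        alpha=float(alpha),
        beta=float(beta),
        phi=phi,
        theta=theta,
        seed=int(seed),
        n_iter=int(n_iter),
        vocabulary=bow.vocabulary,
        corpus_word_counts=bow.word_counts(),
    )


def top_words(fit: TopicModelFit, topn: int = 20) -> list[list[str]]:
    """Per topic, the ``topn`` highest-phi words (ties: alphabetical)."""
    out = []
    for t in range(fit.K):
        order = sorted(range(len(fit.vocabulary)), key=lambda w: (-fit.phi[t, w], fit.vocabulary[w]))
        out.append([fit.vocabulary[w] for w in order[:topn]])
    return out


@dataclass(frozen=True)
class CoherenceResult:
    K: int
    cv: float
    topn: int
    window: int
    per_topic: tuple[float, ...]


def _window_stats(token_docs: Sequence[Sequence[str]], relevant: set[str], window: int):
    """Boolean sliding-window document frequencies for the relevant words.

    Documents shorter than the window contribute a single window; longer
    documents contribute one window per start offset (stride 1).
    """
    word_df: dict[str, int] = {w: 0 for w in relevant}
    pair_df: dict[tuple[str, str], int] = {}
    n_windows = 0
    for doc in token_docs:
        n = len(doc)
        if n == 0:
            continue
        if n <= window:
            spans = [doc]
        else:
            spans = [doc[i : i + window] for i in range(n - window + 1)]
        for span in spans:
            n_windows += 1
            present = sorted(relevant.intersection(span))
            for a in present:
                word_df[a] += 1
            for ai, a in enumerate(present):
                for b in present[ai:]:  # includes (a, a)
                    key = (a, b)
                    pair_df[key] = pair_df.get(key, 0) + 1
    return word_df, pair_df, n_windows


def _npmi(wa: str, wb: str, word_df, pair_df, n_windows: int, eps: float) -> float:
    if wb < wa:
        wa, wb = wb, wa
    p_a = word_df[wa] / n_windows
    p_b = word_df[wb] / n_windows
    p_ab = pair_df.get((wa, wb), 0) / n_windows
    if p_a == 0.0 or p_b == 0.0:
        return 0.0
    num = math.log((p_ab + eps) / (p_a * p_b))
    den = -math.log(p_ab + eps)
    return num / den


def cv_coherence(
    fit_or_topics: TopicModelFit | Sequence[Sequence[str]],
    reference_texts: Sequence[Sequence[str] | str],
    topn: int = 20,
    window: int = 110,
    eps: float = 1e-12,
) -> CoherenceResult:
    """C_V topic coherence.

    One-set segmentation over each topic's top-``topn`` words; word and
    word-pair probabilities estimated from boolean sliding windows of size
    ``window`` over ``reference_texts``; NPMI context vectors; indirect
    cosine confirmation of each word's vector against the topic's summed
    vector; topic score = mean cosine, overall = mean over topics.
    Top words absent from the reference texts get zero NPMI rows (warned).
    """
    if topn < 2:
        raise ValueError("topn must be >= 2")
    if isinstance(fit_or_topics, TopicModelFit):
        topics = top_words(fit_or_topics, topn)
        K = fit_or_topics.K
    else:
        topics = [list(t)[:topn] for t in fit_or_topics]
        K = len(topics)
    token_docs = [tokenize(d) if isinstance(d, str) else list(d) for d in reference_texts]
    relevant = {w for t in topics for w in t}
    word_df, pair_df, n_windows = _window_stats(token_docs, relevant, window)
    if n_windows == 0:
        raise ValueError("no reference windows")
    missing = sorted(w for w in relevant if word_df[w] == 0)
    if missing:
        warnings.warn(f"top words absent from reference texts: {missing[:10]}", stacklevel=2)
    per_topic = []
    for W in topics:
        vecs = np.array(
            [[_npmi(wi, wj, word_df, pair_df, n_windows, eps) for wj in W] for wi in W]
        )
        vsum = vecs.sum(axis=0)
        sims = []
        for i in range(len(W)):
            na = float(np.linalg.norm(vecs[i]))
            nb = float(np.linalg.norm(vsum))
            sims.append(float(vecs[i] @ vsum) / (na * nb) if na > 0 and nb > 0 else 0.0)
        per_topic.append(float(np.mean(sims)))
    return CoherenceResult(K=K, cv=float(np.mean(per_topic)), topn=topn, window=window, per_topic=tuple(per_topic))


def select_num_topics(
    bow: BowCorpus,
    reference_texts: Sequence[Sequence[str] | str],
    k_grid: Sequence[int] = tuple(range(2, 41, 2)),
    alpha: float | None = None,
    beta: float = 0.01,
    n_iter: int = 1000,
    seed: int = 0,
    topn: int = 20,
    window: int = 110,
) -> tuple[int, list[CoherenceResult]]:
    """Fit one model per grid K and pick the coherence argmax (ties: smaller K)."""
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    results = []
    for K in k_grid:
        fit = fit_lda_gibbs(bow, K, alpha=alpha, beta=beta, n_iter=n_iter, seed=seed)
        results.append(cv_coherence(fit, reference_texts, topn=topn, window=window))
    best = max(results, key=lambda r: (r.cv, -r.K))
    return best.K, results


@dataclass(frozen=True)
class RelevanceRanking:
    lam: float
    topics: tuple[tuple[tuple[str, float], ...], ...]  # per topic: (word, relevance)

    def terms(self) -> list[str]:
        """All term slots across topics, in topic-major order (with repeats)."""
        return [w for topic in self.topics for w, _ in topic]

    @property
    def n_terms(self) -> int:
        return len(self.topics[0]) if self.topics else 0


def relevance_rank(fit: TopicModelFit, lam: float = 0.6, n_terms: int = 7) -> RelevanceRanking:
    """lambda-weighted term relevance:

        relevance(w, t) = lam * log phi[t, w] + (1 - lam) * log(phi[t, w] / p_w)

    with ``p_w`` the marginal corpus word probability.  ``lam=1`` ranks by
    within-topic probability, ``lam=0`` by lift.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must be in [0, 1]")
    counts = fit.corpus_word_counts.astype(float)
    p = counts / counts.sum()
    # smoothed marginal: phi is strictly positive, p may have structural zeros
    # only if a vocabulary word never occurs, which build_bow precludes.
    logphi = np.log(fit.phi)
    lift = logphi - np.log(p)[None, :]
    rel = lam * logphi + (1.0 - lam) * lift
    topics = []
    for t in range(fit.K):
        order = sorted(range(len(fit.vocabulary)), key=lambda w: (-rel[t, w], fit.vocabulary[w]))
        topics.append(tuple((fit.vocabulary[w], float(rel[t, w])) for w in order[:n_terms]))
    return RelevanceRanking(lam=float(lam), topics=tuple(topics))


@dataclass(frozen=True)
class OverlapReport:
    overlapping_terms: tuple[str, ...]  # unique, sorted
    matched_themes: dict[str, tuple[str, ...]]  # term -> themes it matched
    n_overlap: int
    n_terms: int
    percent: int  # rounded to whole percent

    def __str__(self) -> str:
        return f"{self.n_overlap} of {self.n_terms} terms overlap ({self.percent}%): {', '.join(self.overlapping_terms)}"


def keyword_overlap(ranking: RelevanceRanking, lexicon: "Lexicon") -> OverlapReport:
    """Compare model terms against the a-priori lexicon.

    A term overlaps iff some single-word root of the lexicon is a prefix of
    it, or it equals a word of some phrase pattern.  The percent is the
    unique overlapping terms over all term slots, rounded to a whole
    percent.
    """
    terms = ranking.terms()
    matched: dict[str, list[str]] = {}
    for term in dict.fromkeys(terms):  # unique, first-seen order
        themes_hit = []
        for theme, pats in lexicon:
            for pat in pats:
                if pat.kind == "root":
                    if term.startswith(pat.tokens[0]):
                        themes_hit.append(theme)
                        break
                else:
                    if term in pat.tokens:
                        themes_hit.append(theme)
                        break
        if themes_hit:
            matched[term] = themes_hit
    overlapping = tuple(sorted(matched))
    n_terms = len(terms)
    percent = round(100.0 * len(overlapping) / n_terms) if n_terms else 0
    return OverlapReport(
        overlapping_terms=overlapping,
        matched_themes={t: tuple(v) for t, v in matched.items()},
        n_overlap=len(overlapping),
        n_terms=n_terms,
        percent=percent,
    )
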