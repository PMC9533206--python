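"""Independent oracles used by the test suite.

These deliberately re-derive the checked quantities through different
mechanisms (regex over a joined token string; explicit window enumeration)
than the implementations under test.
"""

import math
import re


def regex_match_count(tokens, patterns):
    """Regex oracle for the prefix/phrase matching semantics."""
    joined = " " + " ".join(tokens) + " "
    start_to_index = {}
    pos = 1
    for i, t in enumerate(tokens):
        start_to_index[pos] = i
        pos += len(t) + 1
    token_hits = set()
    span_hits = set()
    for p in patterns:
        if p.kind == "root":
            rx = re.compile(r"(?<= )" + re.escape(p.tokens[0]))
            for m in rx.finditer(joined):
                token_hits.add(start_to_index[m.start()])
        else:
            body = r"[^ ]* ".join(re.escape(t) for t in p.tokens)
            rx = re.compile(r"(?<= )(?=" + body + r")")  # lookahead: overlapping spans
            for m in rx.finditer(joined):
                span_hits.add((start_to_index[m.start()], len(p.tokens)))
    return len(token_hits) + len(span_hits)


def cv_oracle(topics, token_docs, window, eps=1e-12):
    """Brute-force C_V: explicit window list, direct probability queries."""
    windows = []
    for doc in token_docs:
        if not doc:
            continue
        if len(doc) <= window:
            windows.append(set(doc))
        else:
            for i in range(len(doc) - window + 1):
                windows.append(set(doc[i : i + window]))
    n = len(windows)

    def prob(*words):
        return sum(1 for w in windows if all(x in w for x in words)) / n

    def npmi(a, b):
        pa, pb, pab = prob(a), prob(b), prob(a, b)
        if pa == 0.0 or pb == 0.0:
            return 0.0
        return math.log((pab + eps) / (pa * pb)) / (-math.log(pab + eps))

    topic_scores = []
    for words in topics:
        vecs = [[npmi(wi, wj) for wj in words] for wi in words]
        vsum = [sum(col) for col in zip(*vecs)]
        sims = []
        for v in vecs:
            dot = sum(x * y for x, y in zip(v, vsum))
            na = math.sqrt(sum(x * x for x in v))
            nb = math.sqrt(sum(y * y for y in vsum))
            sims.append(dot / (na * nb) if na > 0 and nb > 0 else 0.0)
        topic_scores.append(sum(sims) / len(sims))
    return sum(topic_scores) / len(topic_scores)
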