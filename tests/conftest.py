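import datetime

import pytest

import thememiner as tm


@pytest.fixture(scope="session")
def lex():
    return tm.builtin_lexicon()


def make_post(pid="p1", board="ovarian", user="alice", date=None, text=""):
    return tm.Post(pid, board, user, date or datetime.date(2011, 6, 1), text)


@pytest.fixture
def tiny_corpus():
    return tm.Corpus(
        [
            make_post("p1", "ovarian", "alice", datetime.date(2011, 3, 1), "nap nap nap"),
            make_post("p2", "uterine", "bob", datetime.date(2012, 4, 2), "my husband cried"),
            make_post("p3", "ovarian", "alice", datetime.date(2011, 5, 3), ""),
            make_post("p4", "other_gyn", "carol", datetime.date(2015, 6, 4), "so tired and worried, worried sick"),
            make_post("p5", "uterine", "bob", datetime.date(2012, 7, 5), "chemo scan chemo"),
        ]
    )


@pytest.fixture(scope="session")
def synth_corpus(lex):
    cfg = tm.SyntheticConfig(
        n_posts=400,
        theme_prevalence={"Fatigue": 0.2, "Anxiety": 0.1, "Insurance status": 0.15},
        seed=11,
    )
    return tm.generate_corpus(cfg, lex)


FIXTURE_PAGE = """<!DOCTYPE html>
<html><head><title>fixture</title></head><body>
<div class="thread">
<div class="post" id="a1">
<span class="username">ann</span>
<span class="date">2011-02-03</span>
<div class="post-text">feeling tired &amp; worried</div>
</div>
<div class="post" id="a2">
<span class="username">ben</span>
<span class="date">2012-12-31</span>
<div class="post-text">chemo tomorrow</div>
</div>
<div class="post" id="a3">
<span class="username">cat</span>
<span class="date">2000-07-21</span>
<div class="post-text"></div>
</div>
</div>
</body></html>
"""
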