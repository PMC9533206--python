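# thememiner

Keyword-lexicon theme mining and topic modeling for discussion-board post
corpora.

A post corpus (forum messages with board, author, date and text) is scored
against an a-priori lexicon of psychosocial themes: each theme's keywords —
truncated *root* words matched as token prefixes, and multi-token *phrases* —
are counted per post into an integer **theme score**. A post is *related* to
a theme when its score reaches a minimum threshold (default 3), and
*psychosocial-related* when at least one theme qualifies. On top of that the
package provides corpus descriptives (board composition, per-year theme
prevalence, top-word tables), selection of a qualitative reading sample
(top-k posts by total theme score with a per-user cap), and an independent
unsupervised route: LDA fit by collapsed Gibbs sampling, C_V-coherence topic
number selection, λ-weighted relevance ranking of topic terms, and an
overlap comparison of those terms against the lexicon.

A synthetic-corpus generator with planted, recoverable structure makes the
whole pipeline testable end to end without any external data.

## Modules

| module | contents |
|---|---|
| `thememiner.corpus_io` | `Post`/`Corpus`, fixture-HTML parsing, CSV post tables |
| `thememiner.lexicon` | keyword patterns, built-in 29-theme lexicon, loading/validation |
| `thememiner.scoring` | tokenizer, matcher, `ScoreMatrix`, classification, qualitative sample, rater agreement |
| `thememiner.descriptives` | corpus summary, prevalence by (board, year), word frequencies |
| `thememiner.topic_model` | bag-of-words, collapsed-Gibbs LDA, C_V coherence, K selection, relevance, lexicon overlap |
| `thememiner.synthetic` | seeded corpus generator with planted themes/topics, fixture HTML, recovery metrics |

## CLI

```bash
# generate a synthetic corpus (posts.csv + truth.csv, optional fixture HTML)
thememiner synth --n-posts 2000 --seed 1 --html --out-dir data/

# parse fixture HTML pages back into a post table
thememiner parse-html --page data/html/ovarian_page0000.html ovarian --out posts.csv

# theme scores for every post
thememiner score --corpus data/posts.csv --min-score 3 --out scores.csv

# board/year summaries, prevalence, top words (add --plots for PNGs)
thememiner describe --corpus data/posts.csv --scores scores.csv --out-dir desc/

# qualitative sample: top-k total score, max 5 posts per user
thememiner sample --corpus data/posts.csv --scores scores.csv --k 20 --out sample.csv

# coherence sweep, relevance-ranked topic terms, lexicon overlap
thememiner topics --corpus data/posts.csv --k-min 2 --k-max 40 --k-step 2 \
    --lambda 0.6 --n-terms 7 --seed 1 --out-dir topics/
```

`thememiner synth --config cfg.yaml` accepts a YAML file whose keys mirror
`SyntheticConfig` (n_posts, board_weights, year_range, theme_prevalence,
keywords_per_planted_theme, noise_keyword_rate, n_latent_topics, ...).

## File formats

**Post table** — RFC-4180 CSV, UTF-8, header
`post_id,board,username,date,text`; dates are ISO 8601 (date only); text may
contain commas, quotes and newlines (quoted/escaped; round-trips exactly).

**Fixture HTML dialect** — each post is

```html
<div class="post" id="POST_ID">
  <span class="username">NAME</span>
  <span class="date">2011-02-03</span>
  <div class="post-text">TEXT (HTML-escaped)</div>
</div>
```

Pages carry one board each; `generate_fixture_html` writes a
`manifest.json` mapping page files to board labels and
`read_fixture_dir` reconstructs the corpus from it.

**Lexicon config** — plain text, `[Theme name]` headers, one keyword per
line; multi-word lines become phrase patterns, single words become root
(prefix) patterns. The built-in default is
`src/thememiner/data/box1_lexicon.txt` (checksum-pinned by the tests).

**Score matrix export** — CSV with one row per post, one column per theme,
plus `total` (sum of theme scores) and `related` (0/1 at the threshold).

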