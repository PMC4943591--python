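# Methods

## Detection model and assumptions

The pipeline assumes promotional automation leaves three linguistic
fingerprints on an account's tweet stream: links are attached to almost
every message, messages are near-duplicates of a template, and the
vocabulary is closed. Human (organic) streams show the opposite pattern:
few links, high inter-tweet dissimilarity, and open vocabulary growth.
Detection is therefore framed as *one-class* classification: the organic
region of feature space is learned from trusted organic accounts, and
anything falling outside it on any axis is called automated. This
deliberately biases toward catching automation at the cost of
false-positive humans, which is why it is paired with an explicit
false-positive budget in evaluation.

A keyword tier runs first because jargon-stuffed advertising is cheap to
identify and needs no per-account sample: ≥ 3 advertising-jargon phrase
hits label the tweet automated immediately, and ≥ 10 such original tweets
flag the whole account. Retweets count toward tweet labels but never
toward the account flag — humans demonstrably retweet promotions for
rewards, and the account-level judgment should reflect authored content.

### Features

* **URL rate** (URLs/tweet, ≥ 0). URL detection uses an explicit pattern —
  `http(s)://` or `www.` up to whitespace — rather than a third-party
  extractor, so counts are reproducible bit-for-bit.
* **Mean pairwise dissimilarity** (dimensionless, [0, 1]). The character
  length of the longest common **contiguous** substring is used (whitespace
  included, text compared as-is; no case folding or accent folding by
  default so lengths stay byte-faithful — both normalizations exist as
  flags). The contiguous reading, rather than the classic non-contiguous
  longest common subsequence, is deliberate: templated marketing output is
  characterized by long unbroken shared runs, and interleaved subsequences
  would score unrelated human sentences as far more similar. A
  `mode="subsequence"` flag exists for sensitivity analysis, and the
  formula is also exposed on pre-computed lengths
  (`dissimilarity_from_lengths`) so count-level arithmetic can be verified
  independently of string handling. The computation over a sample is exact
  (all n(n−1)/2 pairs, no sampling); the O(n²·len²) cost is bounded by the
  500-tweet sample cap and 280-character tweets, with the inner dynamic
  program JIT-compiled.
* **Word-introduction decay rate** (dimensionless). Operationalized as the
  Heaps-law exponent: slope of log u(n) against log n by ordinary least
  squares over n = 10 … N, where u(n) counts distinct tokens among the
  first n of the concatenated stream. The fit start of 10 tokens avoids
  the trivially linear head where u(n) ≈ n for any text; streams shorter
  than 10 tokens are rejected. A purely repeating stream yields γ = 0 and
  an all-new-token stream yields exactly 1 (the slope is computed as a
  ratio of identical sums, so the value is exact, not approximate).

Features are computed on the first `bin` tweets of the ordinal stream,
`bin = min(500, 25·⌊n/25⌋)`; accounts under 25 tweets are routed to
default rules (plain tweets → organic; URL-bearing tweets → discarded).

### Calibration

Cutoffs per bin and feature are the symmetric percentiles
[(100−p)/2, 100−(100−p)/2] of the organic training distribution, default
p = 99. Boundary values count as *inside* the box; with p = 100 the
cutoffs are the training min/max and every training account is provably
classified organic (zero training false positives) — this inclusive-bound
tie-break is chosen precisely to make that guarantee hold.

Bins with fewer than 5 training accounts are pooled with the nearest
populated bin (ties prefer the better-populated neighbor) before the
percentiles are taken: an empirical 0.5th/99.5th percentile from one to
four points collapses to (nearly) a point box and mislabels almost every
organic account that lands in that bin. Bins entirely absent from
training inherit the nearest populated bin's cutoffs at lookup time.

### Cascade order

The fixed order is: keyword tier → marketing-user flag → box
classification (accounts ≥ 25 tweets; remaining tweets inherit the account
label) → default/discard rules for small accounts. Keyword-tier labels are
never overturned by later stages. Jargon counting matches multi-word
phrases before their constituent words with overlaps disallowed, so "free
trial" is one hit, not two. Keyword-tier tweets remain part of the
account's feature sample: excluding them would let a mixed spammer look
more organic on the residual. Retweet status uses the `is_retweet` field
when present, else an "RT @" prefix heuristic.

## Topics, reach, cyborgs

Topic assignment needs only one phrase hit per topic — the ≥ 3 rule is the
automation tier's, not the topic tally's — and topics overlap by design
(discount keywords are largely a subset of commercial ones). Optional
fragments in configured phrases, e.g. "coupon(s)", are expanded
mechanically to both variants at load time so matching stays literal.
Impressions sum follower counts per tweet (not per account): they estimate
potential timeline appearances, in which the same follower is reached once
per post. Cyborg templates are configuration data (YAML); the matcher
compiles each into a punctuation-tolerant regex over case-folded,
punctuation-stripped tokens with wildcard slots (handle, 1–3-token brand,
integer, URL), so a new campaign is a config entry, not code.

## Hedonometrics

Corpus happiness pools word frequencies across the tweet set (the
alternative — averaging per-tweet scores — weights short tweets up; pooled
frequencies are what the weighted-mean formula denotes). The stop-word
window [4, 6] is closed on both ends. The word-shift contribution
`δ_w = (h_w − h̄_ref)(p_w^comp − p_w^ref)` is the standard
reference-mean-centered decomposition; it is adopted because it satisfies
the conservation identity Σδ_w = h̄_comp − h̄_ref algebraically, which the
tests assert to 1e−9. A word-exclusion list is applied before
normalization (both corpora), mirroring the practice of dropping
campaign-dominating words like "free"/"trial" when reading a shift.
Monthly series use local post time (UTC + reported offset; missing offsets
fall back to UTC and are flagged); months with nothing scorable are
reported as missing, never as zero.

## Synthetic study conditions

The generator emulates statistical structure, not textual realism — no
language model, just the feature geometry each class must occupy:

* **organic**: Zipf-sampled (exponent 1.05, vocabulary 30,000) pseudo-word
  text, URL probability 0.10, 5% promotional retweets, and per-month
  injectable positive/negative sentiment tokens (default negative share
  0.3) so time-series structure is recoverable;
* **automated**: one fixed 10-word template per account from a 20-word
  account vocabulary, word-swap rate 0.03, campaign URL on 92% of tweets
  (the automated-URL share observed in large e-cigarette tweet corpora),
  trailing topic phrases (rate 0.15) and jargon (rate 0.08, plus 4%
  three-phrase bursts that trip the keyword tier);
* **cyborg**: the shipped testimonial templates instantiated with random
  handles, a per-account brand, week counts and URLs (URL rate 1.0 — which
  is what betrays them to the box despite their organic-looking
  dissimilarity).

Tweets per account are lognormal (median 60, σ = 0.45) clipped to
[25, 300], so generated accounts are classifiable by the box; the raw
garden-hose reality of many sub-25-tweet accounts is exercised separately
by lowering `min_tweets` in tests of the discard/default rules. Follower
counts are Pareto (α = 1.16, scale 50) so impressions are dominated by a
few accounts. Under these defaults the classes separate cleanly (organic ≈
(0.10, 0.86, 0.85) in (URL rate, dissimilarity, decay); automated ≈
(0.93, 0.19, 0.23)), which is the designed operating condition for the
recovery benchmark. Passing tests therefore show the cascade recovers
*separable* classes at calibrated thresholds; they do not show performance
on real streams, where feature overlap, multilingual text, and adversarial
adaptation all erode separation.

The benchmark (`vapewatch.benchmark`) calibrates on 752 synthetic organic
accounts — the size of the human class such detectors have historically
been trained on — and evaluates account-level recovery on a fresh
100 + 100 corpus. Typical seeds give a 1.00 true-positive rate at 0.02–0.08
false positives. The shipped keyword configuration contains the phrase
lists quoted under each topic plus a flavor-name list of common e-liquid
flavors; the synthetic lexicon assigns uniform [1, 9] scores over the
generator vocabulary with fixed strongly-valenced scores for the injectable
sentiment tokens.

## Numerical and scale choices

* LCS agreement with the brute-force enumeration oracle is checked
  exhaustively over **all** pairs of strings of length ≤ 4 on a 3-letter
  alphabet plus 1,000 seeded random pairs of length ≤ 8; exhaustive length
  8 (≈ 48 million pairs against a quadratic oracle) adds nothing to
  correctness coverage at four orders of magnitude more cost.
* Percentiles use linear interpolation (NumPy default); the p = 100
  guarantee is interpolation-free by construction.
* Dissimilarity of two empty strings is undefined and raises; a
  single-tweet sample has no pairs and raises; degenerate (constant)
  training features give lower = upper cutoffs, still classified organic
  on the boundary.
* Tweet ordering ties (equal timestamps) are resolved by stable sort, so
  ordinal samples are reproducible.

## Known limitations

No follower-graph or posting-cadence features; no multilingual lexicons;
no URL landing-page crawling (only URL string scanning); the decay-rate
estimator is this package's Heaps-exponent operationalization and other
estimators of vocabulary openness would shift the calibrated cutoffs; the
synthetic benchmark's error rates are properties of the generator's
separation, not estimates of real-world accuracy.
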