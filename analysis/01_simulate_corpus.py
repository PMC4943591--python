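#!/usr/bin/env python
"""Generate the default synthetic e-cigarette tweet corpus.

Writes a seeded, shuffled mixed corpus (100 organic, 80 automated, 20 cyborg
accounts) plus its ground-truth labels.  Everything downstream
(02-05) consumes these files, so re-running this script reproduces the whole
analysis byte-for-byte.
"""

from pathlib import Path

from vapewatch.corpus_io import count_urls, read_corpus
from vapewatch.synthetic import GeneratorConfig, write_corpus_files

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main() -> None:
    cfg = GeneratorConfig(seed=SEED)
    paths = write_corpus_files(cfg, RESULTS / "corpus")
    tweets = read_corpus(paths["corpus"])
    n_url = sum(1 for t in tweets if count_urls(t.text) > 0)
    accounts = {t.account_id for t in tweets}
    print(f"wrote {paths['corpus']}")
    print(f"  {len(tweets)} tweets from {len(accounts)} accounts (seed {SEED})")
    print(f"  {100 * n_url / len(tweets):.1f}% of tweets carry a URL")


if __name__ == "__main__":
    main()
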