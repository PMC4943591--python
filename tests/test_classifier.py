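from __future__ import annotations

import numpy as np
import pytest

from vapewatch.classifier import (
    BoxCalibration,
    calibrate,
    classify_account,
    classify_corpus,
    count_jargon_hits,
    flag_marketing_users,
    keyword_tier,
    label_counts,
    url_commercial,
)
from vapewatch.corpus_io import group_accounts
from vapewatch.features import AccountFeatures, compute_features
from vapewatch.synthetic import GeneratorConfig, generate_account, generate_corpus

from .conftest import make_tweet


class TestKeywordTier:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("Coupon inside! Free trial starter kit", True),
            ("I tried a free trial once", False),
            ("", False),
            ("buy buy buy", True),  # multiplicity counts
        ],
    )
    def test_examples(self, kw_config, text, expected):
        tweet = make_tweet(text) if text else None
        if tweet is None:
            assert count_jargon_hits("", kw_config.marketing_jargon) == 0
        else:
            assert keyword_tier(tweet, kw_config) is expected

    def test_multiword_phrases_not_double_counted(self, kw_config):
        # "free trial" must count once, not as "free" + "trial"
        assert count_jargon_hits("free trial", kw_config.marketing_jargon) == 1


class TestUrlCommercial:
    @pytest.mark.parametrize(
        "url, expected",
        [
            ("shop.example/discount-sale-coupon", True),
            ("example.org/news", False),
            ("x.co/free", False),
        ],
    )
    def test_examples(self, kw_config, url, expected):
        assert url_commercial(url, kw_config) is expected

    def test_empty_url_errors(self, kw_config):
        with pytest.raises(ValueError):
            url_commercial("", kw_config)


class TestMarketingUserFlag:
    def _tweets(self, n_marketing, n_retweet_marketing=0, account="a"):
        tweets, hits = [], {}
        for i in range(n_marketing):
            t = make_tweet("spam", tweet_id=f"m{i}", account_id=account)
            tweets.append(t)
            hits[t.tweet_id] = True
        for i in range(n_retweet_marketing):
            t = make_tweet("RT spam", tweet_id=f"r{i}", account_id=account, retweet=True)
            tweets.append(t)
            hits[t.tweet_id] = True
        return tweets, hits

    def test_threshold_flags(self):
        tweets, hits = self._tweets(10)
        assert flag_marketing_users(tweets, hits) == {"a"}

    def test_below_threshold(self):
        tweets, hits = self._tweets(9)
        assert flag_marketing_users(tweets, hits) == set()

    def test_retweets_do_not_count_toward_flag(self):
        tweets, hits = self._tweets(0, n_retweet_marketing=12)
        assert flag_marketing_users(tweets, hits) == set()


def _features(bin_=25, url=0.1, dis=0.86, dec=0.85):
    return AccountFeatures("x", url, dis, dec, n_tweets=bin_, bin=bin_)


def _box(url=(0.0, 0.2), dis=(0.8, 0.9), dec=(0.7, 1.0)):
    return BoxCalibration(
        cutoffs={25: {"url_rate": url, "mean_dissimilarity": dis, "decay_rate": dec}}
    )


class TestBoxClassification:
    def test_inside_is_organic(self):
        assert classify_account(_features(), _box()) == "organic"

    def test_one_feature_outside_is_automated(self):
        assert classify_account(_features(url=0.9), _box()) == "automated"

    def test_boundary_counts_as_inside(self):
        assert classify_account(_features(url=0.2, dis=0.8, dec=1.0), _box()) == "organic"

    def test_unpopulated_bin_inherits_nearest(self):
        cal = _box()
        assert cal.for_bin(150) == cal.for_bin(25)

    def test_round_trip_persistence(self, tmp_path):
        cal = _box()
        for name in ("cal.yaml", "cal.json"):
            path = tmp_path / name
            cal.save(path)
            assert BoxCalibration.load(path).cutoffs == cal.cutoffs


class TestCalibrate:
    def test_cutoffs_match_direct_percentile_oracle(self, small_config):
        train = [
            generate_account("organic", small_config, seed=11_000 + i)[0]
            for i in range(30)
        ]
        cal = calibrate(train, percentile=90)
        feats = [compute_features(a) for a in train]
        by_bin: dict[int, list] = {}
        for f in feats:
            by_bin.setdefault(f.bin, []).append(f)
        for b, fs in by_bin.items():
            for name in ("url_rate", "mean_dissimilarity", "decay_rate"):
                vals = [getattr(f, name) for f in fs]
                lo, hi = np.percentile(vals, [5.0, 95.0])
                assert cal.cutoffs[b][name] == pytest.approx((lo, hi))

    def test_p100_zero_training_false_positives(self, small_config):
        train = [
            generate_account("organic", small_config, seed=12_000 + i)[0]
            for i in range(25)
        ]
        cal = calibrate(train, percentile=100)
        for acct in train:
            assert classify_account(compute_features(acct), cal) == "organic"

    def test_no_training_accounts_errors(self):
        with pytest.raises(ValueError):
            calibrate([])


class TestCascade:
    def test_small_account_discard_and_default_rules(self, kw_config, small_calibration):
        tweets = [
            make_tweet("look http://x.co/a", tweet_id="u1", account_id="small"),
            make_tweet("see www.y.co/b", tweet_id="u2", account_id="small"),
            make_tweet("plain one", tweet_id="p1", account_id="small"),
            make_tweet("plain two", tweet_id="p2", account_id="small"),
            make_tweet("plain three", tweet_id="p3", account_id="small"),
        ]
        labels, acct_labels = classify_corpus(tweets, kw_config, small_calibration)
        assert {labels[f"u{i}"].label for i in (1, 2)} == {"discarded"}
        assert {labels[f"p{i}"].label for i in (1, 2, 3)} == {"organic"}
        assert {labels[f"p{i}"].source for i in (1, 2, 3)} == {"default_organic"}
        assert acct_labels["small"].label == "not_classified"

    def test_unknown_account_errors(self, kw_config, small_calibration):
        tweets = [make_tweet("x", account_id="ghost")]
        with pytest.raises(ValueError, match="unknown account"):
            classify_corpus(tweets, kw_config, small_calibration, accounts={})

    def test_partition_and_idempotence(self, kw_config, small_calibration, small_config):
        tweets, _, _ = generate_corpus(small_config)
        labels1, accts1 = classify_corpus(tweets, kw_config, small_calibration)
        counts = label_counts(labels1)
        assert sum(counts.values()) == len(tweets)
        assert set(labels1) == {t.tweet_id for t in tweets}
        labels2, accts2 = classify_corpus(tweets, kw_config, small_calibration)
        assert labels1 == labels2 and accts1 == accts2

    def test_marketing_account_inherits_everywhere(self, kw_config, small_calibration):
        tweets = [
            make_tweet("buy save coupon discount", tweet_id=f"m{i}", account_id="mk")
            for i in range(10)
        ] + [make_tweet("innocuous message", tweet_id="i0", account_id="mk")]
        labels, accts = classify_corpus(tweets, kw_config, small_calibration)
        assert accts["mk"].label == "automated"
        assert labels["i0"].label == "automated"
        assert labels["i0"].source == "marketing_user"

    def test_zero_discarded_when_all_accounts_large(
        self, kw_config, small_calibration, small_config
    ):
        tweets, _, _ = generate_corpus(small_config)
        accounts = group_accounts(tweets)
        assert all(len(a) >= 25 for a in accounts.values())
        labels, _ = classify_corpus(tweets, kw_config, small_calibration)
        assert label_counts(labels)["discarded"] == 0
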