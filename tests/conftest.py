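from __future__ import annotations

from datetime import datetime

import pytest
from hypothesis import HealthCheck, settings

from vapewatch.corpus_io import Tweet, default_keyword_config
from vapewatch.synthetic import GeneratorConfig, generate_account
from vapewatch.classifier import calibrate
from vapewatch.topics import default_cyborg_templates

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_tweet(
    text: str,
    tweet_id: str = "t0",
    account_id: str = "a0",
    when: datetime | None = None,
    followers: int = 10,
    tz: int | None = 0,
    retweet: bool = False,
) -> Tweet:
    return Tweet(
        tweet_id=tweet_id,
        account_id=account_id,
        utc_time=when or datetime(2013, 6, 1, 12, 0, 0),
        tz_offset_minutes=tz,
        text=text,
        follower_count=followers,
        is_retweet=retweet,
    )


@pytest.fixture(scope="session")
def kw_config():
    return default_keyword_config()


@pytest.fixture(scope="session")
def cyborg_templates():
    return default_cyborg_templates()


# Small, single-bin study conditions: every account lands in the 25-tweet bin,
# so a modest organic training set calibrates quickly.
@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        n_organic=20,
        n_automated=15,
        n_cyborg=5,
        tweets_log_mean=3.4,  # ~30 tweets
        tweets_log_sigma=0.1,
        min_tweets=25,
        max_tweets=49,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_calibration(small_config):
    train = [
        generate_account("organic", small_config, seed=90_000 + i, account_id=f"tr{i:03d}")[0]
        for i in range(40)
    ]
    return calibrate(train, percentile=99)
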