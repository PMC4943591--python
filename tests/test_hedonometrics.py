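from __future__ import annotations

from datetime import datetime

import pytest
from hypothesis import given
from hypothesis import strategies as st

from vapewatch.hedonometrics import (
    HappinessLexicon,
    corpus_happiness,
    count_words,
    load_labmt_lexicon,
    monthly_series,
    word_shift,
)
from vapewatch.synthetic import GeneratorConfig, generate_corpus, generate_lexicon

from .conftest import make_tweet


@pytest.fixture(scope="module")
def tiny_lexicon():
    return HappinessLexicon({"a": 8.0, "b": 2.0, "neutral": 5.0, "high": 7.1})


class TestCorpusHappiness:
    def test_single_word_corpus(self, tiny_lexicon):
        cs = corpus_happiness({"high": 3}, tiny_lexicon)
        assert cs.h_avg == pytest.approx(7.1)
        assert cs.n_scored_tokens == 3

    def test_hand_weighted_mean(self, tiny_lexicon):
        cs = corpus_happiness({"a": 1, "b": 1}, tiny_lexicon)
        assert cs.h_avg == pytest.approx(5.0)

    def test_all_stop_window_errors(self, tiny_lexicon):
        with pytest.raises(ValueError, match="no scorable"):
            corpus_happiness({"neutral": 10}, tiny_lexicon)

    def test_out_of_lexicon_ignored(self, tiny_lexicon):
        cs = corpus_happiness({"a": 1, "zzz": 50}, tiny_lexicon)
        assert cs.h_avg == pytest.approx(8.0)

    @given(
        st.dictionaries(
            st.sampled_from(["a", "b", "high"]), st.integers(1, 50), min_size=1
        ),
        st.integers(0, 100),
        st.integers(1, 7),
    )
    def test_stop_word_invariance_bounds_and_scale(self, freqs, n_neutral, scale):
        lex = HappinessLexicon({"a": 8.0, "b": 2.0, "neutral": 5.0, "high": 7.1})
        base = corpus_happiness(freqs, lex)
        assert 1.0 <= base.h_avg <= 9.0
        scores = [lex.scores[w] for w in base.freqs]
        assert min(scores) - 1e-9 <= base.h_avg <= max(scores) + 1e-9
        # neutral tokens never move the average
        with_stop = dict(freqs, neutral=n_neutral)
        assert corpus_happiness(with_stop, lex).h_avg == pytest.approx(base.h_avg)
        # multiplying all frequencies by a constant never moves it either
        scaled = {w: f * scale for w, f in freqs.items()}
        assert corpus_happiness(scaled, lex).h_avg == pytest.approx(base.h_avg)


class TestWordShift:
    def test_identical_corpora_zero_shift(self, tiny_lexicon):
        ws = word_shift({"a": 3, "b": 1}, {"a": 3, "b": 1}, tiny_lexicon)
        assert ws.total_shift == pytest.approx(0.0)
        assert all(e.delta == pytest.approx(0.0) for e in ws.entries)

    def test_hand_algebra_two_word_swap(self, tiny_lexicon):
        # ref all-a (h̄=8), comp all-b (h̄=2): δ_b = (2−8)·(1−0) = −6, δ_a = 0
        ws = word_shift({"a": 10}, {"b": 10}, tiny_lexicon)
        assert ws.total_shift == pytest.approx(-6.0)
        top = ws.entries[0]
        assert top.word == "b" and top.delta == pytest.approx(-6.0)
        assert top.freq_direction == "↑" and top.sign == "−"
        assert ws.delta_sum == pytest.approx(ws.total_shift, abs=1e-9)

    def test_exclusion_list(self, tiny_lexicon):
        ws = word_shift({"a": 5, "b": 5}, {"a": 5, "b": 1}, tiny_lexicon, exclude=["b"])
        assert ws.total_shift == pytest.approx(0.0)
        assert all(e.word != "b" for e in ws.entries)

    @given(
        st.dictionaries(st.sampled_from("abcdefgh"), st.integers(1, 99), min_size=1),
        st.dictionaries(st.sampled_from("abcdefgh"), st.integers(1, 99), min_size=1),
    )
    def test_conservation_identity(self, ref, comp):
        lex = HappinessLexicon(
            {w: 1.0 + 8.0 * i / 7 for i, w in enumerate("abcdefgh")}
        )
        ref = {w: f for w, f in ref.items() if lex.is_scored(w)}
        comp = {w: f for w, f in comp.items() if lex.is_scored(w)}
        if not ref or not comp:
            return
        ws = word_shift(ref, comp, lex)
        assert ws.delta_sum == pytest.approx(ws.total_shift, abs=1e-9)

    def test_ranked_by_absolute_contribution_and_truncated(self, tiny_lexicon):
        ws = word_shift({"a": 9, "b": 1}, {"a": 1, "b": 9}, tiny_lexicon, k=1)
        assert len(ws.entries) == 1
        assert ws.delta_sum == pytest.approx(ws.total_shift, abs=1e-9)


class TestLexiconIO:
    def test_labmt_round_trip(self, tmp_path, tiny_lexicon):
        path = tmp_path / "lex.tsv"
        tiny_lexicon.save(path)
        loaded = load_labmt_lexicon(path)
        assert loaded.scores == pytest.approx(tiny_lexicon.scores)

    def test_score_bounds_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            HappinessLexicon({"w": 9.5})


class TestMonthlySeries:
    def test_single_month(self, tiny_lexicon):
        tweets = [make_tweet("a a b", when=datetime(2013, 3, 5))]
        df = monthly_series(tweets, tiny_lexicon)
        assert len(df) == 1
        assert df.iloc[0]["h_avg"] == pytest.approx((8 * 2 + 2) / 3)

    def test_empty_corpus(self, tiny_lexicon):
        assert monthly_series([], tiny_lexicon).empty

    def test_unscorable_month_missing_not_zero(self, tiny_lexicon):
        tweets = [
            make_tweet("a b", when=datetime(2013, 1, 10)),
            make_tweet("zzz qqq", when=datetime(2013, 2, 10)),
        ]
        df = monthly_series(tweets, tiny_lexicon)
        assert [str(m) for m in df["month"]] == ["2013-01"]

    def test_recovers_generator_step_direction(self):
        # three months: negative-word injection stepped up in the last month
        cfg = GeneratorConfig(
            n_organic=20,
            n_automated=0,
            n_cyborg=0,
            seed=21,
            date_start=datetime(2013, 1, 1),
            date_end=datetime(2013, 3, 31),
            monthly_negative_rate={"2013-01": 0.1, "2013-02": 0.1, "2013-03": 0.9},
        )
        tweets, _, _ = generate_corpus(cfg)
        lex = generate_lexicon(2000, seed=3)
        df = monthly_series(tweets, lex).set_index("month")
        h = {str(m): v for m, v in df["h_avg"].items()}
        assert h["2013-03"] < h["2013-01"]
        assert h["2013-03"] < h["2013-02"]
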