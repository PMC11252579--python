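import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisislda.preprocess import (TextPreprocessor, TokenDoc, apply_phrases,
                                  build_vocabulary, fit_phrases, lemmatize,
                                  to_bow, tokenize)


class TestTokenize:
    @pytest.mark.parametrize("text,expected", [
        ("Vaccines WORK! https://t.co/x @who #hope",
         ("vaccines", "work", "hope")),
        ("", ()),
        ("COVID-19 covid-19", ("covid", "19", "covid", "19")),
        ("Stay safe... stay home!!", ("stay", "safe", "stay", "home")),
        ("@user1 @user2 ...", ()),
    ])
    def test_rule_application(self, text, expected):
        assert tokenize(text).tokens == expected

    def test_hashtag_word_kept_without_hash(self):
        assert tokenize("#StayHomeStaySafe now").tokens == (
            "stayhomestaysafe", "now")

    @given(st.text(max_size=80))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_idempotent_on_own_output(self, text):
        once = tokenize(text).tokens
        again = tokenize(" ".join(once)).tokens
        assert once == again


class TestLemmatize:
    LEX = {"vaccinated": ("vaccinate", "verb"), "quickly": ("quickly", "adverb")}

    def test_pos_filter_drops_adverbs(self):
        doc = TokenDoc(("vaccinated", "quickly"))
        assert lemmatize(doc, self.LEX).tokens == ("vaccinate",)

    def test_unknown_token_kept_as_noun(self):
        doc = TokenDoc(("zyzzyva",))
        assert lemmatize(doc, self.LEX).tokens == ("zyzzyva",)

    def test_disabled_filter_only_substitutes(self):
        doc = TokenDoc(("vaccinated", "quickly"))
        out = lemmatize(doc, self.LEX,
                        pos_filter=frozenset({"noun", "verb", "adjective",
                                              "adverb"}))
        assert out.tokens == ("vaccinate", "quickly")


class TestPhrases:
    def test_score_formula_on_hand_counts(self):
        # "social distancing" adjacent in all 4 docs; 6 distinct tokens.
        docs = [TokenDoc(("social", "distancing", filler))
                for filler in ("a", "b", "c", "d")]
        model = fit_phrases(docs, min_count=1, threshold=0.5, order="bigram")
        # count(social,distancing)=4, count(social)=count(distancing)=4, V=6
        expected = (4 - 1) * 6 / (4 * 4)
        assert model.phrase_scores[("social", "distancing")] == pytest.approx(expected)
        merged = apply_phrases(model, docs[0])
        assert merged.tokens[0] == "social_distancing"

    def test_rare_pair_scores_below_zero(self):
        docs = [TokenDoc(("stay", "home"))] + [
            TokenDoc(("stay", "x"), ) for _ in range(5)]
        model = fit_phrases(docs, min_count=5, threshold=0.1)
        assert ("stay", "home") not in model.phrase_scores

    def test_trigram_needs_two_passes(self):
        docs = [TokenDoc(("stay", "home", "safe", f"pad{i}"))
                for i in range(6)]
        model = fit_phrases(docs, min_count=1, threshold=0.1, order="trigram")
        out = apply_phrases(model, docs[0])
        assert out.tokens[0] == "stay_home_safe"

    def test_greedy_leftmost_merge(self):
        model = fit_phrases([TokenDoc(("x",))], min_count=1, threshold=1.0)
        model = type(model)("bigram", 1, 1.0,
                            {("a", "b"): 2.0, ("b", "c"): 2.0})
        assert apply_phrases(model, TokenDoc(("a", "b", "c"))).tokens == \
            ("a_b", "c")

    def test_empty_model_is_identity(self):
        model = fit_phrases([TokenDoc(("q", "r"))], min_count=5, threshold=10)
        doc = TokenDoc(("q", "r", "s"))
        assert apply_phrases(model, doc).tokens == doc.tokens

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            fit_phrases([TokenDoc(("a",))], min_count=0)
        with pytest.raises(ValueError):
            fit_phrases([TokenDoc(("a",))], threshold=0.0)

    @given(st.lists(st.sampled_from("abcde"), min_size=0, max_size=12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_merge_never_increases_count_and_preserves_chars(self, toks):
        model = fit_phrases(
            [TokenDoc(("a", "b")), TokenDoc(("a", "b"))],
            min_count=1, threshold=0.1)
        doc = TokenDoc(tuple(toks))
        out = apply_phrases(model, doc)
        assert len(out) <= len(doc)
        assert "".join(out.tokens).replace("_", "") == "".join(doc.tokens)


class TestVocabularyAndBow:
    def test_max_df_drops_ubiquitous_terms(self):
        docs = [TokenDoc(("common", f"rare{i}")) for i in range(3)]
        vocab = build_vocabulary(docs, min_df=1, max_df_frac=0.9)
        assert "common" not in vocab
        assert all(f"rare{i}" in vocab for i in range(3))

    def test_min_df_and_lexicographic_ids(self):
        docs = [TokenDoc(("b", "a")), TokenDoc(("a", "b")), TokenDoc(("zzz",))]
        vocab = build_vocabulary(docs, min_df=2)
        assert vocab.id_of == {"a": 0, "b": 1}
        assert vocab.df == {"a": 2, "b": 2}

    def test_empty_vocabulary_is_fatal(self):
        with pytest.raises(ValueError, match="empty vocabulary"):
            build_vocabulary([TokenDoc(("solo",))], min_df=2)

    def test_bow_counts_and_oov(self):
        docs = [TokenDoc(("a", "b")), TokenDoc(("a",))]
        vocab = build_vocabulary(docs)
        bow = to_bow(TokenDoc(("a", "b", "a", "zzz")), vocab)
        assert bow.counts == {0: 2, 1: 1}
        assert bow.n_tokens == 3
        assert to_bow(TokenDoc(("oov",)), vocab).n_tokens == 0

    @given(st.lists(st.sampled_from("abcdef"), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bow_token_conservation(self, toks):
        vocab = build_vocabulary([TokenDoc(tuple("abcdef"))])
        bow = to_bow(TokenDoc(tuple(toks)), vocab)
        assert bow.n_tokens == sum(bow.counts.values()) == len(toks)


def test_text_preprocessor_pipeline_shapes():
    texts = ["the vaccines work fine now", "masks and vaccines work",
             "stay home stay safe now"]
    prep = TextPreprocessor(phrase_order="bigram", min_count=1, threshold=0.1)
    bows = prep.fit(texts).transform(texts)
    assert len(bows) == 3
    assert all(b.n_tokens > 0 for b in bows)
    assert prep.vocabulary_.V >= 3
    params = prep.get_params()
    assert params["phrase_order"] == "bigram"
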