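import numpy as np
import pytest
from sklearn.base import clone

from langtraj.assess import (
    ASSESSMENT_NAMES,
    AssessmentTransformer,
    apply_model,
    assess_transcripts,
    assessment_profile,
    meta_features,
    meta_from_counts,
    score_lexicon,
)
from langtraj.featurize import FeatureVector, TokenDocument, featurize, tokenize
from langtraj.io import (
    RESPONDER,
    LinearAssessmentModel,
    Transcript,
    Turn,
    WeightedLexicon,
)


def relfreq_of(tokens):
    n = len(tokens)
    out = {}
    for t in tokens:
        out[t] = out.get(t, 0.0) + 1.0 / n
    return out


# ------------------------------------------------------------ lexicon scoring

def test_category_score_is_weighted_relative_frequency():
    lex = WeightedLexicon("x", {"fp_plural": {"we": 1.0}})
    assert score_lexicon(relfreq_of(["i", "we", "we"]), lex, "fp_plural") == pytest.approx(2 / 3)


def test_wildcard_prefix_match():
    lex = WeightedLexicon("x", {"social": {"friend*": 1.0}})
    assert score_lexicon(relfreq_of(["friends"]), lex, "social") == pytest.approx(1.0)


def test_longest_matching_pattern_wins_and_token_counts_once():
    lex = WeightedLexicon("x", {"social": {"friend*": 2.0, "friends": 5.0, "f*": 0.5}})
    # "friends": exact 'friends' beats both wildcards; "friendly": 'friend*' beats 'f*'
    score = score_lexicon(relfreq_of(["friends", "friendly"]), lex, "social")
    assert score == pytest.approx(0.5 * 5.0 + 0.5 * 2.0)


def test_unknown_category_lists_available():
    lex = WeightedLexicon("x", {"social": {"we": 1.0}})
    with pytest.raises(KeyError, match="social"):
        score_lexicon({"we": 1.0}, lex, "fp_plural")


def test_lexicon_score_matches_brute_force_on_random_documents():
    rng = np.random.default_rng(7)
    vocab = ["we", "us", "went", "friends", "friendly", "dog", "i", "fries"]
    lex = WeightedLexicon("x", {"cat": {"we": 1.0, "fri*": 2.0, "friends": 3.0}})

    def brute(tokens):
        total = 0.0
        for tok in tokens:
            candidates = []
            for pat, w in lex.categories["cat"].items():
                if pat.endswith("*") and tok.startswith(pat[:-1]):
                    candidates.append((len(pat) - 1, 0, w))
                elif tok == pat:
                    candidates.append((len(pat), 1, w))
            if candidates:
                total += max(candidates)[2] / len(tokens)
        return total

    for _ in range(20):
        tokens = list(rng.choice(vocab, size=200))
        got = score_lexicon(relfreq_of(tokens), lex, "cat")
        assert got == pytest.approx(brute(tokens), abs=1e-12)


def test_lexicon_score_invariant_to_token_order():
    rng = np.random.default_rng(3)
    tokens = list(rng.choice(["we", "i", "dog", "friends"], size=120))
    lex = WeightedLexicon("x", {"cat": {"we": 1.0, "friend*": 2.0}})
    before = score_lexicon(relfreq_of(tokens), lex, "cat")
    rng.shuffle(tokens)
    assert score_lexicon(relfreq_of(tokens), lex, "cat") == pytest.approx(before)


# --------------------------------------------------------------- trait models

def test_model_application_is_a_dot_product():
    model = LinearAssessmentModel("toy", 1.0, {"ngram:calm": 2.0})
    fv = FeatureVector(relfreq={1: {"calm": 0.5}})
    assert apply_model(fv, model) == pytest.approx(2.0)


def test_absent_features_leave_only_the_intercept():
    model = LinearAssessmentModel("toy", 0.7, {"ngram:calm": 2.0, "topic:t9": 1.0})
    assert apply_model(FeatureVector(), model) == pytest.approx(0.7)


def test_five_feature_model_hand_computed():
    model = LinearAssessmentModel("toy", 0.5, {
        "ngram:we": 1.0, "ngram:we went": 2.0, "bin:dug": 3.0,
        "topic:t1": 4.0, "ngram:absent": 5.0,
    })
    fv = FeatureVector(
        relfreq={1: {"we": 0.4}, 2: {"we went": 0.1}},
        binary={1: {"dug": 1}},
        topic={"t1": 0.25},
    )
    assert apply_model(fv, model) == pytest.approx(0.5 + 0.4 + 0.2 + 3.0 + 1.0)


def test_model_is_linear_in_features():
    model = LinearAssessmentModel("toy", 1.5, {"ngram:a": 2.0, "ngram:b": -1.0})
    fv = FeatureVector(relfreq={1: {"a": 0.3, "b": 0.2}})
    scaled = FeatureVector(relfreq={1: {"a": 0.6, "b": 0.4}})
    base = apply_model(fv, model) - model.intercept
    assert apply_model(scaled, model) - model.intercept == pytest.approx(2 * base)


def test_increasing_a_positive_weighted_term_increases_the_score():
    model = LinearAssessmentModel("toy", 0.0, {"ngram:worried": 2.0})
    low = FeatureVector(relfreq={1: {"worried": 0.01}})
    high = FeatureVector(relfreq={1: {"worried": 0.05}})
    assert apply_model(high, model) > apply_model(low, model)


def test_unknown_namespace_in_model_errors():
    model = LinearAssessmentModel("toy", 0.0, {"lexicon:we": 1.0})
    with pytest.raises(KeyError, match="namespace"):
        apply_model(FeatureVector(), model)


# -------------------------------------------------------------- meta features

@pytest.mark.parametrize("tokens, expected", [
    (["abc", "de"], (2, 2.5)),
    (["a"], (1, 1.0)),
])
def test_meta_features(tokens, expected):
    doc = TokenDocument("s", [tokens])
    assert meta_features(doc) == pytest.approx(expected)


def test_meta_features_empty_document_errors():
    with pytest.raises(ValueError):
        meta_features(TokenDocument("s", []))


def test_meta_from_counts_matches_token_path():
    doc = TokenDocument("s", [["we", "went", "we"]])
    assert meta_from_counts({"we": 2, "went": 1}) == meta_features(doc)


# ------------------------------------------------------------------- profiles

def _fixture_transcript(sid="s1"):
    return Transcript(sid, [
        Turn(RESPONDER, "we were worried and sad but we helped the people"),
        Turn(RESPONDER, "i'm tired of the dust and the smoke"),
    ])


def test_profile_has_exactly_nine_named_assessments(resources):
    lexicon, topics, models = resources
    doc = tokenize(_fixture_transcript())
    fv = featurize(doc, topic_model=topics)
    profile = assessment_profile(doc, fv, models, lexicon)
    values = profile.as_dict()
    assert list(values) == list(ASSESSMENT_NAMES)
    assert values["word_count"] == doc.word_count
    assert values["fp_plural"] == pytest.approx(2 / doc.word_count)


def test_profile_requires_every_lexicon_category(resources):
    lexicon, topics, models = resources
    doc = tokenize(_fixture_transcript())
    fv = featurize(doc, topic_model=topics)
    crippled = WeightedLexicon("partial", {
        k: v for k, v in lexicon.categories.items() if k != "articles"})
    with pytest.raises(ValueError, match="articles"):
        assessment_profile(doc, fv, models, crippled)


def test_profile_requires_every_trait_model(resources):
    lexicon, topics, models = resources
    doc = tokenize(_fixture_transcript())
    fv = featurize(doc, topic_model=topics)
    with pytest.raises(ValueError, match="anxiety"):
        assessment_profile(doc, fv, {k: v for k, v in models.items() if k != "anxiety"}, lexicon)


def test_identical_transcripts_get_identical_profiles(resources):
    profiles = assess_transcripts([_fixture_transcript("a"), _fixture_transcript("b")])
    assert np.allclose(profiles.loc["a"].to_numpy(), profiles.loc["b"].to_numpy())


def test_transformer_is_sklearn_compatible():
    t = AssessmentTransformer(include_interviewer=False)
    params = t.get_params()
    assert "include_interviewer" in params
    cloned = clone(t)
    frame = cloned.fit().transform([_fixture_transcript()])
    assert frame.shape == (1, 9)
    with pytest.raises(RuntimeError, match="not fitted"):
        AssessmentTransformer().transform([_fixture_transcript()])
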