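"""The nine language-based assessments for one subject.

Four trait scores from pre-trained linear models (anxiety, depression,
neuroticism, extraversion), three function-word category scores from a
weighted lexicon (first-person singular, first-person plural, articles),
and two meta variables (word count, average word length).

Lexicon scores are weighted relative frequencies of matching tokens —
normalized by the subject's total word count, the same denominator as every
1-gram feature.  Wildcard patterns (``friend*``) match by prefix; a token
matched by several patterns within one category counts once, with the
longest matching pattern's weight (exact beats wildcard on ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _ilres

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .featurize import FeatureVector, TokenDocument, featurize, tokenize
from .io import (
    LinearAssessmentModel,
    TopicModel,
    Transcript,
    WeightedLexicon,
    read_assessment_model,
    read_lexicon,
    read_topic_model,
)

#: Canonical assessment order — the row order of every downstream table.
MODEL_ASSESSMENTS = ("anxiety", "depression", "neuroticism", "extraversion")
LEXICON_ASSESSMENTS = ("fp_singular", "fp_plural", "articles")
META_ASSESSMENTS = ("word_count", "avg_word_length")
ASSESSMENT_NAMES = MODEL_ASSESSMENTS + LEXICON_ASSESSMENTS + META_ASSESSMENTS


@dataclass(frozen=True)
class AssessmentProfile:
    """The nine assessments for one subject."""

    subject_id: str
    anxiety: float
    depression: float
    neuroticism: float
    extraversion: float
    fp_singular: float
    fp_plural: float
    articles: float
    word_count: int
    avg_word_length: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ASSESSMENT_NAMES}


def _match_weight(token: str, exact: dict[str, float],
                  wildcards: list[tuple[str, float]]) -> float | None:
    """Longest-match-wins weight for one token, or None when unmatched."""
    best_len, best_weight = -1, None
    w = exact.get(token)
    if w is not None:
        best_len, best_weight = len(token) + 1, w  # +1: exact beats equal-stem wildcard
    for prefix, weight in wildcards:
        if len(prefix) > best_len and token.startswith(prefix):
            best_len, best_weight = len(prefix), weight
    return best_weight


def score_lexicon(relfreq_1grams: dict[str, float], lexicon: WeightedLexicon,
                  category: str) -> float:
    """Weighted relative frequency of category terms in the document."""
    patterns = lexicon.category(category)  # raises with available categories
    exact = {p: w for p, w in patterns.items() if not p.endswith("*")}
    wildcards = sorted(
        ((p[:-1], w) for p, w in patterns.items() if p.endswith("*")),
        key=lambda pw: -len(pw[0]),
    )
    score = 0.0
    for token, rf in relfreq_1grams.items():
        weight = _match_weight(token, exact, wildcards)
        if weight is not None:
            score += weight * rf
    return score


def apply_model(features: FeatureVector, model: LinearAssessmentModel) -> float:
    """intercept + Σ weight(f)·value(f); absent features contribute 0.

    The model is applied exactly as shipped — no refitting, no rescaling.
    """
    score = model.intercept
    for feat, weight in model.weights.items():
        score += weight * features.get(feat)  # raises on unknown namespace
    return score


def meta_features(doc: TokenDocument) -> tuple[int, float]:
    """(word_count, mean characters per token). Errors on an empty document."""
    n = doc.word_count
    if n == 0:
        raise ValueError(f"subject {doc.subject_id}: empty document has no meta features")
    total_chars = sum(len(tok) for tok in doc.tokens)
    return n, total_chars / n


def meta_from_counts(counts_1grams: dict[str, int]) -> tuple[int, float]:
    """Meta features computed from a bag-of-words (document-free path)."""
    n = sum(counts_1grams.values())
    if n == 0:
        raise ValueError("empty bag of words has no meta features")
    total_chars = sum(len(w) * c for w, c in counts_1grams.items())
    return n, total_chars / n


def assessment_profile(
    doc: TokenDocument,
    features: FeatureVector,
    models: dict[str, LinearAssessmentModel],
    lexicon: WeightedLexicon,
) -> AssessmentProfile:
    """Assemble all nine assessments; any missing resource is a hard error."""
    missing_models = [m for m in MODEL_ASSESSMENTS if m not in models]
    if missing_models:
        raise ValueError(f"missing assessment models: {missing_models}")
    missing_cats = [c for c in LEXICON_ASSESSMENTS if c not in lexicon.categories]
    if missing_cats:
        raise ValueError(
            f"lexicon {lexicon.name!r} lacks categories {missing_cats}; "
            f"available: {sorted(lexicon.categories)}"
        )
    relfreq1 = features.relfreq.get(1, {})
    wc, awl = meta_features(doc)
    return AssessmentProfile(
        subject_id=doc.subject_id,
        **{m: apply_model(features, models[m]) for m in MODEL_ASSESSMENTS},
        **{c: score_lexicon(relfreq1, lexicon, c) for c in LEXICON_ASSESSMENTS},
        word_count=wc,
        avg_word_length=awl,
    )


def profiles_frame(profiles: list[AssessmentProfile]) -> pd.DataFrame:
    """Subjects × nine assessments, indexed by subject id."""
    df = pd.DataFrame(
        [{"subject_id": p.subject_id, **p.as_dict()} for p in profiles]
    ).set_index("subject_id")
    return df[list(ASSESSMENT_NAMES)]


def write_profiles(profiles: list[AssessmentProfile], path) -> None:
    df = profiles_frame(profiles).reset_index()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(repr(v) if isinstance(v, float) else str(v) for v in row) + "\n")


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"subject_id": str}).set_index("subject_id")


# ---------------------------------------------------------------------------
# Bundled toy resources
# ---------------------------------------------------------------------------

def load_bundled_resources() -> tuple[WeightedLexicon, TopicModel, dict[str, LinearAssessmentModel]]:
    """Small open stand-in resources shipped with the package.

    A pronoun/article lexicon, a 5-topic toy loading table and four toy trait
    models.  Real resources (e.g. a commercially licensed dictionary or published
    trait-model weights) are user-supplied file paths, never bundled.
    """
    base = _ilres.files("langtraj") / "resources"
    with _ilres.as_file(base / "toy_lexicon.csv") as p:
        lexicon = read_lexicon(p, name="toy_lexicon")
    with _ilres.as_file(base / "toy_topics.csv") as p:
        topics = read_topic_model(p)
    models = {}
    for name in MODEL_ASSESSMENTS:
        with _ilres.as_file(base / f"toy_model_{name}.json") as p:
            models[name] = read_assessment_model(p)
    return lexicon, topics, models


# ---------------------------------------------------------------------------
# sklearn-style surface
# ---------------------------------------------------------------------------

class AssessmentTransformer(TransformerMixin, BaseEstimator):
    """Transcripts → subjects × 9 assessment DataFrame, sklearn style.

    ``fit`` resolves and validates the scoring resources; ``transform`` maps
    a list of :class:`~langtraj.io.Transcript` to a
    :func:`profiles_frame`-shaped DataFrame.  Stateless across documents, so
    it composes with sklearn pipelines and cross-validation.
    """

    def __init__(self, lexicon: WeightedLexicon | None = None,
                 topic_model: TopicModel | None = None,
                 models: dict[str, LinearAssessmentModel] | None = None,
                 include_interviewer: bool = False):
        self.lexicon = lexicon
        self.topic_model = topic_model
        self.models = models
        self.include_interviewer = include_interviewer

    def fit(self, X=None, y=None):
        if self.lexicon is None or self.models is None:
            lex, topics, models = load_bundled_resources()
            self.lexicon_ = self.lexicon or lex
            self.models_ = self.models or models
            self.topic_model_ = self.topic_model or topics
        else:
            self.lexicon_, self.models_, self.topic_model_ = (
                self.lexicon, self.models, self.topic_model)
        missing = [m for m in MODEL_ASSESSMENTS if m not in self.models_]
        if missing:
            raise ValueError(f"missing assessment models: {missing}")
        return self

    def transform(self, X: list[Transcript]) -> pd.DataFrame:
        if not hasattr(self, "lexicon_"):
            raise RuntimeError("AssessmentTransformer is not fitted; call fit() first")
        profiles = []
        for transcript in X:
            doc = tokenize(transcript, include_interviewer=self.include_interviewer)
            fv = featurize(doc, topic_model=self.topic_model_)
            profiles.append(assessment_profile(doc, fv, self.models_, self.lexicon_))
        return profiles_frame(profiles)


def assess_transcripts(transcripts: list[Transcript], **kwargs) -> pd.DataFrame:
    """Thin functional wrapper over :class:`AssessmentTransformer`."""
    return AssessmentTransformer(**kwargs).fit().transform(transcripts)
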