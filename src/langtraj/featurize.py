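"""Convert transcripts into the three linguistic feature families.

1. relative frequencies of 1–3-grams (per-order proper distributions),
2. binary presence indicators for the same n-grams,
3. topic prevalence scores in [0, 1] from a word-to-topic loading table.

The tokenizer is deliberately simple and fully specified: lowercase,
whitespace split (em/en dashes count as whitespace), strip leading and
trailing punctuation, keep word-internal apostrophes, hyphens and slashes —
so ``can't`` and ``9/11`` survive as single tokens.  n-gram windows never
cross a speaker-turn boundary: a turn is the natural utterance unit.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .io import RESPONDER, TopicModel, Transcript

logger = logging.getLogger(__name__)

_DASHES = "–—"  # en dash, em dash: separators, unlike ASCII hyphen


class EmptyDocumentError(ValueError):
    """A transcript yielded zero responder tokens."""


@dataclass
class TokenDocument:
    """A subject's responder speech as lowercase tokens, turn-segmented."""

    subject_id: str
    turn_tokens: list[list[str]]

    @property
    def tokens(self) -> list[str]:
        return [tok for turn in self.turn_tokens for tok in turn]

    @property
    def word_count(self) -> int:
        return sum(len(turn) for turn in self.turn_tokens)


@dataclass
class FeatureVector:
    """Sparse named features for one document.

    ``relfreq``/``binary`` map n-gram order → {space-joined n-gram: value};
    ``topic`` maps topic id → prevalence score in [0, 1].
    """

    relfreq: dict[int, dict[str, float]] = field(default_factory=dict)
    binary: dict[int, dict[str, int]] = field(default_factory=dict)
    topic: dict[str, float] = field(default_factory=dict)

    def get(self, name: str) -> float:
        """Resolve a namespaced feature name (``ngram:``, ``bin:``, ``topic:``).

        Absent features resolve to 0, matching the application contract of
        pre-trained linear models (a phrase the subject never said simply
        contributes nothing).
        """
        ns, _, rest = name.partition(":")
        if ns == "ngram":
            order = rest.count(" ") + 1
            return self.relfreq.get(order, {}).get(rest, 0.0)
        if ns == "bin":
            order = rest.count(" ") + 1
            return float(self.binary.get(order, {}).get(rest, 0))
        if ns == "topic":
            return self.topic.get(rest, 0.0)
        raise KeyError(f"unknown feature namespace in {name!r} (expected ngram:/bin:/topic:)")


def _clean_token(raw: str) -> str:
    # strip leading/trailing non-alphanumerics; internal ' - / survive
    start, end = 0, len(raw)
    while start < end and not raw[start].isalnum():
        start += 1
    while end > start and not raw[end - 1].isalnum():
        end -= 1
    return raw[start:end]


def tokenize_text(text: str) -> list[str]:
    """Tokenize one stretch of speech per the rules above."""
    for dash in _DASHES:
        text = text.replace(dash, " ")
    tokens = []
    for raw in text.lower().split():
        tok = _clean_token(raw)
        if tok:
            tokens.append(tok)
    return tokens


def tokenize(transcript: Transcript, include_interviewer: bool = False) -> TokenDocument:
    """Turn a transcript into a :class:`TokenDocument`.

    Responder turns only by default; ``include_interviewer=True`` exists for
    sensitivity analyses.  Raises :class:`EmptyDocumentError` when no tokens
    remain.
    """
    turn_tokens = []
    for turn in transcript.turns:
        if not include_interviewer and turn.speaker != RESPONDER:
            continue
        toks = tokenize_text(turn.text)
        if toks:
            turn_tokens.append(toks)
    doc = TokenDocument(transcript.subject_id, turn_tokens)
    if doc.word_count == 0:
        raise EmptyDocumentError(
            f"subject {transcript.subject_id}: no responder tokens after tokenization"
        )
    return doc


def extract_ngrams(doc: TokenDocument, max_order: int = 3) -> dict[int, Counter]:
    """Count contiguous 1..max_order-grams; windows never span turns.

    n-grams of order > 1 are keyed by their tokens joined with single spaces.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    counts: dict[int, Counter] = {n: Counter() for n in range(1, max_order + 1)}
    for turn in doc.turn_tokens:
        for n in range(1, max_order + 1):
            for i in range(len(turn) - n + 1):
                counts[n][" ".join(turn[i:i + n])] += 1
    return counts


def relative_frequencies(counts: dict[int, Counter]) -> dict[int, dict[str, float]]:
    """Normalize counts per order; an order with zero windows maps to {}."""
    relfreq: dict[int, dict[str, float]] = {}
    for n, ctr in counts.items():
        total = sum(ctr.values())
        relfreq[n] = {g: c / total for g, c in ctr.items()} if total else {}
    return relfreq


def binary_indicators(counts: dict[int, Counter]) -> dict[int, dict[str, int]]:
    """1 for every observed n-gram; unobserved features are implicitly 0."""
    return {n: {g: 1 for g in ctr} for n, ctr in counts.items()}


def topic_scores(relfreq_1grams: dict[str, float], model: TopicModel) -> dict[str, float]:
    """Topic prevalence: score(t) = Σ_w p(t|w)·relfreq(w) over shared words.

    Scores lie in [0, 1]; if the loading table is column-normalized and the
    document fully in-vocabulary they sum to 1.  A fully out-of-vocabulary
    document scores 0 everywhere (with a logged warning).
    """
    scores = {}
    any_in_vocab = False
    for tid, words in model.topics.items():
        s = 0.0
        for word, weight in words.items():
            rf = relfreq_1grams.get(word)
            if rf is not None:
                s += weight * rf
                any_in_vocab = True
        scores[tid] = s
    if relfreq_1grams and not any_in_vocab:
        logger.warning("document shares no vocabulary with the topic model; all topic scores are 0")
    return scores


def featurize(doc: TokenDocument, topic_model: TopicModel | None = None,
              max_order: int = 3) -> FeatureVector:
    """Full feature extraction for one document."""
    counts = extract_ngrams(doc, max_order=max_order)
    relfreq = relative_frequencies(counts)
    fv = FeatureVector(
        relfreq=relfreq,
        binary=binary_indicators(counts),
        topic=topic_scores(relfreq.get(1, {}), topic_model) if topic_model else {},
    )
    return fv


def features_from_counts(subject_id: str, counts_1grams: dict[str, int],
                         topic_model: TopicModel | None = None) -> FeatureVector:
    """Build a 1-gram-only FeatureVector directly from token counts.

    Used by the synthetic generator's document-free path; the numbers are
    identical to tokenizing a text whose bag of words equals ``counts_1grams``
    (for 1-gram features, which is all the shipped assessments consume).
    """
    ctr = Counter({w: c for w, c in counts_1grams.items() if c > 0})
    counts = {1: ctr}
    relfreq = relative_frequencies(counts)
    return FeatureVector(
        relfreq=relfreq,
        binary=binary_indicators(counts),
        topic=topic_scores(relfreq[1], topic_model) if topic_model else {},
    )


def write_feature_dump(subject_features: dict[str, FeatureVector], path) -> None:
    """Sparse audit TSV: subject, namespace, feature, value."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["subject", "namespace", "feature", "value"])
        for sid in sorted(subject_features):
            fv = subject_features[sid]
            for order in sorted(fv.relfreq):
                for g in sorted(fv.relfreq[order]):
                    w.writerow([sid, "ngram", g, repr(fv.relfreq[order][g])])
            for order in sorted(fv.binary):
                for g in sorted(fv.binary[order]):
                    w.writerow([sid, "bin", g, fv.binary[order][g]])
            for tid in sorted(fv.topic):
                w.writerow([sid, "topic", tid, repr(fv.topic[tid])])
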