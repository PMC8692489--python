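"""Reading and writing of every external artifact.

Transcripts (JSONL turn files or per-subject plain text), weighted lexica
(CSV), topic-word weight tables (CSV), linear assessment models (JSON),
longitudinal cohort tables (CSV) and association-result tables (TSV).

All validation failures are hard errors naming the offending file/row —
clinical-data hygiene: nothing is ever silently dropped or coerced.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

RESPONDER = "responder"
INTERVIEWER = "interviewer"

#: Speaker labels accepted out of the box.  Users with other conventions
#: pass an explicit ``speaker_map`` to :func:`read_transcripts`.
DEFAULT_SPEAKER_MAP = {
    "responder": RESPONDER,
    "r": RESPONDER,
    "subject": RESPONDER,
    "participant": RESPONDER,
    "interviewer": INTERVIEWER,
    "i": INTERVIEWER,
}

#: PCL for DSM-IV: 17 items scored 1-5, so totals live in [17, 85].
PCL_MIN = 17.0
PCL_MAX = 85.0

#: One calendar-time convention throughout: elapsed days / 365.25 = years.
DAYS_PER_YEAR = 365.25


class ValidationError(ValueError):
    """An input artifact violated an invariant; message names the culprit."""


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Turn:
    speaker: str  # RESPONDER or INTERVIEWER
    text: str
    start_time: float | None = None  # seconds from interview start, if known


@dataclass
class Transcript:
    """One responder's interview as an ordered sequence of speaker turns."""

    subject_id: str
    turns: list[Turn]

    def responder_turns(self) -> list[Turn]:
        return [t for t in self.turns if t.speaker == RESPONDER]

    def has_responder_speech(self) -> bool:
        return any(t.text.strip() for t in self.responder_turns())


def _map_speaker(raw: str, speaker_map: dict[str, str], context: str) -> str:
    key = str(raw).strip().lower()
    if key not in speaker_map:
        raise ValidationError(
            f"{context}: unknown speaker label {raw!r}; "
            f"accepted labels: {sorted(speaker_map)}"
        )
    return speaker_map[key]


def _read_jsonl_transcripts(path: Path, speaker_map: dict[str, str]) -> dict[str, Transcript]:
    out: dict[str, Transcript] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"{path}:{lineno}: unparseable JSON line ({exc})") from exc
            try:
                subject = str(rec["subject"])
                speaker = _map_speaker(rec["speaker"], speaker_map, f"{path}:{lineno}")
                text = str(rec["text"])
            except KeyError as exc:
                raise ValidationError(f"{path}:{lineno}: missing required key {exc}") from exc
            t = rec.get("t")
            start = float(t) if t is not None else None
            if start is not None and start < 0:
                raise ValidationError(f"{path}:{lineno}: negative start time {start}")
            out.setdefault(subject, Transcript(subject, [])).turns.append(
                Turn(speaker, text, start)
            )
    return out


def read_transcripts(
    path: str | Path,
    speaker_map: dict[str, str] | None = None,
) -> tuple[list[Transcript], dict[str, str]]:
    """Load transcripts from a JSONL file or a directory of per-subject files.

    A directory may mix ``<subject>.jsonl`` (turn records) and
    ``<subject>.txt`` (the whole file is responder speech).  Subjects with no
    non-empty responder turn are not returned but are *reported* in the skip
    map; the same subject appearing in two files is a hard error.

    Returns
    -------
    (transcripts, skipped)
        ``transcripts`` sorted by subject id; ``skipped`` maps subject id to
        the reason it was excluded.
    """
    path = Path(path)
    smap = {k.lower(): v for k, v in (speaker_map or DEFAULT_SPEAKER_MAP).items()}
    collected: dict[str, Transcript] = {}

    def merge(new: dict[str, Transcript], source: Path) -> None:
        for sid, tr in new.items():
            if sid in collected:
                raise ValidationError(
                    f"duplicate subject id {sid!r} encountered in {source}"
                )
            collected[sid] = tr

    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix in {".jsonl", ".txt"})
        if not files:
            raise ValidationError(f"no .jsonl or .txt transcript files under {path}")
        for f in files:
            if f.suffix == ".jsonl":
                merge(_read_jsonl_transcripts(f, smap), f)
            else:
                text = f.read_text(encoding="utf-8")
                merge({f.stem: Transcript(f.stem, [Turn(RESPONDER, text)])}, f)
    elif path.suffix == ".jsonl":
        merge(_read_jsonl_transcripts(path, smap), path)
    elif path.suffix == ".txt":
        merge({path.stem: Transcript(path.stem, [Turn(RESPONDER, path.read_text(encoding='utf-8'))])}, path)
    else:
        raise ValidationError(f"unsupported transcript path {path} (expect .jsonl, .txt or directory)")

    transcripts, skipped = [], {}
    for sid in sorted(collected):
        tr = collected[sid]
        if tr.has_responder_speech():
            transcripts.append(tr)
        else:
            skipped[sid] = "no non-empty responder turn"
    return transcripts, skipped


def write_transcripts_jsonl(transcripts: list[Transcript], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tr in transcripts:
            for turn in tr.turns:
                rec = {"subject": tr.subject_id, "speaker": turn.speaker, "text": turn.text}
                if turn.start_time is not None:
                    rec["t"] = turn.start_time
                fh.write(json.dumps(rec, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Weighted lexica
# ---------------------------------------------------------------------------

@dataclass
class WeightedLexicon:
    """Category → {pattern: weight}.  Patterns are lowercase terms, optionally
    ending in a single ``*`` wildcard meaning "any token with this prefix"."""

    name: str
    categories: dict[str, dict[str, float]] = field(default_factory=dict)

    def category(self, name: str) -> dict[str, float]:
        if name not in self.categories:
            raise KeyError(
                f"lexicon {self.name!r} has no category {name!r}; "
                f"available: {sorted(self.categories)}"
            )
        return self.categories[name]


def _validate_pattern(pattern: str, context: str) -> str:
    pattern = pattern.strip().lower()
    if not pattern:
        raise ValidationError(f"{context}: empty term")
    star = pattern.find("*")
    if star != -1 and star != len(pattern) - 1:
        raise ValidationError(
            f"{context}: wildcard '*' only allowed as the final character, got {pattern!r}"
        )
    if pattern == "*":
        raise ValidationError(f"{context}: bare '*' matches everything and is rejected")
    return pattern


def read_lexicon(path: str | Path, name: str | None = None) -> WeightedLexicon:
    """Read a ``category,term,weight`` CSV (weight optional, default 1)."""
    path = Path(path)
    lex = WeightedLexicon(name or path.stem)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"category", "term"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(f"{path}: expected header with columns category,term[,weight]")
        for i, row in enumerate(reader, start=2):
            cat = (row["category"] or "").strip()
            if not cat:
                raise ValidationError(f"{path}:{i}: empty category")
            pattern = _validate_pattern(row["term"] or "", f"{path}:{i}")
            raw_w = (row.get("weight") or "").strip()
            weight = float(raw_w) if raw_w else 1.0
            if not math.isfinite(weight):
                raise ValidationError(f"{path}:{i}: non-finite weight {raw_w!r}")
            bucket = lex.categories.setdefault(cat, {})
            if pattern in bucket:
                raise ValidationError(
                    f"{path}:{i}: duplicate pattern {pattern!r} in category {cat!r}"
                )
            bucket[pattern] = weight
    if not lex.categories:
        raise ValidationError(f"{path}: lexicon is empty")
    return lex


def write_lexicon(lexicon: WeightedLexicon, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["category", "term", "weight"])
        for cat in sorted(lexicon.categories):
            for pattern in sorted(lexicon.categories[cat]):
                w.writerow([cat, pattern, repr(lexicon.categories[cat][pattern])])


# ---------------------------------------------------------------------------
# Topic models
# ---------------------------------------------------------------------------

@dataclass
class TopicModel:
    """Word-to-topic loadings interpreted as p(topic | word).

    For each word the loadings across topics must sum to at most 1 (equality
    when the source table is column-normalized).
    """

    topics: dict[str, dict[str, float]]

    @property
    def vocabulary(self) -> set[str]:
        vocab: set[str] = set()
        for words in self.topics.values():
            vocab.update(words)
        return vocab

    def validate(self) -> None:
        per_word: dict[str, float] = {}
        for tid, words in self.topics.items():
            for word, weight in words.items():
                if weight < 0 or not math.isfinite(weight):
                    raise ValidationError(
                        f"topic {tid!r}, word {word!r}: weight {weight} not a finite non-negative"
                    )
                per_word[word] = per_word.get(word, 0.0) + weight
        for word, total in per_word.items():
            if total > 1 + 1e-9:
                raise ValidationError(
                    f"word {word!r}: sum of p(topic|word) over topics is {total:.6g} > 1"
                )


def read_topic_model(path: str | Path) -> TopicModel:
    """Read a ``topic_id,term,weight`` CSV and validate the loadings."""
    path = Path(path)
    topics: dict[str, dict[str, float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"topic_id", "term", "weight"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(f"{path}: expected header topic_id,term,weight")
        for i, row in enumerate(reader, start=2):
            tid = (row["topic_id"] or "").strip()
            term = (row["term"] or "").strip().lower()
            if not tid or not term:
                raise ValidationError(f"{path}:{i}: empty topic_id or term")
            try:
                weight = float(row["weight"])
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"{path}:{i}: bad weight {row['weight']!r}") from exc
            topics.setdefault(tid, {})[term] = weight
    model = TopicModel(topics)
    model.validate()
    return model


def write_topic_model(model: TopicModel, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["topic_id", "term", "weight"])
        for tid in sorted(model.topics):
            for term in sorted(model.topics[tid]):
                w.writerow([tid, term, repr(model.topics[tid][term])])


# ---------------------------------------------------------------------------
# Linear assessment models
# ---------------------------------------------------------------------------

#: Feature namespaces a model weight may address.
NAMESPACES = ("ngram", "bin", "topic")


@dataclass
class LinearAssessmentModel:
    """A pre-trained linear scorer: intercept + Σ weight(f)·value(f).

    Feature names are namespaced ``ngram:<phrase>``, ``bin:<phrase>`` or
    ``topic:<topic_id>`` and resolve against a
    :class:`~langtraj.featurize.FeatureVector`.
    """

    name: str
    intercept: float
    weights: dict[str, float]

    def validate(self) -> None:
        if not math.isfinite(self.intercept):
            raise ValidationError(f"model {self.name!r}: non-finite intercept")
        for feat, w in self.weights.items():
            ns, _, rest = feat.partition(":")
            if ns not in NAMESPACES or not rest:
                raise ValidationError(
                    f"model {self.name!r}: feature {feat!r} must be namespaced "
                    f"as one of {NAMESPACES} (e.g. 'ngram:we')"
                )
            if not math.isfinite(w):
                raise ValidationError(f"model {self.name!r}: non-finite weight for {feat!r}")


def read_assessment_model(path: str | Path) -> LinearAssessmentModel:
    """Read a model JSON: ``{"name": ..., "intercept": ..., "weights": {...}}``."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}: unparseable JSON ({exc})") from exc
    try:
        model = LinearAssessmentModel(
            name=str(raw["name"]),
            intercept=float(raw["intercept"]),
            weights={str(k): float(v) for k, v in raw["weights"].items()},
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: bad model schema ({exc})") from exc
    model.validate()
    return model


def write_assessment_model(model: LinearAssessmentModel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {"name": model.name, "intercept": model.intercept, "weights": model.weights},
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "subject_id", "assessment_date", "pcl", "interview_date",
    "age_at_interview", "gender", "occupation", "marital_status", "event_date",
]

GENDERS = {"male", "female"}
OCCUPATIONS = {"police", "non-police"}
MARITAL = {"married", "not married"}


@dataclass
class CohortTable:
    """Long-format longitudinal cohort: one row per PCL assessment.

    Wraps a validated DataFrame with parsed dates.  ``marital_status`` may be
    entirely absent (the marital-adjusted model then cannot run).
    """

    df: pd.DataFrame

    @property
    def has_marital_status(self) -> bool:
        return "marital_status" in self.df.columns and self.df["marital_status"].notna().all()

    def subjects(self) -> list[str]:
        return sorted(self.df["subject_id"].unique())

    def subject_rows(self, subject_id: str) -> pd.DataFrame:
        return self.df[self.df["subject_id"] == subject_id]

    def demographics(self) -> pd.DataFrame:
        """One row per subject: the time-invariant covariates."""
        cols = ["subject_id", "interview_date", "age_at_interview",
                "gender", "occupation", "event_date"]
        if "marital_status" in self.df.columns:
            cols.append("marital_status")
        demo = self.df[cols].drop_duplicates("subject_id").set_index("subject_id")
        demo["years_event_to_interview"] = [
            (iv - ev).days / DAYS_PER_YEAR
            for iv, ev in zip(demo["interview_date"], demo["event_date"])
        ]
        return demo.sort_index()


def _parse_iso_date(value: str, context: str) -> date:
    try:
        return date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValidationError(f"{context}: date {value!r} is not ISO-8601 (YYYY-MM-DD)") from exc


def read_cohort(path: str | Path) -> CohortTable:
    """Read and validate the longitudinal cohort CSV.

    Enforces: PCL in [17, 85]; ISO dates; one interview date per subject;
    no duplicate (subject, assessment_date); event_date ≤ interview_date;
    categorical codings for gender/occupation/marital status.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(COHORT_COLUMNS) - {"marital_status"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return validate_cohort(df, source=str(path))


def validate_cohort(df: pd.DataFrame, source: str = "<memory>") -> CohortTable:
    df = df.copy()
    for col in ("assessment_date", "interview_date", "event_date"):
        df[col] = [
            v if isinstance(v, date) else _parse_iso_date(v, f"{source} row {i}")
            for i, v in zip(df.index, df[col])
        ]
    for i, row in df.iterrows():
        ctx = f"{source} row {i} (subject {row['subject_id']})"
        pcl = float(row["pcl"])
        if not (PCL_MIN <= pcl <= PCL_MAX):
            raise ValidationError(f"{ctx}: PCL {pcl} outside [{PCL_MIN:.0f}, {PCL_MAX:.0f}]")
        if row["gender"] not in GENDERS:
            raise ValidationError(f"{ctx}: gender {row['gender']!r} not in {sorted(GENDERS)}")
        if row["occupation"] not in OCCUPATIONS:
            raise ValidationError(f"{ctx}: occupation {row['occupation']!r} not in {sorted(OCCUPATIONS)}")
        if "marital_status" in df.columns and pd.notna(row.get("marital_status")):
            if row["marital_status"] not in MARITAL:
                raise ValidationError(f"{ctx}: marital_status {row['marital_status']!r} not in {sorted(MARITAL)}")
        if row["event_date"] > row["interview_date"]:
            raise ValidationError(f"{ctx}: event_date after interview_date")
        if not (0 < float(row["age_at_interview"]) < 120):
            raise ValidationError(f"{ctx}: implausible age {row['age_at_interview']}")
    dup = df.duplicated(subset=["subject_id", "assessment_date"])
    if dup.any():
        bad = df.loc[dup.idxmax()]
        raise ValidationError(
            f"{source}: duplicate (subject, assessment_date) = "
            f"({bad['subject_id']}, {bad['assessment_date']})"
        )
    n_iv = df.groupby("subject_id")["interview_date"].nunique()
    if (n_iv > 1).any():
        bad_subject = n_iv[n_iv > 1].index[0]
        raise ValidationError(f"{source}: subject {bad_subject} has multiple interview dates")
    return CohortTable(df.reset_index(drop=True))


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    df = cohort.df.copy()
    for col in ("assessment_date", "interview_date", "event_date"):
        df[col] = [d.isoformat() for d in df[col]]
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["feature", "beta", "ci_low", "ci_high", "p", "p_bh", "significant", "model", "n"]


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write an association table as TSV.

    Row order follows the input; floats are serialized with ``repr`` so a
    rerun on identical inputs is byte-identical.
    """
    cols = [c for c in RESULT_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    out = table[cols + extra]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(out.columns)
        for row in out.itertuples(index=False):
            w.writerow([repr(v) if isinstance(v, float) else v for v in row])


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "significant" in df.columns:
        df["significant"] = df["significant"].astype(bool)
    return df
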