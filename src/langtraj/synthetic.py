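"""Synthetic interview cohorts with known ground truth.

The study data this package analyzes — interview transcripts linked to
longitudinal PCL records — are private clinical records, so every test runs
on cohorts generated here.  The generator's defaults emulate the published
study conditions: ~10,000-word interviews, baseline PCL ≈ N(33.7, 16.2²)
within the 17–85 instrument range, one pre-interview assessment plus a
baseline and four follow-ups with the last at ≈5.5 years, interviews ≈10.3
years after the index event, 90% male, 48% police.

Mechanism
---------
Each subject carries a latent baseline-severity factor ``b`` and a latent
slope factor ``s`` (standard normal, optionally correlated).  Each
assessment with planted standardized effects (e_b, e_s) gets a feature
latent mixing ``b``, ``s`` and fresh noise; token streams are multinomial
draws from a base unigram distribution whose signal-word pools (anxiety
words, "we" words, long words, …) are linearly modulated by the feature
latents.  PCL observations are ``clip(round(μ + σ·b + slope_i·t + ε), 17,
85)``.

A planted effect is defined as the standardized coefficient the analysis
pipeline recovers in expectation.  Two construction details make that hold:

* modulated pool mass is compensated inside a designated filler-word pool,
  conserving both total probability and total character count, so that
  modulating one assessment's pool perturbs neither the other assessments'
  relative frequencies nor the average word length (the word-length pool is
  compensated at the corpus-mean length, leaving its length signal intact);
* the latent mixing coefficients are inflated by analytically/Monte-Carlo
  computed attenuation factors for multinomial sampling noise of the scores,
  PCL measurement noise + bound clipping of the baseline, and per-subject
  slope-estimation error — so realized scores and fitted slopes correlate
  with the latent factors at the configured strengths.

Every random stream derives from ``(seed, subject index)``, so cohorts are
bytewise reproducible (including under parallel generation).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from . import assess
from .assess import (
    ASSESSMENT_NAMES,
    AssessmentProfile,
    load_bundled_resources,
    profiles_frame,
)
from .featurize import features_from_counts
from .io import (
    DAYS_PER_YEAR,
    INTERVIEWER,
    PCL_MAX,
    PCL_MIN,
    RESPONDER,
    CohortTable,
    Transcript,
    Turn,
    validate_cohort,
)

EVENT_DATE = date(2001, 9, 11)

#: Words carrying the average-word-length signal.
LONG_WORDS = {
    "responsibilities": 0.003, "communication": 0.003, "immediately": 0.004,
    "experiences": 0.004, "neighborhood": 0.003, "understanding": 0.003,
    "information": 0.004, "organizations": 0.003,
}

#: Base unigram weights (normalized at build time).  Signal pools — trait
#: words, pronouns, articles, long words — sit at plausible conversational
#: rates so every assessment has natural between-subject variation.
BASE_WEIGHTS = {
    # anxiety model vocabulary
    "worried": 0.005, "nervous": 0.004, "afraid": 0.004, "panic": 0.003, "scared": 0.004,
    # depression model vocabulary
    "sad": 0.005, "hopeless": 0.003, "tired": 0.005, "empty": 0.003, "alone": 0.004,
    # neuroticism model vocabulary
    "upset": 0.004, "moody": 0.002, "stress": 0.005, "uneasy": 0.002, "irritable": 0.002,
    # extraversion model vocabulary
    "outgoing": 0.002, "party": 0.003, "social": 0.004, "lively": 0.002, "talkative": 0.002,
    # first-person singular
    "i": 0.030, "me": 0.007, "my": 0.010, "mine": 0.001, "myself": 0.001, "i'm": 0.003,
    # first-person plural
    "we": 0.012, "us": 0.004, "our": 0.005, "ourselves": 0.0005, "we're": 0.0005,
    # articles
    "the": 0.045, "a": 0.020, "an": 0.005,
    # topic-model vocabulary
    "rubble": 0.003, "debris": 0.003, "smoke": 0.004, "site": 0.005, "dust": 0.004,
    "doctor": 0.003, "breathing": 0.003, "cough": 0.002, "clinic": 0.002,
    "family": 0.005, "wife": 0.004, "kids": 0.004, "home": 0.006, "brother": 0.003,
    "shift": 0.003, "duty": 0.003, "truck": 0.003, "gear": 0.002, "radio": 0.002,
    # social wildcard targets
    "friends": 0.004, "helped": 0.004, "talked": 0.003, "helping": 0.002,
    # narrative filler (the compensation reservoir)
    "and": 0.030, "to": 0.025, "of": 0.020, "it": 0.025, "was": 0.030, "that": 0.025,
    "in": 0.020, "on": 0.012, "at": 0.010, "for": 0.012, "with": 0.012, "they": 0.015,
    "he": 0.008, "she": 0.005, "you": 0.015, "this": 0.012, "but": 0.015, "not": 0.010,
    "all": 0.010, "just": 0.018, "like": 0.018, "got": 0.012, "get": 0.010,
    "back": 0.012, "out": 0.015, "up": 0.012, "so": 0.018, "when": 0.012,
    "what": 0.012, "about": 0.012, "there": 0.018, "then": 0.015, "down": 0.010,
    "went": 0.010, "day": 0.010, "time": 0.012, "people": 0.012, "work": 0.014,
    "said": 0.010, "were": 0.012, "had": 0.018, "them": 0.010, "from": 0.010,
    "know": 0.020, "going": 0.012, "did": 0.010, "one": 0.010, "because": 0.008,
    "after": 0.008, "over": 0.008,
    **LONG_WORDS,
}

INTERVIEWER_PROMPTS = [
    "And what happened next?",
    "Can you tell me more about that?",
    "How did that affect you?",
    "What do you remember most?",
]


def default_planted_effects() -> dict[str, tuple[float, float]]:
    """Planted standardized effects (on baseline severity, on slope),
    set to the headline effect magnitudes this design is meant to detect."""
    return {
        "depression": (0.32, 0.0),
        "fp_singular": (0.31, 0.0),
        "anxiety": (0.0, 0.30),
        "fp_plural": (0.0, -0.36),
        "avg_word_length": (0.0, -0.35),
    }


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_subjects: int = 75
    seed: int = 0
    words_mean: float = 10_000.0        # interview length, tokens
    words_dispersion: float = 0.25      # lognormal sigma, mean-corrected
    baseline_pcl_mean: float = 33.7
    baseline_pcl_sd: float = 16.2
    pcl_noise_sd: float = 4.0           # visit-level measurement noise
    slope_mean: float = 0.0             # PCL/yr
    slope_sd: float = 3.0               # PCL/yr between subjects
    baseline_slope_corr: float = 0.0    # corr(b, s)
    n_post_visits: int = 4              # follow-ups beyond the baseline visit
    followup_span_mean: float = 5.5     # years to last follow-up
    followup_span_sd: float = 1.3
    followup_span_min: float = 2.6      # keeps every subject longitudinal-eligible
    male_fraction: float = 0.9
    police_fraction: float = 0.48
    married_fraction: float = 0.6
    age_mean: float = 55.0
    age_sd: float = 8.0
    years_event_to_interview_mean: float = 10.31
    years_event_to_interview_sd: float = 1.43
    signal_gain: float = 0.4            # relative pool modulation per latent s.d.
    planted_effects: dict[str, tuple[float, float]] = field(
        default_factory=default_planted_effects)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("baseline_pcl_sd", "pcl_noise_sd", "slope_sd",
                     "words_mean", "age_sd", "years_event_to_interview_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("male_fraction", "police_fraction", "married_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_post_visits < 1:
            raise ValueError("n_post_visits must be >= 1")
        if not -1 < self.baseline_slope_corr < 1:
            raise ValueError("baseline_slope_corr must be in (-1, 1)")
        for feat in self.planted_effects:
            if feat not in ASSESSMENT_NAMES:
                raise ValueError(f"planted effect on unknown assessment {feat!r}")
        # the calibrated latent coefficients must leave non-negative residual variance
        _latent_coefficients(_cfg_key(self))


@dataclass
class GroundTruth:
    """Everything needed to compute oracle effects for a generated cohort."""

    subject_ids: list[str]
    baseline_factor: np.ndarray       # b
    slope_factor: np.ndarray          # s
    true_slopes: np.ndarray           # PCL/yr
    feature_latents: dict[str, np.ndarray]
    planted_effects: dict[str, tuple[float, float]]
    config: GeneratorConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subject_ids": self.subject_ids,
            "baseline_factor": self.baseline_factor.tolist(),
            "slope_factor": self.slope_factor.tolist(),
            "true_slopes": self.true_slopes.tolist(),
            "feature_latents": {k: v.tolist() for k, v in self.feature_latents.items()},
            "planted_effects": {k: list(v) for k, v in self.planted_effects.items()},
            "config": asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        cfg = raw["config"]
        cfg["planted_effects"] = {k: tuple(v) for k, v in cfg["planted_effects"].items()}
        return cls(
            subject_ids=raw["subject_ids"],
            baseline_factor=np.array(raw["baseline_factor"]),
            slope_factor=np.array(raw["slope_factor"]),
            true_slopes=np.array(raw["true_slopes"]),
            feature_latents={k: np.array(v) for k, v in raw["feature_latents"].items()},
            planted_effects={k: tuple(v) for k, v in raw["planted_effects"].items()},
            config=GeneratorConfig(**cfg),
        )


@dataclass
class SyntheticCohort:
    transcripts: list[Transcript] | None
    cohort: CohortTable
    truth: GroundTruth
    counts: dict[str, dict[str, int]]   # subject → token counts (bag of words)


# ---------------------------------------------------------------------------
# Vocabulary, signal pools and the compensated mixture
# ---------------------------------------------------------------------------

def _build_vocabulary():
    words = np.array(sorted(BASE_WEIGHTS), dtype=object)
    probs = np.array([BASE_WEIGHTS[w] for w in words], dtype=float)
    probs = probs / probs.sum()
    index = {w: i for i, w in enumerate(words)}

    lexicon, _, models = load_bundled_resources()
    pools: dict[str, np.ndarray] = {}
    for trait, model in models.items():
        toks = [f.split(":", 1)[1] for f in model.weights if f.startswith("ngram:")]
        pools[trait] = np.array([index[t] for t in toks if t in index], dtype=int)
    for cat in ("fp_singular", "fp_plural", "articles"):
        toks = [p for p in lexicon.categories[cat] if not p.endswith("*")]
        pools[cat] = np.array([index[t] for t in toks if t in index], dtype=int)
    pools["avg_word_length"] = np.array([index[w] for w in LONG_WORDS], dtype=int)

    lengths = np.array([len(w) for w in words], dtype=float)
    pooled = sorted({i for pool in pools.values() for i in pool})
    filler = np.array([i for i in range(len(words)) if i not in set(pooled)], dtype=int)
    # two filler reservoirs: short vs long, to solve mass + character balance
    filler_short = filler[lengths[filler] <= 4]
    filler_long = filler[lengths[filler] > 4]
    return words, probs, pools, lengths, filler_short, filler_long


(_WORDS, _BASE_PROBS, _POOLS, _LENGTHS, _FILL_SHORT, _FILL_LONG) = _build_vocabulary()
_MEAN_LEN = float(_LENGTHS @ _BASE_PROBS)
_SD_LEN = float(math.sqrt(((_LENGTHS - _MEAN_LEN) ** 2) @ _BASE_PROBS))
_POOL_MASS = {k: float(_BASE_PROBS[v].sum()) for k, v in _POOLS.items()}
_POOL_LEN = {k: float(_LENGTHS[v] @ _BASE_PROBS[v] / _BASE_PROBS[v].sum())
             for k, v in _POOLS.items()}
_MASS_FS = float(_BASE_PROBS[_FILL_SHORT].sum())
_MASS_FL = float(_BASE_PROBS[_FILL_LONG].sum())
_LEN_FS = float(_LENGTHS[_FILL_SHORT] @ _BASE_PROBS[_FILL_SHORT] / _MASS_FS)
_LEN_FL = float(_LENGTHS[_FILL_LONG] @ _BASE_PROBS[_FILL_LONG] / _MASS_FL)


def _subject_probs(latents: dict[str, float], gain: float) -> np.ndarray:
    """Per-subject unigram distribution with filler-compensated modulation.

    Pool k's mass is scaled by (1 + gain·f_k); the added mass and added
    characters are removed from the two filler reservoirs, so to first order
    each assessment's relative frequency depends on its own latent only, and
    average word length depends only on the long-word latent.
    """
    p = _BASE_PROBS.copy()
    d_mass = 0.0
    d_chars = 0.0
    for feat, value in latents.items():
        if feat == "word_count":       # modulates the budget, not the mixture
            continue
        pool = _POOLS[feat]
        factor = max(0.05, 1.0 + gain * value)
        delta = (factor - 1.0) * _POOL_MASS[feat]
        p[pool] *= factor
        d_mass += delta
        # the word-length pool is balanced at the corpus-mean length so its
        # intended length signal survives the character compensation
        d_chars += delta * (_MEAN_LEN if feat == "avg_word_length" else _POOL_LEN[feat])
    # solve a + c = -d_mass; a·L_s + c·L_l = -d_chars
    c = (-d_chars + d_mass * _LEN_FS) / (_LEN_FL - _LEN_FS)
    a = -d_mass - c
    p[_FILL_SHORT] *= max(0.05, 1.0 + a / _MASS_FS)
    p[_FILL_LONG] *= max(0.05, 1.0 + c / _MASS_FL)
    return p / p.sum()


# ---------------------------------------------------------------------------
# Attenuation calibration
# ---------------------------------------------------------------------------

_CAL_FIELDS = ("words_mean", "signal_gain", "baseline_pcl_mean", "baseline_pcl_sd",
               "pcl_noise_sd", "slope_mean", "slope_sd", "n_post_visits",
               "followup_span_mean", "baseline_slope_corr")


def _cfg_key(cfg: GeneratorConfig) -> tuple:
    return tuple(getattr(cfg, f) for f in _CAL_FIELDS) + (
        tuple(sorted((k, float(v[0]), float(v[1]))
                     for k, v in cfg.planted_effects.items())),)


def _fit_times(n_post: int, span: float) -> np.ndarray:
    """Expected post-interview observation times entering the slope fit."""
    return np.concatenate([[0.2], np.linspace(1.5, span, n_post)])


@lru_cache(maxsize=32)
def _outcome_attenuation(key: tuple) -> tuple[float, float]:
    """(corr(b, observed baseline PCL), corr(s, fitted slope)) by Monte Carlo.

    Rounding and the 17–85 clipping make the closed form awkward; 200k draws
    pin these factors to ±0.002.
    """
    cfg = dict(zip(_CAL_FIELDS, key[:-1]))
    rng = np.random.default_rng(987654321)
    n = 200_000
    rho = cfg["baseline_slope_corr"]
    z1, z2 = rng.standard_normal((2, n))
    b = z1
    s = rho * z1 + math.sqrt(1 - rho * rho) * z2
    t = _fit_times(int(cfg["n_post_visits"]), cfg["followup_span_mean"])
    slope = cfg["slope_mean"] + cfg["slope_sd"] * s
    level = cfg["baseline_pcl_mean"] + cfg["baseline_pcl_sd"] * b
    obs = (level[:, None] + slope[:, None] * t[None, :]
           + rng.normal(0, cfg["pcl_noise_sd"], (n, t.size)))
    obs = np.clip(np.round(obs), PCL_MIN, PCL_MAX)
    tc = t - t.mean()
    slope_est = (obs - obs.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)
    return (float(np.corrcoef(b, obs[:, 0])[0, 1]),
            float(np.corrcoef(s, slope_est)[0, 1]))


def _feature_attenuation(feat: str, words_mean: float, gain: float) -> float:
    """corr(measured assessment, its latent) under multinomial sampling."""
    if feat == "word_count":
        return 1.0
    m = _POOL_MASS[feat]
    if feat == "avg_word_length":
        sig = gain * m * (_POOL_LEN[feat] - _MEAN_LEN)
        noise = _SD_LEN / math.sqrt(words_mean)
    else:
        sig = gain * m
        noise = math.sqrt(m * (1 - m) / words_mean)
    return abs(sig) / math.hypot(sig, noise)


@lru_cache(maxsize=32)
def _latent_coefficients(key: tuple) -> dict[str, tuple[float, float, float]]:
    """Per feature: (coef on b, coef on s, residual noise coef).

    Inflates the requested effects by the inverse attenuation of the feature
    measurement and of the relevant outcome, then solves the variance budget;
    an infeasible combination (residual variance < 0) is a config error.
    """
    cfg = dict(zip(_CAL_FIELDS, key[:-1]))
    planted = {k: (v1, v2) for k, v1, v2 in key[-1]}
    r_b, r_s = _outcome_attenuation(key)
    rho = cfg["baseline_slope_corr"]
    out = {}
    for feat, (eb, es) in planted.items():
        if eb == 0 and es == 0:
            out[feat] = (0.0, 0.0, 1.0)
            continue
        r_f = _feature_attenuation(feat, cfg["words_mean"], cfg["signal_gain"])
        if r_f * r_b == 0 or r_f * r_s == 0:
            raise ValueError(
                f"planted effects for {feat!r} are infeasible: the measured "
                "score carries no signal (zero gain or zero outcome variance)"
            )
        want_b = eb / (r_f * r_b)
        want_s = es / (r_f * r_s)
        # corr(f,b)=c_b+c_s·rho, corr(f,s)=c_s+c_b·rho → solve the 2×2 system
        c_b = (want_b - rho * want_s) / (1 - rho * rho)
        c_s = (want_s - rho * want_b) / (1 - rho * rho)
        resid = 1 - c_b * c_b - c_s * c_s - 2 * c_b * c_s * rho
        if resid < 0:
            raise ValueError(
                f"planted effects for {feat!r} are infeasible after attenuation "
                f"calibration (residual variance {resid:.3f} < 0)"
            )
        out[feat] = (c_b, c_s, math.sqrt(resid))
    return out


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _visit_times(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Signed years relative to the interview: one pre, one baseline, posts."""
    t_pre = -1.2 + rng.uniform(-0.3, 0.3)
    t_base = 0.2 + rng.uniform(-0.1, 0.1)
    span = max(cfg.followup_span_min,
               rng.normal(cfg.followup_span_mean, cfg.followup_span_sd))
    posts = np.linspace(1.5, span, cfg.n_post_visits) + rng.uniform(
        -0.15, 0.15, cfg.n_post_visits)
    return np.sort(np.concatenate([[t_pre, t_base], posts]))


def _word_budget(cfg: GeneratorConfig, g: float) -> int:
    d = cfg.words_dispersion
    return max(200, int(round(cfg.words_mean * math.exp(d * g - d * d / 2))))


def _make_transcript(sid: str, counts: np.ndarray,
                     rng: np.random.Generator) -> Transcript:
    tokens = np.repeat(_WORDS, counts)
    rng.shuffle(tokens)
    turns: list[Turn] = []
    pos, clock = 0, 0.0
    while pos < tokens.size:
        n = int(rng.integers(25, 60))
        chunk = tokens[pos:pos + n]
        turns.append(Turn(RESPONDER, " ".join(chunk), round(clock, 1)))
        clock += len(chunk) / 2.5  # ~2.5 words per second of speech
        pos += n
        if pos < tokens.size and rng.random() < 0.35:
            prompt = INTERVIEWER_PROMPTS[int(rng.integers(len(INTERVIEWER_PROMPTS)))]
            turns.append(Turn(INTERVIEWER, prompt, round(clock, 1)))
            clock += 3.0
    return Transcript(sid, turns)


def generate_transcript(latent_factors: dict[str, float], config: GeneratorConfig,
                        seed: int, subject_id: str = "s1",
                        word_budget: int | None = None) -> Transcript:
    """One transcript whose signal-pool rates are modulated by the latents."""
    rng = np.random.default_rng(seed)
    budget = word_budget or _word_budget(config, latent_factors.get("word_count", 0.0))
    p = _subject_probs(latent_factors, config.signal_gain)
    counts = rng.multinomial(budget, p)
    return _make_transcript(subject_id, counts, rng)


def generate_cohort(config: GeneratorConfig | None = None,
                    with_transcripts: bool = True) -> SyntheticCohort:
    """Full synthetic cohort: transcripts (optional), PCL table, ground truth.

    ``with_transcripts=False`` skips building token streams and text, keeping
    only the per-subject bag-of-words counts — numerically equivalent for
    every 1-gram-based assessment and orders of magnitude faster for
    simulation studies.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    coeffs = _latent_coefficients(_cfg_key(cfg))
    n = cfg.n_subjects
    rho = cfg.baseline_slope_corr
    width = max(4, len(str(n)))
    sids = [f"s{i:0{width}d}" for i in range(1, n + 1)]

    b_all = np.empty(n)
    s_all = np.empty(n)
    slopes = np.empty(n)
    latents_all: dict[str, list[float]] = {f: [] for f in cfg.planted_effects}
    counts_map: dict[str, dict[str, int]] = {}
    transcripts: list[Transcript] | None = [] if with_transcripts else None
    rows = []

    for i, sid in enumerate(sids):
        rng = np.random.default_rng([cfg.seed, i])
        z1, z2 = rng.standard_normal(2)
        b = z1
        s = rho * z1 + math.sqrt(1 - rho * rho) * z2
        b_all[i], s_all[i] = b, s

        latents = {}
        for feat in cfg.planted_effects:
            c_b, c_s, c_u = coeffs[feat]
            latents[feat] = c_b * b + c_s * s + c_u * rng.standard_normal()
            latents_all[feat].append(latents[feat])

        budget = _word_budget(cfg, latents.get("word_count", rng.standard_normal()))
        p = _subject_probs(latents, cfg.signal_gain)
        counts = rng.multinomial(budget, p)
        counts_map[sid] = {w: int(c) for w, c in zip(_WORDS, counts) if c}
        if with_transcripts:
            transcripts.append(_make_transcript(sid, counts, rng))

        # longitudinal outcome
        slope_i = cfg.slope_mean + cfg.slope_sd * s
        slopes[i] = slope_i
        times = _visit_times(cfg, rng)
        level = cfg.baseline_pcl_mean + cfg.baseline_pcl_sd * b
        pcl = level + slope_i * times + rng.normal(0, cfg.pcl_noise_sd, times.size)
        pcl = np.clip(np.round(pcl), PCL_MIN, PCL_MAX)

        years_ei = max(8.6, rng.normal(cfg.years_event_to_interview_mean,
                                       cfg.years_event_to_interview_sd))
        interview = EVENT_DATE + timedelta(days=round(years_ei * DAYS_PER_YEAR))
        gender = "male" if rng.random() < cfg.male_fraction else "female"
        occupation = "police" if rng.random() < cfg.police_fraction else "non-police"
        marital = "married" if rng.random() < cfg.married_fraction else "not married"
        age = float(np.clip(np.round(rng.normal(cfg.age_mean, cfg.age_sd), 1), 30, 85))

        seen_days: set[int] = set()
        for t, y in zip(times, pcl):
            offset = round(t * DAYS_PER_YEAR)
            while offset in seen_days:  # calendar-day collisions are invalid
                offset += 1
            seen_days.add(offset)
            rows.append({
                "subject_id": sid,
                "assessment_date": interview + timedelta(days=offset),
                "pcl": float(y),
                "interview_date": interview,
                "age_at_interview": age,
                "gender": gender,
                "occupation": occupation,
                "marital_status": marital,
                "event_date": EVENT_DATE,
            })

    cohort = validate_cohort(pd.DataFrame(rows), source="synthetic")
    truth = GroundTruth(
        subject_ids=sids,
        baseline_factor=b_all,
        slope_factor=s_all,
        true_slopes=slopes,
        feature_latents={k: np.array(v) for k, v in latents_all.items()},
        planted_effects=dict(cfg.planted_effects),
        config=cfg,
    )
    return SyntheticCohort(transcripts, cohort, truth, counts_map)


def profile_from_counts(sid: str, counts: dict[str, int], models, lexicon,
                        topic_model=None) -> AssessmentProfile:
    """Score one subject's bag of words through the real assessment layer."""
    fv = features_from_counts(sid, counts, topic_model=topic_model)
    relfreq1 = fv.relfreq.get(1, {})
    wc, awl = assess.meta_from_counts(counts)
    return AssessmentProfile(
        subject_id=sid,
        **{m: assess.apply_model(fv, models[m]) for m in assess.MODEL_ASSESSMENTS},
        **{c: assess.score_lexicon(relfreq1, lexicon, c) for c in assess.LEXICON_ASSESSMENTS},
        word_count=wc,
        avg_word_length=awl,
    )


def simulate_assessments(
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, CohortTable, GroundTruth]:
    """Cohort + assessment profiles via the document-free path."""
    sim = generate_cohort(config, with_transcripts=False)
    lexicon, topics, models = load_bundled_resources()
    profiles = profiles_frame([
        profile_from_counts(sid, sim.counts[sid], models, lexicon, topics)
        for sid in sim.truth.subject_ids
    ])
    return profiles, sim.cohort, sim.truth


# ---------------------------------------------------------------------------
# Oracle effects
# ---------------------------------------------------------------------------

def oracle_effects(truth: GroundTruth, method: str = "analytic",
                   n_mc: int = 200_000, seed: int = 424242) -> pd.DataFrame:
    """Expected no-controls standardized betas the pipeline should recover.

    ``method="analytic"`` — by construction (attenuation-calibrated latents)
    these equal the planted effects.  ``method="monte_carlo"`` re-derives
    them by simulating the whole measurement chain — calibrated latents,
    Gaussian approximations of the score sampling noise, PCL rounding /
    clipping and the per-subject slope fit — as an independent cross-check
    of the calibration algebra.
    """
    cfg = truth.config
    rho = cfg.baseline_slope_corr
    if method == "analytic":
        rows = [{"feature": f, "baseline": eb, "slope": es}
                for f, (eb, es) in truth.planted_effects.items()]
        return pd.DataFrame(rows).set_index("feature")
    if method != "monte_carlo":
        raise ValueError("method must be 'analytic' or 'monte_carlo'")

    coeffs = _latent_coefficients(_cfg_key(cfg))
    rng = np.random.default_rng(seed)
    z1, z2 = rng.standard_normal((2, n_mc))
    b = z1
    s = rho * z1 + math.sqrt(1 - rho * rho) * z2
    t = _fit_times(cfg.n_post_visits, cfg.followup_span_mean)
    slope_true = cfg.slope_mean + cfg.slope_sd * s
    level = cfg.baseline_pcl_mean + cfg.baseline_pcl_sd * b
    obs = (level[:, None] + slope_true[:, None] * t[None, :]
           + rng.normal(0, cfg.pcl_noise_sd, (n_mc, t.size)))
    obs = np.clip(np.round(obs), PCL_MIN, PCL_MAX)
    baseline_obs = obs[:, 0]
    tc = t - t.mean()
    slope_est = (obs - obs.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)

    rows = []
    for feat, (c_b, c_s, c_u) in coeffs.items():
        f = c_b * b + c_s * s + c_u * rng.standard_normal(n_mc)
        r_f = _feature_attenuation(feat, cfg.words_mean, cfg.signal_gain)
        # measured score ∝ latent + sampling noise at the calibrated ratio
        noise_sd = math.sqrt(max(1.0 / r_f**2 - 1.0, 0.0))
        measured = f + noise_sd * rng.standard_normal(n_mc)
        rows.append({
            "feature": feat,
            "baseline": float(np.corrcoef(measured, baseline_obs)[0, 1]),
            "slope": float(np.corrcoef(measured, slope_est)[0, 1]),
        })
    return pd.DataFrame(rows).set_index("feature")
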