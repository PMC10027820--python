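"""Synthetic expository texts and simulated readers.

The generator exists so every pipeline stage — parsing, cleaning, network
construction, metrics, reader statistics — is testable end to end without
recorded eye-tracking data. It is deliberately minimal: a reader walks each
sentence left to right, skipping words with class-specific probabilities
(function words are skipped more readily than content words), occasionally
refixating the current word, and occasionally regressing a few words back
within the sentence before resuming. Fixation durations are Gaussian,
truncated to the 40-1000 ms window that the cleaning stage keeps, so
simulated fixations survive cleaning unchanged.

Skill presets encode the canonical contrast from the reading literature:
skilled readers make more skips, fewer regressions and fewer refixations
than less skilled readers. Regressions stay within the current sentence,
matching sentence-by-sentence presentation.

Texts emulate ~30-sentence / ~300-word expository passages with recurring
topic words (the "Mars"/"Earth" style hubs of science texts) and a closed
class of function words, flagged for the function-word time-share analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fixation_io import (
    FixationRecord,
    Scanpath,
    TextStimulus,
    canonicalize,
    clean_fixations,
    extract_scanpath,
)
from .stats import ReaderOutcome, comprehension_score

__all__ = [
    "ReaderProfile",
    "SKILLED",
    "LESS_SKILLED",
    "FUNCTION_WORDS",
    "generate_text",
    "simulate_fixations",
    "simulate_scanpath",
    "profile_for_skill",
    "generate_cohort",
]


@dataclass(frozen=True)
class ReaderProfile:
    """Generative parameters of one simulated reader.

    Probabilities are per word (skips) or per fixation (regression,
    refixation); durations are in milliseconds.
    """

    p_skip_function: float = 0.30
    p_skip_content: float = 0.12
    p_regress: float = 0.12
    regress_span: int = 3
    p_refix: float = 0.15
    fixation_ms_mean: float = 220.0
    fixation_ms_sd: float = 80.0

    def __post_init__(self) -> None:
        for name in ("p_skip_function", "p_skip_content", "p_regress", "p_refix"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fixation_ms_mean <= 0 or self.fixation_ms_sd < 0:
            raise ValueError("fixation duration parameters must be positive")
        if self.regress_span < 1:
            raise ValueError("regress_span must be >= 1")


#: Skilled readers: more skips, fewer regressions/refixations, faster fixations.
SKILLED = ReaderProfile(
    p_skip_function=0.55,
    p_skip_content=0.25,
    p_regress=0.05,
    p_refix=0.07,
    fixation_ms_mean=200.0,
    fixation_ms_sd=60.0,
)

#: Less skilled readers: near-exhaustive sampling, frequent regressions.
LESS_SKILLED = ReaderProfile(
    p_skip_function=0.20,
    p_skip_content=0.08,
    p_regress=0.20,
    p_refix=0.22,
    fixation_ms_mean=260.0,
    fixation_ms_sd=90.0,
)

FUNCTION_WORDS: tuple[str, ...] = (
    "the", "a", "an", "of", "in", "on", "at", "to", "and", "or", "is",
    "are", "was", "were", "be", "that", "this", "it", "as", "by", "with",
    "for", "from", "but", "not", "can", "will", "its", "their", "these",
)

_TOPIC_POOL = ("mars", "earth", "orbit", "signal", "circuit", "tanker")

_ONSETS = ("b", "c", "d", "f", "g", "l", "m", "n", "p", "r", "s", "t", "v")
_VOWELS = ("a", "e", "i", "o", "u")
_CODAS = ("", "n", "r", "s", "l", "t")


def _content_vocabulary(rng: np.random.Generator, size: int) -> list[str]:
    """Pronounceable pseudo-words, distinct from the function-word list."""
    vocab: list[str] = []
    seen = set(FUNCTION_WORDS) | set(_TOPIC_POOL)
    while len(vocab) < size:
        n_syll = int(rng.integers(2, 4))
        word = "".join(
            rng.choice(_ONSETS) + rng.choice(_VOWELS) + rng.choice(_CODAS)
            for _ in range(n_syll)
        )
        if word not in seen:
            seen.add(word)
            vocab.append(word)
    return vocab


def generate_text(
    n_sentences: int = 30,
    mean_words: int = 10,
    n_topic_words: int = 2,
    seed: int = 0,
    text_id: str = "synthetic",
) -> TextStimulus:
    """Deterministic synthetic expository text.

    Topic words recur across at least half the sentences so that a plain
    sequential read already produces hub nodes; roughly a third of the
    remaining slots hold function words drawn from the closed-class list,
    and content slots draw from a Zipf-like pseudo-word vocabulary.
    """
    if n_sentences < 1:
        raise ValueError("n_sentences must be >= 1")
    if not 0 <= n_topic_words <= len(_TOPIC_POOL):
        raise ValueError(f"n_topic_words must be in [0, {len(_TOPIC_POOL)}]")
    rng = np.random.default_rng(seed)
    topics = list(_TOPIC_POOL[:n_topic_words])
    vocab = _content_vocabulary(rng, size=max(120, 12 * mean_words))
    # Mildly skewed reuse: some content words recur in a handful of
    # sentences, but only the designated topic words recur across most of
    # the text (expository texts have few genuinely pervasive terms).
    ranks = np.arange(1, len(vocab) + 1, dtype=float)
    probs = (1.0 / (ranks + 30)) / (1.0 / (ranks + 30)).sum()
    sentences: list[tuple[str, ...]] = []
    flags: list[tuple[bool, ...]] = []
    for s in range(n_sentences):
        length = max(3, int(rng.poisson(mean_words)))
        tokens: list[str] = []
        for _ in range(length):
            if rng.random() < 0.35:
                tokens.append(str(rng.choice(FUNCTION_WORDS)))
            else:
                tokens.append(vocab[int(rng.choice(len(vocab), p=probs))])
        # alternating parity guarantees >= 50% sentence coverage per topic
        # word while keeping topic co-occurrence within a sentence low
        for t_idx, topic in enumerate(topics):
            if s % 2 == t_idx % 2 or rng.random() < 0.15:
                pos = int(rng.integers(0, len(tokens) + 1))
                tokens.insert(pos, topic)
        sentences.append(tuple(tokens))
        flags.append(tuple(tok in FUNCTION_WORDS for tok in tokens))
    return TextStimulus(
        text_id=text_id,
        sentences=tuple(sentences),
        function_word_flags=tuple(flags),
    )


def _truncated_duration(rng: np.random.Generator, profile: ReaderProfile) -> float:
    return float(
        np.clip(rng.normal(profile.fixation_ms_mean, profile.fixation_ms_sd), 40.0, 1000.0)
    )


def _anchor_words(text: TextStimulus, salience_threshold: float) -> set[str]:
    """Topic-like anchors: non-function words recurring across many sentences."""
    n_sent = len(text.sentences)
    per_sentence: dict[str, int] = {}
    function_keys: set[str] = set()
    for s_idx, sentence in enumerate(text.sentences):
        seen: set[str] = set()
        for w_idx, tok in enumerate(sentence):
            key = canonicalize(tok)
            if (
                text.function_word_flags is not None
                and text.function_word_flags[s_idx][w_idx]
            ):
                function_keys.add(key)
            if key not in seen:
                seen.add(key)
                per_sentence[key] = per_sentence.get(key, 0) + 1
    return {
        key
        for key, count in per_sentence.items()
        if count >= salience_threshold * n_sent and key not in function_keys
    }


def simulate_fixations(
    text: TextStimulus,
    profile: ReaderProfile,
    participant_id: str = "sim",
    seed: int = 0,
    topic_salience_threshold: float = 0.25,
) -> list[FixationRecord]:
    """Simulate one reading pass as raw fixation records.

    Recurring topic words (non-function words present in at least
    ``topic_salience_threshold`` of the sentences) are never skipped: they
    anchor comprehension for readers of every skill level, which is what
    makes them hubs of the resulting network. Regressions land on a
    uniformly chosen non-anchor word within ``regress_span`` words back —
    readers re-check difficult material, not the topic terms they already
    know.

    The records come out in the exact dialect :mod:`scanpathnet.fixation_io`
    consumes, so the full parse/clean/extract pipeline can run on them.
    """
    rng = np.random.default_rng(seed)
    anchors = _anchor_words(text, topic_salience_threshold)
    onset = 0.0
    records: list[FixationRecord] = []

    def fixate(s_idx: int, w_idx: int) -> None:
        nonlocal onset
        dur = _truncated_duration(rng, profile)
        records.append(
            FixationRecord(
                participant_id=participant_id,
                text_id=text.text_id,
                sentence_index=s_idx,
                word_index=w_idx,
                token=text.sentences[s_idx][w_idx],
                onset_ms=onset,
                duration_ms=dur,
            )
        )
        onset += dur + 25.0  # saccade latency between fixations

    for s_idx, sentence in enumerate(text.sentences):
        for w_idx in range(len(sentence)):
            if canonicalize(sentence[w_idx]) in anchors:
                p_skip = 0.0
            elif (
                text.function_word_flags is not None
                and text.function_word_flags[s_idx][w_idx]
            ):
                p_skip = profile.p_skip_function
            else:
                p_skip = profile.p_skip_content
            if rng.random() < p_skip:
                continue
            fixate(s_idx, w_idx)
            if rng.random() < profile.p_refix:
                fixate(s_idx, w_idx)
            if w_idx > 0 and rng.random() < profile.p_regress:
                candidates = [
                    w
                    for w in range(max(0, w_idx - profile.regress_span), w_idx)
                    if canonicalize(sentence[w]) not in anchors
                ]
                if candidates:
                    fixate(s_idx, int(rng.choice(candidates)))
    return records


def simulate_scanpath(
    text: TextStimulus,
    profile: ReaderProfile,
    participant_id: str = "sim",
    seed: int = 0,
    topic_salience_threshold: float = 0.25,
) -> Scanpath:
    """Simulate one reading pass and return the cleaned scanpath."""
    records = simulate_fixations(
        text,
        profile,
        participant_id=participant_id,
        seed=seed,
        topic_salience_threshold=topic_salience_threshold,
    )
    kept, _ = clean_fixations(records)
    if not kept:
        # all-skip profiles on tiny texts can produce zero fixations;
        # force a single fixation on the first word so the scanpath exists
        rng = np.random.default_rng(seed)
        kept = [
            FixationRecord(
                participant_id=participant_id,
                text_id=text.text_id,
                sentence_index=0,
                word_index=0,
                token=text.sentences[0][0],
                onset_ms=0.0,
                duration_ms=_truncated_duration(rng, profile),
            )
        ]
    return extract_scanpath(kept, text)


def profile_for_skill(skill: float) -> ReaderProfile:
    """Interpolate linearly between the less-skilled (0) and skilled (1) presets."""
    if not 0.0 <= skill <= 1.0:
        raise ValueError(f"skill must be in [0, 1], got {skill}")

    def lerp(a: float, b: float) -> float:
        return a + skill * (b - a)

    return ReaderProfile(
        p_skip_function=lerp(LESS_SKILLED.p_skip_function, SKILLED.p_skip_function),
        p_skip_content=lerp(LESS_SKILLED.p_skip_content, SKILLED.p_skip_content),
        p_regress=lerp(LESS_SKILLED.p_regress, SKILLED.p_regress),
        regress_span=LESS_SKILLED.regress_span,
        p_refix=lerp(LESS_SKILLED.p_refix, SKILLED.p_refix),
        fixation_ms_mean=lerp(LESS_SKILLED.fixation_ms_mean, SKILLED.fixation_ms_mean),
        fixation_ms_sd=lerp(LESS_SKILLED.fixation_ms_sd, SKILLED.fixation_ms_sd),
    )


def generate_cohort(
    n_readers: int,
    texts: Sequence[TextStimulus] | None = None,
    seed: int = 0,
    noise: float = 1.0,
) -> tuple[dict[tuple[str, str], Scanpath], list[ReaderOutcome]]:
    """Simulate a cohort of readers over one or more texts.

    Readers are placed along the skill spectrum; behavioral outcome
    components are monotone functions of skill plus Gaussian noise scaled
    by ``noise`` (0 gives a deterministic monotone mapping, so the ability
    rank order equals the skill rank order). Returns the scanpaths keyed by
    (participant, text) and the outcomes with comprehension ability filled.
    """
    if n_readers < 2:
        raise ValueError("a cohort needs >= 2 readers")
    rng = np.random.default_rng(seed)
    if texts is None:
        texts = [generate_text(seed=int(rng.integers(0, 2**31 - 1)))]
    skills = np.linspace(0.03, 0.97, n_readers)
    rng.shuffle(skills)
    scanpaths: dict[tuple[str, str], Scanpath] = {}
    outcomes: list[ReaderOutcome] = []
    width = len(str(n_readers - 1))
    for r, skill in enumerate(skills):
        pid = f"reader{r:0{width}d}"
        profile = profile_for_skill(float(skill))
        for text in texts:
            sp = simulate_scanpath(
                text,
                profile,
                participant_id=pid,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            scanpaths[(pid, text.text_id)] = sp
        assessment = float(np.clip(0.45 + 0.5 * skill + rng.normal(0, 0.06 * noise), 0, 1))
        gsrt = float(85.0 + 30.0 * skill + rng.normal(0, 4.0 * noise))
        total_rt = float(90_000.0 - 35_000.0 * skill + rng.normal(0, 4_000.0 * noise))
        outcomes.append(
            ReaderOutcome(
                participant_id=pid,
                assessment_score=assessment,
                gsrt_score=gsrt,
                total_reading_time_ms=total_rt,
            )
        )
    return scanpaths, comprehension_score(outcomes)
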