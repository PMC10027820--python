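"""Ingest, validate and clean word-level eye-tracking fixation reports.

This module turns tabular fixation reports (EyeLink Data Viewer-style CSV/TSV
exports, one row per fixation with a word-level area of interest) into
per-reader, per-text :class:`Scanpath` objects: time-ordered sequences of
fixated word tokens.

The cleaning rule follows standard reading-research practice: fixations
shorter than 40 ms or longer than 1000 ms are excluded (boundary values are
kept). Word tokens are canonicalized — lower-cased, outer punctuation
stripped — so that recurrences of the same orthographic word ("Could",
"could", "could?") map onto one node key when a network is later built.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

logger = logging.getLogger(__name__)

__all__ = [
    "FixationRecord",
    "TextStimulus",
    "ScanpathEntry",
    "Scanpath",
    "ParseResult",
    "DEFAULT_COLUMNS",
    "canonicalize",
    "parse_fixation_report",
    "write_fixation_report",
    "clean_fixations",
    "extract_scanpath",
    "write_scanpaths",
    "read_scanpaths",
]

#: Default column names, matching EyeLink Data Viewer fixation-report
#: conventions for the session/fixation fields.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "participant": "RECORDING_SESSION_LABEL",
    "text": "TEXT_ID",
    "sentence": "SENTENCE_INDEX",
    "word": "WORD_INDEX",
    "token": "TOKEN",
    "onset": "CURRENT_FIX_START",
    "duration": "CURRENT_FIX_DURATION",
}

_REQUIRED_FIELDS = tuple(DEFAULT_COLUMNS)

_EDGE_PUNCT = re.compile(r"^\W+|\W+$", flags=re.UNICODE)


class FixationFormatError(ValueError):
    """A fixation report is malformed (missing column, bad grouping...)."""


def canonicalize(token: str) -> str:
    """Map an orthographic token to its canonical node key.

    Lower-cases and strips leading/trailing punctuation while keeping
    internal hyphens and apostrophes, so "Could", "could," and "could?"
    all become ``"could"`` and merge into one network node, while
    "well-known" keeps its hyphen.
    """
    return _EDGE_PUNCT.sub("", token.strip().lower())


@dataclass(frozen=True)
class FixationRecord:
    """One fixation: who looked at which word of which text, when, how long."""

    participant_id: str
    text_id: str
    sentence_index: int
    word_index: int
    token: str
    onset_ms: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError(f"duration_ms must be positive, got {self.duration_ms}")
        if self.onset_ms < 0:
            raise ValueError(f"onset_ms must be non-negative, got {self.onset_ms}")
        if self.sentence_index < 0 or self.word_index < 0:
            raise ValueError("sentence_index and word_index must be non-negative")


@dataclass(frozen=True)
class TextStimulus:
    """An ordered text: sentences of word tokens, with optional function-word flags.

    ``function_word_flags`` mirrors ``sentences`` shape-for-shape when present;
    a flag marks a closed-class (function) word such as an article or
    preposition.
    """

    text_id: str
    sentences: tuple[tuple[str, ...], ...]
    function_word_flags: tuple[tuple[bool, ...], ...] | None = None

    def __post_init__(self) -> None:
        if not self.sentences:
            raise ValueError("a stimulus must contain at least one sentence")
        for s in self.sentences:
            if not s or any(not tok for tok in s):
                raise ValueError("every sentence must be a non-empty list of non-empty tokens")
        if self.function_word_flags is not None:
            if tuple(len(s) for s in self.function_word_flags) != tuple(
                len(s) for s in self.sentences
            ):
                raise ValueError("function_word_flags must mirror the sentence shape")

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)

    def token_at(self, sentence_index: int, word_index: int) -> str:
        try:
            return self.sentences[sentence_index][word_index]
        except IndexError:
            raise KeyError(
                f"({sentence_index}, {word_index}) does not resolve to a token "
                f"in text {self.text_id!r}"
            ) from None

    def is_function_word(self, sentence_index: int, word_index: int) -> bool:
        if self.function_word_flags is None:
            raise FixationFormatError(
                f"text {self.text_id!r} carries no function-word flags"
            )
        return self.function_word_flags[sentence_index][word_index]

    # -- serialization ---------------------------------------------------
    @classmethod
    def from_text_file(cls, path: Union[str, Path], text_id: str | None = None) -> "TextStimulus":
        """Plain-text stimulus: one sentence per line, whitespace tokens."""
        path = Path(path)
        sentences = tuple(
            tuple(line.split())
            for line in path.read_text().splitlines()
            if line.strip()
        )
        return cls(text_id=text_id or path.stem, sentences=sentences)

    @classmethod
    def from_json(cls, source: Union[str, Path, Mapping]) -> "TextStimulus":
        obj = source if isinstance(source, Mapping) else json.loads(Path(source).read_text())
        flags = obj.get("function_word_flags")
        return cls(
            text_id=str(obj["text_id"]),
            sentences=tuple(tuple(s) for s in obj["sentences"]),
            function_word_flags=(
                tuple(tuple(bool(b) for b in s) for s in flags) if flags is not None else None
            ),
        )

    def to_json(self, path: Union[str, Path, None] = None) -> dict:
        obj: dict = {"text_id": self.text_id, "sentences": [list(s) for s in self.sentences]}
        if self.function_word_flags is not None:
            obj["function_word_flags"] = [list(s) for s in self.function_word_flags]
        if path is not None:
            Path(path).write_text(json.dumps(obj, indent=1))
        return obj


@dataclass(frozen=True)
class ScanpathEntry:
    node_key: str
    sentence_index: int
    word_index: int
    duration_ms: float


@dataclass(frozen=True)
class Scanpath:
    """Time-ordered sequence of fixated (canonicalized) word tokens."""

    participant_id: str
    text_id: str
    entries: tuple[ScanpathEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def node_keys(self) -> tuple[str, ...]:
        return tuple(e.node_key for e in self.entries)

    @property
    def total_duration_ms(self) -> float:
        return sum(e.duration_ms for e in self.entries)


@dataclass
class ParseResult:
    """Parsed fixation records plus a report of rejected rows."""

    records: list[FixationRecord]
    rejects: list[tuple[int, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _open_source(source: Union[str, Path, TextIO]) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", newline=""), True
    return source, False


def parse_fixation_report(
    source: Union[str, Path, TextIO],
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> ParseResult:
    """Parse a CSV/TSV fixation report into :class:`FixationRecord` objects.

    ``column_map`` maps the seven logical field names (keys of
    :data:`DEFAULT_COLUMNS`) to the column names used in the file. Extra,
    unmapped columns are ignored. Rows whose numeric fields do not parse are
    collected in ``rejects`` (row number, reason) rather than silently
    dropped.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(_REQUIRED_FIELDS)
        if unknown:
            raise FixationFormatError(f"unknown column_map keys: {sorted(unknown)}")
        colmap.update(column_map)

    stream, should_close = _open_source(source)
    try:
        sample = stream.read(4096)
        stream.seek(0)
        if not sample.strip():
            logger.warning("empty fixation report")
            return ParseResult(records=[])
        if delimiter is None:
            delimiter = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(stream, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [colmap[f] for f in _REQUIRED_FIELDS if colmap[f] not in header]
        if missing:
            raise FixationFormatError(
                f"fixation report is missing mapped column(s): {missing}"
            )
        records: list[FixationRecord] = []
        rejects: list[tuple[int, str]] = []
        for rownum, row in enumerate(reader, start=2):  # 1 = header line
            try:
                rec = FixationRecord(
                    participant_id=str(row[colmap["participant"]]).strip(),
                    text_id=str(row[colmap["text"]]).strip(),
                    sentence_index=int(row[colmap["sentence"]]),
                    word_index=int(row[colmap["word"]]),
                    token=str(row[colmap["token"]]).strip(),
                    onset_ms=float(row[colmap["onset"]]),
                    duration_ms=float(row[colmap["duration"]]),
                )
            except (TypeError, ValueError) as exc:
                rejects.append((rownum, str(exc)))
                continue
            records.append(rec)
        if rejects:
            logger.warning("rejected %d malformed fixation row(s)", len(rejects))
        return ParseResult(records=records, rejects=rejects)
    finally:
        if should_close:
            stream.close()


def write_fixation_report(
    records: Iterable[FixationRecord],
    path: Union[str, Path, TextIO],
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write records in the same CSV dialect :func:`parse_fixation_report` reads."""
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    stream, should_close = (
        (open(path, "w", newline=""), True)
        if isinstance(path, (str, Path))
        else (path, False)
    )
    try:
        writer = csv.writer(stream)
        writer.writerow([colmap[f] for f in _REQUIRED_FIELDS])
        for r in records:
            writer.writerow(
                [
                    r.participant_id,
                    r.text_id,
                    r.sentence_index,
                    r.word_index,
                    r.token,
                    f"{r.onset_ms:g}",
                    f"{r.duration_ms:g}",
                ]
            )
    finally:
        if should_close:
            stream.close()


def clean_fixations(
    records: Sequence[FixationRecord],
    min_ms: float = 40.0,
    max_ms: float = 1000.0,
) -> tuple[list[FixationRecord], list[FixationRecord]]:
    """Partition fixations into (kept, removed) by duration.

    Keeps fixations with ``min_ms <= duration_ms <= max_ms`` (boundaries
    inclusive: only fixations strictly shorter than 40 ms or strictly longer
    than 1000 ms are blink artifacts / tracker losses to discard). Input
    order is preserved in both lists, and the operation is idempotent.
    """
    if min_ms >= max_ms:
        raise ValueError(f"min_ms ({min_ms}) must be < max_ms ({max_ms})")
    kept = [r for r in records if min_ms <= r.duration_ms <= max_ms]
    removed = [r for r in records if not (min_ms <= r.duration_ms <= max_ms)]
    return kept, removed


def extract_scanpath(
    records: Sequence[FixationRecord],
    stimulus: TextStimulus,
) -> Scanpath:
    """Order cleaned fixations by onset and map them onto canonical word keys.

    All records must belong to one participant x text pair. Onset ties are
    broken by input order and logged (they indicate malformed input from a
    monocular high-rate tracker).
    """
    if not records:
        raise ValueError("cannot extract a scanpath from zero fixations")
    participants = {r.participant_id for r in records}
    texts = {r.text_id for r in records}
    if len(participants) > 1 or len(texts) > 1:
        raise FixationFormatError(
            f"records span multiple participants/texts: {sorted(participants)} x {sorted(texts)}"
        )
    onsets = [r.onset_ms for r in records]
    if len(set(onsets)) < len(onsets):
        logger.warning(
            "onset ties in fixation records for %s/%s; breaking by input order",
            next(iter(participants)),
            next(iter(texts)),
        )
    ordered = sorted(enumerate(records), key=lambda ir: (ir[1].onset_ms, ir[0]))
    entries = []
    for _, r in ordered:
        token = stimulus.token_at(r.sentence_index, r.word_index)
        entries.append(
            ScanpathEntry(
                node_key=canonicalize(token),
                sentence_index=r.sentence_index,
                word_index=r.word_index,
                duration_ms=r.duration_ms,
            )
        )
    return Scanpath(
        participant_id=next(iter(participants)),
        text_id=next(iter(texts)),
        entries=tuple(entries),
    )


_SCANPATH_COLUMNS = [
    "participant",
    "text",
    "order",
    "node_key",
    "sentence_index",
    "word_index",
    "duration_ms",
]


def write_scanpaths(scanpaths: Iterable[Scanpath], path: Union[str, Path, TextIO]) -> None:
    """Write scanpaths to the package's CSV scanpath format (round-trip safe)."""
    stream, should_close = (
        (open(path, "w", newline=""), True)
        if isinstance(path, (str, Path))
        else (path, False)
    )
    try:
        writer = csv.writer(stream)
        writer.writerow(_SCANPATH_COLUMNS)
        for sp in scanpaths:
            for i, e in enumerate(sp.entries):
                writer.writerow(
                    [
                        sp.participant_id,
                        sp.text_id,
                        i,
                        e.node_key,
                        e.sentence_index,
                        e.word_index,
                        repr(e.duration_ms),
                    ]
                )
    finally:
        if should_close:
            stream.close()


def read_scanpaths(source: Union[str, Path, TextIO]) -> list[Scanpath]:
    """Read scanpaths written by :func:`write_scanpaths`."""
    stream, should_close = _open_source(source)
    try:
        reader = csv.DictReader(stream)
        groups: dict[tuple[str, str], list[tuple[int, ScanpathEntry]]] = {}
        order_seen: list[tuple[str, str]] = []
        for row in reader:
            key = (row["participant"], row["text"])
            if key not in groups:
                groups[key] = []
                order_seen.append(key)
            groups[key].append(
                (
                    int(row["order"]),
                    ScanpathEntry(
                        node_key=row["node_key"],
                        sentence_index=int(row["sentence_index"]),
                        word_index=int(row["word_index"]),
                        duration_ms=float(row["duration_ms"]),
                    ),
                )
            )
        result = []
        for participant, text in order_seen:
            entries = tuple(
                e for _, e in sorted(groups[(participant, text)], key=lambda oe: oe[0])
            )
            result.append(Scanpath(participant_id=participant, text_id=text, entries=entries))
        return result
    finally:
        if should_close:
            stream.close()
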