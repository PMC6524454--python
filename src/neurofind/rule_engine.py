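"""Lexicon-driven rule engine for SBI/WMD document classification.

Pipeline: sentence segmentation -> section detection -> regex concept
matching against the shipped lexicon -> cue-and-scope context assignment
(status / temporality / experiencer / chronicity) -> heuristic document
summarization into one 3-way label per condition.

Matching is case-insensitive and word-boundary anchored; overlapping
candidates resolve longest-match-first, then leftmost. All offsets are
0-based half-open.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from neurofind.corpus_io import Label, Report
from neurofind.errors import FormatError


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

class SectionKind(enum.Enum):
    FINDINGS = "findings"
    IMPRESSION = "impression"
    OTHER = "other"


class Category(enum.Enum):
    SBI_FINDING = "sbi_finding"
    SBI_MODIFIER_CHRONIC = "sbi_modifier_chronic"
    SBI_MODIFIER_ACUTE = "sbi_modifier_acute"
    SBI_LOCATION = "sbi_location"
    WMD_FINDING = "wmd_finding"
    WMD_EXCLUSION = "wmd_exclusion"


class Concept(enum.Enum):
    SBI = "sbi"
    WMD = "wmd"


class Status(enum.Enum):
    CONFIRMED = "confirmed"
    PROBABLE = "probable"
    NEGATED = "negated"


class Temporality(enum.Enum):
    PRESENT = "present"
    HISTORICAL = "historical"
    HYPOTHETICAL = "hypothetical"


class Experiencer(enum.Enum):
    PATIENT = "patient"
    OTHER = "other"


class Chronicity(enum.Enum):
    CHRONIC = "chronic"
    ACUTE = "acute"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class Sentence:
    """A sentence span of one report; offsets index into the report text."""

    report_id: str
    index: int
    start: int
    end: int
    text: str
    section: SectionKind = SectionKind.OTHER

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad sentence span [{self.start}, {self.end})")


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    category: Category
    concept: Concept

    def __post_init__(self) -> None:
        if not self.surface:
            raise FormatError("lexicon surface must be non-empty")


@dataclass(frozen=True)
class ConceptMention:
    """A lexicon match within one sentence, with context attributes.

    ``span`` is relative to the sentence text (0-based half-open).
    Defaults are CONFIRMED / PRESENT / PATIENT / UNSPECIFIED: a mention
    with no firing cue is a current, affirmed patient finding.
    """

    sentence: Sentence
    span: tuple[int, int]
    matched_entry: LexiconEntry
    concept: Concept
    status: Status = Status.CONFIRMED
    temporality: Temporality = Temporality.PRESENT
    experiencer: Experiencer = Experiencer.PATIENT
    chronicity: Chronicity = Chronicity.UNSPECIFIED

    @property
    def surface_text(self) -> str:
        return self.sentence.text[self.span[0] : self.span[1]]

    @property
    def category(self) -> Category:
        return self.matched_entry.category


@dataclass(frozen=True)
class DocumentClassification:
    report_id: str
    sbi_label: Label
    wmd_label: Label
    evidence: tuple[ConceptMention, ...] = ()


@dataclass(frozen=True)
class ContextCue:
    cue: str
    attribute: str  # status | temporality | experiencer
    value: str
    direction: str  # pre | post | both


# ---------------------------------------------------------------------------
# Lexicon and cue loading
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("neurofind.data").joinpath(name).read_text("utf-8")


def load_lexicon(path: str | Path) -> list[LexiconEntry]:
    """Load a TSV lexicon with columns surface, category, concept."""
    with open(path, encoding="utf-8") as fh:
        return _parse_lexicon(fh)


def _parse_lexicon(lines: Iterable[str]) -> list[LexiconEntry]:
    reader = csv.DictReader(lines, delimiter="\t")
    entries = []
    for row in reader:
        entries.append(
            LexiconEntry(
                surface=row["surface"].strip(),
                category=Category(row["category"].strip().lower()),
                concept=Concept(row["concept"].strip().lower()),
            )
        )
    return entries


def default_lexicon() -> list[LexiconEntry]:
    """The packaged default lexicon of finding/modifier/location/exclusion
    keywords for SBI and WMD."""
    return _parse_lexicon(_data_text("box1_lexicon.tsv").splitlines())


def load_cues(path: str | Path) -> list[ContextCue]:
    with open(path, encoding="utf-8") as fh:
        return _parse_cues(fh)


def _parse_cues(lines: Iterable[str]) -> list[ContextCue]:
    reader = csv.DictReader(lines, delimiter="\t")
    return [
        ContextCue(
            cue=row["cue"].strip().lower(),
            attribute=row["attribute"].strip().lower(),
            value=row["value"].strip().lower(),
            direction=row["direction"].strip().lower(),
        )
        for row in reader
    ]


def default_cues() -> list[ContextCue]:
    return _parse_cues(_data_text("context_cues.tsv").splitlines())


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

_ABBREVIATIONS = {
    "vs", "dr", "mr", "mrs", "ms", "st", "e.g", "i.e", "etc", "approx",
    "cm", "mm", "no", "fig", "a.m", "p.m",
}

_BOUNDARY = re.compile(r"[.?!]+(?=\s|$)|\n")


def _is_abbrev_or_enum(text: str, dot_pos: int) -> bool:
    """True when the terminator at ``dot_pos`` ends an abbreviation or a
    bare enumeration number ('1.'), which must not split."""
    i = dot_pos
    while i > 0 and (text[i - 1].isalnum() or text[i - 1] == "."):
        i -= 1
    token = text[i:dot_pos].lower().rstrip(".")
    if not token:
        return False
    if token.isdigit():
        return True
    return token in _ABBREVIATIONS


def segment_sentences(text: str, report_id: str = "") -> list[Sentence]:
    """Abbreviation-safe sentence splitting with character offsets.

    Splits on sentence terminators followed by whitespace and on newlines;
    enumeration markers like "1." and common abbreviations do not split.
    Whitespace-only spans are dropped, so spans plus inter-sentence gaps
    reconstruct the input text.
    """
    if not text or not text.strip():
        raise ValueError("cannot segment empty text")
    breaks: list[int] = []
    for m in _BOUNDARY.finditer(text):
        if m.group() == "\n":
            breaks.append(m.end())
        elif not _is_abbrev_or_enum(text, m.start()):
            breaks.append(m.end())
    breaks.append(len(text))
    sentences: list[Sentence] = []
    prev = 0
    for b in breaks:
        raw = text[prev:b]
        stripped = raw.strip()
        if stripped:
            start = prev + len(raw) - len(raw.lstrip())
            end = start + len(stripped)
            sentences.append(
                Sentence(
                    report_id=report_id,
                    index=len(sentences),
                    start=start,
                    end=end,
                    text=text[start:end],
                )
            )
        prev = b
    return sentences


_HEADER = re.compile(r"^(findings|impression)\b:?", re.IGNORECASE)


def detect_sections(sentences: Sequence[Sentence], text: str) -> list[Sentence]:
    """Assign section labels from line-anchored FINDINGS/IMPRESSION headers.

    A header switches the current section only when the sentence begins it
    and nothing but whitespace precedes it on its line; a mid-sentence
    "impression" does not switch sections.
    """
    out: list[Sentence] = []
    current = SectionKind.OTHER
    for s in sentences:
        m = _HEADER.match(s.text)
        if m is not None:
            line_start = text.rfind("\n", 0, s.start) + 1
            if text[line_start : s.start].strip() == "":
                current = SectionKind(m.group(1).lower())
        out.append(replace(s, section=current))
    return out


# ---------------------------------------------------------------------------
# Concept matching
# ---------------------------------------------------------------------------

def _surface_pattern(surface: str) -> re.Pattern:
    parts = [re.escape(p) for p in surface.split()]
    return re.compile(r"(?<!\w)" + r"\s+".join(parts) + r"(?!\w)", re.IGNORECASE)


_WS = re.compile(r"\s+")


def match_concepts(
    sentence: Sentence, lexicon: Sequence[LexiconEntry]
) -> list[ConceptMention]:
    """Match lexicon surfaces in one sentence (context attributes default).

    Overlaps resolve longest-match-first then leftmost. A WMD exclusion
    match suppresses WMD finding matches it overlaps or immediately
    follows (whitespace-adjacent), so "white matter degenerative changes"
    yields no WMD finding.
    """
    text = sentence.text
    candidates: list[tuple[int, int, LexiconEntry]] = []
    for entry in lexicon:
        for m in _surface_pattern(entry.surface).finditer(text):
            candidates.append((m.start(), m.end(), entry))
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2].category.value))
    accepted: list[tuple[int, int, LexiconEntry]] = []
    for start, end, entry in candidates:
        if all(end <= a or start >= b for a, b, _ in accepted):
            accepted.append((start, end, entry))
    accepted.sort(key=lambda c: c[0])

    exclusions = [c for c in accepted if c[2].category is Category.WMD_EXCLUSION]

    def _suppressed(start: int, end: int) -> bool:
        for xs, xe, _ in exclusions:
            if start < xe and xs < end:  # overlap
                return True
            if xs >= end and text[end:xs].strip() == "":  # adjacent on the left
                return True
        return False

    mentions = []
    for start, end, entry in accepted:
        if entry.category is Category.WMD_FINDING and _suppressed(start, end):
            continue
        mentions.append(
            ConceptMention(
                sentence=sentence,
                span=(start, end),
                matched_entry=entry,
                concept=entry.concept,
            )
        )
    return mentions


# ---------------------------------------------------------------------------
# Context assignment
# ---------------------------------------------------------------------------

_TERMINATOR = re.compile(r"(?<!\w)(?:but|however)(?!\w)|;", re.IGNORECASE)


def _cue_fires(cue: ContextCue, text: str, span: tuple[int, int]) -> bool:
    """A cue fires when it sits on the allowed side of the mention and no
    scope terminator intervenes between cue and mention."""
    pattern = _surface_pattern(cue.cue)
    for m in pattern.finditer(text):
        if cue.direction in ("pre", "both") and m.end() <= span[0]:
            if not _TERMINATOR.search(text, m.end(), span[0]):
                return True
        if cue.direction in ("post", "both") and m.start() >= span[1]:
            if not _TERMINATOR.search(text, span[1], m.start()):
                return True
    return False


def assign_context(
    mention: ConceptMention,
    sentence: Sentence,
    sentence_mentions: Sequence[ConceptMention] = (),
    cues: Sequence[ContextCue] | None = None,
) -> ConceptMention:
    """Resolve status/temporality/experiencer from cue scopes and chronicity
    from the nearest SBI modifier mention in the same sentence.

    Negation outranks hedging when both fire. Defaults are
    CONFIRMED / PRESENT / PATIENT / UNSPECIFIED.
    """
    if cues is None:
        cues = default_cues()
    text = sentence.text
    status = Status.CONFIRMED
    temporality = Temporality.PRESENT
    experiencer = Experiencer.PATIENT

    hedged = False
    for cue in cues:
        if not _cue_fires(cue, text, mention.span):
            continue
        if cue.attribute == "status":
            if cue.value == "negated":
                status = Status.NEGATED
            elif cue.value == "probable":
                hedged = True
        elif cue.attribute == "temporality":
            temporality = Temporality(cue.value)
        elif cue.attribute == "experiencer":
            experiencer = Experiencer(cue.value)
    if hedged and status is not Status.NEGATED:
        status = Status.PROBABLE

    chronicity = Chronicity.UNSPECIFIED
    if mention.concept is Concept.SBI:
        modifier_sets = {
            Category.SBI_MODIFIER_ACUTE: Chronicity.ACUTE,
            Category.SBI_MODIFIER_CHRONIC: Chronicity.CHRONIC,
        }
        best_dist = None
        mid = (mention.span[0] + mention.span[1]) / 2
        for other in sentence_mentions:
            kind = modifier_sets.get(other.category)
            if kind is None:
                continue
            dist = abs((other.span[0] + other.span[1]) / 2 - mid)
            if best_dist is None or dist < best_dist:
                best_dist = dist
                chronicity = kind

    return replace(
        mention,
        status=status,
        temporality=temporality,
        experiencer=experiencer,
        chronicity=chronicity,
    )


# ---------------------------------------------------------------------------
# Document summarization
# ---------------------------------------------------------------------------

def _qualifies(mention: ConceptMention, concept: Concept) -> bool:
    """Base predicate for a mention to support a non-negative label.

    SBI additionally requires non-acute chronicity: an acute infarct is not
    a silent (incidental) one.
    """
    if mention.experiencer is not Experiencer.PATIENT:
        return False
    if mention.temporality is not Temporality.PRESENT:
        return False
    if concept is Concept.SBI and mention.chronicity is Chronicity.ACUTE:
        return False
    return True


def summarize_document(
    report_id: str,
    mentions: Sequence[ConceptMention],
    impression_only: bool = False,
) -> DocumentClassification:
    """Precedence-ladder aggregation of context-resolved mentions.

    Per concept: POSITIVE when any qualifying finding mention is CONFIRMED,
    INDETERMINATE when the best qualifying mention is PROBABLE, NEGATIVE
    otherwise. NEGATIVE evidence carries the negated finding mentions that
    were considered and rejected.
    """
    finding_cat = {Concept.SBI: Category.SBI_FINDING, Concept.WMD: Category.WMD_FINDING}
    labels: dict[Concept, Label] = {}
    evidence: list[ConceptMention] = []
    for concept in (Concept.SBI, Concept.WMD):
        findings = [
            m
            for m in mentions
            if m.category is finding_cat[concept]
            and (not impression_only or m.sentence.section is SectionKind.IMPRESSION)
        ]
        confirmed = [
            m for m in findings if m.status is Status.CONFIRMED and _qualifies(m, concept)
        ]
        probable = [
            m for m in findings if m.status is Status.PROBABLE and _qualifies(m, concept)
        ]
        if confirmed:
            labels[concept] = Label.POSITIVE
            evidence.extend(confirmed)
        elif probable:
            labels[concept] = Label.INDETERMINATE
            evidence.extend(probable)
        else:
            labels[concept] = Label.NEGATIVE
            evidence.extend(m for m in findings if m.status is Status.NEGATED)
    return DocumentClassification(
        report_id=report_id,
        sbi_label=labels[Concept.SBI],
        wmd_label=labels[Concept.WMD],
        evidence=tuple(evidence),
    )


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

_HYPHEN_WRAP = re.compile(r"(\w)-[ \t]*\n[ \t]*(\w)")


def rejoin_hyphenated_linebreaks(text: str) -> str:
    """Rejoin words hyphenated across a line wrap ("infarc-\\ntion")."""
    return _HYPHEN_WRAP.sub(r"\1\2", text)


def extract_mentions(
    report: Report,
    lexicon: Sequence[LexiconEntry] | None = None,
    cues: Sequence[ContextCue] | None = None,
) -> list[ConceptMention]:
    """Run segmentation, section detection, matching and context assignment
    for one report; returns all context-resolved mentions."""
    if lexicon is None:
        lexicon = default_lexicon()
    if cues is None:
        cues = default_cues()
    text = rejoin_hyphenated_linebreaks(report.text)
    sentences = detect_sections(segment_sentences(text, report.report_id), text)
    resolved: list[ConceptMention] = []
    for sentence in sentences:
        raw = match_concepts(sentence, lexicon)
        resolved.extend(assign_context(m, sentence, raw, cues) for m in raw)
    return resolved


def classify_report(
    report: Report,
    lexicon: Sequence[LexiconEntry] | None = None,
    impression_only: bool = False,
    cues: Sequence[ContextCue] | None = None,
) -> DocumentClassification:
    """Deterministic end-to-end rule classification of one report."""
    mentions = extract_mentions(report, lexicon, cues)
    return summarize_document(report.report_id, mentions, impression_only)
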