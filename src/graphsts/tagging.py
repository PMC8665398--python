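"""Concept mention detection for sentences.

Two sources of mentions are supported: a built-in dictionary tagger
(case-insensitive, token-boundary, longest-match-first, left-to-right,
non-overlapping — the usual gazetteer semantics) and a parser for the
tab-separated export format of an external concept tagger, which carries the
same content a UMLS-style tagger emits per mention: character span, matched
text, CUI, preferred name and semantic types.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import RecordFormatError

__all__ = [
    "LexiconEntry", "ConceptMention", "Lexicon",
    "build_lexicon", "read_lexicon_file", "write_lexicon_file",
    "tag_sentence", "parse_tagger_output", "write_tagger_output",
]

_TOKEN_RE = re.compile(r"[0-9a-z]+")


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    cui: str
    preferred_name: str
    semantic_types: tuple[str, ...] = ()

    def __post_init__(self):
        normalized = " ".join(self.surface.lower().split())
        object.__setattr__(self, "surface", normalized)


@dataclass(frozen=True)
class ConceptMention:
    """A tagged span; offsets are 0-based half-open character positions."""
    start: int
    end: int
    matched_text: str
    cui: str
    preferred_name: str
    semantic_types: tuple[str, ...] = ()

    def validate(self, sentence: str | None = None):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if sentence is not None:
            if self.end > len(sentence):
                raise ValueError("span extends past sentence end")
            if sentence[self.start:self.end] != self.matched_text:
                raise ValueError("matched_text does not equal the sentence "
                                 "slice")


@dataclass
class Lexicon:
    """Longest-match index: token tuple -> entry, plus the maximum surface
    length in tokens so the tagger knows how far to look ahead."""
    by_tokens: dict[tuple[str, ...], LexiconEntry] = field(
        default_factory=dict)
    max_tokens: int = 0


def build_lexicon(entries: list[LexiconEntry]) -> Lexicon:
    """Index entries by their token sequence; duplicate surfaces keep the
    first entry."""
    lex = Lexicon()
    for entry in entries:
        if not entry.surface:
            continue
        tokens = tuple(_TOKEN_RE.findall(entry.surface))
        if not tokens or tokens in lex.by_tokens:
            continue
        lex.by_tokens[tokens] = entry
        lex.max_tokens = max(lex.max_tokens, len(tokens))
    return lex


def tag_sentence(sentence: str, lexicon: Lexicon) -> list[ConceptMention]:
    """Greedy left-to-right longest-match tagging over token boundaries.

    Tokens are maximal alphanumeric runs of the lowercased sentence, so
    matching is case-insensitive and punctuation never splits a match span's
    identity — the mention's character span covers the original text from
    the first to the last matched token.
    """
    lowered = sentence.lower()
    tokens = [(m.group(), m.start(), m.end())
              for m in _TOKEN_RE.finditer(lowered)]
    mentions: list[ConceptMention] = []
    i = 0
    while i < len(tokens):
        best_len = 0
        best_entry = None
        limit = min(lexicon.max_tokens, len(tokens) - i)
        for length in range(limit, 0, -1):
            key = tuple(t[0] for t in tokens[i:i + length])
            entry = lexicon.by_tokens.get(key)
            if entry is not None:
                best_len, best_entry = length, entry
                break
        if best_entry is None:
            i += 1
            continue
        start = tokens[i][1]
        end = tokens[i + best_len - 1][2]
        mentions.append(ConceptMention(
            start=start, end=end, matched_text=sentence[start:end],
            cui=best_entry.cui, preferred_name=best_entry.preferred_name,
            semantic_types=best_entry.semantic_types))
        i += best_len
    return mentions


# -- lexicon file: "surface TAB cui TAB preferred_name TAB semtype[;...]" --


def read_lexicon_file(path) -> list[LexiconEntry]:
    entries: list[LexiconEntry] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise RecordFormatError(path, line_no,
                                        "expected 4 tab-separated columns")
            semtypes = tuple(parts[3].split(";")) if parts[3] else ()
            entries.append(LexiconEntry(parts[0], parts[1], parts[2],
                                        semtypes))
    return entries


def write_lexicon_file(entries: list[LexiconEntry], path):
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(f"{e.surface}\t{e.cui}\t{e.preferred_name}\t"
                     f"{';'.join(e.semantic_types)}\n")


# -- external tagger export: one mention per row -------------------------
# sentence_id TAB start TAB end TAB matched_text TAB cui TAB preferred_name
# TAB semtype[;semtype...]


def parse_tagger_output(path, sentences: dict[str, str] | None = None
                        ) -> dict[str, list[ConceptMention]]:
    """Group mention rows by sentence id.  When ``sentences`` supplies the
    text for an id, each mention is validated against it."""
    grouped: dict[str, list[ConceptMention]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise RecordFormatError(path, line_no,
                                        "expected 7 tab-separated columns")
            sid, start_s, end_s, text, cui, name, semtypes_s = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise RecordFormatError(path, line_no,
                                        "start/end must be integers") from None
            mention = ConceptMention(
                start=start, end=end, matched_text=text, cui=cui,
                preferred_name=name,
                semantic_types=tuple(semtypes_s.split(";")) if semtypes_s
                else ())
            try:
                mention.validate(sentences.get(sid) if sentences else None)
            except ValueError as exc:
                raise RecordFormatError(path, line_no, str(exc)) from None
            grouped.setdefault(sid, []).append(mention)
    for mentions in grouped.values():
        mentions.sort(key=lambda m: m.start)
    return grouped


def write_tagger_output(grouped: dict[str, list[ConceptMention]], path):
    with open(path, "w", encoding="utf-8") as fh:
        for sid in grouped:
            for m in grouped[sid]:
                fh.write(f"{sid}\t{m.start}\t{m.end}\t{m.matched_text}\t"
                         f"{m.cui}\t{m.preferred_name}\t"
                         f"{';'.join(m.semantic_types)}\n")
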