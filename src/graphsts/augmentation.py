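"""Dataset records and knowledge-based data augmentation.

Two augmentation rules are implemented.  The first appends, to each sentence,
the preferred names and/or semantic types of its tagged concepts — an
abbreviation like "pacu" then carries its expansion "postoperative anesthesia
care unit (PACU)" into the text the encoder sees.  The second doubles the
dataset by adding a copy of every pair with the two sentences swapped, a
cheap way to signal that the scoring task is symmetric in sentence order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import RecordFormatError
from .tagging import ConceptMention

__all__ = [
    "SentenceRecord", "CATEGORIES",
    "augment_with_concepts", "reverse_pair_double",
    "read_dataset", "write_dataset",
]

CATEGORIES = ("status", "education", "meds", "miscellaneous")


@dataclass(frozen=True)
class SentenceRecord:
    """A sentence pair scored on the 0-5 similarity rubric; the score may be
    absent on inference-only input and the category label is optional."""
    record_id: str
    text1: str
    text2: str
    score: float | None = None
    category: str | None = None

    def __post_init__(self):
        if self.score is not None and not 0.0 <= self.score <= 5.0:
            raise ValueError(f"score {self.score} outside [0, 5]")
        if self.category is not None and self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _appended_block(mentions: list[ConceptMention], use_names: bool,
                    use_semtypes: bool) -> list[str]:
    parts: list[str] = []
    if use_names:
        seen: set[str] = set()
        for m in mentions:
            if m.preferred_name and m.preferred_name not in seen:
                seen.add(m.preferred_name)
                parts.append(m.preferred_name)
    if use_semtypes:
        seen = set()
        for m in mentions:
            for st in m.semantic_types:
                if st and st not in seen:
                    seen.add(st)
                    parts.append(st)
    return parts


def augment_with_concepts(record: SentenceRecord,
                          mentions1: list[ConceptMention],
                          mentions2: list[ConceptMention],
                          use_names: bool = True,
                          use_semtypes: bool = False) -> SentenceRecord:
    """Append concept preferred names (then semantic types) to each sentence.

    Appended strings are space-joined in mention order, duplicates within one
    sentence dropped keeping the first occurrence.  With both flags off the
    record is returned unchanged.
    """
    if not (use_names or use_semtypes):
        return record

    def extend(text: str, mentions: list[ConceptMention]) -> str:
        block = _appended_block(mentions, use_names, use_semtypes)
        return text + " " + " ".join(block) if block else text

    return replace(record,
                   text1=extend(record.text1, mentions1),
                   text2=extend(record.text2, mentions2))


def reverse_pair_double(dataset: list[SentenceRecord]
                        ) -> list[SentenceRecord]:
    """Originals followed by swapped copies; scores and categories kept,
    swapped-copy ids suffixed with ``_rev``."""
    reversed_copies = [
        replace(r, record_id=r.record_id + "_rev",
                text1=r.text2, text2=r.text1)
        for r in dataset
    ]
    return list(dataset) + reversed_copies


# -- dataset TSV: "text1 TAB text2 TAB score[ TAB category]" ---------------


def read_dataset(path) -> list[SentenceRecord]:
    """Rows become records with ids ``r0001``, ``r0002``, ... in file order.
    An empty score field marks an unscored inference row."""
    records: list[SentenceRecord] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) not in (3, 4):
                raise RecordFormatError(path, line_no,
                                        "expected 3 or 4 tab-separated "
                                        "columns")
            score: float | None = None
            if parts[2] != "":
                try:
                    score = float(parts[2])
                except ValueError:
                    raise RecordFormatError(path, line_no,
                                            "score must be numeric") from None
            category = parts[3] if len(parts) == 4 and parts[3] else None
            try:
                records.append(SentenceRecord(
                    record_id=f"r{len(records) + 1:04d}",
                    text1=parts[0], text2=parts[1],
                    score=score, category=category))
            except ValueError as exc:
                raise RecordFormatError(path, line_no, str(exc)) from None
    return records


def write_dataset(records: list[SentenceRecord], path):
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            score = "" if r.score is None else format(r.score, "g")
            if r.category is not None:
                fh.write(f"{r.text1}\t{r.text2}\t{score}\t{r.category}\n")
            else:
                fh.write(f"{r.text1}\t{r.text2}\t{score}\n")
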