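"""Free-text thought reports: ingestion, sentence segmentation and
cue-word filtering.

Reports are the typed recollections a participant enters after a session
(already cleaned to thought content only — stripping meta-commentary is the
caller's responsibility).  The unit of semantic analysis is the sentence,
so reports are split deterministically on terminal punctuation, and before
computing prompt centrality every occurrence of the cue word itself is
removed so that literal cue mentions cannot inflate similarity to the cue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .session import Condition, CueObject

__all__ = [
    "ThoughtReport",
    "SentenceSet",
    "segment_sentences",
    "filter_prompt_words",
    "read_reports_table",
    "read_reports_dir",
]

# Abbreviations whose trailing period must not end a sentence.
_ABBREVIATIONS = {
    "mr", "mrs", "ms", "dr", "prof", "st", "vs", "etc", "e.g", "i.e",
    "eg", "ie", "approx", "jan", "feb", "mar", "apr", "jun", "jul", "aug",
    "sep", "sept", "oct", "nov", "dec", "a.m", "p.m",
}

_CUE_TOKENS = {
    CueObject.FORK: ("fork", "forks"),
    CueObject.TREE: ("tree", "trees"),
}


@dataclass(frozen=True)
class ThoughtReport:
    participant_id: str
    condition: Condition
    cue_object: CueObject
    text: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        object.__setattr__(self, "cue_object", CueObject(self.cue_object))


@dataclass(frozen=True)
class SentenceSet:
    """Ordered, non-empty sentences with a link back to their source report."""

    sentences: tuple[str, ...]
    source: Optional[ThoughtReport] = None

    def __post_init__(self) -> None:
        if any(not s.strip() for s in self.sentences):
            raise ValueError("SentenceSet may not contain empty sentences")

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)


def segment_sentences(text: str, source: ThoughtReport | None = None) -> SentenceSet:
    """Split ``text`` into sentences on terminal punctuation (. ! ?).

    Rule-based and deterministic: a period following a known abbreviation
    does not terminate a sentence; trailing fragments without terminal
    punctuation count as a final sentence; empty fragments are dropped.
    """
    if not text or not text.strip():
        return SentenceSet((), source)
    sentences: list[str] = []
    buf: list[str] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        buf.append(ch)
        if ch in ".!?":
            # absorb runs of terminal punctuation ("?!", "...")
            while i + 1 < n and text[i + 1] in ".!?":
                i += 1
                buf.append(text[i])
            frag = "".join(buf)
            last_word = re.findall(r"[\w.]+(?=[.!?]+$)", frag.strip())
            is_abbrev = (
                ch == "."
                and last_word
                and last_word[-1].lower().rstrip(".") in _ABBREVIATIONS
            )
            if not is_abbrev:
                if frag.strip():
                    sentences.append(frag.strip())
                buf = []
        i += 1
    tail = "".join(buf).strip()
    if tail:
        sentences.append(tail)
    return SentenceSet(tuple(sentences), source)


def filter_prompt_words(s: SentenceSet, cue_object: CueObject) -> SentenceSet:
    """Remove every token equal to the cue word or its plural
    (case-insensitive) from every sentence; drop sentences emptied by the
    removal.  Order is preserved; the operation is idempotent."""
    cue_object = CueObject(cue_object)
    targets = set(_CUE_TOKENS[cue_object])
    pattern = re.compile(
        r"\b(" + "|".join(targets) + r")\b", flags=re.IGNORECASE
    )
    kept: list[str] = []
    for sent in s.sentences:
        stripped = pattern.sub("", sent)
        stripped = re.sub(r"\s+", " ", stripped).strip()
        # a sentence that is only punctuation after cue removal is "empty"
        if re.search(r"\w", stripped):
            kept.append(stripped)
    return SentenceSet(tuple(kept), s.source)


# ---------------------------------------------------------------------------
# Readers


def read_reports_table(path) -> list[ThoughtReport]:
    """Read reports from a delimited table with columns
    ``participant_id, condition, cue_object, text`` (CSV or TSV by suffix)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"participant_id", "condition", "cue_object", "text"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reports table missing columns: {sorted(missing)}")
    return [
        ThoughtReport(
            participant_id=row.participant_id,
            condition=Condition(row.condition),
            cue_object=CueObject(row.cue_object),
            text=row.text,
        )
        for row in df.itertuples()
    ]


def read_reports_dir(directory) -> list[ThoughtReport]:
    """Read one report per ``*.txt`` file named
    ``<participant_id>__<condition>__<cue_object>.txt``."""
    reports = []
    for path in sorted(Path(directory).glob("*.txt")):
        parts = path.stem.split("__")
        if len(parts) != 3:
            raise ValueError(
                f"{path.name}: expected <participant>__<condition>__<cue>.txt"
            )
        pid, cond, cue = parts
        reports.append(
            ThoughtReport(pid, Condition(cond), CueObject(cue), path.read_text())
        )
    return reports
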