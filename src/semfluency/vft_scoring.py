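"""Scoring of verbal-fluency transcripts in a semantic space.

A transcript is the ordered sequence of answers a participant produced in
the 60-second category fluency task (here: animal naming).  Scoring first
NA-codes each position — answers that are disallowed (category names,
breeds), later repetitions of an earlier answer, or out of the space's
vocabulary — and then computes three statistics over the remaining valid
positions:

* ``n_correct`` — the number of valid answers;
* ``mean_vector_length`` — the mean Euclidean norm of the valid answers'
  word vectors (order-free; tracks word unusualness);
* ``mean_cosine_similarity`` — the mean cosine over *positionally adjacent*
  pairs where both members are valid.  An NA between two valid words breaks
  the pair: the flanking words are never bridged.

Participants with no valid word (for the length statistic) or no valid
adjacent pair (for the coherence statistic) have an undefined score; this is
a hard, participant-labelled error so such rows can be reported and excluded
from cohort tables.
"""

from __future__ import annotations

import csv
import enum
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from semfluency.semantic_space import SemanticSpace, normalize_token

__all__ = [
    "Status",
    "Transcript",
    "CodedSequence",
    "FluencyScores",
    "UndefinedScoreError",
    "code_sequence",
    "count_correct",
    "mean_vector_length",
    "mean_adjacent_cosine",
    "score_transcript",
    "read_transcripts_csv",
    "write_scores_csv",
    "load_disallowed",
]


class Status(enum.Enum):
    """Per-position validity code after NA-coding."""

    VALID = "VALID"
    NA_OOV = "NA_OOV"
    NA_DUPLICATE = "NA_DUPLICATE"
    NA_DISALLOWED = "NA_DISALLOWED"


@dataclass(frozen=True)
class Transcript:
    """Ordered raw answers of one participant; may be empty."""

    participant_id: str
    tokens: tuple[str, ...]


@dataclass(frozen=True)
class CodedSequence:
    """A transcript after normalization and NA-coding."""

    participant_id: str
    entries: tuple[tuple[str, Status], ...]

    def count(self, status: Status) -> int:
        return sum(1 for _, s in self.entries if s is status)


@dataclass(frozen=True)
class FluencyScores:
    """Per-participant fluency statistics."""

    participant_id: str
    n_correct: int
    mean_vector_length: float
    mean_cosine_similarity: float
    n_valid_pairs: int
    n_oov: int = 0
    n_duplicate: int = 0
    n_disallowed: int = 0


class UndefinedScoreError(ValueError):
    """A fluency statistic is undefined (no valid words / no valid pair)."""

    def __init__(self, participant_id: str, message: str):
        self.participant_id = participant_id
        super().__init__(f"participant {participant_id!r}: {message}")


def code_sequence(
    transcript: Transcript,
    space: SemanticSpace,
    disallowed: Iterable[str] = (),
    duplicates: Literal["later", "all"] = "later",
) -> CodedSequence:
    """NA-code a transcript against a semantic space.

    Checks are applied in order disallowed -> duplicate -> out-of-vocabulary.
    With ``duplicates="later"`` (default) the first occurrence of a repeated
    answer stays valid and later occurrences are NA; ``"all"`` marks every
    occurrence of a repeated answer (the strict reading of the repetition
    rule).  Tokens that normalize to the empty string are out of vocabulary.
    """
    disallowed_set = {normalize_token(t) for t in disallowed}
    norm = [normalize_token(t) for t in transcript.tokens]
    multiplicity = Counter(norm)
    seen: set[str] = set()
    entries: list[tuple[str, Status]] = []
    for tok in norm:
        if tok and tok in disallowed_set:
            status = Status.NA_DISALLOWED
        elif tok in seen if duplicates == "later" else (tok and multiplicity[tok] > 1):
            status = Status.NA_DUPLICATE
        elif not tok or tok not in space:
            status = Status.NA_OOV
        else:
            status = Status.VALID
        if tok:
            seen.add(tok)
        entries.append((tok, status))
    return CodedSequence(transcript.participant_id, tuple(entries))


def count_correct(coded: CodedSequence) -> int:
    """Number of valid (correct) answers."""
    return coded.count(Status.VALID)


def mean_vector_length(coded: CodedSequence, space: SemanticSpace) -> float:
    """Mean Euclidean norm over valid answers' vectors."""
    norms = [
        np.linalg.norm(space.vector(tok))
        for tok, status in coded.entries
        if status is Status.VALID
    ]
    if not norms:
        raise UndefinedScoreError(
            coded.participant_id, "mean vector length undefined (no valid words)"
        )
    return float(np.mean(norms))


def mean_adjacent_cosine(
    coded: CodedSequence, space: SemanticSpace
) -> tuple[float, int]:
    """Mean cosine over adjacent pairs with both members valid.

    Returns ``(mean, n_valid_pairs)``.  Pairs are strictly positional: a
    pair is counted only when positions i and i+1 are both valid.
    """
    cosines: list[float] = []
    for (tok_a, st_a), (tok_b, st_b) in zip(coded.entries, coded.entries[1:]):
        if st_a is Status.VALID and st_b is Status.VALID:
            va = space.vector(tok_a)
            vb = space.vector(tok_b)
            cosines.append(
                float(np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb)))
            )
    if not cosines:
        raise UndefinedScoreError(
            coded.participant_id,
            "mean adjacent cosine undefined (no valid adjacent pair)",
        )
    return float(np.mean(cosines)), len(cosines)


def score_transcript(
    transcript: Transcript,
    space: SemanticSpace,
    disallowed: Iterable[str] = (),
    duplicates: Literal["later", "all"] = "later",
) -> FluencyScores:
    """Code a transcript and bundle the three fluency statistics."""
    coded = code_sequence(transcript, space, disallowed, duplicates)
    mean_cos, n_pairs = mean_adjacent_cosine(coded, space)
    return FluencyScores(
        participant_id=transcript.participant_id,
        n_correct=count_correct(coded),
        mean_vector_length=mean_vector_length(coded, space),
        mean_cosine_similarity=mean_cos,
        n_valid_pairs=n_pairs,
        n_oov=coded.count(Status.NA_OOV),
        n_duplicate=coded.count(Status.NA_DUPLICATE),
        n_disallowed=coded.count(Status.NA_DISALLOWED),
    )


def read_transcripts_csv(path: str | Path) -> list[Transcript]:
    """Read transcripts from CSV with columns participant_id, position, token.

    Positions are 1-based within participant; rows may arrive in any order.
    Participants appear in order of first occurrence.
    """
    per_participant: dict[str, list[tuple[int, str]]] = {}
    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"participant_id", "position", "token"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"transcript CSV must have columns {sorted(required)}")
        for row in reader:
            pid = row["participant_id"]
            per_participant.setdefault(pid, []).append(
                (int(row["position"]), row["token"])
            )
    transcripts = []
    for pid, items in per_participant.items():
        items.sort(key=lambda it: it[0])
        transcripts.append(Transcript(pid, tuple(tok for _, tok in items)))
    return transcripts


_SCORE_COLUMNS = (
    "participant_id",
    "n_correct",
    "mean_vector_length",
    "mean_cosine_similarity",
    "n_valid_pairs",
    "n_oov",
    "n_duplicate",
    "n_disallowed",
)


def write_scores_csv(scores: Sequence[FluencyScores], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SCORE_COLUMNS)
        for s in scores:
            writer.writerow(
                [
                    s.participant_id,
                    s.n_correct,
                    repr(s.mean_vector_length),
                    repr(s.mean_cosine_similarity),
                    s.n_valid_pairs,
                    s.n_oov,
                    s.n_duplicate,
                    s.n_disallowed,
                ]
            )


def load_disallowed(path: str | Path) -> set[str]:
    """Load a disallowed-word lexicon (one token per line, '#' comments)."""
    out = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(normalize_token(line))
    return out
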