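"""Tagged utterance corpora: reading, validation, stratification, balancing.

The unit of analysis throughout the package is the *utterance*: an ordered
sequence of (surface, category) tokens produced by one speaker, carrying an
optional speaker age in months. Corpora are exchanged as a one-token-per-line
TSV with columns ``utterance_id, position, surface, pos, speaker_role,
age_months`` (header row, UTF-8, age may be empty). Utterance boundaries are
reconstructed wherever the utterance id changes; token positions are 1-based
and consecutive within an utterance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Token",
    "Utterance",
    "TaggedCorpus",
    "CategoryLexicon",
    "CorpusFormatError",
    "EmptyCorpusError",
    "InsufficientDataError",
    "read_tagged_corpus",
    "write_tagged_corpus",
    "stratify_by_age",
    "balance_cohorts",
    "truncate_positions",
    "load_lexicon",
    "default_lexicon",
]

TSV_COLUMNS = ["utterance_id", "position", "surface", "pos", "speaker_role", "age_months"]


class CorpusFormatError(ValueError):
    """Malformed tagged-utterance file (wrong column count, bad field)."""


class EmptyCorpusError(ValueError):
    """A corpus file or corpus object with no utterances."""


class InsufficientDataError(ValueError):
    """A corpus is too small for the requested operation."""


@dataclass(frozen=True)
class Token:
    """One tagged word occurrence at a 1-based utterance position."""

    surface: str
    category: str
    position: int

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")
        if self.position < 1:
            raise ValueError(f"token position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class Utterance:
    """An ordered token sequence with speaker metadata.

    ``age_months`` is absent (None) for corpora without speaker age, e.g.
    subtitle-derived adult speech.
    """

    tokens: tuple[Token, ...]
    speaker_role: str = "child"
    age_months: float | None = None

    def __post_init__(self) -> None:
        if len(self.tokens) < 1:
            raise ValueError("utterance must contain at least one token")
        for i, tok in enumerate(self.tokens, start=1):
            if tok.position != i:
                raise ValueError(
                    f"token positions must be consecutive from 1; "
                    f"expected {i}, got {tok.position}"
                )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    @property
    def categories(self) -> list[str]:
        return [t.category for t in self.tokens]


@dataclass(frozen=True)
class TaggedCorpus:
    """An age-cohort corpus: ordered utterances under one cohort label."""

    cohort_label: str
    utterances: tuple[Utterance, ...]

    def __post_init__(self) -> None:
        if not self.cohort_label:
            raise ValueError("cohort_label must be non-empty")

    @property
    def token_count(self) -> int:
        return sum(len(u) for u in self.utterances)

    @property
    def n_utterances(self) -> int:
        return len(self.utterances)

    def __len__(self) -> int:
        return len(self.utterances)

    def __iter__(self):
        return iter(self.utterances)


@dataclass(frozen=True)
class CategoryLexicon:
    """Named word lists for target categories (pronouns, verbs, ...)."""

    categories: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for name, words in self.categories.items():
            if not words:
                raise ValueError(f"category {name!r} has an empty word list")
            if len(set(words)) != len(words):
                dupes = sorted({w for w in words if list(words).count(w) > 1})
                raise ValueError(f"category {name!r} has duplicate words: {dupes}")

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.categories[name]

    def __contains__(self, name: str) -> bool:
        return name in self.categories

    def items(self):
        return self.categories.items()

    def all_words(self) -> list[str]:
        out: list[str] = []
        for words in self.categories.values():
            out.extend(words)
        return out


def _parse_age(text: str, line_no: int) -> float | None:
    if text == "":
        return None
    try:
        age = float(text)
    except ValueError as exc:
        raise CorpusFormatError(f"line {line_no}: bad age_months {text!r}") from exc
    if age < 0:
        raise CorpusFormatError(f"line {line_no}: negative age_months {text!r}")
    return age


def read_tagged_corpus(path: str | Path, cohort_label: str) -> TaggedCorpus:
    """Read a tagged-utterance TSV into a :class:`TaggedCorpus`.

    Utterance boundaries fall at changes of the ``utterance_id`` column;
    surfaces are lowercased on read. Raises :class:`CorpusFormatError` with the
    offending line number on malformed rows, :class:`EmptyCorpusError` on a
    file with no token rows.
    """
    path = Path(path)
    utterances: list[Utterance] = []
    cur_id: str | None = None
    cur_tokens: list[Token] = []
    cur_role = "child"
    cur_age: float | None = None

    def flush() -> None:
        if cur_tokens:
            utterances.append(
                Utterance(tokens=tuple(cur_tokens), speaker_role=cur_role, age_months=cur_age)
            )

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise EmptyCorpusError(f"{path}: empty file")
        if [h.strip() for h in header] != TSV_COLUMNS:
            raise CorpusFormatError(
                f"{path}: line 1: expected header {TSV_COLUMNS}, got {header}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(TSV_COLUMNS):
                raise CorpusFormatError(
                    f"{path}: line {line_no}: expected {len(TSV_COLUMNS)} columns, "
                    f"got {len(row)}"
                )
            utt_id, pos_s, surface, pos_tag, role, age_s = row
            try:
                position = int(pos_s)
            except ValueError as exc:
                raise CorpusFormatError(
                    f"{path}: line {line_no}: bad position {pos_s!r}"
                ) from exc
            if utt_id != cur_id:
                flush()
                cur_id = utt_id
                cur_tokens = []
                cur_role = role
                cur_age = _parse_age(age_s, line_no)
            cur_tokens.append(
                Token(surface=surface.lower(), category=pos_tag, position=position)
            )
    flush()
    if not utterances:
        raise EmptyCorpusError(f"{path}: no token rows")
    return TaggedCorpus(cohort_label=cohort_label, utterances=tuple(utterances))


def _format_age(age: float | None) -> str:
    if age is None:
        return ""
    if float(age).is_integer():
        return str(int(age))
    return repr(float(age))


def write_tagged_corpus(corpus: TaggedCorpus, path: str | Path) -> None:
    """Write the canonical TSV form (utterance ids numbered from 1)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for uid, utt in enumerate(corpus.utterances, start=1):
            age = _format_age(utt.age_months)
            for tok in utt.tokens:
                writer.writerow(
                    [uid, tok.position, tok.surface, tok.category, utt.speaker_role, age]
                )


def stratify_by_age(
    corpus: TaggedCorpus, bounds: Sequence[tuple[float, float, str]]
) -> list[TaggedCorpus]:
    """Split a corpus into age bands ``[low, high)`` given in months.

    Bands may overlap (an utterance can belong to several); each utterance
    must carry ``age_months`` when any bounds are given.
    """
    if not bounds:
        return []
    for utt in corpus.utterances:
        if utt.age_months is None:
            raise ValueError("stratify_by_age requires age_months on every utterance")
    out: list[TaggedCorpus] = []
    for low, high, label in bounds:
        members = tuple(
            u for u in corpus.utterances if low <= u.age_months < high  # type: ignore[operator]
        )
        out.append(TaggedCorpus(cohort_label=label, utterances=members))
    return out


def balance_cohorts(
    corpora: Sequence[TaggedCorpus], target_tokens: int, seed: int
) -> list[TaggedCorpus]:
    """Subsample whole utterances so every cohort has ~``target_tokens`` tokens.

    Utterances are sampled uniformly without replacement until the running
    token count first reaches the target, then restored to their original
    order; sequences are never split. The resulting count lies in
    ``[target_tokens, target_tokens + max_utterance_length)``.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(corpora))
    out: list[TaggedCorpus] = []
    for corpus, child in zip(corpora, child_seeds):
        if corpus.token_count < target_tokens:
            raise InsufficientDataError(
                f"cohort {corpus.cohort_label!r} has {corpus.token_count} tokens "
                f"< target {target_tokens}"
            )
        rng = np.random.default_rng(child)
        order = rng.permutation(len(corpus.utterances))
        lengths = np.array([len(corpus.utterances[i]) for i in order])
        cum = np.cumsum(lengths)
        n_take = int(np.searchsorted(cum, target_tokens) + 1)
        chosen = np.sort(order[:n_take])
        out.append(
            TaggedCorpus(
                cohort_label=corpus.cohort_label,
                utterances=tuple(corpus.utterances[i] for i in chosen),
            )
        )
    return out


def truncate_positions(
    corpus: TaggedCorpus, max_position: int
) -> tuple[TaggedCorpus, float]:
    """Drop tokens beyond ``max_position``; returns (corpus, removed fraction).

    Utterances emptied entirely cannot occur (max_position >= 1 keeps the
    first token), but the guard is kept for safety.
    """
    if max_position < 1:
        raise ValueError(f"max_position must be >= 1, got {max_position}")
    total = corpus.token_count
    kept_utts: list[Utterance] = []
    kept_tokens = 0
    for utt in corpus.utterances:
        toks = utt.tokens[:max_position]
        if toks:
            kept_tokens += len(toks)
            kept_utts.append(
                Utterance(tokens=toks, speaker_role=utt.speaker_role, age_months=utt.age_months)
            )
    removed_fraction = 0.0 if total == 0 else (total - kept_tokens) / total
    return (
        TaggedCorpus(cohort_label=corpus.cohort_label, utterances=tuple(kept_utts)),
        removed_fraction,
    )


def load_lexicon(path: str | Path) -> CategoryLexicon:
    """Load a two-column TSV ``category<TAB>word`` into a lexicon."""
    path = Path(path)
    cats: dict[str, list[str]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for line_no, row in enumerate(reader, start=1):
            if not row:
                continue
            if len(row) != 2:
                raise CorpusFormatError(
                    f"{path}: line {line_no}: expected 2 columns, got {len(row)}"
                )
            cat, word = row[0].strip(), row[1].strip().lower()
            cats.setdefault(cat, [])
            if word in cats[cat]:
                raise ValueError(
                    f"{path}: line {line_no}: duplicate word {word!r} in category {cat!r}"
                )
            cats[cat].append(word)
    return CategoryLexicon(categories={c: tuple(ws) for c, ws in cats.items()})


#: Category sizes follow the study design where stated (pronouns 7, verbs 30,
#: numbers 12); the open-class lists (names, food, time, kinship, color) are
#: synthetic placeholders standing in for supplementary word lists.
_DEFAULT_LEXICON: dict[str, tuple[str, ...]] = {
    "pronouns": ("i", "you", "he", "she", "it", "we", "they"),
    "verbs": (
        "go", "get", "want", "see", "know", "like", "make", "come", "put", "look",
        "take", "eat", "play", "say", "think", "give", "tell", "find", "help", "read",
        "run", "sit", "open", "hold", "throw", "wash", "draw", "sleep", "jump", "sing",
    ),
    "numbers": (
        "one", "two", "three", "four", "five", "six",
        "seven", "eight", "nine", "ten", "eleven", "twelve",
    ),
    "names": ("alex", "sam", "max", "mia", "ben", "lily", "jack", "emma", "noah", "ruby"),
    "food": ("apple", "banana", "milk", "juice", "bread", "cookie", "cheese", "egg",
             "soup", "rice"),
    "time": ("today", "tomorrow", "yesterday", "morning", "night", "week", "minute", "hour"),
    "kinship": ("mommy", "daddy", "grandma", "grandpa", "sister", "brother", "aunt", "uncle"),
    "color": ("red", "blue", "green", "yellow", "orange", "purple", "pink", "black"),
}


def default_lexicon() -> CategoryLexicon:
    """The built-in target-category lexicon (see module docstring caveats)."""
    return CategoryLexicon(categories=dict(_DEFAULT_LEXICON))
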