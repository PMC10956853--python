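"""Synthetic finding-sentence grammar: content sets, surface realization,
inversion and a membership checker.

The text-generation component is trained on (content set → sentence) pairs.
Clinically these come from edited radiology reports; here a small English
grammar plays that role.  A *content set* is an unordered set of tokens: the
special placeholders ``<SEG>`` (bronchopulmonary segment) and ``<SIZE>``
(major axis), exactly one opacity token, and any number of binary finding
tokens.  Each content token has one or more surface realizations; sentences
are built from a small set of templates.  The grammar is designed to be
*invertible*: every generated sentence maps back to exactly its content set
by phrase matching, which is what makes automatic adequacy evaluation
possible.  A sentence is *grammatical* iff it is a member of the language
(some template + realization choice reproduces it verbatim).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .findings import BINARY_CLASSES, OPACITY_CLASSES

SEG_TOKEN = "<SEG>"
SIZE_TOKEN = "<SIZE>"

#: canonical content ordering: placeholders, opacity, then the finding-list
#: category order (shape, margin, internal, external)
CONTENT_ORDER: tuple[str, ...] = (SEG_TOKEN, SIZE_TOKEN) + OPACITY_CLASSES + BINARY_CLASSES

FINDING_TOKENS = OPACITY_CLASSES + BINARY_CLASSES

DEFAULT_LEXICON: dict[str, list[str]] = {
    "solid": ["solid"],
    "part_solid": ["part-solid"],
    "pure_ggo": ["pure ground-glass", "nonsolid"],
    "irregular_shape": ["an irregular shape"],
    "ill_defined": ["an ill-defined margin", "a poorly defined margin"],
    "irregular_edge": ["an irregular edge"],
    "spiculated": ["spiculation", "a spiculated margin"],
    "lobulated": ["lobulation", "a lobulated contour"],
    "ragged": ["a ragged border"],
    "polygonal": ["a polygonal outline"],
    "air_bronchogram": ["an air bronchogram"],
    "cavity": ["cavitation", "an internal cavity"],
    "calcification": ["calcification", "a calcified focus"],
    "fat": ["internal fat"],
    "pleural_contact": ["pleural contact", "contact with the pleura"],
    "pleural_indentation": ["pleural indentation"],
}

__all__ = [
    "SEG_TOKEN",
    "SIZE_TOKEN",
    "CONTENT_ORDER",
    "DEFAULT_LEXICON",
    "GrammarConfig",
    "content_set",
    "order_contents",
    "realize_sentence",
    "extract_contents",
    "is_grammatical",
    "make_description_corpus",
    "split_corpus",
]


@dataclass(frozen=True)
class GrammarConfig:
    """Lexicon (token → surface realizations), templates and seed."""

    lexicon: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_LEXICON.items()}
    )
    n_templates: int = 2
    max_findings: int = 4
    seed: int = 0

    def __post_init__(self):
        for token in FINDING_TOKENS:
            if token not in self.lexicon or len(self.lexicon[token]) == 0:
                raise ValueError(f"unrealizable content token: {token!r}")
        object.__setattr__(
            self, "lexicon", {k: tuple(v) for k, v in self.lexicon.items()}
        )

    def capacity(self) -> int:
        """Number of distinct content sets the grammar can express."""
        n_bin = len(BINARY_CLASSES)
        combos = sum(math.comb(n_bin, k) for k in range(self.max_findings + 1))
        return len(OPACITY_CLASSES) * combos


def content_set(opacity: str, *findings: str) -> frozenset[str]:
    """Build a content set: placeholders + one opacity + binary findings."""
    if opacity not in OPACITY_CLASSES:
        raise ValueError(f"unknown opacity token {opacity!r}")
    bad = set(findings) - set(BINARY_CLASSES)
    if bad:
        raise ValueError(f"unknown finding tokens: {sorted(bad)}")
    return frozenset({SEG_TOKEN, SIZE_TOKEN, opacity, *findings})


def order_contents(contents: frozenset[str] | set[str]) -> list[str]:
    """Canonical ordering of a content set (set semantics in, list out)."""
    bad = set(contents) - set(CONTENT_ORDER)
    if bad:
        raise ValueError(f"unknown content tokens: {sorted(bad)}")
    return [t for t in CONTENT_ORDER if t in contents]


def _attr_clause(phrases: list[str]) -> str:
    if not phrases:
        return ""
    if len(phrases) == 1:
        return f" showing {phrases[0]}"
    return " showing " + " , ".join(phrases[:-1]) + f" and {phrases[-1]}"


def realize_sentence(
    contents: frozenset[str],
    grammar: GrammarConfig,
    rng: np.random.Generator,
) -> str:
    """Sample one surface sentence realizing exactly `contents`."""
    ordered = order_contents(contents)
    opacity = [t for t in ordered if t in OPACITY_CLASSES]
    if len(opacity) != 1:
        raise ValueError(f"content set must contain exactly one opacity token, got {opacity}")
    if SEG_TOKEN not in contents or SIZE_TOKEN not in contents:
        raise ValueError("content set must contain the <SEG> and <SIZE> placeholders")
    op_phrase = grammar.lexicon[opacity[0]][rng.integers(len(grammar.lexicon[opacity[0]]))]
    binaries = [t for t in ordered if t in BINARY_CLASSES]
    phrases = [
        grammar.lexicon[t][rng.integers(len(grammar.lexicon[t]))] for t in binaries
    ]
    attrs = _attr_clause(phrases)
    template = int(rng.integers(grammar.n_templates))
    if template == 0:
        return f"a {SIZE_TOKEN} {op_phrase} nodule{attrs} is seen in {SEG_TOKEN} ."
    return f"in {SEG_TOKEN} , a {SIZE_TOKEN} {op_phrase} nodule{attrs} is noted ."


def _phrase_index(grammar: GrammarConfig) -> list[tuple[tuple[str, ...], str]]:
    """(phrase words, token) pairs, longest phrases first."""
    idx = [
        (tuple(phrase.split()), token)
        for token, phrases in grammar.lexicon.items()
        for phrase in phrases
    ]
    idx.sort(key=lambda kv: -len(kv[0]))
    return idx


def extract_contents(sentence: str, grammar: GrammarConfig | None = None) -> frozenset[str]:
    """Invert a sentence to its content set by longest-first phrase matching."""
    grammar = grammar or GrammarConfig()
    words = sentence.split()
    index = _phrase_index(grammar)
    found: set[str] = set()
    i = 0
    while i < len(words):
        if words[i] in (SEG_TOKEN, SIZE_TOKEN):
            found.add(words[i])
            i += 1
            continue
        for phrase, token in index:
            if tuple(words[i : i + len(phrase)]) == phrase:
                found.add(token)
                i += len(phrase)
                break
        else:
            i += 1
    return frozenset(found)


def is_grammatical(sentence: str, grammar: GrammarConfig | None = None) -> bool:
    """Membership in the grammar: some template + realization choice must
    reproduce the sentence verbatim."""
    grammar = grammar or GrammarConfig()
    contents = extract_contents(sentence, grammar)
    opacity = [t for t in CONTENT_ORDER if t in contents and t in OPACITY_CLASSES]
    if len(opacity) != 1 or SEG_TOKEN not in contents or SIZE_TOKEN not in contents:
        return False
    binaries = [t for t in CONTENT_ORDER if t in contents and t in BINARY_CLASSES]
    choices = [grammar.lexicon[opacity[0]]] + [grammar.lexicon[t] for t in binaries]
    for picks in itertools.product(*choices):
        op_phrase, phrases = picks[0], list(picks[1:])
        attrs = _attr_clause(phrases)
        candidates = [
            f"a {SIZE_TOKEN} {op_phrase} nodule{attrs} is seen in {SEG_TOKEN} .",
            f"in {SEG_TOKEN} , a {SIZE_TOKEN} {op_phrase} nodule{attrs} is noted .",
        ][: grammar.n_templates]
        if sentence in candidates:
            return True
    return False


def make_description_corpus(
    grammar: GrammarConfig,
    n_pairs: int,
    unique_contents: bool = True,
) -> list[tuple[frozenset[str], str]]:
    """Generate (content set, sentence) pairs; reproducible via grammar.seed.

    With `unique_contents` the content sets are pairwise distinct (required
    for combination-disjoint train/validation/test splits); requesting more
    unique combinations than the grammar supports raises.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if unique_contents and n_pairs > grammar.capacity():
        raise ValueError(
            f"requested {n_pairs} unique combinations but the grammar supports "
            f"only {grammar.capacity()}"
        )
    rng = np.random.default_rng(grammar.seed)
    pairs: list[tuple[frozenset[str], str]] = []
    seen: set[frozenset[str]] = set()
    n_bin = len(BINARY_CLASSES)
    while len(pairs) < n_pairs:
        opacity = OPACITY_CLASSES[rng.integers(len(OPACITY_CLASSES))]
        k = int(rng.integers(0, grammar.max_findings + 1))
        picks = rng.choice(n_bin, size=k, replace=False)
        contents = content_set(opacity, *(BINARY_CLASSES[i] for i in picks))
        if unique_contents:
            if contents in seen:
                continue
            seen.add(contents)
        sentence = realize_sentence(contents, grammar, rng)
        pairs.append((contents, sentence))
    return pairs


def split_corpus(
    pairs: list[tuple[frozenset[str], str]],
    n_val: int,
    n_test: int,
    seed: int = 0,
) -> tuple[list, list, list]:
    """Split so that no content combination is shared across splits."""
    combos = {c for c, _ in pairs}
    if len(combos) != len(pairs):
        raise ValueError("split requires unique content combinations per pair")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    test = [pairs[i] for i in order[:n_test]]
    val = [pairs[i] for i in order[n_test : n_test + n_val]]
    train = [pairs[i] for i in order[n_test + n_val :]]
    return train, val, test
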