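"""Lexicon, phonetic feature scheme, word-feature matrix and priors.

The recognition models operate over a closed 24-word vocabulary of
consonant-vowel-consonant (CVC) monosyllables organised as 8 triples of
phonologically similar words that share their vowel (e.g. thing / sing /
sit).  Each word is coded as a 37-dimensional binary articulatory feature
vector: 13 features for each consonant position (place 6, manner 3,
nasality 2, voicing 2) and 11 for the vowel (height 5, backness 2,
rounding 2, length 2).  Within every (position, group) block exactly one
feature is active, so each word row has 12 ones and block activations can
be read as probability distributions.

The per-segment feature assignments shipped here are a documented
reconstruction of citation-form Southern British English transcriptions
(non-rhotic; diphthongs coded by the height/backness of their nucleus,
with length = long).  They are data, not code: an alternative table can
be supplied to :func:`word_feature_matrix` or loaded from CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FeatureGroup",
    "FeatureScheme",
    "Word",
    "Lexicon",
    "WordFeatureMatrix",
    "PriorVector",
    "build_feature_scheme",
    "default_lexicon",
    "default_segment_table",
    "word_feature_matrix",
    "make_prior",
    "MATCH_PRIOR_BASE",
    "WRITTEN_ONLY_ACCURACY",
    "N_WORDS",
    "N_FEATURES",
]

N_WORDS = 24
N_FEATURES = 37

#: Probability that the spoken word matches the written cue, from the
#: design's trial arithmetic: 288 match trials out of 288 + 48 mismatch.
MATCH_PRIOR_BASE = 288 / 336

#: Group-mean proportion correct when reporting the written word alone;
#: scales the match prior to account for imperfect cue uptake.
WRITTEN_ONLY_ACCURACY = 0.8214

_CONSONANT_GROUPS = (
    ("place", ("bilabial", "labiodental", "dental", "alveolar", "palato-alveolar", "velar")),
    ("manner", ("stop", "sibilant", "non-sibilant")),
    ("nasality", ("nasal", "oral")),
    ("voicing", ("voiceless", "voiced")),
)

_VOWEL_GROUPS = (
    ("height", ("high", "mid-high", "mid", "mid-low", "low")),
    ("backness", ("front", "back")),
    ("rounding", ("rounded", "unrounded")),
    ("length", ("long", "short")),
)


@dataclass(frozen=True)
class FeatureGroup:
    """One block of mutually exclusive features at one syllable position."""

    position: str  # "C1", "V" or "C2"
    name: str  # e.g. "place"
    labels: tuple[str, ...]
    start: int  # first column index in the 37-dim layout

    @property
    def size(self) -> int:
        return len(self.labels)

    @property
    def slice(self) -> slice:
        return slice(self.start, self.start + self.size)


@dataclass(frozen=True)
class FeatureScheme:
    """The fixed grouped layout of the 37 binary phonetic features."""

    groups: tuple[FeatureGroup, ...]

    @property
    def total_dims(self) -> int:
        return sum(g.size for g in self.groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def groups_at(self, position: str) -> tuple[FeatureGroup, ...]:
        return tuple(g for g in self.groups if g.position == position)

    def column_labels(self) -> list[str]:
        return [f"{g.position}:{g.name}:{lab}" for g in self.groups for lab in g.labels]

    def block_slices(self) -> list[slice]:
        return [g.slice for g in self.groups]


def build_feature_scheme() -> FeatureScheme:
    """The 37-dimensional grouped feature layout for CVC syllables.

    Column order is C1 (place, manner, nasality, voicing), V (height,
    backness, rounding, length), C2 (as C1); 13 + 11 + 13 = 37.
    """
    groups: list[FeatureGroup] = []
    start = 0
    for position in ("C1", "V", "C2"):
        spec = _VOWEL_GROUPS if position == "V" else _CONSONANT_GROUPS
        for name, labels in spec:
            groups.append(FeatureGroup(position, name, tuple(labels), start))
            start += len(labels)
    return FeatureScheme(tuple(groups))


@dataclass(frozen=True)
class Word:
    orthography: str
    triple: int  # 1-8; triple-mates share the vowel
    c1: str
    v: str
    c2: str

    def segment(self, position: str) -> str:
        return {"C1": self.c1, "V": self.v, "C2": self.c2}[position]


@dataclass(frozen=True)
class Lexicon:
    words: tuple[Word, ...]

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)

    def __getitem__(self, i: int) -> Word:
        return self.words[i]

    def index(self, orthography: str) -> int:
        for i, w in enumerate(self.words):
            if w.orthography == orthography:
                return i
        raise KeyError(orthography)

    def orthographies(self) -> list[str]:
        return [w.orthography for w in self.words]

    def triples(self) -> np.ndarray:
        return np.array([w.triple for w in self.words])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "word": [w.orthography for w in self.words],
                "triple": [w.triple for w in self.words],
                "C1": [w.c1 for w in self.words],
                "V": [w.v for w in self.words],
                "C2": [w.c2 for w in self.words],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Lexicon":
        return cls(
            tuple(
                Word(str(r.word), int(r.triple), str(r.C1), str(r.V), str(r.C2))
                for r in df.itertuples()
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Lexicon":
        return cls.from_frame(pd.read_csv(path))


# word, triple, C1, V, C2 — segments in an ASCII transcription
# (th=dental fricative, sh=postalveolar fricative, ng=velar nasal;
#  ih=KIT, aa=PALM/BATH, iy=FLEECE, ao=THOUGHT/NORTH, uw=GOOSE,
#  ey=FACE, ay=PRICE, ow=GOAT).
_WORDS = (
    ("thing", 1, "th", "ih", "ng"),
    ("sing", 1, "s", "ih", "ng"),
    ("sit", 1, "s", "ih", "t"),
    ("bath", 2, "b", "aa", "th"),
    ("path", 2, "p", "aa", "th"),
    ("pass", 2, "p", "aa", "s"),
    ("deep", 3, "d", "iy", "p"),
    ("peep", 3, "p", "iy", "p"),
    ("peak", 3, "p", "iy", "k"),
    ("pork", 4, "p", "ao", "k"),
    ("fork", 4, "f", "ao", "k"),
    ("fort", 4, "f", "ao", "t"),
    ("doom", 5, "d", "uw", "m"),
    ("tomb", 5, "t", "uw", "m"),
    ("tooth", 5, "t", "uw", "th"),
    ("take", 6, "t", "ey", "k"),
    ("shake", 6, "sh", "ey", "k"),
    ("shape", 6, "sh", "ey", "p"),
    ("kite", 7, "k", "ay", "t"),
    ("tight", 7, "t", "ay", "t"),
    ("type", 7, "t", "ay", "p"),
    ("zone", 8, "z", "ow", "n"),
    ("moan", 8, "m", "ow", "n"),
    ("mode", 8, "m", "ow", "d"),
)


def default_lexicon() -> Lexicon:
    """The fixed 24-word stimulus set, in printed triple order."""
    return Lexicon(tuple(Word(*w) for w in _WORDS))


# segment -> {group name -> label}; nasal stops are coded manner=stop.
_CONSONANTS: dict[str, dict[str, str]] = {
    "p": {"place": "bilabial", "manner": "stop", "nasality": "oral", "voicing": "voiceless"},
    "b": {"place": "bilabial", "manner": "stop", "nasality": "oral", "voicing": "voiced"},
    "t": {"place": "alveolar", "manner": "stop", "nasality": "oral", "voicing": "voiceless"},
    "d": {"place": "alveolar", "manner": "stop", "nasality": "oral", "voicing": "voiced"},
    "k": {"place": "velar", "manner": "stop", "nasality": "oral", "voicing": "voiceless"},
    "m": {"place": "bilabial", "manner": "stop", "nasality": "nasal", "voicing": "voiced"},
    "n": {"place": "alveolar", "manner": "stop", "nasality": "nasal", "voicing": "voiced"},
    "ng": {"place": "velar", "manner": "stop", "nasality": "nasal", "voicing": "voiced"},
    "f": {"place": "labiodental", "manner": "non-sibilant", "nasality": "oral", "voicing": "voiceless"},
    "th": {"place": "dental", "manner": "non-sibilant", "nasality": "oral", "voicing": "voiceless"},
    "s": {"place": "alveolar", "manner": "sibilant", "nasality": "oral", "voicing": "voiceless"},
    "z": {"place": "alveolar", "manner": "sibilant", "nasality": "oral", "voicing": "voiced"},
    "sh": {"place": "palato-alveolar", "manner": "sibilant", "nasality": "oral", "voicing": "voiceless"},
}

_VOWELS: dict[str, dict[str, str]] = {
    "ih": {"height": "high", "backness": "front", "rounding": "unrounded", "length": "short"},
    "aa": {"height": "low", "backness": "back", "rounding": "unrounded", "length": "long"},
    "iy": {"height": "high", "backness": "front", "rounding": "unrounded", "length": "long"},
    "ao": {"height": "mid-low", "backness": "back", "rounding": "rounded", "length": "long"},
    "uw": {"height": "high", "backness": "back", "rounding": "rounded", "length": "long"},
    "ey": {"height": "mid-high", "backness": "front", "rounding": "unrounded", "length": "long"},
    "ay": {"height": "low", "backness": "front", "rounding": "unrounded", "length": "long"},
    "ow": {"height": "mid", "backness": "back", "rounding": "rounded", "length": "long"},
}


def default_segment_table() -> dict[str, dict[str, str]]:
    """The shipped segment -> per-group feature-label assignment."""
    table = dict(_CONSONANTS)
    table.update(_VOWELS)
    return table


def segment_table_to_csv(table: Mapping[str, Mapping[str, str]], path: str | Path) -> None:
    rows = [{"segment": seg, **assign} for seg, assign in table.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def segment_table_from_csv(path: str | Path) -> dict[str, dict[str, str]]:
    df = pd.read_csv(path)
    table: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        assign = {k: v for k, v in row.items() if k != "segment" and pd.notna(v)}
        table[str(row["segment"])] = {str(k): str(v) for k, v in assign.items()}
    return table


@dataclass(frozen=True)
class WordFeatureMatrix:
    """24 x 37 binary word-to-feature map, used as connection weights.

    ``matrix[w]`` is word ``w``'s clear feature vector; the transpose maps
    feature activations back to lexical activations.
    """

    matrix: np.ndarray
    scheme: FeatureScheme
    lexicon: Lexicon

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.lexicon), self.scheme.total_dims):
            raise ValueError(f"matrix shape {m.shape} inconsistent with lexicon/scheme")

    @property
    def W(self) -> np.ndarray:
        return self.matrix

    def row(self, word: int | str) -> np.ndarray:
        if isinstance(word, str):
            word = self.lexicon.index(word)
        return self.matrix[word]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.astype(int),
            index=self.lexicon.orthographies(),
            columns=self.scheme.column_labels(),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def word_feature_matrix(
    lexicon: Lexicon | None = None,
    scheme: FeatureScheme | None = None,
    segment_table: Mapping[str, Mapping[str, str]] | None = None,
) -> WordFeatureMatrix:
    """Build the binary word-feature transformation matrix.

    Raises
    ------
    KeyError
        if a segment used in the lexicon is missing from the table.
    ValueError
        if a segment does not assign exactly one label in every group
        applicable at its position.
    """
    lexicon = lexicon if lexicon is not None else default_lexicon()
    scheme = scheme if scheme is not None else build_feature_scheme()
    table = segment_table if segment_table is not None else default_segment_table()

    matrix = np.zeros((len(lexicon), scheme.total_dims))
    for w, word in enumerate(lexicon):
        for group in scheme.groups:
            seg = word.segment(group.position)
            if seg not in table:
                raise KeyError(f"segment {seg!r} (word {word.orthography!r}) missing from segment table")
            assign = table[seg]
            if group.name not in assign:
                raise ValueError(
                    f"segment {seg!r} assigns no label in group {group.name!r}"
                )
            label = assign[group.name]
            if label not in group.labels:
                raise ValueError(
                    f"segment {seg!r} assigns unknown label {label!r} in group {group.name!r}"
                )
            matrix[w, group.start + group.labels.index(label)] = 1.0
    return WordFeatureMatrix(matrix, scheme, lexicon)


@dataclass(frozen=True)
class PriorVector:
    """A probability distribution over the 24 lexical candidates."""

    probabilities: np.ndarray
    kind: str = "neutral"
    target: int | None = None

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1:
            raise ValueError("prior must be a vector")
        if np.any(p < 0):
            raise ValueError("prior entries must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"prior must sum to 1 (got {p.sum()!r})")

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.probabilities, dtype=float)


def make_prior(
    kind: str,
    target: int | None = None,
    match_base: float = MATCH_PRIOR_BASE,
    report_accuracy: float = 1.0,
    n_words: int = N_WORDS,
) -> PriorVector:
    """Lexical prior for a trial.

    ``neutral`` is uniform (1/24 each).  ``match`` places probability
    ``match_base * report_accuracy`` on the cued word — the base rate of
    matching trials in the design scaled by how reliably the written cue
    is taken up — and spreads the remainder equally over the other words.
    """
    if kind == "neutral":
        return PriorVector(np.full(n_words, 1.0 / n_words), kind="neutral")
    if kind == "match":
        if target is None:
            raise ValueError("kind='match' requires a target word index")
        if not (0.0 <= match_base <= 1.0 and 0.0 <= report_accuracy <= 1.0):
            raise ValueError("match_base and report_accuracy must lie in [0, 1]")
        p_target = match_base * report_accuracy
        p = np.full(n_words, (1.0 - p_target) / (n_words - 1))
        p[target] = p_target
        return PriorVector(p, kind="match", target=int(target))
    raise ValueError(f"unknown prior kind {kind!r}")
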