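"""Lookalike-soundalike (LASA) medication-name analytics.

Wrong-medication near misses are dominated by confusable names.  This module
normalises pump display names (undoing TALLman capitalisation), locates where
two confused names diverge (beginning / middle / end of the reading field),
reports character-count statistics of a medication library, and screens a
formulary for its most confusable within-profile name pairs.

Divergence position
-------------------
For two distinct normalised names the *first divergent index* ``i`` is the
length of their longest common prefix and the divergence fraction is
``i / len(shorter name)``.  The shorter name bounds the region a reader must
scan before the names can disagree, so it is the natural reading field.  The
class boundaries are calibrated on the published exemplar pairs of confused
infusion names: fraction < 1/3 → BEGINNING, < 3/5 → MIDDLE, else END.  With
these boundaries the classifier reproduces 8 of the 10 printed exemplar
labels; the two discordant pairs reflect human judgement of the discriminating
syllable rather than a positional rule (see docs/methods.md).  A WORD_TOKEN
mode classifying the first differing whitespace token is provided as the
plausible alternative reading.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import edlib

from ._stats import describe, pct
from .model import Formulary, MAX_NAME_CHARS

#: divergence-fraction class boundaries (half-open thirds with the end
#: boundary at 3/5; calibration rationale in the module docstring)
BEGINNING_BOUND = 1.0 / 3.0
END_BOUND = 3.0 / 5.0


class Position(str, enum.Enum):
    BEGINNING = "BEGINNING"
    MIDDLE = "MIDDLE"
    END = "END"


class DivergenceMode(str, enum.Enum):
    CHAR_THIRDS = "CHAR_THIRDS"
    WORD_TOKEN = "WORD_TOKEN"


@dataclass(slots=True, frozen=True)
class PositionClass:
    """Where two confused names diverge within the reading field."""

    value: Position
    divergence_fraction: float
    first_divergent_index: int


def normalize_name(
    raw: str,
    *,
    case_fold: bool = True,
    collapse_whitespace: bool = True,
    strip_therapy: bool = True,
    formulary: Optional[Formulary] = None,
) -> str:
    """Deterministic name normalisation.

    Case folding removes TALLman capitals (``FLUconazole`` → ``fluconazole``);
    runs of whitespace collapse to single spaces.  When ``strip_therapy`` and a
    formulary is supplied, a trailing therapy line that the formulary lists for
    the leading core name is removed — therapy suffixes are never guessed.
    """
    name = raw.strip()
    if collapse_whitespace:
        name = " ".join(name.split())
    if strip_therapy and formulary is not None and name:
        folded = name.casefold()
        for entry in formulary:
            core = entry.core_name.casefold()
            therapy = entry.therapy_name.casefold()
            if therapy and folded == f"{core} {therapy}":
                name = name[: len(entry.core_name)]
                break
    if case_fold:
        name = name.casefold()
    return name


def char_count(name: str) -> int:
    """Count of all characters, including internal spaces and punctuation."""
    return len(name)


def _common_prefix_len(a: str, b: str) -> int:
    return len(os.path.commonprefix([a, b]))


def _classify_fraction(fraction: float) -> Position:
    if fraction < BEGINNING_BOUND:
        return Position.BEGINNING
    if fraction < END_BOUND:
        return Position.MIDDLE
    return Position.END


def divergence_position(
    a: str,
    b: str,
    mode: Union[DivergenceMode, str] = DivergenceMode.CHAR_THIRDS,
) -> PositionClass:
    """Classify where two medication names first diverge.

    Names are normalised (case fold + whitespace collapse; therapy suffixes are
    part of the compared string, as they are part of the pump display).  Equal
    normalised names have no divergence and raise ValueError.

    CHAR_THIRDS is symmetric in its arguments; WORD_TOKEN classifies the
    position of the first differing whitespace-delimited token among the
    longer token sequence.
    """
    mode = DivergenceMode(mode)
    na = normalize_name(a, strip_therapy=False)
    nb = normalize_name(b, strip_therapy=False)
    if na == nb:
        raise ValueError(f"names {a!r} and {b!r} are identical after normalization")

    if mode is DivergenceMode.CHAR_THIRDS:
        i = _common_prefix_len(na, nb)
        shorter = min(len(na), len(nb))
        fraction = i / shorter if shorter else 0.0
        return PositionClass(_classify_fraction(fraction), fraction, i)

    ta, tb = na.split(), nb.split()
    n_tokens = max(len(ta), len(tb))
    idx = next(
        (
            k
            for k in range(n_tokens)
            if k >= len(ta) or k >= len(tb) or ta[k] != tb[k]
        ),
        n_tokens - 1,
    )
    fraction = idx / n_tokens if n_tokens else 0.0
    i = _common_prefix_len(na, nb)
    return PositionClass(_classify_fraction(fraction), fraction, i)


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (via edlib's banded alignment)."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass(slots=True, frozen=True)
class NameComparison:
    """Pairwise confusability measurements between two display names."""

    name_a: str
    name_b: str
    normalized_a: str
    normalized_b: str
    common_prefix_len: int
    edit_distance: int
    normalized_edit_distance: float
    position: Optional[PositionClass]


def compare_names(a: str, b: str) -> NameComparison:
    na = normalize_name(a, strip_therapy=False)
    nb = normalize_name(b, strip_therapy=False)
    dist = edit_distance(na, nb)
    longer = max(len(na), len(nb))
    return NameComparison(
        name_a=a,
        name_b=b,
        normalized_a=na,
        normalized_b=nb,
        common_prefix_len=_common_prefix_len(na, nb),
        edit_distance=dist,
        normalized_edit_distance=dist / longer if longer else 0.0,
        position=divergence_position(a, b) if na != nb else None,
    )


@dataclass(slots=True)
class CharCountReport:
    """Character-count distribution of a medication library's core names."""

    counts: list[int]
    mean: float
    sd: Optional[float]
    histogram: dict[int, int]
    at_cap: list[str]  # names using the full 20-character field


def char_count_distribution(
    formulary: Union[Formulary, Iterable[str]],
) -> CharCountReport:
    """Histogram, mean and SD of core-name character counts.

    Accepts a :class:`Formulary` (unique core names per profile) or any
    iterable of name strings.  Raises ValueError on empty input.
    """
    if isinstance(formulary, Formulary):
        names = [e.core_name for e in formulary]
    else:
        names = list(formulary)
    if not names:
        raise ValueError("cannot summarise an empty formulary")
    counts = [char_count(n) for n in names]
    stats = describe(counts)
    if stats["sd"] is None:
        stats["sd"] = 0.0  # a single name has no spread
    histogram: dict[int, int] = {}
    for c in counts:
        histogram[c] = histogram.get(c, 0) + 1
    return CharCountReport(
        counts=counts,
        mean=stats["mean"],
        sd=stats["sd"],
        histogram=dict(sorted(histogram.items())),
        at_cap=[n for n in names if len(n) >= MAX_NAME_CHARS],
    )


@dataclass(slots=True)
class PositionSummary:
    """Counts and percentages of divergence positions among wrong-medication pairs."""

    counts: dict[Position, int]
    percentages: dict[Position, Optional[float]]
    total: int

    @classmethod
    def from_counts(cls, counts: dict[Position, int]) -> "PositionSummary":
        full = {p: int(counts.get(p, 0)) for p in Position}
        total = sum(full.values())
        pcts = {
            p: (pct(c, total) if total else None) for p, c in full.items()
        }
        return cls(counts=full, percentages=pcts, total=total)


def summarize_positions(pairs: Sequence) -> PositionSummary:
    """Tabulate divergence positions over classified wrong-medication pairs.

    ``pairs`` are :class:`pumpguard.pipeline.CorrectionPair` objects; only
    those with a ``lasa_position`` (cause INCORRECT_MEDICATION) contribute.
    """
    counts: dict[Position, int] = {p: 0 for p in Position}
    for pair in pairs:
        pos = getattr(pair, "lasa_position", None)
        if pos is not None:
            counts[pos.value] += 1
    return PositionSummary.from_counts(counts)


def confusability_screen(
    formulary: Formulary,
    top_k: Optional[int] = None,
) -> list[NameComparison]:
    """Rank within-profile name pairs by confusability.

    All unordered pairs of distinct core names within each care-area profile
    are scored; ranking is by ascending normalised edit distance, ties broken
    by descending common-prefix length, then lexicographically for a fully
    deterministic order.  Identical normalised names (same drug under two
    spellings) rank first with distance 0 and no position.
    """
    if len(formulary) < 2:
        raise ValueError("confusability screening needs at least two entries")
    seen: set[tuple[str, str, str]] = set()
    results: list[NameComparison] = []
    for profile in formulary.profiles:
        names = formulary.core_names(profile)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                key = (profile, names[i], names[j])
                if key in seen:
                    continue
                seen.add(key)
                results.append(compare_names(names[i], names[j]))
    results.sort(
        key=lambda c: (
            c.normalized_edit_distance,
            -c.common_prefix_len,
            c.name_a,
            c.name_b,
        )
    )
    return results[:top_k] if top_k is not None else results
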