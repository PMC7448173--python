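"""Name normalisation, divergence position, character counts, confusability."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from pumpguard import (
    Formulary,
    MedicationEntry,
    Position,
    char_count,
    char_count_distribution,
    compare_names,
    confusability_screen,
    divergence_position,
    edit_distance,
    normalize_name,
)
from pumpguard.lasa import DivergenceMode

NAMES = st.text(alphabet="abcdxyz -.%0123456789", min_size=1, max_size=20).map(str.strip).filter(bool)


# ---- normalisation -------------------------------------------------------


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("FLUconazole", "fluconazole"),
        ("", ""),
        ("Insulin  high   non-ICU", "insulin high non-icu"),
        ("  PACLitaxel ", "paclitaxel"),
    ],
)
def test_normalize_name(raw, expected):
    assert normalize_name(raw) == expected


def test_normalize_strips_known_therapy_suffix():
    form = Formulary(
        [MedicationEntry(core_name="Midazolam", therapy_name="Status epilepticus")]
    )
    assert normalize_name("Midazolam Status epilepticus", formulary=form) == "midazolam"
    # unknown suffixes are never guessed away
    assert normalize_name("Midazolam bolus", formulary=form) == "midazolam bolus"


@settings(derandomize=True, max_examples=100)
@given(NAMES)
def test_normalize_is_idempotent(name):
    once = normalize_name(name)
    assert normalize_name(once) == once


# ---- divergence position -------------------------------------------------


@pytest.mark.parametrize(
    "a, b, position",
    [
        ("Abatacept <60 kg", "Acetaminophen", Position.BEGINNING),
        ("Ceftazidime", "Ceftriaxone", Position.MIDDLE),
        ("0.45% NS", "0.9% Normal saline", Position.BEGINNING),
        ("xxxxxxxxxA", "xxxxxxxxxB", Position.END),
    ],
)
def test_divergence_position_examples(a, b, position):
    result = divergence_position(a, b)
    assert result.value is position


def test_divergence_details_for_ceftazidime_ceftriaxone():
    result = divergence_position("Ceftazidime", "Ceftriaxone")
    assert result.first_divergent_index == 4  # common prefix "ceft"
    assert result.divergence_fraction == pytest.approx(4 / 11)


def test_identical_names_have_no_divergence():
    with pytest.raises(ValueError, match="identical"):
        divergence_position("Heparin", "HEPARIN")


def test_word_token_mode_classifies_by_token_position():
    result = divergence_position(
        "Sodium bicarbonate", "Sodium phosphate", DivergenceMode.WORD_TOKEN
    )
    assert result.value is Position.MIDDLE  # second of two tokens
    first = divergence_position("Abatacept <60 kg", "Acetaminophen", "WORD_TOKEN")
    assert first.value is Position.BEGINNING


@settings(derandomize=True, max_examples=200)
@given(NAMES, NAMES)
def test_divergence_symmetric_and_exhaustive(a, b):
    if normalize_name(a, strip_therapy=False) == normalize_name(b, strip_therapy=False):
        return
    ab = divergence_position(a, b)
    ba = divergence_position(b, a)
    assert ab == ba  # symmetry in CHAR_THIRDS mode
    assert ab.value in tuple(Position)  # exactly one class, always
    assert 0.0 <= ab.divergence_fraction <= 1.0


# ---- character counts ----------------------------------------------------


@settings(derandomize=True, max_examples=50)
@given(st.integers(min_value=0, max_value=200))
def test_char_count_equals_length(n):
    assert char_count("x" * n) == n


def test_char_count_counts_spaces_and_punctuation():
    assert char_count("Cantuzumab mertansine") == 21
    assert char_count("0.45% NS") == 8
    assert char_count("") == 0


def test_char_count_distribution_arithmetic():
    single = char_count_distribution(["Noradrenaline"])
    assert single.mean == 13
    assert single.sd == 0.0
    two = char_count_distribution(["Talizumab", "Cantuzumab mertansin "])
    assert two.mean == 15
    with pytest.raises(ValueError, match="empty"):
        char_count_distribution([])


def test_char_count_distribution_flags_names_at_cap():
    report = char_count_distribution(["Ceftazidime-Continuo", "Heparin"])
    assert report.at_cap == ["Ceftazidime-Continuo"]
    assert report.histogram == {7: 1, 20: 1}


# ---- confusability screening --------------------------------------------


def _brute_levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@settings(derandomize=True, max_examples=200)
@given(NAMES, NAMES)
def test_edit_distance_matches_dp_oracle(a, b):
    assert edit_distance(a, b) == _brute_levenshtein(a, b)
    assert (edit_distance(a, b) == 0) == (a == b)


def test_sister_monoclonals_rank_most_confusable():
    names = [
        "Cantuzumab mertansin",
        "Cantuzumab ravtansin",
        "Altumomab pentetate",
        "Talizumab",
        "Tanezumab",
        "Trastuzumab",
        "Vadastuximab talirin",
        "Heparin",
        "Midazolam",
        "Noradrenaline",
    ]
    form = Formulary([MedicationEntry(core_name=n) for n in names])
    ranked = confusability_screen(form)
    top = ranked[0]
    assert {top.name_a, top.name_b} == {"Cantuzumab mertansin", "Cantuzumab ravtansin"}
    assert top.common_prefix_len == 11  # "cantuzumab " including the space

    # full ranking agrees with a brute-force all-pairs sort
    import itertools

    def norm(n):
        return normalize_name(n, strip_therapy=False)

    brute = []
    for a, b in itertools.combinations(sorted(names), 2):
        na, nb = norm(a), norm(b)
        d = _brute_levenshtein(na, nb)
        import os

        prefix = len(os.path.commonprefix([na, nb]))
        brute.append((d / max(len(na), len(nb)), -prefix, a, b))
    brute.sort()
    expected = [(a, b) for _, _, a, b in brute]
    assert [(c.name_a, c.name_b) for c in ranked] == expected


def test_screening_needs_two_entries():
    form = Formulary([MedicationEntry(core_name="Heparin")])
    with pytest.raises(ValueError):
        confusability_screen(form)


def test_compare_names_invariants():
    cmp_ = compare_names("Cefazolin", "Ceftazidime")
    assert cmp_.common_prefix_len <= min(len(cmp_.normalized_a), len(cmp_.normalized_b))
    assert cmp_.edit_distance > 0
    assert cmp_.position is not None
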