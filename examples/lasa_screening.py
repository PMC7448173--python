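"""Screen a small formulary for confusable (LASA) medication-name pairs.

Classifies where published exemplar pairs of confused names diverge
(beginning / middle / end of the reading field), then ranks all within-profile
pairs of a demo formulary by confusability and summarises its character-count
distribution — the kind of screen a pharmacy can run when curating a DERS
library.
"""

from pumpguard import (
    char_count_distribution,
    confusability_screen,
    default_formulary,
    divergence_position,
    normalize_name,
)

pairs = [
    ("Abatacept <60 kg", "Acetaminophen"),
    ("Ceftazidime", "Ceftriaxone"),
    ("Flucloxacillin", "FLUconazole"),
    ("Ceftazidime-Continuo", "Ceftazidime-extended"),
]
print("where do confused names diverge?")
for a, b in pairs:
    pos = divergence_position(a, b)
    print(f"  {a!r} vs {b!r}: {pos.value.value} "
          f"(first divergent char {pos.first_divergent_index}, "
          f"fraction {pos.divergence_fraction:.2f})")

print(f"\nTALLman normalisation: 'FLUconazole' -> {normalize_name('FLUconazole')!r}")

form = default_formulary()
ranked = confusability_screen(form, top_k=5)
print(f"\ntop confusable pairs among {len(form)} formulary names:")
for i, c in enumerate(ranked, 1):
    print(f"  {i}. {c.name_a!r} vs {c.name_b!r} — edit distance {c.edit_distance}, "
          f"common prefix {c.common_prefix_len}")

report = char_count_distribution(form)
print(f"\nname lengths: mean {report.mean:.2f} characters (SD {report.sd:.2f}); "
      f"{len(report.at_cap)} name(s) already at the 20-character pump cap")
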